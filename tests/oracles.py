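"""Independent brute-force oracles for the path-model algebra.

These enumerate directed paths and Wright traces explicitly (recursively over
the edge list), staying independent of the matrix-inverse implementation they
are used to check.
"""

from functools import lru_cache


def directed_paths(edges: dict, source: str, target: str):
    """All simple directed paths source -> ... -> target as edge-coef products."""
    out = []

    def walk(node, product, visited):
        if node == target:
            out.append(product)
            return
        for (s, t), b in edges.items():
            if s == node and t not in visited:
                walk(t, product * b, visited | {t})

    walk(source, 1.0, {source})
    return out


def path_sum(edges: dict, source: str, target: str) -> float:
    """Sum of coefficient products over all directed paths (1 if source==target)."""
    if source == target:
        return 1.0
    return sum(directed_paths(edges, source, target))


def indirect_effect(edges: dict, source: str, target: str) -> float:
    """Sum over directed paths of length >= 2 (i.e., excluding the direct edge)."""
    total = sum(directed_paths(edges, source, target))
    return total - edges.get((source, target), 0.0)


def implied_correlation(edges, psi, variables, i, j) -> float:
    """Wright trace enumeration: sum over (u, v) source pairs of
    psi_uv * pathsum(u -> i) * pathsum(v -> j)."""
    value = 0.0
    for u in variables:
        for v in variables:
            p = psi.get((u, v), psi.get((v, u), 0.0))
            if p == 0.0:
                continue
            value += p * path_sum(edges, u, i) * path_sum(edges, v, j)
    return value


def psi_from_fitted(model) -> dict:
    """Disturbance/exogenous (co)variance map of a fitted PathModel."""
    spec = model.spec_
    psi = {}
    for u in spec.exogenous:
        for v in spec.exogenous:
            psi[(u, v)] = 1.0 if u == v else float(model.exo_corr_.loc[u, v])
    for v in spec.endogenous:
        psi[(v, v)] = model.disturbance_.get(v, 1.0)
    return psi
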