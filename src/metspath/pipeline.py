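"""End-to-end pipeline: generate/load -> classify -> describe -> ANOVA -> SEM.

All artifacts land under one output directory and are written atomically
(write to a temporary file, then rename), and a manifest records the seed and
a SHA-256 hash of every artifact so that re-running a config can be checked
for bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .anova import two_way_anova
from .cohort import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .criteria import add_mets_columns
from .descriptives import table1
from .errors import ConfigError, EstimabilityError
from .sem import PathModelSpec, run_mets_sem

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ANOVA_VARIABLES = ["wc_cm", "sbp_mmhg", "dbp_mmhg", "fg_mgdl", "tg_mgdl", "hdl_mgdl"]


@dataclass
class RunConfig:
    """Pipeline run configuration (exactly one of input_csv / generator)."""

    out_dir: str
    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    seed: int | None = None
    subgroups: tuple = ("women", "men", "total")
    model_spec: str | None = None      # YAML path; None = packaged default
    alpha: float = 0.05
    sem_outcome: str = "count"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigError("provide exactly one of input_csv or generator")
        bad = set(self.subgroups) - {"women", "men", "total"}
        if bad:
            raise ConfigError(f"unknown subgroup(s): {sorted(bad)}")
        if self.generator is not None and self.seed is not None:
            self.generator.seed = int(self.seed)


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename into place."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _anova_table(classified: pd.DataFrame, subgroups) -> pd.DataFrame:
    masks = {
        "women": classified["sex"] == "F",
        "men": classified["sex"] == "M",
        "total": pd.Series(True, index=classified.index),
    }
    rows = []
    for name in subgroups:
        sub = classified[masks[name]]
        for var in ANOVA_VARIABLES:
            try:
                results = two_way_anova(sub[var], sub["age_group"], sub["bmi_band"])
            except EstimabilityError as exc:
                logger.warning("ANOVA for %s (%s) skipped: %s", var, name, exc)
                rows.append(dict(subgroup=name, variable=var, effect="error",
                                 F=float("nan"), p=float("nan"),
                                 eta2=float("nan"), eta2_band=str(exc)))
                continue
            for r in results:
                rows.append(dict(subgroup=name, variable=var, effect=r.effect,
                                 F=r.F, p=r.p, eta2=r.eta2, eta2_band=r.eta2_band))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        path = out / "cohort.csv"
        _atomic_write(path, lambda tmp: write_cohort(cohort, tmp))
        artifacts["cohort.csv"] = path
    else:
        cohort = read_cohort(config.input_csv)

    classified = add_mets_columns(cohort)

    desc = table1(classified)
    path = out / "descriptives.tsv"
    _atomic_write(path, lambda tmp: desc.to_csv(tmp, sep="\t", index=False))
    artifacts["descriptives.tsv"] = path

    anova_tab = _anova_table(classified, config.subgroups)
    path = out / "anova.tsv"
    _atomic_write(path, lambda tmp: anova_tab.to_csv(tmp, sep="\t", index=False))
    artifacts["anova.tsv"] = path

    spec = PathModelSpec.from_yaml(config.model_spec) if config.model_spec else None
    sem_results = run_mets_sem(
        cohort, spec=spec, subgroups=config.subgroups, outcome=config.sem_outcome
    )
    for name, res in sem_results.items():
        jpath = out / f"sem_{name}.json"
        _atomic_write(jpath, lambda tmp, r=res: r.model.to_json(tmp))
        artifacts[jpath.name] = jpath
        dpath = out / f"sem_{name}.dot"
        _atomic_write(
            dpath,
            lambda tmp, r=res: Path(tmp).write_text(r.model.to_dot(), encoding="utf-8"),
        )
        artifacts[dpath.name] = dpath
        epath = out / f"effects_{name}.tsv"
        _atomic_write(
            epath, lambda tmp, r=res: r.effects.to_csv(tmp, sep="\t", index=False)
        )
        artifacts[epath.name] = epath

    manifest = {
        "seed": config.generator.seed if config.generator is not None else config.seed,
        "alpha": config.alpha,
        "subgroups": list(config.subgroups),
        "files": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    path = out / "manifest.json"
    _atomic_write(
        path,
        lambda tmp: Path(tmp).write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        ),
    )
    return manifest
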