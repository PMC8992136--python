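# Two-level metabolic-syndrome path model: age -> BMI -> components -> status.
variables: [age, bmi, wc, sbp, dbp, fg, tg, hdl, mets]
exogenous: [age]
edges:
  - age -> bmi
  - age -> wc
  - bmi -> wc
  - age -> sbp
  - bmi -> sbp
  - age -> dbp
  - bmi -> dbp
  - age -> fg
  - bmi -> fg
  - age -> tg
  - bmi -> tg
  - age -> hdl
  - bmi -> hdl
  - wc -> mets
  - sbp -> mets
  - dbp -> mets
  - fg -> mets
  - tg -> mets
  - hdl -> mets
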