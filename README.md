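# pcsec

Proteome-constrained genome-scale models with an explicit protein secretory
pathway.

`pcsec` builds, solves and interrogates constraint-based cell models in which
every protein — metabolic enzyme, ribosome, secretory machinery, client —
must be synthesized, processed and paid for inside the model.  It is aimed at
systems biologists and metabolic engineers who want to study how the
secretory pathway (translocation, N-/O-glycosylation, disulfide-bond
formation, GPI anchoring, vesicle traffic, ER quality control and ERAD)
competes for cellular resources, and which machinery components to amplify
to improve recombinant protein secretion.

## The model

At a fixed specific growth rate μ (1/h) the model is a linear program over
nonnegative fluxes `v` (mmol/gDW/h) and protein abundances `a` (mmol/gDW):

```
S · v = 0                                   metabolite mass balance
v_syn,P − μ·a_P − v_deg,P = 0               per-protein balance (dilution)
v_j ≤ kcat_j · a_E(j)                       enzyme capacity
Σ_P L_P · v_transl,P ≤ k_ribo · a_ribo      ribosome capacity
Σ_clients w·v ≤ kcat_m · a_m                secretory machinery capacity
v_upt,t ≤ kcat_t · S/(S+KM_t) · a_t         transporter saturation at glucose S
Σ_P MW_P · a_P ≤ Φ                          proteome mass budget (+ per-compartment caps)
v_misfold,P = r_P · v_transl,P              misfold coupling
```

Each protein's synthesis/processing/degradation reactions are generated from
per-process templates driven by a protein-specific information matrix (PSIM):
amino-acid composition, localization, translocation mode, N-/O-glycosylation
site counts, disulfide bonds, GPI flag, transmembrane domains, misfolding
ratio and chaperone-retention rounds.  Growth maxima are found by binary
search on μ (feasibility is monotone), and the minimal glucose concentration
sustaining a given μ by binary search on S.

On top of the LP the package implements:

* **Glucose-series physiology** — overflow (Crabtree-style) metabolism and
  the high-/low-affinity transporter switch, with a secretory-cost account
  `cost_t(S) = unit_cost_t · V_glc / (kcat_t · S/(S+KM_t))` for each
  transporter.
* **Secretory-cost calculus** — direct cost (capacity-free glucose per mmol
  protein) and unit secretory cost (slope of minimal glucose uptake versus
  forced production at fixed μ, machinery shares included).
* **Misfolding experiments** — ERAD versus ER retention of a CPY-like
  substrate, chaperone (Kar2/Pdi1-analog) occupancy rounds, and misfolded
  protein accumulation under a retro-translocation cap.
* **Recombinant production curves** — maximum secretion across growth rates
  for cassettes with arbitrary PTM profiles, against a capacity-stripped
  basic-GEM contrast.
* **FSEOF-style target prediction** — native-protein abundance trajectories
  under enforced production, scored 1–4 (strict monotone rise, ≥1.2-fold
  change, reference-abundance band, monomer/no-paralog), with negative
  scores marking down-regulation candidates.
* **Feature importance** — a 10-tree random forest over PTM counts and
  amino-acid fractions with exact interventional tree-Shapley attributions.

A deterministic **toy cell** (62 proteins, all 12 secretory processes, two
glucose transporters, fermentation/respiration branch, heme pathway, CPY-like
client, seeded random client panel) makes every analysis runnable without
external data.

## Worked example

```python
import numpy as np
from pcsec import build_toy_cell, amylase_like
from pcsec.simulate import glucose_series
from pcsec.targeting import fseof_scan, select_targets

model = build_toy_cell()                       # deterministic toy cell

series = glucose_series(model, np.geomspace(0.01, 100, 20))
print(series.table[["S", "mu", "overflow", "share_hxt7"]].iloc[[0, 10, 19]])
#              S        mu   overflow  share_hxt7
# 0     0.010000  0.019348  -0.000000         1.0
# 10    1.274275  0.163147   8.131526         1.0
# 19  100.000000  0.258789  12.203600        -0.0

targets = select_targets(fseof_scan(model, amylase_like()), min_score=3)
print(targets[["id", "score", "fold"]].head(3))
#      id  score      fold
# 0  pdi1      4  1.486503
# 1  gost      4  1.451466
# 2  glys      4  1.451402
```

The series shows the fermentative overflow appearing above a critical growth
rate and the switch from the high-affinity transporter (`share_hxt7` 1 → 0)
as glucose rises; the target table ranks the disulfide isomerase and
glycosylation machinery as top amplification candidates for a
cysteine-enriched, glycosylated amylase-like cassette.

The same campaigns are available from the shell:

```
pcsec toy build --seed 7 --out model.json
pcsec simulate glucose-series model.json --out series.tsv
pcsec fseof run model.json --cassette amylase --out targets.tsv
pcsec cost table model.json --out costs.tsv
```

## Documentation

`docs/methods.md` describes the model assumptions, the template coefficient
defaults, the toy cell's parameter regime, numerical choices, and known
limitations.
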