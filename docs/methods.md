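# Methods

This note documents the model behind `pcsec`, the defaults it ships with,
what the toy cell does and does not emulate, and the numerical and design
choices a maintainer should know about.

## Model formulation

At a fixed specific growth rate μ the cell is a linear program.  Variables
are nonnegative: metabolic fluxes and generated per-protein reaction fluxes
(mmol/gDW/h), protein and enzyme-complex abundances (mmol/gDW), and — only
in retro-translocation-capped experiments — per-protein accumulation slacks.
Constraint classes:

* **Mass balance** over small metabolites and protein-form species.  Each
  protein travels a chain of forms (`nascent → er → er_ng → … → mature`);
  intermediate forms are at steady state, and the mature form of a
  cell-resident protein is diluted by growth (`v_in = μ·a`).  Secreted
  (extracellular) proteins drain through an explicit secretion flux instead
  of an abundance.
* **Capacity coupling**: every enzymatic metabolic flux is bounded by
  kcat × complex abundance; complexes draw their subunits through
  allocation rows (Σ stoichiometry × a_complex ≤ a_subunit).  Ribosome
  capacity is charged per translated residue, translocation per residue
  (plus a 50-residue surcharge per transmembrane domain), glycosylation and
  disulfide formation per site, vesicle traffic per molecule.  The
  biomass-protein pseudo-synthesis also occupies the ribosome.
* **Transporter saturation**: uptake ≤ kcat × S/(S+KM) × abundance at the
  extracellular glucose concentration S (g/L).
* **Proteome budget**: Σ MW·a ≤ Φ over all modeled cell-resident proteins,
  plus per-compartment caps (ER lumen, ER membrane) expressed as abundance
  mass caps — compartment volume/area constraints are proportional to
  protein mass at this resolution.
* **Misfold coupling**: the misfolding flux of a protein with misfolding
  ratio r is tied to its translation flux, `v_misfold = r·v_transl`.

Growth is not an LP variable: μ parameterizes the dilution and coupling
rows, and the maximum growth rate is found by binary search on feasibility
(default tolerance 1e-4 1/h, bracket `[0, μ_ub]` grown geometrically from
1/h).  The minimal sustaining glucose concentration for a target μ is a
second binary search, on S.

Units are fixed package-wide: fluxes mmol/gDW/h, abundances mmol/gDW, kcat
1/h, molecular masses g/mmol.  Amino-acid masses are average (not
monoisotopic) free-residue masses; a chain's MW is the residue sum minus
(L−1) waters.

## Template reactions

The secretory reconstruction uses a fixed 12-process vocabulary
(translation, translocation, ER/Golgi N- and O-glycosylation, disulfide
formation, GPI transfer, COPII/COPI, vesicle sorting, ERAD).  Each process
is one parameterized template; coefficients live in a single editable table
(`TemplateConfig`, TSV-serializable) with bases per protein, per residue or
per site.  Defaults — these are stated assumptions, not measurements:

| process | coefficient |
|---|---|
| translation (lumped initiation/elongation/termination) | 4 ATP-equivalents / residue |
| co-translational translocation | 1 GTP / residue |
| post-translational translocation | 1 ATP / residue |
| ER N-glycosylation | 1 glycan precursor / site |
| disulfide formation | 1 O2-derived oxidation equivalent / bond |
| O-mannosylation (ER and Golgi) | 1 mannose donor / site |
| GPI transfer | 1 anchor / protein |
| COPII / COPI / sorting | 1 GTP / protein |
| proteasomal toll (ERAD) | 1 ATP / 4 residues |

Glycoform heterogeneity is collapsed to one N-glycan species.  ERAD returns
the full amino-acid content and ER glycans to the free pools (recycling
fraction configurable).  Complex formation is handled at the
abundance-allocation level rather than by explicit assembly reactions —
identical LP semantics with fewer variables.  Cofactor demands (a heme-like
prosthetic group) are co-substrates of the translation template.

The misfolding branch splits after the last ER modification: misfolded
protein either proceeds directly to retro-translocation and proteasomal
degradation (ERAD branch) or first performs ρ chaperone-binding rounds
(retention branch), each round occupying one slot on the Kar2- and
Pdi1-analog capacity rows.  ρ is an integer discretization of retention
time.  The accumulation slack — misfolded protein stuck in the ER — exists
only when a retro-translocation cap is imposed, mirroring the experimental
device it represents; accumulated protein occupies ER space *and*
sequesters one Kar2 and one Pdi1 analog per molecule, which is why the
model degrades whenever capacity allows and accumulates only beyond the
cap.

## The toy cell

The generator emulates the *regime* of a Crabtree-positive yeast, not its
content.  Key defaults (all in `ToyConfig`, validated at build time):

* **Catabolism**: fermentation yields 2 ATP/glucose at kcat 8000/h on a
  40-kDa-scale enzyme; respiration yields 16 ATP/glucose at kcat 1000/h on
  a 200-kDa-scale two-subunit complex.  Fermentation therefore wins ATP per
  proteome gram while respiration wins ATP per glucose — the inequality
  pair that produces overflow above a critical growth rate under the
  0.17 g/gDW modeled-proteome budget.
* **Transporters**: high-affinity (kcat 6000/h, KM 0.5 g/L, 3 N-glycan
  sites) versus low-affinity (kcat 20000/h, KM 20 g/L, 1 site), identical
  compositions so the kinetic/cost contrast is isolated.  The usage switch
  falls near S ≈ 8 g/L.
* **Quality control**: the retro-translocation complex (≈1 MDa scale,
  kcat 6/h) and proteasome (≈2.4 MDa scale, kcat 12/h) are deliberately
  slow and heavy — whole-protein dislocation and degradation take tens of
  minutes — which makes degraded copies costlier than folded ones and
  yields the fitness ordering folded > partial ERAD > full ERAD >
  retention, with retention rounds (Kar2/Pdi1 kcat 20/h) adding further
  cost.
* **Biomass**: protein content is built at ratio 1 and rescaled to 0.3
  through the biomass-rescaling operation, the removed mass being absorbed
  by a generic non-protein biomass drain; growth- and non-growth-associated
  maintenance are 20 mmol ATP/gDW and 1 mmol ATP/gDW/h.
* **Averaged dummy ER protein**: biomass-protein composition with
  abundance-weighted mean PTM multiplicities over the secretory client
  panel (kept fractional), held at 0.01 g/gDW to represent unmodeled
  secretory throughput.
* **Client panel**: the only seed-dependent part.  PTM counts follow
  documented discrete distributions (N-sites geometric capped at 8,
  disulfides Poisson capped at 6, O-sites Bernoulli×geometric), abundances
  log-normal around 250 ppm.  Seeds change clients only, never core
  metabolism; identical configurations serialize to byte-identical JSON.

What the toy does **not** emulate: realistic stoichiometry or parameter
values of any organism, glycan microheterogeneity, UPR/EGAD signaling,
transcription, redox bookkeeping, or genome-scale coverage.  Passing tests
demonstrate that the mechanisms (capacity coupling, cost accounting,
misfolding economics, targeting logic) behave as designed in a regime
chosen to express them — not that any particular organism's numbers are
reproduced.

## Simulation protocols

* **Glucose series**: for each S, maximize growth, then lexicographically
  minimize total glucose uptake and total modeled proteome mass.  The
  tie-breakers make transporter splits and reported abundances
  deterministic solver vertices.
* **Recombinant curves**: at each μ the glucose concentration is the
  chemostat residual — the minimal concentration sustaining μ in the
  cassette-free model — times a finite sampling margin (default 1.5,
  representing a grid-sampled minimal-concentration search).  Production is
  then maximized at fixed μ.  The rising limb of the resulting bell comes
  from transporter saturation at low residual glucose, the falling limb
  from proteome competition; the capacity-stripped basic-GEM contrast,
  uptake-capped at 10 mmol/gDW/h, is exactly linear decreasing.
* **Expression levels** in misfolding experiments fix the translation flux
  to fold × μ × reference abundance, so the constraint scales with growth
  inside the bisection and a ppm-referenced "native level" means the flux
  that would sustain the PaxDb-style reference abundance at that growth
  rate (ppm → mmol/gDW through a 0.45 g protein/gDW reference proteome).
* **FSEOF window**: defaults to 0.625–0.75 of the cassette-bearing model's
  μ* — the scaled analog of a 0.25–0.30 1/h window for a strain with
  μ* ≈ 0.4 1/h — in uniform steps (default 6), far enough below μ* to avoid
  the fermentation-ratio state switch yet close enough that enforcement
  varies production strongly.
* **Cost estimation**: unit secretory cost uses five forced-production
  points spanning ~0.1–1 % of budget throughput at μ = 0.1 1/h; the slope
  fit must reach R² ≥ 0.99 or the record is flagged.  Direct cost removes
  every capacity row and the maintenance floor, charging only material and
  energy stoichiometry.

## Scoring and attribution

Priority scores follow a strict gate chain (monotone rise → ≥1.2-fold →
reference-abundance band → monomer/no-paralog).  Trajectories are quantized
to 1e-9 relative before ranking, so solver jitter cannot fake strict
monotonicity, and ties count against it.  Two interpretations are explicit
and configurable: the "comparable to reference abundance" band is a ×10
window, and Spearman rank is computed against the enforcement step index
(equivalent to enforcement level when production rises monotonically over
the window).  Only exact rank correlation −1 marks down-regulation;
intermediate negative trends are unscored.

Feature importance trains a 10-tree random forest (seeded 80/20 split,
5-fold cross-validation) on maximum production labels over a fixed-length
cassette grid and computes *exact interventional Shapley* attributions by a
closed-form per-leaf enumeration (see `pcsec/shapley.py`); attributions sum
to prediction minus background mean to machine precision.  Inputs are cast
to float32 to match scikit-learn's internal tree evaluation bit-for-bit.

## Numerical choices

* LPs are solved with HiGHS (through `scipy.optimize.linprog`) at 1e-9
  primal/dual feasibility tolerances.  Abundance variables are internally
  scaled to µmol/gDW to tame conditioning; all reported values and audits
  are unscaled.
* Lexicographic objectives are pinned with a 1e-9 relative slack.
* The CPLEX-LP writer prints coefficients at 17 significant digits; tests
  re-parse emitted files and cross-solve them with GLPK.
* Degenerate transporter ties at the exact crossing concentration are
  solver-arbitrary between equal-cost vertices; reported usage is the
  returned vertex.
* At μ = 0 dilution vanishes (synthesis balances degradation); accumulation
  terms, which carry 1/μ factors, are only assembled at μ > 0.

## Known limitations

* Machinery capacity is one pooled row per machinery; a per-complex
  breakdown of, e.g., the translocon sub-complexes is below this
  resolution.
* COPI retrieval costs are charged to ER/Golgi residents only; whether
  anterograde clients should pay a per-cycle retrieval share is not
  resolved here.
* The direct-cost definition counts the client's own material only;
  machinery-bound energetic molecules are attributed through the unit cost,
  not the direct cost.
* The scaled FSEOF window and the ×10 reference band are interpretations;
  both are parameters (`mu_lo`, `mu_hi`, `paxdb_band`) rather than
  constants.
* Problem sizes are deliberately small (toy cell ≈ 360 LP variables;
  campaign grids of 15–25 points; 60-cassette learning grids), chosen so
  that every analysis, including exhaustive oracles, runs in minutes on one
  CPU.
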