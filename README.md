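# hdxtherm

Differential hydrogen/deuterium-exchange mass spectrometry (HDX-MS)
analysis and one-site isothermal titration calorimetry (ITC) binding
thermodynamics, packaged for studies of membrane-transporter conformational
dynamics — e.g. comparing a transporter alone against the same transporter
trapped in one conformation by a nanobody or a regulatory protein.

It is aimed at people who have peptide-level deuterium-uptake tables (an
HDExaminer-style export) and per-injection calorimetry heats, and want a
reproducible, scriptable version of the standard analysis chain instead of
vendor point-and-click software.

## What it computes

**Differential HDX.** For each peptide × labeling-time cell the state
difference is ΔD = D_bound − D_free (Da); ΔD < 0 is protection, ΔD > 0
deprotection. A cell is significant under the *hybrid criterion* when both

* |ΔD| ≥ T, with the global threshold
  T = t₁₋α/2(df) · s_pooled · √(1/n_free + 1/n_bound), where s_pooled is
  the replicate standard deviation pooled over all peptide × timepoint ×
  state cells, and
* a per-cell Welch's t-test gives p ≤ α.

Peptide-level calls are projected to residues through the observable amide
positions (first residue and prolines excluded) of overlapping peptides
under a configurable consensus rule, and peptides are classified into four
dynamic groups from their D% curves (percent of the theoretic maximum
n_max = L − 1 − internal prolines).

**Forward model.** The synthetic-data module simulates two-state EX2
exchange (k_obs = k_int / PF), uptake D(t) = f_D₂O · Σ (1 − e^(−k_obs t)),
over a realistic overlapping peptide map, so every downstream stage is
testable against known ground truth.

**ITC.** The one-site independent-binding isotherm (Wiseman-type, with
trapezoidal displaced-volume correction and heat-of-dilution handling) is
simulated and fitted by restarted least squares for Ka and ΔH with the
stoichiometry N fixed to 1; Kd = 1/Ka. Affinity changes between conditions
are reported as signed folds: −(Kd_mod/Kd_ref) for a decrease,
+(Kd_ref/Kd_mod) for an increase, at 2-decimal rounding.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_hdx.py
python analysis/02_differential_hdx.py
python analysis/03_residue_consensus.py
```

which prints

```
seed 1: 127 peptides, coverage 86.0%, mean length 9.27, redundancy 2.91, 66 uncovered residues
protected footprint: residues 375-444 (70 residues); deprotected patch: [2, 3, 4]
...
pooled sd 0.1292 Da over 1524 df -> global threshold 0.2069 Da (alpha 0.05)
51/381 peptide x timepoint cells significant (38 protected, 13 deprotected)
...
consensus at 3000 s (rule: any): protected 61, deprotected 31, insignificant 281, uncovered 97
true footprint 375-444 (70 residues); 60 recovered (86% overlap), 1 called outside it
```

Reading: the generator hid a 70-residue protected footprint inside a
470-residue construct; with triplicates at 0.13 Da replicate noise the
pooled sd reproduces that noise (0.129 Da), the hybrid criterion flags the
footprint peptides, and consensus mapping recovers 86% of the footprint
residues — the 14% it misses are mostly residues the peptide map never
covered. `04_classify_dynamics.py` adds the dynamic-group table,
`05_itc_folds.py` the signed fold-of-affinity table, and
`06_validation_studies.py` the operating characteristics (type-I error
0.015 at nominal α = 0.05; median |Kd error| 4.3% at 2% heat noise).

A YAML-configured end-to-end run is also available from the library:

```python
from hdxtherm.io import RunConfig
from hdxtherm.pipeline import run_pipeline
summary = run_pipeline(RunConfig(output_dir="results/run", seed=1))
```

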