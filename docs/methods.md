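# Methods

## Scope and coordinates

The package analyzes peptide-level deuterium uptake of one protein
construct in two states ("free" and "bound") and one-site binding
thermodynamics from titration calorimetry. Residue coordinates are 1-based
inclusive on the construct as stored, including any affinity tag; a
`numbering_offset` (e.g. −1 for a processed initiator methionine) is
applied only when positions are displayed or matched to a structure, so
internal arithmetic never carries the offset.

Coverage counts every residue of a covered peptide range, including
peptide first residues and prolines — exchangeability filtering applies to
uptake, not to coverage, matching how sequence coverage is conventionally
reported. Redundancy is Σ peptide lengths / covered residues; HDX software
packages differ here, and this definition was chosen for being
self-consistent with the coverage definition (it need not reconcile every
published coverage/redundancy triple exactly).

## Exchange model

Per-residue exchange follows the EX2 limit: k_obs = k_int / PF, uptake
fraction 1 − exp(−k_obs t). Peptide uptake sums the fractions of
observable amides (positions start+1..end, prolines excluded; the first
residue's amide back-exchanges too fast to observe) and scales by the
labeling D₂O fraction (default 0.9, a tenfold dilution into labeling
buffer). EX1 opening/closing kinetics are not modeled: the analysis
operates on centroid uptake only, for which EX2 is the appropriate
forward model.

D% — uptake relative to the theoretic maximum n_max = L − 1 − internal
prolines — deliberately uses the raw n_max without dividing by the D₂O
fraction, so simulated curves plateau near 90%. Centroid analyses of
membrane proteins typically apply no back-exchange correction, and
rescaling would silently change every D%-based classification cutoff.

## Synthetic ground truth

`simulate_system` draws a random construct (default 470 residues,
membrane-protein-like composition), log10 k_int uniform in [−3, 0] s⁻¹ and
log10 PF uniform in [0.5, 3] per residue. The bound state adds +1.5 log10
PF on a contiguous footprint of 15% of residues and subtracts the same on
a 3-residue patch just after the N-terminus (clamped at log10 PF ≥ 0),
emulating a binder that rigidifies one face of the protein while
allosterically loosening the terminus. Intrinsic rates are sampled rather
than computed from a sequence-based model: the inference machinery under
test never uses intrinsic-rate corrections, so only the dynamic range of
k_obs matters, and the sampled range spans slow-exchanging core to
fully-labeled loops at the 30–3000 s timepoints.

`simulate_digestion` first places non-adjacent uncovered gaps until the
uncovered-residue goal is met (default coverage 86%), then tiles each
covered segment with overlapping peptides of length 5–15 and adds random
peptides until redundancy ≥ 2.9 or a draw cap is hit (reported with
achieved statistics, never silently). Replicate noise is homoscedastic
Gaussian on peptide uptake (default sd 0.13 Da, triplicates, timepoints
30/300/3000 s), truncated to [0, f_D₂O · n_max] — homoscedasticity is
exactly the assumption pooling replicate sd across cells relies on.
Defaults emulate a published membrane-transporter study design (~150
peptides, mean length ~9.3, redundancy ~2.9, ~86% coverage, triplicates).

What the generator does *not* emulate: isotope envelopes and spectral
overlap, retention-time drift, carry-over, heteroscedastic noise on
fast-exchanging peptides, back-exchange during quench/LC, and EX1
bimodality. Tests passing on this generator therefore validate the
statistics and bookkeeping of the pipeline, not robustness to
spectral-level artifacts.

## Hybrid significance criterion

Per cell (peptide × timepoint), ΔD = mean_bound − mean_free; ΔD < 0 is
protection. Sample sds use the n−1 denominator throughout. The pooled sd
is taken over *all* cells of both states with df weighting,
s_pooled² = Σ(n_c−1)sd_c² / Σ(n_c−1); the global threshold is
T = t₁₋α/2(df) · s_pooled · √(1/n_f + 1/n_b) and a cell is significant iff
|ΔD| ≥ T and Welch's p ≤ α_ttest (both inclusive). Two alphas are
separately configurable (defaults 0.05/0.05; a stricter Welch preset of
0.01 is available, and a manual threshold override — e.g. a published
0.3184 or 0.3071 Da — can replay an exact published rule on any data).

The df for the threshold's t quantile is configurable because two
conventions coexist: `"pooled"` (default) uses the summed replicate df
across all cells, which at hundreds of cells is effectively the normal
quantile (T ≈ 0.207 Da at sd 0.13); `"per_comparison"` uses
n_f + n_b − 2 = 4 for triplicates (t = 2.776), reproducing the ≈ 0.3 Da
thresholds familiar from published triplicate studies. Both keep the
criterion conservative in conjunction with the Welch test: the measured
null significant-cell fraction is ~0.015 at nominal α = 0.05
(`analysis/06_validation_studies.py`).

Degenerate Welch cells (zero variance in both groups) return t = 0, p = 1
at equal means and p = 0 otherwise, so noise-free simulations behave
sensibly. Cells present in only one state, or with fewer than two
replicates, are excluded and logged, never imputed.

## Residue consensus

A residue's contributing peptides are those whose observable amide
positions include it; a peptide contributes no status to its first residue
or to prolines. Under the default rule `any`, one significant covering
peptide sets the status; `majority` and `all` are provided. Direction
conflicts (a residue covered by both significant-protected and
significant-deprotected peptides) resolve to protected and are logged —
protection dominates binder-trapped differential data, and a deterministic
tie-break keeps runs reproducible. Residues with contributors but no
significant peptide are `insignificant`; residues with none are
`uncovered`. Status counts always sum to the protein length.

Structure annotation writes the per-residue mean ΔD (or a status code:
protected −1, deprotected +1, insignificant 0) into the B-factor column of
a PDB/mmCIF file via gemmi, with −99 as the sentinel for unmatched or
uncovered residues, so any molecular viewer can color the consensus map.

## Dynamic groups

The four groups are operationalized from D% curves with explicit,
parameterized cutoffs (all strict at boundaries): III — both states ≥ 60%
at the first timepoint; IV — free state within 40–50% at every timepoint
with significant deprotection at ≥ 1 timepoint; I — significant protection
at every timepoint with bound-state D% ≤ 10% throughout; II — significant
protection at ≥ 1 timepoint with strictly rising free-state uptake;
otherwise unassigned. Precedence III → IV → I → II: the absolute-uptake
bands are the more specific conditions. Fast exchangers are peptides with
free-state D% > 5% at the first timepoint. Published group descriptions
are narrative; making every cutoff a parameter records the operational
choice instead of hiding it, and requiring protection at *every* timepoint
for group I is the stricter reading of "complete inhibition" (relaxable
via the parameters). On the default generator most peptides land in
II/unassigned — the group I/III/IV bands are narrow by construction — so
the classifier is validated on jittered prototype curves of each group
(100% accuracy at the default jitter) rather than on generator output.

## ITC

Overflow-cell dilution is continuous-exponential (M = M₀e^(−v/V₀),
X = Xs(1 − e^(−v/V₀))); the bound fraction solves the one-site quadratic,
cumulative heat Q = NΘM V₀ΔH, and per-injection heats apply the
trapezoidal displaced-volume correction
q_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2. The instrument equation
of any given vendor is proprietary; this standard form means refits of
real exported thermograms can differ in the third significant figure.
Summed corrected heats conserve N·M₀·V₀·ΔH in the small-displacement
limit; with large injected volumes relative to V₀ part of the cell
material leaves the sensed volume before binding, a real effect the
simulation reproduces.

Heats of dilution are handled either by subtracting the mean of the last
k (default 3) injections — valid only when the titration is saturated
there — or by fitting a per-injection offset. Fitting minimizes squared
per-injection heats; dH enters the model linearly at fixed Ka, so the
optimizer seeds from a 15-point log-spaced Ka grid with the closed-form dH
at each node before least-squares refinement (bounds 1 ≤ log10 Ka ≤ 12).
N is fixed to 1 by default. c-values outside [0.1, 1000] warn but do not
fail: weak-affinity titrations legitimately run at low c with N fixed.
Kd = 1/Ka exactly in every report; the exothermic-positive sign convention
is a declared flag and never changes estimates.

Fold of affinity change between a reference and a modulated condition is
−(Kd_mod/Kd_ref) when affinity decreases and +(Kd_ref/Kd_mod) when it
increases, rounded to 2 decimals to match table precision; replicate Kd
sets are compared by a two-sided unpaired Student's t-test.

## Problem sizes and numerics

The validation studies use sizes that exercise the statistics without
waste: the null study runs 200 replications of 150 peptides × 3 timepoints
× triplicates (90,000 cells); footprint recovery uses the full default
470-residue design; ITC recovery refits 50 independent noise draws. The
whole test suite runs in well under a minute. Tolerances: Welch p-values
match an independent reference to 1e−10; the threshold matches
independently tabulated t quantiles to 1e−9; noise-free ITC refits recover
Kd to better than 0.1%. Uptake is written with 4 decimals and p-values
with 3 significant digits so that re-runs diff byte-identically.

## Known limitations

Peptide-spectrum matching, spectral deconvolution and residue-level
exchange-rate fitting (the inverse problem) are out of scope; the
consensus mapping is a union/majority projection, not a deconvolution, so
its residue resolution is bounded by peptide overlap. Multiple-testing
correction beyond the hybrid conjunction is deliberately absent (matching
field practice for this criterion). The ITC model is single-site and
single-temperature; binding polynomials, ΔCp analysis and competitive
formats are not implemented.
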