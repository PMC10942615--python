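"""Simulation studies: error control, recovery, and classifier checks.

These are the package's own validation experiments — each runs the actual
analysis machinery on synthetic systems with known ground truth and
measures an operating characteristic (type-I error rate, footprint
recovery, parameter recovery, classification accuracy).  The analysis
scripts and the test suite both call them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import consensus, differential, itc, simulate


def null_significance_rate(
    n_peptides: int = 150,
    n_timepoints: int = 3,
    n_replicates: int = 3,
    noise_sd: float = 0.13,
    n_replications: int = 200,
    alpha_global: float = 0.05,
    alpha_ttest: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of significant cells when the two states are identical.

    Each replication draws replicate noise around per-cell true means that
    are equal in both states, recomputes the pooled sd and global threshold
    from that replication's own cells, applies the hybrid criterion, and
    the rate is pooled over all replications.  The conjunction of the
    magnitude and Welch criteria keeps this at or below the nominal alpha.
    """
    rng = np.random.default_rng(seed)
    n_cells = n_peptides * n_timepoints
    total_sig = 0
    total_cells = n_replications * n_cells
    for _ in range(n_replications):
        true_means = rng.uniform(0.5, 6.0, size=n_cells)
        reps = rng.normal(
            true_means[None, :, None],
            noise_sd,
            size=(2, n_cells, n_replicates),
        )
        means = reps.mean(axis=2)
        sds = reps.std(axis=2, ddof=1)
        s_pooled = float(np.sqrt(np.mean(sds**2)))
        df_pooled = 2 * n_cells * (n_replicates - 1)
        threshold = differential.global_threshold(
            s_pooled, df_pooled, n_replicates, n_replicates, alpha_global
        )
        _, _, p = differential._welch_arrays(
            means[1], sds[1], n_replicates, means[0], sds[0], n_replicates
        )
        delta = means[1] - means[0]
        sig = (np.abs(delta) >= threshold) & (p <= alpha_ttest)
        total_sig += int(sig.sum())
    return total_sig / total_cells


@dataclass(frozen=True)
class FootprintRecovery:
    n_footprint_peptides: int
    fraction_flagged: float
    footprint_size: int
    n_footprint_recovered: int
    overlap_fraction: float
    threshold_da: float


def footprint_recovery(
    seed: int = 1,
    length: int = 470,
    timepoint: float = 3000.0,
    consensus_rule: str = "any",
) -> FootprintRecovery:
    """Recover a protected footprint from a default synthetic experiment.

    Measures (a) the fraction of peptides lying fully inside the protected
    footprint that the hybrid criterion flags at the late timepoint, and
    (b) the fraction of true-footprint residues that the consensus map
    calls protected.
    """
    truth = simulate.simulate_system(length=length, seed=seed)
    pmap = simulate.simulate_digestion(truth.protein, seed=seed)
    design = simulate.ExperimentDesign(seed=seed)
    free_table, bound_table = simulate.simulate_uptake_tables(
        truth, pmap, design
    )
    deltas, params = differential.differential_analysis(free_table, bound_table)

    fp = truth.footprint_protected
    fp_lo, fp_hi = min(fp), max(fp)
    at_t = deltas[deltas["timepoint_s"] == timepoint]
    interior = at_t[(at_t["start"] >= fp_lo) & (at_t["end"] <= fp_hi)]
    frac_flagged = (
        float(interior["significant"].mean()) if len(interior) else float("nan")
    )

    statusmap = consensus.map_significance_to_residues(
        deltas, pmap, timepoint, consensus_rule
    )
    protected_positions = set(
        statusmap.loc[statusmap["status"] == "protected", "position"]
    )
    recovered = len(protected_positions & fp)
    return FootprintRecovery(
        n_footprint_peptides=len(interior),
        fraction_flagged=frac_flagged,
        footprint_size=len(fp),
        n_footprint_recovered=recovered,
        overlap_fraction=recovered / len(fp),
        threshold_da=params.threshold,
    )


def itc_recovery_study(
    kd_um: float = 16.46,
    dh_kcal_mol: float = -5.0,
    noise_fraction: float = 0.02,
    n_seeds: int = 50,
    seed: int = 0,
    schedule: itc.TitrationSchedule | None = None,
) -> np.ndarray:
    """Relative Kd errors of one-site refits under per-injection noise.

    Noise sd is ``noise_fraction`` of the maximum dilution-corrected heat.
    Returns the signed relative errors (fitted - true)/true over n_seeds
    independent noise draws.
    """
    schedule = schedule or itc.TitrationSchedule()
    params = itc.OneSiteParams(ka_per_m=1e6 / kd_um, dh_kcal_mol=dh_kcal_mol)
    clean = itc.simulate_titration(params, schedule)
    noise_sd = noise_fraction * float(np.max(np.abs(clean.heats_ucal)))
    errors = np.empty(n_seeds)
    base = np.random.SeedSequence(seed).generate_state(n_seeds)
    for i in range(n_seeds):
        noisy = itc.simulate_titration(
            params, schedule, noise_sd_ucal=noise_sd, seed=int(base[i])
        )
        fit = itc.fit_one_site(noisy)
        errors[i] = (fit.kd_um - kd_um) / kd_um
    return errors


def prototype_classification_accuracy(
    n_per_group: int = 50, seed: int = 0
) -> float:
    """Classifier accuracy on jittered prototype D% curves of each group.

    Prototypes: saturating (III), mid-band deprotected (IV), fully
    protected (I), rising-with-protection (II); each gets small uniform D%
    jitter before classification.
    """
    rng = np.random.default_rng(seed)
    timepoints = (30.0, 300.0, 3000.0)
    prototypes = {
        "III": {"free": (70, 80, 85), "bound": (65, 78, 83),
                "sig": (False, False, False), "dir": "none"},
        "IV": {"free": (44, 45, 47), "bound": (47, 48, 49),
               "sig": (True, False, False), "dir": "deprotected"},
        "I": {"free": (10, 20, 40), "bound": (2, 3, 5),
              "sig": (True, True, True), "dir": "protected"},
        "II": {"free": (15, 30, 55), "bound": (10, 22, 40),
               "sig": (False, True, True), "dir": "protected"},
    }
    rows = []
    expected = {}
    pid = 0
    for group, proto in prototypes.items():
        for _ in range(n_per_group):
            pid += 1
            start, end = pid * 20, pid * 20 + 9
            expected[(start, end)] = group
            for i, t in enumerate(timepoints):
                jitter = rng.uniform(-1.5, 1.5)
                rows.append(
                    {
                        "start": start,
                        "end": end,
                        "timepoint_s": t,
                        "dpct_free": proto["free"][i] + jitter,
                        "dpct_bound": proto["bound"][i] + jitter,
                        "significant": proto["sig"][i],
                        "direction": proto["dir"] if proto["sig"][i] else "none",
                    }
                )
    labels = classify_mod.classify_peptides(pd.DataFrame(rows))
    correct = sum(
        expected[(row["start"], row["end"])] == row["group"]
        for _, row in labels.iterrows()
    )
    return correct / len(labels)
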