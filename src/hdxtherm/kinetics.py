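"""Forward EX2 exchange model and uptake summaries.

In the EX2 limit the observed exchange rate of an amide is its intrinsic
rate divided by the protection factor, k_obs = k_int / PF, and the deuterated
fraction after time t of labeling is 1 - exp(-k_obs * t).  Peptide-level
uptake is the sum over its observable amides, scaled by the deuterium
fraction of the labeling buffer.

Uptake is also reported as D%, the percentage of the theoretic maximum
number of exchangeable amides (n_max).  D% deliberately uses the raw n_max
without rescaling by the labeling D2O fraction, so simulated saturation
plateaus below 100% — mirroring centroid-level analyses that apply no
back-exchange correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptides import Peptide


@dataclass(frozen=True)
class ExchangeParams:
    """Per-residue exchange parameters: intrinsic rate (s^-1) and
    protection factor (dimensionless, >= 1)."""

    k_int: float
    pf: float = 1.0

    def __post_init__(self) -> None:
        if self.k_int <= 0:
            raise ValueError("k_int must be > 0")
        if self.pf < 1:
            raise ValueError("protection factor must be >= 1")

    @property
    def k_obs(self) -> float:
        return self.k_int / self.pf


def residue_exchange_fraction(params: ExchangeParams, t) -> float:
    """Deuterated fraction of one amide after t seconds of labeling."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("labeling time must be >= 0")
    out = -np.expm1(-params.k_obs * t)
    return float(out) if out.ndim == 0 else out


def peptide_uptake(truth, state: str, peptide: Peptide, t: float) -> float:
    """Noise-free deuterium uptake (Da) of a peptide at time t.

    Sums the exchange fraction over the amide-bearing positions
    (start+1..end, prolines excluded) of the ground-truth system and scales
    by its labeling D2O fraction.  Result lies in [0, d2o_fraction * n_max].
    """
    if peptide.end > len(truth.protein) or (
        truth.protein.sequence[peptide.start - 1 : peptide.end]
        != peptide.sequence
    ):
        raise ValueError("peptide does not match the ground-truth protein")
    if t < 0:
        raise ValueError("labeling time must be >= 0")
    log10_pf = (
        truth.log10_pf_free if state == "free" else truth.log10_pf_bound
    )
    total = 0.0
    for pos in peptide.amide_positions():
        k_int = truth.k_int[pos - 1]
        pf = 10.0 ** log10_pf[pos - 1]
        total += -np.expm1(-(k_int / pf) * t)
    return truth.d2o_fraction * total


def relative_uptake_percent(d: float, peptide: Peptide) -> float:
    """Uptake as a percentage of the theoretic maximum (D%)."""
    if peptide.n_max <= 0:
        raise ValueError(
            f"D%% undefined for peptide ({peptide.start}, {peptide.end}) "
            "with no observable amide"
        )
    return 100.0 * d / peptide.n_max
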