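"""One-site independent-binding ITC: simulation, dilution correction,
fitting, and fold-of-affinity comparisons.

The forward model is the standard single-site (Wiseman-type) isotherm for
an overflow cell.  After cumulative injected volume v the cell contents are
diluted continuously, M(v) = M0 exp(-v/V0) and X(v) = Xs (1 - exp(-v/V0)),
and the bound fraction Theta solves the single-site quadratic

    Theta^2 - Theta (1 + X/(N M) + 1/(N Ka M)) + X/(N M) = 0.

Cumulative reaction heat is Q = N Theta M V0 dH; the per-injection heat
applies the trapezoidal displaced-volume correction

    q_i = Q(i) - Q(i-1) + (dV_i / V0) * (Q(i) + Q(i-1)) / 2.

Exothermic reactions (dH < 0) release heat; instruments that plot heat
release as positive peaks are handled by the ``exothermic_positive`` sign
flag, which the fit honors so the convention never changes the estimates.

Units: volumes in uL, concentrations in uM, dH in kcal/mol, heats in ucal,
Ka in 1/M and Kd reported in uM (Kd = 1/Ka exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class TitrationSchedule:
    """Cell volume (uL), per-injection volumes (uL), syringe and initial
    cell concentrations (uM), temperature (C)."""

    v0_ul: float = 170.0
    injection_volumes_ul: tuple[float, ...] = (2.0,) * 25
    syringe_um: float = 300.0
    cell_um: float = 35.0
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        if self.v0_ul <= 0 or self.syringe_um <= 0 or self.cell_um <= 0:
            raise ValueError("volumes and concentrations must be > 0")
        if not self.injection_volumes_ul or any(
            dv <= 0 for dv in self.injection_volumes_ul
        ):
            raise ValueError("injection volumes must be > 0")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass(frozen=True)
class OneSiteParams:
    """One-site independent-binding parameters."""

    ka_per_m: float
    dh_kcal_mol: float
    n_sites: float = 1.0
    dilution_offset_ucal: float = 0.0

    def __post_init__(self) -> None:
        if self.ka_per_m <= 0:
            raise ValueError("Ka must be > 0")
        if self.n_sites <= 0:
            raise ValueError("stoichiometry N must be > 0")

    @property
    def kd_um(self) -> float:
        return 1e6 / self.ka_per_m


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (ucal) under a declared sign convention."""

    heats_ucal: np.ndarray
    schedule: TitrationSchedule
    exothermic_positive: bool = True

    def __post_init__(self) -> None:
        heats = np.asarray(self.heats_ucal, dtype=float)
        object.__setattr__(self, "heats_ucal", heats)
        if heats.shape != (self.schedule.n_injections,):
            raise ValueError("thermogram length does not match schedule")


@dataclass(frozen=True)
class BindingFit:
    params: OneSiteParams
    residual_norm: float
    c_value: float
    success: bool
    message: str = ""
    n_fitted: bool = False

    @property
    def kd_um(self) -> float:
        return self.params.kd_um


def _cumulative_heat_ucal(
    ka_per_m: float, dh_kcal_mol: float, n_sites: float,
    schedule: TitrationSchedule,
) -> np.ndarray:
    """Cumulative bound heat Q(i) (ucal, chemical sign) after injection i."""
    v = np.cumsum(schedule.injection_volumes_ul)
    dilution = np.exp(-v / schedule.v0_ul)
    m_um = schedule.cell_um * dilution
    x_um = schedule.syringe_um * (1.0 - dilution)
    m = m_um * 1e-6
    x = x_um * 1e-6
    r = x / (n_sites * m)
    b = 1.0 + r + 1.0 / (n_sites * ka_per_m * m)
    theta = (b - np.sqrt(b * b - 4.0 * r)) / 2.0
    if np.any(~np.isfinite(theta)) or np.any(theta < -1e-9):
        raise ValueError("inconsistent concentrations in titration")
    # uM * uL * kcal/mol = 1e-12 mol * 1e3 cal/mol = 1e-3 ucal
    return n_sites * theta * m_um * schedule.v0_ul * dh_kcal_mol * 1e-3


def _injection_heats_ucal(
    ka_per_m: float, dh_kcal_mol: float, n_sites: float,
    schedule: TitrationSchedule,
) -> np.ndarray:
    """Per-injection heats with the trapezoidal displaced-volume term."""
    q_cum = _cumulative_heat_ucal(ka_per_m, dh_kcal_mol, n_sites, schedule)
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    dv = np.asarray(schedule.injection_volumes_ul)
    return q_cum - q_prev + (dv / schedule.v0_ul) * (q_cum + q_prev) / 2.0


def simulate_titration(
    params: OneSiteParams,
    schedule: TitrationSchedule,
    noise_sd_ucal: float = 0.0,
    seed: int | None = None,
    exothermic_positive: bool = True,
) -> Thermogram:
    """Simulate a thermogram from one-site parameters."""
    q = _injection_heats_ucal(
        params.ka_per_m, params.dh_kcal_mol, params.n_sites, schedule
    )
    q = q + params.dilution_offset_ucal
    if noise_sd_ucal:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd_ucal, q.shape)
    if exothermic_positive:
        q = -q
    return Thermogram(q, schedule, exothermic_positive)


def subtract_dilution_heat(thermogram: Thermogram, k_last: int = 3) -> Thermogram:
    """Subtract the mean of the last k_last heats from every injection.

    Past saturation no further binding occurs, so the tail heats estimate
    the heat of dilution per injection.
    """
    n = thermogram.schedule.n_injections
    if not (1 <= k_last < n):
        raise ValueError(f"k_last must be in [1, {n - 1}]")
    offset = float(np.mean(thermogram.heats_ucal[-k_last:]))
    return replace(thermogram, heats_ucal=thermogram.heats_ucal - offset)


def normalized_heats_kcal_mol(thermogram: Thermogram) -> np.ndarray:
    """Heats per mole of injectant (kcal/mol), chemical sign."""
    q = thermogram.heats_ucal.copy()
    if thermogram.exothermic_positive:
        q = -q
    dv = np.asarray(thermogram.schedule.injection_volumes_ul)
    moles_nmolx1e3 = dv * thermogram.schedule.syringe_um  # 1e-12 mol units
    return q / moles_nmolx1e3 * 1e3


_KA_GRID = np.logspace(2.0, 9.0, 15)


def fit_one_site(
    thermogram: Thermogram,
    fix_n: bool = True,
    fit_offset: bool = False,
) -> BindingFit:
    """Least-squares one-site fit of Ka and dH (and N unless fixed).

    Residuals are squared per-injection heats normalized per mole of
    injectant; the optimizer restarts from a coarse log-spaced Ka grid to
    avoid local minima.  c-values outside [0.1, 1000] are logged as a
    warning, not an error.  All-zero thermograms are rejected.
    """
    schedule = thermogram.schedule
    if schedule.n_injections < 5:
        raise ValueError("need >= 5 injections to fit")
    q_obs = thermogram.heats_ucal.copy()
    if thermogram.exothermic_positive:
        q_obs = -q_obs
    scale = np.max(np.abs(q_obs))
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError("thermogram carries no signal; fit rejected")

    def model(log10_ka, dh, n_sites, offset):
        return (
            _injection_heats_ucal(10.0**log10_ka, dh, n_sites, schedule)
            + offset
        )

    # Grid seed: dH enters linearly at fixed Ka, so solve it in closed form.
    best = None
    for ka0 in _KA_GRID:
        shape = _injection_heats_ucal(ka0, 1.0, 1.0, schedule)
        denom = float(shape @ shape)
        if denom == 0:
            continue
        dh0 = float(shape @ q_obs) / denom
        if dh0 == 0:
            continue
        cost = float(np.sum((q_obs - dh0 * shape) ** 2))
        if best is None or cost < best[0]:
            best = (cost, np.log10(ka0), dh0)
    if best is None:
        raise ValueError("could not seed the fit; fit rejected")
    _, log10_ka0, dh0 = best

    x0 = [log10_ka0, dh0]
    lower, upper = [0.0, -np.inf], [12.0, np.inf]
    if not fix_n:
        x0.append(1.0)
        lower.append(1e-3)
        upper.append(10.0)
    if fit_offset:
        x0.append(0.0)
        lower.append(-np.inf)
        upper.append(np.inf)

    def residuals(x):
        log10_ka, dh = x[0], x[1]
        n_sites = x[2] if not fix_n else 1.0
        offset = x[-1] if fit_offset else 0.0
        return model(log10_ka, dh, n_sites, offset) - q_obs

    result = optimize.least_squares(
        residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14,
        gtol=1e-14,
    )
    log10_ka, dh = result.x[0], result.x[1]
    n_sites = float(result.x[2]) if not fix_n else 1.0
    offset = float(result.x[-1]) if fit_offset else 0.0
    ka = 10.0**log10_ka
    c_value = n_sites * ka * schedule.cell_um * 1e-6
    if not (0.1 <= c_value <= 1000.0):
        warnings.warn(
            f"c-value {c_value:.3g} outside the well-conditioned range "
            "[0.1, 1000]; Kd estimate may be weakly determined",
            stacklevel=2,
        )
    if not result.success:
        raise RuntimeError(
            f"one-site fit did not converge: {result.message}"
        )
    params = OneSiteParams(
        ka_per_m=float(ka),
        dh_kcal_mol=float(dh),
        n_sites=n_sites,
        dilution_offset_ucal=offset,
    )
    return BindingFit(
        params=params,
        residual_norm=float(np.sqrt(2.0 * result.cost)),
        c_value=float(c_value),
        success=bool(result.success),
        message=str(result.message),
        n_fitted=not fix_n,
    )


def fold_affinity_change(kd_reference_um: float, kd_modulated_um: float) -> float:
    """Signed fold of affinity change between two Kd values.

    Negative sign denotes an affinity decrease (Kd went up), positive an
    increase; magnitude is always the >= 1 ratio, rounded to 2 decimals.
    """
    if kd_reference_um <= 0 or kd_modulated_um <= 0:
        raise ValueError("Kd values must be > 0")
    if kd_modulated_um > kd_reference_um:
        return round(-(kd_modulated_um / kd_reference_um), 2)
    return round(kd_reference_um / kd_modulated_um, 2)


def compare_affinities(kds_a, kds_b) -> float:
    """Two-sided unpaired Student's t-test p-value on Kd replicates."""
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicate Kd values per condition")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
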