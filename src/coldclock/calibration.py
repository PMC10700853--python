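"""Ca2+-indicator calibration math.

Free Ca2+ in EGTA-buffered solutions with pH and temperature (Van't Hoff)
corrections of the EGTA association constants, the log-log Hill linearization
of an indicator titration, and the fluorescent-protein temperature correction
used to convert a cold-induced dF/F0 increase into an absolute Ca2+ estimate.

Concentrations are molar internally; interfaces use the units stated in the
field/argument names (mM for buffer species, nM for Kd and Ca levels).
Temperatures are converted as T(K) = temp_C + 273.15.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class EgtaConstants:
    """EGTA proton/Ca association constants at the 20 degC reference.

    log_k1/log_k2: proton association constants (M^-1); log_kca: primary Ca
    association constant (M^-1); dh_*: reaction enthalpies (kcal/mol);
    gas_const: kcal K^-1 mol^-1.
    """

    log_k1: float = 9.58
    log_k2: float = 8.96
    log_kca: float = 10.97
    dh_kca: float = -8.0
    dh_k1: float = -5.8
    dh_k2: float = -5.8
    gas_const: float = 1.9872e-3
    t_ref_K: float = 293.15


DEFAULT_EGTA = EgtaConstants()


@dataclass(frozen=True)
class BufferCondition:
    """An EGTA-buffered calibration solution."""

    ca_egta_mM: float
    egta_free_mM: float
    pH: float
    temp_C: float = 20.0

    def __post_init__(self) -> None:
        if self.ca_egta_mM < 0 or self.egta_free_mM < 0:
            raise ValueError("concentrations must be >= 0")
        if not 6.0 <= self.pH <= 9.0:
            raise ValueError("pH must lie in [6, 9]")
        if not 0.0 <= self.temp_C <= 40.0:
            raise ValueError("temp_C must lie in [0, 40]")


@dataclass(frozen=True)
class HillFit:
    kd_nM: float
    hill_n: float
    f_min: float
    f_max: float
    fit_r2: float

    def __post_init__(self) -> None:
        if self.kd_nM <= 0 or self.hill_n <= 0:
            raise ValueError("kd and Hill coefficient must be positive")
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be below f_max")


@dataclass(frozen=True)
class CalciumEstimate:
    corrected_fold: float
    basal_nM: float
    peak_nM: float
    estimated_nM: float


def vant_hoff_correct(log_k: float, dh_kcal: float, temp_C: float,
                      const: EgtaConstants = DEFAULT_EGTA,
                      literal_printed: bool = False) -> float:
    """Temperature-correct an association constant by the Van't Hoff isochore.

    Standard form: ``logK' = logK + (dH / 2.303 R) (1/T_ref - 1/T)`` with T in
    kelvin, so an exothermic reaction (dH < 0) has a larger K in the cold.
    ``literal_printed=True`` instead evaluates the typeset variant with an
    extra 1/T factor in the denominator, kept only for comparison; it is
    dimensionally inconsistent and not recommended.
    """
    if not 0.0 <= temp_C <= 40.0:
        raise ValueError("temp_C must lie in [0, 40]")
    T = temp_C + KELVIN_OFFSET
    if literal_printed:
        return log_k + dh_kcal * (1.0 / T - 1.0 / const.t_ref_K) / (
            2.303 * const.gas_const * T
        )
    return log_k + dh_kcal * (1.0 / const.t_ref_K - 1.0 / T) / (
        2.303 * const.gas_const
    )


def egta_kd(pH: float, temp_C: float = 20.0,
            const: EgtaConstants = DEFAULT_EGTA) -> float:
    """Effective Kd of EGTA for Ca2+ (molar) at a given pH and temperature.

    ``Kd = (1 + 10^(logK1 - pH) + 10^(logK1 + logK2 - 2 pH)) / KCa`` with the
    proton and Ca association constants first Van't-Hoff-corrected to
    ``temp_C``.  Decreasing in pH (protons compete for EGTA).  On cooling,
    every association constant grows (all enthalpies are negative), but the
    double-protonation term grows faster than K_Ca (|dH1 + dH2| > |dH_Ca|),
    so the effective Kd at fixed pH rises as temperature drops.
    """
    if not 6.0 <= pH <= 9.0:
        raise ValueError("pH must lie in [6, 9]")
    k1 = vant_hoff_correct(const.log_k1, const.dh_k1, temp_C, const)
    k2 = vant_hoff_correct(const.log_k2, const.dh_k2, temp_C, const)
    kca = vant_hoff_correct(const.log_kca, const.dh_kca, temp_C, const)
    return float((1.0 + 10.0 ** (k1 - pH) + 10.0 ** (k1 + k2 - 2.0 * pH))
                 / 10.0 ** kca)


def free_ca(buffer: BufferCondition,
            const: EgtaConstants = DEFAULT_EGTA) -> float:
    """Free Ca2+ (molar): ``Kd_EGTA * [CaEGTA] / [EGTA_free]``."""
    if buffer.egta_free_mM <= 0:
        raise ValueError("free EGTA concentration must be positive")
    kd = egta_kd(buffer.pH, buffer.temp_C, const)
    return float(kd * buffer.ca_egta_mM / buffer.egta_free_mM)


def hill_fit(ca_free_M, F, f_min: float | None = None,
             f_max: float | None = None, fit_endpoints: bool = False) -> HillFit:
    """Fit a Hill binding curve by the log-log linearization.

    Plots ``log10([Ca]_free)`` against ``log10((F - F_min)/(F_max - F))``;
    the slope is the Hill coefficient and the x-intercept (back-transformed)
    is the Kd.  The line is fitted by weighted least squares with weights
    ``(F - F_min)(F_max - F)``, the inverse of the first-order noise
    amplification of the log-ratio transform, so near-saturated points do not
    dominate.  ``f_min``/``f_max`` default to the endpoint measurements
    (min/max of F) and are treated as fixed, matching the calibration-kit
    protocol; ``fit_endpoints=True`` instead co-fits all four parameters to
    the untransformed Hill model.  Points with F outside (f_min, f_max) are
    dropped with a warning; at least 3 usable points are required.
    """
    ca = np.asarray(ca_free_M, dtype=float)
    f = np.asarray(F, dtype=float)
    if ca.shape != f.shape or ca.ndim != 1:
        raise ValueError("ca_free_M and F must be 1-D and equal length")

    if fit_endpoints:
        from scipy.optimize import curve_fit

        def model(c, kd, n, lo, hi):
            return lo + (hi - lo) * c**n / (c**n + kd**n)

        p0 = (np.median(ca), 1.5, f.min(), f.max())
        popt, _ = curve_fit(model, ca, f, p0=p0, maxfev=20000)
        kd, n, lo, hi = popt
        resid = f - model(ca, *popt)
        ss = 1.0 - resid.var() / f.var() if f.var() > 0 else 1.0
        return HillFit(kd * 1e9, n, lo, hi, float(ss))

    if f_min is None:
        f_min = float(f.min())
    if f_max is None:
        f_max = float(f.max())
    if not f_min < f_max:
        raise ValueError("f_min must be below f_max")
    usable = (f > f_min) & (f < f_max) & (ca > 0)
    if usable.sum() < len(f):
        warnings.warn(
            f"dropped {len(f) - int(usable.sum())} point(s) outside "
            "(f_min, f_max) or with non-positive [Ca]",
            stacklevel=2,
        )
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable titration points")
    x = np.log10(ca[usable])
    fu = f[usable]
    y = np.log10((fu - f_min) / (f_max - fu))
    weights = (fu - f_min) * (f_max - fu)
    slope, intercept = np.polyfit(x, y, 1, w=weights)
    if slope <= 0:
        raise ValueError("non-positive Hill slope; titration not monotone")
    yhat = slope * x + intercept
    r2 = 1.0 - np.sum((y - yhat) ** 2) / max(np.sum((y - y.mean()) ** 2), 1e-300)
    kd_M = 10.0 ** (-intercept / slope)
    return HillFit(kd_M * 1e9, float(slope), f_min, f_max, float(r2))


def fp_corrected_fold(dff_cold_pct: float, fp_gain_increase_pct: float,
                      rhythm_amplitude_pct: float) -> float:
    """Cold-induced signal increase, corrected for fluorescent-protein
    brightness, expressed as a multiple of the circadian rhythm amplitude:
    ``(increase - brightness_change) / amplitude``.
    """
    if rhythm_amplitude_pct <= 0:
        raise ValueError("rhythm amplitude must be positive")
    return float((dff_cold_pct - fp_gain_increase_pct) / rhythm_amplitude_pct)


def estimate_absolute_ca(corrected_fold: float, basal_nM: float,
                         peak_nM: float) -> CalciumEstimate:
    """Absolute Ca2+ estimate: ``basal + fold * (peak - basal)`` with basal
    and peak taken from an independent absolute calibration of the rhythm."""
    if peak_nM <= basal_nM:
        raise ValueError("peak_nM must exceed basal_nM")
    est = basal_nM + corrected_fold * (peak_nM - basal_nM)
    return CalciumEstimate(float(corrected_fold), float(basal_nM),
                           float(peak_nM), float(est))
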