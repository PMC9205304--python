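"""Testosterone threshold calibration for sexing young tortoises.

Young gopher tortoises lack external sexual dimorphism, but circulating
plasma testosterone is (stochastically) higher in males.  Given samples of
known-sex animals, this module calibrates cutoffs on the testosterone axis:

* ``T_m`` — the threshold minimising the *sum* of the per-sex error rates
  (the fraction of true females above it plus the fraction of true males
  below it; summing per-sex fractions avoids bias from unequal sex ratios);
* ``T_E`` — the equal-error threshold, where the two per-sex error rates
  are as close to equal as the data allow, so that applying the cutoff does
  not bias the estimated sex ratio;
* ``T_PF`` / ``T_PM`` — likelihood thresholds from an empirical Bayes
  posterior under equal priors: the value below (above) which an animal is
  at least ``level`` likely to be female (male).  Animals between the two
  are scored "unknown", trading sample retention for per-call confidence.

All estimators search a fixed grid from the minimum to the maximum pooled
observed value in steps of 0.1 pg/mL.  "Above" means strictly greater and
"below" strictly less throughout; an animal exactly at a two-way threshold
is called female.  Ties between equally optimal grid values resolve to the
smallest by default.  No parametric distribution is ever fitted — male
testosterone in this species is poorly described by lognormal or gamma
shapes, so everything runs on empirical proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .exceptions import (
    BandCollapseError,
    NoThresholdError,
    SplineFitError,
    UndefinedProbabilityError,
)

DEFAULT_STEP = 0.1

#: Conventional juvenile cutoff (pg/mL): the sexes separate completely at
#: ~3.5 years, and this sits roughly midway between the two distributions.
JUVENILE_CONVENTION_THRESHOLD = 700.0


@dataclass(frozen=True)
class ErrorRates:
    """Per-sex misclassification fractions at a threshold."""

    err_female: float  # true females called male (value above threshold)
    err_male: float    # true males called female (value below threshold)

    @property
    def total(self) -> float:
        return self.err_female + self.err_male


@dataclass
class ThresholdEstimate:
    """A calibrated testosterone cutoff.

    ``kind`` is one of ``"T_m"``, ``"T_E"``, ``"T_P"``.  For likelihood
    thresholds (``T_P``) the probability ``level`` and ``target_sex`` are
    recorded and ``error_rates`` is None.  ``degenerate`` flags fits on
    data where every grid value was equally (un)informative.
    """

    kind: str
    value: float
    error_rates: ErrorRates | None = None
    level: float | None = None
    target_sex: str | None = None
    exclusion_rates: tuple[float, float] | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False
    at_extremum: bool = False


def _as_values(values: Sequence[float], sex: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"no testosterone values supplied for sex {sex!r}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite testosterone value in {sex} sample")
    return arr


def threshold_grid(values: np.ndarray, step: float = DEFAULT_STEP) -> np.ndarray:
    """Candidate thresholds from min to max observed value by ``step``.

    Mirrors ``seq(min, max, by=step)``: the first point is the pooled
    minimum and the last is the largest ``min + k*step`` not exceeding the
    pooled maximum.
    """
    lo = float(np.min(values))
    hi = float(np.max(values))
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def error_rate_curves(
    f_values: np.ndarray, m_values: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-sex error rates at every grid value.

    err_female(t) = #{female > t} / n_F (non-increasing in t);
    err_male(t)   = #{male   < t} / n_M (non-decreasing in t).
    """
    fs = np.sort(np.asarray(f_values, dtype=float))
    ms = np.sort(np.asarray(m_values, dtype=float))
    # count/n directly (not 1 - complement/n) so ties in the objective are
    # exact and resolve identically to naive enumeration
    err_f = (fs.size - np.searchsorted(fs, grid, side="right")) / fs.size
    err_m = np.searchsorted(ms, grid, side="left") / ms.size
    return err_f, err_m


def classification_error_rates(
    f_values: Sequence[float], m_values: Sequence[float], threshold: float
) -> ErrorRates:
    """Per-sex error rates of a two-way sex call at ``threshold``.

    A female errs if her value is strictly above the threshold; a male errs
    if his value is strictly below it (a value exactly at the threshold is
    called female).
    """
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    return ErrorRates(
        err_female=float(np.count_nonzero(f > threshold)) / f.size,
        err_male=float(np.count_nonzero(m < threshold)) / m.size,
    )


def _pick_grid_index(objective: np.ndarray, tie: str) -> int:
    best = objective.min()
    candidates = np.flatnonzero(objective == best)
    if tie == "smallest":
        return int(candidates[0])
    if tie == "midpoint":
        # midpoint of the first contiguous run of optimal grid values
        run_end = candidates[0]
        for c in candidates[1:]:
            if c == run_end + 1:
                run_end = c
            else:
                break
        return int((candidates[0] + run_end) // 2)
    raise ValueError(f"unknown tie rule {tie!r} (use 'smallest' or 'midpoint')")


def _grid_threshold(
    f_values, m_values, step, tie, objective_fn: Callable, kind: str
) -> ThresholdEstimate:
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    if f.size < 2 or m.size < 2:
        raise ValueError("need at least 2 values per sex to calibrate a threshold")
    pooled = np.concatenate([f, m])
    grid = threshold_grid(pooled, step)
    err_f, err_m = error_rate_curves(f, m, grid)
    objective = objective_fn(err_f, err_m)
    idx = _pick_grid_index(objective, tie)
    degenerate = bool(np.all(objective == objective[0])) and grid.size > 1 or grid.size == 1
    return ThresholdEstimate(
        kind=kind,
        value=float(grid[idx]),
        error_rates=ErrorRates(float(err_f[idx]), float(err_m[idx])),
        degenerate=degenerate,
    )


def min_total_error_threshold(
    f_values: Sequence[float],
    m_values: Sequence[float],
    step: float = DEFAULT_STEP,
    tie: str = "smallest",
) -> ThresholdEstimate:
    """Threshold minimising the summed per-sex error percentages (T_m)."""
    return _grid_threshold(
        f_values, m_values, step, tie, lambda ef, em: ef + em, "T_m"
    )


def equal_error_threshold(
    f_values: Sequence[float],
    m_values: Sequence[float],
    step: float = DEFAULT_STEP,
    tie: str = "smallest",
) -> ThresholdEstimate:
    """Threshold with the minimum |female − male| error-rate gap (T_E)."""
    return _grid_threshold(
        f_values, m_values, step, tie, lambda ef, em: np.abs(ef - em), "T_E"
    )


def posterior_prob_female_below(
    f_values: Sequence[float], m_values: Sequence[float], x0: float
) -> float:
    """P(sex = F | T < x0) under equal priors, from empirical proportions.

    With equal prior probability of either sex, Bayes' theorem reduces to
    ``P(T<x0|F) / (P(T<x0|F) + P(T<x0|M))`` with each conditional estimated
    by the per-sex empirical fraction strictly below ``x0``.
    """
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    pf = np.count_nonzero(f < x0) / f.size
    pm = np.count_nonzero(m < x0) / m.size
    if pf + pm == 0.0:
        raise UndefinedProbabilityError(
            f"no observation of either sex below x0={x0}: posterior undefined"
        )
    return float(pf / (pf + pm))


def posterior_prob_male_above(
    f_values: Sequence[float], m_values: Sequence[float], x0: float
) -> float:
    """P(sex = M | T > x0) under equal priors; mirror of the female form."""
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    pf = np.count_nonzero(f > x0) / f.size
    pm = np.count_nonzero(m > x0) / m.size
    if pf + pm == 0.0:
        raise UndefinedProbabilityError(
            f"no observation of either sex above x0={x0}: posterior undefined"
        )
    return float(pm / (pf + pm))


@dataclass
class ProbabilityCurve:
    """Empirical posterior sex probabilities along the testosterone grid.

    ``p_female_below[i]`` is P(F | T < grid[i]) and ``p_male_above[i]`` is
    P(M | T > grid[i]); grid points with an empty conditioning event hold
    NaN (flagged, never imputed).  ``smooth_*`` are cubic smoothing splines
    fitted to the defined points only, with the smoothing parameter chosen
    by generalised cross-validation; evaluations are clamped to [0, 1].
    """

    grid: np.ndarray
    p_female_below: np.ndarray
    p_male_above: np.ndarray
    _spline_female: object = field(default=None, repr=False)
    _spline_male: object = field(default=None, repr=False)

    def smooth_female(self, x: np.ndarray) -> np.ndarray:
        return np.clip(self._spline_female(x), 0.0, 1.0)

    def smooth_male(self, x: np.ndarray) -> np.ndarray:
        return np.clip(self._spline_male(x), 0.0, 1.0)


def _fit_curve_spline(grid: np.ndarray, probs: np.ndarray):
    defined = np.isfinite(probs)
    if defined.sum() < 4:
        raise SplineFitError(
            f"only {int(defined.sum())} defined probability points; need >= 4 "
            "to fit a smoothing spline (supply a larger dataset)"
        )
    return make_smoothing_spline(grid[defined], probs[defined])


def probability_curve(
    f_values: Sequence[float],
    m_values: Sequence[float],
    step: float = DEFAULT_STEP,
) -> ProbabilityCurve:
    """Posterior probability series over the pooled grid, with smooths."""
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    if f.size < 2 or m.size < 2:
        raise ValueError("need at least 2 values per sex for a probability curve")
    pooled = np.concatenate([f, m])
    grid = threshold_grid(pooled, step)

    fs, ms = np.sort(f), np.sort(m)
    # strict inequalities: side="left" counts values < x0, n - side="right" counts > x0
    pf_below = np.searchsorted(fs, grid, side="left") / f.size
    pm_below = np.searchsorted(ms, grid, side="left") / m.size
    pf_above = (f.size - np.searchsorted(fs, grid, side="right")) / f.size
    pm_above = (m.size - np.searchsorted(ms, grid, side="right")) / m.size

    with np.errstate(invalid="ignore", divide="ignore"):
        p_female_below = np.where(
            pf_below + pm_below > 0, pf_below / (pf_below + pm_below), np.nan
        )
        p_male_above = np.where(
            pf_above + pm_above > 0, pm_above / (pf_above + pm_above), np.nan
        )

    return ProbabilityCurve(
        grid=grid,
        p_female_below=p_female_below,
        p_male_above=p_male_above,
        _spline_female=_fit_curve_spline(grid, p_female_below),
        _spline_male=_fit_curve_spline(grid, p_male_above),
    )


def likelihood_threshold(
    curve: ProbabilityCurve,
    level: float,
    target_sex: str,
    fallback_to_extremum: bool = False,
) -> ThresholdEstimate:
    """Testosterone cutoff at which the smoothed posterior reaches ``level``.

    For ``target_sex="F"``: the largest grid value whose smoothed
    P(F | T < x) is still >= level — below it an animal is at least
    ``level`` likely to be female.  For ``"M"``: the smallest grid value
    whose smoothed P(M | T > x) is >= level.  If the smooth never reaches
    the level, raises :class:`NoThresholdError` unless
    ``fallback_to_extremum`` is set, in which case the relevant grid
    extremum is returned flagged ``at_extremum``.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("likelihood level must be in (0.5, 1)")
    if target_sex == "F":
        smoothed = curve.smooth_female(curve.grid)
        hits = np.flatnonzero(smoothed >= level)
        pick, extremum = (hits[-1] if hits.size else None), 0
    elif target_sex == "M":
        smoothed = curve.smooth_male(curve.grid)
        hits = np.flatnonzero(smoothed >= level)
        pick, extremum = (hits[0] if hits.size else None), -1
    else:
        raise ValueError("target_sex must be 'F' or 'M'")

    if pick is None:
        if not fallback_to_extremum:
            raise NoThresholdError(
                f"smoothed P({target_sex}) never reaches level {level:g} on the grid"
            )
        pick = extremum
    return ThresholdEstimate(
        kind="T_P",
        value=float(curve.grid[pick]),
        level=level,
        target_sex=target_sex,
        at_extremum=(pick is None or not hits.size),
    )


def _band(t_pf: ThresholdEstimate | float, t_pm: ThresholdEstimate | float) -> tuple[float, float]:
    lo = t_pf.value if isinstance(t_pf, ThresholdEstimate) else float(t_pf)
    hi = t_pm.value if isinstance(t_pm, ThresholdEstimate) else float(t_pm)
    if lo > hi:
        raise BandCollapseError(
            f"female threshold {lo:g} exceeds male threshold {hi:g}: the "
            "'unknown' band is inverted; assign sexes with the equal-error "
            "threshold instead"
        )
    return lo, hi


def assign_sex(
    t_value: float,
    t_pf: ThresholdEstimate | float,
    t_pm: ThresholdEstimate | float,
) -> str:
    """Three-way sex call: F below the band, M above it, unknown inside.

    Values exactly at either boundary are scored unknown.  Raises
    :class:`BandCollapseError` when the band is inverted (well-separated
    sexes), in which case the two-way equal-error call is the right tool.
    """
    lo, hi = _band(t_pf, t_pm)
    if t_value < lo:
        return "F"
    if t_value > hi:
        return "M"
    return "unknown"


def exclusion_rates(
    f_values: Sequence[float],
    m_values: Sequence[float],
    t_pf: ThresholdEstimate | float,
    t_pm: ThresholdEstimate | float,
) -> tuple[float, float]:
    """Fractions of true females / males scored "unknown" under the band."""
    lo, hi = _band(t_pf, t_pm)
    f = _as_values(f_values, "F")
    m = _as_values(m_values, "M")
    return (
        float(np.count_nonzero(f >= lo)) / f.size,
        float(np.count_nonzero(m <= hi)) / m.size,
    )


def assign_sex_two_way(t_value: float, threshold: ThresholdEstimate | float) -> str:
    """Two-way call at a T_m/T_E threshold: female iff value <= threshold."""
    thr = threshold.value if isinstance(threshold, ThresholdEstimate) else float(threshold)
    return "F" if t_value <= thr else "M"
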