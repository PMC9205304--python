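"""End-to-end report assembly: thresholds and validation per study group.

A "group" is an age class x treatment cell (neonate/hatchling/juvenile x
naive/post-FSH).  For each group with both sexes represented the threshold
report gives the minimum-total-error threshold (T_m), the equal-error
threshold (T_E) with bootstrap CIs on the threshold and on both per-sex
error rates, and the likelihood thresholds at each requested level with
the per-sex fractions that would be scored "unknown".  The validation
report gives leave-one-out cross-validated error rates for the threshold
rules, which are comparable to a random forest's out-of-bag errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import BandCollapseError, EndosexError
from .io import SexingDataset
from .resampling import loocv_threshold_error
from .thresholds import (
    equal_error_threshold,
    exclusion_rates,
    likelihood_threshold,
    min_total_error_threshold,
    probability_curve,
)

logger = logging.getLogger(__name__)

_FITTERS = {"T_m": min_total_error_threshold, "T_E": equal_error_threshold}


@dataclass
class RunConfig:
    """Settings for a full calibration/validation run."""

    group_keys: tuple[str, ...] = ("age_class", "treatment")
    step: float = 0.1
    levels: tuple[float, ...] = (0.8, 0.9, 0.95)
    n_boot: int = 1000
    seed: int | None = None
    estimators: tuple[str, ...] = ("T_m", "T_E")
    tie: str = "smallest"


def _groups(dataset: SexingDataset, config: RunConfig):
    df = dataset.hormone
    if df is None or len(df) == 0:
        raise ValueError("dataset has no hormone records")
    df = df[df["true_sex"].isin(["F", "M"])]
    for key, grp in df.groupby(list(config.group_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        f = grp.loc[grp["true_sex"] == "F", "testosterone"].to_numpy(float)
        m = grp.loc[grp["true_sex"] == "M", "testosterone"].to_numpy(float)
        if f.size < 2 or m.size < 2:
            logger.warning("group %s skipped: needs >= 2 known-sex animals per sex", key)
            continue
        logger.info("group %s: n_female=%d n_male=%d grid=[%g, %g]",
                    key, f.size, m.size, min(f.min(), m.min()), max(f.max(), m.max()))
        yield key, f, m


def _bootstrap_threshold(f, m, fit, step, tie, n_boot, rng):
    """Joint bootstrap of (threshold, err_female, err_male); stratified."""
    reps = np.full((n_boot, 3), np.nan)
    for b in range(n_boot):
        fb = f[rng.integers(0, f.size, f.size)]
        mb = m[rng.integers(0, m.size, m.size)]
        est = fit(fb, mb, step=step, tie=tie)
        reps[b] = (est.value, est.error_rates.err_female, est.error_rates.err_male)
    lo, hi = np.nanpercentile(reps, [2.5, 97.5], axis=0)
    return lo, hi


def run_threshold_report(dataset: SexingDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-group threshold table (long format, one row per estimator/level).

    Columns: group keys, per-sex n, estimator, level, threshold and its
    bootstrap CI, and the per-sex error rates (T_m/T_E, with CIs) or
    "unknown" fractions (likelihood thresholds).  Likelihood rows whose
    female threshold exceeds the male one are flagged ``band_collapsed``
    — there the equal-error rule already meets that accuracy level.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for key, f, m in _groups(dataset, config):
        base = dict(zip(config.group_keys, key))
        base.update(n_female=f.size, n_male=m.size)

        for name in config.estimators:
            fit = _FITTERS[name]
            est = fit(f, m, step=config.step, tie=config.tie)
            row = dict(base, estimator=name, level=np.nan,
                       threshold=est.value,
                       err_female=est.error_rates.err_female,
                       err_male=est.error_rates.err_male,
                       band_collapsed=False)
            if config.n_boot > 0:
                lo, hi = _bootstrap_threshold(
                    f, m, fit, config.step, config.tie, config.n_boot, rng
                )
                row.update(
                    threshold_ci_low=lo[0], threshold_ci_high=hi[0],
                    err_female_ci_low=lo[1], err_female_ci_high=hi[1],
                    err_male_ci_low=lo[2], err_male_ci_high=hi[2],
                )
            rows.append(row)

        if config.levels:
            curve = probability_curve(f, m, step=config.step)
            for level in config.levels:
                t_pf = likelihood_threshold(curve, level, "F", fallback_to_extremum=True)
                t_pm = likelihood_threshold(curve, level, "M", fallback_to_extremum=True)
                row = dict(base, estimator="T_P", level=level,
                           t_pf=t_pf.value, t_pm=t_pm.value)
                try:
                    unk_f, unk_m = exclusion_rates(f, m, t_pf, t_pm)
                    row.update(unknown_female=unk_f, unknown_male=unk_m,
                               band_collapsed=False)
                except BandCollapseError:
                    row.update(unknown_female=np.nan, unknown_male=np.nan,
                               band_collapsed=True)
                rows.append(row)
    if not rows:
        raise EndosexError("no group had both sexes represented")
    return pd.DataFrame(rows)


def run_validation_report(dataset: SexingDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-group leave-one-out cross-validation of the threshold rules."""
    config = config or RunConfig()
    rows = []
    for key, f, m in _groups(dataset, config):
        if f.size < 3 or m.size < 3:
            logger.warning("group %s skipped for LOOCV: needs >= 3 per sex", key)
            continue
        for name in config.estimators:
            est = _FITTERS[name](f, m, step=config.step, tie=config.tie)
            cv = loocv_threshold_error((f, m), estimator=name, step=config.step)
            rows.append(dict(
                zip(config.group_keys, key),
                approach=name, threshold=est.value,
                n_female=f.size, n_male=m.size,
                err_overall=cv.err_overall,
                err_female=cv.err_female, err_male=cv.err_male,
            ))
    if not rows:
        raise EndosexError("no group had enough known-sex animals for LOOCV")
    return pd.DataFrame(rows)
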