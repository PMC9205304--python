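"""Uncertainty and validation machinery for threshold classifiers.

Three tools:

* **stratified bootstrap** — females and males are resampled independently
  with replacement at their original sample sizes; the threshold (or any
  other functional of the two samples) is re-estimated on each replicate
  and the 2.5%/97.5% quantiles of the resulting sampling distribution give
  a 95% percentile interval;
* **leave-one-out cross-validation** — each animal is held out in turn,
  the threshold refit on the remainder, and the held-out animal classified
  (female iff value <= threshold); the resulting per-sex error fractions
  are honest analogues of a random forest's out-of-bag error;
* **permutation t-tests** — a Welch t statistic whose null distribution is
  built by permuting group labels, used to compare the testosterone rise
  after an FSH challenge between males and females.

Every stochastic routine takes a seed and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import BootstrapError
from .io import SexingDataset
from .thresholds import (
    ThresholdEstimate,
    equal_error_threshold,
    min_total_error_threshold,
)

_ESTIMATORS = {
    "T_m": min_total_error_threshold,
    "T_E": equal_error_threshold,
}


@dataclass
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int | None
    replicates: np.ndarray | None = None


@dataclass
class CVResult:
    err_female: float
    err_male: float
    err_overall: float
    n_folds: int


@dataclass
class PermutationTestResult:
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    mean_difference: float
    n_perm: int


@dataclass
class FSHResponse:
    """Paired testosterone measurements around an FSH challenge."""

    id: str
    pre: float   # naive concentration, pg/mL
    post: float  # post-FSH concentration, pg/mL
    sex: str = "unknown"

    @property
    def delta(self) -> float:
        return self.post - self.pre

    @property
    def pct_change(self) -> float:
        if self.pre <= 0:
            raise ValueError(f"pair {self.id}: percent change undefined for pre <= 0")
        return 100.0 * self.delta / self.pre


@dataclass
class FSHSummary:
    mean_delta: float
    se_delta: float
    mean_pct_change: float
    n: int


def bootstrap_ci(
    f_values: Sequence[float],
    m_values: Sequence[float],
    estimator: Callable[[np.ndarray, np.ndarray], float | ThresholdEstimate],
    n_replicates: int = 1000,
    seed: int | None = None,
    keep_replicates: bool = False,
    max_failure_frac: float = 0.1,
) -> BootstrapResult:
    """Stratified bootstrap 95% percentile interval for a two-sample functional.

    ``estimator(f, m)`` may return a float or a :class:`ThresholdEstimate`
    (whose ``value`` is used).  Replicates in which the estimator raises are
    recorded as missing; more than ``max_failure_frac`` failures aborts.
    """
    f = np.asarray(f_values, dtype=float)
    m = np.asarray(m_values, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("need at least 2 values per sex to bootstrap")

    def _value(res):
        return res.value if isinstance(res, ThresholdEstimate) else float(res)

    point = _value(estimator(f, m))
    rng = np.random.default_rng(seed)
    reps = np.full(n_replicates, np.nan)
    for b in range(n_replicates):
        fb = f[rng.integers(0, f.size, f.size)]
        mb = m[rng.integers(0, m.size, m.size)]
        try:
            reps[b] = _value(estimator(fb, mb))
        except Exception:
            pass
    n_failed = int(np.count_nonzero(np.isnan(reps)))
    if n_failed > max_failure_frac * n_replicates:
        raise BootstrapError(
            f"{n_failed}/{n_replicates} bootstrap replicates failed"
        )
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return BootstrapResult(
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_replicates,
        seed=seed,
        replicates=reps if keep_replicates else None,
    )


def loocv_threshold_error(
    data: SexingDataset | tuple[Sequence[float], Sequence[float]],
    estimator: str = "T_E",
    step: float = 0.1,
    age_class: str | None = None,
    treatment: str | None = None,
    tie: str = "midpoint",
) -> CVResult:
    """Leave-one-out cross-validated error of a T_m or T_E sex call.

    For each animal the threshold is refit on all remaining animals and
    the held-out animal is classified female iff its value is <= the refit
    threshold.  The overall error pools misclassifications over animals,
    so it reflects the sample's sex ratio.

    The refit threshold uses the *midpoint* of the run of equally optimal
    grid values by default (not the reporting convention's smallest
    value): removing the boundary animal of a well-separated sample
    shifts the optimal run's edge to that animal's neighbour, so the
    smallest-value rule would misclassify the largest female of every
    perfectly separated dataset, overstating LOOCV error where the
    apparent error is zero.
    """
    if isinstance(data, SexingDataset):
        f = data.hormone_values("F", age_class=age_class, treatment=treatment)
        m = data.hormone_values("M", age_class=age_class, treatment=treatment)
    else:
        f, m = (np.asarray(v, dtype=float) for v in data)
    if f.size < 3 or m.size < 3:
        raise ValueError("need at least 3 known-sex animals per sex for LOOCV")
    fit = _ESTIMATORS[estimator]

    mis_f = 0
    for i in range(f.size):
        thr = fit(np.delete(f, i), m, step=step, tie=tie).value
        if f[i] > thr:
            mis_f += 1
    mis_m = 0
    for j in range(m.size):
        thr = fit(f, np.delete(m, j), step=step, tie=tie).value
        if m[j] <= thr:
            mis_m += 1

    n = f.size + m.size
    return CVResult(
        err_female=mis_f / f.size,
        err_male=mis_m / m.size,
        err_overall=(mis_f + mis_m) / n,
        n_folds=n,
    )


def _welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, standard error and degrees of freedom."""
    nx, ny = x.size, y.size
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        return (0.0 if diff == 0.0 else np.inf * np.sign(diff)), 0.0, np.nan
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return diff / np.sqrt(se2), float(np.sqrt(se2)), float(df)


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Two-sided permutation t-test on the difference in group means.

    The test statistic is the Welch t; its null distribution is obtained by
    randomly permuting the pooled group labels ``n_perm`` times, and the
    p-value uses the add-one convention
    ``p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm)``.  A conventional
    Welch 95% CI on the mean difference is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    t_obs, se, df = _welch_t(x, y)
    diff = float(x.mean() - y.mean())

    if se == 0.0 and t_obs == 0.0:
        # both groups constant and equal: no evidence against the null
        return PermutationTestResult(0.0, 1.0, diff, diff, diff, n_perm)

    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    rng = np.random.default_rng(seed)
    # one permuted label assignment per row, evaluated vectorised
    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    perm = pooled[perm_idx]
    px, py = perm[:, :nx], perm[:, nx:]
    vx = px.var(axis=1, ddof=1)
    vy = py.var(axis=1, ddof=1)
    pdiff = px.mean(axis=1) - py.mean(axis=1)
    se2 = vx / nx + vy / (n - nx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(
            se2 > 0, pdiff / np.sqrt(se2), np.where(pdiff == 0, 0.0, np.inf)
        )
    p = (1 + np.count_nonzero(np.abs(t_perm) >= abs(t_obs))) / (1 + n_perm)

    if se > 0 and np.isfinite(df):
        crit = stats.t.ppf(0.975, df)
        ci_low, ci_high = diff - crit * se, diff + crit * se
    else:
        ci_low = ci_high = diff
    return PermutationTestResult(
        t_statistic=float(t_obs),
        p_value=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        mean_difference=diff,
        n_perm=n_perm,
    )


def paired_responses(
    dataset: SexingDataset, sex: str | None = None
) -> list[FSHResponse]:
    """Extract naive/post-FSH pairs linked by ``pair_key`` from a dataset."""
    df = dataset.hormone
    if df is None or "pair_key" not in df.columns:
        raise ValueError("dataset has no hormone table with pair_key column")
    df = df[df["pair_key"].notna()]
    pairs: list[FSHResponse] = []
    for key, grp in df.groupby("pair_key", sort=True):
        naive = grp[grp["treatment"] == "naive"]
        post = grp[grp["treatment"] == "postFSH"]
        if len(naive) != 1 or len(post) != 1:
            continue
        rec_sex = naive["true_sex"].iloc[0]
        if sex is not None and rec_sex != sex:
            continue
        pairs.append(
            FSHResponse(
                id=str(key),
                pre=float(naive["testosterone"].iloc[0]),
                post=float(post["testosterone"].iloc[0]),
                sex=rec_sex,
            )
        )
    return pairs


def fsh_response_summary(pairs: Iterable[FSHResponse]) -> FSHSummary:
    """Mean +/- SE absolute change and mean percent change over pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no FSH response pairs supplied")
    bad = [p.id for p in pairs if p.pre <= 0]
    if bad:
        raise ValueError(
            f"percent change undefined (pre <= 0) for pair(s): {', '.join(bad)}"
        )
    deltas = np.array([p.delta for p in pairs])
    pcts = np.array([p.pct_change for p in pairs])
    se = float(deltas.std(ddof=1) / np.sqrt(deltas.size)) if deltas.size > 1 else 0.0
    return FSHSummary(
        mean_delta=float(deltas.mean()),
        se_delta=se,
        mean_pct_change=float(pcts.mean()),
        n=len(pairs),
    )
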