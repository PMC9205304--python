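"""Synthetic datasets with the statistical structure of the tortoise study.

Raw plasma-testosterone data for young gopher tortoises show two
overlapping, strictly positive, right-skewed per-sex distributions whose
separation grows with age: neonates overlap heavily, hatchlings less so,
and juveniles separate completely.  The generator models each sex's
testosterone as lognormal, with preset location/scale back-solved from the
published per-sex sample means and standard errors at the published sample
sizes (SD = SE * sqrt(n)).  Lognormality is a modelling convenience — it
reproduces the positivity, the right skew and the occasional extreme male
value through its tail — and the real data are *not* exactly lognormal,
which is precisely why the threshold estimators downstream are
nonparametric.

Scenario presets (frozen constants):

===========================  =====================================================
``neonate_naive``            F: mean 17.9, SD 7.3 (n=44); M: mean 51.7, SD 57.3 (n=18)
``hatchling_naive``          F: mean 27.9, SD 13.8 (n=66); M: mean 206.0, SD 248.0 (n=25)
``juvenile_naive``           F: mean 79.8, SD 25.9 (n=11); M: mean 3341, SD 1497 (n=12)
``hatchling_postFSH_paired`` pre from hatchling_naive; post = pre * factor * noise,
                             factor 2.04 (F) / 3.61 (M)  (mean rises of 104% / 261%)
``null_no_dimorphism``       both sexes drawn from the hatchling female distribution
===========================  =====================================================

The FSH challenge is modelled as a *multiplicative*, male-biased response
on paired measurements: post = pre * sex factor * lognormal(mean 1) noise,
so post-challenge values stay positive and the expected percent change is
100 * (factor - 1) regardless of the noise scale.

Morphometrics are generated as positively correlated linear measurements:
a shared lognormal body-size factor times per-feature lognormal noise,
with males shifted on selected features by a standardized amount
(``morph_sex_shift``, in units of the residual log-scale SD).  The default
shift is weak, matching how faint shell dimorphism is at these ages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SexingDataset

SCENARIOS = (
    "neonate_naive",
    "hatchling_naive",
    "hatchling_postFSH_paired",
    "juvenile_naive",
    "null_no_dimorphism",
)

_SCENARIO_GROUP = {
    "neonate_naive": ("neonate", "naive"),
    "hatchling_naive": ("hatchling", "naive"),
    "hatchling_postFSH_paired": ("hatchling", "naive"),
    "juvenile_naive": ("juvenile", "naive"),
    "null_no_dimorphism": ("hatchling", "naive"),
}

#: Baseline linear measurements (mm) by age class; a neonate gopher
#: tortoise has a ~47 mm carapace, a hatchling ~66 mm.  PMAX is generated
#: as PMIN times (1 + gap) with a strictly positive gap, so PMIN < PMAX
#: holds for every record by construction.
MORPH_BASE = {
    "neonate": {"MCL": 47.0, "SH": 27.0, "CW": 42.0, "PMIN": 33.0},
    "hatchling": {"MCL": 66.0, "SH": 38.0, "CW": 59.0, "PMIN": 46.0},
}
MORPH_HATCHLING_BASE = {"AW": 18.0, "AN": 6.0, "GW": 14.0, "TL": 12.0}
_SIGMA_SIZE = 0.06   # log-SD of the shared body-size factor
_SIGMA_FEAT = 0.025  # residual per-feature log-SD
#: total per-feature log-SD; morph_sex_shift entries are standardized mean
#: differences in units of this (so shift=1 moves a feature's male mean by
#: one observed SD of that feature)
_SIGMA_TOTAL = float(np.sqrt(_SIGMA_SIZE**2 + _SIGMA_FEAT**2))
_GAP_MEAN = 0.18     # mean relative plastron gap (PMAX/PMIN - 1)
_GAP_SIGMA = 0.15

#: Default weak shell dimorphism: males shifted by ~0.5 residual SDs on a
#: few width/height features, in line with morphology alone being a poor
#: sex predictor at these ages.
DEFAULT_MORPH_SHIFT = {"CW": 0.5, "SH": 0.4, "PMAX": 0.3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Per-scenario generative parameters (log-scale locations/scales)."""

    scenario: str
    n_female: int
    n_male: int
    female_loc: float
    female_scale: float
    male_loc: float
    male_scale: float
    fsh_mult_female: float = 1.0
    fsh_mult_male: float = 1.0
    fsh_noise_scale: float = 0.3
    morph_sex_shift: dict = field(default_factory=dict)
    seed: int | None = None

    def female_dist(self) -> stats.rv_continuous:
        return stats.lognorm(s=self.female_scale, scale=np.exp(self.female_loc))

    def male_dist(self) -> stats.rv_continuous:
        return stats.lognorm(s=self.male_scale, scale=np.exp(self.male_loc))


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (location, scale) of a lognormal with given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def _preset(scenario, nf, nm, f_mean, f_sd, m_mean, m_sd, **kw) -> SyntheticConfig:
    floc, fscale = lognormal_params(f_mean, f_sd)
    mloc, mscale = lognormal_params(m_mean, m_sd)
    return SyntheticConfig(
        scenario=scenario, n_female=nf, n_male=nm,
        female_loc=floc, female_scale=fscale,
        male_loc=mloc, male_scale=mscale,
        morph_sex_shift=dict(DEFAULT_MORPH_SHIFT), **kw,
    )


def _build_presets() -> dict[str, SyntheticConfig]:
    # per-sex sample mean, SE and n as published; SD = SE * sqrt(n)
    neo = _preset("neonate_naive", 44, 18,
                  17.9, 1.1 * np.sqrt(44), 51.7, 13.5 * np.sqrt(18))
    hat = _preset("hatchling_naive", 66, 25,
                  27.9, 1.7 * np.sqrt(66), 206.0, 49.6 * np.sqrt(25))
    juv = _preset("juvenile_naive", 11, 12,
                  79.8, 7.8 * np.sqrt(11), 3341.0, 432.0 * np.sqrt(12))
    fsh = dataclasses.replace(
        _preset("hatchling_postFSH_paired", 65, 23,
                27.9, 1.7 * np.sqrt(66), 206.0, 49.6 * np.sqrt(25)),
        fsh_mult_female=2.04, fsh_mult_male=3.61, fsh_noise_scale=0.3,
    )
    floc, fscale = lognormal_params(27.9, 1.7 * np.sqrt(66))
    null = SyntheticConfig(
        scenario="null_no_dimorphism", n_female=50, n_male=50,
        female_loc=floc, female_scale=fscale,
        male_loc=floc, male_scale=fscale,
        morph_sex_shift={},
    )
    return {c.scenario: c for c in (neo, hat, juv, fsh, null)}


_PRESETS = _build_presets()


def scenario_config(name: str, seed: int | None = None, **overrides) -> SyntheticConfig:
    """Frozen preset for a named scenario, with optional field overrides."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    return dataclasses.replace(_PRESETS[name], seed=seed, **overrides)


def analytic_equal_error_threshold(config: SyntheticConfig) -> float:
    """Population equal-error point of the preset distributions.

    Solves 1 - CDF_F(t) = CDF_M(t) by numeric root finding; this is the
    value the empirical equal-error threshold should recover as the sample
    size grows.
    """
    fd, md = config.female_dist(), config.male_dist()

    def gap(t):
        return fd.sf(t) - md.cdf(t)

    lo = min(fd.ppf(1e-9), md.ppf(1e-9))
    hi = max(fd.ppf(1 - 1e-9), md.ppf(1 - 1e-9))
    return float(optimize.brentq(gap, lo, hi))


def _hormone_frame(f_vals, m_vals, age_class, treatment, id_prefix="") -> pd.DataFrame:
    nf, nm = len(f_vals), len(m_vals)
    return pd.DataFrame({
        "id": [f"{id_prefix}F{i:04d}" for i in range(nf)]
        + [f"{id_prefix}M{i:04d}" for i in range(nm)],
        "age_class": age_class,
        "treatment": treatment,
        "testosterone": np.concatenate([f_vals, m_vals]),
        "true_sex": ["F"] * nf + ["M"] * nm,
    })


def generate_hormone_dataset(config: SyntheticConfig) -> SexingDataset:
    """Draw one naive-testosterone dataset under the config's distributions."""
    rng = np.random.default_rng(config.seed)
    f = rng.lognormal(config.female_loc, config.female_scale, config.n_female)
    m = rng.lognormal(config.male_loc, config.male_scale, config.n_male)
    age_class, treatment = _SCENARIO_GROUP.get(config.scenario, ("hatchling", "naive"))
    df = _hormone_frame(f, m, age_class, treatment)
    return SexingDataset(hormone=df, metadata={"scenario": config.scenario, "seed": config.seed})


def generate_paired_fsh(config: SyntheticConfig) -> SexingDataset:
    """Paired naive / post-FSH records sharing a pair key.

    post = pre * sex-specific factor * lognormal noise with mean 1
    (log-SD ``fsh_noise_scale``), so post > 0 always and the expected
    percent change is 100 * (factor - 1) for each sex.
    """
    rng = np.random.default_rng(config.seed)
    age_class = _SCENARIO_GROUP.get(config.scenario, ("hatchling", "naive"))[0]
    frames = []
    for sex, n, loc, scale, mult in (
        ("F", config.n_female, config.female_loc, config.female_scale, config.fsh_mult_female),
        ("M", config.n_male, config.male_loc, config.male_scale, config.fsh_mult_male),
    ):
        pre = rng.lognormal(loc, scale, n)
        s = config.fsh_noise_scale
        noise = rng.lognormal(-0.5 * s**2, s, n) if s > 0 else np.ones(n)
        post = pre * mult * noise
        ids = [f"{sex}{i:04d}" for i in range(n)]
        for treatment, vals in (("naive", pre), ("postFSH", post)):
            frames.append(pd.DataFrame({
                "id": ids,
                "age_class": age_class,
                "treatment": treatment,
                "testosterone": vals,
                "true_sex": sex,
                "pair_key": ids,
            }))
    df = pd.concat(frames, ignore_index=True)
    return SexingDataset(hormone=df, metadata={"scenario": config.scenario, "seed": config.seed})


def generate_morph_dataset(config: SyntheticConfig) -> SexingDataset:
    """Correlated positive linear measurements with weak sex dimorphism.

    Each animal gets a shared lognormal size factor; each measurement is
    its age-class baseline times the size factor times residual lognormal
    noise.  Males are shifted on the features named in
    ``morph_sex_shift`` by shift * residual-SD on the log scale.  PMAX is
    PMIN times one plus a strictly positive relative gap.
    """
    rng = np.random.default_rng(config.seed)
    age_class = _SCENARIO_GROUP.get(config.scenario, ("neonate", "naive"))[0]
    base = MORPH_BASE.get(age_class, MORPH_BASE["neonate"])
    extras = MORPH_HATCHLING_BASE if age_class == "hatchling" else {}
    shift = config.morph_sex_shift

    rows = []
    for sex, n in (("F", config.n_female), ("M", config.n_male)):
        size = rng.lognormal(0.0, _SIGMA_SIZE, n)
        rec = {"id": [f"{sex}{i:04d}" for i in range(n)], "true_sex": sex}
        for feat, mean in {**base, **extras}.items():
            mu = shift.get(feat, 0.0) * _SIGMA_TOTAL if sex == "M" else 0.0
            rec[feat] = mean * size * rng.lognormal(mu, _SIGMA_FEAT, n)
        gap_mu = shift.get("PMAX", 0.0) * _SIGMA_TOTAL if sex == "M" else 0.0
        gap = _GAP_MEAN * rng.lognormal(gap_mu, _GAP_SIGMA, n)
        rec["PMAX"] = rec["PMIN"] * (1.0 + gap)
        rows.append(pd.DataFrame(rec))
    df = pd.concat(rows, ignore_index=True)
    cols = ["id"] + list(base) + ["PMAX"] + list(extras) + ["true_sex"]
    df = df[[c for c in cols if c in df.columns]]
    return SexingDataset(morph=df, metadata={"scenario": config.scenario, "seed": config.seed})
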