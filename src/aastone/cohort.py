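"""Synthetic case-control cohort generation for the urinary amino-acid panel.

The study this package models compared 24-hour urinary concentrations of 35
amino acids and derivatives between recurrent kidney-stone formers (SF, n=15)
and healthy controls (CNT, n=12).  Raw per-subject concentrations were never
deposited; only group summaries (mean +/- SD per analyte) are public.  This
module therefore generates cohorts whose per-group first and second moments
match those summaries, so that the classification pipeline can be exercised
and validated end to end.

Each analyte x group cell is sampled i.i.d. from a positive-support
distribution moment-matched to the target (mean, SD):

* ``lognormal`` (default): closed-form matching with
  ``sigma^2 = ln(1 + s^2/m^2)`` and ``mu = ln(m) - sigma^2/2``.
* ``truncated-normal``: a normal truncated at zero whose parent parameters
  are solved numerically so the *realized* (post-truncation) moments match.
  Naive truncation of N(m, s) inflates the mean of low-abundance analytes.

Sampling streams are derived per (analyte, group) from the root seed, so
adding or removing analytes never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .io import CohortTable

__all__ = [
    "AnalyteSpec",
    "CohortSpec",
    "PANEL_35",
    "DISCRIMINANT_ANALYTES",
    "default_cohort_spec",
    "generate_cohort",
    "draw_group",
]

# The 35-analyte targeted panel, in assay order.
PANEL_35: tuple[str, ...] = (
    "alanine",
    "alpha-aminobutyric acid",
    "aminoadipic acid",
    "anserine",
    "arginine",
    "asparagine",
    "aspartic acid",
    "beta-alanine",
    "beta-aminobutyric acid",
    "carnosine",
    "citrulline",
    "cystine",
    "ethanolamine",
    "gamma-aminobutyric acid",
    "glycine",
    "glutamic acid",
    "histidine",
    "isoleucine",
    "4-hydroxyproline",
    "leucine",
    "lysine",
    "methionine",
    "1-methylhistidine",
    "3-methylhistidine",
    "ornithine",
    "phenylalanine",
    "phosphoethanolamine",
    "proline",
    "sarcosine",
    "serine",
    "taurine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
)

# Published group summaries for the nine analytes that separated stone
# formers from controls: (mean_cnt, sd_cnt, mean_sf, sd_sf), concentration
# units as printed.  All nine are lower in stone formers.
_DISCRIMINANT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "alpha-aminobutyric acid": (14.0, 5.8, 6.1, 2.5),
    "asparagine": (214.5, 73.2, 71.4, 44.0),
    "ethanolamine": (365.4, 69.9, 215.3, 87.6),
    "isoleucine": (9.9, 3.7, 4.2, 3.8),
    "methionine": (8.2, 2.8, 2.7, 2.7),
    "phenylalanine": (49.5, 13.2, 24.7, 15.4),
    "serine": (354.1, 109.0, 105.6, 93.8),
    "tryptophan": (61.2, 14.3, 33.5, 21.5),
    "valine": (34.4, 12.0, 15.2, 11.4),
}

DISCRIMINANT_ANALYTES: tuple[str, ...] = tuple(sorted(_DISCRIMINANT_PARAMS))

# Plausible 24-h urinary levels for the 26 non-discriminant panel members
# (their per-subject values were never published).  Identical in both
# groups, so they carry no class signal; SD set to 35% of the mean, a
# typical between-subject spread for urinary amino acids.
_NULL_ANALYTE_MEANS: dict[str, float] = {
    "alanine": 240.0,
    "aminoadipic acid": 35.0,
    "anserine": 15.0,
    "arginine": 20.0,
    "aspartic acid": 15.0,
    "beta-alanine": 25.0,
    "beta-aminobutyric acid": 15.0,
    "carnosine": 30.0,
    "citrulline": 10.0,
    "cystine": 60.0,
    "gamma-aminobutyric acid": 5.0,
    "glycine": 1100.0,
    "glutamic acid": 25.0,
    "histidine": 650.0,
    "4-hydroxyproline": 12.0,
    "leucine": 40.0,
    "lysine": 150.0,
    "1-methylhistidine": 230.0,
    "3-methylhistidine": 180.0,
    "ornithine": 30.0,
    "phosphoethanolamine": 45.0,
    "proline": 18.0,
    "sarcosine": 6.0,
    "taurine": 600.0,
    "threonine": 130.0,
    "tyrosine": 80.0,
}

_NULL_CV = 0.35


@dataclass(frozen=True)
class AnalyteSpec:
    """Target per-group moments for one analyte.

    Means must be strictly positive; SDs non-negative (an SD of zero yields a
    constant column, useful for degenerate-noise checks).
    """

    name: str
    mean_cnt: float
    sd_cnt: float
    mean_sf: float
    sd_sf: float
    discriminant: bool = False

    def __post_init__(self) -> None:
        if self.mean_cnt <= 0 or self.mean_sf <= 0:
            raise ValueError(
                f"analyte {self.name!r}: group means must be strictly positive"
            )
        if self.sd_cnt < 0 or self.sd_sf < 0:
            raise ValueError(f"analyte {self.name!r}: SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic case-control cohort.

    Parameters
    ----------
    analytes
        Ordered panel of :class:`AnalyteSpec`.
    n_sf, n_cnt
        Number of stone-former (case) and control samples.
    distribution
        ``"lognormal"`` or ``"truncated-normal"``; both are moment-matched
        to each analyte's (mean, SD) and have strictly positive support.
    seed
        Root seed; per-(analyte, group) streams are derived from it.
    rho
        Optional equicorrelation on the latent Gaussian scale (0 = analytes
        independent).  Exposed because the classifier is motivated by
        correlated predictors.
    """

    analytes: tuple[AnalyteSpec, ...]
    n_sf: int = 15
    n_cnt: int = 12
    distribution: str = "lognormal"
    seed: int = 0
    rho: float = 0.0

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")
        if self.n_sf < 2 or self.n_cnt < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.distribution not in ("lognormal", "truncated-normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")

    @property
    def analyte_names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @property
    def discriminant_names(self) -> list[str]:
        return [a.name for a in self.analytes if a.discriminant]

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def default_cohort_spec(
    *,
    n_sf: int = 15,
    n_cnt: int = 12,
    distribution: str = "lognormal",
    seed: int = 0,
    rho: float = 0.0,
) -> CohortSpec:
    """Build the default study-cohort spec: 15 SF vs 12 CNT, 35 analytes.

    Nine analytes carry the published discriminant group summaries (all
    lower in stone formers); the remaining 26 are null analytes with
    identical distributions in both groups.
    """
    analytes = []
    for name in PANEL_35:
        if name in _DISCRIMINANT_PARAMS:
            m_cnt, s_cnt, m_sf, s_sf = _DISCRIMINANT_PARAMS[name]
            analytes.append(
                AnalyteSpec(name, m_cnt, s_cnt, m_sf, s_sf, discriminant=True)
            )
        else:
            m = _NULL_ANALYTE_MEANS[name]
            s = _NULL_CV * m
            analytes.append(AnalyteSpec(name, m, s, m, s, discriminant=False))
    return CohortSpec(
        analytes=tuple(analytes),
        n_sf=n_sf,
        n_cnt=n_cnt,
        distribution=distribution,
        seed=seed,
        rho=rho,
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a lognormal with the given arithmetic moments."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _truncnorm_moments_std(alpha: float) -> tuple[float, float]:
    """Mean and variance of a standard normal truncated below at ``alpha``."""
    lam = float(np.exp(stats.norm.logpdf(alpha) - stats.norm.logsf(alpha)))
    m = lam - alpha
    v = 1.0 + alpha * lam - lam**2
    return m, v


_ALPHA_RANGE = (-40.0, 40.0)  # attainable CV roughly (0.025, 0.9992)


def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal matching (mean, sd).

    Truncating N(mu, sigma) at zero shifts its realized mean upward and
    shrinks its SD, so parent parameters must be solved for.  The CV of a
    zero-truncated normal depends only on alpha = -mu/sigma, increases
    monotonically in alpha, and is bounded above by 1; target CVs at or
    beyond the attainable range are capped (mean still matched exactly,
    realized SD then falls just short of target).
    """

    def cv_gap(alpha: float) -> float:
        m, v = _truncnorm_moments_std(alpha)
        return float(np.sqrt(v) / m) - cv_target

    cv = sd / mean
    lo, hi = _ALPHA_RANGE
    cv_min, cv_max = (
        _truncnorm_moments_std(lo)[1] ** 0.5 / _truncnorm_moments_std(lo)[0],
        _truncnorm_moments_std(hi)[1] ** 0.5 / _truncnorm_moments_std(hi)[0],
    )
    cv_target = float(np.clip(cv, cv_min * 1.0001, cv_max * 0.9999))
    alpha = optimize.brentq(cv_gap, lo, hi, xtol=1e-12)
    m_std, _ = _truncnorm_moments_std(alpha)
    sigma = mean / m_std
    return float(-alpha * sigma), float(sigma)


def _stream(seed: int, analyte: str, group: str) -> np.random.Generator:
    """Deterministic per-(analyte, group) RNG derived from the root seed."""
    key = zlib.crc32(f"{group}|{analyte}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _latent_normal(
    spec: CohortSpec, analyte: str, group: str, n: int
) -> np.ndarray:
    """Standard-normal draws, optionally equicorrelated across analytes."""
    z = _stream(spec.seed, analyte, group).standard_normal(n)
    if spec.rho > 0.0:
        shared = _stream(spec.seed, "__shared__", group).standard_normal(n)
        z = np.sqrt(spec.rho) * shared + np.sqrt(1.0 - spec.rho) * z
    return z


def draw_group(spec: CohortSpec, analyte_name: str, group: str, n: int) -> np.ndarray:
    """Draw ``n`` concentrations for one analyte in one group ("SF"/"CNT").

    Exposed for moment-recovery checks at large ``n`` without building a
    full cohort table.
    """
    matching = [a for a in spec.analytes if a.name == analyte_name]
    if not matching:
        raise KeyError(f"analyte {analyte_name!r} not in spec")
    a = matching[0]
    if group == "SF":
        mean, sd = a.mean_sf, a.sd_sf
    elif group == "CNT":
        mean, sd = a.mean_cnt, a.sd_cnt
    else:
        raise ValueError(f"group must be 'SF' or 'CNT', got {group!r}")

    if sd == 0.0:
        return np.full(n, mean)

    z = _latent_normal(spec, analyte_name, group, n)
    if spec.distribution == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return np.exp(mu + sigma * z)
    # truncated-normal: map latent normal through the truncated CDF so the
    # equicorrelation structure carries over.
    mu, sigma = _truncnorm_params(mean, sd)
    a_std = -mu / sigma
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(u, a_std, np.inf, loc=mu, scale=sigma)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Generate a labelled concentration table from a :class:`CohortSpec`.

    Controls come first (label 0), then stone formers (label 1).  Identical
    spec (including seed) always yields the identical table.
    """
    n = spec.n_cnt + spec.n_sf
    names = spec.analyte_names
    X = np.empty((n, len(names)))
    for j, name in enumerate(names):
        X[:spec.n_cnt, j] = draw_group(spec, name, "CNT", spec.n_cnt)
        X[spec.n_cnt:, j] = draw_group(spec, name, "SF", spec.n_sf)
    y = np.concatenate(
        [np.zeros(spec.n_cnt, dtype=int), np.ones(spec.n_sf, dtype=int)]
    )
    sample_ids = [f"CNT{i + 1:02d}" for i in range(spec.n_cnt)] + [
        f"SF{i + 1:02d}" for i in range(spec.n_sf)
    ]
    return CohortTable(sample_ids=sample_ids, X=X, analyte_names=list(names), y=y)
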