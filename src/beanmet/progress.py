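"""Bayesian genetic-progress regression of a trait on cultivar release year.

The model is simple linear regression, y_i = beta0 + beta1 * X_i + eps_i with
eps ~ N(0, sigma2), fit by Gibbs sampling under vague conjugate priors
(Gaussian on the coefficients, scaled-inverse-chi-square on sigma2).  The
predictor is centred at the mean release year, which makes beta0 the trait
mean of the panel and decorrelates the coefficient updates; beta1 is in trait
units per calendar year and is unchanged by the centring.

The response unit is genotype x N-level means (trait values averaged over
environments and blocks), so beta0 matches the overall N-level mean of the
trait.  Genetic progress in percent per year is the posterior of
100 * beta1 / beta0, summarized per draw; the plug-in ratio of posterior
means, 100 * E[beta1] / E[beta0], is also exposed because the two can differ
in the last printed decimal.

Progress under high vs low N is compared by the overlap of the two beta1 HPD
intervals: no overlap = significant difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, UsageError
from .mcmc_core import (
    Chain,
    DESK_SETTINGS,
    MCMCSettings,
    PosteriorSummary,
    hpd_interval,
    intervals_overlap,
)

__all__ = [
    "ProgressFit",
    "ProgressComparison",
    "genotype_means",
    "fit_progress",
    "percent_progress",
    "percent_progress_plugin",
    "compare_progress",
]

#: Publication-scale chain for this regression (the published description of
#: the burn-in is self-contradictory; this is the resolution used here).
FULL_SCALE_PROGRESS_SETTINGS = MCMCSettings(n_total=100_000, burn_in=10_000, thin=10)


@dataclass
class ProgressFit:
    """Posterior of (beta0, beta1, sigma2) for one trait x N-level panel."""

    chain: Chain
    trait: str
    n_level: str
    center_year: float

    @property
    def beta0(self) -> np.ndarray:
        return self.chain.column("beta0")

    @property
    def beta1(self) -> np.ndarray:
        return self.chain.column("beta1")

    def beta1_summary(self, level: float = 0.95) -> PosteriorSummary:
        b1 = self.beta1
        low, high = hpd_interval(b1, level)
        return PosteriorSummary(
            mean=float(b1.mean()),
            median=float(np.median(b1)),
            hpd_low=low,
            hpd_high=high,
            level=level,
        )


@dataclass(frozen=True)
class ProgressComparison:
    """Delta-beta1 verdict between two fits of the same trait."""

    trait: str
    delta_mean: float
    hpd_a: tuple[float, float]
    hpd_b: tuple[float, float]
    significant: bool


def genotype_means(
    traits_df: pd.DataFrame,
    cultivars: pd.DataFrame,
    trait: str,
    n_level: str | None = None,
) -> pd.DataFrame:
    """Genotype(-by-N) trait means joined with release years.

    Averages the trait over environments and blocks.  With ``n_level`` given,
    restricts to that stratum; otherwise keeps an ``n_level`` column so both
    panels come back at once.
    """
    df = traits_df.dropna(subset=[trait])
    if n_level is not None:
        df = df[df["n_level"] == n_level]
        group = ["genotype"]
    else:
        group = ["genotype", "n_level"]
    means = df.groupby(group, as_index=False)[trait].mean()
    years = cultivars[["code", "release_year"]].rename(columns={"code": "genotype"})
    return means.merge(years, on="genotype", how="left")


def fit_progress(
    release_years,
    values,
    settings: MCMCSettings = DESK_SETTINGS,
    seed: int = 0,
    trait: str = "trait",
    n_level: str = "all",
    prior_var: float = 1e10,
    nu0: float = 0.002,
    s0_sq: float = 1.0,
) -> ProgressFit:
    """Gibbs sampler for the progress regression on one panel."""
    x_raw = np.asarray(release_years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x_raw.shape != y.shape or x_raw.ndim != 1:
        raise UsageError("release_years and values must be 1-D and equal length")
    keep = np.isfinite(x_raw) & np.isfinite(y)
    x_raw, y = x_raw[keep], y[keep]
    if np.unique(x_raw).size < 3:
        raise DesignError("need >= 3 distinct release years for the regression")
    center = float(x_raw.mean())
    x = x_raw - center
    n = y.size
    sxx = float(x @ x)

    rng = np.random.default_rng(seed)
    b0 = float(y.mean())
    b1 = float(x @ y) / sxx
    s2 = float(np.var(y - b0 - b1 * x)) or 1.0

    n_ret = settings.n_retained
    draws = np.empty((n_ret, 3))
    retained = set(settings.retained_iterations().tolist())
    store = 0
    for it in range(settings.n_total):
        # beta0 | beta1, s2   (x is centred, so sum(x) = 0)
        prec0 = n / s2 + 1.0 / prior_var
        m0 = (float(np.sum(y - b1 * x)) / s2) / prec0
        b0 = m0 + rng.standard_normal() / np.sqrt(prec0)
        # beta1 | beta0, s2
        prec1 = sxx / s2 + 1.0 / prior_var
        m1 = (float(x @ (y - b0)) / s2) / prec1
        b1 = m1 + rng.standard_normal() / np.sqrt(prec1)
        # sigma2
        resid = y - b0 - b1 * x
        s2 = (nu0 * s0_sq + float(resid @ resid)) / rng.chisquare(nu0 + n)
        if it in retained:
            draws[store] = (b0, b1, s2)
            store += 1

    chain = Chain(
        names=["beta0", "beta1", "sigma2"],
        draws=draws,
        n_total=settings.n_total,
        burn_in=settings.burn_in,
        thin=settings.thin,
        seed=seed,
    )
    return ProgressFit(chain=chain, trait=trait, n_level=n_level, center_year=center)


def percent_progress(fit: ProgressFit, level: float = 0.95) -> PosteriorSummary:
    """Posterior of the per-draw percent progress 100 * beta1 / beta0."""
    b0, b1 = fit.beta0, fit.beta1
    if not (np.all(b0 > 0) or np.all(b0 < 0)):
        raise DomainError(
            "beta0 draws cross zero; percent progress is undefined for this panel"
        )
    pct = 100.0 * b1 / b0
    low, high = hpd_interval(pct, level)
    return PosteriorSummary(
        mean=float(pct.mean()),
        median=float(np.median(pct)),
        hpd_low=low,
        hpd_high=high,
        level=level,
    )


def percent_progress_plugin(beta1_mean: float, beta0_mean: float) -> float:
    """Plug-in percent progress from posterior means: 100 * b1 / b0."""
    if beta0_mean == 0:
        raise DomainError("beta0 mean is zero; percent progress undefined")
    return 100.0 * beta1_mean / beta0_mean


def compare_progress(
    fit_a: ProgressFit, fit_b: ProgressFit, level: float = 0.95
) -> ProgressComparison:
    """Delta-beta1 test: significant iff the beta1 HPD intervals do not overlap."""
    if fit_a.trait != fit_b.trait:
        raise UsageError(f"fits are for different traits: {fit_a.trait} vs {fit_b.trait}")
    sa = fit_a.beta1_summary(level)
    sb = fit_b.beta1_summary(level)
    return ProgressComparison(
        trait=fit_a.trait,
        delta_mean=sa.mean - sb.mean,
        hpd_a=(sa.hpd_low, sa.hpd_high),
        hpd_b=(sb.hpd_low, sb.hpd_high),
        significant=not intervals_overlap(sa, sb),
    )
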