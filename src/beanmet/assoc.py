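"""Bayesian correlations and Bayesian PCA with HPD intervals.

Correlation: the pair (x, y) is modelled as bivariate normal with the
Jeffreys-type vague prior, under which the covariance posterior is
inverse-Wishart(n - 1, S) with S the centred cross-product matrix; posterior
draws of the correlation are Sigma_12 / sqrt(Sigma_11 Sigma_22).  A
correlation is significant when its 95% HPD interval excludes zero.  A
heavier-tailed bivariate-t model (df = 4, scale-mixture Gibbs) is available
behind ``robust=True`` for outlier-prone panels; the default stays normal.

PCA: variables are standardized (the traits have incommensurate units, so the
analysis is on the correlation scale), the covariance of the standardized
data is sampled from its inverse-Wishart posterior, and every draw is
eigendecomposed.  Components are ordered by eigenvalue within each draw and
eigenvector signs are aligned to the sample-eigenvector reference by dot
product, so HPD intervals are not inflated by label switching or sign flips.
The observation unit for trait panels is genotype x N-level means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .errors import DegenerateChainError, InsufficientSamplesError, UsageError
from .mcmc_core import PosteriorSummary, hpd_interval, hpd_excludes_zero

__all__ = [
    "CorrEstimate",
    "BPcaResult",
    "bayes_corr",
    "corr_matrix",
    "paired_corr_table",
    "bayes_pca",
]

DEFAULT_DRAWS = 2000


@dataclass(frozen=True)
class CorrEstimate:
    """Posterior summary of one pairwise correlation."""

    r_mean: float
    hpd_low: float
    hpd_high: float
    n: int
    significant: bool
    level: float = 0.95

    def summary(self) -> PosteriorSummary:
        return PosteriorSummary(
            mean=self.r_mean,
            median=self.r_mean,
            hpd_low=self.hpd_low,
            hpd_high=self.hpd_high,
            level=self.level,
        )


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise UsageError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _corr_draws_normal(data: np.ndarray, n_draws: int, rng) -> np.ndarray:
    n = data.shape[0]
    s = (data - data.mean(axis=0)).T @ (data - data.mean(axis=0))
    sig = invwishart.rvs(df=n - 1, scale=s, size=n_draws, random_state=rng)
    return sig[:, 0, 1] / np.sqrt(sig[:, 0, 0] * sig[:, 1, 1])


def _corr_draws_t(data: np.ndarray, n_draws: int, rng, df_t: float = 4.0) -> np.ndarray:
    """Scale-mixture Gibbs for a bivariate t: w_i ~ Gamma, then conjugate
    Gaussian/inverse-Wishart updates on the weighted data."""
    n, d = data.shape
    mu = data.mean(axis=0)
    sigma = np.cov(data.T)
    out = np.empty(n_draws)
    burn = max(200, n_draws // 10)
    for i in range(burn + n_draws):
        dev = data - mu
        mahal = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(sigma), dev)
        w = rng.gamma((df_t + d) / 2.0, 2.0 / (df_t + mahal))
        wsum = w.sum()
        mu_hat = (w[:, None] * data).sum(axis=0) / wsum
        mu = rng.multivariate_normal(mu_hat, sigma / wsum)
        dev = data - mu
        s = (w[:, None] * dev).T @ dev
        sigma = invwishart.rvs(df=n + d, scale=s + 1e-10 * np.eye(d), random_state=rng)
        if i >= burn:
            out[i - burn] = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
    return out


def bayes_corr(
    x,
    y,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    level: float = 0.95,
    robust: bool = False,
) -> CorrEstimate:
    """Posterior of the correlation between two trait vectors."""
    xv, yv = _pairwise_complete(x, y)
    n = xv.size
    if n < 10:
        raise InsufficientSamplesError(f"need >= 10 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateChainError("constant input; correlation undefined")
    rng = np.random.default_rng(seed)
    data = np.column_stack([xv, yv])
    draws = (_corr_draws_t if robust else _corr_draws_normal)(data, n_draws, rng)
    low, high = hpd_interval(draws, level)
    summ = PosteriorSummary(
        mean=float(draws.mean()),
        median=float(np.median(draws)),
        hpd_low=low,
        hpd_high=high,
        level=level,
    )
    return CorrEstimate(
        r_mean=summ.mean,
        hpd_low=low,
        hpd_high=high,
        n=n,
        significant=hpd_excludes_zero(summ),
        level=level,
    )


def corr_matrix(
    traits: pd.DataFrame,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    level: float = 0.95,
    robust: bool = False,
) -> pd.DataFrame:
    """Pairwise :func:`bayes_corr` over the columns of an obs x vars frame.

    Uses pairwise-complete observations; returns a symmetric frame of
    :class:`CorrEstimate` objects with ``None`` on the diagonal.
    """
    cols = list(traits.columns)
    if len(cols) < 2:
        raise UsageError("need >= 2 variables for a correlation matrix")
    seeds = np.random.SeedSequence(seed).spawn(len(cols) * (len(cols) - 1) // 2)
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    k = 0
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            est = bayes_corr(
                traits[a],
                traits[b],
                n_draws=n_draws,
                seed=int(seeds[k].generate_state(1)[0] % (2**31)),
                level=level,
                robust=robust,
            )
            out.loc[a, b] = est
            out.loc[b, a] = est
            k += 1
    return out


def _fmt(est: CorrEstimate) -> str:
    star = "*" if est.significant else ""
    return f"{est.r_mean:.2f} ({est.hpd_low:.2f}; {est.hpd_high:.2f}){star}"


def paired_corr_table(
    high: pd.DataFrame,
    low: pd.DataFrame,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Combined correlation table for two N strata.

    High-N correlations fill the upper triangle and low-N the lower triangle
    of one square table (the conventional two-strata display).
    """
    if list(high.columns) != list(low.columns):
        raise UsageError("high and low frames must share the same trait columns")
    mh = corr_matrix(high, n_draws=n_draws, seed=seed)
    ml = corr_matrix(low, n_draws=n_draws, seed=seed + 1)
    cols = list(high.columns)
    out = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                out.loc[a, b] = _fmt(mh.loc[a, b])
            elif i > j:
                out.loc[a, b] = _fmt(ml.loc[a, b])
    return out


@dataclass
class BPcaResult:
    """Posterior PCA: explained-variance fractions, loadings and scores.

    ``explained`` is a (components,) mean with HPD bounds; ``loadings`` are
    variables x components; ``scores`` observations x components.  The raw
    per-draw explained fractions and loadings are retained for property
    checks and custom summaries.
    """

    variables: list[str]
    explained_mean: np.ndarray
    explained_low: np.ndarray
    explained_high: np.ndarray
    loadings_mean: np.ndarray
    loadings_low: np.ndarray
    loadings_high: np.ndarray
    scores_mean: np.ndarray
    scores_low: np.ndarray
    scores_high: np.ndarray
    explained_draws: np.ndarray
    loadings_draws: np.ndarray

    def explained_frame(self) -> pd.DataFrame:
        comp = [f"Comp.{k + 1}" for k in range(self.explained_mean.size)]
        return pd.DataFrame(
            {
                "component": comp,
                "explained": self.explained_mean,
                "hpd_low": self.explained_low,
                "hpd_high": self.explained_high,
            }
        )


def bayes_pca(
    traits: pd.DataFrame,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    level: float = 0.95,
) -> BPcaResult:
    """Bayesian PCA of an observations x variables frame (standardized)."""
    df = traits.dropna()
    n, p = df.shape
    if n < p + 2:
        raise InsufficientSamplesError(
            f"need >= variables + 2 complete rows, got {n} rows for {p} variables"
        )
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateChainError("constant variable; PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    s = z.T @ z
    if np.linalg.matrix_rank(s) < p:
        raise DegenerateChainError("rank-deficient data; PCA posterior undefined")

    # deterministic reference for sign alignment: sample eigenvectors
    ref_vals, ref_vecs = np.linalg.eigh(s / (n - 1))
    order = np.argsort(ref_vals)[::-1]
    ref_vecs = ref_vecs[:, order]

    rng = np.random.default_rng(seed)
    sig = invwishart.rvs(df=n - 1, scale=s, size=n_draws, random_state=rng)
    expl = np.empty((n_draws, p))
    loads = np.empty((n_draws, p, p))
    scores = np.empty((n_draws, n, p))
    for d in range(n_draws):
        vals, vecs = np.linalg.eigh(sig[d])
        idx = np.argsort(vals)[::-1]
        vals, vecs = vals[idx], vecs[:, idx]
        flip = np.sign(np.einsum("ij,ij->j", vecs, ref_vecs))
        flip[flip == 0] = 1.0
        vecs = vecs * flip
        expl[d] = vals / vals.sum()
        loads[d] = vecs
        scores[d] = z @ vecs

    def hpd_stack(arr):
        flat = arr.reshape(n_draws, -1)
        lows = np.empty(flat.shape[1])
        highs = np.empty(flat.shape[1])
        for j in range(flat.shape[1]):
            lows[j], highs[j] = hpd_interval(flat[:, j], level)
        shape = arr.shape[1:]
        return lows.reshape(shape), highs.reshape(shape)

    e_low, e_high = hpd_stack(expl)
    l_low, l_high = hpd_stack(loads)
    s_low, s_high = hpd_stack(scores)
    return BPcaResult(
        variables=list(df.columns),
        explained_mean=expl.mean(axis=0),
        explained_low=e_low,
        explained_high=e_high,
        loadings_mean=loads.mean(axis=0),
        loadings_low=l_low,
        loadings_high=l_high,
        scores_mean=scores.mean(axis=0),
        scores_low=s_low,
        scores_high=s_high,
        explained_draws=expl,
        loadings_draws=loads,
    )
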