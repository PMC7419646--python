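"""Bayesian AMMI (BAMMI): Gibbs sampler, biplot scores, stability calls.

AMMI models the genotype x environment cell-mean table as additive main
effects plus a truncated singular value decomposition of the interaction:

    y_ij = mu + tau_i + delta_j + sum_k lambda_k alpha_ik gamma_jk + eps_ij,

with eps ~ N(0, sigma2_eps), lambda_1 >= lambda_2 >= ... > 0, and the
singular vectors alpha_k (genotypes) and gamma_k (environments) unit-norm,
mutually orthogonal and orthogonal to the 1-vector (the "corrected
subspace").  Environments here are the composite site-season x nitrogen
cells (e.g. ``LD17-HN``), so the decomposition captures G x (E x N) jointly.

Priors: Gaussian with mean zero and a very large variance (1e15) on mu, tau,
delta; positive-truncated Gaussian on each lambda_k with the descending-order
restriction; spherical uniform on the corrected subspace for the singular
vectors; scaled-inverse-chi-square on sigma2_eps.

Full conditionals are all standard: Gaussian for mu/tau/delta (tau and delta
recentred to sum-to-zero each sweep with the means folded into mu),
zero-truncated Gaussian for each lambda_k, and von Mises-Fisher for alpha_k
and gamma_k restricted to the corrected subspace (sampled in an orthonormal
basis of that subspace, then embedded back, which preserves unit norm and
orthogonality exactly).  Two identifiability devices that the model itself
does not pin down are applied per draw: descending relabeling of the
(lambda, alpha, gamma) triples, and joint sign alignment of each
(alpha_k, gamma_k) pair against a running posterior-mean reference (a joint
flip leaves the model term unchanged).

Inference downstream is HPD-based: an environment is favorable/unfavorable
when its delta HPD is entirely positive/negative; a genotype is stable when
its biplot-score HPDs contain zero on both of the first two axes; specific
adaptation is read off positively-aligned non-stable genotype/environment
score pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import ndtr, ndtri
from scipy.stats import vonmises_fisher

from .errors import (
    DegenerateChainError,
    InsufficientSamplesError,
    MissingCellError,
    UsageError,
)
from .mcmc_core import (
    Chain,
    DESK_SETTINGS,
    MCMCSettings,
    geweke_z,
    hpd_interval,
)

__all__ = [
    "GxEMeans",
    "BammiHyperparams",
    "BammiPosterior",
    "BiplotScores",
    "StabilityReport",
    "compute_cell_means",
    "fit_bammi",
    "explained_interaction",
    "biplot_scores",
    "classify_environments",
    "stability_report",
]

logger = logging.getLogger(__name__)

_N_SUFFIX = {"high": "HN", "low": "LN"}


@dataclass
class GxEMeans:
    """Genotype x composite-environment cell means (no missing cells)."""

    values: np.ndarray
    genotypes: list
    environments: list[str]
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, a = self.values.shape
        if g != len(self.genotypes) or a != len(self.environments):
            raise UsageError("cell-mean matrix shape does not match the labels")
        if not np.all(np.isfinite(self.values)):
            raise MissingCellError("cell-mean matrix contains missing values")


@dataclass(frozen=True)
class BammiHyperparams:
    """Prior hyperparameters (defaults: means 0, variances 1e15, vague
    scaled-inverse-chi-square on the residual variance)."""

    mu_mu: float = 0.0
    var_mu: float = 1e15
    mu_tau: float = 0.0
    var_tau: float = 1e15
    mu_delta: float = 0.0
    var_delta: float = 1e15
    mu_lambda: float = 0.0
    var_lambda: float = 1e15
    nu_eps: float = 0.002
    s2_eps: float = 1.0


@dataclass
class BammiPosterior:
    """Retained draws of every BAMMI parameter, constraints enforced."""

    mu: np.ndarray  # (S,)
    tau: np.ndarray  # (S, g)
    delta: np.ndarray  # (S, a)
    lam: np.ndarray  # (S, t)
    alpha: np.ndarray  # (S, g, t)
    gamma: np.ndarray  # (S, a, t)
    sigma2: np.ndarray  # (S,)
    t: int
    genotypes: list
    environments: list[str]
    hyper: BammiHyperparams
    settings: MCMCSettings
    seed: int

    @property
    def n_retained(self) -> int:
        return self.mu.size

    def to_chain(self) -> Chain:
        """Flatten all parameters into one named :class:`Chain`."""
        g, a, t = len(self.genotypes), len(self.environments), self.t
        names = (
            ["mu"]
            + [f"tau[{x}]" for x in self.genotypes]
            + [f"delta[{x}]" for x in self.environments]
            + [f"lambda[{k + 1}]" for k in range(t)]
            + [f"alpha[{k + 1}][{x}]" for k in range(t) for x in self.genotypes]
            + [f"gamma[{k + 1}][{x}]" for k in range(t) for x in self.environments]
            + ["sigma2_eps"]
        )
        cols = [
            self.mu[:, None],
            self.tau,
            self.delta,
            self.lam,
            self.alpha.transpose(0, 2, 1).reshape(self.n_retained, t * g),
            self.gamma.transpose(0, 2, 1).reshape(self.n_retained, t * a),
            self.sigma2[:, None],
        ]
        return Chain(
            names=names,
            draws=np.concatenate(cols, axis=1),
            n_total=self.settings.n_total,
            burn_in=self.settings.burn_in,
            thin=self.settings.thin,
            seed=self.seed,
        )


def compute_cell_means(traits_df: pd.DataFrame, trait: str) -> GxEMeans:
    """Average a trait over blocks into a genotype x composite-environment
    matrix; environment labels get the nitrogen suffix (``LD17-HN``)."""
    need = ["genotype", "environment", "n_level", trait]
    missing = [c for c in need if c not in traits_df.columns]
    if missing:
        raise UsageError(f"trait table missing column(s): {missing}")
    df = traits_df.dropna(subset=[trait]).copy()
    df["composite"] = [
        f"{e}-{_N_SUFFIX.get(n, n.upper())}"
        for e, n in zip(df["environment"], df["n_level"])
    ]
    piv = df.pivot_table(index="genotype", columns="composite", values=trait, aggfunc="mean")
    cnt = df.pivot_table(index="genotype", columns="composite", values=trait, aggfunc="count")
    empty = piv.isna()
    if empty.any().any():
        cells = [
            (g, e) for g in piv.index for e in piv.columns if empty.loc[g, e]
        ]
        raise MissingCellError(f"empty genotype x environment cells: {cells}")
    return GxEMeans(
        values=piv.to_numpy(dtype=float),
        genotypes=list(piv.index),
        environments=list(piv.columns),
        counts=cnt.to_numpy(),
    )


def _truncnorm_pos(mean: float, sd: float, rng) -> float:
    """One draw from N(mean, sd^2) truncated to (0, inf)."""
    a = -mean / sd
    if a < -8.0:  # truncation numerically inactive
        return mean + sd * rng.standard_normal()
    lo = ndtr(a)
    u = rng.uniform(lo, 1.0)
    z = ndtri(min(u, 1.0 - 1e-16))
    return mean + sd * max(z, a)


def _sample_sphere_subspace(direction: np.ndarray, basis: np.ndarray, rng) -> np.ndarray:
    """von Mises-Fisher draw on the unit sphere of span(basis).

    ``direction`` is the (unnormalized) full-space mean direction times the
    concentration; projecting onto the basis gives both the subspace mean and
    the concentration kappa.  kappa -> 0 falls back to the uniform sphere.
    """
    coords = basis.T @ direction
    kappa = float(np.linalg.norm(coords))
    dim = basis.shape[1]
    if kappa < 1e-10:
        s = rng.standard_normal(dim)
        s /= np.linalg.norm(s)
    elif dim == 1:
        # sphere in 1-D subspace is {-1, +1}; exact Bernoulli from the vMF kernel
        p_plus = 1.0 / (1.0 + np.exp(-2.0 * kappa))
        s = np.array([1.0 if rng.uniform() < p_plus else -1.0])
    else:
        s = np.ravel(vonmises_fisher.rvs(coords / kappa, kappa, random_state=rng))
    v = basis @ s
    return v / np.linalg.norm(v)


def _svd_start(y: np.ndarray, t: int):
    """Classical AMMI solution (SVD of the double-centred matrix) used both
    as the sampler start and as the initial sign-alignment reference."""
    g, a = y.shape
    mu = float(y.mean())
    tau = y.mean(axis=1) - mu
    delta = y.mean(axis=0) - mu
    resid = y - mu - tau[:, None] - delta[None, :]
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    return mu, tau, delta, s[:t].copy(), u[:, :t].copy(), vt[:t].T.copy()


def fit_bammi(
    means: GxEMeans,
    t: int = 2,
    settings: MCMCSettings = DESK_SETTINGS,
    seed: int = 0,
    hyper: BammiHyperparams = BammiHyperparams(),
) -> BammiPosterior:
    """Gibbs sampler for the BAMMI model on a cell-mean table.

    ``t`` is the number of multiplicative interaction terms,
    1 <= t <= min(g, a) - 1 (default 2, the two biplot axes).
    """
    y = means.values
    g, a = y.shape
    if not 1 <= t <= min(g, a) - 1:
        raise UsageError(f"t must be in [1, {min(g, a) - 1}], got {t}")
    n = g * a
    rng = np.random.default_rng(seed)

    mu, tau, delta, lam, alpha, gamma = _svd_start(y, t)
    sigma2 = float(np.var(y - _fitted(mu, tau, delta, lam, alpha, gamma))) or 1.0

    ref_alpha = alpha.copy()  # running posterior-mean sign reference
    ref_n = 1

    ones_g = np.ones((g, 1))
    ones_a = np.ones((a, 1))
    h = hyper

    n_ret = settings.n_retained
    S_mu = np.empty(n_ret)
    S_tau = np.empty((n_ret, g))
    S_delta = np.empty((n_ret, a))
    S_lam = np.empty((n_ret, t))
    S_alpha = np.empty((n_ret, g, t))
    S_gamma = np.empty((n_ret, a, t))
    S_sig = np.empty(n_ret)
    retained = set(settings.retained_iterations().tolist())

    store = 0
    for it in range(settings.n_total):
        inter = (alpha * lam) @ gamma.T

        # mu
        r = y - tau[:, None] - delta[None, :] - inter
        prec = n / sigma2 + 1.0 / h.var_mu
        m = (r.sum() / sigma2 + h.mu_mu / h.var_mu) / prec
        mu = m + rng.standard_normal() / np.sqrt(prec)

        # tau (rows), then recentre into mu
        r = y - mu - delta[None, :] - inter
        prec = a / sigma2 + 1.0 / h.var_tau
        m = (r.sum(axis=1) / sigma2 + h.mu_tau / h.var_tau) / prec
        tau = m + rng.standard_normal(g) / np.sqrt(prec)
        shift = tau.mean()
        tau -= shift
        mu += shift

        # delta (columns), recentred likewise
        r = y - mu - tau[:, None] - inter
        prec = g / sigma2 + 1.0 / h.var_delta
        m = (r.sum(axis=0) / sigma2 + h.mu_delta / h.var_delta) / prec
        delta = m + rng.standard_normal(a) / np.sqrt(prec)
        shift = delta.mean()
        delta -= shift
        mu += shift

        # multiplicative terms
        e = y - mu - tau[:, None] - delta[None, :]
        for k in range(t):
            rk = e - (alpha * lam) @ gamma.T + lam[k] * np.outer(alpha[:, k], gamma[:, k])
            # lambda_k | alpha_k, gamma_k : ||alpha||=||gamma||=1 makes the
            # regressor alpha gamma' unit-norm in the Frobenius sense
            v = 1.0 / (1.0 / sigma2 + 1.0 / h.var_lambda)
            m = v * (float(alpha[:, k] @ rk @ gamma[:, k]) / sigma2 + h.mu_lambda / h.var_lambda)
            lam[k] = _truncnorm_pos(m, np.sqrt(v), rng)

            # alpha_k on the corrected subspace (orthogonal to 1 and alpha_-k)
            constraints = np.hstack([ones_g] + [alpha[:, [l]] for l in range(t) if l != k])
            basis = null_space(constraints.T)
            direction = (lam[k] / sigma2) * (rk @ gamma[:, k])
            alpha[:, k] = _sample_sphere_subspace(direction, basis, rng)

            # gamma_k likewise
            constraints = np.hstack([ones_a] + [gamma[:, [l]] for l in range(t) if l != k])
            basis = null_space(constraints.T)
            direction = (lam[k] / sigma2) * (rk.T @ alpha[:, k])
            gamma[:, k] = _sample_sphere_subspace(direction, basis, rng)

        # descending relabeling restores the order restriction
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        alpha = alpha[:, order]
        gamma = gamma[:, order]

        # sigma2
        resid = y - _fitted(mu, tau, delta, lam, alpha, gamma)
        ss = float(resid.ravel() @ resid.ravel())
        sigma2 = (h.nu_eps * h.s2_eps + ss) / rng.chisquare(h.nu_eps + n)

        if it in retained:
            # joint sign flip of (alpha_k, gamma_k) toward the running mean
            for k in range(t):
                if float(alpha[:, k] @ ref_alpha[:, k]) < 0.0:
                    alpha[:, k] = -alpha[:, k]
                    gamma[:, k] = -gamma[:, k]
            ref_alpha = (ref_alpha * ref_n + alpha) / (ref_n + 1)
            ref_n += 1
            S_mu[store] = mu
            S_tau[store] = tau
            S_delta[store] = delta
            S_lam[store] = lam
            S_alpha[store] = alpha
            S_gamma[store] = gamma
            S_sig[store] = sigma2
            store += 1

    post = BammiPosterior(
        mu=S_mu,
        tau=S_tau,
        delta=S_delta,
        lam=S_lam,
        alpha=S_alpha,
        gamma=S_gamma,
        sigma2=S_sig,
        t=t,
        genotypes=list(means.genotypes),
        environments=list(means.environments),
        hyper=hyper,
        settings=settings,
        seed=seed,
    )
    for name, series in (("mu", S_mu), ("sigma2_eps", S_sig), ("lambda[1]", S_lam[:, 0])):
        try:
            z = geweke_z(series)
        except (InsufficientSamplesError, DegenerateChainError):
            continue
        if abs(z) >= 1.96:
            logger.warning("BAMMI Geweke |z|=%.2f >= 1.96 for %s", abs(z), name)
    return post


def _fitted(mu, tau, delta, lam, alpha, gamma) -> np.ndarray:
    return mu + tau[:, None] + delta[None, :] + (alpha * lam) @ gamma.T


def explained_interaction(post: BammiPosterior, level: float = 0.95) -> pd.DataFrame:
    """Share of the fitted interaction per component: lambda_k^2 / sum lambda^2."""
    lam2 = post.lam**2
    frac = lam2 / lam2.sum(axis=1, keepdims=True)
    rows = []
    for k in range(post.t):
        low, high = hpd_interval(frac[:, k], level)
        rows.append(
            {
                "component": f"Comp.{k + 1}",
                "fraction_mean": float(frac[:, k].mean()),
                "hpd_low": low,
                "hpd_high": high,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BiplotScores:
    """Symmetrically scaled biplot scores (sqrt(lambda) times each vector)."""

    genotypes: list
    environments: list[str]
    genotype_mean: np.ndarray  # (g, t)
    genotype_low: np.ndarray
    genotype_high: np.ndarray
    env_mean: np.ndarray  # (a, t)
    env_low: np.ndarray
    env_high: np.ndarray
    genotype_draws: np.ndarray  # (S, g, t)
    env_draws: np.ndarray  # (S, a, t)
    scaling: str = "symmetric"


def biplot_scores(post: BammiPosterior, level: float = 0.95) -> BiplotScores:
    """Per-draw genotype scores sqrt(lambda_k) alpha_k and environment scores
    sqrt(lambda_k) gamma_k, summarized with elementwise HPD intervals."""
    root = np.sqrt(post.lam)[:, None, :]
    g_draws = post.alpha * root
    e_draws = post.gamma * root

    def summarize(draws):
        mean = draws.mean(axis=0)
        low = np.empty_like(mean)
        high = np.empty_like(mean)
        for i in range(mean.shape[0]):
            for k in range(mean.shape[1]):
                low[i, k], high[i, k] = hpd_interval(draws[:, i, k], level)
        return mean, low, high

    gm, gl, gh = summarize(g_draws)
    em, el, eh = summarize(e_draws)
    return BiplotScores(
        genotypes=post.genotypes,
        environments=post.environments,
        genotype_mean=gm,
        genotype_low=gl,
        genotype_high=gh,
        env_mean=em,
        env_low=el,
        env_high=eh,
        genotype_draws=g_draws,
        env_draws=e_draws,
    )


def classify_environments(post: BammiPosterior, level: float = 0.95) -> pd.DataFrame:
    """Favorable / unfavorable / neutral call per composite environment.

    Favorable means the environment main effect delta is entirely positive at
    the chosen HPD level (above the grand mean); unfavorable entirely
    negative; otherwise neutral.
    """
    rows = []
    for j, env in enumerate(post.environments):
        draws = post.delta[:, j]
        low, high = hpd_interval(draws, level)
        if low > 0:
            cls = "favorable"
        elif high < 0:
            cls = "unfavorable"
        else:
            cls = "neutral"
        rows.append(
            {
                "environment": env,
                "delta_mean": float(draws.mean()),
                "hpd_low": low,
                "hpd_high": high,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StabilityReport:
    """Stability/adaptability calls from the first two biplot axes."""

    genotype_table: pd.DataFrame
    environment_table: pd.DataFrame
    specific_adaptations: list[tuple]


def stability_report(
    post: BammiPosterior, scores: BiplotScores, level: float = 0.95
) -> StabilityReport:
    """HPD-based stability and specific-adaptation calls.

    A genotype is *stable* when its score HPDs contain zero on both Comp.1
    and Comp.2; an environment *contributes to the G x E interaction* when
    either axis HPD excludes zero.  A non-stable genotype is called
    specifically adapted to a contributing environment when their
    posterior-mean score vectors (first two axes) point the same way
    (positive inner product).
    """
    if post.t < 2:
        raise UsageError("two-axis stability semantics require t >= 2")

    def contains_zero(low, high):
        return (low <= 0.0) & (high >= 0.0)

    g_zero = contains_zero(scores.genotype_low[:, :2], scores.genotype_high[:, :2])
    stable = g_zero.all(axis=1)
    tau_rows = []
    for i, geno in enumerate(post.genotypes):
        low, high = hpd_interval(post.tau[:, i], level)
        tau_rows.append(
            {
                "genotype": geno,
                "tau_mean": float(post.tau[:, i].mean()),
                "hpd_low": low,
                "hpd_high": high,
                "stable": bool(stable[i]),
            }
        )
    genotype_table = pd.DataFrame(tau_rows)

    e_zero = contains_zero(scores.env_low[:, :2], scores.env_high[:, :2])
    contributes = ~e_zero.all(axis=1)
    env_table = classify_environments(post, level)
    env_table["contributes_to_gxe"] = contributes

    adaptations = []
    for i, geno in enumerate(post.genotypes):
        if stable[i]:
            continue
        for j, env in enumerate(post.environments):
            if not contributes[j]:
                continue
            if float(scores.genotype_mean[i, :2] @ scores.env_mean[j, :2]) > 0.0:
                adaptations.append((geno, env))
    genotype_table["specific_adaptations"] = [
        [e for g2, e in adaptations if g2 == geno] for geno in post.genotypes
    ]
    return StabilityReport(
        genotype_table=genotype_table,
        environment_table=env_table,
        specific_adaptations=adaptations,
    )
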