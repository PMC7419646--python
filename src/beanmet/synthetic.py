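"""Synthetic multi-environment bean trials with recorded ground truth.

The generator emulates the study design the analysis modules assume: 40
cultivars (release years 1970-2017) x 4 site-seasons x 2 nitrogen levels x 4
blocks in a randomized complete block design, with plot seed yield built
additively as

    y = mu + g_i + e_k + n_m + en_km + ge_ik + gn_im + gen_ikm + b + eps,

where the genotype effects carry a linear release-year trend (the genetic
progress signal), the G x E interaction is a rank-t multiplicative structure
(so a BAMMI fit has an exact low-rank truth to recover), the remaining
interactions and blocks are iid Gaussian, and eps is Gaussian plot noise.

Default magnitudes mirror the published trial: overall seed-yield mean
2,309.65 kg ha^-1 with nitrogen effects +/-185.97 (so the high/low means are
2,495.61 and 2,123.68), residual SD 520 kg ha^-1, and a progress slope of
13.1 kg ha^-1 per year.

Measured columns (field seed mass, biomasses, N percentages) are *back-solved*
from target trait values rather than simulated through crop chemistry, so the
trait-derivation round trip is exact: deriving traits from a generated table
reproduces the intended SY/Prot/HI/NUpE/NUtE values bit-for-bit (up to the
clipping of targets into physically valid boxes, which the defaults almost
never touch).  Every dataset returns a TruthRecord with all realized effects
so downstream recovery tests need no other input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trial_data import TrialTable
from .bammi import GxEMeans

__all__ = [
    "SimConfig",
    "TruthRecord",
    "GxETruth",
    "DEFAULT_TRAIT_CORR",
    "TRAIT_LATENTS",
    "simulate_trial",
    "simulate_gxe_means",
    "simulate_correlated_traits",
]

#: Latent (non-SY) traits whose measured inputs are back-solved.
TRAIT_LATENTS = ["prot", "hi", "nupe", "nute"]

#: Target correlation among (prot, hi, nupe, nute), taken from the published
#: low-N estimates and projected to the nearest positive-definite matrix.
_RAW_TRAIT_CORR = np.array(
    [
        [1.00, -0.40, 0.54, -0.67],
        [-0.40, 1.00, -0.69, 0.70],
        [0.54, -0.69, 1.00, -0.47],
        [-0.67, 0.70, -0.47, 1.00],
    ]
)


def _nearest_pd_corr(c: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    vals = np.clip(vals, floor, None)
    m = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


DEFAULT_TRAIT_CORR = _nearest_pd_corr(_RAW_TRAIT_CORR)

# per-N-level latent trait means (high, low) and common SDs
_TRAIT_MEANS = {
    "prot": (20.21, 18.87),
    "hi": (0.46, 0.45),
    "nupe": (0.12, 0.28),
    "nute": (2.51, 2.68),
}
_TRAIT_SDS = {"prot": 1.5, "hi": 0.05, "nupe": 0.05, "nute": 0.35}
# physically valid boxes guaranteeing back-solved N percentages in [0, 100]
_TRAIT_BOX = {
    "prot": (10.0, 30.0),
    "hi": (0.25, 0.60),
    "nupe": (0.03, 1.50),
    "nute": (1.60, 4.00),
}

_DEFAULT_ENVS = ("LD17", "PG17", "PG18", "STO18")
# fertilization: 12 kg N/ha at sowing for all, +40 kg N/ha top-dressed under
# high N, over an 8 m^2 plot -> grams of N per plot
_N_APPLIED = {"high": 52.0 * 8.0 / 10.0, "low": 12.0 * 8.0 / 10.0}
_HARVEST_AREA = 4.0  # m^2, the two central rows


@dataclass
class SimConfig:
    """Generating parameters of one synthetic trial."""

    g: int = 40
    sites: int = 4
    n_levels: int = 2
    blocks: int = 4
    mu: float = 2309.645
    sd_g: float = 150.0
    sd_b: float = 50.0
    sd_ge: float = 80.0
    sd_gn: float = 40.0
    sd_gen: float = 60.0
    env_effects: tuple = (-36.0, 456.7, 64.3, -485.1)
    n_effects: tuple = (185.965, -185.965)
    en_effects: np.ndarray | None = None
    interaction_rank: int = 2
    lambdas: tuple | None = (300.0, 150.0)
    progress_slope: float = 13.1
    release_years: tuple | None = None
    trait_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    sd_eps: float = 520.0
    nue_envs: tuple | None = None  # restrict non-SY measurements to these envs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 2 or self.sites < 2 or self.n_levels != 2 or self.blocks < 1:
            raise ConfigError("need g >= 2, sites >= 2, n_levels == 2, blocks >= 1")
        for name in ("sd_g", "sd_b", "sd_ge", "sd_gn", "sd_gen", "sd_eps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.env_effects) != self.sites:
            raise ConfigError("env_effects length must equal sites")
        if len(self.n_effects) != self.n_levels:
            raise ConfigError("n_effects length must equal n_levels")
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if lam.size != self.interaction_rank:
                raise ConfigError("lambdas length must equal interaction_rank")
            if np.any(lam <= 0) or np.any(np.diff(lam) > 0):
                raise ConfigError("lambdas must be positive and non-increasing")
            if self.interaction_rank > min(self.g, self.sites) - 1:
                raise ConfigError("interaction_rank exceeds min(g, sites) - 1")
        if self.release_years is not None and len(self.release_years) != self.g:
            raise ConfigError("release_years length must equal g")
        c = np.asarray(self.trait_corr, dtype=float)
        if c.shape != (len(TRAIT_LATENTS),) * 2 or not np.allclose(c, c.T):
            raise ConfigError("trait_corr must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(c), 1.0):
            raise ConfigError("trait_corr must have a unit diagonal")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise ConfigError("trait_corr is not positive definite") from None

    @property
    def years(self) -> np.ndarray:
        if self.release_years is not None:
            return np.asarray(self.release_years, dtype=float)
        return np.round(np.linspace(1970, 2017, self.g))


@dataclass
class TruthRecord:
    """Realized generating parameters of one synthetic trial."""

    config: SimConfig
    mu: float
    g_effects: np.ndarray  # (g,), includes the release-year trend
    env_effects: np.ndarray  # (sites,)
    n_effects: np.ndarray  # (2,)
    en_effects: np.ndarray  # (sites, 2)
    ge: np.ndarray  # (g, sites)
    gn: np.ndarray  # (g, 2)
    gen: np.ndarray  # (g, sites, 2)
    block_effects: np.ndarray  # (sites, 2, blocks)
    alpha: np.ndarray | None  # rank-t genotype singular vectors
    gamma: np.ndarray | None  # rank-t site singular vectors
    lambdas: np.ndarray | None
    release_years: np.ndarray
    mean_year: float
    trait_latents: dict  # (genotype, n_level) level latent trait values


@dataclass
class GxETruth:
    """Ground truth of one simulated genotype x environment mean table."""

    mu: float
    tau: np.ndarray
    delta: np.ndarray
    lambdas: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    sd_eps: float


def _orthonormal_contrasts(dim: int, t: int, rng) -> np.ndarray:
    """t orthonormal columns orthogonal to the 1-vector in R^dim."""
    if t > dim - 1:
        raise ConfigError(f"cannot draw {t} sum-to-zero orthonormal vectors in R^{dim}")
    x = rng.standard_normal((dim, t))
    x -= x.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(x)
    # fix the sign convention so the basis is a deterministic function of x
    q *= np.sign(np.diag(r))
    return q


def simulate_trial(config: SimConfig) -> tuple[TrialTable, TruthRecord]:
    """Generate one complete synthetic trial table plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g, K, M, B = cfg.g, cfg.sites, cfg.n_levels, cfg.blocks
    envs = list(_DEFAULT_ENVS[:K]) + [f"E{k + 1}" for k in range(len(_DEFAULT_ENVS), K)]
    nlevels = ["high", "low"]
    years = cfg.years
    mean_year = float(years.mean())

    trend = cfg.progress_slope * (years - mean_year)
    g_rand = cfg.sd_g * rng.standard_normal(g)
    g_eff = trend + g_rand - (trend + g_rand).mean()

    e_eff = np.asarray(cfg.env_effects, dtype=float)
    e_eff = e_eff - e_eff.mean()
    n_eff = np.asarray(cfg.n_effects, dtype=float)
    n_eff = n_eff - n_eff.mean()
    if cfg.en_effects is None:
        en_eff = np.zeros((K, M))
    else:
        en_eff = np.asarray(cfg.en_effects, dtype=float).reshape(K, M)
        en_eff = en_eff - en_eff.mean(axis=1, keepdims=True)
        en_eff = en_eff - en_eff.mean(axis=0, keepdims=True)

    if cfg.lambdas is not None:
        lam = np.asarray(cfg.lambdas, dtype=float)
        alpha = _orthonormal_contrasts(g, lam.size, rng)
        gamma = _orthonormal_contrasts(K, lam.size, rng)
        ge = (alpha * lam) @ gamma.T
    else:
        lam = alpha = gamma = None
        ge = cfg.sd_ge * rng.standard_normal((g, K))
        ge = ge - ge.mean(axis=0) - ge.mean(axis=1, keepdims=True) + ge.mean()

    gn = cfg.sd_gn * rng.standard_normal((g, M))
    gen = cfg.sd_gen * rng.standard_normal((g, K, M))
    blocks = cfg.sd_b * rng.standard_normal((K, M, B))

    # latent non-SY traits per genotype x N level, correlated across traits
    chol = np.linalg.cholesky(np.asarray(cfg.trait_corr, dtype=float))
    sds = np.array([_TRAIT_SDS[t] for t in TRAIT_LATENTS])
    latents = {}
    for m, nl in enumerate(nlevels):
        means = np.array([_TRAIT_MEANS[t][m] for t in TRAIT_LATENTS])
        z = rng.standard_normal((g, len(TRAIT_LATENTS))) @ chol.T
        vals = means + z * sds
        for t_i, t_name in enumerate(TRAIT_LATENTS):
            lo, hi = _TRAIT_BOX[t_name]
            vals[:, t_i] = np.clip(vals[:, t_i], lo, hi)
        latents[nl] = vals

    rows = []
    for i in range(g):
        for k, env in enumerate(envs):
            for m, nl in enumerate(nlevels):
                measured_nue = cfg.nue_envs is None or env in cfg.nue_envs
                for b in range(B):
                    sy = (
                        cfg.mu
                        + g_eff[i]
                        + e_eff[k]
                        + n_eff[m]
                        + en_eff[k, m]
                        + ge[i, k]
                        + gn[i, m]
                        + gen[i, k, m]
                        + blocks[k, m, b]
                        + cfg.sd_eps * rng.standard_normal()
                    )
                    sy = max(sy, 0.0)
                    n_applied = _N_APPLIED[nl]
                    row = {
                        "genotype": i + 1,
                        "environment": env,
                        "n_level": nl,
                        "block": b + 1,
                        "field_seed_mass": sy * _HARVEST_AREA / 10_000.0,
                        "moisture_pct": 13.0,
                        "harvest_area": _HARVEST_AREA,
                        "n_applied": n_applied,
                    }
                    if measured_nue:
                        prot, hi, nupe, nute = latents[nl][i]
                        # small plot-level jitter, clipped back into the box
                        jitter = rng.standard_normal(4) * 0.3 * sds
                        prot = np.clip(prot + jitter[0], *_TRAIT_BOX["prot"])
                        hi = np.clip(hi + jitter[1], *_TRAIT_BOX["hi"])
                        nupe = np.clip(nupe + jitter[2], *_TRAIT_BOX["nupe"])
                        nute = np.clip(nute + jitter[3], *_TRAIT_BOX["nute"])
                        total_n = nupe * n_applied
                        seed_dry = nute * total_n
                        shoot_dry = seed_dry * (1.0 - hi) / hi
                        seed_n_pct = prot / 6.25
                        shoot_n_pct = (
                            (total_n - seed_dry * seed_n_pct / 100.0) / shoot_dry * 100.0
                        )
                        row.update(
                            seed_dry_biomass=seed_dry,
                            shoot_dry_biomass=shoot_dry,
                            seed_n_pct=seed_n_pct,
                            shoot_n_pct=shoot_n_pct,
                        )
                    else:
                        row.update(
                            seed_dry_biomass=np.nan,
                            shoot_dry_biomass=np.nan,
                            seed_n_pct=np.nan,
                            shoot_n_pct=np.nan,
                        )
                    rows.append(row)

    records = pd.DataFrame(rows)
    cultivars = pd.DataFrame(
        {
            "code": np.arange(1, g + 1),
            "name": [f"CV{i:02d}" for i in range(1, g + 1)],
            "release_year": years.astype(int),
            "origin": "synthetic",
            "growth_habit": ["indeterminate", "determinate"] * (g // 2) + ["indeterminate"] * (g % 2),
            "architecture": "semierect",
        }
    )
    environments = pd.DataFrame({"env_id": envs, "site": envs, "season": ""})
    table = TrialTable(records=records, cultivars=cultivars, environments=environments)
    truth = TruthRecord(
        config=cfg,
        mu=cfg.mu,
        g_effects=g_eff,
        env_effects=e_eff,
        n_effects=n_eff,
        en_effects=en_eff,
        ge=ge,
        gn=gn,
        gen=gen,
        block_effects=blocks,
        alpha=alpha,
        gamma=gamma,
        lambdas=lam,
        release_years=years,
        mean_year=mean_year,
        trait_latents=latents,
    )
    return table, truth


def simulate_gxe_means(
    g: int,
    a: int,
    t: int,
    lambdas,
    sd_eps: float,
    seed: int = 0,
    mu: float = 0.0,
    sd_tau: float = 1.0,
    sd_delta: float = 1.0,
) -> tuple[GxEMeans, GxETruth]:
    """Genotype x environment mean table with exact rank-t interaction truth.

    The singular vectors are orthonormal and sum-to-zero by construction —
    the same identification the BAMMI sampler assumes — so recovery
    comparisons need no post-alignment beyond sign.
    """
    lam = np.asarray(lambdas, dtype=float)
    if not 1 <= t <= min(g, a) - 1 or lam.size != t:
        raise ConfigError(f"need 1 <= t <= min(g, a) - 1 and len(lambdas) == t")
    if np.any(lam <= 0) or np.any(np.diff(lam) > 0):
        raise ConfigError("lambdas must be positive and non-increasing")
    rng = np.random.default_rng(seed)
    alpha = _orthonormal_contrasts(g, t, rng)
    gamma = _orthonormal_contrasts(a, t, rng)
    tau = sd_tau * rng.standard_normal(g)
    tau -= tau.mean()
    delta = sd_delta * rng.standard_normal(a)
    delta -= delta.mean()
    y = (
        mu
        + tau[:, None]
        + delta[None, :]
        + (alpha * lam) @ gamma.T
        + sd_eps * rng.standard_normal((g, a))
    )
    means = GxEMeans(
        values=y,
        genotypes=[i + 1 for i in range(g)],
        environments=[f"E{j + 1}" for j in range(a)],
        counts=np.ones((g, a), dtype=int),
    )
    return means, GxETruth(
        mu=mu, tau=tau, delta=delta, lambdas=lam, alpha=alpha, gamma=gamma, sd_eps=sd_eps
    )


def simulate_correlated_traits(
    n: int,
    trait_corr: np.ndarray,
    seed: int = 0,
    means=None,
    sds=None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Multivariate-normal observations with a requested correlation matrix."""
    c = np.asarray(trait_corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
        raise ConfigError("trait_corr must be square and symmetric")
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ConfigError("trait_corr is not positive definite") from None
    p = c.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p)) @ chol.T
    if sds is not None:
        z = z * np.asarray(sds, dtype=float)
    if means is not None:
        z = z + np.asarray(means, dtype=float)
    cols = columns if columns is not None else [f"t{j + 1}" for j in range(p)]
    return pd.DataFrame(z, columns=cols)
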