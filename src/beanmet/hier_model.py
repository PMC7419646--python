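"""Gibbs sampler for the hierarchical G x N x E models and DIC comparison.

The response for one plot is modelled as

    y_ijkm = mu + g_i + b_{j/k/m} + e_k + n_m + ge_ik + gn_im + en_km
             + gen_ikm + eps_ijkm,    eps ~ N(0, sigma2_eps)

with genotype (g), block-within-experiment (b) and all genotype interactions
random, and environment (e), nitrogen (n) and their interaction (en) fixed.
Four nested presets are compared:

* ``full``     — all interaction terms (ge, gn, en, gen);
* ``reduced1`` — only the genotype x nitrogen interaction (gn);
* ``reduced2`` — only the genotype x environment interaction (ge);
* ``null``     — additive main effects only.

Sampling is plain Gibbs with conjugate full conditionals: Gaussian updates
for mu and every effect block (each observation belongs to exactly one level
of a factor, so the levels of one factor are conditionally independent and
updated jointly), and scaled-inverse-chi-square updates for every variance
component.  Fixed-effect blocks are recentred to sum-to-zero each sweep with
the removed means folded into mu, so mu is the overall mean.

Model comparison uses the deviance information criterion

    DIC = D(theta_bar) + 2 p_D,      p_D = mean_dev - D(theta_bar),

where the deviance is conditional on all sampled effects (the lowest-level
focus, matching the MCMC software family commonly used for these models) and
``D(theta_bar)`` plugs in the posterior means of every parameter.  DIC
differences D = |DIC_a - DIC_b| are read as: D < 5 not significant,
5 <= D <= 10 significant, D > 10 highly significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateChainError,
    DesignError,
    InsufficientSamplesError,
    UsageError,
)
from .mcmc_core import Chain, DESK_SETTINGS, MCMCSettings, geweke_z

__all__ = [
    "ModelSpec",
    "Priors",
    "LMMPosterior",
    "DICResult",
    "fit_lmm",
    "compute_dic",
    "classify_dic_difference",
    "compare_model_set",
    "PRESETS",
]

logger = logging.getLogger(__name__)

PRESETS = ("full", "reduced1", "reduced2", "null")


@dataclass(frozen=True)
class ModelSpec:
    """Which interaction terms the model carries."""

    include_ge: bool
    include_gn: bool
    include_en: bool
    include_gen: bool
    preset: str = "custom"

    @classmethod
    def from_preset(cls, name: str) -> "ModelSpec":
        flags = {
            "full": (True, True, True, True),
            "reduced1": (False, True, False, False),
            "reduced2": (True, False, False, False),
            "null": (False, False, False, False),
        }
        if name not in flags:
            raise UsageError(f"unknown preset {name!r}; choose from {PRESETS}")
        ge, gn, en, gen = flags[name]
        return cls(ge, gn, en, gen, preset=name)


@dataclass(frozen=True)
class Priors:
    """Vague proper priors: N(0, fixed_var) for mu and fixed effects;
    scaled-inverse-chi-square(nu0, s0_sq) for every variance component."""

    fixed_var: float = 1e10
    nu0: float = 0.002
    s0_sq: float = 1.0


@dataclass
class DICResult:
    """DIC decomposition for one fitted model."""

    dic: float
    dev_at_mean: float
    p_d: float
    mean_dev: float

    def __post_init__(self) -> None:
        if abs(self.dic - (self.dev_at_mean + 2.0 * self.p_d)) > 1e-9 * max(
            1.0, abs(self.dic)
        ):
            raise UsageError("DIC identity dic = dev_at_mean + 2 p_d violated")
        if abs(self.p_d - (self.mean_dev - self.dev_at_mean)) > 1e-9 * max(
            1.0, abs(self.mean_dev)
        ):
            raise UsageError("DIC identity p_d = mean_dev - dev_at_mean violated")


@dataclass
class LMMPosterior:
    """Posterior chain of one hierarchical fit plus design bookkeeping."""

    chain: Chain
    spec: ModelSpec
    trait: str
    levels: dict[str, list]
    keys: pd.DataFrame  # plot keys in the fitted row order
    deviance: np.ndarray  # conditional deviance per retained draw
    settings: MCMCSettings
    priors: Priors


# --- internal design helpers ----------------------------------------------


def _codes(values) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(values)
    return cat.codes.astype(np.int64), list(cat.categories)


def _build_terms(df: pd.DataFrame, spec: ModelSpec):
    """Return term -> (index array, labels, kind) for the included effects."""
    g_idx, g_lab = _codes(df["genotype"])
    e_idx, e_lab = _codes(df["environment"])
    n_idx, n_lab = _codes(df["n_level"])
    K, M, G = len(e_lab), len(n_lab), len(g_lab)
    exp_idx = e_idx * M + n_idx  # experiment = environment x N combination
    b_codes, b_lab_raw = _codes(df["block"])
    B = len(b_lab_raw)
    blk_idx = exp_idx * B + b_codes
    blk_lab = [
        f"{e}:{n}:{b}" for e in e_lab for n in n_lab for b in b_lab_raw
    ]

    terms: dict[str, dict] = {}

    def add(name, idx, labels, kind):
        terms[name] = {"idx": idx, "labels": labels, "kind": kind}

    add("e", e_idx, [str(x) for x in e_lab], "fixed")
    add("n", n_idx, [str(x) for x in n_lab], "fixed")
    if spec.include_en:
        add(
            "en",
            e_idx * M + n_idx,
            [f"{e}:{n}" for e in e_lab for n in n_lab],
            "fixed",
        )
    add("g", g_idx, [str(x) for x in g_lab], "random")
    add("b", blk_idx, blk_lab, "random")
    if spec.include_ge:
        add(
            "ge",
            g_idx * K + e_idx,
            [f"{g}:{e}" for g in g_lab for e in e_lab],
            "random",
        )
    if spec.include_gn:
        add(
            "gn",
            g_idx * M + n_idx,
            [f"{g}:{n}" for g in g_lab for n in n_lab],
            "random",
        )
    if spec.include_gen:
        add(
            "gen",
            (g_idx * K + e_idx) * M + n_idx,
            [f"{g}:{e}:{n}" for g in g_lab for e in e_lab for n in n_lab],
            "random",
        )
    shape = {"K": K, "M": M, "G": G, "B": B}
    return terms, shape


def fit_lmm(
    table: pd.DataFrame,
    trait: str,
    spec: ModelSpec,
    settings: MCMCSettings = DESK_SETTINGS,
    seed: int = 0,
    priors: Priors = Priors(),
) -> LMMPosterior:
    """Fit one hierarchical model by Gibbs sampling.

    ``table`` is a long trait table with key columns (genotype, environment,
    n_level, block) and the trait column; rows with a missing trait value are
    dropped.  Draw-for-draw reproducible for a given seed, independent of the
    row order of ``table`` (rows are sorted by key before sampling).
    """
    need = ["genotype", "environment", "n_level", "block", trait]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise UsageError(f"trait table missing column(s): {missing}")
    df = (
        table[need]
        .dropna(subset=[trait])
        .sort_values(["genotype", "environment", "n_level", "block"], kind="mergesort")
        .reset_index(drop=True)
    )
    if len(df) == 0:
        raise UsageError(f"trait column {trait!r} is empty")
    for col in ("genotype", "environment", "n_level", "block"):
        if df[col].nunique() < 2:
            raise DesignError(
                f"factor {col!r} has {df[col].nunique()} level(s); need >= 2"
            )

    y = df[trait].to_numpy(dtype=float)
    n_obs = y.size
    terms, _ = _build_terms(df, spec)

    rng = np.random.default_rng(seed)
    sigma2_map = {name: 1.0 for name, t in terms.items() if t["kind"] == "random"}
    # state
    mu = float(y.mean())
    eff = {}
    counts = {}
    for name, t in terms.items():
        q = len(t["labels"])
        eff[name] = np.zeros(q)
        counts[name] = np.bincount(t["idx"], minlength=q).astype(float)
    sigma2_eps = float(y.var()) or 1.0

    fitted = np.full(n_obs, mu)

    n_ret = settings.n_retained
    var_names = [f"var_{k}" for k in sigma2_map] + ["var_eps"]
    names = (
        ["mu"]
        + [f"{name}[{lab}]" for name in terms for lab in terms[name]["labels"]]
        + var_names
    )
    draws = np.empty((n_ret, len(names)))
    deviance = np.empty(n_ret)
    retained = set(settings.retained_iterations().tolist())

    fv = priors.fixed_var
    nu0, s0 = priors.nu0, priors.s0_sq
    two_pi = 2.0 * math.pi

    store_row = 0
    for it in range(settings.n_total):
        # mu
        r_sum = float(np.sum(y - fitted + mu))
        prec = n_obs / sigma2_eps + 1.0 / fv
        mu_new = (r_sum / sigma2_eps) / prec + rng.standard_normal() / math.sqrt(prec)
        fitted += mu_new - mu
        mu = mu_new

        for name, t in terms.items():
            idx = t["idx"]
            u = eff[name]
            prior_var = fv if t["kind"] == "fixed" else sigma2_map[name]
            r = y - fitted + u[idx]
            s = np.bincount(idx, weights=r, minlength=u.size)
            prec_l = counts[name] / sigma2_eps + 1.0 / prior_var
            mean_l = (s / sigma2_eps) / prec_l
            u_new = mean_l + rng.standard_normal(u.size) / np.sqrt(prec_l)
            # empty levels (possible in subset designs) keep a pure prior draw
            fitted += u_new[idx] - u[idx]
            eff[name] = u_new

        # sum-to-zero recentring of fixed blocks; means migrate into mu / main
        # effects so the fitted values (hence the likelihood) are untouched
        for name in ("e", "n"):
            m = float(eff[name].mean())
            eff[name] -= m
            mu += m
        if "en" in terms:
            K = len(terms["e"]["labels"])
            M = len(terms["n"]["labels"])
            en = eff["en"].reshape(K, M)
            grand = float(en.mean())
            row = en.mean(axis=1) - grand
            col = en.mean(axis=0) - grand
            en -= grand + row[:, None] + col[None, :]
            eff["en"] = en.ravel()
            eff["e"] += row
            eff["n"] += col
            mu += grand

        # variance components
        for name in sigma2_map:
            u = eff[name]
            q = u.size
            scale = nu0 * s0 + float(u @ u)
            sigma2_map[name] = scale / rng.chisquare(nu0 + q)
        resid = y - fitted
        ss = float(resid @ resid)
        sigma2_eps = (nu0 * s0 + ss) / rng.chisquare(nu0 + n_obs)

        if it in retained:
            row = [mu]
            for name in terms:
                row.extend(eff[name])
            row.extend(sigma2_map.values())
            row.append(sigma2_eps)
            draws[store_row] = row
            deviance[store_row] = n_obs * math.log(two_pi * sigma2_eps) + ss / sigma2_eps
            store_row += 1

    chain = Chain(
        names=names,
        draws=draws,
        n_total=settings.n_total,
        burn_in=settings.burn_in,
        thin=settings.thin,
        seed=seed,
    )
    _convergence_check(chain, ("mu", "var_eps"), f"{spec.preset}/{trait}")
    return LMMPosterior(
        chain=chain,
        spec=spec,
        trait=trait,
        levels={name: terms[name]["labels"] for name in terms},
        keys=df[["genotype", "environment", "n_level", "block"]].copy(),
        deviance=deviance,
        settings=settings,
        priors=priors,
    )


def _convergence_check(chain: Chain, params, label: str) -> None:
    for p in params:
        try:
            z = geweke_z(chain.column(p))
        except (InsufficientSamplesError, DegenerateChainError):
            continue
        if abs(z) >= 1.96:
            logger.warning("Geweke |z|=%.2f >= 1.96 for %s in fit %s", abs(z), p, label)


def compute_dic(post: LMMPosterior, table: pd.DataFrame) -> DICResult:
    """DIC with deviance conditional on all sampled effects.

    ``mean_dev`` averages the per-draw conditional deviance recorded during
    sampling; ``dev_at_mean`` plugs the posterior means of mu, every effect
    level and sigma2_eps into the same Gaussian likelihood on ``table``.
    """
    need = ["genotype", "environment", "n_level", "block", post.trait]
    df = (
        table[need]
        .dropna(subset=[post.trait])
        .sort_values(["genotype", "environment", "n_level", "block"], kind="mergesort")
        .reset_index(drop=True)
    )
    if len(df) != len(post.keys) or not df[post.keys.columns.tolist()].equals(post.keys):
        raise UsageError("table plots do not match the plots the posterior was fit on")
    y = df[post.trait].to_numpy(dtype=float)
    terms, _ = _build_terms(df, post.spec)

    means = post.chain.draws.mean(axis=0)
    name_to_mean = dict(zip(post.chain.names, means))
    fitted = np.full(y.size, name_to_mean["mu"])
    for name, t in terms.items():
        u = np.array([name_to_mean[f"{name}[{lab}]"] for lab in t["labels"]])
        fitted += u[t["idx"]]
    s2 = name_to_mean["var_eps"]
    resid = y - fitted
    dev_at_mean = y.size * math.log(2.0 * math.pi * s2) + float(resid @ resid) / s2
    mean_dev = float(post.deviance.mean())
    p_d = mean_dev - dev_at_mean
    return DICResult(dic=dev_at_mean + 2.0 * p_d, dev_at_mean=dev_at_mean, p_d=p_d, mean_dev=mean_dev)


def classify_dic_difference(dic_a: float, dic_b: float) -> str:
    """Read a DIC difference on the 5/10 scale (inclusive bounds)."""
    if not (math.isfinite(dic_a) and math.isfinite(dic_b)):
        raise UsageError("DIC values must be finite")
    d = abs(dic_a - dic_b)
    if d < 5.0:
        return "not_significant"
    if d <= 10.0:
        return "significant"
    return "highly_significant"


def compare_model_set(
    table: pd.DataFrame,
    trait: str,
    settings: MCMCSettings = DESK_SETTINGS,
    seed: int = 0,
    priors: Priors = Priors(),
) -> pd.DataFrame:
    """Fit all four presets and rank them by DIC.

    Returns one row per preset (dic, dev_at_mean, p_d, mean_dev) sorted by
    DIC ascending, plus a ``vs_<preset>`` classification column per pairwise
    comparison.  Child seeds for the four fits are spawned from ``seed`` so
    the set is jointly reproducible.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(PRESETS))
    ]
    rows = {}
    for preset, s in zip(PRESETS, child_seeds):
        post = fit_lmm(table, trait, ModelSpec.from_preset(preset), settings, s, priors)
        rows[preset] = compute_dic(post, table)
    out = pd.DataFrame(
        {
            "preset": list(rows),
            "dic": [r.dic for r in rows.values()],
            "dev_at_mean": [r.dev_at_mean for r in rows.values()],
            "p_d": [r.p_d for r in rows.values()],
            "mean_dev": [r.mean_dev for r in rows.values()],
        }
    )
    for other in PRESETS:
        out[f"vs_{other}"] = [
            classify_dic_difference(rows[p].dic, rows[other].dic) for p in out["preset"]
        ]
    return out.sort_values("dic", kind="mergesort").reset_index(drop=True)
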