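import logging

import numpy as np
import pytest

from beanmet.errors import DesignError, UsageError
from beanmet.hier_model import (
    LMMPosterior,
    ModelSpec,
    Priors,
    classify_dic_difference,
    compute_dic,
    fit_lmm,
)
from beanmet.mcmc_core import Chain, MCMCSettings
from beanmet.synthetic import SimConfig, simulate_trial
from beanmet.traits import derive_all

QUICK = MCMCSettings(n_total=3000, burn_in=800, thin=2)


def _null_data(seed=7, sd_eps=1e-6, g=8):
    cfg = SimConfig(
        g=g,
        sites=3,
        blocks=2,
        sd_g=50.0,
        sd_b=0.0,
        sd_ge=0.0,
        sd_gn=0.0,
        sd_gen=0.0,
        sd_eps=sd_eps,
        env_effects=(-100.0, 50.0, 50.0),
        lambdas=None,
        progress_slope=0.0,
        seed=seed,
    )
    return derive_all(simulate_trial(cfg)[0])


def test_model_spec_presets():
    full = ModelSpec.from_preset("full")
    assert (full.include_ge, full.include_gn, full.include_en, full.include_gen) == (
        True,
        True,
        True,
        True,
    )
    r1 = ModelSpec.from_preset("reduced1")
    assert (r1.include_ge, r1.include_gn, r1.include_en, r1.include_gen) == (
        False,
        True,
        False,
        False,
    )
    r2 = ModelSpec.from_preset("reduced2")
    assert (r2.include_ge, r2.include_gn, r2.include_en, r2.include_gen) == (
        True,
        False,
        False,
        False,
    )
    null = ModelSpec.from_preset("null")
    assert not any(
        [null.include_ge, null.include_gn, null.include_en, null.include_gen]
    )
    with pytest.raises(UsageError):
        ModelSpec.from_preset("bogus")


def test_noiseless_fixed_effects_match_least_squares():
    """On balanced near-noiseless null data the posterior means of the
    environment effects match the least-squares decomposition."""
    d = _null_data()
    post = fit_lmm(d, "sy", ModelSpec.from_preset("null"), QUICK, seed=5)
    y = d["sy"].to_numpy()
    tol = 0.01 * y.std()
    for env in d["environment"].unique():
        ls = d.loc[d["environment"] == env, "sy"].mean() - y.mean()
        pm = post.chain.column(f"e[{env}]").mean()
        assert abs(pm - ls) < tol


def test_record_order_determinism():
    d = _null_data(sd_eps=150.0)
    shuffled = d.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = fit_lmm(d, "sy", ModelSpec.from_preset("reduced1"), QUICK, seed=9)
    b = fit_lmm(shuffled, "sy", ModelSpec.from_preset("reduced1"), QUICK, seed=9)
    np.testing.assert_array_equal(a.chain.draws, b.chain.draws)


def test_variance_component_recovery_full_model():
    """sigma2_gen posterior mean recovers truth (median over seeds) at the
    40 x 4 x 2 x 4 design."""
    logging.disable(logging.WARNING)
    try:
        errs = []
        for seed in range(3):
            cfg = SimConfig(
                g=40,
                sites=4,
                blocks=4,
                sd_gen=120.0,
                sd_eps=200.0,
                lambdas=None,
                sd_ge=80.0,
                seed=seed,
            )
            d = derive_all(simulate_trial(cfg)[0])
            post = fit_lmm(
                d,
                "sy",
                ModelSpec.from_preset("full"),
                MCMCSettings(20_000, 10_000, 5),
                seed=seed,
            )
            v = post.chain.column("var_gen").mean()
            errs.append(abs(v - 120.0**2) / 120.0**2)
        assert np.median(errs) < 0.5
    finally:
        logging.disable(logging.NOTSET)


def test_degenerate_design_rejected():
    d = _null_data()
    single_env = d[d["environment"] == d["environment"].iloc[0]]
    with pytest.raises(DesignError):
        fit_lmm(single_env, "sy", ModelSpec.from_preset("null"), QUICK, seed=0)


def test_dic_identities_on_fit():
    d = _null_data(sd_eps=150.0)
    post = fit_lmm(d, "sy", ModelSpec.from_preset("reduced2"), QUICK, seed=2)
    r = compute_dic(post, d)
    assert r.dic == pytest.approx(r.dev_at_mean + 2 * r.p_d, rel=1e-12)
    assert r.p_d == pytest.approx(r.mean_dev - r.dev_at_mean, rel=1e-12)
    assert r.dic == pytest.approx(r.mean_dev + r.p_d, rel=1e-12)


def test_dic_table_mismatch_rejected():
    d = _null_data(sd_eps=150.0)
    post = fit_lmm(d, "sy", ModelSpec.from_preset("null"), QUICK, seed=2)
    with pytest.raises(UsageError):
        compute_dic(post, d.iloc[:-4])


def _toy_posterior(mu_draws, var_eps, df):
    """Hand-built null-model posterior: all effects zero, mu as given."""
    from beanmet.hier_model import _build_terms

    spec = ModelSpec.from_preset("null")
    terms, _ = _build_terms(df, spec)
    names = (
        ["mu"]
        + [f"{name}[{lab}]" for name in terms for lab in terms[name]["labels"]]
        + ["var_g", "var_b", "var_eps"]
    )
    n_draws = len(mu_draws)
    draws = np.zeros((n_draws, len(names)))
    draws[:, 0] = mu_draws
    draws[:, -3:-1] = 1.0
    draws[:, -1] = var_eps
    y = df["sy"].to_numpy()
    dev = np.array(
        [
            y.size * np.log(2 * np.pi * var_eps) + np.sum((y - m) ** 2) / var_eps
            for m in mu_draws
        ]
    )
    chain = Chain(
        names=names, draws=draws, n_total=n_draws, burn_in=0, thin=1, seed=0
    )
    keys = (
        df[["genotype", "environment", "n_level", "block"]]
        .sort_values(["genotype", "environment", "n_level", "block"], kind="mergesort")
        .reset_index(drop=True)
    )
    return LMMPosterior(
        chain=chain,
        spec=spec,
        trait="sy",
        levels={k: terms[k]["labels"] for k in terms},
        keys=keys,
        deviance=dev,
        settings=MCMCSettings(n_draws, 0, 1),
        priors=Priors(),
    )


def test_dic_degenerate_chain_has_zero_pd():
    """mu fixed at the MLE with known variance: p_d = 0, dic = dev_at_mean."""
    d = _null_data(sd_eps=150.0)
    mle = d["sy"].mean()
    post = _toy_posterior(np.full(100, mle), 150.0**2, d)
    r = compute_dic(post, d)
    assert r.p_d == pytest.approx(0.0, abs=1e-6)
    assert r.dic == pytest.approx(r.dev_at_mean, rel=1e-12)


def test_dic_conjugate_mean_effective_parameters():
    """Known-variance normal mean: the analytic effective parameter count is
    exactly 1, and p_d matches it within Monte Carlo error."""
    d = _null_data(sd_eps=150.0)
    y = d["sy"].to_numpy()
    s2 = 150.0**2
    rng = np.random.default_rng(8)
    mu_draws = y.mean() + np.sqrt(s2 / y.size) * rng.standard_normal(20_000)
    post = _toy_posterior(mu_draws, s2, d)
    r = compute_dic(post, d)
    assert r.p_d == pytest.approx(1.0, rel=0.1)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (9_646.7, 9_635.3, "highly_significant"),  # D = 11.4
        (1_375.0, 1_374.6, "not_significant"),  # D = 0.4
        (0.0, 7.5, "significant"),
        (0.0, 5.0, "significant"),  # inclusive bounds
        (0.0, 10.0, "significant"),
        (0.0, 4.999, "not_significant"),
        (0.0, 10.001, "highly_significant"),
    ],
)
def test_classify_dic_difference(a, b, expected):
    assert classify_dic_difference(a, b) == expected


def test_classify_dic_difference_rejects_nonfinite():
    with pytest.raises(UsageError):
        classify_dic_difference(np.nan, 1.0)
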