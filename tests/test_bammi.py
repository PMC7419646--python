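import numpy as np
import pytest

from beanmet.bammi import (
    GxEMeans,
    biplot_scores,
    classify_environments,
    compute_cell_means,
    explained_interaction,
    fit_bammi,
    stability_report,
)
from beanmet.errors import MissingCellError, UsageError
from beanmet.mcmc_core import MCMCSettings
from beanmet.synthetic import simulate_gxe_means


def test_compute_cell_means_blocks_average(small_trial, small_traits):
    table, truth = small_trial
    cfg = truth.config
    means = compute_cell_means(small_traits, "sy")
    assert means.values.shape == (cfg.g, cfg.sites * 2)
    assert all(e.endswith(("-HN", "-LN")) for e in means.environments)
    assert np.all(means.counts == cfg.blocks)
    # one cell is the plain mean of its blocks
    sub = small_traits[
        (small_traits["genotype"] == 1)
        & (small_traits["environment"] == "LD17")
        & (small_traits["n_level"] == "high")
    ]
    j = means.environments.index("LD17-HN")
    assert means.values[0, j] == pytest.approx(sub["sy"].mean(), rel=1e-12)


def test_compute_cell_means_single_block_passthrough(small_traits):
    one = small_traits[small_traits["block"] == 1]
    means = compute_cell_means(one, "sy")
    row = one[
        (one["genotype"] == 2)
        & (one["environment"] == "PG17")
        & (one["n_level"] == "low")
    ]["sy"].iloc[0]
    j = means.environments.index("PG17-LN")
    assert means.values[1, j] == row


def test_compute_cell_means_locality(small_traits):
    full = compute_cell_means(small_traits, "sy")
    drop = small_traits.drop(index=0)  # genotype 1, first plot
    part = compute_cell_means(drop, "sy")
    changed = full.values != part.values
    assert changed.sum() == 1


def test_compute_cell_means_empty_cell(small_traits):
    gone = small_traits[
        ~(
            (small_traits["genotype"] == 1)
            & (small_traits["environment"] == "LD17")
            & (small_traits["n_level"] == "high")
        )
    ]
    with pytest.raises(MissingCellError, match="LD17-HN"):
        compute_cell_means(gone, "sy")


def test_fit_bammi_t_out_of_range(bammi_additive):
    means, _, _ = bammi_additive
    with pytest.raises(UsageError):
        fit_bammi(means, t=0)
    with pytest.raises(UsageError):
        fit_bammi(means, t=min(means.values.shape))


def test_posterior_draw_constraints(bammi_noiseless):
    """Every retained draw satisfies the ordering, orthonormality and
    sum-to-zero restrictions of the model."""
    _, _, post = bammi_noiseless
    g = len(post.genotypes)
    assert np.all(post.lam > 0)
    assert np.all(post.lam[:, :-1] >= post.lam[:, 1:])
    assert np.allclose(post.tau.sum(axis=1), 0.0, atol=1e-8)
    assert np.allclose(post.delta.sum(axis=1), 0.0, atol=1e-8)
    norms_a = np.linalg.norm(post.alpha, axis=1)
    norms_g = np.linalg.norm(post.gamma, axis=1)
    assert np.allclose(norms_a, 1.0, atol=1e-8)
    assert np.allclose(norms_g, 1.0, atol=1e-8)
    assert np.max(np.abs(post.alpha.sum(axis=1))) < 1e-6
    assert np.max(np.abs(post.gamma.sum(axis=1))) < 1e-6
    cross_a = np.einsum("sik,sil->skl", post.alpha, post.alpha)
    off = cross_a - np.eye(post.t)
    assert np.max(np.abs(off)) < 1e-6


def test_noiseless_recovery_vs_svd_oracle(bammi_noiseless):
    means, truth, post = bammi_noiseless
    lam_mean = post.lam.mean(axis=0)
    np.testing.assert_allclose(lam_mean, truth.lambdas, rtol=0.05)
    for k in range(2):
        assert abs(post.alpha.mean(axis=0)[:, k] @ truth.alpha[:, k]) > 0.99
        assert abs(post.gamma.mean(axis=0)[:, k] @ truth.gamma[:, k]) > 0.99
    # posterior-mean reconstruction approaches the cell means as noise -> 0
    recon = (
        post.mu.mean()
        + post.tau.mean(axis=0)[:, None]
        + post.delta.mean(axis=0)[None, :]
        + (post.alpha.mean(axis=0) * lam_mean) @ post.gamma.mean(axis=0).T
    )
    assert np.max(np.abs(recon - means.values)) < 1e-2


def test_explained_interaction(bammi_noiseless):
    _, truth, post = bammi_noiseless
    expl = explained_interaction(post)
    lam2 = truth.lambdas**2
    np.testing.assert_allclose(
        expl["fraction_mean"], lam2 / lam2.sum(), atol=0.01
    )
    # per-draw fractions sum to one exactly
    frac = post.lam**2 / (post.lam**2).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(frac.sum(axis=1), 1.0, rtol=1e-12)


def test_explained_interaction_single_term():
    means, _ = simulate_gxe_means(8, 5, 1, (30.0,), sd_eps=0.5, seed=2, sd_tau=4, sd_delta=3)
    post = fit_bammi(means, t=1, settings=MCMCSettings(1500, 500, 2), seed=1)
    expl = explained_interaction(post)
    assert expl["fraction_mean"].iloc[0] == 1.0


def test_biplot_scores_reconstruct_interaction(bammi_noiseless):
    _, _, post = bammi_noiseless
    scores = biplot_scores(post)
    # per draw, G E^T = sum_k lambda_k alpha_k gamma_k^T
    for d in (0, 1000, -1):
        lhs = scores.genotype_draws[d] @ scores.env_draws[d].T
        rhs = (post.alpha[d] * post.lam[d]) @ post.gamma[d].T
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)
    assert scores.scaling == "symmetric"


def test_additive_data_all_stable(bammi_additive):
    """With no real interaction all genotype score HPDs cover zero."""
    _, _, post = bammi_additive
    scores = biplot_scores(post)
    assert np.all(scores.genotype_low[:, :2] <= 0.0)
    assert np.all(scores.genotype_high[:, :2] >= 0.0)
    report = stability_report(post, scores)
    assert report.genotype_table["stable"].all()
    assert report.specific_adaptations == []
    # lambdas stay small relative to the additive signal
    assert post.lam.mean(axis=0).max() < 10.0


def test_environment_classification_and_delta_recovery(bammi_additive):
    means, truth, post = bammi_additive
    table = classify_environments(post)
    np.testing.assert_allclose(
        table["delta_mean"], truth.delta, atol=1.0
    )
    for _, row in table.iterrows():
        if row["class"] == "favorable":
            assert row["hpd_low"] > 0
        elif row["class"] == "unfavorable":
            assert row["hpd_high"] < 0
        else:
            assert row["hpd_low"] <= 0 <= row["hpd_high"]


def test_classification_boundaries():
    """Hand-built posteriors exercise the favorable/unfavorable boundary."""
    means, _ = simulate_gxe_means(6, 4, 1, (5.0,), sd_eps=0.3, seed=3, sd_delta=20.0)
    post = fit_bammi(means, t=1, settings=MCMCSettings(1200, 400, 2), seed=2)
    table = classify_environments(post)
    strong = table[np.abs(table["delta_mean"]) > 5]
    assert (strong["class"] != "neutral").all()


def test_planted_specific_adaptation():
    """A genotype with a planted interaction in one environment is flagged
    as specifically adapted there; nearly all other genotypes stay stable.

    A single-cell bump of size c leaks ~c/g into every other genotype's
    leading score after double centring, so a couple of spurious non-stable
    calls are part of the model's exact behaviour, not a defect.
    """
    for seed in range(2):
        means, _ = simulate_gxe_means(
            12, 5, 1, (1e-8,), sd_eps=1.0, seed=40 + seed, mu=20.0, sd_tau=3, sd_delta=3
        )
        y = means.values.copy()
        y[0, 0] += 10.0  # planted cell signal
        planted = GxEMeans(
            values=y, genotypes=means.genotypes, environments=means.environments
        )
        post = fit_bammi(planted, t=2, settings=MCMCSettings(3000, 1000, 2), seed=seed)
        scores = biplot_scores(post)
        report = stability_report(post, scores)
        stable = report.genotype_table.set_index("genotype")["stable"]
        assert not stable.loc[means.genotypes[0]]
        assert (means.genotypes[0], means.environments[0]) in report.specific_adaptations
        assert stable.iloc[1:].sum() >= 9


def test_stability_requires_two_axes():
    means, _ = simulate_gxe_means(8, 5, 1, (30.0,), sd_eps=0.5, seed=2, sd_tau=4, sd_delta=3)
    post = fit_bammi(means, t=1, settings=MCMCSettings(1200, 400, 2), seed=1)
    scores = biplot_scores(post)
    with pytest.raises(UsageError):
        stability_report(post, scores)


def test_row_exchangeability_of_posterior_means(bammi_noiseless):
    """Permuting genotype rows permutes the tau posterior means (up to
    Monte Carlo error; the sampler is vectorized so draws are not bitwise
    permutation-equivariant)."""
    means, _, post = bammi_noiseless
    perm = np.array([3, 0, 1, 2, 5, 4, 7, 6, 9, 8, 11, 10])
    permuted = GxEMeans(
        values=means.values[perm],
        genotypes=[means.genotypes[i] for i in perm],
        environments=means.environments,
    )
    post_p = fit_bammi(permuted, t=2, settings=MCMCSettings(3000, 1000, 2), seed=3)
    np.testing.assert_allclose(
        post_p.tau.mean(axis=0), post.tau.mean(axis=0)[perm], atol=0.05
    )


def test_chain_flattening(bammi_additive):
    _, _, post = bammi_additive
    chain = post.to_chain()
    g, a, t = len(post.genotypes), len(post.environments), post.t
    assert len(chain.names) == 1 + g + a + t + t * g + t * a + 1
    np.testing.assert_array_equal(chain.column("mu"), post.mu)
    np.testing.assert_array_equal(
        chain.column(f"tau[{post.genotypes[0]}]"), post.tau[:, 0]
    )
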