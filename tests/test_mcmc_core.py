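import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from beanmet.errors import (
    DegenerateChainError,
    InsufficientSamplesError,
    SchemaError,
    UsageError,
)
from beanmet.mcmc_core import (
    Chain,
    MCMCSettings,
    PosteriorSummary,
    geweke_z,
    hpd_excludes_zero,
    hpd_interval,
    intervals_overlap,
    read_chain_csv,
    summarize,
    write_chain_csv,
)


def hpd_oracle(draws, level):
    """Exhaustive window scan: smallest interval over sorted draws holding
    ceil(level*n) draws, ties by smallest lower endpoint."""
    x = sorted(draws)
    n = len(x)
    m = math.ceil(level * n)
    best = None
    for i in range(n - m + 1):
        lo, hi = x[i], x[i + m - 1]
        if best is None or (hi - lo, lo) < (best[1] - best[0], best[0]):
            best = (lo, hi)
    return best


def test_hpd_constant_draws():
    assert hpd_interval(np.full(50, 3.25)) == (3.25, 3.25)


def test_hpd_integers_matches_oracle():
    x = np.arange(1.0, 101.0)
    lo, hi = hpd_interval(x, 0.95)
    assert hi - lo == 94.0
    assert (lo, hi) == hpd_oracle(x, 0.95)


def test_hpd_standard_normal_endpoints():
    rng = np.random.default_rng(123)
    lo, hi = hpd_interval(rng.standard_normal(100_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hpd_level_to_one_gives_range():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(500)
    assert hpd_interval(x, 0.999999) == (x.min(), x.max())


@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False, width=32), min_size=10, max_size=400
    ),
    st.sampled_from([0.5, 0.8, 0.9, 0.95]),
)
def test_hpd_equals_exhaustive_oracle(xs, level):
    assert hpd_interval(np.array(xs), level) == hpd_oracle(xs, level)


def test_hpd_too_few_draws():
    with pytest.raises(InsufficientSamplesError):
        hpd_interval(np.arange(9.0))


def test_geweke_forced_separation():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1e-3, 2000), rng.normal(10, 1e-3, 2000)])
    assert abs(geweke_z(x)) > 10


def test_geweke_null_chain_moderate():
    rng = np.random.default_rng(17)
    assert abs(geweke_z(rng.standard_normal(10_000))) < 4


def test_geweke_constant_chain_errors():
    with pytest.raises(DegenerateChainError):
        geweke_z(np.ones(2000))


def test_geweke_affine_invariance():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(5000)
    z = geweke_z(x)
    assert geweke_z(3.7 * x + 11.0) == pytest.approx(z, rel=1e-10)


def _chain(draws, names=None):
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 1:
        draws = draws.T
    n = draws.shape[0]
    return Chain(
        names=names or [f"p{j}" for j in range(draws.shape[1])],
        draws=draws,
        n_total=n,
        burn_in=0,
        thin=1,
        seed=0,
    )


def test_summarize_constant_chain():
    s = summarize(_chain(np.full(100, 2.5)))["p0"]
    assert s.mean == s.median == s.hpd_low == s.hpd_high == 2.5


def test_summarize_permutation_invariant():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(501)
    a = summarize(_chain(x))["p0"]
    b = summarize(_chain(rng.permutation(x)))["p0"]
    assert a.mean == pytest.approx(b.mean, rel=1e-12)  # summation order only
    assert (a.median, a.hpd_low, a.hpd_high) == (b.median, b.hpd_low, b.hpd_high)


def test_summarize_columns_independent():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((200, 2))
    both = summarize(_chain(x, names=["a", "b"]))
    assert both["a"] == summarize(_chain(x[:, 0], names=["a"]))["a"]
    assert both["b"] == summarize(_chain(x[:, 1], names=["b"]))["b"]


def _summary(lo, hi, level=0.95):
    return PosteriorSummary(
        mean=(lo + hi) / 2, median=(lo + hi) / 2, hpd_low=lo, hpd_high=hi, level=level
    )


@pytest.mark.parametrize(
    "lo,hi,expected",
    [
        (-0.08, 0.15, False),  # interval straddles zero -> not significant
        (0.17, 0.28, True),
        (0.0, 1.0, False),  # zero on the boundary counts as overlap
        (-1.0, -0.2, True),
    ],
)
def test_hpd_excludes_zero(lo, hi, expected):
    assert hpd_excludes_zero(_summary(lo, hi)) is expected


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((9.3, 17.0), (6.1, 14.5), True),  # overlapping progress intervals
        ((1.0, 2.0), (3.0, 4.0), False),
        ((1.0, 3.0), (3.0, 4.0), True),  # shared endpoint counts as overlap
    ],
)
def test_intervals_overlap(a, b, expected):
    assert intervals_overlap(_summary(*a), _summary(*b)) is expected


def test_intervals_overlap_level_mismatch():
    with pytest.raises(UsageError):
        intervals_overlap(_summary(0, 1), _summary(0, 1, level=0.9))


def test_chain_invariants():
    with pytest.raises(UsageError):
        Chain(names=["a"], draws=np.ones((5, 1)), n_total=100, burn_in=0, thin=1)
    with pytest.raises(UsageError):
        Chain(
            names=["a"],
            draws=np.array([[np.inf]] * 10),
            n_total=10,
            burn_in=0,
            thin=1,
        )


def test_settings_retention_rule():
    s = MCMCSettings(n_total=20_000, burn_in=5_000, thin=5)
    assert s.n_retained == 3000
    its = s.retained_iterations()
    assert its[0] == 5000 and its[-1] < 20_000 and len(its) == 3000


def test_chain_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(4)
    chain = Chain(
        names=["mu", "sigma2"],
        draws=rng.standard_normal((50, 2)),
        n_total=110,
        burn_in=10,
        thin=2,
        seed=99,
    )
    path = tmp_path / "chain.csv"
    write_chain_csv(chain, path)
    back = read_chain_csv(path)
    assert back.names == chain.names
    assert (back.n_total, back.burn_in, back.thin, back.seed) == (110, 10, 2, 99)
    np.testing.assert_allclose(back.draws, chain.draws, rtol=1e-12)

    (tmp_path / "bad.csv").write_text("mu\n1.0\n")
    with pytest.raises(SchemaError):
        read_chain_csv(tmp_path / "bad.csv")
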