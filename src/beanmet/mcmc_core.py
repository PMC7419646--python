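"""Posterior-chain containers and the inference primitives shared by every sampler.

All downstream significance calls in the package reduce to two rules applied to
95% highest-posterior-density (HPD) intervals:

* an effect is *significant* when its HPD interval excludes zero (a zero on an
  endpoint counts as overlap);
* two estimates *differ* when their HPD intervals do not overlap (a shared
  endpoint counts as overlap).

The HPD interval is the empirical shortest interval: over the sorted draws the
contiguous window of ``ceil(level * n)`` draws with the smallest width, ties
broken by the smallest lower endpoint.  This is deterministic and checkable by
exhaustive window scan, which the test suite does.

Convergence is monitored with the Geweke diagnostic: a z-score comparing the
mean of an early chain segment with the mean of a late segment, with the
variance of each segment mean estimated from the spectral density at frequency
zero (Bartlett/triangular lag window).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateChainError,
    InsufficientSamplesError,
    SchemaError,
    UsageError,
)

__all__ = [
    "MCMCSettings",
    "DESK_SETTINGS",
    "Chain",
    "PosteriorSummary",
    "hpd_interval",
    "geweke_z",
    "summarize",
    "hpd_excludes_zero",
    "intervals_overlap",
    "write_chain_csv",
    "read_chain_csv",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length bookkeeping shared by all Gibbs samplers.

    Defaults are desk-scale (20,000 total, 5,000 burn-in, thin 5).  The
    publication-scale settings used for the headline common-bean analysis
    (1,000,000 total with half-million burn-in) are available as presets.
    """

    n_total: int = 20_000
    burn_in: int = 5_000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.thin < 1 or self.n_total <= self.burn_in:
            raise UsageError(
                f"invalid MCMC settings: n_total={self.n_total}, "
                f"burn_in={self.burn_in}, thin={self.thin}"
            )
        if self.n_retained < 1:
            raise UsageError("settings retain no draws")

    @property
    def n_retained(self) -> int:
        return (self.n_total - self.burn_in) // self.thin

    def retained_iterations(self) -> np.ndarray:
        """Iteration indices (0-based) that are stored in the chain."""
        return self.burn_in + self.thin * np.arange(self.n_retained)


DESK_SETTINGS = MCMCSettings()
#: Publication-scale settings of the hierarchical model fits.
FULL_SCALE_LMM_SETTINGS = MCMCSettings(n_total=1_000_000, burn_in=500_000, thin=5)
#: Publication-scale settings of the BAMMI fit.
FULL_SCALE_BAMMI_SETTINGS = MCMCSettings(n_total=1_000_000, burn_in=100_000, thin=5)


@dataclass
class Chain:
    """Named posterior draws plus the bookkeeping needed to reproduce them.

    ``draws`` is a (retained draws x parameters) matrix; ``names`` labels the
    columns.  The container is sampler-agnostic: every model in the package
    returns its posterior in this form so HPD/Geweke inference is uniform.
    """

    names: list[str]
    draws: np.ndarray
    n_total: int
    burn_in: int
    thin: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2:
            raise UsageError("draws must be a 2-D (draws x parameters) array")
        if len(self.names) != self.draws.shape[1]:
            raise UsageError("names length does not match draw columns")
        expected = (self.n_total - self.burn_in) // self.thin
        if expected < 1 or self.draws.shape[0] != expected:
            raise UsageError(
                f"retained draws {self.draws.shape[0]} != "
                f"floor((n_total - burn_in)/thin) = {expected}"
            )
        if not np.all(np.isfinite(self.draws)):
            raise UsageError("chain contains non-finite draws")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r} in chain") from None
        return self.draws[:, j]

    def select(self, names: list[str]) -> "Chain":
        idx = [self.names.index(n) for n in names]
        return replace(self, names=list(names), draws=self.draws[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean, median and HPD bounds of one scalar posterior."""

    mean: float
    median: float
    hpd_low: float
    hpd_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise UsageError(f"level must be in (0, 1), got {self.level}")
        if self.hpd_low > self.hpd_high:
            raise UsageError("hpd_low exceeds hpd_high")


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical shortest interval containing ``ceil(level * n)`` draws.

    Ties in width are broken by the smallest lower endpoint, so the result is
    a deterministic function of the multiset of draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise InsufficientSamplesError(f"need >= 10 draws for an HPD interval, got {n}")
    if not 0.0 < level < 1.0:
        raise UsageError(f"level must be in (0, 1), got {level}")
    m = math.ceil(level * n)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum = smallest lower endpoint
    return float(x[i]), float(x[i + m - 1])


def _spectral_variance_of_mean(x: np.ndarray) -> float:
    """Variance of the segment mean from the spectral density at zero.

    S(0) is estimated by fitting an autoregressive model by Yule-Walker
    (Levinson-Durbin recursion), with the order chosen by AIC up to
    ``10 * log10(n)``: S(0) = sigma2_p / (1 - sum phi)^2.  This is the
    estimator the canonical implementation of the diagnostic uses, and on
    iid chains it keeps the |z| > 1.96 rate at its nominal 5%.  The result
    is S(0)/n.
    """
    n = x.size
    xc = x - x.mean()
    max_order = min(n - 1, int(round(10.0 * math.log10(n))))
    gam = np.array([float(xc[: n - k] @ xc[k:]) / n for k in range(max_order + 1)])
    if gam[0] <= 0.0:
        return 0.0
    best_aic = n * math.log(gam[0])
    s0 = gam[0]
    phi_prev = np.zeros(0)
    err = gam[0]
    for p in range(1, max_order + 1):
        if p == 1:
            k = gam[1] / gam[0]
            phi = np.array([k])
        else:
            k = (gam[p] - float(phi_prev @ gam[1:p][::-1])) / err
            phi = np.concatenate([phi_prev - k * phi_prev[::-1], [k]])
        err *= 1.0 - k * k
        if err <= 0.0:
            break
        aic = n * math.log(err) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            s0 = err / (1.0 - float(phi.sum())) ** 2
        phi_prev = phi
    return max(s0, 0.0) / n


def geweke_z(
    draws: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5
) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Defaults compare the first 10% with the last 50% of the chain.  Segment
    mean variances come from :func:`_spectral_variance_of_mean`.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    n_first = int(math.floor(frac_first * n))
    n_last = int(math.floor(frac_last * n))
    if n_first < 50 or n_last < 50:
        raise InsufficientSamplesError(
            f"Geweke windows need >= 50 draws each (got {n_first} and {n_last})"
        )
    if n_first + n_last > n:
        raise UsageError("Geweke windows overlap; reduce frac_first/frac_last")
    a = x[:n_first]
    b = x[n - n_last :]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateChainError("constant chain segment; Geweke z undefined")
    sv_a = _spectral_variance_of_mean(a)
    sv_b = _spectral_variance_of_mean(b)
    denom = math.sqrt(sv_a + sv_b)
    if denom == 0.0:
        raise DegenerateChainError("zero spectral variance in both segments")
    return float((a.mean() - b.mean()) / denom)


def summarize(chain: Chain, level: float = 0.95) -> dict[str, PosteriorSummary]:
    """Per-parameter :class:`PosteriorSummary` (mean, median, HPD)."""
    out: dict[str, PosteriorSummary] = {}
    for j, name in enumerate(chain.names):
        col = chain.draws[:, j]
        low, high = hpd_interval(col, level)
        out[name] = PosteriorSummary(
            mean=float(col.mean()),
            median=float(np.median(col)),
            hpd_low=low,
            hpd_high=high,
            level=level,
        )
    return out


def summary_frame(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    """Tabular view of :func:`summarize` output."""
    return pd.DataFrame(
        {
            "mean": {k: s.mean for k, s in summaries.items()},
            "median": {k: s.median for k, s in summaries.items()},
            "hpd_low": {k: s.hpd_low for k, s in summaries.items()},
            "hpd_high": {k: s.hpd_high for k, s in summaries.items()},
        }
    )


def hpd_excludes_zero(summary: PosteriorSummary) -> bool:
    """True iff the HPD interval lies strictly on one side of zero.

    Zero sitting exactly on an endpoint counts as overlap (not significant).
    """
    return summary.hpd_low > 0.0 or summary.hpd_high < 0.0


def intervals_overlap(a: PosteriorSummary, b: PosteriorSummary) -> bool:
    """True iff the two HPD intervals share at least one point.

    A shared endpoint counts as overlap, matching the zero-exclusion rule.
    """
    if a.level != b.level:
        raise UsageError(f"interval levels differ: {a.level} vs {b.level}")
    return max(a.hpd_low, b.hpd_low) <= min(a.hpd_high, b.hpd_high)


# --- chain serialization ---------------------------------------------------
# CSV with one column per parameter; the first line is a comment recording the
# sampling metadata so a round-trip restores the full Chain.

def write_chain_csv(chain: Chain, path) -> None:
    meta = (
        f"# n_total={chain.n_total} burn_in={chain.burn_in} "
        f"thin={chain.thin} seed={chain.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(meta)
        chain.to_frame().to_csv(fh, index=False)


def read_chain_csv(path) -> Chain:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise SchemaError("chain CSV must start with a '# key=value ...' line")
        meta: dict[str, str] = {}
        for tok in first[1:].split():
            k, _, v = tok.partition("=")
            meta[k] = v
        body = fh.read()
    df = pd.read_csv(io.StringIO(body))
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return Chain(
        names=list(df.columns),
        draws=df.to_numpy(dtype=float),
        n_total=int(meta["n_total"]),
        burn_in=int(meta["burn_in"]),
        thin=int(meta["thin"]),
        seed=seed,
    )
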