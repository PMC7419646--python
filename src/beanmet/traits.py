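"""Derived agronomic traits: SY, Prot, HI, plant N, NUpE, NUtE, NUsE.

Definitions (all per plot):

* ``SY``   — seed yield standardized to 13% moisture, kg ha^-1:
  ``field_seed_mass * (100 - moisture) / 87 * (10000 / harvest_area)``.
* ``Prot`` — seed protein %, ``seed N % * 6.25`` (Kjeldahl factor).
* ``HI``   — harvest index, the fraction of above-ground dry biomass
  allocated to seed: ``seed / (seed + shoot)``.
* ``total_n`` — g N in the sampled plants, summing seed and shoot pools.
* ``NUpE`` — N uptake efficiency, plant N per unit N applied.
* ``NUtE`` — N utilization efficiency, seed dry biomass per unit plant N.
* ``NUsE`` — N use efficiency, ``NUpE * NUtE`` (= seed biomass / N applied).

Scalar functions raise :class:`~beanmet.errors.DomainError` on invalid input;
:func:`derive_all` instead downgrades per-cell violations to missing values
with a logged warning so one bad plot never aborts a whole table.

The printed field units of the efficiency ratios (mg g^-1, g mg^-1, g g^-1)
are treated as display labels; computation is in consistent grams.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError
from .trial_data import KEY_COLUMNS, TrialTable

__all__ = [
    "TRAIT_NAMES",
    "standardize_sy",
    "compute_prot",
    "compute_hi",
    "compute_total_n",
    "compute_nupe",
    "compute_nute",
    "compute_nuse",
    "n_response_percent",
    "derive_all",
]

logger = logging.getLogger(__name__)

TRAIT_NAMES = ["sy", "prot", "hi", "nupe", "nute", "nuse"]
_STANDARD_MOISTURE = 13.0
KJELDAHL_FACTOR = 6.25


def standardize_sy(field_seed_mass, moisture_pct, harvest_area):
    """Seed yield in kg ha^-1 rescaled to the 13% standard moisture."""
    field_seed_mass = np.asarray(field_seed_mass, dtype=float)
    moisture_pct = np.asarray(moisture_pct, dtype=float)
    harvest_area = np.asarray(harvest_area, dtype=float)
    if np.any(moisture_pct >= 100) or np.any(moisture_pct < 0):
        raise DomainError("moisture_pct must be in [0, 100)")
    if np.any(harvest_area <= 0):
        raise DomainError("harvest_area must be > 0")
    out = (
        field_seed_mass
        * (100.0 - moisture_pct)
        / (100.0 - _STANDARD_MOISTURE)
        * (10_000.0 / harvest_area)
    )
    return out if out.ndim else float(out)


def compute_prot(seed_n_pct):
    """Seed protein % from seed N % via the 6.25 Kjeldahl factor."""
    seed_n_pct = np.asarray(seed_n_pct, dtype=float)
    out = seed_n_pct * KJELDAHL_FACTOR
    if np.any(out > 100):
        raise DomainError("protein content above 100%: seed_n_pct too large")
    if np.any(seed_n_pct < 0):
        raise DomainError("seed_n_pct must be >= 0")
    return out if out.ndim else float(out)


def compute_hi(seed_dry_biomass, shoot_dry_biomass):
    """Harvest index: seed / (seed + shoot) dry biomass, in [0, 1]."""
    seed = np.asarray(seed_dry_biomass, dtype=float)
    shoot = np.asarray(shoot_dry_biomass, dtype=float)
    if np.any(seed < 0) or np.any(shoot < 0):
        raise DomainError("biomasses must be >= 0")
    total = seed + shoot
    if np.any(total <= 0):
        raise DomainError("seed + shoot biomass must be > 0")
    out = seed / total
    return out if out.ndim else float(out)


def compute_total_n(seed_dry_biomass, seed_n_pct, shoot_dry_biomass, shoot_n_pct):
    """Grams of N in the plant sample (seed pool + shoot pool)."""
    seed = np.asarray(seed_dry_biomass, dtype=float)
    shoot = np.asarray(shoot_dry_biomass, dtype=float)
    sn = np.asarray(seed_n_pct, dtype=float)
    hn = np.asarray(shoot_n_pct, dtype=float)
    if np.any(seed < 0) or np.any(shoot < 0) or np.any(sn < 0) or np.any(hn < 0):
        raise DomainError("inputs must be >= 0")
    out = seed * sn / 100.0 + shoot * hn / 100.0
    return out if out.ndim else float(out)


def compute_nupe(total_n, n_applied):
    """N uptake efficiency: plant N over N fertilizer applied to the plot."""
    total_n = np.asarray(total_n, dtype=float)
    n_applied = np.asarray(n_applied, dtype=float)
    if np.any(n_applied <= 0):
        raise DomainError("n_applied must be > 0")
    out = total_n / n_applied
    return out if out.ndim else float(out)


def compute_nute(seed_dry_biomass, total_n):
    """N utilization efficiency: seed dry biomass over plant N."""
    seed = np.asarray(seed_dry_biomass, dtype=float)
    total_n = np.asarray(total_n, dtype=float)
    if np.any(total_n <= 0):
        raise DomainError("total_n must be > 0")
    out = seed / total_n
    return out if out.ndim else float(out)


def compute_nuse(nupe, nute):
    """N use efficiency: NUpE x NUtE (algebraically seed biomass / N applied)."""
    out = np.asarray(nupe, dtype=float) * np.asarray(nute, dtype=float)
    return out if out.ndim else float(out)


def n_response_percent(high_mean: float, low_mean: float) -> float:
    """Percent increase of a trait mean under high vs low N top-dressing."""
    if low_mean <= 0:
        raise DomainError("low-N mean must be > 0 for a percent response")
    return 100.0 * (high_mean - low_mean) / low_mean


def derive_all(table: TrialTable) -> pd.DataFrame:
    """All six derived traits (plus ``total_n``) for every plot.

    Returns a frame keyed by (genotype, environment, n_level, block).  Missing
    or domain-invalid inputs yield missing trait values; a warning is logged
    with the number of cells downgraded per trait.
    """
    rec = table.records
    out = rec[KEY_COLUMNS].copy()
    nan = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        sy_ok = (
            rec["field_seed_mass"].ge(0)
            & rec["moisture_pct"].between(0, 100, inclusive="left")
            & rec["harvest_area"].gt(0)
        )
        sy = (
            rec["field_seed_mass"]
            * (100.0 - rec["moisture_pct"])
            / (100.0 - _STANDARD_MOISTURE)
            * (10_000.0 / rec["harvest_area"])
        )
        out["sy"] = np.where(sy_ok, sy, nan)

        prot = rec["seed_n_pct"] * KJELDAHL_FACTOR
        prot_ok = rec["seed_n_pct"].ge(0) & prot.le(100)
        out["prot"] = np.where(prot_ok, prot, nan)

        total_bio = rec["seed_dry_biomass"] + rec["shoot_dry_biomass"]
        hi_ok = rec["seed_dry_biomass"].ge(0) & rec["shoot_dry_biomass"].ge(0) & total_bio.gt(0)
        out["hi"] = np.where(hi_ok, rec["seed_dry_biomass"] / total_bio, nan)

        total_n = (
            rec["seed_dry_biomass"] * rec["seed_n_pct"] / 100.0
            + rec["shoot_dry_biomass"] * rec["shoot_n_pct"] / 100.0
        )
        tn_ok = (
            rec["seed_dry_biomass"].ge(0)
            & rec["shoot_dry_biomass"].ge(0)
            & rec["seed_n_pct"].ge(0)
            & rec["shoot_n_pct"].ge(0)
        )
        out["total_n"] = np.where(tn_ok, total_n, nan)

        nupe_ok = tn_ok & rec["n_applied"].gt(0)
        out["nupe"] = np.where(nupe_ok, total_n / rec["n_applied"], nan)

        nute_ok = tn_ok & (total_n > 0) & rec["seed_dry_biomass"].ge(0)
        out["nute"] = np.where(nute_ok, rec["seed_dry_biomass"] / total_n, nan)

        out["nuse"] = out["nupe"] * out["nute"]

    # cells whose inputs were all present yet violated a domain rule were
    # downgraded to missing, not errored; surface how many per trait
    for trait, ok in (
        ("sy", sy_ok),
        ("prot", prot_ok),
        ("hi", hi_ok),
        ("nupe", nupe_ok),
        ("nute", nute_ok),
    ):
        n_invalid = int((~ok & _all_inputs_present(trait, rec)).sum())
        if n_invalid:
            logger.warning(
                "derive_all: %d plot(s) with domain-invalid inputs for %s set to missing",
                n_invalid,
                trait,
            )
    return out


_TRAIT_INPUTS = {
    "sy": ["field_seed_mass", "moisture_pct", "harvest_area"],
    "prot": ["seed_n_pct"],
    "hi": ["seed_dry_biomass", "shoot_dry_biomass"],
    "nupe": ["seed_dry_biomass", "seed_n_pct", "shoot_dry_biomass", "shoot_n_pct", "n_applied"],
    "nute": ["seed_dry_biomass", "seed_n_pct", "shoot_dry_biomass", "shoot_n_pct"],
}


def _all_inputs_present(trait: str, rec: pd.DataFrame) -> pd.Series:
    return rec[_TRAIT_INPUTS[trait]].notna().all(axis=1)
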