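"""Plot-level trial tables: schema, readers/writers, and design validation.

The canonical exchange format is a long (tidy) CSV — one row per plot — keyed
by (genotype, environment, n_level, block) and carrying the raw field
measurements from which every derived trait is computed.  Cultivar metadata
(release year, growth habit, ...) travels in a companion registry CSV.
Missing measurements are empty cells and stay missing downstream; they are
never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, SchemaError, UsageError

__all__ = [
    "KEY_COLUMNS",
    "MEASURE_COLUMNS",
    "CULTIVAR_COLUMNS",
    "CultivarInfo",
    "EnvironmentInfo",
    "PlotRecord",
    "TrialTable",
    "DesignReport",
    "read_trial_csv",
    "write_trial_csv",
    "read_cultivars_csv",
    "write_cultivars_csv",
    "validate_design",
]

KEY_COLUMNS = ["genotype", "environment", "n_level", "block"]
MEASURE_COLUMNS = [
    "seed_dry_biomass",
    "shoot_dry_biomass",
    "seed_n_pct",
    "shoot_n_pct",
    "field_seed_mass",
    "moisture_pct",
    "harvest_area",
    "n_applied",
]
TRIAL_COLUMNS = KEY_COLUMNS + MEASURE_COLUMNS
CULTIVAR_COLUMNS = ["code", "name", "release_year", "origin", "growth_habit", "architecture"]

N_LEVELS = ("high", "low")
GROWTH_HABITS = ("determinate", "indeterminate")
ARCHITECTURES = ("erect", "semierect", "prostrate")


@dataclass(frozen=True)
class CultivarInfo:
    """One cultivar registry entry (code is the integer genotype id)."""

    code: int
    name: str
    release_year: int
    origin: str = ""
    growth_habit: str = "indeterminate"
    architecture: str = "semierect"

    def __post_init__(self) -> None:
        if not 1900 <= self.release_year <= 2100:
            raise SchemaError(
                f"cultivar {self.code}: release_year {self.release_year} "
                "outside [1900, 2100]"
            )
        if self.growth_habit not in GROWTH_HABITS:
            raise SchemaError(f"unknown growth_habit {self.growth_habit!r}")
        if self.architecture not in ARCHITECTURES:
            raise SchemaError(f"unknown architecture {self.architecture!r}")


@dataclass(frozen=True)
class EnvironmentInfo:
    """Site-season environment; soil/climate descriptors ride as metadata."""

    env_id: str
    site: str = ""
    season: str = ""
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PlotRecord:
    """One experimental plot.  NaN marks a measurement that was not taken."""

    genotype: int
    environment: str
    n_level: str
    block: int
    seed_dry_biomass: float = np.nan
    shoot_dry_biomass: float = np.nan
    seed_n_pct: float = np.nan
    shoot_n_pct: float = np.nan
    field_seed_mass: float = np.nan
    moisture_pct: float = np.nan
    harvest_area: float = np.nan
    n_applied: float = np.nan

    def __post_init__(self) -> None:
        if self.n_level not in N_LEVELS:
            raise SchemaError(f"n_level must be one of {N_LEVELS}, got {self.n_level!r}")
        for col in ("seed_dry_biomass", "shoot_dry_biomass", "field_seed_mass"):
            v = getattr(self, col)
            if np.isfinite(v) and v < 0:
                raise SchemaError(f"{col} must be >= 0, got {v}")
        for col in ("seed_n_pct", "shoot_n_pct", "moisture_pct"):
            v = getattr(self, col)
            if np.isfinite(v) and not 0 <= v <= 100:
                raise SchemaError(f"{col} must be in [0, 100], got {v}")
        if np.isfinite(self.harvest_area) and self.harvest_area <= 0:
            raise SchemaError(f"harvest_area must be > 0, got {self.harvest_area}")
        if np.isfinite(self.n_applied) and self.n_applied <= 0:
            raise SchemaError(f"n_applied must be > 0, got {self.n_applied}")


@dataclass
class TrialTable:
    """Validated plot records plus cultivar and environment registries.

    ``records`` holds one row per plot with the canonical columns (extra
    columns from the CSV are preserved untouched); ``cultivars`` and
    ``environments`` are registry frames indexed implicitly by ``code`` and
    ``env_id``.
    """

    records: pd.DataFrame
    cultivars: pd.DataFrame
    environments: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
        dup = self.records.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            offenders = (
                self.records.loc[dup, KEY_COLUMNS]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise DuplicateKeyError(
                "duplicate (genotype, environment, n_level, block) keys: "
                + "; ".join(map(str, offenders))
            )
        bad_n = ~self.records["n_level"].isin(N_LEVELS)
        if bad_n.any():
            raise SchemaError(
                f"unknown n_level values: {sorted(self.records.loc[bad_n, 'n_level'].unique())}"
            )
        if "code" not in self.cultivars.columns:
            raise SchemaError("cultivar registry missing column 'code'")
        if self.cultivars["code"].duplicated().any():
            raise DuplicateKeyError("cultivar codes are not unique")
        unknown_g = set(self.records["genotype"]) - set(self.cultivars["code"])
        if unknown_g:
            raise SchemaError(f"records reference unknown cultivar codes: {sorted(unknown_g)}")
        unknown_e = set(self.records["environment"]) - set(self.environments["env_id"])
        if unknown_e:
            raise SchemaError(f"records reference unknown environments: {sorted(unknown_e)}")

    @property
    def genotypes(self) -> list[int]:
        return sorted(self.records["genotype"].unique())

    @property
    def env_ids(self) -> list[str]:
        return sorted(self.records["environment"].unique())


@dataclass(frozen=True)
class DesignReport:
    """Report-only summary of the factorial layout (never mutates data)."""

    n_genotypes: int
    n_environments: int
    n_levels: int
    n_blocks: int
    n_env_n_combinations: int
    n_records: int
    cell_counts: pd.DataFrame
    missing_cells: list[tuple]

    @property
    def n_missing(self) -> int:
        return len(self.missing_cells)


def _normalize_columns(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    lower = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in required if c not in lower]
    if missing:
        raise SchemaError(f"{what} missing mandatory column(s): {', '.join(missing)}")
    return df.rename(columns={lower[c]: c for c in required if lower[c] != c})


def read_cultivars_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _normalize_columns(df, CULTIVAR_COLUMNS, "cultivar CSV")
    # route through the dataclass so registry invariants are enforced
    for row in df[CULTIVAR_COLUMNS].itertuples(index=False):
        CultivarInfo(
            code=int(row.code),
            name=str(row.name),
            release_year=int(row.release_year),
            origin=str(row.origin),
            growth_habit=str(row.growth_habit),
            architecture=str(row.architecture),
        )
    df["code"] = df["code"].astype(int)
    df["release_year"] = df["release_year"].astype(int)
    return df


def read_trial_csv(path, cultivar_path) -> TrialTable:
    """Read and validate a trial CSV plus its cultivar registry.

    The environment registry is derived from the distinct environment codes in
    the trial file; site/season metadata may be attached later.  Unknown
    columns are preserved on ``records``.
    """
    records = pd.read_csv(path)
    records = _normalize_columns(records, TRIAL_COLUMNS, "trial CSV")
    records["genotype"] = records["genotype"].astype(int)
    records["block"] = records["block"].astype(int)
    records["environment"] = records["environment"].astype(str)
    records["n_level"] = records["n_level"].astype(str).str.lower()
    for col in MEASURE_COLUMNS:
        records[col] = pd.to_numeric(records[col], errors="coerce")
    cultivars = read_cultivars_csv(cultivar_path)
    environments = pd.DataFrame(
        {"env_id": sorted(records["environment"].unique()), "site": "", "season": ""}
    )
    return TrialTable(records=records, cultivars=cultivars, environments=environments)


def write_trial_csv(table: TrialTable, path) -> None:
    table.records.to_csv(path, index=False)


def write_cultivars_csv(table: TrialTable, path) -> None:
    table.cultivars.to_csv(path, index=False)


def validate_design(table: TrialTable) -> DesignReport:
    """Summarize the factorial layout and list empty cells.

    A *cell* is one (genotype, environment, n_level, block) combination of the
    levels actually present in the table; the report counts how many are
    populated and identifies the missing ones by key.
    """
    if len(table.records) == 0:
        raise UsageError("cannot validate an empty trial table")
    rec = table.records
    genotypes = sorted(rec["genotype"].unique())
    envs = sorted(rec["environment"].unique())
    nlevels = sorted(rec["n_level"].unique())
    blocks = sorted(rec["block"].unique())
    counts = (
        rec.groupby(KEY_COLUMNS, observed=True).size().rename("count").reset_index()
    )
    full = pd.MultiIndex.from_product(
        [genotypes, envs, nlevels, blocks], names=KEY_COLUMNS
    )
    present = pd.MultiIndex.from_frame(counts[KEY_COLUMNS])
    missing = [tuple(t) for t in full.difference(present)]
    env_n = rec[["environment", "n_level"]].drop_duplicates()
    return DesignReport(
        n_genotypes=len(genotypes),
        n_environments=len(envs),
        n_levels=len(nlevels),
        n_blocks=len(blocks),
        n_env_n_combinations=len(env_n),
        n_records=len(rec),
        cell_counts=counts,
        missing_cells=sorted(missing),
    )
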