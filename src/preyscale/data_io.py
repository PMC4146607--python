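"""Read, validate and transform the predator-prey trait database.

The analysis-ready :class:`TraitTable` carries, per species: taxonomy
(order / family / genus), environment (``aquatic`` / ``terrestrial``),
predator body mass and the minimum / maximum prey mass, all in kg, plus
derived log10 columns.  The prey-mass range is computed on the raw kg
scale (``prey_max - prey_min``) and *then* log10-transformed; rows with
``prey_min == prey_max`` have an undefined log range and are flagged but
retained for the min/max analyses.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "DEFAULT_COLUMNS",
    "SpeciesRecord",
    "TraitTable",
    "read_trait_table",
    "write_trait_table",
    "species_set",
    "normalize_species_name",
]

#: canonical field -> default CSV header
DEFAULT_COLUMNS = {
    "species": "species",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "environment": "environment",
    "predator_mass": "predator_mass",
    "prey_min": "prey_min",
    "prey_max": "prey_max",
}

ENVIRONMENTS = ("aquatic", "terrestrial")

#: user-facing response keys -> derived column names
RESPONSE_COLUMNS = {
    "min": "log_prey_min",
    "max": "log_prey_max",
    "range": "log_prey_range",
}

#: derived (log) column -> raw kg column(s)
RAW_FOR_RESPONSE = {
    "log_prey_min": "prey_min",
    "log_prey_max": "prey_max",
    "log_prey_range": "prey_range_kg",
}


def normalize_species_name(name: str) -> str:
    """Collapse whitespace/underscore runs to single underscores.

    Newick convention writes ``Genus_species``; trait tables often use a
    space.  Both normalize to the same key for tip matching.
    """
    return re.sub(r"[\s_]+", "_", str(name).strip())


@dataclass(frozen=True)
class SpeciesRecord:
    """One validated row of the database (masses in kg)."""

    species: str
    order: str
    family: str
    genus: str
    environment: str
    predator_mass: float
    prey_min: float
    prey_max: float

    def __post_init__(self):
        problems = validate_record(self)
        if problems:
            raise ValidationError(
                f"invalid record for {self.species!r}", problems=problems
            )

    @property
    def log_mass(self) -> float:
        return math.log10(self.predator_mass)

    @property
    def log_prey_min(self) -> float:
        return math.log10(self.prey_min)

    @property
    def log_prey_max(self) -> float:
        return math.log10(self.prey_max)

    @property
    def range_defined(self) -> bool:
        return self.prey_max > self.prey_min

    @property
    def log_prey_range(self) -> float:
        """log10 of (prey_max - prey_min); NaN when the range is zero."""
        if not self.range_defined:
            return float("nan")
        return math.log10(self.prey_max - self.prey_min)


def validate_record(rec: SpeciesRecord) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    problems = []
    for name in ("predator_mass", "prey_min", "prey_max"):
        val = getattr(rec, name)
        if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
            problems.append(f"{rec.species}: {name} must be a positive number, got {val!r}")
    if not problems and rec.prey_max < rec.prey_min:
        problems.append(
            f"{rec.species}: prey_max ({rec.prey_max}) < prey_min ({rec.prey_min})"
        )
    if rec.environment not in ENVIRONMENTS:
        problems.append(
            f"{rec.species}: environment must be one of {ENVIRONMENTS}, got {rec.environment!r}"
        )
    first_token = re.split(r"[\s_]+", str(rec.species).strip())[0]
    if first_token != rec.genus:
        problems.append(
            f"{rec.species}: genus {rec.genus!r} does not match the first name token {first_token!r}"
        )
    return problems


@dataclass
class TraitTable:
    """Validated species table with derived log10 columns.

    ``df`` holds the canonical columns (see :data:`DEFAULT_COLUMNS`) plus
    ``log_mass``, ``log_prey_min``, ``log_prey_max``, ``prey_range_kg``,
    ``log_prey_range`` and the boolean ``range_defined``.  ``raw`` keeps the
    source CSV verbatim (as strings) so writes round-trip bit-identically.
    """

    df: pd.DataFrame
    raw: pd.DataFrame | None = None
    report: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[SpeciesRecord]) -> "TraitTable":
        df = pd.DataFrame([vars(r) for r in records])
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, raw: pd.DataFrame | None = None) -> "TraitTable":
        """Build a table from a frame holding the canonical raw columns."""
        df = df.reset_index(drop=True).copy()
        missing = [c for c in DEFAULT_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing canonical columns: {missing}")
        problems = []
        records = []
        for row in df.itertuples(index=False):
            try:
                rec = SpeciesRecord(
                    species=str(row.species),
                    order=str(row.order),
                    family=str(row.family),
                    genus=str(row.genus),
                    environment=str(row.environment).strip().lower(),
                    predator_mass=float(row.predator_mass),
                    prey_min=float(row.prey_min),
                    prey_max=float(row.prey_max),
                )
            except ValidationError as err:
                problems.extend(err.problems)
                continue
            except (TypeError, ValueError) as err:
                problems.append(f"{row.species}: unparseable mass value ({err})")
                continue
            records.append(rec)
        if problems:
            raise ValidationError(
                f"{len(problems)} invalid row(s) in trait table", problems=problems
            )
        out = pd.DataFrame(
            [vars(r) for r in records], columns=list(DEFAULT_COLUMNS)
        )
        for col in ("predator_mass", "prey_min", "prey_max"):
            out[col] = out[col].astype(float)
        dupes = out["species"][out["species"].duplicated()].unique().tolist()
        if dupes:
            raise ValidationError(
                "duplicate species names", problems=[f"duplicated: {d}" for d in dupes]
            )
        out["log_mass"] = np.log10(out["predator_mass"])
        out["log_prey_min"] = np.log10(out["prey_min"])
        out["log_prey_max"] = np.log10(out["prey_max"])
        out["range_defined"] = out["prey_max"] > out["prey_min"]
        rng = out["prey_max"] - out["prey_min"]
        out["prey_range_kg"] = rng
        with np.errstate(divide="ignore"):
            out["log_prey_range"] = np.where(
                out["range_defined"], np.log10(rng.where(rng > 0, np.nan)), np.nan
            )
        table = cls(df=out, raw=raw)
        table.report = table._build_report()
        return table

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return self.df["species"].tolist()

    @property
    def n_aquatic(self) -> int:
        return int((self.df["environment"] == "aquatic").sum())

    @property
    def n_terrestrial(self) -> int:
        return int((self.df["environment"] == "terrestrial").sum())

    def records(self) -> list[SpeciesRecord]:
        cols = list(DEFAULT_COLUMNS)
        return [SpeciesRecord(**row) for row in self.df[cols].to_dict("records")]

    def subset(self, mask) -> "TraitTable":
        """Row-subset preserving order; derived columns recomputed."""
        return TraitTable.from_frame(self.df.loc[mask, list(DEFAULT_COLUMNS)])

    def response(self, key: str) -> pd.Series:
        """Return a derived response column by key ('min'|'max'|'range') or name."""
        col = RESPONSE_COLUMNS.get(key, key)
        if col not in self.df.columns:
            raise ConfigurationError(f"unknown response {key!r}")
        return self.df[col]

    def _build_report(self) -> dict:
        flagged = self.df.loc[~self.df["range_defined"], "species"].tolist()
        return {
            "n": len(self.df),
            "n_aquatic": self.n_aquatic,
            "n_terrestrial": self.n_terrestrial,
            "zero_range_species": flagged,
            "rejected": [],
        }


def _resolve_columns(header: list[str], config: dict | None) -> dict:
    mapping = dict(DEFAULT_COLUMNS)
    if config:
        columns = config.get("columns", config)
        unknown = [k for k in columns if k not in DEFAULT_COLUMNS]
        if unknown:
            raise ConfigurationError(f"unknown column-mapping keys: {unknown}")
        mapping.update(columns)
    missing = [f"{k} (column {v!r})" for k, v in mapping.items() if v not in header]
    if missing:
        raise ConfigurationError(
            "trait CSV is missing required column(s): " + ", ".join(missing)
        )
    return mapping


def read_trait_table(path, config: dict | None = None) -> TraitTable:
    """Read and validate a trait CSV into a :class:`TraitTable`.

    Parameters
    ----------
    path:
        CSV file with a header row; comma-separated, UTF-8.
    config:
        Optional ``{"columns": {canonical_field: csv_header, ...}}`` mapping
        so databases with different headers load without code changes.

    Raises
    ------
    ConfigurationError
        Missing file or missing required column (named in the message).
    ValidationError
        Non-positive / non-numeric masses, duplicate species, genus not
        matching the species binomial; offending species are listed.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except FileNotFoundError:
        raise ConfigurationError(f"trait table not found: {path}") from None
    mapping = _resolve_columns(list(raw.columns), config)
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    for col in ("predator_mass", "prey_min", "prey_max"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    table = TraitTable.from_frame(df, raw=raw)
    return table


def write_trait_table(table: TraitTable, path, derived: bool = False) -> None:
    """Write a trait table to CSV.

    With ``derived=False`` and a table read from disk, the original CSV
    text is reproduced bit-identically.  ``derived=True`` writes the
    analysis-ready frame including the log columns.
    """
    if derived or table.raw is None:
        table.df.to_csv(path, index=False)
    else:
        table.raw.to_csv(path, index=False)


def species_set(table: TraitTable) -> set[str]:
    """Tip-label set (normalized) used to prune the phylogeny."""
    return {normalize_species_name(s) for s in table.species}


def write_validation_report(table: TraitTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(table.report, fh, indent=2)
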