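"""Domain types and the individual-recode CSV schema shared by all stages.

The canonical interchange format is a one-row-per-respondent CSV
("individual recode" layout): identifier columns, the survey wave, the
two-stage design identifiers (stratum, cluster), the sampling weight, the
binary outcome, and one column per categorical covariate.  A schema file
(YAML) declares each covariate's category set, its reference category for
regression coding, and whether it is an individual- or community-level
variable.  Category labels are matched as exact, case-sensitive strings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Fixed leading columns of the individual-recode CSV, in order.
ID_COLUMNS = ("respondent_id", "wave", "stratum_id", "cluster_id", "weight", "outcome")


class SchemaError(ValueError):
    """A covariate schema is malformed or a required column is absent."""


class ValidationError(ValueError):
    """A data value violates the declared schema."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one categorical covariate.

    Parameters
    ----------
    name
        Column name in the individual-recode CSV.
    categories
        Ordered category labels (the order fixes ordinal scores where a
        numeric scoring of the covariate is needed).
    reference
        Baseline category for dummy coding; must be one of ``categories``.
    level
        ``"individual"`` or ``"community"`` — which level of the two-level
        model the covariate belongs to.
    """

    name: str
    categories: tuple[str, ...]
    reference: str
    level: str = "individual"

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 2:
            raise SchemaError(f"covariate {self.name!r} needs >=2 categories")
        if len(set(cats)) != len(cats):
            raise SchemaError(f"covariate {self.name!r} has duplicate category labels")
        if self.reference not in cats:
            raise SchemaError(
                f"reference {self.reference!r} of covariate {self.name!r} "
                f"is not among its categories {cats}"
            )
        if self.level not in ("individual", "community"):
            raise SchemaError(f"covariate {self.name!r}: level must be individual|community")


@dataclass
class SurveyRecord:
    """One respondent of one survey wave."""

    respondent_id: str
    wave: str
    stratum_id: str
    cluster_id: str
    weight: float
    outcome: int
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValidationError(
                f"record {self.respondent_id!r}: weight must be positive, got {self.weight}"
            )
        if self.outcome not in (0, 1):
            raise ValidationError(
                f"record {self.respondent_id!r}: outcome must be 0 or 1, got {self.outcome}"
            )
        if not self.cluster_id:
            raise ValidationError(f"record {self.respondent_id!r}: empty cluster_id")


@dataclass(frozen=True)
class GroupSummary:
    """A subgroup's weighted share and outcome prevalence within one wave."""

    group: str | tuple[str, ...]
    share: float
    prevalence: float
    n_effective: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.share <= 1.0 + 1e-12):
            raise ValidationError(f"group {self.group!r}: share {self.share} outside [0,1]")
        if not (0.0 <= self.prevalence <= 1.0 + 1e-12):
            raise ValidationError(
                f"group {self.group!r}: prevalence {self.prevalence} outside [0,1]"
            )


# ---------------------------------------------------------------------------
# schema files


def load_schema(path: str | Path) -> list[CovariateSpec]:
    """Read a YAML schema file into a list of :class:`CovariateSpec`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "covariates" not in raw:
        raise SchemaError(f"{path}: expected a mapping with a 'covariates' key")
    specs = []
    for entry in raw["covariates"]:
        try:
            specs.append(
                CovariateSpec(
                    name=entry["name"],
                    categories=tuple(str(c) for c in entry["categories"]),
                    reference=str(entry["reference"]),
                    level=entry.get("level", "individual"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: covariate entry missing key {exc}") from exc
    return specs


def save_schema(specs: Sequence[CovariateSpec], path: str | Path) -> None:
    """Write covariate specs to a YAML schema file."""
    payload = {
        "covariates": [
            {
                "name": s.name,
                "categories": list(s.categories),
                "reference": s.reference,
                "level": s.level,
            }
            for s in specs
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# record IO


def _covariate_columns(specs: Sequence[CovariateSpec]) -> list[str]:
    return sorted(s.name for s in specs)


def read_records(
    path: str | Path,
    schema: Sequence[CovariateSpec],
    allow_missing: bool = False,
) -> list[SurveyRecord]:
    """Read and validate an individual-recode CSV.

    Every row is validated against ``schema``: unknown category labels,
    non-positive weights and non-binary outcomes raise
    :class:`ValidationError` naming the offending row, column and value.
    With ``allow_missing=True`` rows with empty covariate cells are dropped
    (complete-case analysis) and the dropped count is logged; by default a
    missing value is an error.
    """
    path = Path(path)
    by_name = {s.name: s for s in schema}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        header = set(reader.fieldnames)
        for col in (*ID_COLUMNS, *by_name):
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        records: list[SurveyRecord] = []
        n_dropped = 0
        for i, row in enumerate(reader, start=2):  # line numbers incl. header
            cov: dict[str, str] = {}
            missing = False
            for name, spec in by_name.items():
                value = row[name]
                if value == "" or value is None:
                    if allow_missing:
                        missing = True
                        break
                    raise ValidationError(f"{path}:{i}: column {name!r} is empty")
                if value not in spec.categories:
                    raise ValidationError(
                        f"{path}:{i}: column {name!r} has unknown category {value!r}; "
                        f"declared categories are {spec.categories}"
                    )
                cov[name] = value
            if missing:
                n_dropped += 1
                continue
            try:
                weight = float(row["weight"])
                outcome = int(row["outcome"])
            except ValueError as exc:
                raise ValidationError(f"{path}:{i}: {exc}") from exc
            if weight <= 0:
                raise ValidationError(
                    f"{path}:{i}: non-positive weight {row['weight']!r}"
                )
            records.append(
                SurveyRecord(
                    respondent_id=row["respondent_id"],
                    wave=row["wave"],
                    stratum_id=row["stratum_id"],
                    cluster_id=row["cluster_id"],
                    weight=weight,
                    outcome=outcome,
                    covariates=cov,
                )
            )
    if n_dropped:
        logger.warning("%s: dropped %d rows with missing covariates (complete-case)", path, n_dropped)
    return records


def write_records(records: Sequence[SurveyRecord], path: str | Path) -> None:
    """Write records to CSV with a stable column order.

    Columns are the fixed identifier block followed by the covariates in
    alphabetical order, so that write/read round-trips are byte-stable.
    """
    if not records:
        raise ValueError("refusing to write an empty record list")
    cov_names = sorted(records[0].covariates)
    for r in records:
        if sorted(r.covariates) != cov_names:
            raise ValueError(
                f"record {r.respondent_id!r} has covariates {sorted(r.covariates)}, "
                f"expected {cov_names}"
            )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*ID_COLUMNS, *cov_names])
        for r in records:
            writer.writerow(
                [
                    r.respondent_id,
                    r.wave,
                    r.stratum_id,
                    r.cluster_id,
                    repr(r.weight),
                    r.outcome,
                    *(r.covariates[c] for c in cov_names),
                ]
            )


# ---------------------------------------------------------------------------
# DataFrame bridge — the estimation modules operate on tidy frames


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Convert records to a tidy DataFrame (one row per respondent)."""
    if not records:
        raise ValueError("empty record list")
    cov_names = sorted(records[0].covariates)
    data = {
        "respondent_id": [r.respondent_id for r in records],
        "wave": [r.wave for r in records],
        "stratum_id": [r.stratum_id for r in records],
        "cluster_id": [r.cluster_id for r in records],
        "weight": [r.weight for r in records],
        "outcome": [r.outcome for r in records],
    }
    for c in cov_names:
        data[c] = [r.covariates[c] for r in records]
    return pd.DataFrame(data)


def frame_to_records(frame: pd.DataFrame) -> list[SurveyRecord]:
    """Inverse of :func:`records_to_frame`."""
    cov_names = [c for c in frame.columns if c not in ID_COLUMNS]
    return [
        SurveyRecord(
            respondent_id=str(row.respondent_id),
            wave=str(row.wave),
            stratum_id=str(row.stratum_id),
            cluster_id=str(row.cluster_id),
            weight=float(row.weight),
            outcome=int(row.outcome),
            covariates={c: str(getattr(row, c)) for c in cov_names},
        )
        for row in frame.itertuples(index=False)
    ]


def as_frame(data: pd.DataFrame | Iterable[SurveyRecord]) -> pd.DataFrame:
    """Accept either a tidy frame or a record sequence; return the frame."""
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))
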