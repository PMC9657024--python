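"""Compound dataset model and I/O for gas/particle partitioning QSPR work.

The central container is :class:`QsprDataset`, an ordered collection of
:class:`CompoundRecord` objects. Each record carries an experimental
gas/particulate partition coefficient (``log_kp_exp``, log10 of K_P in
m³/µg) together with the molecular descriptors used by the models in this
package: the n-octanol/air partition coefficient (``log_koa``), the average
molecular polarizability ``alpha`` (a.u.) and the most negative molecular
surface electrostatic potential ``vsmin`` (eV).

The canonical 50-compound dataset (22 PAHs, 15 oxygenated, 9 nitrated and
4 aza-heterocyclic derivatives) ships with the package as a CSV fixture and
is loaded with :func:`load_table1`. Its ``vsmin_x100`` column stores the
potential multiplied by 100, the convention of the source table; the loader
rescales it to natural eV units.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "PartitionObservation",
    "CompoundRecord",
    "QsprDataset",
    "CsvDialect",
    "kp_from_concentrations",
    "log_kp_from_concentrations",
    "load_dataset",
    "write_dataset",
    "load_table1",
    "split_by_flag",
]

#: Compound classes admitted in a dataset.
COMPOUND_CLASSES = ("PAH", "O-PAH", "N-PAH", "AZA")

_FIXTURE_NAME = "table1_pah_kp.csv"

# Unicode code points that show up as "minus" in transcribed tables.
_MINUS_CHARS = "−–—"


class DatasetError(ValueError):
    """Raised for invalid records, observations, or unparseable input."""


@dataclass(frozen=True)
class PartitionObservation:
    """One raw gas/particle partitioning measurement.

    Parameters
    ----------
    c_p : float
        Concentration of the compound in the particle phase (ng/m³).
    c_a : float
        Concentration of the compound in the gas phase (ng/m³).
    tsp : float
        Total suspended particulate concentration (µg/m³).
    """

    c_p: float
    c_a: float
    tsp: float

    def __post_init__(self) -> None:
        if not self.c_p >= 0:
            raise DatasetError(f"c_p must be non-negative, got {self.c_p}")
        if not self.c_a > 0:
            raise DatasetError(f"c_a must be positive, got {self.c_a}")
        if not self.tsp > 0:
            raise DatasetError(f"tsp must be positive, got {self.tsp}")


def kp_from_concentrations(obs: PartitionObservation) -> float:
    """Gas/particulate partition coefficient K_P = C_P / (C_A × TSP), m³/µg."""
    return obs.c_p / (obs.c_a * obs.tsp)


def log_kp_from_concentrations(obs: PartitionObservation) -> float:
    """log10 of :func:`kp_from_concentrations`.

    Raises
    ------
    DatasetError
        If ``c_p`` is zero (log K_P undefined).
    """
    kp = kp_from_concentrations(obs)
    if kp == 0:
        raise DatasetError("log K_P undefined for c_p = 0")
    return math.log10(kp)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its endpoint, descriptors and split assignment.

    ``vsmin`` is stored at natural eV scale (negative by construction);
    ``extra_descriptors`` is an optional pass-through map for descriptors
    not used by the shipped models (frontier orbital energies, charges,
    surface-potential statistics and so on).
    """

    abbreviation: str
    name: str
    compound_class: str
    log_kp_exp: float
    log_koa: float
    alpha: float
    vsmin: float
    is_validation: bool = False
    extra_descriptors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise DatasetError("abbreviation must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise DatasetError(
                f"unknown compound class {self.compound_class!r} "
                f"(expected one of {COMPOUND_CLASSES})"
            )
        if not self.alpha > 0:
            raise DatasetError(
                f"{self.abbreviation}: alpha must be positive, got {self.alpha}"
            )
        if not self.vsmin < 0:
            raise DatasetError(
                f"{self.abbreviation}: vsmin must be negative (eV), got {self.vsmin}"
            )

    def descriptor(self, name: str) -> float:
        """Look up a descriptor by name, falling back to ``extra_descriptors``."""
        if name in ("log_koa", "alpha", "vsmin", "log_kp_exp"):
            return float(getattr(self, name))
        if self.extra_descriptors and name in self.extra_descriptors:
            return float(self.extra_descriptors[name])
        raise DatasetError(f"{self.abbreviation}: no descriptor named {name!r}")


@dataclass(frozen=True)
class QsprDataset:
    """Ordered, abbreviation-unique collection of compound records."""

    records: tuple[CompoundRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetError("dataset must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.abbreviation in seen:
                raise DatasetError(f"duplicate abbreviation {rec.abbreviation!r}")
            seen.add(rec.abbreviation)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CompoundRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.abbreviation == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @classmethod
    def from_records(
        cls, records: Iterable[CompoundRecord], provenance: str = ""
    ) -> "QsprDataset":
        return cls(records=tuple(records), provenance=provenance)

    def to_dataframe(self) -> pd.DataFrame:
        """Record table with ``vsmin`` at natural eV scale."""
        return pd.DataFrame(
            {
                "abbreviation": [r.abbreviation for r in self.records],
                "name": [r.name for r in self.records],
                "class": [r.compound_class for r in self.records],
                "log_kp_exp": [r.log_kp_exp for r in self.records],
                "log_koa": [r.log_koa for r in self.records],
                "alpha": [r.alpha for r in self.records],
                "vsmin": [r.vsmin for r in self.records],
                "is_validation": [r.is_validation for r in self.records],
            }
        )

    def descriptor_matrix(self, names: Sequence[str]):
        """Column-stacked descriptor values (list of per-record rows)."""
        return [[rec.descriptor(n) for n in names] for rec in self.records]

    def responses(self, name: str = "log_kp_exp") -> list[float]:
        return [rec.descriptor(name) for rec in self.records]


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for :func:`load_dataset` / :func:`write_dataset`.

    ``vsmin_times_100`` declares that the source stores V_s.min multiplied
    by 100 (the convention of the canonical table); the loader divides by
    100 so records always hold natural eV values.
    """

    abbreviation: str = "abbreviation"
    name: str = "name"
    compound_class: str = "class"
    log_kp_exp: str = "log_kp_exp"
    log_koa: str = "log_koa"
    alpha: str = "alpha"
    vsmin: str = "vsmin_x100"
    is_validation: str = "is_validation"
    vsmin_times_100: bool = True


def _normalize_minus(text: str) -> str:
    for ch in _MINUS_CHARS:
        text = text.replace(ch, "-")
    return text


def load_dataset(
    source: str | Path | io.TextIOBase,
    dialect: CsvDialect | None = None,
    provenance: str = "",
) -> QsprDataset:
    """Read a compound dataset from CSV.

    Parameters
    ----------
    source
        Path or open text stream with a header row.
    dialect
        Column mapping; defaults to the packaged fixture's layout
        (``vsmin_x100`` column at the ×100 scale).

    Raises
    ------
    DatasetError
        On missing columns, empty input, duplicate abbreviations or
        non-numeric cells, with row/column context.
    """
    dialect = dialect or CsvDialect()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    text = _normalize_minus(text)
    try:
        frame = pd.read_csv(io.StringIO(text))
    except pd.errors.EmptyDataError:
        raise DatasetError("no records: input is empty") from None
    if frame.empty:
        raise DatasetError("no records: input has a header but no rows")

    required = {
        "abbreviation": dialect.abbreviation,
        "log_kp_exp": dialect.log_kp_exp,
        "log_koa": dialect.log_koa,
        "alpha": dialect.alpha,
        "vsmin": dialect.vsmin,
    }
    for logical, column in required.items():
        if column not in frame.columns:
            raise DatasetError(f"missing column {column!r} (needed for {logical})")

    records = []
    for idx, row in frame.iterrows():
        def cell(column: str, *, numeric: bool = True, row=row, idx=idx):
            value = row[column]
            if not numeric:
                return str(value)
            try:
                return float(value)
            except (TypeError, ValueError):
                raise DatasetError(
                    f"row {idx + 1}, column {column!r}: non-numeric cell {value!r}"
                ) from None

        vsmin = cell(dialect.vsmin)
        if dialect.vsmin_times_100:
            vsmin /= 100.0
        records.append(
            CompoundRecord(
                abbreviation=cell(dialect.abbreviation, numeric=False),
                name=(
                    cell(dialect.name, numeric=False)
                    if dialect.name in frame.columns
                    else cell(dialect.abbreviation, numeric=False)
                ),
                compound_class=(
                    cell(dialect.compound_class, numeric=False)
                    if dialect.compound_class in frame.columns
                    else "PAH"
                ),
                log_kp_exp=cell(dialect.log_kp_exp),
                log_koa=cell(dialect.log_koa),
                alpha=cell(dialect.alpha),
                vsmin=vsmin,
                is_validation=bool(int(cell(dialect.is_validation)))
                if dialect.is_validation in frame.columns
                else False,
            )
        )
    return QsprDataset.from_records(records, provenance=provenance or str(source))


def write_dataset(
    ds: QsprDataset,
    target: str | Path | io.TextIOBase,
    dialect: CsvDialect | None = None,
) -> None:
    """Write a dataset back to CSV in the given dialect (lossless round trip)."""
    dialect = dialect or CsvDialect()
    frame = ds.to_dataframe()
    out = pd.DataFrame(
        {
            dialect.abbreviation: frame["abbreviation"],
            dialect.name: frame["name"],
            dialect.compound_class: frame["class"],
            dialect.log_kp_exp: frame["log_kp_exp"],
            dialect.log_koa: frame["log_koa"],
            dialect.alpha: frame["alpha"],
            dialect.vsmin: frame["vsmin"] * (100.0 if dialect.vsmin_times_100 else 1.0),
            dialect.is_validation: frame["is_validation"].astype(int),
        }
    )
    out.to_csv(target, index=False)


def load_table1() -> QsprDataset:
    """Load the packaged canonical 50-compound dataset."""
    ref = resources.files("kpqspr.data").joinpath(_FIXTURE_NAME)
    with ref.open("r") as handle:
        return load_dataset(handle, provenance="packaged 50-compound PAH table")


def split_by_flag(ds: QsprDataset) -> tuple[QsprDataset, QsprDataset]:
    """Partition a dataset into (training, validation) by the record flags.

    Order is preserved within each part and the sizes sum to ``len(ds)``.

    Raises
    ------
    DatasetError
        If either part would be empty.
    """
    train = [r for r in ds.records if not r.is_validation]
    valid = [r for r in ds.records if r.is_validation]
    if not train or not valid:
        raise DatasetError(
            "split requires at least one training and one validation record"
        )
    return (
        QsprDataset.from_records(train, provenance=f"{ds.provenance} [training]"),
        QsprDataset.from_records(valid, provenance=f"{ds.provenance} [validation]"),
    )
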