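"""Plain-text readers/writers for ASV tables, taxonomy and sample metadata.

All tables are UTF-8 tab-separated values. Abundance tables carry ASV
identifiers in the first column and one column per sample; taxonomy tables
carry one column per rank; metadata tables carry the replicate-design
coordinates of every sequenced data set.

Sample identifiers are opaque strings: design coordinates (protocol,
prototype, replicate numbers, ...) live only in the metadata table and are
never parsed out of sample names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleRecord",
    "MetadataTable",
    "TaxonomyTable",
    "TableDialect",
    "DesignSpec",
    "DesignSummary",
    "TableFormatError",
    "MetadataError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "summarize_design",
    "MATERIALS",
    "PROTOCOLS",
    "PROTOTYPES",
    "PRIMER_RUNS",
    "PHASES",
]

MATERIALS = ("milk", "water", "mock", "ntc")
PROTOCOLS = ("P1", "P2", "P3", "P4", "P5", "P6")
PROTOTYPES = ("SCC-cfu-", "SCC+cfu-", "SCC+cfu+", "SCC-cfu+")
PRIMER_RUNS = ("V1V2", "V3V4")
PHASES = ("pretrial", "main")

DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


class TableFormatError(ValueError):
    """Raised when a table file violates the expected dialect or invariants."""


class MetadataError(ValueError):
    """Raised when sample metadata violates the study-design invariants."""


@dataclass(frozen=True)
class TableDialect:
    """Descriptor of the on-disk table layout."""

    sep: str = "\t"
    encoding: str = "utf-8"
    index_name: str = "asv_id"


DEFAULT_DIALECT = TableDialect()


# ---------------------------------------------------------------------------
# Abundance table
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """ASV x sample matrix of non-negative integer read counts.

    ``counts`` has shape ``(len(asv_ids), len(sample_ids))``; both identifier
    lists are unique and ordered as on disk.
    """

    asv_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise TableFormatError("counts must be integral")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise TableFormatError("counts must be non-negative")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise TableFormatError("duplicate ASV identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample identifiers")
        self.counts = counts

    # -- basic accessors ----------------------------------------------------

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def sample_totals(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {s: int(t) for s, t in zip(self.sample_ids, sums)}

    def asv_totals(self) -> dict[str, int]:
        sums = self.counts.sum(axis=1)
        return {a: int(t) for a, t in zip(self.asv_ids, sums)}

    # -- subsetting ---------------------------------------------------------

    def select_samples(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return AbundanceTable(
            asv_ids=list(self.asv_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            counts=self.counts[:, idx].copy(),
        )

    def select_asvs(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = set(keep)
        idx = [i for i, a in enumerate(self.asv_ids) if a in keep]
        return AbundanceTable(
            asv_ids=[self.asv_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
        )

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(list(self.asv_ids), list(self.sample_ids), self.counts.copy())

    # -- conversions --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.asv_ids), columns=list(self.sample_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.asv_ids == other.asv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_abundance_table(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> AbundanceTable:
    """Read a TSV abundance table (first column ASV id, one column per sample)."""
    path = Path(path)
    with path.open("r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.sep)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        if len(header) < 1:
            raise TableFormatError(f"{path}: malformed header")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise TableFormatError(f"{path}: duplicate sample column(s) {dupes}")
        asv_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(row)}"
                )
            asv_ids.append(row[0])
            parsed: list[int] = []
            for col, cell in zip(sample_ids, row[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} in column {col!r}"
                    ) from None
                if value < 0:
                    raise TableFormatError(
                        f"{path}:{lineno}: negative count {value} in column {col!r}"
                    )
                parsed.append(value)
            rows.append(parsed)
    if len(set(asv_ids)) != len(asv_ids):
        dupes = sorted({a for a in asv_ids if asv_ids.count(a) > 1})
        raise TableFormatError(f"{path}: duplicate ASV id(s) {dupes}")
    counts = np.asarray(rows, dtype=np.int64).reshape(len(asv_ids), len(sample_ids))
    return AbundanceTable(asv_ids, sample_ids, counts)


def write_abundance_table(
    table: AbundanceTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.sep, lineterminator="\n")
        writer.writerow([dialect.index_name, *table.sample_ids])
        for asv, row in zip(table.asv_ids, table.counts):
            writer.writerow([asv, *(int(v) for v in row)])


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """Design coordinates of one sequenced data set.

    Missing coordinates (e.g. protocol for the MOCK control) are ``None`` and
    serialize as empty strings.
    """

    sample_id: str
    material: str
    primer_run: str
    phase: str
    sequencing_rep: int
    protocol: str | None = None
    prototype: str | None = None
    extraction_rep: int | None = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise MetadataError(f"{self.sample_id}: unknown material {self.material!r}")
        if self.primer_run not in PRIMER_RUNS:
            raise MetadataError(f"{self.sample_id}: unknown primer run {self.primer_run!r}")
        if self.phase not in PHASES:
            raise MetadataError(f"{self.sample_id}: unknown phase {self.phase!r}")
        if self.sequencing_rep < 1:
            raise MetadataError(f"{self.sample_id}: sequencing_rep must be >= 1")
        if self.protocol is not None and self.protocol not in PROTOCOLS:
            raise MetadataError(f"{self.sample_id}: unknown protocol {self.protocol!r}")
        if self.prototype is not None and self.prototype not in PROTOTYPES:
            raise MetadataError(f"{self.sample_id}: unknown prototype {self.prototype!r}")
        if self.material == "milk":
            if self.protocol is None or self.prototype is None or self.extraction_rep is None:
                raise MetadataError(
                    f"{self.sample_id}: milk records require protocol, prototype and extraction_rep"
                )
        elif self.material == "water":
            if self.protocol is None or self.extraction_rep is None:
                raise MetadataError(
                    f"{self.sample_id}: water records require protocol and extraction_rep"
                )
            if self.prototype is not None:
                raise MetadataError(f"{self.sample_id}: water records must not carry a prototype")
        else:  # mock / ntc
            if self.protocol is not None or self.prototype is not None or self.extraction_rep is not None:
                raise MetadataError(
                    f"{self.sample_id}: {self.material} records carry no extraction coordinates"
                )
        if self.extraction_rep is not None and self.extraction_rep < 1:
            raise MetadataError(f"{self.sample_id}: extraction_rep must be >= 1")

    @property
    def design_key(self) -> tuple:
        """Coordinates identifying the data set independently of the primer run."""
        return (
            self.material,
            self.protocol,
            self.prototype,
            self.extraction_rep,
            self.sequencing_rep,
            self.phase,
        )

    @property
    def extract_key(self) -> tuple:
        """Coordinates identifying the physical DNA extract."""
        return (self.material, self.protocol, self.prototype, self.extraction_rep, self.phase)


METADATA_COLUMNS = (
    "sample_id",
    "material",
    "protocol",
    "prototype",
    "extraction_rep",
    "sequencing_rep",
    "primer_run",
    "phase",
)


@dataclass
class MetadataTable:
    """Validated collection of :class:`SampleRecord` with unique sample ids."""

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate sample id(s) {dupes}")
        coords = [(r.design_key, r.primer_run) for r in self.records]
        if len(set(coords)) != len(coords):
            raise MetadataError("duplicate design coordinates (joint-uniqueness violated)")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def sample_ids(
        self,
        material: str | None = None,
        primer_run: str | None = None,
        phase: str | None = None,
        protocol: str | None = None,
    ) -> list[str]:
        out = []
        for r in self.records:
            if material is not None and r.material != material:
                continue
            if primer_run is not None and r.primer_run != primer_run:
                continue
            if phase is not None and r.phase != phase:
                continue
            if protocol is not None and r.protocol != protocol:
                continue
            out.append(r.sample_id)
        return out

    def subset(self, sample_ids: Iterable[str]) -> "MetadataTable":
        keep = set(sample_ids)
        return MetadataTable([r for r in self.records if r.sample_id in keep])


def _parse_opt_str(value: str) -> str | None:
    value = value.strip()
    return value if value else None


def _parse_opt_int(value: str, what: str) -> int | None:
    value = value.strip()
    if not value:
        return None
    try:
        return int(value)
    except ValueError:
        raise MetadataError(f"non-integer {what}: {value!r}") from None


def read_metadata(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> MetadataTable:
    """Read a metadata TSV; column order is free but all columns must exist."""
    path = Path(path)
    with path.open("r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.sep)
        if reader.fieldnames is None:
            raise MetadataError(f"{path}: empty file")
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise MetadataError(f"{path}: missing column(s) {sorted(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                seq_rep = _parse_opt_int(row["sequencing_rep"], "sequencing_rep")
                if seq_rep is None:
                    raise MetadataError("sequencing_rep is required")
                records.append(
                    SampleRecord(
                        sample_id=row["sample_id"].strip(),
                        material=row["material"].strip(),
                        protocol=_parse_opt_str(row["protocol"]),
                        prototype=_parse_opt_str(row["prototype"]),
                        extraction_rep=_parse_opt_int(row["extraction_rep"], "extraction_rep"),
                        sequencing_rep=seq_rep,
                        primer_run=row["primer_run"].strip(),
                        phase=row["phase"].strip(),
                    )
                )
            except MetadataError as exc:
                raise MetadataError(f"{path}:{lineno}: {exc}") from None
    return MetadataTable(records)


def write_metadata(meta: MetadataTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.sep, lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for r in meta.records:
            writer.writerow(
                [
                    r.sample_id,
                    r.material,
                    r.protocol or "",
                    r.prototype or "",
                    "" if r.extraction_rep is None else r.extraction_rep,
                    r.sequencing_rep,
                    r.primer_run,
                    r.phase,
                ]
            )


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """ASV id -> ranked lineage mapping.

    Rank values may be the literal token ``"unclassified"``.
    """

    ranks: tuple[str, ...] = DEFAULT_RANKS
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks = tuple(self.ranks)
        for asv, lineage in self.lineages.items():
            unknown = set(lineage) - set(self.ranks)
            if unknown:
                raise TableFormatError(f"{asv}: unknown rank(s) {sorted(unknown)}")

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def rank_of(self, asv_id: str, rank: str) -> str | None:
        lineage = self.lineages.get(asv_id)
        if lineage is None:
            return None
        return lineage.get(rank)

    def genus_of(self, asv_id: str) -> str | None:
        return self.rank_of(asv_id, "genus")

    def unannotated(self, asv_ids: Iterable[str]) -> list[str]:
        """ASVs referenced by a table but absent from the taxonomy."""
        return [a for a in asv_ids if a not in self.lineages]


def read_taxonomy(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> TaxonomyTable:
    path = Path(path)
    with path.open("r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.sep)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        ranks = tuple(header[1:])
        lineages: dict[str, dict[str, str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TableFormatError(f"{path}:{lineno}: ragged row")
            asv = row[0]
            if asv in lineages:
                raise TableFormatError(f"{path}:{lineno}: duplicate ASV id {asv!r}")
            lineages[asv] = {r: v for r, v in zip(ranks, row[1:])}
    return TaxonomyTable(ranks=ranks, lineages=lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.sep, lineterminator="\n")
        writer.writerow([dialect.index_name, *tax.ranks])
        for asv, lineage in tax.lineages.items():
            writer.writerow([asv, *(lineage.get(r, UNCLASSIFIED) for r in tax.ranks)])


# ---------------------------------------------------------------------------
# Design summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Expected replicate structure of one study phase.

    ``protocols`` maps protocol -> number of extraction replicates. One water
    control accompanies every (protocol, extraction replicate); every extract
    is sequenced ``sequencing_reps`` times.
    """

    protocols: Mapping[str, int]
    n_prototypes: int = 4
    sequencing_reps: int = 1

    @property
    def n_extracts_per_sample(self) -> int:
        return sum(self.protocols.values())

    def expected_milk(self) -> int:
        return self.n_prototypes * self.n_extracts_per_sample * self.sequencing_reps

    def expected_water(self) -> int:
        return self.n_extracts_per_sample * self.sequencing_reps

    def expected_total(self) -> int:
        return self.expected_milk() + self.expected_water()


PRETRIAL_DESIGN = DesignSpec(
    protocols={"P1": 3, "P2": 3, "P3": 3, "P4": 2, "P5": 2, "P6": 3},
    sequencing_reps=1,
)
MAIN_DESIGN = DesignSpec(protocols={"P3": 3, "P4": 2, "P6": 3}, sequencing_reps=3)


@dataclass
class DesignSummary:
    """Counts of data sets per material plus the replicate structure.

    Data sets are counted over design coordinates, i.e. a library sequenced
    with both primer pairs counts once — matching how the study reports
    *n* = 80/96/120.
    """

    phase: str
    n_milk: int
    n_water: int
    n_mock: int
    n_ntc: int
    milk_extracts_per_protocol: dict[str, int]
    sequencing_reps_per_extract: dict[tuple, int]
    deviations: list[str] = field(default_factory=list)

    @property
    def n_extraction_datasets(self) -> int:
        return self.n_milk + self.n_water

    @property
    def n_datasets(self) -> int:
        return self.n_milk + self.n_water + self.n_mock + self.n_ntc


def summarize_design(
    meta: MetadataTable, phase: str, expected: DesignSpec | None = None
) -> DesignSummary:
    """Tally the replicate design of one phase; optionally check it against a spec."""
    if phase not in PHASES:
        raise MetadataError(f"unknown phase {phase!r}")
    records = [r for r in meta.records if r.phase == phase]
    keys = {r.design_key for r in records}
    by_material: dict[str, int] = {m: 0 for m in MATERIALS}
    for key in keys:
        by_material[key[0]] += 1
    milk_extracts: dict[str, set] = {}
    seq_reps: dict[tuple, set] = {}
    for key in keys:
        material, protocol, prototype, ext_rep, seq_rep, _ = key
        if material == "milk":
            milk_extracts.setdefault(protocol, set()).add((prototype, ext_rep))
        if material in ("milk", "water"):
            extract = (material, protocol, prototype, ext_rep)
            seq_reps.setdefault(extract, set()).add(seq_rep)
    summary = DesignSummary(
        phase=phase,
        n_milk=by_material["milk"],
        n_water=by_material["water"],
        n_mock=by_material["mock"],
        n_ntc=by_material["ntc"],
        milk_extracts_per_protocol={p: len(v) for p, v in sorted(milk_extracts.items())},
        sequencing_reps_per_extract={k: len(v) for k, v in sorted(seq_reps.items())},
    )
    if expected is not None:
        if summary.n_milk != expected.expected_milk():
            summary.deviations.append(
                f"milk data sets: found {summary.n_milk}, expected {expected.expected_milk()}"
            )
        if summary.n_water != expected.expected_water():
            summary.deviations.append(
                f"water data sets: found {summary.n_water}, expected {expected.expected_water()}"
            )
        for protocol, n_reps in expected.protocols.items():
            found = summary.milk_extracts_per_protocol.get(protocol, 0)
            want = n_reps * expected.n_prototypes
            if found != want:
                summary.deviations.append(
                    f"{protocol}: found {found} milk extracts, expected {want}"
                )
    return summary
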