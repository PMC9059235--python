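"""Blank-based ASV-table curation rules and TSS normalization.

The rules are deterministic set definitions:

* removal of ASVs present only in water extraction controls,
* removal of single hits (ASVs occupied in exactly one sample),
* removal of samples with fewer than ``tau_depth`` clean reads,
* removal of ASVs below ``tau_rel`` percent pooled relative abundance,
* flagging (not removal) of ASVs recurring across blanks, and
* flagging of taxa implausible for the sample matrix (index-swap candidates).

``run_curation`` chains them in a fixed order and emits a disposition ledger
covering every input ASV and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, MetadataTable, TaxonomyTable, PRIMER_RUNS

__all__ = [
    "CurationParams",
    "CurationReport",
    "CurationError",
    "clean_read_totals",
    "apply_depth_filter",
    "apply_rare_taxon_filter",
    "remove_water_only_asvs",
    "flag_recurrent_water_asvs",
    "remove_single_hit_asvs",
    "flag_foreign_asvs",
    "tss_normalize",
    "run_curation",
]

KEPT = "kept"
REMOVED_WATER_ONLY = "removed:water_only"
REMOVED_SINGLE_HIT = "removed:single_hit"
REMOVED_RARE = "removed:rare"
REMOVED_FLAGGED = "removed:flagged"
FLAG_RECURRENT_WATER = "flagged:recurrent_water"
FLAG_FOREIGN = "flagged:foreign"
SAMPLE_KEPT = "kept"
SAMPLE_REMOVED_LOW_DEPTH = "removed:low_depth"


class CurationError(ValueError):
    """Raised when a curation stage cannot be applied."""


@dataclass(frozen=True)
class CurationParams:
    """Thresholds of the curation and protocol-selection rules.

    All "less than"/"more than" comparisons are strict. ``tau_rel`` is a
    percentage of the pooled read total.
    """

    tau_depth: int = 500
    tau_rel: float = 0.01
    tau_flag_count: int = 100
    tau_flag_reps: int = 2
    tau_median: float = 1000.0
    foreign_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tau_depth < 0 or self.tau_flag_count < 0 or self.tau_flag_reps < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.tau_rel <= 100.0:
            raise ValueError("tau_rel must be a percentage in [0, 100]")
        if self.tau_median < 0:
            raise ValueError("tau_median must be >= 0")
        object.__setattr__(self, "foreign_taxa", tuple(self.foreign_taxa))


@dataclass
class CurationReport:
    """Disposition ledger of one curation run.

    ``asv_disposition`` and ``sample_disposition`` assign exactly one removal
    disposition to every input ASV/sample; ``asv_flags`` may add flags to kept
    ASVs. ``flagged_read_fraction`` is the percentage of milk reads carried by
    foreign-flagged ASVs, per primer run.
    """

    asv_disposition: dict[str, str] = field(default_factory=dict)
    sample_disposition: dict[str, str] = field(default_factory=dict)
    asv_flags: dict[str, list[str]] = field(default_factory=dict)
    flagged_read_fraction: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def kept_asvs(self) -> list[str]:
        return [a for a, d in self.asv_disposition.items() if d == KEPT]

    def removed_asvs(self, disposition: str | None = None) -> list[str]:
        return [
            a
            for a, d in self.asv_disposition.items()
            if d != KEPT and (disposition is None or d == disposition)
        ]

    def summary(self) -> dict:
        asv_counts: dict[str, int] = {}
        for d in self.asv_disposition.values():
            asv_counts[d] = asv_counts.get(d, 0) + 1
        sample_counts: dict[str, int] = {}
        for d in self.sample_disposition.values():
            sample_counts[d] = sample_counts.get(d, 0) + 1
        flag_counts: dict[str, int] = {}
        for flags in self.asv_flags.values():
            for f in flags:
                flag_counts[f] = flag_counts.get(f, 0) + 1
        return {
            "asv_dispositions": asv_counts,
            "sample_dispositions": sample_counts,
            "flags": flag_counts,
            "flagged_read_fraction": dict(self.flagged_read_fraction),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for asv, disp in self.asv_disposition.items():
            rows.append(
                {
                    "id": asv,
                    "kind": "asv",
                    "disposition": disp,
                    "flags": ";".join(self.asv_flags.get(asv, [])),
                }
            )
        for sample, disp in self.sample_disposition.items():
            rows.append({"id": sample, "kind": "sample", "disposition": disp, "flags": ""})
        return pd.DataFrame(rows, columns=["id", "kind", "disposition", "flags"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------


def clean_read_totals(table: AbundanceTable) -> dict[str, int]:
    """Per-sample clean reads = column sum of the ASV table."""
    return table.sample_totals()


def apply_depth_filter(
    table: AbundanceTable, meta: MetadataTable | None, params: CurationParams
) -> tuple[AbundanceTable, dict[str, str]]:
    """Remove samples with fewer than ``tau_depth`` clean reads (strict <)."""
    totals = table.sample_totals()
    dispositions = {
        s: (SAMPLE_REMOVED_LOW_DEPTH if totals[s] < params.tau_depth else SAMPLE_KEPT)
        for s in table.sample_ids
    }
    keep = [s for s, d in dispositions.items() if d == SAMPLE_KEPT]
    return table.select_samples(keep), dispositions


def apply_rare_taxon_filter(
    table: AbundanceTable, params: CurationParams
) -> tuple[AbundanceTable, dict[str, str]]:
    """Remove ASVs below ``tau_rel`` percent pooled relative abundance (strict <)."""
    grand_total = int(table.counts.sum())
    if grand_total == 0:
        raise CurationError("cannot apply relative-abundance filter: grand total is 0")
    pooled_pct = table.counts.sum(axis=1) * (100.0 / grand_total)
    dispositions = {
        a: (REMOVED_RARE if pct < params.tau_rel else KEPT)
        for a, pct in zip(table.asv_ids, pooled_pct)
    }
    keep = [a for a, d in dispositions.items() if d == KEPT]
    return table.select_asvs(keep), dispositions


def remove_water_only_asvs(
    table: AbundanceTable, meta: MetadataTable
) -> tuple[AbundanceTable, dict[str, str]]:
    """Remove ASVs seen in water extraction controls but in no milk sample.

    Milk clean-read totals are untouched by construction (removed ASVs carry
    zero milk reads).
    """
    milk_idx = [i for i, s in enumerate(table.sample_ids) if s in meta and meta[s].material == "milk"]
    water_idx = [i for i, s in enumerate(table.sample_ids) if s in meta and meta[s].material == "water"]
    if not water_idx:
        return table.copy(), {a: KEPT for a in table.asv_ids}
    milk_tot = (
        table.counts[:, milk_idx].sum(axis=1) if milk_idx else np.zeros(table.n_asvs, dtype=np.int64)
    )
    water_tot = table.counts[:, water_idx].sum(axis=1)
    dispositions = {
        a: (REMOVED_WATER_ONLY if (m == 0 and w > 0) else KEPT)
        for a, m, w in zip(table.asv_ids, milk_tot, water_tot)
    }
    keep = [a for a, d in dispositions.items() if d == KEPT]
    return table.select_asvs(keep), dispositions


def flag_recurrent_water_asvs(
    table: AbundanceTable, meta: MetadataTable, params: CurationParams
) -> set[str]:
    """Flag ASVs occupied in more than ``tau_flag_reps`` water replicates with
    at least one water count above ``tau_flag_count``. Flagged ASVs stay in."""
    water_idx = [i for i, s in enumerate(table.sample_ids) if s in meta and meta[s].material == "water"]
    if not water_idx:
        return set()
    water = table.counts[:, water_idx]
    n_occupied = (water > 0).sum(axis=1)
    max_count = water.max(axis=1) if water.size else np.zeros(table.n_asvs, dtype=np.int64)
    flagged = (n_occupied > params.tau_flag_reps) & (max_count > params.tau_flag_count)
    return {a for a, f in zip(table.asv_ids, flagged) if f}


def remove_single_hit_asvs(table: AbundanceTable) -> tuple[AbundanceTable, dict[str, str]]:
    """Remove ASVs non-zero in exactly one sample column, regardless of count."""
    occupancy = (table.counts > 0).sum(axis=1)
    dispositions = {
        a: (REMOVED_SINGLE_HIT if occ == 1 else KEPT)
        for a, occ in zip(table.asv_ids, occupancy)
    }
    keep = [a for a, d in dispositions.items() if d == KEPT]
    return table.select_asvs(keep), dispositions


def flag_foreign_asvs(
    table: AbundanceTable,
    taxonomy: TaxonomyTable | None,
    params: CurationParams,
    meta: MetadataTable | None = None,
) -> tuple[set[str], dict[str, float]]:
    """Flag ASVs whose genus is implausible for the sample matrix.

    Returns the flag set and, when metadata is supplied, the percentage of
    milk reads carried by flagged ASVs per primer run. ASVs without taxonomy
    are treated as not flagged.
    """
    foreign = {g.lower() for g in params.foreign_taxa}
    flagged: set[str] = set()
    if foreign and taxonomy is not None:
        for asv in table.asv_ids:
            genus = taxonomy.genus_of(asv)
            if genus is not None and genus.lower() in foreign:
                flagged.add(asv)
    fractions: dict[str, float] = {}
    if meta is not None:
        flag_mask = np.array([a in flagged for a in table.asv_ids], dtype=bool)
        for run in PRIMER_RUNS:
            idx = [
                i
                for i, s in enumerate(table.sample_ids)
                if s in meta and meta[s].material == "milk" and meta[s].primer_run == run
            ]
            if not idx:
                continue
            total = int(table.counts[:, idx].sum())
            if total == 0:
                fractions[run] = 0.0
            else:
                fractions[run] = 100.0 * float(table.counts[np.ix_(flag_mask, idx)].sum()) / total
    return flagged, fractions


def tss_normalize(table: AbundanceTable) -> pd.DataFrame:
    """Total-sum-scale each sample column to proportions (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise CurationError(f"zero-total sample(s) {zero}; apply the depth filter first")
    props = table.counts / totals.astype(np.float64)
    return pd.DataFrame(props, index=list(table.asv_ids), columns=list(table.sample_ids))


# ---------------------------------------------------------------------------
# Composite pipeline
# ---------------------------------------------------------------------------


def run_curation(
    table: AbundanceTable,
    meta: MetadataTable,
    taxonomy: TaxonomyTable | None = None,
    params: CurationParams | None = None,
    drop_flagged: bool = False,
) -> tuple[AbundanceTable, CurationReport]:
    """Apply all curation rules in fixed order and emit a full ledger.

    Order: water-only removal -> single-hit removal -> sample depth filter ->
    rare-taxon filter -> recurrent-water flagging -> foreign-taxon flagging.
    Recurrent-water flags are evaluated before the depth filter (blank columns
    are typically shallow and would otherwise vanish). Flags never remove
    unless ``drop_flagged`` is set.
    """
    report = CurationReport()
    params = params or CurationParams()

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # re-raise with the stage name attached
            raise CurationError(f"stage {name!r}: {exc}") from exc

    current, disp = _stage("remove_water_only", remove_water_only_asvs, table, meta)
    for a, d in disp.items():
        if d != KEPT:
            report.asv_disposition[a] = d

    current, disp = _stage("remove_single_hit", remove_single_hit_asvs, current)
    for a, d in disp.items():
        if d != KEPT:
            report.asv_disposition[a] = d

    # Flags from blanks are computed before shallow water columns are dropped.
    recurrent = _stage("flag_recurrent_water", flag_recurrent_water_asvs, current, meta, params)

    current, sample_disp = _stage("apply_depth_filter", apply_depth_filter, current, meta, params)
    report.sample_disposition.update(sample_disp)

    current, disp = _stage("apply_rare_taxon_filter", apply_rare_taxon_filter, current, params)
    for a, d in disp.items():
        if d != KEPT:
            report.asv_disposition[a] = d

    foreign, fractions = _stage(
        "flag_foreign", flag_foreign_asvs, current, taxonomy, params, meta
    )
    report.flagged_read_fraction = fractions

    for a in current.asv_ids:
        flags = []
        if a in recurrent:
            flags.append(FLAG_RECURRENT_WATER)
        if a in foreign:
            flags.append(FLAG_FOREIGN)
        if flags:
            report.asv_flags[a] = flags

    if drop_flagged and report.asv_flags:
        dropped = set(report.asv_flags)
        current = current.select_asvs([a for a in current.asv_ids if a not in dropped])
        for a in dropped:
            report.asv_disposition[a] = REMOVED_FLAGGED

    for a in table.asv_ids:
        report.asv_disposition.setdefault(a, KEPT)
    for s in table.sample_ids:
        report.sample_disposition.setdefault(s, SAMPLE_KEPT)

    if not current.sample_ids:
        report.notes.append("all samples removed by curation")
    if not current.asv_ids:
        report.notes.append("all ASVs removed by curation")
    return current, report
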