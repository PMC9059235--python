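"""Synthetic study generator.

Reproduces the nested replicate design of the milk-protocol evaluation —
4 prototype milk samples in a 2x2 SCC/cfu layout, per-protocol extraction
replicates each accompanied by a water control, optional re-sequencing
replicates, MOCK and NTC controls, two primer runs — together with
kit-specific blank contaminants and index-swapped reads from a labeled
"foreign" pool, and returns the planted ground truth alongside the tables.

Generative model per milk data set:

* base composition per prototype ~ Dirichlet(base_alpha),
* fixed per-ASV multiplicative protocol bias exp(N(0, protocol_bias_sigma^2)),
* per-extract perturbation exp(N(0, sigma_ext^2)) of both the composition
  (per ASV) and the expected sequencing depth (scalar),
* per sequencing replicate a log-normal depth draw, a Binomial(depth,
  epsilon) count of index-swapped reads from the foreign profile, and a
  multinomial draw of the remaining reads from the extract composition.

Clean reads (column totals) therefore equal the planted depth exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    DesignSpec,
    MAIN_DESIGN,
    MetadataTable,
    PRETRIAL_DESIGN,
    PRIMER_RUNS,
    PROTOCOLS,
    PROTOTYPES,
    SampleRecord,
    TaxonomyTable,
    DEFAULT_RANKS,
    UNCLASSIFIED,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "DatasetProvenance",
    "SequencedReads",
    "simulate_study",
    "sequence_extract",
    "mock_profile",
    "substream",
]

# 16S-visible members of the vendor mock community (the two yeasts are
# excluded); proportions are equal by convention.
MOCK_GENERA = (
    "Bacillus",
    "Enterococcus",
    "Escherichia",
    "Lactobacillus",
    "Listeria",
    "Pseudomonas",
    "Salmonella",
    "Staphylococcus",
)

MILK_GENERA = (
    "Staphylococcus",
    "Streptococcus",
    "Corynebacterium",
    "Lactobacillus",
    "Bacillus",
    "Bacteroides",
    "Aerococcus",
    "Jeotgalicoccus",
    "Brevibacterium",
    "Sphingomonas",
)

FOREIGN_GENERA = (
    "Aquabacterium",
    "Pelomonas",
    "Acidocella",
    "Cutibacterium",
    "Alcanivorax",
)

CONTAMINANT_GENERA = (
    "Bradyrhizobium",
    "Ralstonia",
    "Caulobacter",
    "Methylobacterium",
    "Herbaspirillum",
)


def substream(seed: int, *labels) -> np.random.Generator:
    """Deterministic named random substream derived from one top-level seed."""
    entropy = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def mock_profile() -> dict[str, float]:
    """Equal-proportion composition over the 8 bacterial mock genera."""
    return {g: 1.0 / len(MOCK_GENERA) for g in MOCK_GENERA}


DEFAULT_DEPTH_MEDIAN = {
    "P1": 900.0,
    "P2": 450.0,
    "P3": 1700.0,
    "P4": 1100.0,
    "P5": 280.0,
    "P6": 6000.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters plus the replicate design and the seed."""

    phase: str = "pretrial"
    design: Mapping[str, int] | None = None  # protocol -> extraction replicates
    sequencing_reps: int | None = None
    primer_runs: tuple[str, ...] = PRIMER_RUNS
    n_asvs: int = 60
    base_alpha: float = 0.8
    protocol_bias_sigma: float = 0.4
    sigma_ext: float = 0.15
    depth_median: Mapping[str, float] | None = None  # V1V2 scale, per protocol
    depth_sigma: float = 0.5
    run_depth_factor: Mapping[str, float] | None = None
    epsilon: float = 0.015
    n_foreign: int = 12
    contaminants_per_protocol: int = 3
    contaminant_mean_counts: tuple[float, ...] = (40.0, 15.0, 5.0)
    n_singletons: int = 0
    singleton_count: int = 2
    include_controls: bool = True
    mock_depth: int = 25000
    ntc_mean: float = 3.0
    unclassified_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("pretrial", "main"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        for name in ("protocol_bias_sigma", "sigma_ext", "depth_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.base_alpha <= 0:
            raise ValueError("base_alpha must be > 0")
        unknown = set(self.resolved_design()) - set(PROTOCOLS)
        if unknown:
            raise ValueError(f"design references unknown protocol(s) {sorted(unknown)}")

    def resolved_design(self) -> dict[str, int]:
        if self.design is not None:
            return dict(self.design)
        return dict((PRETRIAL_DESIGN if self.phase == "pretrial" else MAIN_DESIGN).protocols)

    def resolved_sequencing_reps(self) -> int:
        if self.sequencing_reps is not None:
            return int(self.sequencing_reps)
        return (PRETRIAL_DESIGN if self.phase == "pretrial" else MAIN_DESIGN).sequencing_reps

    def resolved_depth_median(self) -> dict[str, float]:
        base = dict(DEFAULT_DEPTH_MEDIAN)
        if self.depth_median is not None:
            base.update(self.depth_median)
        return base

    def resolved_run_factor(self) -> dict[str, float]:
        base = {"V1V2": 1.0, "V3V4": 2.0}
        if self.run_depth_factor is not None:
            base.update(self.run_depth_factor)
        return base

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            protocols=self.resolved_design(),
            sequencing_reps=self.resolved_sequencing_reps(),
        )


class SequencedReads(NamedTuple):
    """One multinomial sequencing draw with index-swap bookkeeping."""

    milk: np.ndarray
    foreign: np.ndarray
    swapped: int


@dataclass(frozen=True)
class DatasetProvenance:
    """Planted per-data-set read bookkeeping."""

    depth: int
    swapped: int
    contaminant: int


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-ASV labels, per-data-set provenance and the
    generating configuration."""

    asv_labels: dict[str, str]
    provenance: dict[str, DatasetProvenance]
    config: SimulationConfig

    def asvs_with_label(self, prefix: str) -> set[str]:
        return {a for a, lab in self.asv_labels.items() if lab.startswith(prefix)}

    @property
    def foreign_asvs(self) -> set[str]:
        return self.asvs_with_label("foreign")

    @property
    def contaminant_asvs(self) -> set[str]:
        return self.asvs_with_label("contaminant")

    @property
    def singleton_asvs(self) -> set[str]:
        return self.asvs_with_label("singleton")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": a, "kind": "asv", "label": lab, "depth": "", "swapped": "", "contaminant": ""}
            for a, lab in self.asv_labels.items()
        ]
        rows += [
            {
                "id": s,
                "kind": "dataset",
                "label": "",
                "depth": p.depth,
                "swapped": p.swapped,
                "contaminant": p.contaminant,
            }
            for s, p in self.provenance.items()
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sequence_extract(
    composition: Sequence[float] | np.ndarray,
    depth: int,
    epsilon: float,
    foreign_profile: Sequence[float] | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> SequencedReads:
    """Draw one sequencing data set of ``depth`` reads.

    ``Binomial(depth, epsilon)`` reads are replaced by draws from
    ``foreign_profile`` (index swapping); the rest are multinomial draws from
    ``composition``. The swapped-read count is recorded exactly.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    comp = np.asarray(composition, dtype=np.float64)
    fp = np.asarray(foreign_profile, dtype=np.float64)
    if comp.size and not np.isclose(comp.sum(), 1.0, atol=1e-8):
        raise ValueError("composition must be normalized")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swapped = int(rng.binomial(depth, epsilon)) if depth else 0
    milk = rng.multinomial(depth - swapped, comp) if comp.size else np.zeros(0, dtype=np.int64)
    foreign = rng.multinomial(swapped, fp) if fp.size else np.zeros(0, dtype=np.int64)
    if not fp.size and swapped:
        raise ValueError("swapped reads requested but foreign profile is empty")
    return SequencedReads(milk=milk.astype(np.int64), foreign=foreign.astype(np.int64), swapped=swapped)


def _assign_genera(
    asv_ids: Sequence[str], pool: Sequence[str], rng: np.random.Generator, unclassified_fraction: float
) -> dict[str, str]:
    out = {}
    for i, asv in enumerate(asv_ids):
        if rng.random() < unclassified_fraction:
            out[asv] = UNCLASSIFIED
        else:
            out[asv] = pool[i % len(pool)]
    return out


def simulate_study(
    config: SimulationConfig,
) -> tuple[AbundanceTable, MetadataTable, TaxonomyTable, SyntheticTruth]:
    """Generate the full study: abundance table, metadata, taxonomy, truth."""
    seed = config.seed
    design = config.resolved_design()
    seq_reps = config.resolved_sequencing_reps()
    depth_median = config.resolved_depth_median()
    run_factor = config.resolved_run_factor()
    missing = set(design) - set(depth_median)
    if missing:
        raise ValueError(f"no depth median for protocol(s) {sorted(missing)}")

    g = config.n_asvs
    milk_asvs = [f"ASV_M{i + 1:03d}" for i in range(g)]
    foreign_asvs = [f"ASV_F{i + 1:02d}" for i in range(config.n_foreign)]
    contaminant_asvs: dict[str, list[str]] = {
        p: [f"ASV_C_{p}_{i + 1}" for i in range(config.contaminants_per_protocol)]
        for p in sorted(design)
    }
    mock_asvs = [f"ASV_K{i + 1}" for i in range(len(MOCK_GENERA))] if config.include_controls else []
    singleton_asvs = [f"ASV_S{i + 1:02d}" for i in range(config.n_singletons)]

    all_asvs = (
        milk_asvs
        + singleton_asvs
        + foreign_asvs
        + [a for p in sorted(contaminant_asvs) for a in contaminant_asvs[p]]
        + mock_asvs
    )
    asv_index = {a: i for i, a in enumerate(all_asvs)}

    labels: dict[str, str] = {a: "milk" for a in milk_asvs}
    labels.update({a: "singleton" for a in singleton_asvs})
    labels.update({a: "foreign" for a in foreign_asvs})
    for p, asvs in contaminant_asvs.items():
        labels.update({a: f"contaminant:{p}" for a in asvs})
    labels.update({a: "mock" for a in mock_asvs})

    # --- latent compositions -------------------------------------------------
    base_comp = {
        proto: substream(seed, "base", proto).dirichlet(np.full(g, config.base_alpha))
        for proto in PROTOTYPES
    }
    bias = {
        p: np.exp(substream(seed, "bias", p).normal(0.0, config.protocol_bias_sigma, size=g))
        for p in design
    }
    if config.n_foreign:
        foreign_profile = substream(seed, "foreign").dirichlet(np.ones(config.n_foreign))
    else:
        foreign_profile = np.zeros(0)

    contaminant_means = {
        p: np.array(
            [
                config.contaminant_mean_counts[i % len(config.contaminant_mean_counts)]
                for i in range(config.contaminants_per_protocol)
            ]
        )
        for p in design
    }

    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    provenance: dict[str, DatasetProvenance] = {}

    def add_column(sample_id: str, record: SampleRecord, col: np.ndarray, prov: DatasetProvenance):
        columns[sample_id] = col
        records.append(record)
        provenance[sample_id] = prov

    phase_tag = "pre" if config.phase == "pretrial" else "main"

    for protocol in sorted(design):
        n_ext = design[protocol]
        for si, prototype in enumerate(PROTOTYPES, start=1):
            for erep in range(1, n_ext + 1):
                ext_rng = substream(seed, "extract", prototype, protocol, erep)
                comp = base_comp[prototype] * bias[protocol]
                comp = comp * np.exp(ext_rng.normal(0.0, config.sigma_ext, size=g))
                comp = comp / comp.sum()
                depth_effect = float(ext_rng.normal(0.0, config.sigma_ext))
                for run in config.primer_runs:
                    mu = np.log(depth_median[protocol] * run_factor.get(run, 1.0)) + depth_effect
                    for srep in range(1, seq_reps + 1):
                        rng = substream(seed, "seq", prototype, protocol, erep, run, srep)
                        depth = max(1, int(round(rng.lognormal(mu, config.depth_sigma))))
                        reads = sequence_extract(comp, depth, config.epsilon, foreign_profile, rng)
                        col = np.zeros(len(all_asvs), dtype=np.int64)
                        col[[asv_index[a] for a in milk_asvs]] = reads.milk
                        if config.n_foreign:
                            col[[asv_index[a] for a in foreign_asvs]] = reads.foreign
                        sample_id = f"{phase_tag}-{run}-{protocol}-S{si}-E{erep}-R{srep}"
                        add_column(
                            sample_id,
                            SampleRecord(
                                sample_id=sample_id,
                                material="milk",
                                protocol=protocol,
                                prototype=prototype,
                                extraction_rep=erep,
                                sequencing_rep=srep,
                                primer_run=run,
                                phase=config.phase,
                            ),
                            col,
                            DatasetProvenance(depth=depth, swapped=reads.swapped, contaminant=0),
                        )

        # water extraction control per (protocol, extraction replicate)
        for erep in range(1, n_ext + 1):
            for run in config.primer_runs:
                for srep in range(1, seq_reps + 1):
                    rng = substream(seed, "water", protocol, erep, run, srep)
                    cont = rng.poisson(contaminant_means[protocol]).astype(np.int64)
                    total_c = int(cont.sum())
                    swapped = int(rng.binomial(total_c, config.epsilon)) if total_c else 0
                    foreign = (
                        rng.multinomial(swapped, foreign_profile).astype(np.int64)
                        if config.n_foreign
                        else np.zeros(0, dtype=np.int64)
                    )
                    col = np.zeros(len(all_asvs), dtype=np.int64)
                    col[[asv_index[a] for a in contaminant_asvs[protocol]]] = cont
                    if config.n_foreign:
                        col[[asv_index[a] for a in foreign_asvs]] = foreign
                    sample_id = f"{phase_tag}-{run}-{protocol}-W-E{erep}-R{srep}"
                    add_column(
                        sample_id,
                        SampleRecord(
                            sample_id=sample_id,
                            material="water",
                            protocol=protocol,
                            extraction_rep=erep,
                            sequencing_rep=srep,
                            primer_run=run,
                            phase=config.phase,
                        ),
                        col,
                        DatasetProvenance(
                            depth=int(col.sum()), swapped=swapped, contaminant=total_c
                        ),
                    )

    if config.include_controls:
        mock_comp = np.full(len(mock_asvs), 1.0 / len(mock_asvs))
        for run in config.primer_runs:
            for srep in range(1, seq_reps + 1):
                rng = substream(seed, "mock", run, srep)
                col = np.zeros(len(all_asvs), dtype=np.int64)
                col[[asv_index[a] for a in mock_asvs]] = rng.multinomial(
                    config.mock_depth, mock_comp
                )
                sample_id = f"{phase_tag}-{run}-MOCK-R{srep}"
                add_column(
                    sample_id,
                    SampleRecord(
                        sample_id=sample_id,
                        material="mock",
                        sequencing_rep=srep,
                        primer_run=run,
                        phase=config.phase,
                    ),
                    col,
                    DatasetProvenance(depth=int(col.sum()), swapped=0, contaminant=0),
                )
                rng = substream(seed, "ntc", run, srep)
                total = int(rng.poisson(config.ntc_mean))
                col = np.zeros(len(all_asvs), dtype=np.int64)
                if total and config.n_foreign:
                    col[[asv_index[a] for a in foreign_asvs]] = rng.multinomial(
                        total, foreign_profile
                    )
                sample_id = f"{phase_tag}-{run}-NTC-R{srep}"
                add_column(
                    sample_id,
                    SampleRecord(
                        sample_id=sample_id,
                        material="ntc",
                        sequencing_rep=srep,
                        primer_run=run,
                        phase=config.phase,
                    ),
                    col,
                    DatasetProvenance(depth=total, swapped=total, contaminant=0),
                )

    sample_ids = [r.sample_id for r in records]
    counts = np.column_stack([columns[s] for s in sample_ids]) if sample_ids else np.zeros((len(all_asvs), 0), dtype=np.int64)

    # planted single hits: one occupied milk column each, tiny count
    if singleton_asvs:
        rng = substream(seed, "singleton")
        milk_cols = [i for i, r in enumerate(records) if r.material == "milk"]
        for asv in singleton_asvs:
            j = int(rng.choice(milk_cols))
            counts[asv_index[asv], j] = config.singleton_count
            prev = provenance[sample_ids[j]]
            provenance[sample_ids[j]] = DatasetProvenance(
                depth=prev.depth + config.singleton_count,
                swapped=prev.swapped,
                contaminant=prev.contaminant,
            )

    table = AbundanceTable(asv_ids=list(all_asvs), sample_ids=sample_ids, counts=counts)
    meta = MetadataTable(records)

    # --- taxonomy -----------------------------------------------------------
    tax_rng = substream(seed, "taxonomy")
    genera: dict[str, str] = {}
    genera.update(_assign_genera(milk_asvs, MILK_GENERA, tax_rng, config.unclassified_fraction))
    genera.update(_assign_genera(singleton_asvs, MILK_GENERA, tax_rng, config.unclassified_fraction))
    genera.update(_assign_genera(foreign_asvs, FOREIGN_GENERA, tax_rng, 0.0))
    for p in sorted(contaminant_asvs):
        genera.update(_assign_genera(contaminant_asvs[p], CONTAMINANT_GENERA, tax_rng, 0.0))
    genera.update({a: g_ for a, g_ in zip(mock_asvs, MOCK_GENERA)})
    lineages = {
        a: {
            "domain": "Bacteria",
            "phylum": UNCLASSIFIED,
            "class": UNCLASSIFIED,
            "order": UNCLASSIFIED,
            "family": UNCLASSIFIED,
            "genus": genera[a],
        }
        for a in all_asvs
    }
    taxonomy = TaxonomyTable(ranks=DEFAULT_RANKS, lineages=lineages)

    truth = SyntheticTruth(asv_labels=labels, provenance=provenance, config=config)
    return table, meta, taxonomy, truth
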