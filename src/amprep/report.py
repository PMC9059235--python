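"""Pipeline orchestration and human-readable reporting.

``run_pipeline`` chains simulation/loading -> curation -> protocol selection
-> clean-read variability -> alpha diversity -> beta diversity -> top-taxa
summary and writes every intermediate as a TSV next to a run log, so every
reported number is traceable to an exported table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import curation as cur
from . import diversity as div
from . import reproducibility as rep
from .io import (
    AbundanceTable,
    MetadataTable,
    TaxonomyTable,
    UNCLASSIFIED,
    read_abundance_table,
    read_metadata,
    read_taxonomy,
    summarize_design,
    write_abundance_table,
    write_metadata,
    write_taxonomy,
)
from .simulate import SimulationConfig, simulate_study, substream

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_top_taxa", "load_run_config"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One reproducible pipeline run: either three input paths or a simulate
    block, plus all thresholds, the rarefaction spec and one top-level seed."""

    outdir: str | Path = "amprep_out"
    table_path: str | Path | None = None
    metadata_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    simulate: SimulationConfig | None = None
    params: cur.CurationParams = field(default_factory=cur.CurationParams)
    rarefaction: div.RarefactionSpec = field(default_factory=div.RarefactionSpec)
    drop_flagged: bool = False
    top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.table_path is not None and self.metadata_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of {input paths, simulate block} must be given")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a nested YAML document."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    sim = None
    if "simulate" in doc:
        sim_doc = dict(doc["simulate"] or {})
        if "seed" not in sim_doc:
            sim_doc["seed"] = int(doc.get("seed", 0))
        allowed = {f.name for f in dc_fields(SimulationConfig)}
        unknown = set(sim_doc) - allowed
        if unknown:
            raise ValueError(f"unknown simulate key(s) {sorted(unknown)}")
        if "contaminant_mean_counts" in sim_doc:
            sim_doc["contaminant_mean_counts"] = tuple(sim_doc["contaminant_mean_counts"])
        if "primer_runs" in sim_doc:
            sim_doc["primer_runs"] = tuple(sim_doc["primer_runs"])
        sim = SimulationConfig(**sim_doc)
    params_doc = dict(doc.get("curation", {}) or {})
    if "foreign_taxa" in params_doc:
        params_doc["foreign_taxa"] = tuple(params_doc["foreign_taxa"])
    params = cur.CurationParams(**params_doc)
    rar_doc = dict(doc.get("rarefaction", {}) or {})
    if "explicit_depths" in rar_doc:
        rar_doc["explicit_depths"] = {
            (k.split("/")[0], k.split("/")[1]): int(v)
            for k, v in rar_doc["explicit_depths"].items()
        }
    rarefaction = div.RarefactionSpec(**rar_doc)
    inputs = doc.get("inputs", {}) or {}
    return RunConfig(
        outdir=doc.get("outdir", "amprep_out"),
        table_path=inputs.get("table"),
        metadata_path=inputs.get("metadata"),
        taxonomy_path=inputs.get("taxonomy"),
        simulate=sim,
        params=params,
        rarefaction=rarefaction,
        drop_flagged=bool(doc.get("drop_flagged", False)),
        top_n=int(doc.get("top_n", 20)),
        seed=int(doc.get("seed", 0)),
    )


def summarize_top_taxa(
    normalized: pd.DataFrame,
    taxonomy: TaxonomyTable | None,
    groups: Mapping[str, object],
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-group mean relative abundance of the ``top_n`` genera plus a
    "remaining/unknown" remainder row (columns sum to 1 per group).

    Genera are ranked by their mean relative abundance over all grouped
    samples; ASVs without a genus annotation (or annotated "unclassified")
    are pooled into the remainder.
    """
    samples = [s for s in normalized.columns if s in groups]
    if not samples:
        raise PipelineError("no samples covered by the grouping")
    sub = normalized[samples]

    def genus_for(asv: str) -> str | None:
        if taxonomy is None:
            return None
        genus = taxonomy.genus_of(asv)
        if genus is None or genus == UNCLASSIFIED:
            return None
        return genus

    genus_of = {a: genus_for(a) for a in sub.index}
    named = sub.loc[[a for a in sub.index if genus_of[a] is not None]]
    by_genus = named.groupby([genus_of[a] for a in named.index]).sum() if len(named) else pd.DataFrame(columns=samples)
    overall = by_genus.mean(axis=1).sort_values(ascending=False, kind="mergesort") if len(by_genus) else pd.Series(dtype=float)
    top = list(overall.index[:top_n])

    group_labels = sorted({str(groups[s]) for s in samples})
    out = pd.DataFrame(index=top + ["remaining/unknown"], columns=group_labels, dtype=float)
    for label in group_labels:
        cols = [s for s in samples if str(groups[s]) == label]
        named_means = by_genus.loc[top, cols].mean(axis=1) if top else pd.Series(dtype=float)
        out.loc[top, label] = named_means
        out.loc["remaining/unknown", label] = 1.0 - float(named_means.sum())
    out.index.name = "genus"
    return out


def _log(lines: list[str], message: str) -> None:
    lines.append(message)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns a mapping artifact-name -> path. Deterministic given the config:
    rerunning writes byte-identical numeric outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: list[str] = []

    def stage(name):
        _log(log, f"[stage] {name}")

    def save_frame(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", **kwargs)
        artifacts[name] = path

    try:
        stage("inputs")
        if config.simulate is not None:
            table, meta, taxonomy, truth = simulate_study(config.simulate)
            write_abundance_table(table, outdir / "simulated_counts.tsv")
            write_metadata(meta, outdir / "metadata.tsv")
            write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
            truth.write(outdir / "truth.tsv")
            artifacts.update(
                {
                    "simulated_counts": outdir / "simulated_counts.tsv",
                    "metadata": outdir / "metadata.tsv",
                    "taxonomy": outdir / "taxonomy.tsv",
                    "truth": outdir / "truth.tsv",
                }
            )
            _log(log, f"simulated study, seed={config.simulate.seed}, phase={config.simulate.phase}")
            phase = config.simulate.phase
        else:
            table = read_abundance_table(config.table_path)
            meta = read_metadata(config.metadata_path)
            taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
            phases = {r.phase for r in meta.records}
            phase = sorted(phases)[0] if len(phases) == 1 else "main"

        design = summarize_design(meta, phase)
        _log(
            log,
            f"design[{phase}]: milk={design.n_milk} water={design.n_water} "
            f"mock={design.n_mock} ntc={design.n_ntc}",
        )

        stage("curation")
        _log(log, f"curation params: {config.params}")
        curated, cur_report = cur.run_curation(
            table, meta, taxonomy, config.params, drop_flagged=config.drop_flagged
        )
        write_abundance_table(curated, outdir / "curated_counts.tsv")
        artifacts["curated_counts"] = outdir / "curated_counts.tsv"
        cur_report.write(outdir / "curation_ledger.tsv")
        artifacts["curation_ledger"] = outdir / "curation_ledger.tsv"
        with open(outdir / "curation_summary.json", "w", encoding="utf-8") as fh:
            json.dump(cur_report.summary(), fh, indent=2, sort_keys=True)
        artifacts["curation_summary"] = outdir / "curation_summary.json"

        stage("clean_reads")
        clean = cur.clean_read_totals(table)
        save_frame(
            "clean_reads",
            pd.DataFrame(sorted(clean.items()), columns=["sample_id", "clean_reads"]),
            index=False,
        )

        stage("selection")
        medians = rep.median_clean_reads(clean, meta)
        median_rows = [
            {"protocol": p, "primer_run": run, "median_clean_reads": m}
            for p, runs in medians.items()
            for run, m in sorted(runs.items())
        ]
        save_frame("median_clean_reads", pd.DataFrame(median_rows), index=False)
        runs_present = tuple(sorted({r.primer_run for r in meta.records}))
        selected = rep.select_protocols(
            medians, threshold=config.params.tau_median, required_runs=runs_present
        )
        save_frame(
            "protocol_selection",
            pd.DataFrame(
                [
                    {"protocol": p, "selected": p in selected}
                    for p in sorted(medians)
                ]
            ),
            index=False,
        )
        _log(log, f"selected protocols (median > {config.params.tau_median}): {sorted(selected)}")

        stage("variability")
        try:
            variability = rep.decompose_read_variability(clean, meta)
            save_frame(
                "variability",
                pd.DataFrame(
                    [
                        {
                            "protocol": v.protocol,
                            "primer_run": v.primer_run,
                            "prototype": v.prototype,
                            "max_seq_var": v.max_seq_var,
                            "total_var": v.total_var,
                            "ratio_pct": "" if v.ratio_pct is None else v.ratio_pct,
                            "extraction_contribution_pp": ""
                            if v.extraction_contribution_pp is None
                            else v.extraction_contribution_pp,
                        }
                        for v in variability
                    ]
                ),
                index=False,
            )
        except rep.ReproducibilityError as exc:
            _log(log, f"variability decomposition skipped: {exc}")

        stage("alpha_diversity")
        depths = div.protocol_rarefaction_depth(curated, meta, config.rarefaction)
        _log(log, f"rarefaction depths: { {f'{p}/{r}': d for (p, r), d in sorted(depths.items())} }")
        totals = curated.sample_totals()
        div_rows = []
        alpha_values: dict[tuple[str, str], list[tuple[str, float, float, float | None]]] = {}
        for s in curated.sample_ids:
            if s not in meta:
                continue
            rec = meta[s]
            if rec.material != "milk" or (rec.protocol, rec.primer_run) not in depths:
                continue
            d = depths[(rec.protocol, rec.primer_run)]
            if totals[s] < d:
                _log(log, f"{s}: below rarefaction depth {d}, excluded from diversity")
                continue
            rng = substream(config.seed, "rarefy", s)
            res = div.alpha_diversity(curated.column(s), d, rng, sample_id=s)
            div_rows.append(
                {
                    "sample_id": s,
                    "protocol": rec.protocol,
                    "primer_run": rec.primer_run,
                    "prototype": rec.prototype,
                    "d": res.d,
                    "richness": res.richness,
                    "shannon": res.shannon,
                    "evenness": "" if res.evenness is None else res.evenness,
                }
            )
            alpha_values.setdefault((rec.protocol, rec.primer_run), []).append(
                (rec.prototype, res.shannon, float(res.richness), res.evenness)
            )
        save_frame("alpha_diversity", pd.DataFrame(div_rows), index=False)

        anova_rows = []
        for (protocol, run), rows in sorted(alpha_values.items()):
            groups = [r[0] for r in rows]
            for idx, metric in ((1, "shannon"), (2, "richness"), (3, "evenness")):
                vals = [(r[idx], g) for r, g in zip(rows, groups) if r[idx] is not None]
                if len({g for _, g in vals}) < 2 or len(vals) - len({g for _, g in vals}) < 1:
                    continue
                f_stat, p = div.anova_alpha([v for v, _ in vals], [g for _, g in vals])
                anova_rows.append(
                    {
                        "protocol": protocol,
                        "primer_run": run,
                        "metric": metric,
                        "F": f_stat,
                        "p": p,
                    }
                )
        save_frame("anova", pd.DataFrame(anova_rows), index=False)

        stage("beta_diversity")
        normalized = cur.tss_normalize(curated) if curated.sample_ids else None
        dispersion_rows = []
        for run in runs_present:
            milk = [
                s
                for s in curated.sample_ids
                if s in meta and meta[s].material == "milk" and meta[s].primer_run == run
            ]
            if len(milk) < 2:
                continue
            dm = rep.bray_curtis_matrix(normalized[milk])
            save_frame(f"distance_{run}", dm.to_frame())
            ordination = rep.pcoa(dm)
            ord_frame = ordination.to_frame()
            save_frame(f"ordination_{run}", ord_frame)
            groups = {
                s: f"{meta[s].protocol}|{meta[s].prototype}" for s in milk
            }
            for g, value in sorted(rep.group_dispersion(dm, groups).items()):
                protocol, prototype = g.split("|")
                dispersion_rows.append(
                    {
                        "primer_run": run,
                        "protocol": protocol,
                        "prototype": prototype,
                        "mean_within_dissimilarity": "" if value is None else value,
                    }
                )
        save_frame("dispersion", pd.DataFrame(dispersion_rows), index=False)

        stage("top_taxa")
        if normalized is not None and taxonomy is not None:
            for run in runs_present:
                milk = [
                    s
                    for s in curated.sample_ids
                    if s in meta and meta[s].material == "milk" and meta[s].primer_run == run
                ]
                if not milk:
                    continue
                groups = {s: meta[s].prototype for s in milk}
                top = summarize_top_taxa(normalized[milk], taxonomy, groups, config.top_n)
                save_frame(f"top_taxa_{run}", top)

        _log(log, f"seed: {config.seed}")
        _log(log, "done")
    except (PipelineError, Exception) as exc:
        _log(log, f"FAILED: {exc}")
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
        raise

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    artifacts["run_log"] = outdir / "run_log.txt"
    return artifacts
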