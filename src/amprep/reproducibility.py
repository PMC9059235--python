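"""Beta-diversity, replicate dispersion, clean-read variability decomposition
and the median-read protocol-selection rule.

The variability decomposition compares, per (protocol, primer run, prototype)
key, the largest within-extract clean-read range (re-sequencing only) against
the largest clean-read difference between data sets from different extracts
(extraction plus sequencing). Ratios above 100% are legal and indicate that
re-sequencing alone spreads reads more than switching extracts does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .io import AbundanceTable, MetadataTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "VariabilityResult",
    "ReproducibilityError",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "group_dispersion",
    "decompose_read_variability",
    "median_clean_reads",
    "select_protocols",
]


class ReproducibilityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix with sample labels."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ReproducibilityError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ReproducibilityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ReproducibilityError("distance matrix must have a zero diagonal")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.sample_ids))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """BC(x, y) = sum|x - y| / sum(x + y) for non-negative abundance vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ReproducibilityError("vectors must align")
    denom = float(np.sum(x + y))
    if denom == 0.0:
        raise ReproducibilityError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(
    abundances: AbundanceTable | pd.DataFrame, use_relative: bool = True
) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity over the sample columns.

    With ``use_relative`` (default) each column is first scaled to
    proportions, matching analysis on TSS-normalized data.
    """
    if isinstance(abundances, AbundanceTable):
        sample_ids = list(abundances.sample_ids)
        mat = abundances.counts.astype(np.float64)
    else:
        sample_ids = [str(c) for c in abundances.columns]
        mat = abundances.to_numpy(dtype=np.float64)
    if mat.size and mat.min() < 0:
        raise ReproducibilityError("abundances must be non-negative")
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        zero = [s for s, t in zip(sample_ids, totals) if t == 0]
        raise ReproducibilityError(f"zero-total sample(s) {zero}")
    if use_relative:
        mat = mat / totals
    n = len(sample_ids)
    d = np.zeros((n, n))
    cols = mat.T
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = bray_curtis(cols[i], cols[j])
    return DistanceMatrix(sample_ids=sample_ids, values=d)


# ---------------------------------------------------------------------------
# PCoA (classical metric scaling)
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Principal coordinates, with eigenvalues in descending order.

    ``coordinates`` holds one column per retained (positive-eigenvalue) axis;
    negative eigenvalues are reported in ``eigenvalues`` but excluded from the
    coordinates. ``proportion_explained`` is relative to the positive part of
    the spectrum.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


def pcoa(distance: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    B = -1/2 * J (D o D) J with J the centering projector; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues.
    """
    d = distance.values
    n = d.shape[0]
    if n < 2:
        raise ReproducibilityError("PCoA needs at least 2 samples")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d * d) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    if not np.any(positive):
        raise ReproducibilityError("degenerate configuration: no positive eigenvalues")
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = float(eigvals[positive].sum())
    proportion = np.where(positive, eigvals / pos_sum, 0.0)
    return OrdinationResult(
        sample_ids=list(distance.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


# ---------------------------------------------------------------------------
# Replicate dispersion
# ---------------------------------------------------------------------------


def group_dispersion(
    distance: DistanceMatrix, groups: Mapping[str, object]
) -> dict[object, float | None]:
    """Mean within-group dissimilarity over unordered pairs, per group.

    Singleton groups get ``None``.
    """
    members: dict[object, list[int]] = {}
    for i, s in enumerate(distance.sample_ids):
        if s in groups:
            members.setdefault(groups[s], []).append(i)
    out: dict[object, float | None] = {}
    for g, idx in members.items():
        if len(idx) < 2:
            out[g] = None
            continue
        pairs = [distance.values[i, j] for i, j in combinations(idx, 2)]
        out[g] = float(np.mean(pairs))
    return out


# ---------------------------------------------------------------------------
# Clean-read variability decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariabilityResult:
    """Sequencing vs. total clean-read variability for one replicate group.

    ``max_seq_var``: largest within-extract clean-read range (max - min over
    sequencing replicates). ``total_var``: largest |difference| between data
    sets from different extracts. ``ratio_pct`` = 100 * max_seq_var /
    total_var (``None`` when total_var is 0); ``extraction_contribution_pp``
    = 100 * (total_var - max_seq_var) / max_seq_var, i.e. the percentage
    points extraction adds when sequencing variability is set to 100%.
    """

    protocol: str
    primer_run: str
    prototype: str
    max_seq_var: int
    total_var: int
    ratio_pct: float | None
    extraction_contribution_pp: float | None


def decompose_read_variability(
    clean_reads: Mapping[str, int], meta: MetadataTable
) -> list[VariabilityResult]:
    """Decompose clean-read variability per (protocol, primer run, prototype).

    Requires >= 2 extracts per key and >= 2 sequencing replicates per extract.
    """
    groups: dict[tuple[str, str, str], dict[int, list[int]]] = {}
    for sample_id, reads in clean_reads.items():
        if sample_id not in meta:
            continue
        rec = meta[sample_id]
        if rec.material != "milk":
            continue
        key = (rec.protocol, rec.primer_run, rec.prototype)
        groups.setdefault(key, {}).setdefault(rec.extraction_rep, []).append(int(reads))
    results = []
    for key in sorted(groups):
        extracts = groups[key]
        if len(extracts) < 2:
            raise ReproducibilityError(f"{key}: needs >= 2 extracts, found {len(extracts)}")
        for ext, reads in extracts.items():
            if len(reads) < 2:
                raise ReproducibilityError(
                    f"{key}: extract {ext} needs >= 2 sequencing replicates"
                )
        max_seq_var = max(max(r) - min(r) for r in extracts.values())
        total_var = max(
            abs(a - b)
            for ea, eb in combinations(extracts, 2)
            for a in extracts[ea]
            for b in extracts[eb]
        )
        if total_var == 0:
            ratio = None
        else:
            ratio = 100.0 * max_seq_var / total_var
        if max_seq_var == 0:
            contribution = None
        else:
            contribution = 100.0 * (total_var - max_seq_var) / max_seq_var
        results.append(
            VariabilityResult(
                protocol=key[0],
                primer_run=key[1],
                prototype=key[2],
                max_seq_var=int(max_seq_var),
                total_var=int(total_var),
                ratio_pct=ratio,
                extraction_contribution_pp=contribution,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Protocol selection
# ---------------------------------------------------------------------------


def median_clean_reads(
    clean_reads: Mapping[str, int], meta: MetadataTable, material: str = "milk"
) -> dict[str, dict[str, float]]:
    """Per-protocol, per-primer-run median clean reads (even n: mean of the
    central pair)."""
    groups: dict[str, dict[str, list[int]]] = {}
    for sample_id, reads in clean_reads.items():
        if sample_id not in meta:
            continue
        rec = meta[sample_id]
        if rec.material != material or rec.protocol is None:
            continue
        groups.setdefault(rec.protocol, {}).setdefault(rec.primer_run, []).append(int(reads))
    return {
        p: {run: float(np.median(v)) for run, v in runs.items()}
        for p, runs in sorted(groups.items())
    }


def select_protocols(
    medians: Mapping[str, Mapping[str, float]],
    threshold: float = 1000.0,
    required_runs: tuple[str, ...] = ("V1V2", "V3V4"),
) -> set[str]:
    """Protocols whose median clean reads are strictly above ``threshold`` in
    every required primer run; a missing run fails the protocol."""
    selected = set()
    for protocol, by_run in medians.items():
        try:
            ok = all(by_run[run] > threshold for run in required_runs)
        except KeyError:
            ok = False
        if ok:
            selected.add(protocol)
    return selected
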