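"""Protocol-specific rarefaction and alpha-diversity.

Shannon entropy is computed in nats; evenness is Pielou's H / ln(R) and is
undefined (``None``) for single-ASV samples. Rarefaction subsamples reads
without replacement (multivariate hypergeometric draw); samples below the
target depth are excluded, never up-sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io import AbundanceTable, MetadataTable

__all__ = [
    "DiversityResult",
    "RarefactionSpec",
    "DiversityError",
    "rarefy_counts",
    "expected_rarefied_richness",
    "shannon_index",
    "alpha_diversity",
    "protocol_rarefaction_depth",
    "anova_alpha",
]


class DiversityError(ValueError):
    """Raised for invalid rarefaction depths or degenerate ANOVA layouts."""


@dataclass(frozen=True)
class DiversityResult:
    """Alpha-diversity of one sample at rarefaction depth ``d``."""

    sample_id: str
    d: int
    richness: int
    shannon: float
    evenness: float | None


@dataclass(frozen=True)
class RarefactionSpec:
    """How to choose per-(protocol, primer run) rarefaction depths.

    ``policy`` is ``"min-retained-per-protocol"`` (depth = smallest clean-read
    total among the protocol's retained samples) or ``"explicit"``;
    ``explicit_depths`` maps ``(protocol, primer_run)`` -> depth and always
    overrides the policy where present.
    """

    policy: str = "min-retained-per-protocol"
    explicit_depths: Mapping[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.policy not in ("min-retained-per-protocol", "explicit"):
            raise ValueError(f"unknown rarefaction policy {self.policy!r}")
        for key, d in self.explicit_depths.items():
            if d < 1:
                raise ValueError(f"rarefaction depth for {key} must be >= 1")


def _as_count_vector(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise DiversityError("counts must be a 1-D vector")
    if arr.size and (np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0))):
        raise DiversityError("counts must be non-negative integers")
    return arr.astype(np.int64, copy=False)


def rarefy_counts(
    counts: Sequence[int] | np.ndarray, d: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Subsample a count vector to exactly ``d`` reads without replacement."""
    arr = _as_count_vector(counts)
    total = int(arr.sum())
    if d < 1:
        raise DiversityError(f"rarefaction depth must be >= 1, got {d}")
    if d > total:
        raise DiversityError(
            f"rarefaction depth {d} exceeds sample total {total}; exclude the sample"
        )
    if d == total:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, d).astype(np.int64)


def expected_rarefied_richness(counts: Sequence[int] | np.ndarray, d: int) -> float:
    """Analytic expected richness under subsampling to depth ``d``.

    E[R] = sum_i 1 - C(N - n_i, d) / C(N, d), evaluated via log-gamma so it
    stays finite for totals up to ~1e6.
    """
    arr = _as_count_vector(counts)
    arr = arr[arr > 0]
    total = int(arr.sum())
    if d < 1 or d > total:
        raise DiversityError(f"depth {d} outside [1, {total}]")
    # log C(N - n_i, d) - log C(N, d); C(N - n_i, d) = 0 when N - n_i < d
    n = arr.astype(np.float64)
    keep = (total - n) >= d
    log_ratio = np.full(arr.shape, -np.inf)
    if np.any(keep):
        m = total - n[keep]
        log_ratio[keep] = (
            gammaln(m + 1)
            - gammaln(d + 1)
            - gammaln(m - d + 1)
            - (gammaln(total + 1) - gammaln(d + 1) - gammaln(total - d + 1))
        )
    return float(np.sum(1.0 - np.exp(log_ratio)))


def shannon_index(counts: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy (nats) of the non-zero proportions of a count vector."""
    arr = np.asarray(counts, dtype=np.float64)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise DiversityError("cannot compute Shannon index of an all-zero vector")
    p = arr / arr.sum()
    return float(-np.sum(p * np.log(p)))


def alpha_diversity(
    counts: Sequence[int] | np.ndarray,
    d: int,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> DiversityResult:
    """Rarefy once with ``seed`` and report richness, Shannon and evenness."""
    rarefied = rarefy_counts(counts, d, seed)
    nz = rarefied[rarefied > 0]
    richness = int(nz.size)
    h = shannon_index(rarefied)
    evenness = h / float(np.log(richness)) if richness >= 2 else None
    return DiversityResult(sample_id=sample_id, d=int(d), richness=richness, shannon=h, evenness=evenness)


def protocol_rarefaction_depth(
    table: AbundanceTable,
    meta: MetadataTable,
    spec: RarefactionSpec,
    materials: tuple[str, ...] = ("milk",),
) -> dict[tuple[str, str], int]:
    """Per-(protocol, primer run) rarefaction depth for the retained samples."""
    totals = table.sample_totals()
    groups: dict[tuple[str, str], list[int]] = {}
    for s in table.sample_ids:
        if s not in meta:
            continue
        rec = meta[s]
        if rec.material not in materials or rec.protocol is None:
            continue
        groups.setdefault((rec.protocol, rec.primer_run), []).append(totals[s])
    depths: dict[tuple[str, str], int] = {}
    keys = set(groups) | set(spec.explicit_depths)
    for key in sorted(keys):
        if key in spec.explicit_depths:
            depths[key] = int(spec.explicit_depths[key])
        elif spec.policy == "explicit":
            raise DiversityError(f"no explicit rarefaction depth for {key}")
        else:
            if not groups.get(key):
                raise DiversityError(f"no retained samples for {key}")
            depths[key] = int(min(groups[key]))
    return depths


def anova_alpha(
    values: Sequence[float], groups: Sequence
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p).

    Zero within-group variance with unequal means yields ``(inf, 0.0)``;
    a degenerate layout (fewer than 2 groups, or no residual df) is an error.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise DiversityError("values and groups must align")
    unique = [values[labels == g] for g in dict.fromkeys(labels.tolist())]
    k = len(unique)
    n = values.size
    if k < 2:
        raise DiversityError("ANOVA needs at least 2 groups")
    if n - k < 1:
        raise DiversityError("ANOVA needs at least 1 residual degree of freedom")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in unique)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in unique)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        import warnings

        warnings.warn("zero within-group variance with unequal means; p reported as 0-limit")
        return float("inf"), 0.0
    f = ms_between / ms_within
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p
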