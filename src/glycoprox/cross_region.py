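"""Cross-region and cross-study summaries of candidate substrate lists.

Set overlaps between candidate lists (e.g. this screen's HEK293T candidates
against previously published O-GlcNAcome compilations), the fraction of a
region's called substrates that belong to a gene category (ribosomal
components), rank correlation between normalized O-GlcNAc levels and mRNA
abundance, and assembly of a genes x regions level matrix for heatmap export.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import AnnotationSet, CandidateList

__all__ = [
    "OverlapResult",
    "CategoryFraction",
    "overlap",
    "category_fraction",
    "level_mrna_correlation",
    "region_level_matrix",
]


@dataclass(frozen=True)
class OverlapResult:
    """Exact set algebra over two or three candidate lists.

    ``labels`` preserve input order; percentages are reported against the
    first list's size. ``pairwise`` maps a label pair (input order) to the
    intersection size; ``triple`` is None for two lists.
    """

    labels: tuple[str, ...]
    sizes: tuple[int, ...]
    pairwise: dict[tuple[str, str], int]
    triple: int | None
    unique: tuple[int, ...]
    union_size: int
    first_shared_with_any: int  # |first ∩ (union of the others)|

    @property
    def first_shared_percent(self) -> float:
        return 100.0 * self.first_shared_with_any / self.sizes[0]

    @property
    def first_unique(self) -> int:
        return self.unique[0]

    def check_inclusion_exclusion(self) -> None:
        """Assert |A∪B(∪C)| from inclusion–exclusion equals the direct union."""
        total = sum(self.sizes) - sum(self.pairwise.values())
        if self.triple is not None:
            total += self.triple
        if total != self.union_size:
            raise AssertionError(
                f"inclusion–exclusion mismatch: {total} != {self.union_size}"
            )


def overlap(lists: Sequence[CandidateList]) -> OverlapResult:
    """Overlap statistics for two or three identifier lists.

    The lists must already share an identifier namespace (reading through
    :func:`glycoprox.io.read_candidate_list` normalizes case and whitespace).
    A zero overlap between non-empty lists triggers a warning — usually a
    namespace mismatch (accessions vs gene symbols) — but is not an error.
    """
    if len(lists) not in (2, 3):
        raise ValueError("overlap expects 2 or 3 candidate lists")
    labels = tuple(l.provenance or f"list{i + 1}" for i, l in enumerate(lists))
    sets = [set(l.members) for l in lists]

    pairwise = {
        (labels[i], labels[j]): len(sets[i] & sets[j])
        for i, j in combinations(range(len(sets)), 2)
    }
    if all(v == 0 for v in pairwise.values()):
        import warnings

        warnings.warn(
            "no overlap between any pair of lists; check that they use the same "
            "identifier namespace"
        )
    triple = len(sets[0] & sets[1] & sets[2]) if len(sets) == 3 else None
    union = set().union(*sets)
    others = set().union(*sets[1:])
    unique = tuple(
        len(sets[i] - set().union(*(s for j, s in enumerate(sets) if j != i)))
        for i in range(len(sets))
    )
    result = OverlapResult(
        labels=labels,
        sizes=tuple(len(s) for s in sets),
        pairwise=pairwise,
        triple=triple,
        unique=unique,
        union_size=len(union),
        first_shared_with_any=len(sets[0] & others),
    )
    result.check_inclusion_exclusion()
    return result


@dataclass(frozen=True)
class CategoryFraction:
    """Fraction of a called list belonging to an annotation category."""

    region: str
    category: str
    n_called: int
    n_in_category: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_in_category / self.n_called


def category_fraction(
    called: CandidateList, annotation: AnnotationSet, region: str = ""
) -> CategoryFraction:
    """Count and percentage of called identifiers inside the annotation set."""
    if not called.members:
        raise ValueError("called list is empty")
    n_in = len(set(called.members) & set(annotation.members))
    return CategoryFraction(region, annotation.category, len(called.members), n_in)


def level_mrna_correlation(
    levels: Mapping[str, float], mrna: Mapping[str, float], method: str = "spearman"
) -> tuple[float, float]:
    """Correlation between normalized O-GlcNAc levels and mRNA abundance.

    Pairs genes present with finite values in both mappings; Spearman rank
    correlation (midranks for ties) with a two-sided p-value by default,
    Pearson via ``method="pearson"``. Requires at least 3 complete pairs.
    """
    genes = [
        g
        for g in levels
        if g in mrna and np.isfinite(levels[g]) and np.isfinite(mrna[g])
    ]
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes with both values, got {len(genes)}")
    x = np.array([levels[g] for g in genes], dtype=float)
    y = np.array([mrna[g] for g in genes], dtype=float)
    if method == "spearman":
        rho, p = _sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = _sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def region_level_matrix(
    levels_per_region: Mapping[str, Mapping[str, float]], genes: Sequence[str]
) -> pd.DataFrame:
    """Genes x regions matrix of levels; missing entries are NaN, never 0.

    Row order follows ``genes``, column order the mapping's insertion order.
    """
    regions = list(levels_per_region)
    data = np.full((len(genes), len(regions)), np.nan)
    for j, region in enumerate(regions):
        lv = levels_per_region[region]
        for i, g in enumerate(genes):
            if g in lv and lv[g] is not None:
                data[i, j] = lv[g]
    return pd.DataFrame(data, index=list(genes), columns=regions)
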