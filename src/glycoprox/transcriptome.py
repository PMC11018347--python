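"""Single-cell-transcriptome normalization of regional O-GlcNAc levels.

A substrate's apparent O-GlcNAc level (log2 fold change from the proximity
labeling contrast) partly reflects how abundantly the protein is expressed in
the profiled brain region. To adjust for this, a per-gene, per-region
normalizing factor is computed from a single-cell expression atlas of the
adult brain:

    factor(g, region) = mean expression of g in neurons of that region
                        / mean expression of g in neurons of the whole brain

and the normalized O-GlcNAc level is the raw log2 FC divided by this factor.
Only cells typed as neurons enter both averages. Because the factor is a
ratio of means over cells, any per-cell scaling that is uniform across genes
(library-size normalization) cancels; per-gene scalings do not, so the matrix
should carry library-size-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .io import FormatError, normalize_identifier

__all__ = [
    "SingleCellMatrix",
    "read_cluster_region_map",
    "write_cluster_region_map",
    "mean_expression",
    "normalizing_factors",
    "normalize_levels",
    "read_sc_matrix",
    "write_sc_matrix",
]

FACTOR_COLUMNS = ["gene", "region", "region_mean", "brain_mean", "factor"]
LEVEL_COLUMNS = ["protein_group_id", "gene", "region", "raw_log2_fc", "factor", "normalized", "reason"]


@dataclass
class SingleCellMatrix:
    """Genes x cells expression matrix with per-cell cluster and type labels.

    ``counts`` is a dense genes x cells array (fixtures and simulations here
    are small); ``cell_cluster`` and ``cell_type`` are indexed by cell id.
    ``cell_type`` values are "neuron" or "other"; when a dataset carries no
    typing, every cell defaults to "neuron".
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    cell_cluster: pd.Series
    cell_type: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != (n_genes, n_cells) "
                f"({len(self.genes)}, {len(self.cells)})"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.cells if c not in self.cell_cluster.index]
        if missing:
            raise ValueError(f"cells without cluster label: {missing[:5]}")
        if self.cell_type is None:
            import warnings

            warnings.warn("no cell typing supplied; treating every cell as a neuron")
            self.cell_type = pd.Series("neuron", index=self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cells)}
        return np.array([pos[c] for c in cell_ids], dtype=int)


def read_cluster_region_map(path) -> dict[str, str]:
    """Two-column TSV cluster -> region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("cluster-region map needs two columns (cluster, region)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_cluster_region_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame({"cluster": list(mapping), "region": list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )


def mean_expression(matrix: SingleCellMatrix, cell_subset: Sequence[str]) -> pd.Series:
    """Per-gene arithmetic mean of expression over the given cells."""
    cell_subset = list(cell_subset)
    if not cell_subset:
        raise ValueError("cell subset is empty")
    idx = matrix.cell_indices(cell_subset)
    return pd.Series(matrix.counts[:, idx].mean(axis=1), index=matrix.genes, name="mean")


def _neuron_cells(matrix: SingleCellMatrix) -> list[str]:
    return [c for c in matrix.cells if matrix.cell_type.loc[c] == "neuron"]


def normalizing_factors(
    matrix: SingleCellMatrix,
    cluster_region_map: Mapping[str, str],
    region: str,
    weighting: str = "cell",
) -> pd.DataFrame:
    """Per-gene normalizing factors for one region.

    factor = (mean over region neurons) / (mean over all neurons); the
    whole-brain denominator uses every neuron regardless of region. A gene
    with zero whole-brain mean gets factor NaN (undefined, flagged
    downstream). ``weighting="cluster"`` averages cluster means instead of
    pooling cells.
    """
    if weighting not in ("cell", "cluster"):
        raise ValueError("weighting must be 'cell' or 'cluster'")
    missing = sorted(
        {cl for cl in matrix.cell_cluster.loc[matrix.cells] if cl not in cluster_region_map}
    )
    if missing:
        raise FormatError(f"clusters without region assignment: {missing[:5]}")

    neurons = _neuron_cells(matrix)
    if not neurons:
        raise ValueError("no neuron-typed cells in matrix")
    region_cells = [
        c for c in neurons if cluster_region_map[matrix.cell_cluster.loc[c]] == region
    ]
    if not region_cells:
        raise ValueError(f"region {region!r} has no neuron cells")

    if weighting == "cell":
        region_mean = mean_expression(matrix, region_cells).to_numpy()
        brain_mean = mean_expression(matrix, neurons).to_numpy()
    else:
        def cluster_mean(cells: list[str]) -> np.ndarray:
            clusters = pd.Series(
                [matrix.cell_cluster.loc[c] for c in cells], index=cells
            )
            means = [
                mean_expression(matrix, list(clusters.index[clusters == cl])).to_numpy()
                for cl in clusters.unique()
            ]
            return np.mean(means, axis=0)

        region_mean = cluster_mean(region_cells)
        brain_mean = cluster_mean(neurons)

    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(brain_mean > 0, region_mean / brain_mean, np.nan)
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "region": region,
            "region_mean": region_mean,
            "brain_mean": brain_mean,
            "factor": factor,
        },
        columns=FACTOR_COLUMNS,
    )


def _primary_gene(gene_symbol: str) -> tuple[str, bool]:
    """First gene of a semicolon-joined symbol list; flags ambiguity."""
    parts = [p for p in str(gene_symbol).split(";") if p.strip()]
    if not parts:
        return "", False
    return parts[0].strip(), len(parts) > 1


def normalize_levels(records: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Divide each record's log2 FC by its gene's regional normalizing factor.

    ``records`` is an enrichment-record table (needs ``protein_group_id``,
    ``gene_symbol``, ``region``, ``log2_fc``); ``factors`` comes from
    :func:`normalizing_factors`. Joining is by case-folded gene symbol
    (first symbol of a multi-gene group, reported as ambiguous). Genes
    without a defined factor yield NaN with a reason string.
    """
    fac = factors.set_index(factors["gene"].map(normalize_identifier))["factor"]
    rows = []
    for r in records.itertuples(index=False):
        gene, ambiguous = _primary_gene(r.gene_symbol)
        key = normalize_identifier(gene)
        reason = "ambiguous gene symbol; used first" if ambiguous else ""
        if not key:
            factor, normalized, reason = np.nan, np.nan, "no gene symbol"
        elif key not in fac.index:
            factor, normalized, reason = np.nan, np.nan, "gene not in expression matrix"
        else:
            factor = float(fac.loc[key])
            if np.isnan(factor):
                normalized, reason = np.nan, "zero whole-brain expression"
            elif factor == 0:
                normalized, reason = np.nan, "zero regional factor"
            else:
                normalized = float(r.log2_fc) / factor
        rows.append(
            (r.protein_group_id, gene, r.region, float(r.log2_fc), factor, normalized, reason)
        )
    return pd.DataFrame(rows, columns=LEVEL_COLUMNS)


def write_sc_matrix(matrix: SingleCellMatrix, out_dir) -> None:
    """Write as an MTX triplet: matrix.mtx + genes.tsv + cells.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(matrix.counts))
    pd.DataFrame({"gene": matrix.genes}).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell": matrix.cells,
            "cluster": [matrix.cell_cluster.loc[c] for c in matrix.cells],
            "cell_type": [matrix.cell_type.loc[c] for c in matrix.cells],
        }
    ).to_csv(out / "cells.tsv", sep="\t", index=False)


def read_sc_matrix(in_dir) -> SingleCellMatrix:
    ind = Path(in_dir)
    m = spio.mmread(ind / "matrix.mtx")
    counts = np.asarray(m.toarray() if sparse.issparse(m) else m, dtype=float)
    genes = pd.read_csv(ind / "genes.tsv", sep="\t", dtype=str)["gene"].tolist()
    cells_df = pd.read_csv(ind / "cells.tsv", sep="\t", dtype=str)
    cells = cells_df["cell"].tolist()
    cluster = pd.Series(cells_df["cluster"].to_numpy(), index=cells)
    ctype = (
        pd.Series(cells_df["cell_type"].to_numpy(), index=cells)
        if "cell_type" in cells_df.columns
        else None
    )
    return SingleCellMatrix(genes, cells, counts, cluster, ctype)
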