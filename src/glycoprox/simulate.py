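"""Synthetic-data generators with ground truth.

Three generators emulate the statistical structure the analysis assumes, each
paired with the truth needed for recovery tests:

* :func:`generate_lfq_table` — a MaxQuant-style protein-group table for a
  CD-vs-DM proximity-labeling contrast. Log2 intensities are Gaussian
  (log-normal on the raw scale) with a planted mean shift of
  ``effect_log2fc`` for a random substrate subset in the CD samples,
  Bernoulli zeroing for missingness, and flagged contaminant rows.
* :func:`generate_sc_matrix` — a clustered single-cell count matrix with a
  cluster -> region map, gamma-Poisson (negative-binomial) noise around
  configured per-gene per-cluster means.
* :func:`generate_behavior_counts` — binomial T-maze choice counts under a
  specified per-fly probability of avoiding the shock-paired odor; the
  expected learning PI is (2·p_correct − 1) × 100%.

All generators are deterministic given their config seed (one seed per
config, split internally with :class:`numpy.random.SeedSequence`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import BehaviorTrial
from .io import ProteinGroupTable, SampleDesign, SampleInfo
from .transcriptome import SingleCellMatrix

__all__ = [
    "ConfigError",
    "LfqSimConfig",
    "SyntheticTruth",
    "ClusterSpec",
    "ScSimConfig",
    "BehaviorSimConfig",
    "generate_lfq_table",
    "generate_sc_matrix",
    "generate_behavior_counts",
]


class ConfigError(ValueError):
    """A simulation config field failed validation (message names the field)."""


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {message}")


@dataclass(frozen=True)
class LfqSimConfig:
    """Configuration of the LFQ proteomics simulation.

    Defaults describe a streptavidin-enriched pulldown quantified label-free:
    log2 baselines around 25 (raw LFQ intensities ~3x10^7), per-replicate
    noise of 0.5 on the log2 scale, a planted CD−DM shift of 2 for 10% of
    proteins, three replicates per construct, 2% missingness, and 5%
    contaminant rows. ``peptide_count_law`` is one of ("constant", k),
    ("shifted_poisson", mean_extra) for 1 + Poisson(mean_extra), or
    ("geometric", p) for a geometric count ≥ 1.
    """

    n_proteins: int = 2000
    substrate_fraction: float = 0.1
    effect_log2fc: float = 2.0
    replicate_sd: float = 0.5
    n_replicates: int = 3
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    dropout_rate: float = 0.02
    dropout_mode: str = "mcar"  # or "mnar": missingness concentrates at low intensity
    contaminant_fraction: float = 0.05
    peptide_count_law: tuple = ("shifted_poisson", 8.0)
    regions: tuple[str, ...] = ("MB",)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_proteins >= 1, "n_proteins", "must be a positive integer")
        _require(0 <= self.substrate_fraction <= 1, "substrate_fraction", "must be in [0, 1]")
        _require(self.effect_log2fc >= 0, "effect_log2fc", "must be >= 0")
        _require(self.replicate_sd > 0, "replicate_sd", "must be > 0")
        _require(self.n_replicates >= 2, "n_replicates", "must be >= 2")
        _require(0 <= self.dropout_rate <= 1, "dropout_rate", "must be in [0, 1]")
        _require(self.dropout_mode in ("mcar", "mnar"), "dropout_mode", "must be 'mcar' or 'mnar'")
        _require(
            0 <= self.contaminant_fraction <= 1, "contaminant_fraction", "must be in [0, 1]"
        )
        _require(len(self.regions) >= 1, "regions", "must list at least one region")
        law = self.peptide_count_law
        _require(
            isinstance(law, (tuple, list))
            and len(law) == 2
            and law[0] in ("constant", "shifted_poisson", "geometric"),
            "peptide_count_law",
            "must be ('constant', k), ('shifted_poisson', mean) or ('geometric', p)",
        )

    def design(self) -> SampleDesign:
        """The sample design implied by regions x {CD, DM} x replicates."""
        samples = {}
        for region in self.regions:
            for construct in ("CD", "DM"):
                for rep in range(1, self.n_replicates + 1):
                    samples[f"{region}_{construct}_{rep}"] = SampleInfo(region, construct, rep)
        return SampleDesign(samples)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one LFQ simulation."""

    substrate_ids: frozenset[str]
    effect_log2fc: float
    contaminant_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.substrate_ids & self.contaminant_ids:
            raise ValueError("substrate and contaminant ids overlap")


def _peptide_counts(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind, param = law
    if kind == "constant":
        return np.full(n, int(param))
    if kind == "shifted_poisson":
        return 1 + rng.poisson(float(param), n)
    return rng.geometric(float(param), n)  # support starts at 1


def generate_lfq_table(config: LfqSimConfig) -> tuple[ProteinGroupTable, SyntheticTruth]:
    """Simulate a protein-group LFQ table and its planted truth.

    Raw intensity of protein i in sample s is
    2^(baseline_i + effect·[substrate and CD] + N(0, replicate_sd)),
    then zeroed with probability ``dropout_rate`` ("mcar") or with an
    intensity-dependent probability centred on the same overall rate
    ("mnar"). Contaminant rows are appended with exactly one of the three
    MaxQuant filter flags set and no planted effect.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_noise, rng_drop, rng_pep, rng_pick = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    n = config.n_proteins
    n_sub = round(config.substrate_fraction * n)
    n_con = round(config.contaminant_fraction * n)
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    genes = [f"GENE{i}" for i in range(1, n + 1)]
    sub_idx = np.sort(rng_pick.choice(n, size=n_sub, replace=False))
    is_sub = np.zeros(n, dtype=bool)
    is_sub[sub_idx] = True

    con_ids = [f"CON__Q{i:05d}" for i in range(1, n_con + 1)]
    flag_cycle = ["contaminant", "reverse", "only_by_site"]

    design = config.design()
    sample_ids = list(design.samples)
    n_total = n + n_con
    baseline = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_total)

    frame = pd.DataFrame(
        {
            "protein_group_id": ids + con_ids,
            "gene_symbol": genes + [f"CONGENE{i}" for i in range(1, n_con + 1)],
            "peptide_count": _peptide_counts(rng_pep, tuple(config.peptide_count_law), n_total),
            "contaminant": False,
            "reverse": False,
            "only_by_site": False,
        }
    )
    for k, cid in enumerate(con_ids):
        frame.loc[n + k, flag_cycle[k % 3]] = True

    effect = np.zeros(n_total)
    effect[:n][is_sub] = config.effect_log2fc

    intensity_cols: dict[str, np.ndarray] = {}
    for sid in sample_ids:
        info = design.samples[sid]
        shift = effect if info.construct == "CD" else 0.0
        log2_val = baseline + shift + rng_noise.normal(0, config.replicate_sd, n_total)
        intensity = np.power(2.0, log2_val)
        if config.dropout_rate > 0:
            if config.dropout_mode == "mcar":
                p_drop = np.full(n_total, config.dropout_rate)
            else:
                # sigmoid in the log2 intensity: overall rate ~ dropout_rate,
                # concentrated below the baseline mean
                z = (log2_val - config.baseline_log2_mean) / max(config.baseline_log2_sd, 1e-9)
                p_drop = np.clip(2 * config.dropout_rate / (1 + np.exp(z)), 0, 1)
            intensity = np.where(rng_drop.random(n_total) < p_drop, 0.0, intensity)
        intensity_cols[sid] = intensity

    frame = pd.concat([frame, pd.DataFrame(intensity_cols)], axis=1)
    table = ProteinGroupTable(frame, sample_ids)
    truth = SyntheticTruth(
        substrate_ids=frozenset(np.array(ids)[is_sub]),
        effect_log2fc=config.effect_log2fc,
        contaminant_ids=frozenset(con_ids),
    )
    return table, truth


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    region: str
    n_cells: int
    cell_type: str = "neuron"

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", f"cluster {self.label!r} needs >= 1 cell")


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration of the clustered single-cell count simulation.

    ``means`` is a genes x clusters array of expected expression;
    ``dispersion`` parameterizes gamma-Poisson noise (variance
    m + dispersion·m²). A dispersion of exactly 0 is the degenerate
    deterministic mode: every cell reproduces its cluster mean exactly,
    useful for exact downstream identities.
    """

    clusters: tuple[ClusterSpec, ...]
    means: tuple = ()
    n_genes: int = 0
    dispersion: float = 0.1
    seed: int = 0
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _require(len(self.clusters) >= 1, "clusters", "must list at least one cluster")
        labels = [c.label for c in self.clusters]
        _require(
            len(set(labels)) == len(labels),
            "clusters",
            "cluster labels must be unique (each maps to exactly one region)",
        )
        means = np.asarray(self.means, dtype=float)
        _require(means.ndim == 2, "means", "must be a genes x clusters array")
        _require(
            means.shape[1] == len(self.clusters),
            "means",
            f"needs one column per cluster ({len(self.clusters)})",
        )
        _require((means >= 0).all(), "means", "must be non-negative")
        n_genes = self.n_genes or means.shape[0]
        _require(n_genes == means.shape[0], "n_genes", "inconsistent with means rows")
        _require(self.dispersion >= 0, "dispersion", "must be >= 0")
        if self.gene_names:
            _require(
                len(self.gene_names) == means.shape[0], "gene_names", "one name per gene"
            )

    @property
    def mean_matrix(self) -> np.ndarray:
        return np.asarray(self.means, dtype=float)

    @property
    def genes(self) -> list[str]:
        if self.gene_names:
            return list(self.gene_names)
        return [f"g{i}" for i in range(1, self.mean_matrix.shape[0] + 1)]

    def region_map(self) -> dict[str, str]:
        return {c.label: c.region for c in self.clusters}


def generate_sc_matrix(config: ScSimConfig) -> SingleCellMatrix:
    """Simulate a genes x cells count matrix with cluster/region structure."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    means = config.mean_matrix
    genes = config.genes

    blocks, cell_ids, clusters, types = [], [], [], []
    for j, spec in enumerate(config.clusters):
        m = means[:, [j]]  # genes x 1
        if config.dispersion == 0:
            block = np.repeat(m, spec.n_cells, axis=1)
        else:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, np.repeat(m, spec.n_cells, axis=1) / shape)
            block = rng.poisson(lam).astype(float)
        blocks.append(block)
        cell_ids.extend(f"{spec.label}_c{i}" for i in range(1, spec.n_cells + 1))
        clusters.extend([spec.label] * spec.n_cells)
        types.extend([spec.cell_type] * spec.n_cells)

    counts = np.concatenate(blocks, axis=1)
    return SingleCellMatrix(
        genes,
        cell_ids,
        counts,
        pd.Series(clusters, index=cell_ids),
        pd.Series(types, index=cell_ids),
    )


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Binomial T-maze choice simulation: each of ``n_flies`` independently
    avoids the shock-paired odor with probability ``p_correct``."""

    n_flies: int = 100
    p_correct: float = 0.75
    n_trials: int = 2
    seed: int = 0
    group: str = "sim"

    def __post_init__(self) -> None:
        _require(self.n_flies >= 1, "n_flies", "must be a positive integer")
        _require(0 <= self.p_correct <= 1, "p_correct", "must be in [0, 1]")
        _require(self.n_trials >= 1, "n_trials", "must be a positive integer")


def generate_behavior_counts(config: BehaviorSimConfig) -> list[BehaviorTrial]:
    """Simulate learning trials; odors alternate MCH/OCT so consecutive
    trials form reciprocal pairs. Expected PI = (2·p_correct − 1)·100%."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    trials = []
    for i in range(config.n_trials):
        n_minus = int(rng.binomial(config.n_flies, config.p_correct))
        trials.append(
            BehaviorTrial(
                "learning",
                odor="MCH" if i % 2 == 0 else "OCT",
                group=config.group,
                n_cs_minus=n_minus,
                n_cs_plus=config.n_flies - n_minus,
            )
        )
    return trials
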