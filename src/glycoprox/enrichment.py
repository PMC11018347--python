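"""Differential-enrichment calling of candidate O-GlcNAc substrates.

The experimental contrast is TurboID-CpOGA^CD (catalytically dead but still
binding O-GlcNAc, so biotinylating substrates and their neighbours) against
TurboID-CpOGA^DM (additionally binding-dead; the specificity control). A
protein whose label-free quantification (LFQ) intensity is reproducibly higher
in the CD pulldown than in the DM pulldown is a candidate substrate.

Pipeline per brain region:

1. drop MaxQuant artefact rows (contaminant / reverse / only-identified-by-site
   flags);
2. transform every intensity to log2(intensity + 1) — the pseudocount keeps
   unquantified zeros finite;
3. log2 fold change = mean(log2 CD) − mean(log2 DM) across replicates, with a
   two-sided unpaired Student's t-test on the transformed replicate values;
4. apply the calling policy: HEK-style calling uses the fold-change threshold
   alone, brain-region calling additionally admits statistically significant
   proteins and requires detection in at least ``min_cd_detected`` CD
   replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProteinGroupTable, SampleDesign
from .stats import two_sample_t

__all__ = [
    "CallingPolicy",
    "HEK_POLICY",
    "BRAIN_POLICY",
    "filter_contaminants",
    "log2_with_pseudocount",
    "enrich",
    "call_substrates",
]

#: column order of the enrichment-record table
RECORD_COLUMNS = [
    "protein_group_id",
    "gene_symbol",
    "region",
    "mean_log2_cd",
    "mean_log2_dm",
    "log2_fc",
    "t_statistic",
    "p_value",
    "n_detected_cd",
    "n_detected_dm",
    "peptide_count",
    "called",
    "call_basis",
]


@dataclass(frozen=True)
class CallingPolicy:
    """Substrate-calling rule.

    mode="hek": called ⇔ peptide_count ≥ min_peptides and log2_fc > fc_threshold.
    mode="brain": additionally requires detection (intensity > 0) in at least
    ``min_cd_detected`` CD replicates, and also calls proteins with
    p < alpha (restricted to positive log2_fc unless
    ``require_positive_fc_for_pvalue_call`` is disabled, so that significant
    depletion is never called enrichment).

    ``use_bh`` switches the p-value branch to Benjamini–Hochberg adjusted
    p-values; off by default (raw p < alpha).
    """

    mode: str = "brain"
    fc_threshold: float = 1.0
    alpha: float = 0.05
    min_peptides: int = 2
    min_cd_detected: int = 2
    require_positive_fc_for_pvalue_call: bool = True
    use_bh: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("hek", "brain"):
            raise ValueError(f"mode must be 'hek' or 'brain', got {self.mode!r}")
        if not self.fc_threshold > 0:
            raise ValueError("fc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


HEK_POLICY = CallingPolicy(mode="hek")
BRAIN_POLICY = CallingPolicy(mode="brain")


def filter_contaminants(table: ProteinGroupTable) -> ProteinGroupTable:
    """Remove rows flagged contaminant, reverse, or only-identified-by-site."""
    f = table.frame
    keep = ~(f["contaminant"] | f["reverse"] | f["only_by_site"])
    return table.subset(keep)


def log2_with_pseudocount(intensity):
    """log2(intensity + 1); accepts scalars or arrays, rejects negatives."""
    arr = np.asarray(intensity, dtype=float)
    if (arr < 0).any():
        raise ValueError("intensities must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(intensity) else out


def enrich(table: ProteinGroupTable, design: SampleDesign, region: str) -> pd.DataFrame:
    """Per-protein CD-vs-DM enrichment statistics for one brain region.

    Returns a DataFrame with :data:`RECORD_COLUMNS` (``called``/``call_basis``
    initialised to False/"none"; set by :func:`call_substrates`). ``p_value``
    is NaN when a construct has fewer than two replicates.
    """
    design.check_covers(table)
    if region not in design.regions:
        raise KeyError(f"region {region!r} not present in sample design")
    cd_samples = design.samples_for(region, "CD")
    dm_samples = design.samples_for(region, "DM")
    if not cd_samples or not dm_samples:
        raise KeyError(f"region {region!r} lacks CD or DM samples")

    raw_cd = table.frame[cd_samples].to_numpy(dtype=float)
    raw_dm = table.frame[dm_samples].to_numpy(dtype=float)
    log_cd = log2_with_pseudocount(raw_cd)
    log_dm = log2_with_pseudocount(raw_dm)

    mean_cd = log_cd.mean(axis=1)
    mean_dm = log_dm.mean(axis=1)
    can_test = len(cd_samples) >= 2 and len(dm_samples) >= 2
    t_stats = np.full(len(table), np.nan)
    p_vals = np.full(len(table), np.nan)
    if can_test:
        for i in range(len(table)):
            res = two_sample_t(log_cd[i], log_dm[i])
            t_stats[i] = res.statistic
            p_vals[i] = res.p_value

    return pd.DataFrame(
        {
            "protein_group_id": table.frame["protein_group_id"],
            "gene_symbol": table.frame["gene_symbol"],
            "region": region,
            "mean_log2_cd": mean_cd,
            "mean_log2_dm": mean_dm,
            "log2_fc": mean_cd - mean_dm,
            "t_statistic": t_stats,
            "p_value": p_vals,
            "n_detected_cd": (raw_cd > 0).sum(axis=1),
            "n_detected_dm": (raw_dm > 0).sum(axis=1),
            "peptide_count": table.frame["peptide_count"],
            "called": False,
            "call_basis": "none",
        },
        columns=RECORD_COLUMNS,
    )


def call_substrates(records: pd.DataFrame, policy: CallingPolicy) -> pd.DataFrame:
    """Apply a calling policy; returns a copy with ``called``/``call_basis`` set.

    ``call_basis`` records which branch fired: "fc", "pvalue", "both", or
    "none". An undefined p-value (NaN) simply disables the p-value branch.
    """
    rec = records.copy()
    fc = rec["log2_fc"].to_numpy(dtype=float)
    p = rec["p_value"].to_numpy(dtype=float)
    peptides_ok = rec["peptide_count"].to_numpy() >= policy.min_peptides

    fc_hit = fc > policy.fc_threshold
    if policy.mode == "hek":
        eligible = peptides_ok
        pv_hit = np.zeros(len(rec), dtype=bool)
    else:
        eligible = peptides_ok & (rec["n_detected_cd"].to_numpy() >= policy.min_cd_detected)
        p_eff = p
        if policy.use_bh:
            from statsmodels.stats.multitest import multipletests

            p_eff = np.full(len(rec), np.nan)
            defined = ~np.isnan(p)
            if defined.any():
                p_eff[defined] = multipletests(p[defined], method="fdr_bh")[1]
        with np.errstate(invalid="ignore"):
            pv_hit = p_eff < policy.alpha  # NaN compares False
        if policy.require_positive_fc_for_pvalue_call:
            pv_hit &= fc > 0

    fc_hit &= eligible
    pv_hit &= eligible
    rec["called"] = fc_hit | pv_hit
    basis = np.where(
        fc_hit & pv_hit, "both", np.where(fc_hit, "fc", np.where(pv_hit, "pvalue", "none"))
    )
    rec["call_basis"] = basis
    return rec
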