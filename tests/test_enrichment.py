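"""Differential-enrichment statistics and substrate-calling rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoprox import enrichment as en
from glycoprox import io as gio
from glycoprox.io import SampleDesign, SampleInfo
from glycoprox.simulate import LfqSimConfig, generate_lfq_table


def make_table(cd, dm, peptides=3, flags=(False, False, False), n_rows=1):
    """One-region table with given CD/DM intensity vectors per row."""
    cd, dm = np.atleast_2d(cd), np.atleast_2d(dm)
    samples = [f"MB_CD_{i+1}" for i in range(cd.shape[1])] + [
        f"MB_DM_{i+1}" for i in range(dm.shape[1])
    ]
    frame = pd.DataFrame(
        {
            "protein_group_id": [f"P{i}" for i in range(cd.shape[0])],
            "gene_symbol": [f"G{i}" for i in range(cd.shape[0])],
            "peptide_count": peptides,
            "contaminant": flags[0],
            "reverse": flags[1],
            "only_by_site": flags[2],
        }
    )
    for j, s in enumerate(samples):
        block = cd if j < cd.shape[1] else dm
        frame[s] = block[:, j if j < cd.shape[1] else j - cd.shape[1]].astype(float)
    return gio.ProteinGroupTable(frame, samples)


def make_design(n_cd, n_dm, region="MB"):
    samples = {f"{region}_CD_{i+1}": SampleInfo(region, "CD", i + 1) for i in range(n_cd)}
    samples |= {f"{region}_DM_{i+1}": SampleInfo(region, "DM", i + 1) for i in range(n_dm)}
    return SampleDesign(samples)


class TestFilterContaminants:
    def test_flagged_rows_removed_counted(self, small_lfq):
        _, table, truth, _ = small_lfq
        kept = en.filter_contaminants(table)
        assert len(kept) == len(table) - len(truth.contaminant_ids)
        assert not kept.frame["protein_group_id"].isin(truth.contaminant_ids).any()
        # order of survivors preserved
        surv = table.frame.loc[
            ~table.frame["protein_group_id"].isin(truth.contaminant_ids), "protein_group_id"
        ]
        assert kept.frame["protein_group_id"].tolist() == surv.tolist()

    def test_all_rows_flagged_gives_empty(self):
        t = make_table([[4, 4, 4]], [[2, 2, 2]], flags=(False, True, False))
        assert len(en.filter_contaminants(t)) == 0


class TestLog2Pseudocount:
    @pytest.mark.parametrize("x,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_exact_values(self, x, expected):
        assert en.log2_with_pseudocount(x) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            en.log2_with_pseudocount(-1.0)

    @given(st.floats(min_value=0, max_value=1e12), st.floats(min_value=0, max_value=1e12))
    @settings(derandomize=True, max_examples=50)
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert en.log2_with_pseudocount(lo) <= en.log2_with_pseudocount(hi)


class TestEnrich:
    def test_detected_counts_and_fc_for_all_or_nothing(self):
        # raw CD (7,7,7) vs DM (0,0,0): transformed (3,3,3) vs (0,0,0)
        rec = en.enrich(make_table([[7, 7, 7]], [[0, 0, 0]]), make_design(3, 3), "MB").iloc[0]
        assert rec.log2_fc == 3.0
        assert (rec.n_detected_cd, rec.n_detected_dm) == (3, 0)
        assert rec.p_value == 0.0  # degenerate: both groups constant, unequal

    def test_identical_groups_fc_zero_p_one(self):
        rec = en.enrich(make_table([[1, 3, 7]], [[1, 3, 7]]), make_design(3, 3), "MB").iloc[0]
        assert rec.log2_fc == 0.0
        assert rec.p_value == 1.0

    def test_swapping_constructs_negates_fc_keeps_p(self):
        t_fwd = make_table([[10, 20, 40]], [[5, 10, 80]])
        t_rev = make_table([[5, 10, 80]], [[10, 20, 40]])
        design = make_design(3, 3)
        fwd = en.enrich(t_fwd, design, "MB").iloc[0]
        rev = en.enrich(t_rev, design, "MB").iloc[0]
        assert fwd.log2_fc == pytest.approx(-rev.log2_fc, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_single_replicate_yields_undefined_p(self):
        rec = en.enrich(make_table([[8]], [[2]]), make_design(1, 1), "MB").iloc[0]
        assert np.isnan(rec.p_value)
        assert rec.log2_fc == pytest.approx(np.log2(9) - np.log2(3))

    def test_unknown_region_raises(self, small_lfq):
        _, table, _, design = small_lfq
        with pytest.raises(KeyError, match="OL"):
            en.enrich(table, design, "OL")


class TestCalling:
    def row(self, **kw):
        base = dict(
            protein_group_id="P", gene_symbol="G", region="MB",
            mean_log2_cd=0.0, mean_log2_dm=0.0, log2_fc=0.0, t_statistic=0.0,
            p_value=0.5, n_detected_cd=3, n_detected_dm=3, peptide_count=3,
            called=False, call_basis="none",
        )
        base.update(kw)
        return pd.DataFrame([base], columns=en.RECORD_COLUMNS)

    def test_brain_fc_branch(self):
        out = en.call_substrates(self.row(log2_fc=1.5, p_value=0.2), en.BRAIN_POLICY)
        assert out.called.iloc[0] and out.call_basis.iloc[0] == "fc"

    def test_brain_pvalue_branch(self):
        out = en.call_substrates(
            self.row(log2_fc=0.5, p_value=0.01, peptide_count=2), en.BRAIN_POLICY
        )
        assert out.called.iloc[0] and out.call_basis.iloc[0] == "pvalue"

    def test_brain_detection_filter_blocks_call(self):
        out = en.call_substrates(
            self.row(log2_fc=5.0, p_value=0.001, n_detected_cd=1), en.BRAIN_POLICY
        )
        assert not out.called.iloc[0]

    def test_peptide_filter_blocks_call(self):
        out = en.call_substrates(self.row(log2_fc=5.0, peptide_count=1), en.BRAIN_POLICY)
        assert not out.called.iloc[0]

    def test_significant_depletion_not_called(self):
        out = en.call_substrates(self.row(log2_fc=-2.0, p_value=0.001), en.BRAIN_POLICY)
        assert not out.called.iloc[0]
        permissive = en.CallingPolicy(mode="brain", require_positive_fc_for_pvalue_call=False)
        out2 = en.call_substrates(self.row(log2_fc=-2.0, p_value=0.001), permissive)
        assert out2.called.iloc[0]

    def test_hek_mode_ignores_pvalue_and_detection(self):
        row = self.row(log2_fc=0.5, p_value=0.001, n_detected_cd=0)
        assert not en.call_substrates(row, en.HEK_POLICY).called.iloc[0]
        row2 = self.row(log2_fc=1.5, p_value=0.9, n_detected_cd=0)
        out = en.call_substrates(row2, en.HEK_POLICY)
        assert out.called.iloc[0] and out.call_basis.iloc[0] == "fc"

    def test_both_basis_recorded(self):
        out = en.call_substrates(self.row(log2_fc=2.0, p_value=0.01), en.BRAIN_POLICY)
        assert out.call_basis.iloc[0] == "both"

    def test_undefined_p_only_fc_branch(self):
        out = en.call_substrates(self.row(log2_fc=0.5, p_value=np.nan), en.BRAIN_POLICY)
        assert not out.called.iloc[0]

    def test_bh_option_is_more_conservative(self):
        rows = pd.concat(
            [self.row(protein_group_id=f"P{i}", log2_fc=0.5, p_value=p)
             for i, p in enumerate([0.04, 0.5, 0.6, 0.7, 0.8])],
            ignore_index=True,
        )
        raw = en.call_substrates(rows, en.BRAIN_POLICY)
        bh = en.call_substrates(rows, en.CallingPolicy(mode="brain", use_bh=True))
        assert raw.called.sum() == 1 and bh.called.sum() == 0


class TestRecoveryProperties:
    def test_null_calibration(self):
        # no effect, Gaussian log2 noise, no missingness: p<0.05 at ~5%
        config = LfqSimConfig(
            n_proteins=10000, substrate_fraction=0.0, dropout_rate=0.0,
            contaminant_fraction=0.0, seed=42,
        )
        table, _ = generate_lfq_table(config)
        rec = en.enrich(table, config.design(), "MB")
        rate = (rec["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_sensitivity_monotone_in_effect(self):
        sens = []
        for effect in (0.5, 1.0, 2.0):
            config = LfqSimConfig(
                n_proteins=600, substrate_fraction=0.2, effect_log2fc=effect,
                dropout_rate=0.0, contaminant_fraction=0.0, seed=8,
            )
            table, truth = generate_lfq_table(config)
            called = en.call_substrates(
                en.enrich(table, config.design(), "MB"), en.BRAIN_POLICY
            )
            hits = set(called.loc[called.called, "protein_group_id"])
            sens.append(len(hits & truth.substrate_ids) / len(truth.substrate_ids))
        assert sens[0] <= sens[1] <= sens[2]
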