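import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from hubtrace import quant_filter
from hubtrace.synthetic_data import make_quant_table


def table_from_wide(rows):
    """rows: {protein: {group: [replicate ratios]}} -> QuantTable."""
    recs = []
    for prot, groups in rows.items():
        for group, ratios in groups.items():
            for r, val in enumerate(ratios, 1):
                recs.append((prot, group, r, val))
    return quant_filter.QuantTable(
        pd.DataFrame(recs, columns=["protein_id", "group", "replicate", "ratio"]))


class TestLog2FoldChange:
    @pytest.mark.parametrize("ratio,expected", [(1.5, 0.585), (1.0, 0.0), (2.0, 1.0)])
    def test_values(self, ratio, expected):
        assert quant_filter.log2_fold_change(ratio) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValueError):
            quant_filter.log2_fold_change(0.0)


class TestTestContrast:
    def test_identical_groups_p_one(self):
        assert quant_filter.test_contrast([2, 2, 2], [2, 2, 2]) == 1.0

    def test_separated_groups_small_p(self):
        p = quant_filter.test_contrast([10, 10.1, 9.9], [1, 1.1, 0.9])
        assert p < 0.001

    def test_matches_permutation_oracle(self):
        # permutation distribution of the mean difference on log2 ratios
        rng = np.random.default_rng(0)
        case = np.array([1.9, 2.4, 2.1, 2.8])
        ctrl = np.array([1.0, 1.3, 0.9, 1.1])
        obs = abs(np.log2(case).mean() - np.log2(ctrl).mean())
        pooled = np.log2(np.concatenate([case, ctrl]))
        count = 0
        n_draws = 10_000
        for _ in range(n_draws):
            perm = rng.permutation(pooled)
            count += abs(perm[:4].mean() - perm[4:].mean()) >= obs - 1e-12
        p_perm = count / n_draws
        p_t = quant_filter.test_contrast(case, ctrl)
        assert p_t == pytest.approx(p_perm, abs=0.03)

    def test_single_replicate_undefined(self):
        assert math.isnan(quant_filter.test_contrast([2.0], [1.0, 1.1]))


class TestSelectDeregulated:
    def base_table(self):
        return table_from_wide({
            "UP":   {"case": [1.6, 1.62, 1.58], "control": [1.0, 1.01, 0.99]},
            "DOWN": {"case": [0.60, 0.61, 0.59], "control": [1.0, 0.99, 1.01]},
            "FLAT": {"case": [1.02, 0.98, 1.0], "control": [1.0, 1.0, 1.01]},
        })

    def test_thresholds_and_directions(self):
        de = quant_filter.select_deregulated(self.base_table(), ("case", "control"))
        sel = de.selected.set_index("protein_id")
        assert set(sel.index) == {"UP", "DOWN"}
        assert sel.loc["UP", "direction"] == "up"
        assert sel.loc["DOWN", "direction"] == "down"
        # |log2 0.60| = 0.737 >= 0.585
        assert abs(sel.loc["DOWN", "log2_fc"]) == pytest.approx(0.737, abs=1e-3)
        assert de.n_up == 1 and de.n_down == 1

    def test_nonsignificant_rejected_when_both_required(self):
        noisy = table_from_wide({
            "P": {"case": [1.9, 0.8, 2.6], "control": [1.0, 1.4, 0.8]}})
        de = quant_filter.select_deregulated(noisy, ("case", "control"))
        assert len(de) == 0
        de_fc = quant_filter.select_deregulated(noisy, ("case", "control"),
                                                require_both=False)
        assert len(de_fc) == 1  # fold-change-only mode keeps it

    def test_unknown_contrast_errors(self):
        with pytest.raises(KeyError, match="treated"):
            quant_filter.select_deregulated(self.base_table(), ("treated", "control"))

    def test_under_replicated_flagged(self):
        t = table_from_wide({"P": {"case": [1.7], "control": [1.0, 1.0, 1.0]}})
        de = quant_filter.select_deregulated(t, ("case", "control"))
        assert de.table["p_undefined"].all()
        assert len(de) == 0

    def test_bh_adjustment_reported_alongside(self):
        de = quant_filter.select_deregulated(self.base_table(), ("case", "control"),
                                             adjust="bh")
        assert "p_adj" in de.table.columns
        assert (de.table["p_adj"] >= de.table["p"] - 1e-12).all()

    def test_ratio_scale_equivalence(self):
        """|log2 FC| >= log2(f) selects the same set as mean ratio outside (1/f, f)."""
        rng = np.random.default_rng(123)
        for trial in range(40):
            n = 30
            t = table_from_wide({
                f"P{i}": {"case": list(np.exp(rng.normal(0, 0.7, 3))),
                          "control": list(np.exp(rng.normal(0, 0.2, 3)))}
                for i in range(n)})
            f = float(rng.uniform(1.1, 3.0))
            de = quant_filter.select_deregulated(t, ("case", "control"),
                                                 fc_threshold=f, require_both=False)
            mr = de.table.set_index("protein_id")["mean_ratio"]
            by_ratio = set(mr.index[(mr >= f) | (mr <= 1 / f)])
            assert set(de.proteins) == by_ratio

    def test_tightening_thresholds_never_adds(self):
        gen = make_quant_table(n_proteins=120, n_deregulated=30, n_up=20, seed=9)
        loose = quant_filter.select_deregulated(gen.table, ("case", "control"),
                                                fc_threshold=1.3, p_threshold=0.1)
        tight_fc = quant_filter.select_deregulated(gen.table, ("case", "control"),
                                                   fc_threshold=1.6, p_threshold=0.1)
        tight_p = quant_filter.select_deregulated(gen.table, ("case", "control"),
                                                  fc_threshold=1.3, p_threshold=0.01)
        assert set(tight_fc.proteins) <= set(loose.proteins)
        assert set(tight_p.proteins) <= set(loose.proteins)

    def test_planted_recovery_at_defaults(self):
        gen = make_quant_table(seed=3)
        de = quant_filter.select_deregulated(gen.table, ("case", "control"))
        planted = set(gen.planted)
        sel = set(de.proteins)
        tp = len(sel & planted)
        assert tp / len(planted) >= 0.9          # sensitivity
        assert (len(sel) - tp) / max(len(sel), 1) <= 0.1  # false-discovery proportion


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 100.0), st.floats(1.01, 5.0))
def test_fold_threshold_on_log_and_ratio_scales_agree(ratio, f):
    """The two textbook writings of the fold-change rule are the same rule."""
    assume(abs(ratio - f) / f > 1e-9 and abs(ratio * f - 1.0) > 1e-9)
    on_log = abs(math.log2(ratio)) >= math.log2(f)
    on_ratio = ratio >= f or ratio <= 1 / f
    assert on_log == on_ratio


class TestIntersectLists:
    def test_common_candidate_from_four_lists(self):
        venn = quant_filter.intersect_lists({
            "regulators": ["C9", "A", "B"],
            "dereg_case": ["C9", "D"],
            "dereg_treated": ["C9", "E"],
            "significant": ["C9", "F"],
        })
        assert venn.common == {"C9"}
        top = venn.membership.iloc[0]
        assert top["element"] == "C9" and top["n_lists"] == 4

    def test_disjoint_lists_empty(self):
        venn = quant_filter.intersect_lists({"a": ["X"], "b": ["Y"]})
        assert venn.common == set()

    def test_five_lists_no_common(self):
        lists = {f"l{i}": [f"P{i}", "Q"] for i in range(4)}
        lists["l4"] = ["P4", "R"]  # breaks the Q overlap
        venn = quant_filter.intersect_lists(lists)
        assert venn.common == set()

    def test_pairwise_overlap_counts(self):
        venn = quant_filter.intersect_lists(
            {"a": ["X", "Y"], "b": ["Y", "Z"], "c": ["Z"]})
        pw = venn.pairwise.set_index(["list_a", "list_b"])["overlap"]
        assert pw[("a", "b")] == 1
        assert pw[("a", "c")] == 0

    def test_fewer_than_two_lists_errors(self):
        with pytest.raises(ValueError):
            quant_filter.intersect_lists({"only": ["X"]})

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            quant_filter.intersect_lists({"a": ["X"], "b": []})
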