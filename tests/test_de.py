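"""Differential-expression rules: fold change, 2-SD gate, pooled t, tallies."""

import math

import numpy as np
import pytest
from scipy import stats

from phagetime.de import (
    DEThresholds,
    de_call_late_vs_early,
    de_call_vs_control,
    format_tally,
    log2_fold_change,
    tally_de,
)
from tests.conftest import FULL_TIMES, make_counts


def textbook_pooled_t_p(x, y):
    """Pooled-variance two-sample t-test, written from the textbook formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2.0 * stats.t.sf(abs(t), nx + ny - 2)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "mean,ref,pseudo,expected",
        [
            (10, 10, 1, 0.0),
            (79, 9, 1, 3.0),      # log2(80/10)
            (0, 0, 1, 0.0),
            (0, 0, 0, 0.0),       # degenerate without pseudocount
        ],
    )
    def test_forced_arithmetic(self, mean, ref, pseudo, expected):
        assert log2_fold_change(mean, ref, pseudo) == pytest.approx(expected)

    def test_pseudocount_zero_gives_signed_infinities(self):
        assert log2_fold_change(5, 0, 0) == math.inf
        assert log2_fold_change(0, 5, 0) == -math.inf

    def test_antisymmetry(self, rng):
        for _ in range(200):
            a, b = rng.uniform(0, 1000, 2)
            assert log2_fold_change(a, b) == pytest.approx(
                -log2_fold_change(b, a), abs=1e-12
            )


def _counts_one_gene(early_vals, control):
    row = [control] + list(early_vals) + [0] * (10 - 1 - len(early_vals))
    return make_counts({"g": row}, FULL_TIMES, normalized=True)


class TestVsControl:
    def test_no_change_is_ns(self):
        counts = _counts_one_gene([100, 100], 100)
        (call,) = de_call_vs_control(counts, ["t02", "t05"], "t00").to_dict("records")
        assert call["log2fc"] == 0
        assert call["group_sd"] == 0
        assert not call["control_outside_2sd"]
        assert call["status"] == "ns"

    def test_forced_up_call(self):
        counts = _counts_one_gene([64, 64], 8)
        (call,) = de_call_vs_control(counts, ["t02", "t05"], "t00").to_dict("records")
        assert call["log2fc"] == pytest.approx(math.log2(65 / 9))
        assert call["control_outside_2sd"]
        assert call["status"] == "up"

    def test_control_inside_band_blocks_call(self):
        # mean 60, sd ~56.6: control 55 inside +/-2SD -> ns despite any log2fc
        counts = _counts_one_gene([100, 20], 55)
        (call,) = de_call_vs_control(counts, ["t02", "t05"], "t00").to_dict("records")
        sd = np.std([100, 20], ddof=1)
        assert call["group_sd"] == pytest.approx(sd)
        assert abs(55 - 60) <= 2 * sd
        assert not call["control_outside_2sd"]
        assert call["status"] == "ns"

    def test_group_of_one_rejected(self):
        counts = _counts_one_gene([64, 64], 8)
        with pytest.raises(ValueError, match=">=2 samples"):
            de_call_vs_control(counts, ["t02"], "t00")

    def test_two_sd_gate_scale_invariant_without_pseudocount(self, rng):
        thr = DEThresholds(pseudocount=0.0)
        for _ in range(50):
            vals = rng.uniform(1, 500, 3)
            c = rng.uniform(0.1, 20)
            a = _counts_one_gene(vals[:2], vals[2])
            b = _counts_one_gene(vals[:2] * c, vals[2] * c)
            ca = de_call_vs_control(a, ["t02", "t05"], "t00", thr).iloc[0]
            cb = de_call_vs_control(b, ["t02", "t05"], "t00", thr).iloc[0]
            assert ca.control_outside_2sd == cb.control_outside_2sd
            assert ca.log2fc == pytest.approx(cb.log2fc)
            assert ca.status == cb.status


def _counts_late_vs_early(early_vals, late_vals):
    row = [0.0] + [float(v) for v in early_vals] + [0.0] * 3 + [
        float(v) for v in late_vals
    ]
    return make_counts({"g": row}, FULL_TIMES, normalized=True)


class TestLateVsEarly:
    def test_identical_groups_ns(self):
        counts = _counts_late_vs_early([10, 10], [10, 10, 10, 10])
        (call,) = de_call_late_vs_early(
            counts, ["t02", "t05"], ["t28", "t35", "t42", "t49"]
        ).to_dict("records")
        assert call["log2fc"] == 0
        assert call["p_value"] == 1.0       # zero pooled variance, equal means
        assert call["status"] == "ns"

    def test_strong_shift_called_up(self, rng):
        early = 10 + rng.normal(0, 0.1, 3)
        late = 80 + rng.normal(0, 0.1, 4)
        counts = _counts_late_vs_early(list(early[:2]), list(late))
        counts.values.loc["g", "t10"] = early[2]  # 3rd early sample
        call = de_call_late_vs_early(
            counts, ["t02", "t05", "t10"], ["t28", "t35", "t42", "t49"]
        ).iloc[0]
        assert call.log2fc > 1.5 and call.p_value < 1e-6
        assert call.status == "up"
        assert call.p_value == pytest.approx(
            textbook_pooled_t_p(late, early), abs=1e-10
        )

    def test_small_fold_change_ns_despite_significance(self):
        counts = _counts_late_vs_early([10, 20], [12, 18, 14, 16])
        counts.values.loc["g", "t10"] = 15  # 3rd early sample
        call = de_call_late_vs_early(
            counts, ["t02", "t05", "t10"], ["t28", "t35", "t42", "t49"]
        ).iloc[0]
        assert abs(call.log2fc) < 1.5
        assert call.status == "ns"

    def test_pvalues_match_textbook_formula(self, rng):
        for _ in range(100):
            x = rng.uniform(0, 100, 2 + int(rng.integers(0, 3)))
            y = rng.uniform(0, 100, 2 + int(rng.integers(0, 3)))
            row = [0.0] * 10
            counts = make_counts({"g": row}, FULL_TIMES, normalized=True)
            ids = counts.sample_ids
            ex, lt = ids[1 : 1 + len(x)], ids[6 : 6 + len(y)]
            counts.values.loc["g", ex] = x
            counts.values.loc["g", lt] = y
            call = de_call_late_vs_early(counts, ex, lt).iloc[0]
            assert call.p_value == pytest.approx(
                textbook_pooled_t_p(y, x), abs=1e-10
            )

    def test_statuses_mutually_exclusive(self, default_sim):
        _cfg, _f, counts, _iv, _t = default_sim
        from phagetime.normalize import total_count_normalize

        norm = total_count_normalize(counts, "host_only")
        early = [s.sample_id for s in counts.samples if s.time_min in (2, 5)]
        late = [s.sample_id for s in counts.samples
                if s.time_min in (28, 35, 42, 49)]
        table = de_call_late_vs_early(norm, early, late)
        assert set(table.status) <= {"up", "down", "ns"}
        up = table.status == "up"
        down = table.status == "down"
        assert not (up & down).any()


class TestTally:
    def test_printed_tally_arithmetic(self):
        import pandas as pd

        calls = pd.DataFrame(
            {"status": ["down"] * 112 + ["up"] * 7 + ["ns"] * (4349 - 119)}
        )
        t = format_tally(tally_de(calls, n_total_genes=4349))
        assert t["n_de"] == 119
        assert t["genome_pct_down"] == 2.58

    def test_zero_calls(self):
        import pandas as pd

        t = tally_de(pd.DataFrame({"status": []}), n_total_genes=100)
        assert t["n_up"] == t["n_down"] == t["n_de"] == 0

    def test_percentages_recompute_from_integer_tallies(self, rng):
        import pandas as pd

        n_up, n_down, n_ns = rng.integers(0, 50, 3)
        calls = pd.DataFrame(
            {"status": ["up"] * n_up + ["down"] * n_down + ["ns"] * n_ns}
        )
        t = tally_de(calls, n_total_genes=1000)
        assert t["genome_pct_de"] == pytest.approx(100 * (n_up + n_down) / 1000)
        if n_up + n_down:
            assert t["up_of_de_pct"] == pytest.approx(
                100 * n_up / (n_up + n_down)
            )
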