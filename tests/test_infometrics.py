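import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensnet import (AlertFlags, ChemicalRecord, best_mw_threshold, entropy,
                     information_gain, module_stats_table, normalized_gain)
from sensnet.infometrics import MwSplit, stats_to_frame
from sensnet.network import ModulePartition


def entropy_oracle(n_sens, n_non):
    """Direct closed-form evaluation, independent of the implementation."""
    total = n_sens + n_non
    h = 0.0
    for n in (n_sens, n_non):
        if n:
            h -= (n / total) * math.log2(n / total)
    return h


class TestEntropy:
    def test_pure_module_has_zero_entropy(self):
        assert entropy(0, 47) == 0.0
        assert entropy(12, 0) == 0.0

    def test_even_mixture_has_unit_entropy(self):
        assert entropy(10, 10) == pytest.approx(1.0)

    def test_21_79_mixture(self):
        assert entropy(21, 79) == pytest.approx(0.7415, abs=5e-5)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            entropy(0, 0)

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    @settings(deadline=None, max_examples=200)
    def test_symmetry_bounds_and_oracle(self, a, b):
        if a + b == 0:
            return
        h = entropy(a, b)
        assert h == entropy(b, a)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(entropy_oracle(a, b))
        assert (h == pytest.approx(1.0)) == (a == b)
        assert (h == 0.0) == (a == 0 or b == 0)


class TestInformationGain:
    def test_perfect_split_recovers_parent_entropy(self):
        labels = [True, True, False, False]
        feature = [True, True, False, False]
        assert information_gain(labels, feature) == pytest.approx(1.0)

    def test_constant_feature_gains_nothing(self):
        labels = [True, True, False, False]
        assert information_gain(labels, [True] * 4) == pytest.approx(0.0)

    def test_hand_computed_six_chemical_instance(self):
        # 3 sens / 3 non; feature true for 2 sens + 1 non:
        # gain = H(3,3) - (3/6)H(2,1) - (3/6)H(1,2) = 1 - 0.9183 = 0.0817
        labels = [True, True, True, False, False, False]
        feature = [True, True, False, True, False, False]
        assert information_gain(labels, feature) == pytest.approx(0.0817, abs=5e-5)

    def test_accepts_label_vocabulary_strings(self):
        labels = ["sensitizer", "non-sensitizer"]
        assert information_gain(labels, [True, False]) == pytest.approx(1.0)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=40))
    @settings(deadline=None, max_examples=200)
    def test_gain_bounded_by_parent_entropy(self, pairs):
        labels = [lab for lab, _ in pairs]
        feature = [f for _, f in pairs]
        parent = entropy(sum(labels), len(labels) - sum(labels))
        gain = information_gain(labels, feature)
        assert -1e-9 <= gain <= parent + 1e-9


class TestNormalizedGain:
    def test_perfect_separation_scores_100(self):
        assert normalized_gain(0.7415, 0.7415) == pytest.approx(100.0)

    def test_zero_gain_scores_0(self):
        assert normalized_gain(0.0, 0.9) == 0.0

    def test_pure_parent_is_not_applicable(self):
        assert normalized_gain(0.0, 0.0) is None

    def test_gain_exceeding_parent_rejected(self):
        with pytest.raises(ValueError):
            normalized_gain(0.5, 0.4)


def exhaustive_mw_oracle(mws, labels):
    """Scan every midpoint with a from-scratch gain computation."""
    distinct = sorted(set(mws))
    best_t, best_gain = None, -1.0
    for a, b in zip(distinct, distinct[1:]):
        t = (a + b) / 2
        below = [lab for mw, lab in zip(mws, labels) if mw < t]
        above = [lab for mw, lab in zip(mws, labels) if mw >= t]
        n = len(labels)
        parent = entropy_oracle(sum(labels), n - sum(labels))
        gain = parent
        for side in (below, above):
            if side:
                gain -= len(side) / n * entropy_oracle(sum(side),
                                                       len(side) - sum(side))
        if gain > best_gain + 1e-9:
            best_t, best_gain = t, gain
    return best_t, max(best_gain, 0.0)


class TestBestMwThreshold:
    def test_perfect_separation_yields_gap_midpoint_and_gain_100(self):
        mws = [100.0, 150.0, 190.0, 300.0, 420.0]
        labels = [True, True, True, False, False]
        split = best_mw_threshold(mws, labels)
        assert split.threshold == pytest.approx(245.0)  # midpoint of the gap
        assert split.norm_gain == pytest.approx(100.0)

    def test_label_independent_of_mw_gains_little(self):
        mws = [float(100 + 10 * i) for i in range(20)]
        labels = [i % 2 == 0 for i in range(20)]
        split = best_mw_threshold(mws, labels)
        assert split.norm_gain < 10.0

    def test_uniform_labels_report_na_threshold(self, caplog):
        split = best_mw_threshold([100.0, 200.0], [True, True])
        assert split == MwSplit(None, 0.0, None)

    @pytest.mark.parametrize("trial", range(100))
    def test_agrees_with_exhaustive_midpoint_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 50))
        mws = rng.uniform(50, 900, size=n).round(1).tolist()
        labels = (rng.random(n) < 0.4).tolist()
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        split = best_mw_threshold(mws, labels)
        t_oracle, gain_oracle = exhaustive_mw_oracle(mws, labels)
        assert split.gain == pytest.approx(gain_oracle, abs=1e-12)
        assert split.threshold == pytest.approx(t_oracle)


class TestModuleStatsTable:
    def _universe(self):
        def chem(cid, label, ma, mw):
            return ChemicalRecord(id=cid, label=label, mw=mw,
                                  alert_flags=AlertFlags(ma=ma).normalized())
        # module 0: alert 'ma' perfectly predicts the label
        m0 = [chem(f"a{i}", "sensitizer", True, 100.0 + i) for i in range(4)] + \
             [chem(f"b{i}", "non-sensitizer", False, 400.0 + i) for i in range(4)]
        # module 1: all non-sensitizers (pure)
        m1 = [chem(f"p{i}", "non-sensitizer", False, 200.0 + i) for i in range(3)]
        part = ModulePartition.from_communities(
            [{c.id for c in m0}, {c.id for c in m1}],
            labels={c.id: c.label for c in m0 + m1})
        return part, m0 + m1

    def test_pure_module_entropy_zero_and_gains_na(self):
        part, chems = self._universe()
        stats = {s.module: s for s in module_stats_table(part, chems)}
        assert stats["1"].entropy == 0.0
        assert all(v is None for v in stats["1"].alert_gains.values())
        assert stats["1"].mw_threshold is None

    def test_perfect_alert_scores_100_others_less(self):
        part, chems = self._universe()
        stats = {s.module: s for s in module_stats_table(part, chems)}
        assert stats["0"].alert_gains["MA"] == pytest.approx(100.0)
        assert stats["0"].alert_gains["RD"] == pytest.approx(100.0)
        assert stats["0"].alert_gains["SB"] == pytest.approx(0.0)
        # MW also separates perfectly in module 0 by construction
        assert stats["0"].mw_gain == pytest.approx(100.0)

    def test_single_chemical_module_entropy_zero(self):
        chem = ChemicalRecord(id="solo", label="sensitizer", mw=100.0,
                              alert_flags=AlertFlags())
        part = ModulePartition.from_communities([{"solo"}],
                                                labels={"solo": "sensitizer"})
        (_, _, stats) = module_stats_table(part, [chem])
        assert stats.entropy == 0.0

    def test_rd_gain_can_fall_below_specific_alert(self):
        # constructed instance: sb alone is perfectly predictive, while a
        # label-independent sn2 alert dilutes the RD (OR) feature
        def chem(cid, label, sb, sn2):
            return ChemicalRecord(id=cid, label=label, mw=150.0,
                                  alert_flags=AlertFlags(sb=sb, sn2=sn2).normalized())
        chems = [chem("s1", "sensitizer", True, False),
                 chem("s2", "sensitizer", True, True),
                 chem("n1", "non-sensitizer", False, True),
                 chem("n2", "non-sensitizer", False, False)]
        part = ModulePartition.from_communities(
            [{c.id for c in chems}], labels={c.id: c.label for c in chems})
        (_, _, stats) = module_stats_table(part, chems)
        assert stats.alert_gains["SB"] == pytest.approx(100.0)
        assert stats.alert_gains["RD"] < stats.alert_gains["SB"]

    def test_frame_mirrors_stats(self):
        part, chems = self._universe()
        frame = stats_to_frame(module_stats_table(part, chems))
        assert list(frame.columns) == ["Count", "Labeled", "Entropy", "SN2",
                                       "MA", "SB", "AA", "SNAr", "RD", "MW",
                                       "MW Threshold"]
        assert frame.loc["ALL", "Count"] == 11
        assert np.isnan(frame.loc["1", "MA"])
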