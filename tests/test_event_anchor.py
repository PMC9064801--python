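import numpy as np
import pandas as pd
import pytest

import viroconverge as vc
from viroconverge.diversity_metrics import DistanceResult
from viroconverge.event_anchor import WindowSpec, dunn_posthoc


def _meta_two_infants():
    infants = {
        "A": vc.InfantInfo("A", "case", gestational_age_weeks=25.0, event_dol=40.0),
        "K": vc.InfantInfo("K", "control", matched_case_id="A", gestational_age_weeks=25.0),
    }
    samples = {
        "A1": vc.SampleInfo("A1", "A", 33.0),
        "A2": vc.SampleInfo("A2", "A", 41.0),
        "K1": vc.SampleInfo("K1", "K", 38.0),
    }
    return vc.CohortMetadata(infants=infants, samples=samples)


class TestAnchor:
    def test_days_before_event_arithmetic(self):
        anchored = {a.sample_id: a for a in vc.anchor(_meta_two_infants())}
        assert anchored["A1"].days_before_event == pytest.approx(7.0)
        assert anchored["K1"].days_before_event == pytest.approx(2.0)
        assert anchored["A2"].days_before_event == pytest.approx(-1.0)
        assert anchored["A2"].post_event

    def test_translation_invariance_of_windows(self):
        """Shifting every day-of-life and event day by a constant leaves the
        window series unchanged."""
        meta = _meta_two_infants()
        shift = 13.0
        infants = {
            iid: vc.InfantInfo(
                iid,
                i.group,
                i.matched_case_id,
                i.gestational_age_weeks + shift / 7,  # keep PMA consistency irrelevant
                i.birth_weight_g,
                None if i.event_dol is None else i.event_dol + shift,
            )
            for iid, i in meta.infants.items()
        }
        samples = {
            sid: vc.SampleInfo(sid, s.infant_id, s.day_of_life + shift)
            for sid, s in meta.samples.items()
        }
        shifted = vc.CohortMetadata(infants=infants, samples=samples)
        spec = WindowSpec(width=7, step=2, max_lookback=21)
        w1 = vc.build_windows(spec, vc.anchor(meta))
        w2 = vc.build_windows(spec, vc.anchor(shifted))
        for a, b in zip(w1.windows, w2.windows):
            assert [s.sample_id for s in a.case_samples] == [s.sample_id for s in b.case_samples]
            assert [s.sample_id for s in a.control_samples] == [s.sample_id for s in b.control_samples]


class TestPairing:
    def _meta(self, control_days, extra_controls=()):
        infants = {
            "A": vc.InfantInfo("A", "case", gestational_age_weeks=25.0, event_dol=40.0),
            "K1": vc.InfantInfo("K1", "control", matched_case_id="A", gestational_age_weeks=25.0),
        }
        samples = {"A1": vc.SampleInfo("A1", "A", 20.0)}
        for k, d in enumerate(control_days):
            samples[f"K1.{k}"] = vc.SampleInfo(f"K1.{k}", "K1", d)
        for k, d in extra_controls:
            infants.setdefault("K2", vc.InfantInfo("K2", "control", matched_case_id="A", gestational_age_weeks=25.0))
            samples[f"K2.{k}"] = vc.SampleInfo(f"K2.{k}", "K2", d)
        return vc.CohortMetadata(infants=infants, samples=samples)

    def test_closest_in_tolerance_chosen(self):
        meta = self._meta([18.5, 24.0])
        pairs = vc.pair_samples(vc.anchor(meta), meta)
        assert len(pairs) == 1
        assert pairs[0].control_sample_id == "K1.0"
        assert pairs[0].delta_days == pytest.approx(1.5)

    def test_out_of_tolerance_unpaired(self):
        meta = self._meta([24.0])  # |delta| = 4.0 > 3.5
        assert vc.pair_samples(vc.anchor(meta), meta) == []

    def test_two_matched_controls_give_two_pairs(self):
        meta = self._meta([19.0], extra_controls=[(0, 22.0)])
        pairs = vc.pair_samples(vc.anchor(meta), meta)
        assert len(pairs) == 2
        assert {p.control_infant_id for p in pairs} == {"K1", "K2"}

    def test_tie_broken_toward_earlier_sample(self):
        meta = self._meta([18.0, 22.0])  # both |delta| = 2.0
        pairs = vc.pair_samples(vc.anchor(meta), meta)
        assert pairs[0].control_sample_id == "K1.0"


class TestWindows:
    def test_enumeration_lookback_25(self):
        series = vc.build_windows(WindowSpec(7, 2, 25), [])
        intervals = [(w.start, w.stop) for w in series.windows]
        assert intervals == [(float(k), float(k + 7)) for k in range(0, 19, 2)]
        assert len(intervals) == 10

    def test_sample_membership_half_open(self):
        meta = _meta_two_infants()  # A1 at 7.0 days before
        series = vc.build_windows(WindowSpec(7, 2, 25), vc.anchor(meta))
        member = [w.label for w in series.windows if any(s.sample_id == "A1" for s in w.case_samples)]
        assert member == ["9-2d", "11-4d", "13-6d"]

    def test_width_equals_step_tiles(self):
        series = vc.build_windows(WindowSpec(7, 7, 21), [])
        assert [(w.start, w.stop) for w in series.windows] == [(0.0, 7.0), (7.0, 14.0), (14.0, 21.0)]


class TestConvergenceSeries:
    def test_cross_infant_pairs_only(self, default_cohort, default_abundance, default_anchored):
        soer = vc.sorensen(vc.presence_matrix(default_abundance))
        pairs = vc.pair_samples(default_anchored, default_cohort["meta"])
        series = vc.convergence_series(
            soer, vc.build_windows(WindowSpec(7, 2, 25), default_anchored), pairs
        )
        for w in series.windows:
            n_case = len(w.case_samples)
            by_infant = {}
            for s in w.case_samples:
                by_infant[s.infant_id] = by_infant.get(s.infant_id, 0) + 1
            same = sum(v * (v - 1) // 2 for v in by_infant.values())
            expected = n_case * (n_case - 1) // 2 - same
            assert len(w.case_values) == expected

    def test_insufficient_window_marked(self):
        meta = _meta_two_infants()
        soer_df = pd.DataFrame(np.zeros((3, 3)), index=["A1", "A2", "K1"], columns=["A1", "A2", "K1"])
        d = DistanceResult(soer_df, metric="sorensen")
        series = vc.convergence_series(d, vc.build_windows(WindowSpec(7, 2, 14), vc.anchor(meta)), None)
        assert all(w.insufficient for w in series.windows)

    def test_signal_localizes_to_planted_window(self, default_cohort, default_abundance, default_anchored):
        """Between-case dissimilarity drops below between-control in the
        windows overlapping the planted 10 d signature window."""
        soer = vc.sorensen(vc.presence_matrix(default_abundance))
        pairs = vc.pair_samples(default_anchored, default_cohort["meta"])
        series = vc.convergence_series(
            soer, vc.build_windows(WindowSpec(7, 2, 25), default_anchored), pairs
        )
        near = [w for w in series.windows[:3] if w.test]
        hits = sum(
            1
            for w in near
            if w.test.extra["case_median"] < w.test.extra["control_median"] and w.test.p_value <= 0.05
        )
        assert hits >= 2
        far = [w for w in series.windows if w.test and w.start >= 14]
        for w in far:
            drop = w.test.extra["control_median"] - w.test.extra["case_median"]
            assert drop < 0.02 or w.test.p_value > 0.05


class TestAcrossWindows:
    def test_identical_windows_give_zero_statistic(self):
        series = vc.build_windows(WindowSpec(7, 7, 21), [])
        for w in series.windows:
            w.case_values = [1.0, 2.0]
        res = vc.across_window_test(series, group="case")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_closed_form_rank_statistic(self):
        series = vc.build_windows(WindowSpec(7, 7, 21), [])
        for w, vals in zip(series.windows, ([1, 2, 3], [4, 5, 6], [7, 8, 9])):
            w.case_values = list(map(float, vals))
        res = vc.across_window_test(series, group="case")
        assert res.statistic == pytest.approx(7.2)

    def test_dunn_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        groups = [list(rng.normal(m, 1, 8)) for m in (0, 0.5, 2.0)]
        for adjust in ("bonferroni", "bh"):
            for r in dunn_posthoc(groups, adjust=adjust):
                assert r["p_adjusted"] >= r["p"] - 1e-15
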