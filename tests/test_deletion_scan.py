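"""Deletion scan: covered intervals, the two-condition rule, oracle equivalence."""

import numpy as np
import pytest

from bulkmap import deletion_scan as ds
from bulkmap.io_formats import CaptureTarget, DepthTrack


def make_track(contig_depths: dict[str, dict[int, int]]) -> DepthTrack:
    track = DepthTrack()
    for contig, depths in contig_depths.items():
        pos = np.array(sorted(p for p, d in depths.items() if d > 0))
        dep = np.array([depths[p] for p in pos])
        if pos.size:
            track.set_contig(contig, pos, dep)
        else:
            track.set_contig(contig, np.empty(0, int), np.empty(0, int))
    return track


def brute_force_scan(mut_by_contig, wt_by_contig, targets, min_length=150,
                     wt_min=5.0, mut_max=2.0, ratio_min=4.0):
    """Independent per-base reference: literal run/clip/mean/condition logic.

    Depths are plain ``{contig: {pos: depth}}`` dicts; absent means 0.
    """
    intervals = []
    for t in sorted(targets, key=lambda t: (t.contig_id, t.start, t.end)):
        contig = t.contig_id
        wt_depths = wt_by_contig.get(contig, {})
        mut_depths = mut_by_contig.get(contig, {})
        span_hi = max([t.end] + list(wt_depths)) + 1
        run = []
        runs = []
        for p in range(1, span_hi + 1):
            if wt_depths.get(p, 0) > 0:
                run.append(p)
            elif run:
                runs.append(run)
                run = []
        if run:
            runs.append(run)
        for r in runs:
            clipped = [p for p in r if t.start <= p <= t.end]
            if not clipped:
                continue
            m = [mut_depths.get(p, 0) for p in clipped]
            w = [wt_depths.get(p, 0) for p in clipped]
            intervals.append(
                ds.CoverageInterval(contig, clipped[0], clipped[-1],
                                    sum(m) / len(m), sum(w) / len(w))
            )
    intervals.sort(key=lambda iv: (iv.contig_id, iv.start, iv.end))
    calls = []
    for iv in intervals:
        if iv.length < min_length:
            continue
        if iv.mean_depth_wt >= wt_min and iv.mean_depth_mut == 0:
            calls.append(ds.DeletionCall(iv, 1))
        elif (iv.mean_depth_mut <= mut_max and iv.mean_depth_wt >= wt_min
              and iv.mean_depth_wt >= ratio_min * iv.mean_depth_mut):
            calls.append(ds.DeletionCall(iv, 2))
    return intervals, calls


class TestCoveredIntervals:
    def test_single_run_inside_target(self):
        wt = make_track({"c": {10: 5, 11: 6, 12: 7}})
        mut = make_track({"c": {}})
        (iv,) = ds.covered_intervals(mut, wt, [CaptureTarget("c", 1, 100)])
        assert (iv.start, iv.end, iv.length) == (10, 12, 3)
        assert iv.mean_depth_wt == pytest.approx(6.0)
        assert iv.mean_depth_mut == 0.0

    def test_run_clipped_to_target_edge(self):
        wt = make_track({"c": {p: 4 for p in range(5, 26)}})
        mut = make_track({"c": {p: 1 for p in range(5, 26)}})
        (iv,) = ds.covered_intervals(mut, wt, [CaptureTarget("c", 10, 20)])
        assert (iv.start, iv.end) == (10, 20)
        assert iv.mean_depth_wt == pytest.approx(4.0)

    def test_continuous_coverage_split_by_adjacent_targets(self):
        wt = make_track({"c": {p: 8 for p in range(1, 61)}})
        mut = make_track({"c": {}})
        targets = [CaptureTarget("c", 10, 20), CaptureTarget("c", 22, 40)]
        ivs = ds.covered_intervals(mut, wt, targets)
        assert [(iv.start, iv.end) for iv in ivs] == [(10, 20), (22, 40)]

    def test_zero_gap_splits_runs(self):
        depths = {p: 9 for p in range(1, 31) if p != 15}
        wt = make_track({"c": depths})
        mut = make_track({"c": {}})
        ivs = ds.covered_intervals(mut, wt, [CaptureTarget("c", 1, 30)])
        assert [(iv.start, iv.end) for iv in ivs] == [(1, 14), (16, 30)]


class TestCallDeletions:
    def iv(self, length, mut, wt):
        return ds.CoverageInterval("c", 1, length, mut, wt)

    @pytest.mark.parametrize(
        "length,mut,wt,expected",
        [
            (349, 0.4, 24.4, 2),   # published worked-example geometry
            (200, 0.0, 7.0, 1),
            (200, 2.1, 30.0, None),   # mutant mean above 2x
            (149, 0.0, 30.0, None),   # below minimum length
            (200, 1.5, 5.5, None),    # ratio 5.5 < 4 * 1.5
            (150, 0.0, 5.0, 1),       # boundary: length and wt exactly at limits
            (200, 2.0, 8.0, 2),       # mut exactly at 2x, ratio exactly 4
        ],
    )
    def test_condition_rules(self, length, mut, wt, expected):
        calls = ds.call_deletions([self.iv(length, mut, wt)])
        if expected is None:
            assert calls == []
        else:
            assert [c.condition for c in calls] == [expected]

    def test_condition_1_takes_precedence(self):
        calls = ds.call_deletions([self.iv(200, 0.0, 20.0)])
        assert calls[0].condition == 1

    def test_monotone_in_mutant_depth_and_length(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            length = int(rng.integers(1, 400))
            mut = float(rng.uniform(0, 4))
            wt = float(rng.uniform(0, 30))
            called = bool(ds.call_deletions([self.iv(length, mut, wt)]))
            lower_mut = bool(ds.call_deletions([self.iv(length, mut * 0.5, wt)]))
            if called:
                assert lower_mut  # lowering mutant depth never un-calls
            longer_min = bool(
                ds.call_deletions([self.iv(length, mut, wt)], min_length=300)
            )
            if longer_min:
                assert called  # raising min_length never adds a call


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(2024)
        for trial in range(60):
            contig_len = int(rng.integers(200, 2_000))
            # blocky wildtype coverage with zero stretches
            wt_depths = {}
            mut_depths = {}
            p = 1
            while p <= contig_len:
                block = int(rng.integers(20, 250))
                kind = rng.random()
                for q in range(p, min(p + block, contig_len + 1)):
                    if kind < 0.3:
                        pass  # uncovered stretch
                    else:
                        wt_depths[q] = int(rng.integers(1, 30))
                        if rng.random() < 0.7:
                            mut_depths[q] = int(rng.integers(0, 8))
                p += block
            wt = make_track({"c": wt_depths})
            mut = make_track({"c": mut_depths})
            n_targets = int(rng.integers(1, 4))
            targets = []
            for _ in range(n_targets):
                s = int(rng.integers(1, contig_len))
                e = min(contig_len, s + int(rng.integers(50, 500)))
                targets.append(CaptureTarget("c", s, e))
            ivs = ds.covered_intervals(mut, wt, targets)
            calls = ds.call_deletions(ivs)
            oracle_ivs, oracle_calls = brute_force_scan(
                {"c": mut_depths}, {"c": wt_depths}, targets
            )
            assert ivs == oracle_ivs, f"trial {trial}"
            assert calls == oracle_calls, f"trial {trial}"

    def test_simulated_deletion_recovered(self, scenario1):
        sc = scenario1
        ivs = ds.covered_intervals(sc.depth_mut, sc.depth_wt, sc.targets)
        calls = ds.call_deletions(ivs)
        called_contigs = {c.interval.contig_id for c in calls}
        assert sc.deletion.contig_id in called_contigs
        # the het contaminant leaves residual coverage: condition 2, not 1
        for c in calls:
            if c.interval.contig_id == sc.deletion.contig_id:
                assert c.condition == 2
                assert c.interval.mean_depth_mut > 0
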