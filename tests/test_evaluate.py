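import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from seeqrs import DetectionCounts, aggregate, compute_metrics, match_beats, report_table
from seeqrs.benchmark import load_benchmark_leads, load_benchmark_records
from seeqrs.errors import InputError
from seeqrs.evaluate import render_percent


def optimal_match_count(refs, dets, tol):
    """Maximum-cardinality matching via assignment on a padded cost matrix."""
    refs, dets = np.asarray(refs), np.asarray(dets)
    if refs.size == 0 or dets.size == 0:
        return 0
    cost = np.abs(refs[:, None] - dets[None, :]).astype(float)
    big = 10 * (tol + 1 + cost.max())
    cost[cost > tol] = big
    r, c = linear_sum_assignment(cost)
    return int(np.sum(cost[r, c] <= tol))


class TestMatchBeats:
    def test_mixed_outcome(self):
        c = match_beats(np.array([110, 900]), np.array([100, 500]), tolerance=150)
        assert (c.tp, c.fn, c.fp) == (1, 1, 1)

    def test_identity(self):
        idx = np.array([10, 300, 700])
        c = match_beats(idx, idx, tolerance=150)
        assert (c.tp, c.fn, c.fp) == (3, 0, 0)

    def test_nearest_first_pairing(self):
        # 130 is 30 away from the reference, 60 is 40 away: nearest-first
        # pairs 130 and leaves 60 as a false positive
        c = match_beats(np.array([60, 130]), np.array([100]), tolerance=50)
        assert (c.tp, c.fn, c.fp) == (1, 0, 1)

    def test_greedy_equals_optimal_on_separated_instances(self):
        # with beats separated by more than twice the tolerance the match
        # graph splits into independent stars and greedy is provably optimal
        rng = np.random.default_rng(17)
        tol = 50
        for _ in range(200):
            n_ref = int(rng.integers(0, 11))
            refs = np.cumsum(rng.integers(2 * tol + 1, 500, size=n_ref))
            n_det = int(rng.integers(0, 11))
            dets = np.sort(rng.integers(0, int(refs[-1]) + 300 if n_ref else 3000, size=n_det))
            c = match_beats(dets, refs, tolerance=tol)
            assert c.tp == optimal_match_count(refs, dets, tol)
            assert c.tp + c.fn == n_ref
            assert c.tp + c.fp == n_det

    def test_invariant_under_global_time_shift(self):
        rng = np.random.default_rng(23)
        refs = np.cumsum(rng.integers(300, 800, size=20))
        dets = refs + rng.integers(-40, 40, size=20)
        a = match_beats(np.sort(dets), refs, tolerance=150)
        b = match_beats(np.sort(dets) + 5000, refs + 5000, tolerance=150)
        assert a == b

    def test_fs_mismatch_rejected(self):
        class Stub:
            def __init__(self, fs):
                self.r_samples = np.array([1])
                self.fs = fs

        with pytest.raises(InputError):
            match_beats(Stub(1000.0), Stub(500.0), tolerance=10)


class TestComputeMetrics:
    def test_published_total_row(self):
        m = compute_metrics(DetectionCounts(119054, 91, 93))
        assert render_percent(m.se) == "99.924"
        assert render_percent(m.pp) == "99.922"
        assert render_percent(m.acc) == "99.846"
        assert render_percent(m.der) == "0.155"

    def test_published_record_row(self):
        m = compute_metrics(DetectionCounts(1906, 4, 21))
        assert (render_percent(m.der), render_percent(m.se)) == ("1.312", "99.791")
        assert (render_percent(m.pp), render_percent(m.acc)) == ("98.910", "98.705")

    def test_perfect_detection(self):
        m = compute_metrics(DetectionCounts(57, 0, 0))
        assert (m.se, m.pp, m.acc, m.der) == (100.0, 100.0, 100.0, 0.0)

    def test_zero_tp_gives_infinite_der(self):
        m = compute_metrics(DetectionCounts(0, 3, 2))
        assert m.se == m.pp == m.acc == 0.0
        assert np.isinf(m.der)
        assert render_percent(m.der) == "inf"
        with pytest.raises(InputError):
            compute_metrics(DetectionCounts(0, 0, 0))

    def test_accuracy_dominated_by_se_and_pp(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            c = DetectionCounts(*(int(v) for v in rng.integers(1, 2000, size=3)))
            m = compute_metrics(c)
            assert m.acc <= min(m.se, m.pp) + 1e-12


class TestAggregate:
    def test_appendix_leads_sum_to_record_row(self):
        per_lead = load_benchmark_leads("s0020arem")
        total = aggregate(per_lead.values())
        assert total == DetectionCounts(1906, 4, 21)

    def test_single_element_identity(self):
        c = DetectionCounts(5, 1, 2)
        assert aggregate([c]) == c

    def test_sum_of_sums_equals_sum_of_concatenation(self):
        rng = np.random.default_rng(29)
        counts = [
            DetectionCounts(*(int(v) for v in rng.integers(0, 100, size=3)))
            for _ in range(30)
        ]
        split = rng.integers(1, 29)
        assert aggregate(
            [aggregate(counts[:split]), aggregate(counts[split:])]
        ) == aggregate(counts)


class TestReportTable:
    def test_single_perfect_record_row(self):
        out = report_table({"s0010_rem": DetectionCounts(624, 0, 0)})
        assert out.splitlines()[1] == "s0010_rem,624,0,0,0.000,100.000,100.000,100.000"

    def test_empty_mapping_flags_undefined_total(self):
        lines = report_table({}).splitlines()
        assert lines[0] == "Case,TP,FN,FP,DER%,Se%,+P,Acc"
        assert lines[1].startswith("Total,0,0,0,NA")

    def test_total_row_equals_aggregate(self):
        rng = np.random.default_rng(31)
        mapping = {
            f"r{i}": DetectionCounts(*(int(v) for v in rng.integers(1, 500, size=3)))
            for i in range(8)
        }
        total_line = report_table(mapping).splitlines()[-1].split(",")
        agg = aggregate(mapping.values())
        assert [int(v) for v in total_line[1:4]] == [agg.tp, agg.fn, agg.fp]


class TestBenchmarkFixture:
    def test_every_published_cell_reproduced(self):
        rows = load_benchmark_records()
        assert len(rows) == 73  # 72 records + Total
        for row in rows:
            m = compute_metrics(row.counts)
            assert render_percent(m.der) == row.der, row.case
            assert render_percent(m.se) == row.se, row.case
            assert render_percent(m.pp) == row.pp, row.case
            assert render_percent(m.acc) == row.acc, row.case
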