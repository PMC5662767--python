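"""Gate fitting/application vs brute-force oracles, QC rule, properties."""

import numpy as np
import pytest

from smoscreen import (
    EventTable,
    PopulationConfig,
    ScatterGate,
    apply_gate,
    fit_gate,
    qc_report,
    simulate_well,
)
from smoscreen.gating import DegenerateScatterError


def make_table(rng, n, mu=(11.0, 10.0), sigma=0.25, well_id="w"):
    log_fsc = rng.normal(mu[0], sigma, n)
    log_ssc = rng.normal(mu[1], sigma, n)
    fl = np.exp(rng.normal(5.0, 0.3, n))
    return EventTable.from_arrays(well_id, np.exp(log_fsc), np.exp(log_ssc), fl)


class TestFitGate:
    def test_realized_coverage_matches_quantile(self, rng):
        table = make_table(rng, 10_000)
        gate = fit_gate(table, coverage_quantile=0.90)
        inside = gate.contains(table)
        assert 0.89 <= inside.mean() <= 0.91

    def test_coverage_exact_to_one_over_n(self, rng):
        table = make_table(rng, 1000)
        gate = fit_gate(table, coverage_quantile=0.80)
        assert abs(gate.contains(table).mean() - 0.80) <= 1.0 / 1000 + 1e-12

    def test_identical_events_degenerate(self):
        table = EventTable.from_arrays(
            "w", np.full(100, 50.0), np.full(100, 40.0), np.full(100, 5.0)
        )
        with pytest.raises(DegenerateScatterError):
            fit_gate(table)

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError, match="50"):
            fit_gate(make_table(rng, 20))

    def test_half_coverage_selects_nearest_half(self, rng):
        # sort-and-count oracle: the gate at q=0.5 keeps exactly the
        # ceil(n/2) events with smallest Mahalanobis distance
        table = make_table(rng, 1000)
        gate = fit_gate(table, coverage_quantile=0.5)
        dist = gate.mahalanobis(table)
        expected = set(np.argsort(dist, kind="stable")[: int(np.ceil(0.5 * 1000))])
        got = set(np.flatnonzero(gate.contains(table)))
        assert got == expected


class TestApplyGate:
    def brute_force_inside(self, table, gate):
        # independent point-in-ellipse test, one event at a time
        prec = np.linalg.inv(gate.shape)
        out = []
        for fsc, ssc in zip(table.fsc, table.ssc):
            v = np.array([np.log(fsc), np.log(ssc)]) - gate.center
            out.append(float(v @ prec @ v) <= gate.radius**2 + 1e-12)
        return np.array(out)

    def test_matches_point_in_ellipse_enumeration(self, rng):
        table = make_table(rng, 1000, sigma=0.6)
        gate = ScatterGate(
            center=np.array([11.0, 10.0]),
            shape=np.array([[0.09, 0.02], [0.02, 0.06]]),
            radius=1.7,
            coverage_quantile=0.9,
        )
        gated = apply_gate(table, gate)
        oracle = self.brute_force_inside(table, gate)
        assert gated.n_gated == int(oracle.sum())
        assert (gate.contains(table) == oracle).all()

    def test_toy_well_fraction_and_qc(self):
        # 6 of 10 events inside a unit-circle gate at the origin of log space
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=1.0, coverage_quantile=0.9)
        r_in, r_out = 0.5, 3.0
        fsc = np.exp(np.r_[np.full(6, r_in), np.full(4, r_out)])
        table = EventTable.from_arrays("w", fsc, np.ones(10), np.ones(10))
        gated = apply_gate(table, gate)
        assert gated.gated_fraction == 0.6
        assert gated.qc_pass

    def test_exactly_half_inside_fails_qc(self):
        # the rule is strictly "more than 50%"
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=1.0, coverage_quantile=0.9)
        fsc = np.exp(np.r_[np.full(5, 0.5), np.full(5, 3.0)])
        table = EventTable.from_arrays("w", fsc, np.ones(10), np.ones(10))
        gated = apply_gate(table, gate)
        assert gated.gated_fraction == 0.5
        assert not gated.qc_pass

    def test_all_inside_passes(self):
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=2.0, coverage_quantile=0.9)
        table = EventTable.from_arrays("w", np.ones(10), np.ones(10), np.ones(10))
        gated = apply_gate(table, gate)
        assert gated.gated_fraction == 1.0 and gated.qc_pass

    def test_boundary_event_counts_inside(self):
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=1.0, coverage_quantile=0.9)
        table = EventTable.from_arrays("w", np.exp([1.0]), np.ones(1), np.ones(1))
        assert apply_gate(table, gate).n_gated == 1

    def test_empty_table_rejected(self):
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=1.0, coverage_quantile=0.9)
        table = EventTable.from_arrays("w", np.ones(0), np.ones(0), np.ones(0))
        with pytest.raises(ValueError, match="empty"):
            apply_gate(table, gate)

    def test_membership_invariant_under_event_order(self, rng):
        table = make_table(rng, 500)
        gate = fit_gate(table, 0.9)
        perm = rng.permutation(500)
        shuffled = EventTable.from_arrays(
            "w", table.fsc[perm], table.ssc[perm], table.fl[perm]
        )
        assert apply_gate(shuffled, gate).n_gated == apply_gate(table, gate).n_gated

    def test_nested_gates_monotone_in_coverage(self, rng):
        controls = make_table(rng, 5000)
        well = make_table(rng, 1000, sigma=0.5)
        fracs = [
            apply_gate(well, fit_gate(controls, q)).gated_fraction
            for q in (0.5, 0.7, 0.9, 0.99)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_debris_fraction_recovered(self):
        # with well-separated debris, gated fraction ~ (1 - delta)
        for delta in (0.1, 0.3):
            cfg = PopulationConfig(n_events=4000, debris_fraction=delta, seed=0)
            clean = PopulationConfig(n_events=4000, debris_fraction=0.0, seed=0)
            gate = fit_gate(simulate_well(clean, 0.0, seed=31), 0.99)
            well = simulate_well(cfg, 0.0, seed=32)
            assert apply_gate(well, gate).gated_fraction == pytest.approx(
                1 - delta, abs=0.03
            )


class TestQCReport:
    def test_empty_list(self):
        assert qc_report([]).empty

    def test_flags_failures_with_reason(self, rng):
        gate = ScatterGate(np.zeros(2), np.eye(2), radius=1.0, coverage_quantile=0.9)
        good = EventTable.from_arrays("good", np.ones(10), np.ones(10), np.ones(10))
        fsc = np.exp(np.r_[np.full(2, 0.0), np.full(8, 3.0)])
        bad = EventTable.from_arrays("bad", fsc, np.ones(10), np.ones(10))
        report = qc_report([apply_gate(good, gate), apply_gate(bad, gate)])
        assert len(report) == 2
        assert report.set_index("well_id").loc["good", "qc_pass"]
        assert not report.set_index("well_id").loc["bad", "qc_pass"]
        assert "gated_fraction" in report.set_index("well_id").loc["bad", "exclusion_reason"]

    def test_toxic_well_flagged_in_simulation(self):
        clean = PopulationConfig(n_events=4000, debris_fraction=0.0, seed=0)
        toxic = PopulationConfig(n_events=4000, debris_fraction=0.6, seed=0)
        gate = fit_gate(simulate_well(clean, 0.0, seed=41), 0.99)
        report = qc_report([apply_gate(simulate_well(toxic, 0.0, seed=42), gate)])
        assert not report["qc_pass"].iloc[0]


class TestGateSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        gate = fit_gate(make_table(rng, 1000), 0.9)
        path = tmp_path / "gate.json"
        gate.to_json(path)
        back = ScatterGate.from_json(path)
        assert np.allclose(back.center, gate.center)
        assert np.allclose(back.shape, gate.shape)
        assert back.radius == gate.radius
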