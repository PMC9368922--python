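import math

import numpy as np
import pytest

import casim
from casim.repair import RepairState, _choose_partner

from conftest import make_dsbs


@pytest.fixture(scope="module")
def toy_karyotype():
    return casim.Karyotype.uniform_fixture(4, 10_000_000)


def complex_dsbs(karyotype, positions):
    return make_dsbs(karyotype,
                     [(i % len(karyotype), 1000 + 10 * i, p)
                      for i, p in enumerate(positions)],
                     complexity="complex")


def simple_dsbs(karyotype, n):
    return make_dsbs(karyotype, [(i % len(karyotype), 1000 + 10 * i, (0, 0, 0))
                                 for i in range(n)], complexity="simple")


class TestKernel:
    def test_contact_value(self):
        assert casim.misrepair_kernel(0.0) == pytest.approx(0.02)

    def test_one_sigma(self):
        # r² = σ² = 0.8 µm²
        assert casim.misrepair_kernel(math.sqrt(0.8)) == pytest.approx(
            0.02 / math.e)

    def test_distant_breaks_never_interact(self):
        assert casim.misrepair_kernel(10.0) < 1e-50

    def test_vectorized(self):
        vals = casim.misrepair_kernel(np.array([0.0, 1.0]))
        assert vals.shape == (2,)


class TestTheoreticalDecay:
    def test_initial_value(self):
        assert casim.theoretical_decay(30, 12, 0.0) == pytest.approx(42.0)

    def test_one_tau(self):
        assert casim.theoretical_decay(100, 0, 1.7) == pytest.approx(
            36.79, abs=0.01)
        assert casim.theoretical_decay(0, 100, 23.7) == pytest.approx(
            36.79, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            casim.theoretical_decay(1, 1, -0.5)


class TestStepRepair:
    def test_empty_state_unchanged(self, toy_karyotype):
        state = RepairState.from_dsbs([])
        out = casim.step_repair(state, seed=1)
        assert out.n_open_ends == 0 and out.events == []

    def test_simple_pair_closure_rate(self, toy_karyotype):
        """Per-step closure frequency of a simple pair ≈ δt/τ1 = 1/6120."""
        dsbs = simple_dsbs(toy_karyotype, 2)
        rng = np.random.default_rng(0)
        n, reps = 0, 20_000
        for _ in range(reps):
            st = RepairState.from_dsbs(dsbs)
            casim.step_repair(st, seed=rng)
            n += len(st.events)
        p = 1.0 / 6120.0
        mean, se = 2 * reps * p, math.sqrt(2 * reps * p)
        assert abs(n - mean) < 3 * se

    def test_closed_ends_never_reopen(self, toy_karyotype):
        dsbs = simple_dsbs(toy_karyotype, 1)
        st = RepairState.from_dsbs(dsbs)
        st.close(0, 1, 1.0)
        with pytest.raises(ValueError):
            st.close(0, 1, 2.0)


class TestPartnerChoice:
    def test_frequencies_match_normalized_kernel(self, toy_karyotype):
        """Partner tallies over 1e5 attempts vs exhaustive enumeration."""
        pos = [(0, 0, 0), (0.4, 0, 0), (0, 0.9, 0)]
        dsbs = complex_dsbs(toy_karyotype, pos)
        st = RepairState.from_dsbs(dsbs)
        params = casim.RepairParameters(normalize_kernel=False)  # abort mode
        rng = np.random.default_rng(1)
        ends = np.arange(6)
        # enumeration: candidate weights for end 0
        r = np.array([0.0,                                    # cognate end 1
                      0.4, 0.4,                               # ends 2, 3
                      0.9, 0.9])                              # ends 4, 5
        w = casim.misrepair_kernel(r)
        expect = w / w.sum()
        tally = np.zeros(6)
        n_closed = 0
        for _ in range(100_000):
            j = _choose_partner(0, ends, st, params, rng)
            if j >= 0:
                tally[j] += 1
                n_closed += 1
        freq = tally[1:] / n_closed
        se = np.sqrt(expect * (1 - expect) / n_closed)
        assert (np.abs(freq - expect) < 3 * se + 1e-12).all()
        # abort mode: closure probability is ΣI (< 1 here)
        p_close = n_closed / 100_000
        assert abs(p_close - w.sum()) < 3 * math.sqrt(
            w.sum() * (1 - w.sum()) / 100_000)

    def test_proximity_suppression_ratio(self, toy_karyotype):
        """A distant break partners less often by exp(-Δr²/σ²)."""
        near, far = 0.3, 1.5
        pos = [(0, 0, 0), (near, 0, 0), (far, 0, 0)]
        dsbs = complex_dsbs(toy_karyotype, pos)
        st = RepairState.from_dsbs(dsbs)
        params = casim.RepairParameters(normalize_kernel=True)
        rng = np.random.default_rng(2)
        ends = np.arange(6)
        tally = {2: 0, 4: 0}
        for _ in range(100_000):
            j = _choose_partner(0, ends, st, params, rng)
            if j in (2, 3):
                tally[2] += 1
            elif j in (4, 5):
                tally[4] += 1
        expected_ratio = math.exp(-(far ** 2 - near ** 2) / 0.8)
        assert tally[4] / tally[2] == pytest.approx(expected_ratio, rel=0.15)

    def test_no_candidates_aborts(self, toy_karyotype):
        dsbs = complex_dsbs(toy_karyotype, [(0, 0, 0)])
        st = RepairState.from_dsbs(dsbs)
        rng = np.random.default_rng(3)
        assert _choose_partner(
            0, np.array([0]), st, casim.RepairParameters(), rng) == -1


class TestSimulateRepair:
    def test_no_breaks_empty_log(self):
        state, events = casim.simulate_repair([], seed=1)
        assert events == [] and state.remaining_breaks == 0

    def test_simple_population_follows_fast_exponential(self, toy_karyotype):
        """N1 = 1000 simple breaks decay as exp(-t/τ1) (binomial 3 SE)."""
        dsbs = simple_dsbs(toy_karyotype, 1000)
        state, _ = casim.simulate_repair(dsbs, seed=5)
        for t in (1.7, 3.4):
            n_t = casim.remaining_break_trace(state, [t])[0]
            p = math.exp(-t / 1.7)
            se = math.sqrt(1000 * p * (1 - p))
            assert abs(n_t - 1000 * p) < 3 * se

    def test_complex_population_follows_slow_exponential(self, toy_karyotype):
        """Misrepair disabled: N2 = 1000 complex breaks decay as exp(-t/τ2)."""
        rng = np.random.default_rng(6)
        pos = rng.random((1000, 3)) * 4
        dsbs = complex_dsbs(toy_karyotype, pos)
        state, _ = casim.simulate_repair(dsbs, seed=7, allow_misrepair=False)
        for t in (6.0, 23.7):
            n_t = casim.remaining_break_trace(state, [t])[0]
            p = math.exp(-t / 23.7)
            se = math.sqrt(1000 * p * (1 - p))
            assert abs(n_t - 1000 * p) < 3 * se

    def test_sigma_to_zero_limit_is_cognate_only(self, toy_karyotype):
        """Normalised kernel with σ² → 0 selects the cognate end: every
        junction proper and τ2 kinetics recovered."""
        rng = np.random.default_rng(8)
        pos = rng.random((400, 3)) * 4 + 0.2
        dsbs = complex_dsbs(toy_karyotype, pos)
        params = casim.RepairParameters(normalize_kernel=True,
                                        sigma2_um2=1e-6)
        state, events = casim.simulate_repair(dsbs, params, seed=9)
        assert all(ev.kind == "proper" for ev in events)
        n_t = casim.remaining_break_trace(state, [23.7])[0]
        p = math.exp(-1.0)
        se = math.sqrt(400 * p * (1 - p))
        assert abs(n_t - 400 * p) < 3 * se

    def test_end_conservation_and_log_order(self, toy_karyotype):
        rng = np.random.default_rng(10)
        pos = rng.random((40, 3)) * 1.5
        dsbs = complex_dsbs(toy_karyotype, pos) + simple_dsbs(toy_karyotype, 5)
        for i, d in enumerate(dsbs):
            d.id = i  # reindex after concatenation
        state, events = casim.simulate_repair(dsbs, seed=11)
        assert state.n_open_ends + 2 * len(events) == 2 * len(dsbs)
        times = [ev.time_s for ev in events]
        assert times == sorted(times)
        closed = [e for ev in events for e in (ev.end_a, ev.end_b)]
        assert len(closed) == len(set(closed)), "an end closed twice"

    def test_determinism(self, toy_karyotype):
        rng = np.random.default_rng(12)
        pos = rng.random((30, 3)) * 1.5
        dsbs = complex_dsbs(toy_karyotype, pos)
        _, ev1 = casim.simulate_repair(dsbs, seed=13)
        dsbs2 = complex_dsbs(toy_karyotype, pos)
        _, ev2 = casim.simulate_repair(dsbs2, seed=13)
        assert [(e.time_s, e.end_a, e.end_b) for e in ev1] == \
               [(e.time_s, e.end_a, e.end_b) for e in ev2]


class TestStepperEquivalence:
    def test_event_driven_matches_literal_stepper(self, toy_karyotype):
        """The accelerated sampler reproduces the literal sweep's statistics
        on a small mixed population (mean junctions and improper counts)."""
        rng = np.random.default_rng(20)
        pos = rng.random((6, 3)) * 0.8
        params = casim.RepairParameters(dt_s=60.0, horizon_h=3.0,
                                        tau1_h=1.7, tau2_h=2.0)
        reps = 600
        lit_events, lit_improper = [], []
        fast_events, fast_improper = [], []
        for k in range(reps):
            dsbs = complex_dsbs(toy_karyotype, pos) \
                + simple_dsbs(toy_karyotype, 4)
            for i, d in enumerate(dsbs):
                d.id = i
            st = casim.RepairState.from_dsbs(dsbs)
            r = np.random.default_rng((21, k))
            for _ in range(params.n_steps):
                casim.step_repair(st, params, r)
            lit_events.append(len(st.events))
            lit_improper.append(
                sum(e.kind == "improper" for e in st.events))
            dsbs = complex_dsbs(toy_karyotype, pos) \
                + simple_dsbs(toy_karyotype, 4)
            for i, d in enumerate(dsbs):
                d.id = i
            _, ev = casim.simulate_repair(
                dsbs, params, seed=np.random.default_rng((22, k)))
            fast_events.append(len(ev))
            fast_improper.append(sum(e.kind == "improper" for e in ev))
        for a, b in ((lit_events, fast_events),
                     (lit_improper, fast_improper)):
            a, b = np.array(a, float), np.array(b, float)
            se = math.sqrt(a.var(ddof=1) / reps + b.var(ddof=1) / reps)
            assert abs(a.mean() - b.mean()) < 3 * se + 1e-9
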