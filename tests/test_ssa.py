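import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from elonsim import (
    CodonSequence,
    CodonTRNAMap,
    KineticParams,
    LatticeSpec,
    MachineCounts,
    ScenarioConfig,
    SimulationStallError,
    TRNAAbundanceTable,
    jump_rate,
    run_simulation,
    sample_tau,
    select_channel,
    step,
    total_propensity,
)
from elonsim.sequences import species_indices
from elonsim.ssa import initialize_state, jump_propensity_per_complex


@pytest.fixture()
def tiny_scenario():
    """Small two-species scenario on a 10^3 lattice for cheap dynamics."""
    lattice = LatticeSpec.from_volume(0.001, h_nm=10.0)
    trna = TRNAAbundanceTable(entries={"Met1": 120.0, "Gly3": 80.0})
    return ScenarioConfig(
        machines=MachineCounts(ribosomes=8, eftu=150),
        trna=trna,
        kinetics=KineticParams(burn_in_steps=10, stop_steps=100),
        lattice=lattice,
    )


TINY_SEQ = CodonSequence(codons=("ATG", "GGT", "ATG", "GGC"), name="tiny")


class TestPrimitives:
    def test_jump_rate_values(self):
        assert jump_rate(2.567e-12, 20e-9) == pytest.approx(6417.5)
        assert jump_rate(0.0, 1e-9) == 0.0
        assert jump_rate(1.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            jump_rate(1.0, 0.0)

    def test_jump_convention(self):
        lat = LatticeSpec.from_volume(0.064, h_nm=20.0)
        per_dir = KineticParams(jump_convention="per_direction")
        pub = KineticParams(jump_convention="published")
        assert jump_propensity_per_complex(per_dir, lat) == pytest.approx(6 * 6417.5)
        assert jump_propensity_per_complex(pub, lat) == pytest.approx(6417.5)
        with pytest.raises(ValueError):
            KineticParams(jump_convention="diagonal")

    def test_sample_tau_identities(self):
        assert sample_tau(1.0, math.exp(-1)) == pytest.approx(1.0)
        assert sample_tau(2.0, math.exp(-2)) == pytest.approx(1.0)
        with pytest.raises(SimulationStallError):
            sample_tau(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_tau(1.0, 0.0)

    def test_sample_tau_is_exponential(self):
        rng = np.random.default_rng(0)
        alpha0 = 3.5
        taus = [sample_tau(alpha0, 1.0 - rng.random()) for _ in range(100_000)]
        assert stats.kstest(taus, "expon", args=(0, 1 / alpha0)).pvalue > 0.01

    def test_select_channel_examples(self):
        assert select_channel([1.0, 1.0], 0.4) == 0
        assert select_channel([1.0, 3.0], 0.5) == 1
        assert select_channel([0.0, 1.0], 0.0) == 1  # zero channels skipped
        with pytest.raises(SimulationStallError):
            select_channel([0.0, 0.0], 0.5)
        with pytest.raises(ValueError):
            select_channel([-1.0, 2.0], 0.5)

    def test_select_channel_frequencies(self):
        props = [1.0, 2.0, 3.0, 4.0]
        rng = np.random.default_rng(1)
        draws = np.array([select_channel(props, r) for r in rng.random(100_000)])
        counts = np.bincount(draws, minlength=4)
        expected = np.array(props) / 10.0 * len(draws)
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_total_propensity(self, tiny_scenario):
        rng = np.random.default_rng(0)
        seq = species_indices(TINY_SEQ, CodonTRNAMap.load_default(), tiny_scenario.trna.species)
        state = initialize_state(tiny_scenario, seq, rng)
        alpha0, breakdown = total_propensity(state, tiny_scenario.kinetics, tiny_scenario.lattice)
        travel = jump_propensity_per_complex(tiny_scenario.kinetics, tiny_scenario.lattice)
        assert alpha0 == pytest.approx(150 * (travel + 1.0))
        assert breakdown["n_complexes"].sum() == 150
        assert breakdown["alpha_diss"].sum() == pytest.approx(150.0)
        # pure travel when dissociation is off
        kin0 = replace(tiny_scenario.kinetics, k_diss=0.0)
        alpha0_nd, bd = total_propensity(state, kin0, tiny_scenario.lattice)
        assert alpha0_nd == pytest.approx(150 * travel)
        assert bd["alpha_diss"].sum() == 0.0


class TestStepReference:
    """Per-event reference dynamics: conservation, collisions, idling."""

    def _setup(self, tiny_scenario, seed=3):
        rng = np.random.default_rng(seed)
        seq = species_indices(TINY_SEQ, CodonTRNAMap.load_default(), tiny_scenario.trna.species)
        state = initialize_state(tiny_scenario, seq, rng)
        return state, seq, rng

    def test_conservation_over_events(self, tiny_scenario):
        state, seq, rng = self._setup(tiny_scenario)
        totals0 = state.species_totals().copy()
        n_events, n_elong = 2000, 0
        for _ in range(n_events):
            if step(state, tiny_scenario.kinetics, tiny_scenario.lattice, seq, rng) is not None:
                n_elong += 1
        assert np.array_equal(state.species_totals(), totals0)
        assert state.n_complexes == 150
        assert n_elong > 0  # the scenario does elongate

    def test_successful_collision_sets_idle_and_advances_codon(self, tiny_scenario):
        state, seq, rng = self._setup(tiny_scenario)
        before_codons = state.ribosome_codon_index.copy()
        for _ in range(50_000):
            t_event = step(state, tiny_scenario.kinetics, tiny_scenario.lattice, seq, rng)
            if t_event is not None:
                break
        else:
            pytest.fail("no elongation within 50k events")
        (r,) = np.flatnonzero(state.ribosome_codon_index != before_codons)
        assert state.ribosome_codon_index[r] == (before_codons[r] + 1) % len(seq)
        assert state.ribosome_idle_until[r] == pytest.approx(t_event + 1.0 / 24.0)

    def test_idle_ribosomes_do_not_react(self, tiny_scenario):
        state, seq, rng = self._setup(tiny_scenario)
        state.ribosome_idle_until[:] = np.inf
        for _ in range(5000):
            assert step(state, tiny_scenario.kinetics, tiny_scenario.lattice, seq, rng) is None

    def test_time_strictly_increases(self, tiny_scenario):
        state, seq, rng = self._setup(tiny_scenario)
        t_prev = state.t
        for _ in range(200):
            step(state, tiny_scenario.kinetics, tiny_scenario.lattice, seq, rng)
            assert state.t > t_prev
            t_prev = state.t

    def test_kernel_agrees_with_reference(self, tiny_scenario):
        """The JIT loop and the reference step() implement the same
        per-event elongation probability (binomial comparison)."""
        n_events = 30_000
        state, seq, rng = self._setup(tiny_scenario, seed=11)
        ref_elong = 0
        for _ in range(n_events):
            if step(state, tiny_scenario.kinetics, tiny_scenario.lattice, seq, rng) is not None:
                ref_elong += 1
        trace = run_simulation(
            tiny_scenario, TINY_SEQ, seed=12, stop_steps=10**9,
            max_events=n_events, strict=False,
        )
        p_pool = (ref_elong + len(trace.times)) / (2 * n_events)
        se = math.sqrt(2 * p_pool * (1 - p_pool) / n_events)
        z = (ref_elong - len(trace.times)) / n_events / se
        assert abs(z) < 4.0


class TestRunSimulation:
    def test_deterministic_given_seed(self, tiny_scenario):
        a = run_simulation(tiny_scenario, TINY_SEQ, seed=5)
        b = run_simulation(tiny_scenario, TINY_SEQ, seed=5)
        assert np.array_equal(a.times, b.times)
        c = run_simulation(tiny_scenario, TINY_SEQ, seed=6)
        assert not np.array_equal(a.times, c.times)

    def test_trace_contract(self, tiny_scenario):
        trace = run_simulation(tiny_scenario, TINY_SEQ, seed=5)
        assert len(trace.times) == tiny_scenario.kinetics.stop_steps
        assert np.all(np.diff(trace.times) > 0)
        assert trace.counts[-1] == tiny_scenario.kinetics.stop_steps
        assert trace.n_ribosomes == 8

    def test_no_complexes_raises(self, tiny_scenario):
        broken = replace(tiny_scenario, machines=MachineCounts(ribosomes=8, eftu=0))
        with pytest.raises(SimulationStallError):
            run_simulation(broken, TINY_SEQ, seed=1)

    def test_no_ribosomes_raises(self, tiny_scenario):
        broken = replace(tiny_scenario, machines=MachineCounts(ribosomes=0, eftu=150))
        with pytest.raises(SimulationStallError):
            run_simulation(broken, TINY_SEQ, seed=1)

    def test_event_guard_reports_stall(self, tiny_scenario):
        with pytest.raises(SimulationStallError, match="elongations after"):
            run_simulation(tiny_scenario, TINY_SEQ, seed=1, max_events=50)

    def test_csv_export(self, tiny_scenario, tmp_path):
        trace = run_simulation(tiny_scenario, TINY_SEQ, seed=5, stop_steps=50)
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        assert out.exists() and (tmp_path / "trace.csv.json").exists()
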