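import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elonsim import (
    AllocationResult,
    CostTable,
    allocate_atp,
    apply_allocation,
    atp_context,
    flux_demand,
    protein_cost,
    rna_cost,
    simplex_grid,
    unit_costs,
)
from elonsim.atp import UNIT_COSTS, _distribute_trna


class TestFluxDemand:
    def test_cellular_demand_exceeds_170k(self):
        demand = flux_demand(13_500, 0.8, 16.0)
        assert demand == 172_800
        assert demand > 170_000

    def test_identities(self):
        assert flux_demand(1, 1, 1) == 1
        assert flux_demand(0, 0.5, 10) == 0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            flux_demand(100, 1.5, 10)


class TestRNACost:
    def test_average_trna_costs_about_700(self):
        # 76 nt at equal base composition: 19 * (6 + 7 + 11 + 12) = 684
        cost = rna_cost({"T": 19, "C": 19, "A": 19, "G": 19})
        assert cost == 684
        assert cost == pytest.approx(700, rel=0.03)

    def test_single_bases(self):
        assert rna_cost({"A": 1}) == 11
        assert rna_cost({"U": 1}) == 6
        assert rna_cost({}) == 0

    def test_unknown_base(self):
        with pytest.raises(KeyError, match="unknown base"):
            rna_cost({"X": 1})


class TestProteinCost:
    def test_ribosomal_protein_translation_atp(self):
        _, translation, _ = protein_cost(7459, synthesis_atp=35_689)
        assert translation == 29_836  # 4 ATP equivalents per peptide bond

    def test_eftu_total(self):
        synthesis, translation, total = protein_cost(394, synthesis_atp=1989)
        assert translation == 1576
        assert total == 3565

    def test_zero_protein(self):
        assert protein_cost(0, synthesis_atp=0) == (0, 0, 0)

    def test_composition_pricing(self):
        table = CostTable(aa_costs={"A": 2.0, "W": 10.0})
        synthesis, translation, total = protein_cost(
            3, aa_counts={"A": 2, "W": 1}, table=table
        )
        assert synthesis == 14.0
        assert translation == 12.0

    def test_inconsistent_composition(self):
        with pytest.raises(ValueError, match="inconsistent"):
            protein_cost(5, aa_counts={"A": 2})


class TestUnitCostsAndAllocation:
    def test_published_unit_costs(self):
        costs = unit_costs()
        assert costs == {"ribosome": 108_461.0, "trna": 700.0, "eftu": 3565.0}

    def test_published_gfp_optimum_share_arithmetic(self):
        added = allocate_atp(1e8, (0.375, 0.125, 0.5))
        assert added[0] == 345  # floor(3.75e7 / 108461)
        assert added[1] == math.floor(1.25e7 / 700)
        assert added[2] == math.floor(5e7 / 3565)

    def test_zero_budget(self):
        assert allocate_atp(0, (0.2, 0.3, 0.5)) == (0, 0, 0)

    def test_exactly_one_ribosome(self):
        assert allocate_atp(108_461, (1.0, 0.0, 0.0)) == (1, 0, 0)

    def test_invalid_shares(self):
        with pytest.raises(ValueError):
            allocate_atp(1e6, (0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            allocate_atp(-1, (1.0, 0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1e9),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_spend_never_exceeds_budget(self, budget, a, b):
        # two split points of [0, 1] give exact non-negative shares
        lo, hi = min(a, b), max(a, b)
        shares = (lo, hi - lo, 1.0 - hi)
        added = allocate_atp(budget, shares)
        spend = (
            added[0] * UNIT_COSTS["ribosome"]
            + added[1] * UNIT_COSTS["trna"]
            + added[2] * UNIT_COSTS["eftu"]
        )
        assert spend <= budget


class TestTRNADistribution:
    def test_proportional_with_largest_remainder(self, scenario):
        added = _distribute_trna(1000, scenario.trna.entries)
        assert sum(added.values()) == 1000
        # most abundant species gets the largest share
        assert max(added, key=added.get) == "Tyr1"

    def test_uniform_alternative(self, scenario):
        added = _distribute_trna(72, scenario.trna.entries, uniform=True)
        assert set(added.values()) == {2}

    def test_apply_allocation_counts(self, scenario):
        cfg = apply_allocation(scenario, (10, 100, 20))
        assert cfg.machines.ribosomes == 1054
        assert cfg.machines.eftu == 9142
        assert sum(cfg.trna.entries.values()) == pytest.approx(scenario.trna.total + 100)


class TestSimplexGrid:
    @pytest.mark.parametrize("n,expected", [(8, 45), (10, 66), (2, 6), (1, 3)])
    def test_grid_size_is_binomial(self, n, expected):
        grid = simplex_grid(1.0 / n)
        assert len(grid) == expected  # C(n+2, 2)
        assert all(abs(sum(p) - 1) < 1e-9 for p in grid)
        assert len(set(grid)) == len(grid)

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            simplex_grid(0.3)


class TestATPContext:
    def test_one_fmol(self):
        minutes, fraction = atp_context(1.0)
        assert minutes == pytest.approx(0.9, abs=0.01)
        assert fraction == pytest.approx(0.024, abs=0.0005)

    def test_published_series(self):
        # 1, 5 and 10 fmol -> ~0.9, 4.5 and 9 minutes of ATP production
        for fmol, (mins, pct) in zip((1, 5, 10), ((0.9, 2.4), (4.5, 12), (9.0, 24))):
            m, f = atp_context(fmol)
            assert m == pytest.approx(mins, rel=0.01)
            assert 100 * f == pytest.approx(pct, rel=0.01)

    def test_zero(self):
        assert atp_context(0.0) == (0.0, 0.0)


def test_allocation_result_validation():
    with pytest.raises(ValueError):
        AllocationResult(shares=(0.5, 0.5, 0.5), added=(0, 0, 0), normalized_rate=1.0)
    with pytest.raises(ValueError):
        AllocationResult(shares=(1.0, 0.0, 0.0), added=(-1, 0, 0), normalized_rate=1.0)
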