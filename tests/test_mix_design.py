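import pytest
from hypothesis import given
from hypothesis import strategies as st

from mockforge.errors import (
    ConfigError,
    ConsistencyError,
    InfeasibleDesignError,
    InsufficientStockError,
)
from mockforge.mix_design import (
    KIND_CELL,
    KIND_DNA,
    MODE_PER_STRAIN,
    MockDesign,
    StockRecord,
    design_cell_mock,
    design_dna_mock,
    dna_copies_per_ul,
    verify_recipe,
)
from mockforge.strain_registry import StrainRecord


def cell_stock(sid, conc, available=float("inf")):
    return StockRecord(strain_id=sid, copies_per_ml=conc, available_ml=available)


def dna_stock(sid, ng, available=float("inf")):
    return StockRecord(strain_id=sid, ng_per_ul=ng, available_ml=available)


class TestCellMock:
    def test_three_strain_hand_balance(self):
        # 3 strains at 1e11/mL, total target 3e9/mL in a 10 mL batch:
        # each strain contributes 1e9/mL -> 1e9 * 10000 uL / 1e11 = 100 uL
        design = MockDesign(
            kind=KIND_CELL,
            strain_ids=("A", "B", "C"),
            target_total_copies_per_ml=3e9,
            aliquot_volume_ul=100.0,
            aliquot_count=100,
        )
        recipe = design_cell_mock([cell_stock(s, 1e11) for s in "ABC"], design)
        for sid in "ABC":
            assert recipe.per_strain_volume_ul[sid] == pytest.approx(100.0)
        assert recipe.diluent_volume_ul == pytest.approx(9700.0)
        assert recipe.total_volume_ul == pytest.approx(10000.0)

    def test_paper_defaults_15_strains(self, registry):
        design = MockDesign(kind=KIND_CELL, strain_ids=tuple(registry.strain_ids))
        stocks = [cell_stock(s, 1e12) for s in registry.strain_ids]
        recipe = design_cell_mock(stocks, design)
        # (4e10/15) * 10000 uL / 1e12 = 26.67 uL per strain
        for sid in registry.strain_ids:
            assert recipe.per_strain_volume_ul[sid] == pytest.approx(26.6667, abs=1e-4)
        achieved_total = sum(recipe.achieved_per_strain.values())
        assert achieved_total == pytest.approx(4e10, rel=1e-12)

    def test_per_strain_mode_infeasible_when_stock_too_dilute(self):
        design = MockDesign(
            kind=KIND_CELL,
            strain_ids=("A", "B"),
            target_total_copies_per_ml=1e10,
            concentration_mode=MODE_PER_STRAIN,
        )
        # A alone would need more than the batch volume
        stocks = [cell_stock("A", 5e9), cell_stock("B", 1e12)]
        with pytest.raises(InfeasibleDesignError):
            design_cell_mock(stocks, design)

    def test_insufficient_stock_names_strain(self):
        design = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"), target_total_copies_per_ml=4e10)
        stocks = [cell_stock("A", 1e12, available=0.0001), cell_stock("B", 1e12)]
        with pytest.raises(InsufficientStockError, match="'A'"):
            design_cell_mock(stocks, design)

    def test_missing_stock_is_consistency_error(self):
        design = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"))
        with pytest.raises(ConsistencyError, match="B"):
            design_cell_mock([cell_stock("A", 1e12)], design)

    @given(factor=st.floats(min_value=1.1, max_value=10.0))
    def test_scale_invariance(self, factor):
        design = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"), target_total_copies_per_ml=4e10)
        base = design_cell_mock([cell_stock("A", 1e12), cell_stock("B", 2e12)], design)
        scaled = design_cell_mock(
            [cell_stock("A", factor * 1e12), cell_stock("B", factor * 2e12)], design
        )
        for sid in "AB":
            assert scaled.per_strain_volume_ul[sid] == pytest.approx(
                base.per_strain_volume_ul[sid] / factor, rel=1e-9
            )

    def test_volume_conservation(self, registry):
        design = MockDesign(kind=KIND_CELL, strain_ids=tuple(registry.strain_ids))
        stocks = [cell_stock(s, (i + 1) * 1e11) for i, s in enumerate(registry.strain_ids)]
        recipe = design_cell_mock(stocks, design)
        total = sum(recipe.per_strain_volume_ul.values()) + recipe.diluent_volume_ul
        assert total == pytest.approx(recipe.total_volume_ul, rel=1e-9)

    def test_copy_conservation(self):
        design = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"), target_total_copies_per_ml=4e10)
        stocks = [cell_stock("A", 3e11), cell_stock("B", 7e11)]
        recipe = design_cell_mock(stocks, design)
        for stock in stocks:
            batch_copies = stock.copies_per_ml * recipe.per_strain_volume_ul[stock.strain_id] / 1000
            expected = 2e10 * recipe.total_volume_ul / 1000
            assert batch_copies == pytest.approx(expected, rel=1e-9)


class TestDnaCopies:
    def test_ecoli_10ng(self, ecoli):
        assert dna_copies_per_ul(10.0, ecoli) == pytest.approx(1.9189e6, rel=1e-4)

    def test_ldelbrueckii_10ng(self, ldelbrueckii):
        assert dna_copies_per_ul(10.0, ldelbrueckii) == pytest.approx(4.7765e6, rel=1e-4)

    def test_zero(self, ecoli):
        assert dna_copies_per_ul(0.0, ecoli) == 0.0


class TestDnaMock:
    def _registry_pair(self):
        from mockforge.strain_registry import Registry

        reg = Registry()
        reg.add(StrainRecord("one", "S1", 1_000_000, 0.5, 1))
        reg.add(StrainRecord("two", "S2", 2_000_000, 0.5, 1))
        return reg

    def test_two_strain_hand_balance(self):
        reg = self._registry_pair()
        design = MockDesign(
            kind=KIND_DNA,
            strain_ids=("S1", "S2"),
            target_total_ng_per_ul=50.0,
            dna_aliquot_volume_ul=20.0,
            aliquot_count=50,
        )  # 1 mL batch
        recipe = design_dna_mock([dna_stock("S1", 100.0), dna_stock("S2", 100.0)], design, reg)
        assert recipe.achieved_per_strain["S1"] == pytest.approx(50.0 / 3, rel=1e-9)
        assert recipe.achieved_per_strain["S2"] == pytest.approx(100.0 / 3, rel=1e-9)
        assert recipe.per_strain_volume_ul["S1"] == pytest.approx(166.6667, abs=1e-3)
        assert recipe.per_strain_volume_ul["S2"] == pytest.approx(333.3333, abs=1e-3)
        assert recipe.diluent_volume_ul == pytest.approx(500.0, abs=1e-3)

    def test_identical_strains_equal_volumes(self):
        from mockforge.strain_registry import Registry

        reg = Registry()
        for i in range(4):
            reg.add(StrainRecord(f"s{i}", f"S{i}", 3_000_000, 0.4, 1))
        design = MockDesign(kind=KIND_DNA, strain_ids=tuple(f"S{i}" for i in range(4)))
        recipe = design_dna_mock(
            [dna_stock(f"S{i}", 150.0) for i in range(4)], design, reg
        )
        volumes = set(round(v, 9) for v in recipe.per_strain_volume_ul.values())
        assert len(volumes) == 1

    def test_registry_defaults_proportional_to_size(self, registry):
        design = MockDesign(kind=KIND_DNA, strain_ids=tuple(registry.strain_ids))
        stocks = [dna_stock(s, 200.0) for s in registry.strain_ids]
        recipe = design_dna_mock(stocks, design, registry)
        finals = recipe.achieved_per_strain
        assert sum(finals.values()) == pytest.approx(50.0, rel=1e-9)
        size_sum = sum(registry[s].genome_size_bp for s in registry.strain_ids)
        for sid in registry.strain_ids:
            expected = 50.0 * registry[sid].genome_size_bp / size_sum
            assert finals[sid] == pytest.approx(expected, rel=1e-9)

    def test_equimolar_across_strains(self, registry):
        design = MockDesign(kind=KIND_DNA, strain_ids=tuple(registry.strain_ids))
        stocks = [dna_stock(s, 200.0) for s in registry.strain_ids]
        recipe = design_dna_mock(stocks, design, registry)
        molar = [
            dna_copies_per_ul(recipe.achieved_per_strain[sid], registry[sid])
            for sid in registry.strain_ids
        ]
        lo, hi = min(molar), max(molar)
        assert (hi - lo) / hi < 1e-9

    def test_too_dilute_stock_infeasible(self):
        reg = self._registry_pair()
        design = MockDesign(kind=KIND_DNA, strain_ids=("S1", "S2"))
        with pytest.raises(InfeasibleDesignError):
            design_dna_mock([dna_stock("S1", 5.0), dna_stock("S2", 5.0)], design, reg)


class TestVerifyRecipe:
    def test_default_cell_mock_passes(self, registry):
        design = MockDesign(kind=KIND_CELL, strain_ids=tuple(registry.strain_ids))
        stocks = [cell_stock(s, 1e12) for s in registry.strain_ids]
        recipe = design_cell_mock(stocks, design)
        report = verify_recipe(recipe, stocks, design)
        assert report.passed
        # independent total: sum of stock*volume/total equals 4e10
        total = sum(
            1e12 * recipe.per_strain_volume_ul[s] / recipe.total_volume_ul
            for s in registry.strain_ids
        )
        assert total == pytest.approx(4e10, rel=1e-9)

    def test_perturbed_volume_fails_naming_strain(self, registry):
        design = MockDesign(kind=KIND_CELL, strain_ids=tuple(registry.strain_ids))
        stocks = [cell_stock(s, 1e12) for s in registry.strain_ids]
        recipe = design_cell_mock(stocks, design)
        victim = registry.strain_ids[3]
        recipe.per_strain_volume_ul[victim] *= 1.1
        recipe.diluent_volume_ul -= 0.1 * recipe.per_strain_volume_ul[victim] / 1.1
        report = verify_recipe(recipe, stocks, design)
        assert not report.passed
        assert report.failing_strains == [victim]

    def test_mismatched_strain_sets(self):
        design = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"))
        stocks = [cell_stock("A", 1e12), cell_stock("B", 1e12)]
        recipe = design_cell_mock(stocks, design)
        other = MockDesign(kind=KIND_CELL, strain_ids=("A", "C"))
        with pytest.raises(ConsistencyError):
            verify_recipe(recipe, stocks, other)

    def test_dna_mock_passes(self, registry):
        design = MockDesign(kind=KIND_DNA, strain_ids=tuple(registry.strain_ids))
        stocks = [dna_stock(s, 200.0) for s in registry.strain_ids]
        recipe = design_dna_mock(stocks, design, registry)
        assert verify_recipe(recipe, stocks, design, registry).passed


class TestValidation:
    def test_stock_needs_exactly_one_concentration(self):
        with pytest.raises(Exception):
            StockRecord(strain_id="A", copies_per_ml=1e10, ng_per_ul=50.0)
        with pytest.raises(Exception):
            StockRecord(strain_id="A")

    def test_design_needs_two_strains(self):
        with pytest.raises(ConfigError):
            MockDesign(kind=KIND_CELL, strain_ids=("A",))

    def test_kind_mismatch(self):
        design = MockDesign(kind=KIND_DNA, strain_ids=("A", "B"))
        with pytest.raises(ConfigError):
            design_cell_mock([cell_stock("A", 1e12), cell_stock("B", 1e12)], design)

    def test_default_batch_layouts(self):
        cell = MockDesign(kind=KIND_CELL, strain_ids=("A", "B"))
        assert cell.aliquot_count == 100
        assert cell.total_volume_ul == pytest.approx(100 * 100.0)
        dna = MockDesign(kind=KIND_DNA, strain_ids=("A", "B"))
        assert dna.aliquot_count == 50
        assert dna.total_volume_ul == pytest.approx(50 * 30.0)
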