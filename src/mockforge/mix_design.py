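"""Mixing-recipe generation for cell mocks and DNA mocks.

Cell mocks mix PBS-glycerol cell/genome stocks so every strain reaches
an equal copy concentration; the community default is a total of
4e10 copies per mL dispensed as 100 aliquots of 100 uL. DNA mocks mix
purified genomic DNA so genome molarities are equal across strains and
the total mass concentration hits 50 ng/uL, dispensed as 50 aliquots of
30 uL. Designs are solved by exact mass balance with diluent filling the
remaining volume; an over-constrained design is an error, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from mockforge.errors import (
    ConfigError,
    ConsistencyError,
    DomainError,
    InfeasibleDesignError,
    InsufficientStockError,
)
from mockforge.strain_registry import Registry, StrainRecord, genome_mass_grams

KIND_CELL = "cell"
KIND_DNA = "dna"

MODE_TOTAL = "total"
MODE_PER_STRAIN = "per_strain"

_VOLUME_RTOL = 1e-6


@dataclass(frozen=True)
class StockRecord:
    """One strain's stock: cell/genome concentration or DNA mass concentration.

    Exactly one of ``copies_per_ml`` (cell stocks) and ``ng_per_ul``
    (DNA stocks) must be set, matching the design kind.
    """

    strain_id: str
    copies_per_ml: Optional[float] = None
    ng_per_ul: Optional[float] = None
    available_ml: float = float("inf")

    def __post_init__(self) -> None:
        if (self.copies_per_ml is None) == (self.ng_per_ul is None):
            raise DomainError(
                f"stock {self.strain_id!r}: set exactly one of copies_per_ml / ng_per_ul"
            )
        value = self.copies_per_ml if self.copies_per_ml is not None else self.ng_per_ul
        if value <= 0:
            raise DomainError(f"stock {self.strain_id!r}: concentration must be > 0")
        if self.available_ml <= 0:
            raise DomainError(f"stock {self.strain_id!r}: available_ml must be > 0")


@dataclass(frozen=True)
class MockDesign:
    """Target composition and aliquoting plan for one mock batch."""

    kind: str
    strain_ids: tuple[str, ...]
    target_total_copies_per_ml: float = 4e10
    concentration_mode: str = MODE_TOTAL
    aliquot_volume_ul: float = 100.0
    aliquot_count: Optional[int] = None
    target_total_ng_per_ul: float = 50.0
    dna_aliquot_volume_ul: float = 30.0
    dead_volume_ul: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_ids", tuple(self.strain_ids))
        if self.kind not in (KIND_CELL, KIND_DNA):
            raise ConfigError(f"design kind must be 'cell' or 'dna', got {self.kind!r}")
        if len(self.strain_ids) < 2:
            raise ConfigError("a mock design needs >= 2 strains")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ConfigError("design strain_ids contain duplicates")
        if self.concentration_mode not in (MODE_TOTAL, MODE_PER_STRAIN):
            raise ConfigError(f"unknown concentration_mode {self.concentration_mode!r}")
        if self.aliquot_count is None:
            # paper batch defaults: 100 x 100 uL (cell), 50 x 30 uL (dna)
            object.__setattr__(self, "aliquot_count", 100 if self.kind == KIND_CELL else 50)
        if self.aliquot_count <= 0:
            raise ConfigError("aliquot_count must be > 0")
        if self.target_total_copies_per_ml <= 0 or self.target_total_ng_per_ul <= 0:
            raise ConfigError("target concentrations must be > 0")
        if self.dead_volume_ul < 0:
            raise ConfigError("dead_volume_ul must be >= 0")

    @property
    def total_volume_ul(self) -> float:
        per_aliquot = self.aliquot_volume_ul if self.kind == KIND_CELL else self.dna_aliquot_volume_ul
        return per_aliquot * self.aliquot_count + self.dead_volume_ul


@dataclass
class Recipe:
    """Per-strain pipette volumes plus diluent achieving a mock design."""

    kind: str
    per_strain_volume_ul: dict[str, float]
    diluent_volume_ul: float
    total_volume_ul: float
    achieved_per_strain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diluent_volume_ul < -_VOLUME_RTOL * self.total_volume_ul:
            raise InfeasibleDesignError("negative diluent volume: stocks too dilute")
        if any(v < 0 for v in self.per_strain_volume_ul.values()):
            raise DomainError("strain volumes must be >= 0")
        total = sum(self.per_strain_volume_ul.values()) + self.diluent_volume_ul
        if self.total_volume_ul > 0 and abs(total - self.total_volume_ul) > _VOLUME_RTOL * self.total_volume_ul:
            raise DomainError(
                f"volumes sum to {total} uL, expected {self.total_volume_ul} uL"
            )


def _index_stocks(stocks: Sequence[StockRecord], design: MockDesign) -> dict[str, StockRecord]:
    by_id = {}
    for stock in stocks:
        if stock.strain_id in by_id:
            raise ConsistencyError(f"duplicate stock for strain {stock.strain_id!r}")
        by_id[stock.strain_id] = stock
    missing = [sid for sid in design.strain_ids if sid not in by_id]
    if missing:
        raise ConsistencyError(f"no stock for design strains: {', '.join(missing)}")
    return by_id


def design_cell_mock(stocks: Sequence[StockRecord], design: MockDesign) -> Recipe:
    """Solve a cell-mock recipe: equal copies per strain at the target.

    In ``total`` mode the per-strain target concentration is
    ``target_total_copies_per_ml / n``; in ``per_strain`` mode every
    strain targets ``target_total_copies_per_ml`` itself. The pipette
    volume for strain *i* is ``target_i * total_volume / stock_i``.
    """
    if design.kind != KIND_CELL:
        raise ConfigError("design_cell_mock requires a design of kind 'cell'")
    by_id = _index_stocks(stocks, design)
    n = len(design.strain_ids)
    if design.concentration_mode == MODE_TOTAL:
        per_strain_target = design.target_total_copies_per_ml / n
    else:
        per_strain_target = design.target_total_copies_per_ml

    total_ul = design.total_volume_ul
    volumes: dict[str, float] = {}
    achieved: dict[str, float] = {}
    for sid in design.strain_ids:
        stock = by_id[sid]
        if stock.copies_per_ml is None:
            raise ConsistencyError(f"stock {sid!r} is a DNA stock; cell design needs copies_per_ml")
        vol_ul = per_strain_target * total_ul / stock.copies_per_ml
        if vol_ul / 1000.0 > stock.available_ml * (1 + _VOLUME_RTOL):
            raise InsufficientStockError(
                f"strain {sid!r}: needs {vol_ul / 1000.0:.4f} mL but only "
                f"{stock.available_ml:.4f} mL available"
            )
        volumes[sid] = vol_ul
        achieved[sid] = stock.copies_per_ml * vol_ul / total_ul

    used = sum(volumes.values())
    if used > total_ul * (1 + _VOLUME_RTOL):
        raise InfeasibleDesignError(
            f"strain volumes sum to {used:.4f} uL > batch volume {total_ul:.4f} uL; "
            "stocks too dilute for the target concentration"
        )
    return Recipe(
        kind=KIND_CELL,
        per_strain_volume_ul=volumes,
        diluent_volume_ul=max(total_ul - used, 0.0),
        total_volume_ul=total_ul,
        achieved_per_strain=achieved,
    )


def dna_copies_per_ul(ng_per_ul: float, record: StrainRecord) -> float:
    """Genome copies per uL of a DNA solution at ``ng_per_ul``.

    ``copies/uL = ng_per_ul * 1e-9 / genome_mass_grams(record)`` with the
    genome mass from the 660 g/mol/bp duplex convention.
    """
    if ng_per_ul < 0:
        raise DomainError("ng_per_ul must be >= 0")
    return ng_per_ul * 1e-9 / genome_mass_grams(record)


def design_dna_mock(
    stocks: Sequence[StockRecord], design: MockDesign, registry: Registry
) -> Recipe:
    """Solve a DNA-mock recipe: equimolar genomes at the target total mass.

    Equal genome molarity means per-strain mass concentrations
    proportional to genome size; they are scaled so the batch totals
    ``target_total_ng_per_ul``.
    """
    if design.kind != KIND_DNA:
        raise ConfigError("design_dna_mock requires a design of kind 'dna'")
    by_id = _index_stocks(stocks, design)
    missing = [sid for sid in design.strain_ids if sid not in registry]
    if missing:
        raise ConsistencyError(f"registry missing design strains: {', '.join(missing)}")

    sizes = {sid: registry[sid].genome_size_bp for sid in design.strain_ids}
    size_sum = sum(sizes.values())
    total_ul = design.total_volume_ul

    volumes: dict[str, float] = {}
    achieved: dict[str, float] = {}
    for sid in design.strain_ids:
        stock = by_id[sid]
        if stock.ng_per_ul is None:
            raise ConsistencyError(f"stock {sid!r} is a cell stock; DNA design needs ng_per_ul")
        final_ng_per_ul = design.target_total_ng_per_ul * sizes[sid] / size_sum
        vol_ul = final_ng_per_ul * total_ul / stock.ng_per_ul
        if vol_ul / 1000.0 > stock.available_ml * (1 + _VOLUME_RTOL):
            raise InsufficientStockError(
                f"strain {sid!r}: needs {vol_ul / 1000.0:.4f} mL but only "
                f"{stock.available_ml:.4f} mL available"
            )
        volumes[sid] = vol_ul
        achieved[sid] = stock.ng_per_ul * vol_ul / total_ul

    used = sum(volumes.values())
    if used > total_ul * (1 + _VOLUME_RTOL):
        raise InfeasibleDesignError(
            f"strain volumes sum to {used:.4f} uL > batch volume {total_ul:.4f} uL; "
            "stocks too dilute for the target concentration"
        )
    return Recipe(
        kind=KIND_DNA,
        per_strain_volume_ul=volumes,
        diluent_volume_ul=max(total_ul - used, 0.0),
        total_volume_ul=total_ul,
        achieved_per_strain=achieved,
    )


@dataclass
class VerificationReport:
    """Independent mass-balance check of a recipe against its design."""

    passed: bool
    per_strain_relative_error: dict[str, float]
    failing_strains: list[str]
    tolerance: float = _VOLUME_RTOL


def verify_recipe(
    recipe: Recipe,
    stocks: Sequence[StockRecord],
    design: MockDesign,
    registry: Optional[Registry] = None,
) -> VerificationReport:
    """Recompute achieved concentrations by mass balance and compare to target.

    For each strain the achieved concentration is
    ``stock concentration * pipetted volume / total volume``; the report
    fails if any relative error against the design target exceeds 1e-6.
    """
    if set(recipe.per_strain_volume_ul) != set(design.strain_ids):
        raise ConsistencyError("recipe and design strain sets differ")
    by_id = _index_stocks(stocks, design)

    if design.kind == KIND_CELL:
        n = len(design.strain_ids)
        if design.concentration_mode == MODE_TOTAL:
            targets = {sid: design.target_total_copies_per_ml / n for sid in design.strain_ids}
        else:
            targets = {sid: design.target_total_copies_per_ml for sid in design.strain_ids}
        stock_conc = {sid: by_id[sid].copies_per_ml for sid in design.strain_ids}
    else:
        if registry is None:
            raise ConsistencyError("DNA-mock verification needs a registry")
        sizes = {sid: registry[sid].genome_size_bp for sid in design.strain_ids}
        size_sum = sum(sizes.values())
        targets = {
            sid: design.target_total_ng_per_ul * sizes[sid] / size_sum
            for sid in design.strain_ids
        }
        stock_conc = {sid: by_id[sid].ng_per_ul for sid in design.strain_ids}

    errors: dict[str, float] = {}
    failing: list[str] = []
    for sid in design.strain_ids:
        achieved = stock_conc[sid] * recipe.per_strain_volume_ul[sid] / recipe.total_volume_ul
        rel = abs(achieved - targets[sid]) / targets[sid]
        errors[sid] = rel
        if rel > _VOLUME_RTOL:
            failing.append(sid)
    return VerificationReport(
        passed=not failing, per_strain_relative_error=errors, failing_strains=failing
    )
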