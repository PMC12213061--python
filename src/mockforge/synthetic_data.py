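"""Seeded generators for every input the pipeline consumes.

Each generator inverts the corresponding conversion exactly at zero
noise (round-trip identity) and adds the simplest noise model matching
the channel: mean-preserving lognormal multiplicative noise for
continuous concentrations, binomial/multinomial sampling for counting
channels. A single root seed derives independent per-channel substreams
so adding a channel never perturbs the draws of another.

:func:`simulate_study` chains the whole pipeline — enumerate stocks with
channel-specific noise, solve the mixing recipe, assay the achieved
composition by shotgun and ddPCR — emulating a two-condition,
three-batch, triplicate study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mockforge.enumeration import (
    AdenineMeasurement,
    CytometryMeasurement,
    cells_from_cytometry,
    genomes_from_adenine_count_route,
)
from mockforge.errors import ConfigError
from mockforge.mix_design import KIND_CELL, MockDesign, Recipe, StockRecord, design_cell_mock
from mockforge.readout import (
    ABUNDANCE_COLUMNS,
    ASSAY_DDPCR,
    ASSAY_SHOTGUN,
    CountTable,
    DdpcrWell,
    abundance_from_counts,
    abundance_from_ddpcr,
)
from mockforge.strain_registry import (
    AVOGADRO,
    Registry,
    StrainRecord,
    adenines_per_genome,
)

# channel identifiers for substream derivation
_CH_ADENINE = 1
_CH_CYTOMETRY = 2
_CH_DDPCR = 3
_CH_SEQUENCING = 4
_CH_STOCKS = 5

_LAMBDA_SATURATION = 5.0

CONDITION_HPLC = "cell_hplc"
CONDITION_FCM = "cell_fcm"


def channel_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent substream for a (seed, channel, ...) key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative noise with the requested CV."""
    if cv < 0:
        raise ConfigError(f"noise CV must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=n)


@dataclass(frozen=True)
class SimulationConfig:
    """Truth and noise settings for the simulated study.

    true_fractions defaults to uniform 1/n over strain_ids; the study
    layout defaults to 3 batches x 3 replicates. ``exact_assays``
    replaces sampling in the assay channels with their expectations, so
    a config with zero enumeration CVs becomes fully noiseless.
    """

    strain_ids: tuple[str, ...]
    true_fractions: Optional[dict[str, float]] = None
    n_batches: int = 3
    n_replicates: int = 3
    adenine_cv: float = 0.03
    cytometry_cv: float = 0.15
    culture_cv: float = 0.3
    droplet_total: int = 20000
    sequencing_depth: int = 100_000
    extraction_bias: dict[str, float] = field(default_factory=dict)
    exact_assays: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_ids", tuple(self.strain_ids))
        if not self.strain_ids:
            raise ConfigError("strain_ids must be non-empty")
        if self.true_fractions is None:
            uniform = 1.0 / len(self.strain_ids)
            object.__setattr__(
                self, "true_fractions", {sid: uniform for sid in self.strain_ids}
            )
        if set(self.true_fractions) != set(self.strain_ids):
            raise ConfigError("true_fractions keys must match strain_ids")
        total = sum(self.true_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"true_fractions must sum to 1, got {total}")
        for label in ("adenine_cv", "cytometry_cv", "culture_cv"):
            if getattr(self, label) < 0:
                raise ConfigError(f"{label} must be >= 0")
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ConfigError("n_batches and n_replicates must be >= 1")
        if self.droplet_total < 1:
            raise ConfigError("droplet_total must be >= 1")
        if self.sequencing_depth < 0:
            raise ConfigError("sequencing_depth must be >= 0")
        bad_bias = [s for s, b in self.extraction_bias.items() if b <= 0]
        if bad_bias:
            raise ConfigError(f"extraction_bias must be > 0 for {bad_bias}")

    def bias(self, strain_id: str) -> float:
        return self.extraction_bias.get(strain_id, 1.0)


def simulate_adenine(
    config: SimulationConfig,
    record: StrainRecord,
    true_copies_per_ml: float,
    dilution_factor: float = 1.0,
    n_replicates: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[AdenineMeasurement]:
    """Adenine-HPLC replicates whose noiseless inversion is exact.

    The adenine quantity is the exact inverse of the count-route
    conversion, ``copies * adenines_per_genome / (N_A * dilution)``,
    times lognormal noise with CV ``adenine_cv``.
    """
    n = config.n_replicates if n_replicates is None else n_replicates
    rng = rng if rng is not None else channel_rng(config.seed, _CH_ADENINE)
    true_adenine = (
        true_copies_per_ml * adenines_per_genome(record) / (AVOGADRO * dilution_factor)
    )
    factors = _lognormal_factors(rng, config.adenine_cv, n)
    return [
        AdenineMeasurement(
            strain_id=record.strain_id,
            adenine_mol_per_ml=true_adenine * factors[i],
            dilution_factor=dilution_factor,
            replicate_id=f"r{i + 1}",
        )
        for i in range(n)
    ]


def simulate_cytometry(
    config: SimulationConfig,
    strain_id: str,
    true_cells_per_ml: float,
    bead_events: int = 20000,
    bead_stock_per_ml: float = 1e8,
    bead_spike_ratio: float = 0.01,
    dilution_factor: float = 1000.0,
    n_replicates: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[CytometryMeasurement]:
    """Bead-calibrated cytometry replicates inverting cells_from_cytometry.

    cell_events is the exact inverse rounded to an integer, times
    lognormal noise with CV ``cytometry_cv``; the large default bead
    count keeps rounding error negligible.
    """
    n = config.n_replicates if n_replicates is None else n_replicates
    rng = rng if rng is not None else channel_rng(config.seed, _CH_CYTOMETRY)
    r = bead_spike_ratio
    per_event = bead_stock_per_ml * r / (1.0 + r) / bead_events * (1.0 + r) * dilution_factor
    true_events = true_cells_per_ml / per_event
    factors = _lognormal_factors(rng, config.cytometry_cv, n)
    return [
        CytometryMeasurement(
            strain_id=strain_id,
            cell_events=int(round(true_events * factors[i])),
            bead_events=bead_events,
            bead_stock_per_ml=bead_stock_per_ml,
            bead_spike_ratio=bead_spike_ratio,
            dilution_factor=dilution_factor,
            replicate_id=f"r{i + 1}",
        )
        for i in range(n)
    ]


def _ddpcr_lambdas(
    config: SimulationConfig,
    fractions: Mapping[str, float],
    total_copies_per_ul: float,
    droplet_volume_nl: float,
) -> dict[str, float]:
    droplet_volume_ul = droplet_volume_nl * 1e-3
    lambdas = {
        sid: fractions[sid] * total_copies_per_ul * droplet_volume_ul for sid in fractions
    }
    saturated = [sid for sid, lam in lambdas.items() if lam > _LAMBDA_SATURATION]
    if saturated:
        raise ConfigError(
            f"configuration implies droplet saturation (lambda > {_LAMBDA_SATURATION}) "
            f"for strains: {', '.join(sorted(saturated))}; dilute the template"
        )
    return lambdas


def simulate_ddpcr(
    config: SimulationConfig,
    true_fractions: Optional[Mapping[str, float]] = None,
    total_copies_per_ul: float = 1000.0,
    droplet_volume_nl: float = 0.85,
    rng: Optional[np.random.Generator] = None,
) -> list[DdpcrWell]:
    """ddPCR wells per strain/replicate/batch at the implied lambdas.

    Each strain's positives are Binomial(droplet_total, 1 - e^{-lambda})
    with lambda from its share of ``total_copies_per_ul``.
    """
    fractions = dict(true_fractions) if true_fractions is not None else config.true_fractions
    rng = rng if rng is not None else channel_rng(config.seed, _CH_DDPCR)
    lambdas = _ddpcr_lambdas(config, fractions, total_copies_per_ul, droplet_volume_nl)
    wells = []
    for b in range(config.n_batches):
        for r in range(config.n_replicates):
            for sid in fractions:
                p_positive = -math.expm1(-lambdas[sid])
                positives = int(rng.binomial(config.droplet_total, p_positive))
                wells.append(
                    DdpcrWell(
                        strain_id=sid,
                        total_droplets=config.droplet_total,
                        positive_droplets=positives,
                        droplet_volume_nl=droplet_volume_nl,
                        batch_id=f"b{b + 1}",
                        replicate_id=f"r{r + 1}",
                    )
                )
    return wells


def simulate_sequencing(
    config: SimulationConfig,
    true_fractions: Optional[Mapping[str, float]] = None,
    registry: Optional[Registry] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[CountTable]:
    """Multinomial shotgun count tables per replicate per batch.

    Read weights are ``fraction_i * genome_length_i * extraction_bias_i``,
    so genome-normalized abundance of the expectation equals the
    bias-weighted truth. Zero depth yields all-zero tables whose
    no-signal error surfaces downstream.
    """
    fractions = dict(true_fractions) if true_fractions is not None else config.true_fractions
    if registry is None:
        raise ConfigError("simulate_sequencing needs a registry for genome lengths")
    rng = rng if rng is not None else channel_rng(config.seed, _CH_SEQUENCING)
    strain_ids = tuple(fractions)
    lengths = tuple(registry[sid].genome_size_bp for sid in strain_ids)
    weights = np.array(
        [fractions[sid] * registry[sid].genome_size_bp * config.bias(sid) for sid in strain_ids]
    )
    probs = weights / weights.sum()
    tables = []
    for b in range(config.n_batches):
        for r in range(config.n_replicates):
            if config.exact_assays:
                counts = tuple(float(c) for c in probs * config.sequencing_depth)
            else:
                counts = tuple(
                    float(c) for c in rng.multinomial(config.sequencing_depth, probs)
                )
            tables.append(
                CountTable(
                    strain_ids=strain_ids,
                    mapped_counts=counts,
                    genome_lengths_bp=lengths,
                    batch_id=f"b{b + 1}",
                    replicate_id=f"r{r + 1}",
                )
            )
    return tables


@dataclass
class StudyBundle:
    """End-to-end simulation output: stocks, recipes and abundance tables."""

    config: SimulationConfig
    true_stock_copies_per_ml: dict[tuple[str, str, str], float]
    measured_stock_copies_per_ml: dict[tuple[str, str, str], float]
    recipes: dict[tuple[str, str], Recipe]
    achieved_fractions: dict[tuple[str, str, str], float]
    abundance: pd.DataFrame


def simulate_study(config: SimulationConfig, registry: Registry) -> StudyBundle:
    """Simulate a two-condition mock-production study end-to-end.

    For each condition (adenine-HPLC vs cytometry enumeration, with the
    respective noise CVs) and each batch: draw true stock concentrations
    (independent cultures), measure them through the condition's noisy
    channel, solve the cell-mock recipe from the measured values, and
    propagate the pipetted volumes against the *true* concentrations to
    the achieved composition. Each batch is then assayed in triplicate
    by shotgun sequencing and ddPCR on the bias-weighted template.

    With zero enumeration noise and ``exact_assays=True`` the pipeline
    recovers the design composition exactly (CV=0, AFD=1 per strain).
    """
    missing = [sid for sid in config.strain_ids if sid not in registry]
    if missing:
        raise ConfigError(f"registry missing strains: {', '.join(missing)}")
    n = len(config.strain_ids)
    design = MockDesign(
        kind=KIND_CELL,
        strain_ids=config.strain_ids,
        target_total_copies_per_ml=4e10,
    )

    stock_rng = channel_rng(config.seed, _CH_STOCKS)
    adenine_rng = channel_rng(config.seed, _CH_ADENINE)
    cytometry_rng = channel_rng(config.seed, _CH_CYTOMETRY)
    ddpcr_rng = channel_rng(config.seed, _CH_DDPCR)
    seq_rng = channel_rng(config.seed, _CH_SEQUENCING)

    true_stock: dict[tuple[str, str, str], float] = {}
    measured_stock: dict[tuple[str, str, str], float] = {}
    recipes: dict[tuple[str, str], Recipe] = {}
    achieved: dict[tuple[str, str, str], float] = {}
    entries: list[pd.DataFrame] = []

    conditions = ((CONDITION_HPLC, "adenine"), (CONDITION_FCM, "cytometry"))
    for condition, channel in conditions:
        for b in range(config.n_batches):
            batch = f"b{b + 1}"
            # independent culture per batch: true concentration around 2e11/mL
            culture_factors = _lognormal_factors(stock_rng, config.culture_cv, n)
            stocks = []
            for i, sid in enumerate(config.strain_ids):
                truth = 2e11 * culture_factors[i]
                true_stock[(condition, batch, sid)] = truth
                record = registry[sid]
                if channel == "adenine":
                    reps = simulate_adenine(config, record, truth, rng=adenine_rng)
                    concs = [
                        genomes_from_adenine_count_route(m, record).copies_per_ml
                        for m in reps
                    ]
                else:
                    reps = simulate_cytometry(config, sid, truth, rng=cytometry_rng)
                    concs = [cells_from_cytometry(m).copies_per_ml for m in reps]
                measured = float(np.mean(concs))
                measured_stock[(condition, batch, sid)] = measured
                stocks.append(StockRecord(strain_id=sid, copies_per_ml=measured))

            recipe = design_cell_mock(stocks, design)
            recipes[(condition, batch)] = recipe

            actual_copies = np.array(
                [
                    recipe.per_strain_volume_ul[sid] * true_stock[(condition, batch, sid)]
                    for sid in config.strain_ids
                ]
            )
            fractions = actual_copies / actual_copies.sum()
            for sid, frac in zip(config.strain_ids, fractions):
                achieved[(condition, batch, sid)] = float(frac)

            # DNA extraction bias acts on the assay template
            template = np.array(
                [f * config.bias(sid) for sid, f in zip(config.strain_ids, fractions)]
            )
            template = template / template.sum()
            template_map = dict(zip(config.strain_ids, template))

            batch_config = replace(config, n_batches=1)
            tables = simulate_sequencing(
                batch_config, template_map, registry, rng=seq_rng
            )
            for table in tables:
                frame = abundance_from_counts(table)
                frame["batch_id"] = batch
                frame["condition"] = condition
                entries.append(frame)

            if config.exact_assays:
                for r in range(config.n_replicates):
                    frame = pd.DataFrame(
                        {
                            "strain_id": list(config.strain_ids),
                            "batch_id": batch,
                            "replicate_id": f"r{r + 1}",
                            "assay": ASSAY_DDPCR,
                            "fraction": [template_map[sid] for sid in config.strain_ids],
                        },
                        columns=ABUNDANCE_COLUMNS,
                    )
                    frame["condition"] = condition
                    entries.append(frame)
            else:
                wells = simulate_ddpcr(batch_config, template_map, rng=ddpcr_rng)
                frame = abundance_from_ddpcr(wells)
                frame["batch_id"] = batch
                frame["condition"] = condition
                entries.append(frame)

    abundance = pd.concat(entries, ignore_index=True)[ABUNDANCE_COLUMNS + ["condition"]]
    return StudyBundle(
        config=config,
        true_stock_copies_per_ml=true_stock,
        measured_stock_copies_per_ml=measured_stock,
        recipes=recipes,
        achieved_fractions=achieved,
        abundance=abundance,
    )
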