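"""Convert raw enumeration measurements into genome/cell concentrations.

Three routes are supported:

* adenine-HPLC: moles of adenine released by depurination of genomic DNA
  are converted to genome copies, either directly by counting adenine
  residues per genome (the reference "count route") or by first
  converting adenine to a DNA mass via the dNMP molecular weights and
  then dividing by the mass of a single genome (the "mass route").
* flow cytometry: cell events are calibrated against a known spike of
  counting beads.
* microscopy: mean cells per field are scaled up by filter geometry and
  the filtered volume.

All concentrations refer to the initial cell resuspension after undoing
the recorded dilution. Results can be normalized to one OD600 unit for
cross-method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from mockforge.errors import (
    DegenerateCompositionError,
    DomainError,
    InsufficientDataError,
    NoReferenceError,
)
from mockforge.strain_registry import (
    AVOGADRO,
    StrainRecord,
    adenines_per_genome,
    genome_mass_grams,
)

METHOD_ADENINE = "adenine_hplc"
METHOD_CYTOMETRY = "flow_cytometry"
METHOD_MICROSCOPY = "microscopy"

BASIS_GENOMES = "genomes"
BASIS_CELLS = "cells"


@dataclass(frozen=True)
class DnmpMassSet:
    """Molecular weights (g/mol) of the four deoxyribonucleoside monophosphates."""

    damp: float = 331.22
    dtmp: float = 322.21
    dgmp: float = 347.22
    dcmp: float = 307.20

    def __post_init__(self) -> None:
        for label in ("damp", "dtmp", "dgmp", "dcmp"):
            if getattr(self, label) <= 0:
                raise DomainError(f"dNMP mass {label} must be > 0")


#: Free-acid monophosphate masses; A:T/G:C pair sums (~654) are consistent
#: with the 660 g/mol/bp duplex convention.
DEFAULT_DNMP_MASSES = DnmpMassSet()


@dataclass(frozen=True)
class AdenineMeasurement:
    """Adenine-HPLC reading for one replicate of one strain."""

    strain_id: str
    adenine_mol_per_ml: float
    dilution_factor: float = 1.0
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.adenine_mol_per_ml < 0:
            raise DomainError("adenine_mol_per_ml must be >= 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class CytometryMeasurement:
    """Flow-cytometry event counts with the bead calibration context."""

    strain_id: str
    cell_events: int
    bead_events: int
    bead_stock_per_ml: float
    bead_spike_ratio: float = 0.01
    dilution_factor: float = 1.0
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.cell_events < 0:
            raise DomainError("cell_events must be >= 0")
        if self.bead_stock_per_ml <= 0:
            raise DomainError("bead_stock_per_ml must be > 0")
        if not 0 < self.bead_spike_ratio <= 1:
            raise DomainError("bead_spike_ratio must lie in (0, 1]")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class MicroscopyMeasurement:
    """Cells-per-image counts over ≥1 microscope fields of a filter."""

    strain_id: str
    field_counts: tuple[int, ...]
    field_area_mm2: float
    filter_area_mm2: float
    volume_filtered_ml: float
    dilution_factor: float = 1.0
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_counts", tuple(int(c) for c in self.field_counts))
        if any(c < 0 for c in self.field_counts):
            raise DomainError("field counts must be >= 0")
        if self.field_area_mm2 <= 0 or self.filter_area_mm2 <= 0:
            raise DomainError("field and filter areas must be > 0")
        if self.field_area_mm2 > self.filter_area_mm2:
            raise DomainError("field_area_mm2 cannot exceed filter_area_mm2")
        if self.volume_filtered_ml <= 0:
            raise DomainError("volume_filtered_ml must be > 0")
        if self.dilution_factor < 1:
            raise DomainError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class GenomeConcentration:
    """Genome or cell concentration with measurement provenance."""

    strain_id: str
    copies_per_ml: float
    method: str
    basis: str
    replicate_id: str = "r1"
    od600: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copies_per_ml < 0:
            raise DomainError("copies_per_ml must be >= 0")
        if self.method == METHOD_ADENINE and self.basis != BASIS_GENOMES:
            raise DomainError("adenine_hplc concentrations are on the genomes basis")
        if self.method in (METHOD_CYTOMETRY, METHOD_MICROSCOPY) and self.basis != BASIS_CELLS:
            raise DomainError(f"{self.method} concentrations are on the cells basis")
        if self.od600 is not None and self.od600 <= 0:
            raise DomainError("od600 must be > 0")


def genomes_from_adenine_count_route(
    meas: AdenineMeasurement, record: StrainRecord
) -> GenomeConcentration:
    """Genome concentration from adenine moles by residue counting.

    One genome copy holds ``genome_size_bp * (1 - GC)`` adenines, so

    ``copies/mL = adenine_mol_per_ml * N_A / adenines_per_genome * dilution``.

    This is the reference adenine route.
    """
    apg = adenines_per_genome(record)  # raises on degenerate composition
    copies = meas.adenine_mol_per_ml * AVOGADRO / apg * meas.dilution_factor
    return GenomeConcentration(
        strain_id=meas.strain_id,
        copies_per_ml=copies,
        method=METHOD_ADENINE,
        basis=BASIS_GENOMES,
        replicate_id=meas.replicate_id,
    )


def genomes_from_adenine_mass_route(
    meas: AdenineMeasurement,
    record: StrainRecord,
    masses: DnmpMassSet = DEFAULT_DNMP_MASSES,
) -> GenomeConcentration:
    """Genome concentration from adenine via DNA mass (cross-check route).

    Adenine moles are scaled to total nucleotide moles using the adenine
    nucleotide fraction ``f_A = (1 - GC) / 2``, converted to grams of DNA
    with the composition-weighted mean dNMP mass, and divided by the mass
    of one genome particle. Differs from the count route by ~1% because
    the genome mass uses the 660 g/mol/bp convention rather than the
    actual mean nucleotide mass.
    """
    gc = record.gc_fraction
    if not 0.0 < gc < 1.0:
        raise DegenerateCompositionError(
            f"strain {record.strain_id!r}: GC fraction {gc} outside (0, 1)"
        )
    f_a = (1.0 - gc) / 2.0
    total_nucleotide_mol = meas.adenine_mol_per_ml / f_a
    mean_mass = f_a * (masses.damp + masses.dtmp) + (gc / 2.0) * (masses.dgmp + masses.dcmp)
    dna_grams_per_ml = total_nucleotide_mol * mean_mass
    copies = dna_grams_per_ml / genome_mass_grams(record) * meas.dilution_factor
    return GenomeConcentration(
        strain_id=meas.strain_id,
        copies_per_ml=copies,
        method=METHOD_ADENINE,
        basis=BASIS_GENOMES,
        replicate_id=meas.replicate_id,
    )


def cells_from_cytometry(meas: CytometryMeasurement) -> GenomeConcentration:
    """Cell concentration from bead-calibrated cytometry events.

    With spike ratio ``r`` (bead suspension volume per stained-sample
    volume), the measured mixture contains beads at
    ``bead_stock * r / (1 + r)``; the cell concentration of the mixture is
    that times ``cell_events / bead_events``, corrected back to the
    stained sample by ``(1 + r)`` and then by the dilution factor.
    """
    if meas.bead_events <= 0:
        raise NoReferenceError(
            f"strain {meas.strain_id!r}: no bead events recorded; cannot calibrate"
        )
    r = meas.bead_spike_ratio
    beads_in_mixture = meas.bead_stock_per_ml * r / (1.0 + r)
    cells_in_mixture = (meas.cell_events / meas.bead_events) * beads_in_mixture
    copies = cells_in_mixture * (1.0 + r) * meas.dilution_factor
    return GenomeConcentration(
        strain_id=meas.strain_id,
        copies_per_ml=copies,
        method=METHOD_CYTOMETRY,
        basis=BASIS_CELLS,
        replicate_id=meas.replicate_id,
    )


def cells_from_microscopy(meas: MicroscopyMeasurement) -> GenomeConcentration:
    """Cell concentration from per-field microscope counts.

    ``copies/mL = mean(field_counts) * (filter_area / field_area)
    / volume_filtered * dilution``.
    """
    if len(meas.field_counts) == 0:
        raise InsufficientDataError(
            f"strain {meas.strain_id!r}: no microscope fields recorded"
        )
    mean_count = float(np.mean(meas.field_counts))
    copies = (
        mean_count
        * (meas.filter_area_mm2 / meas.field_area_mm2)
        / meas.volume_filtered_ml
        * meas.dilution_factor
    )
    return GenomeConcentration(
        strain_id=meas.strain_id,
        copies_per_ml=copies,
        method=METHOD_MICROSCOPY,
        basis=BASIS_CELLS,
        replicate_id=meas.replicate_id,
    )


def normalize_to_od(conc: GenomeConcentration, od600: float) -> GenomeConcentration:
    """Express a concentration per 1 unit of OD600 (divide by measured OD)."""
    if od600 <= 0:
        raise DomainError(f"od600 must be > 0, got {od600}")
    return replace(conc, copies_per_ml=conc.copies_per_ml / od600, od600=od600)


def aggregate_replicates(concs: Sequence[GenomeConcentration]) -> tuple[float, float]:
    """Mean and sample SD of concentrations over >=2 replicates.

    Aggregation happens on concentrations, not raw signals.
    """
    if len(concs) < 2:
        raise InsufficientDataError("replicate aggregation needs >= 2 concentrations")
    strains = {c.strain_id for c in concs}
    if len(strains) != 1:
        raise DomainError(f"cannot aggregate across strains: {sorted(strains)}")
    values = np.array([c.copies_per_ml for c in concs], dtype=float)
    return float(values.mean()), float(values.std(ddof=1))
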