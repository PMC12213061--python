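"""Assay readouts to relative abundances.

Two orthogonal assays are supported: droplet digital PCR wells (one
strain-specific probe per well, Poisson estimation from the positive
droplet fraction) and shotgun-sequencing count tables in the kallisto
``abundance.tsv`` layout. Both produce tidy abundance entries whose
fractions sum to 1 within each (batch, replicate, assay) group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from mockforge.errors import (
    ConsistencyError,
    DomainError,
    NoDataError,
    SaturationError,
    SchemaError,
)
from mockforge.strain_registry import Registry

ASSAY_SHOTGUN = "shotgun"
ASSAY_DDPCR = "ddpcr"

MODE_GENOME_NORMALIZED = "genome_normalized"
MODE_RAW = "raw"

#: Columns of a tidy abundance table.
ABUNDANCE_COLUMNS = ["strain_id", "batch_id", "replicate_id", "assay", "fraction"]

_KALLISTO_COLUMNS = ["target_id", "length", "eff_length", "est_counts", "tpm"]


@dataclass(frozen=True)
class DdpcrWell:
    """One ddPCR well: droplet counts for a single strain's probe."""

    strain_id: str
    total_droplets: int
    positive_droplets: int
    droplet_volume_nl: float = 0.85
    template_dilution_factor: float = 1.0
    probe_copies_per_genome: int = 1
    batch_id: str = "b1"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.total_droplets < 0:
            raise DomainError("total_droplets must be >= 0")
        if self.positive_droplets < 0:
            raise DomainError("positive_droplets must be >= 0")
        if self.positive_droplets > self.total_droplets:
            raise DomainError("positive_droplets cannot exceed total_droplets")
        if self.droplet_volume_nl <= 0:
            raise DomainError("droplet_volume_nl must be > 0")
        if self.template_dilution_factor < 1:
            raise DomainError("template_dilution_factor must be >= 1")
        if self.probe_copies_per_genome < 1:
            raise DomainError("probe_copies_per_genome must be >= 1")


@dataclass(frozen=True)
class CountTable:
    """Per-strain mapped read counts with genome lengths for one replicate."""

    strain_ids: tuple[str, ...]
    mapped_counts: tuple[float, ...]
    genome_lengths_bp: tuple[int, ...]
    batch_id: str = "b1"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if not (len(self.strain_ids) == len(self.mapped_counts) == len(self.genome_lengths_bp)):
            raise DomainError("count table columns must have equal length")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise DomainError("duplicate strain_id in count table")
        if any(c < 0 for c in self.mapped_counts):
            raise DomainError("mapped counts must be >= 0")
        if any(l <= 0 for l in self.genome_lengths_bp):
            raise DomainError("genome lengths must be > 0")


def ddpcr_lambda(well: DdpcrWell) -> float:
    """Mean template copies per droplet: ``lambda = -ln(1 - p/t)``.

    Raises on saturation (every droplet positive) and on empty wells.
    """
    if well.total_droplets == 0:
        raise NoDataError(f"strain {well.strain_id!r}: well has zero droplets")
    if well.positive_droplets == well.total_droplets:
        raise SaturationError(
            f"strain {well.strain_id!r}: all {well.total_droplets} droplets positive; "
            "lambda undefined — dilute the template"
        )
    return -math.log(1.0 - well.positive_droplets / well.total_droplets)


def ddpcr_concentration(well: DdpcrWell) -> float:
    """Genome-equivalent template copies per uL of the assayed solution.

    ``copies/uL = lambda / (droplet_volume_nl * 1e-3)
    * template_dilution_factor / probe_copies_per_genome``.
    """
    lam = ddpcr_lambda(well)
    droplet_volume_ul = well.droplet_volume_nl * 1e-3
    return (
        lam / droplet_volume_ul * well.template_dilution_factor / well.probe_copies_per_genome
    )


def abundance_from_ddpcr(wells: Sequence[DdpcrWell]) -> pd.DataFrame:
    """Relative abundances from one ddPCR well per strain per replicate.

    Within each (batch, replicate) the genome-equivalent concentrations
    are normalized to fractions. Missing/duplicated strains within a
    replicate and all-zero replicates are errors.
    """
    if not wells:
        raise NoDataError("no ddPCR wells supplied")
    frame = pd.DataFrame(
        {
            "strain_id": [w.strain_id for w in wells],
            "batch_id": [w.batch_id for w in wells],
            "replicate_id": [w.replicate_id for w in wells],
            "concentration": [ddpcr_concentration(w) for w in wells],
        }
    )
    strain_sets = frame.groupby(["batch_id", "replicate_id"])["strain_id"].agg(set)
    expected = strain_sets.iloc[0]
    for (batch, rep), seen in strain_sets.items():
        if seen != expected:
            raise ConsistencyError(
                f"replicate ({batch}, {rep}) strain set differs from the first replicate"
            )
    dup = frame.duplicated(subset=["batch_id", "replicate_id", "strain_id"])
    if dup.any():
        bad = frame.loc[dup, "strain_id"].unique()
        raise ConsistencyError(f"duplicated strain wells within a replicate: {sorted(bad)}")

    def _normalize(group: pd.DataFrame) -> pd.DataFrame:
        total = group["concentration"].sum()
        if total <= 0:
            raise NoDataError(
                f"replicate ({group.name[0]}, {group.name[1]}): all wells negative"
            )
        out = group.copy()
        out["fraction"] = out["concentration"] / total
        return out

    frame = (
        frame.groupby(["batch_id", "replicate_id"], group_keys=False)[frame.columns]
        .apply(_normalize)
        .reset_index(drop=True)
    )
    frame["assay"] = ASSAY_DDPCR
    return frame[ABUNDANCE_COLUMNS]


def read_count_table(
    path: Union[str, Path],
    registry: Registry,
    target_map: Mapping[str, str],
    batch_id: str = "b1",
    replicate_id: str = "r1",
) -> CountTable:
    """Read a kallisto ``abundance.tsv`` file into per-strain counts.

    ``target_map`` maps each ``target_id`` (one sequence per replicon)
    to a strain_id; counts of targets mapped to the same strain are
    summed. Unmapped targets are an error listing the orphans.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _KALLISTO_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"count table missing kallisto columns: {', '.join(missing)}")
    orphans = sorted(set(frame["target_id"]) - set(target_map))
    if orphans:
        raise SchemaError(f"unmapped target_id values: {', '.join(map(str, orphans))}")
    frame["strain_id"] = frame["target_id"].map(target_map)
    unknown = sorted(set(frame["strain_id"]) - set(registry.strain_ids))
    if unknown:
        raise ConsistencyError(f"target map names strains outside the registry: {unknown}")
    summed = frame.groupby("strain_id", sort=True)["est_counts"].sum()
    strain_ids = tuple(summed.index)
    return CountTable(
        strain_ids=strain_ids,
        mapped_counts=tuple(float(v) for v in summed.values),
        genome_lengths_bp=tuple(registry[sid].genome_size_bp for sid in strain_ids),
        batch_id=batch_id,
        replicate_id=replicate_id,
    )


def abundance_from_counts(
    table: CountTable, mode: str = MODE_GENOME_NORMALIZED
) -> pd.DataFrame:
    """Relative abundances from a count table.

    ``genome_normalized`` divides each count by its genome length before
    normalizing (genome-copy basis, comparable to ddPCR); ``raw``
    normalizes the counts directly.
    """
    if mode not in (MODE_GENOME_NORMALIZED, MODE_RAW):
        raise DomainError(f"unknown abundance mode {mode!r}")
    total = sum(table.mapped_counts)
    if total <= 0:
        raise NoDataError(
            f"replicate ({table.batch_id}, {table.replicate_id}): all counts zero"
        )
    if mode == MODE_GENOME_NORMALIZED:
        weights = [c / l for c, l in zip(table.mapped_counts, table.genome_lengths_bp)]
    else:
        weights = list(table.mapped_counts)
    weight_sum = sum(weights)
    return pd.DataFrame(
        {
            "strain_id": table.strain_ids,
            "batch_id": table.batch_id,
            "replicate_id": table.replicate_id,
            "assay": ASSAY_SHOTGUN,
            "fraction": [w / weight_sum for w in weights],
        },
        columns=ABUNDANCE_COLUMNS,
    )
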