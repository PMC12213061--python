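"""Strain metadata registry and derived per-genome constants.

A registry is a table of strains with the genome facts every downstream
conversion needs: total genome size in base pairs, GC content and 16S
rRNA gene copy number. The packaged default fixture describes the 15
strains of the Cell-Mock-002 / DNA-Mock-002 communities.

GC content is stored internally as a fraction in (0, 1); all file I/O
uses percent so that tables read the way strain catalogues print them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

import pandas as pd

from mockforge.errors import DegenerateCompositionError, RegistryLoadError

#: 2019 SI exact value of the Avogadro constant (mol^-1).
AVOGADRO = 6.02214076e23

#: Conventional average molecular weight of one duplex DNA base pair (g/mol).
BASE_PAIR_G_PER_MOL = 660.0

#: Marker accepted by :func:`load_registry` for the packaged fixture.
PACKAGED = "packaged"

_COLUMNS = ["name", "strain_id", "genome_size_bp", "gc_percent", "rrs_copies", "accessions"]
_GRAM_VALUES = {"positive", "negative", "unknown"}


@dataclass(frozen=True)
class StrainRecord:
    """Per-strain genome facts driving every conversion.

    Parameters
    ----------
    name : str
        Organism name.
    strain_id : str
        Collection identifier, unique within a registry.
    genome_size_bp : int
        Total genome size in base pairs, summed over all replicons.
    gc_fraction : float
        GC content as a fraction in (0, 1).
    rrs_copies : int
        16S rRNA gene copy number.
    accessions : tuple of str
        Sequence accession strings.
    gram_stain : str, optional
        One of ``positive``, ``negative``, ``unknown``; metadata only.
    """

    name: str
    strain_id: str
    genome_size_bp: int
    gc_fraction: float
    rrs_copies: int
    accessions: tuple[str, ...] = ()
    gram_stain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genome_size_bp < 1:
            raise RegistryLoadError(
                f"strain {self.strain_id!r}: genome_size_bp must be >= 1, "
                f"got {self.genome_size_bp}"
            )
        if not 0.0 < self.gc_fraction < 1.0:
            raise RegistryLoadError(
                f"strain {self.strain_id!r}: gc_fraction must lie strictly in (0, 1), "
                f"got {self.gc_fraction}"
            )
        if self.rrs_copies < 1:
            raise RegistryLoadError(
                f"strain {self.strain_id!r}: rrs_copies must be >= 1, got {self.rrs_copies}"
            )
        if self.gram_stain is not None and self.gram_stain not in _GRAM_VALUES:
            raise RegistryLoadError(
                f"strain {self.strain_id!r}: gram_stain must be one of {sorted(_GRAM_VALUES)}"
            )

    @property
    def gc_percent(self) -> float:
        return self.gc_fraction * 100.0


@dataclass
class Registry:
    """Mapping of strain_id to :class:`StrainRecord`."""

    records: dict[str, StrainRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StrainRecord]:
        return iter(self.records.values())

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self.records

    def __getitem__(self, strain_id: str) -> StrainRecord:
        try:
            return self.records[strain_id]
        except KeyError:
            raise KeyError(f"strain {strain_id!r} not in registry") from None

    @property
    def strain_ids(self) -> list[str]:
        return list(self.records)

    def add(self, record: StrainRecord) -> None:
        if record.strain_id in self.records:
            raise RegistryLoadError(f"duplicate strain_id {record.strain_id!r}")
        self.records[record.strain_id] = record

    def subset(self, strain_ids: Iterable[str]) -> "Registry":
        return Registry({sid: self[sid] for sid in strain_ids})


def _parse_row(row: Mapping, line_no: int) -> StrainRecord:
    where = f"registry row {line_no} (strain_id={row.get('strain_id')!r})"
    try:
        size = int(row["genome_size_bp"])
    except (TypeError, ValueError):
        raise RegistryLoadError(f"{where}: non-numeric genome_size_bp {row['genome_size_bp']!r}")
    try:
        gc_percent = float(row["gc_percent"])
    except (TypeError, ValueError):
        raise RegistryLoadError(f"{where}: non-numeric gc_percent {row['gc_percent']!r}")
    if not 0.0 < gc_percent < 100.0:
        raise RegistryLoadError(
            f"{where}: gc_percent must lie strictly in (0, 100), got {gc_percent}"
        )
    try:
        rrs = int(row["rrs_copies"])
    except (TypeError, ValueError):
        raise RegistryLoadError(f"{where}: non-numeric rrs_copies {row['rrs_copies']!r}")

    raw_acc = row.get("accessions", "")
    if raw_acc is None or (isinstance(raw_acc, float) and math.isnan(raw_acc)):
        raw_acc = ""
    accessions = tuple(a.strip() for a in str(raw_acc).split(";") if a.strip())

    gram = row.get("gram_stain")
    if gram is not None and (not isinstance(gram, str) or not gram.strip()):
        gram = None

    try:
        return StrainRecord(
            name=str(row["name"]),
            strain_id=str(row["strain_id"]),
            genome_size_bp=size,
            gc_fraction=gc_percent / 100.0,
            rrs_copies=rrs,
            accessions=accessions,
            gram_stain=gram,
        )
    except RegistryLoadError as exc:
        raise RegistryLoadError(f"{where}: {exc}") from None


def load_registry(source: Union[str, Path] = PACKAGED) -> Registry:
    """Load a registry from a tab-separated table or the packaged fixture.

    Parameters
    ----------
    source : str or Path
        Path to a UTF-8 tab-separated table with header columns
        ``name, strain_id, genome_size_bp, gc_percent, rrs_copies,
        accessions`` (``gram_stain`` optional), or the marker
        ``"packaged"`` for the bundled 15-strain fixture.

    Raises
    ------
    RegistryLoadError
        On missing columns, non-numeric values, GC outside (0, 100)
        or duplicated strain_id, naming the offending row.
    """
    if source == PACKAGED:
        with resources.as_file(
            resources.files("mockforge").joinpath("data/table1_strains.tsv")
        ) as path:
            frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    else:
        path = Path(source)
        if not path.exists():
            raise RegistryLoadError(f"registry file not found: {path}")
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise RegistryLoadError(f"registry table missing columns: {', '.join(missing)}")

    registry = Registry()
    for i, row in enumerate(frame.to_dict(orient="records"), start=2):
        registry.add(_parse_row(row, line_no=i))
    return registry


def write_registry(registry: Registry, path: Union[str, Path]) -> None:
    """Write a registry back to the tab-separated interchange format."""
    rows = []
    for rec in registry:
        rows.append(
            {
                "name": rec.name,
                "strain_id": rec.strain_id,
                "genome_size_bp": rec.genome_size_bp,
                "gc_percent": repr(rec.gc_percent),
                "rrs_copies": rec.rrs_copies,
                "accessions": ";".join(rec.accessions),
                "gram_stain": rec.gram_stain or "",
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS + ["gram_stain"]).to_csv(path, sep="\t", index=False)


def adenines_per_genome(record: StrainRecord) -> float:
    """Adenine residues in one duplex genome copy.

    Each A:T base pair contributes exactly one adenine, so the count is
    ``genome_size_bp * (1 - gc_fraction)``.
    """
    at_fraction = 1.0 - record.gc_fraction
    if at_fraction <= 0.0:
        raise DegenerateCompositionError(
            f"strain {record.strain_id!r}: gc_fraction >= 1 leaves no adenine"
        )
    return record.genome_size_bp * at_fraction


def genome_mass_grams(record: StrainRecord) -> float:
    """Mass in grams of a single genome copy.

    Uses the 660 g/mol average molecular weight of one duplex base pair:
    ``genome_size_bp * 660 / N_A``.
    """
    return record.genome_size_bp * BASE_PAIR_G_PER_MOL / AVOGADRO
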