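"""Shared tab-separated table readers/writers.

All tables are UTF-8, header-first, tab-separated; missing values are
empty fields (never "."). Numbers are serialized with repr-level
precision so write -> read is the identity on the data model.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from mockforge.enumeration import (
    AdenineMeasurement,
    CytometryMeasurement,
    GenomeConcentration,
    MicroscopyMeasurement,
)
from mockforge.errors import SchemaError
from mockforge.mix_design import MockDesign, Recipe, StockRecord
from mockforge.readout import ABUNDANCE_COLUMNS, DdpcrWell

PathLike = Union[str, Path]


def _read(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    return frame


def _opt(row, column, default):
    if column not in row or pd.isna(row[column]):
        return default
    return row[column]


def read_adenine_table(path: PathLike) -> list[AdenineMeasurement]:
    frame = _read(path, ["strain_id", "adenine_mol_per_ml"])
    return [
        AdenineMeasurement(
            strain_id=str(row["strain_id"]),
            adenine_mol_per_ml=float(row["adenine_mol_per_ml"]),
            dilution_factor=float(_opt(row, "dilution_factor", 1.0)),
            replicate_id=str(_opt(row, "replicate_id", "r1")),
        )
        for _, row in frame.iterrows()
    ]


def read_cytometry_table(path: PathLike) -> list[CytometryMeasurement]:
    frame = _read(path, ["strain_id", "cell_events", "bead_events", "bead_stock_per_ml"])
    return [
        CytometryMeasurement(
            strain_id=str(row["strain_id"]),
            cell_events=int(row["cell_events"]),
            bead_events=int(row["bead_events"]),
            bead_stock_per_ml=float(row["bead_stock_per_ml"]),
            bead_spike_ratio=float(_opt(row, "bead_spike_ratio", 0.01)),
            dilution_factor=float(_opt(row, "dilution_factor", 1.0)),
            replicate_id=str(_opt(row, "replicate_id", "r1")),
        )
        for _, row in frame.iterrows()
    ]


def read_microscopy_table(path: PathLike) -> list[MicroscopyMeasurement]:
    frame = _read(
        path,
        ["strain_id", "field_counts", "field_area_mm2", "filter_area_mm2", "volume_filtered_ml"],
    )
    out = []
    for _, row in frame.iterrows():
        counts = tuple(int(c) for c in str(row["field_counts"]).split(";") if c != "")
        out.append(
            MicroscopyMeasurement(
                strain_id=str(row["strain_id"]),
                field_counts=counts,
                field_area_mm2=float(row["field_area_mm2"]),
                filter_area_mm2=float(row["filter_area_mm2"]),
                volume_filtered_ml=float(row["volume_filtered_ml"]),
                dilution_factor=float(_opt(row, "dilution_factor", 1.0)),
                replicate_id=str(_opt(row, "replicate_id", "r1")),
            )
        )
    return out


def read_ddpcr_table(path: PathLike) -> list[DdpcrWell]:
    frame = _read(path, ["strain_id", "total_droplets", "positive_droplets"])
    return [
        DdpcrWell(
            strain_id=str(row["strain_id"]),
            total_droplets=int(row["total_droplets"]),
            positive_droplets=int(row["positive_droplets"]),
            droplet_volume_nl=float(_opt(row, "droplet_volume_nl", 0.85)),
            template_dilution_factor=float(_opt(row, "template_dilution_factor", 1.0)),
            probe_copies_per_genome=int(_opt(row, "probe_copies_per_genome", 1)),
            batch_id=str(_opt(row, "batch_id", "b1")),
            replicate_id=str(_opt(row, "replicate_id", "r1")),
        )
        for _, row in frame.iterrows()
    ]


def read_stocks_table(path: PathLike) -> list[StockRecord]:
    frame = _read(path, ["strain_id"])
    if "copies_per_ml" not in frame.columns and "ng_per_ul" not in frame.columns:
        raise SchemaError(f"{path}: needs a copies_per_ml or ng_per_ul column")
    stocks = []
    for _, row in frame.iterrows():
        copies = _opt(row, "copies_per_ml", None)
        ng = _opt(row, "ng_per_ul", None)
        stocks.append(
            StockRecord(
                strain_id=str(row["strain_id"]),
                copies_per_ml=None if copies is None else float(copies),
                ng_per_ul=None if ng is None else float(ng),
                available_ml=float(_opt(row, "available_ml", math.inf)),
            )
        )
    return stocks


def read_target_map(path: PathLike) -> dict[str, str]:
    """2-column (target_id, strain_id) tab-separated mapping file."""
    frame = _read(path, ["target_id", "strain_id"])
    return dict(zip(frame["target_id"].astype(str), frame["strain_id"].astype(str)))


def write_concentrations(concs: Sequence[GenomeConcentration], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "strain_id": c.strain_id,
                "replicate_id": c.replicate_id,
                "copies_per_ml": repr(c.copies_per_ml),
                "method": c.method,
                "basis": c.basis,
                "od600": "" if c.od600 is None else repr(c.od600),
            }
            for c in concs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_recipe(recipe: Recipe, path: PathLike) -> None:
    unit = "copies_per_ml" if recipe.kind == "cell" else "ng_per_ul"
    rows = [
        {
            "component": sid,
            "volume_ul": f"{vol:.4f}",
            f"achieved_{unit}": repr(recipe.achieved_per_strain.get(sid, float("nan"))),
        }
        for sid, vol in recipe.per_strain_volume_ul.items()
    ]
    rows.append(
        {
            "component": "diluent",
            "volume_ul": f"{recipe.diluent_volume_ul:.4f}",
            f"achieved_{unit}": "",
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_abundance(table: pd.DataFrame, path: PathLike) -> None:
    columns = list(ABUNDANCE_COLUMNS)
    if "condition" in table.columns:
        columns.append("condition")
    table[columns].to_csv(path, sep="\t", index=False)


def read_abundance(path: PathLike) -> pd.DataFrame:
    frame = _read(path, ABUNDANCE_COLUMNS)
    frame["fraction"] = frame["fraction"].astype(float)
    return frame


def load_design(path: PathLike) -> MockDesign:
    """Load a MockDesign from a flat key-value YAML document."""
    with open(path, encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict) or "kind" not in payload or "strain_ids" not in payload:
        raise SchemaError(f"{path}: design file needs at least 'kind' and 'strain_ids'")
    known = {
        "kind",
        "strain_ids",
        "target_total_copies_per_ml",
        "concentration_mode",
        "aliquot_volume_ul",
        "aliquot_count",
        "target_total_ng_per_ul",
        "dna_aliquot_volume_ul",
        "dead_volume_ul",
    }
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"{path}: unknown design keys: {', '.join(sorted(unknown))}")
    return MockDesign(**payload)
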