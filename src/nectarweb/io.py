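"""CSV / JSON / YAML round-trips for the tabular interfaces.

Plain-text schemas: flower trait tables and parasitoid trait tables (CSV,
lengths in mm, day-of-year windows), plant x parasitoid verdict matrices,
mixed-kind trait matrices (kind declarations in a ``_kind_`` row), long
parasitism and multi-threshold tables, ranked-model tables, averaged-model
and neutral-model reports (JSON) and scenario configuration (YAML).
All writers use a fixed float format so outputs are byte-stable under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .diversity import TraitMatrix
from .simulate import ScenarioConfig
from .traits import FlowerMorphology, InsectMorphology

__all__ = [
    "FLOAT_FORMAT",
    "write_flora_csv",
    "read_flora_csv",
    "write_parasitoid_csv",
    "read_parasitoid_csv",
    "write_trait_matrix_csv",
    "read_trait_matrix_csv",
    "write_table",
    "write_json",
    "load_scenario_yaml",
    "dump_scenario_yaml",
    "config_hash",
]

FLOAT_FORMAT = "%.10g"

_FLORA_COLS = [
    "species", "w_mm", "h_mm", "p_mm", "d_mm", "nectar_type",
    "flower_onset_doy", "flower_duration_d", "nectar_quantity",
]


def write_flora_csv(flora: Mapping[str, FlowerMorphology], path: str | Path) -> None:
    rows = []
    for name, f in flora.items():
        rows.append(
            {
                "species": name,
                "w_mm": f.opening_width,
                "h_mm": f.corolla_height,
                "p_mm": f.nectar_depth,
                "d_mm": f.tube_diameter,
                "nectar_type": f.nectar_type.value,
                "flower_onset_doy": f.flower_start,
                "flower_duration_d": f.flower_end - f.flower_start,
                "nectar_quantity": f.nectar_quantity,
            }
        )
    pd.DataFrame(rows, columns=_FLORA_COLS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_flora_csv(path: str | Path) -> dict[str, FlowerMorphology]:
    df = pd.read_csv(path)
    out: dict[str, FlowerMorphology] = {}
    for _, r in df.iterrows():
        onset = int(r["flower_onset_doy"])
        out[r["species"]] = FlowerMorphology(
            species=r["species"],
            opening_width=None if pd.isna(r["w_mm"]) else float(r["w_mm"]),
            corolla_height=None if pd.isna(r["h_mm"]) else float(r["h_mm"]),
            nectar_depth=None if pd.isna(r["p_mm"]) else float(r["p_mm"]),
            tube_diameter=None if pd.isna(r["d_mm"]) else float(r["d_mm"]),
            nectar_type=r["nectar_type"],
            flower_start=onset,
            flower_end=onset + int(r["flower_duration_d"]),
            nectar_quantity=None if pd.isna(r.get("nectar_quantity")) else int(r["nectar_quantity"]),
        )
    return out


def write_parasitoid_csv(insects: list[InsectMorphology], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "taxon": i.taxon,
                "head_width_mm": i.head_width,
                "proboscis_length_mm": i.proboscis_length,
                "proboscis_width_mm": i.proboscis_width,
                "activity_start_doy": i.activity_start,
                "activity_end_doy": i.activity_end,
            }
            for i in insects
        ]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_parasitoid_csv(path: str | Path) -> list[InsectMorphology]:
    df = pd.read_csv(path)
    return [
        InsectMorphology(
            taxon=r["taxon"],
            head_width=float(r["head_width_mm"]),
            proboscis_length=float(r["proboscis_length_mm"]),
            proboscis_width=float(r["proboscis_width_mm"]),
            activity_start=int(r["activity_start_doy"]),
            activity_end=int(r["activity_end_doy"]),
        )
        for _, r in df.iterrows()
    ]


def write_trait_matrix_csv(tm: TraitMatrix, path: str | Path) -> None:
    """Trait matrix CSV whose first data row (index ``_kind_``) declares the
    kind of each trait."""
    kinds = pd.DataFrame(
        [[tm.kinds[c] for c in tm.values.columns]],
        index=["_kind_"],
        columns=tm.values.columns,
    )
    pd.concat([kinds, tm.values]).to_csv(path, index_label="species")


def read_trait_matrix_csv(path: str | Path) -> TraitMatrix:
    df = pd.read_csv(path, index_col="species")
    kinds = {c: df.loc["_kind_", c] for c in df.columns}
    values = df.drop(index="_kind_")
    values.index.name = None
    for c, k in kinds.items():
        if k == "quantitative":
            values[c] = pd.to_numeric(values[c])
    return TraitMatrix(values, kinds)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index", double_precision=10))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def load_scenario_yaml(path: str | Path) -> ScenarioConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "distance_decay" in raw:
        raw["distance_decay"] = {float(k): float(v) for k, v in raw["distance_decay"].items()}
    for key in ("distances", "herbivores", "beta0", "season", "trials_range",
                "sown_cover_range", "spontaneous_cover_range", "control_cover_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return ScenarioConfig(**raw)


def dump_scenario_yaml(config: ScenarioConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["distance_decay"] = {float(k): float(v) for k, v in d["distance_decay"].items()}
    Path(path).write_text(yaml.safe_dump(_jsonable(d), sort_keys=True))


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    d = _jsonable(dataclasses.asdict(config)) if dataclasses.is_dataclass(config) else _jsonable(config)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
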