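"""File formats and run configuration.

Images are 16-bit grayscale TIFFs, one per field, named
``{plate}_{well}_{field:02d}.tif``.  Plate layouts, effect tables and all
stage outputs are plain CSV with documented headers.  The run
configuration round-trips losslessly through a single YAML file.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import EffectModel, SimulationConfig, WellImageSet
from .screen import LAYOUT_COLUMNS, validate_layout
from .wavelets import DetectionParams

logger = logging.getLogger("stromascreen")

_FIELD_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[^_]+)_(?P<field>\d+)\.tif$")


def field_filename(plate_id: str, well_id: str, field_index: int) -> str:
    return f"{plate_id}_{well_id}_{field_index:02d}.tif"


def write_well_images(
    image_set: WellImageSet, directory, plate_id: str = "P1"
) -> list[Path]:
    """Write each field of a well as a 16-bit TIFF; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, image in enumerate(image_set.fields):
        path = directory / field_filename(plate_id, image_set.well_id, idx)
        tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
        paths.append(path)
    return paths


def read_well_images(directory, plate_id: str, well_id: str) -> WellImageSet:
    """Load the fields of one well (sorted by field index)."""
    directory = Path(directory)
    paths = sorted(directory.glob(f"{plate_id}_{well_id}_*.tif"))
    if not paths:
        raise FileNotFoundError(
            f"no images for plate {plate_id!r} well {well_id!r} in {directory}"
        )
    fields = [tifffile.imread(p) for p in paths]
    return WellImageSet(well_id=well_id, fields=fields)


def discover_wells(directory) -> pd.DataFrame:
    """Scan an image directory; one row per (plate, well) with field count."""
    directory = Path(directory)
    records: dict[tuple[str, str], int] = {}
    for path in sorted(directory.glob("*.tif")):
        m = _FIELD_RE.match(path.name)
        if m is None:
            logger.warning("ignoring unrecognised image name %s", path.name)
            continue
        key = (m["plate"], m["well"])
        records[key] = records.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"plate_id": p, "well_id": w, "n_fields": n}
            for (p, w), n in sorted(records.items())
        ],
        columns=["plate_id", "well_id", "n_fields"],
    )


def read_layout(path) -> pd.DataFrame:
    layout = pd.read_csv(path, dtype={c: str for c in LAYOUT_COLUMNS if c != "replicate_index"})
    return validate_layout(layout)


def write_layout(layout: pd.DataFrame, path) -> None:
    validate_layout(layout).to_csv(path, index=False)


def read_effects(path, toxic_multiplier: float = 0.0) -> EffectModel:
    """Effect table CSV (sample_id, target_gene, multiplier) -> EffectModel."""
    df = pd.read_csv(path)
    required = {"sample_id", "target_gene", "multiplier"}
    if not required.issubset(df.columns):
        raise ValueError(f"effects file must have columns {sorted(required)}")
    multipliers = {
        (str(r.sample_id), str(r.target_gene)): float(r.multiplier)
        for r in df.itertuples(index=False)
    }
    return EffectModel(multipliers=multipliers, toxic_multiplier=toxic_multiplier)


def write_effects(effects: EffectModel, path) -> None:
    rows = [
        {"sample_id": s, "target_gene": t, "multiplier": m}
        for (s, t), m in sorted(effects.multipliers.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "target_gene", "multiplier"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# run configuration

_TUPLE_FIELDS_SIM = {
    "field_size_px",
    "all_radius_px",
    "msc_radius_px",
    "all_intensity",
    "msc_intensity",
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to one YAML file."""

    seed: int = 0
    images_dir: str | None = None
    layout_csv: str | None = None
    effects_csv: str | None = None
    output_dir: str = "stromascreen_out"
    plate_prefix: str = "P"
    detection: DetectionParams = field(default_factory=DetectionParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_estimators: int = 300
    training_wells: int = 4
    training_counts: tuple[int, int, int] = (150, 150, 60)
    match_tolerance_px: float = 2.5
    alpha: float = 0.05
    consensus_min_samples: int = 2
    add_bh: bool = False
    log_level: str = "INFO"


def config_to_yaml(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    # YAML has no tuple type; lists are converted back on load
    def listify(obj):
        if isinstance(obj, tuple):
            return [listify(x) for x in obj]
        if isinstance(obj, dict):
            return {k: listify(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as handle:
        yaml.safe_dump(listify(data), handle, sort_keys=False)


def config_from_yaml(path) -> RunConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    det = data.pop("detection", {})
    det["detection_scales"] = tuple(det.get("detection_scales", (2, 3)))
    sim = data.pop("simulation", {})
    for key in _TUPLE_FIELDS_SIM & set(sim):
        sim[key] = tuple(sim[key])
    if "training_counts" in data:
        data["training_counts"] = tuple(data["training_counts"])
    return RunConfig(
        detection=DetectionParams(**det),
        simulation=SimulationConfig(**sim),
        **data,
    )


def setup_logging(level: str = "INFO", logfile=None) -> None:
    """Structured logs to stderr and optionally to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
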