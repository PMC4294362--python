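"""Whole-run orchestration from configuration to hit table and heatmap.

``run_all`` executes the full pipeline of a :class:`~stromascreen.io.RunConfig`:
obtain images (simulate them if no image directory is given), train the
object classifier on dedicated simulated wells, classify every screen
well, normalize to scrambled controls, test with the Mann-Whitney U test
and export the screen matrix, hit table and heatmap.  Every stage writes
a schema-stable CSV into the output directory, and the whole run is
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as sio
from .classify import save_model, train
from .pipeline import build_training_set, process_screen
from .screen import analyze_screen, export_heatmap, make_screen_layout
from .simulate import EffectModel, render_screen

logger = logging.getLogger("stromascreen")

DEMO_SAMPLES = ("VHR-A", "VHR-B")
DEMO_TARGETS = tuple(f"GENE{i:02d}" for i in range(1, 13))
#: Planted knockdown effects of the demo screen: two strong shared hits,
#: one sample-specific moderate hit, everything else neutral.
DEMO_EFFECTS = {
    ("VHR-A", "GENE03"): 0.4,
    ("VHR-B", "GENE03"): 0.4,
    ("VHR-A", "GENE08"): 0.5,
    ("VHR-B", "GENE08"): 0.55,
    ("VHR-A", "GENE11"): 0.6,
}


def demo_config(output_dir, seed: int = 7) -> sio.RunConfig:
    """Small but complete screen: 2 samples x 12 targets plus controls.

    Uses 2x2 grids of 256-px fields and scaled-down per-well counts so
    the whole simulate-to-heatmap run stays in the minutes range on one
    CPU while exercising every pipeline stage.
    """
    from .simulate import SimulationConfig

    return sio.RunConfig(
        seed=seed,
        output_dir=str(output_dir),
        simulation=SimulationConfig(
            n_all_viable=150,
            n_all_dead=30,
            n_msc=15,
            fields_per_well=4,
            field_size_px=(256, 256),
            well_radius_px=300.0,
        ),
        training_wells=3,
        training_counts=(120, 120, 60),
    )


def demo_effect_model() -> EffectModel:
    multipliers = {
        (s, t): DEMO_EFFECTS.get((s, t), 1.0)
        for s in DEMO_SAMPLES
        for t in DEMO_TARGETS
    }
    return EffectModel(multipliers=multipliers)


def run_all(config: sio.RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns the paths of everything written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- layout and effects -------------------------------------------------
    if config.layout_csv:
        layout = sio.read_layout(config.layout_csv)
        logger.info("loaded layout with %d wells", len(layout))
    else:
        layout = make_screen_layout(DEMO_SAMPLES, DEMO_TARGETS)
        logger.info("using built-in demo layout (%d wells)", len(layout))
    paths["layout"] = out / "layout.csv"
    sio.write_layout(layout, paths["layout"])

    if config.effects_csv:
        effects = sio.read_effects(config.effects_csv)
    elif not config.layout_csv:
        effects = demo_effect_model()
    else:
        pairs = layout[layout["role"] == "TARGET"][["sample_id", "target_gene"]]
        effects = EffectModel(
            multipliers={(r.sample_id, r.target_gene): 1.0 for r in pairs.itertuples()}
        )

    # --- images -------------------------------------------------------------
    if config.images_dir:
        plate_by_well = dict(zip(layout["well_id"], layout["plate_id"]))
        images = {
            well: sio.read_well_images(config.images_dir, plate, well)
            for well, plate in plate_by_well.items()
        }
        truth = None
        logger.info("loaded images for %d wells", len(images))
    else:
        logger.info("simulating %d wells", len(layout))
        images, truth, counts = render_screen(
            layout, config.simulation, effects, seed=config.seed
        )
        img_dir = out / "images"
        plate_by_well = dict(zip(layout["well_id"], layout["plate_id"]))
        for well, image_set in images.items():
            sio.write_well_images(image_set, img_dir, plate_by_well[well])
        paths["images_dir"] = img_dir
        paths["ground_truth"] = out / "ground_truth.csv"
        truth.to_csv(paths["ground_truth"], index=False)
        paths["true_counts"] = out / "true_counts.csv"
        counts.to_csv(paths["true_counts"], index=False)

    # --- classifier ---------------------------------------------------------
    training = build_training_set(
        config=config.simulation,
        params=config.detection,
        seed=config.seed,
        n_wells=config.training_wells,
        counts=config.training_counts,
        base_tolerance=config.match_tolerance_px,
    )
    model = train(training, n_estimators=config.n_estimators, seed=config.seed)
    logger.info("classifier CV accuracy: %.3f", model.cv_accuracy)
    paths["model"] = out / "model.joblib"
    save_model(model, paths["model"])

    # --- classification and counting ---------------------------------------
    well_results, objects = process_screen(images, layout, config.detection, model)
    paths["well_results"] = out / "well_results.csv"
    well_results.to_csv(paths["well_results"], index=False)
    paths["object_labels"] = out / "object_labels.csv"
    objects.to_csv(paths["object_labels"], index=False)

    # --- screen statistics ---------------------------------------------------
    result = analyze_screen(
        well_results,
        layout,
        alpha=config.alpha,
        min_samples=config.consensus_min_samples,
        add_bh=config.add_bh,
    )
    paths["screen_table"] = out / "screen_table.csv"
    result.table.to_csv(paths["screen_table"], index=False)
    paths["hit_table"] = out / "hit_table.csv"
    result.consensus.to_csv(paths["hit_table"], index=False)
    paths["matrix_csv"] = out / "screen_matrix.csv"
    paths["heatmap_png"] = out / "screen_heatmap.png"
    export_heatmap(result.matrix, paths["heatmap_png"], paths["matrix_csv"])
    summary = pd.Series(result.summary)
    paths["summary"] = out / "summary.csv"
    summary.to_csv(paths["summary"], header=False)
    logger.info(
        "screen: %d tests, %d hits, %d consensus hits",
        result.summary["n_tests"],
        result.summary["n_hits"],
        result.summary["n_consensus_hits"],
    )
    return paths
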