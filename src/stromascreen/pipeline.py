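"""End-to-end orchestration: detect, featurize, classify, count, analyze.

Glues the stage modules together for whole wells and whole screens, and
builds classifier training sets by matching detected candidates to
simulator ground truth.  The command-line interface is a thin wrapper
around the functions here.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify as _classify
from .features import META_COLUMNS, extract_batch
from .simulate import SimulationConfig, WellImageSet, render_well
from .screen import tabulate_wells, validate_layout
from .wavelets import DetectionParams, SpotCandidate, detect_spots, segment_large_objects

logger = logging.getLogger("stromascreen")

ARTIFACT = "ARTIFACT"


def field_candidates(
    image: np.ndarray,
    params: DetectionParams,
    well_id: str | None = None,
    field_index: int = 0,
) -> list[SpotCandidate]:
    """Spot and large-object candidates of one field, masks disjoint."""
    spots = detect_spots(image, params, well_id=well_id, field_index=field_index)
    large = segment_large_objects(
        image, params, spots=spots, well_id=well_id, field_index=field_index
    )
    out = spots + large
    for k, cand in enumerate(out):
        cand.object_id = f"{well_id or 'img'}:{field_index}:{k:04d}"
    return out


def well_candidates(
    image_set: WellImageSet, params: DetectionParams
) -> list[SpotCandidate]:
    out: list[SpotCandidate] = []
    for idx, image in enumerate(image_set.fields):
        out.extend(
            field_candidates(image, params, well_id=image_set.well_id, field_index=idx)
        )
    return out


def well_feature_table(
    image_set: WellImageSet, params: DetectionParams
) -> pd.DataFrame:
    """Detect candidates in every field of a well and featurize them."""
    return extract_batch(image_set, well_candidates(image_set, params))


def label_with_truth(
    feature_table: pd.DataFrame,
    truth: pd.DataFrame,
    base_tolerance: float = 2.5,
    radius_factor: float = 1.0,
) -> pd.Series:
    """Assign each candidate the class of its nearest ground-truth object.

    Each candidate takes the class of the nearest true object whose
    acceptance radius (``max(base_tolerance, radius_factor * radius)``)
    it falls inside; several detections may share one large stromal
    nucleus (its internal speckle fires the spot detector as well as the
    large-object path).  Candidates near no true object are labelled
    ARTIFACT — the debris/false-detection class the classifier is meant
    to reject.
    """
    from scipy.spatial import cKDTree

    labels = pd.Series(ARTIFACT, index=feature_table.index, dtype=object, name="label")
    truth = truth[truth["imaged"]]
    for field_idx, cand_idx in feature_table.groupby("field_index").groups.items():
        t = truth[truth["field_index"] == field_idx]
        if t.empty:
            continue
        cand = feature_table.loc[cand_idx]
        pred_xy = cand[["centroid_row", "centroid_col"]].to_numpy(float)
        true_xy = t[["row", "col"]].to_numpy(float)
        radii = t["radius_px"].to_numpy(float)
        tol = np.maximum(base_tolerance, radius_factor * radii)
        tree = cKDTree(true_xy)
        # query enough neighbours to get past small close-by objects
        k = min(len(t), 4)
        dists, idx = tree.query(pred_xy, k=k)
        dists = np.atleast_2d(dists.T).T
        idx = np.atleast_2d(idx.T).T
        accept = dists <= tol[idx]
        for row, cand_pos in enumerate(np.asarray(cand_idx)):
            hits = np.flatnonzero(accept[row])
            if hits.size:
                j = idx[row, hits[0]]
                labels.loc[cand_pos] = t.iloc[j]["true_class"]
    return labels


_TRAINING_COUNTS = (150, 150, 60)


def build_training_set(
    config: SimulationConfig | None = None,
    params: DetectionParams | None = None,
    seed: int = 0,
    n_wells: int = 4,
    counts: tuple[int, int, int] = _TRAINING_COUNTS,
    per_class_cap: int = 400,
    base_tolerance: float = 2.5,
) -> _classify.TrainingSet:
    """Training set from dedicated simulated wells with known ground truth.

    Renders ``n_wells`` wells at a class-balanced density (the optical
    parameters come from ``config``), detects and featurizes candidates,
    labels them by ground-truth matching, caps each class at
    ``per_class_cap`` examples and drops classes with too few examples
    to train on.
    """
    if config is None:
        config = SimulationConfig(
            field_size_px=(256, 256), well_radius_px=450.0, fields_per_well=9
        )
    if params is None:
        params = DetectionParams()
    tables = []
    for w in range(n_wells):
        image_set, truth = render_well(
            config, well_id=f"TRAIN{w:02d}", seed=seed, counts=counts
        )
        feats = well_feature_table(image_set, params)
        feats["label"] = label_with_truth(feats, truth, base_tolerance=base_tolerance)
        tables.append(feats)
    combined = pd.concat(tables, ignore_index=True)
    capped = combined.groupby("label", group_keys=False).head(per_class_cap)
    counts_by_class = capped["label"].value_counts()
    keep = counts_by_class[counts_by_class >= _classify.MIN_EXAMPLES_PER_CLASS].index
    capped = capped[capped["label"].isin(keep)].reset_index(drop=True)
    logger.info("training set classes: %s", dict(capped["label"].value_counts()))
    return _classify.TrainingSet(
        features=capped.drop(columns=["label"]),
        labels=capped["label"],
    )


def classify_well(
    image_set: WellImageSet,
    params: DetectionParams,
    model: _classify.ClassifierModel,
) -> pd.DataFrame:
    """Object table of one well with predicted labels and probabilities."""
    feats = well_feature_table(image_set, params)
    labels, proba = _classify.predict(model, feats)
    out = feats.loc[:, list(META_COLUMNS)].copy()
    out["label"] = labels
    for cls in proba.columns:
        out[f"p_{cls}"] = proba[cls].to_numpy()
    return out


def process_screen(
    images: Mapping[str, WellImageSet],
    layout: pd.DataFrame,
    params: DetectionParams,
    model: _classify.ClassifierModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every well of a screen and tabulate per-well counts.

    Returns (well results, concatenated object-level label table).
    """
    validate_layout(layout)
    labels_by_well: dict[str, list[str]] = {}
    fields_analyzed: dict[str, int] = {}
    object_tables = []
    for well_id in sorted(images):
        image_set = images[well_id]
        table = classify_well(image_set, params, model)
        object_tables.append(table)
        labels_by_well[well_id] = list(table["label"])
        fields_analyzed[well_id] = image_set.n_fields
        logger.debug("well %s: %d objects", well_id, len(table))
    well_results = tabulate_wells(labels_by_well, layout, fields_analyzed)
    objects = (
        pd.concat(object_tables, ignore_index=True) if object_tables else pd.DataFrame()
    )
    return well_results, objects
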