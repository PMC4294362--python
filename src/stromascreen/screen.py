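"""Screen-level statistics: normalization, Mann-Whitney hit calling, export.

Per-well viable-ALL counts are aggregated over replicates, normalized to
the mean of the scrambled (non-targeting siRNA) negative controls of the
same patient sample, and each (sample, target) is tested against those
controls with a two-sided Mann-Whitney U test.  A knockdown is called a
hit when p < alpha and the normalized survival is below 1 (a decrease);
significant increases are flagged separately.  A cross-sample consensus
marks targets significant in at least k of the screened samples.

The U test is computed by exhaustive enumeration of all C(n1+n2, n1)
group assignments whenever the smaller group has at most 8 observations,
the data are tie-free and the enumeration is small enough to be exact in
negligible time; otherwise the normal approximation with tie and
continuity corrections is used.  Replicate numbers in a plate screen
(e.g. 3 target wells against 6 controls) always take the exact path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")  # headless rendering; imported before pyplot everywhere
import matplotlib.pyplot as plt
from matplotlib.colors import TwoSlopeNorm
from scipy import stats

ROLE_TARGET = "TARGET"
ROLE_NEG_CTRL = "NEG_CTRL"
ROLE_POS_CTRL = "POS_CTRL"
ROLES = (ROLE_TARGET, ROLE_NEG_CTRL, ROLE_POS_CTRL)

LAYOUT_COLUMNS = (
    "plate_id",
    "well_id",
    "sample_id",
    "target_gene",
    "role",
    "replicate_index",
)

WELL_RESULT_COLUMNS = (
    "well_id",
    "n_viable_all",
    "n_dead_all",
    "n_msc",
    "n_artifact",
    "n_objects",
    "fields_analyzed",
)


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check a plate layout table and return a validated copy.

    Requires the canonical columns, known roles, unique well ids and at
    least two negative-control wells per sample (the normalization
    denominator and the U-test reference group).
    """
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout is missing columns: {missing}")
    layout = layout.loc[:, list(LAYOUT_COLUMNS)].copy()
    bad_roles = set(layout["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in layout: {sorted(bad_roles)}")
    if layout["well_id"].duplicated().any():
        dup = layout.loc[layout["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"duplicate well ids in layout: {dup}")
    n_neg = layout[layout["role"] == ROLE_NEG_CTRL].groupby("sample_id").size()
    for sample in layout["sample_id"].unique():
        if n_neg.get(sample, 0) < 2:
            raise ValueError(
                f"sample {sample!r} has fewer than 2 NEG_CTRL wells; "
                "normalization and testing need at least 2"
            )
    return layout


def make_screen_layout(
    samples: Sequence[str],
    targets: Sequence[str],
    n_replicates: int = 3,
    n_neg_ctrl: int = 6,
    n_pos_ctrl: int = 3,
    plate_prefix: str = "P",
    neg_ctrl_gene: str = "SCRAMBLED",
    pos_ctrl_gene: str = "TOXIC",
) -> pd.DataFrame:
    """Build a one-plate-per-sample screen layout.

    Wells are named in 384-well style (rows A-P, columns 1-24) and filled
    row-major: target replicates first, then scrambled negative controls,
    then toxic positive controls.
    """
    rows = []
    for s_idx, sample in enumerate(samples):
        plate = f"{plate_prefix}{s_idx + 1}"
        conditions: list[tuple[str, str, int]] = []
        for gene in targets:
            conditions += [(gene, ROLE_TARGET, r) for r in range(1, n_replicates + 1)]
        conditions += [(neg_ctrl_gene, ROLE_NEG_CTRL, r) for r in range(1, n_neg_ctrl + 1)]
        conditions += [(pos_ctrl_gene, ROLE_POS_CTRL, r) for r in range(1, n_pos_ctrl + 1)]
        if len(conditions) > 384:
            raise ValueError("layout does not fit on a 384-well plate")
        for k, (gene, role, rep) in enumerate(conditions):
            well = f"{plate}-{chr(ord('A') + k // 24)}{k % 24 + 1:02d}"
            rows.append(
                {
                    "plate_id": plate,
                    "well_id": well,
                    "sample_id": sample,
                    "target_gene": gene,
                    "role": role,
                    "replicate_index": rep,
                }
            )
    return pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS))


# ---------------------------------------------------------------------------
# per-well tabulation

def tabulate_wells(
    labels_by_well: dict[str, Sequence[str]],
    layout: pd.DataFrame,
    fields_analyzed: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Count classified objects per well.

    ``labels_by_well`` maps well_id to the predicted class label of every
    object in that well.  Every well must appear in the layout.
    """
    layout = validate_layout(layout)
    known = set(layout["well_id"])
    rows = []
    for well_id, labels in labels_by_well.items():
        if well_id not in known:
            raise KeyError(f"well {well_id!r} not present in layout")
        labels = list(labels)
        rows.append(
            {
                "well_id": well_id,
                "n_viable_all": sum(1 for x in labels if x == "VIABLE_ALL"),
                "n_dead_all": sum(1 for x in labels if x == "DEAD_ALL"),
                "n_msc": sum(1 for x in labels if x == "MSC"),
                "n_artifact": sum(1 for x in labels if x == "ARTIFACT"),
                "n_objects": len(labels),
                "fields_analyzed": (fields_analyzed or {}).get(well_id, 0),
            }
        )
    return pd.DataFrame(rows, columns=list(WELL_RESULT_COLUMNS))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumeration of all group assignments.

    Assumes tie-free pooled data.  The two-sided p-value is the fraction
    of assignments whose U statistic is at least as extreme (in either
    tail) as the observed one; the membership test counts a central U
    only once, so identical tails never double-count.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * n2
    lo = min(u_obs, n1n2 - u_obs)
    hit = 0
    total = 0
    base = n1 * (n1 + 1) / 2
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - base
        if u <= lo + 1e-9 or u >= n1n2 - lo - 1e-9:
            hit += 1
        total += 1
    return hit / total


def mwu_test(x, y, exact_limit: int = 20000) -> float:
    """Two-sided Mann-Whitney U test p-value for two samples.

    Exact enumeration is used when the smaller group has <= 8
    observations, the pooled data are tie-free and the number of
    assignments C(n1+n2, n1) does not exceed ``exact_limit``; otherwise
    the normal approximation with tie and continuity corrections.
    Returns p in (0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == len(pooled)
    n_small = min(len(x), len(y))
    if tie_free and n_small <= 8 and math.comb(len(pooled), n_small) <= exact_limit:
        p = _exact_mwu_p(x, y)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# normalization and hit calling

def normalize_to_controls(
    well_results: pd.DataFrame, layout: pd.DataFrame
) -> pd.DataFrame:
    """Normalized survival per (sample, target) with Mann-Whitney p-values.

    Survival M = mean viable-ALL count of the condition's replicate wells
    divided by the mean of the sample's scrambled-control wells.  A zero
    control mean is flagged and M reported as missing rather than
    infinite.  Deterministic and invariant to well-row order.
    """
    layout = validate_layout(layout)
    merged = layout.merge(well_results, on="well_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between layout wells and well results")
    rows = []
    for sample, sample_df in merged.groupby("sample_id", sort=True):
        ctrl = np.sort(
            sample_df.loc[sample_df["role"] == ROLE_NEG_CTRL, "n_viable_all"].to_numpy(float)
        )
        if len(ctrl) < 2:
            raise ValueError(f"sample {sample!r}: fewer than 2 measured NEG_CTRL wells")
        ctrl_mean = ctrl.mean()
        groups = sample_df.groupby(["target_gene", "role"], sort=True)
        for (gene, role), grp in groups:
            counts = np.sort(grp["n_viable_all"].to_numpy(float))
            survival = counts.mean() / ctrl_mean if ctrl_mean > 0 else np.nan
            if role == ROLE_NEG_CTRL:
                p = 1.0  # reference group against itself
            else:
                p = mwu_test(counts, ctrl)
            rows.append(
                {
                    "sample_id": sample,
                    "target_gene": gene,
                    "role": role,
                    "n_wells": len(counts),
                    "mean_viable": counts.mean(),
                    "control_mean": ctrl_mean,
                    "control_zero": ctrl_mean == 0,
                    "survival": survival,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Normalized screen with per-(sample, target) tests and hit calls."""

    table: pd.DataFrame
    matrix: pd.DataFrame
    pvalues: pd.DataFrame
    consensus: pd.DataFrame
    summary: dict = field(default_factory=dict)


def call_hits(
    table: pd.DataFrame, alpha: float = 0.05, min_samples: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag decrease-hits and build the cross-sample consensus roll-up.

    A (sample, target) is a hit when p < alpha and survival < 1; a
    significant survival > 1 is flagged as an increase instead.  The
    consensus marks targets that are hits in at least ``min_samples``
    samples.
    """
    table = table.copy()
    is_target = table["role"] == ROLE_TARGET
    sig = table["p_value"] < alpha
    table["hit"] = is_target & sig & (table["survival"] < 1.0)
    table["increase"] = is_target & sig & (table["survival"] > 1.0)
    tgt = table[is_target]
    consensus = (
        tgt.groupby("target_gene")
        .agg(
            n_samples=("sample_id", "nunique"),
            n_samples_hit=("hit", "sum"),
            mean_survival=("survival", "mean"),
            min_p=("p_value", "min"),
        )
        .reset_index()
    )
    consensus["n_samples_hit"] = consensus["n_samples_hit"].astype(int)
    consensus["consensus_hit"] = consensus["n_samples_hit"] >= min_samples
    return table, consensus.sort_values("target_gene").reset_index(drop=True)


def analyze_screen(
    well_results: pd.DataFrame,
    layout: pd.DataFrame,
    alpha: float = 0.05,
    min_samples: int = 2,
    add_bh: bool = False,
) -> ScreenResult:
    """Full screen analysis: normalize, test, call hits, pivot matrices.

    ``add_bh`` appends Benjamini-Hochberg q-values per sample as an extra
    column; hit calling stays on the raw p < alpha rule.
    """
    table = normalize_to_controls(well_results, layout)
    if add_bh:
        qs = np.full(len(table), np.nan)
        for sample, idx in table.groupby("sample_id").groups.items():
            mask = table.loc[idx, "role"] == ROLE_TARGET
            sel = np.asarray(idx)[np.asarray(mask)]
            if len(sel):
                qs[sel] = _bh_qvalues(table.loc[sel, "p_value"].to_numpy())
        table["q_value"] = qs
    table, consensus = call_hits(table, alpha=alpha, min_samples=min_samples)
    matrix = table.pivot(index="sample_id", columns="target_gene", values="survival")
    pvalues = table.pivot(index="sample_id", columns="target_gene", values="p_value")
    tgt = table[table["role"] == ROLE_TARGET]
    summary = {
        "n_samples": int(table["sample_id"].nunique()),
        "n_targets": int(tgt["target_gene"].nunique()),
        "n_tests": int(len(tgt)),
        "n_hits": int(tgt["hit"].sum()),
        "n_increases": int(tgt["increase"].sum()),
        "n_consensus_hits": int(consensus["consensus_hit"].sum()),
        "alpha": float(alpha),
        "min_samples": int(min_samples),
    }
    return ScreenResult(table, matrix, pvalues, consensus, summary)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# export

def export_heatmap(
    matrix: pd.DataFrame,
    png_path=None,
    csv_path=None,
) -> None:
    """Write the survival matrix as a diverging heatmap and/or exact CSV.

    The colormap is centred at survival 1 (the scrambled-control level):
    blue marks decreased and red increased viable-ALL survival.  The CSV
    is the untransformed matrix and round-trips exactly.
    """
    if csv_path is not None:
        matrix.to_csv(csv_path)
    if png_path is None:
        return
    values = matrix.to_numpy(float)
    finite = values[np.isfinite(values)]
    vmax = float(finite.max()) if finite.size else 2.0
    vmin = float(finite.min()) if finite.size else 0.0
    # TwoSlopeNorm needs vmin < center < vmax even for flat matrices
    vmin = min(vmin, 1.0 - 1e-6)
    vmax = max(vmax, 1.0 + 1e-6)
    norm = TwoSlopeNorm(vmin=vmin, vcenter=1.0, vmax=vmax)
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad("0.7")
    fig_w = max(4.0, 0.35 * matrix.shape[1] + 2.0)
    fig_h = max(2.5, 0.45 * matrix.shape[0] + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(np.ma.masked_invalid(values), cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=8)
    ax.set_xlabel("target gene")
    ax.set_ylabel("sample")
    fig.colorbar(im, ax=ax, label="survival (fraction of scrambled controls)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
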