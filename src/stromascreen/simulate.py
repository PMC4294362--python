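"""Synthetic co-culture fluorescence microscope with ground truth.

Renders single-channel 16-bit well images of a leukemia-on-stroma
co-culture stained with a live-cell nucleic-acid dye: acute lymphoblastic
leukemia (ALL) blasts appear as small, bright, smooth nuclei; dead blasts
as shrunken, dimmer nuclei; mesenchymal stromal cells (MSC) as much
larger, dimmer nuclei with a speckled internal texture.  The three
populations share one fluorescence channel and are distinguishable only
by size, intensity and structure, which is exactly the discrimination
problem the downstream detection/classification pipeline has to solve.

Each well is imaged as a square grid of contiguous camera fields centred
on the well; with the default geometry the grid covers well over half of
the well area.  Every placed cell is recorded in a ground-truth table
(class, position, radius, peak intensity) whether or not it falls inside
an imaged field, so detector and classifier output can be scored against
a known answer.

The optics/noise model is the standard wide-field one: objects are
rendered as sub-pixel anti-aliased disks, convolved with a Gaussian PSF,
modulated by a planar illumination gradient, and read out through shot
noise (Poisson at a configurable photon gain) plus Gaussian camera read
noise.

All randomness flows from ``numpy.random.Generator`` instances derived
from a user seed and the well identifier, so a given (config, layout,
effects, seed) reproduces every pixel and every ground-truth row.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .screen import ROLE_NEG_CTRL, ROLE_POS_CTRL, validate_layout

VIABLE_ALL = "VIABLE_ALL"
DEAD_ALL = "DEAD_ALL"
MSC = "MSC"
#: Object classes that the simulator renders.
TRUE_CLASSES = (VIABLE_ALL, DEAD_ALL, MSC)

#: Columns of the ground-truth table returned by :func:`render_well`.
GROUND_TRUTH_COLUMNS = (
    "object_id",
    "well_id",
    "true_class",
    "well_row",
    "well_col",
    "field_index",
    "imaged",
    "row",
    "col",
    "radius_px",
    "peak_intensity",
)


def _rng_for(seed: int, well_id: str, stream: str) -> np.random.Generator:
    """Generator keyed on (seed, stream, well) — independent of well order."""
    key = zlib.crc32(f"{stream}:{well_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, photometry and noise of the synthetic co-culture well.

    Counts are per well.  Radii and intensities are (mean, sd) of
    per-object normal draws; intensities are in camera counts on the
    16-bit scale.  The defaults keep the assay's 10:1 ALL:MSC seeding
    ratio at a density where individual nuclei remain resolvable in a
    512 px field; :meth:`high_density` gives the full plate seeding
    density of the wet assay.
    """

    n_all_viable: int = 300
    n_all_dead: int = 60
    n_msc: int = 30
    fields_per_well: int = 9
    field_size_px: tuple[int, int] = (512, 512)
    well_radius_px: float = 900.0
    all_radius_px: tuple[float, float] = (3.0, 0.5)
    dead_radius_scale: float = 0.6
    msc_radius_px: tuple[float, float] = (15.0, 3.0)
    all_intensity: tuple[float, float] = (12000.0, 1500.0)
    dead_intensity_scale: float = 0.4
    msc_intensity: tuple[float, float] = (6000.0, 1000.0)
    msc_texture_amplitude: float = 0.5
    background_level: float = 500.0
    psf_sigma_px: float = 1.0
    read_noise_sd: float = 30.0
    poisson_gain: float = 0.05
    illumination_gradient_amplitude: float = 0.1
    #: ALL-ALL minimum centre distance as a multiple of the mean ALL
    #: radius; 3.0 (= 1.5 nuclear diameters) keeps neighbouring blasts
    #: resolvable under the PSF so ground truth stays matchable.
    min_separation_factor: float = 3.0
    #: MSC-MSC minimum centre distance as a multiple of the mean MSC
    #: radius (<= 0 disables the constraint, e.g. at confluent plate
    #: density where stromal nuclei do touch).
    msc_separation_factor: float = 2.2

    def __post_init__(self) -> None:
        if min(self.n_all_viable, self.n_all_dead, self.n_msc) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        g = math.isqrt(self.fields_per_well)
        if g * g != self.fields_per_well:
            raise ValueError("fields_per_well must be a perfect square (square field grid)")
        h, w = self.field_size_px
        if h < 8 or w < 8:
            raise ValueError("field_size_px too small")
        if max(h, w) > 2.0 * self.well_radius_px:
            raise ValueError("field larger than well")
        if not (0.0 < self.dead_radius_scale < 1.0):
            raise ValueError("dead_radius_scale must lie in (0, 1)")
        if self.msc_radius_px[0] <= self.all_radius_px[0]:
            raise ValueError("MSC nuclei must be larger than ALL nuclei on average")
        if self.poisson_gain <= 0:
            raise ValueError("poisson_gain must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be non-negative")

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.fields_per_well)

    @property
    def well_coverage_fraction(self) -> float:
        """Imaged field area as a fraction of the well disk area."""
        h, w = self.field_size_px
        return self.fields_per_well * h * w / (math.pi * self.well_radius_px**2)

    def field_origin(self, index: int) -> tuple[int, int]:
        """Well-centred (row, col) of pixel (0, 0) of field ``index``."""
        g = self.grid_side
        h, w = self.field_size_px
        i, j = divmod(index, g)
        return (-(g * h) // 2 + i * h, -(g * w) // 2 + j * w)

    @classmethod
    def high_density(cls, **overrides) -> "SimulationConfig":
        """Plate seeding density of the wet assay: 25 000 ALL on 2 500 MSC.

        At this density blasts touch; the separation constraint is
        relaxed, so merged detections are expected and the config is
        meant for ground-truth counting, not detector benchmarking.
        """
        params = dict(
            n_all_viable=25000,
            n_all_dead=2500,
            n_msc=2500,
            min_separation_factor=1.5,
            msc_separation_factor=0.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class WellImageSet:
    """The imaged fields of one well plus acquisition geometry."""

    well_id: str
    fields: list[np.ndarray]
    field_origins: np.ndarray | None = None
    config: SimulationConfig | None = None

    @property
    def n_fields(self) -> int:
        return len(self.fields)


@dataclass(frozen=True)
class EffectModel:
    """Per-(sample, target) viability multipliers for a simulated screen.

    The expected viable-ALL count of a well is baseline x multiplier;
    realized counts are Poisson around that expectation.  Scrambled
    negative controls always have multiplier 1; toxic positive controls
    (siRNA killing the stromal layer) have ``toxic_multiplier`` for the
    leukemia compartment and ``msc_toxic_multiplier`` for the stromal
    compartment.
    """

    multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    toxic_multiplier: float = 0.0
    msc_toxic_multiplier: float = 0.2

    def viability_multiplier(self, sample_id: str, target_gene: str, role: str) -> float:
        if role == ROLE_NEG_CTRL:
            return 1.0
        if role == ROLE_POS_CTRL:
            return float(self.toxic_multiplier)
        key = (sample_id, target_gene)
        if key not in self.multipliers:
            raise KeyError(
                f"no effect multiplier defined for sample {sample_id!r}, target {target_gene!r}"
            )
        m = float(self.multipliers[key])
        if m < 0:
            raise ValueError("viability multipliers must be non-negative")
        return m

    def msc_multiplier(self, role: str) -> float:
        return float(self.msc_toxic_multiplier) if role == ROLE_POS_CTRL else 1.0


# ---------------------------------------------------------------------------
# placement

def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in the well disk (rejection from the square)."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(16, 2 * (n - filled))
        cand = rng.uniform(-radius, radius, size=(m, 2))
        keep = cand[(cand**2).sum(axis=1) <= radius * radius]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _min_dist_points(
    rng: np.random.Generator, n: int, radius: float, dmin: float, max_tries: int = 200
) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise centre distance.

    A spatial hash with cell size dmin limits neighbour checks to the
    3x3 surrounding cells.  Raises if the requested density cannot be
    packed (configuration error, not a retryable condition).
    """
    if n == 0:
        return np.empty((0, 2))
    out = np.empty((n, 2))
    grid: dict[tuple[int, int], list[int]] = {}
    d2 = dmin * dmin
    placed = 0
    tries = 0
    budget = max_tries * n
    while placed < n:
        tries += 1
        if tries > budget:
            raise ValueError(
                f"could not place {n} cells with min distance {dmin:.2f} in well "
                f"radius {radius:.0f}; density too high"
            )
        p = _uniform_disk(rng, 1, radius)[0]
        ci, cj = int(p[0] // dmin), int(p[1] // dmin)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    q = out[idx]
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            out[placed] = p
            grid.setdefault((ci, cj), []).append(placed)
            placed += 1
    return out


# ---------------------------------------------------------------------------
# rendering

def _paint_disk(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    radius: float,
    amplitude: float,
    texture: np.ndarray | None = None,
    tex_origin: tuple[int, int] | None = None,
) -> None:
    """Add an anti-aliased disk; optionally modulated by a texture patch.

    ``texture`` is indexed in the same pixel frame as ``canvas`` shifted
    by ``tex_origin`` so that an object spanning two adjacent fields is
    textured consistently in both.
    """
    h, w = canvas.shape
    y0 = max(0, int(math.floor(cy - radius - 1)))
    y1 = min(h, int(math.ceil(cy + radius + 2)))
    x0 = max(0, int(math.floor(cx - radius - 1)))
    x1 = min(w, int(math.ceil(cx + radius + 2)))
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None]
    xx = np.arange(x0, x1)[None, :]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    val = amplitude * cov
    if texture is not None and tex_origin is not None:
        ty = np.clip(yy - tex_origin[0], 0, texture.shape[0] - 1)
        tx = np.clip(xx - tex_origin[1], 0, texture.shape[1] - 1)
        val = val * texture[ty, tx]
    canvas[y0:y1, x0:x1] += val


def _make_texture(rng: np.random.Generator, radius: float, amplitude: float) -> np.ndarray:
    """Unit-mean band-limited multiplicative speckle for one MSC nucleus."""
    half = int(math.ceil(radius)) + 3
    size = 2 * half + 1
    t = rng.standard_normal((size, size))
    t = ndi.gaussian_filter(t, 2.0)
    sd = t.std()
    if sd > 0:
        t = (t - t.mean()) / sd
    return np.clip(1.0 + amplitude * t, 0.05, None)


def render_well(
    config: SimulationConfig,
    well_id: str = "W000",
    seed: int = 0,
    counts: tuple[int, int, int] | None = None,
    render_images: bool = True,
) -> tuple[WellImageSet, pd.DataFrame]:
    """Render one well and return its images plus the ground-truth table.

    Parameters
    ----------
    counts
        Optional (viable ALL, dead ALL, MSC) override of the config
        counts, used by :func:`render_screen` after drawing Poisson
        realizations.
    render_images
        When False only the ground truth is produced (cell placement and
        photometry are still drawn so the table is identical either way).
    """
    rng = _rng_for(seed, well_id, "render")
    if counts is None:
        counts = (config.n_all_viable, config.n_all_dead, config.n_msc)
    n_v, n_d, n_m = (int(c) for c in counts)
    if min(n_v, n_d, n_m) < 0:
        raise ValueError("cell counts must be non-negative")

    radius = config.well_radius_px
    dmin = config.min_separation_factor * config.all_radius_px[0]
    all_pts = _min_dist_points(rng, n_v + n_d, radius, dmin)
    msc_dmin = config.msc_separation_factor * config.msc_radius_px[0]
    if msc_dmin > 0:
        msc_pts = _min_dist_points(rng, n_m, radius, msc_dmin)
    else:
        msc_pts = _uniform_disk(rng, n_m, radius)

    r_viable = np.clip(rng.normal(*config.all_radius_px, n_v), 0.5, None)
    r_dead = np.clip(rng.normal(*config.all_radius_px, n_d), 0.5, None) * config.dead_radius_scale
    r_msc = np.clip(rng.normal(*config.msc_radius_px, n_m), 2.0, None)
    i_viable = np.clip(rng.normal(*config.all_intensity, n_v), 1.0, None)
    i_dead = np.clip(rng.normal(*config.all_intensity, n_d), 1.0, None) * config.dead_intensity_scale
    i_msc = np.clip(rng.normal(*config.msc_intensity, n_m), 1.0, None)
    textures = [
        _make_texture(rng, r, config.msc_texture_amplitude) for r in r_msc
    ]

    pts = np.concatenate([all_pts, msc_pts]) if n_v + n_d + n_m else np.empty((0, 2))
    radii = np.concatenate([r_viable, r_dead, r_msc])
    intens = np.concatenate([i_viable, i_dead, i_msc])
    classes = [VIABLE_ALL] * n_v + [DEAD_ALL] * n_d + [MSC] * n_m

    g = config.grid_side
    h, w = config.field_size_px
    row0, col0 = config.field_origin(0)

    # field of the object's centre (-1 when outside the imaged grid)
    field_index = np.full(len(pts), -1, dtype=int)
    local = np.full((len(pts), 2), np.nan)
    if len(pts):
        fi = np.floor((pts[:, 0] - row0) / h).astype(int)
        fj = np.floor((pts[:, 1] - col0) / w).astype(int)
        inside = (fi >= 0) & (fi < g) & (fj >= 0) & (fj < g)
        field_index[inside] = fi[inside] * g + fj[inside]
        local[inside, 0] = pts[inside, 0] - row0 - fi[inside] * h
        local[inside, 1] = pts[inside, 1] - col0 - fj[inside] * w

    truth = pd.DataFrame(
        {
            "object_id": [f"{well_id}:{k:05d}" for k in range(len(pts))],
            "well_id": well_id,
            "true_class": classes,
            "well_row": pts[:, 0] if len(pts) else np.array([]),
            "well_col": pts[:, 1] if len(pts) else np.array([]),
            "field_index": field_index,
            "imaged": field_index >= 0,
            "row": local[:, 0] if len(pts) else np.array([]),
            "col": local[:, 1] if len(pts) else np.array([]),
            "radius_px": radii,
            "peak_intensity": intens,
        },
        columns=list(GROUND_TRUTH_COLUMNS),
    )

    origins = np.array([config.field_origin(k) for k in range(config.fields_per_well)])
    fields: list[np.ndarray] = []
    if render_images:
        msc_offset = n_v + n_d
        for k in range(config.fields_per_well):
            oy, ox = origins[k]
            canvas = np.zeros((h, w))
            for idx in range(len(pts)):
                cy = pts[idx, 0] - oy
                cx = pts[idx, 1] - ox
                r = radii[idx]
                if cy < -r - 2 or cy > h + r + 2 or cx < -r - 2 or cx > w + r + 2:
                    continue
                if idx >= msc_offset:
                    tex = textures[idx - msc_offset]
                    half = (tex.shape[0] - 1) // 2
                    anchor = (
                        int(round(pts[idx, 0])) - oy - half,
                        int(round(pts[idx, 1])) - ox - half,
                    )
                    _paint_disk(canvas, cy, cx, r, intens[idx], tex, anchor)
                else:
                    _paint_disk(canvas, cy, cx, r, intens[idx])
            blurred = ndi.gaussian_filter(canvas, config.psf_sigma_px)
            gr, gc = rng.uniform(-1.0, 1.0, 2)
            rows = (np.arange(h)[:, None] - h / 2) / h
            cols = (np.arange(w)[None, :] - w / 2) / w
            illum = 1.0 + config.illumination_gradient_amplitude * (gr * rows + gc * cols)
            expected = np.clip((blurred + config.background_level) * illum, 0.0, None)
            gain = config.poisson_gain
            img = rng.poisson(expected * gain) / gain
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
            fields.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))

    return WellImageSet(well_id, fields, origins, config), truth


# ---------------------------------------------------------------------------
# screen-level simulation

def draw_replicate_counts(
    rng: np.random.Generator, baseline: float, multiplier: float, n_replicates: int
) -> np.ndarray:
    """Poisson realized viable-ALL counts for replicate wells."""
    if baseline < 0 or multiplier < 0:
        raise ValueError("baseline and multiplier must be non-negative")
    return rng.poisson(baseline * multiplier, size=n_replicates)


def draw_screen_counts(
    layout: pd.DataFrame,
    config: SimulationConfig,
    effects: EffectModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the per-well true cell counts of a screen without rendering.

    Viable-ALL counts are Poisson(baseline x multiplier); cells killed by
    an effective knockdown reappear in the dead-ALL expectation; the MSC
    count is depleted in toxic-control wells.  Deterministic per well
    given the seed, independent of layout row order.
    """
    layout = validate_layout(layout)
    rows = []
    for rec in layout.itertuples(index=False):
        m = effects.viability_multiplier(rec.sample_id, rec.target_gene, rec.role)
        rng = _rng_for(seed, rec.well_id, "counts")
        n_v = int(rng.poisson(config.n_all_viable * m))
        dead_expect = config.n_all_dead + config.n_all_viable * max(0.0, 1.0 - min(m, 1.0))
        n_d = int(rng.poisson(dead_expect))
        n_m = int(rng.poisson(config.n_msc * effects.msc_multiplier(rec.role)))
        rows.append(
            {
                "plate_id": rec.plate_id,
                "well_id": rec.well_id,
                "sample_id": rec.sample_id,
                "target_gene": rec.target_gene,
                "role": rec.role,
                "replicate_index": rec.replicate_index,
                "true_viable": n_v,
                "true_dead": n_d,
                "true_msc": n_m,
            }
        )
    return pd.DataFrame(rows)


def render_screen(
    layout: pd.DataFrame,
    config: SimulationConfig,
    effects: EffectModel,
    seed: int = 0,
    render_images: bool = True,
) -> tuple[dict[str, WellImageSet], pd.DataFrame, pd.DataFrame]:
    """Render every well of a screen layout.

    Returns (well_id -> WellImageSet, concatenated ground truth, per-well
    true counts).  Raises ``KeyError`` if a layout target has no entry in
    the effect model.
    """
    counts = draw_screen_counts(layout, config, effects, seed)
    images: dict[str, WellImageSet] = {}
    truths = []
    for rec in counts.itertuples(index=False):
        image_set, truth = render_well(
            config,
            well_id=rec.well_id,
            seed=seed,
            counts=(rec.true_viable, rec.true_dead, rec.true_msc),
            render_images=render_images,
        )
        images[rec.well_id] = image_set
        truths.append(truth)
    truth_table = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=list(GROUND_TRUTH_COLUMNS))
    )
    return images, truth_table, counts
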