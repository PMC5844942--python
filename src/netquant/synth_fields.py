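"""Synthetic two-channel neutrophil/NET field generator with exact ground truth.

Emulates the three phenotypes that drive NET quantification:

* condensed multi-lobed neutrophil nuclei (2-4 overlapping ellipse lobes,
  ~600 px, bright),
* decondensed NETotic nuclei (single enlarged blob, dimmer in stimulated
  conditions),
* apoptotic-body nuclei (dark internal spots plus small peripheral bright
  fragments) which must NOT be counted as NETotic,

plus curved web-like extracellular DNA filaments in the DNA channel, Gaussian
background noise, and a renderer whose area and intensity statistics are
directly steerable so that every downstream algorithm can be tested against
known truth. Presets encode an unstimulated vs PMA-stimulated time course
(0-240 min) and :func:`generate_screen` emits a complete 56-compound,
five-dose modulator screen fixture.

Stimulated conditions apply ``intensity_drop`` to every nucleus in the well
(pan-nuclear chromatin changes dim the whole population, which is what a
population mean-intensity gap measures); decondensed nuclei are additionally
dimmed to at least ``decondensed_intensity_drop`` below the condensed mean,
because chromatin dilution is intrinsic to decondensation whether or not the
well was stimulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.filters import gaussian

from .plate_io import FieldImage, PlateLayout, write_field, write_layout

__all__ = [
    "ConditionParams",
    "GroundTruth",
    "CapacityError",
    "generate_field",
    "preset",
    "PRESET_NAMES",
    "generate_screen",
    "load_screen_config",
    "default_screen_config_path",
]


class CapacityError(RuntimeError):
    """Raised when requested objects cannot be placed without forced overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} requested cells; "
            "reduce n_cells or enlarge the field"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class ConditionParams:
    """Generator parameters for one experimental condition.

    Areas are pixels, intensities arbitrary units on the fixture's scale
    (background ~100, condensed nuclei ~1200). ``decondensed_fraction`` and
    ``apoptotic_fraction`` are per-cell class probabilities and must sum to
    at most 1. ``intensity_drop`` dims every nucleus in the condition.
    """

    n_cells: int = 100
    decondensed_fraction: float = 0.0
    apoptotic_fraction: float = 0.0
    condensed_area_mean: float = 600.0
    condensed_area_sd: float = 50.0
    decondensed_area_mean: float = 1500.0
    decondensed_area_sd: float = 150.0
    condensed_intensity_mean: float = 1200.0
    condensed_intensity_sd: float = 80.0
    intensity_drop: float = 0.0
    decondensed_intensity_drop: float = 500.0
    net_filament_count: int = 0
    net_filament_intensity_mean: float = 500.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("condensed_area_mean", "decondensed_area_mean",
                     "condensed_intensity_mean", "background_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.decondensed_fraction <= 1.0:
            raise ValueError("decondensed_fraction must be in [0, 1]")
        if not 0.0 <= self.apoptotic_fraction <= 1.0:
            raise ValueError("apoptotic_fraction must be in [0, 1]")
        if self.decondensed_fraction + self.apoptotic_fraction > 1.0:
            raise ValueError("decondensed_fraction + apoptotic_fraction must be <= 1")


@dataclass
class GroundTruth:
    """Exact per-object truth for one generated field.

    ``objects`` has one row per object (object_id, class, true_area,
    true_mean_intensity, true_integrated_dna_signal, centroid_row,
    centroid_col). ``nucleus_labels`` and ``filament_labels`` are label
    rasters sharing the field's shape; object ids are unique across both and
    no pixel carries two ids.
    """

    objects: pd.DataFrame = dc_field(repr=False)
    nucleus_labels: np.ndarray = dc_field(repr=False)
    filament_labels: np.ndarray = dc_field(repr=False)

    def count(self, cls: str) -> int:
        return int((self.objects["class"] == cls).sum())

    @property
    def total_filament_signal(self) -> float:
        fil = self.objects[self.objects["class"] == "filament"]
        return float(fil["true_integrated_dna_signal"].sum())


# ---------------------------------------------------------------------------
# nucleus rendering
# ---------------------------------------------------------------------------

def _ellipse_union_mask(patch_shape: tuple[int, int],
                        lobes: list[tuple[float, float, float, float, float]]) -> np.ndarray:
    """Boolean union of ellipses (cy, cx, semi_a, semi_b, theta) in a patch."""
    yy, xx = np.mgrid[0:patch_shape[0], 0:patch_shape[1]]
    mask = np.zeros(patch_shape, dtype=bool)
    for cy, cx, a, b, theta in lobes:
        dy = yy - cy
        dx = xx - cx
        c, s = np.cos(theta), np.sin(theta)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _sample_lobes(rng: np.random.Generator, target_area: float, n_lobes: int
                  ) -> list[tuple[float, float, float, float, float]]:
    """Sample lobe geometry (patch-centre relative) for a nominal total area."""
    r = np.sqrt(target_area / (np.pi * max(n_lobes, 1) * 0.72))
    lobes = []
    for _ in range(n_lobes):
        ratio = rng.uniform(1.1, 1.6) if n_lobes > 1 else rng.uniform(1.0, 1.25)
        b = r / np.sqrt(ratio)
        a = r * np.sqrt(ratio)
        theta = rng.uniform(0, np.pi)
        if n_lobes > 1:
            off_r = rng.uniform(0.25, 0.65) * r * 1.4
            off_t = rng.uniform(0, 2 * np.pi)
            dy, dx = off_r * np.sin(off_t), off_r * np.cos(off_t)
        else:
            dy = dx = 0.0
        lobes.append((dy, dx, a, b, theta))
    return lobes


def _render_nucleus_mask(rng: np.random.Generator, target_area: float,
                         n_lobes: int) -> np.ndarray:
    """Render a lobed nucleus mask calibrated to ``target_area`` pixels.

    Two-pass: render at nominal scale, then rescale linear dimensions by
    sqrt(target/measured) and re-render, which brings the pixel count within
    a few percent of target.
    """
    lobes = _sample_lobes(rng, target_area, n_lobes)
    half = int(np.ceil(2.4 * np.sqrt(target_area / np.pi))) + 3
    shape = (2 * half + 1, 2 * half + 1)

    def render(scale: float) -> np.ndarray:
        placed = [(half + dy * scale, half + dx * scale, a * scale, b * scale, th)
                  for dy, dx, a, b, th in lobes]
        return _ellipse_union_mask(shape, placed)

    mask = render(1.0)
    area0 = mask.sum()
    if area0 > 0:
        mask = render(float(np.sqrt(target_area / area0)))
    # keep a single connected component (lobes are drawn overlapping, but
    # guard against a stray disconnected lobe)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)
    return mask


def _plateau_profile(mask: np.ndarray) -> np.ndarray:
    """Near-flat intensity profile: plateau 1.0 with a shallow ~2.5 px edge ramp."""
    dt = ndimage.distance_transform_edt(mask)
    return np.where(mask, 0.90 + 0.10 * np.clip(dt / 2.5, 0.0, 1.0), 0.0)


def _crop_to_mask(mask: np.ndarray, pad: int = 1) -> tuple[np.ndarray, tuple[int, int]]:
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min() - pad, ys.max() + pad + 1
    x0, x1 = xs.min() - pad, xs.max() + pad + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    return mask[y0:y1, x0:x1], (y0, x0)


# apoptotic-body hole rendering (see _render_one): radius range, core depth
# (fraction of amplitude removed at the centre), centre-placement erosion and
# centre separation factor
_HOLE_RADIUS = (4.5, 5.5)
_HOLE_DEPTH = 0.95
_HOLE_CENTER_EROSION = 5
_HOLE_COUNT_LO, _HOLE_COUNT_HI = 3, 4
_HOLE_SEP = 1.0


@dataclass
class _RenderedNucleus:
    cls: str
    mask: np.ndarray          # cropped boolean patch
    intensity: np.ndarray     # cropped relative-intensity patch (0 off-mask)
    amplitude_abs: float      # sampled absolute mean level (truth)
    extras: np.ndarray | None = None  # bright fragments patch (apoptotic)


def _render_one(rng: np.random.Generator, cls: str, params: ConditionParams) -> _RenderedNucleus:
    bg = params.background_mean
    # the whole population carries the condition's intensity_drop; decondensed
    # nuclei are additionally dimmed to at least the fully-decondensed level
    # (chromatin dilution is intrinsic to decondensation, stimulated or not)
    drop = params.intensity_drop
    if cls == "decondensed":
        drop = max(drop, params.decondensed_intensity_drop)
    amp_abs = rng.normal(params.condensed_intensity_mean - drop,
                         params.condensed_intensity_sd)
    amp_abs = max(amp_abs, bg + 100.0)
    amp_rel = amp_abs - bg

    if cls == "decondensed":
        area = max(rng.normal(params.decondensed_area_mean, params.decondensed_area_sd), 400.0)
        mask = _render_nucleus_mask(rng, area, n_lobes=1)
    else:
        area = max(rng.normal(params.condensed_area_mean, params.condensed_area_sd), 150.0)
        mask = _render_nucleus_mask(rng, area, n_lobes=int(rng.integers(2, 5)))

    profile = _plateau_profile(mask)
    intensity = amp_rel * profile
    extras = None

    if cls == "apoptotic":
        # dark internal spots: 2-4 holes of radius 2.5-4 px rendered at a
        # quarter of the nuclear amplitude
        # conical dark spots: a deep core (25% of amplitude) tapering to the
        # plateau at the rim. The core is unambiguous against a mean - 2*SD
        # cut while the small average darkening keeps the region SD low —
        # a uniformly dark hole would inflate the SD and mask itself.
        interior = ndimage.binary_erosion(mask, iterations=_HOLE_CENTER_EROSION)
        iy, ix = np.nonzero(interior)
        if len(iy) > 0:
            n_holes = int(rng.integers(_HOLE_COUNT_LO, _HOLE_COUNT_HI + 1))
            yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
            centres: list[tuple[int, int, float]] = []
            for _ in range(60):
                if len(centres) >= n_holes:
                    break
                j = rng.integers(len(iy))
                hr = rng.uniform(*_HOLE_RADIUS)
                # keep spots separated so they read as distinct holes
                if any((iy[j] - cy) ** 2 + (ix[j] - cx) ** 2 < (_HOLE_SEP * (hr + chr_)) ** 2
                       for cy, cx, chr_ in centres):
                    continue
                centres.append((int(iy[j]), int(ix[j]), hr))
            for cy, cx, hr in centres:
                dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
                taper = np.clip(1.0 - dist / hr, 0.0, 1.0)
                intensity[mask] *= (1.0 - _HOLE_DEPTH * taper[mask])
        # peripheral bright fragments just outside the body
        ring = ndimage.binary_dilation(mask, iterations=5) & ~ndimage.binary_dilation(mask, iterations=2)
        ry, rx = np.nonzero(ring)
        extras = np.zeros_like(intensity)
        if len(ry) > 0:
            yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
            for _ in range(int(rng.integers(2, 5))):
                j = rng.integers(len(ry))
                fr = rng.uniform(1.5, 2.8)
                frag = ((yy - ry[j]) ** 2 + (xx - rx[j]) ** 2 <= fr ** 2) & ~mask
                extras[frag] = 1.1 * amp_rel

    # chromatin texture
    intensity[mask] += rng.normal(0.0, 0.025 * amp_rel, size=int(mask.sum()))
    intensity = np.clip(intensity, 0.0, None)
    return _RenderedNucleus(cls=cls, mask=mask, intensity=intensity,
                            amplitude_abs=float(amp_abs), extras=extras)


# ---------------------------------------------------------------------------
# filament rendering
# ---------------------------------------------------------------------------

def _smooth_path(rng: np.random.Generator, start: np.ndarray, angle: float,
                 length_px: float, shape: tuple[int, int], step: float = 1.5) -> np.ndarray:
    """Momentum random walk: a smooth curved strand, reflected at borders."""
    n_steps = max(int(length_px / step), 4)
    pts = np.empty((n_steps, 2))
    pos = start.astype(float).copy()
    for i in range(n_steps):
        angle += rng.normal(0.0, 0.13)
        nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
        for d in (0, 1):
            if nxt[d] < 3 or nxt[d] > shape[d] - 4:
                angle = np.pi - angle if d == 1 else -angle
                nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
        pos = np.clip(nxt, 3, np.array(shape) - 4)
        pts[i] = pos
    return pts


def _stamp_path(canvas: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Mark boolean canvas pixels within ``radius`` of any path point."""
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    offsets = np.argwhere(dy ** 2 + dx ** 2 <= radius ** 2) - r
    ipts = np.unique(np.round(pts).astype(int), axis=0)
    coords = (ipts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    np.clip(coords[:, 0], 0, canvas.shape[0] - 1, out=coords[:, 0])
    np.clip(coords[:, 1], 0, canvas.shape[1] - 1, out=coords[:, 1])
    canvas[coords[:, 0], coords[:, 1]] = True


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

_CLASSES = ("condensed", "decondensed", "apoptotic")


def generate_field(params: ConditionParams, shape: tuple[int, int] = (640, 640),
                   seed: int | None = None, plate_id: str = "synth",
                   well: str = "A01", field_index: int = 0
                   ) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field and its exact ground truth.

    Nuclei appear in both channels (a fixed-cell DNA stain images nuclei as
    well as NETs); filaments appear only in the DNA channel. Placement uses
    rejection sampling with a minimum centre distance; if the requested cell
    count cannot be placed a :class:`CapacityError` reports what fitted.
    Identical (params, shape, seed) produce bit-identical rasters.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    shape = tuple(int(s) for s in shape)

    # stratified class allocation: each field carries its class fractions
    # exactly (rounded), so the encoded condition is the field's truth rather
    # than a binomial draw around it — well-to-well spread then reflects the
    # measurement pipeline, which is what the fixture exists to test
    f, a = params.decondensed_fraction, params.apoptotic_fraction
    n_dec = int(round(f * params.n_cells))
    n_apo = min(int(round(a * params.n_cells)), params.n_cells - n_dec)
    n_con = params.n_cells - n_dec - n_apo
    classes = np.array([1] * n_dec + [2] * n_apo + [0] * n_con, dtype=int)
    # place large objects first: markedly better packing at high NETotic load
    order = np.argsort(classes != 1, kind="stable")

    nuc_rel = np.zeros(shape, dtype=np.float64)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    placed_yx: list[np.ndarray] = []
    placed_r: list[float] = []
    records: list[dict] = []
    next_id = 1

    for cls_idx in classes[order]:
        cls = _CLASSES[cls_idx]
        ren = _render_one(rng, cls, params)
        mask, (oy, ox) = _crop_to_mask(ren.mask, pad=0)
        ph, pw = mask.shape
        patch_int = ren.intensity[oy:oy + ph, ox:ox + pw]
        extras_patch = None
        if ren.extras is not None and ren.extras.any():
            extras_patch = ren.extras[oy:oy + ph, ox:ox + pw]
        # effective radius: farthest mask pixel from the patch centre
        ys, xs = np.nonzero(mask)
        r_eff = float(np.sqrt(((ys - ph / 2) ** 2 + (xs - pw / 2) ** 2).max()))
        margin = int(np.ceil(max(ph, pw) / 2)) + 2
        lo0, hi0 = margin, shape[0] - margin
        lo1, hi1 = margin, shape[1] - margin
        if hi0 <= lo0 or hi1 <= lo1:
            raise CapacityError(params.n_cells, len(placed_r))
        centers = np.array(placed_yx) if placed_yx else np.empty((0, 2))
        radii = np.array(placed_r)
        ok = False
        for _ in range(600):
            cy = rng.uniform(lo0, hi0)
            cx = rng.uniform(lo1, hi1)
            if len(radii) == 0 or np.all(
                (centers[:, 0] - cy) ** 2 + (centers[:, 1] - cx) ** 2
                > (radii + r_eff + 6.0) ** 2
            ):
                ok = True
                break
        if not ok:
            raise CapacityError(params.n_cells, len(placed_r))
        y0 = int(round(cy - ph / 2))
        x0 = int(round(cx - pw / 2))
        sl = (slice(y0, y0 + ph), slice(x0, x0 + pw))
        nuc_rel[sl][mask] = patch_int[mask]
        nucleus_labels[sl][mask] = next_id
        if extras_patch is not None:
            keep = (extras_patch > 0) & ~mask
            nuc_rel[sl][keep] = np.maximum(nuc_rel[sl][keep], extras_patch[keep])
        records.append({
            "object_id": next_id,
            "class": cls,
            "true_area": int(mask.sum()),
            "true_mean_intensity": ren.amplitude_abs,
            "true_integrated_dna_signal": np.nan,
            "centroid_row": float(ys.mean() + y0),
            "centroid_col": float(xs.mean() + x0),
        })
        placed_yx.append(np.array([cy, cx]))
        placed_r.append(r_eff)
        next_id += 1

    # --- filaments (DNA channel only) ------------------------------------
    fil_rel = np.zeros(shape, dtype=np.float64)
    filament_labels = np.zeros(shape, dtype=np.int32)
    nucleus_any = nucleus_labels > 0
    decondensed = [r for r in records if r["class"] == "decondensed"]
    for k in range(params.net_filament_count):
        if decondensed:
            anchor = decondensed[k % len(decondensed)]
            angle = rng.uniform(0, 2 * np.pi)
            r_start = np.sqrt(anchor["true_area"] / np.pi) + 2.0
            start = np.array([anchor["centroid_row"] + r_start * np.sin(angle),
                              anchor["centroid_col"] + r_start * np.cos(angle)])
            start = np.clip(start, 3, np.array(shape) - 4)
        else:
            start = rng.uniform(10, np.array(shape) - 10)
            angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(100, 400)
        main = _smooth_path(rng, start, angle, length, shape)
        stamped = np.zeros(shape, dtype=bool)
        width = rng.uniform(2.0, 5.0)
        _stamp_path(stamped, main, width / 2.0)
        for _ in range(int(rng.integers(0, 3))):  # web-like branches
            j = int(rng.integers(len(main)))
            bang = angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.3)
            branch = _smooth_path(rng, main[j], bang, length * rng.uniform(0.3, 0.6), shape)
            _stamp_path(stamped, branch, width / 2.0)
        own = stamped & ~nucleus_any & (filament_labels == 0)
        if own.sum() == 0:
            continue
        amp_abs = max(rng.normal(params.net_filament_intensity_mean,
                                 0.15 * params.net_filament_intensity_mean),
                      params.background_mean + 60.0)
        amp_rel = amp_abs - params.background_mean
        vals = amp_rel * (1.0 + rng.normal(0.0, 0.06, size=int(own.sum())))
        vals = np.clip(vals, 0.0, None)
        fil_rel[own] = vals
        filament_labels[own] = next_id
        ys, xs = np.nonzero(own)
        records.append({
            "object_id": next_id,
            "class": "filament",
            "true_area": int(own.sum()),
            "true_mean_intensity": amp_abs,
            "true_integrated_dna_signal": float(vals.sum()),
            "centroid_row": float(ys.mean()),
            "centroid_col": float(xs.mean()),
        })
        next_id += 1

    # --- assemble channels ------------------------------------------------
    def finalize(blurred: np.ndarray) -> np.ndarray:
        img = blurred + params.background_mean \
            + rng.normal(0.0, params.background_sd, size=shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    nuc_blur = gaussian(nuc_rel, sigma=0.8, preserve_range=True)
    channel_nuclear = finalize(nuc_blur)
    if fil_rel.any():
        channel_dna = finalize(gaussian(nuc_rel + fil_rel, sigma=0.8, preserve_range=True))
    else:
        channel_dna = finalize(nuc_blur)

    columns = ["object_id", "class", "true_area", "true_mean_intensity",
               "true_integrated_dna_signal", "centroid_row", "centroid_col"]
    objects = pd.DataFrame(records, columns=columns)
    fimg = FieldImage(plate_id=plate_id, well=well, field_index=field_index,
                      channel_nuclear=channel_nuclear, channel_dna=channel_dna)
    truth = GroundTruth(objects=objects, nucleus_labels=nucleus_labels,
                        filament_labels=filament_labels)
    return fimg, truth


# ---------------------------------------------------------------------------
# presets: unstimulated vs PMA time course
# ---------------------------------------------------------------------------

_TIMEPOINTS = (0, 60, 90, 120, 180, 240)

# PMA course: decondensed fraction ramps slowly to 10% at 3 h then jumps to
# 60% at 4 h; the population intensity deficit is 200 units through 3 h and
# 500 units at 4 h; filament load rises to a 3-h peak.
_PMA_COURSE: dict[int, dict[str, Any]] = {
    0: dict(decondensed_fraction=0.02, intensity_drop=200.0, net_filament_count=1),
    60: dict(decondensed_fraction=0.04, intensity_drop=200.0, net_filament_count=3),
    90: dict(decondensed_fraction=0.05, intensity_drop=200.0, net_filament_count=4),
    120: dict(decondensed_fraction=0.06, intensity_drop=200.0, net_filament_count=5),
    180: dict(decondensed_fraction=0.10, intensity_drop=200.0, net_filament_count=8),
    240: dict(decondensed_fraction=0.60, intensity_drop=500.0, net_filament_count=6),
}

PRESET_NAMES = tuple(f"unstim_{t}" for t in _TIMEPOINTS) + tuple(f"pma_{t}" for t in _TIMEPOINTS)


def preset(name: str, **overrides) -> ConditionParams:
    """Documented parameter sets for the unstimulated/PMA time course.

    Names are ``unstim_t`` / ``pma_t`` for t in {0, 60, 90, 120, 180, 240}
    minutes. Keyword overrides replace individual fields (e.g. n_cells, seed).
    """
    if name not in PRESET_NAMES:
        raise LookupError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    cond, t = name.rsplit("_", 1)
    kwargs: dict[str, Any] = {}
    if cond == "pma":
        kwargs.update(_PMA_COURSE[int(t)])
    kwargs.update(overrides)
    return ConditionParams(**kwargs)


# ---------------------------------------------------------------------------
# screen fixture generation
# ---------------------------------------------------------------------------

_PROFILES = ("inducer", "inhibitor", "enhancer", "biphasic_low_inhibit",
             "biphasic_low_induce", "apoptotic_confounder", "inert")


def default_screen_config_path() -> Path:
    """Path of the packaged default 56-compound screen fixture config."""
    return Path(__file__).parent / "data" / "default_screen.yaml"


def load_screen_config(path: Path | str | None = None) -> dict:
    """Load and validate a screen fixture YAML (default: the shipped fixture)."""
    path = default_screen_config_path() if path is None else Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "compounds" not in cfg or not cfg["compounds"]:
        raise ValueError("screen config must list compounds")
    controls = cfg.get("controls", {})
    for key in ("unstimulated_wells", "pma_wells"):
        if controls.get(key, 0) < 1:
            raise ValueError(f"screen config missing control condition wells: {key}")
    n_doses = len(cfg["doses_molar"])
    for comp in cfg["compounds"]:
        if comp.get("profile") not in _PROFILES:
            raise ValueError(f"compound {comp.get('name')}: unknown profile {comp.get('profile')!r}")
        mags = comp.get("magnitude_by_dose")
        if mags is None or len(mags) != n_doses:
            raise ValueError(f"compound {comp.get('name')}: magnitude_by_dose must have {n_doses} entries")
    return cfg


def _effects(profile: str, mags: list[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dose signed effects (unstim, pma) and apoptosis flags for a profile."""
    m = np.asarray(mags, dtype=float)
    zero = np.zeros_like(m)
    apo = np.zeros_like(m, dtype=bool)
    if profile == "inert":
        return zero, zero, apo
    if profile == "inducer":
        return m, zero, apo
    if profile == "inhibitor":
        return zero, m, apo  # magnitudes are negative in config
    if profile == "enhancer":
        return zero, m, apo
    if profile in ("biphasic_low_inhibit", "biphasic_low_induce"):
        return zero, m, apo  # sign flip encoded in the config magnitudes
    if profile == "apoptotic_confounder":
        return m, m, np.abs(m) > 0
    raise ValueError(profile)


def _well_namer():
    """Yield 384-well names A01..P24 row-major."""
    for r in range(16):
        for c in range(1, 25):
            yield f"{chr(ord('A') + r)}{c:02d}"


def generate_screen(config: dict | Path | str | None, out_dir: Path | str,
                    seed: int = 0) -> tuple[PlateLayout, pd.DataFrame, pd.DataFrame]:
    """Emit a complete synthetic modulator screen to disk.

    Writes per-field TIFF pairs, ``layout.csv``, ``truth_objects.csv`` (one
    row per rendered object) and ``truth_wells.csv`` (the condition
    parameters each well was generated with). Two 384-well plates are used:
    an unstimulated plate and a PMA plate; the PMA plate carries a few
    unstimulated wells so thresholds can be calibrated per plate.

    Returns (layout, truth_wells, truth_objects).
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_screen_config(config)
    else:
        cfg = config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    doses = [float(d) for d in cfg["doses_molar"]]
    shape = tuple(cfg.get("image_shape", [640, 640]))
    fields_per_well = int(cfg.get("fields_per_well", 1))
    n_cells = int(cfg.get("n_cells", 80))
    f_base = float(cfg.get("pma_base_fraction", 0.25))
    span = float(cfg.get("effect_span", 0.30))
    drop = float(cfg.get("stimulated_intensity_drop", 200.0))
    apo_base = float(cfg.get("baseline_apoptotic_fraction", 0.02))
    apo_conf = float(cfg.get("confounder_apoptotic_fraction", 0.45))
    timepoint = int(cfg.get("timepoint_min", 180))
    controls = cfg.get("controls", {})

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(cfg.get("seed", 0))])

    def cond_params(condition: str, e: float = 0.0, apoptotic: bool = False,
                    child=None) -> ConditionParams:
        if condition == "PMA":
            f = float(np.clip(f_base + e * span, 0.0, 0.95))
            d = drop
        else:  # unstimulated-like wells
            f = float(np.clip(max(e, 0.0) * span, 0.0, 0.95))
            d = 0.0
        apo = apo_conf if apoptotic else apo_base
        f = min(f, 1.0 - apo)
        return ConditionParams(n_cells=n_cells, decondensed_fraction=f,
                               apoptotic_fraction=apo, intensity_drop=d,
                               seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))

    layout_rows: list[dict] = []
    well_rows: list[dict] = []
    object_frames: list[pd.DataFrame] = []

    def emit_well(plate: str, well: str, condition: str, compound: str,
                  dose: float, params_fn) -> None:
        layout_rows.append({"plate": plate, "well": well, "condition": condition,
                            "compound": compound, "dose_molar": dose,
                            "timepoint_min": timepoint, "replicate": 1})
        for fidx in range(fields_per_well):
            child = ss.spawn(1)[0]
            params = params_fn(child)
            fimg, truth = generate_field(params, shape=shape,
                                         seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
                                         plate_id=plate, well=well, field_index=fidx)
            write_field(fimg, out_dir / "images")
            obj = truth.objects.copy()
            obj.insert(0, "field_index", fidx)
            obj.insert(0, "well", well)
            obj.insert(0, "plate", plate)
            object_frames.append(obj)
            if fidx == 0:
                well_rows.append({"plate": plate, "well": well, "condition": condition,
                                  "compound": compound, "dose_molar": dose,
                                  "true_decondensed_fraction": params.decondensed_fraction,
                                  "true_apoptotic_fraction": params.apoptotic_fraction,
                                  "intensity_drop": params.intensity_drop})

    plates = {"unstimulated": ("screenU", _well_namer()),
              "PMA": ("screenP", _well_namer())}

    for condition in ("unstimulated", "PMA"):
        plate, namer = plates[condition]
        for comp in cfg["compounds"]:
            e_un, e_pma, apo = _effects(comp["profile"], comp["magnitude_by_dose"])
            e_vec = e_un if condition == "unstimulated" else e_pma
            for di, dose in enumerate(doses):
                e, is_apo = float(e_vec[di]), bool(apo[di])
                emit_well(plate, next(namer), condition, comp["name"], dose,
                          lambda child, e=e, is_apo=is_apo, condition=condition:
                          cond_params(condition, e, is_apo, child))

    # control wells
    plate_u, namer_u = plates["unstimulated"]
    plate_p, namer_p = plates["PMA"]
    for _ in range(int(controls.get("unstimulated_wells", 12))):
        emit_well(plate_u, next(namer_u), "unstimulated", "", 0.0,
                  lambda child: cond_params("unstimulated", 0.0, False, child))
    for _ in range(int(controls.get("media_wells", 2))):
        emit_well(plate_u, next(namer_u), "media_control", "", 0.0,
                  lambda child: cond_params("unstimulated", 0.0, False, child))
    for _ in range(int(controls.get("toxicity_wells", 1))):
        emit_well(plate_u, next(namer_u), "toxicity_control", "", 0.0,
                  lambda child: dataclasses.replace(
                      cond_params("unstimulated", 0.0, False, child),
                      apoptotic_fraction=0.6, decondensed_fraction=0.0))
    for _ in range(int(controls.get("pma_wells", 12))):
        emit_well(plate_p, next(namer_p), "PMA", "", 0.0,
                  lambda child: cond_params("PMA", 0.0, False, child))
    for _ in range(int(controls.get("unstim_on_pma_plate", 4))):
        emit_well(plate_p, next(namer_p), "unstimulated", "", 0.0,
                  lambda child: cond_params("unstimulated", 0.0, False, child))
    for _ in range(int(controls.get("celastrol_wells", 2))):
        emit_well(plate_p, next(namer_p), "celastrol_control", "", 0.0,
                  lambda child: dataclasses.replace(
                      cond_params("unstimulated", 0.0, False, child),
                      decondensed_fraction=0.02, intensity_drop=drop))
    for _ in range(int(controls.get("media_wells", 2))):
        emit_well(plate_p, next(namer_p), "media_control", "", 0.0,
                  lambda child: cond_params("unstimulated", 0.0, False, child))
    for _ in range(int(controls.get("toxicity_wells", 1))):
        emit_well(plate_p, next(namer_p), "toxicity_control", "", 0.0,
                  lambda child: dataclasses.replace(
                      cond_params("PMA", 0.0, False, child),
                      apoptotic_fraction=0.6, decondensed_fraction=0.0))

    layout_df = pd.DataFrame(layout_rows).sort_values(["plate", "well"]).reset_index(drop=True)
    layout = PlateLayout(table=layout_df)
    write_layout(layout, out_dir / "layout.csv")
    truth_wells = pd.DataFrame(well_rows)
    truth_objects = pd.concat(object_frames, ignore_index=True)
    truth_wells.to_csv(out_dir / "truth_wells.csv", index=False)
    truth_objects.to_csv(out_dir / "truth_objects.csv", index=False)
    return layout, truth_wells, truth_objects
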