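"""RGB clonal-colour analysis for lentivirally colour-marked populations.

The pipeline mirrors the image-based clonal tracking workflow: background
subtraction (rolling paraboloid), mean-filter smoothing, regional-maximum
cell detection, disc-ROI sampling of the *raw* image, removal of cells with
extreme channel values, fixed-range quantisation of each cell's mean RGB
into 8 x 8 x 8 = 512 colour classes, reduction to the 64 most represented
colours, and clone calling at the >0.1%-of-population abundance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, restoration

from pulsefate.errors import ConfigurationError, FormatError
from pulsefate.ontology import UNASSIGNED

U16_MAX = 65535


# ---------------------------------------------------------------------------
# image preprocessing
# ---------------------------------------------------------------------------

def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def subtract_background(
    image: np.ndarray,
    ball_radius: int = 250,
    per_channel: bool = True,
    method: str = "paraboloid",
) -> np.ndarray:
    """Remove smooth background with a rolling paraboloid of revolution.

    ``method="paraboloid"`` slides an ellipsoid kernel (paraboloid-of-
    revolution approximation) under the image; ``method="opening"`` is a
    fast morphological fallback (grey opening with a disc followed by a
    Gaussian blur of the background estimate). Both return the non-negative
    residual image as float.
    """
    img = np.asarray(image, dtype=float)
    if ball_radius < 1:
        raise ConfigurationError("ball_radius must be >= 1")
    if img.ndim == 3 and per_channel:
        return np.stack(
            [subtract_background(img[..., c], ball_radius, method=method)
             for c in range(img.shape[-1])],
            axis=-1,
        )
    if img.ndim != 2:
        raise FormatError("expected a 2D image or a 3-channel 2D image")
    if ball_radius >= max(img.shape):
        raise ConfigurationError(
            "ball_radius larger than both image dimensions"
        )
    if method == "paraboloid":
        # Ellipsoid kernel of width 2r and height r/2: near its apex this
        # matches the paraboloid z = x^2 / (2r) used by the sliding-
        # paraboloid background estimator.
        kernel = restoration.ellipsoid_kernel(
            (2 * ball_radius + 1, 2 * ball_radius + 1), ball_radius / 2.0
        )
        bg = restoration.rolling_ball(img, kernel=kernel)
    elif method == "opening":
        bg = ndimage.grey_opening(
            img, footprint=_disc_footprint(int(ball_radius))
        )
        bg = ndimage.gaussian_filter(bg, sigma=ball_radius / 4.0)
        bg = np.minimum(bg, img)
    else:
        raise ConfigurationError(f"unknown background method {method!r}")
    return np.clip(img - bg, 0.0, None)


def smooth(image: np.ndarray, radius: int = 5) -> np.ndarray:
    """Mean filter over a disc neighbourhood (circular kernel).

    Constant regions are left unchanged; edges use nearest-pixel padding.
    """
    if radius < 1:
        raise ConfigurationError("radius must be >= 1")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return np.stack(
            [smooth(img[..., c], radius) for c in range(img.shape[-1])], axis=-1
        )
    if img.ndim != 2:
        raise FormatError("expected a 2D image or a 3-channel 2D image")
    fp = _disc_footprint(radius).astype(float)
    fp /= fp.sum()
    return ndimage.convolve(img, fp, mode="nearest")


def detect_cells(
    image: np.ndarray,
    noise_tolerance: float = 10.0,
    min_distance: float = 5.0,
) -> np.ndarray:
    """Find one point per cell as regional maxima of the channel sum.

    A regional maximum is kept when its prominence over the surrounding
    intensity exceeds ``noise_tolerance`` (h-maxima transform); maxima
    closer than ``min_distance`` pixels are merged, keeping the brighter
    one. Returns an (n, 2) array of (x, y) = (column, row) coordinates,
    the centroid of each maximum plateau.
    """
    if noise_tolerance <= 0:
        raise ConfigurationError("noise_tolerance must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.sum(axis=-1)
    if img.ndim != 2:
        raise FormatError("expected a 2D image or a 3-channel 2D image")
    if img.max() - img.min() <= noise_tolerance:
        return np.empty((0, 2))
    peaks = morphology.h_maxima(img, noise_tolerance)
    labels = measure.label(peaks)
    points = []
    for region in measure.regionprops(labels, intensity_image=img):
        ry, rx = region.centroid
        points.append((rx, ry, float(region.intensity_max)))
    if not points:
        return np.empty((0, 2))
    points.sort(key=lambda p: -p[2])
    kept: list[tuple[float, float]] = []
    for x, y, _v in points:
        if all(np.hypot(x - kx, y - ky) >= min_distance for kx, ky in kept):
            kept.append((x, y))
    return np.asarray(kept)


def sample_roi_rgb(
    raw_image: np.ndarray,
    points: np.ndarray,
    roi_radius: int = 5,
    image_id: str | int = 0,
) -> pd.DataFrame:
    """Mean R/G/B over a disc ROI of ``roi_radius`` at each detected point.

    Sampling always uses the raw (unprocessed) image. Discs are clipped at
    the image border, in which case the mean is taken over the partial disc.
    Returns one RGB cell record per point: ``cell_id``, ``image_id``,
    ``x``, ``y``, ``mean_r``, ``mean_g``, ``mean_b``.
    """
    img = np.asarray(raw_image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError("raw_image must be a 3-channel (R, G, B) image")
    h, w = img.shape[:2]
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    dy, dx = np.nonzero(_disc_footprint(roi_radius))
    dy = dy - roi_radius
    dx = dx - roi_radius
    rows = []
    for i, (x, y) in enumerate(points):
        if not (0 <= x < w and 0 <= y < h):
            raise ConfigurationError(f"point ({x:g}, {y:g}) outside image")
        ys = int(round(y)) + dy
        xs = int(round(x)) + dx
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        vals = img[ys[keep], xs[keep], :]
        rows.append((i, image_id, x, y, *vals.mean(axis=0)))
    return pd.DataFrame(
        rows, columns=["cell_id", "image_id", "x", "y", "mean_r", "mean_g", "mean_b"]
    )


# ---------------------------------------------------------------------------
# record filtering and colour quantisation
# ---------------------------------------------------------------------------

CHANNELS = ("mean_r", "mean_g", "mean_b")


def filter_rgb_extremes(
    records: pd.DataFrame,
    low_quantile: float = 0.01,
    high_quantile: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells whose R, G or B mean falls outside per-channel quantile
    bands; returns (kept records, rejection log).

    A record is removed iff any channel lies strictly outside its
    [low, high] quantile band. The rejection log has one row per offending
    (cell, channel) pair with the value and the violated bound.
    """
    if len(records) == 0:
        raise ConfigurationError("no records to filter")
    if len(records) < 10:
        raise ConfigurationError(
            "need >= 10 records for quantile estimation"
        )
    if not 0 <= low_quantile < high_quantile <= 1:
        raise ConfigurationError("require 0 <= low_quantile < high_quantile <= 1")
    log_rows = []
    drop = np.zeros(len(records), dtype=bool)
    for ch in CHANNELS:
        vals = records[ch].to_numpy(dtype=float)
        lo = np.quantile(vals, low_quantile)
        hi = np.quantile(vals, high_quantile)
        too_low = vals < lo
        too_high = vals > hi
        for idx in np.nonzero(too_low)[0]:
            log_rows.append((records["cell_id"].iloc[idx], ch, vals[idx], "below", lo))
        for idx in np.nonzero(too_high)[0]:
            log_rows.append((records["cell_id"].iloc[idx], ch, vals[idx], "above", hi))
        drop |= too_low | too_high
    if drop.all():
        raise ConfigurationError(
            "all records rejected by extreme-value filter; review the "
            "quantile thresholds"
        )
    log = pd.DataFrame(
        log_rows, columns=["cell_id", "channel", "value", "reason", "bound"]
    )
    return records.loc[~drop].reset_index(drop=True), log


def quantise_colours(
    records: pd.DataFrame, bins_per_channel: int = 8
) -> pd.DataFrame:
    """Assign every record to one of ``bins_per_channel**3`` colour classes.

    Bins are equal-width over the fixed 16-bit range [0, 65535]; the class
    index is ``bins**2 * bin_r + bins * bin_g + bin_b`` (64*r + 8*g + b for
    the default 8 bins, giving 512 classes). The assignment is total: every
    in-range record receives exactly one class.
    """
    if bins_per_channel < 2:
        raise ConfigurationError("bins_per_channel must be >= 2")
    out = records.copy()
    bins = bins_per_channel
    idx = {}
    for ch in CHANNELS:
        vals = records[ch].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > U16_MAX):
            raise ConfigurationError(f"{ch} values outside [0, 65535]")
        idx[ch] = np.clip(
            (vals.astype(np.int64) * bins) // (U16_MAX + 1), 0, bins - 1
        )
    out["colour_class"] = (
        bins * bins * idx["mean_r"] + bins * idx["mean_g"] + idx["mean_b"]
    ).astype(int)
    return out


def bin_centres(bins_per_channel: int = 8) -> np.ndarray:
    """Centre intensity of each quantisation bin over the 16-bit range."""
    width = (U16_MAX + 1) / bins_per_channel
    return (np.arange(bins_per_channel) + 0.5) * width


def top_k_reduction(
    assignments: pd.DataFrame, k: int = 64
) -> tuple[pd.DataFrame, float]:
    """Keep the ``k`` most represented colour classes as reduced groups.

    The k most frequent classes receive ``reduced_class`` ids 0..k-1 in
    descending frequency (ties broken by ascending colour-class index);
    all other cells are UNASSIGNED (-1). Returns (assignments with the
    ``reduced_class`` column, coverage = assigned / total).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    out = assignments.copy()
    counts = out["colour_class"].value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} distinct colour classes present; keeping all",
            stacklevel=2,
        )
    kept = order[:k]
    mapping = {cls: i for i, cls in enumerate(kept)}
    out["reduced_class"] = (
        out["colour_class"].map(mapping).fillna(UNASSIGNED).astype(int)
    )
    coverage = float((out["reduced_class"] != UNASSIGNED).mean())
    return out, coverage


@dataclass
class CloneTable:
    """Called clonal colours with abundances.

    ``table`` holds one row per reduced colour group (sorted by count
    descending, ties by ascending colour class): ``reduced_class``,
    ``colour_class``, ``count``, ``fraction`` and ``is_positive_clone``.
    Fractions use all cells (including UNASSIGNED) as denominator.
    """

    table: pd.DataFrame
    total_cells: int
    coverage: float

    @property
    def n_positive(self) -> int:
        return int(self.table["is_positive_clone"].sum())

    @property
    def positive(self) -> pd.DataFrame:
        return self.table.loc[self.table["is_positive_clone"]].reset_index(drop=True)


def call_clones(
    assignments: pd.DataFrame, min_fraction: float = 0.001
) -> CloneTable:
    """Call positive clonal colours from reduced assignments.

    A reduced colour group is a positive clone iff its fraction of the
    whole population (UNASSIGNED cells included in the denominator) is
    strictly greater than ``min_fraction``.
    """
    total = len(assignments)
    if total == 0:
        empty = pd.DataFrame(
            columns=["reduced_class", "colour_class", "count", "fraction",
                     "is_positive_clone"]
        )
        return CloneTable(empty, 0, 0.0)
    if "reduced_class" not in assignments.columns:
        raise FormatError("run top_k_reduction before call_clones")
    assigned = assignments.loc[assignments["reduced_class"] != UNASSIGNED]
    grouped = (
        assigned.groupby(["reduced_class", "colour_class"])
        .size()
        .reset_index(name="count")
    )
    grouped["fraction"] = grouped["count"] / total
    grouped["is_positive_clone"] = grouped["fraction"] > min_fraction
    grouped = grouped.sort_values(
        ["count", "colour_class"], ascending=[False, True]
    ).reset_index(drop=True)
    coverage = float(len(assigned)) / total
    return CloneTable(grouped, total, coverage)


def clone_diversity(clone_table: CloneTable) -> dict:
    """Richness, Shannon index and evenness over positive clones.

    Shannon entropy (natural log) is computed over positive-clone fractions
    renormalised to sum to one; evenness is H / ln(richness). An empty
    table yields zeros with ``undefined=True``.
    """
    pos = clone_table.positive
    if len(pos) == 0:
        return {
            "richness": 0, "shannon": 0.0, "evenness": 0.0,
            "cells_per_clone_mean": 0.0, "cells_per_clone_median": 0.0,
            "undefined": True,
        }
    p = pos["fraction"].to_numpy(dtype=float)
    p = p / p.sum()
    shannon = float(-(p * np.log(p)).sum())
    richness = len(pos)
    evenness = shannon / np.log(richness) if richness > 1 else 1.0
    counts = pos["count"].to_numpy()
    return {
        "richness": richness,
        "shannon": shannon,
        "evenness": float(evenness),
        "cells_per_clone_mean": float(counts.mean()),
        "cells_per_clone_median": float(np.median(counts)),
        "undefined": False,
    }


# ---------------------------------------------------------------------------
# end-to-end pipelines
# ---------------------------------------------------------------------------

def analyze_rgb_table(
    records: pd.DataFrame,
    bins_per_channel: int = 8,
    k: int = 64,
    min_fraction: float = 0.001,
    low_quantile: float | None = 0.01,
    high_quantile: float | None = 0.99,
) -> tuple[pd.DataFrame, CloneTable]:
    """Filter, quantise, reduce and call clones on an RGB cell table.

    Set ``low_quantile``/``high_quantile`` to ``None`` to skip extreme-value
    filtering. Returns (per-cell assignments, clone table).
    """
    recs = records
    if low_quantile is not None and high_quantile is not None:
        recs, _ = filter_rgb_extremes(recs, low_quantile, high_quantile)
    assigned = quantise_colours(recs, bins_per_channel)
    assigned, _cov = top_k_reduction(assigned, k)
    clones = call_clones(assigned, min_fraction)
    return assigned, clones


def analyze_image(
    raw_image: np.ndarray,
    ball_radius: int = 250,
    smooth_radius: int = 5,
    noise_tolerance: float = 10.0,
    roi_radius: int = 5,
    background_method: str = "paraboloid",
    image_id: str | int = 0,
) -> pd.DataFrame:
    """Image stage of the pipeline: preprocess, detect cells, sample ROIs.

    Returns the RGB cell-record table measured on the raw image; feed the
    concatenated tables from all images of a condition to
    :func:`analyze_rgb_table`.
    """
    processed = subtract_background(
        raw_image, ball_radius=ball_radius, method=background_method
    )
    processed = smooth(processed, smooth_radius)
    points = detect_cells(processed, noise_tolerance)
    return sample_roi_rgb(raw_image, points, roi_radius, image_id=image_id)
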