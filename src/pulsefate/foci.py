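"""Detection and quantification of nuclear foci (53BP1, PCNA).

Operates on 2D maximum-intensity projections. Foci are connected
components above a robust per-nucleus threshold (median + k * MAD of
in-mask intensity), filtered by a minimum area; the threshold is affine-
equivariant, so counts are invariant to rescaling the image intensities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from pulsefate.errors import ConfigurationError, FormatError
from pulsefate.synthetic.foci import FociRecord


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z; a single 2D slice is returned unchanged."""
    stack = np.asarray(zstack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise FormatError("expected a (z, y, x) stack with >= 1 slice")
    return stack.max(axis=0)


def segment_nuclei(
    image: np.ndarray,
    pixel_size: float = 0.2,
    min_area_um2: float = 20.0,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Label bright nuclei on a dark background by Otsu thresholding.

    Objects smaller than ``min_area_um2`` are removed. Returns an integer
    label image (0 = background); a foreground-free image yields an empty
    labelling with a warning.
    """
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    if img.max() <= img.min():
        warnings.warn("no foreground found; empty labelling", stacklevel=2)
        return np.zeros(img.shape, dtype=int)
    thr = filters.threshold_otsu(img)
    labels = measure.label(img > thr)
    min_px = min_area_um2 / pixel_size**2
    out = np.zeros_like(labels)
    nxt = 1
    for region in measure.regionprops(labels):
        if region.area >= min_px:
            out[labels == region.label] = nxt
            nxt += 1
    if nxt == 1:
        warnings.warn("no foreground found; empty labelling", stacklevel=2)
    return out


def detect_foci(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    k_mad: float = 3.0,
    min_area_um2: float = 0.08,
    pixel_size: float = 0.2,
    cell_id: int = 0,
    time_min: float = 0.0,
    channel: str = "53BP1",
) -> FociRecord:
    """Detect foci inside one nucleus mask.

    The threshold is the in-mask median plus ``k_mad`` times the scaled
    median absolute deviation (1.4826 * MAD, a robust sigma); foci are
    connected components above it with area >= ``min_area_um2`` (reported
    in um^2).
    """
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("nucleus mask is empty")
    img = np.asarray(image, dtype=float)
    vals = img[mask]
    med = np.median(vals)
    mad = 1.4826 * np.median(np.abs(vals - med))
    thr = med + k_mad * mad
    fg = (img > thr) & mask
    labels = measure.label(fg)
    min_px = min_area_um2 / pixel_size**2
    # guard against the degenerate flat-nucleus case where MAD collapses
    if mad == 0 and not np.any(vals > med):
        labels = np.zeros_like(labels)
    foci = []
    for region in measure.regionprops(labels, intensity_image=img):
        if region.area < min_px:
            continue
        cy, cx = region.centroid
        foci.append(
            (cx, cy, region.area * pixel_size**2, float(region.intensity_mean))
        )
    rad_um = np.sqrt(mask.sum() / np.pi) * pixel_size
    return FociRecord(cell_id, time_min, channel, foci, rad_um)


def foci_classes(
    counts, cutoffs: tuple[int, int] = (5, 15)
) -> tuple[float, float, float]:
    """Fractions of cells with < low, [low, high], and > high foci.

    Boundaries: the low class is strictly below ``cutoffs[0]``, the high
    class strictly above ``cutoffs[1]``, the middle inclusive of both.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ConfigurationError("need at least one cell")
    lo, hi = cutoffs
    f_low = float((counts < lo).mean())
    f_high = float((counts > hi).mean())
    f_mid = float(((counts >= lo) & (counts <= hi)).mean())
    return f_low, f_mid, f_high


def classify_s_stage(
    record: FociRecord,
    nucleus_mask: np.ndarray | None = None,
    min_s_foci: int = 5,
    late_area_um2: float = 0.6,
    mid_radial_median: float = 0.62,
) -> str:
    """Position a cell in S phase from its PCNA focus pattern.

    Rules (operational statistics: count, mean focus area, median radial
    position as a fraction of the nucleus radius): fewer than
    ``min_s_foci`` foci -> nonS; few large foci -> lateS; foci enriched at
    mid/outer radius -> midS; many small dispersed interior foci -> earlyS.
    """
    if record.count < min_s_foci:
        return "nonS"
    if nucleus_mask is not None:
        mask = np.asarray(nucleus_mask, dtype=bool)
        if not mask.any():
            raise ConfigurationError("nucleus mask is empty")
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        rad = np.sqrt(mask.sum() / np.pi)
    else:
        rad = record.nucleus_radius_um / 0.2
        cx = cy = rad + 4
    pos = np.array([(f[0], f[1]) for f in record.foci])
    radial = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy) / rad
    mean_area = float(record.areas_um2.mean())
    if mean_area >= late_area_um2:
        return "lateS"
    if float(np.median(radial)) >= mid_radial_median:
        return "midS"
    return "earlyS"


def foci_timeseries(
    records: list[FociRecord],
    division_times_min: list[float],
    phases: list[str] | None = None,
) -> pd.DataFrame:
    """Per-generation summaries of a focus time series.

    Records must be time-ordered; generations are delimited by the
    division times. For each generation the peak focus count and the
    mean/max focus area during G1 are reported (``phases`` supplies the
    per-record phase labels; without them the first fifth of each
    generation is taken as G1). ``peak_trend_down`` flags a monotone
    decline of per-generation peaks.
    """
    times = np.array([r.time_min for r in records])
    if np.any(np.diff(times) < 0):
        raise ConfigurationError("records must be time-ordered")
    gens = np.searchsorted(np.asarray(division_times_min), times, side="right")
    counts = np.array([r.count for r in records])
    rows = []
    for g in np.unique(gens):
        sel = gens == g
        sel_idx = np.nonzero(sel)[0]
        peak = int(counts[sel].max()) if sel.any() else 0
        if phases is not None:
            g1_idx = [i for i in sel_idx if phases[i] == "G1"]
        else:
            g1_idx = list(sel_idx[: max(1, len(sel_idx) // 5)])
        areas = np.concatenate(
            [records[i].areas_um2 for i in g1_idx]
        ) if g1_idx else np.empty(0)
        rows.append(
            (int(g), peak,
             float(areas.mean()) if areas.size else np.nan,
             float(areas.max()) if areas.size else np.nan)
        )
    out = pd.DataFrame(
        rows, columns=["generation", "peak_count", "g1_mean_area_um2",
                       "g1_max_area_um2"]
    )
    peaks = out["peak_count"].to_numpy()
    out.attrs["peak_trend_down"] = bool(np.all(np.diff(peaks) <= 0))
    return out
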