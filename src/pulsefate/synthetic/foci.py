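"""Ground-truth DNA-damage (53BP1) and replication (PCNA) focus kinetics.

Counts follow the phase- and generation-dependent regimes seen in dual
biosensor time lapses: undamaged replication produces a small number of
foci (< 20) that resolve by G2, with daughters carrying a few large G1
nuclear bodies (up to ~5 um^2); cells damaged in G1 accumulate a burst of
~100 foci on S entry that resolves slowly while mean focus size grows;
cells damaged in early S show the same first-cycle burst but markedly
lower counts in later replication rounds, with G1 body size increasing
from daughter to grand-daughter cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pulsefate.errors import ConfigurationError
from pulsefate.synthetic.fucci import CellCycleParams

PIXEL_SIZE_UM = 0.2  # default pixel size of rendered focus images


@dataclass(frozen=True)
class FociKinetics:
    """Rates and size regimes of the focus model.

    appearance_rate / resolution_rate are foci per hour (ramp-up during S,
    clearance afterwards); ``size_growth`` is the area growth of persistent
    foci in um^2/h; ``s_burst_count`` is the expected focus count during a
    damaged first replication (order 100); ``baseline_count`` the count
    during undamaged replication (< 20); ``g1_body_mean_area_um2`` the mean
    area of post-mitotic G1 nuclear bodies.
    """

    appearance_rate: float = 35.0
    resolution_rate: float = 4.0
    size_growth: float = 0.02
    g1_body_mean_area_um2: float = 2.5
    s_burst_count: float = 100.0
    baseline_count: float = 12.0

    def validate(self) -> None:
        for name in ("appearance_rate", "resolution_rate", "size_growth",
                     "g1_body_mean_area_um2", "s_burst_count",
                     "baseline_count"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class FociRecord:
    """Per-nucleus, per-frame focus measurements for one marker channel.

    ``foci`` holds one (x_px, y_px, area_um2, mean_intensity) tuple per
    focus; ``count`` always equals ``len(foci)``.
    """

    cell_id: int
    time_min: float
    channel: str
    foci: list[tuple[float, float, float, float]] = field(default_factory=list)
    nucleus_radius_um: float = 8.0

    @property
    def count(self) -> int:
        return len(self.foci)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([f[2] for f in self.foci]) if self.foci else np.empty(0)


def _latent_count(t_h: np.ndarray, phase_of, kinetics: FociKinetics,
                  exposure_phase: str, generation_of) -> np.ndarray:
    """Deterministic focus-count skeleton over track time (hours)."""
    n = np.zeros_like(t_h)
    for j, t in enumerate(t_h):
        ph = phase_of(t)
        gen = generation_of(t)
        if exposure_phase == "untreated":
            target = kinetics.baseline_count if ph == "S" else 0.0
            g1_target = 3.0 if ph == "G1" and gen > 0 else 0.0
        elif exposure_phase == "G1":
            # burst on S entry, then slow resolution during the arrest
            if ph in ("S", "G2"):
                target = kinetics.s_burst_count
            elif ph == "ARREST":
                target = 0.3 * kinetics.s_burst_count
            else:
                target = 0.0
            g1_target = 0.0
        else:  # earlyS / lateS exposures
            decline = 0.4 ** gen
            target = (
                kinetics.s_burst_count * decline if ph == "S"
                else (kinetics.s_burst_count * 0.5 * decline if ph == "G2" else 0.0)
            )
            g1_target = 4.0 if ph == "G1" and gen > 0 else 0.0
        n[j] = max(target, g1_target)
    return n


def _place_spots(
    rng: np.random.Generator,
    k: int,
    r_lo: float,
    r_hi: float,
    rad_px: float,
    centre: float,
    min_sep_px: float = 3.5,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throw ``k`` spot centres into a radial band of the nucleus,
    keeping centres at least ``min_sep_px`` apart so rendered foci stay
    resolvable as separate particles."""
    xs = np.empty(k)
    ys = np.empty(k)
    n = 0
    for _ in range(k * max_tries):
        if n == k:
            break
        r = np.sqrt(rng.uniform(r_lo**2, r_hi**2)) * rad_px
        theta = rng.uniform(0, 2 * np.pi)
        x = centre + r * np.cos(theta)
        y = centre + r * np.sin(theta)
        if n and np.min(np.hypot(xs[:n] - x, ys[:n] - y)) < min_sep_px:
            continue
        xs[n], ys[n] = x, y
        n += 1
    return xs[:n], ys[:n]


def make_foci_series(
    exposure_phase: str,
    kinetics: FociKinetics | None = None,
    generations: int = 3,
    seed: int = 0,
    params: CellCycleParams | None = None,
    channel: str = "53BP1",
    nucleus_radius_um: float = 8.0,
) -> tuple[list[FociRecord], pd.DataFrame]:
    """Simulate per-frame focus ground truth across ``generations`` cycles.

    Returns (records, truth) where truth has one row per frame with
    ``time_min``, ``generation``, ``phase`` and the latent count, and a
    ``division_time_min`` attribute listing generation boundaries in
    ``truth.attrs["division_times_min"]``.
    """
    if generations < 1:
        raise ConfigurationError("generations must be >= 1")
    if kinetics is None:
        kinetics = FociKinetics()
    kinetics.validate()
    if params is None:
        params = CellCycleParams()
    rng = np.random.default_rng(seed)

    dt_h = params.frame_interval_minutes / 60.0
    t_h = np.arange(0.0, 72.0 + dt_h / 2.0, dt_h)

    arrested = exposure_phase == "G1"
    cycle = params.g1_hours + params.s_hours + params.g2_hours + params.m_hours
    if exposure_phase == "untreated" or not arrested:
        # start just before S so the first replication is observed quickly
        offset = params.g1_hours - 1.0
        div_times = []
        t = cycle - offset
        for _g in range(1, generations):
            div_times.append(t)
            t += cycle
    else:
        offset = params.g1_hours - 1.0
        div_times = []  # G1-exposed cells arrest without dividing

    def generation_of(t: float) -> int:
        # a frame exactly on a division boundary belongs to the daughter
        return int(np.searchsorted(div_times, t, side="right"))

    def phase_of(t: float) -> str:
        if arrested and t + offset > params.g1_hours + params.s_hours:
            return "ARREST"
        age = (t + offset) % cycle if not arrested else t + offset
        if age < params.g1_hours:
            return "G1"
        if age < params.g1_hours + params.s_hours:
            return "S"
        return "G2"

    latent = _latent_count(t_h, phase_of, kinetics, exposure_phase,
                           generation_of)
    # smooth ramp-up/decay at the appearance/resolution rates; mitosis
    # resets the count (damage is repartitioned into G1 nuclear bodies)
    counts = np.zeros_like(latent)
    gens = np.array([generation_of(t) for t in t_h])
    for j in range(1, len(latent)):
        prev = counts[j - 1]
        tgt = latent[j]
        if gens[j] != gens[j - 1]:
            counts[j] = min(tgt, kinetics.appearance_rate * dt_h)
        elif tgt > prev:
            counts[j] = min(tgt, prev + kinetics.appearance_rate * dt_h)
        else:
            counts[j] = max(tgt, prev - kinetics.resolution_rate * dt_h)
    noise = rng.normal(0, 1.0, len(counts)) * (counts > 0)
    counts = np.clip(np.rint(counts + noise), 0, None)

    records = []
    truth_rows = []
    for j, t in enumerate(t_h):
        ph = phase_of(t)
        gen = generation_of(t)
        k = int(counts[j])
        foci = []
        if k > 0:
            if ph == "G1" and gen > 0:
                # few large nuclear bodies; size grows with generation
                gen_scale = 0.4 * gen if exposure_phase != "untreated" else 1.0
                mean_a = min(kinetics.g1_body_mean_area_um2 * gen_scale, 5.0)
                areas = np.clip(rng.gamma(4.0, mean_a / 4.0, k), 0.2, 5.0)
            else:
                base = 0.3 + kinetics.size_growth * max(
                    0.0, t - params.s_hours
                ) * (exposure_phase != "untreated")
                areas = np.clip(rng.gamma(3.0, base / 3.0, k), 0.12, 1.2)
            rad_px = nucleus_radius_um / PIXEL_SIZE_UM
            # cap focus size so k resolvable spots fit in the nucleus:
            # dense bursts are made of small foci, sparse arrest frames of
            # large ones (count and size trade off, as observed)
            region_px = np.pi * (0.85 * rad_px) ** 2
            r_cap_px = max(1.05, 0.45 * np.sqrt(region_px / k) - 0.9)
            area_cap = np.pi * (r_cap_px * PIXEL_SIZE_UM) ** 2
            areas = np.minimum(areas, max(0.13, area_cap))
            max_r_px = np.sqrt(areas.max() / np.pi) / PIXEL_SIZE_UM
            sep = max(3.5, 2.0 * max_r_px + 1.8)
            xs, ys = _place_spots(rng, k, 0.0, 0.85, rad_px, rad_px + 4, sep)
            areas = areas[: len(xs)]
            inten = rng.uniform(8000, 14000, len(xs))
            foci = list(zip(xs, ys, areas, inten))
        records.append(
            FociRecord(0, t * 60.0, channel, foci, nucleus_radius_um)
        )
        truth_rows.append((t * 60.0, gen, ph, float(counts[j])))

    truth = pd.DataFrame(
        truth_rows, columns=["time_min", "generation", "phase", "count"]
    )
    truth.attrs["division_times_min"] = [d * 60.0 for d in div_times]
    return records, truth


# ---------------------------------------------------------------------------
# PCNA pattern archetypes for S sub-staging
# ---------------------------------------------------------------------------

_PCNA_PATTERNS = {
    # (count mean, focus area um^2, radial band of the nucleus radius)
    "earlyS": (80, 0.15, (0.0, 0.75)),
    "midS": (60, 0.20, (0.55, 0.80)),
    "lateS": (12, 1.20, (0.75, 0.95)),
    "nonS": (0, 0.0, (0.0, 0.0)),
}


def make_pcna_pattern(
    stage: str,
    nucleus_radius_um: float = 8.0,
    seed: int = 0,
) -> FociRecord:
    """Archetypal PCNA focus pattern for an S-phase sub-stage.

    early S: many small foci dispersed through the nuclear interior;
    mid S: foci enriched in a perinucleolar/mid-radial annulus;
    late S: few large peripheral clusters; nonS: no replication foci.
    """
    if stage not in _PCNA_PATTERNS:
        raise ConfigurationError(f"unknown S stage {stage!r}")
    rng = np.random.default_rng(seed)
    mean_n, area, (r_lo, r_hi) = _PCNA_PATTERNS[stage]
    k = 0 if mean_n == 0 else max(6, int(rng.poisson(mean_n)))
    rad_px = nucleus_radius_um / PIXEL_SIZE_UM
    cx = cy = rad_px + 4
    foci = []
    if k:
        min_sep = 3.5 if stage != "lateS" else 8.0
        xs, ys = _place_spots(rng, k, r_lo, r_hi, rad_px, cx, min_sep)
        areas = np.clip(rng.gamma(6.0, area / 6.0, len(xs)), 0.05, 4.0)
        inten = rng.uniform(9000, 15000, len(xs))
        foci = list(zip(xs, ys, areas, inten))
    return FociRecord(0, 0.0, "PCNA", foci, nucleus_radius_um)


def render_nucleus_image(
    record: FociRecord,
    pixel_size: float = PIXEL_SIZE_UM,
    noise_sd: float = 150.0,
    nucleus_level: float = 3000.0,
    background: float = 200.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one FociRecord as a 16-bit image plus its true nucleus mask.

    The nucleus is a bright disc; each focus is a flat disc of the focus
    area at the focus intensity (so measured areas can be compared against
    truth), with Gaussian camera noise on top.
    """
    rng = np.random.default_rng(seed)
    rad_px = record.nucleus_radius_um / pixel_size
    size = int(np.ceil(2 * rad_px + 9))
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = rad_px + 4
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad_px**2
    img = np.full((size, size), background)
    img[mask] = nucleus_level
    for x, y, area_um2, inten in record.foci:
        # at least ~2 px per focus so sub-resolution truth stays detectable
        r_px = max(np.sqrt(area_um2 / np.pi) / pixel_size, 1.05)
        spot = (xx - x) ** 2 + (yy - y) ** 2 <= r_px**2
        img[spot & mask] = inten
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16), mask
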