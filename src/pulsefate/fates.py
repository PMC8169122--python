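"""FUCCI phase calling, division detection and single-cell fate ontology.

A track is a per-frame table of reporter intensities (red = G1 reporter,
green = S/G2/M reporter), nuclear area and viability, optionally with
annotated NEBD/ANAPHASE/DEATH events. Phase is called by thresholding the
two reporters with run-length hysteresis; fates are assigned by a fixed
decision order over the events and the called phase sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pulsefate.errors import ConfigurationError, FormatError
from pulsefate.ontology import UNCLASSIFIABLE

REQUIRED_COLUMNS = ("time_min", "red", "green")


def _coerce_track(track) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Accept a SyntheticTrack, a DataFrame, or (frames, events)."""
    if hasattr(track, "frames"):
        return track.frames, list(getattr(track, "events", []) or [])
    if isinstance(track, tuple) and len(track) == 2:
        return track[0], list(track[1] or [])
    return track, []


def _check_frames(frames: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frames.columns]
    if missing:
        raise FormatError(f"track is missing intensity columns: {missing}")


# ---------------------------------------------------------------------------
# phase calling
# ---------------------------------------------------------------------------

def call_phase_track(
    track,
    red_threshold: float = 0.2,
    green_threshold: float = 0.2,
    min_run: int = 2,
) -> np.ndarray:
    """Call a per-frame phase label sequence from a FUCCI intensity trace.

    red-only -> G1; both reporters above threshold -> G1/S; green-only ->
    S/G2/M; neither -> GAP. DEAD (from the ``alive`` column, absorbing)
    overrides colour. Runs shorter than ``min_run`` frames are merged into
    the preceding phase (hysteresis against threshold chatter).
    """
    frames, _ = _coerce_track(track)
    _check_frames(frames)
    if red_threshold <= 0 or green_threshold <= 0:
        raise ConfigurationError("phase thresholds must be positive")
    if len(frames) < 2:
        raise FormatError("track must have at least 2 frames")
    red = frames["red"].to_numpy(dtype=float)
    green = frames["green"].to_numpy(dtype=float)
    labels = np.where(
        red >= red_threshold,
        np.where(green >= green_threshold, "G1/S", "G1"),
        np.where(green >= green_threshold, "S/G2/M", "GAP"),
    ).astype(object)
    if "alive" in frames.columns:
        alive = frames["alive"].to_numpy(dtype=bool)
        if not alive.all():
            first_dead = int(np.argmax(~alive))
            labels[first_dead:] = "DEAD"
    return _merge_short_runs(labels, min_run)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def _merge_short_runs(labels: np.ndarray, min_run: int) -> np.ndarray:
    if min_run <= 1:
        return labels
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        if len(runs) == 1:
            break
        for idx, (start, end, lab) in enumerate(runs):
            if lab == "DEAD" or end - start >= min_run:
                continue
            # merge into the flanking phase: prefer the preceding run
            if idx > 0:
                labels[start:end] = runs[idx - 1][2]
            else:
                labels[start:end] = runs[idx + 1][2]
            changed = True
            break
    return labels


# ---------------------------------------------------------------------------
# division events
# ---------------------------------------------------------------------------

def detect_division_events(
    track,
    proxy_area_drop: float = 0.40,
    proxy_mitotic_minutes: float = 30.0,
    green_threshold: float = 0.2,
    max_mitosis_hours: float = 3.0,
    min_mitosis_minutes: float = 15.0,
) -> list[tuple[float, float]]:
    """Return time-ordered (NEBD_time, anaphase_time) pairs in minutes.

    Annotated NEBD/ANAPHASE events take precedence; an ANAPHASE without a
    preceding NEBD within the plausible mitosis window is flagged and
    dropped. Without annotations a morphology proxy is used: a nuclear-area
    drop of at least ``proxy_area_drop`` within one frame coincident with a
    green-reporter reset marks anaphase, and NEBD is imputed
    ``proxy_mitotic_minutes`` earlier.
    """
    frames, events = _coerce_track(track)
    if events:
        nebds = [t for name, t in events if name == "NEBD"]
        anas = [t for name, t in events if name == "ANAPHASE"]
        pairs = []
        for t_ana in sorted(anas):
            candidates = [
                t for t in nebds
                if min_mitosis_minutes <= t_ana - t <= max_mitosis_hours * 60.0
            ]
            if not candidates:
                continue  # anaphase without a plausible NEBD: dropped
            t_nebd = max(candidates)
            nebds.remove(t_nebd)
            pairs.append((t_nebd, t_ana))
        return sorted(pairs)

    _check_frames(frames)
    if "area_um2" not in frames.columns:
        return []
    area = frames["area_um2"].to_numpy(dtype=float)
    green = frames["green"].to_numpy(dtype=float)
    times = frames["time_min"].to_numpy(dtype=float)
    pairs = []
    for i in range(1, len(area)):
        if not np.isfinite(area[i]) or not np.isfinite(area[i - 1]):
            continue
        if area[i] > (1.0 - proxy_area_drop) * area[i - 1]:
            continue
        # require the green reporter to reset around the drop
        lo = max(0, i - 1)
        hi = min(len(green), i + 2)
        if green[lo:hi].min() > green_threshold:
            continue
        t_ana = times[i]
        pairs.append((t_ana - proxy_mitotic_minutes, t_ana))
    return pairs


def mitotic_length(pair: tuple[float, float]) -> float:
    """Minutes from NEBD to anaphase onset."""
    nebd, ana = pair
    if ana <= nebd:
        raise ConfigurationError("anaphase must follow NEBD")
    return ana - nebd


def interphase_length(
    pair: tuple[float, float], next_pair: tuple[float, float]
) -> float:
    """Minutes from anaphase to the followed daughter's next NEBD."""
    _, ana = pair
    next_nebd, _ = next_pair
    if next_nebd <= ana:
        raise ConfigurationError("events out of order across divisions")
    return next_nebd - ana


# ---------------------------------------------------------------------------
# fate classification
# ---------------------------------------------------------------------------

@dataclass
class FateCall:
    """Classified outcome of one track."""

    fate: str
    n_divisions: int
    division_times: list[float] = field(default_factory=list)
    mitotic_lengths: list[float] = field(default_factory=list)
    first_g1_length_after_division: float | None = None
    condition: str | None = None


def classify_fate(
    track,
    horizon_hours: float = 72.0,
    g2_exit_min_green_hours: float = 20.0,
    g1_terminal_arrest_hours: float = 8.0,
    red_threshold: float = 0.2,
    green_threshold: float = 0.2,
    min_run: int = 2,
) -> FateCall:
    """Classify a track into the single-cell fate ontology.

    Decision order: death (before/after mitosis) > two-or-more divisions
    (PROLIF) > one division (G1_AAM when it ends in a terminal G1 arrest of
    at least ``g1_terminal_arrest_hours``, SINGLE_DIV otherwise) > G2-exit
    (a green period of at least ``g2_exit_min_green_hours`` resolved into
    red without mitosis) > G1 arrest (G1_ABM) > persistent S/G2 arrest.
    Only events at or before the horizon (closed interval) count. All-GAP
    tracks are flagged UNCLASSIFIABLE.
    """
    frames, events = _coerce_track(track)
    phases = call_phase_track(
        track, red_threshold, green_threshold, min_run
    )
    times = frames["time_min"].to_numpy(dtype=float)
    horizon_min = horizon_hours * 60.0
    in_horizon = times <= horizon_min + 1e-6

    pairs = [
        p for p in detect_division_events(track, green_threshold=green_threshold)
        if p[1] <= horizon_min + 1e-6
    ]
    division_times = [p[1] for p in pairs]
    lengths = [mitotic_length(p) for p in pairs]
    n_div = len(pairs)

    first_g1 = None
    if pairs:
        after = (times > pairs[0][1]) & in_horizon
        idx = np.nonzero(after)[0]
        run_len = 0
        started = False
        for i in idx:
            if phases[i] in ("G1", "GAP"):
                run_len += 1
                started = True
            elif started:
                break
        if started and run_len > 0:
            first_g1 = run_len * float(np.median(np.diff(times)))

    death_time = None
    for name, t in events:
        if name == "DEATH" and t <= horizon_min + 1e-6:
            death_time = t
            break
    if death_time is None and "alive" in frames.columns:
        alive = frames["alive"].to_numpy(dtype=bool)
        dead_idx = np.nonzero(~alive & in_horizon)[0]
        if len(dead_idx):
            death_time = float(times[dead_idx[0]])

    call = FateCall(
        fate=UNCLASSIFIABLE,
        n_divisions=n_div,
        division_times=division_times,
        mitotic_lengths=lengths,
        first_g1_length_after_division=first_g1,
    )

    live_phases = phases[in_horizon]
    if np.all(np.isin(live_phases, ("GAP", "DEAD"))) and death_time is None:
        return call  # UNCLASSIFIABLE

    if death_time is not None:
        call.fate = "DBM" if n_div == 0 else "DAM"
        return call
    if n_div >= 2:
        call.fate = "PROLIF"
        return call

    dt_min = float(np.median(np.diff(times)))
    if n_div == 1:
        terminal = _terminal_run_hours(phases, in_horizon, ("G1", "GAP"), dt_min)
        call.fate = (
            "G1_AAM" if terminal >= g1_terminal_arrest_hours else "SINGLE_DIV"
        )
        return call

    green_runs = [
        (s, e) for s, e, lab in _runs(phases[in_horizon]) if lab == "S/G2/M"
    ]
    long_green = [
        (s, e) for s, e in green_runs
        if (e - s) * dt_min / 60.0 >= g2_exit_min_green_hours
    ]
    if long_green:
        s, e = long_green[-1]
        rest = phases[in_horizon][e:]
        if np.any(rest == "G1"):
            call.fate = "G2_EXIT"
        else:
            call.fate = "SG2_ARREST"
        return call
    last_lab = _last_informative(phases[in_horizon])
    if last_lab == "S/G2/M":
        call.fate = "SG2_ARREST"
    else:
        call.fate = "G1_ABM"
    return call


def _terminal_run_hours(phases, in_horizon, labels, dt_min) -> float:
    seq = phases[in_horizon]
    n = 0
    for lab in seq[::-1]:
        if lab in labels:
            n += 1
        else:
            break
    return n * dt_min / 60.0


def _last_informative(seq) -> str | None:
    for lab in seq[::-1]:
        if lab not in ("GAP", "DEAD"):
            return lab
    return None


# ---------------------------------------------------------------------------
# exposure-phase labelling for synchronise-and-pulse protocols
# ---------------------------------------------------------------------------

#: offset-hour breakpoints mapping pulse timing after release to the cell
#: cycle phase that was targeted. palbociclib releases cells at the start
#: of G1; thymidine releases them at the G1/S boundary.
DEFAULT_BREAKPOINTS = {
    "palbo_release": ((3.0, "G1"), (9.0, "G1/S"), (12.0, "earlyS")),
    "thy_release": ((1.0, "G1/S"), (2.5, "earlyS"), (8.0, "lateS"),
                    (12.0, "G2/M")),
}


def label_exposure_phase(
    protocol: str,
    offset_hours: float,
    breakpoints: dict | None = None,
) -> str:
    """Map a synchronisation protocol and pulse offset to the targeted phase.

    (palbo_release, 0) -> G1; (palbo_release, 6) -> G1/S;
    (thy_release, -2) -> G1/S; (thy_release, 4) -> lateS.
    Offsets outside [-4, 12] h are outside the calibrated range.
    """
    table = (breakpoints or DEFAULT_BREAKPOINTS).get(protocol)
    if table is None:
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    if not -4.0 <= offset_hours <= 12.0:
        raise ConfigurationError(
            f"offset {offset_hours:g} h outside the calibrated [-4, 12] h range"
        )
    for upper, label in table:
        if offset_hours <= upper:
            return label
    return table[-1][1]


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def aggregate_cohort(
    fate_calls: list[FateCall],
    conditions: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate classified tracks into a fate-fraction table and a
    divisions-per-cell distribution (0, 1, 2, 3+) per condition.

    UNCLASSIFIABLE tracks are excluded from fractions (with their count
    reported separately under n_unclassifiable).
    """
    if not fate_calls:
        raise ConfigurationError("no classified tracks to aggregate")
    if conditions is None:
        conditions = ["all"] * len(fate_calls)
    df = pd.DataFrame(
        {
            "condition": conditions,
            "fate": [c.fate for c in fate_calls],
            "n_divisions": [c.n_divisions for c in fate_calls],
        }
    )
    classified = df[df["fate"] != UNCLASSIFIABLE]
    rows = []
    for cond, sub in classified.groupby("condition"):
        total = len(sub)
        for fate, cnt in sub["fate"].value_counts().items():
            rows.append((cond, fate, int(cnt), cnt / total))
    fate_table = pd.DataFrame(
        rows, columns=["condition", "fate", "count", "fraction"]
    )
    div_rows = []
    for cond, sub in df.groupby("condition"):
        binned = np.clip(sub["n_divisions"], 0, 3)
        for k in range(4):
            div_rows.append(
                (cond, "3+" if k == 3 else str(k), int((binned == k).sum()))
            )
    divisions = pd.DataFrame(div_rows, columns=["condition", "divisions", "count"])
    return fate_table, divisions


def phase_fractions(data, min_cells: int = 100) -> pd.DataFrame:
    """Red/yellow/green fraction time series.

    Accepts either the output of ``simulate_population`` (passed through on
    its fraction columns) or a mapping time -> sequence of per-cell phase
    labels, where GAP counts as G1-like (red) and DEAD cells are excluded.
    """
    if isinstance(data, pd.DataFrame):
        needed = {"time_h", "frac_red", "frac_yellow", "frac_green"}
        if not needed.issubset(data.columns):
            raise FormatError(
                "expected simulate_population output with fraction columns"
            )
        return data[sorted(needed)].copy()
    rows = []
    for t, labels in data.items():
        labels = np.asarray(labels, dtype=object)
        labels = labels[labels != "DEAD"]
        if len(labels) == 0:
            raise ConfigurationError(f"empty snapshot at t={t}")
        if len(labels) < min_cells:
            raise ConfigurationError(
                f"snapshot at t={t} has {len(labels)} cells; "
                f">= {min_cells} needed for stable fractions"
            )
        red = np.isin(labels, ("G1", "GAP")).mean()
        yellow = (labels == "G1/S").mean()
        green = (labels == "S/G2/M").mean()
        rows.append((t, red, yellow, green))
    return pd.DataFrame(
        rows, columns=["time_h", "frac_red", "frac_yellow", "frac_green"]
    )
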