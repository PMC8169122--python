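"""Scripted single-cell FUCCI trajectories with known fates.

Each synthetic track realises one cell (and, after division, the first
daughter line) over a 72 h time lapse sampled every 30 min. The FUCCI
reporters are modelled on their standard behaviour: the G1 reporter (red)
is high through G1 and decays over the first ~2 h of S phase while the
S/G2/M reporter (green) rises, giving a yellow G1/S window; both reset at
anaphase with a one-frame colourless gap. Fates are assigned exactly from
a count-based allocation (no sampling), shuffled by seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pulsefate.errors import AllocationError, ConfigurationError
from pulsefate.ontology import EXPOSURE_PHASES, FATE_LABELS

HORIZON_HOURS = 72.0
BASE_AREA_UM2 = 140.0
MAX_ENLARGEMENT_FOLD = 6.0


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle timing and arrest/enlargement parameters.

    Durations are hours unless noted. Defaults give a total cycle of 35 h
    with a G1 share whose exponential-growth steady-state occupancy,
    2*(1 - 2**(-G1/T)), is ~0.76 - matching the 70-80% G1 fraction seen in
    untreated tumours. ``treated_cycle_factor`` lengthens the cycles of
    cells that keep proliferating after a drug pulse.
    """

    g1_hours: float = 24.0
    s_hours: float = 7.0
    g2_hours: float = 3.0
    m_hours: float = 1.0
    mitotic_length_minutes: float = 30.0
    duration_cv: float = 0.15
    g2_exit_arrest_hours: float = 30.0
    enlargement_rate: float = 1.5
    p53_functional: bool = True
    frame_interval_minutes: float = 30.0
    yellow_overlap_hours: float = 2.0
    treated_cycle_factor: float = 1.4
    sg2_exit_mean_hours: float = 96.0
    sg2_exit_sd_hours: float = 24.0

    def validate(self) -> None:
        for name in ("g1_hours", "s_hours", "g2_hours", "m_hours",
                     "mitotic_length_minutes", "frame_interval_minutes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.duration_cv < 0:
            raise ConfigurationError("duration_cv must be non-negative")
        if self.enlargement_rate < 1:
            raise ConfigurationError("enlargement_rate must be >= 1")
        if self.g2_exit_arrest_hours <= 0:
            raise ConfigurationError("g2_exit_arrest_hours must be positive")

    @property
    def total_hours(self) -> float:
        return self.g1_hours + self.s_hours + self.g2_hours + self.m_hours


def steady_state_g1_fraction(params: CellCycleParams) -> float:
    """G1 occupancy under exponential growth with the given mean durations."""
    t = params.total_hours
    return 2.0 * (1.0 - 2.0 ** (-params.g1_hours / t))


@dataclass(frozen=True)
class FateAllocation:
    """Fate composition of an exposure cohort.

    ``counts_or_probs`` maps fate labels to either non-negative integer
    counts (applied exactly) or probabilities summing to 1 (used for
    population-scale sampling). ``prolif_divisions`` optionally fixes the
    number of divisions completed by PROLIF tracks before they arrest
    (e.g. 2 for late-S exposure, where surviving proliferators completed
    exactly two divisions within the window).
    """

    exposure_phase: str
    counts_or_probs: dict
    prolif_divisions: int | None = None

    def __post_init__(self) -> None:
        if self.exposure_phase not in EXPOSURE_PHASES:
            raise AllocationError(
                f"unknown exposure phase {self.exposure_phase!r}"
            )
        bad = set(self.counts_or_probs) - set(FATE_LABELS)
        if bad:
            raise AllocationError(f"unknown fate labels: {sorted(bad)}")
        vals = np.array(list(self.counts_or_probs.values()), dtype=float)
        if np.any(vals < 0):
            raise AllocationError("fate counts/probabilities must be non-negative")
        if vals.sum() == 0:
            raise AllocationError("allocation is empty")

    @property
    def is_probabilistic(self) -> bool:
        vals = np.array(list(self.counts_or_probs.values()), dtype=float)
        return bool(abs(vals.sum() - 1.0) < 1e-9 and np.any(vals != np.rint(vals))) or (
            abs(vals.sum() - 1.0) < 1e-9 and vals.max() < 1.0
        )

    def probabilities(self) -> dict:
        vals = np.array(list(self.counts_or_probs.values()), dtype=float)
        return {
            k: float(v / vals.sum()) for k, v in self.counts_or_probs.items()
        }

    def counts_for(self, n: int) -> dict:
        """Exact per-fate counts for a cohort of size ``n``."""
        vals = np.array(list(self.counts_or_probs.values()), dtype=float)
        if np.all(vals == np.rint(vals)) and not abs(vals.sum() - 1.0) < 1e-9:
            if int(vals.sum()) != n:
                raise AllocationError(
                    f"allocation counts sum to {int(vals.sum())}, cohort size is {n}"
                )
            return {k: int(v) for k, v in self.counts_or_probs.items()}
        if abs(vals.sum() - 1.0) > 1e-9:
            raise AllocationError(
                "counts_or_probs must be integer counts or probabilities summing to 1"
            )
        # largest-remainder apportionment of probabilities into n slots
        raw = {k: v * n for k, v in self.probabilities().items()}
        base = {k: int(np.floor(v)) for k, v in raw.items()}
        short = n - sum(base.values())
        order = sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)
        for k in order[:short]:
            base[k] += 1
        return base


def reference_allocations() -> dict[str, FateAllocation]:
    """Default fate allocations for the four synchronise-and-pulse
    conditions tracked at n = 50 cells each.

    G1 exposure (release from palbociclib, pulse immediately): 7/50 single
    divisions, no multi-dividers, the remainder split 40 G2-exit / 3
    persistent S/G2 arrest. G1/S exposure via palbociclib (+6 h) or
    thymidine (-2 h): 13/50 and 16/50 proliferative. Late-S exposure
    (thymidine +4 h): nearly all cells divide once then arrest, 4/50
    complete exactly two divisions.
    """
    return {
        "palbo_G1": FateAllocation(
            "G1", {"SINGLE_DIV": 7, "G2_EXIT": 40, "SG2_ARREST": 3}
        ),
        "palbo_G1S": FateAllocation(
            "G1/S",
            {"PROLIF": 13, "SINGLE_DIV": 10, "G2_EXIT": 14, "SG2_ARREST": 2,
             "G1_ABM": 2, "G1_AAM": 3, "DBM": 2, "DAM": 4},
        ),
        "thy_G1S": FateAllocation(
            "G1/S",
            {"PROLIF": 16, "SINGLE_DIV": 10, "G2_EXIT": 13, "SG2_ARREST": 2,
             "G1_ABM": 1, "G1_AAM": 3, "DBM": 2, "DAM": 3},
        ),
        "thy_lateS": FateAllocation(
            "lateS",
            {"PROLIF": 4, "SINGLE_DIV": 30, "G2_EXIT": 8, "G1_AAM": 4,
             "DBM": 1, "DAM": 3},
            prolif_divisions=2,
        ),
    }


@dataclass
class SyntheticTrack:
    """One simulated FUCCI trajectory with ground truth.

    ``frames`` has columns time_min, red, green, area_um2, alive;
    ``events`` is a time-ordered list of (event_type, time_min) with
    event_type in {NEBD, ANAPHASE, DEATH, G2_EXIT}; ``truth_phases`` gives
    the generator's per-frame colour-class label.
    """

    track_id: int
    frames: pd.DataFrame
    events: list[tuple[str, float]]
    truth_fate: str
    truth_exposure_phase: str
    n_divisions_truth: int
    truth_phases: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

# internal segment states
_G1, _YEL, _GRN, _GAP, _RED_ARREST, _GRN_ARREST, _DEAD = (
    "G1", "YEL", "GRN", "GAP", "RED_ARREST", "GRN_ARREST", "DEAD"
)

_STATE_TO_PHASE = {
    _G1: "G1", _YEL: "G1/S", _GRN: "S/G2/M", _GAP: "GAP",
    _RED_ARREST: "G1", _GRN_ARREST: "S/G2/M", _DEAD: "DEAD",
}

# canonical reporter intensities per state (arbitrary units, amplitude 1)
_STATE_RED = {_G1: 1.0, _YEL: 0.7, _GRN: 0.02, _GAP: 0.05,
              _RED_ARREST: 1.0, _GRN_ARREST: 0.02, _DEAD: 0.0}
_STATE_GREEN = {_G1: 0.02, _YEL: 0.6, _GRN: 1.0, _GAP: 0.05,
                _RED_ARREST: 0.02, _GRN_ARREST: 1.0, _DEAD: 0.0}


def _draw(rng: np.random.Generator, mean: float, cv: float, factor: float = 1.0) -> float:
    if cv == 0:
        return mean * factor
    return max(0.25 * mean, rng.normal(mean, cv * mean)) * factor


def _start_age(phase: str, params: CellCycleParams, rng: np.random.Generator,
               cycle_hours: tuple[float, float, float, float]) -> float:
    """Cycle age (hours since last division) at exposure time 0."""
    g1, s, g2, m = cycle_hours
    yw = min(params.yellow_overlap_hours, s)
    jitter = rng.uniform(-0.4, 0.4)
    if phase == "G1":
        return max(0.0, 1.0 + jitter)
    if phase == "G1/S":
        return max(0.0, g1 + 0.3 * jitter)
    if phase == "earlyS":
        return g1 + yw + 0.5 + jitter * 0.3
    if phase == "lateS":
        return g1 + s - 1.5 + jitter * 0.5
    if phase == "G2/M":
        return g1 + s + 0.5 + jitter * 0.3
    if phase == "untreated":
        # uniform over interphase; mid-mitosis exposure is not scripted
        return rng.uniform(0.0, g1 + s + g2)
    raise ConfigurationError(f"unknown exposure phase {phase!r}")


class _Script:
    """Piecewise colour-state timeline plus events for one track."""

    def __init__(self) -> None:
        self.segments: list[tuple[float, float, str]] = []  # hours
        self.events: list[tuple[str, float]] = []  # minutes
        self.division_times: list[float] = []  # hours
        self.arrest_onset: float | None = None
        self.death_time: float | None = None

    def add(self, t0: float, t1: float, state: str) -> None:
        if t1 > t0:
            self.segments.append((t0, min(t1, HORIZON_HOURS + 1.0), state))

    def event(self, name: str, t_hours: float) -> None:
        if 0.0 <= t_hours <= HORIZON_HOURS:
            self.events.append((name, t_hours * 60.0))


def _run_cycle(script: _Script, t: float, age: float, params: CellCycleParams,
               rng: np.random.Generator, factor: float) -> float:
    """Advance one cell-cycle from cycle-age ``age`` at time ``t``; emit
    colour segments and NEBD/ANAPHASE events; return the anaphase time."""
    cv = params.duration_cv
    g1 = _draw(rng, params.g1_hours, cv, factor)
    s = _draw(rng, params.s_hours, cv, factor)
    g2 = _draw(rng, params.g2_hours, cv, factor)
    m = max(params.mitotic_length_minutes / 60.0,
            _draw(rng, params.m_hours, cv, factor))
    yw = min(params.yellow_overlap_hours, s)
    # phase boundary times relative to cycle start
    b_g1, b_yel, b_grn = g1, g1 + yw, g1 + s + g2 + m
    start = t - age
    script.add(max(t, start), start + b_g1, _G1)
    script.add(max(t, start + b_g1), start + b_yel, _YEL)
    script.add(max(t, start + b_yel), start + b_grn, _GRN)
    nebd = start + g1 + s + g2
    mitotic_len_h = max(
        5.0 / 60.0, _draw(rng, params.mitotic_length_minutes, cv) / 60.0
    )
    anaphase = nebd + mitotic_len_h
    if nebd >= max(t, 0.0):
        script.event("NEBD", nebd)
        script.event("ANAPHASE", anaphase)
        if anaphase <= HORIZON_HOURS:
            script.division_times.append(anaphase)
    # one-frame colourless gap after anaphase
    gap = params.frame_interval_minutes / 60.0
    script.add(anaphase, anaphase + gap, _GAP)
    return anaphase + gap


def _time_to_s_entry(age: float, g1: float) -> float:
    return max(0.0, g1 - age)


def _build_script(fate: str, exposure: str, params: CellCycleParams,
                  rng: np.random.Generator,
                  prolif_divisions: int | None) -> _Script:
    cv = params.duration_cv
    treated = exposure != "untreated"
    factor = params.treated_cycle_factor if treated else 1.0
    horizon = HORIZON_HOURS

    for _retry in range(60):
        script = _Script()
        cyc = (
            _draw(rng, params.g1_hours, cv),
            _draw(rng, params.s_hours, cv),
            _draw(rng, params.g2_hours, cv),
            _draw(rng, params.m_hours, cv),
        )
        g1_0, s_0, g2_0, m_0 = cyc
        age = _start_age(exposure, params, rng, cyc)
        yw = min(params.yellow_overlap_hours, s_0)

        if fate == "PROLIF":
            # first cycle runs at native speed from the exposure position,
            # subsequent (post-damage) cycles are lengthened by `factor`
            t = _run_first_cycle(script, age, cyc, params, rng)
            n_div = 1
            while t < horizon and (
                prolif_divisions is None or n_div < prolif_divisions
            ):
                t = _run_cycle(script, t, 0.0, params, rng, factor)
                if script.division_times and script.division_times[-1] <= horizon:
                    n_div = len(script.division_times)
            if prolif_divisions is not None and n_div >= prolif_divisions:
                # post-division S/G2 arrest (enlarging, still green)
                last = script.division_times[-1]
                gap = params.frame_interval_minutes / 60.0
                script.add(last + gap, last + gap + _draw(rng, params.g1_hours, cv),
                           _G1)
                # abridged G1 then re-entry and arrest
                reentry = last + gap + _draw(rng, 4.0, cv)
                script.segments = [s for s in script.segments if s[0] < reentry]
                script.segments = _truncate(script.segments, reentry)
                script.add(reentry, reentry + yw, _YEL)
                script.add(reentry + yw, horizon, _GRN_ARREST)
                script.arrest_onset = reentry + yw
            if len(script.division_times) >= 2 and (
                prolif_divisions is None or
                len(script.division_times) == prolif_divisions
            ):
                return script
            continue  # redraw durations: PROLIF must fit its divisions

        if fate in ("SINGLE_DIV", "G1_AAM", "DAM"):
            t = _run_first_cycle(script, age, cyc, params, rng)
            div = script.division_times[0] if script.division_times else None
            if div is None or div > horizon - 2.0:
                continue  # division must land inside the window
            if fate == "SINGLE_DIV":
                # daughter: short G1 then S re-entry and persistent arrest
                reentry = t + _draw(rng, 4.0, cv)
                script.add(t, reentry, _G1)
                script.add(reentry, reentry + yw, _YEL)
                script.add(reentry + yw, horizon, _GRN_ARREST)
                script.arrest_onset = reentry + yw
                if horizon - (reentry + yw) < 4.0:
                    continue  # keep a clear green terminal arrest
            elif fate == "G1_AAM":
                script.add(t, horizon, _RED_ARREST)
                script.arrest_onset = t
                if horizon - t < 9.0:
                    continue  # terminal G1 arrest must be visible
            else:  # DAM: daughter dies after the division
                death = min(div + rng.uniform(5.0, 25.0), horizon - 1.0)
                if death <= t:
                    death = t + 0.5
                script.add(t, death, _G1)
                script.segments = _truncate(script.segments, death)
                script.add(death, horizon, _DEAD)
                script.event("DEATH", death)
                script.death_time = death
            return script

        if fate == "DBM":
            t_s = _time_to_s_entry(age, g1_0)
            nebd_est = t_s + max(0.0, g1_0 + s_0 + g2_0 - max(age, g1_0))
            death = min(rng.uniform(20.0, 50.0), max(1.0, 0.8 * nebd_est))
            _emit_interphase(script, age, cyc, yw, 0.0, death)
            script.segments = _truncate(script.segments, death)
            script.add(death, horizon, _DEAD)
            script.event("DEATH", death)
            script.death_time = death
            return script

        if fate == "G2_EXIT":
            green_start = max(0.0, g1_0 + yw - age)
            _emit_interphase(script, age, cyc, yw, 0.0, green_start)
            natural_exit = green_start + s_0 + g2_0 + _draw(
                rng, params.g2_exit_arrest_hours, cv
            )
            exit_t = min(natural_exit, horizon - 2.0)
            if exit_t - green_start < 20.0:
                exit_t = min(green_start + 20.5, horizon - 1.0)
            script.add(green_start, exit_t, _GRN_ARREST)
            script.add(exit_t, horizon, _RED_ARREST)
            script.event("G2_EXIT", exit_t)
            script.arrest_onset = green_start
            return script

        if fate == "SG2_ARREST":
            green_start = max(0.0, g1_0 + yw - age)
            _emit_interphase(script, age, cyc, yw, 0.0, green_start)
            script.add(green_start, horizon, _GRN_ARREST)
            script.arrest_onset = green_start
            if horizon - green_start < 21.0:
                continue  # arrest must dominate the record
            return script

        if fate == "G1_ABM":
            # aborts cycle progression and settles into a G1-like arrest
            settle = min(_time_to_s_entry(age, g1_0), 2.0)
            _emit_interphase(script, age, cyc, yw, 0.0, settle)
            script.segments = _truncate(script.segments, settle)
            script.add(settle, horizon, _RED_ARREST)
            script.arrest_onset = settle
            return script

        raise ConfigurationError(f"unknown fate {fate!r}")

    raise ConfigurationError(
        f"could not realise fate {fate!r} for exposure {exposure!r} within "
        f"the {horizon:g} h window"
    )


def _run_first_cycle(script: _Script, age: float,
                     cyc: tuple[float, float, float, float],
                     params: CellCycleParams, rng: np.random.Generator) -> float:
    """Emit the exposure cycle from cycle-age ``age``; return end time
    (after the post-anaphase gap)."""
    g1, s, g2, m = cyc
    yw = min(params.yellow_overlap_hours, s)
    start = -age
    script.add(0.0, start + g1, _G1)
    script.add(max(0.0, start + g1), start + g1 + yw, _YEL)
    nebd = start + g1 + s + g2
    mitotic_len_h = max(
        5.0 / 60.0, _draw(rng, params.mitotic_length_minutes, params.duration_cv) / 60.0
    )
    anaphase = nebd + mitotic_len_h
    script.add(max(0.0, start + g1 + yw), anaphase, _GRN)
    if nebd >= 0:
        script.event("NEBD", nebd)
        script.event("ANAPHASE", anaphase)
        if anaphase <= HORIZON_HOURS:
            script.division_times.append(anaphase)
    gap = params.frame_interval_minutes / 60.0
    script.add(anaphase, anaphase + gap, _GAP)
    return anaphase + gap


def _emit_interphase(script: _Script, age: float,
                     cyc: tuple[float, float, float, float], yw: float,
                     t0: float, t1: float) -> None:
    """Colour segments for a cell progressing (without mitosis) from cycle
    age ``age``, clipped to [t0, t1]."""
    g1 = cyc[0]
    start = -age
    script.add(t0, min(t1, start + g1), _G1)
    if t1 > start + g1:
        script.add(max(t0, start + g1), min(t1, start + g1 + yw), _YEL)
    if t1 > start + g1 + yw:
        script.add(max(t0, start + g1 + yw), t1, _GRN)


def _truncate(segments: list[tuple[float, float, str]], t: float):
    out = []
    for t0, t1, state in segments:
        if t0 >= t:
            continue
        out.append((t0, min(t1, t), state))
    return out


def _sample_frames(script: _Script, fate: str, params: CellCycleParams,
                   noise_sd: float, rng: np.random.Generator):
    dt = params.frame_interval_minutes
    times = np.arange(0.0, HORIZON_HOURS * 60.0 + 0.5 * dt, dt)
    n = len(times)
    states = np.empty(n, dtype=object)
    states[:] = _G1
    segs = sorted(script.segments, key=lambda s: s[0])
    t_hours = times / 60.0
    # a frame exactly on a boundary belongs to the later segment
    for t0, t1, state in segs:
        mask = (t_hours >= t0 - 1e-9) & (t_hours <= t1 + 1e-9)
        states[mask] = state
    if script.death_time is not None:
        states[t_hours >= script.death_time - 1e-9] = _DEAD

    red = np.array([_STATE_RED[s] for s in states])
    green = np.array([_STATE_GREEN[s] for s in states])
    alive = states != _DEAD
    if noise_sd > 0:
        red = red + rng.normal(0.0, noise_sd, n)
        green = green + rng.normal(0.0, noise_sd, n)
        red[~alive] = 0.0
        green[~alive] = 0.0
        red = np.clip(red, 0.0, None)
        green = np.clip(green, 0.0, None)

    area = _area_profile(t_hours, script, fate, params)
    if noise_sd > 0:
        area = area * (1.0 + rng.normal(0.0, 0.02, n))
    area[~alive] = np.nan

    phases = np.array([_STATE_TO_PHASE[s] for s in states])
    frames = pd.DataFrame(
        {"time_min": times, "red": red, "green": green,
         "area_um2": area, "alive": alive}
    )
    return frames, phases


def _area_profile(t_hours: np.ndarray, script: _Script, fate: str,
                  params: CellCycleParams) -> np.ndarray:
    """Nuclear area: doubles over each cycle (2**(cycle fraction)), halves
    at division; arrested cells grow exponentially at ``enlargement_rate``
    fold per 24 h, capped at a 6-fold enlargement."""
    area = np.full(len(t_hours), BASE_AREA_UM2)
    divs = sorted(script.division_times)
    bounds = [0.0] + [d for d in divs] + [HORIZON_HOURS + 1.0]
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (t_hours >= lo) & (t_hours < hi)
        span = max(hi - lo, 1e-6)
        cycle_span = min(span, params.total_hours)
        frac = np.clip((t_hours[mask] - lo) / cycle_span, 0.0, 1.0)
        area[mask] = BASE_AREA_UM2 * 2.0 ** frac
    if script.arrest_onset is not None:
        # enlargement accumulates from exposure (or from the last division
        # for arrest-after-mitosis fates), not from the arrest read-out
        onset = script.arrest_onset
        growth_start = divs[-1] if divs else 0.0
        mask = t_hours >= onset
        growth = params.enlargement_rate ** (
            (t_hours[mask] - growth_start) / 24.0
        )
        area[mask] = BASE_AREA_UM2 * np.minimum(growth, MAX_ENLARGEMENT_FOLD)
    return area


def make_fucci_cohort(
    allocation: FateAllocation,
    params: CellCycleParams | None = None,
    n: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[SyntheticTrack]:
    """Generate ``n`` FUCCI tracks whose truth fates match the allocation
    exactly (count-based allocations are applied without sampling; the
    order of fates along the cohort is shuffled by ``seed``)."""
    if params is None:
        params = CellCycleParams()
    params.validate()
    counts = allocation.counts_for(n)
    fates: list[str] = []
    for fate, c in counts.items():
        fates.extend([fate] * c)
    root = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(root.spawn(1)[0])
    shuffle_rng.shuffle(fates)
    tracks = []
    child_seqs = root.spawn(len(fates) + 1)[1:]
    for i, (fate, seq) in enumerate(zip(fates, child_seqs)):
        rng = np.random.default_rng(seq)
        script = _build_script(
            fate, allocation.exposure_phase, params, rng,
            allocation.prolif_divisions,
        )
        frames, phases = _sample_frames(script, fate, params, noise_sd, rng)
        events = sorted(script.events, key=lambda e: e[1])
        n_div = sum(1 for e in events if e[0] == "ANAPHASE")
        tracks.append(
            SyntheticTrack(
                track_id=i,
                frames=frames,
                events=events,
                truth_fate=fate,
                truth_exposure_phase=allocation.exposure_phase,
                n_divisions_truth=n_div,
                truth_phases=phases,
            )
        )
    return tracks
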