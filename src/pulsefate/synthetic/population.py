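"""Phase-structured population dynamics with FUCCI colour read-out.

Simulates a population of cycling cells (untreated) or a pulse-treated
population whose per-cell fate is drawn from a phase-at-exposure fate map.
The read-out mimics scoring a FUCCI field: counts of red (G1-like),
yellow (G1/S) and green (S/G2/M) cells over time, plus mean nuclear areas
of arrested versus cycling cells.

Treated dynamics follow the observed behaviour of p53-proficient cells:
most cells arrest in S/G2 during the first replication cycle and later
exit into a G1-like red state without dividing (G2-exit); survivors that
keep proliferating do so with lengthened cycles. With p53 disabled, the
fate map shifts mass from arrest/G2-exit towards continued (aberrant)
division and post-mitotic death.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pulsefate.errors import ConfigurationError
from pulsefate.synthetic.fucci import (
    BASE_AREA_UM2,
    MAX_ENLARGEMENT_FOLD,
    CellCycleParams,
    FateAllocation,
    reference_allocations,
)

_RED, _YELLOW, _GREEN = 0, 1, 2


def default_phase_fate_map(p53_functional: bool = True) -> dict[str, FateAllocation]:
    """Fate allocation per cell-cycle phase at the moment of the pulse.

    The four synchronised-cohort allocations provide the G1, G1/S, early-S
    and late-S columns; G2/M-exposed cells mostly complete the imminent
    division once and then arrest. Without functional p53 the arrest/exit
    mass shifts towards further divisions and death after mitosis.
    """
    ref = reference_allocations()
    mapping = {
        "G1": ref["palbo_G1"],
        "G1/S": ref["palbo_G1S"],
        "earlyS": ref["thy_G1S"],
        "lateS": ref["thy_lateS"],
        "G2/M": FateAllocation(
            "G2/M",
            {"SINGLE_DIV": 0.72, "G1_AAM": 0.14, "DAM": 0.08,
             "PROLIF": 0.04, "DBM": 0.02},
        ),
    }
    if not p53_functional:
        loosened = {}
        for phase, alloc in mapping.items():
            probs = alloc.probabilities()
            shift = 0.6 * probs.get("G2_EXIT", 0.0) + 0.5 * probs.get(
                "SG2_ARREST", 0.0
            )
            probs["G2_EXIT"] = 0.4 * probs.get("G2_EXIT", 0.0)
            probs["SG2_ARREST"] = 0.5 * probs.get("SG2_ARREST", 0.0)
            probs["PROLIF"] = probs.get("PROLIF", 0.0) + 0.7 * shift
            probs["DAM"] = probs.get("DAM", 0.0) + 0.3 * shift
            total = sum(probs.values())
            loosened[phase] = FateAllocation(
                alloc.exposure_phase,
                {k: v / total for k, v in probs.items() if v > 0},
                prolif_divisions=None,
            )
        mapping = loosened
    return mapping


def _steady_state_ages(
    rng: np.random.Generator, totals: np.ndarray
) -> np.ndarray:
    """Sample cell ages from the exponential-growth age distribution
    F(a) = 2 (1 - 2^(-a/T)) for per-cell cycle lengths ``totals``."""
    u = rng.uniform(0.0, 1.0, size=len(totals))
    return -totals * np.log2(1.0 - u / 2.0)


def _draw_durations(
    rng: np.random.Generator, params: CellCycleParams, n: int,
    factor: float = 1.0,
) -> np.ndarray:
    """(n, 4) array of G1/S/G2/M durations in hours."""
    means = np.array(
        [params.g1_hours, params.s_hours, params.g2_hours, params.m_hours]
    )
    if params.duration_cv == 0:
        out = np.tile(means, (n, 1))
    else:
        out = rng.normal(means, params.duration_cv * means, size=(n, 4))
        out = np.maximum(out, 0.25 * means)
    return out * factor


def _grow_lineages(
    rng: np.random.Generator,
    params: CellCycleParams,
    births: np.ndarray,
    horizon: float,
    factor: float = 1.0,
    initial_ages: np.ndarray | None = None,
    max_cells: int = 2_000_000,
) -> pd.DataFrame:
    """Expand cycling cells into all descendants born before ``horizon``.

    Returns one row per cell with birth time, phase-boundary offsets and
    end time (division or horizon).
    """
    rows = []
    cur_births = births
    cur_durs = _draw_durations(rng, params, len(births), factor)
    if initial_ages is not None:
        # founder cells started their cycle before t=0
        cur_births = births - initial_ages
    generation = 0
    n_total = 0
    while len(cur_births):
        totals = cur_durs.sum(axis=1)
        div = cur_births + totals
        rows.append(
            np.column_stack(
                [cur_births, cur_durs[:, 0], cur_durs[:, 1] + cur_durs[:, 2]
                 + cur_durs[:, 3], div]
            )
        )
        n_total += len(cur_births)
        if n_total > max_cells:
            raise ConfigurationError(
                "population exceeded the simulation cell cap"
            )
        parents = div[div < horizon]
        if len(parents) == 0:
            break
        cur_births = np.repeat(parents, 2)
        cur_durs = _draw_durations(rng, params, len(cur_births), factor)
        generation += 1
    data = np.concatenate(rows, axis=0)
    return pd.DataFrame(data, columns=["birth", "g1", "rest", "end"])


def _count_cycling(
    cells: pd.DataFrame, t: float, yellow_hours: float
) -> np.ndarray:
    """(red, yellow, green) counts of cycling cells alive at time ``t``."""
    alive = (cells["birth"].to_numpy() <= t) & (t < cells["end"].to_numpy())
    age = t - cells["birth"].to_numpy()[alive]
    g1 = cells["g1"].to_numpy()[alive]
    red = int((age < g1).sum())
    yellow = int(((age >= g1) & (age < g1 + yellow_hours)).sum())
    green = int((age >= g1 + yellow_hours).sum())
    return np.array([red, yellow, green])


def simulate_population(
    params: CellCycleParams | None = None,
    treatment: str = "none",
    phase_fate_map: dict[str, FateAllocation] | None = None,
    n0: int = 2000,
    duration_days: float = 5.0,
    seed: int = 0,
    sample_interval_hours: float = 2.0,
) -> pd.DataFrame:
    """Simulate FUCCI colour-class dynamics of a population.

    Parameters
    ----------
    treatment
        ``"none"`` for unperturbed growth or ``"pulse"`` for a drug pulse
        at t = 0, after which each cell's fate is drawn from
        ``phase_fate_map`` according to its phase at exposure.
    n0
        Initial cell count (>= 100 recommended for stable fractions).
    duration_days
        Simulated span (<= 21 days).

    Returns a frame indexed by time with colour-class counts, fractions
    (summing to one), total alive cells, and mean nuclear areas of
    arrested and cycling cells.
    """
    if params is None:
        params = CellCycleParams()
    params.validate()
    if n0 < 1:
        raise ConfigurationError("n0 must be >= 1")
    if duration_days > 21:
        raise ConfigurationError("duration_days must be <= 21")
    if treatment not in ("none", "pulse"):
        raise ConfigurationError(f"unknown treatment {treatment!r}")
    if treatment == "pulse":
        if phase_fate_map is None:
            phase_fate_map = default_phase_fate_map(params.p53_functional)
        if not phase_fate_map:
            raise ConfigurationError("phase_fate_map is empty")

    rng = np.random.default_rng(seed)
    horizon = duration_days * 24.0
    times = np.arange(0.0, horizon + 1e-9, sample_interval_hours)
    yellow = min(params.yellow_overlap_hours, params.s_hours)

    if treatment == "none":
        durs0 = _draw_durations(rng, params, n0)
        ages = _steady_state_ages(rng, durs0.sum(axis=1))
        cells = _grow_lineages(
            rng, params, np.zeros(n0), horizon, initial_ages=ages
        )
        rows = []
        for t in times:
            counts = _count_cycling(cells, t, yellow)
            rows.append(_row(t, counts, arrested_area=np.nan,
                             cycling_area=_mean_cycling_area(cells, t, params)))
        return pd.DataFrame(rows)

    return _simulate_pulse(rng, params, phase_fate_map, n0, times, yellow)


def _row(t, counts, arrested_area, cycling_area):
    total = int(counts.sum())
    frac = counts / total if total else np.zeros(3)
    return {
        "time_h": t,
        "n_red": int(counts[0]), "n_yellow": int(counts[1]),
        "n_green": int(counts[2]), "n_total": total,
        "frac_red": frac[0], "frac_yellow": frac[1], "frac_green": frac[2],
        "mean_area_arrested": arrested_area,
        "mean_area_cycling": cycling_area,
    }


def _mean_cycling_area(cells: pd.DataFrame, t: float,
                       params: CellCycleParams) -> float:
    alive = (cells["birth"].to_numpy() <= t) & (t < cells["end"].to_numpy())
    if not alive.any():
        return np.nan
    age = t - cells["birth"].to_numpy()[alive]
    total = (cells["g1"].to_numpy() + cells["rest"].to_numpy())[alive]
    return float(np.mean(BASE_AREA_UM2 * 2.0 ** np.clip(age / total, 0, 1)))


def _simulate_pulse(rng, params, phase_fate_map, n0, times, yellow):
    horizon = float(times[-1])
    durs0 = _draw_durations(rng, params, n0)
    totals0 = durs0.sum(axis=1)
    ages = _steady_state_ages(rng, totals0)
    ages = np.minimum(ages, totals0 - 1e-3)
    g1_0 = durs0[:, 0]
    s_0 = durs0[:, 1]
    g2m_0 = durs0[:, 2] + durs0[:, 3]

    # phase at exposure
    phase = np.empty(n0, dtype=object)
    phase[ages < g1_0] = "G1"
    in_yel = (ages >= g1_0) & (ages < g1_0 + yellow)
    phase[in_yel] = "G1/S"
    s_frac = (ages - g1_0 - yellow) / np.maximum(s_0 - yellow, 1e-6)
    in_s = (ages >= g1_0 + yellow) & (ages < g1_0 + s_0)
    phase[in_s & (s_frac < 0.5)] = "earlyS"
    phase[in_s & (s_frac >= 0.5)] = "lateS"
    phase[ages >= g1_0 + s_0] = "G2/M"

    fate = np.empty(n0, dtype=object)
    for ph in np.unique(phase):
        alloc = phase_fate_map.get(ph)
        if alloc is None:
            raise ConfigurationError(f"phase_fate_map lacks phase {ph!r}")
        probs = alloc.probabilities()
        labels = list(probs)
        p = np.array([probs[k] for k in labels])
        mask = phase == ph
        fate[mask] = rng.choice(labels, size=int(mask.sum()), p=p / p.sum())

    # piecewise colour segments (t0, t1, colour) per non-proliferating cell
    seg_t0, seg_t1, seg_col = [], [], []

    def add(t0, t1, col):
        if t1 > t0:
            seg_t0.append(t0)
            seg_t1.append(min(t1, horizon + 1.0))
            seg_col.append(col)

    def add_interphase(i, t_end):
        """Colour of cell i progressing from its exposure age, up to t_end."""
        a = ages[i]
        add(0.0, min(g1_0[i] - a, t_end), _RED)
        add(max(0.0, g1_0[i] - a), min(g1_0[i] + yellow - a, t_end), _YELLOW)
        add(max(0.0, g1_0[i] + yellow - a), t_end, _GREEN)

    time_to_div = np.maximum(totals0 - ages, 0.05)
    arrest_onset = np.full(n0, np.nan)
    prolif_idx = []

    for i in range(n0):
        f = fate[i]
        if f == "PROLIF":
            prolif_idx.append(i)
            continue
        if f == "G1_ABM":
            add(0.0, horizon + 1.0, _RED)
            arrest_onset[i] = 0.0
        elif f == "G2_EXIT":
            green_start = max(0.0, g1_0[i] + yellow - ages[i])
            exit_t = (green_start + max(0.0, g1_0[i] + s_0[i] - max(ages[i], g1_0[i]))
                      + g2m_0[i]
                      + rng.normal(params.g2_exit_arrest_hours,
                                   0.2 * params.g2_exit_arrest_hours))
            add_interphase(i, green_start)
            add(green_start, exit_t, _GREEN)
            add(exit_t, horizon + 1.0, _RED)
            arrest_onset[i] = green_start
        elif f == "SG2_ARREST":
            green_start = max(0.0, g1_0[i] + yellow - ages[i])
            add_interphase(i, green_start)
            if params.p53_functional:
                exit_t = max(green_start + 1.0,
                             rng.normal(params.sg2_exit_mean_hours,
                                        params.sg2_exit_sd_hours))
                add(green_start, exit_t, _GREEN)
                add(exit_t, horizon + 1.0, _RED)
            else:
                add(green_start, horizon + 1.0, _GREEN)
            arrest_onset[i] = green_start
        elif f in ("SINGLE_DIV", "G1_AAM"):
            div = time_to_div[i]
            add_interphase(i, div)
            if f == "G1_AAM":
                add(div, horizon + 1.0, _RED)
            else:
                # daughters: short G1, re-enter S, arrest, then G2-exit
                reentry = div + rng.uniform(3.0, 6.0)
                exit_t = reentry + params.s_hours + rng.normal(
                    params.g2_exit_arrest_hours,
                    0.2 * params.g2_exit_arrest_hours,
                )
                add(div, reentry, _RED)
                add(reentry, exit_t, _GREEN)
                add(exit_t, horizon + 1.0, _RED)
            arrest_onset[i] = div
        elif f == "DBM":
            death = min(rng.uniform(20.0, 50.0), 0.8 * time_to_div[i])
            add_interphase(i, death)
        elif f == "DAM":
            div = time_to_div[i]
            death = div + rng.uniform(5.0, 25.0)
            add_interphase(i, div)
            add(div, death, _RED)
        else:  # pragma: no cover
            raise ConfigurationError(f"unhandled fate {f!r}")

    # proliferators: finish the exposure cycle at native pace, then cycle
    # with post-damage lengthening
    if prolif_idx:
        idx = np.asarray(prolif_idx)
        for i in idx:
            add_interphase(i, min(time_to_div[i], horizon))
        first_divs = time_to_div[idx]
        first_divs = first_divs[first_divs < horizon]
        daughters = np.repeat(first_divs, 2)
        pro_cells = _grow_lineages(
            rng, params, daughters, horizon,
            factor=params.treated_cycle_factor,
        )
    else:
        pro_cells = pd.DataFrame(columns=["birth", "g1", "rest", "end"])

    # refresh arrays after the prolif interphase additions
    seg_t0 = np.asarray(seg_t0)
    seg_t1 = np.asarray(seg_t1)
    seg_col = np.asarray(seg_col)

    rows = []
    onset = arrest_onset[~np.isnan(arrest_onset)]
    for t in times:
        live = (seg_t0 <= t) & (t < seg_t1)
        counts = np.array(
            [int((seg_col[live] == c).sum()) for c in (_RED, _YELLOW, _GREEN)]
        )
        counts += _count_cycling(pro_cells, t, yellow) if len(pro_cells) else 0
        arrested_alive = onset[onset <= t]
        if len(arrested_alive):
            growth = params.enlargement_rate ** ((t - arrested_alive) / 24.0)
            area_arr = float(
                np.mean(BASE_AREA_UM2 * np.minimum(growth, MAX_ENLARGEMENT_FOLD))
            )
        else:
            area_arr = np.nan
        area_cyc = (
            _mean_cycling_area(pro_cells, t, params)
            if len(pro_cells) else BASE_AREA_UM2 / np.log(2.0)
        )
        rows.append(_row(t, counts, area_arr, area_cyc))
    return pd.DataFrame(rows)
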