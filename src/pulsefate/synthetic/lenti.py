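"""Lentiviral RGB colour-mix populations with known clonal ground truth.

Models co-transduction with three vectors (red, green, blue fluorescent
proteins). Each founder cell receives a Poisson number of integrations per
channel; each integration expresses at a lognormally distributed level, so
the founder's colour is the background plus the scaled sum of its
integration expressions. All descendants of a founder inherit its colour
exactly; measurement noise only enters when an image is rendered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pulsefate.errors import ConfigurationError

U16_MAX = 65535


@dataclass(frozen=True)
class LentiMixModel:
    """Parameters of the three-vector colour-mixing model.

    Parameters
    ----------
    n_founders
        Number of founder cells (clones) in the transduced population.
    mean_integrations_per_channel
        Expected vector copy number for the red, green and blue vectors.
        A founder that draws zero integrations in every channel would be
        colourless and is resampled.
    expression_scale
        16-bit intensity contributed by one integration expressing at the
        mean level.
    expression_cv
        Coefficient of variation of the lognormal per-integration
        expression level.
    background_level
        Additive intensity common to all channels (autofluorescence,
        camera offset).
    founder_concentration
        Dirichlet concentration per founder for clone abundances. ``None``
        gives exactly equal weights; larger values give more even clones.
    distinct_colours
        Resample founders whose quantised 512-class colour collides with an
        earlier founder, so each clone carries a unique colour code; the
        resampling also keeps every channel at least ``bin_margin``
        intensity units away from a quantisation-bin edge, so moderate
        measurement noise cannot flip a clone's colour class.
    bin_margin
        Minimum distance of founder channel intensities from bin edges
        (16-bit units) when ``distinct_colours`` is set.
    seed
        Seed for all randomness derived from this model.
    """

    n_founders: int = 64
    mean_integrations_per_channel: tuple[float, float, float] = (1.8, 1.8, 1.8)
    expression_scale: float = 9000.0
    expression_cv: float = 0.35
    background_level: float = 300.0
    founder_concentration: float | None = 60.0
    distinct_colours: bool = True
    bin_margin: float = 800.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        means = np.asarray(self.mean_integrations_per_channel, dtype=float)
        if means.shape != (3,) or np.any(means < 0):
            raise ConfigurationError(
                "mean_integrations_per_channel must be three non-negative reals"
            )
        if float(means.sum()) == 0.0:
            raise ConfigurationError(
                "mean_integrations_per_channel: all means are zero, every "
                "founder would be colourless"
            )
        if self.expression_scale <= 0:
            raise ConfigurationError("expression_scale must be positive")
        if self.expression_cv < 0:
            raise ConfigurationError("expression_cv must be non-negative")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be non-negative")
        if self.distinct_colours and self.n_founders > 512:
            raise ConfigurationError(
                "n_founders cannot exceed 512 when distinct_colours is set"
            )


def _lognormal_sum(rng: np.random.Generator, k: int, cv: float) -> float:
    """Sum of k lognormal expression levels with mean 1 and the given CV."""
    if k == 0:
        return 0.0
    if cv == 0:
        return float(k)
    sigma2 = np.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return float(np.sum(rng.lognormal(mu, np.sqrt(sigma2), size=k)))


def _quantise_bin(value: np.ndarray | float, bins: int = 8) -> np.ndarray:
    idx = (np.asarray(value, dtype=np.int64) * bins) // (U16_MAX + 1)
    return np.clip(idx, 0, bins - 1)


def sample_founders(
    model: LentiMixModel, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw founder colours and clone weights for a mixing model.

    Returns a frame with one row per founder: ``founder_id``, true channel
    intensities ``r``/``g``/``b`` (clipped to 16-bit range), the quantised
    ``colour_class`` and the clone abundance ``weight``.
    """
    model.validate()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    means = np.asarray(model.mean_integrations_per_channel, dtype=float)

    colours = np.zeros((model.n_founders, 3))
    seen_classes: set[int] = set()
    for i in range(model.n_founders):
        for _attempt in range(100_000):
            copies = rng.poisson(means)
            if copies.sum() == 0:
                continue  # colourless founders are resampled
            rgb = model.background_level + model.expression_scale * np.array(
                [_lognormal_sum(rng, int(k), model.expression_cv) for k in copies]
            )
            rgb = np.clip(rgb, 0.0, U16_MAX)
            b = _quantise_bin(rgb)
            cls = int(64 * b[0] + 8 * b[1] + b[2])
            if model.distinct_colours:
                if cls in seen_classes:
                    continue
                # only interior bin edges can be crossed by noise; the
                # outer range limits are clipped anyway
                width = (U16_MAX + 1) / 8.0
                nearest = width * np.clip(np.round(rgb / width), 1, 7)
                if np.any(np.abs(rgb - nearest) < model.bin_margin):
                    continue
            seen_classes.add(cls)
            colours[i] = rgb
            break
        else:  # pragma: no cover - requires pathological parameters
            raise ConfigurationError(
                "could not sample a distinct colour for every founder; "
                "reduce n_founders or widen the expression distribution"
            )

    if model.founder_concentration is None:
        weights = np.full(model.n_founders, 1.0 / model.n_founders)
    else:
        weights = rng.dirichlet(
            np.full(model.n_founders, float(model.founder_concentration))
        )

    bins = _quantise_bin(colours)
    classes = 64 * bins[:, 0] + 8 * bins[:, 1] + bins[:, 2]
    return pd.DataFrame(
        {
            "founder_id": np.arange(model.n_founders),
            "r": colours[:, 0],
            "g": colours[:, 1],
            "b": colours[:, 2],
            "colour_class": classes.astype(int),
            "weight": weights,
        }
    )


def make_lenti_population(
    model: LentiMixModel,
    n_cells: int,
    image_shape: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expand a founder mix into a cell population table.

    Each cell is assigned to a founder by a weighted draw and inherits the
    founder's true colour exactly. Positions ``x``/``y`` are uniform over
    the image (or a 1000 x 1000 px field when no shape is given); use
    :func:`render_clone_image` for collision-free placement.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    founders = sample_founders(model, rng)
    assignment = rng.choice(
        model.n_founders, size=n_cells, p=founders["weight"].to_numpy()
    )
    shape = image_shape if image_shape is not None else (1000, 1000)
    x = rng.uniform(0, shape[1], size=n_cells)
    y = rng.uniform(0, shape[0], size=n_cells)
    cols = founders.loc[assignment, ["r", "g", "b"]].to_numpy()
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "founder_id": assignment,
            "r": cols[:, 0],
            "g": cols[:, 1],
            "b": cols[:, 2],
            "x": x,
            "y": y,
        }
    )


def place_cells(
    n: int,
    image_shape: tuple[int, int],
    min_separation_px: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Rejection-sample ``n`` (x, y) centres at least ``min_separation_px``
    apart and clear of the image border. Emits a warning (not an error) and
    returns the accepted subset if the field is too crowded."""
    margin = min_separation_px / 2.0 + 1.0
    placed: list[np.ndarray] = []
    for _ in range(n):
        ok = False
        for _t in range(max_tries):
            p = np.array(
                [
                    rng.uniform(margin, image_shape[1] - margin),
                    rng.uniform(margin, image_shape[0] - margin),
                ]
            )
            if all(np.hypot(*(p - q)) >= min_separation_px for q in placed):
                placed.append(p)
                ok = True
                break
        if not ok:
            warnings.warn(
                f"could only place {len(placed)}/{n} cells at separation "
                f"{min_separation_px:g}px; field too crowded",
                stacklevel=2,
            )
            break
    return np.array(placed) if placed else np.empty((0, 2))


def render_clone_image(
    population: pd.DataFrame,
    image_shape: tuple[int, int] = (512, 512),
    cell_radius_px: int = 6,
    noise_sd: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
    repack: bool = False,
    min_separation_px: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a population as a 3-channel 16-bit image plus a truth table.

    Cells are drawn as flat discs of their founder colour; a smooth constant
    background and per-pixel Gaussian noise are added on top. Channel order
    is fixed as (R, G, B) along the last axis. With ``repack=True`` cell
    centres are re-drawn with a minimum separation (default one diameter
    plus 3 px) instead of using the table's ``x``/``y`` columns.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    img = np.full((h, w, 3), float(background))
    if len(population) == 0:
        out = _finalise(img, noise_sd, rng)
        return out, population.copy()

    pop = population.copy().reset_index(drop=True)
    if repack:
        if min_separation_px is None:
            min_separation_px = 2 * cell_radius_px + 3
        centres = place_cells(len(pop), image_shape, min_separation_px, rng)
        pop = pop.iloc[: len(centres)].copy()
        pop["x"] = centres[:, 0]
        pop["y"] = centres[:, 1]
    else:
        occupancy = len(pop) * np.pi * cell_radius_px**2 / (h * w)
        if occupancy > 0.3:
            warnings.warn(
                f"disc occupancy {occupancy:.2f} exceeds packing limit 0.3; "
                "cells will overlap",
                stacklevel=2,
            )

    yy, xx = np.mgrid[-cell_radius_px : cell_radius_px + 1,
                      -cell_radius_px : cell_radius_px + 1]
    disc = (yy**2 + xx**2) <= cell_radius_px**2
    dy, dx = np.nonzero(disc)
    dy = dy - cell_radius_px
    dx = dx - cell_radius_px

    for row in pop.itertuples():
        cy, cx = int(round(row.y)), int(round(row.x))
        ys = np.clip(cy + dy, 0, h - 1)
        xs = np.clip(cx + dx, 0, w - 1)
        img[ys, xs, 0] = row.r
        img[ys, xs, 1] = row.g
        img[ys, xs, 2] = row.b

    out = _finalise(img, noise_sd, rng)
    truth = pop[["cell_id", "founder_id", "r", "g", "b", "x", "y"]].copy()
    return out, truth


def _finalise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
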