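"""Nuclear/cell size quantification and stable/enlarged gating.

Treated populations are gated against untreated controls: the gate is a
high quantile of the control nuclear-area distribution, so it depends on
the control only. Cells above the gate are ENLARGED (arrest/senescence-
associated), the rest STABLE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage import measure

from pulsefate.errors import ConfigurationError


def measure_areas(
    label_mask: np.ndarray,
    pixel_size: float,
    condition: str = "",
) -> pd.DataFrame:
    """One size record per labelled object: area = pixel count * pixel_size^2."""
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    rows = [
        (region.label, condition, region.area * pixel_size**2, "UNSET")
        for region in measure.regionprops(np.asarray(label_mask))
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "nuclear_area_um2", "gate"]
    )


def gate_stable_enlarged(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    control_quantile: float = 0.975,
) -> tuple[pd.DataFrame, dict]:
    """Gate treated cells into STABLE/ENLARGED using a control-derived cut.

    The threshold is the ``control_quantile`` of the control nuclear-area
    distribution; a treated cell is ENLARGED iff its area is strictly
    above it. Returns the gated records and a summary with the threshold,
    class fractions and the mean fold change of ENLARGED cells over the
    control mean.
    """
    if len(control) < 50:
        raise ConfigurationError(
            f"need >= 50 control records to set the gate, got {len(control)}"
        )
    if not 0 < control_quantile < 1:
        raise ConfigurationError("control_quantile must be in (0, 1)")
    ctrl = control["nuclear_area_um2"].to_numpy(dtype=float)
    thr = float(np.quantile(ctrl, control_quantile))
    out = treated.copy()
    areas = out["nuclear_area_um2"].to_numpy(dtype=float)
    out["gate"] = np.where(areas > thr, "ENLARGED", "STABLE")
    enlarged = areas[areas > thr]
    summary = {
        "threshold_um2": thr,
        "frac_enlarged": float((areas > thr).mean()),
        "frac_stable": float((areas <= thr).mean()),
        "n_treated": len(out),
        "n_control": len(control),
        "enlarged_fold_change": (
            float(enlarged.mean() / ctrl.mean()) if enlarged.size else np.nan
        ),
    }
    return out, summary


def fold_change(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Ratio of mean treated to mean control area with a bootstrap CI."""
    if len(treated) == 0 or len(control) == 0:
        raise ConfigurationError("both groups must be non-empty")
    t = treated["nuclear_area_um2"].to_numpy(dtype=float)
    c = control["nuclear_area_um2"].to_numpy(dtype=float)
    ratio = float(t.mean() / c.mean())
    if np.ptp(t) == 0 and np.ptp(c) == 0:
        warnings.warn(
            "zero-variance groups: bootstrap interval collapses to a point",
            stacklevel=2,
        )
        return {"ratio": ratio, "ci_low": ratio, "ci_high": ratio}
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = (
            t[rng.integers(0, len(t), len(t))].mean()
            / c[rng.integers(0, len(c), len(c))].mean()
        )
    alpha = (1.0 - ci) / 2.0
    return {
        "ratio": ratio,
        "ci_low": float(np.quantile(boots, alpha)),
        "ci_high": float(np.quantile(boots, 1.0 - alpha)),
    }
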