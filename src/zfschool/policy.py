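"""Occupancy-to-turn-direction policy and slope estimation.

A larva compares vertical retinal occupancy between its eyes and biases
its turn direction away from the more occupied side.  With per-object
occupancies ``v_i`` and weights ``w_i = v_i / sum(v)`` (the sum running
over both eyes) the probability to turn right is

    p(right) = 0.5 + sum_left w_i * bias(v_i) - sum_right w_i * bias(v_i)

clamped to [0, 1].  With the linear bias ``bias(v) = a * v`` this
reduces to

    p(right) = 0.5 + a * (sum_left v_i^2 - sum_right v_i^2) / sum(v)

i.e. the turn depends linearly on the difference between the eyes of the
occupancy-weighted average of squared vertical angles.  ``a`` is the
response slope (probability per degree); it is the quantity modulated by
the internal state (:func:`zfschool.state.effective_slope`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .retina import OccupancyProfile

__all__ = [
    "ResponseCurve",
    "TurnEvent",
    "eye_statistics",
    "p_turn_right",
    "p_turn_left",
    "estimate_slope",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Turning-bias response: linear slope or a tabulated bias curve.

    ``linear``: bias(v) = slope * v.  ``tabulated``: bias(v) is looked
    up (with linear interpolation) in ``(bias_v_deg, bias_values)``;
    biases must lie in [-0.5, 0.5].
    """

    form: Literal["linear", "tabulated"] = "linear"
    slope: float = 0.0104
    bias_v_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    bias_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        object.__setattr__(self, "bias_v_deg", np.asarray(self.bias_v_deg, dtype=float))
        object.__setattr__(self, "bias_values", np.asarray(self.bias_values, dtype=float))
        if self.form == "tabulated":
            if self.bias_v_deg.size == 0:
                raise ValueError("tabulated curve requires a bias table")
            if np.any(np.abs(self.bias_values) > 0.5 + 1e-12):
                raise ValueError("tabulated biases must lie in [-0.5, 0.5]")

    def bias(self, v_deg) -> np.ndarray:
        v = np.asarray(v_deg, dtype=float)
        if self.form == "linear":
            return self.slope * v
        return np.interp(v, self.bias_v_deg, self.bias_values)


@dataclass(frozen=True)
class TurnEvent:
    """A single bout with its occupancy context at onset.

    ``docc_deg`` is the (non-negative) difference between the more and
    less occupied eye of the weighted-average squared occupancy;
    ``turned_away`` marks whether the heading change pointed away from
    the more occupied eye; ``wall_dist_bl`` is the distance to the arena
    wall in body lengths at bout onset.
    """

    docc_deg: float
    turned_away: bool
    wall_dist_bl: float = np.inf

    def __post_init__(self):
        if self.docc_deg < 0:
            raise ValueError("docc_deg must be >= 0")


def eye_statistics(left: OccupancyProfile, right: OccupancyProfile) -> tuple[float, float, float]:
    """(sum v over both eyes, M_left, M_right) with M = sum v^2 / sum v."""
    vl = left.occupancy_deg
    vr = right.occupancy_deg
    total = float(vl.sum() + vr.sum())
    if total <= 0:
        return 0.0, 0.0, 0.0
    return total, float((vl**2).sum() / total), float((vr**2).sum() / total)


def p_turn_right(
    left: OccupancyProfile, right: OccupancyProfile, curve: ResponseCurve
) -> float:
    """Probability of a rightward turn given the two eyes' occupancy.

    Empty scenes are unbiased (0.5); the sum of weighted biases is
    clamped to [0, 1] after summation.
    """
    vl = left.occupancy_deg
    vr = right.occupancy_deg
    total = float(vl.sum() + vr.sum())
    if total <= 0:
        return 0.5
    p = 0.5 + float(
        (vl / total * curve.bias(vl)).sum() - (vr / total * curve.bias(vr)).sum()
    )
    return float(min(1.0, max(0.0, p)))


def p_turn_left(
    left: OccupancyProfile, right: OccupancyProfile, curve: ResponseCurve
) -> float:
    """Mirror of :func:`p_turn_right` (eyes swapped); the two sum to 1."""
    return 1.0 - p_turn_right(left, right, curve)


def estimate_slope(
    events,
    bin_width_deg: float = 5.0,
    wall_exclusion_bl: float = 1.25,
) -> tuple[ResponseCurve, pd.DataFrame]:
    """Estimate the linear response slope from binned turning events.

    ``events`` is a sequence of :class:`TurnEvent` or a DataFrame with
    columns ``docc_deg, turned_away, wall_dist_bl``.  Events closer than
    ``wall_exclusion_bl`` body lengths to the wall are discarded (wall
    avoidance would confound the social response).  Remaining events are
    binned by occupancy difference; the per-bin fraction turned away
    (with counts) is returned together with a least-squares fit through
    the origin of ``fraction - 0.5`` against bin-center occupancy,
    weighted by per-bin binomial counts.  The returned curve carries the
    fitted slope; its standard error is in ``table.attrs['slope_se']``.

    Raises ``ValueError`` when no analyzable events survive.
    """
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame(
            {
                "docc_deg": [e.docc_deg for e in events],
                "turned_away": [e.turned_away for e in events],
                "wall_dist_bl": [e.wall_dist_bl for e in events],
            }
        )
    df = df[np.isfinite(df["docc_deg"])]
    df = df[df["wall_dist_bl"] >= wall_exclusion_bl]
    if len(df) == 0:
        raise ValueError("no analyzable events")

    bins = np.arange(0.0, df["docc_deg"].max() + bin_width_deg, bin_width_deg)
    if bins.size < 2:
        bins = np.array([0.0, bin_width_deg])
    idx = np.digitize(df["docc_deg"].to_numpy(), bins) - 1
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        n = int(sel.sum())
        frac = float(df["turned_away"].to_numpy()[sel].mean())
        rows.append(
            {
                "bin_center_deg": 0.5 * (bins[b] + bins[b + 1]),
                "n_events": n,
                "p_turn_away": frac,
            }
        )
    table = pd.DataFrame(rows)

    x = table["bin_center_deg"].to_numpy()
    y = table["p_turn_away"].to_numpy() - 0.5
    w = table["n_events"].to_numpy().astype(float)
    denom = float((w * x * x).sum())
    if denom <= 0:
        raise ValueError("no analyzable events with nonzero occupancy difference")
    slope = float((w * x * y).sum() / denom)
    # binomial per-bin variance of the fraction, clipped away from 0/1
    p_hat = np.clip(table["p_turn_away"].to_numpy(), 1.0 / (2 * w), 1 - 1.0 / (2 * w))
    var_frac = p_hat * (1 - p_hat) / w
    slope_se = float(np.sqrt((w**2 * x**2 * var_frac).sum()) / denom)
    table.attrs["slope"] = slope
    table.attrs["slope_se"] = slope_se
    return ResponseCurve(form="linear", slope=slope), table
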