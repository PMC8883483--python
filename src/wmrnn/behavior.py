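"""Response decoding and trial scoring.

The network's "saccadic endpoint" is decoded from the ring of output units by
the population-vector method: the angle of the activity-weighted resultant of
the units' preferred-direction vectors.  A trial counts as correct only if the
fixation output stayed above 0.5 at every bin while the fixation input was on
AND the endpoint fell within 36 degrees of the required direction.  All angles
are degrees, counterclockwise from the positive x axis; signed differences are
wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rnn_core import ActivityRecord

CRITERION_DEG = 36.0      # "within 36 deg" read inclusively (<= 36)
RESPONSE_WINDOW_S = 0.2   # endpoint averages the final 200 ms of the response
GRACE_S = 0.1             # transition steps after go excluded from the hold check


def angular_diff(a, b):
    """Signed difference a - b wrapped to (-180, 180]; antisymmetric up to wrap."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if d.ndim == 0 else d


def population_vector(z: np.ndarray, directions_deg: np.ndarray) -> float:
    """Decoded direction: angle of sum_i z_i (cos th_i, sin th_i), in [0, 360).

    Raises if the resultant length is below 1e-9 (no decodable response).
    """
    z = np.asarray(z, dtype=float)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    x = float(np.sum(z * np.cos(th)))
    y = float(np.sum(z * np.sin(th)))
    if np.hypot(x, y) < 1e-9:
        raise ValueError("no response: population vector resultant is ~0")
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def score_record(record: ActivityRecord, criterion_deg: float = CRITERION_DEG,
                 window_s: float = RESPONSE_WINDOW_S,
                 grace_s: float = GRACE_S) -> pd.DataFrame:
    """Score every trial of an activity record into a behavior table.

    Columns: ``endpoint_deg`` (population-vector angle of the ring outputs
    averaged over the final ``window_s`` of the response epoch),
    ``deviation_deg`` (signed, endpoint minus required direction),
    ``fixation_held``, ``correct``, plus the trial metadata (task_id,
    cue_deg, delay_s, response_deg).  Requires ``meta`` columns ``go`` and
    ``t_end`` (step indices) as produced by the task generator.
    """
    meta = record.meta
    if "go" not in meta.columns:
        raise ValueError("record.meta must carry epoch bookkeeping (go, t_end)")
    n_ring = record.outputs.shape[2] - 1
    directions = np.arange(n_ring) * (360.0 / n_ring)
    win = max(1, int(round(window_s / record.dt_s)))

    rows = []
    for b in range(record.n_trials):
        m = meta.iloc[b]
        go, t_end = int(m["go"]), int(m["t_end"])
        if t_end <= go:
            raise ValueError(f"trial {b} has no response epoch")
        held = bool(np.all(record.outputs[:go, b, 0] > 0.5))
        w0 = max(go, t_end - win)
        z = record.outputs[w0:t_end, b, 1:].mean(axis=0)
        try:
            endpoint = population_vector(z, directions)
            dev = angular_diff(endpoint, m["response_deg"])
            no_response = False
        except ValueError:
            endpoint, dev, no_response = np.nan, np.nan, True
        correct = held and not no_response and abs(dev) <= criterion_deg
        rows.append({
            "endpoint_deg": endpoint, "deviation_deg": dev,
            "fixation_held": held, "correct": bool(correct),
            "task_id": m.get("task_id", ""), "cue_deg": m.get("cue_deg", np.nan),
            "delay_s": m.get("delay_s", np.nan),
            "response_deg": m.get("response_deg", np.nan),
        })
    return pd.DataFrame(rows)


def score_trial(record: ActivityRecord, trial: int, **kw) -> pd.Series:
    """Score a single trial of a record (see :func:`score_record`)."""
    sub = ActivityRecord(rates=record.rates[:, trial:trial + 1],
                         outputs=record.outputs[:, trial:trial + 1],
                         meta=record.meta.iloc[[trial]], dt_s=record.dt_s)
    return score_record(sub, **kw).iloc[0]


def endpoint_distribution(table: pd.DataFrame, split: str = "all",
                          bin_deg: float = 9.0, stage: str | None = None):
    """Histogram of signed endpoint deviations for a split of the table.

    ``split`` is "correct", "error" or "all".  Bins have ``bin_deg`` width
    (default 9 deg) and are centered on multiples of the width (0 at the bin
    center), covering (-180, 180].  Returns a DataFrame with bin centers,
    counts and proportions; an empty split yields an empty histogram with a
    warning.
    """
    if split == "correct":
        sel = table[table["correct"]]
    elif split == "error":
        sel = table[~table["correct"]]
    elif split == "all":
        sel = table
    else:
        raise ValueError("split must be 'correct', 'error' or 'all'")
    edges = np.arange(-180.0 - bin_deg / 2, 180.0 + bin_deg / 2 + 1e-9, bin_deg)
    dev = sel["deviation_deg"].dropna().to_numpy()
    counts, _ = np.histogram(dev, bins=edges)
    if len(sel) == 0:
        import warnings
        warnings.warn(f"endpoint_distribution: empty split '{split}'")
    out = pd.DataFrame({
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "count": counts,
        "proportion": counts / max(len(dev), 1),
    })
    if stage is not None:
        out["stage"] = stage
    return out
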