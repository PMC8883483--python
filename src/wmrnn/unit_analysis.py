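"""Unit-level statistics of recorded network activity.

Implements the analyses that diagnose a bump-attractor-like mechanism in a
trained network: PSTHs and baseline-normalized rates, selection of units with
elevated delay-period activity, spatial tuning and preferred-at-center
rotation, sorted population heatmaps, weight-structure diagonality, the
correlation between delay-rate deviations and signed saccade deviations, the
Fano factor of delay rates, and correct-versus-error rate contrasts.

All functions are pure functions of (ActivityRecord, behavior table, config):
repeated calls agree bitwise.  A drifting-bump surrogate generator with known
ground truth is provided for validating the analysis chain end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as _behavior
from .rnn_core import ActivityRecord

EPS = 1e-6                      # divide-by-zero guard (baseline, Fano mean)
CANONICAL = np.arange(8) * 45.0


def _epoch_cols(meta: pd.DataFrame, *cols):
    missing = [c for c in cols if c not in meta.columns]
    if missing:
        raise ValueError(f"record.meta lacks epoch columns {missing}")


def _window_mean(record: ActivityRecord, trial: int, t0: int, t1: int) -> np.ndarray:
    return record.rates[t0:t1, trial].mean(axis=0)


def delay_window(meta_row, dt_s: float, window_s: float | None = 1.0):
    """(start, stop) step indices of the delay analysis window for one trial.

    ``window_s=None`` means the entire delay; otherwise the last ``window_s``
    seconds of the delay (clipped to the delay onset).
    """
    d0, go = int(meta_row["delay_onset"]), int(meta_row["go"])
    if window_s is None:
        return d0, go
    w = int(round(window_s / dt_s))
    return max(d0, go - w), go


# ---------------------------------------------------------------------------
# PSTHs and normalization

def psth(record: ActivityRecord, unit: int,
         where: pd.Series | np.ndarray | None = None):
    """Trial-averaged rate of one unit, time-locked to cue onset.

    ``where`` is an optional boolean trial filter.  Returns (times_s, mean,
    n_trials) with time 0 at cue appearance.  Requires all selected trials to
    share the same epoch layout.
    """
    _epoch_cols(record.meta, "cue_onset")
    idx = np.arange(record.n_trials) if where is None \
        else np.flatnonzero(np.asarray(where))
    if len(idx) == 0:
        raise ValueError("no trials match the PSTH condition filter")
    onsets = record.meta.iloc[idx]["cue_onset"].to_numpy()
    if len(np.unique(onsets)) != 1:
        raise ValueError("PSTH requires a common cue onset across trials")
    mean = record.rates[:, idx, unit].mean(axis=1)
    times = (np.arange(record.rates.shape[0]) - onsets[0]) * record.dt_s
    return times, mean, len(idx)


def normalized_rate(trace: np.ndarray, baseline: float):
    """(rate - baseline) / baseline; requires baseline > EPS."""
    if baseline <= EPS:
        raise ValueError(f"baseline {baseline} below tolerance {EPS}")
    return (np.asarray(trace, dtype=float) - baseline) / baseline


def baseline_rates(record: ActivityRecord, baseline_s: float = 1.0) -> np.ndarray:
    """Per-unit mean rate in the ``baseline_s`` window before cue onset."""
    _epoch_cols(record.meta, "cue_onset")
    vals = []
    for b in range(record.n_trials):
        c0 = int(record.meta.iloc[b]["cue_onset"])
        t0 = max(0, c0 - int(round(baseline_s / record.dt_s)))
        vals.append(record.rates[t0:c0, b].mean(axis=0))
    return np.mean(vals, axis=0)


# ---------------------------------------------------------------------------
# Delay-unit selection and tuning

@dataclass
class UnitSelection:
    """Units with significantly elevated delay-period activity."""

    units: np.ndarray        # selected unit indices
    t: np.ndarray            # per-unit Welch t statistic (delay vs fixation)
    p: np.ndarray            # per-unit two-sided p value


def select_delay_units(record: ActivityRecord, alpha: float = 0.05,
                       window_s: float | None = None) -> UnitSelection:
    """Units whose delay-period rate is significantly elevated over fixation.

    Per unit, a Welch t-test compares per-trial mean rates in the delay epoch
    against the fixation epoch; a unit is selected iff the delay mean exceeds
    the fixation mean AND p < alpha.  Exactly equal samples (zero variance,
    zero difference) are never selected.
    """
    _epoch_cols(record.meta, "cue_onset", "delay_onset", "go")
    if record.n_trials < 2:
        raise ValueError("need >= 2 trials to select delay units")
    fix = np.stack([_window_mean(record, b, 0, int(record.meta.iloc[b]["cue_onset"]))
                    for b in range(record.n_trials)])
    dly = np.stack([_window_mean(record, b, *delay_window(record.meta.iloc[b],
                                                          record.dt_s, window_s))
                    for b in range(record.n_trials)])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(dly, fix, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    elevated = dly.mean(axis=0) > fix.mean(axis=0)
    selected = np.flatnonzero(elevated & (p < alpha))
    return UnitSelection(units=selected, t=t, p=p)


@dataclass
class TuningProfile:
    """Delay-period tuning of each unit over the 8 cue locations.

    ``rates`` is (units x locations) mean delay rate; ``preferred`` the argmax
    location index; ``rotated`` the same curves rolled so each unit's
    preferred location sits at the center index (n_loc // 2).
    """

    rates: np.ndarray
    preferred: np.ndarray
    rotated: np.ndarray
    locations: np.ndarray
    window_s: float | None

    @property
    def preferred_deg(self) -> np.ndarray:
        return self.locations[self.preferred]


def rotate_to_center(curve: np.ndarray, pref_idx: int) -> np.ndarray:
    """Roll a per-location curve so index ``pref_idx`` lands at the center."""
    n = len(curve)
    return np.roll(curve, n // 2 - pref_idx)


def tuning_profile(record: ActivityRecord, units: np.ndarray | None = None,
                   window_s: float | None = 1.0,
                   locations: np.ndarray = CANONICAL,
                   trials: np.ndarray | None = None) -> TuningProfile:
    """Mean delay-window rate per unit per cue location, with rotation."""
    _epoch_cols(record.meta, "cue_deg", "delay_onset", "go")
    n_units = record.rates.shape[2]
    units = np.arange(n_units) if units is None else np.asarray(units)
    tmask = np.ones(record.n_trials, bool) if trials is None \
        else np.asarray(trials, bool)
    rates = np.full((len(units), len(locations)), np.nan)
    cue = record.meta["cue_deg"].to_numpy()
    for j, loc in enumerate(locations):
        idx = np.flatnonzero(tmask & np.isclose(cue, loc))
        if len(idx) == 0:
            continue
        per_trial = np.stack([
            _window_mean(record, b, *delay_window(record.meta.iloc[b],
                                                  record.dt_s, window_s))
            for b in idx])
        rates[:, j] = per_trial[:, units].mean(axis=0)
    valid = np.isfinite(rates).any(axis=1)
    preferred = np.zeros(len(units), dtype=int)
    if valid.any():
        preferred[valid] = np.nanargmax(np.where(np.isfinite(rates[valid]),
                                                 rates[valid], -np.inf), axis=1)
    rotated = np.stack([rotate_to_center(rates[i], preferred[i])
                        for i in range(len(units))])
    return TuningProfile(rates=rates, preferred=preferred, rotated=rotated,
                         locations=np.asarray(locations, dtype=float),
                         window_s=window_s)


def heatmap_matrix(record: ActivityRecord, units: np.ndarray,
                   window_s: float | None = None) -> np.ndarray:
    """(units x time) matrix of preferred-location PSTHs, sorted and normalized.

    Each row is a unit's trial-averaged rate during presentation of its
    preferred stimulus, divided by its peak delay-period rate (row max over
    the delay <= 1); rows are ordered by ascending preferred location.
    """
    prof = tuning_profile(record, units, window_s)
    cue = record.meta["cue_deg"].to_numpy()
    m = record.meta.iloc[0]
    d0, go = int(m["delay_onset"]), int(m["go"])
    rows = []
    order = np.argsort(prof.preferred, kind="stable")
    for i in order:
        u = units[i]
        idx = np.flatnonzero(np.isclose(cue, prof.preferred_deg[i]))
        trace = record.rates[:, idx, u].mean(axis=1)
        peak = trace[d0:go].max() if go > d0 else trace.max()
        rows.append(trace / max(peak, EPS))
    return np.stack(rows)


# ---------------------------------------------------------------------------
# Behavior-rate correlation

@dataclass
class CorrelationResult:
    """Per-unit-per-location Pearson r between rate and saccade deviations.

    ``per_cell`` is (units x locations) in rotated coordinates (preferred
    location at the center column); NaN marks undefined cells.  ``curve`` is
    the across-unit mean per rotated location, ``mean_r`` the grand mean over
    defined cells, with a one-sample t-test of the cell values against 0.
    """

    per_cell: np.ndarray
    curve: np.ndarray
    offsets_deg: np.ndarray
    mean_r: float
    t: float
    p: float
    per_unit_mean: np.ndarray
    n_excluded: int


def _signed_saccade_deviation(endpoints: np.ndarray, cue: float,
                              preferred: float) -> np.ndarray:
    """Magnitude |endpoint - median endpoint|, signed + toward the preferred
    location, - away; exact ties -> NaN.

    The median endpoint is taken on deviations from the cue (already wrapped)
    and mapped back to an angle.
    """
    dev_from_cue = _behavior.angular_diff(endpoints, cue)
    med_ep = (cue + np.median(dev_from_cue)) % 360.0
    mag = np.abs(_behavior.angular_diff(endpoints, med_ep))
    d_now = np.abs(_behavior.angular_diff(endpoints, preferred))
    d_med = np.abs(_behavior.angular_diff(med_ep, preferred))
    sign = np.where(d_now < d_med, 1.0, np.where(d_now > d_med, -1.0, np.nan))
    return sign * mag


def rate_behavior_correlation(record: ActivityRecord, table: pd.DataFrame,
                              units: np.ndarray | None = None,
                              window_s: float = 1.0, min_trials: int = 8,
                              locations: np.ndarray = CANONICAL
                              ) -> CorrelationResult:
    """Pearson correlation between delay-rate and signed saccade deviations.

    Correct trials only.  Per unit and cue location: the rate deviation of a
    trial is its delay-window mean rate minus the median across same-cue
    trials; the saccade deviation is the absolute deviation of the endpoint
    from the per-cue median endpoint, signed positive when it moves the
    endpoint toward the unit's preferred location.  Cells with fewer than
    ``min_trials`` usable trials or zero variance are left undefined.
    """
    if units is None:
        units = np.arange(record.rates.shape[2])
    prof = tuning_profile(record, units, window_s,
                          trials=table["correct"].to_numpy())
    correct = table["correct"].to_numpy()
    cue = record.meta["cue_deg"].to_numpy()
    endpoints = table["endpoint_deg"].to_numpy()

    n_loc = len(locations)
    per_cell = np.full((len(units), n_loc), np.nan)
    n_excluded = 0
    loc_trials = {}
    for j, loc in enumerate(locations):
        idx = np.flatnonzero(correct & np.isclose(cue, loc))
        if len(idx) == 0:
            loc_trials[j] = (idx, None)
            continue
        w = np.stack([delay_window(record.meta.iloc[b], record.dt_s, window_s)
                      for b in idx])
        rates = np.stack([record.rates[w[k, 0]:w[k, 1], b].mean(axis=0)
                          for k, b in enumerate(idx)])  # trials x all_units
        loc_trials[j] = (idx, rates)

    for i, u in enumerate(units):
        pref = prof.preferred_deg[i]
        for j, loc in enumerate(locations):
            idx, rates = loc_trials[j]
            if rates is None or len(idx) < min_trials:
                n_excluded += 1
                continue
            r_dev = rates[:, u] - np.median(rates[:, u])
            s_dev = _signed_saccade_deviation(endpoints[idx], loc, pref)
            ok = np.isfinite(s_dev)
            if ok.sum() < min_trials:
                n_excluded += 1
                continue
            rd, sd = r_dev[ok], s_dev[ok]
            if rd.std() < 1e-12 or sd.std() < 1e-12:
                n_excluded += 1
                continue
            rot_j = (n_loc // 2 + j - prof.preferred[i]) % n_loc
            per_cell[i, rot_j] = stats.pearsonr(rd, sd).statistic

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(per_cell, axis=0)
        per_unit_mean = np.nanmean(per_cell, axis=1)
    cells = per_cell[np.isfinite(per_cell)]
    if len(cells) >= 2:
        tt = stats.ttest_1samp(cells, 0.0)
        t, p = float(tt.statistic), float(tt.pvalue)
    else:
        t, p = np.nan, np.nan
    offsets = (np.arange(n_loc) - n_loc // 2) * (360.0 / n_loc)
    return CorrelationResult(per_cell=per_cell, curve=curve, offsets_deg=offsets,
                             mean_r=float(cells.mean()) if len(cells) else np.nan,
                             t=t, p=p, per_unit_mean=per_unit_mean,
                             n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Fano factor

@dataclass
class FanoResult:
    """Per-unit-per-location Fano factor of delay-window rates (rotated)."""

    per_cell: np.ndarray     # units x locations, preferred at center column
    curve: np.ndarray        # across-unit mean per rotated location
    offsets_deg: np.ndarray
    mean_ff: float
    n_excluded: int


def fano_factor(record: ActivityRecord, table: pd.DataFrame,
                units: np.ndarray | None = None, n_trials: int = 16,
                window_s: float | None = 1.0,
                locations: np.ndarray = CANONICAL) -> FanoResult:
    """Fano factor (variance / mean, n-1 denominator) of per-trial delay rates.

    Computed over the first ``n_trials`` correct trials per cue location for
    each unit, then rotated so the preferred location sits at the curve's
    center.  Cells with mean below tolerance or fewer than 2 trials are
    undefined and counted in ``n_excluded``.
    """
    if units is None:
        units = np.arange(record.rates.shape[2])
    prof = tuning_profile(record, units, window_s,
                          trials=table["correct"].to_numpy())
    correct = table["correct"].to_numpy()
    cue = record.meta["cue_deg"].to_numpy()
    n_loc = len(locations)
    per_cell = np.full((len(units), n_loc), np.nan)
    n_excluded = 0
    for j, loc in enumerate(locations):
        idx = np.flatnonzero(correct & np.isclose(cue, loc))[:n_trials]
        if len(idx) < 2:
            n_excluded += len(units)
            continue
        rates = np.stack([
            _window_mean(record, b, *delay_window(record.meta.iloc[b],
                                                  record.dt_s, window_s))
            for b in idx])
        for i, u in enumerate(units):
            x = rates[:, u]
            mu = x.mean()
            if mu <= EPS:
                n_excluded += 1
                continue
            rot_j = (n_loc // 2 + j - prof.preferred[i]) % n_loc
            per_cell[i, rot_j] = x.var(ddof=1) / mu
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(per_cell, axis=0)
    cells = per_cell[np.isfinite(per_cell)]
    offsets = (np.arange(n_loc) - n_loc // 2) * (360.0 / n_loc)
    return FanoResult(per_cell=per_cell, curve=curve, offsets_deg=offsets,
                      mean_ff=float(cells.mean()) if len(cells) else np.nan,
                      n_excluded=n_excluded)


def anova_fano_by_location(per_cell: np.ndarray):
    """One-way ANOVA of Fano factor across rotated locations (units as obs).

    Returns (F, df_between, df_within, p).  Groups with fewer than 2 defined
    units are dropped; fewer than 2 usable groups is an error.  Identical
    constant groups yield F = 0, p = 1.
    """
    groups = [col[np.isfinite(col)] for col in per_cell.T]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 locations with >= 2 units each")
    grand = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_between <= 1e-300:
        dfb = len(groups) - 1
        dfw = len(grand) - len(groups)
        return 0.0, dfb, dfw, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), len(groups) - 1, len(grand) - len(groups), float(p)


# ---------------------------------------------------------------------------
# Correct vs error contrast

def welch_ttest(a: np.ndarray, b: np.ndarray):
    """Two-tailed Welch t-test; identical constant groups give t=0, p=1.

    Returns (t, df, p).  Antisymmetric in its arguments.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.var(ddof=0) < 1e-300 and b.var(ddof=0) < 1e-300:
        equal = np.isclose(a.mean(), b.mean())
        sign = np.sign(a.mean() - b.mean())
        return (0.0 if equal else sign * np.inf,
                len(a) + len(b) - 2, 1.0 if equal else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_correct_error(record: ActivityRecord, table: pd.DataFrame,
                          units: np.ndarray | None = None,
                          window_s: float = 1.0, pooled: tuple | None = None):
    """Delay rates at preferred locations: correct vs error trials.

    Each delay unit contributes its mean delay-window rate over correct
    trials at its preferred location (correct group) and likewise over error
    trials (error group); observations may be pooled across networks by
    passing previous (correct_obs, error_obs) arrays via ``pooled``.  Returns
    a dict with group means/sizes and a two-tailed Welch t-test (omitted when
    a group is empty).
    """
    if units is None:
        units = np.arange(record.rates.shape[2])
    prof = tuning_profile(record, units, window_s,
                          trials=table["correct"].to_numpy())
    cue = record.meta["cue_deg"].to_numpy()
    correct = table["correct"].to_numpy()
    c_obs, e_obs = [], []
    for i, u in enumerate(units):
        at_pref = np.isclose(cue, prof.preferred_deg[i])
        for flag, out in ((True, c_obs), (False, e_obs)):
            idx = np.flatnonzero(at_pref & (correct == flag))
            if len(idx) == 0:
                continue
            vals = [ _window_mean(record, b, *delay_window(
                        record.meta.iloc[b], record.dt_s, window_s))[u]
                     for b in idx]
            out.append(float(np.mean(vals)))
    if pooled is not None:
        c_obs = list(pooled[0]) + c_obs
        e_obs = list(pooled[1]) + e_obs
    res = {"mean_correct": float(np.mean(c_obs)) if c_obs else np.nan,
           "mean_error": float(np.mean(e_obs)) if e_obs else np.nan,
           "n_correct": len(c_obs), "n_error": len(e_obs),
           "correct_obs": np.asarray(c_obs), "error_obs": np.asarray(e_obs)}
    if c_obs and e_obs:
        t, df, p = welch_ttest(np.asarray(c_obs), np.asarray(e_obs))
        res.update(t=t, df=df, p=p)
    return res


# ---------------------------------------------------------------------------
# Weight structure

def weight_structure(params, preferred_deg: np.ndarray):
    """Sort weight matrices by preferred location and measure diagonality.

    Returns (sorted mats dict, statistic): the statistic is the mean
    recurrent weight over ordered unit pairs whose preferred locations differ
    by <= 45 deg (circular, excluding self-pairs) minus the mean over pairs
    differing by >= 135 deg.  Positive values mean similarly tuned units
    excite each other more -- the bump-attractor connectivity footprint.
    """
    preferred_deg = np.asarray(preferred_deg, dtype=float)
    order = np.argsort(preferred_deg, kind="stable")
    mats = {"W_in": params.W_in[order, :],
            "W_rec": params.W_rec[np.ix_(order, order)],
            "W_out": params.W_out[:, order]}
    dpref = np.abs(_behavior.angular_diff(preferred_deg[:, None],
                                          preferred_deg[None, :]))
    off_diag = ~np.eye(len(preferred_deg), dtype=bool)
    near = (dpref <= 45.0) & off_diag
    far = (dpref >= 135.0) & off_diag
    if near.sum() == 0 or far.sum() == 0:
        raise ValueError("preferred locations leave a pair class empty")
    stat = float(params.W_rec[near].mean() - params.W_rec[far].mean())
    return mats, stat


# ---------------------------------------------------------------------------
# Drifting-bump surrogate (ground-truth generator for the analysis chain)

def drifting_bump_surrogate(n_units: int = 64, trials_per_loc: int = 16,
                            drift_deg: float = 4.0, obs_noise: float = 0.02,
                            seed: int = 0, fix_steps: int = 50,
                            cue_steps: int = 25, delay_steps: int = 75,
                            resp_steps: int = 25, baseline: float = 0.2,
                            amplitude: float = 1.0, fwhm_deg: float = 90.0,
                            locations: np.ndarray = CANONICAL):
    """Synthetic recording from an idealized bump attractor with known drift.

    A bump centered on the cue performs a Gaussian random walk (per-step sd
    ``drift_deg``) through the delay; each unit's rate is its circular tuning
    curve evaluated at the bump position plus ``obs_noise`` white noise and a
    ``baseline`` offset; the behavioral endpoint is the bump position at the
    go signal.  With ``drift_deg=0`` the bump is frozen: the rate-behavior
    correlation and the location dependence of the Fano factor both vanish,
    which is the ablation the analysis tests rely on.

    Returns (ActivityRecord, behavior table).
    """
    rng = np.random.default_rng(seed)
    prefs = np.arange(n_units) * (360.0 / n_units)
    kappa = np.log(2.0) / (1.0 - np.cos(np.deg2rad(fwhm_deg / 2.0)))
    T = fix_steps + cue_steps + delay_steps + resp_steps
    go = fix_steps + cue_steps + delay_steps
    n_trials = len(locations) * trials_per_loc
    rates = np.empty((T, n_trials, n_units))
    meta_rows, beh_rows = [], []
    b = 0
    for loc in locations:
        for _ in range(trials_per_loc):
            pos = np.full(T, float(loc))
            steps = rng.standard_normal(delay_steps) * drift_deg
            pos[fix_steps + cue_steps:go] = loc + np.cumsum(steps)
            pos[go:] = pos[go - 1]
            drive = np.where(np.arange(T) < fix_steps, 0.0, amplitude)
            delta = np.deg2rad(prefs[None, :] - pos[:, None])
            rates[:, b] = baseline + drive[:, None] * \
                np.exp(kappa * (np.cos(delta) - 1.0))
            rates[:, b] += obs_noise * rng.standard_normal((T, n_units))
            np.maximum(rates[:, b], 0.0, out=rates[:, b])
            endpoint = pos[go - 1] % 360.0
            dev = _behavior.angular_diff(endpoint, loc)
            meta_rows.append(dict(task_id="surrogate", cue_deg=float(loc),
                                  delay_s=delay_steps * 0.02,
                                  response_deg=float(loc), cue_onset=fix_steps,
                                  delay_onset=fix_steps + cue_steps, go=go,
                                  t_end=T))
            beh_rows.append(dict(endpoint_deg=endpoint, deviation_deg=dev,
                                 fixation_held=True,
                                 correct=bool(abs(dev) <= 36.0),
                                 task_id="surrogate", cue_deg=float(loc),
                                 delay_s=delay_steps * 0.02,
                                 response_deg=float(loc)))
            b += 1
    meta = pd.DataFrame(meta_rows)
    record = ActivityRecord(rates=rates, outputs=np.zeros((T, n_trials, 1)),
                            meta=meta, dt_s=0.02)
    return record, pd.DataFrame(beh_rows)
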