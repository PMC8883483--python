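"""Trial generation for the spatial delayed-response task family.

Builds the three-dimensional input tensors (time x trials x input units) that
drive the recurrent network, together with target outputs and loss masks.
Input units are: one binary fixation unit, a ring of direction-tuned stimulus
units (8 by default, 360 for fine-grained simulations), and a one-hot task-rule
block.  The oculomotor delayed response (ODR) task presents a cue on the ring,
requires fixation through a memory delay, and rewards a response toward the
remembered location; the ODRD variant adds a to-be-ignored distractor inside
the delay; "anti" variants require a response opposite (180 deg) to the cue.

All randomness is drawn from caller-supplied numpy Generators; the generator
doubles as the synthetic-data fixture for the analysis code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

DT = 0.02
"""Simulation timestep in seconds (20 ms bins)."""

CANONICAL_ANGLES = np.arange(8) * 45.0
"""The eight cue locations, 45 deg apart on the ring."""

#: variable-delay training draws uniformly from 0 to 3 s in 0.1 s increments
VARIABLE_DELAYS = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)

# loss shaping (see docs/methods.md)
SIGMA_IN = 0.01          # additive Gaussian input noise, all channels
RESPONSE_WEIGHT = 5.0    # loss up-weighting of the response epoch
TARGET_BASELINE = 0.05   # ring-output target outside the response epoch
GRACE_S = 0.1            # post-go transition period excluded from the loss


def n_steps(duration_s: float, dt: float = DT) -> int:
    """Number of timesteps in ``duration_s``; rejects non-commensurate durations."""
    steps = duration_s / dt
    rounded = int(round(steps))
    if abs(steps - rounded) > 1e-9:
        raise ValueError(
            f"duration {duration_s} s is not an integer multiple of dt={dt} s"
        )
    return rounded


@dataclass(frozen=True)
class RingCode:
    """Direction code over a ring of uniformly spaced input (or output) units.

    ``tuning_width`` is the full width at half maximum, in degrees, of the
    circular (von Mises shaped) activation profile.  The default width puts
    roughly one third of the peak drive on the units adjacent to the cue on
    the 8-unit ring; ``tuning_width=0`` requests a one-hot code at the nearest
    preferred direction.
    """

    n_ring: int = 8
    tuning_width: float = 71.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.n_ring < 1:
            raise ValueError("n_ring must be >= 1")
        if self.tuning_width < 0:
            raise ValueError("tuning_width must be >= 0")

    @property
    def directions(self) -> np.ndarray:
        """Preferred directions in degrees, strictly increasing, spacing 360/n."""
        return np.arange(self.n_ring) * (360.0 / self.n_ring)

    @property
    def kappa(self) -> float:
        """Von Mises concentration implied by the half-maximum width."""
        if self.tuning_width == 0:
            return np.inf
        return np.log(2.0) / (1.0 - np.cos(np.deg2rad(self.tuning_width / 2.0)))

    def encode(self, angle_deg: float) -> np.ndarray:
        """Nonnegative activation profile peaking at the unit nearest ``angle_deg``."""
        if not (0.0 <= angle_deg < 360.0):
            raise ValueError(f"angle {angle_deg} outside [0, 360)")
        delta = np.deg2rad(self.directions - angle_deg)
        if np.isinf(self.kappa):
            # one-hot at the nearest preferred direction
            idx = int(np.argmin(np.abs(np.angle(np.exp(1j * delta)))))
            out = np.zeros(self.n_ring)
            out[idx] = self.amplitude
            return out
        return self.amplitude * np.exp(self.kappa * (np.cos(delta) - 1.0))


def encode_stimulus(angle_deg: float, ring: RingCode) -> np.ndarray:
    """Encode a direction as input-ring activation (see :meth:`RingCode.encode`)."""
    return ring.encode(angle_deg)


@dataclass(frozen=True)
class TaskSpec:
    """One task's epoch structure and response rule.

    Durations are in seconds and must be integer multiples of ``DT`` (the
    delay may be 0 for the zero-delay control tasks).  For ODRD-style tasks
    the distractor is placed strictly inside the delay, ``distractor_onset_s``
    after delay onset.
    """

    task_id: str
    rule_index: int
    fixation_s: float = 1.0
    cue_s: float = 0.5
    delay_s: float = 1.5
    response_s: float = 0.5
    response_mapping: str = "pro"          # "pro": toward cue; "anti": cue + 180
    distractor_onset_s: float | None = None
    distractor_s: float | None = None

    def __post_init__(self):
        for name in ("fixation_s", "cue_s", "response_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.response_mapping not in ("pro", "anti"):
            raise ValueError("response_mapping must be 'pro' or 'anti'")
        if (self.distractor_onset_s is None) != (self.distractor_s is None):
            raise ValueError("distractor onset and duration must be given together")
        if self.has_distractor:
            if not (0 < self.distractor_onset_s
                    and self.distractor_onset_s + self.distractor_s < self.delay_s):
                raise ValueError("distractor must fall strictly inside the delay")
        for name in ("fixation_s", "cue_s", "delay_s", "response_s",
                     "distractor_onset_s", "distractor_s"):
            v = getattr(self, name)
            if v is not None:
                n_steps(v)  # raises if not commensurate with DT

    @property
    def has_distractor(self) -> bool:
        return self.distractor_onset_s is not None

    def response_direction(self, cue_angle_deg: float) -> float:
        """Required response direction for a cue at ``cue_angle_deg``."""
        if self.response_mapping == "pro":
            return cue_angle_deg % 360.0
        return (cue_angle_deg + 180.0) % 360.0


def default_registry(delay_s: float = 1.5, odrd_delay_s: float = 3.0) -> list[TaskSpec]:
    """The six-task battery trained together by default.

    Delayed pro/anti response tasks with and without a distractor, plus two
    zero-delay control tasks (immediate pro- and anti-saccades).
    """
    return [
        TaskSpec("odr", 0, delay_s=delay_s),
        TaskSpec("odrd", 1, delay_s=odrd_delay_s,
                 distractor_onset_s=round(odrd_delay_s / 3 / DT) * DT,
                 distractor_s=0.5),
        TaskSpec("anti_odr", 2, delay_s=delay_s, response_mapping="anti"),
        TaskSpec("anti_odrd", 3, delay_s=odrd_delay_s, response_mapping="anti",
                 distractor_onset_s=round(odrd_delay_s / 3 / DT) * DT,
                 distractor_s=0.5),
        TaskSpec("pro_ctrl", 4, delay_s=0.0),
        TaskSpec("anti_ctrl", 5, delay_s=0.0, response_mapping="anti"),
    ]


def odr_registry(delay_s: float = 1.5) -> list[TaskSpec]:
    """Single-task registry: ODR only with a fixed delay."""
    return [TaskSpec("odr", 0, delay_s=delay_s)]


@dataclass
class TrialBatch:
    """A minibatch of trials as (time x trials x units) tensors.

    ``inputs`` holds 1 fixation + n_ring stimulus + n_rules rule channels;
    ``targets``/``mask`` hold 1 fixation output + n_ring response channels.
    ``meta`` is one row per trial with the epoch bookkeeping used by scoring
    and the unit analyses (all step indices refer to the batch time axis).
    Trials shorter than the longest trial in the batch are zero-padded at the
    end with zero mask.
    """

    inputs: np.ndarray
    targets: np.ndarray
    mask: np.ndarray
    meta: pd.DataFrame
    ring: RingCode
    dt: float = DT

    @property
    def n_trials(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("inputs", "targets", "mask"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["dt"] = self.dt
            f.attrs["n_ring"] = self.ring.n_ring
            f.attrs["tuning_width"] = self.ring.tuning_width
            f.attrs["amplitude"] = self.ring.amplitude
            g = f.create_group("meta")
            for col in self.meta.columns:
                vals = self.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)

    @classmethod
    def from_hdf5(cls, path) -> "TrialBatch":
        with h5py.File(path, "r") as f:
            ring = RingCode(int(f.attrs["n_ring"]), float(f.attrs["tuning_width"]),
                            float(f.attrs["amplitude"]))
            meta = {}
            for col, ds in f["meta"].items():
                vals = ds[...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                meta[col] = vals
            return cls(inputs=f["inputs"][...], targets=f["targets"][...],
                       mask=f["mask"][...], meta=pd.DataFrame(meta), ring=ring,
                       dt=float(f.attrs["dt"]))


_TEMPLATE_CACHE: dict = {}


def _trial_template(spec: TaskSpec, cue_angle: float, delay_s: float,
                    distractor_angle: float | None, ring: RingCode,
                    n_rules: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Noiseless single-trial inputs/targets/mask plus epoch bookkeeping.

    Templates are memoized on (spec, cue, delay, distractor, ring, n_rules) —
    batch sampling redraws only the noise, so the cache removes most of the
    per-trial construction cost.  Returned arrays are cached and must not be
    mutated; callers copy before writing.
    """
    key = (spec, float(cue_angle), float(delay_s),
           None if distractor_angle is None else float(distractor_angle),
           ring, n_rules)
    hit = _TEMPLATE_CACHE.get(key)
    if hit is not None:
        u, y, m, meta = hit
        return u, y, m, dict(meta)
    if len(_TEMPLATE_CACHE) > 4096:
        _TEMPLATE_CACHE.clear()
    out = _build_template(spec, cue_angle, delay_s, distractor_angle, ring,
                          n_rules)
    _TEMPLATE_CACHE[key] = out
    u, y, m, meta = out
    return u, y, m, dict(meta)


def _build_template(spec: TaskSpec, cue_angle: float, delay_s: float,
                    distractor_angle: float | None, ring: RingCode,
                    n_rules: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    F, C, D, R = (n_steps(spec.fixation_s), n_steps(spec.cue_s),
                  n_steps(delay_s), n_steps(spec.response_s))
    T = F + C + D + R
    go = F + C + D                      # fixation offset / go signal
    n_in = 1 + ring.n_ring + n_rules
    n_out = 1 + ring.n_ring

    u = np.zeros((T, n_in))
    u[:go, 0] = 1.0                     # fixation input on until go
    u[F:F + C, 1:1 + ring.n_ring] = ring.encode(cue_angle)
    if spec.has_distractor:
        if distractor_angle is None:
            raise ValueError(f"task {spec.task_id} requires a distractor angle")
        d0 = go if D == 0 else F + C + n_steps(spec.distractor_onset_s)
        d1 = d0 + n_steps(spec.distractor_s)
        u[d0:d1, 1:1 + ring.n_ring] = ring.encode(distractor_angle)
    elif distractor_angle is not None:
        raise ValueError(f"task {spec.task_id} has no distractor epoch")
    u[:, 1 + ring.n_ring + spec.rule_index] = 1.0

    resp_dir = spec.response_direction(cue_angle)
    y = np.full((T, n_out), TARGET_BASELINE)
    y[:, 0] = 0.0
    y[:go, 0] = 1.0                     # hold fixation output high until go
    bump = ring.encode(resp_dir) / max(ring.amplitude, 1e-12)   # peak 1
    y[go:, 1:] = bump

    m = np.ones((T, n_out))
    m[go:, :] = RESPONSE_WEIGHT
    grace = n_steps(GRACE_S)
    m[go:go + grace, :] = 0.0           # transition grace period

    meta = dict(task_id=spec.task_id, cue_deg=float(cue_angle),
                distractor_deg=np.nan if distractor_angle is None else float(distractor_angle),
                delay_s=float(delay_s), response_deg=float(resp_dir),
                cue_onset=F, delay_onset=F + C, go=go, t_end=T)
    return u, y, m, meta


def build_trial(spec: TaskSpec, cue_angle: float, delay_s: float | None = None,
                distractor_angle: float | None = None,
                rng: np.random.Generator | None = None,
                ring: RingCode | None = None, n_rules: int = 1,
                sigma_in: float = SIGMA_IN):
    """Build a single noisy trial.

    Returns ``(inputs, targets, mask, meta)`` with time-major arrays.  Noise is
    additive Gaussian (sd ``sigma_in``) on every input channel and timestep;
    pass ``rng=None`` only for a noiseless template (``sigma_in`` ignored).
    """
    ring = ring or RingCode()
    if delay_s is None:
        delay_s = spec.delay_s
    u, y, m, meta = _trial_template(spec, cue_angle, delay_s, distractor_angle,
                                    ring, n_rules)
    if rng is not None and sigma_in > 0:
        u = u + sigma_in * rng.standard_normal(u.shape)
    else:
        u = u.copy()
    return u, y.copy(), m.copy(), meta


def sample_batch(registry: list[TaskSpec], batch_size: int,
                 rng: np.random.Generator, delay_mode: str = "fixed",
                 ring: RingCode | None = None, stratify: bool = True,
                 cue_angles: np.ndarray | None = None,
                 sigma_in: float = SIGMA_IN) -> TrialBatch:
    """Sample a minibatch with tasks interleaved and cue angles drawn uniformly.

    In ``delay_mode="variable"`` each trial's delay is drawn uniformly from
    the 31 admissible values 0.0, 0.1, ..., 3.0 s; in ``"fixed"`` mode each
    task's own delay is used.  With ``stratify=True`` every task in the
    registry appears in every batch (requires ``batch_size >= len(registry)``).
    """
    if not registry:
        raise ValueError("registry must be nonempty")
    if delay_mode not in ("fixed", "variable"):
        raise ValueError("delay_mode must be 'fixed' or 'variable'")
    if stratify and batch_size < len(registry):
        raise ValueError("batch_size must be >= number of tasks for stratified sampling")
    ring = ring or RingCode()
    if cue_angles is None:
        cue_angles = CANONICAL_ANGLES
    n_rules = len(registry)

    if stratify:
        task_idx = np.arange(batch_size) % len(registry)
        rng.shuffle(task_idx)
    else:
        task_idx = rng.integers(0, len(registry), size=batch_size)

    trials = []
    for i in range(batch_size):
        spec = registry[task_idx[i]]
        cue = float(rng.choice(cue_angles))
        delay = float(rng.choice(VARIABLE_DELAYS)) if delay_mode == "variable" \
            else spec.delay_s
        # variable delays too short to contain the distractor window drop it
        if spec.has_distractor and \
                delay > spec.distractor_onset_s + spec.distractor_s:
            others = cue_angles[~np.isclose(cue_angles, cue)]
            distr = float(rng.choice(others)) if len(others) else cue
            u, y, m, meta = build_trial(spec, cue, delay, distr, rng, ring,
                                        n_rules, sigma_in)
        else:
            plain = dataclasses.replace(spec, distractor_onset_s=None,
                                        distractor_s=None) \
                if spec.has_distractor else spec
            u, y, m, meta = build_trial(plain, cue, delay, None, rng, ring,
                                        n_rules, sigma_in)
            meta["task_id"] = spec.task_id
        trials.append((u, y, m, meta))

    T = max(t[0].shape[0] for t in trials)
    n_in = trials[0][0].shape[1]
    n_out = trials[0][1].shape[1]
    B = batch_size
    inputs = np.zeros((T, B, n_in))
    targets = np.zeros((T, B, n_out))
    mask = np.zeros((T, B, n_out))
    for b, (u, y, m, meta) in enumerate(trials):
        t = u.shape[0]
        inputs[:t, b] = u
        targets[:t, b] = y
        mask[:t, b] = m
    meta = pd.DataFrame([t[3] for t in trials])
    return TrialBatch(inputs=inputs, targets=targets, mask=mask, meta=meta,
                      ring=ring)


def analysis_batch(spec: TaskSpec, trials_per_location: int,
                   rng: np.random.Generator, ring: RingCode | None = None,
                   n_rules: int = 1, cue_angles: np.ndarray | None = None,
                   sigma_in: float = SIGMA_IN) -> TrialBatch:
    """A balanced batch: ``trials_per_location`` repeats of every cue location.

    Used for the unit-level analyses, which need matched trial counts per
    stimulus condition.
    """
    ring = ring or RingCode()
    if cue_angles is None:
        cue_angles = CANONICAL_ANGLES
    trials = []
    for cue in cue_angles:
        for _ in range(trials_per_location):
            distr = None
            if spec.has_distractor:
                others = cue_angles[~np.isclose(cue_angles, cue)]
                distr = float(rng.choice(others))
            trials.append(build_trial(spec, float(cue), None, distr, rng, ring,
                                      n_rules, sigma_in))
    T = trials[0][0].shape[0]
    inputs = np.stack([t[0] for t in trials], axis=1)
    targets = np.stack([t[1] for t in trials], axis=1)
    mask = np.stack([t[2] for t in trials], axis=1)
    meta = pd.DataFrame([t[3] for t in trials])
    return TrialBatch(inputs=inputs, targets=targets, mask=mask, meta=meta,
                      ring=ring)


# ---------------------------------------------------------------------------
# YAML configuration

def registry_from_config(cfg: dict) -> tuple[list[TaskSpec], RingCode]:
    """Build a task registry and ring code from a parsed YAML mapping.

    Expected layout::

        ring: {n_ring: 8, tuning_width: 71.0, amplitude: 1.0}
        tasks:
          - {task_id: odr, rule_index: 0, delay_s: 1.5, response_mapping: pro}
    """
    ring = RingCode(**cfg.get("ring", {}))
    tasks = [TaskSpec(**t) for t in cfg["tasks"]]
    idx = [t.rule_index for t in tasks]
    if len(set(idx)) != len(idx):
        raise ValueError("rule_index values must be unique within a registry")
    return tasks, ring


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
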