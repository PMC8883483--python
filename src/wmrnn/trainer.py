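"""Supervised training of the recurrent network on task minibatches.

The loss is a masked mean squared error between the logistic outputs and the
target sequences; gradients are obtained by full backpropagation through the
unrolled Euler dynamics (no truncation; trials are at most a few hundred
steps) and applied with Adam.  The reverse pass is written out in closed form:
for the update r_t = (1-a) r_{t-1} + a f(q_t), q_t = W_rec r_{t-1} + W_in u_t
+ b + noise, the adjoint satisfies

    dL/dr_{t-1} = (1-a) dL/dr_t + (a f'(q_t) dL/dr_t) W_rec + (readout term),

with f' the logistic function.  Training performance bands follow the staging
convention: early (<35%), mid-trained [35, 65), mature [65, 95), fully
trained (>= 95%).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.special import expit

from . import behavior, task_suite
from .rnn_core import NetworkParams, init_params, softplus
from .task_suite import RingCode, TaskSpec

WEIGHT_KEYS = ("W_in", "W_rec", "W_out", "b")

STAGES = ("early", "mid-trained", "mature", "fully-trained")


def classify_stage(percent_correct: float) -> str:
    """Map overall percent correct to the training-stage label.

    Bands are half-open and partition [0, 100]: early < 35, mid-trained
    [35, 65), mature [65, 95), fully trained >= 95.
    """
    p = float(percent_correct)
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"percent correct {p} outside [0, 100]")
    if p < 35.0:
        return "early"
    if p < 65.0:
        return "mid-trained"
    if p < 95.0:
        return "mature"
    return "fully-trained"


def loss(outputs: np.ndarray, targets: np.ndarray, mask: np.ndarray) -> float:
    """Masked mean squared error: sum(mask (z - y)^2) / sum(mask)."""
    if outputs.shape != targets.shape or outputs.shape != mask.shape:
        raise ValueError("outputs, targets and mask must share a shape")
    total = mask.sum()
    if total <= 0:
        raise ValueError("mask must have positive total weight")
    return float((mask * (outputs - targets) ** 2).sum() / total)


@dataclass
class TrainConfig:
    """Hyperparameters of a training run (defaults follow the study setup)."""

    n_rec: int = 256
    eta: float = 1e-3            # Adam learning rate
    batch_size: int = 64
    max_steps: int = 3000
    eval_every: int = 100
    eval_trials: int = 80        # trials per task per evaluation
    delay_mode: str = "fixed"
    seed: int = 0
    sigma_in: float = task_suite.SIGMA_IN
    sigma_rec: float = 0.05
    grad_clip: float = 1.0       # global-norm clip
    stop_at: float = 95.0        # halt once fully trained; None to disable

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")


# ---------------------------------------------------------------------------
# Adam

def adam_init(params: NetworkParams) -> dict:
    state = {"t": 0}
    for k in WEIGHT_KEYS:
        state["m_" + k] = np.zeros_like(getattr(params, k))
        state["v_" + k] = np.zeros_like(getattr(params, k))
    return state


def adam_update(params: NetworkParams, grads: dict, state: dict,
                eta: float, beta1: float = 0.9, beta2: float = 0.999,
                eps: float = 1e-8) -> None:
    """In-place Adam step with standard bias correction."""
    state["t"] += 1
    t = state["t"]
    for k in WEIGHT_KEYS:
        g = grads[k]
        state["m_" + k] = beta1 * state["m_" + k] + (1 - beta1) * g
        state["v_" + k] = beta2 * state["v_" + k] + (1 - beta2) * g * g
        mhat = state["m_" + k] / (1 - beta1 ** t)
        vhat = state["v_" + k] / (1 - beta2 ** t)
        getattr(params, k)[...] -= eta * mhat / (np.sqrt(vhat) + eps)


def global_norm(grads: dict) -> float:
    return float(np.sqrt(sum(float((g ** 2).sum()) for g in grads.values())))


def clip_grads(grads: dict, max_norm: float) -> bool:
    """Scale gradients to ``max_norm`` if their global norm exceeds it."""
    norm = global_norm(grads)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for g in grads.values():
            g *= scale
        return True
    return False


# ---------------------------------------------------------------------------
# Backpropagation through time

def _softplus_inplace(q: np.ndarray, out: np.ndarray) -> None:
    """out = log(1 + e^q), overflow-safe in float32: max(q,0) + log1p(e^-|q|)."""
    np.abs(q, out=out)
    np.negative(out, out=out)
    np.exp(out, out=out)
    np.log1p(out, out=out)
    out += np.maximum(q, 0.0)


def bptt(params: NetworkParams, inputs: np.ndarray, targets: np.ndarray,
         mask: np.ndarray, rng: np.random.Generator | None,
         dtype=np.float32):
    """Forward simulate one batch and return (loss, gradients).

    ``inputs`` is (T x B x n_in); recurrent noise is drawn from ``rng`` during
    the forward pass and treated as a constant in the reverse pass.  The
    unrolled pass runs in ``dtype`` (single precision by default -- gradient
    quantities are O(1) and Adam normalizes per-parameter scale, so float32
    round-off is far below the recurrent noise floor); the master weights
    stay float64.
    """
    T, B, _ = inputs.shape
    N = params.n_rec
    a = dtype(params.alpha)
    one_a = dtype(1.0 - params.alpha)
    W_rec = params.W_rec.astype(dtype)
    W_in = params.W_in.astype(dtype)
    W_out = params.W_out.astype(dtype)
    inputs = inputs.astype(dtype)
    targets = targets.astype(dtype)
    mask = mask.astype(dtype)

    # input projections and noise hoisted out of the recurrence
    ext = inputs.reshape(T * B, -1) @ W_in.T
    ext += params.b.astype(dtype)
    if rng is not None and params.sigma_rec > 0:
        noise = rng.standard_normal(ext.shape, dtype=dtype)
        noise *= dtype(params.noise_scale)
        ext += noise
    ext = ext.reshape(T, B, N)

    R = np.empty((T, B, N), dtype)            # post-update state r_t
    S = np.empty((T, B, N), dtype)            # f'(q_t) = logistic(q_t)
    sp = np.empty((B, N), dtype)
    r = np.zeros((B, N), dtype)
    for t in range(T):
        q = r @ W_rec.T
        q += ext[t]
        S[t] = expit(q)
        _softplus_inplace(q, sp)
        r *= one_a
        r += a * sp
        R[t] = r
    Z = expit(R.reshape(T * B, N) @ W_out.T).reshape(T, B, -1)

    M = mask.sum()
    if M <= 0:
        raise ValueError("mask must have positive total weight")
    diff = Z - targets
    L = float((mask * diff ** 2).sum() / M)

    # readout adjoints for every step at once
    dq_out = dtype(2.0 / M) * mask * diff * Z * (dtype(1.0) - Z)
    dr_out = (dq_out.reshape(T * B, -1) @ W_out).reshape(T, B, N)
    dW_out = dq_out.reshape(T * B, -1).T @ R.reshape(T * B, N)

    DA = np.empty((T, B, N), dtype)           # a f'(q_t) dL/dr_t per step
    carry = np.zeros((B, N), dtype)
    for t in range(T - 1, -1, -1):
        dr = dr_out[t] + carry
        da = dr * S[t]
        da *= a
        DA[t] = da
        carry = one_a * dr + da @ W_rec
    flatDA = DA.reshape(T * B, N)
    dW_rec = flatDA[B:].T @ R.reshape(T * B, N)[:-B]   # pairs (da_t, r_{t-1})
    dW_in = flatDA.T @ inputs.reshape(T * B, -1)
    db = flatDA.sum(axis=0)
    grads = {"W_in": dW_in.astype(float), "W_rec": dW_rec.astype(float),
             "W_out": dW_out.astype(float), "b": db.astype(float)}
    return L, grads


def train_step(params: NetworkParams, batch, opt_state: dict,
               rng: np.random.Generator | None, eta: float,
               grad_clip: float = 1.0):
    """One optimization step; returns (loss, clipped?, skipped?).

    A non-finite gradient skips the parameter update (counted by the caller);
    parameters always stay finite.
    """
    L, grads = bptt(params, batch.inputs, batch.targets, batch.mask, rng)
    if not all(np.all(np.isfinite(g)) for g in grads.values()):
        return L, False, True
    clipped = clip_grads(grads, grad_clip)
    adam_update(params, grads, opt_state, eta)
    return L, clipped, False


# ---------------------------------------------------------------------------
# Evaluation

def evaluate(params: NetworkParams, registry: list[TaskSpec], n_trials: int,
             rng: np.random.Generator, ring: RingCode | None = None,
             sigma_in: float = task_suite.SIGMA_IN) -> dict:
    """Percent correct per task and overall on freshly sampled trials.

    ``n_trials`` is per task; scoring uses the population-vector endpoint and
    the fixation-hold + 36-degree window criterion.  Deterministic given the
    generator's seed; invariant to trial order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ring = ring or RingCode()
    per_task = {}
    total = correct = 0
    for spec in registry:
        batch = task_suite.sample_batch([spec], n_trials, rng,
                                        delay_mode="fixed", ring=ring,
                                        stratify=False, sigma_in=sigma_in)
        # rule block must span the full registry regardless of the task sampled
        batch = _with_rule_block(batch, spec, len(registry), ring)
        from .rnn_core import run_batch
        rec = run_batch(params, batch.inputs, rng, batch.meta)
        table = behavior.score_record(rec)
        per_task[spec.task_id] = 100.0 * table["correct"].mean()
        total += len(table)
        correct += int(table["correct"].sum())
    per_task["overall"] = 100.0 * correct / total
    return per_task


def _with_rule_block(batch, spec: TaskSpec, n_rules: int, ring: RingCode):
    """Re-embed a single-task batch's rule unit into the full rule block."""
    have = batch.inputs.shape[2]
    want = 1 + ring.n_ring + n_rules
    if have == want:
        return batch
    T, B, _ = batch.inputs.shape
    inputs = np.zeros((T, B, want))
    inputs[:, :, :1 + ring.n_ring] = batch.inputs[:, :, :1 + ring.n_ring]
    rule_col = batch.inputs[:, :, 1 + ring.n_ring]
    inputs[:, :, 1 + ring.n_ring + spec.rule_index] = rule_col
    batch.inputs = inputs
    return batch


# ---------------------------------------------------------------------------
# Checkpointing

def checkpoint(params: NetworkParams, opt_state: dict, record: pd.DataFrame,
               path, step: int = 0, seed: int = 0) -> None:
    """Save weights, Adam moments, and the training record to HDF5."""
    with h5py.File(path, "w") as f:
        params.write_group(f.create_group("params"))
        g = f.create_group("adam")
        g.attrs["t"] = opt_state["t"]
        for k in WEIGHT_KEYS:
            g.create_dataset("m_" + k, data=opt_state["m_" + k])
            g.create_dataset("v_" + k, data=opt_state["v_" + k])
        f.attrs["step"] = step
        f.attrs["seed"] = seed
        rg = f.create_group("record")
        for col in record.columns:
            vals = record[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            rg.create_dataset(col, data=vals)


def restore(path):
    """Load a checkpoint; returns (params, opt_state, record, step, seed)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"checkpoint not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            params = NetworkParams.read_group(f["params"])
            g = f["adam"]
            opt_state = {"t": int(g.attrs["t"])}
            for k in WEIGHT_KEYS:
                opt_state["m_" + k] = g["m_" + k][...]
                opt_state["v_" + k] = g["v_" + k][...]
            cols = {}
            for col, ds in f["record"].items():
                vals = ds[...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            record = pd.DataFrame(cols)
            return params, opt_state, record, int(f.attrs["step"]), int(f.attrs["seed"])
    except OSError as e:
        raise OSError(f"corrupt or unreadable checkpoint {path}: {e}") from None


# ---------------------------------------------------------------------------
# Training loop

@dataclass
class TrainResult:
    params: NetworkParams
    record: pd.DataFrame
    snapshots: dict          # stage label -> NetworkParams at first entry
    skipped_updates: int
    converged: bool


def _rng(seed: int, tag: int, idx: int = 0) -> np.random.Generator:
    """Named substream: deterministic child generator of the master seed."""
    return np.random.default_rng([seed, tag, idx])


def train(cfg: TrainConfig, registry: list[TaskSpec] | None = None,
          ring: RingCode | None = None,
          params: NetworkParams | None = None,
          opt_state: dict | None = None, start_step: int = 0) -> TrainResult:
    """Train a network on the registry's tasks until fully trained or budget.

    Evaluation runs every ``eval_every`` updates on fresh seeded trials; the
    first time each performance stage is reached the weights are snapshotted.
    Resuming from a checkpoint (``params``/``opt_state``/``start_step``)
    reproduces the uninterrupted run exactly, because every update draws from
    a substream keyed by (seed, step index).
    """
    registry = registry if registry is not None else task_suite.odr_registry()
    ring = ring or RingCode()
    n_in = 1 + ring.n_ring + len(registry)
    n_out = 1 + ring.n_ring
    if params is None:
        params = init_params(n_in, cfg.n_rec, n_out, _rng(cfg.seed, 0),
                             sigma_rec=cfg.sigma_rec)
        opt_state = adam_init(params)

    rows = []
    snapshots = {}
    skipped = 0
    last_loss = np.nan
    converged = False
    step_i = start_step
    while True:
        if step_i % cfg.eval_every == 0 or step_i >= cfg.max_steps:
            perf = evaluate(params, registry, cfg.eval_trials,
                            _rng(cfg.seed, 2, step_i), ring,
                            sigma_in=cfg.sigma_in)
            stage = classify_stage(perf["overall"])
            if stage not in snapshots:
                snapshots[stage] = params.copy()
            row = {"step": step_i, "loss": last_loss, "stage": stage,
                   "percent_correct": perf["overall"]}
            row.update({f"pct_{k}": v for k, v in perf.items() if k != "overall"})
            rows.append(row)
            if cfg.stop_at is not None and perf["overall"] >= cfg.stop_at:
                converged = True
                break
            if step_i >= cfg.max_steps:
                break
        rng = _rng(cfg.seed, 1, step_i)
        batch = task_suite.sample_batch(registry, cfg.batch_size, rng,
                                        cfg.delay_mode, ring,
                                        sigma_in=cfg.sigma_in)
        last_loss, _, was_skipped = train_step(params, batch, opt_state, rng,
                                               cfg.eta, cfg.grad_clip)
        skipped += int(was_skipped)
        step_i += 1

    record = pd.DataFrame(rows)
    return TrainResult(params=params, record=record, snapshots=snapshots,
                       skipped_updates=skipped, converged=converged)
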