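"""Leaky rate-network dynamics: nonlinearities, initialization, simulation.

The network integrates

    tau dr/dt = -r + f(W_rec r + W_in u + b + sqrt(2 tau sigma_rec^2) xi)

by forward Euler with step ``dt`` (alpha = dt/tau), where f is the Softplus
nonlinearity, xi is unit-variance white noise per recurrent unit, and the
output layer reads z = g(W_out r) through the logistic function g.  With
alpha in (0, 1] the update is a convex combination of the previous state and
a positive function value, so activity stays nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.special import expit as logistic  # g(x) = 1 / (1 + e^-x)
from scipy.stats import ortho_group


def softplus(x):
    """f(x) = log(1 + e^x), overflow-safe for large |x|."""
    return np.logaddexp(0.0, x)


def softplus_deriv(x):
    """f'(x) = logistic(x)."""
    return logistic(x)


@dataclass
class NetworkParams:
    """All trainable weights plus the fixed dynamics constants.

    Weight shapes: ``W_in`` (n_rec x n_in), ``W_rec`` (n_rec x n_rec),
    ``W_out`` (n_out x n_rec), ``b`` (n_rec,).  ``tau`` and ``dt`` are in
    milliseconds; ``sigma_rec`` scales the recurrent noise.
    """

    W_in: np.ndarray
    W_rec: np.ndarray
    W_out: np.ndarray
    b: np.ndarray
    tau: float = 100.0
    dt: float = 20.0
    sigma_rec: float = 0.05

    def __post_init__(self):
        if self.tau <= 0 or not (0 < self.dt <= self.tau):
            raise ValueError("require tau > 0 and 0 < dt <= tau")
        for name in ("W_in", "W_rec", "W_out", "b"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    @property
    def n_rec(self) -> int:
        return self.W_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.W_out.shape[0]

    @property
    def noise_scale(self) -> float:
        """Pre-activation noise sd per step: sigma_rec * sqrt(2 / alpha)."""
        return self.sigma_rec * np.sqrt(2.0 / self.alpha)

    def copy(self) -> "NetworkParams":
        return replace(self, W_in=self.W_in.copy(), W_rec=self.W_rec.copy(),
                       W_out=self.W_out.copy(), b=self.b.copy())

    # -- HDF5 round trip (bit-exact) ------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            self.write_group(f)

    def write_group(self, g) -> None:
        for name in ("W_in", "W_rec", "W_out", "b"):
            g.create_dataset(name, data=getattr(self, name))
        g.attrs["tau"] = self.tau
        g.attrs["dt"] = self.dt
        g.attrs["sigma_rec"] = self.sigma_rec

    @classmethod
    def from_hdf5(cls, path) -> "NetworkParams":
        with h5py.File(path, "r") as f:
            return cls.read_group(f)

    @classmethod
    def read_group(cls, g) -> "NetworkParams":
        return cls(W_in=g["W_in"][...], W_rec=g["W_rec"][...],
                   W_out=g["W_out"][...], b=g["b"][...],
                   tau=float(g.attrs["tau"]), dt=float(g.attrs["dt"]),
                   sigma_rec=float(g.attrs["sigma_rec"]))


def init_params(n_in: int, n_rec: int, n_out: int,
                rng: np.random.Generator, tau: float = 100.0, dt: float = 20.0,
                sigma_rec: float = 0.05) -> NetworkParams:
    """Standard initialization: orthogonal W_rec, N(0,1)/sqrt(n_in) W_in,
    Glorot-uniform W_out, zero background input.

    Weights are unconstrained in sign.  All draws come from ``rng``.
    """
    if rng is None:
        raise ValueError("an explicitly seeded Generator is required")
    if min(n_in, n_rec, n_out) < 1:
        raise ValueError("all unit counts must be >= 1")
    W_rec = ortho_group.rvs(n_rec, random_state=rng) if n_rec > 1 \
        else np.ones((1, 1))
    W_in = rng.standard_normal((n_rec, n_in)) / np.sqrt(n_in)
    bound = np.sqrt(6.0 / (n_rec + n_out))
    W_out = rng.uniform(-bound, bound, size=(n_out, n_rec))
    return NetworkParams(W_in=W_in, W_rec=W_rec, W_out=W_out,
                         b=np.zeros(n_rec), tau=tau, dt=dt, sigma_rec=sigma_rec)


@dataclass
class ActivityRecord:
    """Recurrent-unit rates and outputs sampled every ``dt`` bin.

    ``rates`` is (time x trials x n_rec), ``outputs`` (time x trials x n_out);
    ``meta`` is the per-trial frame copied from the driving TrialBatch (epoch
    step indices ``cue_onset``, ``delay_onset``, ``go``, ``t_end``).
    """

    rates: np.ndarray
    outputs: np.ndarray
    meta: pd.DataFrame
    dt_s: float = 0.02

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]


def step(r: np.ndarray, u_t: np.ndarray, params: NetworkParams,
         rng: np.random.Generator | None = None) -> np.ndarray:
    """One Euler step of the dynamics; ``r`` and ``u_t`` may be batched.

    With ``rng=None`` (or sigma_rec == 0) the update is deterministic.
    """
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite network state")
    a = params.alpha
    pre = r @ params.W_rec.T + u_t @ params.W_in.T + params.b
    if rng is not None and params.sigma_rec > 0:
        pre = pre + params.noise_scale * rng.standard_normal(pre.shape)
    return (1.0 - a) * r + a * softplus(pre)


def readout(r: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Output activations z = g(W_out r), each in (0, 1)."""
    return logistic(r @ params.W_out.T)


def run_batch(params: NetworkParams, inputs: np.ndarray,
              rng: np.random.Generator | None,
              meta: pd.DataFrame | None = None,
              r0: np.ndarray | None = None) -> ActivityRecord:
    """Simulate a batch of trials, recording rates and outputs at every bin.

    ``inputs`` is (time x trials x n_in).  The forward pass is a pure function
    of (params, inputs, rng state): identical seeds give bitwise-identical
    records.  Non-finite states halt with the offending timestep reported.
    """
    T, B, _ = inputs.shape
    N = params.n_rec
    r = np.zeros((B, N)) if r0 is None else np.array(r0, dtype=float)
    if r.ndim == 1:
        r = np.broadcast_to(r, (B, N)).copy()
    a = params.alpha
    # input projection and noise hoisted out of the recurrence (identical
    # math to step(); one noise draw per unit and timestep)
    ext = inputs.reshape(T * B, -1) @ params.W_in.T + params.b
    if rng is not None and params.sigma_rec > 0:
        ext += params.noise_scale * rng.standard_normal(ext.shape)
    ext = ext.reshape(T, B, N)
    rates = np.empty((T, B, N))
    for t in range(T):
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(f"non-finite network state at timestep {t}")
        q = r @ params.W_rec.T
        q += ext[t]
        r = (1.0 - a) * r + a * softplus(q)
        rates[t] = r
    outputs = logistic(rates.reshape(T * B, N) @ params.W_out.T
                       ).reshape(T, B, params.n_out)
    if meta is None:
        meta = pd.DataFrame(index=range(B))
    return ActivityRecord(rates=rates, outputs=outputs, meta=meta.reset_index(drop=True),
                          dt_s=params.dt / 1000.0)


def run_trial(params: NetworkParams, inputs: np.ndarray,
              rng: np.random.Generator | None = None,
              meta: pd.DataFrame | None = None) -> ActivityRecord:
    """Simulate a single trial given (time x n_in) inputs."""
    rec = run_batch(params, inputs[:, None, :], rng, meta)
    return rec
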