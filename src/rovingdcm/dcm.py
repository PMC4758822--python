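"""Bilinear dynamic causal model with balloon–windkessel haemodynamics.

Neuronal dynamics follow the bilinear state equation

    dx/dt = (A + sum_k u_k B_k) x + C u

where A (Hz) is the average coupling, B_k (Hz) the modulation of coupling by
input k, and C the driving-input weights. Each region's neuronal activity
drives a four-state balloon–windkessel cascade (vasodilatory signal s, blood
flow f, venous volume v, deoxyhaemoglobin q) whose nonlinear observation
yields percent BOLD signal change.

The default network is the right-lateralised tactile-deviance hierarchy
TH -> S1 -> AIC -> MCC -> MFG with two inputs: an "all conditions" stream
driving the thalamus and a deviant-vs-standard (+1/-1) modulator acting on
every connection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DEVIANT, STANDARD, StimulusSequence

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("TH", "S1", "AIC", "MCC", "MFG")


class InstabilityError(RuntimeError):
    """Raised when the neuronal system is unstable for an attained input."""


class DegenerateInputError(ValueError):
    """Raised for zero-variance voxel data in eigenvariate extraction."""


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon–windkessel constants for one region.

    kappa: vasodilatory signal decay (1/s); gamma: flow autoregulation (1/s);
    tau: venous transit time (s); alpha: vessel stiffness exponent; e0:
    resting oxygen extraction fraction; v0: resting venous blood volume
    fraction. k1..k3 are the classic 1.5T-lineage observation coefficients
    (k1 = 7*E0, k2 = 2, k3 = 2*E0 - 0.2).
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 0.04
    k1: float = 2.8
    k2: float = 2.0
    k3: float = 0.6

    def __post_init__(self):
        if not (self.kappa > 0 and self.gamma > 0 and self.tau > 0):
            raise ValueError("rates and transit time must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.e0 <= 1:
            raise ValueError("e0 must lie in (0,1]")
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")


@dataclass
class NetworkSpec:
    """Allowed-connection masks for a DCM.

    ``a_mask`` (n x n) marks allowed average connections (A[i, j] != 0 means
    j -> i, self-connections on the diagonal), ``b_masks`` (I x n x n) the
    allowed modulations per input, and ``c_mask`` (n x I) the allowed driving
    inputs.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    a_mask: np.ndarray = None
    b_masks: np.ndarray = None
    c_mask: np.ndarray = None

    def __post_init__(self):
        n = len(self.regions)
        if self.a_mask is None:
            self.a_mask = np.ones((n, n), dtype=bool)
        self.a_mask = np.asarray(self.a_mask, dtype=bool)
        if self.b_masks is None:
            # input 0: all-conditions driver (no modulation); input 1: deviant modulator on everything
            self.b_masks = np.stack([np.zeros((n, n), bool), np.ones((n, n), bool)])
        self.b_masks = np.asarray(self.b_masks, dtype=bool)
        if self.b_masks.ndim == 2:
            self.b_masks = self.b_masks[None]
        if self.c_mask is None:
            c = np.zeros((n, self.b_masks.shape[0]), dtype=bool)
            c[0, 0] = True  # driving input to the first region (TH)
            self.c_mask = c
        self.c_mask = np.asarray(self.c_mask, dtype=bool)
        if self.a_mask.shape != (n, n):
            raise ValueError("a_mask must be square of size n_regions")
        if self.b_masks.shape[1:] != (n, n):
            raise ValueError("b_masks must be (I, n, n)")
        if self.c_mask.shape != (n, self.b_masks.shape[0]):
            raise ValueError("c_mask must be (n_regions, n_inputs)")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_inputs(self) -> int:
        return self.b_masks.shape[0]

    @classmethod
    def full_model(cls, regions: Sequence[str] = DEFAULT_REGIONS) -> "NetworkSpec":
        """All A connections, full modulation of every connection by the
        deviant modulator, driving input to the first region only."""
        return cls(regions=tuple(regions))


@dataclass
class ParameterCounts:
    n_A: int
    n_B_total: int
    n_B_extrinsic: int
    n_B_self: int
    n_C: int


def count_parameters(spec: NetworkSpec) -> ParameterCounts:
    """Count free coupling parameters; B is split into extrinsic
    (between-region, off-diagonal) and self (intrinsic, diagonal) entries."""
    b_total = int(spec.b_masks.sum())
    b_self = int(sum(np.diag(m).sum() for m in spec.b_masks))
    return ParameterCounts(
        n_A=int(spec.a_mask.sum()),
        n_B_total=b_total,
        n_B_extrinsic=b_total - b_self,
        n_B_self=b_self,
        n_C=int(spec.c_mask.sum()),
    )


@dataclass
class DCMParameters:
    """Coupling matrices (Hz) and per-region haemodynamic constants."""

    A: np.ndarray
    B: np.ndarray  # (I, n, n)
    C: np.ndarray  # (n, I)
    hemo: tuple[HemodynamicParameters, ...] = None
    spec: NetworkSpec = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim == 2:
            self.B = self.B[None]
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        n = self.A.shape[0]
        if self.hemo is None:
            self.hemo = tuple(HemodynamicParameters() for _ in range(n))
        elif isinstance(self.hemo, HemodynamicParameters):
            self.hemo = tuple(self.hemo for _ in range(n))
        else:
            self.hemo = tuple(self.hemo)
        if self.spec is not None:
            if np.any(self.A[~self.spec.a_mask] != 0):
                raise ValueError("A has nonzero entries outside the allowed mask")
            if np.any(self.B[~self.spec.b_masks] != 0):
                raise ValueError("B has nonzero entries outside the allowed mask")
            if np.any(self.C[~self.spec.c_mask] != 0):
                raise ValueError("C has nonzero entries outside the allowed mask")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative (stability)")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[0]


@dataclass
class RegionTimeseries:
    """BOLD timeseries (percent signal change), one column per region."""

    values: np.ndarray  # (n_volumes, n_regions)
    TR: float
    regions: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (volumes x regions)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.regions))

    def to_tsv(self, path, seed: int | None = None) -> None:
        """Write TSV with a JSON sidecar carrying TR, units and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {"TR": self.TR, "units": "percent signal change", "seed": seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "RegionTimeseries":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(values=df.to_numpy(), TR=float(sidecar["TR"]),
                   regions=tuple(df.columns))


def neuronal_drift(x: np.ndarray, u: np.ndarray, p: DCMParameters) -> np.ndarray:
    """dx/dt = (A + sum_k u_k B_k) x + C u."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != (p.n_regions,):
        raise ValueError(f"state dimension {x.shape} does not match {p.n_regions} regions")
    if u.shape != (p.n_inputs,):
        raise ValueError(f"input dimension {u.shape} does not match {p.n_inputs} inputs")
    J = p.A + np.tensordot(u, p.B, axes=1)
    return J @ x + p.C @ u


def check_stability(p: DCMParameters, inputs: np.ndarray | None = None) -> float:
    """Return the largest real part over the eigenvalues of A + sum u_k B_k
    for every distinct attained input row; raise InstabilityError if >= 0."""
    rows = np.zeros((1, p.n_inputs)) if inputs is None else np.unique(
        np.asarray(inputs, float), axis=0)
    worst = -np.inf
    worst_row = rows[0]
    for u in rows:
        J = p.A + np.tensordot(u, p.B, axes=1)
        lam = np.linalg.eigvals(J).real.max()
        if lam > worst:
            worst, worst_row = lam, u
    if worst >= 0:
        raise InstabilityError(
            f"unstable neuronal dynamics: max Re(eig) = {worst:.4f} at input {worst_row}"
        )
    return float(worst)


def build_input_sticks(
    seq: StimulusSequence,
    n_volumes: int,
    TR: float,
    substeps: int = 16,
    stick_duration: float | None = None,
) -> np.ndarray:
    """Sample driving/modulatory inputs on the integration grid.

    Returns (n_volumes * substeps, 2): column 0 is the all-conditions stream
    (+1 at every deviant and standard), column 1 the deviant-vs-standard
    modulator (+1 deviant, -1 standard). Events are short boxcars of fixed
    physical duration (default TR/16 s) whose onsets are binned to a TR/16
    microtime grid, so the continuous-time input function — and hence the
    response — is independent of the integration step. Fractional overlap is
    used on grids that do not align with the microtime bins.
    """
    microtime = TR / 16.0
    if stick_duration is None:
        stick_duration = microtime
    dt = TR / substeps
    n_steps = n_volumes * substeps
    u = np.zeros((n_steps, 2))
    run_end = n_volumes * TR
    edges = np.arange(n_steps + 1) * dt
    for e in seq.events:
        if e.label not in (DEVIANT, STANDARD):
            continue
        if e.onset >= run_end:
            continue
        onset = np.round(e.onset / microtime) * microtime
        lo = np.clip(edges[:-1], onset, onset + stick_duration)
        hi = np.clip(edges[1:], onset, onset + stick_duration)
        frac = np.maximum(hi - lo, 0.0) / dt
        u[:, 0] += frac
        u[:, 1] += frac if e.label == DEVIANT else -frac
    return u


def _hemo_arrays(hemo: Sequence[HemodynamicParameters]) -> dict[str, np.ndarray]:
    return {
        name: np.array([getattr(h, name) for h in hemo])
        for name in ("kappa", "gamma", "tau", "alpha", "e0", "v0", "k1", "k2", "k3")
    }


def _integrate_batch(
    A: np.ndarray,  # (batch, n, n)
    B: np.ndarray,  # (batch, I, n, n)
    C: np.ndarray,  # (batch, n, I)
    hemo: dict[str, np.ndarray],  # arrays (n,)
    inputs: np.ndarray,  # (n_steps, I)
    TR: float,
    n_volumes: int,
    substeps: int,
    return_states: bool = False,
) -> np.ndarray:
    """Fixed-step RK4 integration of the neuronal + balloon system.

    States per region: neuronal x and log-transformed s-adjacent balloon
    states (s linear; f, v, q in log space, guaranteeing positivity). Returns
    BOLD (% signal) sampled at volume onsets, shape (batch, n_volumes, n).
    """
    batch, n = A.shape[0], A.shape[1]
    dt = TR / substeps
    n_steps = n_volumes * substeps
    if inputs.shape[0] != n_steps:
        raise ValueError(f"inputs must have {n_steps} rows, got {inputs.shape[0]}")

    kappa, gamma = hemo["kappa"], hemo["gamma"]
    tau, alpha, e0 = hemo["tau"], hemo["alpha"], hemo["e0"]
    inv_alpha = 1.0 / alpha

    # state tensor: (batch, n, 5) = [x, s, ln f, ln v, ln q]
    y = np.zeros((batch, n, 5))

    def drift(y, u):
        x = y[..., 0]
        s = y[..., 1]
        f = np.exp(y[..., 2])
        v = np.exp(y[..., 3])
        q = np.exp(y[..., 4])
        Ju = A + np.einsum("k,bkij->bij", u, B)
        dx = np.einsum("bij,bj->bi", Ju, x) + C @ u
        ds = x - kappa * s - gamma * (f - 1.0)
        df = s / f
        fv = v ** inv_alpha
        dv = (f - fv) / (tau * v)
        extraction = (1.0 - (1.0 - e0) ** (1.0 / f)) / e0
        dq = (f * extraction - fv * q / v) / (tau * q)
        return np.stack([dx, ds, df, dv, dq], axis=-1)

    out = np.empty((batch, n_volumes, n))
    v0, k1, k2, k3 = hemo["v0"], hemo["k1"], hemo["k2"], hemo["k3"]

    def observe(y):
        v = np.exp(y[..., 3])
        q = np.exp(y[..., 4])
        return 100.0 * v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))

    states = np.empty((batch, n_steps + 1, n, 5)) if return_states else None
    # divergence at exploratory parameter values is caught via the finite
    # check below; silence the transient overflow warnings it produces
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for i in range(n_steps):
            if i % substeps == 0:
                out[:, i // substeps] = observe(y)
            if return_states:
                states[:, i] = y
            u = inputs[i]
            k1_ = drift(y, u)
            k2_ = drift(y + 0.5 * dt * k1_, u)
            k3_ = drift(y + 0.5 * dt * k2_, u)
            k4_ = drift(y + dt * k3_, u)
            y = y + (dt / 6.0) * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
            if not np.all(np.isfinite(y[..., 0])) or np.abs(y[..., 0]).max() > 1e6:
                raise InstabilityError(
                    "neuronal state diverged during integration (check stability of A + u.B)"
                )
    if return_states:
        states[:, n_steps] = y
        return out, states
    return out


def simulate_timeseries(
    p: DCMParameters,
    inputs: np.ndarray,
    TR: float = 1.54,
    n_volumes: int = 1109,
    noise_sd: float = 0.0,
    seed: int | None = None,
    substeps: int = 16,
) -> RegionTimeseries:
    """Simulate region BOLD from resting initial conditions.

    ``inputs`` is the per-integration-step input matrix (n_volumes * substeps
    rows). BOLD is sampled at volume-onset times; i.i.d. Gaussian noise of SD
    ``noise_sd`` (% signal) is added. Deterministic given ``seed``.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 1:
        inputs = inputs[:, None]
    check_stability(p, inputs)
    bold = _integrate_batch(
        p.A[None], p.B[None], p.C[None], _hemo_arrays(p.hemo),
        inputs, TR, n_volumes, substeps,
    )[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        bold = bold + rng.normal(0.0, noise_sd, size=bold.shape)
    regions = p.spec.regions if p.spec is not None else tuple(
        f"R{i}" for i in range(p.n_regions))
    return RegionTimeseries(values=bold, TR=TR, regions=regions)


def simulate_states(
    p: DCMParameters,
    inputs: np.ndarray,
    TR: float,
    n_volumes: int,
    substeps: int = 16,
) -> dict[str, np.ndarray]:
    """Integrate and return the full state trajectories on the fine grid.

    Returns arrays of shape (n_steps + 1, n_regions): neuronal ``x``,
    vasodilatory ``s``, and the positive balloon states ``f`` (flow), ``v``
    (volume), ``q`` (deoxyhaemoglobin). Useful for inspecting the neuronal
    level directly, e.g. against linear-ODE closed forms.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 1:
        inputs = inputs[:, None]
    _, states = _integrate_batch(
        p.A[None], p.B[None], p.C[None], _hemo_arrays(p.hemo),
        inputs, TR, n_volumes, substeps, return_states=True,
    )
    st = states[0]
    return {
        "x": st[:, :, 0],
        "s": st[:, :, 1],
        "f": np.exp(st[:, :, 2]),
        "v": np.exp(st[:, :, 3]),
        "q": np.exp(st[:, :, 4]),
    }


def principal_eigenvariate(voxel_series: np.ndarray) -> np.ndarray:
    """First singular-vector summary of a volumes x voxels matrix.

    Returns the first left singular vector scaled by its singular value over
    sqrt(n_voxels), sign-aligned with the mean voxel series.
    """
    Y = np.asarray(voxel_series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] < 1:
        raise DegenerateInputError("need at least one voxel")
    if np.any(~np.isfinite(Y)):
        raise ValueError("voxel data contain non-finite values")
    u, s, _ = np.linalg.svd(Y, full_matrices=False)
    if s[0] <= 0:
        raise DegenerateInputError("zero-variance voxel data")
    ts = u[:, 0] * s[0] / np.sqrt(Y.shape[1])
    mean_series = Y.mean(axis=1)
    if ts @ mean_series < 0:
        ts = -ts
    return ts
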