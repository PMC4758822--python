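"""Variational Laplace (Gaussian fixed-form) model inversion.

The scheme maximises a free-energy lower bound on log model evidence for
models of the form y = g(theta) + e, with Gaussian priors on the parameters
and, optionally, on per-region log noise precisions. Optimisation is
Gauss-Newton ascent with Levenberg-Marquardt regularisation; Jacobians are
forward finite differences of the integrated response. The resulting
Gaussian posterior and free energy feed Bayesian model reduction and
fixed-effects model comparison downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dcm import (
    DCMParameters,
    HemodynamicParameters,
    InstabilityError,
    NetworkSpec,
    RegionTimeseries,
    _hemo_arrays,
    _integrate_batch,
)

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


class InvalidPriorError(ValueError):
    pass


@dataclass
class PriorDensity:
    """Gaussian prior N(mean, cov). Zero variance fixes a parameter at its mean."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise InvalidPriorError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise InvalidPriorError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise InvalidPriorError("covariance must be positive semi-definite")

    @classmethod
    def from_variances(cls, mean, variances) -> "PriorDensity":
        return cls(np.asarray(mean, float), np.diag(np.asarray(variances, float)))


@dataclass
class PosteriorDensity:
    """Gaussian posterior with the Laplace free energy (nats).

    ``free_energy`` approximates the log model evidence and is what gets
    pooled over subjects in fixed-effects model comparison. Dimensions with
    zero prior variance have zero posterior variance and mean equal to the
    prior mean.
    """

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    noise_log_precision: np.ndarray = None
    converged: bool = True
    f_trace: list[float] = field(default_factory=list)
    names: tuple[str, ...] | None = None

    @property
    def noise_precision(self) -> np.ndarray:
        return np.exp(self.noise_log_precision)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": self.free_energy,
            "noise_log_precision": None if self.noise_log_precision is None
            else np.asarray(self.noise_log_precision).tolist(),
            "converged": bool(self.converged),
            "f_trace": [float(f) for f in self.f_trace],
            "names": None if self.names is None else list(self.names),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "PosteriorDensity":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"], float),
            cov=np.asarray(d["cov"], float),
            free_energy=float(d["free_energy"]),
            noise_log_precision=None if d["noise_log_precision"] is None
            else np.asarray(d["noise_log_precision"], float),
            converged=bool(d["converged"]),
            f_trace=list(d["f_trace"]),
            names=None if d["names"] is None else tuple(d["names"]),
        )


@dataclass
class InversionSettings:
    max_iterations: int = 128
    tolerance: float = 0.01  # nats; |dF| threshold
    n_converged: int = 4  # consecutive small |dF| needed
    lm_initial: float = 1e-4  # initial Levenberg-Marquardt damping
    lm_increase: float = 8.0
    lm_decrease: float = 0.5
    max_lm_tries: int = 16
    fd_step: float = 1e-4  # relative forward-difference step
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return ld


def laplace_fit(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    prior: PriorDensity,
    noise_groups: np.ndarray | None = None,
    hyper_mean: np.ndarray | float = 0.0,
    hyper_var: np.ndarray | float = 16.0,
    settings: InversionSettings | None = None,
) -> PosteriorDensity:
    """Fit y = g(theta) + e by variational Laplace.

    ``predict`` maps a batch of parameter vectors (m, p) to predictions
    (m, n); batching is exploited for finite-difference Jacobians.
    ``noise_groups`` assigns each data point to a noise pool (e.g. a region)
    with its own log precision lambda_g; noise covariance is
    exp(-lambda_g) I within each pool. ``hyper_var = 0`` fixes the log
    precisions at ``hyper_mean`` (known noise). The returned free energy is
    exact for linear g with known noise.
    """
    settings = settings or InversionSettings()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if noise_groups is None:
        noise_groups = np.zeros(n, dtype=int)
    noise_groups = np.asarray(noise_groups)
    group_ids = np.unique(noise_groups)
    group_masks = [noise_groups == g for g in group_ids]
    n_g = np.array([m.sum() for m in group_masks])

    hyper_mean = np.broadcast_to(np.atleast_1d(np.asarray(hyper_mean, float)),
                                 (len(group_ids),)).copy()
    hyper_var = np.broadcast_to(np.atleast_1d(np.asarray(hyper_var, float)),
                                (len(group_ids),)).copy()
    if np.any(hyper_var < 0):
        raise InvalidPriorError("hyperprior variances must be >= 0")
    lam = hyper_mean.copy()
    free_hyper = hyper_var > 0

    # reduce to the subspace with nonzero prior variance
    w, U = np.linalg.eigh(prior.cov)
    keep = w > 1e-12 * max(1.0, w.max())
    U = U[:, keep]
    w = w[keep]
    p_red = int(keep.sum())
    if p_red == 0:
        raise InvalidPriorError("prior admits no free parameters")
    P0 = np.diag(1.0 / w)  # prior precision in reduced coordinates
    ld_S0 = float(np.sum(np.log(w)))

    def to_full(xi: np.ndarray) -> np.ndarray:
        return prior.mean + xi @ U.T if xi.ndim > 1 else prior.mean + U @ xi

    def residual(xi: np.ndarray) -> np.ndarray:
        pred = predict(to_full(xi)[None])[0]
        return y - np.asarray(pred, float).ravel()

    def jacobian(xi: np.ndarray, r0: np.ndarray) -> np.ndarray:
        theta0 = to_full(xi)
        h = settings.fd_step * np.maximum(1.0, np.abs(xi))
        thetas = theta0[None] + (U * h).T  # row i: theta0 + h_i * U[:, i]
        preds = np.asarray(predict(thetas), float).reshape(p_red, n)
        g0 = y - r0
        return (preds - g0[None]).T / h[None, :]

    def precision_weights(lam):
        pi = np.empty(n)
        for m, l in zip(group_masks, lam):
            pi[m] = np.exp(l)
        return pi

    _lambda_context = [None]  # per-group Gram matrices of the current Jacobian

    def _lambda_objective(lam, R):
        """All lambda-dependent terms of F, given residual powers R per group
        and the current Gram matrices (via _lambda_context)."""
        grams, = _lambda_context
        H = sum(np.exp(l) * G for l, G in zip(lam, grams)) + P0
        val = -0.5 * _logdet(H)
        for g in range(len(group_ids)):
            val += -0.5 * np.exp(lam[g]) * R[g] + 0.5 * n_g[g] * lam[g]
            if free_hyper[g]:
                pp = 0.5 * np.exp(lam[g]) * R[g] + 1.0 / hyper_var[g]
                val += (-0.5 * (lam[g] - hyper_mean[g]) ** 2 / hyper_var[g]
                        - 0.5 * np.log(pp))
        return val

    def _maximise_lambda(lam, R):
        """Coordinate-wise safeguarded Newton ascent on the exact
        lambda-dependent part of F; never decreases it."""
        grams, = _lambda_context
        lam = lam.copy()
        f0 = _lambda_objective(lam, R)
        for _ in range(16):
            moved = False
            H = sum(np.exp(l) * G for l, G in zip(lam, grams)) + P0
            Hinv = np.linalg.inv(H)
            for g in range(len(group_ids)):
                if not free_hyper[g]:
                    continue
                e = np.exp(lam[g])
                pp = 0.5 * e * R[g] + 1.0 / hyper_var[g]
                tr_g = float(np.trace(Hinv @ grams[g]))
                d1 = (-0.5 * e * R[g] + 0.5 * n_g[g]
                      - (lam[g] - hyper_mean[g]) / hyper_var[g]
                      - 0.5 * (0.5 * e * R[g]) / pp
                      - 0.5 * e * tr_g)
                d2 = -0.5 * e * R[g] - 1.0 / hyper_var[g] - 0.5 * e * tr_g
                step = float(np.clip(-d1 / d2, -8.0, 8.0))
                while abs(step) > 1e-12:
                    cand = lam.copy()
                    cand[g] = float(np.clip(cand[g] + step, -40.0, 40.0))
                    if cand[g] == lam[g]:
                        break
                    fc = _lambda_objective(cand, R)
                    if fc >= f0 - 1e-12:
                        if abs(step) > 1e-8:
                            moved = True
                        lam, f0 = cand, fc
                        break
                    step *= 0.5
            if not moved:
                break
        return lam

    def free_energy(xi, r, lam, H):
        """Laplace free energy with Sigma_q = H^{-1} (trace terms cancel)."""
        pi = precision_weights(lam)
        F = -0.5 * float(r @ (pi * r))
        F += 0.5 * float(n_g @ lam) - 0.5 * n * LOG2PI
        F += -0.5 * float(xi @ P0 @ xi)
        F += 0.5 * (-_logdet(H) - ld_S0)  # 0.5 ln|Sigma_q| - 0.5 ln|S0|
        # hyperparameter terms (only for free log precisions)
        for g in range(len(group_ids)):
            if free_hyper[g]:
                d = lam[g] - hyper_mean[g]
                Rg = float(r[group_masks[g]] @ r[group_masks[g]])
                post_prec = 0.5 * np.exp(lam[g]) * Rg + 1.0 / hyper_var[g]
                F += -0.5 * d * d / hyper_var[g]
                F += -0.5 * np.log(hyper_var[g]) - 0.5 * np.log(post_prec)
        return F

    def eval_point(xi, lam_warm):
        """Evaluate F as a function of the point: Jacobian, optimised noise
        log-precisions and Laplace covariance all taken at ``xi``."""
        r = residual(xi)
        if not np.all(np.isfinite(r)):
            raise InstabilityError("non-finite prediction")
        J = jacobian(xi, r)
        _lambda_context[0] = [J[m].T @ J[m] for m in group_masks]
        if np.any(free_hyper):
            R = np.array([float(r[m] @ r[m]) for m in group_masks])
            lam_opt = _maximise_lambda(lam_warm, R)
        else:
            lam_opt = lam_warm
        pi = precision_weights(lam_opt)
        H = J.T @ (pi[:, None] * J) + P0
        g = J.T @ (pi * r) - P0 @ xi
        F = free_energy(xi, r, lam_opt, H)
        return {"xi": xi, "r": r, "J": J, "lam": lam_opt, "H": H, "g": g, "F": F}

    cur = eval_point(np.zeros(p_red), lam)
    if not np.isfinite(cur["F"]):
        raise RuntimeError("free energy at the prior mean is not finite")
    lm = settings.lm_initial
    f_trace: list[float] = [cur["F"]]
    small_steps = 0
    converged = False

    for _it in range(settings.max_iterations):
        scale = np.trace(cur["H"]) / p_red
        accepted = None
        for _ in range(settings.max_lm_tries):
            try:
                step = np.linalg.solve(cur["H"] + lm * scale * np.eye(p_red),
                                       cur["g"])
                cand = eval_point(cur["xi"] + step, cur["lam"])
            except (np.linalg.LinAlgError, InstabilityError):
                lm = min(max(lm, settings.lm_initial) * settings.lm_increase, 1e12)
                continue
            if np.isfinite(cand["F"]) and cand["F"] >= cur["F"] - 1e-9:
                accepted = cand
                break
            lm = min(max(lm, settings.lm_initial) * settings.lm_increase, 1e12)
        if accepted is None:
            # no ascent direction even under heavy damping: treat as optimum
            converged = True
            break
        dF = accepted["F"] - cur["F"]
        cur = accepted
        f_trace.append(cur["F"])
        lm = max(lm * settings.lm_decrease, settings.lm_initial)
        small_steps = small_steps + 1 if abs(dF) < settings.tolerance else 0
        if small_steps >= settings.n_converged:
            converged = True
            break

    xi, lam = cur["xi"], cur["lam"]
    F_cur, H_cur = cur["F"], cur["H"]

    if not converged and len(f_trace) >= settings.n_converged + 1:
        # flat tail without the counter tripping still counts as converged
        tail = np.diff(f_trace[-(settings.n_converged + 1):])
        converged = bool(np.all(np.abs(tail) < settings.tolerance))
    if not converged:
        logger.warning("laplace_fit: not converged after %d iterations", len(f_trace) - 1)

    Sq_red = np.linalg.inv(H_cur)
    Sq_red = 0.5 * (Sq_red + Sq_red.T)
    mean = to_full(xi)
    cov = U @ Sq_red @ U.T
    return PosteriorDensity(
        mean=mean,
        cov=cov,
        free_energy=float(F_cur),
        noise_log_precision=lam,
        converged=converged,
        f_trace=f_trace,
    )


# ---------------------------------------------------------------------------
# DCM-facing wrapper


class ParameterPacker:
    """Maps the free entries of (A, B, C) to a flat named vector and back."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        n, I = spec.n_regions, spec.n_inputs
        names: list[str] = []
        idx: list[tuple[str, int, int, int]] = []
        for i in range(n):
            for j in range(n):
                if spec.a_mask[i, j]:
                    names.append(f"A({spec.regions[i]}<-{spec.regions[j]})")
                    idx.append(("A", 0, i, j))
        for k in range(I):
            for i in range(n):
                for j in range(n):
                    if spec.b_masks[k, i, j]:
                        names.append(f"B{k}({spec.regions[i]}<-{spec.regions[j]})")
                        idx.append(("B", k, i, j))
        for i in range(n):
            for k in range(I):
                if spec.c_mask[i, k]:
                    names.append(f"C({spec.regions[i]}<-u{k})")
                    idx.append(("C", k, i, 0))
        self.names = tuple(names)
        self._idx = idx

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(self, p: DCMParameters) -> np.ndarray:
        out = np.empty(self.n_params)
        for m, (kind, k, i, j) in enumerate(self._idx):
            out[m] = p.A[i, j] if kind == "A" else (
                p.B[k, i, j] if kind == "B" else p.C[i, k])
        return out

    def unpack_arrays(self, theta: np.ndarray):
        """theta (batch, p) -> (A, B, C) arrays with batch leading axis."""
        theta = np.atleast_2d(theta)
        batch = theta.shape[0]
        n, I = self.spec.n_regions, self.spec.n_inputs
        A = np.zeros((batch, n, n))
        B = np.zeros((batch, I, n, n))
        C = np.zeros((batch, n, I))
        for m, (kind, k, i, j) in enumerate(self._idx):
            if kind == "A":
                A[:, i, j] = theta[:, m]
            elif kind == "B":
                B[:, k, i, j] = theta[:, m]
            else:
                C[:, i, k] = theta[:, m]
        return A, B, C

    def unpack(self, theta: np.ndarray,
               hemo: HemodynamicParameters | None = None) -> DCMParameters:
        A, B, C = self.unpack_arrays(theta[None])
        return DCMParameters(A=A[0], B=B[0], C=C[0], hemo=hemo, spec=self.spec)


def default_priors(spec: NetworkSpec,
                   a_diag_mean: float = -0.5,
                   a_var: float = 1.0 / 16.0,
                   b_var: float = 1.0 / 16.0,
                   c_var: float = 1.0) -> PriorDensity:
    """Shrinkage priors keeping the prior-mean system stable: A-diagonal
    N(-0.5, 1/16), off-diagonal A and all B entries N(0, 1/16), C N(0, 1)."""
    packer = ParameterPacker(spec)
    mean = np.zeros(packer.n_params)
    var = np.empty(packer.n_params)
    for m, (kind, k, i, j) in enumerate(packer._idx):
        if kind == "A":
            mean[m] = a_diag_mean if i == j else 0.0
            var[m] = a_var
        elif kind == "B":
            var[m] = b_var
        else:
            var[m] = c_var
    return PriorDensity.from_variances(mean, var)


def _dcm_predictor(spec: NetworkSpec, inputs: np.ndarray, TR: float,
                   n_volumes: int, substeps: int,
                   hemo: HemodynamicParameters,
                   mean_centre: bool = True) -> Callable[[np.ndarray], np.ndarray]:
    packer = ParameterPacker(spec)
    hemo_arrays = _hemo_arrays(tuple(hemo for _ in range(spec.n_regions)))

    def predict(theta_batch: np.ndarray) -> np.ndarray:
        A, B, C = packer.unpack_arrays(theta_batch)
        bold = _integrate_batch(A, B, C, hemo_arrays, inputs, TR, n_volumes, substeps)
        if mean_centre:
            bold = bold - bold.mean(axis=1, keepdims=True)
        return bold.reshape(theta_batch.shape[0] if theta_batch.ndim > 1 else 1, -1)

    return predict


def variational_laplace(
    data: RegionTimeseries,
    spec: NetworkSpec,
    inputs: np.ndarray,
    priors: PriorDensity | None = None,
    settings: InversionSettings | None = None,
    substeps: int = 16,
    hemo: HemodynamicParameters | None = None,
    hyper_mean: float = 0.0,
    hyper_var: float = 16.0,
) -> PosteriorDensity:
    """Invert a bilinear DCM from region BOLD timeseries.

    Timeseries are mean-centred per region before inversion (standing in for
    confound adjustment), as is the model prediction. One noise log-precision
    hyperparameter is estimated per region. Returns the Gaussian posterior
    over the free coupling parameters with the free-energy approximation to
    log evidence.
    """
    if priors is None:
        priors = default_priors(spec)
    settings = settings or InversionSettings()
    hemo = hemo or HemodynamicParameters()
    packer = ParameterPacker(spec)
    if priors.mean.size != packer.n_params:
        raise InvalidPriorError(
            f"prior has {priors.mean.size} entries; spec defines {packer.n_params} parameters")

    n_volumes = data.n_volumes
    Y = data.values - data.values.mean(axis=0, keepdims=True)
    predict = _dcm_predictor(spec, np.asarray(inputs, float), data.TR,
                             n_volumes, substeps, hemo)
    noise_groups = np.tile(np.arange(spec.n_regions), (n_volumes, 1)).ravel()
    post = laplace_fit(
        predict, Y.ravel(), priors, noise_groups=noise_groups,
        hyper_mean=hyper_mean, hyper_var=hyper_var, settings=settings,
    )
    post.names = packer.names
    return post


def predict_response(
    p_mean: np.ndarray | DCMParameters,
    spec: NetworkSpec,
    inputs: np.ndarray,
    TR: float,
    n_volumes: int,
    substeps: int = 16,
    hemo: HemodynamicParameters | None = None,
) -> RegionTimeseries:
    """Noise-free forward prediction at a parameter vector (or DCMParameters)."""
    from .dcm import simulate_timeseries

    if isinstance(p_mean, DCMParameters):
        params = p_mean
    else:
        packer = ParameterPacker(spec)
        params = packer.unpack(np.asarray(p_mean, float), hemo=hemo)
    return simulate_timeseries(params, inputs, TR=TR, n_volumes=n_volumes,
                               noise_sd=0.0, substeps=substeps)
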