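"""Bayesian model reduction and fixed-effects model comparison.

Given the full model's Gaussian posterior and prior, the log evidence and
posterior of any model with *shrunk* priors follow analytically, without
re-inversion. Parameters are "removed" by setting both the prior mean and
the prior variance to zero; the zero-variance limit is handled exactly by
projecting the Gaussian algebra onto the retained subspace.

Model spaces are built from named *families* of parameters that switch on or
off together; with 8 families the space has 256 models, indexed by the
binary encoding of the family states (0 = null model, 255 = full model).
Evidence is pooled over subjects under fixed-effects assumptions by summing
log evidences; posterior model probabilities are the softmax of the pooled
log evidences, and the Bayes factor is the probability ratio of the two best
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inversion import PosteriorDensity, PriorDensity

MAX_FAMILIES = 20

_ZERO_VAR = 1e-12


class UnsupportedReductionError(ValueError):
    """Raised when the reduced prior is wider than the full prior."""


@dataclass
class ReducedModel:
    id: int
    keep_mask: np.ndarray  # bool over switchable parameters; True = retained

    def __post_init__(self):
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)


@dataclass
class ModelSpace:
    """Named parameter families that switch on/off together.

    ``families`` maps family name -> indices (or names) of the switchable
    parameters it contains; families must partition the switchable set.
    """

    families: dict[str, list]

    def __post_init__(self):
        seen: set = set()
        for name, members in self.families.items():
            if not members:
                raise ValueError(f"family '{name}' is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"families are not disjoint: {overlap}")
            seen |= set(members)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def switchable(self) -> list:
        out = []
        for members in self.families.values():
            out.extend(members)
        return out

    @property
    def n_models(self) -> int:
        return 2 ** self.n_families


@dataclass
class ModelComparison:
    """Fixed-effects comparison over a model space."""

    model_ids: np.ndarray
    pooled_log_evidence: np.ndarray
    posterior_probability: np.ndarray
    best_id: int
    runner_up_id: int
    bayes_factor: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_ids,
                "pooled_log_evidence": self.pooled_log_evidence,
                "pP": self.posterior_probability,
            }
        )

    def summary(self) -> dict:
        return {
            "best": int(self.best_id),
            "runner_up": int(self.runner_up_id),
            "bayes_factor": float(self.bayes_factor),
            "pP_best": float(
                self.posterior_probability[list(self.model_ids).index(self.best_id)]
            ),
        }

    def write(self, tsv_path, json_path=None) -> None:
        """TSV of (model, pooled log evidence, pP) plus a JSON summary."""
        import json
        from pathlib import Path

        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=1))


def reduce_evidence(
    full_posterior: PosteriorDensity,
    full_prior: PriorDensity,
    reduced_prior: PriorDensity,
) -> tuple[float, PosteriorDensity]:
    """Analytic change in log evidence and posterior under a shrunk prior.

    Works entirely from the full model's Gaussian posterior/prior. The
    reduced prior may only shrink (smaller variances; removal = zero mean and
    zero variance); widening raises UnsupportedReductionError. Dimensions
    fixed in the full prior (zero variance) are carried through unchanged.
    """
    m0, S0 = full_prior.mean, full_prior.cov
    mq, Sq = full_posterior.mean, full_posterior.cov
    mr, Sr = reduced_prior.mean, reduced_prior.cov
    p = m0.size
    if not (mq.size == mr.size == p):
        raise ValueError("dimension mismatch between densities")

    v0 = np.diag(S0).copy()
    vr = np.diag(Sr).copy()
    if np.any(vr > v0 + 1e-9 * np.maximum(1.0, v0)):
        raise UnsupportedReductionError(
            "reduced prior variance exceeds the full prior variance")
    fixed_full = v0 <= _ZERO_VAR
    if np.any(np.abs(mr[fixed_full] - m0[fixed_full]) > 1e-9):
        raise UnsupportedReductionError(
            "cannot move a parameter fixed in the full prior")

    free = ~fixed_full  # dims with full prior mass
    removed = free & (vr <= _ZERO_VAR)
    retained = free & ~removed

    f = np.where(free)[0]
    P0 = np.linalg.inv(S0[np.ix_(f, f)])
    Pq = np.linalg.inv(Sq[np.ix_(f, f)])
    dP = Pq - P0
    b_full = Pq @ mq[f] - P0 @ m0[f]
    const = (
        -0.5 * float(mq[f] @ Pq @ mq[f] - m0[f] @ P0 @ m0[f])
        + 0.5 * (_logdet_psd(Pq) - _logdet_psd(P0))
    )

    ret_in_f = retained[f]  # positions of retained dims within the free block
    rem_in_f = removed[f]
    d = mr[np.where(removed)[0]]  # point values of removed dims (usually 0)

    if ret_in_f.sum() == 0:
        # everything removed: evidence of the point model
        const += -0.5 * float(d @ dP[np.ix_(rem_in_f, rem_in_f)] @ d) + float(
            d @ b_full[rem_in_f])
        delta = const
        mean = m0.copy()
        mean[removed] = d
        cov = np.zeros((p, p))
        post = PosteriorDensity(mean=mean, cov=cov, free_energy=float(
            full_posterior.free_energy + delta),
            noise_log_precision=full_posterior.noise_log_precision,
            names=full_posterior.names)
        return float(delta), post

    M = dP[np.ix_(ret_in_f, ret_in_f)]
    b_tilde = b_full[ret_in_f] - dP[np.ix_(ret_in_f, rem_in_f)] @ d
    const += -0.5 * float(d @ dP[np.ix_(rem_in_f, rem_in_f)] @ d) + float(
        d @ b_full[rem_in_f])

    r_idx = np.where(retained)[0]
    Sr_rt = Sr[np.ix_(r_idx, r_idx)]
    Pr = np.linalg.inv(Sr_rt)
    mr_rt = mr[r_idx]

    Apost = M + Pr
    try:
        L = np.linalg.cholesky(Apost)
    except np.linalg.LinAlgError as exc:
        raise UnsupportedReductionError(
            "reduced-model posterior precision is not positive definite") from exc
    b = b_tilde + Pr @ mr_rt
    x = np.linalg.solve(Apost, b)
    ld_A = 2.0 * float(np.sum(np.log(np.diag(L))))

    delta = (
        const
        - 0.5 * float(mr_rt @ Pr @ mr_rt)
        + 0.5 * float(b @ x)
        + 0.5 * (_logdet_psd(Pr) - ld_A)
    )

    mean = m0.copy()
    mean[np.where(removed)[0]] = d
    mean[r_idx] = x
    cov = np.zeros((p, p))
    cov[np.ix_(r_idx, r_idx)] = np.linalg.inv(Apost)
    post = PosteriorDensity(
        mean=mean, cov=cov,
        free_energy=float(full_posterior.free_energy + delta),
        noise_log_precision=full_posterior.noise_log_precision,
        names=full_posterior.names,
    )
    return float(delta), post


def _logdet_psd(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return float(ld)


def enumerate_models(space: ModelSpace) -> list[ReducedModel]:
    """All 2^n_families on/off combinations; model id is the binary encoding
    of family states (family i <-> bit i), so 0 is the null model and
    2^n - 1 the full model."""
    if space.n_families > MAX_FAMILIES:
        raise ValueError(
            f"{space.n_families} families would enumerate {2**space.n_families} "
            f"models; group parameters into at most {MAX_FAMILIES} families")
    sizes = [len(m) for m in space.families.values()]
    offsets = np.cumsum([0] + sizes)
    n_switch = offsets[-1]
    models = []
    for mid in range(2 ** space.n_families):
        keep = np.zeros(n_switch, dtype=bool)
        for fam_i in range(space.n_families):
            if mid >> fam_i & 1:
                keep[offsets[fam_i]:offsets[fam_i + 1]] = True
        models.append(ReducedModel(id=mid, keep_mask=keep))
    return models


def reduced_prior_for(
    model: ReducedModel,
    full_prior: PriorDensity,
    switch_idx: np.ndarray,
) -> PriorDensity:
    """Prior for a reduced model: switched-off parameters get mean 0 and
    variance 0; everything else keeps the full prior."""
    mean = full_prior.mean.copy()
    cov = full_prior.cov.copy()
    off = np.asarray(switch_idx)[~model.keep_mask]
    mean[off] = 0.0
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    return PriorDensity(mean, cov)


def score_model_space(
    posteriors: list[PosteriorDensity],
    full_prior: PriorDensity,
    space: ModelSpace,
    switch_idx: np.ndarray,
) -> pd.DataFrame:
    """Per-subject BMR log-evidence change for every model in the space.

    Returns a subjects x models table of log evidences relative to the full
    model (the full model's column is 0 for every subject).
    """
    models = enumerate_models(space)
    table = np.zeros((len(posteriors), len(models)))
    for s, post in enumerate(posteriors):
        for m, model in enumerate(models):
            rp = reduced_prior_for(model, full_prior, switch_idx)
            delta, _ = reduce_evidence(post, full_prior, rp)
            table[s, m] = delta
    return pd.DataFrame(table, columns=[mo.id for mo in models])


def ffx_pool(per_subject_log_evidence: pd.DataFrame | np.ndarray) -> ModelComparison:
    """Fixed-effects pooling: sum log evidence over subjects, softmax to
    posterior model probabilities, Bayes factor = pP ratio of the top two."""
    if isinstance(per_subject_log_evidence, pd.DataFrame):
        table = per_subject_log_evidence.to_numpy(dtype=float)
        ids = np.asarray(list(per_subject_log_evidence.columns))
    else:
        table = np.atleast_2d(np.asarray(per_subject_log_evidence, dtype=float))
        ids = np.arange(table.shape[1])
    if table.size == 0:
        raise ValueError("empty log-evidence table")
    if np.any(~np.isfinite(table)):
        raise ValueError("log-evidence table has missing or non-finite cells")

    pooled = table.sum(axis=0)
    z = pooled - pooled.max()
    pP = np.exp(z)
    pP /= pP.sum()

    order = np.argsort(pP)[::-1]
    best, runner = order[0], (order[1] if len(order) > 1 else order[0])
    bf = float(pP[best] / pP[runner]) if len(order) > 1 else np.inf
    return ModelComparison(
        model_ids=ids,
        pooled_log_evidence=pooled,
        posterior_probability=pP,
        best_id=int(ids[best]),
        runner_up_id=int(ids[runner]),
        bayes_factor=bf,
    )
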