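"""Synthetic study generation and the end-to-end analysis pipeline.

Emulates the study conditions the analysis assumes: a 25-subject cohort, a
5-region right-lateralised network (TH, S1, AIC, MCC, MFG) with driving
input to the thalamus and deviant-vs-standard modulation of every
connection, a roving oddball session of 158 trains at 2 s ISI sampled over
1109 volumes at TR = 1.54 s, and post-scan difficulty ratings (0-100 VAS)
negatively coupled to the MFG->AIC modulation parameter.

Between-subject variation is Gaussian about configurable group means;
unstable draws are rejected and redrawn. The rating model's residual SD is
calibrated from the slope, the predictor's population SD, and a target
population R^2, so the strength of the rating-connectivity coupling is a
single interpretable number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dcm import (
    DCMParameters,
    HemodynamicParameters,
    InstabilityError,
    NetworkSpec,
    RegionTimeseries,
    build_input_sticks,
    check_stability,
    simulate_timeseries,
)
from .design import StimulusSequence, generate_sequence
from .group import GroupAnalysisResult, run_group_analysis
from .inversion import (
    InversionSettings,
    ParameterPacker,
    PosteriorDensity,
    PriorDensity,
    default_priors,
    variational_laplace,
)
from .reduction import (
    ModelComparison,
    ModelSpace,
    enumerate_models,
    ffx_pool,
    score_model_space,
)

logger = logging.getLogger(__name__)

#: Hierarchy used for the default group-mean sign pattern: forward
#: connections run caudal -> rostral (TH lowest, MFG highest).
FORWARD_PAIRS = (
    ("TH", "S1"), ("TH", "AIC"),
    ("S1", "AIC"), ("S1", "MCC"), ("S1", "MFG"),
    ("AIC", "MCC"), ("AIC", "MFG"),
    ("MCC", "MFG"),
)


def default_group_means(spec: NetworkSpec,
                        a_self: float = -0.5,
                        a_forward: float = 0.2,
                        a_backward: float = 0.1,
                        b_forward: float = 0.25,
                        b_self: float = 0.15,
                        c_drive: float = 0.8) -> dict[str, float]:
    """Illustrative group-mean coupling pattern.

    Positive deviant modulation of the forward hierarchy, of the AIC->S1
    backward connection, and (disinhibitory) of the TH/S1/AIC
    self-connections; magnitudes are package defaults, not measured values.
    """
    packer = ParameterPacker(spec)
    means = {name: 0.0 for name in packer.names}
    regions = spec.regions
    fwd = {(s, t) for (s, t) in FORWARD_PAIRS if s in regions and t in regions}
    for i, tgt in enumerate(regions):
        for j, src in enumerate(regions):
            a_name = f"A({tgt}<-{src})"
            if a_name in means:
                if i == j:
                    means[a_name] = a_self
                elif (src, tgt) in fwd:
                    means[a_name] = a_forward
                elif (tgt, src) in fwd:
                    means[a_name] = a_backward
    mod = spec.n_inputs - 1  # deviant modulator is the last input by convention
    for src, tgt in fwd:
        name = f"B{mod}({tgt}<-{src})"
        if name in means:
            means[name] = b_forward
    for name in (f"B{mod}(S1<-AIC)",):
        if name in means:
            means[name] = b_forward
    for r in ("TH", "S1", "AIC"):
        name = f"B{mod}({r}<-{r})"
        if name in means:
            means[name] = b_self
    for name in means:
        if name.startswith("C("):
            means[name] = c_drive
    return means


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    spec: NetworkSpec = field(default_factory=NetworkSpec.full_model)
    n_subjects: int = 25
    group_means: dict[str, float] | None = None
    between_subject_sd: float | dict[str, float] = 0.1
    snr: float = 2.0  # signal SD / noise SD of the simulated BOLD
    n_trains: int = 158
    isi: float = 2.0
    TR: float = 1.54
    n_volumes: int = 1109
    substeps: int = 16
    # rating model: difficulty = intercept + slope * designated B + residual
    rating_parameter: str = "B1(AIC<-MFG)"  # MFG -> AIC modulation
    rating_slope: float = -60.0  # VAS units per Hz (negative coupling)
    rating_intercept: float = 35.0
    target_r_squared: float = 0.3804  # population R^2 of the rating model
    intensity_diff_mean: float = 11.0
    intensity_diff_sd: float = 19.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 < self.target_r_squared < 1:
            raise ValueError("target_r_squared must lie in (0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        packer = ParameterPacker(self.spec)
        if self.group_means is None:
            self.group_means = default_group_means(self.spec)
        unknown = set(self.group_means) - set(packer.names)
        if unknown:
            raise ValueError(f"unknown parameters in group_means: {sorted(unknown)}")
        if self.rating_parameter not in packer.names:
            raise ValueError(
                f"designated rating parameter '{self.rating_parameter}' not in the network spec")

    def sd_for(self, name: str) -> float:
        if isinstance(self.between_subject_sd, dict):
            return float(self.between_subject_sd.get(name, 0.0))
        return float(self.between_subject_sd)


@dataclass
class SyntheticSubject:
    index: int
    seed: int
    params: DCMParameters
    sequence: StimulusSequence
    timeseries: RegionTimeseries
    difficulty: float
    intensity_difference: float


@dataclass
class RecoveryReport:
    correlation_group_mean_B: float
    winner_id: int
    winner_keep: np.ndarray
    generating_families_selected: bool


@dataclass
class FullAnalysisResult:
    comparison: ModelComparison
    group: GroupAnalysisResult
    recovery: RecoveryReport
    posteriors: list[PosteriorDensity]
    subjects: list[SyntheticSubject]


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def sample_subject_parameters(cfg: CohortConfig, subject_index: int,
                              seed: int | None = None,
                              max_attempts: int = 100) -> DCMParameters:
    """Gaussian draw of one subject's coupling parameters about the group
    means, rejecting draws that violate the stability invariant."""
    if seed is None:
        seed = _subject_seeds(cfg.master_seed, cfg.n_subjects)[subject_index]
    rng = np.random.default_rng(seed)
    packer = ParameterPacker(cfg.spec)
    means = np.array([cfg.group_means.get(nm, 0.0) for nm in packer.names])
    sds = np.array([cfg.sd_for(nm) for nm in packer.names])
    mod_inputs = np.array([[0.0] * cfg.spec.n_inputs,
                           *([_unit(cfg.spec.n_inputs, k, s)
                              for k in range(cfg.spec.n_inputs) for s in (1.0, -1.0)])])
    for attempt in range(max_attempts):
        theta = rng.normal(means, sds)
        # keep self-connections negative regardless of the draw
        for m, nm in enumerate(packer.names):
            if nm.startswith("A(") and _is_self(nm):
                theta[m] = -abs(theta[m]) if theta[m] != 0 else -0.05
        try:
            p = packer.unpack(theta)
            check_stability(p, mod_inputs)
            if attempt > 0:
                logger.info("subject %d: %d unstable draws rejected",
                            subject_index, attempt)
            return p
        except (InstabilityError, ValueError):
            continue
    raise ValueError(
        f"could not draw stable parameters for subject {subject_index} in "
        f"{max_attempts} attempts; group means {cfg.group_means} may be too strong")


def _unit(n: int, k: int, s: float) -> list[float]:
    v = [0.0] * n
    v[k] = s
    return v


def _is_self(name: str) -> bool:
    inner = name[name.index("(") + 1:name.rindex(")")]
    tgt, src = inner.split("<-")
    return tgt == src


def residual_sd_for_target_r2(slope: float, predictor_sd: float,
                              target_r2: float) -> float:
    """Residual SD giving population R^2 = target for a linear rating model."""
    if predictor_sd <= 0:
        raise ValueError("degenerate predictor: zero population SD")
    explained_sd = abs(slope) * predictor_sd
    return explained_sd * np.sqrt(1.0 / target_r2 - 1.0)


def generate_ratings(cfg: CohortConfig, true_params: pd.DataFrame,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-subject difficulty and intensity-difference ratings.

    Difficulty is linearly coupled to the designated modulatory parameter
    with residual SD calibrated to the target population R^2; ratings are
    clipped to the 0-100 VAS (clipping logged). Intensity-difference ratings
    are drawn independently of connectivity — the null control.
    """
    if cfg.rating_parameter not in true_params.columns:
        raise ValueError(f"'{cfg.rating_parameter}' missing from the truth table")
    rng = np.random.default_rng(cfg.master_seed + 1 if seed is None else seed)
    beta = true_params[cfg.rating_parameter].to_numpy(dtype=float)
    sigma = residual_sd_for_target_r2(
        cfg.rating_slope, cfg.sd_for(cfg.rating_parameter), cfg.target_r_squared)
    mean_beta = cfg.group_means.get(cfg.rating_parameter, 0.0)
    difficulty = (cfg.rating_intercept
                  + cfg.rating_slope * (beta - mean_beta)
                  + rng.normal(0.0, sigma, size=beta.size))
    clipped = (difficulty < 0) | (difficulty > 100)
    if clipped.any():
        logger.info("generate_ratings: %d ratings clipped to the VAS bounds",
                    int(clipped.sum()))
    difficulty = np.clip(difficulty, 0.0, 100.0)
    intensity_diff = np.clip(
        rng.normal(cfg.intensity_diff_mean, cfg.intensity_diff_sd, size=beta.size),
        -100.0, 100.0)
    return pd.DataFrame(
        {"difficulty": difficulty, "intensity_difference": intensity_diff},
        index=true_params.index,
    )


def generate_subject(cfg: CohortConfig, subject_index: int) -> SyntheticSubject:
    """Sequence, true parameters and noisy BOLD for one subject.

    Noise SD is set from the subject's own noise-free signal SD divided by
    the configured SNR. Ratings are filled in at cohort level.
    """
    seed = _subject_seeds(cfg.master_seed, cfg.n_subjects)[subject_index]
    params = sample_subject_parameters(cfg, subject_index, seed=seed)
    seq = generate_sequence(cfg.n_trains, isi=cfg.isi, seed=seed + 1)
    u = build_input_sticks(seq, cfg.n_volumes, cfg.TR, substeps=cfg.substeps)
    clean = simulate_timeseries(params, u, TR=cfg.TR, n_volumes=cfg.n_volumes,
                                noise_sd=0.0, substeps=cfg.substeps)
    signal_sd = clean.values.std(axis=0).mean()
    noise_sd = signal_sd / cfg.snr if signal_sd > 0 else 1e-3
    rng = np.random.default_rng(seed + 2)
    noisy = RegionTimeseries(
        values=clean.values + rng.normal(0.0, noise_sd, size=clean.values.shape),
        TR=cfg.TR, regions=clean.regions)
    return SyntheticSubject(index=subject_index, seed=seed, params=params,
                            sequence=seq, timeseries=noisy,
                            difficulty=np.nan, intensity_difference=np.nan)


def generate_cohort(cfg: CohortConfig) -> tuple[list[SyntheticSubject], pd.DataFrame, pd.DataFrame]:
    """All subjects plus the truth table and ratings table."""
    subjects = [generate_subject(cfg, i) for i in range(cfg.n_subjects)]
    packer = ParameterPacker(cfg.spec)
    truth = pd.DataFrame(
        [packer.pack(s.params) for s in subjects],
        columns=list(packer.names),
        index=[f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)],
    )
    ratings = generate_ratings(cfg, truth)
    for s, (_, row) in zip(subjects, ratings.iterrows()):
        s.difficulty = float(row["difficulty"])
        s.intensity_difference = float(row["intensity_difference"])
    return subjects, truth, ratings


def default_model_space(spec: NetworkSpec) -> tuple[ModelSpace, np.ndarray]:
    """Illustrative 8-family space over the full 5-region model (256 models).

    Families: thalamocortical A, forward corticocortical A, backward
    corticocortical A, thalamocortical B, forward B, backward B, self B, and
    driving C. A self-connections are never switched off. Returns the space
    and the indices of the switchable parameters in packed order.
    """
    packer = ParameterPacker(spec)
    names = packer.names
    regions = spec.regions
    fwd = {(s, t) for (s, t) in FORWARD_PAIRS if s in regions and t in regions}

    def classify(name: str) -> str | None:
        kind = name[0]
        if kind not in ("A", "B", "C"):
            return None
        if kind == "C":
            return "C_drive"
        inner = name[name.index("(") + 1:name.rindex(")")]
        tgt, src = inner.split("<-")
        if kind == "A" and tgt == src:
            return None  # self-decay stays in every model
        if tgt == src:
            return "B_self"
        thal = "TH" in (tgt, src)
        direction = "forward" if (src, tgt) in fwd else "backward"
        if kind == "A":
            return "A_thalamocortical" if thal else f"A_{direction}"
        return "B_thalamocortical" if thal else f"B_{direction}"

    fam_order = ["A_thalamocortical", "A_forward", "A_backward",
                 "B_thalamocortical", "B_forward", "B_backward",
                 "B_self", "C_drive"]
    families: dict[str, list[int]] = {f: [] for f in fam_order}
    for idx, name in enumerate(names):
        fam = classify(name)
        if fam is not None and fam in families:
            families[fam].append(idx)
    families = {f: m for f, m in families.items() if m}
    space = ModelSpace(families=families)
    switch_idx = np.array([i for m in families.values() for i in m])
    return space, switch_idx


def run_full_analysis(
    cfg: CohortConfig,
    space: ModelSpace | None = None,
    switch_idx: np.ndarray | None = None,
    settings: InversionSettings | None = None,
    priors: PriorDensity | None = None,
) -> FullAnalysisResult:
    """Generate a cohort, invert every subject, select among reduced models
    by BMR + FFX pooling, and run the group statistics.

    The recovery report compares generating and estimated group-mean
    modulatory parameters and records whether the winning model retains
    exactly the families that were switched on in generation.
    """
    subjects, truth, ratings = generate_cohort(cfg)
    priors = priors or default_priors(cfg.spec)
    settings = settings or InversionSettings()
    if space is None or switch_idx is None:
        space, switch_idx = default_model_space(cfg.spec)

    posteriors = []
    for s in subjects:
        u = build_input_sticks(s.sequence, cfg.n_volumes, cfg.TR,
                               substeps=cfg.substeps)
        try:
            post = variational_laplace(s.timeseries, cfg.spec, u, priors=priors,
                                       settings=settings, substeps=cfg.substeps)
        except Exception as exc:
            raise RuntimeError(f"inversion failed for subject {s.index}") from exc
        posteriors.append(post)

    try:
        logev = score_model_space(posteriors, priors, space, switch_idx)
        comparison = ffx_pool(logev)
    except Exception as exc:
        raise RuntimeError("model reduction / comparison failed") from exc

    winner = next(m for m in enumerate_models(space) if m.id == comparison.best_id)

    packer = ParameterPacker(cfg.spec)
    b_cols = [i for i, nm in enumerate(packer.names) if nm.startswith("B")]
    est = pd.DataFrame([p.mean for p in posteriors], columns=list(packer.names),
                       index=truth.index)
    true_b = truth.iloc[:, b_cols].mean(axis=0).to_numpy()
    est_b = est.iloc[:, b_cols].mean(axis=0).to_numpy()
    corr = float(np.corrcoef(true_b, est_b)[0, 1]) if np.std(true_b) > 0 else np.nan

    # which families were on in generation: a family counts as "on" if any of
    # its parameters has a nonzero group mean
    gen_on = np.array([
        any(abs(cfg.group_means.get(packer.names[i], 0.0)) > 0 for i in members)
        for members in space.families.values()
    ])
    offsets = np.cumsum([0] + [len(m) for m in space.families.values()])
    win_on = np.array([winner.keep_mask[offsets[f]:offsets[f + 1]].any()
                       for f in range(space.n_families)])
    generating_selected = bool(np.all(win_on == gen_on))

    try:
        group = run_group_analysis(
            est[[packer.names[i] for i in b_cols
                 if packer.names[i].startswith(f"B{cfg.spec.n_inputs - 1}")]],
            ratings)
    except Exception as exc:
        raise RuntimeError("group-level statistics failed") from exc

    recovery = RecoveryReport(
        correlation_group_mean_B=corr,
        winner_id=comparison.best_id,
        winner_keep=winner.keep_mask,
        generating_families_selected=generating_selected,
    )
    return FullAnalysisResult(comparison=comparison, group=group,
                              recovery=recovery, posteriors=posteriors,
                              subjects=subjects)
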