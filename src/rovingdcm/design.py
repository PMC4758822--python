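"""Roving oddball stimulus sequences, HRF design regressors, and the
adaptive threshold staircase.

The roving oddball paradigm presents trains of identical stimuli whose
intensity switches at unpredictable times. The first stimulus of each new
train is the *deviant*; the third repetition of that intensity is the
designated *standard*; remaining repetitions are unmodelled fillers. Train
lengths are drawn uniformly from {3, ..., 7} repetitions, so a standard
(position 3) exists in every train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

TRAIN_LENGTHS = (3, 4, 5, 6, 7)

DEVIANT = "deviant"
STANDARD = "standard"
FILLER = "filler"


class StaircaseError(RuntimeError):
    """Raised when the staircase fails to reach 8 reversals within the trial cap."""

    def __init__(self, message: str, trial_log: list[tuple[float, bool]]):
        super().__init__(message)
        self.trial_log = trial_log


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus presentation.

    onset is in seconds from run start; position is the 1-based index within
    the event's train. The label follows the roving-oddball convention:
    deviant iff position 1, standard iff position 3, filler otherwise.
    """

    onset: float
    intensity: str  # "low" or "high"
    position: int
    label: str


@dataclass
class StimulusSequence:
    """An ordered roving-oddball stimulus stream.

    Events are spaced exactly ``isi`` seconds apart, across train boundaries
    included; intensities alternate between consecutive trains.
    """

    events: list[StimulusEvent]
    isi: float
    n_trains: int
    seed: int

    @property
    def deviants(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.label == DEVIANT]

    @property
    def standards(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.label == STANDARD]

    def to_frame(self) -> pd.DataFrame:
        """BIDS-events-style table (onset, duration, trial_type, intensity_level, train_position)."""
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": 0.0,
                "trial_type": [e.label for e in self.events],
                "intensity_level": [e.intensity for e in self.events],
                "train_position": [e.position for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, isi: float | None = None, seed: int = -1) -> "StimulusSequence":
        df = pd.read_csv(path, sep="\t")
        events = [
            StimulusEvent(
                onset=float(r.onset),
                intensity=str(r.intensity_level),
                position=int(r.train_position),
                label=str(r.trial_type),
            )
            for r in df.itertuples()
        ]
        if isi is None:
            onsets = df["onset"].to_numpy()
            isi = float(np.diff(onsets).mean()) if len(onsets) > 1 else 2.0
        n_trains = sum(1 for e in events if e.label == DEVIANT)
        return cls(events=events, isi=float(isi), n_trains=n_trains, seed=seed)


@dataclass
class DesignRegressors:
    """HRF-convolved regressors sampled at volume onsets.

    ``all_conditions`` encodes every modelled trial (deviants and standards)
    with weight +1; ``modulator`` is the parametric deviant-vs-standard
    contrast with weight +1 for deviants and -1 for standards.
    """

    times: np.ndarray
    all_conditions: np.ndarray
    modulator: np.ndarray
    TR: float


@dataclass
class StaircaseResult:
    reversal_intensities: list[float]
    threshold: float
    trial_log: list[tuple[float, bool]]


def generate_sequence(
    n_trains: int,
    isi: float = 2.0,
    seed: int = 0,
    initial_intensity: str = "low",
) -> StimulusSequence:
    """Generate a roving oddball sequence of ``n_trains`` trains.

    Train lengths are i.i.d. uniform on {3,...,7}; intensities strictly
    alternate between trains starting from ``initial_intensity``; events are
    laid out at exact ``isi`` spacing. Deterministic given ``seed``.
    """
    if n_trains < 1:
        raise ValueError(f"n_trains must be >= 1, got {n_trains}")
    if isi <= 0:
        raise ValueError(f"isi must be > 0, got {isi}")
    if initial_intensity not in ("low", "high"):
        raise ValueError("initial_intensity must be 'low' or 'high'")

    rng = np.random.default_rng(seed)
    lengths = rng.choice(TRAIN_LENGTHS, size=n_trains)
    events: list[StimulusEvent] = []
    intensity = initial_intensity
    i_event = 0
    for length in lengths:
        for pos in range(1, int(length) + 1):
            label = DEVIANT if pos == 1 else (STANDARD if pos == 3 else FILLER)
            events.append(
                StimulusEvent(onset=i_event * isi, intensity=intensity, position=pos, label=label)
            )
            i_event += 1
        intensity = "high" if intensity == "low" else "low"
    return StimulusSequence(events=events, isi=isi, n_trains=n_trains, seed=seed)


def canonical_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  peak_disp: float = 1.0, under_disp: float = 1.0,
                  ratio: float = 6.0, support: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, unit-normalised to peak 1.

    Response gamma peaks at 6 s, undershoot gamma at 16 s (dispersions 1 s,
    peak:undershoot amplitude ratio 6); zero outside [0, support].
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = (t >= 0) & (t <= support)
    tt = t[m]
    a1, b1 = peak / peak_disp, 1.0 / peak_disp
    a2, b2 = undershoot / under_disp, 1.0 / under_disp

    def _gpdf(x, a, b):
        with np.errstate(divide="ignore"):
            logpdf = a * np.log(b) + (a - 1) * np.log(np.maximum(x, 1e-300)) - b * x - gammaln(a)
        return np.where(x > 0, np.exp(logpdf), 0.0)

    h = _gpdf(tt, a1, b1) - _gpdf(tt, a2, b2) / ratio
    out[m] = h
    # normalise so the sampled-at-fine-grid peak equals 1
    tg = np.linspace(0, support, 4097)
    hg = _gpdf(tg, a1, b1) - _gpdf(tg, a2, b2) / ratio
    out /= hg.max()
    return out


def build_design_regressors(
    seq: StimulusSequence,
    n_volumes: int,
    TR: float,
    hrf: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DesignRegressors:
    """Build the all-conditions and ±1 parametric-modulator regressors.

    Each deviant/standard event contributes the HRF sampled at volume-onset
    times relative to its onset; deviants weigh +1 and standards -1 in the
    modulator. Fillers contribute to neither regressor. Events past the run
    end are dropped with a warning.
    """
    if n_volumes < 1:
        raise ValueError(f"n_volumes must be >= 1, got {n_volumes}")
    if TR <= 0:
        raise ValueError(f"TR must be > 0, got {TR}")
    if hrf is None:
        hrf = canonical_hrf

    times = np.arange(n_volumes) * TR
    run_end = n_volumes * TR
    all_conditions = np.zeros(n_volumes)
    modulator = np.zeros(n_volumes)

    modelled = [e for e in seq.events if e.label in (DEVIANT, STANDARD)]
    kept = [e for e in modelled if e.onset < run_end]
    if len(kept) < len(modelled):
        logger.warning(
            "build_design_regressors: truncated %d events beyond run end (%.1f s)",
            len(modelled) - len(kept), run_end,
        )
    for e in kept:
        h = hrf(times - e.onset)
        all_conditions += h
        modulator += h if e.label == DEVIANT else -h
    return DesignRegressors(times=times, all_conditions=all_conditions,
                            modulator=modulator, TR=TR)


class LogisticObserver:
    """Stochastic observer detecting with probability 1/(1+exp(-(x-threshold)/slope))."""

    def __init__(self, threshold: float, slope: float):
        if slope <= 0:
            raise ValueError("slope must be > 0")
        self.threshold = threshold
        self.slope = slope

    def detection_probability(self, intensity: float) -> float:
        return 1.0 / (1.0 + np.exp(-(intensity - self.threshold) / self.slope))

    def intensity_at(self, p: float) -> float:
        """Intensity detected with probability p (inverse psychometric function)."""
        return self.threshold + self.slope * np.log(p / (1.0 - p))

    def __call__(self, intensity: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.detection_probability(intensity))


class HardThresholdObserver:
    """Deterministic observer: detects iff intensity >= threshold."""

    def __init__(self, threshold: float):
        self.threshold = threshold

    def __call__(self, intensity: float, rng: np.random.Generator) -> bool:
        return intensity >= self.threshold


#: A one-up/three-down rule converges on the intensity detected with
#: probability (1/2)^(1/3) ~ 0.7937.
ONE_UP_THREE_DOWN_P = 0.5 ** (1.0 / 3.0)


def run_staircase(
    observer: Callable[[float, np.random.Generator], bool],
    start_intensity: float,
    start_step: float | None = None,
    seed: int = 0,
    n_reversals: int = 8,
    max_trials: int = 1000,
    floor: float = 0.1,
) -> StaircaseResult:
    """One-up/three-down adaptive staircase.

    Intensity increases by the current step after a single miss and decreases
    after three consecutive hits. The step halves after every two reversals;
    the run terminates at the ``n_reversals``-th reversal and the threshold is
    the arithmetic mean of the reversal intensities. Intensities are clipped
    at ``floor`` (clipping logged). Default starting step is 20% of the
    starting intensity.
    """
    if start_intensity <= 0:
        raise ValueError("start_intensity must be > 0")
    if start_step is None:
        start_step = 0.2 * start_intensity
    if start_step <= 0:
        raise ValueError("start_step must be > 0")

    rng = np.random.default_rng(seed)
    intensity = float(start_intensity)
    step = float(start_step)
    consecutive_hits = 0
    last_direction = 0
    reversals: list[float] = []
    trial_log: list[tuple[float, bool]] = []

    for _ in range(max_trials):
        hit = bool(observer(intensity, rng))
        trial_log.append((intensity, hit))
        if hit:
            consecutive_hits += 1
            if consecutive_hits < 3:
                continue
            consecutive_hits = 0
            direction = -1
        else:
            consecutive_hits = 0
            direction = +1
        if last_direction != 0 and direction != last_direction:
            reversals.append(intensity)
            if len(reversals) >= n_reversals:
                return StaircaseResult(
                    reversal_intensities=reversals,
                    threshold=float(np.mean(reversals)),
                    trial_log=trial_log,
                )
            if len(reversals) % 2 == 0:
                step /= 2.0
        last_direction = direction
        new_intensity = intensity + direction * step
        if new_intensity < floor:
            logger.info("run_staircase: intensity clipped at floor %.3f mA", floor)
            new_intensity = floor
        intensity = new_intensity

    raise StaircaseError(
        f"staircase did not reach {n_reversals} reversals within {max_trials} trials",
        trial_log,
    )
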