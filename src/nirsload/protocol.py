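"""n-back experiment protocol.

The n-back task presents a stream of letters; the participant responds
whenever the current letter matches the one shown n positions earlier (a
*target*).  Workload scales with n.  A session interleaves 1-, 2- and
3-back trials in pseudo-random order, with rest crosses between trials,
dedicated 10 s relax probes after half of the trials, and one mid-session
break.

This module generates stimulus sequences, scores behavioral responses,
builds the session timeline, segments a continuous recording into labeled
trials, and extracts analysis windows from trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

#: Stimulus alphabet: uppercase consonants (standard n-back practice; the
#: exact letter set does not affect the signal analysis).
ALPHABET: str = "BCDFGHJKLMNPQRSTVWXZ"

N_LETTERS: int = 22          # letters per trial
SOA_S: float = 2.0           # stimulus onset asynchrony
DISPLAY_DUR_S: float = 0.5   # letter on screen
INSTRUCTION_S: float = 5.0
TASK_S: float = 44.0         # 22 letters x 2 s
REST_S: float = 15.0
RELAX_PROBE_S: float = 10.0
BREAK_S: float = 150.0

CONDITIONS: tuple[int, ...] = (1, 2, 3)
TRIALS_PER_CONDITION: int = 10
N_TASK_TRIALS: int = TRIALS_PER_CONDITION * len(CONDITIONS)
N_RELAX_PROBES: int = 15

#: Integer label used for relax trials/windows (task trials carry their n).
RELAX_LABEL: int = 0

#: Total session duration: 30 trials of 64 s + 15 relax probes of 10 s +
#: one 150 s break = 2220 s = 37 min.
SESSION_DURATION_S: float = (
    N_TASK_TRIALS * (INSTRUCTION_S + TASK_S + REST_S)
    + N_RELAX_PROBES * RELAX_PROBE_S
    + BREAK_S
)


class InvalidConditionError(ValueError):
    """Raised when a workload level outside {1, 2, 3} is requested."""


class InvalidWindowError(ValueError):
    """Raised when a window specification does not fit its trial."""


class TruncationError(ValueError):
    """Raised when a recording is shorter than the timeline it should cover."""


# ---------------------------------------------------------------------------
# stimulus sequences


@dataclass
class StimulusSequence:
    """One trial's letter stream with target annotations."""

    n: int
    letters: list[str]
    target_flags: np.ndarray
    soa: float = SOA_S
    display_dur: float = DISPLAY_DUR_S

    @property
    def n_targets(self) -> int:
        return int(np.count_nonzero(self.target_flags))

    def target_positions(self) -> np.ndarray:
        return np.flatnonzero(self.target_flags)


@dataclass
class BehavioralCounts:
    """Hit/miss bookkeeping for one trial."""

    misses: int
    false_alarms: int
    n_targets: int


def compute_target_flags(letters: list[str], n: int) -> np.ndarray:
    """Target definition: position i is a target iff letters[i] == letters[i-n]."""
    flags = np.zeros(len(letters), dtype=bool)
    for i in range(n, len(letters)):
        flags[i] = letters[i] == letters[i - n]
    return flags


def generate_nback_sequence(n: int, rng_seed: int) -> StimulusSequence:
    """Generate a 22-letter n-back trial with 3 +/- 1 targets.

    The target count is drawn uniformly from {2, 3, 4}; letter streams are
    then rejection-sampled until the recomputed target count matches.  This
    keeps the target distribution uniform while allowing arbitrary target
    placements, including chained targets (e.g. three equal letters in a
    row under 1-back).
    """
    if n not in CONDITIONS:
        raise InvalidConditionError(f"n must be one of {CONDITIONS}, got {n!r}")
    rng = np.random.default_rng(rng_seed)
    wanted = int(rng.integers(2, 5))
    alphabet = np.array(list(ALPHABET))
    while True:
        letters = [str(c) for c in rng.choice(alphabet, size=N_LETTERS)]
        flags = compute_target_flags(letters, n)
        if int(flags.sum()) == wanted:
            return StimulusSequence(n=n, letters=letters, target_flags=flags)


def score_responses(seq: StimulusSequence, responses: list[int]) -> BehavioralCounts:
    """Count missed targets and false alarms for a set of response positions."""
    responses = list(responses)
    for pos in responses:
        if not 0 <= pos < len(seq.letters):
            raise IndexError(f"response position {pos} outside sequence of length {len(seq.letters)}")
    resp = set(responses)
    targets = set(int(i) for i in seq.target_positions())
    misses = len(targets - resp)
    false_alarms = len(resp - targets)
    return BehavioralCounts(misses=misses, false_alarms=false_alarms, n_targets=len(targets))


# ---------------------------------------------------------------------------
# session timeline


@dataclass(frozen=True)
class TimelineEvent:
    onset_s: float
    duration_s: float
    kind: str  # instruction | task | rest | relax_probe | break
    condition: int | None = None  # n for instruction/task events

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SessionTimeline:
    """Ordered, contiguous, non-overlapping session events."""

    events: list[TimelineEvent]
    sampling_rate: float = 25.0

    @property
    def duration_s(self) -> float:
        return self.events[-1].end_s if self.events else 0.0

    def task_events(self) -> list[TimelineEvent]:
        return [e for e in self.events if e.kind == "task"]

    def relax_events(self) -> list[TimelineEvent]:
        return [e for e in self.events if e.kind == "relax_probe"]

    def validate(self) -> None:
        t = 0.0
        for e in self.events:
            if abs(e.onset_s - t) > 1e-9:
                raise ValueError(f"event at {e.onset_s} s not contiguous (expected {t} s)")
            if e.duration_s <= 0:
                raise ValueError("non-positive event duration")
            t = e.end_s


def build_session_timeline(rng_seed: int) -> SessionTimeline:
    """Assemble the 37 min session.

    30 task trials (10 per condition, pseudo-random order), each 5 s
    instruction + 44 s task + 15 s rest; a 10 s relax probe appended to the
    rest period of 15 pseudo-randomly chosen trials; a 150 s break after
    trial 15.
    """
    rng = np.random.default_rng(rng_seed)
    order = np.repeat(CONDITIONS, TRIALS_PER_CONDITION)
    rng.shuffle(order)
    probe_trials = set(rng.choice(N_TASK_TRIALS, size=N_RELAX_PROBES, replace=False).tolist())

    events: list[TimelineEvent] = []
    t = 0.0

    def add(duration: float, kind: str, condition: int | None = None) -> None:
        nonlocal t
        events.append(TimelineEvent(onset_s=t, duration_s=duration, kind=kind, condition=condition))
        t += duration

    for trial_idx, cond in enumerate(order):
        add(INSTRUCTION_S, "instruction", int(cond))
        add(TASK_S, "task", int(cond))
        add(REST_S, "rest")
        if trial_idx in probe_trials:
            add(RELAX_PROBE_S, "relax_probe")
        if trial_idx == N_TASK_TRIALS // 2 - 1:
            add(BREAK_S, "break")

    timeline = SessionTimeline(events=events, sampling_rate=25.0)
    timeline.validate()
    assert abs(timeline.duration_s - SESSION_DURATION_S) < 1e-9
    return timeline


# ---------------------------------------------------------------------------
# trial segmentation and windows


@dataclass
class Trial:
    """A labeled segment of a recording (task trial or relax probe)."""

    data: np.ndarray  # (channel, chromophore, sample)
    label: int        # 1, 2, 3 for n-back; RELAX_LABEL for relax probes
    onset_s: float
    sampling_rate: float
    trial_id: int

    @property
    def duration_s(self) -> float:
        return self.data.shape[2] / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Offset/length of an analysis window relative to trial onset, seconds."""

    offset_s: float = 0.0
    length_s: float = 10.0

    def __post_init__(self) -> None:
        if self.offset_s < 0:
            raise InvalidWindowError(f"offset_s must be >= 0, got {self.offset_s}")
        if self.length_s <= 0:
            raise InvalidWindowError(f"length_s must be > 0, got {self.length_s}")


@dataclass
class Window:
    """One analysis window cut from a trial."""

    data: np.ndarray  # (channel, chromophore, sample)
    label: int
    trial_id: int
    offset_s: float
    length_s: float


def _to_index(t: float, fs: float) -> int:
    return int(round(t * fs))


def segment_trials(recording: Recording, timeline: SessionTimeline) -> list[Trial]:
    """Cut a continuous recording into labeled trials.

    Task events become 44 s trials labeled with their n; relax probes become
    10 s trials labeled :data:`RELAX_LABEL`.  Boundaries are half-open sample
    ranges ``[round(onset * fs), round(end * fs))``.
    """
    fs = recording.sampling_rate
    needed = _to_index(timeline.duration_s, fs)
    if recording.n_samples < needed:
        raise TruncationError(
            f"recording has {recording.n_samples} samples but timeline needs {needed}"
        )
    trials: list[Trial] = []
    trial_id = 0
    for event in timeline.events:
        if event.kind == "task":
            label = int(event.condition)
        elif event.kind == "relax_probe":
            label = RELAX_LABEL
        else:
            continue
        start = _to_index(event.onset_s, fs)
        stop = _to_index(event.end_s, fs)
        trials.append(
            Trial(
                data=recording.data[:, :, start:stop],
                label=label,
                onset_s=event.onset_s,
                sampling_rate=fs,
                trial_id=trial_id,
            )
        )
        trial_id += 1
    return trials


def extract_windows(trial: Trial, spec: WindowSpec, tiling: bool = False) -> list[Window]:
    """Extract analysis windows from a trial.

    With ``tiling`` the trial is cut into non-overlapping back-to-back
    windows from trial start (``floor(duration / length)`` of them); without
    it a single window is taken at ``spec.offset_s``.
    """
    fs = trial.sampling_rate
    n = trial.data.shape[2]
    length = _to_index(spec.length_s, fs)
    if length > n:
        raise InvalidWindowError(
            f"window of {spec.length_s} s does not fit trial of {trial.duration_s} s"
        )
    windows: list[Window] = []
    if tiling:
        for k in range(n // length):
            start = k * length
            windows.append(
                Window(
                    data=trial.data[:, :, start : start + length],
                    label=trial.label,
                    trial_id=trial.trial_id,
                    offset_s=start / fs,
                    length_s=spec.length_s,
                )
            )
    else:
        start = _to_index(spec.offset_s, fs)
        if start + length > n:
            raise InvalidWindowError(
                f"window [{spec.offset_s}, {spec.offset_s + spec.length_s}) s "
                f"does not fit trial of {trial.duration_s} s"
            )
        windows.append(
            Window(
                data=trial.data[:, :, start : start + length],
                label=trial.label,
                trial_id=trial.trial_id,
                offset_s=spec.offset_s,
                length_s=spec.length_s,
            )
        )
    return windows
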