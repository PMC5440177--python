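"""Frame timing, radiodecay handling, frame summation and TAC weighting.

Dynamic PET data arrive as a sequence of acquisition frames of increasing
length.  Everything downstream (compartmental fits, graphical and spectral
analyses, reference-tissue models) needs the same three ingredients from
this module: the frame schedule (start/end/duration of every frame and the
isotope decay constant), decay correction relative to scan start, and the
count-statistics frame weights used in weighted least-squares fitting.

Conventions
-----------
* The time origin is scan start; the tracer bolus is injected shortly
  after (default 30 s), so the first frame is essentially pre-injection.
* Frame indices exposed through the public interface are 1-based
  ("frames 16-21" means the 16th through 21st frame inclusive).
* Frame midpoints serve both as the decay-correction reference times and
  as the abscissa at which models are compared with measured frame values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: decay constant of carbon-11 in s^-1 (half-life ~20.4 min)
C11_DECAY_CONSTANT = 0.0005663

#: the standard 24-frame, 90.5-min acquisition: (count, duration_s) pairs
DEFAULT_FRAMING = ((1, 30.0), (4, 15.0), (4, 60.0), (2, 150.0), (10, 300.0), (3, 600.0))

#: maximum ROI-mode frame weight after normalisation
ROI_WEIGHT_CAP = 2.5

#: maximum allowed max/min ratio for voxel-mode weights
VOXEL_WEIGHT_RATIO_CAP = 1000.0


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame timing of a dynamic acquisition.

    Attributes
    ----------
    frame_start, frame_end : ndarray
        Seconds from scan start; frames are contiguous and ordered.
    injection_time : float
        Bolus injection time in seconds from scan start.
    decay_constant : float
        Isotope decay constant in s^-1.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    injection_time: float = 30.0
    decay_constant: float = C11_DECAY_CONSTANT

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("frame_start/frame_end must be equal-length 1-D arrays")
        if np.any(end <= start):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(start[1:], end[:-1]):
            raise ValueError("frames must be contiguous: frame_start[i+1] == frame_end[i]")
        if self.decay_constant <= 0:
            raise ValueError("decay_constant must be positive")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_duration(self) -> np.ndarray:
        """Frame lengths L_i in seconds."""
        return self.frame_end - self.frame_start

    @property
    def frame_mid(self) -> np.ndarray:
        """Frame midpoints in seconds from scan start."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])

    def frame_slice(self, first: int, last: int) -> slice:
        """0-based slice for the 1-based inclusive frame range [first, last]."""
        if not (1 <= first <= last <= self.n_frames):
            raise ValueError(
                f"frame range {first}-{last} invalid for {self.n_frames} frames"
            )
        return slice(first - 1, last)


@dataclass
class TimeActivityCurve:
    """Radioactivity concentration per frame (kBq/ml) in a region or voxel."""

    schedule: FrameSchedule
    activity: np.ndarray
    decay_corrected: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must equal the number of frames")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity values must be finite")


@dataclass
class FrameWeights:
    """Per-frame least-squares weights derived from count statistics.

    ``mode`` selects the normalisation contract: ROI weights are scaled to
    sum to the number of frames with a cap of 2.5 per frame; voxel weights
    keep their scale but the max/min ratio is bounded by 1000.
    """

    raw: np.ndarray
    trues_rate: np.ndarray | None = None
    mode: str = "roi"
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if np.any(self.raw < 0):
            raise ValueError("weights must be non-negative")

    @property
    def values(self) -> np.ndarray:
        """The weights to use in fitting (normalised if available)."""
        return self.raw if self.normalized is None else self.normalized


def build_frame_schedule(
    spec=DEFAULT_FRAMING,
    injection_time: float = 30.0,
    decay_constant: float = C11_DECAY_CONSTANT,
) -> FrameSchedule:
    """Build a contiguous schedule from (count, duration_s) pairs.

    The default spec is the 24-frame acquisition
    1x30 s, 4x15 s, 4x60 s, 2x150 s, 10x300 s, 3x600 s (total 5430 s).
    """
    spec = list(spec)
    if not spec:
        raise ValueError("frame spec must not be empty")
    durations = []
    for count, dur in spec:
        if count < 1:
            raise ValueError("frame count must be >= 1")
        if dur <= 0:
            raise ValueError("frame duration must be positive")
        durations.extend([float(dur)] * int(count))
    end = np.cumsum(durations)
    start = np.concatenate([[0.0], end[:-1]])
    return FrameSchedule(start, end, injection_time, decay_constant)


def decay_correct(tac: TimeActivityCurve, direction: str = "apply") -> TimeActivityCurve:
    """Apply or remove decay correction at frame midpoints.

    ``apply`` multiplies each frame by exp(+lambda * t_mid) and requires
    uncorrected input; ``remove`` is the exact inverse.  The round trip is
    the identity.
    """
    lam = tac.schedule.decay_constant
    factors = np.exp(lam * tac.schedule.frame_mid)
    if direction == "apply":
        if tac.decay_corrected:
            raise ValueError("TAC is already decay-corrected")
        return TimeActivityCurve(tac.schedule, tac.activity * factors, True, tac.label)
    if direction == "remove":
        if not tac.decay_corrected:
            raise ValueError("TAC is not decay-corrected")
        return TimeActivityCurve(tac.schedule, tac.activity / factors, False, tac.label)
    raise ValueError("direction must be 'apply' or 'remove'")


def sum_frames(
    dyn: np.ndarray,
    schedule: FrameSchedule,
    frame_range: tuple[int, int],
    decay_corrected: bool = True,
) -> np.ndarray:
    """Duration-weighted mean image over a 1-based inclusive frame range.

    ``dyn`` is a 4-D array with the frame axis last.  If the input is not
    decay-corrected it is corrected at frame midpoints first, so the output
    is always a decay-corrected summation ('add') image in kBq/ml.
    """
    dyn = np.asarray(dyn, dtype=float)
    if dyn.shape[-1] != schedule.n_frames:
        raise ValueError("last axis of dyn must match the number of frames")
    sl = schedule.frame_slice(*frame_range)
    frames = dyn[..., sl]
    if not decay_corrected:
        frames = frames * np.exp(schedule.decay_constant * schedule.frame_mid[sl])
    dur = schedule.frame_duration[sl]
    return np.tensordot(frames, dur, axes=([-1], [0])) / dur.sum()


def compute_frame_weights(schedule: FrameSchedule, trues_rate: np.ndarray) -> FrameWeights:
    """Raw frame weights w_i = L_i / T_i.

    L_i is the frame length (s) and T_i the true-coincidence rate
    (counts/s) of the non-decay-corrected data, so long quiet frames get
    large weights relative to short busy ones.
    """
    trues_rate = np.asarray(trues_rate, dtype=float)
    if trues_rate.shape != (schedule.n_frames,):
        raise ValueError("trues_rate length must equal the number of frames")
    if np.any(trues_rate <= 0):
        raise ValueError("trues rate must be strictly positive")
    return FrameWeights(raw=schedule.frame_duration / trues_rate, trues_rate=trues_rate)


def normalize_weights(weights: FrameWeights, mode: str | None = None) -> FrameWeights:
    """Normalise raw weights per the ROI or voxel contract.

    ROI mode: scale to sum = n_frames, cap at 2.5, rescale; because the
    rescale can push a weight back over the cap this is iterated to a
    fixed point (at most 10 passes).  Voxel mode: no sum normalisation;
    the smallest weights are floored so that max/min <= 1000.
    """
    mode = mode or weights.mode
    w = weights.raw.astype(float).copy()
    if not np.any(w > 0):
        raise ValueError("all-zero weights cannot be normalised")
    n = w.size
    if mode == "roi":
        # exact fixed point of clip-then-rescale (water-filling): the
        # largest m weights sit at the cap, the rest share the remaining
        # mass proportionally, so sum == n and max <= cap hold together
        cap = ROI_WEIGHT_CAP
        order = np.argsort(w)[::-1]
        sorted_w = w[order]
        tail = np.concatenate([np.cumsum(sorted_w[::-1])[::-1], [0.0]])
        for m in range(n):
            scale = (n - cap * m) / tail[m]
            if sorted_w[m] * scale <= cap:
                break
        else:
            m, scale = n, 0.0
        out = np.empty(n)
        out[order[:m]] = cap
        out[order[m:]] = sorted_w[m:] * scale
        w = np.minimum(out * (n / out.sum()), cap)
    elif mode == "voxel":
        floor = w.max() / VOXEL_WEIGHT_RATIO_CAP
        w = np.maximum(w, floor)
    else:
        raise ValueError("mode must be 'roi' or 'voxel'")
    return replace(weights, mode=mode, normalized=w)


def uniform_weights(schedule: FrameSchedule) -> FrameWeights:
    """Equal weights (one per frame), already in normalised ROI form."""
    w = np.ones(schedule.n_frames)
    return FrameWeights(raw=w, mode="roi", normalized=w.copy())
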