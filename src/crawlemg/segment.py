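"""Crawling-cycle segmentation from the left-palm pressure signal.

During stance the palm loads the sensor and the pressure sits at a plateau;
during swing it returns to zero.  The first derivative of the (smoothed)
pressure is therefore ~0 within phases, sustained-positive at the swing→stance
transition and sustained-negative at stance→swing.  Cycle starting points are
the stance onsets; one crawling cycle spans two adjacent stance onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentationParams", "CycleBoundaries", "detect_cycles",
           "phase_durations", "slice_cycles"]


@dataclass(frozen=True)
class SegmentationParams:
    """Debouncing parameters for derivative-based onset detection.

    An idealized signal has an exactly-zero derivative between transitions; a
    measured one does not, so the signal is pre-smoothed, the derivative is
    thresholded at a fraction of its robust maximum, and phases shorter than
    ``min_phase_ms`` are rejected as bounce.
    """

    smooth_ms: float = 25.0
    deriv_frac: float = 0.10
    min_phase_ms: float = 100.0


@dataclass
class CycleBoundaries:
    """Alternating stance/swing onset sample indices of the left palm.

    The sequence starts with a stance onset ("cycle starting point") and
    alternates strictly; complete cycle ``i`` is the half-open sample interval
    ``[stance_onsets[i], stance_onsets[i+1])``.
    """

    stance_onsets: np.ndarray
    swing_onsets: np.ndarray
    sample_rate: float = field(default=1000.0)

    def __post_init__(self):
        self.stance_onsets = np.asarray(self.stance_onsets, dtype=np.int64)
        self.swing_onsets = np.asarray(self.swing_onsets, dtype=np.int64)
        merged = np.empty(self.stance_onsets.size + self.swing_onsets.size, dtype=np.int64)
        if self.swing_onsets.size not in (self.stance_onsets.size,
                                          self.stance_onsets.size - 1):
            raise ValueError("onsets must alternate stance, swing, stance, ...")
        merged[0::2] = self.stance_onsets
        merged[1::2] = self.swing_onsets
        if merged.size > 1 and np.any(np.diff(merged) <= 0):
            raise ValueError("onsets must alternate stance, swing, stance, ...")

    @property
    def n_cycles(self) -> int:
        return max(self.stance_onsets.size - 1, 0)


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x.astype(float)
    kernel = np.ones(win) / win
    pad = np.pad(x.astype(float), (win // 2, win - 1 - win // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_cycles(
    pressure: np.ndarray,
    sample_rate: float,
    params: SegmentationParams | None = None,
) -> CycleBoundaries:
    """Detect stance and swing onsets from the pressure first derivative.

    A stance onset is the first sample of a sustained positive-derivative run,
    a swing onset the first sample of a sustained negative run; candidates are
    debounced with the minimum phase duration, events before the first stance
    onset are discarded, and the sequence is truncated so that it starts and
    ends with a stance onset (incomplete trailing phases are dropped).

    Detection is invariant to positive rescaling of the signal because the
    threshold is a fraction of the derivative's robust maximum.
    """
    params = params or SegmentationParams()
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure contains non-finite samples")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    min_phase = int(round(params.min_phase_ms * sample_rate / 1000.0))
    if p.size < 2 * max(min_phase, 1):
        raise ValueError("signal shorter than two minimum phase durations")

    win = max(int(round(params.smooth_ms * sample_rate / 1000.0)), 1)
    deriv = np.gradient(_moving_average(p, win))
    robust_max = np.percentile(np.abs(deriv), 99.5)
    if robust_max <= 0:
        raise ValueError("no complete crawling cycle found (flat signal)")
    thr = params.deriv_frac * robust_max

    pos = deriv > thr
    neg = deriv < -thr
    # first samples of each sustained run
    cand = []
    for mask, kind in ((pos, "stance"), (neg, "swing")):
        starts = np.flatnonzero(mask & ~np.concatenate([[False], mask[:-1]]))
        cand.extend((int(s), kind) for s in starts)
    cand.sort()

    stance, swing = [], []
    expect = "stance"
    last = -np.inf
    for idx, kind in cand:
        if kind != expect:
            continue
        if idx - last < min_phase:
            continue
        (stance if kind == "stance" else swing).append(idx)
        last = idx
        expect = "swing" if kind == "stance" else "stance"
    # end on a stance onset: a trailing stance-only phase is incomplete
    if len(swing) == len(stance):
        swing = swing[:-1] if swing else swing
    if len(stance) < 2:
        raise ValueError("no complete crawling cycle found")
    return CycleBoundaries(np.array(stance), np.array(swing), sample_rate)


def phase_durations(
    boundaries: CycleBoundaries, sample_rate: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle stance and swing durations in seconds.

    stance_i = swing_onset_i − stance_onset_i;
    swing_i  = stance_onset_{i+1} − swing_onset_i.
    """
    fs = sample_rate or boundaries.sample_rate
    n = boundaries.n_cycles
    if n < 1:
        raise ValueError("need at least one complete cycle")
    st = boundaries.stance_onsets
    sw = boundaries.swing_onsets
    stance = (sw[:n] - st[:n]) / fs
    swing = (st[1 : n + 1] - sw[:n]) / fs
    return stance, swing


def slice_cycles(emg: np.ndarray, boundaries: CycleBoundaries) -> list[np.ndarray]:
    """Cut a (channels, T) signal into per-cycle segments.

    Cycle ``i`` is the half-open interval ``[stance_onsets[i],
    stance_onsets[i+1])``; concatenating the segments reproduces the spanned
    signal exactly.
    """
    emg = np.atleast_2d(np.asarray(emg))
    if boundaries.stance_onsets.size and boundaries.stance_onsets[-1] > emg.shape[1]:
        raise ValueError("boundaries exceed signal length")
    st = boundaries.stance_onsets
    return [emg[:, st[i] : st[i + 1]] for i in range(boundaries.n_cycles)]
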