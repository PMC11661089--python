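"""Breathing-dynamics statistics computed from trajectory ensembles.

Four observables characterise DNA breathing here:

* the average coordinate profile <y_i> — how far each base pair sits
  open in equilibrium;
* the base-flipping probability — the fraction of samples in which a
  pair's displacement equals or exceeds a threshold tr;
* the bubble probability P_n(l, tr) — the fraction of simulated time a
  maximal run of l simultaneously open pairs starts at position n,
  P = sum_k sum_q dt_q / (t_s * M) over M runs of recorded duration t_s;
* the bubble lifetime tau(n, l, tr) — the pooled mean duration of those
  events, total lifetime / total event count across all runs.

Two event semantics exist for "a bubble of length l at n": the *maximal*
semantics (the open run starts exactly at n and has exactly length l)
used for events, and the *containment* ("all-open occupancy") semantics
(positions n..n+l-1 are simultaneously open, whatever their context),
which is monotone in l and tr.  Both are exported, labelled.

All statistics are reported on the core span of the sequence (flanks are
buffers, not observables), with position indices relative to the core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import TrajectoryEnsemble
from .units import FS_PER_PS

__all__ = [
    "CoordinateProfile",
    "FlippingProfile",
    "BubbleEvent",
    "BubbleStatistics",
    "DEFAULT_FLIP_THRESHOLDS",
    "DEFAULT_BUBBLE_THRESHOLDS",
    "DEFAULT_BUBBLE_LENGTHS",
    "sweep",
    "average_coordinates",
    "flipping_probability",
    "detect_bubbles",
    "bubble_probability",
    "bubble_lifetime",
    "bubble_statistics",
    "all_open_occupancy",
    "assemble_ml_features",
    "decode_one_hot",
]


def sweep(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic sweep start, start+step, ..., <= stop (+eps)."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 6)


#: Five flipping thresholds, 0.7071 A to 3.5355 A in steps of 0.7071 A.
DEFAULT_FLIP_THRESHOLDS = sweep(0.7071, 3.5355, 0.7071)
#: Bubble amplitude thresholds, 0.5 A to 15.0 A in steps of 0.5 A.
DEFAULT_BUBBLE_THRESHOLDS = sweep(0.5, 15.0, 0.5)
#: Bubble lengths, 3 to 20 base pairs.
DEFAULT_BUBBLE_LENGTHS = np.arange(3, 21)


@dataclass(frozen=True)
class CoordinateProfile:
    """Per-position mean opening <y_i> (A) with between-run standard error."""

    positions: np.ndarray
    mean_y: np.ndarray
    stderr_y: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class FlippingProfile:
    """Flipping probability per threshold (rows) and core position (cols)."""

    thresholds: np.ndarray
    prob: np.ndarray

    def at(self, threshold: float) -> np.ndarray:
        (idx,) = np.nonzero(np.isclose(self.thresholds, threshold))
        if len(idx) == 0:
            raise KeyError(f"threshold {threshold} not in profile")
        return self.prob[idx[0]]


@dataclass(frozen=True)
class BubbleEvent:
    """One maximal opening event: positions [n, n+l) open over [start, end] frames."""

    n: int
    l: int
    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class BubbleStatistics:
    """Bubble probability and lifetime tensors over (position, length, threshold).

    ``p`` and ``q`` cover maximal events; ``tau`` (ps) is NaN where no
    event was observed (absent, not zero); ``occupancy`` is the
    containment-semantics all-open occupancy, monotone in l and tr.
    """

    positions: np.ndarray
    lengths: np.ndarray
    thresholds: np.ndarray
    p: np.ndarray  # (N_core, n_lengths, n_thresholds)
    tau: np.ndarray  # same shape, ps; NaN = no events
    q: np.ndarray  # event counts, same shape
    occupancy: np.ndarray  # same shape


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def average_coordinates(ens: TrajectoryEnsemble) -> CoordinateProfile:
    """Mean opening profile over all runs and production frames.

    The standard error is the between-run spread of per-run time means,
    which is robust to within-run time correlation.
    """
    y = ens.core_frames
    if y.shape[1] == 0:
        raise ValueError("ensemble has zero production frames")
    per_run = y.mean(axis=1)  # (M, N_core)
    m = y.shape[0]
    stderr = per_run.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(y.shape[2])
    return CoordinateProfile(
        positions=np.arange(y.shape[2]),
        mean_y=y.mean(axis=(0, 1)),
        stderr_y=stderr,
    )


def flipping_probability(
    ens: TrajectoryEnsemble,
    thresholds: Sequence[float] | None = None,
) -> FlippingProfile:
    """Fraction of (run, frame) samples with y_i >= threshold (inclusive)."""
    thr = DEFAULT_FLIP_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    if thr.size == 0 or np.any(thr <= 0):
        raise ValueError("thresholds must be non-empty and positive")
    y = ens.core_frames
    if y.shape[1] == 0:
        raise ValueError("ensemble has zero production frames")
    prob = np.stack([(y >= t).mean(axis=(0, 1)) for t in thr])
    return FlippingProfile(thresholds=thr, prob=prob)


# ---------------------------------------------------------------------------
# bubbles
# ---------------------------------------------------------------------------


def _maximal_runs(open_mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D mask as (start, length) pairs."""
    padded = np.concatenate(([False], open_mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_bubbles(
    frames: np.ndarray,
    tr: float,
    lengths: Iterable[int] | None = None,
) -> list[BubbleEvent]:
    """Maximal opening events of one run at amplitude threshold ``tr``.

    ``frames`` is (n_frames, N).  A configuration (n, l) holds at a frame
    iff positions n..n+l-1 all satisfy y >= tr and the run is maximal
    (position n-1 closed or absent, n+l closed or absent).  An event is a
    maximal block of consecutive frames over which the same (n, l) holds;
    growth, shrinkage, split or merge ends it and starts new events.
    """
    frames = np.asarray(frames)
    if frames.ndim != 2:
        raise ValueError("frames must be 2-D (n_frames, N)")
    wanted = None if lengths is None else frozenset(int(x) for x in lengths)
    open_mask = frames >= tr
    active: dict[tuple[int, int], int] = {}
    events: list[BubbleEvent] = []

    def _close(key: tuple[int, int], start: int, end: int) -> None:
        if wanted is None or key[1] in wanted:
            events.append(BubbleEvent(n=key[0], l=key[1], start_frame=start, end_frame=end))

    for t in range(frames.shape[0]):
        current = set(_maximal_runs(open_mask[t]))
        for key in list(active):
            if key not in current:
                _close(key, active.pop(key), t - 1)
        for key in current:
            active.setdefault(key, t)
    for key, start in active.items():
        _close(key, start, frames.shape[0] - 1)
    events.sort(key=lambda e: (e.n, e.l, e.start_frame))
    return events


def bubble_probability(
    events_by_run: Sequence[Sequence[BubbleEvent]],
    m: int,
    t_s_ps: float,
    frame_interval_ps: float,
    n_positions: int,
    lengths: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Bubble probability P(n, l) = sum of event lifetimes / (t_s * M).

    ``t_s_ps`` is the recorded duration of one run (n_frames * frame
    interval), which makes an always-open configuration score exactly 1.
    Returns (P, Q) matrices of shape (n_positions, len(lengths)).
    """
    if len(events_by_run) != m:
        raise ValueError(f"expected events from exactly M={m} runs, got {len(events_by_run)}")
    if t_s_ps <= 0:
        raise ValueError("t_s must be positive")
    lengths = np.asarray(lengths, int)
    lidx = {int(l): j for j, l in enumerate(lengths)}
    p = np.zeros((n_positions, len(lengths)))
    q = np.zeros((n_positions, len(lengths)), dtype=np.int64)
    for run_events in events_by_run:
        for ev in run_events:
            j = lidx.get(ev.l)
            if j is None or not (0 <= ev.n < n_positions):
                continue
            p[ev.n, j] += ev.n_frames * frame_interval_ps
            q[ev.n, j] += 1
    p /= t_s_ps * m
    return p, q


def bubble_lifetime(
    events_by_run: Sequence[Sequence[BubbleEvent]],
    frame_interval_ps: float,
    n_positions: int,
    lengths: Sequence[int],
) -> np.ndarray:
    """Pooled mean event lifetime tau(n, l) in ps; NaN where no events."""
    lengths = np.asarray(lengths, int)
    lidx = {int(l): j for j, l in enumerate(lengths)}
    total = np.zeros((n_positions, len(lengths)))
    count = np.zeros((n_positions, len(lengths)))
    for run_events in events_by_run:
        for ev in run_events:
            j = lidx.get(ev.l)
            if j is None or not (0 <= ev.n < n_positions):
                continue
            total[ev.n, j] += ev.n_frames * frame_interval_ps
            count[ev.n, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return tau


def all_open_occupancy(
    core_frames: np.ndarray,
    thresholds: Sequence[float],
    lengths: Sequence[int],
) -> np.ndarray:
    """Containment-semantics occupancy tensor (N_core, n_lengths, n_thresholds).

    Cell (n, l, tr): fraction of (run, frame) samples in which positions
    n..n+l-1 are simultaneously open at threshold tr (no maximality
    requirement).  Exactly non-increasing in l and in tr; windows running
    past the core are reported as 0.
    """
    thresholds = np.asarray(thresholds, float)
    lengths = np.asarray(lengths, int)
    n = core_frames.shape[-1]
    occ = np.zeros((n, len(lengths), len(thresholds)))
    flat = core_frames.reshape(-1, n)  # samples x positions
    for j, l in enumerate(lengths):
        if l < 1 or l > n:
            continue
        wmin = np.lib.stride_tricks.sliding_window_view(flat, l, axis=1).min(axis=2)
        for k, tr in enumerate(thresholds):
            occ[: n - l + 1, j, k] = (wmin >= tr).mean(axis=0)
    return occ


def bubble_statistics(
    ens: TrajectoryEnsemble,
    thresholds: Sequence[float] | None = None,
    lengths: Sequence[int] | None = None,
) -> BubbleStatistics:
    """Full bubble tensor sweep over the ensemble's core positions."""
    thr = DEFAULT_BUBBLE_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    lens = DEFAULT_BUBBLE_LENGTHS if lengths is None else np.asarray(lengths, int)
    core = ens.core_frames
    m, n_frames, n = core.shape
    if n_frames == 0:
        raise ValueError("ensemble has zero production frames")
    dt_frame = ens.config_used.frame_interval_fs / FS_PER_PS
    t_s = n_frames * dt_frame
    p = np.zeros((n, len(lens), len(thr)))
    tau = np.full((n, len(lens), len(thr)), np.nan)
    q = np.zeros((n, len(lens), len(thr)), dtype=np.int64)
    for k, tr in enumerate(thr):
        events = [detect_bubbles(core[r], tr, lengths=lens) for r in range(m)]
        p[:, :, k], q[:, :, k] = bubble_probability(events, m, t_s, dt_frame, n, lens)
        tau[:, :, k] = bubble_lifetime(events, dt_frame, n, lens)
    occ = all_open_occupancy(core, thr, lens)
    return BubbleStatistics(
        positions=np.arange(n), lengths=lens, thresholds=thr, p=p, tau=tau, q=q, occupancy=occ
    )


# ---------------------------------------------------------------------------
# feature assembly for downstream ML
# ---------------------------------------------------------------------------

BASE_ORDER = "ACGT"


def assemble_ml_features(seq: str, profile: CoordinateProfile) -> np.ndarray:
    """Flat feature vector: per-position one-hot blocks, then mean openings.

    Layout (stable): positions are one-hot encoded in base order A, C, G, T
    and concatenated position-major (4 L values), followed by the L mean
    displacements — 5 L features for a length-L sequence.
    """
    seq = seq.upper()
    if len(seq) != len(profile):
        raise ValueError(
            f"sequence length {len(seq)} does not match profile length {len(profile)}"
        )
    onehot = np.zeros((len(seq), 4))
    for i, base in enumerate(seq):
        j = BASE_ORDER.find(base)
        if j < 0:
            raise ValueError(f"non-ACGT character {base!r} at position {i}")
        onehot[i, j] = 1.0
    return np.concatenate([onehot.ravel(), profile.mean_y])


def decode_one_hot(features: np.ndarray) -> str:
    """Invert the one-hot block of :func:`assemble_ml_features`."""
    features = np.asarray(features)
    if features.size % 5:
        raise ValueError("feature vector length must be a multiple of 5")
    l = features.size // 5
    blocks = features[: 4 * l].reshape(l, 4)
    if not np.all(blocks.sum(axis=1) == 1):
        raise ValueError("not a valid one-hot block")
    return "".join(BASE_ORDER[j] for j in blocks.argmax(axis=1))
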