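"""Synthetic sequences and independent statistical oracles.

Everything a test needs is generated here: homopolymers, uniform random
sequences, and wild-type/mutant pairs differing at a single dinucleotide
(the design used to probe single-substitution sensitivity of breathing
profiles in promoter studies).  The oracles — the Boltzmann stationary
density by quadrature and an exhaustive bubble scanner — are deliberately
brute-force and independent of the optimised code paths they validate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .features import BubbleEvent
from .model import BasePairClass, ParameterSet, morse_potential

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "boltzmann_oracle",
    "boltzmann_cdf",
    "brute_force_bubbles",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic sequence (or wt/mt pair).

    ``substitution`` = (position, from_dinucleotide, to_dinucleotide); the
    wild-type carries ``from`` at that position, the mutant ``to``, and the
    two strings differ nowhere else.
    """

    kind: str  # homopolymer | random_uniform | substitution_pair
    length: int
    seed: int = 0
    base: str = "A"  # homopolymer base
    substitution: tuple[int, str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("homopolymer", "random_uniform", "substitution_pair"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "substitution_pair":
            if self.substitution is None:
                raise ValueError("substitution_pair requires a substitution")
            pos, src, dst = self.substitution
            if len(src) != len(dst):
                raise ValueError("from/to dinucleotides must have equal length")
            if not (0 <= pos and pos + len(src) <= self.length):
                raise ValueError(f"substitution at {pos} out of range for length {self.length}")


def make_fixture(spec: FixtureSpec) -> str | tuple[str, str]:
    """Build the sequence(s) described by ``spec``; deterministic given seed.

    ``substitution_pair`` returns (wt, mt) strings over an A/T-rich random
    background, identical except at the substituted positions.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "homopolymer":
        return spec.base * spec.length
    if spec.kind == "random_uniform":
        return "".join(rng.choice(list("ACGT"), size=spec.length))
    pos, src, dst = spec.substitution  # type: ignore[misc]
    background = "".join(rng.choice(list("AT"), size=spec.length))
    wt = background[:pos] + src.upper() + background[pos + len(src) :]
    mt = background[:pos] + dst.upper() + background[pos + len(dst) :]
    return wt, mt


def boltzmann_oracle(
    p: ParameterSet,
    bp: BasePairClass,
    temperature: float,
    y_min: float,
    y_max: float,
    n_grid: int = 20001,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary density exp(-U(y)/k_B T)/Z of an isolated Morse well.

    Computed by numerical quadrature on the bounded grid [y_min, y_max];
    normalised to integrate to 1 (trapezoid rule).  The Morse plateau makes
    the full-line integral divergent, so an unbounded request is rejected.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not (np.isfinite(y_min) and np.isfinite(y_max)) or y_min >= y_max:
        raise ValueError("a bounded grid with y_min < y_max is required "
                         "(the Morse plateau makes the unbounded integral divergent)")
    grid = np.linspace(y_min, y_max, n_grid)
    u = morse_potential(grid, bp, p)
    w = np.exp(-(u - u.min()) / (p.k_B * temperature))
    z = trapezoid(w, grid)
    return grid, w / z


def boltzmann_cdf(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Cumulative distribution of a gridded density (for KS comparisons)."""
    cdf = cumulative_trapezoid(density, grid, initial=0.0)
    return cdf / cdf[-1]


def brute_force_bubbles(frames: np.ndarray, tr: float, lengths=None) -> list[BubbleEvent]:
    """Exhaustive O(T * N * L) bubble scan; authoritative oracle.

    For every frame and every (start, length) pair, checks the maximality
    condition literally: all positions inside open, both neighbours closed
    or absent.  Events are maximal frame intervals of a persisting (n, l).
    Intended for small inputs only (N <= 30, <= 200 frames).
    """
    frames = np.asarray(frames)
    n_frames, n = frames.shape
    open_mask = frames >= tr
    lens = range(1, n + 1) if lengths is None else [int(x) for x in lengths]
    events: list[BubbleEvent] = []
    for start in range(n):
        for l in lens:
            if l < 1 or start + l > n:
                continue
            present = np.zeros(n_frames, dtype=bool)
            for t in range(n_frames):
                inside = bool(open_mask[t, start : start + l].all())
                left_closed = start == 0 or not open_mask[t, start - 1]
                right_closed = start + l == n or not open_mask[t, start + l]
                present[t] = inside and left_closed and right_closed
            t = 0
            while t < n_frames:
                if present[t]:
                    t0 = t
                    while t + 1 < n_frames and present[t + 1]:
                        t += 1
                    events.append(BubbleEvent(n=start, l=l, start_frame=t0, end_frame=t))
                t += 1
    events.sort(key=lambda e: (e.n, e.l, e.start_frame))
    return events
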