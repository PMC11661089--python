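"""Potential-energy surface of the extended Peyrard-Bishop-Dauxois model.

Double-stranded DNA is described as a quasi-one-dimensional lattice of N
base pairs.  The transverse stretching of the n-th pair is the reduced
coordinate ``y_n = (u_n - v_n) / sqrt(2)`` (u, v are the displacements of
the two complementary bases).  The potential has two terms per site:

* a Morse on-site potential ``U(y) = D (exp(-a y) - 1)^2`` modelling the
  hydrogen bonds of one base pair, with (D, a) depending only on whether
  the pair is A-T or G-C;
* an anharmonic stacking coupling between neighbouring pairs,
  ``W(y_n, y_{n-1}) = k/2 (1 + rho exp(-beta (y_n + y_{n-1}))) (y_n - y_{n-1})^2``,
  whose exponential factor weakens the coupling once either pair opens,
  producing the cooperative, entropy-driven character of DNA denaturation.

Everything here is deterministic and analytic; the stochastic thermostat
lives in :mod:`epbdsim.engine`.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .units import KB_EV

__all__ = [
    "BasePairClass",
    "EncodedSequence",
    "ParameterSet",
    "StrandState",
    "ReducedState",
    "encode_sequence",
    "morse_potential",
    "morse_force",
    "stacking_potential_full",
    "stacking_potential_reduced",
    "total_force",
    "total_potential",
]

_VALID_BASES = frozenset("ACGT")


class BasePairClass(enum.Enum):
    """Class of a Watson-Crick pair: A-T (two hydrogen bonds) or G-C (three)."""

    AT = 0
    GC = 1


def _classify(base: str) -> int:
    return 0 if base in "AT" else 1


@dataclass(frozen=True)
class EncodedSequence:
    """A DNA sequence mapped to per-position base-pair classes.

    ``bases`` holds the full sequence including any flanks; ``codes`` is the
    per-position class code (0 = AT, 1 = GC).  ``core_span`` is the 0-based,
    half-open index interval of the biological sequence of interest inside
    the flanked construct.
    """

    bases: str
    codes: np.ndarray
    flank_left_len: int
    flank_right_len: int
    core_span: tuple[int, int]
    id: str = "seq"

    def __post_init__(self) -> None:
        n = len(self.bases)
        if n < 2:
            raise ValueError(
                f"sequence '{self.id}' has length {n}; at least 2 base pairs "
                "are required (stacking needs a neighbour) -- add flanks"
            )
        if len(self.codes) != n:
            raise ValueError("codes/bases length mismatch")
        lo, hi = self.core_span
        if not (0 <= lo < hi <= n):
            raise ValueError(f"core_span {self.core_span} outside [0, {n})")
        if self.flank_left_len + (hi - lo) + self.flank_right_len != n:
            raise ValueError("flank lengths inconsistent with core span")

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def core_length(self) -> int:
        return self.core_span[1] - self.core_span[0]

    @property
    def core_bases(self) -> str:
        return self.bases[self.core_span[0] : self.core_span[1]]

    @property
    def classes(self) -> list[BasePairClass]:
        return [BasePairClass(int(c)) for c in self.codes]


def encode_sequence(
    raw: str,
    flank_left: str = "",
    flank_right: str = "",
    id: str = "seq",
) -> EncodedSequence:
    """Encode a nucleotide string (plus optional flanks) for simulation.

    Flanking sequence buffers boundary effects at the terminal base pairs of
    short inputs; statistics are later reported on the core span only.
    Ambiguity codes are rejected, not silently mapped.
    """
    if not raw:
        raise ValueError("empty sequence")
    full = (flank_left + raw + flank_right).upper()
    for pos, base in enumerate(full.upper()):
        if base not in _VALID_BASES:
            # report the position within the offending segment
            if pos < len(flank_left):
                where = f"left flank position {pos}"
            elif pos < len(flank_left) + len(raw):
                where = f"position {pos - len(flank_left)}"
            else:
                where = f"right flank position {pos - len(flank_left) - len(raw)}"
            raise ValueError(f"non-ACGT character {base!r} at {where}")
    codes = np.fromiter((_classify(b) for b in full), dtype=np.uint8, count=len(full))
    lo = len(flank_left)
    return EncodedSequence(
        bases=full,
        codes=codes,
        flank_left_len=len(flank_left),
        flank_right_len=len(flank_right),
        core_span=(lo, lo + len(raw)),
        id=id,
    )


@dataclass(frozen=True)
class ParameterSet:
    """Physical constants of the Hamiltonian and the Langevin thermostat.

    Units: D in eV, a and beta_stack in 1/A, k_stack in eV/A^2, mass in amu,
    gamma in 1/ps, temperature in K.  ``k_stack`` may be a single float or a
    mapping from dinucleotide (5'->3', e.g. ``"AG"``) to a coupling constant,
    enabling sequence-specific stacking; the default is uniform.
    """

    d_at: float = 0.05
    d_gc: float = 0.075
    a_at: float = 4.2
    a_gc: float = 6.9
    k_stack: float | Mapping[str, float] = 0.025
    rho: float = 2.0
    beta_stack: float = 0.35
    mass: float = 300.0
    gamma: float = 5.0
    k_B: float = KB_EV
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for name in ("d_at", "d_gc", "a_at", "a_gc", "mass", "k_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.beta_stack <= 0:
            raise ValueError("beta_stack must be strictly positive")
        # temperature 0 is the deterministic (noise-free) limit of the thermostat
        if self.gamma < 0 or self.rho < 0 or self.temperature < 0:
            raise ValueError("gamma, rho and temperature must be non-negative")
        if isinstance(self.k_stack, Mapping):
            if any(v <= 0 for v in self.k_stack.values()):
                raise ValueError("all stacking constants must be strictly positive")
        elif self.k_stack <= 0:
            raise ValueError("k_stack must be strictly positive")

    # -- per-sequence vectorised lookups -------------------------------

    def morse_arrays(self, seq: EncodedSequence) -> tuple[np.ndarray, np.ndarray]:
        """Per-position (D, a) arrays for a sequence."""
        d = np.where(seq.codes == 0, self.d_at, self.d_gc)
        a = np.where(seq.codes == 0, self.a_at, self.a_gc)
        return d, a

    def stacking_array(self, seq: EncodedSequence, boundary: str) -> np.ndarray:
        """Per-bond stacking constants.

        Bond ``j`` couples positions ``(j, j+1)``; under periodic boundaries
        an extra wrap bond couples ``(N-1, 0)``.  Returns shape (N-1,) for
        open and (N,) for periodic boundaries.
        """
        n = seq.n
        if isinstance(self.k_stack, Mapping):
            table = {k.upper(): float(v) for k, v in self.k_stack.items()}
            dinucs = [seq.bases[j : j + 2] for j in range(n - 1)]
            if boundary == "periodic":
                dinucs.append(seq.bases[-1] + seq.bases[0])
            try:
                return np.array([table[d] for d in dinucs])
            except KeyError as exc:
                raise KeyError(f"no stacking constant for dinucleotide {exc}") from None
        n_bonds = n if boundary == "periodic" else n - 1
        return np.full(n_bonds, float(self.k_stack))

    def with_(self, **kwargs) -> "ParameterSet":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    # -- flat key-value parameter files --------------------------------

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        """Read a flat ``key = value`` parameter file (``#`` comments)."""
        values: dict[str, float] = {}
        stack_table: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key.startswith("k_stack."):
                    stack_table[key.split(".", 1)[1].upper()] = float(val)
                else:
                    values[key] = float(val)
        known = set(cls.__dataclass_fields__)
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
        if stack_table:
            values["k_stack"] = stack_table
        return cls(**values)

    @classmethod
    def default(cls) -> "ParameterSet":
        """Load the default parameterisation shipped with the package."""
        ref = importlib.resources.files("epbdsim").joinpath("data/default.params")
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.__dataclass_fields__:
                val = getattr(self, name)
                if isinstance(val, Mapping):
                    for k, v in sorted(val.items()):
                        fh.write(f"k_stack.{k} = {v!r}\n")
                else:
                    fh.write(f"{name} = {val!r}\n")

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            out[name] = dict(val) if isinstance(val, Mapping) else val
        return out


@dataclass
class StrandState:
    """Per-strand displacements (u: one strand, v: the complementary one)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shape")


@dataclass
class ReducedState:
    """Reduced coordinates y = (u - v)/sqrt(2) and their velocities.

    ``y`` is in Angstrom; ``ydot`` in Angstrom per internal time unit
    (see :mod:`epbdsim.units`).
    """

    y: np.ndarray
    ydot: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.ydot = np.asarray(self.ydot, dtype=float)
        if self.y.shape != self.ydot.shape:
            raise ValueError("y and ydot must have identical shape")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.ydot))):
            raise ValueError("non-finite state")


# ---------------------------------------------------------------------------
# scalar / per-class operations
# ---------------------------------------------------------------------------


def _morse_params(bp: BasePairClass, p: ParameterSet) -> tuple[float, float]:
    return (p.d_at, p.a_at) if bp is BasePairClass.AT else (p.d_gc, p.a_gc)


def morse_potential(y, bp: BasePairClass, p: ParameterSet):
    """Morse on-site energy ``D (exp(-a y) - 1)^2`` in eV.

    Zero at the closed state y = 0; saturates at the dissociation energy D
    for large opening.
    """
    d, a = _morse_params(bp, p)
    e = np.exp(-a * np.asarray(y, dtype=float))
    return d * (e - 1.0) ** 2


def morse_force(y, bp: BasePairClass, p: ParameterSet):
    """Force -dU/dy of the Morse potential: ``2 D a e^{-a y}(e^{-a y} - 1)``."""
    d, a = _morse_params(bp, p)
    e = np.exp(-a * np.asarray(y, dtype=float))
    return 2.0 * d * a * e * (e - 1.0)


def stacking_potential_full(
    u_n,
    u_nm1,
    v_n,
    v_nm1,
    p: ParameterSet,
    k_u: float | None = None,
    k_v: float | None = None,
):
    """Two-strand stacking energy between neighbouring base pairs.

    Evaluates the full form
    ``K_u/2 (u_n-u_{n-1})^2 + K_v/2 (v_n-v_{n-1})^2 +
    rho/4 exp(-beta[(u_n-v_n)+(u_{n-1}-v_{n-1})]) (K_u du - K_v dv)^2``
    which distinguishes the two strands.  The engine integrates the reduced
    y coordinate only; this form is exposed for evaluation and for the case
    K_u != K_v.
    """
    ku = float(p.k_stack) if k_u is None else k_u
    kv = float(p.k_stack) if k_v is None else k_v
    du = np.asarray(u_n, dtype=float) - u_nm1
    dv = np.asarray(v_n, dtype=float) - v_nm1
    expo = np.exp(-p.beta_stack * ((u_n - v_n) + (u_nm1 - v_nm1)))
    return 0.5 * ku * du**2 + 0.5 * kv * dv**2 + 0.25 * p.rho * expo * (ku * du - kv * dv) ** 2


def stacking_potential_reduced(y_n, y_nm1, p: ParameterSet, k: float | None = None):
    """Anharmonic stacking in the reduced coordinate.

    ``W = k/2 (1 + rho exp(-beta (y_n + y_{n-1}))) (y_n - y_{n-1})^2``;
    non-negative, zero iff the two neighbouring openings are equal.
    """
    kk = float(p.k_stack) if k is None else k
    y_n = np.asarray(y_n, dtype=float)
    dy = y_n - y_nm1
    return 0.5 * kk * (1.0 + p.rho * np.exp(-p.beta_stack * (y_n + y_nm1))) * dy**2


# ---------------------------------------------------------------------------
# vectorised lattice force field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForceField:
    """Precomputed per-position/per-bond constants for one sequence.

    ``forces`` and ``potential`` accept y of shape (..., N) and broadcast
    over leading axes, which is how the engine vectorises over ensemble
    runs.
    """

    d: np.ndarray  # (N,) Morse depth
    a: np.ndarray  # (N,) Morse width
    k_bond: np.ndarray  # (N-1,) open, (N,) periodic
    rho: float
    beta: float
    periodic: bool

    @classmethod
    def build(cls, seq: EncodedSequence, p: ParameterSet, boundary: str) -> "ForceField":
        if boundary not in ("periodic", "open"):
            raise ValueError(f"unknown boundary mode {boundary!r}")
        d, a = p.morse_arrays(seq)
        return cls(
            d=d,
            a=a,
            k_bond=p.stacking_array(seq, boundary),
            rho=p.rho,
            beta=p.beta_stack,
            periodic=(boundary == "periodic"),
        )

    @property
    def n(self) -> int:
        return len(self.d)

    def _bond_pairs(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(y_i, y_j) arrays for every bond, bond j coupling (j, j+1 mod N)."""
        if self.periodic:
            return y, np.roll(y, -1, axis=-1)
        return y[..., :-1], y[..., 1:]

    def forces(self, y: np.ndarray) -> np.ndarray:
        """Analytic force -dV/dy_n at every position; broadcasts over runs."""
        y = np.asarray(y, dtype=float)
        e = np.exp(-self.a * y)
        f = 2.0 * self.d * self.a * e * (e - 1.0)
        yi, yj = self._bond_pairs(y)
        dy = yi - yj
        expo = self.rho * np.exp(-self.beta * (yi + yj))
        # dW/dy_i and dW/dy_j for each bond
        harm = self.k_bond * (1.0 + expo) * dy
        anh = 0.5 * self.k_bond * self.beta * expo * dy**2
        g_i = harm - anh  # dW/dy_i
        g_j = -harm - anh  # dW/dy_j
        if self.periodic:
            f -= g_i
            f -= np.roll(g_j, 1, axis=-1)
        else:
            f[..., :-1] -= g_i
            f[..., 1:] -= g_j
        return f

    def potential(self, y: np.ndarray) -> np.ndarray:
        """Total lattice potential energy, summed over sites and bonds."""
        y = np.asarray(y, dtype=float)
        e = np.exp(-self.a * y)
        u = np.sum(self.d * (e - 1.0) ** 2, axis=-1)
        yi, yj = self._bond_pairs(y)
        dy = yi - yj
        w = 0.5 * self.k_bond * (1.0 + self.rho * np.exp(-self.beta * (yi + yj))) * dy**2
        return u + np.sum(w, axis=-1)


def total_force(
    state: ReducedState,
    seq: EncodedSequence,
    p: ParameterSet,
    boundary: str = "periodic",
) -> np.ndarray:
    """Force ``-U'(y_n) - dW/dy_n`` at every position of the lattice.

    Under periodic boundaries position 0 couples to N-1; under open
    boundaries the terminal positions have a single neighbour.
    """
    y = state.y
    if y.shape[-1] != seq.n:
        raise ValueError(f"state length {y.shape[-1]} != sequence length {seq.n}")
    return ForceField.build(seq, p, boundary).forces(y)


def total_potential(
    state: ReducedState,
    seq: EncodedSequence,
    p: ParameterSet,
    boundary: str = "periodic",
) -> np.ndarray:
    """Total potential energy (Morse + stacking) of a lattice configuration."""
    y = state.y
    if y.shape[-1] != seq.n:
        raise ValueError(f"state length {y.shape[-1]} != sequence length {seq.n}")
    return ForceField.build(seq, p, boundary).potential(y)
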