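"""Langevin-dynamics integrator for the base-pair opening coordinate.

Each base pair's reduced coordinate obeys the Langevin equation

    m y''_n = -U'(y_n) - dW/dy_n - m gamma y'_n + xi_n(t),

with Gaussian white noise satisfying the fluctuation-dissipation relation
<xi xi'> = 2 m gamma k_B T delta(t - t').  The equation is integrated with
a midpoint (second-order Runge-Kutta) scheme; one noise realisation per
step is applied in both stages, with per-step variance 2 m gamma k_B T/dt.

The protocol is: start from the closed, stationary state (y = y' = 0),
run a preheating phase that thermalises the lattice without recording,
then record production frames every ``sampling_stride`` steps.  Ensembles
of M independent trajectories are vectorised over a leading run axis.

Reproducibility: every run owns a pseudorandom stream derived from
(root seed, sequence index, run index) via ``numpy.random.SeedSequence``
spawn keys, consumed strictly in step order.  Results are therefore
bitwise independent of how runs or sequences are batched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from math import sqrt
from typing import Sequence

import numpy as np

from .model import EncodedSequence, ForceField, ParameterSet, ReducedState
from .units import FS_PER_NS, FS_PER_PS, fs_to_internal, per_ps_to_internal

__all__ = [
    "SimulationConfig",
    "NoiseSpec",
    "TrajectoryEnsemble",
    "IntegrationError",
    "rk2_step",
    "run_trajectory",
    "run_ensemble",
]

# Target size (in doubles) of the per-chunk noise buffer.  The chunk
# partition has no effect on results (each run's stream is consumed
# sequentially); it only bounds memory.
_NOISE_BUDGET = 1 << 20


class IntegrationError(RuntimeError):
    """The integrator produced a non-finite state (try a smaller dt)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol parameters of one simulation campaign.

    ``dt`` is in femtoseconds, ``preheat_duration`` in picoseconds and
    ``production_duration`` in nanoseconds, matching the scales on which
    each is naturally quoted.
    """

    dt: float = 1.0
    preheat_duration: float = 200.0
    production_duration: float = 1.0
    sampling_stride: int = 100
    ensemble_size: int = 1000
    seed: int = 0
    boundary: str = "periodic"
    batch_size: int = 32
    record_velocities: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.preheat_duration < 0 or self.production_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.ensemble_size < 1 or self.sampling_stride < 1 or self.batch_size < 1:
            raise ValueError("ensemble_size, sampling_stride, batch_size must be >= 1")
        if self.boundary not in ("periodic", "open"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    @property
    def preheat_steps(self) -> int:
        return int(round(self.preheat_duration * FS_PER_PS / self.dt))

    @property
    def production_steps(self) -> int:
        return int(round(self.production_duration * FS_PER_NS / self.dt))

    @property
    def n_frames(self) -> int:
        return self.production_steps // self.sampling_stride

    @property
    def frame_interval_fs(self) -> float:
        return self.sampling_stride * self.dt

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class NoiseSpec:
    """Discretised thermal-noise contract of the thermostat.

    ``amplitude`` is the per-step, per-position standard deviation of the
    random force, ``sqrt(2 m gamma k_B T / dt)`` in internal units, which
    discretises the white-noise autocorrelation 2 m gamma k_B T delta(t-t').
    """

    amplitude: float

    @classmethod
    def from_params(cls, p: ParameterSet, cfg: SimulationConfig) -> "NoiseSpec":
        gamma_i = per_ps_to_internal(p.gamma)
        dt_i = fs_to_internal(cfg.dt)
        var = 2.0 * p.mass * gamma_i * p.k_B * p.temperature / dt_i
        return cls(amplitude=sqrt(var))

    @staticmethod
    def stream(seed: int, sequence_index: int, run_index: int) -> np.random.Generator:
        """The pseudorandom stream owned by one (sequence, run) pair."""
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(sequence_index, run_index))
        return np.random.Generator(np.random.PCG64(ss))


@dataclass
class TrajectoryEnsemble:
    """Sampled displacements of M independent runs of one sequence.

    ``frames`` has shape (M, n_frames, N) with N the full (flanked)
    sequence length; ``core_frames`` slices out the biological core.
    ``velocities`` (same shape, internal velocity units) is present only
    when the configuration requested it.
    """

    sequence_id: str
    sequence: EncodedSequence
    frames: np.ndarray
    frame_times: np.ndarray
    config_used: SimulationConfig
    parameters_used: ParameterSet
    velocities: np.ndarray | None = None

    @property
    def ensemble_size(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def core_frames(self) -> np.ndarray:
        lo, hi = self.sequence.core_span
        return self.frames[:, :, lo:hi]

    def kinetic_temperature(self) -> tuple[float, float]:
        """Ensemble kinetic temperature and its between-run standard error.

        Uses equipartition: <m y'^2> = k_B T per degree of freedom.  The
        standard error is computed from the spread of per-run means, which
        absorbs within-run time correlation.
        """
        if self.velocities is None:
            raise ValueError("velocities were not recorded (set record_velocities)")
        p = self.parameters_used
        per_run = p.mass * np.mean(self.velocities**2, axis=(1, 2)) / p.k_B
        m = self.ensemble_size
        se = float(np.std(per_run, ddof=1) / sqrt(m)) if m > 1 else float("nan")
        return float(np.mean(per_run)), se

    # -- container I/O (structured array file + JSON metadata block) ---

    def save(self, path) -> None:
        meta = {
            "sequence_id": self.sequence_id,
            "sequence": {
                "bases": self.sequence.bases,
                "flank_left_len": self.sequence.flank_left_len,
                "flank_right_len": self.sequence.flank_right_len,
                "core_span": list(self.sequence.core_span),
                "id": self.sequence.id,
            },
            "config": self.config_used.to_dict(),
            "parameters": self.parameters_used.to_dict(),
        }
        arrays = {
            "frames": self.frames,
            "frame_times": self.frame_times,
            "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        }
        if self.velocities is not None:
            arrays["velocities"] = self.velocities
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrajectoryEnsemble":
        try:
            with np.load(path) as data:
                blocks = {name: data[name] for name in data.files}
        except Exception as exc:  # zipfile/pickle errors for truncated files
            raise ValueError(f"unreadable trajectory container {path}: {exc}") from exc
        for required in ("frames", "frame_times", "meta_json"):
            if required not in blocks:
                raise ValueError(f"trajectory container {path}: missing block '{required}'")
        try:
            meta = json.loads(bytes(blocks["meta_json"]).decode())
        except Exception as exc:
            raise ValueError(f"trajectory container {path}: corrupt block 'meta_json'") from exc
        sd = meta["sequence"]
        from .model import encode_sequence  # local import avoids cycle at module load

        n = len(sd["bases"])
        core = sd["bases"][sd["core_span"][0] : sd["core_span"][1]]
        seq = encode_sequence(
            core,
            flank_left=sd["bases"][: sd["flank_left_len"]],
            flank_right=sd["bases"][n - sd["flank_right_len"] :],
            id=sd["id"],
        )
        return cls(
            sequence_id=meta["sequence_id"],
            sequence=seq,
            frames=blocks["frames"],
            frame_times=blocks["frame_times"],
            config_used=SimulationConfig.from_dict(meta["config"]),
            parameters_used=ParameterSet(**meta["parameters"]),
            velocities=blocks.get("velocities"),
        )


# ---------------------------------------------------------------------------
# integration kernels
# ---------------------------------------------------------------------------


def _rk2_kernel(y, v, xi, ff: ForceField, dt: float, m: float, gamma: float):
    """One midpoint step of the Langevin equation; xi held fixed per step."""
    f1 = ff.forces(y) + xi - m * gamma * v
    y_half = y + 0.5 * dt * v
    v_half = v + 0.5 * dt * f1 / m
    f2 = ff.forces(y_half) + xi - m * gamma * v_half
    return y + dt * v_half, v + dt * f2 / m


def rk2_step(
    state: ReducedState,
    seq: EncodedSequence,
    p: ParameterSet,
    cfg: SimulationConfig,
    noise: np.ndarray | float = 0.0,
) -> ReducedState:
    """Advance one state by a single stochastic midpoint step.

    ``noise`` is the random-force realisation (eV/A) for this step; it is
    applied identically in both stages.  Deterministic given (state, noise).
    """
    if state.y.shape[-1] != seq.n:
        raise ValueError("state length does not match sequence length")
    ff = ForceField.build(seq, p, cfg.boundary)
    dt = fs_to_internal(cfg.dt)
    gamma = per_ps_to_internal(p.gamma)
    y, v = _rk2_kernel(state.y, state.ydot, noise, ff, dt, p.mass, gamma)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v))):
        raise IntegrationError("integrator produced non-finite state; reduce dt")
    return ReducedState(y=y, ydot=v)


def _simulate_runs(
    ff: ForceField,
    rngs: Sequence[np.random.Generator],
    p: ParameterSet,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Integrate a batch of runs sharing one force field.

    ``ff`` arrays may carry a leading run axis for mixed-sequence batches.
    Returns production frames (R, n_frames, N) and optionally velocities.
    """
    r = len(rngs)
    n = ff.d.shape[-1]
    y = np.zeros((r, n))
    v = np.zeros((r, n))  # stationary start: closed helix at rest
    dt = fs_to_internal(cfg.dt)
    gamma = per_ps_to_internal(p.gamma)
    m = p.mass
    sigma = NoiseSpec.from_params(p, cfg).amplitude

    pre = cfg.preheat_steps
    prod = cfg.production_steps
    stride = cfg.sampling_stride
    n_frames = cfg.n_frames
    frames = np.empty((r, n_frames, n))
    vels = np.empty((r, n_frames, n)) if cfg.record_velocities else None

    chunk = max(1, min(4096, _NOISE_BUDGET // max(1, r * n)))
    total = pre + prod
    done = 0
    fidx = 0
    while done < total:
        c = min(chunk, total - done)
        if sigma > 0.0:
            xi = np.stack([rng.standard_normal((c, n)) for rng in rngs])
            xi *= sigma
        with np.errstate(over="ignore", invalid="ignore"):  # blow-ups caught below
            for s in range(c):
                noise = xi[:, s, :] if sigma > 0.0 else 0.0
                y, v = _rk2_kernel(y, v, noise, ff, dt, m, gamma)
                step = done + s  # 0-based global step just completed
                if step >= pre and (step - pre + 1) % stride == 0:
                    frames[:, fidx] = y
                    if vels is not None:
                        vels[:, fidx] = v
                    fidx += 1
        done += c
        if not np.isfinite(y).all():
            raise IntegrationError(
                f"non-finite displacement by step {done} "
                f"(dt={cfg.dt} fs); reduce the time step"
            )
    return frames, vels


def run_trajectory(
    seq: EncodedSequence,
    p: ParameterSet,
    cfg: SimulationConfig,
    run_index: int,
    sequence_index: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One independent trajectory; returns (frames, velocities or None).

    The noise stream is derived from (cfg.seed, sequence_index, run_index),
    so the same triple always reproduces the same frames, bitwise, whether
    the run executes alone or inside a batched ensemble.
    """
    ff = ForceField.build(seq, p, cfg.boundary)
    rng = NoiseSpec.stream(cfg.seed, sequence_index, run_index)
    frames, vels = _simulate_runs(ff, [rng], p, cfg)
    return frames[0], (vels[0] if vels is not None else None)


def run_ensemble(
    sequences: Sequence[EncodedSequence],
    p: ParameterSet,
    cfg: SimulationConfig,
) -> list[TrajectoryEnsemble]:
    """Simulate M independent runs for every sequence.

    Sequences are grouped by length (up to ``cfg.batch_size`` per group) and
    their runs integrated together along a vectorised run axis.  Per-run
    noise streams are keyed by position in ``sequences``, so the output for
    each sequence is independent of the grouping.
    """
    if not sequences:
        raise ValueError("no sequences given")
    m = cfg.ensemble_size
    frame_times = (np.arange(cfg.n_frames) + 1) * cfg.frame_interval_fs

    # stable grouping by length, preserving input order inside each group
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(s.n, []).append(i)

    results: list[TrajectoryEnsemble | None] = [None] * len(sequences)
    for n, idxs in by_len.items():
        for start in range(0, len(idxs), cfg.batch_size):
            batch = idxs[start : start + cfg.batch_size]
            ffs = [ForceField.build(sequences[i], p, cfg.boundary) for i in batch]
            stacked = ForceField(
                d=np.repeat(np.stack([f.d for f in ffs]), m, axis=0),
                a=np.repeat(np.stack([f.a for f in ffs]), m, axis=0),
                k_bond=np.repeat(np.stack([f.k_bond for f in ffs]), m, axis=0),
                rho=p.rho,
                beta=p.beta_stack,
                periodic=(cfg.boundary == "periodic"),
            )
            rngs = [
                NoiseSpec.stream(cfg.seed, i, r) for i in batch for r in range(m)
            ]
            frames, vels = _simulate_runs(stacked, rngs, p, cfg)
            for j, i in enumerate(batch):
                sl = slice(j * m, (j + 1) * m)
                results[i] = TrajectoryEnsemble(
                    sequence_id=sequences[i].id,
                    sequence=sequences[i],
                    frames=frames[sl].copy(),
                    frame_times=frame_times.copy(),
                    config_used=cfg,
                    parameters_used=p,
                    velocities=(vels[sl].copy() if vels is not None else None),
                )
    return results  # type: ignore[return-value]
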