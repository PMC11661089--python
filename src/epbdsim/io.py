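"""FASTA input and tab-separated feature output.

Every feature table carries the sequence ID plus short hashes of the
simulation configuration and parameter set in ``#`` header lines, so a
table can always be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import BubbleStatistics, CoordinateProfile, FlippingProfile

__all__ = [
    "read_fasta",
    "short_hash",
    "write_coordinate_tsv",
    "write_flipping_tsv",
    "write_bubble_tsv",
    "save_bubble_container",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; returns [(record id, sequence string)]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input FASTA not found: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def short_hash(obj) -> str:
    """12-hex-digit digest of a JSON-serialisable object (stable key order)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(sequence_id: str, config_hash: str, params_hash: str) -> str:
    return (
        f"# sequence_id={sequence_id}\n"
        f"# config_hash={config_hash}\n"
        f"# params_hash={params_hash}\n"
    )


def write_coordinate_tsv(path, profile: CoordinateProfile, sequence_id, config_hash, params_hash):
    df = pd.DataFrame(
        {"position": profile.positions, "mean_y": profile.mean_y, "stderr_y": profile.stderr_y}
    )
    with open(path, "w") as fh:
        fh.write(_header(sequence_id, config_hash, params_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_flipping_tsv(path, profile: FlippingProfile, sequence_id, config_hash, params_hash):
    data = {"position": np.arange(profile.prob.shape[1])}
    for t, row in zip(profile.thresholds, profile.prob):
        data[f"p_ge_{t:g}A"] = row
    with open(path, "w") as fh:
        fh.write(_header(sequence_id, config_hash, params_hash))
        pd.DataFrame(data).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_bubble_tsv(path, stats: BubbleStatistics, sequence_id, config_hash, params_hash):
    """Long-format export: one row per (position, length, threshold) cell."""
    n, nl, nt = stats.p.shape
    pos, lj, tk = np.meshgrid(stats.positions, np.arange(nl), np.arange(nt), indexing="ij")
    df = pd.DataFrame(
        {
            "position": pos.ravel(),
            "length": stats.lengths[lj.ravel()],
            "threshold": stats.thresholds[tk.ravel()],
            "P": stats.p.ravel(),
            "Q": stats.q.ravel(),
            "tau_ps": stats.tau.ravel(),
            "occupancy": stats.occupancy.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(_header(sequence_id, config_hash, params_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="")


def save_bubble_container(path, stats: BubbleStatistics, sequence_id, config_hash, params_hash):
    """Structured array container for the full (N, lengths, thresholds) tensors."""
    np.savez_compressed(
        path,
        p=stats.p,
        tau=stats.tau,
        q=stats.q,
        occupancy=stats.occupancy,
        positions=stats.positions,
        lengths=stats.lengths,
        thresholds=stats.thresholds,
        meta_json=np.frombuffer(
            json.dumps(
                {
                    "sequence_id": sequence_id,
                    "config_hash": config_hash,
                    "params_hash": params_hash,
                }
            ).encode(),
            dtype=np.uint8,
        ),
    )
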