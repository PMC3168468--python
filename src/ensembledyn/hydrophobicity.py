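"""Per-residue surrounding hydrophobicity (Hp) over an ensemble.

Hp(i) sums the transfer-free-energy hydrophobicity indexes h_j of all
residues j whose Cα lies within a distance cutoff r_d of residue i's Cα:

    Hp(i) = sum_{j != i} H(r_d - r_ij) * h_j        [kcal/mol]

with H the Heaviside step function (H(0) = 1, so a pair exactly at the
cutoff counts as inside) and r_ij the Cα–Cα distance.  Computed on every
frame and averaged, Hp measures how strongly each residue's environment
excludes water across the sampled ensemble; residues with Hp above
~20 kcal/mol sit in strong hydrophobic clusters.

The residue's own index is excluded by default ("surrounding" residues);
``include_self`` reverses that for sensitivity checks.  Absolute values
depend on the hydrophobicity scale in use, which is a configurable TSV; the
packaged default is a transfer-free-energy scale and every profile records
its provenance label.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .ensemble_io import EnsembleFrameSet


@dataclass
class HydrophobicityScale:
    """Residue-name → hydrophobicity index (kcal/mol), with provenance."""

    values: dict[str, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite hydrophobicity index for {name}")

    def lookup(self, residue_names) -> np.ndarray:
        missing = sorted({n for n in residue_names if n not in self.values})
        if missing:
            raise KeyError(
                f"residue names missing from hydrophobicity scale {self.label!r}: "
                + ", ".join(missing)
            )
        return np.array([self.values[n] for n in residue_names])


def load_scale(path: str | Path | None = None) -> HydrophobicityScale:
    """Load a scale TSV (residue_name, h_kcal_per_mol); default is packaged."""
    if path is None:
        ref = resources.files("ensembledyn.data") / "hydrophobicity_scale.tsv"
        with resources.as_file(ref) as p:
            return load_scale(p)
    label = "custom"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# provenance:"):
                label = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return HydrophobicityScale(
        values=dict(zip(df["residue_name"], df["h_kcal_per_mol"].astype(float))),
        label=label,
    )


@dataclass
class HpProfile:
    """Ensemble-averaged surrounding hydrophobicity per residue."""

    residue_indices: np.ndarray
    residue_names: np.ndarray
    mean_hp: np.ndarray              # kcal/mol, mean over frames
    per_frame: np.ndarray | None     # (n_frames, n_residues) when retained
    r_d: float                       # Cα distance cutoff, nm
    scale_label: str

    def __post_init__(self) -> None:
        if self.r_d <= 0:
            raise ValueError("r_d must be positive")
        if len(self.mean_hp) != len(self.residue_indices):
            raise ValueError("profile length mismatch")


def compute_hp(
    ens: EnsembleFrameSet,
    scale: HydrophobicityScale | None = None,
    r_d: float = 0.8,
    include_self: bool = False,
    on_mean_structure: bool = False,
    keep_per_frame: bool = True,
) -> HpProfile:
    """Surrounding hydrophobicity per residue, averaged over the ensemble.

    ``on_mean_structure`` computes Hp once on the coordinate mean instead of
    frame-averaging (offered for sensitivity analysis; frame-averaging is the
    default and the two differ only through cutoff-crossing fluctuations).
    """
    if scale is None:
        scale = load_scale()
    h = scale.lookup(ens.residue_names)
    ca = ens.calpha_coords
    if on_mean_structure:
        ca = ca.mean(axis=0, keepdims=True)
    n_frames, n_res = ca.shape[0], ca.shape[1]
    per_frame = np.empty((n_frames, n_res))
    for f in range(n_frames):
        d = cdist(ca[f], ca[f])
        inside = d <= r_d          # Heaviside with H(0) = 1
        if not include_self:
            np.fill_diagonal(inside, False)
        per_frame[f] = inside @ h
    return HpProfile(
        residue_indices=ens.residue_indices,
        residue_names=ens.residue_names,
        mean_hp=per_frame.mean(axis=0),
        per_frame=per_frame if keep_per_frame else None,
        r_d=r_d,
        scale_label=scale.label,
    )


def hp_histogram(profile: HpProfile, bin_edges) -> pd.DataFrame:
    """Percentage of residues per Hp bin.

    ``bin_edges`` (strictly increasing, kcal/mol) define ``len(edges) + 1``
    bins: below the first edge, half-open ``[low, high)`` intervals between
    consecutive edges, and an open bin above the last edge.  Percentages are
    over all residues and sum to 100.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) == 0:
        raise ValueError("need at least one bin edge")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(profile.mean_hp, dtype=float)
    if len(values) == 0:
        raise ValueError("empty Hp profile")
    idx = np.searchsorted(edges, values, side="right")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    labels = (
        [f"<{edges[0]:g}"]
        + [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">={edges[-1]:g}"]
    )
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percentage": 100.0 * counts / len(values),
        }
    )
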