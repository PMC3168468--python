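"""Conformational-ensemble containers, I/O, superposition and profile utilities.

The central object is :class:`EnsembleFrameSet`, an ordered set of coordinate
snapshots (in nm) over a fixed atom table.  It is what every analysis stage
consumes, whether the frames come from a real MD trajectory (multi-model PDB
or topology+trajectory pair, read through MDAnalysis) or from the synthetic
generators in :mod:`ensembledyn.synthetic_data`.

Residue numbering is 1-based everywhere in I/O and reports.  Coordinates are
stored in nm and times in ps; Angstrom-based formats are converted on read
and write.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATOM_COLUMNS = ("residue_index", "residue_name", "atom_name", "element")

#: atoms used for "main chain" rmsd, in preference order
MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


@dataclass
class EnsembleFrameSet:
    """Ordered conformational ensemble over a fixed atom table.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    atom_table
        One row per atom with columns ``residue_index`` (1-based),
        ``residue_name``, ``atom_name`` and ``element``.  Atom order is the
        frame coordinate order.
    time_per_frame
        Sampling interval between consecutive frames, in ps.
    system_label
        Free-text label identifying the system (used in all reports).
    superposed
        Whether the frames have been least-squares fitted to a common
        reference (set by :func:`superpose` and by the synthetic generators,
        which sample fluctuations about a fixed mean).
    """

    coords: np.ndarray
    atom_table: pd.DataFrame
    time_per_frame: float = 2.0
    system_label: str = "system"
    superposed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain non-finite values")
        if self.time_per_frame <= 0:
            raise ValueError("time_per_frame must be positive (ps)")
        missing = [c for c in ATOM_COLUMNS if c not in self.atom_table.columns]
        if missing:
            raise ValueError(f"atom_table missing columns: {missing}")
        if len(self.atom_table) != self.coords.shape[1]:
            raise ValueError(
                f"atom_table has {len(self.atom_table)} rows but frames carry "
                f"{self.coords.shape[1]} atoms"
            )
        self.atom_table = self.atom_table.reset_index(drop=True)
        self._calpha_index = self._build_calpha_index()

    def _build_calpha_index(self) -> np.ndarray:
        """Per-residue pointer to its Cα atom row; errors name offenders."""
        rows: list[int] = []
        for resi, group in self.atom_table.groupby("residue_index", sort=True):
            ca = group.index[group["atom_name"] == "CA"]
            if len(ca) != 1:
                name = group["residue_name"].iloc[0]
                raise ValueError(
                    f"residue {name}{resi} has {len(ca)} CA atoms (expected exactly 1)"
                )
            rows.append(int(ca[0]))
        return np.asarray(rows, dtype=int)

    # ------------------------------------------------------------------ views
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_indices(self) -> np.ndarray:
        """Sorted 1-based residue indices."""
        return np.asarray(sorted(self.atom_table["residue_index"].unique()), dtype=int)

    @property
    def n_residues(self) -> int:
        return len(self._calpha_index)

    @property
    def residue_names(self) -> np.ndarray:
        return self.atom_table["residue_name"].to_numpy()[self._calpha_index]

    @property
    def calpha_index(self) -> np.ndarray:
        """Atom-row index of each residue's Cα, in residue order."""
        return self._calpha_index

    @property
    def calpha_coords(self) -> np.ndarray:
        """Cα coordinates, shape (n_frames, n_residues, 3)."""
        return self.coords[:, self._calpha_index, :]

    @property
    def duration_ps(self) -> float:
        return self.n_frames * self.time_per_frame

    def select_atoms(
        self,
        atom_names: Sequence[str] | None = None,
        residue_indices: Sequence[int] | None = None,
    ) -> np.ndarray:
        """Atom-row indices matching the given names and/or residues."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= self.atom_table["atom_name"].isin(atom_names).to_numpy()
        if residue_indices is not None:
            mask &= self.atom_table["residue_index"].isin(residue_indices).to_numpy()
        return np.nonzero(mask)[0]

    def main_chain_selection(self) -> np.ndarray:
        """N/CA/C/O atoms when present, else Cα only (logged downgrade)."""
        sel = self.select_atoms(atom_names=MAIN_CHAIN_ATOMS)
        names = set(self.atom_table["atom_name"].iloc[sel])
        if names <= {"CA"}:
            logger.info(
                "%s: no backbone N/C/O atoms found, using Calpha-only main chain",
                self.system_label,
            )
        return sel

    def slice_frames(self, start: int, stop: int) -> "EnsembleFrameSet":
        return replace(self, coords=self.coords[start:stop].copy())


@dataclass
class ResidueCorrespondence:
    """Gapped one-to-one residue mapping between two homologous systems.

    ``pairs`` lists ``(index_a, index_b)`` tuples in alignment order; a gap on
    either side is ``None``.  Mapped indices are strictly increasing on both
    sides (the alignment is colinear) and one-to-one.
    """

    pairs: list[tuple[int | None, int | None]]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        a_seen = [a for a, _ in self.pairs if a is not None]
        b_seen = [b for _, b in self.pairs if b is not None]
        if len(set(a_seen)) != len(a_seen) or len(set(b_seen)) != len(b_seen):
            raise ValueError("correspondence is not one-to-one")
        if any(x >= y for x, y in zip(a_seen, a_seen[1:])):
            raise ValueError(f"{self.label_a} indices not strictly increasing")
        if any(x >= y for x, y in zip(b_seen, b_seen[1:])):
            raise ValueError(f"{self.label_b} indices not strictly increasing")
        self._a_to_b = {a: b for a, b in self.pairs if a is not None}
        self._b_to_a = {b: a for a, b in self.pairs if b is not None}

    def map_a_to_b(self, index_a: int) -> int | None:
        """B index for an A residue, ``None`` when aligned to a gap."""
        if index_a not in self._a_to_b:
            raise KeyError(
                f"residue {index_a} of {self.label_a} not covered by the correspondence"
            )
        return self._a_to_b[index_a]

    def map_b_to_a(self, index_b: int) -> int | None:
        if index_b not in self._b_to_a:
            raise KeyError(
                f"residue {index_b} of {self.label_b} not covered by the correspondence"
            )
        return self._b_to_a[index_b]

    @property
    def n_gaps(self) -> int:
        return sum(1 for a, b in self.pairs if a is None or b is None)

    @classmethod
    def identity(cls, n_residues: int, label_a: str = "A", label_b: str = "B"):
        return cls([(i, i) for i in range(1, n_residues + 1)], label_a, label_b)


@dataclass
class DomainDefinition:
    """Named residue-index intervals for one system (inclusive bounds).

    A domain may span several disjoint intervals (e.g. a barrel domain split
    by an inserted domain).
    """

    domains: dict[str, list[tuple[int, int]]]
    n_residues: int | None = None

    def __post_init__(self) -> None:
        for name, intervals in self.domains.items():
            for lo, hi in intervals:
                if lo < 1 or lo > hi:
                    raise ValueError(f"domain {name}: bad interval ({lo}, {hi})")
                if self.n_residues is not None and hi > self.n_residues:
                    raise ValueError(
                        f"domain {name}: interval ({lo}, {hi}) exceeds {self.n_residues} residues"
                    )

    def residues(self, name: str) -> list[int]:
        out: list[int] = []
        for lo, hi in self.domains[name]:
            out.extend(range(lo, hi + 1))
        return out


# ---------------------------------------------------------------------------
# Loading and writing
# ---------------------------------------------------------------------------

def load_ensemble(
    path: str | Path,
    topology: str | Path | None = None,
    time_per_frame: float | None = None,
    system_label: str | None = None,
) -> EnsembleFrameSet:
    """Load a conformational ensemble from standard structure/trajectory files.

    Parameters
    ----------
    path
        Multi-model PDB, or a trajectory file (XTC/DCD/...) when
        ``topology`` is given.
    topology
        Optional coordinate/topology file (PDB/GRO) paired with a trajectory.
    time_per_frame
        Override the frame spacing in ps (some formats carry no times).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions / 10.0 for _ in u.trajectory])
        try:
            elements = [str(e) for e in u.atoms.elements]
        except Exception:
            elements = [name[0] for name in u.atoms.names]
        table = pd.DataFrame(
            {
                "residue_index": u.atoms.resids.astype(int),
                "residue_name": [str(r) for r in u.atoms.resnames],
                "atom_name": [str(n) for n in u.atoms.names],
                "element": elements,
            }
        )
        if time_per_frame is None:
            dt = float(getattr(u.trajectory, "dt", 0.0) or 0.0)
            time_per_frame = dt if dt > 0 else 1.0
    return EnsembleFrameSet(
        coords=frames,
        atom_table=table,
        time_per_frame=time_per_frame,
        system_label=system_label or path.stem,
    )


def write_ensemble(ens: EnsembleFrameSet, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    import MDAnalysis as mda

    path = Path(path)
    n_res = ens.n_residues
    resmap = {r: i for i, r in enumerate(ens.residue_indices)}
    atom_res = np.array([resmap[r] for r in ens.atom_table["residue_index"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            ens.n_atoms, n_residues=n_res, atom_resindex=atom_res, trajectory=True
        )
        u.add_TopologyAttr("names", list(ens.atom_table["atom_name"]))
        u.add_TopologyAttr("elements", list(ens.atom_table["element"]))
        resnames = [None] * n_res
        for resi, name in zip(ens.atom_table["residue_index"], ens.atom_table["residue_name"]):
            resnames[resmap[resi]] = name
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", [int(r) for r in ens.residue_indices])
        with mda.Writer(str(path), multiframe=True, n_atoms=ens.n_atoms) as w:
            for frame in ens.coords:
                u.atoms.positions = frame * 10.0
                w.write(u.atoms)


def load_correspondence(
    path: str | Path, label_a: str = "A", label_b: str = "B"
) -> ResidueCorrespondence:
    """Read a correspondence TSV with columns indexA, indexB ('-' for gaps)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    pairs: list[tuple[int | None, int | None]] = []
    for _, row in df.iterrows():
        a = None if row.iloc[0].strip() == "-" else int(row.iloc[0])
        b = None if row.iloc[1].strip() == "-" else int(row.iloc[1])
        pairs.append((a, b))
    return ResidueCorrespondence(pairs, label_a, label_b)


def write_correspondence(corr: ResidueCorrespondence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("indexA\tindexB\n")
        for a, b in corr.pairs:
            fh.write(f"{'-' if a is None else a}\t{'-' if b is None else b}\n")


def write_profile(
    values: Sequence[float],
    ens: EnsembleFrameSet,
    path: str | Path,
    value_name: str = "value",
    header_lines: Iterable[str] = (),
) -> None:
    """Write a per-residue profile as TSV (residue_index, residue_name, value)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"residue_index\tresidue_name\t{value_name}\n")
        for resi, name, v in zip(ens.residue_indices, ens.residue_names, values):
            fh.write(f"{resi}\t{name}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Macro-trajectory assembly
# ---------------------------------------------------------------------------

def join_macrotrajectory(
    parts: Sequence[EnsembleFrameSet],
    discard_ps_per_part: Sequence[float] | None = None,
) -> EnsembleFrameSet:
    """Concatenate replica simulations into one macro-trajectory.

    Each part drops an initial equilibration prefix (``discard_ps_per_part``,
    in ps) before concatenation, so only the equilibrated portions enter the
    joined ensemble.
    """
    if not parts:
        raise ValueError("no parts to join")
    if discard_ps_per_part is None:
        discard_ps_per_part = [0.0] * len(parts)
    if len(discard_ps_per_part) != len(parts):
        raise ValueError("discard list must match the number of parts")
    ref = parts[0]
    kept: list[np.ndarray] = []
    for i, (part, discard) in enumerate(zip(parts, discard_ps_per_part)):
        if not part.atom_table[list(ATOM_COLUMNS)].equals(ref.atom_table[list(ATOM_COLUMNS)]):
            raise ValueError(f"part {i} atom table differs from part 0")
        if part.time_per_frame != ref.time_per_frame:
            raise ValueError(f"part {i} frame spacing differs from part 0")
        n_drop = int(round(discard / part.time_per_frame))
        if n_drop >= part.n_frames:
            raise ValueError(
                f"part {i}: discarding {discard} ps removes all {part.n_frames} frames"
            )
        kept.append(part.coords[n_drop:])
    return replace(ref, coords=np.concatenate(kept, axis=0), superposed=False)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _kabsch_rotations(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Batch of proper rotations mapping each centred frame onto ``ref``.

    ``mobile`` has shape (F, n, 3) (centred per frame), ``ref`` (n, 3)
    (centred).  Returns R of shape (F, 3, 3) with x' = R @ x.
    """
    H = np.einsum("fni,nj->fij", mobile, ref)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.transpose(0, 2, 1)
    d = np.sign(np.linalg.det(V @ U.transpose(0, 2, 1)))
    V = V.copy()
    V[:, :, 2] *= d[:, None]
    return V @ U.transpose(0, 2, 1)


def superpose(
    ens: EnsembleFrameSet,
    selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EnsembleFrameSet:
    """Least-squares fit every frame onto the iteratively refined mean.

    Each frame is rigidly fitted (on ``selection``, default all Cα) to the
    running mean structure; the mean is recomputed and the cycle repeats until
    it shifts by less than ``tol`` nm.  Internal fluctuations are untouched
    (rigid transforms only).
    """
    if selection is None:
        selection = ens.calpha_index
    selection = np.asarray(selection, dtype=int)
    if len(selection) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    coords = ens.coords.copy()

    sel0 = coords[0, selection]
    centred0 = sel0 - sel0.mean(axis=0)
    sv = np.linalg.svd(centred0, compute_uv=False)
    if sv[1] < 1e-9:
        raise ValueError("degenerate (collinear) superposition selection")

    ref = centred0
    for _ in range(max_iter):
        sel = coords[:, selection]
        cent = sel.mean(axis=1, keepdims=True)
        R = _kabsch_rotations(sel - cent, ref)
        coords = np.einsum("fai,fki->fak", coords - cent, R)
        new_ref = coords[:, selection].mean(axis=0)
        new_ref = new_ref - new_ref.mean(axis=0)
        shift = np.abs(new_ref - ref).max()
        ref = new_ref
        if shift < tol:
            break
    return replace(ens, coords=coords, superposed=True)


def representative_frame(
    ens: EnsembleFrameSet, selection: np.ndarray | None = None
) -> int:
    """Index of the frame closest (main-chain rmsd) to the coordinate mean.

    This is the ensemble's "average structure" proxy: the sampled conformation
    with the least main-chain rmsd from the average atomic positions.  Ties
    break toward the lowest frame index.
    """
    if ens.n_frames == 0:
        raise ValueError("empty ensemble")
    if selection is None:
        selection = ens.main_chain_selection()
    sel = ens.coords[:, selection]
    mean = sel.mean(axis=0)
    rmsd = np.sqrt(((sel - mean) ** 2).sum(axis=2).mean(axis=1))
    return int(np.argmin(rmsd))


# ---------------------------------------------------------------------------
# Profile utilities
# ---------------------------------------------------------------------------

def smooth_profile(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centred moving average over a per-residue profile.

    The window must be odd; near the ends the window truncates to the
    available residues, so the output has the same length as the input.
    """
    v = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(v):
        raise ValueError(f"window {window} larger than profile length {len(v)}")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def map_profile(
    values: Sequence[float],
    residue_indices: Sequence[int],
    corr: ResidueCorrespondence,
) -> pd.DataFrame:
    """Carry a per-residue profile of system A onto system B numbering.

    Returns a DataFrame with columns ``index_a``, ``value``, ``index_b`` and
    ``gap``; residues aligned to a gap are flagged, never dropped.
    """
    rows = []
    for resi, v in zip(residue_indices, values):
        b = corr.map_a_to_b(int(resi))
        rows.append(
            {
                "index_a": int(resi),
                "value": float(v),
                "index_b": -1 if b is None else int(b),
                "gap": b is None,
            }
        )
    return pd.DataFrame(rows)
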