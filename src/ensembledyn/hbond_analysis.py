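"""Geometric intramolecular hydrogen-bond detection over an ensemble.

A donor–acceptor pair is hydrogen-bonded in a frame when the donor–acceptor
distance is at most ``distance_cutoff`` (default 0.35 nm) and the angular
criterion holds (default: the donor-vertex angle between the donor→hydrogen
and donor→acceptor vectors is at most 30°).  The donor-vertex convention is
the common MD-package reading of a 30° cutoff; a hydrogen-vertex
(deviation-from-linearity of D–H···A) alternative is available behind the
``angle_vertex`` flag.

The ensemble summary is normalised by chemistry rather than by bond counts:
the headline number is the mean percentage of all donor+acceptor heavy atoms
that participate in at least one bond per frame.  Structures lacking
explicit hydrogens on their donors are rejected outright — distance-only
fallback detection would silently change the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import EnsembleFrameSet


def load_donor_acceptor_table(path: str | Path | None = None) -> pd.DataFrame:
    """Donor/acceptor chemistry table; ``residue_name`` '*' matches any residue."""
    if path is None:
        ref = resources.files("ensembledyn.data") / "hbond_donors_acceptors.tsv"
        with resources.as_file(ref) as p:
            return load_donor_acceptor_table(p)
    df = pd.read_csv(path, sep="\t", comment="#").fillna("")
    if df.empty:
        raise ValueError("empty donor/acceptor table")
    return df


@dataclass
class HBondCriteria:
    """Geometric criteria and chemistry table for H-bond detection."""

    distance_cutoff: float = 0.35        # nm, donor–acceptor
    angle_cutoff: float = 30.0           # degrees
    angle_vertex: str = "donor"          # "donor" or "hydrogen"
    table: pd.DataFrame = field(default_factory=load_donor_acceptor_table)
    exclude_same_residue: bool = True

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")
        if self.table.empty:
            raise ValueError("empty donor/acceptor table")


@dataclass
class HBondSummary:
    """Detected bonds and ensemble persistence statistics."""

    #: one row per (donor atom, hydrogen atom, acceptor atom) triplet detected
    #: in >= 1 frame, with its persistence over frames
    persistence: pd.DataFrame
    #: boolean (n_frames, n_triplets) detection matrix, column order as above
    detected: np.ndarray
    #: atom-row indices of donor heavy atoms and acceptor atoms considered
    donor_atoms: np.ndarray
    acceptor_atoms: np.ndarray
    n_frames: int


def _resolve_chemistry(ens: EnsembleFrameSet, table: pd.DataFrame):
    """Map the chemistry table onto the ensemble's atom table.

    Returns donor triplets [(D_row, H_row)], acceptor rows, and errors for
    donors whose hydrogens are missing.
    """
    at = ens.atom_table
    key = {(int(r), a): i for i, (r, a) in enumerate(zip(at["residue_index"], at["atom_name"]))}
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    missing_h: list[str] = []
    for resi, group in at.groupby("residue_index", sort=True):
        resname = group["residue_name"].iloc[0]
        rows = table[(table["residue_name"] == "*") | (table["residue_name"] == resname)]
        present = set(group["atom_name"])
        for _, row in rows.iterrows():
            heavy = row["heavy_atom"]
            if heavy not in present:
                continue
            if row["role"] == "acceptor":
                acceptors.append(key[(int(resi), heavy)])
            else:
                hs = [h for h in str(row["hydrogens"]).split(",") if h]
                found = [h for h in hs if h in present]
                if not found:
                    missing_h.append(f"{resname}{resi}:{heavy}")
                for h in found:
                    donors.append((key[(int(resi), heavy)], key[(int(resi), h)]))
    if missing_h:
        raise ValueError(
            "donor atoms without attached hydrogens (explicit hydrogens are "
            "required): " + ", ".join(missing_h)
        )
    return donors, sorted(set(acceptors))


def detect_hbonds(ens: EnsembleFrameSet, crit: HBondCriteria | None = None) -> HBondSummary:
    """Detect intramolecular hydrogen bonds in every frame of the ensemble."""
    if crit is None:
        crit = HBondCriteria()
    donors, acceptors = _resolve_chemistry(ens, crit.table)
    at = ens.atom_table
    resid = at["residue_index"].to_numpy()

    if not donors or not acceptors:
        empty = pd.DataFrame(
            columns=["donor", "hydrogen", "acceptor", "persistence"]
        )
        return HBondSummary(
            persistence=empty,
            detected=np.zeros((ens.n_frames, 0), dtype=bool),
            donor_atoms=np.array([d for d, _ in donors], dtype=int),
            acceptor_atoms=np.array(acceptors, dtype=int),
            n_frames=ens.n_frames,
        )

    d_rows = np.array([d for d, _ in donors])
    h_rows = np.array([h for _, h in donors])
    a_rows = np.array(acceptors)
    cos_cut = np.cos(np.radians(crit.angle_cutoff))

    D = ens.coords[:, d_rows]        # (F, nd, 3)
    H = ens.coords[:, h_rows]
    A = ens.coords[:, a_rows]        # (F, na, 3)

    dvec = A[:, None, :, :] - D[:, :, None, :]           # D -> A
    dist = np.linalg.norm(dvec, axis=-1)                 # (F, nd, na)
    ok = dist <= crit.distance_cutoff
    if crit.exclude_same_residue:
        same = resid[d_rows][:, None] == resid[a_rows][None, :]
        ok &= ~same[None, :, :]
    # a donor heavy atom can also be listed as acceptor; never bond to itself
    ok &= (d_rows[:, None] != a_rows[None, :])[None, :, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        if crit.angle_vertex == "donor":
            hvec = H - D                                  # (F, nd, 3)
            num = np.einsum("fda,fdna->fdn", hvec, dvec)
            denom = np.linalg.norm(hvec, axis=-1)[:, :, None] * dist
            cosang = num / denom
            ok &= cosang >= cos_cut
        else:
            # deviation of D-H...A from linearity, measured at the hydrogen
            hd = D - H
            ha = A[:, None, :, :] - H[:, :, None, :]
            num = np.einsum("fda,fdna->fdn", hd, ha)
            denom = np.linalg.norm(hd, axis=-1)[:, :, None] * np.linalg.norm(ha, axis=-1)
            cosang = num / denom
            # ideal geometry has D-H-A = 180 deg; cutoff bounds the deviation
            ok &= cosang <= -np.cos(np.radians(crit.angle_cutoff))

    any_pair = ok.any(axis=0)                             # (nd, na)
    di, ai = np.nonzero(any_pair)
    detected = ok[:, di, ai]                              # (F, n_triplets)
    persistence = pd.DataFrame(
        {
            "donor": d_rows[di],
            "hydrogen": h_rows[di],
            "acceptor": a_rows[ai],
            "donor_residue": resid[d_rows[di]],
            "acceptor_residue": resid[a_rows[ai]],
            "persistence": detected.mean(axis=0),
        }
    )
    return HBondSummary(
        persistence=persistence,
        detected=detected,
        donor_atoms=np.unique(d_rows),
        acceptor_atoms=a_rows,
        n_frames=ens.n_frames,
    )


def normalized_hbond_fraction(summary: HBondSummary) -> float:
    """Mean percentage of donor+acceptor atoms involved in H-bonds per frame.

    Counts distinct heavy atoms (donor or acceptor) that participate in at
    least one bond in a frame, divided by the total number of donor+acceptor
    heavy atoms (atoms playing both roles are counted once), averaged over
    frames and expressed as a percentage.
    """
    pool = np.union1d(summary.donor_atoms, summary.acceptor_atoms)
    if len(pool) == 0:
        raise ValueError("no donor or acceptor atoms in the system")
    if summary.detected.shape[1] == 0:
        return 0.0
    donors = summary.persistence["donor"].to_numpy()
    acceptors = summary.persistence["acceptor"].to_numpy()
    fractions = np.empty(summary.n_frames)
    for f in range(summary.n_frames):
        mask = summary.detected[f]
        involved = set(donors[mask]) | set(acceptors[mask])
        fractions[f] = len(involved) / len(pool)
    return 100.0 * float(fractions.mean())
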