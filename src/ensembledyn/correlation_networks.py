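"""Windowed dynamic cross-correlation matrices and correlation networks.

The residue-pair correlation is

    C(i,j) = c(i,j) / sqrt(c(i,i) * c(j,j)),

where c(i,j) is the covariance of the Cα fluctuation vectors of residues i
and j (the scalar product of displacement vectors averaged over frames).
Correlations are computed on non-overlapping time windows (default 1 ns) —
each window's frames are re-fitted to the window mean so slow drift does not
inflate correlations — and the per-window matrices are averaged elementwise
into the matrix used for analysis; the per-window matrices are retained for
consistency checks.

The network view keeps only significant long-range correlations: |C| above
a cutoff (default 0.4) between residues more than a sequence-separation
cutoff apart (default |i-j| > 12, which removes within-helix and
contiguous-residue correlations).  Pairs inside the same secondary-structure
element (same helix, or both in barrel strands) can additionally be masked
out through an explicit, caller-supplied exclusion mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ensemble_io import EnsembleFrameSet, ResidueCorrespondence, superpose

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Window-averaged residue-pair correlation matrix."""

    matrix: np.ndarray               # (N, N), NaN where a window had zero variance
    residue_indices: np.ndarray
    window_ps: float
    per_window: list[np.ndarray]
    n_windows: int


@dataclass
class CorrelationNetwork:
    """Thresholded long-range correlation edges of one system."""

    edges: pd.DataFrame              # columns i, j (residue indices, i < j), c
    c_cut: float
    sep_cut: int
    mask_provenance: str
    system_label: str = ""

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(self.edges["i"], self.edges["j"])}


def _window_correlation(ca: np.ndarray) -> np.ndarray:
    """Correlation matrix of one window's Cα coordinates (F, N, 3)."""
    fluct = ca - ca.mean(axis=0)
    c = np.einsum("fia,fja->ij", fluct, fluct) / ca.shape[0]
    var = np.diag(c).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = c / np.sqrt(np.outer(var, var))
    bad = var <= 0
    if bad.any():
        corr[bad, :] = np.nan
        corr[:, bad] = np.nan
    idx = np.arange(len(var))
    corr[idx[~bad], idx[~bad]] = 1.0
    return corr


def windowed_correlation(
    ens: EnsembleFrameSet,
    window_ps: float = 1000.0,
    refit_windows: bool | str = "auto",
) -> CorrelationMatrix:
    """Cα cross-correlation matrix averaged over non-overlapping windows.

    A trailing partial window is dropped.  Residues with zero variance in a
    window are masked (NaN) in that window and logged; the average is over
    the windows where the entry is defined.

    ``refit_windows`` re-superposes each window's frames onto the window
    mean so slow rigid drift between windows does not inflate correlations;
    the default ``"auto"`` refits only when the ensemble is not already
    superposed (on a drift-free ensemble the refit would merely perturb the
    fluctuations it is meant to protect).
    """
    if refit_windows == "auto":
        refit_windows = not ens.superposed
    dt = ens.time_per_frame
    win_f = int(round(window_ps / dt))
    if win_f < 2:
        raise ValueError("window shorter than two frames")
    n_win = ens.n_frames // win_f
    if n_win == 0:
        raise ValueError(
            f"trajectory ({ens.duration_ps} ps) shorter than one window ({window_ps} ps)"
        )
    per_window: list[np.ndarray] = []
    for w in range(n_win):
        sl = ens.slice_frames(w * win_f, (w + 1) * win_f)
        if refit_windows:
            sl = superpose(sl)
        corr = _window_correlation(sl.calpha_coords)
        if np.isnan(corr).any():
            logger.warning(
                "%s: zero-variance residues masked in window %d", ens.system_label, w
            )
        per_window.append(corr)
    stack = np.stack(per_window)
    with warnings.catch_warnings():
        # entries masked in every window stay NaN in the average
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        avg = np.nanmean(stack, axis=0)
    return CorrelationMatrix(
        matrix=avg,
        residue_indices=ens.residue_indices,
        window_ps=window_ps,
        per_window=per_window,
        n_windows=n_win,
    )


def build_ss_exclusion_mask(
    residue_elements: dict[int, str],
    helices: set[str],
    barrel_strands: set[str],
    residue_indices: np.ndarray,
) -> np.ndarray:
    """Pair-exclusion mask from a secondary-structure element annotation.

    ``residue_elements`` maps residue index → element id (e.g. ``"a3"``,
    ``"b7"``); ``helices`` and ``barrel_strands`` say which element ids are
    α-helices and barrel β-strands.  A pair is excluded when both residues
    belong to the same helix, or both lie in (any) barrel strands — the two
    discard classes used when isolating functional long-range couplings.
    """
    n = len(residue_indices)
    elem = [residue_elements.get(int(r)) for r in residue_indices]
    mask = np.zeros((n, n), dtype=bool)
    for a in range(n):
        ea = elem[a]
        if ea is None:
            continue
        for b in range(a + 1, n):
            eb = elem[b]
            if eb is None:
                continue
            if (ea == eb and ea in helices) or (ea in barrel_strands and eb in barrel_strands):
                mask[a, b] = mask[b, a] = True
    return mask


def filter_network(
    cm: CorrelationMatrix,
    c_cut: float = 0.4,
    sep_cut: int = 12,
    exclusion_mask: np.ndarray | None = None,
    mask_provenance: str = "none",
    system_label: str = "",
) -> CorrelationNetwork:
    """Keep significant long-range correlations as a weighted edge list.

    An edge (i, j) survives iff |C(i,j)| > ``c_cut`` (strict), the sequence
    separation |i-j| > ``sep_cut`` (strict), the entry is defined, and the
    pair is not excluded by the secondary-structure mask.  Edge weights keep
    the signed C value, suitable for thickness-proportional export.  An
    empty network is a valid result.
    """
    m = cm.matrix
    resi = cm.residue_indices
    n = len(resi)
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            c = m[a, b]
            if not np.isfinite(c) or abs(c) <= c_cut:
                continue
            if abs(int(resi[b]) - int(resi[a])) <= sep_cut:
                continue
            if exclusion_mask is not None and exclusion_mask[a, b]:
                continue
            rows.append({"i": int(resi[a]), "j": int(resi[b]), "c": float(c)})
    edges = pd.DataFrame(rows, columns=["i", "j", "c"])
    return CorrelationNetwork(
        edges=edges,
        c_cut=c_cut,
        sep_cut=sep_cut,
        mask_provenance=mask_provenance,
        system_label=system_label,
    )


@dataclass
class NetworkDiff:
    """Edge sets shared and specific to two systems, in each system's numbering."""

    shared: set[tuple[int, int]]     # A numbering
    only_a: set[tuple[int, int]]     # A numbering
    only_b: set[tuple[int, int]]     # B numbering
    unmappable_a: set[tuple[int, int]]
    unmappable_b: set[tuple[int, int]]


def network_diff(
    a: CorrelationNetwork, b: CorrelationNetwork, corr: ResidueCorrespondence
) -> NetworkDiff:
    """Compare two correlation networks through a residue correspondence.

    Edges of A are mapped into B numbering; an edge touching a gapped residue
    cannot be compared and is reported in the ``unmappable`` set of its own
    system, never silently dropped.
    """
    b_edges = b.edge_set()
    shared: set[tuple[int, int]] = set()
    only_a: set[tuple[int, int]] = set()
    unmappable_a: set[tuple[int, int]] = set()
    mapped_b: set[tuple[int, int]] = set()
    for i, j in a.edge_set():
        bi, bj = corr.map_a_to_b(i), corr.map_a_to_b(j)
        if bi is None or bj is None:
            unmappable_a.add((i, j))
            continue
        key = (min(bi, bj), max(bi, bj))
        if key in b_edges:
            shared.add((i, j))
            mapped_b.add(key)
        else:
            only_a.add((i, j))
    only_b: set[tuple[int, int]] = set()
    unmappable_b: set[tuple[int, int]] = set()
    for i, j in b_edges:
        ai, aj = corr.map_b_to_a(i), corr.map_b_to_a(j)
        if ai is None or aj is None:
            unmappable_b.add((i, j))
        elif (i, j) not in mapped_b:
            only_b.add((i, j))
    return NetworkDiff(
        shared=shared,
        only_a=only_a,
        only_b=only_b,
        unmappable_a=unmappable_a,
        unmappable_b=unmappable_b,
    )
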