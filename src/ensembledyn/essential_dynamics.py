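"""Essential dynamics: covariance analysis of Cα positional fluctuations.

The 3N×3N covariance matrix of the Cα fluctuations (mass-unweighted, equal
frame weights) is diagonalised; the eigenvectors with the largest
eigenvalues describe the large-amplitude collective motions and the span of
the first k of them is the *essential subspace*.  The default picks the
smallest k whose cumulative variance fraction reaches 70% (in well-sampled
protein ensembles this is typically around 10 eigenvectors); a fixed k can
be requested instead for cross-system comparability.

Downstream quantities:

* per-residue rmsf after projection of the trajectory onto the essential
  subspace (fluctuations reconstructed from the first k projections, then
  rmsf about the reconstructed mean);
* per-residue anisotropic U-tensors (3×3 covariance of the reconstructed Cα
  fluctuations), with the ellipsoid scale factor for a chosen probability
  level (χ²₃ quantile convention);
* sampling-quality indices: cosine content of the principal projections
  (values near 1 flag random-diffusion-like, unconverged sampling) and the
  root mean square inner product (RMSIP) between two subspaces;
* rmsf convergence over sliding time windows of several lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .ensemble_io import EnsembleFrameSet

logger = logging.getLogger(__name__)

#: max tolerated Cα-centroid drift (nm) for an ensemble claiming no superposition
DRIFT_TOLERANCE = 0.02


@dataclass
class EssentialSubspace:
    """Eigensystem of the Cα fluctuation covariance matrix."""

    eigenvalues: np.ndarray          # (3N,), nm², descending
    eigenvectors: np.ndarray         # (3N, 3N), columns orthonormal
    mean: np.ndarray                 # (3N,) flattened mean Cα structure
    cumulative_variance: np.ndarray  # (3N,), nondecreasing in [0, 1]
    k: int | None                    # selected dimension; None when degenerate
    degenerate: bool
    n_residues: int
    variance_target: float

    @property
    def dim(self) -> int:
        return len(self.eigenvalues)


@dataclass
class FlexibilityProfile:
    """Per-residue rmsf (nm) of the subspace-filtered fluctuations."""

    residue_indices: np.ndarray
    rmsf: np.ndarray
    k: int


@dataclass
class AnisotropicTensorSet:
    """Per-residue 3×3 Cα covariance tensors in the essential subspace."""

    residue_indices: np.ndarray
    tensors: np.ndarray              # (N, 3, 3), nm²
    probability: float
    ellipsoid_scale: float           # sqrt of the chi2_3 quantile at `probability`
    k: int


def _flat_calpha(ens: EnsembleFrameSet) -> np.ndarray:
    return ens.calpha_coords.reshape(ens.n_frames, -1)


def _check_superposed(ens: EnsembleFrameSet) -> None:
    if ens.superposed:
        return
    ca = ens.calpha_coords
    centroids = ca.mean(axis=1)
    drift = np.linalg.norm(centroids - centroids.mean(axis=0), axis=1).max()
    if drift > DRIFT_TOLERANCE:
        raise ValueError(
            f"ensemble '{ens.system_label}' appears unsuperposed "
            f"(Calpha centroid drift {drift:.3g} nm); run superpose() first"
        )


def compute_subspace(
    ens: EnsembleFrameSet,
    variance_target: float = 0.70,
    k_fixed: int | None = None,
) -> EssentialSubspace:
    """Diagonalise the Cα covariance matrix and select the essential subspace.

    ``k`` is the smallest dimension whose cumulative variance fraction
    reaches ``variance_target``, unless ``k_fixed`` overrides it.  A rigid
    ensemble (zero total variance) is flagged degenerate with ``k = None``.
    """
    if ens.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance analysis")
    _check_superposed(ens)
    X = _flat_calpha(ens)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / ens.n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    # reproducible sign: largest-magnitude component of each eigenvector positive
    lead = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[lead, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs

    total = vals.sum()
    degenerate = total < 1e-12
    if degenerate:
        cumvar = np.zeros_like(vals)
        k = None
        logger.warning("%s: rigid ensemble, essential subspace undefined", ens.system_label)
    else:
        cumvar = np.cumsum(vals) / total
        k = int(np.searchsorted(cumvar, variance_target) + 1)
        k = min(k, len(vals))
    if k_fixed is not None:
        if not 1 <= k_fixed <= len(vals):
            raise ValueError(f"k_fixed must be in 1..{len(vals)}")
        k = k_fixed
    return EssentialSubspace(
        eigenvalues=vals,
        eigenvectors=vecs,
        mean=mean,
        cumulative_variance=cumvar,
        k=k,
        degenerate=degenerate,
        n_residues=ens.n_residues,
        variance_target=variance_target,
    )


def _reconstructed_fluctuations(
    ens: EnsembleFrameSet, sub: EssentialSubspace, k: int | None
) -> np.ndarray:
    """Fluctuations rebuilt from the first-k eigenvector projections, (F, 3N)."""
    if k is None:
        k = sub.k
    if k is None:
        raise ValueError("subspace is degenerate; pass an explicit k")
    X = _flat_calpha(ens)
    if X.shape[1] != sub.dim:
        raise ValueError(
            f"dimension mismatch: ensemble has 3N={X.shape[1]}, subspace {sub.dim}"
        )
    Vk = sub.eigenvectors[:, :k]
    Xc = X - sub.mean
    return (Xc @ Vk) @ Vk.T


def project_and_rmsf(
    ens: EnsembleFrameSet, sub: EssentialSubspace, k: int | None = None
) -> FlexibilityProfile:
    """Per-residue rmsf of the trajectory projected onto the essential subspace.

    Frames are reconstructed from their first-k projections and the rmsf is
    taken about the mean of the reconstructed ensemble; at k = 3N this equals
    the ordinary rmsf, and per residue it can never exceed it.
    """
    Y = _reconstructed_fluctuations(ens, sub, k)
    k_used = k if k is not None else sub.k
    Yc = Y - Y.mean(axis=0)
    per_res = Yc.reshape(ens.n_frames, sub.n_residues, 3)
    rmsf = np.sqrt((per_res ** 2).sum(axis=2).mean(axis=0))
    return FlexibilityProfile(
        residue_indices=ens.residue_indices, rmsf=rmsf, k=int(k_used)
    )


def anisotropic_tensors(
    ens: EnsembleFrameSet,
    sub: EssentialSubspace,
    probability: float = 0.1,
    k: int | None = None,
) -> AnisotropicTensorSet:
    """Per-residue anisotropic U-tensors of the subspace-filtered motion.

    Each tensor is the 3×3 covariance of the reconstructed Cα fluctuations of
    one residue; its trace equals that residue's squared subspace rmsf.  The
    recorded ellipsoid scale converts the tensor into the iso-probability
    ellipsoid at the requested level (``sqrt(chi2.ppf(probability, 3))``).
    """
    if not 0 < probability < 1:
        raise ValueError("probability must be in (0, 1)")
    Y = _reconstructed_fluctuations(ens, sub, k)
    k_used = k if k is not None else sub.k
    Yc = (Y - Y.mean(axis=0)).reshape(ens.n_frames, sub.n_residues, 3)
    tensors = np.einsum("fia,fib->iab", Yc, Yc) / ens.n_frames
    return AnisotropicTensorSet(
        residue_indices=ens.residue_indices,
        tensors=tensors,
        probability=probability,
        ellipsoid_scale=float(np.sqrt(chi2.ppf(probability, df=3))),
        k=int(k_used),
    )


def cosine_content(ens: EnsembleFrameSet, sub: EssentialSubspace, n_projections: int = 5) -> np.ndarray:
    """Cosine content of the first principal projections, each in [0, 1].

    The i-th projection is compared against a half-period-count-i cosine over
    the trajectory length; values near 1 indicate random-diffusion-like
    sampling of that mode.
    """
    X = _flat_calpha(ens)
    if X.shape[1] != sub.dim:
        raise ValueError("dimension mismatch between ensemble and subspace")
    Xc = X - sub.mean
    F = ens.n_frames
    t = (np.arange(F) + 0.5) / F
    out = np.empty(n_projections)
    for i in range(n_projections):
        p = Xc @ sub.eigenvectors[:, i]
        c = np.cos((i + 1) * np.pi * t)
        denom = (p ** 2).sum()
        out[i] = 0.0 if denom == 0 else (2.0 / F) * (c @ p) ** 2 / denom
    return out


def rmsip(a: EssentialSubspace, b: EssentialSubspace, n_vectors: int = 10) -> float:
    """Root mean square inner product between the first eigenvectors of two subspaces.

    RMSIP = sqrt( (1/n) * sum_ij (a_i . b_j)^2 ) over the first ``n_vectors``
    of each; 1 means identical spans, 0 orthogonal spans.
    """
    if a.dim != b.dim:
        raise ValueError("subspaces live in different ambient dimensions")
    n = min(n_vectors, a.dim)
    A = a.eigenvectors[:, :n]
    B = b.eigenvectors[:, :n]
    return float(np.sqrt(((A.T @ B) ** 2).sum() / n))


def sampling_quality(
    ens: EnsembleFrameSet,
    sub: EssentialSubspace,
    other: EssentialSubspace | None = None,
    n_projections: int = 5,
    n_vectors: int = 10,
) -> dict:
    """Convenience bundle: cosine contents, plus RMSIP when ``other`` is given."""
    out = {"cosine_content": cosine_content(ens, sub, n_projections)}
    if other is not None:
        out["rmsip"] = rmsip(sub, other, n_vectors)
    return out


def rmsf_convergence(
    ens: EnsembleFrameSet,
    window_lengths_ns: tuple[float, ...] = (1, 2, 5, 10, 15, 20),
    step_ps: float = 500.0,
) -> dict[float, dict]:
    """Mean rmsf profiles over sliding windows of several lengths.

    For each window length L, windows start at the first frame and advance by
    ``step_ps``; the per-window plain Cα rmsf (about the window mean) is
    averaged into one profile.  The window count is
    ``floor((T - L) / step) + 1``.  Lengths longer than the trajectory are
    skipped with a warning.  A stationary fluctuation process yields profiles
    that agree across window lengths to within sampling error.
    """
    _check_superposed(ens)
    dt = ens.time_per_frame
    F = ens.n_frames
    ca = ens.calpha_coords
    step_f = max(1, int(round(step_ps / dt)))
    results: dict[float, dict] = {}
    for L in window_lengths_ns:
        win_f = int(round(L * 1000.0 / dt))
        if win_f < 2 or win_f > F:
            logger.warning(
                "%s: window length %g ns skipped (trajectory %g ns)",
                ens.system_label, L, F * dt / 1000.0,
            )
            continue
        n_win = (F - win_f) // step_f + 1
        acc = np.zeros(ens.n_residues)
        for w in range(n_win):
            seg = ca[w * step_f : w * step_f + win_f]
            fluct = seg - seg.mean(axis=0)
            acc += np.sqrt((fluct ** 2).sum(axis=2).mean(axis=0))
        results[float(L)] = {
            "profile": acc / n_win,
            "n_windows": int(n_win),
            "window_frames": int(win_f),
        }
    return results
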