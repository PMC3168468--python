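"""Synthetic conformational ensembles with known ground truth.

Every analysis stage in this package can be exercised without any external
trajectory: this module generates

* bead-chain Cα ensembles sampled from a planted low-rank Gaussian
  covariance (so essential-dynamics and cross-correlation recovery can be
  checked against the analytic answer),
* two-state salt-bridge contact time series with a bimodal persistence
  distribution (a low-persistence "noise" population below 10% and a
  "signal" population above 30%, mirroring the gap that motivates
  classifier-based persistence-cutoff selection),
* homolog pairs with indel-containing residue correspondences, and
* a two-system "wild-type vs mutant" comparison fixture with one planted
  gained salt bridge and one planted extra long-range correlated pair.

The generated objects use the same :class:`~ensembledyn.ensemble_io.EnsembleFrameSet`
data model as real input, so every downstream detector runs unchanged.
Nothing here is physically realistic (no force field, no solvent); the
chains exist only to carry planted statistical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_io import EnsembleFrameSet, ResidueCorrespondence

#: mean Cα-Cα spacing of the synthetic bead chain, nm (typical protein value)
CHAIN_SPACING = 0.38

#: default frame storage interval, ps
DEFAULT_DT = 2.0


def _chain_mean(n_residues: int, spacing: float = CHAIN_SPACING) -> np.ndarray:
    """Coarse helical bead chain, shape (n_residues, 3), nm.

    A helix (not a straight line) so the mean structure is non-degenerate:
    least-squares superposition onto it constrains all three rotation axes,
    which a collinear chain would not.
    """
    i = np.arange(n_residues)
    radius, rise, per_turn = 0.5, 0.15, 10.0
    theta = 2.0 * np.pi * i / per_turn
    return np.column_stack([rise * i, radius * np.cos(theta), radius * np.sin(theta)])


def _calpha_table(n_residues: int, residue_name: str = "ALA") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_index": np.arange(1, n_residues + 1),
            "residue_name": residue_name,
            "atom_name": "CA",
            "element": "C",
        }
    )


# ---------------------------------------------------------------------------
# Planted-covariance Gaussian ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantedCovarianceSpec:
    """Low-rank-plus-isotropic Gaussian fluctuation model for a bead chain.

    The Cα fluctuation covariance is ``Sigma = sum_k lam_k v_k v_k^T +
    noise * I`` over the 3N coordinate space, with orthonormal mode vectors
    ``v_k`` and eigenvalues ``lam_k`` in nm².
    """

    n_residues: int
    modes: list[tuple[float, np.ndarray]] = field(default_factory=list)
    isotropic_noise: float = 1e-4
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.isotropic_noise < 0:
            raise ValueError("isotropic_noise must be >= 0")
        dim = 3 * self.n_residues
        vecs = []
        for lam, v in self.modes:
            if lam < 0:
                raise ValueError("mode eigenvalues must be >= 0")
            v = np.asarray(v, dtype=float)
            if v.shape != (dim,):
                raise ValueError(f"mode vector must have length {dim}")
            vecs.append(v)
        if vecs:
            V = np.stack(vecs)
            gram = V @ V.T
            if not np.allclose(gram, np.eye(len(vecs)), atol=1e-8):
                raise ValueError("mode vectors are not orthonormal")

    @property
    def dim(self) -> int:
        return 3 * self.n_residues


@dataclass
class GaussianEnsembleTruth:
    """Analytic quantities implied by a :class:`PlantedCovarianceSpec`."""

    covariance: np.ndarray          # (3N, 3N) nm²
    correlation: np.ndarray         # (N, N) residue-pair correlation
    eigenvalues: np.ndarray         # all 3N, descending, nm²
    mode_vectors: np.ndarray        # (n_modes, 3N), the planted modes
    mean: np.ndarray                # (N, 3) nm


def _analytic_truth(spec: PlantedCovarianceSpec) -> GaussianEnsembleTruth:
    dim = spec.dim
    n = spec.n_residues
    cov = spec.isotropic_noise * np.eye(dim)
    for lam, v in spec.modes:
        cov += lam * np.outer(v, v)
    # residue-pair covariance: trace over the 3x3 block
    c = np.zeros((n, n))
    for a in range(3):
        c += cov[a::3, :][:, a::3]
    var = np.diag(c).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = c / np.sqrt(np.outer(var, var))
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, np.where(var > 0, 1.0, 0.0))
    lams = np.full(dim, spec.isotropic_noise)
    lams[: len(spec.modes)] += np.array([lam for lam, _ in spec.modes])
    lams = np.sort(lams)[::-1]
    modes = (
        np.stack([v for _, v in spec.modes])
        if spec.modes
        else np.zeros((0, dim))
    )
    return GaussianEnsembleTruth(
        covariance=cov,
        correlation=corr,
        eigenvalues=lams,
        mode_vectors=modes,
        mean=_chain_mean(n),
    )


def gen_gaussian_ensemble(
    spec: PlantedCovarianceSpec,
    time_per_frame: float = DEFAULT_DT,
    system_label: str = "synthetic",
) -> tuple[EnsembleFrameSet, GaussianEnsembleTruth]:
    """Sample a Cα bead-chain ensemble from a planted Gaussian covariance.

    Frames are drawn independently about a fixed mean structure (so the
    ensemble is born superposed) as ``x = mean + sum_k sqrt(lam_k) z_k v_k +
    sqrt(noise) * eps`` with standard-normal ``z`` and ``eps``.  Returns the
    ensemble together with the analytic covariance, residue correlation
    matrix and eigensystem implied by the spec.
    """
    truth = _analytic_truth(spec)
    rng = np.random.default_rng(spec.seed)
    dim = spec.dim
    flat = np.zeros((spec.n_frames, dim))
    for lam, v in spec.modes:
        z = rng.standard_normal(spec.n_frames)
        flat += np.sqrt(lam) * z[:, None] * v[None, :]
    if spec.isotropic_noise > 0:
        flat += np.sqrt(spec.isotropic_noise) * rng.standard_normal((spec.n_frames, dim))
    coords = flat.reshape(spec.n_frames, spec.n_residues, 3) + truth.mean[None]
    ens = EnsembleFrameSet(
        coords=coords,
        atom_table=_calpha_table(spec.n_residues),
        time_per_frame=time_per_frame,
        system_label=system_label,
        superposed=True,
    )
    return ens, truth


def pair_mode(n_residues: int, i: int, j: int, axis: int = 1) -> np.ndarray:
    """Unit 3N-vector moving residues ``i`` and ``j`` (1-based) in phase.

    Both residues displace identically along ``axis``, which makes their
    analytic cross-correlation along that mode equal to 1.  Note the raw
    mode carries net translation/rotation; use :func:`rigid_free_pair_modes`
    when the ensemble will be superposed or window-refitted, so the planted
    covariance lives entirely in the internal-motion subspace the analysis
    sees.
    """
    v = np.zeros(3 * n_residues)
    v[3 * (i - 1) + axis] = 1.0
    v[3 * (j - 1) + axis] = 1.0
    return v / np.linalg.norm(v)


def rigid_body_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of rigid translations/rotations at ``mean``.

    Least-squares superposition removes exactly these directions (to first
    order); modes orthogonal to them survive fitting unchanged.
    """
    n = mean.shape[0]
    centred = mean - mean.mean(axis=0)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centred).ravel())
    q, _ = np.linalg.qr(np.stack(basis).T)
    return q.T[:6]


def rigid_free_pair_modes(
    n_residues: int, pairs: Sequence[tuple[int, int]], axis: int = 1
) -> list[np.ndarray]:
    """Orthonormal in-phase pair modes with rigid-body components projected out.

    Each pair mode is orthogonalised against the 6 rigid directions of the
    straight-chain mean structure, then the set is orthonormalised by
    modified Gram-Schmidt (order-preserving, so each mode stays close to its
    raw pair displacement).
    """
    rigid = rigid_body_basis(_chain_mean(n_residues))
    out: list[np.ndarray] = []
    for i, j in pairs:
        v = pair_mode(n_residues, i, j, axis)
        v = v - rigid.T @ (rigid @ v)
        for u in out:
            v = v - u * (u @ v)
        nrm = np.linalg.norm(v)
        if nrm < 1e-9:
            raise ValueError(f"pair mode {(i, j)} vanishes after rigid projection")
        out.append(v / nrm)
    return out


# ---------------------------------------------------------------------------
# Two-state contact series (synthetic salt bridges)
# ---------------------------------------------------------------------------

@dataclass
class ContactSeriesSpec:
    """Bernoulli formed/broken contact series for pseudo salt-bridge pairs.

    Per-pair persistence values are drawn from a two-component mixture whose
    noise component lives below ``noise_max`` (default 0.10) and whose signal
    component lives above ``signal_min`` (default 0.30), leaving the interval
    in between empty — the signal/noise gap that persistence-cutoff selection
    must find.
    """

    n_pairs: int = 50
    n_frames: int = 2000
    contact_distance_formed: float = 0.30   # nm, inside the detection cutoff
    contact_distance_broken: float = 0.80   # nm, outside any sensible cutoff
    detection_cutoff: float = 0.40          # nm, cutoff the series is built for
    noise_weight: float = 0.5
    noise_max: float = 0.10
    signal_min: float = 0.30
    noise_beta: tuple[float, float] = (2.0, 38.0)    # mode near 0.05
    signal_beta: tuple[float, float] = (12.0, 8.0)   # mode near 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_distance_formed >= self.detection_cutoff:
            raise ValueError("formed distance must be below the detection cutoff")
        if self.contact_distance_broken <= self.detection_cutoff:
            raise ValueError("broken distance must be above the detection cutoff")
        if not (0 < self.noise_max < self.signal_min < 1):
            raise ValueError("need 0 < noise_max < signal_min < 1")


def sample_persistence_mixture(spec: ContactSeriesSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw per-pair persistences from the truncated two-component mixture."""
    out = np.empty(spec.n_pairs)
    is_noise = rng.random(spec.n_pairs) < spec.noise_weight
    for i in range(spec.n_pairs):
        a, b = spec.noise_beta if is_noise[i] else spec.signal_beta
        lo, hi = (0.0, spec.noise_max) if is_noise[i] else (spec.signal_min, 1.0)
        # rejection sampling into the component's support keeps the gap empty
        for _ in range(10000):
            p = rng.beta(a, b)
            if lo <= p < hi or (not is_noise[i] and p >= hi):
                p = min(p, 1.0)
                break
        else:  # pragma: no cover - mixture parameters keep acceptance high
            p = (lo + hi) / 2
        out[i] = p
    return out


def gen_contact_series(
    spec: ContactSeriesSpec,
    p_values: Sequence[float] | None = None,
    time_per_frame: float = DEFAULT_DT,
    system_label: str = "contacts",
) -> tuple[EnsembleFrameSet, pd.DataFrame]:
    """Generate an ensemble of charged pseudo-residue pairs with planted persistence.

    Pair ``k`` consists of a GLU-like residue (Cα + OE1, negative) and a
    LYS-like residue (Cα + NZ, positive).  In each frame the NZ–OE1 distance
    is the formed distance with probability ``p_k`` and the broken distance
    otherwise.  Pairs sit ~6 nm apart so they never cross-talk.  Returns the
    ensemble and a truth table with the planted ``p_true`` per pair.
    """
    rng = np.random.default_rng(spec.seed)
    if p_values is None:
        p_values = sample_persistence_mixture(spec, rng)
    p_values = np.asarray(p_values, dtype=float)
    if len(p_values) != spec.n_pairs:
        raise ValueError("p_values length must equal n_pairs")

    rows = []
    coords = np.zeros((spec.n_frames, 4 * spec.n_pairs, 3))
    truth_rows = []
    for k in range(spec.n_pairs):
        res_neg, res_pos = 2 * k + 1, 2 * k + 2
        base = np.array([0.0, 6.0 * k, 0.0])
        formed = rng.random(spec.n_frames) < p_values[k]
        d = np.where(formed, spec.contact_distance_formed, spec.contact_distance_broken)
        a0 = 4 * k
        coords[:, a0] = base + np.array([0.0, 0.0, 0.2])          # CA of GLU
        coords[:, a0 + 1] = base                                   # OE1
        coords[:, a0 + 2, :] = base + np.array([0.0, 0.0, 0.2])    # CA of LYS (x set below)
        coords[:, a0 + 2, 0] = d
        coords[:, a0 + 3, 0] = d                                   # NZ
        coords[:, a0 + 3, 1:] = base[1:]
        rows += [
            (res_neg, "GLU", "CA", "C"),
            (res_neg, "GLU", "OE1", "O"),
            (res_pos, "LYS", "CA", "C"),
            (res_pos, "LYS", "NZ", "N"),
        ]
        truth_rows.append(
            {"residue_neg": res_neg, "residue_pos": res_pos, "p_true": p_values[k]}
        )
    table = pd.DataFrame(rows, columns=["residue_index", "residue_name", "atom_name", "element"])
    ens = EnsembleFrameSet(
        coords=coords,
        atom_table=table,
        time_per_frame=time_per_frame,
        system_label=system_label,
        superposed=True,
    )
    return ens, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Homolog pairs with indels
# ---------------------------------------------------------------------------

def gen_homolog_pair(
    n_residues: int,
    indels: Sequence[tuple[str, int, int]] = (),
    mode_pairs: Sequence[tuple[int, int]] = (),
    eigenvalue: float = 0.02,
    isotropic_noise: float = 5e-4,
    n_frames: int = 2000,
    seed: int = 0,
) -> tuple[EnsembleFrameSet, EnsembleFrameSet, ResidueCorrespondence]:
    """Generate two homologous bead ensembles sharing planted modes.

    ``indels`` is a list of ``(kind, position_a, length)``: kind ``"ins"``
    inserts extra residues in B after A position ``position_a`` (gap rows on
    the A side); kind ``"del"`` removes A residues ``position_a ..
    position_a+length-1`` from B (gap rows on the B side).  ``mode_pairs``
    lists A residue pairs that move in phase in both systems (on their mapped
    B positions), so the correlation structure is recoverable across the
    correspondence.
    """
    # build the correspondence and check indels do not overlap
    claimed: set[int] = set()
    ins_after: dict[int, int] = {}
    deleted: set[int] = set()
    for kind, pos, length in indels:
        if kind not in ("ins", "del"):
            raise ValueError(f"unknown indel kind {kind!r}")
        if length < 1:
            raise ValueError("indel length must be >= 1")
        span = {pos} if kind == "ins" else set(range(pos, pos + length))
        if not span <= set(range(1, n_residues + 1)):
            raise ValueError(f"indel {kind}@{pos} outside 1..{n_residues}")
        if span & claimed:
            raise ValueError("overlapping indels")
        claimed |= span
        if kind == "ins":
            ins_after[pos] = length
        else:
            deleted |= span

    pairs: list[tuple[int | None, int | None]] = []
    b = 1
    for a in range(1, n_residues + 1):
        if a in deleted:
            pairs.append((a, None))
        else:
            pairs.append((a, b))
            b += 1
        for _ in range(ins_after.get(a, 0)):
            pairs.append((None, b))
            b += 1
    corr = ResidueCorrespondence(pairs, "A", "B")
    n_b = b - 1

    def modes_for(n: int, pair_list: list[tuple[int, int]]):
        return [(eigenvalue, v) for v in rigid_free_pair_modes(n, pair_list)]

    a_pairs = [(i, j) for i, j in mode_pairs]
    b_pairs = []
    for i, j in mode_pairs:
        bi, bj = corr.map_a_to_b(i), corr.map_a_to_b(j)
        if bi is not None and bj is not None:
            b_pairs.append((bi, bj))

    spec_a = PlantedCovarianceSpec(
        n_residues=n_residues,
        modes=modes_for(n_residues, a_pairs),
        isotropic_noise=isotropic_noise,
        n_frames=n_frames,
        seed=seed,
    )
    spec_b = PlantedCovarianceSpec(
        n_residues=n_b,
        modes=modes_for(n_b, b_pairs),
        isotropic_noise=isotropic_noise,
        n_frames=n_frames,
        seed=seed + 1,
    )
    ens_a, _ = gen_gaussian_ensemble(spec_a, system_label="A")
    ens_b, _ = gen_gaussian_ensemble(spec_b, system_label="B")
    return ens_a, ens_b, corr


# ---------------------------------------------------------------------------
# Wild-type / mutant comparison fixture
# ---------------------------------------------------------------------------

#: salt-bridge pseudo-residues planted in the comparison fixture:
#: (negative residue, its name/atom, positive residue, its name/atom)
_FIXTURE_BRIDGES = [
    # (res_neg, neg_name, neg_atom, res_pos, pos_name, pos_atom, p_wt, p_mut)
    (5, "ASP", "OD1", 30, "LYS", "NZ", 0.90, 0.90),    # conserved bridge
    (12, "GLU", "OE1", 33, "ARG", "NH1", 0.03, 0.85),  # gained in the mutant
    (17, "ASP", "OD1", 38, "LYS", "NZ", 0.05, 0.05),   # noise in both
]

#: long-range correlated Cα pairs: shared one, plus one extra in the mutant
_FIXTURE_CORR_SHARED = (3, 20)
_FIXTURE_CORR_EXTRA = (8, 35)


def gen_mutant_comparison(
    seed: int = 0,
    n_residues: int = 40,
    n_frames: int = 3000,
    mode_eigenvalue: float = 0.02,
    isotropic_noise: float = 5e-4,
    with_hydrogen_ladder: bool = True,
) -> tuple[dict[str, EnsembleFrameSet], ResidueCorrespondence, dict]:
    """Two-system fixture with one planted gained bridge and one extra correlation.

    Both systems share a bead chain with a planted long-range correlated
    pair (residues 3–20) and a persistent salt bridge (5–30).  The "mutant"
    additionally carries a second correlated pair (8–35) and a gained salt
    bridge (12–33) absent (persistence 3%) in the wild type.  A low-persistence
    noise bridge (17–38) is planted in both.  When ``with_hydrogen_ladder`` is
    set, every residue carries backbone N/H/O pseudo-atoms arranged so that
    consecutive residues hydrogen-bond, giving the H-bond detector something
    to find.

    Returns ``(systems, identity correspondence, truth)`` where truth lists
    the planted differences.
    """
    systems: dict[str, EnsembleFrameSet] = {}
    for role, sub_seed in (("wildtype", 0), ("mutant", 1)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, sub_seed]))
        pairs = [_FIXTURE_CORR_SHARED]
        if role == "mutant":
            pairs.append(_FIXTURE_CORR_EXTRA)
        modes = [(mode_eigenvalue, v) for v in rigid_free_pair_modes(n_residues, pairs)]
        dim = 3 * n_residues
        flat = np.zeros((n_frames, dim))
        for lam, v in modes:
            flat += np.sqrt(lam) * rng.standard_normal(n_frames)[:, None] * v[None, :]
        flat += np.sqrt(isotropic_noise) * rng.standard_normal((n_frames, dim))
        ca = flat.reshape(n_frames, n_residues, 3) + _chain_mean(n_residues)[None]

        res_names = {r: "ALA" for r in range(1, n_residues + 1)}
        charged_atoms: dict[int, tuple[str, str]] = {}
        for rn, nn, na, rp, pn, pa, p_wt, p_mut in _FIXTURE_BRIDGES:
            res_names[rn], res_names[rp] = nn, pn
            charged_atoms[rn] = (na, "O")
            charged_atoms[rp] = (pa, "N")

        rows: list[tuple[int, str, str, str]] = []
        cols: list[np.ndarray] = []
        # backbone pseudo-geometry rides rigidly on each residue's Calpha
        n_off = np.array([-0.12, 0.08, 0.0])
        o_off = np.array([0.12, -0.08, 0.0])
        for r in range(1, n_residues + 1):
            name = res_names[r]
            rows.append((r, name, "CA", "C"))
            cols.append(ca[:, r - 1])
            if with_hydrogen_ladder:
                n_pos = ca[:, r - 1] + n_off
                o_pos = ca[:, r - 1] + o_off
                rows.append((r, name, "N", "N"))
                cols.append(n_pos)
                if r > 1:
                    # amide H points at the previous residue's carbonyl O
                    prev_o = ca[:, r - 2] + o_off
                    hvec = prev_o - n_pos
                    hdir = hvec / np.linalg.norm(hvec, axis=1, keepdims=True)
                    rows.append((r, name, "H", "H"))
                    cols.append(n_pos + 0.10 * hdir)
                else:
                    # N-terminal amide H, pointing away from the chain
                    rows.append((r, name, "H", "H"))
                    cols.append(n_pos + np.array([-0.10, 0.0, 0.0]))
                rows.append((r, name, "O", "O"))
                cols.append(o_pos)
            if r in charged_atoms:
                atom, elem = charged_atoms[r]
                rows.append((r, name, atom, elem))
                cols.append(np.zeros((n_frames, 3)))  # placed below
                if elem == "N":
                    # charged amines are H-bond donors by chemistry; give
                    # them one hydrogen, placed below alongside the N
                    h_name = {"NZ": "HZ1", "NH1": "HH11"}[atom]
                    rows.append((r, name, h_name, "H"))
                    cols.append(np.zeros((n_frames, 3)))

        table = pd.DataFrame(rows, columns=["residue_index", "residue_name", "atom_name", "element"])
        coords = np.stack(cols, axis=1)

        # place charged atoms: each bridge pair toggles formed/broken off in +y
        atom_lookup = {
            (int(ri), an): idx
            for idx, (ri, an) in enumerate(zip(table["residue_index"], table["atom_name"]))
        }
        for b_idx, (rn, nn, na, rp, pn, pa, p_wt, p_mut) in enumerate(_FIXTURE_BRIDGES):
            p = p_wt if role == "wildtype" else p_mut
            formed = rng.random(n_frames) < p
            d = np.where(formed, 0.30, 0.80)
            base = np.array([0.0, 8.0 * (b_idx + 1), 0.0])
            coords[:, atom_lookup[(rn, na)]] = base
            coords[:, atom_lookup[(rp, pa)], 0] = d
            coords[:, atom_lookup[(rp, pa)], 1] = base[1]
            coords[:, atom_lookup[(rp, pa)], 2] = 0.0
            # the amine hydrogen sits perpendicular to the bridge axis, so
            # the donor-vertex angle to the bridge acceptor stays ~90 deg
            # and the planted bridge never doubles as a hydrogen bond
            h_name = {"NZ": "HZ1", "NH1": "HH11"}[pa]
            coords[:, atom_lookup[(rp, h_name)], 0] = d
            coords[:, atom_lookup[(rp, h_name)], 1] = base[1]
            coords[:, atom_lookup[(rp, h_name)], 2] = 0.10

        systems[role] = EnsembleFrameSet(
            coords=coords,
            atom_table=table,
            time_per_frame=DEFAULT_DT,
            system_label=role,
            superposed=True,
        )

    corr = ResidueCorrespondence.identity(n_residues, "wildtype", "mutant")
    truth = {
        "gained_bridges": [(12, 33)],
        "lost_bridges": [],
        "shared_bridges": [(5, 30)],
        "extra_corr_edges": [_FIXTURE_CORR_EXTRA],
        "shared_corr_edges": [_FIXTURE_CORR_SHARED],
    }
    return systems, corr, truth
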