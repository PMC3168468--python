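"""Salt-bridge detection, persistence-cutoff selection and proximity clusters.

A salt bridge is a pair of oppositely charged side-chain groups whose
minimum inter-atomic distance falls below a cutoff (default 0.4 nm) in a
frame; its *persistence* is the fraction of macro-trajectory frames where
the contact is formed.  Bridges kept for network analysis must exceed a
persistence cutoff — by default 24%, but the cutoff can be derived from the
data: the persistence distribution of charge pairs is typically bimodal,
with a "noise" population below 10% and a "signal" population above 30%,
and two supervised classifiers (a linear maximum-margin SVM and a k-nearest
neighbours classifier with k = 4) trained on those two classes place the
decision boundary inside the gap.

Salt-bridging residues are then clustered by spatial/sequence proximity:
nodes of an undirected graph connected when they bridge each other or lie
within 5 residues in sequence (strictly fewer, i.e. |i-j| <= 4); the
connected components are the interaction clusters.  Cross-system
conservation classes and the correlation of acquired mesophilic-like
bridges with phenotype (Tm, kcat/Km) close the comparative loop.

Salt-bridge *strength* (electrostatic free energy, desolvation) is out of
scope by design; only geometry and persistence are analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .ensemble_io import EnsembleFrameSet, ResidueCorrespondence

logger = logging.getLogger(__name__)

#: fixed fallback persistence cutoff when the classifier route is unavailable
DEFAULT_PERSISTENCE_CUTOFF = 0.24

#: default charged side-chain groups; His is excluded by default (its
#: protonation state at neutral pH is ambiguous) and termini are off unless
#: explicitly enabled.  Editable; every report records the table used.
DEFAULT_CHARGED_GROUPS: dict[str, tuple[int, tuple[str, ...]]] = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
}


@dataclass
class ChargedGroupTable:
    """Residue type → (sign, charged atom names)."""

    groups: dict[str, tuple[int, tuple[str, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_CHARGED_GROUPS)
    )
    include_his: bool = False
    label: str = "default (Asp/Glu -, Lys/Arg +, His excluded, no termini)"

    def __post_init__(self) -> None:
        if self.include_his and "HIS" not in self.groups:
            self.groups = {**self.groups, "HIS": (+1, ("ND1", "NE2"))}
        for name, (sign, atoms) in self.groups.items():
            if sign not in (-1, 1) or not atoms:
                raise ValueError(f"bad charged group for {name}")


@dataclass
class SaltBridgeRecord:
    """One oppositely charged residue pair and its contact statistics."""

    residue_a: int                   # a < b
    residue_b: int
    name_a: str
    name_b: str
    sign_a: int
    sign_b: int
    contacts: np.ndarray             # boolean per frame
    min_distance: np.ndarray         # nm per frame

    def __post_init__(self) -> None:
        if self.sign_a * self.sign_b >= 0:
            raise ValueError("salt-bridge partners must carry opposite signs")

    @property
    def persistence(self) -> float:
        return float(self.contacts.mean())

    @property
    def pair(self) -> tuple[int, int]:
        return (self.residue_a, self.residue_b)


def detect_salt_bridges(
    ens: EnsembleFrameSet,
    table: ChargedGroupTable | None = None,
    dist_cut: float = 0.4,
) -> list[SaltBridgeRecord]:
    """All oppositely charged residue pairs with their per-frame contacts.

    A pair is in contact in a frame when the minimum distance between any
    oppositely signed atoms of the two groups is strictly below ``dist_cut``
    nm.  Every pair with at least one contact anywhere is returned with its
    full persistence, unfiltered — thresholding is a separate decision.
    """
    if table is None:
        table = ChargedGroupTable()
    at = ens.atom_table
    charged: list[tuple[int, str, int, np.ndarray]] = []  # (resi, name, sign, atom rows)
    for resi, group in at.groupby("residue_index", sort=True):
        name = group["residue_name"].iloc[0]
        if name not in table.groups:
            continue
        sign, atoms = table.groups[name]
        rows = group.index[group["atom_name"].isin(atoms)].to_numpy()
        if len(rows):
            charged.append((int(resi), name, sign, rows))
    if not charged:
        raise ValueError(
            f"no charged groups found in '{ens.system_label}' with table {table.label!r}"
        )
    records: list[SaltBridgeRecord] = []
    neg = [c for c in charged if c[2] < 0]
    pos = [c for c in charged if c[2] > 0]
    for resi_n, name_n, sign_n, rows_n in neg:
        cn = ens.coords[:, rows_n]                       # (F, an, 3)
        for resi_p, name_p, sign_p, rows_p in pos:
            cp = ens.coords[:, rows_p]                   # (F, ap, 3)
            d = np.linalg.norm(cn[:, :, None, :] - cp[:, None, :, :], axis=-1)
            mind = d.min(axis=(1, 2))
            contacts = mind < dist_cut
            if not contacts.any():
                continue
            a, b = sorted([(resi_n, name_n, sign_n), (resi_p, name_p, sign_p)])
            records.append(
                SaltBridgeRecord(
                    residue_a=a[0], residue_b=b[0],
                    name_a=a[1], name_b=b[1],
                    sign_a=a[2], sign_b=b[2],
                    contacts=contacts,
                    min_distance=mind,
                )
            )
    records.sort(key=lambda r: r.pair)
    return records


def filter_records(
    records: list[SaltBridgeRecord], persistence_cutoff: float = DEFAULT_PERSISTENCE_CUTOFF
) -> list[SaltBridgeRecord]:
    """Bridges formed in at least ``persistence_cutoff`` of the frames."""
    return [r for r in records if r.persistence >= persistence_cutoff]


# ---------------------------------------------------------------------------
# Classifier-based persistence-cutoff selection
# ---------------------------------------------------------------------------

@dataclass
class PersistenceCutoffModel:
    """Cutoff separating noise from signal persistences, with diagnostics."""

    cutoff: float
    svm_boundary: float
    knn_boundary: float
    disagreement_width: float
    n_noise: int
    n_signal: int
    noise_max: float
    signal_min: float
    midrange_labels: pd.DataFrame    # persistence, svm_label, knn_label, agree


def _knn_boundary(train_x: np.ndarray, train_y: np.ndarray, lo: float, hi: float, k: int) -> float:
    """Decision boundary of a 1-D k-NN classifier scanned on a fine grid.

    Ties (k even, split vote) break toward the noise class — the
    conservative choice, admitting fewer bridges.
    """
    nn = NearestNeighbors(n_neighbors=k).fit(train_x.reshape(-1, 1))
    grid = np.linspace(lo, hi, 4001)
    _, idx = nn.kneighbors(grid.reshape(-1, 1))
    votes = train_y[idx].sum(axis=1)          # number of signal votes
    signal = votes > k / 2                    # tie -> noise
    if not signal.any():
        return hi
    if signal.all():
        return lo
    flip = int(np.argmax(signal))             # classes are separated, labels monotone
    return float((grid[flip - 1] + grid[flip]) / 2)


def select_persistence_cutoff(
    records: list[SaltBridgeRecord] | np.ndarray,
    noise_max: float = 0.10,
    signal_min: float = 0.30,
    k: int = 4,
) -> PersistenceCutoffModel:
    """Derive the persistence cutoff from the bimodal persistence distribution.

    Pairs below ``noise_max`` form the noise class, pairs above
    ``signal_min`` the signal class.  A linear maximum-margin SVM and a k-NN
    classifier (k = 4, ties toward noise) are trained on the two classes and
    the mid-range interactions are labelled by both; the cutoff is the
    boundary persistence where the classifiers agree, or the midpoint of the
    two boundaries when they disagree (disagreement width reported).
    """
    if isinstance(records, np.ndarray) or (records and isinstance(records[0], (int, float, np.floating))):
        p = np.asarray(records, dtype=float)
    else:
        p = np.array([r.persistence for r in records], dtype=float)
    noise = p[p < noise_max]
    signal = p[p > signal_min]
    if len(noise) == 0 or len(signal) == 0:
        raise ValueError(
            "cannot train the cutoff classifiers: the "
            + ("noise" if len(noise) == 0 else "signal")
            + f" class is empty; use a fixed cutoff (default {DEFAULT_PERSISTENCE_CUTOFF})"
        )
    train_x = np.concatenate([noise, signal])
    train_y = np.concatenate([np.zeros(len(noise), dtype=int), np.ones(len(signal), dtype=int)])
    k = min(k, len(train_x))

    # hard-margin linear SVM on the 1-D persistence feature
    svm = SVC(kernel="linear", C=1e6).fit(train_x.reshape(-1, 1), train_y)
    w = float(svm.coef_[0][0])
    svm_b = float(np.clip(-svm.intercept_[0] / w, noise_max, signal_min))
    knn_b = _knn_boundary(train_x, train_y, noise_max, signal_min, k)

    disagreement = abs(svm_b - knn_b)
    cutoff = (svm_b + knn_b) / 2
    if disagreement > 1e-9:
        logger.info(
            "cutoff classifiers disagree by %.4f (SVM %.4f, kNN %.4f); using midpoint",
            disagreement, svm_b, knn_b,
        )

    mid = p[(p >= noise_max) & (p <= signal_min)]
    nn = NearestNeighbors(n_neighbors=k).fit(train_x.reshape(-1, 1))
    rows = []
    for x in np.sort(mid):
        svm_label = int(x > svm_b)
        _, idx = nn.kneighbors([[x]])
        knn_label = int(train_y[idx[0]].sum() > k / 2)
        rows.append(
            {
                "persistence": float(x),
                "svm_label": svm_label,
                "knn_label": knn_label,
                "agree": svm_label == knn_label,
            }
        )
    return PersistenceCutoffModel(
        cutoff=float(cutoff),
        svm_boundary=svm_b,
        knn_boundary=knn_b,
        disagreement_width=float(disagreement),
        n_noise=len(noise),
        n_signal=len(signal),
        noise_max=noise_max,
        signal_min=signal_min,
        midrange_labels=pd.DataFrame(rows, columns=["persistence", "svm_label", "knn_label", "agree"]),
    )


# ---------------------------------------------------------------------------
# Spatial-proximity clusters
# ---------------------------------------------------------------------------

@dataclass
class ProximityCluster:
    """Connected component of the salt-bridge residue graph."""

    cluster_id: int
    residues: tuple[int, ...]        # sorted
    bridges: tuple[tuple[int, int], ...]


def build_proximity_clusters(
    records: list[SaltBridgeRecord], seq_dist: int = 5
) -> list[ProximityCluster]:
    """Cluster salt-bridging residues on an undirected proximity graph.

    Nodes are the residues of the (already persistence-filtered) bridges;
    arcs connect bridged pairs and any two nodes strictly fewer than
    ``seq_dist`` residues apart in sequence (i.e. |i-j| <= seq_dist - 1).
    Clusters are the connected components, ordered by their smallest member
    residue; they partition the salt-bridging residue set and are invariant
    to record input order.
    """
    g = nx.Graph()
    bridge_pairs = sorted({r.pair for r in records})
    for a, b in bridge_pairs:
        g.add_edge(a, b)
    nodes = sorted(g.nodes)
    for x in range(len(nodes)):
        for y in range(x + 1, len(nodes)):
            if nodes[y] - nodes[x] < seq_dist:
                g.add_edge(nodes[x], nodes[y])
    comps = sorted((tuple(sorted(c)) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters = []
    for cid, comp in enumerate(comps, start=1):
        members = set(comp)
        clusters.append(
            ProximityCluster(
                cluster_id=cid,
                residues=comp,
                bridges=tuple(p for p in bridge_pairs if p[0] in members and p[1] in members),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Cross-system conservation classes and phenotype correlation
# ---------------------------------------------------------------------------

def classify_conservation(
    per_system: dict[str, list[SaltBridgeRecord]],
    corr_to_reference: dict[str, ResidueCorrespondence],
    cold_label: str,
    warm_label: str,
) -> pd.DataFrame:
    """Label each bridge by its conservation pattern across systems.

    All bridges are mapped into the cold reference's residue numbering
    through the per-system correspondences (pairs are (cold index, system
    index); the cold system itself may be omitted from the map).  Groups:

    * ``I``      — present in every system (conserved core bridges);
    * ``IV``     — present in the warm reference and at least one mutant but
      absent from the cold wild type (mesophilic-like bridges acquired by
      mutants);
    * ``II/III`` — present in exactly one wild type on residues that have no
      corresponding position in the other wild type (gap-mediated);
    * ``unclassified`` — any other pattern.
    """
    systems = sorted(per_system)
    for label in systems:
        if label != cold_label and label not in corr_to_reference:
            raise ValueError(f"missing correspondence to {cold_label} for system {label}")
    mutants = [s for s in systems if s not in (cold_label, warm_label)]

    presence: dict[tuple[int, int], set[str]] = {}
    unmappable: list[dict] = []
    for label in systems:
        for rec in per_system[label]:
            if label == cold_label:
                key = rec.pair
            else:
                corr = corr_to_reference[label]
                ca = corr.map_b_to_a(rec.residue_a)
                cb = corr.map_b_to_a(rec.residue_b)
                if ca is None or cb is None:
                    unmappable.append(
                        {
                            "system": label,
                            "residue_a": rec.residue_a,
                            "residue_b": rec.residue_b,
                        }
                    )
                    continue
                key = (min(ca, cb), max(ca, cb))
            presence.setdefault(key, set()).add(label)

    warm_corr = corr_to_reference.get(warm_label)

    def _to_warm(ref_index: int) -> int | None:
        if warm_corr is None:
            return None
        try:
            return warm_corr.map_a_to_b(ref_index)
        except KeyError:
            return None

    rows = []
    for key in sorted(presence):
        present = presence[key]
        if present == set(systems):
            group = "I"
        elif warm_label in present and cold_label not in present and present & set(mutants):
            group = "IV"
        elif (
            cold_label in present
            and warm_label not in present
            and (_to_warm(key[0]) is None or _to_warm(key[1]) is None)
        ):
            # cold-specific bridge on residues the warm homolog lacks
            group = "II/III"
        else:
            group = "unclassified"
        rows.append(
            {
                "residue_a_ref": key[0],
                "residue_b_ref": key[1],
                "present_in": ";".join(sorted(present)),
                "group": group,
            }
        )
    for item in unmappable:
        # bridges on residues with no reference correspondent; for a wild
        # type these are the gap-mediated class, for mutants the pattern is
        # reported but left unclassified
        rows.append(
            {
                "residue_a_ref": -item["residue_a"],
                "residue_b_ref": -item["residue_b"],
                "present_in": item["system"],
                "group": "II/III" if item["system"] == warm_label else "unclassified",
            }
        )
    return pd.DataFrame(
        rows, columns=["residue_a_ref", "residue_b_ref", "present_in", "group"]
    )


def phenotype_correlation(
    features: pd.Series, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of a per-mutant bridge feature against phenotypes.

    ``features`` is indexed by mutant label (e.g. the count of
    mesophilic-like group-IV bridges acquired); ``phenotypes`` holds one
    column per experimental quantity (Tm, kcat/Km) on the same index.
    Requires at least 3 mutants with both values; a zero-variance feature
    yields an undefined (NaN) coefficient, flagged.
    """
    common = features.index.intersection(phenotypes.index)
    if len(common) < 3:
        raise ValueError("need at least 3 systems with both feature and phenotype")
    x = features.loc[common].astype(float)
    rows = []
    for col in phenotypes.columns:
        y = phenotypes.loc[common, col].astype(float)
        if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            rows.append({"phenotype": col, "r": np.nan, "n": len(common), "defined": False})
            continue
        r, _ = pearsonr(x, y)
        rows.append({"phenotype": col, "r": float(r), "n": len(common), "defined": True})
    return pd.DataFrame(rows, columns=["phenotype", "r", "n", "defined"])
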