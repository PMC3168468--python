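"""Salt-bridge detection, cutoff selection, clustering and conservation."""

import numpy as np
import pandas as pd
import pytest

from ensembledyn.ensemble_io import ResidueCorrespondence
from ensembledyn.saltbridge_networks import (
    SaltBridgeRecord,
    build_proximity_clusters,
    classify_conservation,
    detect_salt_bridges,
    filter_records,
    phenotype_correlation,
    select_persistence_cutoff,
)
from ensembledyn.synthetic_data import ContactSeriesSpec, gen_contact_series

from conftest import make_atom_ensemble


def record(a, b, persistence=1.0, n_frames=100):
    """Minimal salt-bridge record for graph/selection tests."""
    contacts = np.zeros(n_frames, dtype=bool)
    contacts[: int(round(persistence * n_frames))] = True
    return SaltBridgeRecord(
        residue_a=a, residue_b=b, name_a="ASP", name_b="LYS",
        sign_a=-1, sign_b=+1, contacts=contacts,
        min_distance=np.full(n_frames, 0.3),
    )


def fixed_distance_ensemble(pair_specs):
    """GLU/LYS pairs at constant charged-atom distances.

    ``pair_specs`` is a list of (distance_nm, formed_fraction); each pair's
    charged atoms sit at the given distance in a ``formed_fraction`` of 50
    frames and at 0.9 nm otherwise.
    """
    n_frames = 50
    atoms, cols = [], []
    for k, (dist, frac) in enumerate(pair_specs):
        base_y = 6.0 * k
        formed = np.zeros(n_frames, dtype=bool)
        formed[: int(round(frac * n_frames))] = True
        d = np.where(formed, dist, 0.9)
        rn, rp = 2 * k + 1, 2 * k + 2
        atoms += [
            (rn, "GLU", "CA", "C"), (rn, "GLU", "OE1", "O"),
            (rp, "LYS", "CA", "C"), (rp, "LYS", "NZ", "N"),
        ]
        ca_n = np.broadcast_to([0.0, base_y, 0.2], (n_frames, 3))
        oe1 = np.broadcast_to([0.0, base_y, 0.0], (n_frames, 3))
        ca_p = np.stack([d, np.full(n_frames, base_y), np.full(n_frames, 0.2)], axis=1)
        nz = np.stack([d, np.full(n_frames, base_y), np.zeros(n_frames)], axis=1)
        cols += [ca_n, oe1, ca_p, nz]
    return make_atom_ensemble(atoms, np.stack(cols, axis=1))


class TestDetection:
    def test_planted_permanent_bridge_has_unit_persistence(self):
        ens = fixed_distance_ensemble([(0.30, 1.0)])
        rec = detect_salt_bridges(ens)[0]
        assert rec.pair == (1, 2)
        assert rec.persistence == 1.0

    def test_persistence_matches_planted_bernoulli(self):
        spec = ContactSeriesSpec(n_pairs=5, n_frames=2000, seed=41)
        ens, truth = gen_contact_series(spec, p_values=[0.1, 0.3, 0.5, 0.7, 0.9])
        found = {r.pair: r.persistence for r in detect_salt_bridges(ens)}
        for _, row in truth.iterrows():
            p = row["p_true"]
            est = found.get((int(row["residue_neg"]), int(row["residue_pos"])), 0.0)
            assert abs(est - p) < 3 * np.sqrt(p * (1 - p) / 2000) + 1e-12

    def test_same_sign_pair_never_reported(self):
        # two GLU residues 0.3 nm apart plus one LYS far away
        atoms = [
            (1, "GLU", "CA", "C"), (1, "GLU", "OE1", "O"),
            (2, "GLU", "CA", "C"), (2, "GLU", "OE1", "O"),
            (3, "LYS", "CA", "C"), (3, "LYS", "NZ", "N"),
        ]
        frames = np.zeros((3, 6, 3))
        frames[:, 2:4, 0] = 0.3       # GLU2 near GLU1
        frames[:, 4:6, 0] = 5.0       # LYS3 far from both
        ens = make_atom_ensemble(atoms, frames)
        assert detect_salt_bridges(ens) == []

    def test_no_charged_groups_is_hard_error(self):
        atoms = [(1, "ALA", "CA", "C")]
        ens = make_atom_ensemble(atoms, np.zeros((2, 1, 3)))
        with pytest.raises(ValueError, match="charged"):
            detect_salt_bridges(ens)

    def test_counts_monotone_in_distance_and_persistence_cutoffs(self):
        """Sensitivity cutoffs: 0.4/0.45/0.5 nm distance, 20%/24% persistence."""
        ens = fixed_distance_ensemble([(0.35, 0.8), (0.42, 0.8), (0.48, 0.22)])
        counts = [len(detect_salt_bridges(ens, dist_cut=d)) for d in (0.4, 0.45, 0.5)]
        assert counts == [1, 2, 3]
        records = detect_salt_bridges(ens, dist_cut=0.5)
        kept = [len(filter_records(records, p)) for p in (0.20, 0.24)]
        assert kept[0] >= kept[1]
        assert kept == [3, 2]


class TestCutoffSelection:
    def test_separated_mixture_yields_cutoff_inside_gap(self):
        rng = np.random.default_rng(42)
        p = np.concatenate([rng.uniform(0.01, 0.09, 40), rng.uniform(0.35, 0.9, 40)])
        model = select_persistence_cutoff(p)
        assert 0.10 < model.cutoff < 0.30
        assert p[p < 0.10].max() < model.cutoff < p[p > 0.30].min()

    def test_empty_noise_class_suggests_fixed_cutoff(self):
        with pytest.raises(ValueError, match="0.24"):
            select_persistence_cutoff(np.array([0.5, 0.6, 0.7]))

    def test_knn_labels_lone_midrange_point_as_noise(self):
        """A point at 0.12 with 4 nearest neighbours in the noise class."""
        p = np.concatenate([
            np.array([0.05, 0.06, 0.07, 0.08, 0.09 - 1e-4]),   # dense noise near the gap
            np.array([0.12]),                                   # lone mid-range point
            np.array([0.60, 0.65, 0.70, 0.75]),
        ])
        model = select_persistence_cutoff(p)
        row = model.midrange_labels.iloc[0]
        assert row["persistence"] == pytest.approx(0.12)
        assert row["knn_label"] == 0                            # noise by 4-NN vote

    def test_works_on_record_lists(self):
        records = [record(1, 2, 0.05), record(3, 4, 0.06), record(5, 6, 0.7),
                   record(7, 8, 0.8)]
        model = select_persistence_cutoff(records)
        assert 0.10 <= model.cutoff <= 0.30


class TestProximityClusters:
    def test_shared_residue_merges_two_bridges(self):
        clusters = build_proximity_clusters([record(1, 20), record(20, 40)])
        assert len(clusters) == 1
        assert clusters[0].residues == (1, 20, 40)

    def test_sequence_neighbours_merge_at_four_apart(self):
        """|i-j| = 4 merges (strict < 5); |i-j| = 5 does not."""
        near = build_proximity_clusters([record(1, 20), record(24, 40)])
        assert len(near) == 1
        far = build_proximity_clusters([record(1, 20), record(25, 40)])
        assert len(far) == 2

    def test_clusters_partition_and_ignore_input_order(self):
        recs = [record(1, 30), record(3, 50), record(28, 70)]
        a = build_proximity_clusters(recs)
        b = build_proximity_clusters(recs[::-1])
        assert [c.residues for c in a] == [c.residues for c in b]
        all_residues = sorted(r for c in a for r in c.residues)
        assert all_residues == sorted({1, 3, 28, 30, 50, 70})

    def test_matches_bruteforce_flood_fill(self, rng):
        for _ in range(25):
            n_bridges = rng.integers(1, 12)
            pairs = set()
            while len(pairs) < n_bridges:
                i, j = sorted(rng.integers(1, 60, size=2))
                if i != j:
                    pairs.add((int(i), int(j)))
            clusters = build_proximity_clusters([record(i, j) for i, j in pairs])

            # independent flood fill over the same arc rule
            nodes = sorted({r for p in pairs for r in p})
            adj = {u: set() for u in nodes}
            for i, j in pairs:
                adj[i].add(j)
                adj[j].add(i)
            for x in nodes:
                for y in nodes:
                    if x != y and abs(x - y) < 5:
                        adj[x].add(y)
            seen, comps = set(), []
            for u in nodes:
                if u in seen:
                    continue
                stack, comp = [u], set()
                while stack:
                    v = stack.pop()
                    if v in comp:
                        continue
                    comp.add(v)
                    stack.extend(adj[v] - comp)
                seen |= comp
                comps.append(tuple(sorted(comp)))
            comps.sort(key=lambda c: c[0])
            assert [c.residues for c in clusters] == comps

    def test_empty_input_gives_empty_list(self):
        assert build_proximity_clusters([]) == []


class TestConservation:
    def _systems(self, presence, n=50):
        """Build per-system record lists from a {system: [pairs]} table."""
        return {
            label: [record(a, b) for a, b in pairs] for label, pairs in presence.items()
        }

    def _identity_corrs(self, labels, n=50):
        return {lab: ResidueCorrespondence.identity(n, "cold", lab) for lab in labels}

    def test_bridge_present_everywhere_is_group_one(self):
        presence = {
            "cold": [(5, 30)], "warm": [(5, 30)], "m1": [(5, 30)], "m2": [(5, 30)]
        }
        out = classify_conservation(
            self._systems(presence),
            self._identity_corrs(["warm", "m1", "m2"]),
            "cold", "warm",
        )
        assert list(out["group"]) == ["I"]

    def test_warm_plus_mutant_without_cold_is_group_four(self):
        presence = {"cold": [], "warm": [(5, 30)], "m1": [(5, 30)], "m2": []}
        # cold still needs >= 0 bridges; empty list is fine
        out = classify_conservation(
            self._systems(presence),
            self._identity_corrs(["warm", "m1", "m2"]),
            "cold", "warm",
        )
        assert list(out["group"]) == ["IV"]

    def test_gap_mediated_bridges_are_group_two_three(self):
        # warm bridge on residues absent from the cold scaffold
        pairs = [(i, i) for i in range(1, 41)] + [(None, 41), (None, 45)]
        warm_corr = ResidueCorrespondence(pairs, "cold", "warm")
        presence = {"cold": [], "warm": [(41, 45)], "m1": []}
        out = classify_conservation(
            self._systems(presence),
            {"warm": warm_corr, "m1": ResidueCorrespondence.identity(40, "cold", "m1")},
            "cold", "warm",
        )
        assert list(out["group"]) == ["II/III"]

        # cold bridge on residues the warm homolog lacks
        pairs2 = [(i, i) for i in range(1, 41)] + [(41, None), (45, None)]
        warm_corr2 = ResidueCorrespondence(
            sorted(pairs2, key=lambda p: (p[0] is None, p[0])), "cold", "warm"
        )
        presence2 = {"cold": [(41, 45)], "warm": [], "m1": []}
        out2 = classify_conservation(
            self._systems(presence2),
            {"warm": warm_corr2, "m1": ResidueCorrespondence.identity(45, "cold", "m1")},
            "cold", "warm",
        )
        assert list(out2["group"]) == ["II/III"]

    def test_random_presence_tables_match_rule_evaluation(self, rng):
        labels = ["cold", "warm", "m1", "m2", "m3"]
        for _ in range(20):
            pool = [(int(i), int(j)) for i, j in rng.integers(1, 50, size=(8, 2)) if i < j]
            presence = {lab: [p for p in pool if rng.random() < 0.5] for lab in labels}
            out = classify_conservation(
                self._systems(presence),
                self._identity_corrs(["warm", "m1", "m2", "m3"]),
                "cold", "warm",
            )
            for _, row in out.iterrows():
                key = (row["residue_a_ref"], row["residue_b_ref"])
                have = {lab for lab in labels if key in presence[lab]}
                if have == set(labels):
                    expected = "I"
                elif "warm" in have and "cold" not in have and have & {"m1", "m2", "m3"}:
                    expected = "IV"
                else:
                    expected = "unclassified"
                assert row["group"] == expected


class TestPhenotypeCorrelation:
    def _table(self, values):
        return pd.DataFrame({"Tm": values}, index=[f"m{i}" for i in range(len(values))])

    def test_identical_vectors_give_unit_correlation(self):
        f = pd.Series([1.0, 2.0, 3.0, 4.0], index=["m0", "m1", "m2", "m3"])
        out = phenotype_correlation(f, self._table([1.0, 2.0, 3.0, 4.0]))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one(self):
        f = pd.Series([1.0, 2.0, 3.0], index=["m0", "m1", "m2"])
        out = phenotype_correlation(f, self._table([-1.0, -2.0, -3.0]))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        f = pd.Series(x, index=[f"m{i}" for i in range(7)])
        out = phenotype_correlation(f, self._table(y))
        brute = ((x - x.mean()) @ (y - y.mean())) / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert out["r"].iloc[0] == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_feature_flagged_undefined(self):
        f = pd.Series([2.0, 2.0, 2.0], index=["m0", "m1", "m2"])
        out = phenotype_correlation(f, self._table([1.0, 2.0, 3.0]))
        assert not out["defined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_fewer_than_three_systems_rejected(self):
        f = pd.Series([1.0, 2.0], index=["m0", "m1"])
        with pytest.raises(ValueError, match="at least 3"):
            phenotype_correlation(f, self._table([1.0, 2.0]))
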