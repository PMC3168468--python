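"""Ensemble containers, I/O round-trips, superposition and profile utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ensembledyn.ensemble_io import (
    EnsembleFrameSet,
    ResidueCorrespondence,
    join_macrotrajectory,
    load_ensemble,
    map_profile,
    representative_frame,
    smooth_profile,
    superpose,
    write_ensemble,
)
from ensembledyn.synthetic_data import (
    PlantedCovarianceSpec,
    gen_gaussian_ensemble,
    rigid_free_pair_modes,
)

from conftest import make_calpha_ensemble


class TestEnsembleFrameSet:
    def test_missing_calpha_names_the_residue(self):
        table = pd.DataFrame(
            {
                "residue_index": [1, 2],
                "residue_name": ["ALA", "GLY"],
                "atom_name": ["CA", "N"],
                "element": ["C", "N"],
            }
        )
        with pytest.raises(ValueError, match="GLY2"):
            EnsembleFrameSet(coords=np.zeros((1, 2, 3)), atom_table=table)

    def test_nonfinite_coordinates_rejected(self):
        coords = np.zeros((2, 3, 3))
        coords[1, 1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            make_calpha_ensemble(coords)

    def test_frame_and_residue_counts(self, rng):
        ens = make_calpha_ensemble(rng.normal(size=(4, 7, 3)))
        assert ens.n_frames == 4
        assert ens.n_residues == 7
        assert ens.calpha_coords.shape == (4, 7, 3)


class TestRoundTrip:
    def test_pdb_round_trip_preserves_coordinates(self, tmp_path):
        spec = PlantedCovarianceSpec(n_residues=5, n_frames=3, isotropic_noise=1e-3, seed=4)
        ens, _ = gen_gaussian_ensemble(spec)
        path = tmp_path / "ens.pdb"
        write_ensemble(ens, path)
        back = load_ensemble(path, time_per_frame=ens.time_per_frame)
        assert back.n_frames == 3
        assert back.n_residues == 5
        # PDB stores 3 decimals in Angstrom -> 1e-4 nm write precision
        np.testing.assert_allclose(back.coords, ens.coords, atol=5e-4)
        assert list(back.atom_table["atom_name"]) == list(ens.atom_table["atom_name"])


class TestJoinMacrotrajectory:
    def _part(self, n_frames, seed=0):
        rng = np.random.default_rng(seed)
        return make_calpha_ensemble(rng.normal(size=(n_frames, 4, 3)), time_per_frame=2.0)

    def test_plain_concatenation(self):
        joined = join_macrotrajectory([self._part(100, 1), self._part(100, 2)])
        assert joined.n_frames == 200

    def test_discard_in_picoseconds(self):
        joined = join_macrotrajectory(
            [self._part(100, 1), self._part(100, 2)], discard_ps_per_part=[20.0, 20.0]
        )
        assert joined.n_frames == 180

    def test_six_replica_counts_match_bruteforce(self, rng):
        lengths = [3000, 3000, 3000, 5000, 3000, 5000]
        discards_ps = [200.0, 2000.0, 400.0, 1000.0, 600.0, 2000.0]
        parts = [self._part(n, seed=i) for i, n in enumerate(lengths)]
        joined = join_macrotrajectory(parts, discards_ps)
        expected = sum(n - int(round(d / 2.0)) for n, d in zip(lengths, discards_ps))
        assert joined.n_frames == expected

    def test_mismatched_atom_tables_rejected(self):
        a = self._part(10)
        b = make_calpha_ensemble(np.zeros((10, 4, 3)), residue_names=["GLY"] * 4)
        with pytest.raises(ValueError, match="atom table"):
            join_macrotrajectory([a, b])

    def test_discarding_everything_rejected(self):
        with pytest.raises(ValueError, match="removes all"):
            join_macrotrajectory([self._part(10)], discard_ps_per_part=[20.0])


def _random_rigid(rng, coords):
    """Apply a random rotation + translation to every frame."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
        t = rng.normal(scale=2.0, size=3)
        out[f] = coords[f] @ R.T + t
    return out


class TestSuperpose:
    def _base_structure(self, rng, n=12):
        return rng.normal(scale=0.5, size=(n, 3))

    def test_rigid_copies_collapse_to_zero_rmsd(self, rng):
        base = self._base_structure(rng)
        frames = _random_rigid(rng, np.repeat(base[None], 8, axis=0))
        fitted = superpose(make_calpha_ensemble(frames, superposed=False))
        mean = fitted.coords.mean(axis=0)
        rmsd = np.sqrt(((fitted.coords - mean) ** 2).sum(axis=2).mean(axis=1))
        assert rmsd.max() < 1e-9

    def test_idempotence(self, rng):
        frames = self._base_structure(rng)[None] + rng.normal(scale=0.05, size=(6, 12, 3))
        once = superpose(make_calpha_ensemble(frames, superposed=False))
        twice = superpose(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-5

    def test_recovers_planted_internal_rmsd(self, rng):
        """Random rigid transforms must not change the internal motion."""
        n = 20
        modes = rigid_free_pair_modes(n, [(3, 15)])
        spec = PlantedCovarianceSpec(
            n_residues=n, modes=[(0.01, modes[0])], isotropic_noise=1e-4,
            n_frames=40, seed=9,
        )
        clean, _ = gen_gaussian_ensemble(spec)
        mean = clean.coords.mean(axis=0)
        planted_rmsd = np.sqrt(((clean.coords - mean) ** 2).sum(axis=2).mean(axis=1))

        scrambled = make_calpha_ensemble(
            _random_rigid(rng, clean.coords), superposed=False
        )
        fitted = superpose(scrambled)
        fmean = fitted.coords.mean(axis=0)
        fitted_rmsd = np.sqrt(((fitted.coords - fmean) ** 2).sum(axis=2).mean(axis=1))
        np.testing.assert_allclose(fitted_rmsd, planted_rmsd, atol=2e-3)

    def test_preserves_intraframe_distances(self, rng):
        frames = rng.normal(size=(5, 10, 3))
        ens = make_calpha_ensemble(frames, superposed=False)
        fitted = superpose(ens)
        for f in range(5):
            d0 = np.linalg.norm(frames[f][:, None] - frames[f][None], axis=-1)
            d1 = np.linalg.norm(fitted.coords[f][:, None] - fitted.coords[f][None], axis=-1)
            np.testing.assert_allclose(d1, d0, atol=1e-10)

    def test_collinear_selection_rejected(self):
        coords = np.zeros((3, 5, 3))
        coords[:, :, 0] = np.arange(5)
        with pytest.raises(ValueError, match="collinear"):
            superpose(make_calpha_ensemble(coords, superposed=False))


class TestRepresentativeFrame:
    def test_planted_minimum(self, rng):
        base = rng.normal(size=(8, 3))
        dev = rng.normal(size=(3, 8, 3))
        # deviations come in +/- pairs and frame 3 carries none, so frame 3
        # equals the ensemble mean exactly
        frames = base[None] + np.concatenate([dev, -dev, np.zeros((1, 8, 3))])[[0, 1, 2, 6, 3, 4, 5]]
        ens = make_calpha_ensemble(frames)
        assert representative_frame(ens) == 3

    def test_tie_breaks_to_first_frame(self):
        ens = make_calpha_ensemble(np.ones((4, 5, 3)))
        assert representative_frame(ens) == 0

    def test_matches_exhaustive_scan(self, rng):
        frames = rng.normal(size=(50, 9, 3))
        ens = make_calpha_ensemble(frames)
        mean = frames.mean(axis=0)
        brute = np.argmin(
            [np.sqrt(((frames[f] - mean) ** 2).sum(axis=1).mean()) for f in range(50)]
        )
        assert representative_frame(ens) == brute

    def test_empty_ensemble_rejected(self):
        ens = make_calpha_ensemble(np.zeros((1, 4, 3)))
        ens.coords = np.zeros((0, 4, 3))
        with pytest.raises(ValueError, match="empty"):
            representative_frame(ens)


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        np.testing.assert_allclose(smooth_profile([2.0] * 9, 5), 2.0)

    def test_window_one_is_identity(self, rng):
        v = rng.normal(size=15)
        np.testing.assert_allclose(smooth_profile(v, 1), v)

    def test_matches_bruteforce_truncated_means(self, rng):
        v = rng.normal(size=20)
        out = smooth_profile(v, 5)
        brute = [v[max(0, i - 2): i + 3].mean() for i in range(20)]
        np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_any_profile_matches_bruteforce(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=50, deadline=None)
        @given(
            values=st.lists(
                st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=30
            ),
            half=st.integers(0, 5),
        )
        def check(values, half):
            window = 2 * half + 1
            if window > len(values):
                return
            v = np.asarray(values)
            out = smooth_profile(v, window)
            brute = [
                v[max(0, i - half): i + half + 1].mean() for i in range(len(v))
            ]
            np.testing.assert_allclose(out, brute, rtol=1e-9, atol=1e-9)

        check()

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError, match="odd"):
            smooth_profile(np.zeros(10), window)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            smooth_profile(np.zeros(3), 5)


class TestMapProfile:
    def test_identity_correspondence(self, rng):
        v = rng.normal(size=5)
        corr = ResidueCorrespondence.identity(5)
        out = map_profile(v, range(1, 6), corr)
        assert list(out["index_b"]) == [1, 2, 3, 4, 5]
        assert not out["gap"].any()
        np.testing.assert_allclose(out["value"], v)

    def test_single_gap_flagged(self):
        corr = ResidueCorrespondence([(1, 1), (2, None), (3, 2)])
        out = map_profile([1.0, 2.0, 3.0], [1, 2, 3], corr)
        assert out["gap"].sum() == 1
        assert bool(out.loc[out["index_a"] == 2, "gap"].iloc[0])

    def test_matches_dictionary_lookup(self, rng):
        pairs, b = [], 1
        for a in range(1, 21):
            if rng.random() < 0.2:
                pairs.append((a, None))
            else:
                pairs.append((a, b))
                b += 1
        corr = ResidueCorrespondence(pairs)
        lookup = {a: bb for a, bb in pairs}
        v = rng.normal(size=20)
        out = map_profile(v, range(1, 21), corr)
        for _, row in out.iterrows():
            expected = lookup[row["index_a"]]
            assert row["gap"] == (expected is None)
            if expected is not None:
                assert row["index_b"] == expected

    def test_uncovered_index_rejected(self):
        corr = ResidueCorrespondence([(1, 1)])
        with pytest.raises(KeyError):
            map_profile([1.0, 2.0], [1, 2], corr)


class TestResidueCorrespondence:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ResidueCorrespondence([(2, 1), (1, 2)])

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            ResidueCorrespondence([(1, 1), (1, 2)])
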