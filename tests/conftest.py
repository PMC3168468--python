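"""Shared fixtures and builders for the test suite.

All test inputs are generated programmatically — either through the
package's synthetic-data module or through the small builders here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensembledyn.ensemble_io import EnsembleFrameSet


def make_calpha_ensemble(
    coords: np.ndarray,
    residue_names=None,
    time_per_frame: float = 2.0,
    superposed: bool = True,
    label: str = "test",
) -> EnsembleFrameSet:
    """Cα-only ensemble from raw coordinates of shape (F, N, 3)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    if residue_names is None:
        residue_names = ["ALA"] * n
    table = pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "residue_name": residue_names,
            "atom_name": "CA",
            "element": "C",
        }
    )
    return EnsembleFrameSet(
        coords=coords,
        atom_table=table,
        time_per_frame=time_per_frame,
        system_label=label,
        superposed=superposed,
    )


def make_atom_ensemble(atoms, frames, time_per_frame: float = 2.0, superposed=True):
    """Ensemble from an explicit atom list and per-frame coordinates.

    ``atoms`` is a list of (residue_index, residue_name, atom_name, element);
    ``frames`` an array (F, n_atoms, 3).
    """
    table = pd.DataFrame(
        atoms, columns=["residue_index", "residue_name", "atom_name", "element"]
    )
    return EnsembleFrameSet(
        coords=np.asarray(frames, dtype=float),
        atom_table=table,
        time_per_frame=time_per_frame,
        system_label="test",
        superposed=superposed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
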