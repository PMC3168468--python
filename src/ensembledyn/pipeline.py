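"""Pipeline orchestration: per-system analyses and cross-system comparison.

``run_pipeline`` drives every analysis stage (surrounding hydrophobicity,
hydrogen bonds, essential dynamics, correlation networks, salt bridges)
over a set of systems described by an :class:`AnalysisConfig`, then compares
each system against the first through a residue correspondence (network
diffs, gained/lost salt bridges).  All tabular outputs are TSV with a
commented header block recording the parameters and code version, written
deterministically so a rerun on the same inputs is byte-identical.

This module also hosts PDSSP: the per-residue persistence of the most
frequently attained secondary-structure label over the frames of an
ensemble, computed from an externally produced per-frame label table
(DSSP-style output is consumed, never computed here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_io import (
    EnsembleFrameSet,
    ResidueCorrespondence,
    load_correspondence,
    load_ensemble,
    smooth_profile,
    superpose,
)
from .hydrophobicity import compute_hp, load_scale
from .hbond_analysis import HBondCriteria, detect_hbonds, normalized_hbond_fraction
from .essential_dynamics import compute_subspace, project_and_rmsf
from .correlation_networks import filter_network, network_diff, windowed_correlation
from .saltbridge_networks import (
    ChargedGroupTable,
    build_proximity_clusters,
    detect_salt_bridges,
    filter_records,
)

logger = logging.getLogger(__name__)

#: modal-label tie-break priority (first wins); DSSP-style codes
SS_PRIORITY = "HGIEBTS-C"


def pdssp(labels, priority: str = SS_PRIORITY) -> pd.DataFrame:
    """Persistence degree of secondary structure profile.

    ``labels`` is a rectangular frames × residues table of single-letter
    secondary-structure codes (list of lists, 2-D array or DataFrame).  Per
    residue, returns the most frequently attained label and the fraction of
    frames carrying it; ties break by the fixed ``priority`` order and are
    flagged (and logged).
    """
    if isinstance(labels, pd.DataFrame):
        arr = labels.to_numpy()
    else:
        rows = [list(r) for r in labels]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged label table: row lengths {sorted(lengths)}")
        arr = np.array(rows, dtype=object)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("label table must be 2-D and non-empty")
    n_frames, n_res = arr.shape
    rank = {ch: i for i, ch in enumerate(priority)}
    out = []
    for j in range(n_res):
        col = arr[:, j]
        uniq, counts = np.unique(col.astype(str), return_counts=True)
        best = counts.max()
        winners = sorted(uniq[counts == best], key=lambda c: rank.get(c, len(rank)))
        tie = len(winners) > 1
        if tie:
            logger.info("residue %d: modal-label tie %s, keeping %s", j + 1, winners, winners[0])
        out.append(
            {
                "residue": j + 1,
                "modal_label": winners[0],
                "persistence": best / n_frames,
                "tie": tie,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML.

    Each entry of ``systems`` is a mapping with a ``label`` and either an
    ``ensemble`` path (multi-model PDB; optional ``topology`` for trajectory
    formats) or a ``synthetic`` block (``{"preset": "comparative", "role":
    "wildtype"|"mutant"}``) resolved through the synthetic-data generators.
    ``correspondence`` maps non-reference labels to a correspondence TSV, or
    the string ``"identity"``.  All cutoffs default to the standard
    comparative-analysis parameters.
    """

    systems: list[dict] = field(default_factory=list)
    correspondence: dict[str, str] = field(default_factory=dict)
    hp_r_d: float = 0.8                  # nm
    hp_scale: str | None = None          # path to a scale TSV; None = packaged
    hbond_distance: float = 0.35         # nm
    hbond_angle: float = 30.0            # degrees
    corr_window_ps: float = 1000.0       # 1 ns
    corr_c_cut: float = 0.4
    corr_sep_cut: int = 12
    sb_dist_cut: float = 0.4             # nm
    sb_persistence: float = 0.24
    sb_seq_dist: int = 5
    smooth_window: int = 5               # residues
    variance_target: float = 0.70
    ellipsoid_probability: float = 0.1
    seed: int = 0
    outdir: str = "ensembledyn_out"

    def __post_init__(self) -> None:
        for name in (
            "hp_r_d", "hbond_distance", "hbond_angle", "corr_window_ps",
            "corr_c_cut", "sb_dist_cut", "sb_persistence",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def parameter_lines(self) -> list[str]:
        d = asdict(self)
        for k in ("systems", "correspondence", "outdir"):
            d.pop(k)
        return [f"{k} = {d[k]}" for k in sorted(d)]


def _resolve_systems(config: AnalysisConfig) -> dict[str, EnsembleFrameSet]:
    """Load or generate every configured system, keyed by label."""
    from .synthetic_data import gen_mutant_comparison

    comparative_cache = None
    systems: dict[str, EnsembleFrameSet] = {}
    for entry in config.systems:
        label = entry["label"]
        if "synthetic" in entry:
            spec = entry["synthetic"]
            if spec.get("preset") != "comparative":
                raise ValueError(f"unknown synthetic preset {spec.get('preset')!r}")
            if comparative_cache is None:
                comparative_cache, _, _ = gen_mutant_comparison(seed=config.seed)
            ens = comparative_cache[spec["role"]]
            ens = EnsembleFrameSet(
                coords=ens.coords,
                atom_table=ens.atom_table,
                time_per_frame=ens.time_per_frame,
                system_label=label,
                superposed=ens.superposed,
            )
        else:
            ens = load_ensemble(
                entry["ensemble"],
                topology=entry.get("topology"),
                system_label=label,
            )
        systems[label] = ens
    if not systems:
        raise ValueError("no systems configured")
    return systems


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """In-memory pipeline results plus the paths of the written tables."""

    per_system: dict[str, dict]
    diffs: dict[str, dict]
    outdir: Path
    files: list[Path]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str], files: list[Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ensembledyn {__version__}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    files.append(path)


def run_pipeline(config: AnalysisConfig) -> ComparisonReport:
    """Run every per-system analysis, then all cross-system comparisons.

    The first configured system is the comparison reference.  Output tables
    land under ``config.outdir``; given the same config (and seed, for
    synthetic systems) a rerun writes byte-identical files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    header = config.parameter_lines()
    scale = load_scale(config.hp_scale)

    systems = _resolve_systems(config)
    labels = list(systems)
    ref_label = labels[0]

    per_system: dict[str, dict] = {}
    for label in labels:
        ens = systems[label]
        if not ens.superposed:
            ens = superpose(ens)
        stage = "surrounding hydrophobicity"
        try:
            hp = compute_hp(ens, scale=scale, r_d=config.hp_r_d, keep_per_frame=False)
            hp_smooth = smooth_profile(hp.mean_hp, config.smooth_window)

            stage = "essential dynamics"
            sub = compute_subspace(ens, variance_target=config.variance_target)
            flex = project_and_rmsf(ens, sub)
            rmsf_smooth = smooth_profile(flex.rmsf, config.smooth_window)

            stage = "hydrogen bonds"
            crit = HBondCriteria(
                distance_cutoff=config.hbond_distance, angle_cutoff=config.hbond_angle
            )
            try:
                hb = detect_hbonds(ens, crit)
                hb_fraction = normalized_hbond_fraction(hb)
            except ValueError as exc:
                logger.info("%s: hydrogen-bond stage skipped (%s)", label, exc)
                hb, hb_fraction = None, float("nan")

            stage = "correlation network"
            cm = windowed_correlation(ens, window_ps=config.corr_window_ps)
            net = filter_network(
                cm, c_cut=config.corr_c_cut, sep_cut=config.corr_sep_cut,
                system_label=label,
            )

            stage = "salt bridges"
            records = detect_salt_bridges(ens, dist_cut=config.sb_dist_cut)
            kept = filter_records(records, config.sb_persistence)
            clusters = build_proximity_clusters(kept, seq_dist=config.sb_seq_dist)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed for system '{label}': {exc}") from exc

        per_system[label] = {
            "ensemble": ens,
            "hp": hp,
            "hp_smooth": hp_smooth,
            "subspace": sub,
            "rmsf": flex,
            "rmsf_smooth": rmsf_smooth,
            "hbond_fraction": hb_fraction,
            "correlation": cm,
            "network": net,
            "bridges_all": records,
            "bridges_kept": kept,
            "clusters": clusters,
        }

        sys_header = header + [f"system = {label}", f"hp_scale = {scale.label}"]
        _write_tsv(
            pd.DataFrame(
                {
                    "residue_index": ens.residue_indices,
                    "residue_name": ens.residue_names,
                    "hp_mean": hp.mean_hp,
                    "hp_smoothed": hp_smooth,
                }
            ),
            outdir / f"{label}_hp.tsv", sys_header, files,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "residue_index": ens.residue_indices,
                    "rmsf_nm": flex.rmsf,
                    "rmsf_smoothed_nm": rmsf_smooth,
                }
            ),
            outdir / f"{label}_rmsf.tsv", sys_header + [f"subspace_k = {flex.k}"], files,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "eigenvalue_rank": np.arange(1, len(sub.eigenvalues) + 1),
                    "eigenvalue_nm2": sub.eigenvalues,
                    "cumulative_variance": sub.cumulative_variance,
                }
            ),
            outdir / f"{label}_eigenvalues.tsv", sys_header, files,
        )
        _write_tsv(net.edges, outdir / f"{label}_corr_edges.tsv", sys_header, files)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "residue_a": r.residue_a,
                        "residue_b": r.residue_b,
                        "persistence": r.persistence,
                        "kept": r.persistence >= config.sb_persistence,
                    }
                    for r in records
                ],
                columns=["residue_a", "residue_b", "persistence", "kept"],
            ),
            outdir / f"{label}_saltbridges.tsv", sys_header, files,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {"cluster_id": c.cluster_id, "residue": r}
                    for c in clusters
                    for r in c.residues
                ],
                columns=["cluster_id", "residue"],
            ),
            outdir / f"{label}_clusters.tsv", sys_header, files,
        )

    # ---------------- cross-system comparisons against the reference -------
    diffs: dict[str, dict] = {}
    for label in labels[1:]:
        spec = config.correspondence.get(label, "identity")
        if spec == "identity":
            corr = ResidueCorrespondence.identity(
                systems[ref_label].n_residues, ref_label, label
            )
        else:
            corr = load_correspondence(spec, ref_label, label)
        ndiff = network_diff(per_system[ref_label]["network"], per_system[label]["network"], corr)

        ref_pairs = {r.pair for r in per_system[ref_label]["bridges_kept"]}
        other_pairs_mapped = set()
        unmappable = set()
        for r in per_system[label]["bridges_kept"]:
            a, b = corr.map_b_to_a(r.residue_a), corr.map_b_to_a(r.residue_b)
            if a is None or b is None:
                unmappable.add(r.pair)
            else:
                other_pairs_mapped.add((min(a, b), max(a, b)))
        gained = sorted(other_pairs_mapped - ref_pairs)
        lost = sorted(ref_pairs - other_pairs_mapped)
        shared = sorted(ref_pairs & other_pairs_mapped)
        diffs[label] = {
            "network": ndiff,
            "bridges_gained": gained,
            "bridges_lost": lost,
            "bridges_shared": shared,
            "bridges_unmappable": sorted(unmappable),
        }

        rows = []
        for cat, pairs in (
            ("corr_shared", sorted(ndiff.shared)),
            ("corr_only_" + ref_label, sorted(ndiff.only_a)),
            ("corr_only_" + label, sorted(ndiff.only_b)),
            ("corr_unmappable", sorted(ndiff.unmappable_a | ndiff.unmappable_b)),
            ("bridge_shared", shared),
            ("bridge_gained", gained),
            ("bridge_lost", lost),
            ("bridge_unmappable", sorted(unmappable)),
        ):
            for i, j in pairs:
                rows.append({"category": cat, "residue_a": i, "residue_b": j})
        _write_tsv(
            pd.DataFrame(rows, columns=["category", "residue_a", "residue_b"]),
            outdir / f"diff_{ref_label}_vs_{label}.tsv",
            header + [f"reference = {ref_label}", f"other = {label}"],
            files,
        )

    summary_rows = []
    for label in labels:
        d = per_system[label]
        summary_rows.append(
            {
                "system": label,
                "n_frames": d["ensemble"].n_frames,
                "n_residues": d["ensemble"].n_residues,
                "mean_hp": float(np.mean(d["hp"].mean_hp)),
                "mean_rmsf_nm": float(np.mean(d["rmsf"].rmsf)),
                "subspace_k": d["rmsf"].k,
                "hbond_fraction_pct": d["hbond_fraction"],
                "n_corr_edges": len(d["network"].edges),
                "n_bridges_kept": len(d["bridges_kept"]),
                "n_clusters": len(d["clusters"]),
            }
        )
    _write_tsv(pd.DataFrame(summary_rows), outdir / "summary.tsv", header, files)

    return ComparisonReport(per_system=per_system, diffs=diffs, outdir=outdir, files=files)
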