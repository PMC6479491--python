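"""Pipeline orchestration: ensemble -> stability / H-bonds / essential
dynamics / FEL -> representative -> RIN centralities, with a run manifest.

Every stage writes TSV/JSON outputs with fixed number formatting before the
next stage starts, so reruns with an identical configuration and inputs are
bit-identical; the manifest records the configuration echo and a sha256
hash per output file (no wall-clock data, by design).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .essential_dynamics import (cosine_content, fit_essential_dynamics,
                                 free_energy_surface, locate_minimum_frames,
                                 project)
from .hbond import HBondCriterion, detect_hbonds, hbond_count_series, occupancy_table
from .representative import (EnergyProfile, read_energy_file,
                             select_representative)
from .rin_centrality import (CentralityTable, build_rin, centrality_diff,
                             centrality_table, threshold_report)
from .stability import rmsd_series, rmsf_table, sasa_series
from .structure_io import (AtomSelection, TrajectoryEnsemble, read_ensemble,
                           select, write_pdb)
from .synthetic_data import EnsembleSpec, generate_energy_series, generate_ensemble

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "compare_states",
           "load_config"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults follow the analysis conventions
    (3.5 A / 30 deg H-bond criterion, 7 A contact cutoff, cosine-content
    admissibility 0.2, top-20 low-energy clustering, 300 K, C_B thresholds
    0.05 and 0.02/0.03)."""

    ensemble_path: str | None = None  # multi-model PDB; None -> synthetic
    energy_path: str | None = None  # two-column time/energy text
    selection: str = "backbone"
    stride_ps: float = 100.0
    # H-bond stage
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    # essential dynamics / FEL
    n_pcs: int = 20
    fel_bins: int = 32
    temperature: float = 300.0
    cosine_threshold: float = 0.2
    force_fel: bool = False
    # representative selection
    top_k: int = 20
    cluster_cutoff: float = 2.0
    # residue interaction network
    rin_cutoff: float = 7.0
    cb_min: float = 0.05
    diff_threshold: float = 0.02
    map_threshold: float = 0.03
    # synthetic input (used when ensemble_path is None)
    n_residues: int = 20
    n_frames: int = 50
    seed: int = 0
    output_dir: str = "rinflow_out"


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path) -> PipelineConfig:
    """Read a flat key-value YAML configuration document."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _load_or_generate(config: PipelineConfig) -> tuple[TrajectoryEnsemble, EnergyProfile]:
    if config.ensemble_path is not None:
        ensemble = read_ensemble(config.ensemble_path, stride_ps=config.stride_ps)
    else:
        spec = EnsembleSpec(n_residues=config.n_residues,
                            n_frames=config.n_frames,
                            stride_ps=config.stride_ps, seed=config.seed)
        ensemble = generate_ensemble(spec)
    if config.energy_path is not None:
        profile = read_energy_file(config.energy_path)
    else:
        profile = generate_energy_series(
            ensemble.n_frames, minimum_at=ensemble.n_frames // 2,
            seed=(config.seed + 1) % (2 ** 31), stride_ps=config.stride_ps)
    return ensemble, profile


def _intra_protein_hbond_tables(ensemble, criterion):
    """Per-frame intra-protein bond counts and per-residue participation."""
    top = ensemble.topology
    protein = select(top, "protein")
    counts = np.zeros(ensemble.n_frames, dtype=int)
    frames_by_res: dict[int, set[int]] = {}
    for f in range(ensemble.n_frames):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = detect_hbonds(top, ensemble.frames[f], protein, protein,
                                 criterion, frame=f)
        counts[f] = len(recs)
        for r in recs:
            for atom in (r.donor, r.acceptor):
                rid = top.atoms[atom].residue_index
                frames_by_res.setdefault(rid, set()).add(f)
    res_by_index = {res.index: res for res in top.residues}
    rows = pd.DataFrame({
        "residue": [res_by_index[r].label for r in sorted(frames_by_res)],
        "occupancy": [len(frames_by_res[r]) / ensemble.n_frames
                      for r in sorted(frames_by_res)],
    })
    rows = rows.sort_values("occupancy", ascending=False,
                            kind="stable").reset_index(drop=True)
    return counts, rows


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order, writing outputs per stage."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)

    def record(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- input -------------------------------------------------------
        ensemble, profile = _load_or_generate(config)
        top = ensemble.topology
        sel = select(top, config.selection)
        calpha = select(top, "calpha")
        criterion = HBondCriterion(max_da_distance=config.hbond_distance,
                                   max_angle=config.hbond_angle)

        # --- stability ---------------------------------------------------
        rmsd = rmsd_series(ensemble, 0, sel)
        _write_tsv(pd.DataFrame({"time_ps": rmsd.times, "rmsd_A": rmsd.values}),
                   outdir / "rmsd.tsv", f"backbone RMSD vs frame 0, selection={config.selection}")
        record(outdir / "rmsd.tsv")
        rmsf = rmsf_table(ensemble, calpha)
        _write_tsv(pd.DataFrame({"residue": rmsf.residue_labels,
                                 "rmsf_A": rmsf.values}),
                   outdir / "rmsf.tsv", "Calpha RMSF about the mean structure")
        record(outdir / "rmsf.tsv")
        sasa = sasa_series(ensemble, sel)
        _write_tsv(pd.DataFrame({"time_ps": sasa.times, "sasa_nm2": sasa.values}),
                   outdir / "sasa.tsv",
                   f"Shrake-Rupley SASA, probe={sasa.probe_radius} nm")
        record(outdir / "sasa.tsv")
        manifest.stages_completed.append("stability")

        # --- hydrogen bonds ---------------------------------------------
        ligand = select(top, "ligand")
        protein = select(top, "protein")
        if len(ligand):
            counts = hbond_count_series(ensemble, ligand, protein, criterion)
            occ = occupancy_table(ensemble, protein, ligand, criterion)
            occ_rows = occ.rows[["residue", "occupancy"]]
        else:
            counts, occ_rows = _intra_protein_hbond_tables(ensemble, criterion)
        _write_tsv(pd.DataFrame({"time_ps": ensemble.times, "n_hbonds": counts}),
                   outdir / "hbond_counts.tsv",
                   f"H-bonds per frame, {config.hbond_distance} A / {config.hbond_angle} deg")
        record(outdir / "hbond_counts.tsv")
        _write_tsv(occ_rows, outdir / "hbond_occupancy.tsv",
                   "fraction of frames with >= 1 H-bond per residue")
        record(outdir / "hbond_occupancy.tsv")
        manifest.stages_completed.append("hbonds")

        # --- essential dynamics / FEL -------------------------------------
        ed = fit_essential_dynamics(ensemble, sel)
        n_pcs = min(config.n_pcs, len(ed.eigenvalues))
        cumvar = ed.cumulative_variance()
        _write_tsv(pd.DataFrame({
            "pc": np.arange(1, n_pcs + 1),
            "eigenvalue_nm2": ed.eigenvalues[:n_pcs],
            "cumulative_variance": cumvar[:n_pcs],
        }), outdir / "eigenvalues.tsv",
            f"covariance eigenvalues, total={ed.eigenvalues.sum():.10g} nm2")
        record(outdir / "eigenvalues.tsv")
        proj = project(ensemble, ed, k=max(2, min(n_pcs, 2)))
        _write_tsv(pd.DataFrame({"time_ps": proj.times,
                                 "pc1_nm": proj.coordinates[:, 0],
                                 "pc2_nm": proj.coordinates[:, 1]}),
                   outdir / "projections.tsv", "PC projections (nm)")
        record(outdir / "projections.tsv")
        c1 = cosine_content(proj, 1)
        c2 = cosine_content(proj, 2)
        manifest.stages_completed.append("essential_dynamics")

        fel_ok = config.force_fel or (c1 <= config.cosine_threshold
                                      and c2 <= config.cosine_threshold)
        min_frames = None
        if fel_ok:
            surface = free_energy_surface(
                proj, (1, 2), n_bins=config.fel_bins,
                temperature=config.temperature,
                cosine_threshold=config.cosine_threshold, force=True)
            cx = 0.5 * (surface.edges_x[:-1] + surface.edges_x[1:])
            cy = 0.5 * (surface.edges_y[:-1] + surface.edges_y[1:])
            gx, gy = np.meshgrid(cx, cy, indexing="ij")
            _write_tsv(pd.DataFrame({
                "pc1_nm": gx.ravel(), "pc2_nm": gy.ravel(),
                "count": surface.counts.ravel(),
                "delta_g_kJ_mol": surface.delta_g.ravel(),
            }), outdir / "fel.tsv",
                f"free-energy landscape at {config.temperature} K; empty bins NaN")
            record(outdir / "fel.tsv")
            min_frames = locate_minimum_frames(surface, proj)
            manifest.stages_completed.append("fel")
        else:
            warnings.warn(
                f"FEL skipped: cosine content PC1={c1:.3f} PC2={c2:.3f} "
                f"exceeds {config.cosine_threshold} (use force_fel)")

        # --- representative ----------------------------------------------
        k = min(config.top_k, ensemble.n_frames)
        rep = select_representative(ensemble, profile, sel, k=k,
                                    rmsd_cutoff=config.cluster_cutoff)
        rep_df = pd.DataFrame({
            "frame": rep.top_k_frames,
            "time_ps": ensemble.times[rep.top_k_frames],
            "energy": profile.energy[rep.top_k_frames],
            "cluster": rep.cluster_assignment,
        })
        rep_df.attrs["representative"] = rep.representative_frame
        with open(outdir / "representative.tsv", "w") as fh:
            fh.write(f"# representative_frame={rep.representative_frame} "
                     f"lowest_energy_frame={rep.lowest_energy_frame} "
                     f"fel_minimum_frames={list(map(int, min_frames)) if min_frames is not None else 'n/a'}\n")
            rep_df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
        record(outdir / "representative.tsv")
        rep_model = ensemble.frame_model(rep.representative_frame)
        write_pdb(rep_model, outdir / "representative.pdb")
        record(outdir / "representative.pdb")
        manifest.stages_completed.append("representative")

        # --- residue interaction network ----------------------------------
        net = build_rin(rep_model, cutoff=config.rin_cutoff, hbond_criterion=criterion)
        table = centrality_table(net)
        _write_tsv(table.table, outdir / "centrality.tsv",
                   f"RIN centralities, cutoff={config.rin_cutoff} A, N={net.n}")
        record(outdir / "centrality.tsv")
        report = threshold_report(table, cb_min=config.cb_min)
        _write_tsv(report, outdir / "cb_report.tsv",
                   f"residues with C_B >= {config.cb_min} "
                   f"(threshold percentile {report.attrs['percentile']:.1f})")
        record(outdir / "cb_report.tsv")
        node_link = {
            "nodes": [{"id": i, "residue": nd.label, "chain": nd.chain_id,
                       "backbone_center": [round(v, 6) for v in nd.backbone_center],
                       "sidechain_center": ([round(v, 6) for v in nd.sidechain_center]
                                            if nd.sidechain_center is not None else None)}
                      for i, nd in enumerate(net.nodes)],
            "edges": [{"source": e.i, "target": e.j,
                       "contact_types": sorted(e.contact_types),
                       "min_center_distance": round(e.min_center_distance, 6),
                       "hbond_count": e.hbond_count}
                      for e in net.edges],
        }
        (outdir / "network.json").write_text(
            json.dumps(node_link, indent=2, sort_keys=True))
        record(outdir / "network.json")
        manifest.stages_completed.append("rin_centrality")

    manifest.warnings = [str(w.message) for w in caught]
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def compare_states(centrality_tables: list[CentralityTable],
                   labels: list[str] | None = None,
                   threshold: float = 0.02,
                   map_threshold: float = 0.03) -> dict:
    """Pairwise betweenness differences of 2-3 states against the first.

    Returns a report with one CentralityDiff per comparison and the
    residues flagged at each threshold (author-numbered labels).
    """
    if len(centrality_tables) < 2:
        raise ValueError("at least two states are required")
    if labels is None:
        labels = [f"state{i}" for i in range(len(centrality_tables))]
    ref = centrality_tables[0]
    report: dict = {"reference": labels[0], "comparisons": []}
    for other, label in zip(centrality_tables[1:], labels[1:]):
        diff = centrality_diff(ref, other, threshold=threshold,
                               map_threshold=map_threshold)
        t = diff.table
        report["comparisons"].append({
            "state": label,
            "diff": diff,
            "flagged": t.loc[t[f"flag_{threshold:g}"], "residue"].tolist(),
            "flagged_map": t.loc[t[f"flag_{map_threshold:g}"], "residue"].tolist(),
        })
    return report
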