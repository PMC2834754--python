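"""End-to-end profiling: structure -> interface -> descriptor panel ->
class assignment -> reference comparison, with structured reports.

`profile_complex` runs every descriptor stage on one complex (optionally
with its unbound form and a protein/inhibitor form); `profile_dataset`
runs a manifest of complexes, assembles the panel table, computes group
statistics and t-values against caller-supplied reference moments, and
clusters the panel with PCA + k-means.  Stage failures are reported by
stage name; partial reports mark the missing blocks explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ppiface.structure import (
    Structure, PartnerSelection, read_pdb, classify_residue, extract_ligand,
)
from ppiface.sasa import (
    define_interface, ligand_coverage, ligand_neighborhood,
)
from ppiface.geometry import (
    planarity, eccentricity, gap_volume, superpose, pair_ca_atoms,
)
from ppiface.contacts import (
    hydrogen_bonds, hb_density, salt_bridges, segments_for_interface,
    ss_interface_class,
)
from ppiface.pockets import find_pockets, interface_pockets
from ppiface.classify import (
    assign_class, t_value, t_significant, InterfaceClassification,
)
from ppiface.compare import compare_to_reference
from ppiface.reference_data import GroupStats, KEY_DESCRIPTORS

logger = logging.getLogger("ppiface")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, echoed into provenance."""

    probe_radius: float = 1.4        # A, SASA water probe
    sasa_points: int = 960
    atom_burial_threshold: float = 0.1   # A^2
    hbond_cutoff: float = 3.2        # A, H...acceptor
    salt_bridge_cutoff: float = 4.0  # A
    segment_max_gap: int = 4
    ligand_shell: float = 4.5        # A, inhibitor-neighborhood subset
    gap_grid_spacing: float = 1.0    # A
    gap_shell_cutoff: float = 5.0    # A
    pocket_grid_spacing: float = 0.9
    pocket_energy_cutoff: float = -1.4   # kcal/mol
    pocket_cluster_dist: float = 1.6
    pocket_overlap_dist: float = 2.0
    max_pockets: int = 10
    kmeans_k: int = 3
    kmeans_restarts: int = 50
    seed: int = 0


@dataclass
class ComplexReport:
    identifier: str
    selection: str
    descriptors: dict[str, float]
    ppi_class: str | None
    not_computable: dict[str, str] = field(default_factory=dict)
    comparison: dict | None = None
    ligand_subset: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "selection": self.selection,
            "descriptors": self.descriptors,
            "ppi_class": self.ppi_class,
            "not_computable": self.not_computable,
            "comparison": self.comparison,
            "ligand_subset": self.ligand_subset,
            "provenance": self.provenance,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _load(source) -> Structure:
    if isinstance(source, Structure):
        return source
    try:
        return read_pdb(source)
    except Exception as exc:
        raise StageError("parse", exc) from exc


def profile_complex(
    pp_source,
    selection: PartnerSelection | str,
    unbound_source=None,
    ligand_source=None,
    ligand_selection: PartnerSelection | None = None,
    config: PipelineConfig | None = None,
    compare: bool = False,
) -> ComplexReport:
    """Run the full descriptor pipeline on one protein/protein complex.

    When an unbound form is supplied the CA RMSD against the complexed
    form is computed; when a protein/inhibitor form is supplied the
    inhibitor coverage, interface-pocket filtering and the
    inhibitor-neighborhood descriptor subset are added.  Missing inputs
    leave the corresponding blocks marked "input absent".
    """
    cfg = config or PipelineConfig()
    if isinstance(selection, str):
        selection = PartnerSelection.from_string(selection)
    cx = _load(pp_source)
    desc: dict[str, float] = {}
    gaps: dict[str, str] = {}

    def run(stage, fn):
        try:
            result = fn()
            logger.info("stage %s: ok (%s)", stage, cx.id)
            return result
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    interface = run("interface", lambda: define_interface(
        cx, selection, cfg.atom_burial_threshold, cfg.probe_radius,
        cfg.sasa_points))
    desc["asa_mean_side"] = interface.asa_mean_side

    iface_idx = sorted(interface.interface_atoms_a | interface.interface_atoms_b)
    if len(iface_idx) >= 3:
        coords = cx.coords(iface_idx)
        desc["planarity"] = run("planarity", lambda: planarity(coords))
        desc["eccentricity"] = run("eccentricity", lambda: eccentricity(coords))
    else:
        gaps["planarity"] = gaps["eccentricity"] = "interface too small"

    if interface.delta_asa_total > 0:
        gv = run("gap_volume", lambda: gap_volume(
            cx, selection, interface, cfg.gap_grid_spacing, cfg.gap_shell_cutoff))
        desc["gap_volume"] = gv.gap_volume
        desc["gap_index"] = gv.gap_index
    else:
        gaps["gap_volume"] = gaps["gap_index"] = "zero interface"

    bonds = run("hydrogen_bonds", lambda: hydrogen_bonds(
        cx, interface, cfg.hbond_cutoff))
    desc["hb_count"] = float(len(bonds))
    if interface.asa_mean_side > 0:
        desc["hb_per_100A2"] = run("hb_density", lambda: hb_density(
            len(bonds), interface))
    else:
        gaps["hb_per_100A2"] = "zero interface"

    bridges = run("salt_bridges", lambda: salt_bridges(
        cx, interface, cfg.salt_bridge_cutoff))
    desc["salt_bridges"] = float(len(bridges))

    segs = run("segments", lambda: segments_for_interface(
        cx, interface, cfg.segment_max_gap))
    desc["n_segments"] = float(segs.n_segments)

    ss = run("secondary_structure", lambda: ss_interface_class(cx, interface))
    ss_pair = ss.pair_label

    charged = total = 0
    for rid in interface.interface_residues_a | interface.interface_residues_b:
        resname = next(a.residue_name for a in cx.atoms if a.residue_id == rid)
        try:
            cls = classify_residue(resname)
        except ValueError:
            continue
        total += 1
        charged += cls == "charged"
    desc["pct_charged_residues"] = 100.0 * charged / total if total else 0.0

    if unbound_source is not None:
        unbound = _load(unbound_source)
        def _rmsd():
            mob, ref = pair_ca_atoms(unbound, cx, None, selection.side_a)
            return superpose(mob, ref).rmsd
        desc["rmsd_unbound"] = run("rmsd", _rmsd)
    else:
        gaps["rmsd_unbound"] = "input absent"

    ligand_block = None
    if ligand_source is not None:
        lig_cx = _load(ligand_source)
        lsel = ligand_selection or PartnerSelection(
            side_a=selection.side_a, side_b=set(),
            ligand=selection.ligand)
        if lsel.ligand is None:
            raise StageError("ligand", ValueError("no ligand identifier given"))
        lig_idx = run("ligand_extract", lambda: extract_ligand(lig_cx, lsel))
        desc["h_asa_percent"] = run("ligand_coverage", lambda: ligand_coverage(
            lig_cx, lsel, interface, cx,
            probe=cfg.probe_radius, n_points=cfg.sasa_points))
        def _pockets():
            prot_idx = lig_cx.atom_indices(lsel.side_a, hetero=False)
            pockets = find_pockets(
                lig_cx, prot_idx, cfg.pocket_grid_spacing,
                cfg.pocket_energy_cutoff, cfg.pocket_cluster_dist,
                cfg.max_pockets)
            return interface_pockets(
                pockets, lig_cx.coords(lig_idx), cfg.pocket_overlap_dist)
        n_pk, vol_pk = run("pockets", _pockets)
        desc["n_interface_pockets"] = float(n_pk)
        desc["pocket_volume"] = float(vol_pk)

        def _subset():
            atoms, residues = ligand_neighborhood(lig_cx, lig_idx, cfg.ligand_shell)
            return {"n_atoms": len(atoms), "n_residues": len(residues)}
        ligand_block = run("ligand_subset", _subset)
    else:
        gaps["h_asa_percent"] = "input absent"
        gaps["pocket_volume"] = "input absent"

    ppi_class = (assign_class(int(desc["n_segments"]))
                 if "n_segments" in desc else None)

    comparison = None
    if compare:
        query = {k: desc.get(k, float("nan")) for k in KEY_DESCRIPTORS}
        if all(np.isfinite(list(query.values()))):
            comparison = compare_to_reference(query).to_dict()
        else:
            gaps["comparison"] = "key descriptors incomplete"

    return ComplexReport(
        identifier=cx.id,
        selection=f"{''.join(sorted(selection.side_a))}:"
                  f"{''.join(sorted(selection.side_b))}",
        descriptors=desc,
        ppi_class=ppi_class,
        not_computable=gaps,
        comparison=comparison,
        ligand_subset=ligand_block,
        provenance={**asdict(cfg), "ss_class_pair": ss_pair,
                    "version": "0.1.0", "nmr_model": 1},
    )


def profile_dataset(
    manifest: list[dict],
    config: PipelineConfig | None = None,
    reference_stats: dict[str, GroupStats] | None = None,
) -> dict:
    """Profile a list of complexes and analyze the resulting panel.

    *manifest* entries are dicts with keys ``pp`` (path or Structure),
    ``selection`` ("A:B" or PartnerSelection) and optionally ``unbound``,
    ``ligand``, ``ligand_selection``, ``name``.  Returns a dict with the
    panel DataFrame, per-complex reports, optional t-values against
    *reference_stats* (caller-supplied group moments) and the clustering
    results (skipped with a notice when fewer than 3 complexes succeed).
    """
    cfg = config or PipelineConfig()
    reports: dict[str, ComplexReport] = {}
    failures: dict[str, str] = {}
    for i, entry in enumerate(manifest):
        name = entry.get("name", f"complex_{i}")
        try:
            reports[name] = profile_complex(
                entry["pp"], entry["selection"], entry.get("unbound"),
                entry.get("ligand"), entry.get("ligand_selection"), cfg)
        except StageError as exc:
            logger.warning("complex %s skipped: %s", name, exc)
            failures[name] = str(exc)

    panel = pd.DataFrame({name: r.descriptors for name, r in reports.items()}).T
    result: dict = {"panel": panel, "reports": reports, "failures": failures,
                    "config": asdict(cfg)}

    if reference_stats:
        tvals = {}
        for desc_name, ref in reference_stats.items():
            if desc_name not in panel.columns:
                continue
            vals = panel[desc_name].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            g = GroupStats(mean=float(vals.mean()),
                           variance=float(vals.var(ddof=1)), n=len(vals))
            t = t_value(g, ref)
            tvals[desc_name] = {"t": t, "significant": t_significant(t)}
        result["t_values"] = tvals

    usable = [d for d in KEY_DESCRIPTORS if d in panel.columns
              and panel[d].notna().all() and panel[d].std(ddof=1) > 0]
    if len(panel) >= 3 and len(usable) >= 2:
        model = InterfaceClassification(panel, k=min(cfg.kmeans_k, len(panel)),
                                        descriptors=usable)
        result["clustering"] = model.fit(restarts=cfg.kmeans_restarts,
                                         seed=cfg.seed)
    else:
        result["clustering"] = None
        result["clustering_notice"] = (
            "clustering skipped: need >= 3 profiled complexes and >= 2 "
            "non-constant key descriptors")
    return result
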