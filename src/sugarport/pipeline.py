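"""End-to-end orchestration over a (synthetic) input bundle.

Stages run in dependency order: simulate -> transportome -> expression ->
structure (RIN + tunnels) -> integrate.  All randomness derives from the
single top-level seed through fixed per-stage offsets, so identical
configurations produce byte-identical numeric outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import integration, rin, synthetic, transportome as tp, tunnels as tn
from .config import PipelineConfig, config_to_dict
from .structure import read_structure

logger = logging.getLogger(__name__)


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the machine-readable
    run report (also written to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": config_to_dict(config),
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    for stage in config.stages:
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            outputs = runner(config, out, state)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"stage {stage!r}: missing input: {exc}") from exc
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = "completed"
        report["outputs"][stage] = sorted(str(p.name) for p in outputs)
    report["output_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "report.json"
    }
    _write_json(out / "report.json", report)
    return report


# ----------------------------------------------------------------- stages
def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    seed = config.stage_seed("simulate")
    structure, channel_truth = synthetic.make_channel_structure(
        synthetic.ChannelSpec(seed=seed, probe_radius=config.tunnels.probe_radius)
    )
    structure.to_pdb(out / "channel.pdb")
    evidence, sequences, evidence_truth = synthetic.make_evidence_tables(seed=seed + 1)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    synthetic.write_fasta(sequences, out / "proteins.fasta")
    fpkm, diff, sets, expr_truth = synthetic.make_expression(
        synthetic.PlantedExpressionSpec(seed=seed + 2)
    )
    fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)
    synthetic.write_gmt(sets, out / "subfamilies.gmt")
    pinch = channel_truth["pinch_residues"]
    energy, energy_truth = synthetic.make_energy_table(
        seed=seed + 3, planted_top_residue=pinch[0]
    )
    energy.to_csv(out / "energy.tsv", sep="\t", index=False)
    _write_json(
        out / "truth.json",
        {
            "channel": channel_truth,
            "evidence": evidence_truth,
            "expression": expr_truth,
            "energy": energy_truth,
        },
    )
    state["truth"] = {
        "channel": channel_truth,
        "evidence": evidence_truth,
        "expression": expr_truth,
        "energy": energy_truth,
    }
    return [
        out / n
        for n in (
            "channel.pdb",
            "evidence.tsv",
            "proteins.fasta",
            "fpkm.tsv",
            "differential.tsv",
            "subfamilies.gmt",
            "energy.tsv",
            "truth.json",
        )
    ]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(str(path))
    return path


def _stage_transportome(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    p = config.transportome
    evidence = pd.read_csv(_require(out / "evidence.tsv"), sep="\t")
    sequences = synthetic.read_fasta(_require(out / "proteins.fasta"))
    records = [
        tp.EvidenceRecord(
            protein_id=row.protein_id,
            source=row.source,
            feature_id=row.feature_id,
            e_value=row.e_value,
            identity_pct=row.identity_pct,
        )
        for row in evidence.itertuples(index=False)
    ]
    kept = tp.filter_evidence(
        records,
        max_e_value=p.max_e_value,
        min_identity_pct=p.min_identity_pct,
        allowed_tc_classes=p.tc_classes,
    )
    topologies = {
        pid: tp.predict_tm_segments(
            seq,
            window=p.tm_window,
            threshold=p.tm_threshold,
            min_segments=p.min_segments,
            min_segment_length=p.tm_min_segment_length,
            protein_id=pid,
        )
        for pid, seq in sequences.items()
    }
    per_source: dict[str, set[str]] = {s: set() for s in tp.EVIDENCE_SOURCES}
    by_protein: dict[str, list[tp.EvidenceRecord]] = {}
    for rec in kept:
        per_source[rec.source].add(rec.protein_id)
        by_protein.setdefault(rec.protein_id, []).append(rec)
    catalog = tp.consensus_catalog(per_source, topologies, evidence=by_protein)
    motif_rows = []
    for pid in sorted(catalog.members):
        for motif in tp.KNOWN_MOTIFS:
            for hit in tp.scan_motif(sequences[pid], motif, topologies[pid], pid):
                motif_rows.append(
                    {
                        "protein_id": pid,
                        "motif": hit.motif,
                        "start": hit.start,
                        "end": hit.end,
                        "in_tm_segment": hit.in_tm_segment,
                        "tm_index": hit.tm_index,
                    }
                )
    pd.DataFrame(
        {
            "protein_id": sorted(catalog.members),
            "sources": [
                ";".join(
                    sorted({r.source for r in catalog.evidence_index.get(pid, [])})
                )
                for pid in sorted(catalog.members)
            ],
        }
    ).to_csv(out / "catalog.tsv", sep="\t", index=False)
    pd.DataFrame(
        motif_rows,
        columns=["protein_id", "motif", "start", "end", "in_tm_segment", "tm_index"],
    ).to_csv(out / "motifs.tsv", sep="\t", index=False)
    _write_json(
        out / "catalog_summary.json",
        {
            "n_members": len(catalog),
            "per_source_counts": catalog.per_source_counts,
        },
    )
    state["catalog"] = catalog
    return [out / "catalog.tsv", out / "motifs.tsv", out / "catalog_summary.json"]


def _stage_expression(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    p = config.expression
    fpkm = pd.read_csv(_require(out / "fpkm.tsv"), sep="\t", index_col=0)
    diff = pd.read_csv(_require(out / "differential.tsv"), sep="\t")
    sets = synthetic.read_gmt(_require(out / "subfamilies.gmt"))
    degs = expr.call_degs(diff, lfc_min=p.lfc_min, fdr_max=p.fdr_max)
    degs.to_csv(out / "degs.tsv", sep="\t", index=False)
    gene_stats = dict(zip(diff["gene_id"].astype(str), diff["log2fc"]))
    results = expr.enrich_gene_sets(
        gene_stats,
        sets,
        n_perm=p.n_perm,
        seed=config.stage_seed("expression"),
        alpha=p.alpha,
    )
    pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "n_members": r.n_members,
                "observed_mean": r.observed_mean,
                "p_distinct_up": r.p_distinct_up,
                "p_distinct_down": r.p_distinct_down,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    means = expr.condition_means(fpkm)
    target = state.get("truth", {}).get("expression", {}).get(
        "contrast", "xylose/glucose"
    ).split("/")[0]
    candidate = expr.select_candidate(results, sets, means, target)
    _write_json(
        out / "candidate.json",
        {
            "candidate_gene": candidate,
            "condition": target,
            "fpkm": float(means.loc[candidate, target]),
            "significant_sets": sorted(r.set_id for r in results if r.significant),
        },
    )
    return [out / "degs.tsv", out / "enrichment.tsv", out / "candidate.json"]


def _stage_structure(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    structure = read_structure(_require(out / "channel.pdb"))
    r = config.rin
    graph = rin.build_rin(
        structure,
        contact_slack=r.contact_slack,
        hbond_dist_max=r.hbond_dist_max,
        min_seq_separation=r.min_seq_separation,
    )
    profile = rin.betweenness(graph)
    rin.edges_table(graph).to_csv(out / "rin_edges.tsv", sep="\t", index=False)
    rin.centrality_table(profile).to_csv(out / "centrality.tsv", sep="\t", index=False)
    rin.write_graphml(graph, out / "rin.graphml")

    t = config.tunnels
    start = state.get("truth", {}).get("channel", {}).get("start_xyz")
    if start is None:
        truth = json.loads(_require(out / "truth.json").read_text())
        start = truth["channel"]["start_xyz"]
    tunnels = tn.find_tunnels(
        structure,
        tn.TunnelConfig(
            probe_radius=t.probe_radius,
            clustering_threshold=t.clustering_threshold,
            shell_depth=t.shell_depth,
            shell_radius=t.shell_radius,
            grid_spacing=t.grid_spacing,
            bottleneck_cutoff=t.bottleneck_cutoff,
            start_point=tuple(start),
        ),
    )
    _write_json(out / "tunnels.json", tn.tunnels_report(tunnels))
    tn.centerline_pdb(tunnels, out / "tunnel_centerlines.pdb")
    state["structure"] = structure
    state["graph"] = graph
    state["profile"] = profile
    state["tunnels"] = tunnels
    return [
        out / n
        for n in (
            "rin_edges.tsv",
            "centrality.tsv",
            "rin.graphml",
            "tunnels.json",
            "tunnel_centerlines.pdb",
        )
    ]


def _stage_integrate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    profile = state.get("profile")
    tunnels = state.get("tunnels")
    structure = state.get("structure")
    if profile is None or tunnels is None or structure is None:
        raise FileNotFoundError("structure stage outputs (run 'structure' first)")
    if not tunnels:
        raise RuntimeError("no tunnels detected; cannot integrate")
    energy = pd.read_csv(_require(out / "energy.tsv"), sep="\t")
    records = integration.records_from_frame(energy)
    validation = integration.validate_decomposition_table(
        records, tolerance=config.integration.energy_tolerance
    )
    lining = tn.tunnel_residue_set(
        tunnels, structure, cutoff=config.tunnels.bottleneck_cutoff
    )
    comparison = integration.compare_betweenness(profile, lining)
    report = integration.find_key_residues(
        profile,
        tunnels,
        peak_quantile=config.integration.peak_quantile,
        energy={r.residue: r.dG_bind for r in records},
    )
    top = integration.rank_contributors(records, n=min(10, len(records)))
    payload = report.to_dict()
    payload["betweenness_comparison"] = {
        "mean_all": comparison.mean_all,
        "mean_tunnel": comparison.mean_tunnel,
        "mean_non_tunnel": comparison.mean_non_tunnel,
        "statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "test_name": comparison.test_name,
        "n_all": comparison.n_all,
        "n_tunnel": comparison.n_tunnel,
        "note": comparison.note,
    }
    payload["energy_validation"] = {
        "n_rows": int(len(validation)),
        "n_failing": int((~validation["passes"]).sum()),
    }
    payload["top_contributors"] = [
        {"residue": r.residue, "dG_bind": r.dG_bind} for r in top
    ]
    _write_json(out / "key_residues.json", payload)
    return [out / "key_residues.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "transportome": _stage_transportome,
    "expression": _stage_expression,
    "structure": _stage_structure,
    "integrate": _stage_integrate,
}
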