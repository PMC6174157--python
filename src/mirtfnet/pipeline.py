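"""End-to-end orchestration: simulate -> quantify -> DE -> targets -> network -> enrichment.

Every stage writes plain-text artifacts into the output directory and
reports its row counts into a reproducibility manifest
(``manifest.json``).  Identical config (including the seed) gives
byte-identical outputs.  Structured per-stage logs go to standard error.

Target scanning is restricted to the features differentially expressed in
at least one pair -- only those can contribute network edges.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as mio
from .config import PipelineConfig
from .diffexp import run_all_pairs_de, summarize_recurrence
from .enrichment import hypergeom_enrich, top_terms, wallenius_enrich
from .errors import InputError, MirtfnetError
from .network import (
    MIR_UP_GENE_DOWN,
    build_network,
    build_tf_subnetwork,
    edges_to_frame,
    export_edge_list,
    export_node_attributes,
    hub_statistics,
    match_negative_pairs,
)
from .quantify import compute_cpm, compute_rpkm, compute_tpm_mirna
from .synthetic import generate_cohort, write_cohort
from .targets import MiRNARecord, scan_gene

logger = logging.getLogger("mirtfnet")


@dataclass
class RunManifest:
    """Per-stage row counts plus the config echo; mirrors the output files."""

    config: dict
    artifact_version: str = __version__
    rng_seed: int = 0
    counts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    partial: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "artifact_version": self.artifact_version,
                "rng_seed": self.rng_seed,
                "config": self.config,
                "counts": self.counts,
                "completed_stages": self.completed_stages,
                "partial": self.partial,
            },
            indent=1,
            sort_keys=True,
        )


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                manifest.completed_stages.append(name)
                logger.info("stage=%s status=done duration_s=%.2f", name, dt)
            else:
                manifest.partial = True
                logger.error("stage=%s status=failed error=%s", name, exc)
            return False

    return _Ctx()


def _write_venn(venn: dict, path: Path) -> None:
    rows = []
    for direction, cells in venn.items():
        for subset, count in sorted(cells.items(), key=lambda kv: sorted(kv[0])):
            rows.append(
                {
                    "direction": direction,
                    "pair_subset": ",".join(sorted(subset)),
                    "n_features": count,
                }
            )
    pd.DataFrame(rows, columns=["direction", "pair_subset", "n_features"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(cfg: PipelineConfig, outdir) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk).

    Raises :class:`MirtfnetError` naming the failed stage; partial outputs
    are flagged in the manifest, which is written even on failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.model_dump(), rng_seed=cfg.rng_seed)
    manifest_path = outdir / "manifest.json"

    try:
        # -- inputs ----------------------------------------------------
        with _stage(manifest, "inputs"):
            if cfg.mode == "simulate":
                sim_cfg = cfg.simulation_config()
                genes, mirna_recs, mrna_cm, mirna_cm, truth = generate_cohort(sim_cfg)
                write_cohort(genes, mirna_recs, mrna_cm, mirna_cm, truth, outdir / "cohort")
                utrs = {g.gene_id: g.utr_seq for g in genes}
                tf_ids = {g.gene_id for g in genes if g.is_tf}
                go_map = mio.read_gmt(outdir / "cohort" / "go_map.gmt")
            else:
                mrna_cm = mio.read_counts(
                    cfg.inputs.mrna_counts, lengths_path=cfg.inputs.mrna_lengths
                )
                mirna_cm = mio.read_counts(cfg.inputs.mirna_counts)
                utrs = mio.read_fasta(cfg.inputs.utr_fasta)
                mirna_recs = [
                    MiRNARecord(i, s) for i, s in mio.read_fasta(cfg.inputs.mirna_fasta).items()
                ]
                tf_ids = mio.read_tf_list(cfg.inputs.tf_list)
                go_map = mio.read_gmt(cfg.inputs.go_map) if cfg.inputs.go_map else {}
            manifest.counts["n_genes"] = len(mrna_cm.feature_ids)
            manifest.counts["n_mirnas"] = len(mirna_cm.feature_ids)
            manifest.counts["n_pairs"] = len(mrna_cm.pair_ids)

        # -- quantify --------------------------------------------------
        with _stage(manifest, "quantify"):
            if mrna_cm.feature_lengths is not None:
                mio.write_normalized(compute_rpkm(mrna_cm), outdir / "mrna_rpkm.tsv")
            mio.write_normalized(compute_cpm(mrna_cm), outdir / "mrna_cpm.tsv")
            mio.write_normalized(compute_tpm_mirna(mirna_cm), outdir / "mirna_tpm.tsv")
            mio.write_normalized(compute_cpm(mirna_cm), outdir / "mirna_cpm.tsv")

        # -- differential expression -----------------------------------
        with _stage(manifest, "de"):
            de_kwargs = dict(
                dispersion=cfg.dispersion,
                fc_threshold=cfg.fc_threshold,
                fdr_threshold=cfg.fdr_threshold,
                pseudocount=cfg.pseudocount,
                cpm_threshold=cfg.cpm_threshold,
                cpm_min_samples=cfg.cpm_min_samples,
            )
            de_mrna = run_all_pairs_de(mrna_cm, **de_kwargs)
            de_mirna = run_all_pairs_de(mirna_cm, **de_kwargs)
            de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t", index=False, float_format="%.6g")
            de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t", index=False, float_format="%.6g")
            rec_mrna, venn_mrna = summarize_recurrence(de_mrna)
            rec_mirna, venn_mirna = summarize_recurrence(de_mirna)
            rec_mrna.to_csv(outdir / "recurrence_mrna.tsv", sep="\t", index=False)
            rec_mirna.to_csv(outdir / "recurrence_mirna.tsv", sep="\t", index=False)
            _write_venn(venn_mrna, outdir / "venn_mrna.tsv")
            _write_venn(venn_mirna, outdir / "venn_mirna.tsv")
            for label, de in (("mrna", de_mrna), ("mirna", de_mirna)):
                called = de[de["direction"] != "ns"]
                manifest.counts[f"n_tested_{label}"] = int(de["feature_id"].nunique())
                manifest.counts[f"n_de_calls_{label}"] = int(len(called))
                manifest.counts[f"n_de_{label}"] = int(called["feature_id"].nunique())

        # -- target prediction -----------------------------------------
        with _stage(manifest, "targets"):
            de_mirna_ids = sorted(
                de_mirna.loc[de_mirna["direction"] != "ns", "feature_id"].unique()
            )
            de_gene_ids = sorted(
                de_mrna.loc[de_mrna["direction"] != "ns", "feature_id"].unique()
            )
            mirna_by_id = {m.id: m for m in mirna_recs}
            all_sites, all_calls = [], []
            for mid in de_mirna_ids:
                mirna = mirna_by_id.get(mid)
                if mirna is None:
                    raise InputError(f"DE miRNA {mid} missing from the miRNA FASTA")
                for gid in de_gene_ids:
                    utr = utrs.get(gid)
                    if utr is None:
                        raise InputError(f"DE gene {gid} missing from the UTR FASTA")
                    sites, call = scan_gene(
                        gid,
                        utr,
                        mirna,
                        w_au=cfg.w_au,
                        w_pos=cfg.w_pos,
                        align_min=cfg.align_min,
                        align_min_frac=cfg.align_min_frac,
                    )
                    all_sites += sites
                    all_calls.append(call)
            sites_df = pd.DataFrame(
                [
                    {
                        "gene_id": s.gene_id,
                        "mirna_id": s.mirna_id,
                        "utr_start": s.utr_start,
                        "site_type": s.site_type,
                        "align_score": round(s.align_score, 4),
                        "context_score": round(s.context_score, 4),
                    }
                    for s in all_sites
                ],
                columns=["gene_id", "mirna_id", "utr_start", "site_type", "align_score", "context_score"],
            )
            sites_df.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
            calls_df = pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "mirna_id": c.mirna_id,
                        "total_align_score": round(c.total_align_score, 4),
                        "best_context_score": round(c.best_context_score, 4)
                        if c.n_sites
                        else "",
                        "n_sites": c.n_sites,
                        "passes": c.passes,
                    }
                    for c in all_calls
                ],
                columns=["gene_id", "mirna_id", "total_align_score", "best_context_score", "n_sites", "passes"],
            )
            calls_df.to_csv(outdir / "target_calls.tsv", sep="\t", index=False)
            manifest.counts["n_target_sites"] = int(len(sites_df))
            manifest.counts["n_target_calls_pass"] = int(sum(c.passes for c in all_calls))

        # -- network ----------------------------------------------------
        with _stage(manifest, "network"):
            edges = match_negative_pairs(de_mirna, de_mrna, all_calls)
            manifest.counts["n_edges_prefilter"] = len(edges)
            net = build_network(edges, tf_ids=tf_ids, min_pairs=cfg.min_pairs)
            manifest.counts["n_edges"] = len(net.edges)
            manifest.counts["n_network_mirnas"] = net.n_mirnas
            manifest.counts["n_network_genes"] = net.n_genes
            if not net.edges:
                logger.warning(
                    "network is empty at min_pairs=%d; downstream stages will be empty",
                    cfg.min_pairs,
                )
            export_edge_list(net, outdir / "network_edges.tsv", "tsv")
            export_edge_list(net, outdir / "network_edges.sif", "sif")
            export_node_attributes(net, outdir / "network_nodes.tsv")
            tf_net = build_tf_subnetwork(net, pattern=MIR_UP_GENE_DOWN)
            manifest.counts["n_tf_edges"] = len(tf_net.edges)
            manifest.counts["n_tf_subnetwork_mirnas"] = tf_net.n_mirnas
            manifest.counts["n_tf_subnetwork_tfs"] = tf_net.n_genes
            export_edge_list(tf_net, outdir / "tf_network_edges.tsv", "tsv")
            export_edge_list(tf_net, outdir / "tf_network_edges.sif", "sif")
            gene_hubs, mirna_hubs = hub_statistics(tf_net)
            gene_hubs.to_csv(outdir / "tf_hub_genes.tsv", sep="\t", index=False)
            mirna_hubs.to_csv(outdir / "tf_hub_mirnas.tsv", sep="\t", index=False)

        # -- enrichment --------------------------------------------------
        with _stage(manifest, "enrichment"):
            if go_map:
                universe = set(de_mrna["feature_id"].unique())
                study = {
                    e.gene_id for e in net.edges if e.pattern == MIR_UP_GENE_DOWN
                } & universe
                if study:
                    if cfg.enrich_method == "wallenius":
                        rows = wallenius_enrich(study, universe, go_map, weights={})
                    else:
                        rows = hypergeom_enrich(study, universe, go_map)
                else:
                    rows = pd.DataFrame()
                rows.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
                top_terms(rows, cfg.top_k_terms).to_csv(
                    outdir / "enrichment_top.tsv", sep="\t", index=False, float_format="%.6g"
                )
                manifest.counts["n_enriched_terms"] = int(len(rows))
            else:
                manifest.counts["n_enriched_terms"] = 0
    except Exception as exc:
        manifest_path.write_text(manifest.to_json())
        stage = (
            manifest.completed_stages[-1] if manifest.completed_stages else "inputs"
        )
        raise MirtfnetError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest_path.write_text(manifest.to_json())
    return manifest
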