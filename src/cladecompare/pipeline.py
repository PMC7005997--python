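"""End-to-end pipeline: simulate (or load) a clade, then run every analysis
stage and emit a reproducible plain-text report bundle.

Outputs per run (all TSV/BED/Newick/FASTA/JSON):

* ``simulated/``          genomes, annotations, truth tables, true tree
* ``ani_matrix.tsv``, ``mapped_fraction_matrix.tsv``, ``ani_pairs.tsv``
* ``hgt_calls.tsv``, ``donor_summary.tsv``, ``function_summary.tsv``
* ``clusters.tsv``, ``phyletic_matrix.tsv``, ``unique_clusters.tsv``,
  ``branch_counts.tsv``, ``core_tree.nwk``
* ``landscape_<genome>.tsv``, ``low_gc_<genome>.bed``, ``landscape_report.txt``
* ``synteny_<query>_vs_<ref>.anchors.tsv`` / ``.blocks.tsv`` /
  ``.breakpoints.bed``, ``synteny_report.txt``
* ``manifest.json``       materialized config, config hash, versions, seed,
  stage status, and headline numbers (HGT precision/recall on truth)

A stage failure halts the run with the stage named; a ``FAILED`` marker file
records the stage while earlier outputs are kept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ani import compute_ani, write_ani_tsv
from .hgt import screen_genes, summarize_donors, summarize_functions
from .landscape import gc_windows, low_gc_hgt_association, write_low_gc_bed
from .pangenome import (
    branch_table,
    branch_unique_counts,
    cluster_orthologs,
    concatenate_core,
    core_and_single_copy,
    distance_tree,
    unique_per_genome,
)
from .seqio import Genome, read_fasta, read_gff3
from .synthetic import (
    DEFAULT_TAXONOMY,
    CladeConfig,
    ProteinFamily,
    TruthTable,
    parse_tree,
    simulate_clade,
    simulate_hit_table,
    write_clade,
)
from .synteny import (
    SyntenyAnchor,
    anchors_table,
    blocks_table,
    breakpoints,
    cluster_anchors,
    find_anchors,
    mobilome_breakpoint_overlap,
)

#: truth label -> expected screening call
TRUTH_TO_CALL = {
    "native": "native",
    "hgt_recent": "acquired_recent",
    "hgt_ancestral": "acquired_other",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One pipeline run: either a simulator config or real input paths."""

    outdir: str
    seed: int = 0
    simulate: Optional[CladeConfig] = None
    input_fastas: Optional[list[str]] = None
    input_gffs: Optional[list[str]] = None
    input_hits: Optional[str] = None
    input_tree: Optional[str] = None
    focal_genome: Optional[str] = None
    self_genus: str = "Thermosynechococcus"
    ani_fragment_len: int = 3000
    ani_k: int = 16
    ani_min_identity: float = 80.0
    ani_species_cutoff: float = 95.0
    hgt_min_query_cov: float = 0.90
    hgt_min_similarity: float = 40.0
    hgt_top_n: int = 5
    window_len: int = 10_000
    window_step: int = 10_000
    low_gc_threshold_sd: float = 1.0
    n_perm: int = 1000
    min_match_len: int = 20
    min_cluster_len: int = 200
    max_gap: int = 500
    breakpoint_margin: int = 2000
    n_bootstrap: int = 200

    def validate(self) -> None:
        has_sim = self.simulate is not None
        has_real = self.input_fastas is not None
        if has_sim == has_real:
            raise ValueError(
                "exactly one of a simulator config and real input paths must be set"
            )
        if has_sim:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "is_element" in sim:
                length, copies = sim["is_element"]
                sim["is_element"] = (int(length), dict(copies))
            sim = CladeConfig(**sim)
        cfg = cls(simulate=sim, **raw)
        cfg.validate()
        return cfg

    def materialized(self) -> dict[str, Any]:
        data = {k: v for k, v in self.__dict__.items() if k != "simulate"}
        if self.simulate is not None:
            sim = self.simulate.__dict__.copy()
            sim["is_element"] = [self.simulate.is_element[0], dict(self.simulate.is_element[1])]
            data["simulate"] = sim
        return data


def _config_hash(config: PipelineConfig) -> str:
    canonical = yaml.safe_dump(config.materialized(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _precision_recall(truth_genes: pd.DataFrame, calls: pd.DataFrame) -> dict[str, float]:
    """Per-status precision/recall of the screen against truth labels,
    reduced to the minima over the three statuses."""
    expected = truth_genes.set_index("gene_id")["status"].map(TRUTH_TO_CALL)
    observed = calls.set_index("gene_id")["status"]
    joined = pd.DataFrame({"expected": expected, "observed": observed}).dropna()
    precisions, recalls = [], []
    for status in sorted(set(joined["expected"])):
        tp = int(((joined["expected"] == status) & (joined["observed"] == status)).sum())
        fp = int(((joined["expected"] != status) & (joined["observed"] == status)).sum())
        fn = int(((joined["expected"] == status) & (joined["observed"] != status)).sum())
        precisions.append(tp / (tp + fp) if tp + fp else 1.0)
        recalls.append(tp / (tp + fn) if tp + fn else 1.0)
    return {
        "precision": float(min(precisions)) if precisions else float("nan"),
        "recall": float(min(recalls)) if recalls else float("nan"),
        "accuracy": float((joined["expected"] == joined["observed"]).mean()),
        "n_genes": int(len(joined)),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.materialized(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "results": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        genomes: list[Genome]
        truth: Optional[TruthTable] = None
        families: Optional[list[ProteinFamily]] = None
        if config.simulate is not None:
            sim_cfg = config.simulate
            genomes, truth, families = simulate_clade(sim_cfg)
            write_clade(outdir / "simulated", genomes, truth, families, sim_cfg)
            tree = parse_tree(sim_cfg.tree)
            outgroup = sim_cfg.outgroup
        else:
            genomes = []
            for fasta in config.input_fastas:
                genomes.extend(read_fasta(fasta))
            if config.input_gffs:
                by_id = {g.genome_id: g for g in genomes}
                for gff in config.input_gffs:
                    for gid in list(by_id):
                        try:
                            by_id[gid] = read_gff3(gff, by_id[gid])
                        except Exception:
                            continue
                genomes = list(by_id.values())
            tree = parse_tree(Path(config.input_tree).read_text()) if config.input_tree else None
            outgroup = None
        by_id = {g.genome_id: g for g in genomes}
        focal = config.focal_genome or ("CL1" if "CL1" in by_id else genomes[0].genome_id)
        manifest["stages"]["inputs"] = "ok"

        # --------------------------------------------------------------- ANI
        stage = "ani"
        ids = sorted(by_id)
        ani = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
        mapped = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
        pair_results = []
        for q in ids:
            for r in ids:
                if q == r:
                    ani.loc[q, r], mapped.loc[q, r] = 100.0, 1.0
                    continue
                res = compute_ani(
                    by_id[q], by_id[r], config.ani_fragment_len, config.ani_k,
                    config.ani_min_identity, config.ani_species_cutoff,
                )
                if res.ani_percent is not None:
                    ani.loc[q, r] = res.ani_percent
                mapped.loc[q, r] = res.mapped_fraction
                if q < r:
                    pair_results.append(res)
        ani.round(4).to_csv(outdir / "ani_matrix.tsv", sep="\t")
        mapped.round(4).to_csv(outdir / "mapped_fraction_matrix.tsv", sep="\t")
        write_ani_tsv(pair_results, outdir / "ani_pairs.tsv")
        manifest["stages"]["ani"] = "ok"

        # --------------------------------------------------------- HGT screen
        stage = "hgt_screen"
        calls = None
        if config.simulate is not None:
            hits = simulate_hit_table(
                truth, DEFAULT_TAXONOMY if set(by_id) == set(DEFAULT_TAXONOMY) else {
                    g: (config.self_genus, "Synechococcales", "Cyanobacteria") for g in by_id
                },
                self_genus=config.self_genus,
                seed=config.seed,
                genomes=[focal],
            )
        elif config.input_hits:
            hits = pd.read_csv(config.input_hits, sep="\t")
        else:
            hits = None
        if hits is not None:
            focal_genes = [a.locus_tag for a in by_id[focal].genes()]
            calls = screen_genes(
                hits,
                self_genus=config.self_genus,
                all_genes=focal_genes,
                min_query_cov=config.hgt_min_query_cov,
                min_similarity=config.hgt_min_similarity,
                top_n=config.hgt_top_n,
            )
            calls.to_csv(outdir / "hgt_calls.tsv", sep="\t", index=False)
            donors = summarize_donors(calls, self_order="Synechococcales")
            donors.to_csv(outdir / "donor_summary.tsv", sep="\t", index=False)
            ann = {a.locus_tag: a for a in by_id[focal].annotations}
            functions = summarize_functions(calls, ann)
            functions.to_csv(outdir / "function_summary.tsv", sep="\t", index=False)
            status_counts = calls["status"].value_counts().to_dict()
            manifest["results"]["hgt_status_counts"] = {
                k: int(v) for k, v in sorted(status_counts.items())
            }
            if truth is not None:
                focal_truth = truth.genes[truth.genes["genome_id"] == focal]
                manifest["results"]["hgt_recovery"] = _precision_recall(focal_truth, calls)
        manifest["stages"]["hgt_screen"] = "ok"

        # ----------------------------------------------------------- pangenome
        stage = "pangenome"
        if families is not None:
            proteins: dict[str, dict[str, str]] = {g: {} for g in by_id}
            for fam in families:
                for genome_id, (gene_id, seq) in fam.members.items():
                    proteins[genome_id][gene_id] = seq
            clusters = cluster_orthologs(proteins)
            clusters.phyletic_matrix.to_csv(outdir / "phyletic_matrix.tsv", sep="\t")
            rows = [
                {"cluster": cid, "genome": gn, "genes": ",".join(genes)}
                for cid, members in sorted(clusters.clusters.items())
                for gn, genes in sorted(members.items())
            ]
            pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            core, single = core_and_single_copy(clusters, sorted(by_id))
            unique = unique_per_genome(clusters)
            pd.DataFrame(
                [{"genome": g, "n_unique_clusters": n} for g, n in sorted(unique.items())]
            ).to_csv(outdir / "unique_clusters.tsv", sep="\t", index=False)
            manifest["results"]["n_clusters"] = len(clusters.clusters)
            manifest["results"]["n_core_clusters"] = len(core)
            manifest["results"]["n_single_copy_core"] = len(single)
            manifest["results"]["unique_clusters"] = {k: int(v) for k, v in sorted(unique.items())}
            if tree is not None:
                branches = branch_unique_counts(tree, clusters.phyletic_matrix)
                branch_table(branches).to_csv(
                    outdir / "branch_counts.tsv", sep="\t", index=False
                )
            # supermatrix over single-copy-core clusters (one gene per genome)
            single_fams = {
                cid: {
                    gn: proteins[gn][genes[0]]
                    for gn, genes in clusters.clusters[cid].items()
                }
                for cid in sorted(single)
            }
            if single_fams and outgroup is not None:
                supermatrix = concatenate_core(single_fams, sorted(by_id))
                manifest["results"]["supermatrix_sites"] = len(next(iter(supermatrix.values())))
                core_tree = distance_tree(
                    supermatrix, outgroup=outgroup,
                    n_bootstrap=config.n_bootstrap, seed=config.seed,
                )
                core_tree.write(str(outdir / "core_tree.nwk"))
                supports = [
                    n.support for n in core_tree.non_tips(include_self=False)
                    if getattr(n, "support", None) is not None
                ]
                manifest["results"]["min_bootstrap_support"] = (
                    float(min(supports)) if supports else None
                )
        manifest["stages"]["pangenome"] = "ok"

        # ----------------------------------------------------------- landscape
        stage = "landscape"
        report_lines = []
        track = gc_windows(by_id[focal], config.window_len, config.window_step)
        track.to_frame().round(6).to_csv(
            outdir / f"landscape_{focal}.tsv", sep="\t", index=False
        )
        write_low_gc_bed(track, outdir / f"low_gc_{focal}.bed", config.low_gc_threshold_sd)
        manifest["results"]["focal_mean_gc"] = round(track.mean_gc, 5)
        if calls is not None:
            status_of = calls.set_index("gene_id")["status"].to_dict()
            gene_status = [
                (a, status_of.get(a.locus_tag, "native")) for a in by_id[focal].genes()
            ]
            assoc = low_gc_hgt_association(
                track,
                gene_status,
                threshold_sd=config.low_gc_threshold_sd,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            report_lines.append(assoc.report())
            if assoc.defined:
                manifest["results"]["low_gc_hgt"] = {
                    "observed_fraction": round(assoc.observed_fraction, 4),
                    "p_value": assoc.p_value,
                }
        (outdir / "landscape_report.txt").write_text("\n".join(report_lines) + "\n")
        manifest["stages"]["landscape"] = "ok"

        # ------------------------------------------------------------- synteny
        stage = "synteny"
        syn_lines = []
        others = [g for g in sorted(by_id) if g != focal]
        for other in others:
            q, r = by_id[focal], by_id[other]
            anchors = find_anchors(q.sequence, r.sequence, config.min_match_len)
            blocks = cluster_anchors(anchors, config.min_cluster_len, config.max_gap)
            bps = breakpoints(blocks, len(q.sequence))
            tag = f"{focal}_vs_{other}"
            anchors_table(anchors).to_csv(outdir / f"synteny_{tag}.anchors.tsv", sep="\t", index=False)
            blocks_table(blocks).to_csv(outdir / f"synteny_{tag}.blocks.tsv", sep="\t", index=False)
            with open(outdir / f"synteny_{tag}.breakpoints.bed", "w") as fh:
                for bp in bps:
                    kind = "inversion" if bp.is_inversion else "rearrangement"
                    fh.write(f"{focal}\t{bp.position}\t{bp.position + 1}\t{kind}\n")
            mobilome = [a for a in q.annotations if a.feature_kind == "mobile_element"]
            overlap = mobilome_breakpoint_overlap(
                bps, mobilome, len(q.sequence),
                margin=config.breakpoint_margin, n_perm=config.n_perm, seed=config.seed,
            )
            syn_lines.append(f"{tag}: {len(anchors)} anchors, {len(blocks)} blocks, "
                             f"{len(bps)} breakpoints; {overlap.report()}")
            # reverse direction: breakpoints on the partner, where the
            # mobilome actually sits; anchors map by coordinate transposition
            rev_anchors = [
                SyntenyAnchor(a.r_start, a.r_end, a.q_start, a.q_end, a.orientation)
                for a in anchors
            ]
            rev_blocks = cluster_anchors(rev_anchors, config.min_cluster_len, config.max_gap)
            rev_bps = breakpoints(rev_blocks, len(r.sequence))
            rev_mob = [a for a in r.annotations if a.feature_kind == "mobile_element"]
            rev_overlap = mobilome_breakpoint_overlap(
                rev_bps, rev_mob, len(r.sequence),
                margin=config.breakpoint_margin, n_perm=config.n_perm, seed=config.seed,
            )
            syn_lines.append(f"{other}_vs_{focal}: {len(rev_blocks)} blocks, "
                             f"{len(rev_bps)} breakpoints; {rev_overlap.report()}")
        (outdir / "synteny_report.txt").write_text("\n".join(syn_lines) + "\n")
        manifest["stages"]["synteny"] = "ok"

    except Exception as exc:  # halt with the stage named, keep partial output
        manifest["stages"][stage] = "FAILED"
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        _write_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    _write_manifest(manifest, outdir)
    return manifest


def _versions() -> dict[str, str]:
    import skbio

    return {
        "cladecompare": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-bio": skbio.__version__,
    }


def _write_manifest(manifest: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
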