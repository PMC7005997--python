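"""Ortholog clustering, phyletic accounting and the core-genome distance tree.

Clustering is a deterministic reciprocal-best-hit (RBH) graph method: k-mer
similarity scores connect genes across genomes when each is the other's best
hit, within-genome gene pairs are joined when they score higher than either
gene's best between-genome hit (recent paralogs), and connected components
become clusters. The phyletic matrix (cluster x genome copy numbers) then
feeds core-genome extraction, per-genome unique-cluster counts and branch-wise
uniquely-present / uniquely-absent counts on a rooted species tree.

The species tree itself is built by neighbor joining on Poisson-corrected
distances ``d = -ln(1 - p)`` from the concatenated single-copy-core protein
supermatrix, with non-parametric bootstrap over alignment columns and rooting
on a named outgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix
from skbio.tree import nj

PROTEIN_KMER = 4
MAX_P_DISTANCE = 0.99  # ceiling before the log correction diverges


@dataclass
class OrthologClusterSet:
    """Gene membership per cluster plus the cluster x genome copy-number matrix."""

    clusters: dict[str, dict[str, list[str]]]
    phyletic_matrix: pd.DataFrame

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            size = 0
            for genome, genes in members.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(f"gene {g} in more than one cluster")
                    seen.add(g)
                size += len(genes)
            if size != int(self.phyletic_matrix.loc[cid].sum()):
                raise ValueError(f"cluster {cid}: matrix row sum != cluster size")


@dataclass
class BranchAnnotation:
    """Uniquely-present / uniquely-absent cluster counts for one branch,
    identified by the leaf set of its child clade."""

    branch: str
    leaf_set: frozenset[str]
    n_uniquely_present: int
    n_uniquely_absent: int


# ---------------------------------------------------------------------------
# Pairwise protein similarity and RBH clustering
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int = PROTEIN_KMER) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_scores(
    proteins: Mapping[str, Mapping[str, str]], k: int = PROTEIN_KMER
) -> pd.DataFrame:
    """Shared-k-mer counts for all gene pairs that share at least one k-mer.

    Returns a frame with columns query, subject, score (query < subject
    lexicographically; each unordered pair appears once).
    """
    gene_ids: list[str] = []
    genome_of: dict[str, str] = {}
    kmers: dict[str, set[str]] = {}
    for genome in sorted(proteins):
        for gid in sorted(proteins[genome]):
            gene_ids.append(gid)
            genome_of[gid] = genome
            kmers[gid] = _kmer_set(proteins[genome][gid], k)
    index: dict[str, list[str]] = {}
    for gid in gene_ids:
        for km in kmers[gid]:
            index.setdefault(km, []).append(gid)
    counts: dict[tuple[str, str], int] = {}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                a, b = bucket[i], bucket[j]
                if a > b:
                    a, b = b, a
                counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = [
        {"query": a, "subject": b, "score": c} for (a, b), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["query", "subject", "score"])


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:  # deterministic root choice
                ra, rb = rb, ra
            self.parent[rb] = ra


MIN_EDGE_SCORE = 10  # shared k-mers; chance overlap of unrelated proteins is ~1


def cluster_orthologs(
    proteins: Mapping[str, Mapping[str, str]],
    scores: Optional[pd.DataFrame] = None,
    k: int = PROTEIN_KMER,
    min_score: int = MIN_EDGE_SCORE,
) -> OrthologClusterSet:
    """Cluster genes into ortholog groups by RBH graph components.

    ``proteins`` maps genome_id -> {gene_id: amino-acid sequence}. ``scores``
    may carry precomputed pairwise similarity scores (columns query, subject,
    score); otherwise built-in shared-k-mer scores are used. Edges below
    ``min_score`` are ignored so that chance k-mer overlap between unrelated
    proteins cannot link clusters. Deterministic: all candidate lists are
    processed in lexicographic order.
    """
    if scores is None:
        scores = pairwise_scores(proteins, k)
    if len(scores):
        scores = scores[scores["score"] >= min_score]
    genome_of = {
        gid: genome for genome in proteins for gid in proteins[genome]
    }
    all_genes = sorted(genome_of)

    # best between-genome hit per (gene, other genome), and per gene overall
    best_hit: dict[tuple[str, str], tuple[int, str]] = {}
    best_between: dict[str, int] = {g: 0 for g in all_genes}
    within: list[tuple[str, str, int]] = []
    for rec in scores.itertuples(index=False):
        a, b, s = rec.query, rec.subject, int(rec.score)
        ga, gb = genome_of[a], genome_of[b]
        if ga == gb:
            if a != b:
                within.append((a, b, s))
            continue
        for x, gx, y in ((a, gb, b), (b, ga, a)):
            cur = best_hit.get((x, gx))
            # higher score wins; ties broken by lexicographic subject
            if cur is None or (-s, y) < (-cur[0], cur[1]):
                best_hit[(x, gx)] = (s, y)
            if s > best_between[x]:
                best_between[x] = s

    uf = _UnionFind(all_genes)
    for (x, gx), (s, y) in sorted(best_hit.items()):
        back = best_hit.get((y, genome_of[x]))
        if back is not None and back[1] == x:
            uf.union(x, y)
    for a, b, s in sorted(within):
        if s > max(best_between[a], best_between[b]):
            uf.union(a, b)

    components: dict[str, list[str]] = {}
    for g in all_genes:
        components.setdefault(uf.find(g), []).append(g)

    genomes = sorted(proteins)
    clusters: dict[str, dict[str, list[str]]] = {}
    rows = []
    for i, root in enumerate(sorted(components)):
        cid = f"C{i:05d}"
        members: dict[str, list[str]] = {}
        for g in components[root]:
            members.setdefault(genome_of[g], []).append(g)
        clusters[cid] = {gn: sorted(gs) for gn, gs in members.items()}
        rows.append([len(members.get(gn, [])) for gn in genomes])
    matrix = pd.DataFrame(rows, index=sorted(clusters), columns=genomes, dtype=int)
    result = OrthologClusterSet(clusters=clusters, phyletic_matrix=matrix)
    result.validate()
    return result


# ---------------------------------------------------------------------------
# Phyletic accounting
# ---------------------------------------------------------------------------


def core_and_single_copy(
    cluster_set: OrthologClusterSet, genomes: Sequence[str]
) -> tuple[set[str], set[str]]:
    """Core clusters (>=1 copy in every genome) and the single-copy subset."""
    if len(genomes) == 0:
        raise ValueError("empty genome list")
    m = cluster_set.phyletic_matrix[list(genomes)]
    core = set(m.index[(m >= 1).all(axis=1)])
    single = set(m.index[(m == 1).all(axis=1)])
    return core, single


def unique_per_genome(cluster_set: OrthologClusterSet) -> dict[str, int]:
    """Number of clusters found only in each genome (any copy number)."""
    m = cluster_set.phyletic_matrix
    present = m >= 1
    only_one = present.sum(axis=1) == 1
    counts = {g: int((present.loc[only_one, g]).sum()) for g in m.columns}
    return counts


def branch_unique_counts(
    tree: skbio.TreeNode, phyletic_matrix: pd.DataFrame
) -> list[BranchAnnotation]:
    """Per-branch uniquely-present and uniquely-absent cluster counts.

    For the branch above each non-root node with daughter leaf set D:
    uniquely present = clusters present (>=1 copy) in every genome of D and
    absent from all others; uniquely absent = the reverse. The root branch is
    excluded (its leaf set is not a proper subset).
    """
    tree_leaves = {t.name for t in tree.tips()}
    matrix_genomes = set(phyletic_matrix.columns)
    if tree_leaves != matrix_genomes:
        raise ValueError(
            "tree/matrix leaf mismatch: only in tree "
            f"{sorted(tree_leaves - matrix_genomes)}, only in matrix "
            f"{sorted(matrix_genomes - tree_leaves)}"
        )
    present = phyletic_matrix >= 1
    out: list[BranchAnnotation] = []
    for node in tree.preorder(include_self=False):
        leaf_set = frozenset(t.name for t in node.tips(include_self=True))
        others = sorted(tree_leaves - leaf_set)
        inside = sorted(leaf_set)
        uniquely_present = int(
            (present[inside].all(axis=1) & ~present[others].any(axis=1)).sum()
        )
        uniquely_absent = int(
            (~present[inside].any(axis=1) & present[others].all(axis=1)).sum()
        )
        out.append(
            BranchAnnotation(
                branch="+".join(inside),
                leaf_set=leaf_set,
                n_uniquely_present=uniquely_present,
                n_uniquely_absent=uniquely_absent,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Core-genome supermatrix and the NJ tree
# ---------------------------------------------------------------------------


def concatenate_core(
    families: Mapping[str, Mapping[str, str]], genomes: Sequence[str]
) -> dict[str, str]:
    """Concatenate per-family aligned sequences into one supermatrix.

    ``families`` maps family_id -> {genome_id: aligned sequence}; every family
    must cover every genome at one equal length (ragged families are an
    error naming the family). Families are concatenated in sorted id order.
    """
    if len(families) == 0:
        raise ValueError("no families to concatenate")
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    for fid in sorted(families):
        fam = families[fid]
        lengths = {len(s) for s in fam.values()}
        if len(lengths) != 1:
            raise ValueError(f"family {fid} is ragged: lengths {sorted(lengths)}")
        for g in genomes:
            if g not in fam:
                raise ValueError(f"family {fid} missing genome {g}")
            parts[g].append(fam[g])
    return {g: "".join(parts[g]) for g in genomes}


def _distance_matrix(chars: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float((chars[i] != chars[j]).mean())
            p = min(p, MAX_P_DISTANCE)
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(d, ids)


def _clades(tree: skbio.TreeNode) -> set[frozenset[str]]:
    out = set()
    for node in tree.non_tips(include_self=False):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def distance_tree(
    supermatrix: Mapping[str, str],
    outgroup: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> skbio.TreeNode:
    """Neighbor-joining tree from Poisson-corrected p-distances, rooted on
    the outgroup, with column-bootstrap support on internal nodes.

    ``p`` is the per-site mismatch fraction; the correction ``d = -ln(1-p)``
    is capped at ``p = 0.99``. Support values (percent of replicates whose
    rooted tree contains the same clade) are stored on internal nodes as
    ``node.support``; tips and the root carry none.
    """
    ids = sorted(supermatrix)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    if outgroup not in ids:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    lengths = {len(s) for s in supermatrix.values()}
    if len(lengths) != 1:
        raise ValueError("supermatrix rows differ in length")
    chars = np.array([np.frombuffer(supermatrix[g].encode(), dtype=np.uint8) for g in ids])

    dm = _distance_matrix(chars, ids)
    if np.allclose(dm.data, 0):
        warnings.warn("all sequences identical: star tree with zero branch lengths")
    main = nj(dm).root_by_outgroup([outgroup])

    rng = np.random.default_rng(seed)
    n_sites = chars.shape[1]
    clade_hits: dict[frozenset[str], int] = {c: 0 for c in _clades(main)}
    # pairwise mismatch profiles once; each replicate only re-averages columns
    n = len(ids)
    mism = {}
    for i in range(n):
        for j in range(i + 1, n):
            mism[(i, j)] = chars[i] != chars[j]
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_sites, n_sites)
        d = np.zeros((n, n))
        for (i, j), profile in mism.items():
            p = min(float(profile[idx].mean()), MAX_P_DISTANCE)
            d[i, j] = d[j, i] = -np.log(1.0 - p)
        rep = nj(DistanceMatrix(d, ids)).root_by_outgroup([outgroup])
        for clade in _clades(rep):
            if clade in clade_hits:
                clade_hits[clade] += 1
    for node in main.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        # skbio emits the support attribute as the internal node label
        node.support = 100.0 * clade_hits[clade] / n_bootstrap if n_bootstrap else None
    return main


def branch_table(annotations: Sequence[BranchAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "branch": a.branch,
                "n_uniquely_present": a.n_uniquely_present,
                "n_uniquely_absent": a.n_uniquely_absent,
            }
            for a in annotations
        ],
        columns=["branch", "n_uniquely_present", "n_uniquely_absent"],
    )
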