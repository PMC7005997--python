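"""Synthetic clade generator.

Simulates a small clade of annotated bacterial chromosomes with truth-labelled
horizontal gene transfer (HGT), lineage-specific insertion-sequence (IS)
proliferation and chromosomal inversions, plus indel-free protein families and
taxonomy-structured homology-hit tables. The generator exists so that every
downstream analysis (HGT screening, ANI, pangenome phyletics, GC landscape,
synteny) can be exercised end-to-end against known ground truth.

Model summary
-------------
* Vertical descent: Jukes–Cantor substitutions on DNA, Poisson-model
  substitutions on proteins, along a user-supplied rooted tree with branch
  lengths in substitutions/site. No indels, so ancestral coordinates remain
  valid at the leaves and family alignments are trivial.
* HGT: per-branch event counts are Poisson with mean
  ``hgt_rate * branch_length / tree_height``. Each event founds a new gene
  family, inserted as a contiguous low-GC segment (gene plus flanks drawn at
  ``donor_gc``) into one intergenic site shared by all descendant leaves.
  After acquisition the segment's composition relaxes toward the host:
  the GC gap closes by ``min(1, amelioration_rate * t)`` where ``t`` is the
  branch length accumulated since insertion.
* Mobilome and rearrangements: named lineages receive extra IS copies and
  inversions whose boundaries fall between genes; both are recorded in the
  truth tables for breakpoint tests.

All randomness flows from one ``numpy.random.Generator`` seeded from
``CladeConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
import yaml

from .seqio import GeneAnnotation, Genome, reverse_complement, write_fasta, write_gff3

# ---------------------------------------------------------------------------
# Alphabets and taxonomy pools
# ---------------------------------------------------------------------------

DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

#: (genus, order, phylum) pools for putative HGT donors, grouped the way the
#: donor summary reports them relative to a Synechococcales host.
DONOR_POOL: dict[str, list[tuple[str, str, str]]] = {
    "self_order": [
        ("Synechococcus", "Synechococcales", "Cyanobacteria"),
        ("Acaryochloris", "Synechococcales", "Cyanobacteria"),
    ],
    "other_cyanobacteria": [
        ("Anabaena", "Nostocales", "Cyanobacteria"),
        ("Chroococcidiopsis", "Chroococcidiopsidales", "Cyanobacteria"),
        ("Gloeobacter", "Gloeobacterales", "Cyanobacteria"),
    ],
    "proteobacteria": [
        ("Rhodopseudomonas", "Hyphomicrobiales", "Proteobacteria"),
        ("Thiobacillus", "Nitrosomonadales", "Proteobacteria"),
    ],
    "other": [
        ("Thermus", "Thermales", "Deinococcus-Thermus"),
        ("Bacillus", "Bacillales", "Firmicutes"),
        ("Chloroflexus", "Chloroflexales", "Chloroflexota"),
    ],
}

#: Mixture over DONOR_POOL groups used when sampling event donors; mirrors the
#: observed composition of recent-acquisition donors in thermophilic
#: cyanobacteria (self order ~42%, other cyanobacteria ~29%, Proteobacteria
#: ~17%, remainder mixed).
DONOR_MIX: dict[str, float] = {
    "self_order": 0.42,
    "other_cyanobacteria": 0.29,
    "proteobacteria": 0.17,
    "other": 0.12,
}

#: COG letters sampled for native families (None = no category assigned).
NATIVE_COG_POOL = [None, "J", "K", "L", "C", "E", "G", "H", "M", "P", "O", "T", "R", "S"]
NATIVE_COG_WEIGHTS = [0.25, 0.06, 0.06, 0.05, 0.07, 0.09, 0.07, 0.05, 0.07, 0.06, 0.05, 0.04, 0.04, 0.04]

#: COG letters for HGT families: mostly unassigned, then inorganic-ion
#: transport (P) and amino-acid transport (E) dominate among the assigned.
HGT_COG_POOL = [None, "P", "E", "M", "L", "G"]
HGT_COG_WEIGHTS = [0.72, 0.10, 0.07, 0.04, 0.04, 0.03]

DEFAULT_TREE = (
    "(((CL1:0.045,SCTE542:0.045):0.02,((BP1:0.008,NIES2134:0.008):0.015,"
    "NK55:0.03):0.015):0.05,SLIV:0.15)root;"
)

DEFAULT_TAXONOMY = {
    "CL1": ("Thermosynechococcus", "Synechococcales", "Cyanobacteria"),
    "SCTE542": ("Thermosynechococcus", "Synechococcales", "Cyanobacteria"),
    "BP1": ("Thermosynechococcus", "Synechococcales", "Cyanobacteria"),
    "NIES2134": ("Thermosynechococcus", "Synechococcales", "Cyanobacteria"),
    "NK55": ("Thermosynechococcus", "Synechococcales", "Cyanobacteria"),
    "SLIV": ("Synechococcus", "Synechococcales", "Cyanobacteria"),
}


class ConfigError(ValueError):
    """Raised when a CladeConfig violates its invariants."""


@dataclass
class CladeConfig:
    """Parameters of one simulated clade.

    Defaults emulate a six-strain thermophilic-cyanobacteria clade (one
    outgroup), scaled to a 300 kb chromosome: host GC 53.5%, donor GC twelve
    points lower, mobilome proliferation restricted to the BP1/NIES2134
    lineages, and a handful of inversions per rearranged lineage.
    """

    tree: str = DEFAULT_TREE
    outgroup: str = "SLIV"
    genome_length: int = 300_000
    n_gene_families: int = 250
    mean_gene_len: int = 900
    host_gc: float = 0.535
    donor_gc: float = 0.415
    hgt_rate: float = 40.0
    amelioration_rate: float = 2.0
    hgt_flank_len: int = 300
    is_element: tuple[int, dict[str, int]] = field(
        default_factory=lambda: (1200, {"BP1": 12, "NIES2134": 12})
    )
    n_inversions: dict[str, int] = field(
        default_factory=lambda: {"BP1": 2, "NIES2134": 2, "SCTE542": 1}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("host_gc", "donor_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.hgt_rate < 0:
            raise ConfigError(f"hgt_rate must be >= 0, got {self.hgt_rate}")
        if self.amelioration_rate < 0:
            raise ConfigError(
                f"amelioration_rate must be >= 0, got {self.amelioration_rate}"
            )
        if self.n_gene_families < 1:
            raise ConfigError(f"n_gene_families must be >= 1, got {self.n_gene_families}")
        if self.mean_gene_len < 30:
            raise ConfigError(f"mean_gene_len must be >= 30, got {self.mean_gene_len}")
        # worst-case family length is 1.3x the mean (see _draw_gene_lengths)
        if self.genome_length < int(1.3 * self.mean_gene_len) * self.n_gene_families:
            raise ConfigError(
                "genome_length too small to hold n_gene_families genes: "
                f"genome_length={self.genome_length}"
            )
        tree = parse_tree(self.tree)
        leaves = [t.name for t in tree.tips()]
        if len(leaves) < 2:
            raise ConfigError(f"tree must have >= 2 leaves, got {len(leaves)}")
        if len(set(leaves)) != len(leaves):
            raise ConfigError("tree has duplicate leaf names")
        if self.outgroup not in leaves:
            raise ConfigError(f"outgroup {self.outgroup!r} is not a tree leaf")
        _, copies = self.is_element
        for lineage in list(copies) + list(self.n_inversions):
            if lineage not in leaves:
                raise ConfigError(f"named lineage {lineage!r} is not a tree leaf")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CladeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "is_element" in raw:
            length, copies = raw["is_element"]
            raw["is_element"] = (int(length), dict(copies))
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = self.__dict__.copy()
        data["is_element"] = [self.is_element[0], dict(self.is_element[1])]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def parse_tree(newick: str) -> skbio.TreeNode:
    tree = skbio.TreeNode.read(io.StringIO(newick))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    tree.length = None
    return tree


def branch_label(node: skbio.TreeNode) -> str:
    """Stable branch id: the sorted '+'-joined leaf set below the branch."""
    return "+".join(sorted(t.name for t in node.tips(include_self=True)))


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth of a simulated clade.

    ``genes``: one row per annotated gene per genome with its HGT status
    (``native``/``hgt_recent``/``hgt_ancestral``), donor taxon and final
    coordinates.  ``events``: one row per HGT event.  ``inversions``: planted
    inversion intervals per genome (final coordinates).
    """

    genes: pd.DataFrame
    events: pd.DataFrame
    inversions: pd.DataFrame

    def validate(self) -> None:
        statuses = set(self.genes["status"])
        allowed = {"native", "hgt_recent", "hgt_ancestral"}
        if not statuses <= allowed:
            raise ValueError(f"unexpected statuses {statuses - allowed}")
        hgt = self.genes[self.genes["status"] != "native"]
        if hgt["event_id"].isna().any():
            raise ValueError("hgt gene without an event id")


@dataclass
class ProteinFamily:
    """An indel-free protein family: equal-length sequences across members."""

    family_id: str
    members: dict[str, tuple[str, str]]  # genome_id -> (gene_id, aa sequence)
    is_hgt: bool = False
    cog_category: str | None = None

    @property
    def length(self) -> int:
        return len(next(iter(self.members.values()))[1])


# ---------------------------------------------------------------------------
# Sequence-evolution primitives
# ---------------------------------------------------------------------------


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Random DNA codes (0=A,1=C,2=G,3=T) with expected GC fraction ``gc``."""
    is_gc = rng.random(n) < gc
    strong = rng.integers(0, 2, n)  # C or G
    weak = rng.integers(0, 2, n)  # A or T
    codes = np.where(is_gc, np.where(strong == 0, 1, 2), np.where(weak == 0, 0, 3))
    return codes.astype(np.uint8)


def _random_protein(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 20, n).astype(np.uint8)


def jc_mutate(codes: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor evolution for branch length t (substitutions/site)."""
    if t <= 0:
        return codes.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = codes.copy()
    mask = rng.random(codes.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def poisson_mutate(codes: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-model protein evolution: each site substitutes with
    probability 1 - exp(-t), to a uniformly chosen different residue."""
    if t <= 0:
        return codes.copy()
    p = 1.0 - np.exp(-t)
    out = codes.copy()
    mask = rng.random(codes.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 20, n).astype(np.uint8)) % 20
    return out


def _adjust_gc(codes: np.ndarray, target_gc: float, rng: np.random.Generator) -> np.ndarray:
    """Shift composition toward the target GC by flipping randomly chosen
    sites between weak (A/T) and strong (C/G) bases.

    The realised strong-base count is drawn binomially so adjusted segments
    keep the same sampling fluctuation as freshly generated DNA."""
    out = codes.copy()
    strong = (out == 1) | (out == 2)
    current = int(strong.sum())
    target = int(rng.binomial(out.size, target_gc))
    if target > current:
        weak_idx = np.flatnonzero(~strong)
        pick = rng.choice(weak_idx, size=target - current, replace=False)
        out[pick] = np.where(rng.integers(0, 2, pick.size) == 0, 1, 2)
    elif target < current:
        strong_idx = np.flatnonzero(strong)
        pick = rng.choice(strong_idx, size=current - target, replace=False)
        out[pick] = np.where(rng.integers(0, 2, pick.size) == 0, 0, 3)
    return out


def _dna_str(codes: np.ndarray) -> str:
    return DNA[codes].tobytes().decode()


def _aa_str(codes: np.ndarray) -> str:
    return AA[codes].tobytes().decode()


def gc_fraction(codes: np.ndarray) -> float:
    return float(((codes == 1) | (codes == 2)).mean())


# ---------------------------------------------------------------------------
# Clade simulation
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    """One piece of an assembling chromosome."""

    codes: np.ndarray
    kind: str  # "gap", "gene", "hgt", "is"
    gene_id: str | None = None
    strand: str = "+"
    feature_kind: str = "CDS"
    cog: str | None = None
    # hgt bookkeeping
    event_id: str | None = None
    status: str = "native"
    donor: tuple[str, str, str] | None = None
    gene_offset: int = 0  # offset of the annotated gene inside the segment
    gene_len: int = 0


def _draw_gene_lengths(cfg: CladeConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo = max(10, int(0.7 * cfg.mean_gene_len) // 3)
    hi = int(1.3 * cfg.mean_gene_len) // 3
    return (rng.integers(lo, hi + 1, n) * 3).astype(int)


def _sample_donor(rng: np.random.Generator) -> tuple[str, tuple[str, str, str]]:
    groups = list(DONOR_MIX)
    probs = np.array([DONOR_MIX[g] for g in groups])
    group = groups[int(rng.choice(len(groups), p=probs / probs.sum()))]
    pool = DONOR_POOL[group]
    return group, pool[int(rng.integers(len(pool)))]


def simulate_clade(
    config: CladeConfig,
) -> tuple[list[Genome], TruthTable, list[ProteinFamily]]:
    """Simulate one clade; see the module docstring for the model.

    Returns one :class:`~cladecompare.seqio.Genome` per tree leaf, the
    :class:`TruthTable`, and the list of :class:`ProteinFamily` (native
    families span all leaves; HGT families span the leaves below their
    insertion branch).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = parse_tree(config.tree)
    leaves = sorted(t.name for t in tree.tips())
    tree_height = max(
        sum(n.length for n in tip.ancestors() if n.length is not None) + tip.length
        for tip in tree.tips()
    )

    # --- ancestral layout: genes with random strands separated by gaps ----
    nfam = config.n_gene_families
    gene_lens = _draw_gene_lengths(config, rng, nfam)
    total_gap = config.genome_length - int(gene_lens.sum())
    # split intergenic DNA over nfam+1 gaps, minimum 2 bp so every boundary
    # between neighbouring genes exists as an insertion site
    gaps = np.full(nfam + 1, 2)
    extra = rng.multinomial(total_gap - 2 * (nfam + 1), np.full(nfam + 1, 1.0 / (nfam + 1)))
    gaps += extra
    strands = np.where(rng.random(nfam) < 0.5, "+", "-")
    family_cogs = [
        NATIVE_COG_POOL[int(rng.choice(len(NATIVE_COG_POOL), p=NATIVE_COG_WEIGHTS))]
        for _ in range(nfam)
    ]

    ancestor = _random_dna(config.genome_length, config.host_gc, rng)
    root_proteins = [_random_protein(gene_lens[f] // 3, rng) for f in range(nfam)]

    # ancestral coordinates of each element, as an ordered parts list
    boundaries: list[tuple[str, int, int, int]] = []  # (kind, index, start, end)
    pos = 0
    for f in range(nfam):
        boundaries.append(("gap", f, pos, pos + int(gaps[f])))
        pos += int(gaps[f])
        boundaries.append(("gene", f, pos, pos + int(gene_lens[f])))
        pos += int(gene_lens[f])
    boundaries.append(("gap", nfam, pos, pos + int(gaps[nfam])))

    # --- vertical descent + HGT event sampling (preorder traversal) -------
    node_seq: dict[int, np.ndarray] = {id(tree): ancestor}
    node_prot: dict[int, list[np.ndarray]] = {id(tree): root_proteins}
    # events as dicts; the segment DNA/protein evolve independently per leaf
    events: list[dict] = []
    node_events: dict[int, list[int]] = {id(tree): []}
    nodes_by_id: dict[int, skbio.TreeNode] = {}
    event_counter = 0

    for node in tree.preorder(include_self=False):
        nodes_by_id[id(node)] = node
        t = node.length
        parent = node.parent
        node_seq[id(node)] = jc_mutate(node_seq[id(parent)], t, rng)
        node_prot[id(node)] = [poisson_mutate(p, t, rng) for p in node_prot[id(parent)]]
        inherited = list(node_events[id(parent)])
        n_events = (
            int(rng.poisson(config.hgt_rate * t / tree_height))
            if t > 0 and tree_height > 0
            else 0
        )
        for _ in range(n_events):
            u = float(rng.uniform(0, t)) if t > 0 else 0.0
            glen = int(_draw_gene_lengths(config, rng, 1)[0])
            flank = config.hgt_flank_len
            seg = _random_dna(glen + 2 * flank, config.donor_gc, rng)
            group, donor = _sample_donor(rng)
            cog = HGT_COG_POOL[int(rng.choice(len(HGT_COG_POOL), p=HGT_COG_WEIGHTS))]
            events.append(
                {
                    "event_id": f"E{event_counter:03d}",
                    "branch": branch_label(node),
                    "on_terminal_branch": node.is_tip(),
                    "residual_branch_below": t - u,
                    "donor_group": group,
                    "donor_genus": donor[0],
                    "donor_order": donor[1],
                    "donor_phylum": donor[2],
                    "donor_gc": gc_fraction(seg),
                    "segment_codes": seg,
                    "protein": _random_protein(glen // 3, rng),
                    "gene_len": glen,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "cog": cog,
                    # insertion site: index into the ancestral gap list
                    "gap_index": int(rng.integers(0, nfam + 1)),
                    "node_id": id(node),
                }
            )
            inherited.append(event_counter)
            event_counter += 1
        node_events[id(node)] = inherited

    # distance from each event's origin point down to each leaf
    def _path_length(ancestor_node: skbio.TreeNode, tip: skbio.TreeNode) -> float:
        d = 0.0
        n = tip
        while n is not ancestor_node:
            d += n.length
            n = n.parent
        return d

    tips = {t.name: t for t in tree.tips()}

    # --- assemble each leaf chromosome -------------------------------------
    is_len, is_copies = config.is_element
    is_template = _random_dna(is_len, config.host_gc, rng)

    genomes: list[Genome] = []
    gene_rows: list[dict] = []
    inv_rows: list[dict] = []
    fam_members: dict[str, dict[str, tuple[str, str]]] = {
        f"F{f:04d}": {} for f in range(nfam)
    }
    hgt_fam_members: dict[str, dict[str, tuple[str, str]]] = {}

    for leaf_name in leaves:
        tip = tips[leaf_name]
        leaf_seq = node_seq[id(tip)]
        leaf_prot = node_prot[id(tip)]
        leaf_event_ids = node_events[id(tip)]
        # amelioration drifts toward the host's contemporary composition,
        # which substitution drift has pulled slightly off config.host_gc
        host_gc_now = gc_fraction(leaf_seq)

        segments: list[_Segment] = []
        for kind, idx, a, b in boundaries:
            if kind == "gap":
                segments.append(_Segment(leaf_seq[a:b].copy(), "gap"))
            else:
                gid = f"{leaf_name}_F{idx:04d}"
                segments.append(
                    _Segment(
                        leaf_seq[a:b].copy(),
                        "gene",
                        gene_id=gid,
                        strand=str(strands[idx]),
                        cog=family_cogs[idx],
                        gene_len=b - a,
                    )
                )
                fam_members[f"F{idx:04d}"][leaf_name] = (gid, _aa_str(leaf_prot[idx]))

        # HGT insertions: locate the target ancestral gap among current
        # segments; events insert after that gap segment (stable order)
        gap_positions = [i for i, s in enumerate(segments) if s.kind == "gap"]
        inserts: list[tuple[int, _Segment]] = []
        for ev_idx in leaf_event_ids:
            ev = events[ev_idx]
            node = nodes_by_id[ev["node_id"]]
            t_since = ev["residual_branch_below"] + (
                _path_length(node, tip) if node is not tip else 0.0
            )
            frac = min(1.0, config.amelioration_rate * t_since)
            target_gc = config.donor_gc + frac * (host_gc_now - config.donor_gc)
            seg = jc_mutate(ev["segment_codes"], t_since, rng)
            seg = _adjust_gc(seg, target_gc, rng)
            prot = poisson_mutate(ev["protein"], t_since, rng)
            status = "hgt_recent" if ev["on_terminal_branch"] else "hgt_ancestral"
            gid = f"{leaf_name}_{ev['event_id']}"
            flank = config.hgt_flank_len
            inserts.append(
                (
                    gap_positions[ev["gap_index"]],
                    _Segment(
                        seg,
                        "hgt",
                        gene_id=gid,
                        strand=ev["strand"],
                        cog=ev["cog"],
                        event_id=ev["event_id"],
                        status=status,
                        donor=(ev["donor_genus"], ev["donor_order"], ev["donor_phylum"]),
                        gene_offset=flank,
                        gene_len=ev["gene_len"],
                    ),
                )
            )
            fam_id = f"H_{ev['event_id']}"
            hgt_fam_members.setdefault(fam_id, {})[leaf_name] = (gid, _aa_str(prot))

        # IS copies for named lineages: uniform over gap segments
        n_is = is_copies.get(leaf_name, 0)
        for j in range(n_is):
            gpos = gap_positions[int(rng.integers(0, len(gap_positions)))]
            copy = jc_mutate(is_template, 0.002, rng)  # near-identical copies
            inserts.append(
                (
                    gpos,
                    _Segment(
                        copy,
                        "is",
                        gene_id=f"{leaf_name}_IS{j:03d}",
                        strand="+" if rng.random() < 0.5 else "-",
                        feature_kind="mobile_element",
                    ),
                )
            )

        # apply insertions after their gap segment, last-drawn first so that
        # earlier indices stay valid
        for at, seg in sorted(inserts, key=lambda x: -x[0]):
            segments.insert(at + 1, seg)

        # inversions: reverse-complement a run of whole segments
        n_inv = config.n_inversions.get(leaf_name, 0)
        inv_marks: list[tuple[int, int]] = []
        for _ in range(n_inv):
            i0 = int(rng.integers(1, len(segments) - 2))
            i1 = int(rng.integers(i0 + 1, min(i0 + 40, len(segments) - 1)))
            chunk = segments[i0 : i1 + 1]
            for s in chunk:
                s.codes = (3 - s.codes[::-1]).astype(np.uint8)  # revcomp in code space
                s.strand = "-" if s.strand == "+" else "+"
                s.gene_offset = len(s.codes) - s.gene_offset - s.gene_len
            segments[i0 : i1 + 1] = chunk[::-1]
            inv_marks.append((i0, i1))

        # concatenate and emit coordinates
        annotations: list[GeneAnnotation] = []
        pos = 0
        seg_starts: list[int] = []
        for s in segments:
            seg_starts.append(pos)
            if s.kind in ("gene", "hgt", "is"):
                if s.kind == "hgt":
                    g0 = pos + s.gene_offset
                    g1 = g0 + s.gene_len
                else:
                    g0, g1 = pos, pos + len(s.codes)
                annotations.append(
                    GeneAnnotation(
                        locus_tag=s.gene_id,
                        start=g0,
                        end=g1,
                        strand=s.strand,
                        feature_kind=s.feature_kind,
                        product="IS element" if s.kind == "is" else "hypothetical protein",
                        cog_category=s.cog,
                    )
                )
                if s.feature_kind == "CDS":
                    gene_rows.append(
                        {
                            "gene_id": s.gene_id,
                            "genome_id": leaf_name,
                            "status": s.status,
                            "event_id": s.event_id,
                            "donor_genus": s.donor[0] if s.donor else None,
                            "donor_order": s.donor[1] if s.donor else None,
                            "donor_phylum": s.donor[2] if s.donor else None,
                            "start": g0,
                            "end": g1,
                            "gc": gc_fraction(s.codes),
                        }
                    )
            pos += len(s.codes)
        seg_starts.append(pos)
        for i0, i1 in inv_marks:
            inv_rows.append(
                {
                    "genome_id": leaf_name,
                    "start": seg_starts[i0],
                    "end": seg_starts[i1 + 1],
                }
            )

        sequence = _dna_str(np.concatenate([s.codes for s in segments]))
        genomes.append(
            Genome(leaf_name, sequence, circular=True, annotations=annotations)
        )

    families = [
        ProteinFamily(fid, members, is_hgt=False, cog_category=family_cogs[int(fid[1:])])
        for fid, members in sorted(fam_members.items())
    ]
    families += [
        ProteinFamily(fid, members, is_hgt=True)
        for fid, members in sorted(hgt_fam_members.items())
    ]

    event_df = pd.DataFrame(
        [
            {k: v for k, v in ev.items() if k not in ("segment_codes", "protein", "node_id")}
            for ev in events
        ],
        columns=[
            "event_id",
            "branch",
            "on_terminal_branch",
            "residual_branch_below",
            "donor_group",
            "donor_genus",
            "donor_order",
            "donor_phylum",
            "donor_gc",
            "gene_len",
            "strand",
            "cog",
            "gap_index",
        ],
    )
    gene_df = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id",
            "genome_id",
            "status",
            "event_id",
            "donor_genus",
            "donor_order",
            "donor_phylum",
            "start",
            "end",
            "gc",
        ],
    )
    inv_df = pd.DataFrame(inv_rows, columns=["genome_id", "start", "end"])
    truth = TruthTable(genes=gene_df, events=event_df, inversions=inv_df)
    truth.validate()
    return genomes, truth, families


# ---------------------------------------------------------------------------
# Homology-hit table generation
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query_gene",
    "query_genome",
    "subject_id",
    "subject_genome",
    "subject_genus",
    "subject_order",
    "subject_phylum",
    "metagenomic",
    "percent_similarity",
    "percent_identity",
    "hsp_query_cov",
    "bitscore",
]


def simulate_hit_table(
    truth: TruthTable,
    taxonomy: dict[str, tuple[str, str, str]],
    self_genus: str,
    seed: int,
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a protein homology-hit table matching the truth labels.

    The table is constructed to be unambiguous for the screening classifier:
    native genes get self-genus best hits and a self-genus majority among the
    top five retained hits; recently acquired genes get the donor as the best
    hit and a non-self majority; anciently acquired genes get a non-self
    majority but a self-genus best hit. Each gene also receives a same-genome
    self hit (which the filter must drop) and low-coverage / low-similarity
    decoys below the retention thresholds.
    """
    rng = np.random.default_rng(seed)
    for gid in truth.genes["genome_id"].unique():
        if gid not in taxonomy:
            raise KeyError(f"genome {gid!r} missing from taxonomy")
    genes = truth.genes
    if genomes is not None:
        genes = genes[genes["genome_id"].isin(set(genomes))]

    other_self_genomes = [g for g, tax in taxonomy.items() if tax[0] == self_genus]
    if not other_self_genomes:
        raise ValueError(f"no genome in taxonomy has genus {self_genus!r}")
    non_self_pool = [d for pool in DONOR_POOL.values() for d in pool if d[0] != self_genus]
    self_order = taxonomy[other_self_genomes[0]][1]

    rows: list[dict] = []

    def add_hit(gene, genome, subject_genome, genus, order, phylum, bitscore, *,
                cov_ok=True, sim=None, metagenomic=False):
        cov = float(rng.uniform(0.905, 1.0)) if cov_ok else float(rng.uniform(0.30, 0.885))
        if sim is None:
            sim = float(rng.uniform(45.0, 98.0))
        rows.append(
            {
                "query_gene": gene,
                "query_genome": genome,
                "subject_id": f"{genus}_{rng.integers(1_000_000):07d}",
                "subject_genome": subject_genome,
                "subject_genus": genus,
                "subject_order": order,
                "subject_phylum": phylum,
                "metagenomic": metagenomic,
                "percent_similarity": round(sim, 1),
                "percent_identity": round(max(10.0, sim - float(rng.uniform(5, 15))), 1),
                "hsp_query_cov": round(cov, 3),
                "bitscore": round(bitscore, 1),
            }
        )

    for rec in genes.itertuples(index=False):
        gene, genome, status = rec.gene_id, rec.genome_id, rec.status
        genus, order, phylum = taxonomy[genome]
        base = float(rng.uniform(400, 900))
        scores = base - np.arange(5) * rng.uniform(10, 30)
        # similarity tracks rank, as in real searches: the retention
        # threshold then always truncates hit lists from the bottom
        sims = 92.0 - 9.0 * np.arange(5) + rng.uniform(-3, 3, 5)
        # a perfect self hit from the query's own genome: must be filtered out
        add_hit(gene, genome, genome, genus, order, phylum, base + 100, sim=98.0)

        if status == "native":
            pattern = ["self", "self", "other", "self", "other"]
        elif status == "hgt_recent":
            pattern = ["donor", "donor", "self", "donor", "self"]
        else:  # hgt_ancestral
            pattern = ["self", "donor", "donor", "self", "donor"]
        donor = (rec.donor_genus, rec.donor_order, rec.donor_phylum)
        for i, kind in enumerate(pattern):
            sim = float(min(97.0, max(45.0, sims[i])))
            if kind == "self":
                other_g = other_self_genomes[int(rng.integers(len(other_self_genomes)))]
                add_hit(gene, genome, f"db:{other_g}", self_genus, self_order,
                        taxonomy[other_g][2], scores[i], sim=sim)
            else:
                if status == "hgt_recent" or rng.random() < 0.7:
                    g, o, p = donor
                else:
                    g, o, p = non_self_pool[int(rng.integers(len(non_self_pool)))]
                add_hit(gene, genome, f"db:{g}", g, o, p, scores[i], sim=sim)
        # decoys: strong bitscore but failing one retention threshold each
        add_hit(gene, genome, "db:decoy", "Decoyvibrio", "Decoyales", "Decoyota",
                base + 50, cov_ok=False)
        add_hit(gene, genome, "db:decoy", "Decoyvibrio", "Decoyales", "Decoyota",
                base + 40, sim=float(rng.uniform(15.0, 39.0)))

    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------


def write_clade(
    outdir: str | Path,
    genomes: list[Genome],
    truth: TruthTable,
    families: list[ProteinFamily],
    config: CladeConfig,
) -> None:
    """Write FASTA + GFF3 per genome, the true tree, families and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_fasta(g, outdir / f"{g.genome_id}.fasta")
        write_gff3(g, outdir / f"{g.genome_id}.gff3")
    with open(outdir / "true_tree.nwk", "w") as fh:
        fh.write(config.tree.strip() + "\n")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    truth.inversions.to_csv(outdir / "truth_inversions.tsv", sep="\t", index=False)
    with open(outdir / "families.faa", "w") as fh:
        for fam in families:
            for genome_id, (gene_id, seq) in sorted(fam.members.items()):
                fh.write(f">{gene_id} family={fam.family_id} genome={genome_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    config.to_yaml(outdir / "clade_config.yaml")
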