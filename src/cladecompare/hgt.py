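"""HGT screening by taxonomic voting over protein homology hits.

The classifier consumes a ranked homology-hit table (BLAST outfmt-6-like TSV
extended with subject taxonomy). Per query gene:

1. hits from the query's own genome are removed;
2. hits are retained only when their high-scoring pairs cover at least 90% of
   the query length AND their amino-acid similarity is at least 40%
   (both thresholds inclusive), then re-ranked by descending bitscore
   (ties: subject_id lexicographic);
3. the gene is called *putatively acquired* when strictly more than half of
   the top five retained hits come from genera other than the self genus;
   among acquired genes, the call is *recent* when the single best hit is
   also non-self;
4. genes whose best hit lacks a genus assignment or comes from a metagenomic
   survey are flagged for manual examination rather than auto-called.

Summaries report the putative donors of recent acquisitions by taxonomic
group and the functional (COG letter) spectrum of any call subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .seqio import GeneAnnotation

DEFAULT_MIN_QUERY_COV = 0.90
DEFAULT_MIN_SIMILARITY = 40.0
DEFAULT_TOP_N = 5

STATUSES = ("native", "acquired_recent", "acquired_other", "ambiguous_taxonomy", "no_homologs")


@dataclass
class HGTCall:
    gene_id: str
    status: str
    n_retained_hits: int
    n_top5_other_genus: int
    best_hit_genus: Optional[str]
    donor_genus: Optional[str] = None
    donor_order: Optional[str] = None
    donor_phylum: Optional[str] = None


def filter_hits(
    hits: pd.DataFrame,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> pd.DataFrame:
    """Drop self-genome hits, apply the coverage and similarity retention
    thresholds (both inclusive), and re-rank per query by descending
    bitscore with lexicographic subject_id tie-break."""
    df = hits.copy()
    if "query_genome" in df.columns and "subject_genome" in df.columns:
        df = df[df["subject_genome"] != df["query_genome"]]
    df = df[
        (df["hsp_query_cov"] >= min_query_cov)
        & (df["percent_similarity"] >= min_similarity)
    ]
    df = df.sort_values(
        ["query_gene", "bitscore", "subject_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("query_gene").cumcount() + 1
    return df


def classify_gene(
    retained: pd.DataFrame,
    self_genus: str,
    top_n: int = DEFAULT_TOP_N,
) -> HGTCall:
    """Classify one gene from its retained, ranked hits.

    The vote runs over the top ``min(top_n, available)`` hits and requires a
    strict majority of non-self genera for an acquired call; with exactly
    half non-self the gene stays native.
    """
    if len(retained) == 0:
        raise ValueError("classify_gene requires at least the query_gene context")
    gene_id = retained.iloc[0]["query_gene"]
    hits = retained.sort_values("rank") if "rank" in retained.columns else retained
    if len(hits) == 0 or hits["bitscore"].isna().all():
        return HGTCall(gene_id, "no_homologs", 0, 0, None)
    top = hits.head(top_n)
    best = top.iloc[0]
    best_genus = best["subject_genus"]
    if pd.isna(best_genus) or best_genus is None or bool(best.get("metagenomic", False)):
        return HGTCall(
            gene_id,
            "ambiguous_taxonomy",
            len(hits),
            int((top["subject_genus"] != self_genus).sum()),
            None if pd.isna(best_genus) else str(best_genus),
        )
    n_other = int((top["subject_genus"] != self_genus).sum())
    if n_other > len(top) // 2:
        non_self = top[top["subject_genus"] != self_genus]
        donor = non_self.iloc[0]
        status = "acquired_recent" if best_genus != self_genus else "acquired_other"
        return HGTCall(
            gene_id,
            status,
            len(hits),
            n_other,
            str(best_genus),
            donor_genus=str(donor["subject_genus"]),
            donor_order=str(donor.get("subject_order")) if pd.notna(donor.get("subject_order")) else None,
            donor_phylum=str(donor.get("subject_phylum")) if pd.notna(donor.get("subject_phylum")) else None,
        )
    return HGTCall(gene_id, "native", len(hits), n_other, str(best_genus))


def screen_genes(
    hits: pd.DataFrame,
    self_genus: str,
    all_genes: Optional[Iterable[str]] = None,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    top_n: int = DEFAULT_TOP_N,
) -> pd.DataFrame:
    """Run the full screen and return one call row per gene.

    ``all_genes`` lists the gene universe; genes absent from the hit table
    after filtering are reported as ``no_homologs`` so that statuses
    partition the input genes.
    """
    retained = filter_hits(hits, min_query_cov, min_similarity)
    calls: list[HGTCall] = []
    for gene_id, group in retained.groupby("query_gene", sort=True):
        calls.append(classify_gene(group, self_genus, top_n))
    seen = {c.gene_id for c in calls}
    universe = set(all_genes) if all_genes is not None else set(hits["query_gene"])
    for gene_id in sorted(universe - seen):
        calls.append(HGTCall(gene_id, "no_homologs", 0, 0, None))
    df = pd.DataFrame([c.__dict__ for c in calls]).sort_values("gene_id").reset_index(drop=True)
    return df


def summarize_donors(
    calls: pd.DataFrame,
    self_order: str,
    self_phylum: str = "Cyanobacteria",
) -> pd.DataFrame:
    """Donor-group composition of recent acquisitions.

    Groups, relative to the host taxonomy: the self order; other members of
    the self phylum; Proteobacteria; everything else. Fractions are over
    calls with a non-missing donor and sum to 1 (or the frame is empty with
    a zero-count marker row when there are no recent calls).
    """
    recent = calls[calls["status"] == "acquired_recent"]
    groups = {self_order: 0, f"other {self_phylum}": 0, "Proteobacteria": 0, "other": 0}
    for rec in recent.itertuples(index=False):
        if rec.donor_order is None or pd.isna(rec.donor_order):
            continue
        if rec.donor_order == self_order:
            groups[self_order] += 1
        elif rec.donor_phylum == self_phylum:
            groups[f"other {self_phylum}"] += 1
        elif rec.donor_phylum == "Proteobacteria":
            groups["Proteobacteria"] += 1
        else:
            groups["other"] += 1
    total = sum(groups.values())
    rows = [
        {
            "donor_group": name,
            "count": count,
            "fraction": (count / total) if total else 0.0,
        }
        for name, count in groups.items()
    ]
    df = pd.DataFrame(rows, columns=["donor_group", "count", "fraction"])
    df.attrs["n_recent"] = len(recent)
    df.attrs["n_with_donor"] = total
    return df


def summarize_functions(
    calls: pd.DataFrame,
    annotations: Mapping[str, GeneAnnotation] | Iterable[GeneAnnotation],
    statuses: tuple[str, ...] = ("acquired_recent",),
) -> pd.DataFrame:
    """COG-letter spectrum of the selected calls.

    Multi-letter assignments (e.g. "EP") contribute one count to each letter;
    genes without an assignment land in the "unassigned" bucket. Totals are
    reported both per-letter and per-gene (``attrs``). A gene present in
    ``calls`` but missing from ``annotations`` is an error naming the gene.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.locus_tag: a for a in annotations}
    subset = calls[calls["status"].isin(statuses)]
    letter_counts: dict[str, int] = {}
    n_unassigned = 0
    for gene_id in subset["gene_id"]:
        if gene_id not in annotations:
            raise KeyError(f"gene {gene_id!r} missing from annotations")
        cog = annotations[gene_id].cog_category
        if not cog:
            n_unassigned += 1
            continue
        for letter in cog:
            letter_counts[letter] = letter_counts.get(letter, 0) + 1
    rows = [{"cog_category": k, "count": v} for k, v in sorted(letter_counts.items())]
    rows.append({"cog_category": "unassigned", "count": n_unassigned})
    df = pd.DataFrame(rows, columns=["cog_category", "count"])
    df.attrs["n_genes"] = len(subset)
    df.attrs["n_assigned_genes"] = len(subset) - n_unassigned
    return df
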