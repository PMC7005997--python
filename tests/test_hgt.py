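import numpy as np
import pandas as pd
import pytest

from cladecompare.hgt import (
    classify_gene,
    filter_hits,
    screen_genes,
    summarize_donors,
    summarize_functions,
)
from cladecompare.seqio import GeneAnnotation


def _hit(gene="g1", subject="s1", genus="Thermosynechococcus", order="Synechococcales",
         phylum="Cyanobacteria", cov=0.95, sim=60.0, bits=500.0, metagenomic=False,
         query_genome="CL1", subject_genome="db:x"):
    return {
        "query_gene": gene,
        "query_genome": query_genome,
        "subject_id": subject,
        "subject_genome": subject_genome,
        "subject_genus": genus,
        "subject_order": order,
        "subject_phylum": phylum,
        "metagenomic": metagenomic,
        "percent_similarity": sim,
        "percent_identity": sim - 10,
        "hsp_query_cov": cov,
        "bitscore": bits,
    }


def _table(rows):
    return pd.DataFrame(rows)


class TestFilterHits:
    def test_hit_meeting_both_thresholds_is_retained(self):
        out = filter_hits(_table([_hit(cov=0.95, sim=55)]))
        assert len(out) == 1

    def test_coverage_rule_is_strict_at_90_percent(self):
        out = filter_hits(_table([_hit(cov=0.89, sim=90)]))
        assert len(out) == 0

    def test_boundary_values_are_inclusive(self):
        out = filter_hits(_table([_hit(cov=0.90, sim=40.0)]))
        assert len(out) == 1

    def test_exact_retention_of_qualifying_rows(self):
        rows = [
            _hit(subject="s1", cov=0.95, sim=55),
            _hit(subject="s2", cov=0.95, sim=41),
            _hit(subject="s3", cov=0.91, sim=80),
            _hit(subject="s4", cov=0.89, sim=80),  # low coverage
            _hit(subject="s5", cov=0.95, sim=39),  # low similarity
            _hit(subject="s6", cov=0.50, sim=20),  # both low
        ]
        out = filter_hits(_table(rows))
        assert sorted(out["subject_id"]) == ["s1", "s2", "s3"]

    def test_self_genome_hits_removed_before_ranking(self):
        rows = [
            _hit(subject="self", subject_genome="CL1", bits=9999),
            _hit(subject="other", bits=100),
        ]
        out = filter_hits(_table(rows))
        assert list(out["subject_id"]) == ["other"]
        assert list(out["rank"]) == [1]

    def test_ranks_by_bitscore_with_lexicographic_ties(self):
        rows = [
            _hit(subject="zzz", bits=500),
            _hit(subject="aaa", bits=500),
            _hit(subject="mmm", bits=600),
        ]
        out = filter_hits(_table(rows))
        assert list(out["subject_id"]) == ["mmm", "aaa", "zzz"]


class TestClassifyGene:
    SELF = "Thermosynechococcus"

    def _retained(self, genera, metagenomic_first=False):
        rows = []
        for i, genus in enumerate(genera):
            rows.append(
                _hit(subject=f"s{i}", genus=genus, bits=1000 - i * 10,
                     metagenomic=metagenomic_first and i == 0)
            )
        return filter_hits(_table(rows))

    def test_majority_nonself_with_nonself_best_is_recent(self):
        call = classify_gene(self._retained(["Bacillus", "Bacillus", self.SELF,
                                             "Bacillus", self.SELF]), self.SELF)
        assert call.status == "acquired_recent"
        assert call.donor_genus == "Bacillus"

    def test_majority_nonself_with_self_best_is_acquired_other(self):
        call = classify_gene(self._retained([self.SELF, "Bacillus", "Bacillus",
                                             self.SELF, "Bacillus"]), self.SELF)
        assert call.status == "acquired_other"

    def test_exactly_half_nonself_of_four_is_native(self):
        call = classify_gene(self._retained([self.SELF, "Bacillus", "Bacillus",
                                             self.SELF]), self.SELF)
        assert call.status == "native"

    def test_exactly_two_nonself_of_five_is_native(self):
        call = classify_gene(self._retained(["Bacillus", self.SELF, self.SELF,
                                             "Bacillus", self.SELF]), self.SELF)
        assert call.status == "native"

    def test_metagenomic_best_hit_is_flagged_for_manual_examination(self):
        call = classify_gene(
            self._retained(["Bacillus"] * 5, metagenomic_first=True), self.SELF
        )
        assert call.status == "ambiguous_taxonomy"

    def test_missing_genus_on_best_hit_is_flagged(self):
        retained = self._retained(["Bacillus"] * 5)
        retained.loc[retained["rank"] == 1, "subject_genus"] = None
        call = classify_gene(retained, self.SELF)
        assert call.status == "ambiguous_taxonomy"

    def test_vote_only_covers_top_five_of_many(self):
        genera = ["Bacillus"] * 3 + [self.SELF] * 2 + ["Bacillus"] * 10
        call = classify_gene(self._retained(genera), self.SELF)
        assert call.n_top5_other_genus == 3
        assert call.status == "acquired_recent"


class TestScreenProperties:
    def test_statuses_partition_the_gene_universe(self, focal_hits, small_clade):
        genomes, truth, _ = small_clade
        cl1 = next(g for g in genomes if g.genome_id == "CL1")
        universe = [a.locus_tag for a in cl1.genes()]
        calls = screen_genes(focal_hits, "Thermosynechococcus", all_genes=universe)
        assert len(calls) == len(universe)
        assert calls["gene_id"].is_unique
        assert calls["status"].isin(
            ["native", "acquired_recent", "acquired_other",
             "ambiguous_taxonomy", "no_homologs"]
        ).all()

    def test_raising_similarity_threshold_never_raises_counts(self, focal_hits):
        prev_retained, prev_acquired = np.inf, np.inf
        for min_sim in (40, 60, 80, 95):
            retained = filter_hits(focal_hits, min_similarity=min_sim)
            calls = screen_genes(focal_hits, "Thermosynechococcus",
                                 min_similarity=min_sim)
            acquired = int(calls["status"].str.startswith("acquired").sum())
            assert len(retained) <= prev_retained
            assert acquired <= prev_acquired
            prev_retained, prev_acquired = len(retained), acquired

    def test_truth_labels_recovered_exactly(self, focal_hits, small_clade):
        _, truth, _ = small_clade
        calls = screen_genes(focal_hits, "Thermosynechococcus")
        expected = truth.genes[truth.genes.genome_id == "CL1"].set_index("gene_id")[
            "status"
        ].map({"native": "native", "hgt_recent": "acquired_recent",
               "hgt_ancestral": "acquired_other"})
        observed = calls.set_index("gene_id")["status"]
        joined = pd.DataFrame({"e": expected, "o": observed}).dropna()
        assert len(joined) == len(expected)
        assert (joined["e"] == joined["o"]).all()


class TestSummaries:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "status", "donor_genus", "donor_order", "donor_phylum"],
        )

    def test_all_proteobacterial_donors(self):
        rows = [
            [f"g{i}", "acquired_recent", "Thiobacillus", "Nitrosomonadales", "Proteobacteria"]
            for i in range(10)
        ]
        out = summarize_donors(self._calls(rows), self_order="Synechococcales")
        frac = out.set_index("donor_group")["fraction"]
        assert frac["Proteobacteria"] == 1.0
        assert frac.drop("Proteobacteria").sum() == 0.0

    def test_empty_input_reports_zero_counts(self):
        out = summarize_donors(self._calls([]), self_order="Synechococcales")
        assert (out["count"] == 0).all()
        assert out.attrs["n_recent"] == 0

    def test_simulated_donor_mix_recovered_exactly(self, focal_hits, small_clade):
        _, truth, _ = small_clade
        calls = screen_genes(focal_hits, "Thermosynechococcus")
        out = summarize_donors(calls, self_order="Synechococcales")
        recent_truth = truth.genes[
            (truth.genes.genome_id == "CL1") & (truth.genes.status == "hgt_recent")
        ]
        assert out.attrs["n_with_donor"] == len(recent_truth)
        expected_self_order = int((recent_truth["donor_order"] == "Synechococcales").sum())
        got = out.set_index("donor_group")["count"]
        assert got["Synechococcales"] == expected_self_order

    def test_per_letter_counting(self):
        calls = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "status": ["acquired_recent"] * 3}
        )
        ann = {
            "a": GeneAnnotation("a", 0, 3, "+", cog_category="P"),
            "b": GeneAnnotation("b", 3, 6, "+", cog_category="P"),
            "c": GeneAnnotation("c", 6, 9, "+", cog_category="E"),
        }
        out = summarize_functions(calls, ann).set_index("cog_category")["count"]
        assert out["P"] == 2 and out["E"] == 1 and out["unassigned"] == 0

    def test_multi_letter_assignment_counts_each_letter(self):
        calls = pd.DataFrame({"gene_id": ["a"], "status": ["acquired_recent"]})
        ann = {"a": GeneAnnotation("a", 0, 3, "+", cog_category="EP")}
        out = summarize_functions(calls, ann).set_index("cog_category")["count"]
        assert out["E"] == 1 and out["P"] == 1

    def test_missing_annotation_is_named(self):
        calls = pd.DataFrame({"gene_id": ["ghost"], "status": ["acquired_recent"]})
        with pytest.raises(KeyError, match="ghost"):
            summarize_functions(calls, {})
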