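# Methods

This note documents the models, algorithms, parameter choices and known
limitations of cladecompare, in the order the pipeline runs them.

## The clade simulator

The simulator is first-class, tested code: it defines the conditions under
which every downstream analysis is validated.

**Vertical descent.** A rooted tree with branch lengths in
substitutions/site drives evolution from a single ancestor. DNA evolves
under Jukes–Cantor (per-site change probability
`p = ¾(1 − e^(−4t/3))`, uniform among the other three bases); proteins
evolve under the Poisson model (`p = 1 − e^(−t)`, uniform among the other 19
residues). Both are the simplest models consistent with the distance
corrections used later. There are no indels, so ancestral coordinates stay
valid at the leaves and protein families are trivially "aligned" by
construction — multiple sequence alignment is deliberately out of scope.

**Genome organisation.** The ancestor carries `n_gene_families` genes
(lengths uniform in ±30% of `mean_gene_len`, multiples of 3) separated by
random intergenic gaps, at a host GC of 53.5% by default — the value typical
of *Thermosynechococcus* chromosomes. The default clade is six taxa
(five ingroup strains and an outgroup) with branch lengths chosen so that
the closest ingroup pair sits near 99% ANI, the focal pair near 90%, and
the outgroup below the ANI mapping floor, mirroring the divergence
structure of a real thermophilic-cyanobacteria clade at 300 kb scale
(defaults; tests and the acceptance script use 40–150 kb scaled versions of
the same structure, stated below).

**HGT.** Event counts per branch are Poisson with mean
`hgt_rate · branch_length / tree_height` (opportunity proportional to
branch length). Each event founds a new gene family and inserts a
contiguous island — gene plus `hgt_flank_len` donor flanks on each side —
drawn at `donor_gc` (default 41.5%, twelve points below host) into one
intergenic site shared by all descendant leaves. Donor taxa are sampled
from a pool mixing the host's own order (42%), other cyanobacterial orders
(29%), Proteobacteria (17%) and other phyla (12%); COG letters for HGT
families are 72% unassigned with P and E the most common assigned
categories. Events on terminal branches are labelled `hgt_recent`, others
`hgt_ancestral`.

**Amelioration.** No quantitative amelioration model exists in the
literature this emulates; we formalise it linearly: after time `t` since
insertion the island's GC gap to the host closes by
`min(1, amelioration_rate · t)`. Two details matter for unbiased
statistics. First, the target composition is the *contemporary* host
background — substitution drift pulls the background slightly off the
configured host GC, and targeting the configured value would make
ameliorated segments systematically GC-richer than their surroundings.
Second, the realised strong-base count is drawn binomially around the
target, so adjusted segments keep the same sampling fluctuation as freshly
generated DNA. Without either detail the rotation-null permutation test
(below) is measurably biased.

**Mobilome and rearrangements.** Named lineages receive near-identical
copies of one IS-like element (annotated `mobile_element`) and
whole-segment inversions whose boundaries fall between genes; inversion
intervals are recorded in the truth table for breakpoint tests.

**Hit tables.** `simulate_hit_table` emits a BLAST-outfmt-6-like table with
subject taxonomy, built to be unambiguous for the screening rule: native
genes get self-genus best hits and 2/5 non-self; recent acquisitions get
the donor as best hit and 3/5 non-self; ancestral acquisitions get 3/5
non-self under a self-genus best hit. Each gene also receives a same-genome
self hit (the filter must drop it) and decoys that fail exactly one
retention threshold. Similarity decreases strictly with hit rank, as in
real searches; this is what makes the retention threshold truncate hit
lists from the bottom and gives the classifier its threshold-monotonicity
property. Coverage and similarity of informative hits are drawn strictly
above the thresholds, decoys strictly below.

All randomness flows from a single seeded `numpy` generator; identical
configs produce byte-identical outputs.

**What the generator does not emulate.** Indels, codon structure and codon
bias, rate heterogeneity across sites or lineages, within-gene
recombination, gene loss (uniquely-absent branch counts are exercised with
constructed matrices instead), compositional strand asymmetry
(replication-driven GC skew), and database-scale taxon-sampling biases in
hit tables. Passing tests therefore demonstrate correctness of the
*computations* under a clean generative model, not robustness to every
artefact of real annotation pipelines and databases.

## HGT screening

Retention requires HSP coverage ≥ 0.90 of the query length and similarity
≥ 40% (both inclusive). Coverage is understood as the union of HSP query
spans over the query length. "Similarity" is the positives percentage,
distinct from identity; both columns are carried. Self-genome hits are
removed before ranking (otherwise every gene's best hit is itself); ranks
are by descending bitscore with lexicographic subject-id tie-break —
the tie-break is arbitrary but fixed for determinism.

The vote runs over the top `min(5, available)` hits and requires a strict
majority of non-self genera; exactly half is never acquired. With fewer
than five retained hits the same strict-majority rule applies to what is
available. Genes whose best hit lacks genus-level taxonomy or is
metagenomic are flagged `ambiguous_taxonomy` and never auto-resolved.
Function summaries count multi-letter COG assignments once per letter and
report per-gene totals alongside; both the all-genes and the
excluding-pseudogenes denominators can be formed by the caller, since the
gene universe is an explicit argument.

## ANI

Defaults follow the fragment-mapping ANI tools in common use: fragment
length 3000, k = 16, minimum identity 80, species cutoff 95 — all
configurable. Placement votes over match diagonals: every shared canonical
k-mer occurrence pair proposes the window start it implies on either
strand; the modal proposal wins (ties: forward strand, then smaller
coordinate). Identity is the Mash estimate from the Jaccard index of the
fragment's k-mer set against the voted window's. Fragments with > 10% N are
skipped and N-containing k-mers always dropped. The reciprocal-consistency
filter (each reference window granted to at most one fragment, preferring
higher Jaccard then lower query coordinate) stands in for orthologous-pair
filtering and fixes determinism.

The estimator is asymmetric by construction; on similar-length simulated
pairs the asymmetry stays within 0.5 points (asserted in tests). The Mash
relation slightly underestimates identity at high divergence and the
per-fragment Jaccard is noisy near the 80% floor, so values are matched to
published ones within tolerance, never bit-exactly.

## Pangenome phyletics and the core tree

Protein similarity is the count of shared amino-acid 4-mers; edges below 10
shared 4-mers are ignored (chance overlap between unrelated ~300-residue
proteins is ~1, true homologs at the divergences simulated share dozens).
Cross-genome reciprocal best hits plus within-genome pairs scoring above
both members' best between-genome scores (recent paralogs) form a graph
whose connected components are clusters — a deterministic stand-in for
Markov-clustering ortholog tools; real-data cluster counts will differ
from any published OrthoMCL run.

Core = present in every genome; single-copy core = exactly one copy
everywhere. Branch-wise counts: for the branch above each non-root node
with daughter leaf set D, uniquely-present counts clusters present in all
of D and absent elsewhere, uniquely-absent the reverse; the root is
excluded since its leaf set is not a proper subset.

The supermatrix concatenates single-copy-core family sequences (equal
lengths guaranteed by the simulator; real data must arrive pre-aligned).
Distances are Poisson-corrected p-distances, `d = −ln(1 − p)` with `p`
capped at 0.99 to keep the correction finite. Neighbor joining is delegated
to scikit-bio; rooting uses the named outgroup. Bootstrap resamples
alignment columns, rebuilds the tree per replicate, and reports for each
internal node the percentage of replicates containing the same rooted
clade. An all-identical supermatrix triggers a star-tree warning.

## GC landscape

Windows default to 10 kb non-overlapping; N bases leave both numerator and
denominator. The cumulative skew series carries a leading zero so its
extrema are window-boundary coordinates with ties resolved to the smallest
coordinate. Low-GC windows sit below mean − 1 SD of the per-window GC
(threshold in SD units configurable; no published threshold exists for the
observation this formalises).

The association test: observed statistic = fraction of recent-HGT gene
midpoints inside low-GC windows; null = one uniform circular rotation of
all gene coordinates per permutation, preserving gene spacing (HGT arrives
in islands, so spacing structure must survive the null); p-value uses the
add-one estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`, which never returns
zero. An independent-uniform shuffle null is available behind a flag for
comparison. With zero recent genes or zero low-GC windows the test is
reported undefined rather than forced.

**Resolution guidance.** The test has power only when an inserted island
can dominate the window holding its midpoint: the island (gene + flanks)
should span at least two windows, which guarantees the midpoint's window
lies fully inside the island. The calibration and power checks use 1 kb
windows against ~2.4 kb islands on 150 kb genomes with ~15 recent genes
(enough genes that the permutation statistic is not overly discrete);
measured this way the null rejection rate at 0.05 falls within its
binomial 3-SE band and p ≤ 0.01 power under a 0.12 GC offset without
amelioration exceeds 95%. The permutation statistic is discrete, so the
test is mildly conservative — expected for permutation tests on small
count statistics.

## Synteny

Anchors are all maximal exact matches of length ≥ 20 on both strands,
uniqueness not required ("maxmatch" semantics). The finder seeds on exact
`min_match_len`-mers and extends only left-maximal seed pairs, so each
maximal match is found exactly once; the contract is the maximal-match set
itself, which tests verify against a brute-force all-diagonals oracle and
by independent substring re-verification. Chaining is greedy over anchors
in query order: same orientation, query and reference gaps within 500 bp,
reference coordinates advancing in the block's direction (so members never
cross); blocks under 200 anchored bp are dropped, matching common
nucleotide-MUMmer settings. Breakpoints are boundaries between adjacent
retained blocks on the query, flagged as inversions on orientation flips.
The mobilome test marks a ±2 kb margin around each mobilome feature and
uses the same rotation null and add-one estimator as the landscape test.

## Pipeline

One YAML config drives either the simulator or real input paths (exactly
one must be set). Every stage writes plain-text outputs; the manifest
records the materialized config (every default made explicit), a config
hash, the seed, component versions, per-stage status and headline results,
and deliberately contains no timestamps so reruns are byte-identical. A
stage failure halts the run with the stage named and leaves a FAILED
marker beside the partial outputs. Exit codes: 0 ok, 1 bad config, 2 stage
failure.

## Problem sizes

Unit tests simulate 30–60 kb genomes with 20–50 families; the acceptance
surface uses 150 kb genomes with 80 families, 200 bootstrap replicates,
1000 permutations (199 for the 200-replicate calibration), 50 random
≤ 2 kb sequence pairs for the anchor oracle, and 100 random phyletic
matrices for branch-count enumeration. The published-value ANI checks run
on the deposited ~2.6 Mb chromosomes when those FASTA files are present
under `data/accessions/`.

## Known limitations

- RBH-component clustering has no inflation parameter and will split
  families whose within-family divergence approaches between-family chance
  similarity; adequate at simulator scales, cruder than Markov clustering
  on real proteomes.
- NJ on Poisson-corrected distances replaces maximum-likelihood inference;
  topology recovery is the claim, branch-length and model-fit fidelity are
  not.
- The ANI estimator reports identity via a k-mer sketch relation, not
  alignment; expect small negative bias past ~10% divergence and no values
  at all below the mapping floor.
- The exact-match anchor finder is O(total match length) per seed but
  quadratic in copy number for large repeat families.
- The permutation tests assume a circular replicon for the rotation null;
  linear contigs fall back to rotation over the full length, which is only
  approximate near the ends.
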