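# Methods

This note documents the models, parameter choices and numerical decisions
behind `panstrep`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Gene-pool accretion and the BCR rule

The pan-genome is built by an order-dependent accretion algorithm rather
than by all-versus-all clustering. The pool is initialised with all
reference-strain genes as singleton clusters; each subsequent strain's
genes are searched against the pool in input order. Homology between a
query gene and a pool gene is decided from a Smith–Waterman local alignment
(biopython's `PairwiseAligner`) by three cutoffs:

| parameter | default | meaning |
|---|---|---|
| `bcr_min` | 0.5 | coverage "setting value"; a pair is rejected only when **both** the query coverage and the subject coverage fall below it |
| `identity_min` | 70 (nucleotide) / 50 (protein) % | percent identity over aligned columns, gap columns excluded (the BLAST convention) |
| `min_len` | 30 residues | minimum aligned length on the query |

The asymmetric rejection rule (both coverages must fail) means a short gene
fully contained in a longer pool gene still counts as homologous — one-way
coverage suffices. These cutoffs are deliberate conventions, not derived
quantities: absolute cluster counts move with them (shown by a dedicated
test), so cross-study comparisons must hold them fixed. Every result object
echoes the thresholds used.

Cluster representatives are the founding genes; joining a cluster does not
change its representative, so the pool only ever grows, and the search cost
is linear in pool size. Searching all members instead of founders only is
available as `search_all_members=True`; on well-separated families the two
agree (tested against a brute-force single-linkage oracle over the full
pairwise homology graph). Ties on alignment score are broken by the
lexicographically smallest subject gene id, making output deterministic.

Scoring defaults: nucleotide match/mismatch +2/−3 with affine gap cost
5 + 2·L; protein BLOSUM62 with gap cost 11 + 1·L. A gap of length L costs
`gap_open + L*gap_extend`.

**k-mer prefilter.** Pairs sharing fewer than `max(3, min(L)/200)` k-mers
(k = 11 nucleotide, 4 protein) are skipped without alignment. The threshold
scales with length because at kilobase gene lengths unrelated nucleotide
pairs already share a couple of 11-mers by chance, while homologs at the
70% identity cutoff share about 2% of their 11-mers (0.7^11 per position) —
two orders of magnitude above the threshold. Identical sequences bypass the
quadratic DP entirely (the full-length gapless alignment is optimal
whenever diagonal scores are positive). A prefilter-on versus prefilter-off
comparison on divergent simulations is part of the test suite.

## Partition and flower-plot counts

Clusters are partitioned by presence-set size: core = all strains,
specific = exactly one, dispensable = in between. Counts are of clusters,
not genes; intra-strain paralogs that match a pool gene join its cluster
and inflate member counts only. With a single strain every cluster is
reported as strain-specific (core is defined only for ≥ 2 strains).
Reference-strain paralogs are an edge case: because all reference genes
seed the pool as singletons, duplicated reference genes found separate
clusters — family recovery on paralog-bearing simulations is therefore
stated at cluster level for query strains.

## Rarefaction and convergence models

For each sampled strain ordering and each prefix length n, pan(n) counts
clusters whose presence set intersects the first n strains and core(n)
counts clusters containing all of them. All N! orderings are enumerated
when the requested permutation count covers them; otherwise permutations
are drawn uniformly with a seeded generator (default `n_perm = 200`, enough
for stable medians below N = 9 while staying cheap). Presence sets are
encoded as bitmasks so a curve over hundreds of permutations costs
milliseconds.

Per-n **medians** are fitted (robust to ordering outliers; configurable in
principle but medians are the only fitted statistic exposed):

* core: C(n) = A·e^(−n/τ) + Ω by bounded nonlinear least squares
  (`scipy.optimize.curve_fit`, A ≥ 0, τ > 0, Ω ≥ 0). τ is additionally
  capped at the largest strain count: on nearly flat noisy curves the
  unconstrained global optimum degenerates to τ → ∞ with Ω → 0 (the
  exponential impersonates the constant), and a decay constant beyond the
  observed range carries no information anyway. Optimizer failure returns
  `converged=False` with the initial-guess parameters rather than raising.
* pan: P(n) = K·n^γ by linear regression in log–log space. The pan-genome
  is classified *open* when γ > 0 and γ − 1.96·SE(γ) > 0, *closed*
  otherwise (a perfectly constant curve gives γ = 0 exactly and is closed).

Both functional forms are reimplementation choices recorded in the fit
output metadata; the exponential-decay form for the core follows the
standard convergence analysis of pan-genome studies, and the power law is
the usual Heaps-law description of pan growth. Fits require at least three
distinct n values.

## ANI

ANIb-style conventions: 1,020-bp consecutive non-overlapping fragments
(trailing remainder kept if ≥ 100 bp), 30% identity and 70% fragment
coverage filters, reciprocal averaging of the two directions. All are
config fields echoed in the output.

Fragment placement uses banded edit-distance infix alignment (edlib, `HW`
mode) rather than quadratic local alignment: the fragment is consumed end
to end, the genome contributes a free-ended window, and both strands are
tried (fragment and reverse complement, best edit distance wins). Fragment
identity is **edit-based**, 100·(L − d)/L for edit distance d: each edit
operation destroys at most one matching position, so this equals per-site
identity exactly under substitution-only divergence and avoids the path
ambiguity between two substitutions and a paired insertion/deletion that
biases path-counted identity. Coverage is the fraction of fragment residues
aligned to genome bases (gap-free columns / L). Consequences to be aware
of: under infix alignment a fragment is always fully consumed, so the
coverage filter bites mainly through the identity cutoff; and because the
aligner will place even an unrelated fragment somewhere, ANI between
genuinely unrelated genomes is governed by the identity filter, not by a
significance test (there is no E-value machinery).

A pair direction with no passing fragments reports an undefined (None) ANI
and a zero used-fragment count, never an exception; the reciprocal mean
averages the defined directions.

## Presence/absence and ANI trees

Strain profiles are compared by Jaccard distance d = 1 − |F_i ∩ F_j| /
|F_i ∪ F_j| over cluster presence sets (scipy `pdist`); ANI matrices are
converted by d = (100 − ANI)/100. Trees are built with classical neighbor
joining (scikit-bio) and emitted unrooted as Newick; midpoint rooting is an
output option. Negative NJ branch lengths — possible on non-additive input
— are clamped to zero and flagged on the tree object. On additive matrices
NJ reproduces the generating tree's path lengths exactly, which the tests
exploit as an oracle. A two-taxon matrix resolves to a single edge split
evenly.

This distance pipeline is a deliberately transparent surrogate for
likelihood-based gene-content phylogenies; it claims topology-level
comparability only.

## Genome feature statistics

GC content is (G+C)/(A+C+G+T), case-insensitive, with ambiguity codes
excluded from the denominator (the conservative common convention; an
all-ambiguous or empty sequence is an error, not zero). Gene and repeat
intervals are 1-based closed (GFF3). Overlapping gene intervals are merged
before length accounting so gene + intergenic lengths partition the genome
exactly; the gene *count* remains the number of annotated genes, so the
average gene length is union-length / count. Percentages are rounded to two
decimals (the repeat fraction to four, matching the extra precision genome
tables give that small number). Repeat intervals are consumed from
annotation input and never detected. With zero genes the average gene
length is reported as absent, not zero.

## The simulator: what it does and does not emulate

`simulate_pangenome` draws each gene family's ancestor uniformly over the
alphabet (length uniform on `gene_length_range`, default 150–3,000 bp,
bracketing a typical bacterial average CDS around 900 bp) and derives every
member by i.i.d. per-site substitutions at rate *d*, giving the closed-form
expected pairwise identity (1−d)² + d²/(a−1) for alphabet size a — the
calibration target used throughout the tests. Family structure (core
count, dispensable subsets, per-strain specific counts, paralog rate) is
exact by construction and recorded in a truth table. Optional whole-genome
FASTA output concatenates genes with random spacers and emits matching
GFF3; an optional GC bias knob shapes spacer composition only.

Not emulated: rearrangement, horizontal transfer, codon structure,
compositional (GC) bias within genes, length-dependent divergence, and
realistic intergenic architecture. Passing the ground-truth recovery tests
therefore demonstrates that the accretion algorithm and its thresholds
behave correctly on cleanly separated families at controlled divergence —
not that any particular threshold setting is right for a given real genus,
where domain shuffling, partial genes and annotation noise dominate the
hard cases.

Default simulated study shape: 9 strains, 50 core families, 20 dispensable
(in subsets of 2–8 strains), 5 specific per strain. These desk-scale sizes
keep a full 9-strain accretion run in the tens of seconds while exercising
every partition class; they are the sizes used by the acceptance script.

## Determinism

Every stochastic component (simulator, mutation, permutation sampling,
noise replicates) takes an explicit integer seed and uses
`numpy.random.default_rng`; identical config + seed reproduces outputs
byte-for-byte, which the pipeline tests assert via file comparison. The
pipeline writes stage outputs to a temporary area and promotes them
atomically, and the manifest records a SHA-256 over config + seed.

## Known limitations

* Accretion is order-dependent in principle; order-invariance is verified
  only on well-separated simulated families. Real borderline homologs can
  land differently under different strain orders (the order is recorded in
  the result for exactly this reason).
* Identity from a single best-scoring local alignment; no multi-HSP
  tiling, no E-values, no composition adjustment.
* ANIb only — no MUMmer-based ANIm, no tetranucleotide signatures.
* The exponential/power-law curve models are descriptive fits, not
  mechanistic population-genetic models; Ω from a short strain series is a
  fit parameter, not an estimate with guarantees.
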