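# Methods

## Modal consensus and conservation scoring

The consensus of an ortholog alignment is computed per column as the
most frequent symbol with gaps counted as a symbol. Columns whose modal
symbol is the gap are removed before any scoring; the retained-column
index list is kept so results can be mapped back to original
coordinates. Tie-break: any non-gap symbol beats the gap, and among
non-gap symbols the lexicographically smallest one-letter code wins.
The preference for residues over gaps is deliberate — a tie resolved
towards the gap would discard a column that half the sequences support —
and the lexicographic rule exists only to make the output deterministic;
no biological meaning is attached to it.

Conservation of a sequence over a domain is `matched / total`, where
`total` counts the domain's columns that survived gap-modal removal and
`matched` counts those whose residue equals the modal amino acid. Three
scoring rules follow from treating the consensus track as a strict
match/mismatch barcode: a gap in the scored row never matches; an
ambiguity code (`X`) never matches, even against a modal `X`; a column
whose modal symbol is not one of the 20 amino acids can never score.
A domain entirely removed by column filtering is reported as undefined
(`NaN` with `total = 0`), never silently as zero, and the pre-filter
column count is reported alongside for transparency.

Reference coordinates are 1-based inclusive residue indices on the
ungapped reference row (the human ortholog by convention); alignment
columns are 0-based internally. Domain defaults: HAT1 7–19, NLS 78–90,
HAT2 98–108, whole pro-domain 1–112, KKRR core 82–85.

Group summaries (mean, median, quartiles, n) are computed over all
isoform sequences by default; a per-species collapse (longest isoform,
ties by identifier) is available because published alignments often mix
isoform counts per species and neither convention is canonical.

## Motif classification

Classification of the 4-residue core against `KKRR` is total over the
21-symbol alphabet plus gap: `X` anywhere → *unknown*; exact match →
*intact*; all substitutions within {K, R} → *conservative* (basic
character, and hence plausibly import function, retained); anything
else, including a gap, → *loss*. Species status is the unanimous class
across isoforms; disagreement yields *mixed* rather than a majority
call, because an isoform discrepancy in real data usually signals an
annotation problem that deserves review, not averaging.

The NLS propensity score is a deliberately simple proxy: the maximum
over sliding windows (lengths 8–13) of the window's basic-residue
density (#K + #R divided by window length). It is translation invariant
and strictly decreases when a basic residue in a unique best window is
replaced by a non-basic one, which is all the pipeline relies on — the
direction of predictions (KKRR > KKRW/KNRW variants). It is **not** a
re-implementation of any external NLS prediction service, and its
absolute values are not comparable to such scores.

## Read voting

Reads are aligned to the exon query with an affine-gap local aligner
(Biopython's `PairwiseAligner` under the package's scoring surface);
both strands are tried and the better orientation kept, ties to the
forward strand. The scoring scheme is blastn-like — match +2, mismatch
−3, and a gap of length k costs 5 + 2k — and scores are *in this
scheme*; raw scores of other aligners are not comparable, so the score
cut-off (default > 80, strict) is configurable. The default cut-off and
the top-100 cap mirror the published read-analysis procedure. A
brute-force Gotoh dynamic-programming oracle in the test suite verifies
optimal scores exactly on random instances.

Votes are tallied per query position of the motif interval from the
query-projected base calls of the kept hits: aligned read bases count as
themselves, read deletions count as gaps, read insertions do not map to
query positions and are dropped (the analysis is pairwise
query-projected; no multiple sequence alignment is built). `N` bases
count towards coverage but never match the reference. Percent match is
`100 × (reference-base count) / coverage`, undefined at zero coverage.
The consensus takes the majority base per position, resolving ties to
the reference base (flagged), and translates whole codons with the
standard genetic code; uncovered positions become `N`/`X`.

## LFQ enrichment

Pipeline order is fixed: row filters → log2 → validity filter →
imputation → (PCA, moderated test). MaxQuant conventions are honoured on
input: intensities come from `LFQ intensity <sample>` columns, zero
means missing, and `+`-coded flags mark contaminants, reverse (decoy)
hits and only-by-site identifications. The validity rule keeps a row
when at least one experimental group has a valid value in *all* its
replicates (generalisable via `min_valid`).

Imputation draws each missing entry of a sample column from
`N(mean − 1.8·SD, (0.3·SD)²)` using that column's observed mean and SD —
the de-facto default width/downshift for left-censored LFQ missingness,
exposed in `EnrichConfig` and recorded in the run summary. Imputation is
per column rather than over the whole matrix; both modes exist in the
wild and the per-column variant respects sample-to-sample depth
differences.

The moderated statistic is `d = (x̄_target − x̄_control)/(se + s0)` with
`se` the pooled-variance two-sample standard error; at `s0 = 0` it *is*
the classical equal-variance t statistic (asserted to machine precision
in the tests). `s0` (default 2) damps large `d` at tiny variances.
Significance uses a symmetric cut on |d| calibrated by balanced
group-label permutations: for 4-vs-4 designs all 35 complement-distinct
labelings are enumerated and the identity labelling is excluded (it
reproduces the observed statistics, not a null draw), leaving B = 34;
larger designs are subsampled to `max_permutations` with the run seed.
π₀ is estimated as the fraction of observed d inside the permutation
interquartile range divided by 0.5, capped at 1. The expected false
positives at a cut c use a pseudocount-corrected mean,
`FP(c) = (1 + Σ_b #{|d*_b| ≥ c}) / (B + 1)`: with only 34 permutations a
tail estimate of exactly zero is below the resolution the permutation
count can certify, and the add-one floor is what keeps the realised
false-discovery proportion at the nominal level on null data (verified
over 100 seeded null matrices in the tests). The smallest cut with
`π₀ · FP(c) / #{|d| ≥ c} ≤ FDR` is chosen; if none qualifies, nothing is
called. The volcano export's p-values are classical two-tailed Student
p-values on the unmoderated t; the significance flag comes from the
permutation threshold, not from p.

PCA is computed on samples over centred protein features
(scikit-learn, full SVD); coordinates are deterministic up to sign.

## Synthetic data

`simulate_family` evolves a 112-residue ancestral pro-domain (random
residues, with the human NLS tridecapeptide planted at 78–90) down a
species tree. On a branch of length t each site substitutes with
probability `1 − (1 − p)^t` (uniform choice among the 19 other
residues), so over a unit-length root-to-tip path the mismatch
probability against the ancestor is p exactly, up to a back-mutation
term of order p²/19. Per-domain defaults: background 0.2, HAT domains
0.02, NLS flanks 0.05. The four KKRR core columns never mutate at
random: in the real data the core is under strong purifying selection
except in the knockout lineages, and protecting it keeps the generator's
truth table exact for knockout-recovery tests. Knockout clades instead
have the configured replacement motif written into their tips (nested
clades override outer ones, e.g. kangaroo rats' KKRL inside
castorimorpha's KKRW). Two built-in trees: `fixture_tree()` mirrors the
study clades (castorimorpha, toothed/baleen whales, marsupials,
monotremes) with realistic shared branches; `balanced_tree(n)` is a star
of unit-length independent branches whose clade nodes have zero length,
the configuration under which domain conservation recovers `1 − p`
within binomial error (shared branches would shift the modal residue at
clade-shared substitutions and bias conservation upward — a real
phenomenon, but one that breaks the clean parameter-recovery reading).
An optional per-tip indel (default off) writes a short deletion outside
the annotated domains.

`simulate_reads` samples fixed-length reads uniformly over the
variant-applied exon (a deterministic 240-nt synthetic sequence carrying
the human motif codons at positions 100–111), injects per-base errors
(uniform over the three other bases) and reverse-complements a
configured fraction. Defaults — 200 reads of 100 nt, 1% error, half
reverse — give roughly 50–70× coverage of the motif, comparable to a
capped read set from an archive search.

`simulate_lfq` draws per-protein baselines uniformly on log2 ∈ [24, 32],
adds within-group noise (SD 0.5), shifts the enriched proteins (default
50 of 1000 by 4 log2 units — the order of separation seen between a
bait's true interactors and background in streptavidin enrichments) in
the target group, and deletes values with a logistic
intensity-dependent probability (midpoint log2 = 23, scale 1), i.e.
missing-not-at-random, left-censored, exactly the regime the
downshifted-normal imputation assumes. Contaminant/reverse rows (2%
each) are appended with flags set.

What the generators do *not* emulate: realistic substitution matrices or
rate heterogeneity, alignment errors (families are generated aligned),
paired-end structure or quality profiles in reads, and peptide-level
effects (shared peptides, match-between-runs) in LFQ data. Passing tests
therefore demonstrate that the algorithms recover planted truth under
their stated statistical assumptions, not that those assumptions hold in
any particular real dataset.

## Determinism and problem sizes

Every stochastic component takes a seed; the pipeline runner derives
per-stage seeds from the global seed via
`numpy.random.SeedSequence((global_seed, stage_index))` with the fixed
stage enumeration in `pipeline.STAGE_IDS`, so stages can be re-run in
isolation and identical (config, seed) pairs reproduce artefacts
bit-identically (hash-asserted in the tests).

Simulation sizes used by the test suite and acceptance script — 50
species for conservation recovery, 20 replicate families for knockout
recovery, 200 reads for the vote, 100 null and 5 spiked LFQ matrices of
1000 proteins — were chosen as the smallest sizes at which the binomial
and Monte-Carlo error bands stated with each check are meaningfully
narrower than the effects being measured.

## Known limitations

* Alignment itself is upstream (MUSCLE or similar); the package consumes
  aligned FASTA and performs no realignment or tree inference.
* The score threshold of the read filter is specific to this aligner's
  scoring scheme; thresholds quoted for other tools need recalibration.
* The permutation FDR has finite resolution (~1/35 for 4-vs-4); targets
  far below that are met by calling nothing rather than by extrapolating.
* The NLS propensity score orders variants; it does not predict import
  efficiency.
* Species status treats isoform disagreement as "mixed" and never
  majority-votes; downstream conservation grouping treats conservative
  motifs as intact-like by default (flag to treat as loss).
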