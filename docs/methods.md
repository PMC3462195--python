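# Methods

## Problem setting

Secretion screens in filamentous fungi yield, per overexpressed protein, a
binary outcome: a clear extra band of the expected size on a gel (successful
high-level production, label +1) or none (label −1). `secprod` models this
outcome from sequence alone. The working assumption is that generic,
position-independent sequence properties — amino-acid and codon composition,
physicochemical class content, glycosylation-site density — carry most of
the predictive signal, and that a linear model over such features is both
accurate enough and directly interpretable: the sign and magnitude of each
weight is the feature's contribution to predicted success.

## Dataset construction

Records enter the analysis only if they look like bona fide secreted
proteins: a predicted signal peptide (`sp_flag`), length strictly greater
than `min_length` (default 100 residues), no C-terminal HDEL/KDEL
ER-retrieval signal (exact suffix match), and not transmembrane
(`tm_flag`, intended to mean "called transmembrane by two independent
predictors"). Structural annotations (cleavage position, buried/exposed and
helix/strand/coil strings) are consumed as plain input; no structure
prediction is performed here.

Redundancy reduction prevents homologous sequences from being split across
cross-validation folds. Two sequences are redundant when an optimal local
alignment (match +1, mismatch −1, linear gap −2) has identity above
`identity_threshold` (default 0.8) over its aligned columns and spans at
least `coverage_threshold` (default 0.8) of one of the two sequences.
Redundant pairs are single-linkage clustered; each cluster keeps the member
with the smallest mean (1 − identity) to the other members, except that a
cluster containing both labels keeps one representative per label —
discarding either outcome of near-identical sequences with *different*
outcomes would bias the class balance. Ties break on lexicographic id.

Two choices here were genuinely open and are worth recording. First,
identity is defined over the local-alignment span, not the full sequence
length; a local definition makes domain-sharing proteins redundant only
when the shared region dominates at least one of them, which is the
behaviour the coverage threshold is meant to control. A consequence is that
terminal mismatches are excluded from the alignment, so "identity 1.0 at
coverage 0.9" is the expected outcome for sequences differing only at an
end. Second, the thresholds themselves are deliberately configuration, not
constants: the appropriate stringency depends on the screen's diversity.

## Features

All feature matrices are pandas DataFrames keyed by record id with unique
column names, so sets can be concatenated into pools.

- **Compositions** (f0–f10): fractions of symbols in a representation —
  codon composition of the ORF (64 columns, stop codon included as a token),
  amino-acid composition of signal peptide / mature / structural
  subsequences (20 columns each), state-string compositions (B/E: 2, H/E/C:
  3), and the 11 predefined physicochemical cluster compositions (summed
  member fractions; these clusters overlap by nature). An empty structural
  subsequence yields a zero row plus a warning rather than dropping the
  record, keeping matrices aligned across feature sets.
- **Randomized controls** (f4r–f9r): for each structural subsequence, a
  length-matched sample drawn without replacement from the mature sequence,
  seeded per (record, representation, seed) and cached. If the control
  classifies as well as the real subsequence, the subsequence's information
  content is just its length. Sampling is from the mature sequence because
  that is the sequence the structural states are defined on.
- **Codon usage** (f12): count of each of the 59 degenerately encoding
  codons divided by the count of its amino acid; family entries sum to 1
  for amino acids present.
- **Scalar features** (f13): signal-peptide length (residues), protein
  length (residues), codon adaptation index, isoelectric point. CAI is the
  geometric mean of relative adaptiveness w (per family, count divided by
  the family maximum; zero-count reference codons floored at w = 0.01;
  single-codon families and stops excluded). The reference table defaults to
  the input collection's own ORFs and should be supplied from a host-genome
  ORF set when available. pI solves net charge = 0 by bisection on pH
  ∈ [0, 14] to 1e-4, with the Bjellqvist pKa table (generic termini 7.5 /
  3.55 with residue-specific overrides; side chains D 4.05, E 4.45, C 9.0,
  Y 10.0, H 5.98, K 10.0, R 12.0). The implementation is checked against an
  independent one in the test suite.
- **k-mer counts** (f15–f22): overlapping window counts for k = 2..5 on the
  protein or signal peptide. Only observed k-mers become columns; their
  inner products equal the spectrum kernel exactly (unobserved k-mers
  contribute zero), which the tests verify against a brute-force dense
  computation.

The default univariate-selection pool concatenates f0, f1, f2, f3, f6, f10
and f13 — 124 columns — covering every non-redundant compositional view
plus the scalars, while leaving out the structural-subsequence compositions
(which re-describe f2 through annotation masks) and codon usage (largely
determined by f0).

## Classification and evaluation

`SVC(kernel="linear")` provides the quadratic-programming solver; the
package stores models in support-vector form (αᵢyᵢ, support rows, bias) and
computes scores both by kernel expansion and by the explicit weight vector,
requiring agreement to 1e-6. AUROC is computed as the Mann–Whitney
statistic with ties counted ½ and is cross-checked against scikit-learn.

Nested CV uses seeded stratified folds. Stratification is a deliberate
choice (screens can be quite unbalanced; unstratified small folds can lose
a class entirely), as is tuning C to the *smallest* grid value achieving
the maximal inner-CV AUROC — a deterministic preference for simpler models.
The default grid is 10⁻³…10³ in decades. Features are not standardized by
default: compositions already live on [0, 1], and any optional z-scoring
must use training-fold statistics only. Forward selection greedily adds the
candidate maximizing inner-CV AUROC at fixed C (default 1) and stops as
soon as the best achievable score drops below the current one, ties broken
by candidate order.

## Amino-acid clustering

The greedy reduced-alphabet search starts from the single best-scoring
amino acid and, at each iteration, evaluates every remaining amino acid
both as a new singleton cluster and merged into each existing cluster,
committing the single best placement. Candidates are evaluated in
alphabetical order, new-cluster before merges, first maximum wins — a fully
deterministic trace. Because placements continue until all 20 amino acids
are consumed but the returned state is the best one *ever observed*, amino
acids placed after the peak are effectively unselected. On alphabets small
enough to enumerate every partial partition, the greedy result is compared
against exhaustive search in the tests using deterministic evaluators
constructed so the greedy path provably reaches the global optimum; on real
evaluators the method remains a heuristic, as any greedy search is.

## Sequon analysis

The canonical acceptor sequon N-X-[S/T] with X ≠ P is counted at every
position, overlaps included; a permissive N-X-[S/T] switch exists because
glycosylation of proline-containing sites is debatable. Counting defaults
to the full sequence with a mature-only option, since a signal peptide can
in principle contain spurious matches.

## Synthetic data: what it emulates, and what it does not

`generate_proteins` draws i.i.d. residues from a class-specific
composition: negatives use a fixed background (Swiss-Prot average
frequencies), positives add `delta` (default Y +0.03, N +0.02, K −0.03,
M −0.01, renormalized). Accidental sequons are scrubbed (third residue
rerolled to a non-S/T letter) and a Poisson number of sequons — rate per
100 mature residues, default 1.2 positive / 0.5 negative — is then planted
as explicit N-X-[S/T] triplets spaced ≥ 3 apart, with X avoiding P/N/S/T so
planting cannot create overlapping extras. At the default mature-length
range (150–600) these rates put the class means near 4.7 and 2.0 sequons
per protein, the kind of split reported for homologous secretion screens.
Signal peptides (15–30 residues) start with M and use a leucine/alanine-
heavy composition; structural states are i.i.d. with B/E ≈ 0.45/0.55 and
H/E/C ≈ 0.35/0.20/0.45; ORFs come from per-residue codon sampling
(uniform within family unless a bias table is given) plus a TAA stop.
Everything is driven by one seeded generator, so a seed fixes the dataset
byte for byte.

The generator deliberately omits positional structure, domains, real
secondary-structure correlation, and phylogenetic relatedness. Passing
tests therefore demonstrate that the pipeline recovers planted
order-invariant signals at realistic sample sizes and calibrates correctly
under the null — not that real screens are this separable (reported
real-data AUROCs are far from 1), and not that structural-state features
carry real information (in synthetic data the states are label-independent
by construction, which is exactly what the randomized-control comparison
should detect). The scrubbing step slightly depletes S/T downstream of N
relative to a pure i.i.d. model; at the default rates the distortion is
far below the planted effects.

Problem sizes in the shipped tests and acceptance script (n = 400 for
recovery and null runs, n = 100–500 elsewhere, 5–10 outer folds) were
chosen as the smallest sizes at which the planted effects are
comfortably detected with deterministic seeds.

## Known limitations

- Redundancy reduction computes all pairwise alignments (O(n²)); adequate
  for screen-sized sets (hundreds to a few thousand sequences), not for
  proteome-scale deduplication.
- The mixed-label representative rule intentionally keeps near-identical
  positive/negative pairs, so the "no redundant pair survives" invariant
  holds only within a label.
- Decision scores are uncalibrated margins, not probabilities.
- The clustering evaluator re-runs a full CV per candidate placement;
  cost grows roughly cubically with alphabet size and linearly in folds.
  Practical at 20 amino acids with moderate n, but not meant for larger
  alphabets.
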