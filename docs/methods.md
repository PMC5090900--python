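# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Sequence handling and reference numbering

Sequences use the 20 canonical one-letter codes plus `X`; `X` is accepted
on input but never counts as a match in identity computations or scans
(conservative handling of ambiguity).  The gap character is `-`; `.` in
input alignments is normalised to `-` on read so one convention holds
internally.

All residue positions are reported in *reference numbering*: the 1-based
position in the ungapped sequence of a designated alignment row, with the
initiator Met as residue 1.  Expression constructs for AAR panels often
carry an engineered Gly between Met and residue 2 (a cloning-site
artifact); that Gly is deliberately not counted, so reported positions
and mutation names (e.g. `Q15R`) refer to the native deposited sequence.
The column↔residue map is a bijection between non-gap reference columns
and 1..L, enforced at construction.

## Pairwise identity

Global alignments are Needleman–Wunsch with affine gaps, BLOSUM62, and
BLAST protein gap costs: a gap of length k costs `open + k·extend`
(default 11 + k).  End gaps are penalized — AAR orthologs are
near-full-length, so true global alignment is the right default;
semi-global scoring is available via `ScoringScheme(penalize_end_gaps=False)`.
The aligner is Biopython's `PairwiseAligner`; among co-optimal alignments
the aligner's first enumeration is returned, which is deterministic for
fixed inputs.  Scores are validated against exhaustive enumeration of all
monotone alignments for short sequences (an oracle in the test suite and
the acceptance script).

Percent identity divides matching columns by columns where *neither*
sequence is gapped.  No community-wide standard exists for the
denominator; this convention is applied uniformly to both the pairwise
and the MSA-column route so comparisons are self-consistent, and the two
routes agree exactly when the MSA is the stacked pairwise alignment.
Identities are kept at full precision; rounding to integer percent is a
presentation concern only.

## Distances and neighbor joining

The default distance is the linear transform `d = 100 − identity` with no
multiple-hit correction, matching common practice for within-family
protein trees at 50–85% identity; a Poisson correction
(`d = −100·ln(identity/100)`) is available but off by default.

Neighbor joining follows the Saitou–Nei agglomeration: minimise
`Q(i,j) = (m−2)·d(i,j) − r_i − r_j`, join, assign pendant lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(m−2))`, reduce the matrix with
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`.  Ties in Q are broken toward the
lexicographically smallest index pair, so output is deterministic under
row permutations up to relabelling.  Negative computed branch lengths are
clamped to zero after assignment — presentation parity with standard
viewers; on additive input no clamping ever triggers and the path-length
matrix of the output tree equals the input exactly (tested on random
4–8-taxon additive matrices).  For two taxa the single edge is split
equally.  The tree is unrooted, represented with one trifurcating root.

### Clade grouping

The published group structure of AAR trees (two large groups plus a small
outlier group) is a visual call; as an explicit operationalisation the
package cuts the longest edges: candidate edges are ranked internal-first
by decreasing length (ties by preorder index), and a cut is kept only if
it splits a component that still holds leaves on both sides.  This
"effective cut" refinement guarantees exactly k leaf-bearing groups for
any k up to the leaf count — naive removal of the k−1 longest internal
edges cannot produce singleton groups and can yield fewer than k groups
when cuts are adjacent.  k defaults to 3.  Group membership of specific
real strains is not asserted anywhere: the true clade boundaries are not
derivable from group counts alone.

Habitat summaries report counts for marine / freshwater / both / unknown
per group and fractions over labelled leaves; optionally the `both`
category is excluded from the marine/freshwater denominator.

## Quantification

Inputs are replicate-level tables: hydrocarbon amounts per analyte
(pentadecane, heptadecene, heptadecane by default; extra `amount_*`
columns propagate through totals and fractions) and blot band volumes
with per-band detection flags.  Derived quantities:

* **relative activity** = (mean total hydrocarbons / mean soluble
  volume) ÷ the same index for the reference.  The soluble amount is the
  correct normaliser because only soluble AAR is catalytically relevant;
  insoluble material is inclusion bodies.
* **solubility** = 100·S̄/(S̄+P̄) from replicates where both bands were
  detected.
* **relative expression** = mean (S+P) ÷ reference mean (S+P).
* **fractions** = mean analyte amounts over their sum (always summing to
  1 when defined); **relative specificity** = elementwise fraction ratio
  vs the reference, undefined where the reference fraction is 0.

Aggregation is *ratio of means*, not mean of ratios: replicate-level
numerators and denominators are averaged first, matching the logic of
normalising pooled quantities and keeping the estimator well-behaved
when a replicate denominator is small.  Standard errors use first-order
(delta-method) propagation of the component relative SEs; whether
published SEs for such assays are on the ratios or the underlying
quantities is typically unstated, so the choice is documented here and
kept uniform.  Per-quantity SEs for solubility and fractions are the
standard errors of the per-replicate values.  The reference variant
reports ratios of exactly 1 ± 0.

A band flagged undetected is missing data, not zero: a variant whose
soluble band is never detected has activity and solubility
"not determined" (the correct reading of a western blot below the
detection limit — the activity index would otherwise be infinite).  An
optional ADO soluble-amount column is accepted as an internal-control
covariate: it is checked for near-constancy (warning above CV 25%) and
never used in normalisation.

## Residue scanning

Strict criterion (activity-type determinants): a column is reported when
all in-group rows share one non-gap residue r and at most
`max_outgroup_matches` out-group rows carry r.  The default is 0 —
requiring the in-group residue to be absent from the out-group — because
a proposed substitution is only meaningful where the target differs from
the in-group; the tolerance is configurable since "not conserved
outside" is intrinsically looser.

Similarity criterion (specificity-type determinants): all in-group
residues fall within one similarity class while not all out-group
residues do.  Classes default to the Clustal strong groups (STA, NEQK,
NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW), the convention behind `:` marks
in alignment output; identical in-group residues qualify trivially (each
residue also forms its own singleton class, covering letters like G or C
that belong to no strong group).

Gap handling: a gap in any in-group row disqualifies the column; gaps
and `X` in out-group rows count as non-matching.  Columns gapped in the
numbering reference are still scanned but flagged unnumberable and
reported by alignment column.  Output is sorted by reference position,
and every reported position is re-checkable by a brute-force per-column
pass (the test suite does exactly that).

Mutation proposals take each strict hit, look up the target row, and emit
`<wild-type><reference position><in-group consensus>`; positions where
the target already matches the consensus are skipped, gapped targets are
returned as warnings.  Proposals are hypotheses for mutagenesis, not
effect predictions.

## Correlation

Pearson r (scipy) over (percent identity to a reference, property)
pairs, requiring n ≥ 3 and nonzero variance.  The reference's self-point
(identity 100) is excluded by default: including a point that is both
extreme in x and typically extreme in y manufactures correlation, which
is exactly what the leave-one-out comparison (`r_full` vs `r_dropped`)
makes visible.  No p-values are attached by default; a seeded
permutation p-value (default 10,000 shuffles) is available.

## Synthetic data

The family generator draws a root sequence uniformly over the 20 amino
acids (default L = 341, AAR-like), derives each member by i.i.d. per-site
substitutions (default probability 0.05), then overwrites the planted
diagnostic positions — in-group members get the designated residue, the
out-group draws from a disjoint residue set.  Defaults (2 in-group + 6
out-group, 11 planted positions) mirror the design of a small
representative enzyme panel with a two-member high-activity in-group.
Because planting happens after background noise, strict-scan recall on
the planted set is 1 by construction at any background level, while
precision 1 holds at background 0 (the only non-planted column pattern
then is full conservation, which the criterion rejects); at positive
background the false-positive rate is what the scan's configurability is
for.  There is no indel process (keeping reference numbering trivial); a
gap-injection option exists solely to exercise gap-handling code paths.

The measurement generator emits, per replicate, soluble volume
`expression·solubility·LN(cv)`, insoluble volume
`expression·(1−solubility)·LN(cv)` and hydrocarbon total
`activity·expression·solubility·LN(cv)` — LN(cv) being mean-1 lognormal
noise, the natural choice for strictly positive band-intensity and GC–MS
peak measurements — with the three-analyte split drawn from a Dirichlet
around a habitat-dependent mean triple: marine-like (0.75, 0.20, 0.05)
and freshwater-like (0.15, 0.77, 0.08) for (pentadecane, heptadecene,
heptadecane), i.e. a pentadecane-dominant marine profile and a
freshwater profile with pentadecane at ~20% of heptadecene.  Default
noise CV 0.1 and n = 3 replicates represent a careful triplicate assay;
Dirichlet concentration defaults to 300 (small replicate scatter around
the mean split).  When truths are not specified, per-variant activities
are log-uniform on [0.05, 1.5] (the span seen across real AAR panels,
relative to the best enzyme), expression log-uniform on [0.3, 3],
solubility uniform on [0.1, 0.9].  Variants can be flagged below
detection to exercise the not-determined path.

What the generator does *not* emulate: phylogenetic correlation among
sequences (star-like families only, no rate heterogeneity or empirical
substitution model), correlated noise across replicates or between blot
and GC–MS measurements, detection-limit censoring as a function of true
abundance, and any mechanistic sequence→activity link.  Passing recovery
tests therefore demonstrate correctness of the arithmetic and the
criteria under the stated noise model — not that the criteria would
identify true determinants in real families, where conservation
structure is richer.

## Problem sizes and determinism

The test-suite and acceptance-script workloads are sized for quick
reruns: exhaustive alignment verification over all sequence pairs of
length ≤ 4 on a 4-letter alphabet (~93k pairs via a vectorised
enumeration oracle), 200 random 4–8-taxon additive matrices for topology
recovery, 100 three-taxon instances against the closed form, one
341-residue 8-sequence family per scan check, and 200 simulated variants
× 3 replicates for the noisy-recovery statistic.  Every stochastic stage
takes an explicit seed (numpy `default_rng`); identical seeds give
byte-identical pipeline outputs, and report floats are written with 6
significant digits.

## Known limitations

* Clade grouping by longest-edge cuts is one defensible
  operationalisation of a visual grouping; other cut rules can give
  different memberships on trees without clear long internal edges.
* Identity-based p-distances ignore multiple hits; at the low end of the
  family's identity range (~50%) the tree's deeper branch lengths are
  compressed unless the Poisson option is enabled.
* The strict scan with `max_outgroup_matches = 0` may under-call
  positions a human curator would accept as "not conserved outside";
  raising the tolerance trades precision for recall.
* SE propagation is first-order and assumes independent replicate noise
  in numerator and denominator; with n = 3 these SEs are themselves
  noisy.
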