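# aarscan

Comparative sequence and activity analysis for panels of cyanobacterial
acyl-ACP reductases (AARs) — the NADPH-dependent enzymes that reduce
C16/C18 fatty acyl-ACP/CoA to fatty aldehydes, the committed step of
cyanobacterial alkane biosynthesis.  The package is aimed at enzyme
engineers who screen AAR orthologs and variants in *E. coli* (coexpressed
with an aldehyde-deformylating oxygenase, ADO) and need the bioinformatic
side of the screen done reproducibly:

* **identity** — Needleman–Wunsch global alignments (BLOSUM62, affine
  gap cost 11 + k) and percent-identity matrices, both pairwise and on a
  supplied MSA; identity is `100 · matches / (columns where neither
  sequence is gapped)`.
* **tree** — neighbor joining on the p-distance `d = 100 − identity`,
  clade grouping by longest-edge cuts, and per-group habitat composition
  (marine / freshwater / both), the classic overlay that separates
  C16-preferring marine-clade AARs from C18-preferring freshwater ones.
* **quantify** — turns GC–MS hydrocarbon tables (pentadecane C15:0,
  heptadecene C17:1, heptadecane C17:0) and western-blot densitometry
  into per-variant profiles: relative aldehyde-producing activity
  `(total hydrocarbons / soluble AAR) : same for the reference`,
  solubility `100·S/(S+P)`, relative expression `S+P` vs the reference,
  and substrate-specificity fractions, all as mean ± SE over replicates
  with non-detected bands propagated as "not determined".
* **scan** — alignment-column criteria for candidate determinant
  residues: strict conservation inside a designated in-group with the
  residue (nearly) absent outside, or within-class similarity (Clustal
  strong groups) inside the in-group only; hits are numbered on a
  reference sequence (Met = 1) and turned into mutation proposals named
  like `Q15R`.
* **correlate** — Pearson correlation of any profile property against
  percent identity to a reference, with a leave-one-out check that
  exposes correlations carried by a single high-leverage point.
* **simulate** — synthetic sequence families with planted diagnostic
  columns and measurement tables with lognormal/Dirichlet noise around
  known truth, so every stage has an offline recovery test.

## Worked example

```python
from aarscan import (FamilyConfig, MeasurementConfig, generate_family,
                     generate_measurements, variants_from_family,
                     assemble_profiles, identity_matrix, to_distance,
                     neighbor_joining, clade_groups, habitat_summary,
                     build_reference_map, GroupSpec, scan_strict,
                     propose_mutations)

fam = FamilyConfig(length=120, n_ingroup=2, n_outgroup=6, n_planted=5,
                   background_substitution=0.1, seed=11)
records, msa, truth = generate_family(fam)
meas = MeasurementConfig(variants=variants_from_family(records, seed=12),
                         reference_id="M01", noise_cv=0.1, seed=12)
hydro, blot, _ = generate_measurements(meas)

ident = identity_matrix(records)
tree = neighbor_joining(to_distance(ident))
groups = clade_groups(tree, 2)
profiles = assemble_profiles(hydro, blot, "M01")
spec = GroupSpec("high-activity", ("M01", "M02"))
hits = scan_strict(msa, spec, build_reference_map(msa, "M01"))
suggestions, _ = propose_mutations(hits, "F01", msa, spec)
```

printed summaries from this run:

```
identity range: 70.0-85.8%
groups: {'group1': 6, 'group2': 2}
group1 marine fraction: 0.0
F01: activity 0.10 +/- 0.01, solubility 28%, pentadecane fraction 0.14
discriminating positions: [16, 60, 71, 95, 117]
proposed mutations for F01: ['D16W', 'S60L', 'T71I', 'P95Y', 'D117S']
planted truth: [16, 60, 71, 95, 117]
```

Reading this: the two-member in-group (marine-like, `M01`/`M02`) and the
six-member out-group separate cleanly into two tree groups whose habitat
fractions match the labels; variant `F01` has ~10% of the reference's
soluble-normalised activity and a low pentadecane share (a C18-preferring
profile); and the strict scan recovers exactly the five planted
diagnostic columns, proposing the five substitutions that would move
`F01` to the in-group consensus at those positions.

The same flow is available from the shell — `aarscan all -c config.yaml`
runs simulate → identity → tree → quantify → scan → correlate and writes
TSV/Newick/JSON reports into the configured output directory (see
`aarscan --help`).

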