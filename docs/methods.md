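# Methods

## The association measure

Each codon position (1, 2, 3) carries one of four nucleotides. To ask how
strongly the nucleotide identity at a position tracks a physicochemical
property of the encoded amino acid, the four nucleotides are partitioned
into groups and each group is given a number:

| family | partitions | value set | orderings | assignments |
|---|---|---|---|---|
| four groups | 1 | {−2, −1, +1, +2} | 4! | 24 |
| three groups | C(4,2) = 6 (the fused pair) | {−1, 0, +1} | 3! | 36 |
| two groups, 1 vs 3 | C(4,1) = 4 | {−1, +1} | 2 | 8 |
| two groups, 2 vs 2 | C(4,2) = 6 (the −1 pair) | {−1, +1} | 1 | 6 |

74 assignments per position in total. In the 2-vs-2 family, choosing the
−1 pair fixes the +1 pair, so there is a single value ordering per choice;
each bipartition therefore appears once per sign orientation, exactly as in
the 1-vs-3 family. The enumeration is closed under value negation in every
family, which the test suite asserts.

An amino acid's *position value* under an assignment is the unweighted mean
of the assignment values over the nucleotides at that position across its
sense codons (uniform weight per synonymous codon; stop codons excluded
everywhere). For example, under A:−1 / T:+1 / G,C:0 at position 2, leucine
(TTA, TTG, CTT, CTC, CTA, CTG — all with T in the middle) scores +1, serine
(TCx and AGy — all C or G in the middle) scores 0.

The association of an assignment with a property scale is the Pearson
correlation over the **20 amino acids** between the position-value vector
and the scale, with a two-sided p-value from the t distribution with
n − 2 = 18 degrees of freedom. The amino-acid-level sample (n = 20, not the
61 codons) is the convention under which r = 0.864 for hydropathy at
position 2 yields p ≈ 9.4 × 10⁻⁷, which is what the t distribution with
18 df gives — the p-values pin the convention down.

The full catalogue covers 74 assignments × 3 positions × 13 properties =
2886 records. The summary keeps, per (property, position) cell, the record
with maximal |r| (39 records), re-oriented so r is positive — correlation is
antisymmetric under value negation, so the two orientations carry the same
information. Ties break toward fewer groups, then lexicographic assignment
values, deterministically.

The per-property "combined" association regresses the 20 property values on
the three per-position winning value vectors by ordinary least squares
(with intercept) and reports the multiple correlation R, R², and the
overall-F p-value. Collinear predictors fall back to reduced-rank least
squares with a warning. For hydropathy this yields R = 0.890, R² = 0.793.

## Property scales

Thirteen scales are bundled as constants with a per-scale source citation:
Kyte–Doolittle hydropathy; Grantham polarity, chemical composition of the
side chain, and molecular volume; Fasman-handbook residue molecular weight
and melting point; Zimmerman isoelectric point; Jones refractivity; the
four Sneath (1966) indices (aromaticity, aliphaticity, hydrogenation,
hydroxythiolation); and the Woese polar requirement. Pearson correlation is
invariant under affine rescaling of either variable, so the scales' units
are immaterial to r; a z-standardization helper exists for plotting and
testing. Only the hydropathy and polarity scales have unambiguous published
values spot-checked in the tests; the other eleven are faithful transcriptions
of their cited sources but small transcription-lineage differences exist
between published versions, so results depending on them (e.g. which
position wins for melting point) should be treated as indicative. With the
bundled scales, 9 of the 13 properties peak at position 2, and position 2
has the highest mean best-cell r (0.56 vs 0.43 and 0.32).

Custom scales: any 20-row two-column TSV (amino-acid letter, value) can be
read with `read_scale_tsv` and pushed through the same machinery.

## Gene-level statistics

`translate_cds` handles frame-0 CDS with the standard genetic code only: a
single terminal stop is trimmed silently, codons containing N contribute
neither residue nor codon count, an internal stop either invalidates the
gene (default) or truncates it (flag). Length not divisible by 3 is a hard
error.

**T2−A2** is (count of T − count of A) at codon position 2, divided by the
gene's usable sense-codon count (after stop-trim and N-skip). The
denominator makes it a per-codon frequency difference bounded by [−1, +1],
reaching ±1 exactly when every second position is T (resp. A). It is the
gene-level aggregation of the winning position-2 assignment for hydropathy:
G and C score 0 and drop out of the sum.

**GRAVY** is the arithmetic mean of the Kyte–Doolittle index over a
protein's residues; non-standard letters are excluded from numerator and
denominator alike, following the classic codon-analysis tools. The protein
is our own translation of the CDS (one source of truth), and the
implementation is cross-checked against Biopython's independent ProtParam
GRAVY in the tests.

A genome summary is the Pearson r (and two-sided p) of T2−A2 against GRAVY
across the genome's valid genes. At least 3 valid genes are required; below
500 a quality warning fires, since the genome-level correlation grows
unstable in small gene sets.

## Super-class comparison

COG/KOG letters A, B, J, K, L (information storage and processing) map to
the *informational* super-class; the remaining 21 letters are
*operational*. Published category lists occasionally disagree on L
(DNA replication/repair); we follow the standard information-processing
grouping and expose `--l-superclass` to flip it. Proteins whose letters
span both super-classes are flagged `mixed` and excluded from both groups.

Group differences in GRAVY and T2−A2 use the unpaired two-sample Student
t-test (equal variance; Welch behind a flag), two-sided, no
multiple-testing correction. Subcellular-location contrasts (cytoplasmic vs
cytoplasmic membrane, rows = super-classes) use the chi-square test of
independence without continuity correction. Every statistic is computed by
scipy and verified in the tests against explicit-sum formulas to 1e-12.

## Synthetic genome generator

The generator emulates the one axis the downstream statistics measure:
heterogeneity of second-codon-position composition across genes. Each gene
draws a bias β ∈ [−1, 1]; the second-position nucleotide distribution
interpolates linearly between uniform (β = 0) and degenerate all-T (β = +1)
or all-A (β = −1). Given the second-position nucleotide, the codon is
uniform over the sense codons carrying it, so every output is a valid CDS
(ATG start, single terminal stop, no internal stops) and the expected
per-codon T2−A2 of a gene equals its β exactly.

Defaults (chosen once): 1000 genes; lengths ~ Normal(300, 75) codons
clipped to [50, 1000]; β ~ Uniform(−0.8, +0.8); 20% of genes labelled
informational with a β shift of −0.3 (A2-enrichment); location labels
cytoplasmic with probability 0.984 (informational) / 0.755 (operational).
The gene count, length scale and location probabilities mirror typical
bacterial genomes and the published location split; the β heterogeneity is
wide enough that the gene-level correlation comfortably exceeds the
amino-acid-level 0.864.

What the generator does **not** emulate: GC content, realistic amino-acid
usage, codon-usage bias within synonymous families, or gene-length
distributions beyond the clipped normal. Because both T2−A2 and GRAVY are
driven by the same second-position draws, synthetic genome-level r sits at
the very top of the empirically observed range (≈0.98–0.99, vs ≈0.9–0.97
for most real genomes, where amino-acid usage varies independently of
position 2). Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and the amplification mechanism, not the exact
real-data effect sizes.

## Problem sizes and numerical choices

- The full catalogue (2886 Pearson fits over 20 points) builds in about a
  second; tests build it once per session.
- The super-class recovery property is checked over 40 seeded replicates of
  400-gene genomes with mean length 150 codons — sizes the package treats
  as its standard small-replicate benchmark; the property is insensitive to
  genome size well below and above these values.
- Undefined correlations (zero variance in realized position values) are
  flagged, excluded from per-cell maxima, and reported as NaN rather than
  raising.
- Degenerate t-tests (both groups constant) return t = 0, p = 1 when the
  constants agree and NaN otherwise; chi-square requires strictly positive
  margins.
- All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  config + seed reproduces generator output byte-identically.

## Known limitations

- Standard genetic code only; no selenocysteine/pyrrolysine, no alternative
  translation tables.
- Eleven of thirteen scales carry transcription-lineage uncertainty (see
  above); downstream rankings involving them are indicative.
- The combined (multiple-regression) association is one reasonable
  definition of a three-position summary; other aggregation rules would
  give different "general" values.
- Annotations and locations are inputs; the package performs no orthology
  inference or location prediction.
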