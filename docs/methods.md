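# Methods

## Peptide enumeration

Coordinates are 1-based within protein sequences, and mutation positions
are 1-based within each peptide, matching the amino-acid conventions of
variant reports. For a variant altering residues `[a, b]` of the mutant
protein, every in-bounds window of each requested length that overlaps
`[a, b]` is emitted — all registers. A `*` (stop codon) truncates both
sequences before windowing. Defaults: class I lengths {8, 9, 10, 11};
class II {12…18} (class II lengths are a convention, not a sharp rule, so
they are configurable).

Frame-preserving variants (missense, in-frame indel) pair each mutant
window with the wild-type window at the same protein coordinates, when it
differs from the mutant window. For in-frame indels the same-coordinate
equal-length WT window is a design choice: the alternative (an equal
genomic-span window of different length) would break MT/WT column
alignment downstream; the residues after the indel differ between the two
conventions, so indel WT partners should be read as positional context,
not as the exact germline product. Frameshift windows carry no WT
partner — out of frame, none is defined; enumeration covers every window
overlapping at least one novel residue up to the residue before the stop.
Windows yielding an identical mutant peptide (possible with repeats) are
merged with the union of their mutation positions, so peptide counts are
counts of distinct peptides.

Transcripts of one variant are partitioned by the multiset of mutant
peptides they generate; the set id is the sorted `+`-joined transcript
ids, expression sums over members, and the best (minimum) TSL is kept.

## Score aggregation

Per (peptide, allele), the algorithm ensemble is collapsed by the median
(default) or the minimum IC50; the median of an even count is the mean of
the two central values, and missing algorithm outputs are omitted rather
than imputed (predictors legitimately decline some allele/length
combinations). A peptide passes binding for an allele when the configured
aggregate MT IC50 is ≤ 500 nM. The percentile-rank cutoff (≤ 2) can be
combined with the IC50 rule as `off` (default), `and`, or `or`; the
combination rule is a genuine judgement call, and the IC50-only default
keeps the pass criterion on a single scale. When IC50 and percentile
would pick different "best" alleles, the configured metric (IC50 by
default) decides. WT aggregates are reported only where the MT score
passes, mirroring how a reviewer reads the table (WT binding matters for
candidates still in play). Elution/immunogenicity scores are advisory
columns bounded to [0, 1]; they never affect tiering.

## Tiering

Criteria evaluated per variant (defaults in parentheses):

| criterion | rule |
|---|---|
| binding | aggregate MT IC50 at best allele ≤ `ic50_threshold` (500 nM) |
| tsl | TSL present and ≤ `tsl_max` (1) |
| no_expression | allele expression (gene TPM × RNA VAF) missing or zero |
| low_expression | allele expression < `allele_expr_threshold` (2.5) |
| low_rna_vaf | RNA VAF < `rna_vaf_min` (0.01) |
| low_rna_depth | RNA depth < `rna_depth_min` (10 reads) |
| subclonal | DNA VAF < `clonality_fraction` (0.5) × reference VAF |
| anchor | mutation confined to anchors and WT IC50 ≤ threshold |

The clonality reference VAF is tumor purity / 2 — the expectation for a
heterozygous variant in a diploid clonal population — or, without a
purity estimate, the maximum somatic DNA VAF in the sample; the founding
side of the boundary is inclusive. `rna_vaf_min` and `rna_depth_min`
defaults are permissive sanity floors (catch allele dropout and
near-zero coverage without vetoing ordinary candidates).

Anchor positions per (allele, length) are the smallest greedy set of
positions — descending probability, lower index on ties — whose
normalized anchor probabilities sum to ≥ `anchor_contribution_threshold`
(0.8). The anchor scenario then reads: mutation off-anchor (fully or
partly) → accept; mutation confined to anchors with WT IC50 ≤ the WT
threshold (defaults to the binding threshold) → reject (the presented
surface is wild type, so T cells are likely tolerized); confined to
anchors with a non-binding WT → accept (the mutation created the
binding); confined to anchors with no WT measurement → unknown.

Tier labels {Pass, Anchor, Subclonal, LowExpr, NoExpr, Poor} are
assigned as: no failures → Pass; any binding or TSL failure → Poor; a
single failing category among anchor / clonality / expression → its
named tier (expression splits into NoExpr when allele expression is
absent/zero and LowExpr otherwise, with the VAF/depth floors counting as
LowExpr); several failing categories → Poor. The sole-failure rule makes
the named tiers actionable ("fix this one thing") and guarantees
monotonicity: improving any single criterion never worsens the tier.
All failing criteria are always listed on the result regardless of the
label. Rows rank by (tier, allele expression descending, aggregate MT
IC50 ascending).

Re-tiering recomputes every criterion from the fields stored on the
aggregate row — clonality from DNA VAF and the new purity, the anchor
scenario from the stored mutation/anchor overlap and WT IC50 — and is
idempotent; evaluations are untouched. One caveat: changing
`anchor_contribution_threshold` at re-tier time does not re-derive the
overlap itself, which would need the per-peptide anchor vectors from the
metrics file.

## Report formats

The aggregate TSV uses the report headers conventional for upstream
pipelines (`ID`, `Gene`, `AA Change`, `Pos`, `Best Peptide`, `Allele`,
`IC50 MT`, `%ile MT`, `RNA Expr`, `RNA VAF`, `Allele Expr`, `RNA Depth`,
`DNA VAF`, `TSL`, `Tier`, `Eval`, …); unknown columns pass through
verbatim in their original order. Missing values serialize as `NA` in
TSV and `null` in JSON; floats are written with shortest round-trip
representation, so TSV write→read is the identity on every field. The
xlsx export is one-way; only the TSV re-loads with evaluations
preloaded. Variant ids are `chrom-pos-ref-alt` with 1-based positions.
The metrics JSON schema (version 1) is this package's own documented
layout — per variant: transcript sets, the full per-peptide
per-allele per-algorithm score grid, and `"allele|length"`-keyed anchor
vectors — compatible in spirit, not byte-for-byte, with upstream
pipeline metrics files.

## Synthetic cohorts

The generator emulates the input files of a review session, not any
particular predictor. Per variant: 1–3 transcripts (P = 0.6/0.3/0.1;
extra isoforms get a different upstream flank half the time, exercising
transcript-set splits); 15% frameshift; missense flank 12 residues so
every class I length fits in all registers. IC50s come from a
binder/non-binder log-normal mixture — binders exp(N(ln 80, 0.7)) clipped
to [2, 450] nM at one planted best allele, non-binders
exp(N(ln 8000, 0.8)) clipped to [1000, 50000] nM — with per-algorithm
jitter clipped to keep every draw on its component's side of the 500 nM
cutoff. That hard margin is deliberate: planted binder status is
unambiguous, so recovery tests measure the pipeline, not the overlap of
two distributions. Percentiles are a fixed increasing map of IC50
(100·x/(x+2500)) — rank-consistent within an allele but not calibrated
to any background distribution; elution/immunogenicity scores are a
noisy sigmoid of the same base affinity. Expression is gamma(3, 12) + 5
TPM; DNA VAF is uniform in [0.55, 1.0]·purity/2 for founding variants
and [0.10, 0.45]·purity/2 for subclonal ones (default purity 0.8,
subclonal fraction 0.2), again with a margin at the 0.5·reference
boundary. Anchor vectors are Dirichlet draws with concentration 25 on
position 2 and the C terminus, 0.8 elsewhere.

Consequently, passing tests show the machinery is correct under
separable, well-behaved inputs; they do not show robustness to what real
cohorts add — overlapping affinity distributions, algorithm-specific
biases, expression/VAF correlation structure, multi-nucleotide and
splice-altering variants, or HLA typing errors. The demo cohort (seed
42, 25 variants, 6 class I alleles, 8 binding algorithms) anchors the
documentation; recovery tests use 200–500 variants, sizes chosen to make
binomial 3-standard-error bands a few percentage points wide.

## Numerical choices and degenerate inputs

Ties everywhere break deterministically: lexicographic peptide for best
peptide selection, lexicographic allele for best allele, lower position
index for equal anchor probabilities. Anchor mass comparisons use a
1e-12 slack so a threshold of exactly 1.0 terminates on full mass;
anchor vectors must sum to 1 within 1e-6. Empty inputs: enumeration with
an empty length set, aggregation with no binding-class records, and
best-peptide selection from nothing are errors; an empty context list, an
empty binding table, and a zero-length top-k are empty results. A peptide
whose every algorithm declined has no aggregate and never passes.

## Known limitations

* Anchor probabilities are taken as input (or simulated); the package
  does not compute them from structural or binding data.
* No reference-proteome match filtering, manufacturability scoring, or
  PHBR-style multi-allele summarization.
* In-frame indel WT pairing follows the same-coordinate convention
  discussed above.
* The clonality model assumes diploid heterozygous variants; copy-number
  alterations will shift the reference VAF.
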