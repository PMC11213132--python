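# neotier

Neoantigen candidate aggregation, tiering and report handling for
personalized cancer vaccine design.

Somatic mutations in a tumor create mutant peptides (neoantigens) that can
be presented on MHC molecules and recognized by T cells. Selecting which
candidates to manufacture into a vaccine means juggling alternative
transcript isoforms, every peptide length and register covering the
mutation, an ensemble of disagreeing binding-prediction algorithms,
expression and clonality evidence, and allele-specific anchor positions.
Even a single missense variant evaluated at class I lengths 8–11 produces
38 distinct short peptides, and with 6 HLA alleles and 13 algorithms,
2,964 peptide–MHC predictions. `neotier` is the computational engine that
turns this combinatorial mess into a reviewable, tiered, per-variant
report — the library a drill-down review interface sits on top of.

## What it computes

* **Peptide enumeration** — every l-mer window of the mutant protein
  containing an altered residue (all registers, configurable lengths),
  paired with the same-coordinate wild-type window for frame-preserving
  variants; transcripts yielding identical peptide lists are grouped into
  transcript sets.
* **Score aggregation** — per (peptide, allele): median and lowest IC50
  (nM) and median percentile rank over the algorithm ensemble; a peptide
  passes binding when the configured aggregate is ≤ 500 nM (percentile
  rank ≤ 2 combinable as an AND/OR rule). Elution and immunogenicity
  scores in [0, 1] are kept as an orthogonal advisory table.
* **Tiering** — each variant's best peptide is judged on binding,
  allele expression (gene TPM × RNA VAF, default floor 2.5), clonality
  (DNA VAF vs purity/2), transcript support level, and the anchor
  scenario (a mutation confined to anchor positions whose wild-type
  peptide still binds is rejected: the T-cell-facing surface is self).
  Tiers: `Pass` > `Anchor` > `Subclonal` > `LowExpr` > `NoExpr` > `Poor`.
  Re-tiering under new thresholds or a revised tumor-purity estimate is a
  pure function that preserves reviewer evaluations.
* **Report I/O** — a bit-exact round-tripping aggregate TSV plus a
  metrics JSON carrying the transcript sets, full per-algorithm score
  grids and anchor probability vectors; supplementary-class merge, gene
  of-interest flagging, accept/reject/review evaluation tracking, top-30
  anchor-heatmap pair selection, and generic custom-table group/sort.
* **Synthetic cohorts** — a deterministic generator (`FixtureSpec`)
  plants binder/non-binder and founding/subclonal ground truth and runs
  the real pipeline end to end, so everything is testable offline.

## Worked example

```python
import neotier as nt

bundle = nt.make_report_pair(nt.FixtureSpec())   # demo cohort: seed 42, 25 variants
r = bundle.rows[0]
print(r.variant_id, r.gene, r.aa_change, r.best_peptide, r.hla_allele,
      round(r.ic50_mt, 1), round(r.allele_expr, 2), r.tier.value)
```

prints

```
chr12-4492849-A-G GENE011 p.Y13L SPLDIQLARTY HLA-B*08:01 37.0 9.62 Pass
```

— the top-ranked variant: an 11-mer with ensemble-median IC50 37 nM at
HLA-B\*08:01, allele expression 9.62 (well above the 2.5 floor), passing
every criterion. Across the demo cohort the tier distribution is
`{'Pass': 7, 'Subclonal': 2, 'Poor': 16}` over 66,000 generated
predictions. The same pipeline is reachable from the shell:

```sh
neotier fixture --seed 42 --n-variants 25 --out-dir demo/
neotier tier --aggregate demo/aggregate.tsv --purity 0.5 --out demo/retiered.tsv
neotier export --aggregate demo/retiered.tsv --format xlsx --out demo/report.xlsx
```

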