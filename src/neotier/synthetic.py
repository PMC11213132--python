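"""Deterministic synthetic data for the whole prioritization pipeline.

Generates random protein contexts with planted missense or frameshift
variants, a two-component log-normal ensemble of binding predictions
(binder peptides centered well below the 500 nM cutoff, non-binders well
above it, with a hard margin so planted status is never ambiguous),
Dirichlet anchor-probability vectors concentrated on the canonical anchor
positions (2 and the C terminus), and matched aggregate-report / metrics
file pairs produced by running the real enumeration, aggregation and
tiering code end to end. Every draw flows from a single integer seed
through one NumPy generator, so identical specs give identical files on
any platform.

The planted truths (binder status, subclonality, WT binder status) are
retained on each variant plan so recovery tests can compare what the
pipeline reports against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import report
from .aggregate import AggregationConfig, BindingRecord, ScoreClass, select_best_peptide, summarize_peptide
from .peptides import (
    CLASS_I_LENGTHS,
    CLASS_II_LENGTHS,
    PeptidePair,
    ProteinContext,
    VariantType,
    enumerate_registers,
    group_transcript_sets,
)
from .report import AggregateRow, MetricsDocument, VariantMetrics
from .tiering import (
    AnchorMatrix,
    AnchorScenario,
    TierConfig,
    anchor_key,
    anchor_overlap,
    assign_tier,
    classify_clonality,
    determine_anchor_positions,
    scenario_from_overlap,
    VariantMeasurements,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CLASS_I_ALLELES = (
    "HLA-A*02:01",
    "HLA-A*24:02",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)
CLASS_I_ALGORITHMS = (
    "MHCflurry",
    "MHCnuggetsI",
    "NetMHC",
    "NetMHCcons",
    "NetMHCpan",
    "PickPocket",
    "SMM",
    "SMMPMBEC",
)
CLASS_II_ALLELES = ("DRB1*07:01", "DRB1*11:01", "DQB1*03:01", "DPB1*04:01")
CLASS_II_ALGORITHMS = ("MHCnuggetsII", "NetMHCIIpan", "NNalign", "SMMalign")
ELUTION_ALGORITHMS = ("BigMHC_EL", "NetMHCpanEL")
IMMUNOGENICITY_ALGORITHMS = ("DeepImmuno",)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic cohort.

    IC50s are drawn from a binder/non-binder log-normal mixture: binders
    exp(N(ln 80, 0.7)) clipped to [2, 450] nM, non-binders
    exp(N(ln 8000, 0.8)) clipped to [1000, 50000] nM, with a small
    per-algorithm multiplicative jitter that respects the clip margins, so
    a planted binder's ensemble median always sits below 500 nM and a
    non-binder's always above. Expression is gamma-distributed TPM.
    """

    seed: int = 42
    n_variants: int = 25
    mhc_class: str = "I"
    alleles: tuple[str, ...] = CLASS_I_ALLELES
    algorithms: tuple[str, ...] = CLASS_I_ALGORITHMS
    lengths: frozenset[int] = CLASS_I_LENGTHS
    # P(1 transcript), P(2), P(3)
    transcripts_per_variant: tuple[float, ...] = (0.6, 0.3, 0.1)
    flank: int = 12
    frameshift_fraction: float = 0.15
    binder_fraction: float = 0.6
    wt_binder_fraction: float = 0.15
    binder_mu: float = float(np.log(80.0))
    binder_sigma: float = 0.7
    nonbinder_mu: float = float(np.log(8000.0))
    nonbinder_sigma: float = 0.8
    expression_shape: float = 3.0
    expression_scale: float = 12.0
    purity: float = 0.8
    fraction_subclonal: float = 0.2
    with_orthogonal: bool = True

    def __post_init__(self) -> None:
        cap = {"I": 8, "II": 4}[self.mhc_class]
        if len(self.algorithms) > cap:
            raise ValueError(f"class {self.mhc_class} allows at most {cap} binding algorithms")
        for p in (self.frameshift_fraction, self.binder_fraction, self.fraction_subclonal):
            if not (0 <= p <= 1):
                raise ValueError("fractions must lie in [0, 1]")

    @staticmethod
    def class_ii(**overrides) -> "FixtureSpec":
        defaults = dict(
            mhc_class="II",
            alleles=CLASS_II_ALLELES,
            algorithms=CLASS_II_ALGORITHMS,
            lengths=CLASS_II_LENGTHS,
            with_orthogonal=False,
        )
        defaults.update(overrides)
        return FixtureSpec(**defaults)


@dataclass
class VariantPlan:
    """One simulated variant with its planted ground truth."""

    variant_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    gene: str
    aa_change: str
    contexts: list[ProteinContext]
    is_binder: bool
    best_allele_planted: str
    wt_binds: bool
    is_subclonal: bool
    dna_vaf: float
    rna_vaf: float
    rna_depth: int
    gene_expr: float
    tsl: Optional[int]


@dataclass
class FixtureBundle:
    """Everything one synthetic cohort produced, files plus ground truth."""

    spec: FixtureSpec
    plans: list[VariantPlan]
    predictions: list[dict]  # epitope TSV rows
    anchors: dict[tuple[str, int], AnchorMatrix]
    rows: list[AggregateRow]
    metrics: MetricsDocument


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA, size=n))


def _plan_variants(spec: FixtureSpec, rng: np.random.Generator) -> list[VariantPlan]:
    plans: list[VariantPlan] = []
    maxlen = max(spec.lengths)
    for i in range(spec.n_variants):
        gene = f"GENE{i:03d}"
        chrom = f"chr{(i % 22) + 1}"
        pos = int(rng.integers(10_000, 5_000_000))
        ref, alt = (str(x) for x in rng.choice(list("ACGT"), size=2, replace=False))
        vid = f"{chrom}-{pos}-{ref}-{alt}"
        is_fs = bool(rng.random() < spec.frameshift_fraction)
        flank = spec.flank
        n_tx = int(rng.choice([1, 2, 3], p=spec.transcripts_per_variant))
        contexts: list[ProteinContext] = []
        tsl = 1 if rng.random() < 0.75 else int(rng.integers(2, 6))
        if is_fs:
            # frameshift: shared prefix, novel tail before the stop
            prefix = _random_protein(rng, flank + 5)
            tail = _random_protein(rng, int(rng.integers(maxlen - 3, maxlen + 6)))
            wt_rest = _random_protein(rng, len(tail) + 8)
            aa_change = f"p.{prefix[-1]}{len(prefix)}fs"
            for j in range(n_tx):
                contexts.append(
                    ProteinContext(
                        transcript_id=f"V{i:03d}.T{j + 1}",
                        wt_sequence=prefix + wt_rest,
                        mt_sequence=prefix + tail,
                        variant_type=VariantType.FRAMESHIFT,
                        mt_variant_start=len(prefix) + 1,
                        mt_variant_end=len(prefix) + len(tail),
                        expression=float(rng.gamma(spec.expression_shape, spec.expression_scale)),
                        tsl=tsl if j == 0 else int(rng.integers(1, 6)),
                    )
                )
        else:
            core = _random_protein(rng, 2 * flank + 1)
            wt_res = core[flank]
            mt_res = str(rng.choice(AA[AA != wt_res]))
            mt_core = core[:flank] + mt_res + core[flank + 1 :]
            aa_change = f"p.{wt_res}{flank + 1}{mt_res}"
            variants_flanks = [core]
            for j in range(n_tx):
                if j == 0 or rng.random() < 0.5:
                    wt_seq, mt_seq, start = core, mt_core, flank + 1
                else:
                    # isoform with a different upstream flank (splice variation)
                    extra = _random_protein(rng, int(rng.integers(3, 8)))
                    wt_seq = extra + core
                    mt_seq = extra + mt_core
                    start = len(extra) + flank + 1
                contexts.append(
                    ProteinContext(
                        transcript_id=f"V{i:03d}.T{j + 1}",
                        wt_sequence=wt_seq,
                        mt_sequence=mt_seq,
                        variant_type=VariantType.MISSENSE,
                        mt_variant_start=start,
                        mt_variant_end=start,
                        expression=float(rng.gamma(spec.expression_shape, spec.expression_scale)),
                        tsl=tsl if j == 0 else int(rng.integers(1, 6)),
                    )
                )
        is_binder = bool(rng.random() < spec.binder_fraction)
        is_subclonal = bool(rng.random() < spec.fraction_subclonal)
        het = spec.purity / 2.0
        if is_subclonal:
            dna_vaf = float(rng.uniform(0.10, 0.45) * het)
        else:
            dna_vaf = float(rng.uniform(0.55, 1.0) * het)
        rna_vaf = float(np.clip(dna_vaf + rng.normal(0, 0.03), 0.02, 1.0))
        plans.append(
            VariantPlan(
                variant_id=vid,
                chromosome=chrom,
                position=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                aa_change=aa_change,
                contexts=contexts,
                is_binder=is_binder,
                best_allele_planted=str(rng.choice(list(spec.alleles))),
                wt_binds=bool(rng.random() < spec.wt_binder_fraction),
                is_subclonal=is_subclonal,
                dna_vaf=dna_vaf,
                rna_vaf=rna_vaf,
                rna_depth=int(rng.poisson(80)),
                gene_expr=float(rng.gamma(spec.expression_shape, spec.expression_scale)) + 5.0,
                tsl=tsl,
            )
        )
    return plans


def make_contexts(spec: FixtureSpec) -> list[ProteinContext]:
    """All transcript protein contexts of the cohort (flat; determinstic)."""
    rng = np.random.default_rng(spec.seed)
    return [ctx for plan in _plan_variants(spec, rng) for ctx in plan.contexts]


def _draw_ic50(rng: np.random.Generator, spec: FixtureSpec, binder: bool) -> float:
    if binder:
        base = float(np.exp(rng.normal(spec.binder_mu, spec.binder_sigma)))
        return float(np.clip(base, 2.0, 450.0))
    base = float(np.exp(rng.normal(spec.nonbinder_mu, spec.nonbinder_sigma)))
    return float(np.clip(base, 1000.0, 50000.0))


def _jitter(rng: np.random.Generator, base: float, binder: bool) -> float:
    v = base * float(np.exp(rng.normal(0.0, 0.15)))
    # keep each algorithm's value on its component's side of the cutoff
    return float(np.clip(v, 2.0, 480.0)) if binder else float(np.clip(v, 550.0, 60000.0))


def _percentile(ic50: float) -> float:
    # strictly increasing map of IC50 to a percentile-rank-like scale
    return round(100.0 * ic50 / (ic50 + 2500.0), 4)


def _orthogonal_score(rng: np.random.Generator, ic50: float) -> float:
    s = 1.0 / (1.0 + ic50 / 500.0) + float(rng.normal(0, 0.05))
    return float(np.clip(s, 0.0, 1.0))


def _variant_peptides(plan: VariantPlan, spec: FixtureSpec) -> dict[str, PeptidePair]:
    """Distinct mutant peptides across the variant's transcript sets."""
    peptides: dict[str, PeptidePair] = {}
    for ts in group_transcript_sets(plan.contexts, spec.lengths):
        for p in ts.peptides:
            peptides.setdefault(p.mt_peptide, p)
    return peptides


def _predict_variant(
    plan: VariantPlan, spec: FixtureSpec, rng: np.random.Generator
) -> list[dict]:
    rows: list[dict] = []
    for mt_pep, pair in sorted(_variant_peptides(plan, spec).items()):
        for allele in spec.alleles:
            binder = plan.is_binder and allele == plan.best_allele_planted
            base_mt = _draw_ic50(rng, spec, binder)
            base_wt = _draw_ic50(rng, spec, plan.wt_binds) if pair.wt_peptide else None
            for algo in spec.algorithms:
                ic50_mt = _jitter(rng, base_mt, binder)
                ic50_wt = _jitter(rng, base_wt, plan.wt_binds) if base_wt is not None else None
                rows.append(
                    {
                        "chromosome": plan.chromosome,
                        "position": plan.position,
                        "gene": plan.gene,
                        "transcript_id": pair.transcript_ids[0] if pair.transcript_ids else "",
                        "mt_peptide": mt_pep,
                        "wt_peptide": pair.wt_peptide or "",
                        "hla_allele": allele,
                        "algorithm": algo,
                        "ic50_mt": round(ic50_mt, 3),
                        "ic50_wt": round(ic50_wt, 3) if ic50_wt is not None else "",
                        "percentile_mt": _percentile(ic50_mt),
                        "percentile_wt": _percentile(ic50_wt) if ic50_wt is not None else "",
                        "score_class": "binding",
                    }
                )
            if spec.with_orthogonal:
                for score_class, algos in (
                    ("elution", ELUTION_ALGORITHMS),
                    ("immunogenicity", IMMUNOGENICITY_ALGORITHMS),
                ):
                    for algo in algos:
                        rows.append(
                            {
                                "chromosome": plan.chromosome,
                                "position": plan.position,
                                "gene": plan.gene,
                                "transcript_id": pair.transcript_ids[0]
                                if pair.transcript_ids
                                else "",
                                "mt_peptide": mt_pep,
                                "wt_peptide": pair.wt_peptide or "",
                                "hla_allele": allele,
                                "algorithm": algo,
                                "ic50_mt": _orthogonal_score(rng, base_mt),
                                "ic50_wt": _orthogonal_score(rng, base_wt)
                                if base_wt is not None
                                else "",
                                "percentile_mt": "",
                                "percentile_wt": "",
                                "score_class": score_class,
                            }
                        )
    return rows


def make_predictions(spec: FixtureSpec) -> list[dict]:
    """Epitope-TSV rows for the whole cohort (one row per peptide x allele x algorithm)."""
    rng = np.random.default_rng(spec.seed)
    plans = _plan_variants(spec, rng)
    pred_rng = np.random.default_rng(spec.seed + 1)
    return [row for plan in plans for row in _predict_variant(plan, spec, pred_rng)]


def write_epitope_tsv(rows: Sequence[dict], path) -> None:
    import csv
    from pathlib import Path

    from .aggregate import EPITOPE_COLUMNS

    with Path(path).open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=EPITOPE_COLUMNS, delimiter="\t", lineterminator="\n")
        w.writeheader()
        w.writerows(rows)


def make_anchor_matrices(
    alleles: Sequence[str], lengths: Sequence[int], seed: int
) -> dict[tuple[str, int], AnchorMatrix]:
    """Dirichlet anchor vectors peaked at position 2 and the C terminus."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], AnchorMatrix] = {}
    for allele in alleles:
        for length in sorted(set(lengths)):
            alpha = np.full(length, 0.8)
            alpha[1] = 25.0
            alpha[length - 1] = 25.0
            probs = rng.dirichlet(alpha)
            probs = probs / probs.sum()
            out[(allele, length)] = AnchorMatrix(allele, length, tuple(float(p) for p in probs))
    return out


def _records_from_rows(rows: Sequence[dict]) -> list[BindingRecord]:
    recs = []
    for r in rows:
        recs.append(
            BindingRecord(
                mt_peptide=r["mt_peptide"],
                wt_peptide=r["wt_peptide"] or None,
                hla_allele=r["hla_allele"],
                algorithm=r["algorithm"],
                ic50_mt=float(r["ic50_mt"]) if r["ic50_mt"] != "" else None,
                ic50_wt=float(r["ic50_wt"]) if r["ic50_wt"] != "" else None,
                percentile_mt=float(r["percentile_mt"]) if r["percentile_mt"] != "" else None,
                percentile_wt=float(r["percentile_wt"]) if r["percentile_wt"] != "" else None,
                score_class=ScoreClass(r["score_class"]),
            )
        )
    return recs


def make_report_pair(
    spec: FixtureSpec, tier_cfg: TierConfig = TierConfig()
) -> FixtureBundle:
    """Run the full pipeline on a synthetic cohort and assemble report + metrics."""
    rng = np.random.default_rng(spec.seed)
    plans = _plan_variants(spec, rng)
    pred_rng = np.random.default_rng(spec.seed + 1)
    anchors = make_anchor_matrices(spec.alleles, sorted(spec.lengths), spec.seed + 2)
    agg_cfg = tier_cfg.aggregation()

    all_rows: list[AggregateRow] = []
    all_predictions: list[dict] = []
    variants_metrics: dict[str, VariantMetrics] = {}
    for plan in plans:
        pred_rows = _predict_variant(plan, spec, pred_rng)
        all_predictions.extend(pred_rows)
        pairs = _variant_peptides(plan, spec)
        records = _records_from_rows(pred_rows)
        by_pep: dict[str, list[BindingRecord]] = {}
        for rec in records:
            by_pep.setdefault(rec.mt_peptide, []).append(rec)
        summaries = [summarize_peptide(rs, agg_cfg) for rs in by_pep.values()]
        best, n_extra = select_best_peptide(summaries, agg_cfg)
        pair = pairs[best.mt_peptide]

        meas = VariantMeasurements(
            gene=plan.gene,
            dna_vaf=plan.dna_vaf,
            rna_vaf=plan.rna_vaf,
            rna_depth=plan.rna_depth,
            gene_expr=plan.gene_expr,
            tsl=plan.tsl,
            tumor_purity=spec.purity,
        )
        clon = classify_clonality(
            plan.dna_vaf, spec.purity, clonality_fraction=tier_cfg.clonality_fraction
        )
        best_al = best.per_allele[best.best_allele] if best.best_allele else None
        m = anchors.get((best.best_allele, pair.length)) if best.best_allele else None
        if m is not None:
            anc = determine_anchor_positions(m, tier_cfg.anchor_contribution_threshold)
            overlap = anchor_overlap(pair.mutation_positions, anc)
        else:
            overlap = None
        wt_ic50 = best_al.median_ic50_wt if best_al else None
        scenario = (
            scenario_from_overlap(overlap, wt_ic50, tier_cfg)
            if overlap is not None
            else AnchorScenario.UNKNOWN
        )
        result = assign_tier(best, meas, scenario, clon, tier_cfg)

        all_rows.append(
            AggregateRow(
                variant_id=plan.variant_id,
                gene=plan.gene,
                aa_change=plan.aa_change,
                pos_in_peptide="-".join(str(p) for p in sorted(pair.mutation_positions)),
                best_peptide=best.mt_peptide,
                best_wt_peptide=best.wt_peptide,
                hla_allele=best.best_allele,
                ic50_mt=best_al.median_ic50_mt if best_al else None,
                ic50_wt=wt_ic50,
                lowest_ic50_mt=best_al.lowest_ic50_mt if best_al else None,
                percentile_mt=best_al.median_percentile_mt if best_al else None,
                gene_expr=plan.gene_expr,
                rna_vaf=plan.rna_vaf,
                allele_expr=meas.allele_expr,
                rna_depth=plan.rna_depth,
                dna_vaf=plan.dna_vaf,
                tsl=plan.tsl,
                n_passing_peptides=n_extra,
                anchor_overlap=overlap,
                tier=result.tier,
            )
        )

        score_grid: dict[str, dict[str, dict[str, dict]]] = {}
        for rec in records:
            score_grid.setdefault(rec.mt_peptide, {}).setdefault(rec.hla_allele, {})[
                rec.algorithm
            ] = {
                "ic50_mt": rec.ic50_mt,
                "ic50_wt": rec.ic50_wt,
                "percentile_mt": rec.percentile_mt,
                "percentile_wt": rec.percentile_wt,
                "score_class": rec.score_class.value,
            }
        lengths_here = {p.length for p in pairs.values()}
        variants_metrics[plan.variant_id] = VariantMetrics(
            transcript_sets=group_transcript_sets(plan.contexts, spec.lengths),
            peptide_scores=score_grid,
            anchors={
                anchor_key(a, l): list(anchors[(a, l)].probabilities)
                for a in spec.alleles
                for l in sorted(lengths_here)
                if (a, l) in anchors
            },
        )

    all_rows.sort(key=lambda r: (r.tier.order, -(r.allele_expr or 0.0), r.ic50_mt or 1e12))
    return FixtureBundle(
        spec=spec,
        plans=plans,
        predictions=all_predictions,
        anchors=anchors,
        rows=all_rows,
        metrics=MetricsDocument(variants=variants_metrics),
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> dict[str, str]:
    """Serialize a bundle's files into a directory; returns the paths written."""
    from pathlib import Path

    from .tiering import save_anchor_matrices

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "aggregate": str(out / "aggregate.tsv"),
        "metrics": str(out / "metrics.json"),
        "epitopes": str(out / "epitopes.tsv"),
        "anchors": str(out / "anchors.json"),
    }
    report.write_aggregate(bundle.rows, paths["aggregate"])
    report.write_metrics(bundle.metrics, paths["metrics"])
    write_epitope_tsv(bundle.predictions, paths["epitopes"])
    save_anchor_matrices(bundle.anchors, paths["anchors"])
    return paths
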