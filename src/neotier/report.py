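"""Aggregate report and metrics file handling.

The variant-level aggregate report is a tab-delimited table, one row per
variant, carrying the best peptide, its aggregate binding scores,
expression/VAF measurements, the assigned tier and the reviewer's
evaluation. A companion metrics JSON holds the drill-down detail: the
transcript sets, the full per-allele per-algorithm score grids for every
peptide, and the anchor probability vectors. The TSV round-trips
bit-exactly (missing values as "NA"), so an annotated report can be
exported, shared and re-loaded with previous evaluations preloaded; a
spreadsheet (xlsx) export is provided write-only.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .aggregate import AggregationConfig, PeptideSummary
from .errors import InvalidArgumentError, SchemaError
from .peptides import PeptidePair, TranscriptSet
from .tiering import AnchorMatrix, AnchorOverlap, Tier

log = logging.getLogger(__name__)

MISSING = "NA"


class Evaluation(str, Enum):
    ACCEPT = "Accept"
    REJECT = "Reject"
    REVIEW = "Review"
    PENDING = "Pending"


@dataclass
class AggregateRow:
    """One variant's line in the aggregate report."""

    variant_id: str  # "chrom-pos-ref-alt", 1-based position
    gene: str
    aa_change: str
    pos_in_peptide: str  # variant position(s) within the best peptide, e.g. "5" or "3-5"
    best_peptide: str
    best_wt_peptide: Optional[str]
    hla_allele: Optional[str]
    ic50_mt: Optional[float]  # median MT IC50 at the best allele (nM)
    ic50_wt: Optional[float]
    lowest_ic50_mt: Optional[float]
    percentile_mt: Optional[float]
    gene_expr: Optional[float]
    rna_vaf: Optional[float]
    allele_expr: Optional[float]
    rna_depth: Optional[int]
    dna_vaf: Optional[float]
    tsl: Optional[int]
    n_passing_peptides: int = 0
    anchor_overlap: Optional[AnchorOverlap] = None
    tier: Tier = Tier.POOR
    evaluation: Evaluation = Evaluation.PENDING
    gene_of_interest: bool = False
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tier = Tier(self.tier)
        self.evaluation = Evaluation(self.evaluation)
        if self.anchor_overlap is not None:
            self.anchor_overlap = AnchorOverlap(self.anchor_overlap)
        if self.n_passing_peptides < 0:
            raise InvalidArgumentError("n_passing_peptides must be >= 0")


def _fmt_float(v: Optional[float]) -> str:
    return MISSING if v is None else repr(float(v))


def _fmt_int(v: Optional[int]) -> str:
    return MISSING if v is None else str(int(v))


def _fmt_str(v: Optional[str]) -> str:
    return MISSING if v is None else str(v)


def _parse_float(s: str) -> Optional[float]:
    return None if s == MISSING else float(s)


def _parse_int(s: str) -> Optional[int]:
    return None if s == MISSING else int(s)


def _parse_str(s: str) -> Optional[str]:
    return None if s == MISSING else s


# (header, attribute, serializer, parser)
_COLUMNS = [
    ("ID", "variant_id", _fmt_str, str),
    ("Gene", "gene", _fmt_str, str),
    ("AA Change", "aa_change", _fmt_str, str),
    ("Pos", "pos_in_peptide", _fmt_str, str),
    ("Best Peptide", "best_peptide", _fmt_str, str),
    ("Best WT Peptide", "best_wt_peptide", _fmt_str, _parse_str),
    ("Allele", "hla_allele", _fmt_str, _parse_str),
    ("IC50 MT", "ic50_mt", _fmt_float, _parse_float),
    ("IC50 WT", "ic50_wt", _fmt_float, _parse_float),
    ("Lowest IC50 MT", "lowest_ic50_mt", _fmt_float, _parse_float),
    ("%ile MT", "percentile_mt", _fmt_float, _parse_float),
    ("RNA Expr", "gene_expr", _fmt_float, _parse_float),
    ("RNA VAF", "rna_vaf", _fmt_float, _parse_float),
    ("Allele Expr", "allele_expr", _fmt_float, _parse_float),
    ("RNA Depth", "rna_depth", _fmt_int, _parse_int),
    ("DNA VAF", "dna_vaf", _fmt_float, _parse_float),
    ("TSL", "tsl", _fmt_int, _parse_int),
    ("Num Passing Peptides", "n_passing_peptides", _fmt_int, int),
    (
        "Anchor Overlap",
        "anchor_overlap",
        lambda v: MISSING if v is None else v.value,
        lambda s: None if s == MISSING else AnchorOverlap(s),
    ),
    ("Tier", "tier", lambda v: v.value, Tier),
    ("Eval", "evaluation", lambda v: v.value, Evaluation),
    ("Gene of Interest", "gene_of_interest", lambda v: str(bool(v)), lambda s: s == "True"),
]

MANDATORY_HEADERS = [h for h, *_ in _COLUMNS]


def _row_values(row: AggregateRow) -> list[str]:
    return [fmt(getattr(row, attr)) for _, attr, fmt, _ in _COLUMNS]


def write_aggregate(
    rows: Sequence[AggregateRow], path: Union[str, Path], format: str = "tsv"
) -> None:
    """Write the aggregate report as TSV (round-trippable) or xlsx (one-way)."""
    path = Path(path)
    extra_headers: list[str] = []
    for r in rows:
        for k in r.extras:
            if k not in extra_headers:
                extra_headers.append(k)
    header = MANDATORY_HEADERS + extra_headers
    table = [
        _row_values(r) + [r.extras.get(k, MISSING) for k in extra_headers] for r in rows
    ]
    if format == "tsv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            w.writerows(table)
    elif format in ("xlsx", "spreadsheet", "excel"):
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "Aggregate Report"
        ws.append(header)
        for vals in table:
            ws.append(vals)
        wb.save(path)
    else:
        raise InvalidArgumentError(f"unknown export format {format!r}")


def read_aggregate(path: Union[str, Path]) -> list[AggregateRow]:
    """Load an aggregate report TSV, preserving unknown columns verbatim."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("aggregate TSV is empty") from None
        missing = [h for h in MANDATORY_HEADERS if h not in header]
        if missing:
            raise SchemaError(f"aggregate TSV missing mandatory columns: {missing}")
        idx = {h: header.index(h) for h in MANDATORY_HEADERS}
        extra_headers = [h for h in header if h not in idx]
        extra_idx = [(h, header.index(h)) for h in extra_headers]
        rows = []
        for line in reader:
            kwargs = {
                attr: parse(line[idx[h]]) for h, attr, _, parse in _COLUMNS
            }
            kwargs["extras"] = {h: line[i] for h, i in extra_idx}
            rows.append(AggregateRow(**kwargs))
    return rows


# ---------------------------------------------------------------------------
# Metrics JSON

METRICS_VERSION = 1


@dataclass
class VariantMetrics:
    """Drill-down detail for one variant: transcript sets, score grids, anchors."""

    transcript_sets: list[TranscriptSet]
    # mt_peptide -> allele -> algorithm -> {"ic50_mt", "ic50_wt", "percentile_mt",
    #                                       "percentile_wt", "score_class"}
    peptide_scores: dict[str, dict[str, dict[str, dict]]]
    # "allele|length" -> probability vector
    anchors: dict[str, list[float]]


@dataclass
class MetricsDocument:
    variants: dict[str, VariantMetrics]
    version: int = METRICS_VERSION


def _pair_to_dict(p: PeptidePair) -> dict:
    return {
        "mt_peptide": p.mt_peptide,
        "wt_peptide": p.wt_peptide,
        "length": p.length,
        "mutation_positions": sorted(p.mutation_positions),
        "transcript_ids": list(p.transcript_ids),
    }


def _pair_from_dict(d: Mapping) -> PeptidePair:
    return PeptidePair(
        mt_peptide=d["mt_peptide"],
        wt_peptide=d.get("wt_peptide"),
        length=d["length"],
        mutation_positions=frozenset(d["mutation_positions"]),
        transcript_ids=tuple(d.get("transcript_ids", ())),
    )


def _tset_to_dict(t: TranscriptSet) -> dict:
    return {
        "set_id": t.set_id,
        "transcript_ids": list(t.transcript_ids),
        "peptides": [_pair_to_dict(p) for p in t.peptides],
        "total_expression": t.total_expression,
        "best_tsl": t.best_tsl,
    }


def _tset_from_dict(d: Mapping) -> TranscriptSet:
    return TranscriptSet(
        set_id=d["set_id"],
        transcript_ids=tuple(d["transcript_ids"]),
        peptides=tuple(_pair_from_dict(p) for p in d["peptides"]),
        total_expression=d["total_expression"],
        best_tsl=d.get("best_tsl"),
    )


def write_metrics(doc: MetricsDocument, path: Union[str, Path]) -> None:
    payload = {
        "version": doc.version,
        "variants": {
            vid: {
                "transcript_sets": [_tset_to_dict(t) for t in vm.transcript_sets],
                "peptide_scores": vm.peptide_scores,
                "anchors": vm.anchors,
            }
            for vid, vm in doc.variants.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_metrics(path: Union[str, Path]) -> MetricsDocument:
    """Load and validate a metrics JSON document."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"metrics file is not valid JSON: {e}") from e
    if not isinstance(payload, dict) or "variants" not in payload:
        raise SchemaError("metrics JSON must be an object with a 'variants' map")
    variants: dict[str, VariantMetrics] = {}
    for vid, vm in payload["variants"].items():
        for key in ("transcript_sets", "peptide_scores", "anchors"):
            if key not in vm:
                raise SchemaError(f"metrics entry for {vid} lacks '{key}'")
        for akey, probs in vm["anchors"].items():
            allele, _, length = akey.rpartition("|")
            AnchorMatrix(allele, int(length), tuple(probs))  # validates
        variants[vid] = VariantMetrics(
            transcript_sets=[_tset_from_dict(t) for t in vm["transcript_sets"]],
            peptide_scores=vm["peptide_scores"],
            anchors={k: list(v) for k, v in vm["anchors"].items()},
        )
    return MetricsDocument(variants=variants, version=payload.get("version", METRICS_VERSION))


def reconcile(rows: Sequence[AggregateRow], doc: MetricsDocument) -> list[str]:
    """Cross-reference the aggregate rows against the metrics document.

    Returns one warning string per variant present in only one of the two.
    """
    in_rows = {r.variant_id for r in rows}
    in_doc = set(doc.variants)
    warnings = [
        f"variant {v} present in aggregate report but missing from metrics"
        for v in sorted(in_rows - in_doc)
    ]
    warnings += [
        f"variant {v} present in metrics but missing from aggregate report"
        for v in sorted(in_doc - in_rows)
    ]
    return warnings


# ---------------------------------------------------------------------------
# Supplementary class merge, gene flags, evaluations

SUPPLEMENTARY_COLUMNS = ("Best Peptide", "Allele", "IC50 MT", "%ile MT", "Tier")


def merge_supplementary_class(
    rows: Sequence[AggregateRow],
    supplement: Union[str, Path, Sequence[AggregateRow]],
    label: str = "Class II",
) -> list[AggregateRow]:
    """Annotate rows with the other MHC class's median binding summary.

    Left join on variant id: every input row comes back (same order), with
    ``"<col> (<label>)"`` extras taken from the matching supplementary row
    or "NA" when the variant has no counterpart.
    """
    if isinstance(supplement, (str, Path)):
        supplement = read_aggregate(supplement)
    by_id = {r.variant_id: r for r in supplement}
    serializers = {h: fmt for h, _, fmt, _ in _COLUMNS}
    attrs = {h: attr for h, attr, _, _ in _COLUMNS}
    out = []
    for r in rows:
        extras = dict(r.extras)
        s = by_id.get(r.variant_id)
        for col in SUPPLEMENTARY_COLUMNS:
            extras[f"{col} ({label})"] = (
                serializers[col](getattr(s, attrs[col])) if s is not None else MISSING
            )
        out.append(dataclasses.replace(r, extras=extras))
    return out


def flag_genes_of_interest(
    rows: Sequence[AggregateRow], genes: Union[str, Path, Iterable[str]]
) -> list[AggregateRow]:
    """Mark rows whose gene symbol appears (exact, case-sensitive) in the list."""
    if isinstance(genes, (str, Path)):
        wanted = {
            line.strip() for line in Path(genes).read_text().splitlines() if line.strip()
        }
    else:
        wanted = set(genes)
    out = [dataclasses.replace(r, gene_of_interest=r.gene in wanted) for r in rows]
    n = sum(r.gene_of_interest for r in out)
    log.info("genes of interest: %d of %d rows flagged", n, len(out))
    return out


@dataclass(frozen=True)
class EvaluationState:
    accept: int
    reject: int
    review: int
    pending: int

    @property
    def total(self) -> int:
        return self.accept + self.reject + self.review + self.pending


def evaluation_summary(rows: Sequence[AggregateRow]) -> EvaluationState:
    counts = {e: 0 for e in Evaluation}
    for r in rows:
        counts[r.evaluation] += 1
    return EvaluationState(
        accept=counts[Evaluation.ACCEPT],
        reject=counts[Evaluation.REJECT],
        review=counts[Evaluation.REVIEW],
        pending=counts[Evaluation.PENDING],
    )


def set_evaluation(
    rows: Sequence[AggregateRow], variant_id: str, value: Union[str, Evaluation]
) -> None:
    """Record the reviewer's call for one variant (the module's only row mutation)."""
    value = Evaluation(value)
    for r in rows:
        if r.variant_id == variant_id:
            r.evaluation = value
            return
    raise KeyError(f"variant {variant_id!r} not found in aggregate rows")


# ---------------------------------------------------------------------------
# Anchor heatmap data and custom-table grouping


@dataclass(frozen=True)
class AnchorPairView:
    """One MT/WT pair prepared for the anchor heatmap."""

    mt_peptide: str
    wt_peptide: Optional[str]
    hla_allele: Optional[str]
    length: int
    metric_ic50: float
    probabilities: Optional[tuple[float, ...]]
    mutation_positions: frozenset[int]


def top_anchor_pairs(
    summaries: Sequence[PeptideSummary],
    anchors: Mapping[tuple[str, int], AnchorMatrix],
    cfg: AggregationConfig = AggregationConfig(),
    k: int = 30,
    pairs: Optional[Mapping[str, PeptidePair]] = None,
) -> list[AnchorPairView]:
    """The best ``k`` MT/WT pairs with anchor probabilities attached.

    Ordered by the configured aggregate metric at each pair's best allele
    (ascending IC50, i.e. best first; lexicographic peptide tie-break).
    Probabilities are matched by (best allele, peptide length); pairs whose
    combination has no matrix carry ``None``. Mutated positions come from
    the optional peptide-pair map.
    """
    if k < 0:
        raise InvalidArgumentError("k must be >= 0")
    ranked = sorted(summaries, key=lambda s: (s.best_metric(cfg), s.mt_peptide))[:k]
    views = []
    for s in ranked:
        length = len(s.mt_peptide)
        m = anchors.get((s.best_allele, length)) if s.best_allele is not None else None
        muts: frozenset[int] = frozenset()
        if pairs is not None and s.mt_peptide in pairs:
            muts = pairs[s.mt_peptide].mutation_positions
        views.append(
            AnchorPairView(
                mt_peptide=s.mt_peptide,
                wt_peptide=s.wt_peptide,
                hla_allele=s.best_allele,
                length=length,
                metric_ic50=s.best_metric(cfg),
                probabilities=m.probabilities if m is not None else None,
                mutation_positions=muts,
            )
        )
    return views


@dataclass
class CustomTableGroups:
    """Result of grouping a custom feature table."""

    group_by: str
    sort_by: str
    display_cols: list[str]
    groups: dict  # group key -> sorted DataFrame
    representatives: pd.DataFrame  # one best-sorted row per group


def group_custom_table(
    table: pd.DataFrame,
    group_by: str,
    sort_by: str,
    display_cols: Optional[Sequence[str]] = None,
    ascending: bool = True,
) -> CustomTableGroups:
    """Group a user-supplied peptide feature table and pick representatives.

    Rows are grouped by ``group_by``, ordered within each group by
    ``sort_by`` (ascending by default, for score-like columns where lower
    is better), and the best-sorted row of each group becomes its
    representative. Displayed columns default to everything except the
    grouping and sorting columns.
    """
    for col in (group_by, sort_by):
        if col not in table.columns:
            raise SchemaError(f"column {col!r} not present in custom table")
    if display_cols is None:
        display_cols = [c for c in table.columns if c not in (group_by, sort_by)]
    else:
        missing = [c for c in display_cols if c not in table.columns]
        if missing:
            raise SchemaError(f"display columns not present in custom table: {missing}")
    groups: dict = {}
    reps = []
    for key in sorted(table[group_by].unique()):
        sub = (
            table[table[group_by] == key]
            .sort_values(sort_by, ascending=ascending, kind="stable")
            .reset_index(drop=True)
        )
        groups[key] = sub
        reps.append(sub.iloc[0][[group_by] + list(display_cols)])
    representatives = pd.DataFrame(reps).reset_index(drop=True)
    return CustomTableGroups(
        group_by=group_by,
        sort_by=sort_by,
        display_cols=list(display_cols),
        groups=groups,
        representatives=representatives,
    )
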