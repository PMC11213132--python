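"""Ensemble aggregation of per-algorithm MHC binding predictions.

Binding predictors disagree; rather than trusting any single algorithm, the
per-peptide summary takes the median (or lowest) IC50 and percentile rank
across all algorithms that scored a given peptide-allele pair. A peptide
"passes binding" for an allele when the configured aggregate IC50 is at or
below the recommended 500 nM cutoff (percentile rank <= 2 can be combined
via a configurable rule). Orthogonal predictors trained on peptide elution
mass spectrometry or immunogenicity data report scores in [0, 1] and are
kept in a separate advisory table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Optional, Sequence

import pandas as pd

from .errors import InvalidArgumentError, ValidationError

log = logging.getLogger(__name__)

#: Algorithm-count capacities per MHC class (binding-class algorithms).
MAX_BINDING_ALGORITHMS = {"I": 8, "II": 4}


class ScoreClass(str, Enum):
    BINDING = "binding"
    ELUTION = "elution"
    IMMUNOGENICITY = "immunogenicity"


@dataclass(frozen=True)
class BindingRecord:
    """One (peptide, HLA allele, algorithm) prediction.

    For ``score_class`` other than binding, the ``ic50_mt``/``ic50_wt``
    fields hold the predictor's score in [0, 1] (bound enforced when the
    orthogonal table is assembled, so that a bad record can be rejected
    with a message naming it).
    """

    mt_peptide: str
    hla_allele: str
    algorithm: str
    wt_peptide: Optional[str] = None
    ic50_mt: Optional[float] = None
    ic50_wt: Optional[float] = None
    percentile_mt: Optional[float] = None
    percentile_wt: Optional[float] = None
    score_class: ScoreClass = ScoreClass.BINDING

    def __post_init__(self) -> None:
        object.__setattr__(self, "score_class", ScoreClass(self.score_class))
        if self.score_class is ScoreClass.BINDING:
            for name, v in (("ic50_mt", self.ic50_mt), ("ic50_wt", self.ic50_wt)):
                if v is not None and v <= 0:
                    raise InvalidArgumentError(f"{name} must be strictly positive, got {v}")
        for name, v in (
            ("percentile_mt", self.percentile_mt),
            ("percentile_wt", self.percentile_wt),
        ):
            if v is not None and not (0 <= v <= 100):
                raise InvalidArgumentError(f"{name} must lie in [0, 100], got {v}")


@dataclass(frozen=True)
class AggregationConfig:
    """How per-algorithm scores are collapsed and thresholded.

    ``metric`` selects median or lowest IC50 as the aggregate.
    ``percentile_rule`` controls whether the percentile-rank cutoff is
    ignored ("off", default), required in addition ("and"), or accepted as
    an alternative ("or") to the IC50 cutoff.
    """

    metric: str = "median"
    ic50_threshold: float = 500.0
    percentile_threshold: float = 2.0
    percentile_rule: str = "off"

    def __post_init__(self) -> None:
        if self.metric not in ("median", "lowest"):
            raise InvalidArgumentError(f"metric must be 'median' or 'lowest', got {self.metric!r}")
        if self.ic50_threshold <= 0 or self.percentile_threshold <= 0:
            raise InvalidArgumentError("thresholds must be positive")
        if self.percentile_rule not in ("off", "and", "or"):
            raise InvalidArgumentError("percentile_rule must be 'off', 'and' or 'or'")


@dataclass(frozen=True)
class AlleleSummary:
    median_ic50_mt: Optional[float]
    lowest_ic50_mt: Optional[float]
    median_percentile_mt: Optional[float]
    median_ic50_wt: Optional[float]
    median_percentile_wt: Optional[float]
    n_algorithms: int
    passes_binding: bool

    def metric_ic50(self, cfg: AggregationConfig) -> Optional[float]:
        return self.median_ic50_mt if cfg.metric == "median" else self.lowest_ic50_mt


@dataclass(frozen=True)
class PeptideSummary:
    """Per-allele aggregate scores for one MT/WT peptide pair."""

    mt_peptide: str
    wt_peptide: Optional[str]
    per_allele: dict[str, AlleleSummary]
    best_allele: Optional[str]

    def best_metric(self, cfg: AggregationConfig) -> float:
        """Aggregate MT IC50 at the best allele (+inf when unscored)."""
        if self.best_allele is None:
            return math.inf
        v = self.per_allele[self.best_allele].metric_ic50(cfg)
        return math.inf if v is None else v

    def passes_any_allele(self) -> bool:
        return any(a.passes_binding for a in self.per_allele.values())


def _passes(
    metric_ic50: Optional[float], median_pct: Optional[float], cfg: AggregationConfig
) -> bool:
    if metric_ic50 is None:
        return False
    ic50_ok = metric_ic50 <= cfg.ic50_threshold
    if cfg.percentile_rule == "off" or median_pct is None:
        return ic50_ok
    pct_ok = median_pct <= cfg.percentile_threshold
    return (ic50_ok and pct_ok) if cfg.percentile_rule == "and" else (ic50_ok or pct_ok)


def summarize_peptide(
    records: Sequence[BindingRecord], cfg: AggregationConfig = AggregationConfig()
) -> PeptideSummary:
    """Collapse an MT/WT pair's binding records into per-allele aggregates.

    Medians and minima are taken over non-missing binding-class scores per
    allele (missing algorithm outputs are omitted, not imputed). The best
    allele minimizes the configured aggregate MT IC50. WT aggregates are
    reported only for alleles where the MT score passes the binding
    threshold.
    """
    if not records:
        raise InvalidArgumentError("no records supplied")
    peptides = {r.mt_peptide for r in records}
    if len(peptides) != 1:
        raise InvalidArgumentError(f"records mix mt_peptides: {sorted(peptides)}")
    binding = [r for r in records if r.score_class is ScoreClass.BINDING]
    if not binding:
        raise InvalidArgumentError("at least one binding-class record is required")

    wt = next((r.wt_peptide for r in binding if r.wt_peptide is not None), None)
    per_allele: dict[str, AlleleSummary] = {}
    for allele in sorted({r.hla_allele for r in binding}):
        recs = [r for r in binding if r.hla_allele == allele]
        ic50s = sorted(r.ic50_mt for r in recs if r.ic50_mt is not None)
        pcts = [r.percentile_mt for r in recs if r.percentile_mt is not None]
        wt_ic50s = [r.ic50_wt for r in recs if r.ic50_wt is not None]
        wt_pcts = [r.percentile_wt for r in recs if r.percentile_wt is not None]
        med = median(ic50s) if ic50s else None
        low = ic50s[0] if ic50s else None
        med_pct = median(pcts) if pcts else None
        metric = med if cfg.metric == "median" else low
        ok = _passes(metric, med_pct, cfg)
        per_allele[allele] = AlleleSummary(
            median_ic50_mt=med,
            lowest_ic50_mt=low,
            median_percentile_mt=med_pct,
            median_ic50_wt=median(wt_ic50s) if (wt_ic50s and ok) else None,
            median_percentile_wt=median(wt_pcts) if (wt_pcts and ok) else None,
            n_algorithms=len({r.algorithm for r in recs}),
            passes_binding=ok,
        )
    scored = [
        (s.metric_ic50(cfg), allele)
        for allele, s in per_allele.items()
        if s.metric_ic50(cfg) is not None
    ]
    best_allele = min(scored)[1] if scored else None
    return PeptideSummary(
        mt_peptide=binding[0].mt_peptide,
        wt_peptide=wt,
        per_allele=per_allele,
        best_allele=best_allele,
    )


def select_best_peptide(
    summaries: Sequence[PeptideSummary], cfg: AggregationConfig = AggregationConfig()
) -> tuple[PeptideSummary, int]:
    """The variant's best peptide plus the count of other passing peptides.

    Best = minimum configured aggregate MT IC50 at each summary's best
    allele; ties broken lexicographically on the mutant peptide string.
    The count covers the remaining summaries that pass thresholds on at
    least one allele.
    """
    if not summaries:
        raise InvalidArgumentError("no peptide summaries supplied")
    best = min(summaries, key=lambda s: (s.best_metric(cfg), s.mt_peptide))
    n_extra = sum(1 for s in summaries if s is not best and s.passes_any_allele())
    return best, n_extra


def _one_pair(records: Sequence[BindingRecord]) -> None:
    if len({r.mt_peptide for r in records}) > 1:
        raise InvalidArgumentError("records span multiple peptides; supply one pair at a time")


_BINDING_COLS = ["hla_allele", "algorithm", "ic50_mt", "ic50_wt", "percentile_mt", "percentile_wt"]


def assemble_binding_table(
    records: Sequence[BindingRecord],
    cfg: AggregationConfig = AggregationConfig(),
    restrict_to_binding_alleles: bool = False,
) -> pd.DataFrame:
    """Per-algorithm IC50/percentile grid for one MT/WT pair.

    One row per (allele, algorithm) with explicit NaN for missing cells.
    With ``restrict_to_binding_alleles``, only alleles with at least one
    predicted strong binder (any algorithm's MT IC50 at or below the
    configured threshold) are retained.
    """
    _one_pair(records)
    binding = [r for r in records if r.score_class is ScoreClass.BINDING]
    if restrict_to_binding_alleles:
        strong = {
            r.hla_allele
            for r in binding
            if r.ic50_mt is not None and r.ic50_mt <= cfg.ic50_threshold
        }
        binding = [r for r in binding if r.hla_allele in strong]
    rows = [
        {
            "hla_allele": r.hla_allele,
            "algorithm": r.algorithm,
            "ic50_mt": r.ic50_mt,
            "ic50_wt": r.ic50_wt,
            "percentile_mt": r.percentile_mt,
            "percentile_wt": r.percentile_wt,
        }
        for r in binding
    ]
    df = pd.DataFrame(rows, columns=_BINDING_COLS)
    return df.sort_values(["hla_allele", "algorithm"], kind="stable").reset_index(drop=True)


def assemble_orthogonal_table(records: Sequence[BindingRecord]) -> pd.DataFrame:
    """Elution and immunogenicity scores for one pair, sectioned by class.

    Scores live in [0, 1]; a violation raises naming the offending record.
    """
    _one_pair(records)
    rows = []
    for r in records:
        if r.score_class is ScoreClass.BINDING:
            continue
        for name, v in (("MT", r.ic50_mt), ("WT", r.ic50_wt)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"{r.score_class.value} {name} score {v} for "
                    f"({r.mt_peptide}, {r.hla_allele}, {r.algorithm}) outside [0, 1]"
                )
        rows.append(
            {
                "score_class": r.score_class.value,
                "hla_allele": r.hla_allele,
                "algorithm": r.algorithm,
                "score_mt": r.ic50_mt,
                "score_wt": r.ic50_wt,
            }
        )
    df = pd.DataFrame(rows, columns=["score_class", "hla_allele", "algorithm", "score_mt", "score_wt"])
    return df.sort_values(["score_class", "hla_allele", "algorithm"], kind="stable").reset_index(
        drop=True
    )


#: Column order of the per-epitope TSV interchange format.
EPITOPE_COLUMNS = [
    "chromosome",
    "position",
    "gene",
    "transcript_id",
    "mt_peptide",
    "wt_peptide",
    "hla_allele",
    "algorithm",
    "ic50_mt",
    "ic50_wt",
    "percentile_mt",
    "percentile_wt",
    "score_class",
]


def read_epitope_tsv(path) -> pd.DataFrame:
    """Load a per-epitope prediction TSV (missing values as empty fields)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=False, na_values=[""])
    missing = [c for c in EPITOPE_COLUMNS if c not in df.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"epitope TSV missing mandatory columns: {missing}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[BindingRecord]:
    """Turn epitope-TSV rows into :class:`BindingRecord` objects."""

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        BindingRecord(
            mt_peptide=row.mt_peptide,
            wt_peptide=None if pd.isna(row.wt_peptide) else row.wt_peptide,
            hla_allele=row.hla_allele,
            algorithm=row.algorithm,
            ic50_mt=opt(row.ic50_mt),
            ic50_wt=opt(row.ic50_wt),
            percentile_mt=opt(row.percentile_mt),
            percentile_wt=opt(row.percentile_wt),
            score_class=ScoreClass(row.score_class),
        )
        for row in df.itertuples(index=False)
    ]
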