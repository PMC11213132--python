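"""Variant tiering from binding, expression, clonality, TSL and anchor criteria.

Each variant's best peptide is judged against a battery of criteria:

* binding — the aggregate MT IC50 at the best allele within the cutoff
  (500 nM recommended), optionally combined with the percentile rank;
* expression — allele expression (gene TPM x RNA VAF) above a floor, with
  RNA VAF and RNA read depth sanity minima;
* clonality — DNA VAF consistent with the founding clone given tumor
  purity (expected heterozygous clonal VAF = purity / 2);
* transcript support level — best transcript annotated at the top TSL;
* anchor scenario — whether the mutation falls on MHC anchor residues and,
  if so, whether the wild-type peptide itself binds (in which case T cells
  are likely tolerized and the candidate is rejected).

A variant passing everything is tier Pass. A variant failing exactly one
of the anchor / clonality / expression categories (with binding and TSL
intact) gets the matching named tier — Anchor, Subclonal, LowExpr or
NoExpr — so the report shows what single repair would rescue it. Any
binding or TSL failure, or failures in several categories, is tier Poor.
Tiers are totally ordered for ranking; re-tiering under new thresholds or
a revised purity estimate is a pure function that never touches the
reviewer's accept/reject/review evaluations.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .aggregate import AggregationConfig, PeptideSummary
from .errors import InvalidArgumentError
from .peptides import PeptidePair


class Tier(str, Enum):
    """Suitability tiers, best to worst."""

    PASS = "Pass"
    ANCHOR = "Anchor"
    SUBCLONAL = "Subclonal"
    LOWEXPR = "LowExpr"
    NOEXPR = "NoExpr"
    POOR = "Poor"

    @property
    def order(self) -> int:
        return _TIER_ORDER[self]


_TIER_ORDER = {t: i for i, t in enumerate(Tier)}


class AnchorScenario(str, Enum):
    ACCEPT = "accept"
    REJECT_ANCHOR = "reject_anchor"
    UNKNOWN = "unknown"


class AnchorOverlap(str, Enum):
    """How the mutated positions relate to the allele's anchor positions."""

    NONE = "none"
    PARTIAL = "partial"
    ALL = "all"


class Clonality(str, Enum):
    FOUNDING = "founding"
    SUBCLONAL = "subclonal"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantMeasurements:
    """Expression/VAF/purity measurements backing the tiering criteria."""

    gene: str
    dna_vaf: float
    rna_vaf: Optional[float] = None
    rna_depth: Optional[int] = None
    gene_expr: float = 0.0
    tsl: Optional[int] = None
    tumor_purity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.dna_vaf <= 1):
            raise InvalidArgumentError("dna_vaf must lie in [0, 1]")
        if self.rna_vaf is not None and not (0 <= self.rna_vaf <= 1):
            raise InvalidArgumentError("rna_vaf must lie in [0, 1]")
        if self.rna_depth is not None and self.rna_depth < 0:
            raise InvalidArgumentError("rna_depth must be non-negative")
        if self.gene_expr < 0:
            raise InvalidArgumentError("gene_expr must be non-negative")
        if self.tumor_purity is not None and not (0 < self.tumor_purity <= 1):
            raise InvalidArgumentError("tumor_purity must lie in (0, 1]")

    @property
    def allele_expr(self) -> Optional[float]:
        if self.rna_vaf is None:
            return None
        return compute_allele_expr(self.gene_expr, self.rna_vaf)


@dataclass(frozen=True)
class AnchorMatrix:
    """Normalized per-position anchor probabilities for one (allele, length)."""

    hla_allele: str
    length: int
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probabilities)
        object.__setattr__(self, "probabilities", probs)
        if len(probs) != self.length:
            raise InvalidArgumentError(
                f"anchor vector for {self.hla_allele} has {len(probs)} entries, expected {self.length}"
            )
        if any(p < 0 for p in probs):
            raise InvalidArgumentError("anchor probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise InvalidArgumentError(
                f"anchor probabilities for {self.hla_allele}|{self.length} sum to {sum(probs)}, not 1"
            )


@dataclass(frozen=True)
class TierConfig:
    """Thresholds driving tier assignment; all adjustable at re-tier time."""

    ic50_threshold: float = 500.0
    percentile_threshold: float = 2.0
    percentile_rule: str = "off"
    metric: str = "median"
    allele_expr_threshold: float = 2.5
    rna_vaf_min: float = 0.01
    rna_depth_min: int = 10
    tsl_max: int = 1
    clonality_fraction: float = 0.5
    anchor_contribution_threshold: float = 0.8
    wt_ic50_threshold: Optional[float] = None  # None -> ic50_threshold

    def __post_init__(self) -> None:
        for name in (
            "ic50_threshold",
            "percentile_threshold",
            "allele_expr_threshold",
            "clonality_fraction",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not (0 < self.anchor_contribution_threshold <= 1):
            raise InvalidArgumentError("anchor_contribution_threshold must lie in (0, 1]")

    @property
    def effective_wt_threshold(self) -> float:
        return self.ic50_threshold if self.wt_ic50_threshold is None else self.wt_ic50_threshold

    def aggregation(self) -> AggregationConfig:
        return AggregationConfig(
            metric=self.metric,
            ic50_threshold=self.ic50_threshold,
            percentile_threshold=self.percentile_threshold,
            percentile_rule=self.percentile_rule,
        )


@dataclass(frozen=True)
class TierResult:
    tier: Tier
    failing_criteria: tuple[str, ...]
    rank_key: tuple[float, float, float]


def anchor_key(hla_allele: str, length: int) -> str:
    return f"{hla_allele}|{length}"


def load_anchor_matrices(path) -> dict[tuple[str, int], AnchorMatrix]:
    """Load anchor matrices from a JSON map of "allele|length" -> probabilities."""
    import json
    from pathlib import Path

    from .errors import SchemaError

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"anchor file is not valid JSON: {e}") from e
    if not isinstance(payload, dict):
        raise SchemaError("anchor JSON must map 'allele|length' to probability arrays")
    out: dict[tuple[str, int], AnchorMatrix] = {}
    for key, probs in payload.items():
        allele, _, length = key.rpartition("|")
        if not allele or not length.isdigit():
            raise SchemaError(f"malformed anchor key {key!r}; expected 'allele|length'")
        out[(allele, int(length))] = AnchorMatrix(allele, int(length), tuple(probs))
    return out


def save_anchor_matrices(matrices: Mapping[tuple[str, int], AnchorMatrix], path) -> None:
    import json
    from pathlib import Path

    payload = {
        anchor_key(a, l): list(m.probabilities) for (a, l), m in sorted(matrices.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def compute_allele_expr(gene_expr: float, rna_vaf: Optional[float]) -> Optional[float]:
    """Expression attributable to the mutant allele: gene TPM x RNA VAF."""
    if rna_vaf is None:
        return None
    if not (0 <= rna_vaf <= 1):
        raise InvalidArgumentError("rna_vaf must lie in [0, 1]")
    if gene_expr < 0:
        raise InvalidArgumentError("gene_expr must be non-negative")
    return gene_expr * rna_vaf


def determine_anchor_positions(
    m: AnchorMatrix, contribution_threshold: float = 0.8
) -> frozenset[int]:
    """Smallest greedy set of positions whose anchor mass reaches the threshold.

    Positions are taken in order of descending probability (lower index
    first on ties) until the cumulative probability is at least
    ``contribution_threshold``.
    """
    if not (0 < contribution_threshold <= 1):
        raise InvalidArgumentError("contribution_threshold must lie in (0, 1]")
    ranked = sorted(range(1, m.length + 1), key=lambda p: (-m.probabilities[p - 1], p))
    chosen: set[int] = set()
    total = 0.0
    for p in ranked:
        chosen.add(p)
        total += m.probabilities[p - 1]
        if total >= contribution_threshold - 1e-12:
            break
    return frozenset(chosen)


def anchor_overlap(
    mutation_positions: Iterable[int], anchors: frozenset[int] | set[int]
) -> AnchorOverlap:
    muts = set(mutation_positions)
    if not muts & set(anchors):
        return AnchorOverlap.NONE
    if muts <= set(anchors):
        return AnchorOverlap.ALL
    return AnchorOverlap.PARTIAL


def scenario_from_overlap(
    overlap: AnchorOverlap, wt_ic50: Optional[float], cfg: TierConfig = TierConfig()
) -> AnchorScenario:
    """Anchor-scenario decision given mutation/anchor overlap and WT binding.

    Mutation off-anchor (fully or partly) leaves the T-cell-facing surface
    altered: accept. Mutation confined to anchors with a well-binding WT
    peptide means the presented surface is self: reject. Anchor-confined
    mutation with a non-binding WT created the binding de novo: accept;
    with no WT measurement the call is unknown.
    """
    overlap = AnchorOverlap(overlap)
    if overlap is not AnchorOverlap.ALL:
        return AnchorScenario.ACCEPT
    if wt_ic50 is None:
        return AnchorScenario.UNKNOWN
    if wt_ic50 <= cfg.effective_wt_threshold:
        return AnchorScenario.REJECT_ANCHOR
    return AnchorScenario.ACCEPT


def evaluate_anchor_scenario(
    pair: PeptidePair,
    anchors: frozenset[int] | set[int],
    wt_ic50: Optional[float],
    cfg: TierConfig = TierConfig(),
) -> AnchorScenario:
    """Scenario for one peptide pair given the allele's anchor positions."""
    if not anchors:
        raise InvalidArgumentError("anchor set must be nonempty")
    if any(a < 1 or a > pair.length for a in anchors):
        raise InvalidArgumentError("anchor positions out of peptide bounds")
    return scenario_from_overlap(anchor_overlap(pair.mutation_positions, anchors), wt_ic50, cfg)


def classify_clonality(
    dna_vaf: float,
    tumor_purity: Optional[float] = None,
    cohort_max_vaf: Optional[float] = None,
    clonality_fraction: float = 0.5,
) -> Clonality:
    """Founding-clone vs subclonal call from DNA VAF.

    The reference clonal VAF is purity/2 (heterozygous diploid expectation)
    when purity is known, otherwise the maximum somatic DNA VAF observed in
    the sample. A variant is subclonal when its VAF falls strictly below
    ``clonality_fraction`` times the reference; the boundary is inclusive
    on the founding side. With neither reference available the call is
    unknown.
    """
    if not (0 <= dna_vaf <= 1):
        raise InvalidArgumentError("dna_vaf must lie in [0, 1]")
    if tumor_purity is not None:
        reference = tumor_purity / 2.0
    elif cohort_max_vaf is not None:
        reference = cohort_max_vaf
    else:
        return Clonality.UNKNOWN
    return Clonality.SUBCLONAL if dna_vaf < clonality_fraction * reference else Clonality.FOUNDING


# criterion name -> tier category it belongs to
_CRITERION_CATEGORY = {
    "binding": Tier.POOR,
    "tsl": Tier.POOR,
    "no_expression": Tier.NOEXPR,
    "low_expression": Tier.LOWEXPR,
    "low_rna_vaf": Tier.LOWEXPR,
    "low_rna_depth": Tier.LOWEXPR,
    "subclonal": Tier.SUBCLONAL,
    "anchor": Tier.ANCHOR,
}


def _binding_fails(
    metric_ic50: Optional[float], median_pct: Optional[float], cfg: TierConfig
) -> bool:
    if metric_ic50 is None:
        return True
    ic50_ok = metric_ic50 <= cfg.ic50_threshold
    if cfg.percentile_rule == "off" or median_pct is None:
        return not ic50_ok
    pct_ok = median_pct <= cfg.percentile_threshold
    ok = (ic50_ok and pct_ok) if cfg.percentile_rule == "and" else (ic50_ok or pct_ok)
    return not ok


def _tier_from_criteria(failing: Sequence[str]) -> Tier:
    if not failing:
        return Tier.PASS
    cats = {_CRITERION_CATEGORY[c] for c in failing}
    if Tier.POOR in cats or len(cats) > 1:
        return Tier.POOR
    return next(iter(cats))


def _evaluate_criteria(
    metric_ic50: Optional[float],
    median_pct: Optional[float],
    allele_expr: Optional[float],
    rna_vaf: Optional[float],
    rna_depth: Optional[int],
    tsl: Optional[int],
    scenario: AnchorScenario,
    clonality: Clonality,
    cfg: TierConfig,
) -> TierResult:
    failing: list[str] = []
    if _binding_fails(metric_ic50, median_pct, cfg):
        failing.append("binding")
    if tsl is None or tsl > cfg.tsl_max:
        failing.append("tsl")
    if allele_expr is None or allele_expr == 0:
        failing.append("no_expression")
    else:
        if allele_expr < cfg.allele_expr_threshold:
            failing.append("low_expression")
        if rna_vaf is not None and rna_vaf < cfg.rna_vaf_min:
            failing.append("low_rna_vaf")
        if rna_depth is not None and rna_depth < cfg.rna_depth_min:
            failing.append("low_rna_depth")
    if Clonality(clonality) is Clonality.SUBCLONAL:
        failing.append("subclonal")
    if AnchorScenario(scenario) is AnchorScenario.REJECT_ANCHOR:
        failing.append("anchor")
    tier = _tier_from_criteria(failing)
    rank_key = (
        float(tier.order),
        -(allele_expr if allele_expr is not None else 0.0),
        metric_ic50 if metric_ic50 is not None else math.inf,
    )
    return TierResult(tier=tier, failing_criteria=tuple(failing), rank_key=rank_key)


def assign_tier(
    summary: PeptideSummary,
    meas: VariantMeasurements,
    scenario: AnchorScenario,
    clonality: Clonality,
    cfg: TierConfig = TierConfig(),
) -> TierResult:
    """Tier a variant from its best peptide's summary and its measurements.

    Every failed criterion is recorded in ``failing_criteria`` regardless
    of the tier assigned; the ranking key orders rows by tier, then by
    allele expression (descending), then aggregate MT IC50 (ascending).
    """
    agg = cfg.aggregation()
    if summary.best_allele is not None:
        al = summary.per_allele[summary.best_allele]
        metric_ic50 = al.metric_ic50(agg)
        median_pct = al.median_percentile_mt
    else:
        metric_ic50 = None
        median_pct = None
    return _evaluate_criteria(
        metric_ic50,
        median_pct,
        meas.allele_expr,
        meas.rna_vaf,
        meas.rna_depth,
        meas.tsl,
        scenario,
        clonality,
        cfg,
    )


def retier(
    rows: Sequence,
    cfg: TierConfig = TierConfig(),
    tumor_purity: Optional[float] = None,
    cohort_max_vaf: Optional[float] = None,
):
    """Recompute tiers of aggregate rows under new thresholds or purity.

    Pure: returns new rows, leaving inputs — including accept/reject/review
    evaluations — untouched. Clonality is re-derived from each row's DNA
    VAF and the supplied purity (or the maximum DNA VAF across the rows
    when purity is absent); the anchor scenario is re-derived from the
    stored mutation/anchor overlap and WT IC50.
    """
    rows = list(rows)
    if tumor_purity is None and cohort_max_vaf is None and rows:
        vafs = [r.dna_vaf for r in rows if r.dna_vaf is not None]
        cohort_max_vaf = max(vafs) if vafs else None
    out = []
    for r in rows:
        clonality = (
            classify_clonality(r.dna_vaf, tumor_purity, cohort_max_vaf, cfg.clonality_fraction)
            if r.dna_vaf is not None
            else Clonality.UNKNOWN
        )
        scenario = scenario_from_overlap(
            AnchorOverlap(r.anchor_overlap) if r.anchor_overlap is not None else AnchorOverlap.NONE,
            r.ic50_wt,
            cfg,
        )
        if cfg.metric == "lowest" and getattr(r, "lowest_ic50_mt", None) is not None:
            metric_val = r.lowest_ic50_mt
        else:
            metric_val = r.ic50_mt
        result = _evaluate_criteria(
            metric_val,
            r.percentile_mt,
            r.allele_expr,
            r.rna_vaf,
            r.rna_depth,
            r.tsl,
            scenario,
            clonality,
            cfg,
        )
        out.append(dataclasses.replace(r, tier=result.tier))
    return out
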