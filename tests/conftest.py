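import numpy as np
import pytest

from neotier import (
    AggregationConfig,
    AlleleSummary,
    BindingRecord,
    FixtureSpec,
    PeptideSummary,
    ProteinContext,
    make_report_pair,
)


def make_missense_context(flank_left=12, flank_right=12, transcript_id="TX1", seed=0, **kw):
    """A protein with one interior missense substitution and given flanks."""
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVY"))  # W reserved for the mutant residue
    wt = "".join(rng.choice(aa, size=flank_left + 1 + flank_right))
    mt = wt[:flank_left] + "W" + wt[flank_left + 1 :]
    if wt[flank_left] == "W":  # cannot happen with W excluded, but keep the guard
        raise AssertionError
    return ProteinContext(
        transcript_id=transcript_id,
        wt_sequence=wt,
        mt_sequence=mt,
        variant_type="missense",
        mt_variant_start=flank_left + 1,
        mt_variant_end=flank_left + 1,
        **kw,
    )


def make_allele_summary(median_ic50, lowest_ic50=None, pct=None, wt_ic50=None, n_algorithms=4,
                        passes=None, threshold=500.0):
    lowest = lowest_ic50 if lowest_ic50 is not None else median_ic50
    if passes is None:
        passes = median_ic50 is not None and median_ic50 <= threshold
    return AlleleSummary(
        median_ic50_mt=median_ic50,
        lowest_ic50_mt=lowest,
        median_percentile_mt=pct,
        median_ic50_wt=wt_ic50,
        median_percentile_wt=None,
        n_algorithms=n_algorithms,
        passes_binding=passes,
    )


def make_summary(mt_peptide, per_allele, wt_peptide=None):
    best = None
    best_val = float("inf")
    for allele, s in per_allele.items():
        v = s.median_ic50_mt
        if v is not None and (v, allele) < (best_val, best or "~"):
            best, best_val = allele, v
    return PeptideSummary(
        mt_peptide=mt_peptide, wt_peptide=wt_peptide, per_allele=per_allele, best_allele=best
    )


def binding_records(mt_peptide, allele, ic50s, wt_peptide=None, wt_ic50s=None, pcts=None):
    recs = []
    for i, v in enumerate(ic50s):
        recs.append(
            BindingRecord(
                mt_peptide=mt_peptide,
                wt_peptide=wt_peptide,
                hla_allele=allele,
                algorithm=f"algo{i}",
                ic50_mt=v,
                ic50_wt=wt_ic50s[i] if wt_ic50s else None,
                percentile_mt=pcts[i] if pcts else None,
            )
        )
    return recs


@pytest.fixture(scope="session")
def demo_bundle():
    """The canonical small demo cohort (seed 42, 25 variants, class I)."""
    return make_report_pair(FixtureSpec())


@pytest.fixture
def agg_cfg():
    return AggregationConfig()
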