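"""Candidate peptide enumeration from somatic-variant protein contexts.

A somatic variant alters the protein product of every transcript that spans
it. Each altered transcript yields a family of short mutant (MT) peptides:
every window of a requested length (class I typically 8-11 residues) that
contains at least one altered residue, in every register. Where the variant
preserves reading frame, each MT window is paired with the wild-type (WT)
window at the same protein coordinates so that downstream binding
predictions can be contrasted. Transcripts that produce the identical list
of mutant peptides (e.g. isoforms differing only outside the variant
neighbourhood) are grouped into a single transcript set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import InvalidArgumentError

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default class I peptide lengths (8-11-mers).
CLASS_I_LENGTHS = frozenset({8, 9, 10, 11})
#: Default class II peptide lengths (12-18-mers, configurable).
CLASS_II_LENGTHS = frozenset(range(12, 19))


class VariantType(str, Enum):
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"

    @property
    def frame_preserving(self) -> bool:
        return self is not VariantType.FRAMESHIFT


@dataclass(frozen=True)
class ProteinContext:
    """Wild-type and mutant protein sequence for one transcript of a variant.

    Coordinates are 1-based within the mutant protein. ``mt_variant_start``
    and ``mt_variant_end`` delimit the altered residues; for a frameshift
    the end is the last residue before the stop codon. A ``*`` truncates
    enumeration (stop codon); residues at or past it are never windowed.
    """

    transcript_id: str
    wt_sequence: str
    mt_sequence: str
    variant_type: VariantType
    mt_variant_start: int
    mt_variant_end: int
    expression: float = 0.0
    tsl: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_type", VariantType(self.variant_type))
        for name, seq in (("wt_sequence", self.wt_sequence), ("mt_sequence", self.mt_sequence)):
            bad = set(seq) - CANONICAL_AA - {"*"}
            if bad:
                raise InvalidArgumentError(
                    f"{name} of {self.transcript_id} contains non-canonical letters {sorted(bad)}"
                )
        if not (1 <= self.mt_variant_start <= self.mt_variant_end <= len(self.mt_sequence)):
            raise InvalidArgumentError(
                f"variant interval [{self.mt_variant_start}, {self.mt_variant_end}] out of "
                f"bounds for mt_sequence of length {len(self.mt_sequence)}"
            )
        if self.variant_type is VariantType.MISSENSE:
            if self.mt_variant_start != self.mt_variant_end:
                raise InvalidArgumentError("missense variants alter exactly one residue")
            if len(self.wt_sequence) != len(self.mt_sequence):
                raise InvalidArgumentError("missense wt/mt sequences must have equal length")
            i = self.mt_variant_start - 1
            if self.wt_sequence[i] == self.mt_sequence[i] or any(
                w != m for j, (w, m) in enumerate(zip(self.wt_sequence, self.mt_sequence)) if j != i
            ):
                raise InvalidArgumentError(
                    "missense wt/mt sequences must differ at exactly the variant position"
                )
        if self.expression < 0:
            raise InvalidArgumentError("expression must be non-negative")
        if self.tsl is not None and self.tsl < 1:
            raise InvalidArgumentError("tsl must be a positive integer when present")


@dataclass(frozen=True)
class PeptidePair:
    """One MT/WT short-peptide pair at a given length and register.

    ``mutation_positions`` are 1-based within the peptide and cover every
    altered residue the window overlaps. ``wt_peptide`` is absent for
    frameshift-derived windows (no meaningful WT partner out of frame).
    """

    mt_peptide: str
    wt_peptide: Optional[str]
    length: int
    mutation_positions: frozenset[int]
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mt_peptide) != self.length:
            raise InvalidArgumentError("mt_peptide length mismatch")
        if not self.mutation_positions:
            raise InvalidArgumentError("mutation_positions must be nonempty")
        if any(p < 1 or p > self.length for p in self.mutation_positions):
            raise InvalidArgumentError("mutation_positions out of peptide bounds")
        if self.wt_peptide is not None and len(self.wt_peptide) != self.length:
            raise InvalidArgumentError("wt_peptide length mismatch")


@dataclass(frozen=True)
class TranscriptSet:
    """Transcripts of one variant yielding the identical mutant peptide list."""

    set_id: str
    transcript_ids: tuple[str, ...]
    peptides: tuple[PeptidePair, ...]
    total_expression: float
    best_tsl: Optional[int]


def _coding_prefix(seq: str) -> str:
    """Sequence up to (excluding) the first stop codon."""
    stop = seq.find("*")
    return seq if stop < 0 else seq[:stop]


def _validate_lengths(lengths: Iterable[int]) -> list[int]:
    ls = sorted(set(lengths))
    if not ls:
        raise InvalidArgumentError("lengths must be nonempty")
    if any(l < 1 for l in ls):
        raise InvalidArgumentError("peptide lengths must be >= 1")
    return ls


def enumerate_registers(ctx: ProteinContext, lengths: Iterable[int]) -> list[PeptidePair]:
    """All distinct MT peptides of the requested lengths covering the variant.

    Every in-bounds window of each length containing at least one altered
    residue is emitted, in every register. Frame-preserving variants pair
    each MT window with the same-coordinate WT window when it differs from
    the MT window; frameshift windows carry no WT partner. Windows yielding
    an identical mutant peptide (possible with sequence repeats) are merged,
    keeping the union of their mutation positions. A length exceeding the
    (stop-truncated) sequence contributes zero pairs.
    """
    ls = _validate_lengths(lengths)
    mt = _coding_prefix(ctx.mt_sequence)
    wt = _coding_prefix(ctx.wt_sequence)
    var_start = ctx.mt_variant_start
    var_end = min(ctx.mt_variant_end, len(mt))
    if var_start > len(mt):
        return []
    merged: dict[str, PeptidePair] = {}
    for l in ls:
        if l > len(mt):
            continue
        first = max(1, var_start - l + 1)
        last = min(var_end, len(mt) - l + 1)
        for s in range(first, last + 1):
            mt_pep = mt[s - 1 : s - 1 + l]
            muts = frozenset(
                p - s + 1 for p in range(max(var_start, s), min(var_end, s + l - 1) + 1)
            )
            wt_pep: Optional[str] = None
            if ctx.variant_type.frame_preserving:
                w = wt[s - 1 : s - 1 + l]
                if len(w) == l and w != mt_pep:
                    wt_pep = w
            prev = merged.get(mt_pep)
            if prev is None:
                merged[mt_pep] = PeptidePair(
                    mt_peptide=mt_pep,
                    wt_peptide=wt_pep,
                    length=l,
                    mutation_positions=muts,
                    transcript_ids=(ctx.transcript_id,),
                )
            else:
                merged[mt_pep] = replace(
                    prev, mutation_positions=prev.mutation_positions | muts
                )
    return list(merged.values())


def group_transcript_sets(
    contexts: Sequence[ProteinContext], lengths: Iterable[int]
) -> list[TranscriptSet]:
    """Partition one variant's transcripts by identical mutant-peptide multisets.

    Two transcripts share a set iff enumerating their registers yields the
    identical multiset of mutant peptide strings. The set id is the sorted,
    '+'-joined member transcript ids (deterministic); expression is summed
    and the best (minimum) TSL taken across members.
    """
    if not contexts:
        return []
    _validate_lengths(lengths)
    by_key: dict[tuple, list[tuple[ProteinContext, list[PeptidePair]]]] = {}
    order: list[tuple] = []
    for ctx in contexts:
        pairs = enumerate_registers(ctx, lengths)
        key = tuple(sorted(Counter(p.mt_peptide for p in pairs).items()))
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append((ctx, pairs))
    sets: list[TranscriptSet] = []
    for key in order:
        members = by_key[key]
        tids = tuple(sorted(c.transcript_id for c, _ in members))
        # peptide lists are identical across members; merge transcript ids in
        merged = [replace(p, transcript_ids=tids) for p in members[0][1]]
        tsls = [c.tsl for c, _ in members if c.tsl is not None]
        sets.append(
            TranscriptSet(
                set_id="+".join(tids),
                transcript_ids=tids,
                peptides=tuple(merged),
                total_expression=sum(c.expression for c, _ in members),
                best_tsl=min(tsls) if tsls else None,
            )
        )
    return sets


def count_prediction_space(n_peptides: int, n_alleles: int, n_algorithms: int) -> int:
    """Size of the (peptide, HLA allele, algorithm) prediction space."""
    for name, n in (
        ("n_peptides", n_peptides),
        ("n_alleles", n_alleles),
        ("n_algorithms", n_algorithms),
    ):
        if n < 0:
            raise InvalidArgumentError(f"{name} must be >= 0")
    return n_peptides * n_alleles * n_algorithms
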