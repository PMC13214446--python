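"""Classification of STR reads and consensus reads into PCR-error categories.

A sequence is compared with a reference (its UMI-family consensus, or the true
allele) in repeat space.  The categories are the five artefact classes seen in
UMI-based STR sequencing plus ``correct`` and a residual ``other``:

* ``n_minus_1`` / ``n_minus_2`` / ``n_plus_1`` — classic stutter: one repeat
  unit lost, two lost, or one gained, through slipped-strand mispairing;
* ``n_pm_0`` — simultaneous loss of units in one repeat stretch and gain in
  another, leaving total length unchanged;
* ``base_substitution`` — same length, one or more substituted bases;
* ``other`` — anything else (multi-unit stutters, indels that are not whole
  repeat units, combinations).

Both sequences are decomposed into motif blocks; when the block structures are
comparable the count vectors decide the class, otherwise a length-based
fallback (in units of the marker's dominant motif length) applies.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .panel import AlleleStructure, DecompositionFailure, MarkerDef


class ErrorClass(enum.Enum):
    CORRECT = "correct"
    N_MINUS_1 = "n_minus_1"
    N_MINUS_2 = "n_minus_2"
    N_PLUS_1 = "n_plus_1"
    N_PM_0 = "n_pm_0"
    BASE_SUBSTITUTION = "base_substitution"
    OTHER = "other"

    def __str__(self) -> str:
        return self.value


#: classes that count as stutter at the read/consensus summary level
STUTTER_CLASSES = frozenset(
    {ErrorClass.N_MINUS_1, ErrorClass.N_MINUS_2, ErrorClass.N_PLUS_1, ErrorClass.N_PM_0}
)


@dataclass(frozen=True)
class ClassifiedRead:
    """A sequence, the reference it was compared against, and the verdict."""

    seq_id: str
    ref_id: str
    error_class: ErrorClass
    unit_delta: Optional[int]  # (len(seq)-len(ref))/unit_length when integral
    block_deltas: Optional[tuple[int, ...]] = None  # per-block count differences
    substitution_count: Optional[int] = None
    ambiguous_reference: bool = False  # diploid truth: both alleles equidistant


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _subsequence_deltas(ref_blocks, seq_blocks) -> Optional[list[int]]:
    """Per-ref-block count deltas when seq's motif order is a subsequence of
    ref's (a block lost outright appears as a delta of -count).  Leftmost
    pairing; None when seq's blocks cannot be matched in order."""
    deltas = []
    j = 0
    for b in ref_blocks:
        if j < len(seq_blocks) and seq_blocks[j].motif == b.motif:
            deltas.append(seq_blocks[j].count - b.count)
            j += 1
        else:
            deltas.append(-b.count)
    return deltas if j == len(seq_blocks) else None


def _stutter_class(nonzero: list[int], dlen: int) -> Optional[ErrorClass]:
    """Map a nonzero block-delta pattern to a stutter class, if any."""
    if nonzero == [-1]:
        return ErrorClass.N_MINUS_1
    if nonzero == [-2] or nonzero == [-1, -1]:
        return ErrorClass.N_MINUS_2
    if nonzero == [1]:
        return ErrorClass.N_PLUS_1
    if len(nonzero) == 2 and sum(nonzero) == 0 and dlen == 0:
        # simultaneous loss and gain in different stretches; requiring the
        # length to be conserved guards blocks of unequal motif length
        return ErrorClass.N_PM_0
    return None


def classify(
    seq: str,
    ref: str,
    marker: MarkerDef,
    seq_id: str = "",
    ref_id: str = "",
) -> ClassifiedRead:
    """Classify ``seq`` against ``ref`` (both repeat regions of ``marker``).

    Decision procedure: (1) identity -> correct; (2) decompose both — with
    identical motif-block sequences the block count differences decide the
    class; (3) otherwise fall back to total length in units of the dominant
    motif length.
    """
    core = _classify_core(seq, ref, marker)
    if seq_id or ref_id:
        return dataclasses.replace(core, seq_id=seq_id, ref_id=ref_id)
    return core


@lru_cache(maxsize=200_000)
def _classify_core(seq: str, ref: str, marker: MarkerDef) -> ClassifiedRead:
    seq_id = ref_id = ""
    unit = marker.unit_length
    dlen = len(seq) - len(ref)
    unit_delta = dlen // unit if dlen % unit == 0 else None

    if seq == ref:
        return ClassifiedRead(seq_id, ref_id, ErrorClass.CORRECT, 0, None, 0)

    d_seq = marker.decompose(seq)
    d_ref = marker.decompose(ref)
    if isinstance(d_seq, AlleleStructure) and isinstance(d_ref, AlleleStructure):
        if d_seq.motif_vector == d_ref.motif_vector:
            deltas = tuple(
                cs - cr for cs, cr in zip(d_seq.count_vector, d_ref.count_vector)
            )
            nonzero = [d for d in deltas if d != 0]
            if not nonzero:
                # identical structure yet different sequence can only arise
                # through suffix-resolved bases; treat as substitution
                cls: Optional[ErrorClass] = ErrorClass.BASE_SUBSTITUTION
            else:
                cls = _stutter_class(nonzero, dlen)
            if cls is not None:
                return ClassifiedRead(
                    seq_id,
                    ref_id,
                    cls,
                    unit_delta,
                    deltas,
                    _hamming(seq, ref) if dlen == 0 else None,
                )
            return ClassifiedRead(seq_id, ref_id, ErrorClass.OTHER, unit_delta, deltas)
        # differing motif orders: a whole block may have been lost (count
        # reached zero) or created; align the shorter block list into the
        # longer and accept only clean stutter patterns
        aligned = _subsequence_deltas(d_ref.blocks, d_seq.blocks)
        if aligned is None:
            rev = _subsequence_deltas(d_seq.blocks, d_ref.blocks)
            aligned = [-d for d in rev] if rev is not None else None
        if aligned is not None:
            nonzero = [d for d in aligned if d != 0]
            cls = _stutter_class(nonzero, dlen)
            if cls is ErrorClass.N_PM_0 and (
                sorted(nonzero) != [-1, 1] or _hamming(seq, ref) <= 2
            ):
                # a vanished/created block can only account for a single-unit
                # exchange, and when one or two substitutions already explain
                # the sequence, parsimony favours the substitution reading
                # (e.g. a block-edge substitution splitting off a new block)
                cls = None
            if cls is not None:
                return ClassifiedRead(
                    seq_id,
                    ref_id,
                    cls,
                    unit_delta,
                    tuple(aligned),
                    _hamming(seq, ref) if dlen == 0 else None,
                )

    # fallback: length-based tiers
    if dlen == -unit:
        cls = ErrorClass.N_MINUS_1
    elif dlen == -2 * unit:
        cls = ErrorClass.N_MINUS_2
    elif dlen == unit:
        cls = ErrorClass.N_PLUS_1
    elif dlen == 0:
        cls = ErrorClass.BASE_SUBSTITUTION
    else:
        cls = ErrorClass.OTHER
    return ClassifiedRead(
        seq_id,
        ref_id,
        cls,
        unit_delta,
        None,
        _hamming(seq, ref) if dlen == 0 else None,
    )


def classify_family_members(
    members: Sequence[tuple[str, str]],
    consensus_seq: str,
    marker: MarkerDef,
    consensus_id: str = "consensus",
) -> tuple[list[ClassifiedRead], dict[ErrorClass, int]]:
    """Classify every (read_id, sequence) member against the family consensus.

    Returns the per-member verdicts and the class counts (which partition the
    family: counts sum to the number of members).
    """
    out = [
        classify(seq, consensus_seq, marker, seq_id=rid, ref_id=consensus_id)
        for rid, seq in members
    ]
    counts: dict[ErrorClass, int] = {}
    for c in out:
        counts[c.error_class] = counts.get(c.error_class, 0) + 1
    return out, counts


def classify_vs_truth(
    seq: str,
    marker: MarkerDef,
    seq_id: str = "",
) -> ClassifiedRead:
    """Classify a read or consensus sequence against the known diploid genotype.

    A sequence equal to either reference allele is correct, regardless of its
    stutter relationship to the other allele (allele match precedes stutter
    call, mirroring forensic allele-vs-stutter convention).  Otherwise the
    nearer allele by absolute length difference is the comparator; an exact tie
    is resolved toward the first allele and flagged ``ambiguous_reference``.
    """
    ref1, ref2 = marker.reference_sequences()
    if seq == ref1:
        return ClassifiedRead(seq_id, "allele1", ErrorClass.CORRECT, 0, None, 0)
    if seq == ref2:
        return ClassifiedRead(seq_id, "allele2", ErrorClass.CORRECT, 0, None, 0)
    d1, d2 = abs(len(seq) - len(ref1)), abs(len(seq) - len(ref2))
    if d1 < d2:
        return classify(seq, ref1, marker, seq_id=seq_id, ref_id="allele1")
    if d2 < d1:
        return classify(seq, ref2, marker, seq_id=seq_id, ref_id="allele2")
    c1 = classify(seq, ref1, marker, seq_id=seq_id, ref_id="allele1")
    ambiguous = ref1 != ref2
    return ClassifiedRead(
        c1.seq_id,
        c1.ref_id,
        c1.error_class,
        c1.unit_delta,
        c1.block_deltas,
        c1.substitution_count,
        ambiguous_reference=ambiguous,
    )


def sample_incorrect_families(
    consensus_verdicts: Sequence[tuple[str, ClassifiedRead]],
    k: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Uniformly sample up to ``k`` family ids with incorrect consensus reads.

    Mirrors the manual-inspection design in which 50 incorrect-consensus
    UMI families per condition were drawn for dossier review.
    """
    rng = rng if rng is not None else np.random.default_rng()
    incorrect = [
        fam_id
        for fam_id, v in consensus_verdicts
        if v.error_class is not ErrorClass.CORRECT
    ]
    if not incorrect:
        return []
    k = min(k, len(incorrect))
    idx = rng.choice(len(incorrect), size=k, replace=False)
    return [incorrect[i] for i in sorted(idx)]
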