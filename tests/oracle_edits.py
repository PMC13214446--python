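"""Independent edit-injection oracle for repeat-space classification.

Enumerates, directly on an allele's block structure (never via the package's
decomposition), every sequence reachable by single-unit deletions/insertions,
double-unit deletions, one-loss-one-gain pairs, and small substitution sets.
The categories are only mutually exclusive at the sequence level up to
collisions: a boundary-shift stutter can coincide with one or two base
substitutions.  Sequences reachable from more than one category are reported
in the ambiguity sets so callers can exclude them from strict checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from strumi.panel import AlleleStructure, MarkerDef, RepeatBlock, expand_to_sequence


def _edit(blocks, idx: int, delta: int):
    out = []
    for k, b in enumerate(blocks):
        c = b.count + (delta if k == idx else 0)
        if c > 0:
            out.append(RepeatBlock(b.motif, c))
    return out


def _expand(blocks) -> str:
    return "".join(b.motif.bases * b.count for b in blocks)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class EditSets:
    ref: str
    del1: set[str]  # one repeat unit lost
    ins1: set[str]  # one repeat unit gained
    del2: set[str]  # two units lost (one block -2 or two blocks -1)
    pm0: set[str]  # one unit lost in one stretch, one gained in another
    pm0_ambient: set[str]  # any same-length unit-remove + unit-insert outcome


def enumerate_unit_edits(allele: AlleleStructure, marker: MarkerDef) -> EditSets:
    """All whole-unit edit outcomes on blocks of the dominant motif length."""
    unit = marker.unit_length
    blocks = list(allele.blocks)
    ref = expand_to_sequence(allele)
    eligible = [i for i, b in enumerate(blocks) if len(b.motif) == unit]

    del1 = {
        _expand(_edit(blocks, i, -1)) for i in eligible if _edit(blocks, i, -1)
    }
    ins1 = {_expand(_edit(blocks, i, +1)) for i in eligible}
    del2 = set()
    for i in eligible:
        if blocks[i].count >= 2:
            del2.add(_expand(_edit(blocks, i, -2)))
    for i, j in itertools.combinations(eligible, 2):
        twice = _edit(_edit(blocks, j, -1), i, -1)
        if twice:
            del2.add(_expand(twice))
    pm0 = {
        _expand(_edit(_edit(blocks, j, +1), i, -1))
        for i, j in itertools.permutations(eligible, 2)
    }

    # ambient set: remove one unit of ANY block, insert one unit of any
    # allowed same-length motif anywhere -- every sequence a single-unit
    # loss/gain interpretation could possibly explain
    pm0_ambient = set()
    for i, b in enumerate(blocks):
        removed = _edit(blocks, i, -1)
        if not removed:
            continue
        rs = _expand(removed)
        for motif in (x for x in marker.motifs if len(x) == len(b.motif)):
            for p in range(len(rs) + 1):
                pm0_ambient.add(rs[:p] + motif + rs[p:])
    return EditSets(ref=ref, del1=del1, ins1=ins1, del2=del2, pm0=pm0,
                    pm0_ambient=pm0_ambient)


def substitution_neighbors(ref: str, order: int = 1):
    """Yield every sequence within exactly ``order`` base substitutions."""
    bases = "ACGT"
    if order == 1:
        for p in range(len(ref)):
            for b in bases:
                if b != ref[p]:
                    yield ref[:p] + b + ref[p + 1 :]
    elif order == 2:
        for p, q in itertools.combinations(range(len(ref)), 2):
            for b1 in bases:
                if b1 == ref[p]:
                    continue
                s1 = ref[:p] + b1 + ref[p + 1 :]
                for b2 in bases:
                    if b2 != ref[q]:
                        yield s1[:q] + b2 + s1[q + 1 :]
    else:
        raise ValueError("order must be 1 or 2")
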