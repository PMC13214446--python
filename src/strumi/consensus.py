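"""UMI-family construction and plurality consensus calling.

Reads assigned to the same marker and carrying the same UMI form a family —
the sequenced descendants of one UMI-labelled founder molecule.  One consensus
read is generated per family of at least ``min_family_size`` members by taking
the most common member sequence (plurality, not majority).  Exact ties are
resolved toward the lexicographically smallest sequence and flagged, because
the field's convention for consensus ties is unsettled; tie frequency is
therefore always observable downstream.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from .assign import AssignedRead


@dataclass
class UMIFamily:
    marker: str
    umi: str
    members: list[tuple[str, str]]  # (read_id, repeat_region)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_variants(self) -> int:
        return len({seq for _, seq in self.members})

    @property
    def family_id(self) -> str:
        return f"{self.marker}:{self.umi}"


@dataclass(frozen=True)
class ConsensusRecord:
    marker: str
    umi: str
    consensus: str
    size: int
    support: int  # members identical to the consensus
    tie: bool

    @property
    def family_id(self) -> str:
        return f"{self.marker}:{self.umi}"


def _hamming1_neighbors(umi: str) -> Iterable[str]:
    for i, base in enumerate(umi):
        for alt in "ACGT":
            if alt != base:
                yield umi[:i] + alt + umi[i + 1 :]


def build_families(
    assigned: Iterable[AssignedRead], collapse_umi_distance: int = 0
) -> list[UMIFamily]:
    """Group assigned reads into UMI families by exact (marker, UMI) identity.

    With ``collapse_umi_distance=1``, singleton families whose UMI lies within
    Hamming distance 1 of a >=10x larger family at the same marker are absorbed
    into that family (sequencing errors in the UMI create satellite
    singletons).  Output order is deterministic: sorted by (marker, umi).
    """
    if collapse_umi_distance not in (0, 1):
        raise ValueError("collapse_umi_distance must be 0 or 1")
    groups: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    for read in assigned:
        groups[(read.marker, read.umi)].append((read.read_id, read.repeat_region))

    if collapse_umi_distance == 1:
        sizes = {key: len(v) for key, v in groups.items()}
        for (marker, umi), members in sorted(groups.items()):
            if len(members) != 1 or sizes.get((marker, umi), 0) != 1:
                continue
            best: Optional[tuple[str, str]] = None
            best_size = 0
            for neighbor in _hamming1_neighbors(umi):
                cand = (marker, neighbor)
                n = sizes.get(cand, 0)
                if n >= 10 and n > best_size:
                    best, best_size = cand, n
            if best is not None:
                groups[best].extend(members)
                sizes[best] += 1
                del groups[(marker, umi)]
                sizes[(marker, umi)] = 0

    return [
        UMIFamily(marker=marker, umi=umi, members=members)
        for (marker, umi), members in sorted(groups.items())
    ]


def call_consensus(
    family: UMIFamily, min_family_size: int = 3
) -> Optional[ConsensusRecord]:
    """Plurality consensus; ``None`` for families below the size threshold.

    Only families with ``min_family_size`` or more members yield a consensus
    read (default 3).  The consensus is the most common member sequence; with
    tied counts the lexicographically smallest tied sequence wins and the
    record is flagged.
    """
    if family.size < min_family_size:
        return None
    counts = Counter(seq for _, seq in family.members)
    top = max(counts.values())
    tied = sorted(seq for seq, c in counts.items() if c == top)
    return ConsensusRecord(
        marker=family.marker,
        umi=family.umi,
        consensus=tied[0],
        size=family.size,
        support=top,
        tie=len(tied) > 1,
    )


def call_all_consensus(
    families: Iterable[UMIFamily], min_family_size: int = 3
) -> list[ConsensusRecord]:
    out = []
    for fam in families:
        rec = call_consensus(fam, min_family_size)
        if rec is not None:
            out.append(rec)
    return out
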