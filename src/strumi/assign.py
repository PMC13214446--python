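"""Marker assignment and construct trimming for merged UMI-tagged reads.

Each merged read carries ``UMI + stem + left flank + repeat region + right
flank``.  The UMI is taken positionally (the first ``umi_length`` bases), the
stem is skipped, and the remainder is matched against every marker's flank
anchors with a bounded number of Hamming mismatches per flank.  A read is
assigned only when exactly one marker matches with the left flank preceding
the right; the span strictly between the flanks becomes the repeat region.

Flank matching is substitution-only (no indels): the anchors are short and the
synthetic reads carry no indel errors outside the repeat region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam

from .panel import MarkerDef, Panel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    marker: str
    umi: str
    repeat_region: str
    left_mismatches: int
    right_mismatches: int


@dataclass(frozen=True)
class UnassignedRead:
    read_id: str
    reason: str  # too_short | no_flank_match | ambiguous


def merge_pairs(
    fwd: str,
    rev: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[str]:
    """Naive overlap merger for a read pair (rev given in sequencing direction).

    Finds the longest 3' overlap of ``fwd`` with the reverse complement of
    ``rev`` whose mismatch fraction is within bounds; disagreements resolve in
    favour of ``fwd`` (qualities are uninformative here).  Returns the merged
    contig, or ``None`` when no overlap qualifies.
    """
    if not fwd or not rev:
        return None
    rc = revcomp(rev)
    max_ov = min(len(fwd), len(rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = fwd[-ov:]
        head = rc[:ov]
        mism = sum(a != b for a, b in zip(tail, head))
        if mism <= max_mismatch_frac * ov:
            return fwd + rc[ov:]
    return None


def _hamming_scan(body: np.ndarray, flank: np.ndarray) -> tuple[int, int]:
    """Best (mismatches, position) of ``flank`` within ``body`` byte arrays."""
    n, m = len(body), len(flank)
    if n < m:
        return m + 1, -1
    windows = np.lib.stride_tricks.sliding_window_view(body, m)
    mism = (windows != flank).sum(axis=1)
    pos = int(np.argmin(mism))
    return int(mism[pos]), pos


class _MarkerMatcher:
    """Cached flank byte arrays for one marker."""

    def __init__(self, marker: MarkerDef):
        self.marker = marker
        self.left = marker.left_flank
        self.right = marker.right_flank
        self._left_arr = np.frombuffer(self.left.encode(), dtype=np.uint8)
        self._right_arr = np.frombuffer(self.right.encode(), dtype=np.uint8)

    def match(
        self, body: str, body_arr: np.ndarray, max_mm: int
    ) -> Optional[tuple[int, int, int, int]]:
        """Returns (left_pos, left_mm, right_pos, right_mm) or None."""
        lpos = body.find(self.left)
        lmm = 0
        if lpos < 0:
            if max_mm == 0:
                return None
            lmm, lpos = _hamming_scan(body_arr, self._left_arr)
            if lmm > max_mm:
                return None
        tail_start = lpos + len(self.left)
        rpos_rel = body.find(self.right, tail_start)
        rmm = 0
        if rpos_rel < 0:
            if max_mm == 0:
                return None
            rmm, rpos = _hamming_scan(body_arr[tail_start:], self._right_arr)
            if rmm > max_mm or rpos < 0:
                return None
            rpos_rel = tail_start + rpos
        return lpos, lmm, rpos_rel, rmm


def assign_to_marker(
    read_id: str,
    seq: str,
    matchers: list[_MarkerMatcher],
    umi_length: int = 12,
    stem_length: int = 16,
    max_flank_mismatches: int = 2,
) -> AssignedRead | UnassignedRead:
    """Assign one merged read to the unique marker whose flanks both match."""
    prefix = umi_length + stem_length
    min_flank = min(len(m.left) + len(m.right) for m in matchers)
    if len(seq) < prefix + min_flank:
        return UnassignedRead(read_id, "too_short")
    umi = seq[:umi_length]
    body = seq[prefix:]
    body_arr = np.frombuffer(body.encode(), dtype=np.uint8)
    hits = []
    for matcher in matchers:
        res = matcher.match(body, body_arr, max_flank_mismatches)
        if res is not None:
            hits.append((matcher, res))
    if not hits:
        return UnassignedRead(read_id, "no_flank_match")
    if len(hits) > 1:
        return UnassignedRead(read_id, "ambiguous")
    matcher, (lpos, lmm, rpos, rmm) = hits[0]
    repeat = body[lpos + len(matcher.left) : rpos]
    return AssignedRead(read_id, matcher.marker.name, umi, repeat, lmm, rmm)


def build_matchers(panel: Panel) -> list[_MarkerMatcher]:
    return [_MarkerMatcher(m) for m in panel]


def assign_reads(
    reads: Iterable[tuple[str, str]],
    panel: Panel,
    umi_length: int = 12,
    stem_length: int = 16,
    max_flank_mismatches: int = 2,
) -> tuple[list[AssignedRead], Counter]:
    """Assign an iterable of (read_id, sequence); returns hits + reason counts.

    Assignment is per-read and deterministic, hence order-independent.
    """
    matchers = build_matchers(panel)
    assigned: list[AssignedRead] = []
    reasons: Counter = Counter()
    for read_id, seq in reads:
        res = assign_to_marker(
            read_id, seq, matchers, umi_length, stem_length, max_flank_mismatches
        )
        if isinstance(res, AssignedRead):
            assigned.append(res)
        else:
            reasons[res.reason] += 1
    return assigned, reasons


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (plain or gzipped)."""
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def assign_fastq(
    path: str,
    panel: Panel,
    umi_length: int = 12,
    stem_length: int = 16,
    max_flank_mismatches: int = 2,
) -> tuple[list[AssignedRead], Counter]:
    return assign_reads(
        read_fastq(path), panel, umi_length, stem_length, max_flank_mismatches
    )
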