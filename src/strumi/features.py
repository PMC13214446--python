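"""Per-family descriptors of UMI-family composition.

Five features summarise the sequence variation inside a UMI family relative to
its consensus read:

* **purity** — fraction of members identical to the consensus;
* **proportion of n variants** — number of distinct member sequences divided
  by family size;
* **proportion minus one / minus two / plus one** — fraction of members whose
  length is exactly one or two repeat units shorter, or one unit longer, than
  the consensus.

The stutter proportions are deliberately length-based ("one repeat unit" = the
marker's dominant motif length, 4 bp for the packaged panel); the structural
classifier in :mod:`strumi.classify` offers the richer repeat-space view.
Feature analysis is restricted to families with a correct consensus and more
than 40 members, where the within-family variant spectrum reflects errors of
the amplicon-template PCR rather than sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .classify import ClassifiedRead, ErrorClass
from .consensus import ConsensusRecord, UMIFamily
from .panel import MarkerDef


@dataclass(frozen=True)
class FamilyFeatures:
    family_id: str
    marker: str
    size: int
    purity: float
    prop_n_variants: float
    prop_minus_one: float
    prop_minus_two: float
    prop_plus_one: float


def compute_features(
    family: UMIFamily, consensus: ConsensusRecord, marker: MarkerDef
) -> FamilyFeatures:
    """Compute the five descriptors for one family with a called consensus."""
    unit = marker.unit_length
    clen = len(consensus.consensus)
    n = family.size
    minus_one = minus_two = plus_one = 0
    for _, seq in family.members:
        d = len(seq) - clen
        if d == -unit:
            minus_one += 1
        elif d == -2 * unit:
            minus_two += 1
        elif d == unit:
            plus_one += 1
    return FamilyFeatures(
        family_id=family.family_id,
        marker=family.marker,
        size=n,
        purity=consensus.support / n,
        prop_n_variants=family.n_variants / n,
        prop_minus_one=minus_one / n,
        prop_minus_two=minus_two / n,
        prop_plus_one=plus_one / n,
    )


def select_feature_families(
    rows: Iterable[tuple[UMIFamily, ConsensusRecord]],
    consensus_verdicts: Optional[dict[str, ClassifiedRead]] = None,
    min_members_exclusive: int = 40,
    require_correct_consensus: bool = True,
) -> list[tuple[UMIFamily, ConsensusRecord]]:
    """Keep families with strictly more than ``min_members_exclusive`` members
    and (optionally) a consensus classified correct against the truth."""
    out = []
    for fam, cons in rows:
        if fam.size <= min_members_exclusive:
            continue
        if require_correct_consensus:
            if consensus_verdicts is None:
                raise ValueError(
                    "require_correct_consensus needs consensus-vs-truth verdicts"
                )
            verdict = consensus_verdicts.get(fam.family_id)
            if verdict is None or verdict.error_class is not ErrorClass.CORRECT:
                continue
        out.append((fam, cons))
    return out


def expected_member_depth(cycles: int, efficiency: float) -> float:
    """Expected replication depth of a random family member after the adaptor
    PCR.

    Each cycle a uniformly chosen molecule is a fresh copy with probability
    ``efficiency / (1 + efficiency)``; uniform subsampling at the family cap
    leaves this unbiased, so the expected depth is simply additive in the
    number of cycles.
    """
    return cycles * efficiency / (1.0 + efficiency)


def estimate_slip_rate(
    features: Sequence[FamilyFeatures],
    lus: int,
    cycles: int,
    efficiency: float,
    minus_bias: float,
) -> float:
    """Back-calculate the per-unit, per-replication slippage rate.

    Inverts the small-rate relationship  ``E[prop_minus_one] ~= D * q * bias``
    with ``D`` the expected member depth and ``q = 1-(1-s)**LUS`` the
    per-replication slip probability of the longest stretch.  Valid for
    single-stretch markers where essentially all n-1 members arise from one
    slip on the LUS; requires the design parameters (cycle count, efficiency,
    minus bias) to be known, i.e. parameter recovery, not blind inference.
    """
    if not features:
        raise ValueError("no families to estimate from")
    mean_m1 = sum(f.prop_minus_one for f in features) / len(features)
    depth = expected_member_depth(cycles, efficiency)
    q = min(max(mean_m1 / (depth * minus_bias), 0.0), 1.0 - 1e-12)
    return 1.0 - math.exp(math.log1p(-q) / lus)
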