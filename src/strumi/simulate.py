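"""Synthetic two-step UMI library-prep simulator for STR amplicon sequencing.

The generator emulates the two PCR stages of a UMI-barcoded STR assay:

* **barcoding PCR** (default 4 cycles, genomic template): three polymerization
  processes are modelled per template molecule — (1) long products primed off
  the genomic template, (2) short UMI-labelled STR amplicons copied from long
  products (a fresh random UMI is attached at this step), and (3) short
  amplicons copied from other short amplicons (the copy inherits the UMI).
  Errors made before UMI attachment propagate into the founder sequence and
  later surface as families whose correct sequence is rare or absent.
* **adaptor PCR** (default 27 cycles, amplicon template): each UMI-labelled
  founder seeds an independent Galton-Watson family; every molecule replicates
  with probability ``efficiency`` per cycle and each replication can introduce
  slippage (whole repeat units, one unit per event, n-1 favoured) and random
  base substitutions.  Families are capped by uniform subsampling, which
  preserves variant shares in expectation.

Reads are then drawn with replacement proportional to family sizes, sequencing
error is applied per base, and a FASTQ plus a sidecar truth table are written.

Per-replication slippage at a repeat block of ``c`` units occurs with
probability ``1 - (1 - slip_rate)**c``: longer uninterrupted stretches stutter
more, which reproduces the marker-to-marker stutter ordering seen in real STR
panels.  Default rates are chosen so that the read-level n-1 stutter fraction
falls in the mid-single-digit percent range typical of tetranucleotide STR
amplicon sequencing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .panel import (
    AlleleStructure,
    MarkerDef,
    Panel,
    decompose_sequence,
    default_panel,
    expand_to_sequence,
    serialize_strnaming,
)

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
_STEM_TILE = "ACGTCAGTCCTGAGCT"


def default_stem(length: int = 16) -> str:
    """Deterministic stem-loop filler sequence of the requested length."""
    reps = -(-length // len(_STEM_TILE))
    return (_STEM_TILE * reps)[:length]


@dataclass(frozen=True)
class PolymeraseProfile:
    """Mechanistic error knobs of one polymerase in one PCR step.

    sub_rate
        Probability of substituting any given base per replication event.
    slip_rate
        Probability of one slippage event per repeat unit per replication;
        a block of ``c`` units slips with probability ``1-(1-slip_rate)**c``.
    minus_bias
        Probability that a slippage removes (rather than adds) one unit;
        above 0.5 so that n-1 dominates n+1, as observed in vitro.
    efficiency
        Probability that a molecule is replicated in a given cycle.
    min_slip_units
        Minimum block count for slippage eligibility; very short stretches
        are treated as slippage-immune.
    """

    name: str
    sub_rate: float
    slip_rate: float
    minus_bias: float = 0.85
    efficiency: float = 0.95
    min_slip_units: int = 4

    def __post_init__(self) -> None:
        for f in ("sub_rate", "slip_rate", "minus_bias", "efficiency"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {f}={v} outside [0, 1]")
        if self.min_slip_units < 1:
            raise ValueError(f"{self.name}: min_slip_units must be >= 1")


def default_barcoding_profile() -> PolymeraseProfile:
    return PolymeraseProfile(
        name="reference_barcoding",
        sub_rate=1e-5,
        slip_rate=5e-4,
        minus_bias=0.85,
        efficiency=0.8,
    )


def default_adaptor_profile() -> PolymeraseProfile:
    return PolymeraseProfile(
        name="reference_adaptor",
        sub_rate=1e-5,
        slip_rate=5e-4,
        minus_bias=0.85,
        efficiency=0.95,
    )


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic sequencing run."""

    panel: Panel = field(default_factory=default_panel)
    barcoding_profile: PolymeraseProfile = field(
        default_factory=default_barcoding_profile
    )
    adaptor_profile: PolymeraseProfile = field(default_factory=default_adaptor_profile)
    n_templates_per_allele: int = 12
    barcoding_cycles: int = 4
    adaptor_cycles: int = 27
    family_cap: int = 4096
    reads_per_sample: int = 50_000
    seq_error_rate: float = 3e-4
    umi_length: int = 12
    stem_length: int = 16
    seed: int = 0

    @property
    def stem_seq(self) -> str:
        return default_stem(self.stem_length)

    def validate(self) -> None:
        bad = []
        for f in (
            "n_templates_per_allele",
            "barcoding_cycles",
            "adaptor_cycles",
            "family_cap",
            "umi_length",
        ):
            if getattr(self, f) < 1:
                bad.append(f)
        if self.reads_per_sample < 0:
            bad.append("reads_per_sample")
        if self.stem_length < 0:
            bad.append("stem_length")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            bad.append("seq_error_rate")
        if len(self.panel) == 0:
            bad.append("panel")
        if bad:
            raise ValueError(f"invalid SimConfig fields: {', '.join(bad)}")

    def to_jsonable(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_templates_per_allele",
                "barcoding_cycles",
                "adaptor_cycles",
                "family_cap",
                "reads_per_sample",
                "seq_error_rate",
                "umi_length",
                "stem_length",
                "seed",
            )
        }
        d["barcoding_profile"] = dataclasses.asdict(self.barcoding_profile)
        d["adaptor_profile"] = dataclasses.asdict(self.adaptor_profile)
        d["panel"] = [
            {
                "name": m.name,
                "left_flank": m.left_flank,
                "right_flank": m.right_flank,
                "motifs": list(m.motifs),
                "reference_genotype": [
                    serialize_strnaming(a) for a in m.reference_genotype
                ],
                "max_read_len": m.max_read_len,
            }
            for m in self.panel
        ]
        return d


@dataclass
class Molecule:
    """One DNA molecule in the simulation.

    ``kind`` distinguishes the genomic template, long products (primed in one
    end only, no UMI yet) and short UMI-labelled STR amplicons.  The UMI is
    present iff the molecule descends from a completed barcoding product.
    ``lineage_errors`` records every error event on the path from the original
    template: tuples of (cycle, kind, detail).
    """

    marker: MarkerDef
    kind: str  # "template" | "long" | "short"
    left: str
    repeat: str
    right: str
    true_allele: str  # serialized structure of the originating template allele
    umi: Optional[str] = None
    lineage_errors: tuple = ()

    @property
    def amplicon(self) -> str:
        return self.left + self.repeat + self.right

    @property
    def n_slips(self) -> int:
        return sum(1 for e in self.lineage_errors if e[1] == "slip")

    @property
    def n_subs(self) -> int:
        return sum(1 for e in self.lineage_errors if e[1] == "sub")


def _decompose_cached(marker: MarkerDef, repeat: str):
    # decompose_sequence memoises internally; PCR populations reuse a small
    # set of repeat strings so nearly every call is a cache hit
    return decompose_sequence(repeat, marker.motifs)


def _random_umi(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _substitute(seq: str, positions, rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = _OTHER[chars[p]][rng.integers(0, 3)]
    return "".join(chars)


def _slip_block(blocks: list[RepeatBlockLike], i: int, delta: int):
    """Apply a +-1-unit slip to block ``i`` of a mutable block list."""
    motif, count = blocks[i]
    count += delta
    if count <= 0:
        del blocks[i]
    else:
        blocks[i] = (motif, count)


RepeatBlockLike = tuple  # (motif_str, count)


def replicate_molecule(
    m: Molecule,
    profile: PolymeraseProfile,
    rng: np.random.Generator,
    cycle: int = 0,
) -> Molecule:
    """Return an error-bearing copy of ``m`` (the parent is unchanged).

    Independently per replication: (a) each repeat block of ``c`` units with
    ``c >= min_slip_units`` slips with probability ``1-(1-slip_rate)**c``
    (one unit removed with probability ``minus_bias``, else one added), and
    (b) every base of the amplicon substitutes with probability ``sub_rate``.
    Molecules whose repeat region no longer decomposes (after an earlier
    substitution) cannot slip; they only accumulate further substitutions.
    """
    events: list[tuple] = []
    repeat = m.repeat
    decomp = _decompose_cached(m.marker, repeat)
    if isinstance(decomp, AlleleStructure) and profile.slip_rate > 0:
        blocks = [(b.motif.bases, b.count) for b in decomp.blocks]
        changed = False
        for i in range(len(blocks) - 1, -1, -1):  # reverse: deletion-safe
            count = blocks[i][1]
            if count < profile.min_slip_units:
                continue
            q = 1.0 - (1.0 - profile.slip_rate) ** count
            if rng.random() < q:
                delta = -1 if rng.random() < profile.minus_bias else +1
                _slip_block(blocks, i, delta)
                events.append((cycle, "slip", i, delta))
                changed = True
        if changed:
            repeat = "".join(motif * count for motif, count in blocks)

    left, right = m.left, m.right
    if profile.sub_rate > 0:
        amplicon = left + repeat + right
        k = rng.binomial(len(amplicon), profile.sub_rate)
        if k:
            positions = rng.choice(len(amplicon), size=k, replace=False)
            amplicon = _substitute(amplicon, positions, rng)
            events.extend((cycle, "sub", int(p)) for p in sorted(positions))
            nl, nr = len(left), len(right)
            left = amplicon[:nl]
            repeat = amplicon[nl : len(amplicon) - nr]
            right = amplicon[len(amplicon) - nr :] if nr else ""

    return Molecule(
        marker=m.marker,
        kind=m.kind,
        left=left,
        repeat=repeat,
        right=right,
        true_allele=m.true_allele,
        umi=m.umi,
        lineage_errors=m.lineage_errors + tuple(events),
    )


def simulate_barcoding(
    panel: Panel, config: SimConfig, rng: np.random.Generator
) -> list[Molecule]:
    """Run the barcoding PCR and return the UMI-labelled short products."""
    profile = config.barcoding_profile
    eff = profile.efficiency
    founders: list[Molecule] = []
    for marker in panel:
        for allele in marker.reference_genotype:
            template_proto = Molecule(
                marker=marker,
                kind="template",
                left=marker.left_flank,
                repeat=expand_to_sequence(allele),
                right=marker.right_flank,
                true_allele=serialize_strnaming(allele),
            )
            for _ in range(config.n_templates_per_allele):
                longs: list[Molecule] = []
                shorts: list[Molecule] = []
                for cycle in range(1, config.barcoding_cycles + 1):
                    n_longs, n_shorts = len(longs), len(shorts)
                    # process (3): short -> short, UMI inherited
                    for s in shorts[:n_shorts]:
                        if rng.random() < eff:
                            shorts.append(replicate_molecule(s, profile, rng, cycle))
                    # process (2): long -> short, fresh UMI attached
                    for l in longs[:n_longs]:
                        if rng.random() < eff:
                            child = replicate_molecule(l, profile, rng, cycle)
                            child.kind = "short"
                            child.umi = _random_umi(config.umi_length, rng)
                            shorts.append(child)
                    # process (1): genomic template -> long product
                    if rng.random() < eff:
                        child = replicate_molecule(template_proto, profile, rng, cycle)
                        child.kind = "long"
                        longs.append(child)
                founders.extend(shorts)
    return founders


class _Variant:
    """One distinct sequence within a family, with its multiplicity."""

    __slots__ = (
        "left",
        "repeat",
        "right",
        "count",
        "n_slips",
        "n_subs",
        "blocks",
        "_eligible",
        "p_err",
    )

    def __init__(self, marker, profile, left, repeat, right, count, n_slips, n_subs):
        self.left, self.repeat, self.right = left, repeat, right
        self.count = count
        self.n_slips, self.n_subs = n_slips, n_subs
        decomp = _decompose_cached(marker, repeat)
        if isinstance(decomp, AlleleStructure):
            self.blocks = [(b.motif.bases, b.count) for b in decomp.blocks]
        else:
            self.blocks = None
        # eligible blocks and per-replication slip probabilities
        self._eligible = []
        p_clean = 1.0
        if self.blocks is not None:
            for i, (_, c) in enumerate(self.blocks):
                if c >= profile.min_slip_units:
                    q = 1.0 - (1.0 - profile.slip_rate) ** c
                    self._eligible.append((i, q))
                    p_clean *= 1.0 - q
        L = len(left) + len(repeat) + len(right)
        p_clean *= (1.0 - profile.sub_rate) ** L
        self.p_err = 1.0 - p_clean

    @property
    def length(self) -> int:
        return len(self.left) + len(self.repeat) + len(self.right)


def _conditional_first_index(L: int, p: float, rng: np.random.Generator) -> int:
    """Index of the first success among L Bernoulli(p) trials, given >= 1."""
    u = rng.random()
    mass = 1.0 - (1.0 - p) ** L
    f = int(math.floor(math.log1p(-u * mass) / math.log1p(-p)))
    return min(f, L - 1)


def _conditional_sub_positions(
    L: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Substituted positions among L bases conditioned on at least one."""
    f = _conditional_first_index(L, p, rng)
    extra = rng.binomial(L - f - 1, p) if f + 1 < L else 0
    if extra:
        rest = rng.choice(np.arange(f + 1, L), size=extra, replace=False)
        return np.concatenate(([f], rest))
    return np.array([f])


def _make_error_child(
    variant: _Variant,
    marker: MarkerDef,
    profile: PolymeraseProfile,
    rng: np.random.Generator,
) -> tuple[str, str, str, int, int]:
    """Sample one replication outcome conditioned on carrying >= 1 error.

    Events are ordered (slip at eligible block 0, 1, ..., then substitutions);
    the first firing event is drawn from the exact conditional distribution,
    later events fire at their unconditional rates.  Returns the child's
    (left, repeat, right) and the numbers of new slips and substitutions.
    """
    s = profile.sub_rate
    L = variant.length
    p_none = 1.0 - variant.p_err
    u = rng.random() * variant.p_err

    slips: list[tuple[int, int]] = []  # (block index, delta)
    n_new_subs = 0
    acc = 0.0
    pref = 1.0
    first_block = None
    for j, (bi, q) in enumerate(variant._eligible):
        mass = pref * q
        if u < acc + mass:
            first_block = j
            break
        acc += mass
        pref *= 1.0 - q
    if first_block is not None:
        # the chosen block slips; later blocks slip at unconditional rates
        bi, _q = variant._eligible[first_block]
        slips.append((bi, -1 if rng.random() < profile.minus_bias else +1))
        for bi2, q2 in variant._eligible[first_block + 1 :]:
            if rng.random() < q2:
                slips.append((bi2, -1 if rng.random() < profile.minus_bias else +1))
        if s > 0:
            n_new_subs = int(rng.binomial(L, s))
    elif s > 0:
        # no slip fired: the first error is a substitution
        positions = _conditional_sub_positions(L, s, rng)
        n_new_subs = len(positions)
    else:
        # float round-off pushed u past the slip mass with sub_rate 0:
        # attribute the event to the last eligible block
        bi, _q = variant._eligible[-1]
        slips.append((bi, -1 if rng.random() < profile.minus_bias else +1))

    left, repeat, right = variant.left, variant.repeat, variant.right
    if slips:
        blocks = list(variant.blocks)
        for bi, delta in sorted(slips, reverse=True):
            _slip_block(blocks, bi, delta)
        repeat = "".join(motif * count for motif, count in blocks)
    if n_new_subs:
        amplicon = left + repeat + right
        positions = rng.choice(len(amplicon), size=n_new_subs, replace=False)
        amplicon = _substitute(amplicon, positions, rng)
        nl, nr = len(left), len(right)
        left = amplicon[:nl]
        repeat = amplicon[nl : len(amplicon) - nr]
        right = amplicon[len(amplicon) - nr :] if nr else ""
    return left, repeat, right, len(slips), n_new_subs


class FamilyPopulation:
    """The molecule population descending from one UMI-labelled founder.

    Variants (distinct sequences) are tracked with multiplicities rather than
    as individual molecules, which keeps 27-cycle families tractable while the
    per-replication error model stays exact.
    """

    def __init__(self, founder: Molecule, profile: PolymeraseProfile):
        self.founder = founder
        self.profile = profile
        self.variants: dict[tuple[str, str, str], _Variant] = {}
        self._add(
            founder.left, founder.repeat, founder.right, 1, 0, 0
        )

    def _add(self, left, repeat, right, count, n_slips, n_subs) -> None:
        key = (left, repeat, right)
        v = self.variants.get(key)
        if v is None:
            self.variants[key] = _Variant(
                self.founder.marker, self.profile, left, repeat, right,
                count, n_slips, n_subs,
            )
        else:
            v.count += count

    @property
    def size(self) -> int:
        return sum(v.count for v in self.variants.values())

    def molecules(self) -> Iterator[Molecule]:
        """Materialise individual molecules (for small populations/tests)."""
        for v in self.variants.values():
            for _ in range(v.count):
                yield Molecule(
                    marker=self.founder.marker,
                    kind="short",
                    left=v.left,
                    repeat=v.repeat,
                    right=v.right,
                    true_allele=self.founder.true_allele,
                    umi=self.founder.umi,
                    lineage_errors=self.founder.lineage_errors
                    + tuple(("adaptor", "slip", i) for i in range(v.n_slips))
                    + tuple(("adaptor", "sub", i) for i in range(v.n_subs)),
                )

    def step(self, rng: np.random.Generator, family_cap: int) -> None:
        """One adaptor-PCR cycle: replicate, then cap by uniform subsampling."""
        profile = self.profile
        marker = self.founder.marker
        items = list(self.variants.values())
        counts = np.array([v.count for v in items], dtype=np.int64)
        k = rng.binomial(counts, profile.efficiency)
        p_err = np.array([v.p_err for v in items])
        n_err = rng.binomial(k, p_err)
        # clean copies join their parent variant in bulk
        for v, kk, ee in zip(items, k, n_err):
            v.count += int(kk) - int(ee)
            for _ in range(int(ee)):
                left, repeat, right, ds, db = _make_error_child(
                    v, marker, profile, rng
                )
                self._add(left, repeat, right, 1, v.n_slips + ds, v.n_subs + db)
        total = self.size
        if total > family_cap:
            items = list(self.variants.items())
            counts = np.array([v.count for _, v in items], dtype=np.int64)
            kept = rng.multivariate_hypergeometric(counts, family_cap)
            for (key, v), c in zip(items, kept):
                if c == 0:
                    del self.variants[key]
                else:
                    v.count = int(c)


def simulate_adaptor(
    founders: list[Molecule], config: SimConfig, rng: np.random.Generator
) -> list[FamilyPopulation]:
    """Grow one capped Galton-Watson family per UMI-labelled founder."""
    profile = config.adaptor_profile
    pops = []
    for founder in founders:
        if founder.umi is None:
            raise ValueError("adaptor PCR founders must carry a UMI")
        pop = FamilyPopulation(founder, profile)
        for _ in range(config.adaptor_cycles):
            pop.step(rng, config.family_cap)
        pops.append(pop)
    return pops


_TRUTH_COLUMNS = [
    "read_id",
    "marker",
    "umi",
    "true_allele",
    "founder_repeat",
    "repeat",
    "founder_n_slips",
    "founder_n_subs",
    "n_slips",
    "n_subs",
    "n_seq_errors",
]


def sample_sequencing_reads(
    populations: list[FamilyPopulation],
    config: SimConfig,
    rng: np.random.Generator,
    fastq_path: str,
    truth_path: str,
) -> None:
    """Draw reads proportional to family sizes and write FASTQ + truth TSV."""
    stem = config.stem_seq
    e = config.seq_error_rate

    entries: list[tuple[FamilyPopulation, _Variant]] = []
    weights: list[int] = []
    for pop in populations:
        for v in pop.variants.values():
            entries.append((pop, v))
            weights.append(v.count)

    fastq_lines: list[str] = []
    truth_lines: list[str] = ["\t".join(_TRUTH_COLUMNS)]
    if config.reads_per_sample > 0 and entries:
        draws = rng.multinomial(
            config.reads_per_sample, np.array(weights) / float(sum(weights))
        )
        rid = 0
        for (pop, v), n in zip(entries, draws):
            if n == 0:
                continue
            founder = pop.founder
            base = founder.umi + stem + v.left + v.repeat + v.right
            L = len(base)
            qual = "I" * L
            n_err = rng.binomial(n, 1.0 - (1.0 - e) ** L) if e > 0 else 0
            for i in range(int(n)):
                read_id = f"r{rid:07d}"
                rid += 1
                if i < n - n_err:
                    seq, k = base, 0
                else:
                    positions = _conditional_sub_positions(L, e, rng)
                    seq, k = _substitute(base, positions, rng), len(positions)
                fastq_lines.append(f"@{read_id}\n{seq}\n+\n{qual if len(seq)==L else 'I'*len(seq)}")
                truth_lines.append(
                    "\t".join(
                        (
                            read_id,
                            founder.marker.name,
                            founder.umi,
                            founder.true_allele,
                            founder.repeat,
                            v.repeat,
                            str(founder.n_slips),
                            str(founder.n_subs),
                            str(v.n_slips),
                            str(v.n_subs),
                            str(k),
                        )
                    )
                )
    try:
        with open(fastq_path, "w") as fh:
            fh.write("\n".join(fastq_lines) + ("\n" if fastq_lines else ""))
        with open(truth_path, "w") as fh:
            fh.write("\n".join(truth_lines) + "\n")
    except OSError as err:
        raise OSError(f"cannot write simulation output ({err.filename}): {err}") from err


def generate_dataset(
    config: SimConfig, outdir: str, seed: Optional[int] = None
) -> dict[str, str]:
    """One-call generator: barcoding -> adaptor -> sequencing -> files on disk.

    Deterministic given the seed (``config.seed`` unless overridden).  Returns
    the paths of the FASTQ, the truth table and the config echo JSON.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    fastq = os.path.join(outdir, "reads.fastq")
    truth = os.path.join(outdir, "truth.tsv")
    echo = os.path.join(outdir, "config.json")

    founders = simulate_barcoding(config.panel, config, rng)
    populations = simulate_adaptor(founders, config, rng)
    sample_sequencing_reads(populations, config, rng, fastq, truth)

    cfg = config.to_jsonable()
    cfg["seed_used"] = seed
    cfg["n_founders"] = len(founders)
    with open(echo, "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"fastq": fastq, "truth": truth, "config": echo}


def config_digest(config: SimConfig) -> str:
    """Stable hash of a configuration, for run manifests."""
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
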