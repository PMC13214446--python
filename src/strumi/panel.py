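"""STR marker panel model: repeat-structure notation, expansion and decomposition.

STR alleles are written in bracketed motif-count notation, e.g.
``TCTA[1]TCTG[3]TCTA[14]`` for a compound allele of D3S1358.  A trailing
annotation separated by an underscore (``TAGA[15]CAGA[8]_+1T > C``) describes a
flanking-region variant; it is stored verbatim and is not interpreted when the
repeat region is expanded to sequence.

The packaged default panel holds the seven tetranucleotide forensic markers of
the 7-plex assay (D2S441, D1S1656, D3S1358, vWA, D8S1179, D21S11 and D12S391)
with the 2800M reference genotypes.  Flank sequences in the packaged panel are
synthetic 20-nt anchors: the real assay's primer-proximal flanks are not public,
so analyses of real data must supply their own.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

_DNA_RE = re.compile(r"^[ACGT]+$")
_BLOCK_RE = re.compile(r"([ACGT]{1,6})\[(\d+)\]")


@dataclass(frozen=True)
class Motif:
    """A repeat motif of 1-6 uppercase DNA bases."""

    bases: str

    def __post_init__(self) -> None:
        if not (1 <= len(self.bases) <= 6) or not _DNA_RE.match(self.bases):
            raise ValueError(f"invalid motif {self.bases!r}: need 1-6 bases of ACGT")

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class RepeatBlock:
    """``count`` tandem copies of one motif."""

    motif: Motif
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"block count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return self.count * len(self.motif)


@dataclass(frozen=True)
class AlleleStructure:
    """An ordered sequence of repeat blocks plus opaque trailing annotations."""

    blocks: tuple[RepeatBlock, ...]
    suffix_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("AlleleStructure needs at least one block")

    @property
    def count_vector(self) -> tuple[int, ...]:
        return tuple(b.count for b in self.blocks)

    @property
    def motif_vector(self) -> tuple[str, ...]:
        return tuple(b.motif.bases for b in self.blocks)

    def __len__(self) -> int:
        """Total repeat-region length in bp (suffix annotations excluded)."""
        return sum(b.length for b in self.blocks)


@dataclass(frozen=True)
class DecompositionFailure:
    """Returned when a sequence cannot be fully tiled by the allowed motifs.

    ``residue_start`` is the furthest 0-based offset any candidate tiling
    reached before failing.  Such sequences remain classifiable by length.
    """

    blocks: tuple[RepeatBlock, ...]
    residue_start: int
    sequence: str

    def __bool__(self) -> bool:
        return False


class ParseError(ValueError):
    """Malformed bracket-notation string; ``pos`` is the offending offset."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def parse_strnaming(text: str, motifs: Optional[set[str]] = None) -> AlleleStructure:
    """Parse a bracket-notation repeat structure.

    The grammar is ``(MOTIF "[" INT "]")+ ("_" suffix)?``.  Anything after the
    first underscore that follows the last bracketed block is kept verbatim as a
    suffix variant.  If ``motifs`` is given, every parsed motif must be in it.
    """
    text = text.strip()
    blocks: list[RepeatBlock] = []
    pos = 0
    while pos < len(text):
        m = _BLOCK_RE.match(text, pos)
        if m is None:
            break
        motif, count = m.group(1), int(m.group(2))
        if count < 1:
            raise ParseError(f"repeat count must be >= 1, got {count}", pos)
        if motifs is not None and motif not in motifs:
            raise ValueError(
                f"motif {motif!r} at position {pos} not in allowed set {sorted(motifs)}"
            )
        blocks.append(RepeatBlock(Motif(motif), count))
        pos = m.end()
    if not blocks:
        raise ParseError("no bracketed repeat block found", pos)
    suffix: tuple[str, ...] = ()
    if pos < len(text):
        if text[pos] != "_":
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        suffix = (text[pos + 1 :],)
        if not suffix[0]:
            raise ParseError("empty suffix annotation after '_'", pos)
    return AlleleStructure(tuple(blocks), suffix)


def serialize_strnaming(a: AlleleStructure) -> str:
    """Inverse of :func:`parse_strnaming` (round-trips exactly)."""
    s = "".join(f"{b.motif}[{b.count}]" for b in a.blocks)
    for suf in a.suffix_variants:
        s += f"_{suf}"
    return s


def expand_to_sequence(a: AlleleStructure) -> str:
    """Concatenate each motif ``count`` times.  Suffix annotations are ignored;
    they describe flanking-region variants, not the repeat region itself."""
    return "".join(b.motif.bases * b.count for b in a.blocks)


_SUFFIX_SUB_RE = re.compile(r"^\+(\d+)([ACGT])\s*>\s*([ACGT])$")


def apply_suffix_to_flank(suffix: str, right_flank: str) -> str:
    """Apply a simple ``+<pos><ref> > <alt>`` annotation to the right flank.

    Position is 1-based from the end of the repeat region.  Unrecognised
    annotations raise ``ValueError``; callers that store suffixes verbatim never
    need to call this.
    """
    m = _SUFFIX_SUB_RE.match(suffix.strip())
    if m is None:
        raise ValueError(f"unsupported suffix annotation {suffix!r}")
    pos, ref, alt = int(m.group(1)) - 1, m.group(2), m.group(3)
    if pos >= len(right_flank) or right_flank[pos] != ref:
        raise ValueError(f"suffix {suffix!r} does not match flank {right_flank!r}")
    return right_flank[:pos] + alt + right_flank[pos + 1 :]


def _decompose_uncached(
    seq: str, motifs: tuple[str, ...]
) -> AlleleStructure | DecompositionFailure:
    n = len(seq)
    if n == 0:
        return DecompositionFailure((), 0, seq)
    motif_order = {m: i for i, m in enumerate(motifs)}
    dead: set[int] = set()
    furthest = 0

    def choices(pos: int) -> list[tuple[str, int]]:
        out = []
        for motif in motifs:
            lm = len(motif)
            count = 0
            while seq.startswith(motif, pos + count * lm):
                count += 1
            for c in range(count, 0, -1):
                out.append((motif, c))
        # prefer the longest-consuming run; ties break by motif order
        out.sort(key=lambda mc: (-len(mc[0]) * mc[1], motif_order[mc[0]]))
        return out

    def search(pos: int) -> Optional[list[tuple[str, int]]]:
        nonlocal furthest
        furthest = max(furthest, pos)
        if pos == n:
            return []
        if pos in dead:
            return None
        for motif, count in choices(pos):
            rest = search(pos + count * len(motif))
            if rest is not None:
                return [(motif, count)] + rest
        dead.add(pos)
        return None

    tiling = search(0)
    if tiling is None:
        return DecompositionFailure((), furthest, seq)
    # normalise: merge adjacent blocks of the same motif
    merged: list[tuple[str, int]] = []
    for motif, count in tiling:
        if merged and merged[-1][0] == motif:
            merged[-1] = (motif, merged[-1][1] + count)
        else:
            merged.append((motif, count))
    return AlleleStructure(
        tuple(RepeatBlock(Motif(m), c) for m, c in merged)
    )


@lru_cache(maxsize=200_000)
def _decompose_cached(seq: str, motifs: tuple[str, ...]):
    return _decompose_uncached(seq, motifs)


def decompose_sequence(
    seq: str, motifs: Sequence[str]
) -> AlleleStructure | DecompositionFailure:
    """Tile a repeat region with an ordered motif set, greedily with backtracking.

    At each position the motif run consuming the most bases is tried first
    (ties break by motif order); on a dead end shorter runs and later motifs
    are tried, so a valid tiling is found whenever one exists.  Backtracking
    matters for interrupted structures whose single-base spacer is a prefix of
    a longer allowed motif.  Failure — no full tiling, reported with the
    furthest position reached — is a value, not an exception; such sequences
    remain classifiable by length.
    """
    return _decompose_cached(seq, tuple(motifs))


def lus_count(a: AlleleStructure) -> int:
    """Repeat count of the longest uninterrupted stretch (the max block count).

    The LUS is the predominant site of slippage: stutter risk grows with the
    number of consecutive identical units.
    """
    return max(b.count for b in a.blocks)


@dataclass(frozen=True)
class MarkerDef:
    """One STR marker: flank anchors, allowed motifs, reference genotype."""

    name: str
    left_flank: str
    right_flank: str
    motifs: tuple[str, ...]  # ordered; first entry is the dominant motif
    reference_genotype: tuple[AlleleStructure, AlleleStructure]
    max_read_len: int

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError(f"{self.name}: flanks must be non-empty")
        for flank in (self.left_flank, self.right_flank):
            if not _DNA_RE.match(flank):
                raise ValueError(f"{self.name}: flank {flank!r} is not ACGT")
        for allele in self.reference_genotype:
            for b in allele.blocks:
                if b.motif.bases not in self.motifs:
                    raise ValueError(
                        f"{self.name}: reference allele uses motif {b.motif} "
                        f"outside the allowed set {self.motifs}"
                    )

    @property
    def unit_length(self) -> int:
        """Length in bp of one repeat unit (the dominant motif's length)."""
        return len(self.motifs[0])

    def decompose(self, seq: str) -> AlleleStructure | DecompositionFailure:
        return decompose_sequence(seq, self.motifs)

    def reference_sequences(self) -> tuple[str, str]:
        a1, a2 = self.reference_genotype
        return expand_to_sequence(a1), expand_to_sequence(a2)


@dataclass(frozen=True)
class Panel:
    """An ordered collection of markers with unique names."""

    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker names in panel: {names}")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)


def load_panel(path_or_obj) -> Panel:
    """Load a panel from a JSON file path, file object, or parsed list."""
    if isinstance(path_or_obj, (list, tuple)):
        raw = path_or_obj
    elif hasattr(path_or_obj, "read"):
        raw = json.load(path_or_obj)
    else:
        with open(path_or_obj) as fh:
            raw = json.load(fh)
    markers = []
    for entry in raw:
        motifs = tuple(entry["motifs"])
        genotype = tuple(
            parse_strnaming(s, motifs=set(motifs)) for s in entry["reference_genotype"]
        )
        if len(genotype) != 2:
            raise ValueError(
                f"{entry['name']}: reference_genotype must list two alleles"
            )
        markers.append(
            MarkerDef(
                name=entry["name"],
                left_flank=entry["left_flank"],
                right_flank=entry["right_flank"],
                motifs=motifs,
                reference_genotype=genotype,  # type: ignore[arg-type]
                max_read_len=int(entry["max_read_len"]),
            )
        )
    return Panel(tuple(markers))


def save_panel(panel: Panel, path) -> None:
    raw = [
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
        for m in panel
    ]
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)
        fh.write("\n")


def default_panel() -> Panel:
    """The packaged 7-marker tetranucleotide panel with 2800M genotypes."""
    ref = resources.files("strumi.data").joinpath("table1_panel.json")
    with ref.open() as fh:
        return load_panel(fh)
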