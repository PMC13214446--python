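# Methods

## Repeat-structure model

An STR allele is an ordered list of repeat blocks, each a motif (1–6 bp) with
a unit count, written in bracket notation (`TCTA[1]TCTG[3]TCTA[14]`).
Trailing flanking-region annotations separated by `_` (e.g. `_+1T > C`) are
stored verbatim and never applied when expanding the repeat region; an
optional helper applies simple `+<pos><ref> > <alt>` substitutions to a
right-flank sequence. Serialization is the exact inverse of parsing.

Decomposition of a raw repeat region tiles the sequence with the marker's
ordered motif set, trying the longest-consuming tandem run first (ties break
by motif order) and backtracking on dead ends. Pure greedy tiling was the
starting design, but it fails on interrupted structures in the packaged panel
itself: in D21S11's `...TATC[4]A[1]TCTA[2]...` the single-base `A` spacer is
a prefix of the allowed `ATC` motif, so greedy consumes `ATC` and strands the
tail. Backtracking with dead-position memoization keeps greedy behaviour
wherever greedy succeeds, guarantees a tiling is found whenever one exists,
and stays linear in practice. Failure is returned as a value carrying the
furthest position reached; such sequences remain classifiable by length.
The longest uninterrupted stretch (LUS) is the maximum block count.

For same-length motif alphabets the greedy tiling provably inverts expansion
whenever adjacent blocks have distinct motifs (at each block boundary only
the true motif can match), which is the property-tested regime; alphabets
mixing motif lengths rely on backtracking and are covered by the packaged
panel round-trip tests.

## Error classification

Classification compares a sequence with a reference in repeat space, in this
order:

1. identity → `correct`;
2. both decompose with identical motif-block orders → block count deltas:
   one block −1 → `n_minus_1`; one block −2 or two blocks −1 → `n_minus_2`
   (the two geometries are not distinguished; both are two units short);
   one block +1 → `n_plus_1`; two blocks ±k with net zero **and unchanged
   total length** → `n_pm_0`;
3. block orders differ → the shorter block list is aligned into the longer
   as a subsequence (a block whose count reached zero, or a newly created
   block, appears as a whole-block delta) and the same patterns are
   accepted, except that `n_pm_0` additionally requires a single-unit
   exchange and a Hamming distance above 2: when one or two substitutions
   already explain the sequence (a block-edge substitution splitting off a
   new block is the common case), parsimony favours the substitution
   reading;
4. otherwise a length fallback in units of the marker's dominant motif
   length: −1/−2/+1 units → the stutter tiers, equal length → 
   `base_substitution`, anything else → `other`.

The length condition in rule 2 matters for markers whose interruption motifs
are shorter than the dominant unit (D21S11's `A`/`ATC`): equal count deltas
on blocks of unequal motif length change the total length and are not
net-zero stutter. Against a diploid truth, a sequence equal to either
reference allele is `correct` (allele match precedes any stutter reading),
otherwise the allele nearer in length is the comparator; exact ties resolve
to the first allele and are flagged.

The classifier was validated against an edit-injection oracle that enumerates
(on block structures directly, independent of the decomposition code) every
single-unit deletion/insertion, double deletion, one-loss-one-gain pair and
all sequences within two substitutions of every packaged allele — about
390,000 sequences — with collisions (sequences reachable from more than one
category) excluded from strict assertions, since no classifier can resolve
them from sequence alone.

## Consensus and features

Families are exact (marker, UMI) groups; optional collapsing absorbs
singleton families within Hamming distance 1 of a ≥10× larger family at the
same marker (satellites created by sequencing errors in the UMI), and is off
by default because exact grouping is the reproducible baseline. Consensus is
the plurality member sequence of families with at least 3 members; exact
ties resolve to the lexicographically smallest sequence and are flagged and
counted, the tie-handling of the original pipelines being unknown.

The five family features (purity, proportion of n variants, and the three
stutter proportions) follow their printed definitions literally: the stutter
proportions are **length-based** (±1 or −2 dominant-motif units relative to
the consensus length), not structure-based — the structural classifier is a
separate, richer view. Feature analysis selects families with strictly more
than 40 members whose consensus is classified correct against the truth.

## Simulator

The generator emulates a two-step UMI library prep on single-source diploid
templates of the packaged panel.

**Barcoding PCR** (4 cycles): per template copy, three processes with
per-cycle replication probability `efficiency` — genomic template → long
product; long product → UMI-labelled short product (a fresh random UMI per
labelling event); short product → short product (UMI inherited, so one UMI
can label a small clan of barcoding-stage molecules). Errors accumulated
before labelling propagate into the founder and later appear as families
whose correct sequence is absent; errors at or just after labelling leave it
a minority.

**Adaptor PCR** (27 cycles): each founder grows an independent Galton–Watson
family. Populations are represented as variant→multiplicity maps rather than
individual molecules (a capped family holds thousands of identical
molecules); replication draws are binomial per variant and error-bearing
copies are sampled from the exact conditional distribution given at least
one error (first-firing-event decomposition over the slip events and the
substitution block), so the per-molecule error model is preserved exactly.
Above `family_cap` (default 4096) the family is uniformly subsampled each
cycle, which keeps variant shares unbiased (tested). Molecules whose repeat
region no longer decomposes after a substitution cannot slip further — a
rare state (it requires a substitution followed by a slip opportunity in the
same lineage) accepted for simplicity.

**Error model per replication**: each block of `c ≥ min_slip_units` units
slips with probability `1-(1-slip_rate)^c`, removing one unit with
probability `minus_bias` else adding one (n−2 only arises from two events in
a lineage, the standard single-step slippage model); every base of the
amplicon substitutes with probability `sub_rate`. Sequencing adds a constant
per-base substitution error and constant quality strings, since qualities
are unused downstream.

Defaults, chosen once as a realistic regime for a tetranucleotide forensic
panel: `slip_rate` 5·10⁻⁴ per unit per replication, `minus_bias` 0.85,
`sub_rate` 10⁻⁵ per base per replication, sequencing error 3·10⁻⁴ per base,
efficiency 0.8 (barcoding) and 0.95 (adaptor), UMI 12 nt + stem 16 nt
(summing to the 28 bp construct), 12 templates per allele and 50,000 reads
per run. Under these defaults the read-level n−1 fraction sits in the
mid-single-digit percent range (≈7–8 % pooled over the panel, with the
shortest-LUS marker lowest and D12S391 highest), n+1 is roughly one fifth of
n−1, and consensus calling reduces n−1 several-fold — the qualitative regime
of UMI-based STR sequencing. What the simulator does **not** model:
primer-dimer formation, thermodynamics of annealing/ramp rates, polymerase
buffer chemistry, strand-level replication, indel sequencing errors, quality
score structure, or paired-end reads (reads are emitted pre-merged; a naive
overlap merger is provided for user data, replacing no particular published
merger). Passing tests therefore demonstrate internal consistency of the
analysis under this error model, not concordance with any real instrument
run.

## Assignment

Reads are assigned by exact-first, then bounded-Hamming (default ≤2
mismatches per flank) matching of each marker's 20-nt flank anchors, with
the UMI taken positionally from the first 12 bases. Indel-tolerant flank
matching is deliberately out of scope: anchors are short and synthetic reads
carry no flank indels. Reads matching two markers are counted `ambiguous`,
matching none `no_flank_match`; raising the mismatch allowance never loses
assigned reads (tested).

## Statistics

Pairwise comparisons use the two-sided Mann–Whitney U test, exact when the
combined sample is ≤20 without ties, otherwise the normal approximation with
tie correction; two identical constant groups return p = 1. Multi-group
comparisons use Kruskal–Wallis with tie correction followed by Dunn's post
hoc z tests on mean ranks,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),

implemented directly since no installed package provides Dunn's test, and
cross-checked against hand rank-formula evaluation. Benjamini–Hochberg
adjustment (statsmodels) is applied within each family of pairwise
comparisons, with significance at adjusted p < 0.05.

## Slip-rate recovery

The expected replication depth of a random family member after c adaptor
cycles at efficiency e is c·e/(1+e) (each cycle a uniform member is a fresh
copy with probability e/(1+e); uniform capping leaves this unbiased). For a
single-stretch marker, E[prop_minus_one] ≈ depth · (1−(1−s)^LUS) ·
minus_bias to first order, and inverting this at known design parameters
recovers s. Known biases — members reached through barcoding-stage
short-product copies (extra depth, a few percent up) and multi-slip lineages
(≈λe^{−λ} correction, a few percent down) — partially cancel and stay well
inside the 25 % tolerance the recovery test uses.

## Problem sizes in tests

Test and acceptance runs use scaled configurations chosen as the package's
own defaults for fast feedback: family caps of 256–2048, 2,000–55,000 reads,
and 10 seeds for the error-reduction sign check; the Monte-Carlo checks of
closed-form error probabilities use 10⁵ replications (standard errors well
below the asserted tolerances). The slip-rate recovery run uses ≈550
qualifying families at the 3×3 grid's centre point.
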