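# strumi

UMI-family consensus calling and PCR error analysis for short tandem repeat
(STR) amplicon sequencing, with a seeded branching-process simulator of the
two-step barcoding/adaptor library preparation.

## The problem

STR markers — loci of tandemly repeated 1–6 bp motifs — are genotyped by PCR
amplification and sequencing, but the polymerase introduces two kinds of
error. *Stutter* products gain or lose whole repeat units through
slipped-strand mispairing (the n−1 product, one unit short, dominates, and
longer uninterrupted repeat stretches slip more). *Base substitutions* are
random misincorporations governed by polymerase fidelity. Unique molecular
identifiers (UMIs) attached during a low-cycle barcoding PCR let every
sequenced read be traced back to one template molecule: reads sharing a UMI
form a *family*, the family's plurality sequence is its *consensus read*, and
errors arising late in amplification are voted away. Comparing error
proportions before and after consensus calling — and dissecting the variant
spectrum inside families — separates errors made on genomic template in the
first cycles from errors made on amplicon template later. This package
implements that analysis for forensic-style tetranucleotide STR panels and
ships a ground-truthed simulator to exercise it.

## What it computes

For a read (or consensus) sequence $s$ compared with a reference $r$ in
repeat space, the classifier decomposes both into motif blocks (e.g.
`TCTA[1]TCTG[3]TCTA[14]`) and assigns one of: `correct`, `n_minus_1`,
`n_minus_2`, `n_plus_1`, `n_pm_0` (simultaneous loss and gain in different
stretches, net length zero), `base_substitution`, or `other`.

Per UMI family with consensus support $k$ out of $n$ members, the five family
features are

- purity $= k/n$,
- proportion of n variants $=$ (distinct member sequences)$/n$,
- proportion minus one / minus two / plus one $=$ fraction of members exactly
  one/two units shorter, or one unit longer, than the consensus (one unit =
  the marker's dominant motif length, 4 bp for the packaged panel).

The simulator models barcoding PCR (default 4 cycles) as three processes —
long products from genomic template, UMI-labelled short products from long
products, short products from short products — and adaptor PCR (default 27
cycles) as a capped Galton–Watson process per family. Each replication slips
at a block of $c$ units with probability $1-(1-\sigma)^c$ (one unit removed
with probability `minus_bias`, else added) and substitutes each base with
probability `sub_rate`. Group comparisons use Mann–Whitney U,
Kruskal–Wallis with Dunn's post hoc z tests, and Benjamini–Hochberg FDR
control.

The packaged panel (`strumi/data/table1_panel.json`) covers D2S441, D1S1656,
D3S1358, vWA, D8S1179, D21S11 and D12S391 with the 2800M reference genotypes
in bracket notation. Flank anchors are synthetic 20-mers — real-data use
requires user-supplied flanks.

## Worked example

```python
import strumi

cfg = strumi.SimConfig(reads_per_sample=25_000, family_cap=2048, seed=7)
run = strumi.RunConfig(outdir="demo", sim=cfg, seed=7)
manifest = strumi.run_pipeline(run)
```

This simulates a full 7-marker run, assigns reads, builds UMI families, calls
consensus, classifies errors and writes TSV report tables into `demo/`. With
seed 7 it prints/records:

```
n_raw_reads: 25000        prop_assigned: 1.0
n_families: 733           n_consensus: 643 (ties: 0)

summary_read.tsv:       prop_n_minus_1 0.0760  prop_n_plus_1 0.0108  prop_other_errors 0.0448
summary_consensus.tsv:  prop_n_minus_1 0.0156  prop_n_plus_1 0.0016  prop_other_errors 0.0047

features.tsv (231 families > 40 members, correct consensus), means:
purity 0.873  prop_n_variants 0.086  prop_minus_one 0.077  prop_minus_two 0.004  prop_plus_one 0.012
```

Reading: 7.6 % of raw STR reads are n−1 stutters; consensus calling reduces
that about five-fold to 1.6 %, because only errors from the barcoding PCR (or
the first adaptor cycles) can capture a family's plurality. Inside
correct-consensus families, 7.7 % of members are one unit short — the
within-family view of adaptor-PCR slippage. The same pipeline runs from the
shell: `strumi run --out demo --seed 7`, with `simulate`, `assign`,
`families` and `report` subcommands for the individual stages, and
`--no-umi` for the read-level-only analysis.

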