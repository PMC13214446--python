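"""Branching-process simulator: per-replication error model, barcoding tree,
adaptor families, sequencing sampling, determinism and calibration behaviour."""

import itertools
import math
import os
from collections import Counter

import numpy as np
import pytest

import strumi
from strumi import (
    ErrorClass,
    Molecule,
    PolymeraseProfile,
    SimConfig,
    expand_to_sequence,
    generate_dataset,
    replicate_molecule,
    simulate_adaptor,
    simulate_barcoding,
)

from conftest import (
    error_free_profiles,
    read_level_class_counts,
    single_marker_panel,
    small_config,
)


def make_molecule(panel, marker_name="SYN", umi="A" * 12):
    marker = panel[marker_name]
    allele = marker.reference_genotype[0]
    return Molecule(
        marker=marker,
        kind="short",
        left=marker.left_flank,
        repeat=expand_to_sequence(allele),
        right=marker.right_flank,
        true_allele=strumi.serialize_strnaming(allele),
        umi=umi,
    )


class TestReplicateMolecule:
    def test_zero_rates_identity(self):
        panel = single_marker_panel(10)
        m = make_molecule(panel)
        profile = PolymeraseProfile("none", sub_rate=0.0, slip_rate=0.0)
        child = replicate_molecule(m, profile, np.random.default_rng(0))
        assert child.amplicon == m.amplicon
        assert child.lineage_errors == ()

    def test_slip_probability_matches_closed_form(self):
        """A block of 14 units slips per replication with 1-(1-s)**14."""
        panel = single_marker_panel(14)
        m = make_molecule(panel)
        s = 1e-3
        profile = PolymeraseProfile("sliponly", sub_rate=0.0, slip_rate=s,
                                    minus_bias=1.0)
        rng = np.random.default_rng(42)
        n = 100_000
        slipped = sum(
            1
            for _ in range(n)
            if replicate_molecule(m, profile, rng).repeat != m.repeat
        )
        expected = 1.0 - (1.0 - s) ** 14
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(slipped / n - expected) < 4 * se

    def test_minus_slip_removes_one_unit(self, panel):
        marker = panel["D3S1358"]
        allele = marker.reference_genotype[0]  # TCTA[1]TCTG[3]TCTA[14]
        m = Molecule(marker, "short", marker.left_flank,
                     expand_to_sequence(allele), marker.right_flank,
                     strumi.serialize_strnaming(allele), umi="C" * 12)
        profile = PolymeraseProfile("certain", sub_rate=0.0, slip_rate=1.0,
                                    minus_bias=1.0, min_slip_units=10)
        child = replicate_molecule(m, profile, np.random.default_rng(0))
        d = marker.decompose(child.repeat)
        assert strumi.serialize_strnaming(d) == "TCTA[1]TCTG[3]TCTA[13]"
        assert child.n_slips == 1

    def test_substitution_changes_one_base(self):
        panel = single_marker_panel(10)
        m = make_molecule(panel)
        profile = PolymeraseProfile("subby", sub_rate=0.01, slip_rate=0.0)
        rng = np.random.default_rng(5)
        children = [replicate_molecule(m, profile, rng) for _ in range(500)]
        mutated = [c for c in children if c.amplicon != m.amplicon]
        assert mutated  # ~ 1-(1-0.01)^96 per replication
        for c in mutated[:20]:
            assert len(c.amplicon) == len(m.amplicon)
            assert c.n_subs == sum(
                x != y for x, y in zip(c.amplicon, m.amplicon)
            )


def barcoding_count_recursion(cycles: int, eff: float) -> tuple[float, float]:
    """Expected (long, short) product counts per template: exact linear
    recursion of the three-process tree."""
    longs, shorts = 0.0, 0.0
    for _ in range(cycles):
        shorts = shorts * (1 + eff) + longs * eff
        longs = longs + eff
    return longs, shorts


class TestBarcoding:
    def test_deterministic_tree_at_full_efficiency(self):
        """At efficiency 1 the 4-cycle process tree is fixed: 11 UMI-labelled
        short products per template copy (enumeration oracle)."""
        panel = single_marker_panel(10)
        profile = PolymeraseProfile("full", sub_rate=0.0, slip_rate=0.0,
                                    efficiency=1.0)
        cfg = small_config(panel, n_templates_per_allele=1,
                           barcoding_profile=profile)
        founders = simulate_barcoding(panel, cfg, np.random.default_rng(0))
        _, expected = barcoding_count_recursion(4, 1.0)
        assert expected == 11.0
        assert len(founders) == 2 * 11  # homozygous: two template alleles
        assert all(f.umi is not None for f in founders)
        ref = expand_to_sequence(panel["SYN"].reference_genotype[0])
        assert all(f.repeat == ref for f in founders)

    def test_expected_founder_count_matches_recursion(self):
        panel = single_marker_panel(10)
        profile = PolymeraseProfile("partial", sub_rate=0.0, slip_rate=0.0,
                                    efficiency=0.8)
        cfg = small_config(panel, n_templates_per_allele=40,
                           barcoding_profile=profile)
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(30):
            founders = simulate_barcoding(panel, cfg, rng)
            counts.append(len(founders) / (2 * 40))
        _, expected = barcoding_count_recursion(4, 0.8)
        mean = np.mean(counts)
        assert abs(mean - expected) < 0.25  # se ~ 0.05 at this sample size

    def test_distinct_umis_per_labelling_event(self):
        panel = single_marker_panel(10)
        profile = PolymeraseProfile("full", sub_rate=0.0, slip_rate=0.0,
                                    efficiency=1.0)
        cfg = small_config(panel, n_templates_per_allele=5,
                           barcoding_profile=profile)
        founders = simulate_barcoding(panel, cfg, np.random.default_rng(2))
        # shorts copied from shorts share a UMI; labelling events are distinct
        labelled = Counter(f.umi for f in founders)
        # at eff 1: 6 labelling events per template, 11 shorts
        assert len(labelled) == 5 * 2 * 6

    def test_early_errors_propagate_to_founders(self):
        """Founder error fraction matches 1-(1-sub)^(L*depth) averaged over
        the enumerated depth distribution of the full-efficiency tree."""
        panel = single_marker_panel(10)
        sub = 0.002
        profile = PolymeraseProfile("dirty", sub_rate=sub, slip_rate=0.0,
                                    efficiency=1.0)
        cfg = small_config(panel, n_templates_per_allele=60,
                           barcoding_profile=profile)
        founders = simulate_barcoding(panel, cfg, np.random.default_rng(3))
        ref = expand_to_sequence(panel["SYN"].reference_genotype[0])
        amp_len = len(panel["SYN"].left_flank) + len(ref) + len(
            panel["SYN"].right_flank
        )
        frac = sum(1 for f in founders if f.repeat != ref) / len(founders)
        # depth multiset of the 11 founders at eff=1 (hand enumeration of the
        # 4-cycle tree): six at depth 2, four at depth 3, one at depth 4
        depths = [2] * 6 + [3] * 4 + [4] * 1
        # only the repeat region mismatch is observed; errors land in the
        # repeat with probability len(ref)/amp_len
        p_err = np.mean([
            1 - (1 - sub) ** (len(ref) * d) for d in depths
        ])
        assert abs(frac - p_err) < 4 * math.sqrt(p_err * (1 - p_err) / len(founders))


class TestAdaptor:
    def test_error_free_families_are_uniform(self):
        panel = single_marker_panel(10)
        bar, ada = error_free_profiles()
        cfg = small_config(panel, barcoding_profile=bar, adaptor_profile=ada)
        rng = np.random.default_rng(0)
        founders = simulate_barcoding(panel, cfg, rng)
        pops = simulate_adaptor(founders, cfg, rng)
        for pop in pops:
            assert len(pop.variants) == 1
            (variant,) = pop.variants.values()
            assert variant.repeat == pop.founder.repeat

    def test_full_efficiency_doubles_without_cap(self):
        panel = single_marker_panel(10)
        ada = PolymeraseProfile("full", sub_rate=0.0, slip_rate=0.0,
                                efficiency=1.0)
        cfg = small_config(panel, adaptor_profile=ada, adaptor_cycles=6,
                           family_cap=10_000)
        founder = make_molecule(panel)
        (pop,) = simulate_adaptor([founder], cfg, np.random.default_rng(0))
        assert pop.size == 2 ** 6

    def test_cap_limits_family_size(self):
        panel = single_marker_panel(10)
        ada = PolymeraseProfile("full", sub_rate=0.0, slip_rate=0.0,
                                efficiency=1.0)
        cfg = small_config(panel, adaptor_profile=ada, adaptor_cycles=10,
                           family_cap=128)
        founder = make_molecule(panel)
        (pop,) = simulate_adaptor([founder], cfg, np.random.default_rng(0))
        assert pop.size == 128

    def test_two_cycle_slip_distribution_matches_enumeration(self):
        """Single founder, 2 cycles, efficiency 1, slippage only: the number
        of n-1 molecules among the 4 descendants follows the exact law of the
        3 independent replication events (founder->m1, founder->m2, m1->m3)."""
        panel = single_marker_panel(10)
        r = 0.05
        q = 1 - (1 - r) ** 10
        ada = PolymeraseProfile("sliponly", sub_rate=0.0, slip_rate=r,
                                minus_bias=1.0, efficiency=1.0)
        cfg = small_config(panel, adaptor_profile=ada, adaptor_cycles=2,
                           family_cap=100)
        ref = make_molecule(panel).repeat

        # oracle: enumerate the 2^3 slip patterns; a molecule is n-1 when its
        # lineage saw exactly one slip (two slips -> n-2)
        law = Counter()
        for a, b, c in itertools.product([0, 1], repeat=3):
            p = (q if a else 1 - q) * (q if b else 1 - q) * (q if c else 1 - q)
            n_minus_1 = a + b + (1 if a + c == 1 else 0)
            law[n_minus_1] += p

        rng = np.random.default_rng(123)
        n_rep = 4000
        observed = Counter()
        for _ in range(n_rep):
            (pop,) = simulate_adaptor([make_molecule(panel)], cfg, rng)
            lens = []
            for v in pop.variants.values():
                lens.extend([len(v.repeat)] * v.count)
            assert len(lens) == 4
            observed[sum(1 for L in lens if L == len(ref) - 4)] += 1
        for k, p in law.items():
            se = math.sqrt(p * (1 - p) / n_rep)
            assert abs(observed[k] / n_rep - p) < 4.5 * se + 1e-9

    def test_subsampling_preserves_variant_shares(self):
        """Uniform capping keeps the minority-variant share unbiased."""
        panel = single_marker_panel(10)
        marker = panel["SYN"]
        ada = PolymeraseProfile("clean", sub_rate=0.0, slip_rate=0.0,
                                efficiency=0.9)
        cfg = small_config(panel, adaptor_profile=ada, adaptor_cycles=8,
                           family_cap=64)
        ref = make_molecule(panel)
        shares = []
        rng = np.random.default_rng(9)
        for _ in range(300):
            (pop,) = simulate_adaptor([ref], cfg, rng)
            # seed a 25% minority variant by hand, then run 5 more cycles
            minority = expand_to_sequence(
                strumi.parse_strnaming("TCTA[9]")
            )
            pop._add(marker.left_flank, minority, marker.right_flank,
                     pop.size // 3, 1, 0)
            start = pop.size
            target = next(
                v for v in pop.variants.values() if v.repeat == minority
            ).count / start
            for _ in range(5):
                pop.step(rng, cfg.family_cap)
            now = next(
                v for v in pop.variants.values() if v.repeat == minority
            ).count / pop.size
            shares.append(now - target)
        assert abs(np.mean(shares)) < 0.01

    def test_founders_without_umi_rejected(self):
        panel = single_marker_panel(10)
        cfg = small_config(panel)
        bad = make_molecule(panel)
        bad.umi = None
        with pytest.raises(ValueError, match="UMI"):
            simulate_adaptor([bad], cfg, np.random.default_rng(0))


class TestDataset:
    def test_seed_determinism_byte_identical(self, tmp_path):
        panel = single_marker_panel(10)
        cfg = small_config(panel, seed=77)
        p1 = generate_dataset(cfg, str(tmp_path / "a"))
        p2 = generate_dataset(cfg, str(tmp_path / "b"))
        assert open(p1["fastq"]).read() == open(p2["fastq"]).read()
        assert open(p1["truth"]).read() == open(p2["truth"]).read()

    def test_all_markers_present(self, default_run):
        truth = open(default_run["paths"]["truth"]).read().splitlines()
        markers = {line.split("\t")[1] for line in truth[1:]}
        assert markers == set(default_run["config"].panel.names)

    def test_read_ids_conserved(self, default_run):
        fastq_ids = [
            line[1:].strip()
            for line in open(default_run["paths"]["fastq"])
            if line.startswith("@")
        ]
        truth_ids = [
            line.split("\t")[0]
            for line in open(default_run["paths"]["truth"]).read().splitlines()[1:]
        ]
        assert fastq_ids == truth_ids
        assert len(set(fastq_ids)) == len(fastq_ids)

    def test_zero_reads_gives_empty_outputs(self, tmp_path):
        panel = single_marker_panel(10)
        cfg = small_config(panel, reads_per_sample=0)
        paths = generate_dataset(cfg, str(tmp_path))
        assert open(paths["fastq"]).read() == ""
        assert len(open(paths["truth"]).read().splitlines()) == 1  # header

    def test_invalid_config_lists_fields(self):
        panel = single_marker_panel(10)
        cfg = small_config(panel, reads_per_sample=-1, umi_length=0)
        with pytest.raises(ValueError) as err:
            cfg.validate()
        assert "reads_per_sample" in str(err.value)
        assert "umi_length" in str(err.value)


def _read_level_n_minus_1(slip_rate: float, lus: int, seed: int) -> float:
    panel = single_marker_panel(lus)
    bar = PolymeraseProfile("bar", sub_rate=0.0, slip_rate=slip_rate,
                            efficiency=0.8)
    ada = PolymeraseProfile("ada", sub_rate=0.0, slip_rate=slip_rate,
                            efficiency=0.95)
    cfg = small_config(panel, n_templates_per_allele=6, family_cap=256,
                       reads_per_sample=4000, seq_error_rate=0.0,
                       barcoding_profile=bar, adaptor_profile=ada, seed=seed)
    rng = np.random.default_rng(seed)
    founders = simulate_barcoding(panel, cfg, rng)
    pops = simulate_adaptor(founders, cfg, rng)
    counts: Counter = Counter()
    ref = expand_to_sequence(panel["SYN"].reference_genotype[0])
    total = 0
    for pop in pops:
        for v in pop.variants.values():
            total += v.count
            if len(v.repeat) == len(ref) - 4:
                counts["n1"] += v.count
    return counts["n1"] / total


class TestCalibrationBehaviour:
    def test_n_minus_1_monotone_in_slip_rate(self):
        fracs = [
            _read_level_n_minus_1(s, lus=14, seed=5)
            for s in (2.5e-4, 5e-4, 1e-3)
        ]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_longer_stretch_stutters_more(self):
        low = _read_level_n_minus_1(5e-4, lus=10, seed=8)
        high = _read_level_n_minus_1(5e-4, lus=15, seed=8)
        assert high > low
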