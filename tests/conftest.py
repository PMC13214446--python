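"""Shared fixtures: the packaged panel, synthetic single-marker panels, and
small simulation configurations sized for fast, deterministic tests."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

import strumi
from strumi import (
    MarkerDef,
    Panel,
    PolymeraseProfile,
    SimConfig,
    parse_strnaming,
)

# synthetic 20-nt flank anchors free of panel repeat motifs
FLANKS = [
    ("CCTGTGAGCGATTAGCGTTG", "GGTCAACCTTCGAGCATTGA"),
    ("TGCCAATCGAGTGACCTTGA", "CATTGGAGCAGTCGTAACCT"),
    ("GATCCGTTAAGCGTGCATCA", "ACGGATTCACCGTGATAGGT"),
]


def single_marker_panel(lus: int, name: str = "SYN", flank_idx: int = 0) -> Panel:
    """Homozygous single-stretch tetranucleotide marker TCTA[lus]."""
    allele = parse_strnaming(f"TCTA[{lus}]")
    left, right = FLANKS[flank_idx]
    marker = MarkerDef(
        name=name,
        left_flank=left,
        right_flank=right,
        motifs=("TCTA", "TCTG"),
        reference_genotype=(allele, allele),
        max_read_len=200,
    )
    return Panel((marker,))


def error_free_profiles() -> tuple[PolymeraseProfile, PolymeraseProfile]:
    bar = PolymeraseProfile("errfree_bar", sub_rate=0.0, slip_rate=0.0,
                            efficiency=0.8)
    ada = PolymeraseProfile("errfree_ada", sub_rate=0.0, slip_rate=0.0,
                            efficiency=0.95)
    return bar, ada


def small_config(panel: Panel, **overrides) -> SimConfig:
    """A quick configuration: shallow families, modest read counts."""
    cfg = SimConfig(
        panel=panel,
        n_templates_per_allele=4,
        family_cap=256,
        reads_per_sample=2000,
        seed=0,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def read_level_class_counts(assigned, panel) -> Counter:
    """Classify assigned reads against the reference genotype; counts by class."""
    counts: Counter = Counter()
    cache: dict = {}
    for a in assigned:
        key = (a.marker, a.repeat_region)
        v = cache.get(key)
        if v is None:
            v = strumi.classify_vs_truth(a.repeat_region, panel[a.marker])
            cache[key] = v
        counts[v.error_class] += 1
    return counts


@pytest.fixture(scope="session")
def panel() -> Panel:
    return strumi.default_panel()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One default-parameter synthetic run, shared across tests that only read
    its outputs: FASTQ + truth paths plus the assigned reads."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = SimConfig(reads_per_sample=20_000, family_cap=1024, seed=11)
    paths = strumi.generate_dataset(cfg, str(outdir))
    assigned, reasons = strumi.assign_fastq(paths["fastq"], cfg.panel)
    return {"config": cfg, "paths": paths, "assigned": assigned, "reasons": reasons}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
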