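"""End-to-end pipeline: simulate -> assign -> families -> classify -> features
-> report.

Every stage writes plain TSV/FASTQ/JSON artifacts into the run directory so
each stage is independently runnable and inspectable; a ``.stage_<name>.done``
marker records completed stages and a manifest ties the run to its seed and
configuration digest.  Runs are deterministic per seed.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import assign as assign_mod
from .classify import (
    ClassifiedRead,
    classify_family_members,
    classify_vs_truth,
    sample_incorrect_families,
)
from .consensus import build_families, call_consensus
from .features import compute_features, select_feature_families
from .panel import (
    AlleleStructure,
    Panel,
    default_panel,
    load_panel,
    serialize_strnaming,
)
from .report import classified_frame, summarize, write_report
from .simulate import SimConfig, config_digest, generate_dataset

logger = logging.getLogger("strumi")


@dataclass
class RunConfig:
    """Thresholds and wiring for one pipeline run.

    Defaults follow the analysis design: consensus from families of >= 3
    members, feature analysis on families of > 40 members with a correct
    consensus, 50 incorrect-consensus families sampled for inspection, and at
    most 2 mismatches tolerated per flank during marker assignment.
    """

    outdir: str = "strumi_run"
    panel_file: Optional[str] = None
    sim: SimConfig = field(default_factory=SimConfig)
    fastq: Optional[str] = None  # analyse an existing FASTQ instead of simulating
    min_family_size: int = 3
    feature_min_members: int = 40
    inspection_k: int = 50
    max_flank_mismatches: int = 2
    collapse_umi_distance: int = 0
    no_umi: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        bad = [
            name
            for name in ("min_family_size", "feature_min_members", "inspection_k")
            if getattr(self, name) < 1
        ]
        if self.max_flank_mismatches < 0:
            bad.append("max_flank_mismatches")
        if bad:
            raise ValueError(f"invalid RunConfig fields: {', '.join(bad)}")
        self.sim.validate()

    def resolve_panel(self) -> Panel:
        if self.panel_file is not None:
            return load_panel(self.panel_file)
        return self.sim.panel if self.sim is not None else default_panel()


class StageError(RuntimeError):
    def __init__(self, stage: str, path: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed on {path}: {cause}")
        self.stage = stage


def _mark_done(outdir: str, stage: str) -> None:
    with open(os.path.join(outdir, f".stage_{stage}.done"), "w") as fh:
        fh.write("done\n")


def _variant_label(seq: str, marker) -> str:
    decomp = marker.decompose(seq)
    if isinstance(decomp, AlleleStructure):
        return serialize_strnaming(decomp)
    return seq


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written to disk)."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    os.makedirs(cfg.outdir, exist_ok=True)
    panel = cfg.resolve_panel()
    cfg.sim.panel = panel
    rng = np.random.default_rng(cfg.seed)

    manifest: dict = {
        "seed": cfg.seed,
        "config_digest": config_digest(cfg.sim),
        "thresholds": {
            "min_family_size": cfg.min_family_size,
            "feature_min_members": cfg.feature_min_members,
            "inspection_k": cfg.inspection_k,
            "max_flank_mismatches": cfg.max_flank_mismatches,
            "collapse_umi_distance": cfg.collapse_umi_distance,
        },
        "no_umi": cfg.no_umi,
        "files": {},
    }

    # --- stage: simulate -------------------------------------------------
    stage = "simulate"
    try:
        if cfg.fastq is None:
            paths = generate_dataset(cfg.sim, cfg.outdir, seed=cfg.seed)
            fastq = paths["fastq"]
            manifest["files"].update(paths)
        else:
            fastq = cfg.fastq
            manifest["files"]["fastq"] = fastq
        _mark_done(cfg.outdir, stage)
    except Exception as err:  # noqa: BLE001 - stage boundary
        raise StageError(stage, cfg.outdir, err) from err
    logger.info("simulate: %s", fastq)

    # --- stage: assign ---------------------------------------------------
    stage = "assign"
    try:
        assigned, reasons = assign_mod.assign_fastq(
            fastq,
            panel,
            umi_length=cfg.sim.umi_length,
            stem_length=cfg.sim.stem_length,
            max_flank_mismatches=cfg.max_flank_mismatches,
        )
        n_raw = len(assigned) + sum(reasons.values())
        assigned_df = pd.DataFrame(
            [
                (a.read_id, a.marker, a.umi, a.repeat_region,
                 a.left_mismatches, a.right_mismatches)
                for a in assigned
            ],
            columns=["read_id", "marker", "umi", "repeat_region",
                     "left_mismatches", "right_mismatches"],
        )
        reasons_df = pd.DataFrame(
            sorted(reasons.items()), columns=["reason", "count"]
        )
        assigned_path = os.path.join(cfg.outdir, "assigned.tsv")
        assigned_df.to_csv(assigned_path, sep="\t", index=False)
        reasons_path = os.path.join(cfg.outdir, "unassigned_counts.tsv")
        reasons_df.to_csv(reasons_path, sep="\t", index=False)
        manifest["files"]["assigned"] = assigned_path
        manifest["files"]["unassigned_counts"] = reasons_path
        manifest["n_raw_reads"] = n_raw
        manifest["n_assigned"] = len(assigned)
        manifest["prop_assigned"] = len(assigned) / n_raw if n_raw else None
        _mark_done(cfg.outdir, stage)
    except Exception as err:
        raise StageError(stage, fastq, err) from err
    logger.info("assign: %d/%d reads assigned", len(assigned), n_raw)

    # --- stage: classify reads vs truth (with and without UMI) -----------
    stage = "classify_reads"
    tables: dict[str, pd.DataFrame] = {}
    try:
        verdict_cache: dict[tuple[str, str], ClassifiedRead] = {}

        def vs_truth(marker_name: str, seq: str, seq_id: str):
            key = (marker_name, seq)
            hit = verdict_cache.get(key)
            if hit is None:
                hit = classify_vs_truth(seq, panel[marker_name])
                verdict_cache[key] = hit
            return ClassifiedRead(
                seq_id, hit.ref_id, hit.error_class, hit.unit_delta,
                hit.block_deltas, hit.substitution_count, hit.ambiguous_reference,
            )

        read_verdicts = [
            vs_truth(a.marker, a.repeat_region, a.read_id) for a in assigned
        ]
        read_df = classified_frame(read_verdicts, level="read")
        read_df["marker"] = [a.marker for a in assigned]
        tables["classified_reads"] = read_df
        tables["summary_read"] = summarize(read_df, ["level"])
        tables["summary_read_by_marker"] = summarize(read_df, ["level", "marker"])
        _mark_done(cfg.outdir, stage)
    except Exception as err:
        raise StageError(stage, assigned_path, err) from err

    families = []
    consensus_map = {}
    if not cfg.no_umi:
        # --- stage: families + consensus ---------------------------------
        stage = "families"
        try:
            families = build_families(
                assigned, collapse_umi_distance=cfg.collapse_umi_distance
            )
            fam_df = pd.DataFrame(
                [(f.marker, f.umi, f.size, f.n_variants) for f in families],
                columns=["marker", "umi", "size", "n_variants"],
            )
            fam_path = os.path.join(cfg.outdir, "families.tsv")
            fam_df.to_csv(fam_path, sep="\t", index=False)
            manifest["files"]["families"] = fam_path

            records = []
            for fam in families:
                rec = call_consensus(fam, cfg.min_family_size)
                if rec is not None:
                    consensus_map[fam.family_id] = (fam, rec)
                    records.append(rec)
            cons_df = pd.DataFrame(
                [
                    (r.marker, r.umi, r.consensus, r.size, r.support, r.tie)
                    for r in records
                ],
                columns=["marker", "umi", "consensus", "size", "support", "tie"],
            )
            cons_path = os.path.join(cfg.outdir, "consensus.tsv")
            cons_df.to_csv(cons_path, sep="\t", index=False)
            manifest["files"]["consensus"] = cons_path
            manifest["n_families"] = len(families)
            manifest["n_consensus"] = len(records)
            manifest["n_consensus_ties"] = int(sum(r.tie for r in records))
            _mark_done(cfg.outdir, stage)
        except Exception as err:
            raise StageError(stage, assigned_path, err) from err
        logger.info(
            "families: %d families, %d consensus reads", len(families), len(records)
        )

        # --- stage: classify consensus + members -------------------------
        stage = "classify_consensus"
        try:
            cons_verdicts = []
            for fam_id, (fam, rec) in consensus_map.items():
                v = vs_truth(rec.marker, rec.consensus, fam_id)
                cons_verdicts.append((fam_id, v))
            cons_cls_df = classified_frame(
                [v for _, v in cons_verdicts], level="consensus"
            )
            cons_cls_df["marker"] = [
                consensus_map[f][1].marker for f, _ in cons_verdicts
            ]
            tables["classified_consensus"] = cons_cls_df
            tables["summary_consensus"] = summarize(cons_cls_df, ["level"])
            tables["summary_consensus_by_marker"] = summarize(
                cons_cls_df, ["level", "marker"]
            )

            member_rows = []
            for fam_id, (fam, rec) in consensus_map.items():
                marker = panel[rec.marker]
                _, counts = classify_family_members(
                    fam.members, rec.consensus, marker
                )
                for cls, cnt in sorted(counts.items(), key=lambda kv: kv[0].value):
                    member_rows.append((fam_id, rec.marker, cls.value, cnt))
            tables["member_vs_consensus"] = pd.DataFrame(
                member_rows, columns=["family_id", "marker", "error_class", "count"]
            )

            # inspection dossiers of incorrect-consensus families
            sampled = sample_incorrect_families(
                cons_verdicts, k=cfg.inspection_k, rng=rng
            )
            dossiers = []
            for fam_id in sampled:
                fam, rec = consensus_map[fam_id]
                marker = panel[rec.marker]
                variant_counts = Counter(seq for _, seq in fam.members)
                dossiers.append(
                    {
                        "family_id": fam_id,
                        "marker": rec.marker,
                        "size": fam.size,
                        "consensus": _variant_label(rec.consensus, marker),
                        "true_alleles": [
                            serialize_strnaming(a) for a in marker.reference_genotype
                        ],
                        "correct_sequence_present": any(
                            seq in marker.reference_sequences()
                            for seq in variant_counts
                        ),
                        "variants": [
                            {"structure": _variant_label(seq, marker), "count": cnt}
                            for seq, cnt in variant_counts.most_common()
                        ],
                    }
                )
            dossier_path = os.path.join(cfg.outdir, "incorrect_family_dossiers.json")
            with open(dossier_path, "w") as fh:
                json.dump(dossiers, fh, indent=1)
                fh.write("\n")
            manifest["files"]["incorrect_family_dossiers"] = dossier_path
            _mark_done(cfg.outdir, stage)
        except Exception as err:
            raise StageError(stage, cons_path, err) from err

        # --- stage: features ---------------------------------------------
        stage = "features"
        try:
            verdict_by_family = {fid: v for fid, v in cons_verdicts}
            selected = select_feature_families(
                consensus_map.values(),
                consensus_verdicts=verdict_by_family,
                min_members_exclusive=cfg.feature_min_members,
                require_correct_consensus=True,
            )
            feats = [
                compute_features(fam, rec, panel[rec.marker])
                for fam, rec in selected
            ]
            tables["features"] = pd.DataFrame(
                [
                    (
                        f.family_id, f.marker, f.size, f.purity,
                        f.prop_n_variants, f.prop_minus_one,
                        f.prop_minus_two, f.prop_plus_one,
                    )
                    for f in feats
                ],
                columns=[
                    "family_id", "marker", "size", "purity", "prop_n_variants",
                    "prop_minus_one", "prop_minus_two", "prop_plus_one",
                ],
            )
            manifest["n_feature_families"] = len(feats)
            _mark_done(cfg.outdir, stage)
        except Exception as err:
            raise StageError(stage, cfg.outdir, err) from err

    # --- stage: report ----------------------------------------------------
    stage = "report"
    try:
        paths = write_report(tables, cfg.outdir, manifest=None)
        manifest["files"].update(paths)
        manifest_path = os.path.join(cfg.outdir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        manifest["files"]["manifest"] = manifest_path
        _mark_done(cfg.outdir, stage)
    except Exception as err:
        raise StageError(stage, cfg.outdir, err) from err
    logger.info("report written to %s", cfg.outdir)
    return manifest
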