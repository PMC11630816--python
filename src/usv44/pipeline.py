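"""End-to-end orchestration: simulate/ingest -> classify -> subtypes ->
sequences -> clustering -> behavior, with one reproducibility manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from usv44 import behavior, classify, clustering, sequences, subtypes
from usv44.calltable_io import TYPE_ORDER, CallRecord, CallType
from usv44.simulate import Cohort, SyntheticConfig, generate_cohort

log = logging.getLogger("usv44.pipeline")


@dataclass
class PipelineConfig:
    seed: int = 7
    output_dir: Optional[str] = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    rules: classify.ClassRules = field(default_factory=classify.ClassRules)
    subtype_params: subtypes.SubtypeParams = field(default_factory=subtypes.SubtypeParams)
    bout_max_gap: float = sequences.DEFAULT_MAX_GAP
    dbscan_eps: Optional[float] = None  # None: estimate from the k-distance knee
    dbscan_min_pts: int = clustering.DEFAULT_MIN_PTS
    freeze_params: behavior.FreezeParams = field(default_factory=behavior.FreezeParams)
    run_subtypes: bool = True
    run_sequences: bool = True
    run_clustering: bool = True
    run_behavior: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        kwargs = dict(data)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig.from_dict(kwargs["synthetic"])
        if "rules" in kwargs:
            kwargs["rules"] = classify.ClassRules(**kwargs["rules"])
        if "subtype_params" in kwargs:
            kwargs["subtype_params"] = subtypes.SubtypeParams(**kwargs["subtype_params"])
        if "freeze_params" in kwargs:
            kwargs["freeze_params"] = behavior.FreezeParams(**kwargs["freeze_params"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None) -> dict:
    """Run every enabled stage and return the summary bundle.

    When ``cohort`` is not supplied a synthetic cohort is generated from
    ``config.synthetic`` with the master seed.  The summary is a plain
    JSON-serializable dict with one block per stage.
    """
    if cohort is None:
        log.info("simulate: n_rats=%d seed=%d", config.synthetic.n_rats, config.seed)
        cohort = generate_cohort(config.synthetic, seed=config.seed)

    summary: dict = {
        "seed": config.seed,
        "n_sessions": len(cohort.sessions),
        "manifest": cohort.manifest,
    }

    # classify
    log.info("classify: rules=%s", config.rules)
    typed_sessions = []
    all_typed: list[CallRecord] = []
    for meta, records, motion in cohort.sessions:
        labeled, _ = classify.classify_table(records, config.rules)
        typed_sessions.append((meta, labeled, motion))
        all_typed.extend(labeled)
    counts = {t.value: 0 for t in TYPE_ORDER}
    for rec in all_typed:
        counts[rec.call_type.value] += 1
    total = len(all_typed)
    profiles = [classify.iti_profile(recs, meta) for meta, recs, _ in typed_sessions]
    pooled_profile = classify.merge_iti_profiles(profiles)
    summary["classify"] = {
        "rules": asdict(config.rules),
        "n_calls": total,
        "counts": counts,
        "fortyfour_share": counts["fortyfour"] / total if total else None,
        "fortyfour_share_per_iti": pooled_profile.fortyfour_share,
    }

    if config.run_subtypes:
        log.info("subtypes: params=%s", config.subtype_params)
        subtype_counts: dict[str, int] = {}
        step_ratios = []
        for rec in all_typed:
            if rec.call_type is not CallType.FORTYFOUR or rec.contour is None:
                continue
            st, elements = subtypes.subtype_of_contour(rec.contour, config.subtype_params)
            subtype_counts[st.value] = subtype_counts.get(st.value, 0) + 1
            if len(elements) == 2:
                step_ratios.append(subtypes.element_ratio(elements))
        summary["subtypes"] = {
            "params": asdict(config.subtype_params),
            "counts": subtype_counts,
            "n_step_ratios": len(step_ratios),
            "mean_step_ratio": float(np.mean(step_ratios)) if step_ratios else None,
        }

    if config.run_sequences:
        log.info("sequences: max_gap=%.3f", config.bout_max_gap)
        tm_all = sequences.transition_matrix(all_typed, scope="all")
        tm_bout = sequences.transition_matrix(
            all_typed, scope="within_bout", max_gap=config.bout_max_gap
        )
        n_bouts = sum(
            len(sequences.segment_bouts(sorted(recs, key=lambda r: r.onset), config.bout_max_gap))
            for _, recs, _ in typed_sessions
        )
        summary["sequences"] = {
            "max_gap_s": config.bout_max_gap,
            "n_bouts": n_bouts,
            "all": tm_all.to_dict(),
            "within_bout": tm_bout.to_dict(),
        }

    if config.run_clustering:
        eps = config.dbscan_eps
        X, raw = clustering.standardize_features(all_typed)
        if eps is None:
            eps = clustering.estimate_eps(X, k=min(config.dbscan_min_pts, X.shape[0] - 1)).knee
        log.info("clustering: eps=%.4f min_pts=%d", eps, config.dbscan_min_pts)
        result = clustering.dbscan_cluster(
            X, eps=eps, min_pts=config.dbscan_min_pts, raw_features=raw
        )
        summary["clustering"] = result.to_dict()

    if config.run_behavior:
        log.info("behavior: params=%s", config.freeze_params)
        category_means: dict[str, list[float]] = {}
        for meta, recs, motion in typed_sessions:
            mask = behavior.score_freezing(motion, config.freeze_params)
            report = behavior.bin_linkage(sorted(recs, key=lambda r: r.onset), mask, meta)
            for cat, mean in report.freezing_by_category().items():
                category_means.setdefault(cat, []).append(mean)
        summary["behavior"] = {
            "params": asdict(config.freeze_params),
            "mean_freezing_by_category": {
                cat: float(np.mean(vals)) for cat, vals in category_means.items()
            },
        }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
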