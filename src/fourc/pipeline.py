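"""End-to-end orchestration: coverage profiles -> segments -> candidates."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import InteractionSegment, scan_and_call
from .genes import assemble_candidates, assess_locus_activity
from .simulate import Study

__all__ = ["call_all", "run_candidate_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    segments: dict[tuple[str, str], list[InteractionSegment]]
    activity: pd.DataFrame
    candidates: pd.DataFrame


def call_all(study: Study, threshold: float = 1e-8, **call_kwargs):
    """Call interaction segments for every viewpoint x cell-type dataset."""
    segments: dict[tuple[str, str], list[InteractionSegment]] = {}
    for (snp_id, ct), profile in study.profiles.items():
        segments[(snp_id, ct)] = scan_and_call(
            profile, threshold=threshold, **call_kwargs
        )
    return segments


def run_candidate_pipeline(
    study: Study,
    threshold: float = 1e-8,
    max_dist: int = 5000,
    expr_cutoff: float = -0.5,
    **call_kwargs,
) -> PipelineResult:
    """Full synthetic-study run: segment calling, locus-activity assessment
    and the three-criteria candidate table."""
    segments = call_all(study, threshold=threshold, **call_kwargs)
    activity = assess_locus_activity(study.viewpoints, study.ld, study.peaks)
    candidates = assemble_candidates(
        genes=study.genes,
        segments=segments,
        activity=activity,
        expression=study.expression,
        viewpoints=study.viewpoints,
        known_genes=study.known_genes,
        max_dist=max_dist,
        expr_cutoff=expr_cutoff,
    )
    return PipelineResult(segments=segments, activity=activity, candidates=candidates)
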