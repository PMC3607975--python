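"""End-to-end run: filter cascade → deduplicated join → concordance → summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .concordance import (
    CohortSummary,
    ConcordanceResult,
    DEFAULT_TOLERANCES,
    InsufficientPairsError,
    ToleranceSpec,
    concordance,
    summarize_cohort,
)
from .filters import (
    FilterStage,
    StageName,
    filter_pelvic,
    restrict_common_hospitals,
    restrict_overlapping_years,
)
from .linkage import FunnelReport, LinkResult, compute_funnel, link
from .records import RegistryTable
from .synthetic import GroundTruth, TruthEvaluation, evaluate_against_truth

__all__ = ["Exclusion", "RunReport", "run_pipeline"]


@dataclass
class Exclusion:
    """Machine-readable reason one record left the pipeline."""

    registry: str
    record_id: str
    stage: str
    reason: str  # reason codes: filtered | non_linkable | duplicate | unmatched


@dataclass
class RunReport:
    funnel: FunnelReport
    link_result: LinkResult
    concordance: List[ConcordanceResult]
    cohort: Optional[CohortSummary]
    shared_hospitals: List[str]
    linked_hospitals: List[str]
    exclusions: List[Exclusion] = field(default_factory=list)
    truth_evaluation: Optional[TruthEvaluation] = None

    def to_dict(self) -> dict:
        out = {
            "funnel": self.funnel.to_dict(),
            "shared_hospitals": self.shared_hospitals,
            "linked_hospitals": self.linked_hospitals,
            "concordance": [c.to_dict() for c in self.concordance],
            "cohort_summary": self.cohort.to_dict() if self.cohort else None,
        }
        if self.truth_evaluation is not None:
            out["truth_evaluation"] = {
                "sensitivity": self.truth_evaluation.sensitivity,
                "ppv": self.truth_evaluation.ppv,
                "n_true_pairs": self.truth_evaluation.n_true_pairs,
                "n_links": self.truth_evaluation.n_links,
                "n_missed": len(self.truth_evaluation.missed),
                "n_false": len(self.truth_evaluation.false),
            }
        return out


def _stage_exclusions(before: RegistryTable, after: RegistryTable, stage: str):
    kept = {rec.record_id for rec in after.records}
    return [
        Exclusion(before.registry_id.value, rec.record_id, stage, "filtered")
        for rec in before.records
        if rec.record_id not in kept
    ]


def run_pipeline(
    pir: RegistryTable,
    tr: RegistryTable,
    tolerances: Sequence[ToleranceSpec] = DEFAULT_TOLERANCES,
    truth: Optional[GroundTruth] = None,
) -> RunReport:
    """Run the full linkage analysis on two validated registry tables.

    Pure and idempotent: identical inputs produce an identical report.  When
    the generating ground truth is supplied, link sensitivity and positive
    predictive value are evaluated alongside.
    """
    stages = [FilterStage(StageName.INITIAL, len(pir), len(tr))]
    exclusions: List[Exclusion] = []

    pir_h, tr_h, shared = restrict_common_hospitals(pir, tr)
    exclusions += _stage_exclusions(pir, pir_h, StageName.COMMON_HOSPITALS.value)
    exclusions += _stage_exclusions(tr, tr_h, StageName.COMMON_HOSPITALS.value)
    stages.append(FilterStage(StageName.COMMON_HOSPITALS, len(pir_h), len(tr_h)))

    tr_p = filter_pelvic(tr_h)
    exclusions += _stage_exclusions(tr_h, tr_p, StageName.PELVIC_AIS.value)
    stages.append(FilterStage(StageName.PELVIC_AIS, len(pir_h), len(tr_p)))

    pir_y, tr_y = restrict_overlapping_years(pir_h, tr_p)
    exclusions += _stage_exclusions(pir_h, pir_y, StageName.OVERLAPPING_YEARS.value)
    exclusions += _stage_exclusions(tr_p, tr_y, StageName.OVERLAPPING_YEARS.value)
    stages.append(FilterStage(StageName.OVERLAPPING_YEARS, len(pir_y), len(tr_y)))

    result = link(pir_y, tr_y)
    stages.append(
        FilterStage(
            StageName.LINKABLE_KEY,
            len(pir_y) - len(result.non_linkable_pir),
            len(tr_y) - len(result.non_linkable_tr),
        )
    )
    for nl in result.non_linkable_pir:
        exclusions.append(
            Exclusion("PIR", nl.record_id, "link", f"non_linkable: {','.join(nl.missing)}")
        )
    for nl in result.non_linkable_tr:
        exclusions.append(
            Exclusion("TR", nl.record_id, "link", f"non_linkable: {','.join(nl.missing)}")
        )
    for group in result.duplicate_groups_pir:
        for rid in group:
            exclusions.append(Exclusion("PIR", rid, "link", "duplicate"))
    for group in result.duplicate_groups_tr:
        for rid in group:
            exclusions.append(Exclusion("TR", rid, "link", "duplicate"))
    for rec in result.unmatched_pir:
        exclusions.append(Exclusion("PIR", rec.record_id, "link", "unmatched"))
    for rec in result.unmatched_tr:
        exclusions.append(Exclusion("TR", rec.record_id, "link", "unmatched"))

    funnel = compute_funnel(
        stages,
        duplicates_removed=result.duplicates_removed,
        linked_count=len(result.linked),
        non_linkable_pir=len(result.non_linkable_pir),
        non_linkable_tr=len(result.non_linkable_tr),
    )

    concordance_results: List[ConcordanceResult] = []
    cohort = None
    if result.linked:
        for spec in tolerances:
            try:
                concordance_results.append(concordance(result.linked, spec))
            except InsufficientPairsError:
                pass  # variable too incomplete to evaluate on this cohort
        cohort = summarize_cohort(result.linked)

    linked_hospitals = sorted({lr.match_key.hospital_code for lr in result.linked})
    truth_eval = evaluate_against_truth(result.linked, truth) if truth is not None else None

    return RunReport(
        funnel=funnel,
        link_result=result,
        concordance=concordance_results,
        cohort=cohort,
        shared_hospitals=sorted(shared),
        linked_hospitals=linked_hospitals,
        exclusions=exclusions,
        truth_evaluation=truth_eval,
    )
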