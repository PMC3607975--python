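"""Serialization of run reports: JSON bundle, text tables, linked-record CSV.

Reports never contain timestamps or hostnames, so identical inputs yield
byte-identical report files; volatile context belongs in the log stream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import pandas as pd

from .concordance import CohortSummary, ConcordanceResult
from .linkage import FunnelReport, LinkedRecord
from .pipeline import RunReport
from .records import Sex, TileClass, VitalStatus

__all__ = [
    "funnel_text",
    "concordance_text",
    "report_json",
    "write_linked_csv",
    "write_report_bundle",
]


def funnel_text(funnel: FunnelReport) -> str:
    lines = [
        "Linkage funnel",
        f"{'stage':<24}{'PIR':>10}{'TR':>10}",
    ]
    for stage in funnel.stages:
        lines.append(
            f"{stage.name.value:<24}{stage.pir_count:>10,}{stage.tr_count:>10,}"
        )
    lines += [
        f"{'duplicates removed':<24}{funnel.duplicates_removed:>20,}",
        f"{'linked':<24}{funnel.linked_count:>20,}",
        f"{'linkage rate':<24}{funnel.linkage_rate_pir:>9.1f}%{funnel.linkage_rate_tr:>9.1f}%",
    ]
    return "\n".join(lines) + "\n"


def _mean_sd(pair) -> str:
    if pair is None:
        return "-"
    return f"{pair[0]:.1f} ± {pair[1]:.1f}"


def concordance_text(results: List[ConcordanceResult]) -> str:
    lines = [
        "Data concordance of twofold-documented variables",
        f"{'variable':<14}{'n':>6}{'PIR':>14}{'TR':>14}{'p':>10}"
        f"{'exact %':>9}{'tol %':>7}  tolerance",
    ]
    for r in results:
        p = f"{r.test.p_value:.3f}" if r.test.p_value >= 0.001 else "<0.001"
        tol = "none" if r.tolerance == 0 else f"± {r.tolerance:g}"
        lines.append(
            f"{r.variable:<14}{r.n_pairs_complete:>6}{_mean_sd(r.mean_sd_pir):>14}"
            f"{_mean_sd(r.mean_sd_tr):>14}{p:>10}"
            f"{r.exact_match_pct:>9.0f}{r.tolerance_match_pct:>7.0f}  {tol}"
        )
    return "\n".join(lines) + "\n"


def cohort_text(summary: CohortSummary) -> str:
    lines = [
        f"Linked cohort (n = {summary.n})",
        f"  age [years]            {_mean_sd(summary.mean_sd_age)}",
        f"  ISS [points]           {_mean_sd(summary.mean_sd_iss)}",
        f"  mortality              {summary.mortality_pct}%",
        f"  complex pelvic injury  {summary.complex_pelvic_pct}%",
    ]
    for name, pct in summary.tile_distribution_pct.items():
        lines.append(f"  Tile {name:<18} {pct}%")
    if summary.blunt_pct is not None:
        lines.append(f"  blunt mechanism        {summary.blunt_pct}%")
    return "\n".join(lines) + "\n"


def report_json(report: RunReport) -> str:
    return json.dumps(report.to_dict(), indent=2, sort_keys=True)


def _record_columns(rec, prefix: str) -> dict:
    row = {
        f"{prefix}record_id": rec.record_id,
        f"{prefix}vital_status": (
            rec.vital_status.value if rec.vital_status is not VitalStatus.MISSING else ""
        ),
        f"{prefix}iss": "" if rec.iss is None else rec.iss,
        f"{prefix}initial_hb": "" if rec.initial_hb is None else rec.initial_hb,
        f"{prefix}initial_sbp": "" if rec.initial_sbp is None else rec.initial_sbp,
    }
    return row


def write_linked_csv(linked: List[LinkedRecord], path) -> None:
    """Merged pairs with registry-qualified columns (shared variables kept twice)."""
    rows = []
    for lr in linked:
        row = {
            "hospital_code": lr.match_key.hospital_code,
            "admission_date": lr.match_key.admission_date.isoformat(),
            "discharge_date": lr.match_key.discharge_date.isoformat(),
            "age_years": lr.match_key.age_years,
            "sex": lr.match_key.sex.value,
        }
        row.update(_record_columns(lr.pir, "pir_"))
        row["pir_tile_class"] = (
            lr.pir.tile_class.value if lr.pir.tile_class is not TileClass.MISSING else ""
        )
        row["pir_complex_pelvic_injury"] = (
            "" if lr.pir.complex_pelvic_injury is None
            else ("true" if lr.pir.complex_pelvic_injury else "false")
        )
        row.update(_record_columns(lr.tr, "tr_"))
        row["tr_ais_codes"] = ";".join(lr.tr.ais_codes)
        row["tr_mechanism"] = lr.tr.payload.get("mechanism", "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_exclusions_csv(report: RunReport, path) -> None:
    rows = [
        {"registry": e.registry, "record_id": e.record_id, "stage": e.stage, "reason": e.reason}
        for e in report.exclusions
    ]
    pd.DataFrame(rows, columns=["registry", "record_id", "stage", "reason"]).to_csv(
        path, index=False
    )


def write_report_bundle(report: RunReport, out_dir) -> None:
    """report.json + text tables + linked-record CSV + exclusion log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    text = funnel_text(report.funnel)
    if report.concordance:
        text += "\n" + concordance_text(report.concordance)
    if report.cohort is not None:
        text += "\n" + cohort_text(report.cohort)
    (out / "report.txt").write_text(text)
    write_linked_csv(report.link_result.linked, out / "linked.csv")
    write_exclusions_csv(report, out / "exclusions.csv")
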