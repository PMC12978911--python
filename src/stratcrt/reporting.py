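"""Trial report assembly and rendering (JSON + plain text + flow diagram)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import __version__
from .errors import ComputationError
from .pipeline import PrimaryAnalysisResult
from .records import EXCLUSION_REASONS, FlowCounts, report_percentage


@dataclass
class TrialReport:
    """Everything the pipeline computed, plus provenance.

    Every percentage printed by the text renderer is re-derived from the
    counts stored in this object via :func:`report_percentage`.
    """

    flow: dict
    rates: dict
    estimates: dict
    strata: dict
    paired: dict
    provenance: dict = field(default_factory=dict)
    n_ambiguous: int = 0
    meta: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "flow": self.flow,
            "adherence_rates": self.rates,
            "estimates": self.estimates,
            "per_stratum": self.strata,
            "paired_change_tests": self.paired,
            "n_ambiguous_adjudications": self.n_ambiguous,
            "meta": self.meta,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def build_report(
    result: PrimaryAnalysisResult,
    config: dict | None = None,
    seed: int | None = None,
) -> TrialReport:
    return TrialReport(
        flow=result.flow.to_dict(),
        rates=result.rates,
        estimates={k: v.to_dict() for k, v in result.estimates.items()},
        strata={
            k: [s.__dict__ for s in v] for k, v in result.strata.items()
        },
        paired={k: v.__dict__ for k, v in result.paired.items()},
        provenance={
            "package_version": __version__,
            "config": config or {},
            "seed": seed,
        },
        n_ambiguous=result.n_ambiguous,
        meta=result.meta,
    )


def render_flow_diagram(flow: FlowCounts) -> str:
    """CONSORT-style nested text panels, one per (arm, period).

    Raises if the tallies are not conserved (screened != eligible +
    excluded in any cell).
    """
    if not flow.conserved():
        raise ComputationError("flow counts not conserved")
    lines = ["Trial profile", "============="]
    if not flow.cells:
        lines.append("screened: 0")
        return "\n".join(lines)
    for (arm, period), cell in sorted(
        flow.cells.items(), key=lambda kv: (kv[0][1].value, kv[0][0].value)
    ):
        lines.append("")
        lines.append(f"[{arm.value} / {period.value}]")
        if cell.illegible:
            lines.append(f"  illegible (failed validation): {cell.illegible}")
        lines.append(f"  screened: {cell.screened}")
        lines.append(f"  excluded: {cell.total_excluded}")
        for reason in EXCLUSION_REASONS:
            n = cell.excluded.get(reason, 0)
            if n:
                lines.append(f"    {reason}: {n}")
        lines.append(f"  eligible: {cell.eligible}")
    return "\n".join(lines)


def _fmt_est(name: str, est: dict) -> str:
    if est["scale"] == "ratio":
        return (f"{name}: RR {est['point']:.2f} "
                f"(95% CI {est['ci_low']:.2f} to {est['ci_high']:.2f}; "
                f"t={est['t_stat']:.2f}, df={est['df']}, P={est['p_value']:.2f})")
    return (f"{name}: RD {est['point']*100:.1f}% "
            f"(95% CI {est['ci_low']*100:.1f}% to {est['ci_high']*100:.1f}%; "
            f"t={est['t_stat']:.2f}, df={est['df']}, P={est['p_value']:.2f})")


def render_text_report(report: TrialReport) -> str:
    lines = ["Stratified cluster-randomized trial analysis", "=" * 44, ""]
    lines.append("Adherence rates (eligible prescriptions):")
    for key in sorted(report.rates):
        cell = report.rates[key]
        if cell["n"]:
            pct = report_percentage(cell["o"], cell["n"], 1)
            lines.append(f"  {key}: {cell['o']}/{cell['n']} ({pct})")
        else:
            lines.append(f"  {key}: 0/0 (undefined)")
    lines.append("")
    lines.append("Effect estimates (endline, intervention vs control):")
    for name in ("rr_unadjusted", "rr_adjusted", "rd_unadjusted", "rd_adjusted"):
        if name in report.estimates:
            lines.append("  " + _fmt_est(name, report.estimates[name]))
    lines.append("")
    lines.append("Within-arm change, endline - baseline (paired t):")
    for arm, res in sorted(report.paired.items()):
        if res.get("zero_variance"):
            lines.append(f"  {arm}: mean difference {res['mean_difference']*100:.1f}% "
                         "(zero variance; P undefined)")
        else:
            lines.append(
                f"  {arm}: mean difference {res['mean_difference']*100:.1f}% "
                f"(95% CI {res['ci_low']*100:.1f}% to {res['ci_high']*100:.1f}%; "
                f"P={res['p_value']:.2f}, paired t, df={res['df']})"
            )
    if report.n_ambiguous:
        lines.append("")
        lines.append(f"Ambiguous adjudications flagged for review: {report.n_ambiguous}")
    if report.meta.get("n_illegible"):
        lines.append(f"Illegible records excluded before screening: "
                     f"{report.meta['n_illegible']}")
    return "\n".join(lines)
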