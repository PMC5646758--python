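"""End-to-end orchestration: detect -> per-task metrics -> cohort statistics.

Reproduces the structure of the study's results on any dataset: per-condition
means with one-sample tests (deviation vs 0, dwell proportion vs 0.5), the
unscrambled-vs-scrambled paired comparison, EQ correlations on the
complete-case subset, the dependent-correlation comparison for the freeview
task, Cousineau within-subject error bars, and a full exclusion audit.
No multiple-testing correction is applied; the report counts the tests run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import freeview, global_effect
from .gaze_io import DetectionConfig, ExclusionAudit, ParticipantRecord
from .stats import (DependentCorrComparison, TestResult, cousineau_se,
                    one_sample_t, paired_t, pearson_r, steiger_z)

__all__ = ["CohortResult", "run_pipeline", "report_text", "write_report"]

CONDITIONS = ("unscrambled", "scrambled")


def _test_dict(res: TestResult) -> dict:
    return {"statistic": res.statistic, "df": res.df, "p": res.p_two_tailed,
            "d": res.effect_size_d, "n": res.n, "mean": res.mean, "sd": res.sd}


def _corr_dict(res: TestResult) -> dict:
    return {"r": res.mean, "df": res.df, "p": res.p_two_tailed, "n": res.n}


@dataclass
class CohortResult:
    """All cohort-level statistics plus the exclusion audit, as plain data."""

    ge: dict = field(default_factory=dict)
    fv: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    n_tests: int = 0

    def to_dict(self) -> dict:
        return {"ge": self.ge, "fv": self.fv, "exclusions": self.exclusions,
                "n_tests": self.n_tests}


def _task_block(values: dict[str, np.ndarray], mu0: float,
                eq: np.ndarray | None) -> tuple[dict, int]:
    """Condition means/tests, paired comparison, Cousineau SEs, EQ correlations."""
    n_tests = 0
    block: dict = {"n_participants": len(values["unscrambled"])}
    for cond in CONDITIONS:
        v = values[cond]
        res = one_sample_t(v, mu0)
        block[cond] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                       "se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
                       "test_vs_null": _test_dict(res)}
        n_tests += 1
    block["paired"] = _test_dict(paired_t(values["unscrambled"], values["scrambled"]))
    n_tests += 1
    matrix = np.column_stack([values[c] for c in CONDITIONS])
    block["cousineau_se"] = dict(zip(CONDITIONS,
                                     (float(s) for s in cousineau_se(matrix))))
    if eq is not None:
        have = np.array([e is not None for e in eq])
        if have.sum() >= 4:
            eqv = np.asarray([e for e in eq[have]], dtype=float)
            sub = {c: values[c][have] for c in CONDITIONS}
            block["eq_correlation"] = {}
            for cond in CONDITIONS:
                block["eq_correlation"][cond] = _corr_dict(pearson_r(eqv, sub[cond]))
                n_tests += 1
            r_u = block["eq_correlation"]["unscrambled"]["r"]
            r_s = block["eq_correlation"]["scrambled"]["r"]
            r_c = pearson_r(sub["unscrambled"], sub["scrambled"]).mean
            comp = steiger_z(r_u, r_s, r_c, int(have.sum()))
            block["eq_correlation_comparison"] = asdict(comp)
            n_tests += 1
    return block, n_tests


def run_pipeline(participants: list[ParticipantRecord],
                 config: DetectionConfig | None = None,
                 discard_first_fv: bool = False) -> CohortResult:
    """Process every participant's raw trials and assemble cohort statistics.

    Deterministic given the dataset and configuration.  Raises if no
    participant survives the capture filters.
    """
    config = config or DetectionConfig()
    result = CohortResult()
    audit = {"ge": ExclusionAudit(), "fv": ExclusionAudit()}
    n_tests = 0

    ge_rows, ge_eq = [], []
    fv_rows, fv_eq = [], []
    for rec in participants:
        if rec.ge_trials:
            for trial in rec.ge_trials:
                global_effect.process_ge_trial(trial, config)
            summary = global_effect.summarize_participant(rec.ge_trials, config)
            a = audit["ge"]
            a.n_participants_total += 1
            if summary.included:
                a.n_trials_total += sum(summary.n_total.values())
                for trial in rec.ge_trials:
                    if trial.excluded_reason:
                        a.record_trial(trial.excluded_reason)
                ge_rows.append([summary.mean_deviation[c] for c in CONDITIONS])
                ge_eq.append(rec.eq_score)
            else:
                a.record_participant(summary.exclusion_reason or "capture<75%")
        if rec.fv_trials:
            for trial in rec.fv_trials:
                freeview.process_fv_trial(trial, config,
                                          discard_first=discard_first_fv)
            summary = freeview.summarize_participant(rec.fv_trials, config)
            a = audit["fv"]
            a.n_participants_total += 1
            if summary.included:
                a.n_trials_total += sum(summary.n_total.values())
                a.record_trial("not_captured",
                               sum(summary.n_total.values())
                               - sum(summary.n_captured.values()))
                if a.trial_reasons.get("not_captured") == 0:
                    a.trial_reasons.pop("not_captured")
                fv_rows.append([summary.mean_proportion[c] for c in CONDITIONS])
                fv_eq.append(rec.eq_score)
            else:
                a.record_participant(summary.exclusion_reason or "capture<75%")

    if ge_rows:
        arr = np.asarray(ge_rows, dtype=float)
        block, k = _task_block({"unscrambled": arr[:, 0], "scrambled": arr[:, 1]},
                               0.0, np.asarray(ge_eq, dtype=object))
        result.ge = block
        n_tests += k
    if fv_rows:
        arr = np.asarray(fv_rows, dtype=float)
        block, k = _task_block({"unscrambled": arr[:, 0], "scrambled": arr[:, 1]},
                               0.5, np.asarray(fv_eq, dtype=object))
        result.fv = block
        n_tests += k
    if not ge_rows and not fv_rows:
        raise ValueError("empty cohort after exclusions")
    result.exclusions = {task: audit[task].summary() for task in ("ge", "fv")
                         if audit[task].n_participants_total}
    result.n_tests = n_tests
    return result


def report_text(result: CohortResult) -> str:
    """Human-readable report mirroring the statistics block structure."""
    lines: list[str] = []

    def fmt_test(name: str, t: dict) -> str:
        d = f", d = {t['d']:.3f}" if t.get("d") is not None else ""
        return f"  {name}: t({t['df']}) = {t['statistic']:.3f}, p = {t['p']:.4g}{d}"

    for task, label, null in (("ge", "Global effect (deviation toward social, deg)", 0.0),
                              ("fv", "Freeview (social dwell proportion)", 0.5)):
        block = getattr(result, task)
        if not block:
            continue
        lines.append(f"{label} — n = {block['n_participants']}")
        for cond in CONDITIONS:
            c = block[cond]
            lines.append(f"  {cond}: mean = {c['mean']:.3f}, sd = {c['sd']:.3f}, "
                         f"se = {c['se']:.3f} "
                         f"(within-subject se = {block['cousineau_se'][cond]:.3f})")
            lines.append(fmt_test(f"{cond} vs {null}", c["test_vs_null"]))
        lines.append(fmt_test("unscrambled vs scrambled (paired)", block["paired"]))
        if "eq_correlation" in block:
            for cond in CONDITIONS:
                r = block["eq_correlation"][cond]
                lines.append(f"  EQ correlation ({cond}): r({r['df']}) = "
                             f"{r['r']:.3f}, p = {r['p']:.4g}")
            if "eq_correlation_comparison" in block:
                z = block["eq_correlation_comparison"]
                lines.append(f"  dependent-correlation comparison: Z = "
                             f"{z['z_statistic']:.3f}, p = {z['p_two_tailed']:.4g}")
        lines.append("")
    for task, ex in result.exclusions.items():
        lines.append(f"Exclusions ({task}): {ex['trials_excluded']} of "
                     f"{ex['trials_total']} trials "
                     f"({ex['percent_excluded']:.3f}%), "
                     f"{ex['mean_excluded_per_participant']:.3f} per participant; "
                     f"{ex['participants_excluded']} participant(s) removed.")
    lines.append(f"\nTests run (no multiplicity correction): {result.n_tests}")
    return "\n".join(lines) + "\n"


def write_report(result: CohortResult, outdir) -> None:
    """Emit report.json (bit-stable, sorted keys) and report.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(result.to_dict(), indent=2, sort_keys=True,
                   default=float) + "\n")
    (outdir / "report.txt").write_text(report_text(result))
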