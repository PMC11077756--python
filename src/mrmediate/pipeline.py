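"""End-to-end orchestration: bidirectional univariable MR with
diagnostics, report assembly, and rendering to TSV/JSON/text."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, uvmr
from .instruments import (
    apply_exclusion_list, clump, harmonize, instrument_strength,
    select_significant,
)
from .io import RunConfig, TraitTable


@dataclass
class DirectionReport:
    """Univariable MR results for one exposure→outcome direction."""

    exposure: str
    outcome: str
    estimable: bool
    estimates: pd.DataFrame | None = None      # method, beta, se, p, OR, CI, n_snp
    heterogeneity: dict | None = None          # Q, df, p
    egger_intercept: dict | None = None
    presso: dict | None = None
    loo_extrema: dict | None = None
    stage_counts: dict | None = None           # selected → clumped → excluded → harmonized
    notices: list[str] = field(default_factory=list)
    strength: dict | None = None


@dataclass
class AnalysisReport:
    forward: DirectionReport
    reverse: DirectionReport | None
    config: dict
    seed: int


def _estimates_frame(rows: list[uvmr.MREstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "method": e.method, "beta": e.beta, "se": e.se, "pvalue": e.pvalue,
        "or_point": e.or_point, "or_lower": e.or_lower, "or_upper": e.or_upper,
        "n_snp": e.n_snp,
    } for e in rows])


def run_direction(
    exposure: TraitTable,
    outcome: TraitTable,
    config: RunConfig,
    ld=None,
    exclusion=None,
    run_presso: bool = True,
) -> DirectionReport:
    """Select → clump → exclude → harmonize → grade → estimate → diagnose
    for one direction.  Directions with as few as 2 instruments still get
    an IVW row; estimators with higher minimums are skipped with a notice.
    """
    report = DirectionReport(exposure.trait_name, outcome.trait_name, False)
    counts: dict[str, int] = {"input": len(exposure)}

    if exposure.trait_name == outcome.trait_name:
        report.notices.append(
            "exposure and outcome tables share a name; self-regression "
            "results are degenerate")
    sel = select_significant(exposure, config.p_threshold)
    counts["selected"] = len(sel)
    if len(sel) >= 1:
        sel = clump(sel, ld=ld, r2_threshold=config.clump_r2,
                    window_kb=config.clump_window_kb)
    counts["clumped"] = len(sel)
    if exclusion:
        sel = apply_exclusion_list(sel, exclusion)
    counts["after_exclusion"] = len(sel)

    hset = harmonize(sel, outcome,
                     palindrome_eaf_limit=config.palindrome_eaf_limit)
    counts["harmonized"] = hset.n_snp
    report.stage_counts = counts
    if hset.n_snp < 1:
        report.notices.append("no usable instruments; direction not estimable")
        return report

    report.estimable = True
    n_exp = exposure.data["n"].median()
    if np.isfinite(n_exp) and n_exp > 2:
        s = instrument_strength(hset, float(n_exp))
        report.strength = {
            "mean_f": s.mean_f, "min_f": s.min_f,
            "total_r_squared": s.total_r_squared, "n_weak": s.n_weak,
        }

    ests = [uvmr.ivw(hset, model="auto", ci_level=config.ci_level)]
    if hset.n_snp >= 3:
        slope, intercept = uvmr.egger(hset, ci_level=config.ci_level)
        ests.append(slope)
        report.egger_intercept = {
            "beta": intercept.beta, "se": intercept.se, "pvalue": intercept.pvalue}
        ests.append(uvmr.weighted_median(
            hset, reps=config.bootstrap_reps, seed=config.seed,
            ci_level=config.ci_level))
        ests.append(uvmr.weighted_median(
            hset, weights="equal", reps=config.bootstrap_reps,
            seed=config.seed + 1, ci_level=config.ci_level))
        ests.append(uvmr.weighted_mode(
            hset, reps=config.bootstrap_reps, seed=config.seed + 2,
            ci_level=config.ci_level))
        loo = diagnostics.leave_one_out(hset, ci_level=config.ci_level)
        body = loo.table[loo.table["snp_id"] != "all"]
        report.loo_extrema = {
            "min_beta": float(body["beta"].min()),
            "max_beta": float(body["beta"].max()),
        }
    else:
        report.notices.append(
            f"only {hset.n_snp} instrument(s): Egger/median/mode and "
            "leave-one-out skipped")
    report.estimates = _estimates_frame(ests)

    if hset.n_snp >= 2:
        het = uvmr.cochran_q(hset)
        report.heterogeneity = {
            "q": het.q_statistic, "df": het.df, "pvalue": het.pvalue}
    if run_presso and hset.n_snp >= 4:
        pr = diagnostics.mr_presso(
            hset, n_sims=config.presso_sims, seed=config.seed)
        report.presso = {
            "global_pvalue": pr.global_pvalue,
            "n_outliers": len(pr.outlier_indices),
            "distortion_pvalue": pr.distortion_pvalue,
        }
    return report


def run_bidirectional(
    exposure: TraitTable,
    outcome: TraitTable,
    config: RunConfig | None = None,
    ld=None,
    exclusion=None,
) -> AnalysisReport:
    """Forward (exposure→outcome) and reverse (outcome→exposure)
    univariable MR with shared thresholds."""
    config = config or RunConfig()
    fwd = run_direction(exposure, outcome, config, ld, exclusion)
    rev = run_direction(outcome, exposure, config, ld, exclusion)
    return AnalysisReport(fwd, rev, asdict(config), config.seed)


def _direction_payload(d: DirectionReport) -> dict:
    payload = asdict(d)
    payload["estimates"] = (None if d.estimates is None
                            else d.estimates.to_dict(orient="records"))
    return payload


def render_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the report as machine-readable JSON, per-direction TSV
    estimate tables, and a short human-readable text summary.  The JSON
    round-trips all floats exactly (repr-precision serialisation)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    payload = {
        "config": report.config,
        "seed": report.seed,
        "forward": _direction_payload(report.forward),
        "reverse": (None if report.reverse is None
                    else _direction_payload(report.reverse)),
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2))
    written.append(json_path)

    lines = ["MR analysis report", "=" * 40]
    for label, d in (("forward", report.forward), ("reverse", report.reverse)):
        if d is None:
            continue
        lines.append(f"\n[{label}] {d.exposure} -> {d.outcome}")
        lines.append(f"  stages: {d.stage_counts}")
        if not d.estimable:
            lines.append("  not estimable")
        else:
            tsv = out_dir / f"estimates_{label}.tsv"
            d.estimates.to_csv(tsv, sep="\t", index=False)
            written.append(tsv)
            for r in d.estimates.itertuples(index=False):
                lines.append(
                    f"  {r.method:>16}: beta {r.beta: .4f} (SE {r.se:.4f}), "
                    f"OR {r.or_point:.3f} ({r.or_lower:.3f}-{r.or_upper:.3f}), "
                    f"P {r.pvalue:.3f}, nSNP {r.n_snp}")
            if d.heterogeneity:
                h = d.heterogeneity
                lines.append(
                    f"  Cochran's Q {h['q']:.2f} (df {h['df']}), P {h['pvalue']:.3f}")
            if d.egger_intercept:
                lines.append(
                    f"  Egger intercept {d.egger_intercept['beta']:.4f}, "
                    f"P {d.egger_intercept['pvalue']:.3f}")
            if d.presso:
                lines.append(
                    f"  pleiotropy residual test: global P "
                    f"{d.presso['global_pvalue']:.3f}, "
                    f"outliers {d.presso['n_outliers']}")
            else:
                lines.append("  diagnostics: (not run)")
        for note in d.notices:
            lines.append(f"  note: {note}")
    txt_path = out_dir / "report.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    written.append(txt_path)
    return written
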