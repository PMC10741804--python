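"""Cohort-level orchestration: three-way contour comparisons,
dosimetric deltas, rank tests, review-rating tallies, time savings,
interobserver variability, and summary tables.

Summaries follow the clinical reporting convention: per structure and
metric, mean (sample SD, n−1 denominator), median, and range (min–max),
with undefined values excluded and counted. Relative dose differences
ΔD_X = (D_X,test − D_X,ref) / D_X,ref are computed signed; summary
tables report magnitudes, raw per-patient files keep the sign.

Significance of per-structure dose differences between arms is assessed
with the two-sample Wilcoxon rank-sum test, two-sided at α = 0.05 and
without multiple-testing correction; a paired signed-rank alternative
and Benjamini–Hochberg adjustment are available behind flags, with the
active test named in every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_metrics as dm
from . import plan_quality as pq
from .geometry_metrics import compare_structure_sets
from .synthetic_data import LIKERT_LEVELS, Cohort
from .volumes import StructureSet

__all__ = [
    "ALPHA",
    "LikertRating",
    "TimingRecord",
    "CohortSummary",
    "summarize",
    "wilcoxon_rank_sum",
    "time_savings",
    "likert_tally",
    "run_geometric_arm",
    "run_dosimetric_arm",
    "interobserver_report",
    "run_study",
]

ALPHA = 0.05
_CSV_FLOAT = "%.9g"


@dataclass(frozen=True)
class LikertRating:
    """A reviewer's four-level rating of one patient's AI contours."""

    patient_id: str
    rating: str

    def __post_init__(self):
        if self.rating not in LIKERT_LEVELS:
            raise ValueError(
                f"unknown rating {self.rating!r}; expected one of {LIKERT_LEVELS}"
            )


@dataclass(frozen=True)
class TimingRecord:
    patient_id: str
    provenance: str
    minutes: float

    def __post_init__(self):
        if self.minutes <= 0:
            raise ValueError("contouring time must be > 0 minutes")


@dataclass
class CohortSummary:
    """Per structure × metric summary table (mean/SD/median/range)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=_CSV_FLOAT)


def summarize(raw: pd.DataFrame, value_cols: Sequence[str],
              by: Sequence[str] = ("structure",)) -> CohortSummary:
    """Summarize per-patient raw metric rows into the cohort table.

    NaN values (undefined metrics) are excluded per cell and counted in
    ``n_excluded``. SD uses the n−1 denominator.
    """
    rows = []
    for keys, grp in raw.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            ok = vals[np.isfinite(vals)]
            row = dict(zip(by, keys))
            row.update({
                "metric": col,
                "mean": ok.mean() if ok.size else np.nan,
                "sd": ok.std(ddof=1) if ok.size > 1 else (0.0 if ok.size == 1 else np.nan),
                "median": float(np.median(ok)) if ok.size else np.nan,
                "min": ok.min() if ok.size else np.nan,
                "max": ok.max() if ok.size else np.nan,
                "n": int(ok.size),
                "n_excluded": int(vals.size - ok.size),
            })
            rows.append(row)
    return CohortSummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, paired: bool = False) -> float:
    """Two-sided p-value comparing two samples of a dose metric.

    The default is the two-sample Wilcoxon rank-sum (Mann–Whitney)
    test, exact for small tie-free samples; ``paired=True`` switches to
    the signed-rank test on per-patient differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        if np.allclose(x, y):
            return 1.0
        return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def time_savings(t_man_minutes: float, t_adj_minutes: float) -> float:
    """Fractional reduction in contouring time,
    (T_manual − T_adjusted) / T_manual. Negative if adjusting the AI
    contours took longer than contouring from scratch.
    """
    if t_man_minutes <= 0:
        raise ValueError("manual contouring time must be > 0")
    return (t_man_minutes - t_adj_minutes) / t_man_minutes


def likert_tally(ratings: Sequence[LikertRating]) -> pd.DataFrame:
    """Counts and proportions per rating level, levels in scale order."""
    if len(ratings) == 0:
        raise ValueError("no ratings to tally")
    counts = {level: 0 for level in LIKERT_LEVELS}
    for r in ratings:
        counts[r.rating] += 1
    total = len(ratings)
    return pd.DataFrame({
        "rating": list(LIKERT_LEVELS),
        "count": [counts[v] for v in LIKERT_LEVELS],
        "proportion": [counts[v] / total for v in LIKERT_LEVELS],
    })


# ---------------------------------------------------------------------------
# Cohort arms
# ---------------------------------------------------------------------------

def run_geometric_arm(
    pairs: Sequence[tuple[str, StructureSet, StructureSet]],
) -> tuple[CohortSummary, pd.DataFrame]:
    """Per-structure DSC/HD/|RVD| summaries for (test, reference) pairs.

    ``pairs`` is a sequence of (patient id, test set, reference set).
    Returns the cohort summary and the per-patient raw table.
    """
    if len(pairs) == 0:
        raise ValueError("empty cohort: nothing to summarize")
    frames = []
    for pid, test, ref in pairs:
        df = compare_structure_sets(test, ref).to_frame()
        df.insert(0, "patient", pid)
        frames.append(df)
    raw = pd.concat(frames, ignore_index=True)
    summary = summarize(raw, ["dsc", "hd_mm", "rvd_abs"])
    return summary, raw


_DELTA_METRICS = ("d_mean", "d_min", "d_0_03cc")


def _arm_dose_table(
    plans: Sequence[tuple[str, dm.DoseGrid, StructureSet]],
    target: str = "PTV",
) -> pd.DataFrame:
    """Per-patient absolute dose metrics for one planning arm."""
    rows = []
    for pid, dose, sset in plans:
        grid = sset.grid
        d = dose if dose.grid == grid else dm.resample_dose(dose, grid)
        for name, mask in sset.structures.items():
            if mask.is_empty:
                continue
            m = dm.compute_dose_metrics(d, mask, is_target=(name == target))
            rows.append({
                "patient": pid, "structure": name,
                "d_mean": m.d_mean, "d_min": m.d_min, "d_0_03cc": m.d_0_03cc,
                "hi": m.hi if m.hi is not None else np.nan,
                "ci": m.ci if m.ci is not None else np.nan,
            })
    return pd.DataFrame(rows)


def run_dosimetric_arm(
    ref_plans: Sequence[tuple[str, dm.DoseGrid, StructureSet]],
    test_plans: Sequence[tuple[str, dm.DoseGrid, StructureSet]],
    target: str = "PTV",
    paired_test: bool = False,
) -> dict:
    """Dosimetric comparison of two planning arms.

    Each arm is a sequence of (patient id, dose, structure set); each
    plan is evaluated on its own contours. Returns a dict with the
    per-patient signed deltas (``raw``), the |Δ| cohort summary
    (``summary``), the target's ΔHI/ΔCI rows folded into both, and the
    per-structure × metric rank-test table (``tests``). Patients
    missing from either arm are excluded with a note in ``excluded``.
    """
    ref_tab = _arm_dose_table(ref_plans, target)
    test_tab = _arm_dose_table(test_plans, target)
    ref_ids = set(ref_tab["patient"])
    test_ids = set(test_tab["patient"])
    common = sorted(ref_ids & test_ids)
    excluded = sorted((ref_ids | test_ids) - set(common))

    merged = pd.merge(
        test_tab[test_tab["patient"].isin(common)],
        ref_tab[ref_tab["patient"].isin(common)],
        on=["patient", "structure"], suffixes=("_test", "_ref"),
    )
    raw_rows = []
    for _, r in merged.iterrows():
        row = {"patient": r["patient"], "structure": r["structure"]}
        for met in _DELTA_METRICS + ("hi", "ci"):
            t, f = r[f"{met}_test"], r[f"{met}_ref"]
            if np.isfinite(t) and np.isfinite(f) and f != 0:
                row[f"delta_{met}"] = dm.relative_difference(t, f)
            else:
                row[f"delta_{met}"] = np.nan
        raw_rows.append(row)
    raw = pd.DataFrame(raw_rows)
    abs_cols = {}
    for met in _DELTA_METRICS + ("hi", "ci"):
        abs_cols[f"abs_delta_{met}"] = raw[f"delta_{met}"].abs()
    raw = pd.concat([raw, pd.DataFrame(abs_cols)], axis=1)
    summary = summarize(raw, [f"abs_delta_{m}" for m in _DELTA_METRICS + ("hi", "ci")])

    test_rows = []
    for structure, _ in raw.groupby("structure", sort=True):
        for met in _DELTA_METRICS:
            x = test_tab.loc[test_tab["structure"] == structure, met]
            y = ref_tab.loc[ref_tab["structure"] == structure, met]
            p = wilcoxon_rank_sum(x, y, paired=paired_test)
            test_rows.append({
                "structure": structure, "metric": met, "p_value": p,
                "significant": bool(p < ALPHA) if np.isfinite(p) else pd.NA,
                "test": "signed-rank" if paired_test else "rank-sum",
                "alpha": ALPHA,
            })
    tests = pd.DataFrame(test_rows)
    return {"raw": raw, "summary": summary, "tests": tests, "excluded": excluded}


def interobserver_report(
    adj1: Sequence[tuple[str, StructureSet]],
    adj2: Sequence[tuple[str, StructureSet]],
    doses1: Sequence[tuple[str, dm.DoseGrid]] | None = None,
    doses2: Sequence[tuple[str, dm.DoseGrid]] | None = None,
) -> dict:
    """Interobserver variability between two observers' adjusted sets.

    Geometric metrics are symmetric between observers; dose deltas use
    observer 2 as the denominator. Dose grids are optional — without
    them only the geometric part is produced.
    """
    geo_pairs = [(pid1, s1, s2) for (pid1, s1), (_, s2) in zip(adj1, adj2)]
    geo_summary, geo_raw = run_geometric_arm(geo_pairs)
    out = {"geometry_summary": geo_summary, "geometry_raw": geo_raw}
    if doses1 is not None and doses2 is not None:
        plans1 = [(pid, d, s) for (pid, s), (_, d) in zip(adj1, doses1)]
        plans2 = [(pid, d, s) for (pid, s), (_, d) in zip(adj2, doses2)]
        out["dose"] = run_dosimetric_arm(ref_plans=plans2, test_plans=plans1)
    return out


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def run_study(cohort: Cohort, outdir, convention: str = "table") -> dict:
    """Run every analysis arm on a synthetic cohort and write reports.

    Outputs under ``outdir``: geometry_summary.csv (AI vs adjusted, and
    manual vs adjusted), dose_delta_summary.csv, wilcoxon.csv,
    pqm_summary.csv, interobserver_geometry.csv, likert.csv, timing.csv,
    and per-patient raw tables under ``raw/``. Reports are
    deterministic for a fixed cohort.
    """
    outdir = Path(outdir)
    (outdir / "raw").mkdir(parents=True, exist_ok=True)
    site = cohort.site
    pats = cohort.patients

    geo_tables = []
    for label, test_arm, ref_arm in (
        ("ai_vs_adj1", "ai", "adj1"),
        ("man_vs_adj1", "manual", "adj1"),
    ):
        summary, raw = run_geometric_arm(
            [(p.pid, p.sets[test_arm], p.sets[ref_arm]) for p in pats]
        )
        t = summary.table.copy()
        t.insert(0, "comparison", label)
        geo_tables.append(t)
        raw.insert(0, "comparison", label)
        raw.to_csv(outdir / "raw" / f"geometry_{label}.csv", index=False,
                   float_format=_CSV_FLOAT)
    geometry_summary = pd.concat(geo_tables, ignore_index=True)
    geometry_summary.to_csv(outdir / "geometry_summary.csv", index=False,
                            float_format=_CSV_FLOAT)

    dose_cmp = run_dosimetric_arm(
        ref_plans=[(p.pid, p.doses["manual"], p.sets["manual"]) for p in pats],
        test_plans=[(p.pid, p.doses["adj1"], p.sets["adj1"]) for p in pats],
    )
    dose_cmp["summary"].to_csv(outdir / "dose_delta_summary.csv")
    dose_cmp["tests"].to_csv(outdir / "wilcoxon.csv", index=False,
                             float_format=_CSV_FLOAT)
    dose_cmp["raw"].to_csv(outdir / "raw" / "dose_deltas_man_vs_adj1.csv",
                           index=False, float_format=_CSV_FLOAT)

    card = pq.bundled_scorecard(site)
    pqm_rows = []
    for p in pats:
        res_man = pq.evaluate_pqm(card, p.doses["manual"], p.sets["manual"], convention)
        res_adj = pq.evaluate_pqm(card, p.doses["adj1"], p.sets["adj1"], convention)
        delta = dm.relative_difference(res_adj.npqm, res_man.npqm)
        pqm_rows.append({
            "patient": p.pid, "npqm_manual": res_man.npqm, "npqm_adj1": res_adj.npqm,
            "delta_npqm": delta, "abs_delta_npqm": abs(delta),
            "convention": convention,
        })
    pqm_raw = pd.DataFrame(pqm_rows)
    pqm_raw.to_csv(outdir / "raw" / "pqm_per_patient.csv", index=False,
                   float_format=_CSV_FLOAT)
    pqm_summary = summarize(pqm_raw.assign(structure=site),
                            ["npqm_manual", "npqm_adj1", "abs_delta_npqm"])
    pqm_summary.to_csv(outdir / "pqm_summary.csv")

    inter = interobserver_report(
        adj1=[(p.pid, p.sets["adj1"]) for p in pats],
        adj2=[(p.pid, p.sets["adj2"]) for p in pats],
        doses1=[(p.pid, p.doses["adj1"]) for p in pats],
        doses2=[(p.pid, p.doses["adj2"]) for p in pats],
    )
    inter["geometry_summary"].to_csv(outdir / "interobserver_geometry.csv")
    inter["geometry_raw"].to_csv(outdir / "raw" / "interobserver_geometry.csv",
                                 index=False, float_format=_CSV_FLOAT)
    inter["dose"]["summary"].to_csv(outdir / "interobserver_dose.csv")

    likert = likert_tally([LikertRating(p.pid, p.likert) for p in pats])
    likert.to_csv(outdir / "likert.csv", index=False, float_format=_CSV_FLOAT)

    timing_rows = []
    for p in pats:
        for obs in ("adj1", "adj2"):
            timing_rows.append({
                "patient": p.pid, "observer": obs,
                "t_manual_min": p.timing_min["manual"],
                "t_adjusted_min": p.timing_min[obs],
                "time_saving": time_savings(p.timing_min["manual"], p.timing_min[obs]),
            })
    timing = pd.DataFrame(timing_rows)
    timing.to_csv(outdir / "timing.csv", index=False, float_format=_CSV_FLOAT)

    return {
        "geometry_summary": geometry_summary,
        "dose": dose_cmp,
        "pqm_raw": pqm_raw,
        "pqm_summary": pqm_summary,
        "interobserver": inter,
        "likert": likert,
        "timing": timing,
    }
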