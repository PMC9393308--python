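"""Cohort records, normality testing, paired comparisons and reporting.

The statistical layer mirrors how small paired orthopedic cohorts are
analysed: Shapiro-Wilk normality checks per arm, two-sided paired t-tests
at alpha = 0.05 with no multiple-testing correction (Holm-adjusted p values
can be annotated as an extra column, off by default), and demographic
summaries rounded to the precision such tables print (ages 2 dp, follow-up
and percentages 1 dp).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsError",
    "ZeroVarianceError",
    "CohortRecord",
    "PairedStatsResult",
    "load_cohort",
    "table1_cohort_path",
    "load_table1_cohort",
    "shapiro_wilk",
    "paired_t",
    "summarize_cohort",
    "metrics_report",
    "format_p",
]


class StatsError(Exception):
    """Statistical-layer error."""


class ZeroVarianceError(StatsError):
    """Test undefined because the data have zero variance."""


# ---------------------------------------------------------------------------
# cohort records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRecord:
    """One patient's demographic row (the cohort-table schema)."""

    patient_id: int
    sex: str
    side: str
    age_at_diagnosis: float
    age_at_intervention: float
    herring: str
    followup_months: float

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.age_at_diagnosis <= 0 or self.age_at_intervention <= 0:
            raise ValueError("ages must be positive")
        if self.age_at_intervention < self.age_at_diagnosis:
            raise ValueError("age at intervention cannot precede age at diagnosis")
        if self.herring not in ("B", "C"):
            raise ValueError(
                f"Herring class {self.herring!r} not supported: this cohort schema "
                "admits lateral-pillar classes B and C only")


_HEADER_ALIASES = {
    "number": "patient_id",
    "patient": "patient_id",
    "patient_id": "patient_id",
    "sex": "sex",
    "side": "side",
    "age at diagnosis (years)": "age_at_diagnosis",
    "age_at_diagnosis": "age_at_diagnosis",
    "age at intervention (years)": "age_at_intervention",
    "age_at_intervention": "age_at_intervention",
    "herring classification": "herring",
    "herring": "herring",
    "follow-up time (months)": "followup_months",
    "followup_months": "followup_months",
}


def load_cohort(path) -> list:
    """Read a cohort CSV (tidy or printed-table headers) into records."""
    df = pd.read_csv(path, comment="#")
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key not in _HEADER_ALIASES:
            raise ValueError(f"unrecognised cohort column {col!r}")
        renames[col] = _HEADER_ALIASES[key]
    df = df.rename(columns=renames)
    records = []
    for _, row in df.iterrows():
        if pd.isna(row.get("age_at_diagnosis")) or pd.isna(row.get("age_at_intervention")):
            raise ValueError(f"patient {row['patient_id']}: missing age")
        records.append(CohortRecord(
            patient_id=int(row["patient_id"]),
            sex=str(row["sex"]).strip().lower(),
            side=str(row["side"]).strip().lower(),
            age_at_diagnosis=float(row["age_at_diagnosis"]),
            age_at_intervention=float(row["age_at_intervention"]),
            herring=str(row["herring"]).strip().upper(),
            followup_months=float(row["followup_months"]),
        ))
    return records


def table1_cohort_path() -> Path:
    """Path to the packaged 15-patient cohort table."""
    return Path(__file__).parent / "data" / "table1_cohort.csv"


def load_table1_cohort() -> list:
    return load_cohort(table1_cohort_path())


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def shapiro_wilk(values) -> tuple:
    """Shapiro-Wilk W and p for normality; requires 3 <= n <= 5000."""
    x = np.asarray(values, float).ravel()
    if not 3 <= len(x) <= 5000:
        raise StatsError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0.0:
        raise ZeroVarianceError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


@dataclass
class PairedStatsResult:
    """Two-sided paired t-test with per-arm summaries and normality checks."""

    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    t: float
    p: float
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["significant"] = self.significant
        return out


def _shapiro_or_none(x):
    try:
        return shapiro_wilk(x)[1]
    except StatsError:
        return None


def paired_t(values_a, values_b, alpha: float = 0.05) -> PairedStatsResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Raises :class:`ZeroVarianceError` when all paired differences are
    identical (the statistic is undefined), and :class:`StatsError` for
    length mismatches or n < 2.
    """
    a = np.asarray(values_a, float).ravel()
    b = np.asarray(values_b, float).ravel()
    if len(a) != len(b):
        raise StatsError(f"paired samples differ in length ({len(a)} vs {len(b)})")
    if len(a) < 2:
        raise StatsError("paired t-test requires n >= 2")
    d = a - b
    if np.ptp(d) == 0.0:
        raise ZeroVarianceError("paired differences have zero variance; t undefined")
    t, p = stats.ttest_rel(a, b)
    return PairedStatsResult(
        n=len(a),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        mean_diff=float(d.mean()),
        t=float(t), p=float(p),
        shapiro_p_a=_shapiro_or_none(a),
        shapiro_p_b=_shapiro_or_none(b),
        alpha=alpha,
    )


def format_p(p: float) -> str:
    """Render p for display; values below 0.001 print as '< 0.001'."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_cohort(records) -> dict:
    """Demographic summary: counts/percentages and rounded means.

    Rounding follows the printed-table precision (ages to 2 dp, follow-up
    and percentages to 1 dp); unrounded values are kept under ``raw``.
    """
    records = list(records)
    if not records:
        raise StatsError("summarize_cohort requires at least one record")
    n = len(records)
    n_male = sum(r.sex == "male" for r in records)
    n_left = sum(r.side == "left" for r in records)
    n_b = sum(r.herring == "B" for r in records)
    age_dx = np.array([r.age_at_diagnosis for r in records])
    age_op = np.array([r.age_at_intervention for r in records])
    fup = np.array([r.followup_months for r in records])

    def pct(k):
        return round(100.0 * k / n, 1)

    return {
        "n": n,
        "n_male": n_male, "n_female": n - n_male,
        "pct_male": pct(n_male), "pct_female": pct(n - n_male),
        "n_left": n_left, "n_right": n - n_left,
        "pct_left": pct(n_left), "pct_right": pct(n - n_left),
        "mean_age_at_diagnosis": round(float(age_dx.mean()), 2),
        "mean_age_at_intervention": round(float(age_op.mean()), 2),
        "mean_followup_months": round(float(fup.mean()), 1),
        "n_herring_b": n_b, "n_herring_c": n - n_b,
        "pct_herring_b": pct(n_b), "pct_herring_c": pct(n - n_b),
        "raw": {
            "mean_age_at_diagnosis": float(age_dx.mean()),
            "mean_age_at_intervention": float(age_op.mean()),
            "mean_followup_months": float(fup.mean()),
        },
    }


# metric columns used by the bilateral report:
#   side comparison (per stage): healthy vs affected arms
_SIDE_METRICS = {
    "SC_mm": ("sc_healthy", "sc_affected"),
    "AC_mm2": ("ac_healthy", "ac_affected"),
    "FH_mm3": ("fh_healthy", "fh_affected"),
}
#   stage comparison: preop vs postop bilateral differences
_STAGE_METRICS = ("d_sc", "d_ac", "d_fh")


def metrics_report(metrics, alpha: float = 0.05, holm: bool = False) -> dict:
    """Paired-statistics report over per-patient bilateral metrics.

    ``metrics`` is an iterable of objects with ``to_dict()`` (e.g.
    :class:`hipmorph.morphometry.BilateralMetrics`) or plain dicts carrying
    patient, stage and the sc/ac/fh columns.  Produces

    * ``side_comparison``: per stage, healthy vs affected arm for SC, AC
      and FH (printed-table-3 layout), and
    * ``stage_comparison``: preop vs postop for the bilateral differences
      D_SC, D_AC, D_FH (printed-table-4 layout).

    A metric whose paired differences have zero variance is marked
    non-testable instead of aborting the report.  With ``holm=True`` each
    block gains Holm-adjusted p values.
    """
    rows = [m.to_dict() if hasattr(m, "to_dict") else dict(m) for m in metrics]
    df = pd.DataFrame(rows)
    if df.empty:
        raise StatsError("metrics_report requires at least one metrics row")
    report = {"alpha": alpha, "side_comparison": {}, "stage_comparison": {}}

    for stage, sub in df.groupby("stage"):
        block = {}
        for name, (col_h, col_a) in _SIDE_METRICS.items():
            try:
                res = paired_t(sub[col_h], sub[col_a], alpha=alpha)
                block[name] = {"testable": True, "result": res,
                               "p_display": format_p(res.p),
                               "flag": "*" if res.significant else ""}
            except StatsError as exc:
                block[name] = {"testable": False, "reason": str(exc)}
        report["side_comparison"][stage] = block

    wide = df.pivot_table(index="patient", columns="stage",
                          values=list(_STAGE_METRICS), aggfunc="first")
    for name in _STAGE_METRICS:
        try:
            if ("preop" not in wide[name]) or ("postop" not in wide[name]):
                raise StatsError("both stages required for stage comparison")
            both = wide[name].dropna(subset=["preop", "postop"])
            if len(both) < 2:
                raise StatsError("fewer than 2 patients with both stages")
            res = paired_t(both["preop"], both["postop"], alpha=alpha)
            report["stage_comparison"][name] = {
                "testable": True, "result": res,
                "p_display": format_p(res.p),
                "flag": "*" if res.significant else ""}
        except StatsError as exc:
            report["stage_comparison"][name] = {"testable": False, "reason": str(exc)}

    if holm:
        for block in (report["side_comparison"], report["stage_comparison"]):
            _annotate_holm(block)
    return report


def _collect_tests(block, out):
    for key, val in block.items():
        if isinstance(val, dict) and val.get("testable"):
            out.append(val)
        elif isinstance(val, dict) and "testable" not in val:
            _collect_tests(val, out)


def _annotate_holm(block):
    tests = []
    _collect_tests(block, tests)
    if not tests:
        return
    ps = np.array([t["result"].p for t in tests])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    for t, p_adj in zip(tests, adj):
        t["p_holm"] = float(p_adj)
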