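"""Study endpoints: contingency, paired tests, time savings, report tables.

Covers the statistical side of a blinded, randomized contour-evaluation
study: a presence/absence contingency table for missing-structure detection
with sensitivity and specificity; means with 95% t-confidence intervals;
two-sided paired t-tests at alpha = 0.05 (no multiple-testing correction,
but the number of tests performed is reported); per-case relative time
savings with a one-sided test against a clinically meaningful margin;
threshold counts over the OAR roster; a-priori power of the time-savings
test (noncentral t); and the aggregation tables a study report prints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError, PairingError
from .grid import StructureSet

#: Metrics where larger values mean better agreement with the gold standard.
HIGHER_IS_BETTER = {
    "VDSC", "SDSC", "CDC", "Precision", "Sensitivity", "Specificity",
}
#: Metrics where smaller values mean better agreement.
LOWER_IS_BETTER = {
    "HD95", "APL", "DeltaCentroid",
    "abs_dDmean_Gy", "abs_dD0.03cc_Gy", "abs_dNPQM_pct",
}

ALPHA = 0.05


# ---------------------------------------------------------------------------
# missing-structure contingency


@dataclass(frozen=True)
class ContingencyTable:
    """Structure-presence agreement counts (candidate vs gold standard).

    TP: present in both; FN: present in GS only; FP: present in candidate
    only; TN: present in neither.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidParameterError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def presence_contingency(
    candidates: Sequence[StructureSet],
    references: Sequence[StructureSet],
    expected_names: Sequence[str],
) -> ContingencyTable:
    """Presence contingency over all cases x expected structure names.

    ``candidates`` are paired with ``references`` by case id (one reference
    per case id; any number of candidate sets).  A delivered structure with
    zero foreground counts as not present: the contingency counts delivery
    of usable geometry, not file plumbing.
    """
    ref_by_case: Dict[str, StructureSet] = {}
    for ref in references:
        if ref.case_id in ref_by_case:
            raise PairingError(f"duplicate reference set for case {ref.case_id}")
        ref_by_case[ref.case_id] = ref
    tp = fp = tn = fn = 0
    for cand in candidates:
        if cand.case_id not in ref_by_case:
            raise PairingError(f"no reference set for case {cand.case_id}")
        ref = ref_by_case[cand.case_id]
        for name in expected_names:
            in_cand = cand.is_present(name)
            in_ref = ref.is_present(name)
            if in_cand and in_ref:
                tp += 1
            elif in_cand:
                fp += 1
            elif in_ref:
                fn += 1
            else:
                tn += 1
    return ContingencyTable(tp, fp, tn, fn)


def sens_spec(table: ContingencyTable) -> Tuple[float, float]:
    """(sensitivity %, specificity %) of presence detection.

    Zero denominators yield NaN markers, never zeros.  Study reports round
    to the nearest integer percent.
    """
    sens = 100.0 * table.tp / (table.tp + table.fn) if table.tp + table.fn else math.nan
    spec = 100.0 * table.tn / (table.tn + table.fp) if table.tn + table.fp else math.nan
    return sens, spec


# ---------------------------------------------------------------------------
# means, confidence intervals, paired tests


class MeanCI(NamedTuple):
    mean: float
    ci_low: float
    ci_high: float


def mean_ci(values: Sequence[float], confidence: float = 0.95) -> MeanCI:
    """Sample mean with a t-based confidence interval: mean ± t(q, n-1)·s/√n."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("mean_ci needs at least 2 observations")
    m = float(x.mean())
    sem = float(x.std(ddof=1)) / math.sqrt(n)
    half = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1)) * sem
    return MeanCI(m, m - half, m + half)


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test result for one metric and one arm pair."""

    metric: str
    arm_a: str
    arm_b: str
    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: Optional[str] = None  # "zero-variance" | "no-difference" | None


def paired_ttest(
    a_values: Sequence[float],
    b_values: Sequence[float],
    metric: str = "",
    arms: Tuple[str, str] = ("A", "B"),
) -> PairedComparison:
    """Two-sided paired t-test on per-unit differences a - b (alpha 0.05).

    Degenerate difference vectors are flagged rather than given fabricated
    p-values: identically-zero differences report p = 1 ("no-difference");
    zero-variance nonzero differences report significance with the p-value
    flagged "zero-variance".
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size != b.size:
        raise PairingError(f"paired samples differ in length: {a.size} vs {b.size}")
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedComparison(metric, arms[0], arms[1], n, 0.0, 0.0, 0.0,
                                    0.0, 1.0, False, degenerate="no-difference")
        return PairedComparison(metric, arms[0], arms[1], n, mean_d, mean_d, mean_d,
                                math.inf, 0.0, True, degenerate="zero-variance")
    sem = sd / math.sqrt(n)
    t = mean_d / sem
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    ci = mean_ci(d)
    return PairedComparison(metric, arms[0], arms[1], n, mean_d, ci.ci_low,
                            ci.ci_high, t, p, p < ALPHA)


# ---------------------------------------------------------------------------
# timing


@dataclass(frozen=True)
class TimingRecord:
    """Contouring durations for one case and arm, hours.

    ``initial_h`` is the manual initial-contouring time (0 when the initial
    contours come from the model), ``revision_h`` the physician revision
    time.
    """

    case_id: str
    arm: str
    initial_h: float
    revision_h: float

    def __post_init__(self) -> None:
        if self.initial_h < 0 or self.revision_h < 0:
            raise InvalidParameterError("durations must be >= 0")

    @property
    def total_h(self) -> float:
        return self.initial_h + self.revision_h


@dataclass(frozen=True)
class TimeSavingsResult:
    """Per-case relative time savings of the experimental arm, percent."""

    per_case_pct: Tuple[float, ...]
    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    margin_pct: float
    p_greater_than_margin: float
    significant_vs_margin: bool
    excluded_cases: Tuple[str, ...] = ()


def time_savings(
    standard: Sequence[TimingRecord],
    experimental: Sequence[TimingRecord],
    margin_pct: float = 30.0,
    alpha_one_sided: float = 0.025,
) -> TimeSavingsResult:
    """Relative total-time savings, mean with 95% CI, and test vs a margin.

    Per-case savings = 100·(standard total - experimental total)/standard
    total; negative savings (experimental slower) are allowed.  The margin
    test is a one-sided one-sample t-test of mean savings > ``margin_pct``
    at the given one-sided significance level.  Cases with zero standard
    time are excluded with a record in ``excluded_cases``.
    """
    std_by_case = {r.case_id: r for r in standard}
    exp_by_case = {r.case_id: r for r in experimental}
    if set(std_by_case) != set(exp_by_case):
        raise PairingError("standard and experimental arms must cover the same cases")
    savings: List[float] = []
    excluded: List[str] = []
    for case_id in std_by_case:
        st = std_by_case[case_id].total_h
        ex = exp_by_case[case_id].total_h
        if st == 0:
            excluded.append(case_id)
            continue
        savings.append(100.0 * (st - ex) / st)
    if len(savings) < 2:
        raise InsufficientDataError("time_savings needs >= 2 usable cases")
    ci = mean_ci(savings)
    x = np.asarray(savings)
    sem = x.std(ddof=1) / math.sqrt(x.size)
    if sem == 0:
        p = 0.0 if ci.mean > margin_pct else 1.0
    else:
        t = (ci.mean - margin_pct) / sem
        p = float(sps.t.sf(t, x.size - 1))
    return TimeSavingsResult(
        per_case_pct=tuple(savings),
        mean_pct=ci.mean,
        ci_low_pct=ci.ci_low,
        ci_high_pct=ci.ci_high,
        margin_pct=margin_pct,
        p_greater_than_margin=p,
        significant_vs_margin=p < alpha_one_sided,
        excluded_cases=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# roster threshold counts and contour arithmetic


def count_oars_above(
    per_oar_means: Mapping[str, float],
    threshold: float,
    roster_size: int = 42,
) -> Tuple[int, float]:
    """OARs whose arm-mean metric exceeds a threshold, and % of the roster."""
    count = sum(1 for v in per_oar_means.values() if v > threshold)
    pct = 100.0 * count / roster_size if roster_size else 0.0
    return count, pct


def contour_total(n_eligible_structures: int, n_arms: int = 4) -> int:
    """Total contour instances when each eligible structure exists in every arm."""
    if n_eligible_structures < 0 or n_arms < 1:
        raise InvalidParameterError("counts must be non-negative / positive")
    return n_eligible_structures * n_arms


def eligible_structures(sets_by_case: Mapping[str, Sequence[StructureSet]]) -> int:
    """Structures present (non-absent, non-empty) in every arm of their case."""
    count = 0
    for case_id, sets in sets_by_case.items():
        if not sets:
            continue
        names = set(sets[0].names())
        for s in sets[1:]:
            names &= set(s.names())
        count += sum(1 for n in names if all(s.is_present(n) for s in sets))
    return count


# ---------------------------------------------------------------------------
# power


def power_sample_size(
    assumed_savings_pct: float,
    sd_pct: float,
    n: int,
    margin_pct: float,
    alpha_one_sided: float = 0.025,
) -> float:
    """Power of the one-sided one-sample t-test of mean savings > margin.

    Under the alternative of true mean savings ``assumed_savings_pct`` with
    per-case standard deviation ``sd_pct``, the test statistic follows a
    noncentral t with ``n - 1`` degrees of freedom and noncentrality
    (assumed - margin) / (sd/√n).
    """
    if sd_pct <= 0:
        raise InvalidParameterError("sd must be > 0")
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    if not 0 < alpha_one_sided < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    df = n - 1
    nc = (assumed_savings_pct - margin_pct) / (sd_pct / math.sqrt(n))
    t_crit = float(sps.t.ppf(1.0 - alpha_one_sided, df))
    return float(sps.nct.sf(t_crit, df, nc))


# ---------------------------------------------------------------------------
# report


@dataclass
class StudyReport:
    """Aggregated study tables.

    ``timing``: per-arm mean (95% CI) durations and the savings row.
    ``pooled``: per-arm mean (95% CI) of each geometric metric pooled over
    case x structure, with paired significance between arm pairs in
    ``pooled_tests``.  ``per_oar``: per-metric counts of OARs favouring each
    arm (classification detail in ``per_oar_detail``).  ``dose``: per-arm
    mean (95% CI) dosimetric deltas.  ``contingency``: presence summary.
    ``n_tests``: number of hypothesis tests performed (no multiplicity
    correction is applied, matching a per-metric alpha of 0.05).
    """

    timing: Optional[pd.DataFrame]
    pooled: pd.DataFrame
    pooled_tests: pd.DataFrame
    per_oar: pd.DataFrame
    per_oar_detail: pd.DataFrame
    dose: Optional[pd.DataFrame]
    contingency: Optional[pd.DataFrame]
    n_tests: int


def _metric_key(row_metric: str, param) -> str:
    if param is None or (isinstance(param, float) and math.isnan(param)):
        return row_metric
    return f"{row_metric}-{param:g}mm"


def _direction(metric: str) -> Optional[bool]:
    """True if higher is better, False if lower, None if unknown."""
    base = metric.split("-")[0]
    if base in HIGHER_IS_BETTER:
        return True
    if base in LOWER_IS_BETTER:
        return False
    return None


def _paired_frame(df: pd.DataFrame, unit_cols: List[str]) -> pd.DataFrame:
    """Pivot a long table to one column per arm, indexed by pairing unit."""
    return df.pivot_table(index=unit_cols, columns="arm", values="value",
                          aggfunc="mean")


def study_report(
    metric_table: Optional[pd.DataFrame] = None,
    dose_table: Optional[pd.DataFrame] = None,
    timing_table: Optional[pd.DataFrame] = None,
    contingency: Optional[ContingencyTable] = None,
    reference_arm: Optional[str] = None,
) -> StudyReport:
    """Build the study's aggregation tables from long-format inputs.

    ``metric_table``/``dose_table`` are the long CSV outputs of the geometry
    and dosimetry modules; ``timing_table`` has columns case, arm,
    initial_h, revision_h.  Pooled comparisons pair at the case x structure
    level; per-OAR comparisons pair case-level values.  Missing arms leave
    explicit gaps rather than failing.
    """
    n_tests = 0

    # --- geometric metrics -------------------------------------------------
    pooled_rows: List[Dict[str, object]] = []
    test_rows: List[Dict[str, object]] = []
    oar_detail_rows: List[Dict[str, object]] = []
    if metric_table is not None and len(metric_table):
        mt = metric_table.copy()
        mt["metric_key"] = [
            _metric_key(m, p) for m, p in zip(mt["metric"], mt["parameter_mm"])
        ]
        arms = sorted(mt["arm"].unique())
        for key, sub in mt.groupby("metric_key"):
            for arm in arms:
                vals = sub.loc[sub["arm"] == arm, "value"].dropna()
                if len(vals) >= 2:
                    ci = mean_ci(vals)
                    pooled_rows.append(
                        {"metric": key, "arm": arm, "n": len(vals),
                         "mean": ci.mean, "ci_low": ci.ci_low, "ci_high": ci.ci_high}
                    )
                else:
                    pooled_rows.append(
                        {"metric": key, "arm": arm, "n": len(vals),
                         "mean": vals.mean() if len(vals) else math.nan,
                         "ci_low": math.nan, "ci_high": math.nan}
                    )
            wide = _paired_frame(sub, ["case", "structure"]).dropna()
            for i, arm_a in enumerate(arms):
                for arm_b in arms[i + 1:]:
                    if arm_a not in wide.columns or arm_b not in wide.columns:
                        continue
                    if len(wide) < 2:
                        continue
                    cmp = paired_ttest(wide[arm_a], wide[arm_b], key, (arm_a, arm_b))
                    n_tests += 1
                    test_rows.append(
                        {"metric": key, "arm_a": arm_a, "arm_b": arm_b,
                         "n_pairs": cmp.n, "mean_diff": cmp.mean_diff,
                         "p_value": cmp.p_value, "significant": cmp.significant,
                         "degenerate": cmp.degenerate}
                    )
            # per-OAR classification, case-level pairing
            for structure, ssub in sub.groupby("structure"):
                swide = _paired_frame(ssub, ["case"]).dropna()
                for i, arm_a in enumerate(arms):
                    for arm_b in arms[i + 1:]:
                        if (arm_a not in swide.columns or arm_b not in swide.columns
                                or len(swide) < 2):
                            continue
                        cmp = paired_ttest(swide[arm_a], swide[arm_b], key,
                                           (arm_a, arm_b))
                        n_tests += 1
                        higher = _direction(key)
                        if not cmp.significant or higher is None:
                            favored = "no difference"
                        elif (cmp.mean_diff > 0) == higher:
                            favored = arm_a
                        else:
                            favored = arm_b
                        oar_detail_rows.append(
                            {"metric": key, "structure": structure,
                             "arm_a": arm_a, "arm_b": arm_b, "n_pairs": cmp.n,
                             "mean_diff": cmp.mean_diff, "p_value": cmp.p_value,
                             "favored": favored}
                        )

    pooled = pd.DataFrame(
        pooled_rows, columns=["metric", "arm", "n", "mean", "ci_low", "ci_high"]
    )
    pooled_tests = pd.DataFrame(
        test_rows,
        columns=["metric", "arm_a", "arm_b", "n_pairs", "mean_diff", "p_value",
                 "significant", "degenerate"],
    )
    per_oar_detail = pd.DataFrame(
        oar_detail_rows,
        columns=["metric", "structure", "arm_a", "arm_b", "n_pairs", "mean_diff",
                 "p_value", "favored"],
    )
    if len(per_oar_detail):
        per_oar = (
            per_oar_detail.groupby(["metric", "arm_a", "arm_b", "favored"])
            .size()
            .rename("n_oars")
            .reset_index()
        )
    else:
        per_oar = pd.DataFrame(columns=["metric", "arm_a", "arm_b", "favored",
                                        "n_oars"])

    # --- dosimetric deltas -------------------------------------------------
    dose_df: Optional[pd.DataFrame] = None
    if dose_table is not None and len(dose_table):
        rows = []
        for (metric, arm), sub in dose_table.groupby(["metric", "arm"]):
            vals = sub["value"].dropna()
            if len(vals) >= 2:
                ci = mean_ci(vals)
                rows.append({"metric": metric, "arm": arm, "n": len(vals),
                             "mean": ci.mean, "ci_low": ci.ci_low,
                             "ci_high": ci.ci_high})
            else:
                rows.append({"metric": metric, "arm": arm, "n": len(vals),
                             "mean": vals.mean() if len(vals) else math.nan,
                             "ci_low": math.nan, "ci_high": math.nan})
        dose_df = pd.DataFrame(rows)

    # --- timing ------------------------------------------------------------
    timing_df: Optional[pd.DataFrame] = None
    if timing_table is not None and len(timing_table):
        tt = timing_table.copy()
        tt["total_h"] = tt["initial_h"] + tt["revision_h"]
        rows = []
        for arm, sub in tt.groupby("arm"):
            row: Dict[str, object] = {"arm": arm, "n": len(sub)}
            for col in ("initial_h", "revision_h", "total_h"):
                if len(sub) >= 2:
                    ci = mean_ci(sub[col])
                    row[f"{col}_mean"] = ci.mean
                    row[f"{col}_ci_low"] = ci.ci_low
                    row[f"{col}_ci_high"] = ci.ci_high
                else:
                    row[f"{col}_mean"] = float(sub[col].mean())
                    row[f"{col}_ci_low"] = math.nan
                    row[f"{col}_ci_high"] = math.nan
            rows.append(row)
        timing_df = pd.DataFrame(rows)
        arms = list(tt["arm"].unique())
        if len(arms) == 2:
            recs = {
                arm: [TimingRecord(str(c), arm, float(i), float(r))
                      for c, i, r in zip(sub["case"], sub["initial_h"],
                                         sub["revision_h"])]
                for arm, sub in tt.groupby("arm")
            }
            # the standard arm is the slower one unless stated
            totals = {arm: tt.loc[tt["arm"] == arm, "total_h"].mean() for arm in arms}
            std_arm = max(totals, key=totals.get)
            exp_arm = min(totals, key=totals.get)
            if std_arm != exp_arm:
                try:
                    ts = time_savings(recs[std_arm], recs[exp_arm])
                    n_tests += 1
                    timing_df = pd.concat(
                        [timing_df,
                         pd.DataFrame([{
                             "arm": f"savings {exp_arm} vs {std_arm} (%)",
                             "n": len(ts.per_case_pct),
                             "total_h_mean": ts.mean_pct,
                             "total_h_ci_low": ts.ci_low_pct,
                             "total_h_ci_high": ts.ci_high_pct,
                         }])],
                        ignore_index=True,
                    )
                except (PairingError, InsufficientDataError):
                    pass

    # --- contingency ---------------------------------------------------------
    contingency_df: Optional[pd.DataFrame] = None
    if contingency is not None:
        sens, spec = sens_spec(contingency)
        contingency_df = pd.DataFrame(
            [{"tp": contingency.tp, "fp": contingency.fp, "tn": contingency.tn,
              "fn": contingency.fn, "sensitivity_pct": sens,
              "specificity_pct": spec}]
        )

    return StudyReport(
        timing=timing_df,
        pooled=pooled,
        pooled_tests=pooled_tests,
        per_oar=per_oar,
        per_oar_detail=per_oar_detail,
        dose=dose_df,
        contingency=contingency_df,
        n_tests=n_tests,
    )
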