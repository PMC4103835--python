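"""Nonparametric statistics for the per-subject validation arm.

Paired before/after-smoking changes within a group are tested with the
Wilcoxon signed-rank test, between-group differences with the
Mann–Whitney U test. Both tests come in an exact flavour (full
enumeration of the permutation distribution, suitable at the study's
small group sizes) and a normal approximation without continuity
correction, the convention under which the validation arm's printed
p-values reproduce. Significance threshold for summaries is two-sided
0.05; no multiple-testing adjustment is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedTestError, ValidationError

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "summarize_groups",
    "GROUPS",
    "TIMEPOINTS",
]

GROUPS = (
    "young_susceptible",
    "young_non_susceptible",
    "copd",
    "old_healthy_smoker",
    "old_healthy_never_smoker",
)

TIMEPOINTS = ("baseline", "after_smoking")

_EXACT_SIGNED_RANK_MAX_N = 20
_EXACT_RANK_SUM_MAX_N = 14


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str  # 'exact' | 'normal_approx'
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    zero_diffs_dropped: int = 0
    tie_correction_applied: bool = False


def _two_sided_from_pmf(values: np.ndarray, pmf: np.ndarray, observed: float) -> float:
    """2·min(P(T<=t), P(T>=t)), capped at 1, on a discrete distribution."""
    eps = 1e-9
    lo = pmf[values <= observed + eps].sum()
    hi = pmf[values >= observed - eps].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def _signed_rank_sums(ranks: np.ndarray) -> np.ndarray:
    """All 2**n values of W+ over the sign assignments of the given ranks.

    Literal enumeration by doubling (each rank either joins the positive
    set or not); works for mid-ranks too, so tied |differences| are
    handled exactly, conditional on the observed tie pattern.
    """
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return sums


def wilcoxon_signed_rank(before, after, method: str = "exact") -> TestResult:
    """Paired Wilcoxon signed-rank test on (before, after) measurements.

    Differences are after − before; zero differences are dropped and
    counted. ``method='exact'`` enumerates all 2**n sign assignments of
    the ranked |differences| (valid for n <= 20; ties among |differences|
    are handled through mid-ranks with a warning, the p-value then being
    exact conditional on the tie pattern; n > 20 falls back to the normal
    approximation with a warning). ``method='normal_approx'`` uses
    z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − tie term), two-sided,
    without continuity correction.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValidationError("before and after must be 1-D sequences of equal length")
    if method not in ("exact", "normal_approx"):
        raise ValidationError(f"unknown method {method!r}")

    d = a - b
    zero_dropped = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero; the test is undefined")

    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if method == "exact":
        if n > _EXACT_SIGNED_RANK_MAX_N:
            warnings.warn(
                f"n={n} exceeds the exact-enumeration limit "
                f"({_EXACT_SIGNED_RANK_MAX_N}); falling back to the normal approximation",
                stacklevel=2,
            )
        else:
            if has_ties:
                warnings.warn(
                    "tied |differences|: exact p-value enumerated over mid-ranks, "
                    "conditional on the observed tie pattern",
                    stacklevel=2,
                )
            sums = _signed_rank_sums(ranks)
            pmf = np.full(sums.size, 1.0 / sums.size)
            p = _two_sided_from_pmf(sums, pmf, w_plus)
            return TestResult(
                statistic=w_plus,
                p_two_sided=p,
                method="exact",
                n=n,
                zero_diffs_dropped=zero_dropped,
                tie_correction_applied=bool(has_ties),
            )

    # normal approximation (also the fallback path)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var -= tie_term
    if var <= 0:
        raise UndefinedTestError("zero variance after tie correction; the test is undefined")
    z = (w_plus - mean) / sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(
        statistic=w_plus,
        p_two_sided=p,
        method="normal_approx",
        n=n,
        zero_diffs_dropped=zero_dropped,
        tie_correction_applied=tie_term > 0,
    )


def mann_whitney_u(group_a, group_b, method: str = "exact") -> TestResult:
    """Two-group Mann–Whitney U test.

    ``method='exact'`` enumerates all C(n1+n2, n1) assignments of the
    pooled mid-ranks to group A (valid for n1+n2 <= 14; ties are handled
    exactly through the mid-ranks, with the usual caveat that mid-rank
    enumeration conditions on the observed tie pattern — a warning is
    emitted). ``method='normal_approx'`` uses the tie-corrected variance
    without continuity correction. The reported statistic is
    U = min(U1, U2).
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if method not in ("exact", "normal_approx"):
        raise ValidationError(f"unknown method {method!r}")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if method == "exact":
        if n1 + n2 > _EXACT_RANK_SUM_MAX_N:
            warnings.warn(
                f"n1+n2={n1 + n2} exceeds the exact-enumeration limit "
                f"({_EXACT_RANK_SUM_MAX_N}); falling back to the normal approximation",
                stacklevel=2,
            )
        else:
            if has_ties:
                warnings.warn(
                    "ties present: exact p-value computed on mid-ranks, "
                    "conditional on the observed tie pattern",
                    stacklevel=2,
                )
            offset = n1 * (n1 + 1) / 2.0
            u_values = np.array(
                [ranks[list(idx)].sum() - offset for idx in combinations(range(n1 + n2), n1)]
            )
            pmf = np.full(u_values.size, 1.0 / comb(n1 + n2, n1))
            p = _two_sided_from_pmf(u_values, pmf, u1)
            return TestResult(
                statistic=u_min,
                p_two_sided=p,
                method="exact",
                n1=n1,
                n2=n2,
                tie_correction_applied=bool(has_ties),
            )

    n = n1 + n2
    mean = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise UndefinedTestError("zero variance after tie correction; the test is undefined")
    z = (u1 - mean) / sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(
        statistic=u_min,
        p_two_sided=p,
        method="normal_approx",
        n1=n1,
        n2=n2,
        tie_correction_applied=bool(has_ties and tie_term > 0),
    )


MEASUREMENT_COLUMNS = ["subject_id", "group", "timepoint", "analyte", "concentration", "unit"]


def read_measurements(path) -> pd.DataFrame:
    """Read a per-subject concentration table (TSV) and validate it."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s): {', '.join(missing)}")
    return validate_measurements(df[MEASUREMENT_COLUMNS])


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    problems = []
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        problems.append(f"unknown timepoint(s): {sorted(df.loc[bad_tp, 'timepoint'].unique())}")
    if (pd.to_numeric(df["concentration"], errors="coerce") < 0).any():
        problems.append("negative concentrations present")
    dup = df.duplicated(subset=["subject_id", "timepoint", "analyte"])
    if dup.any():
        problems.append(f"{int(dup.sum())} duplicate (subject, timepoint, analyte) record(s)")
    units = df.groupby("analyte")["unit"].nunique()
    mixed = units[units > 1]
    if len(mixed):
        problems.append(f"inconsistent units for analyte(s): {sorted(mixed.index)}")
    if problems:
        raise ValidationError("; ".join(problems))
    return df.reset_index(drop=True)


def summarize_groups(measurements: pd.DataFrame, method: str = "exact") -> dict[str, pd.DataFrame]:
    """Median (range) summaries plus the study's three test families.

    Returns a dict of DataFrames:

    - ``summary``: median, min, max, n per group × timepoint × analyte;
    - ``paired_tests``: within-group before/after signed-rank tests,
      restricted to subjects measured at both timepoints;
    - ``baseline_tests``: Mann–Whitney U between every pair of groups on
      baseline concentrations;
    - ``change_tests``: Mann–Whitney U between groups on per-subject
      changes (after − before), the acute-smoke-response comparison.
    """
    df = validate_measurements(measurements)

    summary = (
        df.groupby(["group", "timepoint", "analyte"])["concentration"]
        .agg(median="median", min="min", max="max", n="size")
        .reset_index()
    )

    paired_rows = []
    changes: dict[tuple[str, str], pd.Series] = {}
    for (group, analyte), sub in df.groupby(["group", "analyte"]):
        wide = sub.pivot(index="subject_id", columns="timepoint", values="concentration")
        if "baseline" not in wide.columns or "after_smoking" not in wide.columns:
            continue
        both = wide.dropna(subset=["baseline", "after_smoking"])
        changes[(group, analyte)] = both["after_smoking"] - both["baseline"]
        if len(both) == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = wilcoxon_signed_rank(both["baseline"], both["after_smoking"], method=method)
        except UndefinedTestError:
            continue
        paired_rows.append(
            {
                "group": group,
                "analyte": analyte,
                "n_pairs": len(both),
                "statistic": res.statistic,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
                "zero_diffs_dropped": res.zero_diffs_dropped,
            }
        )
    paired = pd.DataFrame(
        paired_rows,
        columns=["group", "analyte", "n_pairs", "statistic", "p_two_sided", "method",
                 "zero_diffs_dropped"],
    )

    def _between(frame_by_group: dict[str, np.ndarray], analyte: str, label: str, rows: list):
        names = sorted(frame_by_group)
        for g1, g2 in combinations(names, 2):
            a, b = frame_by_group[g1], frame_by_group[g2]
            if len(a) == 0 or len(b) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mann_whitney_u(a, b, method=method)
            rows.append(
                {
                    "comparison": label,
                    "analyte": analyte,
                    "group_1": g1,
                    "group_2": g2,
                    "n1": res.n1,
                    "n2": res.n2,
                    "statistic": res.statistic,
                    "p_two_sided": res.p_two_sided,
                    "method": res.method,
                }
            )

    baseline_rows: list = []
    base = df[df["timepoint"] == "baseline"]
    for analyte, sub in base.groupby("analyte"):
        by_group = {g: s["concentration"].to_numpy(float) for g, s in sub.groupby("group")}
        _between(by_group, analyte, "baseline", baseline_rows)

    change_rows: list = []
    analytes = sorted({a for _, a in changes})
    for analyte in analytes:
        by_group = {
            g: ch.to_numpy(float) for (g, a), ch in changes.items() if a == analyte and len(ch)
        }
        _between(by_group, analyte, "change_after_minus_before", change_rows)

    cols = ["comparison", "analyte", "group_1", "group_2", "n1", "n2", "statistic",
            "p_two_sided", "method"]
    return {
        "summary": summary,
        "paired_tests": paired,
        "baseline_tests": pd.DataFrame(baseline_rows, columns=cols),
        "change_tests": pd.DataFrame(change_rows, columns=cols),
    }
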