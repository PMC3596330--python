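"""Group summaries and hypothesis tests for cohorts of recordings.

Continuous variables are reported as mean ± SEM and compared with the
unpaired equal-variance (Student's) t-test for two groups or one-way ANOVA
for three or more; categorical variables as n (%) with Pearson's chi-squared
test, falling back to Fisher's exact test whenever any expected cell count
is below 5. Significance is fixed at p < 0.05, two-sided, with no
multiple-testing correction (pairwise comparisons are reported as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

ALPHA = 0.05


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean: float | None = None
    sem: float | None = None
    n_positive: int | None = None
    percent: int | None = None

    def __str__(self) -> str:
        if self.n_positive is not None:
            return f"{self.n_positive} ({self.percent}%)"
        if self.sem is None:
            return f"{self.mean:.1f}"
        return f"{self.mean:.1f}±{self.sem:.1f}"


@dataclass
class ComparisonResult:
    test_name: str  # "t" | "anova" | "chi2" | "fisher"
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_continuous(values, label: str) -> GroupSummary:
    """Mean ± SEM (sample SD over sqrt(n); SEM undefined for n = 1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ParameterError("cannot summarize an empty sample")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return GroupSummary(group_label=label, n=int(v.size), mean=float(v.mean()), sem=sem)


def summarize_categorical(n_positive: int, n: int, label: str) -> GroupSummary:
    """n (%) with the percent rounded half-up to an integer, as printed."""
    if not 0 <= n_positive <= n:
        raise ParameterError("need 0 <= n_positive <= n")
    return GroupSummary(
        group_label=label, n=int(n), n_positive=int(n_positive),
        percent=_round_half_up(100.0 * n_positive / n) if n else 0,
    )


def compare_continuous(*groups) -> ComparisonResult:
    """Student's t-test (2 groups) or one-way ANOVA (>= 3 groups)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            groups[0] and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs n >= 2")
    if len(arrays) == 2:
        t, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return ComparisonResult("t", float(t), float(p))
    f, p = sps.f_oneway(*arrays)
    return ComparisonResult("anova", float(f), float(p))


def compare_categorical(table) -> ComparisonResult:
    """Pearson chi-squared, or Fisher's exact (2x2) when any expected
    count is below 5."""
    tab = np.asarray(table)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ParameterError("table must be 2 x k counts")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
            raise ParameterError("counts must be non-negative integers")
        tab = tab.astype(int)
    if tab.sum() == 0:
        raise ParameterError("empty table")
    expected = sps.contingency.expected_freq(tab)
    if np.any(expected < 5):
        if tab.shape != (2, 2):
            raise ParameterError(
                "expected count < 5 in a 2 x k table; Fisher's exact is only "
                "implemented for 2 x 2"
            )
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        return ComparisonResult("fisher", float(odds), float(p))
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return ComparisonResult("chi2", float(chi2), float(p))


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

#: (row label, record key, kind) in display order
_TABLE_ROWS = [
    ("Spontaneous beating activity", "is_spontaneous", "categorical"),
    ("Phase 4 depolarization", "phase4_flag", "categorical"),
    ("RMP/MDP (mV)", "mdp_or_rmp_mV", "continuous"),
    ("CL (ms)", "cl_ms", "continuous"),
    ("CV (cm/s)", "cv_cm_s", "continuous"),
    ("Anisotropy ratio", "ar", "continuous"),
    ("d(%APA)/dt_max (%APA/ms)", "dapadt_max_pct_per_ms", "continuous"),
    ("APD70 (ms)", "apd70_ms", "continuous"),
    ("APD90 (ms)", "apd90_ms", "continuous"),
]

_MARKS = "*†‡#"


def build_summary_table(records: list[dict], group_order: list[str] | None = None) -> pd.DataFrame:
    """Render grouped feature records as a summary table.

    ``records`` are flat dicts (one per recording) carrying a ``group``
    label plus any of the metric keys used in the table; missing keys are
    skipped. Cells show ``n (%)`` or ``mean ± SEM``; pairwise significance
    at p < 0.05 is marked with shared symbols on the two groups that differ,
    as in printed summary tables.
    """
    if not records:
        cols = group_order or []
        return pd.DataFrame(columns=cols)
    groups = group_order or list(dict.fromkeys(r["group"] for r in records))
    for r in records:
        if r.get("group") not in groups:
            raise ParameterError(f"unknown group label {r.get('group')!r}")
    by_group = {g: [r for r in records if r["group"] == g] for g in groups}

    table: dict[str, dict[str, str]] = {}
    for label, key, kind in _TABLE_ROWS:
        present = [g for g in groups if any(key in r and r[key] is not None for r in by_group[g])]
        if not present:
            continue
        cells: dict[str, str] = {}
        data: dict[str, object] = {}
        for g in present:
            vals = [r[key] for r in by_group[g] if r.get(key) is not None]
            if kind == "categorical":
                s = summarize_categorical(sum(bool(v) for v in vals), len(by_group[g]), g)
            else:
                s = summarize_continuous(vals, g)
            data[g] = vals
            cells[g] = str(s)
        # pairwise significance markers
        mark_i = 0
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                gi, gj = present[i], present[j]
                try:
                    if kind == "categorical":
                        ki = sum(bool(v) for v in data[gi])
                        kj = sum(bool(v) for v in data[gj])
                        res = compare_categorical(
                            [[ki, len(by_group[gi]) - ki], [kj, len(by_group[gj]) - kj]]
                        )
                    else:
                        res = compare_continuous(data[gi], data[gj])
                except ParameterError:
                    continue
                if res.significant and mark_i < len(_MARKS):
                    m = _MARKS[mark_i]
                    cells[gi] += f" {m}"
                    cells[gj] += f" {m}"
                    mark_i += 1
        table[label] = cells
    df = pd.DataFrame.from_dict(table, orient="index")
    # from_dict reorders rows when their key sets differ; restore table order
    return df.reindex(index=list(table), columns=groups)
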