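"""Univariate comparisons: Welch t-tests, Holm families, Tukey letters.

This layer reproduces the published descriptive analysis: Welch two-sample
t-tests between production systems, Holm correction applied within test
families (one family per plotted variable), all-pairs Tukey range tests
with compact letter displays, and "mean (sd) letter" group summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "LetterDisplay",
    "welch_t",
    "holm_adjust",
    "tukey_letters",
    "summarize_groups",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    family: str | None = None


@dataclass(frozen=True)
class LetterDisplay:
    group: str
    mean: float
    sd: float
    letters: str


def welch_t(x, y, family: str | None = None) -> TestResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constants: no evidence of difference
            return TestResult(0.0, float(len(x) + len(y) - 2), 1.0, family=family)
        raise ValueError("both samples have zero variance; t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        family=family,
    )


def holm_adjust(p_values, families=None) -> np.ndarray:
    """Step-down Holm adjustment within each family independently.

    ``families`` is an optional same-length label sequence; ``None`` treats
    all p-values as one family.  Adjusted values are monotone in the sorted
    order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    fams = np.zeros(len(p)) if families is None else np.asarray(families)
    if len(fams) != len(p):
        raise ValueError("families must match p_values in length")
    out = np.empty_like(p)
    for f in pd.unique(fams):
        m = fams == f
        out[m] = multipletests(p[m], method="holm")[1]
    return out


def _compact_letters(labels: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Maintains a list of letter groups (sets of labels allowed to share a
    letter).  Each significant pair splits every group containing both
    members; subsets of surviving groups are absorbed.  Sharing a letter is
    then exactly equivalent to non-significance.
    """
    groups: list[set] = [set(labels)]
    for pair in significant:
        a, b = tuple(pair)
        new_groups = []
        for grp in groups:
            if a in grp and b in grp:
                new_groups.append(grp - {a})
                new_groups.append(grp - {b})
            else:
                new_groups.append(grp)
        # absorb groups contained in another
        groups = [
            g
            for i, g in enumerate(new_groups)
            if g and not any(i != j and g < h for j, h in enumerate(new_groups))
        ]
        # deduplicate
        uniq = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    # order letters by the first (sorted-label) member for determinism
    groups.sort(key=lambda g: sorted(labels.index(x) for x in g))
    letters = {lab: "" for lab in labels}
    for i, grp in enumerate(groups):
        ch = chr(ord("a") + i) if i < 26 else f"<{i}>"
        for lab in grp:
            letters[lab] += ch
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def tukey_letters(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[LetterDisplay]:
    """All-pairs Tukey(-Kramer) HSD with a compact letter display.

    ``groups`` maps label -> sample.  Groups are ordered by decreasing mean
    in the letter assignment (letter 'a' belongs to the highest-mean
    cluster).  A single group gets letter 'a'.
    """
    labels = list(groups)
    if len(labels) == 0:
        raise ValueError("no groups")
    for lab in labels:
        if len(np.asarray(groups[lab])) < 2 and len(labels) > 1:
            raise ValueError(f"group {lab!r} needs at least 2 values")
    means = {lab: float(np.mean(groups[lab])) for lab in labels}
    sds = {lab: float(np.std(groups[lab], ddof=1)) if len(np.asarray(groups[lab])) > 1 else 0.0 for lab in labels}
    order = sorted(labels, key=lambda lab: -means[lab])
    if len(labels) == 1:
        lab = labels[0]
        return [LetterDisplay(lab, means[lab], sds[lab], "a")]

    endog = np.concatenate([np.asarray(groups[lab], dtype=float) for lab in labels])
    codes = np.concatenate([[lab] * len(np.asarray(groups[lab])) for lab in labels])
    res = pairwise_tukeyhsd(endog, codes, alpha=alpha)
    sig = set()
    summ = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for _, row in summ.iterrows():
        if bool(row["reject"]):
            sig.add(frozenset({str(row["group1"]), str(row["group2"])}))
    letters = _compact_letters(order, sig)
    return [LetterDisplay(lab, means[lab], sds[lab], letters[lab]) for lab in labels]


def summarize_groups(
    table: pd.DataFrame,
    rows: str,
    cols: str,
    variable: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way "mean (sd) letter" summary in the published table format.

    One output row per level of ``rows`` (e.g. geographic origin).  Within
    each level of ``cols`` (e.g. production system), Tukey letters compare
    the ``rows`` groups; if ``cols`` has exactly two levels a Welch t-test
    between them is reported per row.  Cells with < 2 observations are
    reported as missing and excluded from the letter comparisons.
    """
    for c in (rows, cols, variable):
        if c not in table.columns:
            raise ValueError(f"column {c!r} missing")
    row_levels = sorted(table[rows].astype(str).unique())
    col_levels = sorted(table[cols].astype(str).unique())

    cells: dict[tuple[str, str], np.ndarray] = {}
    for r in row_levels:
        for c in col_levels:
            v = table.loc[
                (table[rows].astype(str) == r) & (table[cols].astype(str) == c), variable
            ].to_numpy(dtype=float)
            cells[(r, c)] = v

    letters: dict[tuple[str, str], str] = {}
    for c in col_levels:
        usable = {r: cells[(r, c)] for r in row_levels if len(cells[(r, c)]) >= 2}
        if len(usable) >= 2:
            for disp in tukey_letters(usable, alpha=alpha):
                letters[(disp.group, c)] = disp.letters
        elif len(usable) == 1:
            letters[(next(iter(usable)), c)] = "a"

    out_rows = []
    for r in row_levels:
        rec: dict[str, object] = {rows: r}
        for c in col_levels:
            v = cells[(r, c)]
            if len(v) == 0:
                rec[c] = "NA"
            else:
                sd = np.std(v, ddof=1) if len(v) > 1 else float("nan")
                cell = f"{np.mean(v):.2f} ({sd:.2f})"
                if (r, c) in letters:
                    cell += f" {letters[(r, c)]}"
                rec[c] = cell
        if len(col_levels) == 2:
            a, b = (cells[(r, c)] for c in col_levels)
            if len(a) >= 2 and len(b) >= 2 and (np.var(a) > 0 or np.var(b) > 0):
                rec["p_value"] = welch_t(a, b).p_raw
            else:
                rec["p_value"] = float("nan")
        out_rows.append(rec)
    return pd.DataFrame(out_rows)
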