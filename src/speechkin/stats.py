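"""Group statistics: variance checks, mixed-design ANOVA, post hocs.

The study design is a 2 (stutter/control) x 2 (male/female)
between-subjects factorial with repeated measures on two-level within
factors (movement direction, syllable, or sentence). Cell sizes are
unequal, so:

* between-subjects effects use a Type III (unweighted-means) analysis on
  the per-subject means — sum-to-zero coding, each effect tested by the
  increase in residual sum of squares when its columns are dropped from
  the full factorial model;
* each within-subject effect (and its interactions with the between
  factors) is tested on per-subject contrast scores, the classic
  univariate split-plot decomposition. With two-level within factors each
  contrast is a single score per subject, so sphericity is not an issue.

Levene's test (centre = mean) screens homogeneity of variance before each
ANOVA. Pairwise post hocs use the Tukey-Kramer studentized-range
procedure, which generalises Tukey's HSD to unequal group sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import InputError

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "levene_test",
    "mixed_anova",
    "tukey_kramer",
    "correlate_measures",
    "therapy_ttest",
]


@dataclass
class AnovaResult:
    """Per-effect F table from a mixed-design ANOVA."""

    table: pd.DataFrame  # columns: effect, F, df1, df2, p
    n_subjects: int
    dropped_subjects: list[str]

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.table['effect'])}")
        return rows.iloc[0]


@dataclass
class PosthocResult:
    """Tukey-Kramer pairwise comparisons."""

    table: pd.DataFrame  # columns: group1, group2, mean_diff, se, q, p_adj

    def pair(self, a: str, b: str) -> pd.Series:
        t = self.table
        rows = t[((t.group1 == a) & (t.group2 == b)) | ((t.group1 == b) & (t.group2 == a))]
        if rows.empty:
            raise KeyError(f"no comparison {a!r} vs {b!r}")
        return rows.iloc[0]


def levene_test(values, groups) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (centre = mean).

    Returns ``(statistic, p)``. Requires at least two groups with at
    least two observations each.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise InputError("Levene's test needs >= 2 groups of >= 2 observations")
    if all(np.ptp(s) == 0 for s in samples):
        return 0.0, 1.0
    stat, p = _st.levene(*samples, center="mean")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# mixed-design ANOVA


def _sum_coded(levels_per_factor: dict[str, np.ndarray], data: pd.DataFrame):
    """Sum-to-zero design matrix with a full between-factor factorial.

    Returns (X, terms) where terms maps effect name -> column slice.
    """
    n = len(data)
    columns = [np.ones(n)]
    terms: dict[str, list[int]] = {"__intercept__": [0]}
    main_codes: dict[str, list[np.ndarray]] = {}
    col = 1
    for factor, levels in levels_per_factor.items():
        codes = []
        for lev in levels[:-1]:
            x = np.where(
                data[factor].to_numpy() == lev,
                1.0,
                np.where(data[factor].to_numpy() == levels[-1], -1.0, 0.0),
            )
            codes.append(x)
        main_codes[factor] = codes
        terms[factor] = list(range(col, col + len(codes)))
        columns.extend(codes)
        col += len(codes)
    factors = list(levels_per_factor)
    for r in range(2, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            prods = []
            for parts in itertools.product(*(main_codes[f] for f in combo)):
                prods.append(np.prod(np.vstack(parts), axis=0))
            terms[":".join(combo)] = list(range(col, col + len(prods)))
            columns.extend(prods)
            col += len(prods)
    return np.column_stack(columns), terms


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _type3_f(X, terms, y, effect_cols, scale) -> tuple[float, int]:
    """Type III F numerator for one effect: drop its columns, refit."""
    n, p = X.shape
    keep = [j for j in range(p) if j not in effect_cols]
    sse_full = _sse(X, y)
    sse_red = _sse(X[:, keep], y)
    ss = max(sse_red - sse_full, 0.0)
    df1 = len(effect_cols)
    df2 = n - p
    mse = sse_full / df2 if df2 > 0 else np.nan
    if ss <= 1e-12 * max(scale, 1e-300):
        return 0.0, df1
    if mse == 0:
        return np.inf, df1
    return (ss / df1) / mse, df1


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: list[str],
    within: list[str] | None = None,
) -> AnovaResult:
    """Mixed-design ANOVA with Type III between effects.

    ``data`` is a long-format table with one row per subject x
    within-cell observation (replicates within a cell are averaged).
    Within factors must have exactly two levels each (as in the study
    design); between factors may have any number of levels and unequal
    cell sizes. Subjects with incomplete within-cells are excluded
    listwise and reported in ``dropped_subjects``.
    """
    within = list(within or [])
    if not between:
        raise InputError("need at least one between-subjects factor")
    for col in [dv, subject, *between, *within]:
        if col not in data.columns:
            raise InputError(f"column {col!r} missing from data")

    # subject-level between labels (must be constant per subject)
    sub_meta = data.groupby(subject)[between].agg(lambda s: s.unique())
    for f in between:
        bad = sub_meta[f].map(np.size) != 1
        if bad.any():
            raise InputError(f"subjects with inconsistent {f!r}: {list(sub_meta.index[bad])}")
        sub_meta[f] = sub_meta[f].map(lambda v: v[0])

    if within:
        pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
        complete = pivot.dropna()
        dropped = [str(s) for s in pivot.index.difference(complete.index)]
        pivot = complete
    else:
        pivot = data.groupby(subject)[[dv]].mean()
        dropped = []
    meta = sub_meta.loc[pivot.index]

    levels = {f: np.asarray(sorted(meta[f].unique())) for f in between}
    if any(lv.size < 2 for lv in levels.values()):
        raise InputError("each between factor needs >= 2 observed levels")
    X, terms = _sum_coded(levels, meta)
    n, p = X.shape
    if n <= p:
        raise InputError(f"{n} subjects cannot support {p} model parameters")

    rows = []

    def add_effects(y: np.ndarray, suffix: str, include_intercept: bool) -> None:
        scale = float(y @ y)
        for name, cols in terms.items():
            if name == "__intercept__":
                if not include_intercept:
                    continue
                label = suffix
            else:
                label = f"{name}:{suffix}" if suffix else name
            F, df1 = _type3_f(X, terms, y, cols, scale)
            df2 = n - p
            pval = float(_st.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            if F == 0.0:
                pval = 1.0
            rows.append({"effect": label, "F": F, "df1": df1, "df2": df2, "p": pval})

    # between-subjects analysis on the per-subject mean over within cells
    y_between = pivot.to_numpy(dtype=float).mean(axis=1) if within else pivot[dv].to_numpy(dtype=float)
    add_effects(y_between, suffix="", include_intercept=False)

    # within-subject effects from per-subject contrast scores
    if within:
        for f in within:
            if pivot.columns.get_level_values(f).nunique() != 2:
                raise InputError(f"within factor {f!r} must have exactly 2 levels")
        cell_levels = [
            pivot.columns.get_level_values(f).to_numpy() for f in within
        ]
        for r in range(1, len(within) + 1):
            for combo in itertools.combinations(range(len(within)), r):
                signs = np.ones(pivot.shape[1])
                for fi in combo:
                    lv = sorted(set(cell_levels[fi]))
                    signs *= np.where(cell_levels[fi] == lv[0], 1.0, -1.0)
                contrast = (pivot.to_numpy(dtype=float) * signs).mean(axis=1)
                label = ":".join(within[fi] for fi in combo)
                add_effects(contrast, suffix=label, include_intercept=True)

    table = pd.DataFrame(rows)
    return AnovaResult(table=table, n_subjects=n, dropped_subjects=dropped)


def tukey_kramer(values, groups) -> PosthocResult:
    """All pairwise Tukey-Kramer comparisons (HSD for unequal n).

    The standard error for the pair (i, j) is
    ``sqrt(MSE/2 * (1/n_i + 1/n_j))`` with MSE the pooled within-group
    variance; adjusted p-values come from the studentized-range
    distribution with k groups and N - k error df. Groups of size 1 are
    excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in np.unique(groups)]
    samples = {g: values[groups == g] for g in labels}
    singles = [g for g, s in samples.items() if s.size < 2]
    if singles:
        warnings.warn(f"excluding size-1 groups from post hoc: {singles}")
        labels = [g for g in labels if g not in singles]
    if len(labels) < 2:
        raise InputError("Tukey-Kramer needs >= 2 groups of size >= 2")
    k = len(labels)
    ns = np.array([samples[g].size for g in labels])
    means = np.array([samples[g].mean() for g in labels])
    df = int(ns.sum() - k)
    mse = sum(((samples[g] - samples[g].mean()) ** 2).sum() for g in labels) / df
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(_st.studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": min(max(p, 0.0), 1.0),
            }
        )
    return PosthocResult(table=pd.DataFrame(rows))


def correlate_measures(data: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations among all pairs of measures.

    Missing data are pairwise-deleted; a constant column yields an
    undefined correlation reported as NaN. Returns a long-form table with
    columns ``var1, var2, n, r, p``.
    """
    if columns is None:
        columns = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    rows = []
    for a, b in itertools.combinations(columns, 2):
        pair = data[[a, b]].dropna()
        n = len(pair)
        if n < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = _st.pearsonr(pair[a], pair[b])
        rows.append({"var1": a, "var2": b, "n": n, "r": r, "p": p})
    return pd.DataFrame(rows)


def therapy_ttest(values, flags) -> tuple[float, float]:
    """Independent-samples t-test between flagged and unflagged subjects."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    a, b = values[flags], values[~flags]
    if a.size < 2 or b.size < 2:
        raise InputError("both groups need >= 2 observations")
    t, p = _st.ttest_ind(a, b)
    return float(t), float(p)
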