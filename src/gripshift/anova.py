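"""Split-plot (mixed) ANOVA with partial eta squared, post-hocs and correlations.

The experimental design is a classic split plot: between-subject factors
handedness and current hand (2 x 2 cells, possibly unbalanced, e.g.
20/20/10/10 subjects) and within-subject factors previous hand, previous
weight and current weight (2 x 2 x 2 cells per subject, one mean per
cell).  Because every within factor has two levels, each within effect is
a single orthonormal contrast over the 8 cell means, and the whole ANOVA
decomposes into 8 independent between-subject strata:

* the cell-mean average per subject carries the between effects (tested
  against the subject-error stratum);
* each within contrast score carries that within effect and its
  interactions with the between factors (tested against the contrast x
  subject-within-group error stratum).

Within each stratum a Type III analysis with sum-to-zero contrasts is
used — the JASP/SPSS convention, and the only sensible choice with
unbalanced between cells.  All effects have 1 numerator df, so sphericity
is not an issue, and every denominator df equals N - (number of between
cells).  Effect sizes are partial eta squared,
``eta_p^2 = SS_effect / (SS_effect + SS_error) = F df1 / (F df1 + df2)``.

The module follows the statsmodels idiom: build a :class:`MixedAnova`
from a long-format dataframe, call :meth:`~MixedAnova.fit`, read the
:class:`MixedAnovaResults` table or ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedAnova",
    "MixedAnovaResults",
    "mixed_anova",
    "partial_eta_sq",
    "posthoc_ttests",
    "condition_correlations",
]


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: ``F df1 / (F df1 + df2)``."""
    if F < 0:
        raise ValueError("F statistic cannot be negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def _code_factor(values: pd.Series, name: str) -> tuple[np.ndarray, list]:
    """Sum-to-zero (+1/-1) coding of a 2-level factor."""
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"factor {name!r} must have exactly 2 levels, "
                         f"got {levels}")
    return np.where(values.astype(str) == levels[0], 1.0, -1.0), levels


def _subsets(names: list[str]):
    for r in range(len(names) + 1):
        yield from combinations(names, r)


class MixedAnova:
    """Split-plot ANOVA model for long-format per-cell subject means.

    Parameters
    ----------
    data : DataFrame
        One row per subject x within-cell, containing the dependent
        variable, the subject id, the within-factor columns and (constant
        within subject) the between-factor columns.
    dv, subject : str
        Column names of the dependent variable and the subject id.
    within, between : sequence of str
        Factor column names; every factor must have exactly 2 levels.
        ``between`` may be empty (pure repeated measures).
    """

    def __init__(self, data: pd.DataFrame, dv: str, subject: str,
                 within: list[str], between: list[str] = ()):  # noqa: B006
        self.data = data
        self.dv = dv
        self.subject = subject
        self.within = list(within)
        self.between = list(between)
        if not self.within:
            raise ValueError("need at least one within-subject factor")

    # -- internal -----------------------------------------------------------

    def _prepare(self):
        d = self.data
        for col in [self.dv, self.subject, *self.within, *self.between]:
            if col not in d.columns:
                raise ValueError(f"column {col!r} not in data")
        if d[self.dv].isna().any():
            raise ValueError("missing values in the dependent variable")

        cells = d.pivot_table(index=self.subject, columns=self.within,
                              values=self.dv, aggfunc="mean")
        n_cells = 2 ** len(self.within)
        if cells.shape[1] != n_cells or cells.isna().any().any():
            bad = cells.columns[cells.isna().any()].tolist() if cells.shape[1] else []
            raise ValueError(
                f"incomplete within-cell data: expected {n_cells} complete "
                f"cells per subject (problem cells: {bad})")
        subjects = cells.index

        # orthonormal within contrasts
        cols = cells.columns
        if len(self.within) == 1:
            col_levels = {self.within[0]: [c for c in cols]}
            codes = {self.within[0]: np.array(
                [1.0 if str(c) == sorted(map(str, set(cols)))[0] else -1.0
                 for c in cols])}
        else:
            codes = {}
            for k, f in enumerate(self.within):
                vals = pd.Series([c[k] for c in cols])
                codes[f], _ = _code_factor(vals, f)

        contrasts = {}
        for sub in _subsets(self.within):
            c = np.ones(n_cells)
            for f in sub:
                c = c * codes[f]
            contrasts[sub] = c / np.sqrt(n_cells)

        # between design matrix (sum-to-zero, all interactions)
        first = d.drop_duplicates(self.subject).set_index(self.subject)
        first = first.loc[subjects]
        bcodes = {}
        for f in self.between:
            per_subj = d.groupby(self.subject)[f].nunique()
            if (per_subj > 1).any():
                raise ValueError(f"between factor {f!r} varies within a subject")
            bcodes[f], _ = _code_factor(first[f], f)
        bterms = list(_subsets(self.between))
        X = np.column_stack([
            np.prod([bcodes[f] for f in term], axis=0) if term
            else np.ones(len(subjects))
            for term in bterms])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient between design (empty between cell?)")
        return cells.to_numpy(float), contrasts, X, bterms, subjects

    # -- API ----------------------------------------------------------------

    def fit(self, include_intercept: bool = False) -> "MixedAnovaResults":
        M, contrasts, X, bterms, subjects = self._prepare()
        n, p = X.shape
        df2 = n - p
        if df2 < 1:
            raise ValueError("not enough subjects for the between design")
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T

        rows = []
        for wsub, c in contrasts.items():
            y = M @ c
            b = H @ y
            resid = y - X @ b
            sse = float(resid @ resid)
            stratum = ("subject" if not wsub
                       else "*".join(wsub) + " x subject")
            for j, bterm in enumerate(bterms):
                if not wsub and not bterm and not include_intercept:
                    continue
                ss = float(b[j] ** 2 / XtX_inv[j, j])
                if sse > 0:
                    F = ss / (sse / df2)
                else:           # degenerate stratum: no error variance
                    F = np.inf if ss > 0 else 0.0
                name = "*".join([*wsub, *bterm]) or "(intercept)"
                rows.append({
                    "effect": name,
                    "SS_effect": ss,
                    "SS_error": sse,
                    "df1": 1,
                    "df2": df2,
                    "F": F,
                    "p": float(stats.f.sf(F, 1, df2)),
                    "eta_p2": ss / (ss + sse) if ss + sse > 0 else 0.0,
                    "stratum": stratum,
                })
        table = pd.DataFrame(rows).set_index("effect")
        return MixedAnovaResults(model=self, table=table, n_subjects=n)


@dataclass
class MixedAnovaResults:
    """Fitted split-plot ANOVA: per-effect SS, F, p and partial eta squared."""

    model: MixedAnova
    table: pd.DataFrame
    n_subjects: int

    def get(self, effect: str) -> pd.Series:
        """Row for ``effect``; factor order within the name is ignored."""
        key = frozenset(effect.split("*"))
        for name in self.table.index:
            if frozenset(name.split("*")) == key:
                return self.table.loc[name]
        raise KeyError(effect)

    def summary(self) -> str:
        t = self.table.copy()
        t["F"] = t["F"].map("{:.2f}".format)
        t["p"] = t["p"].map("{:.4f}".format)
        t["eta_p2"] = t["eta_p2"].map("{:.2f}".format)
        head = (f"Split-plot ANOVA on {self.model.dv!r} "
                f"({self.n_subjects} subjects; within: "
                f"{', '.join(self.model.within)}; between: "
                f"{', '.join(self.model.between) or 'none'})\n")
        return head + t[["df1", "df2", "F", "p", "eta_p2"]].to_string()


def mixed_anova(summaries: pd.DataFrame, dv: str,
                subject: str = "participant",
                within: list[str] = ("previous_hand", "previous_weight",
                                     "current_weight"),
                between: list[str] = ("handedness", "current_hand"),
                ) -> MixedAnovaResults:
    """Convenience wrapper: build and fit a :class:`MixedAnova` in one call."""
    return MixedAnova(summaries, dv=dv, subject=subject,
                      within=list(within), between=list(between)).fit()


# ---------------------------------------------------------------------------
# post-hoc t-tests and correlations
# ---------------------------------------------------------------------------

def posthoc_ttests(comparisons: list[tuple[str, np.ndarray, np.ndarray, bool]],
                   family_size: int | None = None) -> pd.DataFrame:
    """Bonferroni-corrected t-tests for an explicitly enumerated family.

    Each comparison is ``(label, a, b, paired)``; paired comparisons use a
    paired-samples t-test, unpaired ones a Welch independent t-test.  The
    Bonferroni family defaults to the number of comparisons passed.
    """
    family = family_size if family_size is not None else len(comparisons)
    rows = []
    for label, a, b, paired in comparisons:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{label}: need at least 2 observations per side")
        if paired:
            if len(a) != len(b):
                raise ValueError(f"{label}: paired samples differ in length")
            res = stats.ttest_rel(a, b)
            df = len(a) - 1
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            df = float(res.df)
        t_stat = float(res.statistic)
        p_raw = float(res.pvalue)
        if not np.isfinite(t_stat):  # identical paired vectors -> t = 0
            t_stat, p_raw = 0.0, 1.0
        rows.append({
            "comparison": label,
            "t": t_stat,
            "df": df,
            "p_raw": p_raw,
            "p_bonferroni": min(1.0, family * p_raw),
            "family_size": family,
            "paired": paired,
        })
    return pd.DataFrame(rows)


def condition_correlations(contrasts: pd.DataFrame, force_col: str,
                           bias_col: str = "perceptual_bias",
                           strata: list[str] = ("group", "hand_order",
                                                "current_weight"),
                           ) -> pd.DataFrame:
    """Pearson correlations between force and perceptual contrasts per stratum.

    One correlation per stratum cell (by default group x hand order x
    current weight = 16 cells); Bonferroni correction over the full family
    for the given force parameter.
    """
    strata = [s for s in strata if s in contrasts.columns]
    groups = list(contrasts.groupby(strata, sort=True))
    family = len(groups)
    rows = []
    for key, sub in groups:
        x = sub[force_col].to_numpy(float)
        y = sub[bias_col].to_numpy(float)
        if len(x) < 3:
            raise ValueError(f"stratum {key}: need at least 3 participants")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"stratum {key}: zero variance")
        r, p = stats.pearsonr(x, y)
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(strata, key))
        row.update({"n": len(x), "r": float(r), "p_raw": float(p),
                    "p_bonferroni": min(1.0, family * float(p)),
                    "family_size": family})
        rows.append(row)
    return pd.DataFrame(rows)
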