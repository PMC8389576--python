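"""Factorial group statistics: two-way ANOVA, Tukey HSD, Duncan's multiple
range test, and compact letter displays.

The study design is cytotype × photoperiod with unbalanced cells (3–11
plants).  The workflow per coefficient is:

1. fixed-effects two-way ANOVA with interaction, Type II sums of squares
   (Type III available), via an OLS fit;
2. post-hoc pairwise comparison of the 8 design-cell means against the
   pooled residual mean square — Tukey–Kramer HSD or Duncan's step-down
   multiple range test with the protection level αₚ = 1 − (1−α)^(p−1);
3. a compact letter display (insert-and-absorb): cells share a letter iff
   their pairwise comparison is non-significant.

Duncan's critical values are never larger than Tukey's at the same α, so
every Tukey rejection is also a Duncan rejection (for balanced designs;
with Kramer standard errors in strongly unbalanced data the blocking rule
can, in principle, shield a pair).  No multiplicity correction is applied
*across* coefficients; that choice is recorded in the result metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, NumericalError, ValidationError

CELL_SEP = "@"


def cell_label(cytotype: str, photoperiod_h: float) -> str:
    return f"{cytotype}{CELL_SEP}{photoperiod_h:g}h"


# ---------------------------------------------------------------------------
# Studentized range distribution

def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """P(Q ≤ q) for the studentized range of k groups with df residual
    degrees of freedom."""
    if q <= 0:
        raise ValidationError(f"q must be > 0, got {q}")
    _check_krange(k, df)
    p = float(sps.studentized_range.cdf(q, k, df))
    if not np.isfinite(p):
        raise NumericalError(
            f"studentized range CDF failed to converge at q={q}, k={k}, df={df}")
    return p


def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Inverse of :func:`studentized_range_cdf` (root of CDF(q) = p)."""
    if not 0 < p < 1:
        raise ValidationError(f"p must be in (0, 1), got {p}")
    _check_krange(k, df)
    q = _cached_srq(float(p), int(k), float(df))
    if not np.isfinite(q) or q <= 0:
        raise NumericalError(
            f"studentized range quantile failed at p={p}, k={k}, df={df}")
    return q


from functools import lru_cache


@lru_cache(maxsize=8192)
def _cached_srq(p: float, k: int, df: float) -> float:
    return float(sps.studentized_range.ppf(p, k, df))


def _check_krange(k: int, df: float) -> None:
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")


# ---------------------------------------------------------------------------
# Two-way ANOVA

@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects two-factor ANOVA with interaction."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, mean_sq, F, p
    ss_type: int
    n_obs: int

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("cytotype", "photoperiod_h", "value"):
        if col not in data.columns:
            raise ValidationError(f"data must carry column {col!r}")
    data = data.copy()
    counts = data.groupby(["cytotype", "photoperiod_h"], observed=True).size()
    cytos = data["cytotype"].unique()
    pps = data["photoperiod_h"].unique()
    if len(cytos) < 2 or len(pps) < 2:
        raise ValidationError(
            f"need >=2 levels per factor, got {len(cytos)} cytotypes and "
            f"{len(pps)} photoperiods")
    for cyto in cytos:
        for pp in pps:
            if (cyto, pp) not in counts.index:
                raise ValidationError(f"empty design cell {cell_label(cyto, pp)}")
    return data


def _factor_columns(levels: pd.Series, coding: str) -> np.ndarray:
    """Treatment ('drop first') or sum-to-zero encoded columns of a factor."""
    cats = sorted(levels.unique(), key=str)
    k = len(cats)
    idx = levels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    cols = np.zeros((len(levels), k - 1))
    if coding == "treatment":
        for j in range(1, k):
            cols[:, j - 1] = idx == j
    else:  # sum coding: last level carries -1 in every column
        for j in range(k - 1):
            cols[:, j] = np.where(idx == j, 1.0, np.where(idx == k - 1, -1.0, 0.0))
    return cols


def _ssr(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    x = np.column_stack([np.ones(len(y)), *blocks]) if blocks else \
        np.ones((len(y), 1))
    _, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def two_way_anova(data: pd.DataFrame, ss_type: int = 2) -> AnovaTable:
    """Cytotype × photoperiod ANOVA on a tidy slice (one coefficient).

    Type II sums of squares by default (appropriate for the unbalanced
    3–11-per-cell design when main effects and interaction are both read):
    each term is assessed by the residual-SS drop of adding it to the model
    containing the other terms of equal or lower order.  ``ss_type=3`` uses
    sum-to-zero contrasts and drops each term from the full model.
    """
    if ss_type not in (2, 3):
        raise ValidationError(f"ss_type must be 2 or 3, got {ss_type}")
    data = _prepare(data)
    n = len(data)
    k_cells = data.groupby(["cytotype", "photoperiod_h"], observed=True).ngroups
    if n - k_cells < 1:
        raise DegenerateDataError(
            f"zero residual degrees of freedom (n={n}, cells={k_cells})")
    y = data["value"].to_numpy(dtype=float)
    coding = "treatment" if ss_type == 2 else "sum"
    a = _factor_columns(data["cytotype"], coding)
    b = _factor_columns(data["photoperiod_h"], coding)
    ab = np.einsum("ni,nj->nij", a, b).reshape(len(y), -1)
    df_a, df_b = a.shape[1], b.shape[1]
    df_ab = df_a * df_b
    df_resid = n - 1 - df_a - df_b - df_ab

    ssr_full = _ssr(y, [a, b, ab])
    if ssr_full <= 1e-12 * max(1.0, float(np.var(y))) * n:
        raise DegenerateDataError(
            "residual sum of squares is (numerically) zero; F statistics undefined")
    if ss_type == 2:
        ss_a = _ssr(y, [b]) - _ssr(y, [a, b])
        ss_b = _ssr(y, [a]) - _ssr(y, [a, b])
        ss_ab = _ssr(y, [a, b]) - ssr_full
    else:
        ss_a = _ssr(y, [b, ab]) - ssr_full
        ss_b = _ssr(y, [a, ab]) - ssr_full
        ss_ab = _ssr(y, [a, b]) - ssr_full
    mse = ssr_full / df_resid
    rows = []
    for term, ss, df in (("cytotype", ss_a, df_a), ("photoperiod", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        ss = max(ss, 0.0)
        f = (ss / df) / mse
        rows.append((term, ss, float(df), ss / df, f,
                     float(sps.f.sf(f, df, df_resid))))
    rows.append(("Residual", ssr_full, float(df_resid), mse, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["term", "sum_sq", "df", "mean_sq", "F", "p"]
                       ).set_index("term")
    return AnovaTable(table=out, ss_type=ss_type, n_obs=n)


# ---------------------------------------------------------------------------
# Post-hoc machinery

@dataclass
class PosthocResult:
    method: str  # {tukey, duncan}
    alpha: float
    cells: list[str]  # label order = descending mean
    means: dict[str, float]
    ns: dict[str, int]
    residual_df: float
    residual_ms: float
    pairwise: pd.DataFrame  # cell_a, cell_b, diff, se, critical, significant, ...
    letters: dict[str, str] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def significant(self, a: str, b: str) -> bool:
        pw = self.pairwise
        row = pw[((pw.cell_a == a) & (pw.cell_b == b))
                 | ((pw.cell_a == b) & (pw.cell_b == a))]
        if row.empty:
            raise ValidationError(f"no comparison between {a!r} and {b!r}")
        return bool(row.iloc[0]["significant"])

    def significance_matrix(self) -> dict[frozenset, bool]:
        return {frozenset((r.cell_a, r.cell_b)): bool(r.significant)
                for r in self.pairwise.itertuples()}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "cells": self.cells,
            "means": self.means,
            "n": self.ns,
            "residual_df": self.residual_df,
            "residual_ms": self.residual_ms,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "letters": self.letters,
            "notes": self.notes,
        }


def _cell_stats(data: pd.DataFrame, by: str) -> tuple[list[str], dict, dict]:
    if by == "cells":
        labels = data.apply(
            lambda r: cell_label(r["cytotype"], r["photoperiod_h"]), axis=1)
    elif by == "cytotype":
        labels = data["cytotype"].astype(str)
    elif by == "photoperiod":
        labels = data["photoperiod_h"].map(lambda v: f"{v:g}h")
    else:
        raise ValidationError(f"unknown grouping {by!r}")
    g = data.assign(_cell=labels).groupby("_cell", observed=True)["value"]
    means = g.mean().to_dict()
    ns = g.size().to_dict()
    order = sorted(means, key=means.get, reverse=True)
    return order, means, ns


def _kramer_se(mse: float, na: int, nb: int) -> float:
    return float(np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb)))


def tukey_hsd(
    data: pd.DataFrame,
    anova: AnovaTable,
    alpha: float = 0.05,
    by: str = "cells",
    with_p: bool = True,
) -> PosthocResult:
    """Tukey–Kramer HSD over the design cells (or a factor margin) using the
    pooled residual mean square of the two-way fit.

    ``with_p=False`` skips the (relatively expensive) exact per-pair
    p-values; decisions and letters are unaffected.
    """
    order, means, ns = _cell_stats(_prepare(data), by)
    k, df, mse = len(order), anova.residual_df, anova.residual_ms
    q_crit = studentized_range_quantile(1.0 - alpha, k, df)
    rows = []
    for a, b in itertools.combinations(order, 2):
        diff = means[a] - means[b]
        se = _kramer_se(mse, ns[a], ns[b])
        q_stat = abs(diff) / se
        rows.append({
            "cell_a": a, "cell_b": b, "diff": diff, "se": se,
            "critical": q_crit * se, "significant": q_stat > q_crit,
            "p": float(sps.studentized_range.sf(q_stat, k, df))
                 if with_p else np.nan,
        })
    res = PosthocResult("tukey", alpha, order, means, ns, df, mse,
                        pd.DataFrame(rows),
                        notes={"grouping": by,
                               "across_coefficient_correction": "none"})
    res.letters = compact_letter_display(order, res.significance_matrix())
    return res


def duncan_mrt(
    data: pd.DataFrame,
    anova: AnovaTable,
    alpha: float = 0.05,
    by: str = "cells",
    with_p: bool = True,
) -> PosthocResult:
    """Duncan's multiple range test with the classical step-down blocking
    rule.

    Means are ordered; a span of p consecutive ordered means is tested at
    the protection level αₚ = 1 − (1−α)^(p−1) against
    q(1−αₚ; p, df)·SE(endpoints); a span declared non-significant blocks
    every pair inside it.  Duncan yields decisions, not exact p-values, so
    each pair carries the interval (0, αₚ] or (αₚ, 1].
    """
    order, means, ns = _cell_stats(_prepare(data), by)
    k, df, mse = len(order), anova.residual_df, anova.residual_ms
    asc = list(reversed(order))  # ascending means
    q_crit = {p: studentized_range_quantile((1.0 - alpha) ** (p - 1), p, df)
              for p in range(2, k + 1)}

    decisions: dict[tuple[int, int], bool] = {}

    def visit(i: int, j: int) -> None:
        if i >= j or (i, j) in decisions:
            return
        p = j - i + 1
        a, b = asc[i], asc[j]
        se = _kramer_se(mse, ns[a], ns[b])
        if abs(means[b] - means[a]) > q_crit[p] * se:
            decisions[(i, j)] = True
            visit(i + 1, j)
            visit(i, j - 1)
        else:  # blocking: everything inside a non-significant span is retained
            for x in range(i, j + 1):
                for y in range(x + 1, j + 1):
                    decisions.setdefault((x, y), False)

    visit(0, k - 1)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = asc[i], asc[j]
        p = j - i + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        sig = decisions.get((i, j), False)
        rows.append({
            "cell_a": b, "cell_b": a, "diff": means[b] - means[a],
            "se": _kramer_se(mse, ns[a], ns[b]),
            "critical": q_crit[p] * _kramer_se(mse, ns[a], ns[b]),
            "significant": sig, "span": p, "protection_alpha": alpha_p,
            "p_low": 0.0 if sig else alpha_p,
            "p_high": alpha_p if sig else 1.0,
        })
    res = PosthocResult("duncan", alpha, order, means, ns, df, mse,
                        pd.DataFrame(rows),
                        notes={"grouping": by,
                               "across_coefficient_correction": "none"})
    res.letters = compact_letter_display(order, res.significance_matrix())
    return res


# ---------------------------------------------------------------------------
# Compact letter display

def compact_letter_display(
    cells: list[str], significant: dict[frozenset, bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Guarantees: two cells share at least one letter iff their pairwise
    comparison is non-significant.  Letter count is kept small by absorbing
    subset groups but global minimality is not guaranteed.
    """
    for a, b in itertools.combinations(cells, 2):
        if frozenset((a, b)) not in significant:
            raise ValidationError(
                f"significance matrix misses the pair ({a!r}, {b!r})")
    groups: list[set[str]] = [set(cells)]
    for pair, sig in significant.items():
        if not sig:
            continue
        a, b = tuple(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend((g - {a}, g - {b}))
            else:
                new_groups.append(g)
        # absorb groups contained in another
        groups = [g for g in new_groups
                  if g and not any(g < h for h in new_groups)]
        # drop duplicates
        uniq = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq

    groups.sort(key=lambda g: min(cells.index(c) for c in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(groups) > len(alphabet):
        raise NumericalError("more letter groups than letters available")
    letters = {c: "" for c in cells}
    for letter, g in zip(alphabet, groups):
        for c in g:
            letters[c] += letter
    # internal consistency tripwire
    for a, b in itertools.combinations(cells, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share == significant[frozenset((a, b))]:
            raise NumericalError(
                f"letter display inconsistent for pair ({a}, {b})")
    return letters


# ---------------------------------------------------------------------------
# Per-coefficient driver

@dataclass
class CoefficientAnalysis:
    coefficient: str
    anova: AnovaTable
    posthoc: PosthocResult

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "anova": {
                "ss_type": self.anova.ss_type,
                "n_obs": self.anova.n_obs,
                "table": self.anova.table.reset_index(names="term")
                                          .to_dict(orient="records"),
            },
            "posthoc": self.posthoc.to_dict(),
        }


def analyze_coefficient(
    table: pd.DataFrame,
    coefficient: str,
    method: str = "tukey",
    alpha: float = 0.05,
    ss_type: int = 2,
    by: str = "cells",
    with_p: bool = True,
) -> CoefficientAnalysis:
    """ANOVA → post-hoc → letters for one coefficient of a tidy table
    (columns plant_id, cytotype, photoperiod_h, coefficient, value)."""
    available = sorted(table["coefficient"].unique())
    if coefficient not in available:
        raise ValidationError(
            f"coefficient {coefficient!r} not in table; available: {available}")
    if method not in ("tukey", "duncan"):
        raise ValidationError(f"method must be 'tukey' or 'duncan', got {method!r}")
    data = table[table["coefficient"] == coefficient]
    anova = two_way_anova(data, ss_type=ss_type)
    posthoc = (tukey_hsd if method == "tukey" else duncan_mrt)(
        data, anova, alpha=alpha, by=by, with_p=with_p)
    return CoefficientAnalysis(coefficient, anova, posthoc)


#: figure-style default mapping: Tukey for the quantum yields, Duncan for
#: JIP fluxes, rETR and quenching coefficients
def default_posthoc_method(coefficient: str) -> str:
    return "tukey" if coefficient in ("phi_PSII", "phi_max") else "duncan"
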