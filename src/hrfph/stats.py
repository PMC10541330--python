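"""Cohort-level statistics: contingency tables, exact tests, robust OLS.

The association analysis mirrors a standard neonatal-outcomes workup:
dichotomous outcomes are tabulated by severity category and tested with
Fisher's exact test (Freeman–Halton extension for r x c tables), continuous
outcomes are compared across categories with ordinary least squares using
heteroskedasticity-consistent (HC1) standard errors, and descriptive
summaries are median/IQR for continuous fields and count/percent for flags.

``fisher_exact`` uses exact integer arithmetic throughout: every table with
the observed margins has probability proportional to the multinomial weight
``W = n! / prod(a_ij!)``, and the two-sided p-value under the
point-probability rule is ``sum(W : W <= W_obs) / sum(W)``. On 2 x 2 tables
this reduces to the hypergeometric closed form, with no floating-point tie
tolerance anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composite import CATEGORY_ORDER, Severity, score_observation
from .config import DEFAULT_CONFIG, ScoreConfig
from .errors import (
    DegenerateTableError,
    MissingDataError,
    ValidationError,
)
from .records import BOOL_OUTCOMES, FLOAT_OUTCOMES, PatientRecord

__all__ = [
    "CohortTable",
    "RegressionFit",
    "build_table",
    "fisher_exact",
    "robust_ols",
    "logistic_fit",
    "summarize",
    "round_half_away",
    "scored_frame",
    "analyze_cohort",
    "CohortReport",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTable:
    """Severity-category x outcome-level counts with margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape must match row/column labels")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(int(t) for t in self.array.sum(axis=1))

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(t) for t in self.array.sum(axis=0))

    @property
    def total(self) -> int:
        return int(self.array.sum())


def build_table(
    records: Iterable[Mapping[str, object]] | pd.DataFrame,
    outcome: str,
) -> CohortTable:
    """Tabulate an outcome by severity category.

    ``records`` must carry a ``category`` per patient (see
    :func:`scored_frame`). Rows follow mild < moderate < severe; records with
    a missing outcome are excluded and counted in ``n_excluded`` so shrunken
    denominators stay visible.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if frame.empty:
        raise ValidationError("no records to tabulate")
    if "category" not in frame.columns:
        raise ValidationError("records must carry a 'category' field")
    if outcome not in frame.columns:
        raise ValidationError(f"unknown outcome field {outcome!r}")

    present = frame[~frame[outcome].isna()]
    n_excluded = len(frame) - len(present)
    if present.empty:
        raise MissingDataError(f"outcome {outcome!r} is missing for every record")

    cats = [c.value for c in CATEGORY_ORDER]
    values = sorted(present[outcome].unique(), key=lambda v: (str(type(v)), v))
    if set(present[outcome]) <= {True, False, 0, 1}:
        values = [False, True]
        col_labels = ("no", "yes")
    else:
        col_labels = tuple(str(v) for v in values)
    counts = []
    for cat in cats:
        sub = present[present["category"] == cat]
        counts.append(tuple(int((sub[outcome] == v).sum()) for v in values))
    return CohortTable(
        row_labels=tuple(cats),
        col_labels=col_labels,
        counts=tuple(counts),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2 and Freeman–Halton r x c)
# ---------------------------------------------------------------------------

_FISHER_N_GUARD = 500


def _enumerate_tables(
    row_totals: Sequence[int], col_remaining: list[int]
) -> Iterable[tuple[int, ...]]:
    """Yield every table (flattened row-major) with the given margins."""
    if len(row_totals) == 1:
        if all(c >= 0 for c in col_remaining) and sum(col_remaining) == row_totals[0]:
            yield tuple(col_remaining)
        return
    first, rest = row_totals[0], row_totals[1:]

    def compositions(total: int, caps: list[int]) -> Iterable[tuple[int, ...]]:
        if len(caps) == 1:
            if 0 <= total <= caps[0]:
                yield (total,)
            return
        for x in range(min(total, caps[0]) + 1):
            for tail in compositions(total - x, caps[1:]):
                yield (x, *tail)

    for row in compositions(first, col_remaining):
        remaining = [c - x for c, x in zip(col_remaining, row)]
        for tail in _enumerate_tables(rest, remaining):
            yield row + tail


def fisher_exact(table: CohortTable | Sequence[Sequence[int]] | np.ndarray) -> float:
    """Two-sided exact p-value for independence in an r x c count table.

    Conditional on the observed margins, each table has probability
    proportional to the multinomial weight ``n!/prod(a_ij!)`` (all integers),
    and tables no more probable than the observed one are summed
    (point-probability rule). Rows/columns with zero totals are dropped; a
    table left with a single row or column is uninformative and returns 1.0.
    """
    arr = table.array if isinstance(table, CohortTable) else np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be two-dimensional")
    if np.any(arr < 0):
        raise ValidationError("contingency counts must be non-negative")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    n = int(arr.sum())
    if n == 0:
        raise DegenerateTableError("contingency table has zero total")
    if n > _FISHER_N_GUARD:
        raise ValidationError(
            f"exact enumeration guarded at n <= {_FISHER_N_GUARD}, got n = {n}"
        )
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 1.0

    fact = [math.factorial(k) for k in range(n + 1)]

    def weight(cells: Iterable[int]) -> int:
        denom = math.prod(fact[c] for c in cells)
        return fact[n] // denom  # exact: multinomial coefficients are integers

    w_obs = weight(arr.ravel().tolist())
    row_totals = [int(t) for t in arr.sum(axis=1)]
    col_totals = [int(t) for t in arr.sum(axis=0)]

    numerator = 0
    denominator = 0
    for cells in _enumerate_tables(row_totals, col_totals):
        w = weight(cells)
        denominator += w
        if w <= w_obs:
            numerator += w
    return float(Fraction(numerator, denominator))


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """Point estimates with (robust) standard errors and Wald p-values."""

    params: Mapping[str, float]
    bse: Mapping[str, float]
    pvalues: Mapping[str, float]
    n: int
    method: str
    exact: bool = False


def _design(x: Sequence[float] | np.ndarray | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        mat = x.to_numpy(dtype=float)
    else:
        mat = np.asarray(x, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i + 1}" for i in range(mat.shape[1])]
    return sm.add_constant(mat, has_constant="add"), ["const", *names]


def robust_ols(
    y: Sequence[float] | np.ndarray,
    x: Sequence[float] | np.ndarray | pd.DataFrame,
    cov_type: str = "HC1",
) -> RegressionFit:
    """OLS with heteroskedasticity-consistent (sandwich) standard errors."""
    y = np.asarray(y, dtype=float)
    X, names = _design(x)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("robust_ols requires complete cases (no missing values)")
    if len(y) <= X.shape[1]:
        raise ValidationError("need n greater than the number of predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit(cov_type=cov_type)
    return RegressionFit(
        params=dict(zip(names, res.params)),
        bse=dict(zip(names, res.bse)),
        pvalues=dict(zip(names, res.pvalues)),
        n=len(y),
        method=f"ols_{cov_type.lower()}",
    )


def logistic_fit(
    y: Sequence[int] | np.ndarray,
    x: Sequence[float] | np.ndarray | pd.DataFrame,
) -> RegressionFit:
    """Ordinary maximum-likelihood logistic regression.

    Flagged ``exact=False``: this is the asymptotic fit, not a
    conditional-exact procedure, and it is reported alongside (never instead
    of) the Fisher exact test on the same table.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(x)
    res = sm.Logit(y, X).fit(disp=0)
    return RegressionFit(
        params=dict(zip(names, res.params)),
        bse=dict(zip(names, res.bse)),
        pvalues=dict(zip(names, res.pvalues)),
        n=len(y),
        method="logit_ml",
        exact=False,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(values: Iterable[object], kind: str = "continuous") -> dict[str, float | int]:
    """Median/IQR for continuous fields, count/percent for dichotomous ones.

    Quartiles use linear interpolation between order statistics; percentages
    are rounded half-away-from-zero to the nearest integer for display.
    """
    data = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if kind == "continuous":
        if not data:
            raise MissingDataError("no non-missing values to summarize")
        arr = np.asarray(data, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(arr)}
    if kind == "dichotomous":
        if not data:
            raise MissingDataError("no non-missing values to summarize")
        count = int(sum(bool(v) for v in data))
        denom = len(data)
        return {
            "count": count,
            "denominator": denom,
            "percent": round_half_away(100.0 * count / denom),
        }
    raise ValidationError(f"kind must be 'continuous' or 'dichotomous', got {kind!r}")


# ---------------------------------------------------------------------------
# cohort analysis (Table-2-style report)
# ---------------------------------------------------------------------------

#: outcome rows of the dichotomous block, in report order
DICHOTOMOUS_OUTCOMES = ("death_or_ecls", "ecls", "died", "ino", "vasoactive", "imv", "hfov")
#: continuous outcomes, summarised among survivors (deaths excluded)
CONTINUOUS_OUTCOMES = ("ino_hours", "imv_days", "los_days")


def scored_frame(
    records: Sequence[PatientRecord], config: ScoreConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One row per patient: scores, category, and every known outcome field.

    Records carrying raw observations are scored through the full pipeline;
    records without raw fields may instead carry precomputed ``total`` /
    ``category`` columns (as written by the CLI ``score`` command).
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id}
        if rec.oxygenation is not None and rec.echo is not None:
            res = score_observation(rec.oxygenation, rec.echo, config)
            row.update(hrf=res.hrf, ph=res.ph, total=res.total, category=res.category.value)
        elif "category" in rec.extra and rec.extra["category"]:
            row["category"] = Severity(rec.extra["category"]).value
            if rec.extra.get("total"):
                row["total"] = int(float(rec.extra["total"]))
        else:
            raise MissingDataError(
                f"record {rec.patient_id!r} has neither raw observations nor a category"
            )
        for key in (*BOOL_OUTCOMES, *FLOAT_OUTCOMES):
            row[key] = rec.outcomes.get(key)
        if row.get("death_or_ecls") is None and (
            rec.outcomes.get("died") is not None or rec.outcomes.get("ecls") is not None
        ):
            row["death_or_ecls"] = bool(rec.outcomes.get("died")) or bool(
                rec.outcomes.get("ecls")
            )
        rows.append(row)
    if not rows:
        raise ValidationError("no records to analyze")
    return pd.DataFrame(rows)


@dataclass
class CohortReport:
    """Rendered cohort analysis: per-outcome rows plus overall summaries."""

    category_counts: dict[str, int]
    overall: dict[str, float]
    dichotomous: list[dict[str, object]] = field(default_factory=list)
    continuous: list[dict[str, object]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.dichotomous:
            row = {"outcome": r["outcome"], "kind": "dichotomous", "p_value": r["p_value"],
                   "method": r["method"]}
            for cat in (c.value for c in CATEGORY_ORDER):
                cell = r["per_category"][cat]
                row[cat] = f"{cell['count']}/{cell['denominator']} ({cell['percent']}%)"
            rows.append(row)
        for r in self.continuous:
            row = {"outcome": r["outcome"], "kind": "continuous", "p_value": r["p_value"],
                   "method": r["method"]}
            for cat in (c.value for c in CATEGORY_ORDER):
                cell = r["per_category"].get(cat)
                row[cat] = (
                    f"{cell['median']:g} ({cell['q1']:g}-{cell['q3']:g})" if cell else "-"
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, object]:
        return {
            "category_counts": self.category_counts,
            "overall": self.overall,
            "dichotomous": self.dichotomous,
            "continuous": self.continuous,
        }


def analyze_cohort(
    records: Sequence[PatientRecord], config: ScoreConfig = DEFAULT_CONFIG
) -> CohortReport:
    """Severity-category association analysis of a scored cohort.

    Dichotomous outcomes get per-category count/percent and a Fisher exact
    p-value on the category x outcome table; continuous outcomes get
    median/IQR among survivors and a robust-SE OLS p-value on the category
    ordinal (0 = mild, 1 = moderate, 2 = severe).
    """
    frame = scored_frame(records, config)
    cats = [c.value for c in CATEGORY_ORDER]
    category_counts = {c: int((frame["category"] == c).sum()) for c in cats}
    n = len(frame)

    overall: dict[str, float] = {"n": n}
    for c in cats:
        overall[f"{c.lower()}_share_pct"] = round_half_away(100.0 * category_counts[c] / n)
    for key, name in (
        ("died", "mortality_pct"),
        ("male", "male_pct"),
        ("meconium_aspiration", "meconium_aspiration_pct"),
    ):
        col = frame[key].dropna() if key in frame else pd.Series(dtype=object)
        if len(col):
            overall[name] = summarize(col, "dichotomous")["percent"]
    died = frame["died"].fillna(False).astype(bool) if "died" in frame else None
    if died is not None and died.any() and "ecls" in frame:
        on_ecls = (died & frame["ecls"].fillna(False).astype(bool)).sum()
        overall["deaths_on_ecls_pct"] = round_half_away(100.0 * on_ecls / died.sum())

    report = CohortReport(category_counts=category_counts, overall=overall)

    for outcome in DICHOTOMOUS_OUTCOMES:
        if outcome not in frame or frame[outcome].dropna().empty:
            continue
        table = build_table(frame, outcome)
        per_category = {}
        for cat, row_count in zip(table.row_labels, table.array):
            denom = int(row_count.sum())
            count = int(row_count[1])
            per_category[cat] = {
                "count": count,
                "denominator": denom,
                "percent": round_half_away(100.0 * count / denom) if denom else 0,
            }
        report.dichotomous.append(
            {
                "outcome": outcome,
                "per_category": per_category,
                "p_value": fisher_exact(table),
                "method": "fisher_exact",
                "n_excluded": table.n_excluded,
            }
        )

    survivors = frame[~frame["died"].fillna(False).astype(bool)] if "died" in frame else frame
    for outcome in CONTINUOUS_OUTCOMES:
        if outcome not in frame or survivors[outcome].dropna().empty:
            continue
        sub = survivors[~survivors[outcome].isna()]
        per_category = {}
        for cat in cats:
            vals = sub.loc[sub["category"] == cat, outcome]
            if len(vals):
                per_category[cat] = summarize(vals, "continuous")
        ordinal = sub["category"].map({c: i for i, c in enumerate(cats)})
        p_value = math.nan
        if ordinal.nunique() > 1 and len(sub) > 2:
            fit = robust_ols(sub[outcome].to_numpy(), ordinal.to_numpy())
            p_value = float(fit.pvalues["x1"])
        report.continuous.append(
            {
                "outcome": outcome,
                "per_category": per_category,
                "p_value": p_value,
                "method": "ols_hc1",
                "n_excluded": int(len(frame) - len(sub)),
            }
        )
    return report
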