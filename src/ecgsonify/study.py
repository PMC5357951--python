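"""Scoring statistics for the blinded four-class listening study.

Observers classify sonified 10-s ECG samples into one of four pathology
classes (STEMI, PVC, AFib, Bigeminy; chance level 25 %). This module scores
the response sheets: per-observer accuracy, per-group mean ± SD (sample SD,
n-1), the 4x4 confusion matrix, the share of observers above an accuracy
threshold, and a one-tailed two-sample Student t-test (pooled variance by
default, Welch behind a flag) for comparing groups. A summary-statistic
variant of the test works directly from published (n, mean, sd) triples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES",
    "TTestResult",
    "read_responses",
    "validate_responses",
    "observer_accuracy",
    "group_summary",
    "confusion",
    "fraction_above",
    "one_tailed_t",
    "one_tailed_t_from_summary",
    "simulate_responses",
]

#: Fixed class ordering for confusion matrices and reports.
CLASSES = ("STEMI", "PVC", "AFib", "Bigeminy")

# keys are labels lower-cased with dots/spaces removed, so "A. Fib." matches
_CLASS_ALIASES = {
    "stemi": "STEMI",
    "pvc": "PVC",
    "afib": "AFib",
    "atrialfibrillation": "AFib",
    "bigeminy": "Bigeminy",
}

_REQUIRED = ["observer_id", "group", "sample_id", "true_class", "assigned_class"]


def _canon_class(label: str) -> str:
    key = "".join(c for c in str(label).lower() if c not in ". \t")
    if key not in _CLASS_ALIASES:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return _CLASS_ALIASES[key]


def validate_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a response table.

    Requires the columns observer_id, group, sample_id, true_class,
    assigned_class (``musician`` is optional metadata). Class labels are
    normalized to the canonical four; a duplicated (observer, sample) pair,
    an observer in several groups, or an observer missing some samples is an
    error.
    """
    if table.empty:
        raise ValueError("empty response table")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    out = table.copy()
    out["true_class"] = out["true_class"].map(_canon_class)
    out["assigned_class"] = out["assigned_class"].map(_canon_class)
    dup = out.duplicated(subset=["observer_id", "sample_id"])
    if dup.any():
        pairs = out.loc[dup, ["observer_id", "sample_id"]].values.tolist()
        raise ValueError(f"duplicate (observer, sample) responses: {pairs[:5]}")
    groups_per_obs = out.groupby("observer_id")["group"].nunique()
    if (groups_per_obs > 1).any():
        bad = groups_per_obs[groups_per_obs > 1].index.tolist()
        raise ValueError(f"observers assigned to multiple groups: {bad}")
    counts = out.groupby("observer_id").size()
    if counts.nunique() > 1:
        raise ValueError(
            "every observer must answer the same set of samples; "
            f"response counts vary: {dict(counts)}"
        )
    return out


def read_responses(path: str | Path, column_map: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Read a CSV response sheet. ``column_map`` renames the file's columns
    onto the expected names (for supplementary tables with other headers)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_responses(df)


def observer_accuracy(table: pd.DataFrame) -> pd.Series:
    """Fraction of correct classifications per observer, in [0, 1]."""
    t = validate_responses(table)
    correct = (t["true_class"] == t["assigned_class"]).astype(float)
    return correct.groupby(t["observer_id"]).mean()


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group accuracy summary, in percent.

    Columns: n (observers), mean_pct, sd_pct (sample SD, n-1 denominator;
    NaN for a single-observer group, where the SD is undefined).
    """
    t = validate_responses(table)
    acc = observer_accuracy(t) * 100.0
    group_of = t.groupby("observer_id")["group"].first()
    df = pd.DataFrame({"accuracy_pct": acc, "group": group_of})
    return (
        df.groupby("group")["accuracy_pct"]
        .agg(n="size", mean_pct="mean", sd_pct=lambda s: s.std(ddof=1))
    )


def confusion(table: pd.DataFrame) -> pd.DataFrame:
    """4x4 confusion matrix: rows = true class, columns = assigned class,
    in the fixed ordering of :data:`CLASSES`; entries are counts."""
    t = validate_responses(table)
    mat = pd.crosstab(t["true_class"], t["assigned_class"])
    mat = mat.reindex(index=list(CLASSES), columns=list(CLASSES), fill_value=0)
    mat.index.name = "true"
    mat.columns.name = "assigned"
    return mat


def per_class_accuracy(table: pd.DataFrame) -> pd.Series:
    """Diagonal / row-sum of the confusion matrix, per true class."""
    mat = confusion(table)
    return pd.Series(np.diag(mat), index=mat.index) / mat.sum(axis=1)


def fraction_above(table: pd.DataFrame, threshold: float) -> float:
    """Share of observers whose accuracy is strictly above ``threshold``
    (a fraction, e.g. 0.90)."""
    acc = observer_accuracy(table)
    return float((acc > threshold).mean())


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False  # zero pooled variance: p pinned to 0/1/0.5


def one_tailed_t(group_a: np.ndarray, group_b: np.ndarray,
                 welch: bool = False) -> TTestResult:
    """One-tailed two-sample t-test for the alternative mean(A) > mean(B).

    Default is the classic Student test with pooled variance and
    df = nA + nB - 2; ``welch=True`` switches to the unequal-variance form
    with Welch–Satterthwaite df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if welch:
        return _t_from_summary(a.size, a.mean(), a.std(ddof=1),
                               b.size, b.mean(), b.std(ddof=1), welch=True)
    return _t_from_summary(a.size, a.mean(), a.std(ddof=1),
                           b.size, b.mean(), b.std(ddof=1), welch=False)


def one_tailed_t_from_summary(n_a: int, mean_a: float, sd_a: float,
                              n_b: int, mean_b: float, sd_b: float,
                              welch: bool = False) -> TTestResult:
    """Same test computed from published summary statistics (n, mean, SD)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need at least 2 observations")
    return _t_from_summary(n_a, mean_a, sd_a, n_b, mean_b, sd_b, welch)


def _t_from_summary(n_a, mean_a, sd_a, n_b, mean_b, sd_b, welch) -> TTestResult:
    va, vb = sd_a**2, sd_b**2
    diff = mean_a - mean_b
    if welch:
        se2 = va / n_a + vb / n_b
        if se2 == 0:
            return _degenerate(diff)
        df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
        t = diff / np.sqrt(se2)
    else:
        pooled = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        df = n_a + n_b - 2
        if pooled == 0:
            return _degenerate(diff)
        t = diff / np.sqrt(pooled * (1 / n_a + 1 / n_b))
    p = float(stats.t.sf(t, df))
    return TTestResult(t=float(t), df=float(df), p=p)


def _degenerate(diff: float) -> TTestResult:
    if diff > 0:
        return TTestResult(t=np.inf, df=np.nan, p=0.0, degenerate=True)
    if diff < 0:
        return TTestResult(t=-np.inf, df=np.nan, p=1.0, degenerate=True)
    return TTestResult(t=0.0, df=np.nan, p=0.5, degenerate=True)


def simulate_responses(seed: int, n_samples: int = 12,
                       group_sizes: tuple[int, ...] = (10, 7, 5),
                       p_correct: tuple[float, ...] = (0.78, 0.68, 0.50)
                       ) -> pd.DataFrame:
    """Simulate a blinded-study response sheet.

    Each observer answers every sample; a response is correct with the
    observer's group probability, otherwise uniform over the three wrong
    classes. Defaults mirror a 22-observer, 12-sample, three-group design.
    """
    rng = np.random.default_rng(seed)
    true = [CLASSES[i % 4] for i in range(n_samples)]
    rows = []
    obs = 0
    for g, (size, p) in enumerate(zip(group_sizes, p_correct), start=1):
        for _ in range(size):
            obs += 1
            for s, tc in enumerate(true):
                if rng.random() < p:
                    ac = tc
                else:
                    ac = rng.choice([c for c in CLASSES if c != tc])
                rows.append({"observer_id": f"obs{obs:02d}", "group": g,
                             "musician": bool(rng.random() < 0.3),
                             "sample_id": f"s{s + 1:02d}",
                             "true_class": tc, "assigned_class": ac})
    return pd.DataFrame(rows)
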