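"""Evaluation artifacts: confusion matrices, method-comparison statistics
and the feature-combination ablation.

Per-subject accuracies of the four classifier families are compared with a
heteroscedasticity-robust one-way (Welch) ANOVA after a Levene check of
the equal-variance assumption, followed by Games-Howell pairwise post-hoc
tests; inter-subject variances are compared pairwise with two-sided
variance-ratio F-tests under Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .synthdata import CLASSES
from .features import select_combination
from .datasetprep import split_holdout
from .models import ANNTrainRecipe, train_final, predict, accuracy


# ---------------------------------------------------------------------------
# Confusion matrices

@dataclass
class ConfusionMatrix:
    """Count matrix with true labels on rows, predictions on columns."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Per-class sensitivities; zero-support rows stay zero (flagged in
        ``zero_support_rows``)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        out = np.divide(self.counts, sums, out=np.zeros_like(self.counts),
                        where=sums > 0)
        return out

    @property
    def zero_support_rows(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.counts.sum(axis=1)) if s == 0]


def confusion(
    pred: Sequence, truth: Sequence, labels: Sequence[str] = CLASSES
) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    idx = {l: i for i, l in enumerate(labels)}
    unknown = (set(pred) | set(truth)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the class universe: {sorted(unknown)}")
    k = len(labels)
    counts = np.zeros((k, k))
    for t, p in zip(truth, pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def average_confusions(matrices: Sequence[ConfusionMatrix]) -> np.ndarray:
    """Element-wise mean of row-normalized per-subject matrices."""
    if not matrices:
        raise ValueError("need at least one confusion matrix")
    labels = matrices[0].labels
    if any(m.labels != labels for m in matrices):
        raise ValueError("confusion matrices have different label universes")
    return np.mean([m.row_normalized() for m in matrices], axis=0)


# ---------------------------------------------------------------------------
# Group statistics

def _as_groups(groups: Sequence[np.ndarray], min_n: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < min_n for g in gs):
        raise ValueError(f"every group needs at least {min_n} values")
    return gs


def levene(groups: Sequence[np.ndarray], center: str = "mean") -> tuple[float, float]:
    """Levene's test of equal variances (classical mean centering by
    default; ``center='median'`` gives the Brown-Forsythe variant)."""
    gs = _as_groups(groups)
    w, p = sst.levene(*gs, center=center)
    return float(w), float(p)


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p) with Welch-Satterthwaite denominator degrees
    of freedom.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.any(v <= 0):
        raise ValueError("every group needs positive variance")
    w = n / v
    sw = w.sum()
    mw = np.sum(w * m) / sw
    num = np.sum(w * (m - mw) ** 2) / (k - 1)
    h = np.sum((1 - w / sw) ** 2 / (n - 1))
    den = 1 + 2 * (k - 2) / (k**2 - 1) * h
    f = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * h)
    p = float(sst.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def games_howell(
    groups: Sequence[np.ndarray], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Games-Howell pairwise post-hoc comparisons.

    Per pair: Welch-Satterthwaite degrees of freedom and a p-value from the
    studentized-range distribution with k groups.  Suited to unequal
    variances, as after a significant Welch ANOVA.
    """
    gs = _as_groups(groups)
    k = len(gs)
    names = list(names) if names is not None else [f"g{i + 1}" for i in range(k)]
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        diff = m[i] - m[j]
        df = se2**2 / (
            (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
        )
        q = np.abs(diff) / np.sqrt(se2 / 2)
        p = float(np.clip(sst.studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(diff),
                "se": float(np.sqrt(se2)),
                "df": float(df),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def variance_ftests(
    groups: Sequence[np.ndarray], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Two-sided pairwise variance-ratio F-tests with Benjamini-Hochberg
    FDR-adjusted p-values."""
    gs = _as_groups(groups)
    k = len(gs)
    names = list(names) if names is not None else [f"g{i + 1}" for i in range(k)]
    n = np.array([len(g) for g in gs], dtype=float)
    v = np.array([g.var(ddof=1) for g in gs])
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        f = v[i] / v[j]
        d1, d2 = n[i] - 1, n[j] - 1
        p = 2 * min(sst.f.cdf(f, d1, d2), sst.f.sf(f, d1, d2))
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "f": float(f),
                "df1": float(d1),
                "df2": float(d2),
                "p_raw": float(min(p, 1.0)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# Report assembly

@dataclass
class StatsReport:
    """Method-comparison summary over a cohort of per-subject accuracies."""

    accuracy_table: pd.DataFrame  # subjects x methods
    levene: dict | None = None
    welch: dict | None = None
    games_howell: pd.DataFrame | None = None
    variance_ftests: pd.DataFrame | None = None
    descriptives: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        def r3(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.round(6).to_json(orient="records"))

        out: dict = {
            "accuracy_table": json.loads(
                self.accuracy_table.round(3).to_json(orient="index")
            ),
            "descriptives": r3(self.descriptives.reset_index()),
        }
        if self.levene is not None:
            out["levene"] = self.levene
            out["welch_anova"] = self.welch
            out["games_howell"] = r3(self.games_howell)
            out["variance_ftests"] = r3(self.variance_ftests)
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_method_comparison(
    accuracies: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> StatsReport:
    """Assemble the full method-comparison report.

    ``accuracies`` maps each method to its per-subject accuracies (or is a
    subjects x methods frame).  With a single method, only descriptive
    statistics are produced.
    """
    table = (
        accuracies.copy()
        if isinstance(accuracies, pd.DataFrame)
        else pd.DataFrame(dict(accuracies))
    )
    desc = table.agg(["mean", "std", "var"]).T
    report = StatsReport(accuracy_table=table, descriptives=desc)
    if table.shape[1] < 2 or table.shape[0] < 2:
        return report  # inference needs >= 2 groups of >= 2 subjects
    groups = [table[c].to_numpy(dtype=float) for c in table.columns]
    names = list(table.columns)
    w, p = levene(groups)
    f, df1, df2, pw = welch_anova(groups)
    report.levene = {"w": w, "p": p}
    report.welch = {"f": f, "df1": df1, "df2": df2, "p": pw}
    report.games_howell = games_howell(groups, names)
    report.variance_ftests = variance_ftests(groups, names)
    return report


# ---------------------------------------------------------------------------
# Feature-combination ablation

#: the eight tested combinations: ZC/SSC/WL base plus subsets of MAV/RMS/VAR
ABLATION_COMBOS: tuple[tuple[str, frozenset[str]], ...] = (
    ("ZC/SSC/WL", frozenset({"zc", "ssc", "wl"})),
    ("ZC/SSC/WL + MAV", frozenset({"zc", "ssc", "wl", "mav"})),
    ("ZC/SSC/WL + RMS", frozenset({"zc", "ssc", "wl", "rms"})),
    ("ZC/SSC/WL + VAR", frozenset({"zc", "ssc", "wl", "var"})),
    ("ZC/SSC/WL + MAV + RMS", frozenset({"zc", "ssc", "wl", "mav", "rms"})),
    ("ZC/SSC/WL + MAV + VAR", frozenset({"zc", "ssc", "wl", "mav", "var"})),
    ("ZC/SSC/WL + RMS + VAR", frozenset({"zc", "ssc", "wl", "rms", "var"})),
    ("ZC/SSC/WL + MAV + RMS + VAR", frozenset({"zc", "ssc", "wl", "mav", "rms", "var"})),
)


def run_ablation(
    subject_tables: Mapping[str, pd.DataFrame],
    ann_params: dict,
    recipe: ANNTrainRecipe,
    seed: int = 0,
    train_frac: float = 0.9,
) -> tuple[pd.DataFrame, StatsReport]:
    """Holdout accuracy of the MLP per feature combination per subject.

    Each subject's balanced table is reduced to each combination's columns
    (3 channels x set size), split 90/10, trained and scored; the resulting
    combos x subjects accuracies are then compared with the same
    ANOVA/post-hoc machinery as the method comparison.
    """
    rows = {}
    for sid, table in subject_tables.items():
        accs = {}
        for name, combo in ABLATION_COMBOS:
            sub = select_combination(table, combo)
            train, test = split_holdout(sub, train_frac=train_frac, seed=seed)
            model = train_final(train, "ann", ann_params, recipe, seed)
            accs[name] = accuracy(predict(model, test), test["label"].to_numpy())
        rows[sid] = accs
    acc = pd.DataFrame(rows).T  # subjects x combos
    report = run_method_comparison(acc)
    return acc, report
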