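"""ROC analysis, operating-threshold selection, and risk stratification.

Screening statistics for the diagnosis scores: ROC curves (sensitivity
vs 1-specificity), the Youden-index operating threshold, 2x2 confusion
summaries, micro/macro one-vs-rest AUROC, and the risk-stratification
report — the validation cohort split at the median risk score into low
and high groups, with positive rates (bootstrap CIs), Byar-approximation
Poisson CIs on event counts, a Woolf-interval odds ratio, and a Pearson
chi-square test on the 2x2 group-by-outcome table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import ParameterError, ShapeMismatchError, StratificationError

Z_95 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # true-positive rate at score >= threshold
    specificity: np.ndarray
    auc: float

    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def compute_roc(scores, labels) -> RocCurve:
    """ROC over all distinct-score operating points; trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance statistic (ties counted
    one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ShapeMismatchError(f"{scores.shape} vs {labels.shape}")
    if len(np.unique(labels)) < 2:
        raise ParameterError("both classes must be present to compute a ROC")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(labels, scores)),
    )


def select_optimal_threshold(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J; ties broken toward specificity.

    Preferring the higher-specificity operating point mirrors hospital
    use, where false positives carry the larger cost.  If every score is
    identical (J = 0 everywhere) the degenerate threshold is returned
    with a warning.
    """
    j = roc.youden_j()
    best_j = j.max()
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    if best_j <= 1e-12:
        warnings.warn(
            "degenerate ROC: no threshold separates the classes", stacklevel=2
        )
        return float(finite.min())
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(roc.specificity[candidates])]
    thr = float(roc.thresholds[best])
    if np.isinf(thr):  # sentinel point above the top score
        thr = float(np.nextafter(finite.max(), np.inf))
    return thr


@dataclass
class ThresholdPolicy:
    """Screening favours sensitivity (lower threshold), hospital mode
    favours specificity (higher threshold); 'youden' takes the J-optimal
    point."""

    mode: str = "youden"  # "screening" | "hospital" | "youden"
    shift: float = 0.1

    def apply(self, roc: RocCurve) -> float:
        base = select_optimal_threshold(roc)
        if self.mode == "youden":
            return base
        if self.mode == "screening":
            return max(0.0, base - self.shift)
        if self.mode == "hospital":
            return min(1.0, base + self.shift)
        raise ParameterError(f"unknown threshold policy {self.mode!r}")


# ---------------------------------------------------------------------------
# confusion


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def confusion_from_counts(p: int, tp: int, n: int, fp: int) -> ConfusionMatrix2x2:
    """Build the 2x2 matrix from positives, true positives, negatives,
    false positives (fn = p - tp, tn = n - fp)."""
    if tp > p:
        raise ParameterError(f"tp={tp} exceeds positives p={p}")
    if fp > n:
        raise ParameterError(f"fp={fp} exceeds negatives n={n}")
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=p - tp, tn=n - fp)


def confusion_from_scores(
    scores, labels, threshold: float
) -> ConfusionMatrix2x2:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    return ConfusionMatrix2x2(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
        tn=int((~pred & ~labels).sum()),
    )


# ---------------------------------------------------------------------------
# multiclass AUROC


def micro_macro_auroc(
    score_frame: pd.DataFrame, labels, classes=None
) -> tuple[float, float]:
    """Micro and macro one-vs-rest AUROC.

    ``score_frame`` holds one score column per class; macro is the
    unweighted mean of per-class AUCs (classes absent from the labels
    are dropped with a warning), micro flattens all (class, image)
    indicator/score pairs into one binary problem.
    """
    labels = np.asarray(labels)
    classes = list(classes or score_frame.columns)
    if len(set(labels)) < 2:
        raise ParameterError("need at least two classes present")
    per_class = []
    flat_truth, flat_score = [], []
    for c in classes:
        truth = (labels == c).astype(int)
        score = np.asarray(score_frame[c], dtype=float)
        flat_truth.append(truth)
        flat_score.append(score)
        if truth.sum() == 0:
            warnings.warn(
                f"class {c!r} absent from labels; excluded from macro AUROC",
                stacklevel=2,
            )
            continue
        per_class.append(float(roc_auc_score(truth, score)))
    macro = float(np.mean(per_class))
    micro = float(
        roc_auc_score(np.concatenate(flat_truth), np.concatenate(flat_score))
    )
    return micro, macro


# ---------------------------------------------------------------------------
# interval estimators


def byar_poisson_ci(x: int, level: float = 0.95) -> tuple[float, float]:
    """Byar's approximation to the Poisson exact CI for an event count.

    lower = x (1 - 1/(9x) - z/(3 sqrt(x)))^3,
    upper = (x+1) (1 - 1/(9(x+1)) + z/(3 sqrt(x+1)))^3; lower = 0 at x = 0.
    """
    if x < 0:
        raise ParameterError("event count must be non-negative")
    if abs(level - 0.95) < 1e-9:
        z = Z_95
    else:
        z = float(sp_stats.norm.ppf(0.5 + level / 2.0))
    xu = x + 1
    upper = xu * (1.0 - 1.0 / (9.0 * xu) + z / (3.0 * np.sqrt(xu))) ** 3
    if x == 0:
        return 0.0, float(upper)
    lower = x * (1.0 - 1.0 / (9.0 * x) - z / (3.0 * np.sqrt(x))) ** 3
    return float(lower), float(upper)


def odds_ratio_with_ci(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with the Woolf log-interval.

    The Haldane correction (0.5 added to every cell) is applied iff any
    cell is zero, keeping the estimate finite.
    """
    if min(a, b, c, d) < 0:
        raise ParameterError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if abs(level - 0.95) < 1e-9 else float(
        sp_stats.norm.ppf(0.5 + level / 2.0)
    )
    return (
        float(or_),
        float(np.exp(np.log(or_) - z * se)),
        float(np.exp(np.log(or_) + z * se)),
    )


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction), 1 df."""
    table = np.asarray(table, dtype=float).reshape(2, 2)
    if table.min() < 0:
        raise ParameterError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("all margins must be positive")
    stat, p, _, _ = sp_stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bootstrap_rate_ci(
    flags, reps: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for a proportion (resampling with
    replacement, reproducible per seed)."""
    flags = np.asarray(flags).astype(float)
    if flags.size < 1:
        raise ParameterError("need at least one observation")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(reps, flags.size))
    rates = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# risk stratification


@dataclass
class RiskGroup:
    name: str
    n: int
    positive_events: int
    positive_rate: float
    rate_ci: tuple[float, float]
    event_count_ci: tuple[float, float]
    #: share of the cohort's positive events captured by this group
    share_of_positives: float


@dataclass
class RiskStrataReport:
    disease: str
    median_threshold: float
    low: RiskGroup
    high: RiskGroup
    odds_ratio: float
    or_ci: tuple[float, float]
    chi2: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, or_txt in (
            (self.low, "NA"),
            (
                self.high,
                f"{self.odds_ratio:.1f}({self.or_ci[0]:.1f}, {self.or_ci[1]:.1f})",
            ),
        ):
            rows.append(
                {
                    "subset": f"{g.name} risk",
                    "n": g.n,
                    "positive_events": g.positive_events,
                    "positive_rate_95ci": (
                        f"{g.positive_rate:.2f}"
                        f"({g.rate_ci[0]:.2f}, {g.rate_ci[1]:.2f})"
                    ),
                    "share_of_positives": round(g.share_of_positives, 4),
                    "event_count_byar_95ci": (
                        f"({g.event_count_ci[0]:.1f}, {g.event_count_ci[1]:.1f})"
                    ),
                    "OR_95ci": or_txt,
                    "p_value": "NA" if g is self.low else f"{self.p_value:.3g}",
                }
            )
        return pd.DataFrame(rows)


def stratify_by_median(
    table: pd.DataFrame,
    disease: str,
    score_column: str | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> RiskStrataReport:
    """Split a prediction table at the median risk score for ``disease``.

    Scores >= median form the high-risk group (ties go high).  Reports
    per-group positive rates with bootstrap CIs, Byar CIs on event
    counts, the high-vs-low odds ratio (Woolf interval, Haldane-corrected
    when a cell is empty), and the Pearson chi-square p-value.
    """
    score_column = score_column or f"score_{disease}"
    scores = np.asarray(table[score_column], dtype=float)
    labels = (np.asarray(table["true_label"]) == disease).astype(int)
    if len(np.unique(scores)) < 2:
        raise StratificationError("all scores identical; cannot stratify")
    median = float(np.median(scores))
    high_mask = scores >= median
    if high_mask.all() or (~high_mask).all():
        # median coincides with an extreme; fall back to a strict split
        raise StratificationError(
            "median split produced an empty group (scores too discrete)"
        )
    total_pos = max(int(labels.sum()), 1)
    groups = {}
    for name, mask in (("low", ~high_mask), ("high", high_mask)):
        n = int(mask.sum())
        events = int(labels[mask].sum())
        groups[name] = RiskGroup(
            name=name,
            n=n,
            positive_events=events,
            positive_rate=events / n,
            rate_ci=bootstrap_rate_ci(labels[mask], reps=bootstrap_reps, seed=seed),
            event_count_ci=byar_poisson_ci(events),
            share_of_positives=events / total_pos,
        )
    a = groups["high"].positive_events
    b = groups["high"].n - groups["high"].positive_events
    c = groups["low"].positive_events
    d = groups["low"].n - groups["low"].positive_events
    or_, lo, hi = odds_ratio_with_ci(a, b, c, d)
    chi2, p = chi_square_2x2([[a, b], [c, d]])
    return RiskStrataReport(
        disease=disease,
        median_threshold=median,
        low=groups["low"],
        high=groups["high"],
        odds_ratio=or_,
        or_ci=(lo, hi),
        chi2=chi2,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# prediction tables


def records_to_table(records) -> pd.DataFrame:
    """PredictionRecords -> DataFrame with one score_<class> column each."""
    rows = []
    for r in records:
        row = {
            "image_id": r.image_id,
            "patient_id": r.patient_id,
            "true_label": r.true_label,
        }
        row.update({f"score_{c}": v for c, v in r.scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def score_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("score_")]


def table_micro_macro(table: pd.DataFrame) -> tuple[float, float]:
    classes = [c.removeprefix("score_") for c in score_columns(table)]
    frame = table[score_columns(table)].copy()
    frame.columns = classes
    return micro_macro_auroc(frame, table["true_label"], classes)
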