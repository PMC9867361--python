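"""Classification metrics, cross-validation and descriptive statistics.

The confusion-matrix vocabulary follows the study's clinical convention:
by default the positive class is the abnormal (perceived neck pain)
group, so TP counts painful subjects detected as painful.  The deployed
scoring model's published worked example instead counts the pain-free
class as positive; the ``positive_class`` argument covers both readings.

Per-class precision/recall/F1 are computed by swapping the positive
class; support-weighted averages weight per-class values by true-class
counts.  Divisions by zero yield NaN-flagged components that are
excluded from the weighted averages with a warning flag, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .cohort import ABNORMAL, NORMAL, band_of_usage, cohort_frame

CLASSES = (ABNORMAL, NORMAL)


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int
    positive_class: int = ABNORMAL

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    per_class: dict                      # class label -> ClassMetrics
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    undefined_components: list = field(default_factory=list)

    def display(self) -> dict:
        """Rounded presentation values: percent accuracy, 2-dp proportions."""
        return {
            "accuracy_pct": round(self.accuracy * 100),
            "weighted_precision": round(self.weighted_precision, 2),
            "weighted_recall": round(self.weighted_recall, 2),
            "weighted_f1": round(self.weighted_f1, 2),
        }


def confusion(predictions: Sequence[int], truths: Sequence[int],
              positive_class: int = ABNORMAL) -> ConfusionMatrix:
    """Tabulate TP/FP/TN/FN with a declared positive class."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    for v in list(predictions) + list(truths):
        if v not in CLASSES:
            raise ValueError(f"label outside the two classes: {v!r}")
    pos = positive_class
    tp = sum(p == pos and t == pos for p, t in zip(predictions, truths))
    tn = sum(p != pos and t != pos for p, t in zip(predictions, truths))
    fp = sum(p == pos and t != pos for p, t in zip(predictions, truths))
    fn = sum(p != pos and t == pos for p, t in zip(predictions, truths))
    return ConfusionMatrix(tp, fp, tn, fn, positive_class=pos)


def _prf(tp, fp, fn):
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    if not math.isnan(prec) and not math.isnan(rec) and prec + rec > 0:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        f1 = float("nan")
    return prec, rec, f1


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and support-weighted precision/recall/F1 plus accuracy."""
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    pos, neg_tp, neg_fp, neg_fn = cm.positive_class, cm.TN, cm.FN, cm.FP
    other = NORMAL if pos == ABNORMAL else ABNORMAL
    per = {
        pos: ClassMetrics(*_prf(cm.TP, cm.FP, cm.FN), support=cm.TP + cm.FN),
        other: ClassMetrics(*_prf(neg_tp, neg_fp, neg_fn), support=cm.TN + cm.FP),
    }
    undefined = [f"{k}:{m}" for k, cmx in per.items()
                 for m, v in (("precision", cmx.precision),
                              ("recall", cmx.recall), ("f1", cmx.f1))
                 if math.isnan(v)]

    def wavg(attr):
        pairs = [(getattr(c, attr), c.support) for c in per.values()
                 if not math.isnan(getattr(c, attr))]
        tot = sum(s for _, s in pairs)
        return sum(v * s for v, s in pairs) / tot if tot else float("nan")

    return MetricsReport(
        per_class=per,
        accuracy=(cm.TP + cm.TN) / cm.total,
        weighted_precision=wavg("precision"),
        weighted_recall=wavg("recall"),
        weighted_f1=wavg("f1"),
        undefined_components=undefined,
    )


@dataclass
class CVReport:
    k: int
    fold_confusions: list
    pooled: ConfusionMatrix
    report: MetricsReport
    flagged_folds: list


def kfold_cv(data, trainer: Callable, k: int = 9, target: str = "input_class",
             seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation pooling per-fold confusions.

    ``trainer(train_df)`` must return an object with ``predict(row_dict)``.
    Folds missing a class in their training part are flagged, not run.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    df = data if isinstance(data, pd.DataFrame) else cohort_frame(data)
    if k < 2 or len(df) < k:
        raise ValueError("need k >= 2 and at least k records")
    # stratification needs every class populated in each fold; fall back
    # to plain shuffled folds (e.g. leave-one-out) when k exceeds the
    # minority class size
    if k <= df[target].value_counts().min():
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds, flagged = [], []
    preds_all, truth_all = [], []
    for fold_i, (tr, te) in enumerate(skf.split(df, df[target])):
        tr_df, te_df = df.iloc[tr], df.iloc[te]
        if tr_df[target].nunique() < 2:
            flagged.append(fold_i)
            continue
        model = trainer(tr_df)
        preds = [model.predict(r) for r in te_df.to_dict("records")]
        truths = te_df[target].tolist()
        folds.append(confusion(preds, truths))
        preds_all += preds
        truth_all += truths
    pooled = confusion(preds_all, truth_all)
    return CVReport(k, folds, pooled, metrics(pooled), flagged)


@dataclass
class DescriptiveStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float       # sample SD, n-1 denominator
    se: float       # sd / sqrt(n)


def describe(values) -> DescriptiveStats:
    """n, min, max, mean, sample SD and standard error of one variable."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("describe requires at least one value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return DescriptiveStats(
        n=int(v.size), min=float(v.min()), max=float(v.max()),
        mean=float(v.mean()), sd=sd, se=sd / math.sqrt(v.size))


def correlation_vs_response(values, response01, method: str = "pearson") -> float:
    """Correlation of a variable with the binary class response.

    Pearson on a 0/1 response is the point-biserial coefficient.
    Returns NaN (flagged) when either side has zero variance.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(response01, dtype=float)
    if len(v) != len(r) or len(v) < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if v.std() == 0 or r.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(_st.pearsonr(v, r).statistic)
    if method == "spearman":
        return float(_st.spearmanr(v, r).statistic)
    raise ValueError(f"unknown method: {method}")


@dataclass
class BoxplotSummary:
    n: int
    Q1: float
    Q2: float
    Q3: float
    IQR: float
    whisker_low: float
    whisker_high: float
    mild_outliers: list
    extreme_outliers: list


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles, 1.5*IQR whiskers and mild/extreme outlier fences.

    Quartiles use linear interpolation of the empirical CDF.  Mild
    outliers lie beyond 1.5*IQR from the quartiles, extreme outliers
    beyond 3*IQR (extreme values are not double-counted as mild).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty cell")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    in_mild = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    in_extreme = (v >= q1 - 3 * iqr) & (v <= q3 + 3 * iqr)
    wl = float(v[in_mild].min())
    wh = float(v[in_mild].max())
    mild = v[~in_mild & in_extreme].tolist()
    extreme = v[~in_extreme].tolist()
    return BoxplotSummary(int(v.size), float(q1), float(q2), float(q3),
                          float(iqr), wl, wh, mild, extreme)


FEATURES_FOR_BANDS = ("age", "angle_1", "angle_2", "area",
                      "contrast", "homogeneity", "correlation", "energy")


def band_summaries(records=None, features=FEATURES_FOR_BANDS) -> dict:
    """Box-plot summaries per (usage band x class) cell for each feature.

    Returns ``{feature: {(band_index, class): BoxplotSummary}}``; empty
    cells are omitted.
    """
    df = cohort_frame(records)
    df = df.assign(band=[band_of_usage(h, c).band_index
                         for h, c in zip(df.h_mean, df.input_class)])
    out = {}
    for feat in features:
        cells = {}
        for (band, cls), grp in df.groupby(["band", "input_class"]):
            cells[(int(band), int(cls))] = boxplot_summary(grp[feat])
        out[feat] = cells
    return out


def plot_band_boxes(records=None, feature: str = "angle_1", path=None):
    """Box plot of one feature by usage band, split by class (optional PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cohort_frame(records)
    df = df.assign(band=[band_of_usage(h, c).band_index
                         for h, c in zip(df.h_mean, df.input_class)])
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = [(b, g[feature].to_numpy()) for b, g in df.groupby("band")]
    ax.boxplot([g for _, g in groups], tick_labels=[str(b) for b, _ in groups],
               whis=1.5)
    ax.set_xlabel("usage band")
    ax.set_ylabel(feature)
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
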