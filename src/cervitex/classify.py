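"""The three decision procedures for neck-pain prediction.

1. A printed IF-THEN rule set over usage category, age, image contrast
   and angle_1, evaluated first-match-wins.
2. The deployed symbolic (GEP-derived) scoring model: a closed-form
   expression y over hours and the four texture features, squashed by a
   sigmoid H = 1 / (1 + exp(t1*y + t2)) with t1 = -1797.29, t2 = 7.28;
   H >= 0.5 classifies a subject as normal.  The printed expression is
   typographically ambiguous, so an enumerated grammar of candidate
   parses is scored against the cohort's printed per-patient H values
   and the best parse selected; when no candidate reproduces the printed
   classifications, scoring falls back to the printed H column.
3. A from-scratch C4.5-style decision-tree trainer: information-gain
   splits (binary thresholds on numeric attributes, multiway on
   categoricals), cost-sensitive instance reweighting for the 38/8 class
   imbalance, no pruning.  Exposed both functionally (``train_c45``) and
   as a model/results pair (:class:`CervicalPainTree` /
   :class:`TreeResults`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import ABNORMAL, NORMAL, PatientRecord, cohort_frame

CLASS_NAMES = {NORMAL: "normal", ABNORMAL: "abnormal"}


@dataclass
class Diagnosis:
    label: int                  # NORMAL or ABNORMAL
    source: str                 # "rules" | "gep" | "c45"
    detail: object = None       # fired rule index, or score
    flagged: bool = False       # default/undefined path taken

    @property
    def label_name(self) -> str:
        return CLASS_NAMES[self.label]


# ---------------------------------------------------------------------------
# usage categories and the printed rule set

USAGE_CATEGORIES = ("1_hours", "2_hours", "2_to_8_10", "8_10_hours")


def usage_category(h_mean: float) -> str:
    """Map daily hours onto the rule set's usage vocabulary.

    h <= 1 -> "1_hours"; 1 < h <= 2 -> "2_hours"; 2 < h < 8 ->
    "2_to_8_10"; h >= 8 -> "8_10_hours".  This mapping is a declared
    convention, validated by requiring every cohort record to fire
    exactly one printed rule.
    """
    if h_mean < 0:
        raise ValueError(f"negative usage hours: {h_mean}")
    if h_mean <= 1:
        return "1_hours"
    if h_mean <= 2:
        return "2_hours"
    if h_mean < 8:
        return "2_to_8_10"
    return "8_10_hours"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions mapping to a class label.

    Each condition is ``(field, op, value)`` with op in {"in", "<=", ">"}
    over the fields usage / age / contrast / angle_1.
    """

    conditions: tuple
    label: int

    def matches(self, rec) -> bool:
        for fld, op, val in self.conditions:
            x = usage_category(rec.h_mean) if fld == "usage" else getattr(rec, fld)
            if op == "in":
                if x not in val:
                    return False
            elif op == "<=":
                if not x <= val:
                    return False
            elif op == ">":
                if not x > val:
                    return False
            else:
                raise ValueError(f"unknown op {op}")
        return True


@dataclass
class RuleSet:
    rules: list                         # ordered, first-match-wins
    default_label: int = ABNORMAL       # used (flagged) when nothing fires

    def to_json(self) -> str:
        return json.dumps(
            [{"conditions": [[f, o, sorted(v) if isinstance(v, frozenset) else v]
                             for f, o, v in r.conditions],
              "label": CLASS_NAMES[r.label]} for r in self.rules],
            indent=2)


_UNDER_8 = frozenset({"1_hours", "2_hours", "2_to_8_10"})
_OVER_2 = frozenset({"2_to_8_10", "8_10_hours"})


def printed_rules() -> RuleSet:
    """The seven published IF-THEN rules, in printed order."""
    R = Rule
    return RuleSet([
        R((("usage", "in", frozenset({"1_hours"})),), NORMAL),
        R((("usage", "in", frozenset({"2_hours"})),), NORMAL),
        R((("usage", "in", frozenset({"8_10_hours"})), ("age", "<=", 27)), ABNORMAL),
        R((("usage", "in", _UNDER_8), ("age", "<=", 27)), NORMAL),
        R((("usage", "in", frozenset({"2_to_8_10"})), ("age", ">", 27),
           ("contrast", "<=", 0.1455), ("angle_1", "<=", 72.42)), NORMAL),
        R((("usage", "in", _OVER_2), ("age", ">", 27),
           ("contrast", "<=", 0.1455), ("angle_1", ">", 72.42)), ABNORMAL),
        R((("usage", "in", _OVER_2), ("age", ">", 27),
           ("contrast", ">", 0.1455)), ABNORMAL),
    ])


def matching_rules(record, rules: RuleSet) -> list[int]:
    """1-based indices of every rule whose antecedent the record satisfies."""
    return [i + 1 for i, r in enumerate(rules.rules) if r.matches(record)]


def classify_rules(record, rules: RuleSet | None = None) -> Diagnosis:
    """Evaluate the rule list in order; first match wins.

    If no rule fires the default label (abnormal) is returned with the
    ``flagged`` bit set — never silently.
    """
    if rules is None:
        rules = printed_rules()
    for i, r in enumerate(rules.rules):
        if r.matches(record):
            return Diagnosis(r.label, "rules", detail=i + 1)
    return Diagnosis(rules.default_label, "rules", detail=None, flagged=True)


# ---------------------------------------------------------------------------
# the deployed sigmoid scoring model

T1 = -1797.29
T2 = 7.28


def gep_h(y: float, t1: float = T1, t2: float = T2) -> float:
    """Sigmoid squashing of the raw model output, H = 1/(1+exp(t1*y+t2)).

    Strictly increasing in y for t1 < 0; overflow saturates to the 0/1
    limits instead of raising.
    """
    z = t1 * y + t2
    if z > 700:
        return 0.0
    if z < -700:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def _ref_parse(d0, d2, d6, d7, d8, d9):
    num = (math.exp(d8) / 4) ** 4 * math.exp(math.exp(d6)) \
        * (d9 / 4) * (d2 / 127) * (d7 / 112)
    den = d2 / 4 + math.log(d8) + d6
    return num / den


def _parse_exp_quarter(d0, d2, d6, d7, d8, d9):
    num = math.exp(d8 / 4) ** 4 * math.exp(math.exp(d6)) \
        * (d9 / 4) * (d2 / 127) * (d7 / 112)
    den = d2 / 4 + math.log(d8) + d6
    return num / den


def _parse_powers(d0, d2, d6, d7, d8, d9):
    num = (math.exp(d8) / 4) ** 4 * math.exp(math.exp(d6)) \
        * d9 ** 4 * d2 ** (1 / 127) * d7 ** (1 / 112)
    den = d2 / 4 + math.log(d8) + d6
    return num / den


def _parse_plain_exp(d0, d2, d6, d7, d8, d9):
    num = (math.exp(d8) / 4) ** 4 * math.exp(d6) \
        * (d9 / 4) * (d2 / 127) * (d7 / 112)
    den = d2 / 4 + math.log(d8) + d6
    return num / den


def _parse_nested_den(d0, d2, d6, d7, d8, d9):
    num = (math.exp(d8) / 4) ** 4 * math.exp(math.exp(d6)) \
        * (d9 / 4) * (d2 / 127) * (d7 / 112)
    den = d2 / (4 + math.log(d8) + d6)
    return num / den


def _parse_no_denominator(d0, d2, d6, d7, d8, d9):
    # deliberately degenerate candidate: the division is dropped
    return (math.exp(d8) / 4) ** 4 * math.exp(math.exp(d6)) \
        * (d9 / 4) * (d2 / 127) * (d7 / 112)


def _with_gender(f):
    def g(d0, d2, d6, d7, d8, d9):
        return f(d0, d2, d6, d7, d8, d9) * (1.0 + d0)
    g.__name__ = f.__name__ + "_x_gender"
    return g


#: enumerated grammar of grouping/division readings of the printed
#: expression, with and without a multiplicative gender factor
CANDIDATE_PARSES: dict[str, Callable] = {
    "reference": _ref_parse,
    "exp_quarter": _parse_exp_quarter,
    "integer_powers": _parse_powers,
    "plain_exp_contrast": _parse_plain_exp,
    "nested_denominator": _parse_nested_den,
    "no_denominator": _parse_no_denominator,
    "reference_x_gender": _with_gender(_ref_parse),
    "exp_quarter_x_gender": _with_gender(_parse_exp_quarter),
}


def gep_y(record, parse: str | Callable = "reference") -> float:
    """Evaluate the raw symbolic score y on one record.

    Returns NaN (undefined-flagged) for non-positive correlation — the
    expression takes its logarithm — or a vanishing denominator.
    """
    f = CANDIDATE_PARSES[parse] if isinstance(parse, str) else parse
    d0 = 1.0 if record.gender == "male" else 0.0
    if record.correlation <= 0:
        return float("nan")
    try:
        y = f(d0, record.h_mean, record.contrast, record.homogeneity,
              record.correlation, record.energy)
    except (ZeroDivisionError, OverflowError, ValueError):
        return float("nan")
    return float(y)


@dataclass
class GEPModel:
    """Resolved scoring model: chosen parse plus the sigmoid constants."""

    parse: str = "reference"
    t1: float = T1
    t2: float = T2
    threshold: float = 0.5
    printed_score_mode: bool = False    # score from the cohort's H column

    def score(self, record) -> float:
        if self.printed_score_mode:
            return float(record.gep_h)
        y = gep_y(record, self.parse)
        return float("nan") if math.isnan(y) else gep_h(y, self.t1, self.t2)


@dataclass
class ParseResolution:
    model: GEPModel
    residuals: dict             # parse name -> max |H_computed - H_printed|
    agreements: dict            # parse name -> records whose class matches
    chosen: str
    fallback: bool


def resolve_gep_parse(cohort: Sequence[PatientRecord] | None = None,
                      candidates: dict[str, Callable] | None = None
                      ) -> ParseResolution:
    """Score every candidate parse against the printed per-patient H values.

    The parse minimising the maximum absolute H residual over the cohort
    is selected.  If no candidate reproduces the printed classifications
    (threshold 0.5) on every record, printed-score mode is engaged as a
    fallback and the best residual recorded.  Deterministic for a fixed
    candidate list.
    """
    if cohort is None:
        from .cohort import load_cohort
        cohort = load_cohort()
    if candidates is None:
        candidates = CANDIDATE_PARSES
    residuals, agreements = {}, {}
    for name, f in candidates.items():
        errs, agree = [], 0
        for rec in cohort:
            y = gep_y(rec, f)
            if math.isnan(y):
                errs.append(1.0)
                continue
            h = gep_h(y)
            errs.append(abs(h - rec.gep_h))
            if (h >= 0.5) == (rec.predicted_class == NORMAL):
                agree += 1
        residuals[name] = max(errs)
        agreements[name] = agree
    chosen = min(residuals, key=lambda k: (residuals[k], list(residuals).index(k)))
    fallback = agreements[chosen] < len(cohort)
    model = GEPModel(parse=chosen, printed_score_mode=fallback)
    return ParseResolution(model, residuals, agreements, chosen, fallback)


def classify_gep(record, model: GEPModel) -> Diagnosis:
    """Threshold the model score: H >= 0.5 -> normal, else abnormal.

    An undefined score yields the conservative abnormal label, flagged.
    """
    h = model.score(record)
    if math.isnan(h):
        return Diagnosis(ABNORMAL, "gep", detail=h, flagged=True)
    return Diagnosis(NORMAL if h >= model.threshold else ABNORMAL, "gep", detail=h)


# ---------------------------------------------------------------------------
# cost-sensitive C4.5-style tree induction

@dataclass
class CostMatrix:
    """Misclassification costs C[i][j] = cost of predicting j for true i.

    Rows/columns follow ``class_order``; the diagonal must be zero.  The
    study's setting [(0, 1), (5, 0)] with order (abnormal, normal)
    up-weights the minority pain-free class five-fold.
    """

    costs: tuple = ((0.0, 1.0), (5.0, 0.0))
    class_order: tuple = (ABNORMAL, NORMAL)

    def __post_init__(self):
        c = np.asarray(self.costs, dtype=float)
        if c.shape != (2, 2) or c[0, 0] != 0 or c[1, 1] != 0:
            raise ValueError("cost matrix must be 2x2 with a zero diagonal")
        if (c < 0).any():
            raise ValueError("costs must be non-negative")

    def instance_weights(self, y: np.ndarray) -> np.ndarray:
        """Reweight instances by their class's total misclassification cost.

        Each instance of class i gets weight proportional to sum_j C[i][j];
        weights are normalised to keep the total equal to len(y).
        """
        row_cost = {cls: sum(self.costs[k]) for k, cls in enumerate(self.class_order)}
        w = np.array([row_cost[v] for v in y], dtype=float)
        return w * (len(y) / w.sum())

    @property
    def upweighted_class(self) -> int:
        sums = [sum(r) for r in self.costs]
        return self.class_order[int(np.argmax(sums))]


def entropy(class_counts: Sequence[float], base: float = 2.0) -> float:
    """Shannon entropy of a (possibly weighted) class-count vector.

    The 0*log(0) terms are dropped; an all-zero vector is rejected.
    """
    c = np.asarray(class_counts, dtype=float)
    if (c < 0).any() or c.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive sum")
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _weighted_class_counts(y, w, classes):
    return [float(w[y == cls].sum()) for cls in classes]


def information_gain(y: np.ndarray, partition: Sequence[np.ndarray],
                     weights: np.ndarray | None = None) -> float:
    """Parent entropy minus the weighted entropy of a partition.

    ``partition`` is a list of boolean masks covering the dataset; empty
    parts contribute nothing.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty dataset")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    classes = sorted(set(y.tolist()))
    parent = entropy(_weighted_class_counts(y, w, classes))
    total = w.sum()
    child = 0.0
    for mask in partition:
        wm = w[mask]
        if wm.sum() == 0:
            continue
        child += wm.sum() / total * entropy(_weighted_class_counts(y[mask], wm, classes))
    return parent - child


def threshold_candidates(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted distinct numeric values."""
    u = np.unique(np.asarray(values, dtype=float))
    return (u[:-1] + u[1:]) / 2.0


@dataclass
class TreeNode:
    is_leaf: bool
    label: int | None = None
    counts: dict = field(default_factory=dict)     # weighted class counts
    attr: str | None = None
    threshold: float | None = None                 # numeric binary split
    children: dict = field(default_factory=dict)   # "le"/"gt" or category -> node

    def predict(self, rec) -> int:
        node = self
        while not node.is_leaf:
            x = getattr(rec, node.attr) if not isinstance(rec, dict) else rec[node.attr]
            if node.threshold is not None:
                node = node.children["le" if x <= node.threshold else "gt"]
            else:
                child = node.children.get(x)
                if child is None:       # unseen category: heaviest branch
                    child = max(node.children.values(),
                                key=lambda c: sum(c.counts.values()))
                node = child
        return node.label


@dataclass
class TreeModel:
    root: TreeNode
    features: list
    target: str
    cost_matrix: CostMatrix
    node_count: int = 0
    leaf_count: int = 0

    def predict(self, rec) -> int:
        return self.root.predict(rec)

    def to_rules(self) -> list[tuple[tuple, int]]:
        """Flatten root-to-leaf paths into (conditions, label) conjunctions."""
        out = []

        def walk(node, conds):
            if node.is_leaf:
                out.append((tuple(conds), node.label))
                return
            if node.threshold is not None:
                walk(node.children["le"], conds + [(node.attr, "<=", node.threshold)])
                walk(node.children["gt"], conds + [(node.attr, ">", node.threshold)])
            else:
                for val, child in node.children.items():
                    walk(child, conds + [(node.attr, "in", frozenset({val}))])

        walk(self.root, [])
        return out

    def to_ruleset(self) -> RuleSet:
        return RuleSet([Rule(conds, label) for conds, label in self.to_rules()])

    def to_json(self) -> str:
        def enc(node):
            if node.is_leaf:
                return {"leaf": CLASS_NAMES[node.label], "counts": node.counts}
            d = {"attr": node.attr}
            if node.threshold is not None:
                d["threshold"] = node.threshold
            d["children"] = {str(k): enc(v) for k, v in node.children.items()}
            return d
        return json.dumps(enc(self.root), indent=2)


def _leaf(y, w):
    classes = sorted(set(y.tolist()))
    counts = {cls: float(w[y == cls].sum()) for cls in classes}
    best = max(counts.values())
    tied = [cls for cls, c in counts.items() if c == best]
    label = ABNORMAL if ABNORMAL in tied else tied[0]   # safety-first tie-break
    return TreeNode(True, label=label, counts=counts)


def _best_split(df, y, w, features, min_leaf):
    best = (0.0, None)   # (gain, descriptor)
    for attr in features:             # ties broken by column order
        col = df[attr].to_numpy()
        if col.dtype.kind in "ifu":
            for thr in threshold_candidates(col):
                le = col <= thr
                if min(le.sum(), (~le).sum()) < min_leaf:
                    continue
                g = information_gain(y, [le, ~le], w)
                if g > best[0] + 1e-12:
                    best = (g, (attr, float(thr), None))
        else:
            vals = sorted(set(col.tolist()))
            if len(vals) < 2:
                continue
            masks = [col == v for v in vals]
            if min(m.sum() for m in masks) < min_leaf:
                continue
            g = information_gain(y, masks, w)
            if g > best[0] + 1e-12:
                best = (g, (attr, None, vals))
    return best


def train_c45(data, target: str = "input_class", features: Sequence[str] | None = None,
              cost_matrix: CostMatrix | None = None, min_leaf: int = 2,
              max_depth: int | None = None) -> TreeModel:
    """Induce an unpruned decision tree by recursive information-gain splits.

    ``data`` is a DataFrame or a list of :class:`PatientRecord`.  Numeric
    attributes get binary threshold splits at midpoints between sorted
    distinct values; string-valued attributes split multiway.  The cost
    matrix is applied by instance reweighting before induction.
    Deterministic given the dataset order.
    """
    if not isinstance(data, pd.DataFrame):
        data = cohort_frame(data)
    if features is None:
        features = [c for c in data.columns
                    if c not in (target, "patient_id", "gep_h", "predicted_class")]
    cm = cost_matrix or CostMatrix()
    y_all = data[target].to_numpy()
    w_all = cm.instance_weights(y_all)

    def grow(idx, depth):
        y = y_all[idx]
        w = w_all[idx]
        df = data.iloc[idx]
        if len(set(y.tolist())) == 1 or len(idx) <= min_leaf or \
                (max_depth is not None and depth >= max_depth):
            return _leaf(y, w)
        gain, desc = _best_split(df, y, w, features, min_leaf)
        if desc is None or gain <= 0:
            return _leaf(y, w)
        attr, thr, vals = desc
        node = TreeNode(False, attr=attr, threshold=thr,
                        counts={cls: float(w[y == cls].sum())
                                for cls in sorted(set(y.tolist()))})
        col = df[attr].to_numpy()
        if thr is not None:
            le = col <= thr
            node.children["le"] = grow(idx[le], depth + 1)
            node.children["gt"] = grow(idx[~le], depth + 1)
        else:
            for v in vals:
                node.children[v] = grow(idx[col == v], depth + 1)
        return node

    root = grow(np.arange(len(data)), 0)

    def count(node):
        if node.is_leaf:
            return 1, 1
        n, l = 1, 0
        for c in node.children.values():
            cn, cl = count(c)
            n += cn
            l += cl
        return n, l

    nodes, leaves = count(root)
    return TreeModel(root, list(features), target, cm, nodes, leaves)


# ---------------------------------------------------------------------------
# model / results surface for the trainable classifier

class CervicalPainTree:
    """Cost-sensitive decision-tree model of neck-pain status.

    Statsmodels-flavoured entry point: construct from a cohort (records
    or DataFrame), then :meth:`fit` induces the tree — optionally on a
    stratified train split — and returns a :class:`TreeResults`.
    """

    def __init__(self, data, target: str = "input_class",
                 features: Sequence[str] | None = None,
                 cost_matrix: CostMatrix | None = None, min_leaf: int = 2):
        self.data = data if isinstance(data, pd.DataFrame) else cohort_frame(data)
        self.target = target
        self.features = features
        self.cost_matrix = cost_matrix or CostMatrix()
        self.min_leaf = min_leaf

    @classmethod
    def from_records(cls, records, **kw):
        return cls(cohort_frame(records), **kw)

    def fit(self, train_fraction: float = 1.0, seed: int = 0) -> "TreeResults":
        df = self.data
        if train_fraction < 1.0:
            from sklearn.model_selection import train_test_split
            tr, te = train_test_split(
                df, train_size=train_fraction, random_state=seed,
                stratify=df[self.target])
        else:
            tr, te = df, None
        tree = train_c45(tr, self.target, self.features,
                         self.cost_matrix, self.min_leaf)
        return TreeResults(self, tree, tr, te)


class TreeResults:
    """Fitted tree with its train/test predictions and a summary table."""

    def __init__(self, model: CervicalPainTree, tree: TreeModel,
                 train: pd.DataFrame, test: pd.DataFrame | None):
        self.model = model
        self.tree = tree
        self.train = train
        self.test = test

    def predict(self, data=None) -> np.ndarray:
        df = self.train if data is None else (
            data if isinstance(data, pd.DataFrame) else cohort_frame(data))
        return np.array([self.tree.predict(row) for row in df.to_dict("records")])

    def _eval(self, df):
        from .evaluate import confusion, metrics
        preds = [self.tree.predict(r) for r in df.to_dict("records")]
        cm = confusion(preds, df[self.model.target].tolist(), positive_class=ABNORMAL)
        return cm, metrics(cm)

    def summary(self) -> str:
        cm, rep = self._eval(self.train)
        lines = [
            "Cost-sensitive decision tree (C4.5-style, information gain, unpruned)",
            f"  features: {', '.join(self.tree.features)}",
            f"  cost matrix: {self.model.cost_matrix.costs} "
            f"over classes {self.model.cost_matrix.class_order}",
            f"  nodes: {self.tree.node_count}   leaves: {self.tree.leaf_count}",
            f"  train n={len(self.train)}  accuracy={rep.accuracy:.4f}  "
            f"weighted P={rep.weighted_precision:.4f}  "
            f"weighted R={rep.weighted_recall:.4f}  "
            f"weighted F1={rep.weighted_f1:.4f}",
        ]
        if self.test is not None and len(self.test):
            cm2, rep2 = self._eval(self.test)
            lines.append(
                f"  test  n={len(self.test)}  accuracy={rep2.accuracy:.4f}  "
                f"confusion TP={cm2.TP} FN={cm2.FN} FP={cm2.FP} TN={cm2.TN}")
        lines.append("  rules:")
        for conds, label in self.tree.to_rules():
            txt = " AND ".join(
                f"{a} {'in ' + '/'.join(sorted(v)) if o == 'in' else o + ' ' + format(v, '.4g')}"
                for a, o, v in conds) or "(always)"
            lines.append(f"    IF {txt} THEN {CLASS_NAMES[label]}")
        return "\n".join(lines)
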