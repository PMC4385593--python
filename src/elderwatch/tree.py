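"""Cost-sensitive decision-tree induction with rule extraction.

A C4.5-family learner for binary alert classification: gain-ratio split
selection over numeric thresholds and multiway categorical partitions,
growth to purity (no depth or leaf-size limits), confidence-based
pessimistic pruning, and leaf labelling by minimum expected
misclassification cost.  Every leaf also carries an alert-fraction score,
so the tree doubles as a ranker for ROC analysis.

The public surface follows the Model/Results convention:

>>> results = DecisionTreeModel(data, target="is_alert").fit()
>>> labels, scores = results.predict(new_data)
>>> for rule in results.rules():
...     print(rule)

plus free functions (``train_tree``, ``predict``, ``relabel_leaves``,
``extract_rules``, ``classify_with_rules``) wrapping the same objects.

Design notes: a numeric split stores the *smallest observed value of the
right branch* as its threshold, with semantics (x < T | x >= T).  Extracted
rules therefore render in the conventional ``attr >= 180`` form, and a
planted threshold present in the data is recovered literally.  Missing
values (and categories unseen in training) follow the majority branch, in
training and prediction alike.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist

logger = logging.getLogger(__name__)

_EPS = 1e-12
_TIE = 1e-10


# --------------------------------------------------------------------------
# cost matrix, conditions, rules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs with zero diagonal.

    ``fn`` is the cost of predicting no-alert for a true alert (the
    costly error in this setting); ``fp`` the converse.
    """

    fn: float = 1.0
    fp: float = 1.0

    def __post_init__(self):
        if self.fn < 0 or self.fp < 0:
            raise ValueError("misclassification costs must be nonnegative")

    @classmethod
    def unit(cls) -> "CostMatrix":
        return cls(1.0, 1.0)


_OPS = {
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
}


@dataclass(frozen=True)
class Condition:
    """One atomic antecedent condition; missing values never satisfy it."""

    attr: str
    op: str
    value: object

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unsupported operator {self.op!r}")

    def holds(self, data: pd.DataFrame) -> np.ndarray:
        col = data[self.attr]
        mask = _OPS[self.op](col, self.value)
        return (mask & col.notna()).to_numpy(dtype=bool)

    def holds_record(self, record: Mapping) -> bool:
        v = record.get(self.attr) if hasattr(record, "get") else record[self.attr]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return False
        return bool(_OPS[self.op](v, self.value))

    def __str__(self) -> str:
        v = self.value
        if isinstance(v, float) and float(v).is_integer():
            v = int(v)
        return f"{self.attr} {self.op} {v}"


@dataclass(frozen=True)
class Rule:
    """A conjunctive classification rule (one tree path, simplified)."""

    conditions: tuple[Condition, ...]
    alert: bool

    def matches(self, data: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(data), dtype=bool)
        for c in self.conditions:
            out &= c.holds(data)
        return out

    def matches_record(self, record: Mapping) -> bool:
        return all(c.holds_record(record) for c in self.conditions)

    def __str__(self) -> str:
        ante = " ∧ ".join(str(c) for c in self.conditions) or "TRUE"
        return f"{ante} → Is_Alert = {'true' if self.alert else 'false'}"


#: The two alert rules selected at the end of the original case study,
#: expressed over the prepared/initial attributes.
FINAL_ALERT_RULES: tuple[Rule, ...] = (
    Rule(
        (
            Condition("time_session_max", ">=", 180.0),
            Condition("age", ">", 70.0),
        ),
        alert=True,
    ),
    Rule(
        (
            Condition("time_session_max", ">=", 120.0),
            Condition("atmospheric_conditions", ">=", 1.5),
        ),
        alert=True,
    ),
)


def classify_with_rules(rules: Sequence[Rule], data) -> np.ndarray | int:
    """Alert iff any alert-consequent rule's antecedent holds.

    ``data`` may be a DataFrame (vectorised, returns an int array) or a
    single mapping (returns 0/1).
    """
    alert_rules = [r for r in rules if r.alert]
    if isinstance(data, pd.DataFrame):
        out = np.zeros(len(data), dtype=bool)
        for r in alert_rules:
            out |= r.matches(data)
        return out.astype(int)
    return int(any(r.matches_record(data) for r in alert_rules))


# --------------------------------------------------------------------------
# tree internals
# --------------------------------------------------------------------------


class _Node:
    __slots__ = (
        "n0", "n1", "attr", "kind", "threshold", "categories",
        "children", "majority_child", "prediction", "score",
    )

    def __init__(self, n0: int, n1: int):
        self.n0 = int(n0)
        self.n1 = int(n1)
        self.attr = None
        self.kind = None           # 'num' | 'cat'
        self.threshold = None      # numeric: x < T left, x >= T right
        self.categories = None     # categorical: labels of children, in order
        self.children = None
        self.majority_child = 0
        self.prediction = 1 if n1 > n0 else 0
        self.score = n1 / (n0 + n1) if (n0 + n1) else 0.0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    def make_leaf(self):
        self.attr = self.kind = self.threshold = self.categories = self.children = None


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    m = (p > 0) & (p < 1)
    pm = p[m]
    out[m] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return out


def _entropy_counts(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _ucf(errors: float, n: float, cf: float = 0.25) -> float:
    """Upper confidence limit of the binomial error rate (C4.5-style)."""
    if n <= 0:
        return 0.0
    if errors >= n:
        return 1.0
    return float(_beta_dist.ppf(1.0 - cf, errors + 1.0, n - errors))


@dataclass
class _SplitCandidate:
    gain_ratio: float
    attr: str
    kind: str
    threshold: float | None = None


class DecisionTreeModel:
    """Cost-sensitive C4.5-style decision tree for a binary alert target.

    Parameters
    ----------
    data : DataFrame
        Training table; the target column must be binary (0/1 or bool).
    target : str
        Name of the target column.
    features : sequence of str, optional
        Columns to induce over; defaults to every non-target column.
        Numeric dtypes get threshold splits, everything else multiway
        categorical splits.
    cost_matrix : CostMatrix, optional
        Leaf-labelling costs; default unit costs (plain majority).
    cf : float
        Confidence level of the pessimistic-pruning error estimate.
    prune : bool
        Apply subtree-replacement pruning after growing.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        target: str = "is_alert",
        features: Sequence[str] | None = None,
        cost_matrix: CostMatrix | None = None,
        cf: float = 0.25,
        prune: bool = True,
    ):
        if target not in data.columns:
            raise ValueError(f"target column {target!r} not in data")
        if len(data) == 0:
            raise ValueError("cannot fit a tree on an empty dataset")
        y = data[target]
        uniques = set(pd.unique(y.dropna()))
        if not uniques <= {0, 1, True, False}:
            raise ValueError("target must be binary (0/1)")
        self.data = data
        self.target = target
        self.features = list(features) if features is not None else [
            c for c in data.columns if c != target
        ]
        self.cost_matrix = cost_matrix or CostMatrix.unit()
        self.cf = float(cf)
        self.prune = bool(prune)

        self._y = y.astype(int).to_numpy()
        self._num: dict[str, np.ndarray] = {}
        self._cat: dict[str, tuple[np.ndarray, list]] = {}
        for col in self.features:
            s = data[col]
            if pd.api.types.is_numeric_dtype(s) and not isinstance(
                s.dtype, pd.CategoricalDtype
            ):
                self._num[col] = s.to_numpy(dtype=float)
            else:
                codes, cats = _encode_categorical(s)
                self._cat[col] = (codes, cats)
        self._feature_order = sorted(self.features)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "DecisionTreeResults":
        idx = np.arange(len(self._y))
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10000))
        try:
            root = self._grow(idx)
            if self.prune:
                self._prune(root)
        finally:
            sys.setrecursionlimit(old_limit)
        _relabel(root, self.cost_matrix)
        return DecisionTreeResults(self, root)

    def _grow(self, idx: np.ndarray) -> _Node:
        y = self._y[idx]
        n1 = int(y.sum())
        node = _Node(len(idx) - n1, n1)
        if n1 == 0 or n1 == len(idx) or len(idx) < 2:
            return node
        cand = self._best_split(idx)
        if cand is None:
            return node
        groups = self._partition(idx, cand)
        if groups is None:
            return node
        child_idx, categories, majority = groups
        node.attr = cand.attr
        node.kind = cand.kind
        node.threshold = cand.threshold
        node.categories = categories
        node.majority_child = majority
        node.children = [self._grow(g) for g in child_idx]
        return node

    def _best_split(self, idx: np.ndarray) -> _SplitCandidate | None:
        n = len(idx)
        y = self._y[idx]
        best: _SplitCandidate | None = None
        for attr in self._feature_order:
            if attr in self._num:
                cand = self._best_numeric(attr, idx, y, n)
            else:
                cand = self._best_categorical(attr, idx, y, n)
            if cand is not None and (best is None or cand.gain_ratio > best.gain_ratio + _TIE):
                best = cand
        return best

    def _best_numeric(self, attr, idx, y, n) -> _SplitCandidate | None:
        v = self._num[attr][idx]
        known = ~np.isnan(v)
        nk = int(known.sum())
        if nk < 2:
            return None
        vv = v[known]
        yy = y[known]
        order = np.argsort(vv, kind="stable")
        vv, yy = vv[order], yy[order]
        bounds = np.nonzero(vv[:-1] < vv[1:])[0]
        if bounds.size == 0:
            return None
        cum1 = np.cumsum(yy)
        total1 = cum1[-1]
        nl = bounds + 1
        nr = nk - nl
        n1l = cum1[bounds]
        n1r = total1 - n1l
        h0 = _binary_entropy(np.array([total1 / nk]))[0]
        hl = _binary_entropy(n1l / nl)
        hr = _binary_entropy(n1r / nr)
        gain = (h0 - (nl * hl + nr * hr) / nk) * (nk / n)
        splitinfo = _binary_entropy(nl / nk)
        valid = gain > _EPS
        if not valid.any():
            return None
        gr = np.where(valid, gain / np.maximum(splitinfo, _EPS), -np.inf)
        i = int(np.argmax(gr))
        return _SplitCandidate(float(gr[i]), attr, "num", float(vv[bounds[i] + 1]))

    def _best_categorical(self, attr, idx, y, n) -> _SplitCandidate | None:
        codes, cats = self._cat[attr]
        c = codes[idx]
        known = c >= 0
        nk = int(known.sum())
        if nk < 2:
            return None
        cc = c[known]
        yy = y[known]
        ncat = len(cats)
        sizes = np.bincount(cc, minlength=ncat)
        ones = np.bincount(cc, weights=yy, minlength=ncat)
        present = sizes > 0
        if present.sum() < 2:
            return None
        sz = sizes[present].astype(float)
        o1 = ones[present]
        h0 = _binary_entropy(np.array([yy.sum() / nk]))[0]
        h_groups = _binary_entropy(o1 / sz)
        gain = (h0 - (sz * h_groups).sum() / nk) * (nk / n)
        if gain <= _EPS:
            return None
        p = sz / nk
        splitinfo = float(-(p * np.log2(p)).sum())
        return _SplitCandidate(float(gain / max(splitinfo, _EPS)), attr, "cat")

    def _partition(self, idx, cand: _SplitCandidate):
        """Split node indices into children; missing -> majority branch."""
        if cand.kind == "num":
            v = self._num[cand.attr][idx]
            known = ~np.isnan(v)
            left = known & (v < cand.threshold)
            right = known & (v >= cand.threshold)
            majority = 0 if left.sum() >= right.sum() else 1
            miss = ~known
            if majority == 0:
                left |= miss
            else:
                right |= miss
            if not left.any() or not right.any():
                return None
            return [idx[left], idx[right]], None, majority
        codes, cats = self._cat[cand.attr]
        c = codes[idx]
        present = sorted(set(int(x) for x in c[c >= 0]))
        if len(present) < 2:
            return None
        groups = [idx[c == code] for code in present]
        majority = int(np.argmax([len(g) for g in groups]))
        miss = idx[c < 0]
        if len(miss):
            groups[majority] = np.concatenate([groups[majority], miss])
        return groups, [cats[code] for code in present], majority

    # -- pruning ----------------------------------------------------------

    def _prune(self, node: _Node) -> float:
        """Bottom-up subtree replacement; returns the pessimistic error
        estimate (count scale) of the possibly pruned subtree."""
        if node.is_leaf:
            return _ucf(min(node.n0, node.n1), node.n, self.cf) * node.n
        subtree_est = sum(self._prune(ch) for ch in node.children if ch.n > 0)
        leaf_est = _ucf(min(node.n0, node.n1), node.n, self.cf) * node.n
        if leaf_est <= subtree_est + 1e-9:
            node.make_leaf()
            return leaf_est
        return subtree_est


def _encode_categorical(s: pd.Series) -> tuple[np.ndarray, list]:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return s.cat.codes.to_numpy().astype(int), list(s.cat.categories)
    cats = sorted({str(v) for v in s.dropna().unique()})
    mapping = {c: i for i, c in enumerate(cats)}
    codes = np.array(
        [mapping.get(str(v), -1) if pd.notna(v) else -1 for v in s], dtype=int
    )
    return codes, cats


def _copy_node(node: _Node) -> _Node:
    new = _Node(node.n0, node.n1)
    new.attr = node.attr
    new.kind = node.kind
    new.threshold = node.threshold
    new.categories = list(node.categories) if node.categories is not None else None
    new.majority_child = node.majority_child
    new.prediction = node.prediction
    new.score = node.score
    if node.children is not None:
        new.children = [_copy_node(c) for c in node.children]
    return new


def _relabel(node: _Node, cost: CostMatrix) -> None:
    node.prediction = 1 if node.n1 * cost.fn > node.n0 * cost.fp else 0
    if not node.is_leaf:
        for ch in node.children:
            _relabel(ch, cost)


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------


class DecisionTreeResults:
    """Fitted tree: predictions, scores, extracted rules, summary."""

    def __init__(self, model: DecisionTreeModel, root: _Node):
        self.model = model
        self.tree_ = root

    # -- structure --------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        def count(nd):
            return 1 if nd.is_leaf else sum(count(c) for c in nd.children)
        return count(self.tree_)

    @property
    def depth(self) -> int:
        def d(nd):
            return 0 if nd.is_leaf else 1 + max(d(c) for c in nd.children)
        return d(self.tree_)

    # -- prediction -------------------------------------------------------

    def predict(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Route records to leaves; returns (labels, alert-fraction scores)."""
        n = len(data)
        labels = np.zeros(n, dtype=int)
        scores = np.zeros(n, dtype=float)
        cols = {}
        for attr in self.model._num:
            if attr in data.columns:
                cols[attr] = data[attr].to_numpy(dtype=float)
        for attr, (_, cats) in self.model._cat.items():
            if attr in data.columns:
                mapping = {c: i for i, c in enumerate(cats)}
                s = data[attr]
                codes = np.array(
                    [mapping.get(v if not isinstance(v, str) else v, -1)
                     if pd.notna(v) else -1
                     for v in (s.astype(object))],
                    dtype=int,
                )
                unknown = int(((codes < 0) & s.notna().to_numpy()).sum())
                if unknown:
                    logger.debug(
                        "predict: %d unseen categories in %r routed via majority branch",
                        unknown, attr,
                    )
                cols[attr] = codes

        def route(node: _Node, idx: np.ndarray):
            if node.is_leaf or len(idx) == 0:
                labels[idx] = node.prediction
                scores[idx] = node.score
                return
            if node.attr not in cols:
                route(node.children[node.majority_child], idx)
                return
            v = cols[node.attr]
            if node.kind == "num":
                vals = v[idx]
                known = ~np.isnan(vals)
                left = known & (vals < node.threshold)
                right = known & (vals >= node.threshold)
                rest = ~known
                parts = [idx[left], idx[right]]
                parts[node.majority_child] = np.concatenate(
                    [parts[node.majority_child], idx[rest]]
                )
                for child, part in zip(node.children, parts):
                    route(child, part)
            else:
                codes = v[idx]
                _, cats = self.model._cat[node.attr]
                cat_to_child = {c: k for k, c in enumerate(node.categories)}
                assigned = np.full(len(idx), -1, dtype=int)
                for code in np.unique(codes):
                    if code >= 0 and cats[code] in cat_to_child:
                        assigned[codes == code] = cat_to_child[cats[code]]
                assigned[assigned < 0] = node.majority_child
                for k, child in enumerate(node.children):
                    route(child, idx[assigned == k])

        route(self.tree_, np.arange(n))
        return labels, scores

    # -- cost relabelling -------------------------------------------------

    def relabel(self, cost_matrix: CostMatrix) -> "DecisionTreeResults":
        """Return a copy whose leaves predict the minimum expected cost."""
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, 10000))
        try:
            new_root = _copy_node(self.tree_)
        finally:
            sys.setrecursionlimit(old_limit)
        _relabel(new_root, cost_matrix)
        return DecisionTreeResults(self.model, new_root)

    # -- rules ------------------------------------------------------------

    def rules(self) -> list[Rule]:
        """One simplified conjunctive rule per leaf (DFS order); applying
        the rule set reproduces the tree's predictions on complete records."""
        out: list[Rule] = []

        def simplify(conds: list[Condition]) -> tuple[Condition, ...]:
            lower: dict[str, float] = {}
            upper: dict[str, float] = {}
            cats: list[Condition] = []
            order: list[str] = []
            for c in conds:
                if c.op == ">=":
                    if c.attr not in lower or c.value > lower[c.attr]:
                        lower[c.attr] = c.value
                elif c.op == "<":
                    if c.attr not in upper or c.value < upper[c.attr]:
                        upper[c.attr] = c.value
                else:
                    if c not in cats:
                        cats.append(c)
                if c.attr not in order:
                    order.append(c.attr)
            final: list[Condition] = []
            for attr in order:
                if attr in lower:
                    final.append(Condition(attr, ">=", lower[attr]))
                if attr in upper:
                    final.append(Condition(attr, "<", upper[attr]))
                final.extend(c for c in cats if c.attr == attr)
            return tuple(final)

        def walk(node: _Node, conds: list[Condition]):
            if node.is_leaf:
                out.append(Rule(simplify(conds), bool(node.prediction)))
                return
            if node.kind == "num":
                walk(node.children[0], conds + [Condition(node.attr, "<", node.threshold)])
                walk(node.children[1], conds + [Condition(node.attr, ">=", node.threshold)])
            else:
                # the majority branch doubles as the default for categories
                # unseen at this node, so its rule uses != conditions; that
                # keeps the rule set total over complete in-vocabulary records
                for k, (cat, child) in enumerate(zip(node.categories, node.children)):
                    if k == node.majority_child:
                        extra = [
                            Condition(node.attr, "!=", other)
                            for other in node.categories
                            if other != cat
                        ]
                    else:
                        extra = [Condition(node.attr, "==", cat)]
                    walk(child, conds + extra)

        walk(self.tree_, [])
        return out

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        y = m._y
        labels, _ = self.predict(m.data)
        tp = int(((labels == 1) & (y == 1)).sum())
        fn = int(((labels == 0) & (y == 1)).sum())
        fp = int(((labels == 1) & (y == 0)).sum())
        tn = int(((labels == 0) & (y == 0)).sum())
        lines = [
            "Decision tree results",
            "=" * 54,
            f"Observations:      {len(y)}",
            f"Alert prevalence:  {y.mean():.3f}",
            f"Features:          {len(m.features)}",
            f"Depth / leaves:    {self.depth} / {self.n_leaves}",
            f"Cost (FN, FP):     ({m.cost_matrix.fn:g}, {m.cost_matrix.fp:g})",
            f"Training confusion [tp fn fp tn]: [{tp} {fn} {fp} {tn}]",
            "-" * 54,
            "Rules:",
        ]
        lines += [f"  {r}" for r in self.rules()]
        return "\n".join(lines)

    # -- serialisation ----------------------------------------------------

    def to_json(self) -> str:
        def encode(node: _Node) -> dict:
            d = {"n0": node.n0, "n1": node.n1, "prediction": node.prediction,
                 "score": node.score}
            if not node.is_leaf:
                d.update(
                    attr=node.attr, kind=node.kind, threshold=node.threshold,
                    categories=node.categories, majority_child=node.majority_child,
                    children=[encode(c) for c in node.children],
                )
            return d

        return json.dumps(
            {
                "schema": "elderwatch-tree/1",
                "target": self.model.target,
                "features": self.model.features,
                "cost_matrix": {"fn": self.model.cost_matrix.fn,
                                "fp": self.model.cost_matrix.fp},
                "root": encode(self.tree_),
            },
            indent=2,
        )


# --------------------------------------------------------------------------
# free-function surface
# --------------------------------------------------------------------------


def train_tree(
    records: pd.DataFrame,
    target: str = "is_alert",
    cost: CostMatrix | None = None,
    features: Sequence[str] | None = None,
    **params,
) -> DecisionTreeResults:
    """Fit a cost-sensitive tree; see :class:`DecisionTreeModel`."""
    return DecisionTreeModel(
        records, target=target, features=features, cost_matrix=cost, **params
    ).fit()


def predict(results: DecisionTreeResults, record: Mapping) -> tuple[int, float]:
    """Classify a single record; returns (class, alert-fraction score)."""
    frame = pd.DataFrame([dict(record)])
    labels, scores = results.predict(frame)
    return int(labels[0]), float(scores[0])


def relabel_leaves(results: DecisionTreeResults, cost: CostMatrix) -> DecisionTreeResults:
    return results.relabel(cost)


def extract_rules(results: DecisionTreeResults) -> list[Rule]:
    return results.rules()
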