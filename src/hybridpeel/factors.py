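"""Explanatory-factor analysis of imputation accuracy (regression trees).

Individual-wise accuracy is explained by the data available to an
individual and its close relatives (grandparents, parents, progeny,
grandprogeny): genotyping counts by array density, sequencing counts and
cumulative coverage per relationship level, the individual's own genotyping
status, and its connectedness to the population (sum of additive
relationship coefficients).  Variant-wise accuracy is explained by MAF,
position, distance to the marker panel, and sequencing depth at the site.

Trees are greedy binary recursive partitions minimizing within-node sums
of squares; a split is kept only when it raises the overall model R^2 by
at least ``min_gain`` (default 0.005).  Consecutive splits on one variable
are reported merged as a multi-way partition.  scikit-learn supplies the
tree growing; this module owns the gain accounting, reporting and
cross-validated prediction of low-accuracy individuals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .core import UNKNOWN, GeneticMap, PanelSet, Pedigree, ReadCounts
from .seq_strategy import BudgetPlan

MIN_GAIN = 0.005
MIN_LEAF = 20
LOW_ACCURACY_THRESHOLD = 0.95
ACCURACY_BANDS = ((0.0, 0.5), (0.5, 0.75), (0.75, 0.85), (0.85, 0.9), (0.9, 0.95))
STATUS_CODE = {"none": 0, "LD": 1, "HD": 2}
RELATION_LEVELS = ("gpar", "par", "prog", "gprog")


# ---------------------------------------------------------------------------
# Connectedness (numerator relationship matrix)
# ---------------------------------------------------------------------------

def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix A by the tabular method.

    A_ij = (A_{j,sire(i)} + A_{j,dam(i)}) / 2 for j < i and
    A_ii = 1 + A_{sire(i),dam(i)} / 2.  float32, O(n^2) memory; desk-scale
    pedigrees (<= ~10k) fit comfortably.
    """
    n = ped.n
    A = np.zeros((n, n), dtype=np.float32)
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        row = np.zeros(i, dtype=np.float32)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        f = 0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + f
    return A


def connectedness(ped: Pedigree, iid: str | None = None,
                  A: np.ndarray | None = None):
    """Sum of relationship coefficients to the rest of the pedigree.

    With ``iid`` given, returns that individual's scalar; otherwise the
    full vector in pedigree order.
    """
    if A is None:
        A = relationship_matrix(ped)
    totals = A.sum(axis=1) - np.diag(A)
    if iid is None:
        return totals.astype(float)
    if iid not in ped.index:
        raise KeyError(f"unknown individual {iid}")
    return float(totals[ped.index[iid]])


# ---------------------------------------------------------------------------
# Factor tables
# ---------------------------------------------------------------------------

def _relative_sets(ped: Pedigree) -> dict[str, list[list[int]]]:
    prog = ped.progeny_of()
    rel = {"par": [ped.parents_of(i) for i in range(ped.n)],
           "gpar": [ped.grandparents_of(i) for i in range(ped.n)],
           "prog": prog,
           "gprog": [[g for p in prog[i] for g in prog[p]] for i in range(ped.n)]}
    return rel


def build_individual_factors(ped: Pedigree, statuses: np.ndarray,
                             plan: BudgetPlan | dict[str, float],
                             population_size: int | None = None,
                             A: np.ndarray | None = None) -> pd.DataFrame:
    """Per-individual factor table: 23 explanatory columns plus id.

    Columns: population size; own genotyping status; 12 genotyped-relative
    counts (4 relationship levels x 3 statuses); 8 sequencing variables
    (count and cumulative coverage per level); connectedness.
    """
    coverage = plan.assignment if isinstance(plan, BudgetPlan) else dict(plan)
    cov = np.array([coverage.get(i, 0.0) for i in ped.ids])
    rel = _relative_sets(ped)
    conn = connectedness(ped, A=A)
    popsize = population_size or ped.n
    rows = []
    for i in range(ped.n):
        row = {"id": ped.ids[i], "popsize": popsize,
               "status": STATUS_CODE[str(statuses[i])]}
        for lvl in RELATION_LEVELS:
            members = rel[lvl][i]
            for st in ("none", "LD", "HD"):
                row[f"n_{lvl}_{st}"] = sum(1 for m in members if statuses[m] == st)
            row[f"n_{lvl}_seq"] = sum(1 for m in members if cov[m] > 0)
            row[f"cov_{lvl}_seq"] = float(sum(cov[m] for m in members))
        row["connectedness"] = conn[i]
        rows.append(row)
    return pd.DataFrame(rows)


def build_variant_factors(gmap: GeneticMap, panels: PanelSet, reads: ReadCounts,
                          freqs: np.ndarray,
                          variant_idx: np.ndarray | None = None,
                          population_size: int | None = None) -> pd.DataFrame:
    """Per-variant factor table: MAF, position, panel distance, read depth."""
    idx = np.arange(gmap.n_variants) if variant_idx is None else np.asarray(variant_idx)
    maf = np.minimum(freqs, 1 - freqs)
    tot = reads.total
    rows = []
    popsize = population_size or reads.ref.shape[0]
    for c in gmap.chromosomes:
        cvars = gmap.chrom_slice(c)
        sel = idx[np.isin(idx, cvars)]
        ppos = gmap.pos_cm[cvars[panels.hd_mask[cvars]]]
        length = gmap.pos_cm[cvars].max()
        for v in sel:
            pos = gmap.pos_cm[v]
            dist = 0.0 if panels.hd_mask[v] else float(np.min(np.abs(ppos - pos)))
            rows.append({"variant": gmap.variant_ids[v], "popsize": popsize,
                         "maf": float(maf[v]), "rel_pos": float(pos / length),
                         "panel_dist": dist,
                         "cum_coverage": int(tot[:, v].sum()),
                         "n_ind_seq": int((tot[:, v] > 0).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regression trees
# ---------------------------------------------------------------------------

@dataclass
class TreeModel:
    """Fitted regression tree with per-split global R^2 gains."""

    estimator: DecisionTreeRegressor
    feature_names: list[str]
    min_gain: float
    total_ss: float
    nodes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    @property
    def first_split_variable(self) -> str | None:
        t = self.estimator.tree_
        if t.node_count <= 1:
            return None
        return self.feature_names[t.feature[0]]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(table[self.feature_names].to_numpy(float))

    def summary(self) -> pd.DataFrame:
        return self.nodes

    def merged_splits(self) -> list[list[str]]:
        """Root-to-leaf split variables with consecutive repeats merged."""
        t = self.estimator.tree_
        paths: list[list[str]] = []

        def walk(node, path):
            if t.children_left[node] == -1:
                merged = [v for k, v in enumerate(path) if k == 0 or v != path[k - 1]]
                paths.append(merged)
                return
            var = self.feature_names[t.feature[node]]
            walk(t.children_left[node], path + [var])
            walk(t.children_right[node], path + [var])

        walk(0, [])
        return paths

    def to_json(self) -> str:
        t = self.estimator.tree_
        def node(k):
            if t.children_left[k] == -1:
                return {"n": int(t.n_node_samples[k]), "mean": float(t.value[k, 0, 0])}
            return {"n": int(t.n_node_samples[k]), "mean": float(t.value[k, 0, 0]),
                    "split": self.feature_names[t.feature[k]],
                    "threshold": float(t.threshold[k]),
                    "left": node(t.children_left[k]),
                    "right": node(t.children_right[k])}
        return json.dumps(node(0), indent=1)


def fit_tree(table: pd.DataFrame, response: np.ndarray | pd.Series,
             min_gain: float = MIN_GAIN, min_leaf: int = MIN_LEAF,
             feature_names: list[str] | None = None) -> TreeModel:
    """Grow a regression tree keeping splits with global R^2 gain >= min_gain.

    The gain of a split is its reduction of the total residual sum of
    squares divided by the total sum of squares of the response, which is
    exactly the increase in overall model R^2; scikit-learn's
    ``min_impurity_decrease`` implements this rule when scaled by the
    response variance.
    """
    y = np.asarray(response, float)
    if len(y) < 20:
        raise ValueError("need at least 20 rows to fit a tree")
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("id", "variant") and table[c].dtype.kind in "ifb"]
    X = table[feature_names].to_numpy(float)
    var = y.var()
    est = DecisionTreeRegressor(
        min_impurity_decrease=min_gain * var,  # var == 0 cannot split anyway
        min_samples_leaf=min_leaf,
        random_state=0,
    )
    est.fit(X, y)
    total_ss = var * len(y)
    t = est.tree_
    rows = []
    n = len(y)
    for k in range(t.node_count):
        leaf = t.children_left[k] == -1
        gain = 0.0
        if not leaf:
            l, r = t.children_left[k], t.children_right[k]
            sse_drop = (t.n_node_samples[k] * t.impurity[k]
                        - t.n_node_samples[l] * t.impurity[l]
                        - t.n_node_samples[r] * t.impurity[r])
            gain = sse_drop / total_ss if total_ss > 0 else 0.0
        rows.append({"node": k, "leaf": leaf,
                     "variable": None if leaf else feature_names[t.feature[k]],
                     "threshold": None if leaf else float(t.threshold[k]),
                     "n": int(t.n_node_samples[k]),
                     "mean": float(t.value[k, 0, 0]),
                     "r2_gain": gain})
    model = TreeModel(est, feature_names, min_gain, total_ss, pd.DataFrame(rows))
    return model


def predict_low_accuracy(tree: TreeModel, table: pd.DataFrame,
                         threshold: float = LOW_ACCURACY_THRESHOLD) -> np.ndarray:
    """Flag rows whose leaf-predicted accuracy falls below the threshold."""
    return tree.predict(table) < threshold


def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


@dataclass
class CVResult:
    sensitivity: float
    specificity: float
    by_band: pd.DataFrame
    confusion: tuple[int, int, int, int]  # tp, fn, tn, fp

    def to_frame(self) -> pd.DataFrame:
        out = {"sensitivity": [self.sensitivity], "specificity": [self.specificity]}
        for row in self.by_band.itertuples(index=False):
            out[f"sens_{row.band}"] = [row.sensitivity]
        return pd.DataFrame(out)


def crossvalidate(table: pd.DataFrame, response: np.ndarray | pd.Series,
                  threshold: float = LOW_ACCURACY_THRESHOLD, k: int = 10,
                  seed: int = 0, min_gain: float = MIN_GAIN,
                  min_leaf: int = MIN_LEAF) -> CVResult:
    """Stratified k-fold cross-validated prediction of low accuracy.

    Per fold a tree is fitted on the training rows and test rows are
    flagged when their predicted accuracy is below the threshold;
    sensitivity is additionally broken down by the observed-accuracy bands.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(response, float)
    label = y < threshold
    flags = np.zeros(len(y), dtype=bool)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    both_classes_fill_folds = label.sum() >= k and (~label).sum() >= k
    strat = label if both_classes_fill_folds else np.zeros(len(y), dtype=int)
    for train, test in skf.split(np.zeros(len(y)), strat):
        tree = fit_tree(table.iloc[train], y[train], min_gain, min_leaf)
        flags[test] = predict_low_accuracy(tree, table.iloc[test], threshold)
    tp = int((flags & label).sum())
    fn = int((~flags & label).sum())
    tn = int((~flags & ~label).sum())
    fp = int((flags & ~label).sum())
    sens, spec = sensitivity_specificity(tp, fn, tn, fp)
    rows = []
    for lo, hi in ACCURACY_BANDS:
        band = (y >= lo) & (y < hi)
        pos = band & label
        rows.append({"band": f"{lo}-{hi}",
                     "n": int(pos.sum()),
                     "sensitivity": (float((flags & pos).sum() / pos.sum())
                                     if pos.sum() else float("nan"))})
    return CVResult(sens, spec, pd.DataFrame(rows), (tp, fn, tn, fp))


def linear_screen(table: pd.DataFrame, response: np.ndarray | pd.Series,
                  feature_names: list[str] | None = None) -> pd.DataFrame:
    """Joint OLS of accuracy on all factors; per-coefficient t-test p-values.

    Rank-deficient (aliased) columns are dropped with a warning.
    """
    y = np.asarray(response, float)
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c not in ("id", "variant") and table[c].dtype.kind in "ifb"]
    if not feature_names:
        raise ValueError("no factor columns to screen")
    X = table[feature_names].to_numpy(float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more rows than factors")
    keep: list[int] = []
    ones = np.ones((len(y), 1))
    for j in range(X.shape[1]):
        trial = np.column_stack([ones, X[:, keep + [j]]])
        if np.linalg.matrix_rank(trial) == len(keep) + 2:
            keep.append(j)
    dropped = [feature_names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropped aliased or constant factor columns: {dropped}",
                      stacklevel=2)
    if not keep:
        raise ValueError("no informative factor columns after aliasing checks")
    names = [feature_names[j] for j in keep]
    model = sm.OLS(y, sm.add_constant(X[:, keep])).fit()
    return pd.DataFrame({"factor": names,
                         "coefficient": model.params[1:],
                         "p_value": model.pvalues[1:]})
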