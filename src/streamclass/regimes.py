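"""Hydrologic and thermal regime class machinery.

The inductive path is: gaged flow signatures are reduced to component scores,
clustered with Ward's minimum-variance agglomeration into a nested family of
class solutions, and extrapolated to every reach with a bagged decision-tree
ensemble whose vote fractions double as class-membership probabilities.
Temperature follows the same template with a reference-site screen (land
disturbance, degree of regulation, record window and length) in front of a
regression forest for mean July-August temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .errors import (
    ConfigError,
    DegenerateInputError,
    ImputationError,
    InsufficientDataError,
)
from .seeds import subseed, substream

# ---------------------------------------------------------------------------
# Chained predictive-mean-matching imputation
# ---------------------------------------------------------------------------

def impute_missing(
    panel: pd.DataFrame,
    columns: list[str] | None = None,
    k_donors: int = 5,
    max_iter: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute missing entries by chained predictive mean matching.

    Each incomplete column is regressed (linearly) on the other columns over
    its observed rows; a missing entry receives the *observed* value of one
    of the ``k_donors`` rows with the closest predicted mean, drawn from the
    seeded stream.  Columns are cycled ``max_iter`` times.  Identity on
    complete data; deterministic given ``seed``.
    """
    out = panel.copy()
    if columns is None:
        columns = [c for c in out.columns
                   if pd.api.types.is_numeric_dtype(out[c])]
    sub = out[columns].astype(float)
    miss = sub.isna()
    if not miss.to_numpy().any():
        return out
    for c in columns:
        frac = miss[c].mean()
        if frac == 1.0:
            raise ImputationError(f"column {c!r} has no observed values")
        if frac >= 0.5:
            raise ImputationError(f"column {c!r} is >= 50% missing")
    rng = substream(seed, "pmm-imputation")
    filled = sub.fillna(sub.mean())
    incomplete = [c for c in columns if miss[c].any()]
    for _ in range(max_iter):
        for c in incomplete:
            others = [o for o in columns if o != c]
            obs = ~miss[c].to_numpy()
            X = filled[others].to_numpy()
            y_obs = sub[c].to_numpy()[obs]
            if others:
                model = LinearRegression().fit(X[obs], y_obs)
                pred = model.predict(X)
            else:
                pred = np.full(len(sub), y_obs.mean())
            pred_obs = pred[obs]
            for i in np.flatnonzero(miss[c].to_numpy()):
                d = np.abs(pred_obs - pred[i])
                donors = np.argsort(d, kind="stable")[: min(k_donors, len(d))]
                pick = donors[int(rng.integers(len(donors)))]
                filled.iloc[i, filled.columns.get_loc(c)] = y_obs[pick]
    out[columns] = filled
    return out


# ---------------------------------------------------------------------------
# Dimension reduction
# ---------------------------------------------------------------------------

def reduce_dimensions(matrix, n_components: int):
    """PCA scores and explained-variance fractions.

    Scores are projections onto orthonormal directions of maximal variance;
    fractions are non-increasing and sum to <= 1.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix must be complete; impute first")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("constant matrix has no principal directions")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Ward clustering with nested cuts
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """One cut of the Ward dendrogram: labels 1..k, plus merge history."""

    k: int
    labels: np.ndarray               # site -> class in 1..k
    linkage_matrix: np.ndarray       # shared scipy linkage (heights in col 2)
    parent_map: dict[int, int] | None = None  # label -> label of coarser cut


def cluster_ward(scores, k_list) -> list[ClusterSolution]:
    """Minimum-variance agglomeration, cut at each k (ascending).

    Cuts of one dendrogram are nested by construction: each solution carries
    a ``parent_map`` into the next-coarser requested cut.  Labels are
    renumbered 1..k in order of first appearance for determinism.
    """
    X = np.asarray(scores, dtype=float)
    k_list = sorted(set(int(k) for k in k_list))
    if k_list and k_list[-1] > len(X):
        raise ValueError(f"k={k_list[-1]} exceeds n={len(X)} sites")
    if k_list and k_list[0] < 1:
        raise ValueError("k must be >= 1")
    Z = linkage(X, method="ward")
    solutions: list[ClusterSolution] = []
    for k in k_list:
        raw = fcluster(Z, t=k, criterion="maxclust")
        labels = _relabel_first_appearance(raw)
        solutions.append(ClusterSolution(k, labels, Z))
    for i in range(1, len(solutions)):
        solutions[i].parent_map = nesting_map(
            solutions[i - 1].labels, solutions[i].labels)
    return solutions


def _relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def nesting_map(coarse_labels, fine_labels) -> dict[int, int] | None:
    """fine label -> coarse label if every fine class sits in one coarse
    class (nesting); None if the solutions are not nested."""
    mapping: dict[int, int] = {}
    for c, f in zip(coarse_labels, fine_labels):
        if f in mapping and mapping[f] != c:
            return None
        mapping[int(f)] = int(c)
    return mapping


def within_cluster_sse(Z: np.ndarray, n: int) -> dict[int, float]:
    """Total within-cluster SSE at every cut k, from Ward merge heights.

    Ward heights satisfy delta-ESS = h^2 / 2; the SSE at k clusters is the
    sum over the first n-k merges.
    """
    inc = Z[:, 2] ** 2 / 2.0
    sse = {n: 0.0}
    running = 0.0
    for i, d in enumerate(inc):
        running += float(d)
        sse[n - (i + 1)] = running
    return sse


def elbow_candidates(sse_by_k: dict[int, float]) -> list[int]:
    """Elbow candidates: local maxima of the second difference of SSE vs k,
    sorted by curvature (largest first).  Linear declines yield none."""
    ks = sorted(sse_by_k)
    d2 = {}
    for k in ks[1:-1]:
        if k - 1 in sse_by_k and k + 1 in sse_by_k:
            d2[k] = sse_by_k[k - 1] - 2.0 * sse_by_k[k] + sse_by_k[k + 1]
    cands = []
    keys = sorted(d2)
    for i, k in enumerate(keys):
        left = d2[keys[i - 1]] if i > 0 else -np.inf
        right = d2[keys[i + 1]] if i < len(keys) - 1 else -np.inf
        if d2[k] > 1e-9 and d2[k] >= left and d2[k] >= right:
            cands.append(k)
    return sorted(cands, key=lambda k: -d2[k])


def select_cluster_counts(Z: np.ndarray, k_max: int, n: int | None = None) -> list[int]:
    """Advisory cluster counts from dendrogram curvature (elbows), largest
    curvature first; the user's k_list remains authoritative."""
    if n is None:
        n = Z.shape[0] + 1
    sse = within_cluster_sse(Z, n)
    return [k for k in elbow_candidates(sse) if 2 <= k <= k_max]


# ---------------------------------------------------------------------------
# Reference-site screening
# ---------------------------------------------------------------------------

SCREEN_COLUMNS = ("disturbance", "dor_percent", "rec_start", "rec_end",
                  "jul_aug_consec_days")


def screen_reference_sites(panel: pd.DataFrame) -> pd.DataFrame:
    """Keep least-disturbed sites with adequate summer records.

    A site is kept iff ALL of: disturbance score "very low" or "low";
    degree of regulation strictly below 4%; record window within
    [1995, 2015] inclusive; at least 60 consecutive July-August days.
    Sites missing any screening attribute are excluded; per-site reasons are
    attached as ``result.attrs["screen_log"]``.
    """
    for col in SCREEN_COLUMNS:
        if col not in panel.columns:
            raise KeyError(f"screening attribute {col!r} absent from panel")
    keep = np.ones(len(panel), dtype=bool)
    reasons: list[tuple[object, str]] = []

    def reject(mask, reason):
        nonlocal keep
        for i in np.flatnonzero(mask.to_numpy() & keep):
            reasons.append((panel.iloc[i].get("site_id", i), reason))
        keep &= ~mask.to_numpy()

    missing = panel[list(SCREEN_COLUMNS)].isna().any(axis=1)
    reject(missing, "missing screening attribute")
    reject(~panel["disturbance"].isin(["very low", "low"]) & ~missing,
           "disturbance above low")
    reject((panel["dor_percent"] >= 4.0) & ~missing, "DOR >= 4%")
    reject(((panel["rec_start"] < 1995) | (panel["rec_end"] > 2015)) & ~missing,
           "record outside 1995-2015")
    reject((panel["jul_aug_consec_days"] < 60) & ~missing,
           "fewer than 60 consecutive July-August days")
    out = panel.loc[keep].copy()
    out.attrs["screen_log"] = pd.DataFrame(reasons, columns=["site_id", "reason"])
    return out


# ---------------------------------------------------------------------------
# Tree-ensemble extrapolation
# ---------------------------------------------------------------------------

@dataclass
class ExtrapolationModel:
    """Bagged classification ensemble with out-of-bag diagnostics."""

    forest: RandomForestClassifier
    feature_names: list[str]
    classes: np.ndarray
    oob_error: float
    importances: pd.Series = field(repr=False)             # raw Gini
    normalized_importances: pd.Series = field(repr=False)  # (x-min)/(max-min)


def fit_class_extrapolator(
    features: pd.DataFrame, labels, seed: int = 0, n_trees: int = 500
) -> ExtrapolationModel:
    """Random-forest class-membership model with OOB misclassification rate.

    Requires at least two classes with >= 5 sites each.  Importances are
    normalized to [0, 1] via (x - min)/(max - min), so the most informative
    feature scores 1.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateInputError("need >= 2 classes to fit an extrapolator")
    if counts.min() < 5:
        small = classes[counts < 5].tolist()
        raise InsufficientDataError(f"classes with < 5 sites: {small}")
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, n_jobs=1,
        random_state=subseed(seed, "class-extrapolator"),
    ).fit(features.to_numpy(float), y)
    imp = pd.Series(forest.feature_importances_, index=list(features.columns))
    return ExtrapolationModel(
        forest=forest,
        feature_names=list(features.columns),
        classes=forest.classes_,
        oob_error=1.0 - float(forest.oob_score_),
        importances=imp,
        normalized_importances=_normalize_importance(imp),
    )


def _normalize_importance(imp: pd.Series) -> pd.Series:
    lo, hi = float(imp.min()), float(imp.max())
    if hi == lo:
        return pd.Series(1.0, index=imp.index)
    return (imp - lo) / (hi - lo)


def predict_class_membership(
    model: ExtrapolationModel, features: pd.DataFrame, comids=None
) -> pd.DataFrame:
    """Per-reach labels and tree-vote-fraction probability vectors.

    Probability of class c = fraction of trees voting c; the label is the
    argmax with ties broken toward the lowest class index.  Rows with any
    missing feature are labeled "unclassified" with NaN probabilities.
    """
    X = features[model.feature_names].to_numpy(float)
    n, k = len(X), len(model.classes)
    complete = ~np.isnan(X).any(axis=1)
    votes = np.zeros((n, k))
    if complete.any():
        Xc = X[complete]
        counts = np.zeros((len(Xc), k))
        for tree in model.forest.estimators_:
            # trees inside the forest predict encoded class positions 0..k-1
            pred = tree.predict(Xc).astype(int)
            for j in range(k):
                counts[:, j] += pred == j
        votes[complete] = counts / len(model.forest.estimators_)
    labels = np.where(
        complete,
        model.classes[np.argmax(votes, axis=1)].astype(object),
        "unclassified",
    )
    out = pd.DataFrame({"comid": comids if comids is not None
                        else np.arange(n), "label": labels})
    for j, c in enumerate(model.classes):
        out[f"prob_{c}"] = np.where(complete, votes[:, j], np.nan)
    out["prob_max"] = np.where(complete, votes.max(axis=1), np.nan)
    return out


def compute_expected_probability(k: int) -> float:
    """Chance probability of the predominant class: 1/k, to two decimals.

    Rounding is half-up (0.125 -> 0.13), the convention of printed tables,
    not banker's rounding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    import math

    return math.floor(100.0 / k + 0.5) / 100.0


# ---------------------------------------------------------------------------
# Temperature regression
# ---------------------------------------------------------------------------

@dataclass
class TemperatureModel:
    """Bagged regression ensemble for mean July-August temperature."""

    forest: RandomForestRegressor
    feature_names: list[str]
    oob_r2: float
    oob_mse: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(features[self.feature_names].to_numpy(float))


def fit_temperature_regressor(
    panel: pd.DataFrame,
    feature_cols: list[str],
    target_col: str = "july_august_temp",
    seed: int = 0,
    n_trees: int = 500,
) -> TemperatureModel:
    """Random-forest regression of summer temperature on reach covariates.

    Discharge per unit area (Qwsa) is explicitly barred from the feature
    list: temperature varies with river size, and a size-standardized flow
    ratio would leak that structure in a way the classification deliberately
    keeps out.
    """
    banned = [c for c in feature_cols if "qwsa" in c.lower()]
    if banned:
        raise ConfigError(f"Qwsa must be excluded from temperature features: {banned}")
    X = panel[feature_cols].to_numpy(float)
    y = panel[target_col].to_numpy(float)
    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, n_jobs=1,
        random_state=subseed(seed, "temperature-regressor"),
    ).fit(X, y)
    oob_pred = forest.oob_prediction_
    return TemperatureModel(
        forest=forest,
        feature_names=list(feature_cols),
        oob_r2=float(forest.oob_score_),
        oob_mse=float(np.mean((oob_pred - y) ** 2)),
    )


# ---------------------------------------------------------------------------
# Probability diagnostics
# ---------------------------------------------------------------------------

def summarize_assignment_probabilities(assignments: list[dict]) -> pd.DataFrame:
    """Per-solution diagnostics table.

    Each entry carries: ``solution`` (name), ``k``, ``n_obs``, ``oob_error``
    (fraction), and ``assignment`` (frame with a ``prob_max`` column).
    Output columns mirror the validation bookkeeping: OOB error %, accuracy
    % (their exact complement), median predominant probability, and the 1/k
    chance expectation.
    """
    rows = []
    for entry in assignments:
        probs = entry["assignment"]["prob_max"].dropna()
        oob_pct = 100.0 * entry["oob_error"]
        rows.append({
            "solution": entry["solution"],
            "k": entry["k"],
            "n_obs": entry["n_obs"],
            "oob_error_pct": oob_pct,
            "accuracy_pct": 100.0 - oob_pct,
            "median_prob": float(probs.median()) if len(probs) else np.nan,
            "expected_prob": compute_expected_probability(entry["k"]),
        })
    return pd.DataFrame(rows)
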