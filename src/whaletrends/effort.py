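"""Observation-effort reconstruction and false-zero removal.

Legacy daily count records store a value only when whales were detected,
so a blank day is ambiguous: a true zero (survey happened, no whales) or
a no-effort day (weather prevented the survey).  Years with recorded
effort metadata are used to learn a weather -> effort classification tree;
its predicted effort probability, dichotomised at an optimal cutoff, then
labels the ambiguous days, and blank-or-zero days classified as no-effort
are removed as false zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score
from sklearn.tree import DecisionTreeClassifier, export_text

WEATHER_VARS = [
    "cloud_cover",
    "visibility_km",
    "pressure_mb",
    "air_temp_c",
    "precip_in",
    "wind_dir_deg",
    "wind_speed_kn",
    "swell_height_ft",
    "swell_dir_deg",
]

MILES_TO_KM = 1.609344
FEET_TO_M = 0.3048


@dataclass
class EffortClassifier:
    """A fitted effort tree plus the probability cutoff used to dichotomise it."""

    tree: DecisionTreeClassifier
    features: list[str]
    medians: pd.Series  # per-variable imputation values from the training data
    cutoff: float | None = None

    def summary(self) -> str:
        return export_text(self.tree, feature_names=self.features)


def rule_based_effort(weather: pd.DataFrame) -> pd.Series:
    """Protocol effort rule: visibility > 11.2 km, wind <= Beaufort 4, swell < 3 m.

    Beaufort 4 tops out near 16 knots.  This labeller exists for sanity
    checks against the learned tree, not for the pipeline itself.
    """
    beaufort4_max_kn = 16.0
    return (
        (weather["visibility_km"] > 11.2)
        & (weather["wind_speed_kn"] <= beaufort4_max_kn)
        & (weather["swell_height_ft"] * FEET_TO_M < 3.0)
    ).astype(int)


def _prepare(
    weather: pd.DataFrame, features: list[str], medians: pd.Series | None
) -> tuple[pd.DataFrame, pd.Series]:
    X = weather[features].copy()
    if medians is None:
        medians = X.median()
    n_imputed = int(X.isna().sum().sum())
    if n_imputed:
        warnings.warn(f"median-imputed {n_imputed} missing weather values", stacklevel=3)
        X = X.fillna(medians)
    return X, medians


def fit_cart(
    weather: pd.DataFrame,
    effort: np.ndarray | pd.Series,
    features: list[str] | None = None,
    max_depth: int = 5,
    min_leaf: int = 5,
    prune: bool = True,
    cv: int = 10,
    random_state: int = 0,
) -> EffortClassifier:
    """Fit a Gini classification tree of effort (0/1) on weather.

    Leaves carry the fraction of effort days routed to them.  With
    ``prune`` the cost-complexity parameter is chosen by ``cv``-fold
    cross-validated accuracy over the pruning path.  A single-class
    training set yields a degenerate one-leaf tree with a warning.
    """
    features = features or [v for v in WEATHER_VARS if v in weather.columns]
    y = np.asarray(effort, dtype=int)
    X, medians = _prepare(weather, features, None)
    classes = np.unique(y)
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf, random_state=random_state
    )
    if len(classes) < 2:
        warnings.warn("single-class effort labels: degenerate one-leaf tree", stacklevel=2)
        tree.fit(X, y)
        return EffortClassifier(tree=tree, features=features, medians=medians)
    # n < 2*min_leaf cannot split and yields a single prevalence leaf
    tree.fit(X, y)
    if prune and tree.get_n_leaves() > 1:
        path = tree.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) > 8:  # quantile-spaced subset keeps the search cheap
            alphas = np.unique(np.quantile(alphas, np.linspace(0, 1, 8)))
        if len(alphas) > 1:
            n_splits = min(cv, int(np.min(np.bincount(y))))
            if n_splits >= 2:
                scores = []
                for a in alphas:
                    cand = DecisionTreeClassifier(
                        criterion="gini",
                        max_depth=max_depth,
                        min_samples_leaf=min_leaf,
                        ccp_alpha=float(a),
                        random_state=random_state,
                    )
                    scores.append(cross_val_score(cand, X, y, cv=n_splits).mean())
                best = alphas[int(np.argmax(scores))]  # argmax -> smallest alpha on ties
                tree = DecisionTreeClassifier(
                    criterion="gini",
                    max_depth=max_depth,
                    min_samples_leaf=min_leaf,
                    ccp_alpha=float(best),
                    random_state=random_state,
                ).fit(X, y)
    return EffortClassifier(tree=tree, features=features, medians=medians)


def predict_effort(classifier: EffortClassifier, weather: pd.DataFrame) -> np.ndarray:
    """Per-day effort probability: the effort fraction of the leaf each day lands in."""
    missing = [f for f in classifier.features if f not in weather.columns]
    if missing:
        raise ValueError(f"weather table lacks predictor(s): {missing}")
    X, _ = _prepare(weather, classifier.features, classifier.medians)
    proba = classifier.tree.predict_proba(X)
    if proba.shape[1] == 1:  # degenerate single-class tree
        return np.full(len(X), float(classifier.tree.classes_[0]))
    return proba[:, list(classifier.tree.classes_).index(1)]


def _accuracy(probs: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    return float(np.mean((probs >= threshold).astype(int) == labels))


def optimal_cutoff(
    probabilities: np.ndarray, labels: np.ndarray, criterion: str = "accuracy"
) -> float:
    """Probability threshold that best dichotomises predicted effort.

    Candidates are 0, the midpoints of sorted unique probabilities, and a
    value just above the maximum; days with probability >= cutoff are
    classified as effort.  Ties favour the lower threshold (classify as
    effort).  ``criterion`` is overall accuracy by default; ``"youden"``
    maximises sensitivity + specificity - 1 instead.
    """
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("optimal_cutoff needs both effort classes present")
    uniq = np.unique(probs)
    candidates = [0.0] + list((uniq[:-1] + uniq[1:]) / 2.0)
    top = np.nextafter(uniq[-1], np.inf)
    if top <= 1.0:
        candidates.append(float(top))
    if criterion == "accuracy":
        score = [_accuracy(probs, labels, t) for t in candidates]
    elif criterion == "youden":
        score = []
        for t in candidates:
            pred = (probs >= t).astype(int)
            sens = np.mean(pred[labels == 1] == 1)
            spec = np.mean(pred[labels == 0] == 0)
            score.append(sens + spec - 1.0)
    else:
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    return float(candidates[int(np.argmax(score))])  # argmax takes first (lowest) on ties


def remove_false_zeros(
    daily: pd.DataFrame, predicted_effort: np.ndarray | pd.Series, count_col: str = "count"
) -> pd.DataFrame:
    """Drop days with zero-or-missing count classified as no-effort.

    ``predicted_effort`` is the 0/1 class per row of ``daily``.  Days with
    a positive count are always retained — a sighting implies effort.
    Retained blank days become recorded zeros (one effort day each).
    """
    pred = np.asarray(predicted_effort, dtype=int)
    counts = daily[count_col].to_numpy(dtype=float)
    zeroish = np.isnan(counts) | (counts == 0)
    keep = ~(zeroish & (pred == 0))
    out = daily.loc[keep].copy()
    out[count_col] = out[count_col].fillna(0.0)
    for extra in ("count_am", "count_pm"):
        # backfill zeros only for survey protocols that record pairs at all
        if extra in out.columns and out[extra].notna().any():
            out[extra] = out[extra].fillna(0.0)
    return out.reset_index(drop=True)


def filter_sightings(
    censored: pd.DataFrame,
    weather: pd.DataFrame,
    max_depth: int = 5,
    min_leaf: int = 5,
    cutoff_criterion: str = "accuracy",
    effort_labels: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end effort filter over a censored sighting table.

    Trains the tree on days flagged ``effort_known`` (label: count
    recorded vs blank, or an explicit ``effort_labels`` table with date +
    effort), picks the optimal cutoff, classifies every day, and removes
    false zeros per species.  Returns the filtered table and a report
    with the cutoff, confusion matrix on labelled days and tree summary.
    """
    censored = censored.copy()
    censored["date"] = pd.to_datetime(censored["date"])
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])

    if effort_labels is not None:
        lab = effort_labels.copy()
        lab["date"] = pd.to_datetime(lab["date"])
        labelled = weather.merge(lab[["date", "effort"]], on="date", how="inner")
    else:
        known = censored[censored["effort_known"]]
        per_day = (
            known.groupby("date")["count"].apply(lambda s: int(s.notna().any())).rename("effort")
        )
        labelled = weather.merge(per_day.reset_index(), on="date", how="inner")

    clf = fit_cart(labelled, labelled["effort"], max_depth=max_depth, min_leaf=min_leaf)
    probs_lab = predict_effort(clf, labelled)
    clf.cutoff = optimal_cutoff(probs_lab, labelled["effort"].to_numpy(), cutoff_criterion)

    prob_all = pd.Series(predict_effort(clf, weather), index=weather["date"])
    pred_class = (prob_all >= clf.cutoff).astype(int)
    # where effort metadata is recorded the label is authoritative; the
    # classifier only resolves the legacy (unlabelled) period
    known_class = labelled.set_index("date")["effort"]

    pieces = []
    for _, grp in censored.groupby("species", sort=False):
        pred = grp["date"].map(pred_class).fillna(1).astype(int)
        known = grp["date"].map(known_class)
        pred = known.fillna(pred).astype(int).to_numpy()
        pieces.append(remove_false_zeros(grp, pred))
    filtered = pd.concat(pieces, ignore_index=True)

    pred_lab = (probs_lab >= clf.cutoff).astype(int)
    y_lab = labelled["effort"].to_numpy()
    report = {
        "cutoff": clf.cutoff,
        "n_labelled_days": int(len(labelled)),
        "confusion": {
            "tn": int(np.sum((pred_lab == 0) & (y_lab == 0))),
            "fp": int(np.sum((pred_lab == 1) & (y_lab == 0))),
            "fn": int(np.sum((pred_lab == 0) & (y_lab == 1))),
            "tp": int(np.sum((pred_lab == 1) & (y_lab == 1))),
        },
        "accuracy": _accuracy(probs_lab, y_lab, clf.cutoff),
        "accuracy_at_half": _accuracy(probs_lab, y_lab, 0.5),
        "n_removed": int(len(censored) - len(filtered)),
        "tree": clf.summary(),
    }
    return filtered, report
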