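"""Random-forest uplift suitability modelling and mapping.

Soaring-event centroids are presences, high-altitude flapping bursts
absences.  Under each modelling framework (static terrain/land-cover
predictors, dynamic thermal/orographic uplift potentials, or both) a forest
of regression trees is fit on the binary response, ten times on random 90/10
splits; held-out ROC AUC, and sensitivity/specificity at the threshold
maximizing the true skill statistic (TSS = sensitivity + specificity - 1),
summarize skill.  The map prediction averages the ten forests per cell,
masks cells whose predictor values fall outside the training ranges
(forests extrapolate poorly), and binarizes at the max-TSS threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

from .grid import Raster
from .terrain import PredictorStack
from .synthetic import LAND_USE_NAMES

log = logging.getLogger(__name__)

STATIC_PREDICTORS = ["dem", "slope", "aspect", "roughness", "tpi",
                     "slope_unevenness", "aspect_unevenness", "ndvi",
                     "land_use", "urban_footprint"]
DYNAMIC_PREDICTORS = ["thermal_uplift", "orographic_uplift"]

FRAMEWORKS = {
    "static": STATIC_PREDICTORS,
    "dynamic": DYNAMIC_PREDICTORS,
    "combined": STATIC_PREDICTORS + DYNAMIC_PREDICTORS,
}


class DataError(ValueError):
    pass


class MetricError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class RfEnsemble:
    """Ten cross-validated forests with their metrics and importances."""

    framework: str
    models: list
    feature_names: list[str]
    predictors: list[str]
    metrics: pd.DataFrame            # one row per run
    importances: pd.DataFrame        # mean accuracy decrease / purity increase
    threshold: float                 # mean of the per-run max-TSS thresholds
    seed: int


@dataclass
class SuitabilityMap:
    """Ensemble-mean probability raster with TSS-binarized classification."""

    probability: Raster
    binary: Raster                   # 1 suitable, 0 unsuitable, NaN unclassified
    mask: np.ndarray                 # True where unclassified
    threshold: float


def confusion_metrics(labels, scores, threshold) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) of ``scores >= threshold``."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise MetricError("both classes required to evaluate the confusion matrix")
    pred = s >= threshold
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return sens, spec, sens + spec - 1.0


def max_tss_threshold(labels, scores) -> float:
    """Probability cut maximizing TSS over the grid of observed scores.

    Ties are broken toward the larger threshold.  A maximum TSS of zero
    (no skill at any cut) is logged.
    """
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise MetricError("both classes required for a TSS threshold")
    cuts = np.unique(s)
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    # for each cut: sens = P(s >= cut | y=1), spec = P(s < cut | y=0)
    sens = 1.0 - np.searchsorted(np.sort(s[y == 1]), cuts, side="left") / n1
    spec = np.searchsorted(np.sort(s[y == 0]), cuts, side="left") / n0
    tss = sens + spec - 1.0
    best = tss.max()
    winners = cuts[tss >= best - 1e-12]
    if best <= 0:
        log.info("max_tss_threshold: no cut achieves positive TSS")
    return float(winners.max())


def assemble_observations(events: pd.DataFrame, flaps: pd.DataFrame,
                          stack: PredictorStack, framework: str = "static",
                          ) -> pd.DataFrame:
    """Presence/absence observations annotated with framework predictors.

    Presences come from soaring-event centroids, absences from flapping
    bursts; observations with any missing predictor are dropped (count
    logged) and the per-layer training value ranges are recorded on the
    stack for later out-of-range masking.
    """
    if framework not in FRAMEWORKS:
        raise ConfigurationError(f"unknown framework {framework!r}")
    names = FRAMEWORKS[framework]
    missing_layers = [n for n in names if n not in stack.layers]
    if missing_layers:
        raise ConfigurationError(f"stack lacks layers: {missing_layers}")

    pres = events[["individual_id", "x", "y"]].copy()
    pres["timestamp"] = events["t_start"].to_numpy()
    pres["presence"] = 1
    ab = flaps[["individual_id", "x", "y", "timestamp", "presence"]].copy()
    obs = pd.concat([pres, ab], ignore_index=True)
    vals = stack.extract(obs["x"].to_numpy(float), obs["y"].to_numpy(float), names)
    obs = pd.concat([obs.reset_index(drop=True), vals], axis=1)
    n0 = len(obs)
    obs = obs.dropna(subset=names).reset_index(drop=True)
    if n0 - len(obs):
        log.info("assemble_observations: dropped %d observations with "
                 "missing predictors", n0 - len(obs))
    if (obs["presence"] == 1).sum() == 0 or (obs["presence"] == 0).sum() == 0:
        raise DataError("need both presences and absences after filtering")

    ranges = {n: (float(obs[n].min()), float(obs[n].max()))
              for n in names if n not in stack.categorical}
    stack.training_ranges = (stack.training_ranges or {})
    stack.training_ranges.update(ranges)
    stack.training_categories = (stack.training_categories or {})
    for n in names:
        if n in stack.categorical:
            stack.training_categories[n] = set(obs[n].astype(int).unique())
    return obs


def _design(obs: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """One-hot land use; everything else numeric."""
    X = obs[predictors].copy()
    if "land_use" in X.columns:
        codes = X.pop("land_use").astype(int)
        for code, name in sorted(LAND_USE_NAMES.items()):
            X[f"land_use_{name}"] = (codes == code).astype(float)
    return X.astype(float)


def fit_rf_cv(obs: pd.DataFrame, framework: str = "static", seed: int = 1,
              n_runs: int = 10, test_frac: float = 0.10,
              prevalence: float | None = None, n_trees: int = 500,
              importance_repeats: int = 5) -> RfEnsemble:
    """Ten 90/10 cross-validated random forests on the 0/1 response.

    Forest predictions are probabilities (regression trees on the binary
    response).  If ``prevalence`` (presences per absence) is given, presences
    are resampled to that ratio before splitting.  Per run the held-out AUC,
    the max-TSS threshold and sensitivity/specificity/TSS at it are
    recorded; variable importances (permutation increase in MSE on the
    training split, impurity-based node-purity increase) are averaged
    across runs.
    """
    if framework not in FRAMEWORKS:
        raise ConfigurationError(f"unknown framework {framework!r}")
    predictors = [p for p in FRAMEWORKS[framework] if p in obs.columns]
    if len(obs) < 100:
        raise DataError("need at least 100 observations")
    X_all = _design(obs, predictors)
    y_all = obs["presence"].to_numpy(int)
    if y_all.min() == y_all.max():
        raise DataError("need both classes")

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_runs)]
    models, rows = [], []
    imp_acc = np.zeros(X_all.shape[1])
    imp_pur = np.zeros(X_all.shape[1])
    for r, rs in enumerate(run_seeds):
        rng = np.random.default_rng(rs)
        X, y = X_all, y_all
        if prevalence is not None:
            pres_idx = np.flatnonzero(y_all == 1)
            abs_idx = np.flatnonzero(y_all == 0)
            n_pres = min(len(pres_idx), int(round(prevalence * len(abs_idx))))
            keep = np.concatenate([rng.choice(pres_idx, n_pres, replace=False),
                                   abs_idx])
            X, y = X_all.iloc[keep], y_all[keep]
        n_test = max(int(round(test_frac * len(y))), 2)
        for attempt in range(20):
            perm = rng.permutation(len(y))
            test, train = perm[:n_test], perm[n_test:]
            if len(np.unique(y[test])) == 2 and len(np.unique(y[train])) == 2:
                break
            log.info("fit_rf_cv: run %d resplit (single-class partition)", r)
        else:
            raise DataError("could not find a split with both classes in test")
        rf = RandomForestRegressor(n_estimators=n_trees, max_features="sqrt",
                                   random_state=rs, n_jobs=1)
        rf.fit(X.iloc[train], y[train])
        s_train = rf.predict(X.iloc[train])
        s_test = rf.predict(X.iloc[test])
        thr = max_tss_threshold(y[test], s_test)
        sens, spec, tss = confusion_metrics(y[test], s_test, thr)
        rows.append({
            "run": r, "auc_train": roc_auc_score(y[train], s_train),
            "auc_test": roc_auc_score(y[test], s_test),
            "threshold": thr, "sensitivity": sens, "specificity": spec,
            "tss": tss, "n_train": len(train), "n_test": len(test),
        })
        # paper's "decrease in accuracy (increase in mean standard error)":
        # permutation increase in MSE, on the training split (the held-out
        # 10% is far too small for a stable permutation estimate)
        pi = permutation_importance(rf, X.iloc[train], y[train],
                                    scoring="neg_mean_squared_error",
                                    n_repeats=importance_repeats,
                                    random_state=rs, n_jobs=1)
        imp_acc += pi.importances_mean
        imp_pur += rf.feature_importances_
        models.append(rf)

    metrics = pd.DataFrame(rows)
    importances = pd.DataFrame({
        "feature": list(X_all.columns),
        "accuracy_decrease": imp_acc / n_runs,
        "node_purity_increase": imp_pur / n_runs,
    }).sort_values("accuracy_decrease", ascending=False).reset_index(drop=True)
    return RfEnsemble(framework=framework, models=models,
                      feature_names=list(X_all.columns), predictors=predictors,
                      metrics=metrics, importances=importances,
                      threshold=float(metrics["threshold"].mean()), seed=seed)


def predict_map(ensemble: RfEnsemble, stack: PredictorStack) -> SuitabilityMap:
    """Range-masked, TSS-binarized ensemble suitability map.

    Cells with any predictor missing, outside its training range, or (for
    land use) of a class absent from training are unclassified; elsewhere
    the probability is the mean of the ten forests and the binary layer is
    ``probability >= ensemble.threshold``.
    """
    missing = [p for p in ensemble.predictors if p not in stack.layers]
    if missing:
        raise ConfigurationError(f"stack lacks predictor layers: {missing}")
    if not stack.training_ranges:
        raise ConfigurationError("stack has no training ranges; assemble "
                                 "observations before predicting")
    grid = stack.grid
    nr, nc = grid.shape
    cols = {p: stack.layers[p].data.ravel().astype(float)
            for p in ensemble.predictors}
    tab = pd.DataFrame(cols)
    mask = tab.isna().any(axis=1).to_numpy()
    for p in ensemble.predictors:
        if p in stack.categorical:
            seen = (stack.training_categories or {}).get(p)
            if seen is not None:
                mask |= ~tab[p].isin(list(seen)).to_numpy()
            continue
        lo, hi = stack.training_ranges[p]
        v = tab[p].to_numpy()
        with np.errstate(invalid="ignore"):
            mask |= (v < lo) | (v > hi)
    X = _design(tab.fillna(0.0), ensemble.predictors)
    X = X[ensemble.feature_names]
    prob = np.zeros(len(X))
    for rf in ensemble.models:
        prob += rf.predict(X)
    prob = np.clip(prob / len(ensemble.models), 0.0, 1.0)
    prob[mask] = np.nan
    binary = np.where(prob >= ensemble.threshold, 1.0, 0.0)
    binary[mask] = np.nan
    return SuitabilityMap(
        probability=grid.like(prob.reshape(nr, nc), "suitability_probability"),
        binary=grid.like(binary.reshape(nr, nc), "suitability_binary"),
        mask=mask.reshape(nr, nc), threshold=ensemble.threshold)
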