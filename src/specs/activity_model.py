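"""Promoter-activity estimation from binned counts.

Two estimators are provided. The activity score is the weighted-average
heuristic

    A_i = sum_b ybar_b * n_ib / sum_b n_ib

where ybar_b is the mean fluorescence of sorting bin b and n_ib the log2
normalized count of promoter i in that bin; it is bounded by the extreme bin
means and is used to pick calibration promoters spanning the activity range.
The predictive model is a generalized linear model with elastic-net
regularization over engineered count features (per-bin and total log2
counts, bin proportions, adjacent-bin log-ratios, argmax bin) plus all
first-degree pairwise interaction products, trained on log2 median
fluorescence of calibrated promoters with a 60/40 train/test split and
five-times 5-fold repeated cross-validation for hyperparameter selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import RepeatedKFold

from .ngs_preprocess import PSEUDOCOUNT, CountMatrix
from .screen_simulator import BIN_NAMES, BinScheme

# Hyperparameter grid: elastic-net mixing alpha (l1_ratio) and penalty
# strength lambda, selected by mean CV RMSE (plain minimum, no 1-SE rule).
L1_RATIO_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
LAMBDA_GRID = tuple(np.logspace(-4, 1, 13))


class ActivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Activity score (weighted-average heuristic)
# ---------------------------------------------------------------------------

def activity_score(log2_counts: Sequence[float], bins: BinScheme) -> float:
    """Weighted-average activity: sum_b ybar_b n_b / sum_b n_b.

    ``log2_counts`` are the log2 normalized counts per bin, in bin order.
    All-zero profiles have no defined score and raise.
    """
    n = np.asarray(log2_counts, dtype=float)
    if n.shape != (5,):
        raise ActivityError(f"expected 5 per-bin values, got shape {n.shape}")
    total = n.sum()
    if total <= 0:
        raise ActivityError("all-zero count profile: activity score undefined")
    return float(np.dot(bins.means, n) / total)


def activity_scores(counts: CountMatrix, bins: dict[str, BinScheme]) -> pd.DataFrame:
    """Per-construct, per-state activity scores from a normalized CountMatrix.

    Normalized counts are averaged over replicates per bin and transformed
    as log2(1 + count). Constructs whose profile is all-zero in a state are
    flagged NaN rather than scored.
    """
    out = {}
    for state in counts.states:
        table = counts.mean_normalized_by_bin(state)
        n = np.log2(PSEUDOCOUNT + table.to_numpy())
        totals = n.sum(axis=1)
        ybar = bins[state].means
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = (n @ ybar) / totals
        scores[totals <= 0] = np.nan
        out[state] = pd.Series(scores, index=table.index)
    df = pd.DataFrame(out)
    df.index.name = "construct_id"
    return df


def median_fluorescence(events: pd.Series | np.ndarray,
                        gate: tuple[float, float] | None = None) -> float:
    """log2 of the median of gated per-cell fluorescence values."""
    values = np.asarray(events, dtype=float)
    if gate is not None:
        lo, hi = gate
        values = values[(values >= lo) & (values < hi)]
    if values.size == 0:
        raise ActivityError("no events inside the gate")
    med = float(np.median(values))
    if med <= 0:
        raise ActivityError("non-positive median fluorescence; cannot log-transform")
    return float(np.log2(med))


def calibration_targets(events: pd.DataFrame,
                        gate: tuple[float, float] | None = None) -> pd.DataFrame:
    """log2 median fluorescence per (construct, state) from an event table."""
    for col in ("construct_id", "state", "fluorescence"):
        if col not in events.columns:
            raise ActivityError(f"event table lacks column {col!r}")
    rows = events.groupby(["construct_id", "state"])["fluorescence"].apply(
        lambda v: median_fluorescence(v, gate))
    return rows.rename("log2_median_fluorescence").reset_index()


def choose_calibration(scores: pd.DataFrame, n: int = 81) -> list[str]:
    """Pick calibration promoters spanning the activity-score range.

    Constructs are ranked by their mean score across states (NaNs excluded)
    and ``n`` are taken at evenly spaced ranks, mirroring selection of
    promoters with a broad spectrum of activities. Deterministic.
    """
    mean_scores = scores.mean(axis=1).dropna().sort_values(kind="mergesort")
    if len(mean_scores) < n:
        raise ActivityError(f"only {len(mean_scores)} scoreable constructs < n={n}")
    idx = np.unique(np.round(np.linspace(0, len(mean_scores) - 1, n)).astype(int))
    picked = list(mean_scores.index[idx])
    # pad deterministically if rounding collapsed any ranks
    for cid in mean_scores.index:
        if len(picked) >= n:
            break
        if cid not in picked:
            picked.append(cid)
    return sorted(picked)


# ---------------------------------------------------------------------------
# Feature engineering
# ---------------------------------------------------------------------------

def base_feature_names(bins: Sequence[str] = BIN_NAMES) -> list[str]:
    names = [f"log2_count_{b}" for b in bins]
    names.append("log2_total")
    names += [f"prop_{b}" for b in bins]
    names += [f"log2_ratio_{b2}_{b1}" for b1, b2 in zip(bins[:-1], bins[1:])]
    names.append("argmax_bin")
    return names


def feature_names(bins: Sequence[str] = BIN_NAMES) -> list[str]:
    base = base_feature_names(bins)
    return base + [f"{a}*{b}" for a, b in combinations(base, 2)]


def build_features(counts: CountMatrix) -> pd.DataFrame:
    """Engineer the count features, indexed by (construct_id, state).

    Base features per construct per state (normalized counts averaged over
    replicates, pseudocount of 1 before logs and ratios): five per-bin log2
    counts, log2 total, five bin proportions, four adjacent-bin log2 ratios,
    and the index of the maximal-count bin. All pairwise products of the
    base features are appended as first-degree interaction terms.
    """
    bins = counts.bins
    if list(bins) != list(BIN_NAMES):
        missing = set(BIN_NAMES) - set(bins)
        if missing:
            raise ActivityError(f"missing bin column(s): {sorted(missing)}")
    frames = []
    for state in counts.states:
        table = counts.mean_normalized_by_bin(state)
        c = table.to_numpy(dtype=float)
        logc = np.log2(PSEUDOCOUNT + c)
        total = c.sum(axis=1)
        log_total = np.log2(PSEUDOCOUNT + total)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = c / total[:, None]
        props = np.nan_to_num(props, nan=0.0)
        ratios = logc[:, 1:] - logc[:, :-1]
        argmax = np.argmax(c, axis=1).astype(float)
        base = np.column_stack([logc, log_total, props, ratios, argmax])
        p = base.shape[1]
        inter = np.column_stack([base[:, i] * base[:, j]
                                 for i, j in combinations(range(p), 2)])
        X = np.column_stack([base, inter])
        idx = pd.MultiIndex.from_product([table.index, [state]],
                                         names=["construct_id", "state"])
        frames.append(pd.DataFrame(X, index=idx, columns=feature_names(BIN_NAMES)))
    out = pd.concat(frames).sort_index()
    if not np.isfinite(out.to_numpy()).all():
        raise ActivityError("non-finite feature values")
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ActivityModel:
    """A fitted elastic-net predictor of log2 median fluorescence.

    Prediction is affine in the standardized features:
    ``yhat = (x - mean) / scale @ coef + intercept``. The CV record holds the
    per-fold RMSE of the selected hyperparameters and the held-out test-set
    performance, including an unregularized linear baseline.
    """

    family: str
    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    l1_ratio: float
    lambda_: float
    cv_record: dict = field(default_factory=dict)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.coef + self.intercept

    def predict(self, features: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ActivityError(f"feature schema mismatch; missing: {missing[:5]}")
        X = features[self.feature_names].to_numpy(dtype=float)
        return pd.Series(self.predict_matrix(X), index=features.index,
                         name="predicted_log2_fluorescence")

    # ---- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "family": self.family,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "l1_ratio": self.l1_ratio,
            "lambda": self.lambda_,
            "cv_record": self.cv_record,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ActivityError("unsupported model archive version")
        return cls(
            family=payload["family"],
            feature_names=payload["feature_names"],
            coef=np.array(payload["coef"]),
            intercept=payload["intercept"],
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_scale=np.array(payload["scaler_scale"]),
            l1_ratio=payload["l1_ratio"],
            lambda_=payload["lambda"],
            cv_record=payload["cv_record"],
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant features carry no information
    return (X - mean) / scale, mean, scale


def _fit_enet(Z: np.ndarray, y: np.ndarray, l1_ratio: float,
              lam: float) -> ElasticNet:
    # l1_ratio=0 is pure ridge; sklearn warns but fits it correctly enough
    # for grid comparison purposes.
    est = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=10_000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est.fit(Z, y)
    return est


def train_model(
    features: pd.DataFrame,
    calibration: pd.DataFrame,
    test_fraction: float = 0.4,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    l1_ratio_grid: Sequence[float] = L1_RATIO_GRID,
    lambda_grid: Sequence[float] = LAMBDA_GRID,
) -> tuple[ActivityModel, dict]:
    """Train the elastic-net activity predictor on calibrated promoters.

    ``calibration`` holds (construct_id, state, log2_median_fluorescence).
    Promoters (not rows) are split 60/40 into train/test so both states of a
    promoter land on the same side. Hyperparameters are picked by mean RMSE
    over five-times 5-fold repeated CV on the training split, the model is
    refit on the whole training split, and the report carries R2/RMSE on the
    untouched test split plus an unregularized linear baseline.
    """
    cal = calibration.set_index(["construct_id", "state"])
    target = cal["log2_median_fluorescence"]
    missing = target.index.difference(features.index)
    if len(missing):
        raise ActivityError(f"no features for calibration rows: {list(missing)[:5]}")
    constructs = sorted(set(target.index.get_level_values("construct_id")))
    if len(constructs) < 20:
        raise ActivityError(f"need >= 20 calibration constructs, got {len(constructs)}")
    if len(constructs) * (1 - test_fraction) < n_folds:
        raise ActivityError("fewer training constructs than CV folds")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(constructs))
    n_test = int(round(len(constructs) * test_fraction))
    test_ids = {constructs[i] for i in perm[:n_test]}
    train_ids = [c for c in constructs if c not in test_ids]

    def rows_for(ids):
        mask = target.index.get_level_values("construct_id").isin(ids)
        sub = target[mask]
        X = features.loc[sub.index].to_numpy(dtype=float)
        return X, sub.to_numpy(dtype=float), sub.index

    X_train, y_train, _ = rows_for(train_ids)
    X_test, y_test, _ = rows_for(test_ids)

    # hyperparameter selection: repeated k-fold on the training rows
    cv = RepeatedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    splits = list(cv.split(X_train))
    grid_rmse = {}
    for l1 in l1_ratio_grid:
        for lam in lambda_grid:
            errs = []
            for tr, va in splits:
                Z_tr, mean, scale = _standardize(X_train[tr])
                est = _fit_enet(Z_tr, y_train[tr], l1, lam)
                Z_va = (X_train[va] - mean) / scale
                pred = est.predict(Z_va)
                errs.append(np.sqrt(mean_squared_error(y_train[va], pred)))
            grid_rmse[(l1, lam)] = float(np.mean(errs))
    (best_l1, best_lam) = min(grid_rmse, key=lambda k: (grid_rmse[k], k))

    # final refit on the full training split
    Z_train, mean, scale = _standardize(X_train)
    est = _fit_enet(Z_train, y_train, best_l1, best_lam)
    model = ActivityModel(
        family="glmnet-inter",
        feature_names=list(features.columns),
        coef=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_),
        scaler_mean=mean,
        scaler_scale=scale,
        l1_ratio=float(best_l1),
        lambda_=float(best_lam),
    )

    pred_test = model.predict_matrix(X_test)
    pred_train = model.predict_matrix(X_train)
    baseline = LinearRegression().fit(Z_train, y_train)
    base_pred = baseline.predict((X_test - mean) / scale)
    report = {
        "n_train_constructs": len(train_ids),
        "n_test_constructs": len(test_ids),
        "cv_rmse": grid_rmse[(best_l1, best_lam)],
        "l1_ratio": float(best_l1),
        "lambda": float(best_lam),
        "train_r2": float(r2_score(y_train, pred_train)),
        "test_r2": float(r2_score(y_test, pred_test)),
        "test_rmse": float(np.sqrt(mean_squared_error(y_test, pred_test))),
        "baseline_lm_test_r2": float(r2_score(y_test, base_pred)),
        "test_construct_ids": sorted(test_ids),
    }
    model.cv_record = {k: v for k, v in report.items() if k != "test_construct_ids"}
    return model, report


def predict_library(model: ActivityModel, features: pd.DataFrame,
                    retained: Sequence[str] | None = None) -> pd.DataFrame:
    """Predict log2 median fluorescence for every (construct, state) row.

    Returns a construct x state table. When ``retained`` is given, constructs
    outside it (e.g. failing the replicate filter) are flagged NaN rather
    than silently predicted.
    """
    preds = model.predict(features)
    table = preds.unstack("state")
    if retained is not None:
        retained = set(retained)
        mask = ~table.index.isin(retained)
        table.loc[mask, :] = np.nan
    table.index.name = "construct_id"
    return table
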