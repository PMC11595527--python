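"""Occurrence preparation and ensemble habitat suitability modeling.

The workflow mirrors standard species-distribution practice for
presence/background data:

1. spatial thinning of presence records (default 1 km) against
   pseudoreplication;
2. iterative variance-inflation-factor screening of the covariate stack
   (drop the worst layer while any VIF >= 10);
3. stratified 75/25 train/test split;
4. three learner families fitted on the training set, each scored by AUC
   (Mann-Whitney rank statistic) and TSS (max over thresholds of
   sensitivity + specificity - 1) on the held-out test set;
5. learners failing either quality gate (AUC < 0.8 or TSS < 0.7) are
   excluded; survivors are averaged with weights (AUC - 0.5)^2,
   normalized to sum to one;
6. jackknife variable importance (leave-one-variable-out AUC drop,
   normalized to percent contributions);
7. binarization of the ensemble surface at the max-TSS threshold.

Occurrence tables are pandas DataFrames with columns
``id, x, y, label, source`` (label in {presence, background}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .learners import Learner
from .raster import Raster


# ---------------------------------------------------------------------------
# occurrence handling


def merge_occurrences(*sets: pd.DataFrame) -> pd.DataFrame:
    """Concatenate occurrence tables, reassigning unique ids."""
    merged = pd.concat(sets, ignore_index=True)
    merged["id"] = np.arange(len(merged))
    return merged


def thin_occurrences(points: pd.DataFrame, min_distance: float = 1000.0) -> pd.DataFrame:
    """Drop presences closer than ``min_distance`` to an already-kept one.

    Sequential scan in input order: a presence is kept iff it lies at
    least ``min_distance`` from every previously kept presence.
    Background points pass through untouched. Deterministic; idempotent.
    """
    pres = points[points["label"] == "presence"]
    rest = points[points["label"] != "presence"]
    kept_xy: list[tuple[float, float]] = []
    kept_idx = []
    for idx, row in pres.iterrows():
        p = (row["x"], row["y"])
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_distance**2 for q in kept_xy):
            kept_xy.append(p)
            kept_idx.append(idx)
    return pd.concat([pres.loc[kept_idx], rest]).sort_index()


# ---------------------------------------------------------------------------
# covariate screening


def sample_stack(
    stack: dict[str, Raster], points: pd.DataFrame, layers: list[str] | None = None
) -> np.ndarray:
    """Design matrix of covariate values at point locations (nearest cell)."""
    names = layers if layers is not None else list(stack)
    xs = points["x"].to_numpy()
    ys = points["y"].to_numpy()
    return np.column_stack([stack[name].values_at(xs, ys) for name in names])


def _vif_one(X: np.ndarray, k: int) -> float:
    """VIF of column k: 1 / (1 - R²) from least-squares on the others."""
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    A = np.column_stack([others, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan  # constant layer
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(
    stack: dict[str, Raster],
    sample_points: pd.DataFrame,
    threshold: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF layer while any VIF >= threshold.

    Exact collinearity gives infinite VIF and is removed first; constant
    layers have undefined R² and are removed with a warning. Returns the
    surviving layer names (original order) and a per-round VIF trace.
    """
    names = list(stack)
    if len(names) < 2:
        return names, pd.DataFrame(columns=["round", "layer", "vif", "removed"])
    if len(sample_points) < 3:
        raise ValueError("VIF screening needs at least 3 sample points")
    X = sample_stack(stack, sample_points, names)
    remaining = list(range(len(names)))
    trace_rows = []
    rnd = 0
    while len(remaining) >= 2:
        sub = X[:, remaining]
        vifs = np.array([_vif_one(sub, i) for i in range(len(remaining))])
        if np.any(np.isnan(vifs)):
            drop_local = int(np.flatnonzero(np.isnan(vifs))[0])
            warnings.warn(
                f"layer {names[remaining[drop_local]]!r} is constant at the sample points; removed",
                stacklevel=2,
            )
        elif np.nanmax(vifs) >= threshold:
            drop_local = int(np.nanargmax(vifs))
        else:
            for i, v in zip(remaining, vifs):
                trace_rows.append({"round": rnd, "layer": names[i], "vif": v, "removed": False})
            break
        for i, v in zip(remaining, vifs):
            trace_rows.append(
                {
                    "round": rnd,
                    "layer": names[i],
                    "vif": v,
                    "removed": remaining[drop_local] == i,
                }
            )
        remaining.pop(drop_local)
        rnd += 1
    retained = [names[i] for i in remaining]
    return retained, pd.DataFrame(trace_rows)


# ---------------------------------------------------------------------------
# train/test split and evaluation


def split_train_test(
    occ: pd.DataFrame, train_fraction: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified (presence/background) random split; test size floored."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_pres = int((occ["label"] == "presence").sum())
    if n_pres < 4:
        raise ValueError("need at least 4 presence records to split")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for _, group in occ.groupby("label", sort=True):
        n = len(group)
        n_test = int(np.floor(n * (1.0 - train_fraction)))
        perm = rng.permutation(n)
        test_parts.append(group.iloc[perm[:n_test]])
        train_parts.append(group.iloc[perm[n_test:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


@dataclass(frozen=True)
class EvalScores:
    auc: float
    tss: float


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: test set contains a single class")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss_score(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Max over score thresholds of sensitivity + specificity - 1.

    Returns (TSS, threshold attaining it). Candidate thresholds are the
    distinct observed scores; prediction rule is ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS undefined: test set contains a single class")
    thresholds = np.unique(scores)
    pred = scores[None, :] >= thresholds[:, None]
    sens = (pred & labels[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~labels[None, :]).sum(axis=1) / n_neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))
    return float(tss[best]), float(thresholds[best])


def evaluate(fit: Learner, X_test: np.ndarray, y_test: np.ndarray) -> EvalScores:
    """Held-out AUC and TSS of a fitted learner."""
    scores = fit.predict_score(X_test)
    tss, _ = tss_score(scores, y_test)
    return EvalScores(auc=auc_score(scores, y_test), tss=tss)


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleResult:
    retained: list[tuple[str, float, float]]  # (learner_id, raw_weight, normalized_weight)
    excluded: list[tuple[str, str]]  # (learner_id, reason)
    scores: dict[str, EvalScores]
    suitability: Raster | None = None


def gate_and_weight(
    scores: list[tuple[str, EvalScores]], auc_min: float = 0.8, tss_min: float = 0.7
) -> EnsembleResult:
    """Exclude learners failing either gate; weight survivors by (AUC - 0.5)².

    A learner is excluded if AUC < auc_min or TSS < tss_min — either
    failure alone marks the model "poor". Weights are normalized to sum
    to one over the retained learners.
    """
    if not scores:
        raise ValueError("no learners to gate")
    retained_raw: list[tuple[str, float]] = []
    excluded: list[tuple[str, str]] = []
    for learner_id, ev in scores:
        reasons = []
        if ev.auc < auc_min:
            reasons.append(f"AUC {ev.auc:.3f} < {auc_min}")
        if ev.tss < tss_min:
            reasons.append(f"TSS {ev.tss:.3f} < {tss_min}")
        if reasons:
            excluded.append((learner_id, "; ".join(reasons)))
        else:
            retained_raw.append((learner_id, (ev.auc - 0.5) ** 2))
    if not retained_raw:
        raise ValueError("every learner failed the AUC/TSS quality gates; no usable model")
    total = sum(w for _, w in retained_raw)
    if total == 0:
        # all retained learners sit exactly at AUC = 0.5 (possible only with
        # gates relaxed below 0.5): fall back to equal weights
        retained = [(lid, w, 1.0 / len(retained_raw)) for lid, w in retained_raw]
    else:
        retained = [(lid, w, w / total) for lid, w in retained_raw]
    return EnsembleResult(retained=retained, excluded=excluded, scores=dict(scores))


def ensemble_predict(
    fits: dict[str, Learner], result: EnsembleResult, stack: dict[str, Raster], layers: list[str]
) -> Raster:
    """Weighted per-cell mean of retained learners' predictions."""
    grids = {name: stack[name].grid for name in layers}
    if len(set(grids.values())) != 1:
        raise ValueError("covariate layers are not on a shared grid")
    grid = next(iter(grids.values()))
    X = np.column_stack([stack[name].data.ravel() for name in layers])
    out = np.zeros(X.shape[0], dtype=float)
    for learner_id, _, w in result.retained:
        out += w * fits[learner_id].predict_score(X)
    return Raster(np.clip(out, 0.0, 1.0).reshape(grid.height, grid.width), grid)


# ---------------------------------------------------------------------------
# jackknife importance


def jackknife_importance(
    learner_factory,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    variables: list[str],
) -> pd.DataFrame:
    """Leave-one-variable-out importance as percent contributions.

    For each variable the factory is refit without it (and, for
    reference, with only it); the importance score is the drop in
    held-out AUC when the variable is left out, floored at zero, and the
    scores are normalized to sum to 100.
    """
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = learner_factory().fit(X_train, y_train)
    auc_full = auc_score(full.predict_score(X_test), y_test)
    rows = []
    for k, var in enumerate(variables):
        keep = [i for i in range(len(variables)) if i != k]
        without = learner_factory().fit(X_train[:, keep], y_train)
        auc_without = auc_score(without.predict_score(X_test[:, keep]), y_test)
        only = learner_factory().fit(X_train[:, [k]], y_train)
        auc_only = auc_score(only.predict_score(X_test[:, [k]]), y_test)
        rows.append(
            {
                "variable": var,
                "auc_without": auc_without,
                "auc_only": auc_only,
                "score": max(0.0, auc_full - auc_without),
            }
        )
    table = pd.DataFrame(rows)
    total = table["score"].sum()
    if total == 0:
        warnings.warn(
            "every leave-one-out model matches the full model; uniform contributions",
            stacklevel=2,
        )
        table["contribution_pct"] = 100.0 / len(variables)
    else:
        table["contribution_pct"] = table["score"] / total * 100.0
    table.attrs["auc_full"] = auc_full
    return table


# ---------------------------------------------------------------------------
# binarization


def binarize_habitat(
    suitability: Raster, test_scores: np.ndarray, test_labels: np.ndarray
) -> tuple[Raster, float]:
    """Binary habitat map at the max-TSS threshold of the test set.

    Degenerate test sets (single class, or constant scores) fall back to
    a fixed 0.5 threshold with a warning.
    """
    try:
        if len(np.unique(np.asarray(test_scores, dtype=float))) < 2:
            raise ValueError("constant scores")
        _, threshold = tss_score(test_scores, test_labels)
    except ValueError:
        warnings.warn("degenerate test set; falling back to threshold 0.5", stacklevel=2)
        threshold = 0.5
    binary = (suitability.data >= threshold).astype(np.int64)
    return Raster(binary, suitability.grid), float(threshold)
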