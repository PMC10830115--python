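"""Gaussian-process decoding of navigational variables from manifold coordinates.

Position and speed are decoded by Gaussian-process regression (kernel =
ConstantKernel * RBF + WhiteKernel, hyperparameters by marginal-likelihood
maximization, targets standardized internally) with twofold
cross-validation: bins are either randomly split 50/50 or split into
first/second session halves.  Accuracy is the coefficient of determination

    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

computed on the held-out fold; X and Y position are decoded separately and
the two R^2 values averaged.  The upcoming turn ("path") is decoded from
start-box bins by Gaussian-process classification with leave-one-trial-out
cross-validation, and also from pairwise coactivity (per-trial covariances
of sqrt rates).  Chance levels come from circularly shifting every unit's
spike train and re-running the whole pipeline.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessClassifier, GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel


@contextmanager
def _quiet_fit():
    # hyperparameters pinned at a bound are expected for clean targets
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield

from .session import SpikeTable, circular_shift_spikes


@dataclass
class DecodingResult:
    target: str
    accuracy: float                      # R^2 (regression) or fraction correct (path)
    fold_accuracies: list = field(default_factory=list)
    noisiness: float | None = None       # SD of (prediction - observation)
    n_units: int | None = None
    cv: str | None = None
    seed: int | None = None
    chance: np.ndarray | None = None
    predictions: np.ndarray | None = None
    observed: np.ndarray | None = None


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = np.sum((y - y_pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant observed values; R^2 undefined")
    return float(1 - ss_res / ss_tot)


def _gp_kernel():
    return ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3)) + WhiteKernel(
        0.1, (1e-5, 1e1)
    )


def _new_gpr(seed: int) -> GaussianProcessRegressor:
    return GaussianProcessRegressor(
        kernel=_gp_kernel(), normalize_y=True, random_state=seed, n_restarts_optimizer=0
    )


def gpr_decode(
    coords: np.ndarray,
    targets: np.ndarray,
    cv: str = "twofold-random",
    seed: int = 0,
    average_columns: bool = True,
) -> DecodingResult:
    """Twofold cross-validated GPR decoding; accuracy is the average R^2.

    ``targets`` may be (n,) or (n, k); with ``average_columns`` each column
    is decoded by its own regressor and the R^2 values are averaged (as
    done for X and Y position).
    """
    coords = np.asarray(coords, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    n = len(coords)
    if n < 20:
        raise ValueError("need >= 20 bins")
    if not np.all(np.isfinite(targets)):
        raise ValueError("non-finite targets")

    rng = np.random.default_rng(seed)
    if cv == "twofold-random":
        perm = rng.permutation(n)
        folds = [perm[: n // 2], perm[n // 2:]]
    elif cv == "halves":
        idx = np.arange(n)
        folds = [idx[: n // 2], idx[n // 2:]]
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    fold_acc = []
    preds = np.full(targets.shape, np.nan)
    for f, test in enumerate(folds):
        train = folds[1 - f]
        col_r2 = []
        for c in range(targets.shape[1]):
            gpr = _new_gpr(seed)
            with _quiet_fit():
                gpr.fit(coords[train], targets[train, c])
            yhat = gpr.predict(coords[test])
            preds[test, c] = yhat
            col_r2.append(r_squared(targets[test, c], yhat))
        fold_acc.append(float(np.mean(col_r2)) if average_columns else col_r2)

    noisiness = float(np.std(preds - targets))
    return DecodingResult(
        target="regression", accuracy=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc, noisiness=noisiness, cv=cv, seed=seed,
        predictions=preds.squeeze(), observed=targets.squeeze(),
    )


# ---------------------------------------------------------------------------
# path (upcoming-choice) decoding


def decode_path(
    coords: np.ndarray,
    trial_ids: np.ndarray,
    turns: dict,
    seed: int = 0,
) -> DecodingResult:
    """GP classification of the upcoming turn from start-box bins.

    ``coords`` are manifold coordinates of box bins, ``trial_ids`` assigns
    each bin to its trial, ``turns`` maps trial id -> 'L'/'R'.  Leave-one-
    trial-out: per-bin P(left) is averaged within the held-out trial and
    the higher-probability turn is the prediction (ties broken by a seeded
    coin flip).  Accuracy is the fraction of trials predicted correctly.
    """
    coords = np.asarray(coords, dtype=float)
    trial_ids = np.asarray(trial_ids)
    uniq = [t for t in pd.unique(trial_ids) if np.sum(trial_ids == t) > 0]
    if len(uniq) < 4:
        raise ValueError("need >= 4 trials")
    labels = np.array([turns[t] for t in trial_ids], dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("need both turn labels")
    rng = np.random.default_rng(seed)

    correct = []
    probs = []
    y = (labels == "L").astype(int)
    for t in uniq:
        test = trial_ids == t
        gpc = GaussianProcessClassifier(kernel=_gp_kernel(), random_state=seed)
        if len(set(y[~test])) < 2:
            continue
        with _quiet_fit():
            gpc.fit(coords[~test], y[~test])
        p_left = gpc.predict_proba(coords[test])[:, list(gpc.classes_).index(1)].mean()
        probs.append(p_left)
        if p_left == 0.5:
            pred = "L" if rng.random() < 0.5 else "R"
        else:
            pred = "L" if p_left > 0.5 else "R"
        correct.append(pred == turns[t])
    return DecodingResult(
        target="path", accuracy=float(np.mean(correct)), cv="leave-one-trial-out",
        seed=seed, predictions=np.array(probs), fold_accuracies=correct,
    )


def coactivity_features(
    rates_sqrt: np.ndarray, trial_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial pairwise covariance features of sqrt rates over box bins.

    Returns (features, trial order); trials with <= 1 bin are dropped.
    Feature length is N(N-1)/2 per trial (upper triangle, no diagonal).
    """
    rates_sqrt = np.asarray(rates_sqrt, dtype=float)
    n_units = rates_sqrt.shape[1]
    if n_units < 2:
        raise ValueError("need >= 2 units")
    iu = np.triu_indices(n_units, k=1)
    feats, kept = [], []
    for t in pd.unique(trial_ids):
        rows = rates_sqrt[trial_ids == t]
        if len(rows) <= 1:
            continue
        feats.append(np.cov(rows.T)[iu])
        kept.append(t)
    return np.array(feats), np.array(kept)


def coactivity_decode(
    rates_sqrt: np.ndarray,
    trial_ids: np.ndarray,
    turns: dict,
    seed: int = 0,
) -> DecodingResult:
    """Decode the upcoming turn from pairwise coactivity (GPC, leave-one-out)."""
    feats, kept = coactivity_features(rates_sqrt, trial_ids)
    if len(kept) < 4:
        raise ValueError("need >= 4 trials with >= 2 box bins")
    keep_cols = feats.std(axis=0) > 0
    feats = feats[:, keep_cols]
    res = decode_path(feats, kept, turns, seed=seed)
    res.target = "peer-coactivity"
    return res


# ---------------------------------------------------------------------------
# controls: thinning, unit matching, shuffles


def thin_spikes(spike_table: SpikeTable, keep_fraction: float, seed: int = 0) -> SpikeTable:
    """Keep each spike independently with probability ``keep_fraction``.

    Used to equate mean firing rates between regions (e.g. keeping 25% of
    SUB spikes brings a 5.80-Hz population to the 1.45-Hz range of CA1).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return spike_table
    rng = np.random.default_rng(seed)
    keep = rng.random(len(spike_table.spikes)) < keep_fraction
    spikes = spike_table.spikes[keep].reset_index(drop=True)
    return SpikeTable(spikes=spikes, units=spike_table.units.copy())


def matched_subsample_accuracy(
    spike_table: SpikeTable,
    n_units: int,
    reps: int,
    decoder,
    seed: int = 0,
) -> DecodingResult:
    """Average a decoder over random unit subsets of fixed size.

    ``decoder`` maps a SpikeTable (with the chosen units) to a float
    accuracy.  Subsets are drawn uniformly without replacement.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids = spike_table.unit_ids
    if n_units > len(ids):
        raise ValueError("n_units exceeds available units")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(reps):
        chosen = rng.choice(ids, size=n_units, replace=False)
        accs.append(float(decoder(spike_table.subset(chosen))))
    return DecodingResult(
        target="matched-subsample", accuracy=float(np.mean(accs)),
        fold_accuracies=accs, n_units=n_units, seed=seed,
    )


def shuffle_chance(
    spike_table: SpikeTable,
    interval: tuple[float, float],
    decoder,
    n_shuffle: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Chance distribution: circularly shift spike trains, re-run the decoder."""
    if n_shuffle < 1:
        raise ValueError("n_shuffle must be >= 1")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_shuffle):
        shuffled = circular_shift_spikes(spike_table, interval, rng)
        accs.append(float(decoder(shuffled)))
    return np.array(accs)
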