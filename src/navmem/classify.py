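"""Per-subject multivariate decoding of subsequent-memory success.

An L2-regularized logistic regression predicts whether each studied object
will later be remembered from z-scored log-power features: 10 log-spaced
frequencies in 1-10 Hz (low), 10 in 40-100 Hz (high), or both, per
electrode, averaged over the 0-1500-ms item display.  Performance is the
area under the ROC curve over predictions pooled across leave-one-session-
out folds (leave-one-trial-out for single-session subjects); chance is 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "classifier_frequencies",
    "FeatureMatrix",
    "ClassifierResult",
    "build_features",
    "crossval_auc",
    "shuffle_null",
    "cohort_permutation_p",
    "electrode_sweep",
]

LOW_RANGE = (1.0, 10.0)
HIGH_RANGE = (40.0, 100.0)
N_FREQS_PER_SET = 10


def classifier_frequencies(freq_set: str = "both") -> np.ndarray:
    """10 log-spaced frequencies per range: 1-10 Hz and/or 40-100 Hz."""
    low = np.logspace(np.log10(LOW_RANGE[0]), np.log10(LOW_RANGE[1]), N_FREQS_PER_SET)
    high = np.logspace(np.log10(HIGH_RANGE[0]), np.log10(HIGH_RANGE[1]), N_FREQS_PER_SET)
    if freq_set == "low":
        return low
    if freq_set == "high":
        return high
    if freq_set == "both":
        return np.concatenate([low, high])
    raise ValueError(f"unknown freq_set {freq_set!r}")


@dataclass
class FeatureMatrix:
    """Encoding events x (electrodes x frequencies) z-power features."""

    X: np.ndarray  # events x electrodes x freqs
    y: np.ndarray  # bool, True = remembered
    folds: np.ndarray  # fold id per event (session or trial)
    freqs: np.ndarray
    channels: pd.DataFrame

    @property
    def matrix(self) -> np.ndarray:
        return self.X.reshape(self.X.shape[0], -1)

    @property
    def n_electrodes(self) -> int:
        return self.X.shape[1]


@dataclass
class ClassifierResult:
    auc: float
    predictions: np.ndarray
    labels: np.ndarray
    fold_of: np.ndarray
    skipped_folds: list


def build_features(
    z_values: np.ndarray,
    events: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    freqs: np.ndarray,
    channels: pd.DataFrame,
    fold_by: str = "trial",
) -> FeatureMatrix:
    """Assemble the decoding feature matrix from z-power encoding events.

    ``z_values`` is encoding events x channels x freqs (already z-scored and
    time-averaged over 0-1500 ms).  Events with any rejected (NaN) cell are
    dropped row-wise and logged; dropping every event raises.
    """
    y = np.asarray(labels) == "remembered" if np.asarray(labels).dtype.kind in "OU" else np.asarray(labels, bool)
    folds = events[fold_by].to_numpy()
    ok = ~np.isnan(z_values).any(axis=(1, 2))
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events with rejected cells", stacklevel=2)
    if not ok.any():
        raise ValueError("zero retained events after rejection")
    return FeatureMatrix(
        X=z_values[ok],
        y=y[ok],
        folds=folds[ok],
        freqs=np.asarray(freqs, float),
        channels=channels,
    )


def _fit_predict(X_tr, y_tr, X_te, penalty_c: float) -> np.ndarray:
    # sklearn's default penalty is the L2 ridge; C is its inverse strength
    clf = LogisticRegression(C=penalty_c, solver="lbfgs", max_iter=1000)
    clf.fit(X_tr, y_tr)
    return clf.predict_proba(X_te)[:, 1]


def crossval_auc(
    features: FeatureMatrix, penalty_c: float = 1.0
) -> ClassifierResult:
    """Cross-validated AUC with predictions pooled across held-out folds.

    Folds come from the feature matrix's fold ids.  Training folds with a
    single class are skipped with a warning; if every fold is skipped an
    error is raised.
    """
    X, y, folds = features.matrix, features.y, features.folds
    unique = np.unique(folds)
    if unique.size < 2:
        raise ValueError("need >= 2 folds for cross-validation")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present overall")
    preds = np.full(y.size, np.nan)
    skipped = []
    for f in unique:
        te = folds == f
        tr = ~te
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {f}: single-class training set skipped", stacklevel=2)
            skipped.append(f)
            continue
        preds[te] = _fit_predict(X[tr], y[tr], X[te], penalty_c)
    ok = ~np.isnan(preds)
    if not ok.any() or len(np.unique(y[ok])) < 2:
        raise ValueError("all folds skipped or single-class predictions")
    auc = float(roc_auc_score(y[ok], preds[ok]))
    return ClassifierResult(
        auc=auc, predictions=preds, labels=y, fold_of=folds, skipped_folds=skipped
    )


def shuffle_null(
    features: FeatureMatrix,
    n_shuffles: int = 100,
    penalty_c: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Null AUC distribution from within-subject label permutations.

    Labels are permuted (identity permutations resampled away) and the full
    cross-validation re-run per shuffle.  Returns the ``n_shuffles`` null
    AUCs; combine across subjects with :func:`cohort_permutation_p`.
    """
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    y = features.y
    for s in range(n_shuffles):
        perm = rng.permutation(y.size)
        while np.array_equal(y[perm], y):
            perm = rng.permutation(y.size)
        shuffled = FeatureMatrix(
            X=features.X,
            y=y[perm],
            folds=features.folds,
            freqs=features.freqs,
            channels=features.channels,
        )
        null[s] = crossval_auc(shuffled, penalty_c).auc
    return null


def cohort_permutation_p(true_aucs: np.ndarray, null_aucs: np.ndarray) -> float:
    """Cohort-level permutation p: shuffled cohort-mean AUCs >= the true mean.

    ``null_aucs`` is subjects x shuffles; shuffle index s yields one null
    cohort mean.  p is reported with the +1 correction, so exceeding every
    shuffle gives p < 1/n_shuffles.
    """
    true_mean = float(np.mean(true_aucs))
    null_means = np.asarray(null_aucs).mean(axis=0)
    return (1 + int(np.sum(null_means >= true_mean))) / (null_means.size + 1)


def _feature_tstats(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample t per electrode x frequency between classes."""
    a, b = X[y], X[~y]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(sp, 1e-300) * (1 / na + 1 / nb))
    return (ma - mb) / denom


def electrode_sweep(
    features: FeatureMatrix,
    n_reps: int = 100,
    n_max: int = 50,
    penalty_c: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Mean held-out AUC as a function of electrode count.

    Per repetition: split encoding events into random halves (both classes
    in each); rank electrodes by the maximum |two-sample t| across their
    frequencies on the training half; for N = 1..n_max train on the top-N
    electrodes and score AUC on the held-out half.  Returns the mean AUC per
    N (curve truncated at the subject's electrode count).
    """
    rng = np.random.default_rng(seed)
    n_elec = features.n_electrodes
    n_max = min(n_max, n_elec)
    if n_elec < 2:
        raise ValueError("need >= 2 electrodes for a sweep")
    X3, y = features.X, features.y
    n_ev = y.size
    aucs = np.full((n_reps, n_max), np.nan)
    for rep in range(n_reps):
        for _ in range(100):
            perm = rng.permutation(n_ev)
            tr, te = perm[: n_ev // 2], perm[n_ev // 2 :]
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                break
        else:
            raise ValueError("could not find a half-split with both classes in each half")
        t = _feature_tstats(X3[tr], y[tr])
        order = np.argsort(-np.abs(t).max(axis=1), kind="stable")
        for ni in range(n_max):
            elecs = order[: ni + 1]
            Xtr = X3[tr][:, elecs, :].reshape(tr.size, -1)
            Xte = X3[te][:, elecs, :].reshape(te.size, -1)
            p = _fit_predict(Xtr, y[tr], Xte, penalty_c)
            aucs[rep, ni] = roc_auc_score(y[te], p)
    return aucs.mean(axis=0)
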