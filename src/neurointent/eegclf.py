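"""Four-class motor-imagery classification via one-vs-rest support-vector regression.

One RBF-kernel SVR is trained per class with target 1 for that class's
windows and 0 for the rest; at prediction time the class whose regressor
output is nearest 1 wins, and a softmax over the four raw outputs provides
the posterior vector consumed by decision-level fusion.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

N_CLASSES = 4


class MotorImageryClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest SVR over fused EEG features.

    Parameters
    ----------
    C, epsilon, gamma : SVR hyperparameters (RBF kernel).

    Attributes
    ----------
    regressors_ : list of fitted SVR, one per class in ``{0..3}``.
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1,
                 gamma: str | float = "scale"):
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma

    def fit(self, X, y) -> "MotorImageryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, int)
        present = np.unique(y)
        if len(present) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if not np.all(np.isin(present, np.arange(N_CLASSES))):
            raise ValueError("labels must lie in {0..3}")
        self.regressors_ = []
        for c in range(N_CLASSES):
            target = (y == c).astype(float)
            reg = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon,
                      gamma=self.gamma)
            self.regressors_.append(reg.fit(X, target))
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.arange(N_CLASSES)
        return self

    def decision_values(self, X) -> np.ndarray:
        """Raw per-class regressor outputs, shape (n, 4)."""
        check_is_fitted(self, "regressors_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch with fitted state")
        return np.column_stack([r.predict(X) for r in self.regressors_])

    def predict(self, X) -> np.ndarray:
        """Class whose output is nearest 1; ties go to the lowest index."""
        v = self.decision_values(X)
        return np.argmin(np.abs(1.0 - v), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Softmax of the raw regressor outputs (temperature 1), rows sum to 1."""
        return softmax(self.decision_values(X), axis=1)

    def predict_trial(self, X_windows) -> int:
        """Aggregate the windows of one trial: majority vote over per-window
        predictions, ties resolved by the argmax of the window-mean posterior."""
        X_windows = np.asarray(X_windows, dtype=float)
        if X_windows.shape[0] < 1:
            raise ValueError("predict_trial needs at least one window")
        preds = self.predict(X_windows)
        counts = np.bincount(preds, minlength=N_CLASSES)
        top = np.flatnonzero(counts == counts.max())
        if len(top) == 1:
            return int(top[0])
        mean_proba = self.predict_proba(X_windows).mean(axis=0)
        return int(top[np.argmax(mean_proba[top])])

    def predict_trials(self, X, trial_index) -> np.ndarray:
        """Vectorized :meth:`predict_trial` over windows grouped by trial id."""
        trial_index = np.asarray(trial_index, int)
        out = []
        for t in np.unique(trial_index):
            out.append(self.predict_trial(np.asarray(X)[trial_index == t]))
        return np.asarray(out, int)

    def trial_proba(self, X, trial_index) -> np.ndarray:
        """Window-mean posterior per trial (for fusion at the trial level)."""
        trial_index = np.asarray(trial_index, int)
        proba = self.predict_proba(X)
        return np.stack([proba[trial_index == t].mean(axis=0)
                         for t in np.unique(trial_index)])
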