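"""Channel selection by discriminative variance and band-power ANOVA scores.

The sensorimotor core channels {C3, Cz, C4} are always retained.  Every other
(candidate) channel receives two scores:

* a discriminative variance score
  ``S_var = (1/N) * sum_j sigma2_ij / (sigma2_i + eps)`` comparing per-class
  signal variance against the pooled variance, and
* an ANOVA band-power score ``S_anova = -log10(p)`` from a one-way F-test of
  the per-trial mean-square power across the four motor-imagery classes.

Scores are min-max normalized over the candidates, fused as
``S_fused = alpha * S~_var + (1 - alpha) * S~_anova``, and the top
``k_total - |core|`` candidates join the core set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .preproc import EpochSet

CORE_CHANNELS = ("C3", "Cz", "C4")

P_FLOOR = 1e-300  # p-value underflow cap for -log10(p)


def _check_classes(labels: np.ndarray) -> list[np.ndarray]:
    classes = np.unique(labels)
    groups = [np.flatnonzero(labels == c) for c in classes]
    for c, g in zip(classes, groups):
        if len(g) < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
    return groups


def discriminative_variance_score(epochs: EpochSet, channel: str,
                                  epsilon: float = 1e-10,
                                  pooled_class_variance: bool = False) -> float:
    """Variance-ratio score of one channel.

    ``sigma2_ij`` is by default the mean of per-trial variances within class j;
    with ``pooled_class_variance=True`` it is the variance of the class's
    pooled samples instead.  ``sigma2_i`` is the variance of all samples of
    the channel pooled over trials.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if channel not in epochs.channel_names:
        raise ValueError(f"channel {channel!r} not in epoch set")
    x = epochs.data[:, epochs.channel_names.index(channel), :]
    groups = _check_classes(epochs.labels)
    sigma2_i = float(np.var(x))
    total = 0.0
    for g in groups:
        if pooled_class_variance:
            s2 = float(np.var(x[g]))
        else:
            s2 = float(np.mean(np.var(x[g], axis=-1)))
        total += s2 / (sigma2_i + epsilon)
    return total / len(groups)


def trial_power(x: np.ndarray) -> np.ndarray:
    """Mean-square power per trial: P_t = (1/T) * sum_k x[k]^2."""
    x = np.asarray(x, dtype=float)
    return np.mean(x ** 2, axis=-1)


def anova_power_score(epochs: EpochSet, channel: str) -> float:
    """-log10(p) of a one-way ANOVA of per-trial band power across classes."""
    if channel not in epochs.channel_names:
        raise ValueError(f"channel {channel!r} not in epoch set")
    x = epochs.data[:, epochs.channel_names.index(channel), :]
    powers = trial_power(x)
    groups = _check_classes(epochs.labels)
    samples = [powers[g] for g in groups]
    if np.ptp(powers) == 0:
        warnings.warn("all trial powers identical; ANOVA undefined, score 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*samples)
    if not np.isfinite(p):
        return 0.0
    return float(-np.log10(max(p, P_FLOOR)))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        # all candidates tie on this score: it carries no ranking information
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


class ChannelSelector(BaseEstimator, TransformerMixin):
    """Select ``k_total`` channels: the fixed core plus top fused-score candidates.

    Parameters
    ----------
    k_total : int, default=15
        Total channels retained, core included.
    alpha : float, default=0.5
        Weight of the normalized variance score in the fusion; the ANOVA
        score gets ``1 - alpha``.  Equal weighting by default.
    epsilon : float, default=1e-10
        Smoothing added to the pooled variance denominator.
    core_channels : tuple of str
        Channels retained unconditionally.
    pooled_class_variance : bool, default=False
        Alternative definition of the within-class variance (see
        :func:`discriminative_variance_score`).

    Attributes
    ----------
    scores_ : pandas.DataFrame
        Per-candidate ``S_var``, ``S_anova``, normalized scores, ``S_fused``,
        rank and selection flag.
    selected_channels_ : list of str
        Core channels first, then selected candidates by descending fused
        score (ties broken by ascending channel index).
    """

    def __init__(self, k_total: int = 15, alpha: float = 0.5,
                 epsilon: float = 1e-10,
                 core_channels: tuple[str, ...] = CORE_CHANNELS,
                 pooled_class_variance: bool = False):
        self.k_total = k_total
        self.alpha = alpha
        self.epsilon = epsilon
        self.core_channels = core_channels
        self.pooled_class_variance = pooled_class_variance

    def fit(self, epochs: EpochSet, y=None) -> "ChannelSelector":
        if not isinstance(epochs, EpochSet):
            raise TypeError("ChannelSelector.fit expects an EpochSet")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        core = list(self.core_channels)
        missing = [c for c in core if c not in epochs.channel_names]
        if missing:
            raise ValueError(f"core channels {missing} absent from epoch set")
        if self.k_total < len(core):
            raise ValueError("k_total must be at least the core set size")
        candidates = [c for c in epochs.channel_names if c not in core]
        n_pick = min(self.k_total - len(core), len(candidates))

        s_var = np.array([discriminative_variance_score(
            epochs, c, self.epsilon, self.pooled_class_variance)
            for c in candidates])
        s_anova = np.array([anova_power_score(epochs, c) for c in candidates])
        nv, na = _minmax(s_var), _minmax(s_anova)
        fused = self.alpha * nv + (1 - self.alpha) * na

        order = np.lexsort((np.arange(len(candidates)), -fused))
        rank = np.empty(len(candidates), dtype=int)
        rank[order] = np.arange(1, len(candidates) + 1)
        picked = set(order[:n_pick])

        self.scores_ = pd.DataFrame({
            "channel": candidates,
            "S_var": s_var, "S_anova": s_anova,
            "S_var_norm": nv, "S_anova_norm": na,
            "S_fused": fused, "rank": rank,
            "selected": [i in picked for i in range(len(candidates))],
        })
        self.selected_channels_ = core + [candidates[i] for i in order[:n_pick]]
        self.n_features_in_ = epochs.n_channels
        return self

    def transform(self, epochs: EpochSet) -> EpochSet:
        check_is_fitted(self, "selected_channels_")
        return epochs.pick_channels(self.selected_channels_)

    def score_table(self) -> pd.DataFrame:
        """Candidate score table sorted by rank (CSV-exportable)."""
        check_is_fitted(self, "scores_")
        return self.scores_.sort_values("rank").reset_index(drop=True)


def select_channels(epochs: EpochSet, k_total: int = 15, alpha: float = 0.5,
                    epsilon: float = 1e-10) -> list[str]:
    """Functional wrapper returning the selected channel list."""
    return ChannelSelector(k_total=k_total, alpha=alpha,
                           epsilon=epsilon).fit(epochs).selected_channels_
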