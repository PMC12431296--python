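"""Channel scoring oracles and the fused selection rule."""

import numpy as np
import pytest
from scipy import stats

from neurointent.chansel import (ChannelSelector, anova_power_score,
                                 discriminative_variance_score, trial_power)
from neurointent.preproc import EpochSet, bandpass_filter
from neurointent.synth import EEGSimSpec, generate_mi_eeg


def make_epochs(data, labels, names=None, fs=128.0):
    names = names or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(np.asarray(data, float), labels, names, fs)


class TestVarianceScore:
    def test_equal_class_and_pooled_variance_gives_one(self, rng):
        # one shared population: every class variance ~= pooled variance
        data = rng.standard_normal((40, 1, 64))
        ep = make_epochs(data, np.arange(40) % 4)
        s = discriminative_variance_score(ep, "ch0")
        assert s == pytest.approx(1.0, abs=0.1)

    def test_zero_channel_scores_zero(self):
        ep = make_epochs(np.zeros((8, 1, 32)), np.arange(8) % 4)
        assert discriminative_variance_score(ep, "ch0") == 0.0

    def test_matches_hand_computed_formula(self, rng):
        data = rng.standard_normal((20, 2, 50))
        data[:5] *= 2.0  # double one class's variance
        labels = np.repeat(np.arange(4), 5)
        ep = make_epochs(data, labels)
        eps = 1e-10
        x = data[:, 1, :]
        pooled = np.var(x)
        expected = np.mean([
            np.mean([np.var(x[t]) for t in np.flatnonzero(labels == j)])
            / (pooled + eps) for j in range(4)])
        got = discriminative_variance_score(ep, "ch1", epsilon=eps)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_channel_and_empty_class_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            discriminative_variance_score(toy_epochs, "Oz")
        bad = make_epochs(np.ones((4, 1, 16)), [0, 0, 1, 1])
        bad.labels = np.array([0, 0, 0, 1])  # class 1 has a single trial
        with pytest.raises(ValueError):
            discriminative_variance_score(bad, "ch0")


class TestAnovaScore:
    def test_identical_groups_score_zero(self):
        block = np.tile(np.sin(np.linspace(0, 6, 32)), (3, 1, 1))
        data = np.concatenate([block] * 4)  # four identical groups
        ep = make_epochs(data, np.repeat(np.arange(4), 3))
        with pytest.warns(RuntimeWarning):
            assert anova_power_score(ep, "ch0") == 0.0

    def test_matches_closed_form_f_test(self, rng):
        # independent oracle: textbook one-way ANOVA + F survival function
        data = rng.standard_normal((40, 1, 100))
        data[rng.permutation(40)[:10]] += 0.3
        labels = np.arange(40) % 4
        ep = make_epochs(data, labels)
        p = trial_power(data[:, 0, :])
        groups = [p[labels == j] for j in range(4)]
        k, n = 4, len(p)
        grand = p.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / (k - 1)) / (ssw / (n - k))
        p_oracle = stats.f.sf(f, k - 1, n - k)
        assert anova_power_score(ep, "ch0") == pytest.approx(
            -np.log10(p_oracle), abs=1e-9)

    def test_score_is_minus_log10_p(self, rng):
        # planted mean shift: recover score = -log10(p) exactly
        data = rng.standard_normal((24, 1, 64))
        data[:6] *= 1.5
        labels = np.repeat(np.arange(4), 6)
        ep = make_epochs(data, labels)
        p = trial_power(data[:, 0, :])
        _, p_scipy = stats.f_oneway(*[p[labels == j] for j in range(4)])
        assert anova_power_score(ep, "ch0") == pytest.approx(
            -np.log10(p_scipy), abs=1e-12)


class TestFuseAndSelect:
    def _epochs(self, rng, n_ch=8):
        names = ["C3", "Cz", "C4"] + [f"x{i}" for i in range(n_ch - 3)]
        data = rng.standard_normal((24, n_ch, 64))
        data[:6, 3] *= 3.0  # make x0 discriminative
        return EpochSet(data, np.arange(24) % 4, names, 128.0)

    def test_core_channels_always_selected(self, rng):
        ep = self._epochs(rng)
        sel = ChannelSelector(k_total=5).fit(ep)
        assert set(["C3", "Cz", "C4"]) <= set(sel.selected_channels_)
        assert len(sel.selected_channels_) == 5

    def test_alpha_one_ranks_by_variance_score(self, rng):
        ep = self._epochs(rng)
        sel = ChannelSelector(k_total=6, alpha=1.0).fit(ep)
        t = sel.scores_
        by_fused = t.sort_values("rank")["channel"].tolist()
        by_var = t.sort_values("S_var_norm", ascending=False,
                               kind="stable")["channel"].tolist()
        assert by_fused == by_var

    def test_minmax_endpoints(self, rng):
        sel = ChannelSelector(k_total=6).fit(self._epochs(rng))
        for col in ("S_var_norm", "S_anova_norm"):
            assert sel.scores_[col].max() == pytest.approx(1.0)
            assert sel.scores_[col].min() == pytest.approx(0.0)
            assert sel.scores_[col].between(0, 1).all()

    def test_fused_is_convex_combination(self, rng):
        sel = ChannelSelector(k_total=6, alpha=0.3).fit(self._epochs(rng))
        t = sel.scores_
        assert np.allclose(t["S_fused"],
                           0.3 * t["S_var_norm"] + 0.7 * t["S_anova_norm"])

    def test_trial_order_invariance(self, rng):
        ep = self._epochs(rng)
        perm = rng.permutation(ep.n_trials)
        ep2 = EpochSet(ep.data[perm], ep.labels[perm], ep.channel_names, ep.fs)
        s1 = ChannelSelector(k_total=6).fit(ep).selected_channels_
        s2 = ChannelSelector(k_total=6).fit(ep2).selected_channels_
        assert s1 == s2

    def test_channel_order_invariance(self, rng):
        ep = self._epochs(rng)
        order = [0, 1, 2] + list(3 + rng.permutation(ep.n_channels - 3))
        ep2 = EpochSet(ep.data[:, order], ep.labels,
                       [ep.channel_names[i] for i in order], ep.fs)
        s1 = ChannelSelector(k_total=6).fit(ep).selected_channels_
        s2 = ChannelSelector(k_total=6).fit(ep2).selected_channels_
        assert set(s1) == set(s2)

    def test_constant_score_falls_back_to_other(self):
        # identical data in every candidate: variance scores all tie
        rng = np.random.default_rng(0)
        base = rng.standard_normal((24, 1, 64))
        data = np.concatenate([rng.standard_normal((24, 3, 64)),
                               np.repeat(base, 4, axis=1)], axis=1)
        names = ["C3", "Cz", "C4", "a", "b", "c", "d"]
        ep = EpochSet(data, np.arange(24) % 4, names, 128.0)
        sel = ChannelSelector(k_total=5).fit(ep)
        assert np.allclose(sel.scores_["S_var_norm"], 0.0)
        assert len(sel.selected_channels_) == 5

    def test_planted_erd_channels_recovered(self):
        # the generator plants class-dependent ERD on known non-core channels
        core = {"C3", "Cz", "C4"}
        erd = {0: {"CP3": (0.8, 0.7)}, 1: {"CP4": (0.8, 0.7)},
               2: {"FC3": (0.7, 0.6), "CPz": (0.6, 0.5)},
               3: {"FC4": (0.7, 0.6)}}
        spec = EEGSimSpec(erd_map=erd, noise_amp=1.0)
        planted = set(spec.planted_channels)
        assert planted == {"CP3", "CP4", "FC3", "FC4", "CPz"}
        ep = generate_mi_eeg(spec, 48, seed=3)
        filt = EpochSet(bandpass_filter(ep.data, ep.fs), ep.labels,
                        ep.channel_names, ep.fs)
        sel = ChannelSelector(k_total=15).fit(filt)
        assert planted <= set(sel.selected_channels_)
        assert core <= set(sel.selected_channels_)
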