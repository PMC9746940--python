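"""Split-plot ANOVA: oracle equivalence, identities, post-hocs, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gripshift import (MixedAnova, condition_correlations, mixed_anova,
                       partial_eta_sq, posthoc_ttests)


def _long_data(n_per_cell, rng, within=("w1", "w2", "w3"),
               between=("b1", "b2"), effects=None):
    """Random long-format split-plot data, one row per subject x within cell."""
    effects = effects or {}
    rows = []
    sid = 0
    for bcell in itertools.product(*[["a", "b"]] * len(between)):
        for _ in range(n_per_cell):
            sid += 1
            subj_eff = rng.normal(0, 1)
            for wcell in itertools.product(*[["a", "b"]] * len(within)):
                y = subj_eff + rng.normal(0, 1)
                for term, size in effects.items():
                    signs = 1.0
                    for f in term:
                        if f in within:
                            signs *= 1 if wcell[within.index(f)] == "a" else -1
                        else:
                            signs *= 1 if bcell[between.index(f)] == "a" else -1
                    y += size * signs
                row = {"subject": f"S{sid}", "y": y}
                row.update(dict(zip(within, wcell)))
                row.update(dict(zip(between, bcell)))
                rows.append(row)
    return pd.DataFrame(rows)


def _oracle_type3(data, dv, subject, within, between):
    """Nested-least-squares oracle for the split-plot decomposition.

    For each within-contrast stratum, the Type III SS of a term is the
    increase in residual SS when that term's column is dropped from the
    full sum-to-zero between model — computed here via explicit
    ``np.linalg.lstsq`` fits of full and reduced models, independently of
    the covariance-based formula in the implementation.
    """
    cells = data.pivot_table(index=subject, columns=list(within), values=dv)
    M = cells.to_numpy()
    n_cells = M.shape[1]
    codes = {}
    for k, f in enumerate(within):
        codes[f] = np.array([1.0 if c[k] == "a" else -1.0
                             for c in cells.columns]) if len(within) > 1 else \
            np.array([1.0 if c == "a" else -1.0 for c in cells.columns])
    first = data.drop_duplicates(subject).set_index(subject).loc[cells.index]
    bcodes = {f: np.where(first[f] == "a", 1.0, -1.0) for f in between}

    bterms = []
    for r in range(len(between) + 1):
        bterms += list(itertools.combinations(between, r))
    X = np.column_stack([
        np.prod([bcodes[f] for f in t], axis=0) if t else np.ones(len(M))
        for t in bterms])

    def sse(Xm, y):
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ beta
        return float(r @ r)

    out = {}
    wsubs = []
    for r in range(len(within) + 1):
        wsubs += list(itertools.combinations(within, r))
    for wsub in wsubs:
        c = np.ones(n_cells)
        for f in wsub:
            c = c * codes[f]
        y = M @ (c / np.sqrt(n_cells))
        full = sse(X, y)
        for j, bterm in enumerate(bterms):
            if not wsub and not bterm:
                continue
            reduced = sse(np.delete(X, j, axis=1), y)
            name = "*".join([*wsub, *bterm])
            out[name] = {"SS_effect": reduced - full, "SS_error": full}
    return out


class TestPartialEtaSq:
    @pytest.mark.parametrize("F,expected", [
        (23.81, 0.30), (158.07, 0.74), (92.49, 0.62),
        (207.19, 0.79), (21989.0, 1.00)])
    def test_reported_effect_sizes_follow_from_f(self, F, expected):
        """eta_p^2 = F df1/(F df1 + df2) at df = (1, 56), to two decimals."""
        assert round(partial_eta_sq(F, 1, 56), 2) == expected

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 1, 56) == 0.0

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 1, 56)


class TestMixedAnova:
    def test_emits_all_31_effects_with_df2_56(self):
        rng = np.random.default_rng(0)
        # published-design unbalanced groups: 20/20/10/10
        data = _long_data(20, rng)
        keep = []
        sizes = {("a", "a"): 20, ("a", "b"): 20, ("b", "a"): 10, ("b", "b"): 10}
        for (b1, b2), size in sizes.items():
            subs = data[(data.b1 == b1) & (data.b2 == b2)]["subject"].unique()
            keep += list(subs[:size])
        data = data[data["subject"].isin(keep)]
        res = MixedAnova(data, "y", "subject",
                         within=["w1", "w2", "w3"], between=["b1", "b2"]).fit()
        assert len(res.table) == 31
        assert (res.table["df1"] == 1).all()
        assert (res.table["df2"] == 56).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_least_squares_oracle(self, seed):
        """Type III SS decomposition equals explicit nested-model fits."""
        rng = np.random.default_rng(seed)
        data = _long_data(2, rng)
        res = MixedAnova(data, "y", "subject",
                         within=["w1", "w2", "w3"], between=["b1", "b2"]).fit()
        oracle = _oracle_type3(data, "y", "subject",
                               ("w1", "w2", "w3"), ("b1", "b2"))
        for name, want in oracle.items():
            got = res.get(name)
            assert got["SS_effect"] == pytest.approx(want["SS_effect"], abs=1e-8)
            assert got["SS_error"] == pytest.approx(want["SS_error"], abs=1e-8)

    def test_eta_identity_holds_for_every_effect(self):
        rng = np.random.default_rng(7)
        res = MixedAnova(_long_data(4, rng), "y", "subject",
                         within=["w1", "w2"], between=["b1"]).fit()
        for _, row in res.table.iterrows():
            assert row["eta_p2"] == pytest.approx(
                partial_eta_sq(row["F"], row["df1"], row["df2"]), abs=1e-12)
            assert row["eta_p2"] == pytest.approx(
                row["SS_effect"] / (row["SS_effect"] + row["SS_error"]),
                abs=1e-12)

    def test_pure_between_noise_gives_zero_within_f(self):
        """Identical within-cell means per subject leave no within variance."""
        rng = np.random.default_rng(2)
        rows = []
        for s in range(8):
            m = rng.normal()
            for w1 in "ab":
                for w2 in "ab":
                    rows.append({"subject": s, "b1": "a" if s < 4 else "b",
                                 "w1": w1, "w2": w2, "y": m})
        res = MixedAnova(pd.DataFrame(rows), "y", "subject",
                         within=["w1", "w2"], between=["b1"]).fit()
        for eff in ["w1", "w2", "w1*w2", "w1*b1", "w2*b1", "w1*w2*b1"]:
            assert res.get(eff)["F"] == pytest.approx(0.0, abs=1e-16)

    def test_total_ss_decomposes_on_balanced_data(self):
        rng = np.random.default_rng(5)
        data = _long_data(5, rng, within=("w1", "w2"), between=("b1",))
        res = MixedAnova(data, "y", "subject",
                         within=["w1", "w2"], between=["b1"]).fit(
            include_intercept=True)
        cells = data.pivot_table(index="subject", columns=["w1", "w2"],
                                 values="y").to_numpy()
        total = float(((cells - cells.mean()) ** 2).sum())
        # every stratum contributes its error SS once plus its effect SS;
        # the intercept effect is the grand-mean SS, excluded from the total
        strata = res.table.groupby("stratum")["SS_error"].first().sum()
        effects = res.table.loc[res.table.index != "(intercept)",
                                "SS_effect"].sum()
        assert effects + strata == pytest.approx(total, rel=1e-10)

    def test_type3_equals_type1_when_balanced(self):
        """With balanced between cells the SS type does not matter."""
        rng = np.random.default_rng(11)
        data = _long_data(5, rng, within=("w1",), between=("b1", "b2"))
        res = MixedAnova(data, "y", "subject", within=["w1"],
                         between=["b1", "b2"]).fit()
        # sequential (Type I) SS via successive orthogonal projections
        cells = data.pivot_table(index="subject", columns="w1", values="y")
        y = cells.to_numpy() @ (np.array([1.0, -1.0]) / np.sqrt(2))
        first = data.drop_duplicates("subject").set_index("subject")
        first = first.loc[cells.index]
        b1 = np.where(first["b1"] == "a", 1.0, -1.0)
        b2 = np.where(first["b2"] == "a", 1.0, -1.0)
        cols = [np.ones(len(y)), b1, b2, b1 * b2]
        names = ["w1", "w1*b1", "w1*b2", "w1*b1*b2"]
        sse_prev = float(y @ y)
        X = np.empty((len(y), 0))
        for name, col in zip(names, cols):
            X = np.column_stack([X, col])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(((y - X @ beta) ** 2).sum())
            assert res.get(name)["SS_effect"] == pytest.approx(
                sse_prev - sse, abs=1e-10)
            sse_prev = sse

    def test_agrees_with_pingouin_on_one_between_one_within(self):
        """Independent cross-check against pingouin's mixed ANOVA."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        data = _long_data(10, rng, within=("w1",), between=("b1",),
                          effects={("w1",): 0.4, ("w1", "b1"): 0.2})
        theirs = pg.mixed_anova(data=data, dv="y", within="w1",
                                subject="subject", between="b1")
        res = MixedAnova(data, "y", "subject", within=["w1"],
                         between=["b1"]).fit()
        for source, eff in [("b1", "b1"), ("w1", "w1"),
                            ("Interaction", "w1*b1")]:
            want = float(theirs.loc[theirs["Source"] == source, "F"].iloc[0])
            assert res.get(eff)["F"] == pytest.approx(want, rel=1e-6)

    def test_agrees_with_statsmodels_on_pure_within(self):
        """Independent cross-check against statsmodels AnovaRM."""
        sm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(8)
        data = _long_data(12, rng, within=("w1", "w2"), between=())
        theirs = sm.AnovaRM(data, "y", "subject",
                            within=["w1", "w2"]).fit().anova_table
        res = MixedAnova(data, "y", "subject", within=["w1", "w2"]).fit()
        for source, eff in [("w1", "w1"), ("w2", "w2"), ("w1:w2", "w1*w2")]:
            assert res.get(eff)["F"] == pytest.approx(
                float(theirs.loc[source, "F Value"]), rel=1e-6)

    def test_missing_cell_reported(self):
        rng = np.random.default_rng(3)
        data = _long_data(3, rng, within=("w1", "w2"), between=("b1",))
        data = data[~((data["subject"] == "S1") & (data["w1"] == "a"))]
        with pytest.raises(ValueError, match="incomplete"):
            MixedAnova(data, "y", "subject", within=["w1", "w2"],
                       between=["b1"]).fit()


class TestPosthoc:
    def test_identical_paired_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = posthoc_ttests([("same", x, x, True)])
        assert out["t"].iloc[0] == 0.0
        assert out["p_bonferroni"].iloc[0] == 1.0

    def test_bonferroni_multiplies_by_family_size(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = x + 0.8
        out = posthoc_ttests([("shift", x, y, True)], family_size=16)
        assert out["p_bonferroni"].iloc[0] == pytest.approx(
            min(1.0, 16 * out["p_raw"].iloc[0]))

    def test_welch_for_independent_groups(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 12)
        out = posthoc_ttests([("groups", a, b, False)])
        want = stats.ttest_ind(a, b, equal_var=False)
        assert out["t"].iloc[0] == pytest.approx(want.statistic)
        assert out["df"].iloc[0] == pytest.approx(want.df)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            posthoc_ttests([("bad", [1.0], [2.0], False)])


class TestConditionCorrelations:
    def _contrasts(self, rng, n=10, collinear=None):
        rows = []
        for g in ["RH-right", "RH-left", "LH-right", "LH-left"]:
            for cw in "LH":
                for ho in ("same", "different"):
                    for p in range(n):
                        x = rng.normal()
                        y = {1: x, -1: -x}.get(collinear, rng.normal())
                        rows.append({"participant": f"{g}-{p}", "group": g,
                                     "current_weight": cw, "hand_order": ho,
                                     "force_diff_GFR": x,
                                     "perceptual_bias": y})
        return pd.DataFrame(rows)

    def test_sixteen_strata_family(self):
        out = condition_correlations(self._contrasts(np.random.default_rng(0)),
                                     "force_diff_GFR")
        assert len(out) == 16
        assert (out["family_size"] == 16).all()

    @pytest.mark.parametrize("sign", [1, -1])
    def test_collinear_contrasts(self, sign):
        out = condition_correlations(
            self._contrasts(np.random.default_rng(1), collinear=sign),
            "force_diff_GFR")
        assert np.allclose(out["r"], sign)

    def test_independent_contrasts_rarely_survive_bonferroni(self):
        """Under the null ~0.8 of 16 strata reach p<.05 and ~none survive."""
        rng = np.random.default_rng(2)
        raw_hits = bonf_hits = 0
        for _ in range(40):
            out = condition_correlations(self._contrasts(rng), "force_diff_GFR")
            raw_hits += (out["p_raw"] < 0.05).sum()
            bonf_hits += (out["p_bonferroni"] < 0.05).sum()
        assert 10 <= raw_hits <= 60      # expectation 32 over 640 tests
        assert bonf_hits <= 3

    def test_zero_variance_stratum_rejected(self):
        c = self._contrasts(np.random.default_rng(3))
        c.loc[c["hand_order"] == "same", "force_diff_GFR"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            condition_correlations(c, "force_diff_GFR")
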