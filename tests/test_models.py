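"""Score construction, PCA, grouped CV, models, contributions, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import fingertap as ft
from fingertap.models import FamilyPCA, PCATransform


class TestCommonArmScore:
    def test_bars_scaling_reproduces_printed_means(self):
        # group-mean BARS arm scores map onto the printed unit-range means
        s = ft.ClinicalScores(bars_arm_dominant=1.32, bars_arm_nondominant=1.15)
        d, nd = ft.common_arm_score(s, "ataxia")
        assert d == pytest.approx(0.33, abs=1e-9)
        assert nd == pytest.approx(0.2875, abs=1e-9)
        assert round(nd, 2) == 0.29

    def test_zero_maps_to_zero(self):
        d, nd = ft.common_arm_score(ft.ClinicalScores(), "ataxia")
        assert d == 0.0 and nd == 0.0

    def test_control_always_zero(self):
        s = ft.ClinicalScores(bars_arm_dominant=3.0, updrs_arm_dominant=8)
        assert ft.common_arm_score(s, "control") == (0.0, 0.0)

    def test_parkinsonism_composite_divisor(self):
        s = ft.ClinicalScores(updrs_arm_dominant=6, updrs_arm_nondominant=3)
        d, nd = ft.common_arm_score(s, "parkinsonism")
        assert d == 0.5 and nd == 0.25
        d24, _ = ft.common_arm_score(s, "parkinsonism", updrs_divisor=24)
        assert d24 == 0.25

    def test_out_of_range_rejected(self):
        with pytest.raises(ft.ValidationError):
            ft.common_arm_score(ft.ClinicalScores(bars_arm_dominant=4.5), "ataxia")


def random_feature_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    cols, data = [], []
    for fam, p in (("TS", 8), ("Pk", 6), ("Th", 6), ("PkTh", 4), ("ThTh", 3)):
        for j in range(p):
            cols.append(f"{fam}.dominant.f{j}")
    latent = rng.normal(size=(n, 3))
    X = latent @ rng.normal(size=(3, len(cols))) + 0.3 * rng.normal(size=(n, len(cols)))
    return pd.DataFrame(X, columns=cols)


class TestFamilyPCA:
    def test_ten_columns_from_five_families(self):
        _, reduced = ft.fit_family_pca(random_feature_table())
        assert reduced.shape[1] == 10
        assert list(reduced.columns) == [
            f"{fam}_pc{c}" for fam in ("TS", "Pk", "Th", "PkTh", "ThTh") for c in (1, 2)
        ]

    def test_rank_one_family(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        df = pd.DataFrame({
            "TS.dominant.a": base, "TS.dominant.b": 2 * base + 1,
            "Pk.dominant.a": rng.normal(size=30), "Pk.dominant.b": rng.normal(size=30),
        })
        tf, _ = ft.fit_family_pca(df)
        evr = tf.families["TS"].explained_variance_ratio
        assert evr[0] == pytest.approx(1.0, abs=1e-9)
        assert evr[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        df = random_feature_table(seed=3)
        tf, reduced = ft.fit_family_pca(df)
        for fam, fp in tf.families.items():
            X = df[fp.columns].to_numpy()
            Z = (X - X.mean(0)) / X.std(0)
            C = Z.T @ Z / len(Z)  # correlation matrix of the family
            w, V = np.linalg.eigh(C)
            order = np.argsort(w)[::-1]
            V = V[:, order]
            for c in range(2):
                ours = reduced[f"{fam}_pc{c + 1}"].to_numpy()
                theirs = Z @ V[:, c]
                err = min(np.max(np.abs(ours - theirs)), np.max(np.abs(ours + theirs)))
                assert err < 1e-8

    def test_constant_column_dropped(self):
        df = random_feature_table(seed=4)
        df["TS.dominant.f0"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            tf, reduced = ft.fit_family_pca(df)
        assert "TS.dominant.f0" not in tf.families["TS"].columns
        assert reduced.shape[1] == 10

    def test_loadings_orthonormal(self):
        tf, _ = ft.fit_family_pca(random_feature_table(seed=5))
        for fp in tf.families.values():
            gram = fp.components @ fp.components.T
            assert np.allclose(gram, np.eye(2), atol=1e-8)


class TestGroupedFolds:
    def test_no_subject_spans_folds(self):
        rng = np.random.default_rng(0)
        subs = np.repeat([f"s{i}" for i in range(20)], rng.integers(1, 3, 20))
        folds = ft.grouped_folds(subs, k=10, seed=1)
        df = pd.DataFrame({"s": subs, "f": folds})
        assert (df.groupby("s")["f"].nunique() == 1).all()

    def test_leave_one_subject_out(self):
        subs = np.array([f"s{i}" for i in range(8)])
        folds = ft.grouped_folds(subs, k=8, seed=0)
        assert len(np.unique(folds)) == 8

    def test_default_cohort_fold_balance(self):
        # the full-size roster: 301 recordings over balanced 10 folds
        spec = ft.CohortSpec()
        rng = np.random.default_rng(2)
        subs = []
        for name, g in spec.groups.items():
            n_subjects = g.n_videos - g.n_repeat_videos
            for i in range(n_subjects):
                subs.extend([f"{name}{i}"] * (2 if i < g.n_repeat_videos else 1))
        subs = np.array(subs)
        assert len(subs) == 301
        folds = ft.grouped_folds(subs, k=10, seed=int(rng.integers(100)))
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 301
        assert np.all(np.abs(sizes - 301 / 10) <= 3)

    def test_too_few_subjects(self):
        with pytest.raises(ft.InsufficientDataError, match="smaller k"):
            ft.grouped_folds(np.array(["a", "b", "c"]), k=10)


class TestClassification:
    def test_separates_presets(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.classify(
            table, meta["group"], meta["subject_id"], contrast="ataxia_vs_control",
            penalty="l1", k=10, seed=0, positive_label="ataxia", n_bootstrap=100,
        )
        assert rep.metrics["auc"] >= 0.9
        assert 0 <= rep.metrics["auc"] <= 1
        lo, hi = rep.metrics["auc_ci"]
        assert lo <= rep.metrics["auc"] <= hi

    def test_deterministic(self, cohort_features):
        table, meta, _ = cohort_features
        kw = dict(penalty="l2", k=5, seed=3, positive_label="ataxia",
                  n_bootstrap=50, tune="fixed")
        r1 = ft.classify(table, meta["group"], meta["subject_id"], **kw)
        r2 = ft.classify(table, meta["group"], meta["subject_id"], **kw)
        assert r1.metrics == r2.metrics
        assert r1.oof.equals(r2.oof)

    def test_fold_conservation_and_grouping(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.classify(table, meta["group"], meta["subject_id"], k=10, seed=0,
                          positive_label="ataxia", n_bootstrap=0, tune="fixed")
        oof = rep.oof
        assert len(oof) == len(table)
        assert oof["prob_positive"].notna().all()
        assert (oof.groupby("subject_id")["fold"].nunique() == 1).all()

    def test_auc_invariant_to_monotone_transform(self, cohort_features):
        from sklearn.metrics import roc_auc_score
        table, meta, _ = cohort_features
        rep = ft.classify(table, meta["group"], meta["subject_id"], k=5, seed=1,
                          positive_label="ataxia", n_bootstrap=0, tune="fixed")
        y = (rep.oof["y_true"] == "ataxia").astype(int)
        p = rep.oof["prob_positive"].to_numpy()
        assert roc_auc_score(y, p) == pytest.approx(
            roc_auc_score(y, np.log(p / (1 - p + 1e-12) + 1e-12)), abs=1e-12
        )

    def test_no_leakage_from_test_rows(self, cohort_features):
        # permuting test-fold rows cannot change a training-fold transform
        table, meta, _ = cohort_features
        folds = ft.grouped_folds(meta["subject_id"].to_numpy(), k=5, seed=2)
        tr = folds != 0
        tf1, _ = ft.fit_family_pca(table[tr])
        shuffled = table.copy()
        te_idx = np.nonzero(~tr)[0]
        perm = np.random.default_rng(0).permutation(te_idx)
        shuffled.iloc[te_idx] = table.iloc[perm].to_numpy()
        tf2, _ = ft.fit_family_pca(shuffled[tr])
        for fam in tf1.families:
            assert np.array_equal(tf1.families[fam].components, tf2.families[fam].components)

    def test_bad_penalty_rejected(self, cohort_features):
        table, meta, _ = cohort_features
        with pytest.raises(ft.ParameterError):
            ft.classify(table, meta["group"], meta["subject_id"], penalty="elastic")


class TestRegression:
    def test_recovers_generative_severity(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.regress_severity(
            table, meta["severity_dominant"], meta["subject_id"],
            target="severity", k=10, seed=0, n_bootstrap=100,
        )
        assert rep.metrics["r"] >= 0.8
        assert rep.metrics["r2"] == pytest.approx(rep.metrics["r"] ** 2, abs=1e-12)

    def test_r2_is_square_of_r(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.regress_severity(table, meta["common_arm_dominant"],
                                  meta["subject_id"], k=5, seed=1,
                                  tune="fixed", n_bootstrap=0)
        assert rep.metrics["r2"] == rep.metrics["r"] ** 2

    def test_zero_variance_target_rejected(self, cohort_features):
        table, meta, _ = cohort_features
        with pytest.raises(ft.ParameterError):
            ft.regress_severity(table, pd.Series(np.zeros(len(table))),
                                meta["subject_id"])


class TestContributions:
    @staticmethod
    def _identity_transform(k=4):
        comps = np.eye(k)[:2]
        return PCATransform(families={
            "TS": FamilyPCA(columns=[f"TS.dominant.f{j}" for j in range(k)],
                            mean=np.zeros(k), std=np.ones(k), components=comps,
                            explained_variance_ratio=np.array([0.5, 0.5])),
        })

    def test_identity_loadings_return_weights(self):
        tf = self._identity_transform()
        coef = pd.Series({"TS_pc1": 2.0, "TS_pc2": -1.0})
        contrib = ft.feature_contributions(coef, tf)
        got = contrib.set_index("feature")["contribution"]
        assert got["TS.dominant.f0"] == 2.0
        assert got["TS.dominant.f1"] == -1.0
        assert got["TS.dominant.f2"] == 0.0

    def test_zero_coefficients_zero_contributions(self):
        tf = self._identity_transform()
        coef = pd.Series({"TS_pc1": 0.0, "TS_pc2": 0.0})
        contrib = ft.feature_contributions(coef, tf)
        assert (contrib["contribution"] == 0).all()

    def test_matches_algebraic_expansion_oracle(self):
        df = random_feature_table(seed=7)
        tf, reduced = ft.fit_family_pca(df)
        rng = np.random.default_rng(8)
        coef = pd.Series(rng.normal(size=10), index=reduced.columns)
        contrib = ft.feature_contributions(coef, tf).set_index("feature")["contribution"]
        # oracle: differentiate the composed linear model feature by feature
        for fam, fp in tf.families.items():
            for j, col in enumerate(fp.columns):
                expansion = sum(
                    coef[f"{fam}_pc{c + 1}"] * fp.components[c, j] for c in range(2)
                )
                assert abs(contrib[col] - expansion) < 1e-10

    def test_top_fraction_flagged(self):
        df = random_feature_table(seed=9)
        tf, reduced = ft.fit_family_pca(df)
        coef = pd.Series(np.ones(10), index=reduced.columns)
        contrib = ft.feature_contributions(coef, tf, top_fraction=0.02)
        assert contrib["top"].sum() == max(int(np.ceil(0.02 * len(contrib))), 1)

    def test_mismatched_transform_rejected(self):
        tf = self._identity_transform()
        with pytest.raises(ft.ParameterError):
            ft.feature_contributions(pd.Series({"Pk_pc1": 1.0}), tf)


class TestDiagnostics:
    def test_probability_severity_correlation_positive(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.classify(table, meta["group"], meta["subject_id"], k=5, seed=0,
                          positive_label="ataxia", n_bootstrap=0, tune="fixed")
        diag = ft.diagnostics(rep, meta["age"], meta["severity_dominant"])
        sev = diag.set_index("target").loc["severity"]
        assert sev["r"] > 0

    def test_constant_probabilities_undefined(self, cohort_features):
        table, meta, _ = cohort_features
        rep = ft.classify(table, meta["group"], meta["subject_id"], k=5, seed=0,
                          positive_label="ataxia", n_bootstrap=0, tune="fixed")
        rep.oof["prob_positive"] = 0.5
        rep.oof["y_true"] = "ataxia"
        diag = ft.diagnostics(rep, meta["age"])
        assert np.isnan(diag.iloc[0]["r"])
        assert "undefined" in diag.iloc[0]["note"]

    def test_welch_t_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(25, 3))
        b = rng.normal(0.8, 2, size=(35, 3))
        df = pd.DataFrame(np.vstack([a, b]), columns=["TS.d.x", "Pk.d.y", "Th.d.z"])
        labels = pd.Series(["g1"] * 25 + ["g2"] * 35)
        out = ft.group_tscores(df, labels).set_index("feature")
        for j, col in enumerate(df.columns):
            va, vb = a[:, j].var(ddof=1), b[:, j].var(ddof=1)
            t_hand = (a[:, j].mean() - b[:, j].mean()) / np.sqrt(va / 25 + vb / 35)
            assert abs(out.loc[col, "t"] - t_hand) < 1e-10

    def test_tscores_ranked_by_magnitude(self, cohort_features):
        table, meta, _ = cohort_features
        out = ft.group_tscores(table, meta["group"])
        mags = out["t"].abs().to_numpy()
        finite = mags[np.isfinite(mags)]
        assert np.all(np.diff(finite) <= 1e-12)


class TestContrasts:
    def test_masks(self):
        m = pd.DataFrame({
            "group": ["ataxia", "ataxia", "control", "parkinsonism"],
            "age": [30, 60, 40, 70],
            "common_arm_dominant": [0.1, 0.5, 0.0, 0.2],
        })
        assert ft.select_contrast(m, "ataxia_vs_control").tolist() == [True, True, True, False]
        assert ft.select_contrast(m, "mild_ataxia_vs_control").tolist() == [True, False, True, False]
        assert ft.select_contrast(m, "ataxia_vs_control_under45").tolist() == [True, False, True, False]
        assert ft.select_contrast(m, "ataxia_vs_parkinsonism_over45").tolist() == [False, True, False, True]
        with pytest.raises(ft.ParameterError):
            ft.select_contrast(m, "nope")
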