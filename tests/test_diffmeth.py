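import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from methdrift import diffmeth
from methdrift.core_io import BetaMatrix, SampleSheet
from methdrift.errors import DesignError, DomainError, ValidationError
from methdrift.preprocess import MValueMatrix, m_from_beta
from tests.conftest import paired_sheet


def _fits_from_sheet(sheet, values, probe_ids=None):
    probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
    m = MValueMatrix(probe_ids, sheet.sample_ids, values)
    design = diffmeth.build_design(sheet)
    return diffmeth.fit_per_probe(m, design), design


class TestBuildDesign:
    def test_rank_four_subjects_single_group(self):
        # 4 subjects x 2 timepoints, one group, no covariates -> rank 5
        sheet = paired_sheet(n_subjects=4, n_users=4)
        design = diffmeth.build_design(sheet, covariates=(), groups=("user",))
        assert design.rank == 5
        # brute-force elimination oracle on the raw (pre-drop) columns
        raw = np.column_stack([design.matrix] + [np.ones(8)])
        assert np.linalg.matrix_rank(raw) == 5

    def test_age_column_dropped_and_reported(self, sheet6):
        design = diffmeth.build_design(sheet6)
        assert "cov:age" in design.dropped
        assert all(not c.startswith("cov:age") for c in design.columns)

    def test_constant_covariate_dropped(self, sheet6):
        df = sheet6.frame.copy()
        df["extra"] = 1.0
        design = diffmeth.build_design(SampleSheet(df), covariates=("bmi", "extra"))
        assert "cov:extra" in design.dropped

    def test_missing_cell_raises(self):
        sheet = paired_sheet(n_subjects=4, n_users=4)  # no nonusers
        with pytest.raises(DesignError, match="nonuser"):
            diffmeth.build_design(sheet)

    def test_batch_aliased_with_group_raises(self, sheet6):
        df = sheet6.frame.copy()
        df["batch"] = df["aspirin"]  # batch == group
        with pytest.raises(DesignError, match="batch"):
            diffmeth.build_design(SampleSheet(df))

    def test_two_locations_rejected(self, small_bundle):
        with pytest.raises(DesignError):
            diffmeth.build_design(small_bundle.sheet)

    def test_full_column_rank(self, sheet6):
        design = diffmeth.build_design(sheet6)
        assert np.linalg.matrix_rank(design.matrix) == design.matrix.shape[1]


class TestFitPerProbe:
    def test_exact_linear_probe_zero_variance(self, sheet6):
        design = diffmeth.build_design(sheet6)
        coef = np.arange(design.rank, dtype=float)
        values = (design.matrix @ coef)[None, :].repeat(12, axis=0)
        m = MValueMatrix([f"p{i}" for i in range(12)], sheet6.sample_ids, values)
        fits = diffmeth.fit_per_probe(m, design)
        assert np.allclose(fits.sigma2, 0.0, atol=1e-18)

    def test_duplicated_probe_rows_identical_fits(self, sheet6):
        rng = np.random.default_rng(3)
        row = rng.normal(size=len(sheet6))
        values = np.vstack([row] * 10)
        fits, _ = _fits_from_sheet(sheet6, values)
        assert np.allclose(fits.coefficients[0], fits.coefficients[5])
        assert fits.sigma2[0] == pytest.approx(fits.sigma2[7])

    def test_matches_normal_equations_oracle(self, sheet6):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(50, len(sheet6)))
        fits, design = _fits_from_sheet(sheet6, values)
        X = design.matrix
        for i in range(50):
            oracle = np.linalg.solve(X.T @ X, X.T @ values[i])
            np.testing.assert_allclose(fits.coefficients[i], oracle, atol=1e-10)
            resid = values[i] - X @ oracle
            s2 = resid @ resid / (X.shape[0] - X.shape[1])
            assert fits.sigma2[i] == pytest.approx(s2, abs=1e-10)

    def test_df_must_be_positive(self):
        from methdrift.errors import FitError

        design = diffmeth.Design(
            matrix=np.eye(4),
            columns=[f"c{i}" for i in range(4)],
            dropped=[],
            sample_ids=[f"s{i}" for i in range(4)],
            contrasts={},
        )
        m = MValueMatrix(["p0"], design.sample_ids, np.zeros((1, 4)))
        with pytest.raises(FitError):
            diffmeth.fit_per_probe(m, design)


class TestEBayes:
    def test_all_variances_equal_gives_infinite_d0(self, sheet6):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(40, len(sheet6)))
        fits, _ = _fits_from_sheet(sheet6, values)
        fits.sigma2 = np.full_like(fits.sigma2, 0.25)
        params = diffmeth.squeeze_variances(fits.sigma2, fits.df_residual)
        assert np.isinf(params.d0)
        np.testing.assert_allclose(params.s2_post, 0.25, rtol=1e-10)

    def test_d0_zero_recovers_ordinary_t(self, sheet6):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(30, len(sheet6)))
        fits, design = _fits_from_sheet(sheet6, values)
        params = diffmeth.squeeze_variances(fits.sigma2, fits.df_residual, d0=0.0, s02=1.0)
        table = diffmeth.moderated_contrast(fits, design.contrasts["user"], params)
        c = design.contrasts["user"]
        unscaled = np.sqrt(c @ fits.xtx_inv @ c)
        ordinary_t = (fits.coefficients @ c) / (np.sqrt(fits.sigma2) * unscaled)
        np.testing.assert_allclose(table["t"].to_numpy(), ordinary_t, atol=1e-12)

    def test_posterior_between_prior_and_sample(self):
        s2 = np.array([0.01, 0.05, 0.2, 1.0])
        params = diffmeth.squeeze_variances(s2, df=10, d0=4.0, s02=0.05)
        lo = np.minimum(s2, 0.05)
        hi = np.maximum(s2, 0.05)
        assert np.all(params.s2_post >= lo - 1e-12)
        assert np.all(params.s2_post <= hi + 1e-12)
        expected = (4 * 0.05 + 10 * s2) / 14
        np.testing.assert_allclose(params.s2_post, expected, rtol=1e-12)

    def test_hyperparameter_recovery_single_seed(self):
        rng = np.random.default_rng(0)
        d0, s02, d = 4.0, 0.05, 10
        sigma_true = s02 * d0 / rng.chisquare(d0, size=5000)
        s2 = sigma_true * rng.chisquare(d, size=5000) / d
        d0_hat, s02_hat = diffmeth.estimate_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.3)
        assert s02_hat == pytest.approx(s02, rel=0.1)

    def test_monotone_in_estimate(self, sheet6):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(20, len(sheet6)))
        fits, design = _fits_from_sheet(sheet6, values)
        params, tables = diffmeth.ebayes_moderate(fits)
        table = tables["user"]
        # |t| ordering matches |estimate| ordering at equal posterior se
        same_se = table["se"].round(12).duplicated(keep=False)
        assert (np.sign(table["t"]) == np.sign(table["estimate"])).all()


class TestBHAdjust:
    def test_hand_worked_example(self):
        out = diffmeth.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diffmeth.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(12)
        p = rng.random(10_000)
        mine = diffmeth.bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, rtol=1e-12)  # 1-ulp product order

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(13)
        p = rng.random(400)
        mine = diffmeth.bh_adjust(p)
        n = len(p)
        order = np.argsort(p)
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        # step-up definition: adj_i = min over j with p_j >= p_i of n*p_j/rank_j
        oracle = np.array(
            [
                min(
                    min(n * p[j] / ranks[j] for j in range(n) if ranks[j] >= ranks[i]),
                    1.0,
                )
                for i in range(n)
            ]
        )
        np.testing.assert_allclose(mine, oracle, atol=1e-14)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(14)
        p = rng.random(200)
        adj = diffmeth.bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            diffmeth.bh_adjust([0.5, 1.5])


def _fit_table(probes, adj_p, change):
    return pd.DataFrame(
        {
            "probe_id": probes,
            "estimate": change,
            "adj_p": adj_p,
            "percent_change": change,
        }
    )


class TestClassify:
    def test_set_logic(self):
        probes = ["a", "b", "c", "d"]
        user = _fit_table(probes, [0.01, 0.2, 0.01, 0.9], [3.0, 1.0, -2.0, 0.5])
        nonuser = _fit_table(probes, [0.2, 0.01, 0.01, 0.9], [1.0, 4.0, 2.0, 0.5])
        cat = diffmeth.classify_dmcpgs(user, nonuser)
        assert list(cat.u["probe_id"]) == ["a"]
        assert cat.u["direction"].iloc[0] == "hyper"
        assert list(cat.nu["probe_id"]) == ["b"]
        assert list(cat.shared["probe_id"]) == ["c"]
        assert not set(cat.u["probe_id"]) & set(cat.nu["probe_id"])

    def test_zero_change_excluded_with_count(self):
        probes = ["a"]
        user = _fit_table(probes, [0.01], [0.0])
        nonuser = _fit_table(probes, [0.5], [0.0])
        cat = diffmeth.classify_dmcpgs(user, nonuser)
        assert len(cat.u) == 0 and cat.n_zero_change == 1

    def test_probe_mismatch(self):
        with pytest.raises(ValidationError):
            diffmeth.classify_dmcpgs(
                _fit_table(["a"], [0.1], [1.0]), _fit_table(["b"], [0.1], [1.0])
            )

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(20)
        probes = [f"p{i}" for i in range(50)]
        adj_u, adj_n = rng.random(50), rng.random(50)
        chg_u, chg_n = rng.normal(size=50), rng.normal(size=50)
        cat1 = diffmeth.classify_dmcpgs(
            _fit_table(probes, adj_u, chg_u), _fit_table(probes, adj_n, chg_n), alpha=0.3
        )
        perm = rng.permutation(50)
        cat2 = diffmeth.classify_dmcpgs(
            _fit_table([probes[i] for i in perm], adj_u[perm], chg_u[perm]),
            _fit_table([probes[i] for i in perm], adj_n[perm], chg_n[perm]),
            alpha=0.3,
        )
        assert set(cat1.u["probe_id"]) == set(cat2.u["probe_id"])
        assert set(cat1.nu["probe_id"]) == set(cat2.nu["probe_id"])


class TestMethylationChange:
    def test_equal_betas_zero_change(self, sheet6):
        beta = BetaMatrix(
            ["p0"], sheet6.sample_ids, np.full((1, len(sheet6)), 0.4)
        )
        out = diffmeth.methylation_change(beta, sheet6, ["p0"], "nonuser")
        assert out["percent_change"].iloc[0] == 0.0

    def test_ten_point_shift(self, sheet6):
        df = sheet6.frame
        values = np.where(df["timepoint"] == "t2", 0.5, 0.4)[None, :]
        beta = BetaMatrix(["p0"], sheet6.sample_ids, values)
        out = diffmeth.methylation_change(beta, sheet6, ["p0"], "long_term_user")
        assert out["percent_change"].iloc[0] == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self, sheet6):
        rng = np.random.default_rng(21)
        probes = [f"p{i}" for i in range(10)]
        beta = BetaMatrix(probes, sheet6.sample_ids, rng.random((10, len(sheet6))))
        out = diffmeth.methylation_change(beta, sheet6, probes, "nonuser")
        df = sheet6.frame
        for i, p in enumerate(probes):
            vals_t1, vals_t2 = [], []
            for _, row in df.iterrows():
                if row["aspirin"] != "nonuser":
                    continue
                v = beta.values[i, sheet6.sample_ids.index(row["sample_id"])]
                (vals_t1 if row["timepoint"] == "t1" else vals_t2).append(v)
            expected = 100 * (np.mean(vals_t2) - np.mean(vals_t1))
            assert out["percent_change"].iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_empty_group(self, sheet6):
        beta = BetaMatrix(["p0"], sheet6.sample_ids, np.zeros((1, len(sheet6))))
        df = sheet6.frame.copy()
        df = df[df["timepoint"] == "t1"]
        with pytest.raises(Exception):
            diffmeth.methylation_change(
                beta, SampleSheet(df), ["p0"], "nonuser"
            )


def _catalog(probes_u, probes_nu):
    def df(probes):
        return pd.DataFrame(
            {
                "probe_id": probes,
                "estimate": 1.0,
                "adj_p": 0.01,
                "percent_change": 1.0,
                "direction": "hyper",
            }
        )

    return diffmeth.LocationCatalog(u=df(probes_u), nu=df(probes_nu), shared=df([]))


class TestMethylationIndex:
    def test_constant_half(self, sheet6):
        beta = BetaMatrix(
            ["p0", "p1"], sheet6.sample_ids, np.full((2, len(sheet6)), 0.5)
        )
        mi = diffmeth.methylation_index(
            beta, sheet6, {"proximal": _catalog(["p0"], ["p1"])}
        )
        assert np.allclose(mi["mi"], 50.0)

    def test_two_probe_mean(self, sheet6):
        values = np.vstack(
            [np.full(len(sheet6), 0.2), np.full(len(sheet6), 0.4)]
        )
        beta = BetaMatrix(["p0", "p1"], sheet6.sample_ids, values)
        mi = diffmeth.methylation_index(
            beta, sheet6, {"proximal": _catalog(["p0"], ["p1"])}
        )
        assert np.allclose(mi["mi"], 30.0)

    def test_duplicate_probe_in_both_sets_counted_once(self, sheet6):
        values = np.vstack(
            [np.full(len(sheet6), 0.2), np.full(len(sheet6), 0.4)]
        )
        beta = BetaMatrix(["p0", "p1"], sheet6.sample_ids, values)
        mi = diffmeth.methylation_index(
            beta, sheet6, {"proximal": _catalog(["p0", "p1"], ["p1"])}
        )
        assert np.allclose(mi["mi"], 30.0)  # p1 not double-counted

    def test_empty_union_rejected(self, sheet6):
        beta = BetaMatrix(["p0"], sheet6.sample_ids, np.zeros((1, len(sheet6))))
        with pytest.raises(DomainError):
            diffmeth.methylation_index(beta, sheet6, {"proximal": _catalog([], [])})

    def test_switchers_excluded(self, small_bundle):
        cat = {"proximal": _catalog([small_bundle.beta.probe_ids[0]], [])}
        mi_excl = diffmeth.methylation_index(
            small_bundle.beta, small_bundle.sheet, cat, exclude_switchers=True
        )
        mi_incl = diffmeth.methylation_index(
            small_bundle.beta, small_bundle.sheet, cat, exclude_switchers=False
        )
        switchers = set(
            small_bundle.sheet.frame.loc[
                small_bundle.sheet.frame["switched_at_t2"], "subject_id"
            ]
        )
        assert not set(mi_excl["subject_id"]) & switchers
        assert set(mi_incl["subject_id"]) >= switchers


class TestPlantedRecovery:
    def test_planted_effects_recovered(self, small_bundle):
        from methdrift import preprocess

        sheet = small_bundle.sheet.location("proximal")
        beta = small_bundle.beta.subset_samples(sheet.sample_ids)
        m = preprocess.MValueMatrix.from_beta(beta)
        design = diffmeth.build_design(sheet)
        fits = diffmeth.fit_per_probe(m, design)
        params, tables = diffmeth.ebayes_moderate(fits)
        ut = diffmeth.probe_fit_table(tables["user"], beta, sheet, diffmeth.USER)
        nt = diffmeth.probe_fit_table(tables["nonuser"], beta, sheet, diffmeth.NONUSER)
        cat = diffmeth.classify_dmcpgs(ut, nt)
        truth = small_bundle.truth
        gain = set(truth.probes_of("nonuser_gain"))
        loss = set(truth.probes_of("user_loss"))
        nu_detected = set(cat.nu["probe_id"]) & gain
        u_detected = set(cat.u["probe_id"]) & loss
        # most planted probes are found in the right set with the right sign
        assert len(nu_detected) >= 0.7 * len(gain)
        assert len(u_detected) >= 0.7 * len(loss)
        nu_dirs = cat.nu.set_index("probe_id").loc[sorted(nu_detected), "direction"]
        assert (nu_dirs == "hyper").mean() >= 0.9
        u_dirs = cat.u.set_index("probe_id").loc[sorted(u_detected), "direction"]
        assert (u_dirs == "hypo").mean() >= 0.9
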