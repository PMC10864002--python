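import numpy as np
import pytest

from ifnsig import packaged_gmt
from ifnsig.core_io import ExpressionMatrix, GeneSet, SampleMetadata
from ifnsig.deconv import GroupProfile, SignatureMatrixRef
from ifnsig.nbboot import (
    DispersionTable,
    PanelConfig,
    alpha_from_moments,
    estimate_dispersion,
    run_dataset_panel,
    score_and_compare,
    simulate_replicates,
    stars,
)
from ifnsig.synthetic import BulkEffect, load_signature_matrix, simulate_bulk_cohort

import pandas as pd


def profile_from_values(values_per_gene, group="NR"):
    """Build a GroupProfile from raw per-gene value vectors (mean/CV oracle)."""
    genes, mus, cvs = [], [], []
    for i, vals in enumerate(values_per_gene):
        v = np.asarray(vals, float)
        genes.append(f"G{i}")
        mus.append(v.mean())
        cvs.append(v.std(ddof=1) / v.mean() if v.mean() > 0 else 0.0)
    return GroupProfile(group, "ct", genes, np.array(mus), np.array(cvs))


class TestEstimateDispersion:
    def test_worked_vector_poisson_floor(self):
        # {2,4,6}: mu=4, CV^2=0.25, 1/mu=0.25 -> alpha = 0
        d = estimate_dispersion(profile_from_values([[2, 4, 6]]))
        assert d.alpha[0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_vector_overdispersed(self):
        # {10,20,30,40}: mu=25, CV^2=(500/3)/625, 1/mu=0.04 -> alpha ~ 0.2267
        d = estimate_dispersion(profile_from_values([[10, 20, 30, 40]]))
        assert d.alpha[0] == pytest.approx(500 / 3 / 625 - 0.04, rel=1e-12)
        assert d.alpha[0] == pytest.approx(0.2267, abs=1e-4)

    def test_constant_values_clamped(self):
        d = estimate_dispersion(profile_from_values([[7, 7, 7, 7]]))
        assert d.alpha[0] == 0.0

    def test_zero_mean_gene_flagged_alpha_zero(self):
        prof = GroupProfile("NR", "ct", ["G0"], np.array([0.0]), np.array([0.0]))
        assert estimate_dispersion(prof).alpha[0] == 0.0

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError, match=">= 0"):
            alpha_from_moments(np.array([-1.0]), np.array([0.5]))

    def test_alpha_always_nonnegative(self, rng):
        mu = rng.uniform(0, 100, 200)
        cv = rng.uniform(0, 2, 200)
        assert (alpha_from_moments(mu, cv) >= 0).all()


class TestSimulateReplicates:
    def table(self, mu, alpha, group="NR"):
        mu = np.asarray(mu, float)
        alpha = np.asarray(alpha, float)
        cv = np.sqrt(np.where(mu > 0, 1 / np.maximum(mu, 1e-12) + alpha, 0.0))
        return DispersionTable(group, [f"G{i}" for i in range(len(mu))], mu, cv, alpha)

    def test_poisson_limit_variance(self):
        reps = simulate_replicates({"NR": self.table([50.0], [0.0])}, 10_000, seed=0)
        var = reps["NR"].values[0].var(ddof=1)
        assert abs(var - 50.0) / 50.0 < 0.1

    def test_nb_moment_formula(self):
        # Var = mu + alpha mu^2 = 50 + 0.3 * 2500 = 800
        reps = simulate_replicates({"NR": self.table([50.0], [0.3])}, 10_000, seed=1)
        var = reps["NR"].values[0].var(ddof=1)
        assert abs(var - 800.0) / 800.0 < 0.1

    def test_zero_mean_gene_all_zero(self):
        reps = simulate_replicates({"NR": self.table([0.0, 5.0], [0.2, 0.2])}, 50, seed=2)
        assert (reps["NR"].values[0] == 0).all()

    def test_alpha_recovery_within_15pct(self):
        # parameter-recovery invariant: moment re-estimation of alpha
        for mu0, a0, seed in ((20.0, 0.1, 0), (50.0, 0.3, 1), (200.0, 0.5, 2)):
            reps = simulate_replicates({"NR": self.table([mu0], [a0])}, 5000, seed=seed)
            x = reps["NR"].values[0]
            a_hat = (x.var(ddof=1) - x.mean()) / x.mean() ** 2
            assert abs(a_hat - a0) / a0 < 0.15

    def test_n_reps_validation(self):
        with pytest.raises(ValueError, match=">= 3"):
            simulate_replicates({"NR": self.table([5.0], [0.1])}, 2, seed=0)

    def test_deterministic(self):
        t = {"NR": self.table([5.0, 10.0], [0.1, 0.4])}
        a = simulate_replicates(t, 20, seed=3)["NR"].values
        b = simulate_replicates(t, 20, seed=3)["NR"].values
        np.testing.assert_array_equal(a, b)


def two_group_replicates(shift_genes=(), shift=1.0, n_reps=50, seed=0, n_genes=80):
    rng = np.random.default_rng(99)
    mu = rng.lognormal(3.0, 1.0, n_genes)
    alpha = rng.uniform(0.1, 0.5, n_genes)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    disp = {}
    for group in ("NR", "R"):
        m = mu.copy()
        if group == "R" and len(shift_genes):
            idx = [genes.index(g) for g in shift_genes]
            m[idx] *= 2.0**shift
        cv = np.sqrt(1 / m + alpha)
        disp[group] = DispersionTable(group, genes, m, cv, alpha)
    return simulate_replicates(disp, n_reps, seed), genes


class TestScoreAndCompare:
    def test_planted_shift_detected(self):
        sig_genes = tuple(f"G{i:03d}" for i in range(10))
        reps, _ = two_group_replicates(sig_genes, shift=1.0, seed=5)
        res = score_and_compare(reps, [GeneSet("sig", sig_genes)], "ds")[0]
        assert res.p_value < 0.01
        assert res.median_r > res.median_nr
        assert res.direction == "R>NR"

    def test_label_swap_antisymmetry(self):
        sig_genes = tuple(f"G{i:03d}" for i in range(10))
        reps, _ = two_group_replicates(sig_genes, shift=0.5, seed=6)
        res = score_and_compare(reps, [GeneSet("sig", sig_genes)], "ds")[0]
        swapped_input = {
            "NR": ExpressionMatrix(
                reps["R"].gene_ids,
                [s.replace("R_", "NR_") for s in reps["R"].sample_ids],
                reps["R"].values,
                layer=reps["R"].layer,
            ),
            "R": ExpressionMatrix(
                reps["NR"].gene_ids,
                [s.replace("NR_", "R_") for s in reps["NR"].sample_ids],
                reps["NR"].values,
                layer=reps["NR"].layer,
            ),
        }
        swapped = score_and_compare(swapped_input, [GeneSet("sig", sig_genes)], "ds")[0]
        n1 = len(res.scores_r)
        n2 = len(res.scores_nr)
        assert swapped.u_statistic == pytest.approx(n1 * n2 - res.u_statistic)

    def test_missing_signature_errors(self):
        reps, _ = two_group_replicates(seed=7)
        with pytest.raises(ValueError, match="no genes"):
            score_and_compare(reps, [GeneSet("absent", ("NOPE",))], "ds")

    def test_missing_group_errors(self):
        reps, _ = two_group_replicates(seed=8)
        with pytest.raises(ValueError, match="missing group"):
            score_and_compare({"NR": reps["NR"]}, [GeneSet("s", ("G000",))], "ds")


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, "NS"), (0.02, "NS"), (0.009, "*"), (0.0009, "**"), (0.00009, "***")],
    )
    def test_bins(self, p, expected):
        assert stars(p) == expected


@pytest.fixture(scope="module")
def ref_expr():
    return load_signature_matrix()


@pytest.fixture(scope="module")
def ref(ref_expr):
    return SignatureMatrixRef.from_expression(ref_expr)


class TestRunDatasetPanel:
    def make_panel(self, ref_expr, seed=0, n_datasets=3, n_planted=2):
        neut15 = packaged_gmt("neut_ifn15")[0]
        cohorts = []
        for d in range(n_datasets):
            planted = d < n_planted
            eff = BulkEffect(
                signature_genes=tuple(neut15.genes),
                shift_log2=1.0 if planted else 0.0,
                ifnhi_fraction_nr=0.05,
                ifnhi_fraction_r=0.20 if planted else 0.05,
            )
            b, m, _ = simulate_bulk_cohort(
                (10, 10), ref_expr, eff, 0.0, 1000 * seed + d,
                dataset=f"DS{d + 1}", concentration=5.0,
            )
            cohorts.append((b, m, f"DS{d + 1}"))
        return cohorts, [neut15]

    def test_malformed_cohort_isolated(self, ref_expr, ref):
        cohorts, sets = self.make_panel(ref_expr)
        bad_bulk = ExpressionMatrix(["X1"], ["s1", "s2"], np.ones((1, 2)), layer="cpm")
        bad_meta = SampleMetadata(
            pd.DataFrame(
                {"sample_id": ["s1", "s2"], "group": ["NR", "R"],
                 "dataset": ["bad", "bad"], "timing": ["PRE", "PRE"]}
            )
        )
        cohorts[1] = (bad_bulk, bad_meta, "DS2")
        panel = run_dataset_panel(cohorts, ref, sets, PanelConfig(n_reps=10, seed=0))
        assert set(panel.failures) == {"DS2"}
        assert {r.dataset for r in panel.results} == {"DS1", "DS3"}

    def test_deterministic(self, ref_expr, ref):
        cohorts, sets = self.make_panel(ref_expr)
        t1 = run_dataset_panel(cohorts, ref, sets, PanelConfig(n_reps=10, seed=4)).table()
        t2 = run_dataset_panel(cohorts, ref, sets, PanelConfig(n_reps=10, seed=4)).table()
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_datasets_starred(self, ref_expr, ref):
        cohorts, sets = self.make_panel(ref_expr, seed=1)
        panel = run_dataset_panel(cohorts, ref, sets, PanelConfig(n_reps=50, seed=1))
        by_ds = {r.dataset: r for r in panel.results}
        assert by_ds["DS1"].stars != "NS"
        assert by_ds["DS2"].stars != "NS"
        assert by_ds["DS3"].stars == "NS"

    def test_config_validation(self):
        with pytest.raises(ValueError, match=">= 3"):
            PanelConfig(n_reps=2)
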