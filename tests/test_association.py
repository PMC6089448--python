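import numpy as np
import pytest
from scipy import stats

from ataxmap.association import (
    AEigen,
    a_inverse_henderson,
    build_numerator_relationship,
    genotype_contrasts,
    reml_fit,
    significance_stars,
    solve_mme,
)
from ataxmap.errors import ModelError, PedigreeStructureError
from ataxmap.pedigree import Pedigree, PedigreeEntry
from ataxmap.sim.config import SimConfig
from ataxmap.sim.pedigree import simulate_pedigree


class TestNumeratorRelationship:
    def test_two_unrelated_founders(self):
        ped = Pedigree(
            [
                PedigreeEntry("a", None, None, "M", 0),
                PedigreeEntry("b", None, None, "F", 0),
            ]
        )
        a, order = build_numerator_relationship(ped)
        assert np.array_equal(a, np.eye(2))

    def test_textbook_closed_forms(self, nuclear_pedigree):
        a, order = build_numerator_relationship(nuclear_pedigree)
        i = {an: k for k, an in enumerate(order)}
        assert a[i["s"], i["c1"]] == 0.5          # parent-offspring
        assert a[i["c1"], i["c2"]] == 0.5         # full sibs
        assert a[i["g"], i["g"]] == 1.25          # offspring of full sibs
        assert a[i["s"], i["d"]] == 0.0
        for f in ("s", "d"):
            assert a[i[f], i[f]] == 1.0           # founder diagonal

    def test_symmetric_psd_with_unity_founder_diagonal(self):
        cfg = SimConfig(seed=8, n_founders=14, n_generations=4, generation_sizes=25)
        ped = simulate_pedigree(cfg)
        a, order = build_numerator_relationship(ped)
        assert np.allclose(a, a.T)
        eig = AEigen.from_matrix(a)  # raises on non-PSD
        assert eig.values.min() >= 0
        for f in ped.founders():
            assert a[order.index(f), order.index(f)] == 1.0
        for an in order:
            assert a[order.index(an), order.index(an)] >= 1.0

    def test_cyclic_pedigree_names_member(self):
        with pytest.raises(PedigreeStructureError, match="cycle"):
            Pedigree(
                [
                    PedigreeEntry("a", "c", None, "M", 0),
                    PedigreeEntry("b", "a", None, "M", 1),
                    PedigreeEntry("c", "b", None, "M", 2),
                ]
            )

    def test_henderson_inverse_matches_dense_inverse(self):
        cfg = SimConfig(seed=2, n_founders=10, n_generations=4, generation_sizes=20)
        ped = simulate_pedigree(cfg)
        a, order = build_numerator_relationship(ped)
        ainv, order2 = a_inverse_henderson(ped)
        assert order == order2
        assert np.abs(ainv @ a - np.eye(len(order))).max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_against_gene_dropping_oracle(self, seed):
        """A equals Monte-Carlo IBD allele sharing (small-scale check;
        the full 50-animal x 200k-drop version runs in acceptance)."""
        cfg = SimConfig(seed=seed, n_founders=6, n_generations=3, generation_sizes=8)
        ped = simulate_pedigree(cfg)
        a, order = build_numerator_relationship(ped)
        mc, se = gene_dropping_relationship(ped, order, n_drops=40_000, seed=seed)
        # 4 SE bound: ~100 entries are tested per pedigree, so a strict
        # 3-SE elementwise bound would fail by chance alone
        assert np.all(np.abs(mc - a) < 4 * se + 1e-9)
        assert np.mean(np.abs(mc - a) < 3 * se + 1e-9) > 0.97


def gene_dropping_relationship(ped, order, n_drops, seed):
    """Vectorized gene-dropping oracle: A_ij = 2 * P(random alleles IBD)."""
    rng = np.random.default_rng(seed)
    n = len(order)
    idx = {a: i for i, a in enumerate(order)}
    labels = np.zeros((n, 2, n_drops), dtype=np.int32)
    next_label = 1
    for animal in order:
        i = idx[animal]
        sire, dam = ped.parents(animal)
        for copy, parent in ((0, sire), (1, dam)):
            if parent is None:
                labels[i, copy, :] = next_label
                next_label += 1
            else:
                p = idx[parent]
                pick = rng.integers(0, 2, size=n_drops)
                labels[i, copy, :] = labels[p, pick, np.arange(n_drops)]
    a_mc = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = np.zeros(n_drops)
            for ci in range(2):
                for cj in range(2):
                    match += labels[i, ci] == labels[j, cj]
            stat = match / 2.0  # 2 * mean kinship indicator
            a_mc[i, j] = a_mc[j, i] = stat.mean()
            se[i, j] = se[j, i] = stat.std(ddof=1) / np.sqrt(n_drops)
    # the diagonal of the tabular A counts self-kinship with the same
    # convention: A_ii = 1 + F_i where F = P(the two own alleles IBD)
    for i in range(n):
        own = (labels[i, 0] == labels[i, 1]).mean()
        a_mc[i, i] = 1.0 + own
        se[i, i] = (labels[i, 0] == labels[i, 1]).std(ddof=1) / np.sqrt(n_drops)
    return a_mc, se


@pytest.fixture(scope="module")
def fitted_cohort():
    cfg = SimConfig(seed=21, n_founders=40, n_generations=4, generation_sizes=[150, 250, 360])
    ped = simulate_pedigree(cfg)
    a, order = build_numerator_relationship(ped)
    eig = AEigen.from_matrix(a)
    rng = np.random.default_rng(3)
    classes = rng.choice(["GG", "AG", "AA"], p=[0.757, 0.226, 0.017], size=len(order))
    sa2, se2 = 0.3 * 9.4**2, 0.7 * 9.4**2
    u = eig.sqrt_transform(rng.standard_normal(len(order))) * np.sqrt(sa2)
    e = rng.standard_normal(len(order)) * np.sqrt(se2)
    effect = np.where(classes == "AG", 1.6, np.where(classes == "AA", 0.5, 0.0))
    y = 63.0 + effect + u + e
    return y, classes, a, eig


class TestRemlFit:
    def test_ols_reduction(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        fit = reml_fit(y, classes, a_eig=eig, polygenic=False)
        gg, ag = y[classes == "GG"], y[classes == "AG"]
        assert fit.mu == pytest.approx(gg.mean(), abs=1e-9)
        assert fit.contrasts["AG-GG"].estimate == pytest.approx(
            ag.mean() - gg.mean(), abs=1e-9
        )
        assert fit.sigma_a2 == 0.0

    def test_fixed_lambda_matches_dense_gls_oracle(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        lam = 2.0
        fit = reml_fit(y, classes, a_eig=eig, fixed_lambda=lam)
        # independent dense solve: V = A + lam I (up to sigma_a2 scale)
        x = np.column_stack(
            [np.ones_like(y), (classes == "AG").astype(float), (classes == "AA").astype(float)]
        )
        v = a + lam * np.eye(len(y))
        vinv_x = np.linalg.solve(v, x)
        beta = np.linalg.solve(x.T @ vinv_x, vinv_x.T @ y)
        assert fit.mu == pytest.approx(beta[0], abs=1e-8)
        assert fit.contrasts["AG-GG"].estimate == pytest.approx(beta[1], abs=1e-8)
        assert fit.contrasts["AA-GG"].estimate == pytest.approx(beta[2], abs=1e-8)

    def test_mme_route_agrees(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        fit = reml_fit(y, classes, a_eig=eig)
        ainv = np.linalg.inv(a)
        beta, u = solve_mme(y, classes, ainv, fit.lam)
        assert abs(fit.mu - beta[0]) < 1e-8
        assert abs(fit.contrasts["AG-GG"].estimate - beta[1]) < 1e-8
        assert np.abs(fit.u - u).max() < 1e-6

    def test_optimum_beats_grid(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        fit = reml_fit(y, classes, a_eig=eig)
        for lam in np.exp(np.linspace(np.log(1e-3), np.log(1e3), 25)):
            grid_fit = reml_fit(y, classes, a_eig=eig, fixed_lambda=lam)
            assert (
                fit.log_restricted_likelihood
                >= grid_fit.log_restricted_likelihood - 1e-6
            )

    def test_variance_components_positive_and_plausible(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        fit = reml_fit(y, classes, a_eig=eig)
        assert fit.sigma_a2 > 0 and fit.sigma_e2 > 0
        total = fit.sigma_a2 + fit.sigma_e2
        assert 0.5 * 9.4**2 < total < 1.5 * 9.4**2

    def test_missing_genotype_class_dropped(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        classes2 = classes.copy()
        classes2[:10] = ""
        fit = reml_fit(y, classes2, a)
        assert fit.n == len(y) - 10

    def test_absent_class_non_estimable(self):
        rng = np.random.default_rng(0)
        n = 80
        classes = np.array(["GG"] * 60 + ["AG"] * 20)
        y = rng.normal(60, 7, size=n)
        fit = reml_fit(y, classes, np.eye(n))
        aa = fit.contrasts["AA-GG"]
        assert not aa.estimable
        assert "AA" in aa.reason
        table = genotype_contrasts(fit)
        row = table[table["contrast"] == "AA-GG"].iloc[0]
        assert not row["estimable"]

    def test_non_psd_matrix_raises(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ModelError):
            AEigen.from_matrix(bad)


class TestContrastTable:
    def test_two_se_contrast_p_value(self):
        # closed form: estimate exactly 2 SEs from zero -> p ~ 0.0455
        z = 2.0
        p = 2.0 * stats.norm.sf(z)
        assert p == pytest.approx(0.0455, abs=2e-4)
        assert significance_stars(p) == "*"

    def test_star_thresholds(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""
        assert significance_stars(None) == ""

    def test_table_has_bonferroni_and_note(self, fitted_cohort):
        y, classes, a, eig = fitted_cohort
        fit = reml_fit(y, classes, a_eig=eig)
        table = genotype_contrasts(fit, n_traits_tested=8)
        assert "p_bonferroni" in table.columns
        row = table[table["contrast"] == "AG-GG"].iloc[0]
        assert row["p_bonferroni"] >= row["p_value"]
        assert "approximate" in table.attrs["note"]
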