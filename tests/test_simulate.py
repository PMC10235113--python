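import numpy as np
import pytest

from divkit.phylosignal import fit_lambda, phylo_covariance
from divkit.simulate import (SimConfig, bat_trait_schema, simulate_communities,
                             simulate_dataset, simulate_linked_responses,
                             simulate_traits, simulate_tree)


class TestSimulateTree:
    def test_tip_count(self):
        tree = simulate_tree(97, "yule", 0)
        assert tree.n_tips == 97

    def test_yule_is_ultrametric(self):
        tree = simulate_tree(40, "yule", 1)
        _, C = phylo_covariance(tree)
        assert np.ptp(np.diag(C)) < 1e-9

    def test_seeded_determinism(self):
        a = simulate_tree(30, "yule", 5).as_newick()
        b = simulate_tree(30, "yule", 5).as_newick()
        assert a == b

    def test_genus_blocks_are_clades_of_relatives(self):
        from divkit.phylo import cophenetic

        tree = simulate_tree(40, "yule", 2, genus_size=5)
        D = cophenetic(tree)
        labels = D.species_ids
        same, diff = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                gi, gj = labels[i].split("_")[0], labels[j].split("_")[0]
                (same if gi == gj else diff).append(D.d[i, j])
        assert np.mean(same) < np.mean(diff)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(10, "birth_death", 0, birth_rate=1.0, death_rate=2.0)


class TestSimulateTraits:
    def test_degenerate_variance_rejected(self):
        tree = simulate_tree(10, "yule", 0)
        with pytest.raises(ValueError, match="sigma2"):
            simulate_traits(tree, 1.0, 0.0, 0)

    def test_tiny_variance_nearly_constant(self):
        tree = simulate_tree(10, "yule", 0)
        tt = simulate_traits(tree, 1.0, 1e-12, 0)
        col = tt.values["mass"].to_numpy(dtype=float)
        assert np.ptp(col) < 1e-3

    def test_brownian_traits_recovered_by_lambda_fit(self):
        tree = simulate_tree(80, "yule", 3)
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(8):
            tt = simulate_traits(tree, 1.0, 1.0, rng)
            ests.append(fit_lambda(tree, tt.values["mass"]).lambda_)
        assert np.mean(ests) == pytest.approx(1.0, abs=0.1)

    def test_iid_traits_recovered_as_no_signal(self):
        tree = simulate_tree(80, "yule", 3)
        rng = np.random.default_rng(4)
        ests = []
        for _ in range(8):
            tt = simulate_traits(tree, 0.0, 1.0, rng)
            ests.append(fit_lambda(tree, tt.values["mass"]).lambda_)
        assert np.mean(ests) == pytest.approx(0.0, abs=0.1)

    def test_categorical_trait_clade_biased(self):
        tree = simulate_tree(60, "yule", 6)
        tt = simulate_traits(tree, 1.0, 1.0, 6, clade_bias=0.95)
        feeding = tt.values["feeding_strategy"]
        genera = [s.split("_")[0] for s in tt.species_ids]
        import pandas as pd

        modal_share = pd.DataFrame({"g": genera, "f": feeding}).groupby("g")["f"] \
            .agg(lambda v: v.value_counts().iloc[0] / len(v))
        assert modal_share.mean() > 0.7


class TestSimulateCommunities:
    def test_richness_within_configured_bounds(self):
        cfg = SimConfig(seed=5, richness_range=(5, 43))
        cm, _ = simulate_communities(cfg, 5)
        assert cm.richness().min() >= 5
        assert cm.richness().max() <= 43

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=8)
        a, _ = simulate_communities(cfg, 8)
        b, _ = simulate_communities(cfg, 8)
        np.testing.assert_array_equal(a.abundance, b.abundance)

    def test_abundance_skew_singletons_dominate(self):
        # under the lognormal abundance model, singleton captures must be
        # more common than top-abundance captures
        cfg = SimConfig(seed=2)
        singles = maxima = 0
        for s in range(30):
            cm, _ = simulate_communities(cfg, np.random.default_rng(s))
            vals = cm.abundance[cm.abundance > 0]
            singles += (vals == 1).sum()
            maxima += (vals == vals.max()).sum()
        assert singles > maxima

    def test_richness_range_validation(self):
        with pytest.raises(ValueError, match="richness_range"):
            SimConfig(richness_range=(1, 200))


class TestLinkedResponses:
    def test_beta_family_in_unit_interval(self, full_study):
        y = simulate_linked_responses(
            "beta", dict(beta0=-1, beta1=0.05, phi=20),
            full_study.community.richness(), full_study.covariates, 0)
        assert np.all((y > 0) & (y < 1))

    def test_null_slope_uncorrelated_with_richness(self, full_study):
        S = full_study.community.richness()
        cors = []
        for s in range(100):
            y = simulate_linked_responses(
                "normal", dict(beta0=1, beta1=0.0, sigma=0.3),
                S, full_study.covariates, np.random.default_rng(s))
            cors.append(np.corrcoef(S, y)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_strong_slope_monotone_mean_response(self, full_study):
        S = full_study.community.richness()
        ys = np.mean([simulate_linked_responses(
            "beta", dict(beta0=-3, beta1=0.15, phi=200),
            S, full_study.covariates, np.random.default_rng(s))
            for s in range(50)], axis=0)
        order = np.argsort(S)
        assert np.corrcoef(S[order], ys[order])[0, 1] > 0.95


def test_generated_dataset_reconciles_cleanly(full_study):
    with np.errstate(all="raise"):
        ds = full_study.reconciled()
    assert ds.report.clean
    assert ds.community.n_sites == 20
    assert set(ds.traits.schema.categories) == {
        "foraging", "skull", "jaw", "body_size", "overall"}
    assert len(bat_trait_schema().quantitative_traits()) == 14


def test_simulated_study_files_roundtrip(tmp_path, small_study):
    from divkit.io import (read_community, read_covariates, read_traits,
                           read_tree, reconcile)

    small_study.to_dir(tmp_path)
    cm = read_community(tmp_path / "community.csv")
    tt, _ = read_traits(tmp_path / "traits.csv", tmp_path / "trait_schema.yaml")
    tree = read_tree(tmp_path / "tree.nwk")
    cov = read_covariates(tmp_path / "covariates.csv")
    ds = reconcile(cm, tt, tree, cov)
    np.testing.assert_allclose(ds.community.abundance,
                               small_study.reconciled().community.abundance)
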