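import numpy as np
import pandas as pd
import pytest

from rareburden.enrichment import (GeneRule, GeneSetSpec, carrier_proportion,
                                   compare_group_means, empirical_p,
                                   gene_set_scan, pooled_score, ratio,
                                   sample_matched_sets, set_burden_test,
                                   zygosity_equality_test)
from rareburden.firth import burden_test
from rareburden.collapse import gene_score
from rareburden.variant_sets import MISSLOF

from conftest import toy_cohort


@pytest.fixture(scope="module")
def pool_cohort():
    # 8 samples, 3 genes x 1 pLOF variant each (AF 1e-4 < 1e-3 default rule)
    G = np.array([
        [1, 0, 0],
        [1, 1, 0],   # carrier in two genes: union counts once
        [0, 2, 0],
        [0, 0, 1],
        [0, 0, 0],
        [0, 0, 0],
        [0, 0, 0],
        [0, 0, 0],
    ])
    return toy_cohort(G, chroms=["1", "2", "3"],
                      sexes=["F"] * 8,
                      status=["case"] * 4 + ["control"] * 4,
                      genes=["A", "B", "C"])


class TestPooledScore:
    def test_union_carrier_count(self, pool_cohort):
        spec = GeneSetSpec("s", ["A", "B", "C"])
        score = pooled_score(pool_cohort, spec)
        per_gene_carriers = set()
        for g, j in (("A", 0), ("B", 1), ("C", 2)):
            per_gene_carriers |= set(np.flatnonzero(pool_cohort.genotypes[:, j] > 0))
        assert int((score > 0).sum()) == len(per_gene_carriers)

    def test_codominant_pooling(self, pool_cohort):
        score = pooled_score(pool_cohort, GeneSetSpec("s", ["A", "B", "C"]))
        assert score.tolist() == [1, 1, 2, 1, 0, 0, 0, 0]

    def test_heterozygous_model_excludes_biallelic_only(self, pool_cohort):
        spec = GeneSetSpec("s", ["A", "B", "C"], model="heterozygous")
        score = pooled_score(pool_cohort, spec)
        assert score[2] == 0  # homozygous-only carrier not counted
        assert score[1] == 1

    def test_blof_override(self, pool_cohort):
        cohort = pool_cohort
        cohort.variants.loc["v0", "blof"] = "deleterious"
        spec = GeneSetSpec("s", ["A", "B"],
                           overrides={"A": GeneRule(blof_only=True),
                                      "B": GeneRule(blof_only=True)})
        score = pooled_score(cohort, spec)
        # only gene A's variant is proven LOF
        assert set(np.flatnonzero(score > 0)) == {0, 1}

    def test_override_must_reference_members(self):
        with pytest.raises(ValueError, match="non-member"):
            GeneSetSpec("s", ["A"], overrides={"B": GeneRule()})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetSpec("s", [])


class TestSetBurdenTest:
    def test_singleton_set_equals_single_gene_test(self, planted_x_cohort):
        cohort = planted_x_cohort
        rule = GeneRule(class_rule=MISSLOF, af_max=1e-2)
        spec = GeneSetSpec("only", ["XGENE"], default_rule=rule)
        pooled = set_burden_test(cohort, spec)
        ids = [vid for vid, row in
               cohort.variants[cohort.variants["gene"] == "XGENE"].iterrows()
               if row["vclass"] in ("pLOF", "missense") and row["gnomad_af"] < 1e-2]
        d, pl = cohort.dosages_for(ids)
        score = gene_score(d, pl, "codominant")
        single = burden_test(score, cohort.status, cohort.covariates())
        assert pooled.p == pytest.approx(single.p, rel=1e-9)
        assert pooled.odds_ratio == pytest.approx(single.odds_ratio, rel=1e-9)

    def test_empty_pool_is_skip_record(self, pool_cohort):
        spec = GeneSetSpec("s", ["A"], default_rule=GeneRule(af_max=1e-6))
        res = set_burden_test(pool_cohort, spec)
        assert res.skipped and "empty" in res.reason

    def test_planted_signal_pooling(self):
        # planting effects in 3 of 5 member genes: the pooled test should beat
        # the median single-gene p
        from rareburden.simulate import default_config, simulate_cohort
        from rareburden.scan import run_scan
        genes = {f"SG{i}": {"pLOF": 8e-3} for i in range(5)}
        cfg = default_config(
            n_cases=500, n_controls=500, n_null_genes=0, seed=31,
            carrier_freq=genes,
            planted_effects={f"SG{i}": ("codominant", 1.6) for i in range(3)},
            n_common_background=50)
        cohort = simulate_cohort(cfg)
        rule = GeneRule(af_max=1e-2)
        pooled = set_burden_test(cohort, GeneSetSpec("s", list(genes), default_rule=rule))
        singles = []
        for g in genes:
            res = set_burden_test(cohort, GeneSetSpec(g, [g], default_rule=rule))
            if not res.skipped:
                singles.append(res.p)
        assert pooled.p < np.median(singles)


class TestMatchedSets:
    def _features(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"pli": rng.uniform(0, 1, n),
                             "cones": rng.normal(0, 1, n)},
                            index=[f"g{i}" for i in range(n)])

    def test_infinite_tolerance_uniform(self):
        feats = self._features()
        sets = sample_matched_sets(["g0", "g1"], feats, R=5,
                                   tol_pli=np.inf, tol_cones=np.inf, seed=1)
        assert len(sets) == 5
        for s in sets:
            assert len(s) == 2 and len(set(s)) == 2
            assert not set(s) & {"g0", "g1"}

    def test_zero_tolerance_exact_features(self):
        feats = pd.DataFrame({"pli": [0.5, 0.5, 0.5, 0.9],
                              "cones": [0.0, 0.0, 0.0, 1.0]},
                             index=["t", "m1", "m2", "far"])
        sets = sample_matched_sets(["t"], feats, R=20, tol_pli=0.0,
                                   tol_cones=0.0, seed=2)
        assert all(s[0] in ("m1", "m2") for s in sets)

    def test_empty_pool_error_names_gene(self):
        feats = pd.DataFrame({"pli": [0.1, 0.9], "cones": [0.0, 5.0]},
                             index=["t", "far"])
        with pytest.raises(ValueError, match="'t'"):
            sample_matched_sets(["t"], feats, R=1, tol_pli=0.01, tol_cones=0.01)

    def test_deterministic_under_seed(self):
        feats = self._features()
        a = sample_matched_sets(["g0", "g1", "g2"], feats, R=4, seed=9,
                                tol_pli=np.inf, tol_cones=np.inf)
        b = sample_matched_sets(["g0", "g1", "g2"], feats, R=4, seed=9,
                                tol_pli=np.inf, tol_cones=np.inf)
        assert a == b

    def test_matching_preserves_feature_profile(self):
        feats = self._features(n=400, seed=3)
        targets = ["g0", "g1", "g2", "g3"]
        sets = sample_matched_sets(targets, feats, R=50, tol_pli=0.05,
                                   tol_cones=0.3, seed=4)
        t_mean = feats.loc[targets, "pli"].mean()
        null_means = [feats.loc[s, "pli"].mean() for s in sets]
        assert abs(np.mean(null_means) - t_mean) < 0.06


class TestEmpiricalP:
    def test_observed_smallest(self):
        assert empirical_p(1e-9, np.linspace(0.01, 1, 999)) == pytest.approx(1 / 1000)

    def test_observed_largest(self):
        assert empirical_p(1.0, np.linspace(0.01, 0.99, 99)) == 1.0

    def test_observed_at_median(self):
        nulls = np.linspace(0.001, 0.999, 999)
        p = empirical_p(np.median(nulls), nulls)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_add_one_floor(self):
        assert empirical_p(0.0, np.ones(7)) >= 1 / 8

    def test_no_replicates(self):
        with pytest.raises(ValueError):
            empirical_p(0.5, [])


class TestZygosityEquality:
    def _sim(self, seed, beta_het, beta_bi, n=600):
        rng = np.random.default_rng(seed)
        z = rng.choice([0, 1, 2], size=n, p=[0.8, 0.12, 0.08])
        het, bi = (z == 1).astype(float), (z == 2).astype(float)
        logit = -0.3 + beta_het * het + beta_bi * bi
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return het, bi, y

    def test_null_calibration(self):
        ps = []
        for seed in range(300):
            het, bi, y = self._sim(seed, 0.8, 0.8)
            ps.append(zygosity_equality_test(het, bi, y))
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_power_direction(self):
        ps = []
        for seed in range(40):
            het, bi, y = self._sim(seed, 0.2, 2.5)
            ps.append(zygosity_equality_test(het, bi, y))
        assert np.median(ps) < 0.05

    def test_requires_biallelic_carriers(self):
        het = np.array([1.0, 0, 0, 1])
        bi = np.zeros(4)
        with pytest.raises(ValueError, match="biallelic"):
            zygosity_equality_test(het, bi, np.array([1.0, 0, 1, 0]))

    def test_identical_columns_rejected(self):
        ind = np.array([1.0, 0, 1, 0, 0, 0])
        y = np.array([1.0, 1, 0, 0, 1, 0])
        with pytest.raises(ValueError):
            zygosity_equality_test(ind, ind, y)


class TestReportingOps:
    @pytest.mark.parametrize("n,d,expected", [
        (57, 3269, 1.7), (25, 3269, 0.8), (51, 3269, 1.6),
        (20, 2314, 0.9), (0, 100, 0.0), (1, 16, 6.3),  # 6.25 rounds half-up
    ])
    def test_carrier_proportion_half_up(self, n, d, expected):
        assert carrier_proportion(n, d) == expected

    def test_carrier_proportion_validation(self):
        with pytest.raises(ValueError):
            carrier_proportion(5, 4)

    def test_ratio_male_female(self):
        assert ratio(2314, 955) == 2.4
        assert ratio(542, 831) == 0.7

    def test_welch_identical_groups(self):
        a = np.arange(10.0)
        m_a, s_a, m_b, s_b, p = compare_group_means(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_welch_calibration(self):
        rng = np.random.default_rng(6)
        ps = [compare_group_means(rng.normal(size=30), rng.normal(size=30))[-1]
              for _ in range(400)]
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_welch_power(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            hits += compare_group_means(a, b)[-1] < 0.01
        assert hits >= 95

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            compare_group_means([1.0, 1.0], [2.0, 2.0])


class TestConfigLoading:
    def test_yaml_round_trip(self, tmp_path):
        from rareburden.enrichment import load_gene_set_config
        cfg = tmp_path / "set.yaml"
        cfg.write_text(
            "name: ifn\n"
            "genes: [A, B, C]\n"
            "model: recessive\n"
            "default_rule: {af_max: 0.001}\n"
            "overrides:\n"
            "  A: {blof_only: true}\n"
            "  B: {include_bp: true}\n"
            "R: 99\nseed: 3\ntol_pli: 0.2\n")
        spec, opts = load_gene_set_config(cfg)
        assert spec.name == "ifn" and spec.model == "recessive"
        assert spec.rule_for("A").blof_only
        assert spec.rule_for("B").include_bp
        assert spec.rule_for("C").af_max == 0.001
        assert opts == {"R": 99, "seed": 3, "tol_pli": 0.2}


class TestGeneSetScan:
    def test_empirical_p_respects_add_one_floor(self, planted_x_cohort):
        rule = GeneRule(class_rule=MISSLOF, af_max=1e-2)
        spec = GeneSetSpec("cand", ["XGENE"], default_rule=rule, model="recessive")
        res = gene_set_scan(planted_x_cohort, spec, R=19,
                            tol_pli=np.inf, tol_cones=np.inf, seed=5)
        assert res.empirical_p >= 1 / 20
        assert res.replicates == 19
        assert len(res.null_ps) == 19
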