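import numpy as np
import pandas as pd
import pytest

from ptmb.exceptions import ConfigurationError, ParameterError, ValidationError
from ptmb.io_formats import PathwayCollection
from ptmb.pathway_scoring import (
    build_mutation_frequency_matrix,
    gsva_scores,
    mann_whitney_u,
    select_pathways,
    test_pathway_response,
)

from _reference import gsva_reference, mannwhitney_enumeration
from conftest import make_cohort


class TestFrequencyMatrix:
    @pytest.fixture
    def cohort(self):
        return make_cohort(
            spec={
                "s1": ("R", [("gA", "missense_variant"), ("gA", "stop_gained"),
                             ("gB", "synonymous_variant")]),
                "s2": ("NR", [("gC", "missense_variant")]),
                "s3": ("NR", []),
            }
        )

    lengths = pd.Series({"gA": 1000, "gB": 2000, "gC": 4000})

    def test_per_mb_values(self, cohort):
        M = build_mutation_frequency_matrix(cohort, lengths=self.lengths)
        assert M.loc["s1", "gA"] == pytest.approx(2000.0)
        assert M.loc["s2", "gC"] == pytest.approx(250.0)
        # gB only has a synonymous record -> no column
        assert list(M.columns) == ["gA", "gC"]
        assert (M.loc["s3"] == 0).all()

    def test_count_and_binary_modes(self, cohort):
        C = build_mutation_frequency_matrix(cohort, mode="count")
        B = build_mutation_frequency_matrix(cohort, mode="binary")
        assert C.loc["s1", "gA"] == 2 and B.loc["s1", "gA"] == 1

    def test_per_mb_needs_lengths(self, cohort):
        with pytest.raises(ParameterError):
            build_mutation_frequency_matrix(cohort)
        with pytest.raises(ConfigurationError, match="gA"):
            build_mutation_frequency_matrix(
                cohort, lengths=pd.Series({"gC": 100})
            )


class TestGsvaScores:
    def toy_matrix(self):
        rng = np.random.default_rng(8)
        return pd.DataFrame(
            rng.poisson(2.0, size=(3, 4)).astype(float),
            index=["s1", "s2", "s3"],
            columns=["g1", "g2", "g3", "g4"],
        )

    @pytest.mark.parametrize("kcdf", ["ecdf", "gaussian", "poisson"])
    @pytest.mark.parametrize("es_mode", ["mx_diff", "two_sided_max"])
    def test_matches_reference_walk_small(self, kcdf, es_mode):
        M = self.toy_matrix()
        pw = PathwayCollection({"SET": ["g1", "g3"], "SINGLE": ["g4"]})
        E = gsva_scores(M, pw, kcdf=kcdf, es_mode=es_mode, seed=4)
        ref = gsva_reference(M, dict(pw.items()), kcdf=kcdf, es_mode=es_mode, seed=4)
        for name in pw:
            for s in M.index:
                assert E.loc[name, s] == pytest.approx(ref[(name, s)], abs=1e-10)

    def test_matches_reference_walk_50x20(self):
        rng = np.random.default_rng(19)
        M = pd.DataFrame(
            rng.gamma(1.0, 2.0, size=(20, 50)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"g{j}" for j in range(50)],
        )
        sets = {
            f"P{k}": list(rng.choice(M.columns, size=rng.integers(3, 12), replace=False))
            for k in range(5)
        }
        pw = PathwayCollection(sets)
        E = gsva_scores(M, pw, kcdf="ecdf", seed=2)
        ref = gsva_reference(M, dict(pw.items()), kcdf="ecdf", seed=2)
        for (name, s), v in ref.items():
            assert E.loc[name, s] == pytest.approx(v, abs=1e-10)

    def test_bounded_scores(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(rng.poisson(1.0, size=(10, 30)).astype(float))
        M.columns = [f"g{j}" for j in range(30)]
        pw = PathwayCollection({"A": [f"g{j}" for j in range(7)], "B": ["g8", "g9"]})
        for mode in ("mx_diff", "two_sided_max"):
            E = gsva_scores(M, pw, es_mode=mode, seed=0)
            assert (E.abs() <= 1.0 + 1e-12).all().all()

    def test_ecdf_invariant_under_monotone_transform(self):
        M = self.toy_matrix()
        pw = PathwayCollection({"SET": ["g1", "g3"]})
        E1 = gsva_scores(M, pw, kcdf="ecdf", seed=3)
        E2 = gsva_scores(np.exp(M / 3.0) * 5 + 1, pw, kcdf="ecdf", seed=3)
        assert np.array_equal(E1.to_numpy(), E2.to_numpy())

    def test_sample_permutation_permutes_columns(self):
        M = self.toy_matrix()
        pw = PathwayCollection({"SET": ["g1", "g3"]})
        E1 = gsva_scores(M, pw, seed=1)
        E2 = gsva_scores(M.loc[["s3", "s1", "s2"]], pw, seed=1)
        for s in M.index:
            assert E2[s].to_numpy() == pytest.approx(E1[s].to_numpy())

    def test_degenerate_inputs(self):
        M = self.toy_matrix()
        with pytest.raises(ConfigurationError, match="every matrix gene"):
            gsva_scores(M, PathwayCollection({"ALL": list(M.columns)}))
        with pytest.warns(UserWarning, match="no genes"):
            E = gsva_scores(
                M, PathwayCollection({"SET": ["g1"], "MISS": ["zz"]}), seed=0
            )
        assert list(E.index) == ["SET"]
        with pytest.raises(ConfigurationError), pytest.warns(UserWarning):
            gsva_scores(M, PathwayCollection({"MISS": ["zz"]}))
        with pytest.raises(ValidationError):
            gsva_scores(M.iloc[:2], PathwayCollection({"SET": ["g1"]}))

    def test_constant_gene_gaussian_fallback(self):
        M = self.toy_matrix()
        M["g1"] = 1.0
        with pytest.warns(UserWarning, match="constant gene"):
            E = gsva_scores(M, PathwayCollection({"SET": ["g1", "g2"]}),
                            kcdf="gaussian", seed=0)
        assert np.isfinite(E.to_numpy()).all()


class TestMannWhitney:
    def test_exact_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of 20 assignments as extreme

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == 1.0

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n1, n2 = rng.integers(2, 8, size=2)
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = mannwhitney_enumeration(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        import scipy.stats

        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(0.5, size=12)
            u, p = mann_whitney_u(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_label_swap_keeps_p(self):
        x, y = [3.0, 1.0, 4.0], [2.0, 6.0, 5.0, 7.0]
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)


class TestPathwayResponse:
    def test_direction_and_symmetry(self):
        E = pd.DataFrame(
            [[1.0, 2.0, 3.0, 0.1, 0.2, 0.3]],
            index=["PW"],
            columns=[f"s{i}" for i in range(6)],
        )
        resp = pd.Series(["R"] * 3 + ["NR"] * 3, index=E.columns)
        t = test_pathway_response(E, resp)
        assert t.loc[0, "direction"] == 1
        assert t.loc[0, "p_value"] == pytest.approx(0.1)
        flipped = test_pathway_response(E, resp.map({"R": "NR", "NR": "R"}))
        assert flipped.loc[0, "direction"] == -1
        assert flipped.loc[0, "p_value"] == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        E = pd.DataFrame([[1.0, 2.0, 3.0]], index=["PW"], columns=list("abc"))
        with pytest.raises(ValidationError):
            test_pathway_response(E, pd.Series(["R", "R", "R"], index=list("abc")))


class TestSelectPathways:
    def _tests(self, p, direction):
        return pd.DataFrame(
            {"pathway": ["PW"], "u": [0.0], "p_value": [p], "direction": [direction]}
        )

    def test_counting_rule(self):
        pw = PathwayCollection({"PW": ["gA", "gB"]})
        tables = {f"c{i}": self._tests(0.01, 1) for i in range(4)}
        tables |= {f"c{i}": self._tests(0.5, 1) for i in range(4, 6)}
        sel = select_pathways(tables, pw, min_datasets=4)
        assert sel.pp_pathways == ["PW"]
        assert sel.pp_genes == {"gA", "gB"}
        # significant in only 2 cohorts -> none
        tables2 = {f"c{i}": self._tests(0.01, 1) for i in range(2)}
        tables2 |= {f"c{i}": self._tests(0.9, 1) for i in range(2, 6)}
        sel2 = select_pathways(tables2, pw, min_datasets=4)
        assert sel2.pp_pathways == [] and sel2.table.loc[0, "label"] == "none"

    def test_np_side_and_gene_union(self):
        pw = PathwayCollection({"A": ["g1", "g2"], "B": ["g2", "g3"]})
        t = pd.DataFrame(
            {
                "pathway": ["A", "B"],
                "u": [0.0, 0.0],
                "p_value": [0.01, 0.01],
                "direction": [-1, -1],
            }
        )
        sel = select_pathways({f"c{i}": t for i in range(4)}, pw, min_datasets=4)
        assert sel.np_pathways == ["A", "B"]
        assert sel.np_genes == {"g1", "g2", "g3"}

    def test_limiting_behavior_alpha_one(self):
        pw = PathwayCollection({"PW": ["gA"]})
        tables = {"c1": self._tests(0.99, 1)}
        sel = select_pathways(tables, pw, alpha=1.0, min_datasets=1)
        assert sel.pp_pathways == ["PW"]

    def test_too_few_cohorts(self):
        pw = PathwayCollection({"PW": ["gA"]})
        with pytest.raises(ValidationError):
            select_pathways({"c1": self._tests(0.01, 1)}, pw, min_datasets=4)


def test_planted_pathway_recovery_single_run(default_sim):
    """Default-condition simulation: planted PP pathways dominate selection."""
    from ptmb.pathway_scoring import (
        build_mutation_frequency_matrix,
        gsva_scores,
        select_pathways,
        test_pathway_response,
    )

    sim = default_sim
    tables = {}
    for cohort in sim.cohorts:
        M = build_mutation_frequency_matrix(cohort, lengths=sim.lengths)
        E = gsva_scores(M, sim.pathways, seed=11)
        tables[cohort.name] = test_pathway_response(E, cohort.response_series())
    sel = select_pathways(tables, sim.pathways, min_datasets=4)
    planted = set(sim.manifest["planted_pp"])
    assert sum(p in planted for p in sel.pp_pathways) >= 9
    assert sum(p not in planted for p in sel.pp_pathways) == 0
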