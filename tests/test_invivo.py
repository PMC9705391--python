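"""Subsampling rule, module scoring, anchor normalization and ANOVA."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from organovasc import cluster, invivo
from organovasc.errors import ConfigurationError, DegenerateNormalizationError
from organovasc.simulate import simulate_ec_groups


def _cells(n, n_genes=20, seed=0, prefix="c"):
    rng = np.random.default_rng(seed)
    return ad.AnnData(
        X=sp.csr_matrix(rng.poisson(2.0, size=(n, n_genes)) + 1.0),
        obs=pd.DataFrame(index=[f"{prefix}{i}" for i in range(n)]),
        var=pd.DataFrame(index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene")),
    )


class TestSubsampleMonolayer:
    @pytest.mark.parametrize(
        "n_network,target", [(280, 300), (100, 300), (450, 300), (451, 600), (700, 600)]
    )
    def test_target_selection(self, n_network, target):
        pool = _cells(1000)
        out = invivo.subsample_monolayer(pool, n_network, seed=0)
        assert out.n_obs == target

    def test_tie_goes_to_300(self):
        out = invivo.subsample_monolayer(_cells(1000), 450, seed=0)
        assert out.n_obs == 300

    def test_insufficient_cells_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="using all"):
            out = invivo.subsample_monolayer(_cells(120), 280, seed=0)
        assert out.n_obs == 120

    def test_seed_reproducibility(self):
        pool = _cells(1000)
        a = invivo.subsample_monolayer(pool, 280, seed=3)
        b = invivo.subsample_monolayer(pool, 280, seed=3)
        assert list(a.obs_names) == list(b.obs_names)


class TestJointEmbed:
    def test_copied_groups_coembed(self):
        base = _cells(80, n_genes=40, seed=1)
        both = ad.concat({"MONO_2D": base, "IN_VIVO": base}, label="group", index_unique="-")
        emb = invivo.joint_embed(both, n_comps=5, n_hvg=40)
        g = both.obs["group"].to_numpy()
        c1, c2 = emb[g == "MONO_2D"].mean(0), emb[g == "IN_VIVO"].mean(0)
        assert np.allclose(c1, c2, atol=1e-8)

    def test_no_shared_hvgs_raises(self):
        a = _cells(30, n_genes=10, seed=2)
        b = _cells(30, n_genes=10, seed=3)
        b.var_names = [f"other{i}" for i in range(10)]
        both = ad.concat({"A": a, "B": b}, label="group", index_unique="-", join="outer")
        both.X = sp.csr_matrix(np.nan_to_num(np.asarray(both.X.todense())) + 1.0)
        with pytest.raises(ConfigurationError):
            # disjoint gene spaces: each group's HVGs sit on its own genes
            invivo.joint_embed(both, n_comps=3, n_hvg=5)

    def test_planted_groups_mix_in_embedding(self):
        groups = simulate_ec_groups(
            organ="skin", seed=4, n_genes=300, n_invivo=150, n_network=120, n_mono=150
        )
        emb = invivo.joint_embed(groups, n_comps=10)
        g = groups.obs["group"].to_numpy()
        # per-group standardization removes the program shift: neighbor sets
        # should mix the groups rather than segregate them
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=11).fit(emb)
        _, idx = nn.kneighbors(emb)
        ent = []
        for row in idx[:, 1:]:
            p = pd.Series(g[row]).value_counts(normalize=True)
            ent.append(-(p * np.log(p)).sum())
        assert np.mean(ent) > 0.5  # max possible is log(3) ~ 1.10


class TestModuleScore:
    def test_self_control_scores_near_zero(self):
        norm = cluster.normalize_log1p(_cells(60, n_genes=30, seed=5))
        scores = invivo.module_score(
            norm, list(norm.var_names), n_bins=1, n_ctrl=1000, seed=0
        )
        assert np.abs(scores).max() < 1e-10  # controls are the full gene set

    def test_planted_program_scores_higher(self):
        groups = simulate_ec_groups(organ="skin", seed=6, n_genes=300, n_invivo=200,
                                    n_network=150, n_mono=200)
        norm = cluster.normalize_log1p(groups)
        program = list(norm.var_names[norm.var.in_program])
        scores = invivo.module_score(norm, program, seed=0)
        g = norm.obs["group"].to_numpy()
        assert scores[g == "IN_VIVO"].mean() > scores[g == "MONO_2D"].mean()

    def test_seed_determinism(self):
        norm = cluster.normalize_log1p(_cells(40, n_genes=30, seed=7))
        s1 = invivo.module_score(norm, ["g0", "g5"], seed=9)
        s2 = invivo.module_score(norm, ["g0", "g5"], seed=9)
        assert np.array_equal(s1, s2)

    def test_empty_intersection_raises(self):
        norm = cluster.normalize_log1p(_cells(10, n_genes=5, seed=8))
        with pytest.raises(ConfigurationError):
            invivo.module_score(norm, ["absent1", "absent2"])


class TestNormalizeScore:
    def _raw(self, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.array(
            ["MONO_2D"] * 50 + ["NETWORK_3D"] * 40 + ["IN_VIVO"] * 60
        )
        raw = rng.normal(size=len(groups)) + (groups == "IN_VIVO") * 3.0
        return raw, groups

    def test_anchor_means_exact(self):
        raw, groups = self._raw()
        out = invivo.normalize_score(raw, groups)
        assert out.loc[out.group == "MONO_2D", "normalized_score"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.loc[out.group == "IN_VIVO", "normalized_score"].mean() == pytest.approx(100.0, abs=1e-9)

    def test_affine_equivariance(self):
        raw, groups = self._raw(1)
        out1 = invivo.normalize_score(raw, groups)
        out2 = invivo.normalize_score(3.7 * raw - 11.0, groups)
        assert np.allclose(
            out1.normalized_score.to_numpy(), out2.normalized_score.to_numpy(), atol=1e-8
        )

    def test_coincident_anchors_raise(self):
        groups = np.array(["MONO_2D"] * 5 + ["NETWORK_3D"] * 5 + ["IN_VIVO"] * 5)
        with pytest.raises(DegenerateNormalizationError):
            invivo.normalize_score(np.ones(15), groups)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        raw=hnp.arrays(
            np.float64,
            30,
            elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
        ),
        scale=st.floats(0.1, 20),
        shift=st.floats(-30, 30),
    )
    def test_anchor_pinning_holds_for_any_raw_scores(self, raw, scale, shift):
        """Property: anchors sit at 0/100 and any affine remap of the raw
        scores leaves the normalized scores unchanged."""
        groups = np.array(["MONO_2D"] * 10 + ["NETWORK_3D"] * 10 + ["IN_VIVO"] * 10)
        if abs(raw[:10].mean() - raw[20:].mean()) < 1e-6:
            raw = raw + np.r_[np.zeros(20), np.ones(10)]  # separate the anchors
        out = invivo.normalize_score(raw, groups)
        assert out.loc[out.group == "MONO_2D", "normalized_score"].mean() == pytest.approx(0.0, abs=1e-7)
        assert out.loc[out.group == "IN_VIVO", "normalized_score"].mean() == pytest.approx(100.0, abs=1e-7)
        out2 = invivo.normalize_score(scale * raw + shift, groups)
        assert np.allclose(
            out.normalized_score.to_numpy(), out2.normalized_score.to_numpy(), atol=1e-6
        )


class TestAnovaOneway:
    def test_equal_group_means_f_zero(self):
        g = np.array([2.0, 2.0, 2.0])
        F, p = invivo.anova_oneway(g, g.copy(), g.copy())
        assert F == 0.0 and p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(loc=i * 0.3, size=n) for i, n in enumerate((12, 20, 17))]
        F, p = invivo.anova_oneway(*groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=10) for _ in range(3)]
        F1, _ = invivo.anova_oneway(*groups)
        F2, _ = invivo.anova_oneway(*[5.0 * g - 2.0 for g in groups])
        assert F1 == pytest.approx(F2, rel=1e-12)

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            invivo.anova_oneway(np.array([1.0]), np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def result():
    groups = simulate_ec_groups(organ="skin", seed=12, n_genes=400,
                                n_invivo=300, n_network=250, n_mono=800)
    return invivo.invivo_similarity(groups, seed=12)


class TestInvivoSimilarity:

    def test_network_mean_between_anchors(self, result):
        m = result.group_means
        assert 0.0 < m["NETWORK_3D"] < 100.0

    def test_program_genes_recovered(self, result):
        assert sum("IVP" in g for g in result.program_genes) >= 18

    def test_groups_differ_by_anova(self, result):
        assert result.anova_p < 0.05

    def test_missing_group_rejected(self):
        groups = simulate_ec_groups(organ="skin", seed=13, n_genes=400,
                                    n_invivo=50, n_network=50, n_mono=50)
        sub = groups[groups.obs.group != "IN_VIVO"].copy()
        with pytest.raises(ConfigurationError, match="missing"):
            invivo.invivo_similarity(sub)

    def test_subsample_size_does_not_move_anchors(self):
        # a different monolayer pool size changes the subsample but the
        # anchor means stay pinned by construction
        groups = simulate_ec_groups(organ="heart", seed=14, n_genes=300,
                                    n_invivo=200, n_network=100, n_mono=900)
        res = invivo.invivo_similarity(groups, seed=14)
        m = res.scores.groupby("group")["normalized_score"].mean()
        assert m["MONO_2D"] == pytest.approx(0.0, abs=1e-9)
        assert m["IN_VIVO"] == pytest.approx(100.0, abs=1e-9)
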