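"""Marker screening: target sets, MWW tests, unsupervised RF, MDS, assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evsubtype.io import AbundanceMatrix
from evsubtype.screening import (
    CandidateSelection,
    assemble_candidates,
    mds_embed,
    mww_screen,
    mww_test,
    screen_cohort1,
    select_targets,
    unsupervised_rf,
)

from conftest import make_annotations


class TestSelectTargets:
    def test_intersection_union_rule(self):
        out = select_targets(
            ls={"a", "b", "c"}, ep={"b", "d"}, pb={"c", "e"}, manual={"f"}
        )
        assert out == {"b", "c", "f"}

    def test_manual_only(self):
        assert select_targets(set(), set(), set(), {"x"}) == {"x"}

    def test_all_sets_equal(self):
        ls = {"a", "b"}
        assert select_targets(ls, ls, ls, {"m"}) == {"a", "b", "m"}


def brute_force_mww_p(x, y):
    """Independent oracle: double-loop U over every group assignment."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(g1, g2):
        u = 0.0
        for a in g1:
            for b in g2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mu = n1 * len(y) / 2.0
    u_obs = u_stat(x, y)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(g1, g2) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMWWTest:
    def test_separated_samples_exact_p(self):
        res = mww_test([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_multisets_give_p_one(self):
        res = mww_test([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.p == 1.0

    def test_empty_group_not_computable(self):
        res = mww_test([1.0, np.nan], [np.nan, np.nan])
        assert not res.computable

    def test_missing_values_dropped(self):
        a = mww_test([1, 2, 3, np.nan], [4, 5, 6])
        b = mww_test([1, 2, 3], [4, 5, 6])
        assert a.p == b.p

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 7, size=2)
        # integer values force ties
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        assert mww_test(x, y).p == pytest.approx(brute_force_mww_p(x, y))

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_branch_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        ours = mww_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue)
        assert ours.u == pytest.approx(ref.statistic)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(1.0, 1, size=20)
        res = mww_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)


def _screen_inputs(seed=0, n_per_group=10, planted_fc=1.0):
    """Cohort-1-shaped matrix with an optional planted Stage IV effect on p1."""
    rng = np.random.default_rng(seed)
    groups = {"HC1": n_per_group, "HC2": n_per_group,
              "StageI": n_per_group, "StageIV": n_per_group}
    cols, rows_ann = [], []
    data = {}
    for g, n in groups.items():
        for j in range(n):
            sid = f"{g}-{j}"
            cols.append(sid)
            rows_ann.append({"sample_id": sid, "group": g})
    values = rng.lognormal(mean=5, sigma=0.3, size=(6, len(cols)))
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(6)], columns=cols)
    if planted_fc != 1.0:
        s4 = [c for c in cols if c.startswith("StageIV")]
        df.loc["p1", s4] *= planted_fc
    return AbundanceMatrix(df), make_annotations(rows_ann)


class TestMWWScreen:
    def test_planted_stage_effect_gains_provenance_b(self):
        hits = 0
        for seed in range(10):
            m, ann = _screen_inputs(seed=seed, n_per_group=15, planted_fc=3.0)
            sel = mww_screen(m, ann)
            hits += "B" in sel.table.loc["p1", "provenance"]
        assert hits >= 9

    def test_feature_missing_in_one_group_skips_those_comparisons(self):
        m, ann = _screen_inputs(seed=1)
        stage1 = [s for s in m.sample_ids if s.startswith("StageI-")]
        df = m.data.copy()
        df.loc["p2", stage1] = np.nan
        sel = mww_screen(AbundanceMatrix(df), ann)
        assert np.isnan(sel.table.loc["p2", "p_A"])
        assert np.isnan(sel.table.loc["p2", "p_C"])
        assert not np.isnan(sel.table.loc["p2", "p_B"])

    def test_required_group_absent_is_error(self):
        m, ann = _screen_inputs()
        ann = ann[ann["group"] != "HC2"]
        with pytest.raises(ValueError, match="HC2"):
            mww_screen(m, ann)

    def test_selection_monotone_in_alpha(self):
        m, ann = _screen_inputs(seed=3, planted_fc=2.0)
        loose = set(mww_screen(m, ann, alpha=0.2).selected_features)
        tight = set(mww_screen(m, ann, alpha=0.01).selected_features)
        assert tight <= loose


class TestUnsupervisedRF:
    def test_proximity_structure(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(10, 12)))
        res = unsupervised_rf(AbundanceMatrix(df), n_trees=50, seed=1)
        P = res.proximity
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)
        assert ((P >= 0) & (P <= 1)).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_correlated_separators_rank_top(self, seed):
        """Features that jointly separate two planted sample groups carry
        the dependence structure the permutation contrast destroys, so they
        dominate the importance ranking over independent noise features."""
        rng = np.random.default_rng(seed)
        n = 40
        planted = {f"f{i}" for i in range(8)}
        noise = rng.lognormal(size=(45, n))
        group = np.r_[np.full(n // 2, 1.0), np.full(n // 2, 8.0)]
        seps = group * rng.lognormal(sigma=0.3, size=(8, n))
        df = pd.DataFrame(np.vstack([seps, noise]))
        df.index = [f"f{i}" for i in range(53)]
        res = unsupervised_rf(AbundanceMatrix(df), n_trees=500, seed=seed)
        assert res.importance.idxmax() in planted
        top8 = set(res.importance.nlargest(8).index)
        assert len(top8 & planted) >= 5

    @pytest.mark.parametrize("seed", range(3))
    def test_iid_noise_has_no_dominant_feature(self, seed):
        rng = np.random.default_rng(100 + seed)
        df = pd.DataFrame(rng.lognormal(size=(50, 24)))
        res = unsupervised_rf(AbundanceMatrix(df), n_trees=300, seed=seed)
        assert res.importance.max() <= 3 * res.importance.median()

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            unsupervised_rf(AbundanceMatrix(df), n_trees=10, seed=0)


class TestMDSEmbed:
    def test_two_perfect_blocks_collapse_to_two_points(self):
        P = np.zeros((6, 6))
        P[:3, :3] = 1.0
        P[3:, 3:] = 1.0
        coords = mds_embed(P)
        assert np.allclose(coords[:3], coords[0], atol=1e-6)
        assert np.allclose(coords[3:], coords[3], atol=1e-6)
        assert np.linalg.norm(coords[0] - coords[3]) > 0.5

    def test_identity_proximity_equilateral(self):
        coords = mds_embed(np.eye(3))
        d = [np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert d[0] == pytest.approx(d[1]) == pytest.approx(d[2])

    def test_asymmetric_input_rejected(self):
        P = np.eye(3)
        P[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(P)

    def test_matches_pcoa_oracle(self):
        """Classical MDS must agree with scikit-bio's PCoA up to axis sign."""
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        D /= D.max() * 1.1
        P = 1 - D
        np.fill_diagonal(P, 1.0)
        ours = mds_embed(P)
        ref = pcoa(DistanceMatrix(1 - P)).samples.to_numpy()[:, :2]
        for axis in range(2):
            sign = np.sign(np.dot(ours[:, axis], ref[:, axis]))
            assert np.allclose(ours[:, axis], sign * ref[:, axis], atol=1e-6)


class TestAssembleCandidates:
    def _screen_with(self, feats, mww_selected):
        sel = CandidateSelection.empty(feats)
        sel.table["provenance"] = [
            frozenset({"A"}) if f in mww_selected else frozenset() for f in feats
        ]
        sel.table["selected"] = sel.table["provenance"].map(bool)
        return sel

    def test_union_and_provenance_accumulation(self):
        feats = ["p1", "p2", "p3", "p4", "p5"]
        screen = self._screen_with(feats, {"p1", "p2"})
        imp_d = pd.Series([0.1, 0.9, 0.8, 0.0, 0.0], index=feats)
        imp_e = pd.Series([0.0, 0.0, 0.0, 0.9, 0.1], index=feats)
        out = assemble_candidates(screen, imp_d, imp_e, top_n=2)
        assert set(out.selected_features) == {"p1", "p2", "p3", "p4", "p5"}
        assert out.table.loc["p2", "provenance"] == {"A", "D"}
        assert out.table.loc["p4", "provenance"] == {"E"}

    def test_top_n_zero_rejected(self):
        screen = self._screen_with(["p1"], set())
        with pytest.raises(ValueError):
            assemble_candidates(screen, None, None, top_n=0)

    def test_protein_level_count_collapses_peptides(self):
        feats = ["pep1", "pep2", "pep3", "pep4"]
        mapping = {"pep1": "P1", "pep2": "P1", "pep3": "P1", "pep4": "P2"}
        screen = CandidateSelection.empty(feats, mapping)
        screen.table["provenance"] = [
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"}), frozenset()
        ]
        screen.table["selected"] = screen.table["provenance"].map(bool)
        sel = CandidateSelection(screen.table, mapping)
        assert sel.n_selected_features == 3
        assert sel.n_selected_proteins == 1  # three peptides of one protein

    def test_ranks_are_unique_positive(self):
        feats = [f"p{i}" for i in range(6)]
        screen = self._screen_with(feats, set())
        imp = pd.Series([0.5, 0.5, 0.5, 0.1, 0.9, 0.0], index=feats)
        out = assemble_candidates(screen, imp, None, top_n=1)
        ranks = out.table["rank_D"]
        assert sorted(ranks) == [1, 2, 3, 4, 5, 6]
        assert out.table.loc["p4", "rank_D"] == 1


def test_screen_cohort1_recovers_planted_subgroups():
    """2-means on the patient-set MDS embedding separates Stage I from IV
    when a strong multi-protein stage effect is planted."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(4)
    m, ann = _screen_inputs(seed=4, n_per_group=12)
    df = m.data.copy()
    extra = rng.lognormal(mean=5, sigma=0.3, size=(20, df.shape[1]))
    extra = pd.DataFrame(extra, index=[f"x{i}" for i in range(20)], columns=df.columns)
    s4 = [c for c in df.columns if c.startswith("StageIV")]
    extra.loc[[f"x{i}" for i in range(8)], s4] *= 4.0
    big = AbundanceMatrix(pd.concat([df, extra]))
    result = screen_cohort1(big, ann, n_trees=300, seed=0)
    coords = result.mds_patients
    labels_true = [0 if s.startswith("StageI-") else 1 for s in coords.index]
    pred = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(coords)
    assert adjusted_rand_score(labels_true, pred) >= 0.8
    assert result.candidates.n_selected_features > 0
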