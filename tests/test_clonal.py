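import numpy as np
import pytest

from cfevo.clonal import (
    CloneModel,
    _enumerate_parent_maps,
    _feasible,
    _project_timepoint,
    build_prevalence_matrix,
    cellular_prevalence,
    clone_frequencies,
    cluster_mutations,
    detect_expanding_clones,
    estimate_purity_simple,
    infer_tree,
)
from cfevo.errors import (
    EstimationUnavailable,
    InsufficientData,
    InvalidArgument,
    UnsupportedSize,
)


class TestCellularPrevalence:
    @pytest.mark.parametrize(
        "vaf,purity,cn,mult,expected",
        [
            (0.5, 1.0, 2, 1, 1.0),
            (0.25, 1.0, 2, 1, 0.5),
            (0.1, 0.5, 2, 1, 0.4),  # 0.1 * (1 + 1) / 0.5
            (0.9, 0.5, 2, 1, 1.0),  # clipped
        ],
    )
    def test_formula_and_clipping(self, vaf, purity, cn, mult, expected):
        assert cellular_prevalence(vaf, purity, cn, mult) == pytest.approx(expected)

    def test_zero_purity_rejected(self):
        with pytest.raises(InvalidArgument):
            cellular_prevalence(0.2, 0.0, 2, 1)

    def test_linear_in_vaf_before_clipping(self):
        vals = [cellular_prevalence(v, 0.8, 2, 1) for v in (0.05, 0.10, 0.15)]
        assert vals[1] - vals[0] == pytest.approx(vals[2] - vals[1])


class TestPurityEstimate:
    def test_inverts_prevalence_at_half(self):
        assert estimate_purity_simple([0.25] * 10, [2] * 10) == pytest.approx(0.5)

    def test_caps_at_one(self):
        assert estimate_purity_simple([0.5] * 10, [2] * 10) == pytest.approx(1.0)

    def test_pure_normal_near_zero(self):
        assert estimate_purity_simple([0.001] * 10, [2] * 10) < 0.01

    def test_too_few_mutations(self):
        with pytest.raises(InsufficientData):
            estimate_purity_simple([0.2] * 4, [2] * 4)

    def test_no_neutral_sites(self):
        with pytest.raises(EstimationUnavailable):
            estimate_purity_simple([0.2] * 6, [3] * 6)


class TestPrevalenceMatrix:
    def test_cn_zero_sites_excluded(self):
        keys = ["a", "b"]
        alt = np.array([[30, 30], [30, 30]])
        depth = np.full((2, 2), 100)
        pm = build_prevalence_matrix(keys, alt, depth, [0.6, 0.6], cn_per_site=[2, 0])
        assert pm.keys == ["a"]
        assert pm.excluded_keys == ["b"]

    def test_moderate_overshoot_clipped_not_excluded(self):
        # VAF slightly above the clonal expectation: clip, keep
        alt = np.array([[33]])  # expected 30 at purity .6, depth 100
        pm = build_prevalence_matrix(["a"], alt, np.array([[100]]), [0.6])
        assert pm.keys == ["a"]
        assert pm.cp[0, 0] == pytest.approx(1.0)

    def test_impossible_prevalence_excluded(self):
        alt = np.array([[60]])  # VAF 0.6 at purity .6 -> CP 2: impossible
        pm = build_prevalence_matrix(["a"], alt, np.array([[100]]), [0.6])
        assert pm.excluded_keys == ["a"]


class TestClustering:
    def _matrix(self, centers, n_per, depth, purity, seed):
        rng = np.random.default_rng(seed)
        rows, keys = [], []
        for ci, c in enumerate(centers):
            for j in range(n_per):
                vaf = purity * np.asarray(c) / 2
                rows.append(rng.binomial(depth, vaf))
                keys.append((ci, j))
        alt = np.array(rows)
        dep = np.full_like(alt, depth)
        return build_prevalence_matrix(keys, alt, dep, [purity] * alt.shape[1])

    def test_single_trajectory_k1(self):
        pm = self._matrix([[0.6, 0.6, 0.6]], 30, 300, 0.6, seed=0)
        assert cluster_mutations(pm, k_max=4, seed=0).k == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_three_separated_trajectories(self, seed):
        centers = [[0.9, 0.9], [0.6, 0.55], [0.1, 0.35]]
        pm = self._matrix(centers, 20, 500, 0.8, seed=seed)
        res = cluster_mutations(pm, k_max=6, seed=seed)
        assert res.k == 3
        # assignment accuracy >= 95%: majority label per true cluster
        correct = 0
        truth = np.array([k[0] for k in pm.keys])
        for c in range(3):
            labels = res.assignment[truth == c]
            correct += np.bincount(labels).max()
        assert correct / len(truth) >= 0.95

    def test_bic_selects_minimum(self):
        pm = self._matrix([[0.8, 0.8], [0.2, 0.2]], 25, 400, 0.8, seed=3)
        res = cluster_mutations(pm, k_max=5, seed=3)
        assert res.bic_by_k[res.k] == min(res.bic_by_k.values())


class TestInferTree:
    def test_single_clone(self):
        m = infer_tree(np.array([[0.8, 0.9]]))
        assert m.parent == (-1,) and m.fit_error == 0.0

    def test_noiseless_chain_recovered(self):
        m = infer_tree(np.array([[0.9, 0.9], [0.5, 0.5], [0.2, 0.2]]))
        assert m.parent == (-1, 0, 1)
        assert m.fit_error < 1e-6

    def test_projection_on_forced_tree(self):
        # both clones top-level with sum 1.5: project onto x0+x1 <= 1
        x, err = _project_timepoint((-1, -1), np.array([0.8, 0.7]))
        assert np.allclose(x, [0.55, 0.45], atol=1e-6)
        assert err == pytest.approx(0.125, abs=1e-6)

    def test_enumeration_bound(self):
        with pytest.raises(UnsupportedSize):
            infer_tree(np.full((7, 2), 0.1))

    def test_model_satisfies_constraints(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(0, 1, size=(4, 3))
        m = infer_tree(centers)
        m.validate(eps=1e-4)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_independent_feasibility_search(self, k):
        """For feasible centers the returned tree must be error-free and the
        deepest among all feasible trees found by an independent scan."""
        rng = np.random.default_rng(k)
        # nested prevalences are feasible for a chain by construction
        base = np.sort(rng.uniform(0.1, 0.95, size=k))[::-1]
        centers = np.tile(base[:, None], (1, 2))
        m = infer_tree(centers)
        assert m.fit_error == pytest.approx(0.0, abs=1e-9)
        feasible = [p for p in _enumerate_parent_maps(k) if _feasible(p, centers)]
        assert tuple(m.parent) in feasible

        def total_depth(parent):
            d = 0
            for i in range(k):
                p = parent[i]
                while p != -1:
                    d += 1
                    p = parent[p]
            return d

        assert total_depth(m.parent) == max(total_depth(p) for p in feasible)

    def test_enumeration_counts_are_forests(self):
        # (K+1)^(K-1) rooted labeled forests under an implicit root
        for k in (1, 2, 3, 4):
            assert sum(1 for _ in _enumerate_parent_maps(k)) == (k + 1) ** (k - 1)


class TestCloneFrequencies:
    def test_chain_subtraction(self):
        m = CloneModel(k=2, parent=(-1, 0), clone_prevalence=np.array([[0.9], [0.5]]), fit_error=0.0)
        assert np.allclose(clone_frequencies(m).ravel(), [0.4, 0.5])

    def test_single_clone(self):
        m = CloneModel(k=1, parent=(-1,), clone_prevalence=np.array([[1.0]]), fit_error=0.0)
        assert clone_frequencies(m)[0, 0] == 1.0

    def test_star_parent_residual(self):
        m = CloneModel(
            k=3, parent=(-1, 0, 0),
            clone_prevalence=np.array([[0.9], [0.3], [0.3]]), fit_error=0.0,
        )
        freqs = clone_frequencies(m).ravel()
        assert freqs[0] == pytest.approx(0.3)
        assert np.sum(freqs) <= 1.0 + 1e-9


class TestExpandingClones:
    def _model(self, prevalences):
        prev = np.asarray(prevalences, dtype=float)
        return CloneModel(
            k=prev.shape[0],
            parent=tuple([-1] + list(range(prev.shape[0] - 1))),
            clone_prevalence=prev,
            fit_error=0.0,
        )

    def test_minor_expander_flagged(self):
        # analogue of a 7% -> 75% resistant subclone under a stable lineage
        m = self._model([[1.0, 1.0, 1.0, 1.0], [0.07, 0.09, 0.11, 0.75]])
        calls = detect_expanding_clones(m)
        flagged = [c for c in calls if c.flagged]
        assert len(flagged) == 1
        assert flagged[0].initial_frequency == pytest.approx(0.07)
        assert flagged[0].final_frequency == pytest.approx(0.75)

    def test_stable_dominant_not_flagged(self):
        m = self._model([[1.0, 1.0], [0.65, 0.68]])
        assert not any(c.flagged for c in detect_expanding_clones(m))

    def test_raising_expansion_min_never_adds_flags(self):
        m = self._model([[1.0, 1.0], [0.1, 0.45]])
        flags = []
        for emin in (0.1, 0.2, 0.3, 0.4):
            flags.append(sum(c.flagged for c in detect_expanding_clones(m, expansion_min=emin)))
        assert flags == sorted(flags, reverse=True)

    def test_single_timepoint_rejected(self):
        m = self._model([[1.0], [0.2]])
        with pytest.raises(InvalidArgument):
            detect_expanding_clones(m)

    def test_significant_mutations_attached(self):
        m = self._model([[1.0, 1.0], [0.05, 0.6]])
        m.assignment = np.array([0, 1, 1])
        m.keys = ["m0", "m1", "m2"]
        calls = detect_expanding_clones(m, functional_flags={"m1": True, "m2": False})
        flagged = next(c for c in calls if c.flagged)
        assert flagged.mutations_carried == ("m1", "m2")
        assert flagged.significant_mutations == ("m1",)
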