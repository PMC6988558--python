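"""BN core: CMI, TAN structure, CPT learning, exact inference, complexity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshbn import (BNModel, complexity, conditional_mutual_information,
                     learn_cpts, learn_naive_structure, learn_tan_structure,
                     model_from_json, model_to_json, posterior,
                     posterior_batch, predict)
from marshbn.discretize import DiscretizedCases


def make_dcases(columns: dict, states: dict, response="C") -> DiscretizedCases:
    codes = pd.DataFrame({k: np.asarray(v, dtype=np.int16) for k, v in columns.items()})
    return DiscretizedCases(codes, states, response)


def random_model(rng: np.random.Generator) -> BNModel:
    """Random fitted naive/TAN model with <= 4 covariates for oracle checks."""
    C = int(rng.integers(2, 4))
    k = int(rng.integers(1, 5))
    names = [f"x{i}" for i in range(k)]
    nodes = {n: tuple(f"s{j}" for j in range(int(rng.integers(2, 5)))) for n in names}
    tree_parent = {}
    for i, n in enumerate(names):
        if i == 0 or rng.random() < 0.3:
            tree_parent[n] = None
        else:
            tree_parent[n] = names[int(rng.integers(0, i))]
    model = BNModel("C", tuple(f"c{j}" for j in range(C)), nodes, tree_parent)
    model.prior = rng.dirichlet(np.ones(C))
    for n in names:
        S = len(nodes[n])
        p = tree_parent[n]
        shape = (C, S) if p is None else (C, len(nodes[p]), S)
        model.cpts[n] = rng.dirichlet(np.ones(S), size=shape[:-1])
    return model


def brute_force_posterior(model: BNModel, evidence: dict) -> np.ndarray:
    """Enumerate the full joint and condition on the (partial) evidence."""
    names = list(model.nodes)
    cards = [len(model.nodes[n]) for n in names]
    C = len(model.response_states)
    post = np.zeros(C)
    for c in range(C):
        for combo in itertools.product(*[range(s) for s in cards]):
            assign = dict(zip(names, combo))
            if any(assign[n] != v for n, v in evidence.items()):
                continue
            p = model.prior[c]
            for x, v in assign.items():
                par = model.tree_parent[x]
                p *= model.cpts[x][c, v] if par is None else model.cpts[x][c, assign[par], v]
            post[c] += p
    return post / post.sum()


class TestConditionalMutualInformation:
    def test_conditionally_independent_pair_has_zero_cmi(self):
        # xj uniform regardless of (xi, c): the product table.
        n = 400
        rng = np.random.default_rng(0)
        c = rng.integers(0, 2, n)
        xi = rng.integers(0, 2, n)
        xj = np.tile([0, 1], n // 2)  # independent of everything by construction
        d = make_dcases({"C": c, "xi": xi, "xj": xj},
                        {"C": ("a", "b"), "xi": ("0", "1"), "xj": ("0", "1")})
        value = conditional_mutual_information(d, "xi", "xj")
        assert value == pytest.approx(0.0, abs=0.02)

    def test_exact_copy_of_binary_uniform_gives_one_bit(self):
        xi = np.array([0, 1] * 50)
        c = np.array([0] * 50 + [1] * 50)
        d = make_dcases({"C": c, "xi": xi, "xj": xi.copy()},
                        {"C": ("a", "b"), "xi": ("0", "1"), "xj": ("0", "1")})
        assert conditional_mutual_information(d, "xi", "xj") == pytest.approx(1.0)

    def test_matches_brute_force_sum_on_2x2x2_counts(self):
        # Counts (4,1,1,4) in each class: same dependency pattern per class.
        rows = []
        for c in (0, 1):
            rows += [(c, 0, 0)] * 4 + [(c, 0, 1)] * 1 + [(c, 1, 0)] * 1 + [(c, 1, 1)] * 4
        arr = np.array(rows)
        d = make_dcases({"C": arr[:, 0], "xi": arr[:, 1], "xj": arr[:, 2]},
                        {"C": ("a", "b"), "xi": ("0", "1"), "xj": ("0", "1")})
        # Brute force over the 8 cells of the empirical joint.
        joint = np.zeros((2, 2, 2))
        for c, i, j in rows:
            joint[c, i, j] += 1
        joint /= joint.sum()
        expected = 0.0
        for c, i, j in itertools.product(range(2), repeat=3):
            p = joint[c, i, j]
            pc = joint[c].sum()
            expected += p * np.log2(p * pc / (joint[c, i, :].sum() * joint[c, :, j].sum()))
        assert conditional_mutual_information(d, "xi", "xj") == pytest.approx(expected)

    def test_no_complete_cases_rejected(self):
        d = make_dcases({"C": [0, 1], "xi": [-1, -1], "xj": [0, 1]},
                        {"C": ("a", "b"), "xi": ("0", "1"), "xj": ("0", "1")})
        with pytest.raises(ValueError, match="complete"):
            conditional_mutual_information(d, "xi", "xj")


class TestStructure:
    def _dcases_from_sim(self, small_survey, covs):
        from marshbn import ResponseSpec, discretize_cases, fit_schemes, to_model_cases
        captures = to_model_cases(small_survey, ResponseSpec.rera_presence())
        schemes = fit_schemes(captures, covariates=covs)
        return discretize_cases(captures, schemes, ResponseSpec.rera_presence())

    def test_single_covariate_gives_two_nodes_one_link(self, small_survey):
        d = self._dcases_from_sim(small_survey, ["Dist_Road"])
        model = learn_tan_structure(d, ["Dist_Road"])
        assert complexity(model).n_nodes == 2
        assert model.links == [("outcome", "Dist_Road")]

    @pytest.mark.parametrize("k, expected_links", [(2, 3), (3, 5), (5, 9)])
    def test_tan_link_count_law(self, small_survey, k, expected_links):
        covs = ["Dist_Road", "Patch_Size", "Patch_Size_Expanded",
                "Marsh_Elev", "Dist_Bay"][:k]
        d = self._dcases_from_sim(small_survey, covs)
        model = learn_tan_structure(d, covs)
        assert len(model.links) == expected_links == 2 * k - 1

    def test_tree_orientation_outward_from_root(self, small_survey):
        covs = ["Patch_Size", "Patch_Size_Expanded", "Dist_Road"]
        d = self._dcases_from_sim(small_survey, covs)
        model = learn_tan_structure(d, covs, root="Dist_Road")
        assert model.tree_parent["Dist_Road"] is None
        others = [x for x in covs if x != "Dist_Road"]
        assert all(model.tree_parent[x] is not None for x in others)

    def test_structure_deterministic(self, small_survey):
        covs = ["Patch_Size", "Patch_Size_Expanded", "Dist_Road", "Marsh_Elev"]
        d = self._dcases_from_sim(small_survey, covs)
        m1 = learn_tan_structure(d, covs)
        m2 = learn_tan_structure(d, covs)
        assert m1.tree_parent == m2.tree_parent

    def test_cycle_in_tree_links_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            BNModel("C", ("a", "b"), {"x": ("0",), "y": ("0",)},
                    {"x": "y", "y": "x"})


class TestLearnCpts:
    def _simple_dcases(self):
        # 8 cases: class 0 -> x mostly 0; class 1 -> x mostly 1.
        c = [0, 0, 0, 0, 1, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1, 1, 0]
        return make_dcases({"C": c, "x": x}, {"C": ("a", "b"), "x": ("0", "1")})

    def test_alpha_zero_reproduces_empirical_frequencies(self):
        model = learn_naive_structure(self._simple_dcases(), ["x"])
        learn_cpts(model, self._simple_dcases(), alpha=0.0)
        assert model.cpts["x"][0] == pytest.approx([0.75, 0.25])
        assert model.cpts["x"][1] == pytest.approx([0.25, 0.75])
        assert model.prior == pytest.approx([0.5, 0.5])

    def test_laplace_smoothing_formula(self):
        # Counts (3,1) with alpha=1 over 2 states -> (4/6, 2/6).
        d = make_dcases({"C": [0, 0, 0, 0], "x": [0, 0, 0, 1]},
                        {"C": ("a",), "x": ("0", "1")})
        model = learn_naive_structure(d, ["x"])
        learn_cpts(model, d, alpha=1.0)
        assert model.cpts["x"][0] == pytest.approx([4 / 6, 2 / 6])

    def test_unobserved_parent_configuration_gets_uniform_row(self):
        d = make_dcases({"C": [0, 0], "p": [0, 0], "x": [0, 1]},
                        {"C": ("a", "b"), "p": ("0", "1"), "x": ("0", "1")})
        model = BNModel("C", ("a", "b"), {"p": ("0", "1"), "x": ("0", "1")},
                        {"p": None, "x": "p"})
        learn_cpts(model, d, alpha=0.0)
        # class b never observed; parent state 1 never observed
        assert model.cpts["x"][1, 1] == pytest.approx([0.5, 0.5])

    def test_rows_normalize_for_any_alpha(self):
        d = self._simple_dcases()
        for alpha in (0.0, 0.5, 1.0, 7.0):
            model = learn_cpts(learn_naive_structure(d, ["x"]), d, alpha=alpha)
            assert model.cpts["x"].sum(axis=-1) == pytest.approx(np.ones(2))
            assert model.prior.sum() == pytest.approx(1.0)

    def test_available_case_counting_skips_missing(self):
        d = make_dcases({"C": [0, 0, 0], "x": [0, 1, -1]},
                        {"C": ("a",), "x": ("0", "1")})
        model = learn_cpts(learn_naive_structure(d, ["x"]), d, alpha=0.0)
        assert model.cpts["x"][0] == pytest.approx([0.5, 0.5])


class TestPosterior:
    def _two_state_model(self):
        model = BNModel("C", ("c0", "c1"), {"x": ("0", "1")}, {"x": None})
        model.prior = np.array([0.2, 0.8])
        model.cpts["x"] = np.array([[0.1, 0.9], [0.7, 0.3]])
        return model

    def test_no_evidence_returns_prior(self):
        model = self._two_state_model()
        assert posterior(model, {}) == pytest.approx([0.2, 0.8])

    def test_hand_computed_bayes_update(self):
        # P(C)=(0.2,0.8), P(x=1|C)=(0.9,0.3) -> posterior (0.429, 0.571).
        model = self._two_state_model()
        post = posterior(model, {"x": "1"})
        assert post == pytest.approx([0.18 / 0.42, 0.24 / 0.42])
        assert post == pytest.approx([0.429, 0.571], abs=5e-4)
        assert predict(model, {"x": "1"}) == "c1"

    def test_uniform_posterior_ties_to_first_state(self):
        model = BNModel("C", ("c0", "c1"), {}, {})
        model.prior = np.array([0.5, 0.5])
        assert predict(model, {}) == "c0"

    def test_unknown_state_label_rejected(self):
        model = self._two_state_model()
        with pytest.raises(ValueError, match="unknown state"):
            posterior(model, {"x": "banana"})
        with pytest.raises(ValueError, match="unknown node"):
            posterior(model, {"zzz": "0"})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_factored_posterior_equals_joint_enumeration(self, seed):
        """Tree-factored inference == brute-force joint on random models."""
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        names = list(model.nodes)
        # Random partial evidence, including the all-missing case.
        evidence = {n: int(rng.integers(0, len(model.nodes[n])))
                    for n in names if rng.random() < 0.6}
        expected = brute_force_posterior(model, evidence)
        got = posterior(model, evidence)
        assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_posterior_batch_matches_per_case_inference(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        names = list(model.nodes)
        n = 30
        cols = {"C": rng.integers(0, len(model.response_states), n)}
        for x in names:
            col = rng.integers(0, len(model.nodes[x]), n)
            col[rng.random(n) < 0.3] = -1  # missing
            cols[x] = col
        states = {"C": model.response_states, **model.nodes}
        d = make_dcases(cols, states)
        batch = posterior_batch(model, d)
        for i in range(n):
            ev = {x: int(cols[x][i]) for x in names if cols[x][i] >= 0}
            assert batch[i] == pytest.approx(posterior(model, ev), abs=1e-12)


class TestComplexity:
    def test_naive_binary_response_one_five_state_covariate(self):
        model = BNModel("C", ("p", "a"), {"x": tuple("abcde")}, {"x": None})
        assert complexity(model) == (2, 1, 12)

    def test_tan_binary_response_two_five_state_covariates(self):
        model = BNModel("C", ("p", "a"),
                        {"x": tuple("abcde"), "y": tuple("fghij")},
                        {"x": None, "y": "x"})
        assert complexity(model) == (3, 3, 62)

    def test_tan_nine_state_response_two_five_state_covariates(self):
        model = BNModel("C", tuple(f"s{i}" for i in range(9)),
                        {"x": tuple("abcde"), "y": tuple("fghij")},
                        {"x": None, "y": "x"})
        assert complexity(model) == (3, 3, 279)


def test_model_json_round_trip(small_survey):
    from marshbn import ResponseSpec, discretize_cases, fit_schemes, to_model_cases

    captures = to_model_cases(small_survey, ResponseSpec.rera_presence())
    covs = ["Patch_Size", "Dist_Road"]
    schemes = fit_schemes(captures, covariates=covs)
    d = discretize_cases(captures, schemes, ResponseSpec.rera_presence())
    model = learn_cpts(learn_tan_structure(d, covs), d)
    back = model_from_json(model_to_json(model))
    assert back.response_states == model.response_states
    assert back.tree_parent == model.tree_parent
    assert back.prior == pytest.approx(model.prior)
    for x in covs:
        assert back.cpts[x] == pytest.approx(model.cpts[x])
    ev = {"Patch_Size": model.nodes["Patch_Size"][0]}
    assert posterior(back, ev) == pytest.approx(posterior(model, ev))
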