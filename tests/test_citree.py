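"""Permutation-test variable selection, binary splitting, tree growth."""

import numpy as np
import pandas as pd
import pytest

from herbpersist.citree import (CITParams, association_test, best_split,
                                grow_tree, render_tree,
                                select_split_variable)

KINDS = {"seed_mass": "quantitative", "bud_bank": "binary",
         "sla": "quantitative", "vegetative_mobility": "categorical",
         "leaf_anatomy": "categorical"}


def random_traits(rng, n):
    return pd.DataFrame({
        "seed_mass": rng.lognormal(np.log(2), 1.1, n),
        "bud_bank": rng.random(n) < 0.6,
        "sla": rng.normal(25, 8, n),
        "vegetative_mobility": rng.choice(["none", "slow", "fast"], n),
        "leaf_anatomy": rng.choice(
            ["helomorphic", "hygromorphic", "mesomorphic", "scleromorphic"], n),
    })


def test_association_minimum_attainable_p():
    x = np.arange(20, dtype=float)
    y = x * 2 + 1
    stat, p = association_test(x, y, n_perm=999, seed=0)
    assert p == pytest.approx(1 / 1000)
    assert stat > 0


def test_association_constant_x_is_p_one():
    _, p = association_test([3.0] * 10, np.arange(10.0), n_perm=999, seed=0)
    assert p == 1.0


def test_association_categorical_signal():
    rng = np.random.default_rng(1)
    x = ["A"] * 15 + ["B"] * 15
    y = np.r_[rng.normal(0, 1, 15), rng.normal(5, 1, 15)]
    _, p = association_test(x, y, kind="categorical", n_perm=999, seed=2)
    assert p <= 0.01


def test_association_missing_x_casewise_deleted():
    x = pd.Series([np.nan] * 5 + list(range(20)))
    y = np.r_[np.zeros(5), np.arange(20.0) * 3]
    _, p = association_test(x, y, n_perm=999, seed=0)
    assert p == pytest.approx(1 / 1000)


def test_association_errors():
    with pytest.raises(ValueError):
        association_test([1.0], [2.0], n_perm=99, seed=0)
    with pytest.raises(ValueError):
        association_test([1.0, 2.0], [3.0, 3.0], n_perm=99, seed=0)


def test_association_type_one_error_calibrated():
    """Null rejection rate at alpha = 0.05 stays near nominal."""
    rng = np.random.default_rng(12)
    rejections = 0
    n_rep = 400
    for rep in range(n_rep):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        _, p = association_test(x, y, n_perm=199, seed=rep)
        rejections += p <= 0.05
    assert abs(rejections / n_rep - 0.05) <= 0.03


def test_select_split_variable_planted_signal():
    rng = np.random.default_rng(5)
    traits = random_traits(rng, 200)
    y = traits["sla"].to_numpy() * 3 + rng.normal(0, 5, 200)
    name, p = select_split_variable(traits, KINDS, y,
                                    CITParams(n_perm=999, seed=1))
    assert name == "sla"
    assert p < 0.05


def test_select_split_variable_all_constant():
    traits = pd.DataFrame({"seed_mass": [1.0] * 30, "sla": [2.0] * 30})
    kinds = {"seed_mass": "quantitative", "sla": "quantitative"}
    y = np.random.default_rng(0).normal(size=30)
    name, _ = select_split_variable(traits, kinds, y,
                                    CITParams(n_perm=99, seed=1))
    assert name is None


def test_select_split_variable_tie_breaks_on_declared_order():
    rng = np.random.default_rng(9)
    x = rng.normal(size=100)
    y = x * 2 + rng.normal(0, 0.1, 100)
    traits = pd.DataFrame({"first_copy": x, "second_copy": x})
    kinds = {"first_copy": "quantitative", "second_copy": "quantitative"}
    name, _ = select_split_variable(traits, kinds, y,
                                    CITParams(n_perm=999, seed=1))
    assert name == "first_copy"


def test_best_split_step_function():
    x = [1, 2, 3, 4, 6, 7, 8, 9]
    y = [0, 0, 0, 0, 10, 10, 10, 10]
    rule = best_split(x, y, "quantitative", min_leaf=2)
    assert rule == {"threshold": 4.0}  # largest observed value of left group


def test_best_split_categorical_subset():
    x = ["A", "B", "C"] * 10
    y = [0.0 if v != "C" else 10.0 for v in x]
    rule = best_split(x, y, "categorical", min_leaf=5)
    assert set(rule["levels"]) in ({"C"}, {"A", "B"})


def test_best_split_unique_admissible():
    rule = best_split([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 1.0, 2.0],
                      "quantitative", min_leaf=2)
    assert rule == {"threshold": 2.0}


def test_best_split_no_admissible_split():
    assert best_split([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "quantitative",
                      min_leaf=2) is None


def test_grow_tree_planted_binary_effect():
    rng = np.random.default_rng(21)
    traits = random_traits(rng, 400)
    y = np.where(traits["bud_bank"], 60.0, 25.0) + rng.normal(0, 15, 400)
    tree = grow_tree(traits, y, KINDS, CITParams(n_perm=999, seed=3))
    assert tree.root_trait() == "bud_bank"
    assert tree.root.p_adjusted < 0.05
    assert tree.root.left.n + tree.root.right.n == tree.root.n


def test_grow_tree_pure_noise_mostly_single_leaf():
    rng = np.random.default_rng(33)
    single = 0
    for rep in range(40):
        traits = random_traits(rng, 150)
        y = rng.normal(50, 15, 150)
        tree = grow_tree(traits, y, KINDS,
                         CITParams(n_perm=299, seed=1000 + rep))
        single += tree.root.is_leaf
    assert single >= 0.9 * 40 - 2  # allow ~binomial wiggle around 95%


def test_grow_tree_duplicated_observations_same_topology():
    rng = np.random.default_rng(2)
    traits = random_traits(rng, 200)
    y = np.where(traits["bud_bank"], 60.0, 25.0) + rng.normal(0, 10, 200)
    t1 = grow_tree(traits, y, KINDS, CITParams(n_perm=999, seed=7))
    doubled = pd.concat([traits, traits], ignore_index=True)
    t2 = grow_tree(doubled, np.r_[y, y], KINDS,
                   CITParams(n_perm=999, seed=7))
    assert t1.root_trait() == t2.root_trait()
    assert t2.root.n == 2 * t1.root.n


def test_grow_tree_deterministic_given_seed():
    rng = np.random.default_rng(4)
    traits = random_traits(rng, 300)
    y = traits["seed_mass"].rank().to_numpy() / 3 + rng.normal(0, 5, 300)
    t1 = grow_tree(traits, y, KINDS, CITParams(n_perm=499, seed=11))
    t2 = grow_tree(traits, y, KINDS, CITParams(n_perm=499, seed=11))
    assert t1.to_json() == t2.to_json()


def test_root_variable_matches_argmin_p_when_alpha_near_one():
    """With alpha -> 1 and max_depth = 1 the root split variable equals the
    strongest-association trait (internal consistency)."""
    rng = np.random.default_rng(14)
    traits = random_traits(rng, 120)
    y = traits["sla"].to_numpy() + rng.normal(0, 20, 120)
    params = CITParams(alpha=0.999, max_depth=1, n_perm=999, seed=5)
    tree = grow_tree(traits, y, KINDS, params)
    name, _ = select_split_variable(traits, KINDS, y, params,
                                    seed=params.seed + 1)
    assert tree.root_trait() == name


def test_empty_observations_rejected():
    with pytest.raises(ValueError):
        grow_tree(pd.DataFrame({"a": []}), [], {"a": "quantitative"})


def test_render_tree():
    rng = np.random.default_rng(6)
    traits = random_traits(rng, 200)
    y = np.where(traits["bud_bank"], 70.0, 20.0) + rng.normal(0, 10, 200)
    tree = grow_tree(traits, y, KINDS,
                     CITParams(n_perm=499, seed=2, max_depth=1))
    text = render_tree(tree)
    lines = text.splitlines()
    assert len(lines) == 3  # root split + two leaves
    assert "bud_bank" in lines[0]
    noise_tree = grow_tree(traits, rng.normal(size=200), KINDS,
                           CITParams(n_perm=299, seed=2))
    if noise_tree.root.is_leaf:
        assert render_tree(noise_tree).startswith("leaf:")


def test_rendered_thresholds_appear_at_one_decimal():
    x = pd.DataFrame({"seed_mass": [1.0, 2.0, 3.0, 4.0, 6.9, 7.5, 8.0, 9.0] * 10})
    y = np.r_[[0.0] * 4, [60.0] * 4 * 1].tolist() * 10
    tree = grow_tree(x, y, {"seed_mass": "quantitative"},
                     CITParams(n_perm=499, seed=1, min_node=10, min_leaf=5))
    if not tree.root.is_leaf:
        c = tree.root.rule["threshold"]
        assert f"{c:.1f}" in render_tree(tree)
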