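"""Gower distances, MPD, neighbor joining, patristic distances, FD-PD rho."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herbpersist.community import DEFAULT_TRAIT_SCHEMA, TraitTable, TraitDescriptor
from herbpersist.distance import DistanceMatrix
from herbpersist.diversity import (diversity_scores, fd_pd_correlation,
                                   gower_matrix, mpd, neighbor_joining,
                                   patristic_distances)
from herbpersist.simulate import generate_tree, generate_traits


def gower_pair_oracle(table: TraitTable, i: int, j: int) -> float:
    """Per-pair Gower distance computed trait by trait in pure Python."""
    num = den = 0.0
    for d in table.schema:
        xi, xj = table.data.iloc[i][d.name], table.data.iloc[j][d.name]
        if pd.isna(xi) or pd.isna(xj):
            continue
        if d.kind == "quantitative":
            col = table.data[d.name].dropna()
            rng = col.max() - col.min()
            c = abs(xi - xj) / rng if rng > 0 else 0.0
        else:
            c = 0.0 if xi == xj else 1.0
        num += c
        den += 1.0
    return num / den


def test_gower_worked_examples():
    df = pd.DataFrame({
        "seed_mass": [1.0, 1.0, 5.0],
        "bud_bank": [True, False, True],
        "sla": [20.0, 20.0, 20.0],
        "vegetative_mobility": ["fast", "fast", "fast"],
        "leaf_anatomy": ["mesomorphic", "mesomorphic", "mesomorphic"],
    }, index=["a", "b", "c"])
    table = TraitTable(DEFAULT_TRAIT_SCHEMA, df)
    d = gower_matrix(table)
    # species differing only in the binary trait, five equal weights
    assert d.get("a", "b") == pytest.approx(0.2)
    # a and c sit at the pool min and max of seed mass and agree elsewhere
    assert d.get("a", "c") == pytest.approx(1.0 / 5.0 * 1.0 + 0)
    assert d.get("a", "a") == 0.0


def test_gower_single_quantitative_extremes():
    schema = (TraitDescriptor("sla", "quantitative", "mm2/mg"),)
    table = TraitTable(schema, pd.DataFrame({"sla": [5.0, 30.0]},
                                            index=["lo", "hi"]))
    assert gower_matrix(table).get("lo", "hi") == pytest.approx(1.0)


def test_gower_matches_pairwise_oracle():
    rng = np.random.default_rng(8)
    for rep in range(20):
        table = generate_traits(6, seed=100 + rep)
        # plant some missing values
        mask = rng.random((6, 2)) < 0.25
        dat = table.data.copy()
        dat.loc[mask[:, 0], "seed_mass"] = np.nan
        dat.loc[mask[:, 1], "sla"] = np.nan
        table = TraitTable(table.schema, dat)
        d = gower_matrix(table)
        for i, j in combinations(range(6), 2):
            assert d.values[i, j] == pytest.approx(
                gower_pair_oracle(table, i, j), abs=1e-12)


def test_gower_metric_axioms():
    """Symmetry, identity and triangle inequality on random complete tables."""
    for rep in range(100):
        table = generate_traits(5, seed=500 + rep)
        d = gower_matrix(table).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1 + 1e-12
        for i, j, k in permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_gower_incomparable_pair_errors():
    schema = (TraitDescriptor("seed_mass", "quantitative", "mg"),)
    df = pd.DataFrame({"seed_mass": [1.0, np.nan]}, index=["a", "b"])
    with pytest.raises(ValueError, match="no\\b.*non-missing|share no"):
        gower_matrix(TraitTable(schema, df))


def test_mpd():
    d = DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
    assert mpd(d, ["a", "b"]) == pytest.approx(1.0)
    assert mpd(d, ["a", "b", "c"]) == pytest.approx(2.0)
    assert np.isnan(mpd(d, ["a"]))
    with pytest.raises(KeyError):
        mpd(d, ["a", "zz"])


def test_nj_three_taxon_closed_form():
    d = DistanceMatrix(["A", "B", "C"],
                       np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
    tree = neighbor_joining(d)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})
    back = patristic_distances(tree)
    np.testing.assert_allclose(back.submatrix(["A", "B", "C"]).values,
                               d.values, atol=1e-12)


def test_nj_recovers_additive_matrices():
    """NJ on the patristic matrix of a random binary tree reproduces that
    matrix (additivity guarantee)."""
    for rep in range(25):
        n_leaves = 5 + rep % 12
        tree = generate_tree([f"t{i}" for i in range(n_leaves)],
                             seed=900 + rep)
        d = patristic_distances(tree)
        rebuilt = neighbor_joining(d)
        d2 = patristic_distances(rebuilt).submatrix(d.labels)
        np.testing.assert_allclose(d2.values, d.values, atol=1e-9)


def test_nj_agrees_with_independent_implementation():
    """Topology check against dendropy's own NJ on a non-additive matrix."""
    import dendropy
    rng = np.random.default_rng(17)
    x = rng.random((6, 6))
    d = DistanceMatrix([f"t{i}" for i in range(6)],
                       (x + x.T) * (1 - np.eye(6)))
    mine = neighbor_joining(d)
    csv = ",".join([""] + d.labels) + "\n" + "\n".join(
        ",".join([d.labels[i]] + [str(v) for v in d.values[i]])
        for i in range(6))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO(csv), delimiter=",")
    ref = pdm.nj_tree()
    mine2 = dendropy.Tree.get(data=mine.as_string(schema="newick"),
                              schema="newick",
                              taxon_namespace=ref.taxon_namespace)
    ref.encode_bipartitions()
    mine2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(
        mine2, ref, is_bipartitions_updated=True) == 0


def test_nj_zero_distance_pair_joined_first():
    d = DistanceMatrix(["a", "b", "c", "e"], np.array([
        [0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0.0]]))
    tree = neighbor_joining(d)
    pat = patristic_distances(tree)
    assert pat.get("a", "b") == pytest.approx(0.0, abs=1e-12)


def test_nj_requires_three_labels():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_patristic_star_and_zero_trees():
    import dendropy
    star = dendropy.Tree.get(data="(a:2,b:2,c:2);", schema="newick")
    d = patristic_distances(star)
    assert d.get("a", "b") == d.get("a", "c") == 4.0
    zero = dendropy.Tree.get(data="(a:0,b:0,c:0);", schema="newick")
    assert patristic_distances(zero).values.max() == 0.0


def test_patristic_missing_lengths():
    import dendropy
    bare = dendropy.Tree.get(data="((a,b),(c,e));", schema="newick")
    with pytest.raises(ValueError, match="branch length"):
        patristic_distances(bare)
    nodal = patristic_distances(bare, mode="nodal")
    assert nodal.get("a", "b") == 2.0
    assert nodal.get("a", "c") in (3.0, 4.0)  # depends on rooting of the path


def test_fd_pd_correlation_monotone_cases():
    fd = np.arange(10, dtype=float)
    rho, p = fd_pd_correlation(pd.DataFrame({"fd": fd, "pd": fd * 3 + 1}))
    assert rho == pytest.approx(1.0)
    rho, _ = fd_pd_correlation(pd.DataFrame({"fd": fd, "pd": fd[::-1]}))
    assert rho == pytest.approx(-1.0)


def test_fd_pd_exact_p_matches_enumeration():
    """n = 6: the exact permutation p agrees with brute force over all 720
    rank permutations."""
    fd = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 2.5])
    pdv = np.array([2.0, 0.5, 3.5, 2.2, 4.0, 1.0])
    rho_obs, p = fd_pd_correlation(pd.DataFrame({"fd": fd, "pd": pdv}))
    rx = stats.rankdata(fd)
    ry = stats.rankdata(pdv)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = stats.pearsonr(rx, np.array(perm)).statistic
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    assert total == 720
    assert p == pytest.approx(count / total)


def test_fd_pd_requires_three_complete_pairs():
    df = pd.DataFrame({"fd": [1.0, 2.0, np.nan], "pd": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        fd_pd_correlation(df)


def test_diversity_scores_order_invariance(toy_traits):
    from herbpersist.community import SurveySeries
    cover = np.zeros((2, 4, 2))
    cover[0, :3, 0] = 5.0
    cover[1, 1:, 0] = 5.0
    species = list(toy_traits.species)
    series = SurveySeries("s", [1999, 2000], ["u1", "u2"], species, cover)
    fd_dist = gower_matrix(toy_traits)
    tree = generate_tree(species, seed=4)
    pd_dist = patristic_distances(tree)
    scores = diversity_scores(series, fd_dist, pd_dist)

    # reorder species axis and recompute
    order = [2, 0, 3, 1]
    series2 = SurveySeries("s", [1999, 2000], ["u1", "u2"],
                           [species[i] for i in order],
                           cover[:, order, :])
    scores2 = diversity_scores(series2, fd_dist, pd_dist)
    pd.testing.assert_frame_equal(scores, scores2)
    assert scores.loc[0, "n_species"] == 3
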