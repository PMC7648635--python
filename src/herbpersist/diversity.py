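"""Mixed-type Gower distances, mean pairwise diversity, neighbor joining.

Functional diversity (FD) of a quadrat is the mean pairwise Gower trait
distance among the species present; phylogenetic diversity (PD) is the mean
pairwise patristic distance on a phylogeny.  Site-level concordance of the
two is summarised by a Spearman rank correlation across quadrats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .community import SurveySeries, TraitTable
from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["DiversityScores", "gower_matrix", "mpd", "neighbor_joining",
           "patristic_distances", "fd_pd_correlation", "diversity_scores",
           "read_newick", "write_newick"]


@dataclass(frozen=True)
class DiversityScores:
    """Per-quadrat functional and phylogenetic diversity (NaN when < 2 spp)."""

    unit: str
    fd: float
    pd: float
    n_species: int


def gower_matrix(traits: TraitTable, weights: dict | None = None) -> DistanceMatrix:
    """Gower distance between every species pair of a mixed-type trait table.

    Quantitative components are |xi - xj| / range over the species pool
    (0 when the trait is constant); binary and categorical components are a
    0/1 mismatch.  Missing traits are dropped pairwise and the remaining
    weights renormalised.  A pair with no shared non-missing trait is an
    error.
    """
    species = traits.species
    n = len(species)
    if n < 2:
        raise ValueError("need at least 2 species")
    if weights is None:
        weights = {}
    comp = []   # per trait: (n, n) component matrix
    avail = []  # per trait: (n, n) availability mask
    wts = []
    for d in traits.schema:
        w = float(weights.get(d.name, 1.0))
        if w < 0:
            raise ValueError(f"negative weight for trait {d.name}")
        if w == 0:
            continue
        col = traits.data[d.name]
        if d.kind == "quantitative":
            v = col.to_numpy(dtype=float)
            ok = np.isfinite(v)
            rng = np.nanmax(v) - np.nanmin(v) if ok.any() else 0.0
            diff = np.abs(v[:, None] - v[None, :])
            c = diff / rng if rng > 0 else np.zeros((n, n))
        else:
            vals = col.to_numpy(dtype=object)
            ok = pd.notna(col).to_numpy()
            c = (vals[:, None] != vals[None, :]).astype(float)
        comp.append(np.nan_to_num(c))
        avail.append(np.outer(ok, ok))
        wts.append(w)
    if not comp:
        raise ValueError("no traits with positive weight")
    comp = np.stack(comp)
    avail = np.stack(avail)
    wts = np.asarray(wts)[:, None, None]
    wsum = (wts * avail).sum(axis=0)
    if np.any(wsum == 0):
        i, j = np.argwhere(wsum == 0)[0]
        raise ValueError(
            f"species pair ({species[i]}, {species[j]}) share no "
            "non-missing trait: Gower distance undefined")
    d = (wts * avail * comp).sum(axis=0) / wsum
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species, d)


def mpd(d: DistanceMatrix, present) -> float:
    """Mean pairwise distance among the present labels; NaN when < 2."""
    present = list(present)
    missing = [p for p in present if p not in d.labels]
    if missing:
        raise KeyError(f"labels not in matrix: {missing}")
    if len(present) < 2:
        return float("nan")
    sub = d.submatrix(present).values
    iu = np.triu_indices(len(present), k=1)
    return float(sub[iu].mean())


def _quote(label: str) -> str:
    s = str(label)
    if s.replace("_", "").replace(".", "").replace("-", "").isalnum():
        return s
    return "'" + s.replace("'", "''") + "'"


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei neighbor joining from a distance matrix.

    Iteratively joins the pair minimising Q(i, j) = (r - 2) d_ij - R_i - R_j,
    assigns branch lengths by the standard rate-corrected formula, and
    reduces the matrix.  Negative branch-length estimates are clamped to 0
    with the deficit moved to the sister branch (logged).  Returns an
    unrooted dendropy tree over all labels.
    """
    n = len(d)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    dist = d.values.copy()
    nodes = [_quote(l) for l in d.labels]  # newick fragment per active node

    def clamp(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            logger.info("NJ: clamping negative branch %.3g", bi)
            bj += bi
            bi = 0.0
        if bj < 0:
            logger.info("NJ: clamping negative branch %.3g", bj)
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = dist.sum(axis=1)
        q = (r - 2) * dist - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = dist[i, j]
        bi = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        bj = dij - bi
        bi, bj = clamp(bi, bj)
        new = f"({nodes[i]}:{float(bi):.17g},{nodes[j]}:{float(bj):.17g})"
        dnew = 0.5 * (dist[i, :] + dist[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep],
                          dnew[keep][None, :]])
        dist = np.hstack([dist, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    b0, b1, b2 = (max(b, 0.0) for b in (b0, b1, b2))
    newick = f"({nodes[0]}:{float(b0):.17g},{nodes[1]}:{float(b1):.17g},{nodes[2]}:{float(b2):.17g});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree, mode: str = "branch_length") -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree.

    ``mode="branch_length"`` sums branch lengths (missing lengths are an
    error); ``mode="nodal"`` counts edges instead, the fallback for trees
    without branch lengths.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if mode == "branch_length":
        missing = [e for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node and e.length is None]
        if missing:
            raise ValueError("tree has edges without branch lengths; "
                             "use mode='nodal' for edge-count distances")
        pdm = tree.phylogenetic_distance_matrix()
        get = pdm.patristic_distance
    elif mode == "nodal":
        logger.info("patristic distances in nodal (edge-count) mode")
        pdm = tree.phylogenetic_distance_matrix()
        get = pdm.path_edge_count
    else:
        raise ValueError(f"unknown mode {mode!r}")
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = get(taxa[leaves[i]], taxa[leaves[j]])
    return DistanceMatrix(leaves, out)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean())
    ry = (ry - ry.mean())
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 1.0
    perms = np.array(list(permutations(ry)))
    rhos = perms @ rx / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def fd_pd_correlation(scores, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman correlation between FD and PD across quadrats.

    Accepts a sequence of :class:`DiversityScores` or a DataFrame with
    ``fd``/``pd`` columns.  Quadrats with a missing score are dropped with a
    warning.  The two-sided p-value is exact (full permutation enumeration)
    for n <= ``exact_max_n``, otherwise the asymptotic t-approximation.
    """
    if isinstance(scores, pd.DataFrame):
        fd = scores["fd"].to_numpy(dtype=float)
        pd_ = scores["pd"].to_numpy(dtype=float)
    else:
        scores = list(scores)
        fd = np.array([s.fd for s in scores], dtype=float)
        pd_ = np.array([s.pd for s in scores], dtype=float)
    ok = np.isfinite(fd) & np.isfinite(pd_)
    if (~ok).any():
        logger.warning("dropping %d quadrats with undefined FD or PD",
                       int((~ok).sum()))
    fd, pd_ = fd[ok], pd_[ok]
    if len(fd) < 3:
        raise ValueError("need at least 3 quadrats with both FD and PD")
    rho, p = stats.spearmanr(fd, pd_)
    rho = float(rho)
    if len(fd) <= exact_max_n:
        p = _spearman_exact_p(fd, pd_, rho)
    return rho, float(p)


def diversity_scores(series: SurveySeries, fd_dist: DistanceMatrix,
                     pd_dist: DistanceMatrix, survey=None,
                     alias: dict | None = None) -> pd.DataFrame:
    """FD and PD per sampling unit at one survey (default: the first).

    ``alias`` maps species absent from the phylogenetic matrix to stand-in
    species (e.g. a congener); substitutions are logged, never inferred.
    """
    if survey is None:
        survey = series.surveys[0]
    it = series.surveys.index(survey)
    alias = alias or {}
    rows = []
    for iu, unit in enumerate(series.units):
        present = [sp for isp, sp in enumerate(series.species)
                   if series.occupancy[iu, isp, it]]
        fd_present = [sp for sp in present if sp in fd_dist.labels]
        pd_present = []
        for sp in present:
            sub = alias.get(sp, sp)
            if sub != sp:
                logger.info("unit %s: species %s aliased to %s for PD",
                            unit, sp, sub)
            if sub in pd_dist.labels and sub not in pd_present:
                pd_present.append(sub)
        rows.append({
            "unit": unit,
            "fd": mpd(fd_dist, fd_present),
            "pd": mpd(pd_dist, pd_present),
            "n_species": len(present),
        })
    return pd.DataFrame(rows)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)
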