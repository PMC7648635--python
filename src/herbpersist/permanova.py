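"""Bray–Curtis dissimilarity, trait-abundance composition, and one-way PERMANOVA.

The permutational MANOVA follows Anderson's partition of squared
inter-object distances: with N objects and groups g of sizes n_g,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

Significance is assessed by unrestricted permutation of group labels, with
the add-one rule p = (b + 1)/(m + 1), so p is never reported as exactly 0.
When the number of distinct label assignments is small the test is run
exhaustively instead of by Monte-Carlo sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .community import SurveySeries, TraitTable

logger = logging.getLogger(__name__)

__all__ = ["PermanovaResult", "bray_curtis", "trait_abundance_matrix",
           "permanova"]

#: assignments threshold below which the exact test replaces Monte-Carlo
EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    df_between: int
    df_within: int
    p_value: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def summary(self) -> str:
        mode = "exact" if self.exhaustive else f"{self.n_perm} permutations"
        return (f"PERMANOVA: pseudo-F = {self.pseudo_F:.4g}, "
                f"R^2 = {self.r_squared:.4f}, df = ({self.df_between}, "
                f"{self.df_within}), p = {self.p_value:.4g} ({mode})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "pseudo_F": self.pseudo_F, "r_squared": self.r_squared,
            "df_between": self.df_between, "df_within": self.df_within,
            "p_value": self.p_value, "n_perm": self.n_perm,
            "seed": self.seed, "exhaustive": self.exhaustive,
        }])


def bray_curtis(abundance, labels=None) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between the rows of an abundance table.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).  A pair of all-zero
    rows, for which the index is undefined, is given distance 0 with a
    warning so that empty quadrats remain comparable.
    """
    if isinstance(abundance, pd.DataFrame):
        if labels is None:
            labels = list(abundance.index)
        abundance = abundance.to_numpy(dtype=float)
    x = np.asarray(abundance, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 objects")
    if np.any(x < 0):
        raise ValueError("negative abundance")
    if labels is None:
        labels = list(range(x.shape[0]))
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero = den == 0
    if np.any(zero & ~np.eye(len(labels), dtype=bool)):
        logger.warning("all-zero row pair(s): Bray-Curtis undefined, set to 0")
    den[zero] = 1.0
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def trait_abundance_matrix(series: SurveySeries, traits: TraitTable,
                           survey=None, standardise: bool = True) -> pd.DataFrame:
    """Unit-by-trait-attribute composition at one survey.

    For each binary/categorical attribute the column is the summed cover of
    species bearing that attribute; for each quantitative trait it is the
    cover-weighted mean trait value (0 in an empty unit).  Species absent
    from the trait table are dropped with a warning.  Columns are scaled to
    unit range by default so heterogeneous units are comparable before
    Bray–Curtis.
    """
    if survey is None:
        survey = series.surveys[0]
    if survey not in series.surveys:
        raise ValueError(f"unknown survey label {survey!r}")
    it = series.surveys.index(survey)
    known = [sp for sp in series.species if sp in traits.data.index]
    dropped = [sp for sp in series.species if sp not in traits.data.index]
    if dropped:
        logger.warning("dropping %d species missing from trait table: %s",
                       len(dropped), dropped[:5])
    isp = [series.species.index(sp) for sp in known]
    cov = series.cover[:, isp, it]  # unit x known-species
    tdat = traits.data.loc[known]

    cols: dict[str, np.ndarray] = {}
    for d in traits.schema:
        vals = tdat[d.name]
        if d.kind == "quantitative":
            v = vals.to_numpy(dtype=float)
            ok = np.isfinite(v)
            w = cov[:, ok]
            tot = w.sum(axis=1)
            cwm = np.where(tot > 0, w @ v[ok], 0.0)
            cols[f"cwm_{d.name}"] = np.divide(
                cwm, tot, out=np.zeros_like(cwm), where=tot > 0)
        elif d.kind == "binary":
            truthy = vals.fillna(False).astype(bool).to_numpy()
            cols[f"{d.name}_yes"] = cov[:, truthy].sum(axis=1)
            cols[f"{d.name}_no"] = cov[:, ~truthy & vals.notna().to_numpy()].sum(axis=1)
        else:
            for lev in d.levels:
                mask = (vals == lev).to_numpy()
                cols[f"{d.name}_{lev}"] = cov[:, mask].sum(axis=1)
    out = pd.DataFrame(cols, index=series.units)
    if standardise:
        rng = out.max() - out.min()
        rng[rng == 0] = 1.0
        out = (out - out.min()) / rng
    return out


def _pseudo_f_stats(d2: np.ndarray, assignments: np.ndarray,
                    group_sizes: np.ndarray, ss_total: float):
    """pseudo-F for each row of `assignments` (integer group codes)."""
    n, a = d2.shape[0], len(group_sizes)
    fs = np.empty(len(assignments))
    for r, codes in enumerate(assignments):
        ss_within = 0.0
        for g in range(a):
            idx = np.flatnonzero(codes == g)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        fs[r] = (ss_between / (a - 1)) / (ss_within / (n - a))
    return fs


def _distinct_assignments(codes: np.ndarray):
    """All distinct rearrangements of a vector of integer group codes."""
    n = len(codes)
    counts = np.bincount(codes)
    out = []

    def rec(positions, remaining_counts, current):
        live = [g for g, c in enumerate(remaining_counts) if c > 0]
        if len(live) == 1:
            full = current.copy()
            full[positions] = live[0]
            out.append(full)
            return
        g = live[0]
        for combo in combinations(range(len(positions)), remaining_counts[g]):
            chosen = [positions[i] for i in combo]
            rest = [p for i, p in enumerate(positions) if i not in set(combo)]
            nxt = list(remaining_counts)
            nxt[g] = 0
            cur = current.copy()
            cur[chosen] = g
            rec(rest, nxt, cur)

    rec(list(range(n)), list(counts), np.full(n, -1, dtype=int))
    return np.array(out)


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None, method: str = "auto") -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor.

    Parameters
    ----------
    groups:
        Per-object group labels, aligned with ``d.labels``.
    n_perm:
        Monte-Carlo permutations (ignored when the exact test is used).
    method:
        ``"auto"`` picks the exhaustive test when the number of distinct
        label assignments is at most 10,000; ``"exhaustive"`` forces it;
        ``"monte_carlo"`` forces sampling (requires a seed).
    """
    groups = np.asarray(list(groups))
    n = len(d)
    if len(groups) != n:
        raise ValueError("groups length does not match distance matrix")
    uniq, codes = np.unique(groups, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 1:
        raise ValueError("every group needs at least one object")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = d.values ** 2
    ss_total = d2.sum() / (2 * n)
    obs = _pseudo_f_stats(d2, codes[None, :], sizes, ss_total)[0]
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    n_distinct = math.factorial(n) // math.prod(math.factorial(int(s)) for s in sizes)
    exhaustive = method == "exhaustive" or (
        method == "auto" and n_distinct <= EXHAUSTIVE_LIMIT)
    if exhaustive:
        all_assign = _distinct_assignments(codes)
        fs = _pseudo_f_stats(d2, all_assign, sizes, ss_total)
        # include every distinct assignment once; observed is among them
        p = float(np.count_nonzero(fs >= obs - 1e-12)) / len(fs)
        n_used = len(fs)
    else:
        if seed is None:
            raise ValueError("Monte-Carlo PERMANOVA requires a seed")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        fs = _pseudo_f_stats(d2, perms, sizes, ss_total)
        p = (float(np.count_nonzero(fs >= obs - 1e-12)) + 1) / (n_perm + 1)
        n_used = n_perm
    result = PermanovaResult(float(obs), float(r2), a - 1, n - a, float(p),
                             n_used, seed, exhaustive)
    logger.info("%s", result.summary())
    return result
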