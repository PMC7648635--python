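"""Conditional inference trees relating persistence to functional traits.

Recursive binary partitioning in which every split must first survive a
permutation test of independence: at each node each candidate trait is
tested against the response with a rank-based permutation statistic, the
p-values are Bonferroni-adjusted over the testable traits, and the node
splits on the best trait only if its adjusted p-value is below alpha.
Growth stops when no test rejects, so tree size is controlled by the tests
rather than by pruning.

This is a deliberately simplified rank/permutation analogue of the
conditional-inference framework of ctree: ordered predictors use an
absolute rank-correlation statistic, categorical predictors a
between-group rank dispersion (Kruskal-type) statistic, and all p-values
come from seeded Monte-Carlo permutation of the response with the add-one
rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import TraitTable

logger = logging.getLogger(__name__)

__all__ = ["CITParams", "CITNode", "CITree", "association_test",
           "select_split_variable", "best_split", "grow_tree", "render_tree",
           "observations_from_wrt"]


@dataclass(frozen=True)
class CITParams:
    """Growth controls: significance level, permutations, node-size floors."""

    alpha: float = 0.05
    n_perm: int = 9999
    min_node: int = 20
    min_leaf: int = 7
    max_depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("need n_perm >= 99")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class CITNode:
    """One node: either an internal split or a leaf with a response summary."""

    n: int
    summary: dict                     # n, mean, q1, median, q3 of the response
    trait: str | None = None
    p_adjusted: float | None = None
    rule: dict | None = None          # {"threshold": c} or {"levels": [...]}
    left: "CITNode | None" = None
    right: "CITNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.trait is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "summary": self.summary}
        if not self.is_leaf:
            d.update(trait=self.trait, p_adjusted=self.p_adjusted,
                     rule=self.rule, left=self.left.to_dict(),
                     right=self.right.to_dict())
        return d


@dataclass
class CITree:
    """A grown conditional inference tree plus the parameters that grew it."""

    root: CITNode
    params: CITParams
    trait_names: list = field(default_factory=list)

    @property
    def depth(self) -> int:
        def rec(node):
            if node.is_leaf:
                return 0
            return 1 + max(rec(node.left), rec(node.right))
        return rec(self.root)

    @property
    def n_leaves(self) -> int:
        def rec(node):
            if node.is_leaf:
                return 1
            return rec(node.left) + rec(node.right)
        return rec(self.root)

    def root_trait(self) -> str | None:
        return self.root.trait

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "params": {"alpha": self.params.alpha, "n_perm": self.params.n_perm,
                       "min_node": self.params.min_node,
                       "min_leaf": self.params.min_leaf,
                       "max_depth": self.params.max_depth,
                       "seed": self.params.seed},
            "traits": list(self.trait_names),
            "root": self.root.to_dict(),
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _response_summary(y: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(y, [25, 50, 75])
    return {"n": int(len(y)), "mean": float(np.mean(y)), "q1": float(q1),
            "median": float(med), "q3": float(q3)}


def _is_ordered(kind: str) -> bool:
    return kind in ("quantitative", "binary")


def _encode(x: pd.Series, kind: str) -> np.ndarray:
    if kind == "quantitative":
        return x.to_numpy(dtype=float)
    if kind == "binary":
        return x.map({True: 1.0, False: 0.0}).to_numpy(dtype=float)
    return x.to_numpy(dtype=object)


def association_test(x, y, kind: str = "quantitative", n_perm: int = 9999,
                     seed: int = 0) -> tuple[float, float]:
    """Permutation test of independence between one trait and the response.

    Ordered traits (quantitative or binary) use the absolute Spearman-type
    statistic |sum a_i b_i| on centred ranks; categorical traits use the
    between-group dispersion of response ranks, sum_g n_g (rbar_g - rbar)^2.
    Missing x is dropped casewise.  Returns (statistic, p) with
    p = (b + 1) / (n_perm + 1); a constant trait gives p = 1 by convention.
    """
    stat, p, _ = _association(x, y, kind, n_perm, seed)
    return stat, p


def _association(x, y, kind: str, n_perm: int, seed: int):
    """(statistic, Monte-Carlo p, permutation z-score).

    The z-score standardises the observed statistic against its permutation
    null (mean/sd over the sampled permutations), giving a scale on which
    traits of different kinds stay comparable when their p-values saturate
    at the attainable minimum.
    """
    x = pd.Series(list(x))
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = x.notna().to_numpy() & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(y) < 2:
        raise ValueError("fewer than 2 complete cases")
    if np.all(y == y[0]):
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    n = len(y)
    perms = np.empty((n_perm, n))
    base = np.broadcast_to(ry, (n_perm, n))
    perms[:] = rng.permuted(base, axis=1)

    ordered = _is_ordered(kind)
    if ordered:
        xv = _encode(x, kind)
        if np.all(xv == xv[0]):
            return 0.0, 1.0, 0.0
        rx = stats.rankdata(xv)
        rx = rx - rx.mean()
        obs = abs(float(rx @ ry))
        null = np.abs(perms @ rx)
    else:
        codes, _ = pd.factorize(x, sort=True)
        if codes.max() == 0:
            return 0.0, 1.0, 0.0
        counts = np.bincount(codes).astype(float)
        ind = np.zeros((n, codes.max() + 1))
        ind[np.arange(n), codes] = 1.0
        means_obs = (ry @ ind) / counts
        obs = float(counts @ means_obs ** 2)
        means = (perms @ ind) / counts
        null = (means ** 2) @ counts
    b = int(np.count_nonzero(null >= obs - 1e-12))
    sd = float(null.std())
    z = (obs - float(null.mean())) / sd if sd > 0 else 0.0
    return obs, (b + 1) / (n_perm + 1), z


def select_split_variable(traits: pd.DataFrame, kinds: dict, y,
                          params: CITParams, seed: int | None = None):
    """Bonferroni-adjusted strongest-association trait, or None.

    Returns (trait_name, adjusted_p) for the trait with the smallest
    adjusted p-value when that is below alpha; otherwise (None, smallest
    adjusted p).  Ties break on the unadjusted p, then on the permutation
    z-score of the statistic (p-values saturate at the attainable minimum
    on strong effects, the z-score does not), then on declared column order.
    """
    y = np.asarray(list(y), dtype=float)
    if seed is None:
        seed = params.seed
    results = []
    for name in traits.columns:
        x = traits[name]
        ok = x.notna().to_numpy()
        if ok.sum() < 2:
            continue
        xv = x[ok]
        if len(pd.unique(xv.dropna())) < 2 or np.all(y[ok] == y[ok][0]):
            continue
        # one shared permutation stream per node: identical traits then get
        # identical p and z, so ties genuinely fall to declared order
        _, p, z = _association(xv, y[ok], kinds[name], params.n_perm,
                               (seed * 1009 + 1) % (2**31 - 1))
        results.append((name, p, z))
    if not results:
        return None, 1.0
    m = len(results)
    adjusted = [(min(1.0, p * m), p, -z, i, name)
                for i, (name, p, z) in enumerate(results)]
    p_adj, p_raw, _, _, name = min(adjusted)
    if p_adj < params.alpha:
        return name, p_adj
    return None, p_adj


def best_split(x, y, kind: str, min_leaf: int = 1):
    """Best binary partition of a node on one trait.

    Ordered traits: the cutpoint c among observed values maximising the
    absolute standardised two-sample rank-sum statistic between
    {x <= c} and {x > c}, both children >= min_leaf; the reported threshold
    is the largest observed value of the left group.  Categorical traits:
    exhaustive search over binary level subsets (<= 10 levels).

    Returns ``{"threshold": c}`` or ``{"levels": [...]}`` (levels list =
    left child), or None when no admissible split exists.
    """
    x = pd.Series(list(x))
    y = np.asarray(list(y), dtype=float)
    ok = x.notna().to_numpy()
    x, y = x[ok].reset_index(drop=True), y[ok]
    n = len(y)
    if n < 2 * min_leaf:
        return None
    ry = stats.rankdata(y)
    rbar, svar = ry.mean(), ry.var(ddof=0)
    if svar == 0:
        return None

    def score(mask: np.ndarray) -> float:
        n1 = int(mask.sum())
        if n1 < min_leaf or n - n1 < min_leaf:
            return -np.inf
        w = ry[mask].sum()
        ew = n1 * rbar
        vw = svar * n1 * (n - n1) / (n - 1)
        return abs(w - ew) / np.sqrt(vw)

    if _is_ordered(kind):
        xv = _encode(x, kind)
        order = np.argsort(xv, kind="mergesort")
        xs = xv[order]
        best, best_c = -np.inf, None
        for cut in np.unique(xs)[:-1]:
            s = score(xv <= cut)
            if s > best + 1e-12:
                best, best_c = s, cut
        if best_c is None:
            return None
        return {"threshold": float(best_c)}
    levels = sorted(pd.unique(x))
    if len(levels) > 10:
        raise ValueError("categorical split search limited to 10 levels")
    best, best_subset = -np.inf, None
    for bits in range(1, 2 ** (len(levels) - 1)):
        subset = [lev for i, lev in enumerate(levels) if bits >> i & 1]
        s = score(x.isin(subset).to_numpy())
        if s > best + 1e-12:
            best, best_subset = s, subset
    if best_subset is None:
        return None
    return {"levels": [str(l) for l in best_subset]}


def _left_mask(x: pd.Series, kind: str, rule: dict) -> np.ndarray:
    if "threshold" in rule:
        xv = _encode(x, kind)
        with np.errstate(invalid="ignore"):
            mask = xv <= rule["threshold"]
        mask = np.where(np.isnan(xv), False, mask)
    else:
        mask = x.astype(str).isin(rule["levels"]).to_numpy()
    missing = x.isna().to_numpy()
    if missing.any():
        # observations missing the split variable follow the majority child
        left_n = int(mask[~missing].sum())
        go_left = left_n >= (len(x) - missing.sum()) - left_n
        logger.info("%d observation(s) missing split variable follow the "
                    "%s child", int(missing.sum()),
                    "left" if go_left else "right")
        mask = mask | (missing & go_left)
    return np.asarray(mask, dtype=bool)


def grow_tree(traits: pd.DataFrame, y, kinds: dict,
              params: CITParams | None = None) -> CITree:
    """Grow a conditional inference tree for a numeric response.

    Parameters
    ----------
    traits:
        One row per observation, one column per candidate trait.
    y:
        Response values (weighted residence time in the persistence
        analysis), one per observation.
    kinds:
        Trait name -> kind ("quantitative", "binary", "categorical").
    """
    if params is None:
        params = CITParams()
    y = np.asarray(list(y), dtype=float)
    if len(y) == 0:
        raise ValueError("empty observation set")
    if len(traits) != len(y):
        raise ValueError("traits and response lengths differ")

    def build(idx: np.ndarray, depth: int, node_seed: int) -> CITNode:
        yy = y[idx]
        node = CITNode(n=len(idx), summary=_response_summary(yy))
        if (len(idx) < params.min_node or depth >= params.max_depth
                or np.all(yy == yy[0])):
            return node
        sub = traits.iloc[idx].reset_index(drop=True)
        name, p_adj = select_split_variable(sub, kinds, yy, params,
                                            seed=node_seed)
        if name is None:
            return node
        rule = best_split(sub[name], yy, kinds[name], min_leaf=params.min_leaf)
        if rule is None:
            return node
        mask = _left_mask(sub[name], kinds[name], rule)
        if mask.sum() < params.min_leaf or (~mask).sum() < params.min_leaf:
            return node
        node.trait, node.p_adjusted, node.rule = name, float(p_adj), rule
        node.left = build(idx[mask], depth + 1, node_seed * 2 + 1)
        node.right = build(idx[~mask], depth + 1, node_seed * 2 + 2)
        return node

    root = build(np.arange(len(y)), 0, params.seed + 1)
    return CITree(root, params, list(traits.columns))


def render_tree(tree: CITree) -> str:
    """Indented text rendering: splits with rule and adjusted p, leaves with
    the observation count and response quartiles."""
    lines: list[str] = []

    def fmt_rule(node: CITNode, left: bool) -> str:
        r = node.rule
        if "threshold" in r:
            op = "<=" if left else ">"
            return f"{node.trait} {op} {r['threshold']:.1f}"
        levs = r["levels"]
        if left:
            return f"{node.trait} in {{{', '.join(levs)}}}"
        return f"{node.trait} not in {{{', '.join(levs)}}}"

    def rec(node: CITNode, prefix: str, header: str) -> None:
        if node.is_leaf:
            s = node.summary
            lines.append(f"{prefix}{header}leaf: n = {s['n']}, "
                         f"median = {s['median']:.1f} "
                         f"[{s['q1']:.1f}, {s['q3']:.1f}]")
            return
        lines.append(f"{prefix}{header}split on {node.trait} "
                     f"(p = {node.p_adjusted:.4g}, n = {node.n})")
        rec(node.left, prefix + "  ", f"[{fmt_rule(node, True)}] ")
        rec(node.right, prefix + "  ", f"[{fmt_rule(node, False)}] ")

    rec(tree.root, "", "")
    return "\n".join(lines)


def observations_from_wrt(wrt: pd.DataFrame, traits: TraitTable,
                          response: str = "wrt_pa"):
    """Join a WRT table with species traits into CIT observations.

    One row per (species, unit) with at least one occurrence; predictors are
    the species' fixed trait values replicated across its units.  Returns
    (trait frame, response array, kinds dict); species without trait rows
    are dropped with a warning.
    """
    known = wrt["species"].isin(traits.data.index)
    if (~known).any():
        logger.warning("dropping %d observations for species without traits",
                       int((~known).sum()))
    wrt = wrt[known]
    x = traits.data.loc[wrt["species"]].reset_index(drop=True)
    kinds = {d.name: d.kind for d in traits.schema}
    return x, wrt[response].to_numpy(dtype=float), kinds
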