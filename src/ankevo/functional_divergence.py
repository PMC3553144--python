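"""Type I and type II functional-divergence estimation between two
monophyletic sequence clusters, in the spirit of Gu's rate-shift models.

Per-column substitution counts within each cluster's subtree are obtained
by Fitch parsimony.  Type I divergence is the decoupling of site-specific
evolutionary rates between the clusters: with probability ``1 - theta`` a
site's rate is shared, with probability ``theta`` the two clusters draw
independent rates.  Rates are gamma-distributed and counts are Poisson
given the rate, so the site likelihoods have closed negative-binomial
forms and ``theta`` is fitted by bounded maximum likelihood.  A single
pooled gamma shape is used for both clusters: a shared/independent rate
mixture with cluster-specific shapes has no symmetric definition of the
shared component and would break invariance under swapping the clusters.

Type II divergence targets radical shifts at conserved positions: sites
conserved within each cluster but fixed for different residues between
them.  Each site receives a posterior odds ratio (divergent class vs
background); sites above the cut-off whose cluster consensuses fall in
different biochemical property classes are the radical sites.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_formats import Alignment
from .tree import Tree, TreeError, TreeNode

__all__ = [
    "ClusterPair",
    "SiteCounts",
    "Type1Result",
    "Type2Result",
    "fitch_counts",
    "estimate_type1",
    "candidate_sites_type1",
    "estimate_type2",
    "taxonomic_grouping",
    "sample_counts",
    "property_class",
    "property_change_label",
    "lrt_pvalue",
]

MISSING = {"-", "X", "?"}

#: biochemical property classes used for radical-change calls
PROPERTY_CLASSES = {
    "+": set("KRH"),
    "-": set("DE"),
    "Hydrophobic": set("AVLIMFW"),
    "Hydrophilic": set("STNQCGPY"),
}
_RESIDUE_CLASS = {
    aa: name for name, members in PROPERTY_CLASSES.items() for aa in members
}


def property_class(residue: str) -> str | None:
    return _RESIDUE_CLASS.get(residue.upper())


def property_change_label(res_a: str, res_b: str) -> str:
    """Label of a between-cluster consensus change, e.g. ``Hydrophilic/+``."""
    ca, cb = property_class(res_a), property_class(res_b)
    if ca is None or cb is None:
        raise ValueError(f"no property class for {res_a!r} or {res_b!r}")
    return f"{ca}/{cb}"


@dataclass
class ClusterPair:
    msa: Alignment
    tree: Tree
    cluster_a: frozenset
    cluster_b: frozenset
    require_monophyly: bool = True

    def __post_init__(self) -> None:
        self.cluster_a = frozenset(self.cluster_a)
        self.cluster_b = frozenset(self.cluster_b)
        if self.cluster_a & self.cluster_b:
            raise ValueError("clusters must be disjoint")
        taxa = set(self.msa.taxa)
        for name, cluster in (("A", self.cluster_a), ("B", self.cluster_b)):
            missing = cluster - taxa
            if missing:
                raise ValueError(f"cluster {name}: unknown taxa {sorted(missing)}")
            if len(cluster) < 4:
                raise ValueError(f"cluster {name} needs at least 4 taxa")
            if self.require_monophyly and not self.tree.is_monophyletic(cluster):
                raise TreeError(f"cluster {name} is not monophyletic")


@dataclass
class SiteCounts:
    x_a: np.ndarray  # per-column minimum substitutions in cluster A
    x_b: np.ndarray
    masked: np.ndarray  # True where a cluster had no informative states

    def __post_init__(self) -> None:
        self.x_a = np.asarray(self.x_a, dtype=int)
        self.x_b = np.asarray(self.x_b, dtype=int)
        self.masked = np.asarray(self.masked, dtype=bool)
        if not (len(self.x_a) == len(self.x_b) == len(self.masked)):
            raise ValueError("count vectors disagree in length")
        if np.any(self.x_a < 0) or np.any(self.x_b < 0):
            raise ValueError("negative counts")


@dataclass
class Type1Result:
    theta: float
    se: float
    lrt: float
    alpha_a: float
    alpha_b: float
    scale_a: float
    scale_b: float
    posterior: np.ndarray
    loglik: float
    loglik_null: float

    @property
    def p_value(self) -> float:
        return lrt_pvalue(self.lrt)


@dataclass
class Type2Result:
    theta2: float
    site_score: np.ndarray  # posterior odds ratio, 0 where consensuses agree
    sites: list[int]  # 1-based columns with score > cutoff
    radical_sites: list[int]  # subset with a property-class change
    property_change: dict[int, tuple[str, str, str, str]]
    excluded_columns: list[int] = field(default_factory=list)  # consensus ties


# ---------------------------------------------------------------------------
# Fitch parsimony counts
# ---------------------------------------------------------------------------


def _subtree_for(tree: Tree, cluster: frozenset) -> TreeNode:
    """The node whose leafset equals ``cluster`` (rerooting if the cluster
    sits across the stored root)."""
    for node in tree.root.walk():
        below = frozenset(leaf.label for leaf in node.leaves())
        if below == cluster:
            return node
    # cluster may be the complement of a stored clade: reroot and retry
    all_taxa = frozenset(tree.leaf_names)
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = frozenset(leaf.label for leaf in node.leaves())
        if all_taxa - below == cluster:
            rerooted = tree.reroot_on_node(node)
            return _subtree_for(rerooted, cluster)
    raise TreeError(f"cluster is not monophyletic: {sorted(cluster)}")


def _fitch_column(node: TreeNode, states: dict[str, str]) -> tuple[set, int]:
    """Bottom-up Fitch pass; leaves with missing states carry no state set."""
    if node.is_leaf:
        s = states.get(node.label)
        if s is None or s in MISSING:
            return set(), 0
        return {s}, 0
    child_sets = []
    count = 0
    for child in node.children:
        cs, cc = _fitch_column(child, states)
        count += cc
        if cs:
            child_sets.append(cs)
    if not child_sets:
        return set(), count
    current = child_sets[0]
    for cs in child_sets[1:]:
        inter = current & cs
        if inter:
            current = inter
        else:
            current = current | cs
            count += 1
    return current, count


def fitch_counts(pair: ClusterPair) -> SiteCounts:
    """Per-column minimum substitution counts on each cluster's subtree."""
    sub_a = _subtree_for(pair.tree, pair.cluster_a)
    sub_b = _subtree_for(pair.tree, pair.cluster_b)
    mat = pair.msa.to_array()
    order = {t: i for i, t in enumerate(pair.msa.taxa)}
    L = pair.msa.length
    x_a = np.zeros(L, dtype=int)
    x_b = np.zeros(L, dtype=int)
    masked = np.zeros(L, dtype=bool)
    for col in range(L):
        states = {t: mat[order[t], col] for t in pair.msa.taxa}
        set_a, ca = _fitch_column(sub_a, states)
        set_b, cb = _fitch_column(sub_b, states)
        x_a[col], x_b[col] = ca, cb
        if not set_a or not set_b:
            masked[col] = True
    return SiteCounts(x_a, x_b, masked)


# ---------------------------------------------------------------------------
# Type I mixture likelihood
# ---------------------------------------------------------------------------


def _log_nb(x: np.ndarray, alpha: float, t: float) -> np.ndarray:
    """log P(x) for Poisson(lambda*t) with lambda ~ Gamma(alpha, rate alpha)."""
    return (
        special.gammaln(alpha + x)
        - special.gammaln(alpha)
        - special.gammaln(x + 1.0)
        + x * math.log(t)
        + alpha * math.log(alpha)
        - (alpha + x) * math.log(alpha + t)
    )


def _log_shared(
    xa: np.ndarray, xb: np.ndarray, alpha: float, ta: float, tb: float
) -> np.ndarray:
    s = xa + xb
    return (
        special.gammaln(alpha + s)
        - special.gammaln(alpha)
        - special.gammaln(xa + 1.0)
        - special.gammaln(xb + 1.0)
        + xa * math.log(ta)
        + xb * math.log(tb)
        + alpha * math.log(alpha)
        - (alpha + s) * math.log(alpha + ta + tb)
    )


def _site_loglik(params, xa, xb):
    theta, log_alpha, log_ta, log_tb = params
    alpha = math.exp(log_alpha)
    ta, tb = math.exp(log_ta), math.exp(log_tb)
    ls = _log_shared(xa, xb, alpha, ta, tb)
    li = _log_nb(xa, alpha, ta) + _log_nb(xb, alpha, tb)
    if theta <= 0.0:
        return ls, li, ls
    if theta >= 1.0:
        return ls, li, li
    mix = np.logaddexp(np.log1p(-theta) + ls, math.log(theta) + li)
    return ls, li, mix


def _neg_loglik(params, xa, xb):
    _, _, mix = _site_loglik(params, xa, xb)
    return -float(np.sum(mix))


_BOUNDS = [
    (0.0, 1.0 - 1e-6),
    (math.log(0.05), math.log(50.0)),
    (math.log(1e-4), math.log(100.0)),
    (math.log(1e-4), math.log(100.0)),
]


def _fit(xa, xb, *, theta_fixed=None, restarts=4, seed=0):
    rng = np.random.default_rng(seed)
    mean_a = max(float(np.mean(xa)), 1e-3)
    mean_b = max(float(np.mean(xb)), 1e-3)
    best = None
    starts = []
    for k in range(restarts):
        if k == 0:
            theta0, alpha0 = 0.3, 0.5
        else:
            theta0 = float(rng.uniform(0.05, 0.95))
            alpha0 = float(rng.uniform(0.2, 3.0))
        starts.append(
            [
                theta0 if theta_fixed is None else theta_fixed,
                math.log(alpha0),
                math.log(mean_a),
                math.log(mean_b),
            ]
        )
    for x0 in starts:
        if theta_fixed is None:
            res = optimize.minimize(
                _neg_loglik,
                x0,
                args=(xa, xb),
                method="L-BFGS-B",
                bounds=_BOUNDS,
            )
        else:

            def obj(p):
                return _neg_loglik([theta_fixed, *p], xa, xb)

            res = optimize.minimize(
                obj, x0[1:], args=(), method="L-BFGS-B", bounds=_BOUNDS[1:]
            )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("type I likelihood optimization failed to converge")
    if theta_fixed is not None:
        params = np.array([theta_fixed, *best.x])
    else:
        params = np.asarray(best.x)
    return params, -float(best.fun)


def _theta_se(params, xa, xb) -> float:
    """Standard error of theta from observed-information curvature."""
    h = 1e-4

    def nll_theta(theta):
        p = params.copy()
        p[0] = min(max(theta, 0.0), 1.0 - 1e-9)
        return _neg_loglik(p, xa, xb)

    t0 = params[0]
    lo, hi = max(t0 - h, 0.0), min(t0 + h, 1.0 - 1e-9)
    f0, fl, fh = nll_theta(t0), nll_theta(lo), nll_theta(hi)
    num = fl + fh - 2.0 * f0
    denom = ((hi - lo) / 2.0) ** 2
    curv = num / denom if denom > 0 else np.nan
    if not np.isfinite(curv) or curv <= 0:
        return float("nan")
    return 1.0 / math.sqrt(curv)


def estimate_type1(
    counts: SiteCounts,
    pair: ClusterPair | None = None,
    *,
    restarts: int = 4,
    seed: int = 0,
) -> Type1Result:
    """Fit the shared/independent rate mixture and test theta = 0.

    ``lrt`` is ``2 * (lnL(theta_hat) - lnL(theta=0))``; its null
    reference is a 50:50 mixture of a point mass at zero and chi^2(1)
    because theta = 0 lies on the boundary of the parameter space.
    """
    keep = ~counts.masked
    xa = counts.x_a[keep].astype(float)
    xb = counts.x_b[keep].astype(float)
    if len(xa) < 50:
        warnings.warn(
            f"only {len(xa)} informative columns; theta estimates below "
            "L = 50 are unreliable",
            stacklevel=2,
        )
    params, ll = _fit(xa, xb, restarts=restarts, seed=seed)
    params0, ll0 = _fit(xa, xb, theta_fixed=0.0, restarts=restarts, seed=seed)
    lrt = 2.0 * (ll - ll0)
    if lrt < -1e-6:
        # alternative fit trapped below the null: keep the null
        params, ll = params0, ll0
        lrt = 0.0
    lrt = max(lrt, 0.0)
    theta, log_alpha, log_ta, log_tb = params
    alpha = math.exp(log_alpha)
    ls, li, mix = _site_loglik(params, xa, xb)
    if theta <= 0:
        post_kept = np.zeros_like(xa)
    else:
        post_kept = np.exp(math.log(theta) + li - mix)
    posterior = np.zeros(len(counts.x_a))
    posterior[keep] = post_kept
    return Type1Result(
        theta=float(theta),
        se=_theta_se(params, xa, xb),
        lrt=float(lrt),
        alpha_a=alpha,
        alpha_b=alpha,
        scale_a=math.exp(log_ta),
        scale_b=math.exp(log_tb),
        posterior=posterior,
        loglik=ll,
        loglik_null=ll0,
    )


def lrt_pvalue(lrt: float) -> float:
    """Boundary-corrected p-value: 50:50 mix of point mass at 0 and chi2(1)."""
    if lrt <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(lrt, df=1))


def candidate_sites_type1(
    result: Type1Result,
    *,
    cutoff: float = 0.85,
    reference: str | None = None,
    msa: Alignment | None = None,
) -> list[int]:
    """Columns with posterior strictly above the cut-off, 1-based.

    When ``reference`` names a row of ``msa``, positions are reported in
    that row's ungapped residue numbering (columns where the reference
    is gapped are dropped from the mapping).
    """
    cols = [i + 1 for i, p in enumerate(result.posterior) if p > cutoff]
    if reference is None:
        return cols
    if msa is None:
        raise ValueError("mapping to a reference requires the alignment")
    ref = msa.row(reference).residues
    col_to_res = {}
    res = 0
    for i, ch in enumerate(ref):
        if ch != "-":
            res += 1
            col_to_res[i + 1] = res
    return [col_to_res[c] for c in cols if c in col_to_res]


# ---------------------------------------------------------------------------
# Type II divergence
# ---------------------------------------------------------------------------


def _consensus(column: np.ndarray) -> str | None:
    """Strict-majority consensus; None on a tie or no informative residue."""
    vals, cnt = np.unique(column[~np.isin(column, sorted(MISSING))], return_counts=True)
    if len(vals) == 0:
        return None
    top = cnt.max()
    winners = vals[cnt == top]
    if len(winners) != 1:
        return None
    return str(winners[0])


def _log_f(x_sum, xa, xb, alpha, ta, tb, extra):
    """log of the shared-rate integral with an extra exp(-lambda*extra)."""
    return (
        special.gammaln(alpha + x_sum)
        - special.gammaln(alpha)
        - special.gammaln(xa + 1.0)
        - special.gammaln(xb + 1.0)
        + xa * np.log(ta)
        + xb * np.log(tb)
        + alpha * math.log(alpha)
        - (alpha + x_sum) * np.log(alpha + ta + tb + extra)
    )


def estimate_type2(
    pair: ClusterPair,
    counts: SiteCounts | None = None,
    *,
    cutoff: float = 17.0,
    restarts: int = 3,
    seed: int = 0,
) -> Type2Result:
    """Posterior-odds scoring of radical between-cluster residue shifts.

    Background sites share a gamma-distributed rate that also governs the
    chance of a between-cluster consensus difference; divergent-class
    sites are fixed for different residues regardless of their
    within-cluster rate.  ``theta2`` is the fitted weight of the
    divergent class.  ``site_score`` is the per-site posterior odds of
    the divergent class (the conventional ``> 17`` statistic: an odds
    ratio, not a probability).
    """
    if counts is None:
        counts = fitch_counts(pair)
    mat = pair.msa.to_array()
    order = {t: i for i, t in enumerate(pair.msa.taxa)}
    idx_a = [order[t] for t in sorted(pair.cluster_a)]
    idx_b = [order[t] for t in sorted(pair.cluster_b)]
    L = pair.msa.length
    cons_a, cons_b, c_flag = [], [], np.zeros(L, dtype=bool)
    excluded = []
    usable = np.ones(L, dtype=bool)
    for col in range(L):
        ca = _consensus(mat[idx_a, col])
        cb = _consensus(mat[idx_b, col])
        cons_a.append(ca)
        cons_b.append(cb)
        if ca is None or cb is None:
            usable[col] = False
            excluded.append(col + 1)
        else:
            c_flag[col] = ca != cb
    keep = usable & ~counts.masked
    xa = counts.x_a[keep].astype(float)
    xb = counts.x_b[keep].astype(float)
    cc = c_flag[keep]
    s = xa + xb

    def neg_ll(p):
        theta2 = p[0]
        alpha = math.exp(p[1])
        ta, tb, tm = math.exp(p[2]), math.exp(p[3]), math.exp(p[4])
        lf0 = _log_f(s, xa, xb, alpha, ta, tb, 0.0)
        lfm = _log_f(s, xa, xb, alpha, ta, tb, tm)
        # background: P(counts, c=1) = F(0) - F(tm); P(counts, c=0) = F(tm)
        with np.errstate(over="ignore"):
            diff = lf0 + np.log1p(-np.exp(np.clip(lfm - lf0, None, 0.0)))
        log_bg = np.where(cc, diff, lfm)
        log_bg = np.where(np.isfinite(log_bg), log_bg, -745.0)
        if theta2 <= 0:
            total = log_bg
        else:
            log_div = np.where(cc, lf0, -np.inf)
            total = np.logaddexp(
                math.log1p(-theta2) + log_bg,
                math.log(theta2) + log_div,
            )
        return -float(np.sum(total))

    bounds = [
        (0.0, 0.5),
        (math.log(0.05), math.log(50.0)),
        (math.log(1e-4), math.log(100.0)),
        (math.log(1e-4), math.log(100.0)),
        (math.log(1e-4), math.log(100.0)),
    ]
    rng = np.random.default_rng(seed)
    mean_a = max(float(np.mean(xa)), 1e-3) if len(xa) else 1e-3
    mean_b = max(float(np.mean(xb)), 1e-3) if len(xb) else 1e-3
    best = None
    for k in range(restarts):
        x0 = [
            0.02 if k == 0 else float(rng.uniform(0.0, 0.3)),
            math.log(0.5 if k == 0 else float(rng.uniform(0.2, 3.0))),
            math.log(mean_a),
            math.log(mean_b),
            math.log(max(float(np.mean(cc)) if len(cc) else 0.05, 0.01)),
        ]
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta2, la, lta, ltb, ltm = best.x
    alpha = math.exp(la)
    ta, tb, tm = math.exp(lta), math.exp(ltb), math.exp(ltm)

    # per-site posterior odds ratio (0 where consensuses agree)
    score = np.zeros(L)
    if theta2 > 0:
        xa_all = counts.x_a.astype(float)
        xb_all = counts.x_b.astype(float)
        s_all = xa_all + xb_all
        lf0 = _log_f(s_all, xa_all, xb_all, alpha, ta, tb, 0.0)
        lfm = _log_f(s_all, xa_all, xb_all, alpha, ta, tb, tm)
        with np.errstate(over="ignore"):
            diff = lf0 + np.log1p(-np.exp(np.clip(lfm - lf0, None, 0.0)))
        for col in range(L):
            if not keep[col] or not c_flag[col]:
                continue
            log_bg = diff[col] if np.isfinite(diff[col]) else -745.0
            log_odds = (
                math.log(theta2) - math.log1p(-theta2) + lf0[col] - log_bg
            )
            score[col] = math.exp(min(log_odds, 700.0))

    sites = [c + 1 for c in range(L) if score[c] > cutoff]
    prop = {}
    radical = []
    for col1 in sites:
        ra, rb = cons_a[col1 - 1], cons_b[col1 - 1]
        cls_a = property_class(ra)
        cls_b = property_class(rb)
        prop[col1] = (ra, rb, cls_a or "?", cls_b or "?")
        if cls_a and cls_b and cls_a != cls_b:
            radical.append(col1)
    return Type2Result(
        theta2=float(theta2),
        site_score=score,
        sites=sites,
        radical_sites=radical,
        property_change=prop,
        excluded_columns=excluded,
    )


# ---------------------------------------------------------------------------
# Grouping roster + generative sampler
# ---------------------------------------------------------------------------


def taxonomic_grouping(
    msa: Alignment,
    labels: dict[str, str],
    *,
    tree: Tree | None = None,
    min_group: int = 4,
) -> list[tuple[str, str, frozenset, frozenset]]:
    """Build the all-pairs comparison roster from a taxon → group map.

    Groups with fewer than ``min_group`` taxa are dropped with a warning.
    Returns ``(group_a, group_b, taxa_a, taxa_b)`` tuples for every
    unordered pair of retained groups (10 groups → 45 comparisons).
    """
    groups: dict[str, set] = {}
    for taxon in msa.taxa:
        if taxon in labels:
            groups.setdefault(labels[taxon], set()).add(taxon)
    kept = {}
    for name in sorted(groups):
        if len(groups[name]) < min_group:
            warnings.warn(
                f"group {name!r} has {len(groups[name])} < {min_group} taxa; "
                "dropped",
                stacklevel=2,
            )
            continue
        kept[name] = frozenset(groups[name])
    names = sorted(kept)
    return [
        (a, b, kept[a], kept[b]) for a, b in itertools.combinations(names, 2)
    ]


def sample_counts(
    *,
    theta: float,
    alpha: float,
    t_a: float,
    t_b: float,
    L: int,
    seed: int = 0,
) -> SiteCounts:
    """Draw per-site count pairs from the type I generative model.

    With probability ``1 - theta`` a site's gamma rate is shared between
    the clusters; otherwise each cluster draws its own.  Counts are
    Poisson with cluster scales ``t_a`` and ``t_b``.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = rng.random(L) >= theta
    lam_a = rng.gamma(alpha, 1.0 / alpha, size=L)
    lam_b = rng.gamma(alpha, 1.0 / alpha, size=L)
    lam_b = np.where(shared, lam_a, lam_b)
    x_a = rng.poisson(lam_a * t_a)
    x_b = rng.poisson(lam_b * t_b)
    return SiteCounts(x_a, x_b, np.zeros(L, dtype=bool))
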