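"""Generators for every input the pipeline consumes, with known ground
truth.

The structural generator builds ideal-geometry ankyrin-like Cα traces:
stacked ~33-residue repeats, each two antiparallel helical segments
(rise 1.5 Å/residue, 100°/residue) joined by a hairpin turn, with a
protruding "finger" loop connecting consecutive repeats.  Conformer
ensembles perturb such a base chain along known orthonormal directions
with known variances, optionally contaminated by random rigid-body
transforms.

The sequence generators evolve a protein family down a known tree under
a Poisson equal-exchangeability model with gamma site rates and an
optional planted fraction of rate-shifted sites in one clade, and codon
alignments under a GY94-like model with per-site omega.  Every output is
bit-reproducible from (parameters, seed) and ships with a
:class:`SyntheticTruth` record; downstream recovery tests consume the
truth only in assertions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .io_formats import Alignment, Sequence, Structure
from .selection_kaks import GENETIC_CODE, SENSE_CODONS
from .tree import Tree, TreeNode
from .ensemble_pca import Ensemble

__all__ = [
    "SyntheticTruth",
    "make_ankyrin_calpha",
    "make_ensemble",
    "simulate_family",
    "simulate_codons",
    "balanced_tree",
    "random_tree",
    "two_clade_tree",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: one ankyrin repeat's worth of consensus-like sequence, tiled as needed
ANK_CONSENSUS = "GHTPLHLAAREGHLEIVEVLLKAGADVNAKDKFG"


@dataclass
class SyntheticTruth:
    seed: int
    tree: Tree | None = None
    theta_planted: float | None = None
    shifted_sites: np.ndarray | None = None
    shift_factor: float | None = None
    directions: np.ndarray | None = None  # q × 3N
    variances: np.ndarray | None = None
    omega_profile: np.ndarray | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def balanced_tree(n_leaves: int, branch_length: float, prefix: str = "t") -> Tree:
    """Fully balanced bifurcating tree with uniform branch lengths
    (n_leaves must be a power of two)."""
    if n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two")
    nodes = [TreeNode(label=f"{prefix}{i + 1}", length=branch_length)
             for i in range(n_leaves)]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes), 2):
            parent = TreeNode(length=branch_length)
            parent.add(nodes[i])
            parent.add(nodes[i + 1])
            nxt.append(parent)
        nodes = nxt
    root = nodes[0]
    root.length = None
    return Tree(root)


def random_tree(
    n_leaves: int,
    *,
    seed: int = 0,
    min_branch: float = 0.05,
    max_branch: float = 0.5,
    prefix: str = "t",
) -> Tree:
    """Random bifurcating topology with uniform random branch lengths."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(label=f"{prefix}{i + 1}") for i in range(n_leaves)]
    for leaf in nodes:
        leaf.length = float(rng.uniform(min_branch, max_branch))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(min_branch, max_branch)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add(n)
    return Tree(root)


def two_clade_tree(
    n_per_clade: int = 6,
    *,
    inner: float = 0.15,
    stem: float = 0.3,
    prefix_a: str = "A",
    prefix_b: str = "B",
) -> Tree:
    """Two ladderized clades A and B joined by stem branches — the
    canonical cluster-pair layout for divergence simulations."""

    def ladder(prefix: str) -> TreeNode:
        node = TreeNode(label=f"{prefix}1", length=inner)
        for i in range(2, n_per_clade + 1):
            parent = TreeNode(length=inner)
            parent.add(node)
            parent.add(TreeNode(label=f"{prefix}{i}", length=inner))
            node = parent
        return node

    root = TreeNode()
    a, b = ladder(prefix_a), ladder(prefix_b)
    a.length = stem
    b.length = stem
    root.add(a)
    root.add(b)
    return Tree(root)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TURN = math.radians(100.0)
_HELIX_RADIUS = 2.3  # Å
_CA_SPACING = 3.8  # Å target for loop points


def _helix(start_z: float, n: int, axis_xy: tuple[float, float],
           ascending: bool, phase: float) -> np.ndarray:
    pts = np.empty((n, 3))
    sign = 1.0 if ascending else -1.0
    for i in range(n):
        angle = phase + i * _HELIX_TURN
        pts[i, 0] = axis_xy[0] + _HELIX_RADIUS * math.cos(angle)
        pts[i, 1] = axis_xy[1] + _HELIX_RADIUS * math.sin(angle)
        pts[i, 2] = start_z + sign * i * _HELIX_RISE
    return pts


def _arc_bridge(p0: np.ndarray, p1: np.ndarray, n: int,
                bulge_hint: np.ndarray) -> np.ndarray:
    """n intermediate points from p0 to p1 with ~3.8 Å spacing, placed on
    a circular arc bulging toward ``bulge_hint`` when the straight path
    would be too short."""
    if n == 0:
        return np.empty((0, 3))
    chord = p1 - p0
    c = float(np.linalg.norm(chord))
    segs = n + 1
    s = _CA_SPACING * segs
    if s <= c * 1.0001:
        return np.array([p0 + chord * k / segs for k in range(1, segs)])
    e1 = chord / c
    hint = bulge_hint - (bulge_hint @ e1) * e1
    if np.linalg.norm(hint) < 1e-9:
        hint = np.array([0.0, 0.0, 1.0])
        hint = hint - (hint @ e1) * e1
    nhat = hint / np.linalg.norm(hint)
    half = brentq(lambda x: math.sin(x) - (c / s) * x, 1e-9, math.pi - 1e-9)
    theta = 2.0 * half
    radius = c / (2.0 * math.sin(half))
    mid = 0.5 * (p0 + p1)
    center = mid - radius * math.cos(half) * nhat
    pts = np.empty((n, 3))
    for k in range(1, segs):
        phi = -half + theta * k / segs
        pts[k - 1] = center + radius * (math.sin(phi) * e1 + math.cos(phi) * nhat)
    return pts


def make_ankyrin_calpha(
    n_repeats: int,
    residues_per_repeat: int = 33,
    seed: int = 0,
) -> Structure:
    """Ideal-geometry Cα trace of a stacked ankyrin-like repeat domain.

    Each repeat is inner helix → hairpin turn → outer helix → finger
    loop toward the next repeat, stacked along y.  Consecutive Cα
    distances stay near 3.8 Å so the chain is connected at the 15 Å ANM
    cutoff.  ``seed`` only perturbs nothing here (the trace is
    deterministic); it is kept for interface symmetry with the other
    generators.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    turn_n = 4
    helix_n = (residues_per_repeat - turn_n - 7) // 2
    loop_n = residues_per_repeat - turn_n - 2 * helix_n
    if helix_n < 3 or loop_n < 1:
        raise ValueError("residues_per_repeat too small for the layout")
    dx = 9.5  # inter-helix axis separation within a repeat
    dy = 10.0  # inter-repeat stacking translation
    coords = []
    helix_top = (helix_n - 1) * _HELIX_RISE
    for rep in range(n_repeats):
        y0 = rep * dy
        h1 = _helix(0.0, helix_n, (0.0, y0), ascending=True, phase=0.0)
        h2 = _helix(helix_top, helix_n, (dx, y0), ascending=False, phase=math.pi)
        t1 = _arc_bridge(h1[-1], h2[0], turn_n, np.array([0.0, 0.0, 1.0]))
        next_start = _helix(0.0, 1, (0.0, y0 + dy), ascending=True, phase=0.0)[0]
        loop = _arc_bridge(h2[-1], next_start, loop_n,
                           np.array([0.0, 0.0, -1.0]))
        coords.extend([h1, t1, h2, loop])
    coords = np.vstack(coords)[: n_repeats * residues_per_repeat]
    n = coords.shape[0]
    seq = (ANK_CONSENSUS * (n // len(ANK_CONSENSUS) + 1))[:n]
    return Structure(
        id=f"synthetic-ank{n_repeats}",
        residue_ids=[("A", i + 1) for i in range(n)],
        coords=coords,
        bfactors=None,
        sequence=seq,
    )


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of rigid translations and rotations
    about the centroid."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for k in range(3):
        basis[k::3, k] = 1.0
    for k, axis in enumerate(np.eye(3)):
        rot = np.cross(np.tile(axis, (n, 1)), centered)
        basis[:, 3 + k] = rot.reshape(-1)
    q, _ = np.linalg.qr(basis)
    return q


def make_ensemble(
    base: Structure,
    directions,
    variances,
    M: int,
    *,
    rigid_noise: bool = False,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> tuple[Ensemble, SyntheticTruth]:
    """Conformer ensemble displaced along known orthonormal directions.

    Member m = RigidTransform_m(base + Σ_k z_mk w_k + ε) with
    z_mk ~ Normal(0, σ_k²) and isotropic ε of scale ``noise_sigma``
    (small against the planted σ_k).  ``directions`` may be a q × 3N
    array or ``"random"``; random directions are drawn orthonormal and
    orthogonal to the rigid-body subspace so that superposition does not
    consume planted variance.  Non-orthonormal user directions are
    re-orthonormalized with a warning.
    """
    rng = np.random.default_rng(seed)
    n3 = base.coords.size
    variances = np.asarray(variances, dtype=float)
    q = len(variances)
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    if q >= n3 - 6:
        raise ValueError("q must be below 3N - 6")
    rigid = rigid_body_basis(base.coords)
    if isinstance(directions, str) and directions == "random":
        raw = rng.standard_normal((n3, q))
        raw -= rigid @ (rigid.T @ raw)
        w, _ = np.linalg.qr(raw)
        w = w[:, :q].T
    else:
        w = np.asarray(directions, dtype=float).reshape(q, n3)
        gram = w @ w.T
        if not np.allclose(gram, np.eye(q), atol=1e-8):
            warnings.warn("directions re-orthonormalized", stacklevel=2)
            qmat, _ = np.linalg.qr(w.T)
            w = qmat[:, :q].T
    if noise_sigma >= math.sqrt(float(variances.min())):
        warnings.warn("isotropic noise is not small against the planted "
                      "variances", stacklevel=2)
    members = np.empty((M, base.n_residues, 3))
    z = rng.standard_normal((M, q)) * np.sqrt(variances)[None, :]
    eps = rng.standard_normal((M, n3)) * noise_sigma
    for m in range(M):
        flat = base.coords.reshape(-1) + z[m] @ w + eps[m]
        xyz = flat.reshape(-1, 3)
        if rigid_noise:
            angles = rng.uniform(0, 2 * math.pi, size=3)
            rot = _rotation(angles)
            shift = rng.uniform(-20.0, 20.0, size=3)
            xyz = xyz @ rot.T + shift
        members[m] = xyz
    ens = Ensemble(
        reference=base,
        members=members,
        mask=np.ones((M, base.n_residues), dtype=bool),
        labels=[f"conf{m + 1}" for m in range(M)],
    )
    truth = SyntheticTruth(
        seed=seed,
        directions=w,
        variances=variances,
        params={"M": M, "rigid_noise": rigid_noise, "noise_sigma": noise_sigma},
    )
    return ens, truth


def _rotation(angles) -> np.ndarray:
    ax, ay, az = angles
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


# ---------------------------------------------------------------------------
# protein-family simulator
# ---------------------------------------------------------------------------


def _clade_node(tree: Tree, taxa: frozenset) -> TreeNode:
    for node in tree.root.walk():
        if frozenset(leaf.label for leaf in node.leaves()) == taxa:
            return node
    raise ValueError(f"not a clade of the tree: {sorted(taxa)}")


def simulate_family(
    tree: Tree,
    L: int,
    *,
    alpha: float = 0.5,
    cluster_b: frozenset | None = None,
    theta: float = 0.0,
    shift_factor: float = 1.0,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve a protein alignment down ``tree`` with gamma site rates.

    Each site draws a rate λ ~ Gamma(alpha, mean 1).  With probability
    ``theta`` a site is rate-shifted: inside the ``cluster_b`` clade
    (stem branch included) it uses an independent draw scaled by
    ``shift_factor``.  Substitution is Poisson to a uniform alternative
    residue; the root sequence is uniform over the 20 residues.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if cluster_b is not None:
        cluster_b = frozenset(cluster_b)
        b_node = _clade_node(tree, cluster_b)
    else:
        b_node = None
        if theta > 0:
            raise ValueError("planting rate shifts requires cluster_b")
    rates = rng.gamma(alpha, 1.0 / alpha, size=L)
    shifted = rng.random(L) < theta
    rates_b = np.where(
        shifted,
        rng.gamma(alpha, 1.0 / alpha, size=L) * shift_factor,
        rates,
    )
    aa_idx = np.arange(20)
    root_seq = rng.integers(0, 20, size=L)

    in_b: set[int] = set()
    if b_node is not None:
        in_b = {id(n) for n in b_node.walk()}

    rows: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            lam = rates_b if id(child) in in_b else rates
            child_seq = seq.copy()
            if b > 0:
                n_events = rng.poisson(b * lam)
                for site in np.nonzero(n_events)[0]:
                    state = child_seq[site]
                    for _ in range(n_events[site]):
                        step = int(rng.integers(0, 19))
                        state = aa_idx[(state + 1 + step) % 20]
                    child_seq[site] = state
            if child.is_leaf:
                rows[child.label] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree.root, root_seq)
    sequences = [
        Sequence(taxon, "".join(AMINO_ACIDS[i] for i in rows[taxon]))
        for taxon in tree.leaf_names
    ]
    truth = SyntheticTruth(
        seed=seed,
        tree=tree,
        theta_planted=theta,
        shifted_sites=np.nonzero(shifted)[0],
        shift_factor=shift_factor,
        params={"L": L, "alpha": alpha},
    )
    return Alignment(sequences), truth


# ---------------------------------------------------------------------------
# codon simulator
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """GY94-like generator over the 61 sense codons, uniform frequencies,
    normalized to one expected substitution per unit branch length."""
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rate = kappa if (ci[k], cj[k]) in _TRANSITIONS else 1.0
            if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.mean(np.diag(q))
    if mean_rate > 0:
        q /= mean_rate
    return q


def simulate_codons(
    tree: Tree,
    L_codons: int,
    *,
    omega_profile=1.0,
    kappa: float = 1.0,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve an in-frame codon alignment down ``tree``.

    ``omega_profile`` is a scalar or per-site array of dN/dS values;
    branch lengths are expected codon substitutions per site.  Stop
    codons never occur.
    """
    rng = np.random.default_rng(seed)
    omega = np.broadcast_to(
        np.asarray(omega_profile, dtype=float), (L_codons,)
    ).copy()
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    uniq = np.unique(omega)
    q_by_omega = {w: _codon_rate_matrix(w, kappa) for w in uniq}
    branch_lengths = sorted(
        {node.length for node in tree.root.walk() if node.length}
    )
    p_cache = {}
    for w in uniq:
        for b in branch_lengths:
            p = np.clip(expm(q_by_omega[w] * b), 0.0, None)
            p_cache[(w, b)] = p / p.sum(axis=1, keepdims=True)
    site_class = np.searchsorted(uniq, omega)
    n_codons = len(SENSE_CODONS)
    root = rng.integers(0, n_codons, size=L_codons)
    rows: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            child_seq = seq.copy()
            if b > 0:
                for w_idx, w in enumerate(uniq):
                    sites = np.nonzero(site_class == w_idx)[0]
                    if len(sites) == 0:
                        continue
                    p = p_cache[(w, b)]
                    for site in sites:
                        child_seq[site] = rng.choice(n_codons, p=p[seq[site]])
            if child.is_leaf:
                rows[child.label] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree.root, root)
    sequences = [
        Sequence(
            taxon, "".join(SENSE_CODONS[i] for i in rows[taxon])
        )
        for taxon in tree.leaf_names
    ]
    truth = SyntheticTruth(
        seed=seed,
        tree=tree,
        omega_profile=omega,
        params={"L_codons": L_codons, "kappa": kappa},
    )
    return Alignment(sequences), truth
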