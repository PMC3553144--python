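"""Structural-ensemble PCA and overlap with ANM modes.

Heterogeneous Cα structures are matched onto a reference through global
sequence alignment, iteratively superposed (Kabsch least-squares fits
onto the running mean), and the coordinate covariance across conformers
is eigendecomposed.  Principal components are the dominant deformation
directions of the ensemble; their agreement with ANM modes is measured
as the absolute cosine between eigenvectors and as the correlation of
conformer projections on the two axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Structure
from .seq_similarity import global_align
from .io_formats import Sequence

__all__ = [
    "Ensemble",
    "PCAResult",
    "OverlapReport",
    "kabsch_superpose",
    "build_ensemble",
    "iterative_superposition",
    "ensemble_pca",
    "mode_overlap",
    "pc_cluster",
]


@dataclass
class Ensemble:
    reference: Structure
    members: np.ndarray  # M × N × 3, unobserved positions hold NaN-free imputations
    mask: np.ndarray  # M × N bool, True where the member observed the position
    labels: list[str]
    rmsd_to_mean: np.ndarray | None = None
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.members.ndim != 3 or self.members.shape[2] != 3:
            raise ValueError("members must be M×N×3")
        if self.members.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.mask.shape != self.members.shape[:2]:
            raise ValueError("mask shape disagrees with members")

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    @property
    def n_positions(self) -> int:
        return self.members.shape[1]

    def mean_coords(self) -> np.ndarray:
        return self.members.mean(axis=0)


@dataclass
class PCAResult:
    mean_coords: np.ndarray  # N × 3
    eigenvectors: np.ndarray  # 3N × K, orthonormal columns, descending λ
    eigenvalues: np.ndarray
    fractions: np.ndarray
    projections: np.ndarray  # M × K


@dataclass
class OverlapReport:
    overlap: np.ndarray  # |cos| between PC i and ANM mode j
    projection_r: np.ndarray  # Pearson r of conformer projections


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed copy of the FULL mobile coordinate set and
    the RMSD over the unmasked (shared) positions.  The rotation is
    proper (det = +1); the reflection case is handled by the usual sign
    correction of the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 shared positions to superpose")
    x = mobile[mask]
    y = target[mask]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    moved = (mobile - x.mean(axis=0)) @ rot + y.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[mask] - y) ** 2, axis=1))))
    return moved, rmsd


def _match_to_reference(structure: Structure, reference: Structure):
    """Map reference residue indices to structure indices via global
    sequence alignment.  Returns an int array of length N_ref with -1
    where the structure has no matched residue."""
    res = global_align(
        Sequence("ref", reference.sequence), Sequence("mob", structure.sequence)
    )
    mapping = np.full(reference.n_residues, -1, dtype=int)
    i_ref = i_mob = 0
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if ca != "-" and cb != "-":
            mapping[i_ref] = i_mob
        if ca != "-":
            i_ref += 1
        if cb != "-":
            i_mob += 1
    return mapping


def build_ensemble(
    structures: list[Structure],
    reference: Structure | None = None,
    *,
    min_occupancy: float = 0.9,
    min_coverage: float = 0.4,
) -> Ensemble:
    """Assemble a matched ensemble on the reference's residue set.

    Residue matching goes through global sequence alignment to the
    reference (first structure when unnamed).  Reference positions kept
    are those observed in at least ``min_occupancy`` of the admitted
    members; members matching fewer than ``min_coverage`` of the
    reference positions are excluded and logged.  Each structure in the
    input list is one conformer (multi-model files contribute one
    Structure per model upstream).
    """
    if reference is None:
        reference = structures[0]
    rows, masks, labels, excluded = [], [], [], []
    for s in structures:
        mapping = _match_to_reference(s, reference)
        matched = mapping >= 0
        coverage = matched.mean()
        if coverage < min_coverage:
            excluded.append((s.id, f"coverage {coverage:.0%} < {min_coverage:.0%}"))
            continue
        coords = np.zeros((reference.n_residues, 3))
        coords[matched] = s.coords[mapping[matched]]
        rows.append(coords)
        masks.append(matched)
        labels.append(s.id)
    if len(rows) < 2:
        raise ValueError("fewer than 2 members admitted into the ensemble")
    members = np.stack(rows)
    mask = np.stack(masks)
    occupancy = mask.mean(axis=0)
    keep = occupancy >= min_occupancy
    if not np.any(keep):
        raise ValueError("no reference position meets the occupancy threshold")
    members = members[:, keep, :]
    mask = mask[:, keep]
    ref = Structure(
        id=reference.id,
        residue_ids=[r for r, k in zip(reference.residue_ids, keep) if k],
        coords=reference.coords[keep],
        bfactors=None if reference.bfactors is None else reference.bfactors[keep],
        sequence="".join(c for c, k in zip(reference.sequence, keep) if k),
    )
    # impute unobserved positions from the observed mean of that position
    col_mean = np.zeros((mask.shape[1], 3))
    for j in range(mask.shape[1]):
        obs = mask[:, j]
        col_mean[j] = members[obs, j, :].mean(axis=0)
    for m in range(members.shape[0]):
        miss = ~mask[m]
        members[m, miss, :] = col_mean[miss]
    return Ensemble(
        reference=ref, members=members, mask=mask, labels=labels,
        excluded=excluded,
    )


def iterative_superposition(
    ens: Ensemble, *, tol: float = 1e-5, max_iter: int = 100
) -> Ensemble:
    """Superpose all members onto the running mean until it stabilizes.

    After convergence every member's unobserved positions are re-imputed
    from the mean, and per-member RMSD to the mean (over observed
    positions) is recorded.
    """
    members = ens.members.copy()
    mean = members.mean(axis=0)
    for _ in range(max_iter):
        for m in range(members.shape[0]):
            members[m], _ = kabsch_superpose(members[m], mean, ens.mask[m])
        new_mean = members.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    else:
        warnings.warn("iterative superposition did not converge", stacklevel=2)
    rmsds = np.empty(members.shape[0])
    for m in range(members.shape[0]):
        obs = ens.mask[m]
        members[m][~obs] = mean[~obs]
        rmsds[m] = np.sqrt(
            np.mean(np.sum((members[m][obs] - mean[obs]) ** 2, axis=1))
        )
    return Ensemble(
        reference=ens.reference,
        members=members,
        mask=ens.mask.copy(),
        labels=list(ens.labels),
        rmsd_to_mean=rmsds,
        excluded=list(ens.excluded),
    )


def ensemble_pca(ens: Ensemble) -> PCAResult:
    """PCA of flattened coordinate deviations (covariance divisor M−1)."""
    if ens.n_members < 3:
        raise ValueError("PCA needs at least 3 conformers")
    m = ens.n_members
    flat = ens.members.reshape(m, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / (m - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(evals.sum())
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    projections = dev @ evecs
    return PCAResult(
        mean_coords=mean.reshape(-1, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        fractions=fractions,
        projections=projections,
    )


def mode_overlap(pca: PCAResult, modes, *, ens: Ensemble | None = None,
                 n_pc: int | None = None, n_anm: int | None = None) -> OverlapReport:
    """Absolute-cosine overlap between PC and ANM eigenvectors, plus the
    correlation of conformer projections on each axis pair.

    ``modes`` is an ANM ModeSet (vibrational modes ascending, so column
    0 is the softest mode).  Projection correlations need the ensemble
    the PCA came from; without it they are NaN.
    """
    u_anm = modes.eigenvectors
    if pca.eigenvectors.shape[0] != u_anm.shape[0]:
        raise ValueError(
            "PCA and ANM vectors live on different coordinate spaces "
            f"({pca.eigenvectors.shape[0]} vs {u_anm.shape[0]})"
        )
    n_pc = n_pc or min(3, pca.eigenvectors.shape[1])
    n_anm = n_anm or min(3, u_anm.shape[1])
    v = pca.eigenvectors[:, :n_pc]
    u = u_anm[:, :n_anm]
    v = v / np.linalg.norm(v, axis=0)
    u = u / np.linalg.norm(u, axis=0)
    overlap = np.abs(v.T @ u)
    proj_r = np.full((n_pc, n_anm), np.nan)
    if ens is not None:
        flat = ens.members.reshape(ens.n_members, -1)
        dev = flat - flat.mean(axis=0)
        pc_scores = dev @ v
        anm_scores = dev @ u
        for i in range(n_pc):
            for j in range(n_anm):
                if np.ptp(pc_scores[:, i]) == 0 or np.ptp(anm_scores[:, j]) == 0:
                    continue
                r, _ = stats.pearsonr(pc_scores[:, i], anm_scores[:, j])
                proj_r[i, j] = abs(float(r))
    return OverlapReport(overlap=overlap, projection_r=proj_r)


def pc_cluster(pca: PCAResult, labels: dict[str, str] | list[str], *,
               ens: Ensemble | None = None) -> dict:
    """Per-group centroid and spread in (PC1, PC2) plus a silhouette-style
    separation score (NaN with fewer than 2 groups of size ≥ 1)."""
    if isinstance(labels, dict):
        if ens is None:
            raise ValueError("label map requires the ensemble for member ids")
        groups = [labels[l] for l in ens.labels]
    else:
        groups = list(labels)
    if len(groups) != pca.projections.shape[0]:
        raise ValueError("one label per conformer required")
    xy = pca.projections[:, :2]
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    summary = {}
    arr = np.asarray(groups)
    for name in names:
        pts = xy[arr == name]
        summary[name] = {
            "n": int(len(pts)),
            "centroid": pts.mean(axis=0),
            "spread": float(pts.std(axis=0).mean()),
        }
    if xy.std() == 0:
        score = 0.0
    else:
        from sklearn.metrics import silhouette_score

        counts = {n: (arr == n).sum() for n in names}
        if min(counts.values()) >= 1 and len(names) >= 2:
            try:
                score = float(silhouette_score(xy, arr))
            except ValueError:
                score = float("nan")
        else:
            score = float("nan")
    return {"groups": summary, "separation": score}
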