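"""Anisotropic network model (ANM) normal modes for Cα traces.

The protein is a network of Cα nodes joined by uniform harmonic springs
whenever two residues lie within a cutoff distance (default 15 Å).  The
3N×3N Hessian of the network potential has, for a connected chain,
exactly six zero eigenvalues (rigid translations and rotations); the
remaining 3N−6 eigenpairs are the vibrational modes, and per-residue
mean-square fluctuations follow from inverse-eigenvalue-weighted mode
amplitudes.  Spring constant and kT are set to 1: only relative
fluctuations and correlations are used downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Structure

__all__ = [
    "HessianModel",
    "ModeSet",
    "FluctuationProfile",
    "build_hessian",
    "anm_modes",
    "mean_square_fluctuation",
    "bfactor_compare",
]

DEFAULT_CUTOFF = 15.0
RIGID_TOL_FACTOR = 1e-8
B_FACTOR_CONST = 8.0 * math.pi**2 / 3.0


@dataclass
class HessianModel:
    coords: np.ndarray
    cutoff: float
    gamma: float
    hessian: np.ndarray
    connected: bool = True

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # non-rigid, ascending
    eigenvectors: np.ndarray  # 3N × n_modes, orthonormal columns
    rigid_eigenvalues: np.ndarray
    rigid_eigenvectors: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_residues(self) -> int:
        return self.eigenvectors.shape[0] // 3


@dataclass
class FluctuationProfile:
    msf: np.ndarray  # per-residue ⟨ΔR²⟩ in kT/gamma units
    b_theoretical: np.ndarray | None = None
    pearson_r: float | None = None
    scale: tuple[float, float] | None = None  # least-squares (a, b)


def build_hessian(
    structure: Structure | np.ndarray,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> HessianModel:
    """Assemble the ANM Hessian.

    The off-diagonal 3×3 superblock of a connected pair (i, j) is
    ``-(gamma / r_ij^2) * (r_ij ⊗ r_ij)``; pairs farther apart than the
    cutoff (strictly greater) contribute nothing; diagonal superblocks
    enforce the zero-row-sum (translation-invariance) contract.
    """
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure, float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residues")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu = np.triu_indices(n, k=1)
    if np.any(dist2[iu] == 0.0):
        raise ValueError("duplicate coordinates (zero inter-residue distance)")
    connected_pairs = (dist2 <= cutoff**2)
    np.fill_diagonal(connected_pairs, False)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        js = np.nonzero(connected_pairs[i])[0]
        for j in js:
            if j <= i:
                continue
            r = diff[j, i]  # r_j - r_i
            block = -gamma * np.outer(r, r) / dist2[i, j]
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    # connectivity of the spring network
    connected = _network_connected(connected_pairs)
    if not connected:
        warnings.warn(
            "spring network is disconnected at this cutoff; more than six "
            "zero modes expected",
            stacklevel=2,
        )
    return HessianModel(
        coords=coords, cutoff=cutoff, gamma=gamma, hessian=h, connected=connected
    )


def _network_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i] & ~seen)[0]:
            seen[j] = True
            stack.append(int(j))
    return bool(seen.all())


def anm_modes(model: HessianModel) -> ModeSet:
    """Full symmetric eigendecomposition split into rigid and vibrational
    blocks.  Eigenvalues below ``1e-8 × λ_max`` are classified rigid;
    a connected network must yield exactly six."""
    evals, evecs = np.linalg.eigh(model.hessian)
    tol = RIGID_TOL_FACTOR * float(evals[-1])
    rigid = evals < tol
    n_rigid = int(rigid.sum())
    if n_rigid > 6 and model.connected:
        raise RuntimeError(
            f"{n_rigid} near-zero modes on a connected network "
            "(internal inconsistency)"
        )
    if n_rigid < 6:
        raise RuntimeError(
            f"only {n_rigid} near-zero modes; rigid-body space incomplete"
        )
    return ModeSet(
        eigenvalues=evals[~rigid],
        eigenvectors=evecs[:, ~rigid],
        rigid_eigenvalues=evals[rigid],
        rigid_eigenvectors=evecs[:, rigid],
    )


def mean_square_fluctuation(
    modes: ModeSet, mode_subset=None
) -> FluctuationProfile:
    """Per-residue mean-square fluctuation from inverse-eigenvalue-
    weighted mode amplitudes.

    ``msf_i = Σ_k |U_k[3i:3i+3]|² / λ_k`` over the non-rigid modes (or
    the given 0-based subset of them).  With all modes this equals the
    trace of the i-th 3×3 diagonal superblock of the Hessian
    pseudo-inverse.
    """
    if mode_subset is None:
        idx = np.arange(modes.n_modes)
    else:
        idx = np.asarray(mode_subset, dtype=int)
        if np.any(idx < 0) or np.any(idx >= modes.n_modes):
            raise ValueError(
                "mode subset out of range (rigid modes are excluded from "
                "the ModeSet and cannot be selected)"
            )
    u = modes.eigenvectors[:, idx]
    lam = modes.eigenvalues[idx]
    weighted = (u**2) / lam[None, :]
    per_coord = weighted.sum(axis=1)
    msf = per_coord.reshape(-1, 3).sum(axis=1)
    return FluctuationProfile(msf=msf)


def bfactor_compare(
    profile: FluctuationProfile, structure: Structure
) -> FluctuationProfile:
    """Scale theoretical fluctuations onto experimental B-factors.

    ``b_theoretical = a * (8π²/3) * msf + b`` with (a, b) by least
    squares; the Pearson correlation with the experimental column is
    recorded (NaN when that column is constant).
    """
    if structure.bfactors is None:
        raise ValueError("structure carries no experimental B-factors")
    b_exp = structure.bfactors
    if len(b_exp) != len(profile.msf):
        raise ValueError("profile and structure disagree in residue count")
    x = B_FACTOR_CONST * profile.msf
    if np.ptp(b_exp) == 0.0 or np.ptp(x) == 0.0:
        return FluctuationProfile(
            msf=profile.msf,
            b_theoretical=x,
            pearson_r=float("nan"),
            scale=None,
        )
    a, b = np.polyfit(x, b_exp, 1)
    r, _ = stats.pearsonr(x, b_exp)
    return FluctuationProfile(
        msf=profile.msf,
        b_theoretical=a * x + b,
        pearson_r=float(r),
        scale=(float(a), float(b)),
    )
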