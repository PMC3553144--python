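"""Pairwise sequence comparison, homolog filtering and PEST-motif scanning.

The global aligner is Needleman–Wunsch with affine gaps in the EMBOSS
needle convention (BLOSUM62, gap open 10.0, gap extend 0.5), provided by
Bio.Align.PairwiseAligner.  Identity and similarity percentages use the
full alignment length (gap columns included) as denominator; a column is
"similar" when it is identical or its substitution score is positive.
``X`` scores 0 against everything and never counts as identical.

PEST regions are candidate degradation signals: stretches of at least 12
residues between positive flanks (K/R/H or the termini) that contain at
least one D/E, one P and one S/T and no internal positive residue.  Each
candidate is scored with the Rogers–Wells–Rechsteiner mass-percent /
hydropathy combination used by ePESTfind; scores of +5 or more flag a
"valid" PEST region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import Sequence

__all__ = [
    "AlignmentResult",
    "GroupRangeMatrix",
    "PestRegion",
    "global_align",
    "group_range_matrix",
    "filter_homologs",
    "find_pest",
]

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass
class AlignmentResult:
    score: float
    identity_pct: float
    similarity_pct: float
    aligned_a: str
    aligned_b: str

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass
class GroupRangeMatrix:
    groups: list[str]
    min_pct: np.ndarray  # NaN where undefined (singleton intra range)
    max_pct: np.ndarray
    n_sequences: dict[str, int] = field(default_factory=dict)

    def to_table(self):
        import pandas as pd

        labels = [
            f"{g} ({self.n_sequences.get(g, '?')})" for g in self.groups
        ]
        cells = []
        for i in range(len(self.groups)):
            row = []
            for j in range(len(self.groups)):
                lo, hi = self.min_pct[i, j], self.max_pct[i, j]
                row.append("NA" if np.isnan(lo) else f"{lo:g}–{hi:g}")
            cells.append(row)
        return pd.DataFrame(cells, index=labels, columns=self.groups)


@dataclass
class PestRegion:
    start: int  # 1-based inclusive
    end: int
    score: float
    valid: bool
    segment: str = ""


def _load_matrix(name_or_matrix="BLOSUM62", *, x_neutral: bool = True):
    if not isinstance(name_or_matrix, str):
        return name_or_matrix
    mat = substitution_matrices.load(name_or_matrix)
    if x_neutral and "X" in mat.alphabet:
        mat = mat.copy()
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    return mat


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # EMBOSS convention: a gap of length k costs open + (k-1)*extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: Sequence,
    b: Sequence,
    *,
    matrix="BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch) alignment of two ungapped sequences."""
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    if "-" in a.residues or "-" in b.residues:
        raise ValueError("global_align expects ungapped sequences")
    mat = _load_matrix(matrix)
    aligner = _make_aligner(mat, gap_open, gap_extend)
    alignment = aligner.align(a.residues, b.residues)[0]
    rows = str(alignment).rstrip("\n").split("\n")
    aligned_a, aligned_b = _gapped_strings(alignment)
    identical = similar = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb and ca != "X":
            identical += 1
            similar += 1
        elif _pair_score(mat, ca, cb) > 0:
            similar += 1
    length = len(aligned_a)
    return AlignmentResult(
        score=alignment.score,
        identity_pct=100.0 * identical / length,
        similarity_pct=100.0 * similar / length,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )


def _gapped_strings(alignment) -> tuple[str, str]:
    a = alignment[0]
    b = alignment[1]
    return str(a), str(b)


def _pair_score(mat, ca: str, cb: str) -> float:
    try:
        return float(mat[ca, cb])
    except (KeyError, IndexError):
        return 0.0


def group_range_matrix(
    groups: dict[str, list[Sequence]],
    *,
    metric: str = "similarity",
    **align_kwargs,
) -> GroupRangeMatrix:
    """Min/max pairwise percentage between and within sequence groups.

    Off-diagonal cells range over all cross-group pairs; diagonal cells
    range over unordered distinct pairs within the group (``NaN`` for a
    singleton group).
    """
    if metric not in ("identity", "similarity"):
        raise ValueError("metric must be 'identity' or 'similarity'")
    labels = list(groups)
    for g in labels:
        if not groups[g]:
            raise ValueError(f"group {g!r} is empty")
    k = len(labels)
    mn = np.full((k, k), np.nan)
    mx = np.full((k, k), np.nan)

    def pct(a, b):
        res = global_align(a, b, **align_kwargs)
        return res.identity_pct if metric == "identity" else res.similarity_pct

    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels[i:], start=i):
            vals = []
            if i == j:
                seqs = groups[gi]
                for u in range(len(seqs)):
                    for v in range(u + 1, len(seqs)):
                        vals.append(pct(seqs[u], seqs[v]))
            else:
                for a in groups[gi]:
                    for b in groups[gj]:
                        vals.append(pct(a, b))
            if vals:
                mn[i, j] = mn[j, i] = min(vals)
                mx[i, j] = mx[j, i] = max(vals)
    return GroupRangeMatrix(
        groups=labels,
        min_pct=mn,
        max_pct=mx,
        n_sequences={g: len(groups[g]) for g in labels},
    )


def filter_homologs(
    hits: list[Sequence],
    query: Sequence,
    *,
    identity_min: float = 35.0,
    length_window: tuple[int, int],
    **align_kwargs,
) -> tuple[list[Sequence], list[tuple[str, str]]]:
    """Keep hits strictly inside the length window with identity to the
    query strictly above ``identity_min`` percent.

    Both bounds of the window are exclusive.  Returns ``(kept, log)``
    where the log records ``(hit id, rejection reason)`` for every
    discarded hit.
    """
    lo, hi = length_window
    if not (0 < lo < hi):
        raise ValueError("length window must satisfy 0 < min < max")
    kept, log = [], []
    for hit in hits:
        n = len(hit.ungapped)
        if not (lo < n < hi):
            log.append((hit.id, f"length {n} outside ({lo},{hi})"))
            continue
        ident = global_align(hit, query, **align_kwargs).identity_pct
        if ident <= identity_min:
            log.append((hit.id, f"identity {ident:.1f}% <= {identity_min:g}%"))
            continue
        kept.append(hit)
    return kept, log


# ---------------------------------------------------------------------------
# PEST-motif detection
# ---------------------------------------------------------------------------

# Monoisotopic-free average residue masses (Da), water excluded.
_RESIDUE_MASS = {
    "A": 71.079, "R": 156.188, "N": 114.104, "D": 115.089, "C": 103.145,
    "E": 129.116, "Q": 128.131, "G": 57.052, "H": 137.141, "I": 113.160,
    "L": 113.160, "K": 128.174, "M": 131.199, "F": 147.177, "P": 97.117,
    "S": 87.078, "T": 101.105, "W": 186.213, "Y": 163.176, "V": 99.133,
    "X": 110.0,
}

# Kyte–Doolittle hydropathy, rescaled to 0–90 as in the original
# PEST-FIND formulation: hp = 10*KD + 45.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5,
    "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

POSITIVE = set("KRH")
MIN_PEST_LENGTH = 12


def pest_score(segment: str) -> float:
    """Rogers–Wells–Rechsteiner score of one candidate segment.

    ``score = 0.55 * DEPST_mass_pct - 0.5 * hydrophobicity_index`` where
    DEPST_mass_pct is the mass percent of D/E/P/S/T after subtracting one
    equivalent each of (D or E), P and (S or T) — the heaviest present —
    and the hydrophobicity index is the mole-fraction-weighted rescaled
    Kyte–Doolittle hydropathy.
    """
    seg = segment.upper()
    total_mass = sum(_RESIDUE_MASS.get(c, _RESIDUE_MASS["X"]) for c in seg)
    depst_mass = sum(
        _RESIDUE_MASS[c] for c in seg if c in "DEPST"
    )
    for group in ("ED", "P", "TS"):
        present = [c for c in group if c in seg]
        if present:
            depst_mass -= max(_RESIDUE_MASS[c] for c in present)
    depst_pct = 100.0 * max(depst_mass, 0.0) / total_mass
    hydro = sum(10.0 * _KD.get(c, 0.0) + 45.0 for c in seg) / len(seg)
    return 0.55 * depst_pct - 0.5 * hydro


def find_pest(seq: Sequence, *, threshold: float = 5.0) -> list[PestRegion]:
    """Scan for PEST candidates and score each one.

    Candidates are the maximal stretches between positive residues
    (K/R/H) or the sequence termini, of length >= 12, containing at
    least one D/E, one P and one S/T.  ``valid`` flags score >=
    ``threshold``.
    """
    residues = seq.residues
    if "-" in residues:
        raise ValueError("find_pest expects an ungapped sequence")
    regions = []
    start = 0
    n = len(residues)
    for i in range(n + 1):
        at_flank = i == n or residues[i] in POSITIVE
        if not at_flank:
            continue
        segment = residues[start:i]
        if len(segment) >= MIN_PEST_LENGTH:
            has_de = any(c in "DE" for c in segment)
            has_p = "P" in segment
            has_st = any(c in "ST" for c in segment)
            if has_de and has_p and has_st:
                score = pest_score(segment)
                regions.append(
                    PestRegion(
                        start=start + 1,
                        end=i,
                        score=score,
                        valid=score >= threshold,
                        segment=segment,
                    )
                )
        start = i + 1
    return regions
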