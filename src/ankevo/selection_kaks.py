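"""Site-wise and pairwise Ka/Ks by Nei–Gojobori (1986) counting.

Synonymous and nonsynonymous site counts use codon-degeneracy fractions
(changes producing stop codons count as nonsynonymous); differences for
codons differing at more than one position are averaged over all minimal
mutational pathways, excluding pathways that pass through stop codons.
Both proportions receive the Jukes–Cantor correction
``d = -(3/4) * ln(1 - (4/3) p)``.  omega = Ka/Ks; it is NA when Ks is 0.

This counting stage is a documented stand-in for random-effects codon
maximum likelihood (M8-type site models are a non-goal here): the
qualitative regime call — purifying vs neutral vs positive — is what the
pipeline consumes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import Alignment, Sequence

__all__ = [
    "KaKsResult",
    "GENETIC_CODE",
    "STOP_CODONS",
    "ng86_pairwise",
    "sitewise_kaks",
    "codon_sites",
    "codon_path_differences",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


@dataclass
class KaKsResult:
    ka: float  # NaN for NA
    ks: float
    omega: float  # NaN when Ks == 0 or saturated
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    per_codon: list[str] | None = None  # purifying/neutral/positive/NA
    per_codon_omega: np.ndarray | None = None

    @property
    def is_na(self) -> bool:
        return math.isnan(self.omega)


def _is_codon(c: str) -> bool:
    return len(c) == 3 and all(b in "ACGT" for b in c)


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts of one codon.

    Each of the three positions contributes the fraction of its three
    possible single-nucleotide changes that are synonymous; changes to
    stop codons count as nonsynonymous.  The two fractions sum to 3.
    """
    if codon in STOP_CODONS or not _is_codon(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used (the standard fallback for this rare
    case).
    """
    for c in (c1, c2):
        if c in STOP_CODONS or not _is_codon(c):
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(exclude_stops: bool):
        totals = []
        for order in itertools.permutations(diff_pos):
            syn = nonsyn = 0.0
            cur = c1
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if exclude_stops and nxt in STOP_CODONS:
                    ok = False
                    break
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            if ok:
                totals.append((syn, nonsyn))
        return totals

    totals = walk(exclude_stops=True)
    if not totals:
        totals = walk(exclude_stops=False)
    syn = sum(t[0] for t in totals) / len(totals)
    nonsyn = sum(t[1] for t in totals) / len(totals)
    return syn, nonsyn


def _jc_correct(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")  # saturated
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _codon_pair_ok(ca: str, cb: str) -> bool:
    return _is_codon(ca) and _is_codon(cb) and ca not in STOP_CODONS and cb not in STOP_CODONS


def ng86_pairwise(a: Sequence, b: Sequence) -> KaKsResult:
    """Nei–Gojobori Ka/Ks between two equal-length in-frame sequences.

    Codons containing gaps or ambiguity codes in either sequence are
    skipped for that pair; internal stop codons raise.
    """
    codons_a, codons_b = a.codons(), b.codons()
    if len(codons_a) != len(codons_b):
        raise ValueError(
            f"length mismatch: {len(codons_a)} vs {len(codons_b)} codons"
        )
    for name, codons in ((a.id, codons_a), (b.id, codons_b)):
        for i, c in enumerate(codons[:-1]):
            if c in STOP_CODONS:
                raise ValueError(f"{name!r}: internal stop codon at codon {i + 1}")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if not _codon_pair_ok(ca, cb):
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = codon_path_differences(ca, cb)
        Sd += sd
        Nd += nd
    return _result_from_totals(S, N, Sd, Nd)


def _result_from_totals(S, N, Sd, Nd, **extra) -> KaKsResult:
    ps = Sd / S if S > 0 else float("nan")
    pn = Nd / N if N > 0 else float("nan")
    ks = _jc_correct(ps) if not math.isnan(ps) else float("nan")
    ka = _jc_correct(pn) if not math.isnan(pn) else float("nan")
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        omega = float("nan")
    else:
        omega = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, omega=omega,
        syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd,
        **extra,
    )


def classify_omega(omega: float, *, band: float = 0.1) -> str:
    if math.isnan(omega):
        return "NA"
    if abs(omega - 1.0) <= band:
        return "neutral"
    return "positive" if omega > 1.0 else "purifying"


def sitewise_kaks(
    msa: Alignment, query: str, *, band: float = 0.1
) -> KaKsResult:
    """Per-codon-site Ka/Ks of ``query`` against every other row, pooled.

    For each codon column the pathway-averaged synonymous and
    nonsynonymous differences and sites between the query and every
    other row are pooled; each site is classed purifying / neutral /
    positive from its omega (NA when the column is uninformative).  The
    returned totals give the overall omega across all sites and pairs.
    """
    qrow = msa.row(query)
    others = [s for s in msa.sequences if s.id != query]
    q_codons = qrow.codons()
    n_codons = len(q_codons)
    other_codons = [s.codons() for s in others]
    S_tot = N_tot = Sd_tot = Nd_tot = 0.0
    classes: list[str] = []
    omegas = np.full(n_codons, np.nan)
    for c in range(n_codons):
        qc = q_codons[c]
        S = N = Sd = Nd = 0.0
        informative = False
        for oc in other_codons:
            cb = oc[c]
            if not _codon_pair_ok(qc, cb):
                continue
            informative = True
            sa, na = codon_sites(qc)
            sb, nb = codon_sites(cb)
            S += 0.5 * (sa + sb)
            N += 0.5 * (na + nb)
            sd, nd = codon_path_differences(qc, cb)
            Sd += sd
            Nd += nd
        if not informative:
            classes.append("NA")
            continue
        S_tot += S
        N_tot += N
        Sd_tot += Sd
        Nd_tot += Nd
        if Sd == 0.0 and Nd == 0.0:
            classes.append("NA")  # no substitutions at this site
            continue
        ps = Sd / S if S > 0 else float("nan")
        pn = Nd / N if N > 0 else float("nan")
        ks = _jc_correct(ps) if not math.isnan(ps) else float("nan")
        ka = _jc_correct(pn) if not math.isnan(pn) else float("nan")
        if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
            classes.append("NA")
            continue
        omegas[c] = ka / ks
        classes.append(classify_omega(omegas[c], band=band))
    result = _result_from_totals(
        S_tot, N_tot, Sd_tot, Nd_tot,
        per_codon=classes, per_codon_omega=omegas,
    )
    return result
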