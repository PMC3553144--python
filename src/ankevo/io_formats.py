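"""Readers and writers for the standard formats the pipeline consumes.

Sequences and alignments travel as FASTA, coarse-grained structures as
PDB (Cα atoms only, one :class:`Structure` per MODEL), trees as Newick
and tabular reports as TSV.  Parsing of FASTA and PDB is delegated to
Biopython; this module adds the validation contracts the downstream
stages rely on (alphabet checks, codon-frame checks, altloc and
duplicate-residue rules).

Internally every index is 0-based with half-open ranges; user-facing
reports are 1-based.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Sequence",
    "Alignment",
    "Structure",
    "FastaParseError",
    "SequenceValidationError",
    "PdbParseError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_pdb_calpha",
    "write_pdb_calpha",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: letters legal in a protein record: the 20 standard residues, X, and gap.
PROTEIN_ALPHABET = AMINO_ACIDS | {"X", "-"}
NUCLEOTIDES = set("ACGT")
NUCLEOTIDE_ALPHABET = NUCLEOTIDES | {"N", "-"}


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """A record violates the sequence alphabet or frame contract."""


class PdbParseError(ValueError):
    """A PDB file has no usable Cα trace or violates the residue contract."""


@dataclass
class Sequence:
    """A named residue string.

    ``residues`` holds upper-case amino acids (20 standard letters plus
    ``X`` and, inside alignments only, ``-``) or, for codon inputs, an
    in-frame nucleotide string whose length is divisible by three.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def codons(self) -> list[str]:
        r = self.residues
        if len(r) % 3:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(r)} is not divisible by 3"
            )
        return [r[i : i + 3] for i in range(0, len(r), 3)]


@dataclass
class Alignment:
    """A column-indexed set of equal-length gapped sequences."""

    sequences: list[Sequence]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon labels in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def taxa(self) -> list[str]:
        return [s.id for s in self.sequences]

    def row(self, taxon: str) -> Sequence:
        for s in self.sequences:
            if s.id == taxon:
                return s
        raise KeyError(taxon)

    def to_array(self) -> np.ndarray:
        """Rows × columns character matrix (dtype '<U1')."""
        return np.array([list(s.residues) for s in self.sequences])

    def subset(self, taxa) -> "Alignment":
        order = {t: i for i, t in enumerate(self.taxa)}
        return Alignment([self.sequences[order[t]] for t in taxa])

    def resample_columns(self, columns) -> "Alignment":
        cols = np.asarray(columns, dtype=int)
        mat = self.to_array()[:, cols]
        return Alignment(
            [
                Sequence(s.id, "".join(row), s.description)
                for s, row in zip(self.sequences, mat)
            ]
        )


@dataclass
class Structure:
    """A Cα trace: ordered residues, coordinates and optional B-factors."""

    id: str
    residue_ids: list[tuple[str, int]]
    coords: np.ndarray
    bfactors: np.ndarray | None = None
    sequence: str = ""
    skipped_residues: int = 0  # residues dropped for missing CA (parse report)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N×3")
        n = self.coords.shape[0]
        if len(self.residue_ids) != n:
            raise ValueError("residue_ids and coords disagree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (n,):
                raise ValueError("bfactors must have one entry per residue")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


def _validate_residues(seq: Sequence, *, codon_mode: bool, allow_gaps: bool) -> None:
    alphabet = NUCLEOTIDE_ALPHABET if codon_mode else PROTEIN_ALPHABET
    if not allow_gaps:
        alphabet = alphabet - {"-"}
    for pos, ch in enumerate(seq.residues):
        if ch not in alphabet:
            raise SequenceValidationError(
                f"record {seq.id!r}: illegal character {ch!r} at position {pos + 1}"
            )


def read_fasta(
    path, *, codon_mode: bool = False, allow_gaps: bool = False
) -> list[Sequence]:
    """Read FASTA records, preserving order.

    With ``codon_mode`` the records are nucleotide coding sequences and
    any record whose (ungapped) length is not divisible by 3 is rejected.
    """
    records = []
    with open(path) as handle:
        text = handle.read()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: does not start with a FASTA header")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = Sequence(
            id=rec.id, residues=str(rec.seq), description=rec.description
        )
        if not seq.residues:
            raise FastaParseError(f"record {rec.id!r}: empty sequence")
        _validate_residues(seq, codon_mode=codon_mode, allow_gaps=allow_gaps)
        if codon_mode and len(seq.ungapped) % 3:
            raise SequenceValidationError(
                f"record {seq.id!r}: length {len(seq.ungapped)} "
                "is not divisible by 3"
            )
        records.append(seq)
    if not records and text.strip():
        raise FastaParseError(f"{path}: no parseable FASTA records")
    return records


def write_fasta(sequences, path, width: int = 60) -> None:
    with open(path, "w") as out:
        for s in sequences:
            header = s.id if not s.description or s.description == s.id else s.description
            out.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i : i + width] + "\n")


def read_alignment(path, *, codon_mode: bool = False) -> Alignment:
    """Read a FASTA alignment (gaps allowed, equal row lengths enforced)."""
    return Alignment(read_fasta(path, codon_mode=codon_mode, allow_gaps=True))


def _one_letter(resname: str) -> str:
    return protein_letters_3to1.get(resname.strip().upper(), "X")


def read_pdb_calpha(path, *, chains=None) -> list[Structure]:
    """Read the Cα trace of every MODEL in a PDB file.

    Only ATOM records named ``CA`` with blank or ``'A'`` altloc are kept.
    All chains are concatenated in file order unless ``chains`` names a
    subset.  Residues without a CA are skipped silently but counted in
    the structure's parse report.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        pdb = parser.get_structure("pdb", str(path))
    structures = []
    from pathlib import Path as _Path

    stem = _Path(path).stem
    for model in pdb:
        residue_ids: list[tuple[str, int]] = []
        coords, bfactors, letters = [], [], []
        seen = set()
        skipped = 0
        for chain in model:
            if chains is not None and chain.id not in chains:
                continue
            for residue in chain:
                hetflag, resseq, _icode = residue.id
                if hetflag.strip():
                    continue
                ca = None
                for atom in residue:
                    if atom.get_name() != "CA":
                        continue
                    altloc = atom.get_altloc()
                    if altloc in (" ", "A", ""):
                        ca = atom
                        break
                if ca is None:
                    skipped += 1
                    continue
                key = (chain.id, resseq)
                if key in seen:
                    raise PdbParseError(
                        f"{stem}: duplicate CA for residue {key} "
                        f"in model {model.id}"
                    )
                seen.add(key)
                residue_ids.append(key)
                coords.append(ca.get_coord())
                bfactors.append(ca.get_bfactor())
                letters.append(_one_letter(residue.get_resname()))
        if not residue_ids:
            raise PdbParseError(f"{stem}: model {model.id} has no CA atoms")
        structures.append(
            Structure(
                id=f"{stem}#model{model.id + 1}" if len(pdb) > 1 else stem,
                residue_ids=residue_ids,
                coords=np.array(coords, dtype=float),
                bfactors=np.array(bfactors, dtype=float),
                sequence="".join(letters),
                skipped_residues=skipped,
            )
        )
    if not structures:
        raise PdbParseError(f"{stem}: no models with CA atoms")
    return structures


def write_pdb_calpha(structures, path) -> None:
    """Write one or more Cα-only models as a (multi-MODEL) PDB file."""
    structures = list(structures)
    multi = len(structures) > 1
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    with open(path, "w") as out:
        for m, s in enumerate(structures, start=1):
            if multi:
                out.write(f"MODEL     {m:4d}\n")
            serial = 1
            for i, (chain, resseq) in enumerate(s.residue_ids):
                aa = s.sequence[i] if i < len(s.sequence) else "X"
                resname = one_to_three.get(aa, "UNK")
                x, y, z = s.coords[i]
                b = float(s.bfactors[i]) if s.bfactors is not None else 0.0
                out.write(
                    f"ATOM  {serial:5d}  CA  {resname:>3s} {chain[:1]:1s}"
                    f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
                    f"{b:6.2f}           C\n"
                )
                serial += 1
            if multi:
                out.write("ENDMDL\n")
        out.write("END\n")
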