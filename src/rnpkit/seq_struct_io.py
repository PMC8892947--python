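"""Sequence and structure IO shared by all pipeline stages.

Readers/writers for FASTA/FASTQ and multi-model PDB (optionally DCD), the
standard genetic code with IUPAC-ambiguity-aware translation, and the
:class:`Ensemble` container that the interface-analysis operations consume.

Conventions: residue and sequence numbering are 1-based (PDB convention);
frame indices are 0-based. Chains are kept distinct, never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "NucleotideSequence",
    "PeptideSequence",
    "Ensemble",
    "SSElementSet",
    "read_sequences",
    "write_sequences",
    "translate",
    "read_ensemble",
    "write_ensemble",
    "classify_residue",
    "IUPAC_DNA",
    "AMINO_ACIDS",
]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


#: The 15 IUPAC DNA codes (no gap), mapped to the plain bases they stand for.
IUPAC_DNA: dict[str, str] = {
    k: v for k, v in IUPACData.ambiguous_dna_values.items() if k != "X"
}

#: The 20 canonical amino acids, one-letter.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence in IUPAC alphabet with optional per-base qualities."""

    identifier: str
    residues: str
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.identifier!r}: empty sequence")
        for i, c in enumerate(self.residues):
            if c.upper() not in IUPAC_DNA:
                raise ValueError(
                    f"{self.identifier!r}: invalid nucleotide {c!r} at position {i + 1}"
                )
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise ValueError(
                f"{self.identifier!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PeptideSequence:
    """A protein sequence over the 20 one-letter codes, '*' stop and 'X'."""

    identifier: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.identifier!r}: empty sequence")
        allowed = set(AMINO_ACIDS + "*X")
        for i, c in enumerate(self.residues):
            if c.upper() not in allowed:
                raise ValueError(
                    f"{self.identifier!r}: invalid residue {c!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_RNA_RESNAMES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}
_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SPC"}
_ION_RESNAMES = {"MG", "K", "NA", "CL", "CA", "ZN", "MN"}

_WARNED_RESNAMES: set[str] = set()


def classify_residue(res_name: str) -> str:
    """Assign a polymer class to a residue name.

    Total function: standard amino acids -> ``protein``, ribonucleotides ->
    ``rna``, HOH/WAT -> ``water``, common monatomic ions -> ``ion``,
    anything else -> ``other`` (with a one-time warning per name).
    """
    name = res_name.strip().upper()
    if name in _PROTEIN_RESNAMES:
        return "protein"
    if name in _RNA_RESNAMES:
        return "rna"
    if name in _WATER_RESNAMES:
        return "water"
    if name in _ION_RESNAMES:
        return "ion"
    if name not in _WARNED_RESNAMES:
        _WARNED_RESNAMES.add(name)
        warnings.warn(f"unknown residue name {res_name!r}: classified 'other'")
    return "other"


@dataclass
class Ensemble:
    """Atoms plus one or more coordinate frames of a (macro)molecular system.

    Atom metadata is stored in parallel numpy arrays; ``coords`` has shape
    ``(n_frames, n_atoms, 3)`` in Angstrom. Residue numbering is preserved
    verbatim from the source file.
    """

    atom_names: np.ndarray      # (n_atoms,) str
    elements: np.ndarray        # (n_atoms,) str
    res_names: np.ndarray       # (n_atoms,) str
    res_ids: np.ndarray         # (n_atoms,) int, 1-based as in source
    chain_ids: np.ndarray       # (n_atoms,) str
    polymer_class: np.ndarray   # (n_atoms,) str in {protein,rna,water,ion,other}
    coords: np.ndarray          # (n_frames, n_atoms, 3) float, Angstrom
    frame_spacing: Optional[float] = None  # time per frame, ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an Ensemble needs at least one frame")
        n = len(self.atom_names)
        for arr_name in ("elements", "res_names", "res_ids", "chain_ids",
                         "polymer_class"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != number of atoms")
        if self.coords.shape[1] != n:
            raise ValueError("coordinate frames do not match the atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, **criteria) -> np.ndarray:
        """Boolean atom mask; keyword values may be scalars or collections.

        Example: ``ens.select(polymer_class="rna", atom_names=("OP1", "OP2"))``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        for key, value in criteria.items():
            arr = getattr(self, key)
            if isinstance(value, (str, int, np.integer)):
                mask &= arr == value
            else:
                mask &= np.isin(arr, list(value))
        return mask


@dataclass(frozen=True)
class SSElementSet:
    """Secondary-structure elements as (label, chain, first..last residue)."""

    elements: tuple[tuple[str, str, int, int], ...]

    def __post_init__(self):
        for label, _chain, first, last in self.elements:
            if label not in ("helix", "sheet"):
                raise ValueError(f"unknown SS label {label!r}")
            if last < first:
                raise ValueError(f"empty range {first}..{last}")

    def residue_mask(self, ens: Ensemble) -> np.ndarray:
        """Atom mask for residues covered by any element (must all exist)."""
        mask = np.zeros(ens.n_atoms, dtype=bool)
        for _label, chain, first, last in self.elements:
            m = (ens.chain_ids == chain) & (ens.res_ids >= first) & (ens.res_ids <= last)
            if not m.any():
                raise ValueError(
                    f"SS element {chain}:{first}-{last} matches no ensemble residues"
                )
            mask |= m
        return mask


# ---------------------------------------------------------------------------
# Sequence IO
# ---------------------------------------------------------------------------


def read_sequences(path: str | Path, format: str = "fasta") -> list[NucleotideSequence]:
    """Read a FASTA or FASTQ file into :class:`NucleotideSequence` records.

    Order is preserved; FASTQ Phred qualities are retained. An empty file
    yields an empty list with a warning. Malformed records raise
    :class:`ParseError` naming the (approximate) line.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    out: list[NucleotideSequence] = []
    lines_per_record = 4 if fmt == "fastq" else 2
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            quality = None
            if fmt == "fastq":
                quality = tuple(rec.letter_annotations["phred_quality"])
            out.append(
                NucleotideSequence(rec.id, str(rec.seq).upper(), quality)
            )
    except ValueError as exc:
        line = len(out) * lines_per_record + 1
        raise ParseError(
            f"{path}: malformed {fmt} record near line {line}: {exc}"
        ) from exc
    if not out:
        warnings.warn(f"{path}: no records found")
    return out


def write_sequences(
    seqs: Sequence[NucleotideSequence], path: str | Path, format: str = "fasta"
) -> None:
    """Write records as FASTA or FASTQ (FASTQ requires or fabricates Q40)."""
    fmt = format.lower()
    records = []
    for s in seqs:
        rec = SeqRecord(Seq(s.residues), id=s.identifier, description="")
        if fmt == "fastq":
            qual = s.quality if s.quality is not None else (40,) * len(s)
            rec.letter_annotations["phred_quality"] = list(qual)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _codon_translations(codon: str) -> frozenset[str]:
    """All residues (one-letter, '*' for stop) a possibly-ambiguous codon encodes."""
    out = set()
    for bases in product(*(IUPAC_DNA[c] for c in codon)):
        plain = "".join(bases)
        if plain in _STANDARD_TABLE.stop_codons:
            out.add("*")
        else:
            out.add(_STANDARD_TABLE.forward_table[plain])
    return frozenset(out)


def translate(seq: NucleotideSequence | str, frame_offset: int = 0) -> PeptideSequence:
    """Translate DNA with the standard genetic code in the given frame.

    Trailing partial codons are dropped, stops render as ``*``. An IUPAC
    ambiguity code translates normally when every expansion encodes the same
    residue (e.g. ``GGN`` -> G) and as ``X`` otherwise — ambiguity is never
    silently resolved to an arbitrary residue.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq)
    residues = seq.residues.upper()
    if len(residues) < frame_offset + 3:
        raise ValueError(
            f"{seq.identifier!r}: too short ({len(residues)} nt) for frame "
            f"{frame_offset}"
        )
    peptide = []
    for start in range(frame_offset, len(residues) - 2, 3):
        codon = residues[start : start + 3]
        options = _codon_translations(codon)
        peptide.append(next(iter(options)) if len(options) == 1 else "X")
    return PeptideSequence(seq.identifier, "".join(peptide))


# ---------------------------------------------------------------------------
# Structure IO
# ---------------------------------------------------------------------------


def _stack_to_ensemble(stack, frame_spacing: Optional[float]) -> Ensemble:
    import biotite.structure as struc

    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[np.newaxis]
    res_names = np.asarray(stack.res_name, dtype="U5")
    elements = np.asarray(stack.element, dtype="U2")
    # Fall back to first letter of the atom name when the element column is blank
    blank = elements == ""
    if blank.any():
        names = np.asarray(stack.atom_name)
        elements = elements.copy()
        elements[blank] = [n.strip()[0] for n in names[blank]]
    polymer = np.array([classify_residue(r) for r in res_names], dtype="U7")
    return Ensemble(
        atom_names=np.asarray(stack.atom_name, dtype="U6"),
        elements=elements,
        res_names=res_names,
        res_ids=np.asarray(stack.res_id, dtype=int),
        chain_ids=np.asarray(stack.chain_id, dtype="U4"),
        polymer_class=polymer,
        coords=coords,
        frame_spacing=frame_spacing,
    )


def read_ensemble(
    path: str | Path,
    format: str = "pdb",
    topology: str | Path | None = None,
    frame_spacing: Optional[float] = None,
) -> Ensemble:
    """Read a conformational ensemble.

    ``format="pdb"`` reads a (multi-model) PDB file — the canonical,
    self-contained text format here. ``format="dcd"`` reads a DCD trajectory
    through mdtraj and requires ``topology`` (a PDB) for atom metadata.
    Models with mismatched atom counts raise an error (via the underlying
    reader); unknown residue names are classified ``other`` with a warning.
    """
    fmt = format.lower()
    path = Path(path)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
        return _stack_to_ensemble(stack, frame_spacing)
    if fmt == "dcd":
        if topology is None:
            raise ValueError("DCD input requires a PDB topology file")
        import mdtraj

        traj = mdtraj.load_dcd(str(path), top=str(topology))
        topo_ens = read_ensemble(topology, "pdb", frame_spacing=frame_spacing)
        coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Angstrom
        if coords.shape[1] != topo_ens.n_atoms:
            raise ValueError(
                f"atom count mismatch: DCD has {coords.shape[1]}, "
                f"topology has {topo_ens.n_atoms}"
            )
        topo_ens.coords = coords
        return topo_ens
    raise ValueError(f"unsupported ensemble format {format!r}")


def write_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    stack = struc.AtomArrayStack(ens.n_frames, ens.n_atoms)
    stack.atom_name = ens.atom_names.astype("U6")
    stack.element = ens.elements.astype("U2")
    stack.res_name = ens.res_names.astype("U5")
    stack.res_id = ens.res_ids.astype(int)
    stack.chain_id = ens.chain_ids.astype("U4")
    stack.hetero = ~np.isin(ens.polymer_class, ["protein", "rna"])
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
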