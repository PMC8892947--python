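"""Reduced-alphabet combinatorial library design.

Builds per-position amino-acid substitution pools from a family alignment,
encodes each pool as an optimal degenerate codon by exhaustive search over
all 15^3 = 3,375 IUPAC codons, and accounts for library diversity exactly.

The codon objective is lexicographic: fewest off-target amino-acid species,
then fewest stop codons in the expansion, then smallest degeneracy, then the
alphabetically first IUPAC string — a defined-alphabet-first priority that
keeps reduced-alphabet libraries clean and makes the output deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from rnpkit.seq_struct_io import (
    AMINO_ACIDS,
    IUPAC_DNA,
    PeptideSequence,
    _codon_translations,
)

__all__ = [
    "PositionPool",
    "DegenerateCodon",
    "LibraryScheme",
    "pools_from_alignment",
    "design_codon",
    "codon_profile",
    "diversity",
    "CodonDesignError",
    "load_substitution_table",
    "EARLY_ALPHABET",
    "MID_ALPHABET",
]

#: The 10 prebiotically plausible "early" amino acids.
EARLY_ALPHABET = frozenset("GADVESILPT")
#: The 14-residue "mid-stage" alphabet (early + Lys, Phe, Arg, His).
MID_ALPHABET = EARLY_ALPHABET | frozenset("KFRH")

_IUPAC_SYMBOLS = sorted(IUPAC_DNA)  # 15 symbols, alphabetical


class CodonDesignError(ValueError):
    """No degenerate codon satisfies the requested constraints."""


@lru_cache(maxsize=4096)
def _expand(symbols: str) -> tuple[str, ...]:
    return tuple("".join(b) for b in product(*(IUPAC_DNA[s] for s in symbols)))


@lru_cache(maxsize=4096)
def _encode(symbols: str) -> tuple[str, ...]:
    from rnpkit.seq_struct_io import _STANDARD_TABLE

    out = []
    for codon in _expand(symbols):
        if codon in _STANDARD_TABLE.stop_codons:
            out.append("*")
        else:
            out.append(_STANDARD_TABLE.forward_table[codon])
    return tuple(out)


@dataclass(frozen=True)
class DegenerateCodon:
    """Three IUPAC symbols plus their derived expansion and encoded residues."""

    symbols: str

    def __post_init__(self):
        if len(self.symbols) != 3 or any(s not in IUPAC_DNA for s in self.symbols):
            raise ValueError(f"invalid degenerate codon {self.symbols!r}")

    @property
    def expansion(self) -> tuple[str, ...]:
        """All plain codons the degenerate codon is synthesized as."""
        return _expand(self.symbols)

    @property
    def encoded(self) -> tuple[str, ...]:
        """Multiset of residues ('*' = stop) encoded by the expansion."""
        return _encode(self.symbols)

    @property
    def degeneracy(self) -> int:
        return len(self.expansion)

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True)
class PositionPool:
    """Allowed amino acids at one (1-based) position of the wild-type protein."""

    position: int
    wild_type: str
    allowed: frozenset[str]
    fixed: bool

    def __post_init__(self):
        if not self.allowed:
            raise ValueError(f"position {self.position}: empty pool")
        if self.fixed and len(self.allowed) != 1:
            raise ValueError(
                f"position {self.position}: fixed pool must hold one residue"
            )


@dataclass
class LibraryScheme:
    """An ordered set of position pools with one degenerate codon each."""

    name: str
    pools: list[PositionPool]
    codons: list[DegenerateCodon]
    alphabet: frozenset[str]

    def __post_init__(self):
        if len(self.pools) != len(self.codons):
            raise ValueError("pools and codons must align one-to-one")
        for pool, codon in zip(self.pools, self.codons):
            if not pool.allowed <= set(codon.encoded):
                raise ValueError(
                    f"position {pool.position}: codon {codon} does not cover "
                    f"pool {sorted(pool.allowed)}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "alphabet": "".join(sorted(self.alphabet)),
            "positions": [
                {
                    "position": p.position,
                    "wild_type": p.wild_type,
                    "allowed": "".join(sorted(p.allowed)),
                    "fixed": p.fixed,
                    "codon": c.symbols,
                }
                for p, c in zip(self.pools, self.codons)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LibraryScheme":
        payload = json.loads(Path(path).read_text())
        pools, codons = [], []
        for entry in payload["positions"]:
            pools.append(
                PositionPool(
                    entry["position"],
                    entry["wild_type"],
                    frozenset(entry["allowed"]),
                    entry["fixed"],
                )
            )
            codons.append(DegenerateCodon(entry["codon"]))
        return cls(payload["name"], pools, codons, frozenset(payload["alphabet"]))


# ---------------------------------------------------------------------------
# Substitution-score table
# ---------------------------------------------------------------------------


def load_substitution_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 20x20 substitution-score table (TSV, residues as index/columns).

    With no path, BLOSUM62 is used. Higher scores mean more acceptable
    substitutions; used only to pick fall-back fixed residues.
    """
    if path is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        aas = list(AMINO_ACIDS)
        data = [[mat[a, b] for b in aas] for a in aas]
        return pd.DataFrame(data, index=aas, columns=aas, dtype=float)
    table = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(AMINO_ACIDS) - set(table.index)
    if missing or set(AMINO_ACIDS) - set(table.columns):
        raise ValueError(f"substitution table misses residues: {sorted(missing)}")
    return table.astype(float)


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------


def pools_from_alignment(
    wild_type: PeptideSequence,
    alignment: Sequence[PeptideSequence],
    alphabet: Iterable[str],
    min_column_freq: float,
    substitution_table: Optional[pd.DataFrame] = None,
) -> list[PositionPool]:
    """Per-column substitution pools from a pre-aligned protein family.

    For each column, the pool is the set of residues whose (gap-excluded)
    column frequency reaches ``min_column_freq``, intersected with the
    design alphabet. An empty intersection fixes the position at the
    alphabet member scoring highest against the wild-type residue under
    the substitution table (ties alphabetical); a singleton pool is fixed.
    """
    if not 0 <= min_column_freq <= 1:
        raise ValueError("min_column_freq must be in [0, 1]")
    alphabet = frozenset(alphabet)
    length = len(wild_type)
    for seq in alignment:
        if len(seq) != length:
            raise ValueError(
                f"alignment sequence {seq.identifier!r} length {len(seq)} != "
                f"wild-type length {length}"
            )
    if not alignment:
        warnings.warn("empty alignment: all positions fixed at wild type")
    if substitution_table is None:
        substitution_table = load_substitution_table()

    pools = []
    for col in range(length):
        wt = wild_type.residues[col]
        residues = [s.residues[col] for s in alignment if s.residues[col] != "-"]
        if residues:
            counts = pd.Series(residues).value_counts()
            freqs = counts / counts.sum()
            allowed = frozenset(freqs.index[freqs >= min_column_freq]) & alphabet
        else:
            allowed = frozenset()
        if not allowed:
            scores = substitution_table.loc[wt, sorted(alphabet)]
            best = scores.index[np.argmax(scores.to_numpy())]
            pools.append(PositionPool(col + 1, wt, frozenset({best}), True))
        else:
            pools.append(PositionPool(col + 1, wt, allowed, len(allowed) == 1))
    return pools


# ---------------------------------------------------------------------------
# Degenerate codon optimization
# ---------------------------------------------------------------------------


def _objective(codon: DegenerateCodon, required: frozenset[str]) -> tuple:
    encoded = codon.encoded
    species = set(encoded)
    off_target = len((species - {"*"}) - required)
    stops = sum(1 for e in encoded if e == "*")
    return (off_target, stops, codon.degeneracy, codon.symbols)


@lru_cache(maxsize=1)
def _all_codons() -> tuple[DegenerateCodon, ...]:
    return tuple(
        DegenerateCodon(a + b + c)
        for a in _IUPAC_SYMBOLS
        for b in _IUPAC_SYMBOLS
        for c in _IUPAC_SYMBOLS
    )


def all_degenerate_codons() -> list[DegenerateCodon]:
    """All 3,375 degenerate codons, in lexicographic IUPAC order."""
    return list(_all_codons())


def design_codon(
    required: Iterable[str],
    allow_offtarget: bool = False,
    allow_stop: bool = False,
    relax: bool = False,
) -> DegenerateCodon:
    """Optimal degenerate codon covering a required amino-acid set.

    Exhaustive search over every degenerate codon; a codon is feasible when
    its encoded set contains all required residues, and — under the default
    exact mode — nothing else and no stop. Among feasible codons the one
    minimizing (off-target species, stop count, degeneracy, IUPAC string)
    is returned. If no exact cover exists, a :class:`CodonDesignError`
    names the best near-miss; with ``relax=True`` the search is rerun with
    off-target residues permitted instead.
    """
    required = frozenset(r.upper() for r in required)
    if not required:
        raise ValueError("required set is empty")
    bad = required - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"not canonical amino acids: {sorted(bad)}")

    best = None
    best_key = None
    for codon in all_degenerate_codons():
        species = set(codon.encoded)
        if not required <= species:
            continue
        if not allow_offtarget and (species - {"*"}) - required:
            continue
        if not allow_stop and "*" in species:
            continue
        key = _objective(codon, required)
        if best_key is None or key < best_key:
            best, best_key = codon, key
    if best is not None:
        return best

    if not allow_offtarget:
        if relax:
            return design_codon(
                required, allow_offtarget=True, allow_stop=allow_stop, relax=False
            )
        # best near-miss: covering codon with fewest off-target/stops
        near = min(
            (
                c
                for c in all_degenerate_codons()
                if required <= set(c.encoded)
                and (allow_stop or "*" not in set(c.encoded))
            ),
            key=lambda c: _objective(c, required),
            default=None,
        )
        hint = f"; best near-miss {near}" if near is not None else ""
        raise CodonDesignError(
            f"no exact degenerate codon encodes {sorted(required)}{hint}"
        )
    raise CodonDesignError(f"no degenerate codon covers {sorted(required)}")


def codon_profile(codon: DegenerateCodon | str) -> dict[str, float]:
    """Expected residue frequencies of a degenerate codon.

    Frequencies are expansion counts over degeneracy and sum to 1; stops
    appear under ``'*'`` when present.
    """
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    encoded = codon.encoded
    n = len(encoded)
    profile: dict[str, float] = {}
    for res in encoded:
        profile[res] = profile.get(res, 0.0) + 1.0 / n
    return profile


# ---------------------------------------------------------------------------
# Diversity accounting
# ---------------------------------------------------------------------------


def diversity(scheme: LibraryScheme) -> tuple[int, int, float]:
    """(protein variants, DNA variants, randomized position fraction).

    Protein diversity multiplies, per pool, the number of distinct encoded
    amino acids within the pool's allowed set (for an exact-cover codon this
    is simply the pool size); DNA diversity multiplies codon degeneracies.
    """
    protein_variants = 1
    dna_variants = 1
    randomized = 0
    for pool, codon in zip(scheme.pools, scheme.codons):
        encoded = set(codon.encoded) - {"*"}
        protein_variants *= len(encoded & pool.allowed)
        dna_variants *= codon.degeneracy
        if not pool.fixed:
            randomized += 1
    fraction = randomized / len(scheme.pools) if scheme.pools else 0.0
    return protein_variants, dna_variants, fraction
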