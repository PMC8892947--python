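"""Selection-round enrichment analysis: abundance ranking, logos, consensus.

Turns the per-round read sets of an mRNA-display selection into peptide
count tables, rank-abundance statistics, position frequency matrices and
information-content sequence logos, per-clone enrichment trajectories, and
threshold consensus motifs.

Information content per position is ``log2(20) - H`` bits, where ``H`` is
the Shannon entropy of the residue frequencies; letter height is frequency
times information content. No small-sample correction is applied by
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rnpkit.seq_struct_io import AMINO_ACIDS, NucleotideSequence, PeptideSequence, translate

__all__ = [
    "SelectionRoundTable",
    "PositionFrequencyMatrix",
    "LogoMatrix",
    "count_peptides",
    "rank_abundance",
    "logo",
    "enrichment_trajectory",
    "consensus",
    "plot_logo",
]

MAX_BITS = math.log2(20)


@dataclass
class SelectionRoundTable:
    """Peptide -> read count for one selection round."""

    round_id: int
    counts: dict[str, int]

    def __post_init__(self):
        for pep, c in self.counts.items():
            if c < 1:
                raise ValueError(f"count for {pep!r} must be >= 1, got {c}")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def fraction(self, peptide: str) -> float:
        total = self.total_reads
        return self.counts.get(peptide, 0) / total if total else 0.0

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["peptide", "count"],
        )
        df["fraction"] = df["count"] / self.total_reads
        df.to_csv(path, sep="\t", index=False)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue fractions over equal-length peptides.

    ``freqs`` is a (length x 20) DataFrame with residue columns; rows sum
    to 1. ``support`` is the number of sequences used.
    """

    freqs: pd.DataFrame
    support: int

    def __post_init__(self):
        sums = self.freqs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFM rows must each sum to 1")

    @property
    def length(self) -> int:
        return len(self.freqs)


@dataclass
class LogoMatrix:
    """Per-position letter heights in bits (frequency x information content)."""

    heights: pd.DataFrame

    def __post_init__(self):
        vals = self.heights.to_numpy()
        if (vals < -1e-12).any():
            raise ValueError("logo heights must be nonnegative")
        totals = vals.sum(axis=1)
        if (totals > MAX_BITS + 1e-9).any():
            raise ValueError(f"per-position information exceeds log2(20)")

    @property
    def information_content(self) -> np.ndarray:
        return self.heights.to_numpy().sum(axis=1)


# ---------------------------------------------------------------------------
# Read processing
# ---------------------------------------------------------------------------


def count_peptides(
    reads: Sequence[NucleotideSequence],
    flank5: str = "",
    flank3: str = "",
    min_count: int = 1,
    round_id: int = 0,
) -> SelectionRoundTable:
    """Excise inserts between constant flanks, translate, and tally peptides.

    A read contributes when both flanks match exactly (an empty flank
    matches trivially), the insert translates in frame 0, and the peptide
    contains no stop. Peptides below ``min_count`` after aggregation are
    dropped.
    """
    flank5, flank3 = flank5.upper(), flank3.upper()
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.residues.upper()
        start = seq.find(flank5)
        if start < 0:
            continue
        insert_start = start + len(flank5)
        if flank3:
            end = seq.find(flank3, insert_start)
            if end < 0:
                continue
        else:
            end = len(seq)
        insert = seq[insert_start:end]
        if len(insert) < 3:
            continue
        peptide = translate(NucleotideSequence(read.identifier, insert)).residues
        if "*" in peptide:
            continue
        counts[peptide] = counts.get(peptide, 0) + 1
    counts = {p: c for p, c in counts.items() if c >= min_count}
    if not counts:
        warnings.warn("no reads survived flank matching and translation")
    return SelectionRoundTable(round_id, counts)


def rank_abundance(
    table: SelectionRoundTable, n: int = 100
) -> list[tuple[str, int, float]]:
    """Top-``n`` peptides as (peptide, count, fraction of total reads).

    Descending by count; ties broken lexicographically by peptide.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = table.total_reads
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(pep, c, c / total) for pep, c in ranked[:n]]


# ---------------------------------------------------------------------------
# Logos
# ---------------------------------------------------------------------------


def logo(
    peptides: Sequence[PeptideSequence | str],
    weighting: str = "uniform",
    counts: Optional[Sequence[int]] = None,
) -> tuple[PositionFrequencyMatrix, LogoMatrix]:
    """Position frequency matrix and information-content logo.

    ``weighting="uniform"`` treats each sequence once (the default, as for
    a top-N abundance list); ``weighting="count"`` weights each sequence by
    its read count (``counts`` required). Peptides containing ambiguous
    'X' residues are excluded.
    """
    seqs = [p.residues if isinstance(p, PeptideSequence) else p for p in peptides]
    if weighting not in ("uniform", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "count":
        if counts is None or len(counts) != len(seqs):
            raise ValueError("count weighting requires one count per peptide")
        weights = list(counts)
    else:
        weights = [1] * len(seqs)

    kept = [(s, w) for s, w in zip(seqs, weights) if "X" not in s]
    if not kept:
        raise ValueError("no peptides to build a logo from")
    length = len(kept[0][0])
    if any(len(s) != length for s, _ in kept):
        raise ValueError("all peptides must have equal length")

    aas = list(AMINO_ACIDS)
    counts_mat = np.zeros((length, 20))
    aa_index = {a: i for i, a in enumerate(aas)}
    for seq, w in kept:
        for pos, res in enumerate(seq):
            counts_mat[pos, aa_index[res]] += w
    freqs = counts_mat / counts_mat.sum(axis=1, keepdims=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = MAX_BITS - entropy
    heights = freqs * ic[:, None]

    index = pd.RangeIndex(1, length + 1, name="position")
    pfm = PositionFrequencyMatrix(
        pd.DataFrame(freqs, index=index, columns=aas), support=len(kept)
    )
    lm = LogoMatrix(pd.DataFrame(heights, index=index, columns=aas))
    return pfm, lm


def plot_logo(lm: LogoMatrix, ax=None):
    """Render a logo as stacked per-position letters scaled to bit heights."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.35 * len(lm.heights) + 1, 2.5))
    palette = {r: ("crimson" if r in "DE" else "royalblue" if r in "KRH" else "black")
               for r in AMINO_ACIDS}
    for pos, row in lm.heights.iterrows():
        y = 0.0
        for res, h in sorted(row.items(), key=lambda kv: kv[1]):
            if h <= 0:
                continue
            ax.text(pos, y + h / 2, res, ha="center", va="center",
                    fontsize=9, color=palette[res],
                    fontweight="bold")
            y += h
    ax.set_xlim(0.3, len(lm.heights) + 0.7)
    ax.set_ylim(0, MAX_BITS)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax


# ---------------------------------------------------------------------------
# Enrichment and consensus
# ---------------------------------------------------------------------------


def enrichment_trajectory(
    rounds: Sequence[SelectionRoundTable], peptide: PeptideSequence | str
) -> list[tuple[int, float, Optional[float]]]:
    """Per-round (round_id, fraction, ratio to previous round) for one clone.

    The ratio is ``None`` (missing) whenever the previous round's fraction
    is zero; a clone absent from a round has fraction 0 there.
    """
    if not rounds:
        raise ValueError("need at least one round")
    pep = peptide.residues if isinstance(peptide, PeptideSequence) else peptide
    out = []
    prev: Optional[float] = None
    for table in rounds:
        frac = table.fraction(pep)
        ratio = frac / prev if prev not in (None, 0.0) else None
        out.append((table.round_id, frac, ratio))
        prev = frac
    return out


def consensus(pfm: PositionFrequencyMatrix, threshold: float = 0.5) -> str:
    """Modal residue per position when its frequency reaches the threshold.

    Positions whose mode falls below the threshold render as ``x``; modal
    ties resolve to the alphabetically first residue.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out = []
    for _pos, row in pfm.freqs.iterrows():
        best = row.max()
        if best >= threshold:
            # columns are alphabetical, idxmax takes the first maximum
            out.append(row.idxmax())
        else:
            out.append("x")
    return "".join(out)
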