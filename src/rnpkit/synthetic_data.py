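"""Ground-truth generators for every pipeline input.

Emulates the study conditions of a reduced-alphabet selection campaign:
degenerate-codon library synthesis (uniform codon sampling), multi-round
affinity selection (frequency-proportional multinomial resampling with
static per-motif retention weights — the simplest model consistent with
enrichment of better binders), noisy two-phase sensorgrams (via
:mod:`rnpkit.binding_kinetics`), and small protein-RNA ensembles with
interactions planted at exact target occupancies plus Gaussian coordinate
jitter. Every generator is deterministic given its seed, and each returns
its ground truth so tests can score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from rnpkit.seq_struct_io import Ensemble, NucleotideSequence, translate
from rnpkit.library_design import DegenerateCodon, LibraryScheme, PositionPool, design_codon
from rnpkit.selection_analysis import SelectionRoundTable

__all__ = [
    "SelectionSimSpec",
    "SelectionSimResult",
    "PlantedInteraction",
    "PlantedEnsembleSpec",
    "sample_library",
    "simulate_selection",
    "build_planted_ensemble",
    "example_scheme",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
]

#: Constant flanking sequences used when emitting reads; long enough that a
#: chance internal match in a random insert is negligible.
DEFAULT_FLANK5 = "TATGGCTAGCAA"
DEFAULT_FLANK3 = "GGTTCGGATCCT"


# ---------------------------------------------------------------------------
# Library sampling
# ---------------------------------------------------------------------------


def sample_library(
    scheme: LibraryScheme, n: int, seed: int
) -> list[NucleotideSequence]:
    """Draw ``n`` DNA variants, each position's codon uniform over its expansion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    expansions = [codon.expansion for codon in scheme.codons]
    choices = [rng.integers(0, len(e), size=n) for e in expansions]
    out = []
    for i in range(n):
        dna = "".join(exp[choices[j][i]] for j, exp in enumerate(expansions))
        out.append(NucleotideSequence(f"lib_{i}", dna))
    return out


# ---------------------------------------------------------------------------
# Selection simulation
# ---------------------------------------------------------------------------


@dataclass
class SelectionSimSpec:
    """Conditions of a simulated multi-round affinity selection."""

    scheme: LibraryScheme
    n_reads_per_round: int
    n_rounds: int
    fitness: dict[str, float] = field(default_factory=dict)  # motif -> weight
    seed: int = 0
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    error_rate: float = 0.0  # per-base substitution rate on emitted reads

    def __post_init__(self):
        if self.n_reads_per_round < 1:
            raise ValueError("n_reads_per_round must be >= 1")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        for motif, w in self.fitness.items():
            if w <= 0:
                raise ValueError(f"retention weight for {motif!r} must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SelectionSimResult:
    """Per-round count tables, the emitted reads, and the ground truth.

    ``true_freqs`` maps peptide -> expected (pre-sampling) frequency per
    round, i.e. the multinomial probabilities the reads were drawn from.
    """

    tables: list[SelectionRoundTable]
    reads: list[list[NucleotideSequence]]
    true_freqs: dict[str, list[float]]


def _retention_weight(peptide: str, fitness: dict[str, float]) -> float:
    w = 1.0
    for motif, weight in fitness.items():
        if motif in peptide:
            w *= weight
    return w


def _mutate(dna: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return dna
    bases = "ACGT"
    chars = list(dna)
    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in hits:
        chars[i] = bases[(bases.index(chars[i]) + rng.integers(1, 4)) % 4]
    return "".join(chars)


def simulate_selection(spec: SelectionSimSpec) -> SelectionSimResult:
    """Simulate rounds 0..n_rounds of selection on a finite sampled pool.

    Round 0 draws ``n_reads_per_round`` variants from the library; each
    subsequent round resamples (multinomially) with probabilities
    proportional to previous-round frequency times the peptide's retention
    weight. Variants whose insert contains a stop codon are never retained
    (they cannot be displayed). Reads are emitted as flanked DNA.
    """
    rng = np.random.default_rng(spec.seed)
    naive = sample_library(spec.scheme, spec.n_reads_per_round,
                           seed=int(rng.integers(2**31)))
    # finite founding pool: distinct DNA variants with round-0 counts
    pool: dict[str, int] = {}
    for read in naive:
        pool[read.residues] = pool.get(read.residues, 0) + 1
    variants = sorted(pool)
    peptides = {dna: translate(NucleotideSequence("v", dna)).residues
                for dna in variants}
    displayable = np.array(
        ["*" not in peptides[dna] for dna in variants], dtype=float
    )
    weights = np.array(
        [_retention_weight(peptides[dna], spec.fitness) for dna in variants]
    ) * displayable
    counts = np.array([pool[dna] for dna in variants], dtype=float)

    tables: list[SelectionRoundTable] = []
    reads: list[list[NucleotideSequence]] = []
    true_freqs: dict[str, list[float]] = {}

    def record_round(round_id: int, counts_vec: np.ndarray, probs: np.ndarray):
        table_counts: dict[str, int] = {}
        round_reads: list[NucleotideSequence] = []
        k = 0
        for dna, c in zip(variants, counts_vec.astype(int)):
            if c <= 0:
                continue
            pep = peptides[dna]
            if "*" not in pep:
                table_counts[pep] = table_counts.get(pep, 0) + c
            for _ in range(c):
                seq = spec.flank5 + _mutate(dna, spec.error_rate, rng) + spec.flank3
                round_reads.append(
                    NucleotideSequence(f"r{round_id}_read{k}", seq)
                )
                k += 1
        tables.append(SelectionRoundTable(round_id, table_counts))
        reads.append(round_reads)
        pep_probs: dict[str, float] = {}
        for dna, p in zip(variants, probs):
            pep_probs[peptides[dna]] = pep_probs.get(peptides[dna], 0.0) + p
        for pep, p in pep_probs.items():
            true_freqs.setdefault(pep, [0.0] * (spec.n_rounds + 1))[round_id] = p

    uniform_probs = np.ones(len(variants)) / len(variants)
    record_round(0, counts, counts / counts.sum())
    for r in range(1, spec.n_rounds + 1):
        raw = counts * weights
        if raw.sum() == 0:
            raise RuntimeError("selection extinguished the pool (all stops)")
        probs = raw / raw.sum()
        counts = rng.multinomial(spec.n_reads_per_round, probs).astype(float)
        record_round(r, counts, probs)
    return SelectionSimResult(tables, reads, true_freqs)


# ---------------------------------------------------------------------------
# Planted protein-RNA ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction to plant at a known occupancy.

    ``kind`` is one of ``hbond`` (direct protein-RNA H-bond; ``via``
    selects the protein partner: side chain or backbone), ``water_bridge``,
    or ``ion_bridge`` (``element`` MG or K).
    """

    kind: str
    occupancy: float
    via: str = "side chain"
    element: str = "MG"

    def __post_init__(self):
        if self.kind not in ("hbond", "water_bridge", "ion_bridge"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("target occupancy must lie in [0, 1]")
        if self.via not in ("side chain", "backbone"):
            raise ValueError(f"unknown via {self.via!r}")
        if self.element not in ("MG", "K"):
            raise ValueError(f"unsupported ion element {self.element!r}")


@dataclass
class PlantedEnsembleSpec:
    """A toy protein-RNA ensemble with interactions at set occupancies."""

    n_frames: int
    planted: tuple[PlantedInteraction, ...] = ()
    jitter_sd: float = 0.05  # A, isotropic per-atom Gaussian jitter
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        self.planted = tuple(self.planted)


_SITE_SPACING = 30.0   # A between planted sites: no cross-talk
_NEAR = 2.7            # A, inside the H-bond distance criterion
_ION_NEAR = 2.2        # A, inside the ion coordination cutoffs
_FAR_SHIFT = 8.0       # A displacement that breaks the interaction


def _ser_residue(origin: np.ndarray, res_id: int):
    """A serine with backbone + OG side-chain oxygen, atoms relative to origin."""
    atoms = [
        ("N", "N", np.array([-1.2, 0.8, 0.0])),
        ("CA", "C", np.array([0.0, 0.0, 0.0])),
        ("C", "C", np.array([1.2, 0.8, 0.0])),
        ("O", "O", np.array([1.4, 2.0, 0.0])),
        ("CB", "C", np.array([0.0, -1.5, 0.0])),
        ("OG", "O", np.array([0.0, -2.9, 0.0])),
    ]
    return [
        ("A", res_id, "SER", name, elem, origin + off) for name, elem, off in atoms
    ]


def _rna_residue(anchor: np.ndarray, res_id: int):
    """A uridine fragment; OP1 sits exactly at ``anchor``."""
    atoms = [
        ("OP1", "O", np.array([0.0, 0.0, 0.0])),
        ("P", "P", np.array([1.3, -0.8, 0.0])),
        ("OP2", "O", np.array([2.4, -1.5, 0.4])),
        ("O5'", "O", np.array([1.2, -2.0, -1.1])),
        ("C1'", "C", np.array([3.2, -3.5, 0.0])),
        ("O2'", "O", np.array([4.1, -4.6, 0.3])),
    ]
    return [
        ("B", res_id, "U", name, elem, anchor + off) for name, elem, off in atoms
    ]


def build_planted_ensemble(
    spec: PlantedEnsembleSpec,
) -> tuple[Ensemble, dict[str, np.ndarray]]:
    """Build the toy ensemble plus ground-truth per-frame presence masks.

    Each planted interaction gets its own spatial site (one Ser residue,
    one uridine fragment, plus a water or ion as needed), far from every
    other site. In a Bernoulli(occupancy) subset of frames the mobile
    partner sits inside the detection criteria; otherwise it is displaced
    well beyond them. Gaussian jitter is added to every coordinate.
    Returns ``(ensemble, masks)`` with one boolean frame mask per planted
    interaction, keyed ``"{kind}_{site_index}"``.
    """
    rng = np.random.default_rng(spec.seed)
    static_atoms: list[tuple] = []   # (chain, res_id, res_name, atom, elem, xyz)
    mobile: list[dict] = []          # per planted: atoms + near/far anchors

    plants = spec.planted if spec.planted else ()
    for j, plant in enumerate(plants):
        origin = np.array([_SITE_SPACING * j, 0.0, 0.0])
        ser = _ser_residue(origin, j + 1)
        static_atoms.extend(ser)
        og = origin + np.array([0.0, -2.9, 0.0])
        bb_o = origin + np.array([1.4, 2.0, 0.0])

        if plant.kind == "hbond":
            if plant.via == "side chain":
                near = og + np.array([0.0, -_NEAR, 0.0])
            else:
                # RNA O2' donates to the backbone carbonyl O; anchor the
                # residue so O2' (offset 4.1,-4.6,0.3 from OP1) lands near O
                o2p_target = bb_o + np.array([0.0, _NEAR, 0.0])
                near = o2p_target - np.array([4.1, -4.6, 0.3])
            far = near + np.array([0.0, -_FAR_SHIFT, 0.0])
            mobile.append(
                {"label": f"hbond_{j}", "occupancy": plant.occupancy,
                 "atoms": _rna_residue(np.zeros(3), 100 + j),
                 "near": near, "far": far}
            )
        elif plant.kind == "water_bridge":
            rna_anchor = og + np.array([0.0, -5.4, 0.0])
            static_atoms.extend(_rna_residue(rna_anchor, 100 + j))
            near = og + np.array([0.0, -_NEAR, 0.0])  # midpoint: 2.7 to each
            far = near + np.array([_FAR_SHIFT, 0.0, 0.0])
            mobile.append(
                {"label": f"water_bridge_{j}", "occupancy": plant.occupancy,
                 "atoms": [("W", 500 + j, "HOH", "O", "O", np.zeros(3))],
                 "near": near, "far": far}
            )
        else:  # ion_bridge
            rna_anchor = og + np.array([0.0, -2 * _ION_NEAR, 0.0])
            static_atoms.extend(_rna_residue(rna_anchor, 100 + j))
            near = og + np.array([0.0, -_ION_NEAR, 0.0])
            far = near + np.array([_FAR_SHIFT, 0.0, 0.0])
            name = plant.element
            mobile.append(
                {"label": f"ion_bridge_{j}", "occupancy": plant.occupancy,
                 "atoms": [("I", 900 + j, name, name, name, np.zeros(3))],
                 "near": near, "far": far}
            )

    if not plants:
        # minimal two-chain system so interface operations run cleanly
        static_atoms.extend(_ser_residue(np.zeros(3), 1))
        static_atoms.extend(_rna_residue(np.array([0.0, -12.0, 0.0]), 100))

    n_static = len(static_atoms)
    all_meta = list(static_atoms) + [
        (a[0], a[1], a[2], a[3], a[4]) + (a[5],)
        for grp in mobile for a in grp["atoms"]
    ]
    chains = np.array([a[0] for a in all_meta], dtype="U4")
    res_ids = np.array([a[1] for a in all_meta], dtype=int)
    res_names = np.array([a[2] for a in all_meta], dtype="U5")
    names = np.array([a[3] for a in all_meta], dtype="U6")
    elements = np.array([a[4] for a in all_meta], dtype="U2")

    from rnpkit.seq_struct_io import classify_residue

    polymer = np.array([classify_residue(r) for r in res_names], dtype="U7")

    masks: dict[str, np.ndarray] = {
        grp["label"]: rng.random(spec.n_frames) < grp["occupancy"]
        for grp in mobile
    }

    coords = np.empty((spec.n_frames, len(all_meta), 3))
    static_xyz = np.array([a[5] for a in static_atoms]).reshape(n_static, 3)
    for f in range(spec.n_frames):
        frame = [static_xyz.copy()] if n_static else []
        for grp in mobile:
            anchor = grp["near"] if masks[grp["label"]][f] else grp["far"]
            frame.append(np.array([anchor + a[5] for a in grp["atoms"]]))
        xyz = np.vstack(frame)
        if spec.jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sd, size=xyz.shape)
        coords[f] = xyz

    # feasibility: no two distinct atoms closer than 1 A in the clean frame-0
    from scipy.spatial.distance import pdist

    clean = np.vstack(
        [static_xyz]
        + [np.array([grp["near"] + a[5] for a in grp["atoms"]]) for grp in mobile]
    ) if n_static else np.zeros((0, 3))
    if len(clean) >= 2 and pdist(clean).min() < 1.0:
        raise ValueError("planted geometry infeasible: atoms overlap below 1 A")

    ens = Ensemble(
        atom_names=names, elements=elements, res_names=res_names,
        res_ids=res_ids, chain_ids=chains, polymer_class=polymer,
        coords=coords,
    )
    return ens, masks


# ---------------------------------------------------------------------------
# Example scheme (synthetic)
# ---------------------------------------------------------------------------

# Early-alphabet pools that admit an exact-cover degenerate codon.
_POOLS_3 = [frozenset("ILV"), frozenset("APT"), frozenset("DGV"),
            frozenset("AEG"), frozenset("DEG"), frozenset("DEV")]
_POOLS_4 = [frozenset("APST"), frozenset("ADGV"), frozenset("AEGV"),
            frozenset("DEGV")]


def example_scheme(
    name: str = "synthetic-early-library",
    length: int = 69,
    n_randomized: int = 18,
    seed: int = 0,
) -> LibraryScheme:
    """A synthetic reduced-alphabet scheme with realistic shape.

    Emulates an early-alphabet design: ``length`` positions of which
    ``n_randomized`` (default 26%) carry substitution pools of size 3-4
    (exact-cover codons), the rest fixed — yielding a protein diversity on
    the order of 10^10 for the defaults. Entirely synthetic: positions and
    pools are generated, not taken from any published construct.
    """
    rng = np.random.default_rng(seed)
    early = "GADVESILPT"
    randomized_pos = set(
        rng.choice(length, size=n_randomized, replace=False).tolist()
    )
    # two thirds of randomized positions get size-4 pools, one third size-3
    pools: list[PositionPool] = []
    codons: list[DegenerateCodon] = []
    k4 = 0
    for pos in range(length):
        wt = early[pos % len(early)]
        if pos in randomized_pos:
            if k4 < (2 * n_randomized) // 3:
                allowed = _POOLS_4[k4 % len(_POOLS_4)]
                k4 += 1
            else:
                allowed = _POOLS_3[pos % len(_POOLS_3)]
            pools.append(PositionPool(pos + 1, wt, allowed, False))
            codons.append(design_codon(allowed))
        else:
            pools.append(PositionPool(pos + 1, wt, frozenset({wt}), True))
            codons.append(design_codon({wt}))
    return LibraryScheme(name, pools, codons, frozenset(early))
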