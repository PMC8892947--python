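"""Protein-RNA interface characterization over conformational ensembles.

Detects direct hydrogen bonds, water bridges and metal-ion bridges at a
protein-RNA interface frame by frame, reports each interaction's occupancy
(fraction of analyzed frames in which it is present), builds volumetric
per-voxel occupancy grids for chosen species, and computes backbone RMSD
restricted to secondary-structure elements after optimal (Kabsch)
superposition.

Geometric criteria (defaults): an H-bond requires donor-acceptor heavy-atom
distance <= 3.0 A and, when explicit hydrogens are present, a D-H-A angle
>= 135 deg. Ion coordination uses per-element distance cutoffs
(Mg2+ 3.0 A, K+ 3.5 A) to protein/RNA O and N atoms. The default analysis
window is the final 25% of frames — the tail of a trajectory after
equilibration — and is overridable everywhere via ``frames``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from rnpkit.seq_struct_io import Ensemble, SSElementSet

__all__ = [
    "AtomRef",
    "HBondRecord",
    "BridgeRecord",
    "OccupancyGrid",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_ion_bridges",
    "occupancy_grid",
    "superpose_and_rmsd",
    "sidechain_backbone_summary",
    "DEFAULT_DIST_CUTOFF",
    "DEFAULT_ANGLE_CUTOFF",
    "DEFAULT_ION_CUTOFFS",
    "DEFAULT_MIN_OCCUPANCY",
]

DEFAULT_DIST_CUTOFF = 3.0     # A, donor-acceptor heavy atoms
DEFAULT_ANGLE_CUTOFF = 135.0  # deg, D-H-A
DEFAULT_ION_CUTOFFS = {"MG": 3.0, "K": 3.5}
DEFAULT_MIN_OCCUPANCY = 0.10

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# --- donor/acceptor heavy-atom tables -------------------------------------
# Protein side-chain donors/acceptors by residue; backbone N donates (except
# Pro), backbone O (and OXT) accepts, for every residue.
_PROT_SC_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}
_PROT_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
# RNA: sugar O2' donates and accepts; phosphate and ring oxygens accept;
# exocyclic amines and ring NH donate.
_RNA_DONORS = {
    "A": {"O2'", "N6"},
    "G": {"O2'", "N1", "N2"},
    "C": {"O2'", "N4"},
    "U": {"O2'", "N3"},
}
_RNA_ACCEPTORS_COMMON = {"OP1", "OP2", "O5'", "O3'", "O2'", "O4'"}
_RNA_ACCEPTORS_BASE = {
    "A": {"N1", "N3", "N7"},
    "G": {"O6", "N3", "N7"},
    "C": {"O2", "N3"},
    "U": {"O2", "O4"},
}


class AtomRef(NamedTuple):
    """A stable reference to one atom of an ensemble."""

    chain_id: str
    res_id: int
    res_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_id}:{self.atom_name}"


def _atom_ref(ens: Ensemble, i: int) -> AtomRef:
    return AtomRef(
        str(ens.chain_ids[i]), int(ens.res_ids[i]),
        str(ens.res_names[i]), str(ens.atom_names[i]),
    )


@dataclass
class HBondRecord:
    """A direct protein-RNA hydrogen bond aggregated over frames."""

    donor: AtomRef
    acceptor: AtomRef
    occupancy: float
    donor_side: str          # "protein" or "rna"
    via: str                 # "side chain" or "backbone" (protein atom)
    hydrogen: Optional[AtomRef] = None

    def __post_init__(self):
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class BridgeRecord:
    """An indirect protein-RNA contact via a water molecule or metal ion."""

    bridge_kind: str         # "water" or "ion"
    bridging_species: AtomRef
    protein_partner: AtomRef
    rna_partner: AtomRef
    occupancy: float
    partner_occupancies: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class OccupancyGrid:
    """Per-voxel fraction of frames in which a selected species is present."""

    origin: np.ndarray       # (3,) A
    voxel_size: float        # A
    values: np.ndarray       # (nx, ny, nz) fractions

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_dx(self, path: str | Path) -> None:
        """Export in OpenDX format (readable by VMD/PyMOL at an isovalue)."""
        from gridData import Grid

        edges = [
            self.origin[d] + self.voxel_size * np.arange(self.values.shape[d] + 1)
            for d in range(3)
        ]
        Grid(self.values, edges=edges).export(str(path), "dx")


# ---------------------------------------------------------------------------
# Frame-window handling
# ---------------------------------------------------------------------------


def resolve_frames(ens: Ensemble, frames=None) -> np.ndarray:
    """Frame indices to analyze; default is the final 25% of the trajectory."""
    n = ens.n_frames
    if frames is None:
        start = n - max(1, n // 4)
        idx = np.arange(start, n)
    elif isinstance(frames, slice):
        idx = np.arange(n)[frames]
    elif isinstance(frames, tuple) and len(frames) == 2:
        idx = np.arange(*frames)
    else:
        idx = np.asarray(list(frames), dtype=int)
    if idx.size == 0:
        raise ValueError("empty frame range")
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"frame indices out of range [0, {n})")
    return idx


# ---------------------------------------------------------------------------
# Donor/acceptor classification
# ---------------------------------------------------------------------------


def _donor_acceptor_indices(ens: Ensemble) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray, np.ndarray]:
    """(protein donors, protein acceptors, RNA donors, RNA acceptors)."""
    p_don, p_acc, r_don, r_acc = [], [], [], []
    for i in range(ens.n_atoms):
        cls = ens.polymer_class[i]
        res = str(ens.res_names[i]).strip()
        name = str(ens.atom_names[i]).strip()
        if cls == "protein":
            if name == "N" and res != "PRO":
                p_don.append(i)
            if name in ("O", "OXT"):
                p_acc.append(i)
            if name in _PROT_SC_DONORS.get(res, ()):
                p_don.append(i)
            if name in _PROT_SC_ACCEPTORS.get(res, ()):
                p_acc.append(i)
        elif cls == "rna":
            if name in _RNA_DONORS.get(res, ()):
                r_don.append(i)
            if name in _RNA_ACCEPTORS_COMMON or name in _RNA_ACCEPTORS_BASE.get(res, ()):
                r_acc.append(i)
    return (np.array(p_don, dtype=int), np.array(p_acc, dtype=int),
            np.array(r_don, dtype=int), np.array(r_acc, dtype=int))


def _hydrogens_by_donor(ens: Ensemble) -> dict[int, np.ndarray]:
    """Map donor atom index -> candidate hydrogen indices (same residue)."""
    h_mask = ens.elements == "H"
    if not h_mask.any():
        return {}
    out: dict[int, np.ndarray] = {}
    h_idx = np.flatnonzero(h_mask)
    for i in range(ens.n_atoms):
        if ens.elements[i] == "H":
            continue
        same = h_idx[
            (ens.chain_ids[h_idx] == ens.chain_ids[i])
            & (ens.res_ids[h_idx] == ens.res_ids[i])
        ]
        if same.size:
            out[i] = same
    return out


def _angle_ok(coords: np.ndarray, donor: int, hydrogens: np.ndarray,
              acceptor: int, angle_cutoff: float) -> bool:
    """True when some covalently bound H gives a D-H-A angle >= cutoff."""
    d, a = coords[donor], coords[acceptor]
    for h in hydrogens:
        hv = coords[h]
        if np.linalg.norm(hv - d) > 1.25:  # not bound to this donor
            continue
        v1, v2 = d - hv, a - hv
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_cutoff:
            return True
    return False


# ---------------------------------------------------------------------------
# Direct hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    ens: Ensemble,
    frames=None,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> list[HBondRecord]:
    """Direct protein-RNA hydrogen bonds with per-pair occupancies.

    Per frame a bond exists when the donor-acceptor heavy-atom distance is
    within ``dist_cutoff`` and — if the ensemble carries hydrogens — some
    donor-bound H satisfies the D-H-A angle criterion. Bonds are aggregated
    by (donor, acceptor) pair; only pairs with occupancy >= ``min_occupancy``
    are returned, sorted by descending occupancy.
    """
    idx = resolve_frames(ens, frames)
    p_don, p_acc, r_don, r_acc = _donor_acceptor_indices(ens)
    h_map = _hydrogens_by_donor(ens)
    if not h_map:
        warnings.warn("no hydrogens in ensemble: D-H-A angle test skipped")

    directions = [
        (p_don, r_acc, "protein"),
        (r_don, p_acc, "rna"),
    ]
    counts: dict[tuple[int, int, str], int] = {}
    for f in idx:
        coords = ens.coords[f]
        for donors, acceptors, side in directions:
            if donors.size == 0 or acceptors.size == 0:
                continue
            dists = cdist(coords[donors], coords[acceptors])
            for di, ai in zip(*np.nonzero(dists <= dist_cutoff)):
                d, a = donors[di], acceptors[ai]
                if d in h_map and not _angle_ok(coords, d, h_map[d], a,
                                               angle_cutoff):
                    continue
                counts[(d, a, side)] = counts.get((d, a, side), 0) + 1

    records = []
    for (d, a, side), c in counts.items():
        occ = c / len(idx)
        if occ < min_occupancy:
            continue
        prot_atom = d if side == "protein" else a
        via = ("backbone"
               if str(ens.atom_names[prot_atom]).strip() in ("N", "O")
               else "side chain")
        records.append(
            HBondRecord(_atom_ref(ens, d), _atom_ref(ens, a), occ, side, via)
        )
    records.sort(key=lambda r: (-r.occupancy, str(r.donor), str(r.acceptor)))
    return records


# ---------------------------------------------------------------------------
# Water bridges
# ---------------------------------------------------------------------------


def detect_water_bridges(
    ens: Ensemble,
    frames=None,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    aggregate: str = "site",
) -> list[BridgeRecord]:
    """Waters simultaneously H-bonded to >=1 protein and >=1 RNA polar atom.

    Contacts use the heavy-atom distance criterion (water oxygen to
    protein/RNA donor-or-acceptor atom). ``aggregate="site"`` merges
    exchanging waters by (protein atom, RNA atom) partner pair — the
    conserved-site view; ``aggregate="water"`` keeps individual water
    molecules apart.
    """
    if aggregate not in ("site", "water"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    idx = resolve_frames(ens, frames)
    p_don, p_acc, r_don, r_acc = _donor_acceptor_indices(ens)
    p_polar = np.union1d(p_don, p_acc)
    r_polar = np.union1d(r_don, r_acc)
    waters = np.flatnonzero(
        (ens.polymer_class == "water") & (ens.elements == "O")
    )
    if waters.size == 0:
        warnings.warn("no water molecules in ensemble")
        return []

    counts: dict[tuple, int] = {}
    witness: dict[tuple, dict[tuple, int]] = {}
    for f in idx:
        coords = ens.coords[f]
        dp = cdist(coords[waters], coords[p_polar]) <= dist_cutoff
        dr = cdist(coords[waters], coords[r_polar]) <= dist_cutoff
        seen: set[tuple] = set()
        for wi in np.flatnonzero(dp.any(axis=1) & dr.any(axis=1)):
            w = waters[wi]
            p_hits = p_polar[dp[wi]]
            r_hits = r_polar[dr[wi]]
            if aggregate == "site":
                for p in p_hits:
                    for r in r_hits:
                        key = (int(p), int(r))
                        seen.add(key)
                        witness.setdefault(key, {})
                        witness[key][int(w)] = witness[key].get(int(w), 0) + 1
            else:
                key = (int(w),)
                seen.add(key)
                witness.setdefault(key, {})
                pair = (int(p_hits[0]), int(r_hits[0]))
                witness[key][pair] = witness[key].get(pair, 0) + 1
        for key in seen:
            counts[key] = counts.get(key, 0) + 1

    records = []
    for key, c in counts.items():
        occ = c / len(idx)
        if occ < min_occupancy:
            continue
        if aggregate == "site":
            p, r = key
            best_water = max(witness[key], key=witness[key].get)
            records.append(
                BridgeRecord("water", _atom_ref(ens, best_water),
                             _atom_ref(ens, p), _atom_ref(ens, r), occ)
            )
        else:
            (w,) = key
            best_pair = max(witness[key], key=witness[key].get)
            records.append(
                BridgeRecord("water", _atom_ref(ens, w),
                             _atom_ref(ens, best_pair[0]),
                             _atom_ref(ens, best_pair[1]), occ)
            )
    records.sort(key=lambda r: (-r.occupancy, str(r.bridging_species)))
    return records


# ---------------------------------------------------------------------------
# Metal-ion bridges
# ---------------------------------------------------------------------------


def detect_ion_bridges(
    ens: Ensemble,
    frames=None,
    cutoffs: Optional[dict[str, float]] = None,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> list[BridgeRecord]:
    """Metal ions simultaneously coordinating protein and RNA O/N atoms.

    An ion bridges in a frame when it lies within its element-specific
    cutoff of at least one protein O/N atom and one RNA O/N atom. Records
    are per ion; ``partner_occupancies`` gives the coordination frequency
    of every individual partner atom. Ions whose element has no cutoff
    raise an error naming the element.
    """
    if cutoffs is None:
        cutoffs = dict(DEFAULT_ION_CUTOFFS)
    cutoffs = {k.upper(): v for k, v in cutoffs.items()}
    idx = resolve_frames(ens, frames)
    ions = np.flatnonzero(ens.polymer_class == "ion")
    for i in ions:
        if str(ens.elements[i]).upper() not in cutoffs:
            raise ValueError(
                f"no coordination cutoff defined for ion element "
                f"{ens.elements[i]!r} ({_atom_ref(ens, i)})"
            )
    is_on = np.isin(ens.elements, ["O", "N"])
    p_coord = np.flatnonzero((ens.polymer_class == "protein") & is_on)
    r_coord = np.flatnonzero((ens.polymer_class == "rna") & is_on)

    bridge_counts: dict[int, int] = {}
    partner_counts: dict[int, dict[int, int]] = {}
    for f in idx:
        coords = ens.coords[f]
        for i in ions:
            cut = cutoffs[str(ens.elements[i]).upper()]
            dp = np.linalg.norm(coords[p_coord] - coords[i], axis=1) <= cut
            dr = np.linalg.norm(coords[r_coord] - coords[i], axis=1) <= cut
            if dp.any() and dr.any():
                bridge_counts[i] = bridge_counts.get(i, 0) + 1
                pc = partner_counts.setdefault(i, {})
                for p in np.concatenate([p_coord[dp], r_coord[dr]]):
                    pc[int(p)] = pc.get(int(p), 0) + 1

    records = []
    for i, c in bridge_counts.items():
        occ = c / len(idx)
        if occ < min_occupancy:
            continue
        pc = partner_counts[i]
        prot = [p for p in pc if ens.polymer_class[p] == "protein"]
        rna = [p for p in pc if ens.polymer_class[p] == "rna"]
        best_p = max(prot, key=pc.get)
        best_r = max(rna, key=pc.get)
        records.append(
            BridgeRecord(
                "ion", _atom_ref(ens, i), _atom_ref(ens, best_p),
                _atom_ref(ens, best_r), occ,
                partner_occupancies={
                    _atom_ref(ens, p): n / len(idx) for p, n in pc.items()
                },
            )
        )
    records.sort(key=lambda r: (-r.occupancy, str(r.bridging_species)))
    return records


# ---------------------------------------------------------------------------
# Volumetric occupancy
# ---------------------------------------------------------------------------


def occupancy_grid(
    ens: Ensemble,
    frames=None,
    species: Optional[np.ndarray | dict] = None,
    voxel_size: float = 1.0,
    origin: Optional[np.ndarray] = None,
    dims: Optional[tuple[int, int, int]] = None,
) -> OccupancyGrid:
    """Per-voxel occupancy of a selected species over the analysis window.

    ``species`` is a boolean atom mask or a dict of :meth:`Ensemble.select`
    criteria (e.g. ``{"polymer_class": "ion", "elements": "MG"}``). A voxel
    scores the fraction of frames in which at least one selected atom lies
    inside it. Frames are assumed already superposed (see
    :func:`superpose_and_rmsd`). The grid extent defaults to the selection's
    bounding box padded by one voxel.
    """
    idx = resolve_frames(ens, frames)
    if species is None:
        mask = np.ones(ens.n_atoms, dtype=bool)
    elif isinstance(species, dict):
        mask = ens.select(**species)
    else:
        mask = np.asarray(species, dtype=bool)
    if not mask.any():
        raise ValueError("empty species selection")

    pts = ens.coords[np.ix_(idx, np.flatnonzero(mask))]
    if origin is None:
        origin = pts.reshape(-1, 3).min(axis=0) - voxel_size
    origin = np.asarray(origin, dtype=float)
    if dims is None:
        upper = pts.reshape(-1, 3).max(axis=0) + voxel_size
        dims = tuple(np.ceil((upper - origin) / voxel_size).astype(int) + 1)

    values = np.zeros(dims, dtype=float)
    for f in range(len(idx)):
        vox = np.floor((pts[f] - origin) / voxel_size).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(dims)), axis=1)
        occupied = np.unique(vox[inside], axis=0)
        if occupied.size:
            values[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1.0
    values /= len(idx)
    return OccupancyGrid(origin, voxel_size, values)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def _backbone_selection(ens: Ensemble, ss: SSElementSet) -> np.ndarray:
    """Indices of N/CA/C/O atoms of SS residues, sorted; errors on gaps."""
    res_mask = ss.residue_mask(ens)
    sel = np.flatnonzero(
        res_mask
        & (ens.polymer_class == "protein")
        & np.isin(ens.atom_names, list(BACKBONE_ATOMS))
    )
    # verify completeness per residue
    missing = []
    residues = {(ens.chain_ids[i], ens.res_ids[i])
                for i in np.flatnonzero(res_mask & (ens.polymer_class == "protein"))}
    for chain, rid in sorted(residues):
        names = {str(ens.atom_names[i]) for i in sel
                 if ens.chain_ids[i] == chain and ens.res_ids[i] == rid}
        lack = set(BACKBONE_ATOMS) - names
        if lack:
            missing.append(f"{chain}:{rid} missing {sorted(lack)}")
    if missing:
        raise ValueError("incomplete backbone in SS selection: " + "; ".join(missing))
    return sel


def superpose_and_rmsd(
    ens: Ensemble,
    reference: int | np.ndarray = 0,
    ss: Optional[SSElementSet] = None,
    frames=None,
) -> tuple[np.ndarray, float]:
    """Backbone RMSD per frame after Kabsch superposition on SS elements.

    ``reference`` is a frame index or an (n_atoms, 3) coordinate array with
    the same atom ordering. When ``ss`` is given, both the superposition
    and the RMSD use only the N/CA/C/O atoms of those residues; otherwise
    all protein backbone atoms are used. Returns (per-frame RMSD in A,
    mean over the analysis window).
    """
    idx = resolve_frames(ens, frames)
    if ss is not None:
        sel = _backbone_selection(ens, ss)
    else:
        sel = np.flatnonzero(
            (ens.polymer_class == "protein")
            & np.isin(ens.atom_names, list(BACKBONE_ATOMS))
        )
    if sel.size < 3:
        raise ValueError("need at least 3 backbone atoms to superpose")

    if isinstance(reference, (int, np.integer)):
        ref = ens.coords[int(reference), sel]
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (ens.n_atoms, 3):
            raise ValueError("reference must be a frame index or (n_atoms, 3) array")
        ref = reference[sel]
    ref_centered = ref - ref.mean(axis=0)

    rmsds = np.empty(len(idx))
    for k, f in enumerate(idx):
        mob = ens.coords[f, sel]
        mob_centered = mob - mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob_centered)
        aligned = rot.apply(mob_centered)
        rmsds[k] = np.sqrt(np.mean(np.sum((aligned - ref_centered) ** 2, axis=1)))
    return rmsds, float(rmsds.mean())


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def sidechain_backbone_summary(
    records: Sequence[HBondRecord],
) -> tuple[float, dict[str, int]]:
    """Fraction of H-bonds via protein side chains, and per-residue tallies.

    The tally keys are ``chain:RESnumber`` of the protein partner.
    """
    if not records:
        raise ValueError("no H-bond records to summarize")
    side = sum(1 for r in records if r.via == "side chain")
    tallies: dict[str, int] = {}
    for r in records:
        prot = r.donor if r.donor_side == "protein" else r.acceptor
        key = f"{prot.chain_id}:{prot.res_name}{prot.res_id}"
        tallies[key] = tallies.get(key, 0) + 1
    return side / len(records), tallies
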