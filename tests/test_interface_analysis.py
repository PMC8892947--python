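import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rnpkit.interface_analysis import (
    detect_hbonds,
    detect_ion_bridges,
    detect_water_bridges,
    occupancy_grid,
    sidechain_backbone_summary,
    superpose_and_rmsd,
)
from rnpkit.seq_struct_io import SSElementSet
from rnpkit.synthetic_data import (
    PlantedEnsembleSpec,
    PlantedInteraction,
    build_planted_ensemble,
)
from conftest import make_ensemble

PAIR_ATOMS = [
    ("A", 1, "SER", "N", "N"),
    ("A", 1, "SER", "CA", "C"),
    ("A", 1, "SER", "CB", "C"),
    ("A", 1, "SER", "OG", "O"),
    ("B", 9, "U", "OP1", "O"),
    ("B", 9, "U", "P", "P"),
]


def pair_frames(distances):
    """Frames with the Ser OG at origin region and the U OP1 a given
    distance away along y, other atoms far from everything."""
    frames = []
    for d in distances:
        frames.append(
            [
                [-8.0, 5.0, 0.0],
                [-6.0, 3.0, 0.0],
                [-1.5, 0.0, 0.0],
                [0.0, 0.0, 0.0],     # OG
                [0.0, -d, 0.0],      # OP1
                [1.5, -d - 1.0, 0.0],
            ]
        )
    return np.array(frames)


class TestDetectHBonds:
    def test_static_pair_full_occupancy(self):
        ens = make_ensemble(PAIR_ATOMS, pair_frames([2.8, 2.8, 2.8]))
        (rec,) = detect_hbonds(ens, frames=range(3))
        assert rec.occupancy == 1.0
        assert rec.donor_side == "protein"
        assert rec.via == "side chain"
        assert str(rec.donor) == "A:SER1:OG"
        assert str(rec.acceptor) == "B:U9:OP1"

    def test_hand_counted_three_of_four_frames(self):
        ens = make_ensemble(PAIR_ATOMS, pair_frames([2.8, 2.9, 3.4, 2.7]))
        (rec,) = detect_hbonds(ens, frames=range(4))
        assert rec.occupancy == 0.75

    def test_outside_cutoff_no_record(self):
        ens = make_ensemble(PAIR_ATOMS, pair_frames([3.4]))
        assert detect_hbonds(ens, frames=[0], dist_cutoff=3.0) == []

    def test_angle_criterion_with_explicit_hydrogens(self):
        atoms = PAIR_ATOMS + [("A", 1, "SER", "HG", "H")]
        # linear O-H...O (angle 180): bond; H perpendicular (~90): none
        base = pair_frames([2.8])[0]
        linear = np.vstack([base, [[0.0, -0.95, 0.0]]])
        bent = np.vstack([base, [[0.95, 0.0, 0.0]]])
        ens = make_ensemble(atoms, np.array([linear, bent]))
        (rec,) = detect_hbonds(ens, frames=[0, 1], angle_cutoff=135.0,
                               min_occupancy=0.4)
        assert rec.occupancy == 0.5

    def test_backbone_classification(self):
        # RNA O2' donating to the protein backbone carbonyl O
        atoms = [
            ("A", 1, "GLY", "O", "O"),
            ("A", 1, "GLY", "C", "C"),
            ("B", 3, "U", "O2'", "O"),
        ]
        frames = [[[0.0, 0.0, 0.0], [0.0, 1.3, 0.0], [0.0, -2.8, 0.0]]]
        ens = make_ensemble(atoms, np.array(frames))
        (rec,) = detect_hbonds(ens, frames=[0])
        assert rec.via == "backbone"
        assert rec.donor_side == "rna"

    def test_empty_frame_range_rejected(self):
        ens = make_ensemble(PAIR_ATOMS, pair_frames([2.8]))
        with pytest.raises(ValueError, match="empty frame range"):
            detect_hbonds(ens, frames=[])


class TestDetectWaterBridges:
    def _bridge_atoms(self):
        return PAIR_ATOMS + [("W", 50, "HOH", "O", "O")]

    def test_constructed_bridge_full_occupancy(self):
        # water 2.7 A from Ser OG and 2.7 A from the phosphate OP1
        frames = pair_frames([5.4])
        water = np.array([[0.0, -2.7, 0.0]] * len(frames))[:, None, :]
        ens = make_ensemble(self._bridge_atoms(),
                            np.concatenate([frames, water], axis=1))
        (rec,) = detect_water_bridges(ens, frames=range(len(frames)))
        assert rec.occupancy == 1.0
        assert str(rec.protein_partner) == "A:SER1:OG"
        assert str(rec.rna_partner) == "B:U9:OP1"

    def test_one_sided_contact_no_bridge(self):
        frames = pair_frames([12.0])
        water = np.array([[0.0, -2.7, 0.0]])[None, :, :]  # near protein only
        ens = make_ensemble(self._bridge_atoms(),
                            np.concatenate([frames[:1], water], axis=1))
        assert detect_water_bridges(ens, frames=[0]) == []

    def test_no_waters_warns(self):
        ens = make_ensemble(PAIR_ATOMS, pair_frames([2.8]))
        with pytest.warns(UserWarning, match="no water"):
            assert detect_water_bridges(ens, frames=[0]) == []


class TestDetectIonBridges:
    def _ion_atoms(self, element):
        return PAIR_ATOMS + [("I", 70, element, element, element)]

    def test_permanent_mg_bridge(self):
        # Mg 2.0 A from the Ser OG and 2.1 A from the phosphate OP1
        frames = pair_frames([4.1, 4.1, 4.1])
        ion = np.array([[0.0, -2.0, 0.0]] * 3)[:, None, :]
        ens = make_ensemble(self._ion_atoms("MG"),
                            np.concatenate([frames, ion], axis=1))
        (rec,) = detect_ion_bridges(ens, frames=range(3))
        assert rec.occupancy == 1.0
        assert rec.partner_occupancies  # per-partner coordination reported

    def test_potassium_cutoff_sensitivity(self):
        frames = pair_frames([6.8])
        ion = np.array([[0.0, -3.4, 0.0]])[None, :, :]  # 3.4 A to each side
        ens = make_ensemble(self._ion_atoms("K"),
                            np.concatenate([frames[:1], ion], axis=1))
        assert len(detect_ion_bridges(ens, frames=[0])) == 1  # K cutoff 3.5
        assert detect_ion_bridges(ens, frames=[0], cutoffs={"K": 3.0}) == []

    def test_unknown_ion_element_rejected(self):
        frames = pair_frames([6.8])
        ion = np.array([[0.0, -3.4, 0.0]])[None, :, :]
        ens = make_ensemble(self._ion_atoms("NA"),
                            np.concatenate([frames[:1], ion], axis=1))
        with pytest.raises(ValueError, match="NA"):
            detect_ion_bridges(ens, frames=[0])


class TestPlantedOccupancies:
    def test_recovery_within_three_binomial_se(self):
        spec = PlantedEnsembleSpec(
            n_frames=1000,
            planted=(
                PlantedInteraction("hbond", 0.63),
                PlantedInteraction("water_bridge", 0.60),
                PlantedInteraction("ion_bridge", 0.40, element="MG"),
            ),
            seed=17,
        )
        ens, masks = build_planted_ensemble(spec)
        frames = range(ens.n_frames)
        detected = {
            "hbond_0": detect_hbonds(ens, frames)[0].occupancy,
            "water_bridge_1": detect_water_bridges(ens, frames)[0].occupancy,
            "ion_bridge_2": detect_ion_bridges(ens, frames)[0].occupancy,
        }
        for label, occ in detected.items():
            target = {"hbond_0": 0.63, "water_bridge_1": 0.60,
                      "ion_bridge_2": 0.40}[label]
            se = np.sqrt(target * (1 - target) / 1000)
            assert abs(occ - target) <= 3 * se
            # and exactly equal to the generator's realized mask
            assert occ == pytest.approx(masks[label].mean())

    def test_occupancy_invariant_under_frame_reordering(self):
        spec = PlantedEnsembleSpec(
            n_frames=80, planted=(PlantedInteraction("hbond", 0.5),), seed=3
        )
        ens, _ = build_planted_ensemble(spec)
        occ1 = detect_hbonds(ens, range(80), min_occupancy=0.0)[0].occupancy
        rng = np.random.default_rng(0)
        perm = rng.permutation(80)
        ens.coords = ens.coords[perm]
        occ2 = detect_hbonds(ens, range(80), min_occupancy=0.0)[0].occupancy
        assert occ1 == occ2

    def test_occupancy_invariant_under_rigid_motion(self):
        spec = PlantedEnsembleSpec(
            n_frames=50, planted=(PlantedInteraction("ion_bridge", 0.6),), seed=4
        )
        ens, _ = build_planted_ensemble(spec)
        occ1 = detect_ion_bridges(ens, range(50))[0].occupancy
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        ens.coords = ens.coords @ rot.T + np.array([5.0, -3.0, 12.0])
        occ2 = detect_ion_bridges(ens, range(50))[0].occupancy
        assert occ1 == occ2

    def test_bridge_implies_component_contacts(self):
        spec = PlantedEnsembleSpec(
            n_frames=60, planted=(PlantedInteraction("water_bridge", 0.7),), seed=5
        )
        ens, masks = build_planted_ensemble(spec)
        (rec,) = detect_water_bridges(ens, range(60))
        # in every ground-truth-present frame the water is within the H-bond
        # cutoff of both partners simultaneously
        w = np.flatnonzero(
            (ens.polymer_class == "water") & (ens.elements == "O")
        )[0]
        p = np.flatnonzero(ens.atom_names == "OG")[0]
        r = np.flatnonzero(ens.atom_names == "OP1")[0]
        for f in np.flatnonzero(masks["water_bridge_0"]):
            assert np.linalg.norm(ens.coords[f, w] - ens.coords[f, p]) <= 3.0
            assert np.linalg.norm(ens.coords[f, w] - ens.coords[f, r]) <= 3.0

    def test_empty_planted_list_gives_no_records(self):
        spec = PlantedEnsembleSpec(n_frames=20, planted=(), seed=6)
        ens, masks = build_planted_ensemble(spec)
        assert masks == {}
        assert detect_hbonds(ens, range(20)) == []
        with pytest.warns(UserWarning):
            assert detect_water_bridges(ens, range(20)) == []


class TestOccupancyGrid:
    def _single_atom(self, frames):
        return make_ensemble([("I", 1, "MG", "MG", "MG")],
                             np.asarray(frames, dtype=float))

    def test_stationary_atom_delta_site(self):
        ens = self._single_atom([[[5.0, 5.0, 5.0]]] * 4)
        grid = occupancy_grid(ens, frames=range(4), voxel_size=1.0)
        assert grid.values.max() == 1.0
        assert (grid.values > 0).sum() == 1

    def test_alternating_atom_half_occupancy(self):
        frames = [[[0.5, 0.5, 0.5]], [[4.5, 0.5, 0.5]]] * 3
        ens = self._single_atom(frames)
        grid = occupancy_grid(ens, frames=range(6), voxel_size=1.0)
        occupied = np.sort(grid.values[grid.values > 0])
        assert np.allclose(occupied, [0.5, 0.5])

    def test_counting_identity(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 8, size=(7, 1, 3))
        ens = self._single_atom(frames)
        grid = occupancy_grid(ens, frames=range(7), voxel_size=2.0)
        assert grid.values.max() <= 1.0
        counts = grid.values * 7
        assert np.allclose(counts, np.round(counts))

    def test_empty_selection_rejected(self):
        ens = self._single_atom([[[0.0, 0.0, 0.0]]])
        with pytest.raises(ValueError, match="empty species"):
            occupancy_grid(ens, frames=[0], species={"polymer_class": "water"})

    def test_dx_export(self, tmp_path):
        ens = self._single_atom([[[1.0, 2.0, 3.0]]] * 2)
        grid = occupancy_grid(ens, frames=range(2), voxel_size=1.0)
        out = tmp_path / "density.dx"
        grid.to_dx(out)
        text = out.read_text()
        assert "OpenDX" in text and "object 1" in text


def _helix_ensemble(n_frames, transform=None, noise=None, seed=0):
    """A 4-residue backbone-only chain annotated as one helix."""
    atoms = []
    coords = []
    rng = np.random.default_rng(seed)
    for i in range(4):
        for j, name in enumerate(("N", "CA", "C", "O")):
            atoms.append(("A", i + 1, "ALA", name, name[0]))
            coords.append([1.5 * (4 * i + j), (i % 2) * 1.1, 0.3 * j])
    base = np.array(coords)
    frames = []
    for f in range(n_frames):
        xyz = base.copy()
        if noise is not None:
            xyz = xyz + rng.normal(0, noise, xyz.shape)
        if transform is not None and f > 0:
            rot, trans = transform
            xyz = xyz @ rot.T + trans
        frames.append(xyz)
    return make_ensemble(atoms, np.array(frames)), SSElementSet(
        (("helix", "A", 1, 4),)
    )


class TestSuperposeRMSD:
    def test_identical_frames_zero_rmsd(self):
        ens, ss = _helix_ensemble(3)
        per_frame, mean = superpose_and_rmsd(ens, 0, ss, frames=range(3))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero_rmsd(self):
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.1]).as_matrix()
        ens, ss = _helix_ensemble(3, transform=(rot, np.array([3.0, -8.0, 2.0])))
        _pf, mean = superpose_and_rmsd(ens, 0, ss, frames=range(3))
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_kabsch_matches_numerical_optimum(self):
        # independent oracle: minimize RMSD over rotation vectors numerically
        ens, ss = _helix_ensemble(2, noise=0.4, seed=8)
        ref = ens.coords[0]
        mob = ens.coords[1]
        a = ref - ref.mean(axis=0)
        b = mob - mob.mean(axis=0)

        def rmsd_of(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((b @ r.T - a) ** 2, axis=1)))

        best = min(
            (minimize(rmsd_of, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
             for x0 in ([0.0, 0.0, 0.0], [1.0, -1.0, 0.5], [-2.0, 0.3, 2.0])),
            key=lambda s: s.fun,
        )
        per_frame, _mean = superpose_and_rmsd(ens, 0, ss, frames=[1])
        assert per_frame[0] == pytest.approx(best.fun, abs=1e-6)

    def test_missing_backbone_atoms_listed(self):
        ens, ss = _helix_ensemble(1)
        keep = ~((ens.res_ids == 2) & (ens.atom_names == "CA"))
        sub = make_ensemble(
            [
                (c, r, rn, an, el)
                for c, r, rn, an, el in zip(
                    ens.chain_ids, ens.res_ids, ens.res_names,
                    ens.atom_names, ens.elements,
                )
            ],
            ens.coords,
        )
        sub.atom_names = sub.atom_names[keep]
        sub.elements = sub.elements[keep]
        sub.res_names = sub.res_names[keep]
        sub.res_ids = sub.res_ids[keep]
        sub.chain_ids = sub.chain_ids[keep]
        sub.polymer_class = sub.polymer_class[keep]
        sub.coords = sub.coords[:, keep]
        with pytest.raises(ValueError, match="CA"):
            superpose_and_rmsd(sub, 0, ss, frames=[0])

    def test_default_window_is_last_quarter(self):
        ens, ss = _helix_ensemble(8)
        ens.coords[6:] += 2.0  # rigid shift: still zero after superposition
        per_frame, _ = superpose_and_rmsd(ens, 0, ss)
        assert len(per_frame) == 2


class TestSummary:
    def _records(self, n_side, n_back):
        spec = PlantedEnsembleSpec(
            n_frames=10,
            planted=tuple(
                PlantedInteraction("hbond", 1.0, via="side chain")
                for _ in range(n_side)
            )
            + tuple(
                PlantedInteraction("hbond", 1.0, via="backbone")
                for _ in range(n_back)
            ),
            seed=12,
        )
        ens, _ = build_planted_ensemble(spec)
        return detect_hbonds(ens, range(10))

    def test_seventy_percent_side_chain(self):
        records = self._records(7, 3)
        frac, tallies = sidechain_backbone_summary(records)
        assert frac == pytest.approx(0.7)
        assert sum(tallies.values()) == 10

    def test_all_backbone(self):
        frac, _ = sidechain_backbone_summary(self._records(0, 2))
        assert frac == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sidechain_backbone_summary([])
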