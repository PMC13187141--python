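"""PDB IO, linker span detection, octant metric, QC filter, cutoff."""

import dataclasses

import numpy as np
import pytest

from lbdtandem.linker_geometry import (
    Atom,
    CutoffResult,
    EmbeddingParams,
    EmbeddingProfile,
    LinkerSpan,
    PlacementSite,
    ResidueEmbedding,
    ResidueRec,
    StructureModel,
    compare_to_cutoff,
    filter_misplaced_models,
    find_linker,
    min_bivalent_linker,
    octant_counts,
    read_pdb,
    write_pdb,
)
from lbdtandem.synthetic_data import (
    StructureSimSpec,
    make_linker_structure,
)

from conftest import oracle_octant_count

CORE = "SESVNNDMIVTDNNGAVKFP"


def _point_model(ligand_points, ca=(0.0, 0.0, 0.0), model_id="m", rank=0):
    lig = tuple(
        ResidueRec(resseq=i + 1, resname="LIG",
                   atoms=(Atom(name="C", element="C", coord=tuple(p)),))
        for i, p in enumerate(ligand_points)
    )
    rec = (
        ResidueRec(resseq=1, resname="GLY",
                   atoms=(Atom(name="CA", element="C", coord=tuple(ca)),)),
    )
    return StructureModel(model_id=model_id, chains={"L": lig, "R": rec}, rank=rank)


class TestReadWritePdb:
    def test_round_trip_fixture(self, tmp_path):
        spec = StructureSimSpec(ligand_atom_count=150, ligand_shape="two-lobe",
                                linker_length=12, linker_mode="threading", seed=1)
        model, _ = make_linker_structure(spec)
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        back = read_pdb(path)
        assert len(back.ligand_heavy_coords()) == 150
        np.testing.assert_allclose(
            back.ligand_heavy_coords(), model.ligand_heavy_coords(), atol=1e-3
        )

    def test_missing_receptor_chain_names_found(self, tmp_path):
        spec = StructureSimSpec(ligand_atom_count=10, ligand_shape="slab",
                                linker_length=3, linker_mode="threading", seed=2)
        model, _ = make_linker_structure(spec)
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        with pytest.raises(ValueError, match="'Z'.*L.*R"):
            read_pdb(path, receptor_chain="Z")

    def test_hydrogens_excluded_from_heavy_set(self):
        model = _point_model([(1.0, 1.0, 1.0)])
        with_h = dataclasses.replace(
            model,
            chains={
                "L": (
                    ResidueRec(resseq=1, resname="LIG", atoms=(
                        Atom(name="C", element="C", coord=(1.0, 1.0, 1.0)),
                        Atom(name="H1", element="H", coord=(1.2, 1.0, 1.0)),
                    )),
                ),
                "R": model.chains["R"],
            },
        )
        assert len(with_h.ligand_heavy_coords()) == 1

    def test_waters_excluded(self):
        model = _point_model([(1.0, 1.0, 1.0)])
        with_water = dataclasses.replace(
            model,
            chains={
                "L": model.chains["L"] + (
                    ResidueRec(resseq=2, resname="HOH", atoms=(
                        Atom(name="O", element="O", coord=(2.0, 2.0, 2.0)),
                    )),
                ),
                "R": model.chains["R"],
            },
        )
        assert len(with_water.ligand_heavy_coords()) == 1


class TestFindLinker:
    def test_core_only_length_20(self):
        span = find_linker("MKAV" + CORE + "TRWE")
        assert span.length == 20

    def test_flanking_gs_extension(self):
        span = find_linker("AAGSGS" + CORE + "GSAA")
        assert span.length == 26

    def test_ambiguous_core_errors(self):
        with pytest.raises(ValueError, match="ambiguous"):
            find_linker(CORE + "AAA" + CORE)

    def test_absent_core_errors(self):
        with pytest.raises(ValueError, match="not found"):
            find_linker("MKAVTRWE" * 10)


class TestOctantCounts:
    def test_eight_corner_atoms_count_8(self):
        corners = [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        model = _point_model(corners)
        profile = octant_counts(model, LinkerSpan(0, 1))
        assert profile.residues[0].octant_count == 8
        assert profile.residues[0].embedded

    def test_atom_just_outside_radius(self):
        model = _point_model([(5.1, 0.0, 0.0)])
        profile = octant_counts(model, LinkerSpan(0, 1))
        assert profile.residues[0].octant_count == 0
        assert not profile.residues[0].embedded

    def test_atom_exactly_on_radius_inside(self):
        model = _point_model([(5.0, 0.0, 0.0)])
        profile = octant_counts(model, LinkerSpan(0, 1))
        assert profile.residues[0].octant_count == 1

    def test_five_octants_boundary_embedded(self):
        pts = [(1, 1, 1), (-1, 1, 1), (1, -1, 1), (1, 1, -1), (-1, -1, -1)]
        model = _point_model([tuple(float(x) for x in p) for p in pts])
        profile = octant_counts(model, LinkerSpan(0, 1))
        assert profile.residues[0].octant_count == 5
        assert profile.residues[0].embedded

    def test_plane_tie_assigned_positive(self):
        # one atom on the x=0 plane plus its mirrored twin: 2 distinct octants
        model = _point_model([(0.0, 1.0, 1.0), (-1.0, 1.0, 1.0)])
        profile = octant_counts(model, LinkerSpan(0, 1))
        assert profile.residues[0].octant_count == 2
        assert oracle_octant_count([(0.0, 1.0, 1.0), (-1.0, 1.0, 1.0)], (0, 0, 0)) == 2

    def test_translation_invariance_exact(self):
        spec = StructureSimSpec(ligand_atom_count=500, ligand_shape="slab",
                                linker_length=15, linker_mode="threading", seed=3)
        model, truth = make_linker_structure(spec)
        moved = model.translated((17.25, -3.5, 101.0))
        p0 = octant_counts(model, truth["span"])
        p1 = octant_counts(moved, truth["span"])
        assert [r.octant_count for r in p0.residues] == [r.octant_count for r in p1.residues]

    def test_radius_monotonicity(self, rng):
        lig = rng.normal(scale=4.0, size=(200, 3))
        model = _point_model(lig)
        prev = 0
        for radius in (1.0, 2.5, 5.0, 8.0, 12.0):
            profile = octant_counts(model, LinkerSpan(0, 1),
                                    EmbeddingParams(radius=radius))
            count = profile.residues[0].octant_count
            assert count >= prev
            prev = count

    def test_missing_ca_listed(self):
        model = _point_model([(1.0, 1.0, 1.0)])
        no_ca = dataclasses.replace(
            model,
            chains={
                "L": model.chains["L"],
                "R": (ResidueRec(resseq=1, resname="GLY", atoms=(
                    Atom(name="CB", element="C", coord=(0, 0, 0)),
                )),),
            },
        )
        with pytest.raises(ValueError, match="missing CA.*\\[1\\]"):
            octant_counts(no_ca, LinkerSpan(0, 1))

    def test_pca_frame_rotation_covariant(self, rng):
        from scipy.spatial.transform import Rotation
        from lbdtandem.linker_geometry import _rotate_model

        spec = StructureSimSpec(ligand_atom_count=300, ligand_shape="slab",
                                linker_length=10, linker_mode="threading", seed=4)
        model, truth = make_linker_structure(spec)
        params = EmbeddingParams(frame="pca")
        base = octant_counts(model, truth["span"], params)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        rotated = octant_counts(_rotate_model(model, rot), truth["span"], params)
        assert [r.octant_count for r in base.residues] == [
            r.octant_count for r in rotated.residues
        ]


class TestFilterMisplaced:
    def _docked_model(self, offset=0.0, model_id="m"):
        lig = tuple(
            ResidueRec(resseq=i + 1, resname="LIG", atoms=(
                Atom(name="C", element="C", coord=(float(i), 0.0, 0.0)),
            ))
            for i in range(5)
        )
        rec = tuple(
            ResidueRec(resseq=i + 1, resname="GLY", atoms=(
                Atom(name="CA", element="C", coord=(float(i), 2.0 + offset, 0.0)),
            ))
            for i in range(5)
        )
        return StructureModel(model_id=model_id, chains={"L": lig, "R": rec})

    def _site(self):
        return PlacementSite(lbd_name="lbd_in", receptor_start=1, receptor_end=5,
                             epitope=(("L", 1), ("L", 2)))

    def test_docked_model_kept(self):
        kept, excluded = filter_misplaced_models([self._docked_model()], [self._site()])
        assert len(kept) == 1 and not excluded

    def test_displaced_model_excluded_with_log(self):
        kept, excluded = filter_misplaced_models(
            [self._docked_model(offset=50.0, model_id="bad")], [self._site()]
        )
        assert not kept
        assert excluded[0].model_id == "bad"
        assert excluded[0].lbd_name == "lbd_in"
        assert excluded[0].min_distance > 8.0

    def test_empty_model_list(self):
        kept, excluded = filter_misplaced_models([], [self._site()])
        assert kept == [] and excluded == []

    def test_spec_referencing_absent_residue_errors(self):
        site = PlacementSite(lbd_name="x", receptor_start=1, receptor_end=5,
                             epitope=(("L", 99),))
        with pytest.raises(ValueError, match="99"):
            filter_misplaced_models([self._docked_model()], [site])


def _profile(length, rank, n_embedded):
    residues = tuple(
        ResidueEmbedding(resseq=i + 1, octant_count=8 if i < n_embedded else 0,
                         embedded=i < n_embedded)
        for i in range(length)
    )
    return EmbeddingProfile(model_id=f"L{length}r{rank}", rank=rank,
                            linker_length=length, residues=residues)


class TestMinBivalentLinker:
    def test_series_reaching_zero_at_36(self):
        profiles = {}
        for length in (20, 24, 28, 32, 36, 40):
            n = 0 if length >= 36 else 3
            profiles[length] = [_profile(length, r, n) for r in range(3)]
        result = min_bivalent_linker(profiles, top_n=3)
        assert result.length == 36

    def test_all_non_embedded_returns_smallest(self):
        profiles = {length: [_profile(length, r, 0) for r in range(3)]
                    for length in (28, 20, 36)}
        assert min_bivalent_linker(profiles).length == 20

    def test_no_qualifying_length_absent(self):
        profiles = {length: [_profile(length, r, 1) for r in range(3)]
                    for length in (20, 30)}
        result = min_bivalent_linker(profiles)
        assert result.length is None
        assert "absent" in result.status

    def test_underpopulated_length_skipped_with_warning(self):
        profiles = {
            20: [_profile(20, 0, 0)],  # only 1 model: skipped even though clean
            30: [_profile(30, r, 0) for r in range(3)],
        }
        result = min_bivalent_linker(profiles, top_n=3)
        assert result.length == 30
        assert any("length 20" in w for w in result.warnings)

    def test_rank_order_respected_beyond_top_n(self):
        profiles = {
            40: [_profile(40, 0, 0), _profile(40, 1, 0), _profile(40, 2, 0),
                 _profile(40, 3, 5)],  # rank 4 embedded but outside top 3
        }
        assert min_bivalent_linker(profiles, top_n=3).length == 40

    def test_random_constructed_series_recover_answer(self, rng):
        for trial in range(50):
            lengths = sorted(rng.choice(np.arange(10, 60, 2), size=6, replace=False))
            answer_idx = int(rng.integers(0, 6))
            profiles = {}
            for i, length in enumerate(lengths):
                n = 0 if i >= answer_idx else int(rng.integers(1, 4))
                profiles[int(length)] = [_profile(int(length), r, n) for r in range(3)]
            result = min_bivalent_linker(profiles, top_n=3)
            assert result.length == int(lengths[answer_idx])


class TestCompareToCutoff:
    def test_44_feasible_20_not(self):
        table = compare_to_cutoff({"herring_like": 44, "human_like": 20}, cutoff=36)
        feasible = dict(zip(table["species"], table["bivalency_feasible"]))
        assert feasible == {"herring_like": True, "human_like": False}

    def test_equal_to_cutoff_feasible(self):
        table = compare_to_cutoff({"edge": 36}, cutoff=36)
        assert bool(table["bivalency_feasible"][0]) is True

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            compare_to_cutoff({"bad": -1}, cutoff=36)
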