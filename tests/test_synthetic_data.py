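"""Tests for the synthetic generators: limits, recovery, truth labels."""

import numpy as np
import pytest

from lbdtandem.linker_geometry import octant_counts, write_pdb
from lbdtandem.molclock import GammaModel, jtt_distance
from lbdtandem.seqio_domains import write_fasta
from lbdtandem.synthetic_data import (
    CladeSimSpec,
    GenerationError,
    StructureSimSpec,
    make_gene_model,
    make_linker_structure,
    simulate_clade,
)

from conftest import oracle_octant_count


def _spec(**kw):
    defaults = dict(
        n_taxa=3,
        divergence_times=(50.0, 100.0),
        r_true=0.001,
        seq_length=200,
        gamma_alpha=1.0,
        seed=0,
    )
    defaults.update(kw)
    return CladeSimSpec(**defaults)


class TestCladeSim:
    def test_zero_rate_all_identical(self):
        sim = simulate_clade(_spec(r_true=0.0))
        seqs = {r.sequence for r in sim.records}
        assert len(seqs) == 1

    def test_zero_duplication_identical_copies(self):
        sim = simulate_clade(_spec(d_dup_true=0.0))
        assert sim.dup_records[0].sequence == sim.dup_records[1].sequence

    def test_validation_names_field(self):
        with pytest.raises(ValueError, match="r_true"):
            _spec(r_true=-1)
        with pytest.raises(ValueError, match="seq_length"):
            _spec(seq_length=0)
        with pytest.raises(ValueError, match="divergence_times"):
            _spec(divergence_times=(50.0, -1.0))
        with pytest.raises(ValueError, match="gamma_alpha"):
            _spec(gamma_alpha=0.0)
        with pytest.raises(ValueError, match="dup_taxon"):
            _spec(dup_taxon="nope", d_dup_true=0.1)

    def test_divergence_table_is_additive(self):
        sim = simulate_clade(_spec())
        table = sim.divergence_table.set_index(["taxon_a", "taxon_b"])["time_mya"]
        assert table[("t0", "t1")] == 50.0
        assert table[("t0", "t2")] == 100.0
        assert table[("t1", "t2")] == 150.0

    def test_truth_records_expected_path_lengths(self):
        sim = simulate_clade(_spec(r_true=0.002))
        expected = sim.truth["expected_path_lengths"]
        assert expected[("t0", "t1")] == pytest.approx(0.1)
        assert expected[("t1", "t2")] == pytest.approx(0.3)

    def test_mean_distance_unbiased_monte_carlo(self):
        # r=0.001, T=100 -> true path 0.1; mean estimate within +/-15%
        gamma = GammaModel(alpha=1.0, k=4)
        estimates = []
        for rep in range(20):
            sim = simulate_clade(
                _spec(n_taxa=2, divergence_times=(100.0,), seq_length=10_000,
                      seed=900 + rep)
            )
            a, b = sim.records[0].sequence, sim.records[1].sequence
            estimates.append(jtt_distance(a, b, gamma).d)
        mean = float(np.mean(estimates))
        assert 0.085 <= mean <= 0.115

    def test_same_seed_byte_identical(self, tmp_path):
        paths = []
        for run in ("x", "y"):
            sim = simulate_clade(_spec(d_dup_true=0.3, seed=5))
            fasta = tmp_path / f"{run}.fa"
            write_fasta(sim.records + sim.dup_records, fasta)
            tsv = tmp_path / f"{run}.tsv"
            sim.divergence_table.to_csv(tsv, sep="\t", index=False)
            paths.append((fasta.read_bytes(), tsv.read_bytes()))
        assert paths[0] == paths[1]


class TestLinkerStructure:
    def test_wrapping_outside_shell_zero_embedded(self):
        spec = StructureSimSpec(
            ligand_atom_count=500, ligand_shape="shell", linker_length=40,
            linker_mode="wrapping", shell_radius=20.0, wrap_radius=30.0, seed=1,
        )
        model, truth = make_linker_structure(spec)
        assert truth["n_embedded"] == 0
        assert all(c == 0 for c in truth["octant_counts"])

    def test_threading_dense_slab_hits_count_8(self):
        spec = StructureSimSpec(
            ligand_atom_count=3000, ligand_shape="slab", linker_length=21,
            linker_mode="threading", seed=2,
        )
        model, truth = make_linker_structure(spec)
        assert max(truth["octant_counts"]) == 8
        assert truth["n_embedded"] >= 1

    def test_zero_atoms_all_zero(self):
        spec = StructureSimSpec(
            ligand_atom_count=0, ligand_shape="slab", linker_length=10,
            linker_mode="threading", seed=3,
        )
        model, truth = make_linker_structure(spec)
        assert truth["octant_counts"] == [0] * 10

    def test_wrapping_through_hull_raises(self):
        spec = StructureSimSpec(
            ligand_atom_count=500, ligand_shape="shell", linker_length=30,
            linker_mode="wrapping", shell_radius=20.0, wrap_radius=10.0, seed=4,
        )
        with pytest.raises(GenerationError):
            make_linker_structure(spec)

    @pytest.mark.parametrize("shape,mode", [
        ("slab", "threading"), ("two-lobe", "threading"), ("shell", "wrapping"),
    ])
    def test_truth_matches_independent_oracle(self, shape, mode):
        spec = StructureSimSpec(
            ligand_atom_count=400, ligand_shape=shape, linker_length=15,
            linker_mode=mode, seed=11,
        )
        model, truth = make_linker_structure(spec)
        ligand = model.ligand_heavy_coords()
        cas = [res.ca.coord for res in model.receptor_residues()]
        assert truth["octant_counts"] == [
            oracle_octant_count(ligand, ca) for ca in cas
        ]

    def test_truth_matches_vectorized_classifier(self):
        spec = StructureSimSpec(
            ligand_atom_count=800, ligand_shape="slab", linker_length=25,
            linker_mode="threading", seed=12,
        )
        model, truth = make_linker_structure(spec)
        profile = octant_counts(model, truth["span"])
        assert [r.octant_count for r in profile.residues] == truth["octant_counts"]
        assert [r.embedded for r in profile.residues] == truth["embedded"]

    def test_same_seed_byte_identical_pdb(self, tmp_path):
        blobs = []
        for run in ("x", "y"):
            spec = StructureSimSpec(
                ligand_atom_count=100, ligand_shape="two-lobe", linker_length=8,
                linker_mode="threading", seed=21,
            )
            model, _ = make_linker_structure(spec)
            path = tmp_path / f"{run}.pdb"
            write_pdb(model, path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_validation(self):
        with pytest.raises(ValueError, match="linker_length"):
            StructureSimSpec(ligand_atom_count=10, ligand_shape="slab",
                             linker_length=0, linker_mode="threading")
        with pytest.raises(ValueError, match="ligand_shape"):
            StructureSimSpec(ligand_atom_count=10, ligand_shape="cube",
                             linker_length=5, linker_mode="threading")
        with pytest.raises(ValueError, match="ca_spacing"):
            StructureSimSpec(ligand_atom_count=10, ligand_shape="slab",
                             linker_length=5, linker_mode="threading", ca_spacing=0)


class TestGeneModel:
    def test_linker_zero_domains_adjacent(self):
        fixture = make_gene_model(two_lbd=True, linker_len=0, seed=1)
        (s1, e1), (s2, e2) = fixture.domain_bounds
        assert s2 == e1
        assert fixture.expected_linker_length == 0

    def test_translation_consistency_is_enforced(self):
        fixture = make_gene_model(two_lbd=True, linker_len=20, seed=2)
        # constructor validates translated CDS == protein; spot-check layout
        assert fixture.protein.count(
            fixture.protein[slice(*fixture.domain_bounds[0])]
        ) == 2

    def test_single_domain_no_linker(self):
        fixture = make_gene_model(two_lbd=False, linker_len=20, seed=3)
        assert len(fixture.domain_bounds) == 1
        assert fixture.expected_linker_length is None

    def test_exon_pair_duplication_present(self):
        fixture = make_gene_model(two_lbd=True, linker_len=10, seed=4)
        names = [e.name for e in fixture.exons]
        assert "E2p" in names and "E3p" in names

    def test_negative_linker_rejected(self):
        with pytest.raises(ValueError, match="linker_len"):
            make_gene_model(two_lbd=True, linker_len=-1)
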