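"""Interface featurization: SASA, burial, salt bridges, beta-pairing, dihedrals."""

import numpy as np
import pytest

from elfscan import geometry as geo
from elfscan.structure import (
    AtomRecord,
    StructureModel,
    backbone_dihedrals,
    delta_sasa_insertion,
    detect_interchain_beta_pairs,
    detect_salt_bridges,
    hydrophobicity_map,
    interface_report,
    parse_structure,
    ramachandran_class,
    sasa,
)
from elfscan.synthetic import gen_complex_fixture, to_gemmi, write_fixture


def _atom(name, element, xyz, chain="A", seq=1, res="ALA"):
    return AtomRecord(chain, seq, res, name, element, np.array(xyz, float))


class TestSasa:
    def test_single_atom_closed_form(self):
        model = StructureModel([_atom("CA", "C", [0, 0, 0])])
        area = sasa(model)[("A", 1, "CA")]
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_additive(self):
        model = StructureModel([_atom("CA", "C", [0, 0, 0]),
                                _atom("CA", "C", [50, 0, 0], seq=2)])
        total = sum(sasa(model).values())
        expected = 2 * 4 * np.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)

    def test_overlapping_pair_matches_denser_oracle(self):
        model = StructureModel([_atom("CA", "C", [0, 0, 0]),
                                _atom("N", "N", [1.5, 0, 0], seq=2)])
        total = sum(sasa(model, n_points=960).values())
        oracle = sum(sasa(model, n_points=9600).values())
        assert total == pytest.approx(oracle, rel=0.02)

    def test_convergence_on_peptide(self):
        chain = geo.build_chain(["ALA", "PHE", "GLY"], [geo.BETA_PHI_PSI] * 3)
        from elfscan.structure import model_from_geometry
        model = model_from_geometry({"A": chain})
        t1 = sum(sasa(model, n_points=960).values())
        t2 = sum(sasa(model, n_points=1920).values())
        assert abs(t1 - t2) / t2 < 0.01

    def test_unknown_element_warns_and_uses_default(self):
        model = StructureModel([_atom("QQ", "ZZ", [0, 0, 0])])
        with pytest.warns(UserWarning, match="unknown element"):
            area = sasa(model)[("A", 1, "QQ")]
        assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_probe_radius_respected(self):
        model = StructureModel([_atom("CA", "C", [0, 0, 0])])
        area = sasa(model, probe=0.0)[("A", 1, "CA")]
        assert area == pytest.approx(4 * np.pi * 1.70 ** 2, rel=0.01)


class TestBurial:
    def test_planted_phe_in_cage_is_inserted(self):
        fx = gen_complex_fixture(("insertion",), seed=4)
        res_seq = fx.truth.planted["insertions"][0]["inserted"]
        result = delta_sasa_insertion(fx.model, "B", "A", res_seq)
        assert result.inserted
        assert result.relative_burial >= 0.7
        assert result.sasa_complex <= result.sasa_isolated + 1e-6

    def test_no_receptor_means_no_burial(self):
        chain = geo.build_chain(["GLY", "PHE", "GLY"], [geo.EXTENDED_PHI_PSI] * 3)
        from elfscan.structure import model_from_geometry
        model = model_from_geometry({"B": chain})
        result = delta_sasa_insertion(model, "B", "A", 2)
        assert result.relative_burial == pytest.approx(0.0, abs=1e-9)
        assert not result.inserted

    def test_residue_far_from_interface_not_buried(self):
        fx = gen_complex_fixture(("separated",), seed=0)
        client_res = fx.model.residues("B")[0].res_seq
        result = delta_sasa_insertion(fx.model, "B", "A", client_res)
        assert result.relative_burial == pytest.approx(0.0, abs=0.02)

    def test_glycine_uses_ca_proxy_with_flag(self):
        chain = geo.build_chain(["ALA", "GLY", "ALA"], [geo.EXTENDED_PHI_PSI] * 3)
        from elfscan.structure import model_from_geometry
        model = model_from_geometry({"B": chain})
        with pytest.warns(UserWarning, match="no side chain"):
            result = delta_sasa_insertion(model, "B", "A", 2)
        assert result.ca_proxy


class TestSaltBridges:
    def test_planted_side_chain_bridge_found(self):
        fx = gen_complex_fixture(("salt_bridge",), seed=6)
        bridges = detect_salt_bridges(fx.model, "A", "B")
        truth = fx.truth.planted["salt_bridges"][0]
        assert len(bridges) == 1
        b = bridges[0]
        assert b.kind == "side-chain"
        assert b.basic[1] == truth["basic"]
        assert b.partner[1] == truth["partner"]
        assert b.min_distance == pytest.approx(truth["distance"], abs=0.05)

    def test_planted_backbone_bridge_found(self):
        fx = gen_complex_fixture(("backbone_bridge",), seed=6)
        bridges = detect_salt_bridges(fx.model, "A", "B")
        assert len(bridges) == 1
        assert bridges[0].kind == "backbone-oxygen"
        assert bridges[0].partner_atom == "O"

    def test_beyond_cutoff_not_reported(self):
        fx = gen_complex_fixture(("salt_bridge",), seed=6, n_o_distance=6.0)
        assert detect_salt_bridges(fx.model, "A", "B") == []

    def test_symmetric_in_chain_order(self, full_fixture):
        fwd = detect_salt_bridges(full_fixture.model, "A", "B")
        rev = detect_salt_bridges(full_fixture.model, "B", "A")
        assert {(b.basic, b.partner, b.kind) for b in fwd} == \
               {(b.basic, b.partner, b.kind) for b in rev}

    def test_isometry_invariance(self, full_fixture, rng):
        base = [(b.basic, b.partner, b.kind) for b in
                detect_salt_bridges(full_fixture.model, "A", "B")]
        for _ in range(5):
            moved = full_fixture.model.transformed(
                geo.random_rotation(rng), rng.uniform(-30, 30, 3))
            got = [(b.basic, b.partner, b.kind) for b in
                   detect_salt_bridges(moved, "A", "B")]
            assert got == base


class TestBetaPairing:
    def test_planted_antiparallel_ladder_registry(self):
        fx = gen_complex_fixture(("beta_ladder",), seed=8)
        pairs = detect_interchain_beta_pairs(fx.model, "A", "B")
        assert len(pairs) == 1
        p = pairs[0]
        assert p.orientation == "antiparallel"
        got = [(a[1], b[1]) for a, b in p.registry]
        assert got == [tuple(x) for x in fx.truth.planted["beta"][0]["registry"]]

    def test_helix_contact_yields_no_pairing(self):
        fx = gen_complex_fixture(("helix_contact",), seed=2)
        assert detect_interchain_beta_pairs(fx.model, "A", "B") == []

    def test_same_chain_returns_empty(self, full_fixture):
        assert detect_interchain_beta_pairs(full_fixture.model, "A", "A") == []

    def test_isometry_invariance(self, rng):
        fx = gen_complex_fixture(("beta_ladder",), seed=5)
        base = [p.registry for p in detect_interchain_beta_pairs(fx.model, "A", "B")]
        for _ in range(5):
            moved = fx.model.transformed(geo.random_rotation(rng),
                                         rng.uniform(-30, 30, 3))
            got = [p.registry for p in detect_interchain_beta_pairs(moved, "A", "B")]
            assert got == base


class TestHydrophobicity:
    @pytest.mark.parametrize("res,value", [("ILE", 4.5), ("ARG", -4.5), ("GLY", -0.4)])
    def test_scale_values(self, res, value):
        model = StructureModel([_atom("CA", "C", [0, 0, 0], res=res)])
        assert hydrophobicity_map(model, "A")[1] == value

    def test_nonstandard_residue_neutral_with_warning(self):
        model = StructureModel([_atom("CA", "C", [0, 0, 0], res="XYZ")])
        with pytest.warns(UserWarning, match="non-standard"):
            assert hydrophobicity_map(model, "A")[1] == 0.0


class TestRamachandran:
    @pytest.mark.parametrize("phi,psi,cls,expected", [
        (-63, -43, "general", "favored"),   # alpha region
        (-139, 135, "general", "favored"),  # beta region
        (75, 5, "general", "outlier"),      # mirror-alpha: forbidden w/ side chain
    ])
    def test_general_regions(self, phi, psi, cls, expected):
        assert ramachandran_class(phi, psi, cls) == expected

    def test_glycine_opens_mirror_alpha(self):
        # glycine lacks a side chain and reaches conformations others cannot
        assert ramachandran_class(75, 5, "glycine") in ("favored", "allowed")

    def test_angle_normalization(self):
        assert ramachandran_class(-63 + 360, -43 - 360, "general") == "favored"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ramachandran_class(0, 0, "nonsense")

    def test_built_helix_classified_favored(self):
        chain = geo.build_chain(["ALA"] * 6, [geo.ALPHA_PHI_PSI] * 6)
        from elfscan.structure import model_from_geometry
        model = model_from_geometry({"A": chain})
        for res_seq, (phi, psi) in backbone_dihedrals(model, "A").items():
            if phi is not None and psi is not None:
                assert ramachandran_class(phi, psi) == "favored"


class TestParsing:
    def test_pdb_and_cif_give_identical_models(self, full_fixture, tmp_path):
        paths = write_fixture(full_fixture, tmp_path, stem="fx")
        mp = parse_structure(paths["pdb"])
        mc = parse_structure(paths["cif"])
        assert len(mp.atoms()) == len(mc.atoms())
        for x, y in zip(mp.atoms(), mc.atoms()):
            assert x.key == y.key
            assert x.res_name == y.res_name
            assert np.allclose(x.xyz, y.xyz, atol=1e-3)
            assert x.confidence == pytest.approx(y.confidence, abs=1e-6)

    def test_confidence_read_from_bfactor(self, tmp_path):
        fx = gen_complex_fixture(("salt_bridge",), seed=0, plddt=55.5)
        paths = write_fixture(fx, tmp_path, stem="lowconf", formats=("pdb",))
        model = parse_structure(paths["pdb"])
        assert model.residues("A")[0].confidence == pytest.approx(55.5, abs=0.01)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            parse_structure(bad)

    def test_zero_coordinate_atom_flagged(self, tmp_path):
        chain = geo.build_chain(["ALA"], [geo.EXTENDED_PHI_PSI])
        chain[0].atoms["N"] = np.zeros(3)
        paths_model = to_gemmi({"A": chain})
        p = tmp_path / "zero.pdb"
        paths_model.write_pdb(str(p))
        model = parse_structure(p)
        flagged = [a for a in model.atoms() if a.flagged]
        assert [a.atom_name for a in flagged] == ["N"]


class TestInterfaceReport:
    def test_planted_features_all_reported(self, full_fixture):
        report = interface_report(full_fixture.model, "B", "A", n_points=480)
        truth = full_fixture.truth.planted
        assert len(report.salt_bridges) == len(truth["salt_bridges"])
        assert len(report.beta_pairings) == len(truth["beta"])
        inserted = [b for b in report.burials if b.inserted]
        assert [b.res_seq for b in inserted] == \
               [t["inserted"] for t in truth["insertions"]]

    def test_distant_chains_empty_report(self):
        fx = gen_complex_fixture(("separated",), seed=1)
        report = interface_report(fx.model, "B", "A", n_points=480)
        assert report.burials == []
        assert report.salt_bridges == []
        assert report.beta_pairings == []

    def test_low_confidence_flags(self):
        fx = gen_complex_fixture(("salt_bridge",), seed=1, plddt=40.0)
        report = interface_report(fx.model, "B", "A", n_points=480)
        assert len(report.low_confidence_flags) == \
               len(fx.model.residues("A")) + len(fx.model.residues("B"))

    def test_conservation_overlay(self, full_fixture):
        track = np.linspace(0, 1, 500)
        report = interface_report(full_fixture.model, "B", "A",
                                  conservation=track, n_points=480)
        for res_seq, score in report.conservation.items():
            assert score == pytest.approx(track[res_seq - 1])

    def test_missing_chain_rejected(self, full_fixture):
        with pytest.raises(ValueError):
            interface_report(full_fixture.model, "Z", "A")

    def test_json_serializable(self, full_fixture, tmp_path):
        import json
        report = interface_report(full_fixture.model, "B", "A", n_points=480)
        out = tmp_path / "report.json"
        report.to_json(out)
        loaded = json.loads(out.read_text())
        assert loaded["client_chain"] == "B"
        assert len(loaded["salt_bridges"]) == len(report.salt_bridges)
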