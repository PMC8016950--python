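"""SASA, buried-surface and hydrogen-bond analysis against analytic oracles."""

import math

import numpy as np
import pytest

from graftkit.interface import (SasaParams, buried_surface, contact_table,
                                hydrogen_bonds, shrake_rupley_sasa,
                                sphere_points)
from graftkit.structures import Atom, Residue, StructureModel
from graftkit.synth import SphereSystemSpec, analytic_pair_sasa, make_sphere_system

CARBON = SasaParams(radii_set={"C": 1.7}, points_per_atom=960)


def _pair_model(d):
    model, analytic = make_sphere_system(SphereSystemSpec(
        radii=(1.7, 1.7), centers=((0, 0, 0), (d, 0, 0)), element="C"))
    return model, analytic


def test_isolated_sphere_matches_closed_form():
    model, analytic = make_sphere_system(SphereSystemSpec(
        radii=(1.7,), centers=((0, 0, 0),), element="C"))
    _, per_res = shrake_rupley_sasa(model, ["A"], CARBON)
    value = per_res[("A", "1", "SPH")]
    assert analytic[0] == pytest.approx(4 * math.pi * 3.1 ** 2)
    assert value == pytest.approx(analytic[0], rel=1e-6)


def test_distant_spheres_fully_exposed():
    model, analytic = _pair_model(10.0)
    _, per_res = shrake_rupley_sasa(model, ["A"], CARBON)
    for i, k in enumerate(sorted(per_res)):
        assert per_res[k] == pytest.approx(analytic[i], rel=1e-6)


@pytest.mark.parametrize("d", [2.0, 3.0, 4.5, 5.8])
def test_overlapping_spheres_within_one_percent(d):
    """Sphere-point sampling vs the spherical-cap closed form at 960 points."""
    model, analytic = _pair_model(d)
    _, per_res = shrake_rupley_sasa(model, ["A"], CARBON)
    for i, k in enumerate(sorted(per_res)):
        assert abs(per_res[k] - analytic[i]) / analytic[i] < 0.01


def test_touching_spheres_boundary_case():
    # exactly at contact distance of the inflated spheres: nothing buried
    d = 2 * (1.7 + 1.4)
    model, analytic = _pair_model(d)
    _, per_res = shrake_rupley_sasa(model, ["A"], CARBON)
    full = 4 * math.pi * 3.1 ** 2
    for k in per_res:
        assert per_res[k] == pytest.approx(full, rel=1e-6)


def test_unknown_element_raises_naming_atom():
    res = Residue("UNK", 1, "", {"ZZ": Atom("ZZ", "ZZ", [0, 0, 0])})
    model = StructureModel(chains=[("A", [res])])
    with pytest.raises(KeyError, match="ZZ"):
        shrake_rupley_sasa(model, ["A"], SasaParams())


def test_sphere_point_set_is_deterministic_and_unit():
    pts = sphere_points(960)
    assert pts.shape == (960, 3)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, sphere_points(960))


def test_separated_parts_bury_nothing():
    a = Residue("GLY", 1, "", {"CA": Atom("CA", "C", [0, 0, 0])})
    b = Residue("GLY", 1, "", {"CA": Atom("CA", "C", [50, 0, 0])})
    model = StructureModel(chains=[("A", [a]), ("B", [b])])
    report = buried_surface(model, ["A"], ["B"], SasaParams(points_per_atom=240))
    assert report.buried_b == pytest.approx(0.0, abs=1e-9)
    assert report.buried_fraction == pytest.approx(0.0)


def test_empty_selection_raises(toy_complex):
    with pytest.raises(ValueError):
        buried_surface(toy_complex["model"], [], ["P"])
    with pytest.raises(ValueError):
        buried_surface(toy_complex["model"], ["H"], ["H"])


def test_sasa_monotone_under_rigid_approach():
    """Total SASA decreases as two rigid parts approach."""
    params = SasaParams(points_per_atom=240)
    totals = []
    for d in (20.0, 10.0, 6.0, 4.0):
        a = Residue("GLY", 1, "", {"CA": Atom("CA", "C", [0, 0, 0]),
                                   "C": Atom("C", "C", [1.5, 0, 0])})
        b = Residue("GLY", 1, "", {"CA": Atom("CA", "C", [d, 0, 0]),
                                   "C": Atom("C", "C", [d + 1.5, 0, 0])})
        model = StructureModel(chains=[("A", [a]), ("B", [b])])
        _, per_res = shrake_rupley_sasa(model, ["A", "B"], params)
        totals.append(sum(per_res.values()))
    assert totals == sorted(totals, reverse=True)


def test_bsa_symmetry(toy_complex):
    """Area buried on each side of an interface is (approximately) equal."""
    from graftkit.synth import make_backbone_chain
    # mirror-symmetric interface: chain B is chain A reflected through the
    # plane z = 2.5, so buried areas must match up to point-sampling error
    a_res = make_backbone_chain("AGAGAGA", phi=-120, psi=130)
    b_res = make_backbone_chain("AGAGAGA", phi=-120, psi=130)
    for res in b_res:
        for at in res.atoms.values():
            at.xyz = at.xyz * np.array([1.0, 1.0, -1.0]) + np.array([0, 0, 5.0])
    model = StructureModel(chains=[("A", a_res), ("B", b_res)])
    report = buried_surface(model, ["A"], ["B"], SasaParams(points_per_atom=960))
    assert report.buried_b > 0
    assert report.buried_a == pytest.approx(report.buried_b, rel=0.02)
    # the asymmetric toy complex still balances within a loose factor
    toy_report = buried_surface(toy_complex["model"], ["H", "L"], ["P"],
                                SasaParams(points_per_atom=480))
    assert toy_report.buried_a == pytest.approx(toy_report.buried_b, rel=0.5)


def test_point_density_convergence(toy_complex):
    """Doubling points/atom moves the peptide SASA by < 0.5%."""
    model = toy_complex["model"]
    r1 = buried_surface(model, ["H", "L"], ["P"], SasaParams(points_per_atom=480))
    r2 = buried_surface(model, ["H", "L"], ["P"], SasaParams(points_per_atom=960))
    assert abs(r1.total_sasa_b_free - r2.total_sasa_b_free) / r2.total_sasa_b_free < 0.005


def test_buried_fraction_identity(toy_complex):
    report = buried_surface(toy_complex["model"], ["H", "L"], ["P"],
                            SasaParams(points_per_atom=240))
    assert report.buried_fraction == pytest.approx(
        100.0 * report.buried_b / report.total_sasa_b_free)
    assert report.buried_b <= report.total_sasa_b_free


def test_distant_polar_pair_is_not_a_bond():
    a = Residue("SER", 1, "", {"OG": Atom("OG", "O", [0, 0, 0])})
    b = Residue("ASN", 1, "", {"ND2": Atom("ND2", "N", [4.5, 0, 0])})
    model = StructureModel(chains=[("A", [a]), ("B", [b])])
    hb = hydrogen_bonds(model, ["A"], ["B"])
    assert hb["direct"] == [] and hb["water_mediated"] == []


def test_planted_hydrogen_bonds_detected(toy_complex):
    hb = hydrogen_bonds(toy_complex["model"], ["H", "L"], ["P"])
    direct_pairs = {(b["a"][0], b["a"][1]) for b in hb["direct"]}
    want_res, _ = toy_complex["hbond_direct"]
    assert want_res in direct_pairs
    assert len(hb["water_mediated"]) >= 1
    bridge = hb["water_mediated"][0]
    sides_a = {k[:2] for k, _ in bridge["a"]}
    assert toy_complex["water_bridge"][0] in sides_a


def test_contact_table_threshold_and_annotation(toy_complex):
    report = buried_surface(toy_complex["model"], ["H", "L"], ["P"],
                            SasaParams(points_per_atom=480))
    hb = hydrogen_bonds(toy_complex["model"], ["H", "L"], ["P"])
    table = contact_table(report, 1.0, hb)
    assert table, "interface must produce contacts"
    assert all(r.bsa > 1.0 for r in table)
    assert all(r.polarity in ("hydrophobic", "polar") for r in table)
    # above the maximum BSA the table empties
    top = max(r.bsa for r in table)
    assert contact_table(report, top + 1.0, hb) == []
    # records sorted by chain then position
    order = [(r.chain, int("".join(c for c in r.seqid if c.isdigit()))) for r in table]
    assert order == sorted(order)


def test_against_independent_library_implementation(toy_complex):
    """Cross-check per-atom SASA against biotite on the toy peptide."""
    biotite_struc = pytest.importorskip("biotite.structure")
    model = toy_complex["model"]
    chains = {"P": model.chain("P")}
    atoms = []
    import biotite.structure as struc
    arr = struc.AtomArray(sum(len(r.atoms) for r in chains["P"]))
    i = 0
    for res in chains["P"]:
        for at in res.atoms.values():
            arr.coord[i] = at.xyz
            arr.chain_id[i] = "P"
            arr.res_id[i] = res.number
            arr.res_name[i] = res.name
            arr.atom_name[i] = at.name
            arr.element[i] = at.element
            i += 1
    radii = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}
    vdw = np.array([radii[e] for e in arr.element])
    ref = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=vdw)
    _, per_res = shrake_rupley_sasa(model, ["P"], SasaParams(points_per_atom=960))
    mine = sum(per_res.values())
    assert mine == pytest.approx(float(ref.sum()), rel=0.01)
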