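"""RNA→DNA conversion: sequence map, structure edits, validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptadna import (
    AlphabetError,
    ConsistencyError,
    GeometryError,
    MethylGeometry,
    build_helix,
    convert_sequence,
    convert_structure,
    default_templates,
    methylate_uracil,
    rename_to_dna,
    sequence_of,
    strip_2prime_hydroxyl,
    validate_dna,
)
from aptadna.sequences import A6_RNA, A11_RNA, LN_A6_DNA, LN_A11_DNA_PUBLISHED

from _oracles import charwise_u_to_t


# -- sequence conversion ---------------------------------------------------


def test_published_a6_sequence_converts_exactly():
    assert convert_sequence(A6_RNA) == LN_A6_DNA


def test_published_a11_differs_from_shortened_published_dna():
    """Strict per-base substitution of the 60-nt A11 yields 60 nt; the
    published LN-A11 string is 57 nt (one triplet absent)."""
    strict = convert_sequence(A11_RNA)
    assert strict == charwise_u_to_t(A11_RNA)
    assert len(strict) == 60
    assert len(LN_A11_DNA_PUBLISHED) == 57
    assert strict != LN_A11_DNA_PUBLISHED


@pytest.mark.parametrize("raw,expected", [
    ("", ""),
    ("ACG", "ACG"),
    ("UUUU", "TTTT"),
    ("ccg cau", "ccg cat"),
])
def test_convert_sequence_cases(raw, expected):
    assert convert_sequence(raw) == expected


def test_convert_sequence_rejects_bad_character():
    with pytest.raises(AlphabetError, match="position 3"):
        convert_sequence("ACXGU")
    with pytest.raises(AlphabetError):
        convert_sequence("ACGT")  # T is not an RNA base


@given(st.text(alphabet="ACGUacgu ", max_size=80))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_convert_sequence_matches_charwise_oracle(seq):
    assert convert_sequence(seq) == charwise_u_to_t(seq)


# -- 2'-OH stripping -------------------------------------------------------


def test_strip_removes_o2prime_and_its_hydrogen(single_u_h):
    before = {a.name for a in single_u_h.residues[0].atoms}
    assert {"O2'", "HO2'"} <= before
    out, rep = strip_2prime_hydroxyl(single_u_h)
    after = {a.name for a in out.residues[0].atoms}
    assert after == before - {"O2'", "HO2'"}
    removed = {name for _rid, name in rep.removed_atoms}
    assert removed == {"O2'", "HO2'"}
    # untouched atoms keep bit-identical coordinates
    for a in out.residues[0].atoms:
        orig = single_u_h.residues[0].atom(a.name)
        assert np.array_equal(a.coords, orig.coords)


def test_strip_counts_on_a6(a6_helix):
    out, rep = strip_2prime_hydroxyl(a6_helix)
    n_o2 = sum(r.has_atom("O2'") for r in a6_helix.residues)
    assert n_o2 == 60
    assert len(rep.removed_atoms) == 60
    assert not any(r.has_atom("O2'") for r in out.residues)


def test_strip_is_noop_on_dna():
    dna = build_helix("ACGT")
    out, rep = strip_2prime_hydroxyl(dna)
    assert rep.removed_atoms == []
    assert np.array_equal(out.coords(), dna.coords())


# -- methylation -----------------------------------------------------------


def _methyl_angles(res):
    c4 = res.atom("C4").coords
    c5 = res.atom("C5").coords
    c6 = res.atom("C6").coords
    c7 = res.atom("C7").coords

    def angle(a, b, c):
        u, v = a - b, c - b
        return np.degrees(np.arccos(
            u @ v / np.linalg.norm(u) / np.linalg.norm(v)
        ))

    return angle(c4, c5, c7), angle(c6, c5, c7)


def test_methylate_geometry_on_single_uridine(single_u):
    out, rep = methylate_uracil(single_u)
    res = out.residues[0]
    assert res.has_atom("C7")
    a1, a2 = _methyl_angles(res)
    assert abs(a1 - 120) < 3 and abs(a2 - 120) < 3
    d = np.linalg.norm(res.atom("C7").coords - res.atom("C5").coords)
    assert d == pytest.approx(1.50, abs=1e-9)
    # C7 lies in the best-fit ring plane
    ring = np.array([res.atom(n).coords
                     for n in ("N1", "C2", "N3", "C4", "C5", "C6")])
    centroid = ring.mean(0)
    normal = np.linalg.svd(ring - centroid)[2][2]
    assert abs((res.atom("C7").coords - centroid) @ normal) < 0.15
    # three tetrahedral hydrogens at the C–H bond length
    for h in ("H71", "H72", "H73"):
        assert np.linalg.norm(
            res.atom(h).coords - res.atom("C7").coords
        ) == pytest.approx(1.09, abs=1e-9)


def test_methylate_heavy_only_construction_identical(single_u, single_u_h):
    """C7 placement uses only C4/C5/C6, so models with and without
    hydrogens give the same methyl carbon."""
    with_h, _ = methylate_uracil(single_u_h)
    without_h, _ = methylate_uracil(single_u)
    np.testing.assert_array_equal(
        with_h.residues[0].atom("C7").coords,
        without_h.residues[0].atom("C7").coords,
    )
    assert not single_u.residues[0].has_atom("H5")
    assert single_u_h.residues[0].has_atom("H5")
    assert not with_h.residues[0].has_atom("H5")


def test_methylate_identity_without_uracil():
    s = build_helix("ACG")
    out, rep = methylate_uracil(s)
    assert rep.added_atoms == [] and rep.removed_atoms == []
    assert np.array_equal(out.coords(), s.coords())


def test_methylate_requires_ring_atoms(single_u):
    s = single_u.copy()
    s.residues[0].atoms = [a for a in s.residues[0].atoms if a.name != "C5"]
    with pytest.raises(GeometryError, match="C5"):
        methylate_uracil(s)


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_methyl_geometry_survives_ring_perturbation(seed):
    """Angle and coplanarity postconditions hold for uracil rings whose
    atoms are randomly displaced by up to 0.05 Å."""
    rng = np.random.default_rng(seed)
    s = build_helix("U")
    for a in s.residues[0].atoms:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        a.coords = a.coords + rng.uniform(0, 0.05) * direction
    out, _ = methylate_uracil(s)
    res = out.residues[0]
    a1, a2 = _methyl_angles(res)
    assert abs(a1 - 120) < 3 and abs(a2 - 120) < 3
    ring = np.array([res.atom(n).coords
                     for n in ("N1", "C2", "N3", "C4", "C5", "C6")])
    centroid = ring.mean(0)
    normal = np.linalg.svd(ring - centroid)[2][2]
    assert abs((res.atom("C7").coords - centroid) @ normal) < 0.15


# -- renaming --------------------------------------------------------------


def test_rename_refuses_residues_with_o2prime(single_u):
    with pytest.raises(ConsistencyError):
        rename_to_dna(single_u)


def test_rename_after_strip(single_u):
    stripped, _ = strip_2prime_hydroxyl(single_u)
    meth, _ = methylate_uracil(stripped)
    out, rep = rename_to_dna(meth)
    res = out.residues[0]
    assert res.name == "DT" and res.base_kind == "thymine"
    assert rep.renamed_residues == [("A:1", "U", "DT")]


# -- full conversion -------------------------------------------------------


def test_convert_a6_full_pipeline(a6_helix, a6_converted):
    dna, rep = a6_converted
    assert sequence_of(dna) == LN_A6_DNA
    assert A6_RNA.count("U") == 8
    assert sum(1 for _r, n in rep.added_atoms if n == "C7") == 8
    assert sum(1 for _r, n in rep.removed_atoms if n == "O2'") == 60
    assert len(rep.renamed_residues) == 60
    assert {n for *_x, n in rep.renamed_residues} <= {"DA", "DC", "DG", "DT"}
    assert rep.all_valid


def test_convert_preserves_shared_coordinates_exactly(a6_helix, a6_converted):
    dna, _ = a6_converted
    for res_in, res_out in zip(a6_helix.residues, dna.residues):
        for a in res_in.atoms:
            if a.name == "O2'":
                assert not res_out.has_atom("O2'")
                continue
            np.testing.assert_array_equal(
                a.coords, res_out.atom(a.name).coords
            )


def test_convert_is_idempotent(a6_converted):
    dna, _ = a6_converted
    again, rep = convert_structure(dna)
    assert rep.removed_atoms == [] and rep.added_atoms == []
    assert rep.renamed_residues == []
    assert np.array_equal(again.coords(), dna.coords())


def test_sequence_structure_commutativity():
    """convert_sequence agrees with sequence_of∘convert_structure."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGU"), size=rng.integers(2, 8)))
        s = build_helix(seq)
        dna, _ = convert_structure(s)
        assert sequence_of(dna) == convert_sequence(seq)


# -- validation ------------------------------------------------------------


def test_validator_passes_on_converted_fixture(a6_converted):
    dna, _ = a6_converted
    assert all(c.passed for c in validate_dna(dna))


def test_validator_flags_leftover_o2prime(a6_converted):
    dna, _ = a6_converted
    bad = dna.copy()
    from aptadna import Atom

    res = bad.residues[3]
    res.atoms.append(Atom("O2'", "O", res.atom("C2'").coords + 1.4, 99999))
    fails = [c for c in validate_dna(bad) if not c.passed]
    assert any(
        c.name == "no_2prime_hydroxyl" and c.residue == res.rid()
        for c in fails
    )


def test_validator_flags_bad_methyl_bond(a6_converted):
    dna, _ = a6_converted
    bad = dna.copy()
    dt = next(r for r in bad.residues if r.name == "DT")
    c7 = dt.atom("C7")
    c5 = dt.atom("C5")
    direction = (c7.coords - c5.coords) / np.linalg.norm(c7.coords - c5.coords)
    c7.coords = c5.coords + 2.5 * direction
    fails = [c for c in validate_dna(bad) if not c.passed]
    assert any(c.name == "thymine_methyl" and c.residue == dt.rid()
               for c in fails)


def test_template_table_dna_equals_rna_minus_o2prime():
    t = default_templates()
    for rna, dna in (("A", "DA"), ("C", "DC"), ("G", "DG")):
        assert t[dna].heavy_atoms == t[rna].heavy_atoms - {"O2'"}
    assert t["DT"].heavy_atoms == (t["U"].heavy_atoms - {"O2'"}) | {"C7"}


def test_methyl_geometry_parameter_validation():
    with pytest.raises(ValueError):
        MethylGeometry(c5_c7_bond=-1)
    with pytest.raises(ValueError):
        MethylGeometry(hch_angle=150)
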