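"""Molecular-orbital format: basis-description microsyntax, write/read
round trip, and the dictionary constraints."""

import pytest
from hypothesis import given, settings, strategies as st

from cmlcompchem.core import CmlNode, CmlStructureError, parse_document, serialize_document
from cmlcompchem.fixtures import FixtureSpec, generate_mo_set
from cmlcompchem.mo import (
    CARTESIAN_SHELLS,
    SPHERICAL_SHELLS,
    AtomicBasisDescription,
    MolecularOrbital,
    MolecularOrbitalSet,
    format_basis_description,
    parse_basis_description,
    read_molecular_orbitals,
    validate_mo_set,
    write_molecular_orbitals,
)
from cmlcompchem.writer import WriterError, begin_document


def h2_minimal_set():
    """Two 1s basis functions, two orbitals: the bonding combination doubly
    occupied, the antibonding one empty."""
    return MolecularOrbitalSet(
        descriptions=[
            AtomicBasisDescription(1, "H", "s"),
            AtomicBasisDescription(2, "H", "s"),
        ],
        orbitals=[
            MolecularOrbital(-0.5966, "sg", "none", 2.0, [0.5483, 0.5483]),
            MolecularOrbital(0.2632, "su", "none", 0.0, [1.2178, -1.2178]),
        ],
    )


def write_to_doc(mos):
    session = begin_document("mo test")
    write_molecular_orbitals(session, mos)
    return session.finish()


class TestBasisDescriptionSyntax:
    @pytest.mark.parametrize(
        "desc, text",
        [
            (AtomicBasisDescription(1, "H", "s"), "1:H,s"),
            (AtomicBasisDescription(2, "O", "d-1"), "2:O,d-1"),
            (AtomicBasisDescription(3, "C", "dxy"), "3:C,dxy"),
        ],
    )
    def test_format_and_parse_are_inverses(self, desc, text):
        assert format_basis_description(desc) == text
        assert parse_basis_description(text) == desc

    @pytest.mark.parametrize("bad", ["x:H,s", "1:H", "1H,s", "0:H,s", "1:,s", "1:H,"])
    def test_grammar_violations_rejected(self, bad):
        with pytest.raises(CmlStructureError):
            parse_basis_description(bad)

    def test_unknown_shell_label_rejected(self):
        with pytest.raises(CmlStructureError, match="shell"):
            parse_basis_description("1:H,zz9")

    def test_space_after_comma_tolerated_on_read(self):
        assert parse_basis_description("1:H, s") == AtomicBasisDescription(1, "H", "s")

    @given(
        n=st.integers(min_value=1, max_value=200),
        name=st.sampled_from(["H", "C", "N", "O", "Fe"]),
        shell=st.sampled_from(sorted(CARTESIAN_SHELLS | SPHERICAL_SHELLS)),
    )
    @settings(derandomize=True, max_examples=60)
    def test_round_trip_property(self, n, name, shell):
        d = AtomicBasisDescription(n, name, shell)
        assert parse_basis_description(format_basis_description(d)) == d


class TestWrite:
    def test_h2_structure(self):
        doc = write_to_doc(h2_minimal_set())
        orbital_lists = [
            n
            for n in doc.iter()
            if n.local_name == "list" and n.get("dictRef") == "compchem:molecularOrbital"
        ]
        assert len(orbital_lists) == 2
        vectors = [
            n for n in doc.iter() if n.get("dictRef") == "compchem:aoVector"
        ]
        assert [v.get("size") for v in vectors] == ["2", "2"]
        assert all(v.get("dataType") == "xsd:double" for v in vectors)

    def test_energy_scalar_carries_units(self):
        doc = write_to_doc(h2_minimal_set())
        energy = next(
            n for n in doc.iter() if n.get("dictRef") == "compchem:orbitalEnergy"
        )
        assert energy.get("units") == "units:hartree"

    def test_occupancy_above_two_rejected(self):
        mos = h2_minimal_set()
        mos.orbitals[0].occupancy = 2.5
        with pytest.raises(WriterError):
            write_to_doc(mos)

    def test_spin_resolved_occupancy_above_one_rejected(self):
        mos = h2_minimal_set()
        mos.orbitals[0].spin = "alpha"
        mos.orbitals[0].occupancy = 1.5
        with pytest.raises(WriterError):
            write_to_doc(mos)


class TestRead:
    @pytest.mark.parametrize("seed", range(8))
    def test_write_read_identity(self, seed):
        _, mos = generate_mo_set(FixtureSpec(seed=seed, spin_resolved=seed % 2 == 1))
        # Through serialized bytes, not just the in-memory tree.
        doc = parse_document(serialize_document(write_to_doc(mos)))
        back = read_molecular_orbitals(doc)
        assert back.descriptions == mos.descriptions
        for got, expect in zip(back.orbitals, mos.orbitals, strict=True):
            assert got.energy == expect.energy
            assert got.symmetry == expect.symmetry
            assert got.spin == expect.spin
            assert got.occupancy == expect.occupancy
            assert got.coefficients == expect.coefficients

    def test_document_without_container_reads_none(self):
        doc = begin_document("empty").finish()
        assert read_molecular_orbitals(doc) is None

    def test_unknown_elements_inside_container_ignored(self):
        doc = write_to_doc(h2_minimal_set())
        container = next(
            n for n in doc.iter() if n.get("dictRef") == "compchem:molecularOrbitals"
        )
        alien = CmlNode(qname="x:novel")
        alien.ns_decls["x"] = "http://example.org/x"
        container.children.insert(1, alien)
        back = read_molecular_orbitals(doc)
        clean = read_molecular_orbitals(write_to_doc(h2_minimal_set()))
        assert back == clean

    def test_vector_length_mismatch_names_orbital(self):
        doc = write_to_doc(h2_minimal_set())
        vector = [n for n in doc.iter() if n.get("dictRef") == "compchem:aoVector"][1]
        vector.text += " 0.1"
        with pytest.raises(CmlStructureError, match="orbital 1"):
            read_molecular_orbitals(doc)


class TestValidateSet:
    def test_clean_closed_shell_with_electron_count(self):
        assert validate_mo_set(h2_minimal_set(), electron_count=2) == []

    def test_wrong_electron_count_flagged(self):
        issues = validate_mo_set(h2_minimal_set(), electron_count=4)
        assert [i.code for i in issues] == ["mo-electron-count"]

    def test_unknown_spin_cites_allowed_values(self):
        mos = h2_minimal_set()
        mos.orbitals[0].spin = "gamma"
        (issue,) = validate_mo_set(mos)
        assert "alpha" in issue.message and "beta" in issue.message

    def test_coefficient_length_mismatch_names_orbital(self):
        mos = h2_minimal_set()
        mos.orbitals[1].coefficients.append(0.3)
        (issue,) = validate_mo_set(mos)
        assert issue.code == "mo-vector-length"
        assert issue.location == "orbitals[1]"

    def test_mixed_shell_vocabularies_flagged(self):
        mos = h2_minimal_set()
        mos.descriptions[0] = AtomicBasisDescription(1, "H", "dxy")
        mos.descriptions[1] = AtomicBasisDescription(2, "H", "d-1")
        # Coefficient lengths still match, so exactly the mix is flagged.
        issues = validate_mo_set(mos)
        assert [i.code for i in issues] == ["mo-mixed-vocabulary"]

    def test_writer_and_validator_agree(self):
        """Shared predicate: the writer accepts exactly the sets the
        validator passes."""
        for seed in range(6):
            for code in (None, "occupancy_range", "bad_spin"):
                _, mos = generate_mo_set(FixtureSpec(seed=seed, inject_invalid=code))
                issues = validate_mo_set(mos)
                if issues:
                    with pytest.raises(WriterError):
                        write_to_doc(mos)
                else:
                    write_to_doc(mos)
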