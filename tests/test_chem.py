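"""Formula parsing, monoisotopic mass arithmetic, and adduct algebra."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from duomics import chem
from duomics.chem import (
    Adduct,
    FormulaError,
    adduct_mz,
    formula_to_string,
    load_registry,
    monoisotopic_mass,
    neutral_mass_from_mz,
    parse_formula,
    ppm_error,
)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C5H4N4O", {"C": 5, "H": 4, "N": 4, "O": 1}),
        ("C", {"C": 1}),
        ("C6H14O6", {"C": 6, "H": 14, "O": 6}),
        ("CH4", {"C": 1, "H": 4}),
        ("NaCl", {"Na": 1, "Cl": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


def test_parse_serialize_round_trip():
    for text in ["C5H4N4O", "C57H86O4", "C11H15N5O3S", "C"]:
        assert formula_to_string(parse_formula(text)) == text


@pytest.mark.parametrize("bad", ["", "  ", "Xx4", "C-3", "H2Q", "123"])
def test_parse_formula_rejects_garbage(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_parse_formula_names_unknown_symbol():
    with pytest.raises(FormulaError, match="Qq"):
        parse_formula("C2Qq3")


@pytest.mark.parametrize(
    "formula, expected, tol",
    [
        ({"C": 1}, 12.0, 0.0),  # carbon-12 definition
        ({"C": 5, "H": 4, "N": 4, "O": 1}, 136.0385, 5e-4),  # hypoxanthine
        ({"C": 12, "H": 24, "O": 2}, 200.1776, 5e-4),  # laurate
    ],
)
def test_monoisotopic_mass_reference_values(formula, expected, tol):
    assert monoisotopic_mass(formula) == pytest.approx(expected, abs=max(tol, 1e-12))


def test_monoisotopic_mass_cross_checks_pyteomics():
    """Independent oracle: pyteomics' own monoisotopic mass calculator."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    for text in ["C5H4N4O", "C8H11NO3", "C18H34O2", "C57H86O4", "C11H15N5O3S"]:
        ours = monoisotopic_mass(parse_formula(text))
        theirs = pyteomics_mass.calculate_mass(formula=text)
        assert ours == pytest.approx(theirs, abs=5e-4)


@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "P", "Na"]),
        st.integers(min_value=1, max_value=60),
        min_size=1,
    ),
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "S", "P", "Na"]),
        st.integers(min_value=1, max_value=60),
        min_size=1,
    ),
)
def test_mass_additivity(f1, f2):
    """Mass of a formula union equals the sum of the parts to 1e-9 u."""
    merged = dict(f1)
    for k, v in f2.items():
        merged[k] = merged.get(k, 0) + v
    assert monoisotopic_mass(merged) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


def test_adduct_mz_bare_proton():
    proton = Adduct("M+H[1+]", 1.007276, 1)
    assert adduct_mz(0.0, proton) == pytest.approx(1.007276, abs=1e-9)


def test_adduct_mz_matches_observed_table_rows(adducts):
    by_name = {a.name: a for a in adducts}
    pyridoxine = 169.0739
    mz = adduct_mz(pyridoxine, by_name["M+H[1+]"])
    assert abs(ppm_error(170.081, mz)) <= 10
    oleate = 282.2559
    mz2 = adduct_mz(oleate, by_name["M+H+Na[2+]"])
    assert abs(ppm_error(153.1264, mz2)) <= 10


def test_adduct_mz_rejects_nonphysical():
    loss = Adduct("M-H2O[1+]", -17.003289, 1)
    with pytest.raises(ValueError):
        adduct_mz(10.0, loss)


@given(st.floats(min_value=50.0, max_value=2000.0))
def test_adduct_round_trip(neutral_mass):
    """neutral_mass_from_mz inverts adduct_mz to 1e-9 u for every packaged adduct."""
    from duomics.chem import default_adducts

    for adduct in default_adducts():
        mz = adduct_mz(neutral_mass, adduct)
        assert neutral_mass_from_mz(mz, adduct) == pytest.approx(neutral_mass, abs=1e-9)


def test_registry_masses_populated(registry):
    for compound in registry:
        assert compound.neutral_mass == pytest.approx(
            monoisotopic_mass(compound.formula), abs=1e-6
        )
        assert compound.neutral_mass > 0


def test_registry_verified_rows_within_10ppm(registry, adducts, observed):
    """Every table row flagged verified reproduces its printed m/z within 10 ppm."""
    by_name = {c.name: c for c in registry}
    by_adduct = {a.name: a for a in adducts}
    checked = 0
    for _, row in observed[observed["verified"]].iterrows():
        theo = adduct_mz(by_name[row["compound"]].neutral_mass, by_adduct[row["adduct"]])
        assert abs(ppm_error(row["mz"], theo)) <= 10, row["compound"]
        checked += 1
    assert checked >= 20


def test_load_registry_errors(tmp_path):
    adduct_path = tmp_path / "adducts.tsv"
    adduct_path.write_text("name\tmass_shift\tcharge\nM+H[1+]\t1.007276\t1\n")
    good = tmp_path / "ok.tsv"
    good.write_text(
        "name\tformula\tcas\tkegg\tec_links\tpathways\tverified\n"
        "a\tC6H12O6\t\t\t1.1.1.1\tp\ttrue\n"
        "b\tC5H4N4O\t\t\t\t\ttrue\n"
    )
    compounds, adducts = load_registry(good, adduct_path)
    assert len(compounds) == 2 and compounds[0].neutral_mass > 0

    dup = tmp_path / "dup.tsv"
    dup.write_text(
        "name\tformula\tcas\tkegg\tec_links\tpathways\tverified\n"
        "a\tC6H12O6\t\t\t\t\ttrue\na\tC5H4N4O\t\t\t\t\ttrue\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_registry(dup, adduct_path)

    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "name\tformula\tcas\tkegg\tec_links\tpathways\tverified\n"
        "a\tC6H12O6\t\t\t\t\ttrue\nb\tNotAFormula!\t\t\t\t\ttrue\n"
    )
    with pytest.raises(ValueError, match=":3"):  # error names the offending line
        load_registry(bad, adduct_path)


def test_compound_rejects_malformed_cas():
    with pytest.raises(ValueError, match="CAS"):
        chem.Compound(
            name="x",
            formula={"C": 1},
            neutral_mass=12.0,
            cas="not-a-cas",
        )
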