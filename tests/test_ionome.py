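"""Ionome responses, unit bookkeeping and the reference-table worked examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ktscreen as kt

# Percent changes quoted in the source study's narrative for the packaged
# KN9204/BN207 shoot+root table (verified by hand from the printed
# concentrations before freezing here).
REPORTED_PERCENT_CHANGES = {
    ("shoot", "KN9204", "K"): -76.17,
    ("root", "KN9204", "K"): -48.00,
    ("shoot", "KN9204", "Mn"): -3.68,
    ("root", "KN9204", "Fe"): -2.88,
    ("shoot", "BN207", "Zn"): -6.70,
    ("root", "BN207", "Mn"): -14.35,
    ("shoot", "BN207", "K"): -78.87,
    ("root", "BN207", "P"): -84.23,
    ("shoot", "KN9204", "Ca"): 17.77,
    ("shoot", "KN9204", "Mg"): 16.47,
    ("shoot", "KN9204", "Na"): 11.24,
    ("root", "KN9204", "Ca"): 0.38,
    ("root", "KN9204", "Mg"): 3.23,
    ("root", "KN9204", "Na"): 5.66,
    ("shoot", "BN207", "Ca"): 50.78,
    ("shoot", "BN207", "Mg"): 16.77,
    ("shoot", "BN207", "Na"): 10.22,
    ("root", "BN207", "Ca"): 121.31,
    ("root", "BN207", "Mg"): 6.90,
    ("root", "BN207", "Na"): 26.20,
}


class TestReferenceTable:
    def test_roundtrip_through_writer_and_reader(self, reference_ionome, tmp_path):
        path = tmp_path / "out.csv"
        kt.write_ionome_csv(reference_ionome, path)
        back = kt.read_ionome_csv(path)
        merged = reference_ionome.merge(
            back, on=["tissue", "treatment", "genotype", "element"], suffixes=("", "_rt")
        )
        assert len(merged) == len(reference_ionome)
        assert np.allclose(merged["concentration"], merged["concentration_rt"])
        assert (merged["letters"] == merged["letters_rt"]).all()
        assert (merged["unit"] == merged["unit_rt"]).all()

    def test_significance_letters_parsed_as_annotations(self, reference_ionome):
        row = reference_ionome.query(
            "tissue == 'shoot' and treatment == 'CK' and genotype == 'KN9204' and element == 'K'"
        ).iloc[0]
        assert row["concentration"] == 29.58
        assert row["letters"] == "Aa"

    @pytest.mark.parametrize("key, expected", sorted(REPORTED_PERCENT_CHANGES.items()))
    def test_percent_changes_match_reported_values(self, reference_ionome, key, expected):
        resp = kt.percent_change(reference_ionome).set_index(
            ["tissue", "genotype", "element"]
        )
        assert resp.loc[key, "percent_change"] == pytest.approx(expected, abs=0.01)

    def test_extremes_identify_k_as_largest_shoot_decrease(self, reference_ionome):
        ext = kt.response_extremes(kt.percent_change(reference_ionome))
        row = ext.query(
            "tissue == 'shoot' and genotype == 'KN9204' and direction == 'decrease' "
            "and extreme == 'largest'"
        ).iloc[0]
        assert row["element"] == "K"
        smallest_root = ext.query(
            "tissue == 'root' and genotype == 'KN9204' and direction == 'decrease' "
            "and extreme == 'smallest'"
        ).iloc[0]
        assert smallest_root["element"] == "Fe"


class TestPercentChange:
    def test_no_change_is_zero(self):
        table = kt.generate_ionome_table(seed=1)
        resp = kt.percent_change(table)
        assert np.allclose(resp["percent_change"], 0.0)
        assert (resp["direction"] == "unchanged").all()

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=0.01, max_value=1e3),
    )
    def test_forward_and_reverse_changes_compose_to_identity(self, ck, lk):
        pc_fwd = (lk - ck) / ck * 100
        pc_rev = (ck - lk) / lk * 100
        assert (1 + pc_fwd / 100) * (1 + pc_rev / 100) == pytest.approx(1.0, rel=1e-9)

    def test_zero_control_flagged_not_fabricated(self):
        table = pd.DataFrame(
            {
                "tissue": ["shoot"] * 2,
                "treatment": ["CK", "LK"],
                "genotype": ["g"] * 2,
                "element": ["K"] * 2,
                "concentration": [0.0, 5.0],
                "unit": ["g/kg"] * 2,
                "letters": ["", ""],
            }
        )
        resp = kt.percent_change(table)
        assert resp["flag"].iloc[0] == "zero-control"
        assert np.isnan(resp["percent_change"].iloc[0])


class TestKContentAndKue:
    def test_zero_dry_weight_gives_zero_content(self):
        assert kt.k_content(0.0, 24.44) == 0.0

    def test_unit_sanity_gram_per_kilogram(self):
        assert kt.k_content(1000.0, 1.0) == pytest.approx(1.0)

    def test_direct_multiplication(self):
        # population mean-of-products need not equal product-of-means, so
        # this only asserts the element-wise formula
        assert kt.k_content(21.36, 24.44) == pytest.approx(0.522, abs=5e-4)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            kt.k_content(1.0, 1.0, dry_weight_unit="g")

    def test_content_concentration_roundtrip(self, rng):
        dw = rng.uniform(1, 100, 50)
        conc = rng.uniform(0.1, 50, 50)
        content = kt.k_content(dw, conc)
        back = kt.concentration_from_content(content, dw)
        assert np.allclose(back, conc, rtol=1e-12)

    def test_kue_arithmetic(self):
        # 10 mg DW, 100 ug (0.1 mg) K content -> 1.0 mg^2/ug
        assert kt.kue(10.0, 0.1) == pytest.approx(1.0)

    def test_doubling_dw_quadruples_kue(self):
        assert kt.kue(20.0, 0.1) == pytest.approx(4 * kt.kue(10.0, 0.1))

    def test_kue_rises_as_k_concentration_falls(self):
        # matches the stress direction: biomass drops less than K content
        dw_ck, conc_ck = 21.36, 24.44
        dw_lk, conc_lk = 17.22, 6.93
        kue_ck = kt.kue(dw_ck, kt.k_content(dw_ck, conc_ck))
        kue_lk = kt.kue(dw_lk, kt.k_content(dw_lk, conc_lk))
        assert kue_lk > kue_ck

    def test_zero_content_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kt.kue(10.0, 0.0)

    def test_linear_formula_switch(self):
        assert kt.kue(10.0, 0.1, formula="linear") == pytest.approx(0.1)


class TestGenotypeContrast:
    def test_reference_shoot_k_and_root_ca(self, reference_ionome):
        resp = kt.percent_change(reference_ionome)
        contrast = kt.genotype_contrast(resp, "KN9204", "BN207").set_index(
            ["tissue", "element"]
        )
        shoot_k = contrast.loc[("shoot", "K")]
        assert shoot_k["greater_change_in"] == "BN207"
        assert "decrease" in shoot_k["verdict"]
        root_ca = contrast.loc[("root", "Ca")]
        assert root_ca["greater_change_in"] == "BN207"
        assert "increase" in root_ca["verdict"]

    def test_equal_changes_reported_as_tie(self):
        table = kt.generate_ionome_table(
            effect_map={("shoot", "A", "K"): 0.5, ("shoot", "B", "K"): 0.5},
            genotypes=("A", "B"),
            tissues=("shoot",),
            elements=("K",),
            seed=2,
        )
        contrast = kt.genotype_contrast(kt.percent_change(table), "A", "B")
        assert contrast["greater_change_in"].iloc[0] == "tie"

    def test_missing_genotype_rejected(self, reference_ionome):
        resp = kt.percent_change(reference_ionome)
        with pytest.raises(ValueError, match="absent"):
            kt.genotype_contrast(resp, "KN9204", "nope")
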