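"""Systematic-effect coding and random-effect incidence structures."""

import numpy as np
import pandas as pd
import pytest

from pedgibbs.design import (
    LITTER_CODES,
    ModelSpec,
    build_design,
    build_random_design,
    code_systematic_effects,
    pool_years,
    validate_phenotypes,
)
from pedgibbs.pedigree import inbreeding_table


def small_table():
    return pd.DataFrame(
        {
            "calf_id": ["c1", "c2", "c3", "c4", "c5", "c6"],
            "dam_id": ["d1", "d1", "d2", "d2", "d3", "d3"],
            "sire_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "survival": [1, 0, 1, 1, 0, 1],
            "calving_year": [2000, 2000, 2001, 2001, 2002, 2002],
            "parity": ["primiparous", "primiparous", "multiparous",
                       "multiparous", "multiparous", "primiparous"],
            "dam_age_days": [900.0, 900.0, 1500.0, 1500.0, 2100.0, 2100.0],
            "litter_code": ["F", "M", "F(M)", "M(F)", "F", "M(M)"],
        }
    )


def small_ped():
    from pedgibbs.pedigree import from_records

    recs = [(p, None, None, "M" if p.startswith("s") else "F", 1995)
            for p in ["s1", "s2", "d1", "d2", "d3"]]
    damof = {"c1": "d1", "c2": "d1", "c3": "d2", "c4": "d2", "c5": "d3", "c6": "d3"}
    sireof = {"c1": "s1", "c2": "s1", "c3": "s1", "c4": "s2", "c5": "s2", "c6": "s2"}
    for c in ["c1", "c2", "c3", "c4", "c5", "c6"]:
        recs.append((c, sireof[c], damof[c], "F", 2000))
    return from_records(recs)


class TestModelSpec:
    @pytest.mark.parametrize(
        "name,blocks",
        [
            ("calf", {"calf_additive"}),
            ("calf-dam", {"calf_additive", "maternal_genetic"}),
            ("calf-permanent", {"calf_additive", "maternal_permanent"}),
            ("calf-dam-permanent",
             {"calf_additive", "maternal_genetic", "maternal_permanent"}),
        ],
    )
    def test_named_variants(self, name, blocks):
        spec = ModelSpec.variant(name)
        assert set(spec.random_blocks) == blocks

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            ModelSpec.variant("dam-only")

    def test_maternal_without_calf_block_rejected(self):
        with pytest.raises(ValueError, match="calf additive"):
            ModelSpec(random_blocks=("maternal_genetic",))


class TestYearPooling:
    def test_sparse_terminal_years_merge(self):
        # mirrors pooling a 4-record terminal year into its neighbour
        years = pd.Series([2009] * 6 + [2010] * 6 + [2011] * 4)
        mapping = pool_years(years, min_records=5)
        assert mapping[2011] == mapping[2010]
        assert mapping[2009] != mapping[2010]

    def test_all_years_kept_when_dense(self):
        years = pd.Series([2000] * 5 + [2001] * 7)
        mapping = pool_years(years, min_records=5)
        assert mapping[2000] == "2000" and mapping[2001] == "2001"

    def test_recordless_interior_year_absorbed(self):
        years = pd.Series([1995] * 2 + [1997] * 9)
        mapping = pool_years(years, min_records=5)
        assert mapping[1996] == mapping[1995]


class TestSystematicCoding:
    def test_litter_indicator_single_column(self):
        tab = small_table()
        spec = ModelSpec.variant("calf")
        X, coding = code_systematic_effects(tab, spec)
        names = coding.colnames
        j = names.index("litter:M(F)")
        col = X[:, j]
        assert col.tolist() == [0, 0, 0, 1, 0, 0]
        # exactly one litter indicator per non-reference record
        litter_cols = [k for k, n in enumerate(names) if n.startswith("litter:")]
        assert (X[:, litter_cols].sum(axis=1) <= 1).all()

    def test_age_centering_zeroes_mean_record(self):
        tab = small_table()
        X, coding = code_systematic_effects(tab, ModelSpec.variant("calf"))
        j = coding.colnames.index("age_lin")
        rec = tab.iloc[[2]]  # dam_age 1500 = mean
        row = coding.encode(rec)
        assert row[0, j] == pytest.approx(0.0)
        assert row[0, coding.colnames.index("age_quad")] == pytest.approx(0.0)

    def test_mode_III_all_outbred_drops_column(self):
        tab = small_table()
        ped = small_ped()
        itab = inbreeding_table(ped)
        spec = ModelSpec.variant("calf", inbreeding_mode="III")
        bundle = build_design(tab, ped, spec, dF=itab["delta_F"].to_numpy())
        # nobody inbred -> dF identically zero -> degenerate column dropped
        assert "dF_lin" not in bundle.fixed_names

    def test_mode_II_adds_linear_and_quadratic(self):
        tab = small_table()
        ped = small_ped()
        # plant some inbreeding variation through fake F values
        F = np.linspace(0, 0.3, ped.n)
        spec = ModelSpec.variant("calf", inbreeding_mode="II")
        bundle = build_design(tab, ped, spec, F=F)
        assert "F_lin" in bundle.fixed_names and "F_quad" in bundle.fixed_names

    def test_categorical_row_sums_are_one(self):
        tab = small_table()
        X, coding = code_systematic_effects(tab, ModelSpec.variant("calf"))
        for prefix, levels in [("year:", coding.year_levels),
                               ("litter:", coding.litter_levels)]:
            cols = [k for k, n in enumerate(coding.colnames) if n.startswith(prefix)]
            # rows at the reference level have zero across the block
            assert np.isin(X[:, cols].sum(axis=1), [0.0, 1.0]).all()

    def test_unknown_litter_code_raises(self):
        tab = small_table()
        tab.loc[0, "litter_code"] = "X(Y)"
        with pytest.raises(ValueError, match="litter_code"):
            validate_phenotypes(tab)

    def test_nonpositive_age_raises(self):
        tab = small_table()
        tab.loc[0, "dam_age_days"] = 0.0
        with pytest.raises(ValueError, match="dam_age_days"):
            validate_phenotypes(tab)

    def test_unseen_year_maps_to_nearest_level(self):
        tab = small_table()
        X, coding = code_systematic_effects(tab, ModelSpec.variant("calf", min_year_records=2))
        rec = small_table().iloc[[0]].assign(calving_year=2050)
        row = coding.encode(rec)
        cols = [k for k, n in enumerate(coding.colnames) if n.startswith("year:")]
        assert row[0, cols].sum() == 1.0  # mapped to the latest (non-reference) level


class TestRandomDesign:
    def test_incidence_maps(self):
        tab, ped = small_table(), small_ped()
        spec = ModelSpec.variant("calf-dam-permanent")
        z, m, w, p, dams = build_random_design(tab, ped, spec)
        assert len(z) == len(tab) and (z == ped.positions(tab["calf_id"])).all()
        assert (m == ped.positions(tab["dam_id"])).all()
        # repeated dams share a permanent-environment level
        assert w[0] == w[1] and w[0] != w[2]
        assert dams == ["d1", "d2", "d3"]
        assert p is None

    def test_calf_model_has_no_maternal_structures(self):
        tab, ped = small_table(), small_ped()
        bundle = build_design(tab, ped, ModelSpec.variant("calf"))
        assert bundle.m_idx is None and bundle.w_idx is None and bundle.dam_levels == []

    def test_dropping_a_block_changes_nothing_else(self):
        tab, ped = small_table(), small_ped()
        b1 = build_design(tab, ped, ModelSpec.variant("calf-dam"))
        b2 = build_design(tab, ped, ModelSpec.variant("calf"))
        np.testing.assert_array_equal(b1.X, b2.X)
        np.testing.assert_array_equal(b1.z_idx, b2.z_idx)
        assert b2.m_idx is None and b1.m_idx is not None

    def test_missing_dam_raises_for_maternal_model(self):
        tab = small_table()
        tab.loc[0, "dam_id"] = "ghost"
        ped = small_ped()
        with pytest.raises(ValueError, match="dam"):
            build_random_design(tab, ped, ModelSpec.variant("calf-dam"))

    def test_coding_is_deterministic(self):
        tab, ped = small_table(), small_ped()
        b1 = build_design(tab, ped, ModelSpec.variant("calf-dam-permanent"))
        b2 = build_design(tab, ped, ModelSpec.variant("calf-dam-permanent"))
        np.testing.assert_array_equal(b1.X, b2.X)
        assert b1.fixed_names == b2.fixed_names
        assert b1.dam_levels == b2.dam_levels


def test_paperlike_design_shape(paperlike_fixture):
    """One indicator per categorical factor; Z covers the whole pedigree."""
    ped, tab, _ = paperlike_fixture
    bundle = build_design(tab, ped, ModelSpec.variant("calf-dam"))
    assert bundle.n_records == len(tab)
    assert bundle.z_idx.max() < ped.n
    # all six litter codes should occur in a population this size
    assert set(tab["litter_code"]) == set(LITTER_CODES)
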