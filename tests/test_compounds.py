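import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bupnet.compounds import (
    BindingPartner,
    Compound,
    InductionSpec,
    apparent_km,
    build_cyp2b6_diplotype,
    induction_fold,
    kon_from_binding,
    load_compound,
    load_tissue_composition,
    neutral_fraction,
    partition_coefficients,
)
from bupnet.config import ConfigurationError


@pytest.fixture(scope="module")
def bupropion():
    return load_compound("bupropion")


# ---------------------------------------------------------------------------
# partitioning


def test_user_supplied_partition_map_is_passed_through():
    comp = Compound(name="x", mw=100, fu=0.5, partition_method="user_supplied",
                    user_partition={"liver": 3.0})
    assert partition_coefficients(comp) == {"liver": 3.0}


def test_neutral_low_lipophilicity_limit_approaches_aqueous_ratio():
    """As logP -> -inf with fu = 1, Kp tends to the effective water ratio."""
    comp = Compound(name="x", mw=100, fu=1.0, logp=-12.0, pka_type="neutral")
    table = load_tissue_composition()
    kps = partition_coefficients(comp, table)
    liver, plasma = table.loc["liver"], table.loc["plasma"]
    expected = (liver.f_water + 0.7 * liver.f_phospholipid) / (
        plasma.f_water + 0.7 * plasma.f_phospholipid
    )
    assert kps["liver"] == pytest.approx(expected, rel=1e-9)


def test_bupropion_liver_kp_matches_independent_oracle(bupropion):
    """One-off independently coded evaluation of the lipid-fraction formula."""
    table = load_tissue_composition()
    fn = 1.0 / (1.0 + 10.0 ** (8.75 - 7.4))
    d = 10.0**2.57 * fn
    liver, plasma = table.loc["liver"], table.loc["plasma"]
    num = d * (liver.f_nlipid + 0.3 * liver.f_phospholipid) + liver.f_water + 0.7 * liver.f_phospholipid
    den = d * (plasma.f_nlipid + 0.3 * plasma.f_phospholipid) + plasma.f_water + 0.7 * plasma.f_phospholipid
    expected = num / den * (1.0 + 0.16) / 2.0
    kp = partition_coefficients(bupropion, table)["liver"]
    assert kp == pytest.approx(expected, rel=1e-9)


def test_missing_composition_row_is_reported_by_name(bupropion):
    table = load_tissue_composition().drop(index="liver")
    kps = partition_coefficients(bupropion, table)
    assert "liver" not in kps  # the engine raises when an organ row is missing


def test_charged_method_binds_more_than_neutral_method_for_bases():
    base = dict(name="x", mw=100, fu=0.5, logp=2.0, pka=9.0, pka_type="base")
    neutral = partition_coefficients(Compound(**base, partition_method="berezhkovskiy"))
    charged = partition_coefficients(Compound(**base, partition_method="schmitt_charge_dependent"))
    assert all(charged[o] > neutral[o] for o in neutral)


# ---------------------------------------------------------------------------
# genotype machinery


def test_diplotype_is_symmetric_and_splits_enzyme_in_half(bupropion):
    fwd = build_cyp2b6_diplotype("*1", "*6", bupropion.cyp2b6_alleles)
    rev = build_cyp2b6_diplotype("*6", "*1", bupropion.cyp2b6_alleles)
    assert [(p.km, p.kcat) for p in fwd] == [(p.km, p.kcat) for p in rev]
    assert all(p.enzyme_fraction == 0.5 for p in fwd)
    assert {p.process_id for p in fwd} == {p.process_id for p in rev}


def test_unknown_allele_raises_configuration_error(bupropion):
    with pytest.raises(ConfigurationError, match="unknown CYP2B6 allele"):
        build_cyp2b6_diplotype("*1", "*9", bupropion.cyp2b6_alleles)


@pytest.mark.parametrize("diplotype", [("*1", "*1"), ("*1", "*4"), ("*1", "*6"), ("*6", "*6")])
def test_low_substrate_clearance_equals_per_allele_sum(bupropion, diplotype):
    """At C << KM the diplotype intrinsic clearance is the per-allele sum.

    Brute-force rate evaluation at C = KM/1000 against the closed form
    sum(kcat_allele * E_allele / KM_allele) with E split half-half.
    """
    processes = build_cyp2b6_diplotype(*diplotype, bupropion.cyp2b6_alleles)
    e_total = 2.0  # µmol, arbitrary
    c = min(p.km for p in processes) / 1000.0
    brute = sum(p.kcat * e_total * p.enzyme_fraction * c / (p.km + c) for p in processes)
    closed = sum(p.kcat * e_total * p.enzyme_fraction / p.km for p in processes) * c
    assert brute == pytest.approx(closed, rel=2e-3)


# ---------------------------------------------------------------------------
# interaction kinetics


@given(
    km=st.floats(0.1, 1e3),
    inhibitor=st.floats(0.0, 1e3),
    ki=st.floats(0.1, 1e3),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_apparent_km_is_linear_and_anchored(km, inhibitor, ki):
    value = apparent_km(km, inhibitor, ki)
    assert value >= km
    assert apparent_km(km, 0.0, ki) == km
    assert apparent_km(km, ki, ki) == pytest.approx(2.0 * km)
    # linearity in I
    assert apparent_km(km, 2 * inhibitor, ki) - value == pytest.approx(
        value - apparent_km(km, 0.0, ki), rel=1e-9, abs=1e-12
    )


def test_apparent_km_rejects_nonpositive_ki():
    with pytest.raises(ValueError):
        apparent_km(25.8, 1.0, 0.0)


def test_apparent_km_rifampicin_arithmetic():
    assert apparent_km(25.80, 10.0, 118.50) == pytest.approx(25.80 * (1 + 10 / 118.50))


@given(conc=st.floats(0.0, 1e6), emax=st.floats(0.0, 20.0), ec50=st.floats(1e-3, 1e3))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_induction_fold_is_bounded_and_monotone(conc, emax, ec50):
    spec = InductionSpec("rifampicin", "CYP2B6", ec50=ec50, emax=emax, kdeg=1e-3)
    fold = induction_fold(conc, spec)
    assert 1.0 <= fold <= 1.0 + emax + 1e-12
    assert induction_fold(2 * conc, spec) >= fold
    assert induction_fold(0.0, spec) == 1.0
    assert induction_fold(ec50, spec) == pytest.approx(1.0 + emax / 2.0)


def test_induction_saturating_limit():
    spec = InductionSpec("rifampicin", "CYP2B6", ec50=1.0, emax=9.0, kdeg=1e-3)
    assert induction_fold(1000.0, spec) == pytest.approx(1 + 9 * 1000 / 1001)


def test_kon_from_binding_identities():
    assert kon_from_binding(BindingPartner(kd=0.44, koff=0.05)) == pytest.approx(0.05 / 0.44)
    assert kon_from_binding(BindingPartner(kd=1.3, koff=0.0)) == 0.0
    assert kon_from_binding(BindingPartner(kd=0.7, koff=0.7)) == pytest.approx(1.0)


def test_henderson_hasselbalch_fractions():
    assert neutral_fraction(None, "neutral") == 1.0
    assert neutral_fraction(7.4, "base") == pytest.approx(0.5)
    assert neutral_fraction(7.4, "acid") == pytest.approx(0.5)
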