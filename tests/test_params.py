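"""Parameter pack loading, fixture fidelity against the printed input
tables, validation, and write/load round-trips."""

import math

import pytest
import yaml
from hypothesis import given, strategies as st

from screencea.params import (
    ConfigError,
    fixture_path,
    load_fixture,
    load_parameters,
    validate_parameters,
    write_parameters,
)
from screencea.synthetic import gen_cohort_fixture

# (getter, printed value) pairs spot-checking the packs against the
# published input tables; probabilities are stored as decimals.
FIDELITY_SMOKING = [
    # round-1 scan outcomes
    (lambda p: p.scan_tables["first"].p_regular_negative, 0.7921),
    (lambda p: p.scan_tables["first"].p_regular_indeterminate, 0.1920),
    (lambda p: p.scan_tables["first"].p_regular_positive, 0.0159),
    (lambda p: p.scan_tables["first"].p_indeterminate_negative, 0.9457),
    (lambda p: p.scan_tables["first"].p_indeterminate_positive, 0.0543),
    (lambda p: p.scan_tables["first"].p_true_negative, 0.9993),
    (lambda p: p.scan_tables["first"].p_false_negative, 0.0007),
    (lambda p: p.scan_tables["first"].p_true_positive, 0.3867),
    (lambda p: p.scan_tables["first"].p_false_positive, 0.6133),
    (lambda p: p.scan_tables["first"].stage_distribution["I"], 0.6486),
    (lambda p: p.scan_tables["first"].stage_distribution["II"], 0.0946),
    (lambda p: p.scan_tables["first"].stage_distribution["III"], 0.1892),
    (lambda p: p.scan_tables["first"].stage_distribution["IV"], 0.0676),
    # round-2 scan outcomes
    (lambda p: p.scan_tables["subsequent"].p_regular_negative, 0.9217),
    (lambda p: p.scan_tables["subsequent"].p_regular_indeterminate, 0.0658),
    (lambda p: p.scan_tables["subsequent"].p_regular_positive, 0.0125),
    (lambda p: p.scan_tables["subsequent"].p_indeterminate_positive, 0.0877),
    (lambda p: p.scan_tables["subsequent"].p_true_positive, 0.4435),
    (lambda p: p.scan_tables["subsequent"].p_false_positive, 0.5565),
    (lambda p: p.scan_tables["subsequent"].stage_distribution["I"], 0.7586),
    (lambda p: p.scan_tables["subsequent"].stage_distribution["IV"], 0.0345),
    # epidemiology and demography
    (lambda p: p.epidemiology.total_population, 7333200),
    (lambda p: p.epidemiology.age_band_fraction, 0.3732),
    (lambda p: p.epidemiology.smoker_fractions["daily"], 0.104),
    (lambda p: p.epidemiology.smoker_fractions["ex"], 0.094),
    (lambda p: p.epidemiology.annual_lc_incidence, 3290),
    (lambda p: p.epidemiology.uptake, 0.465),
    (lambda p: p.epidemiology.adherence_round2plus, 1.0),
    (lambda p: p.epidemiology.mean_entry_age, 58.0),
    (lambda p: p.epidemiology.clinical_stage_distribution["I"], 0.1732),
    (lambda p: p.epidemiology.clinical_stage_distribution["IV"], 0.6331),
    # survival anchors
    (lambda p: p.survival.os5y_by_stage["I"], 0.4795),
    (lambda p: p.survival.os5y_by_stage["II"], 0.3772),
    (lambda p: p.survival.os5y_by_stage["III"], 0.1536),
    (lambda p: p.survival.os5y_by_stage["IV"], 0.0482),
    (lambda p: p.survival.pfs1y_by_stage["I"], 0.7203),
    (lambda p: p.survival.pfs1y_by_stage["III"], 0.4915),
    (lambda p: p.survival.pfs1y_by_stage["IV"], 0.3829),
    # utilities
    (lambda p: p.utilities.preprogression_by_stage["I"], 0.85),
    (lambda p: p.utilities.preprogression_by_stage["II"], 0.83),
    (lambda p: p.utilities.preprogression_by_stage["III"], 0.73),
    (lambda p: p.utilities.preprogression_by_stage["IV"], 0.75),
    (lambda p: p.utilities.postprogression_by_stage["I"], 0.73),
    (lambda p: p.utilities.postprogression_by_stage["IV"], 0.75),
    # unit costs and utilization
    (lambda p: p.costs.ldct_cost, 254.0),
    (lambda p: p.costs.unit_costs["contrast_ct"], 507.0),
    (lambda p: p.costs.unit_costs["pet_ct"], 1331.0),
    (lambda p: p.costs.unit_costs["surgery"], 9310.0),
    (lambda p: p.costs.unit_costs["pembrolizumab"], 6726.0),
    (lambda p: p.costs.unit_costs["gefitinib"], 1084.0),
    (lambda p: p.costs.unit_costs["erlotinib"], 83.0),
    (lambda p: p.costs.utilization["chest_xray"]["postdiagnosis"]["I"], 0.489),
    (lambda p: p.costs.utilization["chest_xray"]["postprogression"]["IV"], 0.575),
    (lambda p: p.costs.utilization["surgery"]["postdiagnosis"]["I"], 0.451),
    (lambda p: p.costs.utilization["bronchoscopy"]["ongoing"]["II"], 0.560),
    (lambda p: p.costs.utilization["gefitinib"]["postdiagnosis"]["IV"], 0.371),
    (lambda p: p.costs.utilization["pemetrexed_platinum"]["postprogression"]["I"], 0.472),
    # economics
    (lambda p: p.econ.discount_rate_costs, 0.035),
    (lambda p: p.econ.cycle_length_months, 3.0),
    (lambda p: p.econ.wtp_low, 24302.0),
    (lambda p: p.econ.wtp_high, 40202.0),
    (lambda p: p.econ.n_screen_rounds, 10),
]

FIDELITY_NONSMOKING = [
    (lambda p: p.scan_tables["first"].p_regular_negative, 0.8257),
    (lambda p: p.scan_tables["first"].p_regular_positive, 0.1743),
    (lambda p: p.scan_tables["first"].p_true_negative, 0.9975),
    (lambda p: p.scan_tables["first"].p_false_negative, 0.0025),
    (lambda p: p.scan_tables["first"].p_true_positive, 0.1399),
    (lambda p: p.scan_tables["first"].p_false_positive, 0.8601),
    (lambda p: p.epidemiology.annual_lc_incidence, 3028),
    (lambda p: p.epidemiology.age_band_fraction, 0.2946),
    (lambda p: p.epidemiology.nonsmoking_pool, 1962185),
    (lambda p: p.epidemiology.nonsmoker_high_risk_fraction, 0.10),
    (lambda p: p.econ.n_screen_rounds, 1),
]


@pytest.mark.parametrize("getter,expected", FIDELITY_SMOKING)
def test_smoking_fixture_matches_printed_inputs(smoking_params, getter, expected):
    assert getter(smoking_params) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("getter,expected", FIDELITY_NONSMOKING)
def test_nonsmoking_fixture_matches_printed_inputs(nonsmoking_params, getter, expected):
    assert getter(nonsmoking_params) == pytest.approx(expected, abs=1e-12)


def test_talent_stage_distribution_renormalized_from_printed_percentages(nonsmoking_params):
    """The printed in-situ/invasive stage mix (19.18/77.36/0.94/0.94/1.57)
    sums to 99.99% from percentage rounding; the loader renormalizes it to
    an exact simplex while preserving the printed proportions."""
    sd = nonsmoking_params.scan_tables["first"].stage_distribution
    assert math.fsum(sd.values()) == pytest.approx(1.0, abs=1e-12)
    assert sd["0"] == pytest.approx(0.1918 / 0.9999, rel=1e-12)
    assert sd["I"] == pytest.approx(0.7736 / 0.9999, rel=1e-12)
    # raw file values equal the printed percentages
    raw = yaml.safe_load(fixture_path("nonsmoking.yaml").read_text())
    raw_sd = {str(k): v for k, v in raw["scan_tables"]["first"]["stage_distribution"].items()}
    assert raw_sd["0"] == 0.1918 and raw_sd["I"] == 0.7736


def test_fixtures_validate_cleanly(smoking_params, nonsmoking_params):
    assert validate_parameters(smoking_params) == []
    assert validate_parameters(nonsmoking_params) == []


def test_validate_flags_utility_out_of_range(smoking_params):
    p = smoking_params.copy()
    p.utilities.preprogression_by_stage["I"] = 1.2
    violations = validate_parameters(p)
    assert len(violations) == 1 and "utilities" in violations[0]


def test_validate_flags_tp_fp_simplex(smoking_params):
    p = smoking_params.copy()
    p.scan_tables["first"].p_true_positive = 0.35
    p.scan_tables["first"].p_false_positive = 0.60
    violations = validate_parameters(p)
    assert any("TP+FP" in v for v in violations)


def test_validate_flags_negative_cost_and_bad_stage(smoking_params):
    p = smoking_params.copy()
    p.costs.unit_costs["surgery"] = -1.0
    p.survival.os5y_by_stage["IV"] = 1.5
    violations = validate_parameters(p)
    assert any("unit_costs[surgery]" in v for v in violations)
    assert any("os5y" in v for v in violations)


def test_load_rejects_bad_stage_distribution(tmp_path, smoking_params):
    p = smoking_params.copy()
    path = tmp_path / "bad.yaml"
    write_parameters(p, path)
    raw = yaml.safe_load(path.read_text())
    raw["scan_tables"]["first"]["stage_distribution"]["I"] = 0.55  # sums to ~0.9
    path.write_text(yaml.safe_dump(raw))
    with pytest.raises(ConfigError, match="stage_distribution"):
        load_parameters(path)


def test_load_missing_key_names_the_key(tmp_path):
    path = tmp_path / "incomplete.yaml"
    path.write_text("cohort_label: smoking\nscan_tables: {}\n")
    with pytest.raises(ConfigError, match="epidemiology"):
        load_parameters(path)


def test_load_missing_file():
    with pytest.raises(ConfigError, match="not found"):
        load_parameters("/nonexistent/pack.yaml")


def test_load_malformed_number(tmp_path, smoking_params):
    path = tmp_path / "bad_number.yaml"
    write_parameters(smoking_params, path)
    raw = yaml.safe_load(path.read_text())
    raw["epidemiology"]["uptake"] = "forty-six percent"
    path.write_text(yaml.safe_dump(raw))
    with pytest.raises(ConfigError, match="uptake"):
        load_parameters(path)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_roundtrip_write_then_load_is_identity(seed, tmp_path_factory):
    """load(write(p)) == p for arbitrary valid packs."""
    p = gen_cohort_fixture(seed, scale=500.0)
    path = tmp_path_factory.mktemp("rt") / f"pack_{seed}.yaml"
    write_parameters(p, path)
    q = load_parameters(path)
    assert q == p


def test_general_population_utility_declines_with_age(smoking_params):
    u = smoking_params.utilities.general_population_utility
    vals = [u(a) for a in range(40, 101, 5)]
    assert all(0.0 < v <= 1.0 for v in vals)
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_life_table_terminal_hazard_reused_beyond_support(smoking_params):
    lt = smoking_params.life_table
    assert lt.annual_q(150) == lt.qx[-1]
    assert lt.annual_q(20) == lt.qx[0]
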