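import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_ols_slope
from consenz.errors import InputError, InsufficientDataError
from consenz.pathway_quant import (
    DEFAULT_STOICHIOMETRY,
    BioconversionSeries,
    annualize,
    conversion_fraction,
    initial_rate,
    read_series_csv,
    stoich_convert,
    write_series_csv,
    yield_per_substrate,
)

compounds = st.sampled_from(["L-Phe", "tCA", "styrene"])
concs = st.floats(min_value=1e-3, max_value=1e5, allow_nan=False)


def test_phe_to_styrene_projection():
    assert stoich_convert(600, "L-Phe", "styrene") == pytest.approx(378.3, abs=0.05)


def test_phe_to_tca():
    assert stoich_convert(100, "L-Phe", "tCA") == pytest.approx(89.69, abs=0.01)


def test_zero_converts_to_zero():
    assert stoich_convert(0, "tCA", "styrene") == 0.0


def test_compound_aliases_resolve():
    assert stoich_convert(100, "phenylalanine", "STYRENE".lower()) == pytest.approx(
        stoich_convert(100, "L-Phe", "styrene")
    )


def test_unknown_compound_rejected():
    with pytest.raises(InputError):
        stoich_convert(1, "glucose", "styrene")


@settings(max_examples=50)
@given(x=concs, a=compounds, b=compounds)
def test_stoich_round_trip(x, a, b):
    back = stoich_convert(stoich_convert(x, a, b), b, a)
    assert back == pytest.approx(x, rel=1e-12)


@settings(max_examples=50)
@given(x=concs)
def test_stoich_chain_consistency(x):
    direct = stoich_convert(x, "L-Phe", "styrene")
    chained = stoich_convert(stoich_convert(x, "L-Phe", "tCA"), "tCA", "styrene")
    assert direct == pytest.approx(chained, rel=1e-12)


def test_yield_styrene_per_glucose():
    assert yield_per_substrate(221, 5) == pytest.approx(44.2)
    assert yield_per_substrate(100, 4) == 25.0
    assert yield_per_substrate(0, 5) == 0.0
    with pytest.raises(InputError):
        yield_per_substrate(1, 0)


def test_initial_rate_exact_line():
    series = BioconversionSeries("tCA", ((0, 100), (1, 75), (2, 50)))
    assert initial_rate(series) == pytest.approx(-25.0)


def test_initial_rate_matches_closed_form_ols():
    rng = np.random.default_rng(3)
    times = [0.0, 0.5, 1.0, 1.5, 2.0]
    concs_ = [100 - 26 * t + rng.normal(0, 2) for t in times]
    series = BioconversionSeries("tCA", tuple(zip(times, concs_)))
    assert initial_rate(series) == pytest.approx(oracle_ols_slope(times, concs_))


def test_initial_rate_window_boundary_inclusive():
    series = BioconversionSeries("tCA", ((0, 100), (2.0, 50), (4.0, 0)))
    # only t=0 and t=2 are in the default window
    assert initial_rate(series) == pytest.approx(-25.0)


def test_initial_rate_ignores_points_outside_window():
    linear = BioconversionSeries("tCA", ((0, 100), (1, 74), (2, 48), (10, 48)))
    assert initial_rate(linear) == pytest.approx(-26.0)


def test_initial_rate_insufficient_data():
    with pytest.raises(InsufficientDataError):
        initial_rate(BioconversionSeries("tCA", ((0, 100), (5, 20))))


def test_conversion_fraction_examples():
    assert conversion_fraction(100, 89.69, "L-Phe", "tCA") == pytest.approx(1.0, abs=1e-3)
    assert conversion_fraction(100, 87, "L-Phe", "tCA") == pytest.approx(0.970, abs=1e-3)
    assert conversion_fraction(100, 0, "L-Phe", "tCA") == 0.0
    with pytest.raises(InputError):
        conversion_fraction(0, 10, "L-Phe", "tCA")


def test_conversion_fraction_above_one_flagged_not_clamped(caplog):
    with caplog.at_level("WARNING"):
        frac = conversion_fraction(100, 95, "L-Phe", "tCA")
    assert frac > 1.0
    assert "exceeds 1" in caplog.text


def test_annualize_rounds_to_significant_figures():
    assert annualize(8.5) == 3100.0
    assert annualize(0) == 0.0
    assert annualize(1, sig_figs=None) == 365.0


def test_series_validation():
    with pytest.raises(InputError):
        BioconversionSeries("tCA", ((1.0, 5.0), (0.5, 4.0)))  # not increasing
    with pytest.raises(InputError):
        BioconversionSeries("tCA", ((0.0, -1.0),))


def test_series_csv_round_trip(tmp_path):
    s1 = BioconversionSeries("tCA", ((0.0, 100.0), (2.0, 48.0)))
    s2 = BioconversionSeries("styrene", ((0.0, 0.0), (2.0, 36.0)))
    path = tmp_path / "series.csv"
    write_series_csv([s1, s2], path)
    loaded = read_series_csv(path)
    assert loaded["tCA"].samples == s1.samples
    assert loaded["styrene"].samples == s2.samples
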