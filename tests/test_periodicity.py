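"""FFT periodicity spectra, peak calling and autocorrelation."""

import numpy as np
import pytest

import satreads as sr
from satreads.periodicity import encode_numeric, reverse_complement
from satreads.simulate import (
    FamilySimSpec,
    HORSpec,
    mutate,
    random_sequence,
    tandem_array,
)


def perfect_tandem(unit: str, copies: int) -> str:
    return unit * copies


# ---------------------------------------------------------------------------
# encoding


def test_numeric_encoding_values():
    np.testing.assert_array_equal(
        encode_numeric("ACGT"), np.array([1.0, 2.0, 3.0, 4.0])
    )
    np.testing.assert_array_equal(
        encode_numeric("ANR"), np.array([1.0, 2.5, 2.5])
    )


# ---------------------------------------------------------------------------
# fft_spectrum


def test_pure_period_four_signal_peaks_at_four():
    spectrum = sr.fft_spectrum(perfect_tandem("ACGT", 2_500))
    assert spectrum.length == 10_000
    assert spectrum.dominant_period() == pytest.approx(4.0)


def test_period_axis_is_length_over_frequency():
    """At L = 30 000, frequency index 600 corresponds to period 50 bp."""
    spectrum = sr.fft_spectrum("ACGT" * 7_500)
    # periods are stored ascending; frequency f maps to period L/f
    f = 600
    idx = np.argmin(np.abs(spectrum.periods - 30_000 / f))
    assert spectrum.periods[idx] == pytest.approx(50.0)
    # and the full axis is exactly L/f for f = 1..L//2
    np.testing.assert_allclose(
        spectrum.periods, 30_000 / np.arange(1, 15_001)[::-1]
    )


def test_noiseless_tandem_maximum_at_unit_length():
    """Closed form: for a noiseless tandem of unit p dividing L, the global
    non-DC spectral maximum sits at period p (or an exact divisor comb line),
    and the fundamental statistic returns p."""
    rng = np.random.default_rng(21)
    for p in (10, 25, 50):
        unit = random_sequence(rng, p, 0.5)
        spectrum = sr.fft_spectrum(perfect_tandem(unit, 2_000 // (p // 5)))
        # every nonzero line lies on the comb f = m * L/p <=> period = p/m
        amps = spectrum.amplitude
        periods = spectrum.periods
        strong = periods[amps > 1e-6 * amps.max()]
        ratios = p / strong
        assert np.allclose(ratios, np.round(ratios), atol=1e-6)
        assert sr.dominant_period(
            spectrum, min_period=3, max_period=2 * p
        ) == pytest.approx(p, abs=0.01)


def test_short_sequence_rejected():
    with pytest.raises(ValueError):
        sr.fft_spectrum("ACG")
    with pytest.raises(ValueError, match="twice"):
        sr.fft_spectrum("ACGT" * 100, max_period_of_interest=300)


def test_monomer_recovery_with_substitution_noise():
    """An 80-bp random monomer tiled to 40 kb with 2% substitutions is
    recovered at 80 +/- 1 bp."""
    rng = np.random.default_rng(17)
    monomer = random_sequence(rng, 80, 0.5)
    sequence = mutate(perfect_tandem(monomer, 500), 0.02, 0.0, rng)
    spectrum = sr.fft_spectrum(sequence)
    assert abs(sr.dominant_period(spectrum) - 80) <= 1


def test_margin_robustness():
    """Appending a 10% non-repetitive margin shifts the dominant period by
    at most 2%."""
    rng = np.random.default_rng(23)
    monomer = random_sequence(rng, 80, 0.5)
    core = mutate(perfect_tandem(monomer, 500), 0.02, 0.0, rng)
    padded = core + random_sequence(rng, len(core) // 10, 0.5)
    d_core = sr.dominant_period(sr.fft_spectrum(core))
    d_padded = sr.dominant_period(sr.fft_spectrum(padded))
    assert abs(d_padded - d_core) / d_core <= 0.02


# ---------------------------------------------------------------------------
# average_spectra


def test_averaging_a_spectrum_with_itself_is_idempotent():
    spectrum = sr.fft_spectrum("ACGT" * 2_500)
    grid = np.arange(2.0, 501.0)
    averaged = sr.average_spectra([spectrum, spectrum], period_grid=grid)
    single = sr.average_spectra([spectrum], period_grid=grid)
    np.testing.assert_allclose(averaged.amplitude, single.amplitude)
    assert averaged.n_arrays == 2
    assert single.n_arrays == 1


def test_two_arrays_same_monomer_average_to_single_peak():
    """Two independently generated 49-bp arrays average to one dominant
    49-bp periodicity."""
    rng = np.random.default_rng(31)
    spectra = []
    for _ in range(2):
        monomer = random_sequence(rng, 49, 0.5)
        seq = mutate(perfect_tandem(monomer, 700), 0.02, 0.0, rng)
        spectra.append(sr.fft_spectrum(seq))
    averaged = sr.average_spectra(spectra)
    assert abs(sr.dominant_period(averaged) - 49) <= 1


def test_average_of_no_spectra_rejected():
    with pytest.raises(ValueError):
        sr.average_spectra([])


# ---------------------------------------------------------------------------
# call_peaks


def test_pure_signal_yields_single_non_harmonic_peak():
    spectrum = sr.fft_spectrum(perfect_tandem("ACGT", 2_500))
    calls = sr.call_peaks(spectrum, min_period=3)
    non_harmonic = [c for c in calls if not c.is_harmonic]
    assert len(non_harmonic) == 1
    assert non_harmonic[0].period == pytest.approx(4.0, abs=0.05)


def test_flat_spectrum_has_no_peaks():
    spectrum = sr.PeriodicitySpectrum(
        periods=np.arange(2.0, 100.0),
        amplitude=np.ones(98),
        length=1_000,
    )
    assert sr.call_peaks(spectrum) == []


def test_hor_creates_unflagged_peak_at_twice_monomer():
    """A two-unit HOR (alternating monomer variants) yields peaks at the
    monomer length (the strongest, never flagged as harmonic) and at twice
    the monomer length (the HOR unit)."""
    rng = np.random.default_rng(7)
    fam = FamilySimSpec("F", 104, substitution_rate=0.02,
                        hor=HORSpec(2, 0.08))
    seq = tandem_array(fam, 41_600, rng)
    spectrum = sr.fft_spectrum(seq)
    calls = sr.call_peaks(spectrum, min_period=10, max_period=500)

    def near(period, tol=2.0):
        return [c for c in calls if abs(c.period - period) <= tol]

    (monomer_peak,) = near(104)
    assert not monomer_peak.is_harmonic
    (hor_peak,) = near(208)
    assert not hor_peak.is_harmonic
    assert monomer_peak.amplitude > hor_peak.amplitude
    # the HOR unit is the fundamental tandem period of an ABAB array
    assert sr.dominant_period(spectrum) == pytest.approx(208, abs=2)


def test_harmonic_flag_points_to_integer_multiple_parent():
    rng = np.random.default_rng(19)
    monomer = random_sequence(rng, 80, 0.5)
    seq = mutate(perfect_tandem(monomer, 500), 0.02, 0.0, rng)
    calls = sr.call_peaks(sr.fft_spectrum(seq), min_period=5, max_period=500)
    flagged = [c for c in calls if c.is_harmonic]
    assert flagged, "a non-sinusoidal tandem must show flagged harmonics"
    for c in flagged:
        m = round(c.parent_period / c.period)
        assert m >= 2
        assert abs(c.parent_period - m * c.period) <= 0.02 * c.parent_period


# ---------------------------------------------------------------------------
# autocorrelation


def test_perfect_tandem_autocorrelation_peaks_at_unit_multiples():
    rng = np.random.default_rng(3)
    unit = random_sequence(rng, 10, 0.5)
    profile = sr.autocorrelation(perfect_tandem(unit, 1_000), max_lag=100)
    values = dict(zip(profile.lags, profile.combined))
    for lag in (10, 20, 30, 50, 100):
        assert values[lag] == pytest.approx(1.0, abs=1e-9)
    off_peak = [v for lag, v in values.items() if lag % 10 != 0]
    assert max(off_peak) < 0.9


def test_lag_axis_spans_two_to_two_thousand():
    seq = random_sequence(np.random.default_rng(4), 5_000, 0.5)
    profile = sr.autocorrelation(seq)
    assert profile.lags[0] == 2
    assert profile.lags[-1] == 2_000
    assert len(profile.lags) == 1_999
    assert np.abs(profile.combined).max() <= 1.0


def test_random_sequence_autocorrelation_is_white(seed=41):
    """i.i.d. sequence: combined autocorrelation stays within the
    white-noise band at essentially all lags."""
    L = 40_000
    seq = random_sequence(np.random.default_rng(seed), L, 0.5)
    profile = sr.autocorrelation(seq, max_lag=2_000)
    bound = 3.0 / np.sqrt(L)
    exceed = np.mean(np.abs(profile.combined) > bound)
    assert exceed < 0.01
    assert np.abs(profile.combined).max() < 6.0 / np.sqrt(L)


def test_sequence_not_longer_than_max_lag_rejected():
    with pytest.raises(ValueError):
        sr.autocorrelation("ACGT" * 100, max_lag=400)


# ---------------------------------------------------------------------------
# select_long_arrays


def test_selection_threshold_and_orientation(noise_free_sim, annotated):
    reads = {r.read_id: r.sequence for r in noise_free_sim["reads"]}
    arrays = annotated["arrays"]
    selected = sr.select_long_arrays(arrays, reads, min_length=30_000)
    assert all(a.length >= 30_000 for a, _ in selected)
    assert {a.length for a in arrays if a.length < 30_000}, \
        "fixture should include short arrays too"
    for array, seq in selected:
        raw = reads[array.read_id][array.start : array.end]
        if array.orientation == "forward":
            assert seq == raw
        else:
            assert seq == reverse_complement(raw)


def test_out_of_bounds_array_rejected():
    arrays = [sr.RepeatArray("r", "f", 0, 2_000, "forward")]
    with pytest.raises(ValueError):
        sr.select_long_arrays(arrays, {"r": "ACGT" * 100}, min_length=100)
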