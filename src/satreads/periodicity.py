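"""Sequence periodicity of long satellite arrays.

A tandem array whose monomer is p bp long is, after numeric encoding of the
bases, a nearly periodic signal; its discrete Fourier transform shows
amplitude peaks at frequency indices f with period T = L / f equal to the
monomer length and to any higher-order repeat (HOR) length, i.e. a
homogenization unit spanning several monomers.  Because the 1/2/3/4
encoding is far from sinusoidal, genuine periods are accompanied by
higher harmonics at T/m; peak calls therefore carry a harmonic flag.
An autocorrelation of per-nucleotide indicator tracks provides an
independent view of the same periodicities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.tsa.stattools import acf as _acf

from .annotation import RepeatArray

DEFAULT_MIN_ARRAY_LENGTH = 30_000
DEFAULT_MAX_LAG = 2_000
DEFAULT_MIN_LAG = 2
DEFAULT_PROMINENCE_FACTOR = 5.0
DEFAULT_HARMONIC_TOLERANCE = 0.02

#: Integer encoding of the four bases; ambiguity codes get the mean value
#: 2.5 so they contribute no spectral bias of their own.
BASE_VALUES = {"A": 1.0, "C": 2.0, "G": 3.0, "T": 4.0}
AMBIGUOUS_FILL = 2.5

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def encode_numeric(sequence: str) -> np.ndarray:
    """Map A,C,G,T -> 1,2,3,4; ambiguity codes -> 2.5."""
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, AMBIGUOUS_FILL)
    for base, value in BASE_VALUES.items():
        table[ord(base)] = value
    return table[raw]


def encode_indicator(sequence: str, base: str) -> np.ndarray:
    """Indicator track: 1.0 where the sequence equals ``base``, else 0.0."""
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return (raw == ord(base)).astype(float)


@dataclass
class PeriodicitySpectrum:
    """Amplitude as a function of period T = L/f.

    ``periods`` is stored in ascending period order (descending frequency);
    the DC term (f = 0) is excluded.  ``n_arrays`` is 1 for a single array
    and the number of averaged arrays otherwise.
    """

    periods: np.ndarray
    amplitude: np.ndarray
    length: int
    n_arrays: int = 1
    family_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.periods <= 0) or np.any(np.diff(self.periods) <= 0):
            raise ValueError("period axis must be positive and increasing")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    def dominant_period(
        self, min_period: float | None = None, max_period: float | None = None
    ) -> float:
        """Period of the highest amplitude, optionally within a band."""
        mask = np.ones(len(self.periods), dtype=bool)
        if min_period is not None:
            mask &= self.periods >= min_period
        if max_period is not None:
            mask &= self.periods <= max_period
        if not mask.any():
            raise ValueError("no spectral points in the requested period band")
        idx = np.flatnonzero(mask)[np.argmax(self.amplitude[mask])]
        return float(self.periods[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": self.family_id,
                "period_bp": self.periods,
                "amplitude": self.amplitude,
                "n_arrays": self.n_arrays,
            }
        )


@dataclass
class AutocorrProfile:
    """Autocorrelation of the four per-nucleotide indicator tracks."""

    lags: np.ndarray
    tracks: dict[str, np.ndarray]   # base -> autocorrelation per lag
    combined: np.ndarray            # unweighted mean of the four tracks
    family_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"family_id": self.family_id, "lag": self.lags})
        for base in "ACGT":
            frame[f"acf_{base}"] = self.tracks[base]
        frame["acf_combined"] = self.combined
        return frame


@dataclass(frozen=True)
class PeakCall:
    """One accepted spectral peak."""

    period: float
    amplitude: float
    prominence: float
    is_harmonic: bool = False
    parent_period: float | None = None


# ---------------------------------------------------------------------------
# array selection


def select_long_arrays(
    arrays: Iterable[RepeatArray],
    read_sequences: Mapping[str, str],
    min_length: int = DEFAULT_MIN_ARRAY_LENGTH,
) -> list[tuple[RepeatArray, str]]:
    """Extract the sequences of arrays >= ``min_length`` bp.

    Reverse-oriented arrays are reverse-complemented so every returned
    sequence is in the family's forward orientation.
    """
    out = []
    for array in arrays:
        if array.length < min_length:
            continue
        seq = read_sequences[array.read_id]
        if array.end > len(seq):
            raise ValueError(
                f"array [{array.start}, {array.end}) exceeds read "
                f"{array.read_id} of length {len(seq)}"
            )
        sub = seq[array.start : array.end]
        if array.orientation == "reverse":
            sub = reverse_complement(sub)
        out.append((array, sub))
    return out


# ---------------------------------------------------------------------------
# FFT spectrum


def fft_spectrum(
    sequence: str,
    max_period_of_interest: int | None = None,
    family_id: str = "",
) -> PeriodicitySpectrum:
    """Amplitude spectrum of the numerically encoded sequence.

    The sequence is encoded 1/2/3/4, mean-subtracted (removing the
    uninformative zero-frequency term), Fourier-transformed, and the
    frequency axis converted to periods T = L/f for f = 1..L//2.  The
    sequence must be at least twice ``max_period_of_interest`` long so the
    longest period of interest completes two cycles.
    """
    L = len(sequence)
    if max_period_of_interest is not None and L < 2 * max_period_of_interest:
        raise ValueError(
            f"sequence of {L} bp is shorter than twice the maximum period "
            f"of interest ({max_period_of_interest} bp)"
        )
    if L < 4:
        raise ValueError("sequence too short for a periodicity spectrum")
    x = encode_numeric(sequence)
    x = x - x.mean()
    amplitude = np.abs(np.fft.rfft(x))[1 : L // 2 + 1]
    f = np.arange(1, L // 2 + 1)
    periods = L / f
    # ascending period order
    return PeriodicitySpectrum(
        periods[::-1].copy(), amplitude[::-1].copy(), L, 1, family_id
    )


def average_spectra(
    spectra: Sequence[PeriodicitySpectrum],
    period_grid: np.ndarray | None = None,
    family_id: str = "",
) -> PeriodicitySpectrum:
    """Unweighted average of spectra on a common period grid.

    Arrays differ in length and hence in native period grids, so each
    spectrum is linearly interpolated onto ``period_grid`` (default: 2 to
    2000 bp in 1-bp steps) before averaging.  ``n_arrays`` records how many
    spectra (arrays) entered the average.
    """
    if not spectra:
        raise ValueError("average_spectra requires at least one spectrum")
    if period_grid is None:
        period_grid = np.arange(2.0, 2001.0)
    period_grid = np.asarray(period_grid, dtype=float)
    stack = np.stack(
        [np.interp(period_grid, s.periods, s.amplitude) for s in spectra]
    )
    n = sum(s.n_arrays for s in spectra)
    return PeriodicitySpectrum(
        period_grid.copy(), stack.mean(axis=0),
        int(np.mean([s.length for s in spectra])), n, family_id,
    )


# ---------------------------------------------------------------------------
# peak calling


def _refine_period(spectrum: PeriodicitySpectrum, idx: int) -> float:
    """Amplitude-weighted centroid over the peak bin and its neighbours.

    Indel noise spreads a periodicity over adjacent bins; the centroid is a
    better point estimate than the single maximal bin.
    """
    lo, hi = max(idx - 1, 0), min(idx + 2, len(spectrum.periods))
    w = spectrum.amplitude[lo:hi]
    p = spectrum.periods[lo:hi]
    if w.sum() == 0:
        return float(spectrum.periods[idx])
    return float((w * p).sum() / w.sum())


def call_peaks(
    spectrum: PeriodicitySpectrum,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    harmonic_tolerance: float = DEFAULT_HARMONIC_TOLERANCE,
    min_period: float | None = None,
    max_period: float | None = None,
    max_harmonic_order: int = 12,
) -> list[PeakCall]:
    """Local spectral maxima above ``prominence_factor`` x median amplitude.

    A peak at period p is flagged as a harmonic when an accepted peak of at
    least equal amplitude exists near m*p (integer m >= 2, relative
    tolerance ``harmonic_tolerance``): the non-sinusoidal base encoding
    makes every true period echo at integer fractions of itself, and those
    echoes are weaker than their fundamental.  A genuine shorter period
    (e.g. a monomer beneath its HOR multiple) is stronger than the longer
    peak and is therefore not suppressed.  Peak periods are refined by an
    amplitude-weighted centroid over the neighbouring bins.
    """
    amp = spectrum.amplitude
    if len(amp) < 3:
        return []
    threshold = prominence_factor * float(np.median(amp))
    idxs, props = find_peaks(amp, height=max(threshold, 1e-12))
    if idxs.size == 0:
        return []
    prominences = props.get("peak_heights", amp[idxs]) - np.median(amp)

    accepted = []
    for idx, prom in zip(idxs, prominences):
        period = _refine_period(spectrum, int(idx))
        if min_period is not None and period < min_period:
            continue
        if max_period is not None and period > max_period:
            continue
        accepted.append((period, float(amp[idx]), float(prom)))

    calls: list[PeakCall] = []
    for period, amplitude, prom in accepted:
        is_harmonic = False
        parent = None
        for m in range(2, max_harmonic_order + 1):
            target = m * period
            for other_period, other_amp, _ in accepted:
                if other_period <= period:
                    continue
                if (
                    abs(other_period - target) <= harmonic_tolerance * target
                    and other_amp >= amplitude
                ):
                    is_harmonic = True
                    parent = other_period
                    break
            if is_harmonic:
                break
        calls.append(PeakCall(period, amplitude, prom, is_harmonic, parent))
    calls.sort(key=lambda c: -c.amplitude)
    return calls


def dominant_period(
    spectrum: PeriodicitySpectrum,
    min_period: float = 10.0,
    max_period: float = 500.0,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
    harmonic_tolerance: float = DEFAULT_HARMONIC_TOLERANCE,
) -> float:
    """Fundamental tandem-unit length within a period band.

    The repeated unit of a tandem array shows up as a comb of peaks at
    integer fractions of the unit length, and because the base encoding is
    non-sinusoidal the strongest single line is frequently one of the
    higher harmonics, not the fundamental itself.  The fundamental is
    therefore scored as in harmonic-sum pitch detection: each candidate
    peak is credited with the total amplitude of every accepted peak lying
    on its harmonic series (periods ~ p/m, m >= 1), and the candidate with
    the greatest series total wins.  The series of the true unit length
    contains all of its harmonics, so it dominates any of its own
    sub-periods regardless of how amplitude fluctuates among them.

    Falls back to the raw band maximum when no peak passes the prominence
    screen.
    """
    calls = call_peaks(spectrum, prominence_factor, harmonic_tolerance)
    candidates = [c for c in calls if min_period <= c.period <= max_period]
    if not candidates:
        return spectrum.dominant_period(min_period, max_period)

    def series_total(period: float) -> float:
        total = 0.0
        for other in calls:
            if other.period > period * (1 + harmonic_tolerance):
                continue
            m = max(1, round(period / other.period))
            if abs(period - m * other.period) <= harmonic_tolerance * m * other.period:
                total += other.amplitude
        return total

    best = max(candidates, key=lambda c: (series_total(c.period), c.amplitude))
    return best.period


def peaks_to_frame(calls: Iterable[PeakCall], family_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            (family_id, c.period, c.amplitude, c.is_harmonic,
             float("nan") if c.parent_period is None else c.parent_period)
            for c in calls
        ],
        columns=["family_id", "period_bp", "amplitude", "is_harmonic",
                 "parent_period"],
    )


# ---------------------------------------------------------------------------
# autocorrelation


def autocorrelation(
    sequence: str,
    max_lag: int = DEFAULT_MAX_LAG,
    min_lag: int = DEFAULT_MIN_LAG,
    family_id: str = "",
) -> AutocorrProfile:
    """Autocorrelation of the four per-base indicator tracks.

    Each base N in {A, C, G, T} yields a 0/1 track (1 where the sequence
    equals N); the autocorrelation of each track is computed with the
    standard biased normalization over lags ``min_lag``..``max_lag``
    (default 2..2000) and the four tracks are combined by unweighted mean.
    A perfect tandem of unit p gives combined value 1 at every multiple
    of p.
    """
    L = len(sequence)
    if L <= max_lag:
        raise ValueError(f"sequence of {L} bp is not longer than max_lag {max_lag}")
    lags = np.arange(min_lag, max_lag + 1)
    tracks = {}
    for base in "ACGT":
        track = encode_indicator(sequence, base)
        if np.allclose(track.var(), 0):
            tracks[base] = np.zeros(len(lags))
            continue
        # lag-adjusted normalization so a perfect tandem of unit p scores
        # exactly 1 at lag p; clipped to the correlation range
        values = _acf(track, nlags=max_lag, fft=True, adjusted=True)
        tracks[base] = np.clip(values[min_lag : max_lag + 1], -1.0, 1.0)
    combined = np.mean([tracks[b] for b in "ACGT"], axis=0)
    return AutocorrProfile(lags, tracks, combined, family_id)
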