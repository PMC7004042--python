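"""Periodicity of long arrays: FFT spectra, peak calls and autocorrelation.

A tandem array's monomer length appears as the fundamental of a comb of
spectral peaks (period T = L/f); higher harmonics at T/m are artifacts of
the non-sinusoidal 1/2/3/4 base encoding and are flagged.  A higher-order
repeat (HOR; here two alternating monomer variants) adds a genuine peak at
twice the monomer length.  The autocorrelation of the four base-indicator
tracks shows the same periodicities as maxima at multiples of the unit.
"""

import numpy as np

import satreads as sr
from satreads.simulate import FamilySimSpec, HORSpec, mutate, random_sequence, tandem_array

rng = np.random.default_rng(0)

# a plain 80-bp satellite with 2% substitution noise
monomer = random_sequence(rng, 80, 0.5)
plain = mutate(monomer * 500, 0.02, 0.0, rng)
spectrum = sr.fft_spectrum(plain)
print(f"plain array  (L={len(plain)}): fundamental period = "
      f"{sr.dominant_period(spectrum):.1f} bp (planted 80)")

# a 104-bp satellite with a two-unit HOR
fam = FamilySimSpec("demo", 104, substitution_rate=0.02, hor=HORSpec(2, 0.08))
hor_seq = tandem_array(fam, 41_600, rng)
calls = sr.call_peaks(sr.fft_spectrum(hor_seq), min_period=10, max_period=500)
print(f"\nHOR array (L={len(hor_seq)}): top peaks in 10-500 bp")
for c in sorted(calls, key=lambda c: -c.amplitude)[:6]:
    flag = f"harmonic of {c.parent_period:.0f}" if c.is_harmonic else "genuine"
    print(f"  period {c.period:>7.1f} bp  amplitude {c.amplitude:>9.0f}  {flag}")
print(f"fundamental = {sr.dominant_period(sr.fft_spectrum(hor_seq)):.1f} bp "
      "(the 208-bp HOR unit; the 104-bp monomer peak stays unflagged)")

# autocorrelation view of the plain array
profile = sr.autocorrelation(plain, max_lag=400)
values = dict(zip(profile.lags, profile.combined))
print("\nautocorrelation of the plain array at multiples of 80:",
      [round(float(values[k]), 2) for k in (80, 160, 240, 320, 400)])
print("and at three off-period lags:",
      [round(float(values[k]), 2) for k in (50, 110, 290)])
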