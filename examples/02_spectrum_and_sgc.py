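"""Dominant-period classification and the spectral gravity center (SGC).

Builds one 24-h-dominant and one 12-h-dominant hourly record, estimates
their spectra with a 90% bootstrap envelope, and compares their SGC — the
density-weighted mean period, which sits higher when spectral energy is
concentrated in the circadian range.
"""

import circatemp as ct

t24 = ct.RhythmTruth(mesor=35.0, amp24=1.0, phase24=3.0, noise_sd=0.4,
                     noise_autocorr=0.0)
t12 = ct.RhythmTruth(mesor=35.0, amp24=0.0, phase24=0.0, amp12=1.0,
                     phase12=3.0, noise_sd=0.4, noise_autocorr=0.0)

for label, truth in [("24-h dominant", t24), ("12-h dominant", t12)]:
    series = ct.generate_temperature_series(truth, n_days=7, resolution=60, seed=7)
    hourly = ct.hourly_means(series)
    est = ct.estimate_spectrum(hourly, n_resamples=200, seed=11)
    print(f"{label}: dominant period {est.dominant_period:5.2f} h "
          f"-> {est.dominant_class.value}, SGC {est.sgc:5.2f} h")

print()
print("A record needs at least 72 retained hours (three circadian cycles);")
print("the SGC summarises where the spectrum's mass sits on the 2-54 h grid,")
print("so the 24-h-dominant record scores the higher value.")
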