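"""delta-13C del-notation conversions and upcore trend classification of
methane isotope profiles.
"""
import numpy as np

from seepscape import DepthGrid, IsotopeProfile, classify_trend, delta13c, ratio_from_delta

# del notation: ratio <-> per-mil round trip
ratio = ratio_from_delta(-60.0)
print(f"a -60 permil methane has 13C/12C = {ratio:.7f} "
      f"(back-converts to {delta13c(ratio):+.1f} permil)")

depths = DepthGrid(np.array([1.5, 4.5, 7.5, 10.5, 13.5]))

# heavier methane toward the surface: oxidizers consumed the light isotope
oxidizing = IsotopeProfile(depths, np.array([-48.0, -52.0, -55.0, -58.0, -60.0]))
call = classify_trend(oxidizing)
print(f"Mat-style core: {call.trend} -> {call.interpretation} "
      f"(slope {call.slope_permil_per_cm:+.2f} permil/cm)")

# lighter methane toward the surface: fresh biogenic methane added upcore
methanogenic = IsotopeProfile(depths, np.array([-68.0, -64.0, -61.0, -58.0, -56.0]))
call = classify_trend(methanogenic)
print(f"Edge-style core: {call.trend} -> {call.interpretation}")

# a lone heavy surface point does not make a trend
excursion = IsotopeProfile(depths, np.array([-47.0, -65.0, -64.0, -63.0, -62.0]))
call = classify_trend(excursion)
print(f"surface-excursion core: {call.trend} ({call.reason})")
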