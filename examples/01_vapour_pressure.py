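"""Convert logger humidity readings to vapour pressure.

Indoor loggers record relative humidity; gridded climatologies ship vapour
pressure.  The Magnus saturation formula puts both on the same hPa scale.
"""

from climalogue import saturation_vapour_pressure, vapour_pressure

for t in (0.0, 10.0, 20.0, 30.0):
    print(f"saturation vapour pressure at {t:5.1f} C: {saturation_vapour_pressure(t):7.3f} hPa")

t, rh = 21.5, 48.0
vp = vapour_pressure(t, rh)
print(f"\na living room at {t} C and {rh}% RH holds {vp:.2f} hPa of water vapour")
print("(that is the 'vp' value every seasonal profile in this package carries)")
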