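"""The single-wavelength saturation correction, step by step.

OGB-1 (K_d = 240 nM, dynamic range gamma = 6) is far from linear over
the physiological range, so a fluorescence peak cannot be scaled
directly into nM. Knowing [Ca2+]0 from FLIM pins the resting point on
the saturation curve; the dye ceiling F_max and then the peak [Ca2+]
follow in closed form.
"""

import flimca as fc

ca0 = 31.0      # resting [Ca2+] from the FLIM readout, nM
f_rest = 1.0    # resting intensity, arbitrary units
f_peak = 1.9    # evoked peak intensity, same units

f_max = fc.estimate_fmax(f_rest, ca0)
print(f"F_max = F_rest (ca0 + Kd)/(ca0 + Kd/gamma) = {f_max:.3f} "
      f"(= 271/71 at ca0 = 31 nM)")

ca_peak = fc.estimate_peak(f_peak, f_max)
delta = ca_peak - ca0
print(f"[Ca2+]_peak = Kd (F_peak - F_max/gamma)/(F_max - F_peak) "
      f"= {ca_peak:.1f} nM")
print(f"d[Ca2+] = {delta:.1f} nM")

# the two equations are mutual inverses of the saturation curve:
f_check = f_max * fc.saturation_fluorescence(ca_peak) \
    / fc.saturation_fluorescence(1e12)
print(f"round trip F(ca_peak) = {f_check:.3f} (= F_peak {f_peak})")

# and the correction matters: a naive linear reading would give
naive = ca0 * f_peak / f_rest
print(f"naive linear estimate would be {naive:.1f} nM "
      f"({100 * (naive / ca_peak - 1):+.0f}% off)")
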