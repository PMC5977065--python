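"""Build the four-factor central composite design and inspect its coding.

The four extraction variables (ammonia concentration, ethanol
concentration, return time, liquid-solid ratio) are mapped to
dimensionless coded units x = (z - center) / step, so the design is a
symmetric lattice: 16 factorial corners at +-1, 8 axial points at +-2,
and 6 centre replicates.
"""

import extractopt as xo

factors = xo.glycyrrhizic_factors()
design = xo.build_ccd(factors, axial_distance=2.0, n_center=6)

print(f"{len(design)} runs "
      f"({sum(p.kind == 'factorial' for p in design.points)} factorial, "
      f"{sum(p.kind == 'axial' for p in design.points)} axial, "
      f"{sum(p.kind == 'center' for p in design.points)} centre)")

for f in factors:
    print(f"  {f.name}: centre {f.center} {f.unit}, one coded unit = {f.step} {f.unit}, "
          f"actual range [{f.actual_min}, {f.actual_max}]")

# Coding round-trip: the reported optimum ammonia level in coded units.
x = xo.code_value(0.595, factors[0])
print(f"ammonia 0.595% is coded {x:+.2f}; decoding back gives "
      f"{xo.decode_value(x, factors[0])}%")

# Centre-point replicates summarize run-to-run repeatability.
data = xo.glycyrrhizic_ccd()
mean, rsd = xo.center_point_stats(data)
print(f"centre replicates: mean {mean:.2f} mg, RSD {rsd:.2f}% "
      "(sub-1% RSD indicates a stable extraction protocol)")
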