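"""Size a ring-light stimulus so it lands on the perifovea.

The perifovea (1.25-2.75 mm from the foveal centre) holds the highest
density of melanopsin ipRGCs; a ring of LEDs viewed coaxially stimulates
exactly that annulus if its diameter matches the viewing distance.
"""

import chromapupil as cp

# Where does a 3 cm ring land when viewed from 15 cm?
landing = cp.ring_landing_annulus(cp.RingStimulusGeometry(3.0, 15.0))
print(f"3 cm ring at 15 cm -> {landing.eccentricity_mm:.3f} mm eccentricity "
      f"({'inside' if landing.in_band else 'outside'} the perifoveal band)")

# Inverse design: which diameter targets the band midpoint (2.0 mm)?
d = cp.ring_diameter_for_eccentricity(2.0, eye_distance_cm=15.0)
print(f"diameter targeting 2.0 mm: {d:.2f} cm")

# Sanity check for the ambient lamp: an off-axis source 8 cm below the line
# of sight must NOT reach the perifovea (it only lights the eye for the camera).
print("ambient source at 8 cm offset reaches band:",
      cp.source_in_band(8.0, 15.0))

# Expected output: the 3 cm ring lands at ~1.667 mm (in band), a ~3.6 cm ring
# targets the band midpoint, and the ambient lamp misses the band entirely.
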