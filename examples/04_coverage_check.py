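"""Would this treatment zone have covered a given tumor with margin?

Places two hypothetical spherical tumors inside an indented zone and asks
whether each is covered with a 5 mm safety margin everywhere. The verdict,
the minimum achieved margin and the first failing location are reported --
the acute treatment-control question the inscribed-sphere concept answers.
"""

import ablazone as az

zone, _ = az.make_notched_sphere(20.0, 6.0, through=False, spacing=(1.0, 1.0, 0.5))
ins = az.largest_inscribed_sphere(zone)
print(f"zone inscribed sphere: {ins.diameter_mm:.1f} mm at {ins.center.round(1)}")

# a tumor sized to the treatable-tumor sphere, placed at the Chebyshev center
tumor_ok = az.treatable_tumor_sphere(ins, margin_mm=5.0)
res = az.coverage_check(zone, tumor_ok, margin_mm=5.0)
print(f"\n{tumor_ok.diameter_mm:.1f} mm tumor at the Chebyshev center: "
      f"{'covered' if res.covered else 'NOT covered'} "
      f"(minimum achieved margin {res.min_margin_mm:.1f} mm)")

# the same tumor shifted 6 mm toward the indentation
import numpy as np
shifted = az.TumorSphere(ins.center + np.array([6.0, 0.0, 0.0]),
                         tumor_ok.diameter_mm, 5.0)
res2 = az.coverage_check(zone, shifted, margin_mm=5.0)
print(f"same tumor shifted 6 mm toward the notch: "
      f"{'covered' if res2.covered else 'NOT covered'} "
      f"(minimum achieved margin {res2.min_margin_mm:.1f} mm)")
if res2.first_failure is not None:
    print(f"first failing location (mm): {res2.first_failure.round(1)}")
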