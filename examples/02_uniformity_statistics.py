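"""Coverage-uniformity statistics on a toy depth vector.

Walks the worked example depth [1, 1, 2, 4]: the Lorenz curve of the
sorted depths, the Gini coefficient from the area between the curve and
the diagonal, and the coefficient of variation.  A Gini of 0 and CV of
0 % would mean perfectly even coverage; higher values mean more of the
sequenced bases pile onto fewer genome positions.
"""

import numpy as np

from emda import (
    DepthVector,
    coefficient_of_variation,
    gini,
    lorenz_curve,
    uniformity_report,
)

dv = DepthVector("toy", np.array([1, 1, 2, 4], dtype=np.int64))
curve = lorenz_curve(dv)
print("Lorenz curve points (cumulative genome fraction, base fraction):")
for x, y in zip(curve.x, curve.y):
    print(f"  ({x:.3f}, {y:.4f})")
print(f"Gini (standard, 2 x area) : {gini(curve, 'standard'):.4f}")
print(f"Gini (raw area)           : {gini(curve, 'area'):.5f}")
print(f"CV of per-position depth  : {coefficient_of_variation(dv):.3f} %")

even = DepthVector("even", np.full(4, 2, dtype=np.int64))
report = uniformity_report(even)
print(f"\nconstant depth [2,2,2,2]  : breadth {report.breadth_percent:.0f} %, "
      f"CV {report.cv_percent:.0f} %, Gini {report.gini:.0f} "
      "(the diagonal: perfect uniformity)")
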