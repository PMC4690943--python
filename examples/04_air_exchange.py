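"""Residential air exchange rate from house attributes, step by step.

Walks the leakage chain — normalized leakage from construction year and floor
area, effective leakage area, infiltration flow from stack and wind drivers —
for a leaky older home and a tight newer one.
"""

import airtier as at
from airtier.aer import building_height, house_volume_liters

coeffs = at.LeakageCoefficients()
t_in, t_out, wind = 23.6, 5.0, 3.0  # deg C indoor/outdoor, m/s

for label, year, area, stories, shelter in [
    ("1948 farmhouse", 1948, 140.0, 1, 1),
    ("2008 suburban", 2008, 220.0, 2, 4),
]:
    nl = at.normalized_leakage(year, area, income_low=False, coeffs=coeffs)
    h = building_height(stories)
    a_inf = at.leakage_area(nl, area, h)
    q = at.infiltration_flow(a_inf, coeffs.k_s(stories), coeffs.k_w(stories, shelter),
                             t_in, t_out, wind)
    aer = at.air_exchange_rate(q, house_volume_liters(area, stories))
    print(f"{label}: NL {nl:.3f}, leakage area {a_inf:.0f} cm2, "
          f"flow {q:.1f} L/s, AER {aer:.2f} 1/h")
# Older, lower construction-year homes have exponentially larger normalized
# leakage, hence more infiltration and faster exchange with outdoor air -- the
# driver of block-to-block variation in indoor exposure.
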