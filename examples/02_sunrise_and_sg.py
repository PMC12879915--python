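"""The two measurement-level primitives: solar sunrise and SG correction.

Prints sunrise for a lowland-Bolivia location across the study window and a
worked specific-gravity correction.
"""

import datetime as dt

from cortrhythm import SolarContext, compute_sunrise, correct_specific_gravity

for month in (9, 10, 11, 12):
    ctx = SolarContext(latitude=-14.9, longitude=-66.8, utc_offset_h=-4,
                       date=dt.date(2023, month, 15))
    print(f"2023-{month:02d}-15 sunrise: {compute_sunrise(ctx)}")

raw = 100_000.0          # pg/mL from the assay
sg_sample = 1.010        # dilute urine
sg_target = 1.020        # population mean
corrected = correct_specific_gravity(raw, sg_sample, sg_target)
print(f"\nraw {raw:.0f} pg/mL at SG {sg_sample} -> "
      f"{corrected:.0f} pg/mL at population SG {sg_target}")
# The sample is more dilute than the population average, so the corrected
# concentration is higher than the raw reading.
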