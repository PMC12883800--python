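"""Published county-level survey statistics used as fixed test inputs.

The 2019–2020 transition block (counts of forest sub-compartments moving
between the five vegetation cover types across one year of a county-wide
inventory) and the sample-composition table of the same survey.  Class
order: Arbor, Shrub, Bamboo, Bare, Other.
"""

import numpy as np

TRANSITIONS_2019_2020 = np.array(
    [
        [318154, 248, 231, 243, 231],
        [26, 17029, 25, 27, 25],
        [5, 8, 2705, 4, 4],
        [3, 2, 0, 1186, 3],
        [5, 1, 3, 2, 418],
    ],
    dtype=int,
)

#: Full study-area FSC counts per class and their printed percentage shares.
STUDY_AREA_COUNTS = (319107, 17132, 2726, 1194, 429)
STUDY_AREA_SHARES_PCT = (93.69, 5.03, 0.80, 0.35, 0.13)

#: Rebalanced training-sample counts per class and printed shares.
TRAINING_COUNTS = (1803, 1645, 574, 30, 58)
TRAINING_SHARES_PCT = (43.87, 40.02, 13.97, 0.73, 1.41)

#: Field-verified change accounting for 2019–2020: changes identified by
#: ground survey, of which the algorithm detected / missed.
CHANGES_IDENTIFIED = 329
CHANGES_DETECTED = 273
CHANGES_MISSED = 56

#: Printed retention/conversion percentages for the 2019–2020 block.
RETENTION_PCT = {"Arbor": 99.70, "Shrub": 99.4, "Bamboo": 99.23, "Bare": 99.33}
CONVERSION_PCT = {("Bamboo", "Arbor"): 0.18, ("Shrub", "Arbor"): 0.15}
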