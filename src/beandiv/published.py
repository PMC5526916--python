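"""Published qualitative-trait tables for the Portuguese bean collection.

Printed accession counts per trait state for the three true-type groups
(AP1 Mesoamerican; B1P3, B2P2 Andean), used as worked-example inputs for
the likelihood-ratio chi-square test.
"""

import numpy as np

TRUETYPE_GROUPS = ["AP1", "B1P3", "B2P2"]

#: plain-coat seed colors: white, yellow, pink, light brown, brown, red,
#: purplish red, black (90 plain-coat accessions)
SEED_COAT_COLOR_STATES = ["white", "yellow", "pink", "light_brown",
                          "brown", "red", "purplish_red", "black"]
SEED_COAT_COLOR_COUNTS = np.array([
    [7, 0, 1, 2, 3, 0, 0, 1],
    [4, 1, 2, 0, 0, 5, 1, 0],
    [1, 0, 10, 3, 6, 6, 1, 0],
])

#: seed shapes: round, oval, cuboid, kidney (96 true-type accessions)
SEED_SHAPE_STATES = ["round", "oval", "cuboid", "kidney"]
SEED_SHAPE_COUNTS = np.array([
    [1, 1, 15, 4],
    [0, 1, 17, 7],
    [0, 22, 22, 6],
])

#: growth habit: determinate, indeterminate
GROWTH_HABIT_STATES = ["determinate", "indeterminate"]
GROWTH_HABIT_COUNTS = np.array([
    [12, 9],
    [25, 0],
    [20, 30],
])
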