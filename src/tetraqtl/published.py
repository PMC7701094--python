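"""Published reference values for the blueberry F1 mapping population.

Worked-example inputs from the published autotetraploid highbush
blueberry cross "Sweetcrisp" x "Indigocrisp" (237 F1 individuals, 12
linkage groups): the per-linkage-group map summary and the per-trait
variance components.  These are inputs for demonstration and
arithmetic checks, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

#: per-LG marker counts and map lengths (cM) of the published map
BLUEBERRY_MAP_SUMMARY = pd.DataFrame(
    {
        "lg": list(range(1, 13)),
        "n_markers": [932, 1093, 1060, 826, 1129, 795, 749, 911, 889, 955, 1085, 868],
        "length_cm": [150.40, 189.12, 168.28, 153.23, 187.46, 154.01,
                      128.45, 149.05, 193.78, 151.38, 175.09, 153.72],
    }
)

#: published genotypic and residual variance components per trait
BLUEBERRY_TRAIT_COMPONENTS = {
    "firmness_2018": (298.04, 356.76),
    "firmness_2019": (569.29, 549.37),
    "firmness_retention": (563.38, 192.14),
    "blue_fdf": (0.02, 0.04),
    "delta_fdf": (0.11, 0.22),
}

#: published population size of the F1 cross
BLUEBERRY_N_OFFSPRING = 237
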