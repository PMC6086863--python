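"""Published per-island V-ratio reference table for the Andaman & Nicobar
insectivorous-lizard communities.

The table carries, for each of the 23 surveyed islands, the species
richness, the observed V-ratio, and the null-model mean, variance, tail
proportions and SES reported for that community.  It serves as the input
for desk recomputations (richness-V-ratio correlation, SES arithmetic)
that need no raw field data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILENAME = "andaman_vratio_table.csv"


def load_vratio_reference() -> pd.DataFrame:
    """23 islands x (richness, observed V, null mean/var, tails, SES)."""
    ref = resources.files("nullassembly.data").joinpath(_FILENAME)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
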