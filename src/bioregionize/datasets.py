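"""Bundled example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def amazonian_anuran_scan() -> pd.DataFrame:
    """Published cluster-quality series from an Amazonian anuran
    regionalization (577 species on a 50 × 50 km grid).

    One row per candidate cluster count k = 2..50, with the reported mean
    silhouette width and explained dissimilarity of each clustering solution.
    Used as the worked example for the dual-criterion cluster-count rule,
    which selects k = 7 on this series.
    """
    with resources.files("bioregionize.data").joinpath(
        "amazonian_anuran_scan.csv"
    ).open() as fh:
        return pd.read_csv(fh).set_index("k")


#: ΔAICc values of the six top-ranked multinomial driver models reported for
#: the same Amazonian anuran regionalization (best model first); the worked
#: example for Akaike weights.
AMAZONIAN_DRIVER_DELTA_AICC = (0.0, 6.49, 9.41, 14.06, 25.72, 32.36)
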