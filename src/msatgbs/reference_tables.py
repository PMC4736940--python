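"""Loader for the bundled model-comparison reference table.

The package ships the (K, log-likelihood, AICc, n) summaries of a published
454 microsatellite GBS experiment on Atlantic cod as a worked example for
the AICc / Akaike-weight machinery; ``load_model_tables`` returns them as a
DataFrame with an ``analysis`` column ("yield" or "correspondence").
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def load_model_tables() -> pd.DataFrame:
    path = files("msatgbs").joinpath("data/cod_gbs_model_tables.csv")
    with path.open() as fh:
        return pd.read_csv(fh, comment="#")
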