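"""Packaged reference series.

Two published mean labeling-index time courses from cumulative EdU
exposure in the regenerating posterior bud of *Alitta virens*, one starting
at 1 day post-amputation and one at 2 days post-amputation.  These are the
desk-scale inputs for reproducing the published cell-cycle parameter
estimates (GF = 85.7%, Ts ~ 1.3 h, Tc ~ 33.2 h at 1 dpa; GF = 76%,
Ts ~ 7.3 h, Tc ~ 25.7 h at 2 dpa).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cumulative_series", "CUMULATIVE_SERIES"]

CUMULATIVE_SERIES = ("1dpa", "2dpa")


def load_cumulative_series(start_stage: str) -> pd.DataFrame:
    """Load a packaged cumulative-labeling mean-LI series.

    Parameters
    ----------
    start_stage : {"1dpa", "2dpa"}
        Regeneration stage at which continuous exposure began.

    Returns
    -------
    pandas.DataFrame with columns ``time_h``, ``li_percent``, ``sem_percent``.
    """
    if start_stage not in CUMULATIVE_SERIES:
        raise ValueError(
            f"start_stage must be one of {CUMULATIVE_SERIES}, got {start_stage!r}"
        )
    ref = resources.files("edukin.data") / f"cumulative_{start_stage}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
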