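"""Climatic demand from monthly temperature extremes.

Thermal stress on a population is summarised as the summed absolute
deviation from a 22 °C reference (an established optimum for human
functioning) of four temperatures: the lowest and highest temperatures of
the coldest month and the lowest and highest temperatures of the hottest
month.  Both cold and heat therefore add demand; a population whose four
extremes all sit at 22 °C has zero demand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_TEMP_C = 22.0

TEMPERATURE_COLUMNS = ("t_cold_low", "t_cold_high", "t_hot_low", "t_hot_high")


def climatic_demand(
    t_cold_low,
    t_cold_high,
    t_hot_low,
    t_hot_high,
    reference: float = REFERENCE_TEMP_C,
):
    """Sum of absolute deviations of the four temperature extremes from ``reference``.

    Accepts scalars or aligned arrays.  Raises ``ValueError`` if a month's
    low exceeds its high.
    """
    tcl, tch, thl, thh = (np.asarray(t, dtype=float) for t in
                          (t_cold_low, t_cold_high, t_hot_low, t_hot_high))
    if np.any(tcl > tch):
        raise ValueError("coldest-month low exceeds coldest-month high")
    if np.any(thl > thh):
        raise ValueError("hottest-month low exceeds hottest-month high")
    demand = sum(np.abs(t - reference) for t in (tcl, tch, thl, thh))
    if np.ndim(demand) == 0:
        return float(demand)
    return demand


def demand_table(climate: pd.DataFrame, reference: float = REFERENCE_TEMP_C) -> pd.DataFrame:
    """Per-population demand from a table with ``population_id`` and the four extremes."""
    missing = {"population_id", *TEMPERATURE_COLUMNS} - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns {sorted(missing)}")
    demand = climatic_demand(
        climate["t_cold_low"], climate["t_cold_high"],
        climate["t_hot_low"], climate["t_hot_high"],
        reference=reference,
    )
    return pd.DataFrame(
        {"population_id": climate["population_id"], "climatic_demand": demand}
    )


def read_climate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"population_id", *TEMPERATURE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns {sorted(missing)}")
    return df
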