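"""Published multi-country summary tables, shipped as package data.

These are the printed report-level values (per-country whole-period percent
changes, annual reporting completeness, and 2020 case/stringency
indicators) used as worked examples for the aggregation margins.  They are
inputs to margin computations, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SERVICE_COLUMNS = ["ANC1", "ANC4", "DELIV", "CSEC", "PENTA1", "PENTA3",
                   "MEASLES", "OPD", "IPD"]

WEST = "West Africa"
EAST = "Eastern Africa"


def _read(name: str) -> pd.DataFrame:
    with resources.files("hmispipe.datasets").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_service_changes() -> pd.DataFrame:
    """Whole-period (March-December 2020) percent change per country x service.

    Empty cells (data issues) are NaN.  11 countries; Nigeria is excluded
    from the trend analysis upstream and has no row here.
    """
    return _read("service_changes_2020.csv")


def load_completeness() -> pd.DataFrame:
    """Annual facility-reporting completeness per country, 2017-2020 (long)."""
    return _read("reporting_completeness.csv")


def load_country_indicators() -> pd.DataFrame:
    """2020 cumulative cases per 100k and mean stringency per country."""
    return _read("country_indicators.csv")
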