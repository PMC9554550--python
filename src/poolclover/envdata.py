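"""Per-site environmental feature tables.

The feature set mirrors bioclimatic descriptors of Scandinavian
collection sites: annual mean temperature (degC), annual precipitation
(mm), isothermality (%), precipitation seasonality (CV %), latitude
(degrees) and a snow-coverage feature: the area under the September to
June curve of monthly mean snow thickness (trapezoidal rule, unit
spacing; the unit of the input thickness is carried through verbatim,
giving thickness-unit x months).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNOW_MONTHS = ["Sep", "Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May", "Jun"]


@dataclass(frozen=True)
class SnowSeries:
    """Mean monthly snow thickness at one site, September through June."""

    site_id: str
    thickness: tuple

    def __post_init__(self) -> None:
        if len(self.thickness) != len(SNOW_MONTHS):
            raise ValueError(f"snow series needs {len(SNOW_MONTHS)} monthly values")
        if any(t < 0 for t in self.thickness):
            raise ValueError("snow thickness must be non-negative")


def snow_auc(series: SnowSeries) -> float:
    """Area under the monthly snow-thickness curve (trapezoid, unit months)."""
    return float(np.trapezoid(np.asarray(series.thickness, dtype=float)))


def read_snow_series(path) -> list[SnowSeries]:
    """Long-format TSV with columns site_id, month, thickness."""
    df = pd.read_csv(path, sep="\t")
    order = {m: i for i, m in enumerate(SNOW_MONTHS)}
    out = []
    for site, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("month", key=lambda s: s.map(order))
        out.append(SnowSeries(site_id=str(site), thickness=tuple(grp["thickness"])))
    return out


def build_bioclim_table(
    bioclim: pd.DataFrame,
    snow: list[SnowSeries] | None = None,
) -> pd.DataFrame:
    """Attach the snow AUC feature to a site x variable table."""
    table = bioclim.copy()
    if snow is not None:
        auc = pd.Series({s.site_id: snow_auc(s) for s in snow}, name="snow_auc")
        missing = set(table.index) - set(auc.index)
        if missing:
            raise ValueError(f"sites without snow series: {sorted(missing)}")
        table["snow_auc"] = auc.reindex(table.index)
    if table.isna().any().any():
        raise ValueError("bioclim table must have no missing values")
    return table


def screen_variables(table: pd.DataFrame, min_cv: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Drop variables that barely vary across sites.

    Spread is measured by the coefficient of variation |sd/mean|; for
    signed variables (any negative value, or mean at zero) sd/range is
    used instead, since the CV is meaningless around a zero mean.
    Returns the retained column names and a screening report; a
    zero-variance column is dropped with a note, never an error.
    """
    if table.shape[0] < 3:
        raise ValueError("screening needs at least 3 sites")
    rows = []
    retained = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        rng = float(np.ptp(x))
        mean = float(np.mean(x))
        if sd == 0.0:
            cv, note = 0.0, "zero variance"
        elif (x < 0).any() or mean == 0.0:
            cv, note = sd / rng, "sd/range (signed variable)"
        else:
            cv, note = abs(sd / mean), "|sd/mean|"
        keep = cv >= min_cv
        if keep:
            retained.append(col)
        rows.append({"variable": col, "spread": cv, "measure": note, "retained": keep})
    return retained, pd.DataFrame(rows).set_index("variable")


__all__ = ["SNOW_MONTHS", "SnowSeries", "snow_auc", "read_snow_series",
           "build_bioclim_table", "screen_variables"]
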