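"""Localization table schema and CSV round-trip.

The central record set of the pipeline is a pandas DataFrame with one row per
detected single-molecule event:

======================  =======================================================
column                  meaning
======================  =======================================================
``frame``               0-based camera frame index
``x_nm``, ``y_nm``      coordinates in nm, origin at the field-of-view
                        lower-left corner, x right / y up
``intensity_photons``   background-subtracted integrated spot counts
``sigma_nm``            RMS spot size, sqrt(l1 + l2) of the second-moment
                        matrix (principal moments l1 >= l2)
``asymmetry``           sqrt(l1 / l2) >= 1
``channel``             channel label (string)
======================  =======================================================

Unknown extra columns (e.g. a simulator's ``synapse_id``) are preserved on
read and write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

REQUIRED_COLUMNS = ["frame", "x_nm", "y_nm", "intensity_photons", "sigma_nm", "asymmetry", "channel"]
COORD_COLUMNS = ["x_nm", "y_nm"]
_NUMERIC = ["frame", "x_nm", "y_nm", "intensity_photons", "sigma_nm", "asymmetry"]


def make_table(
    x_nm,
    y_nm,
    frame=0,
    intensity_photons=1.0,
    sigma_nm=150.0,
    asymmetry=1.0,
    channel="A",
    **extra,
) -> pd.DataFrame:
    """Assemble a localization table from arrays; scalars are broadcast."""
    x = np.asarray(x_nm, dtype=float)
    data = {
        "frame": np.broadcast_to(np.asarray(frame), x.shape).astype(int),
        "x_nm": x,
        "y_nm": np.asarray(y_nm, dtype=float),
        "intensity_photons": np.broadcast_to(np.asarray(intensity_photons, dtype=float), x.shape),
        "sigma_nm": np.broadcast_to(np.asarray(sigma_nm, dtype=float), x.shape),
        "asymmetry": np.broadcast_to(np.asarray(asymmetry, dtype=float), x.shape),
        "channel": np.broadcast_to(np.asarray(channel, dtype=object), x.shape),
    }
    for name, vals in extra.items():
        data[name] = np.broadcast_to(np.asarray(vals), x.shape)
    return pd.DataFrame(data)


def validate_table(table: pd.DataFrame, require=REQUIRED_COLUMNS) -> None:
    """Raise :class:`SchemaError` if a required column is absent, or
    :class:`ParseError` if a coordinate is non-finite."""
    for col in require:
        if col not in table.columns:
            raise SchemaError(f"missing required column '{col}'")
    for col in COORD_COLUMNS:
        if col in table.columns and len(table):
            bad = ~np.isfinite(table[col].to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ParseError(f"non-finite coordinate in column '{col}' at row {row}")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV, validating the schema and coordinates."""
    table = pd.read_csv(path)
    for col in _NUMERIC:
        if col in table.columns:
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-numeric value in column '{col}': {exc}") from exc
    if "channel" in table.columns:
        table["channel"] = table["channel"].astype(str)
    validate_table(table)
    return table


def write_localizations(table: pd.DataFrame, path) -> None:
    validate_table(table)
    table.to_csv(path, index=False)
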