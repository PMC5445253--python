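"""Regional grey-matter volume tables and head-size normalization.

Volumes are carried as plain :class:`pandas.DataFrame` objects with a
``subject_id`` column, one column per parcellation measure (mm^3) and a
``tiv`` column (total intracranial volume, mm^3). Normalized tables hold the
same measures expressed as percent of TIV, which removes head-size effects
before any multivariate analysis.
"""

from __future__ import annotations

import logging

import pandas as pd

from .parcellation import ParcellationScheme

__all__ = [
    "validate_volume_table",
    "normalize_to_tiv",
    "read_volume_table",
    "write_volume_table",
]

log = logging.getLogger(__name__)

SUBJECT_COL = "subject_id"
TIV_COL = "tiv"
#: accepted but ignored by the pipeline (descriptive only)
OPTIONAL_COLS = ("whole_brain",)


def validate_volume_table(table: pd.DataFrame, scheme: ParcellationScheme) -> None:
    """Check that *table* carries all scheme measures plus subject id and TIV.

    Raises ``ValueError`` naming each missing or unknown column.
    """
    required = [SUBJECT_COL, *scheme.names, TIV_COL]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"volume table is missing column(s): {', '.join(missing)}")
    known = set(required) | set(OPTIONAL_COLS)
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise ValueError(f"volume table has unknown column(s): {', '.join(unknown)}")
    values = table[scheme.names]
    if (values <= 0).any().any():
        bad = [c for c in scheme.names if (table[c] <= 0).any()]
        raise ValueError(f"non-positive volume(s) in column(s): {', '.join(bad)}")
    if (values.gt(table[TIV_COL], axis=0)).any().any():
        bad = [c for c in scheme.names if (table[c] > table[TIV_COL]).any()]
        raise ValueError(f"measure exceeds TIV in column(s): {', '.join(bad)}")


def normalize_to_tiv(raw: pd.DataFrame, scheme: ParcellationScheme) -> pd.DataFrame:
    """Express each measure as a percentage of total intracranial volume.

    Subjects with missing or non-positive TIV are dropped and logged; row
    order and subject ids are otherwise preserved.
    """
    if TIV_COL not in raw.columns:
        raise ValueError(f"volume table is missing column(s): {TIV_COL}")
    bad = raw[TIV_COL].isna() | (raw[TIV_COL] <= 0)
    validate_volume_table(raw.loc[~bad], scheme)
    if bad.any():
        for sid in raw.loc[bad, SUBJECT_COL]:
            log.warning("subject %s rejected: missing or non-positive TIV", sid)
    kept = raw.loc[~bad]
    out = kept[[SUBJECT_COL]].copy()
    for name in scheme.names:
        out[name] = 100.0 * kept[name] / kept[TIV_COL]
    return out.reset_index(drop=True)


def read_volume_table(path, scheme: ParcellationScheme) -> pd.DataFrame:
    """Read a comma-separated volume table; header order is irrelevant."""
    table = pd.read_csv(path)
    validate_volume_table(table, scheme)
    ordered = [SUBJECT_COL, *scheme.names, TIV_COL]
    ordered += [c for c in OPTIONAL_COLS if c in table.columns]
    return table[ordered]


def write_volume_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
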