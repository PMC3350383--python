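"""Feature-table serialization.

The exchange format for computed features is a TSV with columns
``id``, ``label``, then the 26 feature symbols in canonical order.
Missing values are written as ``NA``; numbers use 6 significant digits
so reruns diff cleanly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector

META_COLUMNS = ("id", "label")


def features_to_frame(rows) -> pd.DataFrame:
    """Build a feature table from ``(id, label, FeatureVector)`` triples."""
    data = []
    for rec_id, label, fv in rows:
        row = {"id": rec_id, "label": label}
        row.update({n: (np.nan if fv[n] is None else fv[n]) for n in FEATURE_NAMES})
        data.append(row)
    return pd.DataFrame(data, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def frame_to_vectors(df: pd.DataFrame):
    """Inverse of :func:`features_to_frame`."""
    out = []
    for _, row in df.iterrows():
        values = {
            n: (None if pd.isna(row[n]) else float(row[n])) for n in FEATURE_NAMES
        }
        out.append((row["id"], row["label"], FeatureVector(values=values)))
    return out


def write_feature_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for n in FEATURE_NAMES:
        out[n] = out[n].map(lambda x: "NA" if pd.isna(x) else f"{x:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"id": str, "label": str})
    missing = (set(META_COLUMNS) | set(FEATURE_NAMES)) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for n in FEATURE_NAMES:
        df[n] = pd.to_numeric(df[n])
    return df
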