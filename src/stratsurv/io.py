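"""Readers and writers for the plain-text interchange formats.

Expression matrices are TSV with gene ids in the first column and sample
ids as remaining column headers; clinical tables are TSV with columns
sample_id, time, event (0/1) and optional grade; gene sets use the GMT
layout (set name, description, tab-separated members).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

__all__ = [
    "read_expression_matrix",
    "read_clinical",
    "read_gmt",
    "read_ihc_table",
]


def read_expression_matrix(path: str | Path,
                           collapse_duplicates: bool = False) -> pd.DataFrame:
    """Load a genes x samples log2 expression TSV.

    Duplicate gene ids are rejected unless ``collapse_duplicates`` is set,
    in which case the duplicate with the highest mean expression is kept
    (probe-to-gene collapse). Malformed numeric cells are reported with
    their row/column coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: malformed numeric cell at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    if numeric.index.duplicated().any():
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        if not collapse_duplicates:
            raise ValueError(f"{path}: duplicate gene ids: {dups[:5]}")
        warnings.warn(f"collapsing {len(dups)} duplicated gene ids by max mean")
        numeric = (numeric.assign(_mean=numeric.mean(axis=1))
                   .sort_values("_mean", ascending=False)
                   .drop(columns="_mean"))
        numeric = numeric[~numeric.index.duplicated(keep="first")]
    if numeric.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    numeric.index.name = "gene_id"
    return numeric


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load the per-sample clinical TSV and validate its invariants."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dups[:5]}")
    times = pd.to_numeric(df["time"], errors="coerce")
    if times.isna().any() or (times <= 0).any():
        offender = df.loc[times.isna() | (times <= 0), "sample_id"].iloc[0]
        raise ValueError(f"{path}: non-positive or malformed time for {offender!r}")
    events = pd.to_numeric(df["event"], errors="coerce")
    if events.isna().any() or not events.isin([0, 1]).all():
        offender = df.loc[~events.isin([0, 1]), "sample_id"].iloc[0]
        raise ValueError(f"{path}: event must be 0 or 1 (sample {offender!r})")
    df = df.copy()
    df["time"] = times.astype(float)
    df["event"] = events.astype(int)
    return df


def clinical_to_records(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(sample_id=str(row.sample_id), time=float(row.time),
                       event=int(row.event))
        for row in clinical.itertuples(index=False)
    ]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, members.

    Lines with fewer than three fields are rejected with their line
    numbers; duplicated members within a set are deduplicated with a
    warning (first occurrence kept).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    bad_lines = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            bad_lines.append(lineno)
            continue
        name, _description, *members = fields
        members = [m for m in members if m]
        seen: dict[str, None] = {}
        dup = False
        for m in members:
            if m in seen:
                dup = True
            seen[m] = None
        if dup:
            warnings.warn(f"{path}:{lineno}: duplicated members in set {name!r} "
                          "deduplicated")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = list(seen)
    if bad_lines:
        raise ValueError(f"{path}: GMT lines with < 3 fields: {bad_lines[:10]}")
    return sets


def read_ihc_table(path: str | Path) -> pd.DataFrame:
    """Load the per-core IHC TSV (patient_id, class, percent_positive,
    intensity) and attach the H-score."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "class", "percent_positive", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing IHC columns: {sorted(missing)}")
    pct = pd.to_numeric(df["percent_positive"], errors="raise")
    inten = pd.to_numeric(df["intensity"], errors="raise")
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError(f"{path}: percent_positive outside [0, 100]")
    if not inten.isin([0, 1, 2, 3]).all():
        raise ValueError(f"{path}: intensity outside {{0,1,2,3}}")
    df = df.copy()
    df["h_score"] = pct * inten
    return df
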