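"""Tidy-CSV input/output for enrichment series and cohort tables.

The enrichment format is one row per sample with columns
``subject_id, analyte, pool, time_min, ttr, concentration`` (UTF-8,
missing values empty); a file may hold many subject/analyte/pool series.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from batkinetics.steady_state import EnrichmentSeries

ENRICHMENT_COLUMNS = ["subject_id", "analyte", "pool", "time_min", "ttr", "concentration"]


def read_enrichment_csv(path: str | Path) -> list[EnrichmentSeries]:
    """Read all series from a tidy enrichment CSV, sorted by time."""
    df = pd.read_csv(path)
    missing = [c for c in ENRICHMENT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"enrichment CSV missing columns: {missing}")
    out = []
    for (sid, analyte, pool), grp in df.groupby(
        ["subject_id", "analyte", "pool"], sort=True
    ):
        grp = grp.sort_values("time_min")
        conc = None
        if "concentration" in grp.columns and grp["concentration"].notna().any():
            conc = grp["concentration"].to_numpy(dtype=float)
        out.append(
            EnrichmentSeries(
                subject_id=str(sid),
                analyte=analyte,
                pool=pool,
                times=grp["time_min"].to_numpy(dtype=float),
                ttr=grp["ttr"].to_numpy(dtype=float),
                concentration=conc,
            )
        )
    return out


def write_enrichment_csv(series: list[EnrichmentSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "analyte": s.analyte.value,
                    "pool": s.pool.value,
                    "time_min": s.times,
                    "ttr": s.ttr,
                    "concentration": (
                        s.concentration if s.concentration is not None else np.nan
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV missing required column {col!r}")
    bad = set(df["group"].unique()) - {"LBAT", "HBAT"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
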