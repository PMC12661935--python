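"""Shared record types for counting and phenology."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

STAGES = ("IFS", "EFS", "MFS", "LFS", "TFS")


@dataclass
class CountRecord:
    """Per-image counts of the three flower classes."""
    image_id: str
    n_bud: int
    n_bloom: int
    n_wither: int
    date: Optional[str] = None          # ISO date
    accession: Optional[str] = None
    stage: Optional[str] = None

    def __post_init__(self):
        if min(self.n_bud, self.n_bloom, self.n_wither) < 0:
            raise ValueError("counts must be non-negative")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def total(self) -> int:
        return self.n_bud + self.n_bloom + self.n_wither


def records_to_frame(records) -> pd.DataFrame:
    """Season CSV layout: accession,date,bud,b_flower,w_flower,stage."""
    return pd.DataFrame([
        {"accession": r.accession, "date": r.date, "bud": r.n_bud,
         "b_flower": r.n_bloom, "w_flower": r.n_wither, "stage": r.stage}
        for r in records
    ])


def frame_to_records(df: pd.DataFrame) -> list:
    out = []
    for i, row in df.iterrows():
        out.append(CountRecord(
            image_id=str(row.get("image", i)),
            n_bud=int(row["bud"]), n_bloom=int(row["b_flower"]),
            n_wither=int(row["w_flower"]),
            date=str(row["date"]) if "date" in df.columns else None,
            accession=str(row["accession"]) if "accession" in df.columns else None,
            stage=str(row["stage"]) if "stage" in df.columns and pd.notna(row.get("stage")) else None,
        ))
    return out
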