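"""Shared response-record containers and table schema helpers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Fixed column order of the response CSV schema.
RESPONSE_COLUMNS = [
    "participant_id",
    "target_id",
    "target_rank",
    "slider_id",
    "repeat_index",
    "raw_position",
    "position",
    "censored",
]

#: Tolerance for flagging imported (not simulated) responses as censored.
CENSOR_TOL = 1e-6


@dataclass(frozen=True)
class ResponseRecord:
    """One slider response.

    ``raw_position`` is the on-screen position chi in [0, 1]; ``position``
    is its image on the lambda scale of the slider that produced it.
    ``censored`` marks responses sitting at a slider bound, which carry only
    one-sided information about the underlying preference.
    """

    participant_id: str
    target_id: str
    target_rank: int
    slider_id: str
    repeat_index: int
    raw_position: float
    position: float
    censored: bool


def records_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=RESPONSE_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[ResponseRecord]:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    return [
        ResponseRecord(
            participant_id=str(row.participant_id),
            target_id=str(row.target_id),
            target_rank=int(row.target_rank),
            slider_id=str(row.slider_id),
            repeat_index=int(row.repeat_index),
            raw_position=float(row.raw_position),
            position=float(row.position),
            censored=bool(row.censored),
        )
        for row in df.itertuples()
    ]
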