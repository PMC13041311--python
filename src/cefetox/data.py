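"""Event-oriented study dataset and its NONMEM-like CSV representation.

One subject holds a dosing regimen, concentration observations across the
three matrices, the seizure outcome (modified Racine stage, dichotomized at
stage > 1 for analysis) and the event/sacrifice times.  The on-disk format is
a tidy CSV with one row per dose (EVID 1) or observation (EVID 0):

    ID, TIME, EVID, AMT, DUR, DV, MATRIX, BLQ, LOQ, WT, STAGE,
    EVENT_TIME, SACRIFICE_TIME

Times in h from the first dose, AMT in mg, DUR in h, DV in mg/L (brain µg/g
numerically identical).  BLQ rows carry an empty DV and BLQ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import MATRICES, DoseEvent, InvalidInputError, Regimen
from .population import Observation

REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MATRIX", "BLQ",
                    "LOQ", "WT", "STAGE", "EVENT_TIME", "SACRIFICE_TIME"]


class ValidationError(ValueError):
    """Raised on malformed dataset files, with offending columns/rows named."""


@dataclass
class Subject:
    subject_id: str
    weight: float  # kg
    regimen: Regimen
    observations: list[Observation] = field(default_factory=list)
    stage: int | None = None          # modified Racine stage 0-7
    event_time: float | None = None   # time-to-seizure (h) if stage > 1
    sacrifice_time: float | None = None

    @property
    def seizure(self) -> bool | None:
        return None if self.stage is None else self.stage > 1


@dataclass
class Dataset:
    subjects: list[Subject]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        for s in self.subjects:
            if s.weight <= 0:
                raise ValidationError(f"subject {s.subject_id}: non-positive weight")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def n_observations(self, matrix: str | None = None) -> int:
        return sum(1 for s in self.subjects for o in s.observations
                   if matrix is None or o.matrix == matrix)

    def observations_frame(self) -> pd.DataFrame:
        """All observations as a tidy frame (one row per record)."""
        rows = [{"ID": s.subject_id, "TIME": o.time, "MATRIX": o.matrix,
                 "DV": o.value, "BLQ": int(o.blq), "LOQ": o.loq}
                for s in self.subjects for o in s.observations]
        return pd.DataFrame(rows, columns=["ID", "TIME", "MATRIX", "DV", "BLQ", "LOQ"])


def to_frame(ds: Dataset) -> pd.DataFrame:
    rows = []
    for s in ds.subjects:
        base = {"ID": s.subject_id, "WT": s.weight,
                "STAGE": s.stage if s.stage is not None else "",
                "EVENT_TIME": s.event_time if s.event_time is not None else "",
                "SACRIFICE_TIME": s.sacrifice_time if s.sacrifice_time is not None else ""}
        for e in s.regimen.events:
            rows.append({**base, "TIME": e.start_time, "EVID": 1, "AMT": e.amount,
                         "DUR": e.duration, "DV": "", "MATRIX": "", "BLQ": 0, "LOQ": ""})
        for o in s.observations:
            rows.append({**base, "TIME": o.time, "EVID": 0, "AMT": "", "DUR": "",
                         "DV": "" if o.blq else o.value, "MATRIX": o.matrix,
                         "BLQ": int(o.blq), "LOQ": o.loq})
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def write_dataset(ds: Dataset, path) -> None:
    to_frame(ds).to_csv(path, index=False)


def _num(value, default=None):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return default
    return float(value)


def read_dataset(path) -> Dataset:
    """Parse and validate a dataset CSV; errors name the column/row at fault."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    subjects: list[Subject] = []
    for sid, grp in df.groupby("ID", sort=False):
        weight = _num(grp["WT"].iloc[0])
        events, obs = [], []
        stage = event_time = sacrifice = None
        for idx, row in grp.iterrows():
            t = _num(row["TIME"])
            if t is None or t < 0:
                raise ValidationError(f"row {idx}: negative or missing TIME")
            stage = int(row["STAGE"]) if _num(row["STAGE"]) is not None else stage
            event_time = _num(row["EVENT_TIME"], event_time)
            sacrifice = _num(row["SACRIFICE_TIME"], sacrifice)
            if int(row["EVID"]) == 1:
                events.append(DoseEvent(t, _num(row["AMT"], 0.0), _num(row["DUR"], 0.0)))
            else:
                m = row["MATRIX"]
                if m not in MATRICES:
                    raise ValidationError(f"row {idx}: unknown matrix code {m!r}")
                blq = bool(int(row["BLQ"]))
                obs.append(Observation(str(sid), t, m,
                                       None if blq else _num(row["DV"]),
                                       blq=blq, loq=_num(row["LOQ"], 0.5)))
        try:
            regimen = Regimen(tuple(sorted(events, key=lambda e: e.start_time)), weight)
        except InvalidInputError as exc:
            raise ValidationError(f"subject {sid}: {exc}") from exc
        subjects.append(Subject(str(sid), weight, regimen, obs, stage,
                                event_time, sacrifice))
    return Dataset(subjects, metadata={"source": str(path)})
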