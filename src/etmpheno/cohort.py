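"""Subject-level cohort of extracted biophysical features.

The study cohort consists of 14 subjects, each contributing a paired
adjacent-normal (AN) biopsy and a tumour biopsy diagnosed as invasive ductal
carcinoma (CA, 10 subjects) or fibroadenoma (FA, 4 subjects).  Each record
carries the four extracted biophysical features:

* ``Z_15k`` — magnitude of the electrical impedance at 15 kHz, in ohm;
* ``K``    — thermal conductivity at 37 degC, in W m^-1 K^-1;
* ``k_stiff`` — mechanical stiffness, the slope of the loading curve at
  20 % strain, in kN m^-1;
* ``pctR`` — percentage relaxation of the normalized load after 150 s of
  stress relaxation, in %.

The published per-subject values are bundled as an immutable fixture; their
group means and standard errors reproduce the published summary statistics
exactly (this is checked at load time, see :func:`load_cohort_fixture`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

GROUPS = ("AN", "FA", "CA")
MODALITIES = ("Z", "K", "k", "%R")

#: cohort CSV schema (also used by the CLI)
COHORT_COLUMNS = ("subject_id", "group", "Z_ohm", "K_wmk", "k_knm", "pctR")

_MODALITY_ATTR = {"Z": "Z_15k", "K": "K", "k": "k_stiff", "%R": "pctR"}


class FixtureIntegrityError(RuntimeError):
    """Raised when the bundled cohort fixture fails its integrity check."""


@dataclass(frozen=True)
class TissueRecord:
    """One tissue sample: group label plus the four biophysical features."""

    subject_id: str
    group: str
    Z_15k: float
    K: float
    k_stiff: float
    pctR: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not (self.Z_15k > 0 and self.K > 0 and self.k_stiff > 0):
            raise ValueError("Z_15k, K and k_stiff must be strictly positive")
        if not 0.0 <= self.pctR <= 100.0:
            raise ValueError("pctR must lie in [0, 100]")

    def feature(self, modality: str) -> float:
        return getattr(self, _MODALITY_ATTR[modality])


class CohortTable:
    """Ordered collection of :class:`TissueRecord` with group-wise access."""

    def __init__(self, records: Sequence[TissueRecord]):
        self._records = tuple(records)
        if not self._records:
            raise ValueError("cohort must contain at least one record")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TissueRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> TissueRecord:
        return self._records[i]

    @property
    def records(self) -> tuple[TissueRecord, ...]:
        return self._records

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for r in self._records:
            sizes[r.group] += 1
        return sizes

    def values(self, modality: str, group: str | None = None) -> np.ndarray:
        """Feature column, optionally restricted to one group."""
        if modality not in MODALITIES:
            raise KeyError(f"unknown modality {modality!r}")
        vals = [
            r.feature(modality)
            for r in self._records
            if group is None or r.group == group
        ]
        return np.asarray(vals, dtype=float)

    def record(self, subject_id: str, group: str) -> TissueRecord:
        for r in self._records:
            if r.subject_id == subject_id and r.group == group:
                return r
        raise KeyError(f"no record ({subject_id}, {group})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self._records],
                "group": [r.group for r in self._records],
                "Z_ohm": [r.Z_15k for r in self._records],
                "K_wmk": [r.K for r in self._records],
                "k_knm": [r.k_stiff for r in self._records],
                "pctR": [r.pctR for r in self._records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        missing = set(COHORT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        recs = [
            TissueRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                Z_15k=float(row.Z_ohm),
                K=float(row.K_wmk),
                k_stiff=float(row.k_knm),
                pctR=float(row.pctR),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(recs)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path))


# Published per-subject feature values.  Each entry: subject id, the four
# AN features, tumour type, the four tumour features.  Some table cells in
# the source render run together; the transcription below is validated by
# checksum here and against every published group mean/SEM in the test suite.
_TABLE1 = (
    ("S1", (4608.1, 0.307, 0.034, 27.83), "CA", (21567.0, 0.124, 0.055, 33.33)),
    ("S2", (29845.0, 0.353, 0.00894, 20.6), "CA", (256510.0, 0.174, 0.0833, 33.0)),
    ("S3", (24092.0, 0.337, 0.01707, 24.2), "CA", (66865.0, 0.184, 0.142, 29.3)),
    ("S4", (16093.0, 0.353, 0.0039, 26.6), "CA", (123700.0, 0.165, 0.076, 36.6)),
    ("S5", (18394.0, 0.414, 0.0178, 32.2), "CA", (57090.0, 0.152, 0.075, 43.3)),
    ("S6", (21633.0, 0.384, 0.015, 21.4), "CA", (146280.0, 0.135, 0.067, 33.0)),
    ("S7", (51204.0, 0.44, 0.03668, 31.7), "CA", (151700.0, 0.265, 0.065, 51.7)),
    ("S8", (14276.0, 0.51, 0.0104, 21.8), "CA", (89743.0, 0.133, 0.1066, 49.6)),
    ("S9", (29218.0, 0.42, 0.01774, 26.3), "FA", (75189.0, 0.298, 0.04856, 30.4)),
    ("S10", (17931.0, 0.495, 0.0205, 19.5), "CA", (132300.0, 0.242, 0.0542, 35.5)),
    ("S11", (44780.0, 0.58, 0.028, 34.1), "FA", (51961.0, 0.253, 0.0612, 51.5)),
    ("S12", (17689.0, 0.525, 0.0178, 19.0), "FA", (24258.0, 0.221, 0.0531, 52.8)),
    ("S13", (16500.0, 0.611, 0.0409, 42.9), "FA", (25639.0, 0.194, 0.0658, 56.6)),
    ("S14", (4624.0, 0.565, 0.018, 21.8), "CA", (54433.0, 0.311, 0.04, 26.6)),
)

#: CRC-32 of the canonical fixture serialization, frozen at transcription time.
_TABLE1_CRC = 0xAA477E1A


def _fixture_canonical() -> str:
    parts = []
    for sid, an, grp, tu in _TABLE1:
        parts.append(sid)
        parts.append(grp)
        parts.extend(repr(v) for v in an)
        parts.extend(repr(v) for v in tu)
    return "|".join(parts)


def load_cohort_fixture() -> CohortTable:
    """The bundled per-subject cohort: 28 records (14 AN, 10 CA, 4 FA).

    Raises
    ------
    FixtureIntegrityError
        If the bundled values fail the frozen checksum or the expected
        cohort shape (a guard against accidental edits of the constants).
    """
    crc = zlib.crc32(_fixture_canonical().encode())
    if crc != _TABLE1_CRC:
        raise FixtureIntegrityError(
            f"cohort fixture checksum mismatch: {crc:#010x} != {_TABLE1_CRC:#010x}"
        )
    records = []
    for sid, an, grp, tu in _TABLE1:
        records.append(TissueRecord(sid, "AN", *an))
        records.append(TissueRecord(sid, grp, *tu))
    table = CohortTable(records)
    if table.group_sizes() != {"AN": 14, "CA": 10, "FA": 4}:
        raise FixtureIntegrityError("cohort fixture has unexpected group sizes")
    return table
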