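"""Reading, validating and summarising tab-delimited ISE data files.

Three dialects are supported, compatible with the files used by the R
package ISEtools (so its ``extdata`` examples load unchanged):

* calibration:       columns ``ISEID  log10x  emf``
* Basic experimental: columns ``ISEID  SampleID  emf``
* Standard Addition:  columns ``ISEID  SampleID  emf1  emf2  V.s  V.add  conc.add``

Files are tab-delimited with a single header row; column binding is by
header name (order-insensitive), values use a decimal point, and
leading/trailing whitespace is stripped.  The experimental dialect is
auto-detected from the header-name set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "CalibrationRecord",
    "BasicSampleRecord",
    "StandardAdditionRecord",
    "ISEDataset",
    "DataFormatError",
    "DataParseError",
    "read_calibration",
    "read_experimental",
    "build_dataset",
    "load_dataset",
    "summarize_dataset",
    "write_dataset",
]

CALIBRATION_COLUMNS = ("ISEID", "log10x", "emf")
BASIC_COLUMNS = ("ISEID", "SampleID", "emf")
SA_COLUMNS = ("ISEID", "SampleID", "emf1", "emf2", "V.s", "V.add", "conc.add")


class DataFormatError(ValueError):
    """The file header does not match any supported dialect."""


class DataParseError(ValueError):
    """A body cell could not be parsed; the message cites the line number."""


class Mode(enum.Enum):
    CALIBRATION_ONLY = "calibration_only"
    BASIC = "basic"
    STANDARD_ADDITION = "standard_addition"


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration observation: sensor, known log10 activity, measured emf."""

    ise_id: int
    log10x: float
    emf: float

    def __post_init__(self):
        _check_id("ISEID", self.ise_id)
        _check_finite("log10x", self.log10x)
        _check_finite("emf", self.emf)


@dataclass(frozen=True)
class BasicSampleRecord:
    """One experimental observation in Basic format."""

    ise_id: int
    sample_id: int
    emf: float

    def __post_init__(self):
        _check_id("ISEID", self.ise_id)
        _check_id("SampleID", self.sample_id)
        _check_finite("emf", self.emf)


@dataclass(frozen=True)
class StandardAdditionRecord:
    """One experimental observation in Standard Addition format.

    ``emf1``/``emf2`` are the potentials before/after an aliquot of volume
    ``v_add`` and activity ``conc_add`` is added to a sample of volume
    ``v_s`` (volumes in any one consistent unit).
    """

    ise_id: int
    sample_id: int
    emf1: float
    emf2: float
    v_s: float
    v_add: float
    conc_add: float

    def __post_init__(self):
        _check_id("ISEID", self.ise_id)
        _check_id("SampleID", self.sample_id)
        _check_finite("emf1", self.emf1)
        _check_finite("emf2", self.emf2)
        if self.v_s <= 0:
            raise ValueError(f"V.s must be > 0, got {self.v_s}")
        if self.v_add <= 0:
            raise ValueError(f"V.add must be > 0, got {self.v_add}")
        if self.conc_add <= 0:
            raise ValueError(f"conc.add must be > 0, got {self.conc_add}")


def _check_id(name, value):
    if int(value) != value or value < 1:
        raise ValueError(f"{name} must be a positive integer, got {value}")


def _check_finite(name, value):
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


# ---------------------------------------------------------------------------
# readers

def _read_table(path, expected: Sequence[str]) -> pd.DataFrame:
    """Read a tab-delimited table, bind columns by header name, coerce to float."""
    raw = pd.read_csv(path, sep="\t", dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing column(s) {missing}; expected header {list(expected)}"
        )
    unknown = [c for c in raw.columns if c not in expected]
    if unknown:
        raise DataFormatError(
            f"{path}: unknown column(s) {unknown}; expected header {list(expected)}"
        )
    out = {}
    for col in expected:
        vals = raw[col].astype(str).str.strip()
        converted = np.empty(len(vals))
        for k, v in enumerate(vals):
            try:
                converted[k] = float(v)  # correctly-rounded parse, exact round trip
            except ValueError:
                raise DataParseError(
                    f"{path}: non-numeric value {v!r} in column {col!r} "
                    f"at line {k + 2}"  # header is line 1
                ) from None
            if not np.isfinite(converted[k]):
                raise DataParseError(
                    f"{path}: non-finite value {v!r} in column {col!r} at line {k + 2}"
                )
        out[col] = converted
    return pd.DataFrame(out)


def read_calibration(path) -> list[CalibrationRecord]:
    """Read a calibration file into records (empty body gives an empty list)."""
    table = _read_table(path, CALIBRATION_COLUMNS)
    return [
        CalibrationRecord(int(r.ISEID), float(r.log10x), float(r.emf))
        for r in table.itertuples(index=False)
    ]


def read_experimental(path):
    """Read an experimental file, auto-detecting Basic vs Standard Addition.

    Detection is a pure function of the header-name set: ``emf1/emf2/V.s/
    V.add/conc.add`` present -> Standard Addition; a single ``emf`` ->
    Basic.  Returns ``(mode, records)``.
    """
    header = pd.read_csv(path, sep="\t", dtype=str, nrows=0)
    names = {c.strip() for c in header.columns}
    if names == set(SA_COLUMNS):
        table = _read_table(path, SA_COLUMNS)
        records = [
            StandardAdditionRecord(
                int(r[0]), int(r[1]), float(r[2]), float(r[3]),
                float(r[4]), float(r[5]), float(r[6]),
            )
            for r in table.itertuples(index=False)
        ]
        return Mode.STANDARD_ADDITION, records
    if names == set(BASIC_COLUMNS):
        table = _read_table(path, BASIC_COLUMNS)
        records = [
            BasicSampleRecord(int(r.ISEID), int(r.SampleID), float(r.emf))
            for r in table.itertuples(index=False)
        ]
        return Mode.BASIC, records
    raise DataFormatError(
        f"{path}: header {sorted(names)} matches neither the Basic schema "
        f"{list(BASIC_COLUMNS)} nor the Standard Addition schema {list(SA_COLUMNS)}"
    )


# ---------------------------------------------------------------------------
# dataset

MIN_CALIBRATION_POINTS = 4  # model has 4 unknowns per sensor (a, b, c, sigma)


@dataclass(frozen=True)
class ISEDataset:
    """A validated calibration table plus optional experimental table.

    Invariants enforced on construction: sensor ids form the contiguous set
    1..n_ise; every sensor has at least four calibration points (the
    identifiability floor for a, b, c, sigma); in Basic/SA mode each
    (sample, sensor) pair appears at most once and every experimental
    sensor also has calibration data.
    """

    calibration: tuple
    experimental: tuple
    mode: Mode
    n_ise: int = field(init=False)
    n_sample: int = field(init=False)

    def __post_init__(self):
        ise_ids = sorted({r.ise_id for r in self.calibration})
        if not ise_ids:
            raise ValueError("calibration data is empty")
        n_ise = len(ise_ids)
        if ise_ids != list(range(1, n_ise + 1)):
            raise ValueError(
                f"sensor ids must be contiguous 1..n, got {ise_ids}; "
                "relabel the ISEID column explicitly"
            )
        counts = {i: 0 for i in ise_ids}
        for r in self.calibration:
            counts[r.ise_id] += 1
        thin = [i for i, n in counts.items() if n < MIN_CALIBRATION_POINTS]
        if thin:
            raise ValueError(
                f"sensor(s) {thin} have fewer than {MIN_CALIBRATION_POINTS} "
                "calibration points; a, b, c and sigma are not identifiable"
            )
        if self.mode is Mode.CALIBRATION_ONLY:
            if self.experimental:
                raise ValueError("calibration_only dataset with experimental records")
            n_sample = 0
        else:
            if not self.experimental:
                raise ValueError(f"mode {self.mode.value} requires experimental records")
            want = StandardAdditionRecord if self.mode is Mode.STANDARD_ADDITION else BasicSampleRecord
            for r in self.experimental:
                if not isinstance(r, want):
                    raise ValueError(f"record {r!r} does not match mode {self.mode.value}")
            missing = sorted({r.ise_id for r in self.experimental} - set(ise_ids))
            if missing:
                raise ValueError(
                    f"experimental sensor(s) {missing} have no calibration data"
                )
            pairs = [(r.sample_id, r.ise_id) for r in self.experimental]
            if len(pairs) != len(set(pairs)):
                dup = sorted({p for p in pairs if pairs.count(p) > 1})
                raise ValueError(f"duplicate (sample, sensor) measurements: {dup}")
            n_sample = len({r.sample_id for r in self.experimental})
        object.__setattr__(self, "n_ise", n_ise)
        object.__setattr__(self, "n_sample", n_sample)

    # -- convenience views -------------------------------------------------
    def calibration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ISEID": [r.ise_id for r in self.calibration],
                "log10x": [r.log10x for r in self.calibration],
                "emf": [r.emf for r in self.calibration],
            }
        )

    def experimental_frame(self) -> pd.DataFrame | None:
        if self.mode is Mode.CALIBRATION_ONLY:
            return None
        if self.mode is Mode.BASIC:
            return pd.DataFrame(
                {
                    "ISEID": [r.ise_id for r in self.experimental],
                    "SampleID": [r.sample_id for r in self.experimental],
                    "emf": [r.emf for r in self.experimental],
                }
            )
        return pd.DataFrame(
            {
                "ISEID": [r.ise_id for r in self.experimental],
                "SampleID": [r.sample_id for r in self.experimental],
                "emf1": [r.emf1 for r in self.experimental],
                "emf2": [r.emf2 for r in self.experimental],
                "V.s": [r.v_s for r in self.experimental],
                "V.add": [r.v_add for r in self.experimental],
                "conc.add": [r.conc_add for r in self.experimental],
            }
        )

    def sample_ids(self) -> list[int]:
        return sorted({r.sample_id for r in self.experimental})

    @classmethod
    def from_files(cls, calibration_path, experimental_path=None) -> "ISEDataset":
        """Load and validate a dataset from file paths (loadISEdata analogue)."""
        cal = read_calibration(calibration_path)
        if experimental_path is None:
            return build_dataset(cal, [], Mode.CALIBRATION_ONLY)
        mode, exp = read_experimental(experimental_path)
        return build_dataset(cal, exp, mode)

    def __str__(self) -> str:
        return summarize_dataset(self)


def build_dataset(calibration, experimental, mode: Mode) -> ISEDataset:
    """Assemble and validate an :class:`ISEDataset` from parsed records."""
    return ISEDataset(tuple(calibration), tuple(experimental), mode)


def load_dataset(calibration_path, experimental_path=None) -> ISEDataset:
    """Functional alias for :meth:`ISEDataset.from_files`."""
    return ISEDataset.from_files(calibration_path, experimental_path)


_MODE_LABEL = {
    Mode.CALIBRATION_ONLY: "calibration only",
    Mode.BASIC: "Basic",
    Mode.STANDARD_ADDITION: "Standard Addition",
}


def summarize_dataset(dataset: ISEDataset) -> str:
    """Human-readable summary for eyeballing data-entry errors."""
    cal = dataset.calibration_frame()
    lines = [
        f"ISE dataset: {dataset.n_ise} ISEs, "
        f"{len(dataset.calibration)} calibration points",
    ]
    for i, grp in cal.groupby("ISEID"):
        lines.append(
            f"  ISE #{int(i)}: {len(grp)} points, "
            f"log10x in [{grp.log10x.min():g}, {grp.log10x.max():g}], "
            f"emf in [{grp.emf.min():g}, {grp.emf.max():g}] mV"
        )
    if dataset.mode is Mode.CALIBRATION_ONLY:
        lines.append("no experimental data")
    else:
        lines.append(
            f"experimental data: {_MODE_LABEL[dataset.mode]} format, "
            f"{dataset.n_sample} samples, {len(dataset.experimental)} measurements"
        )
    return "\n".join(lines)


def write_dataset(dataset: ISEDataset, calibration_path, experimental_path=None) -> None:
    """Write a dataset back to the tab-delimited dialects (fixture writer).

    Floats are written with ``repr`` precision so a read round-trips
    bit-identically for finite inputs.
    """
    cal = dataset.calibration_frame().copy()
    cal["ISEID"] = cal["ISEID"].astype(int)
    cal.to_csv(calibration_path, sep="\t", index=False)
    if dataset.mode is not Mode.CALIBRATION_ONLY:
        if experimental_path is None:
            raise ValueError("dataset has experimental data but no path was given")
        exp = dataset.experimental_frame().copy()
        exp["ISEID"] = exp["ISEID"].astype(int)
        exp["SampleID"] = exp["SampleID"].astype(int)
        exp.to_csv(experimental_path, sep="\t", index=False)
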