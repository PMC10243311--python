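"""Reading and writing RPM/RGSC VXP breathing traces (plus a legacy DAT shim).

The VXP dialect implemented here is the text export of Varian's Real-time
Position Management / Respiratory Gating for Scanners systems: a key=value
header block (``CRC``, ``Version``, ``Data_layout``, ``Patient_ID``,
``Date``, ``Total_study_time``, ``Samples_per_second``, ``Scale_factor``)
followed by a ``[Data]`` marker and comma-separated rows ordered per
``Data_layout``. Amplitudes are stored as raw values that divide by
``Scale_factor`` to give centimetres; timestamps are integer milliseconds;
the ``mark`` column carries ``P`` (peak, end inspiration) or ``Z`` (trough,
end exhalation) on the samples the vendor system marked, empty otherwise.
Unknown header keys are preserved verbatim on round trip.

Some RPM installations record inhalation as *decreasing* amplitude. Polarity
is auto-detected per file: when the mean amplitude at P-marked samples lies
below the mean at Z-marked samples the trace is flagged ``inverted`` and all
analysis views the signal sign-flipped; the recorded amplitudes themselves
are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .errors import EmptyTraceError, TraceDataError, VxpFormatError

logger = logging.getLogger(__name__)

MARK_NONE = ""
MARK_PEAK = "P"
MARK_TROUGH = "Z"

#: default column order for files this package writes
DEFAULT_LAYOUT = ("amplitude", "phase", "timestamp", "validflag", "mark")

_REQUIRED_LAYOUT = {"amplitude", "timestamp", "mark"}
_KNOWN_KEYS = (
    "CRC",
    "Version",
    "Data_layout",
    "Patient_ID",
    "Date",
    "Total_study_time",
    "Samples_per_second",
    "Scale_factor",
)


@dataclass
class VxpHeader:
    """Metadata block of a VXP file."""

    version: str = "1.6"
    data_layout: tuple[str, ...] = DEFAULT_LAYOUT
    patient_id: str = ""
    date: str = ""
    total_study_time: float = 0.0  # seconds
    samples_per_second: float = 25.0  # Hz
    scale_factor: float = 1000.0  # raw units per cm
    crc: str = ""
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples_per_second <= 0:
            raise VxpFormatError("Samples_per_second must be positive")
        if self.scale_factor <= 0:
            raise VxpFormatError("Scale_factor must be positive")
        missing = _REQUIRED_LAYOUT - set(self.data_layout)
        if missing:
            raise VxpFormatError(
                f"Data_layout missing required column(s): {sorted(missing)}"
            )


class TraceSample(NamedTuple):
    """One sampled point of the surrogate signal (amplitude in cm)."""

    timestamp: float
    amplitude: float
    phase: float
    valid: bool
    mark: str


@dataclass
class BreathingTrace:
    """A parsed breathing trace: header metadata plus sample arrays.

    ``amplitude`` is physical (cm, raw/scale_factor). ``signal`` is the
    analysis view: sign-flipped when polarity auto-detection decided the
    file records inhalation downwards.
    """

    header: VxpHeader
    time: np.ndarray  # seconds from trace start
    amplitude: np.ndarray  # cm
    phase: np.ndarray  # radians as recorded (nan where absent)
    valid: np.ndarray  # bool
    marks: np.ndarray  # '' | 'P' | 'Z'
    inverted: bool = False

    def __post_init__(self) -> None:
        n = len(self.time)
        if n == 0:
            raise EmptyTraceError("trace has no samples")
        if n < 2:
            raise TraceDataError("trace must contain at least 2 samples")
        dt = np.diff(self.time)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise TraceDataError(
                f"timestamps not strictly increasing at sample index {bad[0] + 1}"
            )
        nominal = 1.0 / self.header.samples_per_second
        gaps = np.nonzero(dt > 1.5 * nominal)[0]
        if gaps.size:
            logger.warning(
                "%d sampling gap(s) exceeding 50%% jitter (first at t=%.3f s)",
                gaps.size,
                self.time[gaps[0]],
            )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def signal(self) -> np.ndarray:
        """Amplitude oriented so that inhalation peaks are maxima."""
        return -self.amplitude if self.inverted else self.amplitude

    @property
    def sample_rate(self) -> float:
        return self.header.samples_per_second

    def samples(self) -> Iterator[TraceSample]:
        for i in range(len(self)):
            yield TraceSample(
                float(self.time[i]),
                float(self.amplitude[i]),
                float(self.phase[i]),
                bool(self.valid[i]),
                str(self.marks[i]),
            )

    def invalid_gaps(self, min_duration: float = 0.0) -> list[tuple[float, float]]:
        """Contiguous runs of invalid samples lasting at least ``min_duration`` s."""
        out: list[tuple[float, float]] = []
        bad = ~self.valid
        i = 0
        n = len(self)
        while i < n:
            if bad[i]:
                j = i
                while j + 1 < n and bad[j + 1]:
                    j += 1
                span = (float(self.time[i]), float(self.time[j]))
                if span[1] - span[0] + 1.0 / self.sample_rate >= min_duration:
                    out.append(span)
                i = j + 1
            else:
                i += 1
        return out


def _detect_polarity(amplitude: np.ndarray, marks: np.ndarray) -> bool:
    """True when the file records inhalation as decreasing amplitude."""
    at_p = amplitude[marks == MARK_PEAK]
    at_z = amplitude[marks == MARK_TROUGH]
    if at_p.size and at_z.size:
        return bool(at_p.mean() < at_z.mean())
    return False


def read_vxp(path: str | Path, *, invert: bool | None = None) -> BreathingTrace:
    """Parse a VXP trace file.

    Parameters
    ----------
    path:
        File to read.
    invert:
        Override polarity auto-detection (``None`` = auto).
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    keys: dict[str, str] = {}
    data_start = None
    for i, line in enumerate(lines):
        s = line.strip()
        if not s or s == "[Header]":
            continue
        if s == "[Data]":
            data_start = i + 1
            break
        if "=" not in s:
            raise VxpFormatError(f"garbled header line {i + 1}: {s!r}")
        k, _, v = s.partition("=")
        keys[k.strip()] = v.strip()
    if data_start is None:
        raise VxpFormatError("missing [Data] section marker")

    for required in ("Data_layout", "Samples_per_second", "Scale_factor"):
        if required not in keys:
            raise VxpFormatError(f"missing required header key {required!r}")

    def _num(key: str, default: float | None = None) -> float:
        raw = keys.get(key)
        if raw is None:
            return float(default)  # type: ignore[arg-type]
        try:
            return float(raw)
        except ValueError as exc:
            raise VxpFormatError(f"garbled numeric header key {key!r}: {raw!r}") from exc

    layout = tuple(c.strip().lower() for c in keys["Data_layout"].split(","))
    header = VxpHeader(
        version=keys.get("Version", ""),
        data_layout=layout,
        patient_id=keys.get("Patient_ID", ""),
        date=keys.get("Date", ""),
        total_study_time=_num("Total_study_time", 0.0),
        samples_per_second=_num("Samples_per_second"),
        scale_factor=_num("Scale_factor"),
        crc=keys.get("CRC", ""),
        extra={k: v for k, v in keys.items() if k not in _KNOWN_KEYS},
    )

    col = {name: j for j, name in enumerate(layout)}
    rows = [ln.strip() for ln in lines[data_start:] if ln.strip()]
    if not rows:
        raise EmptyTraceError(f"{path}: empty data section")

    n = len(rows)
    time_ms = np.empty(n, dtype=np.int64)
    amp = np.empty(n)
    phase = np.full(n, np.nan)
    valid = np.ones(n, dtype=bool)
    marks = np.full(n, MARK_NONE, dtype="<U1")
    width = len(layout)
    for i, row in enumerate(rows):
        fields = row.split(",")
        if len(fields) != width:
            raise VxpFormatError(
                f"{path}: data row {i + 1} has {len(fields)} fields, expected {width}"
            )
        try:
            time_ms[i] = int(fields[col["timestamp"]])
            amp[i] = float(fields[col["amplitude"]])
            if "phase" in col and fields[col["phase"]] != "":
                phase[i] = float(fields[col["phase"]])
            if "validflag" in col:
                valid[i] = fields[col["validflag"]].strip() == "1"
        except ValueError as exc:
            raise VxpFormatError(f"{path}: unparseable data row {i + 1}: {row!r}") from exc
        m = fields[col["mark"]].strip().upper()
        if m not in ("", MARK_PEAK, MARK_TROUGH):
            raise VxpFormatError(f"{path}: unknown mark {m!r} at data row {i + 1}")
        marks[i] = m

    dup = np.nonzero(np.diff(time_ms) == 0)[0]
    if dup.size:
        raise TraceDataError(
            f"{path}: duplicate timestamp at sample index {dup[0] + 1}"
        )

    amplitude = amp / header.scale_factor
    inverted = _detect_polarity(amplitude, marks) if invert is None else invert
    return BreathingTrace(
        header=header,
        time=time_ms / 1000.0,
        amplitude=amplitude,
        phase=phase,
        valid=valid,
        marks=marks,
        inverted=inverted,
    )


def _fmt(x: float) -> str:
    return repr(float(x))


def write_vxp(trace: BreathingTrace, path: str | Path) -> Path:
    """Serialize a trace to the VXP dialect; ``read_vxp`` parses it back
    identically (timestamps to the millisecond, amplitudes to full float
    precision, marks preserved)."""
    path = Path(path)
    h = trace.header
    lines = ["[Header]"]
    lines.append(f"CRC={h.crc}")
    lines.append(f"Version={h.version}")
    lines.append("Data_layout=" + ",".join(h.data_layout))
    lines.append(f"Patient_ID={h.patient_id}")
    lines.append(f"Date={h.date}")
    lines.append(f"Total_study_time={_fmt(h.total_study_time)}")
    lines.append(f"Samples_per_second={_fmt(h.samples_per_second)}")
    lines.append(f"Scale_factor={_fmt(h.scale_factor)}")
    for k, v in h.extra.items():
        lines.append(f"{k}={v}")
    lines.append("[Data]")

    raw = trace.amplitude * h.scale_factor
    time_ms = np.rint(trace.time * 1000.0).astype(np.int64)
    for i in range(len(trace)):
        fields = []
        for name in h.data_layout:
            if name == "amplitude":
                fields.append(_fmt(raw[i]))
            elif name == "timestamp":
                fields.append(str(int(time_ms[i])))
            elif name == "phase":
                p = trace.phase[i]
                fields.append("" if np.isnan(p) else _fmt(p))
            elif name == "validflag":
                fields.append("1" if trace.valid[i] else "0")
            elif name == "mark":
                fields.append(str(trace.marks[i]))
            else:
                fields.append("0")
        lines.append(",".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dat(path: str | Path) -> BreathingTrace:
    """Parse the minimal legacy two-column dialect: ``seconds,cm`` per row.

    A compatibility shim for much older systems; the resulting trace has no
    marks and no phase column.
    """
    path = Path(path)
    rows = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not rows:
        raise EmptyTraceError(f"{path}: empty file")
    n = len(rows)
    time = np.empty(n)
    amp = np.empty(n)
    for i, row in enumerate(rows):
        fields = row.split(",")
        if len(fields) != 2:
            raise VxpFormatError(
                f"{path}: row {i + 1} has {len(fields)} fields, expected 2"
            )
        try:
            time[i] = float(fields[0])
            amp[i] = float(fields[1])
        except ValueError as exc:
            raise VxpFormatError(f"{path}: unparseable row {i + 1}: {row!r}") from exc
    if n >= 2:
        fs = 1.0 / float(np.median(np.diff(time)))
    else:
        fs = 25.0
    header = VxpHeader(
        version="DAT",
        data_layout=("timestamp", "amplitude", "mark"),
        samples_per_second=fs,
        scale_factor=1.0,
        total_study_time=float(time[-1] - time[0]) if n else 0.0,
    )
    return BreathingTrace(
        header=header,
        time=time,
        amplitude=amp,
        phase=np.full(n, np.nan),
        valid=np.ones(n, dtype=bool),
        marks=np.full(n, MARK_NONE, dtype="<U1"),
    )
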