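"""Sample container, FCS 3.0/3.1 list-mode I/O, and geometric gating.

The FCS reader and writer cover the subset of the standard that matters
for list-mode fluorescence data: FCS 3.0/3.1 headers, a single TEXT
segment, and DATA segments of type ``F`` (float32), ``D`` (float64) or
``I`` (unsigned integers with per-parameter bit masks), in either byte
order. Compensation is assumed to have been applied upstream, so negative
values are kept as-is.

Gating is a convenience: a rectangle gate in two channels followed by an
ellipse (Mahalanobis) gate is the standard two-step lymphocyte selection,
but the geometric parameters are dataset-specific and always user-supplied.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from numpy.typing import NDArray

__all__ = ["Sample", "GateSpec", "read_fcs", "write_fcs", "apply_gate", "FcsFormatError"]


class FcsFormatError(ValueError):
    """Raised when an FCS file violates the parts of the standard we rely on."""


@dataclass
class Sample:
    """One flow-cytometry sample: an events x channels matrix with names.

    ``events`` rows are cells, columns are channels in the order of
    ``channel_names`` (the $PnN short names). Stain names ($PnS) and other
    acquisition keywords live in ``metadata``.
    """

    sample_id: str
    channel_names: list[str]
    events: NDArray[np.float64]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix (events x channels)")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError(
                f"events has {self.events.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted(
                {n for n in self.channel_names if self.channel_names.count(n) > 1}
            )
            raise ValueError(f"duplicate channel names: {dupes}")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("events contain non-finite values")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel(self, name: str) -> NDArray[np.float64]:
        """Return one channel as a 1-D vector."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in sample {self.sample_id!r} "
                f"(has {self.channel_names})"
            ) from None
        return self.events[:, idx]

    def with_channel(self, name: str, values: NDArray[np.float64]) -> "Sample":
        """Return a copy with one channel's values replaced."""
        idx = self.channel_names.index(name)
        events = self.events.copy()
        events[:, idx] = values
        return Sample(self.sample_id, list(self.channel_names), events, dict(self.metadata))


@dataclass
class GateSpec:
    """A rectangle or ellipse gate in a 2-channel projection.

    Rectangle: inclusive bounds ``(x_min, x_max, y_min, y_max)``.
    Ellipse: events with Mahalanobis distance to ``center`` (under
    ``shape``, a symmetric positive-definite 2x2 matrix) at most
    ``threshold`` are kept.
    """

    kind: Literal["rectangle", "ellipse"]
    channel_x: str
    channel_y: str
    rectangle: tuple[float, float, float, float] | None = None
    center: NDArray[np.float64] | None = None
    shape: NDArray[np.float64] | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            if self.rectangle is None:
                raise ValueError("rectangle gate needs bounds (x_min, x_max, y_min, y_max)")
            x0, x1, y0, y1 = self.rectangle
            if not (x0 < x1 and y0 < y1):
                raise ValueError("rectangle bounds must satisfy x_min < x_max, y_min < y_max")
        elif self.kind == "ellipse":
            if self.center is None or self.shape is None or self.threshold is None:
                raise ValueError("ellipse gate needs center, shape matrix and threshold")
            self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
            S = np.asarray(self.shape, dtype=np.float64)
            if S.shape != (2, 2) or not np.allclose(S, S.T):
                raise ValueError("ellipse shape matrix must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(S) <= 0):
                raise ValueError("ellipse shape matrix must be positive definite")
            if self.threshold <= 0:
                raise ValueError("ellipse threshold must be positive")
            self.shape = S
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")


def apply_gate(sample: Sample, gate: GateSpec) -> Sample:
    """Return a new :class:`Sample` restricted to events inside the gate.

    Event order is preserved. An empty result is returned as a valid
    0-row sample with a warning.
    """
    x = sample.channel(gate.channel_x)
    y = sample.channel(gate.channel_y)
    if gate.kind == "rectangle":
        x0, x1, y0, y1 = gate.rectangle  # type: ignore[misc]
        keep = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    else:
        pts = np.column_stack([x, y]) - gate.center
        inv = np.linalg.inv(gate.shape)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        keep = np.sqrt(np.maximum(d2, 0.0)) <= gate.threshold
    if not np.any(keep):
        warnings.warn(
            f"gate on ({gate.channel_x}, {gate.channel_y}) retained no events "
            f"in sample {sample.sample_id!r}",
            stacklevel=2,
        )
    return Sample(
        sample.sample_id, list(sample.channel_names), sample.events[keep], dict(sample.metadata)
    )


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 reading and writing
# ---------------------------------------------------------------------------

_REQUIRED_KEYWORDS = ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # The standard escapes a literal delimiter by doubling it; values are
    # never empty, so split-and-rejoin on the doubled form is safe.
    parts = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(parts):
        part = parts[i]
        while i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            part = part + delim.decode("latin-1") + parts[i + 2]
            i += 2
        merged.append(part)
        i += 1
    parts = merged
    if len(parts) % 2 != 0:
        raise FcsFormatError("TEXT segment has an odd number of delimited tokens")
    kv: dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        kv[k.decode("latin-1").strip().upper()] = v.decode("latin-1").strip()
    return kv


def read_fcs(path: str, sample_id: str | None = None) -> Sample:
    """Read an FCS 3.0/3.1 list-mode file into a :class:`Sample`.

    All parameters become channels; values are returned untransformed and
    untruncated (negatives from compensation survive). $PnN short names
    become ``channel_names``; $PnS stain names are kept in ``metadata``.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 58:
        raise FcsFormatError(f"{path}: file too short to hold an FCS header")
    version = data[:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(segment: slice, name: str) -> int:
        txt = data[segment].decode("latin-1", errors="replace").strip()
        try:
            return int(txt) if txt else 0
        except ValueError:
            raise FcsFormatError(f"{path}: malformed header offset for {name}: {txt!r}") from None

    text_start = _offset(slice(10, 18), "TEXT start")
    text_end = _offset(slice(18, 26), "TEXT end")
    data_start = _offset(slice(26, 34), "DATA start")
    data_end = _offset(slice(34, 42), "DATA end")
    if text_start <= 0 or text_end <= text_start:
        raise FcsFormatError(f"{path}: invalid TEXT segment offsets {text_start}..{text_end}")
    kw = _parse_text_segment(data[text_start : text_end + 1])
    for key in _REQUIRED_KEYWORDS:
        if key not in kw:
            raise FcsFormatError(f"{path}: required keyword {key} missing from TEXT segment")
    if kw["$MODE"].upper() != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE=L) is supported, got {kw['$MODE']}")
    # Large files put the real DATA offsets in TEXT.
    if data_start == 0 and "$BEGINDATA" in kw:
        data_start = int(kw["$BEGINDATA"])
    if data_end == 0 and "$ENDDATA" in kw:
        data_end = int(kw["$ENDDATA"])
    if data_start <= 0 or data_end < data_start:
        raise FcsFormatError(f"{path}: invalid DATA segment offsets {data_start}..{data_end}")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw["$DATATYPE"].upper()
    byteord = kw["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsFormatError(f"{path}: unsupported $BYTEORD {kw['$BYTEORD']!r}")

    names: list[str] = []
    meta = {k: v for k, v in kw.items()}
    for p in range(1, n_par + 1):
        name = kw.get(f"$P{p}N")
        if name is None:
            raise FcsFormatError(f"{path}: missing $P{p}N")
        names.append(name)
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise FcsFormatError(f"{path}: duplicate $PnN channel names: {dupes}")

    bits = [int(kw.get(f"$P{p}B", "32")) for p in range(1, n_par + 1)]
    raw = data[data_start : data_end + 1]

    if dtype_code in ("F", "D"):
        width = 32 if dtype_code == "F" else 64
        if any(b != width for b in bits):
            raise FcsFormatError(
                f"{path}: $DATATYPE={dtype_code} requires $PnB={width} for all parameters"
            )
        np_dtype = np.dtype(f"{endian}f{width // 8}")
        needed = n_tot * n_par * np_dtype.itemsize
        if len(raw) < needed:
            raise FcsFormatError(
                f"{path}: DATA segment holds {len(raw)} bytes, need {needed} "
                f"for {n_tot} events x {n_par} parameters"
            )
        events = (
            np.frombuffer(raw[:needed], dtype=np_dtype).astype(np.float64).reshape(n_tot, n_par)
        )
    elif dtype_code == "I":
        if any(b not in (8, 16, 32, 64) for b in bits):
            raise FcsFormatError(f"{path}: unsupported integer $PnB widths {bits}")
        row_bytes = sum(b // 8 for b in bits)
        needed = n_tot * row_bytes
        if len(raw) < needed:
            raise FcsFormatError(f"{path}: DATA segment truncated ({len(raw)} < {needed} bytes)")
        fields = [(f"p{p}", np.dtype(f"{endian}u{bits[p - 1] // 8}")) for p in range(1, n_par + 1)]
        rec = np.frombuffer(raw[:needed], dtype=np.dtype(fields))
        cols = []
        for p in range(1, n_par + 1):
            col = rec[f"p{p}"].astype(np.uint64)
            # $PnR gives the measurement range; values are masked to
            # ceil(log2($PnR)) bits per the standard.
            rng = kw.get(f"$P{p}R")
            if rng is not None:
                r = int(float(rng))
                if r > 1:
                    mask = (1 << int(np.ceil(np.log2(r)))) - 1
                    col = col & np.uint64(mask)
            cols.append(col.astype(np.float64))
        events = np.column_stack(cols)
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {dtype_code!r} (need F, D or I)")

    sid = sample_id if sample_id is not None else str(path)
    return Sample(sid, names, events, meta)


def write_fcs(sample: Sample, path: str) -> None:
    """Write a :class:`Sample` as an FCS 3.1 file (float32 list mode)."""
    n_tot, n_par = sample.events.shape
    data_bytes = sample.events.astype("<f4").tobytes()

    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for p, name in enumerate(sample.channel_names, start=1):
        kw[f"$P{p}N"] = name
        kw[f"$P{p}B"] = "32"
        kw[f"$P{p}E"] = "0,0"
        col = sample.events[:, p - 1]
        rng = float(np.max(np.abs(col))) if n_tot else 1.0
        kw[f"$P{p}R"] = str(int(max(rng, 1.0)) + 1)
        stain = sample.metadata.get(f"$P{p}S")
        if stain:
            kw[f"$P{p}S"] = stain

    delim = "/"
    header_len = 58

    def _render(kws: Mapping[str, str]) -> bytes:
        out = delim
        for k, v in kws.items():
            out += f"{k}{delim}{v}{delim}"
        return out.encode("latin-1")

    # Offsets depend on the TEXT length, which depends on the offsets;
    # two passes with padding converge.
    for _ in range(3):
        text = _render(kw)
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data_bytes) - 1
        kw2 = dict(kw)
        kw2["$BEGINDATA"] = str(data_start)
        kw2["$ENDDATA"] = str(data_end)
        kw2["$BEGINANALYSIS"] = "0"
        kw2["$ENDANALYSIS"] = "0"
        kw2["$BEGINSTEXT"] = "0"
        kw2["$ENDSTEXT"] = "0"
        text2 = _render(kw2)
        if len(text2) == len(text):
            kw = kw2
            break
        kw = kw2
    text = _render(kw)
    text_end = header_len + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data_bytes) - 1

    def _fmt(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; real offsets live in TEXT
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _fmt(header_len) + _fmt(text_end)
    header += _fmt(data_start if data_end <= 99_999_999 else 0)
    header += _fmt(data_end if data_end <= 99_999_999 else 0)
    header += _fmt(0) + _fmt(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)
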