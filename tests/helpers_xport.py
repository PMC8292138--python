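"""Minimal SAS XPORT (version 5) writer, test-only.

Generates small transport files at test time so the XPT ingestion adapter can
be exercised against a CSV twin without shipping binary fixtures.  Numeric
values are encoded as IBM System/360 doubles, character values as
space-padded ASCII, per the public transport-format specification.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd


def _ibm_from_ieee(value: float) -> bytes:
    """Encode a float as an 8-byte IBM/360 hexadecimal floating-point number."""
    if value == 0.0 or np.isnan(value):
        return b"." + b"\x00" * 7 if np.isnan(value) else b"\x00" * 8
    sign = 0x80 if value < 0 else 0x00
    m = abs(value)
    # find base-16 exponent e with mantissa in [1/16, 1)
    e = 0
    while m >= 1.0:
        m /= 16.0
        e += 1
    while m < 1.0 / 16.0:
        m *= 16.0
        e -= 1
    mant = int(m * (1 << 56))
    if mant >= 1 << 56:  # rounding overflow
        mant >>= 4
        e += 1
    first = sign | (e + 64)
    return bytes([first]) + mant.to_bytes(7, "big")


def _record(text: str) -> bytes:
    return text.ljust(80).encode("ascii")


def _namestr(ntype: int, length: int, varnum: int, name: str, position: int) -> bytes:
    # 140-byte NAMESTR entry; only the fields pandas' reader consumes are filled
    out = struct.pack(
        ">hhhh8s40s8s",
        ntype,  # 1 numeric, 2 character
        0,  # name hash
        length,
        varnum,
        name.ljust(8).encode("ascii"),
        name.ljust(40).encode("ascii"),
        b" " * 8,  # format name
    )
    out += struct.pack(">hhh2s8shhh2s8shhl", 0, 0, 0, b"  ", b" " * 8, 0, 0, 0,
                       b"  ", b" " * 8, 0, 0, position)
    return out.ljust(140, b"\x00")


def write_xport(frame: pd.DataFrame, path, member: str = "DATA") -> None:
    """Write ``frame`` (numeric and string columns) as a v5 transport file."""
    ts = "01JAN20:00:00:00"
    blocks = [
        _record(
            "HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
            "000000000000000000000000000000"
        ),
        ("SAS     SAS     SASLIB  6.06    bsd4.2  " + " " * 24 + ts).ljust(80).encode(),
        _record(ts),
        _record(
            "HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
            "000000000000000001600000000140"
        ),
        _record(
            "HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
            "000000000000000000000000000000"
        ),
        (
            "SAS     "
            + member.ljust(8)
            + "SASDATA 6.06    bsd4.2  "
            + " " * 24
            + ts
        ).ljust(80).encode(),
        _record(ts + " " * 16 + member.ljust(40) + "    "),
        _record(
            "HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
            f"000000{len(frame.columns):04d}00000000000000000000"
        ),
    ]

    specs = []  # (name, is_char, length)
    position = 0
    namestrs = b""
    for varnum, col in enumerate(frame.columns, start=1):
        series = frame[col]
        if series.dtype.kind in "if":
            specs.append((col, False, 8))
            namestrs += _namestr(1, 8, varnum, str(col)[:8].upper(), position)
            position += 8
        else:
            width = max(1, int(series.astype(str).str.len().max()))
            specs.append((col, True, width))
            namestrs += _namestr(2, width, varnum, str(col)[:8].upper(), position)
            position += width
    if len(namestrs) % 80:
        namestrs += b" " * (80 - len(namestrs) % 80)
    blocks.append(namestrs)
    blocks.append(
        _record(
            "HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
            "000000000000000000000000000000"
        )
    )

    data = b""
    for _, row in frame.iterrows():
        for name, is_char, length in specs:
            if is_char:
                data += str(row[name]).ljust(length).encode("ascii")[:length]
            else:
                data += _ibm_from_ieee(float(row[name]))
    if len(data) % 80:
        data += b" " * (80 - len(data) % 80)
    blocks.append(data)

    with open(path, "wb") as fh:
        fh.write(b"".join(blocks))
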