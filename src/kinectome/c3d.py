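"""Minimal C3D motion-capture file I/O.

Supports the subset of the C3D standard needed for marker-trajectory
exchange: Intel (little-endian) byte order, floating-point point data, the
POINT parameter group (USED, FRAMES, LABELS, RATE, SCALE, UNITS,
DATA_START), and no analog channels.  Files written here are readable by
standard C3D tools; reading supports both float and scaled-integer point
data as long as the processor type is Intel.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["C3DContent", "read_c3d", "write_c3d"]

_BLOCK = 512
_PROC_INTEL = 84


@dataclass
class C3DContent:
    """Point data of one C3D file: positions are frames x markers x 3."""

    positions: np.ndarray
    labels: list[str]
    rate: float
    units: str = "m"


# ---------------------------------------------------------------------------
# writing


def _param_record(name: bytes, group_id: int, dtype: int, dims: list[int],
                  data: bytes) -> bytes:
    head = struct.pack("bb", len(name), group_id) + name
    body = struct.pack("b", dtype) + struct.pack("b", len(dims))
    body += bytes(dims) + data + b"\x00"  # empty description
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def _group_record(name: bytes, group_id: int) -> bytes:
    body = b"\x00"  # empty description
    offset = 2 + len(body)
    return (struct.pack("bb", len(name), -group_id) + name
            + struct.pack("<h", offset) + body)


def write_c3d(path: str | Path, positions: np.ndarray, labels: list[str],
              rate: float, units: str = "m") -> None:
    """Write marker trajectories to a C3D file (Intel, float point data)."""
    positions = np.asarray(positions, dtype=np.float32)
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError("positions must have shape (frames, markers, 3)")
    n_frames, n_points, _ = positions.shape
    if len(labels) != n_points:
        raise ValueError("label count does not match marker count")
    if n_frames > 65535:
        raise ValueError("too many frames for the 16-bit frame counter")

    label_len = max(max(len(s) for s in labels), 4)
    label_blob = b"".join(s.ljust(label_len).encode("ascii") for s in labels)
    units_b = units.encode("ascii")

    params = b"".join([
        _group_record(b"POINT", 1),
        _param_record(b"USED", 1, 2, [], struct.pack("<h", n_points)),
        _param_record(b"FRAMES", 1, 2, [], struct.pack("<h", n_frames)),
        _param_record(b"SCALE", 1, 4, [], struct.pack("<f", -1.0)),
        _param_record(b"RATE", 1, 4, [], struct.pack("<f", float(rate))),
        _param_record(b"UNITS", 1, -1, [len(units_b)], units_b),
        _param_record(b"LABELS", 1, -1, [label_len, n_points], label_blob),
    ])
    # 4-byte parameter header + records + terminating zero record
    param_bytes = 4 + len(params) + 4  # leave room for DATA_START added below
    # DATA_START record itself: name(10)+2 head +2 offset +2 type/dims +2 data +1 desc
    ds_record_len = 2 + 10 + 2 + 2 + 0 + 2 + 1
    param_bytes += ds_record_len
    n_param_blocks = -(-param_bytes // _BLOCK)
    data_start_block = 2 + n_param_blocks  # header is block 1, params at 2

    params += _param_record(b"DATA_START", 1, 2, [],
                            struct.pack("<h", data_start_block))
    param_section = struct.pack("BBBB", 1, 0x50, n_param_blocks, _PROC_INTEL)
    param_section += params
    param_section = param_section.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)  # param block #, magic
    struct.pack_into("<h", header, 2, n_points)
    struct.pack_into("<h", header, 4, 0)  # analog samples per frame
    struct.pack_into("<h", header, 6, 1)  # first frame
    struct.pack_into("<h", header, 8, n_frames)
    struct.pack_into("<h", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # scale (negative = float data)
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, float(rate))

    frame_block = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frame_block[:, :, :3] = positions
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(frame_block.tobytes())


# ---------------------------------------------------------------------------
# reading


def _parse_params(raw: bytes) -> dict[tuple[str, str], dict]:
    """Parse the parameter section into {(GROUP, PARAM): record} dicts."""
    if len(raw) < 4:
        raise ValueError("truncated C3D parameter section")
    proc = raw[3]
    if proc != _PROC_INTEL:
        raise ValueError(
            f"unsupported C3D processor type {proc}; only Intel (84) is read"
        )
    groups: dict[int, str] = {}
    records: list[tuple[int, str, bytes, int]] = []  # (gid, name, blob, pos)
    pos = 4
    while pos < len(raw):
        name_len = struct.unpack_from("b", raw, pos)[0]
        if name_len == 0:
            break
        group_id = struct.unpack_from("b", raw, pos + 1)[0]
        name = raw[pos + 2: pos + 2 + abs(name_len)].decode("ascii")
        off_pos = pos + 2 + abs(name_len)
        offset = struct.unpack_from("<h", raw, off_pos)[0]
        body_start = off_pos + 2
        if group_id < 0:
            groups[-group_id] = name
        else:
            records.append((group_id, name, raw, body_start))
        if offset <= 0:
            break
        pos = body_start + offset - 2

    out: dict[tuple[str, str], dict] = {}
    for gid, name, blob, start in records:
        dtype = struct.unpack_from("b", blob, start)[0]
        ndims = struct.unpack_from("b", blob, start + 1)[0]
        dims = list(blob[start + 2: start + 2 + ndims])
        dstart = start + 2 + ndims
        count = int(np.prod(dims)) if dims else 1
        itemsize = {-1: 1, 1: 1, 2: 2, 4: 4}[dtype]
        data = blob[dstart: dstart + count * itemsize]
        gname = groups.get(gid, str(gid))
        out[(gname, name)] = {"dtype": dtype, "dims": dims, "data": data}
    return out


def _param_scalar(rec: dict, fmt: str):
    return struct.unpack("<" + fmt, rec["data"])[0]


def read_c3d(path: str | Path) -> C3DContent:
    """Read marker trajectories from a C3D file."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _BLOCK or raw[1] != 0x50:
        raise ValueError(f"{path}: not a C3D file")
    param_block = raw[0]
    n_points = struct.unpack_from("<h", raw, 2)[0]
    first_frame = struct.unpack_from("<h", raw, 6)[0]
    last_frame = struct.unpack_from("<h", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_start = struct.unpack_from("<h", raw, 16)[0]
    rate = struct.unpack_from("<f", raw, 20)[0]
    n_frames = last_frame - first_frame + 1

    params = _parse_params(raw[(param_block - 1) * _BLOCK:])
    if ("POINT", "USED") in params:
        n_points = _param_scalar(params[("POINT", "USED")], "h")
    if ("POINT", "RATE") in params:
        rate = _param_scalar(params[("POINT", "RATE")], "f")
    if ("POINT", "SCALE") in params:
        scale = _param_scalar(params[("POINT", "SCALE")], "f")
    if ("POINT", "DATA_START") in params:
        data_start = _param_scalar(params[("POINT", "DATA_START")], "h")
    units = "m"
    if ("POINT", "UNITS") in params:
        units = params[("POINT", "UNITS")]["data"].decode("ascii").strip()

    labels = [f"M{i:02d}" for i in range(n_points)]
    if ("POINT", "LABELS") in params:
        rec = params[("POINT", "LABELS")]
        if len(rec["dims"]) == 2:
            width, count = rec["dims"]
            blob = rec["data"].decode("ascii")
            labels = [
                blob[i * width:(i + 1) * width].strip() for i in range(count)
            ]

    offset = (data_start - 1) * _BLOCK
    if scale < 0:
        frame = np.frombuffer(
            raw, dtype="<f4", count=n_frames * n_points * 4, offset=offset
        ).reshape(n_frames, n_points, 4)
        positions = frame[:, :, :3].astype(np.float32)
    else:
        frame = np.frombuffer(
            raw, dtype="<i2", count=n_frames * n_points * 4, offset=offset
        ).reshape(n_frames, n_points, 4)
        positions = frame[:, :, :3].astype(np.float64) * scale
    return C3DContent(
        positions=positions, labels=labels, rate=float(rate), units=units
    )
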