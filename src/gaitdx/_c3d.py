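"""Minimal C3D codec for 3-D point data.

C3D is the standard binary container for motion-capture point data: a
512-byte-block file with a fixed header block, a self-describing parameter
section (groups/parameters), and frame-sequential point data.  This codec
supports the subset needed for marker trajectories:

* Intel (little-endian) processor type, floating-point point storage,
* the ``POINT`` group with ``USED``, ``FRAMES``, ``RATE``, ``SCALE``,
  ``DATA_START`` and ``LABELS``,
* no analog channels.

Files written here are readable by standard C3D tools; reading supports
both float and scaled-integer point data from Intel-ordered files.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

BLOCK = 512
_PROC_INTEL = 84  # processor type byte: 83 + 1


def write(path, labels: list[str], points: np.ndarray, frame_rate: float) -> None:
    """Write point data as a float-storage C3D file.

    Parameters
    ----------
    labels
        One label per point, in storage order.
    points
        Array (n_frames, n_points, 3), millimetres.
    frame_rate
        Frames per second.
    """
    points = np.asarray(points, dtype=np.float32)
    n_frames, n_points, _ = points.shape
    if n_frames > 32767:
        raise ValueError("C3D int16 frame fields cap at 32767 frames")

    param = _build_parameter_section(labels, n_points, n_frames, frame_rate)
    n_param_blocks = (len(param) + BLOCK - 1) // BLOCK
    param = param.ljust(n_param_blocks * BLOCK, b"\x00")
    # patch the parameter-section block count (byte 2 of the section)
    param = param[:2] + bytes([n_param_blocks]) + param[3:]
    data_start_block = 2 + n_param_blocks  # 1-based

    header = bytearray(BLOCK)
    header[0] = 2          # parameter section starts at block 2
    header[1] = 0x50       # C3D magic
    struct.pack_into("<h", header, 2, n_points)
    struct.pack_into("<h", header, 4, 0)              # analog per frame
    struct.pack_into("<h", header, 6, 1)              # first frame
    struct.pack_into("<h", header, 8, n_frames)       # last frame
    struct.pack_into("<h", header, 10, 0)             # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)          # scale < 0 => float data
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)             # analog samples per frame
    struct.pack_into("<f", header, 20, float(frame_rate))

    frames = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frames[:, :, :3] = points  # residual word left at 0
    with Path(path).open("wb") as fh:
        fh.write(bytes(header))
        fh.write(param)
        fh.write(frames.tobytes())


def _entry(name: str, group_id: int, payload: bytes, last: bool = False) -> bytes:
    name_b = name.encode("ascii")
    # offset counts from the byte following the 2-byte offset field
    offset = 0 if last else len(payload)
    return (
        struct.pack("<bb", len(name_b), group_id)
        + name_b
        + struct.pack("<H", offset)
        + payload
    )


def _param_payload(dtype: int, dims: list[int], data: bytes) -> bytes:
    return (
        struct.pack("<b", dtype)
        + struct.pack("<B", len(dims))
        + bytes(dims)
        + data
        + b"\x00"  # empty description
    )


def _build_parameter_section(labels, n_points, n_frames, frame_rate) -> bytes:
    width = max(len(s) for s in labels)
    label_block = b"".join(s.ljust(width).encode("ascii") for s in labels)
    gid = 1
    out = bytes([0x01, 0x50, 0, _PROC_INTEL])  # block count patched later
    out += _entry("POINT", -gid, b"\x00")  # group: empty description
    out += _entry("USED", gid, _param_payload(2, [], struct.pack("<h", n_points)))
    out += _entry("FRAMES", gid, _param_payload(2, [], struct.pack("<h", n_frames)))
    out += _entry("RATE", gid, _param_payload(4, [], struct.pack("<f", frame_rate)))
    out += _entry("SCALE", gid, _param_payload(4, [], struct.pack("<f", -1.0)))
    out += _entry("DATA_START", gid, _param_payload(2, [], struct.pack("<h", 0)))
    out += _entry(
        "LABELS", gid,
        _param_payload(-1, [width, len(labels)], label_block),
        last=True,
    )
    return out


def read(path):
    """Read an Intel-ordered C3D file.

    Returns
    -------
    labels : list[str]
        Stripped point labels in storage order.
    points : ndarray (n_frames, n_points, 3)
    frame_rate : float
    """
    raw = Path(path).read_bytes()
    if len(raw) < BLOCK or raw[1] != 0x50:
        raise IOError(f"{path}: not a C3D file")
    n_points = struct.unpack_from("<h", raw, 2)[0]
    first = struct.unpack_from("<h", raw, 6)[0]
    last = struct.unpack_from("<h", raw, 8)[0]
    scale = struct.unpack_from("<f", raw, 12)[0]
    data_start = struct.unpack_from("<h", raw, 16)[0]
    analog_per_frame = struct.unpack_from("<h", raw, 18)[0]
    frame_rate = struct.unpack_from("<f", raw, 20)[0]
    n_frames = last - first + 1

    param_start = (raw[0] - 1) * BLOCK
    if len(raw) <= param_start + 4:
        raise IOError(f"{path}: truncated parameter section")
    if raw[param_start + 3] != _PROC_INTEL:
        raise IOError(
            f"{path}: unsupported processor type {raw[param_start + 3]} "
            "(only Intel-ordered files are supported)"
        )
    params = _parse_parameters(raw, param_start)
    labels = params.get(("POINT", "LABELS"), [f"M{i}" for i in range(n_points)])
    labels = labels[:n_points]

    offset = (data_start - 1) * BLOCK
    if scale < 0:
        words_per_frame = n_points * 4 + analog_per_frame
        need = offset + n_frames * words_per_frame * 4
        if len(raw) < need:
            raise IOError(f"{path}: truncated point data")
        arr = np.frombuffer(raw, dtype="<f4", count=n_frames * words_per_frame,
                            offset=offset)
        arr = arr.reshape(n_frames, words_per_frame)[:, : n_points * 4]
        points = arr.reshape(n_frames, n_points, 4)[:, :, :3].astype(float)
    else:
        words_per_frame = n_points * 4 + analog_per_frame
        arr = np.frombuffer(raw, dtype="<i2", count=n_frames * words_per_frame,
                            offset=offset)
        arr = arr.reshape(n_frames, words_per_frame)[:, : n_points * 4]
        points = arr.reshape(n_frames, n_points, 4)[:, :, :3].astype(float) * scale
    return labels, points, float(frame_rate)


def _parse_parameters(raw: bytes, start: int) -> dict:
    """Walk the group/parameter entries; return {(GROUP, PARAM): value}."""
    groups: dict[int, str] = {}
    values: dict[tuple[int, str], object] = {}
    pos = start + 4
    end = len(raw)
    while pos + 2 <= end:
        name_len = struct.unpack_from("<b", raw, pos)[0]
        if name_len == 0:
            break
        group_id = struct.unpack_from("<b", raw, pos + 1)[0]
        n = abs(name_len)
        name = raw[pos + 2 : pos + 2 + n].decode("ascii", "replace").strip()
        off_pos = pos + 2 + n
        offset = struct.unpack_from("<H", raw, off_pos)[0]
        body = off_pos + 2
        if group_id < 0:
            groups[-group_id] = name
        else:
            values[(group_id, name)] = _parse_param_value(raw, body)
        if offset == 0:
            break
        pos = body + offset  # offset counts from the byte after the offset field
    out = {}
    for (gid, pname), val in values.items():
        out[(groups.get(gid, str(gid)), pname)] = val
    return out


def _parse_param_value(raw: bytes, pos: int):
    dtype = struct.unpack_from("<b", raw, pos)[0]
    ndims = raw[pos + 1]
    dims = list(raw[pos + 2 : pos + 2 + ndims])
    data_pos = pos + 2 + ndims
    count = int(np.prod(dims)) if dims else 1
    if dtype == -1:  # characters
        if len(dims) == 2:
            width, n = dims
            s = raw[data_pos : data_pos + width * n].decode("ascii", "replace")
            return [s[i * width : (i + 1) * width].strip() for i in range(n)]
        return raw[data_pos : data_pos + count].decode("ascii", "replace").strip()
    size = {1: 1, 2: 2, 4: 4}[dtype]
    fmt = {1: "<b", 2: "<h", 4: "<f"}[dtype]
    vals = [
        struct.unpack_from(fmt, raw, data_pos + i * size)[0] for i in range(count)
    ]
    return vals if len(vals) > 1 else vals[0]
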