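"""Minimal C3D reader/writer for optical motion-capture point data.

Supports the common modern subset of the C3D standard: Intel (little-endian)
byte order and floating-point point data (negative POINT:SCALE).  Analog
channels, integer point storage and non-Intel processor types are rejected
with :class:`C3DFormatError`.  Marker gaps (negative residuals) are returned
as NaN coordinates.

The writer produces files the reader round-trips bit-exactly on positions;
it exists both as general I/O and as the fixture generator for tests.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["C3DFormatError", "read_c3d", "write_c3d"]

_BLOCK = 512
_PROC_INTEL = 84


class C3DFormatError(ValueError):
    """Raised when a file is not a C3D file or uses an unsupported variant."""


def read_c3d(path):
    """Read point data from a C3D file.

    Returns
    -------
    positions : float64 array [T, N, 3] (NaN where the residual marks a gap)
    labels : list of N marker names (trailing blanks stripped)
    rate : sampling rate in Hz (POINT:RATE, falling back to the header)
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 2 * _BLOCK or raw[1] != 0x50:
        raise C3DFormatError("not a C3D file (bad magic byte)")
    param_block = raw[0]
    header = struct.unpack_from("<HHHHHH", raw, 2)
    n_points, analog_per_frame, first_frame, last_frame = header[0:4]
    data_block = struct.unpack_from("<H", raw, 16)[0]
    rate_hdr = struct.unpack_from("<f", raw, 20)[0]

    params = _read_params(raw, (param_block - 1) * _BLOCK)
    point = params.get("POINT", {})
    scale = point.get("SCALE", -1.0)
    if np.ndim(scale):
        scale = float(np.ravel(scale)[0])
    if scale >= 0:
        raise C3DFormatError("integer-scaled point data is not supported")
    n_points = int(np.ravel(point.get("USED", n_points))[0]) if "USED" in point else n_points
    n_frames = last_frame - first_frame + 1
    if "FRAMES" in point:
        n_frames = int(np.ravel(point["FRAMES"])[0])
    rate = float(np.ravel(point.get("RATE", rate_hdr))[0])
    if "DATA_START" in point:
        data_block = int(np.ravel(point["DATA_START"])[0])

    labels = point.get("LABELS")
    if labels is None:
        names = [f"M{i + 1}" for i in range(n_points)]
    else:
        names = [str(s).strip() for s in labels[:n_points]]

    offset = (data_block - 1) * _BLOCK
    count = n_frames * n_points * 4
    flat = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
    frames = flat.reshape(n_frames, n_points, 4)
    positions = frames[:, :, :3].astype(np.float64)
    positions[frames[:, :, 3] < 0] = np.nan
    return positions, names, rate


def _read_params(raw: bytes, start: int) -> dict:
    if raw[start + 3] != _PROC_INTEL:
        raise C3DFormatError("only Intel (little-endian) C3D files are supported")
    groups: dict[int, str] = {}
    values: dict[str, dict] = {}
    pending: list[tuple[int, str, object]] = []
    pos = start + 4
    while pos < len(raw):
        name_len = struct.unpack_from("<b", raw, pos)[0]
        if name_len == 0:
            break
        gid = struct.unpack_from("<b", raw, pos + 1)[0]
        name = raw[pos + 2: pos + 2 + abs(name_len)].decode("ascii").strip()
        p = pos + 2 + abs(name_len)
        next_off = struct.unpack_from("<h", raw, p)[0]
        if gid < 0:  # group record
            groups[-gid] = name
        else:        # parameter record
            dtype = struct.unpack_from("<b", raw, p + 2)[0]
            ndims = raw[p + 3]
            dims = list(raw[p + 4: p + 4 + ndims])
            dp = p + 4 + ndims
            total = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                if len(dims) <= 1:
                    val = raw[dp: dp + total].decode("ascii")
                else:
                    w = dims[0]
                    cnt = total // w
                    val = [raw[dp + k * w: dp + (k + 1) * w].decode("ascii")
                           for k in range(cnt)]
            elif dtype == 1:
                val = np.frombuffer(raw, "<i1", total, dp).copy()
            elif dtype == 2:
                val = np.frombuffer(raw, "<i2", total, dp).copy()
            elif dtype == 4:
                val = np.frombuffer(raw, "<f4", total, dp).copy()
            else:
                raise C3DFormatError(f"unknown parameter type {dtype}")
            pending.append((gid, name, val))
        if next_off == 0:
            break
        pos = p + next_off
    for gid, name, val in pending:
        gname = groups.get(gid, f"GROUP{gid}")
        values.setdefault(gname, {})[name] = val
    return values


def write_c3d(path, positions, labels, rate: float) -> None:
    """Write float point data as a minimal Intel C3D file.

    ``positions`` is [T, N, 3]; NaN coordinates are stored with a negative
    residual (marker gap).  Marker ``labels`` must fit in 32 characters.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError("positions must have shape [T, N, 3]")
    T, N, _ = positions.shape
    if T > 32767:
        raise ValueError("minimal writer supports at most 32767 frames")
    label_w = max(4, max(len(s) for s in labels))
    if label_w > 32:
        raise ValueError("marker labels longer than 32 characters")

    # parameter section: one POINT group
    body = bytearray()
    _group(body, 1, "POINT", last=False)
    _param(body, 1, "USED", 2, np.array([N], "<i2"))
    _param(body, 1, "FRAMES", 2, np.array([T], "<i2"))
    _param(body, 1, "RATE", 4, np.array([rate], "<f4"))
    _param(body, 1, "SCALE", 4, np.array([-1.0], "<f4"))
    padded = [s.ljust(label_w) for s in labels]
    _param(body, 1, "LABELS", -1, "".join(padded).encode("ascii"),
           dims=[label_w, N])
    n_param_blocks = -(-(len(body) + 5) // _BLOCK)
    data_block = 2 + n_param_blocks
    _param(body, 1, "DATA_START", 2, np.array([data_block], "<i2"), last=True)
    n_param_blocks = -(-(len(body) + 4) // _BLOCK)
    data_block = 2 + n_param_blocks

    # patch DATA_START (last int16 payload written before terminator)
    struct.pack_into("<h", body, _DATA_START_POS[0], data_block)

    header = bytearray(_BLOCK)
    header[0] = 2           # first parameter block
    header[1] = 0x50
    struct.pack_into("<HHHHH", header, 2, N, 0, 1, T, 10)
    struct.pack_into("<f", header, 12, -1.0)       # header scale (float data)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)
    struct.pack_into("<f", header, 20, float(rate))

    pblock = bytearray(_BLOCK * n_param_blocks)
    pblock[0] = 1
    pblock[1] = 0x50
    pblock[2] = n_param_blocks
    pblock[3] = _PROC_INTEL
    pblock[4:4 + len(body)] = body

    frames = np.zeros((T, N, 4), dtype="<f4")
    gaps = np.isnan(positions).any(axis=2)
    frames[:, :, :3] = np.nan_to_num(positions, nan=0.0)
    frames[:, :, 3] = np.where(gaps, -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(pblock)
        fh.write(frames.tobytes())


_DATA_START_POS = [0]


def _group(body: bytearray, gid: int, name: str, last: bool) -> None:
    rec = struct.pack("<bb", len(name), -gid) + name.encode("ascii")
    tail = struct.pack("<hB", 0 if last else 3, 0)
    body += rec + tail


def _param(body: bytearray, gid: int, name: str, dtype: int, data,
           dims=None, last: bool = False) -> None:
    if isinstance(data, np.ndarray):
        payload = data.tobytes()
        if dims is None:
            dims = [] if data.size == 1 else [data.size]
    else:
        payload = bytes(data)
        if dims is None:
            dims = [len(payload)]
    rec = struct.pack("<bb", len(name), gid) + name.encode("ascii")
    meta = struct.pack("<bB", dtype, len(dims)) + bytes(dims)
    desc = struct.pack("<B", 0)
    offset = 0 if last else 2 + len(meta) + len(payload) + len(desc)
    if name == "DATA_START":
        _DATA_START_POS[0] = len(body) + len(rec) + 2 + len(meta)
    body += rec + struct.pack("<h", offset) + meta + payload + desc
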