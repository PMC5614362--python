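"""Minimal MRC2014 volume I/O.

Supports the standard 1024-byte header and data modes 0 (int8), 1 (int16)
and 2 (float32), which covers the files produced by common tomographic
reconstruction packages.  Axis correspondence on disk is the MRC default
(columns = x fastest, then y, then z); arrays are returned in (z, y, x)
order.  Extended headers are skipped on read and never written.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_BYTES = 1024

# MRC mode -> dtype (little-endian assumed; MACHST is written accordingly)
_MODE_DTYPES = {0: np.dtype("<i1"), 1: np.dtype("<i2"), 2: np.dtype("<f4")}
_DTYPE_MODES = {np.dtype(np.int8): 0, np.dtype(np.int16): 1, np.dtype(np.float32): 2}


def mode_for_dtype(dtype) -> int:
    """Return the MRC mode for ``dtype``, upcasting anything else to float32."""
    return _DTYPE_MODES.get(np.dtype(dtype), 2)


def read(path) -> np.ndarray:
    """Read an MRC file and return its volume as a (z, y, x) ndarray."""
    with open(path, "rb") as f:
        header = f.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header")
        words = np.frombuffer(header, dtype="<i4")
        nx, ny, nz, mode = (int(w) for w in words[:4])
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) < 1:
            raise ValueError(f"{path}: bad MRC dimensions ({nx}, {ny}, {nz})")
        nsymbt = int(words[23])  # extended header size
        f.seek(HEADER_BYTES + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        data = np.fromfile(f, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"{path}: truncated MRC data block")
    return data.reshape(nz, ny, nx)


def write(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a (z, y, x) volume to ``path`` as MRC mode 0, 1 or 2.

    Integer arrays of width <= 16 bits keep their type; everything else is
    written as float32.  ``voxel_size`` is (dz, dy, dx) in angstroms and only
    fills the cell dimensions of the header.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"MRC writer expects a 3D array, got shape {data.shape}")
    mode = mode_for_dtype(data.dtype)
    out = np.ascontiguousarray(data.astype(_MODE_DTYPES[mode], copy=False))
    nz, ny, nx = out.shape

    words = np.zeros(256, dtype="<i4")
    fwords = words.view("<f4")
    words[0:3] = [nx, ny, nz]
    words[3] = mode
    words[7:10] = [nx, ny, nz]  # sampling grid = full cell
    fwords[10:13] = [nx * voxel_size[2], ny * voxel_size[1], nz * voxel_size[0]]
    fwords[13:16] = 90.0
    words[16:19] = [1, 2, 3]  # x, y, z axis order
    stats = out.astype(np.float64)
    fwords[19] = stats.min()
    fwords[20] = stats.max()
    fwords[21] = stats.mean()
    words[26] = struct.unpack("<i", b"MRCO")[0]  # exttyp placeholder
    words[27] = 20140  # MRC2014 version stamp
    words[52] = struct.unpack("<i", b"MAP ")[0]
    words[53] = struct.unpack("<i", b"\x44\x44\x00\x00")[0]  # little-endian MACHST
    fwords[54] = float(stats.std())

    with open(path, "wb") as f:
        f.write(words.tobytes())
        f.write(out.tobytes())
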