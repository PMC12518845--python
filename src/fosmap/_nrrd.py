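"""Minimal NRRD volume I/O (raw encoding only).

Supports exactly what atlas bundles need: integer 3D label volumes with
little-endian raw encoding. Header fields other than type/dimension/sizes/
endian/encoding are preserved on read but ignored.
"""

from __future__ import annotations

import numpy as np

_TYPE_TO_DTYPE = {
    "signed char": "i1", "int8": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4",
    "long long": "i8", "int64": "i8",
    "unsigned long long": "u8", "uint64": "u8",
    "float": "f4", "double": "f8",
}
_DTYPE_TO_TYPE = {
    "i1": "int8", "u1": "uint8", "i2": "int16", "u2": "uint16",
    "i4": "int32", "u4": "uint32", "i8": "int64", "u8": "uint64",
    "f4": "float", "f8": "double",
}


def read_nrrd(path) -> np.ndarray:
    """Read a raw-encoded NRRD file into a C-ordered array."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if not text or text.startswith("#"):
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        encoding = fields.get("encoding", "raw")
        if encoding != "raw":
            raise ValueError(f"unsupported NRRD encoding {encoding!r} (raw only)")
        dtype_code = _TYPE_TO_DTYPE.get(fields.get("type", ""))
        if dtype_code is None:
            raise ValueError(f"unsupported NRRD type {fields.get('type')!r}")
        endian = "<" if fields.get("endian", "little") == "little" else ">"
        sizes = tuple(int(s) for s in fields["sizes"].split())
        data = np.frombuffer(fh.read(), dtype=endian + dtype_code)
    if data.size != int(np.prod(sizes)):
        raise ValueError(f"{path}: data size does not match header sizes {sizes}")
    # NRRD lists the fastest-varying axis first: fortran order w.r.t. sizes.
    return np.ascontiguousarray(data.reshape(sizes, order="F"))


def write_nrrd(path, array: np.ndarray) -> None:
    """Write an array as little-endian raw-encoded NRRD."""
    array = np.asarray(array)
    type_name = _DTYPE_TO_TYPE[array.dtype.str.lstrip("<>|=")]
    header = (
        f"NRRD0004\n"
        f"type: {type_name}\n"
        f"dimension: {array.ndim}\n"
        f"sizes: {' '.join(str(s) for s in array.shape)}\n"
        f"endian: little\n"
        f"encoding: raw\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(array.astype(array.dtype.newbyteorder("<")).tobytes(order="F"))
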