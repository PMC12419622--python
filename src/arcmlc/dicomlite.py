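"""Minimal DICOM (Part 10) codec for the RT objects this toolkit exchanges.

Implements just enough of the standard to read and write conformant RT-PLAN /
RT-DOSE / RT-STRUCT files: little-endian transfer syntaxes (explicit and
implicit on read, explicit on write), nested sequences with defined or
undefined lengths, and the string/binary VRs those objects use.  No general
DICOM library is bundled with the runtime environment, hence this in-repo
subset; it is not a general-purpose DICOM implementation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .errors import InputError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"

_LONG_VRS = {"OB", "OW", "OF", "OD", "SQ", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN", "SH", "ST", "TM", "UI"}

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE0DD)
_UNDEFINED = 0xFFFFFFFF

# VR dictionary for the tags this toolkit understands (needed for implicit VR).
VR_DICT: dict[tuple[int, int], str] = {
    (0x0002, 0x0000): "UL", (0x0002, 0x0001): "OB", (0x0002, 0x0002): "UI",
    (0x0002, 0x0003): "UI", (0x0002, 0x0010): "UI", (0x0002, 0x0012): "UI",
    (0x0008, 0x0016): "UI", (0x0008, 0x0018): "UI", (0x0008, 0x0060): "CS",
    (0x0020, 0x0032): "DS", (0x0020, 0x0037): "DS",
    (0x0028, 0x0002): "US", (0x0028, 0x0008): "IS", (0x0028, 0x0010): "US",
    (0x0028, 0x0011): "US", (0x0028, 0x0030): "DS", (0x0028, 0x0100): "US",
    (0x0028, 0x0101): "US", (0x0028, 0x0102): "US", (0x0028, 0x0103): "US",
    (0x3004, 0x0002): "CS", (0x3004, 0x0004): "CS", (0x3004, 0x000C): "DS",
    (0x3004, 0x000E): "DS",
    (0x3006, 0x0020): "SQ", (0x3006, 0x0022): "IS", (0x3006, 0x0026): "LO",
    (0x3006, 0x0039): "SQ", (0x3006, 0x0040): "SQ", (0x3006, 0x0042): "CS",
    (0x3006, 0x0046): "IS", (0x3006, 0x0050): "DS", (0x3006, 0x0084): "IS",
    (0x300A, 0x0002): "SH", (0x300A, 0x0070): "SQ", (0x300A, 0x0078): "IS",
    (0x300A, 0x0086): "DS", (0x300A, 0x00B0): "SQ", (0x300A, 0x00B4): "DS",
    (0x300A, 0x00B6): "SQ", (0x300A, 0x00B8): "CS", (0x300A, 0x00BC): "IS",
    (0x300A, 0x00BE): "DS", (0x300A, 0x00C0): "IS", (0x300A, 0x00C2): "LO",
    (0x300A, 0x010E): "DS", (0x300A, 0x0110): "IS", (0x300A, 0x0111): "SQ",
    (0x300A, 0x0112): "IS", (0x300A, 0x011A): "SQ", (0x300A, 0x011C): "DS",
    (0x300A, 0x011E): "DS", (0x300A, 0x0134): "DS",
    (0x300C, 0x0004): "SQ", (0x300C, 0x0006): "IS",
    (0x7FE0, 0x0010): "OW",
}


@dataclass
class Element:
    tag: tuple[int, int]
    vr: str
    value: object  # bytes for leaf elements, list[Dataset] for SQ


@dataclass
class Dataset:
    """An ordered collection of data elements keyed by (group, element)."""

    elements: dict = field(default_factory=dict)

    # -- setters ------------------------------------------------------------
    def set(self, tag: tuple[int, int], vr: str, value) -> None:
        if vr == "SQ":
            self.elements[tag] = Element(tag, vr, list(value))
            return
        if isinstance(value, bytes):
            raw = value
        elif vr in _STRING_VRS:
            if isinstance(value, (list, tuple)):
                value = "\\".join(_num_str(v) if vr in ("DS", "IS") else str(v) for v in value)
            elif vr in ("DS", "IS") and not isinstance(value, str):
                value = _num_str(value)
            raw = str(value).encode("ascii")
            if len(raw) % 2:
                raw += b"\x00" if vr == "UI" else b" "
        elif vr == "US":
            raw = struct.pack("<H", int(value))
        elif vr == "UL":
            raw = struct.pack("<I", int(value))
        else:
            raise InputError(f"cannot encode VR {vr} from {type(value)}")
        self.elements[tag] = Element(tag, vr, raw)

    # -- getters ------------------------------------------------------------
    def __contains__(self, tag) -> bool:
        return tag in self.elements

    def raw(self, tag) -> bytes:
        return self.elements[tag].value

    def string(self, tag, default=None):
        if tag not in self.elements:
            return default
        return self.elements[tag].value.decode("ascii", "replace").strip("\x00 ")

    def strings(self, tag) -> list[str]:
        return [s.strip("\x00 ") for s in self.elements[tag].value.decode("ascii").split("\\")]

    def floats(self, tag, default=None):
        if tag not in self.elements:
            return default
        s = self.elements[tag].value.decode("ascii").strip("\x00 ")
        if not s:
            return default
        return [float(v) for v in s.split("\\")]

    def float1(self, tag, default=None):
        v = self.floats(tag)
        return default if v is None else v[0]

    def ints(self, tag, default=None):
        v = self.floats(tag, None)
        return default if v is None else [int(round(x)) for x in v]

    def int1(self, tag, default=None):
        v = self.ints(tag)
        return default if v is None else v[0]

    def ushort(self, tag, default=None):
        if tag not in self.elements:
            return default
        return struct.unpack("<H", self.elements[tag].value[:2])[0]

    def sequence(self, tag) -> list["Dataset"]:
        if tag not in self.elements:
            return []
        return self.elements[tag].value


def _num_str(v) -> str:
    """DS/IS encoding: <=16 chars, no trailing junk."""
    if isinstance(v, int):
        return str(v)
    s = repr(float(v))
    if len(s) > 16:
        s = "%.10g" % float(v)
    return s


# ---------------------------------------------------------------------------
# Encoding (always Explicit VR Little Endian)
# ---------------------------------------------------------------------------


def _encode_element(el: Element) -> bytes:
    if el.vr == "SQ":
        body = b"".join(_encode_item(item) for item in el.value)
    else:
        body = el.value
        if len(body) % 2:
            body += b"\x00"
    head = struct.pack("<HH", *el.tag) + el.vr.encode("ascii")
    if el.vr in _LONG_VRS:
        head += struct.pack("<HI", 0, len(body))
    else:
        if len(body) > 0xFFFF:
            raise InputError(f"element {el.tag} too long for short-form VR {el.vr}")
        head += struct.pack("<H", len(body))
    return head + body


def _encode_item(ds: Dataset) -> bytes:
    body = encode_dataset(ds)
    return struct.pack("<HHI", *_ITEM, len(body)) + body


def encode_dataset(ds: Dataset) -> bytes:
    return b"".join(_encode_element(el) for _, el in sorted(ds.elements.items()))


def write_file(ds: Dataset, path, sop_class_uid: str, sop_instance_uid: str) -> None:
    """Write a Part-10 file (128-byte preamble, DICM, file meta, dataset)."""
    meta = Dataset()
    meta.set((0x0002, 0x0001), "OB", b"\x00\x01")
    meta.set((0x0002, 0x0002), "UI", sop_class_uid)
    meta.set((0x0002, 0x0003), "UI", sop_instance_uid)
    meta.set((0x0002, 0x0010), "UI", EXPLICIT_VR_LE)
    meta.set((0x0002, 0x0012), "UI", "1.2.826.0.1.3680043.10.1437.1")
    meta_bytes = encode_dataset(meta)
    group_len = Dataset()
    group_len.set((0x0002, 0x0000), "UL", len(meta_bytes))
    with open(path, "wb") as f:
        f.write(b"\x00" * 128 + b"DICM")
        f.write(encode_dataset(group_len) + meta_bytes)
        f.write(encode_dataset(ds))


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


class _Reader:
    def __init__(self, buf: bytes, pos: int, explicit: bool):
        self.buf = buf
        self.pos = pos
        self.explicit = explicit

    def _u16(self) -> int:
        v = struct.unpack_from("<H", self.buf, self.pos)[0]
        self.pos += 2
        return v

    def _u32(self) -> int:
        v = struct.unpack_from("<I", self.buf, self.pos)[0]
        self.pos += 4
        return v

    def read_element(self):
        tag = (self._u16(), self._u16())
        if tag in (_ITEM_DELIM, _SEQ_DELIM, _ITEM):
            length = self._u32()
            return tag, None, length
        if self.explicit:
            vr = self.buf[self.pos : self.pos + 2].decode("ascii")
            self.pos += 2
            if vr in _LONG_VRS:
                self.pos += 2
                length = self._u32()
            else:
                length = self._u16()
        else:
            length = self._u32()
            vr = VR_DICT.get(tag, "UN")
        return tag, vr, length

    def read_dataset(self, end: int) -> Dataset:
        ds = Dataset()
        while self.pos < end:
            tag, vr, length = self.read_element()
            if tag == _ITEM_DELIM:
                break
            if tag in (_ITEM, _SEQ_DELIM):
                raise InputError(f"unexpected sequence framing tag {tag} in dataset")
            if vr == "SQ" or length == _UNDEFINED:
                items = self.read_sequence(length, end)
                ds.elements[tag] = Element(tag, "SQ", items)
            else:
                ds.elements[tag] = Element(tag, vr, self.buf[self.pos : self.pos + length])
                self.pos += length
        return ds

    def read_sequence(self, length: int, outer_end: int) -> list:
        end = outer_end if length == _UNDEFINED else self.pos + length
        items = []
        while self.pos < end:
            tag, _, ilen = self.read_element()
            if tag == _SEQ_DELIM:
                break
            if tag != _ITEM:
                raise InputError(f"expected sequence item, found tag {tag}")
            item_end = end if ilen == _UNDEFINED else self.pos + ilen
            items.append(self.read_dataset(item_end))
        return items


def read_file(path) -> Dataset:
    with open(path, "rb") as f:
        buf = f.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise InputError(f"{path}: not a DICOM Part-10 file (missing DICM marker)")

    meta_reader = _Reader(buf, 132, explicit=True)
    tag, vr, length = meta_reader.read_element()
    if tag != (0x0002, 0x0000):
        raise InputError(f"{path}: file meta group length element missing")
    meta_len = struct.unpack("<I", buf[meta_reader.pos : meta_reader.pos + 4])[0]
    meta_reader.pos += length
    meta = meta_reader.read_dataset(meta_reader.pos + meta_len)
    tsuid = meta.string((0x0002, 0x0010), EXPLICIT_VR_LE)
    if tsuid not in (EXPLICIT_VR_LE, IMPLICIT_VR_LE):
        raise InputError(f"{path}: unsupported transfer syntax {tsuid}")

    body = _Reader(buf, meta_reader.pos, explicit=(tsuid == EXPLICIT_VR_LE))
    return body.read_dataset(len(buf))
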