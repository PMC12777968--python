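"""LZ-string compression, UTF-16-safe dialect.

The report embeds its (potentially large) plot specification as a single
compressed JavaScript string, decompressed client-side.  Binary payloads are
impossible in a static HTML file, so the codec must emit *text*: this is the
lz-string scheme — an LZ78/LZW-family dictionary coder whose bitstream is
packed 15 bits per UTF-16 code unit, offset by 32 so every output unit lands
in a printable, surrogate-free BMP range.  The functions here are
bit-compatible with the reference JavaScript library's
``compressToUTF16``/``decompressFromUTF16`` pair, so the small decompressor
shipped inside the HTML report can read payloads produced here.

Strings are processed as UTF-16 code units (JavaScript string semantics),
so astral characters round-trip through their surrogate pairs.
"""

from __future__ import annotations

import struct
from typing import List

__all__ = ["compress_utf16", "decompress_utf16"]


def _to_units(text: str) -> List[int]:
    """UTF-16 code units of ``text`` (surrogate pairs kept as two units)."""
    raw = text.encode("utf-16-le")
    return list(struct.unpack(f"<{len(raw) // 2}H", raw))


def _from_units(units: List[int]) -> str:
    return struct.pack(f"<{len(units)}H", *units).decode("utf-16-le", "surrogatepass")


class _BitWriter:
    """MSB-first bit packer emitting fixed-width output units."""

    def __init__(self, bits_per_unit: int) -> None:
        self.bits_per_unit = bits_per_unit
        self.val = 0
        self.position = 0
        self.out: List[int] = []

    def write(self, value: int, nbits: int) -> None:
        # lz-string emits values LSB-first across nbits
        for _ in range(nbits):
            self.val = (self.val << 1) | (value & 1)
            if self.position == self.bits_per_unit - 1:
                self.position = 0
                self.out.append(self.val)
                self.val = 0
            else:
                self.position += 1
            value >>= 1

    def flush(self) -> List[int]:
        while True:
            self.val <<= 1
            if self.position == self.bits_per_unit - 1:
                self.out.append(self.val)
                return self.out
            self.position += 1


def _compress(units: List[int], bits_per_unit: int) -> List[int]:
    dictionary: dict = {}
    to_create: dict = {}
    w: tuple = ()
    enlarge_in = 2  # first dictionary entry does not count
    dict_size = 3
    num_bits = 2
    out = _BitWriter(bits_per_unit)

    def emit_w(w: tuple) -> None:
        nonlocal enlarge_in, num_bits
        if w in to_create:
            # fresh symbol: emit marker 0 (8-bit literal) or 1 (16-bit literal)
            if w[0] < 256:
                out.write(0, num_bits)
                out.write(w[0], 8)
            else:
                out.write(1, num_bits)
                out.write(w[0], 16)
            enlarge_in -= 1
            if enlarge_in == 0:
                enlarge_in = 1 << num_bits
                num_bits += 1
            del to_create[w]
        else:
            out.write(dictionary[w], num_bits)
        enlarge_in -= 1
        if enlarge_in == 0:
            enlarge_in = 1 << num_bits
            num_bits += 1

    for c in units:
        cc = (c,)
        if cc not in dictionary:
            dictionary[cc] = dict_size
            dict_size += 1
            to_create[cc] = True
        wc = w + cc
        if wc in dictionary:
            w = wc
        else:
            emit_w(w)
            dictionary[wc] = dict_size
            dict_size += 1
            w = cc

    if w:
        emit_w(w)

    out.write(2, num_bits)  # end-of-stream marker
    return out.flush()


class _BitReader:
    def __init__(self, data: List[int], reset_value: int) -> None:
        self.data = data
        self.reset_value = reset_value
        self.val = data[0] if data else 0
        self.position = reset_value
        self.index = 1

    def read(self, nbits: int) -> int:
        bits = 0
        power = 1
        for _ in range(nbits):
            resb = self.val & self.position
            self.position >>= 1
            if self.position == 0:
                self.position = self.reset_value
                self.val = self.data[self.index] if self.index < len(self.data) else 0
                self.index += 1
            if resb:
                bits |= power
            power <<= 1
        return bits


def _decompress(data: List[int], reset_value: int) -> List[int]:
    if not data:
        return []
    reader = _BitReader(data, reset_value)
    dictionary: List[tuple] = [(), (), ()]
    enlarge_in = 4
    num_bits = 3

    first = reader.read(2)
    if first == 2:
        return []
    if first == 0:
        c = (reader.read(8),)
    elif first == 1:
        c = (reader.read(16),)
    else:
        raise ValueError("corrupt lz-string stream")
    dictionary.append(c)
    w = c
    result: List[int] = list(c)

    while True:
        if reader.index > len(data):
            raise ValueError("truncated lz-string stream")
        code = reader.read(num_bits)
        if code == 0:
            dictionary.append((reader.read(8),))
            code = len(dictionary) - 1
            enlarge_in -= 1
        elif code == 1:
            dictionary.append((reader.read(16),))
            code = len(dictionary) - 1
            enlarge_in -= 1
        elif code == 2:
            return result
        if enlarge_in == 0:
            enlarge_in = 1 << num_bits
            num_bits += 1

        if code < len(dictionary):
            entry = dictionary[code]
        elif code == len(dictionary):
            entry = w + (w[0],)
        else:
            raise ValueError(f"invalid dictionary code {code}")
        result.extend(entry)
        dictionary.append(w + (entry[0],))
        enlarge_in -= 1
        w = entry
        if enlarge_in == 0:
            enlarge_in = 1 << num_bits
            num_bits += 1


def compress_utf16(text: str) -> str:
    """Compress ``text`` to a UTF-16-safe string (15 payload bits per char).

    Output characters lie in ``[32, 32800)`` — printable, below the
    surrogate range — so the result survives any UTF-16 transport and can be
    embedded (suitably escaped) in a JavaScript string literal.
    """
    codes = _compress(_to_units(text), 15)
    return "".join(chr(c + 32) for c in codes) + " "


def decompress_utf16(compressed: str) -> str:
    """Inverse of :func:`compress_utf16`."""
    if compressed == "":
        return ""
    data = [ord(ch) - 32 for ch in compressed]
    return _from_units(_decompress(data, 16384))
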