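"""Minimal uncompressed RIFF/AVI container support.

Writes and reads AVI files holding uncompressed 24-bit DIB ('RGB ') video —
the simplest container layout that standard video tools (ffmpeg, VLC,
MATLAB's VideoReader) accept. One video stream, no audio, BI_RGB frames
stored bottom-up in BGR order with 4-byte row padding, plus an idx1 index.

The frame rate is stored as the rational dwRate/dwScale with scale 1000, so
any rate with millihertz precision round-trips exactly.
"""

from __future__ import annotations

import os
import struct

import numpy as np

_SCALE = 1000  # dwScale; dwRate = fps * _SCALE


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    if len(payload) % 2:
        payload += b"\x00"
    return fourcc + struct.pack("<I", len(payload)) + payload


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def write_avi(path: str | os.PathLike, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (t, h, w) or (t, h, w, 3) uint8 at ``fps`` to AVI."""
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise ValueError("AVI writer expects uint8 frames")
    if frames.ndim == 3:
        frames = np.repeat(frames[..., np.newaxis], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must be (t, h, w) or (t, h, w, 3)")
    n, h, w, _ = frames.shape
    if n == 0:
        raise ValueError("cannot write an empty AVI")
    row_bytes = w * 3
    stride = (row_bytes + 3) & ~3
    frame_size = stride * h
    rate = round(fps * _SCALE)

    avih = struct.pack(
        "<14I",
        round(1e6 / fps),          # dwMicroSecPerFrame
        frame_size * round(fps),   # dwMaxBytesPerSec
        0,                         # dwPaddingGranularity
        0x10,                      # dwFlags: AVIF_HASINDEX
        n, 0, 1,                   # total frames, initial frames, streams
        frame_size, w, h,
        0, 0, 0, 0,                # reserved
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIII4h",
        b"vids", b"RGB ",
        0, 0, 0, 0,                # flags, priority, language, initial frames
        _SCALE, rate,
        0, n, frame_size, 0xFFFFFFFF, 0,
        0, 0, w, h,                # rcFrame
    )
    strf = struct.pack(
        "<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_size, 0, 0, 0, 0
    )
    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih)
        + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_payload = bytearray()
    index = bytearray()
    buf = np.zeros((h, stride), dtype=np.uint8)
    for fr in frames:
        # bottom-up rows, BGR channel order
        buf[:, :row_bytes] = fr[::-1, :, ::-1].reshape(h, row_bytes)
        offset = 4 + len(movi_payload)  # relative to the 'movi' fourcc
        movi_payload += _chunk(b"00db", buf.tobytes())
        index += struct.pack("<4sIII", b"00db", 0x10, offset, frame_size)
    movi = _list(b"movi", bytes(movi_payload))
    idx1 = _chunk(b"idx1", bytes(index))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    """Yield (fourcc, payload_start, payload_size) chunks, descending LISTs."""
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        payload = pos + 8
        if fourcc == b"LIST":
            yield buf[payload:payload + 4], payload + 4, size - 4
            yield from _iter_chunks(buf, payload + 4, payload + size)
        else:
            yield fourcc, payload, size
        pos = payload + size + (size % 2)


def read_avi(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read an uncompressed 24-bit AVI; returns ((t, h, w, 3) uint8, fps)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise ValueError(f"not an AVI file: {path}")

    width = height = None
    bitcount = None
    fps = None
    frame_chunks: list[tuple[int, int]] = []
    for fourcc, start, size in _iter_chunks(buf, 12, len(buf)):
        if fourcc == b"avih":
            fields = struct.unpack_from("<14I", buf, start)
            if fps is None and fields[0] > 0:
                fps = 1e6 / fields[0]
            width, height = fields[8], fields[9]
        elif fourcc == b"strh":
            fcc_type, _, _, _, _, _, scale, rate = struct.unpack_from(
                "<4s4sIHHIII", buf, start
            )[:8]
            if fcc_type == b"vids" and scale > 0:
                fps = rate / scale
        elif fourcc == b"strf":
            hdr = struct.unpack_from("<IiiHHI", buf, start)
            width, height, bitcount = hdr[1], abs(hdr[2]), hdr[4]
            compression = hdr[5]
            if compression != 0:
                raise ValueError("only uncompressed (BI_RGB) AVI is supported")
        elif fourcc in (b"00db", b"00dc") and size > 0:
            frame_chunks.append((start, size))

    if width is None or height is None or fps is None:
        raise ValueError(f"malformed AVI headers in {path}")
    if bitcount not in (24,):
        raise ValueError(f"unsupported AVI bit depth: {bitcount}")
    if not frame_chunks:
        raise ValueError(f"zero frames in {path}")

    stride = (width * 3 + 3) & ~3
    frames = np.empty((len(frame_chunks), height, width, 3), dtype=np.uint8)
    for i, (start, size) in enumerate(frame_chunks):
        if size < stride * height:
            raise ValueError(f"truncated frame {i} in {path}")
        raw = np.frombuffer(buf, dtype=np.uint8, count=stride * height, offset=start)
        rows = raw.reshape(height, stride)[:, : width * 3]
        frames[i] = rows.reshape(height, width, 3)[::-1, :, ::-1]
    return frames, float(fps)
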