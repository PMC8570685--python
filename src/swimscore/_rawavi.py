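"""Minimal uncompressed AVI (RIFF) container support.

Writes 8-bit grayscale video as uncompressed DIB frames with a gray
palette, and reads back 8-bit palettized or 24-bit BGR uncompressed AVI.
Only the 'DIB '/raw (biCompression == 0) codec is handled; anything else
must go through an external decoding backend.

The writer streams frames to disk and patches the RIFF sizes on close, so
long recordings never have to fit in memory.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RawAviWriter", "RawAviReader", "is_raw_avi", "UnsupportedAviError"]

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


class UnsupportedAviError(ValueError):
    """The file is an AVI but uses a codec or layout we cannot decode."""


def _pad4(n: int) -> int:
    return (n + 3) & ~3


class RawAviWriter:
    """Stream 8-bit grayscale frames into an uncompressed AVI file."""

    def __init__(self, path: str | Path, width: int, height: int, fps: float):
        if width <= 0 or height <= 0:
            raise ValueError("frame dimensions must be positive")
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.path = Path(path)
        self.width = int(width)
        self.height = int(height)
        self.fps = float(fps)
        self._stride = _pad4(self.width)  # bytes per row, 8-bit
        self._n_frames = 0
        self._index: list[tuple[int, int]] = []  # (offset in movi, size)
        self._fh = open(self.path, "wb")
        self._write_header_placeholder()

    # -- header layout -------------------------------------------------
    def _write_header_placeholder(self) -> None:
        fh = self._fh
        fh.write(b"RIFF")
        self._riff_size_pos = fh.tell()
        fh.write(struct.pack("<I", 0))
        fh.write(b"AVI ")

        # LIST hdrl
        hdrl_payload = self._build_hdrl(n_frames=0)
        fh.write(b"LIST")
        fh.write(struct.pack("<I", 4 + len(hdrl_payload)))
        self._hdrl_pos = fh.tell()
        fh.write(b"hdrl")
        fh.write(hdrl_payload)

        # LIST movi
        fh.write(b"LIST")
        self._movi_size_pos = fh.tell()
        fh.write(struct.pack("<I", 0))
        self._movi_start = fh.tell()
        fh.write(b"movi")

    def _build_hdrl(self, n_frames: int) -> bytes:
        usec_per_frame = int(round(1_000_000 / self.fps))
        rate = int(round(self.fps * 1000))
        scale = 1000
        frame_bytes = self._stride * self.height

        avih = struct.pack(
            "<14I",
            usec_per_frame,
            frame_bytes * max(1, int(round(self.fps))),
            0,
            _AVIF_HASINDEX,
            n_frames,
            0,
            1,  # one stream
            frame_bytes,
            self.width,
            self.height,
            0, 0, 0, 0,
        )
        strh = (
            b"vids"
            + b"DIB "
            + struct.pack(
                "<10I4h",
                0, 0, 0,  # flags, priority+language, initial frames
                scale,
                rate,
                0,
                n_frames,
                frame_bytes,
                0xFFFFFFFF,  # quality: default
                0,
                0, 0, self.width, self.height,
            )
        )
        # BITMAPINFOHEADER + 256-entry gray palette (BGR0 quads)
        strf = struct.pack(
            "<IiiHHIIiiII",
            40,
            self.width,
            self.height,
            1,
            8,
            0,  # BI_RGB, uncompressed
            frame_bytes,
            0, 0,
            256,
            0,
        ) + b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))

        strl = (
            b"strl"
            + b"strh" + struct.pack("<I", len(strh)) + strh
            + b"strf" + struct.pack("<I", len(strf)) + strf
        )
        return (
            b"avih" + struct.pack("<I", len(avih)) + avih
            + b"LIST" + struct.pack("<I", len(strl)) + strl
        )

    # -- frames --------------------------------------------------------
    def append(self, frame: np.ndarray) -> None:
        """Append one (height, width) uint8 frame."""
        arr = np.asarray(frame)
        if arr.shape != (self.height, self.width):
            raise ValueError(
                f"frame shape {arr.shape} does not match ({self.height}, {self.width})"
            )
        if arr.dtype != np.uint8:
            raise ValueError("frames must be uint8")
        # DIB rows are stored bottom-up, padded to 4-byte boundaries
        padded = np.zeros((self.height, self._stride), dtype=np.uint8)
        padded[:, : self.width] = arr[::-1]
        data = padded.tobytes()
        offset = self._fh.tell() - self._movi_start
        self._fh.write(b"00db")
        self._fh.write(struct.pack("<I", len(data)))
        self._fh.write(data)
        if len(data) % 2:
            self._fh.write(b"\x00")
        self._index.append((offset, len(data)))
        self._n_frames += 1

    def close(self) -> None:
        if self._fh.closed:
            return
        fh = self._fh
        movi_end = fh.tell()
        # idx1 for players that want an index
        fh.write(b"idx1")
        fh.write(struct.pack("<I", 16 * len(self._index)))
        for offset, size in self._index:
            fh.write(b"00db")
            fh.write(struct.pack("<III", _AVIIF_KEYFRAME, offset, size))
        riff_end = fh.tell()

        fh.seek(self._movi_size_pos)
        fh.write(struct.pack("<I", movi_end - self._movi_start))
        fh.seek(self._riff_size_pos)
        fh.write(struct.pack("<I", riff_end - self._riff_size_pos - 4))
        # rewrite hdrl with the real frame count
        fh.seek(self._hdrl_pos + 4)
        fh.write(self._build_hdrl(self._n_frames))
        fh.close()

    def __enter__(self) -> "RawAviWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


@dataclass
class _StreamFormat:
    width: int
    height: int
    bit_count: int
    palette: np.ndarray | None  # (256, 3) RGB or None


def is_raw_avi(path: str | Path) -> bool:
    """True when the file starts with a RIFF/AVI signature."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
    except OSError:
        return False
    return len(head) == 12 and head[:4] == b"RIFF" and head[8:12] == b"AVI "


class RawAviReader:
    """Decode an uncompressed AVI written by :class:`RawAviWriter` (or any
    uncompressed 8-bit palettized / 24-bit BGR AVI)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = open(self.path, "rb")
        self.fps: float = 0.0
        self._fmt: _StreamFormat | None = None
        self._frames: list[tuple[int, int]] = []  # (abs offset of data, size)
        self._parse()
        if self._fmt is None:
            raise UnsupportedAviError(f"{self.path}: no decodable video stream found")
        if not self._frames:
            raise UnsupportedAviError(f"{self.path}: AVI contains no frames")

    @property
    def width(self) -> int:
        return self._fmt.width

    @property
    def height(self) -> int:
        return self._fmt.height

    @property
    def n_frames(self) -> int:
        return len(self._frames)

    # -- parsing -------------------------------------------------------
    def _parse(self) -> None:
        fh = self._fh
        head = fh.read(12)
        if len(head) < 12 or head[:4] != b"RIFF" or head[8:12] != b"AVI ":
            raise UnsupportedAviError(f"{self.path}: not an AVI file")
        riff_size = struct.unpack("<I", head[4:8])[0]
        self._walk(12, 8 + riff_size)

    def _walk(self, pos: int, end: int) -> None:
        fh = self._fh
        while pos + 8 <= end:
            fh.seek(pos)
            hdr = fh.read(8)
            if len(hdr) < 8:
                break
            fourcc = hdr[:4]
            size = struct.unpack("<I", hdr[4:8])[0]
            if fourcc == b"LIST":
                list_type = fh.read(4)
                if list_type in (b"hdrl", b"strl", b"movi", b"rec "):
                    self._walk(pos + 12, pos + 8 + size)
            elif fourcc == b"strh":
                self._read_strh(fh.read(size))
            elif fourcc == b"strf":
                self._read_strf(fh.read(size))
            elif fourcc[2:4] in (b"db", b"dc") and size > 0:
                self._frames.append((pos + 8, size))
            pos += 8 + size + (size & 1)  # chunks are word-aligned

    def _read_strh(self, data: bytes) -> None:
        if data[:4] != b"vids":
            return
        handler = data[4:8]
        if handler not in (b"DIB ", b"\x00\x00\x00\x00", b"RGB ", b"raw "):
            raise UnsupportedAviError(
                f"{self.path}: compressed AVI codec {handler!r} is not supported"
            )
        scale, rate = struct.unpack("<II", data[20:28])
        if scale > 0 and rate > 0:
            self.fps = rate / scale

    def _read_strf(self, data: bytes) -> None:
        if self._fmt is not None or len(data) < 40:
            return
        (_, width, height, _, bit_count, compression) = struct.unpack(
            "<IiiHHI", data[:20]
        )
        if compression != 0:
            raise UnsupportedAviError(
                f"{self.path}: compressed pixel format {compression:#x} not supported"
            )
        if bit_count not in (8, 24):
            raise UnsupportedAviError(
                f"{self.path}: {bit_count}-bit frames not supported (8 or 24 only)"
            )
        palette = None
        if bit_count == 8:
            quads = np.frombuffer(data[40 : 40 + 4 * 256], dtype=np.uint8)
            if quads.size < 4 * 256:
                # gray identity palette assumed when none is stored
                palette = np.repeat(np.arange(256, dtype=np.uint8)[:, None], 3, axis=1)
            else:
                bgr = quads.reshape(-1, 4)[:, :3]
                palette = bgr[:, ::-1].copy()  # -> RGB
        self._fmt = _StreamFormat(width, abs(height), bit_count, palette)

    # -- decoding ------------------------------------------------------
    def read_frame(self, index: int) -> np.ndarray:
        """Return frame `index` as (H, W) uint8 gray or (H, W, 3) uint8 RGB."""
        offset, size = self._frames[index]
        self._fh.seek(offset)
        raw = self._fh.read(size)
        fmt = self._fmt
        bytespp = fmt.bit_count // 8
        stride = _pad4(fmt.width * bytespp)
        rows = np.frombuffer(raw[: stride * fmt.height], dtype=np.uint8)
        rows = rows.reshape(fmt.height, stride)[::-1]  # bottom-up -> top-down
        if fmt.bit_count == 8:
            idx = rows[:, : fmt.width]
            pal = fmt.palette
            if np.array_equal(pal[:, 0], pal[:, 1]) and np.array_equal(
                pal[:, 1], pal[:, 2]
            ):
                return pal[idx, 0]
            return pal[idx]
        bgr = rows[:, : fmt.width * 3].reshape(fmt.height, fmt.width, 3)
        return bgr[:, :, ::-1].copy()

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.read_frame(i)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "RawAviReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
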