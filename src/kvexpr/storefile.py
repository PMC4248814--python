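"""Immutable sorted file of key-value cells for one column family.

A StoreFile is the on-disk unit of the engine: a strictly key-sorted run of
(key, value) cells belonging to exactly one Family, carrying its own start
and end keys (for whole-file range pruning) and a block index (for sub-file
seeks).  Files are written once and never modified.

Binary layout (little-endian, fixed-width integers)::

    header   magic "KVSF" | u16 version (=1)
    blocks   concatenated cells, grouped into blocks of <= block_bytes
             payload; each cell is u32 key_len | key | u32 value_len | value
    trailer  u8 family | u64 cell_count
             u32 start_key_len | start_key | u32 end_key_len | end_key
             u32 n_blocks, then per block:
                 u32 first_key_len | first_key | u64 offset | u32 n_cells
             u32 CRC32 of the block section
    footer   u64 trailer_offset | magic "KVSF"

Values are stored as UTF-8 decimal literals, not binary floats, so the
printed precision of the source data survives storage byte-exactly (e.g.
"6.16791991" is returned exactly as loaded); numeric conversion happens at
the query boundary.
"""

from __future__ import annotations

import math
import os
import struct
import zlib
from bisect import bisect_right
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .keycodec import Family

__all__ = [
    "EncodedCell",
    "StoreFileMeta",
    "StoreConfig",
    "BlockCache",
    "CacheStats",
    "StoreFileError",
    "CorruptStoreFileError",
    "write_storefile",
    "open_storefile",
    "StoreFile",
    "file_may_contain",
    "read_range",
    "dump",
]

_MAGIC = b"KVSF"
_VERSION = 1
_FAMILY_CODES = {Family.RAW: 0, Family.LOG: 1, Family.ZSCORE: 2}
_FAMILY_FROM_CODE = {v: k for k, v in _FAMILY_CODES.items()}


class StoreFileError(ValueError):
    """Invalid input to the writer (unsorted, duplicate, or empty cells)."""


class CorruptStoreFileError(IOError):
    """File fails checksum, magic, version or structural validation."""


@dataclass(frozen=True)
class EncodedCell:
    """One stored cell: encoded key plus the value's decimal literal bytes."""

    key: bytes
    value: bytes

    def __post_init__(self) -> None:
        if not self.key:
            raise StoreFileError("cell key must be non-empty")
        try:
            v = float(self.value.decode("ascii"))
        except (UnicodeDecodeError, ValueError) as exc:
            raise StoreFileError(f"value {self.value!r} is not a decimal literal") from exc
        if not math.isfinite(v):
            raise StoreFileError(f"value {self.value!r} is not finite")


@dataclass(frozen=True)
class BlockIndexEntry:
    first_key: bytes
    offset: int
    n_cells: int


@dataclass(frozen=True)
class StoreFileMeta:
    family: Family
    start_key: bytes
    end_key: bytes
    cell_count: int
    block_index: tuple[BlockIndexEntry, ...]
    checksum: int


@dataclass(frozen=True)
class StoreConfig:
    """Physical-layout knobs.

    max_storefile_bytes caps one file's block payload (default 128 MB, the
    production file size); block_bytes is the unit of disk I/O and caching;
    cache_capacity_blocks bounds the LRU block cache.  Tests shrink
    max_storefile_bytes to force multi-file stores at desk scale.
    """

    max_storefile_bytes: int = 128 * 1024 * 1024
    block_bytes: int = 64 * 1024
    cache_capacity_blocks: int = 256

    def __post_init__(self) -> None:
        if min(self.max_storefile_bytes, self.block_bytes,
               self.cache_capacity_blocks) <= 0:
            raise StoreFileError("all StoreConfig sizes must be positive")
        if self.block_bytes > self.max_storefile_bytes:
            raise StoreFileError("block_bytes must be <= max_storefile_bytes")


@dataclass
class CacheStats:
    """Monotone counters of block-cache behaviour."""

    hits: int = 0
    misses: int = 0
    physical_block_reads: int = 0

    def snapshot(self) -> "CacheStats":
        return CacheStats(self.hits, self.misses, self.physical_block_reads)


class BlockCache:
    """LRU cache of decoded blocks, keyed by (file path, block ordinal).

    A lookup miss triggers exactly one physical block read.  ``reset``
    empties the cache (cold-cache mode, mirroring a benchmark protocol of
    clearing all caches between runs) without zeroing the counters;
    ``reset_stats`` zeroes the counters.
    """

    def __init__(self, capacity_blocks: int = 256) -> None:
        if capacity_blocks <= 0:
            raise StoreFileError("cache capacity must be positive")
        self.capacity = capacity_blocks
        self._blocks: OrderedDict[tuple[str, int], list[EncodedCell]] = OrderedDict()
        self.stats = CacheStats()

    def get_block(self, handle: "StoreFile", block_id: int) -> list[EncodedCell]:
        key = (handle.path, block_id)
        cached = self._blocks.get(key)
        if cached is not None:
            self._blocks.move_to_end(key)
            self.stats.hits += 1
            return cached
        self.stats.misses += 1
        self.stats.physical_block_reads += 1
        cells = handle._read_block_from_disk(block_id)
        self._blocks[key] = cells
        if len(self._blocks) > self.capacity:
            self._blocks.popitem(last=False)
        return cells

    def reset(self) -> None:
        self._blocks.clear()

    def reset_stats(self) -> None:
        self.stats = CacheStats()


def _put_bytes(parts: list[bytes], b: bytes) -> None:
    parts.append(struct.pack("<I", len(b)))
    parts.append(b)


class _Reader:
    def __init__(self, buf: bytes) -> None:
        self.buf = buf
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise CorruptStoreFileError("truncated file")
        out = self.buf[self.pos:self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.take(1)[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]

    def u64(self) -> int:
        return struct.unpack("<Q", self.take(8))[0]

    def lbytes(self) -> bytes:
        return self.take(self.u32())


def write_storefile(
    cells: Sequence[EncodedCell],
    family: Family,
    path: str | os.PathLike,
    cfg: StoreConfig = StoreConfig(),
) -> StoreFileMeta:
    """Write a strictly sorted cell run to ``path``; return its metadata.

    Cells are grouped into blocks whose payload does not exceed
    ``cfg.block_bytes`` (a single oversized cell still gets its own block).
    Raises on empty input, unsorted input, or duplicate keys.
    """
    if not cells:
        raise StoreFileError("refusing to write an empty StoreFile")
    for prev, cur in zip(cells, cells[1:]):
        if cur.key == prev.key:
            raise StoreFileError(f"duplicate key {prev.key!r}")
        if cur.key < prev.key:
            raise StoreFileError("cells are not sorted by key")

    blocks: list[list[EncodedCell]] = []
    current: list[EncodedCell] = []
    current_bytes = 0
    for cell in cells:
        cell_bytes = 8 + len(cell.key) + len(cell.value)
        if current and current_bytes + cell_bytes > cfg.block_bytes:
            blocks.append(current)
            current, current_bytes = [], 0
        current.append(cell)
        current_bytes += cell_bytes
    blocks.append(current)

    block_section: list[bytes] = []
    index: list[BlockIndexEntry] = []
    offset = 0
    for block in blocks:
        parts: list[bytes] = []
        for cell in block:
            _put_bytes(parts, cell.key)
            _put_bytes(parts, cell.value)
        payload = b"".join(parts)
        index.append(BlockIndexEntry(block[0].key, offset, len(block)))
        block_section.append(payload)
        offset += len(payload)
    body = b"".join(block_section)
    checksum = zlib.crc32(body)

    trailer: list[bytes] = [struct.pack("<B", _FAMILY_CODES[family]),
                            struct.pack("<Q", len(cells))]
    _put_bytes(trailer, cells[0].key)
    _put_bytes(trailer, cells[-1].key)
    trailer.append(struct.pack("<I", len(index)))
    for entry in index:
        _put_bytes(trailer, entry.first_key)
        trailer.append(struct.pack("<QI", entry.offset, entry.n_cells))
    trailer.append(struct.pack("<I", checksum))

    header = _MAGIC + struct.pack("<H", _VERSION)
    trailer_offset = len(header) + len(body)
    footer = struct.pack("<Q", trailer_offset) + _MAGIC

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)
        fh.write(b"".join(trailer))
        fh.write(footer)

    return StoreFileMeta(
        family=family,
        start_key=cells[0].key,
        end_key=cells[-1].key,
        cell_count=len(cells),
        block_index=tuple(index),
        checksum=checksum,
    )


class StoreFile:
    """Open handle on one StoreFile; block reads go through a BlockCache."""

    def __init__(self, path: str, meta: StoreFileMeta, body_offset: int,
                 body_length: int) -> None:
        self.path = path
        self.meta = meta
        self._body_offset = body_offset
        self._body_length = body_length
        self._closed = False

    def close(self) -> None:
        self._closed = True

    @property
    def closed(self) -> bool:
        return self._closed

    def _read_block_from_disk(self, block_id: int) -> list[EncodedCell]:
        index = self.meta.block_index
        start = index[block_id].offset
        end = (index[block_id + 1].offset
               if block_id + 1 < len(index) else self._body_length)
        with open(self.path, "rb") as fh:
            fh.seek(self._body_offset + start)
            payload = fh.read(end - start)
        rd = _Reader(payload)
        cells = []
        for _ in range(index[block_id].n_cells):
            key = rd.lbytes()
            value = rd.lbytes()
            cells.append(EncodedCell(key, value))
        return cells


def open_storefile(path: str | os.PathLike) -> StoreFile:
    """Open and validate a StoreFile; verifies magic, version and CRC32."""
    path = os.fspath(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 6 + 12 or raw[:4] != _MAGIC or raw[-4:] != _MAGIC:
        raise CorruptStoreFileError("bad magic or truncated file")
    version = struct.unpack("<H", raw[4:6])[0]
    if version != _VERSION:
        raise CorruptStoreFileError(f"unknown format version {version}")
    trailer_offset = struct.unpack("<Q", raw[-12:-4])[0]
    if not 6 <= trailer_offset <= len(raw) - 12:
        raise CorruptStoreFileError("trailer offset out of bounds")
    body = raw[6:trailer_offset]

    rd = _Reader(raw[trailer_offset:len(raw) - 12])
    family_code = rd.u8()
    if family_code not in _FAMILY_FROM_CODE:
        raise CorruptStoreFileError(f"unknown family code {family_code}")
    cell_count = rd.u64()
    start_key = rd.lbytes()
    end_key = rd.lbytes()
    n_blocks = rd.u32()
    index = []
    prev_offset = -1
    for _ in range(n_blocks):
        first_key = rd.lbytes()
        off, n_cells = struct.unpack("<QI", rd.take(12))
        if off <= prev_offset:
            raise CorruptStoreFileError("block index offsets not increasing")
        prev_offset = off
        index.append(BlockIndexEntry(first_key, off, n_cells))
    checksum = rd.u32()
    if zlib.crc32(body) != checksum:
        raise CorruptStoreFileError("checksum mismatch: file is corrupt")
    if start_key > end_key or not index:
        raise CorruptStoreFileError("inconsistent trailer")

    meta = StoreFileMeta(
        family=_FAMILY_FROM_CODE[family_code],
        start_key=start_key,
        end_key=end_key,
        cell_count=cell_count,
        block_index=tuple(index),
        checksum=checksum,
    )
    return StoreFile(path, meta, body_offset=6, body_length=len(body))


def file_may_contain(meta: StoreFileMeta, lo: bytes, hi: bytes) -> bool:
    """True iff the closed query range [lo, hi] intersects [start, end].

    This is the whole-file pruning test: comparing a row-key range against a
    file's start and end keys.  It may report true for a file that holds no
    matching cell (keys between start and end are sparse) but never false
    when a matching cell exists.
    """
    if lo > hi:
        raise StoreFileError("range lower bound exceeds upper bound")
    return lo <= meta.end_key and hi >= meta.start_key


def read_range(
    handle: StoreFile,
    lo: bytes,
    hi: bytes,
    cache: BlockCache,
    *,
    hi_exclusive: bool = False,
) -> Iterator[EncodedCell]:
    """Yield cells with lo <= key <= hi (or < hi when hi_exclusive) in order.

    Binary-searches the block index for the last block whose first key is
    <= lo, then walks forward block by block; every block access goes
    through the cache, so a warm repeat of the same range performs zero
    physical reads.
    """
    if handle.closed:
        raise StoreFileError("handle is closed")
    if lo > hi:
        raise StoreFileError("range lower bound exceeds upper bound")
    index = handle.meta.block_index
    first_keys = [e.first_key for e in index]
    start_block = max(bisect_right(first_keys, lo) - 1, 0)
    for block_id in range(start_block, len(index)):
        first = first_keys[block_id]
        if (first > hi) or (hi_exclusive and first >= hi):
            return
        for cell in cache.get_block(handle, block_id):
            if cell.key < lo:
                continue
            if cell.key > hi or (hi_exclusive and cell.key >= hi):
                return
            yield cell


def dump(handle: StoreFile, cache: BlockCache | None = None) -> Iterator[str]:
    """Debug routine: emit every cell as a ``key-hex<TAB>value`` TSV line."""
    cache = cache or BlockCache()
    for cell in read_range(handle, handle.meta.start_key, handle.meta.end_key, cache):
        yield f"{cell.key.hex()}\t{cell.value.decode('ascii')}"
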