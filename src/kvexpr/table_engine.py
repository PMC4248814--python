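"""The table abstraction over StoreFiles: write path, read path, caching.

An :class:`ExpressionTable` keeps one in-memory sorted write buffer
(memstore) per Family.  ``put`` fans one expression record out into three
cells, one per Family; ``flush`` writes a Family's memstore as one or more
immutable StoreFiles under ``root/<FAMILY>/``.  Reads (``get`` for one row,
``scan`` for a patient range) merge the memstore with every StoreFile whose
[start, end] key interval may contain the requested range, going through a
shared LRU block cache.

Physical separation by Family is the point of the design: a query for LOG
values never opens a RAW or ZSCORE file, so the blocks pulled into the
cache are all useful to the query, and patients adjacent in row-key order
share blocks — reading one warms the cache for its neighbours.

Single-writer, single-version semantics: the last write for a (row, family,
qualifier) key wins, and memstore content shadows flushed files.
"""

from __future__ import annotations

import heapq
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .keycodec import (
    CodecConfig,
    Family,
    Qualifier,
    RowKey,
    decode_cell_key,
    encode_cell_key,
    row_prefix_range,
    span_range,
)
from .storefile import (
    BlockCache,
    CacheStats,
    EncodedCell,
    StoreConfig,
    StoreFile,
    StoreFileMeta,
    open_storefile,
    read_range,
    write_storefile,
)

__all__ = ["ExpressionRecord", "Cell", "ExpressionTable", "RecordError"]


class RecordError(ValueError):
    """An expression record violates its invariants."""


def _literal(value: float | int | str, name: str) -> str:
    """Normalise a measurement to its decimal literal string.

    Literals given as strings are preserved byte-exactly (the store's
    contract); numbers are rendered with ``repr``, which round-trips.
    """
    text = value if isinstance(value, str) else repr(float(value))
    try:
        parsed = float(text)
    except ValueError as exc:
        raise RecordError(f"{name}={text!r} is not a decimal literal") from exc
    if not math.isfinite(parsed):
        raise RecordError(f"{name}={text!r} is not finite")
    return text


@dataclass(frozen=True)
class ExpressionRecord:
    """One source row: annotations plus the RAW/LOG/ZSCORE value triple.

    The three measurements are held as decimal literal strings so that the
    exact printed precision of the input survives storage and retrieval;
    ``raw_value``/``log_value``/``zscore_value`` give floats.
    """

    gene_symbol: str
    probeset_id: str
    patient_id: int
    trial_name: str
    raw: str
    log: str
    zscore: str

    def __init__(self, gene_symbol: str, probeset_id: str, patient_id: int,
                 trial_name: str, raw: float | str, log: float | str,
                 zscore: float | str) -> None:
        object.__setattr__(self, "gene_symbol", gene_symbol)
        object.__setattr__(self, "probeset_id", probeset_id)
        object.__setattr__(self, "patient_id", int(patient_id))
        object.__setattr__(self, "trial_name", trial_name)
        object.__setattr__(self, "raw", _literal(raw, "raw"))
        object.__setattr__(self, "log", _literal(log, "log"))
        object.__setattr__(self, "zscore", _literal(zscore, "zscore"))
        if not all((gene_symbol, probeset_id, trial_name)):
            raise RecordError("gene_symbol, probeset_id and trial_name are required")
        if float(self.raw) <= 0:
            raise RecordError(f"raw intensity must be positive, got {self.raw}")

    @property
    def raw_value(self) -> float:
        return float(self.raw)

    @property
    def log_value(self) -> float:
        return float(self.log)

    @property
    def zscore_value(self) -> float:
        return float(self.zscore)

    def value_for(self, family: Family) -> str:
        return {Family.RAW: self.raw, Family.LOG: self.log,
                Family.ZSCORE: self.zscore}[family]


@dataclass(frozen=True)
class Cell:
    """A located value: (row, family, qualifier) -> decimal literal."""

    row: RowKey
    family: Family
    qualifier: Qualifier
    value: str

    @property
    def numeric(self) -> float:
        return float(self.value)


class ExpressionTable:
    """Embedded column-family store for expression records.

    Parameters
    ----------
    root : directory holding one subdirectory per Family, each with numbered
        StoreFiles plus a ``MANIFEST.tsv`` (filename, cell count, checksum,
        start/end key hex per line).  An existing store directory is
        reattached.
    store_cfg, codec_cfg : physical layout and key-encoding parameters.
    """

    MANIFEST = "MANIFEST.tsv"

    def __init__(self, root: str | os.PathLike,
                 store_cfg: StoreConfig = StoreConfig(),
                 codec_cfg: CodecConfig = CodecConfig()) -> None:
        self.root = Path(root)
        self.store_cfg = store_cfg
        self.codec_cfg = codec_cfg
        self._memstore: dict[Family, dict[bytes, bytes]] = {f: {} for f in Family}
        self._memstore_bytes: dict[Family, int] = {f: 0 for f in Family}
        self._files: dict[Family, list[StoreFile]] = {f: [] for f in Family}
        self._cache = BlockCache(store_cfg.cache_capacity_blocks)
        # io_log records (family, path) per StoreFile consulted by a read;
        # used to assert family isolation.
        self.io_log: list[tuple[Family, str]] = []
        self._reattach()

    # ------------------------------------------------------------- write path

    def put(self, record: ExpressionRecord) -> list[Cell]:
        """Buffer one record as three cells, one per Family (last write wins).

        When a Family's buffered payload reaches max_storefile_bytes the
        Family is flushed automatically.
        """
        row = RowKey(record.trial_name, record.patient_id)
        qual = Qualifier(record.gene_symbol, record.probeset_id)
        key = encode_cell_key(row, qual, self.codec_cfg)
        cells = []
        for family in Family:
            value = record.value_for(family).encode("ascii")
            store = self._memstore[family]
            if key in store:
                self._memstore_bytes[family] -= len(store[key])
            else:
                self._memstore_bytes[family] += 8 + len(key)
            store[key] = value
            self._memstore_bytes[family] += len(value)
            cells.append(Cell(row, family, qual, value.decode("ascii")))
            if self._memstore_bytes[family] >= self.store_cfg.max_storefile_bytes:
                self.flush(family)
        return cells

    def flush(self, family: Family) -> list[StoreFileMeta]:
        """Write the Family's memstore to StoreFiles and empty it.

        Cells are sorted by encoded key; the run is split into multiple
        files only when its payload exceeds max_storefile_bytes.  Flushing
        an empty memstore is a no-op returning [].
        """
        store = self._memstore[family]
        if not store:
            return []
        cells = [EncodedCell(k, v) for k, v in sorted(store.items())]
        chunks: list[list[EncodedCell]] = []
        current: list[EncodedCell] = []
        size = 0
        for cell in cells:
            nbytes = 8 + len(cell.key) + len(cell.value)
            if current and size + nbytes > self.store_cfg.max_storefile_bytes:
                chunks.append(current)
                current, size = [], 0
            current.append(cell)
            size += nbytes
        chunks.append(current)

        fam_dir = self.root / family.value
        fam_dir.mkdir(parents=True, exist_ok=True)
        metas = []
        for chunk in chunks:
            seq = len(self._files[family]) + 1
            path = fam_dir / f"{seq:06d}.sf"
            meta = write_storefile(chunk, family, path, self.store_cfg)
            self._files[family].append(open_storefile(path))
            self._append_manifest(fam_dir, path.name, meta)
            metas.append(meta)
        store.clear()
        self._memstore_bytes[family] = 0
        return metas

    def _append_manifest(self, fam_dir: Path, name: str, meta: StoreFileMeta) -> None:
        line = "\t".join([name, str(meta.cell_count), str(meta.checksum),
                          meta.start_key.hex(), meta.end_key.hex()])
        with open(fam_dir / self.MANIFEST, "a", encoding="ascii") as fh:
            fh.write(line + "\n")

    def _reattach(self) -> None:
        for family in Family:
            manifest = self.root / family.value / self.MANIFEST
            if not manifest.exists():
                continue
            for line in manifest.read_text(encoding="ascii").splitlines():
                name = line.split("\t", 1)[0]
                self._files[family].append(
                    open_storefile(self.root / family.value / name))

    def flush_all(self) -> dict[Family, list[StoreFileMeta]]:
        return {family: self.flush(family) for family in Family}

    # -------------------------------------------------------------- read path

    def _merged_cells(self, family: Family, lo: bytes,
                      hi: bytes) -> Iterator[EncodedCell]:
        """Merge memstore and overlapping files over half-open [lo, hi).

        Sources are merged by (key, priority); priority 0 is the memstore,
        then files newest-first, so on key collision the freshest write is
        emitted and stale versions are skipped.
        """
        sources = []
        mem = self._memstore[family]
        if mem:
            mem_keys = sorted(k for k in mem if lo <= k < hi)
            sources.append(((k, 0, mem[k]) for k in mem_keys))
        def _file_source(handle: StoreFile, age: int):
            for cell in read_range(handle, lo, hi, self._cache,
                                   hi_exclusive=True):
                yield cell.key, age, cell.value

        for age, handle in enumerate(reversed(self._files[family]), start=1):
            if handle.meta.end_key < lo or handle.meta.start_key >= hi:
                continue
            self.io_log.append((family, handle.path))
            sources.append(_file_source(handle, age))
        last_key = None
        for key, _prio, value in heapq.merge(*sources):
            if key == last_key:
                continue
            last_key = key
            yield EncodedCell(key, value)

    def _decode(self, cell: EncodedCell, family: Family) -> Cell:
        row, qual = decode_cell_key(cell.key, self.codec_cfg)
        return Cell(row, family, qual, cell.value.decode("ascii"))

    def get(self, trial: str, patient_id: int, family: Family,
            qualifier: Qualifier | None = None) -> list[Cell]:
        """All cells of one row in one Family, or the single qualified cell.

        Only StoreFiles whose [start, end] interval can contain the row's
        key prefix are consulted; an absent patient yields an empty list.
        """
        row = RowKey(trial, patient_id)
        if qualifier is not None:
            key = encode_cell_key(row, qualifier, self.codec_cfg)
            lo, hi = key, key + b"\x00"
        else:
            lo, hi = row_prefix_range(row, self.codec_cfg)
        return [self._decode(c, family) for c in self._merged_cells(family, lo, hi)]

    def scan(self, trial: str, patient_lo: int, patient_hi: int,
             family: Family) -> Iterator[Cell]:
        """Sequential retrieval of every cell with patient id in
        [patient_lo, patient_hi] (both inclusive), in global key order,
        including rows of unrequested patients that happen to lie between.
        """
        lo, hi = span_range(trial, patient_lo, patient_hi, self.codec_cfg)
        for cell in self._merged_cells(family, lo, hi):
            yield self._decode(cell, family)

    # ------------------------------------------------------------ cache admin

    def cache_stats(self) -> CacheStats:
        return self._cache.stats.snapshot()

    def reset_cache(self) -> None:
        """Empty the block cache: the next reads are cold, as after a full
        shutdown.  Counters are preserved (they are monotone)."""
        self._cache.reset()

    def reset_cache_stats(self) -> None:
        self._cache.reset_stats()

    def storefiles(self, family: Family) -> list[StoreFile]:
        return list(self._files[family])
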