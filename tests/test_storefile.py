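"""StoreFile format round trips, pruning, block index, and cache behaviour."""

import random

import pytest

from kvexpr.keycodec import Family, Qualifier, RowKey, encode_cell_key
from kvexpr.storefile import (
    BlockCache,
    CorruptStoreFileError,
    EncodedCell,
    StoreConfig,
    StoreFileError,
    dump,
    file_may_contain,
    open_storefile,
    read_range,
    write_storefile,
)
from conftest import TABLE3_ROWS


def _table3_log_cells():
    """The LOG-family cells of the worked example, in on-disk key order."""
    cells = []
    for gene, probeset, pid, trial, _raw, log, _z in TABLE3_ROWS:
        key = encode_cell_key(RowKey(trial, pid), Qualifier(gene, probeset))
        cells.append(EncodedCell(key, log.encode()))
    return sorted(cells, key=lambda c: c.key)


def _random_cells(n, seed, value_bytes=10):
    rng = random.Random(seed)
    keys = set()
    while len(keys) < n:
        keys.add(encode_cell_key(
            RowKey("MULTMYEL", rng.randrange(10**6)),
            Qualifier("".join(rng.choices("ABCDEFGH", k=4)),
                      f"{rng.randrange(10**6)}_at")))
    return [EncodedCell(k, f"{rng.uniform(0, 16):.{value_bytes - 2}f}".encode())
            for k in sorted(keys)]


class TestWriteOpen:
    def test_worked_example_meta(self, tmp_path):
        cells = _table3_log_cells()
        meta = write_storefile(cells, Family.LOG, tmp_path / "log.sf")
        assert meta.cell_count == 3
        assert meta.start_key == encode_cell_key(
            RowKey("MULTMYEL", 79622), Qualifier("EI24", "216396_s_at"))
        assert meta.end_key == encode_cell_key(
            RowKey("MULTMYEL", 79737), Qualifier("GRID1", "1555267_at"))
        reopened = open_storefile(tmp_path / "log.sf")
        assert reopened.meta == meta

    def test_singleton_start_equals_end(self, tmp_path):
        cell = _table3_log_cells()[0]
        meta = write_storefile([cell], Family.LOG, tmp_path / "one.sf")
        assert meta.start_key == meta.end_key == cell.key

    def test_round_trip_10k_cells_small_blocks(self, tmp_path):
        cells = _random_cells(10_000, seed=3)
        cfg = StoreConfig(block_bytes=4 * 1024)
        write_storefile(cells, Family.RAW, tmp_path / "big.sf", cfg)
        handle = open_storefile(tmp_path / "big.sf")
        assert len(handle.meta.block_index) > 1
        got = list(read_range(handle, handle.meta.start_key,
                              handle.meta.end_key, BlockCache(1024)))
        assert got == cells  # keys and decimal literals byte-exact

    def test_writer_reader_meta_equality_many_files(self, tmp_path):
        for i in range(100):
            cells = _random_cells(random.Random(i).randint(1, 40), seed=1000 + i)
            meta = write_storefile(cells, Family.ZSCORE, tmp_path / f"{i}.sf")
            assert open_storefile(tmp_path / f"{i}.sf").meta == meta

    @pytest.mark.parametrize("bad", ["unsorted", "duplicate", "empty"])
    def test_writer_input_validation(self, tmp_path, bad):
        cells = _table3_log_cells()
        if bad == "unsorted":
            cells = [cells[1], cells[0], cells[2]]
        elif bad == "duplicate":
            cells = [cells[0], cells[0], cells[1]]
        else:
            cells = []
        with pytest.raises(StoreFileError):
            write_storefile(cells, Family.LOG, tmp_path / "bad.sf")

    def test_corruption_detected(self, tmp_path):
        write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "c.sf")
        raw = bytearray((tmp_path / "c.sf").read_bytes())
        raw[20] ^= 0xFF  # flip one payload byte
        (tmp_path / "c.sf").write_bytes(bytes(raw))
        with pytest.raises(CorruptStoreFileError):
            open_storefile(tmp_path / "c.sf")

    def test_truncation_detected(self, tmp_path):
        write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "t.sf")
        data = (tmp_path / "t.sf").read_bytes()
        (tmp_path / "t.sf").write_bytes(data[: len(data) // 2])
        with pytest.raises(CorruptStoreFileError):
            open_storefile(tmp_path / "t.sf")


class TestRangePruning:
    def test_printed_range_overlaps(self, tmp_path):
        meta = write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "p.sf")
        lo = encode_cell_key(RowKey("MULTMYEL", 79700), Qualifier("A", "0_at"))
        hi = encode_cell_key(RowKey("MULTMYEL", 79800), Qualifier("Z", "9_at"))
        assert file_may_contain(meta, lo, hi)  # patient 79737 lies inside

    def test_disjoint_range_above_end(self, tmp_path):
        meta = write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "d.sf")
        lo = encode_cell_key(RowKey("MULTMYEL", 99000), Qualifier("A", "0_at"))
        hi = encode_cell_key(RowKey("MULTMYEL", 99999), Qualifier("Z", "9_at"))
        assert not file_may_contain(meta, lo, hi)

    def test_no_false_negatives_vs_exhaustive_scan(self, tmp_path):
        cells = _random_cells(300, seed=9)
        meta = write_storefile(cells, Family.RAW, tmp_path / "n.sf")
        keys = [c.key for c in cells]
        rng = random.Random(10)
        for _ in range(1000):
            a, b = sorted((rng.choice(keys) + bytes([rng.randrange(256)]),
                           rng.choice(keys)))
            has_cell = any(a <= k <= b for k in keys)
            if has_cell:
                assert file_may_contain(meta, a, b)

    def test_inverted_range_rejected(self, tmp_path):
        meta = write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "i.sf")
        with pytest.raises(StoreFileError):
            file_may_contain(meta, meta.end_key, meta.start_key)


class TestReadRange:
    def test_worked_example_full_range_order(self, tmp_path):
        cells = _table3_log_cells()
        write_storefile(cells, Family.LOG, tmp_path / "r.sf")
        handle = open_storefile(tmp_path / "r.sf")
        got = list(read_range(handle, handle.meta.start_key,
                              handle.meta.end_key, BlockCache()))
        assert [c.value for c in got] == [b"9.84109256", b"6.16791991",
                                          b"9.24863917"]

    def test_empty_intersection(self, tmp_path):
        write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "e.sf")
        handle = open_storefile(tmp_path / "e.sf")
        assert list(read_range(handle, b"\xfe", b"\xff", BlockCache())) == []

    def test_partition_completeness(self, tmp_path):
        cells = _random_cells(2000, seed=21)
        cfg = StoreConfig(block_bytes=2 * 1024)
        write_storefile(cells, Family.RAW, tmp_path / "pc.sf", cfg)
        handle = open_storefile(tmp_path / "pc.sf")
        cache = BlockCache(1024)
        keys = [c.key for c in cells]
        cuts = sorted(random.Random(22).sample(range(1, len(keys)), 7))
        bounds = [keys[0]] + [keys[i] for i in cuts] + [keys[-1] + b"\xff"]
        rebuilt = []
        for lo, hi in zip(bounds, bounds[1:]):
            rebuilt.extend(read_range(handle, lo, hi, cache, hi_exclusive=True))
        assert rebuilt == cells

    def test_blocks_read_bounded_by_overlap(self, tmp_path):
        cells = _random_cells(2000, seed=33)
        cfg = StoreConfig(block_bytes=2 * 1024)
        write_storefile(cells, Family.RAW, tmp_path / "bb.sf", cfg)
        handle = open_storefile(tmp_path / "bb.sf")
        index = handle.meta.block_index
        rng = random.Random(34)
        for _ in range(50):
            i, j = sorted(rng.sample(range(len(cells)), 2))
            lo, hi = cells[i].key, cells[j].key
            cache = BlockCache(1024)
            list(read_range(handle, lo, hi, cache))
            firsts = [e.first_key for e in index]
            overlapping = sum(
                1 for b, first in enumerate(firsts)
                if first <= hi and (b + 1 == len(firsts) or firsts[b + 1] > lo))
            touched = cache.stats.hits + cache.stats.misses
            assert touched <= overlapping + 1

    def test_closed_handle_rejected(self, tmp_path):
        write_storefile(_table3_log_cells(), Family.LOG, tmp_path / "cl.sf")
        handle = open_storefile(tmp_path / "cl.sf")
        handle.close()
        with pytest.raises(StoreFileError):
            list(read_range(handle, b"\x00", b"\xff", BlockCache()))


class TestCache:
    def test_warm_repeat_does_no_physical_reads(self, tmp_path):
        cells = _random_cells(500, seed=41)
        cfg = StoreConfig(block_bytes=2 * 1024)
        write_storefile(cells, Family.RAW, tmp_path / "w.sf", cfg)
        handle = open_storefile(tmp_path / "w.sf")
        cache = BlockCache(1024)
        list(read_range(handle, handle.meta.start_key, handle.meta.end_key, cache))
        cold_reads = cache.stats.physical_block_reads
        assert cold_reads > 0 and cache.stats.hits == 0
        list(read_range(handle, handle.meta.start_key, handle.meta.end_key, cache))
        assert cache.stats.physical_block_reads == cold_reads
        assert cache.stats.hits == cold_reads

    def test_reset_makes_cache_cold_again(self, tmp_path):
        cells = _random_cells(100, seed=43)
        write_storefile(cells, Family.RAW, tmp_path / "rc.sf")
        handle = open_storefile(tmp_path / "rc.sf")
        cache = BlockCache()
        list(read_range(handle, handle.meta.start_key, handle.meta.end_key, cache))
        first = cache.stats.physical_block_reads
        cache.reset()
        list(read_range(handle, handle.meta.start_key, handle.meta.end_key, cache))
        assert cache.stats.physical_block_reads == 2 * first

    def test_lru_eviction_bounds_resident_blocks(self, tmp_path):
        cells = _random_cells(2000, seed=44)
        cfg = StoreConfig(block_bytes=1024)
        write_storefile(cells, Family.RAW, tmp_path / "ev.sf", cfg)
        handle = open_storefile(tmp_path / "ev.sf")
        cache = BlockCache(capacity_blocks=2)
        list(read_range(handle, handle.meta.start_key, handle.meta.end_key, cache))
        assert len(cache._blocks) <= 2


def test_dump_emits_one_line_per_cell(tmp_path):
    cells = _table3_log_cells()
    write_storefile(cells, Family.LOG, tmp_path / "dump.sf")
    lines = list(dump(open_storefile(tmp_path / "dump.sf")))
    assert len(lines) == 3
    assert lines[0].split("\t")[1] == "9.84109256"
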