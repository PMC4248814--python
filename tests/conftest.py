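"""Shared fixtures: the printed worked example and a mid-size synthetic store."""

from __future__ import annotations

import pytest

from kvexpr import ExpressionRecord, ExpressionTable, StoreConfig
from kvexpr.baseline import bulk_load
from kvexpr.datagen import StudySpec, cohort_catalogue, generate_expression

# The three example source rows: (gene, probeset, patient, trial, raw, log, z).
TABLE3_ROWS = [
    ("LDOC1", "204454_at", 79622, "MULTMYEL", "71.900002", "6.16791991", "8.3069731"),
    ("EI24", "216396_s_at", 79622, "MULTMYEL", "917.20001", "9.84109256", "9.57629541"),
    ("GRID1", "1555267_at", 79737, "MULTMYEL", "608.29999", "9.24863917", "8.88386512"),
]


@pytest.fixture()
def table3_records() -> list[ExpressionRecord]:
    return [ExpressionRecord(*row) for row in TABLE3_ROWS]


@pytest.fixture()
def table3_engine(tmp_path, table3_records) -> ExpressionTable:
    """Engine loaded with the worked example and flushed to StoreFiles."""
    engine = ExpressionTable(tmp_path / "store")
    for record in table3_records:
        engine.put(record)
    engine.flush_all()
    return engine


SYNTH_SPEC = StudySpec(trial_name="MULTMYEL", n_patients=50, n_probesets=2000,
                       seed=20240217)


@pytest.fixture(scope="session")
def synth_records():
    return list(generate_expression(SYNTH_SPEC))


@pytest.fixture(scope="session")
def synth_engine(tmp_path_factory, synth_records) -> ExpressionTable:
    """50 patients x 2,000 probesets, with a 256 KB file cap so every family
    spans several StoreFiles (multi-file read paths get exercised)."""
    root = tmp_path_factory.mktemp("synth-store")
    engine = ExpressionTable(root, StoreConfig(max_storefile_bytes=256 * 1024,
                                               block_bytes=8 * 1024))
    for record in synth_records:
        engine.put(record)
    engine.flush_all()
    return engine


@pytest.fixture(scope="session")
def synth_baseline(synth_records):
    return bulk_load(synth_records)


@pytest.fixture(scope="session")
def synth_catalogue():
    return cohort_catalogue(SYNTH_SPEC)
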