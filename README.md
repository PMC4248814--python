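# kvexpr

An embedded, single-node column-family key-value storage engine for
high-dimensional transcriptomic data — expression matrices of hundreds of
patients by tens of thousands of microarray probesets — together with the
analytic disk-access cost model that motivates the design and a countable
relational baseline to compare it against.

It is aimed at people who build or study storage back ends for translational
data warehouses (tranSMART-style DEAPP tables) and want the BigTable/HBase
schema ideas — composite row keys, column families, sorted immutable
StoreFiles, scan-vs-point-read planning — as a small, fully inspectable
library rather than a cluster deployment.

## The data model

A source row carries four annotations and three measurements:

```
GENE_SYMBOL  PROBESET_ID  PATIENT_ID  TRIAL_NAME  RAW  LOG  ZSCORE
```

The engine maps each row to three cells, one per **Family** (`RAW`, `LOG`,
`ZSCORE`), located by

```
Row Key   = TRIAL_NAME + PATIENT_ID          (trial first: a two-level index)
Column Key = Family + Qualifier,  Qualifier = GENE_SYMBOL + PROBESET_ID
```

Keys are byte-encoded so that lexicographic byte order equals the logical
(trial, patient, gene, probeset) order; each Family's cells live in separate
sorted **StoreFiles** (immutable, block-indexed, start/end keys for range
pruning, values kept as exact decimal literals).  Because a patient's cells
of one value type are contiguous, a cohort query touches few files, and the
first cold block load warms the cache for every neighbouring record.

Cohort retrieval offers two plans that always return identical cells:
**Random Read** (one point get per patient) and **Scan** (one sequential
sweep over the id span, filtering unrequested patients client-side), with an
automatic choice by cohort density |ids| / (max − min + 1).

## The cost model

With pn patients, ps probesets each, B-tree order m, tr the time to fetch
one relational record (load a 32 KB page) and tkv the time to load one
128 MB StoreFile:

```
T_rel  = pn·ps · log_m(pn·ps) · tr          (one indexed fetch per record)
T_kv  <= 2·pn · log_m(pn) · tkv             (<= 2 StoreFile loads per patient)

T_rel / T_kv = ps · ln(pn·ps) · tr / (2 · ln(pn) · tkv)      (m cancels)
```

At study scale (pn = 559, ps = 54,675, tr = 10 ms, tkv = 9,000 ms) the ratio
is ≈ 82.76, i.e. the ideal key-value layout is about 83× faster than the
ideal relational one before caches and query optimisers are considered.
The `≤ 2 files` assumption holds because one patient-family is
300 B × 54,675 ≈ 16 MB < 128 MB.

## Worked example

```python
from kvexpr import ExpressionRecord, ExpressionTable, Family, Qualifier

records = [
    ExpressionRecord("LDOC1", "204454_at", 79622, "MULTMYEL",
                     "71.900002", "6.16791991", "8.3069731"),
    ExpressionRecord("EI24", "216396_s_at", 79622, "MULTMYEL",
                     "917.20001", "9.84109256", "9.57629541"),
    ExpressionRecord("GRID1", "1555267_at", 79737, "MULTMYEL",
                     "608.29999", "9.24863917", "8.88386512"),
]
engine = ExpressionTable("store/")
for r in records:
    engine.put(r)
engine.flush_all()

for cell in engine.scan("MULTMYEL", 79622, 79737, Family.LOG):
    print(cell.row.patient_id, cell.qualifier.gene_symbol, cell.value)
```

prints the LOG StoreFile in its on-disk key order:

```
79622 EI24 9.84109256
79622 LDOC1 6.16791991
79737 GRID1 9.24863917
```

— patients sort numerically inside the trial, qualifiers lexicographically
inside the patient, and every value is the exact literal that was loaded
(`engine.get("MULTMYEL", 79622, Family.LOG, Qualifier("LDOC1", "204454_at"))`
returns `6.16791991`, digit for digit).

The `examples/` directory has one narrative script per capability: the
worked example, the cost model, cohort queries, and the two-engine benchmark
harness.  A thin CLI exposes the same flows
(`kvexpr generate | load | query | bench | costmodel`).

## Synthetic studies

`kvexpr.datagen` builds seeded studies at any scale (default: trial
MULTMYEL, 559 patients × 54,675 probesets): Affymetrix-style platform
annotations, expression triples whose RAW/LOG pairs are exactly
log2-consistent at stored precision with ZSCORE standardised per probeset,
and the A–G cohort-case catalogue (e.g. case F: groups of 496 and 63
patients; case G: the whole trial), scaled proportionally at smaller sizes.

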