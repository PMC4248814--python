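# Methods

## Storage model

`kvexpr` implements a BigTable-style column-family store as a single-node,
single-writer embedded library.  The unit of storage is a cell
`(row key, family, qualifier) → value`:

* **Row key** — `TRIAL_NAME + 0x00 + zero-padded PATIENT_ID`.  Trial first,
  so one composite key doubles as an index on the trial and on the patient
  within it; the patient id is fixed-width decimal (default width 8,
  configurable) so byte order and numeric order coincide.
* **Qualifier** — `GENE_SYMBOL + 0x00 + PROBESET_ID`, ordered
  lexicographically within a row.
* **Family** — `RAW`, `LOG` or `ZSCORE`; a closed three-value enumeration.
  Families are physically separate: each has its own memstore and its own
  StoreFiles, so a query for one value type never performs I/O for another.

Variable-length string fields are joined by a `0x00` separator rather than
fixed-width padding: gene symbols have no usable fixed width, and `0x00`
sorts before every permitted field byte (NUL is banned in field content),
which preserves prefix order.  Field content is case-sensitive and never
normalised.  The encoded row key is a strict prefix of every cell key of
its row, which is what lets both range scans and whole-file pruning operate
on row-key prefixes.

A **StoreFile** is an immutable, strictly key-sorted file for one Family
with a header (magic, version), a block section (cells grouped into blocks
of ≤ `block_bytes` payload), and a trailer (family, cell count, start/end
keys, block index of (first key, offset, cell count), CRC32 of the block
section).  All integers are little-endian fixed width.  Opening a file
verifies magic, version and checksum.  Values are stored as UTF-8 decimal
literals, not binary floats, so the precision of the source data is the
precision of every query answer — numeric conversion happens only at the
query/matrix boundary.

The write path buffers cells per Family and flushes each memstore to one or
more StoreFiles, splitting only when the payload exceeds
`max_storefile_bytes` (default 128 MB, the production file size; tests use
small caps to exercise multi-file stores at desk scale).  Flushing is
explicit or threshold-triggered; there is no write-ahead log, no
multi-version timestamps, no compaction and no background work — duplicate
keys resolve as last-write-wins with memstore > newest file > older file.

The read path merges the memstore with every StoreFile whose
`[start_key, end_key]` interval intersects the query range (pruning by
metadata only, no false negatives), locates the first block by binary
search on the block index, and streams blocks through a shared LRU block
cache (default 256 blocks of 64 KB).  Cache counters (hits, misses,
physical block reads) are monotone and exposed; `reset_cache` empties the
cache without touching the counters, giving a cold-cache mode for
benchmarking.

## Cohort queries

`run_cohort_query` supports two plans that provably return identical cells:
per-patient point gets (`RANDOM_READ`) and one sequential sweep over
`[min id, max id]` with client-side filtering (`SCAN`).  `AUTO` chooses by
cohort density `|ids| / (max − min + 1)`: scan at density ≥ 0.10 (default,
configurable).  The threshold reflects that sequential scans win except for
small cohorts spread sparsely over a wide id span — roughly break-even
around density ≈ 0.13 (63 patients over a 481-patient span) — and is an
engineering default, not a fitted constant; there is no numeric rule to
inherit, strategy choice having historically been manual.  A mixed plan
(scan some runs, point-read outliers) is deliberately not implemented.
Requested ids absent from the store are silently absent from results,
matching point-get semantics.

`result_to_matrix` pivots a single-family result to a pandas DataFrame
(patients × (gene, probeset), NaN for absent cells); `write_gct` emits the
transpose as GCT 1.2 for downstream expression tools.

## Relational baseline

The comparator stores one record per (patient, probeset) measurement packed
into 32 KB pages under a nominal 300-byte row size (floor packing: 109 rows
per page), with a sorted composite index on (trial, patient) standing in
for the B-tree.  It is an in-process structure rather than an external
DBMS so that page accesses are countable and tests are hermetic; the
benchmark harness asserts, for every cohort case, that the baseline and the
key-value engine return identical (patient, gene, probeset, value) sets
before any timing is reported.  Timings are informational only: absolute
wall-clock is hardware-dependent and appears in no assertion.

## Cost model

`cost_model` evaluates the closed forms

* relational: `pn·ps · log_m(pn·ps) · tr`
* key-value: `2·pn · log_m(pn) · tkv`
* ratio: `ps · ln(pn·ps) · tr / (2 · ln(pn) · tkv)` — the base-m logs cancel
  exactly; natural logs are used internally via the change-of-base identity.

`tr` (10 ms per 32 KB page) and `tkv` (9,000 ms per 128 MB StoreFile) are
nominal figures for one commodity SATA controller and are configurable
parameters, not constants.  The ≤ 2-files-per-patient premise of the
key-value bound is checked by the size arithmetic: one patient-family is
`300 B × ps` (≈ 16 MB at ps = 54,675), and `storefiles_needed` returns 1
whenever that fits one file.  The model deliberately ignores caches, query
optimisers and seek latency; it is an idealised bound, which is why the
measured speedups of real deployments are far below the ~83× ceiling and
why this package asserts content and cache behaviour rather than time.

## Synthetic data generator

`datagen` emulates a multiple-myeloma-scale study (trial "MULTMYEL",
559 × 54,675 at full scale) as a pure function of a seed:

* **Platform** — unique probeset ids (random 7-digit stems, suffix from
  `_at`/`_s_at`/`_x_at`) with synthetic uppercase gene symbols; symbols may
  repeat across probesets, as on real arrays.
* **Expression** — per probeset g, `LOG ~ Normal(μ_g, σ_g)` with
  `μ_g ~ U(4, 12)` and `σ_g ~ U(0.5, 1.5)`: a lognormal intensity model
  spanning the usual microarray dynamic range.  The distribution parameters
  are a modelling choice (no published generative model exists for these
  values) and are visible in the module.  `RAW = 2^LOG` rendered at 8
  significant digits; `LOG` is then re-derived as `round(log2(RAW), 8)`, so
  every stored pair is exactly log2-consistent at stored precision — the
  property the worked-example values obey (e.g. `log2(917.20001) →
  9.84109256`).  `ZSCORE` standardises LOG per probeset across patients
  (sample sd, 8 decimals); plain standardisation is an assumption, chosen
  because the worked example's z-values are inconsistent with a clamped
  variant.  The generator materialises the probeset × patient matrix in
  memory (z-scores need all patients per probeset), which is fine at the
  desk scales used here; full study scale would need a chunked variant.
* **Cohorts** — the A–G catalogue with group sizes fixed at study scale
  (A: 213/137, B: 459/100, C: 308/251, D: 351/208, E: 400/159, F: 496/63,
  G: all 559) and scaled as `round(size × n/559)` otherwise, clamped so the
  two disjoint groups fit the universe.  Case labels `X1`/`X2` query group 1
  and group 2 of comparison X respectively.  Groups are sampled directly as
  sized, disjoint id sets per case: the narrative case definitions are
  mutually inconsistent as filters over a single clinical table (B and D
  imply different Therapy-2 totals), so the sizes are authoritative and the
  emitted clinical table (therapy, survival, alive flag) is decorative.
* Patient ids are consecutive from `patient_id_start` (default 10000), so
  cohort density over the id span behaves like the planner expects.

What passing tests on this data do show: ordering, completeness,
strategy/engine equivalence, cache locality, and exact literal round-trips
under realistic key shapes and value distributions.  What they do not show:
behaviour under real-data irregularities (batch effects, missing probesets,
non-uniform patient-id gaps, QC artefacts) or any wall-clock performance
claim.

## Numerical and engineering choices

* Deterministic everywhere: every random draw flows from explicit seeds
  (numpy `default_rng` with derived seed sequences); repeated runs are
  byte-identical, including TSV output.
* Degenerate inputs: empty memstore flush is a no-op; empty query ranges
  yield empty iterators; single-patient studies set ZSCORE to 0 (no sample
  sd); a zero-variance probeset standardises to 0; empty cohort id sets and
  inverted ranges are errors.
* Scale of shipped checks: the randomized store used by the test suite is
  50 patients × 2,000 probesets (300,000 cells) with a 256 KB file cap and
  8 KB blocks, sized to exercise multi-file merge, pruning and caching
  while keeping the suite fast; the acceptance script loads a 559-patient ×
  100-probeset study.
* The paged-row arithmetic uses floor packing (109 rows of 300 B per 32 KB
  page); at small row counts this coincides with the byte-ratio ceiling.

## Known limitations

Single process, single writer, no durability guarantees (no WAL), no
deletes or multi-versioning, no compression or bloom filters, no secondary
indexes, no region splitting or distribution.  These mirror the scope of an
embedded reference implementation of the schema design; the cluster-level
features of the systems that inspired it are intentionally out of scope.
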