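"""Cohort retrieval: Random Read vs Scan on a small synthetic study.

Generates 30 patients x 100 probesets, loads the store, then runs one
dense and one sparse cohort with both strategies.  Both plans always
return identical cells; they differ in how many cells the plan touches
before client-side filtering, which is what the density heuristic trades
off when strategy is AUTO.
"""

import tempfile

from kvexpr import (
    CohortQuery,
    ExpressionTable,
    Family,
    Strategy,
    choose_strategy,
    result_to_matrix,
    run_cohort_query,
)
from kvexpr.datagen import StudySpec, generate_expression

spec = StudySpec(n_patients=30, n_probesets=100, seed=7)

with tempfile.TemporaryDirectory() as store_dir:
    engine = ExpressionTable(store_dir)
    for record in generate_expression(spec):
        engine.put(record)
    engine.flush_all()

    dense = set(range(10000, 10012))          # 12 contiguous patients
    sparse = {10000, 10014, 10029}            # 3 patients over a span of 30

    for label, ids in [("dense", dense), ("sparse", sparse)]:
        q = CohortQuery(spec.trial_name, ids, Family.LOG)
        print(f"{label} cohort: {len(ids)} patients, density {q.density:.3f} "
              f"-> AUTO picks {choose_strategy(q).value}")
        results = {}
        for strategy in (Strategy.RANDOM_READ, Strategy.SCAN):
            r = run_cohort_query(
                CohortQuery(spec.trial_name, ids, Family.LOG, strategy), engine)
            results[strategy] = r
            print(f"  {strategy.value:<11}: {len(r.cells)} cells returned, "
                  f"{r.cells_touched} touched before filtering")
        assert results[Strategy.RANDOM_READ].cells == results[Strategy.SCAN].cells
        print("  both strategies returned identical cells\n")

    matrix = result_to_matrix(run_cohort_query(
        CohortQuery(spec.trial_name, sparse, Family.LOG, Strategy.SCAN), engine))
    print(f"sparse-cohort matrix: {matrix.shape[0]} patients x "
          f"{matrix.shape[1]} probesets, "
          f"{int(matrix.notna().sum().sum())} filled entries")
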