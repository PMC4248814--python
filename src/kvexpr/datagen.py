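"""Seeded synthetic microarray study generator.

Emulates a multiple-myeloma-style expression study — by default trial
"MULTMYEL" with 559 patients and 54,675 probesets per patient on a
GPL570-like platform — at any configurable scale, producing:

* platform annotations: unique Affymetrix-style probeset ids (digits plus
  an ``_at`` / ``_s_at`` / ``_x_at`` suffix) mapped to synthetic uppercase
  gene symbols;
* expression records whose RAW/LOG pair is exactly log2-consistent at the
  stored decimal precision (the property real pipeline output obeys:
  LOG = round(log2(RAW), 8)), with ZSCORE the per-probeset standardisation
  of LOG across patients;
* the study's cohort catalogue: the A–G test cases with their printed group
  sizes at study scale (A: 213/137, B: 459/100, C: 308/251, D: 351/208,
  E: 400/159, F: 496/63, G: all 559), scaled proportionally at other sizes.

Everything is a pure function of the seed.  Cohort groups are generated
directly as sized, disjoint patient-id sets per case: the printed case
definitions are mutually inconsistent as filters over a single clinical
table (cases B and D imply different Therapy-2 totals), so the sizes, not
the clinical covariates, are authoritative; a decorative clinical table is
emitted for realism only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .table_engine import ExpressionRecord

__all__ = [
    "StudySpec",
    "CohortCase",
    "CASE_SIZES_AT_STUDY_SCALE",
    "STUDY_SCALE_PATIENTS",
    "generate_platform",
    "generate_expression",
    "cohort_catalogue",
    "generate_clinical",
]

STUDY_SCALE_PATIENTS = 559
STUDY_SCALE_PROBESETS = 54_675

# (group1, group2) sizes of each comparison at the 559-patient study scale.
CASE_SIZES_AT_STUDY_SCALE: dict[str, tuple[int, int]] = {
    "A": (213, 137),
    "B": (459, 100),
    "C": (308, 251),
    "D": (351, 208),
    "E": (400, 159),
    "F": (496, 63),
    "G": (STUDY_SCALE_PATIENTS, 0),
}

_PROBESET_SUFFIXES = ("_at", "_s_at", "_x_at")


@dataclass(frozen=True)
class StudySpec:
    """Scale and identity of one synthetic study."""

    trial_name: str = "MULTMYEL"
    n_patients: int = STUDY_SCALE_PATIENTS
    n_probesets: int = STUDY_SCALE_PROBESETS
    seed: int = 0
    patient_id_start: int = 10000

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_probesets < 1:
            raise ValueError("n_patients and n_probesets must be >= 1")

    @property
    def patient_ids(self) -> list[int]:
        return list(range(self.patient_id_start,
                          self.patient_id_start + self.n_patients))


@dataclass(frozen=True)
class CohortCase:
    """One catalogued test case.

    ``case_id`` is the query label: "X1" queries group 1 of comparison X,
    "X2" queries group 2, and "G" queries the whole trial.  Both groups'
    sizes and sampled id sets are carried so the comparison structure stays
    visible.
    """

    case_id: str
    group1_size: int
    group2_size: int
    group1_ids: frozenset[int]
    group2_ids: frozenset[int]

    @property
    def query_ids(self) -> frozenset[int]:
        return self.group2_ids if self.case_id.endswith("2") else self.group1_ids


def generate_platform(n_probesets: int, seed: int) -> list[tuple[str, str]]:
    """Deterministic list of (gene_symbol, probeset_id) annotations.

    Probeset ids are unique (unique numeric stems); gene symbols may repeat
    across probesets, as on real arrays.
    """
    if n_probesets < 1:
        raise ValueError("n_probesets must be >= 1")
    rng = np.random.default_rng([seed, 0xA11E1])
    stems = rng.choice(9_000_000, size=n_probesets, replace=False) + 1_000_000
    suffixes = rng.integers(0, len(_PROBESET_SUFFIXES), size=n_probesets)
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    lengths = rng.integers(3, 7, size=n_probesets)
    picks = rng.integers(0, 26, size=(n_probesets, 6))
    digit = rng.integers(0, 10, size=n_probesets)
    out = []
    for i in range(n_probesets):
        gene = "".join(letters[picks[i, : lengths[i]]])
        if lengths[i] < 6 and digit[i] < 4:  # some symbols carry a digit
            gene += str(digit[i])
        out.append((gene, f"{stems[i]}{_PROBESET_SUFFIXES[suffixes[i]]}"))
    return out


def _raw_literal(x: float) -> str:
    """Render an intensity at 8 significant digits, the precision of
    pipeline-exported raw values (e.g. 917.20001)."""
    return repr(float(f"{x:.8g}"))


def generate_expression(spec: StudySpec) -> Iterator[ExpressionRecord]:
    """Stream the full study, patient-major.

    Per probeset g: LOG ~ Normal(mu_g, sigma_g) with mu_g ~ U(4, 12) and
    sigma_g ~ U(0.5, 1.5) — a lognormal-intensity model spanning the usual
    microarray dynamic range.  RAW is 2**LOG at 8 significant digits and
    LOG is re-derived as round(log2(RAW), 8), so every emitted pair is
    exactly log2-consistent at stored precision.  ZSCORE standardises LOG
    per probeset across patients (sample sd, 8 decimals).
    """
    platform = generate_platform(spec.n_probesets, spec.seed)
    rng = np.random.default_rng([spec.seed, 0xE19])
    mu = rng.uniform(4.0, 12.0, size=spec.n_probesets)
    sigma = rng.uniform(0.5, 1.5, size=spec.n_probesets)
    log0 = rng.normal(mu[:, None], sigma[:, None],
                      size=(spec.n_probesets, spec.n_patients))

    raw = np.empty_like(log0)
    for g in range(spec.n_probesets):
        for j in range(spec.n_patients):
            raw[g, j] = float(f"{2.0 ** log0[g, j]:.8g}")
    log = np.round(np.log2(raw), 8)

    if spec.n_patients > 1:
        centre = log.mean(axis=1, keepdims=True)
        sd = log.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = np.round((log - centre) / sd, 8)
    else:
        z = np.zeros_like(log)

    for j, pid in enumerate(spec.patient_ids):
        for g, (gene, probeset) in enumerate(platform):
            yield ExpressionRecord(
                gene_symbol=gene,
                probeset_id=probeset,
                patient_id=pid,
                trial_name=spec.trial_name,
                raw=repr(float(raw[g, j])),
                log=repr(float(log[g, j])),
                zscore=repr(float(z[g, j])),
            )


def _scaled(size: int, n_patients: int) -> int:
    return int(round(size * n_patients / STUDY_SCALE_PATIENTS))


def cohort_catalogue(spec: StudySpec) -> list[CohortCase]:
    """The thirteen catalogued queries (A1..F2 and G) with sampled id sets.

    At n_patients = 559 group sizes equal the printed values exactly; at
    other scales they are round(printed * n/559), with group 2 clamped so
    the two disjoint groups fit the patient universe.  Case G is the whole
    trial.  Sampling is deterministic per (seed, case).
    """
    universe = np.array(spec.patient_ids)
    cases: list[CohortCase] = []
    for idx, (letter, (s1, s2)) in enumerate(sorted(CASE_SIZES_AT_STUDY_SCALE.items())):
        if letter == "G":
            all_ids = frozenset(int(p) for p in universe)
            cases.append(CohortCase("G", spec.n_patients, 0, all_ids, frozenset()))
            continue
        g1 = _scaled(s1, spec.n_patients)
        g2 = _scaled(s2, spec.n_patients)
        g1 = max(1, min(g1, spec.n_patients))
        g2 = max(1, min(g2, spec.n_patients - g1))
        if g1 + g2 > spec.n_patients:
            raise ValueError(
                f"case {letter}: group sizes {g1}+{g2} exceed {spec.n_patients}")
        for sub in ("1", "2"):
            rng = np.random.default_rng([spec.seed, 0xC0407, idx, int(sub)])
            perm = rng.permutation(universe)
            ids1 = frozenset(int(p) for p in perm[:g1])
            ids2 = frozenset(int(p) for p in perm[g1:g1 + g2])
            cases.append(CohortCase(f"{letter}{sub}", g1, g2, ids1, ids2))
    return cases


def generate_clinical(spec: StudySpec) -> pd.DataFrame:
    """Decorative per-patient clinical covariates (therapy arm, survival
    months, alive flag).  Realism only — cohort membership comes from the
    catalogue's sampled id sets, not from filtering this table."""
    rng = np.random.default_rng([spec.seed, 0xC11])
    n = spec.n_patients
    return pd.DataFrame({
        "patient_id": spec.patient_ids,
        "trial_name": spec.trial_name,
        "therapy": rng.choice([2, 3], size=n, p=[0.63, 0.37]),
        "survival_months": np.round(rng.gamma(4.0, 12.0, size=n), 1),
        "alive": rng.random(n) < 0.55,
    })
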