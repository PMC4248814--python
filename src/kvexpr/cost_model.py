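"""Closed-form B-tree disk-access cost model: relational vs key-value.

Both storage layouts index their data with a B-tree of order m, but they
differ in what one leaf fetch delivers.

Relational model: one row per (patient, probeset) measurement; retrieving a
whole study of pn patients x ps probesets means pn*ps index traversals, each
of depth log_m(pn*ps), each ending in a record fetch costing tr (the time to
load one 32 KB data page):

    T_rel = pn * ps * log_m(pn * ps) * tr

Key-value model: all of one patient's values for one Family are contiguous,
and one Family-worth of one patient's probesets (ps * bytes_per_probeset,
about 16 MB at ps = 54,675 and 300 B each) fits in a single 128 MB
StoreFile — at most two when it straddles a file boundary.  So fetching a
patient costs at most two StoreFile loads of tkv each, after a tree descent
of depth log_m(pn):

    T_kv <= 2 * pn * log_m(pn) * tkv

Their ratio is independent of m (the log base cancels):

    T_rel / T_kv = ps * ln(pn*ps) * tr / (2 * ln(pn) * tkv)

which evaluates to ~83 at the study scale pn=559, ps=54,675 with the
nominal SATA figures tr = 10 ms per 32 KB page and tkv = 9,000 ms per
128 MB file — the theoretical ceiling on the key-value speedup, ignoring
caches and query optimisers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostParams",
    "CostModelError",
    "relational_fetch_time",
    "keyvalue_fetch_time",
    "speedup_ratio",
    "patient_family_bytes",
    "storefiles_needed",
]


class CostModelError(ValueError):
    pass


@dataclass(frozen=True)
class CostParams:
    """Symbols of the cost model.

    pn : patients in the study (>= 2 for ratio computations).
    ps : probesets measured per patient.
    m : B-tree order (branching factor); cancels in the speedup ratio.
    tr : ms to fetch one relational record, i.e. load one 32 KB data page.
    tkv : ms to load one full StoreFile (128 MB).
    bytes_per_probeset : average stored size of one probeset value (300 B).
    page_bytes / storefile_bytes : the two I/O granularities the times refer to.

    The tr/tkv defaults are nominal figures for one commodity SATA
    controller; they are parameters, not constants.
    """

    pn: int
    ps: int
    m: float = 100.0
    tr: float = 10.0
    tkv: float = 9000.0
    bytes_per_probeset: int = 300
    page_bytes: int = 32 * 1024
    storefile_bytes: int = 128 * 1024 * 1024

    def __post_init__(self) -> None:
        if self.pn < 1 or self.ps < 1:
            raise CostModelError("pn and ps must be positive integers")
        if self.m <= 1:
            raise CostModelError("B-tree order m must exceed 1")
        if min(self.tr, self.tkv) <= 0:
            raise CostModelError("tr and tkv must be positive")
        if min(self.bytes_per_probeset, self.page_bytes, self.storefile_bytes) <= 0:
            raise CostModelError("sizes must be positive")


def relational_fetch_time(p: CostParams) -> float:
    """pn*ps * log_m(pn*ps) * tr, in milliseconds: every measurement is a
    separate indexed record fetch."""
    records = p.pn * p.ps
    return records * math.log(records, p.m) * p.tr


def keyvalue_fetch_time(p: CostParams) -> float:
    """2*pn * log_m(pn) * tkv, in milliseconds: at most two StoreFile loads
    per patient after a per-patient tree descent."""
    return 2 * p.pn * math.log(p.pn, p.m) * p.tkv


def speedup_ratio(p: CostParams) -> float:
    """Relational over key-value fetch time; independent of the tree order m.

    ratio = ps * ln(pn*ps) * tr / (2 * ln(pn) * tkv).  Requires pn >= 2
    (ln pn must be positive).
    """
    if p.pn < 2:
        raise CostModelError("speedup ratio undefined for pn < 2 (ln pn <= 0)")
    return (p.ps * math.log(p.pn * p.ps) * p.tr) / (2 * math.log(p.pn) * p.tkv)


def patient_family_bytes(p: CostParams) -> int:
    """Bytes one patient's values occupy in one Family: bytes_per_probeset * ps."""
    return p.bytes_per_probeset * p.ps


def storefiles_needed(p: CostParams) -> int:
    """StoreFiles needed to hold one patient's one-Family data.

    1 when the data fits a single file (the <= 2-files-per-patient
    assumption then holds, since a fitting run can straddle at most one
    file boundary); otherwise the ceiling of bytes over file size.
    """
    nbytes = patient_family_bytes(p)
    if nbytes <= p.storefile_bytes:
        return 1
    return math.ceil(nbytes / p.storefile_bytes)
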