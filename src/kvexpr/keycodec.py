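"""Order-preserving byte encoding of composite row and column keys.

The store sorts cells by a single byte string.  The codec guarantees that
byte-lexicographic order of encoded keys equals the intended logical order

    (trial_name, patient_id, gene_symbol, probeset_id)

so that all cells of one patient are physically adjacent, all patients of one
trial form one contiguous key range, and qualifiers within a row sort by
(gene, probeset).  Two devices make this work:

* variable-length string fields are joined by a 0x00 separator, which sorts
  before every byte that can occur inside a field (NUL is forbidden in field
  content), so a shorter field that is a prefix of a longer one still sorts
  first;
* the numeric patient id is encoded as fixed-width zero-padded decimal, so
  byte order and numeric order coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Family",
    "RowKey",
    "Qualifier",
    "CodecConfig",
    "KeyCodecError",
    "MalformedKeyError",
    "encode_row_key",
    "encode_qualifier",
    "encode_cell_key",
    "decode_cell_key",
]


class KeyCodecError(ValueError):
    """A field violates the codec's domain (NUL byte, width overflow, empty)."""


class MalformedKeyError(ValueError):
    """A byte sequence cannot be decoded as a cell key."""


class Family(str, Enum):
    """The three per-measurement value types, each stored physically apart.

    RAW is the probeset intensity, LOG its base-2 logarithm, ZSCORE a
    standardized score.  Families are the unit of I/O locality: a query for
    one value type never touches files of another.
    """

    RAW = "RAW"
    LOG = "LOG"
    ZSCORE = "ZSCORE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CodecConfig:
    """Codec parameters.

    patient_id_width
        Number of decimal digits the patient id is zero-padded to.  Must be
        at least the digit count of every id stored; 8 comfortably covers
        real accession-style ids (the worked examples use 5-digit ids).
    field_separator
        Single byte joining variable-length fields; must sort below all
        permitted field bytes, hence the 0x00 default.
    """

    patient_id_width: int = 8
    field_separator: bytes = b"\x00"

    def __post_init__(self) -> None:
        if self.patient_id_width < 1:
            raise KeyCodecError("patient_id_width must be >= 1")
        if len(self.field_separator) != 1:
            raise KeyCodecError("field_separator must be a single byte")


@dataclass(frozen=True, order=True)
class RowKey:
    """Composite row key: trial first, then patient, so the encoded key is
    simultaneously an index on the trial and on the patient within it."""

    trial_name: str
    patient_id: int

    def __post_init__(self) -> None:
        if not self.trial_name:
            raise KeyCodecError("trial_name must be non-empty")
        if "\x00" in self.trial_name:
            raise KeyCodecError("trial_name must not contain a NUL byte")
        if self.patient_id < 0:
            raise KeyCodecError("patient_id must be non-negative")


@dataclass(frozen=True, order=True)
class Qualifier:
    """Within-family column name: gene symbol plus probeset id."""

    gene_symbol: str
    probeset_id: str

    def __post_init__(self) -> None:
        for name, value in (("gene_symbol", self.gene_symbol),
                            ("probeset_id", self.probeset_id)):
            if not value:
                raise KeyCodecError(f"{name} must be non-empty")
            if "\x00" in value:
                raise KeyCodecError(f"{name} must not contain a NUL byte")


def encode_row_key(key: RowKey, cfg: CodecConfig = CodecConfig()) -> bytes:
    """Encode ``trial + separator + zero-padded patient id``.

    For a fixed trial, byte order equals numeric patient order; across
    trials, byte order equals (trial, patient) tuple order.
    """
    digits = str(key.patient_id)
    if len(digits) > cfg.patient_id_width:
        raise KeyCodecError(
            f"patient_id {key.patient_id} exceeds configured width "
            f"{cfg.patient_id_width}"
        )
    return (
        key.trial_name.encode("utf-8")
        + cfg.field_separator
        + digits.zfill(cfg.patient_id_width).encode("ascii")
    )


def encode_qualifier(q: Qualifier, cfg: CodecConfig = CodecConfig()) -> bytes:
    """Encode ``gene + separator + probeset``; order = (gene, probeset)."""
    return (
        q.gene_symbol.encode("utf-8")
        + cfg.field_separator
        + q.probeset_id.encode("utf-8")
    )


def encode_cell_key(
    key: RowKey, q: Qualifier, cfg: CodecConfig = CodecConfig()
) -> bytes:
    """Full cell key; global sort order = (trial, patient, gene, probeset).

    The row-key encoding is a strict prefix of every cell key of that row,
    which is what lets range scans and StoreFile pruning operate on row-key
    prefixes alone.
    """
    return encode_row_key(key, cfg) + cfg.field_separator + encode_qualifier(q, cfg)


def decode_cell_key(
    data: bytes, cfg: CodecConfig = CodecConfig()
) -> tuple[RowKey, Qualifier]:
    """Exact inverse of :func:`encode_cell_key` under the same config."""
    if not data:
        raise MalformedKeyError("empty byte sequence")
    parts = data.split(cfg.field_separator)
    if len(parts) != 4:
        raise MalformedKeyError(
            f"expected 4 separator-delimited fields, found {len(parts)}"
        )
    trial_b, patient_b, gene_b, probeset_b = parts
    if len(patient_b) != cfg.patient_id_width or not patient_b.isdigit():
        raise MalformedKeyError(
            f"patient field {patient_b!r} is not {cfg.patient_id_width} decimal digits"
        )
    try:
        row = RowKey(trial_b.decode("utf-8"), int(patient_b))
        qual = Qualifier(gene_b.decode("utf-8"), probeset_b.decode("utf-8"))
    except (UnicodeDecodeError, KeyCodecError) as exc:
        raise MalformedKeyError(str(exc)) from exc
    return row, qual


def row_prefix_range(key: RowKey, cfg: CodecConfig = CodecConfig()) -> tuple[bytes, bytes]:
    """Half-open byte range [lo, hi) covering exactly the cells of one row.

    Cell keys of the row are ``enc(row) + sep + qualifier``; because no other
    row's encoding can extend this row's encoding (NUL is banned in fields),
    ``enc(row) + sep`` .. ``enc(row) + (sep+1)`` brackets precisely this row.
    """
    base = encode_row_key(key, cfg)
    sep = cfg.field_separator[0]
    return base + cfg.field_separator, base + bytes([sep + 1])


def span_range(
    trial: str,
    patient_lo: int,
    patient_hi: int,
    cfg: CodecConfig = CodecConfig(),
) -> tuple[bytes, bytes]:
    """Half-open byte range covering rows patient_lo..patient_hi inclusive."""
    if patient_lo > patient_hi:
        raise KeyCodecError("patient_lo must be <= patient_hi")
    lo, _ = row_prefix_range(RowKey(trial, patient_lo), cfg)
    _, hi = row_prefix_range(RowKey(trial, patient_hi), cfg)
    return lo, hi
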