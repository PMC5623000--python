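"""The fingerprint transform: raw tallies, normalization, binary encoding.

A *raw fingerprint* is a 144 x L table of SNV-pair counts. Each pair of
consecutive SNVs on a chromosome selects a row by its four-letter pair key
and a column by the distance between the SNVs folded modulo L. Pairs closer
than C bases are tallied in a separate 144 x C *close matrix* instead: short
range spacing mostly reflects sequencing technology and pipeline encodings
of multi-nucleotide variants, so it is segregated from the comparable part
of the fingerprint.

Distance convention: d = pos2 - pos1 - 1, the number of intervening
reference bases. The convention is recorded in the file format metadata;
mod-L comparability only requires all compared fingerprints to share it.

The *normalized fingerprint* two-pass z-scores the raw matrix — first each
of the L distance columns (over the 144 rows), then each of the 144 key rows
(over the L columns). The order matters: distance first, then key. Standard
deviations use the population form (divide by n). A column or row whose
deviation is zero is set to zeros rather than dividing by zero, which keeps
tiny or empty genomes well defined.

The *binary fingerprint* is the 144-bit reduction: from an L=2 raw matrix,
bit[row] = 1 iff the odd-distance tally exceeds the even-distance tally
(column 1 > column 0); ties give 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .keys import N_PAIR_KEYS, PAIR_KEYS, N_SNV_KEYS
from .variants import VariantRecord, VariantTable

__all__ = [
    "FingerprintMeta",
    "RawFingerprint",
    "NormalizedFingerprint",
    "BinaryFingerprint",
    "ParameterMismatchError",
    "DEFAULT_L",
    "DEFAULT_C",
    "compute_raw",
    "merge_raw",
    "normalize",
    "binarize",
    "binarize_from_raw",
    "serialize",
]

DEFAULT_L = 20
DEFAULT_C = 20


class ParameterMismatchError(ValueError):
    """Fingerprints computed with different L or C cannot be combined."""


@dataclass
class FingerprintMeta:
    """Provenance and bookkeeping carried by every fingerprint."""

    kind: str  # raw | normalized | population | adjusted | binary
    L: int
    C: int
    n_snvs: int = 0
    n_pairs_raw: int = 0
    n_pairs_close: int = 0
    source: str = ""


@dataclass
class RawFingerprint:
    """144 x L count matrix plus the 144 x C close matrix."""

    meta: FingerprintMeta
    raw: np.ndarray  # (144, L) int64
    close: np.ndarray  # (144, C) int64

    def __post_init__(self) -> None:
        if self.raw.shape != (N_PAIR_KEYS, self.meta.L):
            raise ValueError(f"raw matrix shape {self.raw.shape} != (144, {self.meta.L})")
        if self.close.shape != (N_PAIR_KEYS, self.meta.C):
            raise ValueError(f"close matrix shape {self.close.shape} != (144, {self.meta.C})")


@dataclass
class NormalizedFingerprint:
    """144 x L real matrix; kind is normalized, population or adjusted."""

    meta: FingerprintMeta
    values: np.ndarray  # (144, L) float64

    def __post_init__(self) -> None:
        if self.values.shape != (N_PAIR_KEYS, self.meta.L):
            raise ValueError(
                f"values shape {self.values.shape} != (144, {self.meta.L})"
            )


@dataclass
class BinaryFingerprint:
    """Ordered 144-bit vector indexed by pair-key row."""

    meta: FingerprintMeta
    bits: np.ndarray  # (144,) uint8

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (N_PAIR_KEYS,):
            raise ValueError(f"bits shape {self.bits.shape} != (144,)")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")

    def to01(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def compute_raw(
    snvs: VariantTable | Iterable[VariantRecord],
    L: int = DEFAULT_L,
    C: int = DEFAULT_C,
    source: str = "",
) -> RawFingerprint:
    """Tally consecutive within-chromosome SNV pairs into a raw fingerprint.

    For each consecutive pair, the distance d = pos2 - pos1 - 1 (intervening
    reference bases); pairs with d < C go to close[row][d], all others to
    raw[row][d mod L]. Pairs never span chromosomes. An empty stream yields
    a valid all-zero fingerprint.
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    if C < 0:
        raise ValueError(f"C must be >= 0, got {C}")
    table = VariantTable.coerce(snvs)
    raw = np.zeros((N_PAIR_KEYS, L), dtype=np.int64)
    close = np.zeros((N_PAIR_KEYS, C), dtype=np.int64)
    n_snvs = 0
    for label, pos, kidx in table.per_chrom():
        n_snvs += len(pos)
        if len(pos) < 2:
            continue
        d = np.diff(pos) - 1
        if (d < 0).any():
            bad = int(np.argmax(d < 0))
            raise ValueError(
                f"chromosome {label}: positions {pos[bad]}..{pos[bad + 1]} are "
                "duplicated or unsorted; deduplicate/sort the stream first"
            )
        rows = N_SNV_KEYS * kidx[:-1].astype(np.int64) + kidx[1:]
        is_close = d < C
        np.add.at(close, (rows[is_close], d[is_close]), 1)
        far = ~is_close
        np.add.at(raw, (rows[far], d[far] % L), 1)
    meta = FingerprintMeta(
        kind="raw",
        L=L,
        C=C,
        n_snvs=n_snvs,
        n_pairs_raw=int(raw.sum()),
        n_pairs_close=int(close.sum()),
        source=source,
    )
    return RawFingerprint(meta, raw, close)


def merge_raw(parts: Sequence[RawFingerprint]) -> RawFingerprint:
    """Combine per-chromosome (or otherwise partial) raw fingerprints.

    Partial fingerprints combine by simple element-wise summation; all parts
    must share L and C.
    """
    if not parts:
        raise ValueError("merge_raw needs at least one fingerprint")
    first = parts[0]
    for p in parts[1:]:
        if p.meta.L != first.meta.L or p.meta.C != first.meta.C:
            raise ParameterMismatchError(
                f"cannot merge fingerprints with (L={p.meta.L}, C={p.meta.C}) "
                f"and (L={first.meta.L}, C={first.meta.C})"
            )
        if p.meta.kind != "raw":
            raise ValueError(f"can only merge raw fingerprints, got {p.meta.kind!r}")
    raw = np.sum([p.raw for p in parts], axis=0)
    close = np.sum([p.close for p in parts], axis=0)
    meta = FingerprintMeta(
        kind="raw",
        L=first.meta.L,
        C=first.meta.C,
        n_snvs=sum(p.meta.n_snvs for p in parts),
        n_pairs_raw=int(raw.sum()),
        n_pairs_close=int(close.sum()),
        source="+".join(p.meta.source for p in parts if p.meta.source),
    )
    return RawFingerprint(meta, raw, close)


def _zscore(a: np.ndarray, axis: int) -> np.ndarray:
    """Population z-score along an axis; zero-deviation slices become zeros."""
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)  # ddof=0
    out = a - mean
    np.divide(out, sd, out=out, where=sd > 0)
    # centered-but-degenerate slices are exactly zero already where sd == 0
    out = np.where(sd > 0, out, 0.0)
    return out


def normalize(rf: RawFingerprint) -> NormalizedFingerprint:
    """Two-pass z-scoring: by distance (columns), then by pair key (rows).

    The close matrix is not normalized and not carried into the result.
    """
    if rf.meta.kind != "raw":
        raise ValueError(f"normalize expects a raw fingerprint, got {rf.meta.kind!r}")
    values = rf.raw.astype(np.float64)
    values = _zscore(values, axis=0)  # step 1: by distance
    values = _zscore(values, axis=1)  # step 2: by SNV pair key
    meta = replace(rf.meta, kind="normalized")
    return NormalizedFingerprint(meta, values)


def binarize_from_raw(rf: RawFingerprint) -> BinaryFingerprint:
    """144-bit reduction of an L=2 raw fingerprint: bit = col1 > col0."""
    if rf.meta.L != 2:
        raise ValueError(f"binary fingerprints require L=2, got L={rf.meta.L}")
    bits = (rf.raw[:, 1] > rf.raw[:, 0]).astype(np.uint8)
    meta = replace(rf.meta, kind="binary")
    return BinaryFingerprint(meta, bits)


def binarize(
    snvs: VariantTable | Iterable[VariantRecord],
    C: int = DEFAULT_C,
    source: str = "",
) -> BinaryFingerprint:
    """Compute the 144-bit binary fingerprint of an SNV stream.

    Each bit records whether the distances for that pair key are more often
    odd than even (ties, including empty rows, give 0). No normalization is
    applied.
    """
    return binarize_from_raw(compute_raw(snvs, L=2, C=C, source=source))


def serialize(fp: NormalizedFingerprint | RawFingerprint) -> np.ndarray:
    """Row-major concatenation of the matrix rows, in canonical row order."""
    values = fp.values if isinstance(fp, NormalizedFingerprint) else fp.raw
    return np.ascontiguousarray(values, dtype=np.float64).reshape(-1)
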