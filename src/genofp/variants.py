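"""Streaming biallelic autosomal SNVs out of VCF and TSV inputs.

The fingerprint core consumes a position-sorted, chromosome-grouped stream of
biallelic SNVs and nothing else; this module hides every format dialect
behind :func:`read_snvs`. Variant selection rules:

* only records whose REF is one base and whose single ALT is one base, both
  in A/C/G/T (case-insensitive), are SNVs; everything else is skipped but
  does *not* break the consecutiveness of the flanking SNVs;
* sites that are multi-allelic in the record's ALT field are excluded;
* for the selected sample, a site counts as observed when the genotype
  carries at least one alternate allele — heterozygous and homozygous-alt
  are treated identically, missing genotypes are not observed;
* chromosome labels are normalized by stripping a leading ``chr`` prefix,
  and only labels passing the chromosome filter (autosomes 1-22 by default)
  are emitted.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .keys import BASES, SNV_KEYS, InvalidVariantError, snv_key_index

__all__ = [
    "VariantRecord",
    "ChromFilter",
    "VariantTable",
    "VariantInputError",
    "UnsortedInputError",
    "UnknownSampleError",
    "read_snvs",
    "write_tsv",
]


class VariantInputError(ValueError):
    """A variant input file cannot be parsed or violates the stream contract."""


class UnsortedInputError(VariantInputError):
    """Positions within a chromosome are not in nondecreasing order."""


class UnknownSampleError(VariantInputError):
    """The requested sample is absent from a multi-sample file."""


_BASE_SET = frozenset(BASES)


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic SNV observation.

    Attributes
    ----------
    chrom : normalized chromosome label (leading ``chr`` stripped).
    pos : 1-based reference position.
    ref, alt : single upper-case bases in A/C/G/T, ref != alt.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASE_SET or self.alt not in _BASE_SET:
            raise InvalidVariantError(
                f"alleles {self.ref!r}/{self.alt!r} must be upper-case single bases"
            )
        if self.ref == self.alt:
            raise InvalidVariantError(f"ref == alt == {self.ref!r}: not a variant")
        if self.pos < 1:
            raise InvalidVariantError(f"pos must be >= 1, got {self.pos}")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` (any case); otherwise preserve the label."""
    if label[:3].lower() == "chr":
        return label[3:]
    return label


_HUMAN_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class ChromFilter:
    """Decides which (normalized) chromosome labels are kept.

    ``include_patterns`` is a list of labels or regexes (full-match) to keep;
    ``None`` means the default human autosome set 1-22. ``exclude_patterns``
    always wins over includes, so sex/mito/alt contigs can never leak through
    an over-broad include. Non-human genomes are handled by passing an
    explicit include list.
    """

    include_patterns: Sequence[str] | None = None
    exclude_patterns: Sequence[str] = ()

    def accepts(self, label: str) -> bool:
        norm = normalize_chrom(label)
        for pat in self.exclude_patterns:
            if re.fullmatch(pat, norm):
                return False
        if self.include_patterns is None:
            return norm in _HUMAN_AUTOSOMES
        return any(re.fullmatch(pat, norm) for pat in self.include_patterns)


class VariantTable:
    """Column-oriented SNV stream: chromosome-grouped, position-sorted.

    Stores positions and SNV-key indices in flat numpy arrays with per
    chromosome slices; this is the fast path shared by the fingerprint core
    and the simulators. Equivalent to (and convertible from/to) a stream of
    :class:`VariantRecord`.
    """

    def __init__(
        self,
        chroms: Sequence[str],
        offsets: np.ndarray,
        pos: np.ndarray,
        key_idx: np.ndarray,
    ) -> None:
        self.chroms = list(chroms)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.key_idx = np.asarray(key_idx, dtype=np.int16)
        if len(self.offsets) != len(self.chroms) + 1:
            raise ValueError("offsets must have one more entry than chroms")
        if self.offsets[-1] != len(self.pos) or len(self.pos) != len(self.key_idx):
            raise ValueError("column lengths inconsistent with offsets")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def per_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (label, positions, key indices) per chromosome, in order."""
        for i, label in enumerate(self.chroms):
            s = slice(self.offsets[i], self.offsets[i + 1])
            yield label, self.pos[s], self.key_idx[s]

    def records(self) -> Iterator[VariantRecord]:
        for label, pos, kidx in self.per_chrom():
            for p, k in zip(pos.tolist(), kidx.tolist()):
                key = SNV_KEYS[k]
                yield VariantRecord(label, p, key[0], key[1])

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "VariantTable":
        """Collect a record stream, enforcing grouping and sortedness."""
        chroms: list[str] = []
        counts: list[int] = []
        pos: list[int] = []
        kidx: list[int] = []
        seen: set[str] = set()
        last_pos = 0
        for rec in records:
            if not chroms or rec.chrom != chroms[-1]:
                if rec.chrom in seen:
                    raise UnsortedInputError(
                        f"chromosome {rec.chrom!r} appears in more than one block; "
                        "stream must be grouped by chromosome"
                    )
                seen.add(rec.chrom)
                chroms.append(rec.chrom)
                counts.append(0)
                last_pos = 0
            if rec.pos < last_pos:
                raise UnsortedInputError(
                    f"chromosome {rec.chrom}: position {rec.pos} follows {last_pos}"
                )
            last_pos = rec.pos
            counts[-1] += 1
            pos.append(rec.pos)
            kidx.append(snv_key_index(rec.ref, rec.alt))
        offsets = np.concatenate([[0], np.cumsum(counts, dtype=np.int64)]) if chroms else np.zeros(1, np.int64)
        return cls(chroms, offsets, np.array(pos, np.int64), np.array(kidx, np.int16))

    @classmethod
    def coerce(cls, snvs: "VariantTable | Iterable[VariantRecord]") -> "VariantTable":
        if isinstance(snvs, cls):
            return snvs
        return cls.from_records(snvs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _open_text(path: str | PathLike) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _looks_like_vcf(path: str | PathLike) -> bool:
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz", ".bcf")):
        return True
    if name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")):
        return False
    with _open_text(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def read_snvs(
    source: str | PathLike,
    sample: str | None = None,
    chrom_filter: ChromFilter | None = None,
    pass_only: bool = False,
    stats: dict | None = None,
) -> Iterator[VariantRecord]:
    """Stream the biallelic autosomal SNVs of one sample from a VCF or TSV.

    Parameters
    ----------
    source : path to a VCF (plain or gzipped) or a 4-column whitespace TSV
        (chrom, 1-based pos, ref, alt; ``#`` comments allowed).
    sample : sample name for multi-sample VCFs. ``None`` selects the only
        sample of a single-sample file; files without genotype columns treat
        every retained site as observed.
    chrom_filter : which chromosomes to keep; default human autosomes 1-22.
    pass_only : if true, keep only VCF records whose FILTER is PASS/missing.
    stats : optional dict updated in place with counters
        (``duplicates_dropped``, ``emitted``).

    Yields position-sorted :class:`VariantRecord` grouped by chromosome.
    Raises :class:`UnsortedInputError` on unsorted input (never re-sorts),
    :class:`UnknownSampleError` for a bad sample name.
    """
    cf = chrom_filter or ChromFilter()
    if stats is None:
        stats = {}
    stats.setdefault("duplicates_dropped", 0)
    stats.setdefault("emitted", 0)

    if _looks_like_vcf(source):
        raw = _read_vcf(source, sample, cf, pass_only)
    else:
        raw = _read_tsv(source, cf)

    # grouping / sortedness / duplicate-position policy
    cur_chrom: str | None = None
    last_pos = 0
    seen: set[str] = set()
    for rec in raw:
        if rec.chrom != cur_chrom:
            if rec.chrom in seen:
                raise UnsortedInputError(
                    f"{source}: chromosome {rec.chrom!r} is not contiguous "
                    "(records for it appear in more than one block)"
                )
            seen.add(rec.chrom)
            cur_chrom = rec.chrom
            last_pos = 0
        if rec.pos < last_pos:
            raise UnsortedInputError(
                f"{source}: chromosome {rec.chrom} position {rec.pos} "
                f"follows position {last_pos}; input must be position-sorted"
            )
        if rec.pos == last_pos:
            # zero-distance pair with itself is meaningless; keep the first
            stats["duplicates_dropped"] += 1
            continue
        last_pos = rec.pos
        stats["emitted"] += 1
        yield rec


def _read_vcf(
    source: str | PathLike,
    sample: str | None,
    cf: ChromFilter,
    pass_only: bool,
) -> Iterator[VariantRecord]:
    import pysam

    try:
        vf = pysam.VariantFile(str(source))
    except (OSError, ValueError) as exc:
        raise VariantInputError(f"cannot parse {source}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample is not None:
            if sample not in samples:
                raise UnknownSampleError(
                    f"sample {sample!r} not in {source}; available: {samples}"
                )
        elif len(samples) == 1:
            sample = samples[0]
        elif len(samples) > 1:
            raise UnknownSampleError(
                f"{source} is multi-sample; choose one of {samples}"
            )
        # else: no genotype columns; every retained site counts as observed

        for rec in vf:
            if rec.ref is None or rec.alts is None or len(rec.alts) != 1:
                continue  # multi-allelic or ALT-less records are not SNVs
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref not in _BASE_SET or alt not in _BASE_SET or ref == alt:
                continue
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    continue
            if not cf.accepts(rec.chrom):
                continue
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                if gt is not None and not any(a is not None and a >= 1 for a in gt):
                    continue  # hom-ref or fully missing genotype
            yield VariantRecord(normalize_chrom(rec.chrom), rec.pos, ref, alt)


def _read_tsv(source: str | PathLike, cf: ChromFilter) -> Iterator[VariantRecord]:
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise VariantInputError(
                    f"{source}:{lineno}: expected 4 columns (chrom pos ref alt), "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VariantInputError(
                    f"{source}:{lineno}: position {pos_s!r} is not an integer"
                ) from exc
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1:
                continue
            if ref not in _BASE_SET or alt not in _BASE_SET or ref == alt:
                continue
            if not cf.accepts(chrom):
                continue
            yield VariantRecord(normalize_chrom(chrom), pos, ref, alt)


def write_tsv(records: Iterable[VariantRecord], path: str | PathLike) -> int:
    """Write a record stream as the 4-column TSV fallback format."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\n")
            n += 1
    return n
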