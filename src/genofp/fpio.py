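"""Reading and writing the fingerprint file format.

Text format (optionally gzipped, by ``.gz`` suffix):

* ``##gfp-version=1`` magic, then ``##kind=``, ``##L=``, ``##C=``,
  ``##snvs=``, ``##pairs-raw=``, ``##pairs-close=``, ``##source=`` headers
  (population fingerprints add ``##members=``);
* 144 data rows ``PAIRKEY<TAB>v0<TAB>...<TAB>v(L-1)`` in canonical row
  order; raw fingerprints append a ``##close`` section of 144 x C rows;
  binary fingerprints carry a single 144-character 0/1 line instead.

Values round-trip at full precision (counts as integers, real values via
``repr``). The distance and standard-deviation conventions are recorded so
fingerprints remain comparable across implementations.
"""

from __future__ import annotations

import gzip
from os import PathLike
from typing import Union

import numpy as np

from .fingerprint import (
    BinaryFingerprint,
    FingerprintMeta,
    NormalizedFingerprint,
    RawFingerprint,
)
from .keys import N_PAIR_KEYS, PAIR_KEYS

__all__ = ["write_fingerprint", "read_fingerprint", "FingerprintFormatError"]

FORMAT_VERSION = "1"

Fingerprint = Union[RawFingerprint, NormalizedFingerprint, BinaryFingerprint]


class FingerprintFormatError(ValueError):
    """A fingerprint file is malformed, truncated, or of the wrong kind."""


def _open(path: str | PathLike, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode + "t")


def _fmt(v: float | int, integer: bool) -> str:
    return str(int(v)) if integer else repr(float(v))


def write_fingerprint(fp: Fingerprint, path: str | PathLike, members: list[str] | None = None) -> None:
    """Write any fingerprint kind losslessly; see module docstring for layout."""
    meta = fp.meta
    with _open(path, "w") as fh:
        fh.write(f"##gfp-version={FORMAT_VERSION}\n")
        fh.write(f"##kind={meta.kind}\n")
        fh.write(f"##L={meta.L}\n")
        fh.write(f"##C={meta.C}\n")
        fh.write(f"##snvs={meta.n_snvs}\n")
        fh.write(f"##pairs-raw={meta.n_pairs_raw}\n")
        fh.write(f"##pairs-close={meta.n_pairs_close}\n")
        fh.write(f"##source={meta.source}\n")
        fh.write("##distance-convention=intervening-bases\n")
        fh.write("##sd-convention=population\n")
        if members is not None:
            fh.write("##members=" + ",".join(members) + "\n")
        if isinstance(fp, BinaryFingerprint):
            fh.write(fp.to01() + "\n")
            return
        integer = isinstance(fp, RawFingerprint)
        matrix = fp.raw if integer else fp.values
        for r, key in enumerate(PAIR_KEYS):
            vals = "\t".join(_fmt(v, integer) for v in matrix[r])
            fh.write(f"{key}\t{vals}\n" if meta.L else f"{key}\n")
        if integer:
            fh.write("##close\n")
            for r, key in enumerate(PAIR_KEYS):
                vals = "\t".join(str(int(v)) for v in fp.close[r])
                fh.write(f"{key}\t{vals}\n" if meta.C else f"{key}\n")


def _read_matrix(lines: list[str], start: int, ncols: int, dtype, path) -> tuple[np.ndarray, int]:
    matrix = np.zeros((N_PAIR_KEYS, ncols), dtype=dtype)
    for r in range(N_PAIR_KEYS):
        if start + r >= len(lines):
            raise FingerprintFormatError(f"{path}: truncated at data row {r}")
        fields = lines[start + r].rstrip("\n").split("\t")
        if fields[0] != PAIR_KEYS[r]:
            raise FingerprintFormatError(
                f"{path}: row {r} labelled {fields[0]!r}, expected {PAIR_KEYS[r]!r} "
                "(canonical order required)"
            )
        if len(fields) - 1 != ncols:
            raise FingerprintFormatError(
                f"{path}: row {fields[0]} has {len(fields) - 1} values, expected {ncols}"
            )
        matrix[r] = [dtype(v) for v in fields[1:]]
    return matrix, start + N_PAIR_KEYS


def read_fingerprint(path: str | PathLike, expect_kind: str | None = None) -> Fingerprint:
    """Read a fingerprint file; optionally enforce its kind.

    Population fingerprints are returned as :class:`NormalizedFingerprint`
    (kind ``population``); their member list is available via
    :func:`read_members`.
    """
    fp, _ = _read(path, expect_kind)
    return fp


def read_members(path: str | PathLike) -> list[str]:
    """Member identifiers recorded in a population fingerprint file."""
    _, members = _read(path, None)
    if members is None:
        raise FingerprintFormatError(f"{path}: no ##members header")
    return members


def _read(path: str | PathLike, expect_kind: str | None):
    with _open(path, "r") as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("##gfp-version="):
        raise FingerprintFormatError(f"{path}: not a fingerprint file (missing magic)")
    version = lines[0].strip().split("=", 1)[1]
    if version != FORMAT_VERSION:
        raise FingerprintFormatError(
            f"{path}: format version {version!r} unsupported (expected {FORMAT_VERSION})"
        )
    headers: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("##"):
        body = lines[i][2:].rstrip("\n")
        if "=" not in body:
            break  # section marker such as ##close
        k, v = body.split("=", 1)
        headers[k] = v
        i += 1
    try:
        kind = headers["kind"]
        L = int(headers["L"])
        C = int(headers["C"])
    except KeyError as exc:
        raise FingerprintFormatError(f"{path}: missing header {exc}") from exc
    if expect_kind is not None and kind != expect_kind:
        raise FingerprintFormatError(
            f"{path}: kind is {kind!r}, but {expect_kind!r} is required here"
        )
    meta = FingerprintMeta(
        kind=kind,
        L=L,
        C=C,
        n_snvs=int(headers.get("snvs", 0)),
        n_pairs_raw=int(headers.get("pairs-raw", 0)),
        n_pairs_close=int(headers.get("pairs-close", 0)),
        source=headers.get("source", ""),
    )
    members = headers.get("members")
    members_list = members.split(",") if members else None

    if kind == "binary":
        if i >= len(lines):
            raise FingerprintFormatError(f"{path}: truncated binary fingerprint")
        bitstr = lines[i].strip()
        if len(bitstr) != N_PAIR_KEYS or set(bitstr) - {"0", "1"}:
            raise FingerprintFormatError(
                f"{path}: binary payload must be a 144-character 0/1 string"
            )
        bits = np.frombuffer(bitstr.encode(), dtype=np.uint8) - ord("0")
        return BinaryFingerprint(meta, bits), members_list

    if kind == "raw":
        raw, i = _read_matrix(lines, i, L, np.int64, path)
        if i >= len(lines) or lines[i].strip() != "##close":
            raise FingerprintFormatError(f"{path}: raw fingerprint missing ##close section")
        close, _ = _read_matrix(lines, i + 1, C, np.int64, path)
        return RawFingerprint(meta, raw, close), members_list

    if kind in ("normalized", "population", "adjusted"):
        values, _ = _read_matrix(lines, i, L, np.float64, path)
        return NormalizedFingerprint(meta, values), members_list

    raise FingerprintFormatError(f"{path}: unknown fingerprint kind {kind!r}")
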