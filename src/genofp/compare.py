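"""Pairwise and cohort-scale fingerprint comparison.

Real-valued fingerprints (normalized, population, population-adjusted) are
compared by serializing each 144 x L matrix row-major and computing the
Spearman correlation of the two vectors; identical genomes give 1.0 and the
score degrades gracefully with missing data, noise and decreasing
relatedness. Binary fingerprints are compared by the squared fraction of
matching bits, (matches/144)^2.

The all-against-all path ranks every serialized vector once and computes
the correlation matrix as a single BLAS product of row-standardized rank
matrices; this is what makes millions of comparisons take seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprint import (
    BinaryFingerprint,
    NormalizedFingerprint,
    ParameterMismatchError,
    serialize,
)
from .keys import N_PAIR_KEYS

__all__ = [
    "ComparisonResult",
    "spearman_compare",
    "binary_compare",
    "all_pairs",
    "pairwise_matrix",
    "best_matches",
]

_REAL_KINDS = ("normalized", "population", "adjusted")


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison; ``score`` is symmetric in (id_a, id_b)."""

    id_a: str
    id_b: str
    score: float
    n_features: int
    warning: str | None = None


def _check_real(fp: NormalizedFingerprint, what: str) -> None:
    if not isinstance(fp, NormalizedFingerprint) or fp.meta.kind not in _REAL_KINDS:
        kind = getattr(getattr(fp, "meta", None), "kind", type(fp).__name__)
        raise ValueError(
            f"{what} must be a normalized/population/adjusted fingerprint, got {kind!r}"
        )


def spearman_compare(
    a: NormalizedFingerprint,
    b: NormalizedFingerprint,
    id_a: str = "a",
    id_b: str = "b",
) -> ComparisonResult:
    """Spearman correlation of two row-serialized fingerprints.

    Requires equal L (C may differ: it only affects metadata, not the
    compared values). Ties receive average ranks. A zero-variance vector
    (e.g. from an empty genome) yields score 0.0 with a warning flag rather
    than NaN.
    """
    _check_real(a, "a")
    _check_real(b, "b")
    if a.meta.L != b.meta.L:
        raise ParameterMismatchError(
            f"cannot compare fingerprints with L={a.meta.L} and L={b.meta.L}"
        )
    va, vb = serialize(a), serialize(b)
    if va.std() == 0 or vb.std() == 0:
        return ComparisonResult(id_a, id_b, 0.0, va.size, warning="zero-variance vector")
    rho = stats.spearmanr(va, vb).statistic
    return ComparisonResult(id_a, id_b, float(rho), va.size)


def binary_compare(
    a: BinaryFingerprint,
    b: BinaryFingerprint,
    id_a: str = "a",
    id_b: str = "b",
) -> ComparisonResult:
    """Squared matching-bit fraction: (identical bits / 144)^2."""
    matches = int(np.sum(a.bits == b.bits))
    return ComparisonResult(id_a, id_b, (matches / N_PAIR_KEYS) ** 2, N_PAIR_KEYS)


def _as_items(fps) -> list[tuple[str, object]]:
    if isinstance(fps, Mapping):
        items = list(fps.items())
    else:
        items = list(fps)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate fingerprint identifiers: {dupes}")
    return sorted(items, key=lambda kv: kv[0])


def _score_matrix(items: list[tuple[str, object]]) -> tuple[np.ndarray, int]:
    """Full symmetric score matrix over sorted items (Spearman or binary)."""
    fps = [fp for _, fp in items]
    if all(isinstance(fp, BinaryFingerprint) for fp in fps):
        B = np.stack([fp.bits for fp in fps]).astype(np.float64)
        matches = B @ B.T + (1 - B) @ (1 - B).T
        return (matches / N_PAIR_KEYS) ** 2, N_PAIR_KEYS
    for _, fp in items:
        _check_real(fp, "every fingerprint")
    Ls = {fp.meta.L for fp in fps}
    if len(Ls) > 1:
        raise ParameterMismatchError(f"mixed fingerprint lengths: {sorted(Ls)}")
    X = np.stack([serialize(fp) for fp in fps])
    m = X.shape[1]
    R = stats.rankdata(X, axis=1).astype(np.float64)
    R -= R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance fingerprint(s); their "
            "correlations are reported as 0.0"
        )
    np.divide(R, sd, out=R, where=sd > 0)
    R[degenerate] = 0.0
    scores = (R @ R.T) / m
    return scores, m


def all_pairs(
    fps: Mapping[str, object] | Iterable[tuple[str, object]],
) -> pd.DataFrame:
    """All-against-all comparison; one row per unordered pair.

    Returns a DataFrame (id_a, id_b, score, n_features) with n*(n-1)/2 rows
    in deterministic order: identifiers sorted, id_a < id_b. Identifiers
    must be unique. All fingerprints must share L and belong to one
    comparable kind family (real-valued, or all binary).
    """
    items = _as_items(fps)
    n = len(items)
    if n < 2:
        return pd.DataFrame(columns=["id_a", "id_b", "score", "n_features"])
    scores, m = _score_matrix(items)
    ids = np.array([i for i, _ in items])
    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "id_a": ids[iu],
            "id_b": ids[ju],
            "score": scores[iu, ju],
            "n_features": m,
        }
    )


def pairwise_matrix(
    fps: Mapping[str, object] | Iterable[tuple[str, object]],
    max_n: int = 2000,
) -> pd.DataFrame:
    """Square score matrix for small cohorts (guarded by ``max_n``)."""
    items = _as_items(fps)
    if len(items) > max_n:
        raise ValueError(
            f"{len(items)} fingerprints exceed the square-matrix limit {max_n}; "
            "use all_pairs"
        )
    if not items:
        return pd.DataFrame()
    scores, _ = _score_matrix(items)
    np.fill_diagonal(scores, 1.0)
    ids = [i for i, _ in items]
    return pd.DataFrame(scores, index=ids, columns=ids)


def best_matches(
    query: object,
    candidates: Mapping[str, object] | Iterable[tuple[str, object]],
    k: int = 10,
    query_id: str = "query",
) -> list[ComparisonResult]:
    """Top-k candidates by score, descending; ties broken by identifier."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items = _as_items(candidates)
    if isinstance(query, BinaryFingerprint):
        results = [binary_compare(query, fp, query_id, cid) for cid, fp in items]
    else:
        results = [spearman_compare(query, fp, query_id, cid) for cid, fp in items]
    results.sort(key=lambda r: (-r.score, r.id_b))
    return results[:k]
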