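"""Population fingerprints, adjustment, classification, relatedness outliers.

A population fingerprint is the element-wise mean of the normalized
fingerprints of its members; subtracting it from a member's normalized
fingerprint yields a *population-adjusted* fingerprint in which the shared
population signal is removed, so unrelated individuals decorrelate and
genuinely related pairs stand out.

Unexpectedly related pairs are flagged from the distribution of pairwise
adjusted-fingerprint correlations with a robust z-score, 0.6745 * (score -
median) / MAD, a one-sided normal tail p-value, and Benjamini-Hochberg
control of the false discovery rate (5% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .compare import spearman_compare
from .fingerprint import (
    FingerprintMeta,
    NormalizedFingerprint,
    ParameterMismatchError,
)

__all__ = [
    "PopulationFingerprint",
    "OutlierCall",
    "build_population",
    "adjust_to_population",
    "classify",
    "find_related_outliers",
]

#: Consistency constant making MAD estimate the SD of a normal distribution.
MAD_CONSISTENCY = 0.6745


@dataclass
class PopulationFingerprint(NormalizedFingerprint):
    """Mean of member normalized fingerprints, with the member IDs kept.

    Keeping members allows exact leave-one-out recomputation as
    (n * mean - x) / (n - 1) without re-reading member files.
    """

    members: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.members is None:
            self.members = []


@dataclass(frozen=True)
class OutlierCall:
    """One flagged (or evaluated) pair from the relatedness screen."""

    id_a: str
    id_b: str
    score: float
    robust_z: float
    p: float
    q: float
    flagged: bool


def _check_params(fps: Iterable[NormalizedFingerprint]) -> tuple[int, int]:
    fps = list(fps)
    Ls = {fp.meta.L for fp in fps}
    Cs = {fp.meta.C for fp in fps}
    if len(Ls) > 1 or len(Cs) > 1:
        raise ParameterMismatchError(
            f"fingerprints disagree on parameters: L={sorted(Ls)}, C={sorted(Cs)}"
        )
    return Ls.pop(), Cs.pop()


def build_population(
    fps: Mapping[str, NormalizedFingerprint] | Iterable[tuple[str, NormalizedFingerprint]],
    name: str = "",
) -> PopulationFingerprint:
    """Average the normalized fingerprints of a nonempty member set."""
    items = list(fps.items()) if isinstance(fps, Mapping) else list(fps)
    if not items:
        raise ValueError("cannot build a population fingerprint from zero members")
    L, C = _check_params(fp for _, fp in items)
    for _, fp in items:
        if fp.meta.kind != "normalized":
            raise ValueError(
                f"population members must be normalized fingerprints, got {fp.meta.kind!r}"
            )
    values = np.mean([fp.values for _, fp in items], axis=0)
    meta = FingerprintMeta(kind="population", L=L, C=C, source=name)
    return PopulationFingerprint(meta, values, members=[i for i, _ in items])


def adjust_to_population(
    ind: NormalizedFingerprint, pop: PopulationFingerprint
) -> NormalizedFingerprint:
    """Subtract a population fingerprint from an individual's."""
    if ind.meta.L != pop.meta.L or ind.meta.C != pop.meta.C:
        raise ParameterMismatchError(
            f"individual (L={ind.meta.L}, C={ind.meta.C}) and population "
            f"(L={pop.meta.L}, C={pop.meta.C}) parameters differ"
        )
    meta = replace(
        ind.meta,
        kind="adjusted",
        source=f"{ind.meta.source}|adjusted:{pop.meta.source}",
    )
    return NormalizedFingerprint(meta, ind.values - pop.values)


def _loo_values(pop: PopulationFingerprint, ind: NormalizedFingerprint) -> np.ndarray | None:
    """Population mean without ``ind``; None if the member is the whole pop."""
    n = len(pop.members)
    if n == 1:
        return None
    return (n * pop.values - ind.values) / (n - 1)


def classify(
    ind: NormalizedFingerprint,
    pops: Mapping[str, PopulationFingerprint] | Iterable[tuple[str, PopulationFingerprint]],
    ind_id: str | None = None,
    leave_one_out: bool = False,
) -> list[tuple[str, float]]:
    """Rank candidate populations by Spearman correlation, best first.

    With ``leave_one_out``, a population of which ``ind_id`` is a member is
    re-averaged without it before comparison; a single-member population is
    skipped with a warning in that case. Ties break by population name.
    """
    items = list(pops.items()) if isinstance(pops, Mapping) else list(pops)
    if not items:
        raise ValueError("no candidate populations")
    ranked: list[tuple[str, float]] = []
    for name, pop in sorted(items, key=lambda kv: kv[0]):
        values = pop.values
        if leave_one_out and ind_id is not None and ind_id in pop.members:
            loo = _loo_values(pop, ind)
            if loo is None:
                warnings.warn(
                    f"population {name!r} has {ind_id!r} as its only member; "
                    "skipped under leave-one-out"
                )
                continue
            values = loo
        pop_fp = NormalizedFingerprint(replace(pop.meta, kind="population"), values)
        res = spearman_compare(ind, pop_fp, ind_id or "query", name)
        ranked.append((name, res.score))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def find_related_outliers(pairs: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Flag unexpectedly high pairwise correlations at a given FDR.

    ``pairs`` needs columns id_a, id_b, score (e.g. from
    :func:`genofp.compare.all_pairs` over population-adjusted fingerprints).
    Robust z-scores are taken against the median/MAD of all supplied scores,
    upper-tail normal p-values are Benjamini-Hochberg corrected, and pairs
    with q <= fdr are flagged. Returns the full table sorted by score
    descending, with robust_z, p, q and flagged columns added.
    """
    if not 0 < fdr <= 0.5:
        raise ValueError(f"fdr must be in (0, 0.5], got {fdr}")
    if len(pairs) < 10:
        raise ValueError(f"need at least 10 pairs, got {len(pairs)}")
    scores = pairs["score"].to_numpy(dtype=np.float64)
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    if mad == 0:
        raise ValueError(
            "MAD of pair scores is zero (degenerate score distribution); "
            "inspect the input before outlier calling"
        )
    z = MAD_CONSISTENCY * (scores - med) / mad
    p = stats.norm.sf(z)
    q = stats.false_discovery_control(p, method="bh")
    out = pairs.copy()
    out["robust_z"] = z
    out["p"] = p
    out["q"] = q
    out["flagged"] = q <= fdr
    return out.sort_values("score", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
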