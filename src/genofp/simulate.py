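"""Synthetic cohorts, pedigrees, and genome degradation.

The generator emulates the features of real variant data that the
fingerprint statistics depend on, and nothing more:

* a shared population pool of SNV loci with allele frequencies, so that
  individuals drawn from one population overlap in the variants they carry;
* per-locus SNV keys with a transition:transversion bias (2:1 by default);
* inter-locus spacing whose (distance mod L) profile depends on the flanking
  key pair: each gap is ``L_ref*G + r + 1`` with ``G`` geometric and ``r``
  drawn from a categorical that concentrates ``spacing_peak_weight`` of its
  mass on a key-pair-determined pair of adjacent columns. Purely uniform
  spacing would leave only sampling noise in normalized fingerprints; this
  injected structure is what gives synthetic fingerprints genuine,
  individually-varying signal. The peak straddles two adjacent columns (one
  odd, one even) so that distance *parity* stays unbiased: real inter-SNV
  distances carry no systematic parity signal, which is why the 144-bit
  binary fingerprint is far less informative — and less robust — than the
  full matrix;
* Mendelian inheritance with recombination for pedigrees;
* the two degradation modes used to probe robustness: random variant
  dropout (false negatives) and spurious intervening variants (false
  positives).

Everything is bit-reproducible given (model, spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .compare import binary_compare, spearman_compare
from .fingerprint import (
    DEFAULT_C,
    DEFAULT_L,
    binarize,
    compute_raw,
    normalize,
)
from .keys import N_SNV_KEYS, SNV_KEYS, TRANSITION_KEYS
from .variants import VariantTable

__all__ = [
    "CohortModel",
    "SimulatedGenome",
    "PedigreeSpec",
    "simulate_cohort",
    "simulate_pedigree",
    "degrade_missing",
    "degrade_noise",
    "robustness_curve",
    "max_tolerated_level",
    "write_cohort_vcf",
    "DEFAULT_DEGRADATION_LEVELS",
]

#: Standard degradation grid for full robustness curves (1%..99%).
DEFAULT_DEGRADATION_LEVELS = (
    0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35,
    0.40, 0.45, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 0.99,
)

#: Per-key sampling weights with a 2:1 transition:transversion bias.
def _key_probs(tstv_ratio: float) -> np.ndarray:
    w = np.array(
        [tstv_ratio / 4 if k in TRANSITION_KEYS else 1 / 8 for k in SNV_KEYS]
    )
    return w / w.sum()


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _peak_column(rows: np.ndarray, l_ref: int) -> np.ndarray:
    """Deterministic key-pair -> preferred (d mod L) column map.

    The peak occupies the adjacent column pair {c, c+1}; the caller adds a
    fair parity coin so the two parities are equally likely within the peak.
    """
    return (7 * rows + 3) % l_ref


@dataclass
class CohortModel:
    """A synthetic population pool: loci, keys, frequencies, spacing model.

    Create one with :meth:`create`; the defaults are the pinned study
    conditions used throughout (22 autosomes, 200,000 loci, mean gap
    1,000 bp, spacing peak weight 0.5, ts:tv 2:1).
    """

    chrom_labels: list[str]
    chrom_lengths: np.ndarray
    offsets: np.ndarray  # (n_chroms + 1,) boundaries into the flat locus arrays
    loci_pos: np.ndarray  # (n_loci,) int64, strictly increasing per chromosome
    loci_key: np.ndarray  # (n_loci,) int16 in 0..11
    loci_freq: np.ndarray  # (n_loci,) float64 in (0, 1)
    spacing_peak_weight: float
    l_ref: int
    tstv_ratio: float
    mean_gap: float
    seed: int

    @property
    def n_loci(self) -> int:
        return len(self.loci_pos)

    @classmethod
    def create(
        cls,
        n_chroms: int = 22,
        n_loci: int = 200_000,
        chrom_length: int = 30_000_000,
        mean_gap: float = 1_000.0,
        spacing_peak_weight: float = 0.5,
        l_ref: int = DEFAULT_L,
        tstv_ratio: float = 2.0,
        freq_range: tuple[float, float] = (0.05, 0.95),
        seed: int = 0,
    ) -> "CohortModel":
        """Generate the locus pool by a sequential walk along each chromosome."""
        if not 0 <= spacing_peak_weight <= 1:
            raise ValueError("spacing_peak_weight must be in [0, 1]")
        rng = np.random.default_rng([seed, 0])
        key_probs = _key_probs(tstv_ratio)
        # geometric p chosen so the mean gap hits the requested value
        p_geom = l_ref / max(mean_gap - 1 - (l_ref - 1) / 2, l_ref)
        p_geom = min(p_geom, 1.0)

        per_chrom = np.full(n_chroms, n_loci // n_chroms, dtype=np.int64)
        per_chrom[: n_loci % n_chroms] += 1

        labels = [str(i + 1) for i in range(n_chroms)]
        pos_parts, key_parts = [], []
        for n_c in per_chrom:
            keys = rng.choice(N_SNV_KEYS, size=n_c, p=key_probs).astype(np.int16)
            rows = N_SNV_KEYS * keys[:-1].astype(np.int64) + keys[1:]
            peaks = _peak_column(rows, l_ref)
            on_peak = rng.random(n_c - 1) < spacing_peak_weight
            parity = rng.integers(0, 2, size=n_c - 1)
            r = np.where(
                on_peak, (peaks + parity) % l_ref, rng.integers(0, l_ref, size=n_c - 1)
            )
            g = rng.geometric(p_geom, size=n_c - 1)
            gaps = l_ref * g + r + 1
            start = 1 + rng.integers(0, int(2 * mean_gap))
            pos = start + np.concatenate([[0], np.cumsum(gaps)])
            if pos[-1] > chrom_length:
                raise ValueError(
                    f"chromosome length {chrom_length} too short for {n_c} loci "
                    f"at mean gap {mean_gap}"
                )
            pos_parts.append(pos)
            key_parts.append(keys)
        offsets = np.concatenate([[0], np.cumsum(per_chrom)])
        freq = rng.uniform(*freq_range, size=n_loci)
        return cls(
            chrom_labels=labels,
            chrom_lengths=np.full(n_chroms, chrom_length, dtype=np.int64),
            offsets=offsets.astype(np.int64),
            loci_pos=np.concatenate(pos_parts),
            loci_key=np.concatenate(key_parts),
            loci_freq=freq,
            spacing_peak_weight=spacing_peak_weight,
            l_ref=l_ref,
            tstv_ratio=tstv_ratio,
            mean_gap=mean_gap,
            seed=seed,
        )

    def variant_table(self, mask: np.ndarray) -> VariantTable:
        """SNV stream of the loci selected by a boolean mask."""
        idx = np.flatnonzero(mask)
        new_offsets = np.searchsorted(idx, self.offsets)
        return VariantTable(
            self.chrom_labels, new_offsets, self.loci_pos[idx], self.loci_key[idx]
        )


@dataclass
class SimulatedGenome:
    """One simulated individual: genotypes (0/1/2) over the model's loci."""

    id: str
    model: CohortModel
    genotypes: np.ndarray  # (n_loci,) uint8
    haplotypes: np.ndarray | None = None  # (2, n_loci) uint8, pedigree members
    population: str = "pop0"

    def variant_table(self) -> VariantTable:
        """Observed variants: every locus carrying >= 1 alternate allele."""
        return self.model.variant_table(self.genotypes >= 1)

    def to_tsv(self, path) -> int:
        from .variants import write_tsv

        return write_tsv(self.variant_table().records(), path)

    def to_vcf(self, path) -> None:
        write_cohort_vcf([self], path)


@dataclass
class PedigreeSpec:
    """Founders plus matings; children may themselves be parents later.

    ``matings`` entries are (parent_a, parent_b, n_children); founders are
    named F1..Fk and children C1, C2, ... in order of creation.
    """

    founders: int
    matings: Sequence[tuple[str, str, int]] = ()
    recomb_rate: float = 1.0  # expected crossovers per chromosome per meiosis


def _population_freqs(
    model: CohortModel, n_populations: int, divergence: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies: logit-normal shift, SD=divergence."""
    f = model.loci_freq
    if divergence == 0:
        return np.tile(f, (n_populations, 1))
    shifts = rng.normal(0.0, divergence, size=(n_populations, model.n_loci))
    return expit(logit(f) + shifts)


def simulate_cohort(
    model: CohortModel,
    n_individuals: int,
    n_populations: int = 1,
    divergence: float = 0.0,
    seed: int | None = None,
) -> tuple[list[SimulatedGenome], list[str]]:
    """Sample individuals from one or more diverged populations.

    Population allele frequencies are the pool frequencies shifted on the
    logit scale by N(0, divergence) noise; genotypes are Hardy-Weinberg
    draws Binomial(2, f). Individuals are assigned to populations
    round-robin. Returns (genomes, population labels).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = _rng([model.seed, 1] if seed is None else seed)
    pop_freqs = _population_freqs(model, n_populations, divergence, rng)
    genomes, labels = [], []
    for i in range(n_individuals):
        p = i % n_populations
        g = rng.binomial(2, pop_freqs[p]).astype(np.uint8)
        label = f"pop{p}"
        genomes.append(SimulatedGenome(f"ind{i}", model, g, population=label))
        labels.append(label)
    return genomes, labels


def _gamete(
    model: CohortModel,
    haplotypes: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine one parent's haplotype pair into a transmitted gamete."""
    out = np.empty(model.n_loci, dtype=np.uint8)
    for c in range(len(model.chrom_labels)):
        s = slice(model.offsets[c], model.offsets[c + 1])
        pos = model.loci_pos[s]
        k = rng.poisson(recomb_rate)
        cuts = np.sort(rng.uniform(1, model.chrom_lengths[c], size=k))
        start = rng.integers(2)
        pick = (start + np.searchsorted(cuts, pos)) % 2
        out[s] = np.where(pick == 0, haplotypes[0, s], haplotypes[1, s])
    return out


def simulate_pedigree(
    model: CohortModel,
    spec: PedigreeSpec,
    seed: int | None = None,
) -> dict[str, SimulatedGenome]:
    """Simulate all members of a pedigree, founders plus descendants.

    Founder haplotypes are independent Bernoulli(f) draws from the pool
    frequencies; each child receives one recombined gamete from each parent
    (crossover count Poisson(recomb_rate) per chromosome, breakpoints
    uniform).
    """
    if spec.founders < 1:
        raise ValueError("a pedigree needs at least one founder")
    rng = _rng([model.seed, 2] if seed is None else seed)
    members: dict[str, SimulatedGenome] = {}

    def add(name: str, haps: np.ndarray) -> None:
        members[name] = SimulatedGenome(
            name, model, (haps[0] + haps[1]).astype(np.uint8), haplotypes=haps
        )

    for i in range(spec.founders):
        haps = (rng.random((2, model.n_loci)) < model.loci_freq).astype(np.uint8)
        add(f"F{i + 1}", haps)

    child_n = 0
    for pa, pb, n_children in spec.matings:
        if pa == pb:
            raise ValueError(f"child of a single parent: {pa!r} mated with itself")
        for parent in (pa, pb):
            if parent not in members:
                raise ValueError(f"unknown parent {parent!r}; define founders/children first")
        for _ in range(n_children):
            child_n += 1
            haps = np.stack(
                [
                    _gamete(model, members[pa].haplotypes, spec.recomb_rate, rng),
                    _gamete(model, members[pb].haplotypes, spec.recomb_rate, rng),
                ]
            )
            add(f"C{child_n}", haps)
    return members


def _as_table(g) -> VariantTable:
    if isinstance(g, SimulatedGenome):
        return g.variant_table()
    return VariantTable.coerce(g)


def degrade_missing(g, fraction: float, seed=0) -> VariantTable:
    """Drop each variant independently with the given probability."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    table = _as_table(g)
    rng = _rng(seed)
    keep = rng.random(len(table)) >= fraction
    idx = np.flatnonzero(keep)
    offsets = np.searchsorted(idx, table.offsets)
    return VariantTable(table.chroms, offsets, table.pos[idx], table.key_idx[idx])


def degrade_noise(g, probability: float, seed=0) -> VariantTable:
    """Insert spurious intervening variants between consecutive pairs.

    Each within-chromosome consecutive pair with at least one free
    intervening position receives, with the given probability, one spurious
    SNV at a uniform intervening position with a uniform SNV key. Output
    stays sorted; pairs at adjacent positions can never receive insertions.
    """
    if not 0 <= probability <= 1:
        raise ValueError("probability must be in [0, 1]")
    table = _as_table(g)
    rng = _rng(seed)
    chroms, counts, pos_parts, key_parts = [], [], [], []
    for label, pos, kidx in table.per_chrom():
        if len(pos) >= 2:
            gapsize = np.diff(pos)
            eligible = gapsize >= 2
            insert = eligible & (rng.random(len(gapsize)) < probability)
            if insert.any():
                lo = pos[:-1][insert] + 1
                hi = pos[1:][insert]  # exclusive
                new_pos = rng.integers(lo, hi)
                new_keys = rng.integers(0, N_SNV_KEYS, size=len(new_pos)).astype(np.int16)
                pos_c = np.concatenate([pos, new_pos])
                key_c = np.concatenate([kidx, new_keys])
                order = np.argsort(pos_c, kind="stable")
                pos_c, key_c = pos_c[order], key_c[order]
            else:
                pos_c, key_c = pos, kidx
        else:
            pos_c, key_c = pos, kidx
        chroms.append(label)
        counts.append(len(pos_c))
        pos_parts.append(pos_c)
        key_parts.append(key_c)
    offsets = np.concatenate([[0], np.cumsum(counts, dtype=np.int64)])
    return VariantTable(
        chroms,
        offsets,
        np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64),
        np.concatenate(key_parts) if key_parts else np.empty(0, np.int16),
    )


_DEGRADERS = {"missing": degrade_missing, "noise": degrade_noise}


def robustness_curve(
    g,
    mode: str,
    levels: Sequence[float] = DEFAULT_DEGRADATION_LEVELS,
    L: int = DEFAULT_L,
    C: int = DEFAULT_C,
    seed: int = 0,
    binary: bool = False,
) -> pd.DataFrame:
    """Degrade, re-fingerprint, and compare to the undegraded fingerprint.

    Returns a DataFrame (level, correlation) over the requested degradation
    levels. With ``binary=True`` the score is the squared matching-bit
    fraction of 144-bit fingerprints; otherwise the Spearman correlation of
    L-column normalized fingerprints.
    """
    if mode not in _DEGRADERS:
        raise ValueError(f"mode must be 'missing' or 'noise', got {mode!r}")
    table = _as_table(g)
    if binary:
        clean = binarize(table, C=C)
    else:
        clean = normalize(compute_raw(table, L=L, C=C))
    rows = []
    for i, level in enumerate(levels):
        degraded = _DEGRADERS[mode](table, level, seed=np.random.default_rng([seed, i]))
        if binary:
            score = binary_compare(clean, binarize(degraded, C=C)).score
        else:
            score = spearman_compare(
                clean, normalize(compute_raw(degraded, L=L, C=C))
            ).score
        rows.append((level, score))
    return pd.DataFrame(rows, columns=["level", "correlation"])


def max_tolerated_level(
    g,
    mode: str,
    levels: Sequence[float],
    seeds: Sequence[int],
    threshold: float = 0.75,
    L: int = DEFAULT_L,
    C: int = DEFAULT_C,
    binary: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Largest degradation level whose seed-averaged score stays >= threshold.

    Returns (level, table of per-level mean scores); the level is 0.0 when
    even the smallest level drops below the threshold.
    """
    curves = [
        robustness_curve(g, mode, levels=levels, L=L, C=C, seed=s, binary=binary)
        for s in seeds
    ]
    mean = np.mean([c["correlation"].to_numpy() for c in curves], axis=0)
    table = pd.DataFrame({"level": list(levels), "mean_correlation": mean})
    ok = table[table["mean_correlation"] >= threshold]
    best = float(ok["level"].max()) if len(ok) else 0.0
    return best, table


def write_cohort_vcf(genomes: Sequence[SimulatedGenome], path) -> None:
    """Write simulated genomes as one (single- or multi-sample) VCF.

    All genomes must share a model; sites where no sample carries an
    alternate allele are omitted, genotypes are unphased GT values.
    """
    import gzip

    if not genomes:
        raise ValueError("no genomes to write")
    model = genomes[0].model
    for g in genomes[1:]:
        if g.model is not model:
            raise ValueError("all genomes must come from the same cohort model")
    G = np.stack([g.genotypes for g in genomes])  # (n_samples, n_loci)
    keep = (G >= 1).any(axis=0)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for label, length in zip(model.chrom_labels, model.chrom_lengths):
            fh.write(f"##contig=<ID={label},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.id for g in genomes)
            + "\n"
        )
        for c, label in enumerate(model.chrom_labels):
            for j in range(model.offsets[c], model.offsets[c + 1]):
                if not keep[j]:
                    continue
                key = SNV_KEYS[model.loci_key[j]]
                gts = "\t".join(gt_str[int(G[s, j])] for s in range(len(genomes)))
                fh.write(
                    f"{label}\t{int(model.loci_pos[j])}\t.\t{key[0]}\t{key[1]}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )
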