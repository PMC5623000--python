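"""SNV keys and SNV-pair keys.

A biallelic SNV is classified by its *SNV key*: the reference base followed
by the alternate base, giving 12 admissible two-letter codes. Two consecutive
SNVs on a chromosome are classified by their *pair key*, the concatenation of
the two SNV keys, giving 144 admissible four-letter codes. The pair key is
the row index of every fingerprint matrix; its order is fixed (lexicographic)
so that fingerprints are comparable across runs and implementations.
"""

from __future__ import annotations

from itertools import product

BASES = ("A", "C", "G", "T")

#: The 12 SNV keys in canonical (lexicographic) order.
SNV_KEYS: tuple[str, ...] = tuple(
    r + a for r, a in product(BASES, BASES) if r != a
)

#: The 144 SNV pair keys in canonical order: row = 12*index(first) + index(second).
PAIR_KEYS: tuple[str, ...] = tuple(a + b for a, b in product(SNV_KEYS, SNV_KEYS))

SNV_KEY_INDEX: dict[str, int] = {k: i for i, k in enumerate(SNV_KEYS)}
PAIR_KEY_INDEX: dict[str, int] = {k: i for i, k in enumerate(PAIR_KEYS)}

N_SNV_KEYS = len(SNV_KEYS)  # 12
N_PAIR_KEYS = len(PAIR_KEYS)  # 144

#: Transition keys (purine<->purine, pyrimidine<->pyrimidine).
TRANSITION_KEYS = frozenset({"AG", "GA", "CT", "TC"})


class InvalidVariantError(ValueError):
    """Raised when a ref/alt pair does not describe a biallelic SNV."""


def snv_key(ref: str, alt: str) -> str:
    """Return the SNV key for a ref/alt base pair (case-insensitive).

    >>> snv_key("G", "A")
    'GA'
    """
    r, a = ref.upper(), alt.upper()
    if len(r) != 1 or len(a) != 1 or r not in BASES or a not in BASES:
        raise InvalidVariantError(
            f"ref={ref!r} alt={alt!r}: alleles must be single bases in A/C/G/T"
        )
    if r == a:
        raise InvalidVariantError(f"ref and alt are both {r!r}: not a variant")
    return r + a


def snv_key_index(ref: str, alt: str) -> int:
    """Canonical index (0..11) of the SNV key for ref/alt."""
    return SNV_KEY_INDEX[snv_key(ref, alt)]


def pair_key(first: str, second: str) -> str:
    """Concatenate two SNV keys into a pair key.

    >>> pair_key("GA", "TC")
    'GATC'
    """
    for k in (first, second):
        if k not in SNV_KEY_INDEX:
            raise InvalidVariantError(f"{k!r} is not one of the 12 SNV keys")
    return first + second


def pair_row_index(first: str, second: str) -> int:
    """Row index (0..143) of the pair key formed by two SNV keys."""
    return N_SNV_KEYS * SNV_KEY_INDEX[first] + SNV_KEY_INDEX[second]
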