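"""Sequence-level primitives for double-stranded DNA genotypes.

A transcription-factor binding site is double stranded, so a genotype is an
*unordered* pair {s, revcomp(s)}. We represent it by its canonical form: the
lexicographically smaller of the two strands. All higher-level structures
(landscapes, mutation networks, populations) operate on canonical genotypes.

Point mutations are classified as transitions (purine<->purine, A<->G, or
pyrimidine<->pyrimidine, C<->T) or transversions (the remaining 8 changes).
The classification is invariant under complementing both bases, so it is
well defined on double-stranded genotypes.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

ALPHABET = "ACGT"
_BASES = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

TRANSITION = "transition"
TRANSVERSION = "transversion"


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _validate(s: str) -> None:
    if not s or not _BASES.issuperset(s):
        raise InvalidSequenceError(
            f"sequence must be a nonempty string over A/C/G/T, got {s!r}"
        )


def revcomp(s: str) -> str:
    """Reverse complement of ``s``. Involution: revcomp(revcomp(s)) == s."""
    _validate(s)
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """Canonical double-stranded identity: min(s, revcomp(s)) lexicographically.

    Idempotent, and canonical(s) == canonical(revcomp(s)) for every s.
    """
    rc = revcomp(s)
    return s if s <= rc else rc


def is_palindrome(s: str) -> bool:
    """True if ``s`` equals its own reverse complement (possible for even k)."""
    return s == revcomp(s)


def classify_mutation(from_base: str, to_base: str) -> str:
    """Classify a base change as TRANSITION or TRANSVERSION.

    Symmetric in its arguments and invariant under complementing both bases,
    hence strand independent. Identical bases are not a mutation.
    """
    if from_base not in _BASES or to_base not in _BASES:
        raise InvalidSequenceError(f"invalid bases {from_base!r} -> {to_base!r}")
    if from_base == to_base:
        raise ValueError(f"not a mutation: {from_base!r} -> {to_base!r}")
    pair = {from_base, to_base}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return TRANSITION
    return TRANSVERSION


@lru_cache(maxsize=8)
def enumerate_genotypes(k: int) -> tuple[str, ...]:
    """All distinct canonical genotypes of length ``k``, sorted.

    For even k the count has the closed form (4^k - 4^(k/2))/2 + 4^(k/2):
    non-palindromic strands pair up two-to-one, palindromes (which exist only
    for even k) map to themselves. k = 8 gives 32,896 genotypes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seen = set()
    for tup in itertools.product(ALPHABET, repeat=k):
        seen.add(canonical("".join(tup)))
    return tuple(sorted(seen))


def neighbors(g: str) -> list[tuple[str, str]]:
    """Canonical single-point-mutation neighbors of a canonical genotype.

    Mutates every position of the canonical strand to each alternative base and
    canonicalizes the result; mutating the other strand yields the same
    canonical set, so one strand suffices. Duplicate canonical forms (which
    arise for palindromes, whose position-i and position-(k+1-i) mutants
    coalesce) are merged; the mutation class of a merged pair is well defined
    because classification is complement invariant.

    Returns a sorted list of (neighbor, mutation_class). Degree is 3k for
    non-palindromic g and 3k/2 for palindromic g.
    """
    _validate(g)
    if canonical(g) != g:
        raise ValueError(f"{g!r} is not canonical; call canonical() first")
    out: dict[str, str] = {}
    for i, base in enumerate(g):
        for alt in ALPHABET:
            if alt == base:
                continue
            mut = canonical(g[:i] + alt + g[i + 1 :])
            cls = classify_mutation(base, alt)
            prev = out.setdefault(mut, cls)
            if prev != cls:  # cannot happen: merged mutants are complement pairs
                raise AssertionError(f"ambiguous mutation class for {g} -> {mut}")
    out.pop(g, None)  # a single substitution can never map g to itself, but be safe
    return sorted(out.items())


def hamming(a: str, b: str) -> int:
    """Plain per-position substitution distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def strand_distance(a: str, b: str) -> int:
    """Substitution distance between double-stranded genotypes.

    Minimum of the Hamming distances over the two orientations of ``b``;
    symmetric and invariant under reverse complementing either argument.
    """
    return min(hamming(a, b), hamming(a, revcomp(b)))
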