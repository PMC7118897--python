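"""Small sequence primitives shared by the profilers.

Contains the base-complement tables used for pyrimidine-strand folding of
substitutions, and the canonicalization of microsatellite repeat units
(equivalence under cyclic rotation and reverse complementation).
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    """Complement of a single uppercase base (A<->T, C<->G, N->N)."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return "".join(complement(b) for b in reversed(seq))


def rotations(seq: str) -> list[str]:
    """All cyclic rotations of ``seq`` (length-n list, may contain repeats)."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def smallest_period(seq: str) -> str:
    """Shortest unit whose repetition equals ``seq`` ("ACAC" -> "AC")."""
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and seq[: p] * (n // p) == seq:
            return seq[: p]
    return seq  # unreachable


def canonical_repeat_unit(unit: str) -> str:
    """Canonical class label for a microsatellite repeat unit.

    Units of length 1-3 are reduced to their smallest period and mapped to
    the lexicographically smallest string among all cyclic rotations of the
    unit and of its reverse complement.  Units of declared length 4 or 5 are
    pooled into the pattern-free classes ``unit4`` / ``unit5`` — the declared
    length wins even when the unit is itself periodic (e.g. "ACAC").

    >>> canonical_repeat_unit("GT")
    'AC'
    >>> canonical_repeat_unit("ACAC")
    'unit4'
    """
    unit = unit.upper()
    if not unit or len(unit) > 5:
        raise ValueError(f"repeat unit length must be 1-5, got {unit!r}")
    if any(b not in BASES for b in unit):
        raise ValueError(f"repeat unit contains non-ACGT character: {unit!r}")
    if len(unit) == 4:
        return "unit4"
    if len(unit) == 5:
        return "unit5"
    unit = smallest_period(unit)
    candidates = rotations(unit) + rotations(revcomp(unit))
    return min(candidates)


def canonical_unit_classes(max_len: int = 3) -> list[str]:
    """Distinct canonical classes over all repeat units of length 1..max_len.

    Ordered by unit length then alphabetically.  For max_len=3 this yields
    the 16 canonical mono-/di-/tri-nucleotide repeat classes.
    """
    from itertools import product

    classes = set()
    for n in range(1, max_len + 1):
        for tup in product(BASES, repeat=n):
            unit = "".join(tup)
            if smallest_period(unit) != unit:
                continue  # reducible to a shorter unit's class
            classes.add(canonical_repeat_unit(unit))
    return sorted(classes, key=lambda c: (len(c), c))
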