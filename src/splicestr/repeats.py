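"""Canonical repeat-unit normalization and strand-bias classification.

STR repeat units (1-6 bp) are ambiguous up to rotation (an AC repeat can be
written as CA) and, when strand is irrelevant, up to reverse complement (an AC
repeat on the plus strand reads GT on the minus strand).  Two normal forms are
provided:

* :func:`canonical_unit` — lexicographic minimum over all rotations of the
  unit and of its reverse complement; strand-agnostic, used to collapse units
  genome-wide (e.g. CAG repeats normalize to AGC).
* :func:`stranded_unit` — lexicographic minimum over rotations only; the
  sequence identity relative to the coding strand is preserved, so T-rich and
  A-rich orientations remain distinguishable.

Strand-bias classification partitions coding-strand units into T-rich and
A-rich classes (units with equal A/T counts, or with a G+C majority, are
excluded), supporting tests of the polypyrimidine-tract orientation bias of
splicing-associated repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class StrandBiasClass(str, Enum):
    """Mutually exclusive strand-bias classes for a coding-strand repeat unit."""

    T_RICH = "T_rich"
    A_RICH = "A_rich"
    EXCLUDED_EQUAL_AT = "excluded_equal_AT"
    EXCLUDED_GC_MAJORITY = "excluded_GC_majority"


def _validate_unit(unit: str) -> str:
    unit = unit.upper()
    if not unit or not set(unit) <= _ALPHABET:
        raise ValueError(f"invalid repeat unit {unit!r}: alphabet is A/C/G/T, non-empty")
    return unit


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def repeat_unit_of(sequence: str) -> str:
    """Smallest period of a repeat tract, e.g. ``CAGCAGCAG`` -> ``CAG``.

    Falls back to the full sequence when it is not a whole number of copies of
    a shorter unit.
    """
    sequence = _validate_unit(sequence)
    n = len(sequence)
    for p in range(1, n + 1):
        if n % p == 0 and sequence[:p] * (n // p) == sequence:
            return sequence[:p]
    return sequence


def canonical_unit(unit: str) -> str:
    """Strand-agnostic canonical form: min over rotations x strand orientations.

    The input may be a full repeat tract; it is first reduced to its smallest
    repeat unit, so ``canonical_unit("CAGCAGCAGCAG") == "AGC"``.
    """
    unit = repeat_unit_of(unit)
    candidates = rotations(unit) + rotations(reverse_complement(unit))
    return min(candidates)


def stranded_unit(unit: str) -> str:
    """Coding-strand canonical rotation: min over rotations only (no strand flip)."""
    unit = repeat_unit_of(unit)
    return min(rotations(unit))


def strand_bias_class(unit: str) -> StrandBiasClass:
    """Classify a coding-strand unit as T-rich / A-rich or excluded.

    Rule order: units with equal A and T counts are excluded first, then units
    whose G+C content is at least half the unit length; the remainder (A+T
    majority by construction) are split on the A/T count comparison.  The
    precedence matters only for units like ``CG`` that satisfy both exclusion
    rules; :func:`classify_units` exposes it as a parameter.
    """
    return _classify(_validate_unit(unit), at_first=True)


def _classify(unit: str, at_first: bool) -> StrandBiasClass:
    a, t = unit.count("A"), unit.count("T")
    gc_major = (unit.count("G") + unit.count("C")) / len(unit) >= 0.5
    if at_first:
        if a == t:
            return StrandBiasClass.EXCLUDED_EQUAL_AT
        if gc_major:
            return StrandBiasClass.EXCLUDED_GC_MAJORITY
    else:
        if gc_major:
            return StrandBiasClass.EXCLUDED_GC_MAJORITY
        if a == t:
            return StrandBiasClass.EXCLUDED_EQUAL_AT
    return StrandBiasClass.T_RICH if t > a else StrandBiasClass.A_RICH


def classify_units(units, at_exclusion_first: bool = True) -> list[StrandBiasClass]:
    """Vector form of :func:`strand_bias_class` with configurable rule precedence."""
    return [_classify(_validate_unit(u), at_first=at_exclusion_first) for u in units]


@dataclass(frozen=True)
class TRichTest:
    n_t_rich: int
    n_a_rich: int
    fraction_t_rich: float
    p_value: float


def t_rich_fraction_test(classes) -> TRichTest | None:
    """Fraction of T-rich among classified units and a one-sided exact binomial
    test of that fraction against 0.5 (alternative: T-rich excess).

    Excluded units are ignored.  Returns ``None`` for a bin with no classified
    (T-rich or A-rich) units.
    """
    classes = list(classes)
    n_t = sum(c == StrandBiasClass.T_RICH for c in classes)
    n_a = sum(c == StrandBiasClass.A_RICH for c in classes)
    n = n_t + n_a
    if n == 0:
        return None
    p = stats.binomtest(n_t, n, 0.5, alternative="greater").pvalue
    return TRichTest(n_t, n_a, n_t / n, float(p))


def all_units(max_period: int = 6):
    """Every repeat unit over {A,C,G,T} with length 1..max_period (4^1+...+4^k)."""
    from itertools import product

    for period in range(1, max_period + 1):
        for tup in product("ACGT", repeat=period):
            yield "".join(tup)
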