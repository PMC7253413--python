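"""Substitution-pattern algebra for multi-nucleotide variants (MNVs).

An MNV substitution pattern is the ordered pair of changed reference bases
and their alternate bases, e.g. ``CA->TG`` for an adjacent doublet.  Because
the genome is double-stranded a pattern and its reverse complement describe
the same mutational event, so patterns are collapsed onto a canonical
representative: the lexicographically smaller of the pattern and its reverse
complement (comparing the reference dinucleotide first, then the alternate).

For adjacent MNVs there are 16 reference dinucleotides x 9 alternate
dinucleotides (both bases must change) = 144 ordered patterns, which collapse
to 78 canonical patterns, 12 of which are their own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Pattern classes used when summarising mutational origin: CpG-transition
#: driven, polymerase-zeta doublet error, polymerase slippage at repeats, and
#: pure transversion combinations.  All remaining canonical patterns fall in
#: the implicit "others" class (78 - 15 = 63 patterns).
POL_ZETA_PATTERNS = frozenset({("GA", "TT"), ("GC", "AA")})
CPG_PATTERNS = frozenset({("CA", "TG"), ("AC", "GT"), ("CC", "TT"), ("GA", "AG")})
REPEAT_PATTERNS = frozenset({("AA", "TT"), ("TA", "AT"), ("AT", "TA")})
TRANSVERSION_PATTERNS = frozenset(
    {("TA", "GC"), ("CG", "AT"), ("AT", "CG"), ("CG", "GC"), ("GC", "CG"), ("CG", "AC")}
)

ORIGIN_CLASSES = {
    "CpG": CPG_PATTERNS,
    "pol_zeta": POL_ZETA_PATTERNS,
    "repeat": REPEAT_PATTERNS,
    "transversion": TRANSVERSION_PATTERNS,
}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Pattern:
    """A canonicalized MNV substitution pattern.

    ``ref`` and ``alt`` are the two changed bases (2-character strings); when
    the constituent SNVs are ``d`` bp apart the intervening ``d - 1``
    reference bases are implicit and unchanged.
    """

    ref: str
    alt: str
    d: int = 1

    @property
    def label(self) -> str:
        return f"{self.ref}->{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @property
    def is_self_complementary(self) -> bool:
        return (revcomp(self.ref), revcomp(self.alt)) == (self.ref, self.alt)


def canonical_pattern(ref2: str, alt2: str, d: int = 1) -> Pattern:
    """Collapse a substitution pattern onto its canonical representative.

    Parameters
    ----------
    ref2, alt2 : str
        The two changed reference/alternate bases, 5'->3'.  Both positions
        must actually change (otherwise the pair is not an MNV).
    d : int
        Distance ``pos2 - pos1`` between the constituent SNVs (1 = adjacent).

    Returns
    -------
    Pattern
        The lexicographically smaller of ``(ref2, alt2)`` and its reverse
        complement (reverse-complementing both strings reverses their order,
        so position 1 of the canonical form maps to position 2 of the input).
    """
    ref2, alt2 = ref2.upper(), alt2.upper()
    if len(ref2) != 2 or len(alt2) != 2:
        raise ValueError(f"pattern alleles must be 2 bp: {ref2}->{alt2}")
    if any(b not in BASES for b in ref2 + alt2):
        raise ValueError(f"non-ACGT base in pattern {ref2}->{alt2}")
    if ref2[0] == alt2[0] or ref2[1] == alt2[1]:
        raise ValueError(
            f"{ref2}->{alt2} is not an MNV pattern: both positions must change"
        )
    if d < 1:
        raise ValueError("distance must be >= 1")
    fwd = (ref2, alt2)
    rev = (revcomp(ref2), revcomp(alt2))
    ref_c, alt_c = min(fwd, rev)
    return Pattern(ref_c, alt_c, d)


@lru_cache(maxsize=None)
def enumerate_adjacent_patterns(d: int = 1) -> tuple[Pattern, ...]:
    """All canonical MNV patterns at distance ``d``, sorted.

    For any ``d`` there are 144 ordered patterns (16 reference dinucleotides
    x 3 alternates per position) collapsing to 78 canonical ones.
    """
    seen = set()
    for r1 in BASES:
        for r2 in BASES:
            for a1 in BASES:
                for a2 in BASES:
                    if a1 == r1 or a2 == r2:
                        continue
                    seen.add(canonical_pattern(r1 + r2, a1 + a2, d))
    return tuple(sorted(seen))


def origin_class(pattern: Pattern) -> str:
    """Origin class label for a canonical pattern.

    One of ``CpG``, ``pol_zeta``, ``repeat``, ``transversion`` or ``others``.
    """
    key = (pattern.ref, pattern.alt)
    for name, members in ORIGIN_CLASSES.items():
        if key in members:
            return name
    return "others"
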