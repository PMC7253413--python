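"""Trinucleotide-context SNV mutation-rate tables.

A table maps (5' base, reference base, 3' base, alternate base) to a
per-site per-generation mutation rate.  There are 64 contexts x 3 alternate
bases = 192 entries.  CpG transitions (C->T with a 3' G, equivalently G->A
with a 5' C) carry roughly an order of magnitude higher rate than other
transitions, which is the main driver of the skew in the MNV substitution
spectrum expected under an independent-SNV null model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .patterns import BASES

ContextKey = tuple[str, str, str, str]  # (five, ref, three, alt)


def _all_keys():
    for five, ref, three in itertools.product(BASES, repeat=3):
        for alt in BASES:
            if alt != ref:
                yield five, ref, three, alt


def is_cpg_transition(five: str, ref: str, three: str, alt: str) -> bool:
    """True for a C->T (3' G) or G->A (5' C) substitution at a CpG."""
    return (ref == "C" and alt == "T" and three == "G") or (
        ref == "G" and alt == "A" and five == "C"
    )


def is_transition(ref: str, alt: str) -> bool:
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


@dataclass
class MutationRateTable:
    """Per-generation SNV rates keyed by 3-mer context and alternate base."""

    rates: dict[ContextKey, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [k for k in _all_keys() if k not in self.rates]
        if missing:
            raise ValueError(
                f"rate table incomplete: {len(missing)} of 192 context/alt "
                f"entries missing (first: {missing[0]})"
            )
        bad = [k for k, v in self.rates.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive rate for context {bad[0]}")

    def rate(self, five: str, ref: str, three: str, alt: str) -> float:
        try:
            return self.rates[(five, ref, three, alt)]
        except KeyError:
            raise KeyError(
                f"no rate for context {five}[{ref}->{alt}]{three}"
            ) from None

    # -- constructors -----------------------------------------------------

    @classmethod
    def uniform(cls, mu: float = 1.2e-8) -> "MutationRateTable":
        """Every context/alternate combination gets the same rate ``mu``."""
        return cls({k: mu for k in _all_keys()})

    @classmethod
    def default(
        cls,
        transversion: float = 2.0e-9,
        transition: float = 8.0e-9,
        cpg_transition: float = 8.0e-8,
    ) -> "MutationRateTable":
        """A three-level table capturing the canonical rate hierarchy.

        Non-CpG transversion < non-CpG transition < CpG transition, with the
        defaults chosen so the context-averaged rate is of order the global
        human germline SNV rate (~1.2e-8 /bp/generation).
        """
        rates = {}
        for five, ref, three, alt in _all_keys():
            if is_cpg_transition(five, ref, three, alt):
                rates[(five, ref, three, alt)] = cpg_transition
            elif is_transition(ref, alt):
                rates[(five, ref, three, alt)] = transition
            else:
                rates[(five, ref, three, alt)] = transversion
        return cls(rates)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        """Read a table with columns ``context`` (3-mer), ``alt``, ``rate``."""
        df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str})
        rates = {}
        for row in df.itertuples(index=False):
            ctx = row.context.upper()
            if len(ctx) != 3:
                raise ValueError(f"context must be a 3-mer: {ctx!r}")
            rates[(ctx[0], ctx[1], ctx[2], row.alt.upper())] = float(row.rate)
        return cls(rates)

    def to_tsv(self, path) -> None:
        rows = [
            {"context": f"{k[0]}{k[1]}{k[2]}", "alt": k[3], "rate": v}
            for k, v in sorted(self.rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
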