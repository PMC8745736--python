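"""Degenerate-codon statistics for site-saturation mutagenesis libraries.

An SSM library randomises one codon with a degenerate scheme such as NNK
(N = A/C/G/T, K = G/T; 32 codons, all 20 amino acids, a single TAG stop).
This module enumerates a scheme's codons, tallies the amino-acid profile
under the standard genetic code, and answers the screening sample-size
question: how many clones must be picked to see every amino acid (or the
rarest one) with a stated confidence, assuming independent, unbiased
codon sampling.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "IUPAC_DNA", "DegenerateCodonScheme", "AminoAcidProfile",
    "CoverageEstimate", "degenerate_codon_profile", "library_coverage",
]

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code (E. coli host)


@dataclass(frozen=True)
class DegenerateCodonScheme:
    """A three-symbol degenerate codon, e.g. "NNK"."""

    symbols: str

    def __post_init__(self):
        sym = self.symbols.upper()
        if len(sym) != 3:
            raise ValueError("a codon scheme has exactly 3 symbols")
        for s in sym:
            if s not in IUPAC_DNA:
                raise ValueError(f"invalid IUPAC nucleotide symbol {s!r}")
        object.__setattr__(self, "symbols", sym)

    @property
    def codons(self) -> list[str]:
        """All concrete codons, in lexicographic enumeration order."""
        return ["".join(bases) for bases in
                itertools.product(*(IUPAC_DNA[s] for s in self.symbols))]

    @property
    def size(self) -> int:
        return math.prod(len(IUPAC_DNA[s]) for s in self.symbols)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Codon counts and probabilities per amino acid ('*' marks stops)."""

    counts: dict[str, int]
    n_codons: int

    @property
    def probabilities(self) -> dict[str, float]:
        return {aa: c / self.n_codons for aa, c in self.counts.items()}

    @property
    def n_amino_acids(self) -> int:
        return sum(1 for aa in self.counts if aa != "*")

    @property
    def stop_probability(self) -> float:
        return self.counts.get("*", 0) / self.n_codons


@dataclass(frozen=True)
class CoverageEstimate:
    """Sampling statistics for n independently picked clones."""

    n_clones: int
    expected_fraction_covered: float
    p_all_covered: float
    clones_for_target: int
    target: float


def degenerate_codon_profile(scheme: DegenerateCodonScheme | str
                             ) -> AminoAcidProfile:
    """Translate every codon of the scheme and tally amino-acid counts."""
    if isinstance(scheme, str):
        scheme = DegenerateCodonScheme(scheme)
    counts: Counter[str] = Counter()
    for codon in scheme.codons:
        if codon in _TABLE.stop_codons:
            counts["*"] += 1
        else:
            counts[_TABLE.forward_table[codon]] += 1
    return AminoAcidProfile(counts=dict(counts), n_codons=scheme.size)


def _p_all_covered(probs: list[float], n: int) -> float:
    """P(every amino acid seen in n clones) by inclusion-exclusion.

    Probabilities are grouped by value so that the 2^20 subset sum
    collapses to a small product over multiplicity classes.
    """
    groups = Counter(probs)  # prob -> how many amino acids share it
    values = list(groups.items())
    total = 0.0
    for picks in itertools.product(*(range(c + 1) for _, c in values)):
        j = sum(picks)
        miss_p = sum(p * k for (p, _), k in zip(values, picks))
        weight = math.prod(math.comb(c, k) for (_, c), k in zip(values, picks))
        total += (-1) ** j * weight * (1.0 - miss_p) ** n
    return min(max(total, 0.0), 1.0)


def library_coverage(profile: AminoAcidProfile, n_clones: int,
                     target: float = 0.95) -> CoverageEstimate:
    """Coverage statistics for a library of ``n_clones`` picked clones.

    * ``expected_fraction_covered``: mean over amino acids of
      1 - (1 - p_aa)^n.
    * ``p_all_covered``: probability that all amino acids are observed,
      by inclusion-exclusion (stops are not coverage targets; a stop
      codon at the SSM position simply wastes a clone).
    * ``clones_for_target``: smallest n at which the rarest amino acid is
      seen with probability >= ``target``.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if not 0.0 < target < 1.0:
        raise ValueError("target confidence must lie in (0, 1)")
    probs = [p for aa, p in profile.probabilities.items() if aa != "*"]
    if not probs:
        raise ValueError("profile encodes no amino acids")
    expected = sum(1.0 - (1.0 - p) ** n_clones for p in probs) / len(probs)
    p_all = _p_all_covered(probs, n_clones)
    p_min = min(probs)
    # smallest n with 1 - (1 - p_min)^n >= target
    n_t = max(1, math.ceil(math.log1p(-target) / math.log1p(-p_min)))
    while 1.0 - (1.0 - p_min) ** n_t < target:
        n_t += 1
    while n_t > 1 and 1.0 - (1.0 - p_min) ** (n_t - 1) >= target:
        n_t -= 1
    return CoverageEstimate(
        n_clones=n_clones, expected_fraction_covered=expected,
        p_all_covered=p_all, clones_for_target=n_t, target=target,
    )
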