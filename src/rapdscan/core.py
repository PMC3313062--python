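"""Sequence primitives and the shared run configuration.

The working alphabet is uppercase A/C/G/T with N as the only ambiguity
code; anything else is normalized to N at input time (see
:mod:`rapdscan.seqio`).  Primers must be unambiguous A/C/G/T.
"""
from __future__ import annotations

from dataclasses import dataclass

PAIRING_MODES = ("paper", "convergent")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class ScanConfig:
    """Run parameters shared by every pipeline stage.

    Parameters
    ----------
    max_mismatches
        Tolerated base differences when locating a priming site, 0-3.
        Short arbitrary decamers anneal despite a few mismatches, so the
        default keeps the most permissive setting; each reported site
        carries its own mismatch count for stricter post-filtering.
    min_product, max_product
        Amplifiable product-size window in bp, both boundaries
        inclusive.  Defaults 200 and 2000 bp: shorter products are hard
        to resolve from primer artefacts on a gel, longer ones amplify
        poorly with standard RAPD cycling.
    extension
        Template bases appended to each priming site when deriving a
        SCAR primer, default 10 (a decamer site becomes a 20-mer).
    pairing_mode
        ``"paper"`` pairs all sites of a primer within a sequence
        regardless of orientation; ``"convergent"`` keeps only
        plus-strand-left / minus-strand-right pairs, the geometry an
        actual PCR can amplify exponentially.
    seed
        Seed for synthetic fixture generation.
    """

    max_mismatches: int = 3
    min_product: int = 200
    max_product: int = 2000
    extension: int = 10
    pairing_mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches <= 3:
            raise ValueError(
                f"max_mismatches must be in 0..3, got {self.max_mismatches}"
            )
        if self.min_product <= 0:
            raise ValueError(f"min_product must be positive, got {self.min_product}")
        if self.max_product < self.min_product:
            raise ValueError(
                f"max_product ({self.max_product}) < min_product ({self.min_product})"
            )
        if self.extension < 1:
            raise ValueError(f"extension must be >= 1, got {self.extension}")
        if self.pairing_mode not in PAIRING_MODES:
            raise ValueError(
                f"pairing_mode must be one of {PAIRING_MODES}, got {self.pairing_mode!r}"
            )


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over A/C/G/T/N (N maps to N)."""
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(
            f"cannot reverse-complement: non-ACGTN character(s) {sorted(bad)}"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class CompositionReport:
    """Exact base counts of one sequence plus its GC percentage."""

    a: int
    c: int
    g: int
    t: int
    other: int
    length: int
    gc_percent: float

    def as_row(self) -> dict:
        return {
            "length": self.length,
            "A": self.a,
            "C": self.c,
            "G": self.g,
            "T": self.t,
            "other": self.other,
            "gc_percent": self.gc_percent,
        }


def base_composition(sequence: str) -> CompositionReport:
    """Count each base; gc_percent = 100*(G+C)/length.

    Characters outside A/C/G/T (typically N) fall into ``other``.
    """
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    n = len(sequence)
    a = sequence.count("A")
    c = sequence.count("C")
    g = sequence.count("G")
    t = sequence.count("T")
    return CompositionReport(
        a=a,
        c=c,
        g=g,
        t=t,
        other=n - a - c - g - t,
        length=n,
        gc_percent=100.0 * (g + c) / n,
    )


@dataclass(frozen=True, slots=True)
class PrimerQC:
    """Advisory quality flags for one primer.

    ``passes`` is true when GC content is at least 40% and the primer is
    not a reverse-complement palindrome.  Palindrome here means the
    molecular-biology sense — the sequence equals its own reverse
    complement — because that is the property that promotes primer
    self-annealing; literal string reversal is not meaningful for an
    oligonucleotide.  Failing primers are still scanned: the criteria
    guide primer choice, they do not gate the search.
    """

    name: str
    gc_percent: float
    is_palindrome: bool
    passes: bool


def primer_qc(name: str, sequence: str) -> PrimerQC:
    comp = base_composition(sequence)
    is_pal = sequence == reverse_complement(sequence)
    return PrimerQC(
        name=name,
        gc_percent=comp.gc_percent,
        is_palindrome=is_pal,
        passes=comp.gc_percent >= 40.0 and not is_pal,
    )
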