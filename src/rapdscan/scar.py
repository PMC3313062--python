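"""iSCAR primer design and in-silico PCR verification.

A qualifying amplicon is converted to a locus-specific primer pair by
extending each priming-site footprint a fixed number of template bases
INTO the amplicon: the forward primer is the left footprint plus the
bases to its right, the reverse primer is the reverse complement of the
right footprint plus the bases to its left.  Both extensions are read
from the target sequence, not from the (possibly mismatched) arbitrary
primer, so SCAR primers match their template exactly — which is the
point of converting a RAPD band into a SCAR marker.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .amplicon import AmpliconPrediction
from .core import ScanConfig, reverse_complement
from .seqio import SequenceSet

logger = logging.getLogger("rapdscan")


@dataclass(frozen=True, slots=True)
class ScarPair:
    """A designed forward/reverse primer pair with its expected product."""

    primer_name: str
    sequence_id: str
    forward_primer: str
    reverse_primer: str
    expected_product: int

    def as_row(self) -> dict:
        return {
            "primer_name": self.primer_name,
            "sequence_id": self.sequence_id,
            "forward_primer": self.forward_primer,
            "reverse_primer": self.reverse_primer,
            "expected_product": self.expected_product,
        }


def design_scar(
    amplicon: AmpliconPrediction, target: str, config: ScanConfig
) -> ScarPair | None:
    """Extend both priming sites into the amplicon to form a SCAR pair.

    forward = target[left.start .. left.end + extension] and
    reverse = reverse_complement(target[right.start - extension .. right.end]),
    1-based inclusive, so each designed primer is primer length +
    extension bases long.  Returns None (with a logged warning) when an
    extension would run past an amplicon boundary or the sequence end,
    or when either footprint contains N — a degenerate base in a primer
    would defeat the purpose of the design.
    """
    left, right = amplicon.left_site, amplicon.right_site
    ext = config.extension
    fwd_start, fwd_end = left.start, left.end + ext  # 1-based inclusive
    rev_start, rev_end = right.start - ext, right.end
    if fwd_end > len(target) or fwd_end > right.end or rev_start < 1 or rev_start < left.start:
        logger.warning(
            "skipping SCAR for primer %s in %s: extension exceeds amplicon "
            "or sequence bounds",
            amplicon.primer_name,
            amplicon.sequence_id,
        )
        return None
    forward = target[fwd_start - 1 : fwd_end]
    reverse_footprint = target[rev_start - 1 : rev_end]
    if "N" in forward or "N" in reverse_footprint:
        logger.warning(
            "skipping SCAR for primer %s in %s: footprint contains N",
            amplicon.primer_name,
            amplicon.sequence_id,
        )
        return None
    return ScarPair(
        primer_name=amplicon.primer_name,
        sequence_id=amplicon.sequence_id,
        forward_primer=forward,
        reverse_primer=reverse_complement(reverse_footprint),
        expected_product=amplicon.product_size,
    )


@dataclass(frozen=True, slots=True)
class ScarDesignResult:
    pairs: tuple[ScarPair, ...]
    n_skipped: int
    n_duplicates: int


def design_scars(
    predictions: Sequence[AmpliconPrediction],
    targets: SequenceSet,
    config: ScanConfig,
) -> ScarDesignResult:
    """Design one pair per in-window amplicon, deduplicating identical pairs.

    Pairs with identical (sequence id, forward, reverse) are reported
    once; out-of-window predictions are ignored.
    """
    pairs: list[ScarPair] = []
    seen: set[tuple[str, str, str]] = set()
    n_skipped = 0
    n_dup = 0
    for pred in predictions:
        if not pred.in_window:
            continue
        pair = design_scar(pred, targets[pred.sequence_id].sequence, config)
        if pair is None:
            n_skipped += 1
            continue
        key = (pair.sequence_id, pair.forward_primer, pair.reverse_primer)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        pairs.append(pair)
    return ScarDesignResult(pairs=tuple(pairs), n_skipped=n_skipped, n_duplicates=n_dup)


def insilico_pcr(pair: ScarPair, target: str) -> int | None:
    """Product size the pair would amplify from the target, or None.

    The forward primer must occur exactly on the given strand and the
    reverse complement of the reverse primer exactly downstream of it on
    the same strand; the product spans from the start of the forward
    footprint to the end of the reverse footprint.  With multiple
    placements the smallest product is returned, mirroring the bias of
    PCR toward shorter templates.
    """
    fwd = pair.forward_primer
    rev_fp = reverse_complement(pair.reverse_primer)

    fwd_starts = _find_all(target, fwd)
    rev_starts = _find_all(target, rev_fp)
    if not fwd_starts or not rev_starts:
        return None
    best: int | None = None
    for f in fwd_starts:
        for r in rev_starts:
            if r < f:  # reverse footprint upstream of forward: not amplifiable
                continue
            size = (r + len(rev_fp) - 1) - f + 1
            if best is None or size < best:
                best = size
    return best


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 1-based occurrence starts of needle, overlaps allowed."""
    starts = []
    i = haystack.find(needle)
    while i != -1:
        starts.append(i + 1)
        i = haystack.find(needle, i + 1)
    return starts
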