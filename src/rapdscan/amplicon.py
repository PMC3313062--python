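"""Amplicon prediction from priming-site pairs and primer shortlisting.

Two sites of the same primer in one sequence delimit a potential PCR
product.  The anticipated product size spans both primer footprints:
``right.end - left.start + 1``.  Products inside the amplifiable window
(boundaries inclusive) mark their primer as a shortlist candidate.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

from .core import ScanConfig
from .sitescan import COMPLEMENT, GIVEN, PrimingSite, SiteTable


@dataclass(frozen=True, slots=True)
class AmpliconPrediction:
    primer_name: str
    sequence_id: str
    left_site: PrimingSite
    right_site: PrimingSite
    product_size: int
    in_window: bool

    def as_row(self) -> dict:
        return {
            "primer_name": self.primer_name,
            "sequence_id": self.sequence_id,
            "left_start": self.left_site.start,
            "left_end": self.left_site.end,
            "right_start": self.right_site.start,
            "right_end": self.right_site.end,
            "left_orientation": self.left_site.orientation,
            "right_orientation": self.right_site.orientation,
            "product_size": self.product_size,
            "in_window": self.in_window,
        }


def predict_amplicons(
    table: SiteTable, config: ScanConfig
) -> list[AmpliconPrediction]:
    """Enumerate all eligible ordered site pairs with product sizes.

    For each primer and sequence, every pair with ``left.start <
    right.start`` is considered; pairs whose footprints overlap
    (``right.start <= left.end``) are excluded.  Under pairing mode
    ``"convergent"`` only (given-orientation left, complement-orientation
    right) pairs survive — the configuration pointing the two 3' ends at
    each other, which real PCR requires.  All eligible pairs are
    reported, not just adjacent ones.
    """
    by_group: dict[tuple[str, str], list[PrimingSite]] = {}
    for site in table:
        by_group.setdefault((site.primer_name, site.sequence_id), []).append(site)

    predictions: list[AmpliconPrediction] = []
    for (primer_name, sequence_id), sites in by_group.items():
        sites.sort(key=lambda s: (s.start, s.orientation))
        for left, right in combinations(sites, 2):
            if right.start <= left.end:  # overlapping or coincident footprints
                continue
            if config.pairing_mode == "convergent" and not (
                left.orientation == GIVEN and right.orientation == COMPLEMENT
            ):
                continue
            size = right.end - left.start + 1
            predictions.append(
                AmpliconPrediction(
                    primer_name=primer_name,
                    sequence_id=sequence_id,
                    left_site=left,
                    right_site=right,
                    product_size=size,
                    in_window=config.min_product <= size <= config.max_product,
                )
            )
    return predictions


@dataclass(frozen=True, slots=True)
class ShortlistEntry:
    """One shortlisted primer with its in-window evidence, best pair first."""

    primer_name: str
    n_in_window_pairs: int
    evidence: tuple[AmpliconPrediction, ...]

    @property
    def best(self) -> AmpliconPrediction:
        return self.evidence[0]


@dataclass(frozen=True)
class Shortlist:
    entries: tuple[ShortlistEntry, ...]

    def __iter__(self) -> Iterator[ShortlistEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def primer_names(self) -> tuple[str, ...]:
        return tuple(e.primer_name for e in self.entries)


def shortlist_primers(predictions: Sequence[AmpliconPrediction]) -> Shortlist:
    """Primers with at least one in-window product, ordered by name.

    A primer priming twice or more at an amplifiable distance is the one
    worth taking to the bench; each entry carries all of its in-window
    pairs as evidence, smallest product first (ties broken by sequence
    id then left start, for reproducible reports).
    """
    in_window: dict[str, list[AmpliconPrediction]] = {}
    for pred in predictions:
        if pred.in_window:
            in_window.setdefault(pred.primer_name, []).append(pred)
    entries = []
    for primer_name in sorted(in_window):
        evidence = sorted(
            in_window[primer_name],
            key=lambda p: (p.product_size, p.sequence_id, p.left_site.start),
        )
        entries.append(
            ShortlistEntry(
                primer_name=primer_name,
                n_in_window_pairs=len(evidence),
                evidence=tuple(evidence),
            )
        )
    return Shortlist(entries=tuple(entries))
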