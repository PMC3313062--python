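"""Mismatch-tolerant priming-site search.

Every window of every target is compared against each primer and
against the primer's reverse complement (a RAPD primer anneals to
either strand).  Matching is pure Hamming distance — substitutions
only, no indels — with N in the target always counting as a mismatch.
The scan is exhaustive over all windows; overlapping and
self-overlapping hits are all reported.  Internally the comparison is
vectorised over windows; all exposed coordinates are 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .core import ScanConfig, reverse_complement
from .seqio import PrimerSet, SequenceSet

GIVEN = "given"
COMPLEMENT = "complement"

_N_BYTE = ord("N")


@dataclass(frozen=True, slots=True, order=True)
class PrimingSite:
    """One located primer match; start/end are 1-based inclusive."""

    primer_name: str
    sequence_id: str
    start: int
    end: int
    orientation: str
    mismatches: int

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.primer_name, self.sequence_id, self.start, self.orientation)


@dataclass(frozen=True)
class SiteTable:
    """All priming sites of one run, queryable by primer/sequence/orientation."""

    sites: tuple[PrimingSite, ...]

    def __post_init__(self) -> None:
        keys = [s.key for s in self.sites]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (primer, sequence, start, orientation) entry")

    def __iter__(self) -> Iterator[PrimingSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def by_primer(self, primer_name: str) -> tuple[PrimingSite, ...]:
        return tuple(s for s in self.sites if s.primer_name == primer_name)

    def by_sequence(self, sequence_id: str) -> tuple[PrimingSite, ...]:
        return tuple(s for s in self.sites if s.sequence_id == sequence_id)

    def by_orientation(self, orientation: str) -> tuple[PrimingSite, ...]:
        return tuple(s for s in self.sites if s.orientation == orientation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "primer_name": s.primer_name,
                    "sequence_id": s.sequence_id,
                    "start": s.start,
                    "end": s.end,
                    "orientation": s.orientation,
                    "mismatches": s.mismatches,
                }
                for s in self.sites
            ],
            columns=[
                "primer_name",
                "sequence_id",
                "start",
                "end",
                "orientation",
                "mismatches",
            ],
        )


def _window_mismatches(pattern: str, target: str) -> np.ndarray:
    """Hamming distance of every target window to the pattern.

    N in the target is a forced mismatch at that position, whatever the
    pattern base.  Returns an int array of length len(target)-len(pattern)+1.
    """
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    tgt = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tgt, len(pat))
    mism = (windows != pat) | (windows == _N_BYTE)
    return mism.sum(axis=1)


def hamming_matches(
    pattern: str, target: str, max_mm: int
) -> list[tuple[int, int]]:
    """All (1-based start, mismatch count) windows within max_mm of pattern.

    Windows are enumerated left to right; overlaps are allowed.  A
    pattern longer than the target yields an empty list.
    """
    if max_mm < 0:
        raise ValueError(f"max_mm must be >= 0, got {max_mm}")
    if not pattern or len(pattern) > len(target):
        return []
    mm = _window_mismatches(pattern, target)
    hits = np.flatnonzero(mm <= max_mm)
    return [(int(i) + 1, int(mm[i])) for i in hits]


def scan(primers: PrimerSet, targets: SequenceSet, config: ScanConfig) -> SiteTable:
    """Locate every tolerated priming site of every primer on both strands.

    For each primer the given sequence is searched (orientation
    ``given``) and its reverse complement is searched (orientation
    ``complement``) in every target.  A palindromic primer therefore
    yields coincident sites under both orientations; both records are
    kept, distinguished by the orientation field.
    """
    sites: list[PrimingSite] = []
    for primer in primers:
        patterns = (
            (GIVEN, primer.sequence),
            (COMPLEMENT, reverse_complement(primer.sequence)),
        )
        plen = len(primer.sequence)
        for target in targets:
            for orientation, pattern in patterns:
                for start, mm in hamming_matches(
                    pattern, target.sequence, config.max_mismatches
                ):
                    sites.append(
                        PrimingSite(
                            primer_name=primer.name,
                            sequence_id=target.id,
                            start=start,
                            end=start + plen - 1,
                            orientation=orientation,
                            mismatches=mm,
                        )
                    )
    return SiteTable(sites=tuple(sites))


def site_frequency(table: SiteTable) -> pd.DataFrame:
    """Site counts per (primer, sequence); count >= 2 flags multi-site.

    Primers priming more than once in one sequence are the candidates
    for product prediction, so they are split out into their own view.
    """
    df = table.to_frame()
    if df.empty:
        return pd.DataFrame(
            columns=["primer_name", "sequence_id", "n_sites", "multi_site"]
        )
    counts = (
        df.groupby(["primer_name", "sequence_id"], sort=True)
        .size()
        .reset_index(name="n_sites")
    )
    counts["multi_site"] = counts["n_sites"] >= 2
    return counts


def tally_by_library(table: SiteTable, targets: SequenceSet) -> pd.DataFrame:
    """Site counts per (primer, library label), plus a total row per primer.

    The total row uses the reserved library label ``"total"`` and equals
    the sum over that primer's library rows.
    """
    lib_of = targets.libraries()
    df = table.to_frame()
    if df.empty:
        return pd.DataFrame(columns=["primer_name", "library", "n_sites"])
    df = df.assign(library=df["sequence_id"].map(lib_of))
    per_lib = (
        df.groupby(["primer_name", "library"], sort=True)
        .size()
        .reset_index(name="n_sites")
    )
    totals = (
        per_lib.groupby("primer_name", sort=True)["n_sites"]
        .sum()
        .reset_index()
        .assign(library="total")
    )
    out = pd.concat([per_lib, totals], ignore_index=True)
    return out.sort_values(["primer_name", "library"], kind="mergesort").reset_index(
        drop=True
    )
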