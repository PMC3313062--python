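"""Deterministic synthetic targets with primer sites planted at known positions.

Backgrounds are i.i.d. per-base at a configurable GC fraction — no
repeat structure, no expression model — which is sufficient for
correctness testing and deliberately non-biological.  Each planted site
is the primer (or its reverse complement) carrying exactly the
requested number of substitutions, so ground truth records the exact
coordinates, orientation and mismatch load of every planted footprint.
Background windows may coincidentally match a primer as well; tests
therefore compare scans against ground truth with "superset on
background, exact on planted" semantics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import reverse_complement
from .seqio import PrimerSet, SequenceSet, TargetSequence, write_fasta
from .sitescan import COMPLEMENT, GIVEN, PrimingSite, SiteTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALTERNATIVES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class PlantSpec:
    """Planted sites of one primer within one synthetic sequence.

    ``positions``, ``orientations`` and ``mismatch_loads`` are parallel
    lists (1-based starts; ``"given"``/``"complement"``; substitution
    counts 0-3).  Overlapping footprints are rejected unless
    ``allow_overlap`` is set, because a later plant would corrupt an
    earlier one's ground truth.
    """

    primer_name: str
    sequence_id: str
    positions: tuple[int, ...] = ()
    orientations: tuple[str, ...] = ()
    mismatch_loads: tuple[int, ...] = ()
    background_gc: float = 50.0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not (
            len(self.positions) == len(self.orientations) == len(self.mismatch_loads)
        ):
            raise ValueError(
                "positions, orientations and mismatch_loads must be parallel lists"
            )
        for o in self.orientations:
            if o not in (GIVEN, COMPLEMENT):
                raise ValueError(f"orientation must be given/complement, got {o!r}")
        for m in self.mismatch_loads:
            if not 0 <= m <= 3:
                raise ValueError(f"mismatch load must be in 0..3, got {m}")
        if not 0.0 <= self.background_gc <= 100.0:
            raise ValueError("background_gc must be a percentage in [0, 100]")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    g = gc / 200.0  # per-base probability of G (and of C)
    probs = [0.5 - g, g, g, 0.5 - g]  # A, C, G, T
    return rng.choice(_BASES, size=length, p=probs)


def generate(
    specs: list[PlantSpec],
    primers: PrimerSet,
    seq_length: int,
    seed: int,
) -> tuple[SequenceSet, SiteTable]:
    """Build synthetic sequences with planted sites plus their ground truth.

    Sequences appear in order of first mention in ``specs``; every spec
    footprint must fit within ``seq_length``.  Regeneration with the
    same seed is byte-identical.  The returned SiteTable contains only
    the planted sites (mismatches = the requested load); the scan may
    legitimately find additional background hits.
    """
    rng = np.random.default_rng(seed)
    order: list[str] = []
    by_seq: dict[str, list[PlantSpec]] = {}
    for spec in specs:
        if spec.sequence_id not in by_seq:
            order.append(spec.sequence_id)
            by_seq[spec.sequence_id] = []
        by_seq[spec.sequence_id].append(spec)

    entries: list[TargetSequence] = []
    truth: list[PrimingSite] = []
    for seq_id in order:
        seq_specs = by_seq[seq_id]
        arr = _random_background(rng, seq_length, seq_specs[0].background_gc)
        occupied: list[tuple[int, int]] = []
        for spec in seq_specs:
            primer_seq = primers[spec.primer_name].sequence
            plen = len(primer_seq)
            for pos, orient, load in zip(
                spec.positions, spec.orientations, spec.mismatch_loads
            ):
                end = pos + plen - 1
                if pos < 1 or end > seq_length:
                    raise ValueError(
                        f"planted footprint [{pos}, {end}] of {spec.primer_name!r} "
                        f"exceeds sequence length {seq_length}"
                    )
                if not spec.allow_overlap:
                    for s, e in occupied:
                        if pos <= e and s <= end:
                            raise ValueError(
                                f"planted footprints overlap in {seq_id!r} at "
                                f"[{pos}, {end}]; set allow_overlap to permit"
                            )
                occupied.append((pos, end))
                footprint = (
                    primer_seq if orient == GIVEN else reverse_complement(primer_seq)
                )
                mutated = _substitute(rng, footprint, load)
                arr[pos - 1 : end] = np.frombuffer(
                    mutated.encode("ascii"), dtype=np.uint8
                )
                truth.append(
                    PrimingSite(
                        primer_name=spec.primer_name,
                        sequence_id=seq_id,
                        start=pos,
                        end=end,
                        orientation=orient,
                        mismatches=load,
                    )
                )
        entries.append(
            TargetSequence(id=seq_id, sequence=arr.tobytes().decode("ascii"))
        )
    return SequenceSet(entries=tuple(entries)), SiteTable(sites=tuple(truth))


def _substitute(rng: np.random.Generator, footprint: str, load: int) -> str:
    """Apply exactly `load` substitutions at distinct positions.

    Each substituted base becomes a different base, so the Hamming
    distance of the planted footprint to the clean pattern is exactly
    `load`.
    """
    if load == 0:
        return footprint
    chars = list(footprint)
    positions = rng.choice(len(chars), size=load, replace=False)
    for p in sorted(int(i) for i in positions):
        chars[p] = _ALTERNATIVES[chars[p]][int(rng.integers(3))]
    return "".join(chars)


def convergent_pair_spec(
    primer_name: str,
    sequence_id: str,
    left_start: int,
    product_size: int,
    primer_length: int = 10,
    mismatch_loads: tuple[int, int] = (0, 0),
    background_gc: float = 50.0,
) -> PlantSpec:
    """Spec for one convergent pair yielding a chosen product size.

    The right (complement) footprint starts where ``right.end -
    left.start + 1`` equals the requested size.
    """
    right_start = left_start + product_size - primer_length
    return PlantSpec(
        primer_name=primer_name,
        sequence_id=sequence_id,
        positions=(left_start, right_start),
        orientations=(GIVEN, COMPLEMENT),
        mismatch_loads=mismatch_loads,
        background_gc=background_gc,
    )


def write_fixture(
    targets: SequenceSet, truth: SiteTable, out_dir: str | Path
) -> tuple[Path, Path]:
    """Emit the fixture as multi-FASTA plus a ground-truth sites TSV."""
    from .seqio import SCHEMAS, write_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "targets.fasta"
    truth_tsv = out_dir / "truth_sites.tsv"
    write_fasta([(t.id, t.sequence) for t in targets], fasta)
    write_report(truth.to_frame(), truth_tsv, SCHEMAS["sites"])
    return fasta, truth_tsv
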