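"""Input parsing (primer lists, target FASTA, library maps) and TSV report I/O.

Primer files may be FASTA or two-column ``name<TAB>sequence`` text;
the dialect is auto-detected from a leading ``>``.  All emitted
coordinates are 1-based inclusive, all reports are tab-separated with a
header row and a fixed sort order so that reruns diff cleanly.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("rapdscan")

_PRIMER_ALPHABET = frozenset("ACGT")
_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True, slots=True)
class Primer:
    name: str
    sequence: str


@dataclass(frozen=True)
class PrimerSet:
    """Ordered, validated collection of named primers (A/C/G/T only)."""

    entries: tuple[Primer, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.entries:
            if p.name in seen:
                raise ValueError(f"duplicate primer name: {p.name!r}")
            seen.add(p.name)
            if not p.sequence:
                raise ValueError(f"primer {p.name!r} has an empty sequence")
            bad = set(p.sequence) - _PRIMER_ALPHABET
            if bad:
                raise ValueError(
                    f"primer {p.name!r} contains non-ACGT character(s): {sorted(bad)}"
                )

    def __iter__(self) -> Iterator[Primer]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> Primer:
        for p in self.entries:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass(frozen=True, slots=True)
class TargetSequence:
    id: str
    sequence: str
    library: str = "unassigned"


@dataclass(frozen=True)
class SequenceSet:
    """Ordered target sequences over A/C/G/T/N with optional library labels.

    ``normalized_base_count`` records how many letters outside the
    working alphabet were collapsed to N at load time.
    """

    entries: tuple[TargetSequence, ...]
    normalized_base_count: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.entries:
            if t.id in seen:
                raise ValueError(f"duplicate sequence id: {t.id!r}")
            seen.add(t.id)
            if not t.sequence:
                raise ValueError(f"sequence {t.id!r} is empty")
            if _NON_ACGTN.search(t.sequence):
                raise ValueError(f"sequence {t.id!r} contains non-ACGTN characters")

    def __iter__(self) -> Iterator[TargetSequence]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, seq_id: str) -> TargetSequence:
        for t in self.entries:
            if t.id == seq_id:
                return t
        raise KeyError(seq_id)

    def libraries(self) -> Mapping[str, str]:
        return {t.id: t.library for t in self.entries}


def parse_primers(path: str | Path) -> PrimerSet:
    """Load primers from FASTA or two-column (name, sequence) text.

    Sequences are uppercased; record order is preserved.  Duplicate
    names, non-ACGT characters and empty files are hard errors.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"primer file {path} is empty")
    entries: list[Primer] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(path, "fasta"):
            entries.append(Primer(name=rec.id, sequence=str(rec.seq).upper()))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (name, sequence), "
                    f"got {len(parts)}"
                )
            entries.append(Primer(name=parts[0], sequence=parts[1].upper()))
    if not entries:
        raise ValueError(f"primer file {path} contains no records")
    return PrimerSet(entries=tuple(entries))


def read_targets(
    path: str | Path, library_map: str | Path | None = None
) -> SequenceSet:
    """Load a target multi-FASTA, normalizing ambiguity codes to N.

    Letters outside A/C/G/T/N are replaced by N (the replacement count
    is logged and stored on the returned set).  Sequence ids absent from
    the optional two-column ``id<TAB>library`` map get the library label
    ``"unassigned"``; map rows naming unknown ids are warned about and
    ignored.
    """
    path = Path(path)
    lib_of: dict[str, str] = {}
    raw: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id in {path}: {rec.id!r}")
        seen.add(rec.id)
        raw.append((rec.id, str(rec.seq).upper()))
    if not raw:
        raise ValueError(f"target file {path} contains no FASTA records")

    if library_map is not None:
        for lineno, line in enumerate(
            Path(library_map).read_text().splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{library_map}:{lineno}: expected two tab-separated columns"
                )
            seq_id, lib = parts
            if seq_id not in seen:
                logger.warning(
                    "library map references unknown sequence id %r; ignored", seq_id
                )
                continue
            lib_of[seq_id] = lib

    n_normalized = 0
    entries: list[TargetSequence] = []
    for seq_id, seq in raw:
        cleaned, n_sub = _NON_ACGTN.subn("N", seq)
        n_normalized += n_sub
        entries.append(
            TargetSequence(
                id=seq_id, sequence=cleaned, library=lib_of.get(seq_id, "unassigned")
            )
        )
    if n_normalized:
        logger.warning(
            "normalized %d non-ACGTN letter(s) to N across %d sequence(s)",
            n_normalized,
            len(entries),
        )
    return SequenceSet(entries=tuple(entries), normalized_base_count=n_normalized)


class ReportSchema(NamedTuple):
    columns: tuple[str, ...]
    sort_by: tuple[str, ...]


#: Column layout and deterministic sort keys for every emitted report.
SCHEMAS: dict[str, ReportSchema] = {
    "sites": ReportSchema(
        ("primer_name", "sequence_id", "start", "end", "orientation", "mismatches"),
        ("primer_name", "sequence_id", "start", "orientation"),
    ),
    "multisite": ReportSchema(
        ("primer_name", "sequence_id", "n_sites"),
        ("primer_name", "sequence_id"),
    ),
    "amplicons": ReportSchema(
        (
            "primer_name",
            "sequence_id",
            "left_start",
            "left_end",
            "right_start",
            "right_end",
            "left_orientation",
            "right_orientation",
            "product_size",
            "in_window",
        ),
        ("primer_name", "sequence_id", "left_start", "right_start"),
    ),
    "shortlist": ReportSchema(
        ("primer_name", "n_in_window_pairs", "best_sequence_id", "best_product_size"),
        ("primer_name",),
    ),
    "iscar": ReportSchema(
        ("primer_name", "sequence_id", "forward_primer", "reverse_primer", "expected_product"),
        ("primer_name", "sequence_id", "forward_primer", "reverse_primer"),
    ),
    "composition": ReportSchema(
        ("sequence_id", "length", "A", "C", "G", "T", "other", "gc_percent"),
        ("sequence_id",),
    ),
    "library_tally": ReportSchema(
        ("primer_name", "library", "n_sites"),
        ("primer_name", "library"),
    ),
    "primer_qc": ReportSchema(
        ("primer_name", "sequence", "gc_percent", "is_palindrome", "passes"),
        ("primer_name",),
    ),
}


def write_report(
    rows: pd.DataFrame | Iterable[Mapping],
    path: str | Path,
    schema: ReportSchema,
) -> pd.DataFrame:
    """Write rows as a sorted TSV with a header; returns the sorted frame.

    Row order is fixed by the schema's sort keys so identical row
    multisets serialize to identical bytes regardless of input order.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        df = pd.DataFrame(columns=list(schema.columns))
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise ValueError(f"rows missing required column(s): {sorted(missing)}")
    df = df.loc[:, list(schema.columns)]
    if len(df):
        df = df.sort_values(list(schema.sort_by), kind="mergesort").reset_index(
            drop=True
        )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as plain multi-FASTA, 70-column wrapped."""
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
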