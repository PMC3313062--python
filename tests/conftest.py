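from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make naive_oracle importable

from rapdscan.seqio import Primer, PrimerSet


def random_decamers(rng: np.random.Generator, n: int, length: int = 10) -> PrimerSet:
    bases = np.array(list("ACGT"))
    entries = []
    seen = set()
    while len(entries) < n:
        seq = "".join(rng.choice(bases, size=length))
        if seq in seen:
            continue
        seen.add(seq)
        entries.append(Primer(name=f"P{len(entries) + 1:03d}", sequence=seq))
    return PrimerSet(entries=tuple(entries))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120313)


@pytest.fixture
def decamers(rng) -> PrimerSet:
    return random_decamers(rng, 5)


@pytest.fixture
def primer_file(tmp_path: Path) -> Path:
    path = tmp_path / "primers.fasta"
    path.write_text(">P1\nACGTACGTAC\n>P2\nGGGGGGGGGG\n")
    return path


@pytest.fixture
def target_file(tmp_path: Path) -> Path:
    path = tmp_path / "targets.fasta"
    path.write_text(
        ">seqA\nACGTACGTACGTACGT\n"
        ">seqB\nTTTTTTTTTTTTTTTTTTTT\n"
        ">seqC\nACGTRCGTAC\n"
    )
    return path
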