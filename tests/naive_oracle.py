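"""Independent brute-force references used to check the implementation.

Deliberately simple per-window loops, kept free of any rapdscan
internals so they can serve as oracles.
"""
from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_hits(pattern: str, target: str, max_mm: int) -> list[tuple[int, int]]:
    """Window-by-window Hamming scan: (1-based start, mismatches) pairs.

    N in the target is always a mismatch, matching the scanner's rule.
    """
    L = len(pattern)
    hits = []
    for s in range(len(target) - L + 1):
        mm = 0
        window = target[s : s + L]
        for a, b in zip(pattern, window):
            if b == "N" or a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append((s + 1, mm))
    return hits
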