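"""Small DNA string helpers shared by every module."""

from __future__ import annotations

import zlib

from amptile.errors import ParameterError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
DNA_ALPHABET = frozenset("ACGT")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence", allow_empty: bool = False) -> str:
    if not seq and not allow_empty:
        raise ParameterError(f"{name} must be non-empty")
    if set(seq) - DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ParameterError(f"{name} contains non-ACGT characters: {bad}")
    return seq


def stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a string, stable across processes.

    Used to derive per-molecule random streams from a library seed;
    Python's built-in hash() is salted per process and unusable here.
    """
    return zlib.crc32(text.encode("ascii")) & 0x7FFFFFFF


def homopolymer_runs(seq: str, run_min: int) -> list[tuple[int, int]]:
    """0-based half-open spans of single-base runs of length >= run_min."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= run_min:
            runs.append((i, j))
        i = j
    return runs
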