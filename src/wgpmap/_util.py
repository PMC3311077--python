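"""Small shared helpers: sequence arithmetic and exact tag placement search."""
from __future__ import annotations

from typing import Iterable

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT string of the given length."""
    if length <= 0:
        return ""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASE_LUT[codes].tobytes().decode("ascii")


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply uniform substitutions at the given per-base rate.

    A substituted base is always changed to a *different* base, so `rate`
    is the realized divergence, not 3/4 of it.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # map A,C,G,T -> 0..3, shift by 1..3 mod 4 so the base always changes
    code = np.zeros(256, dtype=np.uint8)
    code[ord("C")] = 1
    code[ord("G")] = 2
    code[ord("T")] = 3
    old = code[arr[hit]]
    new = (old + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    arr[hit] = _BASE_LUT[new]
    return arr.tobytes().decode("ascii")


def find_all(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) start positions of `pattern` in `seq`."""
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def has_homopolymer(seq: str, min_run: int = 5) -> bool:
    """True if `seq` contains a single-base run of at least `min_run` nt."""
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= min_run:
            return True
    return min_run <= 1 and len(seq) > 0


def exact_placements(
    tags: Iterable[str], ref_id: str, sequence: str
) -> dict[str, list[tuple[str, int, str]]]:
    """Full-length, 100%-identity placements of each tag on both strands.

    Returns tag -> list of (ref_id, position, strand) with `position` the
    0-based start of the match on the forward strand.  The search seeds on
    the 5-nt tag prefixes (tags share the restriction-site remnant), which
    keeps it linear in the reference length.
    """
    tagset = set(tags)
    lengths = sorted({len(t) for t in tagset if t})
    prefixes = {t[:5] for t in tagset if len(t) >= 5}
    hits: dict[str, list[tuple[str, int, str]]] = {t: [] for t in tagset}
    if not lengths or not prefixes:
        return hits
    n = len(sequence)
    rc = revcomp(sequence)
    for strand, seq in (("+", sequence), ("-", rc)):
        for pref in prefixes:
            for x in find_all(seq, pref):
                for ln in lengths:
                    cand = seq[x : x + ln]
                    if len(cand) == ln and cand in tagset:
                        pos = x if strand == "+" else n - x - ln
                        hits[cand].append((ref_id, pos, strand))
    for t in hits:
        hits[t].sort()
    return hits
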