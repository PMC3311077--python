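"""Synthetic data generation for sequence-tag (WGP) physical mapping.

Everything needed to exercise the pipeline without real data: repeat-rich
genomes (transposable-element copies duplicated from a small number of master
families, so that identical tags can arise from distinct loci), arrayed BAC
libraries on 384-well plates, in-silico EcoRI/MseI double digestion with
short sequence tags read inward from each EcoRI site, 3-D row/column/split-box
pooling, barcoded pooled reads with substitution errors, and fragmented
reference sequences standing in for draft shotgun assemblies.

All stochastic operations take an explicit integer seed; coordinates are
0-based, half-open throughout.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._util import find_all, mutate_sequence, random_sequence, revcomp

ECORI_SITE = "GAATTC"
MSEI_SITE = "TTAA"
ECORI_REMNANT = "AATTC"

PLATE_ROWS = 16
PLATE_COLS = 24
WELLS_PER_PLATE = PLATE_ROWS * PLATE_COLS

#: pools per 384-well plate: 8 row pools + 8 column pools + 6 split-box pools
POOLS_PER_PLATE = 22


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeModel:
    """A synthetic genome with annotated transposable-element intervals."""

    sequence: str
    te_intervals: list[tuple[int, int, int]]  # (start, end, family_id)
    te_fraction: float  # realized fraction, 0-1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BacClone:
    """One arrayed BAC clone; the insert is a slice of the source genome.

    ``insert_sequence`` is materialized lazily from the genome so that
    libraries of tens of thousands of 138-kb clones stay cheap to hold.
    A chimeric clone (QC fixture) carries a ``second_interval`` whose
    sequence is appended to the primary one.
    """

    clone_id: str
    plate: int
    well: tuple[int, int]  # (row 0-15, col 0-23)
    source_interval: tuple[int, int]
    second_interval: tuple[int, int] | None = None
    _genome: GenomeModel | None = field(default=None, repr=False, compare=False)

    @property
    def insert_sequence(self) -> str:
        if self._genome is None:
            raise ValueError(f"clone {self.clone_id} has no genome attached")
        s, e = self.source_interval
        seq = self._genome.sequence[s:e]
        if self.second_interval is not None:
            s2, e2 = self.second_interval
            seq += self._genome.sequence[s2:e2]
        return seq

    @property
    def insert_length(self) -> int:
        n = self.source_interval[1] - self.source_interval[0]
        if self.second_interval is not None:
            n += self.second_interval[1] - self.second_interval[0]
        return n

    @property
    def is_chimeric(self) -> bool:
        return self.second_interval is not None


@dataclass(frozen=True)
class WgpTag:
    """A short sequence tag anchored at an EcoRI site.

    ``tag_sequence`` starts with the AATTC remnant and reads inward from the
    cut; ``site_coordinate`` is the 0-based start of the GAATTC site on the
    digested sequence; ``side`` says which side of the site the tag covers.
    """

    tag_sequence: str
    site_coordinate: int
    side: str  # "left" | "right"


@dataclass(frozen=True)
class Pool:
    pool_id: str
    plate: int
    dimension: str  # "row" | "column" | "box"
    index: int
    members: tuple[str, ...]  # clone ids


@dataclass
class PoolSet:
    """The 3-D pooling design: row, column and split-box pools per plate."""

    pools: dict[str, Pool]
    well_of_clone: dict[str, tuple[int, int, int]]  # clone -> (plate,row,col)

    def pools_of_clone(self, clone_id: str) -> tuple[str, str, str]:
        plate, row, col = self.well_of_clone[clone_id]
        return (
            pool_id(plate, "row", row // 2),
            pool_id(plate, "column", col // 3),
            pool_id(plate, "box", (row % 2) * 3 + col % 3),
        )

    def clone_at(self, plate: int, row: int, col: int) -> str | None:
        return self._well_index.get((plate, row, col))

    @property
    def _well_index(self) -> dict[tuple[int, int, int], str]:
        idx = getattr(self, "_well_index_cache", None)
        if idx is None:
            idx = {w: c for c, w in self.well_of_clone.items()}
            object.__setattr__(self, "_well_index_cache", idx)
        return idx

    @property
    def plates(self) -> list[int]:
        return sorted({p.plate for p in self.pools.values()})


@dataclass(frozen=True)
class ReadRecord:
    """One pooled, barcoded sequencing read.

    The read is ``barcode + tag`` where the tag already starts with the
    EcoRI remnant (``remnant == tag[:5]`` on an error-free read); for a
    full-length tag ``len(barcode) + len(tag)`` equals the configured read
    length.  ``pool_id`` is simulation provenance, not parser input.
    """

    barcode: str
    remnant: str
    tag: str
    pool_id: str

    @property
    def sequence(self) -> str:
        return self.barcode + self.tag


@dataclass(frozen=True)
class SequencePiece:
    """A draft sequence contig cut from a reference, with its true placement."""

    piece_id: str
    sequence: str
    start: int
    end: int
    strand: str = "+"


def pool_id(plate: int, dimension: str, index: int) -> str:
    return f"p{plate:02d}_{dimension[0]}{index}"


# ---------------------------------------------------------------------------
# genome & library


def simulate_genome(
    length: int,
    te_fraction: float,
    n_families: int = 5,
    seed: int = 0,
    te_divergence: float = 0.02,
    family_length_range: tuple[int, int] = (800, 6000),
) -> GenomeModel:
    """Generate a genome with the requested transposable-element fraction.

    TE copies are per-copy mutated duplicates (default 2% divergence) of
    ``n_families`` master sequences, separated by exponentially distributed
    unique spacers, so repeat-derived tags collide across loci the way they
    do in a TE-rich genome.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0 <= te_fraction < 1:
        raise ValueError("te_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if te_fraction == 0:
        return GenomeModel(random_sequence(length, rng), [], 0.0)
    if n_families < 1:
        raise ValueError("n_families must be >= 1 when te_fraction > 0")

    lo, hi = family_length_range
    hi = min(hi, max(lo, length // 4))
    masters = [
        random_sequence(int(rng.integers(lo, hi + 1)), rng)
        for _ in range(n_families)
    ]
    mean_te = float(np.mean([len(m) for m in masters]))
    mean_spacer = max(1.0, mean_te * (1.0 - te_fraction) / te_fraction)

    pieces: list[str] = []
    intervals: list[tuple[int, int, int]] = []
    pos = 0
    while pos < length:
        spacer = int(rng.exponential(mean_spacer))
        if spacer:
            pieces.append(random_sequence(min(spacer, length - pos), rng))
            pos += len(pieces[-1])
        if pos >= length:
            break
        fam = int(rng.integers(n_families))
        copy = mutate_sequence(masters[fam], te_divergence, rng)
        end = min(pos + len(copy), length)
        pieces.append(copy[: end - pos])
        intervals.append((pos, end, fam))
        pos = end
    sequence = "".join(pieces)
    covered = sum(e - s for s, e, _ in intervals)
    return GenomeModel(sequence, intervals, covered / length)


def simulate_bac_library(
    genome: GenomeModel,
    n_clones: int,
    mean_insert: int = 138_000,
    sd_insert: int = 13_800,
    seed: int = 0,
    min_insert: int | None = None,
    chimera_fraction: float = 0.0,
) -> list[BacClone]:
    """Draw an arrayed BAC library with uniform starts and normal insert sizes.

    Clones fill 384-well plates in order.  ``chimera_fraction`` of clones are
    made chimeric (two intervals from independent loci concatenated), a QC
    fixture only.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if mean_insert <= 0:
        raise ValueError("mean_insert must be positive")
    n = len(genome)
    if mean_insert > n:
        raise ValueError(f"mean_insert {mean_insert} exceeds genome length {n}")
    if min_insert is None:
        min_insert = max(1000, mean_insert // 5)
    rng = np.random.default_rng(seed)
    sizes = rng.normal(mean_insert, sd_insert, size=n_clones)
    sizes = np.clip(np.rint(sizes), min(min_insert, n), n).astype(int)
    chimeric = rng.random(n_clones) < chimera_fraction
    clones = []
    for i in range(n_clones):
        size = int(sizes[i])
        idx = i % WELLS_PER_PLATE
        plate, row, col = i // WELLS_PER_PLATE, idx // PLATE_COLS, idx % PLATE_COLS
        if chimeric[i]:
            half = max(1, size // 2)
            s1 = int(rng.integers(0, n - half + 1))
            s2 = int(rng.integers(0, n - (size - half) + 1))
            clone = BacClone(
                clone_id=f"bac_{i:05d}",
                plate=plate,
                well=(row, col),
                source_interval=(s1, s1 + half),
                second_interval=(s2, s2 + size - half),
                _genome=genome,
            )
        else:
            start = int(rng.integers(0, n - size + 1))
            clone = BacClone(
                clone_id=f"bac_{i:05d}",
                plate=plate,
                well=(row, col),
                source_interval=(start, start + size),
                _genome=genome,
            )
        clones.append(clone)
    return clones


# ---------------------------------------------------------------------------
# digestion


def digest_and_tag(
    sequence: str, tag_length: int = 30, min_tag_length: int = 26
) -> list[WgpTag]:
    """In-silico EcoRI/MseI double digest yielding tags at EcoRI fragment ends.

    Each fragment end cut by EcoRI (G^AATTC) is read inward, starting with
    the AATTC remnant, up to ``tag_length`` nt; the read stops at the next
    cut (MseI T^TAA, another EcoRI site, or the end of the sequence).
    Fragments shorter than ``min_tag_length`` yield nothing; fragments in
    [min_tag_length, tag_length) yield truncated tags.  Cut coordinates are
    modeled on the strand being read, so digesting the reverse complement
    yields exactly the reverse-complemented tag set.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    n = len(sequence)
    eco = find_all(sequence, ECORI_SITE)
    if not eco:
        return []
    mse = find_all(sequence, MSEI_SITE)

    # cut boundaries seen by a rightward read: EcoRI top cut p+1, MseI top cut
    # m+1; by a leftward (bottom-strand) read: EcoRI bottom cut q+5, MseI
    # bottom cut m+3.  These pairs are exactly revcomp-symmetric.
    right_cuts = sorted([q + 1 for q in eco] + [m + 1 for m in mse] + [n])
    left_cuts = sorted([q + 5 for q in eco] + [m + 3 for m in mse] + [0])
    right_cuts_arr = np.asarray(right_cuts)
    left_cuts_arr = np.asarray(left_cuts)

    tags: list[WgpTag] = []
    for p in eco:
        # rightward tag: top strand from the cut at p+1
        i = int(np.searchsorted(right_cuts_arr, p + 1, side="right"))
        avail = int(right_cuts_arr[i]) - (p + 1) if i < len(right_cuts_arr) else 0
        if avail >= min_tag_length:
            ln = min(tag_length, avail)
            tags.append(WgpTag(sequence[p + 1 : p + 1 + ln], p, "right"))
        # leftward tag: bottom strand from the cut at p+5
        j = int(np.searchsorted(left_cuts_arr, p + 5, side="left")) - 1
        avail = (p + 5) - int(left_cuts_arr[j]) if j >= 0 else 0
        if avail >= min_tag_length:
            ln = min(tag_length, avail)
            tags.append(WgpTag(revcomp(sequence[p + 5 - ln : p + 5]), p, "left"))
    return tags


# ---------------------------------------------------------------------------
# pooling & reads


def build_pools(clones: list[BacClone]) -> PoolSet:
    """3-D pooling: per plate, 8 row pools (2 rows = 48 BACs), 8 column pools
    (3 columns = 48 BACs) and 6 split-box pools (one well of each 2x3 box,
    64 BACs), i.e. 22 pools per full plate; every clone sits in exactly one
    pool per dimension."""
    well_of_clone: dict[str, tuple[int, int, int]] = {}
    seen_wells: set[tuple[int, int, int]] = set()
    members: dict[str, list[str]] = {}
    meta: dict[str, tuple[int, str, int]] = {}
    for clone in clones:
        row, col = clone.well
        if not (0 <= row < PLATE_ROWS and 0 <= col < PLATE_COLS):
            raise ValueError(f"clone {clone.clone_id} has invalid well {clone.well}")
        key = (clone.plate, row, col)
        if key in seen_wells:
            raise ValueError(f"well {key} occupied by more than one clone")
        seen_wells.add(key)
        well_of_clone[clone.clone_id] = key
        for dim, idx in (
            ("row", row // 2),
            ("column", col // 3),
            ("box", (row % 2) * 3 + col % 3),
        ):
            pid = pool_id(clone.plate, dim, idx)
            members.setdefault(pid, []).append(clone.clone_id)
            meta[pid] = (clone.plate, dim, idx)
    pools = {
        pid: Pool(pid, plate, dim, idx, tuple(sorted(members[pid])))
        for pid, (plate, dim, idx) in meta.items()
    }
    return PoolSet(pools=pools, well_of_clone=well_of_clone)


def make_barcodes(pool_ids: list[str], length: int = 6, seed: int = 0) -> dict[str, str]:
    """Assign a distinct random barcode to every pool."""
    rng = np.random.default_rng(seed)
    barcodes: set[str] = set()
    out = {}
    for pid in sorted(pool_ids):
        while True:
            bc = random_sequence(length, rng)
            if bc not in barcodes:
                barcodes.add(bc)
                out[pid] = bc
                break
    return out


def simulate_reads(
    pools: PoolSet,
    tags_per_clone: dict[str, list[WgpTag]],
    read_length: int = 36,
    sub_error_rate: float = 0.0,
    barcode_map: dict[str, str] | None = None,
    seed: int = 0,
    depth: int = 1,
) -> list[ReadRecord]:
    """Emit barcode+tag reads for every (pool, member clone, tag) triple.

    Substitution errors are applied uniformly across the whole read at
    ``sub_error_rate``; ``depth`` reads are emitted per triple.
    """
    if barcode_map is None:
        barcode_map = make_barcodes(list(pools.pools), seed=seed)
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("barcode collision: barcodes must be distinct per pool")
    barcode_len = {len(b) for b in barcode_map.values()}
    if len(barcode_len) > 1:
        raise ValueError("all barcodes must have the same length")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    for pid in sorted(pools.pools):
        pool = pools.pools[pid]
        barcode = barcode_map[pid]
        for clone_id in pool.members:
            for tag in tags_per_clone.get(clone_id, []):
                for _ in range(depth):
                    raw = barcode + tag.tag_sequence
                    if len(raw) > read_length:
                        raw = raw[:read_length]
                    seq = mutate_sequence(raw, sub_error_rate, rng)
                    reads.append(
                        ReadRecord(
                            barcode=seq[: len(barcode)],
                            remnant=ECORI_REMNANT,
                            tag=seq[len(barcode) :],
                            pool_id=pid,
                        )
                    )
    return reads


# ---------------------------------------------------------------------------
# reference fragmentation (draft-assembly stand-in)


def fragment_reference(
    reference: str,
    n_pieces: int,
    gap_fraction: float,
    seed: int = 0,
) -> list[SequencePiece]:
    """Cut a reference into ordered, non-overlapping pieces with gaps.

    ``gap_fraction`` of the reference is withheld as inter-piece gaps
    (randomly apportioned between the pieces); the true coordinates of every
    piece are recorded so scaffolding results can be scored against truth.
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    n = len(reference)
    if n < 2 * n_pieces:
        raise ValueError("reference too short for the requested piece count")
    rng = np.random.default_rng(seed)
    total_gap = int(round(gap_fraction * n))
    n_gaps = n_pieces - 1
    if n_gaps == 0:
        total_gap = 0
    gap_sizes = (
        rng.multinomial(total_gap, np.full(n_gaps, 1.0 / n_gaps)).astype(int)
        if n_gaps and total_gap
        else np.zeros(max(n_gaps, 1), dtype=int)
    )
    remaining = n - total_gap
    piece_sizes = 1 + rng.multinomial(
        remaining - n_pieces, np.full(n_pieces, 1.0 / n_pieces)
    ).astype(int)
    pieces = []
    pos = 0
    for i in range(n_pieces):
        size = int(piece_sizes[i])
        pieces.append(
            SequencePiece(
                piece_id=f"piece_{i:04d}",
                sequence=reference[pos : pos + size],
                start=pos,
                end=pos + size,
            )
        )
        pos += size
        if i < n_gaps:
            pos += int(gap_sizes[i])
    return pieces


def clone_tags(
    clones: list[BacClone], tag_length: int = 30, min_tag_length: int = 26
) -> dict[str, list[WgpTag]]:
    """Digest every clone insert; returns clone_id -> tag list."""
    return {
        c.clone_id: digest_and_tag(c.insert_sequence, tag_length, min_tag_length)
        for c in clones
    }
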