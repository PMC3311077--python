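"""3-D pool deconvolution and tag/BAC filtering.

A tag observed in pooled sequencing is assigned to a single well of a plate
if and only if, within that plate, it occurs in exactly one row pool, one
column pool and one split-box pool: the intersection of those three pools is
a unique well.  Tags seen in more pools (two clones of the same plate, or a
repeat shared across wells) are discarded for that plate as ambiguous; plates
are deconvoluted independently, so a tag can legitimately be assigned to one
BAC per plate.  Downstream filters mirror the standard processing chain:
contaminant screen, homopolymer screen, single-BAC ("uninformative") tags,
promiscuous tags (> max_bacs BACs), then per-BAC fingerprint size filters.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._util import has_homopolymer, revcomp
from .simulate import ECORI_REMNANT, PoolSet, ReadRecord


@dataclass
class TagAssignment:
    """tag sequence -> set of clone ids, plus summary statistics."""

    tag_clones: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def clone_tags(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tag, clones in self.tag_clones.items():
            for c in clones:
                out.setdefault(c, set()).add(tag)
        return out

    @property
    def total_tags(self) -> int:
        return sum(len(c) for c in self.tag_clones.values())

    @property
    def unique_tags(self) -> int:
        return len(self.tag_clones)

    @property
    def n_bacs(self) -> int:
        return len({c for cl in self.tag_clones.values() for c in cl})

    @property
    def mean_tags_per_bac(self) -> float:
        return self.total_tags / self.n_bacs if self.n_bacs else 0.0

    @property
    def mean_bacs_per_tag(self) -> float:
        return self.total_tags / self.unique_tags if self.unique_tags else 0.0


@dataclass
class FilterReport:
    """Per-stage removal counts; stages sum to (input - output)."""

    stage_counts: dict[str, int]
    input_count: int
    output_count: int

    @property
    def total_removed(self) -> int:
        return sum(self.stage_counts.values())


@dataclass
class DeconvolutionStats:
    n_observations: int = 0  # (tag, plate) incidence pairs
    n_assigned: int = 0
    n_ambiguous: int = 0  # >1 pool in some dimension within a plate
    n_incomplete: int = 0  # seen in only 1 or 2 dimensions
    n_empty_well: int = 0  # resolved to an unoccupied well

    @property
    def deconvoluted_fraction(self) -> float:
        if self.n_observations == 0:
            return 0.0
        return self.n_assigned / self.n_observations


def mean_per_unit(total: float, units: float, ndigits: int = 1) -> float:
    """Mean count per unit, rounded the way the summary tables print it."""
    if units == 0:
        return 0.0
    return round(total / units, ndigits)


def parse_reads(
    reads: list[ReadRecord],
    barcode_map: dict[str, str],
    remnant: str = ECORI_REMNANT,
) -> tuple[dict[str, Counter], dict[str, int | float]]:
    """Bin reads by pool via exact barcode match; drop invalid reads.

    A read is valid iff its barcode matches a pool barcode exactly and its
    tag starts with the expected restriction-site remnant.  Returns per-pool
    tag multisets (Counter) and validity statistics.
    """
    pool_of_barcode = {bc: pid for pid, bc in barcode_map.items()}
    if len(pool_of_barcode) != len(barcode_map):
        raise ValueError("barcode collision in barcode_map")
    pool_tags: dict[str, Counter] = {pid: Counter() for pid in barcode_map}
    n_valid = 0
    n_bad_barcode = 0
    n_bad_remnant = 0
    for read in reads:
        pid = pool_of_barcode.get(read.barcode)
        if pid is None:
            n_bad_barcode += 1
            continue
        if not read.tag.startswith(remnant):
            n_bad_remnant += 1
            continue
        pool_tags[pid][read.tag] += 1
        n_valid += 1
    total = len(reads)
    stats = {
        "total_reads": total,
        "valid_reads": n_valid,
        "bad_barcode": n_bad_barcode,
        "bad_remnant": n_bad_remnant,
        "valid_fraction": n_valid / total if total else 0.0,
    }
    return pool_tags, stats


def deconvolute(
    pool_tags: dict[str, Counter | set],
    pools: PoolSet,
    min_reads: int = 1,
) -> tuple[TagAssignment, DeconvolutionStats]:
    """Assign pooled tag observations to individual BACs, plate by plate."""
    unknown = set(pool_tags) - set(pools.pools)
    if unknown:
        raise ValueError(f"pool ids not in pool set: {sorted(unknown)[:5]}")
    stats = DeconvolutionStats()
    # tag -> plate -> dimension -> set of pool indices
    seen: dict[str, dict[int, dict[str, set[int]]]] = {}
    for pid, tags in pool_tags.items():
        pool = pools.pools[pid]
        items = tags.items() if isinstance(tags, Counter) else ((t, 1) for t in tags)
        for tag, count in items:
            if count < min_reads:
                continue
            seen.setdefault(tag, {}).setdefault(pool.plate, {}).setdefault(
                pool.dimension, set()
            ).add(pool.index)

    assignment: dict[str, set[str]] = {}
    for tag in sorted(seen):
        for plate in sorted(seen[tag]):
            dims = seen[tag][plate]
            stats.n_observations += 1
            if len(dims) < 3:
                stats.n_incomplete += 1
                continue
            if any(len(v) > 1 for v in dims.values()):
                stats.n_ambiguous += 1
                continue
            (r,) = dims["row"]
            (c,) = dims["column"]
            (b,) = dims["box"]
            row = 2 * r + b // 3
            col = 3 * c + b % 3
            clone = pools.clone_at(plate, row, col)
            if clone is None:
                stats.n_empty_well += 1
                continue
            assignment.setdefault(tag, set()).add(clone)
            stats.n_assigned += 1
    return (
        TagAssignment({t: frozenset(cl) for t, cl in assignment.items()}),
        stats,
    )


def filter_tags(
    assignment: TagAssignment,
    contaminants: list[str] | None = None,
    max_bacs: int = 12,
    min_homopolymer: int = 5,
) -> tuple[TagAssignment, FilterReport]:
    """Tag-level filters, applied in a fixed order.

    1. tags matching a contaminant sequence window (exact substring of the
       vector/host/chloroplast screen, either strand);
    2. tags containing a homopolymer run >= ``min_homopolymer`` nt;
    3. tags present in exactly one BAC (uninformative);
    4. tags present in more than ``max_bacs`` BACs (ambiguity-prone).

    Idempotent: applying the filter to its own output changes nothing.
    """
    blob = ""
    if contaminants:
        parts = []
        for seq in contaminants:
            parts.append(seq.upper())
            parts.append(revcomp(seq.upper()))
        blob = "N".join(parts)
    stages = {"contaminant": 0, "homopolymer": 0, "single_bac": 0, "max_bacs": 0}
    kept: dict[str, frozenset[str]] = {}
    for tag, clones in assignment.tag_clones.items():
        if blob and tag in blob:
            stages["contaminant"] += 1
        elif has_homopolymer(tag, min_homopolymer):
            stages["homopolymer"] += 1
        elif len(clones) == 1:
            stages["single_bac"] += 1
        elif len(clones) > max_bacs:
            stages["max_bacs"] += 1
        else:
            kept[tag] = clones
    report = FilterReport(
        stage_counts=stages,
        input_count=assignment.unique_tags,
        output_count=len(kept),
    )
    return TagAssignment(kept), report


def filter_bacs(
    assignment: TagAssignment,
    low_frac: float = 0.30,
    high_mult: float = 2.5,
    low_abs: int | None = None,
    high_abs: int | None = None,
) -> tuple[TagAssignment, FilterReport]:
    """BAC-level fingerprint size filter.

    Relative mode (default): remove BACs whose tag count is below
    ``low_frac`` x mean or above ``high_mult`` x mean, the mean being
    computed on the assignment as given (i.e. after tag filtering).
    Absolute mode: pass ``low_abs``/``high_abs`` to remove BACs with
    count <= low_abs or >= high_abs (the published <=4 / >=40 convention).
    Stage counts are in BACs removed.
    """
    if not assignment.tag_clones:
        raise ValueError("cannot filter BACs of an empty assignment")
    counts = {c: len(t) for c, t in assignment.clone_tags.items()}
    mean = assignment.mean_tags_per_bac
    removed_low = set()
    removed_high = set()
    for clone, count in counts.items():
        if low_abs is not None or high_abs is not None:
            if low_abs is not None and count <= low_abs:
                removed_low.add(clone)
            elif high_abs is not None and count >= high_abs:
                removed_high.add(clone)
        else:
            if count < low_frac * mean:
                removed_low.add(clone)
            elif count > high_mult * mean:
                removed_high.add(clone)
    removed = removed_low | removed_high
    kept: dict[str, frozenset[str]] = {}
    for tag, clones in assignment.tag_clones.items():
        left = clones - removed
        if left:
            kept[tag] = frozenset(left)
    report = FilterReport(
        stage_counts={"low_tag_bacs": len(removed_low), "high_tag_bacs": len(removed_high)},
        input_count=len(counts),
        output_count=len(counts) - len(removed),
    )
    return TagAssignment(kept), report


def summarize_assignment(assignment: TagAssignment) -> dict[str, float]:
    """Summary-table statistics for an assignment (totals and 1-dp means)."""
    total = assignment.total_tags
    unique = assignment.unique_tags
    n_bacs = assignment.n_bacs
    lengths = [len(t) for t in assignment.tag_clones]
    return {
        "total_tags": total,
        "unique_tags": unique,
        "mean_tag_length": mean_per_unit(sum(lengths), len(lengths)),
        "n_bacs_with_tags": n_bacs,
        "mean_tags_per_bac": mean_per_unit(total, n_bacs),
        "mean_bacs_per_tag": mean_per_unit(total, unique),
    }
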