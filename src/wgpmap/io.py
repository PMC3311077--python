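"""File formats: FASTA/FASTQ via Biopython, versioned TSV tables, BED,
AGP v2 export of superscaffolds, and YAML run configuration.

TSV tables carry a ``# wgpmap <kind> v1`` comment header followed by a
column-name row; readers validate the kind and report malformed records with
their line number.  Plain and gzip-compressed files are both accepted.
"""
from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import PhysicalMap
from .scaffold import SuperScaffold
from .simulate import Pool, PoolSet, ReadRecord, WgpTag

TSV_VERSION = 1


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """Malformed record; carries the offending file and line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read FASTA (wrapped lines and CRLF tolerated) into id -> sequence."""
    with _open(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise FormatError(path, 1, "no FASTA records found")
    return records


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_fastq(path, reads: list[ReadRecord], quality: int = 40) -> None:
    """Write reads as FASTQ with a constant quality."""
    with _open(path, "wt") as fh:
        for i, read in enumerate(reads):
            rec = SeqRecord(
                Seq(read.sequence),
                id=f"read_{i:08d}",
                description=read.pool_id,
            )
            rec.letter_annotations["phred_quality"] = [quality] * len(read.sequence)
            SeqIO.write(rec, fh, "fastq")


# ---------------------------------------------------------------------------
# generic versioned TSV


def _write_tsv(path, kind: str, columns: list[str], rows) -> None:
    with _open(path, "wt") as fh:
        fh.write(f"# wgpmap {kind} v{TSV_VERSION}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _read_tsv(path, kind: str, n_columns: int):
    rows = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\r\n")
        if not header.startswith(f"# wgpmap {kind} "):
            raise FormatError(path, 1, f"expected a 'wgpmap {kind}' TSV header")
        fh.readline()  # column names
        for line_no, line in enumerate(fh, start=3):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_columns:
                raise FormatError(
                    path, line_no, f"expected {n_columns} columns, got {len(parts)}"
                )
            rows.append((line_no, parts))
    return rows


# ---------------------------------------------------------------------------
# concrete tables


def write_tags_tsv(path, tags_per_clone: dict[str, list[WgpTag]]) -> None:
    rows = [
        (cid, t.tag_sequence, t.site_coordinate, t.side)
        for cid in sorted(tags_per_clone)
        for t in tags_per_clone[cid]
    ]
    _write_tsv(path, "tags", ["clone_id", "tag_sequence", "site_coordinate", "side"], rows)


def read_tags_tsv(path) -> dict[str, list[WgpTag]]:
    out: dict[str, list[WgpTag]] = {}
    for line_no, (cid, seq, coord, side) in _read_tsv(path, "tags", 4):
        if side not in ("left", "right"):
            raise FormatError(path, line_no, f"bad side {side!r}")
        try:
            coord = int(coord)
        except ValueError:
            raise FormatError(path, line_no, f"bad coordinate {coord!r}") from None
        out.setdefault(cid, []).append(WgpTag(seq, coord, side))
    return out


def write_pools_tsv(path, pools: PoolSet) -> None:
    rows = []
    for pid in sorted(pools.pools):
        p = pools.pools[pid]
        rows.append((pid, p.plate, p.dimension, p.index, ",".join(p.members)))
    _write_tsv(path, "pools", ["pool_id", "plate", "dimension", "index", "members"], rows)
    # wells are recoverable from clone ids via a side table
    well_rows = [
        (cid, plate, row, col)
        for cid, (plate, row, col) in sorted(pools.well_of_clone.items())
    ]
    _write_tsv(
        Path(str(path) + ".wells"),
        "wells",
        ["clone_id", "plate", "row", "col"],
        well_rows,
    )


def read_pools_tsv(path) -> PoolSet:
    pools = {}
    for line_no, (pid, plate, dim, idx, members) in _read_tsv(path, "pools", 5):
        try:
            plate, idx = int(plate), int(idx)
        except ValueError:
            raise FormatError(path, line_no, "plate/index must be integers") from None
        pools[pid] = Pool(pid, plate, dim, idx, tuple(members.split(",")) if members else ())
    wells = {}
    for line_no, (cid, plate, row, col) in _read_tsv(
        Path(str(path) + ".wells"), "wells", 4
    ):
        wells[cid] = (int(plate), int(row), int(col))
    return PoolSet(pools=pools, well_of_clone=wells)


def write_reads_tsv(path, reads: list[ReadRecord]) -> None:
    rows = [(r.barcode, r.remnant, r.tag, r.pool_id) for r in reads]
    _write_tsv(path, "reads", ["barcode", "remnant", "tag", "pool_id"], rows)


def read_reads_tsv(path) -> list[ReadRecord]:
    return [
        ReadRecord(bc, rem, tag, pid)
        for _, (bc, rem, tag, pid) in _read_tsv(path, "reads", 4)
    ]


def write_barcodes_tsv(path, barcode_map: dict[str, str]) -> None:
    _write_tsv(
        path, "barcodes", ["pool_id", "barcode"], sorted(barcode_map.items())
    )


def read_barcodes_tsv(path) -> dict[str, str]:
    return {pid: bc for _, (pid, bc) in _read_tsv(path, "barcodes", 2)}


def write_assignment_tsv(path, assignment) -> None:
    rows = [
        (tag, cid)
        for tag in sorted(assignment.tag_clones)
        for cid in sorted(assignment.tag_clones[tag])
    ]
    _write_tsv(path, "assignment", ["tag_sequence", "clone_id"], rows)


def read_assignment_tsv(path):
    from .deconvolution import TagAssignment

    acc: dict[str, set[str]] = {}
    for _, (tag, cid) in _read_tsv(path, "assignment", 2):
        acc.setdefault(tag, set()).add(cid)
    return TagAssignment({t: frozenset(c) for t, c in acc.items()})


def write_map_tsv(path, pmap: PhysicalMap) -> None:
    rows = []
    for contig in pmap.contigs:
        for pos, cid in enumerate(contig.order):
            q = "Q" if cid in contig.q_clones else "."
            rows.append((contig.contig_id, pos, cid, contig.offsets[cid], q))
    for cid in sorted(pmap.singletons):
        rows.append(("singleton", 0, cid, 0.0, "."))
    _write_tsv(
        path, "map", ["contig_id", "position", "clone_id", "offset_cb", "flag"], rows
    )


def write_cbmap_tsv(path, pmap: PhysicalMap) -> None:
    rows = [
        (contig.contig_id, slot, band)
        for contig in pmap.contigs
        for slot, band in enumerate(contig.cb_order)
    ]
    _write_tsv(path, "cbmap", ["contig_id", "slot", "band"], rows)


def write_steps_tsv(path, steps) -> None:
    rows = [
        (s.cutoff, s.n_contigs, s.n_singletons, s.n_q_clones, s.n_q_clones_pre_dq, s.length_cb)
        for s in steps
    ]
    _write_tsv(
        path,
        "steps",
        ["cutoff", "n_contigs", "n_singletons", "n_q_clones", "n_q_clones_pre_dq", "length_cb"],
        rows,
    )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """0-based half-open BED intervals (chrom, start, end, name)."""
    out = []
    with _open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, line_no, "BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, line_no, "BED coordinates must be integers") from None
            if start < 0 or end <= start:
                raise FormatError(
                    path, line_no, f"invalid half-open interval [{start}, {end})"
                )
            out.append((chrom, start, end, parts[3] if len(parts) > 3 else ""))
    return out


# ---------------------------------------------------------------------------
# AGP v2 + spacer FASTA for superscaffolds


def superscaffold_agp(
    sscs: list[SuperScaffold],
    contig_lengths: dict[str, int],
    gap_size: int = 100,
) -> list[tuple]:
    """AGP v2 rows for superscaffolds; gaps are type U (unknown size).

    Contigs within an unordered bin are emitted consecutively with U gaps;
    their ambiguity lives in the linkage-evidence column ("within-bin order
    unknown" is not expressible in AGP, so bins are flattened)."""
    rows = []
    for ssc in sscs:
        pos = 0
        part = 0
        comps = [
            (cid, orient)
            for b in ssc.elements
            for cid, orient in b
            if cid in contig_lengths
        ]
        for k, (cid, orient) in enumerate(comps):
            if k > 0:
                part += 1
                rows.append(
                    (ssc.ssc_id, pos + 1, pos + gap_size, part, "U",
                     gap_size, "scaffold", "yes", "map")
                )
                pos += gap_size
            ln = contig_lengths[cid]
            part += 1
            rows.append(
                (ssc.ssc_id, pos + 1, pos + ln, part, "W", cid, 1, ln, orient)
            )
            pos += ln
    validate_agp(rows)
    return rows


def validate_agp(rows) -> None:
    """Coordinate sanity of AGP rows: 1-based, contiguous, consistent parts."""
    by_obj: dict[str, list] = {}
    for row in rows:
        by_obj.setdefault(row[0], []).append(row)
    for obj, obj_rows in by_obj.items():
        expect_beg = 1
        for i, row in enumerate(obj_rows, start=1):
            _, beg, end, part, kind = row[:5]
            if beg != expect_beg:
                raise ValueError(f"{obj}: part {part} starts at {beg}, expected {expect_beg}")
            if end < beg:
                raise ValueError(f"{obj}: part {part} has end < beg")
            if part != i:
                raise ValueError(f"{obj}: part numbers not consecutive")
            if kind == "W":
                comp_beg, comp_end = row[6], row[7]
                if comp_end - comp_beg != end - beg:
                    raise ValueError(f"{obj}: component span mismatch in part {part}")
            expect_beg = end + 1


def write_agp(path, rows) -> None:
    with _open(path, "wt") as fh:
        fh.write("##agp-version\t2.0\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def superscaffold_fasta(
    sscs: list[SuperScaffold],
    contigs: dict[str, str],
    gap_size: int = 100,
) -> dict[str, str]:
    """Superscaffold sequences with fixed-size N spacers (flagged unsized in
    the AGP; the spacer length is a convention, not an estimate)."""
    from ._util import revcomp

    out = {}
    for ssc in sscs:
        parts = []
        for b in ssc.elements:
            for cid, orient in b:
                if cid not in contigs:
                    continue
                seq = contigs[cid]
                parts.append(revcomp(seq) if orient == "-" else seq)
        out[ssc.ssc_id] = ("N" * gap_size).join(parts)
    return out


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Single source of truth for pipeline thresholds and paths."""

    seed: int = 1
    genome: dict = field(
        default_factory=lambda: {
            "length": 1_000_000,
            "te_fraction": 0.0,
            "n_families": 5,
        }
    )
    library: dict = field(
        default_factory=lambda: {
            "n_clones": 384,
            "mean_insert": 138_000,
            "sd_insert": 13_800,
        }
    )
    reads: dict = field(
        default_factory=lambda: {
            "read_length": 36,
            "tag_length": 30,
            "sub_error_rate": 0.0,
            "depth": 1,
        }
    )
    filters: dict = field(
        default_factory=lambda: {
            "max_bacs": 12,
            "min_homopolymer": 5,
            "low_frac": 0.30,
            "high_mult": 2.5,
        }
    )
    assembly: dict = field(
        default_factory=lambda: {
            "gellen": 110_000,
            "tolerance": 0,
            "from_end": 8,
            "final_exponent": 11,
            "dq_max_q": 0.10,
            "dq_step": 3,
            "match": 1,
        }
    )
    evaluation: dict = field(
        default_factory=lambda: {"window": 50_000, "step": 10_000, "cb_unit_kb": 6.1}
    )
    scaffolding: dict = field(default_factory=lambda: {"min_tags": 2, "min_sites": 2})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        base = cls()
        for key, value in data.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(base, key)
            if isinstance(current, dict):
                unknown = set(value) - set(current)
                if unknown:
                    raise ValueError(f"unknown config keys under {key}: {sorted(unknown)}")
                current.update(value)
            else:
                setattr(base, key, value)
        return base


def load_config(path) -> RunConfig:
    with _open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with _open(path, "wt") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_json(path, data) -> None:
    with _open(path, "wt") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
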