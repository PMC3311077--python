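"""Integration of WGP tags into draft sequence assemblies.

Sequence contigs are linked to the physical map through exact tag placements:
a sequence contig is eligible when at least two distinct tags from two
distinct restriction sites tie it to one physical (WGP) contig or singleton.
Sequence contigs on the same WGP contig are ordered by the mean consensus-band
position of their supporting tags; unresolvable orders are grouped into
unordered bins, inter-element gaps are unsized, and large sequence contigs
spanning several WGP contigs order those contigs in turn.  Tag placements also
route pooled sequence scaffolds back to their BAC (and physical contig) of
origin.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from ._util import exact_placements
from .assembly import PhysicalMap
from .deconvolution import TagAssignment

__all__ = [
    "TagPlacement",
    "SuperScaffold",
    "place_tags",
    "link_contigs",
    "assign_scaffolds_to_bacs",
    "evaluate_superscaffold",
]


@dataclass(frozen=True)
class TagPlacement:
    """Full-length exact placement of a tag on a sequence contig."""

    tag_sequence: str
    sequence_contig_id: str
    position: int
    strand: str
    site_id: tuple[str, int]  # (contig id, EcoRI site coordinate)
    multi: bool = False  # tag places at more than one locus


@dataclass
class SuperScaffold:
    """Ordered elements; each element is a bin of one or more sequence contigs
    (a bin of size > 1 means the internal order is ambiguous).  Gaps between
    elements are unsized.  Provenance records the WGP contigs and supporting
    tag counts behind the links."""

    ssc_id: str
    elements: list  # list of bins; bin = list of (seq_contig_id, orientation)
    wgp_units: list = field(default_factory=list)
    support: dict = field(default_factory=dict)  # seq contig -> n tags

    @property
    def contig_ids(self) -> list:
        return [cid for b in self.elements for cid, _ in b]

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def place_tags(
    tags, sequence_contigs: dict[str, str]
) -> list[TagPlacement]:
    """Exact full-length placements on both strands; multi-hit tags marked.

    The restriction-site id is derived from the placement: a '+' hit at x
    puts the EcoRI site at x - 1, a '-' hit of an L-nt tag at x puts it at
    x + L - 5 (the remnant sits at the far end on the other strand).
    """
    tags = set(tags)
    placements: list[TagPlacement] = []
    per_tag: dict[str, list[tuple[str, int, str]]] = {t: [] for t in tags}
    for cid, seq in sequence_contigs.items():
        hits = exact_placements(tags, cid, seq.upper())
        for t, places in hits.items():
            per_tag[t].extend(places)
    for tag in sorted(per_tag):
        places = sorted(per_tag[tag])
        multi = len(places) > 1
        for cid, pos, strand in places:
            site = pos - 1 if strand == "+" else pos + len(tag) - 5
            placements.append(
                TagPlacement(tag, cid, pos, strand, (cid, site), multi)
            )
    return placements


def _tag_slot_positions(pmap: PhysicalMap) -> dict[int, dict]:
    """Per WGP contig: band -> consensus slot index."""
    return {
        contig.contig_id: {band: i for i, band in enumerate(contig.cb_order)}
        for contig in pmap.contigs
    }


def link_contigs(
    placements: list[TagPlacement],
    physical_map: PhysicalMap,
    assignment: TagAssignment,
    min_tags: int = 2,
    min_sites: int = 2,
) -> tuple[list[SuperScaffold], list[dict]]:
    """Link sequence contigs into superscaffolds via the physical map.

    A (sequence contig, WGP unit) link is eligible with >= ``min_tags``
    distinct supporting tags from >= ``min_sites`` distinct restriction
    sites; a WGP unit is a physical contig or a singleton clone.  Sequence
    contigs on one WGP contig are ordered by the mean consensus-slot position
    of their supporting tags (clone offsets as fallback); exact ties share an
    unordered bin.  Sequence contigs eligible to several WGP contigs vote on
    the relative order of those contigs; conflicting votes drop the weaker
    link (ties drop both) and are reported.  Iterates to a fixpoint.
    """
    contig_of_clone = physical_map.contig_of()
    slot_of = _tag_slot_positions(physical_map)
    offsets = {c.contig_id: c.offsets for c in physical_map.contigs}

    # collect support: (seq contig, wgp unit) -> {tags, sites, positions, strands}
    support: dict[tuple[str, object], dict] = defaultdict(
        lambda: {"tags": set(), "sites": set(), "slots": [], "strands": [], "pos": []}
    )
    for pl in placements:
        clones = assignment.tag_clones.get(pl.tag_sequence, ())
        units = set()
        for clone in clones:
            if clone in contig_of_clone:
                units.add(("contig", contig_of_clone[clone]))
            elif clone in physical_map.singletons:
                units.add(("singleton", clone))
        for unit in units:
            rec = support[(pl.sequence_contig_id, unit)]
            rec["tags"].add(pl.tag_sequence)
            rec["sites"].add(pl.site_id)
            rec["strands"].append(pl.strand)
            rec["pos"].append(pl.position)
            if unit[0] == "contig":
                slots = slot_of.get(unit[1], {})
                if pl.tag_sequence in slots:
                    rec["slots"].append(float(slots[pl.tag_sequence]))
                else:
                    offs = offsets.get(unit[1], {})
                    vals = [offs[c] for c in clones if c in offs]
                    if vals:
                        rec["slots"].append(sum(vals) / len(vals))

    eligible = {
        key: rec
        for key, rec in support.items()
        if len(rec["tags"]) >= min_tags and len(rec["sites"]) >= min_sites
    }

    # group eligible sequence contigs per WGP unit
    by_unit: dict[object, list[str]] = defaultdict(list)
    for (seq_id, unit), _ in sorted(eligible.items(), key=lambda kv: str(kv[0])):
        by_unit[unit].append(seq_id)

    # relative order of WGP contigs voted by bridging sequence contigs
    bridge_votes: dict[tuple, dict] = {}
    conflicts: list[dict] = []
    seq_units: dict[str, list] = defaultdict(list)
    for seq_id, unit in eligible:
        seq_units[seq_id].append(unit)
    for seq_id, units in seq_units.items():
        contig_units = [u for u in units if u[0] == "contig"]
        if len(contig_units) < 2:
            continue
        pos_of = {
            u: sum(eligible[(seq_id, u)]["pos"]) / len(eligible[(seq_id, u)]["pos"])
            for u in contig_units
        }
        ordered = sorted(contig_units, key=lambda u: pos_of[u])
        for ua, ub in zip(ordered, ordered[1:]):
            key = tuple(sorted((ua[1], ub[1])))
            weight = min(
                len(eligible[(seq_id, ua)]["tags"]),
                len(eligible[(seq_id, ub)]["tags"]),
            )
            vote = (ua[1], ub[1])
            rec = bridge_votes.setdefault(key, {})
            rec[vote] = rec.get(vote, 0) + weight

    # resolve votes into a partial order over WGP contigs
    order_edges: dict[tuple[int, int], int] = {}
    for key, votes in bridge_votes.items():
        if len(votes) == 1:
            (vote, w), = votes.items()
            order_edges[vote] = w
        else:
            (va, wa), (vb, wb) = sorted(votes.items(), key=lambda kv: -kv[1])
            if wa == wb:
                conflicts.append(
                    {"kind": "order_tie", "units": key, "votes": dict(votes)}
                )
            else:
                conflicts.append(
                    {"kind": "order_conflict", "units": key, "votes": dict(votes)}
                )
                order_edges[va] = wa

    # chain WGP contigs connected by order edges (fixpoint is immediate:
    # the vote set is computed once from all eligible links)
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(u[1] for u in by_unit if u[0] == "contig")
    for (a, b), w in order_edges.items():
        g.add_edge(a, b, weight=w)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: g.edges[e]["weight"])
        conflicts.append(
            {"kind": "order_cycle", "units": tuple(weakest), "votes": {}}
        )
        g.remove_edge(*weakest)

    superscaffolds: list[SuperScaffold] = []
    ssc_idx = 0
    seen_units: set = set()
    for comp in sorted(
        (sorted(c) for c in nx.weakly_connected_components(g)), key=str
    ):
        unit_order = [u for u in nx.topological_sort(g.subgraph(comp))]
        elements: list = []
        units_used = []
        sup: dict[str, int] = {}
        for unit_id in unit_order:
            unit = ("contig", unit_id)
            seen_units.add(unit)
            units_used.append(unit_id)
            elements.extend(_order_on_unit(unit, by_unit[unit], eligible))
            for seq_id in by_unit[unit]:
                sup[seq_id] = len(eligible[(seq_id, unit)]["tags"])
        if elements:
            superscaffolds.append(
                SuperScaffold(f"ssc_{ssc_idx:04d}", elements, units_used, sup)
            )
            ssc_idx += 1
    for unit in sorted(by_unit, key=str):
        if unit in seen_units or unit[0] != "singleton":
            continue
        elements = _order_on_unit(unit, by_unit[unit], eligible)
        if elements:
            sup = {s: len(eligible[(s, unit)]["tags"]) for s in by_unit[unit]}
            superscaffolds.append(
                SuperScaffold(f"ssc_{ssc_idx:04d}", elements, [unit[1]], sup)
            )
            ssc_idx += 1
    return superscaffolds, conflicts


def _order_on_unit(unit, seq_ids: list[str], eligible: dict) -> list:
    """Order sequence contigs along one WGP unit; ties become bins."""
    keyed = []
    for seq_id in seq_ids:
        rec = eligible[(seq_id, unit)]
        if rec["slots"]:
            pos = sum(rec["slots"]) / len(rec["slots"])
        else:
            pos = 0.0  # singleton unit: no internal coordinates
        strands = Counter(rec["strands"])
        orient = "+" if strands.get("+", 0) >= strands.get("-", 0) else "-"
        keyed.append((pos, seq_id, orient))
    keyed.sort(key=lambda t: (t[0], t[1]))
    elements: list = []
    current_bin: list = []
    current_pos = None
    for pos, seq_id, orient in keyed:
        if current_pos is not None and math.isclose(pos, current_pos):
            current_bin.append((seq_id, orient))
        else:
            if current_bin:
                elements.append(current_bin)
            current_bin = [(seq_id, orient)]
            current_pos = pos
    if current_bin:
        elements.append(current_bin)
    return elements


def assign_scaffolds_to_bacs(
    placements: list[TagPlacement],
    assignment: TagAssignment,
    min_tags: int = 2,
) -> tuple[dict[str, set[str]], list[str]]:
    """Assign each sequence scaffold to the BAC(s) contributing >= min_tags
    placed tags; scaffolds with no qualifying BAC are reported unassigned."""
    votes: dict[str, Counter] = defaultdict(Counter)
    scaffolds = set()
    for pl in placements:
        scaffolds.add(pl.sequence_contig_id)
        for clone in assignment.tag_clones.get(pl.tag_sequence, ()):
            votes[pl.sequence_contig_id][clone] += 1
    assigned: dict[str, set[str]] = {}
    unassigned: list[str] = []
    for sid in sorted(scaffolds):
        clones = {c for c, n in votes.get(sid, {}).items() if n >= min_tags}
        if clones:
            assigned[sid] = clones
        else:
            unassigned.append(sid)
    return assigned, unassigned


def evaluate_superscaffold(
    ssc: SuperScaffold, truth_positions: dict[str, float]
) -> float:
    """Percentage of ordered adjacencies contradicting the true order.

    Bin-to-bin adjacencies are checked (contigs within a bin are unordered by
    construction); the whole superscaffold may be reversed, so the error is
    the minimum over both global orientations.  Contigs missing from the
    truth table are skipped.
    """
    bins = [
        [cid for cid, _ in b if cid in truth_positions] for b in ssc.elements
    ]
    bins = [b for b in bins if b]
    if len(bins) < 2:
        return 0.0

    def errors(seq_bins: list) -> int:
        bad = 0
        for a, b in zip(seq_bins, seq_bins[1:]):
            if max(truth_positions[c] for c in a) > min(
                truth_positions[c] for c in b
            ):
                bad += 1
        return bad

    n_adj = len(bins) - 1
    fw = errors(bins)
    rv = errors(list(reversed(bins)))
    return 100.0 * min(fw, rv) / n_adj
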