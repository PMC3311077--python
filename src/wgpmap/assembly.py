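"""Fingerprint contig assembly with the Sulston coincidence score.

Two clones are declared overlapping when the probability that they share
their observed number of bands by chance (the Sulston score) falls below a
cut-off.  With n_lo and n_hi the smaller and larger band counts, M the number
of shared bands, p = (2*tolerance + 1) / gellen the single-band coincidence
probability on a virtual band space of size ``gellen``, and
q = 1 - (1 - p)**n_lo:

    score = sum_{k=M}^{n_hi} C(n_hi, k) * q**k * (1-q)**(n_hi-k)

i.e. the upper tail of a Binomial(n_hi, q).  Scores are computed in log
space so cut-offs of 1e-75 and far beyond are exact.

The map is built with the stringent stepwise protocol: an incremental
single-linkage build at the most stringent cut-off, then singleton-to-end
joins, end-to-end merges and DQing (dissolving contigs with too many
questionable clones and re-assembling their clones at a much more stringent
cut-off) at successively more permissive cut-offs.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Fingerprint",
    "AssemblyParams",
    "Contig",
    "PhysicalMap",
    "StepStats",
    "match_count",
    "sulston_score",
    "log_sulston_score",
    "build_contigs_incremental",
    "stepwise_assembly",
    "consensus_order",
    "map_length",
]


# ---------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class Fingerprint:
    """Per-clone fingerprint: a set of sequence tags (WGP mode, tolerance 0)
    or a sorted multiset of integer band sizes (banded mode)."""

    clone_id: str
    bands: frozenset | tuple
    mode: str = "wgp"  # "wgp" | "banded"

    @classmethod
    def wgp(cls, clone_id: str, tags) -> "Fingerprint":
        return cls(clone_id, frozenset(tags), "wgp")

    @classmethod
    def banded(cls, clone_id: str, sizes) -> "Fingerprint":
        sizes = tuple(sorted(int(s) for s in sizes))
        if any(s <= 0 for s in sizes):
            raise ValueError("band sizes must be positive")
        return cls(clone_id, sizes, "banded")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class AssemblyParams:
    """FPC-style assembly parameters.

    gellen: size G of the virtual band space (110,000 for WGP tags).
    tolerance: band-size tolerance t (0 for sequence tags).
    from_end: a clone is an "end clone" if its placement starts within this
        many consensus-band slots of a contig end.
    cutoff_schedule: strictly increasing probabilities; default 1e-75 with
        exponent +5 per step up to 1e-05 (15 steps).
    dq_max_q / dq_step: dissolve contigs with more than dq_max_q questionable
        clones and re-assemble them dq_step stringency steps (x 10**-5 each)
        tighter.
    match: minimum shared bands for a join or merge.
    q_threshold / q_window_factor: questionable-clone call (see
    ``consensus_order``).
    """

    gellen: int = 110_000
    tolerance: int = 0
    from_end: int = 8
    cutoff_schedule: list = field(
        default_factory=lambda: [10.0 ** (-e) for e in range(75, 0, -5)]
    )
    dq_max_q: float = 0.10
    dq_step: int = 3
    match: int = 1
    q_threshold: float = 0.5
    q_window_factor: float = 1.5

    def __post_init__(self):
        if self.gellen <= 0:
            raise ValueError("gellen must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not self.cutoff_schedule:
            raise ValueError("cutoff_schedule must be non-empty")
        if any(
            b <= a for a, b in zip(self.cutoff_schedule, self.cutoff_schedule[1:])
        ):
            raise ValueError("cutoff_schedule must be strictly increasing")
        if not all(0 < c < 1 for c in self.cutoff_schedule):
            raise ValueError("cutoffs must lie in (0, 1)")


@dataclass
class Contig:
    """An assembled contig: ordered clones plus a consensus-band (CB) map."""

    contig_id: int
    order: list  # clone ids, left to right
    offsets: dict  # clone id -> CB offset of its placement
    cb_order: list  # band identities in consensus slot order
    length_cb: int
    q_clones: set
    clone_intervals: dict  # clone id -> (min_slot, max_slot)
    built_cutoff: float

    @property
    def n_clones(self) -> int:
        return len(self.order)

    @property
    def q_fraction(self) -> float:
        return len(self.q_clones) / self.n_clones if self.order else 0.0


@dataclass
class PhysicalMap:
    contigs: list
    singletons: set
    params: AssemblyParams
    cutoff: float

    @property
    def clone_ids(self) -> set:
        out = set(self.singletons)
        for c in self.contigs:
            out.update(c.order)
        return out

    @property
    def n_q_clones(self) -> int:
        return sum(len(c.q_clones) for c in self.contigs)

    @property
    def length_cb(self) -> int:
        return sum(c.length_cb for c in self.contigs)

    def contig_of(self) -> dict:
        return {cl: c.contig_id for c in self.contigs for cl in c.order}


@dataclass
class StepStats:
    cutoff: float
    n_contigs: int
    n_singletons: int
    n_q_clones: int  # after DQing at this cutoff
    length_cb: int
    n_q_clones_pre_dq: int = 0  # before DQing (what triggers contig splits)


# ---------------------------------------------------------------------------
# pairwise scores


def match_count(a: Fingerprint, b: Fingerprint, tolerance: int = 0) -> int:
    """Shared bands: exact tag-set intersection (WGP) or a maximum one-to-one
    matching of sorted band sizes within +/- tolerance (banded)."""
    if a.mode != b.mode:
        raise ValueError(f"fingerprint mode mismatch: {a.mode} vs {b.mode}")
    if a.mode == "wgp":
        return len(a.bands & b.bands)
    # two-pointer greedy on sorted multisets is a maximum matching here
    i = j = matches = 0
    x, y = a.bands, b.bands
    while i < len(x) and j < len(y):
        if abs(x[i] - y[j]) <= tolerance:
            matches += 1
            i += 1
            j += 1
        elif x[i] < y[j]:
            i += 1
        else:
            j += 1
    return matches


def log_sulston_score(
    a: Fingerprint, b: Fingerprint, params: AssemblyParams, shared: int | None = None
) -> float:
    """Natural log of the Sulston score; exact far below float underflow."""
    if a.n_bands == 0 or b.n_bands == 0:
        raise ValueError("cannot score an empty fingerprint")
    m = match_count(a, b, params.tolerance) if shared is None else shared
    if m <= 0:
        return 0.0
    n_lo, n_hi = min(a.n_bands, b.n_bands), max(a.n_bands, b.n_bands)
    p = (2 * params.tolerance + 1) / params.gellen
    log1mq = n_lo * math.log1p(-p)  # log(1-q)
    q = -math.expm1(log1mq)
    if q <= 0.0:
        return -math.inf
    logq = math.log(q)
    lognf = math.lgamma(n_hi + 1)
    terms = []
    for k in range(m, n_hi + 1):
        logc = lognf - math.lgamma(k + 1) - math.lgamma(n_hi - k + 1)
        terms.append(logc + k * logq + (n_hi - k) * log1mq)
    hi = max(terms)
    return min(0.0, hi + math.log(sum(math.exp(t - hi) for t in terms)))


def sulston_score(
    a: Fingerprint, b: Fingerprint, params: AssemblyParams, shared: int | None = None
) -> float:
    """Sulston coincidence probability in [0, 1] (0.0 may be an underflow of
    a log-score far below 1e-300; use ``log_sulston_score`` for cut-offs)."""
    return math.exp(log_sulston_score(a, b, params, shared))


def _pair_table(fps: list, params: AssemblyParams) -> dict:
    """(clone_a, clone_b) -> (shared, log_score) for all candidate pairs.

    WGP mode prunes through an inverted tag index (pairs sharing no tag can
    never pass ``match >= 1``); banded mode scores all pairs.
    """
    table: dict = {}
    by_id = {fp.clone_id: fp for fp in fps}
    if len(by_id) != len(fps):
        raise ValueError("duplicate clone ids in fingerprint list")
    if fps and fps[0].mode == "wgp":
        index: dict = {}
        for fp in fps:
            for band in fp.bands:
                index.setdefault(band, []).append(fp.clone_id)
        pairs = set()
        for clones in index.values():
            if len(clones) > 1:
                clones = sorted(clones)
                pairs.update(itertools.combinations(clones, 2))
    else:
        pairs = itertools.combinations(sorted(by_id), 2)
    for ca, cb in pairs:
        a, b = by_id[ca], by_id[cb]
        m = match_count(a, b, params.tolerance)
        if m >= 1:
            table[(ca, cb)] = (m, log_sulston_score(a, b, params, shared=m))
    return table


def _lookup(table: dict, ca: str, cb: str) -> tuple:
    key = (ca, cb) if ca < cb else (cb, ca)
    return table.get(key, (0, 0.0))  # no shared bands -> score 1 (log 0)


# ---------------------------------------------------------------------------
# consensus ordering (CB map)


def _seriate(ids: list, by_id: dict, pair_table: dict) -> list:
    """Order a contig's clones along the chromosome by spectral seriation.

    The Fiedler vector (eigenvector of the second-smallest Laplacian
    eigenvalue) of the overlap-similarity graph gives a 1-D embedding that
    recovers the tiling-path order when overlaps decay with distance; the
    similarity is the shared-band count normalized by the smaller
    fingerprint.  Deterministic: ties broken by clone id, eigenvector sign
    canonicalized to put the lexicographically smallest clone in the left
    half.
    """
    import numpy as np

    n = len(ids)
    if n <= 2:
        return list(ids)
    w = np.zeros((n, n))
    pos_of = {c: i for i, c in enumerate(ids)}
    for i, ca in enumerate(ids):
        for cb in ids[i + 1 :]:
            shared, _ = _lookup(pair_table, ca, cb)
            if shared:
                sim = shared / min(by_id[ca].n_bands, by_id[cb].n_bands)
                j = pos_of[cb]
                w[i, j] = w[j, i] = sim
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    order = sorted(range(n), key=lambda i: (fiedler[i], ids[i]))
    if order.index(0) > n // 2:  # canonical global orientation
        order.reverse()
    return [ids[i] for i in order]


def consensus_order(
    fps: list,
    params: AssemblyParams | None = None,
    contig_id: int = 0,
    built_cutoff: float = math.nan,
    pair_table: dict | None = None,
) -> Contig:
    """Greedy seriation of a contig's clones and its consensus-band map.

    Seeds with the lowest-score clone pair, inserts each remaining clone (best
    score against a placed clone first) at the position minimizing the score
    against its flanking neighbors, derives clone offsets from successive
    overlaps, and orders the union of bands by their weighted mean clone
    offset.  ``length_cb`` is the number of consensus slots.

    A clone is flagged questionable (Q) when fewer than ``q_threshold`` of its
    bands are corroborated (shared with another clone of the contig) and fall
    inside one sliding window of ``q_window_factor`` x (its band count) slots
    — i.e. its fingerprint is not consistent with a single placement.
    """
    if not fps:
        raise ValueError("consensus_order needs at least one clone")
    params = params or AssemblyParams()
    if pair_table is None:
        pair_table = _pair_table(fps, params)
    by_id = {fp.clone_id: fp for fp in fps}

    if len(fps) == 1:
        fp = fps[0]
        bands = sorted(fp.bands) if fp.mode == "banded" else sorted(fp.bands)
        return Contig(
            contig_id=contig_id,
            order=[fp.clone_id],
            offsets={fp.clone_id: 0.0},
            cb_order=list(bands),
            length_cb=fp.n_bands,
            q_clones=set(),
            clone_intervals={fp.clone_id: (0, max(fp.n_bands - 1, 0))},
            built_cutoff=built_cutoff,
        )

    ids = sorted(by_id)
    order = _seriate(ids, by_id, pair_table)

    # offsets from successive overlaps along the ordered list
    offsets = {order[0]: 0.0}
    for prev, cur in zip(order, order[1:]):
        shared, _ = _lookup(pair_table, prev, cur)
        step = by_id[prev].n_bands - shared
        offsets[cur] = offsets[prev] + max(step, 0)

    # consensus slots: union of bands ordered by weighted mean clone offset
    band_pos: dict = {}
    band_count: dict = {}
    for cid in order:
        off = offsets[cid]
        for band in by_id[cid].bands:
            band_pos[band] = band_pos.get(band, 0.0) + off
            band_count[band] = band_count.get(band, 0) + 1
    slots = sorted(band_pos, key=lambda b: (band_pos[b] / band_count[b], str(b)))
    slot_of = {b: i for i, b in enumerate(slots)}

    clone_intervals = {}
    q_clones: set = set()
    for cid in order:
        fp = by_id[cid]
        slot_idx = sorted(slot_of[b] for b in fp.bands)
        clone_intervals[cid] = (slot_idx[0], slot_idx[-1])
        corroborated = sorted(
            slot_of[b] for b in fp.bands if band_count[b] >= 2
        )
        window = max(1, int(round(params.q_window_factor * fp.n_bands)))
        best_in_window = 0
        j = 0
        for i in range(len(corroborated)):
            while corroborated[i] - corroborated[j] >= window:
                j += 1
            best_in_window = max(best_in_window, i - j + 1)
        if fp.n_bands and best_in_window / fp.n_bands < params.q_threshold:
            q_clones.add(cid)

    order_sorted = sorted(order, key=lambda c: (offsets[c], c))
    return Contig(
        contig_id=contig_id,
        order=order_sorted,
        offsets=offsets,
        cb_order=slots,
        length_cb=len(slots),
        q_clones=q_clones,
        clone_intervals=clone_intervals,
        built_cutoff=built_cutoff,
    )


# ---------------------------------------------------------------------------
# builds


def _components(
    fps: list, log_cutoff: float, params: AssemblyParams, pair_table: dict
) -> list:
    """Single-linkage components of the pass-cutoff graph (sorted clone lists)."""
    g = nx.Graph()
    g.add_nodes_from(fp.clone_id for fp in fps)
    for (ca, cb), (shared, ls) in pair_table.items():
        if ca in g and cb in g and shared >= params.match and ls <= log_cutoff:
            g.add_edge(ca, cb)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def build_contigs_incremental(
    fps: list,
    cutoff: float,
    params: AssemblyParams | None = None,
    pair_table: dict | None = None,
    _start_id: int = 1,
) -> PhysicalMap:
    """Single-linkage assembly at one cut-off.

    Contigs are the transitive closure of ``score(a, b) <= cutoff`` (with at
    least ``params.match`` shared bands); clones in no passing pair become
    singletons.  Each contig gets a CB map via ``consensus_order``.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    params = params or AssemblyParams()
    if pair_table is None:
        pair_table = _pair_table(fps, params)
    by_id = {fp.clone_id: fp for fp in fps}
    comps = _components(fps, math.log(cutoff), params, pair_table)
    contigs = []
    singletons = set()
    next_id = _start_id
    for comp in comps:
        if len(comp) == 1:
            singletons.add(comp[0])
        else:
            contigs.append(
                consensus_order(
                    [by_id[c] for c in comp],
                    params,
                    contig_id=next_id,
                    built_cutoff=cutoff,
                    pair_table=pair_table,
                )
            )
            next_id += 1
    return PhysicalMap(contigs, singletons, params, cutoff)


def _end_clones(contig: Contig, from_end: int) -> list:
    """Clones whose placement starts within ``from_end`` slots of either end."""
    out = []
    for cid in contig.order:
        lo, hi = contig.clone_intervals[cid]
        if lo < from_end or hi >= contig.length_cb - from_end:
            out.append(cid)
    return out


def stepwise_assembly(
    fps: list,
    params: AssemblyParams | None = None,
) -> tuple[PhysicalMap, list]:
    """Stepwise stringency protocol over ``params.cutoff_schedule``.

    Initial incremental build at the first (most stringent) cut-off; at each
    subsequent cut-off: (i) singleton-to-end joins against clones within
    ``from_end`` slots of a contig end, (ii) end-to-end contig merges,
    (iii) DQing — contigs with more than ``dq_max_q`` questionable clones are
    dissolved and their clones re-assembled ``dq_step`` stringency steps
    (x 10**-5 each) below the current cut-off.  Returns the final map and
    per-step statistics.
    """
    params = params or AssemblyParams()
    by_id = {fp.clone_id: fp for fp in fps}
    pair_table = _pair_table(fps, params)
    schedule = list(params.cutoff_schedule)

    pmap = build_contigs_incremental(
        fps, schedule[0], params, pair_table=pair_table
    )
    next_id = max((c.contig_id for c in pmap.contigs), default=0) + 1
    stats = [_snapshot(pmap, schedule[0])]

    for cutoff in schedule[1:]:
        log_cut = math.log(cutoff)
        contigs = list(pmap.contigs)
        singletons = set(pmap.singletons)

        # (i) singleton-to-end joins
        for s in sorted(singletons):
            best = None
            for contig in contigs:
                for e in _end_clones(contig, params.from_end):
                    shared, ls = _lookup(pair_table, s, e)
                    if shared >= params.match and ls <= log_cut:
                        cand = (ls, contig.contig_id)
                        if best is None or cand < best[0:2]:
                            best = (ls, contig.contig_id, contig)
            if best is not None:
                singletons.discard(s)
                contig = best[2]
                members = [by_id[c] for c in contig.order] + [by_id[s]]
                rebuilt = consensus_order(
                    members,
                    params,
                    contig_id=contig.contig_id,
                    built_cutoff=cutoff,
                    pair_table=pair_table,
                )
                contigs[contigs.index(contig)] = rebuilt

        # (ii) end-to-end merges, best pair first, until none pass
        while True:
            best = None
            for ia in range(len(contigs)):
                for ib in range(ia + 1, len(contigs)):
                    ca, cb = contigs[ia], contigs[ib]
                    for ea in _end_clones(ca, params.from_end):
                        for eb in _end_clones(cb, params.from_end):
                            shared, ls = _lookup(pair_table, ea, eb)
                            if shared >= params.match and ls <= log_cut:
                                cand = (ls, ca.contig_id, cb.contig_id)
                                if best is None or cand < best[0:3]:
                                    best = (ls, ca.contig_id, cb.contig_id, ia, ib)
            if best is None:
                break
            _, _, _, ia, ib = best
            ca, cb = contigs[ia], contigs[ib]
            members = [by_id[c] for c in ca.order + cb.order]
            merged = consensus_order(
                members,
                params,
                contig_id=min(ca.contig_id, cb.contig_id),
                built_cutoff=cutoff,
                pair_table=pair_table,
            )
            contigs = [c for k, c in enumerate(contigs) if k not in (ia, ib)]
            contigs.append(merged)

        # (iii) DQer
        pre_dq_q = sum(len(c.q_clones) for c in contigs)
        survivors = []
        for contig in contigs:
            if contig.q_fraction > params.dq_max_q:
                re_cutoff = cutoff * 10.0 ** (-5 * params.dq_step)
                sub = build_contigs_incremental(
                    [by_id[c] for c in contig.order],
                    max(re_cutoff, 1e-300),
                    params,
                    pair_table=pair_table,
                    _start_id=next_id,
                )
                next_id = max(
                    (c.contig_id for c in sub.contigs), default=next_id - 1
                ) + 1
                survivors.extend(sub.contigs)
                singletons.update(sub.singletons)
            else:
                survivors.append(contig)

        survivors.sort(key=lambda c: c.contig_id)
        pmap = PhysicalMap(survivors, singletons, params, cutoff)
        stats.append(_snapshot(pmap, cutoff, pre_dq_q))

    return pmap, stats


def _snapshot(pmap: PhysicalMap, cutoff: float, pre_dq_q: int | None = None) -> StepStats:
    return StepStats(
        cutoff=cutoff,
        n_contigs=len(pmap.contigs),
        n_singletons=len(pmap.singletons),
        n_q_clones=pmap.n_q_clones,
        length_cb=pmap.length_cb,
        n_q_clones_pre_dq=pmap.n_q_clones if pre_dq_q is None else pre_dq_q,
    )


def map_length(
    pmap: PhysicalMap, cb_unit_kb: float, include_singletons: bool = False,
    mean_clone_cb: float | None = None,
) -> float:
    """Physical map length in Mb: sum of contig CB lengths x kb per CB unit.

    Singletons are excluded by default; with ``include_singletons`` each adds
    ``mean_clone_cb`` (default: mean contig-clone band count) CB units.
    """
    if cb_unit_kb <= 0:
        raise ValueError("cb_unit_kb must be positive")
    total_cb = pmap.length_cb
    if include_singletons and pmap.singletons:
        if mean_clone_cb is None:
            counts = [
                len(c.clone_intervals) and c.length_cb / len(c.order)
                for c in pmap.contigs
            ]
            mean_clone_cb = sum(counts) / len(counts) if counts else 0.0
        total_cb += mean_clone_cb * len(pmap.singletons)
    return total_cb * cb_unit_kb / 1000.0
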