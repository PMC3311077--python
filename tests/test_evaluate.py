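"""Evaluation metrics: tag mapping, chimera/mis-assembly detection, CB-unit
calibration, tag landscape, distance stats, N90/L90, k-mer uniqueness."""
import numpy as np
import pytest

import wgpmap as w
from wgpmap._util import revcomp
from wgpmap.assembly import AssemblyParams, Fingerprint, build_contigs_incremental
from wgpmap.evaluate import (
    ReferenceAlignment,
    cb_unit_size,
    chimera_score_c1c2,
    classify_bacs,
    detect_chimeras,
    gap_percentage,
    inter_tag_distances,
    kmer_uniqueness,
    map_tags_to_reference,
    misassembled_fraction,
    n90_l90,
    tag_landscape,
)


@pytest.fixture(scope="module")
def mapped_world():
    """Unique genome, 6x library, assembled map and reference alignment."""
    g = w.simulate_genome(1_500_000, 0.0, seed=61)
    lib = w.simulate_bac_library(g, 140, 90_000, 9_000, seed=62)
    # keep two well-separated loci so the map has >= 2 contigs
    clones = [
        c for c in lib if c.source_interval[1] < 600_000 or c.source_interval[0] >= 900_000
    ]
    tags = w.clone_tags(clones)
    clone_tagsets = {c: {t.tag_sequence for t in v} for c, v in tags.items()}
    fps = [Fingerprint.wgp(c, clone_tagsets[c]) for c in sorted(clone_tagsets)]
    pmap = build_contigs_incremental(fps, 1e-20, AssemblyParams())
    all_tags = set().union(*clone_tagsets.values())
    alignment = map_tags_to_reference(all_tags, {"ref": g.sequence})
    return g, clones, clone_tagsets, pmap, alignment


class TestMapTagsToReference:
    def test_absent_tag_unplaced(self):
        aln = map_tags_to_reference({"AATTC" + "G" * 25}, {"r": "ACGT" * 100})
        assert aln.placements["AATTC" + "G" * 25] == []

    def test_provenance_placements_inside_interval(self, mapped_world):
        g, clones, clone_tagsets, _, alignment = mapped_world
        clone = clones[0]
        s, e = clone.source_interval
        for tag in clone_tagsets[clone.clone_id]:
            places = alignment.placements[tag]
            assert places, "simulated tag must map back to its genome"
            assert any(s <= pos < e for _, pos, _ in places)

    def test_strand_symmetry(self):
        g = w.simulate_genome(20_000, 0.0, seed=63)
        tags = {t.tag_sequence for t in w.digest_and_tag(g.sequence)}
        fw = map_tags_to_reference(tags, {"r": g.sequence})
        rv = map_tags_to_reference(tags, {"r": revcomp(g.sequence)})
        n = len(g.sequence)
        for t in tags:
            flipped = {
                (rid, n - pos - len(t), {"+": "-", "-": "+"}[strand])
                for rid, pos, strand in rv.placements[t]
            }
            assert flipped == set(fw.placements[t])


class TestClassifyBacs:
    def _aln(self, mapped_tags):
        return ReferenceAlignment(
            {t: [("r", 0, "+")] for t in mapped_tags}, {"r": 1000}
        )

    def test_fully_mapped_matched(self):
        tags = {f"t{i}" for i in range(10)}
        aln = self._aln(tags)
        aln.placements.update({})
        matched, unmatched, _ = classify_bacs({"b": tags}, aln)
        assert matched == {"b"}

    def test_half_mapped_is_unmatched(self):
        """Exactly 50% mapped fails the strict 'more than 50%' rule."""
        tags = {f"t{i}" for i in range(10)}
        aln = self._aln({f"t{i}" for i in range(5)})
        aln.placements.update({f"t{i}": [] for i in range(5, 10)})
        matched, unmatched, _ = classify_bacs({"b": tags}, aln)
        assert unmatched == {"b"}

    def test_zero_tag_clone_counted(self):
        aln = self._aln(set())
        matched, unmatched, skipped = classify_bacs({"b": set()}, aln)
        assert skipped == 1
        assert not matched and not unmatched

    def test_off_target_clone_unmatched(self, mapped_world):
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        foreign = {"AATTC" + f"X{i:024d}" for i in range(10)}
        aln = ReferenceAlignment(
            {**alignment.placements, **{t: [] for t in foreign}},
            alignment.reference_lengths,
        )
        matched, unmatched, _ = classify_bacs({"offt": foreign}, aln)
        assert unmatched == {"offt"}


class TestChimeraDetection:
    def test_clean_map_no_chimeras(self, mapped_world):
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        chimeric, rate = detect_chimeras(pmap, alignment, clone_tagsets, cb_unit_kb=2.2)
        assert chimeric == []
        assert rate == 0.0

    def test_planted_fusion_detected(self, mapped_world):
        """A contig fusing two distant loci is flagged chimerical."""
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        assert len(pmap.contigs) >= 2
        a, b = pmap.contigs[0], pmap.contigs[-1]
        fused = type(a)(
            contig_id=999,
            order=a.order + b.order,
            offsets={**a.offsets, **{c: o + a.length_cb for c, o in b.offsets.items()}},
            cb_order=a.cb_order + b.cb_order,
            length_cb=a.length_cb + b.length_cb,
            q_clones=set(),
            clone_intervals={**a.clone_intervals, **b.clone_intervals},
            built_cutoff=a.built_cutoff,
        )
        fused_map = type(pmap)([fused], set(), pmap.params, pmap.cutoff)
        chimeric, _ = detect_chimeras(
            fused_map, alignment, clone_tagsets, cb_unit_kb=2.2, slack_kb=50.0
        )
        assert chimeric == [999]

    def test_rate_arithmetic(self):
        """2 chimeras over 20 Mb of reference -> 1.0 per 10 Mb."""
        clone_tagsets = {
            f"c{i}{side}": {f"t{i}{side}{j}" for j in range(4)}
            for i in range(2)
            for side in "ab"
        }
        placements = {}
        for i in range(2):
            for j in range(4):
                placements[f"t{i}a{j}"] = [("r", j * 1000, "+")]
                placements[f"t{i}b{j}"] = [("r", 10_000_000 + j * 1000, "+")]
        aln = ReferenceAlignment(placements, {"r": 20_000_000})
        contigs = []
        params = AssemblyParams()
        for i in range(2):
            fps = [
                Fingerprint.wgp(f"c{i}a", clone_tagsets[f"c{i}a"]),
                Fingerprint.wgp(f"c{i}b", clone_tagsets[f"c{i}b"]),
            ]
            from wgpmap.assembly import consensus_order

            contigs.append(consensus_order(fps, params, contig_id=i + 1))
        from wgpmap.assembly import PhysicalMap

        pmap = PhysicalMap(contigs, set(), params, 1e-10)
        chimeric, rate = detect_chimeras(
            pmap, aln, clone_tagsets, cb_unit_kb=1.0, slack_kb=100.0
        )
        assert len(chimeric) == 2
        assert rate == pytest.approx(1.0)


class TestMisassembledFraction:
    def test_clean_simulation_zero(self, mapped_world):
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        assert misassembled_fraction(pmap, alignment, clone_tagsets) == 0.0

    def test_planted_off_target_fraction(self, mapped_world):
        """1 planted off-target BAC among 36 evaluated -> 2.8%."""
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        contig = max(pmap.contigs, key=lambda c: c.n_clones)
        sub = list(contig.order)[:35]
        tagsets = {c: clone_tagsets[c] for c in sub}
        foreign = {"AATTC" + f"Z{i:024d}" for i in range(10)}
        tagsets["offt"] = foreign
        aln = ReferenceAlignment(
            {**alignment.placements, **{t: [] for t in foreign}},
            alignment.reference_lengths,
        )
        from wgpmap.assembly import PhysicalMap, consensus_order

        fps = [Fingerprint.wgp(c, tagsets[c]) for c in sorted(tagsets)]
        fake = consensus_order(fps, pmap.params, contig_id=1)
        pm = PhysicalMap([fake], set(), pmap.params, 1e-10)
        pct = misassembled_fraction(pm, aln, tagsets)
        assert pct == pytest.approx(100 / 36, abs=0.01)
        assert round(pct, 1) == 2.8

    def test_all_off_target(self):
        from wgpmap.assembly import PhysicalMap, consensus_order

        tagsets = {f"b{i}": {f"u{i}_{j}" for j in range(5)} | {"shared"} for i in range(3)}
        aln = ReferenceAlignment(
            {t: [] for ts in tagsets.values() for t in ts}, {"r": 1000}
        )
        params = AssemblyParams()
        fps = [Fingerprint.wgp(c, tagsets[c]) for c in sorted(tagsets)]
        pm = PhysicalMap([consensus_order(fps, params, contig_id=1)], set(), params, 1e-5)
        assert misassembled_fraction(pm, aln, tagsets) == 100.0


class TestCbUnit:
    def test_span_ratio_arithmetic(self):
        """A contig spanning 610 kb with 100 CB slots -> 6.1 kb per CB."""
        from wgpmap.assembly import PhysicalMap, consensus_order

        tags = [f"t{i:03d}" for i in range(100)]
        fps = [
            Fingerprint.wgp("a", set(tags[:60])),
            Fingerprint.wgp("b", set(tags[40:])),
        ]
        params = AssemblyParams()
        contig = consensus_order(fps, params, contig_id=1)
        assert contig.length_cb == 100
        placements = {t: [("r", round(i * 610_000 / 99), "+")] for i, t in enumerate(tags)}
        aln = ReferenceAlignment(placements, {"r": 700_000})
        pm = PhysicalMap([contig], set(), params, 1e-10)
        mean, sd, ratios = cb_unit_size(pm, aln, {"a": set(tags[:60]), "b": set(tags[40:])})
        assert mean == pytest.approx(6.1, rel=0.01)
        assert sd == 0.0

    def test_round_trip_recovers_spacing(self, mapped_world):
        """Estimated kb/CB within 20% of the realized inter-tag spacing
        inside each contig's reference window."""
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        mean, sd, ratios = cb_unit_size(pmap, alignment, clone_tagsets)
        by_id = {c.contig_id: c for c in pmap.contigs}
        spacings = []
        for contig_id, _ in ratios:
            contig = by_id[contig_id]
            contig_tags = set().union(*(clone_tagsets[cid] for cid in contig.order))
            pos = sorted(
                p for t in contig_tags for _, p, _ in alignment.placements[t]
            )
            spacings.append((pos[-1] - pos[0]) / (len(pos) - 1) / 1000.0)
        expected = float(np.mean(spacings))
        assert mean == pytest.approx(expected, rel=0.2)

    def test_no_mappable_contig_rejected(self):
        from wgpmap.assembly import PhysicalMap

        pm = PhysicalMap([], set(), AssemblyParams(), 1e-10)
        with pytest.raises(ValueError):
            cb_unit_size(pm, ReferenceAlignment({}, {}), {})


class TestChimeraScore:
    def _contig(self, tagsets):
        from wgpmap.assembly import consensus_order

        fps = [Fingerprint.wgp(c, ts) for c, ts in sorted(tagsets.items())]
        return consensus_order(fps, AssemblyParams(), contig_id=1)

    def test_all_pairs_share(self):
        tagsets = {"a": {"s", "x1"}, "b": {"s", "x2"}, "c": {"s", "x3"}}
        contig = self._contig(tagsets)
        c2 = sum(len(t) for t in tagsets.values()) / contig.length_cb
        assert chimera_score_c1c2(contig, tagsets) == pytest.approx(1.0 / c2)

    def test_no_sharing_zero(self):
        tagsets = {"a": {"x1", "x2"}, "b": {"y1", "y2"}}
        assert chimera_score_c1c2(self._contig(tagsets), tagsets) == 0.0

    def test_chimera_scores_below_clean(self, mapped_world):
        """A forced fusion of two loci scores below a clean contig."""
        g, clones, clone_tagsets, pmap, alignment = mapped_world
        clean = max(pmap.contigs, key=lambda c: c.n_clones)
        a, b = pmap.contigs[0], pmap.contigs[-1]
        from wgpmap.assembly import consensus_order

        fused_ids = a.order + b.order
        fps = [Fingerprint.wgp(c, clone_tagsets[c]) for c in fused_ids]
        fused = consensus_order(fps, pmap.params, contig_id=999)
        assert chimera_score_c1c2(fused, clone_tagsets) < chimera_score_c1c2(
            clean, clone_tagsets
        )


class TestTagLandscape:
    def test_zero_variance_warns_and_returns_zero(self):
        g = w.simulate_genome(200_000, 0.0, seed=64)
        aln = map_tags_to_reference(
            {t.tag_sequence for t in w.digest_and_tag(g.sequence)},
            {"r": g.sequence},
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            df, r, p = tag_landscape(g.sequence, aln, [])
        assert r == 0.0

    def test_anticorrelated_fixture(self):
        """Tags only outside TE blocks -> strong negative correlation."""
        rng = np.random.default_rng(65)
        n = 600_000
        seq = w.simulate_genome(n, 0.0, seed=66).sequence
        # alternate 50-kb TE-dense and TE-free blocks
        te = [(s, s + 50_000, 0) for s in range(0, n, 100_000)]
        placements = {}
        k = 0
        for start in range(50_000, n, 100_000):  # TE-free blocks only
            for pos in range(start, start + 50_000, 2_000):
                placements[f"tag{k:05d}"] = [("r", pos, "+")]
                k += 1
        aln = ReferenceAlignment(placements, {"r": n})
        df, r, p = tag_landscape(seq, aln, te)
        assert r <= -0.9

    def test_tiling_conserves_counts(self):
        g = w.simulate_genome(300_000, 0.0, seed=67)
        tags = {t.tag_sequence for t in w.digest_and_tag(g.sequence)}
        aln = map_tags_to_reference(tags, {"r": g.sequence})
        df, _, _ = tag_landscape(g.sequence, aln, [], window=50_000, step=50_000)
        total_placements = sum(len(p) for p in aln.placements.values())
        in_range = sum(
            1
            for places in aln.placements.values()
            for _, pos, _ in places
            if pos < len(df) * 50_000
        )
        assert df["tags"].sum() == in_range
        assert in_range <= total_placements

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            tag_landscape("ACGT" * 100, ReferenceAlignment({}, {}), [])


class TestInterTagDistances:
    def test_two_tags_same_site_distance_zero(self):
        g = w.simulate_genome(100_000, 0.0, seed=68)
        tags = {t.tag_sequence for t in w.digest_and_tag(g.sequence)}
        aln = map_tags_to_reference(tags, {"r": g.sequence})
        d = inter_tag_distances(aln, {"r": g.sequence})
        assert d["min"] == 0.0  # flanking tags of one site
        assert d["pct_sites_with_two_tags"] > 0

    def test_equally_spaced(self):
        block = "C" * 4994 + "GAATTC"
        ref = block * 10
        placements = {
            f"AATTCTAG{i:022d}": [("r", i * 5000 + 4995, "+")] for i in range(10)
        }
        aln = ReferenceAlignment(placements, {"r": len(ref)})
        d = inter_tag_distances(aln, {"r": ref})
        assert d["mean"] == 5000.0
        assert d["sd"] == 0.0
        assert d["median"] == 5000.0

    def test_site_multiplicity_bookkeeping(self):
        g = w.simulate_genome(200_000, 0.0, seed=69)
        tags = {t.tag_sequence for t in w.digest_and_tag(g.sequence)}
        aln = map_tags_to_reference(tags, {"r": g.sequence})
        d = inter_tag_distances(aln, {"r": g.sequence})
        assert 0 <= d["pct_sites_without_tags"] <= 100
        assert 0 <= d["pct_sites_with_two_tags"] <= 100

    def test_single_placement_rejected(self):
        aln = ReferenceAlignment({"AATTCT" * 5: [("r", 10, "+")]}, {"r": 100})
        with pytest.raises(ValueError):
            inter_tag_distances(aln, {"r": "A" * 100})


class TestN90L90:
    def test_single_piece(self):
        assert n90_l90([1000], 1000) == (1000, 1)

    def test_worked_example(self):
        assert n90_l90([50, 30, 15, 5], 100) == (15, 3)

    def test_exact_90_percent(self):
        assert n90_l90([30, 30, 30], 100) == (30, 3)

    def test_not_reached(self):
        assert n90_l90([10, 10], 1000) == (None, None)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n90_l90([], 100)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(70)
        for _ in range(200):
            k = int(rng.integers(1, 40))
            lengths = rng.integers(1, 10_000, size=k).tolist()
            ref = int(rng.integers(1, int(sum(lengths) * 1.2)))
            got = n90_l90(lengths, ref)
            srt = sorted(lengths, reverse=True)
            expected = (None, None)
            for i in range(1, len(srt) + 1):
                if sum(srt[:i]) >= 0.9 * ref:
                    expected = (srt[i - 1], i)
                    break
            assert got == expected


class TestKmerUniqueness:
    def test_random_sequence_mostly_unique(self):
        g = w.simulate_genome(100_000, 0.0, seed=71)
        assert kmer_uniqueness(g.sequence, 21) > 0.99

    def test_homopolymer_degenerate(self):
        """One distinct k-mer repeated 91 times: nothing occurs exactly once."""
        assert kmer_uniqueness("A" * 100, 10) == 0.0

    def test_duplicated_sequences_zero(self):
        s = w.simulate_genome(5_000, 0.0, seed=72).sequence
        assert kmer_uniqueness([s, s], 21) == 0.0

    def test_canonical_strand_collapse(self):
        s = w.simulate_genome(5_000, 0.0, seed=73).sequence
        assert kmer_uniqueness([s, revcomp(s)], 21) == 0.0

    def test_uniqueness_rises_with_k_on_repeats(self):
        g = w.simulate_genome(300_000, 0.6, n_families=4, seed=74)
        lo = kmer_uniqueness(g.sequence, 15)
        hi = kmer_uniqueness(g.sequence, 70)
        assert hi >= lo

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_uniqueness("ACGT", 10)


class TestGapPercentage:
    def test_gap_free(self):
        assert gap_percentage(scaffolds=["ACGT" * 100]) == 0.0

    def test_internal_n_runs(self):
        assert gap_percentage(scaffolds=["A" * 900 + "N" * 100]) == pytest.approx(10.0)

    def test_reference_mode_round_trip(self):
        """fragment_reference withholds gap_fraction of the reference."""
        ref = w.simulate_genome(100_000, 0.0, seed=75).sequence
        pieces = w.fragment_reference(ref, 10, 0.3, seed=76)
        pct = gap_percentage(
            placements=[(p.start, p.end) for p in pieces],
            reference_length=len(ref),
        )
        assert pct == pytest.approx(30.0, abs=0.5)
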