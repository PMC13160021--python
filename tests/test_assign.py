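import numpy as np
import pytest

from taxalign import assign as asg
from taxalign import fm_index as fm
from taxalign import simulate as sim
from taxalign.assign import (
    SeedingParams,
    align_candidate,
    align_dp,
    assign_read,
    assign_reads,
    collect_candidates,
    extract_seeds,
    merge_reports,
    resolve_ambiguity,
)
from taxalign.fm_index import build_fm_index, reverse_complement
from taxalign.reference_db import ReferenceChunk, ReferenceSequence, partition_references

from conftest import make_chunk, random_dna, simple_taxonomy

PARAMS = SeedingParams()


class TestExtractSeeds:
    def test_150bp_schedule_has_16_offsets_per_strand(self):
        rng = np.random.default_rng(0)
        read = random_dna(rng, 150)
        seeds = extract_seeds(read, PARAMS)
        fwd = [s for s in seeds if s[2] == "forward"]
        assert [off for off, _, _ in fwd] == list(range(0, 127, 9)) + [132]
        assert len(fwd) == 16
        assert sum(1 for s in seeds if s[2] == "reverse") == 16

    def test_read_of_exactly_one_seed(self):
        seeds = extract_seeds("ACGTACGTACGTACGTAC", PARAMS)  # 18 bp
        assert len(seeds) == 2
        assert {s[2] for s in seeds} == {"forward", "reverse"}
        assert seeds[1][1] == reverse_complement(seeds[0][1])

    def test_all_n_read_yields_nothing(self):
        assert extract_seeds("N" * 150, PARAMS) == []

    def test_short_read_yields_nothing(self):
        assert extract_seeds("ACGT", PARAMS) == []

    def test_seed_content_matches_read_slices(self):
        rng = np.random.default_rng(1)
        read = random_dna(rng, 73)
        for off, seed, strand in extract_seeds(read, PARAMS):
            source = read if strand == "forward" else reverse_complement(read)
            assert seed == source[off : off + 18]


class TestCollectCandidates:
    TAX = simple_taxonomy({2001: 900, 2002: 900})

    def setup_method(self):
        self.TAX.accession_to_taxid = {"accA": 2001, "accB": 2002}

    def test_single_diagonal_cluster(self):
        matches = [(0, "accA", 100, "forward"), (9, "accA", 109, "forward"),
                   (18, "accA", 118, "forward")]
        params = SeedingParams(min_seed_hits=2)
        regions = collect_candidates(matches, self.TAX, params)
        assert len(regions) == 1
        assert regions[0].support == 3
        assert regions[0].projected_start == 100

    def test_tolerance_splits_clusters(self):
        # diagonals 100, 103, 250 with tolerance 5 -> clusters of 2 and 1
        matches = [(0, "accA", 100, "forward"), (9, "accA", 112, "forward"),
                   (0, "accA", 250, "forward")]
        params = SeedingParams(min_seed_hits=1, diagonal_tolerance=5)
        regions = collect_candidates(matches, self.TAX, params)
        assert [r.support for r in regions] == [2, 1]
        params2 = SeedingParams(min_seed_hits=2, diagonal_tolerance=5)
        assert [r.support for r in collect_candidates(matches, self.TAX, params2)] == [2]

    def test_tie_break_is_deterministic(self):
        matches = [(0, "accB", 50, "forward"), (9, "accB", 59, "forward"),
                   (0, "accA", 70, "forward"), (9, "accA", 79, "forward")]
        regions = collect_candidates(matches, self.TAX, SeedingParams(min_seed_hits=2))
        assert [r.accession for r in regions] == ["accA", "accB"]  # taxid asc on tie


class TestAlignCandidate:
    def test_exact_match_zero_edits(self):
        result = align_candidate("ACGTACGT", "TTACGTACGTTT", max_edits=2)
        assert result == (0, 2, 10)

    def test_single_substitution(self):
        assert align_candidate("ACGTACGT", "ACGAACGT", max_edits=1)[0] == 1

    def test_over_threshold_returns_none(self):
        assert align_candidate("AAAAAAAA", "CCCCCCCCCC", max_edits=3) is None

    def test_empty_window_returns_none(self):
        assert align_candidate("ACGT", "", max_edits=2) is None

    @pytest.mark.parametrize("kernel", ["edlib", "dp"])
    def test_kernels_agree_on_planted_substitutions(self, kernel):
        rng = np.random.default_rng(17)
        for _ in range(50):
            read = random_dna(rng, 80)
            k = int(rng.integers(0, 5))
            window = list("G" * 10 + read + "C" * 10)
            positions = rng.choice(80, size=k, replace=False)
            for p in positions:
                old = window[10 + p]
                window[10 + p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
            dist_k = align_candidate(read, "".join(window), max_edits=6, kernel=kernel)
            dist_dp, _, _ = align_dp(read, "".join(window))
            assert dist_k is not None and dist_k[0] == dist_dp <= k

    def test_edlib_equals_dp_on_random_pairs(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            read = random_dna(rng, 40)
            window = random_dna(rng, 60)
            dp_dist, _, _ = align_dp(read, window)
            res = align_candidate(read, window, max_edits=40, kernel="edlib")
            assert res[0] == dp_dist


@pytest.fixture(scope="module")
def shared_gene_setup():
    """Two species sharing one identical 600 bp gene region."""
    rng = np.random.default_rng(71)
    seg = random_dna(rng, 600)
    a = random_dna(rng, 3000) + seg + random_dna(rng, 400)
    b = random_dna(rng, 1000) + seg + random_dna(rng, 2400)
    taxonomy = simple_taxonomy({2001: 900, 2002: 900})
    taxonomy.accession_to_taxid = {"accA": 2001, "accB": 2002}
    chunk = make_chunk({"accA": a, "accB": b}, {"accA": 2001, "accB": 2002})
    return seg, build_fm_index(chunk), taxonomy


class TestAssignRead:
    def test_unique_assignment_without_relatives(self, community, community_reads):
        genomes, taxonomy, refs, index = community
        reads, truths, _ = community_reads
        a = assign_read(reads[0][0], reads[0][1], index, taxonomy)
        assert a.status == "unique"
        assert set(a.hits) == {truths[0].true_taxid}

    def test_identical_gene_in_two_taxa_is_multi_taxon(self, shared_gene_setup):
        seg, index, taxonomy = shared_gene_setup
        read = seg[100:250]
        a = assign_read("r1", read, index, taxonomy)
        assert a.status == "multi_taxon"
        assert set(a.hits) == {2001, 2002}

    def test_early_stop_one_alignment_per_taxon(self):
        rng = np.random.default_rng(73)
        base = sim.generate_genome(taxid=3001, length=20_000, n_genes=8, seed=99)
        strains = [base] + [
            sim.diverge_genome(base, 0.0, seed=s, accession=f"{base.accession}_s{s}")
            for s in (1, 2)
        ]
        taxonomy = sim.build_taxonomy(strains)
        refs = [ReferenceSequence(g.accession, g.taxid, g.sequence) for g in strains]
        index = build_fm_index(ReferenceChunk(0, refs))
        feature = base.features[0]
        read = base.sequence[feature.start : feature.start + 150]
        stats = {}
        a = assign_read("r1", read, index, taxonomy, stats=stats)
        assert set(a.hits) == {3001}
        assert stats["accepted"] == 1  # two remaining strain candidates skipped
        assert stats["alignment_calls"] == 1
        exhaustive = assign_read("r1", read, index, taxonomy, exhaustive=True)
        assert set(exhaustive.hits) == set(a.hits)

    def test_early_stop_equals_exhaustive_on_simulated_reads(
        self, community, community_reads
    ):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        for read_id, seq in reads[:100]:
            fast = assign_read(read_id, seq, index, taxonomy)
            slow = assign_read(read_id, seq, index, taxonomy, exhaustive=True)
            assert set(fast.hits) == set(slow.hits)

    def test_strand_symmetry(self, community, community_reads):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        flipped = [(rid, reverse_complement(seq)) for rid, seq in reads[:200]]
        fwd = assign_reads(reads[:200], index, taxonomy)
        rev = assign_reads(flipped, index, taxonomy)
        for rid, _ in reads[:200]:
            fwd_hits = {(h.taxid, h.accession) for h in fwd[rid].hits.values()}
            rev_hits = {(h.taxid, h.accession) for h in rev[rid].hits.values()}
            assert fwd_hits == rev_hits
            for taxid, hit in fwd[rid].hits.items():
                assert rev[rid].hits[taxid].strand != hit.strand

    def test_hit_sets_monotone_in_max_edits_and_min_seed_hits(
        self, community, community_reads
    ):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        sample = reads[:80]
        loose = assign_reads(sample, index, taxonomy, max_edits=10)
        tight = assign_reads(sample, index, taxonomy, max_edits=3)
        strict_seeds = assign_reads(
            sample, index, taxonomy, SeedingParams(min_seed_hits=6)
        )
        baseline = assign_reads(sample, index, taxonomy)
        for rid, _ in sample:
            assert set(tight[rid].hits) <= set(loose[rid].hits)
            assert set(strict_seeds[rid].hits) <= set(baseline[rid].hits)


class TestMergeAndResolve:
    def _hit(self, rid, taxid, acc, dist, start=10):
        return asg.AlignmentResult(
            read_id=rid, accession=acc, taxid=taxid, strand="forward",
            ref_start=start, ref_end=start + 150, edit_distance=dist,
        )

    def _assignment(self, rid, hits):
        a = asg.ReadAssignment(read_id=rid, hits={h.taxid: h for h in hits})
        a.update_status()
        return a

    def test_disjoint_union(self):
        r1 = {"r": self._assignment("r", [self._hit("r", 1, "a", 0)])}
        r2 = {"r": self._assignment("r", [self._hit("r", 2, "b", 1)])}
        merged = merge_reports([r1, r2])
        assert set(merged["r"].hits) == {1, 2}
        assert merged["r"].status == "multi_taxon"

    def test_same_taxon_keeps_lowest_edit_distance(self):
        r1 = {"r": self._assignment("r", [self._hit("r", 1, "a", 2)])}
        r2 = {"r": self._assignment("r", [self._hit("r", 1, "b", 1)])}
        merged = merge_reports([r1, r2])
        assert merged["r"].hits[1].edit_distance == 1
        assert merged["r"].hits[1].accession == "b"

    def test_reads_absent_from_one_chunk_count_as_unassigned_there(self):
        r1 = {"r": self._assignment("r", [self._hit("r", 1, "a", 0)]),
              "s": self._assignment("s", [])}
        r2 = {"r": self._assignment("r", []),
              "s": self._assignment("s", [self._hit("s", 2, "b", 3)])}
        merged = merge_reports([r1, r2])
        assert merged["r"].status == "unique" and merged["s"].status == "unique"

    def test_chunk_split_invariance(self, community, community_reads):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        single = assign_reads(reads, index, taxonomy)
        per_genome = max(r.length for r in refs)
        chunks = partition_references(refs, 2 * per_genome)
        assert len(chunks) > 1
        reports = [
            assign_reads(reads, build_fm_index(c), taxonomy) for c in chunks
        ]
        merged = merge_reports(reports)
        assert set(merged) == set(single)
        for rid in single:
            assert set(merged[rid].hits) == set(single[rid].hits)
            assert merged[rid].status == single[rid].status
            for taxid, hit in single[rid].hits.items():
                other = merged[rid].hits[taxid]
                assert (other.accession, other.ref_start, other.edit_distance) == (
                    hit.accession, hit.ref_start, hit.edit_distance
                )

    def test_edit_slack_filter(self):
        a = self._assignment("r", [self._hit("r", 1, "a", 1), self._hit("r", 2, "b", 3)])
        resolved = resolve_ambiguity({"r": a}, edit_slack=0)
        assert set(resolved["r"].hits) == {1}
        assert resolved["r"].status == "unique"

    def test_low_abundance_taxon_removed_when_alternative_exists(self):
        assignments = {}
        for i in range(99):
            assignments[f"r{i}"] = self._assignment(f"r{i}", [self._hit(f"r{i}", 1, "a", 0)])
        assignments["rx"] = self._assignment(
            "rx", [self._hit("rx", 1, "a", 0), self._hit("rx", 9, "z", 0)]
        )
        resolved = resolve_ambiguity(
            assignments, edit_slack=100, min_taxon_read_fraction=0.05
        )
        assert set(resolved["rx"].hits) == {1}

    def test_rare_taxon_kept_when_it_is_the_only_hit(self):
        assignments = {
            f"r{i}": self._assignment(f"r{i}", [self._hit(f"r{i}", 1, "a", 0)])
            for i in range(50)
        }
        assignments["rx"] = self._assignment("rx", [self._hit("rx", 9, "z", 2)])
        resolved = resolve_ambiguity(assignments, min_taxon_read_fraction=0.1)
        assert set(resolved["rx"].hits) == {9}

    def test_no_op_configuration_is_identity(self, community, community_reads):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        report = assign_reads(reads[:100], index, taxonomy)
        before = {rid: dict(a.hits) for rid, a in report.items()}
        resolved = resolve_ambiguity(report, edit_slack=10**9, min_taxon_read_fraction=0.0)
        assert {rid: dict(a.hits) for rid, a in resolved.items()} == before


class TestReportIO:
    def test_tsv_round_trip(self, community, community_reads, tmp_path):
        genomes, taxonomy, refs, index = community
        reads, _, _ = community_reads
        report = assign_reads(reads[:50], index, taxonomy)
        path = tmp_path / "assign.tsv"
        asg.write_assignments(report, path)
        loaded = asg.read_assignments(path)
        assert set(loaded) == set(report)
        for rid in report:
            assert loaded[rid].status == report[rid].status
            assert {t: h.edit_distance for t, h in loaded[rid].hits.items()} == {
                t: h.edit_distance for t, h in report[rid].hits.items()
            }
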