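"""Frame scoring, significance, fragment assignment, merging, annotation."""

import itertools

import pytest

import pepsig as ps
from pepsig.hotpep import (
    FrameHit,
    HotpepConfig,
    PeptideIndex,
    annotate_genome,
    assign_fragment,
    is_significant,
    is_significant_stats,
    merge_hits,
    score_frame,
)
from pepsig.ppr import PeptideGroup, score_protein
from pepsig.seqio import GenomeFragment, ProteinRecord, fragment_genome
from pepsig import synthetic as syn


def _hit(start, family="AA9", group="AA9_01", n=3, score=2.0, covered=18,
         end=None, frame=1):
    return FrameHit("g", start, end if end is not None else start + 2000,
                    frame, group, family, n, score, covered)


class TestScoreFrame:
    def test_three_maximally_overlapping_peptides_cover_8(self):
        # consecutive start offsets 0, 1, 2
        frame = "ACDEFGHI"
        group = PeptideGroup("g", "F",
                             {"ACDEFG": 0.5, "CDEFGH": 0.5, "DEFGHI": 0.5})
        n, score, covered = score_frame(frame, group)
        assert (n, covered) == (3, 8)

    def test_three_non_overlapping_peptides_cover_18(self):
        frame = "ACDEFG" + "HIKLMN" + "PQRSTV"
        group = PeptideGroup("g", "F",
                             {"ACDEFG": 0.5, "HIKLMN": 0.5, "PQRSTV": 0.5})
        n, score, covered = score_frame(frame, group)
        assert (n, covered) == (3, 18)

    def test_empty_intersection(self):
        group = PeptideGroup("g", "F", {"WWWWWW": 0.9})
        assert score_frame("ACDEFGHIKL", group) == (0, 0.0, 0)

    def test_match_never_crosses_stop_or_x(self):
        group = PeptideGroup("g", "F", {"ACDEFG": 1.0, "HIKLMN": 1.0})
        assert score_frame("ACD*EFGHIKLMN", group) == (1, 1.0, 6)
        assert score_frame("ACDXEFG", group) == (0, 0.0, 0)

    def test_equivalent_to_protein_scoring_inside_a_frame(self, planted_pool,
                                                          planted_groups):
        # a frame consisting of the protein bounded by stops scores
        # exactly like the protein itself when the flanks add no peptides
        _, proteins, _ = planted_pool
        protein = proteins[0]
        for group in planted_groups[:4]:
            frame_stats = score_frame("*" + protein.seq + "*", group)
            assert frame_stats == score_protein(protein, group)


class TestIsSignificant:
    @pytest.mark.parametrize(
        "n, score, covered, expected",
        [
            (3, 1.01, 10, True),   # all three conditions at their boundaries
            (3, 1.0, 18, False),   # score bound is strict
            (3, 2.5, 8, False),    # maximal-overlap coverage 8 < 10
            (2, 3.0, 12, False),   # two peptides insufficient
            (4, 1.2, 24, True),
            (0, 0.0, 0, False),
        ],
    )
    def test_stated_boundaries(self, n, score, covered, expected):
        assert is_significant_stats(n, score, covered, HotpepConfig()) is expected
        assert is_significant(_hit(0, n=n, score=score, covered=covered),
                              HotpepConfig()) is expected

    def test_exhaustive_boundary_grid(self):
        # conjunction semantics over a grid straddling every boundary
        config = HotpepConfig()
        for n, score, covered in itertools.product(
                [0, 1, 2, 3, 4, 10],
                [0.0, 0.5, 0.999, 1.0, 1.0 + 1e-9, 1.01, 5.0],
                [0, 6, 8, 9, 10, 11, 18, 100]):
            expected = n >= 3 and score > 1.0 and covered >= 10
            assert is_significant_stats(n, score, covered, config) is expected

    def test_monotone_in_thresholds(self):
        # raising any threshold never turns an insignificant hit significant
        base = HotpepConfig()
        hit = _hit(0, n=3, score=1.5, covered=12)
        assert is_significant(hit, base)
        assert not is_significant(hit, HotpepConfig(min_peptides=4))
        assert not is_significant(hit, HotpepConfig(min_score=1.5))
        assert not is_significant(hit, HotpepConfig(min_covered_aa=13))


class TestAssignFragment:
    def test_planted_gene_assigned_to_its_subfamily(self, planted_pool,
                                                    planted_groups,
                                                    group_to_subfamily):
        _, proteins, truth = planted_pool
        protein = proteins[0]
        genome, _ = syn.generate_genome([protein], truth, spacing=(200, 300),
                                        seed=4)
        index = PeptideIndex(planted_groups)
        frags = fragment_genome(genome)
        hits = [assign_fragment(f, index) for f in frags]
        hits = [h for h in hits if h is not None]
        assert hits, "planted gene produced no significant hit"
        best = max(hits, key=lambda h: h.frequency_score)
        assert group_to_subfamily[best.group_id] == truth.protein_truth[protein.id][1]

    def test_random_fragments_never_significant(self, planted_groups):
        index = PeptideIndex(planted_groups)
        for seed in range(50):
            genome = syn.random_genome(2000, seed)
            frag = GenomeFragment(genome.id, 0, genome.seq)
            assert assign_fragment(frag, index) is None

    def test_argmax_between_significant_groups(self):
        strong = PeptideGroup("A_01", "A",
                              {"ACDEFG": 1.0, "HIKLMN": 0.6, "PQRSTV": 0.4})
        weak = PeptideGroup("B_01", "B",
                            {"CDEFGH": 0.6, "IKLMNP": 0.5, "NPQRST": 0.4})
        # CDS for ACDEFGHIKLMNPQRSTV, contains both groups' peptides
        import numpy as np

        cds = syn.reverse_translate(ProteinRecord("p", "ACDEFGHIKLMNPQRSTV"),
                                    np.random.default_rng(0))
        frag = GenomeFragment("g", 0, "TAA" + cds + "TAA")
        hit = assign_fragment(frag, PeptideIndex([strong, weak]))
        assert hit is not None and hit.group_id == "A_01"
        assert hit.frequency_score == pytest.approx(2.0)


class TestMergeHits:
    def test_hits_5700_apart_merge(self):
        calls = merge_hits([_hit(0), _hit(5700)], HotpepConfig())
        assert len(calls) == 1
        assert calls[0].n_fragments == 2
        assert (calls[0].start, calls[0].end) == (0, 7700)

    def test_hits_5800_apart_do_not_merge(self):
        calls = merge_hits([_hit(0), _hit(5800)], HotpepConfig())
        assert len(calls) == 2

    def test_different_families_never_merge(self):
        calls = merge_hits([_hit(0, family="AA9"),
                            _hit(100, family="AA11", group="AA11_01")],
                           HotpepConfig())
        assert len(calls) == 2

    def test_call_takes_best_scoring_hit(self):
        calls = merge_hits([_hit(0, score=1.5, group="AA9_02"),
                            _hit(1900, score=3.0, group="AA9_01"),
                            _hit(3800, score=2.0, group="AA9_03")],
                           HotpepConfig())
        [call] = calls
        assert (call.group_id, call.score, call.n_fragments) == ("AA9_01", 3.0, 3)

    def test_merge_order_independent_and_idempotent(self):
        hits = [_hit(s) for s in (3800, 0, 11600, 1900)]
        a = merge_hits(hits, HotpepConfig())
        b = merge_hits(list(reversed(hits)), HotpepConfig())
        assert a == b
        assert len(a) == 2  # chain {0,1900,3800} and {11600}

    def test_strand_ignored_during_merging(self):
        calls = merge_hits([_hit(0, frame=1), _hit(1900, frame=-2)],
                           HotpepConfig())
        assert len(calls) == 1


class TestAnnotateGenome:
    def test_fungal_mode_recovers_planted_genes(self, planted_pool,
                                                planted_groups,
                                                group_to_subfamily):
        _, proteins, truth = planted_pool
        picks = [p for p in proteins if p.id.endswith("_p001")][:6]
        genome, gt = syn.generate_genome(picks, truth, spacing=(8000, 12000),
                                         seed=17)
        calls = annotate_genome(genome, planted_groups, HotpepConfig(mode="fungal"))
        assert len(calls) == len(picks)
        for call, gene in zip(calls, gt.genes):
            assert call.family == gene.family
            assert group_to_subfamily[call.group_id] == gene.subfamily
            # merged fragment span overlaps the planted coding region
            assert call.start < gene.end and call.end > gene.start

    def test_close_same_family_genes_merge_into_one_call(self, planted_pool,
                                                         planted_groups):
        # two copies 3000 bases apart: a documented artifact of the rule
        _, proteins, truth = planted_pool
        fam1 = [p for p in proteins if truth.protein_truth[p.id][0] == "FAM1"]
        genome, _ = syn.generate_genome(fam1[:2], truth, spacing=(1000, 1500),
                                        seed=23)
        calls = annotate_genome(genome, planted_groups, HotpepConfig(mode="fungal"))
        assert len(calls) == 1
        assert calls[0].n_fragments >= 2

    def test_bacterial_mode_reports_independent_orfs(self, planted_pool,
                                                     planted_groups,
                                                     group_to_subfamily):
        _, proteins, truth = planted_pool
        picks = [p for p in proteins if p.id.endswith("_p002")][:4]
        genome, gt = syn.generate_genome(picks, truth, spacing=(500, 900),
                                         seed=29)
        calls = annotate_genome(genome, planted_groups,
                                HotpepConfig(mode="bacterial"))
        assert len(calls) == len(picks)
        for call, gene in zip(calls, gt.genes):
            assert group_to_subfamily[call.group_id] == gene.subfamily
            # stop-to-stop ORF coordinates recover the coding region exactly
            assert (call.start, call.end) == (gene.start, gene.end)

    def test_gene_free_genomes_yield_zero_calls(self, planted_groups):
        config = HotpepConfig(mode="fungal")
        total = 0
        for seed in range(30):
            genome = syn.random_genome(4000, seed, f"rand{seed}")
            total += len(annotate_genome(genome, planted_groups, config))
        assert total == 0

    def test_raising_thresholds_never_increases_calls(self, planted_pool,
                                                      planted_groups):
        _, proteins, truth = planted_pool
        picks = [p for p in proteins if p.id.endswith("_p003")][:4]
        genome, _ = syn.generate_genome(picks, truth, seed=31)
        base = len(annotate_genome(genome, planted_groups, HotpepConfig()))
        for stricter in (HotpepConfig(min_peptides=20),
                         HotpepConfig(min_score=30.0),
                         HotpepConfig(min_covered_aa=60)):
            assert len(annotate_genome(genome, planted_groups, stricter)) <= base

    def test_recall_non_increasing_in_mutation_rate(self):
        rates = [0.0, 0.1, 0.25, 0.45]
        recalls = []
        for rate in rates:
            spec = syn.SyntheticSpec(n_families=1, subfamilies_per_family=2,
                                     proteins_per_subfamily=8, seed=41,
                                     mutation_rate=0.0)
            proteins, truth = syn.generate_family_pool(spec)
            groups, _ = ps.build_subfamilies(proteins, ps.PPRConfig(), "FAM1")
            # mutate fresh copies of the planted proteins before planting
            import numpy as np

            from pepsig.synthetic import _mutate

            rng = np.random.default_rng(43)
            mutated = [ProteinRecord(p.id, _mutate(rng, p.seq, rate))
                       for p in proteins[:5]]
            genome, gt = syn.generate_genome(mutated, truth, seed=47)
            calls = annotate_genome(genome, groups, HotpepConfig())
            recalls.append(len(calls) / len(gt.genes))
        assert recalls[0] == 1.0
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_tiny_genome_rejected(self, planted_groups):
        from pepsig.seqio import GenomeRecord

        with pytest.raises(ValueError):
            annotate_genome(GenomeRecord("g", "AC"), planted_groups)
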