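"""Seed-and-extend repeat mining, completeness, haplotype grouping."""

import itertools

import numpy as np
import pytest

from ribogap.repeat_scan import (
    RepeatHit,
    ScanParams,
    classify_completeness,
    extract_hit,
    gene_copy_report,
    haplotype_groups,
    repeat_table,
    scan_genome,
)
from ribogap.seqio import SeqRecord, Source, reverse_complement


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq, n_subs, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(1234)


class TestScanGenome:
    def test_verbatim_plant_exact_hit(self, rng):
        query = SeqRecord(id="Q", residues=rand_dna(rng, 400))
        bg = rand_dna(rng, 50_000)
        contig = bg[:20_000] + query.residues + bg[20_000:]
        hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (20_000, 20_400, "+")
        assert h.identity == 1.0 and h.coverage == 1.0
        assert h.completeness == "complete"

    def test_ten_percent_divergent_plant(self, rng):
        query = SeqRecord(id="Q", residues=rand_dna(rng, 400))
        planted = mutate(query.residues, 40, rng)
        bg = rand_dna(rng, 20_000)
        contig = bg[:9_000] + planted + bg[9_000:]
        hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(0.90, abs=0.02)
        assert hits[0].coverage == pytest.approx(1.0, abs=0.02)

    def test_truncated_half_plant(self, rng):
        query = SeqRecord(id="Q", residues=rand_dna(rng, 400))
        bg = rand_dna(rng, 20_000)
        contig = bg[:5_000] + query.residues[200:] + bg[5_000:]  # 5'-truncated
        hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
        assert len(hits) == 1
        assert hits[0].coverage == pytest.approx(0.5, abs=0.02)
        assert hits[0].completeness == "truncate"

    def test_minus_strand_hit_and_strand_symmetry(self, rng):
        query = SeqRecord(id="Q", residues=rand_dna(rng, 300))
        bg = rand_dna(rng, 10_000)
        contig = bg[:4_000] + reverse_complement(query.residues) + bg[4_000:]
        fwd_hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
        assert len(fwd_hits) == 1 and fwd_hits[0].strand == "-"
        # scanning the reverse-complemented genome mirrors the hit set
        rc = reverse_complement(contig)
        rc_hits = scan_genome([SeqRecord(id="c", residues=rc)], query)
        assert len(rc_hits) == 1 and rc_hits[0].strand == "+"
        L = len(contig)
        assert (rc_hits[0].start, rc_hits[0].end) == (
            L - fwd_hits[0].end,
            L - fwd_hits[0].start,
        )

    def test_tandem_neighbours_not_merged(self, rng):
        query = SeqRecord(id="Q", residues=rand_dna(rng, 250))
        spacer = rand_dna(rng, 120)
        bg = rand_dna(rng, 3_000)
        contig = bg + query.residues + spacer + query.residues + bg
        hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
        assert len(hits) == 2
        for h in hits:
            assert h.end - h.start == 250

    def test_query_shorter_than_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_genome(
                [SeqRecord(id="c", residues=rand_dna(rng, 100))],
                SeqRecord(id="q", residues="ACGTACG"),
            )

    def test_planted_recovery_50_replicates(self):
        """Plants at 15 points above min identity with full coverage are
        always recovered (recall 100%)."""
        rng = np.random.default_rng(77)
        query = SeqRecord(id="Q", residues=rand_dna(rng, 300))
        found = 0
        for _ in range(50):
            planted = mutate(query.residues, 15, rng)  # 95% identity
            bg = rand_dna(rng, 5_000)
            pos = int(rng.integers(500, 4_000))
            contig = bg[:pos] + planted + bg[pos:]
            hits = scan_genome([SeqRecord(id="c", residues=contig)], query)
            found += any(
                abs(h.start - pos) < 20 and h.coverage > 0.9 for h in hits
            )
        assert found == 50

    def test_hits_within_contig_bounds(self, birth_death_dataset):
        ds = birth_death_dataset
        for strain, contigs in ds.genome_records.items():
            lengths = {c.id: len(c) for c in contigs}
            for h in scan_genome(contigs, ds.reference_record):
                assert 0 <= h.start < h.end <= lengths[h.contig]


class TestCompleteness:
    @pytest.mark.parametrize(
        "coverage,expected",
        [(1.0, "complete"), (0.5, "truncate"), (0.90, "complete"), (0.899, "truncate")],
    )
    def test_threshold_boundary(self, coverage, expected):
        hit = RepeatHit("c", 0, 10, "+", "q", 1.0, coverage, 10.0)
        assert classify_completeness(hit, 0.90) == expected


class TestRepeatTable:
    def test_tallies(self):
        hits = [
            RepeatHit("A", 0, 10, "+", "ITS", 1.0, 1.0, 1, "complete"),
            RepeatHit("A", 50, 60, "+", "ITS", 1.0, 1.0, 1, "complete"),
            RepeatHit("A", 90, 95, "+", "ITS", 1.0, 0.5, 1, "truncate"),
            RepeatHit("B", 0, 10, "-", "ITS", 1.0, 1.0, 1, "complete"),
        ]
        df = repeat_table(hits)
        assert df.loc[("A", "ITS"), "complete"] == 2
        assert df.loc[("A", "ITS"), "truncate"] == 1
        assert int(df["complete"].sum() + df["truncate"].sum()) == len(hits)

    def test_empty(self):
        assert repeat_table([]).empty

    def test_matches_simulated_truth(self, birth_death_dataset):
        ds = birth_death_dataset
        strain = "A"
        hits = scan_genome(ds.genome_records[strain], ds.reference_record)
        planted = [
            p for p in ds.placements if p.strain == strain and p.kind == "repeat"
        ]
        # every intact planted repeat appears in the table as complete
        df = repeat_table(hits)
        total_complete = int(df["complete"].sum()) if not df.empty else 0
        n_intact = sum(1 for p in planted if "truncated" not in p.status)
        assert total_complete >= n_intact


class TestHaplotypeGroups:
    def _recs(self, seqs):
        return [SeqRecord(id=f"s{i}", residues=s) for i, s in enumerate(seqs)]

    def test_identical_sequence_classes(self):
        g = haplotype_groups(self._recs(["AAA", "AAA", "AAT"]))
        assert g.n_groups == 2
        assert g.groups[0] == ["s0", "s1"]
        assert g.distinguishing_positions(0, 1) == 1

    def test_all_identical_single_group(self):
        g = haplotype_groups(self._recs(["ACGT"] * 4))
        assert g.n_groups == 1
        assert g.distinguishing == {}

    def test_three_planted_clusters_and_column_scan_oracle(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), size=60))
        centers = [base]
        for _ in range(2):
            prev = centers[-1]
            out = list(prev)
            for pos in rng.choice(60, size=5, replace=False):
                out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
            centers.append("".join(out))
        seqs = []
        for c in centers:
            seqs.append(c)
            noisy = list(c)
            pos = int(rng.integers(60))
            noisy[pos] = rng.choice([b for b in "ACGT" if b != noisy[pos]])
            seqs.append("".join(noisy))
        g = haplotype_groups(self._recs(seqs), merge_threshold=1)
        assert g.n_groups == 3
        # oracle: distinguishing counts equal direct column scan of consensuses
        for (i, j), n in g.distinguishing.items():
            a = g.consensus[i].residues
            b = g.consensus[j].residues
            assert n == sum(1 for x, y in zip(a, b) if x != y)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            haplotype_groups(self._recs(["AAA", "AA"]))


class TestGeneCopyReport:
    def test_single_copy_no_intragenomic_pairs(self, rng):
        gene = SeqRecord(id="G1", residues=rand_dna(rng, 250))
        bg = rand_dna(rng, 3_000)
        genome = [SeqRecord(id="c", residues=bg[:1000] + gene.residues + bg[1000:])]
        rep = gene_copy_report({"X": genome}, [gene])
        e = rep.entry("X", "G1")
        assert e.copy_count == 1
        assert e.intragenomic_min_diff is None

    def test_mosaic_signal_from_two_parents(self, rng):
        """Two copies from different simulated parents are less similar to
        each other than to the matching parent's copy."""
        parent1 = rand_dna(rng, 250)
        parent2 = mutate(parent1, 20, rng)   # parents 8% apart
        bgh = rand_dna(rng, 4_000)
        hybrid = [
            SeqRecord(
                id="h",
                residues=bgh[:1000] + parent1 + bgh[1000:2500] + parent2 + bgh[2500:],
            )
        ]
        bg1 = rand_dna(rng, 2_000)
        g1 = [SeqRecord(id="p1", residues=bg1[:800] + parent1 + bg1[800:])]
        query = SeqRecord(id="G", residues=parent1)
        rep = gene_copy_report({"HYB": hybrid, "P1": g1}, [query])
        e = rep.entry("HYB", "G")
        assert e.copy_count == 2
        assert e.intragenomic_min_diff == 20
        assert e.best_external_diff == 0
        assert e.admixture_signal is True

    def test_copy_counts_match_simulated_truth(self, admixed_dataset):
        ds = admixed_dataset
        queries = [
            SeqRecord(id=g.gene, residues=g.seq(), source=Source.GENOME)
            for g in ds.strains["A"].genes
        ]
        genomes = {s: ds.genome_records[s] for s in ds.strains}
        rep = gene_copy_report(genomes, queries)
        for strain, genome in ds.strains.items():
            truth = {}
            for g in genome.genes:
                truth[g.gene] = truth.get(g.gene, 0) + 1
            for q in queries:
                assert rep.entry(strain, q.id).copy_count == truth.get(q.id, 0)


def test_extract_hit_reverse_complement(rng):
    seq = rand_dna(rng, 100)
    contig = [SeqRecord(id="c", residues=seq)]
    hit = RepeatHit("c", 10, 30, "-", "q", 1.0, 1.0, 10.0)
    rec = extract_hit(contig, hit)
    assert rec.residues == reverse_complement(seq[10:30])
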