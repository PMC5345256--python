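import numpy as np
import pytest

from msdaflp import (
    FragmentDB,
    FragmentRecord,
    Genome,
    build_db,
    get_enzyme,
    intragenic_fraction,
    query_loci,
    revcomp,
    selective_bases,
    uniqueness_report,
)
from msdaflp.evaluation import oracle_digest, _db_tuples
from msdaflp.synthetic import SynthGenomeSpec, generate_genome


def mini_db(lengths_by_subset, size_range=(1, 500)):
    """Hand-built database: {(sp, ss): [display lengths]} -> FragmentDB."""
    records = []
    pos = 0
    for (sp, ss), lengths in lengths_by_subset.items():
        for L in lengths:
            records.append(
                FragmentRecord("c1", "+", pos, pos + L, L, sp, ss, pos + L + 2)
            )
            pos += L + 10
    return FragmentDB("mini", "SbfI", "HpaII", 0, size_range, records)


class TestBuildDb:
    def test_plus_fragment_worked_example(self):
        g = Genome({"c1": "AACCTGCAGGTACGTACCGGTT"})
        db = build_db(g, size_range=(1, 500))
        assert len(db) == 1
        f = db.records[0]
        assert (f.orientation, f.insert_start, f.insert_end) == ("+", 8, 17)
        assert f.insert_length == 9
        assert g["c1"][f.insert_start : f.insert_end] == "GGTACGTAC"
        assert (f.sel_primary, f.sel_secondary, f.cpg_pos) == ("TA", "TA", 18)

    def test_minus_fragment_mirror_convention(self):
        # "-" spans from the CCGG bottom-strand cut to the primary
        # bottom-strand cut; the monitored CpG is still the internal C
        g = Genome({"c1": "CCGGAAACCTGCAGGAA"})
        db = build_db(g, size_range=(1, 500))
        assert len(db) == 1
        f = db.records[0]
        assert (f.orientation, f.insert_start, f.insert_end) == ("-", 3, 9)
        assert f.cpg_pos == 2

    def test_revcomp_symmetry(self):
        # reverse-complementing the genome maps "+" fragments onto "-"
        # fragments with identical lengths, selective bases and CpG identity
        genome, _ = generate_genome(
            SynthGenomeSpec(
                n_chromosomes=1, chromosome_length=20_000,
                sbfi_per_chromosome=10, seed=11,
            )
        )
        seq = genome["chr1"]
        mirrored = Genome({"chr1": revcomp(seq)})
        fwd = build_db(genome)
        rev = build_db(mirrored)
        L = len(seq)

        def mirror(f):
            return (
                "-" if f.orientation == "+" else "+",
                L - f.insert_end,
                L - f.insert_start,
                f.display_length,
                f.sel_primary,
                f.sel_secondary,
            )

        assert {mirror(f) for f in fwd} == {
            (f.orientation, f.insert_start, f.insert_end, f.display_length,
             f.sel_primary, f.sel_secondary)
            for f in rev
        }

    def test_no_ccgg_means_no_fragments(self):
        g = Genome({"c1": "A" * 30 + "CCTGCAGG" + "A" * 30})
        assert len(build_db(g, size_range=(1, 500))) == 0

    def test_insert_too_short_for_selective_bases_excluded(self):
        # CCGG immediately after the SbfI cut: insert 3 nt, no room
        g = Genome({"c1": "AACCTGCAGGCCGGAA"})
        assert len(build_db(g, size_range=(1, 500))) == 0

    def test_size_range_filter_and_unfiltered_count(self):
        g = Genome({"c1": "AACCTGCAGGTACGTACCGGTT"})
        db = build_db(g, size_range=(50, 500))
        assert len(db) == 0
        assert db.n_before_size_filter == 1


class TestSelectiveBases:
    def test_plus_convention(self):
        sp, ss = selective_bases("GGTACGTAC", get_enzyme("SbfI"), get_enzyme("HpaII"))
        assert sp == "TA"
        assert ss == revcomp("TA")  # MspI-side primer reads the other strand

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            selective_bases("GGC", get_enzyme("SbfI"), get_enzyme("HpaII"))


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_genomes(self):
        for seed in range(25):
            genome, _ = generate_genome(
                SynthGenomeSpec(
                    n_chromosomes=1, chromosome_length=30_000,
                    sbfi_per_chromosome=15, seed=100 + seed,
                )
            )
            assert _db_tuples(build_db(genome)) == oracle_digest(genome)

    def test_no_internal_ccgg_and_count_bound(self, toy_db):
        genome, _ = generate_genome(
            SynthGenomeSpec(
                n_chromosomes=1, chromosome_length=100_000,
                sbfi_per_chromosome=40, seed=3,
            )
        )
        seq = genome["chr1"]
        n_sbfi = seq.count("CCTGCAGG")
        assert len(toy_db) <= 2 * n_sbfi
        for f in toy_db:
            insert = seq[f.insert_start : f.insert_end]
            # monitored CCGG is the nearest: none strictly inside the insert
            assert "CCGG" not in insert[1:-1]


class TestUniqueness:
    def test_single_subset_duplicates(self):
        rep = uniqueness_report(mini_db({("AA", "AA"): [100, 150, 150, 200]}))
        assert rep.n_single_peak == 2
        assert rep.fraction == 0.5

    def test_all_distinct(self):
        rep = uniqueness_report(mini_db({("AA", "AA"): [100, 150, 200]}))
        assert rep.fraction == 1.0

    def test_comigration_only_within_subset(self):
        # duplicates inside each subset -> 0; split across subsets -> 1
        assert uniqueness_report(
            mini_db({("AA", "AA"): [100, 100], ("CC", "CC"): [100, 100]})
        ).fraction == 0.0
        assert uniqueness_report(
            mini_db({("AA", "AA"): [100], ("CC", "CC"): [100]})
        ).fraction == 1.0

    def test_permutation_invariance(self):
        db1 = mini_db({("AA", "AA"): [100, 150, 150], ("CC", "GG"): [80, 80]})
        shuffled = FragmentDB(
            "mini", "SbfI", "HpaII", 0, (1, 500), db1.records[::-1]
        )
        r1, r2 = uniqueness_report(db1), uniqueness_report(shuffled)
        assert r1.n_single_peak == r2.n_single_peak
        assert r1.total_fragments == r2.total_fragments

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            uniqueness_report(FragmentDB("x", "SbfI", "HpaII", 0, (1, 500), []))


class TestQueryLoci:
    def test_round_trip_contains_fragment(self, toy_db):
        for f in toy_db:
            hits = query_loci(
                toy_db, f.sel_primary, f.sel_secondary, f.display_length, 0.0
            )
            assert f in hits

    def test_outside_size_range_empty(self, toy_db):
        f = toy_db.records[0]
        assert query_loci(toy_db, f.sel_primary, f.sel_secondary, 9_999.0, 0.0) == []

    def test_nearest_first_ordering(self):
        db = mini_db({("AA", "AA"): [200, 201]})
        hits = query_loci(db, "AA", "AA", 200.4, 1.0)
        assert [h.display_length for h in hits] == [200, 201]

    def test_invalid_selective_pair_rejected(self, toy_db):
        with pytest.raises(ValueError):
            query_loci(toy_db, "A", "AA", 100, 1.0)
        with pytest.raises(ValueError):
            query_loci(toy_db, "AA", "NX", 100, 1.0)


class TestIntragenic:
    def test_fractions(self):
        db = mini_db({("AA", "AA"): [100, 100, 100, 100]})
        positions = sorted(f.cpg_pos - 1 for f in db)
        everything = {"c1": [(0, positions[-1] + 10)]}
        assert intragenic_fraction(db, everything).fraction == 1.0
        assert intragenic_fraction(db, {"c1": [(10**7, 10**7 + 5)]}).fraction == 0.0
        three = {"c1": [(p, p + 1) for p in positions[:3]]}
        frac = intragenic_fraction(db, three)
        assert frac.fraction == 0.75
        assert (frac.n_intragenic, frac.n_total) == (3, 4)


class TestSerialization:
    def test_tsv_round_trip(self, toy_db, tmp_path):
        p = tmp_path / "db.tsv"
        toy_db.save(p)
        loaded = FragmentDB.load(p)
        assert loaded.records == toy_db.records
        assert loaded.size_range == toy_db.size_range
        assert loaded.n_before_size_filter == toy_db.n_before_size_filter
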