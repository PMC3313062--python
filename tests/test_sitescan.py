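import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rapdscan.core import ScanConfig, reverse_complement
from rapdscan.seqio import Primer, PrimerSet, SequenceSet, TargetSequence
from rapdscan.sitescan import (
    COMPLEMENT,
    GIVEN,
    PrimingSite,
    SiteTable,
    hamming_matches,
    scan,
    site_frequency,
    tally_by_library,
)

from conftest import random_decamers, random_sequence
from naive_oracle import naive_hits


def _targets(*pairs):
    return SequenceSet(
        entries=tuple(TargetSequence(id=i, sequence=s, library=l)
                      for i, s, l in pairs)
    )


class TestHammingMatches:
    def test_overlapping_exact_hits(self):
        # periodic target: the decamer recurs with period 4
        hits = hamming_matches("ACGTACGTAC", "ACGTACGTACGTACGT", max_mm=0)
        assert hits == [(1, 0), (5, 0)]

    def test_full_length_identity(self):
        assert hamming_matches("AAAAAAAAAA", "AAAAAAAAAA", 0) == [(1, 0)]

    def test_single_substitution_needs_tolerance(self):
        assert hamming_matches("AAAAAAAAAA", "AAAATAAAAA", 0) == []
        assert hamming_matches("AAAAAAAAAA", "AAAATAAAAA", 1) == [(1, 1)]

    def test_pattern_longer_than_target_is_empty(self):
        assert hamming_matches("ACGTACGTAC", "ACGT", 3) == []

    def test_n_in_target_counts_as_mismatch(self):
        assert hamming_matches("AAAAAAAAAA", "AAAANAAAAA", 0) == []
        assert hamming_matches("AAAAAAAAAA", "AAAANAAAAA", 1) == [(1, 1)]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            hamming_matches("ACGT", "ACGT", -1)

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(25):
            target = random_sequence(rng, int(rng.integers(50, 400)))
            pattern = random_sequence(rng, 10)
            for max_mm in range(4):
                assert hamming_matches(pattern, target, max_mm) == naive_hits(
                    pattern, target, max_mm
                )


class TestScan:
    def test_non_palindromic_primer_single_orientation(self):
        primers = PrimerSet(entries=(Primer("P1", "ACGTACGTAC"),))
        targets = _targets(("s1", "ACGTACGTAC", "unassigned"))
        table = scan(primers, targets, ScanConfig(max_mismatches=0))
        # revcomp "GTACGTACGT" does not occur, so one given-orientation site
        assert [s.orientation for s in table] == [GIVEN]
        assert table.sites[0].start == 1 and table.sites[0].end == 10

    def test_palindromic_primer_reports_both_orientations(self):
        primers = PrimerSet(entries=(Primer("P1", "AAAAATTTTT"),))
        targets = _targets(("s1", "AAAAATTTTT", "unassigned"))
        table = scan(primers, targets, ScanConfig(max_mismatches=0))
        assert len(table) == 2
        assert {s.orientation for s in table} == {GIVEN, COMPLEMENT}
        assert {(s.start, s.end) for s in table} == {(1, 10)}

    def test_absent_primer_yields_no_rows(self):
        primers = PrimerSet(entries=(Primer("P1", "GGGGGGGGGG"),))
        targets = _targets(("s1", "A" * 50, "unassigned"))
        table = scan(primers, targets, ScanConfig(max_mismatches=0))
        assert len(table) == 0

    def test_mismatch_ceiling_monotonicity(self, rng, decamers):
        targets = _targets(
            *((f"s{i}", random_sequence(rng, 500), "unassigned") for i in range(10))
        )
        previous: set = set()
        for k in range(4):
            table = scan(decamers, targets, ScanConfig(max_mismatches=k))
            current = {(s.key, s.mismatches) for s in table}
            assert previous <= current
            previous = current

    def test_strand_mirror_symmetry(self, rng, decamers):
        seq = random_sequence(rng, 300)
        fwd = _targets(("s", seq, "unassigned"))
        rev = _targets(("s", reverse_complement(seq), "unassigned"))
        cfg = ScanConfig(max_mismatches=3)
        L = len(seq)
        mirrored = {
            (
                s.primer_name,
                L - s.end + 1,
                L - s.start + 1,
                COMPLEMENT if s.orientation == GIVEN else GIVEN,
                s.mismatches,
            )
            for s in scan(decamers, fwd, cfg)
        }
        observed = {
            (s.primer_name, s.start, s.end, s.orientation, s.mismatches)
            for s in scan(decamers, rev, cfg)
        }
        assert mirrored == observed


class TestSiteTable:
    def test_duplicate_entry_rejected(self):
        site = PrimingSite("P1", "s1", 1, 10, GIVEN, 0)
        with pytest.raises(ValueError, match="duplicate"):
            SiteTable(sites=(site, site))

    def test_queries(self):
        a = PrimingSite("P1", "s1", 1, 10, GIVEN, 0)
        b = PrimingSite("P1", "s2", 5, 14, COMPLEMENT, 1)
        c = PrimingSite("P2", "s1", 3, 12, GIVEN, 2)
        table = SiteTable(sites=(a, b, c))
        assert table.by_primer("P1") == (a, b)
        assert table.by_sequence("s1") == (a, c)
        assert table.by_orientation(COMPLEMENT) == (b,)


class TestSiteFrequency:
    def test_multi_site_flagging(self):
        table = SiteTable(
            sites=(
                PrimingSite("P1", "s1", 1, 10, GIVEN, 0),
                PrimingSite("P1", "s1", 5, 14, GIVEN, 0),
                PrimingSite("P1", "s2", 1, 10, GIVEN, 0),
            )
        )
        freq = site_frequency(table).set_index(["primer_name", "sequence_id"])
        assert freq.loc[("P1", "s1"), "n_sites"] == 2
        assert bool(freq.loc[("P1", "s1"), "multi_site"])
        assert not bool(freq.loc[("P1", "s2"), "multi_site"])

    def test_empty_table(self):
        assert site_frequency(SiteTable(sites=())).empty


class TestTallyByLibrary:
    def test_counts_and_total(self):
        table = SiteTable(
            sites=(
                PrimingSite("P1", "s1", 1, 10, GIVEN, 0),
                PrimingSite("P1", "s1", 21, 30, GIVEN, 0),
                PrimingSite("P1", "s2", 1, 10, GIVEN, 0),
            )
        )
        targets = _targets(
            ("s1", "A" * 40, "mesocarp"), ("s2", "A" * 40, "unassigned")
        )
        tally = tally_by_library(table, targets).set_index(["primer_name", "library"])
        assert tally.loc[("P1", "mesocarp"), "n_sites"] == 2
        assert tally.loc[("P1", "unassigned"), "n_sites"] == 1
        assert tally.loc[("P1", "total"), "n_sites"] == 3

    def test_totals_conserve_site_counts(self, rng, decamers):
        libs = ["mesocarp", "inflorescence", "leaf"]
        targets = _targets(
            *(
                (f"s{i}", random_sequence(rng, 800), libs[i % 3])
                for i in range(9)
            )
        )
        table = scan(decamers, targets, ScanConfig(max_mismatches=3))
        tally = tally_by_library(table, targets)
        for primer in {s.primer_name for s in table}:
            rows = tally[tally["primer_name"] == primer]
            total = rows.loc[rows["library"] == "total", "n_sites"].item()
            assert total == rows.loc[rows["library"] != "total", "n_sites"].sum()
            assert total == len(table.by_primer(primer))

    def test_empty_table_gives_empty_tally(self):
        targets = _targets(("s1", "ACGT", "mesocarp"))
        assert tally_by_library(SiteTable(sites=()), targets).empty


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    pattern=st.text(alphabet="ACGT", min_size=4, max_size=12),
    target=st.text(alphabet="ACGTN", min_size=1, max_size=120),
    max_mm=st.integers(min_value=0, max_value=3),
)
def test_hamming_matches_equals_oracle_property(pattern, target, max_mm):
    assert hamming_matches(pattern, target, max_mm) == naive_hits(
        pattern, target, max_mm
    )
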