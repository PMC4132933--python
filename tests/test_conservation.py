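import numpy as np
import pytest

from conftest import naive_scan
from elavscan.conservation import (
    build_star_alignment,
    classify_conservation,
    pairwise_global_align,
    project_to_alignment,
    species_supports_site,
)
from elavscan.errors import ConfigError, CoordinateError, SpeciesLookupError
from elavscan.io import Interval, MultipleAlignment, SequenceRecord
from elavscan.motifs import EBSSite, MotifMatch, default_elav_motifs, merge_matches, scan_sequence

MOTIFS = default_elav_motifs()


def site_on(seq_id: str, start: int, end: int, index: int = 1) -> EBSSite:
    iv = Interval(seq_id, start, end)
    return EBSSite(iv, index, (MotifMatch(iv, "nrg_TTTTTTTT", ""),))


def ref_sites(aln: MultipleAlignment):
    rec = aln.ungapped_record(aln.ref_species)
    return merge_matches(scan_sequence(rec, MOTIFS))


class TestProjection:
    def test_gapless_projection_is_identity(self):
        aln = MultipleAlignment([("r", "ACGTACGTACGTACGT"), ("o", "ACGTACGTACGTACGT")], "r")
        proj = project_to_alignment(site_on("r", 5, 13), aln)
        assert (proj.col_start, proj.col_end) == (5, 13)

    def test_projection_through_gaps(self):
        aln = MultipleAlignment([("r", "AC--GT"), ("o", "ACGTGT")], "r")
        proj = project_to_alignment(site_on("r", 2, 4), aln)  # the "GT"
        assert (proj.col_start, proj.col_end) == (4, 6)

    def test_site_beyond_reference_is_error(self):
        aln = MultipleAlignment([("r", "AC--GT"), ("o", "ACGTGT")], "r")
        with pytest.raises(CoordinateError):
            project_to_alignment(site_on("r", 2, 7), aln)

    def test_round_trip_reproduces_site_content(self, rng, random_sequence):
        for _ in range(25):
            seq = random_sequence(rng, 60, alphabet="ACGT") + "TTTTTTTT"
            gapped = "".join(
                c + ("-" if rng.random() < 0.2 else "") for c in seq
            )
            aln = MultipleAlignment([("r", gapped), ("o", "A" * len(gapped))], "r")
            for site in ref_sites(aln):
                proj = project_to_alignment(site, aln)
                cols = gapped[proj.col_start:proj.col_end].replace("-", "")
                assert cols == seq[site.interval.start:site.interval.end]


def build_alignment(ref_seq: str, other_rows: list[tuple[str, str]]) -> MultipleAlignment:
    rows = [("r", ref_seq)] + other_rows
    return MultipleAlignment(rows, "r")


class TestSpeciesSupport:
    motif_ctx = "GGGG" + "TTTTATTTAT" + "GGGG"  # width 18, site at [4,14)

    def test_identical_species_supports(self):
        aln = build_alignment(self.motif_ctx, [("sp", self.motif_ctx)])
        site = ref_sites(aln)[0]
        proj = project_to_alignment(site, aln)
        assert species_supports_site(proj, aln, "sp", MOTIFS, window_W=0)

    def test_destroyed_motif_does_not_support(self):
        destroyed = "GGGG" + "TAGTGTGTGT" + "GGGG"
        aln = build_alignment(self.motif_ctx, [("sp", destroyed)])
        proj = project_to_alignment(ref_sites(aln)[0], aln)
        assert not species_supports_site(proj, aln, "sp", MOTIFS, window_W=10)

    def test_shifted_motif_depends_on_window(self):
        # motif shifted 5 columns right in the other species
        ref = "GGGG" + "TTTTATTTAT" + "GGGGGGGGG"
        oth = "GGGGGGGGG" + "TTTTATTTAT" + "GGGG"
        aln = build_alignment(ref, [("sp", oth)])
        proj = project_to_alignment(ref_sites(aln)[0], aln)
        assert species_supports_site(proj, aln, "sp", MOTIFS, window_W=10)
        assert not species_supports_site(proj, aln, "sp", MOTIFS, window_W=2)

    def test_unknown_species_is_lookup_error(self):
        aln = build_alignment(self.motif_ctx, [("sp", self.motif_ctx)])
        proj = project_to_alignment(ref_sites(aln)[0], aln)
        with pytest.raises(SpeciesLookupError):
            species_supports_site(proj, aln, "nope", MOTIFS)

    def test_support_monotone_in_window(self, rng, random_sequence):
        for _ in range(10):
            ref = random_sequence(rng, 30, alphabet="ACGT") + "TTTTTTTT" + "GG"
            rows = []
            for i in range(3):
                shift = int(rng.integers(0, 12))
                oth = ("G" * shift + ref)[: len(ref)].ljust(len(ref), "C")
                rows.append((f"sp{i}", oth))
            aln = build_alignment(ref, rows)
            sites = ref_sites(aln)
            prev = None
            for W in (0, 2, 5, 10, 25):
                calls = classify_conservation(sites, aln, MOTIFS, k=2, window_W=W)
                n = [c.n_supporting for c in calls]
                if prev is not None:
                    assert all(a >= b for a, b in zip(n, prev))
                prev = n

    def test_agrees_with_brute_force_oracle(self, rng, random_sequence):
        """On tiny alignments, support equals an exhaustive enumeration of
        every motif occurrence and every column span in the species row."""
        def oracle(proj, aln, sp, W):
            gapped = aln.gapped(sp)
            cols = [i for i, c in enumerate(gapped) if c != "-"]
            ungapped = gapped.replace("-", "")
            for s, e, _ in naive_scan(ungapped, MOTIFS):
                lo, hi = cols[s], cols[e - 1] + 1
                if lo >= proj.col_start - W and hi <= proj.col_end + W:
                    return True
            return False

        n_checked = 0
        for _ in range(40):
            core = "TTTTTTTT" if rng.random() < 0.7 else "ACGTACGT"
            ref = random_sequence(rng, 10, alphabet="ACGT") + core
            width = 30
            rows = []
            for i in range(3):
                raw = random_sequence(rng, int(rng.integers(18, width + 1)),
                                      alphabet="ACGT" if rng.random() < 0.5 else "ACGTT")
                gapped = list(raw)
                while len(gapped) < width:
                    gapped.insert(int(rng.integers(0, len(gapped) + 1)), "-")
                rows.append((f"sp{i}", "".join(gapped)))
            ref_gapped = list(ref)
            while len(ref_gapped) < width:
                ref_gapped.insert(int(rng.integers(0, len(ref_gapped) + 1)), "-")
            aln = build_alignment("".join(ref_gapped), rows)
            for site in ref_sites(aln):
                proj = project_to_alignment(site, aln)
                for sp, _ in rows:
                    for W in (0, 3, 10):
                        got = species_supports_site(proj, aln, sp, MOTIFS, window_W=W)
                        assert got == oracle(proj, aln, sp, W)
                        n_checked += 1
        assert n_checked > 50


class TestClassify:
    def twelve_rows(self, intact: int) -> MultipleAlignment:
        """12 species; the motif is intact in the first ``intact`` rows and
        actively destroyed (mutant core) in the rest."""
        good = "GGGG" + "TTTTATTTAT" + "GGGG"
        bad = "GGGG" + "TAGTGTGTGT" + "GGGG"
        rows = [(f"sp{i:02d}", good if i < intact else bad) for i in range(12)]
        return MultipleAlignment(rows, "sp00")

    def test_all_twelve_support(self):
        aln = self.twelve_rows(12)
        calls = classify_conservation(ref_sites(aln), aln, MOTIFS)
        assert calls[0].n_supporting == 12 and calls[0].ultraconserved

    @pytest.mark.parametrize("intact,expected", [(7, False), (8, True)])
    def test_threshold_boundary(self, intact, expected):
        aln = self.twelve_rows(intact)
        calls = classify_conservation(ref_sites(aln), aln, MOTIFS)
        assert calls[0].n_supporting == intact
        assert calls[0].ultraconserved is expected

    def test_reference_always_supports_itself(self):
        aln = self.twelve_rows(1)
        calls = classify_conservation(ref_sites(aln), aln, MOTIFS)
        assert "sp00" in calls[0].supporting_species

    def test_default_k_requires_twelve_species(self):
        aln = MultipleAlignment(
            [("a", "TTTTTTTTGG"), ("b", "TTTTTTTTGG")], "a"
        )
        sites = ref_sites(aln)
        with pytest.raises(ConfigError):
            classify_conservation(sites, aln, MOTIFS)  # k not given, n != 12
        calls = classify_conservation(sites, aln, MOTIFS, k=2)
        assert calls[0].ultraconserved

    def test_k_larger_than_panel_rejected(self):
        aln = self.twelve_rows(12)
        with pytest.raises(ConfigError):
            classify_conservation(ref_sites(aln), aln, MOTIFS, k=13)


class TestPairwiseAligner:
    def test_identity_alignment(self):
        aln = pairwise_global_align(SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT"))
        assert aln.score == 4
        assert aln.rows == [("a", "ACGT"), ("b", "ACGT")]

    def test_single_gap_in_shorter_row(self):
        aln = pairwise_global_align(SequenceRecord("a", "ACGT"), SequenceRecord("b", "AGT"))
        assert aln.score == 1
        assert aln.rows[0][1] == "ACGT"
        assert aln.rows[1][1].replace("-", "") == "AGT"
        assert aln.rows[1][1].count("-") == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            SequenceRecord("a", "")

    def test_non_positive_match_score_rejected(self):
        with pytest.raises(ConfigError):
            pairwise_global_align(
                SequenceRecord("a", "AC"), SequenceRecord("b", "AC"), match_score=0
            )

    def test_deterministic(self):
        a = SequenceRecord("a", "ACGTACGTAA")
        b = SequenceRecord("b", "ACTTACATA")
        r1 = pairwise_global_align(a, b)
        r2 = pairwise_global_align(a, b)
        assert r1.rows == r2.rows and r1.score == r2.score

    def test_score_matches_biopython_oracle(self, rng, random_sequence):
        from Bio import Align

        oracle = Align.PairwiseAligner()
        oracle.mode = "global"
        oracle.match_score = 1
        oracle.mismatch_score = -1
        oracle.open_gap_score = -2
        oracle.extend_gap_score = -2
        for _ in range(20):
            a = random_sequence(rng, int(rng.integers(5, 40)), alphabet="ACGT")
            b = random_sequence(rng, int(rng.integers(5, 40)), alphabet="ACGT")
            ours = pairwise_global_align(SequenceRecord("a", a), SequenceRecord("b", b))
            assert ours.score == oracle.score(a, b)


class TestStarAlignment:
    def test_rows_ungap_to_inputs(self, rng, random_sequence):
        ref = SequenceRecord("ref", random_sequence(rng, 50, alphabet="ACGT"))
        others = [
            SequenceRecord(f"sp{i}", random_sequence(rng, int(rng.integers(40, 60)),
                                                     alphabet="ACGT"))
            for i in range(3)
        ]
        aln = build_star_alignment(ref, others)
        assert aln.ungapped_record("ref").seq == ref.seq
        for o in others:
            assert aln.ungapped_record(o.id).seq == o.seq
        widths = {len(g) for _, g in aln.rows}
        assert len(widths) == 1
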