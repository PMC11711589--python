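"""Motif engine: IUPAC arithmetic, double-strand scanning, collapsing,
and methylation-call assignment, checked against brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panepi.io_formats import GenomeRecord, MethylationCall
from panepi.motifs import (IUPAC_SETS, MotifSpec, reverse_complement_iupac,
                           is_palindromic, default_modified_index,
                           scan_motif, collapse_motifs, assign_methylation,
                           motif_type_map)
from panepi.reference import load_reference_motifs

iupac_text = st.text(alphabet=sorted(IUPAC_SETS), min_size=0, max_size=12)
dna_text = st.text(alphabet="ACGT", min_size=0, max_size=200)


def expand_words(iupac: str) -> set[str]:
    """All concrete words matching a degenerate motif (test oracle)."""
    return {"".join(w) for w in
            itertools.product(*[sorted(IUPAC_SETS[c]) for c in iupac])}


def brute_force_scan(seq: str, motif: MotifSpec):
    """Window-by-window oracle over the IUPAC expansion set."""
    fwd = expand_words(motif.iupac)
    rev = expand_words(reverse_complement_iupac(motif.iupac))
    k = len(motif.iupac)
    occs = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if window in fwd:
            occs.append((i + 1, "+", i + motif.modified_index))
        if window in rev:
            occs.append((i + 1, "-", i + 1 + k - motif.modified_index))
    return sorted(occs)


class TestIupacArithmetic:
    @pytest.mark.parametrize("motif,expected", [
        ("GANTC", "GANTC"),
        ("ACGGAG", "CTCCGT"),
        ("", ""),
        ("RAGCWGCTY", "RAGCWGCTY"),
        ("GCRDB", "VHYGC"),
    ])
    def test_reverse_complement(self, motif, expected):
        assert reverse_complement_iupac(motif) == expected

    @given(iupac_text)
    @settings(deadline=None)
    def test_involution(self, motif):
        assert reverse_complement_iupac(
            reverse_complement_iupac(motif)) == motif

    def test_invalid_code_named(self):
        with pytest.raises(ValueError, match="X"):
            reverse_complement_iupac("GXT")

    @pytest.mark.parametrize("motif,expected", [
        ("GANTC", True), ("TGGGCA", False), ("AT", True),
        ("RGATCY", True), ("GCRDB", False),
    ])
    def test_palindromy(self, motif, expected):
        assert is_palindromic(motif) is expected


class TestMotifSpec:
    def test_modified_index_out_of_range(self):
        with pytest.raises(ValueError):
            MotifSpec("GANTC", "6mA", 6)

    def test_incompatible_modified_base(self):
        # position 1 of GANTC is G: cannot carry 6mA
        with pytest.raises(ValueError, match="6mA"):
            MotifSpec("GANTC", "6mA", 1)

    def test_default_index_first_compatible(self):
        assert default_modified_index("GANTC", "6mA") == 2
        assert default_modified_index("RAGCWGCTY", "4mC") == 4
        with pytest.warns(UserWarning, match="modified_index"):
            spec = MotifSpec.from_row("GANTC", "6mA")
        assert spec.modified_index == 2


class TestScanning:
    def test_worked_example(self):
        g = GenomeRecord("s", "r1", "GGAATCG")
        occs = scan_motif(g, MotifSpec("GANTC", "6mA", 2))
        assert [(o.start, o.strand, o.modified_genome_position)
                for o in occs] == [(2, "+", 3), (2, "-", 5)]

    def test_motif_longer_than_sequence(self):
        g = GenomeRecord("s", "r1", "AAAA")
        assert scan_motif(g, MotifSpec("CCCGGG", "4mC", 3)) == []

    def test_n_in_genome_never_matches(self):
        g = GenomeRecord("s", "r1", "GANTC")
        assert scan_motif(g, MotifSpec("GANTC", "6mA", 2)) == []

    def test_overlapping_occurrences_all_reported(self):
        g = GenomeRecord("s", "r1", "AAAA")
        occs = scan_motif(g, MotifSpec("AA", "6mA", 1))
        assert sum(o.strand == "+" for o in occs) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=800,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        g = GenomeRecord("s", "r1", seq)
        for spec in load_reference_motifs():
            got = [(o.start, o.strand, o.modified_genome_position)
                   for o in scan_motif(g, spec)]
            assert got == brute_force_scan(seq, spec), spec.label

    @given(dna_text, st.sampled_from(["GANTC", "GCRDB", "CTGCAG"]))
    @settings(deadline=None, max_examples=50)
    def test_strand_symmetry(self, seq, iupac):
        """Scanning the reverse-complemented sequence swaps strands with
        reflected coordinates."""
        comp = str.maketrans("ACGT", "TGCA")
        rc_seq = seq.translate(comp)[::-1]
        spec = MotifSpec(iupac, "6mA" if "A" in iupac else "4mC",
                         default_modified_index(
                             iupac, "6mA" if "A" in iupac else "4mC"))
        fwd = scan_motif(GenomeRecord("s", "r", seq), spec)
        rev = scan_motif(GenomeRecord("s", "r", rc_seq), spec)
        L, k = len(seq), len(iupac)
        reflected = sorted((L - o.start - k + 2,
                            "-" if o.strand == "+" else "+") for o in fwd)
        assert reflected == sorted((o.start, o.strand) for o in rev)

    @given(dna_text)
    @settings(deadline=None, max_examples=50)
    def test_palindrome_strand_counts_equal(self, seq):
        spec = MotifSpec("GANTC", "6mA", 2)
        occs = scan_motif(GenomeRecord("s", "r", seq), spec)
        assert sum(o.strand == "+" for o in occs) \
            == sum(o.strand == "-" for o in occs)


class TestCollapse:
    def test_contained_motif_collapses(self):
        short = MotifSpec("GANTC", "6mA", 2)
        long = MotifSpec("GGANTCC", "6mA", 3)
        collapsed, mapping = collapse_motifs([long, short])
        assert [m.label for m in collapsed] == ["GANTC"]
        assert mapping == {"GANTC": "GANTC", "GGANTCC": "GANTC"}

    def test_single_motif_identity(self):
        m = MotifSpec("CTGCAG", "6mA", 5)
        collapsed, mapping = collapse_motifs([m])
        assert collapsed == [m] and mapping == {"CTGCAG": "CTGCAG"}

    def test_unrelated_motifs_both_retained(self):
        a = MotifSpec("CTCGAG", "6mA", 5)
        b = MotifSpec("GANTC", "6mA", 2)
        collapsed, _ = collapse_motifs([a, b])
        assert {m.label for m in collapsed} == {"CTCGAG", "GANTC"}

    def test_reverse_complement_containment(self):
        # cross-strand alignment of the methylated base requires a
        # degenerate set (N) at the modified position, since an A on one
        # strand is a T on the other
        inner = MotifSpec("ANG", "6mA", 2)      # rc = CNT
        outer = MotifSpec("GCNTA", "6mA", 3)    # contains rc(inner)
        collapsed, mapping = collapse_motifs([inner, outer])
        assert mapping["GCNTA"] == "ANG"
        assert [m.label for m in collapsed] == ["ANG"]

    def test_conflicting_types_not_merged(self):
        a = MotifSpec("GANTC", "6mA", 2)
        b = MotifSpec("GGANTCC", "4mC", 6)  # C at 6
        collapsed, _ = collapse_motifs([a, b])
        assert len(collapsed) == 2

    def test_mapping_idempotent(self):
        motifs = [MotifSpec("GANTC", "6mA", 2),
                  MotifSpec("GGANTCC", "6mA", 3),
                  MotifSpec("TGGANTCCA", "6mA", 4)]
        _, mapping = collapse_motifs(motifs)
        for src, dst in mapping.items():
            assert mapping[dst] == dst


class TestAssignment:
    spec = MotifSpec("GANTC", "6mA", 2)

    def _occ(self, start, strand):
        g = GenomeRecord("s", "r1", "AAAAAAAAAGAATCAAAA")
        occs = scan_motif(g, self.spec)
        return [o for o in occs if o.start == start and o.strand == strand]

    def test_plus_strand_match(self):
        occs = self._occ(10, "+")
        calls = [MethylationCall("r1", 11, "+", "6mA")]
        out = assign_methylation(occs, calls, {"GANTC": "6mA"})
        assert out[0].methylated

    def test_minus_strand_match(self):
        occs = self._occ(10, "-")
        calls = [MethylationCall("r1", 13, "-", "6mA")]
        out = assign_methylation(occs, calls, {"GANTC": "6mA"})
        assert out[0].methylated

    def test_type_mismatch_strict(self):
        occs = self._occ(10, "+")
        calls = [MethylationCall("r1", 11, "+", "4mC")]
        out = assign_methylation(occs, calls, {"GANTC": "6mA"})
        assert not out[0].methylated

    def test_generic_call_matches_when_allowed(self):
        occs = self._occ(10, "+")
        calls = [MethylationCall("r1", 11, "+", "modified_base")]
        assert assign_methylation(occs, calls,
                                  {"GANTC": "6mA"})[0].methylated
        assert not assign_methylation(occs, calls, {"GANTC": "6mA"},
                                      allow_generic=False)[0].methylated

    def test_wrong_strand_or_position_no_match(self):
        occs = self._occ(10, "+")
        calls = [MethylationCall("r1", 11, "-", "6mA"),
                 MethylationCall("r1", 12, "+", "6mA")]
        assert not assign_methylation(occs, calls,
                                      {"GANTC": "6mA"})[0].methylated

    def test_planted_panel_flags_exact(self, mini_panel):
        """End-to-end: assignment flags exactly the generator's truth."""
        res = mini_panel
        motifs = res.config.resolved_motifs()
        types = motif_type_map(motifs)
        for strain, records in res.genomes.items():
            occs = [o for r in records for m in motifs
                    for o in scan_motif(r, m)]
            flagged = assign_methylation(occs, res.calls[strain], types)
            got = {(o.motif_label, o.replicon_id, o.start, o.strand)
                   for o in flagged if o.methylated}
            truth = res.occurrences
            sub = truth[(truth.strain_id == strain) & truth.methylated]
            expected = set(zip(sub.motif_label, sub.replicon_id,
                               sub.start, sub.strand))
            assert got == expected
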