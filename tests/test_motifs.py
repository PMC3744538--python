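"""Motif compilation, similarity scoring and window scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poloscan as ps
from poloscan.errors import (
    DomainError,
    MatrixError,
    MotifNotationError,
    WindowLengthError,
)

from conftest import hits_as_tuples, naive_scan


class TestCompileMotif:
    def test_kinase_consensus(self, kinase):
        assert kinase.length == 6
        assert kinase.phospho_index == 3
        assert kinase.positions[0] == frozenset("ED")
        assert kinase.is_wildcard(1) and kinase.is_wildcard(4)
        assert kinase.positions[2] == frozenset("ST")
        assert kinase.positions[3] == frozenset("ILVM")
        assert kinase.positions[5] == frozenset("E")

    def test_pbd_bracketed_x_widens_position(self, pbd):
        assert pbd.length == 3
        assert pbd.phospho_index == 2
        assert pbd.positions[0] == frozenset("S")
        assert pbd.positions[1] == frozenset("ST")
        assert pbd.is_wildcard(2)

    def test_strict_mode_drops_bracketed_x(self):
        strict = ps.compile_motif(ps.PBD_CONSENSUS, bracket_x_wildcard=False)
        assert strict.positions[2] == frozenset("P")

    def test_dash_separators_ignored(self):
        assert ps.compile_motif("S-[pS/pT]-[P/X]").positions == ps.compile_motif(
            "S[pS/pT][P/X]"
        ).positions

    @pytest.mark.parametrize(
        "notation",
        [
            "[E/D]X[S/T][I/L/V/M]X[E]",  # no phosphoacceptor anywhere
            "[E/D]X[pS/pT][I/L]X[pE]",  # two phospho tokens... second also bad set
            "[pS][pT]A",  # two phospho tokens
            "[E/D]X[pA/pG]LXE",  # acceptor outside {S, T}
            "A[p]",  # dangling p
            "[E/]XpS",  # empty alternative
            "[E/D]X[pS/pT][I/L/V/M]X[E",  # unbalanced bracket
            "J[pS]A",  # unknown residue letter
            "",  # empty notation
            "pS",  # single position
        ],
    )
    def test_notation_errors(self, notation):
        with pytest.raises(MotifNotationError):
            ps.compile_motif(notation)

    def test_phospho_wildcard_rejected(self):
        with pytest.raises(MotifNotationError):
            ps.compile_motif("A[pX]E")


class TestSimilarityIndex:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ("EASIAE", 1.0),  # exact consensus instance
            ("QASIAE", 5 / 6),  # Q not in {E, D}
            ("QAAIAQ", 3 / 6),  # positions 1, 3, 6 fail; wildcards and 4 match
            ("EXSIAE", 1.0),  # X at a wildcard position still matches
            ("EASXAE", 5 / 6),  # X at constrained position matches nothing
            ("BASIAE", 5 / 6),  # ambiguity code only matches wildcards
        ],
    )
    def test_worked_examples(self, kinase, window, expected):
        assert ps.similarity_index(window, kinase) == pytest.approx(expected)

    def test_window_length_mismatch(self, kinase):
        with pytest.raises(WindowLengthError):
            ps.similarity_index("EASIA", kinase)

    def test_score_ignores_phosphoacceptor_constraint(self, kinase):
        # the acceptor is scored like any position; the hard constraint
        # lives in scan_protein
        assert ps.similarity_index("EAAIAE", kinase) == pytest.approx(5 / 6)


class TestSubstitutionSimilarity:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ("EASIAE", 1.0),  # exact instance under any positive diagonal
            ("QASIAE", 1.0),  # BLOSUM62 Q:E = +2 rescues position 1
            ("GASIAE", 5 / 6),  # G:E = -2, G:D = -1, no rescue
        ],
    )
    def test_blosum62_examples(self, kinase, window, expected):
        assert ps.substitution_similarity(window, kinase) == pytest.approx(expected)

    def test_residue_absent_from_matrix(self, kinase):
        with pytest.raises(MatrixError):
            ps.substitution_similarity("UASIAE", kinase)

    def test_never_below_identity(self, kinase):
        rng = np.random.default_rng(11)
        for _ in range(100):
            window = "".join(rng.choice(list(ps.AMINO_ACIDS), size=6))
            assert ps.substitution_similarity(window, kinase) >= ps.similarity_index(
                window, kinase
            )


class TestScanProtein:
    def test_single_hit_with_coordinates(self, kinase):
        hits = ps.scan_protein(("p", "MEASIAEK"), kinase, 0.8)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.window) == (2, 7, "EASIAE")
        assert h.similarity == 1.0
        assert h.phospho_position == 4
        assert "MEASIAEK"[h.phospho_position - 1] in "ST"

    def test_no_acceptor_means_no_hits(self, kinase):
        assert ps.scan_protein(("p", "A" * 50), kinase, 0.0) == []

    def test_sequence_shorter_than_motif(self, kinase):
        assert ps.scan_protein(("p", "EASIA"), kinase, 0.0) == []
        assert ps.scan_protein(("p", ""), kinase, 0.0) == []

    def test_overlapping_hits_all_retained(self, pbd):
        # SSSS holds two overlapping PBD windows (SS*, starting at 1 and 2)
        hits = ps.scan_protein(("p", "SSSS"), pbd, 1.0)
        assert [h.start for h in hits] == [1, 2]

    def test_substitution_mode_keeps_acceptor_hard(self, kinase):
        # A scores +1 against S in BLOSUM62, but the acceptor must be S/T
        assert ps.scan_protein(("p", "MEAAIAEK"), kinase, 0.0, mode="substitution") == []

    def test_threshold_validation(self, kinase):
        with pytest.raises(DomainError):
            ps.scan_protein(("p", "MEASIAEK"), kinase, 1.5)
        with pytest.raises(DomainError):
            ps.scan_protein(("p", "MEASIAEK"), kinase, 0.5, mode="blast")


class TestScanProteome:
    def test_union_of_per_protein_scans(self, kinase):
        result = ps.scan_proteome(
            [("hit", "MEASIAEK"), ("miss", "A" * 20)], kinase, 0.8
        )
        assert result.hit_proteins == {"hit"}
        assert result.best_similarity == {"hit": 1.0}
        assert result.proteins_scanned == 2

    def test_empty_proteome(self, kinase):
        result = ps.scan_proteome([], kinase, 0.8)
        assert result.hits == [] and result.hit_proteins == set()

    def test_duplicate_ids_rejected(self, kinase):
        with pytest.raises(DomainError, match="dup"):
            ps.scan_proteome([("dup", "AAA"), ("dup", "CCC")], kinase, 0.8)

    def test_hit_table_columns(self, kinase):
        frame = ps.scan_proteome([("p", "MEASIAEK")], kinase, 0.8).to_frame()
        assert list(frame.columns) == [
            "protein_id", "motif_name", "start", "end", "window",
            "phospho_position", "similarity", "mode",
        ]
        assert frame.loc[0, "window"] == "EASIAE"


@st.composite
def random_motifs(draw):
    length = draw(st.integers(min_value=2, max_value=8))
    phospho_index = draw(st.integers(min_value=1, max_value=length))
    positions = []
    for i in range(1, length + 1):
        if i == phospho_index:
            allowed = frozenset(draw(st.sampled_from(["S", "T", "ST"])))
        elif draw(st.booleans()):
            allowed = ps.FULL_ALPHABET
        else:
            allowed = frozenset(
                draw(
                    st.sets(
                        st.sampled_from(ps.AMINO_ACIDS), min_size=1, max_size=6
                    )
                )
            )
        positions.append(allowed)
    return ps.MotifPattern("rand", tuple(positions), phospho_index)


# biased toward S/T so scans actually produce hits; includes ambiguity codes
random_sequences = st.text(
    alphabet=ps.AMINO_ACIDS + "SSTTBZUX*", min_size=0, max_size=200
)


class TestScanProperties:
    @settings(max_examples=75, deadline=None, derandomize=True)
    @given(seq=random_sequences, motif=random_motifs(), threshold=st.floats(0, 1))
    def test_matches_naive_oracle(self, seq, motif, threshold):
        got = hits_as_tuples(ps.scan_protein(("p", seq), motif, threshold))
        assert got == naive_scan(seq, motif, threshold)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seq=random_sequences,
        motif=random_motifs(),
        a=st.floats(0, 1),
        b=st.floats(0, 1),
    )
    def test_threshold_monotonicity(self, seq, motif, a, b):
        lo, hi = sorted((a, b))
        relaxed = {(h.start) for h in ps.scan_protein(("p", seq), motif, lo)}
        strict = {(h.start) for h in ps.scan_protein(("p", seq), motif, hi)}
        assert strict <= relaxed

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet=ps.AMINO_ACIDS, min_size=6, max_size=120),
        motif=random_motifs(),
        threshold=st.sampled_from([0.0, 0.5, 0.8, 1.0]),
    )
    def test_substitution_mode_dominates_identity(self, seq, motif, threshold):
        ident = {h.start for h in ps.scan_protein(("p", seq), motif, threshold)}
        subst = {
            h.start
            for h in ps.scan_protein(("p", seq), motif, threshold, mode="substitution")
        }
        assert ident <= subst

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        motif=random_motifs(),
        data=st.data(),
    )
    def test_wildcard_positions_never_change_score(self, motif, data):
        window = "".join(
            data.draw(st.sampled_from(ps.AMINO_ACIDS)) for _ in range(motif.length)
        )
        mutated = list(window)
        for i in range(motif.length):
            if motif.is_wildcard(i):
                mutated[i] = data.draw(st.sampled_from(ps.AMINO_ACIDS + "BZUX*"))
        assert ps.similarity_index("".join(mutated), motif) == ps.similarity_index(
            window, motif
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=random_sequences, motif=random_motifs())
    def test_reported_phosphosites_are_s_or_t(self, seq, motif):
        for h in ps.scan_protein(("p", seq), motif, 0.0):
            assert seq[h.phospho_position - 1] in "ST"
            assert h.window == seq[h.start - 1 : h.end]
            assert h.similarity == sum(h.per_position_match) / motif.length
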