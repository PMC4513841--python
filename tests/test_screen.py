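"""Coverage-based presence calls: parser, interval merging, candidate ranking."""
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from negselect.screen import (
    AlignmentHit,
    candidate_toxins,
    gene_coverage,
    merge_intervals,
    parse_hit_table,
    presence_matrix,
    write_hit_table,
)


def _hit(gene="toxA", genome="G1", qstart=1, qend=100, **kw):
    defaults = dict(
        percent_identity=95.0,
        alignment_length=abs(qend - qstart) + 1,
        mismatches=5,
        gap_opens=0,
        subject_start=1000,
        subject_end=1000 + abs(qend - qstart),
        evalue=1e-50,
        bitscore=180.0,
    )
    defaults.update(kw)
    return AlignmentHit(gene=gene, genome=genome, query_start=qstart, query_end=qend, **defaults)


class TestParser:
    def test_empty_input(self):
        assert parse_hit_table(io.StringIO("")) == []

    def test_reverse_orientation_normalised(self):
        row = "toxA\tG1\t95.0\t81\t4\t0\t90\t10\t500\t580\t1e-30\t150.0\n"
        [hit] = parse_hit_table(io.StringIO(row))
        assert (hit.query_start, hit.query_end) == (10, 90)

    def test_round_trip_identity(self):
        hits = [_hit(qstart=5, qend=250), _hit(genome="G2", qstart=1, qend=300)]
        buf = io.StringIO()
        write_hit_table(hits, buf)
        assert parse_hit_table(io.StringIO(buf.getvalue())) == hits

    def test_comment_lines_skipped(self):
        text = "# BLASTN 2.2.28+\n# Query: toxA\ntoxA\tG1\t95\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180\n"
        assert len(parse_hit_table(io.StringIO(text))) == 1

    def test_malformed_row_reports_line_number(self):
        text = "toxA\tG1\t95\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180\nbad\trow\n"
        with pytest.raises(ValueError, match="line 2"):
            parse_hit_table(io.StringIO(text))

    def test_crlf_and_lf_parse_identically(self):
        row = "toxA\tG1\t95\t100\t5\t0\t1\t100\t1\t100\t1e-50\t180"
        assert parse_hit_table(io.StringIO(row + "\n")) == parse_hit_table(
            io.StringIO(row + "\r\n")
        )


class TestGeneCoverage:
    def test_no_hits(self):
        assert gene_coverage([], 300) == 0.0

    def test_overlapping_hits_merge(self):
        hits = [_hit(qstart=1, qend=150), _hit(qstart=140, qend=290)]
        assert gene_coverage(hits, 300) == pytest.approx(290 / 300)

    def test_full_length_hit(self):
        assert gene_coverage([_hit(qstart=1, qend=300)], 300) == 1.0

    def test_hits_clipped_to_gene(self):
        assert gene_coverage([_hit(qstart=250, qend=400)], 300) == pytest.approx(51 / 300)

    def test_adjacent_intervals_merge(self):
        assert merge_intervals([(1, 100), (101, 200)]) == [(1, 200)]

    def test_order_permutation_invariance(self):
        hits = [_hit(qstart=a, qend=b) for a, b in [(10, 50), (200, 250), (40, 120)]]
        assert gene_coverage(hits, 300) == gene_coverage(hits[::-1], 300)

    def test_splitting_a_hit_into_abutting_halves(self):
        whole = [_hit(qstart=10, qend=200)]
        halves = [_hit(qstart=10, qend=100), _hit(qstart=101, qend=200)]
        assert gene_coverage(whole, 300) == gene_coverage(halves, 300)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        gene_length=st.integers(1, 1000),
        raw=st.lists(
            st.tuples(st.integers(1, 1200), st.integers(0, 200)), min_size=0, max_size=20
        ),
    )
    def test_matches_per_base_oracle(self, gene_length, raw):
        """Merged-interval coverage equals a brute-force boolean-array oracle."""
        hits = [
            _hit(qstart=start, qend=start + span) for start, span in raw
        ]
        mask = np.zeros(gene_length, dtype=bool)
        for h in hits:
            lo, hi = h.query_interval
            lo, hi = max(lo, 1), min(hi, gene_length)
            if lo <= hi:
                mask[lo - 1 : hi] = True
        assert gene_coverage(hits, gene_length) == pytest.approx(mask.sum() / gene_length)


class TestPresenceMatrix:
    def test_threshold_is_inclusive(self):
        lengths = {"toxA": 100}
        at = presence_matrix([_hit(qstart=1, qend=80)], lengths)
        below = presence_matrix([_hit(qstart=1, qend=79)], lengths)
        assert bool(at.presence.loc["toxA", "G1"]) is True
        assert bool(below.presence.loc["toxA", "G1"]) is False

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            presence_matrix([_hit(gene="mystery")], {"toxA": 100})

    def test_hitless_panel_genomes_all_absent(self):
        m = presence_matrix([_hit()], {"toxA": 100}, genomes=["G1", "G2"])
        assert not m.presence.loc["toxA", "G2"]


class TestCandidateRanking:
    def _matrix(self):
        lengths = {"relE": 288, "mqsR": 297, "ydaS": 228, "common": 300}
        hits = []
        # 'common' present everywhere; 'mqsR' present in target; others absent in target
        genomes = ["target"] + [f"P{i}" for i in range(55)]
        for g in genomes:
            hits.append(_hit(gene="common", genome=g, qstart=1, qend=300))
        hits.append(_hit(gene="mqsR", genome="target", qstart=1, qend=297))
        # relE present in 27 panel genomes -> absent in 28/55 (> half)
        for i in range(27):
            hits.append(_hit(gene="relE", genome=f"P{i}", qstart=1, qend=288))
        # ydaS present in 28 -> absent in 27/55 (not > half)
        for i in range(28):
            hits.append(_hit(gene="ydaS", genome=f"P{i}", qstart=1, qend=228))
        return presence_matrix(hits, lengths, genomes=genomes), [f"P{i}" for i in range(55)]

    def test_target_presence_excludes_gene(self):
        matrix, panel = self._matrix()
        out = candidate_toxins(matrix, "target", panel)
        assert set(out["gene"]) == {"relE", "ydaS"}  # mqsR and common excluded

    def test_majority_absence_flag_strictly_more_than_half(self):
        matrix, panel = self._matrix()
        out = candidate_toxins(matrix, "target", panel).set_index("gene")
        assert out.loc["relE", "absence_fraction"] == pytest.approx(28 / 55)
        assert bool(out.loc["relE", "majority_absent"])
        assert not bool(out.loc["ydaS", "majority_absent"])

    def test_sorted_by_absence_then_length_then_name(self):
        matrix, panel = self._matrix()
        out = candidate_toxins(matrix, "target", panel)
        assert list(out["gene"]) == ["relE", "ydaS"]  # 28/55 before 27/55

    def test_empty_gene_set(self):
        m = presence_matrix([], {}, genomes=["target", "P0"])
        assert candidate_toxins(m, "target", ["P0"]).empty

    def test_unknown_genome_error(self):
        matrix, panel = self._matrix()
        with pytest.raises(KeyError):
            candidate_toxins(matrix, "nope", panel)
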