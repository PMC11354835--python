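"""Global-alignment identity and haplotype assignment."""

import logging

import numpy as np
import pandas as pd
import pytest

import wingmorph as wm
from wingmorph.errors import AnalysisError, ConfigError
from wingmorph.haplotype import SequenceRecord

E2_PRIMER = "GGCAGAATAAGTGCATTG"


def nw_score_oracle(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0):
    """Tiny dynamic-programming Needleman-Wunsch score (no traceback);
    N never matches."""
    n, m = len(a), len(b)
    prev = np.arange(m + 1, dtype=float) * gap
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = i * gap
        for j in range(1, m + 1):
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIdentity:
    def test_self_identity_primer(self):
        s = SequenceRecord("E2", E2_PRIMER)
        assert wm.global_align_identity(s, s) == pytest.approx(100.0)

    def test_hand_alignment(self):
        a = SequenceRecord("a", "ACGT")
        b = SequenceRecord("b", "ACGA")
        assert wm.global_align_identity(a, b) == pytest.approx(75.0)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = SequenceRecord("a", random_seq(rng, 100))
            b = SequenceRecord("b", random_seq(rng, 100))
            assert wm.global_align_identity(a, b) == pytest.approx(
                wm.global_align_identity(b, a), abs=1e-9
            )

    def test_alignment_score_matches_dp_oracle(self, rng):
        """The alignment underlying the identity achieves the optimal NW
        score computed by an independent dynamic program."""
        from wingmorph.haplotype import _make_aligner

        for _ in range(5):
            n = int(rng.integers(10, 40))
            a, b = random_seq(rng, n), random_seq(rng, n + int(rng.integers(0, 8)))
            aligner = _make_aligner(1.0, 0.0, -1.0, False)
            score = aligner.score(a, b)
            assert score == pytest.approx(nw_score_oracle(a, b), abs=1e-9)

    def test_bounds(self, rng):
        a = SequenceRecord("a", random_seq(rng, 50))
        b = SequenceRecord("b", random_seq(rng, 60))
        ident = wm.global_align_identity(a, b)
        assert 0 <= ident <= 100

    def test_n_never_matches(self):
        a = SequenceRecord("a", "AN")
        b = SequenceRecord("b", "AN")
        assert wm.global_align_identity(a, b) == pytest.approx(50.0)
        assert wm.global_align_identity(a, b, n_matches_n=True) == pytest.approx(100.0)

    def test_gap_columns_in_denominator(self):
        a = SequenceRecord("a", "ACGTACGT")
        b = SequenceRecord("b", "ACGTACGTAA")
        # 8 matches over 10 columns (2 gap columns)
        assert wm.global_align_identity(a, b) == pytest.approx(80.0)

    def test_empty_and_bad_alphabet_rejected(self):
        with pytest.raises(AnalysisError):
            SequenceRecord("x", "")
        with pytest.raises(AnalysisError):
            SequenceRecord("x", "ACGU")


class TestAssignment:
    def panel(self, rng, n=4, length=80, divergence=0.1):
        return wm.make_haplotype_panel(
            n_haplotypes=n, length=length, divergence=divergence, seed=11
        )

    def test_exact_member_hit(self, rng):
        panel = self.panel(rng)
        q = SequenceRecord("q", panel[2].record.seq)
        a = wm.assign_haplotype(q, panel)
        assert a.best_haplotype == panel[2].haplotype
        assert a.identity_pct == pytest.approx(100.0)

    def test_tie_lexicographic_with_warning(self, caplog):
        panel = [
            wm.PanelEntry(SequenceRecord("B1", "ACGTACGT"), "B1", "M"),
            wm.PanelEntry(SequenceRecord("A9", "ACGTACGT"), "A9", "A"),
        ]
        q = SequenceRecord("q", "ACGTACGA")
        with caplog.at_level(logging.WARNING, logger="wingmorph.haplotype"):
            a = wm.assign_haplotype(q, panel)
        assert a.best_haplotype == "A9"  # lexicographically first on tie
        assert a.margin == pytest.approx(0.0)
        assert "ambiguous" in caplog.text

    def test_panel_order_invariance(self, rng):
        panel = self.panel(rng)
        q = SequenceRecord("q", panel[1].record.seq[:-3])
        a1 = wm.assign_haplotype(q, panel)
        a2 = wm.assign_haplotype(q, panel[::-1])
        assert a1.best_haplotype == a2.best_haplotype
        assert a1.identity_pct == pytest.approx(a2.identity_pct)

    def test_mutated_query_recovered(self, rng):
        """A query at 3% substitutions keeps its haplotype and lands near
        97% identity."""
        panel = wm.make_haplotype_panel(
            n_haplotypes=5, length=400, divergence=0.08, seed=13
        )
        queries = wm.mutate_sequences(panel, rate=0.03, n_per_haplotype=2, seed=14)
        idents = []
        for q, truth in queries:
            a = wm.assign_haplotype(q, panel)
            assert a.best_haplotype == truth
            idents.append(a.identity_pct)
        assert np.mean(idents) == pytest.approx(97.0, abs=1.0)

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ConfigError):
            wm.assign_haplotype(SequenceRecord("q", "ACGT"), [])

    def test_assign_all_frame(self, rng):
        panel = self.panel(rng)
        queries = [SequenceRecord(f"q{i}", e.record.seq) for i, e in enumerate(panel)]
        df = wm.assign_all(queries, panel)
        assert list(df.columns[:4]) == ["query_id", "identity_pct", "haplotype", "lineage"]
        assert (df["identity_pct"] == 100.0).all()
        assert (df["lineage"] == "A").all()


class TestFastaIO:
    def test_fasta_and_panel_round_trip(self, tmp_path, rng):
        panel = wm.make_haplotype_panel(n_haplotypes=3, length=60, seed=5)
        fasta = tmp_path / "panel.fasta"
        with open(fasta, "w") as fh:
            for e in panel:
                fh.write(f">{e.haplotype}\n{e.record.seq}\n")
        table = tmp_path / "panel.csv"
        pd.DataFrame(
            {"haplotype": [e.haplotype for e in panel],
             "lineage": [e.lineage for e in panel]}
        ).to_csv(table, index=False)
        back = wm.read_panel(fasta, table)
        assert [e.haplotype for e in back] == [e.haplotype for e in panel]
        assert [e.record.seq for e in back] == [e.record.seq for e in panel]

    def test_missing_lineage_column(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">A1\nACGT\n")
        table = tmp_path / "p.csv"
        table.write_text("haplotype\nA1\n")
        with pytest.raises(ConfigError, match="lineage"):
            wm.read_panel(fasta, table)

    def test_amplicon_length_warning(self, tmp_path, caplog):
        fasta = tmp_path / "q.fasta"
        fasta.write_text(">short\nACGTACGT\n")
        with caplog.at_level(logging.WARNING, logger="wingmorph.haplotype"):
            wm.read_fasta(fasta, check_amplicon=True)
        assert "amplicon" in caplog.text
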