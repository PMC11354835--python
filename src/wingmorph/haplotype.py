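"""mtDNA haplotype assignment by global-alignment percent identity.

Query tRNALeu-COII intergenic sequences are aligned globally
(Needleman-Wunsch, match = 1, mismatch = 0, gap = -1 by default) against a
user-supplied reference haplotype panel; percent identity is

    100 * matched columns / aligned columns

with gapped columns counted in the denominator (global identity).  The
best-identity panel member gives the haplotype call and, through the panel
metadata table, the maternal lineage (A / M / C).  ``N`` never matches
anything and is scored as a mismatch by default (conservative;
configurable).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import AnalysisError, ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "PanelEntry",
    "HaplotypeAssignment",
    "read_fasta",
    "read_panel",
    "global_align_identity",
    "assign_haplotype",
    "assign_all",
]

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: Amplicon length range considered typical for the tRNALeu-COII fragment;
#: sequences outside it are accepted with a logged warning.
AMPLICON_RANGE = (400, 740)


@dataclass(frozen=True)
class SequenceRecord:
    """A named IUPAC DNA sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0:
            raise AnalysisError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise AnalysisError(
                f"sequence {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PanelEntry:
    record: SequenceRecord
    haplotype: str
    lineage: str


@dataclass
class HaplotypeAssignment:
    """Best-hit haplotype call for one query sequence."""

    query_id: str
    best_haplotype: str
    lineage: str
    identity_pct: float
    runner_up: Optional[str]
    runner_up_identity_pct: Optional[float]

    @property
    def margin(self) -> Optional[float]:
        if self.runner_up_identity_pct is None:
            return None
        return self.identity_pct - self.runner_up_identity_pct


def read_fasta(path: str | os.PathLike, check_amplicon: bool = False) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; with check_amplicon, warn about
    lengths outside the typical tRNALeu-COII amplicon range."""
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(os.fspath(path), "fasta")
    ]
    if not records:
        raise ConfigError(f"no FASTA records found in {os.fspath(path)!r}")
    if check_amplicon:
        lo, hi = AMPLICON_RANGE
        for rec in records:
            if not (lo <= len(rec) <= hi):
                logger.warning(
                    "sequence %s length %d outside typical amplicon range %d-%d",
                    rec.id, len(rec), lo, hi,
                )
    return records


def read_panel(fasta_path, table_path) -> list[PanelEntry]:
    """Reference panel: FASTA keyed by haplotype name plus a CSV with
    columns haplotype, lineage."""
    records = read_fasta(fasta_path)
    table = pd.read_csv(os.fspath(table_path), dtype=str)
    for col in ("haplotype", "lineage"):
        if col not in table.columns:
            raise ConfigError(f"panel table must have a {col!r} column")
    lineage = dict(zip(table["haplotype"], table["lineage"]))
    entries = []
    for rec in records:
        if rec.id not in lineage:
            raise ConfigError(f"panel sequence {rec.id!r} missing from the lineage table")
        entries.append(PanelEntry(record=rec, haplotype=rec.id, lineage=lineage[rec.id]))
    return entries


def _make_aligner(match: float, mismatch: float, gap: float,
                  n_matches_n: bool) -> PairwiseAligner:
    alphabet = "".join(sorted(IUPAC_DNA))
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and (a != "N" or n_matches_n):
                mat[a, b] = match
            else:
                mat[a, b] = mismatch
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_align_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    n_matches_n: bool = False,
) -> float:
    """Percent identity of the optimal Needleman-Wunsch global alignment.

    Identity = 100 x matched columns / aligned columns; gap columns count
    in the denominator.  A column matches when both characters are equal
    and not N (set n_matches_n=True to let N match itself).

    Optimal global alignments are generally not unique and can differ in
    their match counts, which would make the identity depend on traceback
    order.  The identity is therefore defined over the optimal alignments
    that additionally maximize the number of matches, achieved by adding a
    small match bonus that cannot change the primary optimum (exact for
    integer-valued scores); this also makes identity(a, b) = identity(b, a).
    """
    k_scale = 2 * min(len(a.seq), len(b.seq)) + 2
    aligner = _make_aligner(
        k_scale * match + 1, k_scale * mismatch, k_scale * gap, n_matches_n
    )
    aln = aligner.align(a.seq, b.seq)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    columns = len(s1)
    matches = sum(
        1 for ca, cb in zip(s1, s2)
        if ca == cb and ca != "-" and (ca != "N" or n_matches_n)
    )
    return 100.0 * matches / columns


def assign_haplotype(
    query: SequenceRecord,
    panel: Sequence[PanelEntry],
    ambiguity_margin: float = 0.5,
    **align_kwargs,
) -> HaplotypeAssignment:
    """Best-hit assignment of a query against the panel.

    Ties go to the lexicographically first haplotype name; margins below
    ambiguity_margin percentage points trigger a logged warning.
    """
    if not panel:
        raise ConfigError("haplotype panel is empty")
    scored = sorted(
        (
            (-global_align_identity(query, entry.record, **align_kwargs),
             entry.haplotype, entry)
            for entry in panel
        ),
    )
    best_identity, best_entry = -scored[0][0], scored[0][2]
    runner_up = scored[1][2] if len(scored) > 1 else None
    runner_identity = -scored[1][0] if len(scored) > 1 else None
    if runner_identity is not None and best_identity - runner_identity < ambiguity_margin:
        logger.warning(
            "ambiguous haplotype for %s: %s (%.2f%%) vs %s (%.2f%%)",
            query.id, best_entry.haplotype, best_identity,
            runner_up.haplotype, runner_identity,
        )
    return HaplotypeAssignment(
        query_id=query.id,
        best_haplotype=best_entry.haplotype,
        lineage=best_entry.lineage,
        identity_pct=best_identity,
        runner_up=None if runner_up is None else runner_up.haplotype,
        runner_up_identity_pct=runner_identity,
    )


def assign_all(
    queries: Iterable[SequenceRecord],
    panel: Sequence[PanelEntry],
    **kwargs,
) -> pd.DataFrame:
    """Assign every query; returns a table with columns mirroring the
    standard report layout (query, identity %, haplotype, lineage)."""
    rows = []
    for query in queries:
        a = assign_haplotype(query, panel, **kwargs)
        rows.append(
            {
                "query_id": a.query_id,
                "identity_pct": round(a.identity_pct, 2),
                "haplotype": a.best_haplotype,
                "lineage": a.lineage,
                "runner_up": a.runner_up,
                "margin_pct": None if a.margin is None else round(a.margin, 2),
            }
        )
    return pd.DataFrame(rows)
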