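"""Conservation features from shallow vertebrate/mammal alignments.

Whole-genome-alignment MSAs of ~100 vertebrates or ~30 mammals are shallow
but orthologous and close to human, so simple per-column frequencies carry
strong pathogenicity signal that deep, redundancy-filtered protein-family
models discard.  This module computes, per variant, the wild-type, mutant
and gap frequencies at the variant's column, log-transformed with offset 1,
and reconciles alignments built on a different isoform with the canonical
sequence via local pairwise alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import AMINO_ACIDS, GAP, AnchoredMSA, VariantKey


@dataclass
class AlignmentScoring:
    """Local pairwise-alignment scoring used for isoform reconciliation."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -0.5

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


def project_to_query(msa_rows: list[str], canonical: str,
                     scoring: AlignmentScoring | None = None,
                     gene: str = "", source: str = "vert100") -> AnchoredMSA:
    """Re-anchor a raw query-anchored MSA onto the canonical sequence.

    The raw MSA's query (row 0, gaps removed) may be a different isoform of
    the protein.  A local alignment of that query against ``canonical``
    defines a column map; only columns inside the aligned fragment are
    retained.  Canonical positions with no aligned raw column are flagged
    missing (``column_missing``) so downstream frequency features at those
    positions flow to within-gene imputation.  A best local alignment score
    <= 0 flags the whole gene missing rather than raising.
    """
    if not canonical:
        raise ValueError("canonical sequence must be non-empty")
    if not msa_rows:
        raise ValueError("raw MSA must contain at least the query row")
    scoring = scoring or AlignmentScoring()
    raw_query_aln = msa_rows[0]
    raw_query = raw_query_aln.replace(GAP, "")
    L = len(canonical)

    def all_missing() -> AnchoredMSA:
        return AnchoredMSA(
            gene=gene, query=canonical,
            rows=[canonical] + [GAP * L] * (len(msa_rows) - 1),
            source=source, column_missing=np.ones(L, dtype=bool),
        )

    if not raw_query:
        return all_missing()
    aligner = scoring.aligner()
    score = aligner.score(canonical, raw_query)
    if score <= 0:
        return all_missing()
    aln = aligner.align(canonical, raw_query)[0]
    # aligned blocks: pairs of (canonical range, raw-query range)
    canon_to_raw: dict[int, int] = {}  # 0-based canonical -> 0-based raw query residue
    for (cs, ce), (rs, re) in zip(*aln.aligned):
        for k in range(ce - cs):
            canon_to_raw[cs + k] = rs + k
    # map raw-query residue index -> raw MSA column
    raw_res_to_col: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(raw_query_aln):
        if ch != GAP:
            raw_res_to_col[res] = col
            res += 1
    column_missing = np.ones(L, dtype=bool)
    out_rows = [list(GAP * L) for _ in range(len(msa_rows) - 1)]
    for cpos, rres in canon_to_raw.items():
        col = raw_res_to_col[rres]
        column_missing[cpos] = False
        for i, row in enumerate(msa_rows[1:]):
            out_rows[i][cpos] = row[col]
    return AnchoredMSA(
        gene=gene, query=canonical,
        rows=[canonical] + ["".join(r) for r in out_rows],
        source=source, column_missing=column_missing,
    )


def column_frequencies(msa: AnchoredMSA, key: VariantKey,
                       include_query: bool = True) -> tuple[float, float, float]:
    """Wild-type, mutant and gap frequency at the variant's column.

    The denominator is the number of alignment rows (including the human
    query row by default; set ``include_query=False`` to exclude it).
    Nonstandard letters ('X' and other ambiguity codes) count toward the
    denominator but never toward the wild-type or mutant counts.  Returns
    NaNs at columns flagged missing.
    """
    col = msa.column(key.position)
    if msa.column_missing[key.position - 1]:
        return (math.nan, math.nan, math.nan)
    if not include_query:
        col = col[1:]
    n = len(col)
    if n == 0:
        return (math.nan, math.nan, math.nan)
    wt = sum(1 for c in col if c == key.wt_aa)
    mut = sum(1 for c in col if c == key.mut_aa)
    gap = sum(1 for c in col if c == GAP)
    return (wt / n, mut / n, gap / n)


def aa_and_gap_frequencies(msa: AnchoredMSA, position: int,
                           include_query: bool = True) -> dict[str, float]:
    """All 20 amino-acid frequencies plus gap frequency at a column.

    With nonstandard letters mapped to an ``X`` bucket, the returned values
    sum to 1 exactly.
    """
    col = msa.column(position)
    if not include_query:
        col = col[1:]
    n = len(col)
    freqs = {aa: 0.0 for aa in AMINO_ACIDS}
    freqs[GAP] = 0.0
    freqs["X"] = 0.0
    for c in col:
        bucket = c if (c in AMINO_ACIDS or c == GAP) else "X"
        freqs[bucket] += 1.0 / n
    return freqs


def log_offset(freq: float) -> float:
    """Natural log of (frequency + 1); maps [0, 1] to [0, ln 2] monotonically."""
    if math.isnan(freq):
        return math.nan
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency must lie in [0, 1], got {freq}")
    return math.log1p(freq)


def variant_seen_in_alignment(msa: AnchoredMSA, key: VariantKey) -> bool:
    """True iff the mutant residue appears in any non-query row at the position.

    Observation of the mutant allele as the reference residue of another
    species is strong evidence of benignity; the query (human) row itself
    never counts.
    """
    if msa.column_missing[key.position - 1]:
        return False
    col = msa.column(key.position)
    return any(c == key.mut_aa for c in col[1:])
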