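"""Adapters for externally computed predictor scores and descriptor deltas.

External zero-shot predictors (family density models, masked language
models, inverse-folding networks) are consumed as precomputed
log-probability columns, never run here.  The adapters normalize them to
wild-type-relative log-likelihood ratios, stitch sliding-window scores for
proteins longer than a model's context limit, and compute amino-acid
descriptor differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import VariantKey

Window = tuple[int, int]


@dataclass
class WindowSpec:
    """Sliding-window scheme for long proteins.

    Proteins up to ``max_direct_length`` residues are scored in one pass;
    longer ones with overlapping ``window_length``-residue windows whose
    starts are ``stride`` apart, the final window right-aligned to the
    protein's C-terminus.
    """

    window_length: int = 1000
    stride: int = 250
    max_direct_length: int = 1022

    def __post_init__(self):
        if min(self.window_length, self.stride, self.max_direct_length) < 1:
            raise ValueError("window parameters must be positive")
        if self.stride > self.window_length:
            raise ValueError("stride must not exceed window_length")


def llr_normalize(logp_mut: float, logp_wt: float) -> float:
    """Wild-type-relative log-likelihood ratio: logp(mut) - logp(wt).

    Non-finite inputs yield NaN (missing) rather than an error.
    """
    if not (math.isfinite(logp_mut) and math.isfinite(logp_wt)):
        return math.nan
    return logp_mut - logp_wt


def plan_windows(protein_length: int, spec: WindowSpec | None = None) -> list[Window]:
    """1-based inclusive score windows covering every residue.

    A protein within the direct-length limit gets one full-protein window.
    Otherwise windows start at 1, 1+stride, ... while they fit strictly
    inside the protein, and a final window is right-aligned to end at the
    last residue.
    """
    spec = spec or WindowSpec()
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    if protein_length <= spec.max_direct_length:
        return [(1, protein_length)]
    windows: list[Window] = []
    start = 1
    while start + spec.window_length - 1 < protein_length:
        windows.append((start, start + spec.window_length - 1))
        start += spec.stride
    final_start = protein_length - spec.window_length + 1
    if not windows or final_start > windows[-1][0]:
        windows.append((final_start, protein_length))
    return windows


def window_center(window: Window) -> float:
    start, end = window
    return (start + end) / 2.0


def stitch_window_scores(per_window_scores: Mapping[Window, Mapping[VariantKey, float]],
                         key: VariantKey,
                         spec: WindowSpec | None = None) -> float:
    """Score from the covering window whose center is closest to the variant.

    Window centers carry the richest context, so among windows containing
    the position (and holding a score for this variant) the one minimizing
    |position - center| wins; ties go to the earlier window.  Returns NaN
    when no covering window has a score.
    """
    pos = key.position
    best: tuple[float, int] | None = None
    best_score = math.nan
    for window in per_window_scores:
        start, end = window
        if not start <= pos <= end:
            continue
        scores = per_window_scores[window]
        if key not in scores:
            continue
        rank = (abs(pos - window_center(window)), start)
        if best is None or rank < best:
            best = rank
            best_score = scores[key]
    return best_score


def descriptor_delta(wt_aa: str, mut_aa: str,
                     table: Mapping[str, pd.Series]) -> pd.Series:
    """Component-wise descriptor difference: table[mut] - table[wt]."""
    for aa in (wt_aa, mut_aa):
        if aa not in table:
            raise KeyError(f"amino acid {aa!r} absent from descriptor table")
    return table[mut_aa] - table[wt_aa]
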