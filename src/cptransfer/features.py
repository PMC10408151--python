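"""Feature assembly: turn raw inputs into a variants-by-features table.

Combines, per variant: log-offset conservation frequencies from each
shallow alignment source, structure-conditioned wild-type/mutant scores
from the deep alignment, site features (contact count, pLDDT), external
predictor score columns, and amino-acid descriptor deltas.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adapters import descriptor_delta
from .conservation import column_frequencies, log_offset
from .io import ColumnMeta, FeatureTable, AnchoredMSA, StructureInfo, VariantKey
from .structure import ConditioningSpec, conditioned_scores, pick_conditioning_residues, site_features

#: External predictor columns and the category they belong to.
SCORE_CATEGORY = {
    "esm_llr": "homology",
    "eve_logp": "homology",
    "mpnn_llr": "inverse_folding",
}


def conservation_columns(msa: AnchoredMSA, keys: Sequence[VariantKey],
                         include_query: bool = True) -> dict[str, np.ndarray]:
    """Log-offset wt/mut/gap frequency columns named ``{source}_{...}_freq_log``."""
    wt = np.empty(len(keys))
    mut = np.empty(len(keys))
    gap = np.empty(len(keys))
    for i, k in enumerate(keys):
        if k.position > msa.length:
            wt[i] = mut[i] = gap[i] = math.nan
            continue
        fw, fm, fg = column_frequencies(msa, k, include_query=include_query)
        wt[i] = log_offset(fw) if not math.isnan(fw) else math.nan
        mut[i] = log_offset(fm) if not math.isnan(fm) else math.nan
        gap[i] = log_offset(fg) if not math.isnan(fg) else math.nan
    s = msa.source
    return {f"{s}_wt_freq_log": wt, f"{s}_mut_freq_log": mut, f"{s}_gap_freq_log": gap}


def structure_columns(structure: StructureInfo | None, deep_msa: AnchoredMSA | None,
                      keys: Sequence[VariantKey],
                      spec: ConditioningSpec | None = None,
                      include_query: bool = True) -> dict[str, np.ndarray]:
    """cond_wt_score, cond_mut_score, contact_count and plddt columns."""
    spec = spec or ConditioningSpec()
    n = len(keys)
    cond_wt = np.full(n, math.nan)
    cond_mut = np.full(n, math.nan)
    ccount = np.full(n, math.nan)
    plddt = np.full(n, math.nan)
    cond_cache: dict[int, list[int]] = {}
    for i, k in enumerate(keys):
        if structure is not None:
            ccount[i], plddt[i] = site_features(structure, k.position)
        if structure is None or deep_msa is None or k.position > deep_msa.length:
            continue
        if k.position not in cond_cache:
            cond_cache[k.position] = pick_conditioning_residues(
                k.position, structure, deep_msa, spec)
        cond_wt[i], cond_mut[i] = conditioned_scores(
            deep_msa, k, cond_cache[k.position],
            min_filtered_rows=spec.min_filtered_rows, include_query=include_query)
    return {"cond_wt_score": cond_wt, "cond_mut_score": cond_mut,
            "contact_count": ccount, "plddt": plddt}


def score_columns(score_maps: Mapping[str, Mapping[VariantKey, float]],
                  keys: Sequence[VariantKey]) -> dict[str, np.ndarray]:
    """Align external predictor score maps (already normalized) to the keys."""
    out = {}
    for name, scores in score_maps.items():
        out[name] = np.array([scores.get(k, math.nan) for k in keys])
    return out


def descriptor_columns(table: Mapping[str, pd.Series],
                       keys: Sequence[VariantKey]) -> dict[str, np.ndarray]:
    """One ``desc_{scale}`` delta column per descriptor scale."""
    if not keys:
        return {}
    scales = list(next(iter(table.values())).index)
    cols = {f"desc_{s}": np.empty(len(keys)) for s in scales}
    for i, k in enumerate(keys):
        delta = descriptor_delta(k.wt_aa, k.mut_aa, table)
        for s in scales:
            cols[f"desc_{s}"][i] = delta[s]
    return cols


def build_feature_table(keys: Sequence[VariantKey],
                        msas: Mapping[str, AnchoredMSA] | None = None,
                        structure: StructureInfo | None = None,
                        deep_msa: AnchoredMSA | None = None,
                        score_maps: Mapping[str, Mapping[VariantKey, float]] | None = None,
                        descriptors: Mapping[str, pd.Series] | None = None,
                        conditioning: ConditioningSpec | None = None,
                        include_query: bool = True) -> FeatureTable:
    """Assemble the full feature table for one gene's variants.

    ``msas`` maps source labels (e.g. ``vert100``, ``mamm30``) to anchored
    alignments; ``score_maps`` maps external predictor column names
    (``esm_llr``, ``eve_logp``, ``mpnn_llr``) to keyed score maps.
    """
    columns: dict[str, np.ndarray] = {}
    meta: dict[str, ColumnMeta] = {}
    for source, msa in (msas or {}).items():
        cons = conservation_columns(msa, keys, include_query=include_query)
        columns.update(cons)
        for name in cons:
            meta[name] = ColumnMeta(source, is_frequency=True)
    if structure is not None:
        struct = structure_columns(structure, deep_msa, keys,
                                   spec=conditioning, include_query=include_query)
        columns.update(struct)
        meta["cond_wt_score"] = ColumnMeta("conditioned", is_frequency=True)
        meta["cond_mut_score"] = ColumnMeta("conditioned", is_frequency=True)
        meta["contact_count"] = ColumnMeta("structure_site")
        meta["plddt"] = ColumnMeta("structure_site")
    for name, col in score_columns(score_maps or {}, keys).items():
        columns[name] = col
        meta[name] = ColumnMeta(SCORE_CATEGORY.get(name, "homology"))
    if descriptors:
        for name, col in descriptor_columns(descriptors, keys).items():
            columns[name] = col
            meta[name] = ColumnMeta("descriptor")
    return FeatureTable(list(keys), columns, meta)


def candidate_categories(table: FeatureTable) -> dict[str, list[str]]:
    """Group a table's columns by selection category, preserving column order."""
    out: dict[str, list[str]] = {}
    for name in table.feature_names:
        out.setdefault(table.column_meta[name].category, []).append(name)
    return out
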