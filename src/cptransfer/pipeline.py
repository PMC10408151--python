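"""Directory-based workflow: the glue between the fixture tree and the model.

The on-disk layout is one directory per gene (``canonical.fasta``,
``vert100.fasta`` on its own isoform query, ``mamm30.fasta``,
``deep.fasta``, ``contacts.tsv`` + ``plddt.tsv``, per-predictor score
TSVs, ``dms.tsv``) plus family-level ``labels.tsv`` and
``descriptors.csv``.  These functions power the ``cpt`` CLI and keep it a
thin shell over the library.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .conservation import project_to_query
from .features import build_feature_table
from .impute import ImputerSpec, impute_table
from .io import DMSDataset, FeatureTable, LabeledVariantSet, VariantKey
from .model import TrainingConfig, fit_cpt
from .simulate import EXTERNAL_SCORES


def discover_genes(root: str | Path) -> list[str]:
    root = Path(root)
    return sorted(p.name for p in root.iterdir() if (p / "canonical.fasta").exists())


def load_gene_inputs(root: str | Path, gene: str) -> dict:
    gd = Path(root) / gene
    canonical = next(iter(cio.read_anchored_msa(gd / "canonical.fasta", "canon", gene).rows))
    raw_vert = cio.read_anchored_msa(gd / "vert100.fasta", "vert100", gene)
    vert = project_to_query(raw_vert.rows, canonical, gene=gene, source="vert100")
    mamm = cio.read_anchored_msa(gd / "mamm30.fasta", "mamm30", gene)
    deep = cio.read_anchored_msa(gd / "deep.fasta", "deep", gene)
    structure = cio.read_structure(gd / "contacts.tsv", gene=gene,
                                   plddt_path=gd / "plddt.tsv")
    scores = {}
    for name in EXTERNAL_SCORES:
        f = gd / f"{name}.tsv"
        if f.exists():
            scores[name] = cio.read_score_table(f, column="value")
    dms = cio.read_dms_table(gd / "dms.tsv", gene=gene) if (gd / "dms.tsv").exists() else None
    return {"canonical": canonical, "msas": {"vert100": vert, "mamm30": mamm},
            "deep": deep, "structure": structure, "scores": scores, "dms": dms}


def featurize_tree(root: str | Path,
                   variants: dict[str, list[VariantKey]] | None = None,
                   ) -> dict[str, FeatureTable]:
    """Compute per-gene feature tables for a fixture tree.

    By default the variant set of a gene is the union of keys appearing in
    its score tables, DMS table and the family label table.
    """
    root = Path(root)
    descriptors = cio.read_descriptor_table(root / "descriptors.csv")
    labels = (cio.read_label_table(root / "labels.tsv")
              if (root / "labels.tsv").exists() else None)
    tables = {}
    for gene in discover_genes(root):
        inputs = load_gene_inputs(root, gene)
        if variants and gene in variants:
            keys = variants[gene]
        else:
            seen: dict[VariantKey, None] = {}
            for scores in inputs["scores"].values():
                for k in scores:
                    seen.setdefault(k, None)
            if inputs["dms"] is not None:
                for k in inputs["dms"].keys:
                    seen.setdefault(k, None)
            if labels is not None:
                for k in labels.keys:
                    if k.gene == gene:
                        seen.setdefault(k, None)
            keys = list(seen)
        for k in keys:
            k.check_against(inputs["canonical"])
        tables[gene] = build_feature_table(
            keys, msas=inputs["msas"], structure=inputs["structure"],
            deep_msa=inputs["deep"], score_maps=inputs["scores"],
            descriptors=descriptors)
    return tables


def combine_tables(tables: dict[str, FeatureTable]) -> FeatureTable:
    frames = [t.to_frame() for t in tables.values()]
    meta = next(iter(tables.values())).column_meta
    return cio.feature_table_from_frame(pd.concat(frames, ignore_index=True), meta)


def split_by_gene(table: FeatureTable) -> dict[str, FeatureTable]:
    return {g: table.subset_gene(g) for g in table.genes()}


def impute_tree_features(table: FeatureTable,
                         spec: ImputerSpec | None = None) -> FeatureTable:
    return impute_table(table, spec=spec)


def load_dms(root: str | Path) -> dict[str, DMSDataset]:
    out = {}
    for gene in discover_genes(root):
        f = Path(root) / gene / "dms.tsv"
        if f.exists():
            out[gene] = cio.read_dms_table(f, gene=gene)
    return out


def align_to_table(table: FeatureTable, keys: list[VariantKey]) -> np.ndarray:
    index = {k: i for i, k in enumerate(table.keys)}
    return np.array([index[k] for k in keys])


def train_from_tree(root: str | Path, features_path: str | Path,
                    config: TrainingConfig | None = None,
                    features: list[str] | None = None):
    """Fit a transfer model from an imputed feature table and the tree's DMS data."""
    config = config or TrainingConfig()
    table = cio.read_feature_table(features_path)
    dms = load_dms(root)
    tables = {g: t for g, t in split_by_gene(table).items() if g in dms}
    dms_keep = {}
    for g, t in tables.items():
        have = set(t.keys)
        keep = [i for i, k in enumerate(dms[g].keys) if k in have]
        dms_keep[g] = DMSDataset(gene=g, keys=[dms[g].keys[i] for i in keep],
                                 scores=dms[g].scores[keep])
    return fit_cpt(tables, dms_keep, features=features, config=config)


def predictions_frame(table: FeatureTable, scores: np.ndarray) -> pd.DataFrame:
    out = table.to_frame()[["gene", "position", "wt", "mut"]]
    out["score"] = scores
    return out


def labeled_scores(labels: LabeledVariantSet, pred: pd.DataFrame
                   ) -> tuple[LabeledVariantSet, np.ndarray]:
    """Align a prediction frame to a label set, dropping unscored variants."""
    index = {
        VariantKey(g, int(p), w, m): s
        for g, p, w, m, s in zip(pred["gene"], pred["position"], pred["wt"],
                                 pred["mut"], pred["score"])
    }
    keep = [i for i, k in enumerate(labels.keys) if k in index]
    sub = LabeledVariantSet(keys=[labels.keys[i] for i in keep],
                            labels=labels.labels[keep])
    return sub, np.array([index[k] for k in sub.keys])
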