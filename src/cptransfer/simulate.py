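"""Synthetic protein-family generator with known generative structure.

Emulates everything the transfer pipeline consumes — shallow orthologous
alignments, a deep family alignment, a contact map with per-residue
confidence, external predictor score columns, assay (DMS) tables and
binary labels — from a single seeded generator, so every stage and the
end-to-end pipeline can be tested without downloads.

Generative model
----------------
Query sequences are uniform over the 20 residues.  Alignment rows copy
the query per position with a per-position conservation probability and
otherwise show a random residue or a gap.  Contacts come from a compact
random 3D chain; per-residue confidence is high in contact-dense regions.
A per-variant latent fitness is a fixed linear function of the computed
feature columns (standardized family-wide); external predictor columns
are noisy monotone functions of the core (non-predictor) part of that
latent; assay scores are per-protein affine transforms of the latent plus
Gaussian noise (the affine batch effects motivate the per-protein-model
ensemble); labels threshold the noise-free latent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .features import build_feature_table
from .io import (AMINO_ACIDS, AnchoredMSA, DMSDataset, FeatureTable,
                 LabeledVariantSet, StructureInfo, VariantKey)

#: Generative coefficients on standardized feature columns.  Orientation:
#: higher latent = higher fitness (functionally normal).
DEFAULT_WEIGHTS = {
    "vert100_wt_freq_log": 1.0,
    "vert100_mut_freq_log": 1.5,
    "mamm30_mut_freq_log": 1.0,
    "cond_mut_score": 0.8,
    "contact_count": -0.6,
    "esm_llr": 1.5,
    "eve_logp": 1.5,
    "mpnn_llr": 0.8,
    "desc_hydropathy": -0.4,
}

EXTERNAL_SCORES = ("esm_llr", "eve_logp", "mpnn_llr")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic family.

    Defaults emulate the real training regime at desk scale: six genes
    (five train, one held out, mirroring a handful of same-assay DMS
    proteins), alignments of 100 vertebrates / 30 mammals plus a deep
    200-row family MSA, per-protein affine batch effects, assay noise at
    20% of the signal SD, ~15% missing external density-model scores and a
    ~10% unaligned N-terminal isoform region in the vertebrate MSA.
    """

    seed: int = 0
    n_genes: int = 6
    length_range: tuple[int, int] = (60, 90)
    msa_depths: dict = field(default_factory=lambda: {
        "vert100": 100, "mamm30": 30, "deep": 200})
    conservation_strength: float = 0.8
    conservation_concentration: float = 8.0
    gap_prob: float = 0.3
    contact_cutoff: float = 7.0
    n_variants: int = 400
    n_dms: int = 300
    n_labeled: int = 200
    latent_effect_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    offset_range: tuple[float, float] = (-2.0, 2.0)
    scale_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.2
    score_noise_sd: float = 0.3
    eve_missing_frac: float = 0.15
    vtmsa_missing_frac: float = 0.10
    label_quantile: float = 0.4

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_range[0] < 5:
            raise ValueError("proteins must be at least 5 residues")
        if any(d < 2 for d in self.msa_depths.values()):
            raise ValueError("MSA depths must be >= 2")
        if not 0 <= self.conservation_strength <= 1:
            raise ValueError("conservation_strength must lie in [0, 1]")

    @classmethod
    def noise_free(cls, seed: int = 0, **kw) -> "GeneratorConfig":
        """Conditions for exact-recovery checks: no assay noise, no missingness."""
        return cls(seed=seed, noise_sd=0.0, eve_missing_frac=0.0,
                   vtmsa_missing_frac=0.0, **kw)


@dataclass
class GroundTruth:
    """Generative parameters exposed for parameter-recovery assertions."""

    weights: dict[str, float]
    feature_means: dict[str, float]
    feature_stds: dict[str, float]
    offsets: dict[str, float]
    scales: dict[str, float]
    label_threshold: float
    latent: dict[VariantKey, float]


@dataclass
class FamilyBundle:
    """Everything the generator produced for one synthetic family."""

    config: GeneratorConfig
    genes: list[str]
    queries: dict[str, str]
    msas: dict[str, dict[str, AnchoredMSA]]          # gene -> source -> projected MSA
    raw_vert_msas: dict[str, list[str]]              # gene -> raw isoform-trimmed rows
    deep_msas: dict[str, AnchoredMSA]
    structures: dict[str, StructureInfo]
    score_maps: dict[str, dict[VariantKey, float]]   # column -> keyed scores (NaN = missing)
    dms: dict[str, DMSDataset]
    labels: LabeledVariantSet
    true_features: dict[str, FeatureTable]           # complete (no missingness)
    truth: GroundTruth
    descriptors: dict[str, pd.Series]

    def observed_features(self) -> dict[str, FeatureTable]:
        """Feature tables as the pipeline would compute them from delivered inputs
        (i.e. including the injected missingness)."""
        out = {}
        for g in self.genes:
            keys = [k for k in self.truth.latent if k.gene == g]
            out[g] = build_feature_table(
                keys, msas=self.msas[g], structure=self.structures[g],
                deep_msa=self.deep_msas[g], score_maps=self.score_maps,
                descriptors=self.descriptors)
        return out


def _per_position_conservation(rng, L: int, cfg: GeneratorConfig) -> np.ndarray:
    c, k = cfg.conservation_strength, cfg.conservation_concentration
    if c >= 1.0:
        return np.ones(L)
    if c <= 0.0:
        return np.zeros(L)
    return rng.beta(c * k, (1 - c) * k, size=L)


def _msa_rows(rng, query: str, conservation: np.ndarray, depth: int,
              gap_prob: float) -> list[str]:
    """Alignment rows (query first): copy per position w.p. conservation,
    else a gap (w.p. gap_prob) or a uniformly random residue."""
    L = len(query)
    rows = [query]
    aa = np.array(list(AMINO_ACIDS))
    for _ in range(depth - 1):
        keep = rng.random(L) < conservation
        gaps = rng.random(L) < gap_prob
        subs = aa[rng.integers(0, 20, size=L)]
        row = np.where(keep, list(query), np.where(gaps, "-", subs))
        rows.append("".join(row))
    return rows


def _chain_coordinates(rng, L: int) -> np.ndarray:
    """Compact random chain: 3.8 A steps with persistence and a pull to the
    centroid, giving contact-dense cores and looser tails."""
    coords = np.zeros((L, 3))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    for i in range(1, L):
        pull = -coords[i - 1] * 0.04
        step = 0.6 * direction + 0.8 * rng.standard_normal(3) + pull
        step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + 3.8 * step
        direction = step
    return coords


def _structure(rng, gene: str, L: int, cutoff: float) -> StructureInfo:
    coords = _chain_coordinates(rng, L)
    contacts: dict[int, set[int]] = {}
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(L):
        for j in range(i + 1, L):
            if d[i, j] <= cutoff:
                contacts.setdefault(i + 1, set()).add(j + 1)
    degree = np.array([len(contacts.get(p, ())) for p in range(1, L + 1)])
    plddt = np.clip(45 + 12 * degree + rng.normal(0, 3, size=L), 20, 99)
    return StructureInfo(gene=gene, plddt=plddt, contacts=contacts)


def generate_family(config: GeneratorConfig | None = None) -> FamilyBundle:
    """Generate a complete, internally consistent synthetic family.

    Identical configs (same seed) yield identical bundles; all randomness
    flows from one seeded generator, never global state.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1}" for i in range(cfg.n_genes)]
    descriptors = cio.load_bundled_descriptors("physchem")

    queries: dict[str, str] = {}
    msas: dict[str, dict[str, AnchoredMSA]] = {}
    raw_vert: dict[str, list[str]] = {}
    deep_msas: dict[str, AnchoredMSA] = {}
    structures: dict[str, StructureInfo] = {}
    universe: dict[str, list[VariantKey]] = {}
    dms_keys: dict[str, list[VariantKey]] = {}
    label_keys: list[VariantKey] = []

    full_rows: dict[str, dict[str, list[str]]] = {}
    for g in genes:
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        query = "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=L)])
        queries[g] = query
        conservation = _per_position_conservation(rng, L, cfg)
        per_source: dict[str, AnchoredMSA] = {}
        full_rows[g] = {}
        for source in ("vert100", "mamm30"):
            rows = _msa_rows(rng, query, conservation, cfg.msa_depths[source],
                             cfg.gap_prob)
            full_rows[g][source] = rows
            trim = 0
            if source == "vert100" and cfg.vtmsa_missing_frac > 0:
                trim = int(np.floor(cfg.vtmsa_missing_frac * L))
            missing = np.zeros(L, dtype=bool)
            missing[:trim] = True
            kept_rows = ([query] + ["-" * trim + r[trim:] for r in rows[1:]]
                         if trim else rows)
            per_source[source] = AnchoredMSA(
                gene=g, query=query, rows=kept_rows, source=source,
                column_missing=missing)
            if source == "vert100":
                # raw isoform alignment as delivered on disk: query missing
                # its first `trim` residues, columns for them absent
                raw_vert[g] = [r[trim:] for r in rows]
        msas[g] = per_source
        deep_msas[g] = AnchoredMSA(
            gene=g, query=query,
            rows=_msa_rows(rng, query, conservation, cfg.msa_depths["deep"],
                           cfg.gap_prob),
            source="deep")
        structures[g] = _structure(rng, g, L, cfg.contact_cutoff)

        all_pairs = [(p, m) for p in range(1, L + 1)
                     for m in AMINO_ACIDS if m != query[p - 1]]
        n_var = min(cfg.n_variants, len(all_pairs))
        chosen = rng.choice(len(all_pairs), size=n_var, replace=False)
        universe[g] = [
            VariantKey(g, all_pairs[i][0], query[all_pairs[i][0] - 1], all_pairs[i][1])
            for i in sorted(chosen)
        ]
        n_dms = min(cfg.n_dms, n_var)
        dms_idx = sorted(rng.choice(n_var, size=n_dms, replace=False))
        dms_keys[g] = [universe[g][i] for i in dms_idx]
        n_lab = min(cfg.n_labeled, n_var)
        lab_idx = sorted(rng.choice(n_var, size=n_lab, replace=False))
        label_keys += [universe[g][i] for i in lab_idx]

    # --- core features from complete inputs -------------------------------
    core_tables: dict[str, FeatureTable] = {}
    for g in genes:
        complete_msas = {
            s: AnchoredMSA(gene=g, query=queries[g], rows=full_rows[g][s], source=s)
            for s in ("vert100", "mamm30")
        }
        core_tables[g] = build_feature_table(
            universe[g], msas=complete_msas, structure=structures[g],
            deep_msa=deep_msas[g], score_maps={}, descriptors=descriptors)

    all_keys = [k for g in genes for k in universe[g]]
    core = pd.concat([core_tables[g].df for g in genes], ignore_index=True)

    def zscore(col: pd.Series) -> tuple[pd.Series, float, float]:
        m = float(np.nanmean(col))
        s = float(np.nanstd(col))
        s = s if s > 0 else 1.0
        return (col - m) / s, m, s

    weights = dict(cfg.latent_effect_weights)
    feature_means: dict[str, float] = {}
    feature_stds: dict[str, float] = {}
    core_weighted = np.zeros(len(core))
    for name, w in weights.items():
        if name in EXTERNAL_SCORES or name not in core.columns:
            continue
        z, m, s = zscore(core[name])
        feature_means[name], feature_stds[name] = m, s
        core_weighted += w * z.to_numpy()
    phi0, phi_m, phi_s = zscore(pd.Series(core_weighted))
    phi0 = phi0.to_numpy()

    # --- external predictor columns: noisy monotone functions of phi0 -----
    n_all = len(all_keys)
    raw_scores = {
        "esm_llr": 1.2 * phi0 + cfg.score_noise_sd * rng.standard_normal(n_all),
        "eve_logp": phi0 + 0.4 * np.tanh(phi0)
        + cfg.score_noise_sd * rng.standard_normal(n_all),
        "mpnn_llr": 0.8 * phi0 + cfg.score_noise_sd * rng.standard_normal(n_all),
    }

    # --- full latent over all weighted features ---------------------------
    full = core.copy()
    for name, vals in raw_scores.items():
        full[name] = vals
    latent_arr = np.zeros(n_all)
    for name, w in weights.items():
        if name not in full.columns:
            raise ValueError(f"weighted feature {name!r} was not generated")
        z, m, s = zscore(full[name])
        feature_means[name], feature_stds[name] = m, s
        latent_arr += w * z.to_numpy()
    latent = dict(zip(all_keys, latent_arr.tolist()))

    # --- deliverables: score maps with missingness, DMS, labels -----------
    score_maps: dict[str, dict[VariantKey, float]] = {
        name: dict(zip(all_keys, vals.tolist())) for name, vals in raw_scores.items()
    }
    if cfg.eve_missing_frac > 0:
        n_missing = int(np.floor(cfg.eve_missing_frac * n_all))
        miss_idx = rng.choice(n_all, size=n_missing, replace=False)
        for i in miss_idx:
            score_maps["eve_logp"][all_keys[i]] = float("nan")

    offsets, scales = {}, {}
    dms: dict[str, DMSDataset] = {}
    sd_latent = float(np.std(latent_arr)) or 1.0
    for g in genes:
        offsets[g] = float(rng.uniform(*cfg.offset_range))
        scales[g] = float(rng.uniform(*cfg.scale_range))
        keys = dms_keys[g]
        lat = np.array([latent[k] for k in keys])
        noise = cfg.noise_sd * sd_latent * rng.standard_normal(len(keys))
        dms[g] = DMSDataset(gene=g, keys=keys,
                            scores=offsets[g] + scales[g] * (lat + noise))

    threshold = float(np.quantile(latent_arr, cfg.label_quantile))
    labels = LabeledVariantSet(
        keys=label_keys,
        labels=[1 if latent[k] < threshold else 0 for k in label_keys])

    # --- complete feature tables (for oracle/recovery use) ----------------
    true_features: dict[str, FeatureTable] = {}
    offset_rows = 0
    for g in genes:
        n_g = len(universe[g])
        t = core_tables[g]
        for name, vals in raw_scores.items():
            t.df[name] = vals[offset_rows:offset_rows + n_g]
            t.column_meta[name] = cio.ColumnMeta(
                "inverse_folding" if name == "mpnn_llr" else "homology")
        true_features[g] = t
        offset_rows += n_g

    truth = GroundTruth(weights=weights, feature_means=feature_means,
                        feature_stds=feature_stds, offsets=offsets,
                        scales=scales, label_threshold=threshold,
                        latent=latent)
    return FamilyBundle(config=cfg, genes=genes, queries=queries, msas=msas,
                        raw_vert_msas=raw_vert, deep_msas=deep_msas,
                        structures=structures, score_maps=score_maps,
                        dms=dms, labels=labels, true_features=true_features,
                        truth=truth, descriptors=descriptors)


def ground_truth(bundle: FamilyBundle) -> GroundTruth:
    """Generative parameters of a bundle, for parameter-recovery assertions."""
    return bundle.truth


def write_bundle(bundle: FamilyBundle, out_dir: str | Path) -> None:
    """Write the fixture tree in the standard on-disk formats.

    Layout: one directory per gene with ``canonical.fasta``, per-source
    aligned FASTAs (the vertebrate one on its raw isoform query),
    ``contacts.tsv`` + ``plddt.tsv``, per-predictor score TSVs and
    ``dms.tsv``; family-level ``labels.tsv`` and ``descriptors.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in bundle.genes:
        gd = out / g
        gd.mkdir(exist_ok=True)
        (gd / "canonical.fasta").write_text(f">{g}\n{bundle.queries[g]}\n")
        with open(gd / "vert100.fasta", "w") as fh:
            for i, row in enumerate(bundle.raw_vert_msas[g]):
                fh.write(f">{g}_iso\n{row}\n" if i == 0 else f">{g}_v{i}\n{row}\n")
        cio.write_anchored_msa(bundle.msas[g]["mamm30"], gd / "mamm30.fasta")
        cio.write_anchored_msa(bundle.deep_msas[g], gd / "deep.fasta")
        st = bundle.structures[g]
        with open(gd / "contacts.tsv", "w") as fh:
            for i in sorted(st.contacts):
                for j in sorted(st.contacts[i]):
                    if i < j:
                        fh.write(f"{i}\t{j}\n")
        with open(gd / "plddt.tsv", "w") as fh:
            for p in range(1, st.length + 1):
                fh.write(f"{p}\t{float(st.plddt[p - 1])!r}\n")
        for name, scores in bundle.score_maps.items():
            gene_scores = {k: v for k, v in scores.items() if k.gene == g}
            cio.write_score_table(gene_scores, gd / f"{name}.tsv", column="value")
        cio.write_dms_table(bundle.dms[g], gd / "dms.tsv")
    cio.write_label_table(bundle.labels, out / "labels.tsv")
    pd.DataFrame(
        {aa: bundle.descriptors[aa] for aa in sorted(bundle.descriptors)}
    ).T.rename_axis("aa").reset_index().to_csv(out / "descriptors.csv", index=False)
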