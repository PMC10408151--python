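"""Domain types and file I/O shared by all pipeline stages.

Conventions
-----------
* Residue positions are 1-based indices on the canonical protein sequence.
* Alignments are query-anchored: columns map one-to-one to query residues
  (A2M style, insertions relative to the query removed upstream).
* Missing numeric values are carried as ``NaN`` in :class:`FeatureTable`.
* Models and configs serialize to JSON with explicit feature names; no
  binary pickles.

File formats: aligned FASTA (query first) for MSAs; PDB/mmCIF with
per-residue confidence in the B-factor field, or TSV contact lists, for
structures; TSV tables with header ``gene position wt mut <value>`` for
scores, assay data and labels; CSV for amino-acid descriptor tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: Feature-column categories used for selection and reporting.
CATEGORIES = (
    "homology",
    "vert100",
    "mamm30",
    "inverse_folding",
    "conditioned",
    "structure_site",
    "descriptor",
)


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """A missense variant: gene, 1-based position, wild-type and mutant residue."""

    gene: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa, name in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{name} must be a standard amino acid, got {aa!r}")

    def check_against(self, query: str) -> None:
        """Validate that ``wt_aa`` matches ``query`` at ``position``."""
        if self.position > len(query):
            raise ValueError(
                f"{self}: position {self.position} beyond sequence length {len(query)}"
            )
        if query[self.position - 1] != self.wt_aa:
            raise ValueError(
                f"{self}: wild-type {self.wt_aa} does not match sequence "
                f"residue {query[self.position - 1]} at position {self.position}"
            )


@dataclass
class AnchoredMSA:
    """Query-anchored alignment; columns correspond 1:1 to query residues.

    ``rows[0]`` is the (gap-free) query itself.  ``column_missing`` flags
    query positions with no alignment information (e.g. dropped during
    isoform reconciliation); frequency features at those positions are
    reported missing and flow to imputation.
    """

    gene: str
    query: str
    rows: list[str]
    source: str
    column_missing: np.ndarray | None = None

    def __post_init__(self):
        if len(self.query) < 1:
            raise ValueError("query must be non-empty")
        if not self.rows or self.rows[0] != self.query:
            raise ValueError("row 0 must equal the query")
        if GAP in self.query:
            raise ValueError("query must not contain gaps")
        L = len(self.query)
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise FormatError(
                    f"{self.gene}: row {i} has length {len(row)}, expected {L}"
                )
        if self.column_missing is None:
            self.column_missing = np.zeros(L, dtype=bool)
        else:
            self.column_missing = np.asarray(self.column_missing, dtype=bool)
            if self.column_missing.shape != (L,):
                raise ValueError("column_missing length must equal query length")

    @property
    def length(self) -> int:
        return len(self.query)

    @property
    def depth(self) -> int:
        return len(self.rows)

    def column(self, position: int) -> list[str]:
        """Letters of all rows at a 1-based query position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} out of range 1..{self.length}")
        return [row[position - 1] for row in self.rows]


@dataclass
class StructureInfo:
    """Per-residue structure summary: pLDDT, sidechain contacts, fragment ids.

    ``plddt`` is indexed 0-based internally (position p -> plddt[p-1]); NaN
    marks residues absent from the model.  ``contacts`` maps a 1-based
    position to the set of 1-based positions it contacts (symmetric, no
    self-contacts).
    """

    gene: str
    plddt: np.ndarray
    contacts: dict[int, set[int]] = field(default_factory=dict)
    fragment_id: int = 0

    def __post_init__(self):
        self.plddt = np.asarray(self.plddt, dtype=float)
        clean: dict[int, set[int]] = {}
        for i, js in self.contacts.items():
            for j in js:
                if i == j:
                    raise ValueError(f"self-contact at residue {i}")
                clean.setdefault(i, set()).add(j)
                clean.setdefault(j, set()).add(i)
        self.contacts = clean
        finite = self.plddt[np.isfinite(self.plddt)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("pLDDT values must lie in [0, 100]")

    @property
    def length(self) -> int:
        return len(self.plddt)

    def covers(self, position: int) -> bool:
        return 1 <= position <= self.length and np.isfinite(self.plddt[position - 1])

    def contact_set(self, position: int) -> set[int]:
        return self.contacts.get(position, set())


@dataclass
class ColumnMeta:
    """Per-column metadata: selection category and frequency flag.

    Frequency-flagged columns (log-offset alignment frequencies) are exempt
    from the global rescaling applied before model fitting.
    """

    category: str
    is_frequency: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


class FeatureTable:
    """Variants x named numeric feature columns with explicit missingness.

    Thin wrapper over a pandas DataFrame indexed by variant keys, plus
    per-column :class:`ColumnMeta`.
    """

    def __init__(self, keys: list[VariantKey], columns: Mapping[str, np.ndarray],
                 column_meta: Mapping[str, ColumnMeta]):
        n = len(keys)
        if len(set(keys)) != n:
            raise ValueError("duplicate variant keys")
        data = {}
        for name, col in columns.items():
            arr = np.asarray(col, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} has length {len(arr)}, expected {n}")
            data[name] = arr
        if set(columns) != set(column_meta):
            raise ValueError("column_meta must cover exactly the feature columns")
        self.keys = list(keys)
        self.df = pd.DataFrame(data, index=pd.RangeIndex(n))
        self.column_meta = dict(column_meta)

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in self.keys:
            seen.setdefault(k.gene, None)
        return list(seen)

    def subset_gene(self, gene: str) -> "FeatureTable":
        idx = [i for i, k in enumerate(self.keys) if k.gene == gene]
        return self.subset(idx)

    def subset(self, idx: Iterable[int]) -> "FeatureTable":
        idx = list(idx)
        out = FeatureTable.__new__(FeatureTable)
        out.keys = [self.keys[i] for i in idx]
        out.df = self.df.iloc[idx].reset_index(drop=True)
        out.column_meta = dict(self.column_meta)
        return out

    def frequency_columns(self) -> list[str]:
        return [c for c, m in self.column_meta.items() if m.is_frequency]

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with gene/position/wt/mut key columns prepended."""
        keydf = pd.DataFrame(
            {
                "gene": [k.gene for k in self.keys],
                "position": [k.position for k in self.keys],
                "wt": [k.wt_aa for k in self.keys],
                "mut": [k.mut_aa for k in self.keys],
            }
        )
        return pd.concat([keydf, self.df.reset_index(drop=True)], axis=1)


@dataclass
class DMSDataset:
    """Deep-mutational-scanning assay scores for one protein."""

    gene: str
    keys: list[VariantKey]
    scores: np.ndarray

    MIN_RECORDS = 10

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.keys) != len(self.scores):
            raise ValueError("keys and scores length mismatch")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError(f"{self.gene}: duplicate variant keys in DMS data")
        for k in self.keys:
            if k.gene != self.gene:
                raise ValueError(f"foreign gene {k.gene} in DMS dataset {self.gene}")

    def __len__(self) -> int:
        return len(self.keys)

    def require_trainable(self) -> None:
        if len(self) < self.MIN_RECORDS:
            raise ValueError(
                f"{self.gene}: {len(self)} records < {self.MIN_RECORDS} required for training"
            )


@dataclass
class LabeledVariantSet:
    """Variants with binary clinical-style labels (0 = benign, 1 = pathogenic)."""

    keys: list[VariantKey]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.keys) != len(self.labels):
            raise ValueError("keys and labels length mismatch")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate variant keys in label set")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.keys)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_anchored_msa(path: str | Path, source: str, gene: str | None = None) -> AnchoredMSA:
    """Read an aligned FASTA whose first record is the gap-free query.

    Lowercase letters are uppercased.  Ragged rows or a gapped query raise
    :class:`FormatError` naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    rows = [str(r.seq).upper() for r in records]
    L = len(rows[0])
    for rec, row in zip(records, rows):
        if len(row) != L:
            raise FormatError(
                f"{path}: record {rec.id!r} has length {len(row)}, expected {L}"
            )
    if GAP in rows[0]:
        raise FormatError(f"{path}: query record {records[0].id!r} contains gaps")
    return AnchoredMSA(
        gene=gene if gene is not None else records[0].id,
        query=rows[0],
        rows=rows,
        source=source,
    )


def write_anchored_msa(msa: AnchoredMSA, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=msa.gene if i == 0 else f"{msa.gene}_row{i}", description="")
        for i, row in enumerate(msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def _structure_from_atoms(gene: str, path: Path, contact_cutoff: float | None) -> StructureInfo:
    import gemmi

    from .structure import ContactSpec, extract_contacts

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    plddt_by_pos: dict[int, float] = {}
    coords_by_pos: dict[int, list[tuple[str, np.ndarray]]] = {}
    for chain in model:
        for res in chain:
            pos = res.seqid.num
            bvals = [a.b_iso for a in res]
            if not bvals:
                continue
            plddt_by_pos[pos] = float(np.mean(bvals))
            coords_by_pos[pos] = [
                (a.name, np.array([a.pos.x, a.pos.y, a.pos.z])) for a in res
            ]
        break  # single-chain models; fragments come as separate files
    if not plddt_by_pos:
        raise FormatError(f"{path}: no residues with B-factor confidence values")
    if all(v == 0.0 for v in plddt_by_pos.values()):
        raise FormatError(f"{path}: B-factor column carries no confidence values")
    L = max(plddt_by_pos)
    plddt = np.full(L, np.nan)
    for pos, v in plddt_by_pos.items():
        plddt[pos - 1] = min(max(v, 0.0), 100.0)
    spec = ContactSpec() if contact_cutoff is None else ContactSpec(cutoff_A=contact_cutoff)
    contacts = extract_contacts(coords_by_pos, spec)
    return StructureInfo(gene=gene, plddt=plddt, contacts=contacts)


def read_structure(path: str | Path, gene: str | None = None,
                   plddt_path: str | Path | None = None,
                   contact_cutoff: float | None = None) -> StructureInfo:
    """Read a structure model (PDB/mmCIF) or a precomputed contact TSV.

    PDB/mmCIF: per-residue confidence is taken from the B-factor field
    (clamped to [0, 100]); contacts are derived from sidechain heavy-atom
    distances.  TSV: two tab-separated 1-based positions per line
    (``pos_i<TAB>pos_j``); per-residue confidence comes from a companion
    TSV (``pos<TAB>plddt``) given as ``plddt_path``.  Residue-index gaps
    are recorded as missing pLDDT.
    """
    path = Path(path)
    name = gene if gene is not None else path.stem
    if path.suffix.lower() in {".pdb", ".cif", ".mmcif", ".ent"}:
        return _structure_from_atoms(name, path, contact_cutoff)
    # TSV contact list
    pairs: list[tuple[int, int]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected 'pos_i<TAB>pos_j'")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: non-integer position") from e
        if i == j:
            raise FormatError(f"{path}:{ln}: self-contact {i}")
        pairs.append((i, j))
    if plddt_path is None:
        raise FormatError(
            f"{path}: contact TSV requires a companion pLDDT table (plddt_path)"
        )
    plddt_map: dict[int, float] = {}
    for ln, line in enumerate(Path(plddt_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        pos_s, val_s = line.split("\t")[:2]
        plddt_map[int(pos_s)] = min(max(float(val_s), 0.0), 100.0)
    L = max(
        max(plddt_map, default=0),
        max((max(i, j) for i, j in pairs), default=0),
    )
    plddt = np.full(L, np.nan)
    for pos, v in plddt_map.items():
        plddt[pos - 1] = v
    contacts: dict[int, set[int]] = {}
    for i, j in pairs:
        contacts.setdefault(i, set()).add(j)
    return StructureInfo(gene=name, plddt=plddt, contacts=contacts)


def _read_keyed_table(path: str | Path, value_field: str, cast) -> dict[VariantKey, float]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["gene", "position", "wt", "mut", value_field]
    if header[:5] != expected:
        raise FormatError(f"{path}: header {header[:5]} != {expected}")
    out: dict[VariantKey, float] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise FormatError(f"{path}:{ln}: expected 5 tab-separated fields")
        try:
            key = VariantKey(parts[0], int(parts[1]), parts[2], parts[3])
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from e
        if key in out:
            raise FormatError(f"{path}:{ln}: duplicate key {key}")
        raw = parts[4].strip()
        if raw == "" or raw.upper() in {"NA", "NAN"}:
            out[key] = float("nan")
            continue
        try:
            out[key] = cast(raw)
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: non-numeric value {raw!r}") from e
    return out


def read_score_table(path: str | Path, column: str = "value") -> dict[VariantKey, float]:
    """Read a TSV with header ``gene position wt mut <column>`` into a keyed map."""
    return _read_keyed_table(path, column, float)


def write_score_table(scores: Mapping[VariantKey, float], path: str | Path,
                      column: str = "value") -> None:
    with open(path, "w") as fh:
        fh.write(f"gene\tposition\twt\tmut\t{column}\n")
        for k, v in scores.items():
            val = "NA" if (isinstance(v, float) and np.isnan(v)) else repr(float(v))
            fh.write(f"{k.gene}\t{k.position}\t{k.wt_aa}\t{k.mut_aa}\t{val}\n")


def read_dms_table(path: str | Path, gene: str | None = None) -> DMSDataset:
    scores = _read_keyed_table(path, "score", float)
    keys = list(scores)
    if gene is None:
        genes = {k.gene for k in keys}
        if len(genes) != 1:
            raise FormatError(f"{path}: expected a single gene, found {sorted(genes)}")
        gene = genes.pop()
    return DMSDataset(gene=gene, keys=keys, scores=[scores[k] for k in keys])


def write_dms_table(dms: DMSDataset, path: str | Path) -> None:
    write_score_table(dict(zip(dms.keys, dms.scores)), path, column="score")


def read_label_table(path: str | Path) -> LabeledVariantSet:
    def cast_label(raw: str) -> int:
        v = int(raw)
        if v not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {v}")
        return v

    labels = _read_keyed_table(path, "label", cast_label)
    keys = list(labels)
    return LabeledVariantSet(keys=keys, labels=[int(labels[k]) for k in keys])


def write_label_table(lvs: LabeledVariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tposition\twt\tmut\tlabel\n")
        for k, y in zip(lvs.keys, lvs.labels):
            fh.write(f"{k.gene}\t{k.position}\t{k.wt_aa}\t{k.mut_aa}\t{int(y)}\n")


def read_descriptor_table(path: str | Path) -> dict[str, pd.Series]:
    """Read a 20-row CSV of amino-acid descriptor scales.

    First column is the amino-acid letter; remaining columns are named
    scales.  Every standard amino acid must appear exactly once.
    """
    df = pd.read_csv(path)
    letters = df.iloc[:, 0].astype(str).str.upper()
    dupes = letters[letters.duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate amino-acid rows {sorted(set(dupes))}")
    extra = sorted(set(letters) - set(AMINO_ACIDS))
    if extra:
        raise FormatError(f"{path}: unknown amino-acid letters {extra}")
    missing = sorted(set(AMINO_ACIDS) - set(letters))
    if missing:
        raise FormatError(f"{path}: missing amino acids {missing}")
    values = df.iloc[:, 1:].astype(float)
    values.index = letters
    return {aa: values.loc[aa] for aa in AMINO_ACIDS}


def load_bundled_descriptors(name: str = "zscales") -> dict[str, pd.Series]:
    """Load one of the descriptor tables shipped with the package.

    ``zscales``: the five-component Z-scales; ``physchem``: hydropathy,
    residue volume and isoelectric point.
    """
    here = Path(__file__).parent / "data" / f"{name}.csv"
    if not here.exists():
        raise ValueError(f"no bundled descriptor table named {name!r}")
    return read_descriptor_table(here)


def feature_table_from_frame(df: pd.DataFrame,
                             column_meta: Mapping[str, ColumnMeta]) -> FeatureTable:
    """Build a FeatureTable from a frame with gene/position/wt/mut key columns."""
    keys = [
        VariantKey(str(g), int(p), str(w), str(m))
        for g, p, w, m in zip(df["gene"], df["position"], df["wt"], df["mut"])
    ]
    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c in column_meta}
    return FeatureTable(keys, cols, {c: column_meta[c] for c in cols})


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    meta = {c: dataclasses.asdict(m) for c, m in table.column_meta.items()}
    meta_path.write_text(json.dumps(meta, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True,
                     float_precision="round_trip")
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    meta_raw = json.loads(meta_path.read_text())
    meta = {c: ColumnMeta(**m) for c, m in meta_raw.items()}
    return feature_table_from_frame(df, meta)
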