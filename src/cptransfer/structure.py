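"""Structure-derived features: contacts, pLDDT, and conditioned residue scores.

The conditioned wild-type/mutant scores restrict a deep protein-family MSA
to sequences whose residues at up to two structurally contacting positions
match the human sequence, then measure wild-type/mutant frequencies in the
filtered alignment.  This captures sequence variation conditioned on the
local structural environment matching the human protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conservation import log_offset
from .io import AnchoredMSA, StructureInfo, VariantKey

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ContactSpec:
    """How residue-residue contacts are obtained.

    ``precomputed`` consumes an externally supplied sidechain-contact list;
    ``distance_fallback`` derives contacts from coordinates: residues i, j
    (i != j) are in contact iff some sidechain heavy atom of i lies within
    ``cutoff_A`` of some sidechain heavy atom of j.  Glycine has no
    sidechain heavy atoms and therefore never forms contacts in fallback
    mode.
    """

    mode: str = "distance_fallback"
    cutoff_A: float = 4.5

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be positive")
        if self.mode not in ("precomputed", "distance_fallback"):
            raise ValueError(f"unknown contact mode {self.mode!r}")


@dataclass
class ConditioningSpec:
    """Limits for structure-conditioned scoring.

    At most ``max_residues`` contacts are used for conditioning, and only
    residues with pLDDT above ``plddt_threshold`` qualify (a position at or
    below the threshold gets no conditioning at all).  If filtering leaves
    fewer than ``min_filtered_rows`` alignment rows, the scores are
    declared missing and flow to cross-gene imputation.
    """

    max_residues: int = 2
    plddt_threshold: float = 70.0
    min_filtered_rows: int = 1

    def __post_init__(self):
        if self.max_residues < 0:
            raise ValueError("max_residues must be >= 0")
        if not 0 <= self.plddt_threshold <= 100:
            raise ValueError("plddt_threshold must lie in [0, 100]")


def sidechain_heavy_atoms(atoms: list[tuple[str, np.ndarray]]) -> list[np.ndarray]:
    """Coordinates of non-hydrogen, non-backbone atoms of one residue."""
    out = []
    for name, xyz in atoms:
        if name.upper() in BACKBONE_ATOMS:
            continue
        if name.upper().startswith("H") or name.upper().startswith("D"):
            continue
        out.append(np.asarray(xyz, dtype=float))
    return out


def extract_contacts(coords_by_pos: dict[int, list[tuple[str, np.ndarray]]],
                     spec: ContactSpec | None = None) -> dict[int, set[int]]:
    """Sidechain-sidechain contact adjacency from atomic coordinates.

    ``coords_by_pos`` maps 1-based residue positions to (atom name, xyz)
    lists.  The result is symmetric with no self-contacts; residues with no
    sidechain heavy atoms (glycine, missing sidechains) have none.
    """
    spec = spec or ContactSpec()
    side = {
        pos: np.array(sc)
        for pos, atoms in coords_by_pos.items()
        if (sc := sidechain_heavy_atoms(atoms))
    }
    positions = sorted(side)
    contacts: dict[int, set[int]] = {}
    for ai, i in enumerate(positions):
        for j in positions[ai + 1:]:
            d = np.linalg.norm(side[i][:, None, :] - side[j][None, :, :], axis=-1)
            if d.min() <= spec.cutoff_A:
                contacts.setdefault(i, set()).add(j)
                contacts.setdefault(j, set()).add(i)
    return contacts


def resolve_fragments(fragments: list[StructureInfo], position: int) -> StructureInfo | None:
    """Pick, for one position, the structure fragment with maximal pLDDT there.

    Proteins too long for a single predicted model come as overlapping
    fragments; features at a position use the covering fragment whose pLDDT
    at that position is highest, ties broken by lowest fragment id.
    Returns None when no fragment covers the position.
    """
    covering = [f for f in fragments if f.covers(position)]
    if not covering:
        return None
    return max(covering, key=lambda f: (f.plddt[position - 1], -f.fragment_id))


def pick_conditioning_residues(position: int, structure: StructureInfo,
                               deep_msa: AnchoredMSA,
                               spec: ConditioningSpec | None = None) -> list[int]:
    """Choose up to two contact residues to condition on.

    Candidates are the position's contacts with pLDDT above the threshold;
    they are ranked by the frequency of the human (query) amino acid at the
    contact position in the deep MSA, descending, ties broken by lower
    residue index.  A position whose own pLDDT is at or below the threshold
    gets no conditioning.
    """
    spec = spec or ConditioningSpec()
    if not structure.covers(position):
        return []
    if structure.plddt[position - 1] <= spec.plddt_threshold:
        return []
    candidates = []
    for c in sorted(structure.contact_set(position)):
        if not structure.covers(c) or structure.plddt[c - 1] <= spec.plddt_threshold:
            continue
        if c > deep_msa.length:
            continue
        human_aa = deep_msa.query[c - 1]
        col = deep_msa.column(c)
        freq = sum(1 for ch in col if ch == human_aa) / len(col)
        candidates.append((-freq, c))
    candidates.sort()
    return [c for _, c in candidates[: spec.max_residues]]


def conditioned_scores(deep_msa: AnchoredMSA, key: VariantKey,
                       conditioning: list[int],
                       min_filtered_rows: int = 1,
                       include_query: bool = True) -> tuple[float, float]:
    """Wild-type and mutant frequency in the environment-filtered deep MSA.

    Rows are retained iff they carry the human amino acid at every
    conditioning residue; wild-type and mutant frequencies of the variant
    are computed over retained rows (same denominator convention as the
    conservation features) and log-offset transformed.  With an empty
    conditioning list this equals the unconditioned column frequencies.
    Returns (NaN, NaN) when fewer than ``min_filtered_rows`` rows survive.
    """
    if not 1 <= key.position <= deep_msa.length:
        raise ValueError(f"position {key.position} out of range 1..{deep_msa.length}")
    rows = deep_msa.rows if include_query else deep_msa.rows[1:]
    for c in conditioning:
        if not 1 <= c <= deep_msa.length:
            raise ValueError(f"conditioning residue {c} out of range")
    retained = [
        r for r in rows
        if all(r[c - 1] == deep_msa.query[c - 1] for c in conditioning)
    ]
    if len(retained) < max(min_filtered_rows, 1):
        return (math.nan, math.nan)
    n = len(retained)
    wt = sum(1 for r in retained if r[key.position - 1] == key.wt_aa)
    mut = sum(1 for r in retained if r[key.position - 1] == key.mut_aa)
    return (log_offset(wt / n), log_offset(mut / n))


def site_features(structure: StructureInfo, position: int) -> tuple[float, float]:
    """(sidechain-contact count, pLDDT) at a position; NaNs when uncovered."""
    if not structure.covers(position):
        return (math.nan, math.nan)
    return (float(len(structure.contact_set(position))),
            float(structure.plddt[position - 1]))
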