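"""Quantification of germline CDR - MHC helix contacts in solved complexes.

Given a coordinate file and an annotation naming the TCR and MHC chains and
the residue ranges of the CDR loops and helices, every CDR-residue x
helix-residue heavy-atom pair is tested against two distance rules: a van der
Waals contact at <= 4.5 A, and an electrostatic contact at <= 6.0 A restricted
to chemically plausible donor/acceptor element pairs — N-O (either direction)
always qualifies, O-O only when Ser/Thr/Tyr is involved (hydroxyl oxygen),
and N-N only when His is involved. Contacts are classed by which side of each
residue they use (sidechain or backbone: SC-SC, SC-Back, Back-SC, Back-Back)
and deduplicated to one record per (residue pair, class, bond type), keeping
the closest qualifying atom pair.

Residue-pair contacts are tabulated into 20x20 count matrices, aggregated per
helix alignment column, and compared between groups of complexes with a
label-shuffling permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .alphabet import AMINO_ACIDS, THREE_TO_ONE

__all__ = [
    "ComplexAnnotation",
    "ContactRecord",
    "ContactCountMatrix",
    "VDW_CUTOFF",
    "ELECTROSTATIC_CUTOFF",
    "load_structure",
    "classify_atoms",
    "find_contacts",
    "contact_count_matrix",
    "per_residue_contact_counts",
    "permutation_test",
    "group_comparison",
    "assign_potential_bins",
]

VDW_CUTOFF = 4.5
ELECTROSTATIC_CUTOFF = 6.0

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Standard heavy sidechain atom nomenclature (union over the 20 residues).
_KNOWN_SIDECHAIN = {
    "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2", "CE", "CE1", "CE2", "CE3",
    "CZ", "CZ2", "CZ3", "CH2", "ND1", "ND2", "NE", "NE1", "NE2", "NZ", "NH1",
    "NH2", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "SD", "SG",
}

_HYDROXYL_RESIDUES = {"SER", "THR", "TYR"}

CONTACT_CLASSES = ("SC-SC", "SC-Back", "Back-SC", "Back-Back")


@dataclass
class ComplexAnnotation:
    """Which chains/residue ranges hold the CDR loops and MHC helices.

    ``tcr_regions`` maps chain id -> {loop label -> (first, last) residue
    numbers, inclusive}; ``mhc_regions`` likewise for helix labels.
    ``genes`` optionally records the TRAV/TRBV assignment per TCR chain for
    grouping complexes downstream.
    """

    tcr_regions: dict[str, dict[str, tuple[int, int]]]
    mhc_regions: dict[str, dict[str, tuple[int, int]]]
    genes: dict[str, str] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for regions in (*self.tcr_regions.values(), *self.mhc_regions.values()):
            spans = sorted(regions.values())
            for (a1, b1), (a2, _b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping residue ranges in {regions}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComplexAnnotation":
        def conv(side):
            return {
                chain: {lbl: tuple(rng) for lbl, rng in regions.items()}
                for chain, regions in d[side].items()
            }

        return cls(
            tcr_regions=conv("tcr_regions"),
            mhc_regions=conv("mhc_regions"),
            genes=dict(d.get("genes", {})),
            name=d.get("name", ""),
        )


@dataclass
class ContactRecord:
    """One deduplicated residue-pair contact."""

    tcr_chain: str
    tcr_res_id: int
    tcr_aa: str  # one-letter
    tcr_region: str
    mhc_chain: str
    mhc_res_id: int
    mhc_aa: str
    mhc_region: str
    tcr_atom: str
    mhc_atom: str
    distance: float
    bond_type: str  # vdw | electrostatic
    contact_class: str  # SC-SC | SC-Back | Back-SC | Back-Back


def load_structure(source) -> struc.AtomArray:
    """Read a PDB file to an AtomArray: first model, highest-occupancy altloc,
    hydrogens dropped."""
    pdb = PDBFile.read(source)
    arr = pdb.get_structure(model=1, altloc="occupancy")
    return arr[(arr.element != "H") & (arr.element != "D")]


def classify_atoms(res_name: str, atom_name: str) -> str:
    """'backbone' for N/CA/C/O/OXT, 'sidechain' for everything else.

    Glycine has no sidechain heavy atoms, so it can never appear on the
    sidechain side of a contact. Unrecognized atom names are treated as
    sidechain with a warning.
    """
    if atom_name in BACKBONE_ATOMS:
        return "backbone"
    if atom_name not in _KNOWN_SIDECHAIN:
        warnings.warn(
            f"unknown atom name {atom_name!r} in {res_name}; treating as sidechain",
            stacklevel=2,
        )
    return "sidechain"


def _electrostatic_ok(elem_a: str, elem_b: str, res_a: str, res_b: str) -> bool:
    pair = {elem_a, elem_b}
    if pair == {"N", "O"}:
        return True
    if pair == {"O"}:
        return res_a in _HYDROXYL_RESIDUES or res_b in _HYDROXYL_RESIDUES
    if pair == {"N"}:
        return res_a == "HIS" or res_b == "HIS"
    return False


def _residues_in_range(arr: struc.AtomArray, chain: str, span: tuple[int, int]):
    mask = (arr.chain_id == chain) & (arr.res_id >= span[0]) & (arr.res_id <= span[1])
    sub = arr[mask]
    for res_id in np.unique(sub.res_id):
        res = sub[sub.res_id == res_id]
        yield int(res_id), str(res.res_name[0]), res


def find_contacts(
    structure: struc.AtomArray,
    annotation: ComplexAnnotation,
    vdw_cutoff: float = VDW_CUTOFF,
    electrostatic_cutoff: float = ELECTROSTATIC_CUTOFF,
) -> list[ContactRecord]:
    """All qualifying CDR-helix residue contacts in one complex.

    Both rules are evaluated on all heavy-atom pairs of each CDR residue x
    helix residue; per (residue pair, contact class, bond type) only the
    closest qualifying atom pair is recorded.
    """
    chains = set(np.unique(structure.chain_id))
    for chain in (*annotation.tcr_regions, *annotation.mhc_regions):
        if chain not in chains:
            raise ValueError(f"annotated chain {chain!r} not present in structure")

    tcr_side = [
        (chain, region, res_id, res_name, atoms)
        for chain, regions in annotation.tcr_regions.items()
        for region, span in regions.items()
        for res_id, res_name, atoms in _residues_in_range(structure, chain, span)
    ]
    mhc_side = [
        (chain, region, res_id, res_name, atoms)
        for chain, regions in annotation.mhc_regions.items()
        for region, span in regions.items()
        for res_id, res_name, atoms in _residues_in_range(structure, chain, span)
    ]
    if not tcr_side or not mhc_side:
        raise ValueError("annotation selected no residues on one side")

    records: list[ContactRecord] = []
    for t_chain, t_region, t_res, t_name, t_atoms in tcr_side:
        for m_chain, m_region, m_res, m_name, m_atoms in mhc_side:
            dists = cdist(t_atoms.coord, m_atoms.coord)
            best: dict[tuple[str, str], tuple[float, str, str]] = {}
            for i in range(len(t_atoms)):
                t_side = classify_atoms(t_name, t_atoms.atom_name[i])
                for j in range(len(m_atoms)):
                    d = dists[i, j]
                    if d > electrostatic_cutoff:
                        continue
                    m_side = classify_atoms(m_name, m_atoms.atom_name[j])
                    cclass = (
                        ("SC-" if t_side == "sidechain" else "Back-")
                        + ("SC" if m_side == "sidechain" else "Back")
                    )
                    bonds = []
                    if d <= vdw_cutoff:
                        bonds.append("vdw")
                    if _electrostatic_ok(
                        t_atoms.element[i], m_atoms.element[j], t_name, m_name
                    ):
                        bonds.append("electrostatic")
                    for bond in bonds:
                        key = (cclass, bond)
                        if key not in best or d < best[key][0]:
                            best[key] = (d, t_atoms.atom_name[i], m_atoms.atom_name[j])
            for (cclass, bond), (d, t_atom, m_atom) in sorted(best.items()):
                records.append(
                    ContactRecord(
                        tcr_chain=t_chain,
                        tcr_res_id=t_res,
                        tcr_aa=THREE_TO_ONE.get(t_name, "X"),
                        tcr_region=t_region,
                        mhc_chain=m_chain,
                        mhc_res_id=m_res,
                        mhc_aa=THREE_TO_ONE.get(m_name, "X"),
                        mhc_region=m_region,
                        tcr_atom=t_atom,
                        mhc_atom=m_atom,
                        distance=float(d),
                        bond_type=bond,
                        contact_class=cclass,
                    )
                )
    return records


def records_to_frame(records: Iterable[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class ContactCountMatrix:
    """20x20 residue-pair contact counts, rows = MHC residue, cols = TCR."""

    counts: np.ndarray

    @property
    def symmetrized(self) -> np.ndarray:
        """M + M^T (a pair contributes to both orderings)."""
        return self.counts + self.counts.T

    def to_frame(self, symmetrized: bool = False) -> pd.DataFrame:
        data = self.symmetrized if symmetrized else self.counts
        return pd.DataFrame(data, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


def contact_count_matrix(
    records: Iterable[ContactRecord],
    contact_class: str | None = "SC-SC",
    bond_type: str | None = None,
) -> ContactCountMatrix:
    """Tabulate residue-pair contacts (optionally filtered by class/bond)."""
    counts = np.zeros((20, 20), dtype=np.int64)
    for rec in records:
        if contact_class is not None and rec.contact_class != contact_class:
            continue
        if bond_type is not None and rec.bond_type != bond_type:
            continue
        i = AMINO_ACIDS.find(rec.mhc_aa)
        j = AMINO_ACIDS.find(rec.tcr_aa)
        if i >= 0 and j >= 0:
            counts[i, j] += 1
    return ContactCountMatrix(counts=counts)


def per_residue_contact_counts(
    records: Iterable[ContactRecord],
    helix_map: Mapping[tuple[str, int], str],
    contact_class_prefix: str = "SC-",
) -> pd.Series:
    """Total CDR sidechain contacts per helix alignment column.

    ``helix_map`` maps (MHC chain, residue number) to an alignment column
    label; contacts on residues without a mapping are pooled under
    ``"unmapped"``.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.contact_class.startswith(contact_class_prefix):
            continue
        col = helix_map.get((rec.mhc_chain, rec.mhc_res_id), "unmapped")
        counts[col] = counts.get(col, 0) + 1
    return pd.Series(counts, dtype=np.int64).sort_index()


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided label-shuffling permutation test on the difference of means.

    p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm), which is never zero and
    is exact under the null up to Monte-Carlo error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n_x = x.size
    d_obs = abs(x.mean() - y.mean())
    perm = np.tile(pooled, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    d_perm = np.abs(perm[:, :n_x].mean(axis=1) - perm[:, n_x:].mean(axis=1))
    return float((1 + (d_perm >= d_obs - 1e-12).sum()) / (1 + n_perm))


def assign_potential_bins(
    gene_potentials: Mapping[str, float] | pd.Series,
    labels: Sequence[str] = ("weak", "moderate", "strong"),
) -> pd.Series:
    """Bin genes into weak/moderate/strong by tertiles of their potential.

    Binning is by rank (stable sort), so heavy ties still produce three
    near-equal bins; tied genes at a boundary are split deterministically.
    """
    s = pd.Series(dict(gene_potentials), dtype=float)
    order = s.sort_values(kind="stable").index
    out = pd.Series(
        pd.Categorical([None] * len(s), categories=list(labels), ordered=True),
        index=s.index,
    )
    for label, chunk in zip(labels, np.array_split(np.asarray(order), len(labels))):
        out[chunk] = label
    return out


def group_comparison(
    counts_by_bin: Mapping[str, Sequence[float]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise permutation tests between per-bin contact-count distributions.

    Returns one row per bin pair with group sizes, mean difference and
    two-sided p-value. Bins with fewer than two members are skipped with a
    warning. At least two nonempty bins are required.
    """
    bins = {k: np.asarray(v, dtype=float) for k, v in counts_by_bin.items()}
    nonempty = [k for k, v in bins.items() if v.size]
    if len(nonempty) < 2:
        raise ValueError("group comparison needs at least two nonempty bins")
    rng = np.random.default_rng(seed)
    rows = []
    keys = list(bins)
    for a_i, a in enumerate(keys):
        for b in keys[a_i + 1 :]:
            if bins[a].size < 2 or bins[b].size < 2:
                warnings.warn(f"bin pair ({a}, {b}) skipped: fewer than 2 members")
                continue
            p = permutation_test(
                bins[a], bins[b], n_perm=n_perm, seed=int(rng.integers(2**31))
            )
            rows.append(
                (a, b, bins[a].size, bins[b].size,
                 float(bins[a].mean() - bins[b].mean()), p)
            )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "mean_diff", "p_value"]
    )
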