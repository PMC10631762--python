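"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

* repertoires — gapped loop/helix sequence sets with controlled per-column
  amino-acid distributions (fixed residues, biophysical classes, or explicit
  probability vectors) and optional planted TCR-MHC covariation, emitted
  together with the exact distributions used so expected entropies, mutual
  informations and property profiles are computable in closed form;
* toy two-chain complexes — minimal PDB coordinate files whose atoms are
  placed at prescribed distances, so the qualifying contact list is known by
  construction.

Same seed, same spec => byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .alphabet import AMINO_ACIDS, ONE_TO_THREE
from .contacts import (
    BACKBONE_ATOMS,
    ELECTROSTATIC_CUTOFF,
    VDW_CUTOFF,
    ComplexAnnotation,
    ContactRecord,
    _electrostatic_ok,
)
from .interaction import DEFAULT_CLASSES
from .repertoire import SequenceRecord

__all__ = [
    "RepertoireSpec",
    "CovariationPlan",
    "ToyComplexSpec",
    "PlantedPair",
    "ToyComplex",
    "generate_repertoire",
    "generate_paired_repertoires",
    "generate_toy_complex",
    "write_fasta",
]

#: members of each residue class, in alphabet order (for class-draw columns)
CLASS_MEMBERS: dict[str, str] = {
    cls: "".join(aa for aa in AMINO_ACIDS if DEFAULT_CLASSES[aa] == cls)
    for cls in set(DEFAULT_CLASSES.values())
}


def _column_probabilities(spec) -> np.ndarray:
    """Resolve one column spec to a length-20 probability vector.

    Accepted forms: a single residue (fixed), a class name (uniform within
    the class), a mapping residue -> probability, or a length-20 vector.
    """
    if isinstance(spec, str):
        if len(spec) == 1:
            if spec not in AMINO_ACIDS:
                raise ValueError(f"fixed residue {spec!r} is not canonical")
            p = np.zeros(20)
            p[AMINO_ACIDS.index(spec)] = 1.0
            return p
        if spec in CLASS_MEMBERS:
            members = CLASS_MEMBERS[spec]
            p = np.zeros(20)
            for aa in members:
                p[AMINO_ACIDS.index(aa)] = 1.0 / len(members)
            return p
        raise ValueError(f"column spec {spec!r} is neither a residue nor a class")
    if isinstance(spec, Mapping):
        p = np.zeros(20)
        for aa, prob in spec.items():
            p[AMINO_ACIDS.index(aa)] = prob
    else:
        p = np.asarray(spec, dtype=float)
        if p.shape != (20,):
            raise ValueError("probability vector must have length 20")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("column probabilities must be nonnegative and sum to 1")
    return p


@dataclass
class RepertoireSpec:
    """Specification of one synthetic sequence family.

    ``regions`` maps region label -> list of column specs (the region at full
    length); ``length_ranges`` optionally maps a region to (lo, hi): each
    sequence then keeps the first ceil(L/2) and last floor(L/2) columns of
    the region for a length L drawn uniformly, matching the central pad
    convention of the encoder.
    """

    n_sequences: int
    regions: dict[str, list]
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    family: str = "other"
    id_prefix: str = "SYN"
    seed: int | None = None

    def column_probability_table(self) -> dict[tuple[str, int], np.ndarray]:
        """The exact per-column distributions (the generator's ground truth)."""
        return {
            (region, j): _column_probabilities(col)
            for region, cols in self.regions.items()
            for j, col in enumerate(cols)
        }


def generate_repertoire(
    spec: RepertoireSpec, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], dict[tuple[str, int], np.ndarray]]:
    """Draw a repertoire; returns (records, per-column probability table).

    Residues are drawn column-wise (vectorized over sequences); with a
    length range, sequence i keeps the first ceil(L_i/2) and last
    floor(L_i/2) columns of the region.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    region_draws: dict[str, np.ndarray] = {}
    region_lengths: dict[str, np.ndarray] = {}
    for region, cols in spec.regions.items():
        probs = [_column_probabilities(c) for c in cols]
        draws = np.column_stack([rng.choice(20, size=n, p=p) for p in probs])
        region_draws[region] = draws
        width = len(cols)
        if region in spec.length_ranges:
            lo, hi = spec.length_ranges[region]
            if not 1 <= lo <= hi <= width:
                raise ValueError(
                    f"length range {lo, hi} infeasible for region {region!r} "
                    f"of width {width}"
                )
            region_lengths[region] = rng.integers(lo, hi + 1, size=n)
        else:
            region_lengths[region] = np.full(n, width, dtype=np.int64)
    records = []
    for i in range(n):
        segments = {}
        for region, draws in region_draws.items():
            width = draws.shape[1]
            L = int(region_lengths[region][i])
            head = (L + 1) // 2
            keep = list(range(head)) + list(range(width - (L - head), width))
            segments[region] = "".join(aa[draws[i, keep]])
        records.append(
            SequenceRecord(
                id=f"{spec.id_prefix}-{i + 1}",
                family=spec.family,
                functionality="productive",
                sequence="".join(segments.values()),
                segments=segments,
            )
        )
    return records, spec.column_probability_table()


@dataclass
class CovariationPlan:
    """Plant covariation between one TCR column and one MHC column.

    With probability ``obedience`` the MHC residue at ``mhc_column`` is set to
    ``mapping[tcr residue]``; otherwise it is drawn from the MHC column's own
    distribution. Obedience 1 with a k-symbol equiprobable bijection gives a
    ground-truth mutual information of log2(k) bits under identity pairing;
    obedience 0 leaves the columns independent (true MI 0, finite-sample
    estimates sit at the bias floor).
    """

    tcr_column: tuple[str, int]
    mhc_column: tuple[str, int]
    mapping: dict[str, str]
    obedience: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.obedience <= 1.0:
            raise ValueError("obedience must be in [0, 1]")


def generate_paired_repertoires(
    tcr_spec: RepertoireSpec,
    mhc_spec: RepertoireSpec,
    covariation: Sequence[CovariationPlan] = (),
    seed: int | None = None,
):
    """Draw row-paired TCR and MHC repertoires with planted covariation.

    Returns (tcr_records, mhc_records, ground_truth) where ground_truth holds
    both families' column tables and the covariation plan. Row i of the TCR
    set is the planted partner of row i of the MHC set (identity pairing).
    """
    if tcr_spec.n_sequences != mhc_spec.n_sequences:
        raise ValueError("paired generation requires equal n_sequences")
    rng = np.random.default_rng(seed)
    tcr_records, tcr_probs = generate_repertoire(tcr_spec, rng)
    mhc_records, mhc_probs = generate_repertoire(mhc_spec, rng)
    for plan in covariation:
        t_region, t_col = plan.tcr_column
        m_region, m_col = plan.mhc_column
        for t_rec, m_rec in zip(tcr_records, mhc_records):
            if rng.random() < plan.obedience:
                t_aa = t_rec.segments[t_region][t_col]
                if t_aa not in plan.mapping:
                    raise ValueError(
                        f"covariation mapping lacks residue {t_aa!r}; the TCR "
                        f"column spec conflicts with the plan"
                    )
                seg = m_rec.segments[m_region]
                m_rec.segments[m_region] = (
                    seg[:m_col] + plan.mapping[t_aa] + seg[m_col + 1 :]
                )
        for m_rec in mhc_records:
            m_rec.sequence = "".join(m_rec.segments.values())
    ground_truth = {
        "tcr_columns": tcr_probs,
        "mhc_columns": mhc_probs,
        "covariation": list(covariation),
    }
    return tcr_records, mhc_records, ground_truth


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    """Write records as FASTA with IMGT-style pipe headers (id|functionality)."""
    tag = {"productive": "F", "ORF": "ORF", "pseudogene": "P"}
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|{rec.id}|synthetic|{tag[rec.functionality]}\n")
            fh.write(rec.sequence + "\n")


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    """One TCR-atom/MHC-atom pair placed at a prescribed distance."""

    tcr_aa: str
    tcr_atom: str
    mhc_aa: str
    mhc_atom: str
    distance: float


@dataclass
class ToyComplexSpec:
    """Planted qualifying pairs plus decoy pairs beyond both cutoffs."""

    planted: list[PlantedPair] = field(default_factory=list)
    decoys: list[PlantedPair] = field(default_factory=list)
    seed: int | None = None


@dataclass
class ToyComplex:
    pdb_text: str
    annotation: ComplexAnnotation
    expected: list[ContactRecord]


_SPACING = 30.0  # A between residue slots; far beyond any cutoff
_CONTACT_Y = 6.0  # y of the TCR-side planted atom
_FAR_Y = 60.0  # y of non-planted MHC atoms


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _expected_records(
    pair: PlantedPair, slot: int, t_chain: str, m_chain: str
) -> list[ContactRecord]:
    """Ground-truth contact records implied by one planted pair's geometry."""
    d = pair.distance
    t_side = "SC" if pair.tcr_atom not in BACKBONE_ATOMS else "Back"
    m_side = "SC" if pair.mhc_atom not in BACKBONE_ATOMS else "Back"
    cclass = f"{t_side}-{m_side}"
    bonds = []
    if d <= VDW_CUTOFF:
        bonds.append("vdw")
    if d <= ELECTROSTATIC_CUTOFF and _electrostatic_ok(
        _element_of(pair.tcr_atom),
        _element_of(pair.mhc_atom),
        ONE_TO_THREE[pair.tcr_aa],
        ONE_TO_THREE[pair.mhc_aa],
    ):
        bonds.append("electrostatic")
    return [
        ContactRecord(
            tcr_chain=t_chain,
            tcr_res_id=slot + 1,
            tcr_aa=pair.tcr_aa,
            tcr_region="CDR1",
            mhc_chain=m_chain,
            mhc_res_id=slot + 1,
            mhc_aa=pair.mhc_aa,
            mhc_region="helix1",
            tcr_atom=pair.tcr_atom,
            mhc_atom=pair.mhc_atom,
            distance=d,
            bond_type=bond,
            contact_class=cclass,
        )
        for bond in bonds
    ]


def generate_toy_complex(
    spec: ToyComplexSpec, tcr_chain: str = "A", mhc_chain: str = "B"
) -> ToyComplex:
    """Build a minimal two-chain PDB with atoms at prescribed distances.

    Each planted or decoy pair occupies its own residue slot on a linear
    scaffold with 30 A spacing, so pairs cannot contaminate one another; the
    only atoms within any cutoff of the other chain are the planted ones.
    Residues carry the four backbone atoms plus the planted atom (when it is
    a sidechain atom). The expected contact list is exact ground truth for
    :func:`tcrmhc.contacts.find_contacts`.
    """
    pairs = list(spec.planted) + list(spec.decoys)
    if not pairs:
        raise ValueError("toy complex needs at least one planted or decoy pair")
    seen: dict[tuple, float] = {}
    for slot, pair in enumerate(pairs):
        for key in (
            ("t", slot, pair.tcr_atom),
            ("m", slot, pair.mhc_atom),
        ):
            if key in seen and seen[key] != pair.distance:
                raise ValueError(
                    f"atom {key} required at two different distances: "
                    f"{seen[key]} and {pair.distance}"
                )
            seen[key] = pair.distance

    atoms = []  # (chain, res_id, res_name, atom_name, x, y, z)

    def add_residue(chain: str, res_id: int, aa: str, planted_atom: str | None,
                    planted_pos: tuple | None, base_y: float) -> None:
        x0 = (res_id - 1) * _SPACING
        backbone = {
            "N": (x0 - 1.2, base_y + 0.5, 0.0),
            "CA": (x0, base_y, 0.0),
            "C": (x0 + 1.2, base_y + 0.5, 0.0),
            "O": (x0 + 1.2, base_y + 1.7, 0.0),
        }
        if planted_atom in backbone:
            backbone[planted_atom] = planted_pos
            planted_atom = None
        res_name = ONE_TO_THREE[aa]
        for name, pos in backbone.items():
            atoms.append((chain, res_id, res_name, name, *pos))
        if planted_atom is not None:
            atoms.append((chain, res_id, res_name, planted_atom, *planted_pos))

    for slot, pair in enumerate(pairs):
        res_id = slot + 1
        x = slot * _SPACING
        t_pos = (x, _CONTACT_Y, 0.0)
        m_pos = (x, _CONTACT_Y + pair.distance, 0.0)
        add_residue(tcr_chain, res_id, pair.tcr_aa, pair.tcr_atom, t_pos, 0.0)
        add_residue(mhc_chain, res_id, pair.mhc_aa, pair.mhc_atom, m_pos, _FAR_Y)

    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a[4:] for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a[0] for a in atoms])
    arr.res_id = np.array([a[1] for a in atoms])
    arr.res_name = np.array([a[2] for a in atoms])
    arr.atom_name = np.array([a[3] for a in atoms])
    arr.element = np.array([_element_of(a[3]) for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)

    n_res = len(pairs)
    annotation = ComplexAnnotation(
        tcr_regions={tcr_chain: {"CDR1": (1, n_res)}},
        mhc_regions={mhc_chain: {"helix1": (1, n_res)}},
        name="toy-complex",
    )
    expected: list[ContactRecord] = []
    for slot, pair in enumerate(spec.planted):
        expected.extend(_expected_records(pair, slot, tcr_chain, mhc_chain))
    return ToyComplex(pdb_text=buf.getvalue(), annotation=annotation, expected=expected)
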