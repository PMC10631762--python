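"""The germline TCR-MHC interaction potential.

Amino acids are grouped into five classes (positive, negative, hydrophilic,
hydrophobic, noninteracting) and a class-pair rule table assigns each of the
20x20 residue pairs an integer score: productive contacts (salt bridges,
hydrogen-bond-capable pairs) score positively, destructive ones
(hydrophilic-hydrophobic and like-charge clashes) negatively, and anything
involving a noninteracting residue scores 0.

A CDR loop is scored against an MHC helix by sliding a 3-residue window
(trigram) over each and pairing every loop trigram with every helix trigram
position by position. A triad only counts when all three residue pairs are at
least weakly favourable (score >= +1 under the default validity rule); valid
triads contribute the sum of their three pair scores, so the loop-helix
potential is non-negative by construction. For example NNK against EDQ scores
[+1, +1, +1] and counts (total +3), while KEL against RKA scores [-2, +2, 0]
and is discounted because it contains a clash.

Scores carry no physical units; they rank broad biophysical compatibility,
not binding free energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .repertoire import SequenceRecord

__all__ = [
    "ResidueClassMap",
    "InteractionMatrix",
    "TriadScore",
    "ScoreTable",
    "DEFAULT_CLASSES",
    "DEFAULT_RULES",
    "build_matrix",
    "default_interaction_matrix",
    "score_trigram_pair",
    "loop_helix_potential",
    "gene_allele_scores",
    "helix_distributions",
    "per_residue_breakdown",
    "relu_normalize",
]

CLASS_NAMES = ("positive", "negative", "hydrophilic", "hydrophobic", "noninteracting")

#: Default residue classes (shipped ruleset, overridable via config).
DEFAULT_CLASSES: dict[str, str] = {
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "hydrophilic" for aa in "STNQYCW"},
    **{aa: "hydrophobic" for aa in "FLIMV"},
    **{aa: "noninteracting" for aa in "GAP"},
}

#: Default class-pair scores (unordered pairs).
DEFAULT_RULES: dict[frozenset, int] = {
    frozenset(["positive", "negative"]): +2,
    frozenset(["hydrophilic"]): +1,
    frozenset(["hydrophilic", "positive"]): +1,
    frozenset(["hydrophilic", "negative"]): +1,
    frozenset(["hydrophobic"]): +1,
    frozenset(["positive"]): -2,
    frozenset(["negative"]): -2,
    frozenset(["hydrophobic", "hydrophilic"]): -1,
    frozenset(["hydrophobic", "positive"]): -1,
    frozenset(["hydrophobic", "negative"]): -1,
    frozenset(["noninteracting"]): 0,
    frozenset(["noninteracting", "positive"]): 0,
    frozenset(["noninteracting", "negative"]): 0,
    frozenset(["noninteracting", "hydrophilic"]): 0,
    frozenset(["noninteracting", "hydrophobic"]): 0,
}

# Printed worked examples any configured matrix must reproduce: a scoring
# scheme that cannot reproduce them is not the scheme this package implements.
_WORKED_EXAMPLES = (
    ("NNK", "EDQ", (1, 1, 1), True),
    ("KEL", "RKA", (-2, 2, 0), False),
)


@dataclass
class ResidueClassMap:
    """Assignment of each canonical amino acid to one interaction class."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.classes)
        if missing:
            raise ValueError(f"class map missing amino acids: {sorted(missing)}")
        bad = {aa: c for aa, c in self.classes.items() if c not in CLASS_NAMES}
        if bad:
            raise ValueError(f"unknown classes: {bad}")

    def of(self, aa: str) -> str:
        return self.classes[aa]


@dataclass
class InteractionMatrix:
    """Symmetric 20x20 integer residue-pair score table."""

    scores: np.ndarray  # (20, 20), order AMINO_ACIDS x AMINO_ACIDS
    classes: ResidueClassMap | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.shape != (20, 20):
            raise ValueError("interaction matrix must be 20x20")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("interaction matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        """Pair score for residues ``a``, ``b``; nonstandard residues score 0."""
        ia = AMINO_ACIDS.find(a.upper())
        ib = AMINO_ACIDS.find(b.upper())
        if ia < 0 or ib < 0:
            return 0
        return int(self.scores[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))

    @classmethod
    def from_csv(cls, path) -> "InteractionMatrix":
        """Load an explicit 20x20 override (rows/cols labelled by residue)."""
        df = pd.read_csv(path, index_col=0)
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        m = cls(scores=df.to_numpy())
        m.self_check()
        return m

    def self_check(self) -> None:
        """Assert the matrix reproduces the printed worked trigram examples."""
        for t, h, expected, expected_valid in _WORKED_EXAMPLES:
            got = score_trigram_pair(t, h, self)
            if tuple(got.pair_scores) != expected or got.valid != expected_valid:
                raise ValueError(
                    f"interaction matrix fails self-check on {t}/{h}: "
                    f"got {tuple(got.pair_scores)} valid={got.valid}, "
                    f"expected {expected} valid={expected_valid}"
                )


def build_matrix(
    classes: ResidueClassMap | Mapping[str, str] = None,
    rule_scores: Mapping[frozenset, int] | None = None,
    self_check: bool = True,
) -> InteractionMatrix:
    """Build the 20x20 matrix from a class map and class-pair rule table.

    ``rule_scores`` maps unordered class pairs (frozensets; a singleton for a
    like-class pair) to integer scores and must cover all 15 unordered pairs.
    """
    if classes is None:
        classes = ResidueClassMap(dict(DEFAULT_CLASSES))
    elif not isinstance(classes, ResidueClassMap):
        classes = ResidueClassMap(dict(classes))
    rules = dict(DEFAULT_RULES) if rule_scores is None else dict(rule_scores)
    for i, ci in enumerate(CLASS_NAMES):
        for cj in CLASS_NAMES[i:]:
            if frozenset([ci, cj]) not in rules:
                raise ValueError(f"rule table missing class pair ({ci}, {cj})")
    scores = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = rules[frozenset([classes.of(a), classes.of(b)])]
    matrix = InteractionMatrix(scores=scores, classes=classes)
    if self_check:
        matrix.self_check()
    return matrix


_DEFAULT_MATRIX: InteractionMatrix | None = None


def default_interaction_matrix() -> InteractionMatrix:
    """The shipped ruleset (cached); passes the worked-example self-check."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = build_matrix()
    return _DEFAULT_MATRIX


@dataclass
class TriadScore:
    """Score of one position-aligned trigram pair."""

    tcr_trigram: str
    mhc_trigram: str
    pair_scores: tuple[int, int, int]
    valid: bool

    @property
    def total(self) -> int:
        return sum(self.pair_scores) if self.valid else 0


def _triad_valid(pair_scores: Sequence[int], rule: str) -> bool:
    if rule == "all_weak":
        return all(s >= 1 for s in pair_scores)
    if rule == "no_clash":
        return all(s >= 0 for s in pair_scores) and any(s >= 1 for s in pair_scores)
    raise ValueError(f"unknown validity rule {rule!r}")


def score_trigram_pair(
    t: str,
    m: str,
    matrix: InteractionMatrix | None = None,
    validity: str = "all_weak",
) -> TriadScore:
    """Score a TCR trigram against an MHC trigram position by position.

    The triad is valid (counts toward a potential) only if every one of the
    three residue pairs is at least weakly favourable (``all_weak``, default:
    all pair scores >= +1). The alternative ``no_clash`` rule admits triads
    with no negative pair and at least one favourable one; both reproduce the
    printed worked examples. Nonstandard residues score 0 at their position.
    """
    if len(t) != 3 or len(m) != 3:
        raise ValueError("trigrams must have length 3")
    if matrix is None:
        matrix = default_interaction_matrix()
    pair_scores = tuple(matrix.score(t[i], m[i]) for i in range(3))
    return TriadScore(
        tcr_trigram=t,
        mhc_trigram=m,
        pair_scores=pair_scores,
        valid=_triad_valid(pair_scores, validity),
    )


@dataclass
class LoopHelixScore:
    """Raw potential of one loop-helix pair with per-helix-position attribution."""

    score: int
    helix_attribution: np.ndarray  # per helix position, summed pair scores of valid triads
    n_triads: int
    n_valid: int


def loop_helix_potential(
    loop: str,
    helix: str,
    matrix: InteractionMatrix | None = None,
    validity: str = "all_weak",
    normalize: bool = False,
) -> LoopHelixScore:
    """Sum the scores of all valid trigram triads between a loop and a helix.

    All L-2 contiguous loop trigrams are paired with all M-2 helix trigrams
    (step 1, no special terminal treatment). Within each valid triad, helix
    position j+i accrues its own pair score (the score of residue pair i of
    the triad starting at helix position j), so the attribution over helix
    positions sums exactly to the total. With ``normalize`` the score is
    divided by the number of trigram pairs for cross-length comparison.
    """
    if matrix is None:
        matrix = default_interaction_matrix()
    attribution = np.zeros(len(helix), dtype=float)
    if len(loop) < 3 or len(helix) < 3:
        warnings.warn(
            f"loop/helix shorter than a trigram ({len(loop)}/{len(helix)}); score 0",
            stacklevel=2,
        )
        return LoopHelixScore(score=0, helix_attribution=attribution, n_triads=0, n_valid=0)
    total = 0
    n_triads = 0
    n_valid = 0
    for a in range(len(loop) - 2):
        t = loop[a : a + 3]
        for b in range(len(helix) - 2):
            m = helix[b : b + 3]
            triad = score_trigram_pair(t, m, matrix, validity)
            n_triads += 1
            if triad.valid:
                n_valid += 1
                total += triad.total
                for i in range(3):
                    attribution[b + i] += triad.pair_scores[i]
    score: float | int = total
    if normalize and n_triads:
        score = total / n_triads
        attribution = attribution / n_triads
    return LoopHelixScore(
        score=score, helix_attribution=attribution, n_triads=n_triads, n_valid=n_valid
    )


@dataclass
class ScoreTable:
    """Interaction potentials for every (gene, loop) x (allele, helix) cell."""

    frame: pd.DataFrame  # columns: gene, chain, loop, allele, helix, score

    def pivot(self, loop: str, helix: str) -> pd.DataFrame:
        sub = self.frame[(self.frame.loop == loop) & (self.frame.helix == helix)]
        return sub.pivot(index="allele", columns="gene", values="score")

    def gene_allele_means(self) -> pd.DataFrame:
        """Mean potential over both CDR loops per (gene, allele, helix)."""
        return (
            self.frame.groupby(["gene", "chain", "allele", "helix"], sort=False)["score"]
            .mean()
            .reset_index()
        )

    def gene_means(self) -> pd.Series:
        """Mean potential per gene over all loops, alleles and helices."""
        return self.frame.groupby("gene", sort=False)["score"].mean()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def gene_allele_scores(
    tcr_records: Iterable[SequenceRecord],
    mhc_records: Iterable[SequenceRecord],
    matrix: InteractionMatrix | None = None,
    loops: Sequence[str] = ("CDR1", "CDR2"),
    helices: Sequence[str] = ("helix1", "helix2"),
    validity: str = "all_weak",
    normalize: bool = False,
) -> ScoreTable:
    """Score the complete cross-product of TCR genes and HLA alleles.

    Every CDR loop of every gene is scored against every helix of every
    allele, with no preference for a canonical binding orientation.
    """
    tcr_records = list(tcr_records)
    mhc_records = list(mhc_records)
    if not tcr_records or not mhc_records:
        raise ValueError("need at least one TCR record and one MHC record")
    if matrix is None:
        matrix = default_interaction_matrix()
    rows = []
    for tcr in tcr_records:
        for loop in loops:
            seq = tcr.segments[loop]
            for mhc in mhc_records:
                for helix in helices:
                    res = loop_helix_potential(
                        seq, mhc.segments[helix], matrix, validity, normalize
                    )
                    rows.append((tcr.id, tcr.family, loop, mhc.id, helix, res.score))
    return ScoreTable(
        frame=pd.DataFrame(
            rows, columns=["gene", "chain", "loop", "allele", "helix", "score"]
        )
    )


def helix_distributions(
    table: ScoreTable, hla_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per (HLA group, TCR chain, helix) distribution of mean-over-loop scores.

    Each distribution holds one value per (gene, allele) pair — the mean of
    that pair's potentials over both CDR loops — so its size is
    #genes x #alleles within the group. Quartiles are attached per group.
    """
    alleles = set(table.frame["allele"])
    unknown = alleles - set(hla_groups)
    if unknown:
        raise ValueError(f"alleles without a group label: {sorted(unknown)}")
    means = table.gene_allele_means()
    means["group"] = means["allele"].map(dict(hla_groups))
    q = (
        means.groupby(["group", "chain", "helix"])["score"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
        .reset_index()
    )
    return means.merge(q, on=["group", "chain", "helix"])


def per_residue_breakdown(
    tcr_records: Iterable[SequenceRecord],
    mhc_record: SequenceRecord,
    matrix: InteractionMatrix | None = None,
    loops: Sequence[str] = ("CDR1", "CDR2"),
    helices: Sequence[str] = ("helix1", "helix2"),
    validity: str = "all_weak",
) -> dict[str, np.ndarray]:
    """Mean per-helix-position attribution over all (gene, loop) pairs.

    For one HLA allele, each helix position receives the mean (over every
    gene and CDR loop) of the pair scores it accrues inside valid triads.
    Positions occupied by a noninteracting residue in the helix are exactly
    0. The position sums conserve the mean potential: summing a helix's
    breakdown reproduces the mean loop-helix potential over (gene, loop).
    """
    tcr_records = list(tcr_records)
    if matrix is None:
        matrix = default_interaction_matrix()
    out: dict[str, np.ndarray] = {}
    for helix in helices:
        seq = mhc_record.segments[helix]
        acc = np.zeros(len(seq))
        n = 0
        for tcr in tcr_records:
            for loop in loops:
                res = loop_helix_potential(tcr.segments[loop], seq, matrix, validity)
                acc += res.helix_attribution
                n += 1
        out[helix] = acc / n if n else acc
    return out


def enumerate_gene_pairings(
    trav_records: Iterable[SequenceRecord], trbv_records: Iterable[SequenceRecord]
) -> list[tuple[str, str]]:
    """All possible alpha/beta gene pairings (the receptor-level cross-product).

    With the 45 productive TRAV and 48 productive TRBV genes in humans this
    enumerates the 2160 possible germline alpha-beta receptors.
    """
    return [(a.id, b.id) for a in trav_records for b in trbv_records]


def relu_normalize(values):
    """Map negative potentials to 0 (elementwise max(0, x)); idempotent.

    Used when comparing a potential matrix to empirical contact counts,
    which cannot be negative.
    """
    if isinstance(values, pd.DataFrame):
        return values.clip(lower=0)
    return np.maximum(np.asarray(values), 0)
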