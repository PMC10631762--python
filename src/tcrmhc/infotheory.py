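"""Position-sensitive information theory on encoded repertoires.

Shannon entropy per alignment column quantifies amino-acid diversity at each
structural position (log base 2; the 20-letter maximum is log2(20) ~ 4.32
bits). Mutual information between a TCR column and an MHC column quantifies
covariation under a sampled pairing of TCR genes with HLA alleles: each TCR
row is matched with one MHC row per repetition, I = H(X) - H(X|Y) is computed
on the paired sample, and the average over repetitions is reported.

Structural pad cells (code 0) mark the absence of a residue, not a residue
state, and are excluded from every distribution; an all-pad column has zero
entropy by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import N_CODES, PAD_CODE
from .encoding import AimsMatrix

__all__ = [
    "ColumnDistribution",
    "EntropyProfile",
    "MIMatrix",
    "column_entropy",
    "entropy_profile",
    "subsampled_entropy_profile",
    "mutual_information",
    "mi_bias_bound",
]

LN2 = math.log(2.0)


@dataclass
class ColumnDistribution:
    """Amino-acid counts (codes 1-21) for one alignment column."""

    counts: np.ndarray  # length 21, counts[k-1] is the count of code k

    @classmethod
    def from_column(cls, codes: np.ndarray) -> "ColumnDistribution":
        codes = np.asarray(codes, dtype=np.int64)
        counts = np.bincount(codes[codes != PAD_CODE], minlength=N_CODES)[1:]
        return cls(counts=counts)

    @property
    def n_effective(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        n = self.n_effective
        return self.counts / n if n else np.zeros_like(self.counts, dtype=float)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n <= 1:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def column_entropy(dist: ColumnDistribution | np.ndarray) -> float:
    """Shannon entropy (bits) of one column distribution.

    Accepts a :class:`ColumnDistribution` or a raw column of codes. Returns
    0 for empty or single-residue columns (no diversity is measurable).
    """
    if not isinstance(dist, ColumnDistribution):
        dist = ColumnDistribution.from_column(np.asarray(dist))
    return _entropy_from_counts(dist.counts)


def entropy_profile(matrix: AimsMatrix) -> np.ndarray:
    """Plain per-column entropy (bits) of an encoded repertoire."""
    return np.array([column_entropy(matrix.codes[:, j]) for j in range(matrix.n_columns)])


@dataclass
class EntropyProfile:
    """Per-column mean/std entropy over subsampling repetitions."""

    columns: list[str]
    mean_bits: np.ndarray
    std_bits: np.ndarray
    n_subsample: int
    n_repetitions: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        region = [c.split(":")[0] for c in self.columns]
        return pd.DataFrame(
            {
                "column": self.columns,
                "region": region,
                "mean_bits": self.mean_bits,
                "std_bits": self.std_bits,
            }
        )


def subsampled_entropy_profile(
    matrix: AimsMatrix,
    n_subsample: int | None = None,
    n_repetitions: int = 1000,
    seed: int | None = None,
) -> EntropyProfile:
    """Average per-column entropy over repeated row subsampling.

    Each repetition draws ``n_subsample`` rows without replacement and
    computes the per-column entropy; the mean and standard deviation over
    repetitions are reported. Subsampling equalizes set sizes when families
    of very different depth (e.g. dozens of TCR genes vs hundreds of HLA
    alleles) are displayed side by side.
    """
    n_rows = matrix.n_rows
    if n_subsample is None:
        n_subsample = n_rows
    if n_subsample > n_rows:
        raise ValueError(f"n_subsample={n_subsample} exceeds number of rows {n_rows}")
    rng = np.random.default_rng(seed)
    profiles = np.empty((n_repetitions, matrix.n_columns))
    for r in range(n_repetitions):
        idx = rng.choice(n_rows, size=n_subsample, replace=False)
        sub = matrix.codes[idx]
        profiles[r] = [column_entropy(sub[:, j]) for j in range(matrix.n_columns)]
    return EntropyProfile(
        columns=matrix.column_labels(),
        mean_bits=profiles.mean(axis=0),
        std_bits=profiles.std(axis=0),
        n_subsample=n_subsample,
        n_repetitions=n_repetitions,
        seed=seed,
    )


def mi_bias_bound(k_x: int, k_y: int, n: int) -> float:
    """First-order (Miller-Madow) expectation of mutual information between
    independent variables: (K_x - 1)(K_y - 1) / (2 N ln 2) bits."""
    return (k_x - 1) * (k_y - 1) / (2.0 * n * LN2)


def _mi_pair(x: np.ndarray, y: np.ndarray, miller_madow: bool = False) -> float:
    """MI (bits) between two paired code columns, pads excluded pairwise."""
    mask = (x != PAD_CODE) & (y != PAD_CODE)
    x, y = x[mask], y[mask]
    n = x.size
    if n <= 1:
        return 0.0
    joint = np.bincount(x * N_CODES + y, minlength=N_CODES * N_CODES)
    hx = _entropy_from_counts(np.bincount(x, minlength=N_CODES))
    hy = _entropy_from_counts(np.bincount(y, minlength=N_CODES))
    hxy = _entropy_from_counts(joint)
    mi = hx + hy - hxy
    if miller_madow:
        kx = int((np.bincount(x, minlength=N_CODES) > 0).sum())
        ky = int((np.bincount(y, minlength=N_CODES) > 0).sum())
        kxy = int((joint > 0).sum())
        mi += ((kx - 1) + (ky - 1) - (kxy - 1)) / (2.0 * n * LN2)
    return max(mi, 0.0) if miller_madow else mi


@dataclass
class MIMatrix:
    """Mean/std mutual information (bits) for every TCR x MHC column pair."""

    tcr_columns: list[str]
    mhc_columns: list[str]
    mean_bits: np.ndarray
    std_bits: np.ndarray
    pairing: str
    n_repetitions: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tc in enumerate(self.tcr_columns):
            for j, mc in enumerate(self.mhc_columns):
                rows.append((tc, mc, self.mean_bits[i, j], self.std_bits[i, j]))
        return pd.DataFrame(rows, columns=["tcr_column", "mhc_column", "mean_bits", "std_bits"])


def _draw_partners(
    rng: np.random.Generator,
    n_tcr: int,
    n_mhc: int,
    pairing: str,
    tcr_groups,
    mhc_groups,
) -> np.ndarray:
    if pairing == "identity":
        if n_tcr != n_mhc:
            raise ValueError("identity pairing requires equal row counts")
        return np.arange(n_tcr)
    if pairing == "random":
        return rng.integers(0, n_mhc, size=n_tcr)
    if pairing == "grouped":
        if tcr_groups is None or mhc_groups is None:
            raise ValueError("grouped pairing requires group labels on both matrices")
        mhc_groups = np.asarray(mhc_groups)
        partners = np.empty(n_tcr, dtype=np.int64)
        for g in np.unique(tcr_groups):
            pool = np.flatnonzero(mhc_groups == g)
            if pool.size == 0:
                raise ValueError(f"group {g!r} present in TCR set but absent in MHC set")
            sel = np.flatnonzero(np.asarray(tcr_groups) == g)
            partners[sel] = rng.choice(pool, size=sel.size, replace=True)
        return partners
    raise ValueError(f"unknown pairing scheme {pairing!r}")


def mutual_information(
    tcr: AimsMatrix,
    mhc: AimsMatrix,
    pairing: str = "random",
    n_repetitions: int = 1000,
    seed: int | None = None,
    miller_madow: bool = False,
) -> MIMatrix:
    """Subsampling-averaged MI between every TCR column and MHC column.

    Per repetition each TCR row is matched with one MHC row — drawn uniformly
    with replacement under the ``random`` scheme, within shared organism/group
    labels under ``grouped``, or row-for-row under ``identity`` (which is
    deterministic and needs equal row counts). MI is computed per column pair
    on the paired sample and averaged over repetitions.
    """
    if tcr.n_rows == 0 or mhc.n_rows == 0:
        raise ValueError("both matrices must be nonempty")
    rng = np.random.default_rng(seed)
    reps = 1 if pairing == "identity" else n_repetitions
    acc = np.zeros((tcr.n_columns, mhc.n_columns))
    acc2 = np.zeros_like(acc)
    for _ in range(reps):
        partners = _draw_partners(
            rng, tcr.n_rows, mhc.n_rows, pairing, tcr.groups, mhc.groups
        )
        paired = mhc.codes[partners]
        vals = np.empty_like(acc)
        for i in range(tcr.n_columns):
            xi = tcr.codes[:, i]
            for j in range(mhc.n_columns):
                vals[i, j] = _mi_pair(xi, paired[:, j], miller_madow)
        acc += vals
        acc2 += vals * vals
    mean = acc / reps
    var = np.maximum(acc2 / reps - mean * mean, 0.0)
    return MIMatrix(
        tcr_columns=tcr.column_labels(),
        mhc_columns=mhc.column_labels(),
        mean_bits=mean,
        std_bits=np.sqrt(var),
        pairing=pairing,
        n_repetitions=reps,
        seed=seed,
    )
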