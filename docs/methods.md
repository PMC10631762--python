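# Methods

This note documents the models and conventions implemented in `tcrmhc`, the
choices made where the design was genuinely open, and what the synthetic
data used by the tests does and does not establish about real repertoires.

## Sequence handling and encoding

Input families (TRAV, TRBV, HLA class I, HLA class IIα/β, KIR) are read from
FASTA. IMGT-style pipe-delimited headers are scanned for a functionality
token (`F` = productive, `ORF`, `P` = pseudogene; the regex is
configurable); untagged entries default to productive. Only productive
sequences are analyzed, and duplicates are removed on the *extracted region
segments* — not the full sequence — because downstream analysis sees only
those segments. Among duplicates the first record is kept.

Structurally conserved regions (CDR1/CDR2 loops; TCR-exposed helix residues
and peptide-contacting residues of MHC) are taken from an editable config of
1-based position lists per family. No alignment is inferred: positions are
applied to the reference numbering as given. The shipped defaults
(`tcrmhc/data/regions_default.yaml`) are reasonable conventions — IMGT
unique numbering for the CDR loops, a solvent-exposure reading of the MHC
helices — and are explicitly *not* authoritative; users of real IMGT /
IPD-IMGT-HLA downloads should review them against their own numbering.

Segments are encoded into a region-blocked integer matrix: codes 1–20 are
the canonical amino acids in alphabetical one-letter order (A=1 … Y=20),
21 is `X`/nonstandard, 0 pads structural gaps. Each region occupies one
block whose width is the maximum segment length in the family. The default
`central` pad mode anchors the first ⌈L/2⌉ residues to the block start and
the rest to the block end — loop termini are structurally conserved while
apex length varies — with a `left` mode for testing. Encoding is lossless
(decode(encode(x)) = x), which the suite checks property-style.

## Information theory

Per-column Shannon entropy is `H = −Σ p log₂ p` over codes 1–21, with
`0·log 0 ≡ 0`. Pad cells (code 0) are **excluded** from every distribution:
they mark the absence of a residue, and including them would manufacture
diversity out of block width. An all-pad or single-residue column has H = 0.
The 20-residue maximum is log₂ 20 ≈ 4.32 bits. Entropy profiles are
averaged over repeated subsampling of rows without replacement (default
1000 repetitions; the subsample size defaults to the full set and should be
set to the smaller family when contrasting sets of very different depth);
the standard deviation over repetitions is reported alongside the mean.

Mutual information between a TCR column X and an MHC column Y is
`I = H(X) − H(X|Y)`, computed per repetition on a sampled pairing: each TCR
row receives one MHC partner, drawn uniformly **with replacement** (the
sampling scheme is a convention; each individual carries few HLA alleles,
so no single pairing is privileged), or within shared group labels (e.g.
organism) under the `grouped` scheme, or row-for-row under `identity`
(used with planted covariation). Pairs where either side is pad are
excluded. The mean and std over repetitions (default 1000) are reported.
No finite-sample bias correction is applied by default — averages are
reported raw — but a Miller–Madow correction is available behind a flag.
The documented bias floor for independent columns is the first-order
expectation `(K_x−1)(K_y−1)/(2N ln 2)` bits.

## Biophysical profiles

Property tables assign one scalar per canonical amino acid and are
z-normalized over the 20 values (population std). Defaults: charge K,R = +1,
D,E = −1, H = +0.1 (partial protonation near physiological pH; the exact
histidine treatment is a convention and is exposed in config), others 0;
hydropathy is Kyte–Doolittle. Profiles report the per-column mean and
per-sequence std (the shading convention) over non-pad, non-`X` cells;
all-pad columns are reported as missing (NaN), never as zero.

## Interaction potential

Residues are classed positive {K,R,H}, negative {D,E}, hydrophilic
{S,T,N,Q,Y,C,W}, hydrophobic {F,L,I,M,V}, noninteracting {G,A,P}. The
class-pair rule scores are: positive×negative +2; hydrophilic×hydrophilic,
hydrophilic×charged, hydrophobic×hydrophobic +1; hydrophobic×hydrophilic
and hydrophobic×charged −1; like-charge −2; anything with a noninteracting
residue 0. Both map and rules are config-overridable (an explicit 20×20 CSV
override is also accepted), and every constructed matrix passes a startup
self-check that it reproduces the two reference triads (NNK/EDQ →
[+1,+1,+1] counted; KEL/RKA → [−2,+2,0] discounted); a scheme that cannot
is rejected rather than silently used.

A loop of length L against a helix of length M enumerates all
(L−2)(M−2) contiguous trigram pairs with step 1 and no special terminal
treatment. Triad validity defaults to *all three pair scores ≥ +1*
("at least weakly interacting"); an alternative `no_clash` rule (no
negative pair, at least one positive) is selectable and reproduces the same
reference triads. Valid triads contribute the sum of their pair scores, so
potentials are non-negative and monotone under loop extension. The score is
a raw, unitless sum; an optional per-trigram-pair normalization
(score / (L−2)(M−2)) is available for cross-length comparison, default off.

CDR1 and CDR2 of every gene are scored against both helices of every allele
independently — no geometric weighting and no preference for a canonical
docking orientation. Per-helix-residue decomposition: within each valid
triad, helix position b+i accrues its own pair score (not total/3 — the
attribution should vanish exactly on conserved noninteracting positions),
so position sums conserve the total. Group-level summaries aggregate the
mean-over-loops per (gene, allele) within HLA groups, with quartiles.

## Structural contacts

PDB files are read with biotite (first model, highest-occupancy altloc,
hydrogens dropped; insertion codes preserved in residue selection). An
annotation file names the TCR/MHC chains and the inclusive residue-number
ranges of the CDR loops and helices — structure-to-gene mapping is user
input, not automated.

For every CDR residue × helix residue, all heavy-atom pairs are tested:
van der Waals contact at ≤ 4.5 Å; electrostatic contact at ≤ 6.0 Å when the
element pair is N–O (either direction), O–O with Ser/Thr/Tyr involved
(hydroxyl oxygen), or N–N with His involved. The electrostatic rule is
applied to all heavy atoms, backbone included, with the contact class
recorded (SC-SC, SC-Back, Back-SC, Back-Back; backbone = N, CA, C, O, OXT,
so glycine can never be on the sidechain side). Multiplicity: one record
per (residue pair, class, bond type), keeping the closest qualifying atom
pair — residue-level deduplication avoids inflating counts with atom
multiplicity.

Counts are tabulated into a 20×20 matrix indexed (MHC residue, TCR
residue); "symmetrized" means M + Mᵀ. For comparison against the potential
matrix, negative potentials are mapped to 0 (`relu_normalize`), since
negative contact counts cannot exist. Group comparisons bin genes into
weak/moderate/strong by *rank* tertiles of their mean potential (tie-robust
and deterministic) and use a two-sided label-shuffling permutation test on
the difference of means with `p = (1 + #{|Δperm| ≥ |Δobs|})/(1 + n_perm)`
(default n_perm = 10,000, seeded); bins with fewer than two members are
skipped with a warning.

## Synthetic data

The repertoire generator draws each column independently from a fixed
residue, a uniform-within-class draw, or an explicit probability vector,
with optional per-region length variation (central trimming, mirroring the
encoder), and emits the exact per-column distributions it used. Paired
generation plants covariation between a TCR column and an MHC column
through a residue bijection obeyed with a configurable probability:
obedience 1 over k equiprobable symbols has ground-truth MI log₂ k;
obedience 0 leaves the columns independent. The toy-complex generator
places each planted atom pair at its prescribed distance on a 30 Å-spaced
linear scaffold (four backbone atoms per residue plus the planted atom),
so no unplanted pair can fall within any cutoff and the expected contact
list is exact; geometric conflicts (one atom at two distances) are
rejected. Same seed ⇒ byte-identical FASTA/PDB output.

What the synthetic data does *not* emulate: phylogenetic correlation
between sequences, realistic positional dependence within a loop, codon- or
recombination-level structure, sidechain geometry, or crystal-structure
artifacts (redundant deposits, missing density). Tests passing on synthetic
data therefore establish the correctness of the computations, not the
biological conclusions one would draw on real IMGT/IPD data.

## Numerical choices and problem sizes

- log base 2 everywhere; entropies of empty/singleton samples defined as 0.
- MI is computed from joint counts as H(X)+H(Y)−H(X,Y), algebraically equal
  to H(X)−H(X|Y) on the same sample and numerically non-negative up to
  rounding.
- z-normalization uses the population std (ddof = 0) over 20 values.
- Permutation p-values use the add-one estimator, never exactly zero.
- Tertile binning is by stable rank, so heavy ties still yield three
  near-equal bins.
- The test suite uses deliberately small problem sizes chosen for tight
  closed-form checks: 6-row exhaustive subsampling oracles, 200 random
  loop/helix pairs of length 3–10 against a brute-force enumerator, n =
  5000 sequences for MI recovery (tolerance 0.02 bits), 1000 null
  simulations × 2000 permutations for calibration of the permutation test,
  and toy complexes with ≤ 24 planted/decoy pairs.

## Known limitations

- The potential scores sidechain compatibility only; backbone-mediated
  contacts, geometry, peptide and CDR3 contributions are out of scope.
- Region position lists are conventions applied to reference numbering;
  misnumbered inputs silently extract the wrong residues.
- The interaction ruleset ships as one default ("version 2"-style class
  rules); alternative published revisions can be supplied as CSV overrides
  but are not bundled.
- MI estimates carry finite-sample bias (documented bound above); with few
  sequences, nonzero MI should be compared against that floor before
  interpretation.
- Contact extraction assumes standard PDB atom nomenclature; nonstandard
  residues are classed by atom-name heuristics with warnings.
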