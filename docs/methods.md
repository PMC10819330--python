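# Methods

## Scope and data model

The package post-processes molecular-docking results for a panel of
α-amylase inhibitory peptides. It does not dock: it consumes either (a) the
bundled reference tables for a published panel of 20 food-derived peptides
docked against porcine pancreatic α-amylase (PDB 1PIF), or (b) docked
complexes in PDB format, or (c) synthetic data from its own generators.

The core records are `Peptide` (sequence plus IC50 normalized to enzyme
activity, mmol/U), `HydrogenBond` (peptide id, 1-based position `n_i` from
the N-terminus, length `d_i` in Å, optional enzyme residue label) and
`InteractionRecord` (one peptide–enzyme-residue contact event).

## Activity normalization

IC50 values reported as concentrations are unified across assays as
`IC50[mmol/U] = IC50[mmol/L] × assay volume [L] / enzyme activity [U]`.
Downstream regression uses the negative logarithm. The log base is taken as
10 (pIC50 convention); it only rescales the response and has no effect on
VIP ranks or significance decisions.

## Side-chain classes

Residues are grouped as nonpolar {A,V,L,I,P,F,M,W}, polar uncharged
{G,S,T,C,Y,N,Q}, positively charged {K,R,H}, negatively charged {D,E}.
Cysteine is placed with the polar uncharged class: the reference peptide
panel contains 102 nonpolar residues after excluding C and Q, which is only
consistent if C is not counted as nonpolar. Non-standard residues (the
enzyme's N-terminal pyroglutamate, label `Pca1`) map to an explicit
UNCLASSIFIED bucket, are reported, and are excluded from class aggregation
by default (matching the reference class totals, which count 68 classified
residues out of 69).

## Contact and hydrogen-bond geometry

From a two-chain complex, heavy atoms are partitioned by chain; waters and
hydrogens are discarded. A hydrogen bond is any enzyme N/O to peptide N/O
pair with Euclidean distance ≤ 3.5 Å (boundary inclusive). This
distance-only criterion mirrors the "polar contacts" convention of
structure viewers; no donor/acceptor role assignment and no angle term is
applied, consistent with a definition in which 3.5 Å is purely a length
bound. A residue-level interaction is any heavy-atom pair within a cutoff,
default 4.0 Å (a common interface convention; the reference tables
themselves were produced by manual inspection, so fixture mode bypasses
this choice entirely). Peptide positions use the N→C rank within the chain,
not the author numbering.

## Per-residue metrics

* `IN`: count of peptides contacting an enzyme residue, one unit per
  peptide–residue pair.
* `HBV = Σᵢ D/dᵢ`, `D = 3.5 Å`, over a residue's bonds. Each term is ≥ 1,
  so `HBV ≥ bond count`; scaling all lengths by `c` divides HBV by `c`.
  Both facts are exercised as property tests.

Class summaries report residue count, metric total and mean. Group
comparison uses the Kruskal–Wallis rank test (midrank tie correction,
χ² reference with k−1 df, via scipy) followed by pairwise Dunn z-tests on
the pooled midranks with Bonferroni correction — the standard post hoc for
Kruskal–Wallis; no installed package provides it, so it is implemented
here, with the tie-corrected rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`.
Compact letters are assigned greedily on the non-significance graph in
order of decreasing group mean; redundant letters are absorbed.

Peptide-side aggregation keys on *per-residue entries* (one HBV per
hydrogen-bonding residue occurrence). Occurrence counts in the denominators
come from the peptide sequences, so residues that never bond still count —
this matches the reference table's stated convention. In `mode: paper`,
cysteine and glutamine (which never formed bonds in the panel) are excluded
from the denominators, reproducing the published 102/59/18/13 class counts;
`mode: default` includes all residues.

The bundled reference tables are transcribed verbatim, including a
duplicated proline entry and several internally inconsistent printed
summary cells. `report_flags()` recomputes every aggregate and lists each
printed cell that its own per-residue table cannot reproduce (six enzyme-side
cells and four peptide-side per-amino-acid cells); the flagged cells are
never force-matched. Notably the published peptide-side *class* totals do
match the entry-level sums, which is why entry-level aggregation is the
implemented path.

## Positional statistics

`R_N` and `F` are weighted means over a peptide's `m` bonds with the bond
lengths `d_i` as weights (longer bonds weigh more, as the definitions are
printed; a clearly marked non-standard `weighting="inverse"` switch is
available for sensitivity analysis). The `F` statistic uses
`c_i = L − n_i + 1` — the 1-based position from the C-terminus — which is
the unique reading that makes `F = 1` at both termini and reproduces the
panel's `F = 1.000` for the pentapeptide EAGVD with bonds at residues 1
and 5. Half-span is `(L−1)/2` for odd `L` and `(L−2)/2` for even `L`.
Peptides with no bonds have undefined statistics and are *omitted* (not
zero-filled) from panel summaries; the reference panel therefore has 19 of
20 peptides. Panel means are tested against 0.5 with a two-sided one-sample
t-test (two-sided as the conservative default; no directionality is
assumed).

Mirror symmetry (reversing all positions maps `R_N → 1 − R_N` and leaves
`F` unchanged), scale invariance in the weights, and the [0,1] range are
verified by derandomized property tests and a 1,000-case brute-force
oracle.

## Descriptors and TTPN encoding

The QSAR stage treats the descriptor set as an input. The bundled default
is built from 17 widely used amino-acid scales (3 hydrophobicity scales;
5 electrical: net charge at pH 7, isoelectric point, side-chain pKa,
Grantham polarity, polar requirement; 3 hydrogen-bond: side-chain donor,
acceptor and total site counts; 6 steric: residue mass, van der Waals
volume, heavy-atom count, Zimmerman bulkiness, rotatable bonds, side-chain
length). Missing entries (pKa of non-ionizable side chains) are imputed by
the per-parameter mean. Within each property class the parameters are
standardized across the 20 amino acids and decomposed by PCA; the top
components at quotas 2/4/2/5 (hydrophobic/electrical/hydrogen-bond/steric,
13 total) become the descriptors, each oriented so its loading on the
class's first parameter is non-negative (deterministic signs). Per-class
rather than global PCA keeps each descriptor interpretable as one property
class, which the NSIV summaries require.

TTPN encoding splices the first five and last five residues into a
decapeptide (for lengths 5–9 the overlap is taken verbatim in both
windows — the shortest panel peptide has L = 5) and expands each position
into the 13 descriptors: variable `V-k` is descriptor `d` of position `p`
with `k = 13(p−1) + d`, so `V-14` is descriptor 1 of position 2. Positions
1–5 are N-terminal slots N1–N5, positions 6–10 C-terminal slots C1–C5.

## PLS1, VIP, NSIV

The regression is single-response PLS (PLS1), NIPALS form with deflation of
X only: per component, `w ∝ Xᵀy` (unit norm), score `t = Xw`, X-loading
`p = Xᵀt/tᵀt`, y-loading `q = yᵀt/tᵀt`. X columns and y are autoscaled
(mean 0, variance 1, ddof 1) — required for VIP comparability across
descriptors on different scales. The algorithm is documented because
component *signs* differ between software conventions; VIP is
sign-invariant. Two components are the default, matching common practice
for panels of this size. The fit is cross-checked against scikit-learn's
`PLSRegression` in the test suite (predictions agree to 1e-8); the package
implementation, not the library, is what the pipeline runs.

`VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)` with `SS_a` the
y-variance explained by component `a`. The algebraic identity
mean(VIP²) = 1 holds to 1e-9 for every fitted model and is asserted in the
tests, so VIP > 1 marks above-average importance. Significant variables are
decoded back to (position, class) and counted (NSIV) per slot and per
property class, with class means dividing by the quota.

Because the 13 descriptors behind the published analysis of the reference
panel are not public, the package's descriptor set is its own documented
default: the panel fit (training R² = 0.958 with 2 components, 49
significant variables) is structurally, not numerically, comparable to any
particular published run.

## Synthetic data

Generators are pure functions of a frozen configuration (seed included;
independent substreams per stage). Defaults mirror the study conditions:
20 peptides, lengths uniform on 5–16, uniform residue composition, Poisson
bond counts with mean 3.3 (the reference panel's ~66 bonds over 20
peptides), bond lengths from a normal (mean 3.0 Å, SD 0.2) truncated to
(2.4, 3.5] — typical heavy-atom hydrogen-bond geometry. Bond positions are
drawn with probability ∝ exp(β·g(n)) where `g` is the same
terminal-proximity transform as `F`, so β targets `F` directly: β = 0 gives
the exact enumeration expectation (E[F] equals the unweighted positional
mean because lengths are independent of positions), and β = 10 drives the
panel mean above 0.95. The default β = 1 gives a modest terminal bias of
the kind the reference panel exhibits.

The QSAR generator plants a sparse linear model on the autoscaled TTPN
matrix: 5 support variables with unit effects of random sign and Gaussian
noise at 10% of the signal SD. The synthetic complex generator writes
two-chain PDB text with planted polar pairs at known distances (including
the 3.5 Å boundary) and carbon-only contact pairs inside the 4.0 Å cutoff,
spaced so no unplanned pair qualifies; waters and hydrogens are included to
exercise the parser's filters. None of this emulates real docking geometry
(no physical chain connectivity or rotamers), so passing extraction tests
demonstrates correctness of the geometry predicates, not realism of poses.

## Known limitations

* Support recovery at the study's own scale is information-limited: with 20
  samples, 130 variables and 5 equal planted effects, each active
  variable's population correlation with the response is bounded by
  1/√5 ≈ 0.45 while the 125 inactive variables' null correlations have
  SD ≈ 0.23, so a handful of inactive variables is *expected* to outrank
  the weakest active one. The suite documents this: complete top-10
  recovery is demonstrated at n = 60, and at n = 20 only strong enrichment
  of the support among high VIP ranks is asserted. One acceptance test
  states the n = 20 top-10 recovery property literally and fails by
  design; it is retained as an honest negative result.
* The hydrogen-bond criterion is distance-only; angle-aware definitions
  will disagree on borderline pairs.
* Report-table rounding is decimal half-up to two places, applied at
  presentation only; internal values keep full precision.
* The compact-letter display depends on the post-hoc procedure; other
  post hocs (Conover, Nemenyi) may letter borderline classes differently.
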