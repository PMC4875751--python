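# Methods

This package implements a comparative-signature workflow for protein
families whose members play different regulatory roles in different
lineages — the motivating case is the transcription factor Lrp, a global
regulator (hundreds of target genes) in Enterobacteriales and Vibrionales
but a local regulator in Pasteurellales, with its role untested in
Alteromonadales, contrasted against its consistently local paralog AsnC.
The workflow is: multiple alignment → JTT/neighbor-joining phylogenetics
with bootstrap → per-group conservation logos → two-sample residue
enrichment → signature-segment extraction → signature-based prediction of
the regulatory role of unlabeled orthologs.  A seeded synthetic-data
generator provides families with known (planted) truth so that every stage
is testable without downloads.

## Coordinates and alphabets

All alignment positions are 1-based, ranges inclusive; a reported residue
like D14 means "aspartate at master-alignment column 14".  The residue
alphabet is the 20 standard amino acids plus `X`, which is accepted on
input but treated as missing data (excluded from every count).
Selenocysteine and pyrrolysine letters are rejected rather than silently
remapped.  Gap (`-`) is never part of an ungapped sequence; in the
two-sample test it is deliberately a 21st testable symbol (see below).

## Substitution model

The evolutionary model throughout is the Jones–Taylor–Thornton (JTT)
empirical amino-acid model: a reversible CTMC with rate matrix
Q_ij = s_ij·π_j built from the published exchangeabilities `s` and
equilibrium frequencies π, normalised to one expected substitution per
site per unit time.  Transition matrices P(t) = exp(Qt) are computed from
the symmetric eigendecomposition of D^{1/2} Q D^{-1/2} (exact for a
reversible chain), which makes the thousands of P(t) evaluations in
distance optimisation and bootstrap cheap; the implementation is verified
against `scipy.linalg.expm` to 1e-10.

## Alignment

Pairwise alignment is affine-gap global alignment (Gotoh), BLOSUM62 with
gap open −10 / extend −0.5, with terminal gaps penalised: presence or
absence of N/C-terminal tails is biological signal in this analysis and
free end gaps would hide it.  Percent identity uses the denominator
"columns with residues in both rows" (not alignment length), the closest
match to how identity is conventionally reported; because published
identity figures for this family came from unspecified aligners, a ±2
point tolerance is appropriate when comparing to them.

The multiple aligner is a deliberately simple progressive scheme — 3-mer
distance, UPGMA guide tree, profile–profile affine alignment in postorder
— so the pipeline needs no external binary; a `--prealigned` flag accepts
any externally produced alignment and is the recommended route when
reproducing published figures.  The built-in aligner is cross-checked in
the test suite against MAFFT on low-divergence families.

External queries are mapped into master-alignment coordinates through a
pairwise alignment with a designated anchor row (composition through the
anchor's gap pattern).  When a query is itself a row of the master
alignment, its states are read directly off that row — this is how
signature positions are scored for sequences already in the study
alignment, and it is exact.  Anchor-relative mapping degrades with
divergence; at ≤70% identity to the anchor it is reliable, and the
role classifier flags gap-dominated mappings as low-confidence.

## Distances, trees, support

Pairwise distances are maximum-likelihood under JTT: t maximising
Σ_sites log[π_a P(t)_{ab}] over shared non-gap columns, by bounded scalar
optimisation on (0, 10] (xatol 1e-8).  Saturated pairs return t_max = 10
with a warning instead of infinity.  Gapped columns are handled by
pairwise deletion by default; complete deletion is a flag, since published
analyses often do not state which was used.  Identical sequences
short-circuit to distance 0.

Trees are built by Saitou–Nei neighbor joining with deterministic
label-order tie-breaking; negative branch lengths are clamped to zero with
the deficit shifted to the sister edge so the joined pair's path length is
preserved.  The implementation is validated against an additive-matrix
closed form and against scikit-bio's NJ on random matrices.  This
distance+NJ pipeline is a documented surrogate for a full ML topology
search: the analyses it feeds are topology- and coherence-level (does a
group form one side of a bipartition), not branch-length-level.

Bootstrap support is the standard nonparametric column bootstrap: resample
columns with replacement, rebuild the tree, and score each internal edge
of the full-data tree by the percentage of replicates containing the same
leaf bipartition.  Replicates whose resampled columns leave some pair with
no shared residues are redrawn (with a warning).  Support is written as
internal node labels in Newick.  `collapse_low_support` contracts edges
below a threshold (70% in the study convention), and `clade_coherence`
asks whether a labeled group forms one side of some bipartition —
unrooted monophyly, the "single cluster" criterion.

## Conservation logos

Per column and group: residue counts over non-gap, non-X symbols,
frequencies f, Shannon entropy H = −Σ f·log2 f, and information content
IC = max(0, log2 20 − H − e_n) with the asymptotic small-sample correction
e_n = 19/(2·ln 2·n).  Letter heights f·IC stack to the column IC.  The
correction is a flag (both conventions appear in published logos); closed
forms for both modes are pinned in tests, e.g. a pure column at n = 10
gives 4.3219 − 1.3705 = 2.9514 bits.  Gaps are excluded from the
denominator, and columns with >50% gaps are flagged so terminal-tail
regions read as low-support rather than spuriously conserved.  Logos are
exported as tidy per-position/per-residue height tables; graphics are left
to any plotting layer.

## Two-sample enrichment

For every (column, symbol) with nonzero count in either group, the 2×2
presence/absence × group table is tested with Fisher's exact test,
two-sided.  The original two-sample-logo web tool uses a t-test on binary
indicators; Fisher is exact, deterministic, and valid at the n = 10–20 per
group this design has, so it is the default, with the t-test behind a flag
for fidelity comparisons.  The gap symbol is testable on purpose: the
shorter N-termini of locally-acting orthologs appear as significant gap
enrichment at tail columns.  Multiple testing is uncorrected by default
(mirroring the web tool) with Bonferroni as the recommended mode; the
familywise error under Bonferroni and the conservativeness of the per-cell
rate are both measured empirically by `null_calibration`, which draws both
groups from one shared Dirichlet(0.5) column distribution.

`diagnostic_positions` operationalises the "X > Y" notation: positions
where a residue is significantly enriched in group A with f_A ≥ 0.7 and
f_B ≤ 0.3, with the other group's consensus attached.

## Signature segments and role classification

Columns are classified against a focal group: uppercase = focal consensus
frequency ≥ θ_cons (0.9) and that residue's frequency in the other group
≤ θ_disc (0.2); lowercase = focal-conserved but shared; `*` = wildcard.
Segments are maximal stretches with no two consecutive wildcards, trimmed
to conserved ends, containing ≥ min_len (6) conserved and ≥ 1
discriminative position, ordered by discriminative count so the first
segment is the most family-specific.  Segment boundaries are
threshold-sensitive and anchor-relative; the defaults are fixed and
documented rather than tuned per dataset.

The role classifier ships with an 8-position scheme for Lrp
(D14>A, N21>K, E36>D, R40>K, F60>V, F80>V, S128>A, D/E136>T; position 136
accepts D or E in the global set, exactly as the notation reads).  The
scheme is expressed in anchor-sequence residue coordinates (anchor:
*E. coli* Lrp, whose full N-tail makes its residue numbering coincide with
the master columns) so it survives alignment-column drift between
aligners; master-column coordinates are a flag.  A query is called global
or local on a 0.75 supermajority of scheme positions, otherwise ambiguous;
queries mapping to gaps at more than half the positions are flagged
low-confidence and left ambiguous.  Terminal evidence (N-tail coverage of
columns 1–21, identity to the C-terminal LVIKTR block) is reported
alongside but does not enter the call — in this family the termini and the
signature residues can genuinely disagree, and the call should say so.

## Synthetic data

`simulate_family` emulates the study design: orders are ultrametric Yule
clades (a final exponential hold time keeps cherry edges strictly
positive) scaled to half the configured tree height, joined by a balanced
binary backbone of fixed-length edges; root sequence drawn from π;
residues evolved by P(t) along each branch (optional 4-category discrete
gamma rates).  Defaults are the study conditions: 4 orders × 10 species,
171 columns, root-to-tip height 0.5 substitutions/site, planted
role-diagnostic columns {14, 21, 36, 40, 60, 80, 128, 136} carrying the
global/local residues above with retention 0.95 per sequence, a conserved
N-tail (columns 1–12) and C-terminal LVIKTR block (159–164) present only
in the globally-acting orders, and shorter/variable termini (gap fray) in
the local order — the fray never reaches the first planted column, since
locally-acting orthologs carry residues at the diagnostic positions
themselves.  The fourth ("unknown") order is planted global by default,
mirroring the prediction the real analysis reaches for its best-conserved
member.  `simulate_paralog_pair` joins two such families below a deep
duplication and plants distinct 19-column family-identifying blocks
(columns 106–124) at retention 0.98 — family-diagnostic blocks are
near-invariant within a family; planting them at the conservation
threshold itself would make the planted truth only marginally a signature
by the package's own definition.  `simulate_planted_columns` generates
tree-free groups: iid shared-Dirichlet columns plus the planted scheme.

What the generator does not model: internal indels (gaps occur only as
terminal-tail structure, so the generator knows the true master alignment
exactly), horizontal transfer, codon-level effects, site-specific rate
conservation beyond the optional gamma, and real taxonomic tree shape.
Consequently, passing tests show the statistics behave correctly under
the assumed signal/noise model — not that a real alignment of real
orthologs is free of alignment error or rate heterogeneity artefacts.

## Verification experiments and their design

Three simulation experiments back the acceptance checks, with sizes chosen
to keep the full suite fast:

- **Detector calibration and planted recovery** (tree-free): 20-vs-10
  groups, 171 columns; 10×1000 null positions for calibration; 50 seeds
  for recovery of the 8 planted positions.  The planted-truth experiment
  is run on `simulate_planted_columns` rather than tree-evolved families
  deliberately: in a tree-evolved family, columns fixed differently by
  drift along the deep split are *genuinely* group-separating and the
  detector correctly reports them — as the real analysis does, treating
  all candidates as testable hypotheses that "may simply reflect
  divergence".  Against iid background, planted truth is the complete
  truth, so spurious calls can be required to be zero.
- **Held-out classification**: 25 seeds × full 4×10 families; the
  unknown-order members are scored against the planted scheme read off
  the master alignment; accuracy is summarised as a median over seeds
  because at retention 0.95 a query occasionally carries only 5/8 planted
  residues, for which "ambiguous" is the correct call.
- **Topology recovery**: 100 replicates of 12-taxon neutral families
  built as 6 clades × 2 species, a design whose internal edges all have
  the fixed backbone length and are therefore resolvable at 171 columns.
  With random Yule cherries (e.g. 4 clades × 3 species) some true internal
  edges carry ~0–2 expected substitutions across the whole alignment and
  no estimator can recover them; measured recovery in that regime is
  ~80%, an information limit of the data length, not an estimator defect.
  Paralog-pair coherence uses 100 replicates of 2×(2×5) families.

## Reproducibility

Every stochastic component takes an explicit seed (NumPy `default_rng`);
the pipeline writes artifacts with sha256 checksums and its summary JSON
is byte-identical across re-runs of the same config and seed.  The
published trees and logos this workflow parallels are **not
bit-reproducible** from their description — the original aligner choice,
tree-search settings, and the visual thresholding of logo figures are
unstated — so acceptance for those results is property-based (cluster
coherence, planted-signal recovery, calibration, closed forms) rather
than figure-for-figure equality.  The real-sequence worked example
(91%/68% identity, 8/8 vs 2/8 signature matches) requires a one-time
accession download (`ortho-signature fetch`); it is the only
network-dependent check in the repository.

## Known limitations

- The progressive aligner is adequate for the ~70%-identity regime of
  this family but is not a general-purpose MSA tool; use `--prealigned`
  with a production aligner for new datasets.
- Anchor-based query mapping loses query residues that fall in insertions
  relative to the anchor, and degrades below ~50% identity to the anchor.
- NJ on ML distances does not search topology space; very short internal
  edges resolvable by full ML may be missed.
- Fisher's exact test treats sequences as exchangeable; phylogenetic
  autocorrelation inflates apparent group differences in real data, which
  is why diagnostic positions are candidates for experimental test, not
  conclusions.
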