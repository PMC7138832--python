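# Methods

This note documents the models, numerical choices and limitations behind
`methylsite`, in the package's own terms.

## Problem setting and data model

A methylation site is a lysine (K) or arginine (R) whose side-chain
nitrogen(s) carry one or more methyl groups; lysine admits mono-, di- and
tri-methylation, arginine only mono- and di-. Annotations are 1-based
positions on the protein sequence, each with a *set* of type labels (a site
can be observed in more than one methylation state; type models are trained
one-vs-rest over these overlapping labels). Negative examples are target
residues on the same proteins with no methylation annotation, sampled
uniformly without replacement at a 1:1 ratio against the positives —
functional-site corpora are heavily imbalanced, and 1:1 sampling keeps the
SVM's operating point interpretable. Train/test splitting is done at the
protein level (never the site level) so homologous windows cannot leak
across the split.

The padding/unknown character is 'X' throughout; every encoder treats it
explicitly (zero similarity, zero property value, excluded from
compositions), which makes terminal windows well defined without special
cases.

## Feature subtypes

**LC** (dim 3) — relative location `[p/L, (p−1)/L, (L−p)/L]` of position
*p* in a chain of length *L*.

**PWAA** (dim 20) — for window half-width *L*:
`C(a) = (1/(L(L+1))) Σ_i x_i(a)(i + |i|/L)` over offsets `i = −L..L`.
Downstream occurrences of a residue add, upstream occurrences subtract, so
asymmetric compositional bias (e.g. lysine enrichment downstream of
methyllysine) maps onto single coordinates.

**EBGW** (dim 3·L_seg, default L_seg = 5) — amino acids fall into nonpolar,
polar-uncharged, positively and negatively charged groups; three binary
profiles (nonpolar∪polar, nonpolar∪positive, nonpolar∪negative) are
summarised as ones-densities over nested prefixes of length
`round(j·w/L_seg)`. A prefix of rounded length 0 contributes 0.

**CKSAAP** (dim 441 per spacing, default k = 0..5) — normalised counts of
ordered pairs `(window[i], window[i+k+1])` over the 21-letter alphabet
(including 'X', so terminal windows encode); each k-block sums to exactly 1
by construction.

**KNN** (dim |K-set|, default K ∈ {2,4,8,16,32}) — fraction of positives
among the K nearest training windows under the distance
`1 − (1/w) Σ sim(a_i, b_i)`, with `sim` = BLOSUM62 min-max rescaled to
[0, 1] and `sim(·, 'X') = 0`. Ties break by reference insertion order.
When the training matrix itself is encoded, each window's own exact match
is skipped once (`exclude_self`) — otherwise every training instance would
see its own label and cross-validation accuracy would be inflated.

**AAindex** (dim w·n_props) — each bundled physicochemical property
(hydropathy, polarity, residue volume by default; any AAindex-style table
can be supplied) is z-normalised over the 20 amino acids; 'X' → 0.

**Profile subtypes** (SS, seqRSA, Disorder, seqHSE, PSSM, HH) — parsed from
third-party per-residue files, never computed here: PSI-BLAST ASCII PSSM
log-odds through `s(x) = 1/(1+e^{−x})`; PSIPRED `.ss2` state probabilities
verbatim; generic idx/letter/value tables for disorder (1 channel),
SPINE-X RSA+torsions (3 channels, angles scaled by 1/180) and predicted HSE
(2 channels); HHsuite `.hhm` 20 emission + 10 transition scores decoded as
`2^{−x/1000}` with '*' → 0. All transforms land in [0, 1]. Window slices
pad out-of-chain rows with zeros.

**Structure subtypes** (CHOPS, strHSE, Depth, strRSA) — computed from PDB
coordinates reduced to heavy atoms with per-element van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å, default 1.70):

* *CHOPS*: iterative convex-hull peeling of all heavy atoms; hull vertices
  get the current layer (1 = surface), are removed, and peeling repeats.
  Fewer than 4 remaining points, affine degeneracy, or a Qhull failure
  terminates peeling with one final layer, making the function total. The
  residue value is the layer of the methyl-accepting nitrogen (NZ for Lys,
  min over NH1/NH2 for Arg; CA fallback otherwise) — the same atoms the
  structure-dataset filter requires.
* *strHSE*: C-alpha neighbours within radius r (default 5..30 Å) split at
  the plane normal to the "up" direction — CA→CB for B-variants (glycine
  uses the pseudo-CB `(CA−CAprev)+(CA−CAnext)`, which is also the A-variant
  direction), counting Up (AU/BU) or Down (AD/BD). Chain-terminal residues
  use the single available difference vector; an isolated residue has no
  definable direction and errors.
* *Depth*: distance to the solvent-accessible surface. Predicted models
  contain no waters, so the accessible-surface point cloud (sphere points
  at vdW+probe kept iff outside every other atom's expanded sphere) stands
  in for "nearest surface water" — an analytically testable, MSMS-free
  proxy. Atom depth uses the key side-chain atom (NH1/NH2 midpoint for
  Arg); residue depth averages per-atom minimum distances. L1 depth is
  `1 − ‖mean unit vector to neighbours within r‖` (1 = centrally
  surrounded, →0 = peripheral); an empty neighbour set is reported as NaN
  and imputed as 0 (the peripheral limit) in feature vectors.
* *strRSA*: Shrake–Rupley SASA (kept point fraction × sphere area at
  vdW+probe, probe 1.4 Å, 960 points/atom by default) divided by the
  residue's reference area in an extended Ala-X-Ala tripeptide. The
  reference table is computed on first use *with the same reduced-atom
  builder and the same SASA routine*, so RSA ≈ 1 for extended conformations
  by construction; an external NACCESS-style table can be loaded instead.
  Side-chain RSA excludes N/CA/C/O/OXT.

Structure blocks attach to the centre residue only (they are not windowed):
the descriptors are properties of the site's local 3D neighbourhood, not of
the sequence window. Structures are matched to sequences either by assuming
`res_seq` = sequence position (true for the synthetic generator) or through
a global alignment (match 1, mismatch 0, gap −1) with a 30% identity floor.

**Missing-input policy** — every profile and structure block carries one
trailing flag dimension: 0 when computed, 1 (with zeroed values) when the
source file is absent. The pipeline therefore trains and predicts with any
subset of inputs present, at fixed dimensionality.

## Selection and the two-level network

Per subtype, features are ranked by |Pearson correlation| with the binary
labels (defined as 0 for constant vectors) and selected greedily: the top
feature is always kept; each further candidate joins only if stratified
5-fold CV accuracy of a standardised RBF SVM *strictly* increases, making
the accepted-step accuracy trace strictly increasing by construction. The
strict rule (rather than ≥) avoids accumulating redundant features on ties.
For very wide subtypes the scan is capped at the top `max_candidates`
(default 40) ranked features — the accuracy plateau is reached long before
that on every dataset we generate, and the cap keeps training inside
minutes on one CPU.

The selected columns of all subtypes are concatenated, standardised (means
and variances frozen from the training set — RBF kernels are scale
sensitive), and (C, γ) are chosen by exhaustive stratified-CV accuracy over
the classic log2 grid C = 2⁻⁵..2¹⁵, γ = 2⁻¹⁵..2³ in steps of 2²; ties break
toward smaller C then smaller γ (the simpler model). Probabilities come
from Platt scaling fitted inside cross-validation
(`CalibratedClassifierCV(SVC(), method="sigmoid", ensemble=False)`).

Level 1 (site model) trains on all positives vs 1:1 sampled negatives at
its task window (default 17). Level 2 trains one binary one-vs-rest model
per methylation type on the *methylated* instances only (default windows:
mono 23/17, di 17/19, tri 21 for K/R respectively); a type with fewer
positives (or negatives) than CV folds is skipped with a warning. At
prediction time the type models are consulted only when the site
probability reaches the 0.5 threshold; the two levels are otherwise
independent (level 2 does not consume level-1 outputs as features).
Window-size scanning (`scan_window_sizes`, sizes 9..23) re-fits the full
encode→select→grid pipeline per size and breaks accuracy ties toward the
smaller window. All randomness (fold assignment, negative sampling,
calibration splits) derives from explicit seeds; training is bit-reproducible.

## Evaluation statistics

Threshold metrics follow the standard confusion-table forms; any zero
denominator propagates as NaN and is rendered as the string "Nan" in
reports (e.g. precision when no positives are predicted). CPRE
`= SEN/(SEN + r(1−SPE))` defaults r to the evaluated set's own
negative:positive ratio, under which CPRE reduces *exactly* to PRE — the
safe default when the deployment prevalence is unknown. ROC AUC is the
tie-aware concordance probability; PR AUC uses step-rule integration
(average precision), not trapezoids.

Group comparisons gate on Shapiro–Wilk normality at the same α (paired
comparisons gate on the differences): normal-looking data get Student's
t-test, otherwise Wilcoxon — signed-rank for paired data, rank-sum for
independent groups (the paired/independent distinction is resolved by the
caller; applying a signed-rank test to independent groups would be
invalid). A one-tailed test runs only after a significant two-tailed one,
in the direction of the means (t) or rank sums (Wilcoxon). Identical
paired samples return p = 1; a constant non-zero paired shift has zero
variance and is reported as a degenerate, trivially significant t result.

Compositional bias between positive and negative site windows (41 residues
in the standard logo convention) is tested per (position, amino acid) cell
with a two-proportion test — Fisher's exact when any expected count is
below 5, else the pooled normal approximation — Bonferroni-corrected over
all 40×20 cells; padding characters are excluded from counts.

## Synthetic data: what it emulates, and what it does not

The sequence generator plants candidate K/R sites (three per protein,
spaced ≥ 11 residues, in 60–100-residue proteins) and methylates each with
probability 0.5; flanks of methylated sites are re-drawn from
motif-tilted frequencies. The default motif mirrors the compositional
biases reported around real methylation sites — for lysine, K enriched
downstream (+1..+5) and G upstream (−5..−1); for arginine, G/R-rich
context — with a ×10 frequency tilt chosen so that an ideal observer
separates classes with ~0.95 AUC. The background is uniform over the 20
amino acids by default (sharper planted-effect tests; a natural-frequency
mode exists). Types are drawn from a configurable mixture
(mono .5 / di .3 / tri .2 for K).

One consequence of this (realistic) motif design is worth stating: because
the enriched flank letter *is* the target residue, methylated sites create
unannotated lysines right next to them, and uniform negative sampling
picks those up as hard negatives. An oracle classifier given the exact
planted counts reaches only ≈ 0.83 held-out accuracy on such data; the SVM
pipeline, using wider context, reaches ≈ 0.86 at its best threshold and
0.82–0.87 at the fixed 0.5 threshold depending on the realization, with
held-out AUC 0.91–0.93 from sequence features alone. Numbers at this level
therefore indicate near-ceiling recovery, not a deficient model.

The toy structure generator winds the chain into a tight multi-turn coil
(3.8 Å CA spacing, ≈ 3.6 Å between turns) so the wall is dense; exposed
targets point their side-chain nitrogen 4.5 Å radially outward (first
convex hull by construction), buried targets tuck it against the nearest
non-adjacent backbone atom (occluded, interior hull layers, low RSA). With
structure signal s, a residue's burial matches its label with probability
0.5 + s/2 (default s = 0.9). Adding structure features raises held-out AUC
by ≈ 0.05–0.08 under these defaults — the synthetic analogue of the
sequence → sequence+structure improvement the method is designed to
exploit. The generator favours geometric verifiability over physical
realism: bond geometry is idealised, side chains are reduced to a single
tip atom, and no packing or secondary-structure realism is attempted.
Mock profile files are random draws in the correct dialects — they carry
*no* signal and exist to exercise parsers and missing-input behaviour.

Passing recovery tests on these data shows the pipeline's machinery is
correct and sensitive to planted signal of realistic shape; it does not
certify real-data performance, which depends on annotation quality,
homology structure, and the fidelity of third-party profiles and predicted
structure models.

## Numerical choices and problem sizes

* Geometry: probe 1.4 Å; 960 sphere points/atom for analytic-accuracy
  contexts, 96–192 in large pipeline runs (SASA resolution 1/n_sphere);
  HSE/L1 radii 5..30 Å in 5 Å steps; neighbour tests use ≤ with strict
  dot-product > 0 for the "up" half-sphere.
* Degenerate inputs: constant feature vectors get PCC 0; an all-identical
  feature matrix is rejected before grid search; hull peeling terminates on
  degeneracy as above.
* The end-to-end benchmark uses 400 proteins, an 80/20 protein split,
  max_candidates 40 and 96 sphere points; the statistics calibrations use
  2000 null replicates (gated test) and 300–500 replicates on a reduced
  9-residue grid (composition bias). These sizes keep the full benchmark
  suite within roughly ten minutes on a single CPU while leaving the
  measured properties stable.
* Model archives serialise the fitted network with joblib plus a JSON
  manifest (schema-versioned; windows, selected columns, SVM parameters).

## Known limitations

* The stepwise rule is greedy and order-dependent; it makes no claim of
  optimal subset selection.
* RSA reference areas are self-consistent with the reduced-atom model; for
  full-atom experimental structures an external NACCESS-style table should
  be supplied.
* Arginine tri-methylation is structurally impossible and rejected at the
  data-model level, not merely unmodelled.
* The KNN feature ties each trained model to its reference windows; model
  archives therefore embed the training windows.
* CHOPS layer indices are unbounded above; they enter the SVM after
  standardisation, but extremely large structures will compress layer
  contrast.
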