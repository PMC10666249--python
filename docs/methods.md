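# Methods

## Curation model

Raw records carry an identifier, a SMILES string, an IC50 magnitude, a
concentration unit and a relation qualifier. A record survives cleansing
only if the SMILES parses, the value is present and positive, the unit is
a recognized molar concentration (nM, uM, M) and the relation is an exact
measurement (`=`); censored values (`<`, `>`) are discarded because they
bound rather than measure potency. Potency is expressed as
pIC50 = −log10(IC50 in molar). Duplicate structures (equal canonical
SMILES after RDKit canonicalization) collapse to a single compound; the
default policy keeps the record with the lexicographically smallest id,
which makes the result independent of input order. An alternative policy
(median pIC50 over replicates) is available behind a flag; which of the
two better reflects upstream practice is unknowable from a cleansed
export, so determinism decided the default.

Class boundaries: **active** strictly above pIC50 8, **inactive** strictly
below 6, **intermediate** the closed interval [6, 8]. The strict upper
boundary is a convention choice (a config flag flips active to ≥ 8); the
boundary compounds it affects are rare in practice but the convention is
applied consistently everywhere a threshold appears (classing, scaffold
favorability).

## Descriptors and fingerprints

Exploratory analysis uses eight interpretable descriptors: molecular
weight, Crippen LogP, hydrogen-bond acceptors and donors (Lipinski
definitions), rotatable bonds, topological polar surface area, heteroatom
count and aromatic-ring count. Modelling uses RDKit's full 2D descriptor
list (~210 descriptors). 3D descriptors would require a conformer
protocol and are deliberately excluded: without a fixed embedding they
are not reproducible. Molecules are recanonicalized before any descriptor
call so that atom-contribution sums (LogP, TPSA) are bit-identical across
SMILES spellings of the same structure. Columns that are non-finite for
any compound are dropped dataset-wide rather than imputed — imputation
would invent chemistry.

The pairwise-similarity fingerprint is a 512-entry substructure
dictionary: bit *i* is set iff SMARTS fragment *i* matches the molecule.
The dictionary is a deterministic enumeration of element primitives,
bonded pairs, short element paths, functional groups, ring systems,
branching motifs and element-pair distance patterns, frozen as a packaged
text file so bit assignments never drift. All fragments are defined on
heavy-atom connectivity except a small set of pharmacophoric groups with
explicit hydrogen counts (alcohols, amines, acids); for the
connectivity-only fragments the fingerprint is monotone under
superstructure containment. Tanimoto similarity is |A∩B|/|A∪B|, defined
as 1 when both fingerprints are empty (two featureless molecules are not
evidence of dissimilarity).

## EDA statistics

Descriptive summaries use linear-interpolation quartiles, the n−1 sample
standard deviation, adjusted Fisher–Pearson skewness and excess kurtosis
(the most common reporting conventions). Input is sorted before
accumulation so the summary is exactly permutation-invariant.

Between-class location differences use the Mann–Whitney *U* test by
default — the descriptor distributions are markedly non-normal — with
Student's *t* available as an option. The two-sided exact p-value is
obtained by enumerating all C(n, n_a) group assignments of the pooled
midranks (valid under ties) whenever that count is at most 200,000,
otherwise the tie-corrected normal approximation is used. The exact
branch therefore covers every group-size combination up to well beyond
6 + 6; the enumeration cutoff trades runtime against exactness and is not
a statistical tuning parameter.

PCA is computed on column-standardized (z-scored) data, i.e. on the
correlation matrix: the eight descriptors live on incommensurate scales
and without standardization molecular weight would dominate every
component. Zero-variance columns are dropped with a warning. Components
are ordered by decreasing eigenvalue and each loading vector is signed so
its largest-magnitude entry is positive, which fixes the eigenvector sign
ambiguity deterministically.

## Scaffold analysis

Murcko scaffolds (ring systems plus connecting linkers, terminal side
chains removed) and cyclic skeletons (every atom → carbon, every bond →
single) are extracted with RDKit and canonicalized so identical scaffolds
compare equal as strings. Acyclic molecules have no scaffold: they count
toward N but not toward Ns/Ncsk, and their count is reported separately.
Diversity ratios are reported rounded to three decimals with the raw
quotients retained. Frequency ranking breaks ties lexicographically. The
prevalent subset keeps compounds whose scaffold occurs at least 10 times
(configurable); a scaffold is *favorable* when any member exceeds the
active threshold.

## SALI and cliff networks

SALI = |ΔpIC50| / (1 − sim). Structurally identical pairs (sim = 1) make
the quotient singular; they are reported at a configurable ceiling (10⁶)
with an explicit capped flag — the pathology (same structure, different
measured potency) is worth surfacing, not hiding. Cliff detection offers
a SALI threshold and a top-fraction mode (default: top 1% of edges by
SALI, ties toward the lower canonical pair id); the field has no single
agreed cutoff, so both are explicit parameters. Networks keep nodes
annotated with pIC50 and scaffold frequency and round-trip through
GraphML.

## QSAR modelling

Features with sample variance below 0.1 (unscaled) are dropped, then a
greedy left-to-right scan drops any column whose |Pearson r| with an
earlier retained column exceeds 0.95 — keeping the earlier column makes
the trace reproducible. SMOTE is implemented directly: each minority
class is filled to the majority count with convex combinations
x_i + u(x_j − x_i) of a random member and one of its k ≤ 5 nearest
same-class neighbors; original rows are never modified. Splitting is
stratified (80:20 for the full set, 75:25 for the prevalent subset) and
seeded; the project-wide default seed is 42.

Two balancing orders are provided. The default balances the whole set and
then splits, matching the study design this package reproduces; note that
this leaks interpolated points into the test set, so the honest
alternative — split first, balance the training portion only — is also
implemented and recommended for real model assessment.

Classification is one-vs-rest with six algorithm families (extra trees,
random forest, LightGBM, XGBoost, MLP, Gaussian process), all behind one
seeded, z-scaled fitting path. Gaussian-process training is cubic in
rows, so it subsamples to 600 training rows (seeded) when given more.
Validation reports accuracy, macro-averaged recall and the multiclass
(Gorodkin) Matthews correlation computed from the full confusion grid;
the binary case reduces to the familiar TP/TN/FP/FN closed form, which
the tests verify against an independent implementation. Cross-validation
is stratified 10-fold (auto-reduced when the smallest class is smaller
than k).

## Applicability domain

One mechanism, two gates. The scaffold gate accepts a query only when its
Murcko scaffold is in the training whitelist (the prevalent-scaffold
configuration). The box gate projects the query onto a PCA fitted on the
standardized training features (2 components by default, configurable)
and requires every score to lie in the closed [min, max] interval of the
training scores; intervals are closed, with a ~1e−9 relative float guard,
so training extremes are in-domain by construction. Out-of-domain
predictions abstain and name each failed gate. Distance- and
density-based AD variants are out of scope.

## Synthetic data generator

The generator emulates the statistical shape of a curated ACE-inhibitor
extraction, not its chemistry. Molecules are scaffold templates decorated
with a frozen 14-entry substituent vocabulary (halogens, small alkyls,
hydroxy, methoxy, amino, nitrile, trifluoromethyl, carboxy, carbamoyl)
carrying signed activity effects of ±0.05–0.8 pIC50 units — the size of
typical substituent effects in lead series. True pIC50 is scaffold base +
substituent effects + N(0, noise_sd) with noise_sd defaulting to 0.1
(assay-repeatability scale); IC50 is emitted in nM as 10^(9 − pIC50) so
curation is exercised on realistic units.

The study-shaped dataset (`emulate_study_shape`) has 549 compounds: nine
prevalent scaffold templates with frequencies 40…10 (168 compounds) over
a 254-scaffold tail, class counts exactly 148 active / 247 intermediate /
154 inactive, and four planted cliffs with a pIC50 gap of 4.0. Exact
class counts are achieved by assigning classes first — ordered by
scaffold potency score so scaffold means stay class-correlated — and then
sampling pIC50 inside the class interval with a safety margin at the
boundaries; the counts are verified through the curation module rather
than asserted. Planted cliff pairs differ by a single methyl↔chloro swap,
which the fragment dictionary resolves (similarity ≈ 0.79–0.91) while
keeping the pair in one scaffold; the generator publishes each pair's
realized similarity and SALI as ground truth.

What the generator does **not** emulate: real substituent-effect
nonadditivity, assay heterogeneity across labs, salt/tautomer noise,
activity censoring, or the actual ACE pharmacophore. Passing tests
demonstrate that the pipeline's mechanics (counting, ranking, balancing,
flagging, gating, determinism) are correct, not that the models would
reach any particular accuracy on the real extraction.

## Problem sizes and numerical choices

The test suite and the end-to-end determinism check run the pipeline on
the full 549-compound synthetic set with a reduced model roster (extra
trees + LightGBM, 100 estimators, 5-fold CV) — large enough to exercise
every stage, small enough for a laptop-scale test run; the full
six-algorithm roster is a config change. Reported ratios are rounded to
three decimals only at the reporting boundary. All randomness flows from
a single integer seed; manifests record SHA-256 digests of every artifact
so reproducibility is checkable at the byte level (timings live only in
the manifest).

## Known limitations

* The 512-fragment dictionary is this package's own; it preserves the
  semantics of dictionary-based substructure fingerprints but no
  bit-compatibility with any desktop tool's proprietary dictionary.
* The descriptor block is RDKit's 2D set, not the ~1825-descriptor
  Mordred block; filtered feature sets therefore differ from ones derived
  with other descriptor engines.
* Salt stripping and tautomer standardization beyond canonicalization are
  out of scope for curation.
* Balance-then-split inflates external-validation metrics by design (see
  above); use `balance_mode="train_only"` for honest estimates.
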