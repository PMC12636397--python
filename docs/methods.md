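# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `hdcoop`.

## Coordinate and sequence conventions

A homeodomain is exactly 60 canonical residues, numbered 1–60 (N-terminal
arm 1–8, helix 1 9–25, helix 2 26–39, recognition helix 3 40–60). Domains
of any other length, gaps, and ambiguity codes are rejected rather than
imputed because the rule classifier and all frequency computations assume
complete canonical 60-mers. Conversion to full-protein coordinates is by an
explicit per-sequence offset (`hd_start_in_protein`), never inferred.
Family labels (PairedLike / ANTP / other) come from a user-editable TSV:
subfamily classification is external curation, not a sequence-derived
property, and the published rosters are not bundled — users supply their
own curated FASTA + table.

## Tau quantitation (emsa)

Band intensity is taken as proportional to molar probe species: every
probe molecule carries one fluorophore, so the intensity fractions of the
free, monomer-shifted and dimer-shifted bands estimate species fractions.
Detector linearity is assumed; no background subtraction is performed
(inputs are already-quantified band tables, not images).

τ = 4·f_P2D·f_D / f_PD² per lane. Conventions:

- **Inclusion** is strict: a lane enters aggregates only when bound
  fraction > 0.05.
- **Undefined τ** (no monomer band): τ is singular there; such lanes are
  flagged and excluded from means, never imputed.
- **Aggregation** pools all included lanes of a (protein, probe) group
  across concentrations; mean and sample SD (ddof = 1).
- **Statistics**: Brown–Forsythe (median-centered) Levene at α = 0.05
  chooses Student vs Welch pairwise t-tests in `design="auto"`; Holm
  step-down adjusts pairwise p-values; two-way ANOVA
  (protein × concentration) uses type-II sums of squares via an OLS fit
  with interaction and warns on unbalanced cells. Identical zero-variance
  groups are reported as t = 0, p = 1 rather than NaN.

## The equilibrium lane generator (simulate)

The simulator inverts τ into a generative mass-action model of a probe
with two equivalent half-sites. With x = [P]/kd_site (kd_site the
microscopic per-half-site dissociation constant, default 200 nM):

    [PD] = 2·x·[D],   [P2D] = τ·x²·[D]

so the macroscopic constants are Kd1 = kd_site/2, Kd2 = 2·kd_site/τ and
recomputing τ from any equilibrium state returns the generative value
identically. Free protein is solved by Brent bracketing on the protein
conservation residual, which is strictly increasing in [P]; the bracket
[0, p_total] always contains the root, and both conservation laws hold to
~1e-12 relative afterwards. Defaults mirror the assay design the package
analyzes: 34 nM probe, protein at 25/50/100/200 nM, triplicate lanes.

Noise is multiplicative lognormal per band with mean-one factors
(σ² = ln(1 + CV²), μ = −σ²/2), since gel band intensities are positive
and roughly scale-proportional; an additive-Gaussian mode (clipped at 0)
exists behind a flag for robustness experiments. All randomness flows
through one integer seed; identical configurations are bit-reproducible.

The 12-lane mean-τ recovery tolerance used in the test suite (25% at
CV = 0.10) is a seeded fixed-configuration check calibrated by pilot runs
across many seeds, not a distributional claim: the τ estimator is mildly
biased upward under multiplicative noise (E[1/ε²] > 1), by about
exp(3·ln(1+CV²)) ≈ 3% at CV = 0.10, well inside the band.

**What the generator does not model:** complex dissociation during
electrophoresis (cage effects), gel smearing, lane-to-lane loading drift,
or kinetic (non-equilibrium) binding. Passing recovery tests therefore
shows estimator/generator consistency under the stated noise model, not
robustness to all real-gel artifacts.

## Sequence constraint analysis (constraints)

Because all domains are 60-mers the family alignment is positional.
Information content per position is ic = log₂20 − H with H the Shannon
entropy (0·log 0 ≡ 0); letter heights are frequency × ic, so a column of
heights sums to its ic. The small-sample correction e_n = 19/(2·n·ln 2)
is available behind a flag but defaults off: family sizes in the intended
use (tens to ~100 sequences) make it a minor constant shift and the
differential map subtracts most of it anyway. ic is clamped below at 0.

The differential map subtracts letter heights (not raw frequencies)
between two families, matching the per-letter rendering of sequence
logos; it is exactly antisymmetric under swapping the families.

Inter-sequence distances use a one-hot encoding per position (20
indicator coordinates), giving d = √(2m) for m mismatched positions — the
minimal encoding consistent with "Euclidean distance on a positional
alignment" and a monotone transform of Hamming distance. Substitution-
matrix kernels were deliberately not used; where the original analysis'
encoding is unknown, the one-hot choice is recorded here as this
package's decision.

Complete-linkage agglomeration is implemented in-package so that ties
merge deterministically (lexicographically lowest cluster-index pair,
scipy cluster numbering); merge heights are monotone by the maximum-link
update. On tie-free inputs the tree agrees with
`scipy.cluster.hierarchy.linkage(method="complete")` (checked by
cophenetic comparison in the tests). Newick export uses parent-minus-child
merge heights as branch lengths.

## The cooperativity rule set (rules)

The packaged default has 11 position-specific rules — require R2
(contributory), R3 (critical); forbid E4 (contributory); require P26
(critical); forbid R28 (critical); require E32, E42 (critical); forbid
R43, Q44 (critical); forbid R/K at 46 (critical); forbid K50
(contributory). Eight critical, three contributory. Classification:
any critical violation ⇒ `critical_conflict`; otherwise any violation ⇒
`contributory_conflict`; otherwise `compliant`. Positions without a rule
never affect classification.

Because rules occupy distinct positions and each violation is repairable
by one substitution, the minimum number of substitutions to compliance
equals the violated-position count; both the critical-only and all-rules
scopes are reported, since "make a factor cooperative" most naturally
means satisfying the critical rules while the stricter reading is also
defensible. "Branched hydrophobic" in the position-26 census is fixed as
{V, I, L} (threonine excluded as branched-polar). Rule sets round-trip
through YAML so users can amend them as the field evolves; the packaged
set is regression-tested.

## Variant consequence prediction (variants)

Calls depend only on (position, ref, alt, wild-type sequence); disease
labels are carried through but never consulted. Decision order, first
match wins:

1. **DNA-binding heuristics** (each individually toggleable): any
   substitution at the essential base-contact positions 5 or 51; G or P
   introduced at recognition-helix positions 42–58 (helix destabilization);
   W/F/Y introduced at minor-groove arm positions 2–3 (interface clash);
   a charged residue introduced at the turn proline 26.
2. Variant **gains a rule violation** ⇒ cooperativity_decrease with the
   rule's severity.
3. Variant **removes a wild-type violation** ⇒ cooperativity_increase.
4. **Interface-contact heuristic**: substitution at a protein-protein
   contact position with no rule transition ⇒ cooperativity_decrease
   (no severity). This step exists because the rule table is deliberately
   minimal — e.g. position 43 only *forbids arginine*, yet any
   substitution at this recognition-helix interface position (A43E, A43V)
   perturbs the dimer interface; treating such variants as indeterminate
   would contradict the biochemistry the rules summarize.
5. Otherwise **indeterminate**.

DNA-binding heuristics outrank rule transitions because a protein that
cannot bind DNA has no measurable cooperativity; the full evidence trail
(all fired heuristics and rule transitions) is always emitted so users can
re-rank. The packaged contact map contains only text-attested contacts
(protein-protein 2, 3, 4, 25, 28, 32, 42, 43, 44, 46; DNA base 5, 47, 50,
51, 54; minor groove 2, 3; backbone 46); richer published contact grids
can be supplied as YAML.

Known discordance, documented rather than patched: an R2Q-type variant is
called cooperativity-related by rule 2, although biochemically such a
variant can present mainly as a mild affinity loss when the wild-type
protein's cooperativity is already low. Arginine-to-glutamine changes at
position 2 sit at the boundary between the two mechanisms.

## Structure geometry (geometry)

PDB/mmCIF parsing uses gemmi; author numbering maps to HD positions via an
explicit per-chain offset (the author residue number of HD position 1) —
no heuristic renumbering. Residues without Cα warn; chains named in the
mapping but absent are errors listing the available chains.

Inter-helix spacing uses four inward-facing Cα pairs per helix-helix
combination (H1–H2: 12–37, 15–33, 19–30, 22–29; H1–H3: 13–56, 16–52,
20–49, 23–45; H2–H3: 28–54, 31–51, 34–47, 37–44). These defaults are the
package's own choice of inward-facing pairs and are fully configurable;
reproducing a specific published figure may require that figure's exact
pairs. Family comparisons report per-pair means, the mean difference,
two-sided t-tests with Holm adjustment, and an underpowered flag when a
family has fewer than two resolvable structures.

Superposition is Kabsch (SVD with the determinant sign correction, proper
rotations only). The spacing graft superposes each segment (arm, helices
1–3) of a model onto the corresponding donor segment and transforms the
whole segment rigidly: internal segment geometry is preserved and only
relative segment placement changes. No bond regularization is applied at
the seams — the output is a rigid-segment chimera for spacing analysis,
not a refined model.

SASA is Shrake–Rupley with Bondi van der Waals radii (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å; fallback 1.70), probe 1.4 Å, 960 golden-spiral
sphere points by default (≤1% error on isolated spheres at 4000 points).
A sampling point exactly on another atom's expanded surface is kept by the
lower-index atom only, so exactly coincident spheres count their shared
surface once. Steric overlap of a residue pair is SA(A) + SA(B) − SA(A∪B)
with each object isolated from the rest of the structure; peptide-bonded
(sequence-adjacent same-chain) pairs are rejected as trivially
overlapping. Because the radii table need not match any particular
graphics program bit-for-bit, overlap values are comparable across runs of
this package rather than identical to values from other software; accuracy
is established against a closed-form/numerical two-sphere oracle (≤2%).

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data:
12-lane titrations, families of 15–102 synthetic sequences, 100 random
equilibrium configurations checked against a 10⁶-point grid, and toy
Cα domains. These sizes make every check exact or statistically
well-powered while keeping a full run in seconds. Property-based tests
are derandomized; every stochastic component takes an explicit seed.

## Limitations

- Quantitative τ or ΔΔG prediction from sequence is out of scope; the
  rules are categorical/ordinal.
- The variant heuristics reproduce the well-characterized biochemical
  panel but are not guaranteed to match every curated-database judgment
  call; they are transparent and individually toggleable instead.
- The synthetic sequence families are drawn position-independently
  (no covariation), so tests exercising them do not probe covarying
  residue effects such as the 19/30 bridge.
- Gel image segmentation, Kd fitting from titrations, energy minimization
  of grafted chimeras, and remote database retrieval are out of scope.
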