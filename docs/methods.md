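# Methods

## Scope and data model

One analysis run consumes: a proteome (FASTA; proteins over 10,000 residues
are excluded at load, since window predictors are not meaningful there), a
readthrough-candidate table (TSV with CDS protein, extension peptide
beginning with the recoded-stop residue `X`, optional extension nucleotides,
evidence class, optional readthrough rate and replicate read counts), a
linear-motif pattern table, a flat GO annotation map, and an optional
ortholog pair list. All coordinates are 0-based half-open on the *extended*
protein: CDS occupies `[0, L)`, the `X` sits at `L`, and the extension —
which includes `X` and counts it toward its length — occupies `[L, L+E)`.
Double readthrough (more than one recoded stop per extension) is out of
scope and rejected at parse time.

## Candidate filters

* **Identifier validation.** A candidate id absent from the proteome is
  rescued only by a perfect, equal-length CDS sequence match to a proteome
  entry (it is remapped to that entry's id); otherwise it is excluded with a
  recorded reason.
* **Read support** (profiling evidence only): both replicate extension read
  counts must be ≥ 5 (inclusive, conjunction). Candidates without counts
  pass through.
* **AUG reinitiation**: candidates whose extension nucleotides contain `ATG`
  in any of the first three in-frame codons are excluded — such cases could
  be re-initiation rather than readthrough. The check reads the first nine
  nucleotides of the extension codon string as given.
* **Biological relevance** (`_BR`): evolutionarily conserved candidates are
  kept unconditionally; profiling candidates need a readthrough rate ≥ 1.2%
  of the CDS translation rate (inclusive).

## Segment sets

`RAND_C` donors are non-candidate proteins whose length is within ±5% of the
*extended* candidate length (CDS + extension; the wording of the source
procedure refers to the extended form, and the choice is configurable),
sampled without replacement. If no donor exists the tolerance widens in
1-point steps to at most ±10%, after which the run aborts naming the
candidate — silent fallbacks would corrupt the length matching that the
control set exists to provide. The `_L` threshold is **≥ 25** extension
residues (inclusive); `_L` filtering keeps index-matched partners together
so `|TRC_E_L| = |TRC_C_L| = |RAND_C_L|` by construction.

## Per-residue tracks

All five tracks are computed once on the full extended sequence and segments
are *excised*, never re-predicted: windows deliberately cross the
CDS/extension junction, which is the entire point of full-protein
prediction. Terminal windows are truncated, not padded — padding would
fabricate sequence context.

The three scorers below are simplified, fully parameterised stand-ins for
heavyweight predictors. They share the pipeline contract that matters
(full-length prediction, excision, inclusive thresholds 0.5 / 0.4) and make
no claim of output equivalence with the originals; genuine per-residue
predictor output can be overlaid through `import_scores` (TSV of protein id,
0-based position, value; contiguity and score bounds enforced).

* **Disorder** — `score_i = logistic(gain · (mean_w(propensity) − center))`
  with a TOP-IDP-style propensity table, window 21 (about one short-variant
  disorder-predictor window), gain 10, center 0.05. A residue is
  *disordered* at score ≥ 0.5; motif-overlap checks use the reduced
  threshold 0.4. Because the logistic is monotone, score ≥ 0.5 is exactly
  "windowed mean ≥ center", which makes the generator's calibration (below)
  analytic.
* **Low complexity** — windowed compositional Shannon entropy K2 (bits) over
  12-residue windows; windows with K2 ≤ 2.2 trigger a region, contiguous
  windows with K2 ≤ 2.5 extend it, and every residue covered by a retained
  window is flagged. This is a trigger/extend dialect **without** the
  original minimal-probability subsequence refinement — the pipeline only
  consumes the residue fraction. `X` residues occupy positions but are
  excluded from the composition (the entropy denominator is the non-X count
  in the window), so the ambiguous stop residue cannot artificially raise
  window complexity.
* **Secondary structure** — windowed mean Chou–Fasman helix and strand
  preferences (window 6, split 3-left/2-right); class is the argmax of the
  two means when it exceeds 1.0, else coil; exact ties go to helix. The
  profile fraction counts H or E residues.
* **Binding** (disordered binding sites) — a rescaled Kyte–Doolittle
  interaction propensity, windowed (11) and passed through a logistic, then
  gated to 0 wherever the disorder score is below 0.4: a fold-on-binding
  site must look disordered in isolation. A *binding site* is a maximal run
  with score ≥ 0.5.
* **Pfam occupancy** — never predicted; spans come from annotation input
  (all entity types accepted) and overlapping spans are unioned.

`X` carries the table mean in every propensity scorer, so replacing it by a
hypothetical mean-propensity residue changes nothing (tested). In all
downstream fractions and residue-based tests `X` counts in denominators but
never as positive, and it is excluded from amino-acid composition entirely.

## Motif scanning

Patterns are residue-class regular expressions with a chance-occurrence
probability and species tags; species filtering happens at load. Scanning
reports one hit per *distinct start position* (overlapping matches of one
pattern are separate hits; different patterns on the same span are separate
hits), because motif counts, not unique positions, are the unit of the
density metric. `X` is rewritten into every pattern position as a universal
wildcard (the actual residue is tRNA-dependent). Classification flags use
single-residue overlap throughout: with the extension span (an incomplete
motif completed by one extension residue counts), with disorder ≥ 0.4, and
with binding sites. Reported densities are motifs per 100 residues, rounded
half-away-from-zero to one decimal (so 6.25 → 6.3); raw values are kept in
machine-readable output. The low-probability filter is strict (`< 1e-3`),
and shared-motif reports always list both the 1e-3 and 1e-4 cuts.

## Statistics

* **Mann–Whitney U**, two-sided. When both samples have ≤ 8 values the p is
  computed by full enumeration of all labelings with the deviation
  definition `P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|)`, exact under ties.
  Larger samples use the tie-corrected normal approximation without
  continuity correction (mirroring the symmetric deviation definition); at
  n = 8 the approximation sits within a few hundredths of exact, which is
  why the exact path owns that regime.
* **Kruskal–Wallis + Dunn's** for ≥ 3 groups; Dunn's z uses pooled mean
  ranks with the standard tie correction, and each post-hoc p is multiplied
  by the number of pairwise comparisons (capped at 1) — a Bonferroni-type
  adjustment; Holm would be a drop-in alternative but the multiplicative
  rule is the documented default.
* **Residue-based χ²**: two-category goodness-of-fit with Yates continuity
  correction, observed = positive segment residues, expected = reference
  positive fraction × segment residue count, df = 1. A 2×2 contingency mode
  is available but off by default; the goodness-of-fit reading matches the
  "expected value" construction of the residue comparisons. References with
  degenerate (0 or 1) positive fractions are skipped with a warning.
* **Family-wise thresholds**: α/m with m = 4 for the segment-level family
  (four properties against pooled references → 0.0125 at α = 0.05) and
  m = 8 for the residue-level family (four properties × two references →
  0.00625). Both m values are explicit in config and recorded per row.
* **Normality**: the D'Agostino–Pearson K² omnibus test (n ≥ 20) is run on
  the extension disordered-fraction sample purely to document the
  nonparametric route.

## GO enrichment

One length-matched (±5%, widening as for `RAND_C`) non-candidate is sampled
per candidate, matched on the **unextended** length — the enrichment
concerns genes, not extensions. The universe is study ∪ background (two-list
mode; whole-proteome universe available), the per-term p is the upper-tail
hypergeometric probability, fold is `(k/n)/(K/N)`, and Benjamini–Hochberg
adjustment runs across terms. Because the background is a sample rather
than a superset, `k ≤ K` is not an invariant. Term sets are flat: no
ontology-graph propagation.

## Ortholog comparison

Pairwise global alignment (Gotoh affine-gap dynamic programming; BLOSUM62;
gap open 10, extend 0.5; a length-k gap costs `open + (k−1)·extend`; `X`
scores 0 against everything). The traceback tie-break is fixed —
match/mismatch over gap-in-first-sequence over gap-in-second — so alignments
are deterministic. CDS regions and extensions are aligned separately
(extensions generally do not fit the CDS alignment), identity = identical
columns / alignment length. Shared extension motifs default to motif-type
co-occurrence below the probability cut; a stricter mode additionally
requires ≥ 1 shared alignment column between the hit spans. Both criteria
are reported because positional matching of degenerate motifs between
diverged extensions is genuinely ambiguous.

## Synthetic data generator

The generator emulates the statistical structure the analysis targets, not
any real genome:

* **Proteome**: log-normal lengths, ln-mean 5.86 / ln-sd 0.55 (median ≈ 350
  residues, the scale of real proteomes), clamped to [30, 10000]; uniform
  1/20 background composition by default (a frequency table may be
  supplied).
* **Candidates**: default 60 of 300 proteins; extension lengths log-normal
  ln-mean 3.0 / ln-sd 0.8 (median ≈ 20, matching real readthrough extension
  medians), minimum 4 including the leading `X` (nucleotides start with a
  stop codon, then one synonymous codon per residue). Candidates are drawn
  from the central (5th–90th percentile) length range so every extended
  candidate has length-matched controls — a real proteome outnumbers its
  candidates ~50:1, which makes matching easy there but not in a desk-scale
  proteome with heavy log-normal tails.
* **Composition regimes**: `fly_like` multiplies P, Q, R, H, S background
  frequencies by 2; `yeast_like` multiplies Y, L, I, F, C by 2 and divides
  A, G, D, E, Q by 2; `neutral` is the identity (and requires a zero
  disorder shift). The boost factor is a calibration choice — the emulated
  biology states the direction of the biases, not their size.
* **Disorder shift**: the extension composition is exponentially tilted
  along the disorder-propensity axis until the *expected* disordered
  fraction exceeds the background's by the requested amount. For iid
  residues the 21-window mean propensity is ≈ Normal(μ, σ²/21), so the
  expected fraction is Φ((μ − center)·√21/σ) and the tilt is solved with a
  bracketing root-finder — no simulation inside the generator. Realized
  shifts on short segments fall slightly below the asymptotic target
  because terminal windows truncate; on extensions much shorter than the
  disorder window the CDS context dominates every window and dilutes the
  planted shift — the same artifact that motivates the ≥ 25-residue filter
  on real data.
* **Motif planting**: per-extension Poisson with the configured expected
  count per 100 residues; exemplars are substituted at uniform positions,
  never overlapping each other or the `X`, never truncated (oversized
  exemplars are skipped and logged); C-terminally anchored patterns are
  planted flush with the end. The ledger records every planted span.
* **GO planting**: one marked term annotates candidates at fold ×
  background rate (default background 0.1, capped at 1); all other terms
  annotate uniformly.
* **Readthrough rates** are log-uniform over [0.1%, 10%], spanning the 1.2%
  relevance cut from both sides; read counts are negative binomial (mean
  30, size 5). Conserved-evidence candidates carry neither, as in real
  compiled datasets.
* **Ortholog pairs**: the partner CDS is derived by per-site substitution at
  rate 1 − target identity (uniform over the 19 other residues, no indels);
  the partner extension is drawn independently — conserved CDS, unconserved
  extension, without a nucleotide-level evolution model.

Everything derives from one seeded generator; a fixed seed yields
byte-identical bundles.

**What the generator does not emulate**: real amino-acid background
frequencies (uniform by default), genuine predictor score distributions,
correlated domain architecture, transcript structure, or ribosome-profiling
read placement. Passing tests therefore demonstrate that the pipeline's
operations are correct and its statistics calibrated under known ground
truth — not that any particular biological conclusion transfers to a real
proteome with the stand-in scorers.

## Problem sizes used in the test suite

The calibrated statistical checks run at sizes chosen to make their
guarantees meaningful: planted-shift power uses 100 replicates of 200
segments (length 60) per group; the neutral type-I check uses 500 replicates
of 100 segments (length 50) per group at the 0.0125 corrected threshold;
planted-GO recovery uses 100 replicates of 200 candidates against 200
background proteins with 20 terms. Alignment and entropy oracles run on
exhaustive or randomly drawn toy instances (pairs ≤ 6 residues; 1,000
windows).

## Known limitations

* The stand-in scorers are not IUPred/PSIPRED/ANCHOR/SEG; absolute fractions
  are only comparable *within* a run (candidates and controls see the same
  scorer, which is what the contrasts require).
* The low-complexity dialect omits the original refinement stage and so
  marks slightly wider regions than the original program would.
* Flat GO sets: enrichment of a specific term does not propagate to
  ancestors.
* Ortholog alignment is pairwise-only; no multi-species alignment or
  frameshift detection.
* The pipeline re-entrancy policy is conservative: an existing manifest
  aborts the run unless resume is requested, and resume simply overwrites.
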