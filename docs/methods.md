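# Methods

## Model and procedure

The pipeline treats each injury/treatment model as an independent
contrast on a shared platform: a genes × samples matrix of log2
intensities with a sham and a treated group. Stages:

1. **Preprocessing.** Optional log2(x + offset) transformation for
   linear-scale input (default offset 1.0; skipped when the input is
   declared already log2, the default, since summarized array series
   are distributed that way), then quantile normalization: every
   column's sorted vector is replaced by the rank-wise mean across
   columns. Ties within a column receive the mean of the reference
   values across their tied ranks, which keeps tied inputs tied and
   makes the operation idempotent. Normalization is per contrast (each
   experiment's array set) by default; nothing in the pipeline assumes
   pooled normalization. Only the quantile-normalization component of
   RMA is implemented; background correction and probe-level
   summarization are upstream concerns and the pipeline ingests
   probe-set/gene-level matrices.
2. **DE calls.** log2FC = mean(treated) − mean(control) per gene;
   direction `up` iff log2FC > 1 strictly ("greater than 2-fold", so a
   fold change of exactly 2 fails) and max(group means) ≥ 5 (the
   expression floor, read as a group-level summary — "a minimum
   expression value of 5 in at least one of the conditions" — not a
   single-sample criterion); `down` symmetric.
3. **Vote counting.** One direction-specific vote per contrast in
   which the gene is called. Votes in opposite directions never pool.
   Genes absent from a contrast's platform contribute no vote but stay
   in the union universe. Consensus = genes with ≥ min_votes (default
   4 of 5) in one direction, ordered by votes descending then gene id.
4. **Term enrichment.** Exact hypergeometric upper tail P(X ≥ k)
   computed by log-factorial (lgamma) summation, or the EASE variant
   P(X ≥ k−1) (k ≤ 1 ⇒ p = 1), the conservative default because it is
   what DAVID-class annotation tools report. Universe = all genes
   scored on the platform, not the genome. BH step-up correction by
   default; raw-p filtering available because the original analyses
   report only uncorrected "p < 0.05" thresholds.
5. **Motif enrichment.** PWMs as JASPAR count matrices; log2-odds with
   background-proportional pseudocount (default 0.5); −∞ entries
   floored at −30/column; N bases score 0. A promoter "has" a motif
   (ZOOPS) when its best site over both strands reaches
   `score_fraction` (default 0.8) of the motif's maximum attainable
   score — the simplest auditable occurrence rule given that no
   published scanning thresholds exist for the original analysis.
   Enrichment is the hypergeometric tail on sequence-level hit counts,
   target vs background (all non-target promoters, not GC-matched — a
   documented simplification), BH across motifs.
6. **Exact tests.** Signed-rank: zeros dropped, midranks for ties,
   null enumerated over all 2ⁿ sign assignments conditional on the
   observed midranks (by convolution over doubled ranks, so midranks
   are exact); two-sided p = 2·min(lower, upper tail), capped at 1 —
   the convention that yields the minimum attainable p of 2^(1−n)
   (0.0078125 at n = 8) and matches standard statistics packages.
   n > 20 raises rather than silently approximating. Mann-Whitney:
   exact enumeration of all labelings for pooled n ≤ 12, otherwise a
   tie-corrected normal approximation with continuity correction, with
   the mode reported in the result.

## Promoter windows

BED input is 0-based half-open; the TSS is the start coordinate on the
+ strand and end−1 on the − strand. A window is the slice
[t − w, t + w + 1), length 2w + 1 with the anchor base included
(default w = 500, the promoter-proximal ±500 bp convention); − strand
windows are the mirror-image slice reverse-complemented. Windows
clipped at contig edges are flagged truncated.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study design the pipeline targets: five
contrasts (UC, Stroke, DOC, Alb, TGFb) on one platform, 3 replicates
per group, shared per-gene baselines N(7, 1.5²) truncated below at 3
(a realistic log2 array range), i.i.d. replicate noise N(0, 0.25²),
and planted structure:

- **Consensus genes** carry log2 effects uniform in [1.5, 3] in a
  per-gene breadth of contrasts sampled uniformly from
  {min_breadth, …, n_contrasts} (default {4, 5}) so the vote
  distribution is nondegenerate; breadth can be fixed. Their baselines
  are truncated upward to 6.0 so they sit clearly above the expression
  floor: planted "consensus" genes that the floor filter could never
  see would contradict their purpose as recoverable truth, and the
  floor is exercised separately by the decoys.
- **Model-specific genes** carry one effect in one contrast, random
  sign.
- **Sub-floor decoys** carry |log2FC| > 1 in every contrast but have
  baselines in [3.0, 3.2] and effects capped so the treated mean stays
  ≤ 4.3 — about five group-mean standard errors below the floor at
  default noise — so that the floor filter, not sampling noise,
  determines their (non-)call.
- **Promoters**: i.i.d. ACGT at the configured GC fraction (default
  0.45), with the exact motif consensus planted at a random
  position/strand with probability 0.8 for the designated genes and
  0.05 otherwise; plant positions recorded.
- **Gene sets**: one designated term seeded with half its members from
  the consensus set, the rest uniform.

All generators are pure functions of (params, seed); child generators
are spawned deterministically from the single global seed, and written
TSV/FASTA/GMT round-trip exactly.

Not emulated: probe-level data, batch or spatial array artifacts,
correlated noise between genes, GC- or length-matched background
promoters, realistic effect-size distributions (effects are chosen
only to straddle the stated thresholds). Passing recovery tests
therefore demonstrates correctness of the filtering/voting logic under
the stated noise model, not performance on real arrays, where
normalization choices and probe annotation dominate.

## Numerical choices

- Hypergeometric tail by lgamma summation, exact to ≥ 10 significant
  digits for N ≤ 10⁴ (verified against exact rational enumeration for
  all N ≤ 12).
- Signed-rank null via integer convolution over doubled midranks; no
  floating accumulation error in the counts.
- Quantile-normalization tie groups computed over exact rank spans via
  cumulative sums of the reference vector.
- Strict inequalities at the fold-change threshold; ≥ at the
  expression floor and the vote cutoff, matching the stated rules.
- Deterministic orderings everywhere ties are possible (votes then
  lexicographic gene id; p then term/motif id).

## Problem sizes

Default test and driver scale: 2000 genes × 5 contrasts × 6 samples,
1100 promoters of 1001 nt, 11 motifs, chosen as the smallest scale at
which recovery is a meaningful stochastic claim (tail-sensitive
planted effects, ~5 % chance motif hit rates) while the whole suite
runs in well under a minute of compute per stage.

## Known limitations

- Real-series reproduction depends on upstream RMA summarization that
  is out of scope; consensus counts on re-downloaded GEO data may
  shift slightly.
- EASE/hypergeometric enrichment takes term collections as supplied;
  no ontology propagation or redundancy merging.
- The motif stage does no de-novo discovery and no background
  matching; enrichment p-values are exact for the stated model but the
  model itself is simple.
- Mann-Whitney beyond pooled n = 12 is approximate (reported as such);
  the exact path is deliberately capped to keep enumeration cheap.
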