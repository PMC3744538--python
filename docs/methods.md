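# Methods

## The screening model

`poloscan` re-implements, as a tested library, the sequence arm of a
kinase-substrate discovery screen for dual-recognition kinases such as
polo-like kinase 1 (Plk1).  Plk1 selects substrates through two short
linear signatures: a kinase-domain phosphorylation consensus around the
phosphoacceptor, `[E/D]X[pS/pT][I/L/V/M]X[E]`, and a polo-box-domain
(PBD) docking site, `S-[pS/pT]-[P/X]`, created by a priming kinase.  A
protein is a plausible substrate when it carries both signatures and
lives in the right biological context (cell-cycle machinery, cancer
association).  The screen formalizes this as a five-stage filter
cascade over a proteome:

1. **Motif occurrence** — at least one consensus window whose
   phosphoacceptor residue (S/T) matches exactly.
2. **Similarity threshold** — the best window reaches 80% identity to
   the consensus.  Identity is matched-positions / motif-length over
   *all* positions, wildcards counting as matches, applied inclusively
   (`>= 0.80`).  For the 6-position consensus this admits exactly one
   mismatch among the constrained non-phosphoacceptor positions; the
   phosphoacceptor itself is exempt from mismatching (hard constraint).
   This is the only reading under which a sub-100% threshold both has
   an effect and preserves the phosphosite.
3. **Annotation enrichment** — survivors are grouped into clusters, one
   per annotation term, and each cluster is scored by the probability
   of arising by chance: the upper hypergeometric tail
   P(X ≥ k) with universe N, term carriers K, annotated survivor cohort
   n, and term-carrying survivors k.  Clusters with P > 0.1 are
   discarded; proteins in no retained cluster are dropped.  One-tailed,
   because the screen asks only about over-representation; no
   multiple-testing correction by default (Benjamini–Hochberg is an
   explicit opt-in), matching the flat discard rule the cascade is
   built around.
4. **Docking site** — an exact PBD-motif instance.  The motif is 3
   residues with (in the default "relaxed" reading of `[P/X]`) only one
   non-phosphoacceptor constrained position, so a fractional threshold
   would be meaningless; similarity 1.0 is required.  A "strict" switch
   restricts the third position to proline for users who read `P/X` as
   proline-preferred-and-required.
5. **Context annotation** — at least one term in each required
   namespace (cell-cycle `phase` and `cancer` by default).

Stage sets are nested by construction, so survivor counts are
non-increasing.  Final candidates are ranked deterministically:
descending best similarity, ascending minimum retained-cluster p-value,
descending PBD-site count, ascending identifier.  The original screen
prioritized its final list by expert curation; this key is the
package's own documented, reproducible stand-in.

### Scanning instead of alignment heuristics

The original screen located motif instances by aligning the short
consensus against a protein database with a heuristic local-alignment
tool.  A 6-residue degenerate pattern is not faithfully searchable that
way (word seeding and gap penalties are irrelevant at this scale), so
`poloscan` scans every window of every protein exhaustively — exact,
reproducible, and strictly more sensitive.  A substitution mode is
provided that scores a position as matched when its BLOSUM62 score
against any allowed residue is positive, approximating how the matrix
treats conservative replacements; because the BLOSUM62 diagonal is
positive, the substitution-mode hit set always contains the
identity-mode set.

Conventions: coordinates are 1-based inclusive; ambiguity codes
(B, Z, U, X) and stop (`*`) are legal input and match only wildcard
positions in identity mode; all qualifying windows are reported with no
non-overlap selection; no spacing constraint is imposed between kinase
and PBD sites by default (a configurable `min_gap`/`max_gap` pair
exists, off by default, since the biology does not fix the separation).

## The enrichment statistic

`hypergeom_tail(N, K, n, k)` sums hypergeometric log-pmf terms over
x = k … min(n, K) with `logsumexp`, which keeps far tails (p ~ 1e-14)
accurate where a complement-of-CDF formulation would lose all digits.
The annotated cohort size n counts hit proteins carrying at least one
annotation in the chosen namespaces — unannotated proteins cannot
contribute evidence and are excluded, mirroring a universe defined as
"annotated proteins".  A protein may belong to any number of clusters.

Because enrichment is **cohort-relative**, the cascade as a whole is
monotone in the retention threshold alpha (a larger alpha can only
retain more clusters over the same cohort) but *not* in the similarity
threshold: admitting more background at stage 2 dilutes every cluster
and can remove stage-3 survivors.  Re-running the screen on the final
candidates' sub-proteome reproduces the final set when the candidates
share the enriched terms (as in the default synthetic world), but
idempotence is likewise not a theorem for arbitrary inputs.

## The synthetic world

`generate_world` builds a proteome and annotation set with the
structure the screen assumes, plus complete ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` / `n_planted` | 500 / 50 | proteome size; true substrates |
| `length_mean` / `length_sd` | 150 / 50 residues | normal lengths, clamped ≥ 19 so both motifs fit |
| `background_frequencies` | uniform 0.05 | i.i.d. residue model (Swiss-Prot preset available) |
| `near_miss_rate` | 0.1 | background proteins receiving a single-mismatch consensus window |
| `phase_mixture` | G2+M = 0.5 | phase labels of planted substrates, weighted toward G2/M as expected for a mitotic kinase |
| `q_pos` / `q_neg` | 1.0 / 0.05 | probability of the enriched "cell cycle" term for planted / background |
| `cancer_rate_pos` / `cancer_rate_neg` | 1.0 / 0.05 | cancer-association term, likewise |
| `phase_rate_neg` | 0.1 | background phase-annotation rate |
| `n_noise_terms` / `noise_term_rate` | 20 / 0.05 | uniformly assigned GO terms carrying no signal |

Planted proteins carry exactly one exact instance of each motif at
recorded, non-overlapping positions (wildcard residues drawn from the
background model), plus — by default deterministically — the full
annotation profile of a true substrate: one phase, the enriched term,
and a cancer term.  The defaults therefore define a world in which a
correct implementation recovers every planted substrate; dialing
`q_pos`/`cancer_rate_pos` below 1 models annotation-database
incompleteness, under which sensitivity degrades by roughly their
product and the tests demonstrate exactly that.  Near-miss decoys
mutate one constrained non-phosphoacceptor position of an exact
instance — the minimal perturbation that separates the 0.8 and 1.0
thresholds (such windows score exactly 5/6).

The i.i.d. background makes the scan statistics exactly computable:
`window_match_probability` sums, over every subset of constrained
non-phospho positions allowed to mismatch under the threshold, the
product of per-position match/mismatch probabilities, with the
phosphoacceptor forced to match.  Under uniform frequencies the default
consensus gives 1e-4 per window at threshold 1.0 and 33 × 1e-4 at 0.8
(factor 1 + 18/2 + 16/4 + 19/1).  `expected_hit_rate` multiplies by the
windows per protein of mean length.  `expected_background_final_rate`
composes per-stage background pass probabilities assuming independence
between stages and windows; window-overlap correlation and the
approximation of noise-cluster retention by alpha make it a 3-SD
oracle, not an exact value.

The default protein length (150) was chosen so the 80% similarity stage
retains a minority (~40%) of background proteins, giving the cascade
the same funnel shape as a real proteome screen; with realistically
long proteins and this short a motif, chance relaxed-threshold windows
would saturate stage 2 and the enrichment stage would carry all the
discrimination.  What passing tests on this world show is that the
machinery is correct and calibrated under its stated assumptions; they
do not show that real proteomes satisfy those assumptions (real protein
lengths, residue composition, domain structure, and annotation
correlations all differ, and real annotation databases are incomplete).

## Numerical and degenerate-input choices

* Threshold comparison is done in integer match counts
  (`ceil(min_similarity · length − 1e−9)`), avoiding float-equality
  surprises at boundaries like 0.8 · 6.
* Sequences shorter than the motif scan to an empty hit list, not an
  error; an empty proteome or hit set yields empty results.
* Tail probabilities are clipped into (0, 1]; when the whole support is
  in the tail the value is exactly 1.
* Cluster sorting breaks p-value ties by descending k, then term, then
  namespace; candidate ranking ties end at the identifier — both total
  orders, so output is byte-stable.
* All writers use fixed column orders, `%.6g` floats and LF endings;
  identical seeds and configs produce byte-identical files.

## Problem sizes used by the test suite and acceptance script

The hypergeometric oracle is verified exhaustively for every valid
(N, K, n, k) with N ≤ 12; the scanner against a naive per-window oracle
on 200 random triples (length ≤ 200); threshold semantics exhaustively
over all 20⁴ constrained-position assignments; background statistics on
1,000 × 500-residue proteomes (~10⁶ windows per scan, and ≥ 10⁶ i.i.d.
windows per Monte-Carlo combination); ground-truth recovery on the
default 500-protein world, with enrichment stability over 100 seeded
replicates.  These sizes give every statistical assertion a 3-SD (or
better) separation from its alternative while keeping the whole suite
fast on one CPU.

## Known limitations

* Flat annotation labels: no ontology graph propagation, so parent
  terms must be materialized in the input if wanted.
* The similarity index treats all constrained positions equally; there
  is no position-specific weighting and no probabilistic motif model.
* The substitution mode is a per-position approximation of matrix
  scoring, not an alignment score.
* Structure-level evidence (docking geometry, accessibility) is out of
  scope; the PBD stage is sequence-only.
* The curated intersection steps of the original screen are represented
  only by their algorithmic core (counts, the tail probability, the
  retention threshold, required namespaces).
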