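# Methods

## The marker and the classification model

The tRNA^leu^–cox2 intergenic region of the honey bee (*Apis mellifera*)
mitochondrial genome is a mosaic of a tRNA^leu^ fragment, a non-coding P
element, one to five tandem copies of a ~196 bp Q element, and the 5' part of
the cox2 gene. The P element occurs in four forms distinguished by
characteristic large deletions, and each form is diagnostic for a maternal
evolutionary lineage:

| P form | structure                      | lineage |
|--------|--------------------------------|---------|
| P0     | full length                    | A (African) |
| P1     | 15 bp deletion at the 3' end   | A, sub-lineage AIII |
| P      | 13 bp deletion in the middle   | M (Western European) |
| P2     | 18 bp deletion at the 5' end   | Y |
| absent | —                              | C (Eastern European) |

African sub-lineages carrying the P0 form are told apart by the placement of
DraI (TTTAAA) restriction sites: AI has sites at the 3' end of the tRNA^leu^
and the 5' end of the first Q copy; AII has the tRNA^leu^ site only; Z adds a
third site in the middle of the first Q copy. AIII is read from the P1 form
alone. The element architecture is summarised as a length pattern string
(e.g. `P0QQ` = full-length P plus two Q copies).

The classifier implements exactly this decision structure. Elements are
located by semi-global template alignment (edlib), not by fixed offsets, so
amplicons of different absolute lengths — and reverse-complemented inputs,
detected from anchor alignment scores — are typed by one code path. Anchor
matches require ≥80% identity; each tandem Q repeat requires ≥90%. The P form
is read from the placement of large (≥10 bp) deletions in a global alignment
of the inter-anchor spacer against the full-length P template, with ±2 bp
tolerance on the expected 13/15/18 bp lengths; deletion runs split by
coincidental 1–2 bp flank matches are merged before calling. Two simultaneous
large deletions raise an error rather than a guess.

Sub-lineage windows are: the last 10 bp of the tRNA^leu^ span plus 6 bp of 3'
slack; the first 15 bp of the first Q copy; and the central third of the
first Q copy. When no Q copy is present the Q-site diagnostics collapse; a
tRNA^leu^-only DraI configuration is then called AI, because the only known
Q-less haplotype (A65) belongs to AI — with the consequence that AI and AII
templates are structurally indistinguishable at zero Q copies. Without the
tRNA^leu^ site the sub-lineage is reported indeterminate, not imputed.

## The synthetic reference system

No curated master alignment of the region ships with public data, so the
package defines its own deterministic synthetic templates (fixed RNG seed,
scrubbed of spurious TTTAAA motifs, including across every element junction
realisable by the grammar): a 40 bp tRNA^leu^ fragment, a 68 bp P0 (top of
the published ~53–68 bp range, so the three deletion forms have unambiguous
lengths 55/53/50), a 196 bp Q unit and a 314 bp cox2 fragment. All haplotype
definitions live on a single 818-column master alignment:

    tRNAleu 1–40 | P 41–109 | Q1 110–307 | Q2 308–504 | cox2 505–818

Four columns (100, 139, 298, 337) are insertion slots — gaps in every family
base — hosting the 1 bp insertions that define named variants. The cox2
fragment length was chosen so that (a) every variant-defining column of the
encoded catalog (84–795) falls on a real base of the relevant family, and
(b) the Q-less architecture is exactly 422 bp, the published length of
haplotype A65. Bases flanking the indel slots are pinned to differ from the
inserted/deleted base, which keeps pairwise alignments of variants against
their family base unambiguous (no gap sliding), so edit lists are exact.

The catalog encodes 26 records: the 24 haplotypes observed in the Peruvian
survey plus the A4 and M7 family bases used as alignment anchors. Variants
are stored as edit lists against six family bases (A1 = `P0Q`, A4 = `P0QQ`,
A30 = `P1QQ`, A65 = `P0`, C2 = `Q`, M7 = `PQQ`); this family→pattern mapping
reproduces the published per-pattern counts exactly. Edits for the lineage-A
and M variants follow the published substitution/indel lists; the survey
text names A30d twice, which we resolve as 336-deletion → A30d and
86-substitution → A30e. The C-family variants' diverging positions are not
printed readably, so their single-substitution structure (C2c, C2j, C3
diverging from C2; C1 and C2l from C2c) follows the published network
topology with package-chosen columns. The outgroup is a synthetic *Apis
cerana* analogue: tRNA^leu^ + diverged full-length P + diverged cox2, no Q.

## Synthetic surveys and what they do (not) show

The generator's default population reproduces the published 512-colony,
15-site, 3-region survey with exact per-site haplotype counts. The
deposited per-site table gives only N, Na, Np, Ne and uh, so the shipped
composition is a reconstruction constrained to match: the lineage totals
(333 A / 173 C / 6 M), sub-lineage totals (280 AI / 53 AIII), all six
length-pattern counts, the printed counts of the five major haplotypes,
per-site N and Na, one private haplotype per site, and the stated
single-site occurrences of the rare variants. Per-site Ne/uh then come out
close to, but not exactly at, the printed values (e.g. Barranca uh 0.180 vs
printed 0.181); the printed table itself is shipped separately and is the
reference for identity checks. Sites may alternatively be specified by
haplotype frequencies, in which case colonies are drawn multinomially.

Noise is point substitutions only, at rates up to 2%; substitutions never
fall inside an existing DraI motif and are rejected when they would create
one. Real data can of course mutate restriction sites — that is precisely
what the DraI diagnostics measure — so classifier robustness under this
noise model demonstrates tolerance to sequencing error, not to biological
variation at the diagnostic motifs. Indel noise and chimeras are not
simulated.

## Diversity statistics

Per site, with haplotype frequencies `p_i` over `N` colonies: `Na` = number
of distinct haplotypes; `Ne = 1/Σp_i²`; `uh = (N/(N−1))(1−Σp_i²)`; `Np` =
haplotypes seen in that site and nowhere else (site-private, not
region-private). Values are rounded to 3 decimals only at the report layer.
`uh` is undefined (reported missing) for N < 2.

PhiPT is the AMOVA analogue of F_ST on categorical labels with the binary
distance d(i,j) = [label_i ≠ label_j]: standard variance-component
estimation from sums of squared distances (among/within sites), with
Φ_PT = σ²_A/(σ²_A+σ²_W). Negative estimates are reported as 0 (raw values
kept). Significance is by permutation of colonies among sites (default 999,
seed required); p = (1+#{Φ* ≥ Φ})/(perms+1). No multiple-testing correction
is applied across pairwise comparisons. The pipeline runs PhiPT on combined
lineage/sub-lineage labels (A-AI, A-AIII, C, M), matching how the survey's
ordination was built; haplotype-level labels are equally valid inputs.

PCoA is Gower double-centering of −D²/2 with eigendecomposition. Percent
variance per axis is computed over positive eigenvalues only (summing to
100); negative eigenvalues are excluded from the denominator and reported.
PhiPT matrices are not generally Euclidean, so small negative eigenvalues
are expected and harmless.

## Character coding, tree and network

The catalog alignment is coded as weighted categorical characters:

* per-column characters for polymorphic sites of the P element, both Q
  copies and the cox2 fragment, with gap as a fifth state (1 bp indels stay
  as ordinary gap-state characters);
* binary indicators for the structural events — each large P deletion, P
  absence, first-Q absence and second-Q presence. Element-absence and
  second-Q indicators count one mutational step; large-deletion indicators
  are upweighted. Columns an absent element would occupy are coded missing;
* two upweighted DraI-site presence characters (tRNA^leu^ 3' and first-Q
  5'); their 6 bp windows are excluded from per-column coding so the sites
  are not double-counted. The Q-middle site is coded at weight 1 (no Z
  haplotype occurs in the catalog, so it drops out as monomorphic).

The magnitude of "upweighting" is not published; the default is 10
(configurable), the conventional maximum weight of haplotype-network
software. Because the original alignment numbered the variant-defining
columns 336/337 within its first Q stretch, while the compact synthetic
layout places them in the second Q slot, second-Q columns are retained as
ordinary characters (taxa lacking a second Q are missing there, and the
presence indicator carries the single structural step); dropping them would
collapse legitimately distinct A4 variants.

Step distances are weighted counts of differing characters with missing
states skipped. This is a metric on complete data; taxa missing a whole
element (A65, the outgroup) can violate the triangle inequality as
intermediate points — the usual pairwise-deletion caveat, verified and
documented in the tests.

The phylogeny is neighbor joining (scikit-bio) on step distances — a
distance method is the natural match for this step-count coding; parsimony
would be the obvious alternative. Bootstrap (default 1000, seeded) resamples
characters with probability proportional to weight, and supports are the
percentage of replicate trees containing each internal bipartition of the
reference tree. The tree is rooted on the outgroup when included.

The network is a Bandelt-style median-joining network: iterate (1) the
ε-relaxed minimum spanning network (union of all minimum spanning trees at
ε = 0) on current vectors, (2) add median vectors — coordinate-wise majority
of connected triplets, ties keeping the first vector's state — whenever the
median's star connection is strictly shorter than the triplet's mutual
links, until fixpoint; then (3) prune median vectors of network degree < 3.
ε defaults to 0 (most parsimonious network). Categorical data with quantised
weights produce many tied distances, so the MSN can be edge-rich; the
cluster structure (A, C and M haplotype groups linked only through
upweighted structural steps) is asserted in the tests.

## Numerical and interface choices

* All internal spans are 0-based half-open; user-facing edit columns are
  1-based master-alignment columns. Input orientation (E2→H2) is
  auto-detected; the strand is recorded in the element map.
* Haplotype calls compare master-alignment edit sets; the closest reference
  minimises the symmetric difference, ties broken by catalog order. New
  variants are coined family base + first unused letter suffix (strictly
  alphabetical; no letters skipped). A pattern with no catalog member gets a
  placeholder `X`-series name and a curation flag.
* Report percentages are rounded half-up to 1 decimal; a rounded lineage
  share can therefore differ from the printed value when the source itself
  truncated (e.g. 117/512 = 22.85% prints as 22.9 here).
* The sequence alphabet is strict ACGTN; IUPAC ambiguity codes are rejected
  (Sanger consensus inputs are assumed).
* Problem sizes used by the shipped checks: the 512-colony default survey
  for end-to-end runs; 8-taxon instances for tree/network property checks;
  999 permutations × 200 replicates for the PhiPT null calibration.

## Known limitations

* The synthetic grammar emulates the region's architecture, not its real
  sequence; absolute coordinates are package-defined and only the published
  column numbers of the variant edit lists are preserved.
* The AI/AII distinction is undefined for Q-less amplicons (see above).
* C-family variant positions and the outgroup sequence are synthetic
  stand-ins, suitable for exercising the machinery but not for typing real
  GenBank material without re-anchoring the catalog to a real alignment.
* The noise model never touches diagnostic motifs and adds no indels.
* PhiPT p-values are not corrected for multiple pairwise comparisons.
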