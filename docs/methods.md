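# Methods

## The analysis model

The package assumes a genome carrying `k` ribosomal operon copies that
fall into two types: a majority type whose copies are nearly identical
(>99.5% in the 16S gene) and one divergent type. All analyses work on
aligned sequences with 1-based columns and closed intervals; RNA input
is normalized to the DNA alphabet (U→T) on ingestion. Gaps, N and all
IUPAC ambiguity codes are uniformly treated as missing data.

### Distances

`p_distance` uses pairwise deletion: a column contributes only when
both residues are unambiguous bases; `distance = mismatches / sites`.
Identity is `100·(1−p)` and divergence `100·p`, so the two always sum
to 100 for a pair. Pairwise deletion means each pair may be compared
over a different site set, so the triangle inequality is *not*
guaranteed and is deliberately not asserted anywhere. An alternative
`gaps-as-difference` policy (a gap opposite a base counts as a
difference) is available for sensitivity analysis. Reports round
identities to one decimal; all internal arithmetic is full precision.

### Operon-type signature

A column belongs to the signature when each type's non-missing
residues agree on a consensus base at ≥ the saturation threshold
(default 0.85) and the two consensus bases differ. Modal ties are
broken alphabetically, which is immaterial above a 0.5 threshold. The
saturation denominator excludes missing residues, so a type
represented by a single scorable base at a column can still reach
saturation 1.0 — the threshold governs agreement, not coverage.

Typing a sequence scores only signature positions where it carries an
unambiguous base; the three shares (like type 1 / like type 2 /
neither) are converted to integer percents by the largest-remainder
method so they always total 100. Largest-remainder was chosen because
independent nearest-integer rounding can total 99 or 101 and published
breakdowns of this kind are not reproducible to the rounding rule;
`rounding="nearest"` is available.

A *reversion* is a non-missing residue in a sequence of one type equal
to the other type's consensus at a signature position — the expected
footprint of gene conversion between operon copies. Detection reports
one record per (position, type) with the carrying sequence ids;
distinct flagged positions are the headline count.

### Primer windows

Type-specific reverse primers are sought as alignment windows (default
length 20–30) in which every sequence of the target type carries
identical, gap/ambiguity-free residues, and the other type's majority
consensus differs at ≥3 columns. The ≥3-mismatch default and the
preference for a mismatch at the primer's 3′ end (the window's
leftmost column, since reverse complements are emitted) follow
standard allele-specific-PCR practice; none of these constants is a
measured quantity, and all are exposed. Ranking: most cross
mismatches, then 3′-end mismatch, then leftmost, then shortest.
Thermodynamic QC (Tm, hairpins) is out of scope.

### Secondary structure

A `HelixMap` gives each helix's 5′ and 3′ strand intervals in the
coordinates of a reference ("model") sequence. Folding is purely
combinatorial: strand position *i* pairs against position *L+1−i* of
the opposite strand; canonical means Watson–Crick plus G·U wobble
(wobble can be disabled). Positions mismatched in the reference model
are "closed" — drawn paired — only when the target bases pair
canonically there and at most `max_closable` (default 2) such closures
occur in the helix; if more would close, none do. With
`max_closable=0` the rule reduces to the plain canonical mask, which
is property-tested.

Alignment columns are mapped to model coordinates by counting the
model row's non-gap residues; a column opposite a model gap is an
insertion attributed to the helix or region containing the model
position it follows. Between-type comparison assigns each signature
position (substitution) and each consensus-gap column (insertion or
deletion, by which type holds the base) to a helix or to the unpaired
pool; the assignment is conserved — counts sum to signature positions
plus indel columns. A helix is *structure-altering* when the two type
consensuses fold to different pairing masks or different strand
lengths.

The packaged 16S helix map is a synthetic stand-in layout (35 helices
of 12-bp stems on a 1500-nt model) used by the generator and tests;
for real molecules the map is an input the user supplies, because
published reference coordinates are routinely modified per lineage.
Terminal-loop geometry and free-energy refinement are out of scope.

### ITS annotation

Domains are located by ordered template search: motif domains by their
first full IUPAC match at or after the running cursor (query
ambiguity codes match nothing — conservative counting), helix domains
(D1–D1′, V2, Box-B, V3) by the first canonical hairpin in their search
window (leftmost start, then longest stem, then smallest loop), the
D2–D3 spacer as whatever lies between its neighbours, and the leader
as everything before D1–D1′. Required domains missing → annotation
error with a diagnostic; optional domains (the tRNAs, V2) are marked
absent and the cursor does not advance. Present intervals must tile
without overlap, which is checked.

The default templates are synthetic realizations of the canonical
architecture (they carry the two types' published discriminating
features: ITS start AAC vs TTT, D2–D3 spacer 10–11 vs 4–6 nt, D3
GGTAY vs GGTTC, a longer D4 and a 6-nt vs 15-nt D5) with arbitrary
but hairpin-poor motif bodies; real lineages need their own template
TSVs, which is why templates are data, not constants. D5's anchor
relative to V3 is not standardized, so D5 is a motif slot positioned
by the template file. The Type 2 D5 default is a single 15-mer; the
15–16-nt range seen across real operons is representable by supplying
per-operon template variants.

### Promoter scanning

Upstream inputs must end at the transcript start. The scanner is
greedy and 3′-anchored: first the −10 hexamer maximizing the consensus
match count over discriminator distances 2–8 nt from the 3′ end (ties
to the window nearest the 3′ end), then the −35 at 16–19 nt upstream
of the −10, then the optional −52 at 7–9 nt upstream of the −35.
Spacer and discriminator ranges were read off the layout of published
promoter tables for this system and are configurable; the 3–6
matches-of-6 functionality rule applies to the −35 and −10 only — the
−52 is reported but never affects the call. Elements whose window
would run off the 5′ end are reported absent rather than partially
scored.

### Genospecies delimitation

Criterion 1 links two strains when their identity exceeds the
threshold (default 98.7%) in *every* operon type for which a
comparison exists; candidate clusters are connected components
(single linkage — the minimal-assumption reading, since no clustering
procedure is standard here). Identity exactly at the threshold
separates (≤ means split). Criteria 2 (tree clades) and 3
(morphospecies) then split clusters whose members carry different
labels; a missing label is non-informative and keeps its strain with
the largest labeled subgroup, so absent metadata can never cause a
split. Splits are recorded with their criterion as provenance, and
adding criteria is provably refining (tested). Tree clades are user
input: each leaf takes the label of its nearest labeled ancestor; the
package never infers trees or support values. In the pipeline, the
per-type identity between two strains is the maximum over their
sequence pairs of that type (the most-similar copies stand for the
strain's operon); at the noise levels of interest any summary
(min/mean/max) gives the same partition.

## The synthetic generator

The generator emulates the study design the analyses assume:

| parameter | default | meaning |
|---|---|---|
| n_species × strains_per_species | 3 × 3 | species cluster size |
| operons_per_strain / n_type1 | 5 / 1 | copies per genome; divergent copies |
| gene_length_16s / 23s | 1500 / 2800 nt | gene lengths |
| signature_positions | 123 | planted between-type differences (16S) |
| between_type_divergence | 0.08 | used when the count is unset: round(0.08·L) |
| between_type_divergence_23s | 0.068 | planted 23S divergence fraction |
| within_type_site_noise | 0.002 /site | strain-level drift within a type |
| between_species_divergence | 0.02 /site | background drift separating species |
| reversion_rate | 0.0 | per signature site per sequence |

Construction: one random ancestral gene per molecule; the divergent
type's ancestor differs at exactly the planted signature positions,
sampled inside designated helices of the helix map (overflow goes to
unpaired regions); species backgrounds mutate non-signature sites
identically in both type ancestors, so species drift never erodes the
signature; strain copies add per-site noise; reversions then overwrite
signature sites with the other type's base. 123/1500 = 8.2% sits
inside the published 7.3–9.0% window for this system, and 0.02
between-species drift yields ≈96% between-species identity (safely
below the 98.7% species threshold) while 0.002 within-species noise
keeps conspecific strains >99.5%. ITS and upstream regions are
assembled per operon from the templates, with inter-domain filler
drawn from an A/C-rich alphabet that cannot form canonical hairpins;
each assembled region is rejection-sampled (≤200 draws) until the
package's own annotator/scanner recovers the planted boundaries
exactly, guaranteeing the round-trip property by construction rather
than by luck. All randomness flows from a single numpy Generator, so a
fixed config reruns byte-identically.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: indel evolution and alignment
uncertainty (emitted alignments are gapless by construction),
realistic substitution models (changes are i.i.d. uniform, no
rate-by-site variation, no GTR), chimeric clones, compensated
(pairing-preserving) substitutions inside helices, sequencing error,
and real ITS motif content. In particular, on synthetic data every
signature substitution disrupts pairing, so all signature-bearing
helices are flagged structure-altering, whereas in real molecules most
substitutions are compensated.

Clone libraries are multinomial draws with replacement under
per-operon weights; a zero weight reproduces the PCR bias that hides
an operon type from cloning.

## Numerical and degenerate-input choices

- Modal/consensus ties break alphabetically; alignment traceback ties
  break diagonal > up > left, making the global aligner fully
  deterministic (score equals the brute-force optimum, tested by
  enumeration and against an independent aligner).
- Zero comparable sites between a pair is an error naming the pair,
  not a silent NaN.
- A signature query with every signature position missing is an
  error; missing positions merely shrink the typing denominator.
- Fold "closure" with more closable positions than the budget closes
  none (rather than an arbitrary subset).
- Largest-remainder rounding prefers, on equal remainders, the earlier
  category (type 1 before type 2 before other).

## Problem sizes

Default test and acceptance runs use the 3×3×5 study design
(45 operons, 1500-nt 16S, 2800-nt 23S) and 100 single-strain
replicates for the divergence-window check; brute-force comparisons
run on instances of ≤10 sequences. These sizes exercise every code
path at full fidelity.

## Known limitations

- The three delimitation criteria assume strain-level labels are
  trustworthy; conflicting labels are resolved by splitting, never by
  majority vote across criteria.
- ITS annotation is greedy first-match; templates whose motifs occur
  spuriously upstream of their true location will misannotate. Use
  distinctive (≥8-nt) motifs in custom template files.
- The promoter scanner fixes the −10 before searching the −35, so a
  weak −10 paired with a strong mis-spaced −35 can shadow the intended
  arrangement; the planted-window round-trip in the generator screens
  this out for synthetic data but real upstream regions should be
  reviewed.
- Identity ranges depend on the trimming of the input alignment;
  supply consistently trimmed alignments when comparing against
  published ranges.
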