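# Methods

This note records how each stage is modeled, the defaults and why, what
the synthetic-data generators do and do not emulate, and the numerical
and design choices made where the method was genuinely open.

## Domain identification and classification

Identification is deterministic pattern matching, not a probabilistic
profile search. A domain is a heptapeptide from an exact, user-extensible
set (`WRKYGQK`, `WRKYGKK`, `WRKYGEK`, `WKKYEDK`, plus the 8-mer
`WKKYCEDK`, treated literally as eight residues) followed by a zinc
finger. Finger grammars are enumerated exactly: C2H2 with gaps
(4–5, 22–23, 1) and C2HC with gaps (7, 23, 1). The search window for the
finger's first Cys is 60 residues past the heptapeptide end — the
canonical WRKY domain is ~60 residues, so a finger belonging to the same
domain cannot start later. At a given Cys, smaller gap1 wins, then
smaller gap2, and C2H2 beats C2HC; across Cys positions the leftmost
match wins. These tie-breaks make the scanner a pure function of the
sequence; the test suite holds it equal to an exhaustive window/
enumeration oracle on hundreds of random sequences.

Classification uses only complete domains (heptapeptide + finger): two
C2H2 domains → group 1, one C2H2 → group 2, one C2HC → group 3, anything
else ungrouped with an explanatory note. Group-1 N- vs C-terminal finger
sub-spacings are recorded in notes but not used for assignment. An
E-value threshold field (default 1e-5) is kept in `ScanConfig` purely as
an interoperability placeholder for pipelines that pre-filter with an
external HMM search; nothing in this package consumes it.

Deduplication collapses byte-identical sequences (lexicographically
smallest id kept) and, when a complete domain is required, drops
heptapeptide-only records; survivors are renamed `<prefix>1..N` by
genome position when gene models are available, else input order.

Molecular weight is the sum of average residue masses plus one water
(reported in kDa); pI is solved by bisection on the Henderson–Hasselbalch
net charge to |charge| < 1e-4 with a Bjellqvist-style pKa table
(N-term 7.5, C-term 3.55, C 9.0, D 4.05, E 4.45, H 5.98, K 10.0, R 12.0,
Y 10.0), shipped as an editable mapping.

## Gene clusters

The cluster rule links two neighbouring family genes when the intergenic
gap (next start − previous end − 1) is **strictly** under `max_gap_bp`
(200,000) and at most `max_intervening_genes` (8, inclusive) non-family
genes lie **fully** between their spans; genes overlapping either
boundary gene do not count. Distance is end-to-start rather than
midpoint- or start-based: "separated by" language describes the
intervening interval, and the choice is recorded in output metadata
since published cluster counts can shift slightly under other
conventions. Unsorted input is an error, never silently sorted.
Internally coordinates are handled 1-based inclusive end to end (the
GFF3 dialect); only BED export converts to 0-based half-open.

When a gene has several mRNAs, the exon set of the longest one (greatest
summed exon length, ties to more exons) represents the gene, matching
the common "longest isoform" convention for structure statistics.

## Promoter cis-elements

Promoters are the 1,500 bp immediately upstream of the translational
start (first CDS base), reverse-complemented for minus-strand genes and
truncated with a warning at contig edges. Matching is exact-degenerate:
the IUPAC consensus is expanded to character classes with no mismatch
tolerance, overlaps allowed, both strands scanned, minus-strand hits
reported at forward coordinates. The shipped dictionary follows
published PlantCARE-style entries; variable-length elements (e.g.
TC-rich repeats) are represented by a canonical core, noted per entry.
Correctness is defined against the shipped file — the dictionary is data,
not code. Per-gene category summaries count distinct element *types*
(a motif hit twice counts once); instance counts are exposed separately
because published per-promoter element lists are type-based while
instance counts are the natural quantity for enrichment work.

## Ka/Ks and dating

Protein pairs are aligned globally (BLOSUM62, gap open 10, extend 0.5 —
a standard protein scheme, configurable) and the alignment is
back-threaded onto codons, stripping one trailing stop codon and
verifying translation residue by residue. Ka/Ks uses Nei–Gojobori (1986)
counting: per-codon synonymous site fractions averaged over both
sequences (changes creating stop codons count as nonsynonymous);
multi-hit codon differences averaged over all minimal substitution
pathways, excluding pathways through stop codons (if every pathway is
blocked, all are used — the standard fallback); ps = sd/S, pn = nd/N;
Jukes–Cantor correction. Proportions ≥ 3/4 are flagged saturated rather
than raising, and the Ka/Ks ratio is undefined (None) when Ks = 0.

A counting estimator was chosen over a maximum-likelihood codon model:
the quantities surveyed here (a purifying-selection screen and a
Ks-based date) do not need codon-frequency or transition/transversion
corrections, the counting method is exactly testable against hand
counts, and the substitution is recorded in the survey's run metadata.
One erratum-level note: in some published method descriptions of this
workflow the letters Ka and Ks are swapped in prose; this package uses
the universal convention throughout — Ka nonsynonymous, Ks synonymous.

Dating is T = Ks/(2λ) with λ = 6.1e-9 synonymous substitutions per site
per year, the rate commonly applied to the bean/soybean split. Note that
with this formula Ks of 0.2–0.3 gives 16.4–24.6 Myr; published roundings
of that interval vary by a few percent depending on the exact Ks
endpoints used, so only the formula itself is treated as reproducible.

## Phylogeny

Distances are p-distances with pairwise deletion (MEGA's protein-NJ
default); model-corrected distances are out of scope. Neighbor joining
follows Saitou–Nei with two determinism guarantees: Q-criterion ties
break on the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf), and negative branch lengths
are clamped to zero with the deficit moved to the sibling edge so path
lengths are preserved. On additive matrices the output realizes the
input distances exactly (tested to 1e-9). Bootstrap resamples alignment
columns with replacement under a seeded generator (default seed 1,
recorded in run metadata); support is the percentage of replicate trees
containing each internal split of the full-data tree, so identical
inputs and seeds give byte-identical Newick.

Subgroup assignment (2a–2e, defined only within group 2) takes the tag
of the smallest tag-pure reference clade containing the query on an NJ
tree over query + panel; if no pure clade exists the query takes its
nearest reference's tag (ties to the lexicographically smallest label)
and the result is flagged "nearest-neighbor fallback", making the
procedure total and deterministic. The panel requires at least two
references per tag. Assignments on real data are panel-dependent; the
package ships no curated panel and accepts any aligned, tagged set.

## Expression

ΔCT is mean CT(target) − mean CT(reference) per sample (replicate-paired
when counts match); ΔΔCT subtracts control from treatment; the ratio
2^−ΔΔCT is reported as a signed fold change (+r for r ≥ 1, −1/r
otherwise) so symmetric induction/repression print as ±r. The |FC| ≥ 2
call threshold applies to the signed magnitude, which deliberately
includes borderline values like −2.02. Significance is a two-sided
Welch t-test on replicate ΔCT values (* p < 0.05, ** p < 0.01) — the
test choice is a package decision, recorded in output, since qPCR
reports rarely name one; a zero-variance degenerate case returns p = 1
or 0 by exact comparison. Gene-level summaries count each gene once by
the direction of its drought-contrast calls, with genotype-only
responders counted under the genotype contrast's direction.

The packaged differential-expression fixture (19 genes × 3 comparisons)
is transcribed verbatim from the source experiment's published table,
including its "expression pattern" labels; calls are indexed by the
fold-change column headers, which in two rows disagree with the pattern
labels — the headers are taken as authoritative.

Atlas breadth uses value > 0 as "expressed" by default (the threshold is
a parameter): constitutive = all tissues, tissue-specific = exactly one
(named), silent = none, intermediate otherwise.

## Synthetic data

Generators are deterministic functions of (parameters, seed) with one
RNG stream per invocation, and every record has exactly one truth row.

* **Proteomes** embed each class's exact domain architecture in random
  background drawn from the 17-letter alphabet without C, H and W. This
  is the no-false-positive guarantee in closed form — every heptapeptide
  variant needs W and every finger needs C and H — so planted truth is
  provably the complete scan result, with no rejection loop. Subgroup
  classes share fixed per-subgroup flanking centroids (seeded
  independently of the call seed, so panels and queries from separate
  calls are comparable) mutated at 2% per site by default; queries at
  zero mutation sit exactly on their centroid.
* **Genomes** plant clusters that satisfy the rule strictly (gaps of
  5–190 kb, 0–3 intervening genes) and isolate every other family gene
  by at least twice the maximum gap, so the planted partition is the
  unique correct answer. Gene models use 1–5 exons with realistic
  exon/intron length ranges.
* **Ortholog pairs** plant single-nucleotide substitutions in distinct
  codons at the Jukes–Cantor inverse of the target rates over NG86 site
  counts, so the estimator recovers the targets up to rounding and the
  slight site-count shift synonymous changes cause (sub-1% in practice;
  the acceptance tolerance is 10%). Defaults (Ks 0.25, Ka 0.05, 500
  codons) emulate a legume ortholog set under purifying selection.
* **qPCR tables** encode per-sample expression ratios as CT offsets of
  −log2(ratio) around a constant reference gene, with optional Gaussian
  cycle noise; the default design replays the packaged fold-change
  table, so the published values (e.g. the 8.14-fold induction) are
  recovered to machine precision at zero noise.
* **Promoters** are uniform-background sequences with planted,
  instantiated motif occurrences; restricting the background alphabet
  (e.g. to A/T for G/C-containing motifs) yields provably motif-free
  backgrounds for exact truth checks.

What the generators do **not** emulate: homology between background
regions, duplication/loss histories, codon usage bias, amplification-
efficiency drift, or real promoter composition. Passing closed-loop
tests therefore demonstrates correctness of the algorithms under their
stated models, not robustness to every artifact of real data.

## Problem sizes and defaults used in checks

The shipped verification runs use 200+ random proteins (≤ 300 aa) for
the scanner oracle, 100+ layouts of 100 genes (20 family) for the
cluster oracle, 30–40 random additive trees of 5–8 taxa for NJ, 20 pairs
of 500 codons for Ka/Ks recovery, 100+ random 300-bp promoters for the
element-scan oracle, and a full synthetic survey (1,000 bootstrap
replicates in the acceptance script) run twice for byte-identical
output. These sizes give stable statistics while keeping the whole
verification suite comfortably desk-runnable.

## Known limitations

* Identification is exact-pattern-based; diverged heptapeptides outside
  the configured set (e.g. WSKY/WVKY forms) are found only if added to
  the config, and no E-value ranking exists.
* NG86 underestimates rates under strong transition bias or extreme
  codon usage; for publication-grade selection inference on real data a
  likelihood codon model should corroborate the screen.
* NJ with p-distances can be inconsistent for highly saturated
  alignments; bootstrap support does not correct model misspecification.
* The 2^−ΔΔCT model assumes perfect doubling efficiency; no
  efficiency-corrected variant is implemented.
* Subcellular-localization prediction and external web-service
  verification are out of scope by design.
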