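# Methods

## The array model

A tRNA array unit is defined as a genomic region, within one contig,
containing at least `min_trnas` tRNA genes at a density of at least
`min_density` tRNA genes per kilobase. The defaults (20 genes, 2.0/kb)
are the definition in the literature on bacterial tRNA arrays; both
comparisons are inclusive — a 20-gene window spanning exactly 10,000 bp
(density exactly 2.0) is an array.

Span is measured end-to-end over the covered interval,
`span = end(last gene) − start(first gene) + 1`, i.e. including the first
and last gene bodies, and `density = count / (span/1000)`. An alternative
convention (start-of-first to start-of-last) differs by at most one gene
length, which at array scale (3–19 kb) shifts density by well under the
reporting precision; the end-to-end convention is the conservative one
(it can only lower density).

## The detection scan

Per contig, over position-sorted tRNA genes (tmRNA genes excluded from the
counted list unless `count_tmrna` is set):

1. Open a window of `min_trnas` genes at the left end.
2. If the window's density is below threshold, slide it one gene (both
   ends advance) and re-evaluate.
3. If it qualifies, register it as a *partial array*, then grow only the
   right end one gene at a time, re-registering after each step that keeps
   the density at or above threshold.
4. The first growth step that drops below threshold — or exhausting the
   contig — finalizes the last registered partial array. The scan resumes
   at the gene after the array's last member.

Consequences worth knowing:

* **Greedy, no lookahead.** Growth stops at the first failing extension
  even if a later gene would restore the density. A very dense far cluster
  does not get merged into a near one; it is found separately on the next
  pass. No "maximal density interval" mode is offered — the greedy scan is
  the defined behavior, and the test suite pins it against an independent
  literal simulation of the procedure.
* **Disjointness and termination** follow from resuming after the
  finalized array. Arrays on one contig never share a gene and appear in
  ascending coordinate order.
* Reported arrays always satisfy both thresholds (each registered partial
  did), which the suite also checks against exhaustive enumeration of all
  qualifying windows.
* Genes with identical starts are totally ordered by (start, end, strand,
  isotype), so runs are byte-reproducible. Overlapping predictions are
  kept as distinct genes; no deduplication is attempted.
* tmRNA genes never count toward `total_trnas` or toward array size or
  density by default, but tmRNAs whose coordinates fall fully inside an
  array's span are attached to it (`tmrna_inside`) — co-residence of tmRNA
  in arrays is a reported genomic feature.

## Isotype synteny classification

Each array yields its isotype string (single-letter amino-acid codes in
genomic coordinate order; selenocysteine U, pyrrolysine O, undetermined X).
Pairwise comparison is global (Needleman–Wunsch) alignment with match +1,
mismatch −1, linear gap −1, and a deterministic traceback preferring
diagonal, then up, then left; identity is matches over total alignment
columns, so gaps count against identity. Arrays are grouped by
single-linkage clustering at an identity threshold, default 0.60.

The threshold is a design choice, not a published constant: published
group assignments tolerate variants that lack or duplicate a few isotypes,
so the default is permissive and is exposed on the CLI (`--threshold`).
Group labels (G1, G2, … by descending size, ties by smallest member id;
singletons keep their own id) are reproducible under input permutation but
need not coincide with any manually curated grouping of real data.
Profiles are read in one linear genomic order regardless of strand;
reverse-complement canonicalization is not applied. `--try-reverse`
additionally tests the reversed letter string for arrays annotated in
opposite orientations.

The duplication screen aligns each arrayed tRNA gene's nucleotide sequence
against every non-arrayed tRNA gene of the genome with the same scoring,
keeps the best-scoring match, and flags identity ≥ 90% (of alignment
columns, i.e. gaps count against) as a possible recent intra-genomic
duplication. An empty background yields identity 0, unflagged.

## Genomic context

GC content is (G+C)/(A+C+G+T) with N excluded from numerator and
denominator; an empty or all-N sequence has undefined GC (`None`, an empty
cell in the TSV), never a fabricated number. Region GC is computed on the
forward strand of the array span only (not span+flanks); genome GC spans
all contigs of the assembly. Flanks default to 2,000 bp per side and are
silently clipped at contig edges — normal in draft assemblies — with the
realized lengths reported and a warning logged.

## The synthetic-genome generator

The generator emulates the input shape of a real survey: multi-contig
draft assemblies whose background base composition has a controlled GC
fraction (bases i.i.d.), with planted dense clusters — tens of genes at
fixed start-to-start spacing — and dispersed background tRNAs placed
uniformly at random subject to a minimum gap from planted regions (and
optionally from each other, `background_min_spacing`, needed to build
guaranteed-negative fixtures). Defaults mirror the scale of real arrays:
76 bp genes and 150 bp spacing give, e.g., 25 genes over 3,676 bp at
6.8/kb, inside the observed 2–9/kb range.

Determinism: one seed drives everything; each contig uses a substream
keyed by (seed, contig index), so appending a contig to a recipe leaves
earlier contigs' sequences unchanged, and identical recipes produce
byte-identical FASTA and prediction files.

What it does *not* emulate — and therefore what passing tests do not show
about real data: gene sequences are random placeholder bases (detection is
purely coordinate-based, but the duplication screen on simulated data is
meaningless); there is no tRNA secondary structure, no codon-usage or
strand bias, no prediction noise (false/missed gene calls), and no
compositional heterogeneity beyond the planted-gene/background contrast.
Recovery tests on planted arrays validate the detector's window logic, not
the upstream gene predictor.

`include_tmrna_at=k` inserts a tmRNA into an extra slot at index k of the
planted cluster (same spacing), so it lands inside the array span and
exercises the tmRNA co-residence report.

## Numerical and degenerate-input choices

* Densities are kept at full float precision internally and printed to two
  decimals in reports; the report parser re-derives full-precision density
  from the integer count and length, so write→parse round-trips exactly.
* Thresholds: `min_trnas ≥ 2`, `min_density > 0`, clustering threshold in
  (0, 1]; violations raise before any work happens.
* Empty inputs are well-defined: an empty prediction file parses to no
  contigs; a genome with no qualifying window reports one line with empty
  array fields (exit 0 on the CLI); an empty report renders as a header
  line only.
* Alignment of an empty profile is an error (arrays are never empty, so
  this only guards direct library misuse).

## Problem sizes in the validation suite

The suite runs the detector against the literal reference simulation on
1,000 random instances of up to 200 genes, against exhaustive window
enumeration on 200 instances, and on 100 seeded synthetic genomes of
120 kb (plus 100 background-only negatives of 400 kb); alignment is
checked exhaustively over all string pairs up to length 4 on a 2-letter
alphabet and on randomized pairs up to length 6. The whole suite completes
in a few seconds on one CPU.

## Known limitations

* The detector reports the greedy scan's arrays, which are a subset of all
  qualifying windows; it is not an optimizer over interval density.
* Group labels depend on the identity threshold; there is no notion of
  statistical support for a grouping.
* GFF3 isotype extraction covers the common `product=tRNA-Xxx` /
  `isotype=` attribute conventions; exotic attribute schemes fall back to
  isotype X (still counted as tRNA genes — the definition counts predicted
  genes, not classifiable ones).
* The ARAGORN dialect accepted here is one of that program's output modes
  (`-fons`-style headers with `[start,end]` coordinate blocks and a `c`
  marker for the complementary strand); other modes should be converted to
  the generic table format.
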