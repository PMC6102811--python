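# Methods

This note documents the models, algorithms and numerical choices behind
`amptile`, what the simulator does and does not emulate, and the
problem sizes used by the test suite and the acceptance script.

## Library simulator

A simulated library is defined by a reference locus, a tiling path of
amplicons over it, a set of per-sample barcodes, and an error profile.

**Reference.** `make_reference` draws i.i.d. bases at a configurable GC
fraction and optionally plants homopolymer runs (8–12 bases of one
nucleotide, ≥100 bp apart, positions recorded as ground truth).  Locus
identifiers follow the `locus_<chrom>_<start>_<end>` convention with
1-based inclusive coordinates in the identifier and 0-based half-open
coordinates everywhere in code.

**Tiling design.** `design_tiling` partitions a locus into `n` amplicons
whose lengths and pairwise overlaps are drawn from configured ranges and
then repaired one unit at a time until the tiling spans the locus
end-to-end; infeasible geometry raises a design error naming the
constraint.  Primers are read off the amplicon ends (the reverse primer
stored in oligo orientation, i.e. reverse-complemented).  Defaults
mirror a realistic study design: six amplicons of 3,500–4,500 bp with
200–400 bp overlaps across a ~23 kb locus, 20 bp primers.

**Barcoding.** Each sample carries one symmetric 16 bp barcode (same
barcode on both primers) behind a shared 5' `GTTAG` padding.  The full
sense-strand molecule template for panel entry *(s, a)* is

```
padding + barcode + amplicon_core + revcomp(padding + barcode)
```

i.e. padding outermost.  The exact concatenation order of padding vs
barcode on real synthesis oligos varies by vendor; padding-outermost is
chosen here because a "5' padding" reads naturally as the outermost
element and the two-level 121 bp search window comfortably covers
padding+barcode+primer under either order.  Padding inclusion in the
clustering composite is a config flag (`clustering.include_padding`,
default on).

**Raw reads.** A molecule with `k` passes yields `k` independently
corrupted copies of its template, reverse-complemented on odd passes
(alternating strand, as successive passes around a circular insert
produce).  Subreads are emitted already adapter-split — one FASTQ record
per pass named `<movie>/<zmw>/<k>` — because the pipeline consumes
subreads, not polymerase traces; the adapter sequence itself is not
modeled.  Pass counts follow a shifted Poisson `1 + Pois(mean − 1)`
(default mean 9.39, matching a deep amplicon run on RS II-class
chemistry), or a constant when configured.

**Error model.** Per base: deletion with `del_rate`; else substitution
with `sub_rate` (to a uniformly chosen different base); insertion after
the position with `ins_rate`, plus `homopolymer_ins_rate` extra inside
runs of one base of length ≥ `run_min` (default 6), where the inserted
base copies the run base.  This reproduces the dominant systematic error
mode of single-molecule amplicon data: recurring +1 insertions in
homopolymeric tracts that survive consensus calling because a majority
of molecules share them.  The default profile is
sub/ins/del = 0.10/0.05/0.04 (≈19 % total, the upper end of raw
single-molecule error).  `protect_ends` copies the first and last *n*
template bases error-free; tests use it to create the "clean end
windows" condition under which exact-match clustering is provably
complete.  All randomness flows from explicit seeds; identical seeds
give byte-identical FASTQ and truth tables.

Not emulated: polymerase kinetics, per-base quality values (qualities
are a constant placeholder and never read), chimeric molecules, adapter
dimers.  Consequently, passing tests demonstrate the pipeline's
behavior under the stated error model, not robustness to library
artifacts outside it.

## CCS construction

Subreads are oriented against a seed (the longest subread; ties go to
the earliest) by choosing, per subread, the orientation with the smaller
edit distance.  A star alignment of all subreads to the seed (global
edit-distance alignment, `edlib`) defines a column set: one column per
seed position plus insertion columns between positions (insertion
strings are padded to the widest insert, non-inserting reads vote a
gap).  Each column is called by majority with deterministic tie-breaks
(gap wins only on a strict majority; base ties resolve A<C<G<T).  The
called consensus becomes the next round's alignment template, iterating
to a fixpoint (at most 5 rounds) — one round is biased by the seed's own
errors; iterating removes that bias.  Star alignment was chosen over
partial-order alignment for transparency and testability; on triples of
lightly corrupted copies it provably matches an exhaustive optimal
3-sequence dynamic-programming alignment (tested).

**Predicted accuracy.** The mean per-column agreement `1 − ε` estimates
the per-pass error rate.  The emitted value is the consensus-scale
accuracy `P[Binomial(n, ε) ≤ ⌊n/2⌋]` — the probability that errors do
not form a majority in a column of `n` passes.  A single-pass molecule
has ε = 0 by construction and accuracy 1.0, so the default filter
(minimum 1 pass at 0.90) never rejects single-pass reads; error-free
multi-pass molecules also score exactly 1.0.  This is a surrogate for
the proprietary instrument-side predicted-accuracy model, deliberately
simple and fully determined by the data.

## Clustering

`match_primer_pair` is an exact substring test: a read is *sense* for a
panel entry if the forward probe occurs wholly within the first
`search_space` bases **and** the reverse-complement of the reverse probe
within the last `search_space` bases; *antisense* if the
reverse-complemented read passes the same test (sense is tested first —
a deterministic tie rule for palindromic pathologies).  One-level mode
probes are the bare primers (window default 21 bp); two-level mode
probes are `padding+barcode+primer` composites (window default 121 bp,
sized for barcode+padding+primer plus slack).  A CCS matching exactly
one entry is assigned; more than one is `ambiguous`, zero is
`no_match` — ambiguous molecules are never assigned, because one wrong
molecule pollutes an entire polishing cluster, while dropping one only
costs depth.  An optional Hamming tolerance (`max_mismatch`, default 0)
exists for robustness experiments and is off by default.  Whitelists are
written one molecule identifier per line per non-empty cluster, named
`<sample|nobc>__<amplicon>.whitelist.txt`.

Both primers are required.  Molecules whose CCS lost a flank therefore
go unassigned — visible in the worked example in the README — which is
the intended trade of completeness for purity.

## Cluster polishing

`polish_cluster` is a deterministic iterative majority polisher standing
in for likelihood-based polishing (the single largest declared
substitution in this package; no vendor dependency, and the clustering
being tested upstream determines what gets polished either way).  Each
round: orient every subread to the current template (initial template =
longest subread), align globally with `edlib` (distance bound
`max(100, 0.45·len)` for speed, falling back to unbounded), and vote
per column exactly as in CCS construction, except base-column ties
prefer the current template's base (stability) before the fixed order.
Insertion columns are voted column-wise, so a systematic insertion
carried by enough subreads to deny the gap a strict majority is
retained — this is what lets homopolymer +1 errors shared by ≥60 % of
copies survive, as they do in real data.  Iteration stops at a fixpoint
(zero edits between successive templates) or `max_iters` (default 5).
Polishing its own output returns it unchanged (tested idempotence).

`consensus_all` counts all whitelisted subreads (optionally filtered by
`min_subread_length`, default 0), filters clusters with fewer than
`min_subreads` (default 100; evaluation uses 0), and orients emitted
consensus sequences to the panel's forward-primer sense.  A whitelisted
molecule missing from the subread source is a hard error listing the
identifiers, since it signals upstream corruption.

Measured behavior at the defaults: 100 subreads at ~10 % error polish a
3 kb template to ≥99.9 % identity (usually exactly); at ~19 % error a
residual ~0.1–0.3 % remains, concentrated at short homopolymers where
alignment paths split votes — the same plateau real pipelines show.

## Tiling assembly

`find_overlaps` detects suffix–prefix (dovetail) overlaps: a probe of
the right member's prefix is located in the left member's tail
(`edlib` infix mode), then the implied overlap is verified by a
prefix-anchored alignment; an edge requires overlap ≥ `min_overlap`
(default 40 bp) and identity ≥ `min_identity` (default 0.94 — AMOS
minimus-style conventions; both config-exposed).  Arrangements are
normalized so the left member is forward; both orientations of the
right member are tried; the best edge per pair is kept.

`layout_consensus` places members by BFS from the longest member,
checking redundant edges for consistency (orientation must agree and
offsets match within 20 bp, else an assembly error).  Members are merged
left-to-right into a running column list by aligning each next member's
prefix onto the working consensus.  Final per-column conflict rules:

* 1 voter → its base;
* 2 voters agreeing → the base; disagreeing (including base vs gap) → `N`;
* ≥3 voters → the plurality base; ties → `N`; a strict gap majority
  drops the column.

`N` positions therefore mark exactly the two-voter disagreements and
multi-voter ties, and are exported as a BED file alongside the layout
TSV and assembly FASTA.  `trim_ends` removes `trim_bp` bases from each
consensus end before assembly (default: the panel's barcode+padding
length, since that is the extraneous sequence on amplicon consensus
ends).  Assembly is per sample when barcoded.  On an error-free
simulated tiling path the contig equals the reference substring exactly
(tested round-trip).

## Evaluation

`align_and_report` aligns a query locally to every locus on both strands
(match +1, mismatch −2, gap open −5, gap extend −2 via Biopython's
`PairwiseAligner`; the open/extend values approximate common
megablast-style defaults at that match/mismatch ratio and are
config-exposed).  Percent identity is `100·matches/alignment_columns`
with `columns = matches + mismatches + inserted + deleted bases`;
classification is *complete* (100 % identity, whole query aligned),
*truncated* (100 % identity, partial span — e.g. untrimmed barcode
ends), *partial* (<100 %), or *unmapped*.  `classify_errors` decomposes
total error into insertion, deletion and substitution fractions,
counting indel **bases** by default ("single nucleotide" errors =
substitutions); event-based counting (indel runs) is available behind a
flag because the base-vs-event convention is genuinely ambiguous in
common usage.

`bootstrap_experiment` draws, per amplicon, `d` CCS identifiers with
replacement (d = 1..40 by default, 25 replicates each), pools the
corresponding raw subreads (a molecule drawn twice counts twice),
polishes with the support filter at 0, assembles each replicate's
consensus set, and aligns everything to the reference.  The subread
depth of an assembly is the minimum depth over its member clusters.
The full default grid over 8 amplicons yields exactly
8 × 40 × 25 = 8,000 consensus records.  Everything is deterministic for
a fixed seed.

On simulated data this harness reproduces the qualitative findings it
was built to measure: accuracy rises with depth and saturates at 100 %
when errors are unbiased, while enabling the homopolymer insertion bias
caps accuracy below 100 % at any depth and makes insertions dominate
the error decomposition.

## Problem sizes in tests and the acceptance script

The simulator defaults are study-scale (3.5–4.5 kb amplicons, ~23 kb
locus); the test suite and `scripts/acceptance.py` run the same
machinery at reduced scale so the whole suite completes in minutes on
one CPU.  Chosen sizes, as the package's own test design:

* clustering study: 6 samples × 6 amplicons of ~680–780 bp over a
  3.4 kb locus, depth 20 (720 molecules), mean 9.39 passes,
  sub/ins/del = 0.05/0.03/0.02 with `protect_ends=121`;
* consensus fidelity: 100 single-pass subreads of a 3 kb template at
  ~10 % error;
* bootstrap (scaled): 4 amplicons of ~700–800 bp, depths
  {1, 2, 4, 8, 16} × 10 replicates; homopolymer-bias variant with 6
  planted runs and `homopolymer_ins_rate=0.4`;
* bootstrap (full grid): 8 amplicons of 200–240 bp, zero error, single
  pass, depths 1..40 × 25 replicates — exercising the complete
  experiment bookkeeping at trivial per-record cost.

## Known limitations

* Polishing is majority-vote, not likelihood-based: per-base qualities
  are ignored and heterozygous/phased alleles are out of scope (clusters
  are assumed to come from homozygous material).
* Exact-match clustering drops molecules with any end-window error;
  completeness on real data depends on CCS end fidelity.
* Containment overlaps (one consensus inside another) are handled by
  the dovetail machinery only insofar as a dovetail edge exists; true
  repeat resolution and general-purpose assembly are non-goals.
* The exhaustive-MSA consensus oracle is exponential in sequence count
  and is exercised at 3 sequences × ≤24 bp; larger instances are
  computationally out of reach for an exact check.
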