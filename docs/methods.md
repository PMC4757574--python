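# Methods

## The problem

Sequence-specific endoribonucleases ("RNA interferases", e.g. the MazF
toxins of bacterial toxin–antitoxin systems) cleave single-stranded RNA at
short recognition motifs — usually 3, 5 or 7 nt.  `cleavemap` implements a
sequencing-based assay for discovering that specificity: a pool of
synthetic substrate RNAs of near-uniform base composition is digested by
the enzyme, cleavage-derived 5′ ends are tagged by ligating a 45-nt barcode
RNA, and paired-end short reads of the library are analyzed for positions
where read coverage steps up sharply — the footprint of many molecules
beginning at the same cleaved phosphodiester bond.

## The analysis model

**Read preparation.**  Reads are quality-trimmed by the modified-Mott rule:
base *i* scores `limit − 10^(−Q_i/10)` (default limit 0.05) and the
retained subread is the contiguous window with maximal score sum (ties:
earliest end, then earliest start — a documented deterministic choice;
trimming is idempotent).  Reads whose trimmed sequence still contains more
than `max_ambiguities` N bases (default 0) are rejected.  The 3′-terminal
15 nt of the barcode (`CTGGCTTTGATGAAA`, the *anchor*) is then located by
exact substring search in the read and, if absent, in its reverse
complement; everything strictly 3′ of the leftmost anchor is the candidate
fragment, and fragments shorter than 15 nt are discarded.  Exact search is
provably equivalent to the legacy workbench score model (match +1,
mismatch/gap cost 5, minimum match score 15): any single edit inside a
15-nt anchor leaves at most 14 − 5 = 9 < 15; the test suite verifies the
equivalence by dynamic programming over every single-edit anchor variant.
Consecutive anchors (barcode concatemers) are consumed entirely, so a
prepared fragment never begins with the anchor.

**Mapping.**  Prepared fragments must match a reference substring exactly,
full-length, zero mismatches or indels, in the orientation fixed by the
anchor search.  Comparisons use a canonical T-alphabet so DNA reads map
onto RNA references.  Fragments with two or more exact placements
(dominated by the substrates' shared poly(A) tails) are *multimapped* and
excluded — a deterministic, conservative alternative to random placement
that cannot fabricate a coverage step.  Mapping equals a naive
every-position scan by construction and by test.

**Coverage step statistic.**  Per reference, `coverage[n]` counts mapped
fragments whose interval contains *n*, and the relative coverage increase
is `rci[n] = coverage[n] / coverage[n−1]`, undefined (not 0, not ∞) where
`coverage[n−1] = 0`.  Candidate cleavage positions must have `rci` defined
and `coverage[n]` strictly greater than `min_coverage` (default 1000; the
filter applies at the stepped-up position *n*, and strictness is
configurable since ">1000" is ambiguous between > and ≥).  Qualifying
positions are ranked by `rci` descending (ties: larger coverage, then
smaller position) and the top 5 per reference are kept.  The stepped-up
nucleotide is numbered 0; the cut falls between positions −1 and 0.

**Motif model.**  Windows of ±5 nt around each zero position (N-padded at
reference edges; N reduces the column total rather than being imputed) are
stacked into a 4×11 position frequency matrix.  Column information content
is `2 + Σ_b f_b log2 f_b` bits over non-N counts, uncorrected for small
samples by default (a flag enables the standard `3/(2·ln2·n)` correction;
logo renderers differ on this, so the uncorrected formula is the
documented contract).  A column is *called* when IC ≥ 1.0 bit and the
modal base frequency ≥ 0.8; the reported motif is the maximal contiguous
run of called columns containing position 0 (or −1 when 0 is uncalled).
With no such run the tool reports "no conserved motif".  These two
thresholds are the package's own rule — the assay literature reports
logos, not a call rule — and were chosen so that a 3-nt recognition site
supported by ~25 windows is called decisively while the nonspecific
control (below) never is; both are tunable.

## The simulator

The generator emulates the library chemistry end to end and is the
package's test bed:

| parameter | default | meaning |
|---|---|---|
| n_refs × ref_length | 5 × 1000 nt | diverse regions, uniform over {A,C,G,U} |
| head / tail | GGG / 30 nt poly(A) | transcription start and stabilizing tail (total 1033 nt) |
| motif, cut_offset | ACA, 0 | every occurrence is a cleavage site; cut 5′ of base `cut_offset` |
| p_cleave | 0.9 | per-site, per-molecule cut probability |
| background_break_rate | 1e-4 per bond | nonspecific hydrolysis |
| n_molecules | 1000 per reference | digested substrate copies; partial digestion across the pool is what produces fragment diversity |
| ligation_efficiency | 0.1 | probability a fragment 5′ end receives the 45-nt barcode (the kinase step is folded in; the value echoes the ~9% barcode-bearing read recovery typical of this chemistry) |
| read_length | 250 | MiSeq v2-like 2×250 pairs |
| n_read_pairs | 750 000 | pairs drawn uniformly from the fragment pool |
| error_rate | 0 | per-base substitution errors (Q36 everywhere) |

R1 is the first 250 nt of the (possibly barcoded) fragment; R2 is the
reverse complement of its last 250 nt and exercises the
reverse-orientation anchor search.  A truth table records every read's
fragment of origin and whether its 5′ end is a cleavage end.

`n_read_pairs = 750 000` is chosen so that anchored coverage depth
(~0.1 × 1.5 M reads × ~69 nt mean fragment length over 5 165 reference
positions ≈ 1 900×) comfortably clears the fixed `min_coverage = 1000`
candidate filter, reproducing the regime in which that filter is
meaningful.  At, say, 200 k pairs the same arithmetic gives ≈ 540× and the
filter would reject every position — depth and threshold must be scaled
together, which is what the reduced-depth test configurations do
(120 k pairs with `min_coverage 150`).

**Negative control.**  `nonspecific_control_config()` models a
structure/sequence-nonspecific nuclease by disabling motif cleavage and
raising the background break rate to 0.01 per bond (~10 breaks per
1033-nt molecule), so the substrates fragment on the same scale as in a
motif-directed digest.  The spec of a *control* requires comparable
fragmentation: at the background default of 1e-4 almost nothing fragments
and the control would be vacuous rather than discriminating.

**What the simulator does not model** (and hence what green tests do not
show about real data): PCR duplication and amplification bias, positional
quality decay, indel sequencing errors, RNA secondary structure (the real
substrates are designed to avoid it), structure-guided cleavage of an
RNase III-type enzyme (emulated only as uniform breakage), incomplete
kinase treatment as a separate step, and enzyme sequence preferences
beyond a single exact motif.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; every exported table is
  1-based inclusive and says so in a header comment.
* Quality encoding is fixed to Phred+33; no autodetection.
* RCI at `coverage[n−1] = 0` is NaN and such positions can never be
  candidates; with the default depth regime the choice is immaterial.
* Flat-coverage ties (rci exactly 1.0 everywhere) resolve to the smallest
  positions — visible in degenerate tests, irrelevant once any true step
  exists.
* An all-N PFM column has IC 0 and is never called.
* Empty FASTQ input, zero candidates, and zero windows are tagged errors
  or explicit "no candidate" reports, never silent successes.
* Byte-identical reruns: FASTQ/TSV outputs are deterministic functions of
  the configuration and seed (the logo image is exempt from the
  byte-level guarantee).

## Problem sizes used in the checks

The automated checks run the full pipeline at simulator defaults
(5 × 1033 nt references, 750 k read pairs, 1000 molecules per reference)
over 20 seeds per planted enzyme (ACA cut 5′ of A; UAC cut between U and
A) and 10 seeds of the nonspecific control; reduced-depth configurations
(120 k pairs, `min_coverage` 150) are used for file-route smoke tests.
Substrate k-mer saturation is evaluated on a five-substrate synthetic
stand-in pool generated by the simulator itself: the pool reproduces the
qualitative saturation profile of designed substrate sets (all 64
triplets present; heptads far from saturation, ~26%), and all counts are
verified against an independent brute-force counter.  Designed
maximal-diversity substrates differ from random ones in their exact
quartet/pentad percentages, so those two figures are characteristic of
the stand-in pool, not of any particular published substrate set.

## Known limitations

* Only one motif per enzyme is called; enzymes with degenerate or multiple
  recognition sites would blur the PFM rather than yield two calls.
* Recognition sites longer than the ±5 window (7-base cutters) are out of
  reach of both the window and the substrates' heptad diversity.
* Exact mapping means a single sequencing error discards a read; at the
  simulator's default error rate of zero this is moot, and at realistic
  MiSeq error rates it costs depth, not correctness.
* The genome-wide motif-free transcript scan depends on the annotation
  release of the genome supplied; its counts are reported, not asserted.
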