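# cleavemap

Cleavage-specificity mapping of RNA interferases (sequence-specific
endoribonucleases, e.g. bacterial MazF toxins) from barcoded 5′-end
sequencing of digested synthetic substrate RNAs.

Bacterial toxin–antitoxin systems deploy endoribonucleases that cleave
single-stranded RNA at short recognition motifs (typically 3–5 nt).
Discovering a new enzyme's motif is the experimental bottleneck this
toolchain addresses: a pool of designed substrate RNAs of near-uniform
base composition is digested in vitro, cleavage-derived 5′ ends receive a
45-nt barcode RNA by ligation, and the library is sequenced paired-end.
In the mapped reads, a cleaved bond shows up as a *coverage step*: many
reads begin at the same reference position *n*.  `cleavemap` quantifies
this with the relative coverage increase

    rci[n] = coverage[n] / coverage[n−1]

takes the top-5 stepped positions per reference among those with
coverage > 1000, stacks ±5 nt windows around each (the stepped-up base is
numbered 0; the cut falls between −1 and 0), and summarizes the 25 windows
as a position frequency matrix with per-column information content
`2 + Σ_b f_b log2 f_b` bits.  Columns with IC ≥ 1 bit and modal base
frequency ≥ 0.8 form the called motif; a nonspecific digest yields
"no conserved motif".

The package also ships:

* a **read simulator** implementing the full generative model (motif-directed
  digestion with per-site cleavage probability, background breakage,
  partial-efficiency barcode ligation, MiSeq-like 2×250 pairs, complete
  ground-truth tables), so every pipeline stage is testable without
  downloads; and
* a **substrate evaluator**: k-mer saturation of a substrate pool
  (what fraction of the 4^k possible words it contains, which bounds the
  motif lengths the assay can resolve) and a scanner for motif-free
  transcripts.

For whom: molecular microbiologists characterizing toxin ribonucleases,
and method developers who need a reproducible, fully simulated version of
a degradome-style 5′-end assay.

## Worked example

Simulate an enzyme that recognizes UAC and cuts between U and A, then run
the complete analysis in memory:

```python
from cleavemap import SimulationConfig, run_simulated

result, sim = run_simulated(SimulationConfig(seed=1, motif="UAC", cut_offset=1))
print(result.report_line)
```

prints

```
consensus=UAC, span -1..+1, cut between -1 and 0, support 25 windows
```

meaning: across the five simulated 1033-nt substrates, the 25 stacked
windows are unanimous over three consecutive columns, U at −1, A at 0 and
C at +1 — the cut (always between −1 and 0) falls between U and A, and the
coverage step sits on the adenine.  Of 1 500 000 simulated reads, 114 494
(7.63%) carried the barcode anchor and survived preparation, and 99.98% of
those mapped uniquely — the rest of the library is unligated background,
just as in the real chemistry.  The per-column information content shows
the motif sharply:

```
-5: 0.06  -4: 0.01  -3: 0.01  -2: 0.01  -1: 2.00
+0: 2.00  +1: 2.00  +2: 0.29  +3: 0.02  +4: 0.02  +5: 0.07
```

The same workflow is available from the shell, stage by stage or end to
end:

```sh
cleavemap simulate --seed 1 --motif UAC --cut-offset 1 --out-dir sim/
cleavemap run-all --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
         --refs sim/references.fasta --out-dir out/
cleavemap kmers --refs sim/references.fasta --k 3 --k 4 --k 5 --k 7
cleavemap motif-free --refs transcripts.fasta --motif UAC
```

`run-all` writes the prep report, mapping summary, per-position
coverage/RCI table, candidate table, PFM, sequence logo and a one-line
motif report under `out/` (all positions 1-based in the files), and exits
nonzero if no candidate position qualifies.

See `docs/methods.md` for the model, parameter meanings, defaults and
their rationale, and known limitations.

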