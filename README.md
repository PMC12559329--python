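# nickloop

Analysis toolkit for reconstituted-biochemistry studies of trinucleotide
repeat instability on looped circular DNA substrates.

When a CAG/CTG repeat tract slips during replication or repair, one strand
of the duplex extrudes an extrahelical loop (e.g. a 12-nt (CAG)₄ loop-out).
Which strand gets nicked, and exactly where relative to the loop, decides
whether the repeat subsequently **expands** (the strand opposite the loop is
incised 5′ of it and displacement synthesis copies the loop, inserting
(CTG)₄) or **contracts** (the looped strand is incised one nucleotide 3′ of
the loop and the loop is excised). `nickloop` implements the two bespoke
computational procedures such experiments need, on top of a fully synthetic
data layer, so every stage is testable without any external data:

1. **Strand-specific nick mapping at single-nucleotide resolution**
   (`nickloop.gloesim`, `nickloop.nickmap`) — 3′-OH-capture (GLOE-seq-style)
   single-end reads are aligned against the circular plasmid reference
   concatenated three times; unique alignments starting in the middle copy
   are kept, and a read aligned to the top strand reports a cut on the
   bottom strand (and vice versa) at the base paired across its 5′-most
   mapped position. Loop-spanning reads that fail the duplex-only pass are
   rescued against the looped-strand reference.
2. **Simulated-reference Sanger-trace decomposition**
   (`nickloop.tracedecomp`) — a mutant chromatogram is expressed as a
   non-negative mixture of reference traces fabricated by inserting or
   removing bases in the control sequence at the target site
   (shifts −15…+15 nt). For observation vector *y* (window scans × 4
   channels) and template matrix *X*, the model is

   *y* = *X f* + ε,  *f* ≥ 0,

   solved by active-set NNLS; standard errors come from the
   variance–covariance matrix σ̂²(X_S′X_S)⁻¹ of the unconstrained normal
   equations on the active set *S* (df = n − |S|), with a two-tailed
   *t*-test per component. The per-shift fractions f_s quantify, e.g., the
   (CTG)₄ insertion frequency (repeat expansion, shift +12) or the loss of
   the (CAG)₄ loop (contraction, shift −12).

`nickloop.substrates` builds the circular heteroduplex substrates and
predicts expansion/contraction product sequences; `nickloop.pipeline` and
the `nickloop` CLI tie everything together.

## Worked example

The numbered scripts under `analysis/` reproduce the full study flow on the
standard synthetic substrate (3,200-nt circular plasmid, (CAG)₄ loop on the
top strand at position 1000, generator seed 7). For instance:

```sh
$ python analysis/02_map_nick_profiles.py
[fan1_loop3prime] totals={'n_input': 20000, 'n_unique_primary': 20000, 'n_rescued': 0, 'n_ambiguous': 0, 'n_unmapped_final': 0}
  exact per-read recovery: 19997/20000 (99.98%)
  cut fraction on looped strand: 1.000
  modal looped-strand cut: +1 nt from the loop 3' boundary (plasmid coordinate 1000)

$ python analysis/03_expansion_decomposition.py
planted (CTG)4 insertion fraction: 0.155
mean recovered over 20 replicates: 0.1524 (sd 0.0011)
dominant component correct in 20/20 replicates
single-replicate call: +12 nt insertion matching the loop complement (expansion) (fraction 0.151, R^2 0.9994)
```

The first run plants the FAN1-with-RFC–PCNA incision scenario (a dominant
nick on the looped strand one nucleotide past the loop), simulates 20,000
75-nt reads, and the pipeline recovers essentially every read at its exact
cut position, with the modal cut exactly 1 nt downstream of the loop 3′
boundary. The second mixes mutant traces at a 15.5% insertion frequency and
the decomposition recovers 15.2 ± 0.1%, identifying the insert as the
12-nt loop complement. `analysis/04_contraction_decomposition.py` likewise
recovers ~75% shortening signal, dominated by the −12 nt component, from
mixtures planted at 75% loop loss. All outputs (per-position cut tables,
BED, polar plots with the looped strand in red and the opposite strand in
black, decomposition tables and trace plots) land under `results/`.

Equivalent one-off runs are available from the CLI
(`nickloop substrate make`, `nickloop gloesim reads`, `nickloop nickmap run`,
`nickloop tracedecomp simulate|decompose`,
`nickloop demo expansion|contraction`).

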