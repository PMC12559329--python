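# Methods

## Substrate model and coordinate conventions

A substrate is a circular duplex plasmid (top strand = the FASTA sequence,
5′→3′; bottom strand its reverse complement) with an extrahelical loop of
length L on one strand, inserted between duplex positions i−1 and i of the
carrier strand in that strand's own 5′→3′ sense. All coordinates are
0-based and circular (mod length). Cut profiles index both strands by
plasmid (top-strand) coordinate with a strand flag — one canonical frame —
and segregate loop-internal positions into loop-local coordinates, since
they have no duplex image. `HeteroduplexSubstrate.profile_bin` is the
single projection used by both the simulator's truth bookkeeping and the
cut caller, so the two sides cannot drift apart.

The standard substrate used by the analyses is a synthetic random plasmid:
3,200 nt, GC 0.5, generator seed 7, with a (CAG)₄ (12-nt) loop on the top
strand at position 1000. It stands in for the real looped plasmid at the
same scale and architecture; its exact sequence is immaterial to every
result, and a real plasmid FASTA can be substituted via
`load_plasmid`/`substrate make --fasta`. The substrate generator warns if
the loop sequence occurs elsewhere in the plasmid (repeat context makes
loop-spanning reads multi-map); a random 3.2 kb sequence contains (CAG)₄
with probability ~2×10⁻⁴.

Product prediction: expansion inserts the reverse complement of the loop
into the opposite strand across the loop site (both strands N+L);
contraction excises the loop (both strands N). These sequences feed the
trace-mixture simulations below.

## Read simulation and the nick-geometry contract

A nick at index p on strand s is a broken backbone between p and its 3′
neighbour; the base at p carries the free 3′-OH that the capture chemistry
marks. The emitted read is a substring of the *complementary* strand,
starting at the base paired with the 3′-OH nucleotide and extending in that
strand's 5′→3′ direction. The wet protocol's exact ±1 adapter phasing is
not published; this package therefore defines correctness as simulator/
caller round-trip identity under this one documented convention, which is
shared by `gloesim` and `nickmap`. A 3′-OH inside the loop is unpaired; its
read starts across the first paired base 3′ of the loop, so such nicks
(which no bundled preset plants) collapse onto loop3′+1 in any caller.

Defaults that define the simulated study conditions: 75-nt fixed-length
reads (a truncated-geometric option mimics sonication spread), constant
high base quality (carried, never used), substitution errors at a
configurable rate (0 for the recovery benchmarks, 10⁻³ in the demo runs),
20,000 reads per scenario run and 50,000 for the deep round-trip benchmark.
Sampling uses an explicit inverse-CDF draw from the normalized intensity
vector, making fixed-seed output byte-identical.

Scenario presets: `mutl_opposite_5prime` places a decaying series of 10
discrete peaks (25 nt spacing, first peak 10 nt 5′ of the loop, decay
length 120 nt, 5% uniform background) on the strand opposite the loop —
all 5′ of it, so the 3′-OHs prime synthesis toward the loop;
`fan1_loop3prime` places 95% of intensity at looped-strand coordinate
loop3′+1 with 5% uniform background; `uniform` is the flat control. Peak
spacings and decay are simulation choices at the scale of discrete
incision-site patterns seen on blots; no published per-site intensity table
exists to calibrate against.

## Cut calling

The reference is the circular sequence concatenated three times, so every
read shorter than the plasmid has a non-wrapping alignment; unique
alignments are canonicalized to a start in the middle copy [N, 2N) and
shifted by −N, which counts each circular locus exactly once and avoids
edge artifacts (an all-copies-mod-N mode is provided for comparison with
external aligners that pick an arbitrary copy). The internal aligner is an
exact k-mer seed (k = 20) + ungapped extension with ≤ 2 mismatches; with
three or more disjoint seeds per 75-nt read, every alignment within the
mismatch budget is found (pigeonhole). Equal-score hits at distinct
circular loci are ambiguous — counted, never dropped. External SAM against
the exported 3× reference is accepted as a drop-in primary pass.

Cut assignment inverts the read geometry: a plus-orientation hit at plasmid
start s is a bottom-strand cut at s; a minus-orientation hit over
[s, s+len) is a top-strand cut at s+len−1. Reads the duplex pass cannot
place (typically loop-spanning) are re-aligned against the looped-strand
reference; the default keeps the loop in that reference and reports
loop-internal cut coordinates loop-locally rather than projecting them onto
the duplex. The alternative reading — deleting the loop from the
second-pass reference — is implemented behind `exclude_loop_from_rescue`,
but for a top-strand loop it degenerates to the primary reference, which is
why the loop-retaining reading is the default. Duplicates are not collapsed
(no UMIs in the protocol). Raw counts are primary; CPM is provided for
cross-run comparison and polar plots show raw counts.

Read-count conservation (n_input = unique + rescued + ambiguous +
unmapped) is enforced at finalization and raises on violation. A read left
ambiguous by either pass and not rescued is reported ambiguous.

## Chromatogram model and decomposition

One scan per called base; channel b at scan t carries
exp(−λt)·Σ_k f_k·[seq_k[t] = b] plus N(0, σ) noise clipped at zero
(λ = 0.001/base, a gentle decay over a ~250-scan read-out; σ defaults to
0.01 of the initial amplitude). The noiseless model is exactly linear in
the mixture fractions, which is what makes template decomposition exact in
the noiseless limit. No inter-scan peak spreading or mobility shifts are
modelled — real traces would first need base-calling and per-scan peak
quantification (AB1 parsing is out of scope; traces are exchanged as
per-scan TSV).

Templates for shifts −15…+15 are fabricated from the control sequence
itself: positive shifts insert the expected repeat unit phased in 3-nt
steps ((CTG)ₙ prefixes for the expansion read-out), negative shifts delete
at the target site. The fitting window starts 5 scans downstream of
target_site + max shift and spans 80 scans — downstream of every template's
edit, where the shifts dephase the sequence frames; no published window
exists, so these are declared defaults.

The fit is active-set NNLS with covariance-based two-tailed t-tests
(σ̂²(X_S′X_S)⁻¹ on the active set, df = n−|S|), α = 0.001, no
multiple-testing correction by default, Bonferroni exposed. Two refinements
are on by default and matter quantitatively:

* **Baseline regressor.** Zero-clipping gives every near-zero channel a
  positive mean (~0.4σ). A constant column absorbs most of this floor;
  its coefficient is excluded from the fractions.
* **Supported-set refit.** A first NNLS pass over all templates leaves
  ~half of the spurious components active with small positive (half-normal)
  coefficients; because fractions are normalized to the coefficient sum,
  that inflates the denominator and biases every reported fraction downward
  by O(σ) (measured: −0.019 at σ = 0.02 for a 0.7 planted fraction). The
  fit is therefore re-run restricted to the components significant at α in
  the first pass. With both refinements the measured recovery bias is
  within ±0.006 for planted fractions 0.1–0.7 at σ ≤ 0.02; the trade-off
  is a detection floor — true components too small to reach significance in
  the first pass are dropped rather than estimated.

Reported signal uses two normalizations side by side, since it is ambiguous
whether published trace-signal percentages are relative to the decomposed
signal or the total trace: fractions of the decomposed signal (primary) and
the same rescaled by R² (share of the total including the unexplained
residual).

### Significance calibration

Per-component t-tests after non-negativity selection are post-selection
inferences: conditional on a null component staying active, its t-statistic
is positively truncated, and the two-tailed test at level α rejects with
probability ≈ α per active component. The *per-shift* spurious-significance
rate is therefore controlled at α (measured 14 spurious significant shifts
in 30,000 shift tests over 1,000 null replicates at α = 0.001). The
*per-run* ("any spurious indel") rate is necessarily ≈ n_active·α — about
1.4% here — for any uncorrected per-component test; users needing
familywise control at α should set `bonferroni=True`, which multiplies
p-values by the number of non-control shifts and brings the measured
per-run null rate to the α level.

## What the synthetic layer does and does not show

The generators emulate the *geometry* of the real data (circular substrate
scale, loop architecture, strand-specific 3′-OH read geometry, read length,
scenario-shaped incision profiles; per-base trace model with decay and
noise). They do not emulate PCR duplicates, adapter artifacts, indel
sequencing errors, coverage biases, peak spreading/mobility shifts, or the
sequence-specific incision preferences of the real nucleases. Passing
round-trip and recovery benchmarks therefore validates the *pipelines* —
that cut positions and indel fractions planted under the documented
conventions are recovered at single-nucleotide / percentage-point
accuracy — not any biological claim about the enzymes themselves.

## Problem sizes and numerical choices

Benchmarks use 50,000 reads (deep round trip), 20,000 reads (scenario
runs), 20 replicate traces for expansion recovery, 10 for contraction, and
1,000 null replicates for calibration — sizes at which the sampling error
of each measured quantity is comfortably below its tolerance. NNLS is
scipy's active-set implementation; a condition number > 10¹² on the
active-set Gram matrix raises a degeneracy error naming the collinear
shifts (fully repeat-periodic contexts can make shift templates identical).
Zero-mapped-read profiles normalize to zero without error; empty loops
degenerate cleanly (the substrate becomes a plain duplex and the rescue
reference equals the primary one).
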