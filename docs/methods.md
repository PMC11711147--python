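# Methods

## Quantification model

Each array sample is measured in two channels: IP (anti-m6A
immunoprecipitated RNA) and Sup (supernatant). For transcript *t* on sample
*s* the modified percentage and total expression are

    percent-m6A(t, s) = 100 · IP_n / (IP_n + Sup_n)
    expression(t, s)  = IP_n + Sup_n

where IP_n, Sup_n are linear-scale normalized intensities. When several
probes map to one transcript their normalized log2 signals are averaged per
channel first (the default synthetic fixture uses one probe per transcript).

### Spike-in normalization

Every array (sample × channel) carries exogenous spike-in probes at a common
nominal level. With anchor `s[s,c]` = mean over spike-ins of
`log2(raw + ε)`, and `G` the grand mean of all anchors,

    log2_norm = log2(raw + ε) − s[s,c] + G.

Subtraction on the log2 scale is division on the linear scale, so any factor
multiplying all probes of one array cancels exactly; `G` merely restores an
interpretable fluorescence scale and cancels from every downstream ratio.
The additive floor ε (default 1.0 fluorescence unit) guards `log2(0)` on
real extractions. ε biases very low signals toward the floor, so the
exact-recovery tests on strictly positive simulated intensities run with
ε = 0; with the default ε the same recoveries hold to ~1e-3 rather than
1e-9, which is immaterial at array signal levels but not below the exactness
tolerance.

An alternative reading of spike-in anchoring — dividing linear intensities
by the linear spike-in mean rather than subtracting the log2 mean — differs
only through Jensen's gap on the spike-in set; with identical spike-in
levels per array the two coincide. The log2-subtraction form is used
throughout.

## Differential screening

Both layers use the pooled-variance (Student's) two-sample t-test — chosen
over Welch deliberately, as the classical two-group array analysis — on:

* methylation: raw percent-m6A values (a `meth_on_logit` option tests
  log2-odds instead; fold changes are unaffected);
* expression: log2 expression.

Fold change is the ratio of group mean percentages (methylation) or
`2^Δ(mean log2)` (expression), sci over sham. A transcript passes the screen
when fold change ≥ 1.5 — boundary inclusive, reading the cutoff as a
minimum — or ≤ 1/1.5, with raw p < 0.05. Degenerate rows with zero pooled
variance get p = 1 when the means agree and p = 0 otherwise.
Benjamini–Hochberg adjusted p-values are computed within each
layer × biotype stratum and reported, but screening deliberately uses raw
p-values; the adjusted column is diagnostic.

## Nine-quadrant integration

The conjoint analysis crosses the methylation axis {hyper, ns, hypo} with
the expression axis {up, ns, down} at the stricter gate |log2FC| ≥ 1
(fold change ≥ 2, boundary inclusive) AND p < 0.05 per axis — both gates,
since the conjoint lists are intersections of "differential" lists. Every
transcript lands in exactly one of the nine cells; a mode (hyper-up,
hyper-down, hypo-up, hypo-down) is called only when both axes are non-ns.
Discordant modes are computed and reported even though the concordant pair
is the biologically highlighted one.

## lncRNA positional classes and cis targets

Coordinates are 0-based half-open (BED convention) everywhere. The six
positional classes are assigned by precedence: exon-sense-overlapping
(overlaps a coding gene, same strand) → intronic (contained in a coding
span, same strand) → natural-antisense (overlaps, opposite strand) →
intronic-antisense (contained, opposite strand) → bidirectional (TSS within
1 kb of a coding TSS, opposite strand, no overlap) → intergenic. With
span-only annotation (no exon structure), containment implies overlap, so
the two intronic classes are unreachable in practice; they become meaningful
only if exon-resolved annotation is substituted. This is a documented
limitation, not a bug: the precedence order is kept so exon-aware inputs
slot in without behaviour changes elsewhere.

A cis pair is a lncRNA and an mRNA on the same chromosome whose span-to-span
gap is at most the window (default 100 kb, inclusive; overlap counts as
distance 0), strand-agnostic. Span boundaries rather than TSS anchor the
distance — the simplest defensible convention when no anchor is specified.
lncRNA enrichment maps a lncRNA list to the union of its cis-target mRNA
symbols and runs the ordinary over-representation test on that list.

## Enrichment

One-sided hypergeometric upper tail, `p = P(X ≥ k)` with
`X ~ Hypergeom(N, K, n)` (scipy's survival function; the test suite checks
it against exact rational tail sums to 1e-12). The universe defaults to the
annotated transcripts of the matching biotype — the array background, the
convention for microarray enrichment — not the genome. Only
over-representation is tested; BH adjustment runs across sets; results sort
by p-value with set-id tie-breaks.

## MCODE

Vertex weight = (highest k-core number of the node's closed neighbourhood) ×
(density of that highest k-core); nodes under the degree cutoff (default 2)
are unscored. Complexes grow from the highest-weighted unused seed,
admitting unvisited neighbours with weight ≥ seed weight × (1 − vwp),
vwp = 0.2 by default (the plugin defaults: haircut on, fluff off, no loops).
Nodes touched by an expansion are never reused, so clusters are disjoint.
The haircut strips members with in-cluster degree < 2, iterated, but stops
at two nodes so a lone interacting pair survives as a minimal module — on a
star graph with vwp = 0 this collapses every candidate below the size floor
and returns nothing, which matches a hand trace of the seeded expansion.
Cluster score = 2E/(n−1) = density × n; ranking by score, then size, then
seed id, makes output independent of node input order. PPI edges require
combined score strictly greater than 0.4 (the wording "greater than" read
literally; STRING's own ≥ 0.4 convention is one configuration flag away).

## Synthetic experiments

The generator emulates the 3-vs-3 two-channel design at desk scale (2,000
mRNA + 500 lncRNA by default):

* baseline modified fraction π ~ Beta(2, 18) (mean 10%, typical m6A
  stoichiometry); baseline expression E = 2^N(10, 1.5);
* planted effects: methylation on the log-odds of π (logit-additive, so the
  percentage stays in (0, 100) for any effect size; default +1 log2 unit,
  i.e. odds doubling), expression on log2 E (default 1.5 log2 units);
  planted modes hyper-up / hypo-down / hyper-only / up-only are split across
  biotypes proportionally to pool sizes;
* noise: per probe × sample × channel multiplicative 2^N(0, 0.25); per
  array × channel scale factor 2^N(0, 0.25) that normalization must remove;
* spike-ins: one shared nominal level (2^10), scaled only by the array
  factor — never by biological noise — so the anchor is exactly
  identifiable and its test is sharp;
* geometry: mRNAs in 300-kb slots on five chromosomes (neighbours always
  farther apart than the cis window); each lncRNA anchors to a random mRNA
  either within the window (a controllable `cis_fraction`, slightly negative
  gaps producing occasional overlaps) or at 135–150 kb, outside it.

The truth table records the expression effect directly and the methylation
effect on the percent scale (`log2(π_sci/π_sham)`) — the scale the pipeline
estimates — not the odds scale it was planted on.

What the generator does **not** model: multiple probes per transcript,
dye bias, spatial artifacts, background fluorescence, heavy-tailed or
intensity-dependent noise, correlated transcripts. Passing tests therefore
demonstrate correctness of the computations under the stated generative
model, not robustness to real-array pathologies.

### Detection power at the default conditions

For an odds-scale effect of 1 log2 unit with per-channel noise 0.25, the
replicate log2-odds of the percentage has sd 0.25·√2 ≈ 0.354, giving the
3-vs-3 pooled t-test a noncentrality of 1/(0.354·√(2/3)) ≈ 3.46 and
theoretical two-sided power ≈ 0.74 at α = 0.05 — before the fold-change
gate, which costs more. A direct 50,000-transcript evaluation of the
generative model puts asymptotic hyper-call sensitivity at ≈ 0.67, and the
full pipeline measures ≈ 0.61–0.65 across seeds. This is a property of the
design (three replicates, this noise level, this effect size), invariant to
the baseline methylation distribution on the log-odds scale; detecting such
effects at ≥ 90% sensitivity would need larger effects, more replicates or
less noise. The noise-free recovery checks instead plant a 3-log2-unit odds
effect, chosen because an odds-doubling can never move the percent-scale
fold change past the conjoint gate of 2 (the percent ratio is 2/(1+π) < 2
for any π > 0), so concordant modes would be unrepresentable at effect 1.

## Numerical and I/O choices

* All output reals print with 12 significant digits; written tables re-read
  bit-equivalently at that precision, and reruns (same inputs, same config)
  are byte-identical. The run manifest records the exact configuration and
  input paths; `run_from_manifest` replays it.
* Problem sizes in the test suite (hundreds to a few thousand transcripts,
  graphs of ≤ 50 nodes, 1,000-gene interval scans) are desk-scale choices
  that keep the whole suite under a minute while exercising every code path
  at full numerical fidelity.
* Ties: enrichment results order by (p, set_id); MCODE seeds and members by
  (−weight, node id); cluster ranking by (−score, −size, seed id).
* Degenerate inputs: empty study lists, missing channels, absent spike-ins,
  sub-replicate groups and malformed tables raise typed validation errors
  naming the offending sample/row/line.

## Known limitations

* The intronic lncRNA classes require exon-resolved annotation (above).
* The pooled t-test on percentages is approximate for fractions near 0 or 1;
  the logit option is sounder there but departs from the classical
  percent-scale convention, so it is off by default.
* Enrichment treats gene sets as flat lists (no ontology propagation, no
  pathway topology).
* MCODE fluff post-processing is not implemented (off in the reference
  plugin defaults).
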