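# Methods

This note documents the model implemented by `openadj`, the conventions and
parameters that matter, what the simulator does and does not emulate, and the
design choices made where the method leaves room.

## Model and definitions

A **breakend** is an oriented genomic position (chrom, pos, orient): a break
between nucleotides n and n+1 produces the counterpart pair (n, +) and
(n+1, −), where "+" retains the lower-coordinate side. All internal
coordinates are 1-based nucleotide indices; BEDPE/BED on disk (0-based
half-open) is converted at the I/O boundary, with the breakend position of
each side taken as the end coordinate of its 1-bp interval. An **adjacency**
is an unordered pair of breakends fused in the derivative genome; it is
stored in canonical order (chrom, pos, "+" before "−", uid) so that endpoint
order never affects results.

Rearrangement histories are sequences of **k-breaks** (cut at k locations,
re-fuse all 2k ends) under two assumptions: no breakpoint reuse, and no new
telomeres (circular products are allowed and may be lost, producing
deletions). An adjacency {x, y} is **closed** when {x′, y′} is also an
adjacency of the history — forced for k = 2 — and **open** otherwise; open
adjacencies arise only from k > 2. Openness is detected through two
signatures:

1. **Counterpart-asymmetry.** Breakends are matched into counterpart pairs
   {x, x′} when (i) they lie on the same chromosome within distance D with
   x ≤ x′, (ii) they are convergent (x is "+", x′ is "−"), (iii) they do not
   themselves form a detected adjacency, and (iv) no other breakend lies
   strictly between them. An adjacency {x, y} is counterpart-asymmetric when
   a matched counterpart of one endpoint is fused to a breakend other than
   the other endpoint's counterpart.
2. **Copy-number asymmetry.** Δ(x) := N(x′) − N(x) collapsed to sign; an
   adjacency is copy-asymmetric when Δ(x) ≠ Δ(y). Because fused breakends
   change copy number together under no-reuse, closed adjacencies are
   copy-symmetric; asymmetry certifies openness.

Per adjacency set Ã: OAR = |O|/|Ã| (O = either signature; a lower bound on
the (k>2)-break adjacency fraction) and CAE = |C| / (2 p_Δ (1−p_Δ) |Ã|)
(C = copy-asymmetric subset, p_Δ = fraction of breakends with Δ ≠ 0). CAE
derives from a Bernoulli model — endpoint copy changes are {−1, 0}-valued
with rate p_Δ, dependent within 2-break adjacencies and independent within
multi-break ones — under which a multi-break adjacency is asymmetric with
probability 2 p_Δ (1−p_Δ); dividing |C| by that rate makes CAE an unbiased
estimate of the multi-break fraction. CAE is undefined at p_Δ ∈ {0, 1} and
reported as NaN.

## The Δ step function in practice

Copy evidence comes from a segmentation, not base-level copy numbers. For
every internal boundary between consecutive segments with different values,
an interval of length L is centered on the boundary midpoint (the window
covers L consecutive positions placed symmetrically around the half-integer
midpoint; with even L this is exact). A breakend is matched to an interval
iff it lies inside it and is the *unique* breakend of the analyzed set
inside it; a breakend inside two overlapping intervals is treated as
ambiguous and left unmatched. Matched breakends receive Δ = the sign of the
copy change read across the breakend *toward its counterpart side*: the
left-to-right boundary sign for "+" breakends and its negation for "−"
breakends. This oriented reading is what makes both flanks of a deletion
read Δ = −1 and keeps closed adjacencies copy-symmetric; reading the raw
left-to-right sign at both flanks would mark every deletion adjacency
asymmetric.

Further conventions: boundaries are only formed between segments whose gap
is at most L (copy number is undefined across larger gaps); chromosome ends
produce no boundary; Δ magnitudes are discarded because absolute tumor copy
number is unreliable; gains (Δ = +1) participate in p_Δ and in the
asymmetry comparison even though the CAE derivation assumes deletions only —
a documented model approximation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| D | 2000 bp | maximum counterpart distance; generous relative to typical breakpoint localization, accommodating small "deletion bridges" at junctions |
| L | 10 kb | boundary-interval length; tolerates segmentation boundary error |
| min_set_size | 15 | smallest adjacency set retained in cohort analyses; below this OAR/CAE are too granular |
| scope | per-set | counterpart evidence restricted to the analyzed set; `genome-wide` pools all sets of a genome |

`sweep-d` exposes the orientation spectrum of close breakend pairs over a
grid of D values: the convergent (+,−) class is compared against the
uniform null of 0.25 with a one-sided exact binomial test.

## Statistical procedures

Group comparison of OAR/CAE uses the Mann-Whitney rank-sum test: an exact
permutation null when both groups have 2–8 members (ties handled by
mid-ranks), otherwise the normal approximation with tie correction.
Two-sided by default with a one-sided option, since the directional
hypothesis (one-off > stepwise) is often pre-specified. Correlation with an
external per-set multi-break fraction annotation k̂ uses Pearson's r with
the usual t-based p-value and requires at least three annotated sets with
nonzero variance.

## Simulator

`simulate_history` applies k-breaks to a reference of named chromosome
lengths: each event samples k distinct cut bonds uniformly over the linear
retained chromosomes, then a uniform perfect matching on the 2k free ends
conditioned on no counterpart re-fusion (every break is effective; for
k = 2 this leaves the two aberrant repair configurations, sampled
uniformly). Circular products are lost with probability `circle_loss_p`
(default 1, the deletion interpretation); retained circles contribute copy
number but are not cut by later events — a simulator convention. The true
copy profile is derived as maximal constant-coverage segments, plus a
constant offset of 1 for the unrearranged homologue, so a flat diploid
background reads 2 and a heterozygous deletion reads 1.

`observe` collects the novel fusions present on retained derivative
chromosomes, drops each independently with probability `dropout_p`, and
jitters breakend positions with integer Gaussian noise (sd `jitter_sd`,
clipped at ±3 sd, orientation preserved); segmentation boundaries can be
jittered likewise. The truth fraction (share of observed adjacencies from
k > 2 events) is computed after dropout.

Two placement constraints are on by default and matter for the validation
suites: cut bonds keep a minimum spacing (default 3·D = 6 kb) from *all*
other cuts of the history, and an edge margin (default 50 kb) from
chromosome ends. With spacing above both D and the interval half-width
L/2, exact-resolution matching and Δ assignment provably have no spurious
candidates, which is what makes the guarantees sharp: across seeded exact
simulations, zero truth-closed adjacencies are flagged (either signature),
every flagged adjacency has a multi-break truth label, and OAR never
exceeds the truth fraction. Setting `min_spacing=0` gives a "realistic"
mode where clustered breakpoints can create false counterpart candidates —
the regime CAE is designed to be robust to.

What the simulator does *not* emulate: sequence-level artifacts (read
support, microhomology), breakage-fusion-bridge cycles, subclonal mixtures,
duplications (rearrangement without re-replication only ever loses
sequence, matching the deletions-only CAE model), and caller-specific error
profiles. Passing tests therefore show correctness of the method under its
own model assumptions plus simple dropout/jitter noise — not robustness to
every failure mode of real SV calling.

The Bernoulli cohort generator (`bernoulli_cohort`) implements the CAE
derivation's random model directly (endpoint Δ pairs, no genome), with the
multi-break share fixed at round(frac·n) to isolate estimator bias from
composition noise. Calibration at n = 2000 adjacencies and 50 seeds puts
|mean CAE − truth fraction| well below 0.05 for p_Δ ∈ [0.2, 0.8].

## Validation problem sizes

The validation suites run on two 80-Mb chromosomes with histories of 5–20
events (100 seeded runs for the exact-mode guarantees), 500 random dense
instances of up to 200 breakends for brute-force equivalence, and cohorts
of 20 + 8 simulated genomes for the rank-sum separation check — sizes
chosen to exercise every code path while keeping the full suite in a few
seconds.

## Known limitations

* OAR depends on counterpart matching and hence on breakend clustering;
  densely clustered calls can inflate it (CAE exists precisely to provide a
  clustering-independent estimate).
* Both measures are local: they score each adjacency independently and do
  not attempt to reconstruct the global k-break history.
* The CAE derivation assumes deletions only; gain-heavy genomes push it
  outside its model.
* Intra-tumor heterogeneity and purity/ploidy are not modeled; the copy
  input must already be segmented.
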