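# Methods

This note documents the models and conventions behind `cladeprimer`, the
choices made where several defensible conventions exist, and what the
synthetic tests do and do not demonstrate about real data.

## Matching model

Matching is substitution-only: a primer of length L is compared against
every length-L template window, and a position is a mismatch iff the IUPAC
sets of the primer base and the template base are disjoint. Degeneracy in
the primer is therefore "free" — an R over an A or a G is a match — which is
the convention under which a well-designed non-degenerate primer scores 0
against its own target and under which published degenerate community
primers are normally screened. Indels, thermodynamic duplex stability,
primer-dimer formation and 3′-end mismatch weighting are all out of model;
a mismatch at the 3′ terminus counts the same as one at the 5′ end.

Orientation semantics: a forward primer is compared as written against the
+ strand; a reverse primer is compared 5′→3′ against the reverse complement
of each + strand window. All footprints are reported in 1-based inclusive
+ strand coordinates; mismatch positions are primer-relative (1 = the
primer's 5′ base). Hits are sorted by (mismatch count, start), which makes
scans deterministic.

## Primer properties

* **GC%** is the expected G+C fraction over the uniform mixture of concrete
  oligos a degenerate primer encodes: S counts 1, the two-base codes
  containing one of G/C count 1/2, D/H count 1/3, B/V count 2/3, N counts
  1/2. For non-degenerate primers this is the ordinary GC fraction. This
  convention was fixed because one bundled published primer (AAA641F) is
  degenerate and its printed length and GC are mutually inconsistent, so a
  package-level definition was needed; the printed sequence is treated as
  authoritative throughout.
* **Tm** defaults to the Wallace rule 2(A+T) + 4(G+C) on expected counts.
  Published primer tables often use undisclosed, salt-corrected
  calculators, so Tm values are reported for orientation but never asserted
  against published numbers; the calculator is a pluggable callable.
* **Degeneracy** is the product of per-position set sizes.

## Product sizes

The bundled published primer pairs are described by their sources with
product sizes equal to rev_end − fwd_start of the printed binding
coordinates (186, 1191, 212 bp), one less than the inclusive footprint span.
Both numbers are carried on every prediction (`product_size_reported`,
`product_size_inclusive`) rather than silently picking one. Amplicon
pairing requires the forward footprint strictly upstream of the reverse
footprint (non-overlapping) and an inclusive product ≤ 5000 nt by default —
a generous conventional PCR ceiling that bounds the pairing combinatorics.

## Coverage and specificity tables

A sequence is "covered" at allowance m if it carries at least one footprint
at ≤ m mismatches anywhere along its length; levels are cumulative, so the
"3+" column means ≤ 3 and both columns are monotone non-decreasing in m.
Out-group hits count *sequences*, not sites. Sequences shorter than the
primer count as not covered rather than erroring, since partial records are
common in reference databases. The pair-coverage variant counts a sequence
only when both primers hit in amplifiable orientation; its coverage can
never exceed the smaller single-primer coverage.

The mismatch report gives, per primer, the minimum mismatch count over all
strand-appropriate footprints, optionally restricted to a known binding
window. The restriction keeps footprints *intersecting* the window (rather
than contained in it) because published windows are occasionally off by one
against the primer length, making containment impossible.

## Phylogenetics

Identity and p-distance are computed over columns where both rows carry a
concrete A/C/G/T; gaps and ambiguity codes are excluded alike. This is
conservative and reproducible; it discards a small amount of signal from
ambiguity codes. An error is raised when no comparable column exists.

The Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is defined for
0 ≤ p < 3/4; p at or beyond saturation raises rather than returning
infinity, forcing the caller to decide how to treat saturated pairs.

Neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion. Two conventions make it deterministic and well-formed:

* Q-ties are broken by the smallest (i, j) index pair in current matrix
  order (row-major argmin).
* A negative edge produced by the branch-length formulas is clamped to 0
  and its deficit moved to the sibling edge, preserving the pair's summed
  length; at the final trifurcation negative edges are clamped to 0.

On additive matrices NJ reproduces the generating tree's topology and path
lengths to machine precision (asserted at 1e-9). The implementation is
cross-checked in the test suite against scikit-bio's independent `nj` on
simulated data; scikit-bio is never the implementation path. No multiple
aligner is included: amplicons cut at identical coordinates are already
columnwise comparable, and alignment of heterogeneous data is out of scope.

## qPCR quantification

The standard curve is an ordinary least-squares fit of Ct against
log₁₀(copies) over a serial dilution (≥ 2 points with distinct copy
numbers; two points give the exact interpolating line). Efficiency uses the
field convention E = 10^(−1/slope) − 1, so the ideal slope −log₂10 ≈ −3.32
gives E = 100%. Copies per reaction invert the curve,
10^((Ct − intercept)/slope), and scale to copies per gram wet weight by
elution_volume / template_volume / mass_extracted. These three parameters
are explicit inputs with neutral defaults of 1.0 — published environmental
copy numbers depend on extraction metadata that is rarely reported, so the
conversion is parameterized rather than calibrated. Replicate aggregation
reports mean, sample SD (ddof = 1; 0 for a single value), median and
quartiles by linear interpolation (type 7), the convention fixed so
boxplot-style summaries are reproducible. Non-detects are an explicit "ND"
in plate tables, excluded from statistics and reported as a count.

## Synthetic data generator

`generate_reference_db` emulates the structure of a clade-specific
coverage/specificity study: an in-group clade sharing one concrete
realization of each (possibly degenerate) primer site planted in a random
ancestor, per-sequence background substitutions outside the footprints, and
a scheduled number of planted mismatches inside them; plus an out-group
that either lacks the sites entirely or carries both sites degraded by a
fixed mismatch count. Planted mismatches substitute to a base *outside* the
primer's IUPAC set at that position (positions drawn without replacement
among non-N primer positions), so every planted mismatch is a true mismatch
under the matching model, and background mutations never touch footprints,
so planted counts are exact. All generators are pure functions of
(config, seed).

Defaults are study-like and fixed once: in-group 109 sequences (the size of
the GOM Arc I clade in the SSU reference release the field analysis of
these primers used), out-group 200 (a desk-scale stand-in for a
half-million-sequence database), templates 1600 nt (full-length *mcrA*
scale), the McrA159F/McrA345R pair planted at its published coordinates
(159 / ending 345), background rate 0.02 substitutions/site, and a planted
mismatch ladder of 70/10/10/10% at 0/1/2/3 mismatches giving a Table-style
coverage ladder of 70/80/90/100%. Plate simulation defaults mirror
triplicate reactions on duplicate extractions (six reactions per sample),
a tenfold standard ladder 10¹–10⁷ copies, Gaussian Ct noise σ = 0.2, and an
ideal-efficiency curve (slope −3.3219, intercept 40).

What the generator does **not** emulate: realistic phylogenetic
autocorrelation within the in-group (members are independent perturbations
of one ancestor), GC skew and compositional bias, indels, chimeras, partial
records, or the taxonomic fine structure of a real non-target database.
Passing the synthetic suite therefore shows that scanning, pairing,
coverage accounting and quantification are *correct as specified*, not that
any particular primer is specific against a current reference snapshot —
the latter requires running the same operations against a real database,
which the package supports but does not ship. Likewise, published
mismatch counts against specific GenBank genomes are reproducible only
after fetching those accessions; the bundled catalog carries the primer
sequences and published binding windows needed to do so.

JC evolution along a tree substitutes each site with probability
(3/4)(1 − e^(−4d/3)) per edge, uniformly to one of the three other bases —
the exact JC transition kernel, so observed p-distances converge on the
closed-form expectation (verified within binomial error at 10 kb).

## Problem sizes in tests

The oracle-equality acceptance check uses 50 databases of up to ~35
sequences × 400 nt against a pure-Python brute-force scanner; NJ recovery
uses 100 simulated 5-taxon alignments of 10 kb; qPCR recovery uses 200
simulated plates. These sizes give stable statistics (recovery and
agreement sit at 100% across seeds) while keeping the whole suite fast.

## Known limitations

* No thermodynamic model: two primers with equal mismatch counts are
  treated identically regardless of mismatch position or identity.
* Coverage counts any footprint anywhere on the sequence unless a window is
  supplied; on real full-length genomes a spurious distant low-mismatch
  footprint would count as coverage.
* NJ is O(n³) with dense matrices; it is intended for amplicon sets of tens
  to a few hundred taxa, not database-scale trees.
* The p ≥ 0.75 saturation error means deeply divergent pairs must be
  handled (filtered or re-modeled) by the caller.
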