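# Methods

## Scope and model

`nrpsmith` predicts nonribosomal peptide structure from NRPS domain
architectures under a strictly linear, co-linear model of biosynthesis:
one module incorporates one monomer, in gene order across the
synthetase proteins of a cluster. Iterative and non-linear assembly
logic is deliberately out of scope, as are A-domain specificity
prediction (monomer candidates are consumed as input from external
predictors), de-novo domain scanning (domain tables from
InterProScan-class tools are input), multiple alignment, and phylogenetic
classification.

## Architecture parsing and module segmentation

Architecture strings are hyphen-separated fields; superscript/subscript
markup (`^`, `_`) and case are ignored before alias matching, so
`^L^C_L_`, `LCL` and `lcl` are the same token. Unknown fields are
errors naming the field and its position — never silently mapped to the
generic X token.

Segmentation scans left to right: a condensation-superfamily token
closes any open module and opens a new one; an A token opens a module
when none is open; T/E/Te/Cy/PKS attach to the open module; tokens
before the first module form a non-monomer prologue (leading T or PKS
segments occur in real clusters and must not count as modules). Two
consequences follow from the one-A-per-module invariant: the module
count always equals the A-domain count, and a trailing C-type domain
with no following A (the fungal terminal Ct) attaches to the previous
module as a release domain. Tandem C-C without an intervening A is kept
in one module and flagged; in domain-table mode the context rules later
resolve it to E + DCL, and re-segmentation of the relabelled tokens puts
the E into the preceding module where it acts.

Coordinates are 0-based half-open internally and 1-based inclusive in
all on-disk tables and reports. Module indices are 1-based and
assembly-global, matching how practitioners number modules.

## Down-Seq delimitation and active site

The Up-Seq is the annotated C-core hit as given (its exact right edge
depends on the upstream scanner and is not second-guessed). The
Down-Seq runs from the core end to the next domain start, or to the
protein end for terminal domains. The expected spacer is 165±10 aa;
lengths outside that band raise `SPACER_ATYPICAL`, and outside a hard
band of [130, 210] aa additionally `SPACER_EXTREME`. The hard band
admits both the ~150-aa typical Down-Seq and the 171-aa length of the
TIGR01720 region found after E-domain cores; both bounds are
configurable. Atypical lengths are never errors — real annotations are
noisy — only overlapping annotations are.

The HHxxxDG active-site finder returns the leftmost exact window; if
none exists it allows at most one mismatch among the flanking fixed
positions (H1, G7) while requiring the catalytic H2 and D6 exactly,
since the second histidine performs the proton abstraction/re-addition
and the aspartate is equally invariant. This mismatch policy is a
heuristic of this package, kept deliberately conservative.

## Signature models and scoring

Per subtype, the model is an ordered list of window position-frequency
matrices (PFMs) over a background distribution: two windows (WL1, WL2)
for C-starter and Ct, three (plus WL3) for LCL, DCL, dual C/E and E.
Choices, with defaults and rationale:

* **pseudocounts** — `f(a,i) = (count + α·bg(a)) / (nongap + α)` with
  α = 0.5 distributed by background; gap and X mass are excluded from
  the numerator and reported as a gap fraction.
* **information content** — Schneider–Stephens:
  `R = max(0, log₂20 − H − e_n)` with the small-sample correction
  `e_n = 19/(2·ln2·n)`; letter heights are `f·R`, so they sum to R by
  construction.
* **degenerate signatures** — residues with frequency ≥ 0.5 are majors
  (capitals), those in [0.15, 0.5) are bracketed alternatives, positions
  with neither are wildcards `x`. Multi-major positions are
  parenthesized so render/parse round-trips losslessly.
* **scoring** — per-residue log-odds in bits against the background,
  with PFM frequencies floored at 1e-3 (so a never-observed residue
  costs ~4.3 bits rather than −∞), X contributing 0 and gaps a flat
  −2-bit penalty. Background defaults to uniform (1/20); a
  Robinson–Robinson table is provided as an alternative.
* **window placement** — a model's windows must occur in order
  (WL1 < WL2 < WL3) without overlap; the joint optimum is found by
  dynamic programming over offsets, ties resolved toward the smallest
  offsets. The ordering constraint prevents a strong WL2 match from
  being picked up twice in short regions.
* **window length** — 12 residues by default (the classical C6/C7 core
  motifs are ~7–12 residues), configurable per window.

No "official" signature matrices ship with the package: models are
trained from user-supplied aligned Down-Seq blocks (`signatures build`),
with windows located as the non-overlapping stretches of maximal summed
information content, again by DP. The bundled example models used in
tests and examples are generated deterministically from random
consensus motifs — they define the synthetic benchmark, they are not
signatures of real domains.

## Classification thresholds

A signature call requires the best model's combined score to reach 60%
of that model's self-consensus score (its ceiling) and to beat the
runner-up by ≥ 3 bits; otherwise the verdict is UNKNOWN. No numeric
cutoffs exist in the literature for this formulation; these defaults
were calibrated once on the synthetic null (i.i.d. background Down-Seqs
score far below threshold, planted ones far above) and are exposed as
parameters. Eβ is never predicted by signature — with a single known
example no signature can be extracted — and enters only via explicit
annotation.

The tandem C-C context rule requires no intervening A-domain and an
inter-core gap of at most 210 aa. The gap cap mirrors the spacer hard
band because the first core's Down-Seq (150–171 aa) always lies between
consecutive cores; a materially smaller cap would never fire on real
annotations.

Reconciliation prefers the signature verdict, falls back to context
when the signature is UNKNOWN, and flags (rather than hides) conflicts
between two confident calls.

## Isomery rules

R1 (E in module *i* → D at *i*), R2 (dual C/E leading module *i* → D at
*i−1*), R3 (DCL leading module *i+1* without an E in module *i* →
D_UNCONFIRMED at *i*), R4 (Ala candidate + alanine racemase present →
D_UNCONFIRMED). D is absorbing and beats D_UNCONFIRMED; rules only warn,
never error (e.g. `E_WITHOUT_DCL`, `CE_NO_PRECEDING`). R3 yields
D_UNCONFIRMED rather than D because the DCL itself performs no
epimerization — the D state is expected at that junction but its source
(upstream E on another protein, trans-racemase, annotation gap) is
unverified, and overcalling D would contaminate catalog matching.

The chromophore offset (pyoverdins) is an explicit caller decision: the
side-chain prediction gains a position-1 chromophore call and every
module's reported position shifts by one. It is never inferred from
sequence. Catalog matching treats UNKNOWN and D_UNCONFIRMED isomery as
compatible with both L and D entries by default (strict mode available);
entries of different length never match.

## Synthetic generator

The generator emulates the geometry the classifier relies on: a
300-residue Up-Seq with the HHxxxDG motif planted at a recorded offset
(resampled in the rare case a spurious earlier match would shadow it), a
Down-Seq spacer drawn uniformly on [155, 175] aa, and the subtype's
windows planted in order at random non-overlapping offsets, each
position emitting the consensus residue with probability 0.9 (the
signal strength) and a background draw otherwise. A/T/Te placeholders
are plain background with recorded coordinates. Emitted domain tables
label every C/E core as generic `C?` spanning the Up-Seq only — exactly
what a domain scanner reports — so subtype recovery is a genuine test.

What the generator does **not** emulate: indels within windows,
positional correlations, phylogenetic relatedness between sequences,
compositional bias of real proteomes, and scanner noise on annotation
boundaries. Passing synthetic benchmarks therefore demonstrates the
machinery (delimitation, scanning, thresholds, rule application) under
the stated geometry, not classifier accuracy on real domains — for real
use, models must be trained on real aligned Down-Seq blocks.

Benchmark sizes used by the test suite (chosen to exercise the
statistics at comfortable depth): 200 Down-Seqs per subtype for the
accuracy property, 20–50 replicates for planted-recovery and
determinism checks, and a few dozen random assemblies end to end.

## Known limitations

* Architecture-string mode trusts subtype labels as given; only
  domain-table mode with generic C labels exercises classification.
* Context rule 1 (C-starter) needs the true protein start; fragmentary
  proteins will miscall it.
* The catalog matcher compares monomer names literally; it knows nothing
  of monomer chemistry or derivative relationships.
* Only linear co-linear biosynthesis is modelled; branched, iterative or
  trans-AT systems are out of scope.
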