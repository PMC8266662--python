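# Methods

## Orientation of single-molecule replication tracks

A fibre is an ordered list of non-overlapping analog tracks (IdU from the
first pulse, CldU from the second) on a genome-mapped molecule. Tracks are
grouped into structures by a greedy left-to-right scan that prefers event
readings over pairs of independent forks:

| pattern | reading | event anchor |
|---|---|---|
| IdU·CldU | rightward fork | — |
| CldU·IdU | leftward fork | — |
| CldU·IdU·CldU | initiation (fired during pulse 1) | centre of the IdU track |
| CldU·IdU·gap·IdU·CldU | initiation (fired before pulse 1) | centre of the inter-IdU gap |
| IdU·CldU·IdU | termination (merged during pulse 2) | centre of the CldU track |
| IdU·CldU·gap·CldU·IdU | termination (not yet merged) | centre of the inter-CldU gap |
| lone intact CldU | initiation (fired during pulse 2) | track centre |
| lone IdU, broken lone CldU | unoriented | — |

Two adjacency tolerances govern the grammar. Within one fork, an
IdU-to-CldU gap is a labelling/detection artifact: `max_fork_gap`
(default 3 kb). Between the facing same-analog tracks of a diverging or
converging pair the gap is genuinely pre- or un-replicated DNA whose width
grows with the firing/merging time offset (at ~3.7 kb per minute for
~2 kb/min forks), so it has its own wider tolerance, `max_event_gap`
(default 10 kb ≈ a 2–3 min offset). Both are configurable; the defaults are
deliberate, explicit stand-ins for what microscopists judge by eye.

A lone CldU track is read as a second-pulse origin only when both its ends
are intact: if the track is cut by a fibre break it is indistinguishable
from a truncated passing fork, and its centre estimates nothing, so it is
left unoriented.

Direction is then assigned per fibre: structure interiors carry their fork
directions (shared event tracks split at the anchor); every unlabelled
interval is split at its midpoint with each half inheriting the direction
of the adjacent fork; the *outer* half of a fibre-end gap is never
assigned, because the fork serving it could have come from an unobserved
origin beyond the molecule. Consequently oriented segments tile the
**assignable span** — from the leading-gap midpoint to the trailing-gap
midpoint — exactly once on a fully oriented fibre, not the whole molecule.
A track flagged broken abuts the fragment boundary by construction, so the
segment simply ends at the break with no midpoint extension.

Coordinates are 0-based half-open; midpoints round down to integer bp.
Floor-rounding makes reflection symmetry exact only when coordinate sums
are even; the randomized symmetry tests therefore draw coordinates on an
even lattice (combing measurements are ~kb-scale, so 1-bp parity carries no
information). Greedy scanning resolves genuinely ambiguous strings (e.g.
IdU·CldU·IdU·CldU with all gaps small) deterministically in favour of the
leftmost event; such strings do not arise from well-separated structures.

## Profiles

Coverages are binned by exact bp overlap; the binned RFD is the ratio of
summed coverages `(R − L)/(R + L)`, undefined (NaN, omitted from bedGraph)
where total coverage is zero — never coerced to 0, which would fake
balanced replication. The OEM at a window boundary is the drop in
normalised leftward coverage, algebraically `(RFD_{i+1} − RFD_i)/2`; the
(I − T) profile counts initiation minus termination events in
non-overlapping windows. All window sizes default to 10 kb.

`call_zones` reports maximal runs of at least `min_run` boundaries with
OEM ≥ `threshold` (initiation zones) or ≤ −threshold (termination zones),
optionally merging same-kind runs separated by at most `merge_within`
boundaries; a zone's centre is the |OEM|-weighted mean boundary position.
Defaults (`threshold=0.1`, `min_run=1`, `merge_within=0`) suit sharp,
efficient zones. Broad zones need care: under the default two-zone model
the termination-zone OEM trough is only ≈ −0.03 (see below), so the
validation suite derives thresholds from the model's analytic OEM (half
the extremum per sign) with `min_run=2, merge_within=5` for the broad TZ —
fixed from the model before any simulation is scored, not tuned to one.

## Fork speed

With pulse duration `t` (default 20 min per analog): both tracks intact →
`v = (d_IdU + d_CldU)/(2t)`, position = centre of the combined span; one
track broken → `v = d_intact/t`, position = centre of the intact track;
both broken → no measurement. Speeds are kb/min with 1 kb = 1000 bp; the
combing stretching factor is upstream of this tool's inputs.

## Read-based (OK-seq style) RFD

Oriented reads carry an explicit fork direction; the BED reader's
`convention` flag maps strand to direction (`fork`: + is rightward, used by
this package's own files; `okseq`: a forward-strand Okazaki fragment marks
a *leftward* fork). Binned RFD uses read-bp overlap by default (the same
coverage definition as for combing segments) or read midpoints
(`count_mode="reads"`). Subsampling draws `n` reads without replacement,
`draws` times, each draw on an independent counter-derived substream of the
user seed, so ensembles are reproducible bit for bit. Profile comparison
uses Spearman rank correlation over jointly defined bins (midranked ties),
delegated to scipy.

## Fork-travel kinetics

For an exponentially growing culture, `T_S = f_S · T_doubling`. A fork
whose origin fires in quarter `q` of S phase is credited the full remaining
time from that quarter's start at constant velocity:
`d(q) = (1 − (q−1)/4) · T_S · v`. The firing-quarter fractions `f(q)`
(measured as the fraction of BrdU label per S-phase quarter at the zone)
weight these into a mean potential travel `Σ d(q) f(q)`. For a locus of
length `L` between two zones, the average meeting point is the
proportional split `d₁/(d₁+d₂) · L`, and the fraction of forks able to
traverse the locus before the far zone fires is `f_S1(source) ·
f_S4(target) · 100` — a fork must start in the first quarter while the
target fires only in the last. A distance-feasibility boolean
(`d(2) ≥ L`, i.e. an S1-starting fork covers the locus by the end of S3) is
reported alongside, not folded into the percentage. All chains are computed
unrounded; rounding is half-up at presentation only, which is what makes
the derived rows land on their printed values (e.g. 414.94 → 415,
0.1653 → 0.17).

## The locus simulator

Each simulated cell draws origins: every initiation zone fires with its
efficiency, at a position uniform within the zone width, at a time drawn by
quarter index from its firing distribution and uniformly within the
quarter; dispersed origins are a Poisson process (rate per Mb per cell)
over the window plus `flank` on each side, firing uniformly over S. Forks
propagate at constant `v_R`/`v_L`; an origin whose position is replicated
before it fires is passively suppressed (processed in firing order);
replication time is the lower envelope of ±1/v lines, so labelling is
closed-form and exact to the rasterisation step (1 bp by default). Two
virtual boundary forks entering the window edges at the end of S guarantee
complete replication without competing with interior origins. Fragment
lengths are lognormal (mean 95 kb, log-sd 0.35 — the shape is a modelling
choice, the mean matches reported fibre sizes); fragments overhang the
window into the flanks so window coverage is uniform; label runs cut by a
fragment end are flagged broken. Only fibres that carry signal are
returned, as in a real experiment where unlabelled fragments are never
selected or measured. Reads are emitted uniformly over the window in
batches per fresh cell, each read taking the fork direction at its midpoint
in that cell.

The default two-zone model places fully efficient zones at 90 kb and
710 kb of an 800-kb window — 620 kb apart, inside the window so both have
flanking DNA and are callable — with `v_R = 1.9`, `v_L = 1.8` kb/min,
`T_S = 465` min, early firing (26.3/53.2/17.6/2.9 %) at the 5′ zone and
late firing (5.7/20.1/41.0/33.2 %) at the 3′ zone. The dispersed-only
model uses 5.3 origins/Mb/cell ≈ one fired origin per cell per mean fibre
length.

For fully efficient zone-only models the population RFD is computed
deterministically (`analytic_rfd`): at each position the probability that
each origin's fork arrives first is integrated on a 0.25-min time grid over
the firing-time densities, averaged over 8 position nodes per zone width,
and bin-averaged at 5 points per bin. This quadrature truth is what the
stochastic round trip is validated against.

### Problem sizes in the validation suite

The randomized suite uses 10 000 grammar-level fibres for the
partition/mirror properties; 1000 simulated fibres (≈ the pooled depth of
several hundred-track experiments) for the round trip; 6000 fibres for the
detection-limit property (sized by a pre-run power analysis: OEM sampling
noise must sit well below the 0.1 zone threshold across ~80 boundaries);
60 000 reads with 100 × 2500-read subsamples for the subsampling contract.
Fibre rasterisation uses 10-bp resolution in the large ensembles and 1 bp
where exact track lengths matter (fork-speed recovery).

## Known limitations and honest discrepancies

- **Meeting point: closed form vs physics.** The kinetics meeting point
  splits the locus by the *ratio of mean* travel distances,
  `d₁/(d₁+d₂)·L = 383 kb` for the default parameters. The physical mean
  meeting point of two forks with those firing distributions is
  `E[x] = (E[t₂−t₁] + L/v_L) · v_R v_L/(v_R+v_L) ≈ 431 kb` — the additive
  head-start enters linearly, not through a ratio — and the simulator,
  being physical, reproduces the latter. The two estimators agree only for
  synchronous firing. The validation suite asserts the closed-form value
  against the simulated TZ centre and that check fails by ~2–5 bins; it is
  left failing deliberately, as a documented model-vs-estimator
  discrepancy, rather than papered over.
- **Broad termination zones are noise-limited at realistic depth.** With
  the default timing distributions the meeting point has ≈ 130 kb spread,
  so the TZ descent is ~300 kb wide and its per-boundary OEM (≈ −0.03) is
  comparable to sampling noise even at 1000 fibres. The TZ is called, but
  its centre estimate wanders by tens of kb between seeds; the
  zone-position check against the analytic TZ centre also fails at this
  depth and is likewise left red. Sharp initiation zones are recovered
  within one bin reliably.
- The simulator has no replication-timing structure beyond S quarters, no
  fork-speed variation along fibres, no sister-fork correlation, and no
  chromatin context; passing its round trips shows the *analysis chain* is
  correct, not that real fibres obey the model.
- The dispersed-origin firing-time distribution (uniform over S) and the
  lognormal fragment-length shape are modelling choices; both are
  configurable.
- Greedy event-first parsing is one consistent reading of ambiguous track
  strings; with well-separated structures (the realistic regime) parsing
  is unambiguous.
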