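# Methods

`smsbs` models a flow-order, virtual-terminator single-molecule
sequencing-by-synthesis (smSBS) run and the computational pipeline that turns
its per-image spot coordinates into identified DNA barcodes. This note
records the model, its assumptions, the parameters that matter, and the
numerical and design choices made where the design was open.

## The sequencing model

One *flow* adds a single virtual-terminator nucleotide species (VT-C, VT-T,
VT-A or VT-G): a molecule extends by at most one base per flow, and only when
the flowed base complements its next unpaired template base. Four flows, one
per base (default order C, T, A, G), form a *quad* (Q); a run is `n_quads`
quads (24 by default, i.e. 96 flows). Every flow is followed by fluorescence
imaging of the incorporated dyes and a cleavage step; one post-cleave image
per quad confirms cleavage. Before the first cycle, a *fill-and-lock* step
fills the capture region (dTTP across the poly-A tail in oligo-dT capture)
and locks every molecule with a VT, producing the *initial-position* image in
which all molecules are visible. Because the fill-and-lock mix carries
several VT species in a single dye channel, the lock base is imaged but never
base-called; by default it consumes the first position of the synthesis
track (`lock_policy="consume_first"`; both conventions are implemented since
the alternative cannot be excluded for templates captured by a specific
primer).

The *synthesis track* of a template is the reverse complement of the copied
template portion, i.e. the base string the polymerase must add in order.
Ideal chemistry (`expected_schedule`) walks the flow schedule against the
track: homopolymers consume one flow of their base per quad, so a k-mer
homopolymer needs k quads, while bases that follow each other in flow order
can all incorporate within one quad.

## The generative run simulator

`simulate_run` places `density` molecules uniformly at random per field of
view (FOV, default 512 px square), assigns each a barcode (optionally with
abundance weights emulating unequal loading stoichiometry), and walks the
flow schedule per molecule with these stochastic fates:

| parameter | meaning | default |
|---|---|---|
| `p_pause` | a matching flow yields no incorporation this quad (retried later) | 0.10 |
| `p_dark`  | an incorporation yields no detectable spot (a deletion) | 0.02 |
| `p_mis`   | per-quad probability of one misincorporation at a non-matching flow | 0.02 |
| `p_detach` | per-quad full stop (molecule leaves the surface) | 0.04 |
| `p_cleavefail` | dye persists into the quad's post-cleave image | 0.01 |
| `nonspecific_rate` | Poisson mean of spurious spots per image | 5 |
| `drift.max_abs_px` | integer stage drift per imaging event | 4 |

`p_pause` and `p_dark` are alternatives of one categorical draw at the
matching flow (their sum must be ≤ 1). `p_mis` is deliberately a *per-quad*
rate: with roughly one called base per quad this makes `p_mis` directly
interpretable as a per-base misincorporation rate, and keeps the planted
per-base error of a run simply `p_mis + p_dark`. A misincorporation is an
insertion (no template consumed) or a substitution (one position consumed)
with probability ½ each; both shapes occur in terminator chemistry and
nothing in the run data distinguishes their mix, so an even split is assumed.
The defaults above reproduce the benchmark regime of a real run: ~4% planted
per-base error, mean read length around 18–20 nt after 24 quads, and
saturating extension traces. Surface-anchoring chemistries are expressed
purely as `p_detach` presets (`ANCHORING_PRESETS`: covalent 0.020,
4×biotin–avidin 0.035, 1×biotin–avidin 0.060 per quad), chosen to order mean
read lengths the way those chemistries do.

Imaging and coordinates: spots are integer pixels (0-based, x = column,
round-half-to-even), matching what an instrument spot detector emits. Stage
drift is an integer translation per imaging event, drawn independently per
event (default) or as a clipped random walk, with the initial-position image
defining the origin. Spots that drift outside the FOV are lost — a real edge
effect; fixtures that need exact round-trips place molecules with
`edge_margin_px` of clearance. Detached molecules keep their anchor (from
the initial image) but emit nothing further. Post-cleave images carry only
cleave-failed dyes plus non-specific spots.

What the simulator does **not** emulate: optics (point-spread overlap at
high density, photobleaching, focus drift), sub-pixel and rotational stage
error, sequence-dependent incorporation kinetics, and polymerase-specific
error spectra. Passing tests therefore demonstrate correctness of the
decoding pipeline under the stated statistical model, not instrument-level
fidelity. A Gaussian-PSF renderer and a simple threshold/local-maximum
detector (`render_images` / `detect_spots`) exist for detector-parity checks
and demos only.

## Drift correction

Correction operates on spot *coordinates*, never on images. Every molecule
is visible in the initial-position image, so those positions are the anchor
set (including any non-specific spot — indistinguishable at this stage, as
on the instrument). For each imaging event an exhaustive integer search over
`[-window, window]²` (default window 8 px) finds the translation maximising
agreement with the anchors; since drift and coordinates are both integer,
translations are ranked primarily by exact coordinate matches, then by the
number of spots within Chebyshev distance 1 of an anchor (this
one-pixel-tolerance count alone is ±1-ambiguous: all nine translations
around the truth tie on it), then by smallest |dx|+|dy|, then
lexicographically. Two rounds are run: round 1 against all anchors; the
anchors matched in the most round-1-corrected incorporation events — the top
10% per FOV — become *position markers*; round 2 re-estimates every offset
against markers only, suppressing the influence of noise spots and stalled
molecules. An event that happens to contain fewer than 4 marker matches
falls back to its round-1 offset (at 50 molecules/FOV the marker set has
only 5 members, so marker-free events are common); events whose final
support is still that weak are flagged low-confidence but corrected anyway.
Post-cleave images are corrected with their own event's estimate. Sub-pixel
registration, rotation and scale are out of scope by design.

## Base calling and filtering

After correction, a spot is assignable to anchors within Chebyshev distance
1 (the "one pixel tolerance") and goes to the nearest by Euclidean distance;
exact distance ties leave it unassigned, and each anchor accepts at most one
spot per imaging event (nearest wins, losers stay unassigned). An anchor's
read is the flow bases of its assigned incorporation spots in flow order,
with per-base (quad, flow) provenance. Anchors with assigned post-cleave
spots in ≥ 1 quad are excluded wholesale as cleave failures (the whole read,
not the base — a persisting dye corrupts every later image of that
position). Anchors with no incorporations yield retained length-0 reads
(reported as a 0-nt class) that `filter_reads` always removes; the default
length filter is < 5 nt, with 19 nt used for genomic mapping applications.
FASTQ output uses a constant Q40 placeholder quality and read IDs of the
form `fov{f}_a{a}_x{x}_y{y}` for spatial traceability.

## Identification

Reads are short (5–40 nt), so identification is full Smith–Waterman local
alignment (plus strand only) against every reference barcode, with the
classic +1/−2 nucleotide scores and affine gaps (−2 first gap base, −1
extension); no seeding heuristic is used — at these lengths exhaustive
alignment is cheap and strictly more sensitive than word seeding. The best
score S becomes an e-value E = K·m·n·exp(−λS) with m the read length, n the
summed reference length, and the standard ungapped Karlin–Altschul
parameters for +1/−2 (λ = 1.28, K = 0.46) used as an approximation for the
gapped statistics. A read is identified when the best reference is unique
and E < 0.01 (0.1 for a single-barcode reference). Traceback tie-breaks
prefer diagonal, then up, then left, making alignments deterministic.
Byproduct reads (TSO, its reverse complement, the RT/PCR primer and their
concatemers) are flagged by the same machinery. Note the e-value threshold
implies a minimum read length: an error-free 9-mer against a 30×20 nt panel
already has E ≈ 0.03, so very short reads are honestly unidentifiable.

Multiplexing capacity is estimated by Monte Carlo: reads are drawn from a
read model (normal length, clipped; independent per-base errors split evenly
among substitution/insertion/deletion) and identified against a reference of
growing size; the false-positive rate (reads assigned to a wrong barcode) is
reported per size with the largest size keeping FP ≤ 0.01 ("negligible").
`estimate_multiplex_capacity` does the same for an n-plex panel with
uniformly drawn sources and reports correct/incorrect/unidentified rates
with Wilson 95% intervals.

## Analytics

*Extension traces* are per-read cumulative called length per quad; the *stop
quad* is the last quad with an increment, and the histogram bin at the final
quad counts reads still extending when the run ended (whether they would
have stopped later is unobservable). A *pause* is a blank quad at or before
the stop quad; the pause frequency is the blank fraction up to the stop
quad, averaged over reads — with only pausing active this recovers `p_pause`
directly.

Mean read length versus quad count follows the elongation-attrition model
L(Q) = r·s·(1−s^Q)/(1−s): each molecule survives into the next quad with
probability s and gains r nt per active quad (L = r·Q at s = 1). Two points
determine (r, s) exactly — L(Q₂)/L(Q₁) = (1−s^Q₂)/(1−s^Q₁) pins s (closed
form when Q₂ = 2Q₁, else a bracketed root), L(Q₁) then gives r; more points
are fit by bounded least squares. The benchmark calibration from mean
lengths 8.1 nt at 6Q and 13.7 nt at 12Q gives s ≈ 0.9403, r ≈ 1.665 nt/quad.

*Accuracy* is alignment-based: each read is locally aligned to its source
(the molecule's synthesis track in truth mode, the identified barcode in
reference mode) and the error rate is (mismatches + insertions +
deletions) / aligned columns. Two estimator properties matter when reading
its output. First, local alignment clips any terminal run with negative net
score, so errors near read ends are invisible and the estimate under-reads
the planted rate on short reads (≈2.5% reported for 4% planted at ~18-nt
reads); the truth-mode oracle used in tests accounts for this by counting
event-log errors within the best-scoring event window, and agrees with the
report to < 0.1%. Second, the 4×4 dinucleotide-context table (second-base
error rate by called pair) counts query-base errors only, and same-base
pairs read *lower* than other pairs under context-free errors because gap
placement inside a homopolymer is ambiguous and consistent traceback hides
second-base errors there — so elevated same-base error in real data is, if
anything, understated by this estimator.

Group comparisons use the two-sided Mann–Whitney U test (normal
approximation with tie correction); count reproducibility uses Pearson
correlation on raw per-barcode counts (log10(x+1) optionally), requiring
identical key sets of ≥ 3 barcodes. Mean read lengths are reported excluding
reads < 5 nt by default.

## Problem sizes and reproducibility

The packaged benchmark run uses 30 barcodes × 25 nt (pairwise Hamming ≥ 8),
1,000 molecules in 4 FOVs, 24 quads, ±2 px drift and the default error
rates — large enough that the error estimate pools > 12,000 aligned bases
while the whole pipeline completes in a few seconds. Stochastic tests fix
seeds or average over ≥ 10–20 seeds. Every random draw flows from a single
`numpy.random.default_rng` seed per run; identical (config, references,
weights) inputs yield bit-identical spot tables, reads and reports, and the
run manifest (config echo, schedule, reference checksum, per-stage counts,
package version) suffices to reproduce a run exactly.

## Known limitations

- Karlin–Altschul parameters are the ungapped values; e-values for gapped
  alignments are approximate (thresholds are configurable).
- The misincorporation model records the flowed base with a fixed ½/½
  insertion/substitution split and at most one event per quad.
- Cleave failure persists for one post-cleave image only and excludes the
  whole read; partial (per-base) exclusion is not modelled.
- Drift is a pure integer translation; sub-pixel error, rotation and
  field-dependent distortion are absent, so registration performance on real
  instruments will be worse than the simulator suggests.
- The spot detector stand-in is a thresholded local-maximum finder, not a
  production localisation algorithm.
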