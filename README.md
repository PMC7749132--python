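# smsbs

Simulation and decoding of flow-order, virtual-terminator **single-molecule
sequencing-by-synthesis** (smSBS) — the chemistry used to spatially decode
DNA barcode molecules (in-house barcode panels, antibody–oligo conjugates)
at single-molecule resolution on a TIRF microscope.

In smSBS, one reversibly terminating nucleotide species (VT-C, VT-T, VT-A,
VT-G) is flowed at a time; each molecule extends by at most one base per
flow, incorporated dyes are imaged, then cleaved. Four flows form a *quad*
(Q); a typical run is 24 quads (96 flows). Decoding such a run is a
coordinate-level computational problem: every molecule's position is anchored
by an initial fill-and-lock image, each subsequent image is shifted by
integer-pixel stage drift, and the sequence of a molecule is the flow bases
of the spots that land within one pixel of its anchor. This package provides,
for anyone building or benchmarking such a system:

- **`smsbs.chemistry`** — flow schedules, synthesis tracks, ideal
  incorporation schedules (which flows a given template lights up);
- **`smsbs.simulate`** — a seeded generative model of a run: pausing, dark
  (undetected) incorporations, misincorporation, full stops, cleave
  failures, stage drift and non-specific spots, with ground truth attached;
- **`smsbs.register`** — two-round stage-drift correction on spot
  coordinates (all anchors, then the top-10% most active "position
  markers");
- **`smsbs.basecall`** — spot-to-anchor assignment with one-pixel tolerance,
  read assembly with per-base (quad, flow) provenance, cleave-failure
  exclusion and length/byproduct filters;
- **`smsbs.identify`** — Smith–Waterman identification against a barcode
  panel with Karlin–Altschul e-values (E = K·m·n·e^(−λS), threshold 0.01;
  0.1 for single-barcode references), byproduct flagging, and Monte-Carlo
  multiplexing-capacity estimation;
- **`smsbs.analytics`** — extension traces, stop/pause statistics,
  alignment-based accuracy with a dinucleotide-context error table, the
  elongation-attrition model L(Q) = r·s·(1−s^Q)/(1−s), count correlations
  and Mann–Whitney length comparisons.

See `docs/methods.md` for the models and their assumptions.

## Worked example

Simulate a benchmark-style run (30 barcodes × 25 nt, 1,000 molecules over 4
fields of view, 24 quads, default error rates and ±4 px drift), decode it,
and fit the elongation model to the canonical 6Q/12Q calibration points:

```python
import numpy as np
import smsbs as s

refs = s.make_barcode_library(30, length=25, seed=1, min_pairwise_hamming=8)
cfg = s.RunConfig(n_fovs=4, density=250, n_quads=24, seed=42)
sim = s.simulate_run(cfg, refs)

anchors = s.anchors_from_spots(sim.spots)
corrected, drift = s.correct_run(sim.spots, anchors)
assignments = s.assign_spots(corrected, anchors)
reads = s.call_reads(assignments, cfg.schedule, anchors)
kept, removed = s.filter_reads(reads, min_len=5)

results, counts = s.identify_reads(kept, refs, threshold=0.01)
n_id = sum(r.best_ref_id != "UNIDENTIFIED" for r in results)
lengths = [r.length for r in kept]
print(f"anchors: {len(anchors)}   reads kept: {len(kept)} / {len(reads)}")
print(f"mean read length: {np.mean(lengths):.1f} +- {np.std(lengths):.1f} nt")
print(f"identified: {n_id} / {len(kept)} ({100 * n_id / len(kept):.1f}%)")

fit = s.fit_elongation({6: 8.1, 12: 13.7})
print(f"elongation fit: s = {fit.s:.4f}, r = {fit.r:.3f} nt/quad")
print(f"predicted L(18) = {s.expected_length(18, fit.r, fit.s):.1f} nt, "
      f"L(24) = {s.expected_length(24, fit.r, fit.s):.1f} nt")
```

Output:

```text
anchors: 1021   reads kept: 679 / 1021
mean read length: 18.4 +- 6.5 nt
identified: 548 / 679 (80.7%)
elongation fit: s = 0.9403, r = 1.665 nt/quad
predicted L(18) = 17.6 nt, L(24) = 20.2 nt
```

Reading the numbers: 1,021 anchors are the initial-position spots (1,000
molecules plus a few non-specific spots); 679 reads survive the < 5 nt,
cleave-failure and length-0 filters; at the default 4% planted per-base
error and 4%/quad full-stop rate, reads average ~18 nt and 81% are
confidently identified (E < 0.01) — the unidentified remainder is dominated
by molecules that stopped early. The two-point elongation fit says molecules
survive each quad with probability s ≈ 0.94 and gain r ≈ 1.7 nt per active
quad, predicting the saturating mean lengths at 18Q and 24Q.

There is also a CLI (`smsbs run|simulate|detect|register|basecall|identify|
capacity|qc`); `smsbs run --config cfg.yaml --out-dir out/` executes the
whole pipeline and writes FASTA/FASTQ/TSV outputs plus a JSON report and a
reproducibility manifest.

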