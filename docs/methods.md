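# Methods

## Model and procedure

`kmerperiod` treats k-mer periodicity as a spectral property of the
distribution of pairwise occurrence distances. For a motif *m* (IUPAC
pattern, expanded positionwise to concrete words) and sequences
s<sub>1</sub>..s<sub>N</sub>:

1. Occurrences of *m* are mapped per sequence; matches may overlap, and a
   window containing an N never matches (so assembly gaps cannot fabricate
   occurrences). Distances are measured between occurrence **start**
   positions, within each sequence only, and pooled by summation across the
   set — one distogram, hence one spectrum, per sequence set.
2. The distogram over distances 1..L is normalized to a frequency histogram,
   smoothed (moving average, width 3), and detrended by subtracting a local
   average (width ~10; see numerical choices). The signal length is always L,
   zero-padded if the histogram is shorter.
3. PSD(k/L) = |DFT(signal)[k]|² / L² for k = 1..⌊L/2⌋. The DC term is
   excluded (it is ≈ 0 after detrending). A peak at frequency f indicates the
   motif recurs preferentially every 1/f bp.
4. Significance is empirical: the identical pipeline is applied to n
   independently shuffled copies of the sequence set. Per frequency bin the
   report contains the observed PSD, the log2 fold-change against the median
   shuffled PSD, the upper-tail empirical p-value
   (⌗{null ≥ observed}+1)/(n+1), and its Benjamini–Hochberg adjustment
   across the grid's ⌊L/2⌋ bins.

The underlying assumption is stationarity across the pooled set: one spectrum
summarizes the set, so sequences are expected to carry the periodic signal in
comparable phase-free form (pairwise distances are phase-invariant, so
sequences need not be aligned to each other).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `max_distance` (L) | 200 | bp | distogram cap; fixes the grid step 1/L = 0.005 cycles/bp |
| `smooth_window` | 3 | bp | masks the universal 3-bp genomic periodicity |
| `detrend_window` | 10 | bp | local-average width for distance-decay removal |
| `n_shuffling` | 500 | – | null size; p-value floor 1/(n+1) ≈ 0.002 |
| `shuffle order` | mono | – | letter permutation; `di` preserves exact dinucleotide counts |
| `window_size` | 100 | bp | track: sliding-window length (also the per-window L) |
| `step_size` | 2 | bp | track: window stride |
| `smooth_track` | 20 | scored positions | track: centered rolling-mean width |

The defaults reproduce the standard configuration for 10-bp WW periodicity
analysis of few-hundred-bp promoter windows. With n = 500 shufflings and a
100-bin grid, a bin beating every shuffle attains p = 1/501 and a BH-adjusted
value below 0.05 as soon as four or more bins sit at the floor; much smaller
n makes the BH floor (1/(n+1))·(m/k) hard to clear and is not recommended
when FDR thresholds are applied.

## Shuffling

`mono` draws a uniformly random permutation of each sequence's letters
(exact letter counts preserved). `di` is the Altschul–Erickson Eulerian-path
shuffle: dinucleotides are edges of a multigraph on the letters; a random
last-exit edge per vertex is drawn until it forms an arborescence into the
final letter, remaining edges are permuted, and the Eulerian walk is read
off — exact dinucleotide (and hence letter) counts are preserved. `mono` is
the default; for dinucleotide motifs `di` is the stricter null (it holds the
motif's own abundance fixed) and can be selected per run. Each shuffling
iteration uses an RNG stream spawned from the master seed, so results are
bit-reproducible and independent of how iterations might be scheduled.

## Numerical choices

- **Moving-average edges**: the window shrinks symmetrically at the
  boundaries (mean over available neighbors), keeping output length L with
  no invented padding; edge bins carry negligible spectral weight at L = 200.
- **Detrend width parity**: a centered moving average needs an odd width, so
  the 10-bp request uses the nearest odd width ≥ 10, i.e. 11. A trailing
  10-wide window was rejected because it phase-shifts the signal.
- **PSD scale**: |DFT|²/L² is one of several common conventions; l2FC,
  p-values and FDR are invariant to any fixed positive rescaling (covered by
  a test that injects a rescaled spectral backend), so absolute PSD values
  should not be compared across tools.
- **Degenerate inputs**: a motif with no occurrences yields an all-zero
  distogram, a warning, and an NA metrics table; a zero null median with a
  positive observation reports l2FC = +Inf (never numeric garbage); 0/0
  reports NA.
- **Ties** in the empirical p-value use ≥, matching the plus-one estimator.
- **Track windows** with fewer than two motif occurrences score 0 rather
  than NA: no pairwise distance evidence means no measurable periodicity
  strength, and tracks stay dense.
- **Window centers**: for the even default window the center is
  start + window_size/2 (the right-of-middle base). The requested period is
  mapped to the nearest grid frequency of the window-level grid (k/100 for
  the default window, so period 10 sits exactly on-grid at 0.100).
- **Track smoothing** operates on runs of scored positions (spacing ≤ step),
  so smoothing never bridges the gap between disjoint input intervals.
  Overlapping intervals contribute the average of their duplicate center
  scores.

## Synthetic data

`make_periodic_sequences` writes a concrete motif at positions
phase + i·period + round(N(0, jitter_sd)), each site kept with probability
`occupancy`, on an i.i.d. background; planting overwrites letters in place so
length and downstream phases are preserved, and sites that would overlap the
previous plant are skipped and recorded in the truth file. This emulates the
one feature the pipeline measures — a motif recurring at a fixed spacing
with tunable noise — but deliberately not the rest of real promoter
sequence: no nucleosome-occupancy model, no GC heterogeneity along the
sequence, no phase coherence between sequences beyond the common `phase`,
no overlapping motif grammar. Passing the synthetic benchmarks therefore
demonstrates that the statistics recover a planted spacing at realistic
sizes (50 sequences × 300 bp) and stay calibrated on composition-matched
noise; it does not by itself validate biological conclusions on genomic
sequence, where decay structure and compositional heterogeneity are
stronger.

Benchmark problem sizes: planted-recovery and null-calibration runs use 50
sequences of 300 bp (10- and 20-seed panels; 500 and 100 shufflings
respectively); track benchmarks use a 10-kb synthetic genome with a 1-kb
planted segment and the default window/step/smoothing.

## Known limitations

- One pooled spectrum per set: a periodicity present in a small subset of
  sequences is diluted; the track builder is the tool for localizing signal.
- Empirical p-values are lower-bounded at 1/(n+1); reported small p-values
  are overestimates of the true tail probability.
- Single-window track scores (100 bp → ≤ ~50 occurrence pairs) are noisy by
  construction; they are meaningful after the rolling smoothing and in
  aggregate, not window by window.
- The spectral estimate is a plain FFT periodogram (no tapering/Welch
  averaging), matching the method this package implements; for very short
  L the frequency resolution is coarse.
- `threads` in the CLI is accepted for interface stability but execution is
  serial; per-iteration RNG streams guarantee any future parallel execution
  cannot change results.
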