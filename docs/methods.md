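# Methods

## Coordinates of the mass map

For a neutral peptide of monoisotopic mass *M* (Da) and average mass *A*
(Da) the package computes, carried at full precision and reported to 2–4
decimals:

* nominal mass `N = round(0.9995 × M)` — round-to-nearest, not truncation.
  The 0.9995 scale maps the peptide mass ladder onto integers; truncation
  would mis-assign any peptide whose scaled mass falls in the upper half of a
  unit interval (e.g. a 2272.856 Da peptide would get NMD 0.82 instead of the
  correct 0.38), so `integer(...)` is implemented as nearest-integer with
  half-up tie-breaking.
* `NMD = 1000 (M − N)/M` — decreases with sulfur and acidic residues.
* `NIS = 1000 (A − M)/M` — increases with sulfur.

Both are intensive (charge- and size-normalized) quantities; records from
different charge states of one peptide coincide.

### Candidate rule

A record is flagged as a likely cysteine-containing peptide when
`NMD < nmd_max` **and** `NIS > nis_min` (defaults 0.55 / 0.65, strict
inequalities). An `or` mode is provided because genuine cysteine peptides sit
close to either boundary (the worked-example 3.3 kDa peptide has theoretical
NMD 0.554); `and` is the default because it is the joint rule the screen was
designed around. Thresholds are configuration, not constants.

## Chemistry layer

Compositions are exact integer atom counts over C/H/N/O/S. A species is one
or two chains, an optional C-terminal amide per chain (−O −H +N +2H relative
to the free acid) and a disulfide count (−2 H per bond, applied at the
composition level so that isotope distributions of oxidized species are
exact). Ambiguity codes (B, J, O, U, X, Z) are rejected loudly at this layer
with symbol and position; the FASTA layer catches the error and skips the
entry with a logged reason, because database exports do contain them and a
screen must keep going.

Isotope masses and abundances are a pinned CHNOS table (IUPAC/NIST values of
the early-2010s vintage); standard atomic weights are derived from it as
abundance-weighted means, which keeps `average_mass`, `monoisotopic_mass`
and the isotope distribution mutually consistent (they agree with CIAAW
conventional weights to <1 mDa/atom). The printed 3-decimal masses of the
published peptide tables reproduce within 2 mDa under this table; 2-decimal
NMD/NIS values are insensitive to the table vintage.

Isotope distributions are computed by element-wise convolution on
nominal-mass bins with binary exponentiation per element; each bin tracks its
abundance-weighted mean mass, i.e. fine structure is collapsed to one
centroid per isotopomer — what a resolution-30,000 zoom scan actually
resolves. Trailing bins below 1e-14 abundance are pruned, so abundances sum
to 1 within 1e-9 and the expectation identity
`mean(distribution) == average_mass` holds to <1 mDa even at 8 kDa. Any
`min_abundance` cut is applied only after the full convolution.

## Zoom-scan pipeline

Zoom scans are narrow centroid scans around a selected precursor. Detection
does not rely on dialect-specific "zoom" flags: a scan qualifies when its
acquired m/z window spans ≤ 5 m/z (configurable) and a precursor/target m/z
is annotated. mzXML is read through pyteomics; mzML through a small lxml
reader covering the subset the pipeline needs (pyteomics' mzML parser
requires an optional extra package). Retention times are normalized to
seconds on read. Profile-mode zoom scans are rejected per scan — peak
picking is out of scope.

Processing per scan:

1. **Quality filter** — scans with total ion current below `min_tic`
   (default 1e4 a.u., instrument-dependent and configurable) are discarded.
2. **Denoise** — peaks below 3% of the most abundant peak are removed
   (`rel_noise`, default 0.03).
3. **Series + charge** — the longest run of peaks with mutually consistent
   adjacent spacings is selected via dynamic programming over candidate
   charges 1..12; the charge minimizes the summed absolute deviation of the
   run's spacings from 1.0033548/z (the ¹³C−¹²C spacing dominates peptide
   envelopes; averagine-weighted spacings are deliberately out of scope).
   Spacing tolerance is ±0.01 m/z: generous against centroid jitter at
   R = 30,000, tight against the 1.0034/12 minimum spacing to discriminate.
   Equal-length runs tie-break toward the run containing the most intense
   peak, then by summed intensity (determinism). The run must contain the
   scan's base peak, otherwise the scan is rejected as chimeric.
4. **Masses** — neutral monoisotopic mass `z × (mz₀ − 1.007276467)` from the
   lowest-m/z member (proton mass, not H-atom mass: electrospray
   protonation); neutral average mass from the intensity-weighted mean m/z of
   the series members.
5. **Clustering** — repeat observations of one peptide (replicate scans,
   different charge states) are merged by single linkage on neutral mass
   (±5 ppm) and retention time (±60 s); consensus masses are TIC-weighted
   means.

Per-scan failures are logged and reported, never fatal; only an unreadable
file aborts a run.

### Known bias of the average-mass estimator

The 3%-of-base-peak cutoff truncates the faint wings of the isotopomer
envelope. For peptides ≳2 kDa only a negligible heavy tail is lost (the
average comes out 5–15 ppm low on noise-free synthetic scans, well inside the
±40 ppm the estimator is specified to hold). For peptides below ~1.5 kDa the
4th/5th isotopomer itself sits near the 3% line, and losing it biases the
average mass low by 35–70 ppm — equivalently NIS low by 0.035–0.07, worst for
sulfur-rich sequences whose S-34 satellite is clipped. This is a property of
the prescribed estimator, not of its implementation: the experimental NIS of
sub-1.5 kDa peptides should be treated as a lower bound. (On real
instruments additional intensity effects can push the bias the other way;
the published workflow reported an aggregate +26 ppm average-mass error.)
One pipeline test intentionally keeps the tight ±0.03 NIS recovery band
across the full 0.8–8.2 kDa range and documents the resulting failure for a
1.1 kDa species rather than widening the band.

## Disulfide counting

For an unreduced mass *U* absent from the reduced map (±5 ppm) and candidate
reduced chain masses *R₁* (+ optionally *R₂*, pairs drawn with repetition so
homodimers are covered), the bond count is
`n = argmin_n |ΣR − U − n × 2.0156501|` over n = 1..max_bonds (default 10),
accepted when the residual is ≤ `red_tol`. Ties break toward smaller n
(parsimony). The default tolerance is **0.02 Da absolute**, not ppm: the
worked four-bond example's printed masses leave an ~9 mDa residual, so a
few-mDa window is required and a ppm-scaled one would be too tight at small
mass. All matching assignments are reported sorted by residual; the CLI
report keeps the best per unreduced mass unless `--all-candidates` is given.
Which cysteines pair with which is out of scope.

## Synthetic acquisition model

The generator emulates the acquisition the pipeline targets so every stage is
testable without instrument data:

* centroid peaks at `(isotopomer mass + z × proton)/z` for all isotopomers
  above 1% of the envelope maximum that fall inside a −1.50/+2.25 m/z window
  around the precursor (= most abundant isotopomer, as instruments pick the
  base peak). The window is applied directly on the m/z axis; that is the
  only reading under which the whole envelope of a multiply charged peptide
  fits the window, which is the premise of the acquisition.
* intensities proportional to abundance with multiplicative Gaussian noise,
  CV 5% — this folds the instrument's four-microscan averaging into a single
  term rather than simulating microscans;
* m/z jitter Gaussian at 2 ppm (1σ), the scale of centroid errors at
  R = 30,000;
* a sparse uniform noise floor (5 peaks/scan below 2% of base) modelling
  centroid-mode chemical noise rather than a baseline;
* everything deterministic under a fixed seed.

Runs interleave wide survey scans (ignored by the pipeline) with zoom scans
and are written as mzXML or mzML (64-bit peaks, so both dialects re-read to
identical tables). The reduction experiment writes paired runs: oxidized
species unreduced; every bond opened (+2 H each) and chains separated in the
reduced run. Each precursor is acquired at two adjacent charge states with
two replicate scans, as data-dependent acquisition does in practice (the
published dataset averaged ~5 spectra per peptide); clustering then averages
the repeats, which is what makes the 5 ppm consensus-mass recovery
statistically comfortable at 2 ppm per-peak jitter.

What the generator does **not** emulate: chromatographic peak shapes,
detector saturation or coalescence (hence no positive average-mass bias),
isotope fine structure, co-isolated contaminant envelopes, and vendor
formats. Passing round-trip tests therefore demonstrate the correctness of
the processing chain under the stated noise model, not instrument-grade
accuracy on real data.

## Problem sizes and numerical choices in the test suite

The pipeline tests use 3–20 species per run (0.8–8.2 kDa, charges 2–10,
derived as ~mass/900 to keep precursors in the survey range and envelopes
inside the zoom window), three replicate scans per species for consensus
tests, and 20–50 random sequences for the property suites; the full suite
runs in well under a minute on one core. Single-linkage clustering can
occasionally split one replicate that drew >5 ppm jitter into its own
cluster; recovery tests therefore judge each species by its dominant
(most-scans) record and additionally require that every record maps onto a
planted species.

## Limitations

* Monoisotopic peak = lowest-m/z series member; above ~8 kDa the
  monoisotopic isotopomer drops below the 3% cutoff and this assignment
  fails. The supported range is the acquisition's design range (≤ ~8.2 kDa).
* Deisotoping survey scans without zoom scans is out of scope, as are MS²
  interpretation, de novo sequencing and database searching.
* The NIS of small (<1.5 kDa) peptides is biased low by envelope truncation
  (see above).
* FASTA entries carry no modification annotation; the theoretical table's
  default policy is fully reduced free-acid chains ("smaller than 35
  residues" is read literally as length ≤ 34, configurable), with
  `all-cys-paired` and per-entry overrides available.
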