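# Methods

This note documents the models, numerical choices and limitations behind
`exonskip`, in the order data flows through the package.

## Data model and training filter

A record is one ASO with one experimental skipping measurement. Sequences
are stored in the RNA alphabet; T on input is treated as U, because PMO and
2OMe sequences are reported in both alphabets in the literature. Target
coordinates are 1-based inclusive exon positions, with exon position 1 the
first base after the splice acceptor; when both coordinates are present the
span must equal the ASO length. Records with an unreported concentration are
storable (`concentration_uM = None`) but excluded from training.

The training filter keeps, per chemistry, records with (i) an absolute
numerical efficacy, (ii) a reported positive concentration, (iii) the
reference cell line (default "RD", case-insensitive; configurable so the
framework generalises to other normalising contexts), (iv) a non-EC50
readout and (v) a sequential, single-site ASO. Replicate measurements of one
ASO are kept as separate rows (averaging would discard the concentration
dimension); all splits group by normalised sequence, so replicates can never
straddle a split.

## Accessibility and binding energy

Accessibility is the equilibrium probability that a base is unpaired in the
folded target RNA. The in-house backend computes it exactly for a
pair-additive secondary-structure ensemble: each Watson–Crick or wobble pair
contributes a fixed energy (G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol), hairpin
loops enclose at least 3 bases, structures are non-crossing, and Boltzmann
weights use RT = 0.6163 kcal/mol (37 °C). Inside–outside dynamic programming
gives exact pair probabilities; the unpaired profile is 1 minus each base's
total pairing probability. Folding is local: windows of 80 bases (step 40)
with a maximum pairing span of 40, each base averaged over the windows
covering it — the RNAplfold-style locality assumption that regulatory
accessibility is governed by nearby structure. The backend is a contract
(`unpaired_profile(seq)`), and an adapter for the ViennaRNA partition
function is provided; tests pin down the in-house backend (against
exhaustive structure enumeration on short sequences) and check that backend
swaps preserve orderings, not values.

Binding energy of an ASO to its site uses a structure-competition model:

    dG_bind = dG_duplex + dG_open
    dG_duplex = initiation + sum of nearest-neighbor stacks
    dG_open   = −RT · ln(max(mean unpaired probability of the site, 1e-6))

The stacking table ships as a versioned TSV of the 16 Watson–Crick RNA/RNA
nearest-neighbor free energies at 37 °C (Xia-style unified parameters, keyed
by the target-strand dinucleotide). The initiation row is 0.0 in the shipped
table: end/initiation corrections are deliberately lumped into the opening
term so that any duplex of ≥ 2 pairs has non-positive dG_duplex and the
binding feature is dominated by composition and accessibility, which is what
the regressor consumes after standardization anyway. The 1e-6 floor on the
opening probability keeps fully structured sites at a large but finite
penalty (~8.5 kcal/mol). A duplex-only mode (no opening term) is available
as a backend option. PMO and 2OMe backbones share the RNA/RNA table — no
chemistry-specific nearest-neighbor parameters are used; chemistry enters
only through separate trained models.

## Features

All features are pure functions of (context, site, ASO, concentration,
resources); repeated evaluation is bit-identical. Notable conventions:

- **ACP** (acceptor-to-center distance) is floor((start+end)/2); the
  even-length tie breaks toward the acceptor. Fixed so models are
  reproducible.
- **%GC of exon when blocked** is computed over exon bases outside the site;
  a site covering the whole exon yields 0 with a warning.
- **Exon v intron %GC** divides by the upstream-intron %GC and returns NaN
  (flagging the record) when that is zero or the flank is absent.
- **NI score per base** sums a k-mer lookup table over all overlapping exon
  k-mers and divides by exon length; k is taken from the resource file, not
  hard-coded. No canonical score values are asserted — the table is a
  user-supplied resource.
- **ACC_LAST15 / ACC_LAST8** are the *mean* unpaired probability over the
  last 15/8 bases of the site (mean chosen over sum/min; flagged as a
  convention), folded in the full exon+flank context so near-edge sites keep
  natural structure.
- **dG (50-base flanks)** computes the opening penalty on the site ± 50
  bases of natural context, truncated at the ends of the available sequence.
- A vector with any failing or non-finite feature is marked incomplete and
  excluded from training with a log line.

Standardization is z-scoring with population standard deviation, constants
fitted on the build/training portion of each split only (never validation or
test) to avoid leakage; constant features get their sd clamped to 1 with a
warning.

## Model selection protocol

Splits operate on sequence groups, never rows. The 90/10 train/test split
stratifies groups by quantile bins (default 5) of per-group mean efficacy,
allocating test picks across bins by largest remainder, so the two sides
have similar efficacy distributions. Validation uses repeated (default 100)
independent 80/20 group splits. Subset enumeration covers every subset of at
most `max_features` (default 6) features containing the concentration; the
per-repeat grid search over the RBF-SVR's C, gamma, epsilon picks the
highest validation R², breaking ties toward the smallest (C, γ, ε). All
subsets share the same repeat splits (variance reduction). The winner is the
subset with the highest mean validation R², ties broken by smaller subset
then lexicographic names — which also makes selection invariant to registry
column order. The final model refits the winning subset on the full training
set (not kept from the best repeat), using the hyperparameter point most
frequently chosen across that subset's repeats.

R² is the squared Pearson correlation of predicted vs experimental values
(the R² of a least-squares line through the scatter), not 1 − SSE/SST. It is
undefined for a constant side; degenerate validation repeats are skipped
with a warning. The efficacy target stays on the raw percent scale;
predictions are not clipped (the plot layer floors at 0 for display only).

Permutation importance on held-out data is the baseline R² minus the R²
after shuffling one feature column, a fresh shuffle per repeat (default
100), reported as mean ± sd; features outside the model's subset are exactly
zero.

The default grid is C ∈ {0.1, 1, 10, 100}, γ ∈ {0.001, 0.01, 0.1, 1},
ε ∈ {0.01, 0.1, 1} — standard log grids, config-overridable. All randomness
derives from one master seed per run.

## Synthetic generator and what it shows

Each synthetic record gets its own random context (exon of 80–160 bases,
200-base flanks, i.i.d. bases at a target GC fraction), a random window
(18–30-mer), and a concentration drawn from {0.1, 0.3, 1, 3, 10} μM.
Efficacy is β0 + β·z + noise, clamped to [0, 100], with z the
dataset-standardized planted features. Defaults plant concentration (β=8),
ASO GC count (β=12, dominant) and ACP (β=8) around β0 = 50; test
configurations keep the clamping rate under 2% so linear-recovery arguments
hold. `noise_ceiling` estimates Var(signal)/(Var(signal)+σ²) by simulation,
and `calibrate_sigma` inverts it; the benchmark calibrates to a ceiling of
0.8.

The scaled-down benchmark (`exonskip.benchmark`) runs the full protocol at
n = 300 records, an 8-feature registry (the six cheap sequence/positional
features, concentration, and a sequence-hash decoy), max 3 features, 20
validation repeats and a coarse 3×3×2 grid spanning the same decades as the
default — sizes chosen so ten seeded replicates complete in a few minutes on
one CPU while recovery remains non-trivial. Thermodynamic features are
excluded from the benchmark registry so its ground truth stays exact and
cheap.

What passing shows: the engine can recover a planted low-dimensional signal
through the full filter → split → subset-search → refit → importance chain,
without sequence leakage, at the expected noise ceiling. What it does not
show: real skipping data are not linear in these features, real exons are
not i.i.d. sequence, replicate structure and between-study heterogeneity are
richer, and the informative features for real data plausibly include the
thermodynamic ones. Published performance on curated corpora (test R² ≈
0.6–0.7) is not reproducible here because those corpora are not packaged;
this package reproduces the method, not the dataset.

## Scanner

Candidate windows are confined to the exon (junction-spanning ASOs are out
of scope); window starts are 1-based exon coordinates and profiles are
indexed by window start. The smoothing is a centered 15-base moving average
with NaN where the full window does not fit (no zero padding). Scans are
deterministic and invariant to case, U/T spelling and surrounding whitespace
of the input sequences. Exported TSVs carry run metadata in `#` header
lines; raw (possibly negative) predictions are exported as-is.

## Known limitations

- The pair-additive folding model ignores loop-type free energies, dangles
  and coaxial stacking; accessibility values are coarser than Turner-model
  partition functions (orderings on simple panels agree; tests enforce
  exactly that, not value agreement).
- No chemistry-specific thermodynamics; PMO and 2OMe differ only by their
  trained models and default concentrations.
- Efficacy is modeled on the raw percent scale; heteroscedasticity near the
  0/100 bounds is not modeled.
- The correlation-based R² rewards rank agreement up to affine error; it is
  the selection metric, not a calibration guarantee.
- Off-target assessment, intron-targeting and dual-site ASOs are out of
  scope.
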