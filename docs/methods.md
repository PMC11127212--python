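# Methods

## Mass arithmetic and isotope patterns

Monoisotopic masses are sums over a packaged isotope table
(`data/elements.tsv`, CODATA/IUPAC values; C 12 exact, H 1.00782503207,
N 14.0030740048, O 15.9949146196, S 31.97207100, Na 22.9897692809,
P 30.97376163, plus halogens and K). Formula parsing accepts plain Hill
notation without parentheses or charge labels; charges belong to the adduct
registry.

Adduct m/z uses the charge-carrier (proton-mass) convention:
`[M+H]+` adds 1.007276466 Da, `[M−H]−` subtracts it, `[M+Na]+` adds
Na − e⁻, `[M+H−H2O]+` adds proton − water, `[M+Na−2H]−` adds
Na − 2H + e⁻, and `[M]+` subtracts only the electron mass. This convention
was chosen because it reproduces printed mass errors of level-1 reference
identifications to ~0.1 ppm, whereas the H-atom convention is ~2.7 ppm off
at m/z 206. All supported adducts are singly charged, which covers
small-molecule ESI work; the charge field exists for extension.

Isotope patterns are aggregated by nominal mass shift (no fine structure),
computed by polynomial expansion — each element's single-atom abundance
polynomial raised to its count by binary exponentiation under truncation,
elements convolved together — truncated at 4 peaks (M…M+3) and
renormalized. This matches the coarse envelope that isotope-similarity
scoring actually uses; fine structure is irrelevant at quadrupole-TOF
resolving powers. Elements whose principal isotope is not the lightest
(e.g. Se) are rejected rather than silently mis-aggregated.

## CCS calibration

The calibration model is the standard TWIMS power law. Measured drift times
are first EDC-corrected, `t′ = t − c·√(m/z)/1000` (c is instrument-specific
and deliberately has **no default** in computations; the suite uses the
conventional placeholder c = 1.41). Literature CCS values are normalized as
`Ω′ = Ω·√μ/z` with reduced mass `μ = m_ion·m_gas/(m_ion + m_gas)` (drift gas
nitrogen, 28.0134 Da, configurable), and `ln Ω′` is regressed on `ln t′` by
OLS. Applying the model inverts those transforms. The lock-CCS correction
is a single multiplicative factor (reference/measured of a continuously
infused lock compound, leucine enkephalin in practice), constrained to
(0.5, 2) — anything outside signals gross miscalibration rather than a
correctable drift. No first-principles Mason–Schamp conversion (no
pressure/temperature handling) and no multi-segment calibrations are
attempted.

On noiseless synthetic calibrants the fit recovers (A, B) and round-trips
every reference CCS to ≲1e−12 relative; with 1% multiplicative CCS noise on
12 calibrants, the median exponent error over 100 seeded fits is ~0.003.

## Library model and packaged fixture

A library entry is one compound (name, HMDB accession, Hill formula,
monoisotopic mass, ClassyFire-style super class, authentic-standard flag)
with one record per observed adduct (m/z, RT in minutes, CCS in Å²,
optional fragment spectrum). Serialization is one CSV row per record with
spectra in a sidecar NIST MSP file keyed `hmdb_id|adduct|mode` (read and
written through matchms). Stored masses are validated against the formula
to 0.0005 Da on load; decoy entries are exempt and explicitly flagged.

The packaged fixture transcribes a published human-urine level-1
identification table: 55 compounds, 67 adduct records (23 compounds with a
positive-mode record, 44 with a negative-mode one, 53 VLMs at the 250 Da
threshold). The printed per-row Δppm, ΔRT, ΔCCS, identification scores and
isotope similarities are kept as pass-through annotations — they are vendor
outputs, never recomputed quantities — so tests can compare computed against
printed values explicitly. Formulas are implied by the HMDB accessions; all
55 pass the 0.0005 Da consistency check (worst case 0.0003 Da). Super-class
labels were assigned at transcription time from the accessions and are
annotations, not assertions. Two documented source discrepancies: leucine
and isoleucine CCS values from a separate analysis (131.44 / 133.13 Å²)
differ from the table's 131.50 for both positive-mode ions (the fixture
stores the table values), and the sodiated-negative mass error of
isovaleric acid is not reproducible under any charge-carrier convention, so
sodium-containing negative adducts are excluded from mass-error checks.

## Matching engine

Candidates are all (entry, adduct record) pairs in the feature's ionization
mode passing the requested dimension filters. Defaults equal the urine
screening criteria: ±20 ppm precursor and fragment mass error, isotope
similarity ≥ 80% (inclusive), ±0.3 min RT, and CCS within ±2% **or** ±4 Å²
(both inclusive). A dimension unavailable on either side (feature without
envelope, record without spectrum or CCS) is skipped and recorded, never
failed — the workflow is incremental by design. RT is only compared within
one mode, since acidic/basic chromatography makes RT method-specific.

Isotope similarity is `100·(1 − ½·Σ|p_i − q_i|)` against the
formula-derived pattern. MS/MS matching pairs each reference fragment
greedily (most intense first) with the nearest unused observed peak and
scores the intensity-weighted fraction of matched reference signal; the
MS/MS *filter* passes when at least one reference fragment is matched,
a deliberately permissive rule reflecting that the criterion's published
role is to discard candidates sharing no fragments, not to threshold
spectral similarity. The reference spectrum is the measured standard
spectrum when present, else in-silico peaks.

The composite score is the transparent equal-weight mean of the available
subscores (mass, RT and CCS as linear ramps to zero at tolerance; isotope
and MS/MS percentages used directly; all clamped to [0, 100]). Vendor
identification scores are proprietary and are not replicated; the printed
ones remain as fixture annotations. Ranking is by descending composite with
deterministic tie-breaks (|Δppm|, then name, then adduct).

Confidence levels: level 1 requires an authentic standard plus passes on
m/z, RT and at least one of MS/MS or CCS (≥ 2 orthogonal properties beyond
mass); level 2 is an MS/MS match without the standard-based requirements;
level 3 is m/z (+isotope) only; level 4 otherwise, including a failed mass
filter. The funnel applies criteria cumulatively — (m/z+isotope) → +RT →
+MS/MS → +CCS — and reports per-stage counts and the ranked winner, so both
the "CCS eliminates" and the "CCS re-ranks" readings of the final stage are
inspectable.

## Synthetic data

The generators emulate feature-level observations only — no chromatographic
peak shapes, raw signals or spectral noise. Noise is Gaussian in the same
domains as the tolerances (ppm / minutes / percent), with defaults of 5 ppm,
0.075 min and 0.5% — one quarter of each default tolerance, a realistic
error scale for a lock-corrected TWIMS-QTOF platform, and the level at which
the engine should rarely mis-rank. Isotope envelopes are copied noiselessly
from the formula; fragment lists support random dropout. All generators are
deterministic under a fixed seed.

Decoys: `mz_shift` displaces record m/z (entries flagged decoy, exempt from
mass validation); `isomer` keeps formula and m/z but displaces RT by +3σ
and CCS by max(3%, 4.5 Å²) — the absolute floor ensures the shift defeats
*both* branches of the dual CCS criterion even for small ions, where a bare
3% would still pass the ±4 Å² branch.

The funnel fixture realizes the worked urine example: a positive-mode
feature (m/z 205.0968, RT 5.71, CCS 147.31) against ten candidates — five
tryptophan-related isomers/isobars whose spectra share fragments with the
observed ion (the two dipeptides match as in-source water-loss ions and
share the tropylium fragment), and five formula-consistent synthetic
isobars with disjoint spectra. Only the l-tryptophan record's CCS sits
within tolerance; stereoisomer CCS values were placed outside it to encode
the elimination reading. Those placements, the racemic accession and the
isobars are synthetic constructs and are labelled as such.

## Verification strategy and problem sizes

Published results that require the full 174-standard library, instrument
raw data or an external compound database (inter-day RSD < 0.85%, 74%
within ±2% of literature TWIMS CCS, main-trendline R² = 0.9118, adduct
shifts, HMDB candidate counts) are out of desk-reproduction reach; the
operations behind them are instead validated by properties: exact
round-trips and parameter recovery on synthetic data, equivalence of the
matching engine with an independently coded exhaustive filter (1,000 seeded
random instances), ≥ 95% rank-1 recovery at quarter-tolerance noise (500
seeded features against the 55-entry fixture; measured ~99–100%), and
funnel/tolerance monotonicity over randomized sweeps. These sizes keep the
whole suite within seconds while giving each stochastic check enough
trials for stable rates. Passing these properties demonstrates internal
correctness of the algorithms, not instrument-level accuracy on real
matrices.

## Numerical choices and edge cases

* %RSD uses the sample SD (n−1), appropriate for triplicate designs;
  it is scale-invariant by construction.
* Accuracy thresholds (±2%) are inclusive; ions missing from either side of
  a comparison are listed, not scored.
* Trendline fits and their R² live in log-log space (the space of the
  linear model) and say so in the report; zero-variance classes return a
  flagged perfect fit instead of raising, so batch runs survive degenerate
  inputs; classes with < 3 points are skipped.
* Adduct-shift statistics are paired per compound, antisymmetric under pair
  swap, with SD undefined (None) for a single pair.
* Corrected drift times must stay positive — a non-positive value raises,
  signalling a wrong EDC coefficient or unit mismatch.
* Output files use fixed float formatting (m/z 4 decimals, RT/CCS/scores 2),
  making identical runs byte-identical.

## Known limitations

No vendor raw-file parsing (feature tables are the ingestion boundary), no
in-silico fragmentation engine (in-silico peaks are consumed, not
generated), no retention-time projection between chromatographic methods,
no multiply-charged species in the adduct registry, and no decoy-based FDR
calibration (the decoy generator exists; calibration is future work).
Synthetic tests cannot certify accuracy on real biological matrices.
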