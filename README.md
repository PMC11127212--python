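# twims4d

Four-dimensional metabolite annotation for traveling-wave ion-mobility mass
spectrometry (TWIMS-QTOF), aimed at untargeted metabolomics of very
low-molecular-weight metabolites (VLMs, monoisotopic mass ≤ 250 Da) in
biofluids such as human urine.

Matching a detected ion on accurate mass alone returns thousands of isobaric
and isomeric candidates. This package implements the library-search strategy
that narrows those candidates by filtering on four orthogonal molecular
descriptors against a reference library of authentic standards:

* **m/z** — precursor mass error within ±20 ppm, plus isotope-envelope
  similarity ≥ 80%;
* **RT** — retention time within ±0.3 min of the standard (per
  chromatographic method/polarity);
* **MS/MS** — fragment matching at ±20 ppm against measured or in-silico
  reference spectra;
* **CCS** — collision cross-section within ±2% *or* ±4 Å² (the dual
  criterion avoids over-filtering small ions).

A candidate confirmed against an authentic standard on m/z, RT and at least
one of MS/MS or CCS earns identification confidence level 1 under the
Metabolomics Standards Initiative convention.

Because TWIMS does not yield CCS from first principles, the package also
implements the standard power-law CCS calibration: after the m/z-dependent
EDC flight-time correction *t′ = t − c·√(m/z)/1000*, reduced-mass-normalized
CCS values Ω′ = Ω·√μ/z of calibrant ions are fit as

    ln Ω′ = ln A + B · ln t′

by ordinary least squares, with an optional single-point multiplicative
lock-CCS correction from a continuously infused reference compound. QC
analytics (inter-day %RSD, accuracy vs drift-tube or TWIMS literature CCS,
matrix-effect deviation, per-class m/z–CCS power trendlines CCS = a·(m/z)^b,
paired adduct CCS shifts) round out the toolkit.

The package ships a transcription of a published 55-compound human-urine
level-1 identification table (with per-adduct m/z, RT, CCS and the printed
per-row errors kept as annotations) and seeded synthetic-data generators, so
the whole pipeline is testable without instrument data.

## Worked example

```python
from twims4d import (load_table1_fixture, summarize_library,
                     build_funnel_fixture, annotation_funnel, MatchTolerances)

lib = load_table1_fixture()
s = summarize_library(lib)
print(f"{s.n_entries} compounds | positive: {s.per_mode['positive']}  "
      f"negative: {s.per_mode['negative']}  VLMs (<=250 Da): {s.n_vlm}")

feature, candidates = build_funnel_fixture()
report = annotation_funnel(feature, candidates, MatchTolerances())
for label, n in report.stages:
    print(f"{label:>12}: {n} candidates")
top = report.top_candidate
print(f"winner: {top.entry.name} ({top.adduct}), composite "
      f"{top.composite:.1f}, MSI level {top.msi_level}")
```

prints

```
55 compounds | positive: 23  negative: 44  VLMs (<=250 Da): 53
  mz+isotope: 10 candidates
         +rt: 10 candidates
       +msms: 5 candidates
        +ccs: 1 candidates
winner: l-Tryptophan ([M+H]+), composite 98.0, MSI level 1
```

The feature is a urine ion at m/z 205.0968 / RT 5.71 min / CCS 147.31 Å²:
mass, isotope and RT filtering leave ten isobaric candidates; fragment
matching removes five whose reference spectra share no fragments with the
observed ion; the CCS criterion finally singles out l-tryptophan, whose
match against an authentic standard on all four descriptors yields a level-1
identification.

The same workflow is available from the shell:

```
twims4d fixture --what funnel --out-dir example
twims4d annotate --library example/funnel_library.csv \
                 --features example/funnel_feature.csv \
                 --out matches.csv --funnel funnel.json
```

Other subcommands: `calibrate` (fit a CCS calibration from a calibrant
table), `simulate` (seeded synthetic features from a library), and
`evaluate precision|accuracy|matrix|trendlines|adduct-shifts`.

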