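"""Seeded generators for synthetic features, decoy libraries and the
worked-example identification funnel, so every pipeline stage is testable
without instrument data.

Noise is expressed in the same domains as the search tolerances — ppm for
mass, minutes for RT, percent for CCS — so a noise level is directly
comparable to the filter widths. Defaults are one quarter of each default
tolerance (5 ppm, 0.075 min, 0.5%), a realistic error scale for a calibrated
TWIMS-QTOF platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chem import adduct_mz, isotope_pattern, monoisotopic_mass, parse_formula
from .annotate import Feature
from .library4d import AdductRecord, FragmentSpectrum, LibraryEntry

__all__ = [
    "NoiseModel",
    "simulate_features",
    "make_decoys",
    "build_funnel_fixture",
]


@dataclass(frozen=True)
class NoiseModel:
    """Feature-level measurement noise, expressed on tolerance scales."""

    ppm_sd: float = 5.0
    rt_sd: float = 0.075  # minutes
    ccs_sd_pct: float = 0.5
    intensity_log_sd: float = 0.5  # sd of log10 intensity around 1e5 counts
    fragment_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_sd", "rt_sd", "ccs_sd_pct", "intensity_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.fragment_dropout <= 1.0):
            raise ValueError("fragment_dropout must lie in [0, 1]")


def simulate_features(
    library: Sequence[LibraryEntry],
    n_per_entry: int,
    noise: NoiseModel | None = None,
) -> list[Feature]:
    """Draw noisy features from library records, with ground-truth labels.

    For each entry, ``n_per_entry`` features are generated from randomly
    chosen adduct records of that entry. m/z is perturbed in ppm, RT in
    minutes, CCS multiplicatively in percent; the isotope envelope is the
    noiseless formula-derived pattern; fragments are copied with random
    dropout (at least one peak always survives). Deterministic under a fixed
    seed.
    """
    if not library:
        raise ValueError("library is empty")
    if n_per_entry < 0:
        raise ValueError("n_per_entry must be >= 0")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    features: list[Feature] = []
    for entry in library:
        envelope = isotope_pattern(entry.formula, 4)
        for i in range(n_per_entry):
            record = entry.records[int(rng.integers(len(entry.records)))]
            mz = record.mz * (1.0 + rng.normal(0.0, noise.ppm_sd) * 1e-6)
            rt = max(0.0, record.rt + rng.normal(0.0, noise.rt_sd))
            ccs = None
            if record.ccs is not None:
                ccs = record.ccs * (1.0 + rng.normal(0.0, noise.ccs_sd_pct / 100.0))
            fragments = None
            if record.spectrum is not None:
                keep = rng.random(len(record.spectrum.peaks)) >= noise.fragment_dropout
                if not keep.any():
                    keep[int(rng.integers(len(keep)))] = True
                fragments = FragmentSpectrum(
                    peaks=tuple(p for p, k in zip(record.spectrum.peaks, keep) if k),
                    source=record.spectrum.source,
                )
            features.append(
                Feature(
                    feature_id=f"{entry.hmdb_id}:{record.adduct}:{i}",
                    mode=record.mode,
                    mz=mz,
                    rt=rt,
                    ccs=ccs,
                    intensity=float(10 ** rng.normal(5.0, noise.intensity_log_sd)),
                    isotope_envelope=envelope,
                    fragments=fragments,
                    truth=entry.hmdb_id,
                )
            )
    return features


def make_decoys(
    library: Sequence[LibraryEntry],
    strategy: str = "mz_shift",
    magnitude: float = 0.01,
    rt_sd: float = 0.075,
) -> list[LibraryEntry]:
    """Falsified library entries for false-annotation studies.

    ``mz_shift`` adds ``magnitude`` Da to every record m/z (breaking the
    formula/mass link, so decoys are marked exempt from mass validation).
    ``isomer`` keeps formula and m/z but displaces RT by +3 sigma and CCS by
    enough to fail both branches of the dual CCS criterion (3% or 4.5 A^2,
    whichever is larger), emulating a wrong isomer assignment.
    """
    decoys: list[LibraryEntry] = []
    for entry in library:
        if strategy == "mz_shift":
            records = [
                replace_record(r, mz=r.mz + magnitude) for r in entry.records
            ]
        elif strategy == "isomer":
            records = [
                replace_record(
                    r,
                    rt=r.rt + 3.0 * rt_sd,
                    ccs=None if r.ccs is None else r.ccs + max(0.03 * r.ccs, 4.5),
                )
                for r in entry.records
            ]
        else:
            raise ValueError(f"unknown decoy strategy {strategy!r}")
        decoys.append(
            LibraryEntry(
                name=f"DECOY {entry.name}",
                hmdb_id=f"DECOY_{entry.hmdb_id}",
                formula=entry.formula,
                monoisotopic_mass=entry.monoisotopic_mass,
                superclass=entry.superclass,
                records=records,
                authentic_standard=False,
                is_decoy=True,
            )
        )
    return decoys


def replace_record(record: AdductRecord, **changes) -> AdductRecord:
    """Copy an adduct record with selected fields replaced."""
    kwargs = dict(
        adduct=record.adduct,
        mode=record.mode,
        mz=record.mz,
        rt=record.rt,
        ccs=record.ccs,
        spectrum=record.spectrum,
        annotations=dict(record.annotations),
    )
    kwargs.update(changes)
    return AdductRecord(**kwargs)


# ---------------------------------------------------------------------------
# Worked-example funnel fixture
# ---------------------------------------------------------------------------

# Characteristic fragments of protonated tryptophan (m/z 205.097):
# NH3 loss, indole-acylium/immonium series and the tropylium ion.
_TRP_FRAGMENTS = (
    (91.0542, 10.0),
    (118.0651, 30.0),
    (144.0808, 40.0),
    (146.0600, 60.0),
    (188.0706, 100.0),
)

# Fragments plausible for the phenylalanine-containing dipeptides; they share
# the tropylium ion at 91.0542 with tryptophan, so an MS/MS comparison still
# matches at least one reference peak.
_PHE_PEPTIDE_FRAGMENTS = (
    (91.0542, 20.0),
    (120.0808, 100.0),
    (166.0863, 45.0),
)


def _entry(name: str, hmdb_id: str, formula: str, adduct: str, rt: float,
           ccs: float, spectrum: FragmentSpectrum | None,
           authentic: bool) -> LibraryEntry:
    f = parse_formula(formula)
    mass = monoisotopic_mass(f)
    return LibraryEntry(
        name=name,
        hmdb_id=hmdb_id,
        formula=f,
        monoisotopic_mass=round(mass, 4),
        superclass="organoheterocyclic compounds" if "Tryptophan" in name else "organic acids and derivatives",
        records=[
            AdductRecord(
                adduct=adduct,
                mode="positive",
                mz=round(adduct_mz(mass, adduct), 4),
                rt=rt,
                ccs=ccs,
                spectrum=spectrum,
            )
        ],
        authentic_standard=authentic,
    )


def build_funnel_fixture() -> tuple[Feature, list[LibraryEntry]]:
    """The worked urine-feature example: one ESI+ ion and ten candidates.

    The feature (m/z 205.0968, RT 5.71 min, CCS 147.31 A^2, tryptophan
    fragments) matches ten candidates on m/z + isotope similarity + RT: five
    tryptophan-related isomers/isobars whose reference spectra share
    fragments with the observed ion (glycyl-phenylalanine,
    phenylalanyl-glycine — both matching as in-source water-loss ions — and
    l-/d-/racemic tryptophan), plus five synthetic isobars whose spectra
    share nothing and therefore fail the MS/MS stage. Only the l-tryptophan
    record carries a CCS within tolerance, so the funnel narrows
    10 -> 10 -> 5 -> 1.

    The five non-tryptophan isobars, the racemic-tryptophan accession and
    all CCS/RT values except l-tryptophan's are synthetic constructs chosen
    to realize the candidate structure; they assert no real chemistry.
    """
    trp_spectrum = FragmentSpectrum(_TRP_FRAGMENTS, source="measured")
    trp_insilico = FragmentSpectrum(_TRP_FRAGMENTS, source="in_silico")
    pep_spectrum = FragmentSpectrum(_PHE_PEPTIDE_FRAGMENTS, source="in_silico")

    library = [
        # the true identification: authentic standard, CCS within tolerance
        _entry("l-Tryptophan", "HMDB00929", "C11H12N2O2", "[M+H]+",
               rt=5.71, ccs=147.31, spectrum=trp_spectrum, authentic=True),
        # stereoisomers: identical chemistry, CCS placed outside tolerance
        _entry("d-Tryptophan", "HMDB13609", "C11H12N2O2", "[M+H]+",
               rt=5.75, ccs=153.50, spectrum=trp_insilico, authentic=False),
        _entry("(+/-)-Tryptophan", "SYN-RAC-TRP", "C11H12N2O2", "[M+H]+",
               rt=5.68, ccs=154.00, spectrum=trp_insilico, authentic=False),
        # dipeptide isobars matching as water-loss ions
        _entry("Glycyl-phenylalanine", "HMDB28848", "C11H14N2O3", "[M+H-H2O]+",
               rt=5.55, ccs=157.00, spectrum=pep_spectrum, authentic=False),
        _entry("Phenylalanyl-glycine", "HMDB28995", "C11H14N2O3", "[M+H-H2O]+",
               rt=5.85, ccs=156.00, spectrum=pep_spectrum, authentic=False),
    ]
    # five synthetic isobars: same formula (hence same m/z and isotope
    # pattern), RT within tolerance, but disjoint fragment spectra
    for i in range(5):
        decoy_spectrum = FragmentSpectrum(
            ((60.0444 + 3 * i, 50.0), (84.0808 + 5 * i, 100.0)),
            source="in_silico",
        )
        library.append(
            _entry(f"Synthetic isobar {chr(65 + i)}", f"SYN{i + 1:05d}",
                   "C11H12N2O2", "[M+H]+", rt=5.60 + 0.05 * i, ccs=152.0 + i,
                   spectrum=decoy_spectrum, authentic=False)
        )

    feature = Feature(
        feature_id="urine-ESIpos-205.0968",
        mode="positive",
        mz=205.0968,
        rt=5.71,
        ccs=147.31,
        intensity=1.2e5,
        isotope_envelope=isotope_pattern("C11H12N2O2", 4),
        fragments=trp_spectrum,
    )
    return feature, library
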