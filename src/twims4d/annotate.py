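"""4D spectral-library matching: candidate generation, per-dimension
filters, subscores, composite scoring, confidence levels and the stepwise
identification funnel.

A detected ion (a :class:`Feature`) is compared against every library
(entry, adduct record) of the same ionization mode across up to five
dimensions:

``mz``
    precursor mass error within +/-20 ppm (default);
``isotope``
    similarity of the observed isotope envelope to the formula-derived
    theoretical pattern, >= 80% (default);
``rt``
    retention time within +/-0.3 min (default), meaningful only within one
    chromatographic method/polarity;
``msms``
    fragment matching against the reference spectrum at +/-20 ppm — the
    dimension passes when at least one reference fragment is matched;
``ccs``
    collision cross-section within +/-2% OR +/-4 A^2 (the dual criterion
    balances filter efficiency against over-filtering of small ions).

Dimensions missing from the feature or the record (no CCS, no spectrum, no
envelope) are skipped, not failed, and the skip is recorded. The funnel
applies the criteria cumulatively — (m/z + isotope) -> +RT -> +MS/MS ->
+CCS — reproducing the stepwise narrowing of candidate metabolites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import IsotopePattern, isotope_pattern, ppm_error
from .library4d import AdductRecord, FragmentSpectrum, LibraryEntry, spectrum_key
from .mobility import CcsDeviation, delta_ccs

__all__ = [
    "ALL_DIMENSIONS",
    "Feature",
    "MatchTolerances",
    "CandidateMatch",
    "FunnelReport",
    "isotope_similarity",
    "msms_score",
    "ccs_within_tolerance",
    "evaluate_candidate",
    "generate_candidates",
    "composite_score",
    "rank_candidates",
    "assign_msi_level",
    "annotation_funnel",
    "read_features",
    "write_features",
]

#: Matching dimensions in funnel order.
ALL_DIMENSIONS = ("mz", "isotope", "rt", "msms", "ccs")


@dataclass
class Feature:
    """One detected ion from an IM-MS run.

    Carries either a CCS value directly or a raw drift time to be converted
    through a :class:`~twims4d.mobility.CalibrationModel` upstream. ``truth``
    is an optional ground-truth label used by synthetic data.
    """

    feature_id: str
    mode: str
    mz: float
    rt: float
    ccs: float | None = None
    drift_time: float | None = None
    intensity: float = 0.0
    isotope_envelope: IsotopePattern | None = None
    fragments: FragmentSpectrum | None = None
    truth: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive|negative, got {self.mode!r}")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt < 0:
            raise ValueError("RT must be >= 0")


@dataclass(frozen=True)
class MatchTolerances:
    """Search tolerances; defaults are the library-search criteria used for
    urine screening (20 ppm, 0.3 min, 2% or 4 A^2, isotope similarity 80%)."""

    ppm: float = 20.0
    rt: float = 0.3
    ccs_pct: float = 2.0
    ccs_abs: float = 4.0
    isotope_min: float = 80.0
    fragment_ppm: float = 20.0

    def __post_init__(self) -> None:
        for name in ("ppm", "rt", "ccs_pct", "ccs_abs", "isotope_min", "fragment_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"tolerance {name} must be strictly positive")


@dataclass
class CandidateMatch:
    """A (feature, entry, adduct record) comparison with per-dimension results."""

    entry: LibraryEntry
    adduct: str
    record: AdductRecord
    dppm: float
    drt: float
    dccs: CcsDeviation | None = None
    isotope_similarity: float | None = None
    msms_score: float | None = None
    subscores: dict[str, float] = field(default_factory=dict)
    composite: float = 0.0
    msi_level: int = 4
    passed_filters: set[str] = field(default_factory=set)
    dimensions_used: set[str] = field(default_factory=set)
    dimensions_skipped: set[str] = field(default_factory=set)


@dataclass
class FunnelReport:
    """Candidate counts after each cumulative criterion plus the final winner."""

    feature_id: str
    stages: list[tuple[str, int]]
    top_candidate: CandidateMatch | None

    def counts(self) -> list[int]:
        return [n for _, n in self.stages]

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "stages": [{"criteria": label, "n_candidates": n} for label, n in self.stages],
            "top_candidate": None if self.top_candidate is None else {
                "name": self.top_candidate.entry.name,
                "hmdb_id": self.top_candidate.entry.hmdb_id,
                "adduct": self.top_candidate.adduct,
                "composite": round(self.top_candidate.composite, 2),
                "msi_level": self.top_candidate.msi_level,
            },
        }


# ---------------------------------------------------------------------------
# Subscores
# ---------------------------------------------------------------------------

def isotope_similarity(observed: IsotopePattern, theoretical: IsotopePattern) -> float:
    """Percent similarity of two isotope patterns.

    ``100 * (1 - 0.5 * sum|p_i - q_i|)`` — 100 for identical normalized
    patterns, 0 for disjoint ones. The shorter pattern is zero-padded.
    """
    p = observed.as_array()
    q = theoretical.as_array()
    n = max(len(p), len(q))
    p = np.pad(p, (0, n - len(p)))
    q = np.pad(q, (0, n - len(q)))
    for arr, label in ((p, "observed"), (q, "theoretical")):
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"{label} pattern is not normalized")
    return float(100.0 * (1.0 - 0.5 * np.abs(p - q).sum()))


def msms_score(observed: FragmentSpectrum, reference: FragmentSpectrum,
               fragment_ppm: float = 20.0) -> float:
    """Intensity-weighted fraction of reference fragments matched, in percent.

    Each reference peak is greedily paired with the nearest unused observed
    peak; the pair counts when the mass error is within ``fragment_ppm``.
    """
    if reference is None or not reference.peaks:
        raise ValueError("reference spectrum must be non-empty")
    ref_mz = reference.mz
    ref_int = reference.intensities
    obs_mz = observed.mz
    used = np.zeros(len(obs_mz), dtype=bool)
    matched_intensity = 0.0
    # visit reference peaks from most to least intense so high-signal
    # fragments get first claim on observed peaks
    for idx in np.argsort(-ref_int):
        errors = np.abs(1e6 * (obs_mz - ref_mz[idx]) / ref_mz[idx])
        errors[used] = np.inf
        j = int(np.argmin(errors))
        if errors[j] <= fragment_ppm:
            used[j] = True
            matched_intensity += ref_int[idx]
    return float(100.0 * matched_intensity / ref_int.sum())


def ccs_within_tolerance(dccs: CcsDeviation, tol: MatchTolerances) -> bool:
    """Dual CCS criterion: pass on |delta| <= 2% OR |delta| <= 4 A^2."""
    return abs(dccs.delta_pct) <= tol.ccs_pct or abs(dccs.delta_abs) <= tol.ccs_abs


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

def evaluate_candidate(feature: Feature, entry: LibraryEntry, record: AdductRecord,
                       tol: MatchTolerances) -> CandidateMatch:
    """Compute deltas, per-dimension pass flags and subscores for one pairing.

    All available dimensions are evaluated regardless of which ones are used
    for filtering, so confidence-level assignment can see every orthogonal
    property that matched.
    """
    cand = CandidateMatch(
        entry=entry,
        adduct=record.adduct,
        record=record,
        dppm=ppm_error(feature.mz, record.mz),
        drt=feature.rt - record.rt,
    )
    cand.dimensions_used.update(("mz", "rt"))
    if abs(cand.dppm) <= tol.ppm:
        cand.passed_filters.add("mz")
    cand.subscores["mz"] = _clamp(100.0 * (1.0 - abs(cand.dppm) / tol.ppm))
    if abs(cand.drt) <= tol.rt:
        cand.passed_filters.add("rt")
    cand.subscores["rt"] = _clamp(100.0 * (1.0 - abs(cand.drt) / tol.rt))

    if feature.isotope_envelope is not None:
        theo = _theoretical_pattern(entry.formula, max(2, len(feature.isotope_envelope)))
        cand.isotope_similarity = isotope_similarity(feature.isotope_envelope, theo)
        cand.dimensions_used.add("isotope")
        if cand.isotope_similarity >= tol.isotope_min:
            cand.passed_filters.add("isotope")
        cand.subscores["isotope"] = _clamp(cand.isotope_similarity)
    else:
        cand.dimensions_skipped.add("isotope")

    if feature.fragments is not None and record.spectrum is not None:
        cand.msms_score = msms_score(feature.fragments, record.spectrum, tol.fragment_ppm)
        cand.dimensions_used.add("msms")
        if cand.msms_score > 0:
            cand.passed_filters.add("msms")
        cand.subscores["msms"] = _clamp(cand.msms_score)
    else:
        cand.dimensions_skipped.add("msms")

    if feature.ccs is not None and record.ccs is not None:
        cand.dccs = delta_ccs(feature.ccs, record.ccs)
        cand.dimensions_used.add("ccs")
        if ccs_within_tolerance(cand.dccs, tol):
            cand.passed_filters.add("ccs")
        cand.subscores["ccs"] = _clamp(
            100.0 * (1.0 - min(abs(cand.dccs.delta_pct) / tol.ccs_pct, 1.0))
        )
    else:
        cand.dimensions_skipped.add("ccs")

    cand.composite = composite_score(cand, tol)
    cand.msi_level = assign_msi_level(cand)
    return cand


def _clamp(x: float) -> float:
    return float(min(100.0, max(0.0, x)))


#: formulae recur across candidates, so theoretical patterns are memoized
_theoretical_pattern = lru_cache(maxsize=4096)(isotope_pattern)


def generate_candidates(feature: Feature, library: Sequence[LibraryEntry],
                        tol: MatchTolerances,
                        dimensions: Iterable[str] = ALL_DIMENSIONS) -> list[CandidateMatch]:
    """All (entry, adduct record) pairings that pass the requested filters.

    Only records of the feature's ionization mode are considered. A requested
    dimension that is unavailable on the feature or record is skipped rather
    than failed. Raises on an empty dimension set.
    """
    dims = set(dimensions)
    if not dims:
        raise ValueError("at least one matching dimension is required")
    unknown = dims - set(ALL_DIMENSIONS)
    if unknown:
        raise ValueError(f"unknown dimensions: {sorted(unknown)}")
    out = []
    for entry in library:
        for record in entry.records:
            if record.mode != feature.mode:
                continue
            cand = evaluate_candidate(feature, entry, record, tol)
            required = dims & cand.dimensions_used
            if required <= cand.passed_filters:
                out.append(cand)
    return out


def composite_score(candidate: CandidateMatch, tol: MatchTolerances) -> float:
    """Equal-weight mean of the available per-dimension subscores (0-100)."""
    if not candidate.subscores:
        raise ValueError("candidate has no subscores")
    return float(np.mean(list(candidate.subscores.values())))


def rank_candidates(candidates: Sequence[CandidateMatch]) -> list[CandidateMatch]:
    """Order by descending composite; ties by |dppm| then name (deterministic)."""
    return sorted(
        candidates,
        key=lambda c: (-c.composite, abs(c.dppm), c.entry.name, c.adduct),
    )


def assign_msi_level(candidate: CandidateMatch) -> int:
    """Identification confidence level (1 best, 4 worst).

    Level 1 requires an authentic standard matched on m/z, RT and at least
    one of MS/MS or CCS — i.e. two or more orthogonal properties beyond mass
    against an in-house reference. Level 2 is an MS/MS match without the
    standard-based requirements; level 3 is m/z (+isotope) only; everything
    else is level 4.
    """
    passed = candidate.passed_filters
    if "mz" not in passed:
        return 4
    if (
        candidate.entry.authentic_standard
        and "rt" in passed
        and ("msms" in passed or "ccs" in passed)
    ):
        return 1
    if "msms" in passed:
        return 2
    if not (passed & {"rt", "msms", "ccs"}):
        return 3
    return 4


#: Cumulative criteria stages of the identification funnel.
FUNNEL_STAGES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("mz+isotope", ("mz", "isotope")),
    ("+rt", ("mz", "isotope", "rt")),
    ("+msms", ("mz", "isotope", "rt", "msms")),
    ("+ccs", ("mz", "isotope", "rt", "msms", "ccs")),
)


def annotation_funnel(feature: Feature, library: Sequence[LibraryEntry],
                      tol: MatchTolerances | None = None) -> FunnelReport:
    """Apply the matching criteria cumulatively and report candidate counts.

    Stage order: (m/z + isotope similarity) -> +RT -> +MS/MS -> +CCS. The
    final stage's survivors are ranked and the top candidate reported.
    """
    tol = tol or MatchTolerances()
    stages: list[tuple[str, int]] = []
    final: list[CandidateMatch] = []
    for label, dims in FUNNEL_STAGES:
        cands = generate_candidates(feature, library, tol, dims)
        stages.append((label, len(cands)))
        final = cands
    ranked = rank_candidates(final)
    return FunnelReport(
        feature_id=feature.feature_id,
        stages=stages,
        top_candidate=ranked[0] if ranked else None,
    )


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def _envelope_to_str(env: IsotopePattern | None) -> str:
    if env is None:
        return ""
    return ";".join(f"{i}:{a:.6g}" for i, a in enumerate(env.relative_abundances))


def _envelope_from_str(text: str) -> IsotopePattern | None:
    if not text:
        return None
    pairs = [item.split(":") for item in text.split(";")]
    abund = np.zeros(len(pairs))
    for shift, frac in pairs:
        abund[int(shift)] = float(frac)
    abund = abund / abund.sum()  # repair rounding from serialization
    return IsotopePattern(tuple(abund.tolist()))


def write_features(features: Sequence[Feature], path: str | Path,
                   msp_path: str | Path | None = None) -> None:
    """Write a feature table (CSV) with fragment spectra in a sidecar MSP."""
    from .library4d import _write_msp  # shared sidecar writer

    path = Path(path)
    rows = []
    spectra: dict[str, FragmentSpectrum] = {}
    for f in features:
        key = ""
        if f.fragments is not None:
            key = f"feature|{f.feature_id}"
            spectra[key] = f.fragments
        rows.append({
            "feature_id": f.feature_id,
            "mode": f.mode,
            "mz": f.mz,
            "rt_min": f.rt,
            "ccs_A2": "" if f.ccs is None else f.ccs,
            "drift_time_ms": "" if f.drift_time is None else f.drift_time,
            "intensity": f.intensity,
            "isotopes": _envelope_to_str(f.isotope_envelope),
            "msp_key": key,
            "truth": f.truth or "",
        })
    columns = ["feature_id", "mode", "mz", "rt_min", "ccs_A2", "drift_time_ms",
               "intensity", "isotopes", "msp_key", "truth"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    if spectra:
        _write_msp(spectra, Path(msp_path) if msp_path else path.with_suffix(".msp"))


def read_features(path: str | Path, msp_path: str | Path | None = None) -> list[Feature]:
    """Read a feature table written by :func:`write_features`."""
    from .library4d import _read_msp

    path = Path(path)
    df = pd.read_csv(path, dtype={"msp_key": str, "isotopes": str, "truth": str})
    if df.empty:
        return []
    msp = Path(msp_path) if msp_path else path.with_suffix(".msp")
    spectra = _read_msp(msp) if msp.exists() else {}
    features = []
    for row in df.itertuples():
        key = row.msp_key if isinstance(row.msp_key, str) else ""
        features.append(
            Feature(
                feature_id=str(row.feature_id),
                mode=str(row.mode),
                mz=float(row.mz),
                rt=float(row.rt_min),
                ccs=None if pd.isna(row.ccs_A2) else float(row.ccs_A2),
                drift_time=None if pd.isna(row.drift_time_ms) else float(row.drift_time_ms),
                intensity=float(row.intensity),
                isotope_envelope=_envelope_from_str(
                    row.isotopes if isinstance(row.isotopes, str) else ""
                ),
                fragments=spectra.get(key),
                truth=(row.truth if isinstance(row.truth, str) and row.truth else None),
            )
        )
    return features
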