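"""The 4D reference library: data model, CSV/JSON readers and writers, the
packaged 55-compound urine identification fixture, and library summaries.

A library entry is one compound (name, HMDB accession, formula, ClassyFire
super class) with one record per observed adduct, each carrying the four
identification dimensions: m/z, retention time (method-specific, minutes),
CCS (A^2, optional) and a fragment spectrum (optional). Serialization is one
CSV row per (entry, adduct record) — mirroring how published identification
tables are laid out — with fragment spectra in a sidecar NIST MSP file keyed
by ``hmdb_id|adduct|mode``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ChemicalFormula, get_adduct, monoisotopic_mass, parse_formula

__all__ = [
    "FragmentSpectrum",
    "AdductRecord",
    "LibraryEntry",
    "LibrarySummary",
    "LibraryValidationError",
    "SUPERCLASSES",
    "MASS_CONSISTENCY_TOL",
    "read_library",
    "write_library",
    "load_table1_fixture",
    "summarize_library",
]

#: Chemical super classes used to bin library compounds (ClassyFire style).
SUPERCLASSES = (
    "benzenoids",
    "lipids and lipid-like molecules",
    "nucleosides, nucleotides, and analogs",
    "organic acids and derivatives",
    "organic oxygen compounds",
    "organoheterocyclic compounds",
    "other",
)

#: Maximum tolerated |computed - stored| monoisotopic mass (Da).
MASS_CONSISTENCY_TOL = 0.0005

ANNOTATION_COLUMNS = (
    "dppm_printed",
    "drt_printed",
    "dccs_printed",
    "score_printed",
    "msms_score_printed",
    "isotope_similarity_printed",
)


class LibraryValidationError(ValueError):
    """Raised when library contents violate schema or mass-consistency rules."""


@dataclass(frozen=True)
class FragmentSpectrum:
    """An MS/MS spectrum as (m/z, intensity) peaks in ascending m/z order."""

    peaks: tuple[tuple[float, float], ...]
    source: str = "measured"  # "measured" | "in_silico"

    def __post_init__(self) -> None:
        if self.source not in ("measured", "in_silico"):
            raise ValueError(f"spectrum source must be measured|in_silico, got {self.source!r}")
        peaks = tuple((float(m), float(i)) for m, i in self.peaks)
        if not peaks:
            raise ValueError("spectrum must contain at least one peak")
        mzs = [m for m, _ in peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z values must be strictly ascending")
        if any(i < 0 for _, i in peaks) or all(i == 0 for _, i in peaks):
            raise ValueError("intensities must be >= 0 and not all zero")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass
class AdductRecord:
    """One observed adduct of a library compound in one ionization mode."""

    adduct: str
    mode: str  # "positive" | "negative"
    mz: float
    rt: float  # minutes
    ccs: float | None = None  # A^2
    spectrum: FragmentSpectrum | None = None
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spec = get_adduct(self.adduct)  # validates the name
        self.adduct = spec.name
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive|negative, got {self.mode!r}")
        if self.mode != spec.polarity:
            raise LibraryValidationError(
                f"adduct {self.adduct} is {spec.polarity} but record mode is {self.mode}"
            )
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt < 0:
            raise ValueError("RT must be >= 0")
        if self.ccs is not None and not (50.0 < self.ccs < 500.0):
            raise LibraryValidationError(
                f"CCS {self.ccs} A^2 outside the plausible small-molecule range (50, 500)"
            )


@dataclass
class LibraryEntry:
    """One compound with its per-adduct records.

    ``authentic_standard`` marks compounds measured in-house against a
    reference standard (a prerequisite for level-1 identifications);
    ``is_decoy`` marks deliberately falsified entries, which are exempt from
    the formula/mass consistency check.
    """

    name: str
    hmdb_id: str
    formula: ChemicalFormula
    monoisotopic_mass: float
    superclass: str = "other"
    records: list[AdductRecord] = field(default_factory=list)
    authentic_standard: bool = True
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.superclass not in SUPERCLASSES:
            raise LibraryValidationError(
                f"{self.name}: unknown superclass {self.superclass!r}"
            )
        if not self.records:
            raise LibraryValidationError(f"{self.name}: entry has no adduct records")
        if not self.is_decoy:
            computed = monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) > MASS_CONSISTENCY_TOL:
                raise LibraryValidationError(
                    f"{self.name}: stored mass {self.monoisotopic_mass:.4f} differs from "
                    f"formula mass {computed:.4f} by more than {MASS_CONSISTENCY_TOL} Da"
                )

    def modes(self) -> set[str]:
        return {r.mode for r in self.records}


@dataclass(frozen=True)
class LibrarySummary:
    """Counts describing a library: entries, CCS coverage, adducts, modes, VLMs."""

    n_entries: int
    n_ccs_values: int
    per_adduct: dict[str, int]
    per_mode: dict[str, int]
    n_vlm: int
    vlm_threshold: float


def _check_unique(entries: Sequence[LibraryEntry]) -> None:
    seen_ids: set[str] = set()
    seen_records: set[tuple[str, str, str]] = set()
    for e in entries:
        if e.hmdb_id in seen_ids:
            raise LibraryValidationError(f"duplicate hmdb_id {e.hmdb_id}")
        seen_ids.add(e.hmdb_id)
        for r in e.records:
            key = (e.hmdb_id, r.adduct, r.mode)
            if key in seen_records:
                raise LibraryValidationError(f"duplicate record {key}")
            seen_records.add(key)


# ---------------------------------------------------------------------------
# MSP sidecar (fragment spectra)
# ---------------------------------------------------------------------------

def _write_msp(spectra: Mapping[str, FragmentSpectrum], path: Path) -> None:
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    out = []
    for key, spec in spectra.items():
        out.append(
            Spectrum(
                mz=spec.mz.astype(float),
                intensities=spec.intensities.astype(float),
                metadata={"compound_name": key, "comment": f"source={spec.source}"},
                metadata_harmonization=False,
            )
        )
    if path.exists():
        path.unlink()  # save_as_msp appends
    save_as_msp(out, str(path), style="nist")


def _read_msp(path: Path) -> dict[str, FragmentSpectrum]:
    from matchms.importing import load_from_msp

    spectra: dict[str, FragmentSpectrum] = {}
    for s in load_from_msp(str(path), metadata_harmonization=False):
        key = s.metadata.get("compound_name") or s.metadata.get("name")
        source = "measured"
        comment = str(s.metadata.get("comment", ""))
        if "in_silico" in comment:
            source = "in_silico"
        spectra[key] = FragmentSpectrum(
            peaks=tuple(zip(s.peaks.mz.tolist(), s.peaks.intensities.tolist())),
            source=source,
        )
    return spectra


def spectrum_key(hmdb_id: str, adduct: str, mode: str) -> str:
    """Sidecar MSP key for one adduct record."""
    return f"{hmdb_id}|{adduct}|{mode}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "name", "hmdb_id", "formula", "monoisotopic_mass", "superclass",
    "authentic_standard", "adduct", "mode", "mz", "rt_min", "ccs_A2", "msp_key",
}


def _entries_from_rows(df: pd.DataFrame, spectra: Mapping[str, FragmentSpectrum]) -> list[LibraryEntry]:
    entries: list[LibraryEntry] = []
    for hmdb_id, group in df.groupby("hmdb_id", sort=False):
        first = group.iloc[0]
        records = []
        for _, row in group.iterrows():
            ccs = row["ccs_A2"]
            ccs = None if pd.isna(ccs) or ccs == "" else float(ccs)
            key = row["msp_key"]
            spec = spectra.get(key) if isinstance(key, str) and key else None
            annotations = {
                c: float(row[c]) for c in ANNOTATION_COLUMNS
                if c in df.columns and not pd.isna(row[c])
            }
            records.append(
                AdductRecord(
                    adduct=str(row["adduct"]),
                    mode=str(row["mode"]),
                    mz=float(row["mz"]),
                    rt=float(row["rt_min"]),
                    ccs=ccs,
                    spectrum=spec,
                    annotations=annotations,
                )
            )
        entries.append(
            LibraryEntry(
                name=str(first["name"]),
                hmdb_id=str(hmdb_id),
                formula=parse_formula(str(first["formula"])),
                monoisotopic_mass=float(first["monoisotopic_mass"]),
                superclass=str(first["superclass"]),
                records=records,
                authentic_standard=_as_bool(first["authentic_standard"]),
                is_decoy=_as_bool(first["is_decoy"]) if "is_decoy" in df.columns else False,
            )
        )
    _check_unique(entries)
    return entries


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def read_library(path: str | Path, format: str = "csv",
                 msp_path: str | Path | None = None) -> list[LibraryEntry]:
    """Load a library from CSV (one row per adduct record) or JSON.

    Fragment spectra referenced through ``msp_key`` are resolved from the
    companion MSP file (default: same path with an ``.msp`` suffix).
    """
    path = Path(path)
    if format == "json":
        return _library_from_json(json.loads(path.read_text()))
    if format != "csv":
        raise ValueError(f"unknown library format {format!r}")
    df = pd.read_csv(path, dtype={"msp_key": str}, keep_default_na=True)
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise LibraryValidationError(f"library CSV missing columns: {sorted(missing)}")
    if df.empty:
        return []
    df["msp_key"] = df["msp_key"].fillna("")
    msp = Path(msp_path) if msp_path else path.with_suffix(".msp")
    spectra = _read_msp(msp) if msp.exists() else {}
    return _entries_from_rows(df, spectra)


def write_library(entries: Sequence[LibraryEntry], path: str | Path,
                  format: str = "csv", msp_path: str | Path | None = None) -> None:
    """Write a library to CSV+MSP or JSON such that reading it back is lossless."""
    path = Path(path)
    _check_unique(entries)
    if format == "json":
        path.write_text(json.dumps(_library_to_json(entries), indent=1) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown library format {format!r}")
    rows = []
    spectra: dict[str, FragmentSpectrum] = {}
    for e in entries:
        for r in e.records:
            key = ""
            if r.spectrum is not None:
                key = spectrum_key(e.hmdb_id, r.adduct, r.mode)
                spectra[key] = r.spectrum
            row = {
                "name": e.name,
                "hmdb_id": e.hmdb_id,
                "formula": str(e.formula),
                "monoisotopic_mass": e.monoisotopic_mass,
                "superclass": e.superclass,
                "authentic_standard": e.authentic_standard,
                "is_decoy": e.is_decoy,
                "adduct": r.adduct,
                "mode": r.mode,
                "mz": r.mz,
                "rt_min": r.rt,
                "ccs_A2": "" if r.ccs is None else r.ccs,
                "msp_key": key,
            }
            row.update(r.annotations)
            rows.append(row)
    base_columns = ["name", "hmdb_id", "formula", "monoisotopic_mass", "superclass",
                    "authentic_standard", "is_decoy", "adduct", "mode", "mz",
                    "rt_min", "ccs_A2", "msp_key"]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=base_columns)
    df.to_csv(path, index=False)
    if spectra:
        _write_msp(spectra, Path(msp_path) if msp_path else path.with_suffix(".msp"))


def _library_to_json(entries: Sequence[LibraryEntry]) -> list[dict]:
    out = []
    for e in entries:
        out.append({
            "name": e.name,
            "hmdb_id": e.hmdb_id,
            "formula": str(e.formula),
            "monoisotopic_mass": e.monoisotopic_mass,
            "superclass": e.superclass,
            "authentic_standard": e.authentic_standard,
            "is_decoy": e.is_decoy,
            "records": [
                {
                    "adduct": r.adduct,
                    "mode": r.mode,
                    "mz": r.mz,
                    "rt_min": r.rt,
                    "ccs_A2": r.ccs,
                    "annotations": r.annotations,
                    "spectrum": None if r.spectrum is None else {
                        "source": r.spectrum.source,
                        "peaks": [list(p) for p in r.spectrum.peaks],
                    },
                }
                for r in e.records
            ],
        })
    return out


def _library_from_json(data: list[dict]) -> list[LibraryEntry]:
    entries = []
    for d in data:
        records = []
        for r in d["records"]:
            spec = r.get("spectrum")
            records.append(
                AdductRecord(
                    adduct=r["adduct"],
                    mode=r["mode"],
                    mz=r["mz"],
                    rt=r["rt_min"],
                    ccs=r.get("ccs_A2"),
                    spectrum=None if spec is None else FragmentSpectrum(
                        peaks=tuple(tuple(p) for p in spec["peaks"]),
                        source=spec["source"],
                    ),
                    annotations=dict(r.get("annotations", {})),
                )
            )
        entries.append(
            LibraryEntry(
                name=d["name"],
                hmdb_id=d["hmdb_id"],
                formula=parse_formula(d["formula"]),
                monoisotopic_mass=d["monoisotopic_mass"],
                superclass=d["superclass"],
                records=records,
                authentic_standard=d.get("authentic_standard", True),
                is_decoy=d.get("is_decoy", False),
            )
        )
    _check_unique(entries)
    return entries


# ---------------------------------------------------------------------------
# Packaged fixture and summaries
# ---------------------------------------------------------------------------

def load_table1_fixture() -> list[LibraryEntry]:
    """The packaged 55-compound human-urine identification set.

    Transcribed from the published level-1 identification table (name, HMDB
    accession, monoisotopic mass, adduct, m/z, RT, CCS), with the printed
    per-row mass error, RT error, CCS error, identification scores and isotope
    similarity retained as pass-through annotations on each record. Formulas
    are those implied by the HMDB accessions and are validated against the
    printed monoisotopic masses on load.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("twims4d").joinpath("data/table1_identifications.csv")
    ) as p:
        return read_library(p, "csv")


def summarize_library(entries: Sequence[LibraryEntry], vlm_threshold: float = 250.0) -> LibrarySummary:
    """Count entries, CCS coverage, adducts, per-mode entries and VLMs.

    A compound counts toward a mode if it has at least one record in that
    mode; VLMs (very low-molecular-weight metabolites) are entries with
    monoisotopic mass at or below ``vlm_threshold`` Da.
    """
    per_adduct: dict[str, int] = {}
    per_mode: dict[str, int] = {"positive": 0, "negative": 0}
    n_ccs = 0
    for e in entries:
        for r in e.records:
            per_adduct[r.adduct] = per_adduct.get(r.adduct, 0) + 1
            if r.ccs is not None:
                n_ccs += 1
        for mode in e.modes():
            per_mode[mode] += 1
    return LibrarySummary(
        n_entries=len(entries),
        n_ccs_values=n_ccs,
        per_adduct=per_adduct,
        per_mode=per_mode,
        n_vlm=sum(1 for e in entries if e.monoisotopic_mass <= vlm_threshold),
        vlm_threshold=vlm_threshold,
    )
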