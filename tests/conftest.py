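import itertools

import numpy as np
import pytest

from twims4d import (
    Feature,
    MatchTolerances,
    build_funnel_fixture,
    load_table1_fixture,
)
from twims4d.chem import ELEMENTS, isotope_pattern
from twims4d.library4d import AdductRecord, LibraryEntry


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def funnel_fixture():
    return build_funnel_fixture()


@pytest.fixture
def tol():
    return MatchTolerances()


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written without reusing package internals)
# ---------------------------------------------------------------------------

def brute_force_isotope_pattern(counts: dict[str, int], n_peaks: int):
    """Enumerate every isotopologue combination of a small formula and
    aggregate abundances by nominal mass shift. Exponential in atom count —
    usable only for tiny formulas."""
    atoms = []
    for el, n in counts.items():
        isotopes = sorted(ELEMENTS[el], key=lambda t: -t[1])
        principal = isotopes[0][0]
        atoms.extend(
            [[(int(round(m - principal)), a) for m, a in isotopes]] * n
        )
    agg: dict[int, float] = {}
    for combo in itertools.product(*atoms):
        shift = sum(s for s, _ in combo)
        prob = 1.0
        for _, a in combo:
            prob *= a
        agg[shift] = agg.get(shift, 0.0) + prob
    dist = np.array([agg.get(i, 0.0) for i in range(n_peaks)])
    return dist / dist.sum()


def oracle_filter(feature, library, tolerances, dimensions):
    """Exhaustive reimplementation of the per-dimension filters, returning
    the set of (hmdb_id, adduct) keys that survive. Skips unavailable
    dimensions the same way the engine specifies, but shares no code."""
    survivors = set()
    for entry in library:
        for record in entry.records:
            if record.mode != feature.mode:
                continue
            ok = True
            if "mz" in dimensions:
                if abs(1e6 * (feature.mz - record.mz) / record.mz) > tolerances.ppm:
                    ok = False
            if ok and "rt" in dimensions:
                if abs(feature.rt - record.rt) > tolerances.rt:
                    ok = False
            if ok and "isotope" in dimensions and feature.isotope_envelope is not None:
                theo = isotope_pattern(entry.formula, len(feature.isotope_envelope))
                p = np.asarray(feature.isotope_envelope.relative_abundances)
                q = np.asarray(theo.relative_abundances)
                sim = 100.0 * (1.0 - 0.5 * float(np.abs(p - q).sum()))
                if sim < tolerances.isotope_min:
                    ok = False
            if ok and "msms" in dimensions and feature.fragments is not None \
                    and record.spectrum is not None:
                any_match = any(
                    abs(1e6 * (om - rm) / rm) <= tolerances.fragment_ppm
                    for rm, _ in record.spectrum.peaks
                    for om, _ in feature.fragments.peaks
                )
                if not any_match:
                    ok = False
            if ok and "ccs" in dimensions and feature.ccs is not None \
                    and record.ccs is not None:
                delta = feature.ccs - record.ccs
                if abs(100.0 * delta / record.ccs) > tolerances.ccs_pct \
                        and abs(delta) > tolerances.ccs_abs:
                    ok = False
            if ok:
                survivors.add((entry.hmdb_id, record.adduct))
    return survivors


_FORMULA_POOL = (
    "C5H10O2", "C4H8O3", "C7H8O", "C4H4N2O2", "C5H8O3", "C6H12O2", "C4H6O4",
    "C5H11NO2", "C6H5NO2", "C2H7NO3S", "C5H6N2O2", "C6H13NO2", "C5H4N4O",
    "C9H11NO2", "C6H8O6", "C11H12N2O2", "C10H12N2O3", "C10H16N2O3S",
)


def random_instance(rng: np.random.Generator, n_entries: int = 8):
    """A random small (feature, library, tolerances, dimensions) instance for
    comparing the matching engine with the exhaustive oracle filter."""
    from twims4d.chem import adduct_mz, monoisotopic_mass, parse_formula

    entries = []
    adducts_by_mode = {
        "positive": ["[M+H]+", "[M+Na]+", "[M+H-H2O]+"],
        "negative": ["[M-H]-", "[M+Na-2H]-"],
    }
    for i in range(n_entries):
        formula = str(rng.choice(_FORMULA_POOL))
        mode = "positive" if rng.random() < 0.5 else "negative"
        adduct = str(rng.choice(adducts_by_mode[mode]))
        mass = monoisotopic_mass(formula)
        mz = adduct_mz(mass, adduct) * (1.0 + rng.normal(0, 15) * 1e-6)
        entries.append(
            LibraryEntry(
                name=f"compound-{i}",
                hmdb_id=f"RND{i:05d}",
                formula=parse_formula(formula),
                monoisotopic_mass=mass,
                records=[
                    AdductRecord(
                        adduct=adduct,
                        mode=mode,
                        mz=mz,
                        rt=float(rng.uniform(0.5, 12.0)),
                        ccs=float(rng.uniform(100, 180)) if rng.random() < 0.8 else None,
                    )
                ],
            )
        )
    target = entries[int(rng.integers(n_entries))]
    rec = target.records[0]
    feature = Feature(
        feature_id="probe",
        mode=rec.mode,
        mz=rec.mz * (1.0 + rng.normal(0, 10) * 1e-6),
        rt=max(0.0, rec.rt + rng.normal(0, 0.2)),
        ccs=(None if rec.ccs is None or rng.random() < 0.2
             else rec.ccs * (1.0 + rng.normal(0, 0.02))),
        isotope_envelope=(isotope_pattern(target.formula, 4)
                          if rng.random() < 0.8 else None),
    )
    tolerances = MatchTolerances(
        ppm=float(rng.uniform(5, 30)),
        rt=float(rng.uniform(0.1, 0.6)),
        ccs_pct=float(rng.uniform(1, 4)),
        ccs_abs=float(rng.uniform(2, 6)),
        isotope_min=float(rng.uniform(50, 99)),
    )
    dims = {"mz"} | {
        d for d in ("isotope", "rt", "msms", "ccs") if rng.random() < 0.7
    }
    return feature, entries, tolerances, dims
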