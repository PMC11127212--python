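"""QC analytics for CCS measurement campaigns.

Covers the four evaluation families used to validate an ion-mobility CCS
library: inter-day precision (%RSD per compound), accuracy against external
reference CCS sets (drift-tube or traveling-wave literature values, or
machine-learning predictions), matrix-effect deviation (spiked biological
matrix vs neat solvent), per-chemical-class m/z-CCS power trendlines
(conformational space), and paired adduct CCS-shift statistics (e.g. how much
larger sodiated ions ride than their protonated forms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .library4d import LibraryEntry
from .mobility import CcsDeviation, delta_ccs

__all__ = [
    "PrecisionReport",
    "AccuracyReport",
    "TrendlineFit",
    "AdductShiftStats",
    "interday_rsd",
    "accuracy_vs_reference",
    "matrix_effect_report",
    "fit_class_trendlines",
    "adduct_shift_stats",
]


@dataclass(frozen=True)
class PrecisionReport:
    """Per-compound replicate precision of CCS measurements."""

    per_compound: dict[str, tuple[float, float, float]]  # name -> (mean, sd, rsd_pct)
    worst_case_rsd_pct: float

    def rsd(self, compound: str) -> float:
        return self.per_compound[compound][2]


@dataclass(frozen=True)
class AccuracyReport:
    """Per-ion CCS deviations against a named reference source."""

    source: str
    deviations: dict[str, CcsDeviation]
    fraction_within_2pct: float
    max_abs_pct: float
    threshold_pct: float
    missing_in_measured: tuple[str, ...] = ()
    missing_in_reference: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrendlineFit:
    """Power-law fit ``ccs = a * mz**b`` for one chemical class.

    The fit (and its R^2) lives in log-log space, the space in which the
    model is linear; ``zero_variance`` flags degenerate classes whose CCS
    does not vary, reported as a perfect flagged fit rather than an error.
    """

    class_label: str
    a: float
    b: float
    r2: float
    n_points: int
    r2_space: str = "log-log"
    zero_variance: bool = False


@dataclass(frozen=True)
class AdductShiftStats:
    """Paired CCS difference between two adducts of the same compounds."""

    adduct_pair: tuple[str, str]
    n_pairs: int
    mean_shift: float
    sd_shift: float | None  # None when only one pair exists


def interday_rsd(replicate_ccs: Mapping[str, Sequence[float]]) -> PrecisionReport:
    """Relative standard deviation of replicate CCS values per compound.

    Uses the sample standard deviation (n-1 denominator), appropriate for
    the small replicate counts of inter-day designs (typically triplicate).
    """
    per_compound: dict[str, tuple[float, float, float]] = {}
    for compound, values in replicate_ccs.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"{compound}: need at least 2 replicates")
        mean = float(arr.mean())
        if mean <= 0:
            raise ValueError(f"{compound}: non-positive mean CCS")
        sd = float(arr.std(ddof=1))
        per_compound[compound] = (mean, sd, 100.0 * sd / mean)
    if not per_compound:
        raise ValueError("no compounds supplied")
    return PrecisionReport(
        per_compound=per_compound,
        worst_case_rsd_pct=max(v[2] for v in per_compound.values()),
    )


def accuracy_vs_reference(
    measured: Mapping[str, float],
    reference: Mapping[str, float],
    source_label: str,
    threshold_pct: float = 2.0,
) -> AccuracyReport:
    """CCS deviations of measured values against a reference CCS set.

    Only ions present in both maps are scored; the rest are listed, not
    failed. The within-threshold fraction is inclusive (|delta| exactly at
    the threshold counts as within).
    """
    shared = sorted(set(measured) & set(reference))
    if not shared:
        raise ValueError("no shared ions between measured and reference sets")
    deviations = {ion: delta_ccs(measured[ion], reference[ion]) for ion in shared}
    abs_pct = np.array([abs(d.delta_pct) for d in deviations.values()])
    return AccuracyReport(
        source=source_label,
        deviations=deviations,
        fraction_within_2pct=float(np.mean(abs_pct <= threshold_pct)),
        max_abs_pct=float(abs_pct.max()),
        threshold_pct=threshold_pct,
        missing_in_measured=tuple(sorted(set(reference) - set(measured))),
        missing_in_reference=tuple(sorted(set(measured) - set(reference))),
    )


def matrix_effect_report(
    neat: Mapping[str, float], matrix: Mapping[str, float], threshold_pct: float = 2.0
) -> AccuracyReport:
    """Deviation of CCS measured in a biological matrix vs neat solvent."""
    return accuracy_vs_reference(matrix, neat, source_label="neat", threshold_pct=threshold_pct)


def fit_class_trendlines(
    ions: Iterable[tuple[float, float, str]],
    per_class: bool = True,
    min_points: int = 3,
) -> list[TrendlineFit]:
    """Power-regression trendlines of CCS against m/z.

    Ordinary least squares of ln(ccs) on ln(mz) per chemical class, plus an
    all-ion main trendline. Classes with fewer than ``min_points`` ions are
    skipped. Returns the main fit first.
    """
    rows = [(float(mz), float(ccs), str(label)) for mz, ccs, label in ions]
    fits: list[TrendlineFit] = []
    groups: list[tuple[str, list[tuple[float, float]]]] = [
        ("all", [(mz, ccs) for mz, ccs, _ in rows])
    ]
    if per_class:
        by_class: dict[str, list[tuple[float, float]]] = {}
        for mz, ccs, label in rows:
            by_class.setdefault(label, []).append((mz, ccs))
        groups.extend(sorted(by_class.items()))
    for label, points in groups:
        if len(points) < min_points:
            continue
        log_mz = np.log([p[0] for p in points])
        log_ccs = np.log([p[1] for p in points])
        if np.ptp(log_ccs) == 0.0:
            fits.append(TrendlineFit(label, a=float(math.exp(log_ccs[0])), b=0.0,
                                     r2=1.0, n_points=len(points), zero_variance=True))
            continue
        res = stats.linregress(log_mz, log_ccs)
        fits.append(
            TrendlineFit(
                class_label=label,
                a=float(math.exp(res.intercept)),
                b=float(res.slope),
                r2=float(res.rvalue ** 2),
                n_points=len(points),
            )
        )
    return fits


def adduct_shift_stats(
    entries: Sequence[LibraryEntry], pair: tuple[str, str]
) -> AdductShiftStats:
    """Paired CCS shift ``ccs(pair[0]) - ccs(pair[1])`` across a library.

    For each compound carrying CCS values for both adducts, the difference
    is taken in the order given; mean and sample SD are reported (SD is None
    for a single pair). Swapping the pair flips the sign of the mean.
    """
    adduct_a, adduct_b = pair
    diffs = []
    for e in entries:
        ccs_a = next((r.ccs for r in e.records if r.adduct == adduct_a and r.ccs is not None), None)
        ccs_b = next((r.ccs for r in e.records if r.adduct == adduct_b and r.ccs is not None), None)
        if ccs_a is not None and ccs_b is not None:
            diffs.append(ccs_a - ccs_b)
    if not diffs:
        raise ValueError(f"no compounds carry CCS for both {adduct_a} and {adduct_b}")
    arr = np.asarray(diffs)
    return AdductShiftStats(
        adduct_pair=(adduct_a, adduct_b),
        n_pairs=len(diffs),
        mean_shift=float(arr.mean()),
        sd_shift=float(arr.std(ddof=1)) if len(diffs) >= 2 else None,
    )
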