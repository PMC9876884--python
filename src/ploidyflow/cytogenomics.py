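"""2C genome size, AT/GC base composition, ploidy and hybrid-origin calls.

The estimators implement the internal-standard calibration used in plant
flow cytometry:

* 2C(sample, pg) = mean_peak(sample) * 2C(standard) / mean_peak(standard),
  with the co-processed *S. lycopersicum* standard at 2C = 2.00 pg;
* AT%(sample) = AT%(standard) * (R_DAPI / R_PI)^(1/r), where each R is the
  sample/standard fluorescence-intensity ratio for that fluorochrome and
  r = 3 is the DAPI binding-length exponent; GC% = 100 - AT%.

Ploidy is called against a reference monoploid (1Cx) value on the genus
basic chromosome number x = 11 (*Psidium*), cytotype variation is flagged
when the within-group 2C range approaches the reference 1Cx, mixoploidy
when two or more somatic populations each carry at least a reporting
fraction of cells, and hybrid-origin scenarios enumerate the four
reduced/unreduced gamete combinations of a diploid x tetraploid cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .histogram import PeakEstimate
from .synthetic import STANDARD_2C_PG, STANDARD_AT_PERCENT

__all__ = [
    "BASIC_CHROMOSOME_NUMBER",
    "DEFAULT_REFERENCE_1CX",
    "CalibrationStandard",
    "GenomeEstimate",
    "PloidyCall",
    "CytotypeReport",
    "MixoploidyCall",
    "HybridScenario",
    "QCError",
    "estimate_2c",
    "estimate_at_gc",
    "monoploid_value",
    "infer_ploidy",
    "flag_cytotypes",
    "detect_mixoploidy",
    "hybrid_expected_2c",
    "classify_hybrid",
    "expected_fish_signals",
]

#: Basic chromosome number of the genus (x = 11 in Psidium).
BASIC_CHROMOSOME_NUMBER = 11

#: Reference monoploid genome size (pg): the diploid P. guajava 1Cx value.
DEFAULT_REFERENCE_1CX = 0.475


class QCError(ValueError):
    """Raised when estimation is attempted on a QC-failed peak."""


@dataclass(frozen=True)
class CalibrationStandard:
    """Internal standard of known genome size and base composition."""

    name: str = "S. lycopersicum"
    c2: float = STANDARD_2C_PG
    at_percent: float = STANDARD_AT_PERCENT

    def __post_init__(self) -> None:
        if self.c2 <= 0:
            raise ValueError("standard c2 must be > 0")
        if not 0 < self.at_percent < 100:
            raise ValueError("standard at_percent must lie in (0, 100)")


@dataclass(frozen=True)
class GenomeEstimate:
    """Per-access genome estimate; gc_percent = 100 - at_percent exactly."""

    access_id: str
    c2: float
    at_percent: float = float("nan")
    gc_percent: float = float("nan")
    qc_pass: bool = True


@dataclass(frozen=True)
class ATGCEstimate:
    at_percent: float
    gc_percent: float
    valid: bool


@dataclass(frozen=True)
class PloidyCall:
    ploidy: int
    two_n: int  # = 11 * ploidy
    cx1: float  # monoploid value, c2 / ploidy
    residual: float  # |c2 - ploidy * reference_1cx|
    ambiguous: bool


@dataclass(frozen=True)
class CytotypeReport:
    range_pg: float
    flagged: bool
    reference_1cx: float
    factor: float
    calls: tuple  # (access_id, PloidyCall) pairs


@dataclass(frozen=True)
class MixoploidyCall:
    component_c2: tuple[float, ...]
    component_fractions: tuple[float, ...]
    is_mixoploid: bool
    reporting_threshold: float


@dataclass(frozen=True)
class HybridScenario:
    """One gamete-fusion scenario of a diploid (a) x tetraploid (b) cross."""

    name: str
    parent_a_reduced: bool
    parent_b_reduced: bool
    expected_c2: float


def _require_qc(peak: PeakEstimate, role: str) -> None:
    # Only an explicit QC failure is refused; unchecked peaks (qc_pass None)
    # are the caller's responsibility.
    if peak.qc_pass is False:
        raise QCError(f"{role} peak failed QC ({peak.qc_reason or 'flagged'})")


def estimate_2c(
    sample_peak: PeakEstimate,
    standard_peak: PeakEstimate,
    standard: CalibrationStandard = CalibrationStandard(),
) -> float:
    """Nuclear 2C value (pg) of the access from G0/G1 peak means.

    2C = sample mean channel * standard 2C / standard mean channel.
    Scale-invariant: any common gain factor cancels.
    """
    _require_qc(sample_peak, "sample")
    _require_qc(standard_peak, "standard")
    if standard_peak.mean_channel <= 0:
        raise ValueError("standard peak mean must be > 0")
    return sample_peak.mean_channel * standard.c2 / standard_peak.mean_channel


def estimate_at_gc(
    r_dapi: float,
    r_pi: float,
    standard: CalibrationStandard = CalibrationStandard(),
    r_exponent: float = 3.0,
) -> ATGCEstimate:
    """AT% and GC% from the two fluorochromes' sample/standard ratios.

    AT = AT_standard * (R_DAPI / R_PI)^(1/r); GC = 100 - AT.  Estimates
    falling outside (0, 100) are reported but flagged invalid.
    """
    if r_dapi <= 0 or r_pi <= 0:
        raise ValueError("fluorescence ratios must be positive")
    at = standard.at_percent * (r_dapi / r_pi) ** (1.0 / r_exponent)
    gc = 100.0 - at
    return ATGCEstimate(at, gc, valid=0.0 < at < 100.0)


def monoploid_value(c2: float, ploidy: int) -> float:
    """1Cx (pg): 2C DNA amount divided by the ploidy level."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return c2 / ploidy


def infer_ploidy(
    c2: float,
    reference_1cx: float = DEFAULT_REFERENCE_1CX,
    ambiguity_factor: float = 0.25,
) -> PloidyCall:
    """Nearest-integer ploidy call against a reference monoploid value.

    ploidy = round(c2 / 1Cx_ref), at least 1; 2n = 11 * ploidy.  Calls
    whose residual |c2 - ploidy * 1Cx_ref| exceeds ``ambiguity_factor``
    times the reference are flagged ambiguous.  Odd levels are allowed
    (the genus reports 3x, 5x, 7x cytotypes).
    """
    if reference_1cx <= 0:
        raise ValueError("reference_1cx must be > 0")
    ploidy = max(1, int(round(c2 / reference_1cx)))
    residual = abs(c2 - ploidy * reference_1cx)
    return PloidyCall(
        ploidy=ploidy,
        two_n=BASIC_CHROMOSOME_NUMBER * ploidy,
        cx1=c2 / ploidy,
        residual=residual,
        ambiguous=residual > ambiguity_factor * reference_1cx,
    )


def flag_cytotypes(
    values: Sequence[tuple[str, float]],
    reference_1cx: float = DEFAULT_REFERENCE_1CX,
    factor: float = 0.9,
) -> CytotypeReport:
    """Flag cytotype variation within a set of accesses.

    The within-set 2C range (max - min) is compared against the reference
    1Cx; variation "close to or higher than" the monoploid value — here
    range >= factor * 1Cx, default factor 0.9 — indicates accesses with
    different chromosome numbers (euploid/aneuploid cytotypes).  A
    singleton set reports range 0, unflagged.
    """
    if not values:
        raise ValueError("need at least one (access_id, c2) value")
    c2s = np.array([v for _, v in values], float)
    rng = float(c2s.max() - c2s.min()) if len(values) > 1 else 0.0
    calls = tuple((aid, infer_ploidy(c2, reference_1cx)) for aid, c2 in values)
    return CytotypeReport(
        range_pg=rng,
        flagged=len(values) > 1 and rng >= factor * reference_1cx,
        reference_1cx=reference_1cx,
        factor=factor,
        calls=calls,
    )


def detect_mixoploidy(
    peaks: Sequence[PeakEstimate],
    standard_peak: PeakEstimate,
    standard: CalibrationStandard = CalibrationStandard(),
    reporting_threshold: float = 0.10,
) -> MixoploidyCall:
    """Mixoploidy call from a sample's somatic G0/G1 peaks.

    ``peaks`` must exclude the standard peak.  Each somatic peak is
    converted to 2C via the standard, fractions are renormalized over
    somatic peaks only, and the sample is mixoploid iff at least two
    components each reach ``reporting_threshold``.
    """
    if not peaks:
        raise ValueError("no sample peaks supplied")
    if any(p.is_standard for p in peaks):
        raise ValueError("sample peaks must exclude the standard peak")
    c2 = tuple(estimate_2c(p, standard_peak, standard) for p in peaks)
    raw = np.array([p.event_fraction for p in peaks], float)
    frac = tuple(raw / raw.sum())
    n_major = sum(f >= reporting_threshold for f in frac)
    return MixoploidyCall(c2, frac, n_major >= 2, reporting_threshold)


def hybrid_expected_2c(
    parent_a_c2: float, parent_b_c2: float
) -> list[HybridScenario]:
    """Expected hybrid 2C under the four gamete-fusion scenarios.

    For a diploid parent a crossed with a tetraploid parent b, a gamete
    contributes half the parental 2C if reduced and the full 2C if
    unreduced: allotriploid (both reduced), allotetraploid (a unreduced,
    b reduced), allopentaploid (a reduced, b unreduced), allohexaploid
    (both unreduced).  Names reflect the 2x x 4x cross; the arithmetic is
    general.
    """
    if parent_a_c2 <= 0 or parent_b_c2 <= 0:
        raise ValueError("parental 2C values must be positive")
    a, b = parent_a_c2, parent_b_c2
    return [
        HybridScenario("allotriploid", True, True, a / 2 + b / 2),
        HybridScenario("allotetraploid", False, True, a + b / 2),
        HybridScenario("allopentaploid", True, False, a / 2 + b),
        HybridScenario("allohexaploid", False, False, a + b),
    ]


def classify_hybrid(
    observed_c2: float,
    scenarios: Sequence[HybridScenario],
    tolerance: float,
) -> str:
    """Nearest-scenario classification of an observed hybrid 2C.

    Returns the best scenario's name, or ``"unresolved"`` when the best
    distance exceeds ``tolerance`` or the two best distances tie within
    10% of the tolerance.
    """
    if not scenarios:
        raise ValueError("scenarios must be nonempty")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    dists = sorted(
        (abs(observed_c2 - s.expected_c2), s.name) for s in scenarios
    )
    best_d, best_name = dists[0]
    if best_d > tolerance:
        return "unresolved"
    if len(dists) > 1 and dists[1][0] - best_d <= 0.10 * tolerance:
        return "unresolved"
    return best_name


def expected_fish_signals(copies_per_monoploid: int, ploidy: int) -> int:
    """Expected FISH signal count: copies per monoploid genome x ploidy."""
    if copies_per_monoploid < 1 or ploidy < 1:
        raise ValueError("both arguments must be >= 1")
    return copies_per_monoploid * ploidy
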