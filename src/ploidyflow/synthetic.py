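"""Event-level flow-cytometry simulator for genome-size analysis.

Emulates the fluorescence event structure that the downstream estimators
assume: each nuclear population contributes a Gaussian G0/G1 peak whose
mean is proportional to its 2C DNA amount (propidium iodide channel) or to
2C scaled by base composition (DAPI channel), an optional G2 peak at twice
the G0/G1 mean, and an exponentially decaying debris background.  Every
simulated sample carries an internal-standard population of known 2C and
AT%, mirroring the co-chopped *Solanum lycopersicum* reference used in
plant flow cytometry.

Measurement model per population with DNA amount ``c2`` (pg) and AT
fraction ``at`` (percent):

* PI channel mean   = ``gain_pi * c2``                 (intercalator, base-blind)
* DAPI channel mean = ``gain_dapi * c2 * (at/100)**r`` (AT-preferential,
  binding-length exponent ``r``, default 3)

Event intensities are continuous arbitrary units; a binning utility lives
in :mod:`ploidyflow.histogram` for instrument-like 1024-channel output.
Ground-truth per-event population labels are kept in the sample metadata
so tests can use label-wise averages as an exact oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

PI = "PI"
DAPI = "DAPI"
CHANNELS = (PI, DAPI)

#: Internal standard used throughout: Solanum lycopersicum 'Stupické'.
STANDARD_2C_PG = 2.00
STANDARD_AT_PERCENT = 64.50

#: DAPI binding-length exponent.
DEFAULT_R_EXPONENT = 3.0

#: Default peak coefficient of variation (percent). Instrument-quality plant
#: histograms run at CV 2-5%; 3% is a typical mid-range value.
DEFAULT_CV_PERCENT = 3.0

DEBRIS_LABEL = "debris"


class SpecError(ValueError):
    """Raised for simulation specs violating their invariants."""


@dataclass(frozen=True)
class PopulationSpec:
    """Ground truth for one nuclear population within a sample."""

    label: str
    c2_true: float  # pg
    at_true: float = STANDARD_AT_PERCENT  # percent AT, in (0, 100)
    cv_true: float = DEFAULT_CV_PERCENT  # percent
    event_fraction: float = 1.0  # fraction of non-debris events
    is_standard: bool = False

    def validate(self) -> None:
        if self.c2_true <= 0:
            raise SpecError(f"population {self.label!r}: c2_true must be > 0")
        if not 0 < self.at_true < 100:
            raise SpecError(f"population {self.label!r}: at_true must lie in (0, 100)")
        if self.cv_true <= 0:
            raise SpecError(f"population {self.label!r}: cv_true must be > 0")
        if not 0 < self.event_fraction <= 1:
            raise SpecError(
                f"population {self.label!r}: event_fraction must lie in (0, 1]"
            )


def internal_standard(
    event_fraction: float = 0.5, cv_true: float = DEFAULT_CV_PERCENT
) -> PopulationSpec:
    """The *S. lycopersicum* internal standard (2C = 2.00 pg, AT = 64.50%)."""
    return PopulationSpec(
        label="standard",
        c2_true=STANDARD_2C_PG,
        at_true=STANDARD_AT_PERCENT,
        cv_true=cv_true,
        event_fraction=event_fraction,
        is_standard=True,
    )


@dataclass(frozen=True)
class SampleSpec:
    """Full recipe for one simulated two-channel sample."""

    sample_id: str
    populations: tuple[PopulationSpec, ...]
    g2_fraction: float = 0.0
    debris_fraction: float = 0.0
    n_events: int = 10_000
    gain_pi: float = 100.0
    gain_dapi: float = 100.0
    r_exponent: float = DEFAULT_R_EXPONENT
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))

    def validate(self) -> None:
        if not self.populations:
            raise SpecError("sample needs at least one population")
        for pop in self.populations:
            pop.validate()
        n_std = sum(p.is_standard for p in self.populations)
        if n_std != 1:
            raise SpecError(
                f"exactly one population must be flagged is_standard (got {n_std})"
            )
        total = sum(p.event_fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"population event fractions must sum to 1 (got {total})")
        if not 0 <= self.g2_fraction < 0.5:
            raise SpecError("g2_fraction must lie in [0, 0.5)")
        if not 0 <= self.debris_fraction < 0.5:
            raise SpecError("debris_fraction must lie in [0, 0.5)")
        if self.n_events < 1:
            raise SpecError("n_events must be >= 1")
        if self.gain_pi <= 0 or self.gain_dapi <= 0:
            raise SpecError("gains must be positive")

    @property
    def standard(self) -> PopulationSpec:
        return next(p for p in self.populations if p.is_standard)


@dataclass
class FlowSample:
    """Fluorescence events for one sample on one channel."""

    sample_id: str
    channel: str
    events: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.channel not in CHANNELS:
            raise SpecError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.events.size == 0:
            raise SpecError("events must be nonempty")
        if np.any(self.events < 0):
            raise SpecError("intensities must be nonnegative")


def population_mean(
    pop: PopulationSpec, channel: str, spec: SampleSpec
) -> float:
    """True G0/G1 peak mean of ``pop`` on ``channel`` under ``spec``'s gains."""
    if channel == PI:
        return spec.gain_pi * pop.c2_true
    return spec.gain_dapi * pop.c2_true * (pop.at_true / 100.0) ** spec.r_exponent


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws with negatives redrawn (intensities are physical)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, 0.0, None)


def _truncated_exponential(
    rng: np.random.Generator, scale: float, upper: float, n: int
) -> np.ndarray:
    """Exponential decay truncated at ``upper`` via inverse CDF."""
    u = rng.uniform(0.0, 1.0 - np.exp(-upper / scale), size=n)
    return -scale * np.log1p(-u)


def _allocate_counts(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``n``, largest-remainder apportionment."""
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def simulate_sample(spec: SampleSpec) -> tuple[FlowSample, FlowSample]:
    """Simulate one sample; returns ``(pi_sample, dapi_sample)``.

    A single RNG stream seeded from ``spec.seed`` drives both channels, so
    identical specs give bit-identical event lists.  Populations whose
    means sit closer than 3 pooled standard deviations are simulated as
    requested but flagged via a ``"peaks_may_merge:..."`` warning in the
    metadata (the estimator may then merge them).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_debris = int(round(spec.n_events * spec.debris_fraction))
    n_signal = spec.n_events - n_debris
    fractions = np.array([p.event_fraction for p in spec.populations])
    counts = _allocate_counts(n_signal, fractions)

    warnings: list[str] = []
    samples: list[FlowSample] = []
    for channel in CHANNELS:
        means = np.array([population_mean(p, channel, spec) for p in spec.populations])
        sds = means * np.array([p.cv_true for p in spec.populations]) / 100.0
        for i in range(len(means)):
            for j in range(i + 1, len(means)):
                pooled = float(np.hypot(sds[i], sds[j]))
                if abs(means[i] - means[j]) < 3.0 * pooled:
                    warnings.append(
                        "peaks_may_merge:%s:%s/%s"
                        % (channel, spec.populations[i].label, spec.populations[j].label)
                    )
        events: list[np.ndarray] = []
        labels: list[np.ndarray] = []
        for pop, n_pop, mu, sd in zip(spec.populations, counts, means, sds):
            n_g2 = int(round(n_pop * spec.g2_fraction))
            n_g1 = n_pop - n_g2
            if n_g1:
                events.append(_truncated_normal(rng, mu, sd, n_g1))
                labels.append(np.full(n_g1, pop.label))
            if n_g2:
                events.append(_truncated_normal(rng, 2 * mu, 2 * sd, n_g2))
                labels.append(np.full(n_g2, pop.label + "/G2"))
        if n_debris:
            scale = 0.3 * means.min()
            events.append(_truncated_exponential(rng, scale, means.max(), n_debris))
            labels.append(np.full(n_debris, DEBRIS_LABEL))
        samples.append(
            FlowSample(
                sample_id=spec.sample_id,
                channel=channel,
                events=np.concatenate(events),
                metadata={
                    "labels": np.concatenate(labels),
                    "true_means": dict(zip((p.label for p in spec.populations), means)),
                    "warnings": list(warnings),
                    "seed": spec.seed,
                },
            )
        )
    return samples[0], samples[1]


def simulate_mixoploid(
    spec_low: PopulationSpec,
    spec_high: PopulationSpec,
    fraction_low: float,
    base: SampleSpec,
) -> tuple[FlowSample, FlowSample]:
    """Simulate a mixoploid: internal standard plus two somatic populations.

    ``fraction_low`` is the fraction of *sample* (non-standard, non-debris)
    cells belonging to ``spec_low``; the standard keeps the event fraction
    it has in ``base``.
    """
    if not 0 < fraction_low < 1:
        raise SpecError("fraction_low must lie in (0, 1)")
    std = base.standard
    f_sample = 1.0 - std.event_fraction
    populations = (
        std,
        dataclasses.replace(
            spec_low, event_fraction=f_sample * fraction_low, is_standard=False
        ),
        dataclasses.replace(
            spec_high, event_fraction=f_sample * (1.0 - fraction_low), is_standard=False
        ),
    )
    return simulate_sample(dataclasses.replace(base, populations=populations))


def simulate_correlated_pair(
    n: int, rho: float, seed: int, mean: tuple[float, float] = (0.0, 0.0),
    sd: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal draws with population Pearson correlation ``rho``.

    Used to emulate phenotype pairs (e.g. genome size vs essential-oil
    yield) with a known correlation for estimator-closure tests.
    """
    if not -1.0 <= rho <= 1.0:
        raise SpecError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    return mean[0] + sd[0] * z1, mean[1] + sd[1] * z2
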