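"""End-to-end analysis pipeline.

Simulate or ingest two-channel event data, detect and QC G0/G1 peaks,
estimate 2C / AT% / GC% against the internal standard, call ploidy,
cytotypes and mixoploidy, enumerate hybrid scenarios where parents are
configured, cluster accessions by the optimized Tocher method, summarize
per group and (when a phenotype table is supplied) correlate genome and
phenotype variables.  Everything is driven by one configuration mapping
(YAML/JSON-friendly) and a single seed; identical config + seed give
identical outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytogenomics import (
    DEFAULT_REFERENCE_1CX,
    CalibrationStandard,
    GenomeEstimate,
    detect_mixoploidy,
    estimate_2c,
    estimate_at_gc,
    flag_cytotypes,
    hybrid_expected_2c,
    infer_ploidy,
)
from .histogram import detect_peaks, mark_standard, qc_cv, read_flow_table
from .phenotype import correlate, summarize_groups
from .synthetic import (
    DAPI,
    PI,
    PopulationSpec,
    SampleSpec,
    FlowSample,
    population_mean,
    simulate_sample,
)
from .tocher import euclidean_distances, tocher_optimized

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending sample."""


@dataclass
class PipelineConfig:
    """All knobs of the analysis in one place.

    Exactly one input mode: ``samples`` (simulation specs) or
    ``events_path`` (tidy event table).  ``metadata`` maps sample ids to
    species/family labels; ``standard_expected`` gives the expected
    standard peak position per channel in file mode (in simulate mode it
    is derived from the gains).
    """

    samples: list[dict] = field(default_factory=list)
    events_path: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)
    phenotype_path: str | None = None
    standard: CalibrationStandard = field(default_factory=CalibrationStandard)
    standard_expected: dict[str, float] = field(default_factory=dict)
    r_exponent: float = 3.0
    cv_threshold: float = 5.0
    reference_1cx: float = DEFAULT_REFERENCE_1CX
    cytotype_factor: float = 0.9
    mixoploidy_threshold: float = 0.10
    cluster_variables: tuple[str, ...] = ("c2", "gc_percent")
    correlation_mode: str = "individuals"  # or "group_means"
    hybrid_parents: tuple[float, float] | None = None
    max_peaks: int = 5
    min_fraction: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if bool(self.samples) == bool(self.events_path):
            raise PipelineError("configure exactly one input mode: samples | events_path")
        for name in ("cv_threshold", "reference_1cx", "cytotype_factor",
                     "mixoploidy_threshold", "min_fraction", "r_exponent"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if self.correlation_mode not in ("individuals", "group_means"):
            raise PipelineError("correlation_mode must be individuals | group_means")


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load a YAML/JSON config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.update(overrides)
    if "standard" in raw and isinstance(raw["standard"], dict):
        raw["standard"] = CalibrationStandard(**raw["standard"])
    if "hybrid_parents" in raw and raw["hybrid_parents"] is not None:
        raw["hybrid_parents"] = tuple(raw["hybrid_parents"])
    if "cluster_variables" in raw:
        raw["cluster_variables"] = tuple(raw["cluster_variables"])
    return PipelineConfig(**raw)


def _build_sample_spec(raw: dict, seed: int, index: int) -> SampleSpec:
    pops = tuple(PopulationSpec(**p) for p in raw["populations"])
    kwargs = {k: v for k, v in raw.items() if k != "populations"}
    kwargs.setdefault("seed", seed + index)
    return SampleSpec(populations=pops, **kwargs)


@dataclass
class PipelineReport:
    estimates: pd.DataFrame
    summary: pd.DataFrame
    ploidy: pd.DataFrame
    cytotypes: pd.DataFrame
    mixoploidy: pd.DataFrame
    hybrids: pd.DataFrame | None
    clusterings: dict[str, pd.DataFrame]
    correlations: pd.DataFrame | None
    log: dict


def _analyze_channel(
    sample: FlowSample, expected_standard: float, config: PipelineConfig
):
    det = detect_peaks(
        sample,
        max_peaks=config.max_peaks,
        min_fraction=config.min_fraction,
        expected_means=(expected_standard,),
    )
    if not det.peaks:
        return None, None, det.flags
    peaks = qc_cv(mark_standard(det.peaks, expected_standard), config.cv_threshold)
    std = next(p for p in peaks if p.is_standard)
    others = [p for p in peaks if not p.is_standard]
    return std, others, det.flags


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage; see module docstring.  Raises :class:`PipelineError`
    with the stage name and sample id on any stage failure."""
    config.validate()
    log: dict[str, Any] = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {
            "cv_threshold": config.cv_threshold,
            "reference_1cx": config.reference_1cx,
            "cytotype_factor": config.cytotype_factor,
            "mixoploidy_threshold": config.mixoploidy_threshold,
            "min_fraction": config.min_fraction,
            "r_exponent": config.r_exponent,
            "standard_c2": config.standard.c2,
            "standard_at_percent": config.standard.at_percent,
        },
        "stages": {},
    }

    # -- input stage -------------------------------------------------------
    expected: dict[str, dict[str, float]] = {}
    if config.samples:
        samples: dict[str, dict[str, FlowSample]] = {}
        for i, raw in enumerate(config.samples):
            spec = _build_sample_spec(dict(raw), config.seed, i)
            pi, dapi = simulate_sample(spec)
            samples[spec.sample_id] = {PI: pi, DAPI: dapi}
            expected[spec.sample_id] = {
                PI: population_mean(spec.standard, PI, spec),
                DAPI: population_mean(spec.standard, DAPI, spec),
            }
    else:
        flat = read_flow_table(config.events_path)
        samples = {}
        for s in flat:
            samples.setdefault(s.sample_id, {})[s.channel] = s
        if not set(config.standard_expected) >= {PI, DAPI}:
            raise PipelineError(
                "stage 'input': file mode needs standard_expected for PI and DAPI"
            )
        for sid in samples:
            expected[sid] = dict(config.standard_expected)
    log["stages"]["input"] = {"n_samples": len(samples)}

    # -- peaks / QC / estimates -------------------------------------------
    est_rows, mixo_rows, qc_rows = [], [], []
    estimates: list[GenomeEstimate] = []
    for sid, by_channel in samples.items():
        try:
            std_pi, others_pi, flags_pi = _analyze_channel(
                by_channel[PI], expected[sid][PI], config
            )
            have_dapi = DAPI in by_channel
            std_da = others_da = None
            flags_da: list[str] = []
            if have_dapi:
                std_da, others_da, flags_da = _analyze_channel(
                    by_channel[DAPI], expected[sid][DAPI], config
                )
        except Exception as exc:  # pragma: no cover - defensive wrapping
            raise PipelineError(f"stage 'peaks' failed for sample {sid!r}: {exc}") from exc

        qc_rows.append(
            {
                "sample_id": sid,
                "pi_flags": ";".join(flags_pi or []),
                "dapi_flags": ";".join(flags_da or []),
                "pi_standard_cv": getattr(std_pi, "cv", np.nan),
                "pi_standard_pass": getattr(std_pi, "qc_pass", False),
            }
        )
        if std_pi is None or not others_pi:
            continue
        dominant = max(others_pi, key=lambda p: p.event_fraction)
        usable = std_pi.qc_pass and dominant.qc_pass
        if not usable:
            continue
        c2 = estimate_2c(dominant, std_pi, config.standard)
        at = gc = np.nan
        if have_dapi and std_da is not None and others_da:
            dom_da = max(others_da, key=lambda p: p.event_fraction)
            if std_da.qc_pass and dom_da.qc_pass:
                r_pi = dominant.mean_channel / std_pi.mean_channel
                r_da = dom_da.mean_channel / std_da.mean_channel
                res = estimate_at_gc(r_da, r_pi, config.standard, config.r_exponent)
                if res.valid:
                    at, gc = res.at_percent, res.gc_percent
        estimates.append(GenomeEstimate(sid, c2, at, gc, qc_pass=True))
        est_rows.append(
            {"access_id": sid, "c2": c2, "at_percent": at, "gc_percent": gc,
             "group": config.metadata.get(sid, "")}
        )
        passing = [p for p in others_pi if p.qc_pass]
        if passing:
            call = detect_mixoploidy(
                passing, std_pi, config.standard, config.mixoploidy_threshold
            )
            mixo_rows.append(
                {
                    "sample_id": sid,
                    "is_mixoploid": call.is_mixoploid,
                    "component_c2": ";".join(f"{c:.3f}" for c in call.component_c2),
                    "component_fractions": ";".join(
                        f"{f:.3f}" for f in call.component_fractions
                    ),
                }
            )
    est_df = pd.DataFrame(
        est_rows, columns=["access_id", "c2", "at_percent", "gc_percent", "group"]
    )
    log["stages"]["estimates"] = {
        "n_in": len(samples), "n_passed_qc": len(est_rows),
        "qc_summary": qc_rows,
    }

    # -- ploidy & cytotypes ------------------------------------------------
    ploidy_rows = []
    for row in est_rows:
        call = infer_ploidy(row["c2"], config.reference_1cx)
        ploidy_rows.append(
            {"access_id": row["access_id"], "c2": row["c2"], "ploidy": call.ploidy,
             "two_n": call.two_n, "cx1": call.cx1, "residual": call.residual,
             "ambiguous": call.ambiguous}
        )
    ploidy_df = pd.DataFrame(
        ploidy_rows,
        columns=["access_id", "c2", "ploidy", "two_n", "cx1", "residual", "ambiguous"],
    )

    cyto_rows = []
    if est_rows:
        by_group: dict[str, list] = {}
        for row in est_rows:
            by_group.setdefault(row["group"] or row["access_id"], []).append(
                (row["access_id"], row["c2"])
            )
        for group, vals in by_group.items():
            rep = flag_cytotypes(vals, config.reference_1cx, config.cytotype_factor)
            cyto_rows.append(
                {"group": group, "n": len(vals), "range_pg": rep.range_pg,
                 "cytotype_variation": rep.flagged}
            )
    cyto_df = pd.DataFrame(
        cyto_rows, columns=["group", "n", "range_pg", "cytotype_variation"]
    )
    mixo_df = pd.DataFrame(
        mixo_rows,
        columns=["sample_id", "is_mixoploid", "component_c2", "component_fractions"],
    )

    # -- hybrids -----------------------------------------------------------
    hybrids_df = None
    if config.hybrid_parents is not None:
        a, b = config.hybrid_parents
        hybrids_df = pd.DataFrame(
            [
                {"scenario": s.name, "parent_a_reduced": s.parent_a_reduced,
                 "parent_b_reduced": s.parent_b_reduced,
                 "expected_c2": round(s.expected_c2, 2)}
                for s in hybrid_expected_2c(a, b)
            ]
        )

    # -- clustering --------------------------------------------------------
    clusterings: dict[str, pd.DataFrame] = {}
    for var in config.cluster_variables:
        if est_df.empty or var not in est_df.columns:
            continue
        sub = est_df.dropna(subset=[var])
        if len(sub) < 2:
            continue
        dm = euclidean_distances(list(zip(sub["access_id"], sub[var])))
        grouping = tocher_optimized(dm)
        assign = grouping.assignment()
        clusterings[var] = pd.DataFrame(
            {
                "access_id": sub["access_id"],
                var: sub[var],
                "tocher_group": [assign[i] + 1 for i in sub["access_id"]],
            }
        )
        log["stages"][f"tocher_{var}"] = {
            "theta": grouping.theta, "n_groups": grouping.n_groups,
        }

    # -- summary & correlations -------------------------------------------
    groups_map = {r["access_id"]: (r["group"] or r["access_id"]) for r in est_rows}
    summary_df = (
        summarize_groups(estimates, groups_map) if estimates else pd.DataFrame()
    )

    corr_df = None
    if config.phenotype_path:
        pheno = pd.read_csv(config.phenotype_path)
        merged = est_df.merge(pheno, on="access_id", how="inner")
        if config.correlation_mode == "group_means":
            merged = merged.groupby("group", sort=False).mean(numeric_only=True).reset_index()
        corr_df = correlate(merged.drop(columns=["group"], errors="ignore"))

    report = PipelineReport(
        estimates=est_df, summary=summary_df, ploidy=ploidy_df,
        cytotypes=cyto_df, mixoploidy=mixo_df, hybrids=hybrids_df,
        clusterings=clusterings, correlations=corr_df, log=log,
    )
    if config.out_dir:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.estimates.round(6).to_csv(out_dir / "estimates.csv", index=False)
    report.summary.round(6).to_csv(out_dir / "summary.csv", index=False)
    report.ploidy.round(6).to_csv(out_dir / "ploidy.csv", index=False)
    report.cytotypes.round(6).to_csv(out_dir / "cytotypes.csv", index=False)
    report.mixoploidy.to_csv(out_dir / "mixoploidy.csv", index=False)
    if report.hybrids is not None:
        report.hybrids.to_csv(out_dir / "hybrids.csv", index=False)
    for var, df in report.clusterings.items():
        df.round(6).to_csv(out_dir / f"tocher_{var}.csv", index=False)
    if report.correlations is not None:
        report.correlations.round(6).to_csv(out_dir / "correlations.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(report.log, fh, indent=2, default=str)
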