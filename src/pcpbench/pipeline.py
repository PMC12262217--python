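"""Orchestration: evaluate model configurations on a PCP file, end to end.

This is the library layer behind the command-line interface. A
:class:`RunConfig` names a PCP file and one or more :class:`ModelSpec`
entries (each with a framework tag); :func:`run_evaluate` filters the PCPs,
fits a branch length per PCP per model, computes per-site amino-acid
distributions at the fitted branch length, and writes a report set per
model: ``metrics.json``, ``counts.tsv``, ``branch_fits.tsv``, ``events.tsv``,
plus a dataset-level ``filter_report.json``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import engines, metrics, models, pcp_io
from .synthetic_data import SimulationConfig, generate_dataset

__all__ = ["ModelSpec", "RunConfig", "run_evaluate", "run_simulate", "evaluate_model"]

log = logging.getLogger("pcpbench")

FRAMEWORKS = ("NT", "NT-AA", "AA")


@dataclass
class ModelSpec:
    """One model to evaluate: a framework tag plus its input tables.

    NT needs ``kmer_file`` or ``per_site_file``; NT-AA additionally needs
    ``selection`` (``"blosum62"`` or a DMS TSV path); AA needs
    ``logits_file`` (per-PCP logit tables).
    """

    name: str
    framework: str
    kmer_file: str | None = None
    per_site_file: str | None = None
    selection: str | None = None
    logits_file: str | None = None

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"framework must be one of {FRAMEWORKS}, got {self.framework!r}")
        if self.framework in ("NT", "NT-AA"):
            if bool(self.kmer_file) == bool(self.per_site_file):
                raise ValueError(
                    f"model {self.name!r}: exactly one of kmer_file/per_site_file required"
                )
        if self.framework == "NT-AA" and not self.selection:
            raise ValueError(f"model {self.name!r}: NT-AA framework requires a selection source")
        if self.framework == "AA" and not self.logits_file:
            raise ValueError(f"model {self.name!r}: AA framework requires logits_file")


@dataclass
class RunConfig:
    """Declarative description of one evaluation run."""

    pcps: str
    models: list[ModelSpec]
    out: str
    seed: int = 0
    max_sub_frequency: float = 0.30
    window_reference: str | None = None
    exclude_naive_parents: bool = False
    naive_reference: str | None = None
    ssp_bin_edges: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
    region_bounds: dict[str, tuple[int, int]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        specs = [ModelSpec(**m) for m in raw.pop("models")]
        rb = raw.pop("region_bounds", None)
        if rb is not None:
            rb = {k: tuple(v) for k, v in rb.items()}
        return cls(models=specs, region_bounds=rb, **raw)

    def scheme(self) -> pcp_io.RegionScheme:
        if self.region_bounds is None:
            return pcp_io.RegionScheme()
        return pcp_io.RegionScheme(region_bounds=dict(self.region_bounds))


@dataclass
class ModelRun:
    """In-memory results of evaluating one model on a filtered PCP set."""

    spec_name: str
    report: metrics.MetricsReport
    fits: pd.DataFrame
    counts: pd.DataFrame
    events: pd.DataFrame
    dists: list[engines.CodonSiteDistribution] = field(repr=False, default_factory=list)
    engine_events: dict = field(default_factory=dict)


def _load_nt_model(spec: ModelSpec):
    if spec.kmer_file:
        table = models.read_kmer_model(spec.kmer_file, name=spec.name)
        return lambda parent: models.kmer_rates(table, parent)
    table = models.read_per_site_model(spec.per_site_file, name=spec.name)
    return lambda parent: models.per_site_rates(table, parent)


def _selection_profile(spec: ModelSpec, parent_aa: str) -> engines.SelectionProfile:
    if spec.selection == "blosum62":
        R = models.blosum_ratios(models.blosum62_matrix(), parent_aa)
    else:
        dms = models.read_dms(spec.selection)
        R = models.dms_ratios(dms, parent_aa)
    return engines.SelectionProfile.from_ratios(R)


def evaluate_model(
    pcps: Sequence[pcp_io.PCP],
    spec: ModelSpec,
    scheme: pcp_io.RegionScheme | None = None,
    seed: int = 0,
    ssp_bin_edges: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
) -> ModelRun:
    """Fit branch lengths and compute distributions and metrics for one model."""
    scheme = scheme or pcp_io.RegionScheme()
    engine_events: dict = {}
    fit_rows = []
    dists: list[engines.CodonSiteDistribution] = []

    if spec.framework in ("NT", "NT-AA"):
        rates_of = _load_nt_model(spec)
        # BLOSUM62 is parent-independent in its matrix; load once
        blosum = models.blosum62_matrix() if spec.selection == "blosum62" else None
        dms = (
            models.read_dms(spec.selection)
            if spec.framework == "NT-AA" and spec.selection != "blosum62"
            else None
        )
        for pcp in pcps:
            rates = rates_of(pcp.parent_nt)
            if spec.framework == "NT":
                fit = engines.fit_branch_nt(pcp, rates)
                dist = engines.codon_aa_distribution(rates, pcp.parent_nt, fit.tau_hat)
            else:
                if blosum is not None:
                    R = models.blosum_ratios(blosum, pcp.parent_aa)
                else:
                    R = models.dms_ratios(dms, pcp.parent_aa)
                profile = engines.SelectionProfile.from_ratios(R)
                fit = engines.fit_branch_ntaa(pcp, rates, profile, events=engine_events)
                dist = engines.apply_selection(
                    rates, pcp.parent_nt, profile, fit.tau_hat, events=engine_events
                )
            fit_rows.append(_fit_row(pcp, spec, fit))
            dists.append(dist)
    else:
        logit_tables = models.read_logits(spec.logits_file)
        for pcp in pcps:
            if pcp.pcp_id not in logit_tables:
                raise KeyError(f"model {spec.name!r}: no logits for pcp {pcp.pcp_id!r}")
            probs = models.logits_to_probabilities(logit_tables[pcp.pcp_id])
            fit = engines.fit_branch_aa(pcp, probs)
            dist = engines.aa_scaled_distribution(probs, pcp.parent_aa, fit.tau_hat)
            fit_rows.append(_fit_row(pcp, spec, fit))
            dists.append(dist)

    report = metrics.compute_metrics(
        pcps, dists, model_name=spec.name, scheme=scheme, seed=seed,
        ssp_bin_edges=ssp_bin_edges,
    )
    ssps = [metrics.site_substitution_probability(d) for d in dists]
    O, E = metrics.counts_distributions(pcps, ssps)
    counts = pd.DataFrame(
        {"imgt_position": O.index, "observed": O.to_numpy(), "expected": E.to_numpy()}
    )
    event_rows = []
    for pcp, dist in zip(pcps, dists):
        for ev in metrics.collect_events(pcp, dist, scheme):
            csp_sorted = np.sort(ev.csp)[::-1]
            p = ev.csp[metrics.AA_INDEX[ev.child_aa]]
            event_rows.append(
                {
                    "pcp_id": ev.pcp_id,
                    "imgt_position": ev.imgt_label,
                    "region": ev.region,
                    "parent_aa": ev.parent_aa,
                    "child_aa": ev.child_aa,
                    "csp_of_outcome": float(p),
                    "csp_rank": int(np.searchsorted(-csp_sorted, -p) + 1),
                }
            )
    events_df = pd.DataFrame(
        event_rows,
        columns=[
            "pcp_id", "imgt_position", "region", "parent_aa", "child_aa",
            "csp_of_outcome", "csp_rank",
        ],
    )
    return ModelRun(
        spec_name=spec.name,
        report=report,
        fits=pd.DataFrame(fit_rows),
        counts=counts,
        events=events_df,
        dists=dists,
        engine_events=engine_events,
    )


def _fit_row(pcp: pcp_io.PCP, spec: ModelSpec, fit: engines.BranchFit) -> dict:
    return {
        "pcp_id": pcp.pcp_id,
        "framework": spec.framework,
        "tau_init": fit.init_tau,
        "tau_hat": fit.tau_hat,
        "log_likelihood": fit.log_likelihood,
    }


def run_evaluate(config: RunConfig) -> dict[str, ModelRun]:
    """Evaluate every model in the config on the (filtered) PCP file and
    write one report set per model under ``config.out``."""
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    pcps = pcp_io.read_pcps(config.pcps)
    log.info("read %d PCPs from %s", len(pcps), config.pcps)

    if config.window_reference:
        ref = Path(config.window_reference).read_text().strip()
        before = len(pcps)
        pcps = [p for p in pcps if pcp_io.window_mutation_filter(p.parent_nt, ref)]
        log.info("window filter dropped %d PCPs", before - len(pcps))
    if config.exclude_naive_parents:
        if not config.naive_reference:
            raise ValueError("exclude_naive_parents requires naive_reference")
        naive = Path(config.naive_reference).read_text().strip().lower()
        before = len(pcps)
        pcps = [p for p in pcps if p.parent_nt != naive]
        log.info("naive-parent exclusion dropped %d PCPs", before - len(pcps))

    pcps, filter_report = pcp_io.filter_pcps(pcps, max_sub_frequency=config.max_sub_frequency)
    (out_dir / "filter_report.json").write_text(filter_report.to_json())
    log.info(
        "filtering kept %d / %d PCPs (%s)",
        filter_report.n_retained, filter_report.n_input, filter_report.dropped,
    )
    if not pcps:
        raise ValueError("no PCPs survived filtering")

    scheme = config.scheme()
    runs: dict[str, ModelRun] = {}
    for spec in config.models:
        run = evaluate_model(
            pcps, spec, scheme=scheme, seed=config.seed,
            ssp_bin_edges=config.ssp_bin_edges,
        )
        model_dir = out_dir / spec.name
        model_dir.mkdir(exist_ok=True)
        (model_dir / "metrics.json").write_text(run.report.to_json())
        run.counts.to_csv(model_dir / "counts.tsv", sep="\t", index=False)
        run.fits.to_csv(model_dir / "branch_fits.tsv", sep="\t", index=False)
        run.events.to_csv(model_dir / "events.tsv", sep="\t", index=False)
        if run.engine_events:
            log.info("model %s: engine events %s", spec.name, run.engine_events)
        log.info(
            "model %s: overlap=%.4f r_precision=%.4f accuracy=%.4f perplexity=%.4f",
            spec.name,
            run.report.overall.get("overlap", float("nan")),
            run.report.overall.get("r_precision", float("nan")),
            run.report.overall.get("substitution_accuracy", float("nan")),
            run.report.overall.get("csp_perplexity", float("nan")),
        )
        runs[spec.name] = run
    return runs


def run_simulate(config: SimulationConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a synthetic dataset and print a short summary."""
    pcp_path, truth_path = generate_dataset(config, out_dir)
    pcps = pcp_io.read_pcps(pcp_path)
    subs = sorted(len(p.aa_substitutions()) for p in pcps)
    median = subs[len(subs) // 2] if subs else 0
    log.info(
        "wrote %d PCPs (median %d AA substitutions per PCP) to %s",
        len(pcps), median, pcp_path,
    )
    return pcp_path, truth_path
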