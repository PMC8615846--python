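"""End-to-end orchestration: simulate -> behavioral statistics -> HRFs -> model search.

A :class:`RunConfig` fully determines a run (master seed, task timing, agent, generating
network, search settings); :func:`run_pipeline` executes the enabled stages in order,
persisting every intermediate artifact under the output directory as it goes, and
returns a :class:`RunReport`.  Re-running with the same config reproduces byte-identical
tables.  Output layout::

    out_dir/
      provenance.json              config hash, package version, stage list
      events/sub-NN_transfer_events.tsv
      timeseries/sub-NN_matrix.tsv
      behavior/attack_bins.tsv, rates.tsv, anova.tsv, pairwise.tsv, learning.json
      hrf/sub-NN_<input>.json, hrf_summary.tsv
      search/group_edges.tsv, individual_edges.tsv, fit_table.tsv, audit.log,
             group_structure.json
      recovery.json                when the generating truth is known
      summary.txt                  human-readable digest
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .behavior import (
    bin_attacks,
    learning_test,
    pairwise_probes,
    rm_anova_3way,
    transfer_rates,
)
from .gimme import GIMME, GIMMEResults, SearchConfig, evaluate_recovery
from .task import (
    AgentParams,
    NETWORK_PRESETS,
    TaskConfig,
    TrueNetwork,
    gen_instrumental_run,
    gen_transfer_behavior,
    gen_transfer_schedule,
    simulate_bold,
    write_events,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "write_report"]

ALL_STAGES = ("simulate", "behavior", "search", "recovery")


class PipelineError(RuntimeError):
    """A pipeline stage failed; prior artifacts are preserved on disk."""


@dataclass(frozen=True)
class RunConfig:
    """Master configuration of one pipeline run."""

    seed: int = 0
    n_subjects: int = 11
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    network: str | TrueNetwork = "paper_like"
    search: SearchConfig = field(default_factory=SearchConfig)
    out_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise PipelineError(f"unknown stages {unknown}; valid: {ALL_STAGES}")

    def resolve_network(self) -> TrueNetwork:
        if isinstance(self.network, TrueNetwork):
            return self.network
        if isinstance(self.network, str):
            if self.network in NETWORK_PRESETS:
                return NETWORK_PRESETS[self.network](n_subjects=self.n_subjects)
            path = Path(self.network)
            if path.exists():
                return TrueNetwork.from_json(path)
            raise PipelineError(
                f"network {self.network!r} is neither a preset {sorted(NETWORK_PRESETS)} "
                "nor an existing file"
            )
        raise PipelineError("network must be a preset name, file path, or TrueNetwork")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.network, TrueNetwork):
            d["network"] = self.network.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            t = dict(d["task"])
            for key in ("pav_iti_choices_s", "recharge_range_s"):
                if key in t:
                    t[key] = tuple(t[key])
            d["task"] = TaskConfig(**t)
        if "agent" in d and isinstance(d["agent"], dict):
            d["agent"] = AgentParams(**d["agent"])
        if "search" in d and isinstance(d["search"], dict):
            s = dict(d["search"])
            if "candidate_classes" in s:
                s["candidate_classes"] = tuple(s["candidate_classes"])
            d["search"] = SearchConfig(**s)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = TrueNetwork.from_dict(d["network"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RunReport:
    """Consolidated outputs of the enabled stages."""

    provenance: dict
    schedules: list = field(default_factory=list)
    matrices: list = field(default_factory=list)
    attack_bins: pd.DataFrame | None = None
    learning: dict | None = None
    rates: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    search: GIMMEResults | None = None
    recovery: dict | None = None


def _outdir(config: RunConfig) -> Path | None:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; see the module docstring for the layout."""
    out = _outdir(config)
    report = RunReport(
        provenance={
            "config_hash": config.config_hash(),
            "package_version": _version,
            "seed": config.seed,
            "stages": list(config.stages),
        }
    )
    truth = config.resolve_network() if set(config.stages) & {"simulate", "recovery"} else None
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            _stage_simulate(config, truth, report, out)
        if "behavior" in config.stages:
            stage = "behavior"
            _stage_behavior(config, report, out)
        if "search" in config.stages:
            stage = "search"
            _stage_search(config, report, out)
        if "recovery" in config.stages and report.search is not None:
            stage = "recovery"
            report.recovery = evaluate_recovery(report.search, truth)
            if out:
                with open(out / "recovery.json", "w") as fh:
                    json.dump(report.recovery, fh, indent=1)
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    if out:
        write_report(report, out)
    return report


def _stage_simulate(config: RunConfig, truth: TrueNetwork, report: RunReport, out):
    schedules = [
        gen_transfer_schedule(config.task, seed=config.seed * 1000 + i)
        for i in range(config.n_subjects)
    ]
    report.schedules = schedules
    report.matrices = simulate_bold(truth, schedules, config.task, seed=config.seed)
    if out:
        (out / "events").mkdir(exist_ok=True)
        (out / "timeseries").mkdir(exist_ok=True)
        for i, (sch, mat) in enumerate(zip(schedules, report.matrices), start=1):
            write_events(sch, out / "events" / f"sub-{i:02d}_transfer_events.tsv")
            mat.to_csv(
                out / "timeseries" / f"sub-{i:02d}_matrix.tsv",
                sep="\t",
                index=False,
                float_format="%.8g",
            )


def _stage_behavior(config: RunConfig, report: RunReport, out):
    if not report.schedules:
        raise PipelineError("behavior stage requires the simulate stage")
    bins_rows, first, last = [], [], []
    rate_frames = []
    for i, schedule in enumerate(report.schedules):
        _, _, attacks = gen_instrumental_run(
            config.task, config.agent, seed=config.seed * 1000 + i
        )
        bins = bin_attacks(attacks, config.task.session_length_s)
        bins_rows.append({"subject": f"sub-{i + 1:02d}", **{f"bin{b}": v for b, v in enumerate(bins)}})
        first.append(bins[0])
        last.append(bins[-1])
        record = gen_transfer_behavior(schedule, config.agent, seed=config.seed * 1000 + i)
        rate_frames.append(
            transfer_rates(
                record, schedule, config.task.transfer_reps_per_cs, subject_id=f"sub-{i + 1:02d}"
            )
        )
    t, df, p = learning_test(first, last)
    report.attack_bins = pd.DataFrame(bins_rows)
    report.learning = {"t": t, "df": df, "p": p}
    report.rates = pd.concat(rate_frames, ignore_index=True)
    report.anova = rm_anova_3way(report.rates)
    report.pairwise = pairwise_probes(report.rates)
    if out:
        b = out / "behavior"
        b.mkdir(exist_ok=True)
        report.attack_bins.to_csv(b / "attack_bins.tsv", sep="\t", index=False)
        report.rates.to_csv(b / "rates.tsv", sep="\t", index=False, float_format="%.6f")
        report.anova.to_csv(b / "anova.tsv", sep="\t", index=False, float_format="%.6g")
        report.pairwise.to_csv(b / "pairwise.tsv", sep="\t", index=False, float_format="%.6g")
        with open(b / "learning.json", "w") as fh:
            json.dump(report.learning, fh, indent=1)
        summary = {
            "anova": {r["effect"]: {k: r[k] for k in ("F", "p", "ges")} for _, r in report.anova.iterrows()},
            "pairwise": {
                r["comparison"]: {k: r[k] for k in ("t", "p_raw", "p_bonferroni")}
                for _, r in report.pairwise.iterrows()
            },
        }
        with open(b / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)


def _stage_search(config: RunConfig, report: RunReport, out):
    if not report.matrices:
        raise PipelineError("search stage requires the simulate stage")
    model = GIMME(report.matrices, config.search, tr_s=config.task.tr_s)
    result = model.fit()
    report.search = result
    if out:
        s = out / "search"
        s.mkdir(exist_ok=True)
        h = out / "hrf"
        h.mkdir(exist_ok=True)
        hrf_rows = []
        for i, per_input in enumerate(result.hrfs, start=1):
            for name, est in per_input.items():
                est.to_json(h / f"sub-{i:02d}_{name}.json")
                hrf_rows.append(
                    {
                        "subject": i,
                        "input": name,
                        "peak_time_s": est.peak_time_s,
                        "smoothing_lambda": est.smoothing_lambda,
                    }
                )
        pd.DataFrame(hrf_rows).to_csv(
            h / "hrf_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.group_edge_table().to_csv(
            s / "group_edges.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.edge_table(level="individual").to_csv(
            s / "individual_edges.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.fit_table().to_csv(
            s / "fit_table.tsv", sep="\t", index=False, float_format="%.6g"
        )
        result.group_structure.to_json(s / "group_structure.json")
        with open(s / "audit.log", "w") as fh:
            for entry in result.audit:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")


def write_report(report: RunReport, out_dir) -> list[str]:
    """Write provenance and the human-readable summary; returns the file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=1)
    lines = [f"pitgimme run {report.provenance['config_hash']}"]
    if report.learning is not None:
        lines.append(
            "instrumental learning: t(%d) = %.2f, p = %.4g"
            % (report.learning["df"], report.learning["t"], report.learning["p"])
        )
    if report.anova is not None:
        lines.append("three-way RM ANOVA:")
        lines.append(report.anova.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    if report.pairwise is not None:
        sig = report.pairwise[report.pairwise["significant"]]
        lines.append(
            "significant pairwise probes (Bonferroni): "
            + (", ".join(sig["comparison"]) if len(sig) else "none")
        )
    if report.search is not None:
        lines.append(report.search.summary())
    if report.recovery is not None:
        lines.append(
            "recovery vs truth: precision %.3f recall %.3f direction %.3f beta RMSE %.3f"
            % (
                report.recovery["precision"],
                report.recovery["recall"],
                report.recovery["direction_accuracy"],
                report.recovery["beta_rmse"],
            )
        )
    text = "\n".join(lines) + "\n"
    with open(out / "summary.txt", "w") as fh:
        fh.write(text)
    return sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
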