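"""End-to-end orchestration: plan -> stitch -> profile -> features.

A single :func:`run_pipeline` call takes a validated :class:`RunConfig`,
runs the stages in order (skipping stitching when an already-assembled
model is supplied), and returns a consolidated, schema-versioned
:class:`RunReport` whose every number is taken verbatim from one upstream
stage. The LPD-3 preset pins the planner and annotation parameters used
for the 4018-residue LPD-3/BLTP1 bridge (four ~1500-residue fragments with
>= 500-residue overlaps, terminal regions 1-72 and 3945-4018, and the
tunnel-entry mutation G200E); the user supplies the sequence/model files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import MegastitchError, ParameterError
from .fragment_planner import FragmentPlan, plan_fragments, validate_plan
from .seqfeatures import annotate_sequence
from .stitcher import assemble
from .structure_io import StructureModel, read_fasta, read_structure, write_structure
from .tunnel import (
    MutationSpec,
    estimate_axis,
    mutation_blockage,
    radius_profile,
    rod_length,
    tunnel_summary,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "LPD3_PRESET"]

SCHEMA_VERSION = 1

log = logging.getLogger("megastitch")

#: fixed parameters for the full-length LPD-3/BLTP1 analysis
LPD3_PRESET = {
    "L": 4018,
    "target_len": 1500,
    "min_overlap": 500,
    "max_len": 2500,
    "tm_region": (1, 72),
    "amphiphilic_region": (3945, 4018),
    "mutations": ["G200E"],
}


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Supply either ``fragment_paths`` (+ planner parameters or ``plan``) or
    ``model_path`` for an already-assembled structure. ``fasta_path`` is
    optional and enables the sequence-feature stage.
    """

    fasta_path: str | None = None
    fragment_paths: list[str] = field(default_factory=list)
    model_path: str | None = None
    plan: FragmentPlan | None = None
    # planner parameters (used when plan is None and fragments are given)
    length: int | None = None
    target_len: int = 1500
    min_overlap: int = 500
    max_len: int = 2500
    # stitcher
    splice_rule: str = "midpoint"
    trim_overlap: int = 0
    # profiler
    axis_window: int = 50
    station_step: float = 2.0
    shell: float = 3.0
    probe: float = 1.4
    # features
    tm_region: tuple[int, int] | None = None
    amphiphilic_region: tuple[int, int] | None = None
    mutations: list[str] = field(default_factory=list)
    # run control
    outdir: str = "megastitch_out"
    seed: int = 0
    lpd3_preset: bool = False

    def apply_preset(self) -> None:
        if not self.lpd3_preset:
            return
        self.length = LPD3_PRESET["L"]
        self.target_len = LPD3_PRESET["target_len"]
        self.min_overlap = LPD3_PRESET["min_overlap"]
        self.max_len = LPD3_PRESET["max_len"]
        self.tm_region = LPD3_PRESET["tm_region"]
        self.amphiphilic_region = LPD3_PRESET["amphiphilic_region"]
        self.mutations = list(LPD3_PRESET["mutations"])

    def validate(self) -> None:
        if self.model_path is None and not self.fragment_paths:
            raise ParameterError("supply either fragment_paths or model_path")
        for p in [self.fasta_path, self.model_path, *self.fragment_paths]:
            if p is not None and not Path(p).exists():
                raise ParameterError(f"input file does not exist: {p}")

    def echo(self) -> dict:
        return {
            "fasta_path": self.fasta_path,
            "fragment_paths": list(self.fragment_paths),
            "model_path": self.model_path,
            "plan": self.plan.to_dict() if self.plan else None,
            "length": self.length,
            "target_len": self.target_len,
            "min_overlap": self.min_overlap,
            "max_len": self.max_len,
            "splice_rule": self.splice_rule,
            "trim_overlap": self.trim_overlap,
            "axis_window": self.axis_window,
            "station_step": self.station_step,
            "shell": self.shell,
            "probe": self.probe,
            "tm_region": list(self.tm_region) if self.tm_region else None,
            "amphiphilic_region": list(self.amphiphilic_region)
            if self.amphiphilic_region
            else None,
            "mutations": list(self.mutations),
            "outdir": self.outdir,
            "seed": self.seed,
            "lpd3_preset": self.lpd3_preset,
        }


@dataclass
class RunReport:
    """Consolidated pipeline output; serializes to the report JSON."""

    data: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=float))

    def __getitem__(self, key: str):
        return self.data[key]


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write report/model/profile artifacts.

    Raises a stage-attributed :class:`MegastitchError` subclass on any
    failure; nothing is written unless all stages succeed except for the
    assembled model, which is written as soon as stitching completes.
    """
    config.apply_preset()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "seed": config.seed,
        "config": config.echo(),
    }

    # ---- sequence features ------------------------------------------------
    seq = None
    if config.fasta_path:
        _stage("features")
        seq = read_fasta(config.fasta_path)
        features = annotate_sequence(
            seq,
            tm_region=config.tm_region,
            amphiphilic_region=config.amphiphilic_region,
        )
        report["features"] = features.to_dict()
    else:
        report["features"] = None

    # ---- plan + stitch ----------------------------------------------------
    if config.model_path is not None:
        _stage("load-model")
        model = read_structure(config.model_path)
        report["plan"] = "not applicable"
        report["stitch"] = "not applicable"
    else:
        _stage("plan")
        plan = config.plan
        if plan is None:
            L = config.length if config.length is not None else (len(seq) if seq else None)
            if L is None:
                raise ParameterError(
                    "cannot derive sequence length: give length, plan or fasta"
                )
            plan = plan_fragments(L, config.target_len, config.min_overlap, config.max_len)
        coverage = validate_plan(plan)
        report["plan"] = {**plan.to_dict(), "coverage": coverage.to_dict()}

        _stage("stitch")
        if len(config.fragment_paths) != plan.n_fragments:
            raise ParameterError(
                f"plan expects {plan.n_fragments} fragments, got "
                f"{len(config.fragment_paths)} files"
            )
        fragments = [read_structure(p) for p in config.fragment_paths]
        model, stitch = assemble(
            fragments, plan, splice_rule=config.splice_rule, trim_overlap=config.trim_overlap
        )
        report["stitch"] = stitch.to_dict()
        write_structure(model, outdir / "assembled.pdb")

    # ---- geometry ---------------------------------------------------------
    _stage("profile")
    axis = estimate_axis(model, window=config.axis_window, step=config.station_step)
    profile = radius_profile(model, axis, shell=config.shell)
    summary = tunnel_summary(profile, probe=config.probe)
    length_A = rod_length(model)
    report["geometry"] = {
        "rod_length_A": length_A,
        "rod_length_nm": length_A / 10.0,
        "axis_arclength_A": axis.length,
        "tunnel": summary.to_dict(),
    }
    profile.to_frame().to_csv(outdir / "profile.tsv", sep="\t", index=False)

    # ---- mutation scans ---------------------------------------------------
    muts = {}
    for text in config.mutations:
        _stage(f"mutate-scan {text}")
        spec = MutationSpec.parse(text)
        table = mutation_blockage(model, spec, axis=axis, shell=config.shell)
        muts[text] = {
            "min_delta_radius_A": float(table["delta_radius"].min()),
            "argmin_s_A": float(table.loc[table["delta_radius"].idxmin(), "s"]),
            "n_stations": int(len(table)),
        }
    report["mutations"] = muts

    run_report = RunReport(report)
    run_report.to_json(outdir / "report.json")
    return run_report
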