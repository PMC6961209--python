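"""Stage orchestration: simulate -> pre-process -> sort -> smooth -> seam.

The desk-scale pipeline mirrors the stage order of filament processing:

1. ``preprocess``  — Tilt/Psi set to priors, Rot/origins reset.
2. ``segavg``      — 7-segment averages for classification SNR.
3. ``pfsort``      — supervised PF-number sorting + per-tube unification.
4. ``global``      — global Rot search against the assigned decorated
                     reference, per-tube Rot clustering/regression, and a
                     local re-search of origins at the unified Rot.
5. ``xysmooth``    — per-tube X/Y shift smoothing.
6. ``reavg``       — re-centred refined segment averages.
7. ``seam``        — decorator-only seam/register classification,
                     consensus correction, re-check, and tube QC.

Each stage writes its STAR table (and stack, when it produces images)
into a numbered directory; a manifest records the configuration and
per-stage counts.  Stages can be re-run individually and resume from the
artifacts of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import helical_geometry as hg
from . import reference_matching as rm
from . import seam_correction as sc
from . import segment_averaging as sa
from . import synthetic_data as sd
from . import trajectory_smoothing as ts
from . import star_io

__all__ = ["PipelineError", "PipelineConfig", "run_pipeline",
           "process_dataset", "export_for_relion", "import_from_relion"]

STAGES = ("preprocess", "segavg", "pfsort", "global",
          "xysmooth", "reavg", "seam")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Flat per-stage parameter sections with simulator defaults."""

    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    segavg: dict = dataclasses.field(default_factory=lambda: {"half_window": 3})
    pfsort: dict = dataclasses.field(
        default_factory=lambda: {"rot_step": 1.8, "max_shift": 65.0})
    global_search: dict = dataclasses.field(
        default_factory=lambda: {"rot_step": 1.8, "max_shift": 45.0})
    local_search: dict = dataclasses.field(
        default_factory=lambda: {"rot_step": 0.9, "rot_local_range": 1.8,
                                 "max_shift": 45.0})
    rotunify: dict = dataclasses.field(default_factory=lambda: {"tolerance": 8.0})
    xysmooth: dict = dataclasses.field(
        default_factory=lambda: {"jump_threshold": 20.5})
    qc: dict = dataclasses.field(
        default_factory=lambda: {"min_cluster_fraction": 0.5})
    seam: dict = dataclasses.field(
        default_factory=lambda: {"resolution_limit": 12.0})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for f in dataclasses.fields(cls):
            key = "global" if f.name == "global_search" else (
                "local" if f.name == "local_search" else f.name)
            if key in raw:
                kw[f.name] = raw[key]
        return cls(**kw)

    def sim_config(self) -> sd.SimConfig:
        return sd.SimConfig(seed=self.seed, **self.simulate)


def _params_for_label(label: str) -> hg.HelicalParams:
    n, s = (int(x) for x in label.split("-"))
    return hg.helical_table(n, s)


def process_dataset(dataset: sd.SyntheticDataset,
                    config: PipelineConfig | None = None) -> dict:
    """Run the full in-memory pipeline on a simulated dataset.

    Returns a state dict with per-stage tables, reports, and the final
    seam-convergence fraction.
    """
    if config is None:
        config = PipelineConfig()
    state: dict = {"dataset": dataset}
    stack, table = dataset.stack, dataset.table

    # 1. pre-processing
    table0 = star_io.set_priors_and_reset(table)
    state["preprocess"] = table0

    # 2. segment averages
    avgs = sa.make_segment_averages(stack, table0, **config.segavg)
    state["segavg"] = avgs

    # 3. PF-number sorting with per-tube unification
    res = rm.pf_sort(avgs, table0, search=rm.SearchGrid(**config.pfsort))
    unified, per_tube = rm.unify_class_per_tube(res.df, table0)
    per_tube["arch"] = [res.labels[c] for c in per_tube["modal_class"]]
    state["pfsort"] = {"result": res, "per_tube": per_tube,
                       "confidence": rm.confidence_report(per_tube)}
    arch_by_tube = dict(zip(per_tube["tube_id"], per_tube["arch"]))
    params_by_tube = {t: _params_for_label(a) for t, a in arch_by_tube.items()}

    # 4. global Rot search against the assigned decorated reference,
    #    per-tube unification, then a local origin re-search
    table1 = star_io.set_priors_and_reset(table0)
    df1 = table1.df
    length = 1.5 * table1.box_size * table1.pixel_size
    parts = []
    for label in sorted(set(arch_by_tube.values())):
        tube_ids = [t for t, a in arch_by_tube.items() if a == label]
        params = _params_for_label(label)
        lat = hg.build_lattice(params, length, decorated=True,
                               seam_pf=0 if params.has_seam else None)
        refs = rm.ReferenceSet([lat], [label], table1.pixel_size,
                               table1.box_size)
        sel = df1["tube_id"].isin(tube_ids).to_numpy()
        sub = table1.copy()
        sub.df = df1.loc[sel].reset_index(drop=True)
        gres = rm.match(avgs[sel], sub, refs,
                        rm.SearchGrid(**config.global_search))
        sub = gres.apply_to(sub)
        sub.df["_score"] = gres.df["score"].to_numpy()
        # per-tube Rot unification
        unified_tubes = []
        for tube in star_io.group_by_tube(sub):
            unified_tubes.append(ts.unify_rot(
                tube, scores=tube.df["_score"].to_numpy(), **config.rotunify))
        sub.df = pd.concat([t.df for t in unified_tubes], ignore_index=True)
        sub.df = sub.df.drop(columns="_score")
        # local re-search of origins at the unified Rot
        lres = rm.match(avgs[sel], sub, refs,
                        rm.SearchGrid(**config.local_search))
        sub = lres.apply_to(sub)
        parts.append(sub.df)
    table2 = table1.copy()
    table2.df = pd.concat(parts, ignore_index=True).sort_values(
        ["tube_id", "segment_index"], kind="stable").reset_index(drop=True)
    state["global"] = table2
    state["arch_by_tube"] = arch_by_tube
    state["params_by_tube"] = params_by_tube

    # 5. X/Y shift smoothing
    smoothed = [ts.smooth_xy_shifts(t, **config.xysmooth)
                for t in star_io.group_by_tube(table2)]
    table3 = table2.copy()
    table3.df = pd.concat([t.df for t in smoothed], ignore_index=True)
    state["xysmooth"] = table3

    # 6. re-centred refined segment averages
    ravgs, table4, excluded = sa.recentre_and_reaverage(
        stack, table3, **config.segavg)
    state["reavg"] = (ravgs, table4, excluded)

    # 7. seam check, correction, re-check + QC
    fraction, report, corrected = sc.verify_seam_convergence(
        ravgs, table4, params_by_tube, **config.seam)
    twist_by_tube = {t: params_by_tube[t].twist for t in params_by_tube}
    kept, rejected, qc_report = ts.qc_reject_tubes(
        corrected, twist_by_tube=twist_by_tube, **config.qc)
    state["seam"] = {"fraction_converged": fraction, "report": report,
                     "table": corrected, "qc": qc_report,
                     "kept": kept, "rejected": rejected}
    return state


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig | str | Path, out_dir,
                 stages=None) -> dict:
    """File-based pipeline run: simulate, process, persist per-stage dirs.

    ``stages`` may restrict which processing stages are (re)written; all
    requested stages' dependencies must already exist on disk or be
    produced in the same run, otherwise a :class:`PipelineError` names the
    missing artifact.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else list(stages)
    for s in requested:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    # dependency check: every stage before the first requested one must exist
    first = min(STAGES.index(s) for s in requested)
    for i, s in enumerate(STAGES[:first]):
        d = out / f"{i + 1:02d}_{s}"
        if not d.exists():
            raise PipelineError(
                f"stage {requested[0]!r} requires missing artifact {d}")

    sim_dir = out / "00_simulate"
    sim_dir.mkdir(exist_ok=True)
    dataset = sd.simulate_dataset(config.sim_config())
    hg.write_mrc(sim_dir / "particles.mrcs", dataset.stack,
                 dataset.config.pixel_size)
    star_io.write_particle_star(dataset.table, sim_dir / "particles.star")
    _write_tsv(dataset.truth, sim_dir / "truth.tsv")

    state = process_dataset(dataset, config)

    counts = {"n_segments": len(dataset.table),
              "n_tubes": int(len(dataset.table.tube_ids))}
    for i, s in enumerate(STAGES):
        if s not in requested:
            continue
        d = out / f"{i + 1:02d}_{s}"
        d.mkdir(exist_ok=True)
        if s == "preprocess":
            star_io.write_particle_star(state["preprocess"], d / "particles.star")
        elif s == "segavg":
            hg.write_mrc(d / "averages.mrcs", state["segavg"],
                         dataset.config.pixel_size)
            star_io.write_particle_star(state["preprocess"], d / "particles.star")
        elif s == "pfsort":
            st = state["pfsort"]
            tbl = st["result"].apply_to(state["preprocess"])
            star_io.write_particle_star(tbl, d / "particles.star")
            _write_tsv(st["per_tube"], d / "per_tube.tsv")
            _write_tsv(st["confidence"], d / "confidence.tsv")
            counts["pf_confidence_mean"] = float(
                st["per_tube"]["confidence"].mean())
        elif s == "global":
            star_io.write_particle_star(state["global"], d / "particles.star")
        elif s == "xysmooth":
            star_io.write_particle_star(state["xysmooth"], d / "particles.star")
        elif s == "reavg":
            ravgs, table4, _ = state["reavg"]
            hg.write_mrc(d / "averages.mrcs", ravgs, dataset.config.pixel_size)
            star_io.write_particle_star(table4, d / "particles.star")
        elif s == "seam":
            st = state["seam"]
            star_io.write_particle_star(st["table"], d / "particles.star")
            _write_tsv(st["report"], d / "seam_report.tsv")
            _write_tsv(st["qc"], d / "qc_report.tsv")
            ts.plot_rot_series(st["table"], d / "rot_series.png",
                               rejected=st["rejected"])
            counts["seam_fraction_converged"] = st["fraction_converged"]
            counts["tubes_rejected"] = len(st["rejected"])

    manifest = {
        "seed": config.seed,
        "stages": requested,
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return state


def export_for_relion(table: star_io.ParticleTable, path,
                      dialect: str = "angstrom") -> None:
    """Write a table for downstream refinement; unknown columns survive."""
    star_io.write_particle_star(table, path, dialect=dialect)


def import_from_relion(path, dialect: str = "auto",
                       **kwargs) -> star_io.ParticleTable:
    """Read a refinement output table (either origin dialect)."""
    return star_io.read_particle_star(path, dialect=dialect, **kwargs)
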