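"""End-to-end pipeline: simulate -> contrast -> clusters -> means -> gap ->
subgroup contrasts -> symptoms, with file-based caching and a run manifest.

Each stage writes its outputs into the run directory and is skipped on
re-run when its outputs already exist and no upstream stage was re-executed;
deleting one stage's outputs regenerates that stage and everything
downstream.  All randomness derives from a single top-level seed, expanded
deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import TierConfig
from .clusters import analyze_clusters, cluster_table
from .contrast import contrast
from .gapping import gap_analysis
from .io import read_cohort, read_mask, read_volume, write_cohort, write_mask, write_volume
from .subgroups import SubgroupDesign, extract_cluster_means, subgroup_contrast, symptom_compare
from .synthetic import PlantedEffect, SimConfig, SymptomModel, generate_cohort

__all__ = ["run_pipeline", "render_report", "validate_config"]

STAGES = ["simulate", "contrast", "clusters", "extract_means", "gap",
          "subgroup_contrast", "symptoms"]

_REQUIRED_KEYS = {"seed", "simulate"}
_KNOWN_KEYS = _REQUIRED_KEYS | {"tier_config", "gap", "outdir"}


def validate_config(config: dict) -> dict:
    missing = sorted(_REQUIRED_KEYS - set(config))
    unknown = sorted(set(config) - _KNOWN_KEYS)
    problems = []
    if missing:
        problems.append(f"missing keys: {missing}")
    if unknown:
        problems.append(f"unknown keys: {unknown}")
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _sim_config(config: dict) -> SimConfig:
    sim = dict(config.get("simulate", {}))
    effects = [PlantedEffect(**{**e, "box": tuple(tuple(b) for b in e["box"])})
               for e in sim.pop("effects", [])]
    symptoms = SymptomModel(**sim.pop("symptoms", {}))
    shape = tuple(sim.pop("shape", (32, 32, 32)))
    sim.pop("seed", None)
    return SimConfig(shape=shape, effects=effects, symptoms=symptoms,
                     seed=_stage_seed(config["seed"], "simulate"), **sim)


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.tier_config = TierConfig.from_dict(config.get("tier_config", {}))
        self.patients = self.controls = self.aoes = self.cohort = None
        self.clusters = None
        self.followups = []
        self.means = None
        self.gap = None
        self.gap_labels = None
        self.manifest = {
            "version": __version__,
            "config": config,
            "stages": {},
            "outputs": {},
            "input_hashes": {},
        }

    def record(self, stage: str, outputs, elapsed: float, cached: bool):
        self.manifest["stages"][stage] = {
            "elapsed_s": round(elapsed, 4),
            "cached": cached,
            "seed": _stage_seed(self.config["seed"], stage),
        }
        self.manifest["outputs"][stage] = [str(p) for p in outputs]
        for p in outputs:
            p = Path(p)
            if p.is_file():
                self.manifest["input_hashes"][str(p)] = _sha256(p)


def _load_volumes(d: Path, prefix: str):
    return [read_volume(p, subject_id=p.name[len(prefix):-len(".nii.gz")])
            for p in sorted(d.glob(f"{prefix}*.nii.gz"))]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    upstream_reran = False

    for stage in STAGES:
        fn = _STAGE_FNS[stage]
        outputs = fn(run, plan_only=True)
        cached = all(Path(p).exists() for p in outputs) and not upstream_reran
        t0 = time.perf_counter()
        fn(run, cached=cached)
        run.record(stage, outputs, time.perf_counter() - t0, cached)
        upstream_reran = upstream_reran or not cached

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(run.manifest, indent=2))
    return run.manifest


# ---------------------------------------------------------------- stages

def _stage_simulate(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    vols = out / "volumes"
    masks = out / "masks"
    outputs = [out / "cohort.tsv", out / "truth.json", vols, masks]
    if plan_only:
        return outputs
    cfg = _sim_config(run.config)
    if cached:
        run.cohort = read_cohort(out / "cohort.tsv")
        run.patients = _load_volumes(vols, "pat_")
        run.controls = _load_volumes(vols, "ctl_")
        meta = json.loads((out / "truth.json").read_text())
        run.aoes = [read_mask(masks / m["file"], m["name"], m["tier"])
                    for m in meta["aoe_files"]]
        return
    sim = generate_cohort(cfg)
    vols.mkdir(exist_ok=True)
    masks.mkdir(exist_ok=True)
    for v in sim.patients:
        write_volume(v, vols / f"pat_{v.subject_id}.nii.gz")
    for v in sim.controls:
        write_volume(v, vols / f"ctl_{v.subject_id}.nii.gz")
    aoe_files = []
    for a in sim.aoes:
        fname = f"{a.name}.nii.gz"
        write_mask(a, masks / fname)
        aoe_files.append({"file": fname, "name": a.name, "tier": a.tier})
    write_cohort(sim.cohort, out / "cohort.tsv")
    truth = dict(sim.truth)
    truth["aoe_files"] = aoe_files
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    run.patients, run.controls = sim.patients, sim.controls
    run.aoes, run.cohort = sim.aoes, sim.cohort


def _stage_contrast(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    outputs = [out / "t_map.nii.gz", out / "p_map.nii.gz", out / "contrast.json"]
    if plan_only:
        return outputs
    sm = contrast(run.patients, run.controls, variance=run.tier_config.variance)
    run.statmap = sm
    if cached:
        return
    import nibabel as nib
    nib.save(nib.Nifti1Image(sm.t_field, sm.affine), str(out / "t_map.nii.gz"))
    nib.save(nib.Nifti1Image(sm.p_field, sm.affine), str(out / "p_map.nii.gz"))
    (out / "contrast.json").write_text(json.dumps({
        "df": sm.df, "group_sizes": list(sm.group_sizes),
        "variance": sm.variance, "n_search": sm.n_search,
    }, indent=2))


def _stage_clusters(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    outputs = [out / "clusters.tsv", out / "clusters.json"]
    if plan_only:
        return outputs
    run.clusters = analyze_clusters(run.statmap, run.aoes, run.tier_config)
    if cached:
        return
    table = cluster_table(run.clusters)
    table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    (out / "clusters.json").write_text(json.dumps({
        "n_clusters": len(run.clusters),
        "tier_config": run.tier_config.to_dict(),
    }, indent=2))


def _followup_clusters(run: _Run):
    """Primary-tier clusters meeting their extent requirement, best first.

    Heterogeneity screening deliberately includes clusters that met the
    extent but not the Bonferroni threshold.
    """
    primaries = [c for c in run.clusters
                 if c.tier == "primary" and c.size >= (c.k or 0)]
    return sorted(primaries, key=lambda c: c.peak_p)


def _stage_extract_means(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    outputs = [out / "cluster_means.tsv"]
    if plan_only:
        return outputs
    run.followups = _followup_clusters(run)
    frames = []
    for rank, c in enumerate(run.followups):
        cid = f"{c.aoe_name}#{rank}"
        pm = extract_cluster_means(c, run.patients)
        cm = extract_cluster_means(c, run.controls)
        frames.append(pd.DataFrame({
            "cluster_id": cid,
            "subject_id": list(pm.index) + list(cm.index),
            "group": ["patient"] * len(pm) + ["control"] * len(cm),
            "cluster_mean_fa": list(pm.values) + list(cm.values)}))
    run.means = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["cluster_id", "subject_id",
                                            "group", "cluster_mean_fa"]))
    if not cached:
        run.means.to_csv(out / "cluster_means.tsv", sep="\t", index=False)


def _stage_gap(run: _Run, plan_only=False, cached=False):
    """Gapping analysis per follow-up cluster; the cluster with the largest
    maximal gap ratio defines the subgroup split."""
    out = run.outdir
    outputs = [out / "gap.json", out / "subgroup_labels.tsv"]
    if plan_only:
        return outputs
    run.gap = None
    run.gap_labels = None
    if run.means.empty:
        if not cached:
            (out / "gap.json").write_text(json.dumps(
                {"status": "no primary cluster met threshold"}, indent=2))
            pd.DataFrame(columns=["subject_id", "label"]).to_csv(
                out / "subgroup_labels.tsv", sep="\t", index=False)
        return
    gcfg = run.config.get("gap", {})
    seed0 = _stage_seed(run.config["seed"], "gap")
    results = {}
    best_id = None
    for i, (cid, sub) in enumerate(run.means.groupby("cluster_id", sort=True)):
        pat = sub[sub.group == "patient"]
        res = gap_analysis(pat.cluster_mean_fa.to_numpy(),
                           n_sims=int(gcfg.get("n_sims", 10_000)),
                           df_t=int(gcfg.get("df_t", 4)),
                           seed=(seed0 + 2 * i) % (2 ** 31))
        results[cid] = (res, pat)
        if best_id is None or res.max_ratio > results[best_id][0].max_ratio:
            best_id = cid
    run.gap, pat = results[best_id]
    labels = pd.DataFrame({"subject_id": pat.subject_id.to_numpy(),
                           "label": run.gap.labels_in_input_order()})
    run.gap_labels = labels
    if not cached:
        payload = {cid: res.to_dict() for cid, (res, _) in results.items()}
        payload["subgrouping_cluster"] = best_id
        (out / "gap.json").write_text(json.dumps(payload, indent=2))
        labels.to_csv(out / "subgroup_labels.tsv", sep="\t", index=False)


def _stage_subgroup_contrast(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    outputs = [out / "clusters_above_gap.tsv", out / "clusters_below_gap.tsv"]
    if plan_only:
        return outputs
    if run.gap is None:
        run.design = None
        if not cached:
            for p in outputs:
                pd.DataFrame().to_csv(p, sep="\t", index=False)
        return
    label_map = dict(zip(run.gap_labels.subject_id, run.gap_labels.label))
    run.design = SubgroupDesign.from_cohort(run.cohort, label_map)
    for sub, path in [("above_gap", outputs[0]), ("below_gap", outputs[1])]:
        if len(run.design.members(sub)) >= 2:
            _, table, _ = subgroup_contrast(
                run.design, sub, run.patients, run.controls, run.aoes,
                run.tier_config)
        else:
            table = pd.DataFrame()
        if not cached:
            table.to_csv(path, sep="\t", index=False)


def _stage_symptoms(run: _Run, plan_only=False, cached=False):
    out = run.outdir
    outputs = [out / "symptoms.tsv"]
    if plan_only:
        return outputs
    if run.gap is None:
        if not cached:
            pd.DataFrame().to_csv(outputs[0], sep="\t", index=False)
        return
    label_map = dict(zip(run.gap_labels.subject_id, run.gap_labels.label))
    table = symptom_compare(run.cohort, label_map)
    run.symptoms = table
    if not cached:
        table.to_csv(outputs[0], sep="\t", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "contrast": _stage_contrast,
    "clusters": _stage_clusters,
    "extract_means": _stage_extract_means,
    "gap": _stage_gap,
    "subgroup_contrast": _stage_subgroup_contrast,
    "symptoms": _stage_symptoms,
}


# ---------------------------------------------------------------- report

def _fmt_cluster_section(path: Path, title: str) -> list[str]:
    lines = [f"## {title}", ""]
    if not path.exists():
        lines += ["(stage output missing)", ""]
        return lines
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        lines += ["no clusters met threshold", ""]
    else:
        lines += [df.to_string(index=False), ""]
    return lines


def render_report(outdir) -> str:
    """Human-readable summary of all stage outputs present in ``outdir``.

    Idempotent: regenerating the report from unchanged outputs yields
    byte-identical text.  Also written to ``report.md``.
    """
    outdir = Path(outdir)
    lines = ["# Pipeline report", ""]
    lines += _fmt_cluster_section(outdir / "clusters.tsv", "Whole-cohort clusters")
    gap_path = outdir / "gap.json"
    lines += ["## Gapping analysis", ""]
    if gap_path.exists():
        payload = json.loads(gap_path.read_text())
        if "status" in payload:
            lines += [payload["status"], ""]
        else:
            best = payload.pop("subgrouping_cluster", None)
            for cid, gap in payload.items():
                tag = " (defines subgroups)" if cid == best else ""
                lines += [
                    f"### {cid}{tag}",
                    f"maximal middle-gap ratio: {gap['max_ratio']:.4f}",
                    f"boundary between {gap['boundary_values'][0]:.6f} "
                    f"and {gap['boundary_values'][1]:.6f}",
                    f"subgroup split: {gap['n_below']} below gap, "
                    f"{gap['n_above']} above gap",
                    f"p (Gaussian null): {gap['p_gaussian']}",
                    f"p (t null, df={gap['df_t']}): {gap['p_t']}",
                    "",
                ]
    else:
        lines += ["(stage output missing)", ""]
    lines += _fmt_cluster_section(outdir / "clusters_above_gap.tsv",
                                  "Above-gap subgroup contrast")
    lines += _fmt_cluster_section(outdir / "clusters_below_gap.tsv",
                                  "Below-gap subgroup contrast")
    lines += ["## Symptom comparison", ""]
    sym_path = outdir / "symptoms.tsv"
    if sym_path.exists():
        try:
            sym = pd.read_csv(sym_path, sep="\t")
        except pd.errors.EmptyDataError:
            sym = pd.DataFrame()
        lines += [sym.to_string(index=False) if not sym.empty
                  else "no symptom comparison (no subgroups)", ""]
    else:
        lines += ["(stage output missing)", ""]
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
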