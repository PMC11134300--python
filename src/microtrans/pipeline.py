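"""End-to-end orchestration: simulate → social/kinship → similarity → models.

Stages form a small make-like dependency graph over CSV/TSV intermediates:
a stage re-runs when an output is missing or an input is newer than its
outputs, so deleting one intermediate regenerates only that stage and its
downstream dependents.  Every run appends a manifest recording inputs,
output hashes and seeds; with a fixed seed, re-runs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asv_association as asv
from . import community_matrix as cm
from . import dyadic_lmm as dl
from . import pedigree_kinship as pk
from . import rfid_social as rs
from . import trajectories as tj
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger("microtrans")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig | None = None
    # pre-existing inputs (ignored when sim is set; simulate writes them)
    events_csv: str | None = None
    pedigree_csv: str | None = None
    counts_tsv: str | None = None
    meta_csv: str | None = None
    metrics: tuple[str, ...] = ("bray_curtis", "jaccard")
    sections: tuple[str, ...] = ("ileum", "cecum", "colon")
    min_prevalence: int = 20
    unrelated_threshold: float = 0.25
    fdr_alpha: float = 0.05
    alpha: float = 0.05
    logit_eps: float = 1e-3
    n_perm: int = 999
    trajectory_metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1 or not 0 < self.alpha < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.min_prevalence < 1:
            raise ValueError("min_prevalence must be positive")
        if not 0 <= self.unrelated_threshold <= 2:
            raise ValueError("unrelated_threshold out of range")
        if self.sim is None:
            for name in ("events_csv", "pedigree_csv", "counts_tsv", "meta_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"input {name} missing or not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("sim") is not None:
            sim_raw = dict(raw["sim"])
            if "age_profile" in sim_raw:
                from .simdata import AgeProfile

                sim_raw["age_profile"] = AgeProfile(**sim_raw["age_profile"])
            for key in ("depth_range", "subspecies", "sections"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            raw["sim"] = SimConfig(**sim_raw)
        for key in ("metrics", "sections"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _needs_run(inputs: list[Path], outputs: list[Path]) -> bool:
    if any(not o.exists() for o in outputs):
        return True
    if not inputs:
        return False
    newest_in = max(p.stat().st_mtime_ns for p in inputs if p.exists())
    oldest_out = min(o.stat().st_mtime_ns for o in outputs)
    return newest_in > oldest_out


def validate_inputs(paths: dict[str, str]) -> dict:
    """Schema and referential-integrity checks on the raw input files.

    Returns a report listing problems (missing columns, orphan samples with
    no metadata, individuals absent from the pedigree, metadata rows whose
    sample has no counts) without mutating anything.
    """
    problems: list[str] = []
    report: dict = {"problems": problems, "orphans": {}}
    try:
        events = pd.read_csv(paths["events"])
        for c in ("timestamp_s", "mouse_id", "nestbox_id", "reader"):
            if c not in events.columns:
                problems.append(f"events: missing column {c}")
        if "reader" in events.columns:
            bad = set(events["reader"].astype(str)) - {"outer", "inner"}
            if bad:
                problems.append(f"events: unknown reader values {sorted(bad)}")
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read events file: {exc}") from exc
    ped = pd.read_csv(paths["pedigree"], dtype=str)
    for c in ("id", "dam", "sire"):
        if c not in ped.columns:
            problems.append(f"pedigree: missing column {c}")
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    meta = pd.read_csv(paths["meta"])
    for c in cm.SampleMeta.REQUIRED:
        if c not in meta.columns:
            problems.append(f"meta: missing column {c}")
    ped_ids = set(ped.get("id", pd.Series(dtype=str)).astype(str))
    meta_samples = set(meta.get("sample_id", pd.Series(dtype=str)).astype(str))
    count_samples = set(counts.index.astype(str))
    ev_mice = set(events.get("mouse_id", pd.Series(dtype=str)).astype(str))
    report["orphans"] = {
        "samples_without_metadata": sorted(count_samples - meta_samples),
        "metadata_without_counts": sorted(meta_samples - count_samples),
        "individuals_not_in_pedigree": sorted(
            set(meta.get("individual", pd.Series(dtype=str)).astype(str)) - ped_ids
        ),
        "event_mice_not_in_pedigree": sorted(ev_mice - ped_ids),
    }
    return report


def _stage(manifest: dict, name: str, inputs: list[Path], outputs: list[Path], fn) -> None:
    t0 = time.perf_counter()
    if _needs_run(inputs, outputs):
        logger.info("stage %s: running", name)
        fn()
        ran = True
    else:
        logger.info("stage %s: up to date", name)
        ran = False
    manifest["stages"].append({
        "name": name,
        "ran": ran,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        "seconds": round(time.perf_counter() - t0, 3),
    })
    missing = [str(o) for o in outputs if not o.exists()]
    if missing:
        raise RuntimeError(f"stage {name} did not produce outputs: {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [],
                      "config": _config_dict(config)}

    if config.sim is not None:
        events_csv = out / "events.csv"
        pedigree_csv = out / "pedigree.csv"
        counts_tsv = out / "counts.tsv"
        meta_csv = out / "meta.csv"

        def do_sim():
            sim = dataclasses.replace(config.sim, seed=config.seed)
            simulate_dataset(sim).write(out)

        _stage(manifest, "simulate", [],
               [events_csv, pedigree_csv, counts_tsv, meta_csv, out / "truth.json"],
               do_sim)
    else:
        events_csv = Path(config.events_csv)
        pedigree_csv = Path(config.pedigree_csv)
        counts_tsv = Path(config.counts_tsv)
        meta_csv = Path(config.meta_csv)

    report = validate_inputs({
        "events": str(events_csv), "pedigree": str(pedigree_csv),
        "counts": str(counts_tsv), "meta": str(meta_csv),
    })
    if report["problems"]:
        raise RuntimeError(f"input validation failed: {report['problems']}")
    (out / "validation_report.json").write_text(json.dumps(report, indent=2) + "\n")

    contacts_csv = out / "contacts.csv"

    def do_social():
        events = rs.read_events_csv(events_csv)
        visits, parse_report = rs.parse_visits(events)
        ped = pk.PedigreeTable.from_csv(pedigree_csv)
        rs.contact_matrix(visits, ped.ids).to_csv(contacts_csv)
        parse_report.to_json(out / "parse_report.json")

    _stage(manifest, "social", [events_csv, pedigree_csv],
           [contacts_csv, out / "parse_report.json"], do_social)

    relatedness_csv = out / "relatedness.csv"
    classes_csv = out / "dyad_classes.csv"

    def do_kinship():
        ped = pk.PedigreeTable.from_csv(pedigree_csv)
        A = pk.additive_relationship(ped)
        A.to_csv(relatedness_csv)
        pk.classify_dyads(A, ped, config.unrelated_threshold).to_csv(
            classes_csv, index=False)

    _stage(manifest, "kinship", [pedigree_csv], [relatedness_csv, classes_csv],
           do_kinship)

    sim_outputs = [out / f"similarity_{m}_{s}.csv"
                   for m in config.metrics for s in _present_sections(meta_csv, config)]
    rarefied_tsv = out / "counts_rarefied.tsv"

    def do_similarity():
        counts = cm.CountTable.from_tsv(counts_tsv)
        counts = cm.merge_duplicates(counts)
        depth = int(counts.depths().min())
        rare = cm.rarefy(counts, depth, seed=config.seed)
        rare.to_tsv(rarefied_tsv)
        meta = cm.SampleMeta.from_csv(meta_csv)
        long_rows = []
        for sec in _present_sections(meta_csv, config):
            samp = [s for s in rare.sample_ids
                    if meta.table.at[s, "gut_section"] == sec]
            sub = cm.CountTable(rare.counts.loc[samp])
            for metric in config.metrics:
                S = cm.dissimilarity(sub, metric)
                S.to_csv(out / f"similarity_{metric}_{sec}.csv")
                iu = np.triu_indices(len(samp), k=1)
                long_rows.append(pd.DataFrame({
                    "sample_i": np.array(samp)[iu[0]],
                    "sample_j": np.array(samp)[iu[1]],
                    "gut_section": sec, "metric": metric,
                    "S": S.values[iu],
                }))
        pd.concat(long_rows).to_csv(out / "dyads_long.csv", index=False,
                                    float_format="%.10f")

    _stage(manifest, "similarity", [counts_tsv, meta_csv],
           sim_outputs + [rarefied_tsv, out / "dyads_long.csv"], do_similarity)

    dyadic_out = [out / "dyadic_fits.csv", out / "variance_fractions.csv"]

    def do_dyadic():
        meta = cm.SampleMeta.from_csv(meta_csv)
        A = pk.RelatednessMatrix.from_csv(relatedness_csv)
        Cmat = rs.ContactMatrix.from_csv(contacts_csv)
        classes = pd.read_csv(classes_csv)
        fit_rows, frac_rows = [], []
        for sec in _present_sections(meta_csv, config):
            for metric in config.metrics:
                S = _load_similarity(out, metric, sec)
                Sl = cm.logit_similarity(S, eps=config.logit_eps)
                dyads = dl.build_dyads(Sl, meta, A, Cmat, dyad_classes=classes,
                                       section=sec)
                for subsp, sub in dyads.groupby("subspecies_pair"):
                    sub = sub.reset_index(drop=True)
                    try:
                        step = dl.lrt_and_stepwise(
                            sub, ("relatedness", "contact"), alpha=config.alpha)
                        fit = dl.fit_mm_lmm(sub, ("relatedness", "contact"))
                        fracs = dl.variance_partition(fit, sub)
                    except ValueError as exc:
                        raise RuntimeError(
                            f"dyadic stage failed for {sec}/{metric}/{subsp}: {exc}"
                        ) from exc
                    for row in step.lrt_table.itertuples(index=False):
                        fit_rows.append((sec, metric, subsp, row.term, row.lrt_chi2,
                                         row.df, row.p_value, row.retained))
                    for term, frac in fracs.items():
                        frac_rows.append((sec, metric, subsp, term, frac))
        pd.DataFrame(fit_rows, columns=[
            "section", "metric", "subspecies", "term", "lrt_chi2", "df",
            "p_value", "retained"]).to_csv(dyadic_out[0], index=False,
                                           float_format="%.8f")
        pd.DataFrame(frac_rows, columns=[
            "section", "metric", "subspecies", "term", "fraction"]).to_csv(
            dyadic_out[1], index=False, float_format="%.8f")

    _stage(manifest, "dyadic",
           [out / "dyads_long.csv", relatedness_csv, contacts_csv, classes_csv,
            meta_csv] + sim_outputs,
           dyadic_out, do_dyadic)

    asv_out = [out / "asv_results.csv", out / "congruence_report.json"]

    def do_asv():
        rare = cm.CountTable.from_tsv(rarefied_tsv)
        meta = cm.SampleMeta.from_csv(meta_csv)
        A = pk.RelatednessMatrix.from_csv(relatedness_csv)
        Cmat = rs.ContactMatrix.from_csv(contacts_csv)
        clr = asv.clr_transform(rare)
        preds = {"relatedness": A, "contact": Cmat}
        results = []
        subspecies = sorted(meta.table["subspecies"].unique())
        for sec in _present_sections(meta_csv, config):
            for subsp in subspecies:
                res = asv.asv_screen(rare, clr, preds, meta, sec, subsp,
                                     min_prevalence=config.min_prevalence,
                                     n_perm=config.n_perm, seed=config.seed,
                                     fdr_alpha=config.fdr_alpha)
                results.append(res)
        allres = pd.concat(results, ignore_index=True)
        allres.to_csv(asv_out[0], index=False, float_format="%.8f")
        congruence = {}
        if len(subspecies) == 2:
            a, b = subspecies
            for sec in _present_sections(meta_csv, config):
                for pred in preds:
                    ra = allres.query(
                        "section == @sec and subspecies == @a and predictor == @pred")
                    rb = allres.query(
                        "section == @sec and subspecies == @b and predictor == @pred")
                    try:
                        congruence[f"{sec}:{pred}"] = asv.subspecies_congruence(ra, rb)
                    except ValueError as exc:
                        congruence[f"{sec}:{pred}"] = {"error": str(exc)}
        Path(asv_out[1]).write_text(json.dumps(congruence, indent=2) + "\n")

    _stage(manifest, "asv",
           [rarefied_tsv, relatedness_csv, contacts_csv, meta_csv], asv_out, do_asv)

    traj_out = [out / "trajectory_fit.csv", out / "baseline.csv",
                out / "aic_table.csv", out / "crossing_report.json"]

    def do_trajectory():
        meta = cm.SampleMeta.from_csv(meta_csv)
        ped = pk.PedigreeTable.from_csv(pedigree_csv)
        A = pk.RelatednessMatrix.from_csv(relatedness_csv)
        Cmat = rs.ContactMatrix.from_csv(contacts_csv)
        classes = pd.read_csv(classes_csv)
        metric = config.trajectory_metric
        pred_rows, base_rows, aic_rows, crossing = [], [], [], {}
        for sec in _present_sections(meta_csv, config):
            S = _load_similarity(out, metric, sec)
            Sl = cm.logit_similarity(S, eps=config.logit_eps)
            series = tj.build_kin_series(Sl, meta, ped, section=sec)
            dyads = dl.build_dyads(Sl, meta, A, Cmat, dyad_classes=classes,
                                   section=sec, within_subspecies_only=False)
            base = tj.baseline_estimate(dyads, config.unrelated_threshold)
            base_rows.append((sec, base.mean_logit_similarity, base.ci_lower,
                              base.ci_upper, base.n_dyads))
            for ptype in ("mother_offspring", "father_offspring", "same_litter_sib"):
                sub = series[series["pair_type"] == ptype].reset_index(drop=True)
                if len(sub) < 12:
                    continue
                fit = tj.fit_trajectory(sub, include_sex=(ptype != "same_litter_sib"))
                cross = tj.trajectory_vs_baseline(fit, base)
                crossing[f"{sec}:{ptype}"] = cross
                for row in fit.aic_table.itertuples(index=False):
                    aic_rows.append((sec, ptype, row.candidate, row.aic,
                                     row.candidate == fit.chosen))
                p = fit.predictions.assign(section=sec, pair_type=ptype)
                pred_rows.append(p)
        (pd.concat(pred_rows) if pred_rows else pd.DataFrame(
            columns=["age_days", "fit", "lo", "hi", "section", "pair_type"])
         ).to_csv(traj_out[0], index=False, float_format="%.8f")
        pd.DataFrame(base_rows, columns=[
            "section", "baseline", "lo", "hi", "n_dyads"]).to_csv(
            traj_out[1], index=False, float_format="%.8f")
        pd.DataFrame(aic_rows, columns=[
            "section", "pair_type", "candidate", "aic", "chosen"]).to_csv(
            traj_out[2], index=False, float_format="%.8f")
        Path(traj_out[3]).write_text(json.dumps(crossing, indent=2) + "\n")

    _stage(manifest, "trajectory",
           [pedigree_csv, meta_csv, relatedness_csv, contacts_csv, classes_csv]
           + sim_outputs,
           traj_out, do_trajectory)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("sim") is not None and not isinstance(d["sim"], dict):
        d["sim"] = dataclasses.asdict(d["sim"])
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
        if isinstance(v, dict):
            for k2, v2 in list(v.items()):
                if isinstance(v2, tuple):
                    v[k2] = list(v2)
    return d


def _present_sections(meta_csv: Path, config: RunConfig) -> list[str]:
    present = set(pd.read_csv(meta_csv)["gut_section"].astype(str))
    return [s for s in config.sections if s in present]


def _load_similarity(out: Path, metric: str, section: str) -> cm.SimilarityMatrix:
    df = pd.read_csv(out / f"similarity_{metric}_{section}.csv", index_col=0)
    return cm.SimilarityMatrix(list(df.index.astype(str)),
                               df.to_numpy(dtype=float), metric=metric)
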