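"""End-to-end analysis pipeline: SOR tracks, group scans, ROC, clustering,
survival, written as TSV artifacts with a JSON manifest."""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cna_io, sor
from .cluster import cluster_crosstab, exclude_sex_chromosomes, weighted_kmeans
from .genome import GenomeBuild, load_genome, load_hg18
from .stats import differential_scan, roc_auc
from .survival import km_fit, logrank_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    calls_path: str
    clinical_path: str
    out_dir: str
    chrom_sizes_path: Optional[str] = None  # bundled hg18 when None
    cytoband_path: Optional[str] = None
    blacklist_path: Optional[str] = None
    directions: tuple[str, ...] = ("gain", "loss")
    k: int = 3
    seed: int = 1
    restarts: int = 100
    alternative: str = "two-sided"
    bootstrap_reps: int = 2000
    factors: tuple[str, ...] = ("grade", "stage", "recurrence")
    plots: bool = False


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _binary_groupings(case_set: cna_io.CaseSet, factors) -> dict[str, pd.Series]:
    """Two-level groupings per factor; the three-level stage factor is
    reduced to its A-vs-C contrast (the stages compared in the study)."""
    out = {}
    clin = case_set.clinical_frame()
    for factor in factors:
        levels = sorted(clin[factor].unique())
        if len(levels) == 2:
            out[factor] = clin[factor]
        elif factor == "stage":
            mask = clin["stage"].isin(["A", "C"])
            if mask.sum() > 0 and clin.loc[mask, "stage"].nunique() == 2:
                out["stage_A_vs_C"] = clin.loc[mask, "stage"]
    return out


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage and return a mapping artifact name -> path.

    Deterministic given the seeds in ``config``; rerunning with unchanged
    inputs reproduces byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame, fname: str) -> None:
        path = out / fname
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        artifacts[name] = str(path)

    with _stage("load"):
        if config.chrom_sizes_path and config.cytoband_path:
            build = load_genome(config.chrom_sizes_path, config.cytoband_path)
        else:
            build = load_hg18()
        calls = cna_io.read_cna_table(config.calls_path, build=build)
        if config.blacklist_path:
            calls = cna_io.subtract_blacklist(
                calls, cna_io.read_blacklist(config.blacklist_path)
            )
        clinical = cna_io.read_clinical_table(config.clinical_path)
        case_set = cna_io.CaseSet(calls=calls, clinical=clinical)

    with _stage("sor"):
        profiles = {d: sor.build_sors(case_set, d) for d in config.directions}
        for d, profile in profiles.items():
            save(f"sor_{d}", profile.to_frame(), f"sor_{d}.tsv")

    with _stage("pga"):
        pga = sor.pga_per_case(case_set, build)
        save("pga", pga.rename("pga_percent").reset_index(), "pga.tsv")
        roc_rows = []
        clin = case_set.clinical_frame()
        targets = {
            "grade_III": clin["grade"] == "III",
            "recurrence": clin["recurrence"] == "yes",
            "stage_A_vs_BC": clin["stage"] != "A",
            "stage_AB_vs_C": clin["stage"] == "C",
        }
        for name, labels in targets.items():
            if labels.nunique() < 2:
                continue
            res = roc_auc(pga.to_numpy(), labels.to_numpy(),
                          bootstrap_reps=config.bootstrap_reps, seed=config.seed)
            roc_rows.append(
                {"classification": name, "auc": res.auc, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "n_pos": res.n_pos, "n_neg": res.n_neg}
            )
        save("roc", pd.DataFrame(roc_rows), "roc.tsv")

    with _stage("scan"):
        groupings = _binary_groupings(case_set, config.factors)
        for gname, grouping in groupings.items():
            tables = []
            subset = case_set.subset(list(grouping.index))
            for d in config.directions:
                profile = sor.build_sors(subset, d)
                tables.append(
                    differential_scan(subset, profile, grouping,
                                      alternative=config.alternative, adjust=True)
                )
            save(f"scan_{gname}", pd.concat(tables, ignore_index=True),
                 f"scan_{gname}.tsv")

    with _stage("cluster"):
        combined = sor.build_sor_profile(case_set)
        segments = exclude_sex_chromosomes(combined.segments)
        matrix = sor.profile_matrix(case_set, segments)
        weights = [s.length for s in segments]
        model = weighted_kmeans(matrix, weights, k=config.k, seed=config.seed,
                                restarts=config.restarts)
        save("clusters", model.assignments.rename("cluster").reset_index(),
             "clusters.tsv")
        save("centroids", model.centroid_frame().reset_index(), "centroids.tsv")
        for factor in config.factors:
            ct = cluster_crosstab(model, case_set.grouping(factor))
            save(f"crosstab_{factor}", ct.table.reset_index(),
                 f"crosstab_{factor}.tsv")

    with _stage("survival"):
        clin = case_set.clinical_frame()
        times = clin["time"].to_numpy(dtype=float)
        events = clin["event"].to_numpy()
        logrank_rows = []
        groupers = {f: clin[f] for f in config.factors}
        groupers["cluster"] = model.assignments
        km_tables = []
        for name, grouping in groupers.items():
            if grouping.nunique() < 2:
                continue
            res = logrank_test(times, events, grouping.to_numpy())
            logrank_rows.append(
                {"grouping": name, "chi_square": res.chi_square, "df": res.df,
                 "p_value": res.p_value}
            )
            for level in sorted(grouping.unique()):
                mask = (grouping == level).to_numpy()
                if events[mask].size == 0:
                    continue
                curve = km_fit(times[mask], events[mask]).to_frame()
                curve.insert(0, "group", f"{name}={level}")
                km_tables.append(curve)
        save("logrank", pd.DataFrame(logrank_rows), "logrank.tsv")
        save("km_curves", pd.concat(km_tables, ignore_index=True), "km_curves.tsv")

    if config.plots:
        with _stage("plots"):
            from . import plot

            fig = plot.frequency_track(profiles, build)
            fig_path = out / "frequency_track.png"
            fig.savefig(fig_path, dpi=150)
            artifacts["frequency_track"] = str(fig_path)

    with _stage("manifest"):
        try:
            version = metadata.version("sorcna")
        except metadata.PackageNotFoundError:  # pragma: no cover
            version = "unknown"
        manifest = {
            "package": "sorcna",
            "version": version,
            "parameters": {
                "calls": config.calls_path,
                "clinical": config.clinical_path,
                "blacklist": config.blacklist_path,
                "genome": build.build_name,
                "directions": list(config.directions),
                "k": config.k,
                "seed": config.seed,
                "restarts": config.restarts,
                "alternative": config.alternative,
                "bootstrap_reps": config.bootstrap_reps,
                "factors": list(config.factors),
            },
            "n_cases": case_set.n_cases,
            "n_calls": len(case_set.calls),
            "artifacts": sorted(artifacts),
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = str(path)
    return artifacts
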