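"""End-to-end cryptic-relatedness check.

:func:`run_ibdcheck` wires the stages together: load -> QC -> conditional
IBS tables -> study-pair IBD estimation -> (optionally) LD-model fitting or
reuse -> gene-drop simulation of reference relationships -> prediction
ellipses -> automatic flagging -> report files.  By default no simulation is
performed and the result carries study-pair estimates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import genedrop, ld_model, qc, reference_clusters
from .genotype_data import (
    GenotypeTable,
    attach_subjects,
    infer_genetic_map,
    read_plink,
    read_subjects_tsv,
    read_vcf,
)
from .ibd_mme import CondIBSTable, cond_ibs_table, estimate_all_pairs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; every field has a scriptable default.

    With ``simulate`` false (the default) only study-pair IBD estimates are
    produced: no LD fitting, no reference clusters, no flags.
    """

    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    vcf_path: Optional[str] = None
    subjects_path: Optional[str] = None
    reference_col: str = "is_reference"
    simulate: bool = False
    relationships: tuple[str, ...] = genedrop.DEFAULT_RELATIONSHIPS
    n_pairs: int = 200
    coverage: float = 0.95
    fit_ld: bool = True
    ld_files: Optional[str] = None  # directory of previously fitted models
    filter: bool = True
    thresholds: qc.FilterThresholds = field(default_factory=qc.FilterThresholds)
    user_pedigree: Optional[str] = None
    cm_per_mb: float = 1.0
    seed: int = 0
    outdir: str = "ibdcheck_out"


@dataclass
class RunResult:
    """Outputs of one run; every flagged pair is re-verifiable from the
    stored estimates and ellipses."""

    study: pd.DataFrame
    sim: dict[str, pd.DataFrame]
    ellipses: dict[str, reference_clusters.PredictionEllipse]
    flagged: pd.DataFrame
    ld_files: list[str]
    qc_report: pd.DataFrame
    config: RunConfig
    data: GenotypeTable = field(repr=False, default=None)
    tables: CondIBSTable = field(repr=False, default=None)


def _load(config: RunConfig) -> GenotypeTable:
    if config.vcf_path:
        data = read_vcf(config.vcf_path)
    elif config.ped_path and config.map_path:
        data = read_plink(config.ped_path, config.map_path)
    else:
        raise ValueError("provide either --vcf or --ped/--map inputs")
    if config.subjects_path:
        subjects = read_subjects_tsv(config.subjects_path, config.reference_col)
        data = attach_subjects(data, subjects)
    return data


def check_table(data: GenotypeTable, config: RunConfig) -> RunResult:
    """Run the pipeline on an in-memory genotype table."""
    rng = np.random.default_rng(config.seed)

    data, qc_report = qc.apply_qc(data, config.thresholds, enabled=config.filter)
    logger.info(
        "after QC: %d subjects, %d SNPs (%d items removed)",
        data.n_subjects, data.n_snps, len(qc_report),
    )
    data = replace_snps(data, infer_genetic_map(data.snps, rate=config.cm_per_mb))

    tables = cond_ibs_table(data)
    study = estimate_all_pairs(data, tables)
    logger.info("estimated %d study pairs", len(study))

    sim: dict[str, pd.DataFrame] = {}
    ellipses: dict[str, reference_clusters.PredictionEllipse] = {}
    flagged = pd.DataFrame(
        columns=["subject1", "subject2", "relationship", "mode", "k0", "k1"]
    )
    ld_files: list[str] = []

    if config.simulate:
        if config.ld_files:
            paths = sorted(Path(config.ld_files).glob("ld_model_chr*.txt"))
            if not paths:
                raise ValueError(f"no LD model files found under {config.ld_files}")
            models = ld_model.load_models(paths)
            missing = set(data.chromosomes) - set(models)
            if missing:
                raise ValueError(f"LD files lack chromosomes {sorted(missing)}")
            ld_files = [str(p) for p in paths]
            logger.info("reusing %d fitted LD model files; fitting skipped", len(ld_files))
        else:
            models = ld_model.fit_models(data, fit_ld=config.fit_ld)
            ld_files = ld_model.save_models(models, Path(config.outdir) / "ld_models")
            logger.info("fitted and saved %d LD model files", len(ld_files))

        relationships = list(config.relationships)
        if "unrelated" not in relationships:
            relationships.insert(0, "unrelated")
        for rel in relationships:
            ped = (
                genedrop.read_pedigree(config.user_pedigree)
                if rel == "user"
                else genedrop.builtin_pedigree(rel)
            )
            sim[rel] = genedrop.simulate_reference_pairs(
                ped, config.n_pairs, models, data, tables, rng
            )
            n_bad = int((sim[rel]["status"] != "ok").sum())
            if n_bad:
                logger.info("%s: %d inestimable simulated pairs excluded", rel, n_bad)
        ellipses = reference_clusters.fit_relationship_ellipses(
            sim, config.coverage, n_study_pairs=len(study)
        )
        flagged = reference_clusters.flag_pairs(study, ellipses)

    return RunResult(
        study=study,
        sim=sim,
        ellipses=ellipses,
        flagged=flagged,
        ld_files=ld_files,
        qc_report=qc_report,
        config=config,
        data=data,
        tables=tables,
    )


def replace_snps(data: GenotypeTable, snps) -> GenotypeTable:
    return GenotypeTable(data.genotypes, list(snps), data.subjects)


def run_ibdcheck(config: RunConfig) -> RunResult:
    """Load inputs per the config and run the full check."""
    data = _load(config)
    return check_table(data, config)


# -- report --------------------------------------------------------------------


def _window(e: reference_clusters.PredictionEllipse, pad: float = 1.6):
    b = e.boundary()
    lo = b.min(axis=0)
    hi = b.max(axis=0)
    c = (lo + hi) / 2
    half = np.maximum((hi - lo) / 2 * pad, 0.02)
    return c - half, c + half


def render_report(result: RunResult, outdir) -> list[str]:
    """Write TSVs and static plots; returns the file paths.

    Always: study estimate TSV, QC report and the overview scatter of
    (k0, k1) for all study pairs (with the Bonferroni-adjusted unrelated
    ellipse when simulation ran).  With simulation: a per-relationship plot
    windowed to its ellipse (unrelated ellipse overlaid when the windows
    overlap, flagged pairs highlighted), simulated estimates, ellipse
    parameters and the flagged-pair TSV.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def save_tsv(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        files.append(str(path))

    save_tsv(result.study, "study_estimates.tsv")
    save_tsv(result.qc_report, "qc_report.tsv")

    ok = result.study[result.study["status"] == "ok"]

    def overview():
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(ok["k0"], ok["k1"], s=8, alpha=0.6, label="study pairs")
        if "unrelated" in result.ellipses:
            e = result.ellipses["unrelated"]
            b = e.boundary()
            ax.plot(b[:, 0], b[:, 1], color="magenta",
                    label=f"unrelated ({e.coverage:.4f})")
        ax.set_xlabel("P(Z=0)")
        ax.set_ylabel("P(Z=1)")
        ax.set_title("Estimated IBD coefficients, all study pairs")
        ax.legend(loc="best", fontsize=8)
        path = outdir / "ibd_all_pairs.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        files.append(str(path))

    overview()

    if result.sim:
        sim_all = pd.concat(result.sim.values(), ignore_index=True)
        save_tsv(sim_all, "sim_estimates.tsv")
        save_tsv(result.flagged, "flagged_pairs.tsv")
        save_tsv(_ellipse_frame(result.ellipses), "ellipses.tsv")
        unrel = result.ellipses.get("unrelated")
        for rel, e in result.ellipses.items():
            if rel == "unrelated":
                continue
            lo, hi = _window(e)
            fig, ax = plt.subplots(figsize=(6, 6))
            ax.scatter(ok["k0"], ok["k1"], s=10, alpha=0.7, label="study pairs")
            b = e.boundary()
            ax.plot(b[:, 0], b[:, 1], color="C1", label=f"{rel} ({e.coverage:.2f})")
            if unrel is not None:
                bu = unrel.boundary()
                overlaps = (bu.min(axis=0) <= hi).all() and (bu.max(axis=0) >= lo).all()
                if overlaps:
                    ax.plot(bu[:, 0], bu[:, 1], color="magenta", label="unrelated")
            fl = result.flagged[result.flagged["relationship"] == rel]
            if len(fl):
                ax.scatter(fl["k0"], fl["k1"], s=40, facecolors="none",
                           edgecolors="red", label="flagged")
            ax.set_xlim(lo[0], hi[0])
            ax.set_ylim(lo[1], hi[1])
            ax.set_xlabel("P(Z=0)")
            ax.set_ylabel("P(Z=1)")
            ax.set_title(f"Study pairs vs simulated {rel}")
            ax.legend(loc="best", fontsize=8)
            path = outdir / f"ibd_{rel.replace('.', '_')}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            files.append(str(path))
    return files


def _ellipse_frame(ellipses) -> pd.DataFrame:
    rows = []
    for rel, e in ellipses.items():
        rows.append(
            {
                "relationship": rel,
                "mean_k0": e.mean[0],
                "mean_k1": e.mean[1],
                "cov00": e.cov[0, 0],
                "cov01": e.cov[0, 1],
                "cov11": e.cov[1, 1],
                "coverage": e.coverage,
                "threshold": e.threshold,
                "n_sim": e.n_sim,
            }
        )
    return pd.DataFrame(rows)


def load_ellipses(path) -> dict[str, reference_clusters.PredictionEllipse]:
    """Reload the ellipse parameters written by :func:`render_report`."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[r["relationship"]] = reference_clusters.PredictionEllipse(
            relationship=r["relationship"],
            mean=np.array([r["mean_k0"], r["mean_k1"]]),
            cov=np.array([[r["cov00"], r["cov01"]], [r["cov01"], r["cov11"]]]),
            coverage=float(r["coverage"]),
            threshold=float(r["threshold"]),
            n_sim=int(r["n_sim"]),
        )
    return out
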