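"""End-to-end orchestration: simulate → thresholds → IHS → constraint → report.

``run_full_analysis`` executes every stage in dependency order and writes
a machine-readable report bundle.  In simulate mode the generator writes
its fixtures in the pipeline's own input formats and the run proceeds by
reading them back through the real readers, so both modes share identical
downstream code paths.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sps

from . import __version__
from .constraint import (
    MutationRateTable,
    assign_deciles,
    calibrate_rate_scale,
    constraint_table,
    decile_confusion,
    enumerate_snvs,
    rank_loeuf_differences,
)
from .dos import StabilityThresholds, count_dos_fraction, ihs_table
from .formats_io import (
    GeneAnnotation,
    annotations_to_frame,
    read_cds_fasta,
    read_ddg_table,
    read_variants_tsv,
)
from .simulate import (
    SimulationConfig,
    generate_clinical_labels,
    generate_ddg_matrices,
    generate_genes,
    simulate_population_variants,
    write_simulation,
)
from .thresholds import (
    DepletionScan,
    compute_fdr,
    derive_thresholds,
    distribution_summary,
)

logger = logging.getLogger("mutstab")

DEFAULT_CONFIG: dict = {
    "mode": "simulate",          # simulate | real
    "seed": 0,
    # simulate-mode study conditions (generator defaults used when absent)
    "n_genes": 200,
    "cohort_size": 1000,
    "n_benign": 1000,
    "n_pathogenic": 1000,
    # real-mode input paths
    "cds_fasta": None,
    "ddg_table": None,
    "variants": None,
    "clinical_variants": None,
    "rates_table": None,
    # analysis parameters
    "threshold": 0.5,            # fallback symmetric |ΔΔG| cutoff, kcal/mol
    "derive_thresholds": True,
    "grid_step": 0.05,
    "depletion_cutoff": 0.1,
    "min_tail_n": 50,
    "ci": 0.90,
    "cap": 2.0,
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(source: str | Path | Mapping | None) -> dict:
    """Merge a flat YAML mapping (or dict) over the defaults, validating keys."""
    config = dict(DEFAULT_CONFIG)
    if source is None:
        return config
    if isinstance(source, Mapping):
        user = dict(source)
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config.update(user)
    if config["mode"] not in ("simulate", "real"):
        raise ValueError("mode must be 'simulate' or 'real'")
    return config


def config_hash(config: Mapping) -> str:
    canonical = json.dumps(dict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything one full analysis produces, plus provenance."""

    thresholds: StabilityThresholds
    scan: DepletionScan | None
    ihs: pd.DataFrame
    constraint_plof: pd.DataFrame
    constraint_dos: pd.DataFrame
    confusion: np.ndarray | None
    ranking: pd.DataFrame
    stratum_summaries: pd.DataFrame
    fdr: float | None
    dos_fraction_pathogenic: float | None
    provenance: dict
    truth: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        spearman = None
        merged = self.constraint_plof.merge(
            self.constraint_dos, on="gene_id", suffixes=("_plof", "_dos")
        )
        if len(merged) >= 3:
            rho = _sps.spearmanr(merged["loeuf_plof"], merged["loeuf_dos"])
            spearman = float(rho.statistic)
        return {
            "thresholds": {"lower": self.thresholds.lower, "upper": self.thresholds.upper},
            "thresholds_derived": self.scan is not None and self.scan.chosen is not None,
            "fdr_benign": self.fdr,
            "dos_fraction_pathogenic": self.dos_fraction_pathogenic,
            "n_genes": int(len(self.ihs)),
            "median_ihs": float(self.ihs["ihs"].median()) if len(self.ihs) else None,
            "median_observed_dos": float(self.constraint_dos["observed"].median()),
            "median_observed_plof": float(self.constraint_plof["observed"].median()),
            "spearman_plof_vs_dos_loeuf": spearman,
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.6g")
        self.ihs.to_csv(outdir / "ihs.tsv", **fmt)
        self.constraint_plof.to_csv(outdir / "constraint_plof.tsv", **fmt)
        self.constraint_dos.to_csv(outdir / "constraint_dos.tsv", **fmt)
        self.ranking.to_csv(outdir / "loeuf_difference.tsv", **fmt)
        self.stratum_summaries.to_csv(outdir / "stratum_summaries.tsv", **fmt)
        if self.scan is not None:
            pd.DataFrame(
                {
                    "grid": self.scan.grid,
                    "upper_tail_ratio": self.scan.upper_tail_ratio,
                    "lower_tail_ratio": self.scan.lower_tail_ratio,
                }
            ).to_csv(outdir / "threshold_scan.tsv", **fmt)
        if self.confusion is not None:
            pd.DataFrame(
                self.confusion,
                index=[f"plof_bin{i}" for i in range(10)],
                columns=[f"dos_bin{j}" for j in range(10)],
            ).to_csv(outdir / "decile_confusion.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_error_manifest(outdir: Path, completed: list[str], stage: str, err: Exception) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "error_manifest.json", "w") as fh:
        json.dump(
            {"failed_stage": stage, "error": str(err), "completed_stages": completed},
            fh,
            indent=2,
        )


def run_full_analysis(
    config: str | Path | Mapping | None, outdir: str | Path
) -> ReportBundle:
    """Run the whole pipeline and write the report bundle to ``outdir``.

    Partial failure leaves the completed stage outputs in place together
    with ``error_manifest.json`` naming the failed stage.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    completed: list[str] = []
    stage = "inputs"
    try:
        bundle = _run_stages(cfg, outdir, completed)
    except Exception as err:  # noqa: BLE001 - manifest then re-raise
        stage = completed[-1] if completed else stage
        _write_error_manifest(outdir, completed, f"after:{stage}", err)
        raise
    return bundle


def _run_stages(cfg: dict, outdir: Path, completed: list[str]) -> ReportBundle:
    seed = int(cfg["seed"])
    truth = None

    # ---- stage: inputs -------------------------------------------------
    if cfg["mode"] == "simulate":
        sim = SimulationConfig(
            n_genes=int(cfg["n_genes"]),
            cohort_size=int(cfg["cohort_size"]),
            seed=seed,
        )
        genes0, truth = generate_genes(sim)
        enums0 = {g.gene_id: enumerate_snvs(g) for g in genes0}
        matrices0, _, _ = generate_ddg_matrices(genes0, truth, sim)
        variants0 = simulate_population_variants(
            genes0, matrices0, truth, sim, enums=enums0
        )
        benign0, path0 = generate_clinical_labels(
            genes0, matrices0, sim,
            n_benign=int(cfg["n_benign"]), n_pathogenic=int(cfg["n_pathogenic"]),
            enums=enums0,
        )
        paths = write_simulation(
            outdir / "inputs", genes0, matrices0, truth, variants0, benign0, path0, sim
        )
    else:
        required = ["cds_fasta", "ddg_table", "variants", "rates_table"]
        for key in required:
            if not cfg[key]:
                raise FileNotFoundError(f"real-data mode requires config key {key!r}")
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(f"input file not found: {cfg[key]}")
        paths = {
            "cds_fasta": Path(cfg["cds_fasta"]),
            "ddg_table": Path(cfg["ddg_table"]),
            "variants": Path(cfg["variants"]),
            "clinical": Path(cfg["clinical_variants"]) if cfg["clinical_variants"] else None,
            "rates": Path(cfg["rates_table"]),
        }

    # Both modes read through the same readers from here on.
    genes = read_cds_fasta(paths["cds_fasta"])
    matrices = {m.protein_id: m for m in read_ddg_table(paths["ddg_table"])}
    variants = read_variants_tsv(paths["variants"], genes).variants
    clinical = (
        read_variants_tsv(paths["clinical"], genes).variants
        if paths.get("clinical") and Path(paths["clinical"]).exists()
        else []
    )
    rates = MutationRateTable.from_tsv(paths["rates"])
    enums = {g.gene_id: enumerate_snvs(g) for g in genes}
    completed.append("inputs")

    # ---- stage: calibration -------------------------------------------
    syn_counts: dict[str, int] = {}
    seen = set()
    for v in variants:
        key = (v.gene_id, v.nt_position, v.ref_base, v.alt_base)
        if key in seen or v.allele_count < 1:
            continue
        seen.add(key)
        if v.consequence == "synonymous":
            syn_counts[v.gene_id] = syn_counts.get(v.gene_id, 0) + 1
    k = calibrate_rate_scale(genes, rates, syn_counts, enums=enums)
    completed.append("calibration")

    # ---- stage: plof constraint ---------------------------------------
    ci, cap = float(cfg["ci"]), float(cfg["cap"])
    plof = constraint_table(
        genes, variants, rates, k, "plof", ci=ci, cap=cap, enums=enums
    )
    completed.append("constraint_plof")

    # ---- stage: thresholds --------------------------------------------
    fallback = StabilityThresholds(-float(cfg["threshold"]), float(cfg["threshold"]))
    scan = None
    chosen = fallback
    if cfg["derive_thresholds"] and "decile" in plof.columns:
        bins = plof.set_index("gene_id")["decile"]
        con_genes = set(bins[bins == 0].index)
        unc_genes = set(bins[bins == 9].index)
        con = [v.ddg for v in variants
               if v.gene_id in con_genes and v.consequence == "missense" and v.ddg is not None]
        unc = [v.ddg for v in variants
               if v.gene_id in unc_genes and v.consequence == "missense" and v.ddg is not None]
        if con and unc:
            scan = derive_thresholds(
                con, unc,
                grid_step=float(cfg["grid_step"]),
                depletion_cutoff=float(cfg["depletion_cutoff"]),
                min_tail_n=int(cfg["min_tail_n"]),
            )
            if scan.chosen is not None:
                chosen = scan.chosen
            else:
                logger.warning("threshold scan found no cutoffs; using fallback ±%.2f",
                               fallback.upper)
    completed.append("thresholds")

    # ---- stage: ihs ----------------------------------------------------
    ihs = ihs_table([matrices[g.gene_id] for g in genes if g.gene_id in matrices],
                    threshold=chosen.upper)
    completed.append("ihs")

    # ---- stage: dos constraint ----------------------------------------
    dos = constraint_table(
        genes, variants, rates, k, "dos",
        matrices=matrices, thresholds=chosen, ci=ci, cap=cap, enums=enums,
    )
    confusion = None
    if "decile" in plof.columns and "decile" in dos.columns:
        confusion = decile_confusion(
            plof.set_index("gene_id")["decile"], dos.set_index("gene_id")["decile"]
        )
    ranking = rank_loeuf_differences(plof, dos)
    completed.append("constraint_dos")

    # ---- stage: fdr and summaries -------------------------------------
    benign_ddgs = [v.ddg for v in clinical
                   if v.clinical_label == "benign" and v.ddg is not None]
    fdr = compute_fdr(benign_ddgs, chosen) if benign_ddgs else None
    pathogenic = [v for v in clinical if v.clinical_label == "pathogenic"]
    dos_frac = count_dos_fraction(pathogenic, chosen)[2] if pathogenic else None

    strata = []
    if "decile" in plof.columns:
        bins = plof.set_index("gene_id")["decile"]
        by_bin: dict[int, list[float]] = {}
        for v in variants:
            if v.consequence == "missense" and v.ddg is not None and v.gene_id in bins:
                by_bin.setdefault(int(bins[v.gene_id]), []).append(v.ddg)
        for b in sorted(by_bin):
            row = distribution_summary(by_bin[b])
            row.pop("quantiles")
            strata.append({"decile": b, **row})
    stratum_summaries = pd.DataFrame(strata)
    completed.append("summaries")

    provenance = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "mode": cfg["mode"],
        "versions": {
            "mutstab": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    bundle = ReportBundle(
        thresholds=chosen,
        scan=scan,
        ihs=ihs,
        constraint_plof=plof,
        constraint_dos=dos,
        confusion=confusion,
        ranking=ranking,
        stratum_summaries=stratum_summaries,
        fdr=fdr,
        dos_fraction_pathogenic=dos_frac,
        provenance=provenance,
        truth=truth,
    )
    bundle.write(outdir)
    completed.append("report")
    return bundle


def join_external_scores(
    ihs: pd.DataFrame, annotations: Iterable[GeneAnnotation]
) -> pd.DataFrame:
    """Left-join the per-gene IHS table with external constraint labels
    (published LOEUF, pLi, S_het category, Bayes factors); unmatched genes
    are tallied in ``df.attrs['n_unmatched']``."""
    ann = annotations_to_frame(list(annotations))
    if ann.empty or not set(ihs["gene_id"]) & set(ann["gene_id"]):
        raise ValueError("no overlap between IHS table and annotations")
    merged = ihs.merge(ann, on="gene_id", how="left")
    merged.attrs["n_unmatched"] = int((~merged["gene_id"].isin(ann["gene_id"])).sum())
    return merged
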