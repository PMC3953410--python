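"""End-to-end pipeline orchestration and publication-style report tables.

``run_pipeline`` drives simulate/ingest → QC → GRS construction →
per-SNP and per-score association testing → score×PA interaction from a
single config, and renders four report tables:

* table1 — per-SNP and per-score effects on BMI with explained variance;
* table2 — effects on body/trunk/leg fat percentage;
* table3 — obesity and overweight odds ratios;
* table4 — PA-stratified score effects and the interaction term.

Every stage reports its row count and exclusions in a machine-readable
manifest so the shifting analysis n (e.g. a DXA subset) is explicit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (AssocResult, OrResult, covariate_design,
                          explained_variance, inverse_normal_transform,
                          linear_assoc, logistic_assoc)
from .grs import GrsVector, compute_grs, grs_summary
from .gxe_stats import InteractionResult, fit_interaction
from .panel_io import (CohortTable, load_default_panel, read_genotypes,
                       read_panel, read_phenotypes, write_genotypes,
                       write_panel, write_phenotypes, SnpPanelRecord)
from .qc import kept_snps, snp_qc
from .synthetic_cohort import SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ReportBundle",
    "run_pipeline",
    "render_table",
    "fmt_beta_se",
    "fmt_or_ci",
    "fmt_p",
]

TABLE_LAYOUTS = ("table1", "table2", "table3", "table4")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: Exception,
                 manifest: dict | None = None) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest or {}


@dataclass
class PipelineConfig:
    """One run: either input file paths or simulation settings, never both."""

    inputs: dict[str, str] | None = None      # panel/genotypes/phenotypes paths
    simulate: dict[str, Any] | None = None    # SimulationConfig overrides
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.01
    subsets: tuple[str, ...] = ("overall", "ea", "eaa")
    max_missing: int = 3
    transform: bool = False                   # inverse-normal transform traits
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("set exactly one of inputs / simulate")
        if self.inputs is not None:
            required = {"genotypes", "phenotypes"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs lacks paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "subsets" in raw:
            raw["subsets"] = tuple(raw["subsets"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = yaml.safe_dump({
            "inputs": self.inputs, "simulate": self.simulate,
            "call_rate_min": self.call_rate_min, "hwe_p_min": self.hwe_p_min,
            "subsets": list(self.subsets), "max_missing": self.max_missing,
            "transform": self.transform, "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    panel: list[SnpPanelRecord]
    qc_table: pd.DataFrame
    kept: list[str]
    grs: dict[str, GrsVector]
    assoc_bmi: list[AssocResult]
    assoc_fat: dict[str, list[AssocResult]]
    or_results: dict[str, list[OrResult]]
    interactions: dict[str, InteractionResult]
    tables: dict[str, str]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.qc_table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        for name, text in self.tables.items():
            (out / f"{name}.tsv").write_text(text)
        for name, vec in self.grs.items():
            pd.DataFrame({
                "individual_id": vec.individual_ids,
                "score": vec.score,
                "n_missing_imputed": vec.n_missing_imputed,
            }).to_csv(out / f"grs_{name}.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------- formatting

def fmt_beta_se(beta: float, se: float) -> str:
    """Effect display: two decimals, SE in parentheses, e.g. ``0.11 (0.02)``."""
    return f"{beta:.2f} ({se:.2f})"


def fmt_or_ci(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}–{hi:.2f})"


def fmt_p(p: float) -> str:
    """p-values: two significant figures; scientific notation below 0.001."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return f"{p:.2E}"
    return f"{p:.2g}"


def render_table(results: Sequence[Mapping[str, Any]], layout: str) -> str:
    """Render association/interaction results as tab-delimited report text.

    Each element of ``results`` is a mapping whose keys depend on the layout
    (see the per-layout helpers); numeric cells use the report conventions
    (betas/SE and OR/CI to 2 decimals, p to 2 significant figures with
    scientific notation below 0.001).
    """
    if layout not in TABLE_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    if not results:
        raise ValueError("no results to render")
    renderer = {
        "table1": _render_table1, "table2": _render_table2,
        "table3": _render_table3, "table4": _render_table4,
    }[layout]
    try:
        return renderer(results)
    except KeyError as exc:
        raise ValueError(f"layout {layout!r} requires key {exc}") from exc


def _render_table1(rows: Sequence[Mapping[str, Any]]) -> str:
    lines = ["Gene\tSNP\tEAF\tBeta (SE)\tP\tExplained variance (%)"]
    for r in rows:
        a: AssocResult = r["assoc"]
        ev = r.get("explained_variance")
        lines.append("\t".join([
            str(r.get("gene", "")), str(r.get("snp", "")),
            "" if r.get("eaf") is None else f"{r['eaf']:.2f}",
            fmt_beta_se(a.beta, a.se), fmt_p(a.p),
            "" if ev is None else f"{100.0 * ev:.2f}",
        ]))
    return "\n".join(lines) + "\n"


def _render_table2(rows: Sequence[Mapping[str, Any]]) -> str:
    lines = ["Gene\tSNP\tBody fat Beta (SE)\tP\tTrunk fat Beta (SE)\tP"
             "\tLeg fat Beta (SE)\tP"]
    for r in rows:
        cells = [str(r.get("gene", "")), str(r.get("snp", ""))]
        for trait in ("body", "trunk", "leg"):
            a: AssocResult = r[trait]
            cells += [fmt_beta_se(a.beta, a.se), fmt_p(a.p)]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _render_table3(rows: Sequence[Mapping[str, Any]]) -> str:
    lines = ["Gene\tSNP\tObesity vs. Normal\tP\tOverweight vs. Normal\tP"]
    for r in rows:
        cells = [str(r.get("gene", "")), str(r.get("snp", ""))]
        for contrast in ("obesity", "overweight"):
            o: OrResult = r[contrast]
            cells += [fmt_or_ci(o.odds_ratio, o.ci_low, o.ci_high), fmt_p(o.p)]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _render_table4(rows: Sequence[Mapping[str, Any]]) -> str:
    lines = ["Score\tN low\tBeta low (SE)\tP\tN moderate\tBeta moderate (SE)"
             "\tP\tN high\tBeta high (SE)\tP\tInteraction Beta (SE)\tP"]
    for r in rows:
        res: InteractionResult = r["interaction"]
        cells = [str(r.get("label", res.predictor))]
        for level in ("low", "moderate", "high"):
            s = res.stratum[level]
            if s.beta is None:
                cells += [str(s.n), "absent", ""]
            else:
                cells += [str(s.n), fmt_beta_se(s.beta, s.se), fmt_p(s.p)]
        cells += [fmt_beta_se(res.beta_interaction, res.se), fmt_p(res.p)]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------ pipeline

def _load_stage(config: PipelineConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        panel = (read_panel(sim.pop("panel")) if "panel" in sim
                 else load_default_panel())
        sim.setdefault("seed", config.seed)
        cohort = simulate_cohort(SimulationConfig(panel=panel, **sim))
        return panel, cohort.genotypes, cohort.phenotypes
    panel = (read_panel(config.inputs["panel"]) if "panel" in config.inputs
             else load_default_panel())
    genotypes = read_genotypes(config.inputs["genotypes"], panel)
    phenotypes = read_phenotypes(config.inputs["phenotypes"])
    return panel, genotypes, phenotypes


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run QC → GRS → associations → interaction and render all tables."""
    manifest: dict[str, Any] = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "grscore": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    stage = "load"
    try:
        panel, genotypes, phenotypes = _load_stage(config)
        by_rsid = {r.rsid: r for r in panel}
        manifest["stages"]["load"] = {
            "n_individuals": genotypes.n_individuals,
            "n_snps": genotypes.n_snps,
        }

        stage = "qc"
        qc_results = snp_qc(genotypes, config.call_rate_min, config.hwe_p_min)
        kept = kept_snps(qc_results)
        qc_table = pd.DataFrame([{
            "rsid": r.rsid, "call_rate": r.call_rate, "hwe_p": r.hwe_p,
            "n0": r.genotype_counts[0], "n1": r.genotype_counts[1],
            "n2": r.genotype_counts[2], "pass": r.passed,
            "reasons": ";".join(r.reasons),
        } for r in qc_results])
        manifest["stages"]["qc"] = {
            "n_snps_in": len(qc_results), "n_snps_kept": len(kept),
            "failed": [r.rsid for r in qc_results if not r.passed],
        }

        stage = "grs"
        grs: dict[str, GrsVector] = {}
        for name in config.subsets:
            members = {
                "overall": kept,
                "ea": [s for s in kept if by_rsid[s].in_ea_set],
                "eaa": [s for s in kept if by_rsid[s].in_eaa_set],
            }[name]
            vec = compute_grs(genotypes, panel, members, config.max_missing)
            vec.subset_name = name
            grs[name] = vec
        manifest["stages"]["grs"] = {
            name: {"n_scored": len(vec), "n_excluded": len(vec.excluded),
                   "n_snps": len(vec.snps_used),
                   "summary": (grs_summary(vec)._asdict() if len(vec) > 1 else None)}
            for name, vec in grs.items()
        }

        # align phenotype rows to the genotype matrix by individual_id
        pheno = (phenotypes.data.set_index("individual_id")
                 .reindex(genotypes.individual_ids).reset_index())
        cohort = CohortTable(pheno)
        cov_bmi = covariate_design(cohort, "bmi-set")
        cov_dxa = covariate_design(cohort, "dxa-set")

        def trait_vector(name: str) -> np.ndarray:
            v = cohort.data[name].to_numpy(dtype=float)
            return inverse_normal_transform(v) if config.transform else v

        def score_for(ids: list[str], vec: GrsVector) -> np.ndarray:
            s = pd.Series(vec.score, index=vec.individual_ids)
            return s.reindex(ids).to_numpy()

        stage = "association"
        bmi = trait_vector("bmi")
        sample_eaf = {
            s: float(np.nanmean(genotypes.column(s)) / 2.0) for s in kept
        }
        assoc_bmi: list[AssocResult] = []
        table1_rows = []
        bmi_int = inverse_normal_transform(cohort.data["bmi"].to_numpy(dtype=float))
        for s in kept:
            dose = genotypes.column(s)
            res = linear_assoc(bmi, dose, cov_bmi, "bmi", s,
                               transformed=config.transform)
            res_std = linear_assoc(bmi_int, dose, cov_bmi, "bmi_int", s,
                                   transformed=True)
            assoc_bmi.append(res)
            table1_rows.append({
                "gene": by_rsid[s].gene, "snp": s, "eaf": by_rsid[s].eaf,
                "assoc": res,
                "explained_variance": explained_variance(sample_eaf[s],
                                                         res_std.beta),
            })
        for name, vec in grs.items():
            score = score_for(genotypes.individual_ids, vec)
            res = linear_assoc(bmi, score, cov_bmi, "bmi", f"{name} GRS",
                               transformed=config.transform)
            assoc_bmi.append(res)
            table1_rows.append({"gene": f"{name.upper()} GRS", "snp": "",
                                "eaf": None, "assoc": res,
                                "explained_variance": None})

        assoc_fat: dict[str, list[AssocResult]] = {}
        table2_rows = []
        fat_traits = {"body": "body_fat_pct", "trunk": "trunk_fat_pct",
                      "leg": "leg_fat_pct"}
        for short, trait in fat_traits.items():
            vals = trait_vector(trait)
            assoc_fat[trait] = [
                linear_assoc(vals, genotypes.column(s), cov_dxa, trait, s,
                             transformed=config.transform)
                for s in kept
            ]
        for i, s in enumerate(kept):
            table2_rows.append({
                "gene": by_rsid[s].gene, "snp": s,
                **{short: assoc_fat[trait][i]
                   for short, trait in fat_traits.items()},
            })
        manifest["stages"]["association"] = {
            "n_snps": len(kept),
            "n_bmi": assoc_bmi[0].n if assoc_bmi else 0,
        }

        stage = "logistic"
        wc = cohort.data["weight_class"]
        or_results: dict[str, list[OrResult]] = {"obesity": [], "overweight": []}
        table3_rows = []
        for s in kept:
            dose = genotypes.column(s)
            row = {"gene": by_rsid[s].gene, "snp": s}
            for contrast, case in (("obesity", "obese"),
                                   ("overweight", "overweight")):
                o = logistic_assoc(wc, case, "normal", dose, cov_bmi, s)
                or_results[contrast].append(o)
                row[contrast] = o
            table3_rows.append(row)
        for name, vec in grs.items():
            score = score_for(genotypes.individual_ids, vec)
            row = {"gene": f"{name.upper()} GRS", "snp": ""}
            for contrast, case in (("obesity", "obese"),
                                   ("overweight", "overweight")):
                o = logistic_assoc(wc, case, "normal", score, cov_bmi,
                                   f"{name} GRS")
                or_results[contrast].append(o)
                row[contrast] = o
            table3_rows.append(row)

        stage = "interaction"
        interactions: dict[str, InteractionResult] = {}
        table4_rows = []
        for name, vec in grs.items():
            score = score_for(genotypes.individual_ids, vec)
            res = fit_interaction(bmi, score, cohort.pa_code, cov_bmi,
                                  "bmi", f"{name} GRS")
            interactions[name] = res
            table4_rows.append({"label": f"{name.upper()} GRS",
                                "interaction": res})
        manifest["stages"]["interaction"] = {
            name: {"beta": r.beta_interaction, "p": r.p, "n": r.n}
            for name, r in interactions.items()
        }

        stage = "render"
        tables = {
            "table1": render_table(table1_rows, "table1"),
            "table2": render_table(table2_rows, "table2"),
            "table3": render_table(table3_rows, "table3"),
            "table4": render_table(table4_rows, "table4"),
        }
    except Exception as exc:  # noqa: BLE001 - stage accounting
        raise PipelineError(stage, exc, manifest) from exc

    bundle = ReportBundle(
        panel=list(panel), qc_table=qc_table, kept=kept, grs=grs,
        assoc_bmi=assoc_bmi, assoc_fat=assoc_fat, or_results=or_results,
        interactions=interactions, tables=tables, manifest=manifest,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def write_simulated_inputs(cohort, out_dir: str | Path) -> dict[str, str]:
    """Write a simulated cohort as the three tab-delimited input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": str(out / "panel.tsv"),
        "genotypes": str(out / "genotypes.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
    }
    write_panel(cohort.truth.panel, paths["panel"])
    write_genotypes(cohort.genotypes, paths["genotypes"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    return paths
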