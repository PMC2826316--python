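"""Configuration and the end-to-end pipeline driver.

:func:`run_pipeline` wires the stages together in the order the analysis
runs: simulate (or ingest) -> bucket/normalize -> dose-response
chemometrics -> gene filter cascade -> metabolite-transcriptome fusion ->
enrichment and pathway overlay -> reports.  Every run directory carries the
config hash and seeds, and a rerun with an identical config reproduces the
stage outputs byte for byte; a structured JSON-lines log records each stage.
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

from . import io as pio
from .chemometrics import ScalingSpec, fit_pls, permutation_validate, q2_cv
from .endpoints import anova_dunnett, tally_lipid_changes
from .fusion import FusionConfig, fuse_all
from .spectra import (
    SCHEME_PRESETS,
    bucket_spectra,
    normalize_total,
)
from .synthetic import (
    EXPRESSION_PANEL,
    default_ground_truth,
    make_design,
    metabolite_concentrations,
    simulate_expression,
    simulate_lipid_changes,
    simulate_spectra,
)
from .transcripts import ExpressionSet, enrich, pathway_overlay, run_cascade

__all__ = ["PipelineConfig", "run_pipeline", "builtin_term_map", "builtin_pathway_defs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on, hashable for provenance."""

    out_dir: str = "pbomics_run"
    seed: int = 0
    n_rep: int = 5
    n_null_genes: int = 300
    bucket_scheme: str = "liver_extract"
    nmr_scaling: str = "pareto"
    fold_threshold: float = 1.5
    fdr_alpha: float = 0.05
    q2_threshold: float = 0.40
    enrichment_alpha: float = 0.05
    kegg_min_overlap: int = 3
    dose_permutations: int = 200
    fusion_permutations: int = 30
    fusion_metabolites: tuple[str, ...] = ("succinate", "glucose", "glycogen")
    term_map_path: str | None = None
    pathway_defs_path: str | None = None

    def __post_init__(self) -> None:
        if self.bucket_scheme not in SCHEME_PRESETS:
            raise ValueError(
                f"unknown bucket scheme {self.bucket_scheme!r}; "
                f"presets: {sorted(SCHEME_PRESETS)}"
            )
        for name, v, lo, hi in (
            ("fdr_alpha", self.fdr_alpha, 0.0, 1.0),
            ("q2_threshold", self.q2_threshold, 0.0, 1.0),
            ("enrichment_alpha", self.enrichment_alpha, 0.0, 1.0),
        ):
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        for p in (self.term_map_path, self.pathway_defs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"annotation file not found: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def builtin_term_map() -> dict[str, set[str]]:
    """Annotation term map over the synthetic probeset namespace."""
    panel = [name for name, _, _ in EXPRESSION_PANEL]
    return {
        "xenobiotic_metabolism": {
            g for g in panel if g.startswith(("Cyp", "Ugt", "Aldh", "Ephx", "Gsta"))
        },
        "glutathione_metabolism": {
            "Gclc_glutamine_cysteine_ligase",
            "Gsr_glutathione_reductase",
            "Glul_glutamine_synthetase",
            "Me1_malic_enzyme",
        },
        "glycolysis_glycogen": {"Gck_hexokinaseD"},
        "heme_biosynthesis": {"Alas1_aminolevulinate_synthase"},
        "lipid_transport": {"Lpl_lipoprotein_lipase"},
        "housekeeping": {f"null_{i:04d}" for i in range(1, 51)},
    }


def builtin_pathway_defs() -> dict[str, tuple[set[str], set[str]]]:
    """Pathway definitions listing both gene and metabolite members."""
    return {
        "glycogen_synthesis": (
            {"Gck_hexokinaseD"},
            {"glycogen", "glucose"},
        ),
        "glutathione_synthesis": (
            {
                "Gclc_glutamine_cysteine_ligase",
                "Gsr_glutathione_reductase",
                "Glul_glutamine_synthetase",
            },
            {"glutathione", "glutamine", "glycine"},
        ),
        "tca_heme": (
            {"Alas1_aminolevulinate_synthase"},
            {"succinate"},
        ),
        "lipoprotein_handling": (
            {"Lpl_lipoprotein_lipase"},
            {"plasma_lipid"},
        ),
    }


class _RunLog:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        path.write_text("")

    def stage(self, name: str, t0: float, **info) -> None:
        rec = {
            "stage": name,
            "wall_s": round(time.monotonic() - t0, 3),
            "config_hash": self.config_hash,
            **info,
        }
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _changed_metabolites(conc: pd.DataFrame, design_frame: pd.DataFrame) -> dict[str, str]:
    """Metabolites with a Dunnett-significant dose effect, with direction."""
    out: dict[str, str] = {}
    doses = sorted(design_frame["dose_ppm"].unique())
    for met in conc.columns:
        groups = {
            str(d): conc.loc[design_frame.index[design_frame["dose_ppm"] == d], met]
            .to_numpy()
            for d in doses
        }
        rep = anova_dunnett(groups, control=str(doses[0]))
        flagged = rep.table[rep.table["flag"] != ""]
        if not flagged.empty:
            top = str(doses[-1])
            direction = (
                "up"
                if np.mean(groups[top]) > np.mean(groups[str(doses[0])])
                else "down"
            )
            out[met] = direction
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage on synthetic data; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log = _RunLog(out / "run_log.jsonl", chash)
    (out / "run_info.json").write_text(
        json.dumps(
            {"config": dataclasses.asdict(config), "config_hash": chash},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    # ---- stage: simulate -------------------------------------------------
    t0 = time.monotonic()
    design = make_design(config.n_rep, seed=config.seed)
    truth = default_ground_truth(seed=config.seed)
    spectra = simulate_spectra(design, truth)
    conc = metabolite_concentrations(design, truth)
    values, flags = simulate_expression(
        design, truth, n_null_genes=config.n_null_genes, metabolite_table=conc
    )
    lipids = simulate_lipid_changes(seed=config.seed)
    pio.write_design_tsv(out / "design.tsv", design)
    pio.write_spectra(out / "spectra", spectra)
    pio.write_matrix_tsv(out / "metabolites.tsv", conc)
    pio.write_matrix_tsv(out / "expression.tsv", values)
    flags.to_csv(out / "flags.tsv", sep="\t")
    lipids.to_csv(out / "lipid_changes.csv", index=False)
    log.stage("simulate", t0, n_samples=len(design.samples), n_probesets=len(values))

    # ---- stage: bucket / normalize ---------------------------------------
    t0 = time.monotonic()
    scheme = SCHEME_PRESETS[config.bucket_scheme]
    table = normalize_total(bucket_spectra(spectra, scheme))
    pio.write_matrix_tsv(out / "buckets_normalized.tsv", table.data)
    log.stage("bucket", t0, n_buckets=table.data.shape[1])

    # ---- stage: chemometrics (dose models per day) -----------------------
    t0 = time.monotonic()
    frame = design.to_frame()
    spec = ScalingSpec(center=True, mode=config.nmr_scaling)
    dose_rows = []
    for day in design.days:
        ids = frame.index[frame["day"] == day]
        X = table.data.loc[ids].to_numpy()
        y = frame.loc[ids, "dose_ppm"].to_numpy(dtype=float)
        model = fit_pls(X, y, 2, x_scaling=spec)
        q2_comp, q2_cum = q2_cv(X, y, 2, 7, spec)
        val = permutation_validate(
            X, y, 1, n_permutations=config.dose_permutations,
            seed=config.seed + day, x_scaling=spec,
        )
        dose_rows.append(
            {
                "day": day,
                "r2y": model.r2y_cum,
                "q2_1comp": q2_comp[0],
                "q2_cum_2comp": q2_cum,
                "max_permuted_q2": float(val.permuted[:, 2].max()),
                "beats_all_permutations": bool(val.real_q2 > val.permuted[:, 2].max()),
            }
        )
    dose_models = pd.DataFrame(dose_rows).set_index("day")
    pio.write_matrix_tsv(out / "dose_models.tsv", dose_models)
    log.stage("chemometrics", t0, n_days=len(design.days))

    # ---- stage: gene cascade ---------------------------------------------
    t0 = time.monotonic()
    es = ExpressionSet(values=values, flags=flags, design=design)
    cascade = run_cascade(es, config.fold_threshold, config.fdr_alpha)
    anova_tab = cascade["anova"].table.copy()
    anova_tab["significant"] = anova_tab.index.isin(cascade["significant"])
    pio.write_matrix_tsv(out / "de_results.tsv", anova_tab)
    if len(cascade["ratios"]):
        pio.write_matrix_tsv(out / "de_ratios.tsv", cascade["ratios"])
    log.stage(
        "cascade",
        t0,
        detected=len(cascade["detected"]),
        fold_change=len(cascade["fold_change"]),
        significant=len(cascade["significant"]),
    )

    # ---- stage: fusion -----------------------------------------------------
    t0 = time.monotonic()
    X_fusion = cascade["normalized"].loc[cascade["detected"]].T
    fusion_cfg = FusionConfig(
        n_permutations=config.fusion_permutations,
        q2_threshold=config.q2_threshold,
        seed=config.seed,
    )
    mets = conc[[m for m in config.fusion_metabolites if m in conc.columns]]
    results, summary = fuse_all(X_fusion, mets, fusion_cfg)
    pio.write_matrix_tsv(out / "fusion_summary.tsv", summary)
    for res in results:
        (out / f"fusion_{res.metabolite}.json").write_text(
            pio.fusion_result_to_json(res) + "\n"
        )
    log.stage("fusion", t0, n_metabolites=len(results))

    # ---- stage: enrichment / overlay ---------------------------------------
    t0 = time.monotonic()
    term_map = (
        pio.read_gmt(config.term_map_path)
        if config.term_map_path
        else builtin_term_map()
    )
    pathway_defs = (
        pio.read_pathway_defs(config.pathway_defs_path)
        if config.pathway_defs_path
        else builtin_pathway_defs()
    )
    universe = set(values.index)
    de_set = set(cascade["significant"])
    go_results = enrich(de_set, term_map, universe, min_overlap=1,
                        alpha=config.enrichment_alpha)
    kegg_results = enrich(de_set, term_map, universe,
                          min_overlap=config.kegg_min_overlap,
                          alpha=config.enrichment_alpha)
    enr = pd.DataFrame(
        [
            {
                "term": r.term,
                "term_size": r.term_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "qualifies_go": r.qualifies,
                "qualifies_kegg": k.qualifies,
            }
            for r, k in zip(go_results, kegg_results)
        ]
    ).set_index("term")
    pio.write_matrix_tsv(out / "enrichment.tsv", enr)

    changed = _changed_metabolites(conc, frame)
    de_dir = {}
    ratios = cascade["ratios"]
    for g in cascade["significant"]:
        mean_ratio = ratios.loc[g].mean() if g in ratios.index else 1.0
        de_dir[g] = "up" if mean_ratio > 1 else "down"
    overlay = pathway_overlay(de_dir, changed, pathway_defs)
    pio.write_matrix_tsv(out / "pathway_overlay.tsv", overlay)
    log.stage("integration", t0, co_perturbed=int(overlay["co_perturbed"].sum()))

    # ---- stage: reports ----------------------------------------------------
    t0 = time.monotonic()
    tally_frames = []
    for day, sub in lipids.groupby("day"):
        tal = tally_lipid_changes(sub)
        fa = tal.fatty_acids.reset_index()
        fa.insert(0, "day", day)
        tally_frames.append(fa)
    pd.concat(tally_frames).to_csv(out / "lipid_tally.tsv", sep="\t", index=False)
    log.stage("reports", t0)
    return out
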