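"""Microarray expression analysis: normalization, filter cascade, DE, enrichment.

The expression side of the study follows a fixed cascade, each stage only
removing probesets:

1. global normalization — every array (column) scaled to mean 500;
2. flooring at 0.01 and per-gene normalization to the row median;
3. detection filter — keep probesets with >= 3 Present flags AND an
   intensity >= 90 (on the globally normalized scale) in >= 3 samples;
4. fold-change filter — keep probesets whose treated-group median differs
   from the time-matched control median by >= 1.5-fold (either direction)
   in at least one (dose, day) cell;
5. two-way ANOVA (dose, day, interaction) on log2 values with
   Benjamini-Hochberg FDR control at 0.05 on the treatment effect.

Survivors are expressed as ratios to the time-matched control median,
clustered hierarchically on 1 - Pearson correlation, and interpreted by
hypergeometric over-representation of annotation terms and by overlaying
transcript and metabolite changes on shared pathway definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import StudyDesign

__all__ = [
    "ExpressionSet",
    "AnovaTable",
    "EnrichmentResult",
    "global_normalize",
    "floor_and_median_normalize",
    "filter_detected",
    "filter_foldchange",
    "benjamini_hochberg",
    "anova2_bh",
    "ratios_to_control",
    "hcluster_pearson",
    "enrich",
    "pathway_overlay",
    "run_cascade",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionSet:
    """Probesets x samples intensities with P/M/A detection flags."""

    values: pd.DataFrame
    flags: pd.DataFrame
    design: StudyDesign

    def __post_init__(self) -> None:
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags must be congruent in shape")
        if list(self.values.columns) != [s.sample_id for s in self.design.samples]:
            raise ValueError("value columns must match the design sample ids in order")


def global_normalize(values: pd.DataFrame, target: float = 500.0) -> pd.DataFrame:
    """Scale each array (column) so its mean intensity equals ``target``."""
    means = values.mean(axis=0)
    bad = means.index[means <= 0]
    if len(bad):
        raise ValueError(f"array {bad[0]!r} has non-positive mean; cannot normalize")
    return values.mul(target / means, axis=1)


def floor_and_median_normalize(
    values: pd.DataFrame, floor: float = 0.01
) -> pd.DataFrame:
    """Floor intensities at ``floor`` then divide each row by its median.

    After this per-gene normalization each probeset's median across samples
    is 1, so heatmaps and ratio profiles are comparable across probesets.
    """
    v = values.clip(lower=floor)
    med = v.median(axis=1)
    return v.div(med, axis=0)


def filter_detected(
    es: ExpressionSet,
    min_present: int = 3,
    intensity_threshold: float = 90.0,
    min_above: int = 3,
) -> list[str]:
    """Probesets with detectable expression.

    Kept iff the probeset has >= ``min_present`` Present flags AND an
    intensity >= ``intensity_threshold`` (globally normalized scale, before
    per-gene normalization) in >= ``min_above`` samples.
    """
    n_present = (es.flags == "P").sum(axis=1)
    n_above = (es.values >= intensity_threshold).sum(axis=1)
    keep = (n_present >= min_present) & (n_above >= min_above)
    return list(es.values.index[keep])


def _day_groups(design: StudyDesign) -> dict[int, dict[int, list[str]]]:
    """day -> dose -> sample ids."""
    out: dict[int, dict[int, list[str]]] = {}
    for s in design.samples:
        out.setdefault(s.day, {}).setdefault(s.dose, []).append(s.sample_id)
    return out


def filter_foldchange(
    values: pd.DataFrame,
    design: StudyDesign,
    threshold: float = 1.5,
    control_dose: int = 0,
) -> list[str]:
    """Probesets changing >= ``threshold``-fold vs time-matched control.

    For every treated (dose > control, day) cell, ``r`` is the ratio of the
    treated-group median to the same-day control median; the probeset is
    kept iff ``max(r, 1/r) >= threshold`` in at least one cell.
    """
    groups = _day_groups(design)
    best = pd.Series(1.0, index=values.index)
    for day, by_dose in groups.items():
        if control_dose not in by_dose:
            raise ValueError(f"no control group at day {day}")
        ctrl = values[by_dose[control_dose]].median(axis=1)
        if (ctrl <= 0).any():
            raise ValueError("non-positive control median; floor values first")
        for dose, ids in by_dose.items():
            if dose == control_dose:
                continue
            r = values[ids].median(axis=1) / ctrl
            best = np.maximum(best, np.maximum(r, 1.0 / r))
    return list(values.index[best >= threshold])


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _balanced_anova2(
    logv: np.ndarray, dose_codes: np.ndarray, day_codes: np.ndarray, n_rep: int
) -> pd.DataFrame:
    """Vectorised balanced two-way ANOVA across all probesets at once.

    ``logv`` is genes x samples; factors are categorical with equal cell
    sizes ``n_rep``.  Returns per-gene F and p for dose, day and the
    interaction, identical to OLS type-II sums of squares on a balanced
    layout.
    """
    n_dose = dose_codes.max() + 1
    n_day = day_codes.max() + 1
    g, n = logv.shape
    cell = np.zeros((g, n_day, n_dose))
    for b in range(n_day):
        for a in range(n_dose):
            cell[:, b, a] = logv[:, (day_codes == b) & (dose_codes == a)].mean(axis=1)
    grand = cell.mean(axis=(1, 2))
    dose_mean = cell.mean(axis=1)  # g x n_dose
    day_mean = cell.mean(axis=2)  # g x n_day
    ss_dose = n_rep * n_day * ((dose_mean - grand[:, None]) ** 2).sum(axis=1)
    ss_day = n_rep * n_dose * ((day_mean - grand[:, None]) ** 2).sum(axis=1)
    inter = (
        cell
        - dose_mean[:, None, :]
        - day_mean[:, :, None]
        + grand[:, None, None]
    )
    ss_inter = n_rep * (inter**2).sum(axis=(1, 2))
    fitted = np.zeros_like(logv)
    for b in range(n_day):
        for a in range(n_dose):
            mask = (day_codes == b) & (dose_codes == a)
            fitted[:, mask] = cell[:, b, a][:, None]
    ss_err = ((logv - fitted) ** 2).sum(axis=1)
    df_dose, df_day = n_dose - 1, n_day - 1
    df_inter = df_dose * df_day
    df_err = n - n_dose * n_day
    mse = ss_err / df_err
    out = {}
    for term, ss, df in (
        ("dose", ss_dose, df_dose),
        ("day", ss_day, df_day),
        ("dose:day", ss_inter, df_inter),
    ):
        f = (ss / df) / mse
        out[f"F_{term}"] = f
        out[f"p_{term}"] = stats.f.sf(f, df, df_err)
    return pd.DataFrame(out)


def _ols_anova2(
    logv: pd.DataFrame, dose: np.ndarray, day: np.ndarray, drop_interaction: bool
) -> pd.DataFrame:
    """Per-gene OLS two-way ANOVA (type II) for unbalanced designs."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    formula = "y ~ C(day) + C(dose)" + ("" if drop_interaction else " + C(day):C(dose)")
    for _, row in logv.iterrows():
        df = pd.DataFrame({"y": row.to_numpy(), "dose": dose, "day": day})
        tab = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)
        rec = {
            "F_dose": tab.loc["C(dose)", "F"],
            "p_dose": tab.loc["C(dose)", "PR(>F)"],
            "F_day": tab.loc["C(day)", "F"],
            "p_day": tab.loc["C(day)", "PR(>F)"],
        }
        if not drop_interaction:
            rec["F_dose:day"] = tab.loc["C(day):C(dose)", "F"]
            rec["p_dose:day"] = tab.loc["C(day):C(dose)", "PR(>F)"]
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class AnovaTable:
    """Per-probeset two-way ANOVA results with BH-adjusted p-values."""

    table: pd.DataFrame  # indexed by probeset
    alpha: float

    @property
    def significant_treatment(self) -> list[str]:
        return list(self.table.index[self.table["p_dose_adj"] < self.alpha])

    @property
    def significant_interaction(self) -> list[str]:
        if "p_dose:day_adj" not in self.table:
            return []
        return list(self.table.index[self.table["p_dose:day_adj"] < self.alpha])


def anova2_bh(
    values: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    already_log: bool = False,
) -> AnovaTable:
    """Two-way ANOVA (dose, day, interaction) per probeset with BH FDR.

    Values are log2-transformed first (expression changes are
    multiplicative) unless ``already_log``.  Dose and day are categorical
    factors.  Balanced designs use an exact vectorised computation;
    unbalanced designs fall back to per-gene OLS with type-II sums of
    squares.  Cells with < 2 replicates force the interaction term to be
    dropped (logged).  BH adjustment is applied per term across probesets;
    a probeset is called significant when its adjusted treatment (dose)
    p-value is below ``alpha``.
    """
    frame = design.to_frame().loc[list(values.columns)]
    dose = frame["dose_ppm"].to_numpy()
    day = frame["day"].to_numpy()
    doses = np.unique(dose)
    days = np.unique(day)
    counts = pd.crosstab(day, dose)
    drop_interaction = (counts.to_numpy() < 2).any()
    if drop_interaction:
        logger.warning("a (dose, day) cell has < 2 replicates; interaction dropped")
    logv = values.to_numpy(dtype=float)
    if not already_log:
        logv = np.log2(np.clip(logv, 1e-12, None))
    balanced = counts.to_numpy().min() == counts.to_numpy().max()
    if balanced and not drop_interaction:
        dose_codes = np.searchsorted(doses, dose)
        day_codes = np.searchsorted(days, day)
        res = _balanced_anova2(logv, dose_codes, day_codes, int(counts.iloc[0, 0]))
    else:
        res = _ols_anova2(
            pd.DataFrame(logv, index=values.index, columns=values.columns),
            dose,
            day,
            drop_interaction,
        )
    res.index = values.index
    for term in ("dose", "day", "dose:day"):
        if f"p_{term}" in res:
            res[f"p_{term}_adj"] = benjamini_hochberg(res[f"p_{term}"].to_numpy())
    return AnovaTable(table=res, alpha=alpha)


def ratios_to_control(
    values: pd.DataFrame, design: StudyDesign, control_dose: int = 0
) -> pd.DataFrame:
    """Each sample's value divided by its day's control-group median.

    Control samples are reported as ratios too (their group median maps
    to 1), so the output is a complete probesets x samples ratio matrix.
    """
    groups = _day_groups(design)
    out = values.copy().astype(float)
    for day, by_dose in groups.items():
        if control_dose not in by_dose:
            raise ValueError(f"no control group at day {day}")
        med = values[by_dose[control_dose]].median(axis=1)
        if (med <= 0).any():
            bad = med.index[med <= 0][0]
            raise ValueError(f"zero/negative control median at day {day}: {bad!r}")
        ids = [sid for dose_ids in by_dose.values() for sid in dose_ids]
        out[ids] = values[ids].div(med, axis=0)
    return out


def hcluster_pearson(
    ratios: pd.DataFrame, method: str = "average", n_clusters: int | None = None
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of probeset ratio profiles.

    Distance between two probesets is 1 - Pearson correlation of their
    ratio profiles across samples; linkage is average by default
    (configurable to complete).  Returns the scipy linkage matrix and a
    flat cluster assignment (``n_clusters`` defaults to 4, echoing the
    transient-up / transient-down / sustained-up / sustained-down reading
    of the cluster heatmap).
    """
    if method not in ("average", "complete"):
        raise ValueError("linkage method must be 'average' or 'complete'")
    if ratios.shape[0] < 2:
        raise ValueError("clustering needs at least 2 probesets")
    x = ratios.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = ratios.index[sd == 0][0]
        raise ValueError(f"probeset {bad!r} has a constant profile; cannot correlate")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    z = linkage(np.maximum(dist[iu], 0.0), method=method)
    k = n_clusters if n_clusters is not None else min(4, ratios.shape[0])
    flat = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=ratios.index)
    return z, flat


@dataclass
class EnrichmentResult:
    """One term's over-representation outcome."""

    term: str
    term_size: int
    list_size: int
    overlap: int
    p_value: float
    qualifies: bool
    members: tuple[str, ...] = field(default_factory=tuple)


def enrich(
    gene_list: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    min_overlap: int = 1,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms.

    ``p = P(overlap >= observed)`` drawing ``len(gene_list)`` genes without
    replacement from ``universe`` where ``term_size`` genes carry the term.
    No multiple-testing correction is applied; a term qualifies iff
    ``overlap >= min_overlap`` and ``p < alpha`` (use ``min_overlap=3`` for
    pathway-style analyses, 1 for GO-style).
    """
    if not gene_list <= universe:
        extra = sorted(gene_list - universe)[:3]
        raise ValueError(f"gene list members missing from universe, e.g. {extra}")
    results = []
    m_universe = len(universe)
    n_list = len(gene_list)
    for term, members in term_map.items():
        in_universe = members & universe
        if not in_universe:
            logger.warning("term %r has no universe members; skipped", term)
            continue
        overlap_genes = tuple(sorted(in_universe & gene_list))
        k = len(overlap_genes)
        p = float(stats.hypergeom.sf(k - 1, m_universe, len(in_universe), n_list))
        results.append(
            EnrichmentResult(
                term=term,
                term_size=len(in_universe),
                list_size=n_list,
                overlap=k,
                p_value=p,
                qualifies=(k >= min_overlap and p < alpha),
                members=overlap_genes,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def pathway_overlay(
    de_genes: dict[str, str],
    changed_metabolites: dict[str, str],
    pathway_defs: dict[str, tuple[set[str], set[str]]],
) -> pd.DataFrame:
    """Flag pathways perturbed at both the transcript and metabolite level.

    ``de_genes`` and ``changed_metabolites`` map member name -> direction
    ("up"/"down"); ``pathway_defs`` maps pathway -> (gene members,
    metabolite members).  A pathway is flagged iff it contains at least one
    differentially expressed gene AND at least one changed metabolite; the
    report lists the intersecting members with their directions.
    """
    rows = []
    for pathway, (genes, mets) in pathway_defs.items():
        g_hits = sorted(set(genes) & set(de_genes))
        m_hits = sorted(set(mets) & set(changed_metabolites))
        rows.append(
            {
                "pathway": pathway,
                "n_de_genes": len(g_hits),
                "n_changed_metabolites": len(m_hits),
                "co_perturbed": bool(g_hits and m_hits),
                "gene_members": ";".join(
                    f"{g}:{de_genes[g]}" for g in g_hits
                ),
                "metabolite_members": ";".join(
                    f"{m}:{changed_metabolites[m]}" for m in m_hits
                ),
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def run_cascade(
    es: ExpressionSet,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
) -> dict:
    """The full filter/DE cascade on raw intensities.

    Returns a dict with the globally normalized values, survivors of each
    stage, the ANOVA table, the significant probesets (treatment effect,
    BH < alpha) and their control-normalized ratio matrix.  Stages only
    remove probesets, so survivor counts are non-increasing.
    """
    gn = global_normalize(es.values)
    detected = filter_detected(
        ExpressionSet(values=gn, flags=es.flags, design=es.design)
    )
    fc = filter_foldchange(gn.loc[detected], es.design, threshold=fold_threshold)
    anova = anova2_bh(gn.loc[fc], es.design, alpha=alpha)
    significant = anova.significant_treatment
    ratios = (
        ratios_to_control(gn.loc[significant], es.design)
        if significant
        else pd.DataFrame(columns=gn.columns)
    )
    return {
        "normalized": gn,
        "detected": detected,
        "fold_change": fc,
        "anova": anova,
        "significant": significant,
        "interaction_significant": anova.significant_interaction,
        "ratios": ratios,
    }
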