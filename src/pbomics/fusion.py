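"""Metabolite-on-transcriptome PLS data fusion.

For each metabolite of interest, a PLS1 model is built with the expression
matrix as the X-block and the metabolite's per-sample level as the single
response.  The first component's X-weights, ranked by magnitude, name the
transcripts most strongly co-varying with the metabolite — a hypothesis
generator for which enzymes drive (or respond to) a metabolic change.

A metabolite's model is accepted only if it clears both hurdles:

* cross-validated Q² (7 round-robin segments) above 0.40, and
* real Q² greater than every one of 30 models refit after randomly
  permuting the response.

Under a global null the pass probability is at most ~1/31 before the Q²
threshold bites, so accepted correlates are rarely chance findings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import ScalingSpec, fit_pls, permutation_validate, q2_cv

__all__ = ["FusionConfig", "FusionResult", "fuse_metabolite", "fuse_all",
           "gene_gene_correlation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the fusion acceptance procedure.

    Defaults mirror the validation rules used for the dose models: a single
    PLS component, unit-variance scaling of the expression block, Q² from 7
    round-robin cross-validation segments, 30 response permutations and an
    acceptance threshold of Q² > 0.40.
    """

    n_components: int = 1
    n_permutations: int = 30
    q2_threshold: float = 0.40
    n_segments: int = 7
    x_scaling: str = "unit_variance"  # or "pareto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_scaling not in ("unit_variance", "pareto", "none"):
            raise ValueError(f"unknown x_scaling {self.x_scaling!r}")
        if not 0 < self.q2_threshold < 1:
            raise ValueError("q2_threshold must be in (0, 1)")

    @property
    def scaling_spec(self) -> ScalingSpec:
        return ScalingSpec(center=True, mode=self.x_scaling)


@dataclass
class FusionResult:
    """Outcome of one metabolite's transcriptome-PLS model.

    ``loadings`` is the full first-component weight vector indexed by
    probeset, sorted by descending magnitude (ties broken by probeset id);
    ``passed`` is True iff real Q² > threshold AND real Q² exceeds every
    permuted Q².
    """

    metabolite: str
    n_components: int
    q2: float
    permuted_q2: np.ndarray
    passed: bool
    loadings: pd.Series
    r2y: float
    seed: int

    def top_transcripts(self, k: int = 10) -> list[str]:
        return list(self.loadings.index[:k])


def _aligned(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    if list(X.index) == list(y.index):
        return X, y
    missing_x = [i for i in y.index if i not in X.index]
    missing_y = [i for i in X.index if i not in y.index]
    if missing_x or missing_y:
        raise ValueError(
            "sample ids do not match between expression and metabolite blocks; "
            f"unmatched: {sorted(set(missing_x + missing_y))[:5]}"
        )
    return X, y.loc[X.index]


def fuse_metabolite(
    X: pd.DataFrame,
    y: pd.Series,
    config: FusionConfig = FusionConfig(),
) -> FusionResult:
    """Fit and validate one metabolite's transcriptome-PLS model.

    ``X`` is samples x probesets (e.g. the filtered transcriptome), ``y``
    the metabolite's per-sample level, both indexed by sample id.
    """
    X, y = _aligned(X, y)
    if float(np.std(y.to_numpy(dtype=float))) == 0:
        raise ValueError(f"metabolite {y.name!r} has zero variance")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    spec = config.scaling_spec

    model = fit_pls(Xv, yv, config.n_components, x_scaling=spec)
    _, q2_real = q2_cv(Xv, yv, config.n_components, config.n_segments, spec)
    val = permutation_validate(
        Xv,
        yv,
        config.n_components,
        n_permutations=config.n_permutations,
        seed=config.seed,
        n_segments=config.n_segments,
        x_scaling=spec,
    )
    perm_q2 = val.permuted[:, 2]
    passed = bool(q2_real > config.q2_threshold and q2_real > perm_q2.max())

    # component-1 weights on the full (unscaled-column-dropped) gene set
    kept = X.columns
    if model.W.shape[0] != len(kept):  # zero-variance probesets were dropped
        sd = Xv.std(axis=0, ddof=1)
        kept = X.columns[sd != 0]
    w = pd.Series(model.W[:, 0], index=kept, name=y.name)
    order = sorted(w.index, key=lambda g: (-abs(w[g]), g))
    return FusionResult(
        metabolite=str(y.name),
        n_components=model.n_components,
        q2=float(q2_real),
        permuted_q2=perm_q2,
        passed=passed,
        loadings=w.loc[order],
        r2y=model.r2y_cum,
        seed=config.seed,
    )


def fuse_all(
    X: pd.DataFrame,
    metabolites: pd.DataFrame,
    config: FusionConfig = FusionConfig(),
) -> tuple[list[FusionResult], pd.DataFrame]:
    """Run :func:`fuse_metabolite` for every metabolite column.

    Zero-variance metabolite columns are skipped with a log message.
    Returns the per-metabolite results and a summary table (pass flag, Q²,
    top-3 correlates).
    """
    if metabolites.shape[1] < 1:
        raise ValueError("metabolite table has no columns")
    results: list[FusionResult] = []
    rows = []
    for name in metabolites.columns:
        y = metabolites[name]
        if float(np.std(y.to_numpy(dtype=float))) == 0:
            logger.warning("metabolite %r has zero variance; skipped", name)
            continue
        res = fuse_metabolite(X, y, config)
        results.append(res)
        rows.append(
            {
                "metabolite": name,
                "q2": res.q2,
                "passed": res.passed,
                "max_permuted_q2": float(res.permuted_q2.max()),
                "top_correlates": ";".join(res.top_transcripts(3)),
            }
        )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        summary = summary.set_index("metabolite")
    return results, summary


def gene_gene_correlation(X: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Pearson correlation of two probesets' expression across all samples.

    ``X`` may be samples x probesets or probesets x samples; the gene axis
    is found by name.
    """
    if gene_a in X.columns and gene_b in X.columns:
        a = X[gene_a].to_numpy(dtype=float)
        b = X[gene_b].to_numpy(dtype=float)
    elif gene_a in X.index and gene_b in X.index:
        a = X.loc[gene_a].to_numpy(dtype=float)
        b = X.loc[gene_b].to_numpy(dtype=float)
    else:
        missing = [g for g in (gene_a, gene_b) if g not in X.columns and g not in X.index]
        raise KeyError(f"gene(s) not found: {missing}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("gene with zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
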