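"""Univariate endpoint statistics and the lipid-species tally.

Study endpoints (relative liver weight, body weight, Ki67 labelling index,
clinical chemistry) are compared across dose groups by one-way ANOVA
followed by Dunnett's many-to-one test against the control group, with the
usual ``*`` (p < 0.05) / ``**`` (p < 0.01) flag convention.  Because
published tables report only group means, SDs and n, the test is computed
directly from those sufficient summaries; raw vectors are accepted too and
give identical answers for balanced one-way layouts.

Dunnett's two-sided adjusted p-value is the tail probability of the maximum
absolute component of an equicorrelated multivariate t (correlation 1/2 for
balanced designs), evaluated here by direct numerical integration over the
shared control-mean and pooled-variance variables — exact up to quadrature
error, no table lookup.

The lipid tally summarises an annotated list of significantly changed lipid
species into per-fatty-acid and per-headgroup counts, split by direction of
change and broken down by acylation class (free fatty acid / monoacyl /
diacyl).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "DunnettReport",
    "LipidTally",
    "summarize_groups",
    "anova_dunnett",
    "percent_change",
    "tally_lipid_changes",
]


@dataclass(frozen=True)
class GroupSummary:
    name: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"group {self.name!r}: SD must be >= 0")
        if self.n < 2:
            raise ValueError(f"group {self.name!r}: n must be >= 2 for inference")


def summarize_groups(raw: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean/SD/n summaries of raw per-group observation vectors."""
    return [
        GroupSummary(name, float(np.mean(v)), float(np.std(v, ddof=1)), len(v))
        for name, v in raw.items()
    ]


def _dunnett_p_twosided(
    t_obs: float, a: np.ndarray, df: int, n_z: int = 96, n_s: int = 128
) -> float:
    """P(max_i |T_i| > t_obs) for the many-to-one comparison family.

    ``a[i] = (1/n_i) / (1/n_i + 1/n_0)`` encodes the correlation structure
    induced by the shared control mean; the pooled variance has ``df``
    degrees of freedom.  Conditioning on the standardised control mean z0
    and on S = sigma_hat/sigma makes the comparisons independent, leaving a
    two-dimensional quadrature (Gauss-Hermite in z0, Gauss-Legendre over the
    probability transform of S).
    """
    if t_obs <= 0:
        return 1.0
    b = 1.0 - a
    # z0 nodes: int phi(z) f(z) dz via Gauss-Hermite (weight e^{-x^2})
    xh, wh = np.polynomial.hermite.hermgauss(n_z)
    z0 = xh * math.sqrt(2.0)
    wz = wh / math.sqrt(math.pi)
    # S nodes: S = sigma_hat/sigma, nu*S^2 ~ chi2_nu
    s_dist = stats.chi(df, scale=1.0 / math.sqrt(df))
    xu, wu = np.polynomial.legendre.leggauss(n_s)
    u = 0.5 * (xu + 1.0)
    ws = 0.5 * wu
    s = s_dist.ppf(u)
    # inner product over comparisons, outer over (z0, s) grid
    ts = t_obs * s  # (n_s,)
    zb = np.sqrt(b)[:, None, None] * z0[None, :, None]  # (k, n_z, 1)
    ra = np.sqrt(a)[:, None, None]
    upper = (ts[None, None, :] + zb) / ra
    lower = (-ts[None, None, :] + zb) / ra
    probs = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    joint = probs.prod(axis=0)  # (n_z, n_s)
    p_all_within = float(wz @ joint @ ws)
    return min(max(1.0 - p_all_within, 0.0), 1.0)


@dataclass
class DunnettReport:
    """One-way ANOVA F test plus Dunnett comparisons to control."""

    f_stat: float
    p_anova: float
    df_between: int
    df_error: int
    control: str
    table: pd.DataFrame  # per group: mean, sd, n, t, p_adj, flag

    def flags(self) -> dict[str, str]:
        return {g: self.table.at[g, "flag"] for g in self.table.index}


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_dunnett(
    groups: Mapping[str, Sequence[float]] | Sequence[GroupSummary],
    control: str,
) -> DunnettReport:
    """One-way ANOVA and two-sided Dunnett comparisons against the control.

    ``groups`` is either a mapping of group name to raw observations or a
    sequence of :class:`GroupSummary` (mean, SD, n).  The two routes agree
    exactly, since (mean, SD, n) are sufficient for the one-way layout.
    """
    if isinstance(groups, Mapping):
        summaries = summarize_groups(groups)
    else:
        summaries = list(groups)
    names = [g.name for g in summaries]
    if control not in names:
        raise ValueError(f"control group {control!r} not among {names}")
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    for g in summaries:
        if g.n < 2:
            raise ValueError(f"group {g.name!r} has n < 2")

    means = np.array([g.mean for g in summaries])
    sds = np.array([g.sd for g in summaries])
    ns = np.array([g.n for g in summaries])
    k = len(summaries)
    n_tot = int(ns.sum())
    grand = float((ns * means).sum() / n_tot)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_e = k - 1, n_tot - k
    if ss_within == 0:
        raise ValueError("zero pooled within-group variance; no error estimate")
    ms_within = ss_within / df_e
    f = (ss_between / df_b) / ms_within
    p_anova = float(stats.f.sf(f, df_b, df_e))

    ci = names.index(control)
    n0 = ns[ci]
    treated = [i for i in range(k) if i != ci]
    a = np.array([(1.0 / ns[i]) / (1.0 / ns[i] + 1.0 / n0) for i in treated])
    rows = []
    for idx, i in enumerate(treated):
        se = math.sqrt(ms_within * (1.0 / ns[i] + 1.0 / n0))
        t = (means[i] - means[ci]) / se
        p_adj = _dunnett_p_twosided(abs(t), a, df_e)
        rows.append((names[i], means[i], sds[i], int(ns[i]), t, p_adj, _flag(p_adj)))
    table = pd.DataFrame(
        rows, columns=["group", "mean", "sd", "n", "t", "p_adj", "flag"]
    ).set_index("group")
    return DunnettReport(
        f_stat=f,
        p_anova=p_anova,
        df_between=df_b,
        df_error=df_e,
        control=control,
        table=table,
    )


def percent_change(control_mean: float, treated_mean: float) -> int:
    """Percent change of a treated mean vs control, rounded half away from zero."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    x = 100.0 * (treated_mean - control_mean) / control_mean
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


_CLASSES = ("FFA", "monoacyl", "diacyl")
_CLASS_COLS = {"FFA": "ffa", "monoacyl": "monoacyl", "diacyl": "diacyl"}


@dataclass
class LipidTally:
    """Per-fatty-acid and per-headgroup change counts.

    Both tables are indexed by (key, direction) with columns
    ``total, ffa, monoacyl, diacyl`` where ``total`` is the sum of the
    class breakdown — the printed "total (FFA/monoacyl/diacyl)" format.
    """

    fatty_acids: pd.DataFrame
    headgroups: pd.DataFrame


def tally_lipid_changes(
    species: pd.DataFrame, double_count_identical: bool = True
) -> LipidTally:
    """Tally an annotated changed-species list for one timepoint.

    Each species row needs ``class`` (FFA/monoacyl/diacyl), ``headgroup``,
    ``fa1``/``fa2`` (carbon:double-bond codes; ``fa2`` empty except for
    diacyl species) and ``direction`` (up/down).  A fatty acid is counted
    once per occurrence, so a diacyl species with two identical chains
    counts that chain twice (set ``double_count_identical=False`` to count
    species instead); headgroup rows always count species once.
    """
    fa_counts: dict[tuple[str, str], np.ndarray] = {}
    hg_counts: dict[tuple[str, str], np.ndarray] = {}

    def bump(store, key, direction, cls):
        arr = store.setdefault((key, direction), np.zeros(3, dtype=int))
        arr[_CLASSES.index(cls)] += 1

    for _, row in species.iterrows():
        cls = row["class"]
        if cls not in _CLASSES:
            raise ValueError(f"unknown lipid class {cls!r} in {row.get('species_id')}")
        direction = row["direction"]
        fas = [
            fa
            for fa in (row.get("fa1", ""), row.get("fa2", ""))
            if isinstance(fa, str) and fa  # empty/NaN slot = no fatty acid
        ]
        if not double_count_identical:
            fas = list(dict.fromkeys(fas))
        for fa in fas:
            bump(fa_counts, fa, direction, cls)
        head = row.get("headgroup", "none")
        if head and head != "none":
            bump(hg_counts, head, direction, cls)

    def to_frame(store) -> pd.DataFrame:
        if not store:
            return pd.DataFrame(
                columns=["total", "ffa", "monoacyl", "diacyl"],
                index=pd.MultiIndex.from_tuples([], names=["key", "direction"]),
                dtype=int,
            )
        idx = pd.MultiIndex.from_tuples(sorted(store), names=["key", "direction"])
        data = np.vstack([store[k] for k in sorted(store)])
        df = pd.DataFrame(
            data, index=idx, columns=["ffa", "monoacyl", "diacyl"]
        )
        df.insert(0, "total", df.sum(axis=1))
        return df

    return LipidTally(fatty_acids=to_frame(fa_counts), headgroups=to_frame(hg_counts))
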