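"""Synthetic joint metabolomic + transcriptomic datasets with known truth.

Emulates a 28-day-style repeat-dose rodent study: four dose groups (0, 50,
500, 1000 ppm in diet) sampled at days 1, 3, 7 and 14 with five animals per
(dose, day) cell.  Every downstream stage of the pipeline — bucketing, PLS
chemometrics, the microarray filter cascade, enrichment and metabolite-on-
transcriptome fusion — can therefore be exercised against planted ground
truth instead of a data download.

The generators share one statistical skeleton:

* Dose acts through ``u = log(dose + 1) / log(1001)``, a saturating
  transform (0, 0.57, 0.90, 1.0 at the four design doses) reflecting the
  near-equal responses observed at the two highest doses.
* A :class:`PlantedEffect` multiplies (or shifts) its target — a spectral
  metabolite or a probeset — by ``exp(slope * u * day_profile[day])``.
* Metabolite concentrations carry lognormal within-group noise; spectra are
  sums of positive Lorentzian peaks on a small positive baseline, so
  intensities are strictly positive and interval integrals are analytic.
* Gene-metabolite links are constructed by orthogonalised mixing, so a
  linked probeset attains its target Pearson correlation with the
  metabolite column *exactly* at the sample level.

All generators are pure functions of their arguments and a seed; one master
seed is split deterministically into independent child streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "StudyDesign",
    "PlantedEffect",
    "GroundTruth",
    "SpectralMetabolite",
    "METABOLITE_LIBRARY",
    "DEFAULT_DOSES",
    "DEFAULT_DAYS",
    "default_ground_truth",
    "make_design",
    "metabolite_concentrations",
    "simulate_spectra",
    "simulate_expression",
    "simulate_lipid_changes",
]

DEFAULT_DOSES = (0, 50, 500, 1000)
DEFAULT_DAYS = (1, 3, 7, 14)

#: Normalising constant for the saturating dose transform.
_LOG_DOSE_MAX = math.log(1001.0)


def dose_signal(dose: float) -> float:
    """Saturating dose transform ``log(dose+1)/log(1001)`` in [0, 1]."""
    return math.log(dose + 1.0) / _LOG_DOSE_MAX


@dataclass(frozen=True)
class Sample:
    sample_id: str
    dose: int
    day: int
    replicate: int


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial (dose x day x replicate) sampling plan."""

    samples: tuple[Sample, ...]
    seed: int = 0

    @property
    def doses(self) -> tuple[int, ...]:
        return tuple(sorted({s.dose for s in self.samples}))

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted({s.day for s in self.samples}))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "dose_ppm": [s.dose for s in self.samples],
                "day": [s.day for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id")


def make_design(
    n_rep: int,
    doses: tuple[int, ...] = DEFAULT_DOSES,
    days: tuple[int, ...] = DEFAULT_DAYS,
    seed: int = 0,
) -> StudyDesign:
    """Build the factorial study design: every (dose, day) cell gets n_rep animals.

    Sample order is day-major then dose then replicate, which is also the
    order cross-validation segments are cut from downstream.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not doses or not days:
        raise ValueError("doses and days must be non-empty")
    for name, values in (("dose", doses), ("day", days)):
        seen: set[int] = set()
        for v in values:
            if v in seen:
                raise ValueError(f"duplicate {name} level: {v}")
            seen.add(v)
    samples = tuple(
        Sample(f"d{day:02d}_p{dose:04d}_r{rep}", int(dose), int(day), rep)
        for day in days
        for dose in doses
        for rep in range(1, n_rep + 1)
    )
    return StudyDesign(samples=samples, seed=seed)


@dataclass(frozen=True)
class PlantedEffect:
    """A dose-dependent perturbation of one feature.

    ``target`` names a spectral metabolite (see :data:`METABOLITE_LIBRARY`)
    or a probeset; ``slope`` is the effect per unit of the normalised
    log-dose signal, so for a multiplicative effect the top dose (1000 ppm)
    scales the feature by ``exp(slope)``.  ``day_profile`` multiplies the
    slope per study day.
    """

    target: str
    slope: float
    mode: str = "multiplicative"
    day_profile: dict[int, float] = field(
        default_factory=lambda: {d: 1.0 for d in DEFAULT_DAYS}
    )

    def __post_init__(self) -> None:
        if self.mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")

    def factor(self, dose: float, day: int) -> float:
        """Multiplicative factor (or additive shift) at (dose, day)."""
        try:
            w = self.day_profile[day]
        except KeyError:
            raise ValueError(
                f"effect on {self.target!r} has no day_profile entry for day {day}"
            ) from None
        s = self.slope * w * dose_signal(dose)
        return math.exp(s) if self.mode == "multiplicative" else s


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generators need to plant recoverable structure."""

    effects: tuple[PlantedEffect, ...]
    gene_metabolite_links: tuple[tuple[str, str, float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, met, r in self.gene_metabolite_links:
            if abs(r) > 1:
                raise ValueError(f"link {gene}-{met} has |r| = {abs(r)} > 1")


@dataclass(frozen=True)
class SpectralMetabolite:
    """Peak model for one synthetic metabolite.

    ``peaks`` are (center ppm, half-width gamma, relative weight) Lorentzians
    summing the metabolite's signal; ``interval`` is a clean ppm window over
    an isolated resonance, used when checking planted interval integrals.
    """

    peaks: tuple[tuple[float, float, float], ...]
    base: float
    interval: tuple[float, float]


_G = 0.006  # default Lorentzian half-width (ppm)

METABOLITE_LIBRARY: dict[str, SpectralMetabolite] = {
    "glucose": SpectralMetabolite(
        peaks=((3.40, _G, 0.15), (3.46, _G, 0.15), (3.72, _G, 0.25),
               (3.84, _G, 0.20), (5.22, _G, 0.125), (5.24, _G, 0.125)),
        base=30.0,
        interval=(5.13, 5.31),
    ),
    "glycogen": SpectralMetabolite(
        peaks=((3.65, _G, 0.30), (3.98, _G, 0.30), (5.41, _G, 0.40)),
        base=25.0,
        interval=(5.31, 5.51),
    ),
    "succinate": SpectralMetabolite(
        peaks=((2.41, _G, 1.0),), base=3.0, interval=(2.36, 2.46)
    ),
    "adenosine": SpectralMetabolite(
        peaks=((8.35, _G, 0.4), (8.24, _G, 0.4), (6.05, _G, 0.2)),
        base=2.0,
        interval=(8.30, 8.40),
    ),
    "glutamine": SpectralMetabolite(
        peaks=((2.14, _G, 0.5), (2.45, _G, 0.5)), base=4.0, interval=(2.10, 2.18)
    ),
    "glutathione": SpectralMetabolite(
        peaks=((2.17, _G, 0.3), (2.55, _G, 0.4), (2.95, _G, 0.3)),
        base=3.0,
        interval=(2.91, 2.99),
    ),
    "lactate": SpectralMetabolite(
        peaks=((1.33, _G, 0.7), (4.11, _G, 0.3)), base=6.0, interval=(1.28, 1.38)
    ),
    "alanine": SpectralMetabolite(
        peaks=((1.48, _G, 1.0),), base=3.0, interval=(1.43, 1.53)
    ),
    "creatine": SpectralMetabolite(
        peaks=((3.04, _G, 0.6), (3.93, _G, 0.4)), base=4.0, interval=(2.99, 3.09)
    ),
    "taurine": SpectralMetabolite(
        peaks=((3.27, _G, 0.5), (3.43, _G, 0.5)), base=5.0, interval=(3.22, 3.32)
    ),
    "glycine": SpectralMetabolite(
        peaks=((3.57, _G, 1.0),), base=3.0, interval=(3.52, 3.62)
    ),
}


def _fold(f: float) -> float:
    """Slope giving fold change ``f`` at the top dose."""
    return math.log(f)


#: Dose-responsive probeset panel: (probeset, fold change at 1000 ppm,
#: day profile).  Magnitudes and directions follow the classic hepatic
#: phenobarbital response: xenobiotic-metabolising enzymes strongly induced,
#: glycolytic/glutamine genes repressed.
EXPRESSION_PANEL: tuple[tuple[str, float, dict[int, float]], ...] = (
    ("Gck_hexokinaseD", 0.40, {1: 0.8, 3: 0.6, 7: 1.0, 14: 1.0}),
    ("Glul_glutamine_synthetase", 0.30, {1: 0.5, 3: 0.8, 7: 0.7, 14: 1.0}),
    ("Gclc_glutamine_cysteine_ligase", 1.80, {1: 0.8, 3: 1.0, 7: 0.1, 14: 0.2}),
    ("Lpl_lipoprotein_lipase", 5.16, {1: 0.1, 3: 0.5, 7: 1.2, 14: 1.0}),
    ("Ephx1_epoxide_hydrolase", 3.33, {1: 0.8, 3: 0.9, 7: 0.8, 14: 1.0}),
    ("Cyp3a3", 1.81, {1: 0.95, 3: 1.0, 7: 0.9, 14: 1.0}),
    ("Aldh1a1_aldehyde_dehydrogenase", 24.59, {1: 0.5, 3: 0.7, 7: 0.85, 14: 1.0}),
    ("Ugt1a6_udp_glucuronosyltransferase", 5.89, {1: 0.9, 3: 1.05, 7: 1.05, 14: 1.0}),
    ("Gsta_yb4_glutathione_s_transferase", 7.89, {1: 0.4, 3: 1.05, 7: 1.0, 14: 1.0}),
    ("Cyp2b2", 8.71, {1: 0.9, 3: 1.0, 7: 0.9, 14: 1.0}),
)

_ALL_DAYS = {d: 1.0 for d in DEFAULT_DAYS}


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The study conditions every acceptance check runs under.

    Spectral effects: glucose and glycogen halve at the top dose, succinate
    rises ~1.8x, adenosine falls, glutamine/glutathione rise early.  Gene
    effects: the :data:`EXPRESSION_PANEL` fold changes.  Links: one probeset
    tracks succinate at r = 0.9 (heme-synthesis surrogate) and a probeset
    pair shares a glutathione latent at r = sqrt(0.7) each, making the pair
    correlate at r ~= 0.7.
    """
    met_effects = (
        PlantedEffect("glucose", _fold(0.5), day_profile=dict(_ALL_DAYS)),
        PlantedEffect("glycogen", _fold(0.5), day_profile=dict(_ALL_DAYS)),
        PlantedEffect("succinate", _fold(1.8), day_profile=dict(_ALL_DAYS)),
        PlantedEffect("adenosine", _fold(0.7), day_profile=dict(_ALL_DAYS)),
        PlantedEffect(
            "glutamine", _fold(1.4), day_profile={1: 1.0, 3: 1.0, 7: 1.0, 14: 0.3}
        ),
        PlantedEffect(
            "glutathione", _fold(1.3), day_profile={1: 1.0, 3: 1.0, 7: 1.0, 14: 0.3}
        ),
    )
    gene_effects = tuple(
        PlantedEffect(name, _fold(fc), day_profile=dict(profile))
        for name, fc, profile in EXPRESSION_PANEL
    )
    r_pair = math.sqrt(0.7)
    links = (
        ("Alas1_aminolevulinate_synthase", "succinate", 0.9),
        ("Me1_malic_enzyme", "glutathione", r_pair),
        ("Gsr_glutathione_reductase", "glutathione", r_pair),
    )
    return GroundTruth(
        effects=met_effects + gene_effects, gene_metabolite_links=links, seed=seed
    )


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _metabolite_effects(truth: GroundTruth) -> dict[str, PlantedEffect]:
    return {e.target: e for e in truth.effects if e.target in METABOLITE_LIBRARY}


def _gene_effects(truth: GroundTruth) -> list[PlantedEffect]:
    return [e for e in truth.effects if e.target not in METABOLITE_LIBRARY]


def metabolite_concentrations(
    design: StudyDesign,
    truth: GroundTruth,
    noise_sd: float = 0.12,
) -> pd.DataFrame:
    """Latent per-sample metabolite concentrations (samples x metabolites).

    Concentration = library base level, times the planted dose/day factor,
    times lognormal within-animal noise of log-sd ``noise_sd``.
    """
    effects = _metabolite_effects(truth)
    rng = _child_rng(truth.seed, 1)
    names = list(METABOLITE_LIBRARY)
    rows = []
    for s in design.samples:
        noise = rng.normal(0.0, noise_sd, len(names))
        row = []
        for j, name in enumerate(names):
            conc = METABOLITE_LIBRARY[name].base
            eff = effects.get(name)
            if eff is not None:
                f = eff.factor(s.dose, s.day)
                conc = conc * f if eff.mode == "multiplicative" else conc + f
            row.append(max(conc, 1e-9) * math.exp(noise[j]))
        rows.append(row)
    return pd.DataFrame(rows, index=design.sample_ids, columns=names)


_BASELINE = 0.01  # small positive spectral baseline


def simulate_spectra(
    design: StudyDesign,
    truth: GroundTruth,
    ppm_grid: tuple[float, float, float] = (0.10, 10.05, 0.002),
    noise_sd: float = 0.12,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Simulate one positive 1D spectrum per sample.

    Each spectrum is a constant positive baseline plus, per metabolite, its
    Lorentzian peaks scaled by that sample's latent concentration (from
    :func:`metabolite_concentrations`, sharing the same seed).  ``noise_sd``
    is the lognormal concentration noise, so interval integrals over a
    planted metabolite's region are monotone in log(dose + 1) in expectation
    and become strictly monotone as ``noise_sd -> 0``.
    """
    start, end, step = ppm_grid
    if not (start < end and step > 0):
        raise ValueError("ppm_grid must be (start < end, step > 0)")
    for e in _metabolite_effects(truth).values():
        met = METABOLITE_LIBRARY[e.target]
        centers = [c for c, _, _ in met.peaks]
        if min(centers) < start or max(centers) > end:
            raise ValueError(
                f"effect target {e.target!r} has peaks outside the ppm grid "
                f"[{start}, {end}]"
            )
    ppm = np.arange(start, end + step / 2, step)
    conc = metabolite_concentrations(design, truth, noise_sd=noise_sd)
    # precompute unit peak shapes
    shapes = {
        name: sum(
            w * g**2 / ((ppm - c) ** 2 + g**2) for c, g, w in met.peaks
        )
        for name, met in METABOLITE_LIBRARY.items()
    }
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid in design.sample_ids:
        intensity = np.full_like(ppm, _BASELINE)
        for name in METABOLITE_LIBRARY:
            intensity = intensity + conc.at[sid, name] * shapes[name]
        out[sid] = (ppm, intensity)
    return out


def _orthogonal_mix(z: np.ndarray, eps: np.ndarray, r: float) -> np.ndarray:
    """Unit-variance vector with sample correlation exactly ``r`` to ``z``.

    ``eps`` is projected orthogonal to ``z`` and standardised before mixing,
    so the achieved Pearson correlation is exact, not merely in expectation.
    """
    z = (z - z.mean()) / z.std(ddof=0)
    e = eps - eps.mean()
    e = e - (e @ z) / (z @ z) * z
    sd = e.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate noise vector in gene-metabolite link")
    e = e / sd
    return r * z + math.sqrt(max(0.0, 1.0 - r * r)) * e


def simulate_expression(
    design: StudyDesign,
    truth: GroundTruth,
    n_null_genes: int = 500,
    metabolite_table: pd.DataFrame | None = None,
    log2_noise_sd: float = 0.15,
    frac_unexpressed: float = 0.1,
    p_flag_expressed: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a probesets x samples expression matrix plus P/A flags.

    Row blocks, in order: the dose-responsive probesets named by gene
    effects in ``truth`` (multiplicative fold changes on a log2-noise
    background), the metabolite-linked probesets (exact sample-level Pearson
    correlation with their metabolite column), and ``n_null_genes`` null
    probesets with no dose structure, of which a fraction are "unexpressed"
    (low intensity, mostly Absent flags) so the detection filter has work
    to do.

    Returns (values, flags), both probesets x samples.
    """
    if metabolite_table is None:
        metabolite_table = metabolite_concentrations(design, truth)
    if list(metabolite_table.index) != design.sample_ids:
        metabolite_table = metabolite_table.reindex(design.sample_ids)
        if metabolite_table.isna().any().any():
            raise ValueError("metabolite_table rows do not align with design samples")
    rng = _child_rng(truth.seed, 2)
    flag_rng = _child_rng(truth.seed, 3)
    n = len(design.samples)
    u = np.array([dose_signal(s.dose) for s in design.samples])
    day = np.array([s.day for s in design.samples])

    names: list[str] = []
    values: list[np.ndarray] = []
    expressed: list[bool] = []

    for eff in _gene_effects(truth):
        # bound the probeset's top intensity so strongly induced genes do not
        # dominate the array total (on a genome-wide array DE probesets are a
        # small fraction of total signal, keeping mean normalization stable)
        fc_max = math.exp(max(abs(eff.slope), 0.0))
        base = float(rng.uniform(300.0, 3000.0)) / max(fc_max, 1.0)
        w = np.array([eff.day_profile.get(d, 1.0) for d in day])
        log2fc = (eff.slope / math.log(2.0)) * w * u
        vals = base * 2.0 ** (log2fc + rng.normal(0.0, log2_noise_sd, n))
        names.append(eff.target)
        values.append(vals)
        expressed.append(True)

    for gene, met, r in truth.gene_metabolite_links:
        if met not in metabolite_table.columns:
            raise ValueError(f"link {gene!r} references unknown metabolite {met!r}")
        z = metabolite_table[met].to_numpy(dtype=float)
        if r == 0.0:
            g = _orthogonal_mix(z, rng.normal(0.0, 1.0, n), 0.0)
        else:
            g = _orthogonal_mix(z, rng.normal(0.0, 1.0, n), r)
        base = float(rng.uniform(300.0, 900.0))
        vals = np.maximum(base + 0.25 * base * g, 1.0)
        names.append(gene)
        values.append(vals)
        expressed.append(True)

    n_unexpressed = int(round(frac_unexpressed * n_null_genes))
    for i in range(n_null_genes):
        is_expr = i >= n_unexpressed
        if is_expr:
            base = float(rng.lognormal(math.log(400.0), 0.8))
        else:
            base = float(rng.uniform(5.0, 40.0))
        vals = base * 2.0 ** rng.normal(0.0, log2_noise_sd, n)
        names.append(f"null_{i + 1:04d}")
        values.append(vals)
        expressed.append(is_expr)

    mat = pd.DataFrame(np.vstack(values), index=names, columns=design.sample_ids)
    p_present = np.where(np.array(expressed)[:, None], p_flag_expressed, 0.05)
    flags = pd.DataFrame(
        np.where(flag_rng.random(mat.shape) < p_present, "P", "A"),
        index=mat.index,
        columns=mat.columns,
    )
    return mat, flags


# ---------------------------------------------------------------------------
# lipid-species change lists
# ---------------------------------------------------------------------------

_FA_POOL = (
    "14:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2",
    "20:0", "20:3", "20:4", "20:5", "22:0", "22:4", "22:6",
)
_HEADGROUPS = ("GpIns", "GpEtn", "GpCho", "GpGro", "GpSer", "GPA")
_LIPID_CLASSES = ("FFA", "monoacyl", "diacyl")


def simulate_lipid_changes(
    seed: int = 0,
    n_species_per_day: int = 40,
    days: tuple[int, ...] = (3, 7, 14),
) -> pd.DataFrame:
    """Random annotated lipid-species change list, Table-4-shaped.

    Each row is one significantly changed species: its acylation class,
    phospholipid headgroup ("none" for free fatty acids), one or two fatty
    acids coded carbons:double-bonds, a direction of change, and the study
    day.  Deterministic for a fixed seed.
    """
    rng = _child_rng(seed, 4)
    rows = []
    k = 0
    for day in days:
        for _ in range(n_species_per_day):
            k += 1
            cls = _LIPID_CLASSES[int(rng.integers(len(_LIPID_CLASSES)))]
            if cls == "FFA":
                head = "none"
                fa1, fa2 = _FA_POOL[int(rng.integers(len(_FA_POOL)))], ""
            else:
                head = _HEADGROUPS[int(rng.integers(len(_HEADGROUPS)))]
                fa1 = _FA_POOL[int(rng.integers(len(_FA_POOL)))]
                fa2 = (
                    _FA_POOL[int(rng.integers(len(_FA_POOL)))]
                    if cls == "diacyl"
                    else ""
                )
            direction = "up" if rng.random() < 0.5 else "down"
            rows.append(
                {
                    "species_id": f"lip_{k:04d}",
                    "class": cls,
                    "headgroup": head,
                    "fa1": fa1,
                    "fa2": fa2,
                    "direction": direction,
                    "day": day,
                }
            )
    return pd.DataFrame(rows)
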