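"""Synthetic biopsy cohorts with known latent injury levels.

Each simulated patient carries two latent ground-truth levels in [0, 1]:
``acute_level`` (ongoing Wallerian-type axonal degeneration) and
``chronic_level`` (long-standing axonal depletion). Observable quantities
are generated from them:

* serum NfL is log-normal with a log-linear age trend and a log-scale
  acute-degeneration effect (``beta_acute``) — NfL is released into blood
  during active axonal breakdown, not by historical loss;
* CSF NfL shares the age trend and carries a CNS-disease effect
  (``beta_cns``) — central release inflates CSF far more than peripheral
  injury does;
* nerve-tissue NfL increases with the acute level;
* the five histological parameters are deterministic monotone functions of
  the latent levels (see :func:`ground_truth_histology_targets`) that the
  slide renderer and segmentation chains are tested against.

The defaults mirror the study conditions: 35 patients, ages spanning
26-82 years, about a quarter with serum-relevant CNS disease, right-skewed
NfL with log-scale noise SD 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import CohortRecord, classify_timecourse
from .nfl import NfLPanel, cap_at_detection_limit

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "HistoMetrics",
    "simulate_cohort",
    "ground_truth_histology_targets",
]


@dataclass(frozen=True)
class HistoMetrics:
    """The five per-patient histological parameters.

    Chronic axonal loss: ``nf70_pct_area`` (% fascicular area NF70+) and
    ``fiber_density`` (myelinated fibers / mm^2). Acute degeneration:
    ``degen_density`` (degenerating fibers / mm^2), ``cd68_pct_area``
    (% fascicular area CD68+), and ``ovoid_fraction`` (teased fibers with
    ovoids / assessable fibers).
    """

    nf70_pct_area: float
    fiber_density: float
    degen_density: float
    cd68_pct_area: float
    ovoid_fraction: float


@dataclass(frozen=True)
class GroundTruth:
    """Latent per-patient injury levels."""

    acute_level: float
    chronic_level: float
    cns_disease: bool

    def __post_init__(self) -> None:
        if not (0 <= self.acute_level <= 1 and 0 <= self.chronic_level <= 1):
            raise ValueError("latent levels must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator parameters.

    Log-scale effects act on ln(pg/mL): ``beta_age`` per year (applied to
    age centered at 50), ``beta_acute`` per unit acute level (serum and,
    via ``beta_acute_tissue``, nerve tissue), ``beta_cns`` for CNS disease
    (CSF). ``acute_chronic_corr`` is a Gaussian-copula correlation between
    the two latent levels (independent by default; real cohorts confound
    them). Histology targets: a fully healthy nerve has
    ``healthy_fiber_density`` fibers/mm^2 and ``healthy_nf70_pct`` NF70+
    area; chronic loss depletes both; acute degeneration drives
    degenerating-fiber density, CD68+ area, and the ovoid fraction. Fiber
    densities are far below real sural values so that the slide renderer
    can place every fiber without overlap at desk-scale image sizes.
    """

    n_patients: int = 35
    seed: int = 0
    age_range: tuple[int, int] = (26, 82)
    p_male: float = 23 / 35
    p_cns: float = 9 / 35
    p_vasculitis: float = 10 / 35
    beta_age: float = 0.022
    beta_acute: float = 1.5
    beta_acute_tissue: float = 1.0
    beta_cns: float = 1.0
    sigma_noise: float = 0.4
    acute_chronic_corr: float = 0.0
    baseline_serum: float = 10.0
    baseline_csf: float = 500.0
    baseline_tissue: float = 800.0
    total_protein_mg_ml: float = 2.0
    sigma_protein: float = 0.2
    healthy_fiber_density: float = 700.0
    chronic_fiber_loss: float = 0.85
    healthy_nf70_pct: float = 30.0
    chronic_nf70_loss: float = 0.8
    max_degen_density: float = 250.0
    baseline_cd68_pct: float = 0.5
    max_extra_cd68_pct: float = 12.0
    max_ovoid_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in ("baseline_serum", "baseline_csf", "baseline_tissue", "sigma_noise",
                     "total_protein_mg_ml", "sigma_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_male", "p_cns", "p_vasculitis"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1 < self.acute_chronic_corr < 1:
            raise ValueError("acute_chronic_corr must be in (-1, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def ground_truth_histology_targets(gt: GroundTruth, config: SimulationConfig) -> HistoMetrics:
    """Expected histological parameters implied by a patient's latent levels.

    Acute parameters (degenerating-fiber density, CD68+ area, ovoid
    fraction) increase strictly with ``acute_level``; chronic parameters
    (fiber density, NF70+ area) decrease strictly with ``chronic_level``.
    A patient with ``acute_level == 0`` has no degenerating fibers; one with
    ``chronic_level == 0`` has the configured healthy density and NF70 area.
    """
    a, c = gt.acute_level, gt.chronic_level
    return HistoMetrics(
        nf70_pct_area=config.healthy_nf70_pct * (1.0 - config.chronic_nf70_loss * c),
        fiber_density=config.healthy_fiber_density * (1.0 - config.chronic_fiber_loss * c),
        degen_density=config.max_degen_density * a,
        cd68_pct_area=config.baseline_cd68_pct + config.max_extra_cd68_pct * a,
        ovoid_fraction=config.max_ovoid_fraction * a,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[CohortRecord], list[GroundTruth], list[NfLPanel]]:
    """Draw a synthetic cohort: records, latent truths, and NfL panels.

    Identical configs (including seed) give identical output. CSF and
    tissue concentrations exceeding the assay detection limits are capped
    with the corresponding flags set, exactly as measured panels would be.
    """
    if config.n_patients < 2:
        raise ValueError(f"n_patients must be >= 2, got {config.n_patients}")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # latent levels via a Gaussian copula so a confounding knob is available
    rho = config.acute_chronic_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    acute = norm.cdf(z[:, 0])
    chronic = norm.cdf(z[:, 1])

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    male = rng.random(n) < config.p_male
    cns = rng.random(n) < config.p_cns
    vasc = rng.random(n) < config.p_vasculitis
    onset_days = rng.integers(0, 180, size=n)
    delta_days = rng.integers(-20, 26, size=n)

    eps = rng.normal(0.0, config.sigma_noise, size=(3, n))
    age_term = config.beta_age * (ages - 50.0)
    serum = np.exp(np.log(config.baseline_serum) + age_term + config.beta_acute * acute + eps[0])
    csf = np.exp(
        np.log(config.baseline_csf) + age_term + config.beta_cns * cns.astype(float) + eps[1]
    )
    tissue = np.exp(
        np.log(config.baseline_tissue) + config.beta_acute_tissue * acute + eps[2]
    )
    protein = np.exp(rng.normal(np.log(config.total_protein_mg_ml), config.sigma_protein, size=n))

    records, truths, panels = [], [], []
    for i in range(n):
        sid = f"S{i + 1}"
        records.append(
            CohortRecord(
                study_id=sid,
                age=int(ages[i]),
                sex="m" if male[i] else "f",
                clinical_dx="synthetic neuropathy",
                path_dx="synthetic",
                timecourse=classify_timecourse(int(onset_days[i])),
                delta_days_to_biopsy=int(delta_days[i]),
                cns_disease="yes" if cns[i] else "no",
                vasculitis="definite_or_probable" if vasc[i] else "other",
            )
        )
        truths.append(
            GroundTruth(
                acute_level=float(acute[i]),
                chronic_level=float(chronic[i]),
                cns_disease=bool(cns[i]),
            )
        )
        csf_v, csf_cap = cap_at_detection_limit(float(csf[i]), "csf")
        tis_v, tis_cap = cap_at_detection_limit(float(tissue[i]), "tissue")
        panels.append(
            NfLPanel(
                study_id=sid,
                serum=float(serum[i]),
                csf=csf_v,
                tissue=tis_v,
                total_protein=float(protein[i]),
                csf_capped=csf_cap,
                tissue_capped=tis_cap,
            )
        )
    return records, truths, panels
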