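"""NfL post-processing: detection-limit capping, tissue %-protein, serum/CSF
ratio, age-specific Z-scores, and the capping sensitivity analysis.

Serum NfL rises with axonal injury anywhere in the nervous system, so three
confounder-adjustment devices are provided: the serum/CSF ratio discounts
central release, the age-specific Z-score removes the age trend, and the
capping sensitivity analysis probes how results depend on CSF/tissue values
that saturated the assay's validated detection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "DETECTION_LIMITS",
    "NfLPanel",
    "NfLDerived",
    "ReferenceModel",
    "DEFAULT_REFERENCE",
    "cap_at_detection_limit",
    "tissue_pct_protein",
    "serum_csf_ratio",
    "age_z_score",
    "derive_panel",
    "capping_sensitivity",
]

#: Maximum validated assay detection limits, pg/mL, per compartment.
DETECTION_LIMITS = {"csf": 25_000.0, "tissue": 7_800.0}


@dataclass(frozen=True)
class NfLPanel:
    """Raw NfL concentrations for one patient, with capping flags.

    ``serum``, ``csf`` and ``tissue`` are pg/mL; ``total_protein`` is the
    mg/mL total-protein concentration of the tissue homogenate aliquot.
    Missing compartments are ``None``. A capped flag being set implies the
    stored value equals the corresponding detection limit.
    """

    study_id: str
    serum: float | None = None
    csf: float | None = None
    tissue: float | None = None
    total_protein: float | None = None
    csf_capped: bool = False
    tissue_capped: bool = False

    def __post_init__(self) -> None:
        for name in ("serum", "csf", "tissue", "total_protein"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.study_id}: {name} must be > 0, got {v}")
        if self.csf_capped and self.csf != DETECTION_LIMITS["csf"]:
            raise ValueError(f"{self.study_id}: csf_capped implies csf == detection limit")
        if self.tissue_capped and self.tissue != DETECTION_LIMITS["tissue"]:
            raise ValueError(f"{self.study_id}: tissue_capped implies tissue == detection limit")


@dataclass(frozen=True)
class NfLDerived:
    """Derived per-patient NfL quantities.

    ``serum_csf_ratio_lower_bound`` marks ratios whose CSF denominator was
    capped: the true CSF value may exceed the limit, so the stored ratio is
    an upper bound and the true ratio is only known to be below it.
    """

    study_id: str
    serum_z: float | None
    serum_csf_ratio: float | None
    serum_csf_ratio_lower_bound: bool
    tissue_pct_protein: float | None


@dataclass(frozen=True)
class ReferenceModel:
    """Parametric age reference for serum NfL on the natural-log scale.

    ``mu(age)`` is the mean of ln(serum NfL pg/mL) at a given age and
    ``sigma(age)`` the log-scale SD. The packaged default is a synthetic
    stand-in (log-linear mean, constant SD) documenting plausible adult
    values; clinical use requires user-supplied reference parameters.
    """

    mu: Callable[[float], float]
    sigma: Callable[[float], float]
    age_min: float = 18.0
    age_max: float = 90.0

    def check_age(self, age: float) -> None:
        if not (self.age_min <= age <= self.age_max):
            raise ValueError(
                f"age {age} outside reference support [{self.age_min}, {self.age_max}]"
            )


def _default_mu(age: float) -> float:
    # ln 8 pg/mL at age 20, ~2.5%/year increase
    return math.log(8.0) + 0.025 * (age - 20.0)


DEFAULT_REFERENCE = ReferenceModel(mu=_default_mu, sigma=lambda age: 0.5)


def cap_at_detection_limit(value: float, compartment: str) -> tuple[float, bool]:
    """Cap a concentration at the compartment's validated detection limit.

    Returns ``(capped_value, was_capped)``. Idempotent: re-capping a capped
    value is a no-op.
    """
    if compartment not in DETECTION_LIMITS:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of {sorted(DETECTION_LIMITS)}"
        )
    if value <= 0:
        raise ValueError(f"concentration must be > 0, got {value}")
    limit = DETECTION_LIMITS[compartment]
    if value > limit:
        return limit, True
    return value, False


def tissue_pct_protein(nfl_pg_ml: float, total_protein_mg_ml: float) -> float:
    """Express tissue NfL as % of the total protein fraction.

    Both quantities refer to the same homogenate aliquot; 1 mg/mL equals
    1e9 pg/mL, so the result is ``nfl / (protein * 1e9) * 100``.
    """
    if total_protein_mg_ml <= 0:
        raise ValueError(f"total protein must be > 0, got {total_protein_mg_ml}")
    if nfl_pg_ml < 0:
        raise ValueError(f"NfL concentration must be >= 0, got {nfl_pg_ml}")
    return nfl_pg_ml / (total_protein_mg_ml * 1e9) * 100.0


def serum_csf_ratio(
    serum: float | None, csf: float | None, csf_capped: bool = False
) -> tuple[float | None, bool]:
    """Serum/CSF NfL ratio with the capped-denominator flag propagated.

    Returns ``(ratio, lower_bound_uncertain)``; the flag is True when the
    CSF value was capped, in which case the reported ratio is an upper
    bound on the true ratio. Missing compartments yield ``(None, False)``.
    """
    if serum is None or csf is None:
        return None, False
    if serum <= 0 or csf <= 0:
        raise ValueError("serum and CSF concentrations must be > 0")
    return serum / csf, csf_capped


def age_z_score(serum: float, age: float, ref: ReferenceModel = DEFAULT_REFERENCE) -> float:
    """Age-specific Z-score of serum NfL: ``(ln serum - mu(age)) / sigma(age)``."""
    if serum <= 0:
        raise ValueError(f"serum must be > 0, got {serum}")
    ref.check_age(age)
    sd = ref.sigma(age)
    if sd <= 0:
        raise ValueError(f"reference sigma must be > 0 at age {age}, got {sd}")
    return (math.log(serum) - ref.mu(age)) / sd


def derive_panel(
    panel: NfLPanel, age: float | None = None, ref: ReferenceModel = DEFAULT_REFERENCE
) -> NfLDerived:
    """Compute all derived quantities for one panel.

    The Z-score requires ``age``; it is ``None`` when age or serum is missing.
    """
    ratio, lb = serum_csf_ratio(panel.serum, panel.csf, panel.csf_capped)
    z = None
    if age is not None and panel.serum is not None:
        z = age_z_score(panel.serum, age, ref)
    pct = None
    if panel.tissue is not None and panel.total_protein is not None:
        pct = tissue_pct_protein(panel.tissue, panel.total_protein)
    return NfLDerived(
        study_id=panel.study_id,
        serum_z=z,
        serum_csf_ratio=ratio,
        serum_csf_ratio_lower_bound=lb,
        tissue_pct_protein=pct,
    )


def capping_sensitivity(
    panels: Sequence[NfLPanel],
    analysis: Callable[[list[NfLPanel]], dict],
    multipliers: Iterable[float] = (1.0, 1.5, 2.0, 5.0),
) -> pd.DataFrame:
    """Re-run a downstream analysis with capped values inflated by each multiplier.

    For each multiplier m >= 1, every capped CSF/tissue value is replaced by
    ``limit * m`` (multiplier 1 reproduces the primary analysis exactly) and
    ``analysis`` is called on the modified panel list. Its returned dict of
    scalars becomes one row of the output table, indexed by multiplier.
    """
    multipliers = list(multipliers)
    if not multipliers:
        raise ValueError("at least one multiplier required")
    if any(m < 1 for m in multipliers):
        raise ValueError("multipliers must be >= 1 (caps are lower bounds on the true value)")
    rows = []
    for m in multipliers:
        modified = []
        for p in panels:
            q = p
            if p.csf_capped:
                q = replace(q, csf=DETECTION_LIMITS["csf"] * m, csf_capped=m == 1.0)
            if p.tissue_capped:
                q = replace(q, tissue=DETECTION_LIMITS["tissue"] * m, tissue_capped=m == 1.0)
            modified.append(q)
        rows.append({"multiplier": m, **analysis(modified)})
    return pd.DataFrame(rows).set_index("multiplier")
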