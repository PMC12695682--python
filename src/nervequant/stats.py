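"""Spearman rank correlation with Fisher-z confidence intervals, the
cross-compartmental analysis panel, and plain-text report rendering.

Serum NfL is strongly right-skewed, so all associations are assessed by
rank correlation. Each result carries the coefficient, a 95% CI obtained by
Fisher z-transforming r with standard error 1/sqrt(n-3), a two-tailed p from
the t-approximation with n-2 degrees of freedom, and the number of
pairwise-complete observations used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "MODERATE_R_CUTOFF",
    "spearman",
    "moderate_correlation_flag",
    "run_panel",
    "render_report",
    "DEFAULT_PANEL_SPEC",
]

#: |r| at or above this is considered moderately strong and clinically meaningful.
MODERATE_R_CUTOFF = 0.5


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation with 95% CI, two-tailed p, and n."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __str__(self) -> str:  # mirrors the conventional "r [CI]; p; n" layout
        return (
            f"r = {self.r:.2f} [{self.ci_low:.2f} to {self.ci_high:.2f}]; "
            f"p = {self.p:.4g}; n = {self.n}"
        )


def _rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (the Spearman coefficient)."""
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y, exact_p: bool = False) -> CorrelationResult:
    """Spearman rank correlation of two series on pairwise-complete pairs.

    Ties receive average ranks; r is the Pearson correlation of the ranks.
    The 95% CI back-transforms ``atanh(r) -/+ 1.96/sqrt(n-3)``. The p-value
    uses the t-approximation ``t = r*sqrt((n-2)/(1-r^2))`` with n-2 df;
    ``exact_p=True`` (n <= 10 only) enumerates all rank permutations instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 pairwise-complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = _rank_correlation(x, y)

    if exact_p:
        if n > 10:
            raise ValueError(f"exact permutation p limited to n <= 10, got n = {n}")
        ry = sps.rankdata(y, method="average")
        observed = abs(r)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_correlation(x, np.asarray(perm))) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)

    if abs(r) >= 1.0 or n <= 3:
        ci_low, ci_high = (-1.0, 1.0) if n <= 3 and abs(r) < 1 else (r, r)
    else:
        z = math.atanh(r)
        half = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p=float(p), n=int(n))


def moderate_correlation_flag(result: CorrelationResult) -> bool:
    """True iff |r| meets the moderate-correlation cutoff of 0.5."""
    return abs(result.r) >= MODERATE_R_CUTOFF


# The standard analysis battery: every NfL measure against the acute
# composite and both chronic-loss parameters, on all patients and restricted
# to patients without relevant CNS disease.
DEFAULT_PANEL_SPEC: list[tuple[str, str]] = [
    (x, y)
    for x in ("serum_nfl", "tissue_nfl", "serum_csf_ratio", "serum_z")
    for y in ("acute_composite", "nf70_pct_area", "fiber_density")
]


def run_panel(
    merged: pd.DataFrame,
    spec: list[tuple[str, str]] | None = None,
    exclude_unclear_cns: bool = False,
) -> pd.DataFrame:
    """Run the correlation battery on a merged per-patient table.

    ``merged`` must contain one row per patient with a ``cns_disease``
    column plus the variables named in ``spec`` (default: the full battery).
    Every pair is evaluated on all patients and on the subgroup without CNS
    disease; patients flagged ``unclear`` are retained in the restricted
    subgroup unless ``exclude_unclear_cns`` is set.

    Returns a tidy DataFrame with columns
    ``x, y, subgroup, r, ci_low, ci_high, p, n``; pairs with fewer than
    three complete observations yield NaN statistics with the available n.
    """
    spec = DEFAULT_PANEL_SPEC if spec is None else spec
    missing = {v for pair in spec for v in pair} - set(merged.columns)
    if missing:
        raise ValueError(f"merged table lacks variables: {sorted(missing)}")
    if "cns_disease" not in merged.columns:
        raise ValueError("merged table lacks the cns_disease column")

    excluded_flags = ("yes", "unclear") if exclude_unclear_cns else ("yes",)
    subgroups = {
        "all": merged,
        "no_cns": merged[~merged["cns_disease"].isin(excluded_flags)],
    }
    rows = []
    for x_var, y_var in spec:
        for name, sub in subgroups.items():
            pair = sub[[x_var, y_var]].dropna()
            if len(pair) >= 3 and pair[x_var].nunique() > 1 and pair[y_var].nunique() > 1:
                res = spearman(pair[x_var], pair[y_var])
                rows.append(
                    {
                        "x": x_var,
                        "y": y_var,
                        "subgroup": name,
                        "r": res.r,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p,
                        "n": res.n,
                    }
                )
            else:
                rows.append(
                    {
                        "x": x_var,
                        "y": y_var,
                        "subgroup": name,
                        "r": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "n": len(pair),
                    }
                )
    return pd.DataFrame(rows)


def render_report(panel: pd.DataFrame, summary=None) -> str:
    """Render a deterministic plain-text report of a correlation panel.

    One line per analysis in panel order, ``r`` and CI to two decimals,
    p to three significant figures, with the subgroup annotated. An optional
    :class:`~nervequant.cohort.CohortSummary` is printed as a header block.
    """
    lines = ["Cross-compartmental correlation report", "=" * 38]
    if summary is not None:
        lines += [
            f"Cohort: n = {summary.n_total} "
            f"({summary.n_male} m, {summary.n_female} f); "
            f"CNS disease: {summary.n_cns_yes}; "
            f"vasculitis: {summary.n_vasculitis} "
            f"({summary.n_vasculitis_acute_or_subacute} acute/subacute); "
            f"median days sample-to-biopsy: {summary.median_delta_days:g}",
            "",
        ]
    lines.append(f"{'x':<16} {'y':<18} {'subgroup':<8} result")
    lines.append("-" * 78)
    for _, row in panel.iterrows():
        if np.isnan(row["r"]):
            result = f"insufficient data (n = {int(row['n'])})"
        else:
            result = (
                f"r = {row['r']:.2f} [{row['ci_low']:.2f} to {row['ci_high']:.2f}]; "
                f"p = {row['p']:.3g}; n = {int(row['n'])}"
            )
        lines.append(f"{row['x']:<16} {row['y']:<18} {row['subgroup']:<8} {result}")
    return "\n".join(lines) + "\n"
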