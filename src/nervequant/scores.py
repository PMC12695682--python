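"""Composite acute-degeneration score and the separate chronic-loss series.

Three complementary parameters quantify acute axonal degeneration — the
density of degenerating fibers in semithin sections, the fraction of teased
fibers with ovoids, and total CD68+ macrophage infiltration — each with its
own technical limitations and, for teased fibers, limited sample
availability. To combine them, the first two are expressed as a percentage
of their dataset maximum (the CD68 value already is), and the per-patient
composite is the mean of the available normalized components. The two
chronic-loss parameters (NF70+ area and myelinated-fiber density) capture
distinct aspects of axonal depletion and are reported separately rather
than composited.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ihc import normalize_to_dataset_max
from .stats import spearman

__all__ = ["acute_composite", "component_cross_correlation", "chronic_parameters"]

ACUTE_COMPONENTS = ("degen_density", "ovoid_fraction", "cd68_total_pctmax")


def acute_composite(components: pd.DataFrame) -> pd.DataFrame:
    """Per-patient acute axonal degeneration score (%max).

    ``components`` has one row per patient with columns ``degen_density``
    (fibers/mm^2), ``ovoid_fraction`` (may be missing for patients without
    teased preparations), and ``cd68_total_pctmax`` (already %max). The
    first two are normalized to the maximum over patients with data; the
    score is the mean of the available normalized components. Patients
    with fewer than two available components get a missing score with a
    warning. Returns a DataFrame with ``acute_composite`` and
    ``n_components``, indexed like the input.
    """
    missing_cols = set(ACUTE_COMPONENTS) - set(components.columns)
    if missing_cols:
        raise ValueError(f"components table lacks columns: {sorted(missing_cols)}")
    norm = pd.DataFrame(index=components.index)
    norm["degen"] = normalize_to_dataset_max(components["degen_density"])
    norm["ovoid"] = (
        normalize_to_dataset_max(components["ovoid_fraction"])
        if components["ovoid_fraction"].notna().any()
        else np.nan
    )
    norm["cd68"] = components["cd68_total_pctmax"]

    n_avail = norm.notna().sum(axis=1)
    score = norm.mean(axis=1, skipna=True)
    score[n_avail < 2] = np.nan
    if (n_avail < 2).any():
        ids = list(components.index[n_avail < 2])
        warnings.warn(f"fewer than 2 acute components for {ids}; composite set to missing")
    return pd.DataFrame({"acute_composite": score, "n_components": n_avail})


def component_cross_correlation(components: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between the acute components.

    Each pair is evaluated on pairwise-complete observations; pairs with
    fewer than three complete pairs (or a constant series) yield NaN with
    the available n recorded. Returns a tidy DataFrame with columns
    ``a, b, r, ci_low, ci_high, p, n``.
    """
    rows = []
    cols = [c for c in ACUTE_COMPONENTS if c in components.columns]
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = components[[a, b]].dropna()
            if len(pair) >= 3 and pair[a].nunique() > 1 and pair[b].nunique() > 1:
                res = spearman(pair[a], pair[b])
                rows.append(
                    {"a": a, "b": b, "r": res.r, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p, "n": res.n}
                )
            else:
                rows.append(
                    {"a": a, "b": b, "r": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p": np.nan, "n": len(pair)}
                )
    return pd.DataFrame(rows)


def chronic_parameters(
    nf70_pct_area: pd.Series, fiber_density: pd.Series
) -> dict[str, pd.Series]:
    """Package the two chronic-loss parameters as separate labeled series.

    No composite is formed: the two parameters reflect distinct aspects of
    chronic axonal loss and did not track each other, so they are analyzed
    independently downstream.
    """
    return {
        "nf70_pct_area": nf70_pct_area.rename("nf70_pct_area"),
        "fiber_density": fiber_density.rename("fiber_density"),
    }
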