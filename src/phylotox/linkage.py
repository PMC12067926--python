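"""Linking community structure to function.

Two analyses connect the isolate screen to the community experiment:

* ordinary least-squares regressions of community growth (dAUC) on
  replicate-averaged diversity metrics (richness, Shannon, SES.MPD), asking
  which facet of diversity best predicts functional loss;
* per-genus correlations (Pearson and Spearman, BH-adjusted within each
  test family) between the mean monoculture response of a genus and the
  fold change of its aggregated relative abundance in the community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylosignal import bh_adjust

__all__ = [
    "RegressionResult",
    "diversity_growth_regression",
    "genus_fold_change",
    "mono_community_correlation",
]

PSEUDO_ABUNDANCE = 1e-4


@dataclass
class RegressionResult:
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def diversity_growth_regression(
    metric: pd.Series,
    dauc: pd.Series,
    predictor: str | None = None,
) -> RegressionResult:
    """OLS of community relative growth on a diversity metric per treatment.

    Treatments with a missing metric (e.g. a degenerate SES.MPD null) or
    missing growth value are dropped pairwise.
    """
    pair = pd.concat([metric.rename("x"), dauc.rename("y")], axis=1, join="inner").dropna()
    x = pair["x"].to_numpy(dtype=float)
    y = pair["y"].to_numpy(dtype=float)
    if len(pair) < 3:
        raise ValueError("regression needs at least 3 aligned treatments")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        predictor=predictor or (metric.name or "metric"),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(pair),
    )


def genus_fold_change(
    table: pd.DataFrame,
    taxonomy: pd.Series,
    genus: str,
    treatments: pd.Series,
    control_label: str = "DMSO",
    eps: float = PSEUDO_ABUNDANCE,
) -> pd.Series:
    """Fold change of a genus's aggregated relative abundance per treatment.

    The genus's species-level relative abundances are summed within each
    sample, averaged over replicates of each treatment, and divided by the
    control average. A pseudo-abundance ``eps`` is added to numerator and
    denominator so compositional zeros yield finite ratios.
    """
    from .community_structure import normalize_table

    taxonomy = taxonomy.reindex(table.columns)
    members = taxonomy.index[taxonomy == genus]
    if members.empty:
        raise ValueError(f"genus {genus!r} not present in the taxonomy map")
    treatments = treatments.reindex(table.index)
    if treatments.isna().any():
        raise ValueError("every sample needs a treatment label")
    if control_label not in set(treatments):
        raise ValueError(f"no samples labelled with control {control_label!r}")
    rel = normalize_table(table)
    genus_sum = rel[members].sum(axis=1)
    per_treatment = genus_sum.groupby(treatments).mean()
    control = per_treatment.loc[control_label]
    fc = (per_treatment + eps) / (control + eps)
    return fc.drop(index=control_label).rename(genus)


def mono_community_correlation(
    genus_dauc: pd.DataFrame,
    genus_fold: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson and Spearman correlations between monoculture and community responses.

    Both inputs are genera × chemicals matrices: the mean monoculture dAUC of
    each genus and its community abundance fold change. Two-sided p-values;
    BH adjustment applied separately to the Pearson family and the Spearman
    family across genera.
    """
    genera = genus_dauc.index.intersection(genus_fold.index)
    if genera.empty:
        raise ValueError("no shared genera between the two matrices")
    rows = {}
    for genus in genera:
        pair = pd.concat(
            [genus_dauc.loc[genus].rename("x"), genus_fold.loc[genus].rename("y")],
            axis=1,
        ).dropna()
        if len(pair) < 5:
            raise ValueError(f"genus {genus!r} has fewer than 5 paired observations")
        x, y = pair["x"].to_numpy(), pair["y"].to_numpy()
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise ValueError(f"genus {genus!r} has a constant response vector")
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        rows[genus] = {
            "pearson_r": float(pr.statistic),
            "p_pearson": float(pr.pvalue),
            "spearman_rho": float(sr.statistic),
            "p_spearman": float(sr.pvalue),
            "n": len(pair),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genus"
    tiny = np.finfo(float).tiny  # exact fits give p = 0, outside BH's domain
    out["p_adj_pearson"] = bh_adjust(out["p_pearson"].clip(lower=tiny))
    out["p_adj_spearman"] = bh_adjust(out["p_spearman"].clip(lower=tiny))
    return out[
        ["pearson_r", "p_pearson", "p_adj_pearson",
         "spearman_rho", "p_spearman", "p_adj_spearman", "n"]
    ]
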