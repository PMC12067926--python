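"""Growth quantification and chemical-impact screening from optical-density curves.

A culture's growth over 72 h is summarised by the area under its OD curve
(AUC), obtained by fitting a cubic smoothing spline to the hourly A600
readings and integrating the fitted spline exactly over the observed time
span. The impact of a chemical on a culture is the relative growth

    dAUC = mean(AUC, chemical replicates) / mean(AUC, DMSO replicates),

so dAUC = 1 means no effect and dAUC < 1 growth inhibition. Significance is
screened per culture with Dunnett's many-to-one test of every chemical's AUC
against the DMSO control, controlling the familywise error rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

CONTROL_LABEL = "DMSO"

REQUIRED_COLUMNS = ["culture_id", "chemical_id", "replicate", "time_h", "od"]

__all__ = [
    "GrowthCurve",
    "AUCRecord",
    "ResponseMatrix",
    "fit_auc",
    "compute_dauc",
    "dunnett_screen",
    "build_response_matrix",
    "read_growth_table",
    "wide_to_long",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One well's timestamped A600 readings.

    ``chemical_id == "DMSO"`` is reserved for the solvent-only control.
    """

    culture_id: str
    chemical_id: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.shape != times.shape:
            raise ValueError("times and od must be 1-D and of equal length")
        if len(times) < 4:
            raise ValueError(
                f"growth curve needs at least 4 time points, got {len(times)}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)):
            raise ValueError("od readings must be finite")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class AUCRecord:
    culture_id: str
    chemical_id: str
    replicate: int
    auc: float


@dataclass
class ResponseMatrix:
    """Strains × chemicals relative-growth matrix with per-cell significance.

    ``dauc`` has cultures as rows and chemicals as columns (control column
    absent — the control's relative growth is identically 1). ``p_adj`` and
    ``significant`` are aligned to ``dauc``; p-values are Dunnett-adjusted
    within each culture.
    """

    dauc: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.05

    def tidy(self) -> pd.DataFrame:
        """Long-format (culture, chemical, dauc, p_adj, significant) table."""
        out = (
            self.dauc.stack(future_stack=True)
            .rename("dauc")
            .to_frame()
            .join(self.p_adj.stack(future_stack=True).rename("p_adj"))
            .join(self.significant.stack(future_stack=True).rename("significant"))
            .reset_index()
        )
        out.columns = ["culture_id", "chemical_id", "dauc", "p_adj", "significant"]
        return out


def fit_auc(
    curve: GrowthCurve,
    smoothing: float | None = None,
    baseline: str = "none",
) -> AUCRecord:
    """Area under a growth curve via an integrated cubic smoothing spline.

    Parameters
    ----------
    curve
        The well's readings.
    smoothing
        Regularisation weight of the smoothing spline (``lam`` of
        :func:`scipy.interpolate.make_smoothing_spline`). ``None`` selects it
        by generalised cross-validation; ``0`` interpolates.
    baseline
        ``"none"`` integrates the readings as given. ``"min3"`` subtracts the
        minimum of the first three readings from every reading (a per-well
        blank correction) and clips negative values at zero before fitting.

    Returns
    -------
    AUCRecord
        The definite integral of the fitted spline over
        ``[times[0], times[-1]]``, floored at zero.
    """
    if smoothing is not None and smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    od = curve.od
    if baseline == "min3":
        od = np.clip(od - od[:3].min(), 0.0, None)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    if np.ptp(od) == 0.0:
        # GCV is ill-posed for exactly constant data; the integral is exact
        auc = float(od[0] * (curve.times[-1] - curve.times[0]))
    elif len(od) == 4:
        # too few points to smooth: integrate the interpolating cubic
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(curve.times, od)
        auc = float(spline.integrate(curve.times[0], curve.times[-1]))
    else:
        spline = make_smoothing_spline(curve.times, od, lam=smoothing)
        auc = float(spline.integrate(curve.times[0], curve.times[-1]))
    return AUCRecord(curve.culture_id, curve.chemical_id, curve.replicate, max(auc, 0.0))


def _auc_frame(records: list[AUCRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    missing = {"culture_id", "chemical_id", "replicate", "auc"} - set(df.columns)
    if missing:
        raise ValueError(f"AUC records missing columns: {sorted(missing)}")
    return df


def compute_dauc(
    records: list[AUCRecord] | pd.DataFrame,
    chemical: str,
    control_label: str = CONTROL_LABEL,
) -> float:
    """Relative growth of one culture under one chemical.

    ``records`` must contain AUC records for a single culture, including its
    control replicates. Returns mean(chemical AUCs) / mean(control AUCs).
    """
    df = _auc_frame(records)
    if df["culture_id"].nunique() != 1:
        raise ValueError("compute_dauc expects records of a single culture")
    num = df.loc[df["chemical_id"] == chemical, "auc"]
    den = df.loc[df["chemical_id"] == control_label, "auc"]
    if num.empty:
        raise ValueError(f"no replicates for chemical {chemical!r}")
    if den.empty:
        raise ValueError(f"no control ({control_label!r}) replicates")
    if den.mean() == 0:
        raise ZeroDivisionError(
            f"mean control AUC is zero for culture {df['culture_id'].iloc[0]!r}; "
            "relative growth is undefined"
        )
    return float(num.mean() / den.mean())


def dunnett_screen(
    records: list[AUCRecord] | pd.DataFrame,
    alpha: float = 0.05,
    control_label: str = CONTROL_LABEL,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Dunnett's many-to-one test of each chemical's AUC against the control.

    Two-sided adjusted p-values from the equicorrelated multivariate-t
    distribution (quasi-Monte Carlo, seeded for reproducibility). Returns a
    DataFrame indexed by chemical with columns ``p_adj`` and ``significant``.
    """
    df = _auc_frame(records)
    if df["culture_id"].nunique() != 1:
        raise ValueError("dunnett_screen expects records of a single culture")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    control = df.loc[df["chemical_id"] == control_label, "auc"].to_numpy()
    if control.size == 0:
        raise ValueError(f"missing control group {control_label!r}")
    chemicals = sorted(c for c in df["chemical_id"].unique() if c != control_label)
    if not chemicals:
        raise ValueError("no treatment groups to compare")
    groups = [df.loc[df["chemical_id"] == c, "auc"].to_numpy() for c in chemicals]
    pooled = np.concatenate(groups + [control])
    if np.ptp(pooled) == 0.0:
        raise ValueError("zero variance across all groups; Dunnett's test undefined")
    res = stats.dunnett(*groups, control=control, rng=seed)
    p = np.asarray(res.pvalue, dtype=float)
    return pd.DataFrame(
        {"p_adj": p, "significant": p < alpha}, index=pd.Index(chemicals, name="chemical_id")
    )


def build_response_matrix(
    assays: pd.DataFrame,
    alpha: float = 0.05,
    control_label: str = CONTROL_LABEL,
    smoothing: float | None = None,
    baseline: str = "none",
    seed: int | None = 0,
    screen: bool = True,
) -> ResponseMatrix:
    """Assemble the strains × chemicals dAUC matrix with Dunnett significance.

    ``assays`` is a long table with columns culture_id, chemical_id,
    replicate, time_h, od (one row per reading). Rows and columns of the
    result are sorted lexicographically, so the output is invariant to the
    input record order. Missing (culture, chemical) combinations yield NaN
    cells with a warning. ``screen=False`` skips the Dunnett screen (all
    p-values NaN), useful when only the dAUC values are needed.
    """
    df = validate_growth_table(assays)
    records = []
    for (cult, chem, rep), grp in df.groupby(
        ["culture_id", "chemical_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curve = GrowthCurve(cult, chem, int(rep), grp["time_h"].to_numpy(), grp["od"].to_numpy())
        records.append(fit_auc(curve, smoothing=smoothing, baseline=baseline))
    aucs = _auc_frame(records)

    cultures = sorted(aucs["culture_id"].unique())
    chemicals = sorted(c for c in aucs["chemical_id"].unique() if c != control_label)
    dauc = pd.DataFrame(np.nan, index=cultures, columns=chemicals)
    p_adj = pd.DataFrame(np.nan, index=cultures, columns=chemicals)
    for cult in cultures:
        sub = aucs[aucs["culture_id"] == cult]
        have = set(sub["chemical_id"])
        if control_label not in have:
            raise ValueError(f"culture {cult!r} has no {control_label!r} control wells")
        absent = set(chemicals) - have
        if absent:
            warnings.warn(
                f"culture {cult!r} missing chemicals {sorted(absent)}; cells left NaN",
                stacklevel=2,
            )
        counts = sub.groupby("chemical_id")["replicate"].nunique()
        if (counts < 3).any():
            logger.warning(
                "culture %r has groups with fewer than 3 replicates: %s",
                cult,
                counts[counts < 3].to_dict(),
            )
        for chem in have - {control_label}:
            dauc.loc[cult, chem] = compute_dauc(sub, chem, control_label)
        if screen:
            scr = dunnett_screen(sub, alpha=alpha, control_label=control_label, seed=seed)
            p_adj.loc[cult, scr.index] = scr["p_adj"]
    significant = (p_adj < alpha).where(p_adj.notna(), other=False)
    dauc.index.name = p_adj.index.name = significant.index.name = "culture_id"
    return ResponseMatrix(dauc=dauc, p_adj=p_adj, significant=significant, alpha=alpha)


def validate_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    out = df.copy()
    out["replicate"] = out["replicate"].astype(int)
    if not np.all(np.isfinite(out["od"])):
        raise ValueError("od column contains non-finite values")
    return out


def read_growth_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format growth table (TSV or CSV, sniffed by extension)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return validate_growth_table(pd.read_csv(path, sep=sep))


def wide_to_long(wide: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide plate-reader export to the long growth-table format.

    ``wide`` has a ``time_h`` column plus one column per well; ``plate_map``
    maps wells to assay labels with columns well, culture_id, chemical_id,
    replicate.
    """
    need = {"well", "culture_id", "chemical_id", "replicate"}
    if missing := need - set(plate_map.columns):
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    if "time_h" not in wide.columns:
        raise ValueError("wide table needs a time_h column")
    long = wide.melt(id_vars="time_h", var_name="well", value_name="od")
    merged = long.merge(plate_map, on="well", how="inner")
    return merged[REQUIRED_COLUMNS]
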