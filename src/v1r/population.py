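"""Population-level analysis: hierarchical clustering and Hill dose-response.

Cells are described by three firing-pattern features (mean 1/2Ad, CV 1/2Ad,
ddr).  Because mean 1/2Ad and ddr are dispersed over orders of magnitude,
clustering operates on (log10 mean 1/2Ad, CV 1/2Ad, log10 ddr), each
z-scored; agglomeration uses complete linkage with Euclidean distances and
the number of clusters is chosen by maximizing the mean silhouette width
over k = 2..12.  The 4-AP block of IKdr is described by the Hill equation

    remaining(c) = (100 - Imin) / (1 + (c / IC50)^nH) + Imin   [percent]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from sklearn.metrics import silhouette_samples

__all__ = [
    "FEATURE_COLUMNS",
    "standardize",
    "hierarchical_cluster",
    "silhouette_select_k",
    "DoseResponseModel",
    "hill_inhibition",
    "fit_hill",
]

FEATURE_COLUMNS = ("mean_half_ad_ms", "cv_half_ad_pct", "ddr")


def standardize(table: pd.DataFrame) -> np.ndarray:
    """Feature matrix (log10 mean 1/2Ad, CV 1/2Ad, log10 ddr), z-scored.

    z-scoring uses the sample standard deviation (ddof=1).  Raises on
    non-positive mean 1/2Ad or ddr (log undefined), naming the offending
    row, and on degenerate tables (n < 2 or a constant column).
    """
    if len(table) < 2:
        raise ValueError("standardize requires at least 2 rows")
    for col in ("mean_half_ad_ms", "ddr"):
        bad = table.index[table[col] <= 0]
        if len(bad):
            raise ValueError(f"non-positive {col} in row(s) {list(bad[:5])}")
    mat = np.column_stack(
        [
            np.log10(table["mean_half_ad_ms"].to_numpy(float)),
            table["cv_half_ad_pct"].to_numpy(float),
            np.log10(table["ddr"].to_numpy(float)),
        ]
    )
    sd = mat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a feature column has zero variance; cannot z-score")
    return (mat - mat.mean(axis=0)) / sd


def hierarchical_cluster(matrix: np.ndarray, k: int) -> np.ndarray:
    """Complete-linkage agglomerative clustering cut at k clusters.

    Intercluster distance is the maximum Euclidean distance between members.
    Returns integer labels 1..k (scipy fcluster convention); deterministic
    for a given row order.
    """
    n = len(matrix)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    merge = linkage(matrix, method="complete", metric="euclidean")
    return fcluster(merge, t=k, criterion="maxclust")


def silhouette_select_k(
    matrix: np.ndarray, k_range: Sequence[int] = range(2, 13)
) -> Tuple[int, dict]:
    """Best cluster number by mean silhouette width (Rousseeuw).

    Returns (best_k, {k: per-point silhouette values}).  Singleton clusters
    get silhouette 0 (the standard convention, matching sklearn).
    """
    n = len(matrix)
    k_range = [k for k in k_range]
    if not k_range or max(k_range) > n - 1:
        raise ValueError("require n > max(k_range)")
    sil = {}
    for k in k_range:
        labels = hierarchical_cluster(matrix, k)
        sil[k] = silhouette_samples(matrix, labels)
    best = max(k_range, key=lambda k: float(np.mean(sil[k])))
    return best, sil


# ---------------------------------------------------------------------------
# Hill dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseModel:
    """Hill model of fractional block: remaining current in percent."""

    imin: float   # residual current at saturating dose, %
    ic50: float   # dose producing half-maximal inhibition, uM
    nh: float     # Hill coefficient

    def __post_init__(self) -> None:
        if not 0 <= self.imin < 100:
            raise ValueError("Imin must be in [0, 100)")
        if self.ic50 <= 0 or self.nh <= 0:
            raise ValueError("IC50 and nH must be positive")


def hill_inhibition(
    conc: Union[float, np.ndarray], model: DoseResponseModel
) -> Union[float, np.ndarray]:
    """Remaining current (%) at the given concentration(s); 100 at zero dose,
    Imin at saturation, monotone decreasing in between."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / model.ic50) ** model.nh, 0.0)
    out = (100.0 - model.imin) / (1.0 + ratio) + model.imin
    return float(out) if out.ndim == 0 else out


def fit_hill(
    doses: Sequence[float], responses: Sequence[float]
) -> Tuple[DoseResponseModel, dict]:
    """Least-squares Hill fit of remaining current (%) vs dose (uM).

    Requires at least 4 dose points and responses spanning both sides of
    the midpoint between max and min response.  Initial guesses:
    Imin = min(response), IC50 = dose whose response is nearest the
    midpoint, nH = 1; bounds Imin in [0, 100), IC50 > 0, nH in (0, 10].
    Returns the model and diagnostics (residual SD, parameter SEs).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose points")
    span = responses.max() - responses.min()
    if span < 5.0:
        raise ValueError("no inhibition signal: responses span < 5 percentage points")
    mid = 0.5 * (responses.max() + responses.min())
    if not (np.any(responses > mid) and np.any(responses < mid)):
        raise ValueError("responses must span both sides of the midpoint")

    def f(c, imin, ic50, nh):
        return (100.0 - imin) / (1.0 + (np.maximum(c, 1e-12) / ic50) ** nh) + imin

    p0 = [
        max(float(responses.min()), 0.0),
        float(doses[np.argmin(np.abs(responses - mid))]),
        1.0,
    ]
    p0[1] = max(p0[1], 1e-6)
    try:
        popt, pcov = curve_fit(
            f,
            doses,
            responses,
            p0=p0,
            bounds=([0.0, 1e-9, 1e-3], [99.999, np.inf, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"Hill fit did not converge (initial guesses {p0})"
        ) from err
    model = DoseResponseModel(imin=float(popt[0]), ic50=float(popt[1]), nh=float(popt[2]))
    resid = responses - f(doses, *popt)
    dof = max(doses.size - 3, 1)
    diagnostics = {
        "residual_sd": float(np.sqrt(np.sum(resid**2) / dof)),
        "param_se": {
            name: float(se)
            for name, se in zip(("imin", "ic50", "nh"), np.sqrt(np.diag(pcov)))
        },
    }
    return model, diagnostics
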