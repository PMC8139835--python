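"""Synthetic inputs emulating the study's recordings.

Three generators cover every pipeline stage without external data:

* conductance pairs (GNap, GKdr) drawn from per-phenotype regions of the
  conductance plane that respect the observed zonation — single spiking
  only below GNap = 0.6 nS, repetitive spiking above it when GKdr exceeds
  3.5 nS, plateaus when GKdr is below 3.5 nS, mixed events in a narrow band
  at the RS/PP boundary;
* a 163-cell firing-feature table with five clusters at the reported
  centroids and sizes (46 SS, 69 RS, 35 PP, 4 ME-short, 9 ME-long),
  dispersions reconstructed from the reported SEMs (SD = SEM * sqrt(n));
* noisy Hill dose-response tables for the 4-AP block of IKdr.

All generators are deterministic given a seed.  The tables emulate the
summary statistics of the recorded population, not raw voltage traces:
within-cluster feature correlations and recording artefacts are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .population import DoseResponseModel, hill_inhibition

__all__ = [
    "ClusterSpec",
    "CohortSpec",
    "PAPER_COHORT",
    "sample_conductance_population",
    "generate_feature_table",
    "generate_dose_response",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster of the feature-table cohort.

    ``mean_half_ad`` (ms) and ``ddr`` are sampled log-normally (the
    clustering operates in log space), CV (%) normally truncated at 0.
    ``cv_zero`` forces CV = 0 exactly (pure SS cells fire at most 3 spikes,
    pure PP cells produce a single plateau).  SDs are linear-scale.
    """

    name: str
    n: int
    mean_half_ad: float
    sd_half_ad: float
    cv: float
    sd_cv: float
    ddr: float
    sd_ddr: float
    cv_zero: bool = False


@dataclass(frozen=True)
class CohortSpec:
    clusters: Tuple[ClusterSpec, ...]

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.clusters)


def _sd(sem: float, n: int) -> float:
    return sem * np.sqrt(n)


#: the recorded 163-cell cohort: centroids are reported means, dispersions
#: reconstructed from SEMs.  The two mixed-event clusters are separated by
#: their CV centroids; their 1/2Ad and ddr centroids were reported as not
#: significantly different between the two, so both are placed between the
#: RS and PP centroids (short-PP cells nearer RS, long-PP nearer PP) with
#: moderate dispersion.
PAPER_COHORT = CohortSpec(
    clusters=(
        ClusterSpec("SS", 46, 9.73, _sd(0.66, 46), 0.0, 0.0, 0.0051, _sd(0.0004, 46), cv_zero=True),
        ClusterSpec("RS", 69, 23.91, _sd(1.43, 69), 27.36, _sd(1.64, 69), 0.11, _sd(0.01, 69)),
        ClusterSpec("PP", 35, 833.5, _sd(89.99, 35), 0.0, 0.0, 0.441, _sd(0.044, 35), cv_zero=True),
        ClusterSpec("ME_short", 4, 80.0, 30.0, 170.9, _sd(8.9, 4), 0.25, 0.08),
        ClusterSpec("ME_long", 9, 250.0, 90.0, 87.61, _sd(7.37, 9), 0.35, 0.10),
    )
)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal samples with the given linear-scale mean and SD."""
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_feature_table(
    spec: CohortSpec = PAPER_COHORT, seed: int = 0
) -> pd.DataFrame:
    """Synthetic firing-feature table (one row per cell).

    Columns: cell_id, mean_half_ad_ms, cv_half_ad_pct, ddr, cluster.  The
    default spec reproduces the recorded cohort's cluster sizes and
    centroids; rows are deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cell = 0
    for c in spec.clusters:
        half_ad = _lognormal(rng, c.mean_half_ad, c.sd_half_ad, c.n)
        ddr = np.clip(_lognormal(rng, c.ddr, c.sd_ddr, c.n), 1e-6, 1.0)
        if c.cv_zero:
            cv = np.zeros(c.n)
        else:
            cv = np.abs(rng.normal(c.cv, c.sd_cv, c.n))
        for i in range(c.n):
            rows.append(
                {
                    "cell_id": f"cell_{cell:04d}",
                    "mean_half_ad_ms": float(half_ad[i]),
                    "cv_half_ad_pct": float(cv[i]),
                    "ddr": float(ddr[i]),
                    "cluster": c.name,
                }
            )
            cell += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conductance-plane populations
# ---------------------------------------------------------------------------

#: per-phenotype sampling boxes (gnap_lo, gnap_hi, gkdr_lo, gkdr_hi) in nS,
#: E12.5.  The boxes sit inside the phenotype regions of the activity map at
#: I = 20 pA: SS below the minimal GNap for repetitive firing, RS between
#: the fold-of-cycle lines, PP below the plateau boundary near 3.5 nS of
#: GKdr, ME hugging the RS/PP transition.
_E125_BOXES = {
    "SS": (0.10, 0.45, 6.0, 12.0),
    "RS": (0.85, 1.60, 7.0, 14.0),
    "PP": (0.90, 1.60, 1.5, 2.8),
    "ME": (1.10, 1.60, 3.5, 5.0),
}

#: mixture weights follow the cohort proportions (SS, RS, PP, ME)
_E125_WEIGHTS = {"SS": 46 / 163, "RS": 69 / 163, "PP": 35 / 163, "ME": 13 / 163}

#: at E14.5 GNap has decreased and GKdr increased; all sampled cells sit
#: well inside the quiescent/SS region
_E145_BOXES = {"SS": (0.05, 0.40, 8.0, 20.0)}
_E145_WEIGHTS = {"SS": 1.0}


def sample_conductance_population(
    n: int, seed: int = 0, age: str = "E12.5"
) -> pd.DataFrame:
    """(GNap, GKdr) pairs with their generating phenotype label.

    Pairs are sampled uniformly within per-phenotype boxes respecting the
    observed zonation of the conductance plane; the label is attached from
    the generating box (the boundary ME band excepted, simulation through
    the model recovers it).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    boxes = _E125_BOXES if age == "E12.5" else _E145_BOXES
    weights = _E125_WEIGHTS if age == "E12.5" else _E145_WEIGHTS
    rng = np.random.default_rng(seed)
    names = list(boxes)
    probs = np.array([weights[k] for k in names])
    probs = probs / probs.sum()
    rows = []
    for _ in range(n):
        name = names[rng.choice(len(names), p=probs)]
        g0, g1, k0, k1 = boxes[name]
        rows.append(
            {
                "gnap_ns": float(rng.uniform(g0, g1)),
                "gkdr_ns": float(rng.uniform(k0, k1)),
                "label": name,
            }
        )
    return pd.DataFrame(rows, columns=["gnap_ns", "gkdr_ns", "label"])


def generate_dose_response(
    model: DoseResponseModel = DoseResponseModel(imin=5.0, ic50=2.9, nh=1.0),
    doses: Optional[Sequence[float]] = None,
    replicates: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy remaining-current (%) measurements along a dose ladder.

    Default doses span 0.3-300 uM in half-decade steps.  Gaussian noise is
    added per replicate and values are clipped to [0, 110] (measured
    fractions can slightly exceed 100%).
    """
    if doses is None:
        doses = 0.3 * 10 ** (0.5 * np.arange(7))  # 0.3 ... 300 uM
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        truth = hill_inhibition(float(d), model)
        for r in range(replicates):
            val = truth + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "dose_um": float(d),
                    "replicate": r,
                    "remaining_pct": float(np.clip(val, 0.0, 110.0)),
                }
            )
    return pd.DataFrame(rows)
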