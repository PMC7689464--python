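"""MitoRatio: robust Mahalanobis distance to the mitochondrial centroid.

For each protein, in each condition, the squared Mahalanobis distance from
its concatenated replicate x fraction profile to the mean profile of the
mitochondrial marker proteins is computed, with a robust (Minimum
Covariance Determinant) estimate of the marker covariance.  The statistic

    log2 MitoRatio = log2(d2_control / d2_treatment)

is large for proteins that move closer to the mitochondria upon treatment
-- the signature of cargo in vesicles captured by a mitochondrially
re-anchored golgin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.covariance import MinCovDet

from vesicleshift.errors import (
    DimensionError,
    InsufficientMarkersError,
    VesicleShiftError,
)
from vesicleshift.profiles import MarkerMap, ProfileDataset, concatenate_replicates

logger = logging.getLogger(__name__)

_MAX_CONDITION = 1e8


@dataclass
class RobustCovariance:
    """Robust location and scatter of the mitochondrial marker profiles."""

    location: np.ndarray
    scatter: np.ndarray
    support_size: int

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if self.scatter.shape != (len(self.location),) * 2:
            raise DimensionError("scatter shape must match location dimension")
        self._chol = linalg.cholesky(self.scatter, lower=True, check_finite=False)


def _shrink_to_diagonal(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic shrinkage of the sample covariance toward its diagonal.

    Ledoit-Wolf-style intensity for the diagonal target: the ratio of the
    summed sampling variances of the off-diagonal covariances to their
    summed squares, clipped to [0, 1].
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    # w[k,i,j] = x_ki * x_kj (centred); var of s_ij estimated from these
    W = np.einsum("ki,kj->kij", Xc, Xc)
    var_S = n / (n - 1.0) ** 3 * np.sum((W - W.mean(axis=0)) ** 2, axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(S[off] ** 2)
    gamma = 1.0 if denom <= 0 else float(np.clip(var_S[off].sum() / denom, 0.0, 1.0))
    target = np.diag(np.diag(S))
    return gamma * target + (1.0 - gamma) * S, gamma


def _condition_number(S: np.ndarray) -> float:
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0:
        return np.inf
    return float(w.max() / w.min())


def robust_cov(
    marker_profiles: np.ndarray, random_state: int = 0
) -> RobustCovariance:
    """Robust location/scatter of mitochondrial marker profiles.

    Uses the Minimum Covariance Determinant estimator (default support
    ceil((n + p + 1) / 2), consistency-corrected) when markers outnumber
    dimensions comfortably.  When p >= n, or the scatter is ill-conditioned
    (condition number > 1e8), the sample covariance shrunk analytically
    toward its diagonal is used instead, with a final ridge if needed.
    """
    P = np.asarray(marker_profiles, dtype=float)
    if P.ndim != 2:
        raise DimensionError("marker profiles must be a 2-D matrix")
    n, p = P.shape
    if n < 5:
        raise InsufficientMarkersError(
            f"need >= 5 mitochondrial markers, got {n}"
        )
    # MCD needs both enough samples and a non-degenerate scatter; exactly
    # sum-constrained compositional profiles are rank-deficient and take
    # the shrinkage branch instead.
    sample_cov_ok = _condition_number(np.cov(P, rowvar=False)) <= _MAX_CONDITION
    if n > 2 * p and sample_cov_ok:
        mcd = MinCovDet(random_state=random_state).fit(P)
        loc, S = mcd.location_, mcd.covariance_
        support = int(mcd.support_.sum())
        if _condition_number(S) > _MAX_CONDITION:
            logger.info("MCD scatter ill-conditioned; shrinking toward diagonal")
            S, _ = _shrink_to_diagonal(P[mcd.support_])
    else:
        loc = P.mean(axis=0)
        S, gamma = _shrink_to_diagonal(P)
        support = n
        logger.info(
            "p=%d >= n=%d regime: diagonal shrinkage (intensity %.3f)", p, n, gamma
        )
    # final guarantee of positive-definiteness
    tries = 0
    while _condition_number(S) > _MAX_CONDITION and tries < 50:
        S = S + (np.trace(S) / p * 1e-8) * np.eye(p)
        tries += 1
    return RobustCovariance(location=loc, scatter=S, support_size=support)


def sq_mahalanobis(x: np.ndarray, rc: RobustCovariance) -> np.ndarray | float:
    """Squared Mahalanobis distance(s) (x - m)' S^-1 (x - m).

    Computed via the Cholesky factor of the scatter (no explicit inverse).
    Accepts a single vector or a matrix of row vectors.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(rc.location):
        raise DimensionError(
            f"profile dimension {X.shape[1]} != covariance dimension "
            f"{len(rc.location)}"
        )
    dev = X - rc.location
    sol = linalg.solve_triangular(rc._chol, dev.T, lower=True, check_finite=False)
    d2 = np.sum(sol**2, axis=0)
    return float(d2[0]) if single else d2


def mito_ratio(
    d2_control: float | np.ndarray,
    d2_treatment: float | np.ndarray,
    floor: float = 1e-8,
) -> float | np.ndarray:
    """log2 ratio of squared distances, floored for finiteness.

    ``log2(max(d2_control, floor) / max(d2_treatment, floor))``: positive
    when the protein sits nearer the mitochondrial centroid in treatment.
    """
    c = np.asarray(d2_control, dtype=float)
    t = np.asarray(d2_treatment, dtype=float)
    if np.any(c < 0) or np.any(t < 0):
        raise VesicleShiftError("squared distances must be non-negative")
    # difference of logs: exactly antisymmetric under condition swap
    out = np.log2(np.maximum(c, floor)) - np.log2(np.maximum(t, floor))
    return float(out) if out.ndim == 0 else out


@dataclass
class MitoRatioResult:
    """Per-protein distances and log2 MitoRatio for one comparison."""

    table: pd.DataFrame  # columns: d2_control, d2_treatment, log2_mitoratio
    cov_control: RobustCovariance
    cov_treatment: RobustCovariance


def mito_ratio_table(
    control: ProfileDataset,
    treatment: ProfileDataset,
    markers: MarkerMap,
    mito_class: str = "mitochondria",
    protein_ids: list[str] | None = None,
    floor: float = 1e-8,
    random_state: int = 0,
) -> MitoRatioResult:
    """MitoRatio for every protein of a normalised two-condition comparison.

    The mitochondrial centroid and robust covariance are estimated
    separately within each condition from that condition's mitochondrial
    marker profiles, so organelle-wide profile changes under treatment
    (e.g. mitochondrial swelling by vesicle capture) are absorbed.
    """
    mito_ids = [p for p in markers.members(mito_class) if p in set(control.protein_ids)]
    mito_ids = [p for p in mito_ids if p in set(treatment.protein_ids)]
    if len(mito_ids) < 5:
        raise InsufficientMarkersError(
            f"only {len(mito_ids)} '{mito_class}' markers present in both conditions"
        )
    rc_c = robust_cov(
        concatenate_replicates(control.subset(mito_ids)), random_state=random_state
    )
    rc_t = robust_cov(
        concatenate_replicates(treatment.subset(mito_ids)), random_state=random_state
    )
    if protein_ids is None:
        protein_ids = [p for p in control.protein_ids if p in set(treatment.protein_ids)]
    d2c = sq_mahalanobis(concatenate_replicates(control.subset(protein_ids)), rc_c)
    d2t = sq_mahalanobis(concatenate_replicates(treatment.subset(protein_ids)), rc_t)
    table = pd.DataFrame(
        {
            "d2_control": d2c,
            "d2_treatment": d2t,
            "log2_mitoratio": mito_ratio(d2c, d2t, floor=floor),
        },
        index=pd.Index(protein_ids, name="accession"),
    )
    return MitoRatioResult(table=table, cov_control=rc_c, cov_treatment=rc_t)
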