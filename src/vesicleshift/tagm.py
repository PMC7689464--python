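"""T-augmented Gaussian mixture model, MAP variant (TAGM-MAP).

Each organelle class is a Gaussian component over the concatenated
replicate x fraction profile; a single fixed heavy-tailed multivariate-T
component absorbs outliers (proteins in no annotated compartment, or
multi-localised).  Parameters carry conjugate priors -- Dirichlet on the
mixing weights, Normal-inverse-Wishart on each (mean, covariance), Beta on
the outlier weight -- and are fitted by EM to their joint posterior mode.
Marker proteins have fixed class membership; only their outlier indicator
is latent.

The fitted model yields per-protein posterior localisation probabilities;
the pipeline uses the maximum a posteriori class to discard proteins
predicted mitochondrial or nuclear before differential testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import gammaln
from scipy.stats import invwishart

from vesicleshift.errors import NumericalError, VesicleShiftError
from vesicleshift.profiles import MarkerMap

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TAGMPriors:
    """Hyperparameters of the conjugate priors.

    beta0: Dirichlet concentration per class.
    mu0, lambda0, nu0, S0: Normal-inverse-Wishart on each class (mean, cov).
    u, v: Beta prior on the outlier weight epsilon.
    kappa, t_location, t_scale: fixed multivariate-T outlier component.
    """

    beta0: np.ndarray
    mu0: np.ndarray
    lambda0: float
    nu0: float
    S0: np.ndarray
    u: float = 2.0
    v: float = 10.0
    kappa: float = 4.0
    t_location: np.ndarray = None  # type: ignore[assignment]
    t_scale: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = len(self.mu0)
        if self.lambda0 <= 0:
            raise VesicleShiftError("lambda0 must be positive")
        if self.nu0 <= d - 1:
            raise VesicleShiftError("nu0 must exceed dimension - 1")
        if self.kappa <= 0 or np.any(np.asarray(self.beta0) <= 0):
            raise VesicleShiftError("kappa and beta0 must be positive")


def default_priors(X: np.ndarray, markers_or_k: MarkerMap | int) -> TAGMPriors:
    """Data-derived default priors (the standard TAGM workflow defaults).

    mu0 = data mean; lambda0 = 0.01; nu0 = D + 2; S0 = diag(variances) /
    K^(2/D); beta0 = 1 per class; Beta(2, 10) on the outlier weight;
    outlier T with 4 degrees of freedom, located at the data mean with
    scale half the data covariance.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    K = (
        markers_or_k
        if isinstance(markers_or_k, int)
        else len(markers_or_k.classes)
    )
    mu0 = X.mean(axis=0)
    variances = X.var(axis=0, ddof=1)
    S0 = np.diag(variances) / K ** (2.0 / d)
    cov = np.cov(X, rowvar=False)
    # guard against singular data covariance for the fixed outlier component
    eig_floor = 1e-10 * max(np.trace(cov) / d, 1e-12)
    w = np.linalg.eigvalsh(cov)
    if w.min() < eig_floor:
        logger.warning("singular data covariance; ridge added to outlier scale")
        cov = cov + (eig_floor - min(w.min(), 0.0)) * np.eye(d)
    return TAGMPriors(
        beta0=np.ones(K),
        mu0=mu0,
        lambda0=0.01,
        nu0=d + 2.0,
        S0=S0,
        u=2.0,
        v=10.0,
        kappa=4.0,
        t_location=mu0.copy(),
        t_scale=cov / 2.0,
    )


@dataclass
class TAGMFit:
    """MAP parameter estimates of the augmented mixture."""

    class_labels: tuple[str, ...]
    means: np.ndarray  # K x D
    covariances: np.ndarray  # K x D x D
    weights: np.ndarray  # K mixing weights, sum 1
    epsilon: float  # outlier weight
    priors: TAGMPriors
    converged: bool
    log_posterior_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class TAGMPosterior:
    """Per-protein posterior localisation probabilities."""

    protein_ids: list[str]
    class_labels: tuple[str, ...]
    probabilities: np.ndarray  # n x K, P(class k and not outlier | x)
    outlier_probability: np.ndarray  # n
    map_class: np.ndarray  # n, argmax over classes

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.probabilities,
            index=pd.Index(self.protein_ids, name="accession"),
            columns=[f"p_{c}" for c in self.class_labels],
        )
        df.insert(0, "map_class", self.map_class)
        df["p_outlier"] = self.outlier_probability
        return df


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = len(mean)
    try:
        L = linalg.cholesky(cov, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not positive-definite: {exc}") from exc
    dev = X - mean
    sol = linalg.solve_triangular(L, dev.T, lower=True, check_finite=False)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG2PI + logdet + maha)


def _t_logpdf(X: np.ndarray, loc: np.ndarray, scale: np.ndarray, df: float) -> np.ndarray:
    d = len(loc)
    L = linalg.cholesky(scale, lower=True, check_finite=False)
    dev = X - loc
    sol = linalg.solve_triangular(L, dev.T, lower=True, check_finite=False)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return (
        gammaln((df + d) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * (d * np.log(df * np.pi) + logdet)
        - 0.5 * (df + d) * np.log1p(maha / df)
    )


def _ridge(cov: np.ndarray) -> np.ndarray:
    """Regularise a covariance update: ridge 1e-6 * trace / D on the diagonal."""
    d = cov.shape[0]
    return cov + (1e-6 * np.trace(cov) / d) * np.eye(d)


def fit_tagm_map(
    X: np.ndarray,
    marker_labels: np.ndarray,
    priors: TAGMPriors | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    fix_epsilon: float | None = None,
    class_labels: tuple[str, ...] | None = None,
) -> TAGMFit:
    """Fit the augmented mixture by EM to the joint posterior mode.

    Parameters
    ----------
    X : (n, D) feature matrix (markers and unknowns).
    marker_labels : length-n object array; class label for markers, None
        (or empty string) for unknown proteins.
    fix_epsilon : if given, the outlier weight is held at this value
        (0 disables the outlier component entirely).

    The log posterior is non-decreasing over iterations (up to the small
    ridge regularisation applied to covariance updates); a decrease beyond
    numerical tolerance raises :class:`NumericalError`.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    marker_labels = np.asarray(marker_labels, dtype=object)
    is_marker = np.array([bool(lab) for lab in marker_labels])
    if class_labels is None:
        class_labels = tuple(sorted({lab for lab in marker_labels if lab}))
    K = len(class_labels)
    label_index = {lab: k for k, lab in enumerate(class_labels)}
    if priors is None:
        priors = default_priors(X, K)
    for lab in class_labels:
        if np.sum(marker_labels == lab) < 2:
            raise VesicleShiftError(f"class '{lab}' has fewer than 2 markers")

    # fixed outlier log-density, computed once
    log_t = _t_logpdf(X, priors.t_location, priors.t_scale, priors.kappa)

    # deterministic initialisation: conjugate posterior mode of each class's
    # marker profiles (keeps class covariances at within-class scale while
    # remaining positive-definite when markers are fewer than dimensions)
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    for lab, k in label_index.items():
        Xk = X[marker_labels == lab]
        nk = len(Xk)
        xbar = Xk.mean(axis=0)
        means[k] = (priors.lambda0 * priors.mu0 + nk * xbar) / (
            priors.lambda0 + nk
        )
        dev = Xk - xbar
        dev0 = (xbar - priors.mu0)[:, None]
        shrink = (priors.lambda0 * nk / (priors.lambda0 + nk)) * (dev0 @ dev0.T)
        covs[k] = _ridge(
            (priors.S0 + dev.T @ dev + shrink) / (priors.nu0 + nk + d + 2.0)
        )
    weights = np.full(K, 1.0 / K)
    eps = 0.01 if fix_epsilon is None else float(fix_epsilon)

    beta0 = np.asarray(priors.beta0, dtype=float)
    if len(beta0) != K:
        beta0 = np.full(K, beta0.flat[0])

    marker_k = np.array(
        [label_index[lab] if lab else -1 for lab in marker_labels], dtype=int
    )

    def log_posterior(log_gauss: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            log_eps = np.log(eps) if eps > 0 else -np.inf
            log_1meps = np.log1p(-eps) if eps < 1 else -np.inf
        # per-protein mixture density
        comp = np.logaddexp(log_1meps + log_gauss, log_eps + log_t[:, None])
        lp = 0.0
        unk = ~is_marker
        if unk.any():
            full = comp[unk] + np.log(weights)[None, :]
            lp += np.logaddexp.reduce(full, axis=1).sum()
        if is_marker.any():
            mk = marker_k[is_marker]
            lp += np.sum(comp[is_marker, mk] + np.log(weights)[mk])
        # priors
        lp += np.sum((beta0 - 1.0) * np.log(weights))
        if fix_epsilon is None:
            lp += (priors.u - 1.0) * np.log(max(eps, 1e-300)) + (
                priors.v - 1.0
            ) * np.log(max(1.0 - eps, 1e-300))
        for k in range(K):
            lp += invwishart.logpdf(covs[k], df=priors.nu0, scale=priors.S0)
            lp += _gauss_logpdf(
                means[k][None, :], priors.mu0, covs[k] / priors.lambda0
            )[0]
        return float(lp)

    trace = []
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        # E-step
        log_gauss = np.column_stack(
            [_gauss_logpdf(X, means[k], covs[k]) for k in range(K)]
        )
        with np.errstate(divide="ignore"):
            log_eps = np.log(eps) if eps > 0 else -np.inf
            log_1meps = np.log1p(-eps) if eps < 1 else -np.inf
        logw = np.log(weights)

        # unknowns: joint responsibilities over (class, in/out)
        log_a = logw[None, :] + log_1meps + log_gauss  # n x K
        log_b = logw[None, :] + log_eps + log_t[:, None]  # n x K
        stacked = np.concatenate([log_a, log_b], axis=1)
        norm = np.logaddexp.reduce(stacked, axis=1)
        a = np.exp(log_a - norm[:, None])
        b = np.exp(log_b - norm[:, None])
        # markers: class fixed, only outlier indicator latent
        if is_marker.any():
            idx = np.nonzero(is_marker)[0]
            mk = marker_k[idx]
            la = log_1meps + log_gauss[idx, mk]
            lb = log_eps + log_t[idx]
            nrm = np.logaddexp(la, lb)
            a[idx] = 0.0
            b[idx] = 0.0
            a[idx, mk] = np.exp(la - nrm)
            b[idx, mk] = np.exp(lb - nrm)

        lp = log_posterior(log_gauss)
        if not np.isfinite(lp):
            raise NumericalError(f"non-finite log posterior at iteration {it}")
        if lp < prev - 1e-6 * (1.0 + abs(prev)):
            raise NumericalError(
                f"EM log posterior decreased at iteration {it}: {prev} -> {lp}"
            )
        trace.append(lp)
        if prev > -np.inf and abs(lp - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = lp

        # M-step
        r = a + b  # class responsibility regardless of outlier status
        nk_class = r.sum(axis=0)
        weights = (nk_class + beta0 - 1.0) / (n + beta0.sum() - K)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        if fix_epsilon is None:
            eps = (b.sum() + priors.u - 1.0) / (n + priors.u + priors.v - 2.0)
            eps = float(np.clip(eps, 1e-12, 1.0 - 1e-12))
        nk = a.sum(axis=0)  # in-component weight
        for k in range(K):
            if nk[k] < 1e-10:
                continue
            xbar = (a[:, k] @ X) / nk[k]
            means[k] = (priors.lambda0 * priors.mu0 + nk[k] * xbar) / (
                priors.lambda0 + nk[k]
            )
            dev = X - xbar
            Sk = (a[:, k][:, None] * dev).T @ dev
            dev0 = (xbar - priors.mu0)[:, None]
            shrink = (priors.lambda0 * nk[k] / (priors.lambda0 + nk[k])) * (
                dev0 @ dev0.T
            )
            covs[k] = _ridge(
                (priors.S0 + Sk + shrink) / (priors.nu0 + nk[k] + d + 2.0)
            )

    if not converged:
        warnings.warn("TAGM EM reached max_iter without converging", stacklevel=2)
    return TAGMFit(
        class_labels=class_labels,
        means=means,
        covariances=covs,
        weights=weights,
        epsilon=eps,
        priors=priors,
        converged=converged,
        log_posterior_trace=np.asarray(trace),
    )


def posterior_localisation(
    fit: TAGMFit, X: np.ndarray, protein_ids: list[str] | None = None
) -> TAGMPosterior:
    """Posterior localisation probabilities under a fitted model.

    For each protein, ``probabilities[:, k]`` is the posterior probability
    of residing in organelle k (and not being an outlier); these plus the
    outlier probability sum to one.  The MAP class is the argmax over the
    organelle probabilities.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if protein_ids is None:
        protein_ids = [str(i) for i in range(n)]
    K = len(fit.class_labels)
    pr = fit.priors
    log_t = _t_logpdf(X, pr.t_location, pr.t_scale, pr.kappa)
    log_gauss = np.column_stack(
        [_gauss_logpdf(X, fit.means[k], fit.covariances[k]) for k in range(K)]
    )
    eps = fit.epsilon
    with np.errstate(divide="ignore"):
        log_eps = np.log(eps) if eps > 0 else -np.inf
        log_1meps = np.log1p(-eps) if eps < 1 else -np.inf
    logw = np.log(fit.weights)
    log_a = logw[None, :] + log_1meps + log_gauss
    log_b = logw[None, :] + log_eps + log_t[:, None]
    stacked = np.concatenate([log_a, log_b], axis=1)
    norm = np.logaddexp.reduce(stacked, axis=1)
    a = np.exp(log_a - norm[:, None])
    b = np.exp(log_b - norm[:, None]).sum(axis=1)
    map_class = np.asarray(fit.class_labels, dtype=object)[np.argmax(a, axis=1)]
    return TAGMPosterior(
        protein_ids=list(protein_ids),
        class_labels=fit.class_labels,
        probabilities=a,
        outlier_probability=b,
        map_class=map_class,
    )


def match_discard_classes(
    classes: tuple[str, ...],
    patterns: tuple[str, ...] = ("mito", "nucle", "chromatin"),
) -> set[str]:
    """Classes whose label matches any discard pattern (case-insensitive)."""
    return {
        c for c in classes if any(p.lower() in c.lower() for p in patterns)
    }


def prefilter_discard(
    post: TAGMPosterior,
    discard_classes: set[str] | tuple[str, ...],
    markers: MarkerMap | None = None,
) -> list[str]:
    """Retain proteins whose MAP class is not in ``discard_classes``.

    Computed on the control condition: proteins already resident in the
    compartments to be discarded (typically mitochondria and nucleus) are
    removed before differential testing so that movement *toward* those
    compartments remains detectable.  Marker proteins of non-discarded
    classes are always retained under their curated label.
    """
    discard = set(discard_classes)
    unknown = discard - set(post.class_labels)
    if unknown:
        raise VesicleShiftError(f"unknown discard classes: {sorted(unknown)}")
    retained = []
    for pid, cls in zip(post.protein_ids, post.map_class):
        if markers is not None and pid in markers:
            if markers.class_of(pid) not in discard:
                retained.append(pid)
            continue
        if cls not in discard:
            retained.append(pid)
    return retained
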