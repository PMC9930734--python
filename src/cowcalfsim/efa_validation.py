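"""Exploratory factor analysis for comparing simulated and field herd data.

The validation pipeline pools simulated output with an external dataset,
standardizes the combined table, and applies classical EFA: parallel
analysis for the number of factors, iterated principal-axis factoring
(PAF) on the reduced correlation matrix, oblique oblimin rotation (gradient
projection, gamma = 0), regression-method (Thurstone) factor scores, and
two-SD normal data ellipses per data source for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FactorModel:
    """An extracted (and optionally rotated) factor solution."""

    loadings: np.ndarray  # variables x factors (pattern matrix)
    communalities: np.ndarray  # per variable, in [0, 1]
    factor_correlations: np.ndarray  # oblique Phi (identity when unrotated)
    variance_explained: np.ndarray  # per factor, proportion of total variance
    converged: bool = True
    heywood: bool = False
    variables: list = field(default_factory=list)

    @property
    def structure(self) -> np.ndarray:
        """Structure matrix: pattern loadings times factor correlations."""
        return self.loadings @ self.factor_correlations

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())


def _correlation(data: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(data, rowvar=False)
    return np.atleast_2d(corr)


def parallel_analysis(
    data,
    n_reps: int = 50,
    rng: np.random.Generator | None = None,
) -> int:
    """Number of factors whose real-data eigenvalues exceed the mean
    eigenvalues of same-shape random normal data."""
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if p < 3 or n < 50:
        raise ValueError("parallel analysis needs >= 3 variables and >= 50 records")
    corr = _correlation(x)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    real = np.sort(np.linalg.eigvalsh(corr))[::-1]
    rng = rng or np.random.default_rng()
    rand = np.zeros(p)
    for _ in range(n_reps):
        sim = rng.normal(size=(n, p))
        rand += np.sort(np.linalg.eigvalsh(_correlation(sim)))[::-1]
    rand /= n_reps
    # retain leading factors until the first one that fails to beat noise
    exceed = real > rand
    k = 0
    for flag in exceed:
        if not flag:
            break
        k += 1
    return k


def paf_extract(
    corr_matrix,
    n_factors: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    variables: list | None = None,
) -> FactorModel:
    """Iterated principal-axis factoring on the reduced correlation matrix.

    Communalities start at squared multiple correlations and are iterated
    until stable; eigenvalues are floored at zero.  Heywood cases
    (communalities exceeding one) are clamped and flagged.
    """
    r = np.asarray(corr_matrix, dtype=float)
    p = r.shape[0]
    if n_factors < 1 or n_factors > p:
        raise ValueError("n_factors out of range")
    try:
        inv_diag = np.diag(np.linalg.inv(r))
        h2 = 1.0 - 1.0 / inv_diag  # squared multiple correlations
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    heywood = False
    converged = False
    loadings = np.zeros((p, n_factors))
    for _ in range(max_iter):
        reduced = r.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.sqrt(np.maximum(vals[order], 0.0))
        loadings = vecs[:, order] * lam
        new_h2 = np.sum(loadings**2, axis=1)
        if np.any(new_h2 > 1.0):
            heywood = True
            new_h2 = np.minimum(new_h2, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            converged = True
            break
        h2 = new_h2
    # orient each factor so its largest loading is positive
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    return FactorModel(
        loadings=loadings,
        communalities=h2,
        factor_correlations=np.eye(n_factors),
        variance_explained=np.sum(loadings**2, axis=0) / p,
        converged=converged,
        heywood=heywood,
        variables=list(variables) if variables is not None else [],
    )


def _oblimin_criterion(loadings: np.ndarray, gamma: float):
    p, k = loadings.shape
    l2 = loadings**2
    n_mat = np.ones((k, k)) - np.eye(k)
    x = l2 @ n_mat
    if gamma != 0.0:
        x = (np.eye(p) - gamma * np.ones((p, p)) / p) @ x
    return float(np.sum(l2 * x) / 4.0), loadings * x


def oblimin_rotate(
    model: FactorModel,
    gamma: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FactorModel:
    """Oblique oblimin rotation by gradient projection.

    Communalities are invariant under the rotation; the returned model
    carries the oblique factor-correlation matrix Phi.
    """
    a = model.loadings
    p, k = a.shape
    if k == 1:
        return model
    t = np.eye(k)
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = _oblimin_criterion(lam, gamma)
    g = -(lam.T @ gq @ ti).T
    al = 1.0
    for _ in range(max_iter):
        gp = g - t @ np.diag(np.sum(t * g, axis=0))
        s = np.sqrt(np.sum(gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            v = 1.0 / np.sqrt(np.sum(x**2, axis=0))
            tt = x * v
            ti = np.linalg.inv(tt)
            lam = a @ ti.T
            ft, gq = _oblimin_criterion(lam, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        t = tt
        f = ft
        g = -(lam.T @ gq @ ti).T
    phi = t.T @ t
    structure = lam @ phi
    return FactorModel(
        loadings=lam,
        communalities=model.communalities,
        factor_correlations=phi,
        variance_explained=np.sum(lam * structure, axis=0) / p,
        converged=model.converged,
        heywood=model.heywood,
        variables=model.variables,
    )


def thurstone_scores(model: FactorModel, standardized_data) -> np.ndarray:
    """Regression-method factor scores: Z R^{-1} S with S the structure
    matrix; score means are ~0 for centered data."""
    z = np.asarray(standardized_data, dtype=float)
    r = _correlation(z)
    weights = np.linalg.solve(r, model.structure)
    return z @ weights


def two_sd_ellipse(scores, group_labels) -> dict:
    """Per-group bivariate normal data-ellipse parameters at two SDs.

    Returns ``{group: (center, axis_lengths, angle_rad)}`` where the axis
    lengths are full widths of the 2-SD ellipse along its principal axes.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(group_labels)
    out = {}
    for grp in np.unique(labels):
        pts = scores[labels == grp]
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        angle = float(np.arctan2(vecs[1, -1], vecs[0, -1]))
        out[grp] = (center, 2.0 * 2.0 * np.sqrt(np.maximum(vals[::-1], 0.0)), angle)
    return out


def run_efa(
    frame: pd.DataFrame,
    n_factors: int | None = None,
    gamma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[FactorModel, np.ndarray]:
    """Full pipeline on a numeric table: standardize, choose the factor
    count by parallel analysis when not given, extract by PAF, rotate by
    oblimin, and return (model, Thurstone scores)."""
    x = frame.to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    if n_factors is None:
        n_factors = max(parallel_analysis(z, rng=rng), 1)
    model = paf_extract(_correlation(z), n_factors, variables=list(frame.columns))
    model = oblimin_rotate(model, gamma=gamma)
    scores = thurstone_scores(model, z)
    return model, scores
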