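"""Animal-model mixed-model equations, variance components, and accuracy.

The same machinery serves both evaluations: pedigree BLUP supplies
``A_inverse`` as the relationship kernel, single-step genomic BLUP supplies
``H_inverse``.  Residuals are homogeneous (``R = I * sigma_e2``), so the
coefficient matrix is assembled on the variance-ratio scale::

    [[X'X, X'Z], [Z'X, Z'Z + alpha * K]],   alpha = sigma_e2 / sigma_a2

Prediction error variances come from the animal-block diagonal of the dense
inverse of that matrix times ``sigma_e2``; the default accuracy follows the
reliability-form formula ``1 - PEV / sigma_a2`` (a square-root mode is also
provided).  Variance components are estimated by EM-REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ModelError
from .relmatrix import RelationshipMatrix

DEFAULT_FIXED_EFFECTS = (
    ("birth_year", "class"),
    ("birth_month", "class"),
    ("slaughter_place", "class"),
    ("slaughter_age_months", "covariate"),
)


@dataclass
class ModelSpec:
    """Single-trait animal-model specification."""

    trait: str
    fixed_effects: tuple[tuple[str, str], ...] = DEFAULT_FIXED_EFFECTS
    sigma_a2: float | None = None
    sigma_e2: float | None = None

    @property
    def alpha(self) -> float:
        if not self.sigma_a2 or self.sigma_a2 <= 0 or self.sigma_e2 is None or self.sigma_e2 < 0:
            raise ModelError("variance components must be set and positive to form alpha")
        return self.sigma_e2 / self.sigma_a2


@dataclass
class VarianceEstimate:
    """EM-REML result."""

    sigma_a2: float
    sigma_e2: float
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class EvaluationResult:
    """Per-animal breeding values with their error variances and accuracies."""

    table: pd.DataFrame  # columns: animal, breeding_value, pev, accuracy
    fixed_effects: pd.Series
    sigma_a2: float
    sigma_e2: float
    accuracy_mode: str

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2


# ---------------------------------------------------------------------------
# phenotype filters
# ---------------------------------------------------------------------------


def apply_phenotype_filters(
    phenotypes: pd.DataFrame,
    age_range: tuple[float, float] = (26, 36),
    trait_bounds: dict[str, tuple[float, float]] | None = None,
    age_col: str = "slaughter_age_months",
) -> tuple[pd.DataFrame, dict]:
    """Drop records outside the slaughter-age window or trait bounds.

    The age window is inclusive: records with age < lower or age > upper are
    removed (age exactly at either bound is retained).
    """
    if age_col not in phenotypes.columns:
        raise ModelError(f"phenotype table lacks the {age_col!r} column")
    lo, hi = age_range
    age = pd.to_numeric(phenotypes[age_col], errors="coerce")
    bad_age = (age < lo) | (age > hi)
    bad_trait = pd.Series(False, index=phenotypes.index)
    per_trait: dict[str, int] = {}
    for trait, (tlo, thi) in (trait_bounds or {}).items():
        vals = pd.to_numeric(phenotypes[trait], errors="coerce")
        bad = vals.notna() & ((vals < tlo) | (vals > thi))
        per_trait[trait] = int(bad.sum())
        bad_trait |= bad
    keep = ~(bad_age | bad_trait)
    report = {
        "n_in": int(len(phenotypes)),
        "n_removed_age": int(bad_age.sum()),
        "n_removed_trait": per_trait,
        "n_out": int(keep.sum()),
        "age_range": list(age_range),
    }
    out = phenotypes.loc[keep].copy()
    if out.empty:
        warnings.warn("phenotype filters removed every record")
    return out, report


# ---------------------------------------------------------------------------
# design and MME assembly
# ---------------------------------------------------------------------------


def build_design(
    phenotypes: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector and full-rank fixed-effect design matrix.

    Class effects expand to dummy columns with the first (sorted) level
    constrained to zero (corner-point parameterisation); covariates enter
    as single columns.  An intercept column is always included.
    """
    if spec.trait not in phenotypes.columns:
        raise ModelError(f"trait {spec.trait!r} missing from phenotype table")
    y = pd.to_numeric(phenotypes[spec.trait], errors="coerce").to_numpy(float)
    if np.isnan(y).any():
        raise ModelError(f"missing {spec.trait!r} values among phenotyped records")
    cols = [np.ones(len(phenotypes))]
    names = ["(intercept)"]
    for name, kind in spec.fixed_effects:
        if name not in phenotypes.columns:
            raise ModelError(f"fixed effect {name!r} missing from phenotype table")
        col = phenotypes[name]
        if col.isna().any():
            raise ModelError(f"fixed effect {name!r} has missing values")
        if kind == "class":
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first level -> corner point
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{name}={lev}")
        elif kind == "covariate":
            cols.append(pd.to_numeric(col, errors="coerce").to_numpy(float))
            names.append(name)
        else:
            raise ModelError(f"unknown fixed-effect kind {kind!r} for {name!r}")
    X = np.column_stack(cols)
    return y, X, names


@dataclass
class MMESystem:
    """Assembled mixed-model equations (alpha-scaled, residual absorbed)."""

    lhs: np.ndarray
    rhs: np.ndarray
    effect_names: list[str]
    animal_ids: tuple[str, ...]
    n_fixed: int
    x_rank_deficient: bool = False


def build_mme(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    kinv: RelationshipMatrix,
) -> MMESystem:
    """Assemble ``[[X'X, X'Z], [Z'X, Z'Z + alpha K]]`` and its right-hand side.

    Animals without phenotype contribute no rows to Z but keep equations
    through ``alpha K``, so they receive predictions.  Phenotyped animals
    must all appear among ``kinv.ids``.
    """
    if kinv.kind not in ("A_inverse", "H_inverse"):
        raise ModelError(f"relationship kernel must be an inverse kind, got {kinv.kind!r}")
    ids = kinv.ids
    lookup = {lab: i for i, lab in enumerate(ids)}
    animals = phenotypes["animal"].astype(str)
    missing = sorted(set(animals) - set(ids))
    if missing:
        raise ModelError(f"phenotyped animals absent from relationship matrix: {missing[:5]}")
    y, X, names = build_design(phenotypes, spec)
    n_obs, p = X.shape
    q = len(ids)
    rank = int(np.linalg.matrix_rank(X))
    deficient = rank < p
    if deficient:
        warnings.warn(
            "fixed-effect design is rank deficient beyond the corner-point "
            "constraint; solving with a generalized inverse"
        )
    rows = np.arange(n_obs)
    cols = np.array([lookup[a] for a in animals])
    Z = sparse.csr_matrix((np.ones(n_obs), (rows, cols)), shape=(n_obs, q))
    Zd = np.asarray(Z.todense())
    alpha = spec.alpha
    K = kinv.to_dense()
    lhs = np.zeros((p + q, p + q))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Zd
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = Zd.T @ Zd + alpha * K
    rhs = np.concatenate([X.T @ y, Zd.T @ y])
    return MMESystem(
        lhs=lhs,
        rhs=rhs,
        effect_names=names,
        animal_ids=ids,
        n_fixed=p,
        x_rank_deficient=deficient,
    )


@dataclass
class MMESolution:
    fixed: pd.Series
    random: pd.Series


def solve_mme(mme: MMESystem) -> MMESolution:
    """Solve the assembled equations by direct dense factorisation."""
    try:
        if mme.x_rank_deficient:
            sol = np.linalg.lstsq(mme.lhs, mme.rhs, rcond=None)[0]
        else:
            sol = np.linalg.solve(mme.lhs, mme.rhs)
    except np.linalg.LinAlgError as exc:
        raise ModelError("mixed-model equations are singular") from exc
    p = mme.n_fixed
    return MMESolution(
        fixed=pd.Series(sol[:p], index=mme.effect_names),
        random=pd.Series(sol[p:], index=list(mme.animal_ids)),
    )


def compute_pev(mme: MMESystem, sigma_e2: float) -> np.ndarray:
    """Prediction error variance per animal.

    ``PEV_i = C^uu_ii * sigma_e2`` with ``C^uu_ii`` the animal-block diagonal
    of the inverse coefficient matrix (explicit dense inverse; desk scale).
    """
    try:
        cinv = np.linalg.inv(mme.lhs)
    except np.linalg.LinAlgError:
        cinv = np.linalg.pinv(mme.lhs)
    p = mme.n_fixed
    return np.diag(cinv)[p:] * sigma_e2


def compute_accuracy(
    pev: np.ndarray, sigma_a2: float, mode: str = "paper"
) -> np.ndarray:
    """Accuracy from PEV.

    ``mode="paper"`` applies the reliability-form formula
    ``Acc = 1 - PEV / sigma_a2`` as printed in the analysis being
    reproduced; ``mode="sqrt"`` takes its square root (the conventional
    accuracy).  Values are clamped to [0, 1] with a warning on numerical
    overshoot.
    """
    if sigma_a2 <= 0:
        raise ModelError("sigma_a2 must be positive for accuracy")
    rel = 1.0 - np.asarray(pev, float) / sigma_a2
    if (rel < -1e-8).any():
        warnings.warn("PEV exceeded sigma_a2 for some animals; accuracy clamped to 0")
    rel = np.clip(rel, 0.0, 1.0)
    if mode == "paper":
        return rel
    if mode == "sqrt":
        return np.sqrt(rel)
    raise ModelError(f"unknown accuracy mode {mode!r}")


def compute_heritability(sigma_a2: float, sigma_e2: float) -> tuple[float, float]:
    """``h2 = sigma_a2 / sigma_p2`` with ``sigma_p2 = sigma_a2 + sigma_e2``."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ModelError("variance components must be non-negative")
    sigma_p2 = sigma_a2 + sigma_e2
    if sigma_p2 == 0:
        raise ModelError("phenotypic variance is zero; heritability undefined")
    return sigma_a2 / sigma_p2, sigma_p2


def evaluate(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    kinv: RelationshipMatrix,
    accuracy_mode: str = "paper",
) -> EvaluationResult:
    """Full evaluation: assemble, solve, PEV, accuracy."""
    mme = build_mme(spec, phenotypes, kinv)
    sol = solve_mme(mme)
    pev = compute_pev(mme, spec.sigma_e2)
    acc = compute_accuracy(pev, spec.sigma_a2, mode=accuracy_mode)
    table = pd.DataFrame(
        {
            "animal": list(mme.animal_ids),
            "breeding_value": sol.random.to_numpy(),
            "pev": pev,
            "accuracy": acc,
        }
    )
    return EvaluationResult(
        table=table,
        fixed_effects=sol.fixed,
        sigma_a2=spec.sigma_a2,
        sigma_e2=spec.sigma_e2,
        accuracy_mode=accuracy_mode,
    )


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------


def _reml_loglik_rotated(
    yr: np.ndarray, Xr: np.ndarray, d: np.ndarray, sa2: float, se2: float
) -> float:
    """Restricted log-likelihood (up to a constant) in the rotated basis."""
    v = d * sa2 + se2
    vinv = 1.0 / v
    XtVi = Xr.T * vinv
    M = XtVi @ Xr
    beta = np.linalg.solve(M, XtVi @ yr)
    r = yr - Xr @ beta
    quad = float(r @ (vinv * r))
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return -0.5 * (float(np.sum(np.log(v))) + logdet_m + quad)


def relationship_covariance(
    kinv: RelationshipMatrix, ids: Sequence[str]
) -> np.ndarray:
    """Covariance block (on the sigma_a2 = 1 scale) among ``ids``.

    Inverts the relationship kernel and extracts the principal submatrix for
    the requested animals — the marginal relationship of those animals, which
    is all REML needs.
    """
    idx = kinv.index_of(ids)
    full = np.linalg.inv(kinv.to_dense())
    sub = full[np.ix_(idx, idx)]
    return (sub + sub.T) / 2.0


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    covariance: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    start: tuple[float, float] | None = None,
) -> VarianceEstimate:
    """EM-REML for the single-random-effect animal model.

    Parameters
    ----------
    y, X
        Response and full-rank fixed-effect design for the phenotyped
        records.
    covariance
        Relationship covariance among those records (``sigma_a2 = 1``
        scale), e.g. the phenotyped block of A or of H.
    tol
        Relative-change convergence threshold on both components.

    Notes
    -----
    The model is rotated to the eigenbasis of the covariance so each EM
    iteration is O(n p^2); the iteration is the standard EM fixed point

    ``sigma_a2 <- (u' K u + sigma_e2 tr(K C^uu)) / q`` and
    ``sigma_e2 <- y'(y - X b - Z u) / (n - rank X)``

    written for the rotated equations, so the restricted likelihood is
    non-decreasing across iterations.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = y.size
    p = X.shape[1]
    if n < 2:
        raise ModelError("EM-REML needs at least two phenotyped records")
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("fixed-effect design must be full rank for EM-REML")
    d, U = np.linalg.eigh(np.asarray(covariance, float))
    if d.min() <= 1e-10:
        raise ModelError(
            "relationship covariance is singular among phenotyped records "
            "(duplicate or clone animals?)"
        )
    yr = U.T @ y
    Xr = U.T @ X
    vy = float(np.var(y))
    if vy <= 0:
        raise ModelError("response has zero variance; components not identifiable")
    sa2, se2 = start if start is not None else (0.5 * vy, 0.5 * vy)
    yty = float(yr @ yr)
    Xty = Xr.T @ yr
    loglik_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        alpha = se2 / sa2
        w = 1.0 + alpha / d  # diagonal of the rotated animal block
        winv = 1.0 / w
        t = 1.0 - winv
        S = (Xr.T * t) @ Xr  # absorbed fixed-effect equations
        beta = np.linalg.solve(S, Xr.T @ (t * yr))
        resid_fixed = yr - Xr @ beta
        u = winv * resid_fixed
        # tr(D^-1 C^uu) for C^uu = W^-1 + W^-1 Xr S^-1 Xr' W^-1
        Sinv_Xt = np.linalg.solve(S, Xr.T)  # p x n
        quad_rows = np.einsum("ij,ji->i", Xr, Sinv_Xt)
        tr_term = float(np.sum(winv / d) + np.sum(quad_rows * winv**2 / d))
        u_quad = float(np.sum(u * u / d))
        sa2_new = (u_quad + se2 * tr_term) / n
        se2_new = (yty - float(beta @ Xty) - float(u @ yr)) / (n - p)
        loglik_path.append(_reml_loglik_rotated(yr, Xr, d, sa2, se2))
        if min(sa2_new, se2_new) < 1e-12 * (sa2_new + se2_new):
            raise ModelError(
                "a variance component collapsed toward zero; the model is "
                "not identifiable on these data"
            )
        rel_change = max(
            abs(sa2_new - sa2) / max(sa2, 1e-300),
            abs(se2_new - se2) / max(se2, 1e-300),
        )
        sa2, se2 = sa2_new, se2_new
        if rel_change < tol:
            converged = True
            break
    loglik_path.append(_reml_loglik_rotated(yr, Xr, d, sa2, se2))
    return VarianceEstimate(
        sigma_a2=sa2, sigma_e2=se2, n_iter=it, converged=converged, loglik_path=loglik_path
    )


def reml_components(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    kinv: RelationshipMatrix,
    covariance: np.ndarray | None = None,
    **kwargs,
) -> VarianceEstimate:
    """Estimate variance components for a model spec by EM-REML.

    ``covariance`` may be passed directly (phenotyped-animal block of the
    relationship matrix) to skip the kernel inversion.
    """
    y, X, _ = build_design(phenotypes, spec)
    if covariance is None:
        covariance = relationship_covariance(kinv, phenotypes["animal"].astype(str))
    return em_reml(y, X, covariance, **kwargs)
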