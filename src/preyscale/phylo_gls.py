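"""Phylogenetic GLS with Pagel's lambda: covariance construction,
profile-likelihood lambda estimation, AICc.

Conventions
-----------
* ML (not REML) likelihood throughout; sigma^2 is profiled out
  analytically, lambda is maximized over [0, 1] by bounded scalar
  optimization seeded by an 11-point grid.  Boundary values 0 and 1 are
  admissible.
* Parameter count ``k`` = number of design columns + 1 (sigma^2) + 1
  (lambda, when it is estimated).
* Environment dummy coding: aquatic = 0, terrestrial = 1, so the
  interaction coefficient is the terrestrial-minus-aquatic slope
  difference.
* Effect size ``r`` has no universal definition; the default is the
  likelihood-ratio form ``r = sqrt(1 - exp((2/n) (ll_null - ll_model)))``
  comparing the model against the intercept-only fit on the same tree;
  ``effect_size="tstat"`` switches to ``r = sqrt(t^2 / (t^2 + df))`` for
  the mass coefficient.  Both are conventions, documented here because
  downstream tables depend on the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .data_io import RESPONSE_COLUMNS, TraitTable, normalize_species_name
from .errors import NumericalError, ParameterError, ValidationError
from .treekit import Phylogeny

__all__ = [
    "ModelSpec",
    "MODELS",
    "PGLSFit",
    "phylo_covariance",
    "apply_lambda",
    "gls_fit",
    "fit_pgls",
    "aicc",
    "loglik_at_lambda",
]

_MAX_CONDITION = 1e12
_GRID_POINTS = 11


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect design for one candidate model.

    ``columns`` are drawn from {"intercept", "log_mass", "env",
    "log_mass:env"} with env coded aquatic=0 / terrestrial=1.
    """

    name: str
    columns: tuple[str, ...]

    def design(self, table: TraitTable) -> np.ndarray:
        m = table.df["log_mass"].to_numpy(float)
        e = (table.df["environment"] == "terrestrial").to_numpy(float)
        pool = {
            "intercept": np.ones(len(m)),
            "log_mass": m,
            "env": e,
            "log_mass:env": m * e,
        }
        return np.column_stack([pool[c] for c in self.columns])

    @property
    def n_columns(self) -> int:
        return len(self.columns)


MODELS: dict[str, ModelSpec] = {
    "interaction": ModelSpec(
        "interaction", ("intercept", "log_mass", "env", "log_mass:env")
    ),
    "mass_only": ModelSpec("mass_only", ("intercept", "log_mass")),
    "null": ModelSpec("null", ("intercept",)),
}


@dataclass
class PGLSFit:
    """Result of one PGLS fit on one tree."""

    model: str
    response: str
    beta: np.ndarray
    se: np.ndarray
    coef_names: tuple[str, ...]
    sigma2: float
    lambda_hat: float
    loglik: float
    aicc: float
    n: int
    k: int
    effect_r: float | None = None
    species: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "response": self.response,
            "beta": {nm: float(b) for nm, b in zip(self.coef_names, self.beta)},
            "se": {nm: float(s) for nm, s in zip(self.coef_names, self.se)},
            "sigma2": float(self.sigma2),
            "lambda": float(self.lambda_hat),
            "loglik": float(self.loglik),
            "aicc": float(self.aicc),
            "n": self.n,
            "k": self.k,
            "effect_r": None if self.effect_r is None else float(self.effect_r),
        }


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------
def phylo_covariance(phylo: Phylogeny, species_order: list[str]) -> np.ndarray:
    """Brownian variance-covariance matrix of a dated tree.

    ``V[i, i]`` is the root-to-tip depth of species ``i``; ``V[i, j]`` is
    the depth of the most recent common ancestor of ``i`` and ``j``.
    Rows/columns follow ``species_order`` (matched after normalizing
    whitespace/underscores).
    """
    norm_order = [normalize_species_name(s) for s in species_order]
    index = {s: i for i, s in enumerate(norm_order)}
    if len(index) != len(norm_order):
        raise ValidationError("species_order contains duplicates")
    tree = phylo.dendropy_tree
    tip_norm = {}
    for lf in tree.leaf_node_iter():
        tip_norm[lf] = normalize_species_name(lf.taxon.label)
    missing = sorted(set(index) - set(tip_norm.values()))
    if missing:
        raise ValidationError("species not in tree", problems=missing)
    extra = sorted(set(tip_norm.values()) - set(index))
    if extra:
        raise ValidationError(
            "tree has tips absent from species_order", problems=extra
        )
    n = len(norm_order)
    V = np.zeros((n, n))
    # bottom-up: each node knows the row indices under it; cross-child pairs
    # share that node as their MRCA.
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[tip_norm[nd]]
            nd._rows = [i]
            V[i, i] = nd._root_distance
        else:
            depth = nd._root_distance
            kids = nd.child_nodes()
            rows = []
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ra = np.asarray(kids[a]._rows)
                    rb = np.asarray(kids[b]._rows)
                    V[np.ix_(ra, rb)] = depth
                    V[np.ix_(rb, ra)] = depth
            for ch in kids:
                rows.extend(ch._rows)
                del ch._rows
            nd._rows = rows
    del tree.seed_node._rows
    return V


def apply_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonals scaled by lam, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ParameterError(f"lambda must be in [0, 1], got {lam}")
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


# ---------------------------------------------------------------------------
# GLS core
# ---------------------------------------------------------------------------
def _cholesky(V: np.ndarray) -> np.ndarray:
    try:
        return sla.cholesky(V, lower=True)
    except sla.LinAlgError as err:
        diag = {"condition_number": float(np.linalg.cond(V))}
        raise NumericalError(
            f"covariance matrix is not positive definite ({err})", diagnostics=diag
        ) from None


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray, check_condition: bool = False):
    """Generalized least squares under covariance proportional to ``V``.

    Returns ``(beta, se, sigma2, loglik)`` with the ML residual rate
    ``sigma2 = e' V^-1 e / n`` and

    ``loglik = -(n/2) ln(2 pi sigma2) - (1/2) ln|V| - n/2``.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n or V.shape != (n, n):
        raise ParameterError(
            f"dimension mismatch: y={len(y)}, X={X.shape}, V={V.shape}"
        )
    L = _cholesky(V)
    if check_condition:
        cond = float(np.linalg.cond(V))
        if cond > _MAX_CONDITION:
            raise NumericalError(
                f"covariance condition number {cond:.3g} exceeds {_MAX_CONDITION:.0e}",
                diagnostics={"condition_number": cond},
            )
    # whiten: solve L z = y / X
    zy = sla.solve_triangular(L, y, lower=True)
    ZX = sla.solve_triangular(L, X, lower=True)
    beta, _res, rank, _sv = np.linalg.lstsq(ZX, zy, rcond=None)
    if rank < p:
        raise NumericalError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)",
            diagnostics={"design_condition": float(np.linalg.cond(ZX))},
        )
    resid = zy - ZX @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdetV - 0.5 * n
    XtVinvX_inv = np.linalg.inv(ZX.T @ ZX)
    se = np.sqrt(sigma2 * np.diag(XtVinvX_inv))
    return beta, se, float(sigma2), float(loglik)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion."""
    if n - k - 1 <= 0:
        raise ParameterError(f"AICc undefined: n={n}, k={k} gives n-k-1 <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def loglik_at_lambda(y, X, V, lam: float) -> float:
    """Profile log-likelihood of lambda (beta and sigma^2 maximized out)."""
    return gls_fit(y, X, apply_lambda(V, lam))[3]


def _profile_lambda(y, X, V):
    """Maximize the lambda profile on [0, 1]: coarse grid then Brent."""
    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    vals = np.array([loglik_at_lambda(y, X, V, g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise NumericalError(
            "non-finite log-likelihood on the lambda grid",
            diagnostics={"grid": grid.tolist(), "loglik": vals.tolist()},
        )
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID_POINTS - 1)]
    best_lam, best_ll = grid[i], vals[i]
    if hi > lo:
        res = minimize_scalar(
            lambda lam: -loglik_at_lambda(y, X, V, lam),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    return best_lam, best_ll


def _prepare(table: TraitTable, phylo: Phylogeny, response: str):
    """Align data and tree, dropping rows where the response is undefined.

    Dropping rows subsets V, which equals the pruned-tree covariance
    exactly (MRCA depths are unaffected by removing other tips).
    """
    col = RESPONSE_COLUMNS.get(response, response)
    y_all = table.df[col].to_numpy(float)
    keep = np.isfinite(y_all)
    sub = table if keep.all() else table.subset(keep)
    V = phylo_covariance(phylo, table.species)
    idx = np.flatnonzero(keep)
    return sub, y_all[keep], V[np.ix_(idx, idx)]


def fit_pgls(
    table: TraitTable,
    phylo: Phylogeny,
    response: str,
    model: ModelSpec | str,
    lambda_mode: str | float = "ml",
    effect_size: str | None = "lrt",
) -> PGLSFit:
    """Fit one candidate model by PGLS on one tree.

    Parameters
    ----------
    response:
        One of ``min`` / ``max`` / ``range`` (or a derived column name).
        Rows with an undefined response (zero prey range) are excluded.
    lambda_mode:
        ``"ml"`` maximizes Pagel's lambda over [0, 1]; a float in [0, 1]
        fixes it (k then excludes lambda).
    effect_size:
        ``"lrt"`` (default), ``"tstat"`` or ``None`` to skip.
    """
    if isinstance(model, str):
        model = MODELS[model]
    sub, y, V = _prepare(table, phylo, response)
    X = model.design(sub)
    n = len(y)
    if lambda_mode == "ml":
        lam, _ = _profile_lambda(y, X, V)
        k = model.n_columns + 2
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ParameterError(f"fixed lambda must be in [0, 1], got {lam}")
        k = model.n_columns + 1
    beta, se, sigma2, ll = gls_fit(y, X, apply_lambda(V, lam), check_condition=True)

    effect_r = None
    if effect_size == "lrt" and model.name != "null":
        X0 = MODELS["null"].design(sub)
        if lambda_mode == "ml":
            lam0, ll0 = _profile_lambda(y, X0, V)
        else:
            ll0 = loglik_at_lambda(y, X0, V, lam)
        effect_r = float(np.sqrt(max(0.0, 1.0 - np.exp((2.0 / n) * (ll0 - ll)))))
    elif effect_size == "tstat" and model.name != "null":
        j = model.columns.index("log_mass")
        t = beta[j] / se[j]
        df = n - model.n_columns
        effect_r = float(np.sqrt(t * t / (t * t + df)))

    return PGLSFit(
        model=model.name,
        response=response,
        beta=beta,
        se=se,
        coef_names=model.columns,
        sigma2=sigma2,
        lambda_hat=lam,
        loglik=ll,
        aicc=aicc(ll, k, n),
        n=n,
        k=k,
        effect_r=effect_r,
        species=sub.species,
    )
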