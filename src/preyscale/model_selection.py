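"""Three-model AICc selection over a tree ensemble.

Per tree, the interaction / mass-only / null models are fit by PGLS with
ML lambda and their AICc differences are taken relative to that tree's
best model.  Summaries aggregate over trees: mean ΔAICc with 2.5/97.5
percentile CIs, mean lambda and effect size, and coefficient CIs as
mean estimate ± 1.96 × mean SE (``ci_method="percentile"`` switches to
per-tree estimate percentiles).  The overall best model (lowest mean
AICc) is displayed with ΔAICc 0 and no CI, matching how such tables are
conventionally printed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import TraitTable
from .errors import PreyscaleError, UsageError, ValidationError
from .phylo_gls import MODELS, PGLSFit, fit_pgls
from .treekit import TreeEnsemble

__all__ = [
    "ModelSummary",
    "CoefficientSummary",
    "EnsembleSummary",
    "run_model_set",
    "environment_lines",
    "slope_difference_ci",
]

log = logging.getLogger(__name__)

Z95 = 1.96
EQUAL_SUPPORT_DELTA = 2.0
_TIE_TOL = 1e-12
MODEL_ORDER = ("interaction", "mass_only", "null")


@dataclass
class ModelSummary:
    name: str
    delta_aicc_mean: float
    delta_aicc_ci: tuple[float, float] | None
    lambda_mean: float
    effect_r_mean: float | None
    aicc_mean: float
    n_trees: int
    equally_supported: bool = False


@dataclass
class CoefficientSummary:
    name: str
    estimate_mean: float
    se_mean: float
    ci_low: float
    ci_high: float


@dataclass
class EnsembleSummary:
    response: str
    models: dict[str, ModelSummary]
    best_model: str
    coefficients: dict[str, dict[str, CoefficientSummary]]
    environment_lines: dict[str, tuple[float, float]]
    fits: pd.DataFrame
    n_failures: int = 0
    failures: list = field(default_factory=list)

    def model_table(self) -> pd.DataFrame:
        """Long-format table of per-model support (one row per model)."""
        rows = []
        for name in MODEL_ORDER:
            if name not in self.models:
                continue
            m = self.models[name]
            ci = m.delta_aicc_ci
            rows.append(
                {
                    "response": self.response,
                    "model": name,
                    "delta_aicc": m.delta_aicc_mean,
                    "delta_aicc_ci_low": None if ci is None else ci[0],
                    "delta_aicc_ci_high": None if ci is None else ci[1],
                    "lambda": m.lambda_mean,
                    "effect_r": m.effect_r_mean,
                    "equally_supported": m.equally_supported,
                }
            )
        return pd.DataFrame(rows)


def _percentile_ci(x: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(x, 2.5)),
        float(np.percentile(x, 97.5)),
    )


def run_model_set(
    table: TraitTable,
    ensemble: TreeEnsemble,
    response: str,
    effect_size: str | None = "lrt",
    ci_method: str = "se",
    max_failure_fraction: float = 0.05,
) -> EnsembleSummary:
    """Fit the three candidate models on every tree and aggregate.

    Single-tree fit failures are recorded and excluded with a warning; a
    failure fraction above ``max_failure_fraction`` is a hard error.
    """
    if len(ensemble) == 0:
        raise ValidationError("ensemble is empty")
    records = []
    fits: dict[int, dict[str, PGLSFit]] = {}
    failures = []
    for t_idx, tree in enumerate(ensemble):
        per_tree = {}
        try:
            for name in MODEL_ORDER:
                per_tree[name] = fit_pgls(
                    table, tree, response, MODELS[name],
                    lambda_mode="ml", effect_size=effect_size,
                )
        except PreyscaleError as err:
            failures.append((t_idx, str(err)))
            log.warning("tree %d excluded: %s", t_idx, err)
            continue
        fits[t_idx] = per_tree
    if len(failures) > max_failure_fraction * len(ensemble):
        raise ValidationError(
            f"{len(failures)}/{len(ensemble)} tree fits failed",
            problems=[f"tree {i}: {msg}" for i, msg in failures],
        )
    if failures:
        warnings.warn(
            f"{len(failures)} tree fit(s) failed and were excluded", stacklevel=2
        )
    if not fits:
        raise ValidationError("no successful fits")

    for t_idx, per_tree in fits.items():
        aiccs = {name: f.aicc for name, f in per_tree.items()}
        best_val = min(aiccs.values())
        # tie-break: among models within _TIE_TOL of the minimum, the one
        # with fewest parameters is "the" best (delta exactly 0).
        tied = [n for n, a in aiccs.items() if a - best_val < _TIE_TOL]
        best_name = min(tied, key=lambda n: per_tree[n].k)
        for name, f in per_tree.items():
            delta = 0.0 if name == best_name else f.aicc - best_val
            records.append(
                {
                    "tree": t_idx,
                    "model": name,
                    "response": response,
                    "aicc": f.aicc,
                    "delta_aicc": delta,
                    "lambda": f.lambda_hat,
                    "loglik": f.loglik,
                    "sigma2": f.sigma2,
                    "effect_r": f.effect_r,
                    "is_best": name == best_name,
                    **{f"beta_{nm}": b for nm, b in zip(f.coef_names, f.beta)},
                    **{f"se_{nm}": s for nm, s in zip(f.coef_names, f.se)},
                }
            )
    fit_log = pd.DataFrame(records).sort_values(["tree", "model"]).reset_index(drop=True)

    models: dict[str, ModelSummary] = {}
    mean_aicc = {
        name: float(fit_log.loc[fit_log["model"] == name, "aicc"].mean())
        for name in MODEL_ORDER
    }
    best_overall = min(mean_aicc, key=mean_aicc.get)
    for name in MODEL_ORDER:
        sel = fit_log[fit_log["model"] == name]
        deltas = sel["delta_aicc"].to_numpy(float)
        if name == best_overall:
            d_mean, d_ci = 0.0, None
        else:
            d_mean, d_ci = float(deltas.mean()), _percentile_ci(deltas)
        eff = sel["effect_r"].dropna()
        models[name] = ModelSummary(
            name=name,
            delta_aicc_mean=d_mean,
            delta_aicc_ci=d_ci,
            lambda_mean=float(sel["lambda"].mean()),
            effect_r_mean=float(eff.mean()) if len(eff) else None,
            aicc_mean=mean_aicc[name],
            n_trees=len(sel),
        )
    for m in models.values():
        m.equally_supported = m.delta_aicc_mean < EQUAL_SUPPORT_DELTA

    coefficients: dict[str, dict[str, CoefficientSummary]] = {}
    for name in MODEL_ORDER:
        sel = fit_log[fit_log["model"] == name]
        coefficients[name] = {}
        for col in MODELS[name].columns:
            est = sel[f"beta_{col}"].to_numpy(float)
            ses = sel[f"se_{col}"].to_numpy(float)
            mu, se_mu = float(est.mean()), float(ses.mean())
            if ci_method == "se":
                lo, hi = mu - Z95 * se_mu, mu + Z95 * se_mu
            elif ci_method == "percentile":
                lo, hi = _percentile_ci(est)
            else:
                raise UsageError(f"unknown ci_method {ci_method!r}")
            coefficients[name][col] = CoefficientSummary(col, mu, se_mu, lo, hi)

    inter = coefficients["interaction"]
    lines = _lines_from_beta(
        {c: s.estimate_mean for c, s in inter.items()}
    )

    return EnsembleSummary(
        response=response,
        models=models,
        best_model=best_overall,
        coefficients=coefficients,
        environment_lines=lines,
        fits=fit_log,
        n_failures=len(failures),
        failures=failures,
    )


def _lines_from_beta(beta: dict[str, float]) -> dict[str, tuple[float, float]]:
    b0 = beta["intercept"]
    b1 = beta["log_mass"]
    b2 = beta.get("env", 0.0)
    b3 = beta.get("log_mass:env", 0.0)
    return {
        "aquatic": (b1, b0),
        "terrestrial": (b1 + b3, b0 + b2),
    }


def environment_lines(fit: PGLSFit) -> dict[str, tuple[float, float]]:
    """Per-environment (slope, intercept) from an interaction-model fit.

    Aquatic is the 0-coded baseline; the terrestrial line adds the env and
    interaction coefficients.
    """
    if fit.model != "interaction":
        raise UsageError(
            f"environment_lines requires the interaction model, got {fit.model!r}"
        )
    beta = dict(zip(fit.coef_names, fit.beta))
    return _lines_from_beta(beta)


def slope_difference_ci(summary: EnsembleSummary) -> tuple[float, float]:
    """95% CI of the terrestrial-minus-aquatic slope difference.

    This is the interaction coefficient's aggregated CI; significance is
    read as the CI excluding 0.
    """
    try:
        coef = summary.coefficients["interaction"]["log_mass:env"]
    except KeyError:
        raise UsageError("summary lacks an interaction-model fit") from None
    return (coef.ci_low, coef.ci_high)
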