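"""Fit normalization-model variants to coherence-response data and compare them.

Each variant is fitted by bounded nonlinear least squares to an observed d'
table covering both cueing conditions and validities, minimizing the sum of
squared differences between the model-predicted and observed d'. Variants are
then ranked by adjusted R^2, AIC and BIC (Gaussian least-squares forms) and
contrasted with nested F-tests. Free-parameter counts are: base model 5
(attention gains for the narrow and broad conditions, semi-saturation
constant, exponent, d' scale), free-suppression variant 6 (+ suppressive
width), self-normalization variant 6 (+ mixing weight), coherence-independent
tuned normalization 7 (+ two attentional normalization gains).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .linking import ModelConfig, _predict_vector
from .population import ModelParams, Variant

__all__ = [
    "VARIANT_FREE_PARAMS",
    "PARAM_BOUNDS",
    "ModelFitResult",
    "ComparisonTable",
    "fit_variant",
    "compare_variants",
    "adjusted_r2",
    "aic_bic",
    "nested_f_test",
]

#: Free parameters per variant, in fit-vector order.
VARIANT_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "nmoa": ("gain_narrow", "gain_broad", "norm_constant", "exponent", "scale"),
    "nmoa_free": ("gain_narrow", "gain_broad", "norm_constant", "exponent", "scale",
                  "supp_feature_sigma"),
    "cdn": ("gain_narrow", "gain_broad", "norm_constant", "exponent", "scale",
            "cdn_weight"),
    "cin": ("gain_narrow", "gain_broad", "norm_constant", "exponent", "scale",
            "cin_gain_narrow", "cin_gain_broad"),
}

#: Box bounds for every fittable parameter. The SSE surface has plateaus
#: (notably a semi-saturation / scale trade-off), hence the multi-start.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "gain_narrow": (0.0, 10.0),
    "gain_broad": (0.0, 10.0),
    "norm_constant": (1e-4, 10.0),
    "exponent": (0.5, 6.0),
    "scale": (1e-3, 100.0),
    "cdn_weight": (0.0, 1.0),
    "cin_gain_narrow": (0.0, 50.0),
    "cin_gain_broad": (0.0, 50.0),
    "supp_feature_sigma": (5.0, 180.0),
}

#: Values at which an extension parameter makes the variant collapse to the
#: base model; used to embed a fitted base solution as a warm start.
_IDENTITY_EXTENSION = {
    "supp_feature_sigma": 180.0,
    "cdn_weight": 0.0,
    "cin_gain_narrow": 0.0,
    "cin_gain_broad": 0.0,
}

_PARAMS_FIELDS = {
    "norm_constant", "exponent", "scale", "supp_feature_sigma",
    "cdn_weight", "cin_gain_narrow", "cin_gain_broad",
}


@dataclass
class ModelFitResult:
    """Best-of-starts least-squares fit of one variant."""

    variant: str
    params: dict
    k: int
    sse: float
    n_obs: int
    predictions: pd.DataFrame
    boundary_flags: dict
    config: ModelConfig
    n_starts: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": {p: float(v) for p, v in self.params.items()},
            "k": self.k,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "boundary_flags": {p: bool(v) for p, v in self.boundary_flags.items()},
            "n_starts": self.n_starts,
            "seed": self.seed,
        }


def _apply_free(config: ModelConfig, names: Sequence[str], x: np.ndarray) -> ModelConfig:
    cfg_kw, par_kw = {}, {}
    for name, v in zip(names, x):
        (par_kw if name in _PARAMS_FIELDS else cfg_kw)[name] = float(v)
    return replace(config, params=replace(config.params, **par_kw), **cfg_kw)


def _row_positions(config: ModelConfig, data: pd.DataFrame) -> np.ndarray:
    """Map data rows to positions in predict_all_fast's deterministic order."""
    cs = list(config.coherences)
    n_c = len(cs)
    cond = data["condition"].map({"narrow": 0, "broad": 1})
    val = data["validity"].map({"valid": 0, "invalid": 1})
    if cond.isna().any() or val.isna().any():
        raise ValueError("condition must be narrow/broad and validity valid/invalid")
    c_idx = data["coherence"].map({c: i for i, c in enumerate(cs)})
    if c_idx.isna().any():
        raise ValueError("observed rows not covered by the model's coherence levels")
    return (cond * 2 * n_c + val * n_c + c_idx).to_numpy(int)


def _predictions(config: ModelConfig, variant: str, data: pd.DataFrame,
                 positions: Optional[np.ndarray] = None) -> np.ndarray:
    if positions is None:
        positions = _row_positions(config, data)
    return _predict_vector(replace(config, variant=variant))[positions]


def fit_variant(data: pd.DataFrame, variant: Variant,
                base_config: Optional[ModelConfig] = None,
                fixed: Optional[dict] = None,
                n_starts: int = 32, seed: int = 0,
                extra_starts: Optional[Sequence[dict]] = None,
                n_points: int = 120) -> ModelFitResult:
    """Fit one model variant to an observed d' table.

    ``data`` needs columns (condition, validity, coherence, dprime) and must
    cover both conditions and validities. Starting points are a seeded
    Latin-hypercube over the parameter bounds plus any ``extra_starts``
    (parameter dicts, e.g. an embedded reduced-model solution); the best
    solution over all converged starts is returned, ties broken by the
    lexicographically smallest parameter vector. ``fixed`` pins named
    parameters, removing them from the fit vector. Parameters ending on a
    bound are reported in ``boundary_flags``.
    """
    if variant not in VARIANT_FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    need = {"condition", "validity", "coherence", "dprime"}
    if not need.issubset(data.columns):
        raise ValueError(f"data must provide columns {sorted(need)}")
    for cond in ("narrow", "broad"):
        for val in ("valid", "invalid"):
            if not ((data["condition"] == cond) & (data["validity"] == val)).any():
                raise ValueError(f"data lacks the ({cond}, {val}) cell")

    fixed = dict(fixed or {})
    config = base_config if base_config is not None else ModelConfig()
    config = replace(config, n_points=n_points, variant=variant,
                     coherences=tuple(sorted(data["coherence"].unique())))
    if fixed:
        config = _apply_free(config, list(fixed), np.array([fixed[p] for p in fixed]))

    names = [p for p in VARIANT_FREE_PARAMS[variant] if p not in fixed]
    k = len(VARIANT_FREE_PARAMS[variant])
    lo = np.array([PARAM_BOUNDS[p][0] for p in names])
    hi = np.array([PARAM_BOUNDS[p][1] for p in names])
    obs = data["dprime"].to_numpy(float)
    positions = _row_positions(config, data)

    def residuals(x):
        try:
            return _predictions(_apply_free(config, names, x), variant, data, positions) - obs
        except (FloatingPointError, ZeroDivisionError):
            return np.full(len(obs), 1e6)

    rng_seed = seed % (2 ** 31)
    sampler = stats.qmc.LatinHypercube(d=len(names), seed=rng_seed)
    n_lhs = max(n_starts, 1)
    starts = list(stats.qmc.scale(sampler.random(n_lhs), lo, hi))
    for extra in extra_starts or []:
        x = np.array([extra.get(p, _IDENTITY_EXTENSION.get(p, np.mean(PARAM_BOUNDS[p])))
                      for p in names])
        starts.append(np.clip(x, lo, hi))

    best = None
    n_converged = 0
    for s in starts:
        try:
            sol = optimize.least_squares(residuals, s, bounds=(lo, hi),
                                         xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.fun)):
            continue
        n_converged += 1
        sse = float(np.sum(sol.fun ** 2))
        key = (round(sse, 12), tuple(np.round(sol.x, 10)))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError(f"fit of variant {variant!r} failed to converge from any start")

    sol = best[1]
    params = dict(zip(names, (float(v) for v in sol.x)))
    params.update({p: float(v) for p, v in fixed.items()})
    at_bound = {
        p: bool(np.isclose(params[p], PARAM_BOUNDS[p][0]) or np.isclose(params[p], PARAM_BOUNDS[p][1]))
        for p in names
    }
    fitted_cfg = _apply_free(config, list(params), np.array(list(params.values())))
    pred = data[["condition", "validity", "coherence", "dprime"]].copy()
    pred["dprime_pred"] = _predictions(fitted_cfg, variant, data)
    return ModelFitResult(
        variant=variant, params=params, k=k,
        sse=float(np.sum(sol.fun ** 2)), n_obs=len(obs),
        predictions=pred, boundary_flags=at_bound,
        config=fitted_cfg, n_starts=len(starts), seed=seed,
    )


# ---------------------------------------------------------------------------
# Goodness of fit and model selection
# ---------------------------------------------------------------------------

def adjusted_r2(sse: float, n_obs: int, k: int, sst: float) -> float:
    """Adjusted coefficient of determination 1 - (SSE/(n-k-1)) / (SST/(n-1))."""
    if n_obs <= k + 1:
        raise ValueError("adjusted R^2 needs n_obs > k + 1")
    if sst <= 0:
        raise ValueError("total sum of squares must be positive")
    return 1.0 - (sse / (n_obs - k - 1)) / (sst / (n_obs - 1))


def aic_bic(sse: float, n_obs: int, k: int) -> tuple[float, float]:
    """Gaussian least-squares information criteria (additive constants dropped).

    AIC = n ln(SSE/n) + 2k, BIC = n ln(SSE/n) + k ln(n).
    """
    if sse <= 0:
        raise ValueError("information criteria need SSE > 0")
    ll_term = n_obs * np.log(sse / n_obs)
    return float(ll_term + 2 * k), float(ll_term + k * np.log(n_obs))


def nested_f_test(reduced: "ModelFitResult | tuple[float, int]",
                  full: "ModelFitResult | tuple[float, int]",
                  n_obs: Optional[int] = None) -> tuple[float, float]:
    """F-test of a reduced model against a full model fitted to the same data.

    F = ((SSE_r - SSE_f)/(k_f - k_r)) / (SSE_f/(n - k_f)) with a p-value from
    the F distribution on (k_f - k_r, n - k_f) degrees of freedom. A full
    model fitting worse than the reduced one signals an optimizer failure
    and raises.
    """
    def unpack(m):
        if isinstance(m, ModelFitResult):
            return m.sse, m.k, m.n_obs
        return m[0], m[1], n_obs
    sse_r, k_r, n_r = unpack(reduced)
    sse_f, k_f, n_f = unpack(full)
    n = n_f or n_r
    if n is None:
        raise ValueError("n_obs required when passing (sse, k) tuples")
    if n_r is not None and n_f is not None and n_r != n_f:
        raise ValueError("reduced and full fits use different data sizes")
    if k_r >= k_f:
        raise ValueError("reduced model must have fewer parameters than the full model")
    if sse_r < sse_f - 1e-9 * max(sse_r, 1.0):
        raise ArithmeticError(
            "full model fits worse than the reduced model: refit the full model"
        )
    df1, df2 = k_f - k_r, n - k_f
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the F-test")
    F = max((sse_r - sse_f), 0.0) / df1 / (sse_f / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


@dataclass
class ComparisonTable:
    """Model-selection summary over fitted variants."""

    fits: dict
    criteria: pd.DataFrame
    f_tests: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "criteria": self.criteria.to_dict(orient="records"),
                "f_tests": self.f_tests.to_dict(orient="records"),
                "fits": {v: f.to_dict() for v, f in self.fits.items()},
            },
            indent=2,
        )


def compare_variants(data: pd.DataFrame,
                     variants: Sequence[Variant] = ("nmoa", "nmoa_free", "cdn", "cin"),
                     base_config: Optional[ModelConfig] = None,
                     n_starts: int = 32, seed: int = 0,
                     n_points: int = 120) -> ComparisonTable:
    """Fit several variants to the same data and rank them.

    The base model is always fitted first and its solution is embedded as a
    warm start for every extension (each extension contains the base model
    exactly), which enforces the nesting inequality SSE_full <= SSE_reduced;
    a residual violation beyond optimizer tolerance triggers one warm
    refit. F-tests are reported for every parameter-nested pair.
    """
    order = list(variants)
    if "nmoa" in order:
        order.remove("nmoa")
        order.insert(0, "nmoa")
    fits: dict[str, ModelFitResult] = {}
    for i, variant in enumerate(order):
        extra = []
        if variant != "nmoa" and "nmoa" in fits:
            extra.append(dict(fits["nmoa"].params))
        fit = fit_variant(data, variant, base_config=base_config,
                         n_starts=n_starts, seed=seed + i, extra_starts=extra,
                         n_points=n_points)
        if "nmoa" in fits and variant != "nmoa" and fit.sse > fits["nmoa"].sse + 1e-6:
            fit = fit_variant(data, variant, base_config=base_config, n_starts=4,
                              seed=seed + 100 + i, extra_starts=extra, n_points=n_points)
            if fit.sse > fits["nmoa"].sse + 1e-6:
                raise RuntimeError(f"nesting violated for {variant}: refit did not recover")
        fits[variant] = fit

    obs = data["dprime"].to_numpy(float)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    crit_rows = []
    for v, f in fits.items():
        aic, bic = aic_bic(f.sse, f.n_obs, f.k)
        crit_rows.append((v, f.k, f.sse, adjusted_r2(f.sse, f.n_obs, f.k, sst), aic, bic))
    criteria = pd.DataFrame(
        crit_rows, columns=["variant", "k", "sse", "adj_r2", "aic", "bic"]
    )

    f_rows = []
    for vr in fits:
        for vf in fits:
            if fits[vr].k < fits[vf].k:
                try:
                    F, p = nested_f_test(fits[vr], fits[vf])
                except ArithmeticError:
                    F, p = np.nan, np.nan
                f_rows.append((vr, vf, F, p))
    f_tests = pd.DataFrame(f_rows, columns=["reduced", "full", "F", "p"])
    return ComparisonTable(fits=fits, criteria=criteria, f_tests=f_tests)
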