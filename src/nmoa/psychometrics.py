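"""Behavioural analysis of transparent-motion direction-discrimination data.

Implements the complete psychophysical pipeline: signal-detection d' from
clockwise/counter-clockwise judgements, joint Naka-Rushton fits of the four
coherence-response curves per subject with a shared slope, the gain
decomposition into coherence gain (c50 shifts) and response gain (d'max
changes) with modulation indices, the saturation-based subject-exclusion
rule, offset binning of trials relative to the cue, cumulative-Gaussian JND
estimation, and Bonferroni-corrected paired tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "dprime",
    "dprime_from_rates",
    "naka_rushton",
    "dprime_table",
    "CRFFit",
    "fit_crf_joint",
    "modulation_index",
    "gain_summary",
    "exclusion_filter",
    "group_by_offset",
    "fit_cumulative_gaussian",
    "PairedTestResult",
    "paired_tests",
    "circular_difference",
]

#: Columns every trial table must provide.
TRIAL_COLUMNS = (
    "subject",
    "session",
    "cue_type",
    "validity",
    "coherence",
    "cued_direction",
    "sample_direction",
    "test_direction",
    "change_sign",
    "response",
)


def circular_difference(a, b) -> np.ndarray:
    """Minimal absolute angular difference in degrees, in [0, 180]."""
    return np.abs((np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# d'
# ---------------------------------------------------------------------------

def _corrected_rate(k: int, n: int) -> float:
    """Proportion k/n with extreme values pulled in by the 1/(2n) rule."""
    p = k / n
    if p <= 0.0:
        return 1.0 / (2 * n)
    if p >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def dprime(n_cw_given_cw: int, n_cw_given_ccw: int,
           n_cw_trials: int, n_ccw_trials: int) -> float:
    """Sensitivity d' = z(p_CW|CW) - z(p_CW|CCW) from trial counts.

    p_CW|CW is the proportion of clockwise responses to clockwise changes
    (hits) and p_CW|CCW the proportion of clockwise responses to
    counter-clockwise changes (false alarms). Perfect proportions are
    corrected by the 1/(2N) rule before the normal quantile so d' stays
    finite.
    """
    if n_cw_trials < 1 or n_ccw_trials < 1:
        raise ValueError("each change direction needs at least one trial")
    p_hit = _corrected_rate(n_cw_given_cw, n_cw_trials)
    p_fa = _corrected_rate(n_cw_given_ccw, n_ccw_trials)
    return float(stats.norm.ppf(p_hit) - stats.norm.ppf(p_fa))


def dprime_from_rates(p_hit: float, p_fa: float) -> float:
    """d' directly from (uncorrected) proportions; both must lie in (0, 1)."""
    if not (0.0 < p_hit < 1.0 and 0.0 < p_fa < 1.0):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    return float(stats.norm.ppf(p_hit) - stats.norm.ppf(p_fa))


def dprime_table(trials: pd.DataFrame,
                 by: Sequence[str] = ("subject", "cue_type", "validity", "coherence"),
                 coherence_mask: Optional[Sequence[float]] = None,
                 measure: Literal["dprime", "pc"] = "dprime") -> pd.DataFrame:
    """Per-cell performance from a trial table.

    ``coherence_mask`` optionally restricts the analysis to a subset of
    coherence levels (the robustness check that drops the highest levels).
    ``measure="pc"`` is the robustness variant that reports the proportion
    of correct responses minus 0.5 (chance) instead of d'; the value is
    still returned in the ``dprime`` column so downstream fits run
    unchanged. Cells missing one of the two change directions are dropped
    with a warning.
    """
    t = trials
    if coherence_mask is not None:
        t = t[t["coherence"].isin(list(coherence_mask))]
    rows = []
    dropped = 0
    for key, g in t.groupby(list(by), sort=True):
        cw = g[g["change_sign"] == "CW"]
        ccw = g[g["change_sign"] == "CCW"]
        if len(cw) == 0 or len(ccw) == 0:
            dropped += 1
            continue
        if measure == "pc":
            d = float((g["response"] == g["change_sign"]).mean() - 0.5)
        else:
            d = dprime(
                int((cw["response"] == "CW").sum()),
                int((ccw["response"] == "CW").sum()),
                len(cw),
                len(ccw),
            )
        rows.append((*np.atleast_1d(key), d, len(g)))
    if dropped:
        warnings.warn(f"dropped {dropped} cell(s) missing one change direction")
    return pd.DataFrame(rows, columns=[*by, "dprime", "n_trials"])


# ---------------------------------------------------------------------------
# Naka-Rushton coherence-response fitting
# ---------------------------------------------------------------------------

def naka_rushton(c, dmax: float, c50: float, n: float):
    """Saturating coherence-response function dmax * c^n / (c^n + c50^n)."""
    if c50 <= 0 or n <= 0:
        raise ValueError("c50 and the exponent must be positive")
    c = np.asarray(c, dtype=float)
    out = dmax * c ** n / (c ** n + c50 ** n)
    return out if out.ndim else float(out)


_CELLS = (("narrow", "valid"), ("narrow", "invalid"), ("broad", "valid"), ("broad", "invalid"))

SlopeMode = Literal["shared", "per_condition", "free"]


@dataclass
class CRFFit:
    """Jointly fitted Naka-Rushton coefficients for one subject.

    ``coefficients`` maps (cue_type, validity) to (d'max, c50); the slope is
    shared according to ``slope_mode`` (one exponent per subject by default).
    """

    coefficients: dict
    exponents: dict
    slope_mode: SlopeMode
    sse: float
    n_obs: int
    k: int
    r2: dict
    saturation_flags: dict = field(default_factory=dict)

    def exponent(self, cue_type: str = "narrow", validity: str = "valid") -> float:
        return self.exponents[(cue_type, validity)]

    def aic_bic(self) -> tuple[float, float]:
        sse = max(self.sse, 1e-300)
        n = self.n_obs
        return (
            n * np.log(sse / n) + 2 * self.k,
            n * np.log(sse / n) + self.k * np.log(n),
        )


def _slope_groups(mode: SlopeMode) -> dict:
    if mode == "shared":
        return {cell: 0 for cell in _CELLS}
    if mode == "per_condition":
        return {cell: (0 if cell[0] == "narrow" else 1) for cell in _CELLS}
    if mode == "free":
        return {cell: i for i, cell in enumerate(_CELLS)}
    raise ValueError(f"unknown slope mode {mode!r}")


def fit_crf_joint(dtable: pd.DataFrame, slope_mode: SlopeMode = "shared",
                  n_starts: int = 8, seed: int = 0,
                  bounds: Optional[dict] = None) -> CRFFit:
    """Fit four Naka-Rushton curves with a constrained slope to one subject.

    ``dtable`` holds columns (cue_type, validity, coherence, dprime) for a
    single subject. Free parameters are (d'max, c50) per curve plus one
    exponent per slope group (1 for "shared", 2 for "per_condition", 4 for
    "free"). Least squares with seeded Latin-hypercube multi-start; the best
    solution over all starts is returned, ties broken lexicographically.
    Curves whose estimated c50 exceeds the highest tested coherence are
    flagged as non-saturating (the fit is still returned).
    """
    cells = [c for c in _CELLS if ((dtable["cue_type"] == c[0]) & (dtable["validity"] == c[1])).any()]
    if not cells:
        raise ValueError("no recognised (cue_type, validity) cells in the table")
    groups = _slope_groups(slope_mode)
    group_ids = sorted({groups[c] for c in cells})
    group_pos = {g: i for i, g in enumerate(group_ids)}

    cell_data = {}
    for cell in cells:
        g = dtable[(dtable["cue_type"] == cell[0]) & (dtable["validity"] == cell[1])]
        c = g["coherence"].to_numpy(float)
        d = g["dprime"].to_numpy(float)
        if len(np.unique(c)) < 4:
            raise ValueError(f"cell {cell} needs at least 4 coherence levels")
        if not np.all(np.isfinite(d)):
            raise ValueError(f"non-finite d' in cell {cell}")
        cell_data[cell] = (c, d)

    c_max = max(cd[0].max() for cd in cell_data.values())
    d_hi = max(cd[1].max() for cd in cell_data.values())
    b = {
        "dmax": (1e-3, max(4.0 * d_hi, 10.0)),
        "c50": (1e-4, 2.0),
        "n": (0.3, 8.0),
    }
    if bounds:
        b.update(bounds)

    # parameter vector: [dmax_i, c50_i for each cell] + [n_g for each group]
    lo = np.concatenate([np.tile([b["dmax"][0], b["c50"][0]], len(cells)),
                         np.full(len(group_ids), b["n"][0])])
    hi = np.concatenate([np.tile([b["dmax"][1], b["c50"][1]], len(cells)),
                         np.full(len(group_ids), b["n"][1])])

    def residuals(x):
        res = []
        for i, cell in enumerate(cells):
            dmax, c50 = x[2 * i], x[2 * i + 1]
            n = x[2 * len(cells) + group_pos[groups[cell]]]
            c, d = cell_data[cell]
            res.append(dmax * c ** n / (c ** n + c50 ** n) - d)
        return np.concatenate(res)

    sampler = stats.qmc.LatinHypercube(d=len(lo), seed=seed)
    starts = [stats.qmc.scale(sampler.random(1), lo, hi)[0] for _ in range(max(n_starts - 1, 0))]
    # a deterministic, data-informed start
    x0 = []
    for cell in cells:
        c, d = cell_data[cell]
        x0 += [max(d.max(), 0.1), 0.15]
    x0 += [1.5] * len(group_ids)
    starts.insert(0, np.clip(np.asarray(x0), lo, hi))

    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(residuals, s, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        key = (sse, tuple(sol.x))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError("joint Naka-Rushton fit failed from every start")
    sol = best[1]
    sse = float(np.sum(sol.fun ** 2))

    coefficients, exponents, r2, flags = {}, {}, {}, {}
    for i, cell in enumerate(cells):
        dmax, c50 = float(sol.x[2 * i]), float(sol.x[2 * i + 1])
        n = float(sol.x[2 * len(cells) + group_pos[groups[cell]]])
        coefficients[cell] = (dmax, c50)
        exponents[cell] = n
        c, d = cell_data[cell]
        pred = dmax * c ** n / (c ** n + c50 ** n)
        sst = float(np.sum((d - d.mean()) ** 2))
        r2[cell] = 1.0 - float(np.sum((d - pred) ** 2)) / sst if sst > 0 else np.nan
        flags[cell] = bool(c50 > c_max)

    n_obs = int(sum(len(cd[0]) for cd in cell_data.values()))
    k = 2 * len(cells) + len(group_ids)
    return CRFFit(coefficients, exponents, slope_mode, sse, n_obs, k, r2, flags)


def modulation_index(zeta_valid: float, zeta_invalid: float) -> float:
    """Normalized valid-invalid contrast (a - b) / (a + b) of a coefficient."""
    denom = zeta_valid + zeta_invalid
    if denom == 0:
        raise ZeroDivisionError("modulation index undefined for a zero coefficient sum")
    return (zeta_valid - zeta_invalid) / denom


def gain_summary(fit: CRFFit) -> pd.DataFrame:
    """Per-condition gain decomposition of a joint fit.

    Returns, for each cue condition, the valid-invalid differences and
    modulation indices of both coefficients: a negative delta_c50 / MI_c50
    is a coherence-gain effect, a positive delta_dmax / MI_dmax a
    response-gain effect.
    """
    rows = []
    for cond in ("narrow", "broad"):
        if (cond, "valid") not in fit.coefficients or (cond, "invalid") not in fit.coefficients:
            continue
        dv, cv = fit.coefficients[(cond, "valid")]
        di, ci = fit.coefficients[(cond, "invalid")]
        rows.append(
            (cond, dv - di, cv - ci, modulation_index(dv, di), modulation_index(cv, ci))
        )
    return pd.DataFrame(rows, columns=["condition", "delta_dmax", "delta_c50", "mi_dmax", "mi_c50"])


# ---------------------------------------------------------------------------
# Exclusion and binning rules
# ---------------------------------------------------------------------------

def exclusion_filter(dtable: pd.DataFrame, threshold: float = 1.0,
                     rule: Literal["any", "mean"] = "any") -> tuple[bool, pd.DataFrame]:
    """Saturation screen: exclude a subject whose d' still climbs at the top.

    For each (cue_type, validity) curve the increase between the two highest
    coherence levels is computed; with ``rule="any"`` the subject is excluded
    when any curve increases by at least ``threshold`` (the boundary value
    triggers exclusion), with ``rule="mean"`` when the mean increase does.
    Returns (exclude, per-curve deltas).
    """
    rows = []
    for (cue, val), g in dtable.groupby(["cue_type", "validity"]):
        g = g.sort_values("coherence")
        levels = g["coherence"].to_numpy()
        if len(levels) < 2:
            raise ValueError(f"curve ({cue}, {val}) lacks the two highest coherence levels")
        d = g["dprime"].to_numpy(float)
        rows.append((cue, val, d[-1] - d[-2]))
    deltas = pd.DataFrame(rows, columns=["cue_type", "validity", "delta_dprime"])
    if rule == "any":
        exclude = bool((deltas["delta_dprime"] >= threshold).any())
    elif rule == "mean":
        exclude = bool(deltas["delta_dprime"].mean() >= threshold)
    else:
        raise ValueError(f"unknown exclusion rule {rule!r}")
    return exclude, deltas


#: Fixed cue-sample offset bins in degrees (close, medium, far); jitter is
#: drawn from +-10 so the half-open edges at 2.5 and 6.5 reproduce the
#: integer groupings 0-2, 3-6, 7-10.
CUE_SAMPLE_EDGES = (0.0, 2.5, 6.5, np.inf)

OFFSET_LABELS = ("close", "medium", "far")


def group_by_offset(trials: pd.DataFrame, mode: Literal["cue_test", "cue_sample"],
                    jnd: Optional[float] = None, jitter_range: float = 10.0,
                    separation: float = 135.0) -> pd.DataFrame:
    """d' per offset bin (close/medium/far) and cue validity.

    ``cue_test`` bins the absolute circular cue-test offset into three
    equal-width parts of its possible range [0, jitter_range + jnd] (the
    direction jitter plus the change magnitude; both configurable);
    ``cue_sample`` uses the fixed cue-sample bins. Invalid trials are
    referenced to the inferred uncued direction (the cue rotated by the
    component ``separation``), mirroring how the offset is defined for
    them. Empty bins are returned with ``n_trials`` 0 and d' NaN.
    """
    t = trials.copy()
    # reference direction: the cued direction for valid trials, the inferred
    # uncued direction for invalid ones (nearer of cue +- separation).
    ref = t["cued_direction"].to_numpy(float)
    invalid = (t["validity"] == "invalid").to_numpy()
    if invalid.any():
        probe = t["sample_direction"].to_numpy(float)
        plus = (ref + separation) % 360.0
        minus = (ref - separation) % 360.0
        use_plus = circular_difference(probe, plus) <= circular_difference(probe, minus)
        ref = np.where(invalid, np.where(use_plus, plus, minus), ref)

    target = t["test_direction"] if mode == "cue_test" else t["sample_direction"]
    offset = circular_difference(target, ref)

    if mode == "cue_test":
        if jnd is None or jnd <= 0:
            raise ValueError("cue_test binning needs a positive JND")
        upper = jitter_range + jnd
        edges = np.array([0.0, upper / 3, 2 * upper / 3, np.inf])
    elif mode == "cue_sample":
        edges = np.asarray(CUE_SAMPLE_EDGES)
    else:
        raise ValueError(f"unknown offset mode {mode!r}")

    t["offset_bin"] = pd.cut(offset, edges, labels=OFFSET_LABELS, include_lowest=True)
    rows = []
    for val in ("valid", "invalid"):
        for label in OFFSET_LABELS:
            g = t[(t["validity"] == val) & (t["offset_bin"] == label)]
            cw = g[g["change_sign"] == "CW"]
            ccw = g[g["change_sign"] == "CCW"]
            if len(cw) == 0 or len(ccw) == 0:
                rows.append((val, label, np.nan, len(g)))
                continue
            d = dprime(
                int((cw["response"] == "CW").sum()),
                int((ccw["response"] == "CW").sum()),
                len(cw), len(ccw),
            )
            rows.append((val, label, d, len(g)))
    return pd.DataFrame(rows, columns=["validity", "offset_bin", "dprime", "n_trials"])


# ---------------------------------------------------------------------------
# JND estimation and paired tests
# ---------------------------------------------------------------------------

def fit_cumulative_gaussian(direction_change: Sequence[float],
                            response_cw: Sequence[bool]) -> tuple[float, float]:
    """Maximum-likelihood cumulative-Gaussian psychometric fit.

    Models p(clockwise response) = Phi((change - bias) / sigma) and returns
    (bias, JND) where the JND is the fitted sigma (the slope parameter).
    Raises if the responses are perfectly separated (the MLE diverges) or if
    fewer than 5 distinct change magnitudes spanning both signs are given.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(direction_change, dtype=float)
    y = np.asarray(response_cw, dtype=float)
    if len(np.unique(x)) < 5 or x.min() >= 0 or x.max() <= 0:
        raise ValueError("need >= 5 distinct change magnitudes spanning both signs")
    if y.min() == y.max():
        raise FloatingPointError("responses are constant: cumulative-Gaussian fit diverges")
    model = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit()
    except PerfectSeparationError as err:  # pragma: no cover - depends on data
        raise FloatingPointError("perfect separation: cumulative-Gaussian fit diverges") from err
    b0, b1 = res.params
    if not np.isfinite(b1) or b1 <= 0 or abs(b1) > 1e4:
        raise FloatingPointError("degenerate slope in cumulative-Gaussian fit")
    return float(-b0 / b1), float(1.0 / b1)


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    t_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    alpha_corrected: float
    significant_t: bool
    significant_wilcoxon: bool
    degenerate: bool


def paired_tests(a: Sequence[float], b: Sequence[float],
                 alternative: Literal["two-sided", "greater", "less"] = "two-sided",
                 alpha: float = 0.05, m: int = 1) -> PairedTestResult:
    """Paired t and Wilcoxon signed-rank tests with a Bonferroni threshold.

    ``m`` is the number of comparisons in the family; significance is judged
    at alpha / m. Zero-variance differences yield a degenerate flag with
    NaN statistics instead of an error.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired observations")
    alpha_c = alpha / m
    diffs = a - b
    if np.allclose(diffs, diffs[0]) and np.isclose(np.std(diffs), 0.0):
        if np.isclose(diffs[0], 0.0):
            return PairedTestResult(np.nan, np.nan, np.nan, np.nan, alpha_c, False, False, True)
        # constant nonzero difference: the t statistic diverges, p -> 0
        direction_ok = (
            alternative == "two-sided"
            or (alternative == "greater" and diffs[0] > 0)
            or (alternative == "less" and diffs[0] < 0)
        )
        p = 0.0 if direction_ok else 1.0
        w_stat, w_p = stats.wilcoxon(a, b, alternative=alternative)
        return PairedTestResult(np.inf * np.sign(diffs[0]), p, float(w_stat), float(w_p),
                                alpha_c, direction_ok, w_p < alpha_c, True)
    t_stat, t_p = stats.ttest_rel(a, b, alternative=alternative)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w_stat, w_p = stats.wilcoxon(a, b, alternative=alternative)
    return PairedTestResult(float(t_stat), float(t_p), float(w_stat), float(w_p),
                            alpha_c, bool(t_p < alpha_c), bool(w_p < alpha_c), False)
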