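"""Virtual observer: trial-level simulation of the transparent-motion study.

Generates complete synthetic experiments matching the study design — two cue
types (narrow and broad focus) with 75% validity, six coherence levels from
1.6% to 100%, two transparent-motion components 135 degrees apart with +-10
degree direction jitter, JND-scaled direction changes, 576 trials per session
and 5 sessions per subject — and simulates binary clockwise /
counter-clockwise judgements as independent Bernoulli draws from an
equal-variance signal-detection observer whose sensitivity follows
Naka-Rushton coherence-response curves. The ground-truth curves can be given
explicitly or derived from a population-model configuration, so the entire
analysis pipeline is testable end to end without human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linking import COHERENCE_LEVELS, ModelConfig, predict_all
from .psychometrics import TRIAL_COLUMNS, naka_rushton, fit_crf_joint

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "generate_design",
    "dprime_to_probabilities",
    "simulate_responses",
    "simulate_experiment",
    "ground_truth_from_model",
]

#: Reference directions: 0 and +-45 degrees around straight rightward and
#: straight leftward motion.
REFERENCE_DIRECTIONS = (315.0, 0.0, 45.0, 135.0, 180.0, 225.0)

_CELLS = (("narrow", "valid"), ("narrow", "invalid"), ("broad", "valid"), ("broad", "invalid"))


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of one synthetic experiment."""

    n_subjects: int = 6
    n_sessions: int = 5
    trials_per_session: int = 576
    coherence_levels: tuple[float, ...] = COHERENCE_LEVELS
    cue_validity: float = 0.75
    cue_types: tuple[str, ...] = ("narrow", "broad")
    reference_directions: tuple[float, ...] = REFERENCE_DIRECTIONS
    component_separation: float = 135.0
    direction_jitter: float = 10.0
    jnd: float = 12.86

    def __post_init__(self) -> None:
        if not 0.0 < self.cue_validity < 1.0:
            raise ValueError("cue validity must lie in (0, 1)")
        if list(self.coherence_levels) != sorted(self.coherence_levels):
            raise ValueError("coherence levels must be sorted ascending")
        if self.jnd <= 0 or self.direction_jitter < 0:
            raise ValueError("jnd must be positive and jitter nonnegative")
        n_cells = len(self.cue_types) * len(self.coherence_levels) * len(self.reference_directions)
        if self.trials_per_session % n_cells:
            raise ValueError(
                f"{self.trials_per_session} trials per session cannot be balanced over "
                f"{n_cells} cue-type x coherence x cue-direction cells"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Generating coherence-response curves, one per cue-type x validity cell.

    ``curves`` maps (cue_type, validity) to (d'max, c50); ``exponent`` is the
    Naka-Rushton slope shared by all four curves; ``bias`` shifts the
    observer's decision criterion (0 = unbiased, the study's trained
    default). ``source`` optionally records the raw model-predicted values
    the curves were fitted to.
    """

    curves: dict
    exponent: float = 1.5
    bias: float = 0.0
    source: Optional[pd.DataFrame] = None
    saturation_flags: Optional[dict] = None

    def __post_init__(self) -> None:
        for cell in _CELLS:
            if cell not in self.curves:
                raise ValueError(f"ground truth lacks the {cell} cell")
            dmax, c50 = self.curves[cell]
            if dmax <= 0 or c50 <= 0:
                raise ValueError(f"nonpositive coefficients in cell {cell}")
        if self.exponent <= 0:
            raise ValueError("shared exponent must be positive")

    def dprime_at(self, cue_type: str, validity: str, coherence) -> np.ndarray:
        dmax, c50 = self.curves[(cue_type, validity)]
        return naka_rushton(coherence, dmax, c50, self.exponent)


def generate_design(spec: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Generate the trial table of a synthetic experiment, without responses.

    Cue type, coherence and cue direction are exactly balanced within each
    session; validity is an independent 75% Bernoulli draw per trial. Both
    motion components are jittered +-10 degrees; the probed ("sample")
    component is the cued one on valid trials and the one 135 degrees away
    on invalid trials; the test direction is the sample rotated by the JND
    with a random sign. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cells = [
        (ct, coh, ref)
        for ct in spec.cue_types
        for coh in spec.coherence_levels
        for ref in spec.reference_directions
    ]
    reps = spec.trials_per_session // len(cells)
    rows = []
    for subject in range(1, spec.n_subjects + 1):
        for session in range(1, spec.n_sessions + 1):
            base = np.repeat(np.arange(len(cells)), reps)
            order = rng.permutation(base)
            for cell_idx in order:
                ct, coh, cue_dir = cells[cell_idx]
                valid = rng.random() < spec.cue_validity
                side = rng.choice([-1.0, 1.0])
                jit = rng.uniform(-spec.direction_jitter, spec.direction_jitter, size=2)
                cued_comp = (cue_dir + jit[0]) % 360.0
                uncued_comp = (cue_dir + side * spec.component_separation + jit[1]) % 360.0
                sample = cued_comp if valid else uncued_comp
                change = rng.choice(["CW", "CCW"])
                # clockwise = decreasing angle in standard math convention
                test = (sample - spec.jnd) % 360.0 if change == "CW" else (sample + spec.jnd) % 360.0
                rows.append(
                    (subject, session, ct, "valid" if valid else "invalid", coh,
                     cue_dir, sample, test, change)
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "cue_type", "validity", "coherence",
                 "cued_direction", "sample_direction", "test_direction", "change_sign"],
    )


def dprime_to_probabilities(d: float, bias: float = 0.0) -> tuple[float, float]:
    """Response probabilities of an equal-variance observer at sensitivity d'.

    Returns (p(CW response | CW change), p(CW response | CCW change)) with an
    unbiased criterion by default: Phi(d'/2 - bias) and Phi(-d'/2 - bias).
    The d' formula inverts this mapping exactly.
    """
    if d < 0:
        raise ValueError("sensitivity must be >= 0")
    return (
        float(stats.norm.cdf(d / 2.0 - bias)),
        float(stats.norm.cdf(-d / 2.0 - bias)),
    )


def simulate_responses(design: pd.DataFrame, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Attach Bernoulli responses to a design table.

    Each trial's true sensitivity is the ground-truth Naka-Rushton value for
    its cell and coherence; the clockwise-response probability follows the
    equal-variance observer given the trial's change sign. Trials are
    independent; the draw is deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    out = design.copy()
    d_true = np.empty(len(out))
    for (ct, val), idx in out.groupby(["cue_type", "validity"]).groups.items():
        if (ct, val) not in truth.curves:
            raise KeyError(f"ground truth lacks the ({ct}, {val}) cell")
        d_true[out.index.get_indexer(idx)] = truth.dprime_at(
            ct, val, out.loc[idx, "coherence"].to_numpy(float)
        )
    p_cw_cw = stats.norm.cdf(d_true / 2.0 - truth.bias)
    p_cw_ccw = stats.norm.cdf(-d_true / 2.0 - truth.bias)
    is_cw = (out["change_sign"] == "CW").to_numpy()
    p_cw = np.where(is_cw, p_cw_cw, p_cw_ccw)
    out["response"] = np.where(rng.random(len(out)) < p_cw, "CW", "CCW")
    return out


def simulate_experiment(spec: DesignSpec, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Convenience: design plus responses from one master seed."""
    s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(seed).spawn(2))
    return simulate_responses(generate_design(spec, seed=s1), truth, seed=s2)


def ground_truth_from_model(config: ModelConfig,
                            variant: Optional[str] = None,
                            coherences: Optional[Sequence[float]] = None,
                            bias: float = 0.0) -> GroundTruth:
    """Derive generator curves from a population-model configuration.

    Evaluates the model's predicted d' at the design coherence levels and
    fits the four curves jointly with a shared exponent to obtain the
    (d'max, c50) parameterization the generator needs. Non-saturating cells
    (fitted c50 above the highest design coherence) are flagged but kept.
    """
    if variant is not None:
        config = replace(config, variant=variant)
    if coherences is not None:
        config = replace(config, coherences=tuple(coherences))
    pred = predict_all(config)
    table = pred.rename(columns={"condition": "cue_type", "dprime_pred": "dprime"})
    fit = fit_crf_joint(table, slope_mode="shared")
    return GroundTruth(
        curves=dict(fit.coefficients),
        exponent=fit.exponent(),
        bias=bias,
        source=pred,
        saturation_flags=dict(fit.saturation_flags),
    )
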