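"""Link population responses to predicted coherence-response functions.

The linking model is deliberately minimal: behavioural sensitivity on validly
and invalidly cued trials is proportional to the response of the population
unit tuned to the cued and the uncued motion component respectively. A single
positive scale factor maps unit response to d'; every attentional effect on
the predicted psychometric functions therefore originates in the population
model, never in the readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .population import (
    KAPPA_BROAD_DEFAULT,
    KAPPA_NARROW_DEFAULT,
    AttentionSpec,
    DirectionGrid,
    ModelParams,
    PopulationState,
    StimulusSpec,
    Variant,
    respond,
)

__all__ = [
    "COHERENCE_LEVELS",
    "NeurometricCurve",
    "PredictedCRF",
    "ModelConfig",
    "readout_units",
    "neurometric_curve",
    "predict_crf",
    "predict_condition",
    "predict_all",
]

#: The six coherence levels of the transparent-motion study design
#: (1.6% .. 100%), shared by simulator, analysis and model fits.
COHERENCE_LEVELS: tuple[float, ...] = (0.016, 0.064, 0.128, 0.256, 0.512, 1.0)


@dataclass(frozen=True)
class NeurometricCurve:
    """Responses of the attended and unattended readout units across coherence."""

    coherences: np.ndarray
    attended_response: np.ndarray
    unattended_response: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.coherences) == len(self.attended_response) == len(self.unattended_response)):
            raise ValueError("curve arrays must share length")


@dataclass(frozen=True)
class PredictedCRF:
    """Predicted d' per coherence for one cue condition and validity."""

    condition: Literal["narrow", "broad"]
    validity: Literal["valid", "invalid"]
    coherences: np.ndarray
    predicted_dprime: np.ndarray


@dataclass(frozen=True)
class ModelConfig:
    """A complete, runnable model specification.

    Bundles the population-model constants with the study's stimulus
    geometry (two components 135 degrees apart), the attention gains for
    the narrow and broad cueing conditions, and the coherence levels at
    which predictions are evaluated. All fields mirror flat config-file
    keys and every default is overridable.
    """

    variant: Variant = "nmoa"
    params: ModelParams = field(default_factory=ModelParams)
    component_directions: tuple[float, ...] = (0.0, 135.0)
    cued_direction: float = 0.0
    band_concentration: float = 33.0
    gain_narrow: float = 0.5
    gain_broad: float = 0.5
    kappa_narrow: float = KAPPA_NARROW_DEFAULT
    kappa_broad: float = KAPPA_BROAD_DEFAULT
    coherences: tuple[float, ...] = COHERENCE_LEVELS
    n_points: int = 360

    def grid(self) -> DirectionGrid:
        return DirectionGrid(self.n_points)

    def stimulus(self, coherence: float) -> StimulusSpec:
        return StimulusSpec(
            component_directions=self.component_directions,
            coherence=coherence,
            band_concentration=self.band_concentration,
        )

    def attention(self, condition: str) -> AttentionSpec:
        if condition == "narrow":
            gain, kappa = self.gain_narrow, self.kappa_narrow
        elif condition == "broad":
            gain, kappa = self.gain_broad, self.kappa_broad
        else:
            raise ValueError(f"unknown condition {condition!r}")
        return AttentionSpec(
            cued_direction=self.cued_direction,
            condition=condition,  # type: ignore[arg-type]
            gain=gain,
            concentration=kappa,
        )


def readout_units(
    grid: DirectionGrid,
    state: PopulationState,
    component_directions: Sequence[float],
    cued_direction: float,
) -> tuple[float, float]:
    """Responses of the units tuned to the cued and the uncued component.

    Components are snapped to the nearest grid point; a snap farther than a
    quarter grid step raises a warning rather than silently reading a unit
    tuned away from the component.
    """
    dirs = np.asarray(component_directions, dtype=float)
    for d in dirs:
        snapped = grid.index_of(d) * grid.spacing
        off = abs((d - snapped + 180.0) % 360.0 - 180.0)
        if off > 0.25 * grid.spacing:
            warnings.warn(
                f"component at {d:.2f} deg is {off:.2f} deg from the nearest grid point",
                stacklevel=2,
            )
    dist = np.abs((dirs - cued_direction + 180.0) % 360.0 - 180.0)
    attended_dir = dirs[int(np.argmin(dist))]
    if len(dirs) > 1:
        unattended_dir = dirs[int(np.argmax(dist))]
    else:
        unattended_dir = attended_dir
    return (
        float(state.R[grid.index_of(attended_dir)]),
        float(state.R[grid.index_of(unattended_dir)]),
    )


def neurometric_curve(
    config: ModelConfig,
    condition: Literal["narrow", "broad"],
    coherences: Optional[Sequence[float]] = None,
) -> NeurometricCurve:
    """Evaluate the two readout units across coherence with attention on the cue."""
    cs = np.asarray(coherences if coherences is not None else config.coherences, dtype=float)
    if np.any(np.diff(cs) < 0):
        raise ValueError("coherences must be sorted ascending")
    grid = config.grid()
    attn = config.attention(condition)
    att = np.empty(len(cs))
    unatt = np.empty(len(cs))
    for i, c in enumerate(cs):
        state = respond(grid, config.stimulus(c), attn, config.params, config.variant)
        att[i], unatt[i] = readout_units(
            grid, state, config.component_directions, config.cued_direction
        )
    return NeurometricCurve(coherences=cs, attended_response=att, unattended_response=unatt)


def predict_crf(
    curve: NeurometricCurve,
    scale: float,
    condition: Literal["narrow", "broad"] = "narrow",
) -> tuple[PredictedCRF, PredictedCRF]:
    """Rescale the neurometric curve into predicted valid/invalid d' curves."""
    if scale <= 0:
        raise ValueError("d' scale must be positive")
    valid = PredictedCRF(condition, "valid", curve.coherences, scale * curve.attended_response)
    invalid = PredictedCRF(condition, "invalid", curve.coherences, scale * curve.unattended_response)
    return valid, invalid


def predict_condition(
    config: ModelConfig, condition: Literal["narrow", "broad"]
) -> tuple[PredictedCRF, PredictedCRF]:
    curve = neurometric_curve(config, condition)
    return predict_crf(curve, config.params.scale, condition)


def predict_all(config: ModelConfig) -> pd.DataFrame:
    """Predicted d' for all four curves (2 conditions x 2 validities).

    Returns a tidy frame (condition, validity, coherence, dprime_pred),
    fully deterministic given the configuration.
    """
    rows = []
    for condition in ("narrow", "broad"):
        for crf in predict_condition(config, condition):
            for c, d in zip(crf.coherences, crf.predicted_dprime):
                rows.append((crf.condition, crf.validity, float(c), float(d)))
    return pd.DataFrame(rows, columns=["condition", "validity", "coherence", "dprime_pred"])


# ---------------------------------------------------------------------------
# Fast readout path for fitting loops
# ---------------------------------------------------------------------------
#
# Both the drive A*E and the pooled suppression S scale exactly as c^n, so the
# two readout units' responses across coherence reduce to scalar expressions
# once the direction-domain convolutions are done for a unit-coherence
# stimulus. This path is algebraically identical to evaluating `respond` per
# coherence (tests assert agreement to 1e-12) but orders of magnitude faster
# inside optimizer loops.

from functools import lru_cache

from .population import _kernel, circular_convolve, von_mises_profile as _vm


@lru_cache(maxsize=128)
def _unit_drive(n_points: int, components: tuple, band_k: float, rf_sigma: float) -> np.ndarray:
    grid = DirectionGrid(n_points)
    image = np.zeros(n_points)
    for d in components:
        image += _vm(grid, d, band_k)
    return circular_convolve(image, _kernel(grid, rf_sigma))


@lru_cache(maxsize=256)
def _supp_kernel(n_points: int, supp_sigma: float) -> np.ndarray:
    return _kernel(DirectionGrid(n_points), supp_sigma)


def _predict_vector(config: ModelConfig) -> np.ndarray:
    """Predicted d' in the fixed order (condition, validity, coherence)."""
    grid = config.grid()
    p = config.params
    e1 = _unit_drive(config.n_points, tuple(config.component_directions),
                     config.band_concentration, p.rf_feature_sigma)
    cs = np.asarray(config.coherences, dtype=float)
    cn = cs ** p.exponent
    sigma_n = p.norm_constant ** p.exponent

    dirs = np.asarray(config.component_directions, float)
    dist = np.abs((dirs - config.cued_direction + 180.0) % 360.0 - 180.0)
    att_dir = dirs[int(np.argmin(dist))]
    un_dir = dirs[int(np.argmax(dist))] if len(dirs) > 1 else att_dir
    i_att, i_un = grid.index_of(att_dir), grid.index_of(un_dir)

    out = []
    for condition in ("narrow", "broad"):
        attn = config.attention(condition)
        a = 1.0 + attn.gain * _vm(grid, attn.cued_direction, attn.kappa) if attn.gain > 0 \
            else np.ones(config.n_points)
        ae1 = a * e1
        s1 = circular_convolve(ae1, _supp_kernel(config.n_points, p.supp_feature_sigma))
        for validity, i in (("valid", i_att), ("invalid", i_un)):
            num = cn * ae1[i]
            if config.variant in ("nmoa", "nmoa_free"):
                denom = cn * s1[i] + sigma_n
            elif config.variant == "cin":
                g = p.cin_gain(condition)
                n_i = 1.0 + g * _vm(grid, attn.cued_direction, attn.kappa)[i] if g > 0 else 1.0
                denom = cn * s1[i] + (sigma_n / n_i if p.cin_divides else sigma_n * n_i)
            elif config.variant == "cdn":
                w = p.cdn_weight
                denom = cn * (w * ae1[i] + (1.0 - w) * s1[i]) + sigma_n
            else:
                raise ValueError(f"unknown model variant {config.variant!r}")
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            out.append(p.scale * r)
    return np.concatenate(out)


def predict_all_fast(config: ModelConfig) -> pd.DataFrame:
    """Exact fast equivalent of :func:`predict_all` (same output frame)."""
    vec = _predict_vector(config)
    cs = np.asarray(config.coherences, dtype=float)
    rows = []
    i = 0
    for condition in ("narrow", "broad"):
        for validity in ("valid", "invalid"):
            for c in cs:
                rows.append((condition, validity, float(c), float(vec[i])))
                i += 1
    return pd.DataFrame(rows, columns=["condition", "validity", "coherence", "dprime_pred"])
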