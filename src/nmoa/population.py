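"""Steady-state population responses under the normalization model of attention.

The model describes a population of direction-selective units (MT-like) whose
preferred directions tile the circle. Each unit's response is its attentionally
scaled excitatory drive divided by a normalization signal pooled over the
population plus a semi-saturation constant:

    R(theta) = A(theta) E(theta) / (S(theta) + sigma^n)

with E the stimulus drive (coherence raised to an exponent, filtered by the
unit's direction tuning), A >= 1 a multiplicative attention field, and S the
suppressive drive obtained by convolving A*E with a broad pooling filter.

Two tuned-normalization extensions are provided:

* coherence-independent tuned normalization ("cin"): attention divides the
  semi-saturation constant for units tuned near the attended direction,
  R = A E / (S + sigma^n / N(theta)), N(theta) >= 1 peaking at the cue;
* coherence-dependent self-normalization ("cdn"): each unit mixes its own
  drive into its normalization pool,
  R = A E / (w A E + (1 - w) S + sigma^n), 0 <= w <= 1.

Both reduce exactly to the base model when their extra parameter vanishes.

Space is collapsed to a single uniform channel: the modelled stimulus fills
the visual field and spatial attention is flat, so the spatial filters
contribute only a constant factor that is absorbed into the response scale.
All angles at the interface are degrees; the circular feature axis is sampled
on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DirectionGrid",
    "StimulusSpec",
    "AttentionSpec",
    "ModelParams",
    "PopulationState",
    "Variant",
    "sigma_deg_to_kappa",
    "von_mises_profile",
    "circular_convolve",
    "excitatory_drive",
    "attention_field",
    "suppressive_drive",
    "respond",
]

Variant = Literal["nmoa", "nmoa_free", "cin", "cdn"]

#: Default attention-field concentrations for the two cueing conditions.
#: kappa = 15 corresponds to roughly a 15 degree sigma (narrow focus),
#: kappa = 0.5 to roughly 90 degrees (broad focus).
KAPPA_NARROW_DEFAULT = 15.0
KAPPA_BROAD_DEFAULT = 0.5

#: Concentration of each coherent-motion band on the direction axis
#: (about 10 degrees sigma).
BAND_KAPPA_DEFAULT = 33.0


def sigma_deg_to_kappa(sigma_deg: float) -> float:
    """Convert a Gaussian sigma in degrees to a von Mises concentration.

    Uses the narrow-distribution equivalence 1/kappa ~ sigma^2 (radians).
    """
    if sigma_deg <= 0:
        raise ValueError(f"tuning width must be positive, got {sigma_deg}")
    return 1.0 / np.deg2rad(sigma_deg) ** 2


@dataclass(frozen=True)
class DirectionGrid:
    """Uniform sampling of the circular motion-direction axis in degrees."""

    n_points: int = 360

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("grid needs at least 4 points")

    @property
    def spacing(self) -> float:
        return 360.0 / self.n_points

    @property
    def directions(self) -> np.ndarray:
        return np.arange(self.n_points) * self.spacing

    def index_of(self, direction_deg: float) -> int:
        """Index of the grid point nearest ``direction_deg`` (circular)."""
        return int(np.round(direction_deg / self.spacing)) % self.n_points


@dataclass(frozen=True)
class StimulusSpec:
    """One or two coherent-motion bands embedded in noise.

    ``coherence`` plays the role of signal strength (the fraction of
    coherently moving dots); ``band_concentration`` sets each band's width
    on the direction axis.
    """

    component_directions: tuple[float, ...] = (0.0, 135.0)
    coherence: float = 1.0
    band_concentration: float = BAND_KAPPA_DEFAULT

    def __post_init__(self) -> None:
        k = len(self.component_directions)
        if k not in (1, 2):
            raise ValueError("stimulus must have 1 or 2 direction components")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError(f"coherence must lie in [0, 1], got {self.coherence}")
        if self.band_concentration <= 0:
            raise ValueError("band concentration must be positive")

    @property
    def separation(self) -> Optional[float]:
        """Minimal angular separation of the two components, or None."""
        if len(self.component_directions) < 2:
            return None
        a, b = self.component_directions[:2]
        d = abs((a - b + 180.0) % 360.0 - 180.0)
        if d <= 0:
            raise ValueError("two-component stimulus needs distinct directions")
        return d


@dataclass(frozen=True)
class AttentionSpec:
    """A feature-based attention field centred on the cued direction."""

    cued_direction: float = 0.0
    condition: Literal["narrow", "broad"] = "narrow"
    gain: float = 0.0
    concentration: Optional[float] = None  # None -> condition default

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("attentional gain must be >= 0")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("attention concentration must be positive")
        if self.condition not in ("narrow", "broad"):
            raise ValueError(f"unknown attention condition {self.condition!r}")

    @property
    def kappa(self) -> float:
        if self.concentration is not None:
            return self.concentration
        return KAPPA_NARROW_DEFAULT if self.condition == "narrow" else KAPPA_BROAD_DEFAULT


@dataclass(frozen=True)
class ModelParams:
    """All fixed and fittable model constants.

    exponent
        Power applied to coherence in the excitatory drive (``c^n``).
    norm_constant
        Semi-saturation constant sigma; ``sigma^n`` enters the denominator.
    rf_feature_sigma
        Direction-tuning width of the excitatory receptive field, degrees.
    supp_feature_sigma
        Width of the suppressive pooling filter, degrees; 180 is the broad,
        physiologically motivated default, and it is the free parameter of
        the "nmoa_free" variant.
    cdn_weight
        Self-normalization mixing weight w in [0, 1] (cdn variant only).
    cin_gain_narrow, cin_gain_broad
        Attentional reduction of the semi-saturation constant per cueing
        condition (cin variant only).
    scale
        Linear factor mapping unit response to behavioural d'.
    cin_divides
        If True (default) the cin normalization field divides sigma^n,
        weakening normalization at the attended direction; if False it
        multiplies it (the opposite sign of effect).
    """

    exponent: float = 2.0
    norm_constant: float = 0.1
    rf_feature_sigma: float = 37.0
    supp_feature_sigma: float = 180.0
    cdn_weight: float = 0.0
    cin_gain_narrow: float = 0.0
    cin_gain_broad: float = 0.0
    scale: float = 1.0
    cin_divides: bool = True

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.norm_constant < 0:
            raise ValueError("normalization constant must be >= 0")
        if self.rf_feature_sigma <= 0 or self.supp_feature_sigma <= 0:
            raise ValueError("tuning widths must be positive")
        if not 0.0 <= self.cdn_weight <= 1.0:
            raise ValueError("self-normalization weight must lie in [0, 1]")
        if self.cin_gain_narrow < 0 or self.cin_gain_broad < 0:
            raise ValueError("cin gains must be >= 0")
        if self.scale <= 0:
            raise ValueError("response scale must be positive")

    def cin_gain(self, condition: str) -> float:
        return self.cin_gain_narrow if condition == "narrow" else self.cin_gain_broad


@dataclass
class PopulationState:
    """Drives and responses over the direction grid for one configuration."""

    grid: DirectionGrid
    E: np.ndarray
    A: np.ndarray
    S: np.ndarray
    R: np.ndarray
    norm_field: Optional[np.ndarray] = None  # N(theta) when variant == "cin"

    def to_frame(self) -> pd.DataFrame:
        """Tabular dump (direction_deg, E, A, S, R) for inspection."""
        return pd.DataFrame(
            {
                "direction_deg": self.grid.directions,
                "E": self.E,
                "A": self.A,
                "S": self.S,
                "R": self.R,
            }
        )


def von_mises_profile(grid: DirectionGrid, center: float, concentration: float) -> np.ndarray:
    """Peak-normalized von Mises weights exp(kappa (cos(theta - mu) - 1)).

    The profile is circularly symmetric about ``center``, equals 1 at the
    grid point nearest ``center`` and approaches a uniform profile of ones
    as the concentration tends to zero.
    """
    if concentration <= 0:
        raise ValueError(f"von Mises concentration must be positive, got {concentration}")
    delta = np.deg2rad(grid.directions - center)
    w = np.exp(concentration * (np.cos(delta) - 1.0))
    return w / w.max()


def _kernel(grid: DirectionGrid, sigma_deg: float) -> np.ndarray:
    """Sum-normalized von Mises kernel centred on zero offset."""
    kappa = sigma_deg_to_kappa(sigma_deg)
    delta = np.deg2rad(grid.directions)  # offsets 0 .. 360-spacing, circular
    w = np.exp(kappa * (np.cos(delta) - 1.0))
    return w / w.sum()


def circular_convolve(signal: np.ndarray, kernel: np.ndarray,
                      method: Literal["fft", "direct"] = "fft") -> np.ndarray:
    """Circular convolution of two equal-length arrays on the grid.

    The direct path is the literal wraparound sum; the spectral path uses
    the FFT. Both agree to ~1e-12 and the spectral one is the default.
    """
    if signal.shape != kernel.shape:
        raise ValueError("signal and kernel must share the grid length")
    if method == "direct":
        n = len(signal)
        out = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            out[i] = np.dot(kernel, signal[(i - idx) % n])
        return out
    return np.real(np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(kernel), n=len(signal)))


def excitatory_drive(grid: DirectionGrid, stim: StimulusSpec, params: ModelParams) -> np.ndarray:
    """Stimulus drive: c^n times the band image filtered by direction tuning.

    The band image is the sum of peak-normalized von Mises bands at the
    component directions; the receptive-field filter has width
    ``rf_feature_sigma`` and unit mass, so the drive stays on the band scale.
    """
    image = np.zeros(grid.n_points)
    for d in stim.component_directions:
        image += von_mises_profile(grid, d, stim.band_concentration)
    rf = _kernel(grid, params.rf_feature_sigma)
    # the convolution of nonnegative arrays is nonnegative; clip FFT roundoff
    return stim.coherence ** params.exponent * np.maximum(circular_convolve(image, rf), 0.0)


def attention_field(grid: DirectionGrid, attn: Optional[AttentionSpec]) -> np.ndarray:
    """Multiplicative attention gain A(theta) = 1 + gamma * profile(cue)."""
    if attn is None or attn.gain == 0:
        return np.ones(grid.n_points)
    return 1.0 + attn.gain * von_mises_profile(grid, attn.cued_direction, attn.kappa)


def suppressive_drive(grid: DirectionGrid, attended_drive: np.ndarray,
                      params: ModelParams,
                      supp_sigma: Optional[float] = None) -> np.ndarray:
    """Pooled normalization signal: unit-mass filter convolved with A*E.

    The filter is sum-normalized, so the total suppressive mass equals the
    total attended drive and S has weighted-average semantics.
    """
    if np.any(attended_drive < 0):
        raise ValueError("attended drive must be nonnegative")
    kernel = _kernel(grid, supp_sigma if supp_sigma is not None else params.supp_feature_sigma)
    return np.maximum(circular_convolve(attended_drive, kernel), 0.0)


def respond(grid: DirectionGrid, stim: StimulusSpec, attn: Optional[AttentionSpec],
            params: ModelParams, variant: Variant = "nmoa") -> PopulationState:
    """Steady-state population response for one stimulus/attention setup.

    ``nmoa`` and ``nmoa_free`` share the same expression (the latter simply
    treats the suppressive width as fittable); ``cin`` divides the
    semi-saturation constant by an attention-tuned field N(theta) >= 1;
    ``cdn`` mixes each unit's own drive into its normalization pool.
    """
    if variant not in ("nmoa", "nmoa_free", "cin", "cdn"):
        raise ValueError(f"unknown model variant {variant!r}")
    E = excitatory_drive(grid, stim, params)
    A = attention_field(grid, attn)
    AE = A * E
    S = suppressive_drive(grid, AE, params)
    sigma_n = params.norm_constant ** params.exponent

    if sigma_n == 0 and not np.any(AE > 0):
        raise ZeroDivisionError(
            "response undefined: zero semi-saturation constant with zero stimulus drive"
        )

    norm_field = None
    if variant in ("nmoa", "nmoa_free"):
        denom = S + sigma_n
    elif variant == "cin":
        g = params.cin_gain(attn.condition if attn is not None else "narrow")
        if attn is not None and g > 0:
            norm_field = 1.0 + g * von_mises_profile(grid, attn.cued_direction, attn.kappa)
        else:
            norm_field = np.ones(grid.n_points)
        denom = S + (sigma_n / norm_field if params.cin_divides else sigma_n * norm_field)
    else:  # cdn
        w = params.cdn_weight
        denom = w * AE + (1.0 - w) * S + sigma_n

    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, AE / np.where(denom > 0, denom, 1.0), 0.0)
    if not np.all(np.isfinite(R)):
        raise FloatingPointError("non-finite population response")
    return PopulationState(grid=grid, E=E, A=A, S=S, R=R, norm_field=norm_field)
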