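"""Staining-signal extraction along the bisector chord.

Converts photographs to a scalar signal image, samples the signal along
the concave→convex chord, normalizes chord position to s ∈ [0, 1]
(0 = concave edge, 1 = convex edge) and aggregates per-genotype
ensembles as pointwise mean ± SD.

Signal polarity: histochemical GUS staining is *dark* on a bright
background, so with the default polarity ``"stain_dark"`` the signal is
the inverted luminance (white level − gray value): heavier staining ⇒
larger signal.  Synthetic images from :mod:`hookquant.synthetic` are
already signal-valued and should be read with ``"stain_bright"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import OutOfBoundsError, ValidationError
from .geometry import BisectorChord

#: RGB → luminance weights (the historical ImageJ/ITU-601 default).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

__all__ = [
    "IntensityProfile",
    "EnsembleSummary",
    "to_signal",
    "sample_chord",
    "normalize_resample",
    "ensemble_mean_sd",
    "read_image",
    "profiles_to_frame",
    "plot_ensembles",
]


@dataclass(frozen=True)
class IntensityProfile:
    """Signal values on the normalized concave→convex axis.

    ``positions`` is a strictly increasing grid on [0, 1] with endpoints
    exactly 0 and 1; ``values`` are non-negative signal values in native
    (arbitrary) units.
    """

    positions: np.ndarray
    values: np.ndarray
    seedling_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or val.shape != pos.shape:
            raise ValidationError("positions and values must be 1-D and equal length")
        if pos.size < 2:
            raise ValidationError("profile needs at least 2 points")
        if not (pos[0] == 0.0 and pos[-1] == 1.0):
            raise ValidationError("positions must span exactly [0, 1]")
        if not np.all(np.diff(pos) > 0):
            raise ValidationError("positions must be strictly increasing")
        if not np.all(np.isfinite(val)) or np.any(val < 0):
            raise ValidationError("values must be finite and non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class EnsembleSummary:
    """Pointwise mean ± SD of an ensemble of profiles on a common grid."""

    positions: np.ndarray
    mean_values: np.ndarray
    sd_values: np.ndarray
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("ensemble needs n >= 1")
        if np.any(np.asarray(self.sd_values) < 0):
            raise ValidationError("sd_values must be non-negative")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a numpy array (grayscale 2-D or RGB 3-D)."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _white_level(arr: np.ndarray, white_level) -> float:
    if white_level is not None:
        return float(white_level)
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 255.0


def to_signal(image, polarity: str = "stain_dark", white_level=None) -> np.ndarray:
    """Convert an RGB or grayscale image to a scalar staining-signal image.

    RGB inputs are reduced to luminance with the fixed weights
    (0.299, 0.587, 0.114).  With ``polarity="stain_dark"`` the output is
    ``white − luminance`` (white = the maximum representable value for
    integer images, 255.0 for float images unless ``white_level`` is
    given) so that heavier staining yields a larger signal.  With
    ``"stain_bright"`` the luminance is returned unchanged.  Output is
    float64 in the input's native units.
    """
    arr = np.asarray(image)
    if polarity not in ("stain_dark", "stain_bright"):
        raise ValidationError(f"unknown polarity {polarity!r}")
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValidationError(
                f"RGB image must have 3 channels, got {arr.shape[2]}"
            )
        w = np.asarray(LUMA_WEIGHTS)
        lum = arr[..., 0] * w[0] + arr[..., 1] * w[1] + arr[..., 2] * w[2]
        if np.issubdtype(arr.dtype, np.integer):
            lum = np.round(lum)
    elif arr.ndim == 2:
        lum = arr.astype(float)
    else:
        raise ValidationError("image must be 2-D grayscale or 3-channel RGB")
    if arr.size == 0:
        raise ValidationError("image is empty")
    white = _white_level(arr, white_level)
    if polarity == "stain_dark":
        return (white - lum).astype(float)
    return np.asarray(lum, dtype=float)


def sample_chord(
    signal: np.ndarray,
    chord: BisectorChord,
    step: float = 0.5,
    band_width: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the signal along a chord at equal arc-length steps.

    Returns ``(positions, values)``: positions in pixels from the concave
    point (first 0, last = chord length), values by bilinear
    interpolation.  ``band_width`` > 1 averages over that many
    perpendicular offsets spaced 1 px apart (default: single-pixel line).
    """
    img = np.asarray(signal, dtype=float)
    if img.ndim != 2:
        raise ValidationError("sample_chord expects a 2-D signal image")
    if step <= 0:
        raise ValidationError("step must be > 0")
    if band_width < 1:
        raise ValidationError("band_width must be >= 1")
    a = np.asarray(chord.concave_point, dtype=float)
    b = np.asarray(chord.convex_point, dtype=float)
    H, W = img.shape
    for name, p in (("concave_point", a), ("convex_point", b)):
        if not (0 <= p[0] <= H - 1 and 0 <= p[1] <= W - 1):
            raise OutOfBoundsError(f"chord {name} lies outside the image")
    L = chord.length
    pos = np.arange(0.0, L, step)
    if pos.size == 0 or L - pos[-1] > 1e-9:
        pos = np.append(pos, L)
    else:
        pos[-1] = L
    d = (b - a) / L
    perp = np.array([-d[1], d[0]])
    offsets = np.arange(band_width, dtype=float) - (band_width - 1) / 2.0
    acc = np.zeros_like(pos)
    for off in offsets:
        pts = a[None, :] + pos[:, None] * d[None, :] + off * perp[None, :]
        acc += map_coordinates(img, pts.T, order=1, mode="nearest")
    return pos, acc / len(offsets)


def normalize_resample(
    positions,
    values,
    n_points: int = 101,
    seedling_id: str = "",
    metadata: dict | None = None,
) -> IntensityProfile:
    """Map raw arc-length positions affinely to [0, 1] and resample onto a
    uniform ``n_points`` grid by linear interpolation.

    Endpoint values are preserved exactly.  Hook diameters vary between
    seedlings; this normalization makes profiles comparable on the common
    concave (0) → convex (1) axis.
    """
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.ndim != 1 or val.shape != pos.shape or pos.size < 2:
        raise ValidationError("raw profile needs >= 2 matching samples")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if not np.all(np.diff(pos) > 0):
        raise ValidationError("raw positions must be strictly increasing")
    s = (pos - pos[0]) / (pos[-1] - pos[0])
    s[0], s[-1] = 0.0, 1.0
    grid = np.linspace(0.0, 1.0, n_points)
    out = np.interp(grid, s, val)
    out[0], out[-1] = val[0], val[-1]
    # clip tiny negative interpolation artifacts on noisy input
    out = np.clip(out, 0.0, None)
    return IntensityProfile(
        positions=grid,
        values=out,
        seedling_id=seedling_id,
        metadata=dict(metadata or {}),
    )


def ensemble_mean_sd(profiles: list[IntensityProfile]) -> EnsembleSummary:
    """Pointwise arithmetic mean and sample SD (ddof=1) across profiles.

    All profiles must share an identical position grid.  With a single
    profile the SD is defined as 0 everywhere.
    """
    if len(profiles) < 1:
        raise ValidationError("need at least one profile")
    grid = profiles[0].positions
    for p in profiles[1:]:
        if p.positions.shape != grid.shape or not np.allclose(
            p.positions, grid, atol=1e-12, rtol=0
        ):
            raise ValidationError("profiles are not on a common grid")
    vals = np.stack([p.values for p in profiles])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    return EnsembleSummary(
        positions=grid.copy(), mean_values=mean, sd_values=sd, n=len(profiles)
    )


def profiles_to_frame(profiles: list[IntensityProfile]) -> pd.DataFrame:
    """Long-format table (seedling_id, s, value) for CSV export."""
    frames = [
        pd.DataFrame(
            {"seedling_id": p.seedling_id, "s": p.positions, "value": p.values}
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


def plot_ensembles(summaries: dict[str, EnsembleSummary], path) -> None:
    """Convenience plot of mean ± SD curves per group, written to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, summ in sorted(summaries.items()):
        ax.plot(summ.positions, summ.mean_values, label=f"{label} (n={summ.n})")
        ax.fill_between(
            summ.positions,
            summ.mean_values - summ.sd_values,
            summ.mean_values + summ.sd_values,
            alpha=0.25,
        )
    ax.set_xlabel("normalized position (0 = concave, 1 = convex)")
    ax.set_ylabel("signal (a.u.)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
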