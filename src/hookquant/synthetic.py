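"""Synthetic seedling-hook images, staining profiles and angle tables with
known ground truth.

The generator draws a stylized dark-grown seedling: a straight vertical
hypocotyl joined to a circular-arc hook of a prescribed interior angle,
ending in a short cotyledon stub.  Within the hook the staining signal
varies only across the tissue cross-section: at relative depth
u ∈ [0, 1] (0 = concave/inner edge, 1 = convex/outer edge) the signal is

    g(u) = B + S0 · exp(−λ·u)

— a baseline plus an exponential decay from the concave auxin maximum
toward the convex side — plus optional additive Gaussian pixel noise.
Because the hook is a circular arc, the bisector chord, the true hook
angle and the analytic ARDI (half-mass position of g) are all known in
closed form, so every downstream measurement can be validated against
ground truth.

Synthetic images are already signal-valued ("stain_bright" polarity):
larger pixel value = more staining.

Random number consumption order (fixed so seeds are portable):
``render_hook_image`` draws the full noise field row-major in one call;
``simulate_profile_ensemble`` draws, per seedling in order, the decay,
baseline and amplitude parameters and then the per-point noise vector;
``simulate_angle_table`` iterates groups in sorted key order and draws
``n_per_group`` angles per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DegenerateProfileError, ValidationError
from .geometry import SeedlingLandmarks
from .profile import IntensityProfile

__all__ = [
    "SyntheticHookSpec",
    "GroundTruth",
    "Scenario",
    "SCENARIOS",
    "analytic_ardi",
    "analytic_area",
    "render_hook_image",
    "simulate_profile_ensemble",
    "simulate_angle_table",
    "sample_scenario_specs",
    "write_image",
]


@dataclass(frozen=True)
class SyntheticHookSpec:
    """Parameters of one synthetic seedling image.

    Defaults describe the reference study conditions: a nearly closed
    hook (160°), 40 px tissue diameter, a staining field with baseline
    B = 150, amplitude S0 = 100 and decay λ = 3 (concave maximum) on a
    dim background, with pixel noise of SD 5 (5% of the amplitude).
    """

    image_width: int = 220
    image_height: int = 220
    hook_angle_true: float = 160.0
    tissue_half_width: float = 20.0
    gradient_decay: float = 3.0
    gradient_baseline: float = 150.0
    gradient_amplitude: float = 100.0
    noise_sd: float = 5.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.hook_angle_true <= 180.0):
            raise ValidationError("hook_angle_true must lie in [0, 180] degrees")
        if self.tissue_half_width < 2:
            raise ValidationError("tissue_half_width must be >= 2 px")
        for name in (
            "gradient_decay",
            "gradient_baseline",
            "gradient_amplitude",
            "noise_sd",
            "background_level",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.image_width < 32 or self.image_height < 32:
            raise ValidationError("image_width/image_height must be >= 32 px")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic targets implied by a :class:`SyntheticHookSpec`.

    ``ardi_true`` is None only in the degenerate no-signal case
    (B = S0 = 0), where the half-mass position is undefined.
    """

    hook_angle_true: float
    ardi_true: Optional[float]
    area_true: float
    chord_endpoints_true: Optional[tuple] = None

    def __post_init__(self):
        if self.ardi_true is not None and not (0.0 <= self.ardi_true <= 1.0):
            raise ValidationError("ardi_true must lie in [0, 1]")
        if self.area_true < 0:
            raise ValidationError("area_true must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "hook_angle_true": self.hook_angle_true,
            "ardi_true": self.ardi_true,
            "area_true": self.area_true,
        }
        if self.chord_endpoints_true is not None:
            d["chord_endpoints_true"] = [
                [float(x) for x in p] for p in self.chord_endpoints_true
            ]
        return d


def analytic_area(
    gradient_decay: float, gradient_baseline: float, gradient_amplitude: float
) -> float:
    """∫₀¹ (B + S0·e^{−λu}) du in signal·length units (unit-length axis)."""
    lam, B, S0 = gradient_decay, gradient_baseline, gradient_amplitude
    if lam == 0:
        return B + S0
    return B + S0 * (1.0 - math.exp(-lam)) / lam


def analytic_ardi(
    gradient_decay: float, gradient_baseline: float, gradient_amplitude: float
) -> float:
    """Closed-form half-mass position of the generating profile.

    Returns the unique s* ∈ [0, 1] with
    ∫₀^{s*} (B + S0·e^{−λu}) du = ½ ∫₀¹ (B + S0·e^{−λu}) du,
    located to absolute tolerance ≤ 1e−9.  A uniform profile (λ = 0 or
    S0 = 0, or B ≫ S0) gives 0.5; larger λ pulls s* toward the concave
    side.
    """
    lam, B, S0 = gradient_decay, gradient_baseline, gradient_amplitude
    if lam < 0 or B < 0 or S0 < 0:
        raise ValidationError("gradient parameters must be non-negative")
    if B + S0 <= 0:
        raise DegenerateProfileError("B = S0 = 0: profile carries no signal")
    if lam == 0 or S0 == 0:
        return 0.5
    total = B + S0 * (1.0 - math.exp(-lam)) / lam

    def cum_minus_half(s: float) -> float:
        return B * s + S0 * (1.0 - math.exp(-lam * s)) / lam - 0.5 * total

    return float(brentq(cum_minus_half, 0.0, 1.0, xtol=1e-12))


@dataclass(frozen=True)
class _Layout:
    """Internal drawing geometry derived from a spec (all in (row, col))."""

    junction: np.ndarray  # hypocotyl/arc junction J
    center: np.ndarray  # arc center C
    radius: float  # centerline radius R
    hyp_len: float
    cot_len: float

    def normal(self, t: float) -> np.ndarray:
        """Outward radial unit vector at arc parameter t (radians)."""
        return np.array([-math.sin(t), -math.cos(t)])

    def tangent(self, t: float) -> np.ndarray:
        return np.array([-math.cos(t), math.sin(t)])


def _layout(spec: SyntheticHookSpec) -> _Layout:
    H, W = spec.image_height, spec.image_width
    h = spec.tissue_half_width
    R = max(1.8 * h, round(0.22 * min(H, W)))
    hyp_len = round(0.30 * H)
    cot_len = max(10.0, 0.5 * R)
    rj, cj = 0.55 * H, 0.30 * W
    return _Layout(
        junction=np.array([rj, cj]),
        center=np.array([rj, cj + R]),
        radius=R,
        hyp_len=hyp_len,
        cot_len=cot_len,
    )


def _landmarks_and_truth(
    spec: SyntheticHookSpec, lay: _Layout
) -> tuple[SeedlingLandmarks, GroundTruth]:
    A = math.radians(spec.hook_angle_true)
    h = spec.tissue_half_width
    J, C, R = lay.junction, lay.center, lay.radius
    base = J + np.array([lay.hyp_len, 0.0])
    E = C + R * lay.normal(A)  # arc end
    tip = E + lay.cot_len * lay.tangent(A)
    n_mid = lay.normal(A / 2.0)
    concave = C + (R - h) * n_mid
    convex = C + (R + h) * n_mid
    lm = SeedlingLandmarks(
        hypocotyl_axis=(tuple(base), tuple(J)),
        cotyledon_line=(tuple(E), tuple(tip)),
        hook_vertex=tuple(concave),
    )
    if spec.gradient_baseline == 0 and spec.gradient_amplitude == 0:
        ardi = None
    else:
        ardi = analytic_ardi(
            spec.gradient_decay, spec.gradient_baseline, spec.gradient_amplitude
        )
    truth = GroundTruth(
        hook_angle_true=spec.hook_angle_true,
        ardi_true=ardi,
        area_true=analytic_area(
            spec.gradient_decay, spec.gradient_baseline, spec.gradient_amplitude
        ),
        chord_endpoints_true=(tuple(concave), tuple(convex)),
    )
    return lm, truth


def _check_fits(spec: SyntheticHookSpec, lay: _Layout, lm: SeedlingLandmarks,
                truth: GroundTruth) -> None:
    H, W = spec.image_height, spec.image_width
    h = spec.tissue_half_width
    pts = [
        np.asarray(lm.hypocotyl_axis[0]) + np.array([0.0, h]),
        np.asarray(lm.hypocotyl_axis[0]) - np.array([0.0, h]),
        np.asarray(lm.cotyledon_line[1]),
        np.asarray(truth.chord_endpoints_true[1]) + h * 0.1,
        np.asarray(truth.chord_endpoints_true[1]),
    ]
    for p in pts:
        if not (0 <= p[0] <= H - 1 and 0 <= p[1] <= W - 1):
            raise ValidationError(
                "image too small to contain the drawn seedling; "
                "increase image_width/image_height or reduce tissue_half_width"
            )


def render_hook_image(
    spec: SyntheticHookSpec,
) -> tuple[np.ndarray, GroundTruth, SeedlingLandmarks]:
    """Render one synthetic seedling.

    Returns ``(image, ground_truth, landmarks)``.  The image is float64,
    signal-valued (larger = more staining), with edge antialiasing so
    that bilinear sampling near tissue boundaries behaves like the
    continuous field.  Identical specs (including seed) yield identical
    images.
    """
    lay = _layout(spec)
    lm, truth = _landmarks_and_truth(spec, lay)
    _check_fits(spec, lay, lm, truth)

    H, W = spec.image_height, spec.image_width
    h = spec.tissue_half_width
    A = math.radians(spec.hook_angle_true)
    B, S0, lam = (
        spec.gradient_baseline,
        spec.gradient_amplitude,
        spec.gradient_decay,
    )
    C, J, R = lay.center, lay.junction, lay.radius

    rows, cols = np.meshgrid(
        np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij"
    )

    def edge_alpha(signed_inside_dist):
        # ~1 px linear blend centered on the geometric edge
        return np.clip(0.5 + signed_inside_dist, 0.0, 1.0)

    alpha = np.zeros((H, W))
    u = np.zeros((H, W))

    # hook arc: annulus sector around C
    vr, vc = rows - C[0], cols - C[1]
    rho = np.hypot(vr, vc)
    t = np.mod(np.arctan2(-vr, -vc), 2.0 * math.pi)
    in_sweep = t <= A
    a_arc = edge_alpha(rho - (R - h)) * edge_alpha((R + h) - rho)
    a_arc = np.where(in_sweep, a_arc, 0.0)
    u_arc = np.clip((rho - (R - h)) / (2.0 * h), 0.0, 1.0)
    take = a_arc > alpha
    alpha = np.where(take, a_arc, alpha)
    u = np.where(take, u_arc, u)

    # hypocotyl: vertical band below J; concave side faces the arc center
    off = cols - J[1]
    along = rows - J[0]
    a_hyp = (
        edge_alpha(h - np.abs(off))
        * edge_alpha(along)
        * edge_alpha(lay.hyp_len - along)
    )
    u_hyp = np.clip((h - off) / (2.0 * h), 0.0, 1.0)
    take = a_hyp > alpha
    alpha = np.where(take, a_hyp, alpha)
    u = np.where(take, u_hyp, u)

    # cotyledon stub: band along the end tangent
    E = C + R * lay.normal(A)
    that, nhat = lay.tangent(A), lay.normal(A)
    wr, wc = rows - E[0], cols - E[1]
    along_c = wr * that[0] + wc * that[1]
    perp_c = wr * nhat[0] + wc * nhat[1]
    a_cot = (
        edge_alpha(h - np.abs(perp_c))
        * edge_alpha(along_c)
        * edge_alpha(lay.cot_len - along_c)
    )
    u_cot = np.clip((perp_c + h) / (2.0 * h), 0.0, 1.0)
    take = a_cot > alpha
    alpha = np.where(take, a_cot, alpha)
    u = np.where(take, u_cot, u)

    tissue_val = B + S0 * np.exp(-lam * u)
    img = alpha * tissue_val + (1.0 - alpha) * spec.background_level

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 65535.0)
    return img, truth, lm


def write_image(path, image: np.ndarray) -> None:
    """Write a signal image as 8-bit (if it fits) or 16-bit grayscale PNG/TIFF."""
    img = np.asarray(image, dtype=float)
    img = np.clip(np.round(img), 0, 65535)
    dtype = np.uint8 if img.max() <= 255 else np.uint16
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.astype(dtype))


def simulate_profile_ensemble(
    n: int,
    decay_mean: float = 3.0,
    decay_sd: float = 0.0,
    baseline_mean: float = 150.0,
    baseline_sd: float = 0.0,
    amplitude_mean: float = 100.0,
    amplitude_sd: float = 0.0,
    noise_sd: float = 5.0,
    n_points: int = 101,
    seed: int = 0,
) -> tuple[list[IntensityProfile], list[GroundTruth]]:
    """Draw ``n`` independent 1-D staining profiles on the [0, 1] grid.

    Per-seedling parameters (λ, B, S0) are Gaussian around the given
    means (clipped at 0); per-point Gaussian noise of SD ``noise_sd`` is
    added and values are clipped at 0.  Each profile's ground truth
    carries the analytic ARDI and area for its own drawn parameters.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_points)
    profiles, truths = [], []
    for i in range(n):
        lam = max(0.0, float(rng.normal(decay_mean, decay_sd))) if decay_sd else decay_mean
        B = max(0.0, float(rng.normal(baseline_mean, baseline_sd))) if baseline_sd else baseline_mean
        S0 = max(0.0, float(rng.normal(amplitude_mean, amplitude_sd))) if amplitude_sd else amplitude_mean
        clean = B + S0 * np.exp(-lam * grid)
        noisy = clean + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
        profiles.append(
            IntensityProfile(
                positions=grid.copy(),
                values=np.clip(noisy, 0.0, None),
                seedling_id=f"sim_{i:03d}",
            )
        )
        truths.append(
            GroundTruth(
                hook_angle_true=float("nan"),
                ardi_true=analytic_ardi(lam, B, S0),
                area_true=analytic_area(lam, B, S0),
            )
        )
    return profiles, truths


def _normalize_group_means(group_means: dict) -> dict[tuple, float]:
    out = {}
    for key, mean in group_means.items():
        if not isinstance(key, tuple):
            raise ValidationError(
                "group_means keys must be (genotype, concentration) or "
                "(genotype, day, concentration) tuples"
            )
        if len(key) == 2:
            genotype, conc = key
            day = 2
        elif len(key) == 3:
            genotype, day, conc = key
        else:
            raise ValidationError(f"bad group key {key!r}")
        if not (0.0 <= mean <= 180.0):
            raise ValidationError(
                f"group mean for {key!r} must lie in [0, 180] degrees"
            )
        if conc < 0:
            raise ValidationError("concentrations must be >= 0")
        out[(str(genotype), int(day), float(conc))] = float(mean)
    return out


def simulate_angle_table(
    group_means: dict,
    noise_sd: float,
    n_per_group: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a hook-angle measurement table.

    ``group_means`` maps ``(genotype, concentration)`` or
    ``(genotype, day, concentration)`` to the group mean angle in
    degrees.  Each group receives ``n_per_group`` Gaussian records
    (SD ``noise_sd``) clipped to the valid [0, 180] range.  Columns:
    seedling_id, genotype, day, concentration_uM, angle_deg.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2 (ANOVA needs >= 2 per group)")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    means = _normalize_group_means(group_means)
    rng = np.random.default_rng(seed)
    records = []
    for (genotype, day, conc) in sorted(means):
        mu = means[(genotype, day, conc)]
        angles = (
            rng.normal(mu, noise_sd, n_per_group)
            if noise_sd > 0
            else np.full(n_per_group, mu)
        )
        angles = np.clip(angles, 0.0, 180.0)
        for i, ang in enumerate(angles):
            records.append(
                {
                    "seedling_id": f"{genotype}_d{day}_c{conc:g}_{i:03d}",
                    "genotype": genotype,
                    "day": day,
                    "concentration_uM": conc,
                    "angle_deg": float(ang),
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class Scenario:
    """Named generator parameter set emulating one genotype condition."""

    gradient_decay: float
    angle_mean: float = 160.0
    angle_sd: float = 6.0
    half_width_mean: float = 20.0
    half_width_sd: float = 2.0
    gradient_baseline: float = 150.0
    gradient_amplitude: float = 100.0
    noise_sd: float = 5.0
    background_level: float = 10.0
    image_size: int = 220


#: Registered scenarios.  "wt_like": steep concave-maximum gradient of a
#: well-formed hook; "hyl1_like": flattened gradient and a more open hook;
#: "concave_shifted": hyperpolarized gradient; "flat_gradient": uniform
#: staining (analytic ARDI exactly 0.5).
SCENARIOS: dict[str, Scenario] = {
    "wt_like": Scenario(gradient_decay=3.0, angle_mean=160.0, angle_sd=6.0),
    "hyl1_like": Scenario(gradient_decay=0.3, angle_mean=110.0, angle_sd=10.0),
    "concave_shifted": Scenario(gradient_decay=6.0, angle_mean=168.0, angle_sd=4.0),
    "flat_gradient": Scenario(gradient_decay=0.0, angle_mean=150.0, angle_sd=6.0),
}


def sample_scenario_specs(
    scenario: str | Scenario,
    n: int,
    seed: int = 0,
    noise_sd: Optional[float] = None,
) -> list[SyntheticHookSpec]:
    """Draw ``n`` per-seedling specs for a scenario.

    Hook angle and tissue half-width vary between seedlings (Gaussian,
    clipped to valid ranges); each spec receives its own child seed drawn
    from the scenario stream.  ``noise_sd`` overrides the scenario's
    pixel-noise level (e.g. 0 for closure tests).
    """
    if isinstance(scenario, str):
        try:
            sc = SCENARIOS[scenario]
        except KeyError:
            raise ValidationError(
                f"unknown scenario {scenario!r}; registered: "
                + ", ".join(sorted(SCENARIOS))
            ) from None
    else:
        sc = scenario
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        angle = float(np.clip(rng.normal(sc.angle_mean, sc.angle_sd), 15.0, 178.0))
        hw = float(np.clip(rng.normal(sc.half_width_mean, sc.half_width_sd), 8.0, 30.0))
        child_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(
            SyntheticHookSpec(
                image_width=sc.image_size,
                image_height=sc.image_size,
                hook_angle_true=angle,
                tissue_half_width=hw,
                gradient_decay=sc.gradient_decay,
                gradient_baseline=sc.gradient_baseline,
                gradient_amplitude=sc.gradient_amplitude,
                noise_sd=sc.noise_sd if noise_sd is None else noise_sd,
                background_level=sc.background_level,
                seed=child_seed,
            )
        )
    return specs
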