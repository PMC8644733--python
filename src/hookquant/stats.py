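"""Summary statistics and group comparisons for hook staining gradients.

Implements the two per-seedling summaries read off the normalized
concave→convex profile g(s):

* total integrated intensity, A = ∫₀¹ g(s) ds (trapezoid rule), and
* the Auxin Response Distribution Index (ARDI): the smallest s* at which
  the cumulative integral reaches A/2.  ARDI = 0.5 for uniform staining;
  values below 0.5 indicate signal concentrated toward the concave side.

Group comparisons follow the field's standard recipe: one-way or two-way
fixed-effects ANOVA followed by Tukey's HSD post-test, with a compact
letter display (groups sharing a letter are not significantly different
at the chosen alpha).  Dose-response strength is summarized as the slope
of the mean hook angle per decade of inhibitor concentration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

from .errors import (
    DegenerateProfileError,
    MissingCellError,
    ValidationError,
)
from .profile import IntensityProfile

__all__ = [
    "GradientSummary",
    "ComparisonResult",
    "integrated_intensity",
    "ardi",
    "one_way_anova_tukey",
    "two_way_anova_tukey",
    "compact_letter_display",
    "dose_response_slope",
    "minimum_effective_concentration",
    "read_angle_table",
    "validate_angle_table",
    "summarize_profiles",
]

ANGLE_TABLE_COLUMNS = ["seedling_id", "genotype", "day", "concentration_uM", "angle_deg"]


@dataclass(frozen=True)
class GradientSummary:
    """Per-seedling integrated intensity and ARDI."""

    seedling_id: str
    area: float
    ardi: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.ardi <= 1.0):
            raise ValidationError("ardi must lie in [0, 1]")
        if self.area < 0:
            raise ValidationError("area must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    """ANOVA + Tukey HSD outcome for one set of groups.

    ``pairwise_p`` maps unordered group pairs (as sorted 2-tuples) to
    Tukey HSD p-values; ``letters`` is the compact letter display:
    groups sharing any letter do not differ at ``alpha``.
    """

    groups: tuple
    n_per_group: dict
    means: dict
    anova: pd.DataFrame
    pairwise_p: dict
    letters: dict
    alpha: float
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": str(g),
                "n": self.n_per_group[g],
                "mean": self.means[g],
                "letters": self.letters[g],
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": str(a), "group_b": str(b), "p_tukey": p}
            for (a, b), p in sorted(self.pairwise_p.items(), key=lambda kv: kv[0])
        ]
        return pd.DataFrame(rows)


def _profile_arrays(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, IntensityProfile):
        return profile.positions, profile.values
    pos, val = profile
    return np.asarray(pos, dtype=float), np.asarray(val, dtype=float)


def integrated_intensity(profile) -> float:
    """Trapezoidal integral of the profile over s ∈ [0, 1].

    Linear in the values; non-negative for non-negative profiles.
    """
    pos, val = _profile_arrays(profile)
    return float(np.trapezoid(val, pos))


def ardi(profile) -> float:
    """Auxin Response Distribution Index of a profile.

    The smallest s* at which the cumulative trapezoidal integral reaches
    half the total, with linear interpolation of the cumulative inside
    the bracketing grid interval.  Scale-invariant: multiplying the
    values by any positive constant leaves ARDI unchanged.

    Raises
    ------
    DegenerateProfileError
        If the profile integrates to zero (no signal).
    """
    pos, val = _profile_arrays(profile)
    cum = cumulative_trapezoid(val, pos, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise DegenerateProfileError("profile has zero total intensity")
    half = 0.5 * total
    k = int(np.searchsorted(cum, half, side="left"))
    if k == 0:
        return float(pos[0])
    dc = cum[k] - cum[k - 1]
    if dc <= 0:  # flat cumulative plateau: resolve to the leftmost point
        return float(pos[k - 1])
    frac = (half - cum[k - 1]) / dc
    return float(pos[k - 1] + frac * (pos[k] - pos[k - 1]))


def summarize_profiles(profiles: Sequence[IntensityProfile]) -> list[GradientSummary]:
    """Per-seedling area and ARDI for a batch of profiles."""
    return [
        GradientSummary(
            seedling_id=p.seedling_id,
            area=integrated_intensity(p),
            ardi=ardi(p),
            metadata=dict(p.metadata),
        )
        for p in profiles
    ]


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def compact_letter_display(groups: Sequence, significant_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Guarantees: groups sharing a letter are NOT in ``significant_pairs``;
    any pair not in ``significant_pairs`` shares at least one letter.
    """
    groups = list(groups)
    sig = {tuple(sorted(p, key=str)) for p in significant_pairs}
    cols: list[set] = [set(groups)]
    for pair in sorted(sig, key=str):
        a, b = pair
        new_cols: list[set] = []
        for col in cols:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns that are subsets (or duplicates) of another
        kept: list[set] = []
        for i, c in enumerate(new_cols):
            absorbed = False
            for j, d in enumerate(new_cols):
                if i == j:
                    continue
                if c < d or (c == d and i > j):
                    absorbed = True
                    break
            if not absorbed and c:
                kept.append(c)
        cols = kept
    order = {g: i for i, g in enumerate(groups)}
    cols.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for idx, col in enumerate(cols):
        letter = _letter(idx)
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def _letter(idx: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    idx += 1
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out = alphabet[rem] + out
    return out


def _coerce_groups(
    data: Union[Mapping, pd.DataFrame],
    value_col: str = "value",
    group_col: str = "group",
) -> dict:
    if isinstance(data, pd.DataFrame):
        grouped = {
            g: np.asarray(sub[value_col], dtype=float)
            for g, sub in data.groupby(group_col, sort=True)
        }
    else:
        grouped = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(grouped) < 2:
        raise ValidationError("need at least 2 groups")
    for g, v in grouped.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"group {g!r} contains non-finite values")
    return grouped


def one_way_anova_tukey(
    data: Union[Mapping, pd.DataFrame],
    alpha: float = 0.05,
    value_col: str = "value",
    group_col: str = "group",
) -> ComparisonResult:
    """One-way ANOVA with Tukey's HSD post-test and letter display.

    ``data`` is either a mapping ``group -> 1-D array`` or a long
    DataFrame with ``value_col``/``group_col`` columns.  Tukey p-values
    come from the studentized-range distribution (Tukey–Kramer for
    unequal group sizes).
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    grouped = _coerce_groups(data, value_col, group_col)
    labels = sorted(grouped, key=str)
    samples = [grouped[g] for g in labels]
    f_stat, p_omni = sps.f_oneway(*samples)
    tk = sps.tukey_hsd(*samples)
    pairwise = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        key = tuple(sorted((labels[i], labels[j]), key=str))
        pairwise[key] = float(tk.pvalue[i, j])
    sig = [k for k, p in pairwise.items() if p < alpha]
    letters = compact_letter_display(labels, sig)
    anova = pd.DataFrame(
        {"source": ["group"], "F": [float(f_stat)], "p": [float(p_omni)]}
    )
    return ComparisonResult(
        groups=tuple(labels),
        n_per_group={g: int(grouped[g].size) for g in labels},
        means={g: float(grouped[g].mean()) for g in labels},
        anova=anova,
        pairwise_p=pairwise,
        letters=letters,
        alpha=alpha,
    )


def two_way_anova_tukey(
    data: pd.DataFrame,
    value_col: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Balanced two-way fixed-effects ANOVA with interaction, plus Tukey
    HSD over all cell means.

    Requires >= 2 levels per factor and the same cell count (>= 2) in
    every factor combination; with a balanced design the sums of squares
    are unambiguous (all classical SS types coincide).  Cells are labeled
    ``"<a>:<b>"`` in the pairwise results and letter display.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    df = data[[value_col, factor_a, factor_b]].copy()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValidationError("each factor needs >= 2 levels")
    levels_a = sorted(df[factor_a].unique(), key=str)
    levels_b = sorted(df[factor_b].unique(), key=str)
    counts = df.groupby([factor_a, factor_b]).size()
    for a in levels_a:
        for b in levels_b:
            n = int(counts.get((a, b), 0))
            if n < 2:
                raise MissingCellError(
                    f"cell ({factor_a}={a!r}, {factor_b}={b!r}) has {n} "
                    "observations; need >= 2"
                )
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index[0]
        raise ValidationError(
            f"unbalanced design: cell ({factor_a}={bad[0]!r}, "
            f"{factor_b}={bad[1]!r}) differs in size; two-way ANOVA here "
            "requires equal cell counts"
        )

    work = df.rename(columns={value_col: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = pd.DataFrame(
        {
            "source": [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"],
            "sum_sq": table["sum_sq"].to_numpy(),
            "df": table["df"].to_numpy(),
            "F": table["F"].to_numpy(),
            "p": table["PR(>F)"].to_numpy(),
        }
    )

    cells = {
        f"{a}:{b}": df.loc[(df[factor_a] == a) & (df[factor_b] == b), value_col]
        .to_numpy(dtype=float)
        for a in levels_a
        for b in levels_b
    }
    labels = sorted(cells, key=str)
    tk = sps.tukey_hsd(*[cells[c] for c in labels])
    pairwise = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        key = tuple(sorted((labels[i], labels[j]), key=str))
        pairwise[key] = float(tk.pvalue[i, j])
    sig = [k for k, p in pairwise.items() if p < alpha]
    letters = compact_letter_display(labels, sig)
    return ComparisonResult(
        groups=tuple(labels),
        n_per_group={c: int(cells[c].size) for c in labels},
        means={c: float(cells[c].mean()) for c in labels},
        anova=anova,
        pairwise_p=pairwise,
        letters=letters,
        alpha=alpha,
        note="tukey over all genotype x treatment cells",
    )


# ---------------------------------------------------------------------------
# Angle tables and dose response


def validate_angle_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the hook-angle table contract and return a copy."""
    missing = [c for c in ANGLE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"angle table missing columns: {missing}")
    df = table[ANGLE_TABLE_COLUMNS].copy()
    ang = df["angle_deg"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ang)) or np.any(ang < 0) or np.any(ang > 180):
        raise ValidationError("angle_deg values must lie in [0, 180]")
    conc = df["concentration_uM"].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentration_uM values must be >= 0")
    return df


def read_angle_table(path) -> pd.DataFrame:
    """Read and validate an angle table CSV with the required header
    (seedling_id, genotype, day, concentration_uM, angle_deg)."""
    return validate_angle_table(pd.read_csv(path))


def dose_response_slope(
    table: pd.DataFrame,
    c_low: float,
    c_high: float,
    day: Optional[int] = None,
) -> pd.DataFrame:
    """Per-genotype dose-response slope in degrees per log10 µM.

    slope = (mean angle at c_high − mean angle at c_low)
            / (log10 c_high − log10 c_low)

    computed per genotype (and per day if ``day`` is None).  A more
    negative slope means a stronger response to the transport inhibitor
    (hook closure lost faster per decade of concentration).  The mock
    treatment (c = 0) cannot sit on the log axis, so both concentrations
    must be positive.
    """
    df = validate_angle_table(table)
    if c_low <= 0 or c_high <= 0:
        raise ValidationError(
            "c_low and c_high must be > 0 (mock c=0 is excluded from the log scale)"
        )
    if c_high == c_low:
        raise ValidationError("c_low and c_high must differ")
    if day is not None:
        df = df[df["day"] == day]
        if df.empty:
            raise MissingCellError(f"no rows for day {day}")
    denom = np.log10(c_high) - np.log10(c_low)
    rows = []
    for (genotype, d), sub in df.groupby(["genotype", "day"], sort=True):
        lo = sub.loc[np.isclose(sub["concentration_uM"], c_low), "angle_deg"]
        hi = sub.loc[np.isclose(sub["concentration_uM"], c_high), "angle_deg"]
        if lo.empty or hi.empty:
            missing = c_low if lo.empty else c_high
            raise MissingCellError(
                f"genotype {genotype!r} day {d}: no rows at {missing} uM"
            )
        rows.append(
            {
                "genotype": genotype,
                "day": d,
                "slope_deg_per_decade": float((hi.mean() - lo.mean()) / denom),
                "n_low": int(lo.size),
                "n_high": int(hi.size),
            }
        )
    return pd.DataFrame(rows)


def minimum_effective_concentration(
    table: pd.DataFrame,
    alpha: float = 0.05,
    day: Optional[int] = None,
) -> pd.DataFrame:
    """Smallest concentration whose angle distribution differs from mock.

    Per genotype (and day), runs one-way ANOVA + Tukey across all
    concentration groups (mock = concentration 0 must be present) and
    reports the smallest nonzero concentration whose Tukey comparison
    against mock is significant at ``alpha``; NaN when none differs.
    """
    df = validate_angle_table(table)
    if day is not None:
        df = df[df["day"] == day]
        if df.empty:
            raise MissingCellError(f"no rows for day {day}")
    rows = []
    for (genotype, d), sub in df.groupby(["genotype", "day"], sort=True):
        concs = sorted(sub["concentration_uM"].unique())
        if 0.0 not in concs:
            raise ValidationError(
                f"genotype {genotype!r} day {d}: mock group (concentration 0) missing"
            )
        if len(concs) < 2:
            raise ValidationError(
                f"genotype {genotype!r} day {d}: need at least one nonzero concentration"
            )
        groups = {
            c: sub.loc[sub["concentration_uM"] == c, "angle_deg"].to_numpy(float)
            for c in concs
        }
        res = one_way_anova_tukey(groups, alpha=alpha)
        mec = float("nan")
        for c in concs:
            if c == 0.0:
                continue
            p = res.pairwise_p[tuple(sorted((0.0, c), key=str))]
            if p < alpha:
                mec = c
                break
        rows.append({"genotype": genotype, "day": d, "mec_uM": mec})
    return pd.DataFrame(rows)
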