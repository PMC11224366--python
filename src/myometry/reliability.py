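"""Agreement and repeatability statistics for segmentation-derived metrics.

Covers the validation battery used for AI muscle segmentations: overlap
coefficients between label maps, relative volume error and fat-fraction
difference between repeat observations, Bland-Altman agreement with fixed-
and proportional-bias tests, and Spearman rank correlation against ordinal
clinical ratings.

A note on overlap naming: in parts of the muscle-MRI literature the
intersection-over-union ratio |A∩B| / |A∪B| is printed under the name
"Dice". That ratio is the Jaccard index; the Dice coefficient proper is
2|A∩B| / (|A| + |B|). Both are computed and reported here — ``dice`` is the
standard Dice and ``jaccard`` the IoU — related by dice = 2j / (1 + j), so
results remain comparable with either convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MuscleLabelMap
from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    UndefinedOverlapError,
)

logger = logging.getLogger("myometry")


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    code: int
    dice: float
    jaccard: float


def overlap(map_a: MuscleLabelMap, map_b: MuscleLabelMap, code: int) -> OverlapResult:
    """Dice and Jaccard overlap of one code between two label maps."""
    if map_a.labels.shape != map_b.labels.shape:
        raise AlignmentError("label maps are on different grids")
    a = map_a.mask(code)
    b = map_b.mask(code)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise UndefinedOverlapError(f"code {code} empty in both maps")
    inter = int(np.count_nonzero(a & b))
    union = na + nb - inter
    return OverlapResult(code=code, dice=2.0 * inter / (na + nb), jaccard=inter / union)


# ---------------------------------------------------------------------------
# Paired error metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPair:
    """Two repeat observations of the same metric for the same muscle."""

    code: int
    metric: str
    value_a: float
    value_b: float


def abs_volume_error(a: float, b: float) -> float:
    """Absolute volume difference as percent of the pair mean."""
    if a <= 0 or b <= 0 or not (np.isfinite(a) and np.isfinite(b)):
        raise DomainError(f"volumes must be positive and finite, got ({a}, {b})")
    return 100.0 * abs(a - b) / ((a + b) / 2.0)


def abs_ff_difference(a: float, b: float) -> float:
    """Absolute fat-fraction difference in percentage points."""
    for v in (a, b):
        if not np.isfinite(v) or not 0.0 <= v <= 100.0:
            raise DomainError(f"fat fractions must lie in [0, 100], got ({a}, {b})")
    return abs(a - b)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    """Agreement between paired observations.

    Differences are oriented (second - first). Fixed bias is tested with a
    one-sample t on the differences (df = n-1); proportional bias with the
    least-squares slope of difference on pair mean (df = n-2). Limits of
    agreement are bias +/- 1.96 SD.
    """

    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    t_fixed: float
    df_fixed: int
    p_fixed: float
    slope: float
    intercept: float
    t_slope: float
    df_slope: int
    p_slope: float
    degenerate: bool = False


def bland_altman(
    pairs: list[RepeatPair] | list[tuple[float, float]],
    one_sided: bool = False,
) -> BlandAltmanResult:
    """Bland-Altman analysis of (first, second) observation pairs."""
    if pairs and isinstance(pairs[0], RepeatPair):
        ab = np.array([(p.value_a, p.value_b) for p in pairs], dtype=float)
    else:
        ab = np.asarray(pairs, dtype=float)
    n = len(ab)
    if n < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 pairs, got {n}")
    diff = ab[:, 1] - ab[:, 0]
    mean = ab.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))

    degenerate = sd == 0.0
    if degenerate:
        t_fixed = p_fixed = float("nan")
    else:
        t_fixed = bias / (sd / np.sqrt(n))
        p_fixed = float(stats.t.sf(abs(t_fixed), n - 1) * (1 if one_sided else 2))

    if np.ptp(mean) == 0.0 or degenerate:
        # no spread in means, or identical pairs: slope is 0 by convention
        # when diffs are constant, undefined t either way
        slope = 0.0 if degenerate or np.ptp(diff) == 0 else float("nan")
        intercept = bias
        t_slope = p_slope = float("nan")
    else:
        fit = stats.linregress(mean, diff)
        slope, intercept = float(fit.slope), float(fit.intercept)
        if fit.stderr == 0:
            t_slope = float("inf") if slope != 0 else 0.0
            p_slope = 0.0 if slope != 0 else 1.0
        else:
            t_slope = slope / fit.stderr
            p_slope = float(stats.t.sf(abs(t_slope), n - 2) * (1 if one_sided else 2))
    return BlandAltmanResult(
        n=n, bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        t_fixed=float(t_fixed) if not degenerate else float("nan"),
        df_fixed=n - 1, p_fixed=p_fixed,
        slope=slope, intercept=intercept,
        t_slope=float(t_slope), df_slope=n - 2, p_slope=float(p_slope),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    exact: bool  # p from exhaustive permutation rather than t-approximation
    defined: bool = True


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling.

    The p-value is computed by exhaustive permutation of one variable for
    n <= ``exact_max_n`` (two-sided: fraction of permutations with |rho| at
    least the observed), and by the t approximation
    t = rho sqrt((n-2)/(1-rho^2)), df = n-2, otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1D sequences")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"Spearman needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: Spearman correlation undefined")
        return SpearmanResult(rho=float("nan"), p=float("nan"), n=n, exact=False, defined=False)
    rho = _rank_rho(x, y)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = np.array([_rank_rho(x, y[p]) for p in perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p=p, n=n, exact=True)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho=rho, p=0.0, n=n, exact=False)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p=p, n=n, exact=False)


# ---------------------------------------------------------------------------
# Ordinal rating maps
# ---------------------------------------------------------------------------

#: FF (%) upper bounds for fat ratings 1..5; above the last bound -> 6.
#: 30 and 60 are the scale's printed anchors; the sub-30 splits (5, 15) and
#: the 85 split between ratings 5 and 6 have no printed anchors and are
#: package defaults.
FAT_RATING_BOUNDS = (5.0, 15.0, 30.0, 60.0, 85.0)


def fat_rating_from_ff(ff: float, bounds: tuple[float, ...] = FAT_RATING_BOUNDS) -> int:
    """Map a volumetric FF (%) to the ordinal 1-6 fat rating (monotone step)."""
    if not np.isfinite(ff) or not 0 <= ff <= 100:
        raise DomainError(f"FF must lie in [0, 100], got {ff}")
    rating = 1
    for b in bounds:
        if ff >= b:
            rating += 1
    return rating


def stir_grade_from_fraction(
    stir_pct: float,
    mild_diffuse: bool = False,
    zero_floor: float = 1.0,
) -> int:
    """Map a STIR content (%) to the ordinal 0-4 grade.

    Grade 1 ("mild diffuse elevation") is categorical, not a volume
    fraction; it is asserted via ``mild_diffuse`` rather than inferred from
    the percentage. Otherwise: below ``zero_floor`` -> 0, under 30% -> 2,
    30-60% -> 3, above 60% -> 4.
    """
    if not np.isfinite(stir_pct) or not 0 <= stir_pct <= 100:
        raise DomainError(f"STIR content must lie in [0, 100], got {stir_pct}")
    if mild_diffuse and stir_pct < 30.0:
        return 1
    if stir_pct < zero_floor:
        return 0
    if stir_pct < 30.0:
        return 2
    if stir_pct <= 60.0:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

VALID_DESIGNS = ("scan_rescan", "inter_observer", "intra_observer", "ai_vs_vetted")


@dataclass
class ReliabilityReport:
    design: str
    per_muscle: pd.DataFrame
    volume_agreement: BlandAltmanResult | None  # None when < 3 pooled pairs
    ff_agreement: BlandAltmanResult | None
    sign_convention: str = "second - first"


def reliability_report(
    runs: list[dict[int, "CompositionMetrics"]],  # noqa: F821 - forward ref
    design: str,
    label_maps: list[MuscleLabelMap] | None = None,
) -> ReliabilityReport:
    """Per-muscle and pooled agreement across >= 2 repeat metric tables.

    ``runs`` are per-muscle composition tables keyed by code (e.g. from
    ``composition.composition_table``). All run pairs contribute; muscles
    must be shared across runs with positive volume everywhere. When label
    maps are supplied, Dice/Jaccard overlap is added per muscle.
    """
    if design not in VALID_DESIGNS:
        raise DomainError(f"design must be one of {VALID_DESIGNS}, got {design!r}")
    if len(runs) < 2:
        raise InsufficientDataError("need at least two runs")
    shared = set(runs[0])
    for run in runs[1:]:
        shared &= set(run)
    shared_codes = sorted(
        c for c in shared if all(run[c].boundary_volume > 0 for run in runs)
    )
    if len(shared_codes) < 2:
        raise InsufficientDataError(f"only {len(shared_codes)} shared muscles with data")

    run_pairs = list(itertools.combinations(range(len(runs)), 2))
    rows = []
    vol_pairs: list[tuple[float, float]] = []
    ff_pairs: list[tuple[float, float]] = []
    for code in shared_codes:
        verrs, fdiffs, dices, jaccs = [], [], [], []
        for i, j in run_pairs:
            a, b = runs[i][code], runs[j][code]
            verrs.append(abs_volume_error(a.boundary_volume, b.boundary_volume))
            vol_pairs.append((a.boundary_volume, b.boundary_volume))
            if np.isfinite(a.fat_fraction) and np.isfinite(b.fat_fraction):
                fdiffs.append(abs_ff_difference(a.fat_fraction, b.fat_fraction))
                ff_pairs.append((a.fat_fraction, b.fat_fraction))
            if label_maps is not None:
                ov = overlap(label_maps[i], label_maps[j], code)
                dices.append(ov.dice)
                jaccs.append(ov.jaccard)
        ref = runs[0][code]
        row = {
            "code": code, "muscle": ref.name, "side": ref.side,
            "abs_volume_error_mean": float(np.mean(verrs)),
            "abs_volume_error_sd": float(np.std(verrs, ddof=1)) if len(verrs) > 1 else 0.0,
            "abs_ff_difference_mean": float(np.mean(fdiffs)) if fdiffs else float("nan"),
            "abs_ff_difference_sd": float(np.std(fdiffs, ddof=1)) if len(fdiffs) > 1 else 0.0,
        }
        if label_maps is not None:
            row["dice_mean"] = float(np.mean(dices))
            row["jaccard_mean"] = float(np.mean(jaccs))
        rows.append(row)

    per_muscle = pd.DataFrame(rows).sort_values("code").reset_index(drop=True)
    vol_ba = bland_altman(vol_pairs) if len(vol_pairs) >= 3 else None
    ff_ba = bland_altman(ff_pairs) if len(ff_pairs) >= 3 else None
    logger.info("reliability report (%s): %d muscles, %d run pairs; differences are second - first",
                design, len(shared_codes), len(run_pairs))
    return ReliabilityReport(
        design=design, per_muscle=per_muscle,
        volume_agreement=vol_ba, ff_agreement=ff_ba,
    )
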