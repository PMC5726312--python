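"""Agreement statistics between visually interpreted and mapped pressure scores.

The mapped product is checked against plots whose human pressure was scored
by visual interpretation of high-resolution satellite imagery.  Both score
sets are normalised to a 0-1 scale and compared with:

* RMSE of the normalised scores;
* Cohen's kappa on scores discretised into equal-width ordinal classes
  (``ceil(1/tolerance)`` classes over [0, 1], right-closed at 1), the
  chance-corrected analogue of the "within 20%" match band;
* a within / above / below decomposition at the tolerance band
  (|difference| <= tolerance counts as agreement, boundary inclusive);
* map-intersection checks: inside wilderness blocks, the share of plots
  scored exactly pressure free and the share within tolerance of zero;
  inside Last of the Wild blocks, the share below the plot's biorealm
  threshold and the share within tolerance above it.

The published kappa's exact categorisation is not recoverable from its
description; the equal-width-class construction here is a documented choice,
and the tolerance is a parameter so 15% / 25% sensitivity bands are a flag
away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .grid_core import AGREEMENT_TOLERANCE, SCORE_MAX, PressureGrid


class ValidationError(ValueError):
    """Malformed validation input (length mismatch, range, missing realm)."""


@dataclass
class ValidationPlot:
    """One visually scored validation plot.

    ``visual_score_norm`` and ``hfp_score_norm`` live on the normalised
    0-1 scale; ``hfp_score_norm`` is filled by overlay on a pressure grid.
    """

    plot_id: int | str
    row: int
    col: int
    visual_score_norm: float
    certain: bool
    hfp_score_norm: float | None = None
    realm_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.visual_score_norm <= 1.0:
            raise ValidationError("visual_score_norm must lie in [0, 1]")
        if self.hfp_score_norm is not None and not 0.0 <= self.hfp_score_norm <= 1.0:
            raise ValidationError("hfp_score_norm must lie in [0, 1]")


@dataclass
class AgreementReport:
    """Aggregate agreement between visual and mapped scores over a plot set."""

    n: int
    rmse: float
    kappa: float | None          # None when chance agreement is 1 (degenerate)
    tolerance: float
    n_within: int
    n_hfp_above: int             # mapped score exceeds visual by > tolerance
    n_hfp_below: int             # mapped score below visual by > tolerance
    pct_within: float
    kappa_alt: dict[float, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_within + self.n_hfp_above + self.n_hfp_below != self.n:
            raise ValidationError("within/above/below counts must sum to n")


@dataclass
class MapValidationReport:
    """Intersection check of validation plots against a wilderness-style map.

    ``n`` is the number of plots falling inside map blocks; ``n_agree`` /
    ``pct_agree`` count strict agreement (visual score exactly zero for
    pressure-free maps, at or below the biorealm threshold for Last of the
    Wild maps); ``n_within_tolerance`` relaxes that by the tolerance band.
    """

    n: int
    n_agree: int
    pct_agree: float
    n_within_tolerance: int
    pct_within_tolerance: float
    tolerance: float
    criterion: str = ""


def normalize_hfp(score, scale_max: int = SCORE_MAX):
    """Normalise integer pressure scores onto [0, 1] (score / 50 by default)."""
    arr = np.asarray(score)
    if ((arr < 0) | (arr > scale_max)).any():
        raise ValidationError(f"scores must lie in 0..{scale_max}")
    out = arr / scale_max
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def filter_certain(plots: list[ValidationPlot]) -> list[ValidationPlot]:
    """Keep only plots whose visual score was flagged certain (order kept)."""
    return [p for p in plots if p.certain]


def rmse(a, b) -> float:
    """Root mean squared error between two equal-length score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("rmse requires two equal-length 1-D vectors")
    if len(a) == 0:
        raise ValidationError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _discretize(x: np.ndarray, tolerance: float) -> np.ndarray:
    """Equal-width ordinal classes over [0, 1], right-closed at 1."""
    k = math.ceil(1.0 / tolerance)
    return np.minimum((x * k).astype(np.int64), k - 1)


def kappa_with_tolerance(a, b, tolerance: float = AGREEMENT_TOLERANCE) -> float | None:
    """Cohen's kappa on tolerance-width score classes.

    Both vectors are discretised into ``ceil(1/tolerance)`` equal-width
    classes over [0, 1] and unweighted kappa ``(p_o - p_e) / (1 - p_e)`` is
    computed from the contingency table.  Returns ``None`` when the chance
    agreement ``p_e`` equals 1 (all observations in one identical class).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("kappa requires two equal-length non-empty vectors")
    if not 0.0 < tolerance <= 1.0:
        raise ValidationError("tolerance must lie in (0, 1]")
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ValidationError("scores must lie in [0, 1]")
    k = math.ceil(1.0 / tolerance)
    ca, cb = _discretize(a, tolerance), _discretize(b, tolerance)
    table = np.zeros((k, k))
    np.add.at(table, (ca, cb), 1.0)
    n = table.sum()
    p_o = np.trace(table) / n
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    if p_e >= 1.0 - 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def agreement_counts(a, b, tolerance: float = AGREEMENT_TOLERANCE) -> tuple[int, int, int]:
    """Decompose plot pairs into (within, b above, b below) at the band.

    ``within`` is boundary-inclusive (|b - a| <= tolerance); ``b above``
    means the second vector exceeds the first by more than the tolerance.
    The three counts always sum to the number of pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("agreement_counts requires equal-length vectors")
    diff = b - a
    n_above = int((diff > tolerance).sum())
    n_below = int((-diff > tolerance).sum())
    n_within = len(a) - n_above - n_below
    return n_within, n_above, n_below


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (as printed)."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def overlay_hfp(plots: list[ValidationPlot], grid: PressureGrid) -> list[ValidationPlot]:
    """Fill each plot's mapped score by overlay on the pressure grid."""
    out = []
    for p in plots:
        s = int(grid.scores[p.row, p.col])
        if s == grid.nodata_value:
            raise ValidationError(f"plot {p.plot_id} falls on a nodata cell")
        out.append(
            ValidationPlot(
                p.plot_id, p.row, p.col, p.visual_score_norm, p.certain,
                hfp_score_norm=s / SCORE_MAX, realm_id=p.realm_id,
            )
        )
    return out


def score_agreement(
    plots: list[ValidationPlot],
    tolerance: float = AGREEMENT_TOLERANCE,
    alt_tolerances: tuple[float, ...] = (0.15, 0.25),
) -> AgreementReport:
    """Full agreement report (RMSE, banded kappa, decomposition) for a plot set.

    Plots must carry overlaid mapped scores.  The certainty filter is the
    caller's responsibility (apply :func:`filter_certain` first when the
    protocol requires it).
    """
    if not plots:
        raise ValidationError("no plots to score")
    if any(p.hfp_score_norm is None for p in plots):
        raise ValidationError("plots lack mapped scores; run overlay_hfp first")
    visual = np.array([p.visual_score_norm for p in plots])
    mapped = np.array([p.hfp_score_norm for p in plots])
    n_within, n_above, n_below = agreement_counts(visual, mapped, tolerance)
    return AgreementReport(
        n=len(plots),
        rmse=rmse(visual, mapped),
        kappa=kappa_with_tolerance(visual, mapped, tolerance),
        tolerance=tolerance,
        n_within=n_within,
        n_hfp_above=n_above,
        n_hfp_below=n_below,
        pct_within=percent(n_within, len(plots)),
        kappa_alt={
            t: kappa_with_tolerance(visual, mapped, t) for t in alt_tolerances
        },
    )


def _plots_in_blocks(plots, blocks, shape):
    mask = np.zeros(shape, dtype=bool)
    for b in blocks:
        mask[b.cells[:, 0], b.cells[:, 1]] = True
    inside = [p for p in plots if mask[p.row, p.col]]
    return inside, mask


def validate_wilderness_map(wmap, plots: list[ValidationPlot],
                            tolerance: float = AGREEMENT_TOLERANCE) -> MapValidationReport:
    """Check plots falling inside pressure-free blocks.

    Strict agreement means the plot was visually scored as completely free
    of human pressure (normalised score exactly 0); the relaxed count admits
    scores within the tolerance band of zero.
    """
    inside, _ = _plots_in_blocks(plots, wmap.blocks, wmap.grid_shape)
    n = len(inside)
    if n == 0:
        return MapValidationReport(0, 0, 0.0, 0, 0.0, tolerance, "pressure_free")
    n_zero = sum(1 for p in inside if p.visual_score_norm == 0.0)
    n_within = sum(1 for p in inside if p.visual_score_norm <= tolerance)
    return MapValidationReport(
        n=n,
        n_agree=n_zero,
        pct_agree=percent(n_zero, n),
        n_within_tolerance=n_within,
        pct_within_tolerance=percent(n_within, n),
        tolerance=tolerance,
        criterion="pressure_free",
    )


def validate_low_map(low_map, plots: list[ValidationPlot],
                     tolerance: float = AGREEMENT_TOLERANCE) -> MapValidationReport:
    """Check plots falling inside Last of the Wild blocks.

    Each intersecting plot is resolved to its block's biorealm; agreement
    means the visual score is at or below the normalised biorealm threshold
    (t_r / 50), and the relaxed count admits scores up to ``tolerance``
    above the threshold (boundary inclusive).
    """
    shape = low_map.grid_shape
    realm_of = np.zeros(shape, dtype=np.int64)
    for b in low_map.blocks:
        if b.realm_id is None:
            raise ValidationError(f"block {b.block_id} carries no realm id")
        realm_of[b.cells[:, 0], b.cells[:, 1]] = b.realm_id
    inside = [p for p in plots if realm_of[p.row, p.col] > 0]
    n = len(inside)
    if n == 0:
        return MapValidationReport(0, 0, 0.0, 0, 0.0, tolerance, "last_of_wild")
    entries = low_map.thresholds.entries
    n_below = n_within = 0
    for p in inside:
        rid = int(realm_of[p.row, p.col])
        if rid not in entries:
            raise ValidationError(f"plot {p.plot_id} in realm {rid} absent from thresholds")
        t_norm = entries[rid].threshold / SCORE_MAX
        if p.visual_score_norm <= t_norm:
            n_below += 1
        if p.visual_score_norm <= t_norm + tolerance:
            n_within += 1
    return MapValidationReport(
        n=n,
        n_agree=n_below,
        pct_agree=percent(n_below, n),
        n_within_tolerance=n_within,
        pct_within_tolerance=percent(n_within, n),
        tolerance=tolerance,
        criterion="last_of_wild",
    )
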