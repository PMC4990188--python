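"""Per-block CE and CR, the effectiveness statistic, and the compensation line.

The framework quantifies, within each experimental block,

* competitive exclusion ``CE = S_removal - S_control``: mean focal richness
  in competitor-removal plots minus control plots (both without the
  releasing factor) — the number of species the competitors exclude;
* competitive release ``CR = S_releasing - S_control``: mean focal richness
  in plots with the releasing factor minus control plots — the number of
  species the releasing factor restores;
* effectiveness ``CR / CE``: the fraction of excluded species the releasing
  factor brings back, 0 (no release) to 1 (full compensation).

Each block is one point in CR-CE space.  Points on the line y = x indicate
full compensation; points below it partial compensation.  Across blocks the
effectiveness can alternatively be estimated as the slope of an OLS
regression of CR on CE, provided the intercept does not differ from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConsistencyError, DegenerateFitError
from .richness import plot_mean_richness
from .survey import TREATMENTS

logger = logging.getLogger(__name__)

#: default guard below which |CE| is treated as zero and the ratio undefined
DEFAULT_EPSILON = 1e-9

COMPENSATION_LABELS = ("none", "partial", "full", "overcompensation")


@dataclass(frozen=True)
class BlockMetrics:
    """One block's position in CR-CE space at one spatial scale.

    ``s_control``/``s_removal``/``s_releasing`` are mean focal richness per
    sampling unit (species counts); CE and CR are in species at the same
    scale; ``effectiveness`` is dimensionless and NaN when |CE| is within
    the guard epsilon.
    """

    habitat: str
    block: str
    scale: str
    s_control: float
    s_removal: float
    s_releasing: float
    ce: float
    cr: float
    effectiveness: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.effectiveness)


@dataclass(frozen=True)
class EffectivenessSummary:
    """Mean +/- SE of per-block effectiveness ratios for one habitat x scale."""

    habitat: str
    scale: str
    n: int
    mean: float
    se: float  # NaN when n < 2
    n_undefined: int = 0


@dataclass(frozen=True)
class CompensationFit:
    """OLS fit of CR on CE across blocks at one scale.

    The slope estimates the releasing factor's effectiveness when the
    intercept does not differ from zero.  ``p_slope_one`` tests H0: slope=1
    (two-sided, t with n-2 df); the signed ``t_slope_one`` lets a one-sided
    "significantly lower than 1" reading be recovered.
    """

    scale: str
    n: int
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    p_slope_zero: float
    p_slope_one: float
    p_intercept_zero: float
    t_slope_one: float
    df_resid: int

    def to_dict(self) -> dict:
        return asdict(self)


def block_metrics(
    richness_table: pd.DataFrame,
    blocks: Sequence[tuple[str, str]],
    epsilon: float = DEFAULT_EPSILON,
) -> list[BlockMetrics]:
    """CE, CR and effectiveness for each full block.

    Parameters
    ----------
    richness_table
        Output of :func:`crce.richness.richness_at_scale` for the focal
        group at one scale.
    blocks
        (habitat, block) pairs to evaluate; each must contain all three
        treatments (see :func:`crce.survey.full_blocks`).
    epsilon
        Guard on |CE| below which the ratio CR/CE is reported as NaN.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    scale = _infer_scale(richness_table)
    per_plot = plot_mean_richness(richness_table)

    out: list[BlockMetrics] = []
    for habitat, block in blocks:
        sub = per_plot[(per_plot["habitat"] == habitat) & (per_plot["block"] == block)]
        means = sub.groupby("treatment")["mean_richness"].mean()
        missing = [t for t in TREATMENTS if t not in means.index]
        if missing:
            raise ConsistencyError(
                f"block {habitat}/{block} lacks treatment(s) {missing}"
            )
        s_con, s_rem, s_rel = (
            float(means["control"]),
            float(means["removal"]),
            float(means["releasing"]),
        )
        ce = s_rem - s_con
        cr = s_rel - s_con
        eff = cr / ce if abs(ce) > epsilon else float("nan")
        out.append(
            BlockMetrics(habitat, block, scale, s_con, s_rem, s_rel, ce, cr, eff)
        )
    return out


def metrics_frame(metrics: Iterable[BlockMetrics]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of BlockMetrics."""
    return pd.DataFrame([asdict(m) for m in metrics])


def effectiveness_summary(
    metrics: Iterable[BlockMetrics],
    habitat: str | None = None,
    scale: str | None = None,
) -> EffectivenessSummary:
    """Mean and standard error of per-block effectiveness ratios.

    The estimator is the mean of per-block CR/CE ratios (not the ratio of
    mean CR to mean CE); SE = sample sd / sqrt(n).  Undefined ratios
    (|CE| within the guard) are excluded with a warning and counted.
    """
    selected = [
        m
        for m in metrics
        if (habitat is None or m.habitat == habitat)
        and (scale is None or m.scale == scale)
    ]
    if not selected:
        raise ValueError("no block metrics in the requested habitat/scale subset")
    defined = [m.effectiveness for m in selected if m.defined]
    n_undef = len(selected) - len(defined)
    if n_undef:
        logger.warning(
            "%d block(s) with |CE| below the guard excluded from the "
            "effectiveness summary (habitat=%s, scale=%s)",
            n_undef,
            habitat,
            scale,
        )
    if not defined:
        raise ValueError("no defined effectiveness ratios in the subset")
    arr = np.asarray(defined, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size >= 2 else float("nan")
    return EffectivenessSummary(
        habitat=habitat if habitat is not None else "all",
        scale=scale if scale is not None else (selected[0].scale if len({m.scale for m in selected}) == 1 else "all"),
        n=len(defined),
        mean=mean,
        se=se,
        n_undefined=n_undef,
    )


def _points(metrics: Iterable[BlockMetrics | tuple[float, float]]) -> np.ndarray:
    pts = []
    for m in metrics:
        if isinstance(m, BlockMetrics):
            pts.append((m.ce, m.cr))
        else:
            ce, cr = m
            pts.append((float(ce), float(cr)))
    arr = np.asarray(pts, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("CE/CR points must be finite")
    return arr


def fit_compensation_line(
    points: Iterable[BlockMetrics | tuple[float, float]],
    scale: str | None = None,
) -> CompensationFit:
    """OLS of CR on CE with tests against slope = 0, slope = 1, intercept = 0.

    Uses ordinary (unweighted) least squares with an intercept; all tests
    are two-sided t tests on n - 2 residual degrees of freedom.  R^2 is the
    squared Pearson correlation of fitted and observed CR, which for OLS
    with an intercept equals the usual coefficient of determination.
    """
    points = list(points)
    arr = _points(points)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 points to fit the compensation line")
    ce, cr = arr[:, 0], arr[:, 1]
    if np.ptp(ce) == 0:
        raise DegenerateFitError("all CE values identical; slope is unidentifiable")

    model = sm.OLS(cr, sm.add_constant(ce)).fit()
    intercept, slope = model.params
    intercept_se, slope_se = model.bse
    df_resid = int(model.df_resid)
    # collinear points: SEs are floating-point noise and every t statistic
    # is meaningless; report the degenerate limits instead
    scale_y = max(1.0, float(np.sum((cr - cr.mean()) ** 2)))
    if model.ssr <= 1e-12 * scale_y:
        tol = 1e-9 * max(1.0, abs(float(slope)), abs(float(intercept)))
        return CompensationFit(
            scale=scale if scale is not None else _common_scale(points),
            n=int(arr.shape[0]),
            slope=float(slope),
            slope_se=0.0,
            intercept=float(intercept),
            intercept_se=0.0,
            r_squared=float(model.rsquared),
            p_slope_zero=1.0 if abs(slope) <= tol else 0.0,
            p_slope_one=1.0 if abs(slope - 1.0) <= tol else 0.0,
            p_intercept_zero=1.0 if abs(intercept) <= tol else 0.0,
            t_slope_one=0.0 if abs(slope - 1.0) <= tol else math.copysign(
                math.inf, slope - 1.0
            ),
            df_resid=df_resid,
        )
    t_slope_one = float((slope - 1.0) / slope_se)
    p_slope_one = float(2 * stats.t.sf(abs(t_slope_one), df_resid))
    return CompensationFit(
        scale=scale if scale is not None else _common_scale(points),
        n=int(arr.shape[0]),
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        r_squared=float(model.rsquared),
        p_slope_zero=float(model.pvalues[1]),
        p_slope_one=p_slope_one,
        p_intercept_zero=float(model.pvalues[0]),
        t_slope_one=t_slope_one,
        df_resid=df_resid,
    )


def classify_compensation(
    point: BlockMetrics | CompensationFit | tuple[float, float],
    delta: float = 0.0,
) -> str:
    """Classify a CR-CE point (or a fitted line) against the compensation line.

    For a point with CE > 0: ``full`` if |CR - CE| <= delta, ``none`` if
    |CR| <= delta, ``overcompensation`` if CR > CE + delta, else
    ``partial``.  For a :class:`CompensationFit` the slope plays the role
    of CR/CE (full at slope ~ 1, none at slope ~ 0).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if isinstance(point, CompensationFit):
        ce, cr = 1.0, point.slope
    elif isinstance(point, BlockMetrics):
        ce, cr = point.ce, point.cr
    else:
        ce, cr = map(float, point)
    if ce <= 0:
        raise ValueError("point classification requires CE > 0")
    if abs(cr - ce) <= delta:
        return "full"
    if abs(cr) <= delta:
        return "none"
    if cr > ce + delta:
        return "overcompensation"
    return "partial"


def count_below_compensation_line(
    points: Iterable[BlockMetrics | tuple[float, float]],
) -> int:
    """Number of points strictly below the line CR = CE (on the line is not below)."""
    arr = _points(points)
    if arr.size == 0:
        return 0
    return int(np.sum(arr[:, 1] < arr[:, 0]))


def plot_crce_space(
    metrics: Iterable[BlockMetrics],
    fits: Iterable[CompensationFit] = (),
    ax=None,
):
    """Scatter blocks in CR-CE space with the y = x compensation line.

    Returns the matplotlib Axes.  Purely presentational; all numbers shown
    come from :func:`block_metrics` / :func:`fit_compensation_line`.
    """
    import matplotlib.pyplot as plt

    metrics = list(metrics)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    frame = metrics_frame(metrics)
    markers = {"valley": "o", "slope": "s"}
    for (scale, habitat), sub in frame.groupby(["scale", "habitat"]):
        ax.scatter(
            sub["ce"], sub["cr"],
            marker=markers.get(habitat, "o"),
            label=f"{habitat}, {scale}",
        )
    lim = max(1.0, float(frame[["ce", "cr"]].max().max()) * 1.1)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="compensation line y = x")
    for fit in fits:
        xs = np.array([0.0, lim])
        ax.plot(xs, fit.intercept + fit.slope * xs, lw=1, alpha=0.7)
    ax.set_xlabel("competitive exclusion CE (species)")
    ax.set_ylabel("competitive release CR (species)")
    ax.legend(fontsize=7)
    return ax


def _infer_scale(richness_table: pd.DataFrame) -> str:
    if "quadrat" in richness_table.columns:
        return "quadrat"
    if "cluster" in richness_table.columns:
        return "cluster"
    return "plot"


def _common_scale(points) -> str:
    scales = {m.scale for m in points if isinstance(m, BlockMetrics)}
    return scales.pop() if len(scales) == 1 else "unspecified"
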