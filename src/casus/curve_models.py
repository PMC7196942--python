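"""Cubic and segmented-cubic regression of blood flow on stenosis scores.

Flow falls with the stenosis score, but not as a single smooth decline:
collateral recruitment produces a compensated plateau at intermediate total
scores, giving the global-flow-versus-total-score relation an inverse-S
shape.  A single cubic captures the overall trend; a three-segment fit with
breakpoints on the score axis (the published thresholds are 5 and 10)
resolves the two sharp-decline phases around the plateau.  Segments are
fitted independently (no continuity constraint at the breakpoints) and a
pooled R² — one minus the summed segment SSE over the total sum of squares
— ranks candidate breakpoint pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)

#: Default candidate breakpoint grid: all integer pairs 3 <= t1 < t2 <= 12.
DEFAULT_BREAKPOINT_GRID: Tuple[Tuple[int, int], ...] = tuple(
    (t1, t2) for t1, t2 in itertools.combinations(range(3, 13), 2)
)


@dataclass(frozen=True)
class CubicFit:
    """Polynomial OLS fit: coefficients (b0..b_degree), R², overall-F p-value."""

    coefficients: Tuple[float, ...]
    r_squared: float
    p_value: float
    n: int
    degree: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        powers = np.vander(x, N=len(self.coefficients), increasing=True)
        return powers @ np.asarray(self.coefficients)


@dataclass(frozen=True)
class SegmentedFit:
    """Independent per-segment polynomial fits with a pooled R²."""

    breakpoints: Tuple[float, float]
    segment_fits: Tuple[CubicFit, CubicFit, CubicFit]
    pooled_r_squared: float
    candidate_scores: Tuple[Tuple[Tuple[float, float], float], ...] = field(
        default=(), repr=False
    )

    def segment_of(self, x: float) -> int:
        t1, t2 = self.breakpoints
        if x < t1:
            return 0
        if x <= t2:
            return 1
        return 2

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        for i, xi in enumerate(x.ravel()):
            out.ravel()[i] = self.segment_fits[self.segment_of(xi)].predict([xi])[0]
        return out


def _fit_polynomial(x: np.ndarray, y: np.ndarray, degree: int) -> CubicFit:
    design = np.vander(x, N=degree + 1, increasing=True)
    model = sm.OLS(y, design).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(model.resid**2))
    # Zero-variance outcome: define R² = 0 (nothing to explain).
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    r2 = float(min(max(r2, 0.0), 1.0))
    pval = float(model.f_pvalue) if degree >= 1 and np.isfinite(model.f_pvalue) else 1.0
    coeffs = tuple(float(c) for c in model.params)
    return CubicFit(coefficients=coeffs, r_squared=r2, p_value=pval,
                    n=int(len(y)), degree=degree)


def _validate_xy(x, y, min_n: int, min_distinct: int) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise FitError(f"need at least {min_n} observations, got {len(x)}")
    if len(np.unique(x)) < min_distinct:
        raise FitError(
            f"need at least {min_distinct} distinct x values, got {len(np.unique(x))}"
        )
    return x, y


def fit_cubic(x: Sequence[float], y: Sequence[float]) -> CubicFit:
    """OLS fit of y = b0 + b1·x + b2·x² + b3·x³.

    Requires ≥ 5 observations with ≥ 4 distinct x values; raises
    :class:`FitError` on rank deficiency.
    """
    x, y = _validate_xy(x, y, min_n=5, min_distinct=4)
    return _fit_polynomial(x, y, degree=3)


def fit_linear(x: Sequence[float], y: Sequence[float]) -> CubicFit:
    """OLS line with slope, intercept and R² (≥ 3 points, ≥ 2 distinct x)."""
    x, y = _validate_xy(x, y, min_n=3, min_distinct=2)
    return _fit_polynomial(x, y, degree=1)


def _max_feasible_degree(x: np.ndarray) -> int:
    return min(3, len(np.unique(x)) - 1, len(x) - 1)


def _segment_masks(x: np.ndarray, t1: float, t2: float):
    return x < t1, (x >= t1) & (x <= t2), x > t2


def fit_segmented(
    x: Sequence[float],
    y: Sequence[float],
    candidate_breakpoints: Optional[Sequence[Tuple[float, float]]] = None,
) -> SegmentedFit:
    """Three-segment fit over a candidate breakpoint grid; best pair by pooled R².

    Segments are x < t1, t1 ≤ x ≤ t2, x > t2.  Each segment gets an
    independent cubic when it has ≥ 5 points with ≥ 4 distinct x, otherwise
    the highest-order polynomial it supports.  Pooled R² =
    1 − Σ(segment SSE)/SST(all y).  Candidates leaving a segment with fewer
    than 2 points are skipped with a warning; ties go to the smaller first
    threshold, then the smaller second.
    """
    x, y = _validate_xy(x, y, min_n=6, min_distinct=3)
    if candidate_breakpoints is None:
        candidate_breakpoints = DEFAULT_BREAKPOINT_GRID
    candidates = [tuple(pair) for pair in candidate_breakpoints]
    if not candidates:
        raise ValidationError("candidate breakpoint list is empty")
    if any(not t1 < t2 for t1, t2 in candidates):
        raise ValidationError("breakpoints must be strictly increasing pairs")

    sst = float(np.sum((y - y.mean()) ** 2))
    results: List[Tuple[Tuple[float, float], float, tuple]] = []
    for t1, t2 in sorted(candidates):
        masks = _segment_masks(x, t1, t2)
        if any(int(m.sum()) < 2 for m in masks):
            logger.warning(
                "breakpoints (%s, %s) leave a segment with < 2 points; skipped",
                t1, t2,
            )
            continue
        fits = []
        sse = 0.0
        for mask in masks:
            xs, ys = x[mask], y[mask]
            fit = _fit_polynomial(xs, ys, _max_feasible_degree(xs))
            fits.append(fit)
            sse += float(np.sum((ys - fit.predict(xs)) ** 2))
        pooled = 0.0 if sst == 0 else min(max(1.0 - sse / sst, 0.0), 1.0)
        results.append(((float(t1), float(t2)), pooled, tuple(fits)))

    if not results:
        raise FitError("every candidate breakpoint pair left an empty segment")

    # max pooled R²; sorted order makes ties resolve to the smaller pair
    best_pair, best_r2, best_fits = max(results, key=lambda r: r[1])
    scores = tuple((pair, r2) for pair, r2, _ in results)
    return SegmentedFit(
        breakpoints=best_pair,
        segment_fits=best_fits,
        pooled_r_squared=best_r2,
        candidate_scores=scores,
    )


def fit_report(cubic: CubicFit, segmented: Optional[SegmentedFit] = None) -> dict:
    """JSON-serialisable summary of a cubic (and optional segmented) fit."""
    report = {
        "cubic": {
            "coefficients": list(cubic.coefficients),
            "r_squared": cubic.r_squared,
            "p_value": cubic.p_value,
            "n": cubic.n,
        }
    }
    if segmented is not None:
        report["segmented"] = {
            "breakpoints": list(segmented.breakpoints),
            "pooled_r_squared": segmented.pooled_r_squared,
            "segments": [
                {
                    "degree": f.degree,
                    "coefficients": list(f.coefficients),
                    "r_squared": f.r_squared,
                    "n": f.n,
                }
                for f in segmented.segment_fits
            ],
        }
    return report


def plot_fit(x, y, cubic: CubicFit, segmented: Optional[SegmentedFit] = None,
             path: Optional[str] = None):
    """Scatter of the data with the fitted curve(s); saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=10, alpha=0.4, label="patients")
    grid = np.linspace(min(x), max(x), 200)
    ax.plot(grid, cubic.predict(grid), label=f"cubic (R²={cubic.r_squared:.3f})")
    if segmented is not None:
        ax.plot(grid, segmented.predict(grid), "--",
                label=f"segmented (R²={segmented.pooled_r_squared:.3f})")
        for t in segmented.breakpoints:
            ax.axvline(t, color="grey", lw=0.5)
    ax.set_xlabel("total stenosis score")
    ax.set_ylabel("global blood flow (mL/min)")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
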