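"""Abundance-class assignment from the coefficient of variation across tissues.

Each gene's tissue specificity is summarised by its coefficient of
variation (CV), ``100 * sd / mean`` of its per-tissue mean abundance.  The
CV distribution over all genes is typically bimodal: a dominant mode of
uniformly expressed (UE) genes and a smaller high-CV mode of
tissue-enriched (TE) genes.  The class boundary is found geometrically on a
Gaussian kernel density estimate of the CVs: the tangent is traced at the
point of steepest descent right of the dominant mode, and the CV where that
tangent crosses the x-axis is the UE/TE threshold.  For a pure Gaussian
density N(mu, sigma^2) this construction gives exactly mu + 2*sigma, so a
dominant mode near CV 65 with spread ~30 yields the canonical threshold of
CV = 125.

TE genes are then assigned the tissue where their mean abundance is
highest; a configurable joint rule assigns both tissues of a designated
pair (by default breast and ovary) when they are the top two and within a
two-fold difference of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .data import TissueProfile
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)


def compute_cv(profile: TissueProfile, ddof: int = 1) -> pd.DataFrame:
    """Coefficient of variation (percent) of per-tissue means for each gene.

    ``cv = 100 * sd(tissue means, ddof) / mean(tissue means)``.  Requires
    strictly positive mean abundance for every gene (guaranteed upstream by
    the expression filter); raises :class:`DataError` naming offending
    genes otherwise.
    """
    v = profile.values
    means = v.mean(axis=1)
    bad = means[means <= 0]
    if len(bad):
        raise DataError(f"zero mean abundance for genes: {list(bad.index[:5])}")
    cv = 100.0 * v.std(axis=1, ddof=ddof) / means
    return pd.DataFrame({"cv": cv, "n_tissues": v.shape[1]}, index=v.index)


@dataclass(eq=False)
class DensityCurve:
    """A density evaluated on a strictly increasing uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise DataError("grid and density must be 1-D arrays of equal length")
        if not (np.diff(self.grid) > 0).all():
            raise DataError("grid must be strictly increasing")
        if (self.density < 0).any():
            raise DataError("density must be non-negative")

    def mass(self) -> float:
        """Trapezoidal integral of the curve over its grid."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ThresholdResult:
    """Tangent construction output: where the steepest tangent hits zero."""

    threshold: float
    tangent_point_x: float
    density_at_point: float
    derivative_at_point: float


def estimate_density(
    values,
    bandwidth_rule: str | float = "scott",
    grid_points: int = 1024,
    grid_span: tuple[float, float] | None = None,
) -> DensityCurve:
    """Gaussian kernel density estimate on a uniform grid.

    ``grid_span`` defaults to ``[0, 1.05 * max(values)]``, matching the
    natural support of CV values.  At least 10 observations with non-zero
    spread are required; the recorded ``bandwidth`` is the kernel standard
    deviation actually used.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise DataError("density estimation requires at least 10 values")
    if np.ptp(x) == 0:
        raise DataError("cannot estimate a density from identical values "
                        "(zero variance)")
    kde = gaussian_kde(x, bw_method=bandwidth_rule)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    if grid_span is None:
        grid_span = (0.0, 1.05 * float(x.max()))
    lo, hi = grid_span
    if not hi > lo:
        raise ConfigError("grid span must be a non-empty interval")
    grid = np.linspace(lo, hi, int(grid_points))
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=bandwidth)


def steepest_descent_threshold(curve: DensityCurve) -> ThresholdResult:
    """Tangent-crossing threshold at the steepest descent of a bimodal curve.

    The numerical derivative (central differences on the grid) is minimised
    over grid points strictly right of the global mode; at that point x0 the
    tangent line ``f(x0) + f'(x0) (x - x0)`` crosses zero at
    ``x0 - f(x0)/f'(x0)``, which is returned as the threshold.  Ties in the
    derivative are broken towards the smallest x.
    """
    f = curve.density
    d = np.gradient(f, curve.grid)
    mode = int(np.argmax(f))
    if mode == len(f) - 1:
        raise DataError("global mode sits at the right edge of the grid")
    region = slice(mode + 1, len(f))
    i = mode + 1 + int(np.argmin(d[region]))
    if d[i] >= 0:
        raise DataError("no descending flank right of the global mode")
    x0, f0, d0 = float(curve.grid[i]), float(f[i]), float(d[i])
    return ThresholdResult(
        threshold=x0 - f0 / d0,
        tangent_point_x=x0,
        density_at_point=f0,
        derivative_at_point=d0,
    )


def classify_abundance(cv_table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Label genes tissue-enriched (TE) when CV strictly exceeds the threshold.

    Genes at or below the threshold are uniformly expressed (UE).  Returns a
    copy of ``cv_table`` with an ``abundance_class`` column and an empty
    ``enriched_tissues`` column (filled by
    :func:`assign_tissue_enrichment`).
    """
    if threshold <= 0:
        raise ConfigError("CV threshold must be positive")
    out = cv_table.copy()
    out["abundance_class"] = np.where(out["cv"] > threshold, "TE", "UE")
    out["enriched_tissues"] = [() for _ in range(len(out))]
    return out


def assign_tissue_enrichment(
    profile: TissueProfile,
    assignments: pd.DataFrame,
    joint_tissue_pair: tuple[str, str] = ("breast", "ovary"),
    joint_fold: float = 2.0,
) -> pd.DataFrame:
    """Attach the enrichment tissue(s) to every TE gene.

    The enrichment tissue is the argmax of the gene's per-tissue mean
    abundance.  When the top two tissues are exactly ``joint_tissue_pair``
    and the maximum is within ``joint_fold`` times the runner-up, both
    tissues are assigned.  Exact ties for the maximum outside the joint
    pair retain all tied tissues with a logged warning.  UE genes keep an
    empty tissue set.
    """
    out = assignments.copy()
    pair = frozenset(joint_tissue_pair)
    enriched: dict[str, tuple[str, ...]] = {}
    te_genes = out.index[out["abundance_class"] == "TE"]
    missing = [g for g in te_genes if g not in profile.values.index]
    if missing:
        raise DataError(f"tissue profile missing TE genes: {missing[:5]}")
    for gene in te_genes:
        row = profile.values.loc[gene]
        ranked = row.sort_values(ascending=False, kind="stable")
        top_value = ranked.iloc[0]
        ties = tuple(ranked.index[ranked == top_value])
        if len(ties) > 1:
            log.warning("stage=enrichment action=argmax_tie gene=%s tissues=%s",
                        gene, ";".join(ties))
            enriched[gene] = tuple(sorted(ties))
            continue
        if (len(ranked) >= 2
                and frozenset(ranked.index[:2]) == pair
                and top_value <= joint_fold * ranked.iloc[1]):
            enriched[gene] = tuple(sorted(pair))
        else:
            enriched[gene] = (ranked.index[0],)
    out["enriched_tissues"] = [enriched.get(g, ()) for g in out.index]
    return out


def plot_cv_density(curve: DensityCurve, result: ThresholdResult, ax=None):
    """Diagnostic plot of the CV density, tangent line and threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.density, label="CV density")
    x0, f0, d0 = (result.tangent_point_x, result.density_at_point,
                  result.derivative_at_point)
    xs = np.array([x0 - 0.2 * (result.threshold - x0), result.threshold])
    ax.plot(xs, f0 + d0 * (xs - x0), "--", label="steepest tangent")
    ax.axvline(result.threshold, color="k", lw=0.8,
               label=f"threshold = {result.threshold:.1f}")
    ax.set_xlabel("coefficient of variation (%)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
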