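"""Inflection-anchored line fits on the Cat2 -> Max3 segment and the
per-tissue line family q = alpha*k + beta.

Between the Cat2 minimum and the last maximum every Brdicka curve contains
a near-linear stretch.  Each curve is summarised by the line y = k*E + q
fitted by ordinary least squares to the m = 11 samples centred on the
segment's inflection point (the zero crossing of the discrete second
difference).  Within one tissue the (k, q) pairs of all replicates are
almost perfectly collinear: q = alpha*k + beta, which is equivalent to all
segment lines sharing the single point (-alpha, beta) — substituting q
into y = k*E + q gives y = k*(E + alpha) + beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (DegenerateFamilyError, NoInflectionError, ParameterError)
from .extremes import (DEFAULT_MIN_DISTANCE, find_extremes,
                       merge_close_extremes, name_peaks)
from .io import Dataset, Voltammogram

DEFAULT_HALFWIDTH = 5


def find_inflection(curve: Voltammogram,
                    between: tuple[int, int]) -> int:
    """Index of the second-difference zero crossing between two extremes.

    Candidates are interior samples where the discrete second difference
    vanishes or changes sign; among several the one with the steepest
    first difference is returned.
    """
    lo, hi = between
    if not 0 <= lo < hi < len(curve):
        raise ParameterError(f"invalid interval {between}")
    y = curve.currents
    d1 = np.diff(y)
    d2 = np.diff(y, 2)            # d2[i] = y[i+2] - 2 y[i+1] + y[i]

    cands = []
    for i in range(lo + 1, hi - 1):   # open interval, d2 centred at sample i
        a, b = d2[i - 1], d2[i]       # curvature at i and i+1
        if a == 0.0:
            cands.append(i)
        elif a * b < 0.0:
            cands.append(i if abs(a) <= abs(b) else i + 1)
    cands = sorted({i for i in cands if lo < i < hi})
    if not cands:
        raise NoInflectionError(
            f"no second-difference sign change in ({lo}, {hi})")
    slope = lambda i: abs(0.5 * (d1[i - 1] + d1[i]))
    return int(max(cands, key=slope))


@dataclass
class SegmentFit:
    """One curve's inflection-anchored line on the Cat2 -> Max3 segment."""

    inflection_index: int
    inflection_potential: float
    k: float                   # slope, current units per V
    q: float                   # intercept, current units
    m: int                     # number of fitted samples
    rms_residual: float
    tissue: str = ""
    subject: int = 0
    replicate: int = 0


def fit_line_at_inflection(curve: Voltammogram, inflection: int,
                           halfwidth: int = DEFAULT_HALFWIDTH) -> SegmentFit:
    """OLS of current on potential over inflection +- halfwidth samples."""
    if not (halfwidth >= 1 and inflection - halfwidth >= 0
            and inflection + halfwidth < len(curve)):
        raise ParameterError("fit window out of curve bounds")
    sl = slice(inflection - halfwidth, inflection + halfwidth + 1)
    e, y = curve.potentials[sl], curve.currents[sl]
    res = stats.linregress(e, y)
    resid = y - (res.slope * e + res.intercept)
    return SegmentFit(inflection, float(curve.potentials[inflection]),
                      float(res.slope), float(res.intercept),
                      2 * halfwidth + 1, float(np.sqrt(np.mean(resid ** 2))),
                      curve.tissue, curve.subject, curve.replicate)


def fit_curve_segment(curve: Voltammogram,
                      min_distance: int = DEFAULT_MIN_DISTANCE,
                      windows=None,
                      halfwidth: int = DEFAULT_HALFWIDTH) -> SegmentFit:
    """Locate Cat2 and Max3, find the inflection between them, fit the line."""
    ext = merge_close_extremes(find_extremes(curve), min_distance)
    named = name_peaks(ext, windows)
    if named.cat2 is None or named.max3 is None:
        raise NoInflectionError(
            f"curve {curve.key} lacks a named Cat2 or Max3 extreme")
    infl = find_inflection(curve, (named.cat2.index, named.max3.index))
    return fit_line_at_inflection(curve, infl, halfwidth)


@dataclass
class TissueLineFamily:
    """Per-tissue line family q = alpha*k + beta and its intersection."""

    tissue: str
    alpha: float
    beta: float
    r2: float
    n_fits: int

    @property
    def intersection(self) -> tuple[float, float]:
        return (-self.alpha, self.beta)


def fit_tissue_family(fits: list[SegmentFit],
                      tissue: str | None = None) -> TissueLineFamily:
    """OLS of q on k over one tissue's segment fits."""
    if len(fits) < 3:
        raise ParameterError("need at least 3 segment fits for a family")
    k = np.array([f.k for f in fits])
    q = np.array([f.q for f in fits])
    if np.ptp(k) == 0.0:
        raise DegenerateFamilyError("all slopes identical (vertical family)")
    res = stats.linregress(k, q)
    return TissueLineFamily(tissue or fits[0].tissue,
                            float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), len(fits))


def fit_families(dataset: Dataset, **kwargs
                 ) -> tuple[list[TissueLineFamily], list[SegmentFit]]:
    """Segment fits for every curve, grouped into per-tissue families.

    Curves without a usable segment (no Cat2/Max3 or no inflection) are
    skipped; tissues with fewer than 3 usable fits are skipped.
    """
    per_tissue: dict[str, list[SegmentFit]] = {}
    all_fits = []
    for curve in dataset:
        try:
            fit = fit_curve_segment(curve, **kwargs)
        except NoInflectionError:
            continue
        per_tissue.setdefault(curve.tissue, []).append(fit)
        all_fits.append(fit)
    families = [fit_tissue_family(fits, tissue)
                for tissue, fits in per_tissue.items() if len(fits) >= 3]
    return families, all_fits


def correlate_alpha_with_level(families: list[TissueLineFamily],
                               levels: dict[str, float]) -> float:
    """Pearson correlation of -alpha with tissue concentration, percent."""
    if len(families) < 3:
        raise ParameterError("need at least 3 tissues for a correlation")
    missing = [f.tissue for f in families if f.tissue not in levels]
    if missing:
        raise ParameterError(f"no concentration for tissue(s) {missing}")
    neg_alpha = [-f.alpha for f in families]
    conc = [levels[f.tissue] for f in families]
    return 100.0 * float(stats.pearsonr(neg_alpha, conc).statistic)
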