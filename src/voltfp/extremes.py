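"""Local-extreme detection, merging, naming and replicate cleaning.

Extremes are located with a discrete-differentiation chain: a first-order
FIR difference, a signum-like normalisation to +-0.5 (zero maps to +0.5),
and a second difference whose non-zero entries mark sign changes of the
slope.  The marked index is shifted by the one-sample group delay of the
chain, so the reported extreme is the sample at which the slope sign
changes.  Endpoints are never extremes.  The equivalent neighbour
comparison rule is::

    rising(p)  := x[p] >= x[p-1]
    extreme at p (0 < p < n-1)  iff  rising(p) != rising(p+1)

so a flat run entered from below yields its last sample as the maximum and
a flat run entered from above yields its first sample as the minimum —
exactly what the 0 -> +0.5 normalisation produces.

Insignificant extremes caused by minor waves are removed by merging any
neighbouring pair closer than a minimum index distance (default 5 samples,
i.e. 10 mV at the 2 mV step), dropping the member that deviates less from
its local surroundings, and restoring min/max alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .io import Dataset, Voltammogram

DEFAULT_MIN_DISTANCE = 5

#: default naming windows, volts (disjoint; configurable)
DEFAULT_PEAK_WINDOWS = {
    "co1": (-0.95, -0.70),
    "rs2co": (-1.33, -1.10),
    "cat1": (-1.46, -1.33),
    "cat2": (-1.62, -1.46),
}

MIN, MAX = "min", "max"


def differentiate(x: np.ndarray) -> np.ndarray:
    """First-order FIR difference, zero-padded to the input length."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("need a 1-D signal with at least 2 samples")
    return np.concatenate(([0.0], np.diff(x)))


def sign_normalize(d: np.ndarray) -> np.ndarray:
    """Signum-like normalisation: +0.5 for inputs >= 0, -0.5 otherwise."""
    return np.where(np.asarray(d, dtype=float) >= 0.0, 0.5, -0.5)


@dataclass
class ExtremeSet:
    """Ordered local extremes of one curve."""

    positions: np.ndarray          # sample indices, strictly increasing
    potentials: np.ndarray         # V at those indices
    values: np.ndarray             # stored currents at those indices
    kinds: list[str]               # MIN / MAX per extreme

    def __len__(self) -> int:
        return len(self.positions)

    def take(self, idx) -> "ExtremeSet":
        idx = np.asarray(idx, dtype=int)
        return ExtremeSet(self.positions[idx], self.potentials[idx],
                          self.values[idx], [self.kinds[i] for i in idx])


def find_extremes(curve: Voltammogram) -> ExtremeSet:
    """Locate local extremes via the difference / signum / difference chain."""
    y = curve.currents
    d = differentiate(y)
    s = sign_normalize(d)
    marks = differentiate(s)
    # marked index n means the slope sign changed between samples n-1 and n;
    # the extreme sits at n-1 (one-sample chain delay).  Endpoints excluded.
    raw = np.nonzero(marks)[0] - 1
    raw = raw[(raw > 0) & (raw < len(y) - 1)]
    kinds = [MAX if marks[p + 1] < 0 else MIN for p in raw]
    return ExtremeSet(raw.astype(int), curve.potentials[raw], y[raw], kinds)


def _prominence(e: ExtremeSet, i: int) -> float:
    """Absolute deviation of extreme i from the mean of its flanking extremes."""
    if len(e) < 2:
        return abs(float(e.values[i]))
    left = e.values[i - 1] if i > 0 else e.values[i + 1]
    right = e.values[i + 1] if i < len(e) - 1 else e.values[i - 1]
    return abs(e.values[i] - 0.5 * (left + right))


def merge_close_extremes(e: ExtremeSet, min_distance: int = DEFAULT_MIN_DISTANCE
                         ) -> ExtremeSet:
    """Merge neighbouring extremes closer than ``min_distance`` samples.

    Distances are the first differences of the extreme positions; for each
    suspicious pair the less prominent member is dropped, repeatedly, and
    min/max alternation is then restored by dropping the weaker of any
    same-kind adjacent pair.  Idempotent.
    """
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    keep = list(range(len(e)))

    def gaps(idx):
        return np.diff(e.positions[idx])

    while len(keep) >= 2:
        g = gaps(keep)
        bad = np.nonzero(g < min_distance)[0]
        if len(bad) == 0:
            break
        i = int(bad[0])            # leftmost suspicious pair
        a, b = keep[i], keep[i + 1]
        sub = e.take(keep)
        drop = a if _prominence(sub, i) <= _prominence(sub, i + 1) else b
        keep.remove(drop)

    # restore alternation
    changed = True
    while changed and len(keep) >= 2:
        changed = False
        for i in range(len(keep) - 1):
            a, b = keep[i], keep[i + 1]
            if e.kinds[a] == e.kinds[b]:
                if e.kinds[a] == MAX:
                    drop = a if e.values[a] <= e.values[b] else b
                else:
                    drop = a if e.values[a] >= e.values[b] else b
                keep.remove(drop)
                changed = True
                break
    return e.take(keep)


@dataclass
class PeakRef:
    """One named extreme."""

    index: int          # sample index in the curve
    potential: float
    value: float
    kind: str


@dataclass
class NamedPeaks:
    """Named catalytic minima and the maxima between/after them."""

    co1: PeakRef | None = None
    rs2co: PeakRef | None = None
    cat1: PeakRef | None = None
    cat2: PeakRef | None = None
    max1: PeakRef | None = None
    max2: PeakRef | None = None
    max3: PeakRef | None = None

    def minima(self):
        return {"co1": self.co1, "rs2co": self.rs2co,
                "cat1": self.cat1, "cat2": self.cat2}


def name_peaks(e: ExtremeSet,
               windows: dict[str, tuple[float, float]] | None = None
               ) -> NamedPeaks:
    """Assign named peaks to merged extremes.

    Each catalytic minimum is the most prominent minimum inside its
    potential window; the maxima are then assigned positionally: max1
    between RS2Co and Cat1, max2 between Cat1 and Cat2, max3 the last
    maximum after Cat2.
    """
    windows = dict(DEFAULT_PEAK_WINDOWS if windows is None else windows)
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (na, wa), (nb, wb) in zip(items, items[1:]):
        if wa[1] > wb[0]:
            raise ConfigurationError(
                f"windows {na} and {nb} overlap: {wa} vs {wb}")

    named = NamedPeaks()
    for name, (lo, hi) in windows.items():
        cands = [i for i in range(len(e))
                 if e.kinds[i] == MIN and lo <= e.potentials[i] <= hi]
        if cands:
            best = max(cands, key=lambda i: _prominence(e, i))
            setattr(named, name, PeakRef(int(e.positions[best]),
                                         float(e.potentials[best]),
                                         float(e.values[best]), MIN))
    maxima = [i for i in range(len(e)) if e.kinds[i] == MAX]

    def pos(ref):
        return ref.index if ref is not None else None

    def between(lo_pos, hi_pos):
        sel = [i for i in maxima
               if (lo_pos is None or e.positions[i] > lo_pos)
               and (hi_pos is None or e.positions[i] < hi_pos)]
        return sel

    if named.rs2co is not None and named.cat1 is not None:
        sel = between(pos(named.rs2co), pos(named.cat1))
        if sel:
            i = max(sel, key=lambda i: e.values[i])
            named.max1 = PeakRef(int(e.positions[i]), float(e.potentials[i]),
                                 float(e.values[i]), MAX)
    if named.cat1 is not None and named.cat2 is not None:
        sel = between(pos(named.cat1), pos(named.cat2))
        if sel:
            i = max(sel, key=lambda i: e.values[i])
            named.max2 = PeakRef(int(e.positions[i]), float(e.potentials[i]),
                                 float(e.values[i]), MAX)
    if named.cat2 is not None:
        sel = between(pos(named.cat2), None)
        if sel:
            i = sel[-1]            # the last local maximum
            named.max3 = PeakRef(int(e.positions[i]), float(e.potentials[i]),
                                 float(e.values[i]), MAX)
    return named


def flag_outlier_replicates(group: list[Voltammogram],
                            factor: float = 5.0,
                            manual_flags: list[tuple[str, int, int]] | None = None
                            ) -> list[Voltammogram]:
    """Flag replicates dramatically different from their group.

    Each curve's RMS distance to the pointwise median curve of the group is
    compared with the median of those distances; curves beyond
    ``factor x median`` are flagged.  An explicit manual flag list
    overrides the automatic rule.  Groups smaller than 3 cannot be flagged
    automatically (empty result).
    """
    if manual_flags is not None:
        manual = {tuple(f) for f in manual_flags}
        return [c for c in group if c.key in manual]
    if len(group) < 3:
        import warnings
        warnings.warn("group too small for automatic outlier flagging")
        return []
    ys = np.vstack([c.currents for c in group])
    med = np.median(ys, axis=0)
    dist = np.sqrt(np.mean((ys - med) ** 2, axis=1))
    thresh = factor * float(np.median(dist))
    return [c for c, d in zip(group, dist) if d > thresh]


def clean_dataset(dataset: Dataset, factor: float = 5.0,
                  manual_flags: list[tuple[str, int, int]] | None = None
                  ) -> tuple[Dataset, list[tuple[str, int, int]]]:
    """Drop outlier replicates group by group; returns (cleaned, flagged keys)."""
    flagged: list[tuple[str, int, int]] = []
    for (_, _), curves in dataset.groups():
        if manual_flags is not None:
            keys = {tuple(f) for f in manual_flags}
            flagged.extend(c.key for c in curves if c.key in keys)
        else:
            flagged.extend(c.key for c in flag_outlier_replicates(curves, factor))
    flagged_set = set(flagged)
    return dataset.subset(lambda c: c.key not in flagged_set), flagged
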