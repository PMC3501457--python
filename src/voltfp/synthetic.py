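"""Synthetic Brdicka-reaction voltammograms with controlled structure.

The generator emulates differential-pulse voltammograms of heat-treated rat
tissue extracts measured in a cobalt/ammonia electrolyte: a catalytic
current envelope with bell-shaped peaks (RS2Co, Cat1, Cat2) riding on a
drifting background that plunges into the hydrogen-evolution wall at the
negative end of the scan.  Curves are stored in acquisition orientation
(from -0.7 V toward -1.8 V) with the catalytic peaks as local *minima* of
the stored current.

Structural guarantees, by construction:

* seven tissues (liver, kidney, brain, eye, spleen, heart, gonad) produce
  exactly six local extremes on noise-free curves (RS2Co, Max1, Cat1,
  Max2, Cat2, Max3); blood and muscle produce four (their RS2Co signal is
  a broad unresolved shoulder);
* tissues that show the Co1 signal carry a monotone shoulder decaying from
  the -0.7 V edge, shaping the early curve without adding extremes (the
  measured Co1 sits at the initial potential itself);
* between Cat2 and the last maximum each curve contains a designed
  near-linear stretch: within a protected window around a per-tissue pivot
  potential E* the curve is an odd cubic through (E*, y*).  Every
  replicate's least-squares segment line therefore passes through
  (E*, y*) exactly when family noise is off, so the per-tissue line family
  q = alpha*k + beta holds with alpha = -E* and beta = y*;
* per-tissue pivot potentials are assigned so that -alpha correlates
  positively with the tissue metallothionein level.

Variability model: per-subject scalar gain about the pivot, per-replicate
gain, a smooth multiplicative shape field, a bounded per-curve intercept
jitter (the "family noise"), and i.i.d. sample noise.  All randomness is
driven by per-cell seed sequences derived from the dataset seed, so a
dataset is a pure function of (spec, profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError
from .io import (N_POINTS, POTENTIAL_WINDOW, Dataset, Voltammogram,
                 default_potentials)

TISSUES = ("liver", "blood", "kidney", "brain", "eye",
           "spleen", "heart", "muscle", "gonad")

#: metallothionein level per tissue, ug/g wet weight.  Kidney, liver, brain
#: and spleen follow reported electrochemical determinations; the remaining
#: tissues are set to plausible values (heart/muscle roughly half of liver).
MT_LEVELS = {
    "kidney": 67.0, "brain": 50.5, "liver": 48.7, "spleen": 41.5,
    "eye": 30.0, "gonad": 28.5, "heart": 26.0, "muscle": 24.0, "blood": 21.0,
}

# default noise magnitudes (see docs/methods.md for rationale)
DEFAULT_NOISE_SD = 1e-4        # i.i.d. per-sample current noise
DEFAULT_FAMILY_NOISE_FRAC = 0.01   # bound of intercept jitter, fraction of |beta|
DEFAULT_SUBJECT_GAIN_SD = 0.06     # log-sd of per-subject gain
DEFAULT_REPLICATE_GAIN_SD = 0.04   # log-sd of per-replicate gain
DEFAULT_SHAPE_NOISE_SD = 0.02      # sd of smooth multiplicative shape field

# segment geometry (sample units on the default 518-point grid).  The
# designed odd cubic replaces the curve from a C1 junction just after the
# Cat2 minimum to a short blend into the falling wall tail; its slope is
# maximal at the pivot, so the pivot is the steepest point between Cat2
# and Max3 and the discrete second difference changes sign there only.
_JOFF = 10     # junction: samples after the Cat2 centre (inside its convex zone)
_WR = 9        # pure-cubic reach right of the pivot
_TAIL = 8      # blend length from the cubic into the clamped tail
_BFRAC = 0.25  # cubic curvature scale: pivot slope = (1 + 3*_BFRAC) x junction slope

#: default corrupt design cells: 8 measurements over 6 (tissue, subject)
#: groups, rats 6 and 8, in blood/muscle/heart/gonad; the first two emulate
#: aborted (incomplete) scans, the rest amplitude collapse.
DEFAULT_OUTLIER_FLAGS = [
    ("blood", 8, 1), ("muscle", 6, 2), ("muscle", 8, 4),
    ("heart", 6, 1), ("heart", 6, 3),
    ("gonad", 6, 2), ("gonad", 8, 1), ("gonad", 8, 5),
]


@dataclass
class TissueProfile:
    """Deterministic shape parameters of one tissue's voltammogram."""

    tissue_name: str
    peak_centers: list[float]      # V, sorted (most negative first)
    peak_heights: list[float]      # current units, positive
    peak_widths: list[float]       # V
    has_co1: bool
    baseline_params: tuple[float, float]   # wall (amplitude, decay scale V)
    segment_alpha: float           # alpha of q = alpha*k + beta (= -E*), V
    segment_beta: float            # beta (= y*), current units
    n_extremes_target: int         # 4 or 6
    # internal shape constants
    offset: float = 0.0            # background current level d0
    drift: float = 0.8             # background drift, current units / V
    co1_height: float = 0.0
    co1_decay: float = 0.30        # V
    segment_slope: float = 0.0     # k0: designed segment slope dI/dE at E*
    segment_curvature: float = 0.0  # c3 of the odd cubic
    pivot_index: int = 0           # acquisition index of E* on the 518 grid
    mt_level: float = 0.0          # ug/g

    def __post_init__(self):
        lo, hi = min(POTENTIAL_WINDOW), max(POTENTIAL_WINDOW)
        if not all(lo < c < hi for c in self.peak_centers):
            raise ParameterError("peak centers must lie inside the potential window")
        if sorted(self.peak_centers) != list(self.peak_centers):
            raise ParameterError("peak centers must be sorted")
        if not (len(self.peak_centers) == len(self.peak_heights)
                == len(self.peak_widths)):
            raise ParameterError("peak parameter lists must have equal length")
        if len(self.peak_centers) not in (3, 4):
            raise ParameterError("expected 3 or 4 peaks")

    @property
    def pivot_potential(self) -> float:
        """E*, the x-coordinate of the designed family intersection."""
        return -self.segment_alpha


@dataclass
class DatasetSpec:
    """Design of a synthetic measurement campaign."""

    n_tissues: int = 9
    n_subjects: int = 8
    n_replicates: int = 5
    n_points: int = N_POINTS
    potential_window: tuple[float, float] = POTENTIAL_WINDOW
    outlier_flags: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0
    outlier_mode: str = "mixed"    # mixed | collapse | truncate
    noise_sd: float = DEFAULT_NOISE_SD
    family_noise_frac: float = DEFAULT_FAMILY_NOISE_FRAC
    subject_gain_sd: float = DEFAULT_SUBJECT_GAIN_SD
    replicate_gain_sd: float = DEFAULT_REPLICATE_GAIN_SD
    shape_noise_sd: float = DEFAULT_SHAPE_NOISE_SD


@dataclass
class SubjectOffset:
    """Per-subject perturbation: scalar gain about the tissue pivot."""

    gain: float = 1.0


# Per-tissue base parameters.  Peaks are given on the x = -E axis
# (x in volts, increasing with acquisition) as (RS2Co, Cat1, Cat2)
# triples; `pivot_off` is the pivot's distance after the Cat2 centre in
# samples.  Liver/gonad share all extreme-visible parameters (they differ
# in background level and wall steepness only), as do eye/spleen up to
# peak widths: those pairs are the designed hard cases for the
# extreme-based feature sets.
_BASE = {
    # tissue:  centers_x,                heights,            widths,
    #          d0,   wall_A, wall_tau, co1_h, pivot_off
    "liver":  ((1.250, 1.375, 1.475), (1.8, 2.2, 3.1), (0.033, 0.032, 0.030),
               0.50, 1.20, 0.050, 0.08, 19),
    "gonad":  ((1.250, 1.375, 1.475), (1.8, 2.2, 3.1), (0.033, 0.032, 0.030),
               0.58, 2.00, 0.050, 0.00, 19),
    "kidney": ((1.235, 1.360, 1.465), (2.0, 2.5, 3.6), (0.034, 0.032, 0.030),
               0.52, 1.30, 0.052, 0.08, 18),
    "brain":  ((1.262, 1.388, 1.482), (1.6, 2.0, 2.9), (0.033, 0.031, 0.029),
               0.48, 1.15, 0.048, 0.07, 19),
    "heart":  ((1.255, 1.380, 1.478), (1.2, 1.5, 1.7), (0.032, 0.031, 0.030),
               0.50, 1.00, 0.050, 0.08, 21),
    "eye":    ((1.248, 1.372, 1.473), (1.1, 1.4, 1.6), (0.033, 0.031, 0.029),
               0.50, 1.05, 0.050, 0.06, 21),
    "spleen": ((1.248, 1.372, 1.473), (1.1, 1.4, 1.6), (0.043, 0.041, 0.029),
               0.55, 1.05, 0.050, 0.00, 20),
    "blood":  ((1.300, 1.385, 1.490), (0.45, 1.0, 0.95), (0.060, 0.031, 0.030),
               0.55, 1.00, 0.050, 0.05, 23),
    "muscle": ((1.310, 1.400, 1.485), (0.40, 0.9, 0.85), (0.060, 0.030, 0.029),
               0.45, 0.95, 0.050, 0.00, 22),
}
# Alternative preset in which the three cluster groups dominate the curve
# shape: within a group the tissues are nearly identical, so decision
# trees must separate {liver, kidney, gonad, brain} / {blood, muscle} /
# {heart, eye, spleen} before anything else.
_BASE_GROUPED = {
    "liver":  ((1.246, 1.371, 1.473), (1.90, 2.35, 3.20), (0.033, 0.032, 0.030),
               0.50, 1.20, 0.050, 0.08, 19),
    "kidney": ((1.248, 1.373, 1.475), (1.96, 2.42, 3.30), (0.033, 0.032, 0.030),
               0.52, 1.20, 0.050, 0.08, 19),
    "brain":  ((1.250, 1.375, 1.477), (1.84, 2.28, 3.10), (0.033, 0.032, 0.030),
               0.48, 1.20, 0.050, 0.07, 19),
    "gonad":  ((1.252, 1.377, 1.479), (1.93, 2.39, 3.26), (0.033, 0.032, 0.030),
               0.51, 1.20, 0.050, 0.00, 19),
    "heart":  ((1.251, 1.376, 1.475), (1.15, 1.45, 1.70), (0.032, 0.031, 0.029),
               0.50, 1.00, 0.050, 0.08, 21),
    "eye":    ((1.253, 1.378, 1.477), (1.12, 1.41, 1.64), (0.032, 0.031, 0.029),
               0.50, 1.00, 0.050, 0.06, 21),
    "spleen": ((1.255, 1.380, 1.479), (1.18, 1.49, 1.74), (0.032, 0.031, 0.029),
               0.52, 1.00, 0.050, 0.00, 21),
    "blood":  ((1.300, 1.385, 1.490), (0.45, 1.0, 0.95), (0.060, 0.031, 0.030),
               0.55, 1.00, 0.050, 0.05, 23),
    "muscle": ((1.310, 1.400, 1.485), (0.40, 0.9, 0.85), (0.060, 0.030, 0.029),
               0.45, 0.95, 0.050, 0.00, 22),
}

#: the cluster structure the grouped preset is built around
TISSUE_GROUPS = ({"liver", "kidney", "gonad", "brain"},
                 {"blood", "muscle"},
                 {"heart", "eye", "spleen"})

# tissues that share shape jitter with a partner (keeps the designed
# near-degeneracies intact under seeding)
_JITTER_PARTNER = {"gonad": "liver", "spleen": "eye"}
_FOUR_EXTREME = ("blood", "muscle")


def _envelope(x: np.ndarray, centers, heights, widths,
              d0: float, drift: float, wall_a: float, wall_tau: float,
              co1_h: float, co1_decay: float) -> np.ndarray:
    """Positive current envelope on the x = -E axis."""
    e = d0 + drift * (x - x[0]) + wall_a * np.exp((x - x[-1]) / wall_tau)
    if co1_h:
        e = e + co1_h * np.exp(-(x - x[0]) / co1_decay)
    for c, h, w in zip(centers, heights, widths):
        e = e + h * np.exp(-0.5 * ((x - c) / w) ** 2)
    return e


def _raw_curve(profile: TissueProfile, potentials: np.ndarray) -> np.ndarray:
    """Stored (mirrored) base curve before segment shaping."""
    x = -potentials
    centers_x = [-c for c in reversed(profile.peak_centers)]
    heights = list(reversed(profile.peak_heights))
    widths = list(reversed(profile.peak_widths))
    if profile.has_co1 and len(centers_x) == 4:
        # the Co1 entry (least negative potential) is realised as the
        # monotone edge shoulder, not as a Gaussian bump
        co1_h = heights[0]
        centers_x, heights, widths = centers_x[1:], heights[1:], widths[1:]
    else:
        co1_h = profile.co1_height
    e = _envelope(x, centers_x, heights, widths,
                  profile.offset, profile.drift,
                  *profile.baseline_params, co1_h, profile.co1_decay)
    return -e


def _smootherstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _cat2_params(profile: TissueProfile):
    """(centre_x, height, width) of the Cat2 peak (most negative potential)."""
    return (-profile.peak_centers[0], profile.peak_heights[0],
            profile.peak_widths[0])


def _base_curve(profile: TissueProfile, potentials: np.ndarray) -> np.ndarray:
    """Raw curve with the designed segment: raw up to the C1 junction after
    Cat2, the odd cubic through the pivot, then a blend into the falling
    tail with the Cat2 dip contribution frozen."""
    s = _raw_curve(profile, potentials)
    n = len(s)
    step = abs(potentials[1] - potentials[0])
    i_star = profile.pivot_index
    c2_x, c2_h, c2_w = _cat2_params(profile)
    i_c2 = int(round((c2_x - (-potentials[0])) / step))
    jn = i_c2 + _JOFF

    j = np.arange(n) - i_star
    a_idx = -profile.segment_slope * step          # index-space pivot slope
    b_idx = -profile.segment_curvature * step ** 3
    cubic = profile.segment_beta + a_idx * j + b_idx * j ** 3

    # tail: raw with the Cat2 Gaussian frozen at the blend start
    x = -potentials
    x_cl = x[min(i_star + _WR, n - 1)]
    phi = np.exp(-0.5 * ((x - c2_x) / c2_w) ** 2)
    phi_cl = np.exp(-0.5 * ((x_cl - c2_x) / c2_w) ** 2)
    tail = s + c2_h * (phi - phi_cl)

    out = s.copy()
    right = min(i_star + _WR, n - 1)
    out[jn:right + 1] = cubic[jn:right + 1]
    blend = np.arange(right + 1, min(right + 1 + _TAIL, n))
    if len(blend):
        w = 1.0 - _smootherstep((blend - (right + 1) + 1.0) / (_TAIL + 1.0))
        out[blend] = w * cubic[blend] + (1.0 - w) * tail[blend]
    if right + 1 + _TAIL < n:
        out[right + 1 + _TAIL:] = tail[right + 1 + _TAIL:]
    return out


def make_tissue_profiles(seed: int = 0,
                         preset: str = "default") -> list[TissueProfile]:
    """Nine deterministic tissue profiles (blood and muscle with <= 4 extremes).

    The seed perturbs peak positions (within +-1 mV), heights and widths
    (within +-2 %); tissue pairs designed to be indistinguishable to the
    extreme-based representations share their perturbation draws.  The
    ``grouped`` preset makes the three cluster groups dominate the shape
    (see TISSUE_GROUPS); ``default`` is the study condition.
    """
    if not isinstance(seed, (int, np.integer)):
        raise ParameterError("seed must be an integer")
    if preset not in ("default", "grouped"):
        raise ParameterError(f"unknown preset {preset!r}")
    base_table = _BASE if preset == "default" else _BASE_GROUPED
    pots = default_potentials()
    step = abs(pots[1] - pots[0])
    jitter: dict[str, tuple] = {}
    for name in TISSUES:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 7, TISSUES.index(name)]))
        jitter[name] = (rng.uniform(-1e-3, 1e-3, 3),
                        rng.uniform(0.98, 1.02, 3),
                        rng.uniform(0.98, 1.02, 3))
    for name, partner in _JITTER_PARTNER.items():
        dj, hj, wj = jitter[partner]
        # share centre and height jitter; spleen keeps its own widths
        jitter[name] = (dj, hj, wj if name == "gonad" else jitter[name][2])

    profiles = []
    for name in TISSUES:
        centers_x, heights, widths, d0, wall_a, wall_tau, co1_h, pivot_off = base_table[name]
        dj, hj, wj = jitter[name]
        centers_x = tuple(c + d for c, d in zip(centers_x, dj))
        heights = tuple(h * f for h, f in zip(heights, hj))
        widths = tuple(w * f for w, f in zip(widths, wj))
        # pivot: fixed sample offset behind the (grid-snapped) Cat2 centre
        i_c2 = int(round((centers_x[-1] - 0.7) / step))
        i_star = i_c2 + pivot_off
        x_star = 0.7 + i_star * step
        if co1_h > 0:
            # Co1 entry at the window edge, realised as the monotone shoulder
            centers_x = (0.72,) + centers_x
            heights = (co1_h,) + heights
            widths = (0.30,) + widths
        prof = TissueProfile(
            tissue_name=name,
            peak_centers=[-c for c in reversed(centers_x)],
            peak_heights=list(reversed(heights)),
            peak_widths=list(reversed(widths)),
            has_co1=co1_h > 0,
            baseline_params=(wall_a, wall_tau),
            segment_alpha=x_star,
            segment_beta=0.0,
            n_extremes_target=4 if name in _FOUR_EXTREME else 6,
            offset=d0,
            co1_height=co1_h,
            pivot_index=i_star,
            mt_level=MT_LEVELS[name],
        )
        # anchor the designed line family: C1 junction on the Cat2 flank,
        # pivot slope (1 + 3*_BFRAC) x the junction slope
        raw = _raw_curve(prof, pots)
        jn = i_c2 + _JOFF
        w_l = pivot_off - _JOFF
        r0 = float(raw[jn])
        s0 = float(0.5 * (raw[jn + 1] - raw[jn - 1]))    # index-space slope
        b_idx = -_BFRAC * s0 / w_l ** 2
        a_idx = s0 + 3.0 * abs(b_idx) * w_l ** 2
        prof.segment_beta = r0 + a_idx * w_l + b_idx * w_l ** 3
        prof.segment_slope = -a_idx / step               # dI/dE at the pivot
        prof.segment_curvature = -b_idx / step ** 3
        profiles.append(prof)
    return profiles


def generate_voltammogram(profile: TissueProfile,
                          subject_offset: SubjectOffset | float | None = None,
                          replicate_noise_sd: float = DEFAULT_NOISE_SD,
                          rng: np.random.Generator | None = None,
                          *,
                          tissue: str | None = None,
                          subject: int = 1,
                          replicate: int = 1,
                          family_noise_frac: float = DEFAULT_FAMILY_NOISE_FRAC,
                          replicate_gain_sd: float = DEFAULT_REPLICATE_GAIN_SD,
                          shape_noise_sd: float = DEFAULT_SHAPE_NOISE_SD,
                          potentials: np.ndarray | None = None) -> Voltammogram:
    """One synthetic curve: pivot-anchored gain model plus noise.

    The stored current is ``y* + G(x) * (base(x) - y*) + eps + noise`` with
    G a positive gain (subject gain x replicate gain x smooth shape field)
    and eps a bounded intercept jitter (|eps| <= family_noise_frac * |beta|).
    Because G multiplies the deviation from the pivot current y*, every
    noise-free curve passes through (E*, y*) exactly, which realises the
    q = alpha*k + beta line family.
    """
    if replicate_noise_sd < 0:
        raise ParameterError("replicate_noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    if isinstance(subject_offset, (int, float)):
        subject_offset = SubjectOffset(gain=float(subject_offset))
    if subject_offset is None:
        subject_offset = SubjectOffset()
    pots = default_potentials() if potentials is None else potentials
    base = _base_curve(profile, pots)
    beta = profile.segment_beta

    gain = subject_offset.gain
    if replicate_gain_sd > 0:
        gain = gain * float(np.exp(rng.normal(0.0, replicate_gain_sd)))
    dev = base - beta
    if shape_noise_sd > 0:
        f = gaussian_filter1d(rng.standard_normal(len(pots)), 50.0, mode="nearest")
        f = f / max(float(f.std()), 1e-12)
        # damp the field over the featureless start of the scan so its
        # slope cannot overcome the gentle background drift there
        damp = _smootherstep((-pots - 1.08) / 0.16)
        dev = dev * (1.0 + shape_noise_sd * f * damp)
    y = beta + gain * dev
    if family_noise_frac > 0:
        y = y + rng.uniform(-1.0, 1.0) * family_noise_frac * abs(beta)
    if replicate_noise_sd > 0:
        y = y + rng.normal(0.0, replicate_noise_sd, len(pots))
    return Voltammogram(pots.copy(), y,
                        tissue or profile.tissue_name, subject, replicate)


def _corrupt(curve: Voltammogram, mode: str) -> Voltammogram:
    """Emulate a failed measurement: aborted scan or amplitude collapse."""
    y = curve.currents.copy()
    if mode == "truncate":
        cut = int(0.4 * len(y))
        y[cut:] = y[cut]
    elif mode == "collapse":
        y = y[0] + 0.05 * (y - y[0])
    else:
        raise ParameterError(f"unknown outlier mode {mode!r}")
    return Voltammogram(curve.potentials, y, *curve.key)


def generate_dataset(spec: DatasetSpec,
                     profiles: list[TissueProfile] | None = None) -> Dataset:
    """Full design: n_tissues x n_subjects x n_replicates labelled curves.

    Curves listed in ``spec.outlier_flags`` are replaced by corrupted
    versions.  Deterministic given (spec, profiles).
    """
    if profiles is None:
        profiles = make_tissue_profiles(spec.seed)
    if len(profiles) < spec.n_tissues:
        raise ParameterError(
            f"need {spec.n_tissues} profiles, got {len(profiles)}")
    profiles = profiles[: spec.n_tissues]
    names = {p.tissue_name for p in profiles}
    cells = {(p.tissue_name, s, r)
             for p in profiles
             for s in range(1, spec.n_subjects + 1)
             for r in range(1, spec.n_replicates + 1)}
    for flag in spec.outlier_flags:
        if tuple(flag) not in cells:
            raise ParameterError(f"outlier flag {flag} references no design cell")
    del names

    pots = default_potentials(spec.n_points, spec.potential_window)
    seed = int(spec.seed) % (2 ** 31)
    flagged = {tuple(f) for f in spec.outlier_flags}
    n_trunc = 2 if spec.outlier_mode == "mixed" else 0
    trunc_cells = {tuple(f) for f in spec.outlier_flags[:n_trunc]} \
        if spec.outlier_mode == "mixed" else set()

    curves = []
    for ti, prof in enumerate(profiles):
        for s in range(1, spec.n_subjects + 1):
            rng_s = np.random.default_rng(np.random.SeedSequence([seed, 1, ti, s]))
            off = SubjectOffset(gain=float(np.exp(
                rng_s.normal(0.0, spec.subject_gain_sd))))
            for r in range(1, spec.n_replicates + 1):
                rng_c = np.random.default_rng(
                    np.random.SeedSequence([seed, 2, ti, s, r]))
                cur = generate_voltammogram(
                    prof, off, spec.noise_sd, rng_c,
                    subject=s, replicate=r,
                    family_noise_frac=spec.family_noise_frac,
                    replicate_gain_sd=spec.replicate_gain_sd,
                    shape_noise_sd=spec.shape_noise_sd,
                    potentials=pots)
                key = (prof.tissue_name, s, r)
                if key in flagged:
                    mode = spec.outlier_mode
                    if mode == "mixed":
                        mode = "truncate" if key in trunc_cells else "collapse"
                    cur = _corrupt(cur, mode)
                curves.append(cur)
    return Dataset(curves,
                   provenance=f"synthetic Brdicka curves, seed={spec.seed}",
                   n_tissues=spec.n_tissues,
                   n_subjects=spec.n_subjects,
                   n_replicates=spec.n_replicates)
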