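"""Voltammogram containers and text-format input/output.

A voltammogram is a single differential-pulse scan: 518 equidistant
(potential, current) samples acquired from -0.7 V toward -1.8 V, labelled
with the tissue of origin, the subject (rat) and the replicate number.
Currents are stored in acquisition orientation, i.e. the catalytic peaks
RS2Co/Cat1/Cat2 are local *minima* of the stored values (biochemical plots
mirror the current axis, which is why the peaks "look like maxima").

Two interchange dialects are defined, both UTF-8 with "." decimals and a
mandatory header:

* ``tidy-csv``  — one row per sample: tissue,subject,replicate,potential_V,current
* ``wide-tsv``  — one row per curve: tissue, subject, replicate, then one
  column per potential (the header carries the potential values).

Numbers are written with 12+ significant digits so that write -> read is
an identity to 1e-12 relative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError, ParameterError, ParseError

#: default number of samples per curve
N_POINTS = 518

#: default potential window in volts (most negative, least negative)
POTENTIAL_WINDOW = (-1.8, -0.7)

_EQUIDISTANT_TOL = 1e-9  # volts


def default_potentials(n_points: int = N_POINTS,
                       window: tuple[float, float] = POTENTIAL_WINDOW) -> np.ndarray:
    """Equidistant potential grid in acquisition order (-0.7 V -> -1.8 V)."""
    lo, hi = min(window), max(window)
    return np.linspace(hi, lo, n_points)


@dataclass
class Voltammogram:
    """One labelled curve: equidistant potentials (decreasing) and currents."""

    potentials: np.ndarray
    currents: np.ndarray
    tissue: str
    subject: int
    replicate: int

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape or self.potentials.ndim != 1:
            raise ParameterError("potentials and currents must be 1-D and equally long")
        if len(self.potentials) >= 2:
            steps = np.diff(self.potentials)
            if not np.all(steps < 0):
                raise ParameterError("potentials must be strictly decreasing (acquisition order)")
            if np.ptp(steps) > _EQUIDISTANT_TOL:
                raise ParameterError(
                    f"potentials not equidistant within {_EQUIDISTANT_TOL} V")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.tissue, self.subject, self.replicate)

    def __len__(self) -> int:
        return len(self.potentials)


@dataclass
class Dataset:
    """A collection of curves with unique (tissue, subject, replicate) keys."""

    curves: list[Voltammogram]
    provenance: str = ""
    n_tissues: int = 0
    n_subjects: int = 0
    n_replicates: int = 0

    def __post_init__(self):
        keys = [c.key for c in self.curves]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise IntegrityError(f"duplicate curve key {dup}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def subset(self, keep) -> "Dataset":
        """New Dataset with curves for which ``keep(curve)`` is true."""
        return Dataset([c for c in self.curves if keep(c)],
                       provenance=self.provenance,
                       n_tissues=self.n_tissues,
                       n_subjects=self.n_subjects,
                       n_replicates=self.n_replicates)

    def groups(self):
        """Yield ((tissue, subject), [curves]) in first-appearance order."""
        order: dict[tuple[str, int], list[Voltammogram]] = {}
        for c in self.curves:
            order.setdefault((c.tissue, c.subject), []).append(c)
        yield from order.items()


_DIALECTS = ("tidy-csv", "wide-tsv")
_FMT = "{:.12e}"


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_curves(dataset: Dataset, path, dialect: str = "tidy-csv") -> None:
    """Write a dataset to ``path`` in the given dialect."""
    _check_dialect(dialect)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if dialect == "tidy-csv":
            w = csv.writer(fh)
            w.writerow(["tissue", "subject", "replicate", "potential_V", "current"])
            for c in dataset:
                for p, y in zip(c.potentials, c.currents):
                    w.writerow([c.tissue, c.subject, c.replicate,
                                _FMT.format(p), _FMT.format(y)])
        else:
            w = csv.writer(fh, delimiter="\t")
            if dataset.curves:
                pots = dataset.curves[0].potentials
                w.writerow(["tissue", "subject", "replicate",
                            *(_FMT.format(p) for p in pots)])
                for c in dataset:
                    if len(c) != len(pots):
                        raise IntegrityError(
                            "wide-tsv requires all curves on one potential grid")
                    w.writerow([c.tissue, c.subject, c.replicate,
                                *(_FMT.format(y) for y in c.currents)])
            else:
                w.writerow(["tissue", "subject", "replicate"])


def read_curves(path, dialect: str = "tidy-csv",
                expected_length: int | None = None) -> Dataset:
    """Read a dataset written by :func:`write_curves`.

    ``expected_length`` enforces a per-curve sample count (e.g. 518); by
    default any consistent length is accepted.  Non-equidistant potential
    grids are rejected with tolerance 1e-9 V; malformed rows raise
    :class:`ParseError` with the line number.
    """
    _check_dialect(dialect)
    if dialect == "tidy-csv":
        ds = _read_tidy(path)
    else:
        ds = _read_wide(path)
    if expected_length is not None:
        for c in ds:
            if len(c) != expected_length:
                raise IntegrityError(
                    f"curve {c.key} has {len(c)} samples, expected {expected_length}")
    return ds


def _read_tidy(path) -> Dataset:
    per_curve: dict[tuple[str, int, int], tuple[list, list]] = {}
    prev_key = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != [
                "tissue", "subject", "replicate", "potential_V", "current"]:
            raise ParseError("bad or missing tidy-csv header", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(f"expected 5 fields, got {len(row)}", line=lineno)
            try:
                key = (row[0], int(row[1]), int(row[2]))
                p, y = float(row[3]), float(row[4])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            if key != prev_key and key in per_curve:
                # rows of one curve must be contiguous; a reappearing key is
                # a second curve with the same label
                raise IntegrityError(f"duplicate curve key {key}")
            per_curve.setdefault(key, ([], []))[0].append(p)
            per_curve[key][1].append(y)
            prev_key = key
    curves = [Voltammogram(np.array(p), np.array(y), t, s, r)
              for (t, s, r), (p, y) in per_curve.items()]
    return Dataset(curves)


def _read_wide(path) -> Dataset:
    curves = []
    seen: set[tuple[str, int, int]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:3] != ["tissue", "subject", "replicate"]:
            raise ParseError("bad or missing wide-tsv header", line=1)
        try:
            pots = np.array([float(v) for v in header[3:]])
        except ValueError as exc:
            raise ParseError(f"non-numeric potential in header: {exc}", line=1) from None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}", line=lineno)
            try:
                key = (row[0], int(row[1]), int(row[2]))
                ys = np.array([float(v) for v in row[3:]])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            if key in seen:
                raise IntegrityError(f"duplicate curve key {key}")
            seen.add(key)
            curves.append(Voltammogram(pots.copy(), ys, *key))
    return Dataset(curves)
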