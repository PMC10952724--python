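"""The Spectrum2D container and its plain-text grid format.

Spectra are real-valued matrices with monotone ppm axes.  The on-disk
format is a self-describing whitespace-separated text grid::

    # exsy2d v1
    # shape <n1> <n2>
    # axis1_ppm <n1 floats>
    # axis2_ppm <n2 floats>
    # meta <key> <value ...>        (zero or more; value parsed as JSON if possible)
    <n1 rows of n2 floats>

Values are written with 17 significant digits, so a write -> read round
trip is lossless at (beyond) 15 significant digits.  Axis 1 is the
indirect (F1) dimension, axis 2 the direct (F2) dimension; axes are stored
ascending in ppm and rendered descending by NMR convention when plotted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, SpectrumFormatError, ValidationError

__all__ = ["Spectrum2D", "read_spectrum", "write_spectrum"]

_MAGIC = "# exsy2d v1"


@dataclass
class Spectrum2D:
    """Real 2D spectrum with ppm axes; the fitting target and the
    back-transformation input."""

    values: np.ndarray
    axis1_ppm: np.ndarray
    axis2_ppm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.axis1_ppm = np.asarray(self.axis1_ppm, dtype=float)
        self.axis2_ppm = np.asarray(self.axis2_ppm, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("spectrum values must be a 2D matrix")
        if self.values.shape != (self.axis1_ppm.size, self.axis2_ppm.size):
            raise DimensionError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.axis1_ppm.size}, {self.axis2_ppm.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectrum values must be finite")
        for name, ax in (("axis1_ppm", self.axis1_ppm), ("axis2_ppm", self.axis2_ppm)):
            if ax.size > 1:
                steps = np.diff(ax)
                if not (np.all(steps > 0) or np.all(steps < 0)):
                    raise ValidationError(f"{name} must be monotone")

    @property
    def shape(self):
        return self.values.shape

    def pixel_area_ppm2(self) -> float:
        d1 = np.abs(np.median(np.diff(self.axis1_ppm))) if self.axis1_ppm.size > 1 else 1.0
        d2 = np.abs(np.median(np.diff(self.axis2_ppm))) if self.axis2_ppm.size > 1 else 1.0
        return float(d1 * d2)

    def congruent_with(self, other: "Spectrum2D", rtol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.axis1_ppm, other.axis1_ppm, rtol=rtol)
                and np.allclose(self.axis2_ppm, other.axis2_ppm, rtol=rtol))


def _fmt_floats(arr) -> str:
    return " ".join(format(x, ".17g") for x in np.asarray(arr).ravel())


def write_spectrum(spec: Spectrum2D, path) -> None:
    """Write a spectrum in the documented plain-text grid format."""
    n1, n2 = spec.shape
    lines = [_MAGIC, f"# shape {n1} {n2}",
             f"# axis1_ppm {_fmt_floats(spec.axis1_ppm)}",
             f"# axis2_ppm {_fmt_floats(spec.axis2_ppm)}"]
    for key, value in spec.meta.items():
        lines.append(f"# meta {key} {json.dumps(value)}")
    for row in spec.values:
        lines.append(_fmt_floats(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum2D:
    """Read a spectrum written by :func:`write_spectrum`.

    Raises :class:`SpectrumFormatError` (with the offending line number)
    for malformed headers, bad numbers or dimension mismatches.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise SpectrumFormatError(f"missing magic header {_MAGIC!r}", line=1)
    shape = None
    axis1 = axis2 = None
    meta = {}
    rows = []
    for lineno, raw in enumerate(lines[1:], start=2):
        text = raw.strip()
        if not text:
            continue
        if text.startswith("#"):
            fields = text[1:].split()
            if not fields:
                continue
            tag = fields[0]
            try:
                if tag == "shape":
                    shape = (int(fields[1]), int(fields[2]))
                elif tag == "axis1_ppm":
                    axis1 = np.array([float(x) for x in fields[1:]])
                elif tag == "axis2_ppm":
                    axis2 = np.array([float(x) for x in fields[1:]])
                elif tag == "meta":
                    key = fields[1]
                    payload = " ".join(fields[2:])
                    try:
                        meta[key] = json.loads(payload)
                    except json.JSONDecodeError:
                        meta[key] = payload
                else:
                    raise SpectrumFormatError(f"unknown header tag {tag!r}", line=lineno)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, SpectrumFormatError):
                    raise
                raise SpectrumFormatError(f"malformed header {text!r}", line=lineno) from exc
        else:
            try:
                rows.append([float(x) for x in text.split()])
            except ValueError as exc:
                raise SpectrumFormatError(f"non-numeric data {text.split()[:3]}...", line=lineno) from exc
            if shape is not None and len(rows[-1]) != shape[1]:
                raise SpectrumFormatError(
                    f"row has {len(rows[-1])} values, expected {shape[1]}", line=lineno)
    if shape is None:
        raise SpectrumFormatError("missing '# shape' header", line=1)
    if axis1 is None or axis2 is None:
        raise SpectrumFormatError("missing axis header(s)", line=1)
    if len(rows) != shape[0]:
        raise SpectrumFormatError(
            f"expected {shape[0]} data rows, found {len(rows)}", line=len(lines))
    if axis1.size != shape[0] or axis2.size != shape[1]:
        raise SpectrumFormatError(
            f"axis lengths ({axis1.size}, {axis2.size}) do not match shape {shape}", line=1)
    try:
        return Spectrum2D(np.array(rows), axis1, axis2, meta)
    except (DimensionError, ValidationError) as exc:
        raise SpectrumFormatError(str(exc)) from exc
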