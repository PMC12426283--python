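"""Three-standard probe calibration and reflection/permittivity inversion.

An open-ended coaxial probe pressed against a sample reflects in proportion
to the impedance mismatch at the aperture.  Over the narrow band used here
the probe is well described by a bilinear (Moebius) map between the complex
relative permittivity ``eps*`` of the sample and the measured reflection
coefficient ``rho``:

    eps* = (A1*rho - A2) / (A3 - rho)        (inversion)
    rho  = (A2 + A3*eps*) / (A1 + eps*)      (forward map)

The three complex coefficients ``A1, A2, A3`` are fitted per frequency from
three standards:

    short circuit:   eps* -> infinity  =>  rho1 = A3
    open (air):      eps* = 1          =>  rho2 = (A2 + A3) / (A1 + 1)
    reference liquid: eps* of a known liquid  =>  rho3

which gives, in closed form,

    A3 = rho1
    A1 = [eps_std*(rho3 - rho1) + (rho1 - rho2)] / (rho2 - rho3)
    A2 = rho2*(A1 + 1) - A3

Calibration is solved independently at each frequency; no cross-frequency
smoothing or regularization is applied.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dielectric import ComplexPermittivity, FrequencyGrid, MaterialModel, evaluate_debye
from .errors import (
    ConfigurationError,
    DegenerateStandardsError,
    PhysicalityWarning,
    SingularityError,
)

_SINGULARITY_TOL = 1e-12
#: Plausibility window for inverted real permittivity.
PLAUSIBLE_EPS_RANGE = (1.0, 1000.0)


def _match_frequency(frequencies: np.ndarray, frequency: float) -> int:
    idx = int(np.argmin(np.abs(frequencies - frequency)))
    if not np.isclose(frequencies[idx], frequency, rtol=1e-9, atol=1e-3):
        raise KeyError(f"frequency {frequency} Hz not on the calibrated grid")
    return idx


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Per-frequency complex triples (A1, A2, A3) of the bilinear probe model."""

    frequencies: tuple[float, ...]
    a1: tuple[complex, ...]
    a2: tuple[complex, ...]
    a3: tuple[complex, ...]

    def __post_init__(self) -> None:
        n = len(self.frequencies)
        if not (len(self.a1) == len(self.a2) == len(self.a3) == n):
            raise ConfigurationError("coefficient arrays must match the frequency grid")
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        object.__setattr__(self, "a1", tuple(complex(v) for v in self.a1))
        object.__setattr__(self, "a2", tuple(complex(v) for v in self.a2))
        object.__setattr__(self, "a3", tuple(complex(v) for v in self.a3))

    @classmethod
    def single(
        cls, frequency: float, a1: complex, a2: complex, a3: complex
    ) -> "CalibrationCoefficients":
        return cls((frequency,), (a1,), (a2,), (a3,))

    def at(self, frequency: float) -> tuple[complex, complex, complex]:
        idx = _match_frequency(np.asarray(self.frequencies), frequency)
        return self.a1[idx], self.a2[idx], self.a3[idx]

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class CalibrationStandards:
    """Measured reflection coefficients of the short / open / liquid standards."""

    frequencies: tuple[float, ...]
    rho_short: tuple[complex, ...]
    rho_open: tuple[complex, ...]
    rho_liquid: tuple[complex, ...]
    standard_material: MaterialModel
    magnitude_tolerance: float = 0.05

    def __post_init__(self) -> None:
        n = len(self.frequencies)
        if not (len(self.rho_short) == len(self.rho_open) == len(self.rho_liquid) == n):
            raise ConfigurationError("standard arrays must match the frequency grid")
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        for attr in ("rho_short", "rho_open", "rho_liquid"):
            vals = tuple(complex(v) for v in getattr(self, attr))
            object.__setattr__(self, attr, vals)
            mags = np.abs(np.asarray(vals))
            if np.any(mags > 1.0 + self.magnitude_tolerance):
                raise ConfigurationError(
                    f"{attr}: |rho| = {mags.max():.4f} exceeds passivity bound "
                    f"1 + {self.magnitude_tolerance}"
                )

    def at(self, frequency: float) -> tuple[complex, complex, complex]:
        idx = _match_frequency(np.asarray(self.frequencies), frequency)
        return self.rho_short[idx], self.rho_open[idx], self.rho_liquid[idx]


def forward_reflection(
    coeffs: CalibrationCoefficients, eps: ComplexPermittivity
) -> complex:
    """Map a complex permittivity to the reflection coefficient the probe sees.

    ``rho = (A2 + A3*eps*) / (A1 + eps*)``; the frequency is taken from ``eps``.
    """
    a1, a2, a3 = coeffs.at(eps.frequency)
    e = eps.eps_complex
    denom = a1 + e
    if abs(denom) < _SINGULARITY_TOL * max(1.0, abs(a1), abs(e)):
        raise SingularityError(f"A1 + eps* vanishes at {eps.frequency} Hz")
    return (a2 + a3 * e) / denom


def invert_reflection(
    coeffs: CalibrationCoefficients, rho_m: complex, frequency: float
) -> ComplexPermittivity:
    """Invert a measured reflection coefficient to complex permittivity.

    Exact Moebius inverse of :func:`forward_reflection`.  Results with
    ``eps_real`` outside [1, 1000] are flagged (``plausible=False``) and a
    :class:`~oecp.errors.PhysicalityWarning` is emitted, but no exception is
    raised, so noisy sweeps do not abort pipelines.
    """
    a1, a2, a3 = coeffs.at(frequency)
    denom = a3 - rho_m
    if abs(denom) < _SINGULARITY_TOL * max(1.0, abs(a3)):
        raise SingularityError(
            f"rho_m equals A3 (short-circuit limit) at {frequency} Hz"
        )
    eps_c = (a1 * rho_m - a2) / denom
    lo, hi = PLAUSIBLE_EPS_RANGE
    plausible = lo <= eps_c.real <= hi
    if not plausible:
        warnings.warn(
            f"inverted eps' = {eps_c.real:.3g} at {frequency} Hz is outside "
            f"[{lo}, {hi}]",
            PhysicalityWarning,
            stacklevel=2,
        )
    return ComplexPermittivity.from_complex(eps_c, frequency, plausible=plausible)


def solve_three_standard(
    standards: CalibrationStandards, frequency: float | None = None
) -> CalibrationCoefficients:
    """Solve the bilinear coefficients from short / open / liquid standards.

    With ``frequency=None`` the system is solved independently at every grid
    frequency.  Raises :class:`DegenerateStandardsError` when the open and
    liquid reflections coincide or the standard liquid is indistinguishable
    from air (``eps* = 1``).
    """
    if frequency is None:
        freqs = standards.frequencies
    else:
        freqs = (float(frequency),)
    a1s, a2s, a3s = [], [], []
    for f in freqs:
        rho1, rho2, rho3 = standards.at(f)
        eps_std = evaluate_debye(standards.standard_material, f).eps_complex
        if abs(rho2 - rho3) < _SINGULARITY_TOL:
            raise DegenerateStandardsError(
                f"open and liquid standards coincide at {f} Hz (rho2 = rho3)"
            )
        if abs(eps_std - 1.0) < _SINGULARITY_TOL:
            raise DegenerateStandardsError(
                f"standard liquid has eps* = 1 at {f} Hz; system underdetermined"
            )
        a3 = rho1
        a1 = (eps_std * (rho3 - rho1) + (rho1 - rho2)) / (rho2 - rho3)
        a2 = rho2 * (a1 + 1.0) - a3
        a1s.append(a1)
        a2s.append(a2)
        a3s.append(a3)
    return CalibrationCoefficients(freqs, tuple(a1s), tuple(a2s), tuple(a3s))


# ---------------------------------------------------------------------------
# Touchstone .s1p reading and coefficient CSV I/O
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def read_touchstone_s1p(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a one-port Touchstone file; return (frequencies_hz, s11_complex).

    Supports the option-line dialects ``# <HZ|KHZ|MHZ|GHZ> S <RI|MA|DB> R <z>``
    with '!' comments.  Touchstone defaults (GHz, MA) apply when the option
    line omits them.
    """
    unit_scale = 1e9
    fmt = "MA"
    freqs: list[float] = []
    s11: list[complex] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].upper().split()
                for i, tok in enumerate(tokens):
                    if tok in _UNIT_SCALE:
                        unit_scale = _UNIT_SCALE[tok]
                    elif tok in ("RI", "MA", "DB"):
                        fmt = tok
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed data line {line!r}")
            f, x, y = float(parts[0]), float(parts[1]), float(parts[2])
            if fmt == "RI":
                val = complex(x, y)
            elif fmt == "MA":
                val = x * np.exp(1j * np.deg2rad(y))
            else:  # DB
                val = 10.0 ** (x / 20.0) * np.exp(1j * np.deg2rad(y))
            freqs.append(f * unit_scale)
            s11.append(val)
    if not freqs:
        raise ValueError(f"{path}: no data lines found")
    return np.asarray(freqs), np.asarray(s11)


def standards_from_touchstone(
    short_path: str | Path,
    open_path: str | Path,
    liquid_path: str | Path,
    standard_material: MaterialModel,
    magnitude_tolerance: float = 0.05,
) -> CalibrationStandards:
    """Assemble :class:`CalibrationStandards` from three .s1p files."""
    f1, r1 = read_touchstone_s1p(short_path)
    f2, r2 = read_touchstone_s1p(open_path)
    f3, r3 = read_touchstone_s1p(liquid_path)
    if not (np.allclose(f1, f2) and np.allclose(f1, f3)):
        raise ConfigurationError("the three .s1p files are on different frequency grids")
    return CalibrationStandards(
        frequencies=tuple(f1),
        rho_short=tuple(r1),
        rho_open=tuple(r2),
        rho_liquid=tuple(r3),
        standard_material=standard_material,
        magnitude_tolerance=magnitude_tolerance,
    )


def write_coefficients_csv(coeffs: CalibrationCoefficients, path: str | Path) -> None:
    """Write per-frequency (A1, A2, A3) as CSV (re/im columns)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["frequency_hz", "a1_re", "a1_im", "a2_re", "a2_im", "a3_re", "a3_im"]
        )
        for f, a1, a2, a3 in zip(coeffs.frequencies, coeffs.a1, coeffs.a2, coeffs.a3):
            writer.writerow(
                [f"{f:.6g}"]
                + [f"{v:.10g}" for v in (a1.real, a1.imag, a2.real, a2.imag, a3.real, a3.imag)]
            )


def read_coefficients_csv(path: str | Path) -> CalibrationCoefficients:
    """Read a coefficient CSV written by :func:`write_coefficients_csv`."""
    freqs, a1s, a2s, a3s = [], [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            freqs.append(float(row["frequency_hz"]))
            a1s.append(complex(float(row["a1_re"]), float(row["a1_im"])))
            a2s.append(complex(float(row["a2_re"]), float(row["a2_im"])))
            a3s.append(complex(float(row["a3_re"]), float(row["a3_im"])))
    return CalibrationCoefficients(tuple(freqs), tuple(a1s), tuple(a2s), tuple(a3s))
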