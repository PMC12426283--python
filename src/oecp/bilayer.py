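"""Synthetic bilayer displacement sweeps.

The physical protocol this module emulates measures a probe that starts in
full contact with a solid Tissue 1 (Teflon) and is displaced in 0.05 mm
increments, either vertically or horizontally, into a liquid Tissue 2.  The
measured effective permittivity rises monotonically from the Teflon value
toward the liquid value, quickly at first and then slowly.

That transition is modeled here by a two-parameter exponential,

    eps_eff(d) = eps2' + (eps1' - eps2') * exp(-d / lambda),

with the transition scale ``lambda`` solved in closed form so that the curve
crosses 90% of Tissue 2's permittivity exactly at the configured ground-truth
sensing distance D_true:

    lambda = D_true / ln[(eps2' - eps1') / (0.1 * eps2')].

The equivalent conductivity is interpolated with the same exponential
weight.  The scale is recomputed from the materials' permittivities at each
evaluated frequency, so the 90% crossing sits at D_true at *every*
frequency; for weakly dispersive liquids lambda is essentially
frequency-independent.  The exponential family is an explicit modeling
assumption (monotone, analytically invertible), not a measured curve shape.

Measurement noise is additive complex Gaussian on the reflection
coefficient (instrument plane), with ``noise_rho`` the standard deviation of
each quadrature, so noise propagates nonlinearly through the Moebius
inversion exactly as in a real VNA chain.  Replicates differ only by their
noise streams, which are spawned deterministically from the master seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .calibration import CalibrationCoefficients, CalibrationStandards, forward_reflection
from .dielectric import (
    EPS0,
    ComplexPermittivity,
    FrequencyGrid,
    MaterialModel,
    evaluate_debye,
)
from .errors import ConfigurationError, IngestError

AXES = ("vertical", "horizontal")


@dataclass(frozen=True)
class ProbeGeometry:
    """Cross-sectional dimensions of an open-ended coaxial probe, in mm."""

    name: str
    inner_conductor_d: float
    insulator_d: float
    outer_conductor_d: float

    def __post_init__(self) -> None:
        if not (0 < self.inner_conductor_d < self.insulator_d < self.outer_conductor_d):
            raise ConfigurationError(
                f"probe {self.name!r}: diameters must satisfy "
                "0 < inner < insulator < outer, got "
                f"({self.inner_conductor_d}, {self.insulator_d}, {self.outer_conductor_d})"
            )


#: The two small-aperture probes characterized by the study.
G1 = ProbeGeometry("G1", 0.51, 1.68, 2.20)
G2 = ProbeGeometry("G2", 0.92, 2.98, 3.58)
PROBES: dict[str, ProbeGeometry] = {"G1": G1, "G2": G2}


@dataclass(frozen=True)
class BilayerConfig:
    """Ground truth for one synthetic bilayer condition.

    ``true_sensing_distance`` (mm) is the displacement at which the
    noise-free effective permittivity reaches 90% of Tissue 2's value.
    ``noise_rho`` is the per-quadrature standard deviation of the complex
    Gaussian noise added to every synthetic reflection coefficient.
    """

    tissue1: MaterialModel
    tissue2: MaterialModel
    probe: ProbeGeometry
    axis: str
    true_sensing_distance: float
    step: float = 0.05
    max_displacement: float = 2.0
    noise_rho: float = 0.0
    n_replicates: int = 5
    seed: int = 0
    transition_scale_mm: float | None = None  # overrides the closed-form lambda

    def __post_init__(self) -> None:
        problems = []
        if self.axis not in AXES:
            problems.append(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.step <= 0:
            problems.append(f"step must be > 0, got {self.step}")
        if not 0 < self.true_sensing_distance < self.max_displacement:
            problems.append(
                f"true_sensing_distance ({self.true_sensing_distance}) must lie in "
                f"(0, max_displacement={self.max_displacement})"
            )
        if self.noise_rho < 0:
            problems.append(f"noise_rho must be >= 0, got {self.noise_rho}")
        if self.n_replicates < 1:
            problems.append(f"n_replicates must be >= 1, got {self.n_replicates}")
        eps1 = evaluate_debye(self.tissue1, 300e6).eps_real
        eps2 = evaluate_debye(self.tissue2, 300e6).eps_real
        if not eps2 > eps1:
            problems.append(
                f"tissue2 eps' ({eps2:.3g}) must exceed tissue1 eps' ({eps1:.3g}) at 300 MHz"
            )
        if problems:
            raise ConfigurationError("invalid bilayer config: " + "; ".join(problems))

    def displacements(self) -> np.ndarray:
        """Displacement grid in mm, starting at 0 with constant step."""
        n = int(math.floor(self.max_displacement / self.step + 0.5))
        return np.round(np.arange(n + 1) * self.step, 9)


@dataclass(frozen=True)
class DisplacementSweep:
    """One replicate's measurements along one displacement axis.

    ``rho`` and ``eps_real`` are (n_frequencies, n_displacements) arrays;
    either may be None (a sweep may carry raw reflections, inverted
    permittivities, or both).
    """

    axis: str
    probe: ProbeGeometry
    replicate_id: int
    displacements: np.ndarray
    frequencies: np.ndarray
    rho: np.ndarray | None = None
    eps_real: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if d.size == 0:
            raise ConfigurationError("sweep has no displacements")
        steps = np.diff(d)
        if d.size > 1 and (np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)):
            raise ConfigurationError("displacements must be strictly increasing with constant step")
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "frequencies", f)
        for attr in ("rho", "eps_real"):
            arr = getattr(self, attr)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (f.size, d.size):
                    raise ConfigurationError(
                        f"{attr} must have shape (n_frequencies, n_displacements) = "
                        f"({f.size}, {d.size}), got {arr.shape}"
                    )
                object.__setattr__(self, attr, arr)
        if self.rho is None and self.eps_real is None:
            raise ConfigurationError("sweep must carry rho and/or eps_real")

    def frequency_index(self, frequency: float) -> int:
        idx = int(np.argmin(np.abs(self.frequencies - frequency)))
        if not np.isclose(self.frequencies[idx], frequency, rtol=1e-9, atol=1e-3):
            raise KeyError(f"frequency {frequency} Hz not in sweep")
        return idx

    def eps_real_at(self, frequency: float) -> np.ndarray:
        if self.eps_real is None:
            raise ConfigurationError(
                "sweep carries no inverted permittivities; invert rho first"
            )
        return np.asarray(self.eps_real[self.frequency_index(frequency)], dtype=float)


# ---------------------------------------------------------------------------
# Transition curve
# ---------------------------------------------------------------------------

def transition_scale(config: BilayerConfig, frequency: float) -> float:
    """Exponential scale lambda (mm) at one frequency.

    Solved so the noise-free curve crosses 0.9*eps2' exactly at
    ``true_sensing_distance``; raises if the 90% threshold is unreachable,
    i.e. (eps2' - eps1') <= 0.1*eps2'.
    """
    if config.transition_scale_mm is not None:
        return float(config.transition_scale_mm)
    eps1 = evaluate_debye(config.tissue1, frequency).eps_real
    eps2 = evaluate_debye(config.tissue2, frequency).eps_real
    contrast = eps2 - eps1
    if contrast <= 0.1 * eps2:
        raise ConfigurationError(
            f"90% threshold unreachable at {frequency} Hz: eps2'-eps1' = "
            f"{contrast:.3g} <= 0.1*eps2' = {0.1 * eps2:.3g}"
        )
    return config.true_sensing_distance / math.log(contrast / (0.1 * eps2))


def transition_curve(
    config: BilayerConfig, displacement: float, frequency: float
) -> ComplexPermittivity:
    """Noise-free effective permittivity of the bilayer at one displacement.

    Both the real permittivity and the equivalent conductivity are blended
    between Tissue 1 and Tissue 2 with the weight ``exp(-d/lambda)``.
    """
    if displacement < 0:
        raise ConfigurationError(f"displacement must be >= 0, got {displacement}")
    lam = transition_scale(config, frequency)
    p1 = evaluate_debye(config.tissue1, frequency)
    p2 = evaluate_debye(config.tissue2, frequency)
    w = math.exp(-displacement / lam)
    return ComplexPermittivity(
        frequency=frequency,
        eps_real=p2.eps_real + (p1.eps_real - p2.eps_real) * w,
        sigma=p2.sigma + (p1.sigma - p2.sigma) * w,
    )


def scale_lambda_by_aperture(
    lambda_ref: float, probe_ref: ProbeGeometry, probe_new: ProbeGeometry
) -> float:
    """Scale a transition length by the ratio of outer-conductor diameters.

    Sensing extent grows linearly with the aperture (outer conductor)
    diameter, so a scale known for one probe transfers to another as
    ``lambda_new = lambda_ref * outer_new / outer_ref``.
    """
    if lambda_ref <= 0:
        raise ConfigurationError(f"lambda_ref must be > 0, got {lambda_ref}")
    return lambda_ref * probe_new.outer_conductor_d / probe_ref.outer_conductor_d


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def _replicate_rng(seed: int, replicate_id: int, stream: int = 0) -> np.random.Generator:
    # deterministic child stream per (seed, replicate, purpose)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), int(replicate_id)]))


def synthesize_sweep(
    config: BilayerConfig,
    grid: FrequencyGrid,
    true_coeffs: CalibrationCoefficients,
    replicate_id: int = 0,
) -> DisplacementSweep:
    """Generate one replicate's reflection sweep from the bilayer model.

    For every (displacement, frequency), ``rho = forward(true_coeffs,
    eps_eff) + noise``.  With ``noise_rho = 0`` the sweep is deterministic;
    fixed (seed, replicate_id) always reproduces the identical sweep.
    """
    d = config.displacements()
    freqs = grid.as_array()
    rng = _replicate_rng(config.seed, replicate_id)
    rho = np.empty((freqs.size, d.size), dtype=complex)
    for i, f in enumerate(freqs):
        lam = transition_scale(config, f)
        p1 = evaluate_debye(config.tissue1, f)
        p2 = evaluate_debye(config.tissue2, f)
        w = np.exp(-d / lam)
        eps_r = p2.eps_real + (p1.eps_real - p2.eps_real) * w
        sigma = p2.sigma + (p1.sigma - p2.sigma) * w
        omega = 2.0 * np.pi * f
        eps_c = eps_r - 1j * sigma / (omega * EPS0)
        a1, a2, a3 = true_coeffs.at(f)
        rho[i] = (a2 + a3 * eps_c) / (a1 + eps_c)
    if config.noise_rho > 0:
        noise = rng.standard_normal(rho.shape) + 1j * rng.standard_normal(rho.shape)
        rho = rho + config.noise_rho * noise
    return DisplacementSweep(
        axis=config.axis,
        probe=config.probe,
        replicate_id=replicate_id,
        displacements=d,
        frequencies=freqs,
        rho=rho,
    )


def synthesize_replicates(
    config: BilayerConfig,
    grid: FrequencyGrid,
    true_coeffs: CalibrationCoefficients,
) -> list[DisplacementSweep]:
    """Generate ``config.n_replicates`` sweeps differing only by noise stream."""
    return [
        synthesize_sweep(config, grid, true_coeffs, replicate_id=r)
        for r in range(config.n_replicates)
    ]


def synthesize_standards(
    true_coeffs: CalibrationCoefficients,
    standard: MaterialModel,
    grid: FrequencyGrid,
    noise_rho: float = 0.0,
    seed: int = 0,
) -> CalibrationStandards:
    """Generate short/open/liquid standard reflections from true coefficients."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_001]))
    freqs = grid.as_array()
    rho1 = np.empty(freqs.size, dtype=complex)
    rho2 = np.empty(freqs.size, dtype=complex)
    rho3 = np.empty(freqs.size, dtype=complex)
    for i, f in enumerate(freqs):
        a1, a2, a3 = true_coeffs.at(f)
        rho1[i] = a3  # short: eps* -> infinity
        rho2[i] = (a2 + a3) / (a1 + 1.0)  # open: eps* = 1
        eps_std = evaluate_debye(standard, f).eps_complex
        rho3[i] = (a2 + a3 * eps_std) / (a1 + eps_std)
    if noise_rho > 0:
        for arr in (rho1, rho2, rho3):
            arr += noise_rho * (
                rng.standard_normal(arr.shape) + 1j * rng.standard_normal(arr.shape)
            )
    return CalibrationStandards(
        frequencies=tuple(freqs),
        rho_short=tuple(rho1),
        rho_open=tuple(rho2),
        rho_liquid=tuple(rho3),
        standard_material=standard,
        magnitude_tolerance=max(0.05, 5.0 * noise_rho),
    )


#: Aperture fringing capacitance of the 2.20 mm probe (F); scaled linearly
#: with outer-conductor diameter for other probes.
APERTURE_CAPACITANCE_REF = 50e-15
_Z0 = 50.0


def ideal_probe_coefficients(
    probe: ProbeGeometry,
    grid: FrequencyGrid,
    c_ref: float = APERTURE_CAPACITANCE_REF,
    z0: float = _Z0,
) -> CalibrationCoefficients:
    """Bilinear coefficients of an ideal capacitive-aperture probe.

    The aperture is modeled as a lumped fringing capacitance ``C`` loaded by
    the sample, giving ``rho = (K - eps*)/(K + eps*)`` with
    ``K = -j / (omega * z0 * C)``, i.e. (A1, A2, A3) = (K, K, -1).  ``C``
    scales linearly with the outer-conductor diameter.  These serve as the
    generator's "true" instrument coefficients.
    """
    cap = c_ref * probe.outer_conductor_d / G1.outer_conductor_d
    freqs = grid.as_array()
    ks = [-1j / (2.0 * np.pi * f * z0 * cap) for f in freqs]
    return CalibrationCoefficients(
        tuple(freqs), tuple(ks), tuple(ks), tuple(-1.0 + 0j for _ in ks)
    )


# ---------------------------------------------------------------------------
# Sweep CSV and config YAML I/O
# ---------------------------------------------------------------------------

SWEEP_CSV_COLUMNS = (
    "axis",
    "probe",
    "replicate",
    "frequency_hz",
    "displacement_mm",
    "rho_re",
    "rho_im",
    "eps_real",
)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_sweep_csv(sweeps: list[DisplacementSweep] | DisplacementSweep, path: str | Path) -> None:
    """Write sweeps in the canonical CSV schema (6 significant digits, LF)."""
    if isinstance(sweeps, DisplacementSweep):
        sweeps = [sweeps]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SWEEP_CSV_COLUMNS)
        for sw in sweeps:
            for i, f in enumerate(sw.frequencies):
                for j, d in enumerate(sw.displacements):
                    rho_re = rho_im = ""
                    if sw.rho is not None:
                        rho_re = _fmt(sw.rho[i, j].real)
                        rho_im = _fmt(sw.rho[i, j].imag)
                    eps = "" if sw.eps_real is None else _fmt(sw.eps_real[i, j])
                    writer.writerow(
                        [sw.axis, sw.probe.name, sw.replicate_id, _fmt(f), _fmt(d), rho_re, rho_im, eps]
                    )


def read_sweep_csv(
    path: str | Path, probes: dict[str, ProbeGeometry] | None = None
) -> list[DisplacementSweep]:
    """Read sweeps from the canonical CSV schema; one sweep per replicate.

    Missing rho columns (or empty values) are permitted when only eps' is
    recorded.  Raises :class:`IngestError` with the offending line number on
    malformed rows.
    """
    probes = PROBES if probes is None else probes
    rows: dict[tuple[str, str, int], list[tuple[float, float, complex | None, float | None]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "displacement_mm" not in reader.fieldnames:
            raise IngestError(f"{path}: not a sweep CSV (missing header)")
        has_rho = "rho_re" in reader.fieldnames and "rho_im" in reader.fieldnames
        has_eps = "eps_real" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                axis = row["axis"]
                probe_name = row["probe"]
                rep = int(row["replicate"])
                f = float(row["frequency_hz"])
                d = float(row["displacement_mm"])
                rho = None
                if has_rho and row["rho_re"] not in ("", None):
                    rho = complex(float(row["rho_re"]), float(row["rho_im"]))
                eps = None
                if has_eps and row["eps_real"] not in ("", None):
                    eps = float(row["eps_real"])
            except (KeyError, TypeError, ValueError) as exc:
                raise IngestError(f"{path}:{lineno}: malformed row ({exc})") from None
            if axis not in AXES:
                raise IngestError(f"{path}:{lineno}: unknown axis {axis!r}")
            rows.setdefault((axis, probe_name, rep), []).append((f, d, rho, eps))
    sweeps = []
    for (axis, probe_name, rep), recs in sorted(rows.items()):
        if probe_name not in probes:
            raise IngestError(f"{path}: unknown probe {probe_name!r}")
        freqs = sorted({r[0] for r in recs})
        disps = sorted({r[1] for r in recs})
        steps = np.diff(disps)
        if len(disps) > 1 and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            bad = disps[int(np.argmax(np.abs(steps - steps[0]))) + 1]
            raise IngestError(
                f"{path}: non-uniform displacement step at {bad} mm (replicate {rep})"
            )
        fidx = {f: i for i, f in enumerate(freqs)}
        didx = {d: j for j, d in enumerate(disps)}
        rho_arr = np.full((len(freqs), len(disps)), np.nan + 0j, dtype=complex)
        eps_arr = np.full((len(freqs), len(disps)), np.nan)
        any_rho = any_eps = False
        for f, d, rho, eps in recs:
            if rho is not None:
                rho_arr[fidx[f], didx[d]] = rho
                any_rho = True
            if eps is not None:
                eps_arr[fidx[f], didx[d]] = eps
                any_eps = True
        sweeps.append(
            DisplacementSweep(
                axis=axis,
                probe=probes[probe_name],
                replicate_id=rep,
                displacements=np.asarray(disps),
                frequencies=np.asarray(freqs),
                rho=rho_arr if any_rho else None,
                eps_real=eps_arr if any_eps else None,
            )
        )
    if not sweeps:
        raise IngestError(f"{path}: no data rows")
    return sweeps


def _material_to_record(mat: MaterialModel) -> dict:
    return {
        "name": mat.name,
        "eps_static": mat.eps_static,
        "eps_inf": mat.eps_inf,
        "tau": mat.tau,
        "sigma_static": mat.sigma_static,
        "temperature": mat.temperature,
    }


def save_bilayer_config(config: BilayerConfig, path: str | Path) -> None:
    """Serialize a bilayer configuration as YAML, field for field."""
    doc = {
        "tissue1": _material_to_record(config.tissue1),
        "tissue2": _material_to_record(config.tissue2),
        "probe": {
            "name": config.probe.name,
            "inner_conductor_d": config.probe.inner_conductor_d,
            "insulator_d": config.probe.insulator_d,
            "outer_conductor_d": config.probe.outer_conductor_d,
        },
        "axis": config.axis,
        "true_sensing_distance": config.true_sensing_distance,
        "step": config.step,
        "max_displacement": config.max_displacement,
        "noise_rho": config.noise_rho,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
        "transition_scale_mm": config.transition_scale_mm,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_bilayer_config(path: str | Path) -> BilayerConfig:
    """Load a bilayer configuration written by :func:`save_bilayer_config`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    t1 = MaterialModel(**doc["tissue1"])
    t2 = MaterialModel(**doc["tissue2"])
    probe = ProbeGeometry(**doc["probe"])
    return BilayerConfig(
        tissue1=t1,
        tissue2=t2,
        probe=probe,
        axis=doc["axis"],
        true_sensing_distance=doc["true_sensing_distance"],
        step=doc["step"],
        max_displacement=doc["max_displacement"],
        noise_rho=doc["noise_rho"],
        n_replicates=doc["n_replicates"],
        seed=doc["seed"],
        transition_scale_mm=doc.get("transition_scale_mm"),
    )


def invert_sweep(
    sweep: DisplacementSweep, coeffs: CalibrationCoefficients
) -> DisplacementSweep:
    """Return a copy of ``sweep`` with eps_real filled by Moebius inversion."""
    if sweep.rho is None:
        raise ConfigurationError("sweep carries no reflection coefficients to invert")
    eps = np.empty_like(sweep.rho, dtype=float)
    for i, f in enumerate(sweep.frequencies):
        a1, a2, a3 = coeffs.at(f)
        eps_c = (a1 * sweep.rho[i] - a2) / (a3 - sweep.rho[i])
        eps[i] = eps_c.real
    return replace(sweep, eps_real=eps)
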