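"""Debye material models and complex-permittivity arithmetic.

A material is described by a single-pole Debye relaxation

    eps(omega) = eps_inf + (eps_static - eps_inf) / (1 + j*omega*tau)

plus a static ionic conductivity ``sigma_static``.  The package works with
the complex relative permittivity under the e^{+j omega t} time-harmonic
convention,

    eps* = eps' - j * sigma / (omega * eps0),

so a lossy medium always has a negative imaginary part.  ``sigma`` here is
the *equivalent* conductivity: the dielectric (relaxation) loss and the
static ionic loss folded into a single term, which is what a reflection
measurement actually sees.

The packaged material library (``data/materials.yaml``) carries literature
Debye parameters for the reference liquids used to validate probe
calibrations (ethanol, methanol, deionized water) and dispersion-free
entries for Teflon and the two tissue-mimicking phantom solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

#: Vacuum permittivity, F/m (CODATA).
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class MaterialModel:
    """A named material with single-pole Debye parameters.

    Parameters
    ----------
    name:
        Human-readable identifier, e.g. ``"deionized_water"``.
    eps_static:
        Static (low-frequency) relative permittivity, dimensionless.
    eps_inf:
        High-frequency relative permittivity, dimensionless.
    tau:
        Relaxation time in seconds; ``tau = 0`` gives a dispersion-free
        material whose real permittivity equals ``eps_static`` everywhere.
    sigma_static:
        Static ionic conductivity in S/m.
    temperature:
        Reference temperature in degrees Celsius (annotation only).
    source:
        Free-text provenance note for the parameter set.
    """

    name: str
    eps_static: float
    eps_inf: float
    tau: float
    sigma_static: float = 0.0
    temperature: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        problems = []
        if not self.eps_static >= self.eps_inf:
            problems.append(
                f"eps_static ({self.eps_static}) must be >= eps_inf ({self.eps_inf})"
            )
        if not self.eps_inf >= 1.0:
            problems.append(f"eps_inf ({self.eps_inf}) must be >= 1")
        if self.tau < 0:
            problems.append(f"tau ({self.tau}) must be >= 0")
        if self.sigma_static < 0:
            problems.append(f"sigma_static ({self.sigma_static}) must be >= 0")
        if problems:
            raise ConfigurationError(
                f"invalid material {self.name!r}: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class ComplexPermittivity:
    """Complex relative permittivity at one frequency.

    Canonically stored as ``(frequency, eps_real, sigma)`` so that the
    decomposition round-trips exactly; ``eps_complex`` is derived.

    ``plausible`` is set to False (never raised) by reflection inversion when
    ``eps_real`` falls outside [1, 1000].
    """

    frequency: float
    eps_real: float
    sigma: float
    plausible: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise DomainError(f"frequency must be > 0, got {self.frequency}")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def eps_complex(self) -> complex:
        return complex(self.eps_real, -self.sigma / (self.omega * EPS0))

    @classmethod
    def from_complex(
        cls, value: complex, frequency: float, plausible: bool = True
    ) -> "ComplexPermittivity":
        """Decompose ``eps* = eps' - j sigma/(omega eps0)`` at ``frequency``."""
        if frequency <= 0:
            raise DomainError(f"frequency must be > 0, got {frequency}")
        omega = 2.0 * np.pi * frequency
        return cls(
            frequency=frequency,
            eps_real=float(np.real(value)),
            sigma=float(-np.imag(value) * omega * EPS0),
            plausible=plausible,
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing measurement frequencies in Hz."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.size == 0:
            raise ConfigurationError("frequency grid is empty")
        if np.any(freqs <= 0):
            raise ConfigurationError("frequencies must be positive")
        if np.any(np.diff(freqs) <= 0):
            raise ConfigurationError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", tuple(float(f) for f in freqs))

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """300 MHz to 1.5 GHz at 200 MHz intervals (7 points)."""
        return cls(tuple(np.arange(300e6, 1500e6 + 1.0, 200e6)))

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


def evaluate_debye(material: MaterialModel, frequency: float) -> ComplexPermittivity:
    """Evaluate a material's complex permittivity at one frequency.

    Returns a :class:`ComplexPermittivity` whose ``sigma`` is the equivalent
    conductivity: the Debye relaxation loss ``omega*eps0 * wt*(es-einf)/(1+wt^2)``
    plus the static conductivity.
    """
    if frequency <= 0:
        raise DomainError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * np.pi * frequency
    wt = omega * material.tau
    delta = material.eps_static - material.eps_inf
    eps_real = material.eps_inf + delta / (1.0 + wt * wt)
    eps_imag_debye = wt * delta / (1.0 + wt * wt)
    sigma = material.sigma_static + eps_imag_debye * omega * EPS0
    return ComplexPermittivity(frequency=frequency, eps_real=float(eps_real), sigma=float(sigma))


def complex_from_real_and_sigma(
    eps_real: float, sigma: float, frequency: float
) -> ComplexPermittivity:
    """Build a :class:`ComplexPermittivity` from its (eps', sigma) decomposition."""
    if frequency <= 0:
        raise DomainError(f"frequency must be > 0, got {frequency}")
    return ComplexPermittivity(frequency=frequency, eps_real=float(eps_real), sigma=float(sigma))


# ---------------------------------------------------------------------------
# Material library
# ---------------------------------------------------------------------------

def _library_path() -> Path:
    return Path(str(resources.files("oecp").joinpath("data/materials.yaml")))


def load_material_library(path: str | Path | None = None) -> dict[str, MaterialModel]:
    """Load a material library from YAML (the packaged one by default)."""
    path = _library_path() if path is None else Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    library: dict[str, MaterialModel] = {}
    for record in raw["materials"]:
        mat = MaterialModel(
            name=record["name"],
            eps_static=float(record["eps_static"]),
            eps_inf=float(record["eps_inf"]),
            tau=float(record["tau"]),
            sigma_static=float(record.get("sigma_static", 0.0)),
            temperature=record.get("temperature"),
            source=record.get("source"),
        )
        library[mat.name] = mat
    return library


def save_material_library(
    library: dict[str, MaterialModel], path: str | Path
) -> None:
    """Write a material library as a human-editable YAML file."""
    records = []
    for mat in library.values():
        rec = {
            "name": mat.name,
            "eps_static": mat.eps_static,
            "eps_inf": mat.eps_inf,
            "tau": mat.tau,
            "sigma_static": mat.sigma_static,
        }
        if mat.temperature is not None:
            rec["temperature"] = mat.temperature
        if mat.source is not None:
            rec["source"] = mat.source
        records.append(rec)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump({"materials": records}, fh, sort_keys=False)


_DEFAULT_LIBRARY: dict[str, MaterialModel] | None = None


def get_material(name: str) -> MaterialModel:
    """Fetch a material from the packaged library by name."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_material_library()
    try:
        return _DEFAULT_LIBRARY[name]
    except KeyError:
        known = ", ".join(sorted(_DEFAULT_LIBRARY))
        raise KeyError(f"unknown material {name!r}; library has: {known}") from None


def with_conductivity(material: MaterialModel, sigma_static: float) -> MaterialModel:
    """Copy of ``material`` with a different static conductivity."""
    return replace(material, sigma_static=sigma_static)
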