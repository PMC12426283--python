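"""End-to-end orchestration: generate -> calibrate -> invert -> extract -> stats.

A :class:`RunConfig` names the liquids, probes, axes and frequency grid of a
study; :func:`run_pipeline` then

1. builds the generator's "true" instrument coefficients for each probe,
2. synthesizes noisy calibration standards and solves the three-standard
   calibration,
3. synthesizes replicate displacement sweeps of reflection coefficients,
4. inverts them with the *fitted* coefficients (so calibration noise
   propagates, as on a real bench),
5. extracts sensing distances with the 90% rule and summarizes replicates,
6. runs the frequency-stability ANOVA per liquid and the radius-vs-depth
   OLS fit per probe and frequency,

and returns a :class:`RunReport` of tidy tables plus a provenance block.
Runs are deterministic for a fixed master seed: every random stream is
spawned from it in a fixed order, and CSV artifacts are written in a
canonical format (fixed column order, '.' decimal, LF endings, 6
significant digits).

The default ground-truth sensing distances are the study conditions: the
measured sensing depths/radii of the three reference liquids and the two
tissue phantoms for both probes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bilayer import (
    AXES,
    PROBES,
    BilayerConfig,
    DisplacementSweep,
    ideal_probe_coefficients,
    invert_sweep,
    read_sweep_csv,
    synthesize_replicates,
    synthesize_standards,
)
from .calibration import CalibrationCoefficients, CalibrationStandards, solve_three_standard
from .dielectric import FrequencyGrid, evaluate_debye, load_material_library
from .errors import ConfigurationError, DegenerateVarianceError, IngestError, SummaryError
from .extraction import (
    NOT_REACHED,
    extract_sensing_distance,
    summarize_replicates,
)
from .stats import anova_one_way, fit_linear

#: Ground-truth sensing distances (mm) per (material, probe, axis) used as
#: the generator's default study conditions: reference liquids and tissue
#: phantoms, both probes, vertical (depth) and horizontal (radius).
DEFAULT_SENSING_TABLE: dict[tuple[str, str, str], float] = {
    ("ethanol", "G1", "vertical"): 0.44,
    ("ethanol", "G1", "horizontal"): 0.36,
    ("ethanol", "G2", "vertical"): 0.75,
    ("ethanol", "G2", "horizontal"): 0.71,
    ("methanol", "G1", "vertical"): 0.50,
    ("methanol", "G1", "horizontal"): 0.42,
    ("methanol", "G2", "vertical"): 0.81,
    ("methanol", "G2", "horizontal"): 0.81,
    ("deionized_water", "G1", "vertical"): 0.62,
    ("deionized_water", "G1", "horizontal"): 0.63,
    ("deionized_water", "G2", "vertical"): 0.98,
    ("deionized_water", "G2", "horizontal"): 0.99,
    ("dmso", "G1", "vertical"): 0.55,
    ("dmso", "G1", "horizontal"): 0.45,
    ("dmso", "G2", "vertical"): 0.85,
    ("dmso", "G2", "horizontal"): 0.87,
    ("sugar_salt_solution", "G1", "vertical"): 0.58,
    ("sugar_salt_solution", "G1", "horizontal"): 0.55,
    ("sugar_salt_solution", "G2", "vertical"): 0.93,
    ("sugar_salt_solution", "G2", "horizontal"): 0.93,
}

#: Liquids included in the frequency-stability ANOVA by default.  The two
#: phantom solutions are characterized at a single frequency (300 MHz) and
#: are therefore excluded.
DEFAULT_STABILITY_MATERIALS = ("ethanol", "methanol", "deionized_water")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic sensing-volume study."""

    materials: tuple[str, ...] = DEFAULT_STABILITY_MATERIALS
    probes: tuple[str, ...] = ("G1", "G2")
    axes: tuple[str, ...] = ("vertical", "horizontal")
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    sensing_table: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SENSING_TABLE)
    )
    step: float = 0.05
    max_displacement: float = 2.0
    noise_rho: float = 1e-3
    n_replicates: int = 5
    seed: int = 0
    standard_material: str = "deionized_water"
    tissue1_material: str = "teflon"
    stability_materials: tuple[str, ...] = DEFAULT_STABILITY_MATERIALS
    selection: str = "nearest"

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` listing every violation at once."""
        library = load_material_library()
        problems: list[str] = []
        for m in set(self.materials) | {self.standard_material, self.tissue1_material}:
            if m not in library:
                problems.append(f"unknown material {m!r}")
        for p in self.probes:
            if p not in PROBES:
                problems.append(f"unknown probe {p!r}")
        for ax in self.axes:
            if ax not in AXES:
                problems.append(f"unknown axis {ax!r}")
        for m in self.materials:
            for p in self.probes:
                for ax in self.axes:
                    if (m, p, ax) not in self.sensing_table and p in PROBES and ax in AXES:
                        problems.append(f"sensing_table missing entry for ({m}, {p}, {ax})")
        if self.noise_rho < 0:
            problems.append(f"noise_rho must be >= 0, got {self.noise_rho}")
        if self.n_replicates < 1:
            problems.append(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.step <= 0:
            problems.append(f"step must be > 0, got {self.step}")
        for m in self.stability_materials:
            if m not in self.materials:
                problems.append(f"stability material {m!r} not among run materials")
        if problems:
            raise ConfigurationError("invalid run config: " + "; ".join(problems))

    def fingerprint(self) -> str:
        doc = {
            "materials": list(self.materials),
            "probes": list(self.probes),
            "axes": list(self.axes),
            "grid": list(self.grid.frequencies),
            "sensing_table": {"|".join(k): v for k, v in sorted(self.sensing_table.items())},
            "step": self.step,
            "max_displacement": self.max_displacement,
            "noise_rho": self.noise_rho,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "standard_material": self.standard_material,
            "tissue1_material": self.tissue1_material,
            "stability_materials": list(self.stability_materials),
            "selection": self.selection,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Tidy result tables of one pipeline run."""

    distances: pd.DataFrame  # one row per (condition, frequency, replicate)
    summaries: pd.DataFrame  # one row per (condition, frequency)
    anova: pd.DataFrame      # one row per (material, probe, axis)
    fits: pd.DataFrame       # one row per (probe, frequency)
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        """Write all tables as canonical CSVs plus a JSON report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in (
            ("distances", self.distances),
            ("summaries", self.summaries),
            ("anova", self.anova),
            ("fits", self.fits),
        ):
            frame.to_csv(
                outdir / f"{name}.csv", index=False, float_format="%.6g",
                lineterminator="\n",
            )
        doc = {
            "provenance": self.provenance,
            "n_conditions": int(len(self.summaries)),
            "anova": self.anova.to_dict(orient="records"),
            "fits": self.fits.to_dict(orient="records"),
        }
        with open(outdir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _condition_seed(master_seed: int, index: int) -> int:
    # deterministic, well-separated child seed per condition, < 2^31
    ss = np.random.SeedSequence([int(master_seed), 20_000 + int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic sensing-volume study.

    Idempotent for a fixed seed; ``not_reached`` extractions are recorded in
    the distance table and excluded from summaries, never fatal.
    """
    config.validate()
    library = load_material_library()
    tissue1 = library[config.tissue1_material]
    standard = library[config.standard_material]
    grid = config.grid

    # One calibration per (probe, replicate): each independent replicate
    # session measures its own standards, so calibration noise contributes
    # to within-replicate scatter instead of becoming a systematic
    # per-frequency bias shared by every replicate.
    fitted: dict[tuple[str, int], CalibrationCoefficients] = {}
    for k, probe_name in enumerate(config.probes):
        probe = PROBES[probe_name]
        true_coeffs = ideal_probe_coefficients(probe, grid)
        for r in range(config.n_replicates):
            standards = synthesize_standards(
                true_coeffs, standard, grid,
                noise_rho=config.noise_rho,
                seed=_condition_seed(config.seed, 90_000 + 100 * k + r),
            )
            fitted[(probe_name, r)] = solve_three_standard(standards)

    distance_rows: list[dict] = []
    summary_rows: list[dict] = []
    cond_index = 0
    # distances keyed by (material, probe, axis, frequency) -> replicate values
    extracted: dict[tuple, list] = {}
    for material_name in config.materials:
        material = library[material_name]
        for probe_name in config.probes:
            probe = PROBES[probe_name]
            for axis in config.axes:
                d_true = config.sensing_table[(material_name, probe_name, axis)]
                bilayer = BilayerConfig(
                    tissue1=tissue1,
                    tissue2=material,
                    probe=probe,
                    axis=axis,
                    true_sensing_distance=d_true,
                    step=config.step,
                    max_displacement=config.max_displacement,
                    noise_rho=config.noise_rho,
                    n_replicates=config.n_replicates,
                    seed=_condition_seed(config.seed, cond_index),
                )
                cond_index += 1
                true_coeffs = ideal_probe_coefficients(probe, grid)
                sweeps = synthesize_replicates(bilayer, grid, true_coeffs)
                inverted = [
                    invert_sweep(sw, fitted[(probe_name, sw.replicate_id)])
                    for sw in sweeps
                ]
                for f in grid:
                    eps2 = evaluate_debye(material, f).eps_real
                    dists = [
                        extract_sensing_distance(
                            sw, eps2, f, selection=config.selection
                        )
                        for sw in inverted
                    ]
                    key = (material_name, probe_name, axis, f)
                    extracted[key] = dists
                    for sw, dist in zip(inverted, dists):
                        distance_rows.append(
                            {
                                "material": material_name,
                                "probe": probe_name,
                                "axis": axis,
                                "frequency_hz": f,
                                "replicate": sw.replicate_id,
                                "distance_mm": dist.value,
                                "method": dist.method,
                            }
                        )
                    try:
                        summ = summarize_replicates(dists, condition=key)
                        summary_rows.append(
                            {
                                "material": material_name,
                                "probe": probe_name,
                                "axis": axis,
                                "frequency_hz": f,
                                "mean_mm": summ.mean,
                                "sd_mm": summ.sd,
                                "n": summ.n,
                                "n_not_reached": summ.n_not_reached,
                            }
                        )
                    except SummaryError:
                        summary_rows.append(
                            {
                                "material": material_name,
                                "probe": probe_name,
                                "axis": axis,
                                "frequency_hz": f,
                                "mean_mm": np.nan,
                                "sd_mm": np.nan,
                                "n": 0,
                                "n_not_reached": len(dists),
                            }
                        )

    # frequency-stability ANOVA per (material, probe, axis)
    anova_rows: list[dict] = []
    for material_name in config.stability_materials:
        for probe_name in config.probes:
            for axis in config.axes:
                groups = []
                for f in grid:
                    dists = extracted.get((material_name, probe_name, axis, f), [])
                    vals = [dd.value for dd in dists if dd.method != NOT_REACHED]
                    groups.append(vals)
                row = {
                    "material": material_name,
                    "probe": probe_name,
                    "axis": axis,
                    "degenerate": False,
                }
                usable = [g for g in groups if len(g) >= 2]
                if len(usable) < 2:
                    row.update(f_statistic=np.nan, p_value=np.nan,
                               df_between=np.nan, df_within=np.nan, degenerate=True)
                else:
                    try:
                        res = anova_one_way(usable)
                        row.update(
                            f_statistic=res.f_statistic, p_value=res.p_value,
                            df_between=res.df_between, df_within=res.df_within,
                        )
                    except DegenerateVarianceError:
                        # zero variance everywhere: perfect frequency stability
                        n_total = sum(len(g) for g in usable)
                        row.update(
                            f_statistic=0.0, p_value=1.0,
                            df_between=len(usable) - 1,
                            df_within=n_total - len(usable),
                            degenerate=True,
                        )
                anova_rows.append(row)

    # radius-vs-depth OLS per (probe, frequency), across materials
    fit_rows: list[dict] = []
    summaries = pd.DataFrame(summary_rows)
    if "vertical" in config.axes and "horizontal" in config.axes:
        for probe_name in config.probes:
            for f in grid:
                depths, radii = [], []
                for material_name in config.materials:
                    sel = summaries[
                        (summaries.material == material_name)
                        & (summaries.probe == probe_name)
                        & (summaries.frequency_hz == f)
                    ]
                    dv = sel[sel.axis == "vertical"].mean_mm
                    dh = sel[sel.axis == "horizontal"].mean_mm
                    if len(dv) and len(dh) and np.isfinite(dv.iloc[0]) and np.isfinite(dh.iloc[0]):
                        depths.append(float(dv.iloc[0]))
                        radii.append(float(dh.iloc[0]))
                if len(depths) >= 2 and len(set(depths)) > 1:
                    fit = fit_linear(depths, radii)
                    fit_rows.append(
                        {
                            "probe": probe_name,
                            "frequency_hz": f,
                            "slope": fit.slope,
                            "intercept": fit.intercept,
                            "r_squared": fit.r_squared,
                            "n": fit.n,
                        }
                    )

    provenance = {
        "seed": config.seed,
        "config_hash": config.fingerprint(),
        "package_version": __version__,
    }
    return RunReport(
        distances=pd.DataFrame(distance_rows),
        summaries=summaries,
        anova=pd.DataFrame(anova_rows),
        fits=pd.DataFrame(fit_rows),
        provenance=provenance,
    )


def ingest_measured_sweep(
    path: str | Path,
    standards: CalibrationStandards | None = None,
    coefficients: CalibrationCoefficients | None = None,
) -> list[DisplacementSweep]:
    """Read measured sweeps from the canonical CSV schema.

    Sweeps carrying only reflection coefficients require either calibration
    ``standards`` (solved here) or pre-solved ``coefficients`` to invert;
    eps'-only files pass straight through.  Returns one sweep per replicate,
    interchangeable with synthetic sweeps downstream.
    """
    sweeps = read_sweep_csv(path)
    needs_inversion = any(sw.eps_real is None for sw in sweeps)
    if needs_inversion:
        if coefficients is None and standards is None:
            raise IngestError(
                f"{path}: sweeps carry reflection coefficients but no permittivities; "
                "provide calibration standards (.s1p triple) or solved coefficients "
                "to invert them"
            )
        if coefficients is None:
            coefficients = solve_three_standard(standards)
        sweeps = [
            invert_sweep(sw, coefficients) if sw.eps_real is None else sw
            for sw in sweeps
        ]
    return sweeps
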