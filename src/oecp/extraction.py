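"""Sensing depth/radius extraction by the 90%-threshold rule.

The sensing distance is the displacement at which the measured real
permittivity reaches 90% of Tissue 2's value.  Because measurements are
recorded on a discrete displacement grid, a tolerance band of +/-3% around
the 90% target is used: samples with eps' in [0.87, 0.93]*eps2' are
"in band".  If no sample lands in the band but some sample exceeds the 93%
edge, the first such displacement is averaged with the last earlier
displacement still below the 87% edge (bracket averaging).  If the sweep
never reaches 87%, the outcome is reported as ``not_reached`` rather than
raised, so batch runs complete.

Only the real permittivity is thresholded; conductivity is carried through
the pipeline but not used for extraction.  No sub-step interpolation is
performed — the recorded micrometer positions themselves (or their bracket
average) are the estimate.

When several samples fall inside the band, the default selection takes the
one whose value is closest to the 90% target (ties go to the smaller
displacement), which keeps the discretization error of a monotone sweep
within half a step.  ``selection="first"`` instead records the first
in-band sample encountered while scanning outward, i.e. a sample near the
87% edge.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bilayer import DisplacementSweep
from .errors import ExtractionInputError, SummaryError

IN_BAND = "in_band"
BRACKET_AVERAGE = "bracket_average"
NOT_REACHED = "not_reached"


@dataclass(frozen=True)
class SensingDistance:
    """An extracted sensing depth (vertical) or radius (horizontal)."""

    value: float  # mm; NaN when method == not_reached
    axis: str
    method: str
    frequency: float
    band_low: float = 0.87
    band_high: float = 0.93
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if not self.band_low < 0.90 < self.band_high:
            raise ExtractionInputError(
                f"band [{self.band_low}, {self.band_high}] must straddle 0.90"
            )
        if self.method != NOT_REACHED and not self.value >= 0:
            raise ExtractionInputError(f"sensing distance must be >= 0, got {self.value}")

    @property
    def reached(self) -> bool:
        return self.method != NOT_REACHED


@dataclass(frozen=True)
class SensingVolumeSummary:
    """Replicate mean and sample SD for one (material, probe, axis, frequency)."""

    mean: float
    sd: float
    n: int
    condition: tuple = ()
    n_not_reached: int = 0
    sd_defined: bool = True


def extract_sensing_distance(
    sweep: DisplacementSweep,
    eps2_real: float,
    frequency: float,
    threshold: float = 0.90,
    band_halfwidth: float = 0.03,
    selection: str = "nearest",
) -> SensingDistance:
    """Apply the threshold rule to one sweep at one frequency.

    Parameters
    ----------
    eps2_real:
        Tissue 2's real permittivity at ``frequency``; the target value is
        ``threshold * eps2_real`` and the acceptance band is
        ``(threshold +/- band_halfwidth) * eps2_real``.
    selection:
        ``"nearest"`` (default): among in-band samples, record the one whose
        value is closest to the target.  ``"first"``: record the first
        in-band sample in displacement order.
    """
    if eps2_real <= 0:
        raise ExtractionInputError(f"eps2_real must be > 0, got {eps2_real}")
    if selection not in ("nearest", "first"):
        raise ExtractionInputError(f"unknown selection {selection!r}")
    d = sweep.displacements
    eps = sweep.eps_real_at(frequency)
    if d.size == 0:
        raise ExtractionInputError("empty sweep")
    if d.size > 1 and np.any(np.diff(d) <= 0):
        raise ExtractionInputError("displacements must be strictly increasing")

    target = threshold * eps2_real
    lo = (threshold - band_halfwidth) * eps2_real
    hi = (threshold + band_halfwidth) * eps2_real
    band_kwargs = dict(
        axis=sweep.axis,
        frequency=float(frequency),
        band_low=threshold - band_halfwidth,
        band_high=threshold + band_halfwidth,
        replicate_id=sweep.replicate_id,
    )

    in_band = (eps >= lo) & (eps <= hi)
    if np.any(in_band):
        idx = np.flatnonzero(in_band)
        if selection == "first":
            pick = idx[0]
        else:
            err = np.abs(eps[idx] - target)
            pick = idx[int(np.argmin(err))]  # argmin ties -> first
        return SensingDistance(value=float(d[pick]), method=IN_BAND, **band_kwargs)

    above = np.flatnonzero(eps > hi)
    if above.size:
        i_hi = above[0]
        below = np.flatnonzero(eps[:i_hi] < lo)
        # no sub-87% sample before the jump: the crossing precedes the grid
        d_lo = d[below[-1]] if below.size else d[0]
        return SensingDistance(
            value=float((d_lo + d[i_hi]) / 2.0), method=BRACKET_AVERAGE, **band_kwargs
        )

    return SensingDistance(value=math.nan, method=NOT_REACHED, **band_kwargs)


def summarize_replicates(
    distances: list[SensingDistance], condition: tuple = ()
) -> SensingVolumeSummary:
    """Mean and sample SD (n-1 denominator) over replicate sensing distances.

    ``not_reached`` entries are excluded and counted; a single usable value
    yields sd = 0 with ``sd_defined=False``.  Raises :class:`SummaryError`
    when no replicate reached the threshold.
    """
    if not distances:
        raise SummaryError("no replicate distances given")
    usable = [dist.value for dist in distances if dist.reached]
    n_excluded = len(distances) - len(usable)
    if not usable:
        raise SummaryError(
            f"no usable replicates ({n_excluded} not_reached) for condition {condition}"
        )
    arr = np.asarray(usable)
    if arr.size == 1:
        return SensingVolumeSummary(
            mean=float(arr[0]), sd=0.0, n=1, condition=condition,
            n_not_reached=n_excluded, sd_defined=False,
        )
    return SensingVolumeSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
        condition=condition,
        n_not_reached=n_excluded,
    )


# ---------------------------------------------------------------------------
# Results CSV
# ---------------------------------------------------------------------------

DISTANCES_CSV_COLUMNS = (
    "condition", "axis", "probe", "material", "frequency_hz",
    "replicate", "distance_mm", "method",
)
SUMMARY_CSV_COLUMNS = (
    "material", "probe", "axis", "frequency_hz", "mean_mm", "sd_mm", "n", "n_not_reached",
)


def write_distances_csv(records: list[dict], path: str | Path) -> None:
    """Write per-replicate extraction records (dicts keyed by column name)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.DictWriter(fh, fieldnames=DISTANCES_CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow({k: rec.get(k, "") for k in DISTANCES_CSV_COLUMNS})


def write_summary_csv(summaries: list[SensingVolumeSummary], path: str | Path) -> None:
    """Write condition summaries in a Table-style layout (mean, SD per condition)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SUMMARY_CSV_COLUMNS)
        for s in summaries:
            material, probe, axis, freq = (list(s.condition) + [""] * 4)[:4]
            writer.writerow(
                [material, probe, axis, f"{freq:.6g}" if freq != "" else "",
                 f"{s.mean:.6g}", f"{s.sd:.6g}", s.n, s.n_not_reached]
            )
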