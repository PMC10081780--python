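"""Bead and light dosimetry arithmetic for fibrin-labeling experiments.

Carboxylate-modified polystyrene microspheres ("beads", 20 nm diameter) are
supplied as a weight/volume suspension; the number concentration follows from
the solids fraction, the material density and the bead diameter.  Downstream
quantities — serial dilutions, the expected number of beads occupying one
fibrin fiber's volume, and the optical energy deposited during time-lapse
imaging — are simple deterministic arithmetic, kept at full precision here
and rounded only when formatting reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BeadPrep",
    "FiberGeometry",
    "LightSchedule",
    "beads_per_mL",
    "beads_per_uL",
    "dilute",
    "fiber_volume",
    "beads_per_fiber_volume",
    "light_dose",
    "dilution_series",
    "dosimetry_report",
    "sig_round",
]

#: cubic micrometres per microlitre
UM3_PER_UL = 1e9

#: dilution factors of the standard serial-dilution experiment
DEFAULT_DILUTION_FACTORS = (100, 300, 1000, 2000, 3000, 10000)


@dataclass(frozen=True)
class BeadPrep:
    """A bead stock suspension.

    Parameters
    ----------
    solids_fraction:
        Weight/volume fraction of bead material, e.g. ``0.02`` for a
        "2% solids" stock.
    material_density:
        Density of the bead material in g/mL (1.05 for polystyrene).
    bead_diameter:
        Bead diameter in μm (0.02 for 20 nm fluorospheres).
    dilution_factor:
        Dilution applied to the stock, ``>= 1`` (1 = undiluted).
    """

    solids_fraction: float = 0.02
    material_density: float = 1.05
    bead_diameter: float = 0.02
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.solids_fraction <= 1.0:
            raise ValueError(f"solids_fraction must be in [0, 1], got {self.solids_fraction}")
        if self.material_density <= 0:
            raise ValueError(f"material_density must be > 0, got {self.material_density}")
        if self.bead_diameter <= 0:
            raise ValueError(f"bead_diameter must be > 0, got {self.bead_diameter}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")


@dataclass(frozen=True)
class FiberGeometry:
    """Cylindrical reference geometry of a single fibrin fiber (μm)."""

    length: float = 20.0
    diameter: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"fiber length must be > 0, got {self.length}")
        if self.diameter <= 0:
            raise ValueError(f"fiber diameter must be > 0, got {self.diameter}")

    @property
    def volume(self) -> float:
        """Cylinder volume π·(d/2)²·L in μm³."""
        return math.pi * (self.diameter / 2.0) ** 2 * self.length


@dataclass(frozen=True)
class LightSchedule:
    """Illumination schedule of a time-lapse acquisition.

    ``continuous`` keeps the shutter open for ``total_duration`` seconds;
    ``gated`` opens it only for ``n_exposures`` exposures of
    ``exposure_time`` seconds each.  The default power, 170 μW, is the
    midpoint of the 160–180 μW measured at the sample plane; the default
    gated schedule is one 200 ms exposure every 30 s over one hour.
    """

    power: float = 170e-6
    mode: str = "continuous"
    total_duration: float = 3600.0
    n_exposures: int = 120
    exposure_time: float = 0.2

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError(f"power must be >= 0, got {self.power}")
        if self.mode not in ("continuous", "gated"):
            raise ValueError(f"mode must be 'continuous' or 'gated', got {self.mode!r}")
        if self.total_duration < 0:
            raise ValueError("total_duration must be >= 0")
        if self.mode == "gated":
            if self.n_exposures < 0 or self.exposure_time < 0:
                raise ValueError("gated schedule requires non-negative exposures")
            if self.n_exposures * self.exposure_time > self.total_duration:
                raise ValueError(
                    "gated schedule inconsistent: "
                    f"{self.n_exposures} x {self.exposure_time} s exceeds "
                    f"total_duration {self.total_duration} s"
                )


def beads_per_mL(prep: BeadPrep) -> float:
    """Number concentration of an *undiluted* stock, beads/mL.

    Uses the manufacturer relation ``6·C·10¹² / (ρ·π·d³)`` with C the
    solids fraction, ρ the material density (g/mL) and d the bead diameter
    (μm).  The dilution factor of ``prep`` is deliberately not applied;
    see :func:`dilute`.
    """
    return 6.0 * prep.solids_fraction * 1e12 / (
        prep.material_density * math.pi * prep.bead_diameter ** 3
    )


def beads_per_uL(prep: BeadPrep) -> float:
    """Undiluted stock concentration in beads/μL (beads/mL ÷ 10³)."""
    return beads_per_mL(prep) / 1e3


def dilute(stock: float, factor: float) -> float:
    """Concentration after a ``1:factor`` dilution (factor ≥ 1)."""
    if factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {factor}")
    return stock / factor


def fiber_volume(geom: FiberGeometry) -> float:
    """Reference fiber volume in μm³ (0.157 for the 20 μm × 100 nm default)."""
    return geom.volume


def beads_per_fiber_volume(conc_per_uL: float, geom: FiberGeometry) -> float:
    """Expected bead count inside one fiber volume at a solution concentration.

    ``conc_per_uL`` is beads/μL; one μL is 10⁹ μm³.
    """
    if conc_per_uL < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_per_uL}")
    return conc_per_uL / UM3_PER_UL * fiber_volume(geom)


def light_dose(schedule: LightSchedule) -> float:
    """Energy (J) deposited into the sample over one acquisition."""
    if schedule.mode == "continuous":
        return schedule.power * schedule.total_duration
    return schedule.power * schedule.n_exposures * schedule.exposure_time


def dilution_series(
    prep: BeadPrep, factors: tuple[float, ...] = DEFAULT_DILUTION_FACTORS
) -> dict[float, float]:
    """Map dilution factor → concentration (beads/μL) for a stock prep."""
    stock = beads_per_uL(prep)
    return {f: dilute(stock, f) for f in factors}


def sig_round(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (report formatting only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def dosimetry_report(
    prep: BeadPrep,
    geom: FiberGeometry,
    schedule: LightSchedule | None = None,
    factors: tuple[float, ...] = DEFAULT_DILUTION_FACTORS,
) -> dict:
    """Flat report of all derived dosimetry quantities.

    Concentrations are display-rounded to 3 significant figures and
    beads-per-fiber-volume to 2; full precision is available through the
    individual functions.
    """
    stock_uL = beads_per_uL(prep)
    working = dilute(stock_uL, prep.dilution_factor)
    report = {
        "stock_beads_per_mL": sig_round(beads_per_mL(prep), 3),
        "stock_beads_per_uL": sig_round(stock_uL, 3),
        "dilution_factor": prep.dilution_factor,
        "working_beads_per_uL": sig_round(working, 3),
        "fiber_volume_um3": sig_round(fiber_volume(geom), 2),
        "stock_beads_per_fiber_volume": sig_round(
            beads_per_fiber_volume(stock_uL, geom), 2
        ),
        "working_beads_per_fiber_volume": sig_round(
            beads_per_fiber_volume(working, geom), 2
        ),
        "dilution_series_beads_per_uL": {
            str(f): sig_round(c, 3) for f, c in dilution_series(prep, factors).items()
        },
        "dilution_series_beads_per_fiber_volume": {
            str(f): sig_round(beads_per_fiber_volume(c, geom), 2)
            for f, c in dilution_series(prep, factors).items()
        },
    }
    if schedule is not None:
        report["light_dose_J"] = sig_round(light_dose(schedule), 3)
        report["light_mode"] = schedule.mode
    return report
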