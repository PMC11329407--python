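"""Age-dependent tensile-failure thresholds and the degenerated-volume statistic.

Two threshold families for the onset of collagen-network damage are provided:

* a piecewise-linear monotonic-tension threshold digitized from Kempson's
  human cartilage tensile data (30 MPa up to age 30, declining to a 6.8 MPa
  plateau above 75 years);
* a cyclic fatigue threshold after Weightman,
  ``25.4 - 0.15 Age - 1.65 log10(N)`` MPa for N loading cycles
  (N = 1e5, 1e6, 1e7 are the representative choices).

An element counts as degenerated when its maximum principal solid stress
exceeds the threshold at any stance frame; only central-region elements are
counted, and volumes are normalized by the central-region cartilage volume
of the compartment (both tissues), so femoral + tibial fractions sum to the
compartment fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CompartmentMesh, element_volumes
from .mechanics import StressField


def threshold_kempson(age: float) -> float:
    """Piecewise monotonic-tension failure threshold (MPa) at a given age."""
    if age <= 0:
        raise ValueError("age must be positive")
    if age <= 30:
        return 30.0
    if age <= 45:
        return 30.0 - (age - 30.0) * (20.0 / 15.0)
    if age <= 65:
        return 10.0 - (age - 45.0) * (3.0 / 20.0)
    if age <= 75:
        return 7.0 - (age - 65.0) * (2.0 / 100.0)
    return 6.8


def threshold_weightman(age: float, cycles: float) -> float:
    """Cyclic tensile fatigue threshold (MPa): 25.4 - 0.15 Age - 1.65 log10(N)."""
    if age <= 0:
        raise ValueError("age must be positive")
    if cycles < 1:
        raise ValueError("cycle count must be at least 1")
    value = 25.4 - 0.15 * age - 1.65 * np.log10(cycles)
    if value <= 0:
        raise ValueError(
            f"fatigue threshold exhausted at age {age}, N = {cycles:g}"
        )
    return float(value)


@dataclass(frozen=True)
class ThresholdSpec:
    """A named threshold choice evaluated at a subject's age."""

    kind: str  # "kempson" | "weightman"
    age: float
    cycles: float | None = None

    @property
    def value(self) -> float:
        if self.kind == "kempson":
            return threshold_kempson(self.age)
        if self.kind == "weightman":
            if self.cycles is None:
                raise ValueError("weightman threshold needs a cycle count")
            return threshold_weightman(self.age, self.cycles)
        raise ValueError(f"unknown threshold kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "kempson":
            return "kempson"
        return f"weightman@{self.cycles:.0e}".replace("e+0", "e")


@dataclass(frozen=True)
class DegenerationResult:
    """Degenerated-volume fractions for one compartment.

    Per-tissue fractions are normalized by the same compartment reference
    (central-region cartilage of both tissues), so femoral + tibial equals
    the compartment fraction.
    """

    fraction_femoral: float
    fraction_tibial: float
    fraction_compartment: float
    reference_volume: float  # mm^3
    degenerated_volume: float  # mm^3
    threshold_mpa: float
    compartment: str = ""


def degenerated_volume(
    field: StressField, mesh: CompartmentMesh, threshold: float
) -> DegenerationResult:
    """Degenerated central-region volume fraction from a stance stress field."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if field.envelope.shape[0] != mesh.n_elements:
        raise ValueError("stress field and mesh are inconsistent")
    central = mesh.region == "central"
    vol = element_volumes(mesh)
    ref = vol[central].sum()
    exceeded = central & (field.envelope > threshold)
    out = {}
    for tissue in ("femoral_cartilage", "tibial_cartilage"):
        mask = exceeded & (mesh.tissue == tissue)
        out[tissue] = vol[mask].sum() / ref
    deg = vol[exceeded].sum()
    return DegenerationResult(
        fraction_femoral=float(out["femoral_cartilage"]),
        fraction_tibial=float(out["tibial_cartilage"]),
        fraction_compartment=float(deg / ref),
        reference_volume=float(ref),
        degenerated_volume=float(deg),
        threshold_mpa=float(threshold),
        compartment=mesh.compartment,
    )


def overall_knee_fraction(
    medial: DegenerationResult, lateral: DegenerationResult
) -> float:
    """Whole-knee fraction: summed degenerated volume over summed references."""
    ref = medial.reference_volume + lateral.reference_volume
    return (medial.degenerated_volume + lateral.degenerated_volume) / ref
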