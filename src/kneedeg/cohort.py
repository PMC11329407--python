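"""Synthetic study cohort: subject records, KL grouping, and a seeded generator.

The generator emulates the marginal summaries of a knee-osteoarthritis study
population (97 knees, 71% female, KL follow-up split 29/37/31 across
KL 0–1 / KL 2 / KL 3–4) using distributions matched to published
median/inter-quartile summaries: log-normal for positively skewed lengths and
mass, normal for age, walking speed and frontal-plane alignment.  Height and
mass are coupled through a Gaussian copula; other variables are independent.

KL grade at follow-up is planted through a latent score built from a
mechanistic quantity (peak medial joint contact force per unit medial
cartilage thickness) plus standard-normal noise, so that downstream
classification pipelines can be validated against a known effect size.  A
real study observes outcomes; this link is an explicit synthetic construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

G = 9.81  # m/s^2

# median and [Q1, Q3] of the emulated population ("All" column of the study
# demographics table); lengths in mm, mass kg, height cm, speed m/s, deg
_MARGINALS = {
    "age": (58.00, 53.75, 61.25, "normal"),
    "mass": (73.60, 64.35, 88.32, "lognormal"),
    "height": (166.5, 159.9, 172.9, "lognormal"),
    "walking_speed": (1.37, 1.25, 1.50, "normal"),
    "joint_alignment": (5.14, 2.49, 7.21, "normal"),
    "icd": (40.60, 37.8, 43.4, "lognormal"),
    "ap_medial": (53.05, 51.05, 56.42, "lognormal"),
    "ap_lateral": (62.59, 59.62, 65.88, "lognormal"),
    "js_medial": (4.79, 4.37, 5.48, "lognormal"),
    "js_lateral": (5.38, 4.74, 6.20, "lognormal"),
    "femoral_fraction_medial": (0.55, 0.48, 0.5725, "normal"),
    "femoral_fraction_lateral": (0.40, 0.36, 0.46, "normal"),
}

FEMALE_FRACTION = 0.71
RIGHT_FRACTION = 0.57
# follow-up KL group proportions KL 0-1 / KL 2 / KL 3-4
GROUP_COUNTS_REF = (29, 37, 31)

# half inter-quartile width of a standard normal: Phi^-1(0.75) - Phi^-1(0.25)
_IQR_Z = 1.3489795003921634

_RANGES = {
    "age": (30.0, 95.0),
    "mass": (35.0, 180.0),
    "height": (130.0, 210.0),
    "walking_speed": (0.4, 2.5),
    "joint_alignment": (-12.0, 22.0),
    "femoral_fraction_medial": (0.2, 0.8),
    "femoral_fraction_lateral": (0.2, 0.8),
}


@dataclass(frozen=True)
class Subject:
    """Demographic and gait record for one knee."""

    id: str
    age: float
    sex: str  # "female" | "male"
    mass: float  # kg
    height: float  # cm
    walking_speed: float  # m/s
    joint_alignment: float  # degrees, frontal plane (positive = varus)
    knee_side: str  # "left" | "right"
    kl_baseline: int
    kl_followup: int

    def __post_init__(self) -> None:
        if self.age <= 0 or self.mass <= 0 or self.height <= 0:
            raise ValueError("age, mass and height must be positive")
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.knee_side not in ("left", "right"):
            raise ValueError(f"unknown knee_side {self.knee_side!r}")
        for g in (self.kl_baseline, self.kl_followup):
            if not (0 <= int(g) <= 4):
                raise ValueError(f"KL grade {g} outside 0-4")


@dataclass(frozen=True)
class AnatomicMeasurements:
    """MRI-style anatomic measurements for one knee (lengths in mm)."""

    icd: float
    ap_medial: float
    ap_lateral: float
    js_medial: float
    js_lateral: float
    femoral_fraction_medial: float
    femoral_fraction_lateral: float

    def __post_init__(self) -> None:
        for name in ("icd", "ap_medial", "ap_lateral", "js_medial", "js_lateral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("femoral_fraction_medial", "femoral_fraction_lateral"):
            f = getattr(self, name)
            if not (0.0 < f < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1)")

    def joint_space(self, compartment: str) -> float:
        return self.js_medial if compartment == "medial" else self.js_lateral

    def femoral_fraction(self, compartment: str) -> float:
        if compartment == "medial":
            return self.femoral_fraction_medial
        return self.femoral_fraction_lateral


def assign_kl_group(subject: "Subject | int") -> str:
    """Map a follow-up KL grade to its study group label.

    Grades 0–1 → ``"KL01"``, 2 → ``"KL2"``, 3–4 → ``"KL34"``.
    """
    grade = subject.kl_followup if isinstance(subject, Subject) else subject
    grade = int(grade)
    if not 0 <= grade <= 4:
        raise ValueError(f"KL grade {grade} outside 0-4")
    if grade <= 1:
        return "KL01"
    if grade == 2:
        return "KL2"
    return "KL34"


def _draw_marginal(rng: np.ndarray, name: str) -> np.ndarray:
    """Transform standard-normal draws to the matched marginal."""
    med, q1, q3, kind = _MARGINALS[name]
    z = rng
    if kind == "lognormal":
        sigma = np.log(q3 / q1) / _IQR_Z
        x = med * np.exp(sigma * z)
    else:
        sigma = (q3 - q1) / _IQR_Z
        x = med + sigma * z
    lo, hi = _RANGES.get(name, (1e-9, np.inf))
    return np.clip(x, lo, hi)


def clean_peak_loads(frame: pd.DataFrame) -> pd.DataFrame:
    """Noise-free musculoskeletal surrogate for peak stance-phase JCFs.

    Returns body-weight-normalized peak joint contact forces (columns
    ``peak_medial_bw``, ``peak_lateral_bw``, ``peak_total_bw``).  The total
    peak increases with walking speed and decreases weakly with body mass;
    a varus (positive) frontal-plane alignment shifts load to the medial
    compartment.  Compartment maxima occur at different gait instants, so the
    two compartment peaks sum to slightly more than the total peak.
    """
    sex_female = (frame["sex"] == "female").astype(float)
    total = (
        2.2
        + 0.55 * (frame["walking_speed"] - 1.37)
        - 0.006 * (frame["mass"] - 73.6)
        + 0.002 * (frame["height"] - 166.5)
        - 0.003 * (frame["age"] - 58.0)
        - 0.05 * sex_female
    )
    total = np.clip(total, 0.8, None)
    share_med = np.clip(0.5 + 0.018 * frame["joint_alignment"], 0.35, 0.85)
    out = pd.DataFrame(index=frame.index)
    out["peak_total_bw"] = total
    out["peak_medial_bw"] = total * share_med
    out["peak_lateral_bw"] = total * (1.0 - share_med) * 1.06
    return out


def generate_cohort_frame(
    n: int,
    seed: int,
    effect_size: float = 1.5,
    copula_rho: float = 0.5,
) -> pd.DataFrame:
    """Generate a synthetic cohort table, one row per knee.

    ``effect_size`` controls the planted association between the latent
    mechanical score (noise-free peak medial JCF per unit medial cartilage
    thickness) and follow-up KL grade; 0 makes KL independent of mechanics.
    """
    if n < 3:
        raise ValueError("n must be at least 3 (one knee per KL group)")
    rng = np.random.default_rng(seed)

    df = pd.DataFrame({"id": [f"K{i:04d}" for i in range(n)]})
    # Gaussian copula between height and mass, remaining variables independent
    rho = float(copula_rho)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z_hm = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    df["height"] = _draw_marginal(z_hm[:, 0], "height")
    df["mass"] = _draw_marginal(z_hm[:, 1], "mass")
    for name in (
        "age",
        "walking_speed",
        "joint_alignment",
        "icd",
        "ap_medial",
        "ap_lateral",
        "js_medial",
        "js_lateral",
        "femoral_fraction_medial",
        "femoral_fraction_lateral",
    ):
        df[name] = _draw_marginal(rng.standard_normal(n), name)
    df["sex"] = np.where(rng.random(n) < FEMALE_FRACTION, "female", "male")
    df["knee_side"] = np.where(rng.random(n) < RIGHT_FRACTION, "right", "left")
    df["kl_baseline"] = rng.integers(0, 2, size=n)

    # latent-score KL assignment: extreme tertile-like split 29/37/31
    peaks = clean_peak_loads(df)
    mech = peaks["peak_medial_bw"].to_numpy() * df["mass"].to_numpy() * G
    mech = mech / df["js_medial"].to_numpy()
    z_mech = (mech - mech.mean()) / mech.std()
    latent = effect_size * z_mech + rng.standard_normal(n)

    n1 = int(round(n * GROUP_COUNTS_REF[0] / sum(GROUP_COUNTS_REF)))
    n2 = int(round(n * GROUP_COUNTS_REF[1] / sum(GROUP_COUNTS_REF)))
    n1, n2 = max(n1, 1), max(n2, 1)
    if n1 + n2 >= n:  # tiny cohorts: keep one knee for the top group
        n2 = max(n - n1 - 1, 1)
        n1 = n - n2 - 1
    order = np.argsort(latent, kind="stable")
    grade = np.empty(n, dtype=int)
    grade[order[:n1]] = rng.integers(0, 2, size=n1)  # KL 0-1
    grade[order[n1 : n1 + n2]] = 2  # KL 2
    grade[order[n1 + n2 :]] = rng.integers(3, 5, size=n - n1 - n2)  # KL 3-4
    df["kl_followup"] = grade
    df["kl_group"] = [assign_kl_group(int(g)) for g in grade]
    return df


def generate_cohort(
    n: int, seed: int, effect_size: float = 1.5, copula_rho: float = 0.5
) -> list[tuple[Subject, AnatomicMeasurements]]:
    """Generate the cohort as (Subject, AnatomicMeasurements) records."""
    frame = generate_cohort_frame(n, seed, effect_size, copula_rho)
    return list(iter_records(frame))


def iter_records(frame: pd.DataFrame) -> Iterator[tuple[Subject, AnatomicMeasurements]]:
    """Yield typed (Subject, AnatomicMeasurements) records from a cohort table."""
    for row in frame.itertuples(index=False):
        subject = Subject(
            id=row.id,
            age=float(row.age),
            sex=str(row.sex),
            mass=float(row.mass),
            height=float(row.height),
            walking_speed=float(row.walking_speed),
            joint_alignment=float(row.joint_alignment),
            knee_side=str(row.knee_side),
            kl_baseline=int(row.kl_baseline),
            kl_followup=int(row.kl_followup),
        )
        meas = AnatomicMeasurements(
            icd=float(row.icd),
            ap_medial=float(row.ap_medial),
            ap_lateral=float(row.ap_lateral),
            js_medial=float(row.js_medial),
            js_lateral=float(row.js_lateral),
            femoral_fraction_medial=float(row.femoral_fraction_medial),
            femoral_fraction_lateral=float(row.femoral_fraction_lateral),
        )
        yield subject, meas
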