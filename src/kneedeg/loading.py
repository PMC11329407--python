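"""Stance-phase compartmental loading under three individualization schemes.

All schemes pair an axial joint contact force (JCF) curve with a fixed knee
flexion-angle trajectory over the stance phase (0-100%, 51 grid points):

* ``50%/50%`` — peak total JCF = body weight x a literature peak multiplier
  (default 2.6 BW), split evenly between compartments;
* ``LS-NN`` — load sharing between compartments predicted by a shallow
  neural network, total peak still from body weight;
* ``LS & Peak-NN`` — both compartment peaks taken directly from the network.

The network is a single-hidden-layer feed-forward regressor (tanh, default
width 10) mapping standardized (height, mass, walking speed, frontal-plane
alignment, age, sex) to the three stance peaks in body weights.  It is
trained on a synthetic musculoskeletal surrogate whose noise is calibrated so
the attainable correlations mirror those reported for musculoskeletal-model
-trained networks (medial ~0.61, lateral ~0.67, total ~0.80).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .cohort import G, Subject, clean_peak_loads, generate_cohort_frame

PREDICTOR_COLUMNS = ["height", "mass", "walking_speed", "joint_alignment", "age", "sex"]
TARGET_COLUMNS = ["peak_medial_bw", "peak_lateral_bw", "peak_total_bw"]
# attainable correlation ceilings for the surrogate targets
TARGET_R = {"peak_medial_bw": 0.61, "peak_lateral_bw": 0.67, "peak_total_bw": 0.80}

STANCE_GRID = np.linspace(0.0, 100.0, 51)


@dataclass(frozen=True)
class ReferenceGaitCurve:
    """Normalized total-JCF shape (max 1) and fixed flexion trajectory."""

    stance_percent: np.ndarray
    normalized_jcf: np.ndarray
    flexion_deg: np.ndarray
    peak_bw_multiplier: float = 2.6

    def __post_init__(self) -> None:
        if np.any(self.normalized_jcf < 0):
            raise ValueError("reference JCF shape must be non-negative")


@dataclass(frozen=True)
class GaitLoading:
    """Per-compartment axial force curves (N) paired with flexion angles."""

    stance_percent: np.ndarray
    flexion_deg: np.ndarray
    force_medial: np.ndarray
    force_lateral: np.ndarray
    peak_total: float
    peak_medial: float
    peak_lateral: float
    share_medial: float
    share_lateral: float
    scheme: str = ""

    def force(self, compartment: str) -> np.ndarray:
        return self.force_medial if compartment == "medial" else self.force_lateral


def reference_curve(
    peak_bw_multiplier: float = 2.6,
    n_points: int = 51,
) -> ReferenceGaitCurve:
    """Default analytic stance curve: two humps (~25% and ~75% stance) with a
    midstance trough at ~0.6 of the peak, and a flexion trajectory peaking at
    ~15 deg near 15% stance with ~5 deg at midstance."""
    s = np.linspace(0.0, 100.0, n_points)
    window = np.sin(np.pi * s / 100.0) ** 0.5
    humps = 1.0 + 0.35 * np.cos(2.0 * np.pi * (s - 25.0) / 50.0)
    tilt = 1.0 - 0.0008 * (s - 25.0)  # push-off hump slightly below loading response
    shape = window * humps * tilt
    shape = np.clip(shape, 0.0, None)
    shape /= shape.max()
    flexion = 5.0 + 10.0 * np.exp(-(((s - 15.0) / 14.0) ** 2))
    return ReferenceGaitCurve(s, shape, flexion, peak_bw_multiplier)


def read_curve_csv(path, peak_bw_multiplier: float = 2.6) -> ReferenceGaitCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return ReferenceGaitCurve(
        df["stance_percent"].to_numpy(float),
        df["normalized_jcf"].to_numpy(float),
        df["flexion_deg"].to_numpy(float),
        peak_bw_multiplier,
    )


def write_curve_csv(curve: ReferenceGaitCurve, path) -> None:
    pd.DataFrame(
        {
            "stance_percent": curve.stance_percent,
            "normalized_jcf": curve.normalized_jcf,
            "flexion_deg": curve.flexion_deg,
        }
    ).to_csv(path, index=False)


def _make_loading(curve, peak_medial, peak_lateral, peak_total, scheme,
                  contact_fraction=1.0):
    shape = curve.normalized_jcf
    return GaitLoading(
        stance_percent=curve.stance_percent,
        flexion_deg=curve.flexion_deg,
        force_medial=shape * peak_medial * contact_fraction,
        force_lateral=shape * peak_lateral * contact_fraction,
        peak_total=peak_total,
        peak_medial=peak_medial * contact_fraction,
        peak_lateral=peak_lateral * contact_fraction,
        share_medial=peak_medial / peak_total,
        share_lateral=peak_lateral / peak_total,
        scheme=scheme,
    )


def loading_5050(
    subject: Subject, curve: ReferenceGaitCurve, contact_fraction: float = 1.0
) -> GaitLoading:
    """Even 50%/50% split of a body-weight-scaled total peak JCF."""
    peak_total = curve.peak_bw_multiplier * subject.mass * G
    half = 0.5 * peak_total
    return _make_loading(curve, half, half, peak_total, "50/50", contact_fraction)


class PeakPredictor:
    """Single-hidden-layer tanh network predicting stance JCF peaks (BW).

    Holds the trained weights plus input/output standardization constants;
    prediction is a plain numpy forward pass, so a predictor restored from
    JSON needs no fitted scikit-learn estimator.
    """

    def __init__(self, coefs, intercepts, x_mean, x_scale, y_mean, y_scale,
                 hidden_width: int):
        self.coefs = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_scale = np.asarray(x_scale, dtype=float)
        self.y_mean = np.asarray(y_mean, dtype=float)
        self.y_scale = np.asarray(y_scale, dtype=float)
        self.hidden_width = hidden_width

    def predict_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        x = frame[PREDICTOR_COLUMNS].copy()
        if x["sex"].dtype == object:
            x["sex"] = (x["sex"] == "female").astype(float)
        xs = (x.to_numpy(float) - self.x_mean) / self.x_scale
        h = np.tanh(xs @ self.coefs[0] + self.intercepts[0])
        ys = h @ self.coefs[1] + self.intercepts[1]
        y = ys * self.y_scale + self.y_mean
        y = np.clip(y, 0.05, None)  # peaks are physically positive
        return pd.DataFrame(y, columns=TARGET_COLUMNS, index=frame.index)

    def predict_subject(self, subject: Subject) -> tuple[float, float, float]:
        frame = pd.DataFrame(
            [
                {
                    "height": subject.height,
                    "mass": subject.mass,
                    "walking_speed": subject.walking_speed,
                    "joint_alignment": subject.joint_alignment,
                    "age": subject.age,
                    "sex": 1.0 if subject.sex == "female" else 0.0,
                }
            ]
        )
        row = self.predict_frame(frame).iloc[0]
        return (
            float(row["peak_medial_bw"]),
            float(row["peak_lateral_bw"]),
            float(row["peak_total_bw"]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden_width": self.hidden_width,
                "coefs": [c.tolist() for c in self.coefs],
                "intercepts": [b.tolist() for b in self.intercepts],
                "x_mean": self.x_mean.tolist(),
                "x_scale": self.x_scale.tolist(),
                "y_mean": self.y_mean.tolist(),
                "y_scale": self.y_scale.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PeakPredictor":
        d = json.loads(text)
        return cls(
            d["coefs"], d["intercepts"], d["x_mean"], d["x_scale"],
            d["y_mean"], d["y_scale"], d["hidden_width"],
        )


def make_training_table(
    n: int, seed: int, noise_scale: float = 1.0
) -> pd.DataFrame:
    """Synthetic musculoskeletal surrogate training table.

    Noise-free peaks come from the linear surrogate (mass, speed, alignment;
    alignment medializes load); Gaussian noise is added per target with a
    standard deviation chosen so corr(observed, noise-free) equals the
    configured attainable ceiling.  ``noise_scale`` = 0 gives noise-free
    targets.
    """
    frame = generate_cohort_frame(n, seed, effect_size=0.0)
    rng = np.random.default_rng(seed + 1)
    clean = clean_peak_loads(frame)
    table = frame[["id"] + PREDICTOR_COLUMNS].copy()
    table["sex"] = (frame["sex"] == "female").astype(float)
    for col in TARGET_COLUMNS:
        r = TARGET_R[col]
        sd_clean = clean[col].std()
        noise_sd = noise_scale * sd_clean * np.sqrt(1.0 / r**2 - 1.0)
        table[col] = clean[col] + rng.normal(0.0, noise_sd, size=n)
    return table


def train_peak_predictor(
    training_table: pd.DataFrame, seed: int, hidden_width: int = 10
) -> PeakPredictor:
    """Train the peak predictor (deterministic given seed)."""
    missing = [c for c in PREDICTOR_COLUMNS + TARGET_COLUMNS
               if c not in training_table.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing}")
    x = training_table[PREDICTOR_COLUMNS].copy()
    if x["sex"].dtype == object:
        x["sex"] = (x["sex"] == "female").astype(float)
    x = x.to_numpy(float)
    y = training_table[TARGET_COLUMNS].to_numpy(float)
    x_mean, x_scale = x.mean(axis=0), x.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean, y_scale = y.mean(axis=0), y.std(axis=0)
    y_scale[y_scale == 0] = 1.0
    net = MLPRegressor(
        hidden_layer_sizes=(hidden_width,),
        activation="tanh",
        solver="lbfgs",
        alpha=1e-3,
        max_iter=6000,
        random_state=seed,
    )
    net.fit((x - x_mean) / x_scale, (y - y_mean) / y_scale)
    return PeakPredictor(
        net.coefs_, net.intercepts_, x_mean, x_scale, y_mean, y_scale, hidden_width
    )


def evaluate_predictor(predictor: PeakPredictor, table: pd.DataFrame) -> dict:
    """Pearson r between predictions and (noisy) targets, per output."""
    pred = predictor.predict_frame(table)
    return {
        col: float(np.corrcoef(pred[col], table[col])[0, 1])
        for col in TARGET_COLUMNS
    }


def loading_ls_nn(
    subject: Subject,
    curve: ReferenceGaitCurve,
    predictor: PeakPredictor,
    contact_fraction: float = 1.0,
) -> GaitLoading:
    """Network-predicted load sharing with a body-weight-scaled total peak.

    Shares are ratios of independently predicted compartment maxima to the
    predicted total maximum; because compartment maxima occur at different
    gait instants, the shares are not renormalized to sum to one.
    """
    med_bw, lat_bw, tot_bw = predictor.predict_subject(subject)
    if tot_bw <= 0:
        raise ValueError("predicted total peak JCF must be positive")
    peak_total = curve.peak_bw_multiplier * subject.mass * G
    return _make_loading(
        curve,
        (med_bw / tot_bw) * peak_total,
        (lat_bw / tot_bw) * peak_total,
        peak_total,
        "LS-NN",
        contact_fraction,
    )


def loading_ls_peak_nn(
    subject: Subject,
    curve: ReferenceGaitCurve,
    predictor: PeakPredictor,
    contact_fraction: float = 1.0,
) -> GaitLoading:
    """Network-predicted load sharing and compartment peaks."""
    med_bw, lat_bw, tot_bw = predictor.predict_subject(subject)
    if tot_bw <= 0:
        raise ValueError("predicted total peak JCF must be positive")
    bw = subject.mass * G
    return _make_loading(
        curve, med_bw * bw, lat_bw * bw, tot_bw * bw, "LS&Peak-NN", contact_fraction
    )


LOADING_SCHEMES = ("50/50", "LS-NN", "LS&Peak-NN")


def build_loading(
    scheme: str,
    subject: Subject,
    curve: ReferenceGaitCurve,
    predictor: PeakPredictor | None = None,
    contact_fraction: float = 1.0,
) -> GaitLoading:
    """Dispatch to one of the three loading schemes by name."""
    if scheme == "50/50":
        return loading_5050(subject, curve, contact_fraction)
    if predictor is None:
        raise ValueError(f"scheme {scheme!r} needs a trained peak predictor")
    if scheme == "LS-NN":
        return loading_ls_nn(subject, curve, predictor, contact_fraction)
    if scheme == "LS&Peak-NN":
        return loading_ls_peak_nn(subject, curve, predictor, contact_fraction)
    raise ValueError(f"unknown loading scheme {scheme!r}")
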