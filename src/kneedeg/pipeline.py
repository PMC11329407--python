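"""End-to-end experiment orchestration.

For every knee of a (synthetic or loaded) cohort and every model variant
(thickness mode x loading scheme), the pipeline scales the compartment
templates, builds the stance loading, solves the contact surrogate, applies
every configured degeneration threshold, and finally runs the statistical
layer: a KL-contrast AUC grid (three contrasts x lateral/medial/overall,
with DeLong p-values) and the nonparametric comparison battery.  Per-knee
failures are logged and skipped so a cohort-scale run survives individual
degenerate inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import assign_kl_group, generate_cohort_frame, iter_records
from .degeneration import ThresholdSpec, degenerated_volume, overall_knee_fraction
from .geometry import TemplateConfig, build_template, scale_mesh
from .loading import build_loading, make_training_table, reference_curve, train_peak_predictor
from .mechanics import FEMUR_PROPS, TIBIA_PROPS, simulate_stance
from .stats import delong_test, nonparametric_battery

log = logging.getLogger("kneedeg")

KL_CONTRASTS = (("KL01", "KL2"), ("KL01", "KL34"), ("KL2", "KL34"))
SCOPES = ("lateral", "medial", "overall")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment grid."""

    n: int = 97
    seed: int = 1
    effect_size: float = 1.5
    thickness_modes: tuple = ("fixed_ratio", "scaled_ratio")
    loading_schemes: tuple = ("50/50", "LS-NN", "LS&Peak-NN")
    thresholds: tuple = (
        ("kempson", None),
        ("weightman", 1e5),
        ("weightman", 1e6),
        ("weightman", 1e7),
    )
    central_fraction: float = 1.0 / 3.0
    peak_bw_multiplier: float = 2.6
    nn_training_size: int = 500
    cohort_csv: str | None = None  # load instead of generating
    template: TemplateConfig = field(default_factory=TemplateConfig)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n", "seed", "effect_size", "thickness_modes", "loading_schemes",
                "thresholds", "central_fraction", "peak_bw_multiplier",
                "nn_training_size", "cohort_csv",
            )
        }
        d["template"] = {
            "nx": self.template.nx,
            "nz": self.template.nz,
            "layers_femoral": self.template.layers_femoral,
            "layers_tibial": self.template.layers_tibial,
        }
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Top-level keys mirror the constructor arguments; ``template`` may be
        a mapping of :class:`TemplateConfig` fields.  ``thresholds`` entries
        are (kind, cycles) pairs, cycles null for the monotonic threshold.
        """
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "template" in raw:
            raw["template"] = TemplateConfig(**raw["template"])
        for key in ("thickness_modes", "loading_schemes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(
                (kind, None if cycles is None else float(cycles))
                for kind, cycles in raw["thresholds"]
            )
        return cls(**raw)


@dataclass
class ExperimentResult:
    cohort: pd.DataFrame
    degeneration: pd.DataFrame  # long table, one row per knee x variant x threshold
    auc_grid: pd.DataFrame
    comparisons: list
    manifest: dict
    errors: list

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        self.degeneration.to_csv(out / "degeneration.csv", index=False)
        self.auc_grid.to_csv(out / "auc_grid.csv", index=False)
        pd.DataFrame([c.__dict__ for c in self.comparisons]).to_csv(
            out / "comparisons.csv", index=False
        )
        with open(out / "manifest.json", "w") as f:
            json.dump(self.manifest, f, indent=2, default=str)


def simulate_cohort(config: RunConfig, cohort: pd.DataFrame | None = None) -> tuple:
    """Mechanics + degeneration for every knee x variant; returns the long
    degeneration table and the per-knee error log."""
    if cohort is None:
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
        else:
            cohort = generate_cohort_frame(config.n, config.seed, config.effect_size)

    curve = reference_curve(config.peak_bw_multiplier)
    predictor = None
    if any(s != "50/50" for s in config.loading_schemes):
        table = make_training_table(config.nn_training_size, config.seed + 10_000)
        predictor = train_peak_predictor(table, config.seed % (2**31 - 1))

    templates = {
        c: build_template(c, config.template) for c in ("medial", "lateral")
    }
    tmpl_meas = config.template.measurements

    rows = []
    errors = []
    for subject, meas in iter_records(cohort):
        try:
            for mode in config.thickness_modes:
                meshes = {
                    c: scale_mesh(templates[c], tmpl_meas, meas, mode,
                                  config.central_fraction)
                    for c in ("medial", "lateral")
                }
                for scheme in config.loading_schemes:
                    loading = build_loading(scheme, subject, curve, predictor)
                    fields = {
                        c: simulate_stance(meshes[c], loading, FEMUR_PROPS, TIBIA_PROPS)
                        for c in ("medial", "lateral")
                    }
                    for kind, cycles in config.thresholds:
                        spec = ThresholdSpec(kind, subject.age, cycles)
                        res = {
                            c: degenerated_volume(fields[c], meshes[c], spec.value)
                            for c in ("medial", "lateral")
                        }
                        overall = overall_knee_fraction(res["medial"], res["lateral"])
                        variant = f"{scheme}|{mode}"
                        for c in ("medial", "lateral"):
                            rows.append(
                                {
                                    "knee_id": subject.id,
                                    "kl_group": assign_kl_group(subject),
                                    "age": subject.age,
                                    "variant": variant,
                                    "thickness_mode": mode,
                                    "loading_scheme": scheme,
                                    "threshold": spec.label,
                                    "threshold_mpa": spec.value,
                                    "compartment": c,
                                    "fraction": res[c].fraction_compartment,
                                    "fraction_femoral": res[c].fraction_femoral,
                                    "fraction_tibial": res[c].fraction_tibial,
                                    "fraction_overall": overall,
                                }
                            )
        except Exception as exc:  # noqa: BLE001 - per-knee robustness
            log.warning("knee %s failed: %s", subject.id, exc)
            errors.append({"knee_id": subject.id, "error": str(exc)})
    return cohort, pd.DataFrame(rows), errors


def auc_grid(degeneration: pd.DataFrame) -> pd.DataFrame:
    """KL-contrast AUC grid with DeLong p-values, per variant x threshold."""
    rows = []
    for (variant, threshold), sub in degeneration.groupby(["variant", "threshold"]):
        knee = sub.pivot_table(
            index=["knee_id", "kl_group"], columns="compartment", values="fraction"
        ).reset_index()
        knee["overall"] = sub.groupby("knee_id")["fraction_overall"].first().loc[
            knee["knee_id"]
        ].to_numpy()
        for scope in SCOPES:
            for lo, hi in KL_CONTRASTS:
                pos = knee.loc[knee["kl_group"] == hi, scope].to_numpy()
                neg = knee.loc[knee["kl_group"] == lo, scope].to_numpy()
                if len(pos) < 2 or len(neg) < 2:
                    continue
                roc = delong_test(pos, neg, label=f"{lo} vs {hi}")
                rows.append(
                    {
                        "variant": variant,
                        "threshold": threshold,
                        "scope": scope,
                        "contrast": f"{lo} vs {hi}",
                        "auc": roc.auc,
                        "delong_p": roc.p_value,
                        "n_pos": roc.n_pos,
                        "n_neg": roc.n_neg,
                    }
                )
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, outdir=None) -> ExperimentResult:
    """Run the full grid and statistical layer; optionally write artifacts."""
    cohort, degeneration, errors = simulate_cohort(config)
    grid = auc_grid(degeneration) if len(degeneration) else pd.DataFrame()
    comparisons = []
    if len(degeneration):
        headline = degeneration[
            degeneration["threshold"] == "weightman@1e6"
        ]
        if len(headline) == 0:
            headline = degeneration[
                degeneration["threshold"] == degeneration["threshold"].iloc[0]
            ]
        comparisons = nonparametric_battery(headline)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_knees": int(cohort.shape[0]),
        "n_failed": len(errors),
    }
    result = ExperimentResult(cohort, degeneration, grid, comparisons, manifest, errors)
    if outdir is not None:
        result.write(outdir)
    return result
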