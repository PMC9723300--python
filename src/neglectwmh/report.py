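"""Experiment orchestration and the model-comparison report.

``run_experiment`` takes an :class:`ExperimentConfig` (constructible from a
YAML file), simulates or loads a cohort, fits every requested model version
with the shared repetition substreams, optionally runs permutation tests, and
writes schema-stable CSV reports plus a reproducibility manifest.  Reruns with
the same config and seed produce byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .design import DEFAULT_VAR_THRESHOLD, build_design, make_fold_safe_builder
from .features import MODEL_VERSIONS
from .permutation import NullDistribution, null_distribution
from .simulate import CohortTable, SimulationConfig, read_cohort, simulate_cohort
from .streams import RandomStream
from .svr import CvConfig, FitResult, run_repetitions

_FLOAT_FMT = "%.10g"


class ReportError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Everything needed to rerun an experiment end to end."""

    seed: int = 0
    cohort: Union[SimulationConfig, str, Path] = field(default_factory=SimulationConfig)
    versions: list[str] = field(default_factory=lambda: ["base", "add_bilateral"])
    cv: CvConfig = field(default_factory=CvConfig)
    var_threshold: float = DEFAULT_VAR_THRESHOLD
    pca_mode: str = "pooled"         # "pooled" (PCA on full cohort) | "fold-safe"
    perm_versions: list[str] = field(default_factory=list)
    n_perm: int = 0
    perm_mode: str = "fast"
    outdir: Union[str, Path] = "experiment_out"

    def __post_init__(self) -> None:
        if not self.versions:
            raise ReportError("at least one model version is required")
        if "base" not in self.versions:
            raise ReportError("the 'base' (lesion-only) version must be included for comparison")
        for v in self.versions + self.perm_versions:
            if v not in MODEL_VERSIONS:
                raise ReportError(f"unknown model version {v!r}")
        if self.pca_mode not in ("pooled", "fold-safe"):
            raise ReportError("pca_mode must be 'pooled' or 'fold-safe'")

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "versions": list(self.versions),
            "var_threshold": self.var_threshold,
            "pca_mode": self.pca_mode,
            "perm_versions": list(self.perm_versions),
            "n_perm": self.n_perm,
            "perm_mode": self.perm_mode,
            "outdir": str(self.outdir),
            "cv": {
                "outer_k": self.cv.outer_k,
                "inner_k": self.cv.inner_k,
                "epsilon": self.cv.epsilon,
                "C_grid_log2": [float(np.log2(c)) for c in self.cv.C_grid],
                "gamma_grid_log2": [float(np.log2(g)) for g in self.cv.gamma_grid],
                "n_repetitions": self.cv.n_repetitions,
            },
        }
        if isinstance(self.cohort, SimulationConfig):
            sim = {
                k: v
                for k, v in dataclasses.asdict(self.cohort).items()
                if k != "critical_region"
            }
            sim["grid"] = list(sim["grid"])
            sim["voxel_size_mm"] = list(sim["voxel_size_mm"])
            sim["lesion_volume_lognormal"] = list(sim["lesion_volume_lognormal"])
            d["cohort"] = {"synthetic": sim}
        else:
            d["cohort"] = {"directory": str(self.cohort)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cv_d = d.get("cv", {})
        cv = CvConfig(
            outer_k=cv_d.get("outer_k", 10),
            inner_k=cv_d.get("inner_k", 5),
            epsilon=cv_d.get("epsilon", 0.1),
            C_grid=2.0 ** np.asarray(cv_d.get("C_grid_log2", list(range(-5, 16))), dtype=float),
            gamma_grid=2.0 ** np.asarray(cv_d.get("gamma_grid_log2", list(range(-15, 6))), dtype=float),
            n_repetitions=cv_d.get("n_repetitions", 10),
        )
        cohort_d = d.get("cohort", {})
        cohort: Union[SimulationConfig, str]
        if "directory" in cohort_d:
            cohort = cohort_d["directory"]
        else:
            sim = dict(cohort_d.get("synthetic", {}))
            for key in ("grid", "voxel_size_mm", "lesion_volume_lognormal"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cohort = SimulationConfig(**sim)
        return cls(
            seed=d.get("seed", 0),
            cohort=cohort,
            versions=list(d.get("versions", ["base"])),
            cv=cv,
            var_threshold=d.get("var_threshold", DEFAULT_VAR_THRESHOLD),
            pca_mode=d.get("pca_mode", "pooled"),
            perm_versions=list(d.get("perm_versions", [])),
            n_perm=d.get("n_perm", 0),
            perm_mode=d.get("perm_mode", "fast"),
            outdir=d.get("outdir", "experiment_out"),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    report: pd.DataFrame
    fits: dict[str, FitResult]
    nulls: dict[str, NullDistribution]
    cohort: CohortTable
    paths: dict[str, Path]


def _load_cohort(config: ExperimentConfig) -> CohortTable:
    if isinstance(config.cohort, SimulationConfig):
        sim = dataclasses.replace(config.cohort, seed=config.seed)
        return simulate_cohort(sim)
    return read_cohort(config.cohort)


def run_experiment(config: ExperimentConfig, write: bool = True) -> ExperimentResult:
    """Fit all requested model versions (and permutation tests) and write the
    comparison report."""
    cohort = _load_cohort(config)
    y = cohort.targets()
    stream = RandomStream(config.seed)

    fits: dict[str, FitResult] = {}
    for name in config.versions:
        if config.pca_mode == "fold-safe":
            features = make_fold_safe_builder(cohort, name, config.var_threshold)
        else:
            features = build_design(cohort, name, config.var_threshold).values
        fits[name] = run_repetitions(features, y, config.cv, stream)

    nulls: dict[str, NullDistribution] = {}
    if config.n_perm > 0:
        for name in config.perm_versions:
            nulls[name] = null_distribution(
                cohort,
                name,
                config.cv,
                config.n_perm,
                stream,
                mode=config.perm_mode,
                var_threshold=config.var_threshold,
                true_fit=fits.get(name),
            )

    rows = []
    base_r2 = fits["base"].r2_averaged
    for name in config.versions:
        fit = fits[name]
        row = {"version": name, "r2_averaged": fit.r2_averaged, "delta_r2_vs_base": fit.r2_averaged - base_r2,
               "r2_stability": float(fit.r2_per_repetition.max() - fit.r2_per_repetition.min())}
        for r, val in enumerate(fit.r2_per_repetition):
            row[f"r2_rep{r}"] = val
        row["p_perm"] = nulls[name].p_value if name in nulls else np.nan
        row["perm_significant_quantile_rule"] = (
            nulls[name].significant_quantile_rule if name in nulls else pd.NA
        )
        rows.append(row)
    report = pd.DataFrame(rows)

    paths: dict[str, Path] = {}
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["report"] = outdir / "report.csv"
        report.to_csv(paths["report"], index=False, float_format=_FLOAT_FMT)
        pred_df = pd.DataFrame({"id": cohort.table["id"], "target": y})
        for name, fit in fits.items():
            pred_df[f"pred_{name}"] = fit.averaged_predictions
        paths["predictions"] = outdir / "predictions.csv"
        pred_df.to_csv(paths["predictions"], index=False, float_format=_FLOAT_FMT)
        for name, null in nulls.items():
            paths[f"null_{name}"] = null.to_csv(outdir / f"null_{name}.csv")
            paths[f"null_{name}_plot"] = null.plot(outdir / f"null_{name}.png")
        import nibabel, scipy, sklearn  # versions for the manifest

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "substreams": "SIM/RATING/FLAIR for simulation; (CV, repetition, fold) for "
                          "sample randomization; (PERM, k) for permutation k",
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "nibabel": nibabel.__version__,
            },
        }
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ExperimentResult(report=report, fits=fits, nulls=nulls, cohort=cohort, paths=paths)


def compare_versions(report: pd.DataFrame) -> pd.DataFrame:
    """Ordered comparison table: ΔR² vs base and across-repetition stability."""
    if "base" not in set(report["version"]):
        raise ReportError("report lacks the base version")
    base_r2 = float(report.loc[report["version"] == "base", "r2_averaged"].iloc[0])
    out = report[["version", "r2_averaged", "r2_stability", "p_perm"]].copy()
    out["delta_r2_vs_base"] = out["r2_averaged"] - base_r2
    return out.sort_values("r2_averaged", ascending=False).reset_index(drop=True)
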