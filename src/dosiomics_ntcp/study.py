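"""Orchestration of the full cross-fractionation modelling study.

Eight models are built from two cohorts (HF and CF) and three dose
representations (physical dose, BED at α/β = 2 Gy and 3 Gy):

=============  ==========  ==============  =========================
model          training    representation  evaluated on
=============  ==========  ==============  =========================
HF_BED2        HF          bed2            HF (apparent), CF (test)
HF_BED3        HF          bed3            HF (apparent), CF (test)
CF_BED2        CF          bed2            CF (apparent), HF (test)
CF_BED3        CF          bed3            CF (apparent), HF (test)
HFCF_BED2      HF + CF     bed2            HF and CF separately
HFCF_BED3      HF + CF     bed3            HF and CF separately
HF_PhyD        HF          phyd            HF only (apparent)
CF_PhyD        CF          phyd            CF only (apparent)
=============  ==========  ==============  =========================

Gray-level ranges: each BED representation shares one range across both
cohorts (so cross-scheme texture axes are comparable); physical dose uses a
per-cohort range. Normalization bounds are fit on each model's training
cohort and carried to its test cohorts. Combined models add the binary
fractionation scheme code (1 = HF, 0 = CF) as an extra candidate predictor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dose as dp
from . import features as ft
from . import synthetic as syn
from .modeling import (
    SCHEME_CODE,
    SURGERY,
    CohortData,
    FinalModel,
    SelectionFrequencies,
    build_final_model,
    cross_evaluate,
)


@dataclass(frozen=True)
class ModelDesign:
    name: str
    training: tuple[str, ...]  # cohorts pooled for training
    representation: str
    evaluation: tuple[tuple[str, str], ...]  # (cohort label, kind)


MODEL_DESIGNS: tuple[ModelDesign, ...] = (
    ModelDesign("HF_BED2", ("HF",), "bed2", (("HF", "apparent"), ("CF", "test"))),
    ModelDesign("HF_BED3", ("HF",), "bed3", (("HF", "apparent"), ("CF", "test"))),
    ModelDesign("CF_BED2", ("CF",), "bed2", (("CF", "apparent"), ("HF", "test"))),
    ModelDesign("CF_BED3", ("CF",), "bed3", (("CF", "apparent"), ("HF", "test"))),
    ModelDesign(
        "HFCF_BED2", ("HF", "CF"), "bed2", (("HF", "apparent"), ("CF", "apparent"))
    ),
    ModelDesign(
        "HFCF_BED3", ("HF", "CF"), "bed3", (("HF", "apparent"), ("CF", "apparent"))
    ),
    ModelDesign("HF_PhyD", ("HF",), "phyd", (("HF", "apparent"),)),
    ModelDesign("CF_PhyD", ("CF",), "phyd", (("CF", "apparent"),)),
)

DESIGNS_BY_NAME = {d.name: d for d in MODEL_DESIGNS}


@dataclass
class StudyConfig:
    """Configuration of one synthetic study run."""

    seed: int = 0
    n_bootstrap: int = 1000
    n_hf: int = syn.ARM_DEFAULTS["HF"]["n"]
    n_cf: int = syn.ARM_DEFAULTS["CF"]["n"]
    heterogeneity: float = 1.0
    bin_width: float = 1.0
    grid_shape: tuple[int, int, int] = (48, 36, 36)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    target_spacing: float = 2.0
    outcome_terms: dict[str, float] = field(
        default_factory=lambda: dict(syn.DEFAULT_TERMS)
    )
    outcome_representation: str = "bed2"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        return d

    def cohort_spec(self, scheme_name: str) -> syn.CohortSpec:
        arm = syn.ARM_DEFAULTS[scheme_name]
        n = self.n_hf if scheme_name == "HF" else self.n_cf
        return syn.CohortSpec(
            n_patients=n,
            scheme=dp.SCHEMES[scheme_name],
            surgery_prevalence=arm["surgery_prevalence"],
            outcome_model=syn.OutcomeModel(
                terms=dict(self.outcome_terms),
                target_event_rate=arm["event_rate"],
            ),
            heterogeneity=self.heterogeneity,
            grid_shape=self.grid_shape,
            spacing=self.spacing,
            target_spacing=self.target_spacing,
            bin_width=self.bin_width,
            outcome_representation=self.outcome_representation,
            # distinct seeds per arm so the two cohorts' geometries differ
            seed=int(np.random.default_rng([self.seed, 10 if scheme_name == "HF" else 11]).integers(2**31)),
        )


@dataclass
class StudyResult:
    models: dict[str, FinalModel]
    performance: pd.DataFrame
    frequencies: dict[str, SelectionFrequencies]
    manifest: dict


def _config_hash(config: StudyConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Build the three dose representations, fit the 8 models and assemble
    the cross-fractionation performance matrix."""
    config = config or StudyConfig()
    specs = {s: config.cohort_spec(s) for s in ("HF", "CF")}
    volumes = {s: syn.generate_volumes(specs[s]) for s in specs}
    ids = {
        s: [f"{s}{i:04d}" for i in range(specs[s].n_patients)] for s in specs
    }

    # shared gray-level range per BED representation; per-cohort for PhyD
    raw_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for rep in ("bed2", "bed3"):
        transformed = {
            s: [
                (dp.apply_representation(d, specs[s].scheme, rep), m)
                for d, m in volumes[s]
            ]
            for s in specs
        }
        shared_range = dp.compute_range_max(
            transformed["HF"] + transformed["CF"], bin_width=config.bin_width
        )
        for s in specs:
            table, _ = syn.extract_cohort_features(
                volumes[s],
                specs[s].scheme,
                rep,
                bin_width=config.bin_width,
                range_max=shared_range,
                ids=ids[s],
            )
            raw_tables[(s, rep)] = table
    for s in specs:
        table, _ = syn.extract_cohort_features(
            volumes[s], specs[s].scheme, "phyd", bin_width=config.bin_width, ids=ids[s]
        )
        raw_tables[(s, "phyd")] = table

    # one outcome per patient, simulated on the outcome representation
    covariates: dict[str, pd.DataFrame] = {}
    outcomes: dict[str, np.ndarray] = {}
    for s in specs:
        cov = syn.simulate_covariates(specs[s])
        cov.index = pd.Index(ids[s])
        covariates[s] = cov
        gen_raw = raw_tables[(s, config.outcome_representation)]
        gen_norm = ft.apply_normalization(gen_raw, ft.fit_normalization(gen_raw))
        rng = np.random.default_rng([specs[s].seed, 5])
        y, _, _ = syn.simulate_outcomes(
            gen_norm, cov, specs[s].outcome_model, rng
        )
        outcomes[s] = y

    def make_cohort(schemes: tuple[str, ...], rep: str, bounds=None):
        raw = pd.concat([raw_tables[(s, rep)] for s in schemes])
        cov = pd.concat([covariates[s] for s in schemes])
        y = np.concatenate([outcomes[s] for s in schemes])
        if bounds is None:
            bounds = ft.fit_normalization(raw)
        norm = ft.apply_normalization(raw, bounds)
        label = "+".join(schemes)
        return (
            CohortData(norm, cov, y, scheme=label, representation=rep),
            bounds,
        )

    models: dict[str, FinalModel] = {}
    frequencies: dict[str, SelectionFrequencies] = {}
    evaluations: dict[str, list] = {}
    for i, design in enumerate(MODEL_DESIGNS):
        train, bounds = make_cohort(design.training, design.representation)
        candidates = list(ft.FEATURE_NAMES)
        if len(design.training) > 1:
            candidates.append(SCHEME_CODE)
        model_seed = int(
            np.random.default_rng([config.seed, 20, i]).integers(2**31)
        )
        model, freqs = build_final_model(
            train,
            candidates,
            n_bootstrap=config.n_bootstrap,
            seed=model_seed,
            name=design.name,
        )
        models[design.name] = model
        frequencies[design.name] = freqs
        plan = []
        for label, kind in design.evaluation:
            cohort, _ = make_cohort((label,), design.representation, bounds=bounds)
            plan.append((label, cohort, kind))
        evaluations[design.name] = plan

    performance = cross_evaluate(models, evaluations)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "models": [d.name for d in MODEL_DESIGNS],
    }
    return StudyResult(models, performance, frequencies, manifest)


def write_reports(result: StudyResult, out_dir) -> list[Path]:
    """Write model JSONs, predictor table, performance matrix, selection
    frequencies and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, model in result.models.items():
        p = out / f"model_{name}.json"
        model.to_json(p)
        written.append(p)

    rows = []
    for name, model in result.models.items():
        for pred in model.signature:
            rows.append(
                {
                    "model": name,
                    "predictor": pred,
                    "median_or": model.odds_ratios[pred],
                    "median_p": model.median_p[pred],
                }
            )
        rows.append(
            {
                "model": name,
                "predictor": "constant",
                "median_or": model.baseline_odds,
                "median_p": np.nan,
            }
        )
    table1 = out / "predictors.csv"
    pd.DataFrame(rows).to_csv(table1, index=False, float_format="%.6g")
    written.append(table1)

    # Table-2 shape: one row per (model, measure), HF / CF columns
    perf = result.performance
    rows = []
    for name in result.models:
        sub = perf[perf.model == name]
        for measure in ("auc", "cal_slope", "cal_intercept"):
            row = {"model": name, "measure": measure, "HF": np.nan, "CF": np.nan}
            for _, r in sub.iterrows():
                row[r["data"]] = r[measure]
            rows.append(row)
    table2 = out / "performance.csv"
    pd.DataFrame(rows).to_csv(table2, index=False, float_format="%.6g")
    written.append(table2)

    perf_long = out / "performance_long.csv"
    perf.to_csv(perf_long, index=False, float_format="%.6g")
    written.append(perf_long)

    rows = []
    for name, freqs in result.frequencies.items():
        for cand, count in freqs.counts.items():
            rows.append({"model": name, "candidate": cand, "count": count})
    freq_path = out / "selection_frequencies.csv"
    pd.DataFrame(rows).to_csv(freq_path, index=False)
    written.append(freq_path)

    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest)
    return written
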