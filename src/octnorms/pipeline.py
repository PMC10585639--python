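"""End-to-end orchestration: simulate → fit → sensitivity → meta → power.

A :class:`RunConfig` toggles stages and carries their configurations;
:func:`run_pipeline` executes enabled stages in order, writes their
tables under an output directory, and finishes with a machine-readable
``manifest.json`` recording the package version, the global seed, each
stage's derived seed and the SHA-256 digest of every file written.
Stage seeds are derived from the global seed and the stage name with a
stable hash, so any stage can be rerun alone and reproduce its output;
reruns with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .io import RESPONSES, Cohort, read_cohort, write_cohort
from .lmm import descriptives, fit_all
from .meta import pool_by_age, select_eye, filter_eligible, synthetic_study_table
from .power import PowerSpec, analytic_power, posthoc_power
from .sensitivity import SensitivityConfig, run_sensitivity
from .simulate import GeneratorConfig, default_config, generate

import numpy as np

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

_STAGES = ("simulate", "fit", "sensitivity", "meta", "power")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2³¹, independent of process hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """What to run, where to write, and each stage's parameters."""

    outdir: str | Path = "octnorms-run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    cohort_path: str | Path | None = None  # use a file instead of simulating
    generator: GeneratorConfig | None = None
    sensitivity: SensitivityConfig | None = None
    sensitivity_responses: tuple[str, ...] = ("c0", "choroid")
    power_spec: PowerSpec | None = None
    posthoc_responses: tuple[str, ...] = ("c0", "choroid")
    posthoc_n_sims: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needs_cohort = {"fit", "sensitivity", "power"} & set(self.stages)
        if needs_cohort and "simulate" not in self.stages and self.cohort_path is None:
            raise ValueError(
                f"stages {sorted(needs_cohort)} need a cohort: enable 'simulate' "
                "or set cohort_path"
            )
        if ({"sensitivity", "power"} & set(self.stages)) and "fit" not in self.stages:
            raise ValueError("'sensitivity' and 'power' stages depend on 'fit'")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "octnorms",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    cohort: Cohort | None = None
    if "simulate" in config.stages:
        stage_seed = derive_seed(config.seed, "simulate")
        gen = config.generator or default_config()
        gen = replace(gen, seed=stage_seed)
        cohort, truth = generate(gen)
        cohort_file = outdir / "cohort.csv"
        write_cohort(cohort, cohort_file)
        truth_file = outdir / "truth_effects.csv"
        truth.subject_effects.to_csv(truth_file, index=False, float_format="%.6f")
        written += [cohort_file, truth_file]
        manifest["stages"]["simulate"] = {
            "seed": stage_seed,
            "n_subjects": cohort.n_subjects,
            "n_eyes": len(cohort),
        }
    elif config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        manifest["stages"]["load"] = {"path": str(config.cohort_path)}

    fits_frame: pd.DataFrame | None = None
    if "fit" in config.stages:
        assert cohort is not None
        fits_frame = fit_all(cohort)
        fits_file = outdir / "fits.csv"
        fits_frame.to_csv(fits_file, index=False, float_format="%.6f")
        report = descriptives(cohort)
        desc_file = outdir / "descriptives.csv"
        desc = report.intereye.join(report.bland_altman)
        desc.to_csv(desc_file, float_format="%.6f")
        written += [fits_file, desc_file]
        effects = fits_frame[fits_frame["coefficient"] == "ethnicity"]
        manifest["stages"]["fit"] = {
            "n_responses": int(fits_frame["response"].nunique()),
            "effect_rows": int(len(effects)),
            "sex_chi2": round(report.sex_chi2, 6),
            "age_rank_sum_w": round(report.age_w, 6),
        }

    if "sensitivity" in config.stages:
        assert cohort is not None
        stage_seed = derive_seed(config.seed, "sensitivity")
        frames = []
        thresholds: dict[str, dict] = {}
        for i, response in enumerate(config.sensitivity_responses):
            base = config.sensitivity or SensitivityConfig()
            sens_config = replace(base, response=response, seed=stage_seed + i)
            result = run_sensitivity(cohort, sens_config)
            frame = result.levels.copy()
            frame.insert(0, "response", response)
            frames.append(frame)
            thresholds[response] = {
                str(c): result.thresholds[c] for c in result.thresholds
            }
        sens_file = outdir / "sensitivity.csv"
        pd.concat(frames, ignore_index=True).to_csv(
            sens_file, index=False, float_format="%.6f"
        )
        written.append(sens_file)
        manifest["stages"]["sensitivity"] = {
            "seed": stage_seed,
            "thresholds": thresholds,
        }

    if "meta" in config.stages:
        stage_seed = derive_seed(config.seed, "meta")
        rng = np.random.default_rng(stage_seed)
        studies, _ = filter_eligible(synthetic_study_table())
        studies = [select_eye(s, rng) for s in studies]
        rows = []
        for sector in RESPONSES[:-1]:
            for group, estimate in pool_by_age(studies, sector).items():
                rows.append(
                    {
                        "sector": sector,
                        "age_group": f"[{group[0]},{group[1]})",
                        "k": estimate.k,
                        "pooled_mean": estimate.pooled_mean,
                        "ci_lo": estimate.ci95[0],
                        "ci_hi": estimate.ci95[1],
                        "tau2": estimate.tau2,
                        "q": estimate.q,
                        "i2": estimate.i2,
                    }
                )
        meta_file = outdir / "pooled.csv"
        pd.DataFrame(rows).to_csv(meta_file, index=False, float_format="%.6f")
        written.append(meta_file)
        manifest["stages"]["meta"] = {"seed": stage_seed, "n_rows": len(rows)}

    if "power" in config.stages:
        assert cohort is not None
        stage_seed = derive_seed(config.seed, "power")
        spec = config.power_spec or PowerSpec(n=cohort.n_subjects, r_squared=0.20)
        apriori = analytic_power(spec)
        power_rows = [
            {
                "kind": "apriori",
                "response": "",
                "power": apriori.power,
                "n_sims": "",
                "mcse": "",
            }
        ]
        if fits_frame is not None:
            from .lmm import fit_sector

            for i, response in enumerate(config.posthoc_responses):
                fit = fit_sector(cohort, response)
                result = posthoc_power(
                    fit,
                    cohort,
                    n_sims=config.posthoc_n_sims,
                    seed=stage_seed + i,
                )
                power_rows.append(
                    {
                        "kind": "posthoc_ethnicity",
                        "response": response,
                        "power": result.power,
                        "n_sims": result.n_sims,
                        "mcse": result.mcse,
                    }
                )
        power_file = outdir / "power.csv"
        pd.DataFrame(power_rows).to_csv(power_file, index=False, float_format="%.6f")
        written.append(power_file)
        manifest["stages"]["power"] = {
            "seed": stage_seed,
            "apriori_power": round(apriori.power, 6),
        }

    for path in written:
        manifest["files"][path.name] = _digest(path)
    manifest_file = outdir / "manifest.json"
    manifest_file.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
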