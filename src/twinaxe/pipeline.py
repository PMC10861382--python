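"""Umbrella pipeline: simulate -> psychometrics -> fit -> compare -> report.

Each stage's seed is derived deterministically from the config seed, all
artifacts land under ``config.out_dir``, and a manifest (inputs, seeds,
package version, output file hashes) is written last — rerunning the same
config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, read_twin_csv, write_truth_csv, write_twin_csv
from .irt import classical_stats, fit_irt, select_one_twin
from .report import compare_genetic_models, credibility_curve, model_selection_table, summarize
from .sampler import run_chains
from .simulate import default_item_bank, simulate_cohort
from .types import CohortDesign, GeneticParams, ItemResponseTable, MCMCSettings, ModelSpec

logger = logging.getLogger("twinaxe")

__all__ = ["run_pipeline", "save_fit", "load_fit_meta"]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_fit(fit, run_dir: Path) -> None:
    """Persist a PosteriorFit as draws CSV + metadata JSON + summary tables."""
    run_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in fit.draws.items():
        for c in range(arr.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c + 1,
                        "iteration": np.arange(1, arr.shape[1] + 1),
                        "parameter": name,
                        "value": arr[c],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(run_dir / "draws.csv", index=False)
    meta = {
        "model": fit.spec.label,
        "flavour": fit.spec.flavour,
        "interaction": fit.spec.interaction,
        "seed": fit.seed,
        "settings": {
            "n_chains": fit.settings.n_chains,
            "burn_in": fit.settings.burn_in,
            "n_iter": fit.settings.n_iter,
            "thin": fit.settings.thin,
        },
        "dic": fit.dic,
        "dic_marginal": fit.dic_marginal,
        "psrf": fit.psrf,
        "converged": bool(fit.converged),
        "data_hash": fit.data_hash,
    }
    (run_dir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    summarize(fit).to_csv(run_dir / "summary.csv", index=False)
    if "beta0" in fit.draws:
        credibility_curve(fit).to_csv(run_dir / "credibility_curve.csv", index=False)


def load_fit_meta(run_dir) -> dict:
    return json.loads((Path(run_dir) / "meta.json").read_text())


def run_pipeline(config: PipelineConfig) -> tuple[int, dict]:
    """Run the configured stages in order; returns (exit status, manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    status = 0
    try:
        table = _stage_data(config, out, manifest)
        if config.irt_models:
            _stage_irt(config, table, out, manifest)
        if config.genetic_models:
            _stage_fit(config, table, out, manifest)
    except Exception as exc:  # partial manifest on failure
        logger.error("pipeline failed: %s", exc)
        manifest["error"] = str(exc)
        status = 1
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return status, manifest


def _stage_data(config, out: Path, manifest) -> ItemResponseTable:
    t0 = time.time()
    if config.simulate is not None:
        sim = dict(config.simulate)
        params = GeneticParams(
            model=sim.get("model", "AE"),
            interaction=bool(sim.get("interaction", False)),
            sigma2_a=sim.get("sigma2_a", 0.0),
            sigma2_c=sim.get("sigma2_c", 0.0),
            sigma2_d=sim.get("sigma2_d", 0.0),
            beta0=sim.get("beta0", 0.0),
            beta1=sim.get("beta1", 0.0),
        )
        design = CohortDesign(
            n_mz=sim.get("n_mz", 415),
            n_dz=sim.get("n_dz", 669),
            n_categories=tuple(sim.get("n_categories", (7,) * 9)),
            missingness_spec=tuple(
                (float(f), int(m)) for f, m in sim.get("missingness", [])
            ),
        )
        bank = default_item_bank(design.n_items, design.n_categories[0])
        table, latents = simulate_cohort(params, design, bank, config.seed)
        write_twin_csv(table, out / "data.csv")
        write_truth_csv(latents, out / "truth.csv")
        manifest["stages"]["simulate"] = {
            "seed": config.seed,
            "n_families": table.n_families,
            "wall_s": round(time.time() - t0, 3),
        }
        return table
    if config.input_csv is None:
        raise ValueError("config needs either a simulate block or input_csv")
    table = read_twin_csv(config.input_csv)
    manifest["stages"]["load"] = {
        "input": str(config.input_csv),
        "n_families": table.n_families,
        "wall_s": round(time.time() - t0, 3),
    }
    return table


def _stage_irt(config, table, out: Path, manifest) -> None:
    t0 = time.time()
    seed = config.seed + 1
    responses = select_one_twin(table, seed)
    rows = []
    for kind in config.irt_models:
        fit = fit_irt(responses, table.n_categories, kind=kind)
        rows.append(
            {
                "model": kind,
                "log_lik": fit.log_lik,
                "n_parameters": fit.n_parameters,
                "AIC": fit.aic,
                "converged": fit.converged,
            }
        )
    aic = pd.DataFrame(rows)
    aic["preferred"] = aic["AIC"] == aic["AIC"].min()
    aic.to_csv(out / "irt_aic.csv", index=False)
    stats = classical_stats(table)
    pd.DataFrame(
        {
            "statistic": ["cronbach_alpha", "mz_sum_corr", "dz_sum_corr"],
            "value": [
                stats["cronbach_alpha"],
                stats["mz_sum_corr"],
                stats["dz_sum_corr"],
            ],
        }
    ).to_csv(out / "classical_stats.csv", index=False)
    manifest["stages"]["irt"] = {
        "seed": seed,
        "models": list(config.irt_models),
        "wall_s": round(time.time() - t0, 3),
    }


def _stage_fit(config, table, out: Path, manifest) -> None:
    table_data = table
    settings = MCMCSettings(**config.sampler)
    fits = []
    for k, gm in enumerate(config.genetic_models):
        t0 = time.time()
        spec = ModelSpec(
            flavour=gm["flavour"], interaction=bool(gm.get("interaction", False))
        )
        seed = config.seed + 100 + k
        fit = run_chains(table, spec, settings, seed=seed)
        label = spec.flavour.lower() + ("_axe" if spec.interaction else "")
        save_fit(fit, out / f"fit_{label}")
        fits.append(fit)
        manifest["stages"][f"fit_{label}"] = {
            "seed": seed,
            "converged": bool(fit.converged),
            "DIC": fit.dic["DIC"],
            "wall_s": round(time.time() - t0, 3),
        }
    if len(fits) >= 1:
        try:
            table = compare_genetic_models(table_data, fits)
        except (ValueError, NotImplementedError):
            table = model_selection_table(fits)
        table.to_csv(out / "dic_table.csv", index=False)
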