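"""End-to-end orchestration: simulate -> chemometrics -> model conditioning
-> pFBA classification -> flux enrichment -> report bundle.

Every run writes five CSV artifacts (regression metrics, regression sign
summary, PCA scores/loadings, reaction classification, enrichment table)
plus a JSON manifest carrying the seed, the config hash, and a SHA-256
checksum per artifact; re-running with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    autoscale,
    cross_validate,
    ipls_reverse,
    pca,
    regression_summary,
    simpls_fit,
)
from .constraint import MetabolicModel, constrain_exchanges, read_model_tsv
from .datamodel import (
    FermentationDataset,
    build_utilization_matrix,
    estimate_exchange_fluxes,
    read_fermentation_csv,
)
from .enrichment import flux_enrichment
from .pfba import classify_reactions, fva, single_reaction_deletions
from .synthetic import (
    DEFAULT_SAMPLE_TIMES,
    VOC_NAMES,
    SimulationSpec,
    generate_toy_network,
    simulate_fermentation,
)

log = logging.getLogger("vinoflux")

MOLAR_MASSES = {"glucose": 180.16, "fructose": 180.16, "Leu": 131.17,
                "ethanol": 46.07, "NH3": 17.03}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (flags override file values)."""

    out_dir: str = "vinoflux_run"
    dataset_csv: str | None = None  # simulate when absent
    model_tsv: str | None = None  # ehrlich_motif toy when absent
    responses: list[str] = field(default_factory=lambda: ["biomass"] + VOC_NAMES)
    pls_times: list[float] = field(
        default_factory=lambda: list(DEFAULT_SAMPLE_TIMES[:5])
    )
    max_lv: int = 18
    cv_splits: int = 24
    ipls: bool = True
    # growth-phase window for finite-difference flux estimation; wide
    # enough that concentration drops dominate measurement noise
    flux_window: tuple[float, float] = (20.0, 72.0)
    flux_analytes: list[str] = field(default_factory=lambda: ["glucose", "Leu"])
    rel_tolerance: float = 0.0
    eps_growth: float = 1e-6
    alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def hash(self) -> str:
        """Hash of the analysis-relevant settings (paths and logging are
        excluded so runs into different directories compare equal)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fit_response_models(
    ds: FermentationDataset,
    responses: list[str],
    times: list[float],
    max_lv: int = 18,
    cv_splits: int = 24,
    use_ipls: bool = True,
) -> tuple[pd.DataFrame, list, list[str]]:
    """Fit one PLS model per response on the pooled utilization block.

    Returns (metrics table, fitted models, predictor column names).
    Each response gets: optional reverse-iPLS variable selection, LV count
    chosen by Venetian-blinds RMSECV, and a final SIMPLS fit.
    """
    um = build_utilization_matrix(ds, times=times, responses=responses)
    metrics_rows = []
    models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, resp in enumerate(responses):
            y = um.Y[:, [k]]
            mask = np.ones(um.X.shape[1], dtype=bool)
            if use_ipls:
                mask = ipls_reverse(
                    um.X, y, interval_size=1, max_lv=max_lv, n_splits=cv_splits
                )
            Xsel = um.X[:, mask]
            rmsecv, q2, n_lv = cross_validate(
                Xsel, y, max_lv=max_lv, n_splits=cv_splits
            )
            model = simpls_fit(Xsel, y, n_lv=n_lv, selected_mask=mask)
            vx, vy = model.variance_captured
            metrics_rows.append(
                {
                    "response": resp,
                    "n_latent_variables": n_lv,
                    "RMSEC": model.metrics["RMSEC"],
                    "RMSECV": float(rmsecv[n_lv - 1]),
                    "R2": model.metrics["R2"],
                    "Q2": float(q2[n_lv - 1]),
                    "pct_variance_X": vx,
                    "pct_variance_Y": vy,
                    "n_selected_variables": int(mask.sum()),
                }
            )
            models.append(model)
    return pd.DataFrame(metrics_rows), models, um.columns


def _pca_table(ds: FermentationDataset, t: float, analytes: list[str]) -> pd.DataFrame:
    """PCA of end-point VOC concentrations across strain x replicate."""
    rows, ids = [], []
    for strain in ds.strains:
        for rep in ds.replicates(strain):
            vals = []
            for a in analytes:
                times, values, _ = ds.series(strain, rep, a)
                hit = np.flatnonzero(np.isclose(times, t))
                vals.append(float(values[hit[0]]) if hit.size else np.nan)
            rows.append(vals)
            ids.append(f"{strain}_r{rep}")
    X = np.asarray(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xs, _, _ = autoscale(X)
        n_comp = min(4, min(Xs.shape) - 1, np.linalg.matrix_rank(Xs))
        scores, loadings, pct = pca(Xs, n_comp)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, columns=pcs)
    score_df.insert(0, "kind", "score")
    score_df.insert(1, "id", ids)
    load_df = pd.DataFrame(loadings, columns=pcs)
    load_df.insert(0, "kind", "loading")
    load_df.insert(1, "id", analytes)
    var_df = pd.DataFrame([pct], columns=pcs)
    var_df.insert(0, "kind", "pct_variance")
    var_df.insert(1, "id", "explained")
    return pd.concat([score_df, load_df, var_df], ignore_index=True)


def classification_table(model: MetabolicModel, eps_growth: float = 1e-6) -> pd.DataFrame:
    cls = classify_reactions(model, eps_growth=eps_growth)
    growth, _ = single_reaction_deletions(model, eps_growth=eps_growth)
    ranges = fva(model, fraction_of_optimum=1.0)
    rows = [
        {
            "reaction": r,
            "subsystem": model.subsystem[j],
            "category": cls.category[r],
            "knockout_growth": growth[r],
            "fva_min": ranges[r][0],
            "fva_max": ranges[r][1],
        }
        for j, r in enumerate(model.reactions)
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
        "artifacts": {},
    }
    manifest_path = out / "manifest.json"

    def finish_stage(name: str, t0: float, ok: bool = True) -> None:
        manifest["stages"][name] = {
            "ok": ok,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %-14s ok=%s (%.2fs)", name, ok,
                 manifest["stages"][name]["wall_time_s"])

    def write_artifact(name: str, df: pd.DataFrame) -> None:
        path = out / name
        with path.open("w") as fh:
            fh.write(f"# vinoflux {__version__} seed={config.seed} "
                     f"config={config.hash()}\n")
            df.to_csv(fh, index=False)
        manifest["artifacts"][name] = _sha256(path)

    try:
        # -- data ---------------------------------------------------------
        t0 = time.perf_counter()
        if config.dataset_csv:
            ds = read_fermentation_csv(config.dataset_csv)
        else:
            ds, _ = simulate_fermentation(SimulationSpec(seed=config.seed))
        finish_stage("data", t0)

        # -- chemometrics --------------------------------------------------
        t0 = time.perf_counter()
        metrics, models, columns = fit_response_models(
            ds,
            config.responses,
            config.pls_times,
            max_lv=config.max_lv,
            cv_splits=config.cv_splits,
            use_ipls=config.ipls,
        )
        signs = regression_summary(models, config.responses, columns)
        write_artifact("pls_metrics.csv", metrics)
        sign_df = signs.to_frame().reset_index(names="response")
        write_artifact("pls_signs.csv", sign_df)
        vocs = [r for r in config.responses if r != "biomass"] or config.responses
        write_artifact("pca.csv", _pca_table(ds, t=168.0, analytes=vocs))
        finish_stage("chemometrics", t0)

        # -- model setup ---------------------------------------------------
        t0 = time.perf_counter()
        if config.model_tsv:
            model = read_model_tsv(config.model_tsv)
        else:
            model, _ = generate_toy_network("ehrlich_motif")
        strain = ds.strains[-1]
        fluxes = estimate_exchange_fluxes(
            ds,
            window=config.flux_window,
            molar_masses={a: MOLAR_MASSES[a] for a in config.flux_analytes},
            analytes=[a for a in config.flux_analytes
                      if f"EX_{a}" in model.reactions],
            strain=strain,
            replicate=ds.replicates(strain)[0],
        )
        conditioned = constrain_exchanges(
            model, fluxes, rel_tolerance=config.rel_tolerance
        )
        finish_stage("model-setup", t0)

        # -- pFBA classification ------------------------------------------
        t0 = time.perf_counter()
        cls_table = classification_table(conditioned, eps_growth=config.eps_growth)
        write_artifact("classification.csv", cls_table)
        finish_stage("pfba", t0)

        # -- enrichment ----------------------------------------------------
        t0 = time.perf_counter()
        universe = {
            row.reaction: row.subsystem
            for row in cls_table.itertuples()
            if row.category != "blocked"
        }
        hits = {
            row.reaction
            for row in cls_table.itertuples()
            if row.category == "essential"
        }
        enr = flux_enrichment(universe, hits, alpha=config.alpha)
        write_artifact("enrichment.csv", enr)
        finish_stage("fea", t0)
    except Exception as exc:  # partial outputs preserved, failure recorded
        stage = "data"
        for name in ("data", "chemometrics", "model-setup", "pfba", "fea"):
            if name not in manifest["stages"]:
                stage = name
                break
        manifest["stages"][stage] = {"ok": False, "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
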