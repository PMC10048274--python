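"""End-to-end orchestration: simulate -> mask -> train -> select bands -> validate.

Every stage writes its artifacts (CSV/JSON) into the output directory and
stamps them with the global seed and a hash of the configuration, so a run
is fully reproducible and each stage can be re-run from the persisted
intermediates.  A single global seed fans out into named sub-seeds
(simulate / split / cv / rf) so the stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy_profile as ap
from .bandselect import permutation_pvalues, select_bands, refit_on_selection
from .chemometrics import (
    CVResult,
    ModelSpec,
    _fit_by_spec,
    grid_search,
    linear_profile,
    predict,
    train_test_split,
)
from .preprocess import PreprocessMethod, apply_method, mask_water_regions
from .simulate import (
    SimConfig,
    simulate_blanks,
    simulate_calibration_set,
    simulate_validation_set,
)
from .spectra import SpectraSet

log = logging.getLogger("mirprofile")

__all__ = ["RunConfig", "run_all", "write_report", "TABLE3_COLUMNS"]

#: columns of the per-level validation summary (Table-3 style)
TABLE3_COLUMNS = [
    "level_mg_per_100mL",
    "mean_mg_per_100mL",
    "relative_bias_pct",
    "recovery_pct",
    "repeatability_pct",
    "intermediate_precision_pct",
    "relative_tolerance_limits_pct",
    "tolerance_limits_mg_per_100mL",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    methods: tuple[str, ...] = ("RAW", "SNV", "SG", "SG1", "SG2", "S_SG", "S_SG1", "S_SG2")
    algorithms: tuple[str, ...] = ("PLSR", "PCR", "ANN")
    max_components: int = 25
    ann_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    cv_folds: int = 10
    train_frac: float = 0.8
    band_selection: bool = True
    n_permutations: int = 1000
    n_trees: int = 500
    alpha: float = 0.05
    n_blanks: int = 10
    beta: float = 0.667
    gamma: float = 0.9
    acceptance_pct: float = 20.0
    make_plots: bool = False

    def sub_seed(self, stage: str) -> int:
        tag = {"simulate": 1, "split": 2, "cv": 3, "rf": 4}[stage]
        return int(
            np.random.SeedSequence([tag, int(self.seed)]).generate_state(1)[0] % 2**31
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(asdict(self), default=str)),
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _leaderboard_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.spec
        rows.append(
            {
                "algorithm": s.algorithm,
                "pre_processing": s.method.id,
                "LV": s.n_components if s.algorithm != "ANN" else None,
                "size": s.size,
                "decay": s.decay,
                "RMSE_CV": r.rmse_cv,
                "RMSE_CV_SD": r.rmse_cv_sd,
                "R2_CV": r.r2_cv,
                "RMSE_P": r.rmse_p,
                "R2_P": r.r2_p,
            }
        )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the result bundle as a dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    sim_cfg = SimConfig(**{**asdict_shallow(cfg.sim), "seed": cfg.sub_seed("simulate")})

    try:
        log.info("stage simulate: calibration/validation/blank sets")
        cal = simulate_calibration_set(sim_cfg)
        val = simulate_validation_set(sim_cfg)
        blanks = simulate_blanks(cfg.n_blanks, sim_cfg)
        cal.to_csv(outdir / "calibration_spectra.csv", outdir / "calibration_meta.csv")
        val.to_csv(outdir / "validation_spectra.csv", outdir / "validation_meta.csv")
    except Exception as e:  # pragma: no cover - defensive stage tagging
        raise RuntimeError(f"[simulate] stage failed: {e}") from e

    try:
        cal_m = mask_water_regions(cal)
        val_m = mask_water_regions(val)
        blank_m = mask_water_regions(blanks)
        log.info("stage mask: retained %d of %d points", cal_m.n_points, cal.n_points)
    except Exception as e:
        raise RuntimeError(f"[preprocess] stage failed: {e}") from e

    try:
        train, test = train_test_split(cal_m, cfg.train_frac, cfg.sub_seed("split"))
        methods = [PreprocessMethod(mid) for mid in cfg.methods]
        log.info("stage train: grid search, %d/%d train/test", train.n_samples, test.n_samples)
        results = grid_search(
            train,
            cfg.algorithms,
            methods,
            max_components=cfg.max_components,
            ann_sizes=cfg.ann_sizes,
            k=cfg.cv_folds,
            seed=cfg.sub_seed("cv"),
            test=test,
        )
        leaderboard = _leaderboard_frame(results)
        leaderboard.to_csv(outdir / "leaderboard_full_spectrum.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"[train] stage failed: {e}") from e

    selection = None
    results_sel = None
    if cfg.band_selection:
        try:
            log.info("stage select-bands: B=%d, trees=%d", cfg.n_permutations, cfg.n_trees)
            imp = permutation_pvalues(
                train.absorbance,
                train.concentrations,
                B=cfg.n_permutations,
                n_trees=cfg.n_trees,
                seed=cfg.sub_seed("rf"),
                wavenumbers=train.wavenumbers,
                alpha=cfg.alpha,
            )
            mask, regions = select_bands(imp, cfg.alpha)
            log.info("selected %d of %d points", int(mask.sum()), mask.size)
            pd.DataFrame(
                {
                    "wavenumber_cm1": train.wavenumbers,
                    "importance": imp.observed_importance,
                    "p_value": imp.p_values,
                    "selected": mask,
                }
            ).to_csv(outdir / "band_importance.csv", index=False)
            pd.DataFrame(regions, columns=["start_cm1", "end_cm1"]).to_csv(
                outdir / "selected_regions.tsv", sep="\t", index=False
            )
            selection = {"mask": mask, "regions": regions, "n_before": int(mask.size),
                         "n_after": int(mask.sum())}
            if mask.any():
                results_sel = refit_on_selection(
                    train,
                    mask,
                    test=test,
                    algorithms=cfg.algorithms,
                    methods=methods,
                    max_components=cfg.max_components,
                    ann_sizes=cfg.ann_sizes,
                    k=cfg.cv_folds,
                    seed=cfg.sub_seed("cv"),
                )
                _leaderboard_frame(results_sel).to_csv(
                    outdir / "leaderboard_selected.csv", index=False
                )
        except Exception as e:
            raise RuntimeError(f"[select-bands] stage failed: {e}") from e

    try:
        # final model: winner of the selected-band search when available
        final_results = results_sel if results_sel else results
        winner = final_results[0]
        feature_mask = selection["mask"] if results_sel else np.ones(train.n_points, bool)
        tr_sub = train.select_points(feature_mask)
        Xtr = apply_method(tr_sub, winner.spec.method).absorbance
        model = _fit_by_spec(winner.spec, Xtr, tr_sub.concentrations)

        def predict_set(s: SpectraSet) -> np.ndarray:
            sub = s.select_points(feature_mask)
            return predict(model, apply_method(sub, winner.spec.method).absorbance)

        val_pred = predict_set(val_m)
        blank_pred = predict_set(blank_m)
        pd.DataFrame(
            {
                "level_mg_per_100mL": val_m.concentrations,
                "day": val_m.meta["day"],
                "replicate": val_m.meta["replicate"],
                "predicted_mg_per_100mL": val_pred,
            }
        ).to_csv(outdir / "validation_predictions.csv", index=False)

        lod_res = ap.lod(blank_pred)
        slope, intercept, r2 = linear_profile(val_pred, val_m.concentrations)
        level_data = []
        for conc in sorted(set(val_m.concentrations)):
            sel = val_m.concentrations == conc
            sub = pd.DataFrame({"day": val_m.meta["day"][sel], "y": val_pred[sel]})
            mat = (
                sub.pivot_table(index="day", values="y", aggfunc=list)["y"]
                .apply(pd.Series)
                .to_numpy()
            )
            level_data.append(ap.LevelData(y_r=float(conc), measurements=mat))
        profile = ap.build_profile(
            level_data, cfg.acceptance_pct, cfg.beta, cfg.gamma
        )
    except Exception as e:
        raise RuntimeError(f"[validate] stage failed: {e}") from e

    bundle = {
        "stamp": stamp,
        "calibration": cal_m,
        "leaderboard": leaderboard,
        "leaderboard_selected": _leaderboard_frame(results_sel) if results_sel else None,
        "selection": selection,
        "winner": winner,
        "lod": lod_res,
        "linear_profile": {"slope": slope, "intercept": intercept, "r2": r2},
        "profile": profile,
    }
    write_report(bundle, outdir)
    if cfg.make_plots:
        from .plotting import plot_accuracy_profile

        fig = plot_accuracy_profile(profile)
        fig.savefig(outdir / "accuracy_profile.png", dpi=150)
    return bundle


def asdict_shallow(cfg: SimConfig) -> dict:
    keys = SimConfig.__dataclass_fields__
    return {k: getattr(cfg, k) for k in keys}


def _profile_tables(profile: ap.AccuracyProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    plot_rows = []
    for c, s, iv in zip(profile.levels, profile.stats, profile.intervals):
        rows.append(
            {
                TABLE3_COLUMNS[0]: c,
                TABLE3_COLUMNS[1]: None if s is None else s.mean,
                TABLE3_COLUMNS[2]: iv.bias_pct,
                TABLE3_COLUMNS[3]: None if s is None else s.recovery_pct,
                TABLE3_COLUMNS[4]: None if s is None else s.rsd_re_pct,
                TABLE3_COLUMNS[5]: None if s is None else s.rsd_ip_pct,
                TABLE3_COLUMNS[6]: f"[{iv.l_pct:.2f}, {iv.u_pct:.2f}]",
                TABLE3_COLUMNS[7]: f"[{iv.l_abs:.2f}, {iv.u_abs:.2f}]",
            }
        )
        plot_rows.append(
            {
                "concentration": c,
                "bias_pct": iv.bias_pct,
                "lower_pct": iv.l_pct,
                "upper_pct": iv.u_pct,
                "acceptance_low": -profile.acceptance_pct,
                "acceptance_high": profile.acceptance_pct,
            }
        )
    return pd.DataFrame(rows, columns=TABLE3_COLUMNS), pd.DataFrame(plot_rows)


def write_report(bundle: dict, outdir: str | Path) -> Path:
    """Write the markdown report + CSV/JSON artifacts; returns report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile: ap.AccuracyProfile = bundle["profile"]
    table3, plot_data = _profile_tables(profile)
    table3.to_csv(outdir / "validation_levels.csv", index=False)
    plot_data.to_csv(outdir / "profile_plot_data.csv", index=False)
    prof_json = {
        "beta": profile.beta,
        "gamma": profile.gamma,
        "acceptance_pct": profile.acceptance_pct,
        "lloq": profile.lloq,
        "uloq": profile.uloq,
        "levels": profile.levels,
        "within_acceptance": profile.within_acceptance,
        "lod": bundle["lod"].lod,
        "s0": bundle["lod"].s0,
        "linear_profile": bundle["linear_profile"],
        **bundle["stamp"],
    }
    (outdir / "profile.json").write_text(json.dumps(prof_json, indent=2))

    lines = [
        "# mirprofile run report",
        "",
        f"seed: {bundle['stamp']['seed']}  config: {bundle['stamp']['config_hash']}",
        "",
        "## Model leaderboard (full spectrum, top 5)",
        "",
        bundle["leaderboard"].head(5).to_markdown(index=False),
        "",
    ]
    sel = bundle.get("selection")
    if sel is None:
        lines += ["## Band selection", "", "stage disabled", ""]
    elif sel["n_after"] == 0:
        lines += ["## Band selection", "", "no bands selected", ""]
    else:
        lines += [
            "## Band selection",
            "",
            f"points {sel['n_before']} -> {sel['n_after']}; regions: "
            + ", ".join(f"{a:.0f}-{b:.0f}" for a, b in sel["regions"]),
            "",
        ]
        if bundle.get("leaderboard_selected") is not None:
            lines += [bundle["leaderboard_selected"].head(5).to_markdown(index=False), ""]
    lp = bundle["linear_profile"]
    lines += [
        "## Validation",
        "",
        f"LOD = {bundle['lod'].lod:.3g} mg/100 mL (S0 = {bundle['lod'].s0:.3g})",
        f"linear profile: y = {lp['slope']:.4g} x + {lp['intercept']:.4g}, R2 = {lp['r2']:.4g}",
        f"LLOQ = {profile.lloq if profile.lloq is None else round(profile.lloq, 2)}, "
        f"ULOQ = {profile.uloq if profile.uloq is None else round(profile.uloq, 2)} mg/100 mL",
        "",
        table3.to_markdown(index=False),
        "",
    ]
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
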