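"""Configuration-driven orchestration of the full analysis.

Stages: simulate (synthetic photographs, pair tables, repeated measurements,
encounter histories) → traits → heritability → cluster → survive.  A single
global seed fans out to per-stage seeds by stable hashing so stages are
reproducible independently; every CSV output carries the config hash and the
stage seed in a header comment, and ``run_full`` emits a manifest of output
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import clustering, cmr, similarity, synthetic
from .extraction import AnalysisRectangle, extract_spot_map
from .traits import NoMeasurableSpotsError, AnimalTraitProfile, aggregate_profile, measure_all

log = logging.getLogger("spotpatterns")

MEASURED_TRAITS = [c for c in AnimalTraitProfile.COLUMNS if c != "mode_shade"]

DEFAULT_CONFIG = {
    "seed": 20120101,
    "output_dir": "spotpatterns_out",
    "simulate": {
        "n_animals": 40,
        "n_repeat_animals": 10,
        "n_repeats": 3,
        "scene": {},                 # CoatSceneParams overrides
        "po": {"n_pairs": 31, "po_slope": 0.26},
        "cmr": {"n_released_per_occasion": 20},
        "schedule": {"start": "2012-01", "end": "2016-02"},
    },
    "extraction": {"saturated_fraction": 0.007, "min_area_gu2": 1e-5},
    "heritability": {"alpha": 0.05, "n_boot": 500},
    "cluster": {"k_max": 6, "B": 20, "force_k": None},
    "survive": {"n_restarts": 2, "groups_from_cluster": True},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    def merge(base, over):
        out = dict(base)
        for k, v in (over or {}).items():
            out[k] = merge(base[k], v) if isinstance(base.get(k), dict) else v
        return out
    return merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


def _write_csv(df: pd.DataFrame, path: Path, config: dict, seed: int,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash(config)} seed={seed}\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


# ---------------------------------------------------------------------------


def run_simulate(config: dict, outdir: Path) -> dict:
    """Generate every synthetic input the later stages consume."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config["seed"], "simulate")
    sim = config["simulate"]
    rng = np.random.default_rng(seed)
    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    meta_rows, truth_rows = [], []
    for i in range(sim["n_animals"]):
        params = synthetic.CoatSceneParams(
            **{**sim["scene"], "seed": int(rng.integers(2 ** 31))})
        image, rect, truths = synthetic.gen_coat_image(params)
        path = img_dir / f"animal{i:03d}.png"
        iio.imwrite(path, image)
        meta_rows.append({"image_path": f"images/animal{i:03d}.png",
                          "x0": rect.x0, "y0": rect.y0,
                          "x1": rect.x1, "y1": rect.y1,
                          "animal_id": f"animal{i:03d}", "date": "2014-02-01"})
        for t in truths:
            truth_rows.append({"animal_id": f"animal{i:03d}",
                               "center_x_gu": t.center[0],
                               "center_y_gu": t.center[1],
                               "area_gu2": t.analytic_area,
                               "perimeter_gu": t.analytic_perimeter,
                               "major_gu": t.major_axis,
                               "minor_gu": t.minor_axis,
                               "orientation_deg": t.orientation_deg,
                               "touches_edge": t.touches_edge,
                               "merged": t.merged})
    meta = pd.DataFrame(meta_rows)
    _write_csv(meta, outdir / "metadata.csv", config, seed)
    _write_csv(pd.DataFrame(truth_rows), outdir / "ground_truth.csv", config, seed)
    pairs = synthetic.gen_po_pairs(synthetic.PODesign(
        **{**sim["po"], "seed": int(rng.integers(2 ** 31))}))
    _write_csv(pairs, outdir / "po_pairs.csv", config, seed)
    repeats = synthetic.gen_repeat_measurements(
        sim["n_repeat_animals"], sim["n_repeats"], R_true=0.85,
        seed=int(rng.integers(2 ** 31)), trait_name="circularity")
    _write_csv(repeats, outdir / "repeats.csv", config, seed)
    sched = cmr.SurveySchedule.from_date_range(**sim["schedule"])
    design = synthetic.CMRSimDesign(
        schedule=sched, **{**sim["cmr"], "seed": int(rng.integers(2 ** 31))})
    histories = synthetic.gen_encounter_histories(design)
    cmr.write_inp(histories, outdir / "histories.inp",
                  header=f"config={config_hash(config)} seed={seed}")
    log.info("simulate: %d scenes, %d pairs, %d histories",
             sim["n_animals"], len(pairs), histories.n_individuals)
    return {"metadata": outdir / "metadata.csv", "inp": outdir / "histories.inp"}


def run_traits(config: dict, outdir: Path) -> Path:
    """Measure per-animal trait profiles for every image in the metadata CSV."""
    seed = stage_seed(config["seed"], "traits")
    meta = _read_csv(outdir / "metadata.csv")
    ext = config["extraction"]
    rows, excluded = [], []
    for _, rec in meta.iterrows():
        try:
            image = iio.imread(outdir / rec["image_path"])
        except (OSError, ValueError) as exc:
            log.warning("skipping unreadable image %s: %s", rec["image_path"], exc)
            excluded.append({"animal_id": rec["animal_id"], "reason": str(exc)})
            continue
        rect = AnalysisRectangle(int(rec["x0"]), int(rec["y0"]),
                                 int(rec["x1"]), int(rec["y1"]))
        labeled, color_rect = extract_spot_map(
            image[..., :3], rect,
            saturated_fraction=ext["saturated_fraction"],
            min_area_gu2=ext["min_area_gu2"])
        try:
            profile = aggregate_profile(measure_all(labeled), color_rect)
        except NoMeasurableSpotsError:
            log.warning("animal %s: no measurable spots, excluded", rec["animal_id"])
            excluded.append({"animal_id": rec["animal_id"],
                             "reason": "no measurable spots"})
            continue
        rows.append({"animal_id": rec["animal_id"], **profile.to_row()})
    traits = pd.DataFrame(rows)
    _write_csv(traits, outdir / "traits.csv", config, seed)
    cols = list(AnimalTraitProfile.COLUMNS)
    summary = pd.DataFrame({
        "trait": cols,
        "mean": [traits[c].mean() for c in cols],
        "sd": [traits[c].std(ddof=1) for c in cols],
    })
    summary["cv"] = summary["sd"] / summary["mean"]
    _write_csv(summary, outdir / "traits_summary.csv", config, seed)
    if excluded:
        _write_csv(pd.DataFrame(excluded), outdir / "excluded.csv", config, seed)
    return outdir / "traits.csv"


def run_heritability(config: dict, outdir: Path) -> Path:
    """Repeatability and PO-regression summary for the simulated pair table."""
    seed = stage_seed(config["seed"], "heritability")
    pairs = _read_csv(outdir / "po_pairs.csv")
    repeats = _read_csv(outdir / "repeats.csv")
    po = similarity.po_regression(pairs)
    norm_p, het_p = similarity.regression_diagnostics(po)
    rep = similarity.repeatability(repeats, "circularity",
                                   n_boot=config["heritability"]["n_boot"],
                                   seed=seed)
    adj = similarity.bonferroni_alpha(config["heritability"]["alpha"], 11)
    out = pd.DataFrame([{
        "trait": "simulated", "slope": po.slope, "slope_se": po.slope_se,
        "heritability": po.heritability, "heritability_se": po.heritability_se,
        "F": po.F_stat, "p": po.p_value, "n_pairs": po.n_pairs,
        "normality_p": norm_p, "heteroscedasticity_p": het_p,
        "R": rep.R, "R_se": rep.R_se, "R_p": rep.p_value,
        "alpha_adjusted": adj.rounded,
    }])
    _write_csv(out, outdir / "heritability.csv", config, seed)
    return outdir / "heritability.csv"


def run_cluster(config: dict, outdir: Path) -> Path:
    """PCA, gap curve and phenotype-group assignment from the trait table."""
    seed = stage_seed(config["seed"], "cluster")
    traits = _read_csv(outdir / "traits.csv").set_index("animal_id")
    tm = clustering.standardize(traits, MEASURED_TRAITS)
    pca_res = clustering.pca(tm)
    pca_df = pd.DataFrame({
        "dimension": np.arange(1, len(pca_res.eigenvalues) + 1),
        "eigenvalue": pca_res.eigenvalues,
        "percent_variance": pca_res.percent_variance,
    })
    _write_csv(pca_df, outdir / "pca_summary.csv", config, seed)
    contrib = pd.DataFrame(pca_res.contributions, index=pca_res.trait_names,
                           columns=[f"dim{j+1}" for j in range(pca_res.contributions.shape[1])])
    _write_csv(contrib, outdir / "pca_contributions.csv", config, seed, index=True)
    cl = config["cluster"]
    gap = clustering.gap_statistic(tm.X, k_max=min(cl["k_max"], len(tm.X) - 1),
                                   B=cl["B"], seed=seed)
    _write_csv(gap.to_frame(), outdir / "gap_curve.csv", config, seed)
    k = cl["force_k"] or gap.chosen_k
    model = clustering.kmeans_fit(tm.X, k, seed=seed)
    assign = pd.DataFrame({"animal_id": tm.animal_ids, "group": model.assignment})
    _write_csv(assign, outdir / "phenotype_groups.csv", config, seed)
    return outdir / "phenotype_groups.csv"


def run_survive(config: dict, outdir: Path) -> Path:
    """Phenotype-group survival model set and model-averaged estimates."""
    seed = stage_seed(config["seed"], "survive")
    sched = cmr.SurveySchedule.from_date_range(**config["simulate"]["schedule"])
    data = cmr.read_inp(outdir / "histories.inp", sched, ["cov"])
    sv = config["survive"]
    fits = [cmr.fit_model(data, cmr.SurvivalModelSpec(), seed=seed,
                          n_restarts=sv["n_restarts"])]
    fits.append(cmr.covariate_effect_models(data, "cov", seed=seed,
                                            n_restarts=sv["n_restarts"]))
    table = cmr.model_selection_table(fits)
    _write_csv(table, outdir / "model_selection.csv", config, seed)
    est_rows = []
    for age in range(min(9, sched.n_primary - 1)):
        est = cmr.model_average_survival(fits, age)
        est_rows.append({"age_seasons": age, "survival": est.estimate,
                         "se": est.se, "ci_lo": est.ci_lo, "ci_hi": est.ci_hi})
    _write_csv(pd.DataFrame(est_rows), outdir / "survival_estimates.csv",
               config, seed)
    return outdir / "model_selection.csv"


def run_full(config: dict, outdir: Path | None = None) -> Path:
    """All stages in order; writes a manifest of output-file hashes."""
    outdir = Path(outdir or config["output_dir"])
    stages = [("simulate", run_simulate), ("traits", run_traits),
              ("heritability", run_heritability), ("cluster", run_cluster),
              ("survive", run_survive)]
    for name, fn in stages:
        try:
            fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    payload = {"config": config_hash(config), "seed": config["seed"],
               "outputs": manifest}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2,
                                                     sort_keys=True))
    return outdir / "manifest.json"
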