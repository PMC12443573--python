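"""End-to-end orchestration: scenes -> indices -> inversion -> traits -> GWAS.

``make_fixtures`` writes a complete synthetic input bundle (multiband TIFFs,
plot layout, SPAD tables, genotypes + map, QTL truth); ``run_pipeline``
consumes such a bundle and executes every analysis stage for both the
measured and the network-predicted trait, writing CSV outputs and a manifest
with content hashes so reruns are verifiably deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import featsel, gwas, inversion, reflectance, synthio, traitstats, vegindex

log = logging.getLogger(__name__)

BAND_ORDER = synthio.BANDS  # (red, rededge, nir, green, blue)


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run."""

    input_dir: str
    output_dir: str
    gff_path: str | None = None
    p_threshold: float = gwas.DEFAULT_P_THRESHOLD
    k_top: int = 5
    n_pcs: int = 3
    maf_floor: float = 0.05
    ld_decay_default: float = gwas.DEFAULT_LD_DECAY_BP
    # full-batch GD needs more epochs than an adaptive optimizer for the
    # same training error; 5000 converges on these feature counts
    hyperparams: inversion.Hyperparams = field(
        default_factory=lambda: inversion.Hyperparams(epochs=5000)
    )
    n_replicates: int = 8
    seed: int = 0
    envs: tuple[str, ...] = synthio.ENVS
    treatments: tuple[str, ...] = synthio.TREATMENTS
    stages: tuple[str, ...] = synthio.STAGES


def make_fixtures(
    config: synthio.SimConfig, out_dir, overwrite: bool = False
) -> dict:
    """Write the full synthetic input bundle for :func:`run_pipeline`.

    Files: ``scene_<env>_<trt>_<stage>.tif`` (5-band, order red/rededge/
    nir/green/blue, documented in TIFF metadata), ``plots.csv``,
    ``spad.csv``, ``genotypes.csv``, ``map.csv``, ``truth.json``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    pop = synthio.simulate_genotypes(config)
    trial = synthio.simulate_spad_phenotypes(pop, config)
    scenes = synthio.render_all_scenes(trial, config)

    plot_rows = []
    for key, scene in scenes.items():
        env, trt, stage = key
        stack = np.stack(
            [scene.bands[b] for b in BAND_ORDER]
        ).astype(np.float32)
        tifffile.imwrite(
            out / f"scene_{env}_{trt}_{stage}.tif",
            stack,
            metadata={"bands": list(BAND_ORDER), "whiteboard": list(scene.whiteboard)},
        )
        p = scene.plots.copy()
        p[["env", "treatment", "stage"]] = env, trt, stage
        plot_rows.append(p)
    pd.concat(plot_rows, ignore_index=True).to_csv(out / "plots.csv", index=False)
    trial.spad.to_csv(out / "spad.csv", index=False)

    geno = pd.DataFrame(
        pop.genotypes, columns=pop.snp_map["marker"], copy=False
    )
    geno.insert(0, "genotype", [f"G{i + 1:03d}" for i in range(pop.n_genotypes)])
    geno.to_csv(out / "genotypes.csv", index=False)
    pop.snp_map.to_csv(out / "map.csv", index=False)
    truth = {
        "seed": config.seed,
        "qtl": [{"index": i, "marker": pop.snp_map["marker"][i], "effect": e}
                for i, e in pop.qtl_truth],
        "subpop_labels": pop.subpop_labels.tolist(),
        "whiteboard_dn": synthio.WHITEBOARD_DN,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"n_scenes": len(scenes), "n_markers": pop.n_markers, "dir": str(out)}


def _read_bundle(input_dir):
    d = Path(input_dir)
    plots = pd.read_csv(d / "plots.csv")
    spad = pd.read_csv(d / "spad.csv")
    geno = pd.read_csv(d / "genotypes.csv")
    snp_map = pd.read_csv(d / "map.csv")
    scenes = {}
    for f in sorted(d.glob("scene_*.tif")):
        env, trt, stage = f.stem.split("_")[1:]
        with tifffile.TiffFile(f) as tf:
            stack = tf.asarray()
        scenes[(env, trt, stage)] = {
            b: stack[i].astype(float) for i, b in enumerate(BAND_ORDER)
        }
    return plots, spad, geno, snp_map, scenes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the output manifest.

    Stages: plot reflectance extraction -> vegetation indices -> feature
    selection -> inversion model (per env x treatment x stage cell) ->
    trait statistics (measured and predicted) -> Q+K genome scan on both
    trait sources -> locus merging, overlap and summaries.
    """
    outd = Path(config.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    stage_name = "load-inputs"
    try:
        plots, spad, geno, snp_map, scenes = _read_bundle(config.input_dir)

        # ---- reflectance ----
        stage_name = "reflectance"
        refl_parts = []
        for key, bands in scenes.items():
            env, trt, stage = key
            sel = plots.query(
                "env == @env and treatment == @trt and stage == @stage"
            ).reset_index(drop=True)
            r = reflectance.extract_plot_reflectance(bands, sel)
            r[["env", "treatment", "stage"]] = env, trt, stage
            refl_parts.append(r)
        plot_refl = pd.concat(refl_parts, ignore_index=True)
        plot_refl.to_csv(outd / "plot_reflectance.csv", index=False)
        summary = reflectance.band_stage_summary(plot_refl)
        summary.to_csv(outd / "band_stage_summary.csv", index=False)
        reflectance.stage_decreases(summary).to_csv(
            outd / "stage_decreases.csv", index=False
        )

        # ---- vegetation indices ----
        stage_name = "vegindex"
        vi, vi_valid = vegindex.compute_all_vi(plot_refl)
        vi.to_csv(outd / "vegindex.csv", index=False)
        vi_valid.to_csv(outd / "vegindex_valid.csv", index=False)

        # measured plot-level SPAD (replicate means) aligned to VI rows
        spad_mean = (
            spad.groupby(["genotype", "env", "treatment", "stage"], observed=True)[
                "spad"
            ]
            .mean()
            .reset_index()
        )
        cell_keys = ["env", "treatment", "stage"]
        merged = vi.merge(spad_mean, on=["genotype"] + cell_keys, how="inner")

        # ---- feature selection + inversion per cell ----
        stage_name = "featsel/inversion"
        imp_rows, sel_rows, fit_rows, pred_rows = [], {}, [], []
        for i, (key, grp) in enumerate(merged.groupby(cell_keys, observed=True)):
            tab = featsel.importance_table(
                grp, grp["spad"], seed=config.seed + i
            )
            t = tab.reset_index(names="index_name")
            t[cell_keys] = key
            imp_rows.append(t)
            sel = featsel.select_indices(tab, k_top=config.k_top)
            sel_rows["/".join(key)] = sel.indices
            feats = grp[sel.indices]
            report = inversion.replicate_fit(
                feats,
                grp["spad"].to_numpy(),
                n_replicates=config.n_replicates,
                hyperparams=config.hyperparams,
                seed=config.seed + i,
            )
            report[cell_keys] = key
            fit_rows.append(report)
            # final model on all plots of the cell -> predicted trait
            model = inversion.train_inversion_model(
                feats, grp["spad"].to_numpy(),
                hyperparams=config.hyperparams, seed=config.seed + i,
            )
            (outd / f"model_{'_'.join(key)}.json").write_text(model.to_json())
            pred = grp[["genotype"] + cell_keys].copy()
            pred["spad_pred"] = inversion.predict_spad(model, feats)
            pred_rows.append(pred)
        pd.concat(imp_rows, ignore_index=True).to_csv(
            outd / "importance.csv", index=False
        )
        (outd / "selection.json").write_text(json.dumps(sel_rows, indent=1))
        fit_report = pd.concat(fit_rows, ignore_index=True).drop(
            columns=["train_idx", "val_idx"], errors="ignore"
        )
        fit_report.to_csv(outd / "fit_report.csv", index=False)
        predicted = pd.concat(pred_rows, ignore_index=True)
        predicted.to_csv(outd / "predicted_spad.csv", index=False)

        # ---- trait statistics ----
        stage_name = "traitstats"
        meas_summary = traitstats.trait_summary_table(spad, source="measured")
        # predicted trait has no replicates; summarize genotype values directly
        pred_long = predicted.rename(columns={"spad_pred": "spad"}).copy()
        pred_long["replicate"] = 1
        pred_rows_sum = []
        for key, grp in pred_long.groupby(cell_keys, observed=True):
            x = grp["spad"].to_numpy()
            sd = float(np.std(x, ddof=1))
            mu = float(np.mean(x))
            pred_rows_sum.append(
                dict(zip(cell_keys, key))
                | {
                    "source": "predicted",
                    "mean": mu,
                    "median": float(np.median(x)),
                    "cv_pct": 100 * sd / mu if mu > 0 else np.nan,
                    "sd": sd,
                    "max": float(x.max()),
                    "min": float(x.min()),
                    "n": int(x.size),
                    "h2": np.nan,
                }
            )
        trait_summary = pd.concat(
            [meas_summary, pd.DataFrame(pred_rows_sum)], ignore_index=True
        )
        trait_summary.to_csv(outd / "trait_summary.csv", index=False)

        # ---- GWAS ----
        stage_name = "gwas"
        geno_ids = geno["genotype"].tolist()
        G_raw = geno.drop(columns="genotype").to_numpy(dtype=float)
        G, snp_map_f, gw_log = gwas.impute_and_filter(
            G_raw, snp_map, maf_floor=config.maf_floor
        )
        K = gwas.compute_kinship(G)
        Q = gwas.compute_q(G, q=config.n_pcs)
        decay = gwas.estimate_ld_decay(
            G, snp_map_f, default=config.ld_decay_default
        )
        decay_bp = float(decay) if decay.crossed else config.ld_decay_default

        traits = {
            "measured": spad_mean.rename(columns={"spad": "value"}),
            "predicted": predicted.rename(columns={"spad_pred": "value"}),
        }
        assoc_parts, loci_parts = [], []
        for source, tab in traits.items():
            for key, grp in tab.groupby(cell_keys, observed=True):
                y = (
                    grp.set_index("genotype")["value"]
                    .reindex(geno_ids)
                    .to_numpy()
                )
                res = gwas.mlm_scan(y, G, snp_map_f, K=K, Q=Q)
                res[["source"] + cell_keys] = (source, *key)
                assoc_parts.append(res)
                sig = res[res["p"] < config.p_threshold]
                cell_loci = gwas.merge_loci(sig, decay_bp)
                if len(cell_loci):
                    loci_parts.append(cell_loci)
        assoc = pd.concat(assoc_parts, ignore_index=True)
        assoc.to_csv(outd / "assoc.csv", index=False)
        gwas.manhattan_table(assoc).to_csv(outd / "manhattan.csv", index=False)
        loci = (
            pd.concat(loci_parts, ignore_index=True)
            if loci_parts
            else gwas.merge_loci(None, decay_bp)
        )
        loci.to_csv(outd / "loci.csv", index=False)

        stage_name = "summaries"
        overlap_parts = []
        for key, grp in loci.groupby(cell_keys, observed=True):
            meas = grp[grp["source"] == "measured"]
            pred = grp[grp["source"] == "predicted"]
            ov = gwas.overlap_loci(meas, pred, window=decay_bp)
            if len(ov):
                ov[cell_keys] = key
                overlap_parts.append(ov)
        overlap = (
            pd.concat(overlap_parts, ignore_index=True)
            if overlap_parts
            else pd.DataFrame()
        )
        overlap.to_csv(outd / "overlap.csv", index=False)
        locus_summary = gwas.summarize_loci(loci)
        locus_summary.cells.to_csv(outd / "locus_summary.csv", index=False)
        (outd / "locus_overall.json").write_text(
            json.dumps(locus_summary.overall, indent=1, default=float)
        )

        if config.gff_path:
            stage_name = "annotation"
            gwas.annotate_loci(loci, config.gff_path).to_csv(
                outd / "locus_genes.csv", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest = {
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "ld_decay_bp": decay_bp,
        "gwas_log": gw_log,
        "outputs": {
            f.name: _sha256(f)
            for f in sorted(outd.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    (outd / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
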