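"""Seeded synthetic genotypes, SPAD phenotypes and five-band plot scenes.

The generator emulates a replicated two-environment wheat trial: 119
genotypes drawn from three subpopulations, grown under normal irrigation (W)
and drought (D) in two environments (E1, E2), phenotyped for flag-leaf SPAD
at heading (HS), flowering (FL) and grain filling (GF) with two replicates,
and imaged by a five-band multispectral sensor whose scenes include a
whiteboard calibration panel (DN 65000 at 99.8% reflectance).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

ENVS = ("E1", "E2")
TREATMENTS = ("W", "D")
STAGES = ("HS", "FL", "GF")
REPLICATES = (1, 2)

BANDS = ("red", "rededge", "nir", "green", "blue")

#: Wheat chromosome labels: 7 homoeologous groups x 3 subgenomes.
WHEAT_CHROMOSOMES = tuple(f"{i}{s}" for i in range(1, 8) for s in "ABD")

#: Scene-wide mean band reflectance (fraction) per (treatment, stage),
#: band order (red, rededge, nir, green, blue). These are the observed
#: stage dynamics of a wheat canopy under the two irrigation regimes.
BAND_BASELINES: dict[tuple[str, str], tuple[float, ...]] = {
    ("W", "HS"): (0.0768, 0.3403, 0.5684, 0.1593, 0.0674),
    ("W", "FL"): (0.0765, 0.3311, 0.5514, 0.1506, 0.0638),
    ("W", "GF"): (0.0585, 0.2722, 0.3747, 0.0770, 0.0454),
    ("D", "HS"): (0.0788, 0.3374, 0.5540, 0.1582, 0.0670),
    ("D", "FL"): (0.0770, 0.3142, 0.5233, 0.1481, 0.0638),
    ("D", "GF"): (0.0695, 0.2788, 0.3493, 0.0831, 0.0494),
}

#: SPAD sensitivity of each band (reflectance units per SPAD unit around the
#: baseline). Greener canopies absorb more strongly in the chlorophyll
#: absorption bands (red, blue, and the lower red edge) and scatter slightly
#: more in the near infrared, so visible-band slopes are negative.
BAND_SPAD_SLOPES: tuple[float, ...] = (-0.0020, -0.0035, 0.0015, -0.0030, -0.0010)

#: Mean SPAD per (treatment, stage); grand means rise from heading to grain
#: filling, with a mild drought offset.
SPAD_BASELINES: dict[tuple[str, str], float] = {
    ("W", "HS"): 54.5,
    ("W", "FL"): 55.5,
    ("W", "GF"): 56.3,
    ("D", "HS"): 54.8,
    ("D", "FL"): 55.9,
    ("D", "GF"): 57.0,
}

#: Small environment offset (added for E2) so the two sites differ.
ENV_OFFSET = {"E1": 0.0, "E2": 0.4}

WHITEBOARD_DN = 65000.0
WHITEBOARD_REFLECTANCE = 0.998


@dataclass
class SimConfig:
    """Parameters of the synthetic trial generator.

    Defaults reproduce the study conditions: 119 genotypes in three
    subpopulations (16/35/68 split), 21 chromosomes, two environments, two
    treatments, three stages, two replicates, broad-sense heritability
    around 0.7.
    """

    n_genotypes: int = 119
    n_snps: int = 2000
    n_chromosomes: int = 21
    n_subpops: int = 3
    n_qtl: int = 8
    qtl_effect_sd: float = 1.0
    target_h2: float = 0.7
    band_noise_sd: float = 0.01
    plot_noise_sd: float = 0.005
    plot_rows: int = 7
    plot_cols: int = 17
    seed: int = 0
    maf_floor: float = 0.05
    drift: float = 0.1
    subpop_weights: tuple[float, ...] = (16.0, 35.0, 68.0)
    chrom_length_bp: int = 800_000_000
    plot_px: int = 12
    plot_margin_px: int = 3
    polygenic_sd: float = 1.0

    def validate(self) -> None:
        for name in ("n_genotypes", "n_snps", "n_chromosomes", "n_subpops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in [0, 1]")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if self.plot_rows * self.plot_cols < self.n_genotypes:
            raise ValueError("plot grid too small for n_genotypes")


@dataclass
class SyntheticPopulation:
    """Dosage matrix with a marker map, subpopulation labels and QTL truth."""

    genotypes: np.ndarray  # (n, m) dosages in {0,1,2}
    snp_map: pd.DataFrame  # columns: marker, chrom, pos (1-based bp)
    subpop_labels: np.ndarray  # (n,) int labels
    qtl_truth: list[tuple[int, float]]  # (marker index, effect in SPAD units)

    @property
    def n_genotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SyntheticTrial:
    """Replicated SPAD table plus the underlying true genetic values.

    ``spad`` is long-format with columns
    (genotype, env, treatment, stage, replicate, spad);
    ``true_genetic_value`` drops the replicate and noise.
    """

    spad: pd.DataFrame
    true_genetic_value: pd.DataFrame


@dataclass
class SyntheticScene:
    """Five DN-valued rasters with plot polygons and a whiteboard panel."""

    bands: dict[str, np.ndarray]  # band name -> 2-D DN array (float)
    whiteboard: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    plots: pd.DataFrame  # plot_id, genotype, x0, y0, x1, y1 (pixel rect)
    key: tuple[str, str, str]  # (env, treatment, stage)
    true_plot_reflectance: pd.DataFrame  # genotype + 5 r_* columns (pre-noise)
    clipped_pixels: int = 0


def _subpop_sizes(config: SimConfig) -> np.ndarray:
    w = np.asarray(config.subpop_weights, dtype=float)[: config.n_subpops]
    if w.size < config.n_subpops:
        w = np.ones(config.n_subpops)
    sizes = np.floor(w / w.sum() * config.n_genotypes).astype(int)
    sizes[: config.n_genotypes - sizes.sum()] += 1
    return sizes


def simulate_genotypes(config: SimConfig) -> SyntheticPopulation:
    """Draw a structured biallelic dosage matrix.

    Subpopulation allele frequencies follow the Balding–Nichols model: for an
    ancestral frequency p and drift Fst, each subpopulation frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F). Dosages are Binomial(2, p_subpop). Markers
    with minor-allele frequency below ``maf_floor`` are dropped; QTL markers
    are then planted on the retained panel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = _subpop_sizes(config)
    labels = np.repeat(np.arange(config.n_subpops), sizes)

    # oversample so the MAF filter still leaves ~n_snps markers
    m_raw = int(config.n_snps * 1.6) + 50
    p_anc = rng.uniform(0.1, 0.9, size=m_raw)
    if config.drift > 0 and config.n_subpops > 1:
        f = config.drift
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m_raw))
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))
    dosages = rng.binomial(2, p_sub[labels, :]).astype(np.int8)

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(maf >= config.maf_floor)
    if keep.size == 0:
        raise ValueError("no polymorphic markers left after MAF filtering")
    keep = keep[: config.n_snps]
    dosages = dosages[:, keep]
    m = dosages.shape[1]

    chroms = np.array(WHEAT_CHROMOSOMES[: config.n_chromosomes])
    chrom_idx = np.sort(rng.integers(0, config.n_chromosomes, size=m))
    pos = np.empty(m, dtype=np.int64)
    for c in range(config.n_chromosomes):
        sel = chrom_idx == c
        k = int(sel.sum())
        if k == 0:
            continue
        p = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False))
        pos[sel] = p + 1  # 1-based
    snp_map = pd.DataFrame(
        {
            "marker": [f"SNP{i + 1:05d}" for i in range(m)],
            "chrom": chroms[chrom_idx],
            "pos": pos,
        }
    )

    qtl_idx = (
        rng.choice(m, size=min(config.n_qtl, m), replace=False)
        if config.n_qtl
        else np.array([], dtype=int)
    )
    effects = rng.normal(0.0, config.qtl_effect_sd, size=qtl_idx.size)
    qtl_truth = [(int(i), float(e)) for i, e in zip(qtl_idx, effects)]

    return SyntheticPopulation(
        genotypes=dosages, snp_map=snp_map, subpop_labels=labels, qtl_truth=qtl_truth
    )


def simulate_spad_phenotypes(
    pop: SyntheticPopulation, config: SimConfig
) -> SyntheticTrial:
    """Forward-simulate replicated SPAD values.

    Per (env, treatment, stage) cell the phenotype is

        baseline + sum_j effect_j * (dosage_j - mean_j) + polygenic + noise

    with the replicate-noise variance set from the realized genetic variance
    so the expected broad-sense heritability equals ``target_h2``.
    """
    config.validate()
    if not pop.qtl_truth and config.target_h2 > 0 and config.polygenic_sd == 0:
        raise ValueError("target_h2 > 0 requires QTLs or a polygenic term")
    if config.target_h2 >= 1.0:
        raise ValueError(
            "target_h2 = 1 is inestimable with replicate noise; use < 1"
        )
    rng = np.random.default_rng(config.seed + 1)
    n = pop.n_genotypes
    z = pop.genotypes.astype(float)
    z -= z.mean(axis=0, keepdims=True)

    g_qtl = np.zeros(n)
    for idx, eff in pop.qtl_truth:
        g_qtl += eff * z[:, idx]
    # polygenic background: many small marker effects
    u = rng.normal(0.0, 1.0, size=pop.n_markers)
    g_poly = z @ u
    sd = g_poly.std()
    if sd > 0 and config.polygenic_sd > 0:
        g_poly *= config.polygenic_sd / sd
    else:
        g_poly = np.zeros(n)
    g = g_qtl + g_poly
    g -= g.mean()  # baselines are exact cell means
    var_g = g.var(ddof=1)
    if config.target_h2 == 0:
        g = np.zeros(n)
        var_g = 0.0
        noise_sd = 1.0
    else:
        noise_sd = np.sqrt(var_g * (1 - config.target_h2) / config.target_h2)

    genos = [f"G{i + 1:03d}" for i in range(n)]
    rows, truth_rows = [], []
    for env, trt, stage in itertools.product(ENVS, TREATMENTS, STAGES):
        base = SPAD_BASELINES[(trt, stage)] + ENV_OFFSET[env]
        mu = base + g
        for i, geno in enumerate(genos):
            truth_rows.append((geno, env, trt, stage, mu[i]))
        for rep in REPLICATES:
            noise = rng.normal(0.0, noise_sd, size=n)
            for i, geno in enumerate(genos):
                rows.append((geno, env, trt, stage, rep, mu[i] + noise[i]))

    spad = pd.DataFrame(
        rows, columns=["genotype", "env", "treatment", "stage", "replicate", "spad"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["genotype", "env", "treatment", "stage", "value"]
    )
    return SyntheticTrial(spad=spad, true_genetic_value=truth)


def _plot_grid(config: SimConfig) -> pd.DataFrame:
    """Rectangular plot layout; one plot per genotype, row-major."""
    px, margin = config.plot_px, config.plot_margin_px
    pitch = px + margin
    recs = []
    for i in range(config.n_genotypes):
        r, c = divmod(i, config.plot_cols)
        y0 = margin + r * pitch
        x0 = margin + c * pitch
        recs.append((f"P{i + 1:03d}", f"G{i + 1:03d}", x0, y0, x0 + px, y0 + px))
    return pd.DataFrame(recs, columns=["plot_id", "genotype", "x0", "y0", "x1", "y1"])


def render_scene(
    trial: SyntheticTrial,
    key: tuple[str, str, str],
    config: SimConfig,
    noise_sd: float | None = None,
    plot_noise_sd: float | None = None,
) -> SyntheticScene:
    """Render the five-band DN scene for one (env, treatment, stage) key.

    Plot band reflectance is an affine function of the plot's replicate-mean
    SPAD around the stage/treatment baseline (slopes in
    :data:`BAND_SPAD_SLOPES`; the visible bands decrease with SPAD), plus a
    plot-level reflectance jitter (field heterogeneity that pixel averaging
    cannot remove) and i.i.d. pixel noise. DN = reflectance x 65000 / 0.998;
    the whiteboard panel is rendered at DN 65000. The recorded
    ``true_plot_reflectance`` is the painted (post-jitter) plot value, so a
    noiseless extraction round-trips exactly.
    """
    env, trt, stage = key
    sub = trial.spad.query(
        "env == @env and treatment == @trt and stage == @stage"
    )
    if sub.empty:
        raise KeyError(f"key {key!r} not present in trial")
    if noise_sd is None:
        noise_sd = config.band_noise_sd
    if plot_noise_sd is None:
        plot_noise_sd = config.plot_noise_sd
    key_id = zlib.crc32("/".join(key).encode()) % 100003
    rng = np.random.default_rng((config.seed + 7919 * key_id) % (2**31))
    plot_spad = sub.groupby("genotype")["spad"].mean()
    plots = _plot_grid(config)
    plots = plots[plots["genotype"].isin(plot_spad.index)].reset_index(drop=True)

    base = BAND_BASELINES[(trt, stage)]
    spad_base = SPAD_BASELINES[(trt, stage)] + ENV_OFFSET[env]

    height = config.plot_margin_px + config.plot_rows * (
        config.plot_px + config.plot_margin_px
    )
    width = config.plot_margin_px + config.plot_cols * (
        config.plot_px + config.plot_margin_px
    )
    # whiteboard strip appended below the plot grid
    wb_h = max(config.plot_px, 8)
    wb = (height + 2, height + 2 + wb_h, 2, 2 + 2 * wb_h)
    full_h = height + wb_h + 6

    soil = (0.12, 0.20, 0.25, 0.15, 0.08)  # background reflectance
    bands: dict[str, np.ndarray] = {}
    truth = {"genotype": plots["genotype"].to_numpy()}
    clipped = 0
    for b, name in enumerate(BANDS):
        refl = np.full((full_h, width), soil[b], dtype=float)
        plot_refl = base[b] + BAND_SPAD_SLOPES[b] * (
            plot_spad.loc[plots["genotype"]].to_numpy() - spad_base
        )
        if plot_noise_sd > 0:
            plot_refl = plot_refl + rng.normal(
                0.0, plot_noise_sd, size=plot_refl.shape
            )
        plot_refl = np.clip(plot_refl, 0.0, 1.0)
        truth[f"r_{name}"] = plot_refl
        for (x0, y0, x1, y1), r in zip(
            plots[["x0", "y0", "x1", "y1"]].to_numpy(), plot_refl
        ):
            refl[y0:y1, x0:x1] = r
        if noise_sd > 0:
            refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
        below, above = refl < 0, refl > 1
        clipped += int(below.sum() + above.sum())
        refl = np.clip(refl, 0.0, 1.0)
        dn = refl * WHITEBOARD_DN / WHITEBOARD_REFLECTANCE
        dn[wb[0] : wb[1], wb[2] : wb[3]] = WHITEBOARD_DN
        bands[name] = dn
    return SyntheticScene(
        bands=bands,
        whiteboard=wb,
        plots=plots,
        key=key,
        true_plot_reflectance=pd.DataFrame(truth),
        clipped_pixels=clipped,
    )


def render_all_scenes(
    trial: SyntheticTrial,
    config: SimConfig,
    noise_sd: float | None = None,
    plot_noise_sd: float | None = None,
) -> dict[tuple[str, str, str], SyntheticScene]:
    """Render one scene per (env, treatment, stage) key in the trial."""
    keys = (
        trial.spad[["env", "treatment", "stage"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    return {
        k: render_scene(trial, k, config, noise_sd=noise_sd, plot_noise_sd=plot_noise_sd)
        for k in keys
    }
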