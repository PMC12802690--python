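"""Synthetic developmental methylome generator with known ground truth.

Emulates the study conditions of an early/mid-gestation cortex series:
~90 donors aged 6-23 post-conception weeks (pcw), per-site trajectories that
are constant, linear (percentage points per week) or nonlinear (sigmoid,
gaussian bump or sine on the pcw axis), additive Gaussian noise on the
proportion scale, and small sex/batch nuisance offsets.  Every generated
dataset carries a truth table sufficient to score classification accuracy,
slope bias and enrichment recovery downstream.

Noise is additive Gaussian with clipping to [0.001, 0.999] rather than a
beta distribution: the downstream analyses are linear-model based and this
keeps the oracle math exact (with zero noise every curve equals its
specification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CGI_CLASSES, GENIC_CLASSES, BetaMatrix, GeneSet, PeakSet

# Study-condition defaults: 91 donors aged 6-23 pcw; nuisance offsets of
# 0.5 (sex) and 1.0 (batch) percentage points on the proportion scale.
DEFAULT_AGE_RANGE = (6.0, 23.0)
DEFAULT_N_SAMPLES = 91
DEFAULT_NOISE_SD = 0.03
DEFAULT_SEX_EFFECT = 0.005
DEFAULT_BATCH_EFFECT = 0.010
DEFAULT_EFFECT_GRID = (0.5, 1.0, 2.0, 4.0)  # |slope| pp/week, order of the top reported sites
CLIP_LO, CLIP_HI = 0.001, 0.999


@dataclass
class TrajectorySpec:
    """Ground-truth mean curve of one site, on the proportion scale."""

    klass: str  # constant | linear | nonlinear
    baseline: float
    slope: float = 0.0  # percentage points per week (linear class)
    shape: str | None = None  # sigmoid | gaussian_bump | sine
    shape_params: dict = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    sex_effect: float = 0.0
    batch_effects: tuple = ()
    age_origin: float = DEFAULT_AGE_RANGE[0]  # pcw at which the curve equals baseline

    def mean_curve(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, float)
        if self.klass == "constant":
            mu = np.full_like(ages, self.baseline)
        elif self.klass == "linear":
            mu = self.baseline + (self.slope / 100.0) * (ages - self.age_origin)
        elif self.klass == "nonlinear":
            mu = self.baseline + _shape_curve(self.shape, self.shape_params, ages,
                                              self.age_origin)
        else:
            raise ValueError(f"unknown trajectory class {self.klass!r}")
        return np.clip(mu, CLIP_LO, CLIP_HI)


def _shape_curve(shape: str, params: dict, ages: np.ndarray, origin: float) -> np.ndarray:
    amp = params["amplitude"]
    if shape == "sigmoid":
        x0, width = params["inflection"], params["width"]
        return amp / (1.0 + np.exp(-(ages - x0) / width))
    if shape == "gaussian_bump":
        x0, width = params["inflection"], params["width"]
        return amp * np.exp(-0.5 * ((ages - x0) / width) ** 2)
    if shape == "sine":
        period = params["period"]
        phase = params.get("phase", 0.0)
        return amp * np.sin(2.0 * np.pi * (ages - origin) / period + phase)
    raise ValueError(f"unknown nonlinear shape {shape!r}")


def _class_counts(class_mix, n_sites: int) -> dict[str, int]:
    classes = ("constant", "linear", "nonlinear")
    mix = np.asarray(class_mix, float)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {mix.sum()!r}")
    # deterministic largest-remainder allocation
    raw = mix * n_sites
    counts = np.floor(raw).astype(int)
    rem = n_sites - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return dict(zip(classes, counts))


def simulate_dataset(
    n_sites: int = 1000,
    n_samples: int = DEFAULT_N_SAMPLES,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    class_mix: tuple[float, float, float] = (0.6, 0.2, 0.2),
    effect_grid: tuple[float, ...] = DEFAULT_EFFECT_GRID,
    noise_sd: float = DEFAULT_NOISE_SD,
    sex_effect: float = DEFAULT_SEX_EFFECT,
    batch_effect: float = DEFAULT_BATCH_EFFECT,
    n_batches: int = 3,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a (BetaMatrix, sample sheet, truth table) triple.

    ``class_mix`` is the (constant, linear, nonlinear) site proportion;
    allocation to classes is deterministic (largest remainder).  Ages are
    uniform over ``age_range``, sex is Bernoulli(0.5), batch is balanced
    over ``n_batches`` labels (2-4).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 2 <= n_batches <= 4:
        raise ValueError("n_batches must be in 2..4")
    rng = np.random.default_rng(seed)
    counts = _class_counts(class_mix, n_sites)

    ages = rng.uniform(age_range[0], age_range[1], size=n_samples)
    sex = rng.integers(0, 2, size=n_samples)  # 1 = male
    batch = rng.integers(0, n_batches, size=n_samples)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_value": ages,
            "age_unit": "pcw",
            "sex": np.where(sex == 1, "M", "F"),
            "batch": [f"batch{b + 1}" for b in batch],
            "donor_id": [f"D{i:04d}" for i in range(n_samples)],
            "fraction": "bulk",
            "stage": "prenatal",
        }
    )

    site_ids, specs = [], []
    i = 0
    for klass in ("constant", "linear", "nonlinear"):
        for _ in range(counts[klass]):
            site_ids.append(f"site{i:06d}")
            specs.append(_draw_spec(klass, rng, effect_grid, noise_sd, sex_effect,
                                    batch_effect, n_batches, age_range[0]))
            i += 1

    values = np.empty((n_sites, n_samples))
    for j, spec in enumerate(specs):
        mu = spec.mean_curve(ages)
        offs = spec.sex_effect * sex
        if spec.batch_effects:
            offs = offs + np.asarray(spec.batch_effects)[batch]
        eps = rng.normal(0.0, spec.noise_sd, size=n_samples) if spec.noise_sd > 0 else 0.0
        values[j] = np.clip(mu + offs + eps, CLIP_LO, CLIP_HI)

    beta = BetaMatrix(site_ids, sample_ids, values)
    truth = _truth_table(site_ids, specs, ages, noise_sd)
    return beta, sheet, truth


def _draw_spec(klass, rng, effect_grid, noise_sd, sex_effect, batch_effect, n_batches,
               age_origin):
    baseline = rng.uniform(0.15, 0.75)
    batch_offsets = tuple(rng.normal(0.0, batch_effect, size=n_batches)) if batch_effect else ()
    common = dict(noise_sd=noise_sd, sex_effect=sex_effect, batch_effects=batch_offsets,
                  age_origin=age_origin)
    if klass == "constant":
        return TrajectorySpec("constant", baseline, **common)
    if klass == "linear":
        slope = float(rng.choice(effect_grid)) * float(rng.choice([-1.0, 1.0]))
        return TrajectorySpec("linear", baseline, slope=slope, **common)
    shape = str(rng.choice(["sigmoid", "gaussian_bump", "sine"]))
    params = {"amplitude": float(rng.uniform(0.1, 0.25))}
    if shape == "sine":
        params["period"] = float(rng.uniform(10.0, 30.0))
        params["phase"] = float(rng.uniform(0.0, 2.0 * np.pi))
    else:
        params["inflection"] = float(rng.uniform(9.0, 20.0))
        params["width"] = float(rng.uniform(1.0, 4.0))
    return TrajectorySpec("nonlinear", baseline, shape=shape, shape_params=params, **common)


def min_detectable_slope(ages: np.ndarray, noise_sd: float, alpha: float = 9e-8,
                         power: float = 0.8) -> float:
    """Design-time detectable |slope| (pp/week) for the per-site age regression."""
    from scipy import stats

    ages = np.asarray(ages, float)
    n = ages.size
    se = noise_sd / (ages.std(ddof=0) * np.sqrt(n))  # proportion/week
    z = stats.norm.isf(alpha / 2) + stats.norm.isf(1 - power)
    return 100.0 * z * se


def _truth_table(site_ids, specs, ages, noise_sd) -> pd.DataFrame:
    thresh = min_detectable_slope(ages, noise_sd) if noise_sd > 0 else 0.0
    rows = []
    for sid, spec in zip(site_ids, specs):
        rows.append(
            {
                "site_id": sid,
                "true_class": spec.klass,
                "true_slope": spec.slope,
                "true_shape": spec.shape,
                "true_shape_params": repr(spec.shape_params) if spec.shape else "",
                "baseline": spec.baseline,
                "is_dmp": spec.klass == "linear" and abs(spec.slope) > thresh,
            }
        )
    return pd.DataFrame(rows)


def simulate_gp_benchmark(
    n_per_class: int = 100,
    n_samples: int = 90,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    slope: float = 1.0,
    amplitude: float = 0.2,
    width: float = 3.0,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, BetaMatrix, pd.Series]:
    """Fixed benchmark for the trajectory classifier: equal thirds of
    constant, linear (``slope`` pp/week) and nonlinear (sigmoid of the given
    amplitude and width) sites at ``noise_sd`` Gaussian noise.

    Returns (ages, BetaMatrix, true class per site).
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n_samples)
    site_ids, labels, rows = [], [], []
    i = 0
    for klass in ("constant", "linear", "nonlinear"):
        for _ in range(n_per_class):
            base = rng.uniform(0.15, 0.75)
            if klass == "constant":
                spec = TrajectorySpec("constant", base, noise_sd=noise_sd)
            elif klass == "linear":
                spec = TrajectorySpec("linear", base, slope=slope, noise_sd=noise_sd,
                                      age_origin=age_range[0])
            else:
                spec = TrajectorySpec(
                    "nonlinear", base, shape="sigmoid", noise_sd=noise_sd,
                    shape_params={"amplitude": amplitude, "width": width,
                                  "inflection": float(rng.uniform(9.0, 20.0))},
                )
            mu = spec.mean_curve(ages)
            rows.append(np.clip(mu + rng.normal(0, noise_sd, n_samples), CLIP_LO, CLIP_HI))
            site_ids.append(f"bench{i:04d}")
            labels.append(klass)
            i += 1
    beta = BetaMatrix(site_ids, [f"S{j:03d}" for j in range(n_samples)], np.asarray(rows))
    return ages, beta, pd.Series(labels, index=site_ids, name="true_class")


# ---------------------------------------------------------------------------
# Annotation / peaks / gene sets with planted enrichment
# ---------------------------------------------------------------------------

def simulate_annotation(
    truth: pd.DataFrame,
    n_genes: int = 200,
    n_cell_types: int = 3,
    geneset_sizes: tuple[int, ...] = (30,),
    enrichment_factor: float = 1.0,
    base_peak_prob: float = 0.10,
    base_geneset_odds_factor: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[PeakSet], list[GeneSet]]:
    """Simulate probe annotation, peak sets and gene sets linked to a truth table.

    Sites are laid out on two synthetic chromosomes as a mixture of clustered
    runs (consecutive gaps <= 150 bp, so <=500 bp region candidates exist) and
    isolated sites.  Peak membership for each cell type is Bernoulli with the
    odds multiplied by ``enrichment_factor`` for true-DMP sites, so the planted
    log-odds equals ``log(enrichment_factor)`` exactly.  Gene-set membership is
    biased the same way for genes containing a true-DMP site.
    """
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be > 0")
    rng = np.random.default_rng(seed)
    n_sites = len(truth)
    site_ids = truth["site_id"].tolist()
    is_dmp = truth["is_dmp"].to_numpy(bool)

    chromosomes, positions = _layout_positions(n_sites, rng)
    genes = [f"GENE{g:04d}" for g in range(n_genes)]
    # contiguous sites share genes: assign gene ids in blocks along the layout
    gene_of_site = np.minimum((np.arange(n_sites) * n_genes) // max(n_sites, 1), n_genes - 1)
    gene_symbols = [[genes[g]] for g in gene_of_site]

    annot = pd.DataFrame(
        {
            "site_id": site_ids,
            "chromosome": chromosomes,
            "position": positions,
            "gene_symbols": gene_symbols,
            "cgi_class": rng.choice(CGI_CLASSES, size=n_sites,
                                    p=[0.25, 0.1, 0.1, 0.05, 0.05, 0.45]),
            "genic_class": rng.choice(GENIC_CLASSES, size=n_sites,
                                      p=[0.1, 0.08, 0.07, 0.35, 0.05, 0.35]),
            "probe_type": "cg",
        }
    )
    annot = annot.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    order = annot["site_id"].map({s: i for i, s in enumerate(site_ids)}).to_numpy()
    is_dmp = is_dmp[order]
    positions = annot["position"].to_numpy()
    chromosomes = annot["chromosome"].to_numpy()

    base_odds = base_peak_prob / (1.0 - base_peak_prob)
    peak_sets = []
    for ct in range(n_cell_types):
        odds = base_odds * np.where(is_dmp, enrichment_factor, 1.0)
        prob = odds / (1.0 + odds)
        member = rng.random(n_sites) < prob
        # one minimal interval per member site: covers exactly that position
        intervals = [
            (chromosomes[i], int(positions[i]) - 1, int(positions[i]))
            for i in np.flatnonzero(member)
        ]
        peak_sets.append(PeakSet(f"celltype{ct + 1}", intervals))

    dmp_genes = set(annot.loc[is_dmp, "gene_symbols"].str[0])
    factor = enrichment_factor if base_geneset_odds_factor is None else base_geneset_odds_factor
    gene_sets = []
    for k, size in enumerate(geneset_sizes):
        w = np.array([factor if g in dmp_genes else 1.0 for g in genes])
        pick = rng.choice(genes, size=min(size, n_genes), replace=False, p=w / w.sum())
        gene_sets.append(GeneSet(f"SET{k + 1}", list(pick)))

    return annot, peak_sets, gene_sets


def _layout_positions(n_sites: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two chromosomes; mixture of tight runs (gaps 50-150 bp) and isolated sites."""
    chroms, pos = [], []
    half = (n_sites + 1) // 2
    for chrom, count in (("chr1", half), ("chr2", n_sites - half)):
        p = 10_000
        placed = 0
        while placed < count:
            if rng.random() < 0.4:
                run = int(min(rng.integers(3, 7), count - placed))
            else:
                run = 1
            for _ in range(run):
                chroms.append(chrom)
                pos.append(p)
                p += int(rng.integers(50, 151))
                placed += 1
            p += int(rng.integers(5_000, 50_000))
    return np.array(chroms), np.array(pos)


# ---------------------------------------------------------------------------
# Cell mixtures for deconvolution
# ---------------------------------------------------------------------------

def simulate_reference_profiles(
    n_cell_types: int = 4,
    n_sites: int = 500,
    n_distinct: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type mean methylation profiles (cell types x sites in [0.05, 0.95]).

    A subset of ``n_distinct`` sites per cell type is pushed toward 0 or 1 to
    make the types separable, mimicking cell-type-specific methylation marks.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, size=n_sites)
    profiles = np.tile(base, (n_cell_types, 1))
    for ct in range(n_cell_types):
        marks = rng.choice(n_sites, size=min(n_distinct, n_sites), replace=False)
        profiles[ct, marks] = rng.choice([0.05, 0.95], size=marks.size)
    sites = [f"site{i:06d}" for i in range(n_sites)]
    return pd.DataFrame(profiles, index=[f"CT{c + 1}" for c in range(n_cell_types)],
                        columns=sites)


def simulate_purified_samples(
    profiles: pd.DataFrame, n_per_type: int = 5, noise_sd: float = 0.02, seed: int = 0
) -> tuple[BetaMatrix, pd.Series]:
    """Noisy purified samples drawn around each cell-type profile."""
    rng = np.random.default_rng(seed)
    cols, labels, mats = [], [], []
    for ct in profiles.index:
        for r in range(n_per_type):
            cols.append(f"{ct}_rep{r + 1}")
            labels.append(ct)
            v = np.clip(profiles.loc[ct].to_numpy() + rng.normal(0, noise_sd, profiles.shape[1]),
                        CLIP_LO, CLIP_HI)
            mats.append(v)
    beta = BetaMatrix(list(profiles.columns), cols, np.column_stack(mats))
    return beta, pd.Series(labels, index=cols, name="cell_type")


def simulate_mixtures(
    profiles: pd.DataFrame,
    n_mixtures: int = 100,
    dirichlet_alpha: float | np.ndarray = 1.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Bulk mixtures of reference profiles with Dirichlet proportions.

    ``profiles`` is cell types x sites in [0, 1].  Each mixture is
    ``proportions . profiles + Gaussian noise``, clipped to [0.001, 0.999].
    Returns the mixture BetaMatrix (sites x mixtures) and the true proportions
    (mixtures x cell types).
    """
    vals = profiles.to_numpy(float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("reference profile values must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = profiles.shape[0]
    alpha = np.full(k, dirichlet_alpha, float) if np.isscalar(dirichlet_alpha) else np.asarray(dirichlet_alpha, float)
    props = rng.dirichlet(alpha, size=n_mixtures)
    mix = props @ vals
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, size=mix.shape)
    mix = np.clip(mix, CLIP_LO, CLIP_HI)
    sample_ids = [f"mix{i:03d}" for i in range(n_mixtures)]
    beta = BetaMatrix(list(profiles.columns), sample_ids, mix.T)
    truth = pd.DataFrame(props, index=sample_ids, columns=profiles.index)
    return beta, truth
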