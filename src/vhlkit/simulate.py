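"""Forward simulators with known ground truth for every analysis layer.

Three generators mirror the three input shapes of the toolkit:

* :func:`simulate_tumor_cohort` — bulk tumor/normal admixture.  Each sample
  draws a purity and ploidy, composes tumor subclones (copy losses and
  mutations) into a locus copy number ``CN_t`` and tumor allele fraction
  ``AF_true``, then emits the bulk observables through the admixture model

      CNR_obs = log2((PT*CN_t + 2(1-PT)) / (PT*PL + 2(1-PT))) + eps_cnr
      VAF_obs = AF_true * PT*CN_t / (PT*CN_t + 2(1-PT)) + eps_vaf

  (noise additive Gaussian on CNR, truncated to [0,1] on VAF; optional
  binomial read-depth sampling for VAF).  With zero noise the purity/ploidy
  adjustment is the exact algebraic inverse — the central recovery property.

* :func:`simulate_concordance_study` — k differential-expression comparisons
  with a planted subset of features carrying a fixed signed effect.

* :func:`simulate_tissue` — inhomogeneous Poisson point patterns of
  marker-labeled cells, with per-phenotype intensity a function of signed
  distance to a known region geometry (sampled by thinning).

Every generator is deterministic given its seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Callable

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .genomic import expected_cnr, expected_vaf
from .spatial import RegionBoundary, signed_distance_to_boundary


# ---------------------------------------------------------------------------
# Tumor cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneSpec:
    """One tumor subclone: its cell fraction, copies lost at the locus
    (0/1/2 of the diploid pair), and mutant copy count if it carries the
    mutation."""
    fraction: float
    copies_lost: int = 0
    mutation_present: bool = False
    mutant_copies: int = 0

    @property
    def copies(self) -> int:
        return 2 - self.copies_lost


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated bulk cohort at a single locus.

    Defaults describe the canonical adjusted-cohort scenario: purities
    Beta(2,2) rescaled to [0.3, 0.9], near-diploid ploidies, and one clone
    carrying a clonal one-copy VHL loss with a mutation on the remaining
    copy.  Noise SDs are on the observed scales (log2 ratio / allele
    fraction).
    """
    n_samples: int = 459
    gene: str = "VHL"
    purity_alpha: float = 2.0
    purity_beta: float = 2.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    ploidy_mean: float = 2.0
    ploidy_sd: float = 0.2
    ploidy_range: tuple[float, float] = (1.5, 4.0)
    clone_architecture: tuple[CloneSpec, ...] = (
        CloneSpec(fraction=1.0, copies_lost=1, mutation_present=True, mutant_copies=1),
    )
    cnr_noise_sd: float = 0.15
    vaf_noise_sd: float = 0.05
    purity_obs_sd: float = 0.03
    read_depth: int | None = None
    seed: int = 0

    def validate(self) -> None:
        fr = np.array([c.fraction for c in self.clone_architecture])
        if not np.isclose(fr.sum(), 1.0):
            raise ValueError("clone fractions must sum to 1")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("clone fractions must lie in [0, 1]")
        cn_t = sum(c.fraction * c.copies for c in self.clone_architecture)
        for c in self.clone_architecture:
            if c.copies_lost not in (0, 1, 2):
                raise ValueError("copies_lost must be 0, 1 or 2")
            if c.mutation_present and c.mutant_copies > c.copies:
                raise ValueError("mutant_copies cannot exceed per-clone gene copies")
            if c.mutation_present and cn_t == 0:
                raise ValueError("mutation planted on a locus with CN_t = 0")

    @property
    def cn_t_true(self) -> float:
        return float(sum(c.fraction * c.copies for c in self.clone_architecture))

    @property
    def af_true(self) -> float:
        mutant = sum(c.fraction * c.mutant_copies
                     for c in self.clone_architecture if c.mutation_present)
        return float(mutant / self.cn_t_true) if self.cn_t_true > 0 else 0.0


def _draw_purity_ploidy(spec: CohortSpec, rng: np.random.Generator, n: int):
    lo, hi = spec.purity_range
    pt = lo + (hi - lo) * rng.beta(spec.purity_alpha, spec.purity_beta, size=n)
    pl = np.clip(rng.normal(spec.ploidy_mean, spec.ploidy_sd, size=n),
                 *spec.ploidy_range)
    return pt, pl


def simulate_tumor_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (purity table, copy-number table, variant table, truth table).

    The truth table records per-sample PT, PL, CN_t and AF_true.  The purity
    table carries a consensus column equal to the true purity and ABSOLUTE /
    ESTIMATE method columns scattered around it by ``purity_obs_sd``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    pt, pl = _draw_purity_ploidy(spec, rng, n)
    cn_t = np.full(n, spec.cn_t_true)
    af_true = np.full(n, spec.af_true)

    cnr_obs = expected_cnr(cn_t, pt, pl) + rng.normal(0, spec.cnr_noise_sd, n) \
        if spec.cnr_noise_sd else expected_cnr(cn_t, pt, pl)
    vaf_clean = expected_vaf(af_true, pt, cn_t)
    if spec.read_depth:
        vaf_obs = rng.binomial(spec.read_depth, np.clip(vaf_clean, 0, 1)) / spec.read_depth
    elif spec.vaf_noise_sd:
        vaf_obs = np.clip(vaf_clean + rng.normal(0, spec.vaf_noise_sd, n), 0.0, 1.0)
    else:
        vaf_obs = vaf_clean

    purity = pd.DataFrame({
        "sample_id": sample_ids,
        "purity_absolute": np.clip(pt + rng.normal(0, spec.purity_obs_sd, n), 0, 1),
        "purity_estimate_method": np.clip(pt + rng.normal(0, spec.purity_obs_sd, n), 0, 1),
        "purity_consensus": pt,
        "ploidy": pl,
    })
    cn = pd.DataFrame({"sample_id": sample_ids, "gene": spec.gene,
                       "cnr_observed": cnr_obs})
    has_mut = any(c.mutation_present for c in spec.clone_architecture)
    variants = pd.DataFrame({
        "sample_id": sample_ids, "gene": spec.gene,
        "vaf_observed": vaf_obs,
        "in_cosmic": True, "vep_impact": "MODERATE",
    }) if has_mut else pd.DataFrame(
        columns=["sample_id", "gene", "vaf_observed", "in_cosmic", "vep_impact"])
    truth = pd.DataFrame({
        "sample_id": sample_ids, "purity": pt, "ploidy": pl,
        "cn_t": cn_t, "af_true": af_true,
    })
    return purity, cn, variants, truth


def simulate_filter_cohort(
    n_samples: int = 500,
    n_low_purity: int = 37,
    n_disagreement: int = 12,
    n_incompatible_vaf: int = 5,
    seed: int = 0,
    gene: str = "VHL",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort with planted filter violations for exact bookkeeping checks.

    Disjoint sample groups are planted to fail the low-purity, the
    ABSOLUTE/ESTIMATE-disagreement, and the AF_adj-incompatibility filters;
    all other samples pass every filter.  Observation noise is zero so the
    removal counts are exact.  The truth table labels each sample's planted
    violation ("none" otherwise).
    """
    if n_low_purity + n_disagreement + n_incompatible_vaf > n_samples:
        raise ValueError("planted groups exceed cohort size")
    rng = np.random.default_rng(seed)
    base = CohortSpec(
        n_samples=n_samples, gene=gene,
        purity_range=(0.45, 0.9),
        cnr_noise_sd=0.0, vaf_noise_sd=0.0, purity_obs_sd=0.0, seed=seed,
    )
    purity, cn, variants, truth = simulate_tumor_cohort(base)
    planted = np.full(n_samples, "none", dtype=object)
    idx = rng.permutation(n_samples)
    g_low = idx[:n_low_purity]
    g_dis = idx[n_low_purity:n_low_purity + n_disagreement]
    g_inc = idx[n_low_purity + n_disagreement:
                n_low_purity + n_disagreement + n_incompatible_vaf]

    # low purity: consensus strictly below the 0.4 gate
    low_pt = rng.uniform(0.1, 0.38, size=n_low_purity)
    for col in ("purity_consensus", "purity_absolute", "purity_estimate_method"):
        purity.loc[g_low, col] = low_pt
    planted[g_low] = "low_purity"

    # disagreement: |ABSOLUTE - ESTIMATE| strictly above the 0.3 gate
    diff = rng.uniform(0.32, 0.5, size=n_disagreement)
    pa = purity.loc[g_dis, "purity_consensus"].to_numpy()
    purity.loc[g_dis, "purity_absolute"] = np.clip(pa, 0, 1)
    purity.loc[g_dis, "purity_estimate_method"] = np.clip(pa - diff, 0, 1)
    planted[g_dis] = "disagreement"

    # incompatible: observed VAF engineered so raw AF_adj lands above 1.1
    pt = purity.loc[g_inc, "purity_consensus"].to_numpy()
    cn_t = truth.loc[g_inc, "cn_t"].to_numpy()
    target_raw = rng.uniform(1.15, 1.3, size=n_incompatible_vaf)
    bad_vaf = target_raw * pt * cn_t / (pt * cn_t + 2 * (1 - pt))
    variants.loc[g_inc, "vaf_observed"] = np.clip(bad_vaf, 0, 1)
    planted[g_inc] = "incompatible_vaf"

    truth = truth.assign(planted=planted)
    return purity, cn, variants, truth


# ---------------------------------------------------------------------------
# Concordance study
# ---------------------------------------------------------------------------

def _default_p_model(log2fc: np.ndarray, noise_sd: float) -> np.ndarray:
    """Two-sided normal tail p-value for |log2fc| measured in noise SD units."""
    from scipy.stats import norm
    z = np.abs(log2fc) / noise_sd
    return np.clip(2 * norm.sf(z), 1e-300, 1.0)


def simulate_concordance_study(
    n_features: int = 10000,
    k: int = 3,
    n_planted: int = 200,
    effect: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 1,
    p_model: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """k comparison tables with a planted concordant feature subset.

    Planted features carry a fixed signed effect (random sign, constant
    across comparisons) plus iid N(0, noise_sd); null features are pure
    noise.  Returns ``(tables, truth)`` where truth lists planted ids and
    their effects.
    """
    if n_planted > n_features:
        raise ValueError("n_planted cannot exceed n_features")
    rng = np.random.default_rng(seed)
    ids = np.array([f"G{i:05d}" for i in range(n_features)])
    planted_idx = rng.choice(n_features, size=n_planted, replace=False)
    effects = np.zeros(n_features)
    effects[planted_idx] = effect * rng.choice([-1.0, 1.0], size=n_planted)
    p_model = p_model or _default_p_model
    tables = {}
    for j in range(k):
        lfc = effects + rng.normal(0, noise_sd, size=n_features)
        tables[f"comparison_{j + 1}"] = pd.DataFrame({
            "feature_id": ids, "log2fc": lfc,
            "p_value": p_model(lfc, noise_sd),
        })
    truth = pd.DataFrame({
        "feature_id": ids, "planted": effects != 0, "effect": effects,
    })
    return tables, truth


# ---------------------------------------------------------------------------
# Tissue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypePattern:
    """One cell phenotype: marker values and an intensity field.

    ``intensity`` maps signed distance to the region boundary (µm, negative
    inside) to an expected cell density in cells/µm²; ``lambda_max`` must
    dominate it over the window (thinning envelope).
    """
    markers: dict[str, bool]
    intensity: Callable[[np.ndarray], np.ndarray]
    lambda_max: float


def uniform_inside(lam_in: float, lam_out: float = 0.0) -> Callable:
    """Intensity: lam_in inside the region (d <= 0), lam_out outside."""
    def f(d):
        return np.where(np.asarray(d) <= 0, lam_in, lam_out)
    return f


def exponential_decay_outside(lam0: float, tau: float, lam_in: float = 0.0) -> Callable:
    """Intensity: lam_in inside; lam0 * exp(-d/tau) outside (infiltration gradient)."""
    def f(d):
        d = np.asarray(d, dtype=float)
        return np.where(d <= 0, lam_in, lam0 * np.exp(-d / tau))
    return f


def disc(cx: float, cy: float, radius: float, n_vertices: int = 256) -> Polygon:
    """Polygonal disc (region geometry helper)."""
    return Point(cx, cy).buffer(radius, quad_segs=max(n_vertices // 4, 8))


@dataclass(frozen=True)
class TissueSpec:
    """Study conditions for a simulated two-region tissue.

    ``window`` is (xmin, ymin, xmax, ymax) in µm; ``region`` the true
    marker-positive geometry; ``phenotypes`` the point processes to sample.
    """
    window: tuple[float, float, float, float]
    region: Polygon
    phenotypes: tuple[PhenotypePattern, ...]
    seed: int = 0


def simulate_tissue(spec: TissueSpec, seed: int | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Sample marker-labeled cells from inhomogeneous Poisson processes.

    Each phenotype is sampled by thinning a homogeneous Poisson process at
    ``lambda_max`` over the window, keeping each candidate with probability
    intensity(d)/lambda_max where d is its signed distance to the true region
    boundary.  Returns the cell table (x_um, y_um, one boolean column per
    marker) and a truth dict (region WKT, per-phenotype expected parameters).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x0, y0, x1, y1 = spec.window
    area = (x1 - x0) * (y1 - y0)
    boundary = RegionBoundary.from_geometry(spec.region)
    all_markers = sorted({m for ph in spec.phenotypes for m in ph.markers})
    frames = []
    for ph in spec.phenotypes:
        n_cand = rng.poisson(ph.lambda_max * area)
        xs = rng.uniform(x0, x1, size=n_cand)
        ys = rng.uniform(y0, y1, size=n_cand)
        d = signed_distance_to_boundary(np.column_stack([xs, ys]), boundary)
        accept = rng.uniform(size=n_cand) < ph.intensity(d) / ph.lambda_max
        df = pd.DataFrame({"x_um": xs[accept], "y_um": ys[accept]})
        for m in all_markers:
            df[m] = bool(ph.markers.get(m, False))
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    truth = {
        "region_wkt": spec.region.wkt,
        "region_area_um2": float(spec.region.area),
        "window": spec.window,
        "phenotypes": [
            {"markers": dict(ph.markers), "lambda_max": ph.lambda_max}
            for ph in spec.phenotypes
        ],
    }
    return cells, truth


def default_infiltration_tissue(
    tau: float = 1000.0,
    lam0: float = 2e-4,
    region_radius: float = 3000.0,
    window_half: float = 8000.0,
    region_marker: str = "VHL",
    target_marker: str = "Ki67",
    region_lambda: float = 5e-4,
    target_lambda_in: float = 2e-4,
    seed: int = 0,
) -> TissueSpec:
    """Disc-shaped marker-positive region with an exponential infiltration
    gradient of target-positive cells outside it (cells/µm² intensities)."""
    region = disc(0.0, 0.0, region_radius)
    w = window_half
    return TissueSpec(
        window=(-w, -w, w, w),
        region=region,
        phenotypes=(
            PhenotypePattern({region_marker: True, target_marker: False},
                             uniform_inside(region_lambda), region_lambda),
            PhenotypePattern({target_marker: True, region_marker: False},
                             exponential_decay_outside(lam0, tau, lam_in=target_lambda_in),
                             max(lam0, target_lambda_in)),
        ),
        seed=seed,
    )


def interface_gradient(lam_peak: float, tau: float, side: str = "inside",
                       extent: float = 2000.0) -> Callable:
    """Monotone intensity across the boundary, peaking ``extent`` µm into its side.

    ``side="inside"``: lam_peak at d <= -extent, decaying as exp(-Δd/tau)
    toward and beyond the boundary; ``side="outside"`` is the mirror image.
    Within any distance band the intensity is strictly monotone, so band
    densities of two opposite gradients have perfectly opposed ranks.
    """
    if side == "inside":
        def f(d):
            s = np.maximum(np.asarray(d, dtype=float), -extent)
            return lam_peak * np.exp(-(s + extent) / tau)
    elif side == "outside":
        def f(d):
            s = np.minimum(np.asarray(d, dtype=float), extent)
            return lam_peak * np.exp((s - extent) / tau)
    else:
        raise ValueError("side must be 'inside' or 'outside'")
    return f


def default_coexclusion_tissue(
    region_radius: float = 3000.0,
    window_half: float = 7000.0,
    lam_a: float = 4e-4,
    lam_b: float = 4e-4,
    interface_tau: float = 1000.0,
    inner_extent: float = 2000.0,
    outer_extent: float = 4000.0,
    hard: bool = False,
    seed: int = 0,
) -> TissueSpec:
    """Co-excluding phenotypes around a disc boundary (VHL+POSTN− inside,
    VHL−POSTN+ outside).

    By default each phenotype's intensity decays exponentially (scale
    ``interface_tau``) across the interface — the smooth segregation that
    real serial-section stains show, under which the two band-density curves
    are strictly monotone in opposite directions.  ``hard=True`` instead
    confines each phenotype entirely to its side (a step function); exact
    zero counts then tie large blocks of bands and cap the attainable
    midrank Spearman magnitude well below 1.
    """
    region = disc(0.0, 0.0, region_radius)
    w = window_half
    if hard:
        int_a, int_b = uniform_inside(lam_a), uniform_inside(0.0, lam_b)
    else:
        int_a = interface_gradient(lam_a, interface_tau, "inside", inner_extent)
        int_b = interface_gradient(lam_b, interface_tau, "outside", outer_extent)
    return TissueSpec(
        window=(-w, -w, w, w),
        region=region,
        phenotypes=(
            PhenotypePattern({"VHL": True, "POSTN": False}, int_a, lam_a),
            PhenotypePattern({"VHL": False, "POSTN": True}, int_b, lam_b),
        ),
        seed=seed,
    )


def uniform_tissue(
    lam_a: float = 1e-4,
    lam_b: float = 1e-4,
    region_radius: float = 3000.0,
    window_half: float = 7000.0,
    seed: int = 0,
) -> TissueSpec:
    """Both phenotypes spatially uniform (null tissue for the co-exclusion test)."""
    region = disc(0.0, 0.0, region_radius)
    w = window_half

    def flat(lam):
        return lambda d: np.full_like(np.asarray(d, dtype=float), lam)

    return TissueSpec(
        window=(-w, -w, w, w),
        region=region,
        phenotypes=(
            PhenotypePattern({"VHL": True, "POSTN": False}, flat(lam_a), lam_a),
            PhenotypePattern({"VHL": False, "POSTN": True}, flat(lam_b), lam_b),
        ),
        seed=seed,
    )
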