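"""Purity/ploidy correction of copy-number ratios and variant allele frequencies.

Bulk tumor sequencing mixes tumor cells (fraction ``PT``, the purity) with
diploid normal cells.  The observed log2 copy-number ratio (CNR) and variant
allele frequency (VAF) at a locus therefore understate the tumor-cell signal.
Assuming diploid normal contamination, the tumor copy number is

    CN_t = (2**CNR * (2*(1 - PT) + PL*PT) - 2*(1 - PT)) / PT

where ``PL`` is the tumor ploidy, the adjusted ratio is
``CNR_adj = log2(CN_t / 2)``, and the adjusted allele frequency is

    AF_adj = VAF * (PT*CN_t + 2*(1 - PT)) / (PT*CN_t)

AF_adj is interpretable as the mutant fraction of tumor-cell gene copies: a
fully clonal heterozygous mutation on a diploid locus gives AF_adj = 0.5 at
any purity.  Values slightly above 1 arise from noise and are clamped
(raw in (1, 1.1] -> 1); larger excursions mark the record as incompatible
with the model and it is removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

VARIANT_CLONALITY_CATEGORIES = ("subclonal", "likely_clonal", "clonal_with_LOH")
COPY_LOSS_CATEGORIES = ("neutral_or_gain", "one_copy_loss_range", "two_copy_loss_range")

STATUS_OK = "ok"
STATUS_REMOVED = "removed_incompatible"


# ---------------------------------------------------------------------------
# Core algebra
# ---------------------------------------------------------------------------

def tumor_copy_number(cnr_observed, purity, ploidy):
    """Tumor copy number CN_t from an observed log2 ratio, purity and ploidy.

    Raises ``ValueError`` when any purity is <= 0 (a normal-only sample has
    no tumor signal to recover) or any input is non-finite.
    """
    cnr = np.asarray(cnr_observed, dtype=float)
    pt = np.asarray(purity, dtype=float)
    pl = np.asarray(ploidy, dtype=float)
    if not (np.all(np.isfinite(cnr)) and np.all(np.isfinite(pt)) and np.all(np.isfinite(pl))):
        raise ValueError("non-finite input to tumor_copy_number")
    if np.any(pt <= 0):
        raise ValueError("purity must be > 0 (division by zero for normal-only sample)")
    return (2.0 ** cnr * (2.0 * (1.0 - pt) + pl * pt) - 2.0 * (1.0 - pt)) / pt


def adjusted_cnr(cn_t):
    """CNR_adj = log2(CN_t / 2); undefined (NaN) where CN_t <= 0."""
    cn_t = np.asarray(cn_t, dtype=float)
    out = np.full(cn_t.shape, np.nan)
    pos = cn_t > 0
    out[pos] = np.log2(cn_t[pos] / 2.0)
    return out if out.ndim else float(out)


def expected_cnr(cn_t, purity, ploidy):
    """Forward model: the log2 ratio a bulk sample would show for a given CN_t."""
    pt = np.asarray(purity, dtype=float)
    pl = np.asarray(ploidy, dtype=float)
    cn_t = np.asarray(cn_t, dtype=float)
    return np.log2((pt * cn_t + 2.0 * (1.0 - pt)) / (pt * pl + 2.0 * (1.0 - pt)))


def expected_vaf(af_true, purity, cn_t):
    """Forward model: bulk VAF produced by a tumor-cell allele fraction."""
    pt = np.asarray(purity, dtype=float)
    cn_t = np.asarray(cn_t, dtype=float)
    return np.asarray(af_true, dtype=float) * pt * cn_t / (pt * cn_t + 2.0 * (1.0 - pt))


def raw_adjusted_vaf(vaf, purity, cn_t):
    """Unclamped AF_adj. Caller handles clamping / incompatibility."""
    pt = np.asarray(purity, dtype=float)
    cn_t = np.asarray(cn_t, dtype=float)
    if np.any(pt <= 0):
        raise ValueError("purity must be > 0")
    if np.any(cn_t <= 0):
        raise ValueError("cn_t must be > 0; incompatible records must be removed upstream")
    return np.asarray(vaf, dtype=float) * (pt * cn_t + 2.0 * (1.0 - pt)) / (pt * cn_t)


# ---------------------------------------------------------------------------
# Sample filtering
# ---------------------------------------------------------------------------

def consensus_purity_filter(
    purity: pd.DataFrame,
    min_purity: float = 0.4,
    max_disagreement: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep samples with complete, internally consistent purity estimates.

    A sample is kept iff its consensus purity is strictly greater than
    ``min_purity`` and, when both ABSOLUTE and ESTIMATE values are present,
    they differ by strictly less than ``max_disagreement``.  Samples missing
    the consensus value (or ploidy, when the column exists) are removed as
    incomplete.

    Returns ``(kept, removed)``; ``removed`` carries a ``reason`` column with
    values ``incomplete`` / ``low_purity`` / ``disagreement``.
    """
    df = purity.copy()
    if "purity_consensus" not in df.columns:
        raise ValueError("purity table must have a purity_consensus column")
    for col in ("purity_consensus", "purity_absolute", "purity_estimate_method"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            bad = np.isinf(vals) | ((~np.isnan(vals)) & ((vals < 0) | (vals > 1)))
            if bad.any():
                raise ValueError(f"non-finite or out-of-range values in {col}")
    if "ploidy" in df.columns:
        pl = df["ploidy"].to_numpy(dtype=float)
        if np.any(np.isinf(pl)) or np.any(pl[~np.isnan(pl)] <= 0):
            raise ValueError("ploidy must be finite and > 0")

    reason = np.full(len(df), "", dtype=object)
    consensus = df["purity_consensus"].to_numpy(dtype=float)
    incomplete = np.isnan(consensus)
    if "ploidy" in df.columns:
        incomplete |= df["ploidy"].isna().to_numpy()
    reason[incomplete] = "incomplete"

    low = (~incomplete) & ~(consensus > min_purity)
    reason[low] = "low_purity"

    if {"purity_absolute", "purity_estimate_method"} <= set(df.columns):
        pa = df["purity_absolute"].to_numpy(dtype=float)
        pe = df["purity_estimate_method"].to_numpy(dtype=float)
        both = ~np.isnan(pa) & ~np.isnan(pe)
        disagree = both & ~(np.abs(pa - pe) < max_disagreement)
        reason[(reason == "") & disagree] = "disagreement"

    removed = df[reason != ""].copy()
    removed["reason"] = reason[reason != ""]
    kept = df[reason == ""].copy()
    logger.info("purity filter kept %d / %d samples", len(kept), len(df))
    return kept, removed


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_variant_clonality(af_adj, likely_clonal_threshold: float = 0.4,
                               loh_threshold: float = 0.9):
    """Clonality category of an adjusted allele frequency.

    Strictly above ``loh_threshold`` -> clonal mutation with loss of
    heterozygosity; strictly above ``likely_clonal_threshold`` -> likely
    clonal; otherwise subclonal.  Equality at a threshold falls in the lower
    category.
    """
    af = np.asarray(af_adj, dtype=float)
    if np.any(~np.isfinite(af)) or np.any(af < 0) or np.any(af > 1):
        raise ValueError("af_adj must lie in [0, 1]")
    out = np.select(
        [af > loh_threshold, af > likely_clonal_threshold],
        ["clonal_with_LOH", "likely_clonal"],
        default="subclonal",
    )
    return out if out.ndim else str(out)


def classify_copy_loss(cnr_adj, two_copy_line: float = -1.1, one_copy_line: float = -0.4):
    """Copy-loss category of an adjusted CNR relative to empirical reference lines.

    The default lines (-1.1 two-copy, -0.4 one-copy) are the conventional
    display references for VHL loss on adjusted-cohort density plots; they
    are configurable empirical values, not derived quantities.
    """
    cnr = np.asarray(cnr_adj, dtype=float)
    if np.any(~np.isfinite(cnr)):
        raise ValueError("cnr_adj must be finite")
    out = np.select(
        [cnr <= two_copy_line, cnr <= one_copy_line],
        ["two_copy_loss_range", "one_copy_loss_range"],
        default="neutral_or_gain",
    )
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# Variant annotation filter
# ---------------------------------------------------------------------------

_DAMAGING_IMPACTS = frozenset({"MODERATE", "HIGH"})


def filter_annotated_variants(
    variants: pd.DataFrame,
    min_vaf: float = 0.1,
    return_dropped: bool = False,
):
    """Keep COSMIC-listed variants with VEP impact above LOW and VAF > ``min_vaf``.

    A missing annotation field fails the corresponding filter (conservative
    drop); drop reasons are logged and optionally returned.
    """
    cosmic = variants.get("in_cosmic")
    cosmic_ok = (
        cosmic.astype("boolean").fillna(False).to_numpy(dtype=bool)
        if cosmic is not None else np.zeros(len(variants), bool)
    )
    impact = variants.get("vep_impact")
    impact_ok = (
        impact.astype("string").str.upper().isin(_DAMAGING_IMPACTS).fillna(False).to_numpy()
        if impact is not None else np.zeros(len(variants), bool)
    )
    vaf_ok = (variants["vaf_observed"].to_numpy(dtype=float) > min_vaf)

    keep = cosmic_ok & impact_ok & vaf_ok
    if not keep.all():
        n = len(variants)
        logger.info(
            "variant filter dropped %d/%d (not in COSMIC: %d, impact<=LOW/missing: %d, VAF<=%g: %d)",
            int((~keep).sum()), n, int((~cosmic_ok).sum()), int((~impact_ok).sum()),
            min_vaf, int((~vaf_ok).sum()),
        )
    kept = variants[keep].copy()
    if return_dropped:
        dropped = variants[~keep].copy()
        reasons = []
        for c, i, v in zip(cosmic_ok[~keep], impact_ok[~keep], vaf_ok[~keep]):
            rs = []
            if not c:
                rs.append("not_in_cosmic")
            if not i:
                rs.append("low_impact")
            if not v:
                rs.append("low_vaf")
            reasons.append(";".join(rs))
        dropped["reason"] = reasons
        return kept, dropped
    return kept


# ---------------------------------------------------------------------------
# Coding-change annotation
# ---------------------------------------------------------------------------

def coding_change_to_protein(
    cds_position: int,
    ref_base: str,
    alt_base: str,
    reference_codon: str,
) -> tuple[int, str]:
    """Map a coding single-nucleotide change to a protein substitution label.

    CDS positions are 1-based: the affected codon is ``ceil(pos / 3)`` and the
    within-codon offset ``((pos - 1) mod 3)``.  Returns ``(codon_index,
    label)`` with labels like ``"L169P"`` (or ``"L2="`` for a synonymous
    change) under the standard genetic code.
    """
    cds_position = int(cds_position)
    if cds_position < 1:
        raise ValueError("cds_position must be a positive 1-based coordinate")
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    codon = reference_codon.upper()
    if len(codon) != 3:
        raise ValueError("reference_codon must be a 3-mer")
    codon_index = (cds_position + 2) // 3
    offset = (cds_position - 1) % 3
    if codon[offset] != ref_base:
        raise ValueError(
            f"reference codon {codon} has {codon[offset]} at CDS position "
            f"{cds_position}, not {ref_base}: coordinate inconsistency"
        )
    alt_codon = codon[:offset] + alt_base + codon[offset + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    label = f"{aa_ref}{codon_index}=" if aa_alt == aa_ref else f"{aa_ref}{codon_index}{aa_alt}"
    return codon_index, label


# ---------------------------------------------------------------------------
# Density summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityCurve:
    x: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def peak(self) -> float:
        """Location of the grid maximum."""
        return float(self.x[int(np.argmax(self.density))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "density": self.density})


def silverman_bandwidth(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * len(v) ** (-1 / 5)


def cohort_density(
    values: Sequence[float],
    bandwidth: float | None = None,
    grid_size: int = 512,
    tail_factor: float = 3.0,
) -> DensityCurve:
    """Gaussian kernel density of a cohort of values on an even grid.

    The grid spans the data range extended by ``tail_factor`` bandwidths on
    each side; the default bandwidth is Silverman's rule.  The curve
    integrates to 1 (trapezoid rule) up to the mass truncated beyond the
    grid ends.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("cohort_density requires at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError(
            "bandwidth must be positive; give an explicit bandwidth for degenerate data"
        )
    grid = np.linspace(v.min() - tail_factor * h, v.max() + tail_factor * h, grid_size)
    # Gaussian mixture over the observations; explicit form keeps zero-variance
    # inputs (all values identical) well defined under a fixed bandwidth.
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(x=grid, density=dens, bandwidth=h)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PurityPloidyAdjuster(BaseEstimator):
    """Purity/ploidy adjustment of per-gene copy-number and variant tables.

    ``fit`` takes the per-sample purity/ploidy table, applies the cohort
    filters, and stores the usable samples; ``adjust_copy_number`` and
    ``adjust_variants`` then transform observation tables into adjusted
    records with clonality calls.

    Parameters
    ----------
    min_purity : consensus purity must be strictly greater than this.
    max_disagreement : |ABSOLUTE − ESTIMATE| must be strictly less than this
        (checked only when both are present).
    clamp_low, clamp_high : raw AF_adj in (clamp_low, clamp_high] is set to
        clamp_low; above clamp_high the record is removed as incompatible.
    purity_source : purity column feeding the equations, "consensus" or
        "absolute".
    default_cn_t : CN_t assumed for variants whose gene has no copy-number
        record (copy-neutral fallback, flagged in the output).
    """

    def __init__(
        self,
        min_purity: float = 0.4,
        max_disagreement: float = 0.3,
        clamp_low: float = 1.0,
        clamp_high: float = 1.1,
        purity_source: str = "consensus",
        default_cn_t: float = 2.0,
    ):
        self.min_purity = min_purity
        self.max_disagreement = max_disagreement
        self.clamp_low = clamp_low
        self.clamp_high = clamp_high
        self.purity_source = purity_source
        self.default_cn_t = default_cn_t

    # -- fitting ------------------------------------------------------------
    def fit(self, purity: pd.DataFrame, y=None):
        if self.purity_source not in ("consensus", "absolute"):
            raise ValueError("purity_source must be 'consensus' or 'absolute'")
        kept, removed = consensus_purity_filter(
            purity, min_purity=self.min_purity, max_disagreement=self.max_disagreement
        )
        col = "purity_consensus" if self.purity_source == "consensus" else "purity_absolute"
        kept = kept.dropna(subset=[col])
        self.purity_column_ = col
        self.samples_ = kept.set_index("sample_id")
        self.removed_samples_ = removed
        return self

    def _sample_params(self, sample_ids: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        known = sample_ids.isin(self.samples_.index).to_numpy()
        pt = np.full(len(sample_ids), np.nan)
        pl = np.full(len(sample_ids), np.nan)
        sub = self.samples_.loc[sample_ids[known]]
        pt[known] = sub[self.purity_column_].to_numpy(dtype=float)
        pl[known] = sub["ploidy"].to_numpy(dtype=float)
        return known, pt, pl

    # -- copy number --------------------------------------------------------
    def adjust_copy_number(self, cn: pd.DataFrame) -> pd.DataFrame:
        """Adjusted records for a (sample_id, gene, cnr_observed) table.

        Rows for samples that failed the purity filter are dropped.  CN_t <= 0
        (the observed ratio is below what pure normal contamination could
        produce) marks the record ``removed_incompatible``.
        """
        self._check_fitted()
        cn = cn.copy()
        known, pt, pl = self._sample_params(cn["sample_id"])
        if not known.all():
            logger.info("dropping %d copy-number rows from filtered-out samples",
                        int((~known).sum()))
        cn, pt, pl = cn[known].reset_index(drop=True), pt[known], pl[known]
        cn_t = tumor_copy_number(cn["cnr_observed"].to_numpy(dtype=float), pt, pl)
        out = cn
        out["purity"] = pt
        out["ploidy"] = pl
        out["cn_t"] = cn_t
        out["cnr_adj"] = adjusted_cnr(cn_t)
        incompatible = ~(cn_t > 0)
        out["status"] = np.where(incompatible, STATUS_REMOVED, STATUS_OK)
        out["reason"] = np.where(incompatible, "nonpositive_cn_t", "")
        ok = out["status"] == STATUS_OK
        out["copy_loss_call"] = ""
        out.loc[ok, "copy_loss_call"] = classify_copy_loss(out.loc[ok, "cnr_adj"].to_numpy())
        return out

    # -- variants -----------------------------------------------------------
    def adjust_variants(
        self, variants: pd.DataFrame, cn_adjusted: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Adjusted allele frequencies with clamp/incompatibility status.

        ``cn_adjusted`` (output of :meth:`adjust_copy_number`) supplies the
        per-sample-per-gene CN_t; rows without a usable CN_t fall back to
        ``default_cn_t`` with ``cn_t_source="default"``.
        """
        self._check_fitted()
        variants = variants.copy()
        known, pt, _pl = self._sample_params(variants["sample_id"])
        if not known.all():
            logger.info("dropping %d variant rows from filtered-out samples",
                        int((~known).sum()))
        variants, pt = variants[known].reset_index(drop=True), pt[known]

        cn_t = np.full(len(variants), float(self.default_cn_t))
        source = np.full(len(variants), "default", dtype=object)
        if cn_adjusted is not None:
            usable = cn_adjusted[cn_adjusted["status"] == STATUS_OK]
            lut = usable.set_index(["sample_id", "gene"])["cn_t"]
            keys = pd.MultiIndex.from_frame(variants[["sample_id", "gene"]])
            hit = keys.isin(lut.index)
            cn_t[hit] = lut.loc[keys[hit]].to_numpy(dtype=float)
            source[hit] = "copy_number_table"

        raw = raw_adjusted_vaf(variants["vaf_observed"].to_numpy(dtype=float), pt, cn_t)
        clamped = (raw > self.clamp_low) & (raw <= self.clamp_high)
        incompatible = raw > self.clamp_high
        af_adj = np.where(clamped, self.clamp_low, raw)
        af_adj = np.where(incompatible, np.nan, af_adj)

        out = variants
        out["purity"] = pt
        out["cn_t"] = cn_t
        out["cn_t_source"] = source
        out["af_adj_raw"] = raw
        out["af_adj"] = af_adj
        out["clamped"] = clamped
        out["status"] = np.where(incompatible, STATUS_REMOVED, STATUS_OK)
        out["reason"] = np.where(incompatible, "af_adj_above_clamp", "")
        ok = out["status"] == STATUS_OK
        out["clonality_call"] = ""
        out.loc[ok, "clonality_call"] = classify_variant_clonality(
            out.loc[ok, "af_adj"].to_numpy()
        )
        return out

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("PurityPloidyAdjuster must be fitted with a purity table first")


def adjust_copy_number(cn: pd.DataFrame, purity: pd.DataFrame, **params) -> pd.DataFrame:
    """Functional wrapper: filter samples and adjust a copy-number table."""
    return PurityPloidyAdjuster(**params).fit(purity).adjust_copy_number(cn)


def adjust_vaf(variants: pd.DataFrame, purity: pd.DataFrame,
               cn_adjusted: pd.DataFrame | None = None, **params) -> pd.DataFrame:
    """Functional wrapper: filter samples and adjust a variant table."""
    return PurityPloidyAdjuster(**params).fit(purity).adjust_variants(variants, cn_adjusted)
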