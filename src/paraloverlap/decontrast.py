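"""Negative-binomial GLM differential expression with the combined contrast.

The model is a six-condition cell-means NB GLM with a log link and a
log(size-factor) offset:

    y_gs ~ NB(mean = sf_s · q_g,cond(s),  dispersion α_g)

fitted jointly across all conditions with one shared size-factor set.  The
effect of a factor is the combined contrast

    log2FC_g = (β_TF-OE − β_ctrl-OE) − (β_TF-KO − β_ctrl-KO)

which adds concordant OE/KO signal and cancels responses shared between a
targeting condition and its matched non-targeting control (CRISPR-system
stress).  Inference is a two-sided Wald test against the normal reference,
with Benjamini–Hochberg adjustment; DEGs are called at strict thresholds
padj < alpha and |log2FC| > min_abs_log2fc.

Normalization is median-of-ratios; dispersions are method-of-moments
estimates pooled within conditions and shrunk toward the trend
α(μ) = a0 + a1/μ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from paraloverlap.data import CONDITIONS, CountMatrix, contrast_weights

LN2 = float(np.log(2.0))
ALPHA_FLOOR = 1e-8
INFO_RIDGE = 1e-8  # ridge on the information matrix for empty conditions


@dataclass
class ContrastSpec:
    """Combined OE/KO contrast for one paralog."""

    tf_label: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = contrast_weights(self.tf_label)
        nz = [w for w in self.weights.values() if w != 0]
        if len(nz) != 4 or abs(sum(nz)) > 1e-12:
            raise ValueError("contrast must have exactly four non-zero weights summing to 0")


@dataclass
class NBFit:
    """Cell-means fit: per-gene per-condition log2 means and variances."""

    coef_log2: pd.DataFrame  # genes × conditions
    var_log2: pd.DataFrame  # genes × conditions (block-diagonal covariance)
    base_mean: pd.Series  # mean of normalized counts
    dispersion: pd.Series


@dataclass
class DEGSet:
    """Up/down-regulated gene sets for one factor."""

    tf_label: str
    up: set
    down: set
    universe_size: int
    thresholds: tuple[float, float] = (0.05, 0.58)

    @property
    def all(self) -> set:
        return self.up | self.down

    def to_dict(self) -> dict:
        return {
            "tf_label": self.tf_label,
            "up": sorted(self.up),
            "down": sorted(self.down),
            "universe_size": self.universe_size,
            "thresholds": {
                "alpha_fdr": self.thresholds[0],
                "min_abs_log2fc": self.thresholds[1],
            },
        }


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_low_counts(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes with at least ``min_total`` counts summed over all samples."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("count filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], cm.sample_sheet.copy())


def estimate_size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with all-positive counts; ``pseudo_reference=True`` falls back to a
    geometric mean computed with a 0.5 pseudo-count on every gene (useful for
    sparse matrices with no all-positive gene).
    """
    mat = cm.counts.to_numpy(dtype=float)
    if pseudo_reference:
        logmat = np.log(mat + 0.5)
    else:
        use = np.all(mat > 0, axis=1)
        if not use.any():
            raise ValueError(
                "no gene has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        logmat = np.log(mat[use])
    logref = logmat.mean(axis=1)
    sf = np.exp(np.median(logmat - logref[:, None], axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------


def estimate_dispersions(
    cm: CountMatrix,
    sf: pd.Series,
    shrink_weight: float = 0.5,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by pooled within-condition method of moments.

    For normalized counts z = y/sf within a condition, Var(z) = μ·E[1/sf] + αμ²,
    so each condition yields α̂_c = (v_c − m_c·mean(1/sf)) / m_c²; estimates are
    pooled across conditions weighted by degrees of freedom, then shrunk toward
    a least-squares fit of the trend α(μ) = a0 + a1/μ with weight
    ``shrink_weight``, and floored at ``alpha_floor``.
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must be in [0,1]")
    counts = cm.counts.to_numpy(dtype=float)
    sf_v = sf.loc[cm.sample_ids].to_numpy()
    z = counts / sf_v[None, :]

    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    mu_hat = np.zeros(counts.shape[0])
    n_cond = 0
    for cond in CONDITIONS:
        cols = [i for i, s in enumerate(cm.sample_ids) if cm.sample_sheet[s] == cond]
        if len(cols) < 2:
            continue
        n_cond += 1
        zc = z[:, cols]
        m = zc.mean(axis=1)
        v = zc.var(axis=1, ddof=1)
        inv_sf = np.mean(1.0 / sf_v[cols])
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = np.where(m > 0, (v - m * inv_sf) / np.maximum(m, 1e-300) ** 2, 0.0)
        w = len(cols) - 1
        num += w * a_c
        den += w
        mu_hat += m
    if n_cond == 0:
        raise ValueError("need at least 2 replicates in at least one condition")
    alpha_raw = num / np.maximum(den, 1)
    mu_hat /= n_cond

    # trend fit α ≈ a0 + a1/μ on moderately expressed genes
    ok = mu_hat > 1
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_hat[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu_hat, 1e-8)
    alpha = (1 - shrink_weight) * np.maximum(alpha_raw, 0.0) + shrink_weight * trend
    alpha = np.maximum(alpha, alpha_floor)
    return pd.Series(alpha, index=cm.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------


def fit_nb_glm(
    cm: CountMatrix,
    sf: pd.Series,
    dispersion: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 100,
    pseudo: float = 0.5,
) -> NBFit:
    """Fit the cell-means NB GLM for every gene at fixed dispersion.

    With one coefficient per condition the fit decouples by condition and a
    vectorized Fisher-scoring iteration over genes solves each 1-D problem.
    Conditions whose counts are all zero for a gene get a pseudo-fraction
    coefficient log((Σy + pseudo)/Σsf) and a ridge-stabilized variance.
    """
    counts = cm.counts.to_numpy(dtype=float)
    sf_v = sf.loc[cm.sample_ids].to_numpy()
    alpha = dispersion.loc[cm.gene_ids].to_numpy()

    n_genes = counts.shape[0]
    coef = np.empty((n_genes, len(CONDITIONS)))
    var = np.empty((n_genes, len(CONDITIONS)))

    for ci, cond in enumerate(CONDITIONS):
        cols = [i for i, s in enumerate(cm.sample_ids) if cm.sample_sheet[s] == cond]
        if not cols:
            raise ValueError(f"condition {cond} has no samples")
        y = counts[:, cols]
        s = sf_v[cols]
        tot = y.sum(axis=1)
        eta = np.log((tot + pseudo) / s.sum())  # init / pseudo-fraction floor
        free = tot > 0
        for _ in range(max_iter):
            mu = s[None, :] * np.exp(eta)[:, None]
            a = alpha[:, None]
            score = np.sum(y - mu * (1.0 + a * y) / (1.0 + a * mu), axis=1)
            info = np.sum(mu / (1.0 + a * mu), axis=1)
            step = score / (info + INFO_RIDGE)
            np.clip(step, -10.0, 10.0, out=step)
            step[~free] = 0.0
            eta = eta + step
            if np.max(np.abs(step), initial=0.0) < tol:
                break
        mu = s[None, :] * np.exp(eta)[:, None]
        info = np.sum(mu / (1.0 + alpha[:, None] * mu), axis=1)
        coef[:, ci] = eta / LN2
        var[:, ci] = 1.0 / (info + INFO_RIDGE) / LN2**2

    z = counts / sf_v[None, :]
    return NBFit(
        coef_log2=pd.DataFrame(coef, index=cm.gene_ids, columns=list(CONDITIONS)),
        var_log2=pd.DataFrame(var, index=cm.gene_ids, columns=list(CONDITIONS)),
        base_mean=pd.Series(z.mean(axis=1), index=cm.gene_ids, name="base_mean"),
        dispersion=pd.Series(alpha, index=cm.gene_ids, name="dispersion"),
    )


def combined_contrast(fit: NBFit, contrast: ContrastSpec) -> pd.DataFrame:
    """Wald test of c'β for the combined OE/KO contrast.

    Returns a frame with log2fc, se, wald_z and the two-sided normal p-value.
    """
    c = np.array([contrast.weights.get(cond, 0.0) for cond in CONDITIONS])
    beta = fit.coef_log2.to_numpy()
    v = fit.var_log2.to_numpy()
    lfc = beta @ c
    se = np.sqrt(v @ (c**2))  # conditions are independent blocks
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"log2fc": lfc, "se": se, "wald_z": z, "pvalue": p}, index=fit.coef_log2.index
    )


# ---------------------------------------------------------------------------
# multiple testing, DEG calling, orchestration
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs propagate and are excluded
    from the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must be in [0,1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def shrink_log2fc(lfc: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Simple normal-prior posterior-mean shrinkage.

    The prior variance is estimated by moments, τ² = max(0, var(lfc) − mean(se²));
    each estimate is scaled by τ²/(τ² + se²).
    """
    tau2 = max(float(np.nanvar(lfc)) - float(np.nanmean(se**2)), 0.0)
    return lfc * tau2 / (tau2 + se**2)


def run_de(
    cm: CountMatrix,
    tf_label: str,
    min_total: int = 10,
    shrink: bool = False,
    shrink_weight: float = 0.5,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Full DE pipeline for one factor: filter → size factors → dispersions →
    GLM → combined contrast → BH.

    Returns one row per input gene with columns base_mean, log2fc, se,
    wald_z, pvalue, padj, tested; genes failing the count filter carry
    ``tested=False`` and NaN statistics.
    """
    cm_f = filter_low_counts(cm, min_total)
    sf = estimate_size_factors(cm_f, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(cm_f, sf, shrink_weight=shrink_weight)
    fit = fit_nb_glm(cm_f, sf, disp)
    res = combined_contrast(fit, ContrastSpec(tf_label))
    if shrink:
        res["log2fc"] = shrink_log2fc(res["log2fc"].to_numpy(), res["se"].to_numpy())
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    res["base_mean"] = fit.base_mean
    res["tested"] = True
    out = res.reindex(cm.gene_ids)
    out["tested"] = out["tested"].notna() & out["tested"].eq(True)
    out.index.name = "gene_id"
    return out[["base_mean", "log2fc", "se", "wald_z", "pvalue", "padj", "tested"]]


def call_degs(
    de: pd.DataFrame,
    tf_label: str,
    alpha_fdr: float = 0.05,
    min_abs_log2fc: float = 0.58,
) -> DEGSet:
    """Call up/down DEG sets at strict thresholds padj < α and |lfc| > cutoff."""
    tested = de[de["tested"]]
    sig = tested["padj"] < alpha_fdr
    up = set(tested.index[sig & (tested["log2fc"] > min_abs_log2fc)])
    down = set(tested.index[sig & (tested["log2fc"] < -min_abs_log2fc)])
    return DEGSet(
        tf_label=tf_label,
        up=up,
        down=down,
        universe_size=int(tested.shape[0]),
        thresholds=(alpha_fdr, min_abs_log2fc),
    )


def write_de(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_de(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
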