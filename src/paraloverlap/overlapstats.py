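"""Observed vs. bootstrap-expected DEG-set overlap.

The question: two paralogous factors bind the same motif — do they regulate
the same genes?  The observed statistic is the Jaccard index
J(A, B) = |A ∩ B| / |A ∪ B| between the DEG sets of the two factors.  The
null ("same targets") is built empirically: resample replicates within every
condition (constrained bootstrap, at least ``min_unique`` distinct samples
per condition), rerun the whole DE pipeline per bootstrap replicate, and
take the *within-factor* pairwise Jaccard distribution — the overlap two
analyses of the SAME regulator show — as the expected overlap.  Observed and
expected are compared with a one-sample Z test on the bootstrap spread,
basic bootstrap confidence intervals, and an observed/expected percentage.

Also here: Fisher exact overlap tests (conditional-MLE odds ratio with exact
CI, as in R's ``fisher.test``), Pearson correlation of Wald Z-scores with a
bootstrap CI, and the CRISPR guide off-target exclusion filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from paraloverlap.data import CONDITIONS, CountMatrix
from paraloverlap.decontrast import DEGSet, call_degs, run_de

# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def jaccard(A, B) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when the union is empty."""
    A, B = set(A), set(B)
    union = len(A | B)
    if union == 0:
        return 0.0
    return len(A & B) / union


@dataclass
class OverlapTest:
    """2×2 overlap test of two gene sets drawn from a common universe."""

    nA: int
    nB: int
    n_intersect: int
    universe_size: int
    jaccard: float
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float  # ad/bc
    or_ci: tuple[float, float]
    pvalue: float

    @property
    def n_union(self) -> int:
        return self.nA + self.nB - self.n_intersect

    def to_dict(self) -> dict:
        return {
            "nA": self.nA,
            "nB": self.nB,
            "n_intersect": self.n_intersect,
            "n_union": self.n_union,
            "universe_size": self.universe_size,
            "jaccard": self.jaccard,
            "odds_ratio": self.odds_ratio,
            "sample_odds_ratio": self.sample_odds_ratio,
            "or_ci": list(self.or_ci),
            "pvalue": self.pvalue,
        }


def fisher_overlap(nA: int, nB: int, n_intersect: int, universe_size: int) -> OverlapTest:
    """Fisher's exact test on the 2×2 membership table.

    Table: [[both, A only], [B only, neither]].  Reports the exact two-sided
    p-value, the conditional-MLE odds ratio with exact CI, and the sample
    odds ratio ad/bc for reference.
    """
    if n_intersect > min(nA, nB):
        raise ValueError("n_intersect cannot exceed min(nA, nB)")
    if nA + nB - n_intersect > universe_size:
        raise ValueError("union exceeds universe_size")
    a = n_intersect
    b = nA - n_intersect
    c = nB - n_intersect
    d = universe_size - nA - nB + n_intersect
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table)[1])
    if b * c == 0:
        sample_or = np.inf if a * d > 0 else 0.0
    else:
        sample_or = a * d / (b * c)
    res = _odds_ratio(table)
    ci = res.confidence_interval(0.95)
    union = nA + nB - n_intersect
    return OverlapTest(
        nA=nA,
        nB=nB,
        n_intersect=n_intersect,
        universe_size=universe_size,
        jaccard=(n_intersect / union) if union else 0.0,
        odds_ratio=float(res.statistic),
        sample_odds_ratio=float(sample_or),
        or_ci=(float(ci.low), float(ci.high)),
        pvalue=p,
    )


def basic_bootstrap_ci(
    values,
    alpha: float = 0.05,
    center: float | None = None,
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> tuple[float, float]:
    """Basic (reflected-percentile) bootstrap interval.

    With point estimate θ̂ (default: the mean of ``values``) and empirical
    quantiles q of the bootstrap distribution, the interval is
    (2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2}), optionally clipped — Jaccard quantities
    live in [0, 1].
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("need at least one finite value")
    theta = float(np.mean(v)) if center is None else float(center)
    qlo, qhi = np.quantile(v, [alpha / 2, 1 - alpha / 2])
    lo, hi = 2 * theta - qhi, 2 * theta - qlo
    if clip is not None:
        lo = min(max(lo, clip[0]), clip[1])
        hi = min(max(hi, clip[0]), clip[1])
    return float(lo), float(hi)


def z_test_overlap(
    observed_j: float, within_tf_j_values, alternative: str = "two-sided"
) -> tuple[float, float]:
    """One-sample Z test of the observed Jaccard against the bootstrap null.

    z = (mean(values) − observed) / sd(values, ddof=1); p from the normal
    reference.  ``alternative='greater'`` asks whether the expected overlap
    exceeds the observed one.
    """
    v = np.asarray(within_tf_j_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two bootstrap values")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        return np.nan, np.nan
    z = (float(np.mean(v)) - float(observed_j)) / sd
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


def oe_ratio(observed_j: float, expected_j_tf1: float, expected_j_tf2: float) -> float:
    """Observed/expected overlap as a percentage, one decimal.

    100 × observed J divided by the mean of the two within-factor expected
    Jaccard indices.
    """
    mean_exp = (expected_j_tf1 + expected_j_tf2) / 2.0
    if mean_exp <= 0:
        return float("nan")
    return round(100.0 * observed_j / mean_exp, 1)


# ---------------------------------------------------------------------------
# constrained bootstrap of the DE pipeline
# ---------------------------------------------------------------------------


@dataclass
class BootstrapConfig:
    """Settings of the bootstrap-null overlap analysis."""

    n_boot: int = 100
    min_unique: int = 3
    alpha_fdr: float = 0.05
    min_abs_log2fc: float = 0.58
    min_total: int = 10
    max_pairs: int = 10_000
    seed: int = 0

    def validate(self, condition_sizes: dict[str, int] | None = None) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.min_unique < 1:
            raise ValueError("min_unique must be >= 1")
        if condition_sizes is not None:
            small = {c: n for c, n in condition_sizes.items() if n < self.min_unique}
            if small:
                raise ValueError(
                    f"min_unique={self.min_unique} exceeds replicate count in {small}"
                )


def bootstrap_resample_indices(
    condition_sizes: dict[str, int],
    config: BootstrapConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], int]:
    """Draw with-replacement indices per condition, constrained to contain at
    least ``min_unique`` distinct samples; rejected draws are redrawn.

    Returns (indices per condition, number of rejected draws).
    """
    config.validate(condition_sizes)
    out: dict[str, np.ndarray] = {}
    rejections = 0
    for cond, n in condition_sizes.items():
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= config.min_unique:
                out[cond] = idx
                break
            rejections += 1
    return out, rejections


@dataclass
class BootstrapDEGs:
    """DEG sets from rerunning the pipeline on bootstrap-resampled replicates."""

    tf_label: str
    sets: list[DEGSet]
    rejections: int = 0
    n_failed: int = 0


def _resample_matrix(
    cm: CountMatrix, indices: dict[str, np.ndarray]
) -> tuple[CountMatrix, CountMatrix]:
    """Resampled matrix plus its deduplicated companion (each distinct
    original sample once per condition)."""
    cols, conds, names = [], [], []
    ucols, uconds, unames = [], [], []
    for cond in CONDITIONS:
        samples = cm.condition_samples(cond)
        seen = set()
        for j, i in enumerate(indices[cond]):
            cols.append(samples[i])
            conds.append(cond)
            names.append(f"{cond}_b{j + 1}")
            if i not in seen:
                seen.add(i)
                ucols.append(samples[i])
                uconds.append(cond)
                unames.append(f"{cond}_u{len(seen)}")
    counts = cm.counts[cols].copy()
    counts.columns = names
    ucounts = cm.counts[ucols].copy()
    ucounts.columns = unames
    return (
        CountMatrix(counts, pd.Series(conds, index=names)),
        CountMatrix(ucounts, pd.Series(uconds, index=unames)),
    )


def bootstrap_deg_sets(
    cm: CountMatrix, tf_label: str, config: BootstrapConfig
) -> BootstrapDEGs:
    """Run the constrained bootstrap: resample replicates within every
    condition, rerun size factors → dispersions → GLM → contrast → BH →
    DEG calling, ``n_boot`` times.

    ``cm`` should already be count-filtered; the filter is not re-applied per
    replicate so every bootstrap DEG set shares one gene universe.  Dispersion
    is estimated from the distinct samples drawn in the replicate (duplicated
    bootstrap columns carry no information about biological variance and would
    deflate the estimate, inflating false positives).
    """
    from paraloverlap.decontrast import (
        ContrastSpec,
        bh_adjust,
        combined_contrast,
        estimate_dispersions,
        estimate_size_factors,
        fit_nb_glm,
    )

    rng = np.random.default_rng(config.seed)
    sizes = {c: len(cm.condition_samples(c)) for c in CONDITIONS}
    config.validate(sizes)
    sets: list[DEGSet] = []
    total_rej = 0
    n_failed = 0
    for _ in range(config.n_boot):
        idx, rej = bootstrap_resample_indices(sizes, config, rng)
        total_rej += rej
        cm_b, cm_u = _resample_matrix(cm, idx)
        try:
            sf = estimate_size_factors(cm_b, pseudo_reference=True)
            sf_u = estimate_size_factors(cm_u, pseudo_reference=True)
            disp = estimate_dispersions(cm_u, sf_u)
            fit = fit_nb_glm(cm_b, sf, disp)
            res = combined_contrast(fit, ContrastSpec(tf_label))
            res["padj"] = bh_adjust(res["pvalue"].to_numpy())
            res["tested"] = True
            sets.append(
                call_degs(res, tf_label, config.alpha_fdr, config.min_abs_log2fc)
            )
        except Exception:
            n_failed += 1
    return BootstrapDEGs(tf_label, sets, rejections=total_rej, n_failed=n_failed)


def _select(deg: DEGSet, which: str) -> set:
    if which == "up":
        return deg.up
    if which == "down":
        return deg.down
    if which == "all":
        return deg.up | deg.down
    raise ValueError(f"which must be up/down/all, got {which!r}")


def pairwise_jaccard(
    sets: list[DEGSet],
    which: str = "all",
    max_pairs: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Jaccard over all unordered pairs of DEG sets (within-factor null).

    When the pair count exceeds ``max_pairs`` a seeded subsample of pairs is
    used.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    members = [_select(s, which) for s in sets]
    pairs = list(itertools.combinations(range(len(members)), 2))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in chosen]
    return np.array([jaccard(members[i], members[j]) for i, j in pairs])


def cross_pairwise_jaccard(
    sets_a: list[DEGSet],
    sets_b: list[DEGSet],
    which: str = "all",
    max_pairs: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Jaccard over all (i, j) pairs of one factor's bootstrap sets against
    the other's — the bootstrap distribution of the observed overlap."""
    ma = [_select(s, which) for s in sets_a]
    mb = [_select(s, which) for s in sets_b]
    pairs = list(itertools.product(range(len(ma)), range(len(mb))))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in chosen]
    return np.array([jaccard(ma[i], mb[j]) for i, j in pairs])


# ---------------------------------------------------------------------------
# full overlap analysis
# ---------------------------------------------------------------------------


@dataclass
class OverlapNullResult:
    """Observed vs. expected overlap for one DEG category (up/down/all)."""

    which: str
    observed_j: float
    j_within_tf1: np.ndarray
    j_within_tf2: np.ndarray
    j_cross: np.ndarray
    expected_j_tf1: float
    expected_j_tf2: float
    ci_tf1: tuple[float, float]
    ci_tf2: tuple[float, float]
    ci_cross: tuple[float, float]
    z_tf1: float
    p_tf1: float
    z_tf2: float
    p_tf2: float
    oe_ratio: float

    def to_dict(self) -> dict:
        return {
            "which": self.which,
            "observed_j": self.observed_j,
            "expected_j_tf1": self.expected_j_tf1,
            "expected_j_tf2": self.expected_j_tf2,
            "ci_tf1": list(self.ci_tf1),
            "ci_tf2": list(self.ci_tf2),
            "ci_cross": list(self.ci_cross),
            "z_tf1": self.z_tf1,
            "p_tf1": self.p_tf1,
            "z_tf2": self.z_tf2,
            "p_tf2": self.p_tf2,
            "oe_ratio": self.oe_ratio,
            "n_within_tf1": int(self.j_within_tf1.size),
            "n_within_tf2": int(self.j_within_tf2.size),
            "n_cross": int(self.j_cross.size),
        }


def _nan_pair() -> tuple[float, float]:
    return (float("nan"), float("nan"))


def analyze_category(
    which: str,
    deg1: DEGSet,
    deg2: DEGSet,
    boots1: BootstrapDEGs,
    boots2: BootstrapDEGs,
    config: BootstrapConfig,
    alternative: str = "two-sided",
) -> OverlapNullResult:
    obs = jaccard(_select(deg1, which), _select(deg2, which))
    j1 = pairwise_jaccard(boots1.sets, which, config.max_pairs, config.seed)
    j2 = pairwise_jaccard(boots2.sets, which, config.max_pairs, config.seed)
    jx = cross_pairwise_jaccard(
        boots1.sets, boots2.sets, which, config.max_pairs, config.seed
    )
    e1, e2 = float(np.mean(j1)), float(np.mean(j2))

    def safe_z(vals):
        try:
            return z_test_overlap(obs, vals, alternative)
        except ValueError:
            return (float("nan"), float("nan"))

    z1, p1 = safe_z(j1)
    z2, p2 = safe_z(j2)
    return OverlapNullResult(
        which=which,
        observed_j=obs,
        j_within_tf1=j1,
        j_within_tf2=j2,
        j_cross=jx,
        expected_j_tf1=e1,
        expected_j_tf2=e2,
        ci_tf1=basic_bootstrap_ci(j1) if j1.size else _nan_pair(),
        ci_tf2=basic_bootstrap_ci(j2) if j2.size else _nan_pair(),
        ci_cross=basic_bootstrap_ci(jx, center=obs) if jx.size else _nan_pair(),
        z_tf1=z1,
        p_tf1=p1,
        z_tf2=z2,
        p_tf2=p2,
        oe_ratio=oe_ratio(obs, e1, e2),
    )


@dataclass
class OverlapAnalysis:
    """Bundle of the full observed-vs-expected overlap analysis."""

    deg_tf1: DEGSet
    deg_tf2: DEGSet
    categories: dict[str, OverlapNullResult]
    fisher: dict[str, OverlapTest]
    boots_tf1: BootstrapDEGs
    boots_tf2: BootstrapDEGs


def overlap_analysis(
    cm: CountMatrix,
    config: BootstrapConfig,
    alternative: str = "two-sided",
) -> OverlapAnalysis:
    """End-to-end overlap analysis on one count matrix.

    Runs the main DE for both factors, calls DEG sets, runs the constrained
    bootstrap for each factor, and assembles observed/expected Jaccard
    statistics plus Fisher overlap tests for the up, down and all categories.
    """
    from paraloverlap.decontrast import filter_low_counts

    cm_f = filter_low_counts(cm, config.min_total)
    sizes = {c: len(cm_f.condition_samples(c)) for c in CONDITIONS}
    config.validate(sizes)

    degs, boots = {}, {}
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s) for s in ss.generate_state(2)]
    for tf, child in zip(("TF1", "TF2"), child_seeds):
        de = run_de(cm_f, tf, min_total=0, pseudo_reference=True)
        degs[tf] = call_degs(de, tf, config.alpha_fdr, config.min_abs_log2fc)
        cfg_tf = BootstrapConfig(**{**config.__dict__, "seed": child % (2**31)})
        boots[tf] = bootstrap_deg_sets(cm_f, tf, cfg_tf)

    categories = {
        which: analyze_category(
            which, degs["TF1"], degs["TF2"], boots["TF1"], boots["TF2"], config, alternative
        )
        for which in ("up", "down", "all")
    }
    universe = degs["TF1"].universe_size
    fisher = {}
    for which in ("up", "down", "all"):
        A = _select(degs["TF1"], which)
        B = _select(degs["TF2"], which)
        if A and B:
            fisher[which] = fisher_overlap(len(A), len(B), len(A & B), universe)
    return OverlapAnalysis(
        deg_tf1=degs["TF1"],
        deg_tf2=degs["TF2"],
        categories=categories,
        fisher=fisher,
        boots_tf1=boots["TF1"],
        boots_tf2=boots["TF2"],
    )


# ---------------------------------------------------------------------------
# Z-score correlation and off-target filter
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    pearson_r: float
    r_squared: float
    ci: tuple[float, float]
    pvalue: float
    n_genes: int
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "ci": list(self.ci),
            "pvalue": self.pvalue,
            "n_genes": self.n_genes,
            "n_boot": self.n_boot,
        }


def zscore_correlation(
    de1: pd.DataFrame, de2: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> CorrelationResult:
    """Pearson correlation of the two factors' Wald Z-scores over the shared
    tested universe, with a percentile bootstrap CI over genes."""
    shared = de1.index[de1["tested"]].intersection(de2.index[de2["tested"]])
    z1 = de1.loc[shared, "wald_z"].to_numpy()
    z2 = de2.loc[shared, "wald_z"].to_numpy()
    ok = np.isfinite(z1) & np.isfinite(z2)
    z1, z2 = z1[ok], z2[ok]
    if z1.size < 3:
        raise ValueError("need at least 3 shared tested genes")
    r, p = stats.pearsonr(z1, z2)
    rng = np.random.default_rng(seed)
    boot_r = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, z1.size, z1.size)
        boot_r[b] = stats.pearsonr(z1[idx], z2[idx])[0]
    lo, hi = np.quantile(boot_r, [0.025, 0.975])
    return CorrelationResult(
        pearson_r=float(r),
        r_squared=float(r**2),
        ci=(float(lo), float(hi)),
        pvalue=float(p),
        n_genes=int(z1.size),
        n_boot=n_boot,
    )


OFFTARGET_CONTEXTS = ("exon", "intron", "intergenic", "promoter", "other")

VERDICT_SHARED = "shared_effect_not_offtarget"
VERDICT_SPECIFIC = "possible_guide_specific_offtarget"
VERDICT_NO_EFFECT = "no_expression_effect"


def offtarget_filter(
    candidates: pd.DataFrame,
    deg_tf1: DEGSet,
    deg_tf2: DEGSet,
    cfd_min: float = 0.1,
) -> pd.DataFrame:
    """Filter guide off-target candidates and classify the survivors.

    Keeps rows with CFD > ``cfd_min`` (strict) and exonic/intronic context.
    A kept gene differentially expressed for exactly one factor is a possible
    guide-specific off-target; a gene affected by BOTH factors cannot be an
    off-target of a specific guide sequence; a gene affected by neither shows
    no expression effect.
    """
    required = {"gene_id", "cfd", "context"}
    if not required <= set(candidates.columns):
        raise ValueError(f"candidate table needs columns {sorted(required)}")
    bad = ~candidates["context"].isin(OFFTARGET_CONTEXTS)
    if bad.any():
        row = candidates.index[bad][0]
        raise ValueError(
            f"unknown context {candidates.loc[row, 'context']!r} in row {row}"
        )
    kept = candidates[
        (candidates["cfd"] > cfd_min) & candidates["context"].isin(["exon", "intron"])
    ].copy()
    de1, de2 = deg_tf1.all, deg_tf2.all
    verdicts = []
    for g in kept["gene_id"]:
        in1, in2 = g in de1, g in de2
        if in1 and in2:
            verdicts.append(VERDICT_SHARED)
        elif in1 or in2:
            verdicts.append(VERDICT_SPECIFIC)
        else:
            verdicts.append(VERDICT_NO_EFFECT)
    kept["verdict"] = verdicts
    return kept
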