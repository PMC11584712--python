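"""Synthetic data with known ground truth for the six-condition design.

Counts are gamma-Poisson (negative binomial) with a mean/dispersion trend
α(μ) = a0 + a1/μ, log-normal per-gene baselines and log-normal size factors.
Two designated genes ("TF1", "TF2") carry the perturbed factors themselves:
a large positive log2 fold change under their own OE condition and a
fractional knockdown under their own KO condition.  A configurable set of
target genes responds to each factor (positive effect at OE, mirrored and
scaled negative effect at KO), and a configurable set of "stress" genes
responds to the CRISPR system itself, identically in targeting and
non-targeting conditions of the same system — exactly the structure the
combined contrast is designed to cancel.

A companion generator lays genes out on synthetic chromosomes and places
binding-site peaks near direct targets, for testing the peak-integration
stage without any sequencing data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paraloverlap.data import CONDITIONS, KO_SYSTEM, OE_SYSTEM, CountMatrix

TF_GENES = ("TF1", "TF2")


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Defaults mirror the perturbation study this package models: 6 replicates
    in each of 6 conditions; the overexpressed factors reach log2FC 4.2 and
    5.2 over control while knockout leaves 35% / 47% of transcript; ~190 and
    ~120 target genes with a fifth of the smaller set shared.
    """

    n_genes: int = 2000
    n_reps: int = 6
    baseline_log_mean: float = 4.0  # natural-log mean of per-gene baseline
    baseline_log_sd: float = 1.5
    dispersion_a0: float = 0.05  # α(μ) = a0 + a1/μ
    dispersion_a1: float = 2.0
    libsize_sd: float = 0.15  # log-normal sd of size factors
    n_targets_tf1: int = 190
    n_targets_tf2: int = 120
    shared_fraction: float = 0.2
    frac_down: float = 0.3
    effect_log2fc_mean: float = 1.0  # magnitude at OE, log2 units
    effect_log2fc_sd: float = 0.5
    ko_oe_ratio: float = 0.5  # KO-side effect = −ratio × OE-side effect
    stress_fraction: float = 0.1
    stress_log2fc_sd: float = 0.5
    tf_oe_log2fc: tuple[float, float] = (4.2, 5.2)
    tf_ko_fraction_remaining: tuple[float, float] = (0.35, 0.47)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < len(TF_GENES) + self.n_targets_tf1 + self.n_targets_tf2:
            raise ValueError(
                "n_genes too small: n_targets_tf1 + n_targets_tf2 (+2 TF genes) "
                f"exceed n_genes={self.n_genes}"
            )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError(f"shared_fraction must be in [0,1], got {self.shared_fraction}")
        if not 0.0 <= self.frac_down <= 1.0:
            raise ValueError(f"frac_down must be in [0,1], got {self.frac_down}")
        if self.n_reps < 3:
            raise ValueError(f"n_reps must be >= 3, got {self.n_reps}")
        for name in (
            "baseline_log_sd",
            "dispersion_a0",
            "dispersion_a1",
            "libsize_sd",
            "effect_log2fc_sd",
            "stress_log2fc_sd",
            "ko_oe_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.stress_fraction <= 1.0:
            raise ValueError(f"stress_fraction must be in [0,1], got {self.stress_fraction}")
        for frac in self.tf_ko_fraction_remaining:
            if not 0.0 < frac <= 1.0:
                raise ValueError(
                    f"tf_ko_fraction_remaining must be in (0,1], got {frac}"
                )


ROLE_NONE = "none"
ROLE_UP = "up-target"
ROLE_DOWN = "down-target"


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``table`` has one row per gene with the columns

    * ``tf1_role`` / ``tf2_role`` — up-target / down-target / none
    * ``stress_oe_log2fc`` / ``stress_ko_log2fc`` — system-stress effects
    * ``lfc_<condition>`` — true log2FC relative to the matched control for
      the four TF-perturbation conditions
    * ``combined_tf1`` / ``combined_tf2`` — the true value of the combined
      contrast (OE − ctrl-OE) − (KO − ctrl-KO)
    """

    table: pd.DataFrame

    def targets(self, tf_label: str) -> set[str]:
        role = self.table[f"{tf_label.lower()}_role"]
        return set(self.table.index[role != ROLE_NONE])

    def stress_only(self) -> set[str]:
        t = self.table
        mask = (
            (t["tf1_role"] == ROLE_NONE)
            & (t["tf2_role"] == ROLE_NONE)
            & ((t["stress_oe_log2fc"] != 0) | (t["stress_ko_log2fc"] != 0))
            & (~t.index.isin(TF_GENES))
        )
        return set(t.index[mask])

    def null_genes(self) -> set[str]:
        t = self.table
        mask = (
            (t["tf1_role"] == ROLE_NONE)
            & (t["tf2_role"] == ROLE_NONE)
            & (~t.index.isin(TF_GENES))
        )
        return set(t.index[mask])


def _assign_roles(rng: np.random.Generator, n: int, frac_down: float) -> np.ndarray:
    roles = np.where(rng.random(n) < frac_down, ROLE_DOWN, ROLE_UP)
    return roles


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix and its ground truth from the generative model.

    Counts[g, s] ~ NB(mean = sf_s · μ_g · 2^Δ(g, cond(s)), dispersion α(μ_g))
    where Δ combines target effects, system-stress effects and the TF genes'
    own perturbation.  Identical configs (including seed) give identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = list(TF_GENES) + [f"G{i:05d}" for i in range(n - len(TF_GENES))]

    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu

    # --- target assignment -------------------------------------------------
    n1, n2 = config.n_targets_tf1, config.n_targets_tf2
    n_shared = int(round(config.shared_fraction * min(n1, n2)))
    pool = rng.permutation(np.arange(len(TF_GENES), n))
    shared = pool[:n_shared]
    only1 = pool[n_shared : n_shared + (n1 - n_shared)]
    only2 = pool[n_shared + (n1 - n_shared) : n_shared + (n1 - n_shared) + (n2 - n_shared)]

    tf1_role = np.full(n, ROLE_NONE, dtype=object)
    tf2_role = np.full(n, ROLE_NONE, dtype=object)
    shared_roles = _assign_roles(rng, n_shared, config.frac_down)
    tf1_role[shared] = shared_roles
    tf2_role[shared] = shared_roles  # shared targets respond in the same direction
    tf1_role[only1] = _assign_roles(rng, len(only1), config.frac_down)
    tf2_role[only2] = _assign_roles(rng, len(only2), config.frac_down)

    def effect_sizes(role: np.ndarray) -> np.ndarray:
        is_t = role != ROLE_NONE
        mag = np.abs(
            rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, int(is_t.sum()))
        )
        e = np.zeros(n)
        e[is_t] = np.where(role[is_t] == ROLE_UP, mag, -mag)
        return e

    e1 = effect_sizes(tf1_role)
    e2 = effect_sizes(tf2_role)

    # --- stress effects (per CRISPR system, shared with controls) ----------
    stress_oe = np.zeros(n)
    stress_ko = np.zeros(n)
    candidates = np.arange(len(TF_GENES), n)
    n_stress = int(round(config.stress_fraction * n))
    stress_idx = rng.choice(candidates, size=min(n_stress, len(candidates)), replace=False)
    stress_oe[stress_idx] = rng.normal(0.0, config.stress_log2fc_sd, len(stress_idx))
    stress_ko[stress_idx] = rng.normal(0.0, config.stress_log2fc_sd, len(stress_idx))

    # --- per-condition log2 offsets Δ --------------------------------------
    delta = pd.DataFrame(0.0, index=gene_ids, columns=list(CONDITIONS))
    for cond in OE_SYSTEM:
        delta[cond] += stress_oe
    for cond in KO_SYSTEM:
        delta[cond] += stress_ko
    delta["TF1-OE"] += e1
    delta["TF1-KO"] += -config.ko_oe_ratio * e1
    delta["TF2-OE"] += e2
    delta["TF2-KO"] += -config.ko_oe_ratio * e2
    # the perturbed factors themselves (override any target/stress signal)
    for k, tf in enumerate(TF_GENES):
        delta.loc[tf, :] = 0.0
        delta.loc[tf, OE_SYSTEM] = stress_oe[k]
        delta.loc[tf, KO_SYSTEM] = stress_ko[k]
        delta.loc[tf, f"{tf}-OE"] += config.tf_oe_log2fc[k]
        delta.loc[tf, f"{tf}-KO"] += np.log2(config.tf_ko_fraction_remaining[k])

    # --- samples, size factors, counts -------------------------------------
    sample_ids = [f"{cond}_r{j + 1}" for cond in CONDITIONS for j in range(config.n_reps)]
    cond_of = np.repeat(np.arange(len(CONDITIONS)), config.n_reps)
    if config.libsize_sd > 0:
        sf = rng.lognormal(0.0, config.libsize_sd, len(sample_ids))
        sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    else:
        sf = np.ones(len(sample_ids))

    dmat = delta.to_numpy()[:, cond_of]  # genes × samples
    mean = sf[None, :] * mu[:, None] * np.exp2(dmat)
    with np.errstate(divide="ignore"):
        shape = np.where(alpha > 0, 1.0 / np.where(alpha > 0, alpha, 1.0), np.inf)
    counts = np.empty(mean.shape, dtype=np.int64)
    pois_mask = alpha <= 0
    if pois_mask.any():
        counts[pois_mask] = rng.poisson(mean[pois_mask])
    nb_mask = ~pois_mask
    if nb_mask.any():
        lam = rng.gamma(
            shape[nb_mask][:, None], mean[nb_mask] * alpha[nb_mask][:, None]
        )
        counts[nb_mask] = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        pd.Series([CONDITIONS[c] for c in cond_of], index=sample_ids),
    )

    # --- truth table --------------------------------------------------------
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["tf1_role"] = tf1_role
    truth["tf2_role"] = tf2_role
    truth["stress_oe_log2fc"] = stress_oe
    truth["stress_ko_log2fc"] = stress_ko
    # log2FC relative to matched control: stress cancels by construction
    truth["lfc_TF1-OE"] = delta["TF1-OE"].to_numpy() - stress_oe
    truth["lfc_TF1-KO"] = delta["TF1-KO"].to_numpy() - stress_ko
    truth["lfc_TF2-OE"] = delta["TF2-OE"].to_numpy() - stress_oe
    truth["lfc_TF2-KO"] = delta["TF2-KO"].to_numpy() - stress_ko
    truth["combined_tf1"] = truth["lfc_TF1-OE"] - truth["lfc_TF1-KO"]
    truth["combined_tf2"] = truth["lfc_TF2-OE"] - truth["lfc_TF2-KO"]
    truth["baseline_mu"] = mu
    truth["dispersion"] = alpha
    return cm, SimTruth(truth)


# ---------------------------------------------------------------------------
# peak / TSS fixtures
# ---------------------------------------------------------------------------


@dataclass
class PeakSimConfig:
    """Layout of the synthetic binding-site fixture.

    Genes are spaced evenly along synthetic chromosomes; a fraction of
    direct-target genes receives one peak at a distance drawn uniformly on
    [0, ``peak_dist_max``] from its TSS, non-target genes receive background
    peaks at a lower rate.
    """

    gene_spacing: int = 200_000
    genes_per_chrom: int = 500
    target_peak_fraction: float = 0.9
    peak_dist_max: int = 100_000
    background_rate: float = 0.05
    peak_width: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.gene_spacing <= self.peak_width:
            raise ValueError(
                f"gene_spacing={self.gene_spacing} too small to place peaks of "
                f"width {self.peak_width}"
            )
        if not 0 <= self.target_peak_fraction <= 1:
            raise ValueError("target_peak_fraction must be in [0,1]")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0,1]")
        if self.peak_dist_max < 0 or self.peak_width <= 0:
            raise ValueError("peak_dist_max must be >= 0 and peak_width > 0")


def simulate_peaks(truth: SimTruth, gene_ids, config: PeakSimConfig):
    """Place TSSs and binding-site peaks for the genes of a simulation.

    Returns a :class:`~paraloverlap.peaklink.PeakSet` (narrowPeak-style, with
    summits) and a :class:`~paraloverlap.peaklink.TSSTable`.  The peak set's
    ``meta`` records ``n_proximal``: how many peaks lie within ±5 kb of any
    TSS (summit position), for cross-checking downstream annotation.
    """
    from paraloverlap.peaklink import PeakSet, TSSTable

    config.validate()
    gene_ids = list(gene_ids)
    unknown = set(gene_ids) - set(truth.table.index)
    if unknown:
        raise ValueError(f"gene_ids not present in truth: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(config.seed)

    margin = config.peak_dist_max + config.peak_width
    chrom, tss_pos, strand = [], [], []
    for i, g in enumerate(gene_ids):
        c = i // config.genes_per_chrom
        j = i % config.genes_per_chrom
        chrom.append(f"chrS{c + 1}")
        tss_pos.append(margin + j * config.gene_spacing)
        strand.append("+" if rng.random() < 0.5 else "-")
    tss_df = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chrom, "tss": tss_pos, "strand": strand}
    )

    is_target = np.array(
        [
            truth.table.loc[g, "tf1_role"] != ROLE_NONE
            or truth.table.loc[g, "tf2_role"] != ROLE_NONE
            for g in gene_ids
        ]
    )

    rows = []
    half = config.peak_width // 2
    for i, g in enumerate(gene_ids):
        if is_target[i]:
            place = rng.random() < config.target_peak_fraction
            dist = rng.uniform(0, config.peak_dist_max)
        else:
            place = rng.random() < config.background_rate
            dist = rng.uniform(0, config.gene_spacing / 2)
        if not place:
            continue
        sign = 1 if rng.random() < 0.5 else -1
        center = max(tss_pos[i] + sign * int(round(dist)), half)
        start = center - half
        end = start + config.peak_width
        rows.append(
            {
                "chrom": chrom[i],
                "start": start,
                "end": end,
                "name": f"peak_{len(rows):05d}",
                "score": int(rng.integers(100, 1000)),
                "strand": ".",
                "signal": float(np.round(rng.uniform(1, 50), 3)),
                "pvalue": -1.0,
                "qvalue": -1.0,
                "summit": half,
            }
        )
    peaks_df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "signal",
            "pvalue",
            "qvalue",
            "summit",
        ],
    )

    # record proximal-peak count (summit within ±5 kb of any TSS)
    n_prox = 0
    by_chrom = tss_df.groupby("chrom")["tss"]
    tss_sorted = {c: np.sort(v.to_numpy()) for c, v in by_chrom}
    for _, p in peaks_df.iterrows():
        pos = p["start"] + p["summit"]
        arr = tss_sorted.get(p["chrom"])
        if arr is None or len(arr) == 0:
            continue
        k = np.searchsorted(arr, pos)
        d = min(
            abs(pos - arr[k - 1]) if k > 0 else np.inf,
            abs(pos - arr[k]) if k < len(arr) else np.inf,
        )
        if d <= 5000:
            n_prox += 1

    return (
        PeakSet(peaks_df, meta={"n_proximal": int(n_prox)}),
        TSSTable(tss_df),
    )


def write_truth(truth: SimTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")


def read_truth(path) -> SimTruth:
    return SimTruth(pd.read_csv(path, sep="\t", index_col="gene_id"))


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
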