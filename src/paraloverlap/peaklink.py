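"""Binding-site integration: peaks, TSS tables, distances and target calls.

All coordinates are 0-based half-open (BED convention).  Peak positions are
taken at the narrowPeak summit when present, else at the interval midpoint.
Peak→gene association follows the window logic of binding-and-expression
target analysis: every (gene, peak) pair within a maximum TSS distance
(default 1 Mb, inclusive) is a candidate link, the promoter is TSS ± 5 kb
(inclusive), and each gene's regulatory potential is the distance-decayed
sum S_g = Σ_peaks exp(−(0.5 + 4Δ)) with Δ = |distance| / 100 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from paraloverlap.decontrast import DEGSet

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signal", "pvalue", "qvalue", "summit"]


@dataclass
class PeakSet:
    """Genomic intervals, optionally with narrowPeak summit offsets."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need <= set(self.df.columns):
            raise ValueError(f"peak table needs columns {sorted(need)}")
        if len(self.df):
            if (self.df["start"] >= self.df["end"]).any():
                raise ValueError("intervals must satisfy start < end")
            if (self.df["start"] < 0).any():
                raise ValueError("coordinates must be non-negative")
            if "summit" in self.df.columns:
                s = self.df["summit"]
                ok = s.isna() | (s < 0) | ((s >= 0) & (s < self.df["end"] - self.df["start"]))
                if not ok.all():
                    raise ValueError("summit offsets must lie within the interval")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def positions(self) -> np.ndarray:
        """Representative position per peak: summit if present (≥0), else midpoint."""
        mid = (self.df["start"] + self.df["end"]) // 2
        if "summit" in self.df.columns:
            s = self.df["summit"]
            return np.where(s.fillna(-1) >= 0, self.df["start"] + s.fillna(-1), mid).astype(
                np.int64
            )
        return mid.to_numpy(dtype=np.int64)

    def names(self) -> pd.Series:
        if "name" in self.df.columns:
            return self.df["name"]
        return pd.Series([f"peak_{i}" for i in range(len(self.df))])


@dataclass
class TSSTable:
    """One primary transcription start site per gene."""

    df: pd.DataFrame  # gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "tss"}
        if not need <= set(self.df.columns):
            raise ValueError(f"TSS table needs columns {sorted(need)}")
        if "strand" not in self.df.columns:
            self.df = self.df.assign(strand="+")
        dup = self.df["gene_id"].duplicated()
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate TSS entries collapsed (first listed wins)",
                stacklevel=2,
            )
            self.df = self.df[~dup]
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_interval_lines(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _parse_bedlike(path, expect: str | None = None) -> pd.DataFrame:
    rows = _read_interval_lines(path)
    if not rows:
        return pd.DataFrame(columns=BED6_COLS)
    ncol = len(rows[0][1])
    if expect == "narrowPeak" and ncol != 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, found {ncol}")
    if ncol not in (3, 4, 5, 6, 10):
        raise ValueError(f"{path}: unsupported column count {ncol}")
    cols = NARROWPEAK_COLS[:ncol] if ncol != 10 else NARROWPEAK_COLS
    recs = []
    for lineno, fields in rows:
        if len(fields) != ncol:
            raise ValueError(f"{path}:{lineno}: inconsistent column count")
        rec = dict(zip(cols, fields))
        try:
            rec["start"] = int(rec["start"])
            rec["end"] = int(rec["end"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if rec["start"] >= rec["end"]:
            raise ValueError(f"{path}:{lineno}: start >= end")
        recs.append(rec)
    df = pd.DataFrame(recs)
    for c, typ in (("score", float), ("signal", float), ("pvalue", float),
                   ("qvalue", float), ("summit", int)):
        if c in df.columns:
            df[c] = df[c].astype(typ)
    if "strand" not in df.columns:
        df["strand"] = "."
    if "name" not in df.columns:
        df["name"] = [f"peak_{i:05d}" for i in range(len(df))]
    return df


def read_bed(path) -> PeakSet:
    """Read BED3/BED4/BED5/BED6 (dialect by column count)."""
    return PeakSet(_parse_bedlike(path))


def read_narrowpeak(path) -> PeakSet:
    """Read ENCODE narrowPeak (BED6+4); summit offsets become absolute via
    ``start + summit`` when used."""
    return PeakSet(_parse_bedlike(path, expect="narrowPeak"))


def read_peaks(path) -> PeakSet:
    """Auto-detect BED vs narrowPeak by column count."""
    return PeakSet(_parse_bedlike(path))


def read_tss(path) -> TSSTable:
    """Read a TSS table from BED6 (name = gene_id; TSS at start for +/.,
    end−1 for −) or a TSV with columns gene_id, chrom, tss[, strand]."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t")
        return TSSTable(df)
    bed = _parse_bedlike(path)
    tss = np.where(bed["strand"] == "-", bed["end"] - 1, bed["start"])
    return TSSTable(
        pd.DataFrame(
            {
                "gene_id": bed["name"],
                "chrom": bed["chrom"],
                "tss": tss,
                "strand": bed["strand"].replace(".", "+"),
            }
        )
    )


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.df.copy()
    for c in BED6_COLS:
        if c not in df.columns:
            df[c] = "." if c == "strand" else 0
    df[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    df = peaks.df.copy()
    defaults = {"name": ".", "score": 0, "strand": ".", "signal": 0.0,
                "pvalue": -1.0, "qvalue": -1.0, "summit": -1}
    for c, v in defaults.items():
        if c not in df.columns:
            df[c] = v
    df["summit"] = df["summit"].fillna(-1).astype(int)
    df[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_tss_bed(tss: TSSTable, path) -> None:
    df = tss.df
    start = np.where(df["strand"] == "-", df["tss"], df["tss"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": start,
            "end": start + 1,
            "name": df["gene_id"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# distances and linking
# ---------------------------------------------------------------------------


def _tss_by_chrom(tss: TSSTable):
    out = {}
    for chrom, sub in tss.df.groupby("chrom"):
        order = np.argsort(sub["tss"].to_numpy(), kind="stable")
        out[chrom] = (
            sub["tss"].to_numpy()[order],
            sub["gene_id"].to_numpy()[order],
            sub["strand"].to_numpy()[order],
        )
    return out


def tss_distance_annotation(
    peaks: PeakSet, tss: TSSTable, promoter_halfwidth: int = 5000
) -> tuple[pd.DataFrame, float]:
    """Annotate every peak with its nearest TSS and compute the promoter
    fraction (share of peaks within ±``promoter_halfwidth``, inclusive).

    Distance is signed relative to gene orientation: (position − TSS) × strand.
    Peaks on chromosomes without any TSS are excluded from the fraction's
    denominator.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    index = _tss_by_chrom(tss)
    missing = sorted(set(peaks.df["chrom"]) - set(index))
    if missing:
        warnings.warn(f"peak chromosomes without TSS entries: {missing}", stacklevel=2)
    pos = peaks.positions()
    rows = []
    for i in range(len(peaks)):
        chrom = peaks.df.loc[i, "chrom"]
        if chrom not in index:
            rows.append((None, np.nan, False))
            continue
        arr, genes, strands = index[chrom]
        k = int(np.searchsorted(arr, pos[i]))
        best, bestd = None, np.inf
        for j in (k - 1, k):
            if 0 <= j < len(arr) and abs(pos[i] - arr[j]) < bestd:
                bestd = abs(pos[i] - arr[j])
                best = j
        sign = -1 if strands[best] == "-" else 1
        dist = int(pos[i] - arr[best]) * sign
        rows.append((genes[best], dist, abs(dist) <= promoter_halfwidth))
    annot = peaks.df.copy()
    annot["nearest_gene"] = [r[0] for r in rows]
    annot["tss_distance"] = [r[1] for r in rows]
    annot["within_promoter"] = [r[2] for r in rows]
    denom = annot["nearest_gene"].notna().sum()
    frac = float(annot["within_promoter"].sum() / denom) if denom else float("nan")
    return annot, frac


def link_peaks_to_genes(
    peaks: PeakSet,
    tss: TSSTable,
    max_dist: int = 1_000_000,
    promoter_halfwidth: int = 5000,
    active_ids: set | None = None,
) -> pd.DataFrame:
    """All (gene, peak) pairs with |position − TSS| ≤ ``max_dist`` (inclusive).

    Columns: gene_id, peak_id, distance (signed by gene strand),
    within_promoter, active (True unless ``active_ids`` restricts it).
    """
    pos = peaks.positions()
    names = peaks.names()
    rows = []
    peaks_by_chrom: dict[str, list[int]] = {}
    for i, chrom in enumerate(peaks.df["chrom"]):
        peaks_by_chrom.setdefault(chrom, []).append(i)
    for _, g in tss.df.iterrows():
        idxs = peaks_by_chrom.get(g["chrom"], [])
        if not idxs:
            continue
        parr = pos[idxs]
        order = np.argsort(parr, kind="stable")
        sorted_pos = parr[order]
        lo = int(np.searchsorted(sorted_pos, g["tss"] - max_dist, side="left"))
        hi = int(np.searchsorted(sorted_pos, g["tss"] + max_dist, side="right"))
        sign = -1 if g["strand"] == "-" else 1
        for k in range(lo, hi):
            i = idxs[order[k]]
            dist = int(pos[i] - g["tss"]) * sign
            pid = names.iloc[i]
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "peak_id": pid,
                    "distance": dist,
                    "within_promoter": abs(dist) <= promoter_halfwidth,
                    "active": True if active_ids is None else pid in active_ids,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "peak_id", "distance", "within_promoter", "active"]
    )


def filter_active_peaks(peaks: PeakSet, marks: PeakSet) -> PeakSet:
    """Retain peaks overlapping any mark interval by ≥1 bp (half-open:
    [100,200) and [200,300) do not overlap)."""
    trees: dict[str, IntervalTree] = {}
    for _, m in marks.df.iterrows():
        trees.setdefault(m["chrom"], IntervalTree()).addi(m["start"], m["end"])
    keep = []
    for i, p in peaks.df.iterrows():
        tree = trees.get(p["chrom"])
        keep.append(bool(tree is not None and tree.overlap(p["start"], p["end"])))
    return PeakSet(peaks.df[np.array(keep, dtype=bool)].copy(), meta=dict(peaks.meta))


def classify_direct_targets(
    links: pd.DataFrame, degs: DEGSet
) -> tuple[int, int, pd.DataFrame]:
    """Split a factor's DEGs into direct (≥1 linked peak) and indirect.

    Returns (n_up_direct, n_down_direct, per-gene table).
    """
    linked = set(links["gene_id"])
    rows = []
    for g in sorted(degs.up):
        rows.append({"gene_id": g, "direction": "up", "direct": g in linked})
    for g in sorted(degs.down):
        rows.append({"gene_id": g, "direction": "down", "direct": g in linked})
    table = pd.DataFrame(rows, columns=["gene_id", "direction", "direct"])
    n_up = int(((table["direction"] == "up") & table["direct"]).sum())
    n_down = int(((table["direction"] == "down") & table["direct"]).sum())
    return n_up, n_down, table


def regulatory_potential(links: pd.DataFrame, gene_ids) -> pd.Series:
    """Distance-decayed binding score S_g = Σ_peaks exp(−(0.5 + 4Δ)),
    Δ = |distance| / 100 kb; genes without linked peaks score 0."""
    s = pd.Series(0.0, index=pd.Index(gene_ids, name="gene_id"))
    if len(links):
        w = np.exp(-(0.5 + 4.0 * np.abs(links["distance"].to_numpy()) / 1e5))
        contrib = pd.Series(w).groupby(links["gene_id"].to_numpy()).sum()
        common = s.index.intersection(contrib.index)
        s.loc[common] = contrib.loc[common]
    return s


@dataclass
class FunctionPrediction:
    activating_p: float
    repressive_p: float
    potentials: pd.Series
    n_up: int
    n_down: int
    n_background: int

    def to_dict(self) -> dict:
        return {
            "activating_p": self.activating_p,
            "repressive_p": self.repressive_p,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_background": self.n_background,
        }


def predict_tf_function(
    links: pd.DataFrame, de: pd.DataFrame, fdr_cut: float = 0.05, min_stratum: int = 5
) -> FunctionPrediction:
    """Do binding sites activate or repress transcription?

    Compares the regulatory potential of up- and downregulated genes
    (padj < ``fdr_cut``, no fold-change cutoff for power) against non-DE
    genes with one-sided two-sample KS tests: a small ``activating_p`` means
    upregulated genes carry systematically more nearby binding than
    background.
    """
    tested = de[de["tested"]]
    sig = tested["padj"] < fdr_cut
    up = tested.index[sig & (tested["log2fc"] > 0)]
    down = tested.index[sig & (tested["log2fc"] < 0)]
    bg = tested.index[~sig]
    s = regulatory_potential(links, tested.index)

    def one_sided(stratum) -> float:
        if len(stratum) < min_stratum or len(bg) < min_stratum:
            warnings.warn("stratum too small for KS test; skipped", stacklevel=2)
            return float("nan")
        # alternative='less': CDF of the stratum lies below background,
        # i.e. the stratum is stochastically larger
        return float(
            stats.ks_2samp(s.loc[stratum], s.loc[bg], alternative="less").pvalue
        )

    return FunctionPrediction(
        activating_p=one_sided(up),
        repressive_p=one_sided(down),
        potentials=s,
        n_up=len(up),
        n_down=len(down),
        n_background=len(bg),
    )
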