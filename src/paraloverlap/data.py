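"""Count-matrix container and the six-condition vocabulary.

The experimental design has two CRISPR systems (an activation/overexpression
system and a knockout system), each applied with guides targeting either
paralog or with non-targeting control guides:

    TF1-OE, TF2-OE, ctrl-OE   (CRISPRa system)
    TF1-KO, TF2-KO, ctrl-KO   (CRISPR-KO system)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = (
    "TF1-OE",
    "TF1-KO",
    "TF2-OE",
    "TF2-KO",
    "ctrl-OE",
    "ctrl-KO",
)

#: conditions belonging to each CRISPR system (stress effects are shared
#: within a system, which is what the combined contrast cancels)
OE_SYSTEM: tuple[str, ...] = ("TF1-OE", "TF2-OE", "ctrl-OE")
KO_SYSTEM: tuple[str, ...] = ("TF1-KO", "TF2-KO", "ctrl-KO")

TF_LABELS: tuple[str, ...] = ("TF1", "TF2")


def contrast_weights(tf_label: str) -> dict[str, float]:
    """Weights of the combined contrast (TF-OE − ctrl-OE) − (TF-KO − ctrl-KO)."""
    if tf_label not in TF_LABELS:
        raise ValueError(f"tf_label must be one of {TF_LABELS}, got {tf_label!r}")
    return {
        f"{tf_label}-OE": 1.0,
        "ctrl-OE": -1.0,
        f"{tf_label}-KO": -1.0,
        "ctrl-KO": 1.0,
    }


@dataclass
class CountMatrix:
    """Genes × samples integer counts with a sample→condition mapping.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample; finite
        non-negative integers.
    sample_sheet
        Series mapping sample id → condition label.  Every column of
        ``counts`` must be labelled; labels must come from :data:`CONDITIONS`
        (apply an alias map before construction if needed).
    """

    counts: pd.DataFrame
    sample_sheet: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene_ids must be unique")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                raise ValueError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.sample_sheet = self.sample_sheet.loc[list(self.counts.columns)]
        bad = set(self.sample_sheet.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(
                f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        return [s for s in self.counts.columns if self.sample_sheet[s] == condition]

    def condition_sizes(self) -> dict[str, int]:
        return {c: len(self.condition_samples(c)) for c in CONDITIONS}

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.sample_sheet.copy())


def read_counts(path) -> pd.DataFrame:
    """Read a gene × sample count table (TSV, gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_samples(path, alias: dict[str, str] | None = None) -> pd.Series:
    """Read a sample sheet CSV with columns ``sample_id,condition``."""
    df = pd.read_csv(path)
    if not {"sample_id", "condition"} <= set(df.columns):
        raise ValueError("sample sheet needs columns sample_id,condition")
    cond = df.set_index("sample_id")["condition"]
    if alias:
        cond = cond.replace(alias)
    return cond


def load_count_matrix(counts_path, samples_path, alias=None) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_samples(samples_path, alias))


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    sheet = pd.DataFrame(
        {"sample_id": cm.sample_sheet.index, "condition": cm.sample_sheet.values}
    )
    sheet.to_csv(samples_path, index=False)
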