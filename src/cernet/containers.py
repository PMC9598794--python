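"""Core in-memory containers for the pipeline.

All expression data travels as a :class:`CountMatrix` (integer counts,
features x samples, tagged with the RNA class and the high/low group of every
sample).  Genomic structure lives in a :class:`FeatureAnnotation` using
0-based half-open coordinates internally; GTF at the file boundary is 1-based
inclusive.  Sequences are plain RNA strings (ACGU) keyed by feature id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
GROUPS = ("high", "low")
SEQ_ROLES = ("utr3", "lncrna", "mirna_mature")

_RNA_ALPHABET = set("ACGUN")


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with sample group labels."""

    values: pd.DataFrame
    rna_class: str
    groups: dict[str, str]

    def __post_init__(self):
        bad: list[str] = []
        if self.rna_class not in RNA_CLASSES:
            bad.append(f"rna_class={self.rna_class!r} not in {RNA_CLASSES}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            bad.append(f"duplicate feature ids: {dups[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            bad.append("duplicate sample ids")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad.append("non-integer counts")
            else:
                self.values = self.values.round().astype(np.int64)
                vals = self.values.to_numpy()
        if vals.size and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            bad.append(f"negative count at feature {idx[r]!r}, sample {cols[c]!r}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            bad.append(f"samples without a group label: {missing}")
        for s, g in self.groups.items():
            if g not in GROUPS:
                bad.append(f"unknown group {g!r} for sample {s!r}")
        if bad:
            raise ValidationError("invalid CountMatrix: " + "; ".join(bad), bad)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class FeatureAnnotation:
    """Per-feature genomic interval (0-based half-open), exon count, spliced
    transcript length (bp) and biotype."""

    table: pd.DataFrame  # index: feature id; columns below

    COLUMNS = ("chrom", "start", "end", "strand", "exon_count", "length", "biotype")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}", missing)
        t = self.table
        bad = []
        if t.index.has_duplicates:
            bad.append("duplicate feature ids")
        if len(t):
            if (t["start"] >= t["end"]).any():
                ids = t.index[t["start"] >= t["end"]].tolist()
                bad.append(f"start >= end for {ids[:5]}")
            if (t["exon_count"] < 1).any():
                bad.append("exon_count < 1")
            if (t["length"] <= 0).any():
                bad.append("non-positive transcript length")
        if bad:
            raise ValidationError("invalid FeatureAnnotation: " + "; ".join(bad), bad)

    def __len__(self) -> int:
        return len(self.table)

    def interval(self, feature_id: str) -> tuple[str, int, int]:
        row = self.table.loc[feature_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])


@dataclass
class SequenceSet:
    """RNA sequences (ACGU) keyed by feature id, with a shared role tag."""

    sequences: dict[str, str]
    role: str

    def __post_init__(self):
        if self.role not in SEQ_ROLES:
            raise ValidationError(f"unknown sequence role {self.role!r}")
        for fid, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty sequence for {fid!r}")
            extra = set(seq) - _RNA_ALPHABET
            if extra:
                raise ValidationError(
                    f"illegal characters {sorted(extra)} in sequence {fid!r}"
                )
            if self.role == "mirna_mature" and not 18 <= len(seq) <= 26:
                raise ValidationError(
                    f"mature miRNA {fid!r} length {len(seq)} outside [18, 26]"
                )

    def __getitem__(self, fid: str) -> str:
        return self.sequences[fid]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class SampleTable:
    """Sample phenotypes: group label plus IMF percentage (and optional
    covariates as extra columns)."""

    table: pd.DataFrame  # index: sample id; columns: group, imf_percent, ...

    def __post_init__(self):
        if "group" not in self.table.columns:
            raise ValidationError("sample table needs a 'group' column")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown groups {sorted(bad)}")

    def group_map(self) -> dict[str, str]:
        return dict(self.table["group"])

    def require_two_groups(self):
        counts = self.table["group"].value_counts()
        if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
            raise ValidationError("both groups must be non-empty")


@dataclass
class NormalizedMatrix:
    """Normalized expression values with provenance of the transform."""

    values: pd.DataFrame  # features x samples, non-negative reals
    size_factors: pd.Series  # per sample, positive
    transform: str = "none"  # "none" | "vst-proxy"

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")
        if self.transform not in ("none", "vst-proxy"):
            raise ValidationError(f"unknown transform tag {self.transform!r}")


@dataclass
class DEResult:
    """Per-feature differential-expression summary."""

    feature_id: str
    rna_class: str
    base_mean: float
    log2fc: float
    p: float
    padj: float
    call: str = "ns"  # "up" | "down" | "ns"


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results (id-indexed; columns baseMean, log2fc, p, padj, call)."""
    return pd.DataFrame(
        {
            "baseMean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
            "call": [r.call for r in results],
        },
        index=pd.Index([r.feature_id for r in results], name="id"),
    )
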