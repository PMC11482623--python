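"""Spike-in quantification: counting, TPM/CPM, linearity, detection,
downsampling and replicate correlation.

TPM (transcripts per million) is the length-normalized abundance
``tpm_i = 1e6 * (count_i / length_kb_i) / sum_j (count_j / length_kb_j)``;
CPM is the depth-normalized count ``1e6 * count_i / sum(counts)``.  Both sum
to 1e6 whenever any count is nonzero.  Linearity of a spike-in experiment is
judged by ordinary least squares of log2(TPM) on log2(known concentration)
over the detected (TPM > 0) transcripts, together with the detected dynamic
range in decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TranscriptLadder",
    "LinearityResult",
    "count_reads",
    "tpm",
    "cpm",
    "expression_table",
    "linearity_assessment",
    "downsample_counts",
    "detected_count",
    "replicate_correlation",
]


@dataclass
class TranscriptLadder:
    """A spike-in transcript set: ids, lengths (nt), relative concentrations.

    ``group`` labels each transcript as ercc_like or sirv_like; an optional
    ``sequences`` list enables FASTA emission of simulated reads.
    """

    transcript_ids: list
    lengths: np.ndarray
    concentrations: np.ndarray
    groups: list
    sequences: list | None = None

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        n = len(self.transcript_ids)
        if not (self.lengths.size == self.concentrations.size == len(self.groups) == n):
            raise ValueError("all ladder columns must have equal length")
        if len(set(self.transcript_ids)) != n:
            raise ValueError("transcript ids must be unique")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be positive")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if n >= 2 and np.unique(self.concentrations).size < 2:
            raise ValueError("ladder needs at least 2 distinct concentrations")
        if self.sequences is not None and len(self.sequences) != n:
            raise ValueError("sequences must have one entry per transcript")

    def __len__(self) -> int:
        return len(self.transcript_ids)

    def sequence_map(self) -> dict:
        if self.sequences is None:
            return {}
        return dict(zip(self.transcript_ids, self.sequences))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "transcript_id": self.transcript_ids,
                "length_nt": self.lengths,
                "concentration": self.concentrations,
                "group": self.groups,
            }
        )
        if self.sequences is not None:
            df["sequence"] = self.sequences
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TranscriptLadder":
        seqs = df["sequence"].tolist() if "sequence" in df.columns else None
        return cls(
            df["transcript_id"].tolist(),
            df["length_nt"].to_numpy(),
            df["concentration"].to_numpy(),
            df["group"].tolist(),
            sequences=seqs,
        )

    @classmethod
    def from_tsv(cls, path) -> "TranscriptLadder":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class LinearityResult:
    slope: float
    intercept: float
    pearson_r: float
    dynamic_range_log10: float
    n_detected: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "dynamic_range_log10": self.dynamic_range_log10,
            "n_detected": self.n_detected,
        }


def count_reads(reads, ladder: TranscriptLadder) -> pd.Series:
    """Exact per-transcript read tally (zero-filled over the whole ladder).

    ``reads`` may be ReadRecord objects, FASTA truth headers (``id|copies|mod``)
    or bare transcript ids.
    """
    ids = []
    for r in reads:
        if hasattr(r, "transcript_id"):
            ids.append(r.transcript_id)
        else:
            ids.append(str(r).split("|")[0])
    known = set(ladder.transcript_ids)
    unknown = sorted({i for i in ids if i not in known})
    if unknown:
        raise KeyError(f"reads reference unknown transcripts: {unknown[:10]}")
    tally = pd.Series(ids, dtype=object).value_counts()
    return tally.reindex(ladder.transcript_ids, fill_value=0).astype(int)


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million; accepts integer or expected (float) counts."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / (lengths / 1000.0)
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def cpm(counts) -> np.ndarray:
    """Counts per million; all-zero input maps to all zeros."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    return 1e6 * counts / total


def expression_table(counts, ladder: TranscriptLadder) -> pd.DataFrame:
    """Assemble the per-transcript expression table (count, tpm, cpm)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size != len(ladder):
        raise ValueError("one count per ladder transcript required")
    return pd.DataFrame(
        {
            "transcript_id": ladder.transcript_ids,
            "count": counts,
            "tpm": tpm(counts, ladder.lengths),
            "cpm": cpm(counts),
        }
    ).set_index("transcript_id")


def linearity_assessment(table: pd.DataFrame,
                         ladder: TranscriptLadder) -> LinearityResult:
    """OLS of log2(TPM) on log2(concentration) over detected transcripts.

    Zeros are excluded (regression on TPM > 0 only); the detected dynamic
    range is log10(max/min concentration) among detected transcripts.
    """
    t = table["tpm"].reindex(ladder.transcript_ids).to_numpy()
    conc = ladder.concentrations
    detected = t > 0
    if detected.sum() < 3:
        raise ValueError("need at least 3 detected transcripts")
    x = np.log2(conc[detected])
    y = np.log2(t[detected])
    fit = stats.linregress(x, y)
    dr = float(np.log10(conc[detected].max() / conc[detected].min()))
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        dynamic_range_log10=dr,
        n_detected=int(detected.sum()),
    )


def downsample_counts(counts, n_target: int, seed: int = 0) -> np.ndarray:
    """Subsample reads without replacement (multivariate hypergeometric)."""
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        as_int = counts.astype(np.int64)
        if np.any(as_int != counts):
            raise ValueError("downsampling requires integer counts")
        counts = as_int
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if n_target > total:
        raise ValueError(f"n_target {n_target} exceeds total reads {total}")
    if n_target < 0:
        raise ValueError("n_target must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, n_target)


def detected_count(table: pd.DataFrame, metric: str = "tpm",
                   threshold: float = 0.0) -> int:
    """Number of transcripts with metric strictly above the threshold."""
    if metric not in ("tpm", "cpm", "count"):
        raise ValueError("metric must be 'tpm', 'cpm' or 'count'")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return int((table[metric] > threshold).sum())


def replicate_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          metric: str = "tpm") -> float:
    """Pearson r of log2(metric + 1) across the shared transcript universe."""
    if metric not in ("tpm", "cpm", "count"):
        raise ValueError("metric must be 'tpm', 'cpm' or 'count'")
    if set(table_a.index) != set(table_b.index):
        raise ValueError("tables must share the same transcript universe")
    a = np.log2(table_a[metric].sort_index().to_numpy() + 1.0)
    b = np.log2(table_b[metric].sort_index().to_numpy() + 1.0)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in a replicate")
    return float(np.corrcoef(a, b)[0, 1])
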