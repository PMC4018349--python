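"""RPKM quantification and the eyestalk-vs-brain expression contrast.

Expression is summarised as RPKM (reads mapped to the transcript, per
kilobase of transcript, per million reads in the library):

    rpkm = counts * 1e9 / (length_nt * lib_size)

The tissue contrast is a one-way ANOVA on untransformed RPKM with the two
pooled-sex libraries per tissue as replicates (n = 2 vs n = 2; with two
groups this is the pooled two-sided t-test). A log2(x+1) transform is
available but off by default. No multiple-testing correction is applied.
With a single male and a single female library per tissue, a male-vs-female
contrast has n = 1 per group and is refused rather than computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionRecord",
    "compute_rpkm",
    "rpkm_matrix",
    "tissue_contrast",
    "summarize",
]

TISSUES = ("brain", "eyestalk")


@dataclass(frozen=True)
class SampleInfo:
    name: str
    tissue: str  # brain | eyestalk
    sex: str  # M | F

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class CountMatrix:
    """Per-transcript read counts for a set of libraries.

    ``counts`` is a samples x transcripts DataFrame of non-negative integers;
    ``lib_size`` the total mapped reads per library (at least the column sum
    attributable to these transcripts); ``lengths`` transcript lengths in nt.
    """

    samples: list[SampleInfo]
    counts: pd.DataFrame
    lib_size: dict[str, int]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if list(self.counts.index) != names:
            raise ValueError("counts rows must match sample order")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integral")
        for name in names:
            if self.lib_size[name] < int(self.counts.loc[name].sum()):
                raise ValueError(
                    f"library size of {name} smaller than its mapped counts"
                )


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    rpkm: dict[str, float]
    brain_mean: float
    eyestalk_mean: float
    p_value: float
    significant: bool
    testable: bool = True


def compute_rpkm(counts: float, length_nt: int, lib_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt < 1:
        raise ValueError("transcript length must be >= 1 nt")
    if lib_size < 1:
        raise ValueError("library size must be >= 1 read")
    return counts * 1e9 / (length_nt * lib_size)


def rpkm_matrix(matrix: CountMatrix) -> pd.DataFrame:
    """RPKM for every (sample, transcript) of a count matrix."""
    out = {}
    for tid in matrix.counts.columns:
        length = matrix.lengths[tid]
        out[tid] = [
            compute_rpkm(matrix.counts.at[s.name, tid], length, matrix.lib_size[s.name])
            for s in matrix.samples
        ]
    return pd.DataFrame(out, index=[s.name for s in matrix.samples])


def tissue_contrast(
    brain: np.ndarray | list,
    eyestalk: np.ndarray | list,
    alpha: float = 0.05,
    log2_transform: bool = False,
) -> tuple[float, bool]:
    """One-way ANOVA (two groups = pooled t-test) on per-tissue RPKM values.

    Returns (p_value, significant-at-alpha). Both groups need at least two
    values. When both groups are constant and equal the contrast is null by
    construction and p = 1; constant but different groups give p = 0.
    """
    brain = np.asarray(brain, dtype=float)
    eyestalk = np.asarray(eyestalk, dtype=float)
    if len(brain) < 2 or len(eyestalk) < 2:
        raise ValueError("each tissue group needs >= 2 values for the contrast")
    if log2_transform:
        brain = np.log2(brain + 1.0)
        eyestalk = np.log2(eyestalk + 1.0)
    if np.ptp(brain) == 0 and np.ptp(eyestalk) == 0:
        p = 1.0 if brain[0] == eyestalk[0] else 0.0
    else:
        _, p = stats.f_oneway(brain, eyestalk)
        p = float(p)
        if np.isnan(p):  # degenerate within-group variance
            p = 1.0 if np.mean(brain) == np.mean(eyestalk) else 0.0
    return p, bool(p < alpha)


def quantify(
    matrix: CountMatrix, alpha: float = 0.05, log2_transform: bool = False
) -> list[ExpressionRecord]:
    """RPKM + tissue contrast for every transcript of a count matrix."""
    rpkm = rpkm_matrix(matrix)
    by_tissue = {
        t: [s.name for s in matrix.samples if s.tissue == t] for t in TISSUES
    }
    records = []
    for tid in rpkm.columns:
        brain = rpkm.loc[by_tissue["brain"], tid].to_numpy()
        eyestalk = rpkm.loc[by_tissue["eyestalk"], tid].to_numpy()
        testable = len(brain) >= 2 and len(eyestalk) >= 2
        if testable:
            p, sig = tissue_contrast(brain, eyestalk, alpha, log2_transform)
        else:
            p, sig = float("nan"), False
        records.append(
            ExpressionRecord(
                transcript_id=tid,
                rpkm=dict(zip(rpkm.index, rpkm[tid])),
                brain_mean=float(brain.mean()) if len(brain) else float("nan"),
                eyestalk_mean=float(eyestalk.mean()) if len(eyestalk) else float("nan"),
                p_value=p,
                significant=sig,
                testable=testable,
            )
        )
    return records


def summarize(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Per-transcript report: four sample RPKMs, tissue means, significance."""
    rows = []
    for r in records:
        row = {"transcript": r.transcript_id}
        row.update({f"rpkm_{k}": v for k, v in r.rpkm.items()})
        row.update(
            {
                "br_mean": round(r.brain_mean, 2),
                "es_mean": round(r.eyestalk_mean, 2),
                "p_value": r.p_value,
                "significant": r.significant if r.testable else "untestable",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
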