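"""Count-matrix containers, TMM normalisation, CPM, and the expression filter.

Libraries from the 2 diet x 2 fraction polysome-profiling design differ in
depth and in RNA composition, so between-sample normalisation uses the
trimmed mean of M-values (TMM): per-sample scaling factors computed from
doubly trimmed, precision-weighted log-ratios against a reference sample.
Expression is reported as counts per million (CPM) over the TMM-effective
library size, and genes are considered reliably quantifiable when their
mean CPM across all samples is at least 8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import DIETS, FRACTIONS, GROUPS

__all__ = [
    "SampleDesign",
    "CountMatrix",
    "tmm_factors",
    "cpm_matrix",
    "filter_quantifiable",
]

CPM_THRESHOLD = 8.0


@dataclass
class SampleDesign:
    """Maps each sample to its (diet, fraction, replicate) cell.

    ``table`` has columns sample, diet (AL/DR), fraction (TO/TR),
    replicate.  The full 2x2 design with >= 2 replicates per group is
    required.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "diet", "fraction", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        bad_diet = set(self.table["diet"]) - set(DIETS)
        bad_frac = set(self.table["fraction"]) - set(FRACTIONS)
        if bad_diet or bad_frac:
            raise ValueError(f"unknown diet/fraction labels: {bad_diet | bad_frac}")
        sizes = self.table.groupby(["diet", "fraction"]).size()
        if len(sizes) != 4 or (sizes < 2).any():
            raise ValueError("full 2x2 design with >= 2 replicates per group required")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def group_of(self) -> pd.Series:
        """Sample -> group label (e.g. ``DR_TR``)."""
        g = self.table["diet"] + "_" + self.table["fraction"]
        return pd.Series(g.values, index=self.table["sample"].values)

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        diet, frac = group.split("_")
        m = (self.table["diet"] == diet) & (self.table["fraction"] == frac)
        return list(self.table.loc[m, "sample"])


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix plus its design."""

    counts: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if list(self.counts.columns) != self.design.samples:
            missing = set(self.design.samples) ^ set(self.counts.columns)
            if missing:
                raise ValueError(f"samples mismatch between counts and design: {missing}")
            self.counts = self.counts[self.design.samples]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample, M (log2 ratio vs the reference, library-size scaled)
    and A (average log2 abundance) are computed over genes nonzero in both;
    the most extreme ``logratio_trim`` of M and ``abundance_trim`` of A are
    dropped from each tail, and the factor is 2**(precision-weighted mean M).
    The reference defaults to the sample whose upper-quartile expression is
    closest to the across-sample mean upper quartile.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"all-zero sample(s): {zero}")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    props = counts.values / lib.values
    if reference_sample is None:
        uq = np.array([np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0 for c in props.T])
        reference_sample = counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    ref = counts[reference_sample].values.astype(float)
    ref_lib = lib[reference_sample]

    factors = {}
    for s in counts.columns:
        obs = counts[s].values.astype(float)
        obs_lib = lib[s]
        keep = (obs > 0) & (ref > 0)
        if s == reference_sample or keep.sum() == 0:
            factors[s] = 1.0
            continue
        p_obs, p_ref = obs[keep] / obs_lib, ref[keep] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M; weights are reciprocals
        w = (obs_lib - obs[keep]) / (obs_lib * obs[keep]) + (ref_lib - ref[keep]) / (
            ref_lib * ref[keep]
        )
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if sel.sum() == 0:
            factors[s] = 1.0
            continue
        f = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
        factors[s] = float(f) if np.isfinite(f) else 1.0

    fac = pd.Series(factors)[counts.columns]
    fac /= np.exp(np.mean(np.log(fac)))
    return fac


def cpm_matrix(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over (optionally TMM-adjusted) library sizes.

    ``log=True`` returns log2(CPM) with ``prior_count`` added to the scaled
    counts before the log.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        if (np.asarray(factors) <= 0).any():
            raise ValueError("factors must be positive")
        lib = lib * factors[counts.columns]
    if (lib == 0).any():
        raise ValueError("zero effective library size")
    cpm = counts / lib * 1e6
    if log:
        cpm = np.log2(cpm + prior_count * 1e6 / lib.mean())
    return cpm


def filter_quantifiable(cpm: pd.DataFrame, threshold: float = CPM_THRESHOLD) -> pd.Index:
    """Genes whose mean CPM across all samples is >= ``threshold``.

    The boundary is inclusive; input gene order is preserved.
    """
    keep = cpm.mean(axis=1) >= threshold
    return cpm.index[keep]
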