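"""Microsatellite diversity statistics and resampling standardisations.

Five per-locus statistics drive the ABC inference, each averaged across
loci: allelic richness k, allele size range r, Nei gene diversity He,
the M-ratio M = k/(r+1), and the proportion of low-frequency alleles
(sample frequency strictly below 5%).  Observed heterozygosity Ho is
additionally reported for diversity tables.

Two resampling standardisations make panels with very different sample
sizes comparable: diversity reporting resamples 10 individuals with
replacement 1000 times (mean and 95% CI), and the ABC observables
resample 40 individuals with replacement 1000 times (mean summary
vector).  Datasets smaller than the resample size are used in full,
unsampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

STAT_NAMES = ("k", "size_range", "he", "m_ratio", "lfa")


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n_typed: int
    k: int
    size_range: int
    ho: float
    he: float
    m_ratio: float
    lfa: float


@dataclass(frozen=True)
class SummaryVector:
    """Mean over loci of (k, size_range, He, M, lfa)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (5,):
            raise ValueError("SummaryVector must have exactly 5 entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite summary statistic")
        object.__setattr__(self, "values", v)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(STAT_NAMES))

    def __getitem__(self, name: str) -> float:
        return float(self.values[STAT_NAMES.index(name)])


@dataclass
class StandardizedDiversity:
    """Resampled diversity summary: mean and 95% CI per statistic.

    ``table`` rows are statistics (ho, ar, he, lfa) with columns
    mean, ci_low, ci_high.
    """

    table: pd.DataFrame
    n_ind_resampled: int
    n_reps: int


def _nei_he(counts: np.ndarray, unbiased: bool) -> float:
    n2 = counts.sum()
    if n2 == 0:
        return 0.0
    p = counts / n2
    he = 1.0 - float(np.sum(p * p))
    if unbiased and n2 > 1:
        he *= n2 / (n2 - 1.0)
    return he


def locus_stats(
    ds: GenotypeDataset, locus: str, unbiased: bool = True
) -> LocusStats:
    """Per-locus diversity statistics with pairwise deletion of missing
    genotypes.  A monomorphic locus is valid: He = Ho = 0, M = 1.

    He defaults to the unbiased Nei estimator (2n/(2n-1))(1 - sum p^2)
    over gene copies; set ``unbiased=False`` for the plug-in form.  The
    M-ratio is meaningful on repeat-unit encoding (convert bp data with
    :func:`msatbot.genotype_io.to_repeat_units` first).
    """
    j = ds.locus_index(locus)
    g = ds.calls[:, j, :]
    typed = g[g[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        raise ValueError(f"locus {locus}: no non-missing genotypes")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    k = alleles.size
    r = int(alleles.max() - alleles.min())
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    he = _nei_he(counts, unbiased)
    freqs = counts / counts.sum()
    lfa = float(np.sum(freqs < 0.05)) / k
    return LocusStats(locus, n, k, r, ho, he, k / (r + 1.0), lfa)


def locus_stats_table(ds: GenotypeDataset, unbiased: bool = True) -> pd.DataFrame:
    """All per-locus statistics as one DataFrame (CSV-exportable)."""
    rows = [locus_stats(ds, l.id, unbiased) for l in ds.loci]
    return pd.DataFrame([r.__dict__ for r in rows])


def mean_sumstats(ds: GenotypeDataset, unbiased: bool = True) -> SummaryVector:
    """Dataset summary vector: arithmetic mean of per-locus statistics."""
    if ds.n_loci == 0:
        raise ValueError("dataset has no loci")
    tab = locus_stats_table(ds, unbiased)
    return SummaryVector(
        tab[["k", "size_range", "he", "m_ratio", "lfa"]].mean().to_numpy()
    )


def _resample_matrix(
    calls: np.ndarray, n_ind: int, n_reps: int, rng: np.random.Generator,
    unbiased: bool,
) -> np.ndarray:
    """(n_reps, n_loci, 6) array of per-locus (k, r, he, m, lfa, ho) for
    resampled individual sets; loci with no typed individual in a
    resample contribute NaN and are skipped in the means."""
    n_total, n_loci, _ = calls.shape
    out = np.full((n_reps, n_loci, 6), np.nan)
    for rep in range(n_reps):
        idx = rng.integers(0, n_total, size=n_ind)
        sub = calls[idx]
        for j in range(n_loci):
            g = sub[:, j, :]
            typed = g[g[:, 0] != MISSING]
            if typed.shape[0] == 0:
                continue
            alleles, counts = np.unique(typed.ravel(), return_counts=True)
            k = alleles.size
            r = alleles.max() - alleles.min()
            freqs = counts / counts.sum()
            out[rep, j, 0] = k
            out[rep, j, 1] = r
            out[rep, j, 2] = _nei_he(counts, unbiased)
            out[rep, j, 3] = k / (r + 1.0)
            out[rep, j, 4] = np.sum(freqs < 0.05) / k
            out[rep, j, 5] = np.mean(typed[:, 0] != typed[:, 1])
    return out


def resampled_stats(
    ds: GenotypeDataset,
    n_ind: int,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    kind: str = "sumstats",
    unbiased: bool = True,
):
    """Resampling standardisation of diversity statistics.

    ``kind="sumstats"`` returns the mean :class:`SummaryVector` over
    ``n_reps`` resamples of ``n_ind`` individuals drawn with
    replacement (the ABC observable, default 40 individuals).
    ``kind="diversity"`` returns a :class:`StandardizedDiversity` with
    mean and 2.5/97.5-percentile CI of Ho, allelic richness, He and the
    low-frequency-allele proportion (default use: 10 individuals).

    If the dataset holds fewer than ``n_ind`` individuals the full
    dataset is used once, unsampled.
    """
    if n_ind <= 0:
        raise ValueError("n_ind must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if kind not in ("sumstats", "diversity"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(rng)

    if ds.n_individuals < n_ind:
        stats = _resample_full(ds, unbiased)
        per_rep = stats[None, :, :]
        n_reps_eff = 1
    else:
        per_rep = _resample_matrix(ds.calls, n_ind, n_reps, rng, unbiased)
        n_reps_eff = n_reps

    # mean across loci within a resample, then across resamples
    rep_means = np.nanmean(per_rep, axis=1)  # (n_reps, 6)
    if kind == "sumstats":
        return SummaryVector(rep_means[:, :5].mean(axis=0))
    cols = {"ho": 5, "ar": 0, "he": 2, "lfa": 4}
    rows = {}
    for name, c in cols.items():
        v = rep_means[:, c]
        rows[name] = (
            float(np.mean(v)),
            float(np.percentile(v, 2.5)),
            float(np.percentile(v, 97.5)),
        )
    table = pd.DataFrame(rows, index=["mean", "ci_low", "ci_high"]).T
    return StandardizedDiversity(table, n_ind, n_reps_eff)


def _resample_full(ds: GenotypeDataset, unbiased: bool) -> np.ndarray:
    tab = locus_stats_table(ds, unbiased)
    return tab[["k", "size_range", "he", "m_ratio", "lfa", "ho"]].to_numpy()
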