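"""Cornuet-Luikart heterozygosity-excess test.

During a recent decline, allele number drops faster than gene
diversity, so observed heterozygosity He transiently exceeds the
equilibrium heterozygosity H_eq expected for the observed allele
number.  Per locus, H_eq is the mean heterozygosity of coalescent
simulations of a constant-size population conditioned to carry exactly
the observed number of alleles; the dataset-level statistic
prop_het-exc is the fraction of polymorphic loci with He > H_eq, with
0.5 the expectation for a demographically stable population (> 0.5
suggests decline, < 0.5 expansion).

Mutation models: strict SMM (all steps one repeat), two-phase models
(TPM) mixing single steps with geometric multi-step jumps of a given
variance (default 0.30), and the generalized stepwise model (GSM).
Presets SMM / TPM70 / TPM80 / TPM90 match common practice (70-90%
single-step mutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .genotype_io import MISSING, GenotypeDataset
from .sumstats import _nei_he


@dataclass(frozen=True)
class MutationModelSpec:
    """A microsatellite mutation step-size model.

    kind="SMM": every step is one repeat unit.
    kind="TPM": with probability ``p_single`` the step is one unit,
    otherwise geometric with parameter q solving (1-q)/q^2 =
    ``geometric_variance`` on support {1, 2, ...}.
    kind="GSM": step magnitude geometric with P(S=s) = (1-g) g^(s-1),
    g = ``gsm_par`` the proportion of multistep mutations.
    """

    kind: str
    p_single: float | None = None
    geometric_variance: float | None = None
    gsm_par: float | None = None

    def __post_init__(self):
        if self.kind not in ("SMM", "TPM", "GSM"):
            raise ValueError(f"unknown mutation model kind {self.kind!r}")
        if self.kind == "TPM":
            if self.p_single is None or not 0 <= self.p_single <= 1:
                raise ValueError("TPM needs p_single in [0, 1]")
            if self.geometric_variance is None or self.geometric_variance < 0:
                raise ValueError("TPM needs geometric_variance >= 0")
        if self.kind == "GSM":
            if self.gsm_par is None or not 0 <= self.gsm_par <= 1:
                raise ValueError("GSM needs gsm_par in [0, 1]")

    def kernel_params(self) -> tuple[float, float]:
        """(p_single, pi_geom) for the simulation kernels, where the
        multistep magnitude is geometric with success probability
        pi_geom: P(S = s) = pi (1 - pi)^(s-1)."""
        if self.kind == "SMM":
            return 1.0, 1.0
        if self.kind == "GSM":
            return 0.0, 1.0 - self.gsm_par
        return self.p_single, geometric_param_from_variance(
            self.geometric_variance
        )

    @property
    def label(self) -> str:
        if self.kind == "TPM":
            return f"TPM{round(100 * self.p_single)}"
        if self.kind == "GSM":
            return f"GSM{self.gsm_par:g}"
        return "SMM"


def geometric_param_from_variance(variance: float) -> float:
    """Success probability q of the geometric step distribution with a
    given variance: solves (1 - q)/q^2 = variance; variance 0 gives
    q = 1 (all steps size one)."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return 1.0
    q = (-1.0 + np.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)
    return float(q)


def tpm_spec(p_single: float, variance: float = 0.30) -> MutationModelSpec:
    """Two-phase model with the given single-step proportion and
    multistep geometric variance (default 0.30)."""
    return MutationModelSpec("TPM", p_single=p_single,
                             geometric_variance=variance)


SMM = MutationModelSpec("SMM")
TPM70 = tpm_spec(0.70)
TPM80 = tpm_spec(0.80)
TPM90 = tpm_spec(0.90)
DEFAULT_MODELS = (SMM, TPM70, TPM80, TPM90)


@dataclass
class HetExcessResult:
    """Per-locus He vs H_eq comparison and the dataset proportion.

    ``table`` columns: locus, n_copies, k, he_obs, heq_mean, heq_sd,
    excess.  ``prop_het_exc`` is the fraction of polymorphic loci in
    excess; monomorphic loci are excluded.
    """

    table: pd.DataFrame
    prop_het_exc: float
    model: MutationModelSpec
    n_sims: int
    criterion: str

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["model"] = self.model.label
        out["prop_het_exc"] = self.prop_het_exc
        out.to_csv(path, index=False)


def calibrate_theta(
    n_copies: int,
    k: int,
    model: MutationModelSpec,
    rng: np.random.Generator | None = None,
    n_pilot: int = 400,
    n_iter: int = 18,
) -> float:
    """Scaled mutation rate theta = 4 N mu whose expected allele count
    in a sample of ``n_copies`` gene copies equals ``k`` under the
    model, found by bisection on log(theta) against Monte-Carlo pilot
    simulations (the allele count is monotone in theta)."""
    if not 2 <= k <= n_copies:
        raise ValueError("need 2 <= k <= n_copies")
    rng = np.random.default_rng(rng)
    p_single, pi_geom = model.kernel_params()
    lo, hi = 1e-3, 1e4
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        mean_k = _kernels.mean_allele_count(
            n_copies, mid, p_single, pi_geom, n_pilot,
            int(rng.integers(1, 2**31 - 1)),
        )
        if mean_k < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def heq_simulate(
    n_copies: int,
    k: int,
    model: MutationModelSpec,
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
    unbiased: bool = True,
    theta: float | None = None,
) -> np.ndarray:
    """Equilibrium-heterozygosity draws conditional on allele number.

    Follows the Cornuet-Luikart conditioning: theta is first calibrated
    so that the expected allele count of a constant-size sample equals
    the observed ``k`` (see :func:`calibrate_theta`), then loci are
    simulated unconditionally at that theta and the Nei heterozygosity
    of replicates segregating exactly ``k`` alleles is retained, one
    per draw.  A draw failing to hit ``k`` within ``max_attempts``
    simulations raises (with theta matched to k this is vanishingly
    rare).
    """
    if not 2 <= k <= n_copies:
        raise ValueError("need 2 <= k <= n_copies")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    p_single, pi_geom = model.kernel_params()
    if theta is None:
        theta = calibrate_theta(n_copies, k, model, rng)
    seed = int(rng.integers(1, 2**31 - 1))
    draws = _kernels.heq_draws(
        n_copies, k, theta, p_single, pi_geom, n_sims, max_attempts,
        unbiased, seed,
    )
    n_bad = int(np.isnan(draws).sum())
    if n_bad:
        raise RuntimeError(
            f"H_eq simulation failed for {n_bad}/{n_sims} draws "
            f"(n_copies={n_copies}, k={k}, model={model.label}); "
            "increase max_attempts"
        )
    return draws


def prop_het_excess(
    ds: GenotypeDataset,
    model: MutationModelSpec = TPM80,
    n_sims: int = 10_000,
    rng: np.random.Generator | None = None,
    criterion: str = "median",
    unbiased: bool = True,
) -> HetExcessResult:
    """Heterozygosity-excess test for one dataset under one mutation
    model.

    A polymorphic locus is in excess when its observed gene diversity
    exceeds the median of its H_eq draws (``criterion="mean"`` compares
    against the mean instead; the median is the default because
    P(He > median H_eq) = 1/2 exactly for a stable population, whereas
    the left skew of the conditional H_eq distribution pushes the
    mean-based rate above 1/2 even under a perfectly matched model).  H_eq draws are shared between loci with identical
    (gene-copy count, allele count) since the conditional distribution
    depends on nothing else.
    """
    if criterion not in ("mean", "median"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = np.random.default_rng(rng)
    cache: dict[tuple[int, int], np.ndarray] = {}
    rows = []
    for loc in ds.loci:
        j = ds.locus_index(loc.id)
        g = ds.calls[:, j, :]
        typed = g[g[:, 0] != MISSING]
        n2 = 2 * typed.shape[0]
        alleles, counts = np.unique(typed.ravel(), return_counts=True)
        k = alleles.size
        if k < 2:
            continue
        he_obs = _nei_he(counts, unbiased)
        key = (n2, k)
        if key not in cache:
            cache[key] = heq_simulate(n2, k, model, n_sims, rng,
                                      unbiased=unbiased)
        draws = cache[key]
        center = float(np.mean(draws)) if criterion == "mean" \
            else float(np.median(draws))
        rows.append((loc.id, n2, k, he_obs, float(np.mean(draws)),
                     float(np.std(draws)), he_obs > center))
    if not rows:
        raise ValueError("no polymorphic locus: prop_het-exc undefined")
    table = pd.DataFrame(
        rows, columns=["locus", "n_copies", "k", "he_obs", "heq_mean",
                       "heq_sd", "excess"],
    )
    prop = float(table["excess"].mean())
    return HetExcessResult(table, prop, model, n_sims, criterion)
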