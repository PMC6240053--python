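"""Single-population coalescent with piecewise-constant size and
generalized stepwise microsatellite mutation.

Two demographies are contrasted.  The *bottleneck* model has three
epochs looking backwards in time: present size N_e until t_bot_end,
bottleneck size N_e_bot until t_bot_start, then the historical size
N_e_hist.  The *non-bottleneck* model has present size N_e switching
instantaneously to N_e_hist at t_hist.  All size changes are
instantaneous; times are in generations.

Default priors: N_e and N_e_hist ~ lognormal(logmean 10.5, logsd 1)
(median exp(10.5) ~ 36,000 diploids), N_e_bot ~ U[1, 500],
t_bot_start ~ U[10, 70], t_bot_end ~ U[1, 30] (jointly constrained to
t_bot_end < t_bot_start by rejection), t_hist ~ U[10, 70],
mu ~ U[1e-5, 1e-4] mutations/locus/generation, GSM_par ~ U[0, 0.3].

Mutation follows a generalized stepwise model: mutation count on a
branch is Poisson(mu x branch length); each mutation moves the allele
by a signed step whose magnitude is geometric,
P(S = s) = (1-g) g^(s-1) for s >= 1, so the GSM parameter g is exactly
the proportion of multistep (|step| >= 2) mutations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _kernels
from .genotype_io import GenotypeDataset, Locus

BOTTLENECK = "bottleneck"
NON_BOTTLENECK = "non_bottleneck"
MODEL_KINDS = (BOTTLENECK, NON_BOTTLENECK)

PARAM_NAMES = ("ne", "ne_hist", "ne_bot", "t_bot_start", "t_bot_end",
               "t_hist", "mu", "gsm_par")


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


@dataclass(frozen=True)
class DemographicParams:
    """One parameter draw for either demographic model.

    Sizes are diploid effective sizes; times are generations before
    present.  Fields irrelevant to a model kind are None.
    """

    model_kind: str
    ne: float
    ne_hist: float
    mu: float
    gsm_par: float
    ne_bot: float | None = None
    t_bot_start: float | None = None
    t_bot_end: float | None = None
    t_hist: float | None = None

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.ne < 1 or self.ne_hist < 1:
            raise ValueError("effective sizes must be >= 1")
        if not 0.0 <= self.gsm_par <= 1.0:
            raise ValueError("gsm_par must be a probability")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.model_kind == BOTTLENECK:
            if self.ne_bot is None or self.t_bot_start is None \
                    or self.t_bot_end is None:
                raise ValueError("bottleneck model needs ne_bot, "
                                 "t_bot_start and t_bot_end")
            if self.ne_bot < 1:
                raise ValueError("ne_bot must be >= 1")
            if not 1 <= self.t_bot_end < self.t_bot_start:
                raise ValueError("need 1 <= t_bot_end < t_bot_start")
        else:
            if self.t_hist is None:
                raise ValueError("non-bottleneck model needs t_hist")
            if self.t_hist <= 0:
                raise ValueError("t_hist must be positive")

    def epochs(self) -> tuple[np.ndarray, np.ndarray]:
        """(bounds, sizes) for the piecewise-constant demography,
        looking backwards in time."""
        if self.model_kind == BOTTLENECK:
            bounds = np.array([self.t_bot_end, self.t_bot_start], float)
            sizes = np.array([self.ne, self.ne_bot, self.ne_hist], float)
        else:
            bounds = np.array([self.t_hist], float)
            sizes = np.array([self.ne, self.ne_hist], float)
        return bounds, sizes

    def as_row(self) -> dict:
        d = asdict(self)
        d.pop("model_kind")
        return {k: (np.nan if d.get(k) is None else d.get(k))
                for k in PARAM_NAMES}

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_row(cls, model_kind: str, row) -> "DemographicParams":
        get = lambda k: None if (row[k] is None or
                                 (isinstance(row[k], float) and
                                  np.isnan(row[k]))) else float(row[k])
        if model_kind == BOTTLENECK:
            return cls(model_kind, get("ne"), get("ne_hist"), get("mu"),
                       get("gsm_par"), ne_bot=get("ne_bot"),
                       t_bot_start=get("t_bot_start"),
                       t_bot_end=get("t_bot_end"))
        return cls(model_kind, get("ne"), get("ne_hist"), get("mu"),
                   get("gsm_par"), t_hist=get("t_hist"))


@dataclass(frozen=True)
class Prior:
    """A univariate prior: uniform on [a, b] or lognormal(logmean,
    logsd) with an optional truncation floor."""

    kind: str  # "uniform" | "lognormal"
    a: float
    b: float

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        if self.kind == "lognormal":
            return np.maximum(rng.lognormal(self.a, self.b, size=size), 1.0)
        raise ValueError(f"unknown prior kind {self.kind!r}")

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "uniform":
            return (self.a, self.b)
        return (1.0, np.inf)

    def variance(self) -> float:
        if self.kind == "uniform":
            return (self.b - self.a) ** 2 / 12.0
        s2 = self.b**2
        return (np.exp(s2) - 1.0) * np.exp(2 * self.a + s2)


@dataclass(frozen=True)
class PriorSet:
    """Independent priors for all demographic parameters (both models)."""

    ne: Prior = Prior("lognormal", 10.5, 1.0)
    ne_hist: Prior = Prior("lognormal", 10.5, 1.0)
    ne_bot: Prior = Prior("uniform", 1.0, 500.0)
    t_bot_start: Prior = Prior("uniform", 10.0, 70.0)
    t_bot_end: Prior = Prior("uniform", 1.0, 30.0)
    t_hist: Prior = Prior("uniform", 10.0, 70.0)
    mu: Prior = Prior("uniform", 1e-5, 1e-4)
    gsm_par: Prior = Prior("uniform", 0.0, 0.3)

    def spec_hash(self) -> str:
        import hashlib

        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def sample_priors(
    model_kind: str,
    priors: PriorSet | None = None,
    rng: np.random.Generator | None = None,
) -> DemographicParams:
    """Draw one parameter set from the priors.

    For the bottleneck model the pair (t_bot_start, t_bot_end) is
    rejection-resampled until t_bot_end < t_bot_start, which preserves
    the marginal supports while excluding inverted epochs.
    """
    priors = priors or PriorSet()
    rng = np.random.default_rng(rng)
    common = dict(
        ne=float(priors.ne.sample(rng)),
        ne_hist=float(priors.ne_hist.sample(rng)),
        mu=float(priors.mu.sample(rng)),
        gsm_par=float(priors.gsm_par.sample(rng)),
    )
    if model_kind == BOTTLENECK:
        while True:
            ts = float(priors.t_bot_start.sample(rng))
            te = float(priors.t_bot_end.sample(rng))
            if te < ts:
                break
        return DemographicParams(
            BOTTLENECK, ne_bot=float(priors.ne_bot.sample(rng)),
            t_bot_start=ts, t_bot_end=te, **common,
        )
    if model_kind == NON_BOTTLENECK:
        return DemographicParams(
            NON_BOTTLENECK, t_hist=float(priors.t_hist.sample(rng)), **common
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class Genealogy:
    """A binary coalescent genealogy of n gene copies.

    ``parent[v]`` is the parent node of v (root: -1); ``times`` are node
    times in generations, tips at 0, strictly increasing rootward along
    any path.  Nodes n..2n-2 are internal, in coalescence order.
    """

    n: int
    parent: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a genealogy needs at least 2 gene copies")
        internal = self.times[self.n:]
        if not (np.diff(internal) > 0).all() or not (internal > 0).all():
            raise ValueError("coalescence times must be positive and ordered")

    @property
    def total_branch_length(self) -> float:
        v = np.arange(2 * self.n - 2)
        return float(np.sum(self.times[self.parent[v]] - self.times[v]))

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])


def simulate_genealogy(
    n_copies: int,
    params: DemographicParams,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Kingman coalescent under the piecewise-constant demography of
    ``params``; pairwise coalescence rate 1/(2N(t)) per generation."""
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    bounds, sizes = params.epochs()
    if (sizes <= 0).any():
        raise ValueError("all epoch sizes must be positive")
    rng = np.random.default_rng(rng)
    n_nodes = 2 * n_copies - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.coalescent_genealogy(n_copies, bounds, sizes, parent, times)
    return Genealogy(n_copies, parent, times)


def mutate_gsm(
    g: Genealogy,
    mu: float,
    gsm_par: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Allele sizes (repeat units) of the tips after GSM mutation.

    Mutations are Poisson(mu x branch length) per branch; each step is
    +/-1 with probability 1-gsm_par, otherwise a larger geometric jump;
    the root carries a fixed reference state of 100 repeat units and tip
    sizes are floored at 1.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(rng)
    state = np.empty(2 * g.n - 1, dtype=np.int64)
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    _kernels.mutate_tips(g.n, g.parent, g.times, mu, 0.0, 1.0 - gsm_par,
                         state)
    return state[: g.n].copy()


def step_model_params(mutation=None, gsm_par: float = 0.0):
    """(p_single, pi_geom) kernel parameters for a mutation model.

    ``mutation`` may be any object exposing ``kernel_params()`` (see
    :class:`msatbot.het_excess.MutationModelSpec`); by default a GSM
    with multistep proportion ``gsm_par`` is used.
    """
    if mutation is not None:
        return mutation.kernel_params()
    return 0.0, 1.0 - gsm_par


def simulate_dataset(
    params: DemographicParams,
    n_ind: int = 40,
    n_loci: int = 10,
    rng: np.random.Generator | None = None,
    mutation=None,
    species_id: str = "sim",
) -> GenotypeDataset:
    """Simulate a diploid genotype panel: one independent genealogy of
    2 x n_ind gene copies per locus, mutated, copies paired by
    consecutive index (exchangeable, hence equivalent to random
    pairing).  No missing data.  Allele sizes are repeat units."""
    if n_ind < 1 or n_loci < 1:
        raise ValueError("n_ind and n_loci must be >= 1")
    rng = np.random.default_rng(rng)
    bounds, sizes = params.epochs()
    p_single, pi_geom = step_model_params(mutation, params.gsm_par)
    _kernels.seed_kernel_rng(_kernel_seed(rng))
    alleles = _kernels.simulate_dataset_alleles(
        2 * n_ind, n_loci, bounds, sizes, params.mu, p_single, pi_geom
    )
    calls = alleles.reshape(n_loci, n_ind, 2).transpose(1, 0, 2)
    loci = [Locus(f"L{j + 1}", motif_bp=2, encoding="repeat_units")
            for j in range(n_loci)]
    individuals = [f"ind{i + 1}" for i in range(n_ind)]
    return GenotypeDataset(species_id, loci, individuals, calls.copy())


def equilibrium_het_smm(ne: float, mu: float) -> float:
    """Closed-form equilibrium heterozygosity under the strict SMM,
    1 - 1/sqrt(1 + 2 theta) with theta = 4 Ne mu (testing oracle)."""
    if ne <= 0 or mu < 0:
        raise ValueError("need ne > 0 and mu >= 0")
    theta = 4.0 * ne * mu
    return 1.0 - 1.0 / np.sqrt(1.0 + 2.0 * theta)
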