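"""Numba-compiled simulation kernels.

Everything here operates on flat numpy arrays so that the hot loops
(coalescent genealogies, stepwise mutation, conditional equilibrium
heterozygosity, HWE permutation) compile to machine code.  The public,
documented API lives in :mod:`msatbot.coalsim`, :mod:`msatbot.het_excess`
and :mod:`msatbot.genotype_io`; these kernels are implementation detail.

Conventions
-----------
* A genealogy of ``n`` gene copies is stored as ``parent`` (int64,
  length ``2n-1``, root has parent -1) and ``times`` (float64 node times
  in generations, tips at 0).  Internal nodes are created in coalescence
  order, so ``parent[v] > v`` for every non-root node: a single downward
  pass in decreasing node index propagates allele states from the root.
* Piecewise-constant demography: ``bounds`` holds the epoch change times
  (generations, increasing) and ``sizes`` the diploid N per epoch
  (``len(sizes) == len(bounds) + 1``); pairwise coalescence rate is
  ``1/(2N)`` per generation.
* Mutation step sizes: with probability ``p_single`` a step is exactly
  one repeat unit, otherwise geometric on {1, 2, ...} with success
  probability ``pi_geom``; direction is +/-1 equiprobable.  A pure GSM
  with multistep proportion g is ``p_single=0, pi_geom=1-g``; the SMM is
  ``p_single=1``.
"""

import numpy as np
from numba import njit

ROOT_STATE = 100  # repeat units assigned to the MRCA; shift-invariant downstream


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed numba's internal RNG state (separate from numpy's)."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _geometric_step(p_single, pi_geom):
    """Signed mutation step in repeat units."""
    if p_single >= 1.0 or np.random.random() < p_single:
        s = 1
    elif pi_geom >= 1.0:
        s = 1
    else:
        # inverse-transform geometric on {1, 2, ...}
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        s = 1 + int(np.log(u) / np.log(1.0 - pi_geom))
    if np.random.random() < 0.5:
        return s
    return -s


@njit(cache=True)
def coalescent_genealogy(n, bounds, sizes, parent, times):
    """Simulate a Kingman genealogy under piecewise-constant diploid size.

    Fills ``parent`` and ``times`` (preallocated, length 2n-1) in place.
    Epoch boundaries are handled through the memorylessness of the
    exponential: a waiting time overshooting the current epoch is
    redrawn from the boundary at the next epoch's rate.
    """
    n_nodes = 2 * n - 1
    for v in range(n_nodes):
        parent[v] = -1
        times[v] = 0.0
    active = np.empty(n, dtype=np.int64)
    for v in range(n):
        active[v] = v
    k = n
    t = 0.0
    ep = 0
    n_bounds = bounds.shape[0]
    nxt = n
    while k > 1:
        rate = (k * (k - 1) / 2.0) / (2.0 * sizes[ep])
        w = np.random.exponential(1.0 / rate)
        if ep < n_bounds and t + w > bounds[ep]:
            t = bounds[ep]
            ep += 1
            continue
        t += w
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        a = active[i]
        b = active[j]
        parent[a] = nxt
        parent[b] = nxt
        times[nxt] = t
        lo = i if i < j else j
        hi = j if i < j else i
        active[lo] = nxt
        active[hi] = active[k - 1]
        k -= 1
        nxt += 1


@njit(cache=True)
def mutate_tips(n, parent, times, mu, p_single, pi_geom, state):
    """Drop Poisson(mu * branch length) mutations on every branch and
    propagate allele states root-to-tips; fills ``state`` (length 2n-1).

    Tip states (first n entries) are floored at one repeat unit.
    """
    n_nodes = 2 * n - 1
    state[n_nodes - 1] = ROOT_STATE
    for v in range(n_nodes - 2, -1, -1):
        bl = times[parent[v]] - times[v]
        nm = np.random.poisson(mu * bl)
        d = 0
        for _ in range(nm):
            d += _geometric_step(p_single, pi_geom)
        state[v] = state[parent[v]] + d
    for v in range(n):
        if state[v] < 1:
            state[v] = 1


@njit(cache=True)
def locus_summary(alleles, n, unbiased, out):
    """Five per-locus statistics from n gene-copy allele sizes.

    ``out`` receives (k, size_range, He, M, lfa).  He is Nei gene
    diversity, unbiased (2n/(2n-1)) correction optional; lfa is the
    proportion of alleles at sample frequency strictly below 5%.
    """
    srt = np.sort(alleles[:n])
    k = 1
    sum_p2 = 0.0
    n_lfa = 0
    run = 1
    for i in range(1, n):
        if srt[i] != srt[i - 1]:
            p = run / n
            sum_p2 += p * p
            if p < 0.05:
                n_lfa += 1
            k += 1
            run = 1
        else:
            run += 1
    p = run / n
    sum_p2 += p * p
    if p < 0.05:
        n_lfa += 1
    he = 1.0 - sum_p2
    if unbiased and n > 1:
        he *= n / (n - 1.0)
    r = srt[n - 1] - srt[0]
    out[0] = k
    out[1] = r
    out[2] = he
    out[3] = k / (r + 1.0)
    out[4] = n_lfa / k


@njit(cache=True)
def simulate_dataset_alleles(n_copies, n_loci, bounds, sizes, mu,
                             p_single, pi_geom):
    """Allele-size matrix (n_loci, n_copies) of independent loci."""
    n_nodes = 2 * n_copies - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    state = np.empty(n_nodes, dtype=np.int64)
    out = np.empty((n_loci, n_copies), dtype=np.int64)
    for l in range(n_loci):
        coalescent_genealogy(n_copies, bounds, sizes, parent, times)
        mutate_tips(n_copies, parent, times, mu, p_single, pi_geom, state)
        out[l, :] = state[:n_copies]
    return out


@njit(cache=True)
def simulate_dataset_stats(n_copies, n_loci, bounds, sizes, mu,
                           p_single, pi_geom, unbiased, out5):
    """Mean over loci of the five summary statistics (fused fast path)."""
    n_nodes = 2 * n_copies - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    state = np.empty(n_nodes, dtype=np.int64)
    tmp = np.empty(5, dtype=np.float64)
    for i in range(5):
        out5[i] = 0.0
    for _ in range(n_loci):
        coalescent_genealogy(n_copies, bounds, sizes, parent, times)
        mutate_tips(n_copies, parent, times, mu, p_single, pi_geom, state)
        locus_summary(state, n_copies, unbiased, tmp)
        for i in range(5):
            out5[i] += tmp[i]
    for i in range(5):
        out5[i] /= n_loci


@njit(cache=True)
def build_table_rows(n_copies, n_loci, boundsM, sizesM, mus, p_singles,
                     pi_geoms, unbiased, seed):
    """Summary-statistic rows for a batch of parameter draws.

    boundsM: (n_rows, n_ep-1) epoch change times; sizesM: (n_rows, n_ep)
    diploid sizes.  Returns (n_rows, 5).
    """
    np.random.seed(seed)
    n_rows = sizesM.shape[0]
    out = np.empty((n_rows, 5), dtype=np.float64)
    row = np.empty(5, dtype=np.float64)
    for r in range(n_rows):
        simulate_dataset_stats(n_copies, n_loci, boundsM[r], sizesM[r],
                               mus[r], p_singles[r], pi_geoms[r],
                               unbiased, row)
        out[r, :] = row
    return out


@njit(cache=True)
def _allele_count_once(n_copies, theta, p_single, pi_geom,
                       parent, times, state):
    """Distinct tip allele count of one constant-size simulation.

    Times are in units of 2N generations (sizes = 0.5 makes the
    pairwise rate 1), so the per-branch mutation rate is theta/2.
    """
    bounds = np.empty(0, dtype=np.float64)
    sizes = np.full(1, 0.5)
    coalescent_genealogy(n_copies, bounds, sizes, parent, times)
    mutate_tips(n_copies, parent, times, theta / 2.0, p_single, pi_geom,
                state)
    srt = np.sort(state[:n_copies])
    k = 1
    for i in range(1, n_copies):
        if srt[i] != srt[i - 1]:
            k += 1
    return k


@njit(cache=True)
def mean_allele_count(n_copies, theta, p_single, pi_geom, n_pilot, seed):
    """Monte-Carlo mean allele count at a given theta (for calibration)."""
    np.random.seed(seed)
    n_nodes = 2 * n_copies - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    state = np.empty(n_nodes, dtype=np.int64)
    tot = 0.0
    for _ in range(n_pilot):
        tot += _allele_count_once(n_copies, theta, p_single, pi_geom,
                                  parent, times, state)
    return tot / n_pilot


@njit(cache=True)
def heq_draws(n_copies, k_target, theta, p_single, pi_geom, n_sims,
              max_attempts, unbiased, seed):
    """Equilibrium heterozygosity draws conditional on allele number.

    Simulates constant-size coalescent loci at the supplied ``theta``
    (pre-calibrated so that the expected allele count is k_target) and
    retains the Nei heterozygosity of replicates carrying exactly
    ``k_target`` distinct alleles.  A draw that fails to hit k_target
    within ``max_attempts`` unconditional simulations is returned as
    NaN for the caller to diagnose.
    """
    np.random.seed(seed)
    n_nodes = 2 * n_copies - 1
    parent = np.empty(n_nodes, dtype=np.int64)
    times = np.empty(n_nodes, dtype=np.float64)
    state = np.empty(n_nodes, dtype=np.int64)
    stats = np.empty(5, dtype=np.float64)
    out = np.empty(n_sims, dtype=np.float64)
    for s in range(n_sims):
        he = np.nan
        for _ in range(max_attempts):
            k = _allele_count_once(n_copies, theta, p_single, pi_geom,
                                   parent, times, state)
            if k == k_target:
                locus_summary(state, n_copies, unbiased, stats)
                he = stats[2]
                break
        out[s] = he
    return out


@njit(cache=True)
def hwe_exact_mc(copies, n_ind, n_alleles, n_mc, seed):
    """Monte-Carlo exact HWE p-value for one locus.

    ``copies``: int64 array of 2*n_ind gene copies recoded 0..k-1, the
    observed genotypes being consecutive pairs.  Statistic is the
    conditional probability of the genotype table given allele counts
    (Levene); p = fraction of permuted tables with probability <= the
    observed one (within a small numerical tolerance).
    """
    np.random.seed(seed)
    n2 = 2 * n_ind
    logfact = np.empty(n2 + 1, dtype=np.float64)
    logfact[0] = 0.0
    for i in range(1, n2 + 1):
        logfact[i] = logfact[i - 1] + np.log(i)
    log2 = np.log(2.0)

    def _logprob(c):
        # log conditional probability of genotype counts given allele counts
        geno = np.zeros((n_alleles, n_alleles), dtype=np.int64)
        for i in range(n_ind):
            a = c[2 * i]
            b = c[2 * i + 1]
            if a > b:
                a, b = b, a
            geno[a, b] += 1
        lp = logfact[n_ind]
        n_het = 0
        for a in range(n_alleles):
            for b in range(a, n_alleles):
                lp -= logfact[geno[a, b]]
                if a != b:
                    n_het += geno[a, b]
        lp += n_het * log2
        counts = np.zeros(n_alleles, dtype=np.int64)
        for i in range(n2):
            counts[c[i]] += 1
        for a in range(n_alleles):
            lp += logfact[counts[a]]
        lp -= logfact[n2]
        return lp

    obs_lp = _logprob(copies)
    work = copies.copy()
    n_le = 0
    for _ in range(n_mc):
        for i in range(n2 - 1, 0, -1):
            j = np.random.randint(i + 1)
            tmp = work[i]
            work[i] = work[j]
            work[j] = tmp
        if _logprob(work) <= obs_lp + 1e-9:
            n_le += 1
    return (n_le + 1.0) / (n_mc + 1.0)
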