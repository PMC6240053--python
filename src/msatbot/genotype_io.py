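"""Reading, writing and quality control of microsatellite genotype panels.

The exchange format is GenePop: a free-text title line, one locus name
per line (or comma-separated), then ``POP`` followed by one line per
individual with 2- or 3-digit diploid allele codes, ``00``/``000``
denoting a missing allele.  Because published panels mix both code
widths, the width is auto-detected per file.

Locus metadata (repeat-motif length, allele encoding) has no standard
GenePop slot, so the writer serialises it into the title line in a
``key=value`` syntax the reader understands; files written elsewhere
simply fall back to defaults (bp encoding, dinucleotide motif).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import _kernels

MISSING = 0  # sentinel allele code for a missing gene copy


class GenePopParseError(ValueError):
    """Raised when a GenePop file violates the dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    id : str
        Unique locus name within a dataset.
    motif_bp : int
        Length of the repeat motif in base pairs (1-6).
    encoding : {"bp", "repeat_units"}
        Whether allele sizes are fragment lengths in bp or repeat counts.
    """

    id: str
    motif_bp: int = 2
    encoding: str = "bp"

    def __post_init__(self):
        if self.motif_bp < 1:
            raise ValueError(f"motif_bp must be >= 1, got {self.motif_bp}")
        if self.encoding not in ("bp", "repeat_units"):
            raise ValueError(f"unknown encoding {self.encoding!r}")


@dataclass
class GenotypeDataset:
    """Diploid allele-size matrix for one population sample.

    ``calls`` has shape (n_individuals, n_loci, 2) with positive integer
    allele sizes and 0 for a missing gene copy; the order of the two
    copies of a genotype is irrelevant to every downstream statistic
    (they are kept sorted for canonical equality).
    """

    species_id: str
    loci: list[Locus]
    individuals: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        # canonicalise: a half-missing genotype counts as missing entirely
        half = (self.calls == MISSING).any(axis=2) & (
            self.calls != MISSING
        ).any(axis=2)
        self.calls[half] = MISSING
        self.calls = np.sort(self.calls, axis=2)
        if (self.calls < 0).any():
            raise ValueError("allele sizes must be positive (0 = missing)")
        typed = (self.calls[:, :, 0] != MISSING).sum(axis=0)
        if (typed == 0).any():
            bad = [ids[j] for j in np.flatnonzero(typed == 0)]
            raise ValueError(f"loci with no non-missing genotype: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        for j, l in enumerate(self.loci):
            if l.id == locus_id:
                return j
        raise KeyError(locus_id)

    def locus_alleles(self, locus_id: str) -> np.ndarray:
        """Non-missing gene copies at a locus, as a flat array."""
        j = self.locus_index(locus_id)
        a = self.calls[:, j, :].ravel()
        return a[a != MISSING]

    def __eq__(self, other):
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.species_id == other.species_id
            and self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# GenePop read / write


def _parse_title(line: str):
    """Extract species id and optional locus metadata from the title line."""
    meta = {}
    sid = line.strip()
    m = re.search(r"\[msat\s+(.*?)\]", line)
    if m:
        sid = line[: m.start()].strip().rstrip(";").strip()
        for kv in m.group(1).split():
            if "=" in kv:
                k, v = kv.split("=", 1)
                meta[k] = v
    return sid or "dataset", meta


def read_genepop(path) -> GenotypeDataset:
    """Read a GenePop-format genotype file.

    Accepts 2- and 3-digit allele codes (auto-detected from the first
    genotype line); ``0``-coded alleles are missing.  Multiple POP
    blocks are concatenated into a single sample.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopParseError(f"{path}: empty file")
    species_id, meta = _parse_title(lines[0])

    locus_names: list[str] = []
    i = 1
    saw_pop = False
    while i < len(lines):
        s = lines[i].strip()
        if s.upper() == "POP":
            saw_pop = True
            i += 1
            break
        if s:
            locus_names.extend(x.strip() for x in s.split(",") if x.strip())
        i += 1
    if not saw_pop:
        raise GenePopParseError(f"{path}: no POP line found")
    if not locus_names:
        raise GenePopParseError(f"{path}: no locus names before POP")

    individuals: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width = None
    for ln, raw in enumerate(lines[i:], start=i + 1):
        s = raw.strip()
        if not s:
            continue
        if s.upper() == "POP":
            continue
        if "," not in s:
            raise GenePopParseError(
                f"{path}:{ln}: genotype line lacks the 'name ,' separator"
            )
        name, _, geno = s.partition(",")
        toks = geno.split()
        if len(toks) != len(locus_names):
            raise GenePopParseError(
                f"{path}:{ln}: {len(toks)} genotypes for "
                f"{len(locus_names)} loci"
            )
        row = []
        for tok in toks:
            if width is None:
                if len(tok) in (4, 6):
                    width = len(tok) // 2
                else:
                    raise GenePopParseError(
                        f"{path}:{ln}: genotype {tok!r} is neither 4 nor "
                        "6 digits"
                    )
            if len(tok) != 2 * width or not tok.isdigit():
                raise GenePopParseError(
                    f"{path}:{ln}: genotype {tok!r} inconsistent with "
                    f"{width}-digit allele codes"
                )
            row.append((int(tok[:width]), int(tok[width:])))
        individuals.append(name.strip())
        rows.append(row)
    if not rows:
        raise GenePopParseError(f"{path}: no genotype rows")

    calls = np.array(rows, dtype=np.int64)
    motifs = meta.get("motifs", "").split(",") if "motifs" in meta else []
    encoding = meta.get("encoding", "bp")
    loci = []
    for j, name in enumerate(locus_names):
        motif = int(motifs[j]) if j < len(motifs) and motifs[j] else 2
        loci.append(Locus(id=name, motif_bp=motif, encoding=encoding))
    return GenotypeDataset(species_id, loci, individuals, calls)


def write_genepop(ds: GenotypeDataset, path) -> None:
    """Write a dataset as GenePop; the code width (2 or 3 digits) is the
    smallest that fits the largest allele.  Locus metadata goes into the
    title line so that ``read_genepop`` round-trips losslessly."""
    amax = int(ds.calls.max(initial=0))
    if amax > 999:
        raise ValueError(
            f"allele size {amax} not representable in 3-digit GenePop codes"
        )
    width = 2 if amax <= 99 else 3
    motifs = ",".join(str(l.motif_bp) for l in ds.loci)
    enc = ds.loci[0].encoding if ds.loci else "bp"
    with open(path, "w") as fh:
        fh.write(f"{ds.species_id} [msat encoding={enc} motifs={motifs}]\n")
        for l in ds.loci:
            fh.write(l.id + "\n")
        fh.write("POP\n")
        for i, ind in enumerate(ds.individuals):
            codes = [
                f"{a:0{width}d}{b:0{width}d}" for a, b in ds.calls[i]
            ]
            fh.write(f"{ind} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# Encoding conversion


def estimate_motif(sizes: np.ndarray, fallback: int) -> int:
    """Modal gap among sorted distinct allele sizes (ties -> smallest)."""
    distinct = np.unique(sizes)
    if distinct.size < 2:
        return fallback
    gaps = np.diff(distinct)
    vals, counts = np.unique(gaps, return_counts=True)
    return int(vals[np.argmax(counts)])


def to_repeat_units(ds: GenotypeDataset) -> GenotypeDataset:
    """Convert bp-encoded allele sizes to (approximate) repeat units.

    Per locus the motif is estimated as the modal gap among sorted
    distinct allele sizes; each allele maps to
    ``round((size - min_size) / motif) + round(min_size / motif)`` so
    off-lattice alleles snap to the nearest unit (the mapping is an
    approximation for loci with imperfect periodicity).  Already
    unit-encoded datasets are returned unchanged.
    """
    if all(l.encoding == "repeat_units" for l in ds.loci):
        return ds
    calls = ds.calls.copy()
    loci = []
    for j, loc in enumerate(ds.loci):
        if loc.encoding == "repeat_units":
            loci.append(loc)
            continue
        if loc.motif_bp < 1:
            raise ValueError(f"locus {loc.id}: declared motif must be >= 1")
        alleles = ds.locus_alleles(loc.id)
        motif = estimate_motif(alleles, fallback=loc.motif_bp)
        mn = int(alleles.min())
        offset = int(round(mn / motif))
        col = calls[:, j, :]
        mask = col != MISSING
        units = np.rint((col[mask] - mn) / motif).astype(np.int64) + offset
        units = np.maximum(units, 1)
        col[mask] = units
        loci.append(replace(loc, encoding="repeat_units"))
    return GenotypeDataset(ds.species_id, loci, list(ds.individuals), calls)


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests


@dataclass
class HweResult:
    """Per-locus HWE test results with multiplicity correction.

    ``table`` columns: locus, k, n_typed, chi2_stat, chi2_df, chi2_p,
    exact_p, testable, flagged.  A locus is flagged only when BOTH the
    chi-square and the exact test are significant after correction.
    """

    table: pd.DataFrame
    alpha: float
    corrected_alpha: float
    correction: str
    n_tests: int

    @property
    def flagged_loci(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "locus"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["corrected_alpha"] = self.corrected_alpha
        out.to_csv(path, index=False)


def _hwe_chi2(pairs: np.ndarray):
    """Chi-square of observed genotype counts vs Hardy-Weinberg
    expectations from sample allele frequencies.  Genotype classes are
    not pooled.  Returns (stat, df, p)."""
    alleles, inv = np.unique(pairs.ravel(), return_inverse=True)
    k = alleles.size
    n = pairs.shape[0]
    enc = inv.reshape(n, 2)
    freqs = np.bincount(inv, minlength=k) / (2 * n)
    obs = np.zeros((k, k))
    for a, b in enc:
        lo, hi = (a, b) if a <= b else (b, a)
        obs[lo, hi] += 1
    stat = 0.0
    for a in range(k):
        for b in range(a, k):
            e = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            if e > 0:
                stat += (obs[a, b] - e) ** 2 / e
    df = k * (k + 1) // 2 - k
    p = float(_sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), p


def hwe_tests(
    ds: GenotypeDataset,
    n_mc: int = 10_000,
    alpha: float = 0.05,
    correction: str = "bonferroni_table_wide",
    rng: np.random.Generator | None = None,
    n_tests_override: int | None = None,
) -> HweResult:
    """Chi-square and Monte-Carlo exact HWE tests per locus.

    The exact p-value permutes gene copies among individuals within a
    locus and compares the Levene conditional probability of the
    permuted genotype table with the observed one (``n_mc`` >= 1000
    required).  Monomorphic or empty loci are untestable and excluded
    from the Bonferroni denominator.  ``n_tests_override`` lets a
    multi-dataset run apply a table-wide correction across datasets.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for the exact test")
    if correction not in ("bonferroni_table_wide", "bonferroni_per_dataset",
                          "none"):
        raise ValueError(f"unknown correction {correction!r}")
    rng = np.random.default_rng(rng)
    rows = []
    for loc in ds.loci:
        j = ds.locus_index(loc.id)
        g = ds.calls[:, j, :]
        typed = g[g[:, 0] != MISSING]
        n = typed.shape[0]
        k = np.unique(typed.ravel()).size if n else 0
        if n == 0 or k < 2:
            rows.append((loc.id, k, n, np.nan, 0, np.nan, np.nan, False))
            continue
        stat, df, chi2_p = _hwe_chi2(typed)
        _, inv = np.unique(typed.ravel(), return_inverse=True)
        seed = int(rng.integers(2**31 - 1))
        exact_p = float(
            _kernels.hwe_exact_mc(inv.astype(np.int64), n, k, n_mc, seed)
        )
        rows.append((loc.id, k, n, stat, df, chi2_p, exact_p, True))
    table = pd.DataFrame(
        rows,
        columns=["locus", "k", "n_typed", "chi2_stat", "chi2_df", "chi2_p",
                 "exact_p", "testable"],
    )
    n_testable = int(table["testable"].sum())
    if correction == "none":
        n_tests = 1
    elif n_tests_override is not None:
        n_tests = max(int(n_tests_override), 1)
    else:
        n_tests = max(n_testable, 1)
    corrected = alpha / n_tests
    table["flagged"] = (
        table["testable"]
        & (table["chi2_p"] < corrected)
        & (table["exact_p"] < corrected)
    )
    return HweResult(table, alpha, corrected, correction, n_tests)


# ---------------------------------------------------------------------------
# Subsetting


def subset(
    ds: GenotypeDataset,
    keep_individuals=None,
    keep_loci=None,
) -> GenotypeDataset:
    """Restrict a dataset to a set of individuals and/or loci.

    Order is preserved; dataset invariants are re-checked (dropping
    individuals can leave a locus with no genotypes, which is an error).
    """
    if keep_individuals is None and keep_loci is None:
        raise ValueError("nothing to subset: give individuals and/or loci")
    ind_idx = np.arange(ds.n_individuals)
    loc_idx = np.arange(ds.n_loci)
    if keep_individuals is not None:
        keep = set(keep_individuals)
        unknown = keep - set(ds.individuals)
        if unknown:
            raise KeyError(f"unknown individuals: {sorted(unknown)}")
        ind_idx = np.array(
            [i for i, x in enumerate(ds.individuals) if x in keep], dtype=int
        )
        if ind_idx.size == 0:
            raise ValueError("empty individual selection")
    if keep_loci is not None:
        keep = set(keep_loci)
        unknown = keep - {l.id for l in ds.loci}
        if unknown:
            raise KeyError(f"unknown loci: {sorted(unknown)}")
        loc_idx = np.array(
            [j for j, l in enumerate(ds.loci) if l.id in keep], dtype=int
        )
        if loc_idx.size == 0:
            raise ValueError("empty locus selection")
    return GenotypeDataset(
        ds.species_id,
        [ds.loci[j] for j in loc_idx],
        [ds.individuals[i] for i in ind_idx],
        ds.calls[np.ix_(ind_idx, loc_idx)],
    )
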