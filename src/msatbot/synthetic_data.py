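"""Study-like synthetic genotype panels with known demographic truth.

Emulates a multi-species microsatellite panel of the kind assembled
from published pinniped datasets: per species, 16-2386 individuals
(median target 253) typed at 5-35 loci (median target 14), generated
under either the bottleneck or the non-bottleneck demography with
parameters drawn from the standard priors (or fixed by the caller).
Roughly 11 of 30 species are bottlenecked by default.  Missing
genotypes are off by default and can be switched on for robustness
checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import coalsim
from .coalsim import (BOTTLENECK, NON_BOTTLENECK, DemographicParams,
                      PriorSet, sample_priors, simulate_dataset)
from .genotype_io import MISSING, GenotypeDataset, Locus, write_genepop


@dataclass
class PanelConfig:
    """Configuration of a synthetic multi-species panel."""

    n_species: int = 30
    bottleneck_fraction: float = 11 / 30
    n_ind_range: tuple = (16, 2386)
    n_ind_median: int = 253
    n_loci_range: tuple = (5, 35)
    n_loci_median: int = 14
    missing_rate: float = 0.0
    priors: PriorSet = field(default_factory=PriorSet)
    #: optional explicit DemographicParams per species (overrides priors)
    fixed_params: list | None = None

    def __post_init__(self):
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if not 0 <= self.bottleneck_fraction <= 1:
            raise ValueError("bottleneck_fraction must be a proportion")


@dataclass
class TruthManifest:
    """Ground truth for a generated panel: one entry per species with
    the generating parameters, seed and file path."""

    entries: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))


def _median_split_int(lo: int, med: int, hi: int,
                      rng: np.random.Generator) -> int:
    """Discretised log-uniform with its median pinned at ``med``: half
    the mass log-uniform on [lo, med], half on [med, hi]."""
    if rng.random() < 0.5:
        a, b = np.log(lo), np.log(med)
    else:
        a, b = np.log(med), np.log(hi)
    return int(np.clip(round(np.exp(rng.uniform(a, b))), lo, hi))


def _apply_missing(ds: GenotypeDataset, rate: float,
                   rng: np.random.Generator) -> GenotypeDataset:
    if rate == 0:
        return ds
    calls = ds.calls.copy()
    mask = rng.random(calls.shape[:2]) < rate
    # never wipe out a whole locus
    for j in range(calls.shape[1]):
        if mask[:, j].all():
            mask[rng.integers(calls.shape[0]), j] = False
    calls[mask] = MISSING
    return GenotypeDataset(ds.species_id, list(ds.loci),
                           list(ds.individuals), calls)


def generate_panel(
    config: PanelConfig | None = None,
    rng: np.random.Generator | None = None,
    out_dir=None,
):
    """Generate a synthetic panel; returns (datasets, TruthManifest).

    With ``out_dir`` set, each dataset is written as a GenePop file and
    a ``manifest.json`` records the generating parameters and seeds.
    The first ``round(bottleneck_fraction * n_species)`` species are
    bottlenecked (order carries no information: demography parameters
    are drawn independently per species).
    """
    config = config or PanelConfig()
    rng = np.random.default_rng(rng)
    n_bot = int(round(config.bottleneck_fraction * config.n_species))
    datasets, entries = [], []
    for s in range(config.n_species):
        model = BOTTLENECK if s < n_bot else NON_BOTTLENECK
        if config.fixed_params is not None:
            params = config.fixed_params[s]
            model = params.model_kind
        else:
            params = sample_priors(model, config.priors, rng)
        n_ind = _median_split_int(*_rng_args(config.n_ind_range,
                                             config.n_ind_median), rng)
        n_loci = _median_split_int(*_rng_args(config.n_loci_range,
                                              config.n_loci_median), rng)
        seed = int(rng.integers(1, 2**31 - 1))
        ds = simulate_dataset(params, n_ind, n_loci,
                              rng=np.random.default_rng(seed),
                              species_id=f"species_{s + 1:02d}_{model}")
        ds = _apply_missing(ds, config.missing_rate,
                            np.random.default_rng(seed + 1))
        path = None
        if out_dir is not None:
            path = str(Path(out_dir) / f"{ds.species_id}.gen")
            write_genepop(ds, path)
        datasets.append(ds)
        entries.append({
            "species_id": ds.species_id, "model": model,
            "params": asdict(params), "seed": seed, "path": path,
            "n_ind": n_ind, "n_loci": n_loci,
        })
    manifest = TruthManifest(entries)
    if out_dir is not None:
        manifest.to_json(Path(out_dir) / "manifest.json")
    return datasets, manifest


def _rng_args(rng_range, median):
    lo, hi = rng_range
    return lo, median, hi


FIXTURE_KINDS = ("monomorphic", "missing_heavy", "two_allele_hwe",
                 "off_lattice", "tiny")


def generate_fixture(kind: str) -> GenotypeDataset:
    """Deterministic edge-case datasets for tests and examples.

    monomorphic: one allele everywhere (He = Ho = 0, M = 1).
    missing_heavy: scattered missing genotypes, pairwise deletion path.
    two_allele_hwe: exact 25/50/25 genotype counts (HWE chi2 = 0).
    off_lattice: bp alleles {150, 152, 155}, imperfect dinucleotide
    lattice exercising the approximate repeat-unit mapping.
    tiny: 16 individuals, for the use-full-dataset resampling rule.
    """
    if kind == "monomorphic":
        calls = np.full((10, 2, 2), 12, dtype=np.int64)
        loci = [Locus("M1", 2, "repeat_units"), Locus("M2", 2, "repeat_units")]
        return GenotypeDataset("fix_monomorphic", loci,
                               [f"i{k}" for k in range(10)], calls)
    if kind == "missing_heavy":
        rng = np.random.default_rng(424242)
        calls = rng.integers(10, 14, size=(12, 3, 2)).astype(np.int64)
        miss = rng.random((12, 3)) < 0.3
        miss[0, :] = False  # keep every locus testable
        calls[miss] = MISSING
        loci = [Locus(f"H{j}", 2, "repeat_units") for j in range(3)]
        return GenotypeDataset("fix_missing_heavy", loci,
                               [f"i{k}" for k in range(12)], calls)
    if kind == "two_allele_hwe":
        calls = np.empty((100, 1, 2), dtype=np.int64)
        calls[:25, 0] = (10, 10)
        calls[25:75, 0] = (10, 12)
        calls[75:, 0] = (12, 12)
        return GenotypeDataset("fix_two_allele_hwe",
                               [Locus("W1", 2, "repeat_units")],
                               [f"i{k}" for k in range(100)], calls)
    if kind == "off_lattice":
        sizes = [150, 152, 155, 150, 152, 155, 150, 152]
        calls = np.array([[(sizes[i], sizes[(i + 3) % 8])]
                          for i in range(8)], dtype=np.int64)
        return GenotypeDataset("fix_off_lattice", [Locus("O1", 2, "bp")],
                               [f"i{k}" for k in range(8)], calls)
    if kind == "tiny":
        rng = np.random.default_rng(161616)
        calls = rng.integers(8, 16, size=(16, 5, 2)).astype(np.int64)
        loci = [Locus(f"T{j}", 2, "repeat_units") for j in range(5)]
        return GenotypeDataset("fix_tiny", loci,
                               [f"i{k}" for k in range(16)], calls)
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"choose from {FIXTURE_KINDS}")
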