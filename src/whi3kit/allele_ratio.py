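"""Genotype-dependent stabilization estimates from duplex-PCR band ratios.

A diploid carries two distinguishable alleles of the same gene — a long
and a short form — where one allele retains the protein's binding motifs
and the other has them mutated away. Duplex RT-PCR amplifies both from
one RNA prep, so the long:short band ratio is an internally controlled
relative-abundance readout. Two normalizations convert ratios into a
fold-stabilization attributable to the protein:

* **Method 1** compares the motif-free allele's relative abundance
  (against its motif-bearing partner) between genotypes; a
  motif-independent allele bias cancels in the quotient.
* **Method 2** compares the motif-bearing allele between genotypes, each
  normalized to the motif-free partner allele in the same cell.

Group differences are tested with a seeded two-sided permutation test on
the mean long:short ratio, which makes no distributional assumption.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from .io_formats import DuplexMeasurement
from .synthetic_data import LONG_MOTIF_CONFIG, SHORT_MOTIF_CONFIG


def long_short_ratio(m: DuplexMeasurement) -> float:
    """Long-allele band intensity over short-allele band intensity."""
    return m.long_intensity / m.short_intensity


def mut_allele_relative_abundance(
    measurements: Iterable[DuplexMeasurement],
    reducer: Callable[[np.ndarray], float] = np.mean,
) -> float:
    """Relative abundance of the motif-free (mutated) allele against its
    motif-bearing partner, reduced over replicate lanes (mean by default,
    median exposed via ``reducer``)."""
    ratios = []
    for m in measurements:
        if m.allele_config == SHORT_MOTIF_CONFIG:  # long allele is the mutated one
            ratios.append(m.long_intensity / m.short_intensity)
        elif m.allele_config == LONG_MOTIF_CONFIG:
            ratios.append(m.short_intensity / m.long_intensity)
        else:
            raise ValueError(f"unknown allele configuration {m.allele_config!r}")
    if not ratios:
        raise ValueError("no measurements")
    return float(reducer(np.asarray(ratios)))


def normalize_method1(rel_mut_allele_WT: float, rel_mut_allele_mutant: float) -> float:
    """Fold stabilization from the motif-free allele's relative abundance in
    each genotype: ``rel(WT genotype) / rel(mutant genotype)``.

    Because both inputs are normalized within one cell, any
    motif-independent effect of the mutations cancels.
    """
    if rel_mut_allele_WT <= 0 or rel_mut_allele_mutant <= 0:
        raise ValueError("relative abundances must be positive")
    return rel_mut_allele_WT / rel_mut_allele_mutant


def method1_from_measurements(
    wt_lanes: Iterable[DuplexMeasurement],
    mutant_lanes: Iterable[DuplexMeasurement],
    reducer: Callable[[np.ndarray], float] = np.mean,
) -> float:
    """Method-1 fold computed directly from lanes of the two genotypes."""
    return normalize_method1(
        mut_allele_relative_abundance(wt_lanes, reducer),
        mut_allele_relative_abundance(mutant_lanes, reducer),
    )


def normalize_method2(
    wt_lanes: Iterable[DuplexMeasurement],
    mutant_lanes: Iterable[DuplexMeasurement],
    n_boot: int = 1000,
    seed: int = 0,
    reducer: Callable[[np.ndarray], float] = np.mean,
) -> tuple[float, tuple[float, float]]:
    """Fold change of the motif-bearing allele between genotypes, each lane
    normalized to the motif-free partner allele.

    Lanes must be the ``Long-GCAU/Short-gcau_mut`` configuration. Returns
    ``mean(long:short | mutant) / mean(long:short | WT)`` with a seeded
    bootstrap 95% CI (resampling lanes within each genotype).
    """
    def _ratios(lanes):
        vals = []
        for m in lanes:
            if m.allele_config != LONG_MOTIF_CONFIG:
                raise ValueError(
                    f"method 2 expects the {LONG_MOTIF_CONFIG} configuration, "
                    f"got {m.allele_config!r}"
                )
            vals.append(long_short_ratio(m))
        if not vals:
            raise ValueError("empty genotype group")
        return np.asarray(vals)

    wt, mut = _ratios(wt_lanes), _ratios(mutant_lanes)
    fold = float(reducer(mut) / reducer(wt))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bw = rng.choice(wt, size=wt.size, replace=True)
        bm = rng.choice(mut, size=mut.size, replace=True)
        boots.append(reducer(bm) / reducer(bw))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return fold, (float(lo), float(hi))


def genotype_effect_test(
    ratios_WT: Sequence[float],
    ratios_mutant: Sequence[float],
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the genotype difference in mean ratio.

    ``p = (1 + #{permutations with |mean diff| >= observed}) / (n_perm + 1)``
    (the plus-one correction keeps p > 0). Needs >= 3 values per group.
    """
    a = np.asarray(ratios_WT, dtype=float)
    b = np.asarray(ratios_mutant, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("permutation test needs at least 3 replicates per group")
    observed = abs(a.mean() - b.mean())
    # canonical pooling (sorted values, split at the smaller group size) makes
    # the result invariant to swapping the two group labels
    pooled = np.sort(np.concatenate([a, b]))
    k = min(a.size, b.size)
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: each row is one permutation
    perms = np.tile(pooled, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    diff = np.abs(perms[:, :k].mean(axis=1) - perms[:, k:].mean(axis=1))
    exceed = int((diff >= observed - 1e-12).sum())
    return (1 + exceed) / (n_perm + 1)
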