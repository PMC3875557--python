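"""Target calling from RIP-chip log-ratios and gene-list overlap statistics.

The experimental design: a TAP-tagged RNA-binding protein is
immunoprecipitated and co-precipitating mRNAs are quantified on arrays; a
matched control uses the same protein with its RNA-binding domain (RRM)
deleted. For each gene the *net* enrichment is the IP log2 ratio minus the
control log2 ratio, averaged over independent experiments. Genes whose net
enrichment exceeds the mean by ``z_cutoff`` sample standard deviations
(default 1.65, the one-sided 5% normal point) are called targets.

Overlap between two target lists drawn from a common gene universe is
scored with the hypergeometric upper tail, computed in log space so that
p-values far below the double-precision underflow limit (e.g. ~1e-74 for
the two published Whi3 target lists) keep an accurate magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import RipExperiment

logger = logging.getLogger("whi3kit")


@dataclass
class TargetCall:
    """Result of thresholding mean net enrichment ratios."""

    net_ratio: dict[str, float]
    threshold: float
    targets: list[str]  # descending net ratio, ties broken by gene_id
    z_cutoff: float = 1.65

    def to_frame(self):
        import pandas as pd

        order = sorted(self.net_ratio, key=lambda g: (-self.net_ratio[g], g))
        rank = {g: i + 1 for i, g in enumerate(order)}
        tset = set(self.targets)
        return pd.DataFrame(
            {
                "gene_id": order,
                "net_ratio": [self.net_ratio[g] for g in order],
                "rank": [rank[g] for g in order],
                "is_target": [g in tset for g in order],
            }
        ).set_index("gene_id")


def net_enrichment(experiments: Iterable[RipExperiment]) -> dict[str, float]:
    """Mean net (IP minus control) log2 ratio per gene across experiments.

    Genes absent from any experiment are dropped with a warning.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("at least one experiment is required")
    common = set.intersection(*(e.genes for e in experiments))
    dropped = set.union(*(e.genes for e in experiments)) - common
    if dropped:
        logger.warning("net_enrichment: dropping %d genes absent from some experiment", len(dropped))
    return {
        g: float(np.mean([e.ip_ratio[g] - e.control_ratio[g] for e in experiments]))
        for g in sorted(common)
    }


def call_targets(net: Mapping[str, float], z_cutoff: float = 1.65) -> TargetCall:
    """Call targets as genes whose net ratio is > mean + z_cutoff * sample SD.

    The SD uses the n-1 denominator. The comparison is strict, so a
    zero-variance input yields an empty target list.
    """
    if len(net) < 2:
        raise ValueError("target calling needs at least two genes")
    values = np.array([net[g] for g in net], dtype=float)
    threshold = float(values.mean() + z_cutoff * values.std(ddof=1))
    targets = sorted(
        (g for g, v in net.items() if v > threshold),
        key=lambda g: (-net[g], g),
    )
    return TargetCall(net_ratio=dict(net), threshold=threshold, targets=targets, z_cutoff=z_cutoff)


class OverlapResult(NamedTuple):
    overlap: int
    p_value: float
    log10_p: float


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    i = np.asarray(i, dtype=float)
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def overlap_test(
    list_a: Iterable[str], list_b: Iterable[str], universe_n: int
) -> OverlapResult:
    """Hypergeometric upper-tail test for the overlap of two gene lists.

    Returns the overlap count k, ``p = P(X >= k)`` for
    X ~ Hypergeometric(N=universe_n, K=|A|, n=|B|), and log10(p). The tail
    is summed in log space, so extreme overlaps report an accurate
    magnitude even when ``p_value`` itself underflows to 0.
    """
    a, b = set(list_a), set(list_b)
    if len(a | b) > universe_n:
        raise ValueError("universe smaller than the union of the two lists")
    K, n = len(a), len(b)
    k = len(a & b)
    if k == 0:
        return OverlapResult(0, 1.0, 0.0)
    lo, hi = k, min(K, n)
    i = np.arange(lo, hi + 1)
    logp = float(logsumexp(_log_hypergeom_pmf(i, universe_n, K, n)))
    logp = min(logp, 0.0)  # guard rounding just above 1
    return OverlapResult(k, math.exp(logp), logp / math.log(10))
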