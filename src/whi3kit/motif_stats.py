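"""Motif densities, quartile summaries and structure meta-profiles.

The binding determinant studied here is a short tetra/pentanucleotide
(GCAU / UGCAU); an AU-rich element (AUUUUA) in the 3'UTR is a second motif
of interest and CGUA serves as an irrelevant control. Motif density is
occurrences per kb over the whole transcript including both UTRs; a local
clustering statistic records the maximum count in any 300-nt window.

Conventions (the source assays leave these open; fixed here and
documented): occurrences may overlap; an occurrence belongs to the region
(5'UTR / ORF / 3'UTR) containing its *start* position; ``N`` never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel

logger = logging.getLogger("whi3kit")

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")  # Q4 = densest


@dataclass(frozen=True)
class MotifProfile:
    """Motif statistics for one transcript."""

    gene_id: str
    motif: str
    count: int
    density: float  # occurrences per kb, UTRs included
    local_max: int  # max occurrences in any `window`-nt window
    region_counts: dict  # {"utr5": int, "orf": int, "utr3": int}


@dataclass(frozen=True)
class ParsTrack:
    """Per-nucleotide structure scores (nuclease cut frequencies) for one gene."""

    gene_id: str
    scores: tuple

    def __post_init__(self):
        if len(self.scores) == 0:
            raise ValueError(f"{self.gene_id}: empty score track")


def find_motif(sequence: str, motif: str, allow_overlap: bool = True) -> list[int]:
    """Start positions of motif occurrences on the sense strand."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = []
    start, m = 0, len(motif)
    while True:
        i = sequence.find(motif, start)
        if i < 0:
            return positions
        positions.append(i)
        start = i + 1 if allow_overlap else i + m


def count_motif(sequence: str, motif: str, allow_overlap: bool = True) -> int:
    """Number of motif start positions in the sequence (overlaps counted by default)."""
    return len(find_motif(sequence, motif, allow_overlap))


def local_max_density(sequence: str, motif: str, window: int = 300) -> int:
    """Maximum motif count in any sliding window of ``window`` nt.

    An occurrence is inside a window when its start position is; a window
    longer than the sequence reduces to the total count.
    """
    if window < len(motif):
        raise ValueError("window must be at least the motif length")
    starts = find_motif(sequence, motif)
    if not starts or window >= len(sequence):
        return len(starts)
    starts_arr = np.asarray(starts)
    # two-pointer sweep over occurrence-anchored windows
    best = 0
    j = 0
    for i, s in enumerate(starts_arr):
        while starts_arr[j] <= s - window:
            j += 1
        best = max(best, i - j + 1)
    return best


def motif_density(gene: GeneModel, motif: str, window: int = 300) -> MotifProfile:
    """Full motif profile for a transcript: count, per-kb density, local max, region split."""
    starts = find_motif(gene.sequence, motif)
    orf_end = gene.utr5_len + gene.orf_len
    region_counts = {
        "utr5": sum(1 for s in starts if s < gene.utr5_len),
        "orf": sum(1 for s in starts if gene.utr5_len <= s < orf_end),
        "utr3": sum(1 for s in starts if s >= orf_end),
    }
    return MotifProfile(
        gene_id=gene.gene_id,
        motif=motif,
        count=len(starts),
        density=len(starts) * 1000.0 / gene.length,
        local_max=local_max_density(gene.sequence, motif, window),
        region_counts=region_counts,
    )


def density_table(genes: Mapping[str, GeneModel], motif: str) -> pd.DataFrame:
    """Per-gene density DataFrame for a whole transcriptome."""
    rows = [motif_density(g, motif) for g in genes.values()]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "count": [r.count for r in rows],
            "density": [r.density for r in rows],
            "local_max": [r.local_max for r in rows],
        }
    ).set_index("gene_id")


def assign_quartiles(values: Mapping[str, float]) -> dict[str, str]:
    """Split genes into four quartiles by value; Q4 is the highest.

    Sizes follow the largest-remainder rule (the first ``n % 4`` quartiles,
    counted from Q1, get one extra gene). Ties in value are broken by
    gene_id sort, so the assignment is deterministic.
    """
    n = len(values)
    if n < 4:
        raise ValueError("quartile assignment needs at least four genes")
    order = sorted(values, key=lambda g: (values[g], g))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    out: dict[str, str] = {}
    idx = 0
    for label, size in zip(QUARTILE_LABELS, sizes):
        for g in order[idx : idx + size]:
            out[g] = label
        idx += size
    return out


def quartile_response_summary(
    fold_changes: Mapping[str, float],
    quartiles: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean log2 fold change per density quartile, with 95% bootstrap CIs.

    Genes with a fold change but no quartile label are dropped with a
    warning; an empty quartile is an error. The bootstrap (``n_boot``
    draws, seeded) resamples genes within each quartile.
    """
    missing = [g for g in fold_changes if g not in quartiles]
    if missing:
        logger.warning("quartile_response_summary: dropping %d unlabelled genes", len(missing))
    rng = np.random.default_rng(seed)
    rows = []
    for label in QUARTILE_LABELS:
        vals = np.array(
            [fold_changes[g] for g in sorted(fold_changes) if quartiles.get(g) == label]
        )
        if vals.size == 0:
            raise ValueError(f"quartile {label} is empty")
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {"quartile": label, "n": vals.size, "mean_log2": vals.mean(),
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows).set_index("quartile")


def utr3_presence_fraction(
    genes: Mapping[str, GeneModel], motif: str, gene_set: Iterable[str]
) -> float:
    """Fraction of ``gene_set`` with >=1 motif occurrence wholly inside the 3'UTR."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    hits = 0
    for gid in gene_set:
        g = genes[gid]
        utr3_start = g.utr5_len + g.orf_len
        starts = find_motif(g.sequence, motif)
        if any(s >= utr3_start and s + len(motif) <= g.length for s in starts):
            hits += 1
    return hits / len(gene_set)


def category_enrichment(k_in_set: int, n_set: int, background_freq: float) -> float:
    """One-sided binomial upper tail P(X >= k), X ~ Binomial(n, background_freq)."""
    if not (0 <= k_in_set <= n_set):
        raise ValueError("need 0 <= k <= n")
    if not (0 < background_freq < 1):
        raise ValueError("background frequency must be in (0, 1)")
    return float(stats.binom.sf(k_in_set - 1, n_set, background_freq))


def pars_metaprofile(
    tracks: Mapping[str, ParsTrack],
    occurrences: Iterable[tuple[str, int]],
    motif_len: int,
    groups: Mapping[str, str],
    flank: int = 50,
) -> dict[str, np.ndarray]:
    """Motif-centred mean structure profiles, one per gene group.

    ``occurrences`` are (gene_id, start) pairs; windows are the motif plus
    ``flank`` nt on each side, aligned on the motif, and averaged per
    position within each group (e.g. target vs non-target). Occurrences
    whose window runs off the transcript are dropped (count logged). A
    group with no usable occurrence is an error.
    """
    width = 2 * flank + motif_len
    acc: dict[str, list[np.ndarray]] = {}
    dropped = 0
    for gene_id, start in occurrences:
        track = tracks[gene_id]
        scores = np.asarray(track.scores, dtype=float)
        lo, hi = start - flank, start + motif_len + flank
        if lo < 0 or hi > scores.size:
            dropped += 1
            continue
        acc.setdefault(groups[gene_id], []).append(scores[lo:hi])
    if dropped:
        logger.info("pars_metaprofile: dropped %d occurrences without full flanks", dropped)
    profiles = {}
    for group in sorted(set(groups.values())):
        windows = acc.get(group, [])
        if not windows:
            raise ValueError(f"group {group!r} has no usable motif occurrence")
        profiles[group] = np.vstack(windows).mean(axis=0)
        assert profiles[group].size == width
    return profiles
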