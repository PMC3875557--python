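"""RPKM, translational efficiency and the rank test for a focal gene.

Abundance is quantified as reads per kilobase of gene length per million
mapped reads (RPKM), after dropping genes with fewer than 7 reads.
Translational efficiency (TE) is footprint RPKM divided by mRNA RPKM; the
relative TE of a gene is its mutant TE over its wild-type TE. The
significance of one gene's relative TE is empirical: genes with fewer
than ``read_floor`` raw reads in any of the four libraries are excluded,
the remainder are ranked by relative TE (descending, ties share the
better rank), and the one-tailed p-value is ``rank / n_ranked``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountTable

logger = logging.getLogger("whi3kit")


@dataclass(frozen=True)
class TEResult:
    """Relative translational efficiency of a focal gene and its rank test."""

    gene_id: str
    rpkm_fp_wt: float
    rpkm_fp_mut: float
    rpkm_rna_wt: float
    rpkm_rna_mut: float
    te_wt: float
    te_mut: float
    rel_te: float
    log2_rel_te: float
    rank: int
    n_ranked: int
    p_one_tailed: float


def compute_rpkm(
    table: CountTable, lengths: Mapping[str, int], min_reads: int = 7
) -> pd.Series:
    """RPKM per gene; genes with fewer than ``min_reads`` reads are dropped.

    ``lengths`` are in nucleotides (conventionally the ORF length; the full
    transcript is a documented alternative). A counted gene without a
    length is an error.
    """
    missing = [g for g in table.counts if g not in lengths]
    if missing:
        raise KeyError(f"{table.sample_id}: no length for gene(s) {missing[:5]}")
    total_millions = table.total_mapped / 1e6
    out = {}
    for g, c in table.counts.items():
        if c < min_reads:
            continue
        out[g] = c / ((lengths[g] / 1000.0) * total_millions)
    return pd.Series(out, name=table.sample_id).sort_index()


def translational_efficiency(fp_rpkm: pd.Series, rna_rpkm: pd.Series) -> pd.Series:
    """TE = footprint RPKM / RNA RPKM over the gene intersection.

    Genes with zero RNA RPKM are dropped with a warning.
    """
    common = fp_rpkm.index.intersection(rna_rpkm.index)
    rna = rna_rpkm.loc[common]
    zero = rna.index[rna == 0]
    if len(zero):
        logger.warning("translational_efficiency: dropping %d genes with zero RNA RPKM", len(zero))
        common = common.difference(zero)
    return (fp_rpkm.loc[common] / rna_rpkm.loc[common]).rename("te")


def relative_te(te_mut: pd.Series, te_wt: pd.Series) -> pd.Series:
    """Per-gene mutant/wild-type TE ratio over the gene intersection."""
    common = te_mut.index.intersection(te_wt.index)
    return (te_mut.loc[common] / te_wt.loc[common]).rename("rel_te")


def min_reads_across(tables: Iterable[CountTable]) -> dict[str, int]:
    """Per-gene minimum raw count across libraries (for the read floor)."""
    tables = list(tables)
    genes = set.intersection(*(set(t.counts) for t in tables))
    return {g: min(t.counts[g] for t in tables) for g in genes}


def rank_test(
    rel_te: pd.Series | Mapping[str, float],
    focal: str,
    per_gene_reads: Mapping[str, int],
    read_floor: int = 200,
    te_wt: pd.Series | None = None,
    te_mut: pd.Series | None = None,
    rpkm: Mapping[str, pd.Series] | None = None,
) -> TEResult:
    """Empirical one-tailed rank test of the focal gene's relative TE.

    ``per_gene_reads`` maps each gene to its minimum raw count across the
    four libraries (see :func:`min_reads_across`); genes below
    ``read_floor`` are excluded from the ranking. The focal gene must pass
    the floor itself. Ties share the better (smaller) rank.
    """
    rel = pd.Series(rel_te, dtype=float)
    if focal not in rel.index:
        raise KeyError(f"focal gene {focal!r} has no relative TE")
    keep = [g for g in rel.index if per_gene_reads.get(g, 0) >= read_floor]
    if focal not in keep:
        raise ValueError(
            f"focal gene {focal!r} is excluded by the {read_floor}-read floor"
        )
    ranked = rel.loc[keep]
    focal_val = float(ranked.loc[focal])
    rank = int((ranked > focal_val).sum()) + 1  # ties share the better rank
    n = len(ranked)
    get = lambda s: float(s.loc[focal]) if s is not None and focal in s.index else float("nan")  # noqa: E731
    rp = rpkm or {}
    return TEResult(
        gene_id=focal,
        rpkm_fp_wt=get(rp.get("fp_wt")),
        rpkm_fp_mut=get(rp.get("fp_mut")),
        rpkm_rna_wt=get(rp.get("rna_wt")),
        rpkm_rna_mut=get(rp.get("rna_mut")),
        te_wt=get(te_wt),
        te_mut=get(te_mut),
        rel_te=focal_val,
        log2_rel_te=float(np.log2(focal_val)),
        rank=rank,
        n_ranked=n,
        p_one_tailed=rank / n,
    )


def te_analysis(
    tables: Mapping[str, CountTable],
    lengths: Mapping[str, int],
    focal: str,
    min_reads: int = 7,
    read_floor: int = 200,
) -> tuple[pd.Series, TEResult]:
    """Full pipeline from the four count tables to the focal-gene rank test.

    ``tables`` must contain keys ``rna_wt``, ``rna_mut``, ``fp_wt``,
    ``fp_mut``. Returns the per-gene relative-TE series and the focal
    :class:`TEResult`.
    """
    rpkm = {name: compute_rpkm(t, lengths, min_reads=min_reads) for name, t in tables.items()}
    te_wt = translational_efficiency(rpkm["fp_wt"], rpkm["rna_wt"])
    te_mut = translational_efficiency(rpkm["fp_mut"], rpkm["rna_mut"])
    rel = relative_te(te_mut, te_wt)
    reads = min_reads_across(tables.values())
    result = rank_test(
        rel, focal, reads, read_floor=read_floor,
        te_wt=te_wt, te_mut=te_mut, rpkm=rpkm,
    )
    return rel, result


def footprint_fold(abundance_fold: float, te_fold: float) -> float:
    """Decomposition of a footprint change into abundance x efficiency.

    The fold change in total ribosome footprints over a gene is the
    product of its mRNA abundance fold change and its TE fold change.
    """
    return abundance_fold * te_fold
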