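"""Readers, writers and the shared coordinate conventions.

All coordinates are 0-based half-open and all lengths are in nucleotides.
Sequences are held as RNA (``A,C,G,U,N``); DNA input is transcribed
``T -> U`` at ingest and case-folded to upper. Motif analysis is strictly
mRNA-level: only the sense strand is ever scanned.

Tabular formats are tab-delimited with a header row; lines starting with
``#`` are comments (a ``#total_mapped`` line in a count table is the one
structured comment, see :func:`read_count_table`).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("whi3kit")

RNA_ALPHABET = frozenset("ACGUN")

#: UTR length assumed when a gene has no annotation (flank rule).
DEFAULT_UTR_FLANK = 200


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One transcript: sequence plus 5'UTR / ORF / 3'UTR extents.

    The invariant ``utr5_len + orf_len + utr3_len == len(sequence)`` is
    enforced at construction; the ORF must be non-empty.
    """

    gene_id: str
    sequence: str
    utr5_len: int
    orf_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: negative UTR length")
        if self.orf_len <= 0:
            raise ValueError(f"{self.gene_id}: ORF length must be positive")
        if self.utr5_len + self.orf_len + self.utr3_len != len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: utr5+orf+utr3 = "
                f"{self.utr5_len + self.orf_len + self.utr3_len} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-RNA characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def orf(self) -> str:
        return self.sequence[self.utr5_len : self.utr5_len + self.orf_len]

    @property
    def utr3(self) -> str:
        return self.sequence[self.utr5_len + self.orf_len :]


@dataclass
class CountTable:
    """Per-gene read counts for one sequencing library."""

    sample_id: str
    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"{self.sample_id}:{g}: count must be a nonnegative integer")
        self.counts = {g: int(c) for g, c in self.counts.items()}
        if self.total_mapped <= 0:
            raise ValueError(f"{self.sample_id}: total_mapped must be positive")
        if self.total_mapped < sum(self.counts.values()):
            raise ValueError(f"{self.sample_id}: total_mapped smaller than summed counts")


@dataclass
class RipExperiment:
    """One immunoprecipitation experiment: IP and matched control log2 ratios."""

    experiment_id: str
    ip_ratio: dict[str, float]
    control_ratio: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.ip_ratio) != set(self.control_ratio):
            raise ValueError(f"{self.experiment_id}: IP and control gene sets differ")
        import math

        for d in (self.ip_ratio, self.control_ratio):
            for g, v in d.items():
                if not math.isfinite(v):
                    raise ValueError(f"{self.experiment_id}:{g}: non-finite log ratio")

    @property
    def genes(self) -> set[str]:
        return set(self.ip_ratio)


@dataclass(frozen=True)
class DecayCourse:
    """One transcription shut-off time course (one gene, one replicate)."""

    genotype: str
    gene: str
    timepoints: tuple[float, ...]
    target_quantity: tuple[float, ...]
    reference_quantity: tuple[float, ...]
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        n = len(self.timepoints)
        if n < 2:
            raise ValueError("a decay course needs at least two timepoints")
        if len(self.target_quantity) != n or len(self.reference_quantity) != n:
            raise ValueError("timepoints and quantities must have equal lengths")
        if self.timepoints[0] != 0:
            raise ValueError("first timepoint must be 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(q <= 0 for q in self.target_quantity):
            raise ValueError("target quantities must be positive")


@dataclass(frozen=True)
class DuplexMeasurement:
    """Band intensities for one duplex-PCR lane of a long/short-allele diploid."""

    genotype: str  # "WT" or "mutant"
    allele_config: str  # e.g. "Long-GCAU/Short-gcau_mut"
    long_intensity: float
    short_intensity: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.long_intensity <= 0 or self.short_intensity <= 0:
            raise ValueError("band intensities must be positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def transcribe(seq: str) -> str:
    """Upper-case and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{gene_id: RNA sequence}``.

    DNA is transcribed (T->U) and sequences upper-cased. Duplicate ids and
    empty records are errors.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if not record.id:
                raise FormatError(f"{path}: record with empty header")
            if record.id in out:
                raise FormatError(f"{path}: duplicate record id {record.id!r}")
            seq = transcribe(str(record.seq))
            if not seq:
                raise FormatError(f"{path}: empty sequence for {record.id!r}")
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise FormatError(f"{path}:{record.id}: invalid characters {sorted(bad)}")
            out[record.id] = seq
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene_id in sequences:
            fh.write(f">{gene_id}\n")
            seq = sequences[gene_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# UTR annotation
# ---------------------------------------------------------------------------

def _fallback_gene_model(gene_id: str, seq: str, utr5, utr3, flank: int) -> GeneModel:
    """Fill missing UTR lengths with ``min(flank, available flank)``.

    The available flank is capped so that the ORF keeps at least 1 nt: with
    both UTRs missing each side gets at most ``(len-1)//2``; with one side
    given, the other gets at most ``len - given - 1``.
    """
    n = len(seq)
    if utr5 is not None and utr3 is not None:
        u5, u3 = int(utr5), int(utr3)
        if u5 + u3 >= n:
            raise FormatError(f"{gene_id}: utr5+utr3 = {u5 + u3} leaves no ORF in {n} nt")
    elif utr5 is None and utr3 is None:
        u5 = u3 = min(flank, (n - 1) // 2)
    elif utr5 is None:
        u3 = int(utr3)
        if u3 >= n:
            raise FormatError(f"{gene_id}: utr3 = {u3} leaves no ORF in {n} nt")
        u5 = min(flank, n - u3 - 1)
    else:
        u5 = int(utr5)
        if u5 >= n:
            raise FormatError(f"{gene_id}: utr5 = {u5} leaves no ORF in {n} nt")
        u3 = min(flank, n - u5 - 1)
    return GeneModel(gene_id, seq, u5, n - u5 - u3, u3)


def read_utr_table(
    path: str | Path,
    sequences: Mapping[str, str],
    flank: int = DEFAULT_UTR_FLANK,
) -> dict[str, GeneModel]:
    """Read a UTR annotation TSV and build gene models for *all* sequences.

    The table needs a ``gene_id`` column; ``utr5_len`` / ``utr3_len`` columns
    (either may be missing, or individual cells may be empty) give UTR
    lengths. Genes without a row, or with missing cells, fall back to
    ``flank``-nt UTRs (default 200 nt), shrunk if the transcript is short.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    annotations: dict[str, tuple] = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if gid not in sequences:
            raise FormatError(f"{path}: gene {gid!r} not present in the sequence set")
        u5 = row.get("utr5_len")
        u3 = row.get("utr3_len")
        u5 = None if u5 is None or pd.isna(u5) else int(u5)
        u3 = None if u3 is None or pd.isna(u3) else int(u3)
        annotations[gid] = (u5, u3)
    out = {}
    for gid, seq in sequences.items():
        u5, u3 = annotations.get(gid, (None, None))
        out[gid] = _fallback_gene_model(gid, seq, u5, u3, flank)
    return out


def read_utr_bed(
    path: str | Path,
    sequences: Mapping[str, str],
    flank: int = DEFAULT_UTR_FLANK,
) -> dict[str, GeneModel]:
    """Read UTR extents from a BED file (chrom = gene_id, half-open intervals).

    The interval name column must be ``utr5`` or ``utr3``; the UTR length is
    the interval length. Unannotated genes fall back as in
    :func:`read_utr_table`.
    """
    path = Path(path)
    annotations: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED line needs chrom/start/end/name")
            gid, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if gid not in sequences:
                raise FormatError(f"{path}:{lineno}: gene {gid!r} not in sequence set")
            if name not in ("utr5", "utr3"):
                raise FormatError(f"{path}:{lineno}: interval name must be utr5 or utr3")
            annotations.setdefault(gid, {})[name] = end - start
    out = {}
    for gid, seq in sequences.items():
        ann = annotations.get(gid, {})
        out[gid] = _fallback_gene_model(gid, seq, ann.get("utr5"), ann.get("utr3"), flank)
    return out


def write_utr_table(path: str | Path, genes: Mapping[str, GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tutr5_len\tutr3_len\n")
        for gid in genes:
            g = genes[gid]
            fh.write(f"{gid}\t{g.utr5_len}\t{g.utr3_len}\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> list[CountTable]:
    """Read a count TSV (``gene_id`` + one column per sample) into CountTables.

    By default each library's total mapped reads is its column sum; a
    structured comment line ``#total_mapped<TAB>sample=value ...`` overrides
    it (larger totals arise when reads map outside the tabulated genes).
    """
    path = Path(path)
    overrides: dict[str, int] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#total_mapped"):
                for tok in line.strip().split("\t")[1:]:
                    name, _, val = tok.partition("=")
                    overrides[name] = int(val)
            elif not line.startswith("#"):
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    tables = []
    for sample in df.columns:
        col = df[sample]
        if (col < 0).any() or (col != col.astype(int)).any():
            raise FormatError(f"{path}:{sample}: counts must be nonnegative integers")
        counts = {g: int(c) for g, c in col.items()}
        total = overrides.get(sample, sum(counts.values()))
        tables.append(CountTable(sample_id=sample, counts=counts, total_mapped=total))
    return tables


def write_count_table(path: str | Path, tables: Iterable[CountTable]) -> None:
    tables = list(tables)
    genes = sorted(set().union(*(t.counts for t in tables)))
    with open(path, "w") as fh:
        fh.write(
            "#total_mapped\t"
            + "\t".join(f"{t.sample_id}={t.total_mapped}" for t in tables)
            + "\n"
        )
        fh.write("gene_id\t" + "\t".join(t.sample_id for t in tables) + "\n")
        for g in genes:
            fh.write(g + "\t" + "\t".join(str(t.counts.get(g, 0)) for t in tables) + "\n")


# ---------------------------------------------------------------------------
# RIP-chip, decay and duplex tables (long format)
# ---------------------------------------------------------------------------

def read_ripchip_table(path: str | Path) -> list[RipExperiment]:
    """Read a long-format RIP TSV: experiment_id, gene_id, ip_ratio, control_ratio."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "experiment_id": str})
    needed = {"experiment_id", "gene_id", "ip_ratio", "control_ratio"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: columns {sorted(needed)} required")
    out = []
    for exp_id, grp in df.groupby("experiment_id", sort=True):
        out.append(
            RipExperiment(
                experiment_id=str(exp_id),
                ip_ratio=dict(zip(grp["gene_id"], grp["ip_ratio"].astype(float))),
                control_ratio=dict(zip(grp["gene_id"], grp["control_ratio"].astype(float))),
            )
        )
    return out


def write_ripchip_table(path: str | Path, experiments: Iterable[RipExperiment]) -> None:
    with open(path, "w") as fh:
        fh.write("experiment_id\tgene_id\tip_ratio\tcontrol_ratio\n")
        for exp in experiments:
            for g in sorted(exp.ip_ratio):
                fh.write(
                    f"{exp.experiment_id}\t{g}\t"
                    f"{float(exp.ip_ratio[g])!r}\t{float(exp.control_ratio[g])!r}\n"
                )


def read_decay_table(path: str | Path) -> list[DecayCourse]:
    """Read a long-format shut-off TSV: genotype, gene, replicate, time_min, target_q, reference_q."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"genotype", "gene", "replicate", "time_min", "target_q", "reference_q"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: columns {sorted(needed)} required")
    courses = []
    for (geno, gene, rep), grp in df.groupby(["genotype", "gene", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        courses.append(
            DecayCourse(
                genotype=str(geno),
                gene=str(gene),
                replicate_id=str(rep),
                timepoints=tuple(grp["time_min"].astype(float)),
                target_quantity=tuple(grp["target_q"].astype(float)),
                reference_quantity=tuple(grp["reference_q"].astype(float)),
            )
        )
    return courses


def write_decay_table(path: str | Path, courses: Iterable[DecayCourse]) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tgene\treplicate\ttime_min\ttarget_q\treference_q\n")
        for c in courses:
            for t, q, r in zip(c.timepoints, c.target_quantity, c.reference_quantity):
                fh.write(
                    f"{c.genotype}\t{c.gene}\t{c.replicate_id}\t"
                    f"{float(t)!r}\t{float(q)!r}\t{float(r)!r}\n"
                )


def read_duplex_table(path: str | Path) -> list[DuplexMeasurement]:
    """Read a duplex-PCR TSV: genotype, allele_config, replicate, long_intensity, short_intensity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"genotype", "allele_config", "replicate", "long_intensity", "short_intensity"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: columns {sorted(needed)} required")
    return [
        DuplexMeasurement(
            genotype=str(r.genotype),
            allele_config=str(r.allele_config),
            replicate_id=str(r.replicate),
            long_intensity=float(r.long_intensity),
            short_intensity=float(r.short_intensity),
        )
        for r in df.itertuples()
    ]


def write_duplex_table(path: str | Path, measurements: Iterable[DuplexMeasurement]) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tallele_config\treplicate\tlong_intensity\tshort_intensity\n")
        for m in measurements:
            fh.write(
                f"{m.genotype}\t{m.allele_config}\t{m.replicate_id}\t"
                f"{float(m.long_intensity)!r}\t{float(m.short_intensity)!r}\n"
            )


def read_ratio_table(path: str | Path) -> pd.DataFrame:
    """Read a generic per-gene ratio TSV (gene_id index, float columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    return df.set_index("gene_id").astype(float)


def write_ratio_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
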