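"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the real assays:

* a transcriptome whose genes carry *exact*, requested motif counts
  (spontaneous occurrences are scrubbed before planting), spanning a
  range of motif densities;
* immunoprecipitation log-ratio pairs where a planted target set receives
  a net enrichment shift on top of Gaussian noise;
* four negative-binomial count libraries (RNA and ribosome footprints,
  wild-type and mutant) in which mutant mRNA abundance scales with motif
  density and one focal gene carries a planted translational-efficiency
  multiplier;
* first-order transcription shut-off courses with multiplicative
  lognormal noise;
* duplex-PCR band intensities from diploids carrying a motif-bearing and
  a motif-free allele, with a genotype-dependent destabilization factor
  and a motif-independent allele bias.

Every generator is fully deterministic under the configured seed; each
draws from its own substream derived from that one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .io_formats import (
    CountTable,
    DecayCourse,
    DuplexMeasurement,
    GeneModel,
    RipExperiment,
)
from .motif_stats import ParsTrack, count_motif, find_motif, motif_density

_BASES = np.array(list("ACGU"))

# substream ids: one per generator so adding draws to one stage never
# perturbs another
_STREAMS = {
    "transcriptome": 0,
    "ripchip": 1,
    "counts": 2,
    "decay": 3,
    "duplex": 4,
    "panel": 5,
    "pars": 6,
    "utr3": 7,
}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study, with defaults matching the
    effect sizes the pipeline is meant to resolve (~1.5-fold abundance and
    translational-efficiency effects, minute-scale half-lives).
    """

    seed: int = 0
    n_genes: int = 200
    motif: str = "GCAU"
    length_range: tuple[int, int] = (1000, 3000)
    density_range: tuple[float, float] = (0.0, 8.0)  # motifs per kb
    utr_len: int = 200
    # RIP-chip
    target_fraction: float = 0.1
    enrichment_effect: float = 3.0  # log2 net shift for planted targets
    rip_noise_sd: float = 0.5  # SD of one experiment's net ratio
    n_experiments: int = 2
    # count libraries
    abundance_slope: float = 0.1  # log2 fold change per motif/kb in the mutant
    te_effect_gene: tuple[str, float] = ("CLN3-like", 1.53)
    library_size: int = 2_000_000
    dispersion: float = 0.01  # NB: var = mu + dispersion * mu^2
    abundance_sigma: float = 0.7  # lognormal spread of baseline expression
    te_sigma: float = 0.3  # lognormal spread of per-gene efficiency
    # decay courses
    decay_half_life: float = 1.9  # minutes (wild-type)
    timepoints: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 15.0)
    noise_cv: float = 0.1  # lognormal CV for qPCR-style readouts
    # duplex-PCR
    destabilization: float = 1.5  # fold destabilization of the motif allele by the protein
    allele_bias: float = 0.46  # motif-independent abundance of the mutated allele
    duplex_noise_cv: float = 0.2
    n_wt_lanes: int = 15
    n_mut_lanes: int = 12

    def __post_init__(self) -> None:
        if not (0 < self.target_fraction < 1):
            raise ValueError("target_fraction must be in (0, 1)")
        for name in ("n_genes", "utr_len", "n_experiments", "library_size",
                     "n_wt_lanes", "n_mut_lanes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rip_noise_sd", "decay_half_life", "destabilization",
                     "allele_bias"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.noise_cv < 0 or self.duplex_noise_cv < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.density_range[0] < 0 or self.density_range[1] < self.density_range[0]:
            raise ValueError("density_range must be a nondecreasing nonnegative pair")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-generator substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def focal_gene(self) -> str:
        return self.te_effect_gene[0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("length_range", "density_range", "timepoints", "te_effect_gene"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _scrub_motif(seq: list[str], motif: str, rng: np.random.Generator,
                 protected: Sequence[tuple[int, int]] = (),
                 region: tuple[int, int] | None = None,
                 max_rounds: int = 200) -> None:
    """Mutate bases in place until the motif has no occurrence outside
    ``protected`` windows (restricted to ``region`` if given)."""
    m = len(motif)
    lo, hi = region if region is not None else (0, len(seq))
    for _ in range(max_rounds):
        text = "".join(seq)
        spurious = [
            s for s in find_motif(text, motif)
            if lo <= s and s + m <= hi
            and not any(p0 <= s < p1 or p0 < s + m <= p1 for p0, p1 in protected)
        ]
        if not spurious:
            return
        for s in spurious:
            # pick a mutable base of this occurrence outside protected windows
            choices = [
                i for i in range(s, s + m)
                if not any(p0 <= i < p1 for p0, p1 in protected)
            ]
            i = int(rng.choice(choices))
            seq[i] = str(rng.choice(_BASES[_BASES != seq[i]]))
    raise RuntimeError("motif scrubbing failed to converge")


def synthesize_gene(
    gene_id: str,
    length: int,
    density: float,
    motif: str,
    rng: np.random.Generator,
    utr_len: int = 200,
) -> GeneModel:
    """Random transcript of the given length carrying *exactly*
    ``round(density * length / 1000)`` motif occurrences.

    The background is scrubbed of spontaneous occurrences, then the exact
    number of non-overlapping copies is planted at random positions.
    """
    m = len(motif)
    count = int(round(density * length / 1000.0))
    if count * m > length:
        raise ValueError(
            f"{gene_id}: density {density}/kb needs {count} x {m} nt motifs "
            f"in a {length}-nt gene"
        )
    seq = list(rng.choice(_BASES, size=length))
    # choose non-overlapping plant positions
    planted: list[int] = []
    for _ in range(10_000):
        if len(planted) == count:
            break
        p = int(rng.integers(0, length - m + 1))
        if all(abs(p - q) >= m for q in planted):
            planted.append(p)
    else:
        raise RuntimeError(f"{gene_id}: could not place {count} motif copies")
    windows = [(p, p + m) for p in planted]
    for p in planted:
        seq[p : p + m] = list(motif)
    _scrub_motif(seq, motif, rng, protected=windows)
    u5 = min(utr_len, (length - 1) // 2)
    u3 = min(utr_len, length - u5 - 1)
    return GeneModel(gene_id, "".join(seq), u5, length - u5 - u3, u3)


def generate_transcriptome(cfg: SimulationConfig) -> dict[str, GeneModel]:
    """Gene models with realized motif densities spanning ``density_range``.

    Densities are evenly spaced across the range (deterministic coverage of
    both extremes); gene lengths are uniform over ``length_range``. The last
    gene is the focal gene named by ``te_effect_gene`` and sits at the
    middle of the density range.
    """
    rng = cfg.rng("transcriptome")
    n = cfg.n_genes
    lo, hi = cfg.density_range
    densities = np.linspace(lo, hi, n)
    rng.shuffle(densities)
    genes: dict[str, GeneModel] = {}
    for i in range(n):
        gid = cfg.focal_gene if i == n - 1 else f"g{i:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        dens = (lo + hi) / 2.0 if i == n - 1 else float(densities[i])
        genes[gid] = synthesize_gene(gid, length, dens, cfg.motif, rng, cfg.utr_len)
    return genes


def plant_utr3_presence(
    genes: Mapping[str, GeneModel],
    motif: str,
    gene_set: Iterable[str],
    fraction: float,
    rng: np.random.Generator,
) -> dict[str, GeneModel]:
    """Return gene models where exactly ``round(fraction * n)`` members of
    ``gene_set`` carry >=1 occurrence of ``motif`` wholly in the 3'UTR and
    the rest carry none (occurrences elsewhere are untouched)."""
    gene_set = sorted(gene_set)
    n_with = int(round(fraction * len(gene_set)))
    chosen = set(rng.choice(gene_set, size=n_with, replace=False)) if n_with else set()
    out = dict(genes)
    m = len(motif)
    for gid in gene_set:
        g = genes[gid]
        utr3_start = g.utr5_len + g.orf_len
        seq = list(g.sequence)
        if gid in chosen:
            if g.utr3_len < m:
                raise ValueError(f"{gid}: 3'UTR too short to plant {motif}")
            p = utr3_start + int(rng.integers(0, g.utr3_len - m + 1))
            seq[p : p + m] = list(motif)
            _scrub_motif(seq, motif, rng, protected=[(p, p + m)],
                         region=(utr3_start, g.length))
        else:
            _scrub_motif(seq, motif, rng, region=(utr3_start, g.length))
        out[gid] = GeneModel(gid, "".join(seq), g.utr5_len, g.orf_len, g.utr3_len)
    return out


# ---------------------------------------------------------------------------
# RIP-chip
# ---------------------------------------------------------------------------

def generate_ripchip(
    cfg: SimulationConfig, genes: Mapping[str, GeneModel]
) -> tuple[list[RipExperiment], list[str]]:
    """IP/control log-ratio experiments with a planted target set.

    Per experiment the net (IP minus control) ratio of a planted target is
    ``enrichment_effect`` plus N(0, rip_noise_sd); non-targets are centred
    at 0. IP and control each carry half of the net noise variance.
    """
    if cfg.n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = cfg.rng("ripchip")
    gene_ids = sorted(genes)
    n_targets = int(round(cfg.target_fraction * len(gene_ids)))
    targets = sorted(rng.choice(gene_ids, size=n_targets, replace=False))
    target_set = set(targets)
    sd = cfg.rip_noise_sd / np.sqrt(2.0)
    experiments = []
    for e in range(cfg.n_experiments):
        shifts = np.array([cfg.enrichment_effect if g in target_set else 0.0 for g in gene_ids])
        ip = shifts + rng.normal(0.0, sd, size=len(gene_ids))
        control = rng.normal(0.0, sd, size=len(gene_ids))
        experiments.append(
            RipExperiment(
                experiment_id=f"exp{e + 1}",
                ip_ratio=dict(zip(gene_ids, ip)),
                control_ratio=dict(zip(gene_ids, control)),
            )
        )
    return experiments, targets


# ---------------------------------------------------------------------------
# Count libraries
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(
    cfg: SimulationConfig, genes: Mapping[str, GeneModel]
) -> dict[str, CountTable]:
    """Four count libraries: RNA and footprints, wild-type and mutant.

    Expected mutant RNA abundance is the wild-type abundance times
    ``2 ** (abundance_slope * motif_density)``; expected footprint
    abundance is the RNA abundance times a per-gene translational
    efficiency, with the focal gene's efficiency multiplied by the planted
    factor in the mutant. Counts are negative binomial with the configured
    dispersion; totals are the realized column sums.
    """
    rng = cfg.rng("counts")
    gene_ids = sorted(genes)
    n = len(gene_ids)
    dens = np.array([motif_density(genes[g], cfg.motif).density for g in gene_ids])
    base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n)
    mu_rna_wt = base / base.sum() * cfg.library_size
    mu_rna_mut = mu_rna_wt * 2.0 ** (cfg.abundance_slope * dens)
    te = rng.lognormal(mean=0.0, sigma=cfg.te_sigma, size=n)
    focal_idx = gene_ids.index(cfg.focal_gene) if cfg.focal_gene in genes else None
    mu_fp_wt = mu_rna_wt * te
    te_mut = te.copy()
    if focal_idx is not None:
        te_mut[focal_idx] *= cfg.te_effect_gene[1]
    mu_fp_mut = mu_rna_mut * te_mut
    # keep footprint depth comparable to the RNA library
    mu_fp_wt = mu_fp_wt / mu_fp_wt.sum() * cfg.library_size
    mu_fp_mut = mu_fp_mut / mu_fp_mut.sum() * cfg.library_size
    tables = {}
    for name, mu in (
        ("rna_wt", mu_rna_wt),
        ("rna_mut", mu_rna_mut),
        ("fp_wt", mu_fp_wt),
        ("fp_mut", mu_fp_mut),
    ):
        counts = _nb_counts(rng, mu, cfg.dispersion)
        tables[name] = CountTable(
            sample_id=name,
            counts=dict(zip(gene_ids, (int(c) for c in counts))),
            total_mapped=int(counts.sum()),
        )
    return tables


# ---------------------------------------------------------------------------
# Decay courses
# ---------------------------------------------------------------------------

def generate_decay_courses(
    cfg: SimulationConfig,
    n_courses: int = 1,
    n_replicates: int = 3,
    half_life: float | None = None,
    genotype: str = "WT",
    gene: str = "CLN3-like",
    rng_offset: int = 0,
) -> list[list[DecayCourse]]:
    """Simulated shut-off courses: ``n_courses`` independent experiments,
    each with ``n_replicates`` replicate time series.

    True relative abundance is ``2 ** (-t / half_life)``; target and
    reference quantities each carry independent lognormal noise of CV
    ``noise_cv``. Returns a list of courses, each a list of replicate
    :class:`DecayCourse` objects sharing one fit. ``rng_offset`` selects an
    independent substream, so successive calls (e.g. per genotype) do not
    reuse the same noise draws.
    """
    hl = cfg.decay_half_life if half_life is None else half_life
    if hl <= 0:
        raise ValueError("half_life must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS["decay"], rng_offset))
    )
    t = np.asarray(cfg.timepoints, dtype=float)
    truth = 2.0 ** (-t / hl)
    out = []
    for c in range(n_courses):
        reps = []
        for r in range(n_replicates):
            target = truth * _lognormal_factor(rng, cfg.noise_cv, size=t.size)
            reference = np.ones_like(t) * _lognormal_factor(rng, cfg.noise_cv, size=t.size)
            reps.append(
                DecayCourse(
                    genotype=genotype,
                    gene=gene,
                    timepoints=tuple(t),
                    target_quantity=tuple(target),
                    reference_quantity=tuple(reference),
                    replicate_id=f"c{c + 1}r{r + 1}",
                )
            )
        out.append(reps)
    return out


# ---------------------------------------------------------------------------
# Duplex-PCR lanes
# ---------------------------------------------------------------------------

LONG_MOTIF_CONFIG = "Long-GCAU/Short-gcau_mut"
SHORT_MOTIF_CONFIG = "Long-gcau_mut/Short-GCAU"


def generate_duplex(
    cfg: SimulationConfig,
    allele_config: str = LONG_MOTIF_CONFIG,
) -> list[DuplexMeasurement]:
    """Duplex band intensities for one allele configuration in both genotypes.

    The motif-bearing allele has relative abundance ``1/destabilization``
    in the wild-type genotype (the protein destabilizes it) and 1 in the
    mutant genotype; the motif-free allele has abundance ``allele_bias``
    in both. Band intensities are abundance times lognormal noise times a
    random per-lane scale. Defaults give 15 wild-type and 12 mutant lanes.
    """
    if allele_config not in (LONG_MOTIF_CONFIG, SHORT_MOTIF_CONFIG):
        raise ValueError(f"unknown allele configuration {allele_config!r}")
    rng = cfg.rng("duplex")
    out = []
    for genotype, n_lanes in (("WT", cfg.n_wt_lanes), ("mutant", cfg.n_mut_lanes)):
        intact = 1.0 / cfg.destabilization if genotype == "WT" else 1.0
        mutated = cfg.allele_bias
        if allele_config == LONG_MOTIF_CONFIG:
            ab_long, ab_short = intact, mutated
        else:
            ab_long, ab_short = mutated, intact
        for r in range(n_lanes):
            scale = float(rng.uniform(0.5, 2.0))
            out.append(
                DuplexMeasurement(
                    genotype=genotype,
                    allele_config=allele_config,
                    long_intensity=ab_long * float(_lognormal_factor(rng, cfg.duplex_noise_cv)) * scale,
                    short_intensity=ab_short * float(_lognormal_factor(rng, cfg.duplex_noise_cv)) * scale,
                    replicate_id=f"{genotype}{r + 1}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Expression panel and structure tracks
# ---------------------------------------------------------------------------

def generate_expression_panel(
    cfg: SimulationConfig, genes: Mapping[str, GeneModel]
):
    """Five-condition log2 fold-change panel with a density-proportional
    planted effect: positive in the deletion-mutant columns, negative in
    the over-expressor columns, plus Gaussian measurement noise."""
    import pandas as pd

    rng = cfg.rng("panel")
    gene_ids = sorted(genes)
    dens = np.array([motif_density(genes[g], cfg.motif).density for g in gene_ids])
    effect = cfg.abundance_slope * dens
    noise = lambda: rng.normal(0.0, 0.3, size=len(gene_ids))  # noqa: E731
    return pd.DataFrame(
        {
            "whi3_glucose": effect + noise(),
            "whi3_ethanol": 0.6 * effect + noise(),
            "whi3_external": 0.4 * effect + noise(),
            "overexp_glucose": -0.5 * effect + noise(),
            "overexp_ethanol": -0.3 * effect + noise(),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def generate_pars_tracks(
    cfg: SimulationConfig,
    genes: Mapping[str, GeneModel],
    target_genes: Iterable[str],
    dip_depth: float = 1.0,
    dip_sigma: float = 5.0,
    baseline_sd: float = 0.1,
) -> dict[str, ParsTrack]:
    """Per-nucleotide structure-score tracks with a planted dip.

    Every gene gets a noisy flat baseline of 1; in ``target_genes`` a
    Gaussian dip of depth ``dip_depth`` is subtracted around the centre of
    each motif occurrence (modelling motif-local single-strandedness).
    """
    rng = cfg.rng("pars")
    targets = set(target_genes)
    m = len(cfg.motif)
    tracks = {}
    for gid in sorted(genes):
        g = genes[gid]
        scores = 1.0 + rng.normal(0.0, baseline_sd, size=g.length)
        if gid in targets:
            x = np.arange(g.length)
            for s in find_motif(g.sequence, cfg.motif):
                center = s + m / 2.0
                scores -= dip_depth * np.exp(-((x - center) ** 2) / (2.0 * dip_sigma**2))
        tracks[gid] = ParsTrack(gene_id=gid, scores=tuple(scores))
    return tracks
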