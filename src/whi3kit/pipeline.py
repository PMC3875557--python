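"""End-to-end demo: simulate every input, run every stage, write a manifest.

``run_demo`` wires the generators and analysis operations into the full
workflow — simulate, call targets, motif quartiles, differential screen,
decay fits, translational-efficiency rank test, allele-ratio
normalization, structure meta-profile — entirely on synthetic fixtures
with planted ground truth, so a single seeded command exercises and
cross-checks the whole pipeline. All computation is delegated to the
documented library operations; this module only sequences them and
records their outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import (
    allele_ratio,
    decay_kinetics,
    expression_response,
    io_formats,
    motif_stats,
    ripchip_targets,
    synthetic_data,
    translation_profiling,
)
from .synthetic_data import SimulationConfig

CONTROL_MOTIF = "CGUA"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_demo(seed: int, outdir: str | Path, cfg: SimulationConfig | None = None) -> dict:
    """Run the full synthetic-data demo and return the summary dict.

    Writes fixtures (FASTA + TSVs), per-stage result tables, a
    ``summary.json`` of recovered quantities, and a ``manifest.json`` with
    the seed, configuration and package version. Deterministic under seed.
    """
    cfg = cfg if cfg is not None else SimulationConfig(seed=seed)
    outdir = Path(outdir)
    fixtures = outdir / "fixtures"
    results = outdir / "results"
    fixtures.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}

    genes = _simulate(cfg, fixtures)
    summary["n_genes"] = len(genes)
    summary.update(_ripchip(cfg, genes, fixtures, results))
    summary.update(_quartiles(cfg, genes, results))
    summary.update(_screen(cfg, genes, results, summary["called_targets"]))
    summary.update(_decay(cfg, fixtures, results))
    summary.update(_te(cfg, genes, fixtures))
    summary.update(_allele(cfg, fixtures))
    summary.update(_pars(cfg, genes))

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")
    manifest = {
        "seed": seed,
        "package": "whi3kit",
        "version": __version__,
        "config": {k: _jsonify(v) for k, v in vars(cfg).items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


@_stage("simulate")
def _simulate(cfg, fixtures):
    genes = synthetic_data.generate_transcriptome(cfg)
    io_formats.write_fasta(fixtures / "transcriptome.fasta", {g: genes[g].sequence for g in genes})
    io_formats.write_utr_table(fixtures / "utrs.tsv", genes)
    return genes


@_stage("ripchip")
def _ripchip(cfg, genes, fixtures, results):
    experiments, truth = synthetic_data.generate_ripchip(cfg, genes)
    io_formats.write_ripchip_table(fixtures / "ripchip.tsv", experiments)
    net = ripchip_targets.net_enrichment(experiments)
    call = ripchip_targets.call_targets(net)
    call.to_frame().to_csv(results / "targets.tsv", sep="\t")
    ov = ripchip_targets.overlap_test(call.targets, truth, universe_n=len(genes))
    truth_set = set(truth)
    sens = len(set(call.targets) & truth_set) / len(truth_set) if truth else float("nan")
    fdr = (
        len(set(call.targets) - truth_set) / len(call.targets) if call.targets else 0.0
    )
    return {
        "planted_targets": len(truth),
        "called_targets": call.targets,
        "n_called": len(call.targets),
        "target_sensitivity": sens,
        "target_fdr": fdr,
        "overlap_with_truth_log10_p": ov.log10_p,
    }


@_stage("motif_quartiles")
def _quartiles(cfg, genes, results):
    tables = synthetic_data.generate_counts(cfg, genes)
    lengths = {g: genes[g].orf_len for g in genes}
    rpkm_wt = translation_profiling.compute_rpkm(tables["rna_wt"], lengths)
    rpkm_mut = translation_profiling.compute_rpkm(tables["rna_mut"], lengths)
    common = rpkm_wt.index.intersection(rpkm_mut.index)
    fc = dict(np.log2(rpkm_mut.loc[common] / rpkm_wt.loc[common]))
    out = {}
    for motif, tag in ((cfg.motif, "motif"), (CONTROL_MOTIF, "control")):
        dens = motif_stats.density_table(genes, motif)["density"]
        q = motif_stats.assign_quartiles(dict(dens))
        summ = motif_stats.quartile_response_summary(fc, q, seed=cfg.seed)
        summ.to_csv(results / f"quartiles_{tag}.tsv", sep="\t")
        out[f"quartile_means_{tag}"] = [float(x) for x in summ["mean_log2"]]
    return out


@_stage("screen")
def _screen(cfg, genes, results, called_targets):
    panel = synthetic_data.generate_expression_panel(cfg, genes)
    audit = expression_response.screen_audit(panel)
    audit.to_csv(results / "screen_audit.tsv", sep="\t")
    up, down = expression_response.screen_differential(panel)
    out = {"screen_up": len(up), "screen_down": len(down)}
    if up and called_targets:
        frac, fold, ov = expression_response.target_enrichment_in_screen(
            up, called_targets, universe_n=len(genes)
        )
        out.update(
            screen_target_fraction=frac,
            screen_target_fold=fold,
            screen_target_log10_p=ov.log10_p,
        )
    return out


@_stage("decay")
def _decay(cfg, fixtures, results):
    wt_courses = synthetic_data.generate_decay_courses(
        cfg, n_courses=1, n_replicates=3, half_life=cfg.decay_half_life, genotype="WT"
    )[0]
    mut_cfg_hl = cfg.decay_half_life * cfg.destabilization  # planted stabilization
    mut_courses = synthetic_data.generate_decay_courses(
        cfg, n_courses=1, n_replicates=3, half_life=mut_cfg_hl, genotype="mutant",
        rng_offset=1,
    )[0]
    io_formats.write_decay_table(fixtures / "decay.tsv", wt_courses + mut_courses)
    fit_wt = decay_kinetics.fit_courses(wt_courses)
    fit_mut = decay_kinetics.fit_courses(mut_courses)
    fold, ci = decay_kinetics.stabilization_fold(fit_mut, fit_wt, n_boot=1000, seed=cfg.seed)
    pd.DataFrame(
        [
            {"genotype": "WT", "half_life": fit_wt.half_life,
             "ci_low": fit_wt.ci95[0], "ci_high": fit_wt.ci95[1]},
            {"genotype": "mutant", "half_life": fit_mut.half_life,
             "ci_low": fit_mut.ci95[0], "ci_high": fit_mut.ci95[1]},
        ]
    ).to_csv(results / "decay_fits.tsv", sep="\t", index=False)
    return {
        "half_life_wt": fit_wt.half_life,
        "half_life_mutant": fit_mut.half_life,
        "stabilization_fold": fold,
        "stabilization_ci": list(ci),
        "planted_stabilization": cfg.destabilization,
    }


@_stage("te_rank")
def _te(cfg, genes, fixtures):
    tables = synthetic_data.generate_counts(cfg, genes)
    io_formats.write_count_table(fixtures / "counts.tsv", tables.values())
    lengths = {g: genes[g].orf_len for g in genes}
    _, res = translation_profiling.te_analysis(tables, lengths, focal=cfg.focal_gene)
    return {
        "focal_gene": res.gene_id,
        "focal_rel_te": res.rel_te,
        "planted_rel_te": cfg.te_effect_gene[1],
        "focal_te_rank": res.rank,
        "focal_te_p": res.p_one_tailed,
    }


@_stage("allele")
def _allele(cfg, fixtures):
    lanes = synthetic_data.generate_duplex(cfg)
    io_formats.write_duplex_table(fixtures / "duplex.tsv", lanes)
    wt = [m for m in lanes if m.genotype == "WT"]
    mut = [m for m in lanes if m.genotype == "mutant"]
    m1 = allele_ratio.method1_from_measurements(wt, mut)
    m2, ci = allele_ratio.normalize_method2(wt, mut, seed=cfg.seed)
    p = allele_ratio.genotype_effect_test(
        [allele_ratio.long_short_ratio(m) for m in wt],
        [allele_ratio.long_short_ratio(m) for m in mut],
        n_perm=10_000,
        seed=cfg.seed,
    )
    return {
        "allele_method1_fold": m1,
        "allele_method2_fold": m2,
        "allele_method2_ci": list(ci),
        "allele_genotype_p": p,
        "planted_destabilization": cfg.destabilization,
    }


@_stage("pars")
def _pars(cfg, genes):
    experiments, truth = synthetic_data.generate_ripchip(cfg, genes)
    tracks = synthetic_data.generate_pars_tracks(cfg, genes, target_genes=truth)
    occurrences = [
        (gid, s)
        for gid, g in genes.items()
        for s in motif_stats.find_motif(g.sequence, cfg.motif)
    ]
    groups = {g: ("target" if g in set(truth) else "non-target") for g in genes}
    profiles = motif_stats.pars_metaprofile(
        tracks, occurrences, motif_len=len(cfg.motif), groups=groups
    )
    return {
        "pars_target_min": float(profiles["target"].min()),
        "pars_nontarget_min": float(profiles["non-target"].min()),
    }
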