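"""Multi-condition differential screen and target enrichment among hits.

The screen crosses a deletion mutant and an over-expressor of the
RNA-binding protein with two growth media (plus one external mutant
dataset). A gene is *up* when it rises at least two-fold (1.0 log2) in the
mutant/glucose experiment, also rises in the mutant/ethanol or the
external mutant experiment, and falls in at least one over-expressor
experiment; *down* mirrors the rule with all signs flipped. Missing values
fail the clause they appear in, so incomplete rows are treated
conservatively. A ``slack`` parameter relaxes the two-fold clause for
borderline rows instead of hard-coding any tolerance.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .ripchip_targets import OverlapResult, overlap_test

PANEL_COLUMNS = (
    "whi3_glucose",
    "whi3_ethanol",
    "whi3_external",
    "overexp_glucose",
    "overexp_ethanol",
)


def load_example_panel() -> pd.DataFrame:
    """The bundled 40-gene example panel (the published screen's hit rows,
    including their missing values), for demonstrations and audits."""
    with resources.files("whi3kit.data").joinpath("expression_screen_example.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"gene_id": str})
    return df.set_index("gene_id").astype(float)


def _check_panel(panel: pd.DataFrame) -> pd.DataFrame:
    if panel.empty:
        raise ValueError("expression panel is empty")
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing condition columns: {missing}")
    return panel[list(PANEL_COLUMNS)].astype(float)


def screen_audit(
    panel: pd.DataFrame, up_threshold: float = 1.0, slack: float = 0.0
) -> pd.DataFrame:
    """Per-gene, per-clause booleans for the screen (NaN comparisons are False)."""
    p = _check_panel(panel)
    g, e, x = p["whi3_glucose"], p["whi3_ethanol"], p["whi3_external"]
    og, oe = p["overexp_glucose"], p["overexp_ethanol"]
    thr = up_threshold - slack
    audit = pd.DataFrame(index=p.index)
    audit["up_fold"] = g >= thr
    audit["up_confirm"] = (e > 0) | (x > 0)
    audit["up_overexp"] = (og < 0) | (oe < 0)
    audit["up"] = audit["up_fold"] & audit["up_confirm"] & audit["up_overexp"]
    audit["down_fold"] = g <= -thr
    audit["down_confirm"] = (e < 0) | (x < 0)
    audit["down_overexp"] = (og > 0) | (oe > 0)
    audit["down"] = audit["down_fold"] & audit["down_confirm"] & audit["down_overexp"]
    return audit


def screen_differential(
    panel: pd.DataFrame, up_threshold: float = 1.0, slack: float = 0.0
) -> tuple[list[str], list[str]]:
    """Apply the three-clause screen; returns (up genes, down genes).

    With ``up_threshold`` = 1.0 log2 the fold clause is the two-fold rule;
    ``slack`` (log2) relaxes it symmetrically for both directions.
    """
    audit = screen_audit(panel, up_threshold=up_threshold, slack=slack)
    return list(audit.index[audit["up"]]), list(audit.index[audit["down"]])


def target_enrichment_in_screen(
    screen_hits: Iterable[str], targets: Iterable[str], universe_n: int
) -> tuple[float, float, OverlapResult]:
    """Fraction of screen hits that are targets, fold enrichment over the
    random expectation, and the hypergeometric overlap p-value."""
    hits, tset = set(screen_hits), set(targets)
    if not hits:
        raise ValueError("empty screen hit list")
    fraction = len(hits & tset) / len(hits)
    expected = len(tset) / universe_n
    fold = fraction / expected if expected > 0 else np.inf
    result = overlap_test(hits, tset, universe_n)
    return fraction, fold, result
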