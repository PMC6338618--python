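"""Transcription-factor promoter-binding maps and candidate filtering.

Given precomputed promoter-binding annotations (gene -> set of TFs), the
candidate regulator of a co-regulated gene group is sought as the
intersection of the genes' TF sets, then narrowed to TFs whose own
expression responds to treatment in the stated direction — the logic that
singles out one TF (e.g. JUN) from seven shared promoter binders.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


def read_tf_map(path: str | Path) -> dict[str, set[str]]:
    """Flat TSV (gene, tf), one binding per row; symbols upper-cased."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "tf"} <= set(df.columns):
        raise ValueError("TF map TSV must have columns 'gene' and 'tf'")
    out: dict[str, set[str]] = {}
    for gene, grp in df.groupby(df["gene"].str.upper()):
        out[str(gene)] = set(grp["tf"].str.upper())
    return out


def write_tf_map(tf_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(tf_map) for t in sorted(tf_map[g])]
    pd.DataFrame(rows, columns=["gene", "tf"]).to_csv(path, sep="\t", index=False)


def shared_tfs(
    tf_map: dict[str, set[str]], genes: list[str]
) -> tuple[set[str], dict[frozenset, int]]:
    """TFs bound at every listed gene's promoter, plus Venn region counts.

    The Venn regions are keyed by the exact subset of query genes a TF
    binds; region counts sum to the size of the union of the genes' sets.
    """
    if not genes:
        raise ValueError("at least one gene must be queried")
    missing = [g for g in genes if g not in tf_map]
    if missing:
        raise ValueError(f"genes absent from the TF map: {missing}")
    sets = {g: tf_map[g] for g in genes}
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for tf in union:
        region = frozenset(g for g in genes if tf in sets[g])
        regions[region] = regions.get(region, 0) + 1
    common = set.intersection(*sets.values())
    return common, regions


def filter_tfs_by_expression(
    tfs: set[str],
    deg_table: pd.DataFrame,
    direction: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> set[str]:
    """Keep TFs whose own expression change passes the DEG rule, directionally.

    ``deg_table`` is gene-indexed with columns log2fc and p_value.
    ``direction`` is "up" or "down". TFs absent from the table are treated
    as non-significant and logged.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    kept = set()
    for tf in sorted(tfs):
        if tf not in deg_table.index:
            log.info("TF %s absent from the expression table; treated as non-significant", tf)
            continue
        l2, p = float(deg_table.loc[tf, "log2fc"]), float(deg_table.loc[tf, "p_value"])
        fc = 2.0**l2
        if max(fc, 1.0 / fc) > fc_threshold and p < p_threshold:
            if (direction == "up" and l2 > 0) or (direction == "down" and l2 < 0):
                kept.add(tf)
    if not kept:
        log.warning("no TF passed the %s-regulation filter", direction)
    return kept
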