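"""Weighted running-sum enrichment, compound reversal scoring, GSEA.

The core statistic is the weighted Kolmogorov-Smirnov enrichment score:
walk a gene list ranked by decreasing log2 fold change; on each set member
step up by |metric|^p (normalized), on each non-member step down by
1/(N - N_H); the ES is the running sum's largest deviation from zero. A
compound's connectivity to a two-sided signature combines the ES of the up
and down halves (WTCS); its *reversal* activity is -WTCS, so a compound
that drives signature-up genes down and signature-down genes up scores
positive and ranks as an anti-phenotype hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene sets / signatures

@dataclass
class GeneSignature:
    """Disjoint up/down gene sets defining the phenotype to reverse."""

    name: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        self.up, self.down = set(self.up), set(self.down)
        common = self.up & self.down
        if common:
            raise ValueError(f"genes in both signature halves: {sorted(common)}")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def signature_from_gmt(path: str | Path, name: str) -> GeneSignature:
    """Load NAME from a GMT holding NAME_UP and NAME_DN member lists."""
    sets = read_gmt(path)
    up, dn = f"{name}_UP", f"{name}_DN"
    if up not in sets or dn not in sets:
        raise ValueError(f"GMT must contain both {up} and {dn}")
    return GeneSignature(name, set(sets[up]), set(sets[dn]))


def load_default_signature() -> GeneSignature:
    """The packaged six-gene lung-metastasis signature core.

    ANGPTL4, MMP1, PTGS2 and TNC mark the up half; LY6E and RARRES3 the
    down half — the validated core of the 13-gene metastasis signature.
    """
    from importlib.resources import files

    path = files("revscreen").joinpath("data/bclm_signature.gmt")
    return signature_from_gmt(str(path), "BCLM")


# ---------------------------------------------------------------------------
# ranked profiles

def rank_genes(metric: pd.Series) -> tuple[list[str], np.ndarray]:
    """Order genes by decreasing metric; ties broken by gene name (stable)."""
    if metric.index.has_duplicates:
        raise ValueError("ranked profiles require unique gene names")
    s = metric.sort_index().sort_values(ascending=False, kind="stable")
    return list(s.index), s.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# weighted KS enrichment score

@dataclass
class ESResult:
    es: float
    index: int  # 0-based rank of the extremum
    running: np.ndarray
    leading_edge: list[str] = field(default_factory=list)


def weighted_es(
    genes: list[str],
    metric: np.ndarray,
    gene_set: set[str],
    weight_p: float = 1.0,
) -> ESResult:
    """Weighted KS enrichment score over a ranked gene list.

    P_hit(i) accumulates |metric|^p over set members up to rank i (scaled to
    end at 1); P_miss(i) accumulates 1/(N - N_H) over non-members. The ES is
    the running difference at its largest |deviation|; when the maximal
    positive and negative deviations tie in magnitude the positive extreme
    wins, and within a sign the earliest index wins. The leading edge is the
    set members at or before the extremum (at or after, for negative ES).
    """
    n = len(genes)
    mask = np.fromiter((g in gene_set for g in genes), dtype=bool, count=n)
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked profile")
    if n_hit >= n:
        raise ValueError("gene set covers the whole profile; ES undefined")
    w = np.abs(np.asarray(metric, dtype=float)) ** weight_p
    w = np.where(mask, w, 0.0)
    n_r = w.sum()
    if n_r == 0:
        raise ValueError("all set-member metrics are zero; ES undefined")
    p_hit = np.cumsum(w) / n_r
    p_miss = np.cumsum(~mask) / (n - n_hit)
    dev = p_hit - p_miss
    pos, neg = dev.max(), dev.min()
    # positive extreme wins a magnitude tie; the 1e-12 slack keeps the
    # decision stable against float accumulation order
    if pos >= -neg - 1e-12:
        es = float(pos)
        idx = int(np.argmax(dev))
    else:
        es = float(neg)
        idx = int(np.argmin(dev))
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if mask[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(genes) if mask[i] and i >= idx]
    return ESResult(es=es, index=idx, running=dev, leading_edge=leading)


def wtcs(es_up: float, es_down: float) -> float:
    """Two-sided connectivity score: (es_up - es_down)/2 on opposite signs, else 0."""
    if not (np.isfinite(es_up) and np.isfinite(es_down)):
        raise ValueError("ES values must be finite")
    if es_up * es_down >= 0:
        return 0.0
    return (es_up - es_down) / 2.0


# ---------------------------------------------------------------------------
# permutation nulls

def null_es(
    genes: list[str],
    metric: np.ndarray,
    set_size: int,
    n_perm: int,
    weight_p: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Null ES from random gene-label memberships of the same size."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(genes)
    out = np.empty(n_perm)
    arr = np.asarray(genes, dtype=object)
    for k in range(n_perm):
        members = set(arr[rng.choice(n, size=set_size, replace=False)])
        out[k] = _null_es_one(genes, metric, members, weight_p)
    return out


def _null_es_one(genes, metric, members, weight_p) -> float:
    # a random membership landing entirely on zero metrics carries no mass;
    # its null score is 0 by continuity
    try:
        return weighted_es(genes, metric, members, weight_p).es
    except ValueError:
        return 0.0


def null_wtcs(
    genes: list[str],
    metric: np.ndarray,
    n_up: int,
    n_down: int,
    n_perm: int,
    weight_p: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Null WTCS from random disjoint up/down memberships."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(genes)
    arr = np.asarray(genes, dtype=object)
    out = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(n, size=n_up + n_down, replace=False)
        up = set(arr[pick[:n_up]])
        dn = set(arr[pick[n_up:]])
        out[k] = wtcs(
            _null_es_one(genes, metric, up, weight_p),
            _null_es_one(genes, metric, dn, weight_p),
        )
    return out


def permutation_p(observed: float, nulls: np.ndarray) -> float:
    """Two-sided add-one permutation p: (1 + #{|null| >= |obs|}) / (1 + n)."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one permutation")
    return float((1 + np.sum(np.abs(nulls) >= abs(observed))) / (1 + nulls.size))


# ---------------------------------------------------------------------------
# compound activity scoring

def score_compounds(
    profiles: dict[str, "object"],
    signature: GeneSignature,
    weight_p: float = 1.0,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank compounds by signature-reversal activity.

    Per compound: rank genes by decreasing log2fc, compute the ES of the
    signature's up and down halves, their WTCS, and reversal = -WTCS
    (positive = reversal); a permutation p on |WTCS| comes from random
    disjoint memberships of the same sizes. Output sorted by decreasing
    reversal, ties by compound id. Compounds whose profile misses a
    signature gene are skipped with a warning and returned separately.
    """
    rows = []
    skipped: list[str] = []
    need = sorted(signature.up | signature.down)
    rng = np.random.default_rng(seed)
    for comp in sorted(profiles):
        prof = profiles[comp]
        table = prof.table if hasattr(prof, "table") else prof
        if not set(need) <= set(table.index):
            log.warning("compound %s misses signature genes; skipped", comp)
            skipped.append(comp)
            continue
        genes, metric = rank_genes(table["log2fc"])
        es_up = weighted_es(genes, metric, signature.up, weight_p).es
        es_dn = weighted_es(genes, metric, signature.down, weight_p).es
        score = wtcs(es_up, es_dn)
        nulls = null_wtcs(
            genes, metric, len(signature.up), len(signature.down), n_perm, weight_p, rng=rng
        )
        rows.append((comp, es_up, es_dn, score, -score, permutation_p(score, nulls)))
    df = pd.DataFrame(
        rows, columns=["compound", "es_up", "es_down", "wtcs", "reversal", "p_perm"]
    )
    df = df.sort_values(["reversal", "compound"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True), skipped


# ---------------------------------------------------------------------------
# GSEA

def gsea(
    metric: pd.Series,
    gene_sets: dict[str, list[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
) -> pd.DataFrame:
    """GSEA over a single ranked profile with gene-label permutation nulls.

    NES = ES / mean(|null ES| of the same sign); p from the two-sided
    add-one permutation estimator; FDR by Benjamini-Hochberg across the
    tested sets. Sets intersecting the profile in fewer than ``min_size``
    genes are skipped with a warning. Results sorted by decreasing NES.
    """
    genes, ranked = rank_genes(metric)
    universe = set(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if len(members) < min_size:
            log.warning("gene set %s intersects the profile in %d genes; skipped", name, len(members))
            continue
        res = weighted_es(genes, ranked, members, weight_p)
        nulls = null_es(genes, ranked, len(members), n_perm, weight_p, rng=rng)
        same_sign = nulls[np.sign(nulls) == np.sign(res.es)] if res.es != 0 else nulls
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(nulls))
        nes = res.es / denom if denom > 0 else np.nan
        rows.append(
            (name, len(members), res.es, nes, permutation_p(res.es, nulls),
             ",".join(res.leading_edge))
        )
    if not rows:
        raise ValueError("no gene set passed the minimum-intersection filter")
    df = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p_perm", "leading_edge"])
    df["fdr"] = stats.false_discovery_control(df["p_perm"], method="bh")
    return df.sort_values("nes", ascending=False, kind="stable").reset_index(drop=True)


def write_ranked_profile(metric: pd.Series, path: str | Path) -> None:
    genes, vals = rank_genes(metric)
    pd.DataFrame({"gene": genes, "log2fc": vals}).to_csv(path, sep="\t", index=False)


def read_ranked_profile(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["log2fc"].to_numpy(), index=df["gene"])
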