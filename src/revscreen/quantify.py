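"""Stable-gene normalization, plate-wise fold changes, DEG calling.

Normalization follows a median-of-ratios scheme restricted to the stable
control panel: signature genes may be strongly perturbed by treatment, so
only the 33 control genes inform the per-well size factor. Fold change is
always computed against the averaged DMSO signal of the same plate, which
cancels plate-level batch effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counting import UNASSIGNED
from .plates import DMSO, PlateLayout
from .probes import ProbeSet

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5  # added before log2 so zero counts stay finite


def gene_counts(counts: pd.DataFrame, probes: ProbeSet) -> pd.DataFrame:
    """Collapse a probe-level count matrix to genes (drops UNASSIGNED)."""
    df = counts.drop(columns=[UNASSIGNED], errors="ignore")
    mapping = dict(zip(probes.probe_ids, probes.genes))
    unknown = set(df.columns) - set(mapping)
    if unknown:
        raise ValueError(f"count matrix has probes absent from the manifest: {sorted(unknown)}")
    out = df.rename(columns=mapping)
    return out.T.groupby(level=0).sum().T


def _plate_of(well: str) -> str:
    return well.rsplit("_", 1)[0]


def size_factors(
    counts: pd.DataFrame,
    control_genes: list[str],
    plates: dict[str, str] | None = None,
) -> pd.Series:
    """Per-well size factors from stable control genes, per plate.

    Within each plate: restrict to control genes with nonzero counts in all
    wells, take each well's counts over the per-gene geometric mean across
    wells, and use the median of those ratios; factors are rescaled to
    geometric mean 1 per plate. If no control gene is nonzero everywhere,
    falls back to total-control-count scaling with a warning.
    """
    ctrl = [g for g in control_genes if g in counts.columns]
    if len(ctrl) < 3:
        raise ValueError("need at least 3 control genes present in the count matrix")
    if plates is None:
        plates = {w: _plate_of(w) for w in counts.index}
    factors = pd.Series(index=counts.index, dtype=float)
    for plate in sorted(set(plates.values())):
        wells = [w for w in counts.index if plates[w] == plate]
        sub = counts.loc[wells, ctrl].astype(float)
        zero_wells = sub.index[sub.sum(axis=1) == 0]
        if len(zero_wells):
            raise ValueError(f"well {zero_wells[0]} has zero counts on all control genes")
        ok = sub.columns[(sub > 0).all(axis=0)]
        if len(ok) == 0:
            log.warning(
                "plate %s: no control gene nonzero in every well; "
                "falling back to total-control-count scaling",
                plate,
            )
            f = sub.sum(axis=1)
        else:
            logm = np.log(sub[ok])
            ratios = sub[ok] / np.exp(logm.mean(axis=0))
            f = ratios.median(axis=1)
        f = f / np.exp(np.log(f).mean())  # geometric mean 1 per plate
        factors.loc[wells] = f
    return factors


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """normalized(w, g) = raw(w, g) / size_factor(w)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts.div(factors, axis=0)


@dataclass
class FoldChangeProfile:
    """Per-compound fold changes versus same-plate averaged DMSO.

    ``table`` is gene-indexed with columns fold_change, log2fc, p_value.
    ``plate`` is the hosting plate id or ``combined`` for cross-plate
    inverse-variance pooling; ``n_wells`` the replicate count behind it.
    """

    compound_id: str
    table: pd.DataFrame
    plate: str
    n_wells: int
    per_plate: list["FoldChangeProfile"] = field(default_factory=list)

    def covers(self, genes: list[str]) -> bool:
        return set(genes) <= set(self.table.index)


def _profile_one_plate(
    log2n: pd.DataFrame,
    norm: pd.DataFrame,
    comp_wells: list[str],
    dmso_wells: list[str],
    compound: str,
    plate: str,
) -> FoldChangeProfile:
    genes = norm.columns
    fc = norm.loc[comp_wells, genes].mean(axis=0) / norm.loc[dmso_wells, genes].mean(axis=0)
    a = log2n.loc[comp_wells, genes]
    b = log2n.loc[dmso_wells, genes]
    if len(comp_wells) >= 2:
        with warnings.catch_warnings():
            # near-identical replicate signals trip scipy's precision warning;
            # the resulting p is ~1 either way
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0, equal_var=True)
        # per-gene SE of the mean difference, for inverse-variance pooling
        na, nb = len(comp_wells), len(dmso_wells)
        sp2 = (a.var(axis=0, ddof=1) * (na - 1) + b.var(axis=0, ddof=1) * (nb - 1)) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        mu = b.mean(axis=0)
        sd = b.std(axis=0, ddof=1)
        se = sd.replace(0.0, np.nan)
        z = (a.iloc[0] - mu) / se
        p = 2 * stats.norm.sf(np.abs(z))
    p = pd.Series(np.asarray(p, dtype=float), index=genes).fillna(1.0).clip(1e-300, 1.0)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p_value": p,
            "se_log2": pd.Series(np.asarray(se, dtype=float), index=genes),
        }
    )
    return FoldChangeProfile(compound, table, plate, len(comp_wells))


def fold_changes(norm: pd.DataFrame, layout: PlateLayout) -> dict[str, FoldChangeProfile]:
    """Fold-change profiles for every compound in the layout.

    FC_g = mean normalized signal over the compound's wells / mean over the
    same plate's DMSO wells. p-values: two-sided two-sample t-test on log2
    signals with >= 2 replicate wells, else a two-sided normal score of the
    single well against the plate's DMSO log2 mean and SD. A compound split
    across plates yields per-plate profiles plus an inverse-variance
    weighted combined profile.
    """
    log2n = np.log2(norm + PSEUDOCOUNT)
    out: dict[str, FoldChangeProfile] = {}
    for comp in layout.compounds:
        plate_profiles = []
        for plate in layout.plates_of(comp):
            comp_wells = layout.wells_of(comp, plate)
            dmso_wells = layout.wells_of(DMSO, plate)
            if len(dmso_wells) < 2:
                raise ValueError(f"plate {plate} lacks the >= 2 DMSO wells needed for {comp}")
            missing = [w for w in comp_wells + dmso_wells if w not in norm.index]
            if missing:
                raise ValueError(f"wells missing from the normalized matrix: {missing}")
            plate_profiles.append(
                _profile_one_plate(log2n, norm, comp_wells, dmso_wells, comp, plate)
            )
        if len(plate_profiles) == 1:
            prof = plate_profiles[0]
            prof.table = prof.table.drop(columns="se_log2")
            out[comp] = prof
        else:
            log.info("compound %s spans %d plates; pooling", comp, len(plate_profiles))
            out[comp] = _pool_profiles(comp, plate_profiles)
    return out


def _pool_profiles(compound: str, profiles: list[FoldChangeProfile]) -> FoldChangeProfile:
    genes = profiles[0].table.index
    l2 = np.stack([p.table["log2fc"].to_numpy() for p in profiles])
    se = np.stack([p.table["se_log2"].to_numpy() for p in profiles])
    w = 1.0 / np.clip(se, 1e-9, None) ** 2
    pooled = (w * l2).sum(axis=0) / w.sum(axis=0)
    se_c = np.sqrt(1.0 / w.sum(axis=0))
    z = pooled / se_c
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    table = pd.DataFrame(
        {"fold_change": 2.0**pooled, "log2fc": pooled, "p_value": p}, index=genes
    )
    for prof in profiles:
        prof.table = prof.table.drop(columns="se_log2")
    return FoldChangeProfile(
        compound, table, "combined", sum(p.n_wells for p in profiles), per_plate=profiles
    )


def call_degs(
    profile: FoldChangeProfile,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Differentially expressed genes: max(FC, 1/FC) > 2 and p < 0.05, strict.

    Returns (up genes, down genes) by the sign of log2fc.
    """
    t = profile.table
    mag = np.maximum(t["fold_change"], 1.0 / t["fold_change"])
    hit = (mag > fc_threshold) & (t["p_value"] < p_threshold)
    up = sorted(t.index[hit & (t["log2fc"] > 0)])
    down = sorted(t.index[hit & (t["log2fc"] < 0)])
    return up, down


def overlap_percent(set_a: set, set_b: set) -> tuple[float, int]:
    """Percent of A that is also in B, plus the rounded display form."""
    if not set_a:
        raise ValueError("set A must be non-empty")
    pct = 100.0 * len(set(set_a) & set(set_b)) / len(set(set_a))
    return pct, int(round(pct))


def write_profiles(profiles: dict[str, FoldChangeProfile], path: str | Path) -> None:
    """Long-format TSV: compound, plate, n_wells, gene, fold_change, log2fc, p_value."""
    rows = []
    for comp in sorted(profiles):
        prof = profiles[comp]
        for gene, r in prof.table.iterrows():
            rows.append(
                (comp, prof.plate, prof.n_wells, gene, r["fold_change"], r["log2fc"], r["p_value"])
            )
    pd.DataFrame(
        rows, columns=["compound", "plate", "n_wells", "gene", "fold_change", "log2fc", "p_value"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, FoldChangeProfile]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for comp, grp in df.groupby("compound"):
        table = grp.set_index("gene")[["fold_change", "log2fc", "p_value"]]
        out[comp] = FoldChangeProfile(
            str(comp), table, str(grp["plate"].iloc[0]), int(grp["n_wells"].iloc[0])
        )
    return out
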