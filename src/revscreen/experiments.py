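"""Reproducible end-to-end experiments on synthetic screens.

Each function builds its own inputs with the synthetic-data generators,
runs the pipeline, and measures an outcome: planted-hit recovery of the
reversal score, exactness of probe counting, calibration of permutation
p-values, and power/type-I error of the stratified log-rank comparison.
They are the workhorses behind the worked examples and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import counting, quantify
from .enrichment import GeneSignature, null_es, permutation_p, rank_genes, score_compounds
from .plates import build_layout
from .probes import generate_probe_set
from .simulate import generate_cohort, generate_screen
from .survival import logrank, stratify

DEFAULT_PANEL = dict(n_up=7, n_down=6, n_control=33, length=30, max_mismatch=3)


def _default_probes(seed: int):
    return generate_probe_set(seed=seed, **DEFAULT_PANEL)


@dataclass
class PlantedHitResult:
    ranked: pd.DataFrame
    planted: list[str]
    n_in_top10: int


def planted_hit_screen(
    workdir: str | Path,
    seed: int = 1,
    n_compounds: int = 100,
    n_planted: int = 5,
    effect: float = 2.0,
    reads_per_well: float = 10_000,
    replicates: int = 2,
    error_rate: float = 0.005,
    n_perm: int = 199,
) -> PlantedHitResult:
    """Full screen from FASTQ with planted signature reversers.

    ``n_planted`` compounds push every signature-up gene down and every
    signature-down gene up by |log2 effect| = ``effect``; the rest are
    inert. Returns the ranked compound table and how many planted
    reversers land in the top 10 by reversal score.
    """
    workdir = Path(workdir)
    probes = _default_probes(seed)
    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    rng = np.random.default_rng(seed + 1)
    planted_ids = sorted(str(c) for c in rng.choice(compounds, size=n_planted, replace=False))
    effects = {g: -effect for g in probes.signature_up}
    effects |= {g: +effect for g in probes.signature_down}
    planted = {c: dict(effects) for c in planted_ids}

    layout = build_layout(compounds, replicates=replicates)
    fastq_dir = workdir / "fastq"
    generate_screen(
        probes, layout, planted, fastq_dir,
        reads_per_well=reads_per_well, error_rate=error_rate, seed=seed + 2,
    )
    counts = counting.count_dir(fastq_dir, probes, max_mismatch=DEFAULT_PANEL["max_mismatch"])
    gcounts = quantify.gene_counts(counts, probes)
    factors = quantify.size_factors(gcounts, probes.control_genes)
    norm = quantify.normalize(gcounts, factors)
    profiles = quantify.fold_changes(norm, layout)
    signature = GeneSignature("planted", set(probes.signature_up), set(probes.signature_down))
    ranked, _ = score_compounds(profiles, signature, n_perm=n_perm, seed=seed + 3)
    top10 = set(ranked.head(10)["compound"])
    return PlantedHitResult(ranked, planted_ids, len(top10 & set(planted_ids)))


def counting_exactness(workdir: str | Path, seed: int = 1, n_compounds: int = 4) -> dict:
    """Error-free reads must reproduce the truth counts bit-exactly.

    Also corrupts every probe at exactly 4 positions and verifies that all
    such reads are unassigned at a 3-mismatch budget. Returns the percent
    of wells recovered exactly and the percent of 4-mismatch reads
    unassigned.
    """
    workdir = Path(workdir)
    probes = _default_probes(seed)
    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    layout = build_layout(compounds, replicates=2, dmso_per_plate=4)
    truth, _ = generate_screen(
        probes, layout, {}, workdir / "fastq",
        reads_per_well=2000, error_rate=0.0, seed=seed,
    )
    counts = counting.count_dir(workdir / "fastq", probes, max_mismatch=3)
    counted = counts.drop(columns=[counting.UNASSIGNED]).loc[truth.index]
    exact = (counted.to_numpy() == truth.to_numpy()).all(axis=1)

    rng = np.random.default_rng(seed + 1)
    n_unassigned = 0
    n_reads = 0
    for p in probes.probes:
        for _ in range(5):
            seq = list(p.sequence)
            pos = rng.choice(len(seq), size=4, replace=False)
            for i in pos:
                seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
            n_reads += 1
            if counting.match_read("".join(seq), probes, max_mismatch=3) is None:
                n_unassigned += 1
    return {
        "exact_well_percent": 100.0 * float(exact.mean()),
        "four_mismatch_unassigned_percent": 100.0 * n_unassigned / n_reads,
    }


def permutation_calibration(
    seed: int = 1,
    n_compounds: int = 200,
    n_genes: int = 46,
    set_size: int = 7,
    n_perm: int = 199,
) -> dict:
    """Permutation p-values of the enrichment score under the null.

    Each null compound is a random log2fc profile with no planted signal;
    the ES of a fixed gene set gets a membership-permutation p. Under the
    null these p-values are uniform; returns them with the KS test p.
    """
    rng = np.random.default_rng(seed)
    gene_names = [f"G{i:03d}" for i in range(n_genes)]
    members = set(gene_names[:set_size])
    pvals = np.empty(n_compounds)
    from .enrichment import weighted_es

    for k in range(n_compounds):
        metric = pd.Series(rng.normal(0, 1, n_genes), index=gene_names)
        genes, ranked = rank_genes(metric)
        obs = weighted_es(genes, ranked, members).es
        nulls = null_es(genes, ranked, set_size, n_perm, rng=rng)
        pvals[k] = permutation_p(obs, nulls)
    ks = sps.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_p": float(ks.pvalue)}


def logrank_rejection_rate(
    hr: float,
    n_per_arm: int = 200,
    n_seeds: int = 100,
    alpha: float = 0.05,
    seed: int = 1,
    censor_frac: float = 0.0,
) -> float:
    """Fraction of simulated cohorts where the log-rank test rejects.

    Cohorts come from the generator with the stated hazard ratio between
    the top and bottom halves by the first gene's expression; groups are
    taken from a median-split stratification of that gene.
    """
    n = 2 * n_per_arm
    rejections = 0
    for k in range(n_seeds):
        cohort = generate_cohort(
            n=n, r_target=0.5, hr=hr, censor_frac=censor_frac,
            seed=seed + k, high_frac=0.5,
        )
        strat = stratify(cohort.set_index("sample_id").iloc[:, 0], 0.5, 0.4999, gene="JUN")
        sel = strat.groups != "middle"
        sub = cohort.set_index("sample_id")[sel.to_numpy()]
        _, p = logrank(
            sub["time_months"], sub["event"], strat.groups[sel.to_numpy()].to_numpy()
        )
        rejections += p < alpha
    return rejections / n_seeds
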