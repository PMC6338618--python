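"""Synthetic inputs: sequencing screens with planted hits, clinical cohorts.

The screening raw data these tools emulate is a sequencing readout of a
46-probe panel across 384-well plates: each well's reads are (noisy) copies
of probe sequences, with per-well sequencing depth varying log-normally and
per-gene counts overdispersed (negative binomial). Compound effects are
planted as log2 shifts on signature genes only; stable-control genes are
never perturbed, which is what makes control-based normalization honest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plates import DMSO, PlateLayout, well_key
from .probes import ProbeSet

log = logging.getLogger(__name__)

_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _BASE2IDX[b] = i
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated screen.

    planted: compound -> {gene: log2 effect} (signature genes only).
    baseline_mu: gene -> expected count at nominal depth.
    depth_factors: well key -> true relative depth (1.0 = nominal).
    """

    planted: dict[str, dict[str, float]]
    baseline_mu: dict[str, float]
    dispersion: float
    error_rate: float
    seed: int
    depth_factors: dict[str, float] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _mutate(reads_idx: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions in base-index space (no indels)."""
    if error_rate <= 0 or reads_idx.size == 0:
        return reads_idx
    mask = rng.random(reads_idx.shape) < error_rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        reads_idx = reads_idx.copy()
        reads_idx[mask] = (reads_idx[mask] + shift) % 4
    return reads_idx


def generate_screen(
    probes: ProbeSet,
    layout: PlateLayout,
    planted: dict[str, dict[str, float]],
    out_dir: str | Path,
    reads_per_well: float = 10_000,
    dispersion: float = 0.1,
    error_rate: float = 0.005,
    depth_sigma: float = 0.2,
    baseline_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Write per-well FASTQ files and return the true count matrix.

    Per well w and gene g the true count is NB with mean
    ``baseline_mu[g] * 2**effect(g) * depth_w`` where depth_w is log-normal
    with median exp(-sigma^2/2) * reads_per_well (so mean total ~
    reads_per_well) and effect is the planted log2 shift of the well's
    treatment (0 for DMSO and unplanted compounds). Every counted read is
    emitted once as a FASTQ record: the probe sequence with substitutions
    at ``error_rate``. Deterministic for a fixed seed; the number of FASTQ
    records in a well always equals the sum of that well's truth counts.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    layout.validate()  # raises if some plate lacks DMSO wells
    known = set(layout.compounds)
    unknown = set(planted) - known
    if unknown:
        raise ValueError(f"planted compounds absent from the layout: {sorted(unknown)}")
    sig = set(probes.signature_genes)
    for comp, effects in planted.items():
        off = set(effects) - sig
        if off:
            raise ValueError(
                f"planted effects for {comp} touch non-signature genes: {sorted(off)}"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = probes.genes

    if baseline_weights is None:
        w = rng.lognormal(0.0, 0.5, size=len(genes))
    else:
        w = np.array([baseline_weights[g] for g in genes], dtype=float)
    w = w / w.sum()
    baseline_mu = {g: float(w[i] * reads_per_well) for i, g in enumerate(genes)}
    base = w * reads_per_well

    probe_idx = np.stack(
        [_BASE2IDX[np.frombuffer(s.encode(), dtype=np.uint8)] for s in probes.sequences]
    )
    L = probes.length
    qual = "I" * L

    truth_rows: dict[str, np.ndarray] = {}
    depth_factors: dict[str, float] = {}
    for rec in layout.table.itertuples(index=False):
        key = well_key(rec.plate, rec.well)
        depth = float(rng.lognormal(-0.5 * depth_sigma**2, depth_sigma)) if depth_sigma > 0 else 1.0
        depth_factors[key] = depth
        effects = planted.get(rec.treatment, {}) if rec.treatment != DMSO else {}
        shift = np.array([2.0 ** effects.get(g, 0.0) for g in genes])
        counts = _nb_draw(rng, base * shift * depth, dispersion).astype(np.int64)
        truth_rows[key] = counts

        reads_idx = np.repeat(probe_idx, counts, axis=0)
        reads_idx = _mutate(reads_idx, error_rate, rng)
        seqs = _IDX2BASE[reads_idx].view(f"S{L}").ravel()
        with open(out_dir / f"{key}.fastq", "w") as fh:
            fh.write(
                "".join(
                    f"@{key}:{i}\n{s.decode()}\n+\n{qual}\n" for i, s in enumerate(seqs)
                )
            )

    truth = pd.DataFrame.from_dict(truth_rows, orient="index", columns=probes.probe_ids)
    truth.index.name = "well"
    synth = SyntheticTruth(
        planted={c: dict(e) for c, e in planted.items()},
        baseline_mu=baseline_mu,
        dispersion=dispersion,
        error_rate=error_rate,
        seed=seed,
        depth_factors=depth_factors,
    )
    return truth, synth


def generate_cohort(
    n: int,
    r_target: float,
    hr: float,
    censor_frac: float,
    seed: int = 0,
    genes: tuple[str, ...] = ("JUN", "TARGET1"),
    sigma: float = 0.5,
    baseline_hazard: float = 0.02,
    high_frac: float = 0.5,
) -> pd.DataFrame:
    """Simulate a tumor cohort with correlated expression and a planted hazard.

    Log-expression follows a one-factor Gaussian model: the first gene is
    the factor, every other gene correlates with it at ``r_target`` on the
    log scale; expression is the exponential (log-normal, scale ``sigma``).
    Survival times are exponential; samples in the top ``high_frac`` by the
    first gene's expression have their hazard multiplied by ``hr``. With
    probability ``censor_frac`` a sample is right-censored at a uniform
    fraction of its survival time. Columns: sample_id, one per gene,
    time_months, event.
    """
    if n < 10:
        raise ValueError("cohort size must be >= 10")
    if not abs(r_target) < 1:
        raise ValueError("|r_target| must be < 1")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    z0 = rng.standard_normal(n)
    expr = {genes[0]: np.exp(sigma * z0)}
    for g in genes[1:]:
        e = rng.standard_normal(n)
        expr[g] = np.exp(sigma * (r_target * z0 + np.sqrt(1 - r_target**2) * e))

    order = np.argsort(-expr[genes[0]], kind="stable")
    n_high = int(np.floor(n * high_frac))
    high = np.zeros(n, dtype=bool)
    high[order[:n_high]] = True
    hazard = baseline_hazard * np.where(high, hr, 1.0)
    times = rng.exponential(1.0 / hazard)
    events = np.ones(n, dtype=int)
    cens = rng.random(n) < censor_frac
    times = np.where(cens, np.maximum(times * rng.random(n), 1e-6), times)
    events[cens] = 0

    df = pd.DataFrame({"sample_id": [f"S{i + 1:04d}" for i in range(n)]})
    for g in genes:
        df[g] = expr[g]
    df["time_months"] = times
    df["event"] = events
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
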