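"""End-to-end screen orchestration: count -> normalize -> fold-change -> score."""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import counting, quantify
from .enrichment import score_compounds, signature_from_gmt
from .plates import PlateLayout
from .probes import ProbeSet

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full screen run (YAML-backed)."""

    probes: Path
    layout: Path
    fastq_dir: Path
    signature_gmt: Path
    signature_name: str = "BCLM"
    out_dir: Path = Path("screen_out")
    max_mismatch: int = 3
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    weight_p: float = 1.0
    n_perm: int = 199
    seed: int = 0
    gene_sets_gmt: Path | None = None
    tf_map: Path | None = None
    cohort: Path | None = None

    def __post_init__(self) -> None:
        for name in ("probes", "layout", "fastq_dir", "signature_gmt"):
            setattr(self, name, Path(getattr(self, name)))
        self.out_dir = Path(self.out_dir)
        for name in ("gene_sets_gmt", "tf_map", "cohort"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("probes", "layout", "fastq_dir", "signature_gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValueError(f"config path {name} does not exist: {p}")
        for name in ("gene_sets_gmt", "tf_map", "cohort"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config path {name} does not exist: {p}")


def _write_with_seed(df: pd.DataFrame, path: Path, seed: int, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_screen(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write a report bundle.

    Stages: probe counting from FASTQ, stable-gene normalization, per-plate
    fold changes vs DMSO, signature-reversal scoring with permutation p.
    Outputs (seed recorded in every table header): count_matrix.tsv,
    size_factors.tsv, fold_changes.tsv, ranked_compounds.tsv, degs.tsv.
    Deterministic given the config seed; on any stage failure partial
    outputs are removed and the stage is named in the error.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "inputs"
        probes = ProbeSet.from_tsv(config.probes)
        layout = PlateLayout.from_tsv(config.layout)
        signature = signature_from_gmt(config.signature_gmt, config.signature_name)

        stage = "count"
        counts = counting.count_dir(config.fastq_dir, probes, config.max_mismatch)
        log.info("count: %d wells x %d probes", counts.shape[0], counts.shape[1] - 1)
        p = out / "count_matrix.tsv"
        _write_with_seed(counts, p, config.seed, index=True)
        written.append(p)

        stage = "normalize"
        gcounts = quantify.gene_counts(counts, probes)
        factors = quantify.size_factors(gcounts, probes.control_genes)
        norm = quantify.normalize(gcounts, factors)
        log.info("normalize: %d size factors", len(factors))
        p = out / "size_factors.tsv"
        _write_with_seed(factors.rename("size_factor").to_frame(), p, config.seed, index=True)
        written.append(p)

        stage = "fold-change"
        profiles = quantify.fold_changes(norm, layout)
        log.info("fold-change: %d compound profiles", len(profiles))
        p = out / "fold_changes.tsv"
        with open(p, "w") as fh:
            fh.write(f"# seed: {config.seed}\n")
        quantify_path = p
        _append_profiles(profiles, quantify_path)
        written.append(p)

        stage = "deg"
        deg_rows = []
        for comp in sorted(profiles):
            up, down = quantify.call_degs(
                profiles[comp], config.fc_threshold, config.p_threshold
            )
            deg_rows += [(comp, g, "up") for g in up] + [(comp, g, "down") for g in down]
        degs = pd.DataFrame(deg_rows, columns=["compound", "gene", "direction"])
        p = out / "degs.tsv"
        _write_with_seed(degs, p, config.seed, index=False)
        written.append(p)

        stage = "score"
        ranked, skipped = score_compounds(
            profiles, signature, config.weight_p, config.n_perm, config.seed
        )
        log.info("score: %d compounds ranked, %d skipped", len(ranked), len(skipped))
        p = out / "ranked_compounds.tsv"
        _write_with_seed(ranked, p, config.seed, index=False)
        written.append(p)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"screen stage {stage!r} failed: {exc}") from exc
    return {
        "counts": out / "count_matrix.tsv",
        "size_factors": out / "size_factors.tsv",
        "fold_changes": out / "fold_changes.tsv",
        "degs": out / "degs.tsv",
        "ranked": out / "ranked_compounds.tsv",
    }


def _append_profiles(profiles, path: Path) -> None:
    tmp = path.with_suffix(".tmp")
    quantify.write_profiles(profiles, tmp)
    with open(tmp) as src, open(path, "a") as dst:
        shutil.copyfileobj(src, dst)
    tmp.unlink()


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
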