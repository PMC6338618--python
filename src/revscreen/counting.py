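"""Mismatch-tolerant assignment of reads to probes and well-level counting.

A read is assigned to the unique probe with minimal Hamming distance over
the first L bases, provided that distance does not exceed the mismatch
budget (3 by default, inclusive); ties between probes and reads shorter
than L are left unassigned. Because probe panels are built with pairwise
distance > 2 * budget, ties cannot occur for reads within budget of a true
probe, so assignment is deterministic and order-independent.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .probes import ProbeSet

log = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
_WELL_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})\.fastq(\.gz)?$")


def match_read(read: str, probes: ProbeSet, max_mismatch: int = 3) -> str | None:
    """Assign one read; returns the probe_id or None (unassigned).

    Comparison runs over the first L bases (trailing adapter bases are
    ignored). Per-probe scanning abandons a probe as soon as its mismatch
    count exceeds the budget; the result equals the naive full distance
    computation. A minimal distance shared by two or more probes is a tie
    and the read is discarded.
    """
    L = probes.length
    if len(read) < L:
        log.debug("read shorter than probe length %d; unassigned", L)
        return None
    read = read[:L]
    best_id: str | None = None
    best_d = max_mismatch + 1
    tied = False
    for p in probes.probes:
        d = 0
        limit = best_d  # early exit: cannot beat (or tie) the current best
        for x, y in zip(read, p.sequence):
            if x != y:
                d += 1
                if d > limit:
                    break
        else:
            if d < best_d:
                best_d, best_id, tied = d, p.probe_id, False
            elif d == best_d:
                tied = True
    if best_d > max_mismatch or tied:
        return None
    return best_id


def _encode(seqs: list[str], L: int) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(-1, L)


def match_batch(
    reads: list[str], probes: ProbeSet, max_mismatch: int = 3, chunk: int = 20_000
) -> np.ndarray:
    """Vectorized batch assignment; returns probe indices (-1 = unassigned).

    Equivalent to calling :func:`match_read` per read (tested property).
    """
    L = probes.length
    out = np.full(len(reads), -1, dtype=np.int64)
    ok = [i for i, r in enumerate(reads) if len(r) >= L]
    if not ok:
        return out
    pmat = _encode(probes.sequences, L)
    seqs = [reads[i][:L] for i in ok]
    ok = np.asarray(ok)
    for start in range(0, len(seqs), chunk):
        block = _encode(seqs[start : start + chunk], L)
        d = (block[:, None, :] != pmat[None, :, :]).sum(axis=2, dtype=np.int32)
        dmin = d.min(axis=1)
        unique = (d == dmin[:, None]).sum(axis=1) == 1
        hit = (dmin <= max_mismatch) & unique
        idx = np.where(hit, d.argmin(axis=1), -1)
        out[ok[start : start + chunk][: len(idx)]] = idx
    return out


def parse_well_filename(path: str | Path) -> tuple[str, str]:
    m = _WELL_RE.match(Path(path).name)
    if m is None:
        raise ValueError(
            f"cannot parse plate/well from FASTQ filename {Path(path).name!r} "
            "(expected PLATE_ROWCOL.fastq)"
        )
    return m.group("plate"), m.group("well")


def count_wells(
    fastq_paths: Iterable[str | Path],
    probes: ProbeSet,
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Build the wells x probes count matrix from per-well FASTQ files.

    Returns a DataFrame indexed by well key with one column per probe_id
    plus an ``UNASSIGNED`` column; per well, assigned + unassigned equals
    the number of reads processed. File order and read order within a file
    do not affect the result.
    """
    paths = sorted(Path(p) for p in fastq_paths)
    if not paths:
        raise ValueError("no FASTQ files given")
    keys = []
    for p in paths:
        plate, well = parse_well_filename(p)
        keys.append(f"{plate}_{well}")
    dup = {k for k in keys if keys.count(k) > 1}
    if dup:
        raise ValueError(f"duplicate well files for: {sorted(dup)}")

    n_probes = len(probes.probes)
    rows = np.zeros((len(paths), n_probes + 1), dtype=np.int64)
    for i, path in enumerate(paths):
        seqs: list[str] = []
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                seqs.append(entry.sequence or "")
        if not seqs:
            log.warning("empty FASTQ file %s; zero row emitted", path)
            continue
        idx = match_batch(seqs, probes, max_mismatch=max_mismatch)
        counts = np.bincount(idx[idx >= 0], minlength=n_probes)
        rows[i, :n_probes] = counts
        rows[i, n_probes] = int((idx < 0).sum())

    df = pd.DataFrame(rows, index=keys, columns=probes.probe_ids + [UNASSIGNED])
    df.index.name = "well"
    return df.sort_index()


def count_dir(fastq_dir: str | Path, probes: ProbeSet, max_mismatch: int = 3) -> pd.DataFrame:
    paths = sorted(Path(fastq_dir).glob("*.fastq")) + sorted(Path(fastq_dir).glob("*.fastq.gz"))
    return count_wells(paths, probes, max_mismatch=max_mismatch)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
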