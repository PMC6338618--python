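"""Probe panel definition, generation and manifest I/O.

An HTS2-style screen reads out the expression of a small gene panel by
sequencing synthetic probes. Each probe is a fixed-length DNA sequence tied
to one gene; genes are either part of the phenotype signature (up- or
down-regulated in the phenotype) or stable internal controls used for
normalization. The default panel shape is 13 signature genes plus 33
stable controls (46 probes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

ROLES = ("signature_up", "signature_down", "stable_control")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Probe:
    probe_id: str
    gene: str
    role: str
    sequence: str


@dataclass
class ProbeSet:
    """An ordered collection of probes with gene identity and role.

    Invariants (checked by :meth:`validate`): sequences are unique and all
    the same length; when a mismatch budget is given, every pair of probes
    is separated by a Hamming distance strictly greater than twice that
    budget, which guarantees every read within budget of one probe is
    unambiguous.
    """

    probes: list[Probe]

    def __post_init__(self) -> None:
        self.validate()

    # -- views ------------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def genes(self) -> list[str]:
        return [p.gene for p in self.probes]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    @property
    def length(self) -> int:
        return len(self.probes[0].sequence)

    def genes_by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown probe role {role!r}")
        return [p.gene for p in self.probes if p.role == role]

    @property
    def signature_up(self) -> list[str]:
        return self.genes_by_role("signature_up")

    @property
    def signature_down(self) -> list[str]:
        return self.genes_by_role("signature_down")

    @property
    def control_genes(self) -> list[str]:
        return self.genes_by_role("stable_control")

    @property
    def signature_genes(self) -> list[str]:
        return self.signature_up + self.signature_down

    def gene_of(self, probe_id: str) -> str:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p.gene
        raise KeyError(probe_id)

    # -- checks -----------------------------------------------------------
    def validate(self, max_mismatch: int | None = None) -> None:
        if not self.probes:
            raise ValueError("empty probe set")
        seqs = self.sequences
        if len(set(seqs)) != len(seqs):
            raise ValueError("probe sequences are not unique")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("probe sequences have unequal lengths")
        for p in self.probes:
            if p.role not in ROLES:
                raise ValueError(f"unknown probe role {p.role!r} for {p.probe_id}")
        if max_mismatch is not None:
            floor = 2 * max_mismatch
            for a, b in itertools.combinations(self.probes, 2):
                if hamming(a.sequence, b.sequence) <= floor:
                    raise ValueError(
                        f"probes {a.probe_id} and {b.probe_id} are within "
                        f"Hamming distance {floor}; assignment would be ambiguous"
                    )

    def min_pairwise_distance(self) -> int:
        return min(
            hamming(a.sequence, b.sequence)
            for a, b in itertools.combinations(self.probes, 2)
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("probe_id\tgene\trole\tsequence\n")
            for p in self.probes:
                fh.write(f"{p.probe_id}\t{p.gene}\t{p.role}\t{p.sequence}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeSet":
        probes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["probe_id", "gene", "role", "sequence"]:
                raise ValueError(f"unexpected probe manifest header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                probe_id, gene, role, seq = line.rstrip("\n").split("\t")[:4]
                probes.append(Probe(probe_id, gene, role, seq))
        return cls(probes)


def generate_probe_set(
    n_up: int,
    n_down: int,
    n_control: int,
    length: int = 30,
    max_mismatch: int = 3,
    seed: int = 0,
) -> ProbeSet:
    """Generate a random probe panel with guaranteed unambiguous assignment.

    Sequences are sampled uniformly over {A,C,G,T}^length and accepted only
    if their Hamming distance to every previously accepted sequence exceeds
    ``2 * max_mismatch``, so a read within ``max_mismatch`` of one probe can
    never be equally close to another. Deterministic for a fixed seed.

    Gene names are synthetic: SIGU / SIGD for the signature halves and CTRL
    for stable controls.
    """
    n_total = n_up + n_down + n_control
    if n_total < 1:
        raise ValueError("at least one probe must be requested")
    if length < 20:
        raise ValueError("probe length must be >= 20")
    rng = np.random.default_rng(seed)
    floor = 2 * max_mismatch
    accepted = np.empty((0, length), dtype=np.uint8)
    max_tries = 1000 * n_total
    tries = 0
    while accepted.shape[0] < n_total:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not satisfy the minimum pairwise Hamming distance "
                f"> {floor} for {n_total} probes of length {length} after "
                f"{max_tries} draws"
            )
        cand = _BASES[rng.integers(0, 4, size=length)]
        if accepted.shape[0]:
            d = (accepted != cand[None, :]).sum(axis=1)
            if int(d.min()) <= floor:
                continue
        accepted = np.vstack([accepted, cand])

    seqs = [row.tobytes().decode() for row in accepted]
    probes = []
    i = 0
    for k in range(n_up):
        probes.append(Probe(f"SIGU{k + 1:02d}_probe", f"SIGU{k + 1:02d}", "signature_up", seqs[i]))
        i += 1
    for k in range(n_down):
        probes.append(Probe(f"SIGD{k + 1:02d}_probe", f"SIGD{k + 1:02d}", "signature_down", seqs[i]))
        i += 1
    for k in range(n_control):
        probes.append(Probe(f"CTRL{k + 1:02d}_probe", f"CTRL{k + 1:02d}", "stable_control", seqs[i]))
        i += 1
    ps = ProbeSet(probes)
    ps.validate(max_mismatch=max_mismatch)
    return ps
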