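"""KZFP gene census: pairing KRAB and zinc-finger-array domain hits into
gene calls, and delineating/naming KZFP gene clusters.

KZFP genes are defined by juxtaposed KRAB- and C2H2 zinc-finger-coding
domains on the same strand.  Domain hits (e.g. from an upstream HMM scan
of the translated genome) are paired by proximity and strandness; gene
clusters are maximal groups of at least `min_size` genes in which every
member's center lies within `max_center_gap` (default 250 kb) of the
center of another member — i.e. single-linkage chains over sorted gene
centers.  Clusters are named after their chromosome and numbered from
the short arm (ascending coordinate): "Chr 19.1", "Chr 19.2", ...
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class DomainHit:
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # "KRAB" | "ZF_ARRAY"
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.kind not in ("KRAB", "ZF_ARRAY"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class KZFPGene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    krab: tuple[int, int]
    zf_array: tuple[int, int]
    coding: bool = True
    age_myo: float | None = None

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Cluster:
    name: str
    chrom: str
    members: list[str]
    span: tuple[int, int]

    @property
    def n_members(self) -> int:
        return len(self.members)


def _pair_gap(krab: DomainHit, zf: DomainHit, enforce_order: bool) -> int | None:
    """Separation between a KRAB hit and a ZF-array hit, or None if the
    configuration is inadmissible.

    With `enforce_order`, the KRAB must lie upstream of the ZF array in
    transcription orientation (the domain order of the protein); the gap
    is the end-to-start distance.  Without it, the gap is the plain
    separation (0 if the hits overlap).
    """
    if enforce_order:
        if krab.strand == "+":
            gap = zf.start - krab.end
        else:
            gap = krab.start - zf.end
        return gap if gap >= 0 else None
    return max(0, max(krab.start, zf.start) - min(krab.end, zf.end))


def pair_domains(
    krab_hits: Iterable[DomainHit],
    zf_hits: Iterable[DomainHit],
    max_gap: int = 50_000,
    require_same_strand: bool = True,
    enforce_order: bool = True,
    id_prefix: str = "KZFP",
) -> tuple[list[KZFPGene], list[DomainHit]]:
    """Greedily pair each KRAB hit with its nearest admissible ZF-array hit.

    Candidate pairs are same-chromosome (and same-strand if required)
    with gap <= max_gap; they are consumed in order of increasing gap,
    ties broken by leftmost KRAB then leftmost ZF array, and each hit is
    used at most once.  Returns (genes, unpaired hits); the gene interval
    is the union of the paired hits and ids are assigned in coordinate
    order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    krabs = sorted(krab_hits, key=lambda h: (h.chrom, h.start, h.end))
    zfs = sorted(zf_hits, key=lambda h: (h.chrom, h.start, h.end))
    candidates = []
    for ik, k in enumerate(krabs):
        for iz, z in enumerate(zfs):
            if k.chrom != z.chrom:
                continue
            if require_same_strand and k.strand != z.strand:
                continue
            gap = _pair_gap(k, z, enforce_order)
            if gap is None or gap > max_gap:
                continue
            candidates.append((gap, k.start, z.start, ik, iz))
    candidates.sort()
    used_k: set[int] = set()
    used_z: set[int] = set()
    pairs = []
    for gap, _, _, ik, iz in candidates:
        if ik in used_k or iz in used_z:
            continue
        used_k.add(ik)
        used_z.add(iz)
        pairs.append((ik, iz))
    genes = []
    for ik, iz in pairs:
        k, z = krabs[ik], zfs[iz]
        genes.append(
            KZFPGene(
                id="",
                chrom=k.chrom,
                start=min(k.start, z.start),
                end=max(k.end, z.end),
                strand=k.strand,
                krab=(k.start, k.end),
                zf_array=(z.start, z.end),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    width = max(4, len(str(len(genes))))
    for i, g in enumerate(genes, start=1):
        g.id = f"{id_prefix}_{i:0{width}d}"
    unpaired = [h for i, h in enumerate(krabs) if i not in used_k]
    unpaired += [h for i, h in enumerate(zfs) if i not in used_z]
    return genes, unpaired


def call_clusters(
    genes: Iterable[KZFPGene],
    min_size: int = 3,
    max_center_gap: int = 250_000,
) -> list[Cluster]:
    """Single-linkage cluster calling on gene centers, per chromosome.

    A cluster is a maximal chain of genes in which consecutive sorted
    centers are <= max_center_gap apart (inclusive threshold); chains
    with fewer than min_size members are discarded.  Non-coding KZFP
    genes participate like any other member.  The result is independent
    of input order and clusters are returned unnamed (see
    :func:`name_clusters`).
    """
    by_chrom: dict[str, list[KZFPGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: (g.center, g.start, g.id))
        chain: list[KZFPGene] = []
        for g in gs:
            if chain and g.center - chain[-1].center > max_center_gap:
                if len(chain) >= min_size:
                    clusters.append(_make_cluster(chrom, chain))
                chain = []
            chain.append(g)
        if len(chain) >= min_size:
            clusters.append(_make_cluster(chrom, chain))
    return clusters


def _make_cluster(chrom: str, chain: list[KZFPGene]) -> Cluster:
    members = sorted(chain, key=lambda g: (g.start, g.end, g.id))
    return Cluster(
        name="",
        chrom=chrom,
        members=[g.id for g in members],
        span=(min(g.start for g in chain), max(g.end for g in chain)),
    )


def name_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Assign "Chr <chrom>.<k>" names, numbering from the short arm
    (ascending span start), independently per chromosome."""
    counters: dict[str, int] = {}
    out = sorted(clusters, key=lambda c: (c.chrom, c.span[0], c.span[1]))
    for c in out:
        counters[c.chrom] = counters.get(c.chrom, 0) + 1
        label = c.chrom[3:] if c.chrom.lower().startswith("chr") else c.chrom
        c.name = f"Chr {label}.{counters[c.chrom]}"
    return out


def genes_to_frame(genes: list[KZFPGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "krab_start": [g.krab[0] for g in genes],
            "krab_end": [g.krab[1] for g in genes],
            "zf_start": [g.zf_array[0] for g in genes],
            "zf_end": [g.zf_array[1] for g in genes],
            "coding": [g.coding for g in genes],
            "age_myo": [g.age_myo for g in genes],
        }
    )


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [c.name for c in clusters],
            "chrom": [c.chrom for c in clusters],
            "start": [c.span[0] for c in clusters],
            "end": [c.span[1] for c in clusters],
            "n_members": [c.n_members for c in clusters],
            "members": [",".join(c.members) for c in clusters],
        }
    )
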