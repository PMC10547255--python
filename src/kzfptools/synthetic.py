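"""Synthetic genomes, KZFP gene models, variant tables, peaks and
coverage masks with known planted structure.

Every downstream stage of the package (census, fingerprint, constraint,
TE enrichment, MSA profiles) can be exercised against ground truth
produced here: repeat subfamilies are planted at known coordinates,
proteins carry known -1/+3/+6 fingerprint triplets, per-gene variant
rates follow known constraint multipliers, and peak sets overlap a
chosen target subfamily at a chosen fraction.

Randomness is driven by one master seed per generator call; substreams
are spawned with ``numpy.random.SeedSequence`` so each artifact is
reproducible independently.  Fixed seed implies byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .intervals import IntervalSet, MappablePositions
from .msa import AlignedCopy

# amino-acid filler alphabet without C and H, so that planted C2H2
# fingers are the only matches the finger regex can find
_FILLER = np.array(list("ADEFGIKLMNPQRSTVWY"))

KRAB_LEN = 45  # residues; typical Kruppel-associated box size
_LINKER_LEN = 10
_TAIL_LEN = 5
FINGER_LEN = 21  # C x2 C x12 H x3 H
_FINGER_TRIPLET_REL = (9, 12, 15)  # -1/+3/+6 residues within a finger


@dataclass
class SubfamilySpec:
    subfamily: str
    family: str
    n_fragments: int
    length_dist: int | tuple[int, int] | Callable
    te_class: str = "Unknown"


@dataclass
class SyntheticGenome:
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    repeat_annotation: pd.DataFrame  # chrom,start,end,strand,subfamily,family,class
    seed: int
    sequence: dict[str, str] | None = None


@dataclass
class PlantedTruth:
    """Ground truth sidecar for parameter-recovery tests."""

    target_subfamily: str | None = None
    target_fraction: float | None = None
    constraint_multipliers: dict[str, float] = field(default_factory=dict)
    cluster_layout: list = field(default_factory=list)
    fingerprints: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _draw_lengths(dist, rng: np.random.Generator, size: int) -> np.ndarray:
    if callable(dist):
        out = np.asarray(dist(rng, size), dtype=np.int64)
    elif isinstance(dist, tuple):
        lo, hi = dist
        out = rng.integers(lo, hi + 1, size=size)
    else:
        out = np.full(size, int(dist), dtype=np.int64)
    if size and out.min() <= 0:
        raise ValueError("lengths must be positive")
    return out


def generate_genome(
    seed: int,
    chrom_lengths: dict[str, int],
    subfamily_spec: Sequence[SubfamilySpec | tuple],
    max_tries: int = 1000,
    with_sequence: bool = False,
) -> SyntheticGenome:
    """Plant repeat fragments uniformly and without overlap.

    Each fragment picks a chromosome with probability proportional to
    its length and a uniform start; placements colliding with existing
    fragments are rejected and retried up to ``max_tries`` times, after
    which the offending chromosome is reported.  Fragments of different
    subfamilies never overlap either (RepeatMasker fragments are mostly
    disjoint); abutting is allowed.
    """
    specs = [s if isinstance(s, SubfamilySpec) else SubfamilySpec(*s) for s in subfamily_spec]
    for c, l in chrom_lengths.items():
        if l <= 0:
            raise ValueError(f"chromosome {c} has non-positive length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for spec in specs:
        frag_lens = _draw_lengths(spec.length_dist, rng, spec.n_fragments)
        for L in frag_lens:
            placed = False
            last_chrom = None
            for _ in range(max_tries):
                ci = rng.choice(len(chroms), p=probs)
                c = chroms[ci]
                last_chrom = c
                if chrom_lengths[c] < L:
                    continue
                s = int(rng.integers(0, chrom_lengths[c] - L + 1))
                e = s + int(L)
                if any(s < oe and e > os_ for os_, oe in occupied[c]):
                    continue
                occupied[c].append((s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((c, s, e, strand, spec.subfamily, spec.family, spec.te_class))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {L}-bp {spec.subfamily} fragment "
                    f"(last tried chromosome {last_chrom}) after {max_tries} tries"
                )
    ann = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    sequence = None
    if with_sequence:
        srng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E9]))
        sequence = {
            c: "".join(srng.choice(list("ACGT"), size=chrom_lengths[c]))
            for c in chroms
        }
    return SyntheticGenome(chroms, dict(chrom_lengths), ann, seed, sequence)


def _make_protein(n_fingers: int, rng: np.random.Generator) -> tuple[str, list[str]]:
    """KRAB + linker + tandem C2H2 fingers + tail; returns (protein, planted triplets)."""

    def filler(n: int) -> str:
        return "".join(rng.choice(_FILLER, size=n))

    parts = [filler(KRAB_LEN), filler(_LINKER_LEN)]
    triplets = []
    for _ in range(n_fingers):
        x = list(filler(FINGER_LEN))
        x[0], x[3], x[16], x[20] = "C", "C", "H", "H"
        triplets.append("".join(x[i] for i in _FINGER_TRIPLET_REL))
        parts.append("".join(x))
    parts.append(filler(_TAIL_LEN))
    return "".join(parts), triplets


def generate_kzfp_genes(
    genome: SyntheticGenome,
    n_genes: int,
    cluster_layout: Sequence[tuple[str, int, int, int]] = (),
    n_fingers_dist: int | tuple[int, int] | Callable = (4, 12),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], PlantedTruth]:
    """Place KZFP gene models and emit matching protein sequences.

    ``cluster_layout`` entries (chrom, center, n_members, spacing) place
    n_members genes with centers spacing bp apart, centered on `center`;
    genes beyond the layout are placed uniformly, rejecting overlap with
    existing gene bodies.  Each protein is KRAB + a tandem C2H2 array
    with randomized -1/+3/+6 residues; the planted triplets are returned
    in the truth sidecar.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E4E]))
    n_layout = sum(int(n) for _, _, n, _ in cluster_layout)
    if n_layout > n_genes:
        raise ValueError("cluster_layout places more genes than n_genes")
    n_fingers = _draw_lengths(n_fingers_dist, rng, n_genes)
    proteins: dict[str, str] = {}
    truth = PlantedTruth(cluster_layout=[list(e) for e in cluster_layout])
    rows = []
    bodies: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}

    def add_gene(gid: str, chrom: str, center: int, nf: int, forced: bool) -> None:
        prot, triplets = _make_protein(nf, rng)
        cds_len = 3 * len(prot) + 3
        start = max(0, center - cds_len // 2)
        end = start + cds_len
        if end > genome.chrom_lengths[chrom]:
            raise ValueError(f"gene {gid} does not fit on {chrom}")
        if any(start < oe and end > os_ for os_, oe in bodies[chrom]):
            raise ValueError(f"gene {gid} overlaps an existing gene body on {chrom}")
        bodies[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        krab_aa = (0, KRAB_LEN)
        zf_aa = (KRAB_LEN + _LINKER_LEN, KRAB_LEN + _LINKER_LEN + FINGER_LEN * nf)
        if strand == "+":
            krab_g = (start + 3 * krab_aa[0], start + 3 * krab_aa[1])
            zf_g = (start + 3 * zf_aa[0], start + 3 * zf_aa[1])
        else:
            krab_g = (end - 3 * krab_aa[1], end - 3 * krab_aa[0])
            zf_g = (end - 3 * zf_aa[1], end - 3 * zf_aa[0])
        proteins[gid] = prot
        truth.fingerprints[gid] = triplets
        rows.append(
            dict(
                gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                cds_length=cds_len, n_fingers=int(nf),
                krab_aa_start=krab_aa[0], krab_aa_end=krab_aa[1],
                zf_aa_start=zf_aa[0], zf_aa_end=zf_aa[1],
                krab_start=krab_g[0], krab_end=krab_g[1],
                zf_start=zf_g[0], zf_end=zf_g[1],
                n_exons=4, coding=True, age_myo=np.nan,
            )
        )

    gi = 0
    for chrom, center, n_members, spacing in cluster_layout:
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom} in layout")
        for j in range(n_members):
            c = int(center + (j - (n_members - 1) / 2) * spacing)
            add_gene(f"G{gi + 1:04d}", chrom, c, int(n_fingers[gi]), True)
            gi += 1
    chroms = genome.chrom_names
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    while gi < n_genes:
        for attempt in range(1000):
            c = chroms[rng.choice(len(chroms), p=probs)]
            center = int(rng.integers(0, genome.chrom_lengths[c]))
            try:
                add_gene(f"G{gi + 1:04d}", c, center, int(n_fingers[gi]), False)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not place isolated gene without overlap")
        gi += 1
    cols = ["gene_id", "chrom", "start", "end", "strand", "cds_length", "n_fingers",
            "krab_aa_start", "krab_aa_end", "zf_aa_start", "zf_aa_end",
            "krab_start", "krab_end", "zf_start", "zf_end", "n_exons", "coding", "age_myo"]
    models = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return models, proteins, truth


def default_ac_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Non-singleton allele counts: 1 + geometric, shifted to >= 2.

    Mimics the steep allele-frequency spectrum of population cohorts
    after singleton removal.
    """
    return 1 + rng.geometric(0.3, size=size)


def generate_variants(
    gene_models: pd.DataFrame,
    base_rate: float,
    constraint_multipliers: dict[str, float],
    ac_dist: Callable | None = None,
    singleton_fraction: float = 0.3,
    lof_fraction: float = 0.08,
    spoiled_fraction: float = 0.0,
    lof_low_conf_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene variant tables with planted constraint multipliers.

    Per gene: count ~ Poisson(base_rate x multiplier x CDS length),
    positions uniform over the CDS, consequence stop-gain/frameshift/
    splice with total probability ``lof_fraction`` (else missense),
    allele count 1 with probability ``singleton_fraction`` else drawn
    from ``ac_dist``, FILTER "PASS" except a ``spoiled_fraction``.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be >= 0")
    for g, m in constraint_multipliers.items():
        if m < 0:
            raise ValueError(f"negative multiplier for {g}")
    if ac_dist is None:
        ac_dist = default_ac_dist
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A2]))
    rows = []
    for _, g in gene_models.iterrows():
        mult = float(constraint_multipliers.get(g.gene_id, 1.0))
        lam = base_rate * mult * int(g.cds_length)
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        pos = rng.integers(1, int(g.cds_length) + 1, size=n)
        is_lof = rng.random(n) < lof_fraction
        kinds = np.where(
            is_lof,
            rng.choice(["stop_gain", "frameshift", "splice"], size=n),
            "missense",
        )
        is_singleton = rng.random(n) < singleton_fraction
        ac = np.where(is_singleton, 1, ac_dist(rng, n)).astype(np.int64)
        filt = rng.random(n) >= spoiled_fraction
        low_conf = is_lof & (rng.random(n) < lof_low_conf_fraction)
        for i in range(n):
            rows.append(
                (g.gene_id, int(pos[i]), kinds[i], int(ac[i]), bool(filt[i]), bool(low_conf[i]))
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "cds_position", "consequence", "allele_count",
                 "filter_pass", "lof_low_confidence"],
    )
    return df.sort_values(["gene_id", "cds_position"], kind="mergesort").reset_index(drop=True)


def generate_peaks(
    annotation: pd.DataFrame,
    mappable: IntervalSet,
    n_peaks: int,
    target_subfamily: str | None,
    target_fraction: float,
    width_dist: int | tuple[int, int] | Callable = (150, 350),
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place peaks, a planted fraction of which overlap a target subfamily.

    floor(target_fraction x n_peaks) peaks are centered uniformly within
    a uniformly chosen target fragment (guaranteeing >= 1 bp overlap);
    the remainder start uniformly within the mappable set.  All peaks
    are clipped to chromosome bounds.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0,1]")
    if iv.total_length(mappable) == 0:
        raise ValueError("empty mappable set")
    if n_peaks == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    if chrom_lengths is None:
        chrom_lengths = {c: int(a[:, 1].max()) for c, a in mappable.items()}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEAC]))
    widths = _draw_lengths(width_dist, rng, n_peaks)
    n_target = int(np.floor(target_fraction * n_peaks))
    if n_target > 0:
        frags = annotation[annotation["subfamily"] == target_subfamily]
        if len(frags) == 0:
            raise ValueError(f"target subfamily {target_subfamily!r} absent from annotation")
        frags = frags.reset_index(drop=True)
    rows = []
    for i in range(n_target):
        f = frags.iloc[int(rng.integers(0, len(frags)))]
        center = int(rng.integers(f.start, f.end))
        w = int(widths[i])
        s = max(0, center - w // 2)
        e = min(int(chrom_lengths[f.chrom]), s + w)
        rows.append((f.chrom, s, e))
    if n_peaks > n_target:
        mp = MappablePositions(mappable)
        flat = rng.integers(0, mp.total, size=n_peaks - n_target)
        cis, bases = mp.positions(flat)
        for j, (ci, b) in enumerate(zip(cis, bases)):
            c = mp.chrom_name(int(ci))
            w = int(widths[n_target + j])
            s = int(b)
            e = min(int(chrom_lengths[c]), s + w)
            rows.append((c, s, e))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks["name"] = [f"peak_{i + 1}" for i in range(len(peaks))]
    return peaks


def generate_zero_coverage(
    chrom_lengths: dict[str, int],
    n_regions: int,
    length_dist: int | tuple[int, int] | Callable = (10_000, 80_000),
    seed: int = 0,
) -> IntervalSet:
    """Random zero-coverage regions (merged), emulating unmappable tracts."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0C0F]))
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    rows = []
    lengths = _draw_lengths(length_dist, rng, n_regions)
    for L in lengths:
        c = chroms[rng.choice(len(chroms), p=probs)]
        L = min(int(L), chrom_lengths[c])
        s = int(rng.integers(0, chrom_lengths[c] - L + 1))
        rows.append((c, s, s + L))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return iv.from_dataframe(df) if len(df) else {}


def make_synthetic_alignment(
    n_copies: int,
    n_columns: int,
    bump_column: int,
    bump_width: int = 5,
    bump_height: float = 10.0,
    gap_prob: float = 0.1,
    noise_sd: float = 0.5,
    chrom: str = "chrA",
    seed: int = 0,
) -> tuple[list[AlignedCopy], dict[str, np.ndarray], int]:
    """Aligned TE copies plus a signal track with a rectangular bump.

    Each copy drops alignment columns at random (never the bump window),
    its retained columns map to consecutive genomic bases laid end to
    end on one chromosome (alternating strand), and the track carries
    baseline noise plus ``bump_height`` at bases that correspond to the
    bump window.  Returns (copies, track, bump_column) for planted-peak
    recovery tests of the MSA projection pipeline.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x35A]))
    protected = set(range(bump_column, min(n_columns, bump_column + bump_width)))
    copies: list[AlignedCopy] = []
    spans = []
    cursor = 100
    for ci in range(n_copies):
        gaps = rng.random(n_columns) < gap_prob
        for j in protected:
            gaps[j] = False
        n_bases = int((~gaps).sum())
        strand = "+" if ci % 2 == 0 else "-"
        seq_letters = rng.choice(list("ACGT"), size=n_bases)
        aligned = []
        k = 0
        for j in range(n_columns):
            if gaps[j]:
                aligned.append("-")
            else:
                aligned.append(str(seq_letters[k]))
                k += 1
        start, end = cursor, cursor + n_bases
        copies.append(AlignedCopy(f"copy{ci + 1}", chrom, start, end, strand, "".join(aligned)))
        spans.append((start, end, strand, gaps))
        cursor = end + 50
    track = {chrom: np.abs(rng.normal(0.0, noise_sd, size=cursor + 100))}
    for (start, end, strand, gaps), _ in zip(spans, copies):
        nongap_cols = np.flatnonzero(~gaps)
        for i, j in enumerate(nongap_cols):
            if j in protected:
                pos = start + i if strand == "+" else end - 1 - i
                track[chrom][pos] += bump_height
    return copies, track, bump_column
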