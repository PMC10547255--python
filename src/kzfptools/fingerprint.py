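"""C2H2 zinc finger detection, zinc fingerprint extraction and paralog
clustering.

A C2H2 zinc finger is the ~23-residue DNA-binding module of KZFPs,
coordinated by two cysteines and two histidines.  DNA contact is made
chiefly by the residues at recognition-helix positions -1, +3 and +6;
the ordered concatenation of these triplets across a protein's finger
array is its *zinc fingerprint*, and fingerprint similarity defines
paralogy within the family.

Conventions
-----------
The first zinc-coordinating histidine is helix position +7, so the
fingerprint residues sit at offsets anchor-7 (position -1), anchor-4
(+3) and anchor-1 (+6) from that histidine.  Fingers are found with a
regular-expression surrogate for the Pfam zf-C2H2 profile,
``C-x(2,4)-C-x(12)-H-x(3,5)-H``; fingers with non-canonical linker
spacing are missed by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

C2H2_PATTERN = re.compile(r"(C)(.{2,4})(C)(.{12})(H)(.{3,5})(H)")

#: fingerprint helix positions relative to the first coordinating His (= +7)
FINGERPRINT_OFFSETS = (-7, -4, -1)  # helix -1, +3, +6


@dataclass(frozen=True)
class ZincFinger:
    """A single C2H2 match within a protein (0-based half-open)."""

    start: int
    end: int
    sequence: str
    helix_anchor: int  # protein index of the first zinc-coordinating His

    @property
    def cys_his_positions(self) -> tuple[int, int, int, int]:
        """Protein indices of the two Cys and two His (structural residues)."""
        m = C2H2_PATTERN.fullmatch(self.sequence)
        if m is None:  # pragma: no cover - enforced at construction
            raise ValueError("finger sequence lost its C2H2 pattern")
        return tuple(self.start + m.start(g) for g in (1, 3, 5, 7))

    @property
    def fingerprint_positions(self) -> tuple[int, int, int]:
        """Protein indices of the helix -1 / +3 / +6 residues."""
        return tuple(self.helix_anchor + o for o in FINGERPRINT_OFFSETS)


@dataclass
class ZincFingerprint:
    protein_id: str
    triplets: list[str] = field(default_factory=list)
    skipped: list[int] = field(default_factory=list)  # finger indices skipped

    def __len__(self) -> int:
        return len(self.triplets)


def find_zf_domains(protein: str) -> list[ZincFinger]:
    """Locate non-overlapping C2H2 fingers, scanning left to right.

    Matching is greedy in the standard leftmost-first regex sense: each
    finger starts at the earliest position where the pattern fits, and
    the search resumes after its last histidine.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    fingers = []
    for m in C2H2_PATTERN.finditer(protein):
        fingers.append(
            ZincFinger(
                start=m.start(),
                end=m.end(),
                sequence=m.group(0),
                helix_anchor=m.start(5),
            )
        )
    return fingers


def extract_fingerprint(fingers: list[ZincFinger], protein: str, protein_id: str = "") -> ZincFingerprint:
    """Read the -1/+3/+6 triplet of each finger.

    A finger whose anchor sits fewer than 7 residues into the protein
    cannot carry a full triplet; it is skipped and recorded in
    ``ZincFingerprint.skipped``.
    """
    fp = ZincFingerprint(protein_id=protein_id)
    for i, f in enumerate(fingers):
        if f.helix_anchor < 7 or f.helix_anchor - f.start < 7:
            fp.skipped.append(i)
            continue
        fp.triplets.append("".join(protein[f.helix_anchor + o] for o in FINGERPRINT_OFFSETS))
    return fp


def fingerprint_from_protein(protein: str, protein_id: str = "") -> ZincFingerprint:
    return extract_fingerprint(find_zf_domains(protein), protein, protein_id)


def fingerprint_identity(a: ZincFingerprint | list[str], b: ZincFingerprint | list[str]) -> float:
    """Best ungapped sliding identity between two fingerprints.

    The triplet arrays are slid against each other over every integer
    offset with at least one aligned triplet; identity is the maximal
    count of matching residues divided by 3 x (length of the shorter
    array), so overhanging fingers of the longer array are free but the
    shorter array pays for any of its own fingers left unmatched.
    """
    ta = a.triplets if isinstance(a, ZincFingerprint) else list(a)
    tb = b.triplets if isinstance(b, ZincFingerprint) else list(b)
    if not ta or not tb:
        raise ValueError("fingerprint identity undefined for empty fingerprints")
    na, nb = len(ta), len(tb)
    best = 0
    for off in range(-(nb - 1), na):
        matched = 0
        for i in range(max(0, off), min(na, nb + off)):
            x, y = ta[i], tb[i - off]
            matched = matched + sum(1 for p, q in zip(x, y) if p == q)
        best = max(best, matched)
    return best / (3 * min(na, nb))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_paralogs(fingerprints: list[ZincFingerprint], threshold: float = 0.60) -> list[set[str]]:
    """Single-linkage paralog sets at a fingerprint-identity cutoff.

    Two KZFPs are joined when identity >= threshold (inclusive, default
    the family's classic 60% cutoff); sets are the connected components,
    singletons included, ordered by first appearance.
    """
    n = len(fingerprints)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if not fingerprints[i].triplets or not fingerprints[j].triplets:
                continue
            if fingerprint_identity(fingerprints[i], fingerprints[j]) >= threshold:
                uf.union(i, j)
    groups: dict[int, set[str]] = {}
    order: list[int] = []
    for i, fp in enumerate(fingerprints):
        r = uf.find(i)
        if r not in groups:
            groups[r] = set()
            order.append(r)
        groups[r].add(fp.protein_id)
    return [groups[r] for r in order]
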