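"""Isotype-synteny classification of tRNA arrays and the duplication screen.

Each array is summarized as its isotype string: the single-letter amino
acid codes of its tRNA genes in ascending genomic-coordinate order
(selenocysteine = U, pyrrolysine = O, undetermined = X). Arrays whose
isotype strings align at or above an identity threshold (single linkage)
form a synteny group; groups are named G1, G2, … in descending member
count and singletons keep their own label.

The same global aligner, run on nucleotide sequences, powers the
intra-genomic duplication screen: each arrayed tRNA gene is compared
against every non-arrayed tRNA gene of the genome and flagged when the
best pairwise identity reaches 90%.

Alignment is Needleman–Wunsch with match +1, mismatch −1, linear gap −1,
and a deterministic traceback (diagonal preferred over up over left).
Identity is matches divided by total alignment columns, so gaps count
against identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detector import ArrayUnit

__all__ = [
    "IsotypeProfile", "ProfileAlignment", "GroupAssignment", "DuplicationHit",
    "isotype_string", "align_profiles", "global_align", "cluster_groups",
    "duplication_screen", "DUPLICATION_IDENTITY_PCT",
]

GAP = "-"
#: identity threshold (percent) above which an arrayed gene is flagged as a
#: possible recent intra-genomic duplication
DUPLICATION_IDENTITY_PCT = 90.0


@dataclass(frozen=True)
class IsotypeProfile:
    """The isotype string of one array, in genomic-coordinate order."""

    array_id: str
    letters: str


@dataclass(frozen=True)
class ProfileAlignment:
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping array_id -> group label ("G1", "G2", … or "singleton-<id>")."""

    labels: dict[str, str]


@dataclass(frozen=True)
class DuplicationHit:
    arrayed_gene_id: str
    best_match_gene_id: str
    identity_pct: float

    @property
    def flagged(self) -> bool:
        return self.identity_pct >= DUPLICATION_IDENTITY_PCT


def isotype_string(array: ArrayUnit) -> IsotypeProfile:
    """Concatenate the array's gene isotypes in genomic order."""
    return IsotypeProfile(
        array_id=array.array_id,
        letters="".join(g.isotype for g in array.genes),
    )


def global_align(a: str, b: str) -> ProfileAlignment:
    """Needleman–Wunsch with +1 match, −1 mismatch, −1 gap (linear).

    The traceback is deterministic: on ties the diagonal move wins, then
    the up move (gap in ``b``), then the left move (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    # score matrix, (n+1) x (m+1)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if ai == b[j - 1] else -1)
            up = prev[j] - 1
            left = row[j - 1] - 1
            row[j] = max(diag, up, left)
    # traceback, tie order: diagonal, up, left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
                1 if a[i - 1] == b[j - 1] else -1):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] - 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b)
                  if x == y and x != GAP)
    return ProfileAlignment(aligned_a, aligned_b, matches, len(aligned_a))


def align_profiles(a: IsotypeProfile, b: IsotypeProfile) -> ProfileAlignment:
    """Globally align two isotype strings (see :func:`global_align`)."""
    return global_align(a.letters, b.letters)


def cluster_groups(profiles: list[IsotypeProfile], threshold: float = 0.60,
                   try_reverse: bool = False) -> GroupAssignment:
    """Single-linkage clustering of arrays by pairwise isotype identity.

    Two arrays are linked when their alignment identity is at or above
    ``threshold``; connected components of size >= 2 become groups named
    G1, G2, … (descending size, ties broken by the lexicographically
    smallest member id), components of size 1 become ``singleton-<id>``.
    With ``try_reverse`` the reversed letter string is also tried and the
    better identity used (arrays read in opposite genomic orientations).
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = [p.array_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids among profiles")

    # union-find over profile indices
    parent = list(range(len(profiles)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(len(profiles)), key=lambda k: ids[k])
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            pa, pb = profiles[order[ai]], profiles[order[bi]]
            ident = align_profiles(pa, pb).identity
            if try_reverse:
                rev = IsotypeProfile(pb.array_id, pb.letters[::-1])
                ident = max(ident, align_profiles(pa, rev).identity)
            if ident >= threshold:
                ra, rb = find(order[ai]), find(order[bi])
                if ra != rb:
                    parent[rb] = ra

    components: dict[int, list[str]] = {}
    for k in range(len(profiles)):
        components.setdefault(find(k), []).append(ids[k])
    groups = sorted(
        (sorted(members) for members in components.values()),
        key=lambda m: (-len(m), m[0]),
    )
    labels: dict[str, str] = {}
    gnum = 0
    for members in groups:
        if len(members) == 1:
            labels[members[0]] = f"singleton-{members[0]}"
        else:
            gnum += 1
            for mid in members:
                labels[mid] = f"G{gnum}"
    return GroupAssignment(labels)


def duplication_screen(arrayed: list[tuple[str, str]],
                       background: list[tuple[str, str]]
                       ) -> list[DuplicationHit]:
    """Screen arrayed tRNA gene sequences against non-arrayed ones.

    For each (gene_id, sequence) in ``arrayed``, globally align against
    every background gene and keep the best-scoring pair's identity
    (percent of alignment columns that match). Genes at >= 90% identity
    are flagged as possible recent intra-genomic duplications. With an
    empty background every hit has identity 0 and is unflagged.
    """
    for gid, seq in arrayed + background:
        if set(seq.upper()) - set("ACGTN"):
            raise ValueError(f"gene {gid}: sequence not over ACGTN")
    hits = []
    for gid, seq in arrayed:
        best_id, best_pct, best_score = "", 0.0, None
        for bgid, bgseq in background:
            aln = global_align(seq.upper(), bgseq.upper())
            score = 2 * aln.matches - aln.columns  # match +1, else -1
            if best_score is None or score > best_score:
                best_id, best_pct, best_score = bgid, 100 * aln.identity, score
        hits.append(DuplicationHit(gid, best_id, best_pct))
    return hits


def group_table(profiles: list[IsotypeProfile],
                assignment: GroupAssignment) -> str:
    """TSV of array_id, group, profile, and the gapped alignment of the
    profile against its group's first (lexicographically smallest) member."""
    by_group: dict[str, list[IsotypeProfile]] = {}
    for p in profiles:
        by_group.setdefault(assignment.labels[p.array_id], []).append(p)
    lines = ["array_id\tgroup\tprofile\talignment_to_reference"]
    for group in sorted(by_group):
        members = sorted(by_group[group], key=lambda p: p.array_id)
        ref = members[0]
        for p in members:
            aln = align_profiles(ref, p)
            lines.append(f"{p.array_id}\t{group}\t{p.letters}\t{aln.aligned_b}")
    return "\n".join(lines) + "\n"
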