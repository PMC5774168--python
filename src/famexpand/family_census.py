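"""Minimum gene-family census from transcript hits.

The census estimates, per annotated reference family, the minimum number of
distinct genes a set of transcripts could have arisen from:

1. select transcripts whose top hit matches a superfamily keyword set
   (e.g. "cytochrome P450"; "cathepsin" / "cysteine peptidase");
2. ignore transcripts shorter than 250 nt (guards against over-counting);
3. collapse near-identical transcripts (>= 95% nucleotide identity over the
   best local alignment, with >= 80% coverage of the shorter sequence) into
   isoform clusters by single linkage;
4. within each group of clusters sharing one top-hit subject, call each
   cluster representative's ORF complete or truncated and resolve gene
   units: complete-ORF clusters are distinct genes; truncated clusters whose
   subject intervals do not overlap are chained together as fragments of one
   gene, while overlapping truncated clusters must be distinct genes;
5. roll gene units up by reference family and clan.

The resulting counts carry ">=" (minimum) semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .seqio import SequenceRecord, hydrate_hits
from .translated_search import (AlignmentHit, ScoringScheme, nt_scheme,
                                smith_waterman, top_hits_from, translate_frame,
                                search)

DEFAULT_KEYWORDS: Dict[str, Tuple[str, ...]] = {
    "P450": ("cytochrome p450",),
    "cathepsin": ("cathepsin", "cysteine peptidase"),
}


@dataclass
class ProteinRecord:
    """Reference protein with its family/clan annotation."""

    id: str
    seq: str
    family: str
    clan: str = ""
    description: str = ""


@dataclass
class OrfCall:
    """Completeness call for the reading frame fixed by a transcript's hit."""

    transcript_id: str
    frame: int
    aa_start: int
    aa_end: int
    has_start: bool
    has_stop: bool

    @property
    def status(self) -> str:
        return "complete" if (self.has_start and self.has_stop) else "truncated"


@dataclass
class GeneCluster:
    """A set of transcripts judged to arise from one gene."""

    cluster_id: str
    family: str
    member_transcripts: List[str]
    subject_id: str
    subject_intervals: List[Tuple[int, int]]
    basis: str  # isoform | fragment_merge | singleton


@dataclass
class FamilyCount:
    family: str
    clan: str
    transcript_count: int
    gene_count: int

    def __post_init__(self) -> None:
        if self.gene_count > self.transcript_count:
            raise ValueError("gene_count cannot exceed transcript_count")


@dataclass
class CensusConfig:
    e_max: float = 1e-3
    census_min_len: int = 250
    isoform_identity: float = 0.95
    isoform_coverage: float = 0.80
    min_overlap: int = 15
    overlap_frac: float = 0.10
    keywords: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORDS))


@dataclass
class CensusResult:
    family_counts: List[FamilyCount]
    clusters: List[GeneCluster]
    gene_units: List[List[str]]  # cluster ids per gene unit
    ledger: pd.DataFrame

    def counts_frame(self) -> pd.DataFrame:
        rows = [{"family": fc.family, "clan": fc.clan,
                 "transcript_count": fc.transcript_count,
                 "gene_count": fc.gene_count,
                 "display": f">={fc.gene_count}"}
                for fc in self.family_counts]
        return pd.DataFrame(
            rows, columns=["family", "clan", "transcript_count",
                           "gene_count", "display"])

    def clan_matrix(self) -> pd.DataFrame:
        """Clan-by-family gene-count matrix (families as columns)."""
        df = self.counts_frame()
        if df.empty:
            return pd.DataFrame()
        return df.pivot_table(index="clan", columns="family",
                              values="gene_count", fill_value=0,
                              aggfunc="sum")


def select_family_transcripts(
        top_hits: Mapping[str, AlignmentHit],
        annotations: Mapping[str, ProteinRecord],
        keywords: Mapping[str, Sequence[str]] = DEFAULT_KEYWORDS,
        ) -> Dict[str, List[str]]:
    """Assign transcripts to superfamilies by case-insensitive substring
    match of keywords against the top hit's description and family label.

    Keyword groups must be disjoint; each transcript joins at most one
    superfamily (first matching group in mapping order wins).
    """
    if not keywords:
        raise ValueError("keyword mapping must be non-empty")
    lowered = {g: [k.lower() for k in kws] for g, kws in keywords.items()}
    for (g1, k1), (g2, k2) in combinations(lowered.items(), 2):
        shared = set(k1) & set(k2)
        if shared:
            raise ValueError(
                f"keyword groups {g1!r} and {g2!r} share keywords {shared}")
    selected: Dict[str, List[str]] = {g: [] for g in keywords}
    for qid in sorted(top_hits):
        hit = top_hits[qid]
        prot = annotations.get(hit.subject_id)
        if prot is None:
            raise KeyError(
                f"protein {hit.subject_id!r} missing from annotation table")
        text = f"{prot.description} {prot.family}".lower()
        for group, kws in lowered.items():
            if any(k in text for k in kws):
                selected[group].append(qid)
                break
    return selected


def apply_min_length(transcripts: Sequence[SequenceRecord],
                     min_len: int = 250) -> List[SequenceRecord]:
    """Keep transcripts of at least min_len nucleotides (census-only filter)."""
    return [t for t in transcripts if len(t.seq) >= min_len]


def _kmer_set(seq: str, k: int) -> Set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(transcripts: Sequence[SequenceRecord], k: int = 15
                     ) -> List[Tuple[int, int]]:
    """Pairs sharing at least one exact k-mer on either strand.

    Screening step before exact alignment (as CD-HIT-style clusterers do).
    Any two sequences above ~93% identity over >=250 nt must share a 15-mer
    by pigeonhole, so the screen cannot miss a pair near the 95% isoform
    threshold; random unrelated pairs almost never pass it.
    """
    from .translated_search import reverse_complement
    kmers = []
    for t in transcripts:
        kmers.append(_kmer_set(t.seq, k) | _kmer_set(reverse_complement(t.seq), k))
    pairs = []
    for i, j in combinations(range(len(transcripts)), 2):
        if kmers[i] & kmers[j]:
            pairs.append((i, j))
    return pairs


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def pairwise_nt_identity(a: str, b: str,
                         scheme: Optional[ScoringScheme] = None
                         ) -> Tuple[float, float]:
    """(identity, coverage) of the best local nucleotide alignment.

    Identity is over aligned columns; coverage is aligned columns divided by
    the shorter sequence's length. Both strands of `b` are tried and the
    higher-scoring orientation kept.
    """
    from .translated_search import reverse_complement
    scheme = scheme or nt_scheme()
    fwd = smith_waterman(a, b, scheme)
    rev = smith_waterman(a, reverse_complement(b), scheme)
    aln = fwd if fwd.score >= rev.score else rev
    if aln.aligned_cols == 0:
        return 0.0, 0.0
    return aln.identity, aln.aligned_cols / min(len(a), len(b))


def cluster_isoforms(transcripts: Sequence[SequenceRecord],
                     identity_min: float = 0.95,
                     coverage_min: float = 0.80,
                     ) -> List[List[SequenceRecord]]:
    """Single-linkage clustering of near-identical transcripts.

    Two transcripts link iff their best local nucleotide alignment has
    identity >= identity_min and covers >= coverage_min of the shorter one;
    clusters are the connected components. Within each cluster the first
    element returned is the representative: the longest member (ties broken
    by lexicographic id).
    """
    uf = _UnionFind(len(transcripts))
    for i, j in _candidate_pairs(transcripts):
        ident, cov = pairwise_nt_identity(transcripts[i].seq, transcripts[j].seq)
        if ident >= identity_min and cov >= coverage_min:
            uf.union(i, j)
    groups: Dict[int, List[SequenceRecord]] = {}
    for idx, t in enumerate(transcripts):
        groups.setdefault(uf.find(idx), []).append(t)
    clusters = []
    for members in groups.values():
        members.sort(key=lambda t: (-len(t.seq), t.id))
        clusters.append(members)
    clusters.sort(key=lambda ms: ms[0].id)
    return clusters


def call_orf(transcript: SequenceRecord, top_hit: AlignmentHit) -> OrfCall:
    """ORF completeness in the reading frame fixed by the hit.

    Takes the maximal stop-free stretch of the translated frame containing
    the hit's query interval (if the aligned interval itself crosses a stop,
    the stop-free stretch overlapping it most is used). has_start requires a
    methionine at or before the hit start inside that stretch; has_stop
    requires the stretch to be terminated by a stop codon within the
    transcript rather than by running off its end.
    """
    frame = top_hit.frame
    if frame is None:
        raise ValueError(f"hit for {transcript.id} has no resolved frame")
    if abs(frame) - 1 >= len(transcript.seq):
        raise ValueError(
            f"frame {frame} inconsistent with transcript {transcript.id} "
            f"of length {len(transcript.seq)}")
    pep = translate_frame(transcript.seq, frame)
    if top_hit.q_aa_end > len(pep):
        raise ValueError(
            f"hit interval exceeds translated frame of {transcript.id}")
    # stop-free segments as (start, end) 1-based inclusive
    segments = []
    start = 1
    for pos, ch in enumerate(pep, start=1):
        if ch == "*":
            if pos > start:
                segments.append((start, pos - 1))
            start = pos + 1
    if start <= len(pep):
        segments.append((start, len(pep)))
    qs, qe = top_hit.q_aa_start, top_hit.q_aa_end
    containing = [s for s in segments if s[0] <= qs and s[1] >= qe]
    contains_hit = bool(containing)
    if containing:
        seg = containing[0]
    else:
        # a stop interrupts the aligned region itself; no ORF consistent
        # with the alignment exists, so the call cannot be complete
        overlapping = [
            (min(s[1], qe) - max(s[0], qs) + 1, -s[0], s) for s in segments
            if min(s[1], qe) >= max(s[0], qs)]
        if not overlapping:
            seg = (qs, qe)
        else:
            seg = max(overlapping)[2]
    has_start = any(pep[k - 1] == "M"
                    for k in range(seg[0], min(qs, seg[1]) + 1))
    has_stop = (contains_hit and seg[1] < len(pep) and pep[seg[1]] == "*")
    return OrfCall(transcript_id=transcript.id, frame=frame,
                   aa_start=seg[0], aa_end=seg[1],
                   has_start=has_start, has_stop=has_stop)


# --- gene-unit resolution ----------------------------------------------------


def _overlap_len(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def intervals_conflict(a: Tuple[int, int], b: Tuple[int, int],
                       min_overlap: int = 15, overlap_frac: float = 0.10
                       ) -> bool:
    """True when two subject intervals overlap 'significantly': by at least
    min_overlap residues, or by at least overlap_frac of the shorter
    interval. min_overlap=1 gives the literal any-overlap rule."""
    ov = _overlap_len(a, b)
    if ov <= 0:
        return False
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return ov >= min(min_overlap, overlap_frac * shorter)


@dataclass
class ClusterCall:
    """Input to gene-unit resolution: one isoform cluster with its
    representative's subject interval and ORF status."""

    cluster_id: str
    interval: Tuple[int, int]
    complete: bool


def resolve_gene_units(calls: Sequence[ClusterCall],
                       min_overlap: int = 15, overlap_frac: float = 0.10
                       ) -> List[List[str]]:
    """Resolve isoform clusters sharing one top-hit subject into gene units.

    Complete-ORF clusters are each their own unit (a complete ORF cannot be
    a fragment). Truncated clusters, sorted by subject start, are chained
    into groups of pairwise non-overlapping intervals - each chain is one
    gene whose fragments tile different parts of the subject - using the
    FEWEST possible chains: a first-fit pass provides an upper bound and a
    branch-and-bound search certifies (or improves it to) the true minimum,
    so the reported count is the smallest gene set consistent with the
    overlap rule.

    Returns the units as lists of cluster ids; the number of units is the
    minimum gene count for this subject.
    """
    units: List[List[str]] = []
    for c in calls:
        if c.complete:
            units.append([c.cluster_id])
    truncated = sorted(
        (c for c in calls if not c.complete),
        key=lambda c: (c.interval[0], c.interval[1], c.cluster_id))
    n = len(truncated)
    conflict = [[intervals_conflict(a.interval, b.interval,
                                    min_overlap, overlap_frac)
                 for b in truncated] for a in truncated]

    # first-fit by subject start: optimal for plain interval overlap and a
    # tight upper bound for the thresholded rule
    greedy: List[List[int]] = []
    for i in range(n):
        for chain in greedy:
            if not any(conflict[i][j] for j in chain):
                chain.append(i)
                break
        else:
            greedy.append([i])

    best = [len(greedy), [list(c) for c in greedy]]

    def dfs(i: int, chains: List[List[int]]) -> None:
        if len(chains) >= best[0]:
            return
        if i == n:
            best[0] = len(chains)
            best[1] = [list(c) for c in chains]
            return
        for chain in chains:
            if not any(conflict[i][j] for j in chain):
                chain.append(i)
                dfs(i + 1, chains)
                chain.pop()
        if len(chains) + 1 < best[0]:
            chains.append([i])
            dfs(i + 1, chains)
            chains.pop()

    if n:
        dfs(0, [])
    units.extend([[truncated[j].cluster_id for j in chain]
                  for chain in best[1]])
    return units


# --- the census --------------------------------------------------------------


def census(transcripts: Sequence[SequenceRecord],
           proteome: Sequence[ProteinRecord],
           hits: Optional[Sequence[AlignmentHit]] = None,
           config: Optional[CensusConfig] = None,
           scheme: Optional[ScoringScheme] = None,
           ) -> CensusResult:
    """Run the full census pipeline and return counts plus full provenance.

    When hits is None the built-in translated search is run; otherwise the
    supplied hits (e.g. from read_hit_table) are used as-is, after resolving
    any reverse-strand frames against the transcript lengths.
    """
    config = config or CensusConfig()
    annotations = {p.id: p for p in proteome}
    by_id = {t.id: t for t in transcripts}

    if hits is None:
        prot_records = [SequenceRecord(id=p.id, seq=p.seq) for p in proteome]
        hits, top = search(transcripts, prot_records, scheme=scheme,
                           e_max=config.e_max)
    else:
        hits = hydrate_hits(hits, {t.id: len(t.seq) for t in transcripts})
        hits = [h for h in hits if h.e_value <= config.e_max]
        top = top_hits_from(hits)
    for h in hits:
        if h.subject_id not in annotations:
            raise KeyError(
                f"protein {h.subject_id!r} missing from annotation table")

    selected = select_family_transcripts(top, annotations, config.keywords)

    clusters: List[GeneCluster] = []
    gene_units: List[List[str]] = []
    ledger_rows: List[Dict[str, object]] = []
    family_transcripts: Dict[str, int] = {}
    family_genes: Dict[str, int] = {}

    for group in selected:
        ids = selected[group]
        records = apply_min_length([by_id[q] for q in ids],
                                   config.census_min_len)
        dropped = set(ids) - {r.id for r in records}
        for tid in sorted(dropped):
            ledger_rows.append({
                "transcript_id": tid, "superfamily": group,
                "cluster_id": "", "gene_unit": "", "subject_id": "",
                "family": "", "clan": "",
                "rule": f"excluded:shorter_than_{config.census_min_len}nt"})
        iso = cluster_isoforms(records, config.isoform_identity,
                               config.isoform_coverage)
        # group clusters by the representative's top-hit subject
        by_subject: Dict[str, List[Tuple[GeneCluster, ClusterCall]]] = {}
        for idx, members in enumerate(iso):
            rep = members[0]
            rep_hit = top[rep.id]
            orf = call_orf(rep, rep_hit)
            prot = annotations[rep_hit.subject_id]
            gc = GeneCluster(
                cluster_id=f"{group}.c{idx:04d}",
                family=prot.family,
                member_transcripts=[m.id for m in members],
                subject_id=rep_hit.subject_id,
                subject_intervals=[(rep_hit.s_start, rep_hit.s_end)],
                basis="isoform" if len(members) > 1 else "singleton")
            call = ClusterCall(cluster_id=gc.cluster_id,
                               interval=(rep_hit.s_start, rep_hit.s_end),
                               complete=orf.status == "complete")
            clusters.append(gc)
            by_subject.setdefault(rep_hit.subject_id, []).append((gc, call))

        cluster_by_id = {c.cluster_id: c for c in clusters}
        for sid in sorted(by_subject):
            entries = by_subject[sid]
            prot = annotations[sid]
            units = resolve_gene_units([call for _, call in entries],
                                       config.min_overlap,
                                       config.overlap_frac)
            for unit in units:
                unit_id = f"{sid}.g{len(gene_units):04d}"
                gene_units.append(unit)
                merged = len(unit) > 1
                for cid in unit:
                    gc = cluster_by_id[cid]
                    if merged:
                        gc.basis = "fragment_merge"
                    rule = ("fragment_merge" if merged else
                            ("isoform" if len(gc.member_transcripts) > 1
                             else "singleton"))
                    for tid in gc.member_transcripts:
                        ledger_rows.append({
                            "transcript_id": tid, "superfamily": group,
                            "cluster_id": cid, "gene_unit": unit_id,
                            "subject_id": sid, "family": prot.family,
                            "clan": prot.clan, "rule": rule})
                family_genes[prot.family] = family_genes.get(prot.family, 0) + 1
            n_tr = sum(len(cluster_by_id[cid].member_transcripts)
                       for unit in units for cid in unit)
            family_transcripts[prot.family] = (
                family_transcripts.get(prot.family, 0) + n_tr)

    clans = {p.family: p.clan for p in proteome}
    counts = [FamilyCount(family=fam, clan=clans.get(fam, ""),
                          transcript_count=family_transcripts[fam],
                          gene_count=family_genes[fam])
              for fam in sorted(family_genes)]
    ledger = pd.DataFrame(
        ledger_rows, columns=["transcript_id", "superfamily", "cluster_id",
                              "gene_unit", "subject_id", "family", "clan",
                              "rule"])
    return CensusResult(family_counts=counts, clusters=clusters,
                        gene_units=gene_units, ledger=ledger)
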