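"""Assembly-level descriptive statistics: N50, length distribution, ortholog
hit ratio (OHR) and multi-reference hit partitions.

OHR is the number of non-gap query residues in a transcript's translated
top-hit alignment divided by the length of the subject ortholog, both in
amino acids. A value near 1 indicates a fully assembled transcript; a value
near 0 a poor fragment. The numerator is counted in translated residues
(not nucleotides) because the denominator is a protein length - counting
nucleotides would inflate OHR roughly threefold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .translated_search import AlignmentHit


def n50(lengths: Sequence[int]) -> int:
    """Shortest length such that contigs at least that long hold >= half the
    total bases: sort descending and take the length where the running sum
    first reaches half the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum * 2, csum[-1]))
    return int(arr[idx])


def length_histogram(lengths: Sequence[int], edges: Sequence[int]
                     ) -> List[int]:
    """Counts per half-open bin [lo, hi); bins are (-inf, e0), [e0, e1), ...,
    [e_last, inf). Returns len(edges)+1 counts summing to len(lengths)."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    bins = [-np.inf] + edges + [np.inf]
    counts, _ = np.histogram(np.asarray(lengths, dtype=float), bins=bins)
    return [int(c) for c in counts]


@dataclass
class OhrRecord:
    query_id: str
    subject_id: str
    ohr: float


def ohr(hit: AlignmentHit, subject_length: int,
        subject_seqs: Optional[Mapping[str, str]] = None) -> float:
    """Ortholog hit ratio of one alignment: q_nongap / subject_length.

    If subject_seqs is given, subject_length is cross-checked against the
    actual protein record. Values above 1.2 (heavily gapped subjects) warn
    but are reported uncapped.
    """
    if subject_length < 1:
        raise ValueError("subject_length must be >= 1")
    if hit.q_nongap < 1:
        raise ValueError("hit has no non-gap query residues")
    if subject_seqs is not None:
        actual = len(subject_seqs[hit.subject_id])
        if actual != subject_length:
            raise ValueError(
                f"subject {hit.subject_id}: stated length {subject_length} "
                f"!= proteome record length {actual}")
    value = hit.q_nongap / subject_length
    if value > 1.2:
        warnings.warn(
            f"OHR {value:.2f} > 1.2 for {hit.query_id}->{hit.subject_id}; "
            "subject alignment is heavily gapped")
    return value


def ohr_table(top_hits: Mapping[str, AlignmentHit],
              proteome: Sequence) -> List[OhrRecord]:
    """Per-transcript OHR from the top-hit map, using proteome lengths."""
    lengths = {p.id: len(p.seq) for p in proteome}
    out = []
    for qid in sorted(top_hits):
        h = top_hits[qid]
        out.append(OhrRecord(qid, h.subject_id, ohr(h, lengths[h.subject_id])))
    return out


def ohr_summary(records: Sequence[OhrRecord],
                thresholds: Sequence[float] = (0.5, 0.7)
                ) -> Dict[float, Optional[float]]:
    """Fraction of queries (with matches) whose OHR strictly exceeds each
    threshold; None per threshold when there are no records."""
    if not records:
        return {t: None for t in thresholds}
    n = len(records)
    return {t: sum(1 for r in records if r.ohr > t) / n for t in thresholds}


@dataclass
class PartitionTable:
    """Counts of queries hitting each non-empty subset of reference sets."""

    references: List[str]
    cells: Dict[FrozenSet[str], int]
    universe: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(sorted(k)), "count": v}
            for k, v in sorted(self.cells.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["subset", "count"])


def hit_partition(hit_sets: Mapping[str, Iterable[str]]) -> PartitionTable:
    """Partition queries by the exact set of references they hit.

    hit_sets maps reference name -> iterable of query ids with a significant
    hit to that reference. Every query with at least one hit lands in exactly
    one cell, so cell counts sum to the universe.
    """
    refs = sorted(hit_sets)
    sets = {r: set(hit_sets[r]) for r in refs}
    universe = set().union(*sets.values()) if sets else set()
    cells: Dict[FrozenSet[str], int] = {}
    for q in universe:
        key = frozenset(r for r in refs if q in sets[r])
        cells[key] = cells.get(key, 0) + 1
    return PartitionTable(references=refs, cells=cells, universe=len(universe))


def assembly_summary(lengths: Sequence[int],
                     edges: Sequence[int] = (250, 500, 1000, 2000)
                     ) -> Dict[str, object]:
    """Headline assembly numbers: contig count, total bases, mean, min/max,
    N50 and the binned length distribution."""
    arr = np.asarray(lengths)
    return {
        "contigs": int(arr.size),
        "total_bases": int(arr.sum()),
        "mean_length": float(arr.mean()) if arr.size else float("nan"),
        "min_length": int(arr.min()) if arr.size else 0,
        "max_length": int(arr.max()) if arr.size else 0,
        "n50": n50(lengths) if arr.size else 0,
        "histogram": length_histogram(lengths, list(edges)),
        "histogram_edges": list(edges),
    }
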