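"""Sequence and hit-table I/O plus the read- and contig-level filters.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the strict
validation the pipeline relies on (unique ids, declared alphabet) and the
whole-read rejection rules used upstream of assembly: reads shorter than 40
bases, reads containing ambiguous nucleotides, and reads whose mean per-base
error probability exceeds 0.01 (Phred 20) are discarded; assembled contigs
shorter than 150 bases are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .translated_search import AlignmentHit

NT_CHARS = set("ACGTN")
AA_CHARS = set("ARNDCQEGHILKMFPSTWYVX*")


@dataclass
class SequenceRecord:
    """One FASTA record; seq is uppercase and alphabet-checked."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """One FASTQ read with per-base Phred scores."""

    id: str
    seq: str
    qual: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)


def _check_alphabet(rec_id: str, seq: str, molecule: str) -> None:
    allowed = NT_CHARS if molecule == "nt" else AA_CHARS
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id}: illegal {molecule} character {ch!r} "
                f"at position {pos}")


def read_fasta(path, molecule: str = "nt") -> List[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    molecule is 'nt' or 'aa' and fixes the allowed alphabet. Sequences are
    uppercased; the id is the token before the first whitespace and the rest
    of the header becomes the description. Duplicate ids or illegal
    characters raise; an empty file warns and returns [].
    """
    if molecule not in ("nt", "aa"):
        raise ValueError("molecule must be 'nt' or 'aa'")
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        _check_alphabet(rec.id, seq, molecule)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path) -> List[ReadRecord]:
    """Read 4-line FASTQ (Phred+33) into ReadRecords with integer quals."""
    reads: List[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(ReadRecord(id=rec.id, seq=str(rec.seq).upper(),
                                qual=list(rec.letter_annotations["phred_quality"])))
    return reads


def filter_reads(reads: Sequence[ReadRecord], min_len: int = 40,
                 max_mean_error: float = 0.01, forbid_ambiguous: bool = True,
                 ) -> Tuple[List[ReadRecord], Dict[str, int]]:
    """Whole-read rejection, mirroring a pre-assembly QC step.

    A read is kept iff it is at least min_len bases, contains no N (when
    forbid_ambiguous), and its mean per-base error probability
    (mean of 10**(-Q/10)) is <= max_mean_error. Each discarded read is
    attributed to the first failing rule in the fixed order
    length -> ambiguity -> quality, so the counts are deterministic.
    """
    if min_len <= 0 or max_mean_error <= 0:
        raise ValueError("thresholds must be positive")
    kept: List[ReadRecord] = []
    discarded = {"length": 0, "ambiguous": 0, "quality": 0}
    for read in reads:
        if len(read) < min_len:
            discarded["length"] += 1
        elif forbid_ambiguous and "N" in read.seq:
            discarded["ambiguous"] += 1
        else:
            mean_err = sum(10.0 ** (-q / 10.0) for q in read.qual) / len(read)
            # boundary-inclusive within float tolerance: an all-Q20 read sits
            # exactly at the 0.01 threshold and must be kept
            if mean_err > max_mean_error * (1.0 + 1e-9):
                discarded["quality"] += 1
            else:
                kept.append(read)
    return kept, discarded


def filter_contigs(contigs: Sequence[SequenceRecord], min_len: int = 150
                   ) -> List[SequenceRecord]:
    """Drop assembled contigs shorter than min_len bases; order preserved."""
    return [c for c in contigs if len(c) >= min_len]


# --- BLAST tabular (outfmt-6 dialect) ---------------------------------------
#
# 12 tab-separated columns: query, subject, %identity, alignment length,
# mismatches, gap opens, q.start, q.end, s.start, s.end, e-value, bit score.
# Query coordinates are 1-based inclusive NUCLEOTIDE positions on the forward
# strand of the transcript, with q.start > q.end signalling a reverse-strand
# (negative frame) alignment, exactly as blastx prints them; subject
# coordinates are amino acids. Internally coordinates live in amino-acid
# units on the translated query frame, so parsing converts.


def _frame_and_aa_coords(qs: int, qe: int, qlen: Optional[int]
                         ) -> Tuple[Optional[int], Optional[int], Optional[int]]:
    if qs <= qe:
        frame = (qs - 1) % 3 + 1
        aa_s = (qs - frame) // 3 + 1
        aa_e = (qe - frame + 1) // 3
        return frame, aa_s, aa_e
    if qlen is None:
        return None, None, None  # needs query length; hydrated later
    rs = qlen - qs + 1
    re_ = qlen - qe + 1
    frame = (rs - 1) % 3 + 1
    aa_s = (rs - frame) // 3 + 1
    aa_e = (re_ - frame + 1) // 3
    return -frame, aa_s, aa_e


def read_hit_table(path, query_lengths: Optional[Mapping[str, int]] = None
                   ) -> List[AlignmentHit]:
    """Parse a 12-column BLAST tabular file into AlignmentHits.

    '#' comment lines are skipped. %identity is converted to a fraction.
    Reverse-strand alignments need the query length to recover frame and
    translated-frame coordinates; pass query_lengths (id -> nt length) to
    resolve them at parse time, otherwise such hits carry frame=None until
    hydrated by the census.
    """
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                mism = int(fields[4])
                gapo = int(fields[5])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                ev = float(fields[10])
                bits = float(fields[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparsable numeric field") from None
            qlen = query_lengths.get(qid) if query_lengths else None
            if query_lengths is not None and qlen is None:
                raise ValueError(
                    f"{path}:{lineno}: query {qid!r} missing from "
                    f"query_lengths")
            frame, aa_s, aa_e = _frame_and_aa_coords(qs, qe, qlen)
            q_nongap = (abs(qe - qs) + 1) // 3
            if aa_s is None:
                # unresolved reverse-strand hit: keep nt span, mark frame None
                aa_s, aa_e = min(qs, qe), max(qs, qe)
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid, frame=frame,
                q_aa_start=aa_s, q_aa_end=aa_e,
                s_start=ss, s_end=se, bit_score=bits, e_value=ev,
                identity=pident / 100.0, q_nongap=q_nongap,
                aligned_cols=length, mismatches=mism, gap_opens=gapo,
                q_len_nt=qlen if qlen is not None else 0))
    return hits


def hydrate_hits(hits: Iterable[AlignmentHit],
                 query_lengths: Mapping[str, int]) -> List[AlignmentHit]:
    """Resolve frame and translated-frame coordinates for reverse-strand hits
    parsed without query lengths (frame=None)."""
    out: List[AlignmentHit] = []
    for h in hits:
        if h.frame is not None:
            out.append(h)
            continue
        qlen = query_lengths.get(h.query_id)
        if qlen is None:
            raise ValueError(f"no length known for query {h.query_id!r}")
        # frame None implies q.start > q.end in the file: start was the max
        qs, qe = h.q_aa_end, h.q_aa_start
        frame, aa_s, aa_e = _frame_and_aa_coords(qs, qe, qlen)
        out.append(AlignmentHit(
            query_id=h.query_id, subject_id=h.subject_id, frame=frame,
            q_aa_start=aa_s, q_aa_end=aa_e, s_start=h.s_start,
            s_end=h.s_end, bit_score=h.bit_score, e_value=h.e_value,
            identity=h.identity, q_nongap=h.q_nongap,
            aligned_cols=h.aligned_cols, mismatches=h.mismatches,
            gap_opens=h.gap_opens, q_len_nt=qlen,
            raw_score=h.raw_score))
    return out


def _nt_query_coords(hit: AlignmentHit) -> Tuple[int, int]:
    frame = hit.frame
    if frame is None:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id} has no frame; cannot "
            "write nucleotide coordinates")
    off = abs(frame)
    nt_s = 3 * (hit.q_aa_start - 1) + off
    nt_e = 3 * hit.q_aa_end + off - 1
    if frame > 0:
        return nt_s, nt_e
    if not hit.q_len_nt:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id}: reverse-strand hit "
            "requires q_len_nt")
    return hit.q_len_nt - nt_s + 1, hit.q_len_nt - nt_e + 1


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits in the 12-column tabular dialect read_hit_table parses."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = _nt_query_coords(h)
            fh.write("\t".join([
                h.query_id, h.subject_id,
                f"{h.identity * 100.0:.10g}", str(h.aligned_cols),
                str(h.mismatches), str(h.gap_opens),
                str(qs), str(qe), str(h.s_start), str(h.s_end),
                f"{h.e_value:.10g}", f"{h.bit_score:.10g}",
            ]) + "\n")
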