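"""Synthetic reference proteomes and fragmented transcriptome assemblies with
a complete ground-truth ledger.

The generator emulates the situation the census is built for: a reference
proteome partitioned into named families (one anchor protein per family),
families holding several paralogous genes at controlled amino-acid identity,
and an assembly in which each gene appears as a full-length transcript or as
subject-disjoint fragments, sometimes accompanied by a near-identical isoform
copy, alongside short junk contigs and optional per-base substitution noise.
Every emitted transcript is recorded against its true gene, so census output
can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from . import _sw
from .family_census import ProteinRecord
from .seqio import SequenceRecord
from .translated_search import ScoringScheme, reverse_complement

AA20 = "ARNDCQEGHILKMFPSTWYV"
_CODONS_FOR: Dict[str, List[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)

CLANS = ("CYP2", "Mito", "CYP3", "CYP4")

# fragments must survive the 250-nt census filter with margin
MIN_FRAGMENT_AA = 90
FRAGMENT_GAP_AA = 20
# leading stretch of every non-initial fragment kept methionine-free so a
# downstream fragment can never masquerade as a complete ORF
MET_FREE_PREFIX_AA = 10


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    genes_per_family gives the true gene count of each family; when None,
    counts are drawn uniformly from 1..10 for n_families families.
    isoform_nt_identity is the identity of an emitted isoform to its sibling
    transcript as observed in the assembly, i.e. inclusive of base_error_rate
    noise on both copies.
    """

    seed: int = 0
    n_families: int = 20
    genes_per_family: Optional[List[int]] = None
    protein_length_range: Tuple[int, int] = (220, 320)
    paralog_aa_identity: float = 0.85
    fragment_prob: float = 0.5
    n_fragments: int = 2
    isoform_prob: float = 0.2
    isoform_nt_identity: float = 0.97
    junk_contigs: int = 50
    junk_length_range: Tuple[int, int] = (150, 240)
    base_error_rate: float = 0.0
    superfamily: str = "P450"

    def __post_init__(self) -> None:
        for name in ("paralog_aa_identity", "fragment_prob", "isoform_prob",
                     "isoform_nt_identity", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("protein_length_range", "junk_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name} must be an ordered positive range")
        if self.n_fragments < 2:
            raise ValueError("n_fragments must be >= 2")


@dataclass
class TruthRow:
    transcript_id: str
    true_gene_id: str
    true_family: str
    role: str  # full | fragment_i_of_k | isoform | junk


@dataclass
class SyntheticTruth:
    rows: List[TruthRow]
    family_gene_counts: Dict[str, int]

    def gene_of(self, transcript_id: str) -> Optional[str]:
        for r in self.rows:
            if r.transcript_id == transcript_id:
                return r.true_gene_id if r.role != "junk" else None
        return None


@dataclass
class GeneCds:
    gene_id: str
    family: str
    protein: str  # amino acids incl. leading M, no stop char
    cds: str      # ATG..stop nucleotides


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    proteome: List[ProteinRecord]
    genes: List[GeneCds]
    transcripts: List[SequenceRecord]
    truth: SyntheticTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, len(AA20), size=length - 1)
    return "M" + "".join(AA20[i] for i in body)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [ _CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))]
               for aa in protein ]
    codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    return "".join(codons)


def generate_proteome(config: GeneratorConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> List[ProteinRecord]:
    """One founder protein per family, with family and clan annotation.

    A single reference protein per family keeps the census's top-hit
    assignment unambiguous so the merge logic itself is what gets tested.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    out = []
    for i in range(config.n_families):
        if config.superfamily == "P450":
            family = f"CYP{i + 6}"
            clan = CLANS[i % len(CLANS)]
            desc = f"cytochrome P450 {family} (synthetic reference)"
        else:
            family = f"CathepsinL{i + 1}"
            clan = ""
            desc = f"cathepsin L-like cysteine peptidase {family} (synthetic)"
        length = int(rng.integers(lo, hi + 1))
        out.append(ProteinRecord(id=f"{family}_REF",
                                 seq=_random_protein(rng, length),
                                 family=family, clan=clan, description=desc))
    return out


def _mutate_protein(rng: np.random.Generator, protein: str,
                    identity: float) -> str:
    n_mut = round((1.0 - identity) * len(protein))
    if n_mut == 0:
        return protein
    positions = rng.choice(np.arange(1, len(protein)), size=n_mut,
                           replace=False)
    seq = list(protein)
    for p in positions:
        choices = [a for a in AA20 if a != seq[p]]
        seq[p] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def generate_genes(config: GeneratorConfig,
                   proteome: Sequence[ProteinRecord],
                   rng: Optional[np.random.Generator] = None,
                   scheme: Optional[ScoringScheme] = None) -> List[GeneCds]:
    """True gene set: per family, gene 1 reverse-translates the founder
    exactly; further genes are paralogs mutated to paralog_aa_identity in
    protein space and then reverse-translated with fresh codon choices.

    Each paralog is verified to score best against its own family founder
    under the pipeline's protein scoring; a violating paralog is redrawn
    (up to 100 attempts).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    scheme = scheme or ScoringScheme()
    go_ext = scheme.gap_open + scheme.gap_extend
    founders = {p.family: p for p in proteome}
    founder_codes = [(p.family, scheme.encode(p.seq)) for p in proteome]
    if config.genes_per_family is None:
        counts = [int(rng.integers(1, 11)) for _ in proteome]
    else:
        counts = list(config.genes_per_family)
        if len(counts) != len(proteome):
            raise ValueError("genes_per_family length must match n_families")
    genes: List[GeneCds] = []
    for prot, k in zip(proteome, counts):
        for g in range(1, k + 1):
            if g == 1:
                pep = prot.seq
            else:
                pep = None
                for _ in range(100):
                    cand = _mutate_protein(rng, prot.seq,
                                           config.paralog_aa_identity)
                    code = scheme.encode(cand)
                    own = 0
                    best_other = 0
                    for fam, fcode in founder_codes:
                        s = _sw.sw_score(code, fcode, scheme.matrix, go_ext,
                                         scheme.gap_extend)
                        if fam == prot.family:
                            own = s
                        elif s > best_other:
                            best_other = s
                    if own > best_other:
                        pep = cand
                        break
                if pep is None:
                    raise RuntimeError(
                        f"could not build a paralog of {prot.family} whose "
                        "top hit is its own founder; lower the divergence")
            cds = _reverse_translate(rng, pep)
            genes.append(GeneCds(gene_id=f"{prot.family}.g{g}",
                                 family=prot.family, protein=pep, cds=cds))
    return genes


def _choose_fragments(rng: np.random.Generator, protein: str, k: int
                      ) -> Optional[List[Tuple[int, int]]]:
    """k subject-disjoint amino-acid spans covering the protein ends, with
    gaps >= FRAGMENT_GAP_AA between consecutive spans, every span >=
    MIN_FRAGMENT_AA, and no methionine in the leading stretch of any
    non-initial span (keeps downstream fragments unambiguously truncated)."""
    length = len(protein)
    if length < k * MIN_FRAGMENT_AA + (k - 1) * FRAGMENT_GAP_AA:
        return None
    for _ in range(200):
        # cuts[i] is the subject end of piece i+1; the next piece starts
        # FRAGMENT_GAP_AA residues later
        cuts = []
        prev_start = 1
        feasible = True
        for i in range(k - 1):
            lo = prev_start + MIN_FRAGMENT_AA - 1
            hi = length - (k - 1 - i) * (MIN_FRAGMENT_AA + FRAGMENT_GAP_AA)
            if lo > hi:
                feasible = False
                break
            cut = int(rng.integers(lo, hi + 1))
            cuts.append(cut)
            prev_start = cut + FRAGMENT_GAP_AA + 1
        if not feasible or length - prev_start + 1 < MIN_FRAGMENT_AA:
            continue
        spans = []
        ok = True
        start = 1
        for i in range(k):
            end = cuts[i] if i < k - 1 else length
            if i > 0:
                prefix = protein[start - 1:start - 1 + MET_FREE_PREFIX_AA]
                if "M" in prefix:
                    ok = False
                    break
            spans.append((start, end))
            if i < k - 1:
                start = cuts[i] + FRAGMENT_GAP_AA + 1
        if ok:
            return spans
    return None


def _synonymous_divergence(rng: np.random.Generator, cds: str,
                           target_div: float) -> str:
    """Introduce ~target_div nucleotide divergence by synonymous codon swaps,
    leaving the encoded protein unchanged."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    target = round(target_div * len(cds))
    changed = 0
    order = rng.permutation(len(codons) - 1)  # keep the stop codon
    for idx in order:
        if changed >= target:
            break
        codon = codons[idx]
        aa = standard_dna_table.forward_table.get(codon)
        if aa is None:
            continue
        alts = [c for c in _CODONS_FOR[aa] if c != codon]
        if not alts:
            continue
        alt = alts[rng.integers(0, len(alts))]
        changed += sum(1 for a, b in zip(codon, alt) if a != b)
        codons[idx] = alt
    return "".join(codons)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(arr), size=n_err, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_transcripts(config: GeneratorConfig, genes: Sequence[GeneCds],
                         rng: Optional[np.random.Generator] = None,
                         ) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """Emit the synthetic assembly: per gene a full-length transcript or
    subject-disjoint fragments, optional isoform copies, junk contigs, point
    errors and random strand orientation."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    transcripts: List[SequenceRecord] = []
    rows: List[TruthRow] = []
    counter = 0

    def emit(seq: str, gene: Optional[GeneCds], role: str) -> None:
        nonlocal counter
        counter += 1
        tid = f"contig{counter:05d}"
        seq = _apply_errors(rng, seq, config.base_error_rate)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        transcripts.append(SequenceRecord(id=tid, seq=seq))
        rows.append(TruthRow(
            transcript_id=tid,
            true_gene_id=gene.gene_id if gene else "",
            true_family=gene.family if gene else "",
            role=role))

    for gene in genes:
        emitted_clean: List[Tuple[str, str]] = []  # (seq pre-error, role)
        spans = None
        if rng.random() < config.fragment_prob:
            spans = _choose_fragments(rng, gene.protein, config.n_fragments)
            if spans is None:
                warnings.warn(
                    f"{gene.gene_id}: no valid {config.n_fragments}-piece "
                    "fragmentation (protein too short or no methionine-free "
                    "cut found); emitting full-length")
        if spans is None:
            emitted_clean.append((gene.cds, "full"))
        else:
            k = len(spans)
            for i, (s, e) in enumerate(spans, start=1):
                nt = gene.cds[(s - 1) * 3: e * 3 + (3 if e == len(gene.protein) else 0)]
                emitted_clean.append((nt, f"fragment_{i}_of_{k}"))
        for seq, role in emitted_clean:
            emit(seq, gene, role)
        if rng.random() < config.isoform_prob:
            src, _ = emitted_clean[rng.integers(0, len(emitted_clean))]
            div = max(0.0, (1.0 - config.isoform_nt_identity)
                      - 2.0 * config.base_error_rate)
            iso = _synonymous_divergence(rng, src, div) if len(src) % 3 == 0 \
                else src
            emit(iso, gene, "isoform")

    lo, hi = config.junk_length_range
    for _ in range(config.junk_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        emit(seq, None, "junk")

    order = rng.permutation(len(transcripts))
    transcripts = [transcripts[i] for i in order]
    rows = [rows[i] for i in order]

    fam_counts: Dict[str, int] = {}
    for gene in genes:
        fam_counts[gene.family] = fam_counts.get(gene.family, 0) + 1
    return transcripts, SyntheticTruth(rows=rows,
                                       family_gene_counts=fam_counts)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Full dataset: proteome, true genes, transcripts and truth ledger,
    deterministic under (seed, config)."""
    proteome = generate_proteome(config)
    genes = generate_genes(config, proteome)
    transcripts, truth = generate_transcripts(config, genes)
    return SyntheticDataset(config=config, proteome=proteome, genes=genes,
                            transcripts=transcripts, truth=truth)


@dataclass
class RecoveryReport:
    per_family: List[Tuple[str, int, int, bool]]  # family, true, est, exact
    exact_match_fraction: float
    cluster_purity: float


def score_recovery(result, truth: SyntheticTruth) -> RecoveryReport:
    """Compare census output against generator truth.

    Exactness is per family (estimated minimum gene count == true count);
    purity is the fraction of isoform clusters whose member transcripts all
    descend from one true gene.
    """
    est = {fc.family: fc.gene_count for fc in result.family_counts}
    for fam in est:
        if fam not in truth.family_gene_counts:
            raise KeyError(f"family {fam!r} in census but not in truth")
    gene_by_tid = {r.transcript_id: r.true_gene_id for r in truth.rows
                   if r.role != "junk"}
    per_family = []
    for fam in sorted(truth.family_gene_counts):
        t = truth.family_gene_counts[fam]
        e = est.get(fam, 0)
        per_family.append((fam, t, e, t == e))
    frac = (sum(1 for *_, ok in per_family if ok) / len(per_family)
            if per_family else float("nan"))
    n_pure = 0
    clusters = result.clusters
    for c in clusters:
        members = {gene_by_tid.get(t, f"__junk__{t}")
                   for t in c.member_transcripts}
        if len(members) == 1:
            n_pure += 1
    purity = n_pure / len(clusters) if clusters else float("nan")
    return RecoveryReport(per_family=per_family, exact_match_fraction=frac,
                          cluster_purity=purity)
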