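"""Synthetic-data engine: reference, reads, spike-ins, mock callers, truth.

Every stage of the pipeline is testable without external data through this
module.  It builds a small reference genome with valid ORFs and planted
repeat tracts, simulates aligned reads with sequencing error and germline
variants, injects somatic variants into the reads at controlled target VAFs
(the spike-in), fabricates external-caller call sets with configurable
sensitivity profiles, and scores call sets against the spike-in truth.

Spike-in semantics mirror read-level mutation engines: each read overlapping
a target site is independently converted to the alternate allele with
probability equal to the target VAF, so realized VAFs scatter binomially
around the target and sit below it at low depth — the behaviour observed
with real spike-in data.  A site whose depth is below the minimum ``m``
(default 2) is skipped and recorded as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .feature_annot import (
    CLASS_LABELS,
    GeneModel,
    INDEL_FEATURES,
    SNV_FEATURES,
    Transcript,
)
from .variant_model import (
    GenomicVariant,
    ReferenceWindow,
    VariantType,
    left_normalize,
)
from .vartracker import CallRecord, PileupConfig, pileup_sites

__all__ = [
    "SimReference",
    "SpikeInSpec",
    "MockCallerProfile",
    "make_reference",
    "simulate_reads",
    "write_sam",
    "read_sam",
    "spike_in",
    "vaf_series",
    "chip_vaf_targets",
    "verify_spikein",
    "mock_caller",
    "spikein_recall_precision",
    "synthetic_feature_table",
    "MUTECT_LIKE",
    "VARDICT_LIKE",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: gene names drawn from recurrently mutated leukemia drivers, so privileged-
#: gene logic can be exercised on simulated data
_GENE_NAMES = ("DNMT3A", "TET2", "ASXL1", "PPM1D", "JAK2", "TP53", "SF3B1", "CREBBP")


# --------------------------------------------------------------------------
# reference
# --------------------------------------------------------------------------

@dataclass
class SimReference:
    """A simulated genome: sequences, transcript model, target regions."""

    seqs: dict[str, str]
    gene_model: GeneModel
    regions: list[tuple[str, int, int]]  # BED-style, 0-based half-open

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.regions:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    def cds_sites(self) -> list[tuple[str, int, str]]:
        """(gene, 1-based position, ref base) for every coding base."""
        out = []
        for t in self.gene_model.transcripts:
            for p in t.cds_positions():
                out.append((t.gene, p, self.seqs[t.chrom][p - 1]))
        return out


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n codons avoiding stop codons, with approximate GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(_BASES, size=3, p=p))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_reference(
    n_genes: int = 6,
    gene_len: int = 300,
    gc: float = 0.5,
    seed: int = 0,
    intergenic: int = 120,
    intron_gene_index: int = 1,
    minus_strand_index: int = 2,
) -> SimReference:
    """Build a deterministic single-contig genome with ``n_genes`` valid ORFs.

    Each gene is an ATG...stop ORF of ~``gene_len`` bp free of internal stop
    codons.  One gene carries a 90-bp intron (two-exon transcript), one is on
    the minus strand, and homopolymer (>= 8 bp) and short-tandem-repeat
    tracts are planted both inside one CDS (codon-aligned, stop-free) and in
    intergenic sequence so context features have signal.
    """
    if n_genes < 1 or gene_len < 30 or not 0 < gc < 1:
        raise ValueError("infeasible reference parameters")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    parts: list[str] = []
    transcripts: list[Transcript] = []
    cursor = 0  # 0-based

    def _pad(n: int) -> None:
        nonlocal cursor
        parts.append(_random_seq(rng, n, gc))
        cursor += n

    _pad(intergenic)
    # plant intergenic repeat tracts
    parts.append("A" * 9 + _random_seq(rng, 5, gc) + "AGC" * 4)
    cursor += 9 + 5 + 12
    _pad(intergenic // 2)

    n_codons = max(4, gene_len // 3)
    for gi in range(n_genes):
        name = _GENE_NAMES[gi % len(_GENE_NAMES)]
        body = _random_codons(rng, n_codons - 2, gc)
        if gi == min(n_genes - 1, 3):
            # codon-aligned repeat tracts inside this CDS: AAA-codon run
            # (lysine) and ACx tandem (Thr/His alternation); both stop-free
            body = "AAA" * 3 + "ACACAC" * 2 + body[21:]
        orf = "ATG" + body + "TAA"
        strand = "-" if gi == minus_strand_index and n_genes > 2 else "+"
        genomic = str(Seq(orf).reverse_complement()) if strand == "-" else orf

        if gi == intron_gene_index and n_genes > 1:
            # split after a codon boundary; 90 bp intron
            cut = (len(genomic) // 2 // 3) * 3
            intron = _random_seq(rng, 90, gc)
            exon1 = genomic[:cut]
            exon2 = genomic[cut:]
            start1 = cursor + 1
            end1 = cursor + len(exon1)
            start2 = end1 + len(intron) + 1
            end2 = start2 + len(exon2) - 1
            parts.append(exon1 + intron + exon2)
            cursor = end2
            exons = ((start1, end1), (start2, end2))
            cds_start, cds_end = start1, end2
        else:
            start = cursor + 1
            end = cursor + len(genomic)
            parts.append(genomic)
            cursor = end
            exons = ((start, end),)
            cds_start, cds_end = start, end
        transcripts.append(
            Transcript(
                name=f"{name}_t1",
                gene=name,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        _pad(intergenic)

    seq = "".join(parts)
    gm = GeneModel(transcripts)
    regions = [
        (chrom, t.start - 1 - 20, min(len(seq), t.end + 20)) for t in transcripts
    ]
    return SimReference(seqs={chrom: seq}, gene_model=gm, regions=regions)


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def _make_read(
    name: str,
    chrom: str,
    start0: int,
    seq: str,
    quals: Sequence[int],
    reverse: bool,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 16 if reverse else 0
    a.reference_id = header.get_tid(chrom)
    a.reference_start = start0
    a.mapping_quality = 60
    a.cigartuples = [(0, len(seq))]
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    return a


def _header_for(ref: SimReference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": L} for c, L in ref.contig_lengths().items()
            ],
        }
    )


def simulate_reads(
    ref: SimReference,
    mean_depth: float = 100.0,
    read_len: int = 100,
    err_rate: float = 0.001,
    seed: int = 0,
    n_het: int = 3,
    n_hom: int = 2,
    base_quality: int = 35,
) -> tuple[list[pysam.AlignedSegment], list[tuple[GenomicVariant, str]]]:
    """Uniform-coverage single-end reads plus planted germline variants.

    Germline heterozygous/homozygous SNVs are planted in coding sequence by
    converting reads with per-read probability 0.5 / 1.0 (the same machinery
    as the somatic spike-in), giving the expected ~50%/100% VAFs.  Returns
    coordinate-sorted reads and the germline truth list.
    """
    rng = np.random.default_rng(seed)
    header = _header_for(ref)
    reads: list[pysam.AlignedSegment] = []
    for chrom, seq in ref.seqs.items():
        L = len(seq)
        n_reads = int(round(mean_depth * L / read_len))
        starts = np.sort(rng.integers(0, max(1, L - read_len), size=n_reads))
        for i, s in enumerate(starts):
            frag = list(seq[s : s + read_len])
            errs = np.nonzero(rng.random(len(frag)) < err_rate)[0]
            for e in errs:
                frag[e] = rng.choice(_BASES[_BASES != frag[e]])
            reads.append(
                _make_read(
                    f"r{chrom}_{i}",
                    chrom,
                    int(s),
                    "".join(frag),
                    [base_quality] * len(frag),
                    bool(rng.random() < 0.5),
                    header,
                )
            )

    # plant germline variants through the conversion machinery
    germline: list[tuple[GenomicVariant, str]] = []
    cds = ref.cds_sites()
    if cds and (n_het or n_hom):
        picks = rng.choice(len(cds), size=min(len(cds), n_het + n_hom), replace=False)
        for j, pick in enumerate(picks):
            _, pos, base = cds[int(pick)]
            alt = str(rng.choice(_BASES[_BASES != base]))
            chrom = ref.gene_model.transcripts[0].chrom
            v = GenomicVariant(chrom, pos, base, alt)
            zygosity = "het" if j < n_het else "hom"
            vaf = 0.5 if zygosity == "het" else 1.0
            for read in reads:
                if _covers(read, v) and rng.random() < vaf:
                    _convert_read(read, v, ref.seqs[chrom])
            germline.append((v, zygosity))
    reads.sort(key=lambda r: (r.reference_id, r.reference_start))
    return reads, germline


def write_sam(reads: Sequence[pysam.AlignedSegment], ref: SimReference, path: str) -> None:
    """Write reads as coordinate-sorted SAM."""
    header = _header_for(ref)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in sorted(reads, key=lambda x: (x.reference_id, x.reference_start)):
            fh.write(r)


def read_sam(path: str) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return list(fh)


# --------------------------------------------------------------------------
# spike-in
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeInSpec:
    """One requested somatic spike: variant, target VAF, minimum depth m."""

    variant: GenomicVariant
    target_vaf: float
    min_depth: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.target_vaf <= 1:
            raise ValueError(f"target_vaf {self.target_vaf} outside (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def _covers(read: pysam.AlignedSegment, v: GenomicVariant) -> bool:
    """Read fully spans the variant's reference footprint (0-based exclusive
    end ``pos-1+len(ref)``; for insertions the anchor base plus one)."""
    if v.vtype is VariantType.INS:
        span_end = v.pos + 1
    elif v.vtype is VariantType.DEL:
        # need a matched base beyond the deleted run so the gap stays internal
        span_end = v.pos - 1 + len(v.ref) + 1
    else:
        span_end = v.pos - 1 + len(v.ref)
    return read.reference_start <= v.pos - 1 and read.reference_end >= span_end


def _columns(read: pysam.AlignedSegment) -> list[list]:
    """Alignment as editable columns [op, qidx, rpos] (op in M/I/D)."""
    cols = []
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):
            for k in range(length):
                cols.append(["M", qpos + k, rpos + k])
            qpos += length
            rpos += length
        elif op == 1:
            for k in range(length):
                cols.append(["I", qpos + k, None])
            qpos += length
        elif op == 2:
            for k in range(length):
                cols.append(["D", None, rpos + k])
            rpos += length
        elif op == 4:
            for k in range(length):
                cols.append(["S", qpos + k, None])
            qpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op} in simulated read")
    return cols


_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def _convert_read(read: pysam.AlignedSegment, v: GenomicVariant, refseq: str) -> bool:
    """Rewrite one read to carry ``v``; returns False if not applicable.

    Base qualities are preserved (inserted bases copy the anchor quality).
    """
    cols = _columns(read)
    seq = read.query_sequence
    quals = list(read.query_qualities)

    def col_at(rp: int):
        for c in cols:
            if c[2] == rp:
                return c
        return None

    anchor = col_at(v.pos - 1)
    if anchor is None or anchor[0] != "M":
        return False

    new_cols: list[tuple[str, str | None, int | None, int]] = []
    if v.vtype is VariantType.SNV:
        for op, qi, rp in cols:
            base = seq[qi] if qi is not None else None
            q = quals[qi] if qi is not None else 0
            if rp == v.pos - 1 and op == "M":
                base = v.alt
            new_cols.append((op, base, rp, q))
    elif v.vtype is VariantType.DEL:
        del_span = set(range(v.pos, v.pos + len(v.ref) - 1))  # 0-based deleted bases
        for op, qi, rp in cols:
            base = seq[qi] if qi is not None else None
            q = quals[qi] if qi is not None else 0
            if rp is not None and rp in del_span and op == "M":
                new_cols.append(("D", None, rp, 0))
            else:
                new_cols.append((op, base, rp, q))
    else:  # INS after the anchor base
        aq = quals[anchor[1]]
        for op, qi, rp in cols:
            base = seq[qi] if qi is not None else None
            q = quals[qi] if qi is not None else 0
            new_cols.append((op, base, rp, q))
            if rp == v.pos - 1 and op == "M":
                for b in v.alt[1:]:
                    new_cols.append(("I", b, None, aq))

    new_seq, new_quals, ops = [], [], []
    for op, base, rp, q in new_cols:
        if op in ("M", "I", "S"):
            new_seq.append(base)
            new_quals.append(q)
        ops.append(op)
    # compress ops to CIGAR
    cig: list[tuple[int, int]] = []
    for op in ops:
        code = _OP_CODE[op]
        if cig and cig[-1][0] == code:
            cig[-1] = (code, cig[-1][1] + 1)
        else:
            cig.append((code, 1))
    # trim leading/trailing deletions (cannot start or end an alignment)
    while cig and cig[0][0] == 2:
        cig.pop(0)
    while cig and cig[-1][0] == 2:
        cig.pop()
    read.query_sequence = "".join(new_seq)
    read.cigartuples = cig
    read.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in new_quals)
    )
    return True


def spike_in(
    reads: Sequence[pysam.AlignedSegment],
    specs: Sequence[SpikeInSpec],
    ref: SimReference,
    seed: int = 0,
) -> tuple[list[pysam.AlignedSegment], pd.DataFrame]:
    """Inject somatic variants into reads; return mutated reads + truth table.

    Each read fully spanning a spec's site is converted independently with
    probability ``target_vaf``.  Sites with position depth below the spec's
    ``min_depth`` are skipped with reason ``depth_below_m``; REF mismatches
    against the reference are recorded as failures and the run continues.

    The truth table records, per spec: whether it was spiked, reads
    converted, realized depth and VAF, and the left-normalized position used
    for position-based truth matching.
    """
    rng = np.random.default_rng(seed)
    reads = [r.__copy__() if hasattr(r, "__copy__") else r for r in reads]
    rows = []
    for spec in specs:
        v = spec.variant
        seq = ref.seqs.get(v.chrom)
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "target_vaf": spec.target_vaf,
            "spiked": False,
            "reason": "",
            "reads_converted": 0,
            "realized_depth": 0,
            "realized_vaf": 0.0,
            "norm_pos": v.pos,
        }
        if seq is None or seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
            row["reason"] = "ref_mismatch"
            rows.append(row)
            continue
        window = ReferenceWindow(
            v.chrom, max(1, v.pos - 50), seq[max(0, v.pos - 51) : v.end + 50]
        )
        row["norm_pos"] = left_normalize(v, window).pos

        depth = sum(
            1 for r in reads if r.reference_start <= v.pos - 1 < r.reference_end
        )
        row["realized_depth"] = depth
        if depth < spec.min_depth:
            row["reason"] = "depth_below_m"
            rows.append(row)
            continue
        converted = 0
        for r in reads:
            if _covers(r, v) and rng.random() < spec.target_vaf:
                if _convert_read(r, v, seq):
                    converted += 1
        row["spiked"] = converted >= 1
        if converted == 0:
            row["reason"] = "no_read_converted"
        row["reads_converted"] = converted
        row["realized_vaf"] = converted / depth if depth else 0.0
        rows.append(row)
    reads.sort(key=lambda r: (r.reference_id, r.reference_start))
    truth = pd.DataFrame(rows)
    return reads, truth


def functional_snv_specs(
    ref: SimReference,
    n: int,
    target_vafs,
    seed: int = 0,
    min_depth: int = 2,
) -> list[SpikeInSpec]:
    """Pick ``n`` coding SNVs with functional consequences as spike targets.

    Mirrors how known CHIP mutations distribute: protein-altering changes in
    driver genes.  Positions are unique; alt bases are chosen so the change
    is not synonymous.
    """
    from .feature_annot import FUNCTIONAL_CONSEQUENCES, classify_consequence

    rng = np.random.default_rng(seed)
    target_vafs = np.broadcast_to(np.asarray(target_vafs, dtype=float), (n,))
    cds = ref.cds_sites()
    order = rng.permutation(len(cds))
    specs: list[SpikeInSpec] = []
    used: set[int] = set()
    for idx in order:
        if len(specs) == n:
            break
        _, pos, base = cds[int(idx)]
        if pos in used:
            continue
        chrom = next(iter(ref.seqs))
        for alt in rng.permutation(_BASES[_BASES != base]):
            v = GenomicVariant(chrom, pos, base, str(alt))
            if (
                classify_consequence(v, ref.gene_model, ref.seqs)
                in FUNCTIONAL_CONSEQUENCES
            ):
                specs.append(
                    SpikeInSpec(v, float(target_vafs[len(specs)]), min_depth)
                )
                used.add(pos)
                break
    if len(specs) < n:
        raise ValueError(f"only found {len(specs)} functional sites, wanted {n}")
    return specs


def vaf_series() -> list[float]:
    """The 13 uniform spike-in VAF levels: 0.5%, 1%..10% by 1%, 20%, 30%."""
    return [0.005] + [i / 100 for i in range(1, 11)] + [0.20, 0.30]


def chip_vaf_targets(
    n: int, variant_type: str = "SNV", seed: int = 0
) -> np.ndarray:
    """Empirical-style CHIP VAF targets: log-normal, median 12.5% for SNVs
    and 14.8% for INDELs, clipped to (0.5%, 95%]."""
    rng = np.random.default_rng(seed)
    median = 0.125 if variant_type == "SNV" else 0.148
    draws = np.exp(rng.normal(math.log(median), 0.7, size=n))
    return np.clip(draws, 0.005, 0.95)


def verify_spikein(
    reads: Sequence[pysam.AlignedSegment],
    truth: pd.DataFrame,
    ref: SimReference,
    cfg: PileupConfig | None = None,
) -> pd.DataFrame:
    """Re-pileup the mutated reads at each truth site and report observed
    alt evidence; flags any spiked-but-unobservable record as a defect."""
    cfg = cfg or PileupConfig()
    sites = {
        (s.chrom, s.pos): s for s in pileup_sites(list(reads), ref.seqs, cfg=cfg)
    }
    out = truth.copy()
    observed_counts, observed_vafs, defects = [], [], []
    for _, row in out.iterrows():
        site = sites.get((row["chrom"], int(row["pos"])))
        count = sum(site.allele_counts.values()) if site else 0
        depth = site.depth if site else 0
        observed_counts.append(count)
        observed_vafs.append(count / depth if depth else 0.0)
        defects.append(bool(row["spiked"]) and count == 0)
    out["observed_alt_count"] = observed_counts
    out["observed_vaf"] = observed_vafs
    out["defect"] = defects
    return out


# --------------------------------------------------------------------------
# mock external callers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MockCallerProfile:
    """Detection behaviour of a simulated external caller.

    ``sensitivity``: ordered (vaf_upper_bound, detection probability) bins;
    a variant's realized VAF selects the first bin whose bound exceeds it.
    """

    name: str
    sensitivity: tuple[tuple[float, float], ...]
    min_alt_reads: int = 2
    fp_per_mb: float = 2.0

    def detection_prob(self, vaf: float) -> float:
        for bound, p in self.sensitivity:
            if vaf <= bound:
                return p
        return self.sensitivity[-1][1]


#: assembly-based caller archetype: precise but weak below 10% VAF
MUTECT_LIKE = MockCallerProfile(
    "CALLER_B", ((0.02, 0.02), (0.05, 0.05), (0.10, 0.10), (1.0, 0.85)), 2, 0.5
)
#: heuristic caller archetype: sensitive at moderate VAFs
VARDICT_LIKE = MockCallerProfile(
    "CALLER_A", ((0.02, 0.30), (0.05, 0.60), (0.10, 0.80), (1.0, 0.95)), 2, 2.0
)


def mock_caller(
    truth: pd.DataFrame,
    profile: MockCallerProfile,
    ref: SimReference,
    seed: int = 0,
    germline: Sequence[tuple[GenomicVariant, str]] = (),
    typical_depth: int = 100,
) -> list[CallRecord]:
    """Fabricate a caller's output from the spike-in truth.

    Spiked variants are detected with the profile's VAF-binned probability,
    subject to its minimum supporting-read threshold; germline variants are
    always reported (all callers find them reliably); false positives are
    placed uniformly over target regions at ``fp_per_mb``.
    """
    rng = np.random.default_rng(seed)
    calls: list[CallRecord] = []
    for _, row in truth.iterrows():
        if not row["spiked"]:
            continue
        if int(row["reads_converted"]) < profile.min_alt_reads:
            continue
        if rng.random() < profile.detection_prob(float(row["realized_vaf"])):
            calls.append(
                CallRecord(
                    variant=GenomicVariant(
                        row["chrom"], int(row["pos"]), row["ref"], row["alt"]
                    ),
                    caller_id=profile.name,
                    alt_count=int(row["reads_converted"]),
                    depth=int(row["realized_depth"]),
                )
            )
    for v, zygosity in germline:
        exp_vaf = 0.5 if zygosity == "het" else 1.0
        alt = max(1, int(rng.binomial(typical_depth, exp_vaf)))
        calls.append(
            CallRecord(
                variant=v,
                caller_id=profile.name,
                alt_count=alt,
                depth=max(alt, typical_depth),
            )
        )
    covered = sum(e - s for _, s, e in ref.regions)
    n_fp = rng.poisson(profile.fp_per_mb * covered / 1e6)
    truth_pos = set(zip(truth["chrom"], truth["pos"]))
    for _ in range(n_fp):
        chrom, s, e = ref.regions[int(rng.integers(len(ref.regions)))]
        pos = int(rng.integers(s + 1, e + 1))
        if (chrom, pos) in truth_pos:
            continue
        base = ref.seqs[chrom][pos - 1]
        if base == "N":
            continue
        alt = str(rng.choice(_BASES[_BASES != base]))
        calls.append(
            CallRecord(
                variant=GenomicVariant(chrom, pos, base, alt),
                caller_id=profile.name,
                alt_count=int(rng.integers(profile.min_alt_reads, profile.min_alt_reads + 3)),
                depth=typical_depth,
            )
        )
    return calls


def spikein_recall_precision(calls, truth: pd.DataFrame) -> tuple[float, float]:
    """Score a call set against the spike-in truth, position-only matching.

    A truth variant counts as recovered if any call occupies its pre-placed
    (or left-normalized) position, regardless of the alternate allele; calls
    at non-truth positions are false positives.  Only successfully spiked
    truths enter the denominator.
    """
    spiked = truth[truth["spiked"]]
    truth_positions: set[tuple[str, int]] = set()
    for _, row in spiked.iterrows():
        truth_positions.add((row["chrom"], int(row["pos"])))
        truth_positions.add((row["chrom"], int(row["norm_pos"])))

    call_positions = set()
    for c in calls:
        v = getattr(c, "variant", c)
        call_positions.add((v.chrom, v.pos))

    recovered = 0
    for _, row in spiked.iterrows():
        hits = {(row["chrom"], int(row["pos"])), (row["chrom"], int(row["norm_pos"]))}
        if hits & call_positions:
            recovered += 1
    n_truth = len(spiked)
    false_pos = len(call_positions - truth_positions)
    recall = recovered / n_truth if n_truth else float("nan")
    denom = recovered + false_pos
    precision = recovered / denom if denom else float("nan")
    return recall, precision


# --------------------------------------------------------------------------
# synthetic feature tables (desk-scale classifier training data)
# --------------------------------------------------------------------------

def synthetic_feature_table(
    n: int = 3000,
    class_fractions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    separation: float = 1.0,
    seed: int = 1,
    variant_type: str = "SNV",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Labeled feature vectors with controllable class separation.

    Each row's features are drawn from the generator of an *effective*
    class: with probability ``separation`` the true label's generator, else
    a uniformly random class.  At separation 0 features carry no label
    information (holdout accuracy ~ the largest class fraction); at 1 the
    class archetypes are fully expressed:

    - CHIP: low VAF (typically 2-30%), multi-caller status, clean context,
      frequent somatic-catalogue membership, zero germline MAF;
    - GERMLINE: VAF near 0.5 or 1.0, population MAF present, full status;
    - ARTIFACT: single-caller status, one or two supporting reads, low
      mapping/base quality, repeat-context flags.
    """
    if abs(sum(class_fractions) - 1) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n)) for f in class_fractions]
    counts[-1] = n - sum(counts[:-1])
    labels = np.repeat(CLASS_LABELS, counts)

    rows = []
    for lab in labels:
        eff = lab if rng.random() < separation else CLASS_LABELS[rng.integers(3)]
        rows.append(_draw_row(eff, rng, variant_type))
    names = SNV_FEATURES if variant_type == "SNV" else INDEL_FEATURES
    X = pd.DataFrame(rows, columns=list(names))
    perm = rng.permutation(n)
    return X.iloc[perm].reset_index(drop=True), labels[perm]


def _draw_row(cls: str, rng: np.random.Generator, variant_type: str) -> dict:
    depth = int(rng.poisson(100)) + 1
    if cls == "CHIP":
        status = int(rng.choice([1, 2, 3], p=[0.10, 0.35, 0.55]))
        vaf = float(np.clip(rng.beta(2.5, 18), 0.02, 0.45))
        mapq, baseq = rng.normal(58, 2), rng.normal(34, 1.5)
        sb = rng.exponential(3)
        spans, rpos = rng.random() < 0.05, rng.normal(0.5, 0.08)
        hp = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        in_str, in_lc = rng.random() < 0.03, rng.random() < 0.03
        mafs = [0.0, 0.0, 0.0, 0.0]
        cosmic = int(rng.random() < 0.7)
        cfreq = float(cosmic * (1 + rng.geometric(0.05)))
        conseq = int(rng.choice([3, 6, 7, 8], p=[0.45, 0.1, 0.2, 0.25]))
    elif cls == "GERMLINE":
        status = int(rng.choice([2, 3], p=[0.15, 0.85]))
        vaf = float(
            np.clip(
                rng.normal(0.5, 0.04) if rng.random() < 0.85 else rng.normal(0.98, 0.01),
                0.05,
                1.0,
            )
        )
        mapq, baseq = rng.normal(58, 2), rng.normal(34, 1.5)
        sb = rng.exponential(3)
        spans, rpos = rng.random() < 0.05, rng.normal(0.5, 0.08)
        hp = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        in_str, in_lc = rng.random() < 0.03, rng.random() < 0.03
        mafs = [
            float(rng.uniform(0.005, 0.5)) if rng.random() < 0.9 else 0.0
            for _ in range(4)
        ]
        cosmic = int(rng.random() < 0.05)
        cfreq = float(cosmic * (1 + rng.geometric(0.3)))
        conseq = int(rng.choice([1, 3], p=[0.3, 0.7]))
    else:  # ARTIFACT
        status = 1
        vaf = float(np.clip(rng.beta(1.2, 60), 1.0 / depth, 0.15))
        if rng.random() < 0.5:
            # sequencing-noise singleton on otherwise clean alignments
            mapq, baseq = rng.normal(58, 2), rng.normal(33, 2)
        else:
            # alignment-shadow artifact in messy context
            mapq, baseq = rng.normal(32, 8), rng.normal(19, 4)
        sb = rng.exponential(15)
        spans, rpos = rng.random() < 0.4, float(np.clip(rng.beta(0.4, 0.4), 0, 1))
        hp = int(rng.choice([1, 3, 5, 6, 8], p=[0.15, 0.2, 0.3, 0.2, 0.15]))
        in_str, in_lc = rng.random() < 0.45, rng.random() < 0.35
        mafs = [0.0, 0.0, 0.0, 0.0]
        cosmic = int(rng.random() < 0.02)
        cfreq = float(cosmic)
        conseq = int(rng.choice([3, 8], p=[0.6, 0.4]))

    alt = max(1, int(round(vaf * depth)))
    vaf = alt / depth
    callers = {"called_by_tracker": 1.0, "called_by_caller_a": 0.0, "called_by_caller_b": 0.0}
    if status >= 2:
        first = "called_by_caller_a" if rng.random() < 0.6 else "called_by_caller_b"
        callers[first] = 1.0
    if status == 3:
        callers["called_by_caller_a"] = callers["called_by_caller_b"] = 1.0

    row = {
        "status_meta": float(status),
        **callers,
        "depth": float(depth),
        "alt_count": float(alt),
        "vaf": vaf,
        "mean_mapq_alt": float(np.clip(mapq, 0, 60)),
        "mean_baseq_alt": float(np.clip(baseq, 2, 40)),
        "strand_bias_phred": float(min(sb, 200.0)),
        "spans_indel": float(spans),
        "homopolymer_len": float(hp),
        "in_str": float(in_str),
        "in_low_complexity": float(in_lc),
        "gc_content_101bp": float(np.clip(rng.normal(0.5, 0.06), 0, 1)),
        "maf_db1": mafs[0],
        "maf_db2": mafs[1],
        "maf_db3": mafs[2],
        "maf_db4": mafs[3],
        "max_germline_maf": max(mafs),
        "cosmic_match": float(cosmic),
        "cosmic_freq": cfreq,
        "consequence_class": float(conseq),
    }
    if variant_type == "SNV":
        row["mean_read_pos_fraction"] = float(np.clip(rpos, 0, 1))
        row["is_transition"] = float(rng.random() < 0.6)
        row["base_change_class"] = float(rng.integers(6))
    else:
        length = int(rng.choice([-9, -6, -3, -2, -1, 1, 2, 3, 6, 9]))
        row["indel_length"] = float(length)
    return row
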