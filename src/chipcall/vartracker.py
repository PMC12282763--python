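"""Permissive single-sample variant tracker.

Scans coordinate-sorted alignments for *any* alternative-allele evidence —
down to a single supporting read — and reports candidate sites with the
read-level attributes the downstream classifier needs (supporting-read
counts, strand split, mapping/base quality of the alt reads, proximity to
indels, relative position within the read).  Sensitivity, not precision, is
the goal: the classifier and cohort filters remove the noise later.

The engine is a single pass over reads.  Base observations below the
base-quality floor (default Phred 13) are not counted; at most ``depth_cap``
reads are tallied per position (first-come in stream order, default 1000);
duplicate/secondary/supplementary/QC-fail reads are excluded.  Indel alleles
are taken from the CIGAR, anchored at the preceding reference base in the
VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

from .variant_model import GenomicVariant

__all__ = [
    "PileupConfig",
    "PileupSite",
    "CallRecord",
    "pileup_sites",
    "genotype_candidates",
    "resolve_multiallelic",
    "UnsortedInputError",
]

#: indel anywhere within this many bp marks a site as indel-spanning
SPANS_INDEL_WINDOW = 5


class UnsortedInputError(ValueError):
    """Input alignments are not coordinate-sorted."""


@dataclass(frozen=True)
class PileupConfig:
    """Tallying thresholds for the tracker.

    ``min_base_quality`` mirrors the conventional mpileup floor of Phred 13;
    ``depth_cap`` bounds the per-position tally in read-dense regions
    (default 1000); ``min_mapq`` is 0 by default — the tracker is permissive
    and leaves mapping-quality judgement to the classifier.
    """

    min_base_quality: int = 13
    depth_cap: int = 1000
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")
        if self.depth_cap < 1:
            raise ValueError("depth_cap must be >= 1")


@dataclass
class _AlleleStats:
    count: int = 0
    fwd: int = 0
    mapq_sum: float = 0.0
    baseq_sum: float = 0.0
    read_pos_sum: float = 0.0


@dataclass
class PileupSite:
    """Per-position evidence summary at a site with alternative alleles.

    Allele keys: an SNV allele is its base (``"G"``); an insertion is
    ``"+SEQ"`` (inserted bases); a deletion is ``"-SEQ"`` (deleted bases).
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    allele_counts: dict[str, int]
    allele_fwd_counts: dict[str, int]
    mean_mapq_alt: float
    mean_baseq_alt: float
    spans_indel: bool
    mean_read_pos_fraction: float

    def top_allele(self) -> str:
        """Max-count allele; deterministic alphabetical tie-break (use
        :func:`resolve_multiallelic` for the seeded-random tie rule)."""
        return max(sorted(self.allele_counts), key=lambda a: self.allele_counts[a])

    def variant_for(self, allele: str, ref_seqs: Mapping[str, str]) -> GenomicVariant:
        """VCF-convention variant for one of this site's alleles."""
        seq = ref_seqs[self.chrom]
        if allele.startswith("+"):
            anchor = seq[self.pos - 1]
            return GenomicVariant(self.chrom, self.pos, anchor, anchor + allele[1:])
        if allele.startswith("-"):
            deleted = allele[1:]
            anchor = seq[self.pos - 1]
            return GenomicVariant(self.chrom, self.pos, anchor + deleted, anchor)
        return GenomicVariant(self.chrom, self.pos, self.ref_base, allele)


@dataclass
class CallRecord:
    """One caller's evidence for one variant."""

    variant: GenomicVariant
    caller_id: str
    alt_count: int
    depth: int
    site: PileupSite | None = None
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.alt_count < 1:
            raise ValueError("alt_count must be >= 1")
        if not 0 < self.vaf <= 1:
            raise ValueError(f"vaf {self.vaf} outside (0, 1]")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


_EXCLUDE_FLAGS = (
    pysam.FUNMAP | pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FDUP | pysam.FQCFAIL
)


def _iter_reads(alignments) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str,)):
        with pysam.AlignmentFile(alignments, check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


@dataclass
class _SiteAccumulator:
    depth: int = 0
    alleles: dict = field(default_factory=dict)

    def stats(self, allele: str) -> _AlleleStats:
        return self.alleles.setdefault(allele, _AlleleStats())


def pileup_sites(
    alignments,
    ref_seqs: Mapping[str, str],
    region: tuple[str, int, int] | None = None,
    cfg: PileupConfig | None = None,
) -> list[PileupSite]:
    """Tally alignments and emit every position with alt-allele evidence.

    Parameters
    ----------
    alignments : str or iterable of pysam.AlignedSegment
        Path to a coordinate-sorted SAM/BAM, or an in-memory read stream.
    ref_seqs : mapping of contig -> sequence
        Reference sequences (full contigs, 0-based strings).
    region : (chrom, start, end), optional
        1-based inclusive restriction; reads outside are ignored.
    cfg : PileupConfig

    Raises
    ------
    UnsortedInputError
        If read start coordinates decrease within a contig.
    """
    cfg = cfg or PileupConfig()
    if region is not None:
        rchrom, rstart, rend = region
        if rchrom not in ref_seqs:
            raise ValueError(f"region contig {rchrom!r} not in reference")
        if rend > len(ref_seqs[rchrom]) or rstart < 1:
            raise ValueError(
                f"region {rchrom}:{rstart}-{rend} outside contig bounds "
                f"(length {len(ref_seqs[rchrom])})"
            )

    acc: dict[tuple[str, int], _SiteAccumulator] = {}
    indel_anchors: set[tuple[str, int]] = set()

    last_seen: dict[str, int] = {}
    for read in _iter_reads(alignments):
        if read.is_unmapped or (read.flag & _EXCLUDE_FLAGS):
            continue
        chrom = read.reference_name
        if chrom not in ref_seqs:
            raise ValueError(f"read contig {chrom!r} not in reference")
        if read.reference_start < last_seen.get(chrom, -1):
            raise UnsortedInputError(
                f"alignments not coordinate-sorted at {chrom}:{read.reference_start + 1}"
            )
        last_seen[chrom] = read.reference_start
        if read.mapping_quality < cfg.min_mapq:
            continue
        if region is not None:
            if chrom != rchrom or read.reference_end < rstart or read.reference_start + 1 > rend:
                continue
        _tally_read(read, ref_seqs[chrom], acc, indel_anchors, cfg)

    sites: list[PileupSite] = []
    for (chrom, pos), a in sorted(acc.items()):
        if not a.alleles:
            continue
        if region is not None and not (rstart <= pos <= rend):
            continue
        n_alt = sum(s.count for s in a.alleles.values())
        mapq = sum(s.mapq_sum for s in a.alleles.values()) / n_alt
        baseq = sum(s.baseq_sum for s in a.alleles.values()) / n_alt
        rpf = sum(s.read_pos_sum for s in a.alleles.values()) / n_alt
        spans = any(
            (chrom, p) in indel_anchors
            for p in range(pos - SPANS_INDEL_WINDOW, pos + SPANS_INDEL_WINDOW + 1)
        )
        sites.append(
            PileupSite(
                chrom=chrom,
                pos=pos,
                ref_base=ref_seqs[chrom][pos - 1],
                depth=a.depth,
                allele_counts={k: v.count for k, v in a.alleles.items()},
                allele_fwd_counts={k: v.fwd for k, v in a.alleles.items()},
                mean_mapq_alt=mapq,
                mean_baseq_alt=baseq,
                spans_indel=spans,
                mean_read_pos_fraction=rpf,
            )
        )
    return sites


def _tally_read(
    read: pysam.AlignedSegment,
    refseq: str,
    acc: dict,
    indel_anchors: set,
    cfg: PileupConfig,
) -> None:
    chrom = read.reference_name
    seq = read.query_sequence
    quals = read.query_qualities
    mapq = read.mapping_quality
    fwd = not read.is_reverse
    qlen = len(seq)

    qpos = 0
    rpos = read.reference_start  # 0-based
    counted_here: dict[int, bool] = {}

    def _count_position(rp: int) -> bool:
        """Apply the per-position depth cap; return True if this read is tallied."""
        key = (chrom, rp + 1)
        a = acc.setdefault(key, _SiteAccumulator())
        if rp in counted_here:
            return counted_here[rp]
        ok = a.depth < cfg.depth_cap
        if ok:
            a.depth += 1
        counted_here[rp] = ok
        return ok

    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X
            for k in range(length):
                rp, qp = rpos + k, qpos + k
                if not _count_position(rp):
                    continue
                base = seq[qp]
                if base != refseq[rp] and base != "N":
                    if quals[qp] >= cfg.min_base_quality:
                        s = acc[(chrom, rp + 1)].stats(base)
                        s.count += 1
                        s.fwd += int(fwd)
                        s.mapq_sum += mapq
                        s.baseq_sum += quals[qp]
                        s.read_pos_sum += qp / max(1, qlen - 1)
            rpos += length
            qpos += length
        elif op == 1:  # I — anchored at preceding reference base
            anchor_rp = rpos - 1
            if anchor_rp >= read.reference_start:
                indel_anchors.add((chrom, anchor_rp + 1))
                if counted_here.get(anchor_rp, False):
                    allele = "+" + seq[qpos : qpos + length]
                    s = acc[(chrom, anchor_rp + 1)].stats(allele)
                    s.count += 1
                    s.fwd += int(fwd)
                    s.mapq_sum += mapq
                    s.baseq_sum += float(np.mean(quals[qpos : qpos + length]))
                    s.read_pos_sum += qpos / max(1, qlen - 1)
            qpos += length
        elif op == 2:  # D — anchored at preceding reference base
            anchor_rp = rpos - 1
            if anchor_rp >= read.reference_start:
                indel_anchors.add((chrom, anchor_rp + 1))
                # the read spans the deleted bases: count depth there
                for k in range(length):
                    _count_position(rpos + k)
                if counted_here.get(anchor_rp, False):
                    allele = "-" + refseq[rpos : rpos + length]
                    s = acc[(chrom, anchor_rp + 1)].stats(allele)
                    s.count += 1
                    s.fwd += int(fwd)
                    anchor_q = quals[qpos - 1] if qpos > 0 else 30
                    s.baseq_sum += anchor_q
                    s.mapq_sum += mapq
                    s.read_pos_sum += (qpos - 1) / max(1, qlen - 1)
            rpos += length
        elif op == 4:  # S
            qpos += length
        elif op == 3:  # N
            rpos += length
        # H/P consume nothing we track


def resolve_multiallelic(site: PileupSite, rng_seed: int = 0) -> str:
    """Choose the site's alternative allele: most supporting reads, exact
    ties broken by a seeded uniform draw among the tied alleles."""
    if not site.allele_counts:
        raise ValueError(f"no alternative alleles at {site.chrom}:{site.pos}")
    best = max(site.allele_counts.values())
    tied = sorted(a for a, c in site.allele_counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, site.pos])
    return tied[int(rng.integers(len(tied)))]


def genotype_candidates(
    sites: Iterable[PileupSite],
    ref_seqs: Mapping[str, str],
    min_alt_reads: int = 1,
    rng_seed: int = 0,
) -> list[CallRecord]:
    """One tracker call per candidate site passing ``min_alt_reads``.

    Multiallelic sites are resolved first (most-supported allele, seeded
    random tie-break); adjacent SNVs are left as separate records (no MNP
    assembly).
    """
    out: list[CallRecord] = []
    for site in sites:
        if not site.allele_counts:
            continue
        allele = resolve_multiallelic(site, rng_seed)
        count = site.allele_counts[allele]
        if count < min_alt_reads:
            continue
        v = site.variant_for(allele, ref_seqs)
        out.append(
            CallRecord(
                variant=v,
                caller_id="TRACKER",
                alt_count=count,
                depth=site.depth,
                site=site,
                allele=allele,
            )
        )
    return out
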