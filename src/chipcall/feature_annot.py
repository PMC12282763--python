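"""Variant annotation and feature-vector assembly.

Turns a merged call plus its pileup evidence into the fixed-length numeric
vector the classifier consumes: 26 features for SNVs, 24 for INDELs.  The
vector covers calling status, read-level quality metrics, sequence context
(homopolymer runs, short tandem repeats, low-complexity regions, GC),
population databases (four germline-frequency tables, a somatic-cancer
catalogue), and predicted protein consequence from a minimal codon-based
annotator over a supplied transcript model.

The feature order is frozen; ``schema_hash`` is embedded into trained model
bundles and checked at prediction time so that train- and predict-time
vectors can never silently disagree.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .variant_model import (
    GenomicVariant,
    ReferenceWindow,
    VariantKey,
    VariantType,
)

__all__ = [
    "Consequence",
    "FUNCTIONAL_CONSEQUENCES",
    "Transcript",
    "GeneModel",
    "ResourceTables",
    "ClassLabel",
    "CLASS_LABELS",
    "SNV_FEATURES",
    "INDEL_FEATURES",
    "schema_hash",
    "classify_consequence",
    "functional_filter",
    "context_features",
    "strand_bias_phred",
    "build_feature_vector",
]


# --------------------------------------------------------------------------
# consequence classes
# --------------------------------------------------------------------------

class Consequence(enum.IntEnum):
    """Predicted protein-level consequence, with a fixed ordinal encoding.

    Tree models are insensitive to the ordering but require a deterministic
    numeric code; the encoding below is frozen.
    """

    NONCODING = 0
    SYNONYMOUS = 1
    INFRAME_INDEL = 2
    MISSENSE = 3
    START_LOSS = 4
    STOP_LOSS = 5
    ESSENTIAL_SPLICE = 6
    NONSENSE = 7
    FRAMESHIFT = 8


#: Consequences treated as having a functional effect; variants outside this
#: set (synonymous, noncoding) are dropped before classification.
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.STOP_LOSS,
        Consequence.START_LOSS,
        Consequence.INFRAME_INDEL,
        Consequence.FRAMESHIFT,
        Consequence.ESSENTIAL_SPLICE,
    }
)

#: bp from an exon/intron boundary (into the intron) treated as essential splice
SPLICE_WINDOW = 2


class ClassLabel(str, enum.Enum):
    """The three prediction classes, in fixed encoding order."""

    CHIP = "CHIP"
    GERMLINE = "GERMLINE"
    ARTIFACT = "ARTIFACT"


CLASS_LABELS: tuple[str, str, str] = ("CHIP", "GERMLINE", "ARTIFACT")


# --------------------------------------------------------------------------
# gene model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """One transcript: exon structure plus the CDS span it encloses.

    Coordinates are 1-based inclusive.  ``cds_start``/``cds_end`` bound the
    coding region in genomic coordinates; exonic bases inside those bounds
    are coding.  For complete transcripts the spliced CDS length must be a
    multiple of 3 and translate without internal stops.
    """

    name: str
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        last_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} reversed in {self.name}")
            if s <= last_end:
                raise ValueError(f"exons overlap or unordered in {self.name}")
            last_end = e
        if not self.cds_start <= self.cds_end:
            raise ValueError(f"empty CDS in {self.name}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases, ascending."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            out.extend(range(lo, hi + 1))
        return out


class GeneModel:
    """A set of transcripts with point lookup by position."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = sorted(transcripts, key=lambda t: (t.chrom, t.start))
        for t in self.transcripts:
            # fail fast on inconsistent coding spans
            if len(t.cds_positions()) % 3 != 0:
                raise ValueError(
                    f"transcript {t.name}: CDS length {len(t.cds_positions())} "
                    "not divisible by 3"
                )

    def overlapping(self, chrom: str, pos: int) -> list[Transcript]:
        return [
            t
            for t in self.transcripts
            if t.chrom == chrom and t.start <= pos <= t.end
        ]

    def gene_at(self, chrom: str, pos: int) -> str | None:
        hits = self.overlapping(chrom, pos)
        return hits[0].gene if hits else None

    # ---- tab-separated persistence (documented columns) -------------------

    COLUMNS = (
        "transcript gene chrom strand exon_starts exon_ends cds_start cds_end canonical"
    ).split()

    def to_tsv(self, path: str) -> None:
        rows = []
        for t in self.transcripts:
            rows.append(
                {
                    "transcript": t.name,
                    "gene": t.gene,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "exon_starts": ",".join(str(s) for s, _ in t.exons),
                    "exon_ends": ",".join(str(e) for _, e in t.exons),
                    "cds_start": t.cds_start,
                    "cds_end": t.cds_end,
                    "canonical": int(t.canonical),
                }
            )
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GeneModel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        ts = []
        for _, r in df.iterrows():
            starts = [int(x) for x in r["exon_starts"].split(",")]
            ends = [int(x) for x in r["exon_ends"].split(",")]
            ts.append(
                Transcript(
                    name=r["transcript"],
                    gene=r["gene"],
                    chrom=r["chrom"],
                    strand=r["strand"],
                    exons=tuple(zip(starts, ends)),
                    cds_start=int(r["cds_start"]),
                    cds_end=int(r["cds_end"]),
                    canonical=bool(int(r["canonical"])),
                )
            )
        return cls(ts)


# --------------------------------------------------------------------------
# consequence annotation
# --------------------------------------------------------------------------

def _splice_distance(t: Transcript, pos: int) -> int | None:
    """Distance into the nearest intron from an exon boundary, or None if exonic."""
    for i, (s, e) in enumerate(t.exons):
        if s <= pos <= e:
            return None  # exonic
    best = None
    for i in range(len(t.exons) - 1):
        intron_lo = t.exons[i][1] + 1
        intron_hi = t.exons[i + 1][0] - 1
        if intron_lo <= pos <= intron_hi:
            d = min(pos - intron_lo, intron_hi - pos) + 1
            best = d
    return best


def classify_consequence(
    v: GenomicVariant, gm: GeneModel, ref_seqs: Mapping[str, str]
) -> Consequence:
    """Predict the protein consequence of a normalized variant.

    Uses codon translation of the canonical transcript covering the site.
    Intronic positions within ``SPLICE_WINDOW`` bp of an exon boundary are
    essential-splice; other intronic, UTR and intergenic positions are
    noncoding.  Coding indels are frameshift unless their length is a
    multiple of 3.
    """
    if v.vtype is VariantType.MNP:
        raise ValueError("split MNPs before consequence annotation")
    hits = gm.overlapping(v.chrom, v.pos)
    if not hits:
        return Consequence.NONCODING
    t = next((h for h in hits if h.canonical), hits[0])

    sd = _splice_distance(t, v.pos)
    if sd is not None:
        return Consequence.ESSENTIAL_SPLICE if sd <= SPLICE_WINDOW else Consequence.NONCODING

    cds_pos = t.cds_positions()
    if v.vtype in (VariantType.INS, VariantType.DEL):
        # affected bases: for DEL the deleted span, for INS the insertion point
        if v.vtype is VariantType.DEL:
            affected = range(v.pos + 1, v.pos + len(v.ref))
            if not any(p in set(cds_pos) for p in affected):
                return Consequence.NONCODING
        else:
            if v.pos not in set(cds_pos):
                return Consequence.NONCODING
        shift = abs(v.indel_length) % 3
        return Consequence.FRAMESHIFT if shift else Consequence.INFRAME_INDEL

    # SNV in an exon: translate the affected codon
    try:
        idx = cds_pos.index(v.pos)
    except ValueError:
        return Consequence.NONCODING  # exonic UTR
    seq = ref_seqs[v.chrom]
    cds_ref = "".join(seq[p - 1] for p in cds_pos)
    cds_alt = cds_ref[:idx] + v.alt + cds_ref[idx + 1 :]
    if t.strand == "-":
        cds_ref = str(Seq(cds_ref).reverse_complement())
        cds_alt = str(Seq(cds_alt).reverse_complement())
        idx = len(cds_pos) - 1 - idx
    codon_i = idx // 3
    ref_codon = cds_ref[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = cds_alt[codon_i * 3 : codon_i * 3 + 3]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return Consequence.SYNONYMOUS
    if codon_i == 0 and ref_aa == "M":
        return Consequence.START_LOSS
    if ref_aa == "*":
        return Consequence.STOP_LOSS
    if alt_aa == "*":
        return Consequence.NONSENSE
    return Consequence.MISSENSE


def functional_filter(
    annotated: Sequence[tuple[object, Consequence]]
) -> list[tuple[object, Consequence]]:
    """Retain calls with a functional consequence, preserving order."""
    return [(c, q) for c, q in annotated if q in FUNCTIONAL_CONSEQUENCES]


# --------------------------------------------------------------------------
# sequence-context features
# --------------------------------------------------------------------------

def _longest_run_at(seq: str, i: int) -> int:
    """Longest single-base run containing or immediately adjacent to index i."""
    best = 1
    for j in (i - 1, i, i + 1):
        if not 0 <= j < len(seq):
            continue
        b = seq[j]
        lo = j
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = j
        while hi < len(seq) - 1 and seq[hi + 1] == b:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def _tandem_repeat_at(seq: str, i: int, min_copies: int = 3) -> bool:
    """True if an exact tandem of a 2-6 bp unit with >= min_copies overlaps i."""
    n = len(seq)
    for unit in range(2, 7):
        lo = max(0, i - unit * (min_copies + 2))
        hi = min(n, i + unit * (min_copies + 2))
        for start in range(lo, min(hi, i + 1)):
            u = seq[start : start + unit]
            if len(u) < unit or len(set(u)) == 1:
                continue
            copies = 1
            j = start + unit
            while seq[j : j + unit] == u:
                copies += 1
                j += unit
            if copies >= min_copies and start <= i < j:
                return True
    return False


def _in_intervals(
    intervals: Iterable[tuple[str, int, int]], chrom: str, pos: int
) -> bool:
    """1-based inclusive interval membership."""
    return any(c == chrom and s <= pos <= e for c, s, e in intervals)


def context_features(
    v: GenomicVariant,
    ref_seqs: Mapping[str, str],
    str_intervals: Iterable[tuple[str, int, int]] = (),
    low_complexity_intervals: Iterable[tuple[str, int, int]] = (),
) -> tuple[int, bool, bool, float]:
    """(homopolymer_len, in_str, in_low_complexity, gc_content_101bp) at ``v``.

    The 101-bp GC window is clipped at contig edges and computed on the
    available bases.
    """
    seq = ref_seqs[v.chrom]
    i = v.pos - 1
    homopolymer_len = _longest_run_at(seq, i)
    in_str = _in_intervals(str_intervals, v.chrom, v.pos) or _tandem_repeat_at(seq, i)
    in_lc = _in_intervals(low_complexity_intervals, v.chrom, v.pos)
    lo, hi = max(0, i - 50), min(len(seq), i + 51)
    window = seq[lo:hi]
    gc = sum(b in "GC" for b in window) / len(window)
    return homopolymer_len, in_str, in_lc, gc


def strand_bias_phred(
    alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int, cap: float = 200.0
) -> float:
    """Phred-scaled Fisher-exact strand-bias score (higher = more biased)."""
    _, p = stats.fisher_exact([[alt_fwd, alt_rev], [ref_fwd, ref_rev]])
    if p <= 0:
        return cap
    return min(cap, -10.0 * np.log10(p))


# --------------------------------------------------------------------------
# resource tables
# --------------------------------------------------------------------------

def _read_keyed_tsv(path: str, value_col: str) -> dict[VariantKey, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for _, r in df.iterrows():
        out[VariantKey(str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"])] = float(
            r[value_col]
        )
    return out


def _read_key_set(path: str) -> set[VariantKey]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        VariantKey(str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"])
        for _, r in df.iterrows()
    }


def _read_bed(path: str) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) -> 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out


@dataclass
class ResourceTables:
    """Population/annotation resources consulted during featurization.

    ``germline_mafs`` holds four named germline-frequency tables (mirroring
    four population databases); ``cosmic`` maps a variant key to the number
    of catalogued samples carrying it; ``known_chip`` is the compiled list of
    previously reported CHIP mutations; ``driver_genes``/``driver_mutations``
    restrict cohort reporting; interval sets flag repeat contexts.  All keys
    are normalized variant keys.
    """

    germline_mafs: tuple[dict[VariantKey, float], ...] = field(
        default_factory=lambda: ({}, {}, {}, {})
    )
    cosmic: dict[VariantKey, int] = field(default_factory=dict)
    known_chip: set[VariantKey] = field(default_factory=set)
    driver_genes: set[str] = field(default_factory=set)
    driver_mutations: set[VariantKey] = field(default_factory=set)
    low_complexity: list[tuple[str, int, int]] = field(default_factory=list)
    str_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.germline_mafs) != 4:
            raise ValueError("exactly 4 germline MAF tables are required")
        for table in self.germline_mafs:
            for k, maf in table.items():
                if not 0.0 <= maf <= 1.0:
                    raise ValueError(f"MAF {maf} for {k} outside [0,1]")
        for k, n in self.cosmic.items():
            if n < 1:
                raise ValueError(f"COSMIC sample count {n} for {k} < 1")

    def max_germline_maf(self, key: VariantKey) -> float:
        return max(t.get(key, 0.0) for t in self.germline_mafs)

    def cosmic_lookup(self, key: VariantKey, vtype: VariantType) -> tuple[int, int]:
        """(match flag, sample count).  SNVs match on the full key; INDELs on
        position + type + length (strict length tolerance)."""
        if vtype is VariantType.SNV:
            n = self.cosmic.get(key, 0)
            return (1, n) if n else (0, 0)
        for k, n in self.cosmic.items():
            if (
                k.chrom == key.chrom
                and k.pos == key.pos
                and (len(k.alt) - len(k.ref)) == (len(key.alt) - len(key.ref))
            ):
                return 1, n
        return 0, 0

    @classmethod
    def from_files(
        cls,
        germline_maf_paths: Sequence[str],
        cosmic_path: str | None = None,
        known_chip_path: str | None = None,
        driver_gene_path: str | None = None,
        driver_mutation_path: str | None = None,
        low_complexity_bed: str | None = None,
        str_bed: str | None = None,
    ) -> "ResourceTables":
        if len(germline_maf_paths) != 4:
            raise ValueError("exactly 4 germline MAF tables are required")
        mafs = tuple(_read_keyed_tsv(p, "maf") for p in germline_maf_paths)
        cosmic = (
            {k: int(v) for k, v in _read_keyed_tsv(cosmic_path, "sample_count").items()}
            if cosmic_path
            else {}
        )
        known = _read_key_set(known_chip_path) if known_chip_path else set()
        drivers = set()
        if driver_gene_path:
            drivers = set(
                pd.read_csv(driver_gene_path, sep="\t")["gene"].astype(str)
            )
        driver_muts = _read_key_set(driver_mutation_path) if driver_mutation_path else set()
        lc = _read_bed(low_complexity_bed) if low_complexity_bed else []
        strs = _read_bed(str_bed) if str_bed else []
        return cls(mafs, cosmic, known, drivers, driver_muts, lc, strs)


# --------------------------------------------------------------------------
# feature schema
# --------------------------------------------------------------------------

#: The 26 SNV predictors, in frozen order.
SNV_FEATURES: tuple[str, ...] = (
    "status_meta",
    "called_by_tracker",
    "called_by_caller_a",
    "called_by_caller_b",
    "depth",
    "alt_count",
    "vaf",
    "mean_mapq_alt",
    "mean_baseq_alt",
    "strand_bias_phred",
    "spans_indel",
    "mean_read_pos_fraction",
    "homopolymer_len",
    "in_str",
    "in_low_complexity",
    "gc_content_101bp",
    "maf_db1",
    "maf_db2",
    "maf_db3",
    "maf_db4",
    "max_germline_maf",
    "cosmic_match",
    "cosmic_freq",
    "is_transition",
    "consequence_class",
    "base_change_class",
)

#: The 24 INDEL predictors: the SNV set minus the substitution-specific
#: features, plus the signed indel length.
INDEL_FEATURES: tuple[str, ...] = tuple(
    f
    for f in SNV_FEATURES
    if f not in ("is_transition", "base_change_class", "mean_read_pos_fraction")
) + ("indel_length",)

assert len(SNV_FEATURES) == 26 and len(INDEL_FEATURES) == 24

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: pyrimidine-strand collapsed substitution classes, frozen encoding
_BASE_CHANGE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def base_change_class(ref: str, alt: str) -> int:
    """Six-level substitution class (mutated pyrimidine convention)."""
    if ref in "AG":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return _BASE_CHANGE_CLASSES.index(f"{ref}>{alt}")


def schema_hash(variant_type: str) -> str:
    """Stable hash of the frozen feature order for a variant type."""
    names = SNV_FEATURES if variant_type == "SNV" else INDEL_FEATURES
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


def build_feature_vector(
    merged_call,
    site,
    consequence: Consequence,
    rt: ResourceTables,
    ref_seqs: Mapping[str, str],
) -> pd.Series:
    """Assemble the fixed-order numeric feature vector for one merged call.

    ``site`` carries the tracker's pileup evidence; for calls seen only by
    external callers it is a targeted re-pileup of the alignments at the
    site.  Missing database entries encode as 0.
    """
    v = merged_call.variant
    key = merged_call.key
    is_snv = v.vtype is VariantType.SNV
    names = SNV_FEATURES if is_snv else INDEL_FEATURES

    best = merged_call.best_evidence
    depth = best.depth
    alt_count = best.alt_count
    vaf = alt_count / depth if depth else 0.0

    hp, in_str, in_lc, gc = context_features(
        v, ref_seqs, rt.str_regions, rt.low_complexity
    )
    mafs = [t.get(key, 0.0) for t in rt.germline_mafs]
    cosmic_match, cosmic_freq = rt.cosmic_lookup(key, v.vtype)

    if site is not None:
        mean_mapq = site.mean_mapq_alt
        mean_baseq = site.mean_baseq_alt
        spans = float(site.spans_indel)
        read_pos = site.mean_read_pos_fraction
        alt_fwd = site.allele_fwd_counts.get(site.top_allele(), 0)
        ref_fwd = max(0, (site.depth - sum(site.allele_counts.values())) // 2)
        ref_rev = max(0, site.depth - sum(site.allele_counts.values()) - ref_fwd)
        sb = strand_bias_phred(alt_fwd, alt_count - alt_fwd, ref_fwd, ref_rev)
    else:
        mean_mapq = mean_baseq = 0.0
        spans = 0.0
        read_pos = 0.5
        sb = 0.0

    values = {
        "status_meta": float(merged_call.status),
        "called_by_tracker": float("TRACKER" in merged_call.callers),
        "called_by_caller_a": float("CALLER_A" in merged_call.callers),
        "called_by_caller_b": float("CALLER_B" in merged_call.callers),
        "depth": float(depth),
        "alt_count": float(alt_count),
        "vaf": vaf,
        "mean_mapq_alt": float(mean_mapq),
        "mean_baseq_alt": float(mean_baseq),
        "strand_bias_phred": float(sb),
        "spans_indel": spans,
        "homopolymer_len": float(hp),
        "in_str": float(in_str),
        "in_low_complexity": float(in_lc),
        "gc_content_101bp": gc,
        "maf_db1": mafs[0],
        "maf_db2": mafs[1],
        "maf_db3": mafs[2],
        "maf_db4": mafs[3],
        "max_germline_maf": max(mafs),
        "cosmic_match": float(cosmic_match),
        "cosmic_freq": float(cosmic_freq),
        "consequence_class": float(int(consequence)),
    }
    if is_snv:
        values["mean_read_pos_fraction"] = float(read_pos)
        values["is_transition"] = float((v.ref, v.alt) in _TRANSITIONS)
        values["base_change_class"] = float(base_change_class(v.ref, v.alt))
    else:
        values["indel_length"] = float(v.indel_length)

    vec = pd.Series([values[n] for n in names], index=list(names), dtype=float)
    assert len(vec) == (26 if is_snv else 24)
    return vec
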