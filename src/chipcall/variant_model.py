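"""Canonical variant representation and normalization.

Every stage of the pipeline — the pileup tracker, the multi-caller merge,
feature extraction and resource-table lookups — exchanges variants through
the :class:`GenomicVariant` record defined here.  Two call sets can only be
compared once both are in canonical form, so this module also implements the
two normalization steps applied to every raw call: decomposition of
multi-nucleotide substitutions into individual SNVs, and VCF-style left
normalization of indels (parsimonious alleles, shifted as far left as the
reference allows).  The :class:`VariantKey` of a normalized variant is the
merge currency: two representations of the same mutation map to the same key.

Coordinates follow the VCF convention: ``pos`` is the 1-based position of the
first reference base of ``ref``.  Symbolic and breakend alleles are rejected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import NamedTuple

__all__ = [
    "VariantType",
    "GenomicVariant",
    "VariantKey",
    "ReferenceWindow",
    "ReferenceMismatchError",
    "WindowTooShortError",
    "left_normalize",
    "split_mnp",
    "variant_key",
]

_VALID_BASES = frozenset("ACGTN")


class VariantType(str, enum.Enum):
    """Kind of small variant, derivable from the allele lengths."""

    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNP = "MNP"


class ReferenceMismatchError(ValueError):
    """The REF allele does not match the reference sequence at the site."""


class WindowTooShortError(ValueError):
    """Left normalization ran off the start of the supplied window."""


def _classify(ref: str, alt: str) -> VariantType:
    if len(ref) == len(alt):
        return VariantType.SNV if len(ref) == 1 else VariantType.MNP
    return VariantType.INS if len(ref) < len(alt) else VariantType.DEL


@dataclass(frozen=True)
class GenomicVariant:
    """A small variant in VCF representation (1-based, anchored alleles).

    Parameters
    ----------
    chrom : str
        Contig name.
    pos : int
        1-based position of the first base of ``ref``.
    ref, alt : str
        Reference and alternate allele strings (uppercase A/C/G/T/N).
    normalized : bool
        True once the record has passed :func:`left_normalize`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        ref, alt = self.ref.upper(), self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        for allele, name in ((ref, "ref"), (alt, "alt")):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(
                    f"{name} allele {allele!r} contains non-ACGTN characters "
                    "(symbolic/breakend alleles are not supported)"
                )
        if ref == alt:
            raise ValueError(f"ref and alt are identical ({ref!r})")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")

    @property
    def vtype(self) -> VariantType:
        return _classify(self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        """Signed length change (positive for insertions, 0 for substitutions)."""
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        """1-based inclusive position of the last REF base."""
        return self.pos + len(self.ref) - 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


class VariantKey(NamedTuple):
    """Hashable identity of a normalized variant; the merge currency."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence with its 1-based start coordinate."""

    chrom: str
    start: int  # 1-based position of seq[0]
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        if not self.start <= pos <= self.end:
            raise WindowTooShortError(
                f"position {pos} outside window {self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[pos - self.start]

    def slice(self, pos: int, length: int) -> str:
        """``length`` reference bases starting at 1-based ``pos``."""
        if pos < self.start or pos + length - 1 > self.end:
            raise WindowTooShortError(
                f"span {pos}-{pos + length - 1} outside window "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        off = pos - self.start
        return self.seq[off : off + length]


def _check_ref(v: GenomicVariant, window: ReferenceWindow) -> None:
    observed = window.slice(v.pos, len(v.ref))
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {v.chrom}:{v.pos}: variant says {v.ref!r}, "
            f"reference has {observed!r}"
        )


def left_normalize(v: GenomicVariant, window: ReferenceWindow) -> GenomicVariant:
    """Return the parsimonious, left-aligned equivalent of ``v``.

    Implements the standard VCF normalization algorithm: shared suffix bases
    are trimmed (extending to the left through the reference when an allele
    would empty), then shared prefix bases are trimmed down to the single
    anchor base indels require.  SNVs are fixed points.  Re-applying is a
    no-op.

    The window must cover the variant and enough upstream sequence for the
    shift (50 bp is ample for the repeat lengths this pipeline simulates);
    running off its start raises :class:`WindowTooShortError`.
    """
    if window.chrom != v.chrom:
        raise ValueError(f"window contig {window.chrom!r} != variant contig {v.chrom!r}")
    _check_ref(v, window)
    if v.vtype is VariantType.SNV:
        return replace(v, normalized=True)

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        # trim identical trailing base; if an allele would empty, pull in the
        # preceding reference base on the left instead
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                prev = window.base(pos - 1)  # raises WindowTooShortError at edge
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        else:
            break
    # trim shared leading bases, keeping one anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return GenomicVariant(v.chrom, pos, ref, alt, normalized=True)


def split_mnp(v: GenomicVariant) -> list[GenomicVariant]:
    """Decompose a multi-nucleotide substitution into its component SNVs.

    Positions where the ref and alt base agree emit nothing, so the output
    length equals the Hamming distance between the alleles.  SNVs pass
    through as a singleton; indels are a usage error.
    """
    if v.vtype is VariantType.SNV:
        return [v]
    if v.vtype is not VariantType.MNP:
        raise ValueError(f"split_mnp expects SNV or MNP, got {v.vtype.value} ({v})")
    out: list[GenomicVariant] = []
    for i, (r, a) in enumerate(zip(v.ref, v.alt)):
        if r != a:
            out.append(GenomicVariant(v.chrom, v.pos + i, r, a, normalized=v.normalized))
    return out


def variant_key(v: GenomicVariant, window: ReferenceWindow) -> VariantKey:
    """Normalize ``v`` and return its :class:`VariantKey`.

    MNPs must be split first (:func:`split_mnp`); passing one is a usage
    error because a single key cannot represent multiple component SNVs.
    """
    if v.vtype is VariantType.MNP:
        raise ValueError(f"variant_key cannot key an MNP ({v}); call split_mnp first")
    n = v if v.normalized else left_normalize(v, window)
    return VariantKey(n.chrom, n.pos, n.ref, n.alt)


def apply_variant(v: GenomicVariant, window: ReferenceWindow) -> str:
    """Mutated copy of the window sequence — the semantic identity oracle.

    Two representations of the same mutation yield identical mutated
    sequences when applied to the same window; tests use this to validate
    normalization without trusting it.
    """
    _check_ref(v, window)
    off = v.pos - window.start
    return window.seq[:off] + v.alt + window.seq[off + len(v.ref) :]
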