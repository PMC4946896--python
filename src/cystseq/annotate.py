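"""Consequence classification of amplicon-local variants.

Variants are held in left-anchored VCF style: a substitution has equal-length
``ref``/``alt`` strings; an indel shares its first (anchor) base between
``ref`` and ``alt``.  Classification follows the callability rule used for
ultra-sensitive cyst-fluid genotyping: silent and intronic changes are not
reportable, except within the canonical splice sites (the two intronic bases
flanking each exon), which remain callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq

from .panel import Amplicon, NONCODING


class Consequence(str, Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    NONCODING_ = "noncoding"


#: consequence classes excluded from mutation calling
SILENT_CLASSES = frozenset({Consequence.SILENT, Consequence.INTRONIC, Consequence.NONCODING_})


@dataclass(frozen=True)
class Variant:
    """An amplicon-local variant in left-anchored (VCF-style) representation."""

    position: int
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def __str__(self) -> str:
        return f"{self.position}:{self.ref}>{self.alt}"


def _check_bounds(variant: Variant, amplicon: Amplicon) -> None:
    pos, ref = variant.position, variant.ref
    if pos < 0 or pos + len(ref) > len(amplicon):
        raise ValueError(f"variant {variant} spans the edge of {amplicon.amplicon_id}: uncallable")
    observed = amplicon.insert_seq[pos:pos + len(ref)]
    if observed != ref:
        raise ValueError(
            f"variant {variant}: ref allele {ref!r} does not match insert ({observed!r})"
        )
    if variant.ref == variant.alt:
        raise ValueError(f"variant {variant} has identical ref and alt")


def _affected_positions(variant: Variant, amplicon: Amplicon) -> list[int]:
    pos, ref, alt = variant.position, variant.ref, variant.alt
    if len(ref) == len(alt):
        return [pos + i for i in range(len(ref)) if ref[i] != alt[i]]
    if len(ref) > len(alt):  # deletion (possibly delins): bases after the anchor
        return list(range(pos + 1, pos + len(ref)))
    # insertion: the two bases flanking the insertion point
    return [p for p in (pos, pos + 1) if p < len(amplicon)]


def _codon_span(amplicon: Amplicon, cds_indices: list[int]) -> list[int]:
    """Complete-codon indices covering the given CDS indices; partial codons dropped."""
    phase = amplicon.cds_frame
    n = len(amplicon.exonic_positions)
    n_codons = (n - phase) // 3
    codons = set()
    for idx in cds_indices:
        c = (idx - phase) // 3
        if idx >= phase and 0 <= c < n_codons:
            codons.add(c)
    return sorted(codons)


def _translate_codon(cds: str, phase: int, codon: int) -> str:
    start = phase + 3 * codon
    return str(Seq(cds[start:start + 3]).translate())


def classify(variant: Variant, amplicon: Amplicon) -> Consequence:
    """Classify a variant against the amplicon's CDS model.

    Substitutions are translated through the standard codon table in the
    amplicon's frame (reverse-complemented for minus-strand CDS).  Indels whose
    net length change is a multiple of three and whose changed bases lie fully
    inside one exon are in-frame; other coding indels are frameshifts.  Any
    variant touching a canonical splice-site position is ``splice_site``.
    Substitutions whose codon is truncated at the amplicon edge cannot be
    translated and are classified ``noncoding`` (conservatively uncallable).
    """
    _check_bounds(variant, amplicon)
    affected = _affected_positions(variant, amplicon)
    if any(p in amplicon.splice_positions for p in affected):
        return Consequence.SPLICE_SITE
    if amplicon.cds_frame == NONCODING:
        return Consequence.NONCODING_
    exonic = [p for p in affected if amplicon.is_exonic(p)]
    if not exonic:
        return Consequence.INTRONIC

    if variant.is_indel:
        net = len(variant.alt) - len(variant.ref)
        changed = affected
        inside_one_exon = any(
            all(s <= p < e for p in changed) for s, e in amplicon.exon_intervals
        )
        if net % 3 == 0 and inside_one_exon:
            return Consequence.INFRAME_INDEL
        return Consequence.FRAMESHIFT

    # substitution / MNV: translate ref and alt haplotypes at the touched codons
    alt_insert = (
        amplicon.insert_seq[:variant.position]
        + variant.alt
        + amplicon.insert_seq[variant.position + len(variant.ref):]
    )
    ref_cds = amplicon.coding_sequence()
    alt_cds = amplicon.coding_sequence(alt_insert)
    codons = _codon_span(amplicon, [amplicon.cds_index(p) for p in exonic])
    if not codons:
        return Consequence.NONCODING_
    phase = amplicon.cds_frame
    changed_aas = [
        (_translate_codon(ref_cds, phase, c), _translate_codon(alt_cds, phase, c))
        for c in codons
    ]
    if all(r == a for r, a in changed_aas):
        return Consequence.SILENT
    if any(a == "*" and r != "*" for r, a in changed_aas):
        return Consequence.NONSENSE
    return Consequence.MISSENSE  # includes stop-loss, treated as missense-like


def _protein(cds: str, phase: int) -> str:
    core = cds[phase:]
    core = core[: 3 * (len(core) // 3)]
    return str(Seq(core).translate())


def hgvs_label(variant: Variant, amplicon: Amplicon) -> str | None:
    """Protein-level label (e.g. ``V600E``, ``R280K``, ``V600_S605>D``).

    Only missense, nonsense and in-frame indel variants get labels; silent,
    intronic, splice-site and frameshift variants return ``None``.  Codon
    numbering comes from the amplicon's ``codon_offset``.
    """
    cls = classify(variant, amplicon)
    phase = amplicon.cds_frame
    if cls in (Consequence.MISSENSE, Consequence.NONSENSE):
        alt_insert = (
            amplicon.insert_seq[:variant.position]
            + variant.alt
            + amplicon.insert_seq[variant.position + len(variant.ref):]
        )
        ref_cds = amplicon.coding_sequence()
        alt_cds = amplicon.coding_sequence(alt_insert)
        exonic = [p for p in _affected_positions(variant, amplicon) if amplicon.is_exonic(p)]
        codons = _codon_span(amplicon, [amplicon.cds_index(p) for p in exonic])
        parts = []
        for c in codons:
            r = _translate_codon(ref_cds, phase, c)
            a = _translate_codon(alt_cds, phase, c)
            if r != a:
                parts.append(f"{r}{amplicon.codon_offset + c}{a}")
        return ";".join(parts) if parts else None

    if cls is Consequence.INFRAME_INDEL:
        # translate both haplotypes fully, trim the shared prefix/suffix
        alt_insert = (
            amplicon.insert_seq[:variant.position]
            + variant.alt
            + amplicon.insert_seq[variant.position + len(variant.ref):]
        )
        ref_prot = _protein(amplicon.coding_sequence(), phase)
        # alt haplotype has a different length; rebuild its CDS with shifted bounds
        alt_cds = _shifted_cds(variant, amplicon, alt_insert)
        if amplicon.cds_strand == "-":
            alt_cds = str(Seq(alt_cds).reverse_complement())
        alt_prot = _protein(alt_cds, phase)
        i = 0
        while i < min(len(ref_prot), len(alt_prot)) and ref_prot[i] == alt_prot[i]:
            i += 1
        j_r, j_a = len(ref_prot), len(alt_prot)
        while j_r > i and j_a > i and ref_prot[j_r - 1] == alt_prot[j_a - 1]:
            j_r -= 1
            j_a -= 1
        seg_ref = ref_prot[i:j_r]
        seg_alt = alt_prot[i:j_a]
        off = amplicon.codon_offset
        if not seg_alt:  # pure in-frame deletion
            if len(seg_ref) == 1:
                return f"{seg_ref}{off + i}del"
            return f"{seg_ref[0]}{off + i}_{seg_ref[-1]}{off + j_r - 1}del"
        if not seg_ref:  # pure in-frame insertion
            return f"{ref_prot[i - 1]}{off + i - 1}_{ref_prot[i]}{off + i}ins{seg_alt}"
        left = f"{seg_ref[0]}{off + i}"
        if len(seg_ref) > 1:
            left += f"_{seg_ref[-1]}{off + j_r - 1}"
        return f"{left}>{seg_alt}"

    return None


def _shifted_cds(variant: Variant, amplicon: Amplicon, alt_insert: str) -> str:
    """Exonic concatenation of an indel haplotype, shifting exon bounds after the event."""
    shift = len(variant.alt) - len(variant.ref)
    event_end = variant.position + len(variant.ref)
    parts = []
    for s, e in amplicon.exon_intervals:
        s2 = s + shift if s >= event_end else s
        e2 = e + shift if e >= event_end else e
        parts.append(alt_insert[s2:e2])
    return "".join(parts)
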