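"""Amplicon panel model and I/O.

A *panel* is a set of short PCR amplicons (typically 110-142 bp inserts after
primer trimming) tiled over the coding regions of cancer driver genes, amplified
in a small number of multiplex pools such that no two amplicons of the same gene
in one pool overlap the same gene region.  Each amplicon carries the minimal
coding-sequence (CDS) annotation needed for consequence calling: which local
positions are exonic, the reading-frame phase of the first exonic base, the CDS
strand, the codon number of the first complete codon, and the canonical splice
site positions (the +/-1, +/-2 intronic bases at each exon boundary).

Coordinates are 0-based, half-open everywhere in memory and in the panel TSV;
only exported variant tables use 1-based positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: gene symbols of the published 17-gene ovarian panel; user genes are also accepted
PANEL_GENES = (
    "AKT1", "APC", "BRAF", "CDKN2A", "CTNNB1", "EGFR", "FBXW7", "FGFR2",
    "KRAS", "MAPK1", "NRAS", "PIK3CA", "PIK3R1", "POLE", "PPP2R1A", "PTEN", "TP53",
)

NONCODING = "noncoding"


@dataclass(frozen=True)
class Amplicon:
    """One primer-trimmed amplicon insert with its CDS annotation.

    ``cds_frame`` is the phase of the first exonic base: the number of bases of
    the coding sequence (read on the coding strand) that belong to an upstream,
    incomplete codon.  ``codon_offset`` is the codon number of the first
    complete codon, so protein-level labels (e.g. V600E) use transcript
    numbering supplied by the panel rather than re-derived from full
    transcripts.  ``gene_start`` is an optional gene-local coordinate of the
    insert used only for multiplex-pool overlap validation.
    """

    amplicon_id: str
    gene: str
    insert_seq: str
    pool: int
    cds_frame: int | str = NONCODING
    cds_strand: str = "+"
    exon_intervals: tuple[tuple[int, int], ...] = ()
    splice_positions: frozenset[int] = frozenset()
    codon_offset: int = 1
    gene_start: int | None = None

    def __post_init__(self) -> None:
        if not self.insert_seq or set(self.insert_seq) - VALID_BASES:
            bad = set(self.insert_seq) - VALID_BASES
            raise ValueError(
                f"{self.amplicon_id}: insert contains non-ACGT characters {sorted(bad)}"
                if self.insert_seq else f"{self.amplicon_id}: empty insert"
            )
        if self.pool not in (1, 2, 3):
            raise ValueError(f"{self.amplicon_id}: pool must be 1, 2 or 3")
        if self.cds_strand not in ("+", "-"):
            raise ValueError(f"{self.amplicon_id}: cds_strand must be '+' or '-'")
        if self.cds_frame != NONCODING and self.cds_frame not in (0, 1, 2):
            raise ValueError(f"{self.amplicon_id}: cds_frame must be 0-2 or '{NONCODING}'")
        last = 0
        for start, end in self.exon_intervals:
            if not (0 <= start < end <= len(self.insert_seq)):
                raise ValueError(f"{self.amplicon_id}: malformed exon interval {start}-{end}")
            if start < last:
                raise ValueError(f"{self.amplicon_id}: exon intervals overlap or unsorted")
            last = end
        for pos in self.splice_positions:
            if not 0 <= pos < len(self.insert_seq):
                raise ValueError(f"{self.amplicon_id}: splice position {pos} out of range")
            if self.is_exonic(pos):
                raise ValueError(f"{self.amplicon_id}: splice position {pos} is exonic")

    def __len__(self) -> int:
        return len(self.insert_seq)

    def is_exonic(self, pos: int) -> bool:
        return any(start <= pos < end for start, end in self.exon_intervals)

    @cached_property
    def exonic_positions(self) -> tuple[int, ...]:
        """All exonic positions, ascending in amplicon coordinates."""
        out: list[int] = []
        for start, end in self.exon_intervals:
            out.extend(range(start, end))
        return tuple(out)

    @cached_property
    def _exonic_rank(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.exonic_positions)}

    def cds_index(self, pos: int) -> int:
        """Index of amplicon position ``pos`` within the coding-strand CDS."""
        k = self._exonic_rank[pos]
        if self.cds_strand == "+":
            return k
        return len(self.exonic_positions) - 1 - k

    def coding_sequence(self, haplotype: str | None = None) -> str:
        """Coding-strand concatenation of the exonic bases of ``haplotype``.

        ``haplotype`` defaults to the reference insert; it must be the same
        length as the insert (substitution haplotypes only).
        """
        seq = self.insert_seq if haplotype is None else haplotype
        if len(seq) != len(self.insert_seq):
            raise ValueError("haplotype length must match insert length")
        cds = "".join(seq[s:e] for s, e in self.exon_intervals)
        if self.cds_strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


@dataclass
class Panel:
    """A validated collection of amplicons with unique ids."""

    amplicons: list[Amplicon]

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate amplicon ids: {dupes}")
        self._by_id = {a.amplicon_id: a for a in self.amplicons}

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    def __contains__(self, amplicon_id: str) -> bool:
        return amplicon_id in self._by_id

    @property
    def genes(self) -> set[str]:
        return {a.gene for a in self.amplicons}

    def by_gene(self, gene: str) -> list[Amplicon]:
        return [a for a in self.amplicons if a.gene == gene]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "amplicon_id", "gene", "pool", "cds_frame", "cds_strand",
    "exon_intervals", "splice_positions", "codon_offset", "gene_start",
]


def _fmt_intervals(ivals: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivals)


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        try:
            s, e = token.split("-")
            out.append((int(s), int(e)))
        except ValueError as err:
            raise ValueError(f"malformed exon interval {token!r}") from err
    return tuple(out)


def panel_to_frame(panel: Panel) -> pd.DataFrame:
    rows = []
    for a in panel:
        rows.append({
            "amplicon_id": a.amplicon_id,
            "gene": a.gene,
            "pool": a.pool,
            "cds_frame": a.cds_frame,
            "cds_strand": a.cds_strand,
            "exon_intervals": _fmt_intervals(a.exon_intervals),
            "splice_positions": ",".join(str(p) for p in sorted(a.splice_positions)),
            "codon_offset": a.codon_offset,
            "gene_start": "" if a.gene_start is None else a.gene_start,
        })
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def panel_to_tsv(panel: Panel) -> str:
    return panel_to_frame(panel).to_csv(sep="\t", index=False)


def panel_to_fasta(panel: Panel) -> str:
    buf = io.StringIO()
    records = [SeqRecord(Seq(a.insert_seq), id=a.amplicon_id, description="") for a in panel]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def write_panel(panel: Panel, tsv_path: str | Path, fasta_path: str | Path) -> None:
    Path(tsv_path).write_text(panel_to_tsv(panel))
    Path(fasta_path).write_text(panel_to_fasta(panel))


def load_panel(panel_table: str | Path, reference: str | Path) -> Panel:
    """Load and validate a panel from a TSV table plus a matching FASTA.

    Every table row's ``amplicon_id`` must have a FASTA record; sequences are
    upper-cased and checked for non-ACGT characters by the ``Amplicon``
    constructor.
    """
    table = pd.read_csv(panel_table, sep="\t", dtype=str, keep_default_na=False)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")}
    amplicons = []
    for _, row in table.iterrows():
        aid = row["amplicon_id"]
        if aid not in seqs:
            raise ValueError(f"amplicon {aid!r} missing from reference FASTA")
        frame_raw = row.get("cds_frame", NONCODING)
        frame: int | str = NONCODING if frame_raw in ("", NONCODING) else int(frame_raw)
        splice_raw = row.get("splice_positions", "").strip()
        splice = frozenset(int(p) for p in splice_raw.split(",") if p != "")
        gene_start_raw = row.get("gene_start", "").strip()
        amplicons.append(Amplicon(
            amplicon_id=aid,
            gene=row["gene"],
            insert_seq=seqs[aid],
            pool=int(row["pool"]),
            cds_frame=frame,
            cds_strand=row.get("cds_strand", "+") or "+",
            exon_intervals=_parse_intervals(row.get("exon_intervals", "")),
            splice_positions=splice,
            codon_offset=int(row.get("codon_offset", "1") or 1),
            gene_start=None if gene_start_raw == "" else int(gene_start_raw),
        ))
    return Panel(amplicons)


# ---------------------------------------------------------------------------
# pool validation
# ---------------------------------------------------------------------------

def validate_pools(panel: Panel) -> list[tuple[str, str]]:
    """Return all pairs of same-pool, same-gene amplicons that overlap.

    Overlap is assessed on the gene-local coordinates (``gene_start`` anchored
    intervals); amplicons without coordinates cannot conflict.  An empty list
    means the pool assignment is valid.
    """
    violations: list[tuple[str, str]] = []
    amps = [a for a in panel if a.gene_start is not None]
    for i, a in enumerate(amps):
        for b in amps[i + 1:]:
            if a.pool != b.pool or a.gene != b.gene:
                continue
            if a.gene_start < b.gene_start + len(b) and b.gene_start < a.gene_start + len(a):
                violations.append((a.amplicon_id, b.amplicon_id))
    return violations


# ---------------------------------------------------------------------------
# toy panel generator
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
# sense codons only, so random coding sequence never contains an internal stop
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]

# gene-specific codon anchors so that literature-style labels (V600E in BRAF,
# R280K in TP53) are exercised by the toy panel
_GENE_ANCHORS = {
    "BRAF": (598, {600: "GTG", 601: "AAA", 602: "GCT", 603: "ACA",
                   604: "GTG", 605: "TCA"}),   # V600 ... S605
    "TP53": (276, {280: "AGA"}),               # R280
    "KRAS": (5, {12: "GGT", 61: None}),        # G12 (codon 61 outside short inserts)
}


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_toy_panel(
    n_amplicons: int = 6,
    genes: tuple[str, ...] | list[str] = ("TP53", "KRAS", "BRAF"),
    seed: int = 0,
) -> tuple[Panel, str, str]:
    """Generate a deterministic toy panel for simulation and testing.

    Insert lengths are uniform in [110, 142]; every amplicon gets a CDS frame
    so consequence calling is exercised; amplicons at odd indices include an
    internal intron with canonical splice-site positions, and one amplicon is
    placed on the minus strand.  Same-gene amplicons tile the gene 100 bases
    apart (so neighbours overlap) and pools are assigned by greedy interval
    coloring, which keeps every pool overlap-free.

    Returns ``(panel, fasta_text, tsv_text)``.
    """
    if n_amplicons < 1:
        raise ValueError("n_amplicons must be >= 1")
    rng = np.random.default_rng(seed)
    genes = tuple(genes)
    amplicons: list[Amplicon] = []
    per_gene_count: dict[str, int] = {}

    for i in range(n_amplicons):
        gene = genes[i % len(genes)]
        k = per_gene_count.get(gene, 0)
        per_gene_count[gene] = k + 1
        length = int(rng.integers(110, 143))
        strand = "-" if (i == 3 and n_amplicons > 3) else "+"
        with_intron = i % 2 == 1 and length >= 120

        anchor = _GENE_ANCHORS.get(gene) if k == 0 and strand == "+" else None
        codon_offset = anchor[0] if anchor else int(rng.integers(1, 400))

        if with_intron:
            # exon1 [0, a) | intron [a, b) | exon2 [b, length)
            a = int(rng.integers(30, 54))
            intron_len = int(rng.integers(12, 20))
            b = a + intron_len
            tail = length - b
            trim = (a + tail) % 3            # keep total coding a codon multiple
            a -= trim
            exons = ((0, a), (b, length))
            splice = frozenset({a, a + 1, b - 2, b - 1})
        else:
            exonic_len = length - (length % 3)
            exons = ((0, exonic_len),)
            splice = frozenset(
                p for p in (exonic_len, exonic_len + 1) if p < length
            ) if exonic_len < length else frozenset()

        n_exonic = sum(e - s for s, e in exons)
        coding = _random_coding(rng, n_exonic // 3)
        if anchor:
            coding_list = list(coding)
            for codon_num, codon_seq in anchor[1].items():
                if codon_seq is None:
                    continue
                start = (codon_num - codon_offset) * 3
                if 0 <= start and start + 3 <= len(coding_list):
                    coding_list[start:start + 3] = codon_seq
            coding = "".join(coding_list)

        exonic_seq = coding if strand == "+" else str(Seq(coding).reverse_complement())
        seq = list(_random_bases(rng, length))
        pos_iter = iter(exonic_seq)
        for s, e in exons:
            for p in range(s, e):
                seq[p] = next(pos_iter)
        insert = "".join(seq)

        amplicons.append(Amplicon(
            amplicon_id=f"{gene}_amp{k + 1:02d}",
            gene=gene,
            insert_seq=insert,
            pool=1,  # reassigned below by greedy coloring
            cds_frame=0,
            cds_strand=strand,
            exon_intervals=exons,
            splice_positions=splice,
            codon_offset=codon_offset,
            gene_start=k * 100,
        ))

    # greedy pool coloring per gene: smallest pool free of overlapping neighbours
    colored: list[Amplicon] = []
    for a in amplicons:
        used = {
            b.pool for b in colored
            if b.gene == a.gene
            and a.gene_start < b.gene_start + len(b)
            and b.gene_start < a.gene_start + len(a)
        }
        pool = next(p for p in (1, 2, 3) if p not in used)
        colored.append(replace(a, pool=pool))

    panel = Panel(colored)
    return panel, panel_to_fasta(panel), panel_to_tsv(panel)
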