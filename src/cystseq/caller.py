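"""UID-family error-corrected mutation calling.

The calling cascade converts raw UID-tagged amplicon reads into mutation
calls in five stages:

1. **Quality filtering** — a read is discarded outright if any of its 14 UID
   bases has Phred quality below 15; template positions with quality below 20
   are masked (excluded from consensus voting at that position only).
2. **Template matching** — the template portion of each read is assigned to
   the amplicon whose insert it matches with the fewest mismatches, provided
   the mismatch fraction is at most 10%; ties and worse matches are unmatched.
3. **UID grouping** — reads are partitioned into UID families by
   (amplicon, UID); families below a minimum size (default 2) cannot
   error-correct and are dropped into a QC tally.
4. **Supermutant consensus** — a family is scored *supermutant* for a
   candidate allele when strictly more than 90% of its voting reads carry the
   alternate allele, *wildtype* when more than 90% carry the reference, and
   *ambiguous* otherwise (including zero voting reads).
5. **Calling** — the mutant allele fraction (MAF) is the fraction of eligible
   (supermutant + wildtype) families that are supermutant.  A candidate is a
   final call when its MAF exceeds 0.1%, exceeds the matched-control
   mean + 5 SD threshold for that allele, and its consequence is neither
   silent nor intronic (canonical splice sites remain callable).

Candidate alleles are enumerated from observed supermutants only.  The
sample-level engine (:func:`call_sample`) is vectorised with numpy; the
operation-level functions (:func:`filter_reads`, :func:`score_family`, ...)
express the same rules on explicit read records and serve as the reference
semantics.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .annotate import SILENT_CLASSES, Consequence, Variant, classify, hgvs_label
from .panel import Amplicon, Panel
from .simulate import UID_LENGTH, FastqRead

logger = logging.getLogger(__name__)

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One quality-parsed read split into UID and template portions."""

    uid: str
    template_seq: str
    template_quals: np.ndarray  # Phred scores, len == len(template_seq)
    uid_quals: np.ndarray | None = None
    matched_amplicon: str | None = None

    def __post_init__(self) -> None:
        self.template_quals = np.asarray(self.template_quals, dtype=np.int16)
        if len(self.template_seq) != len(self.template_quals):
            raise ValueError("template_seq and template_quals lengths differ")
        if len(self.uid) != UID_LENGTH:
            raise ValueError(f"UID must be {UID_LENGTH} bases")

    @classmethod
    def from_raw(cls, sequence: str, quality: str, uid_length: int = UID_LENGTH) -> "ReadRecord":
        quals = np.frombuffer(quality.encode("ascii"), np.uint8).astype(np.int16) - 33
        return cls(
            uid=sequence[:uid_length],
            template_seq=sequence[uid_length:],
            template_quals=quals[uid_length:],
            uid_quals=quals[:uid_length],
        )


@dataclass
class UIDFamily:
    """Reads sharing one (amplicon, UID) pair — one original template molecule."""

    amplicon_id: str
    uid: str
    reads: list[ReadRecord]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class SupermutantCall:
    """Per-allele family tally.  ``n_total_families`` is the eligible
    denominator (supermutant + wildtype; ambiguous families excluded)."""

    amplicon_id: str
    position: int
    ref: str
    alt: str
    n_supermutant_families: int
    n_total_families: int
    n_ambiguous_families: int = 0

    @property
    def maf(self) -> float:
        if self.n_total_families == 0:
            return float("nan")
        return self.n_supermutant_families / self.n_total_families

    @property
    def variant(self) -> Variant:
        return Variant(self.position, self.ref, self.alt)


@dataclass
class VariantCall:
    """A candidate with consequence annotation and the three pass gates."""

    call: SupermutantCall
    gene: str
    consequence: Consequence
    protein_label: str | None
    flag_maf_gt_floor: bool
    flag_exceeds_control: bool
    flag_nonsilent: bool

    @property
    def final_call(self) -> bool:
        return self.flag_maf_gt_floor and self.flag_exceeds_control and self.flag_nonsilent

    @property
    def maf(self) -> float:
        return self.call.maf


@dataclass
class CallerConfig:
    min_family_size: int = 2
    concordance: float = 0.90
    q_uid: int = 15
    q_variant: int = 20
    max_mismatch_frac: float = 0.10
    maf_floor: float = 0.001
    control_sd_multiplier: float = 5.0


@dataclass
class QCStats:
    """Read accounting; family sizes + discarded + unmatched + small-family
    reads always sum to the input total."""

    n_reads: int = 0
    n_uid_quality_discarded: int = 0
    n_unmatched: int = 0
    n_in_small_families: int = 0
    n_reads_in_families: int = 0
    n_families: int = 0
    n_small_families: int = 0


@dataclass
class SampleTally:
    """Supermutant/eligible counts for every (position, alt) of every amplicon,
    kept in dense arrays for control modelling.  Indel candidates are sparse."""

    sub_supermutant: dict[str, np.ndarray] = field(default_factory=dict)  # (L, 4)
    sub_eligible: dict[str, np.ndarray] = field(default_factory=dict)     # (L, 4)
    indel: dict[tuple[str, int, str, str], tuple[int, int]] = field(default_factory=dict)
    n_families: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operation-level functions (reference semantics)
# ---------------------------------------------------------------------------

def filter_reads(
    reads: Sequence[ReadRecord], q_uid: int = 15, q_variant: int = 20
) -> tuple[list[ReadRecord], list[np.ndarray]]:
    """Apply the UID-Q15 / template-Q20 quality rules.

    Returns the retained reads and, for each, a boolean mask of template
    positions that may vote (quality >= ``q_variant``).
    """
    kept, masks = [], []
    for read in reads:
        if read.uid_quals is not None and (np.asarray(read.uid_quals) < q_uid).any():
            continue
        kept.append(read)
        masks.append(np.asarray(read.template_quals) >= q_variant)
    return kept, masks


def match_template(
    read: ReadRecord, panel: Panel, max_mismatch_frac: float = 0.10
) -> str | None:
    """Assign a read to the amplicon with the fewest mismatches (gapped edit
    distance), requiring mismatch fraction <= ``max_mismatch_frac`` of the
    insert length; ties are unmatched."""
    best_id, best_frac, tie = None, np.inf, False
    for amp in panel:
        dist = edlib.align(read.template_seq, amp.insert_seq, mode="NW")["editDistance"]
        frac = dist / len(amp.insert_seq)
        if frac < best_frac:
            best_id, best_frac, tie = amp.amplicon_id, frac, False
        elif frac == best_frac:
            tie = True
    if best_id is None or tie or best_frac > max_mismatch_frac:
        return None
    return best_id


def group_by_uid(
    reads: Sequence[ReadRecord], min_family_size: int = 2
) -> tuple[list[UIDFamily], int]:
    """Partition amplicon-matched reads into UID families.

    Families smaller than ``min_family_size`` are excluded; the second return
    value counts the reads they contained (QC tally).
    """
    groups: dict[tuple[str, str], list[ReadRecord]] = defaultdict(list)
    for read in reads:
        if read.matched_amplicon is None:
            raise ValueError("reads must be amplicon-matched before grouping")
        groups[(read.matched_amplicon, read.uid)].append(read)
    families, n_dropped = [], 0
    for (aid, uid), members in groups.items():
        if len(members) >= min_family_size:
            families.append(UIDFamily(aid, uid, members))
        else:
            n_dropped += len(members)
    return families, n_dropped


def _indel_read_vote(
    read: ReadRecord, amplicon: Amplicon, variant: Variant, q_variant: int
) -> str | None:
    """Vote of one read on an indel allele via gapped alignment to the two
    candidate haplotypes; quality gate = min quality over the event's
    flanking two bases.  Returns 'alt', 'ref' or None (abstain/masked)."""
    lo = max(0, variant.position - 2)
    hi = min(len(read.template_quals), variant.position + len(variant.ref) + 2)
    if hi > lo and read.template_quals[lo:hi].min() < q_variant:
        return None
    ref_hap = amplicon.insert_seq
    alt_hap = (
        ref_hap[:variant.position] + variant.alt + ref_hap[variant.position + len(variant.ref):]
    )
    d_ref = edlib.align(read.template_seq, ref_hap, mode="NW")["editDistance"]
    d_alt = edlib.align(read.template_seq, alt_hap, mode="NW")["editDistance"]
    if d_alt < d_ref:
        return "alt"
    if d_ref < d_alt:
        return "ref"
    return None


def score_family(
    family: UIDFamily,
    position: int,
    alt_allele: str,
    ref_allele: str,
    concordance: float = 0.90,
    q_variant: int = 20,
    amplicon: Amplicon | None = None,
) -> str:
    """Score one family for one candidate allele.

    Returns ``'supermutant'`` when the fraction of voting reads carrying the
    alternate allele strictly exceeds ``concordance`` (default >90%),
    ``'wildtype'`` when the reference fraction strictly exceeds it, else
    ``'ambiguous'`` (including families with zero voting reads).
    """
    is_indel = len(ref_allele) != len(alt_allele)
    n_alt = n_ref = n_vote = 0
    for read in family.reads:
        if is_indel:
            if amplicon is None:
                raise ValueError("indel scoring requires the amplicon")
            vote = _indel_read_vote(
                read, amplicon, Variant(position, ref_allele, alt_allele), q_variant
            )
            if vote is None:
                continue
            n_vote += 1
            n_alt += vote == "alt"
            n_ref += vote == "ref"
        else:
            end = position + len(ref_allele)
            if end > len(read.template_seq):
                continue
            quals = read.template_quals[position:end]
            if (quals < q_variant).any():
                continue
            obs = read.template_seq[position:end]
            n_vote += 1
            n_alt += obs == alt_allele
            n_ref += obs == ref_allele
    if n_vote == 0:
        return "ambiguous"
    if n_alt > concordance * n_vote:
        return "supermutant"
    if n_ref > concordance * n_vote:
        return "wildtype"
    return "ambiguous"


def compute_maf(
    families: Sequence[UIDFamily],
    position: int,
    alt_allele: str,
    ref_allele: str,
    concordance: float = 0.90,
    q_variant: int = 20,
    amplicon: Amplicon | None = None,
) -> SupermutantCall:
    """Tally supermutant/wildtype families for one allele and form the MAF.

    Ambiguous families are excluded from the denominator; a zero eligible
    denominator yields a NaN MAF (flagged by the caller).
    """
    n_sm = n_wt = n_amb = 0
    aid = families[0].amplicon_id if families else (amplicon.amplicon_id if amplicon else "")
    for fam in families:
        status = score_family(
            fam, position, alt_allele, ref_allele, concordance, q_variant, amplicon
        )
        n_sm += status == "supermutant"
        n_wt += status == "wildtype"
        n_amb += status == "ambiguous"
    if n_sm + n_wt == 0:
        logger.warning("no eligible families at %s:%d %s>%s", aid, position, ref_allele, alt_allele)
    return SupermutantCall(
        amplicon_id=aid, position=position, ref=ref_allele, alt=alt_allele,
        n_supermutant_families=n_sm, n_total_families=n_sm + n_wt,
        n_ambiguous_families=n_amb,
    )


# ---------------------------------------------------------------------------
# vectorised sample engine
# ---------------------------------------------------------------------------

def _read_fastq(path: str | Path) -> list[FastqRead]:
    import pysam

    out = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            out.append(FastqRead(entry.name, entry.sequence, entry.quality))
    return out


def haplotype_diff(haplotype: str, insert: str) -> Variant | None:
    """Canonical single-variant difference between a haplotype and the insert.

    Trims the longest common suffix, then the longest common prefix, and
    emits one left-aligned, anchored variant covering the changed span (a
    delins when lengths differ, an MNV/substitution otherwise).  Returns
    ``None`` for identical sequences.  Applying this to both an observed
    consensus and a ground-truth haplotype gives comparable representations
    even in repeat contexts, where indel placement is otherwise ambiguous.
    """
    if haplotype == insert:
        return None
    j = 0
    while (j < min(len(haplotype), len(insert))
           and haplotype[len(haplotype) - 1 - j] == insert[len(insert) - 1 - j]):
        j += 1
    h_core, i_core = haplotype[:len(haplotype) - j], insert[:len(insert) - j]
    i = 0
    while i < min(len(h_core), len(i_core)) and h_core[i] == i_core[i]:
        i += 1
    if len(haplotype) == len(insert):
        return Variant(i, i_core[i:], h_core[i:])
    if not i_core:  # pure insertion before position 0: right-anchor on insert[0]
        return Variant(0, insert[0], h_core + insert[0])
    if not h_core:  # pure deletion of the insert's first bases: right-anchored
        return Variant(0, i_core + insert[len(i_core)], insert[len(i_core)])
    anchor = max(i - 1, 0)
    return Variant(anchor, i_core[anchor:], h_core[anchor:])


def call_sample(
    reads: Iterable[FastqRead] | Sequence[tuple[str, str]] | str | Path,
    panel: Panel,
    config: CallerConfig | None = None,
) -> tuple[list[SupermutantCall], SampleTally, QCStats]:
    """Run the full calling cascade on one sample's reads.

    ``reads`` may be FASTQ records/(sequence, quality) pairs or a FASTQ path.
    Returns all observed supermutant candidates (each with >= 1 supermutant
    family), the dense per-position tally used for control modelling, and the
    read-accounting QC stats.
    """
    cfg = config or CallerConfig()
    if isinstance(reads, (str, Path)):
        reads = _read_fastq(reads)
    seqs: list[str] = []
    quals: list[str] = []
    for r in reads:
        if isinstance(r, FastqRead):
            seqs.append(r.sequence)
            quals.append(r.quality)
        else:
            s, q = r[-2], r[-1]
            seqs.append(s)
            quals.append(q)

    qc = QCStats(n_reads=len(seqs))
    tally = SampleTally()
    calls: list[SupermutantCall] = []

    inserts_by_len: dict[int, list[Amplicon]] = defaultdict(list)
    for amp in panel:
        inserts_by_len[len(amp)].append(amp)
    amp_order = [a.amplicon_id for a in panel]
    amp_index = {aid: i for i, aid in enumerate(amp_order)}

    # bucket by read length
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        by_len[len(s)].append(i)

    # per amplicon: main-length reads as (codes, qual, uid) and odd-length reads
    main_codes: dict[str, list[np.ndarray]] = defaultdict(list)
    main_quals: dict[str, list[np.ndarray]] = defaultdict(list)
    main_uids: dict[str, list[np.ndarray]] = defaultdict(list)
    odd_reads: dict[str, list[tuple[str, str, np.ndarray]]] = defaultdict(list)

    for read_len, idx in by_len.items():
        tpl_len = read_len - UID_LENGTH
        if tpl_len <= 0:
            qc.n_unmatched += len(idx)
            continue
        buf = "".join(seqs[i] for i in idx).encode("ascii")
        qbuf = "".join(quals[i] for i in idx).encode("ascii")
        S = np.frombuffer(buf, np.uint8).reshape(len(idx), read_len)
        Q = np.frombuffer(qbuf, np.uint8).reshape(len(idx), read_len).astype(np.int16) - 33

        ok = ~(Q[:, :UID_LENGTH] < cfg.q_uid).any(axis=1)
        qc.n_uid_quality_discarded += int((~ok).sum())
        S, Q = S[ok], Q[ok]
        kept_idx = np.asarray(idx)[ok]
        if not len(S):
            continue
        T = S[:, UID_LENGTH:]
        QT = Q[:, UID_LENGTH:]
        U = S[:, :UID_LENGTH]

        cands = inserts_by_len.get(tpl_len, [])
        n = len(S)
        assign = np.full(n, -1, dtype=np.int64)
        if cands:
            mm = np.empty((n, len(cands)), dtype=np.int64)
            for j, amp in enumerate(cands):
                ins = np.frombuffer(amp.insert_seq.encode(), np.uint8)
                mm[:, j] = (T != ins).sum(axis=1)
            best_j = mm.argmin(axis=1)
            best = mm[np.arange(n), best_j]
            n_best = (mm == best[:, None]).sum(axis=1)
            good = (best <= cfg.max_mismatch_frac * tpl_len) & (n_best == 1)
            assign[good] = np.array([amp_index[cands[j].amplicon_id] for j in range(len(cands))])[best_j[good]]

        # fallback: gapped alignment for unassigned reads (indel haplotypes etc.)
        pending = np.flatnonzero(assign < 0)
        if len(pending):
            cache: dict[str, int] = {}
            for r in pending:
                tseq = T[r].tobytes().decode("ascii")
                hit = cache.get(tseq, -2)
                if hit == -2:
                    best_id, best_frac, tie = -1, np.inf, False
                    for amp in panel:
                        d = edlib.align(tseq, amp.insert_seq, mode="NW")["editDistance"]
                        frac = d / len(amp.insert_seq)
                        if frac < best_frac:
                            best_id, best_frac, tie = amp_index[amp.amplicon_id], frac, False
                        elif frac == best_frac:
                            tie = True
                    hit = -1 if (tie or best_frac > cfg.max_mismatch_frac) else best_id
                    cache[tseq] = hit
                assign[r] = hit

        qc.n_unmatched += int((assign < 0).sum())
        for j, aid in enumerate(amp_order):
            sel = assign == j
            if not sel.any():
                continue
            amp = panel[aid]
            uid_rows = U[sel]
            if tpl_len == len(amp):
                main_codes[aid].append(T[sel])
                main_quals[aid].append(QT[sel])
                main_uids[aid].append(uid_rows)
            else:
                for r in np.flatnonzero(sel):
                    odd_reads[aid].append((
                        U[r].tobytes().decode("ascii"),
                        T[r].tobytes().decode("ascii"),
                        QT[r],
                    ))

    for aid in amp_order:
        amp = panel[aid]
        _call_amplicon(
            amp, main_codes.get(aid, []), main_quals.get(aid, []),
            main_uids.get(aid, []), odd_reads.get(aid, []),
            cfg, calls, tally, qc,
        )
    return calls, tally, qc


def _call_amplicon(
    amp: Amplicon,
    code_chunks: list[np.ndarray],
    qual_chunks: list[np.ndarray],
    uid_chunks: list[np.ndarray],
    odd: list[tuple[str, str, np.ndarray]],
    cfg: CallerConfig,
    calls: list[SupermutantCall],
    tally: SampleTally,
    qc: QCStats,
) -> None:
    L = len(amp)
    aid = amp.amplicon_id
    ref_codes = _BASE_LUT[np.frombuffer(amp.insert_seq.encode(), np.uint8)]

    if code_chunks:
        T = np.vstack(code_chunks)
        QT = np.vstack(qual_chunks)
        U = np.vstack(uid_chunks)
        uid_strs = [row.tobytes().decode("ascii") for row in U]
    else:
        T = np.empty((0, L), dtype=np.uint8)
        QT = np.empty((0, L), dtype=np.int16)
        uid_strs = []
    odd_uids = [u for u, _, _ in odd]

    all_uids = np.array(uid_strs + odd_uids, dtype=object)
    if len(all_uids) == 0:
        tally.sub_supermutant[aid] = np.zeros((L, 4), np.int64)
        tally.sub_eligible[aid] = np.zeros((L, 4), np.int64)
        tally.n_families[aid] = 0
        return
    uniq, inverse, counts = np.unique(all_uids, return_inverse=True, return_counts=True)
    keep_family = counts >= cfg.min_family_size
    small_reads = int(counts[~keep_family].sum())
    qc.n_in_small_families += small_reads
    qc.n_small_families += int((~keep_family).sum())

    fam_map = np.full(len(uniq), -1, dtype=np.int64)
    fam_map[keep_family] = np.arange(int(keep_family.sum()))
    F = int(keep_family.sum())
    qc.n_families += F
    qc.n_reads_in_families += int(counts[keep_family].sum())
    tally.n_families[aid] = F

    fam_of_read = fam_map[inverse]
    n_main = len(uid_strs)
    fam_main = fam_of_read[:n_main]
    fam_odd = fam_of_read[n_main:]

    sel = fam_main >= 0
    Tm, QTm, fm = _BASE_LUT[T[sel]], QT[sel], fam_main[sel]

    # dense per-family base counts: key = fam * (L*5) + pos * 5 + code
    voting_codes = np.where((QTm >= cfg.q_variant) & (Tm < 4), Tm, 4).astype(np.int64)
    if F > 0 and len(Tm):
        pos_idx = np.arange(L, dtype=np.int64)[None, :]
        flat = (fm[:, None] * (L * 5) + pos_idx * 5 + voting_codes).ravel()
        counts5 = np.bincount(flat, minlength=F * L * 5).reshape(F, L, 5)
    else:
        counts5 = np.zeros((F, L, 5), dtype=np.int64)
    base_counts = counts5[:, :, :4]
    voting = base_counts.sum(axis=2)

    sm3 = base_counts > cfg.concordance * voting[:, :, None]       # (F, L, 4)
    wt = sm3[:, np.arange(L), ref_codes]                           # (F, L)
    is_ref = np.zeros((L, 4), dtype=bool)
    is_ref[np.arange(L), ref_codes] = True

    n_sm = sm3.sum(axis=0)
    n_sm[is_ref] = 0
    n_wt = wt.sum(axis=0)
    n_elig = n_sm + n_wt[:, None]
    tally.sub_supermutant[aid] = n_sm
    tally.sub_eligible[aid] = np.where(is_ref, 0, n_elig)

    for p, b in zip(*np.nonzero(n_sm)):
        calls.append(SupermutantCall(
            amplicon_id=aid, position=int(p), ref=amp.insert_seq[p], alt="ACGT"[b],
            n_supermutant_families=int(n_sm[p, b]),
            n_total_families=int(n_elig[p, b]),
            n_ambiguous_families=F - int(n_elig[p, b]),
        ))

    # ---- indel candidates from odd-length families -----------------------
    if not odd:
        return
    odd_by_family: dict[int, list[int]] = defaultdict(list)
    for k, f in enumerate(fam_odd):
        if f >= 0:
            odd_by_family[int(f)].append(k)

    candidates: set[Variant] = set()
    for f, members in odd_by_family.items():
        lens = [len(odd[k][1]) for k in members]
        modal_len = max(set(lens), key=lens.count)
        rows = [np.frombuffer(odd[k][1].encode(), np.uint8) for k in members
                if len(odd[k][1]) == modal_len]
        stack = np.vstack(rows)
        consensus = bytes(
            np.array([np.bincount(stack[:, c], minlength=256).argmax()
                      for c in range(modal_len)], dtype=np.uint8)
        ).decode("ascii")
        var = haplotype_diff(consensus, amp.insert_seq)
        if var is not None and len(var.ref) != len(var.alt):
            candidates.add(var)

    if not candidates:
        return
    # joint scoring: each read votes for the uniquely nearest haplotype among
    # the reference and all candidate alt haplotypes, so a spurious candidate
    # (e.g. from one noisy family consensus) cannot capture reads that match
    # another haplotype better
    variants = sorted(candidates, key=lambda v: (v.position, v.ref, v.alt))
    haps = [
        amp.insert_seq[:v.position] + v.alt + amp.insert_seq[v.position + len(v.ref):]
        for v in variants
    ]
    span_lo = min(max(0, v.position - 2) for v in variants)
    span_hi = max(v.position + len(v.ref) + 2 for v in variants)
    dist_cache: dict[str, int] = {}

    def nearest(tseq: str) -> int:
        """Index of the uniquely nearest haplotype: -1 = ref, -2 = tie."""
        hit = dist_cache.get(tseq)
        if hit is not None:
            return hit
        dists = [edlib.align(tseq, amp.insert_seq, mode="NW")["editDistance"]]
        dists += [edlib.align(tseq, h, mode="NW")["editDistance"] for h in haps]
        best = min(dists)
        winners = [k for k, d in enumerate(dists) if d == best]
        hit = (winners[0] - 1) if len(winners) == 1 else -2
        dist_cache[tseq] = hit
        return hit

    # per family: votes[c] for each candidate, ref votes, total voting reads
    per_family = np.zeros((F, len(variants) + 2), dtype=np.int64)  # [alt..., ref, voting]
    for r in range(len(Tm)):
        f = fm[r]
        quals = QTm[r]
        lo, hi = span_lo, min(L, span_hi)
        if quals[lo:hi].min() < cfg.q_variant:
            continue
        tseq = Tm[r]
        if (tseq == ref_codes).all():
            vote = -1
        else:
            vote = nearest(bytes(b"ACGTN"[c] for c in tseq).decode("ascii"))
        if vote == -2:
            continue
        per_family[f, -1] += 1
        per_family[f, vote if vote >= 0 else -2] += 1
    for k, f in enumerate(fam_odd):
        if f < 0:
            continue
        _, tseq, quals = odd[k]
        lo, hi = span_lo, min(len(quals), span_hi)
        if hi > lo and quals[lo:hi].min() < cfg.q_variant:
            continue
        vote = nearest(tseq)
        if vote == -2:
            continue
        per_family[f, -1] += 1
        per_family[f, vote if vote >= 0 else -2] += 1

    voting_i = per_family[:, -1]
    ref_votes = per_family[:, -2]
    wt_fams = ref_votes > cfg.concordance * voting_i
    for c, var in enumerate(variants):
        alt_votes = per_family[:, c]
        sm_fams = alt_votes > cfg.concordance * voting_i
        n_sm_i = int(sm_fams.sum())
        n_wt_i = int(wt_fams.sum())
        if n_sm_i > 0:
            sc = SupermutantCall(
                amplicon_id=aid, position=var.position, ref=var.ref, alt=var.alt,
                n_supermutant_families=n_sm_i, n_total_families=n_sm_i + n_wt_i,
                n_ambiguous_families=F - n_sm_i - n_wt_i,
            )
            calls.append(sc)
            tally.indel[(aid, var.position, var.ref, var.alt)] = (n_sm_i, n_sm_i + n_wt_i)


# ---------------------------------------------------------------------------
# control model and final calling
# ---------------------------------------------------------------------------

@dataclass
class ControlModel:
    """Per-allele supermutant-fraction background from control samples.

    The decision threshold for an allele is ``mean + multiplier * sd`` of its
    supermutant fraction across controls; alleles never observed in controls
    have mean = sd = 0, so any supermutant passes that gate.
    """

    sub_mean: dict[str, np.ndarray]
    sub_sd: dict[str, np.ndarray]
    indel_stats: dict[tuple[str, int, str, str], tuple[float, float]]
    n_controls: int

    @classmethod
    def build(cls, control_tallies: Sequence[SampleTally]) -> "ControlModel":
        if len(control_tallies) < 2:
            raise ValueError("control model requires >= 2 control samples (sd undefined)")
        amp_ids = sorted({aid for t in control_tallies for aid in t.sub_supermutant})
        sub_mean, sub_sd = {}, {}
        for aid in amp_ids:
            fracs = []
            for t in control_tallies:
                sm = t.sub_supermutant[aid].astype(float)
                el = t.sub_eligible[aid].astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    f = np.where(el > 0, sm / np.where(el > 0, el, 1), 0.0)
                fracs.append(f)
            stack = np.stack(fracs)
            sub_mean[aid] = stack.mean(axis=0)
            sub_sd[aid] = stack.std(axis=0, ddof=1)
        indel_keys = {k for t in control_tallies for k in t.indel}
        indel_stats = {}
        for key in indel_keys:
            vals = []
            for t in control_tallies:
                sm, el = t.indel.get(key, (0, 0))
                vals.append(sm / el if el else 0.0)
            arr = np.asarray(vals)
            indel_stats[key] = (float(arr.mean()), float(arr.std(ddof=1)))
        return cls(sub_mean, sub_sd, indel_stats, len(control_tallies))

    def mean_sd(self, amplicon_id: str, position: int, ref: str, alt: str) -> tuple[float, float]:
        if len(ref) == len(alt) == 1:
            mean = self.sub_mean.get(amplicon_id)
            if mean is None:
                return 0.0, 0.0
            b = "ACGT".index(alt)
            return float(mean[position, b]), float(self.sub_sd[amplicon_id][position, b])
        return self.indel_stats.get((amplicon_id, position, ref, alt), (0.0, 0.0))

    def threshold(self, amplicon_id: str, position: int, ref: str, alt: str,
                  multiplier: float = 5.0) -> float:
        mean, sd = self.mean_sd(amplicon_id, position, ref, alt)
        return mean + multiplier * sd


def build_control_model(control_tallies: Sequence[SampleTally]) -> ControlModel:
    """Build the mean + k*SD background model from >= 2 control samples."""
    return ControlModel.build(control_tallies)


def call_mutations(
    calls: Sequence[SupermutantCall],
    control: ControlModel,
    panel: Panel,
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Apply the three pass gates to supermutant candidates.

    ``final_call`` requires MAF > the 0.1% floor, MAF strictly above the
    control mean + 5 SD threshold, and a non-silent, non-intronic consequence
    (canonical splice sites count as callable).
    """
    cfg = config or CallerConfig()
    out = []
    for sc in calls:
        amp = panel[sc.amplicon_id]
        try:
            consequence = classify(sc.variant, amp)
            label = hgvs_label(sc.variant, amp)
        except ValueError:
            consequence, label = Consequence.NONCODING_, None
        maf = sc.maf
        thr = control.threshold(sc.amplicon_id, sc.position, sc.ref, sc.alt,
                                cfg.control_sd_multiplier)
        out.append(VariantCall(
            call=sc,
            gene=amp.gene,
            consequence=consequence,
            protein_label=label,
            flag_maf_gt_floor=bool(maf == maf and maf > cfg.maf_floor),
            flag_exceeds_control=bool(maf == maf and maf > thr),
            flag_nonsilent=consequence not in SILENT_CLASSES,
        ))
    return out
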