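"""Synthetic UID-tagged amplicon reads and cohort-level simulation.

The read simulator emulates the molecular structure of a UID (molecular
barcode) assay: each template molecule receives a random 14-base UID before
amplification, every read derived from that template carries the UID as its
first 14 cycles, early-PCR errors are shared by a template's whole read family,
and sequencing errors hit individual read bases.  Base qualities are Q30 for
correctly sequenced bases and Q12 for erroneous ones by default, so the
UID-Q15 / variant-Q20 quality gates of the caller are exercised.

The cohort simulator emulates a surgical ovarian-cyst cohort with five
histologic classes (non-neoplastic, benign, borderline, type I, type II
cancer): per-class sample counts, detection probabilities, mutant-allele
fraction (MAF) distributions, cyst-DNA yields, serum CA-125/HE4 levels and
menopausal status.  Its defaults target the published class structure: e.g.
borderline tumors are detected with probability 19/23 and carry BRAF V600E in
12/19 of detected cases, type II cancers carry a TP53 mutation with
probability 0.94, and class MAF distributions are log-normals moment-matched
to the published medians and interquartile ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotate import Consequence, Variant, classify
from .panel import Amplicon, Panel

logger = logging.getLogger(__name__)

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

UID_LENGTH = 14


class FastqRead(NamedTuple):
    """One simulated read: layout = 14-base UID followed by the template portion."""

    name: str
    sequence: str
    quality: str  # Phred+33


def write_fastq(reads: Sequence[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeVariant:
    """A ground-truth variant spiked into simulated templates at a set MAF."""

    amplicon_id: str
    position: int  # 0-based amplicon-local, VCF-style anchor for indels
    ref: str
    alt: str
    true_maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_maf <= 1.0:
            raise ValueError(f"true_maf must be in [0, 1], got {self.true_maf}")

    @property
    def variant(self) -> Variant:
        return Variant(self.position, self.ref, self.alt)


@dataclass(frozen=True)
class SimulationConfig:
    """Read-level simulator knobs.

    ``family_size_mean`` is the Poisson rate of the zero-truncated family-size
    model (reads per template); ``early_pcr_error_rate`` is per template per
    base, applied once and propagated to the whole family; ``seq_error_rate``
    is per read per base.
    """

    n_templates_per_amplicon: int = 3000
    family_size_mean: float = 10.0
    family_size_model: str = "poisson_truncated"  # or "fixed"
    seq_error_rate: float = 1e-3
    early_pcr_error_rate: float = 3e-6
    q_correct: int = 30
    q_error: int = 12
    uid_length: int = UID_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "early_pcr_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.family_size_model not in ("poisson_truncated", "fixed"):
            raise ValueError("family_size_model must be 'poisson_truncated' or 'fixed'")
        if self.family_size_mean <= 0:
            raise ValueError("family_size_mean must be positive")


@dataclass
class Template:
    """One original molecule: its UID and the haplotype it carries."""

    uid: str
    haplotype: str


# ---------------------------------------------------------------------------
# template and read generation
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _apply_spikes(insert: str, spikes: Sequence[SpikeVariant]) -> str:
    """Apply spikes (sorted descending by position so coordinates stay valid)."""
    hap = insert
    for sp in sorted(spikes, key=lambda s: -s.position):
        assert hap[sp.position:sp.position + len(sp.ref)] == sp.ref
        hap = hap[:sp.position] + sp.alt + hap[sp.position + len(sp.ref):]
    return hap


def simulate_templates(
    panel: Panel,
    amplicon_id: str,
    n_templates: int,
    spikes: Sequence[SpikeVariant] = (),
    seed: int | np.random.Generator = 0,
    uid_length: int = UID_LENGTH,
) -> list[Template]:
    """Draw template molecules for one amplicon.

    Each template gets an independent uniform-random UID; it carries each
    spike's alt allele with independent probability ``true_maf``.  UID
    collisions are possible (a real phenomenon) and are logged when the
    collision rate exceeds 1%.
    """
    rng = _as_rng(seed)
    amp = panel[amplicon_id]
    for sp in spikes:
        if sp.amplicon_id != amplicon_id:
            raise ValueError(f"spike {sp} does not reference amplicon {amplicon_id}")
        if amp.insert_seq[sp.position:sp.position + len(sp.ref)] != sp.ref:
            raise ValueError(f"spike ref {sp.ref!r} does not match insert at {sp.position}")

    uid_codes = rng.integers(0, 4, size=(n_templates, uid_length), dtype=np.uint8)
    uid_bytes = _BASE_BYTES[uid_codes]
    uids = [row.tobytes().decode("ascii") for row in uid_bytes]
    n_unique = len(set(uids))
    if n_templates and (n_templates - n_unique) / n_templates > 0.01:
        logger.warning(
            "UID collision rate %.2f%% on %s (%d templates)",
            100 * (n_templates - n_unique) / n_templates, amplicon_id, n_templates,
        )

    carries = np.zeros((n_templates, len(spikes)), dtype=bool)
    for j, sp in enumerate(spikes):
        carries[:, j] = rng.random(n_templates) < sp.true_maf

    # build one haplotype string per distinct spike subset
    hap_cache: dict[tuple[int, ...], str] = {}
    templates = []
    for i in range(n_templates):
        key = tuple(np.flatnonzero(carries[i]))
        hap = hap_cache.get(key)
        if hap is None:
            hap = _apply_spikes(amp.insert_seq, [spikes[j] for j in key])
            hap_cache[key] = hap
        templates.append(Template(uid=uids[i], haplotype=hap))
    return templates


def _family_sizes(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.family_size_model == "fixed":
        return np.full(n, int(round(config.family_size_mean)), dtype=np.int64)
    sizes = rng.poisson(config.family_size_mean, size=n)
    while True:
        zeros = sizes == 0
        if not zeros.any():
            return sizes
        sizes[zeros] = rng.poisson(config.family_size_mean, size=int(zeros.sum()))


def amplify_and_sequence(
    templates: Sequence[Template],
    config: SimulationConfig,
    rng: int | np.random.Generator | None = None,
    read_prefix: str = "read",
) -> list[FastqRead]:
    """Amplify templates into UID families and sequence them with errors.

    Each template yields ``family_size`` reads; early-PCR errors mutate the
    template haplotype once (shared by the whole family); sequencing errors
    hit individual read bases, including UID bases, and are assigned
    ``q_error`` while correct bases get ``q_correct``.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if not templates:
        return []

    # early-PCR errors: substitution-only, once per affected template base
    haps = [t.haplotype for t in templates]
    if config.early_pcr_error_rate > 0:
        for i, t in enumerate(templates):
            k = rng.binomial(len(t.haplotype), config.early_pcr_error_rate)
            if k:
                hap = list(haps[i])
                for p in rng.choice(len(hap), size=k, replace=False):
                    old = _BASE_LUT[ord(hap[p])]
                    hap[p] = "ACGT"[(old + rng.integers(1, 4)) % 4]
                haps[i] = "".join(hap)

    sizes = _family_sizes(len(templates), config, rng)
    reads: list[FastqRead] = []

    # group by read length (haplotypes may differ in length via indel spikes)
    by_len: dict[int, list[int]] = {}
    for i, h in enumerate(haps):
        by_len.setdefault(len(h), []).append(i)

    for hap_len, idx in by_len.items():
        idx = np.asarray(idx)
        fam = sizes[idx]
        n_reads = int(fam.sum())
        read_len = config.uid_length + hap_len
        tmpl_of_read = np.repeat(idx, fam)

        mat = np.empty((n_reads, read_len), dtype=np.uint8)
        uid_codes = np.array(
            [_BASE_LUT[np.frombuffer(templates[i].uid.encode(), np.uint8)] for i in idx],
            dtype=np.uint8,
        )
        hap_codes = np.array(
            [_BASE_LUT[np.frombuffer(haps[i].encode(), np.uint8)] for i in idx],
            dtype=np.uint8,
        )
        rows = np.repeat(np.arange(len(idx)), fam)
        mat[:, :config.uid_length] = uid_codes[rows]
        mat[:, config.uid_length:] = hap_codes[rows]

        quals = np.full((n_reads, read_len), config.q_correct, dtype=np.uint8)
        if config.seq_error_rate > 0:
            err = rng.random((n_reads, read_len)) < config.seq_error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                mat[err] = (mat[err] + shift) % 4
                quals[err] = config.q_error

        seq_bytes = _BASE_BYTES[mat]
        qual_bytes = quals + 33
        for r in range(n_reads):
            reads.append(FastqRead(
                name=f"{read_prefix}:{tmpl_of_read[r]}:{r}",
                sequence=seq_bytes[r].tobytes().decode("ascii"),
                quality=qual_bytes[r].tobytes().decode("ascii"),
            ))
    return reads


def simulate_sample(
    panel: Panel,
    spikes: Sequence[SpikeVariant],
    config: SimulationConfig,
    rng: int | np.random.Generator | None = None,
    sample_id: str = "sample",
) -> list[FastqRead]:
    """Simulate a whole sample: every panel amplicon at the configured depth."""
    rng = _as_rng(config.seed if rng is None else rng)
    reads: list[FastqRead] = []
    for amp in panel:
        amp_spikes = [s for s in spikes if s.amplicon_id == amp.amplicon_id]
        templates = simulate_templates(
            panel, amp.amplicon_id, config.n_templates_per_amplicon,
            amp_spikes, rng, config.uid_length,
        )
        reads.extend(amplify_and_sequence(
            templates, config, rng, read_prefix=f"{sample_id}:{amp.amplicon_id}",
        ))
    return reads


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

CLASSES = ("non_neoplastic", "benign", "borderline", "type1", "type2")
SURGERY_CLASSES = frozenset({"borderline", "type1", "type2"})

_Z75 = norm.ppf(0.75)  # 0.6744898


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and interquartile range."""
    if not 0 < q1 <= median <= q3:
        raise ValueError("need 0 < q1 <= median <= q3")
    sigma = (math.log(q3) - math.log(q1)) / (2 * _Z75)
    return math.log(median), sigma


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


@dataclass(frozen=True)
class ClassParams:
    """Per-histology generation targets."""

    n: int
    detection_prob: float
    maf_median: float | None = None  # as fractions, e.g. 0.024
    maf_q1: float | None = None
    maf_q3: float | None = None

    def maf_lognormal(self) -> tuple[float, float]:
        if self.maf_median is None:
            raise ValueError("class has no MAF distribution")
        return lognormal_from_median_iqr(self.maf_median, self.maf_q1, self.maf_q3)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation targets.

    Defaults emulate the published surgical cohort with sufficient DNA for
    sequencing: class counts (6, 12, 23, 13, 18), detection probabilities
    equal to the published detection fractions, and class MAF log-normals
    matched to the published medians/IQRs.  DNA yields are wide log-normals
    (median 400 ng, sigma 2.3 for surgical classes vs 44 ng, sigma 0.85
    otherwise): strongly different in rank terms yet heavily overlapping, so
    DNA amount is univariately significant while adding little to the
    multivariate model once mutation status is known.  CA-125 medians 70 vs
    15 U/mL put roughly 28% of surgical-class vs 89% of benign-class
    patients below the 35 U/mL normal cutoff (a moderate association); HE4
    is class-independent, emulating its published non-association.
    """

    classes: dict = field(default_factory=lambda: {
        "non_neoplastic": ClassParams(n=6, detection_prob=0.0),
        "benign": ClassParams(n=12, detection_prob=0.0),
        "borderline": ClassParams(n=23, detection_prob=19 / 23,
                                  maf_median=0.024, maf_q1=0.015, maf_q3=0.108),
        "type1": ClassParams(n=13, detection_prob=10 / 13,
                             maf_median=0.078, maf_q1=0.033, maf_q3=0.287),
        "type2": ClassParams(n=18, detection_prob=1.0,
                             maf_median=0.603, maf_q1=0.313, maf_q3=0.708),
    })
    braf_fraction_borderline: float = 12 / 19
    tp53_prob_type2: float = 0.94
    type1_gene_weights: dict = field(default_factory=lambda: {
        "KRAS": 5, "TP53": 3, "BRAF": 1, "NRAS": 1,
        "PIK3R1": 1, "PPP2R1A": 1, "PTEN": 1,
    })
    early_prob_type1: float = 8 / 13
    early_prob_type2: float = 3 / 18
    dna_surgery: tuple[float, float] = (400.0, 2.3)    # log-normal (median ng, sigma)
    dna_benign: tuple[float, float] = (44.0, 0.85)
    ca125_surgery: tuple[float, float] = (70.0, 1.2)   # log-normal (median U/mL, sigma)
    ca125_benign: tuple[float, float] = (15.0, 0.7)
    he4: tuple[float, float] = (70.0, 0.55)            # pmol/L, class-independent
    menopause_prop: float = 0.5
    maf_clip: tuple[float, float] = (1e-4, 0.98)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cp in self.classes.items():
            if cp.n < 0 or not 0.0 <= cp.detection_prob <= 1.0:
                raise ValueError(f"invalid class parameters for {name}")


# --- spike catalog ---------------------------------------------------------

def _first_missense(amp: Amplicon) -> tuple[int, str, str] | None:
    for pos in amp.exonic_positions:
        ref = amp.insert_seq[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            try:
                cls = classify(Variant(pos, ref, alt), amp)
            except ValueError:
                continue
            if cls is Consequence.MISSENSE:
                return pos, ref, alt
    return None


def _inframe_deletion(amp: Amplicon, length: int = 6) -> tuple[int, str, str] | None:
    for start, end in amp.exon_intervals:
        for pos in range(start, end - length - 1):
            ref = amp.insert_seq[pos:pos + length + 1]
            alt = ref[0]
            try:
                cls = classify(Variant(pos, ref, alt), amp)
            except ValueError:
                continue
            if cls is Consequence.INFRAME_INDEL:
                return pos, ref, alt
    return None


def spike_catalog(panel: Panel) -> dict[str, list[tuple[str, int, str, str]]]:
    """Per-gene deterministic candidate mutations usable as simulation spikes.

    Prefers literature-style anchors when the toy panel provides them: BRAF
    V600E (GTG->GAG at codon 600) and a 6-nt in-frame deletion for PIK3R1.
    Returns ``gene -> [(amplicon_id, position, ref, alt), ...]``.
    """
    catalog: dict[str, list[tuple[str, int, str, str]]] = {}
    for gene in sorted(panel.genes):
        entries: list[tuple[str, int, str, str]] = []
        for amp in panel.by_gene(gene):
            if gene == "BRAF" and amp.cds_strand == "+":
                c600 = 600 - amp.codon_offset
                start = amp.cds_frame + 3 * c600
                if 0 <= start and start + 3 <= len(amp.exonic_positions):
                    pos = amp.exonic_positions[start + 1]
                    if amp.insert_seq[pos - 1:pos + 2] == "GTG":
                        entries.append((amp.amplicon_id, pos, "T", "A"))  # GTG->GAG = V600E
            if gene == "PIK3R1":
                hit = _inframe_deletion(amp)
                if hit:
                    entries.append((amp.amplicon_id, *hit))
            hit = _first_missense(amp)
            if hit:
                entries.append((amp.amplicon_id, *hit))
        if entries:
            catalog[gene] = entries
    return catalog


# --- cohort draw -----------------------------------------------------------

def simulate_cohort(
    panel: Panel,
    config: CohortConfig,
    rng: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[SpikeVariant]]]:
    """Draw a cohort: sample table, ground-truth variant table and spike lists.

    Non-neoplastic and benign samples receive no spiked variants.  Detected
    borderline samples draw BRAF V600E vs a KRAS mutation; detected type I
    samples draw from the type-I gene set; detected type II samples carry a
    TP53 mutation with probability ``tp53_prob_type2`` (else a non-TP53 gene).
    Sample MAFs come from the class log-normals, clipped to ``maf_clip``.

    Returns ``(samples, truth, spikes_by_sample)`` where ``truth`` has one row
    per spiked variant with 1-based exported positions.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    catalog = spike_catalog(panel)

    def gene_spike(gene: str, maf: float, prefer_indel: bool = False) -> SpikeVariant:
        entries = catalog.get(gene)
        if not entries:
            if not catalog:
                raise ValueError("panel has no usable spike sites")
            fallback = sorted(catalog)[0]
            logger.warning("panel has no spike site for %s; using %s", gene, fallback)
            entries = catalog[fallback]
        if prefer_indel:
            indels = [e for e in entries if len(e[2]) != len(e[3])]
            if indels:
                entries = indels
        aid, pos, ref, alt = entries[0]
        return SpikeVariant(aid, pos, ref, alt, maf)

    sample_rows = []
    truth_rows = []
    spikes_by_sample: dict[str, list[SpikeVariant]] = {}
    counter = 0

    for cls_name in CLASSES:
        cp = config.classes[cls_name]
        surgery = cls_name in SURGERY_CLASSES
        dna_median, dna_sigma = config.dna_surgery if surgery else config.dna_benign
        ca_median, ca_sigma = config.ca125_surgery if surgery else config.ca125_benign
        for _ in range(cp.n):
            counter += 1
            sid = f"CYST{counter:03d}"
            menopause = "post" if rng.random() < config.menopause_prop else "pre"
            detected = surgery and rng.random() < cp.detection_prob
            dna_ng = float(np.exp(rng.normal(math.log(dna_median), dna_sigma)))
            ca125 = float(np.exp(rng.normal(math.log(ca_median), ca_sigma)))
            he4 = float(np.exp(rng.normal(math.log(config.he4[0]), config.he4[1])))

            if cls_name == "borderline":
                stage = "I"
            elif cls_name == "type1":
                stage = ("I" if rng.random() < 0.5 else "II") \
                    if rng.random() < config.early_prob_type1 else \
                    ("III" if rng.random() < 0.5 else "IV")
            elif cls_name == "type2":
                stage = ("I" if rng.random() < 0.5 else "II") \
                    if rng.random() < config.early_prob_type2 else \
                    ("III" if rng.random() < 0.5 else "IV")
            else:
                stage = "NA"

            spikes: list[SpikeVariant] = []
            if detected:
                mu, sigma = cp.maf_lognormal()
                maf = float(np.clip(np.exp(rng.normal(mu, sigma)), *config.maf_clip))
                if cls_name == "borderline":
                    gene = "BRAF" if rng.random() < config.braf_fraction_borderline else "KRAS"
                    spikes.append(gene_spike(gene, maf))
                elif cls_name == "type1":
                    genes = sorted(g for g in config.type1_gene_weights if g in catalog)
                    weights = np.array([config.type1_gene_weights[g] for g in genes], float)
                    gene = genes[rng.choice(len(genes), p=weights / weights.sum())]
                    spikes.append(gene_spike(gene, maf, prefer_indel=(gene == "PIK3R1")))
                else:  # type2
                    if rng.random() < config.tp53_prob_type2:
                        gene = "TP53"
                    else:
                        others = sorted(g for g in catalog if g != "TP53")
                        gene = others[int(rng.integers(len(others)))] if others else "TP53"
                    spikes.append(gene_spike(gene, maf))

            spikes_by_sample[sid] = spikes
            for sp in spikes:
                truth_rows.append({
                    "sample_id": sid, "amplicon_id": sp.amplicon_id,
                    "pos_1based": sp.position + 1, "ref": sp.ref, "alt": sp.alt,
                    "true_maf": sp.true_maf,
                })
            sample_rows.append({
                "sample_id": sid, "cyst_class": cls_name, "stage": stage,
                "dna_ng": round(dna_ng, 1), "ca125": round(ca125, 1),
                "he4": round(he4, 1), "menopause": menopause,
            })

    samples = pd.DataFrame(sample_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "amplicon_id", "pos_1based", "ref", "alt", "true_maf"],
    )
    return samples, truth, spikes_by_sample
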