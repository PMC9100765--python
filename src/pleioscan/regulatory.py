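"""Allele-aware transcription-factor binding-site scanning (pipeline Phase 1).

Identifies regulatory SNPs (rSNPs): promoter SNPs whose allele change
creates ("Gain") or destroys ("Loss") a predicted TF binding site.  For each
SNP inside a promoter window (default -500..+100 bp around the TSS, in
transcription direction) the two allele-specific 51-base flanking sequences
are scanned against a PWM library with an information-weighted matrix
similarity score (MSS) normalized to [0, 1], plus a "core" score restricted
to the five most informative consecutive motif positions.  A TF's site is
"present" in a sequence when at least one window passes both score cutoffs;
Gain/Loss is the asymmetric presence between the two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .util import logger

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

FLANK = 25          # bases either side of the SNP
WINDOW = 2 * FLANK + 1  # 51-base allele-specific window, SNP central
CORE_LEN = 5

DEFAULT_MSS_CUTOFF = 0.95
DEFAULT_CORE_CUTOFF = 0.90
DEFAULT_MAF_FLOOR = 0.05
DEFAULT_UPSTREAM = 500
DEFAULT_DOWNSTREAM = 100

GAIN = "Gain"
LOSS = "Loss"
NO_STRONG_EFFECT = "NoStrongEffect"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other base (e.g. N) maps to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def information_vector(freq: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) * ln(4 f(i,b)).

    Zero at a uniform position, ln 4 at a single-base position; the 0*ln(0)
    terms are taken as 0.
    """
    f = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=1)


@dataclass
class PWM:
    """A position weight matrix: per-position base frequencies over A,C,G,T."""

    name: str
    freq: np.ndarray  # shape (length, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: frequency matrix must be (L, 4)")
        rowsums = self.freq.sum(axis=1)
        if np.any(self.freq < -1e-12) or np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.name}: rows must be frequencies summing to 1")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def info(self) -> np.ndarray:
        return information_vector(self.freq)

    @property
    def core_positions(self) -> range:
        """Contiguous run of min(5, length) positions maximizing summed I(i)."""
        k = min(CORE_LEN, self.length)
        info = self.info
        sums = np.convolve(info, np.ones(k), mode="valid")
        start = int(np.argmax(sums))  # first maximizer: deterministic
        return range(start, start + k)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freq, axis=1))

    @property
    def is_scorable(self) -> bool:
        """False when every position is uniform (Max == Min)."""
        info = self.info
        weighted = info[:, None] * self.freq
        return float(weighted.max(1).sum() - weighted.min(1).sum()) > 1e-12


@dataclass
class SNPRecord:
    """A biallelic SNP with line dosages (alt-allele count; NaN = missing)."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.id}: only single-nucleotide alleles supported")

    @property
    def maf(self) -> float:
        return compute_maf(self.dosages)


@dataclass
class GeneAnnotation:
    """A gene model; the TSS is the start on + strand, the end on - strand."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end
        raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class FlankingPair:
    """The two allele-specific 51-base windows around a SNP (SNP central)."""

    snp_id: str
    ref_seq: str
    alt_seq: str
    snp_index: int = FLANK + 1  # 1-based central position (26)


@dataclass
class TFBSHit:
    pwm_name: str
    strand: str  # '+' or '-'
    offset: int  # 0-based start of the match within the scanned window
    mss: float
    core: float


@dataclass
class RegulatoryConsequence:
    snp_id: str
    gene_id: str
    pwm_name: str
    effect: str  # Gain | Loss | NoStrongEffect
    best_ref_mss: float = 0.0
    best_alt_mss: float = 0.0


# ---------------------------------------------------------------------------
# SNP filtering and promoter assignment


def compute_maf(dosages: Sequence[float]) -> float:
    """Minor-allele frequency: min(p, 1-p) of the alt-allele frequency.

    Missing dosages (NaN) are excluded from both numerator and denominator.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("MAF undefined: all dosages missing")
    p = float(d.sum()) / (2.0 * d.size)
    return min(p, 1.0 - p)


def filter_snps_by_maf(snps: Iterable[SNPRecord], floor: float = DEFAULT_MAF_FLOOR) -> list[SNPRecord]:
    """Discard SNPs with MAF strictly below ``floor`` (boundary is kept)."""
    return [s for s in snps if s.maf >= floor]


def select_promoter_snps(
    snps: Iterable[SNPRecord],
    annotations: Iterable[GeneAnnotation],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[tuple[SNPRecord, str]]:
    """Assign SNPs to genes whose promoter window contains them.

    The window is [-upstream, +downstream] around the TSS *in transcription
    direction*: for a minus-strand gene it maps to genomic
    [TSS - downstream, TSS + upstream].  A SNP may pair with several genes.
    """
    genes = []
    for ann in annotations:
        if ann.strand not in ("+", "-"):
            logger.warning("gene %s: unknown strand %r, skipped", ann.gene_id, ann.strand)
            continue
        genes.append(ann)
    pairs: list[tuple[SNPRecord, str]] = []
    for snp in snps:
        for ann in genes:
            if ann.chrom != snp.chrom:
                continue
            offset = snp.pos - ann.tss if ann.strand == "+" else ann.tss - snp.pos
            if -upstream <= offset <= downstream:
                pairs.append((snp, ann.gene_id))
    return pairs


def extract_allele_sequences(
    snp: SNPRecord, genome: Mapping[str, str], flank: int = FLANK
) -> FlankingPair:
    """Extract the ref/alt allele-specific windows of 2*flank+1 bases.

    Raises ``KeyError`` on an unknown contig and ``ValueError`` when the
    genomic base at the SNP position differs from the VCF ref allele.
    Returns ``None``-equivalent by raising ``IndexError`` when the SNP sits
    closer than ``flank`` bases to a contig end (caller skips with warning).
    """
    contig = genome[snp.chrom]
    i = snp.pos - 1  # 0-based
    if i - flank < 0 or i + flank >= len(contig):
        raise IndexError(f"{snp.id}: fewer than {flank} bases of context")
    window = str(contig[i - flank : i + flank + 1]).upper()
    if window[flank] != snp.ref.upper():
        raise ValueError(
            f"{snp.id}: genome base {window[flank]} at {snp.chrom}:{snp.pos} "
            f"does not match VCF ref allele {snp.ref}"
        )
    alt_seq = window[:flank] + snp.alt.upper() + window[flank + 1 :]
    return FlankingPair(snp_id=snp.id, ref_seq=window, alt_seq=alt_seq, snp_index=flank + 1)


# ---------------------------------------------------------------------------
# MATCH-style scoring


def _score_bounds(pwm: PWM) -> tuple[np.ndarray, float, float, float, float]:
    """Weighted score matrix and (min, max) attainable sums, full and core."""
    weighted = pwm.info[:, None] * pwm.freq  # (L, 4)
    lo, hi = weighted.min(1), weighted.max(1)
    core = pwm.core_positions
    return weighted, float(lo.sum()), float(hi.sum()), float(lo[core.start:core.stop].sum()), float(hi[core.start:core.stop].sum())


def matrix_similarity_score(pwm: PWM, window_seq: str) -> tuple[float, float]:
    """(mss, core) of one window of exactly motif length.

    mss = (Current - Min) / (Max - Min) with Current = sum_i I(i) f(i, s_i);
    the core score is the same quantity over the 5 most informative
    consecutive positions.  Both are clamped to [0, 1].
    """
    if len(window_seq) != pwm.length:
        raise ValueError("window length must equal motif length")
    if not pwm.is_scorable:
        raise ValueError(f"PWM {pwm.name} is unscorable (all positions uniform)")
    idx = encode_sequence(window_seq)
    if np.any(idx < 0):
        raise ValueError("window contains non-ACGT bases")
    weighted, lo, hi, core_lo, core_hi = _score_bounds(pwm)
    current = weighted[np.arange(pwm.length), idx]
    mss = (float(current.sum()) - lo) / (hi - lo)
    core = pwm.core_positions
    denom = core_hi - core_lo
    core_score = (
        (float(current[core.start : core.stop].sum()) - core_lo) / denom if denom > 1e-12 else 1.0
    )
    return float(np.clip(mss, 0.0, 1.0)), float(np.clip(core_score, 0.0, 1.0))


def _scan_one_strand(encoded: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mss, core) for every offset of a strand; NaN at N-bases."""
    L = pwm.length
    weighted, lo, hi, core_lo, core_hi = _score_bounds(pwm)
    n_off = encoded.size - L + 1
    if n_off <= 0:
        return np.empty(0), np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)  # (n_off, L)
    valid = np.all(windows >= 0, axis=1)
    safe = np.where(windows >= 0, windows, 0)
    per_pos = weighted[np.arange(L)[None, :], safe]  # (n_off, L)
    mss = (per_pos.sum(1) - lo) / (hi - lo)
    core = pwm.core_positions
    denom = core_hi - core_lo
    if denom > 1e-12:
        core_s = (per_pos[:, core.start : core.stop].sum(1) - core_lo) / denom
    else:
        core_s = np.ones(n_off)
    mss = np.where(valid, np.clip(mss, 0, 1), np.nan)
    core_s = np.where(valid, np.clip(core_s, 0, 1), np.nan)
    return mss, core_s


def scan_sequence(
    seq: str,
    pwm: PWM,
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
) -> list[TFBSHit]:
    """All passing motif matches on both strands of ``seq``.

    A minus-strand hit at reported offset j covers the same bases
    seq[j : j+L] as a plus-strand hit would; windows containing ambiguous
    bases are skipped.
    """
    if not pwm.is_scorable:
        logger.warning("PWM %s unscorable (uniform), excluded from scanning", pwm.name)
        return []
    L = pwm.length
    if len(seq) < L:
        return []
    fwd = encode_sequence(seq)
    rev = encode_sequence(reverse_complement(seq))
    hits: list[TFBSHit] = []
    for strand, enc in (("+", fwd), ("-", rev)):
        mss, core = _scan_one_strand(enc, pwm)
        for j in np.nonzero((mss >= mss_cutoff) & (core >= core_cutoff))[0]:
            offset = int(j) if strand == "+" else len(seq) - L - int(j)
            hits.append(TFBSHit(pwm.name, strand, offset, float(mss[j]), float(core[j])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def classify_consequence(
    pair: FlankingPair,
    pwm: PWM,
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    gene_id: str = "",
) -> RegulatoryConsequence:
    """Gain / Loss / NoStrongEffect of the SNP on this TF's binding.

    Loss: the TF has >= 1 passing hit in the reference-allele window and none
    in the alternate-allele window; Gain is the converse; anything else
    (including hits in both windows with slightly changed scores) is
    NoStrongEffect.
    """
    ref_hits = scan_sequence(pair.ref_seq, pwm, mss_cutoff, core_cutoff)
    alt_hits = scan_sequence(pair.alt_seq, pwm, mss_cutoff, core_cutoff)
    if ref_hits and not alt_hits:
        effect = LOSS
    elif alt_hits and not ref_hits:
        effect = GAIN
    else:
        effect = NO_STRONG_EFFECT
    return RegulatoryConsequence(
        snp_id=pair.snp_id,
        gene_id=gene_id,
        pwm_name=pwm.name,
        effect=effect,
        best_ref_mss=max((h.mss for h in ref_hits), default=0.0),
        best_alt_mss=max((h.mss for h in alt_hits), default=0.0),
    )


def identify_rsnps(
    snps: Iterable[SNPRecord],
    genome: Mapping[str, str],
    annotations: Iterable[GeneAnnotation],
    pwm_library: Sequence[PWM],
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[RegulatoryConsequence]:
    """Full Phase-1 sweep: promoter SNP x PWM Gain/Loss calls.

    Returns only Gain/Loss records (a SNP with none is not an rSNP), sorted
    by (snp id, gene id, pwm name).
    """
    pairs = select_promoter_snps(snps, annotations, upstream, downstream)
    flank_cache: dict[str, FlankingPair | None] = {}
    out: list[RegulatoryConsequence] = []
    for snp, gene_id in pairs:
        if snp.id not in flank_cache:
            try:
                flank_cache[snp.id] = extract_allele_sequences(snp, genome)
            except IndexError as exc:
                logger.warning("%s", exc)
                flank_cache[snp.id] = None
        pair = flank_cache[snp.id]
        if pair is None:
            continue
        for pwm in pwm_library:
            if not pwm.is_scorable:
                logger.warning("PWM %s unscorable, skipped", pwm.name)
                continue
            cons = classify_consequence(pair, pwm, mss_cutoff, core_cutoff, gene_id)
            if cons.effect in (GAIN, LOSS):
                out.append(cons)
    out.sort(key=lambda c: (c.snp_id, c.gene_id, c.pwm_name))
    return out
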