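"""Promoter-window extraction and known-motif PWM enrichment.

Motifs are JASPAR-style count matrices converted to log2-odds over a
background base composition.  Scanning follows the ZOOPS convention: a
promoter "has" a motif when its best site on either strand reaches a
configurable fraction (default 0.8) of the motif's maximum attainable
log-odds score.  Enrichment compares the fraction of target promoters
with a hit against a background promoter set with an exact
hypergeometric tail, BH-corrected across motifs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from votesig.enrichment import bh_adjust, hypergeom_tail

__all__ = [
    "PositionWeightMatrix",
    "PromoterWindow",
    "PromoterSet",
    "MotifEnrichmentRow",
    "load_motifs",
    "pwm_log_odds",
    "best_site_score",
    "has_hit",
    "extract_windows",
    "motif_enrichment",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N
LOG_ODDS_FLOOR = -30.0  # per-column floor replacing -inf at zero probability


@dataclass
class PositionWeightMatrix:
    """A motif as a 4 x L count matrix plus scoring conventions."""

    motif_id: str
    counts: np.ndarray  # shape (4, L), rows A, C, G, T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.5
    score_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id!r}: counts must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id!r}: negative count")
        if self.pseudocount < 0:
            raise ValueError(f"motif {self.motif_id!r}: negative pseudocount")
        col_tot = self.counts.sum(axis=0) + self.pseudocount
        if (col_tot <= 0).any():
            raise ValueError(f"motif {self.motif_id!r}: zero column total with zero pseudocount")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id!r}: background must sum to 1")
        if not 0 < self.score_fraction <= 1:
            raise ValueError(f"motif {self.motif_id!r}: score_fraction must lie in (0, 1]")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


def load_motifs(path: str | Path) -> list[PositionWeightMatrix]:
    """Parse a (possibly multi-record) JASPAR-style count-matrix file."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    # a JASPAR block is a >header line plus exactly four count rows
    for block in text.split(">")[1:]:
        rows = [ln for ln in block.splitlines()[1:] if ln.strip()]
        if len(rows) != 4:
            raise ValueError(
                f"{path}: malformed motif block {block.splitlines()[0]!r}: "
                f"expected 4 count rows, found {len(rows)}"
            )
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            out.append(PositionWeightMatrix(motif_id=m.matrix_id or m.name, counts=counts))
        return out
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: malformed motif file: {exc}") from exc


def write_motifs(pwms: list[PositionWeightMatrix], path: str | Path) -> None:
    """Write motifs in JASPAR count-matrix format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for i, base in enumerate(ALPHABET):
                row = " ".join(f"{v:.2f}" for v in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def pwm_log_odds(pwm: PositionWeightMatrix) -> np.ndarray:
    """4 x L log2-odds matrix: log2 p(base|position) - log2 p(base|bg).

    Probabilities use background-proportional pseudocounts; -inf entries
    (zero probability with zero pseudocount) are floored at -30 to keep
    scores finite.
    """
    col_tot = pwm.counts.sum(axis=0) + pwm.pseudocount
    probs = (pwm.counts + pwm.pseudocount * pwm.background[:, None]) / col_tot[None, :]
    with np.errstate(divide="ignore"):
        lo = np.log2(probs) - np.log2(pwm.background)[:, None]
    return np.maximum(lo, LOG_ODDS_FLOOR)


def max_score(pwm: PositionWeightMatrix) -> float:
    """Maximum attainable log-odds score (sum of per-column maxima)."""
    return float(pwm_log_odds(pwm).max(axis=0).sum())


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string (case-insensitive) as integer codes."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGTN character {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_codes(codes: np.ndarray, lo5: np.ndarray) -> float:
    L = lo5.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return float(lo5[windows, np.arange(L)].sum(axis=1).max())


def _lo5(pwm: PositionWeightMatrix) -> np.ndarray:
    """Log-odds with an appended all-zero row so code 4 (N) scores 0."""
    lo = pwm_log_odds(pwm)
    return np.vstack([lo, np.zeros(lo.shape[1])])


def best_site_score(seq: str, pwm: PositionWeightMatrix) -> float:
    """Maximum summed log-odds over both strands and all offsets.

    N positions contribute 0.  Symmetric under reverse complement of the
    input sequence.
    """
    if len(seq) < pwm.length:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {pwm.length}")
    lo5 = _lo5(pwm)
    codes = encode(seq)
    rc = _COMPLEMENT_CODE[codes][::-1]
    return max(_scan_codes(codes, lo5), _scan_codes(rc, lo5))


def has_hit(seq: str, pwm: PositionWeightMatrix) -> bool:
    """ZOOPS occurrence: best site >= score_fraction x max attainable."""
    return best_site_score(seq, pwm) >= pwm.score_fraction * max_score(pwm)


@dataclass
class PromoterWindow:
    """One promoter-proximal sequence anchored at a TSS."""

    gene_id: str
    sequence: str
    rel_start: int = -500
    rel_end: int = 500
    strand: str = "+"
    truncated: bool = False

    def __post_init__(self) -> None:
        expected = self.rel_end - self.rel_start + 1
        if not self.truncated and len(self.sequence) != expected:
            raise ValueError(
                f"{self.gene_id}: window length {len(self.sequence)} != {expected} and not flagged truncated"
            )


@dataclass
class PromoterSet:
    """Ordered collection of promoter windows keyed by gene id."""

    windows: dict[str, PromoterWindow] = field(default_factory=dict)
    plants: dict[str, tuple[int, str]] = field(default_factory=dict)  # gene -> (pos, strand) of planted sites

    def __len__(self) -> int:
        return len(self.windows)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.windows

    def sequence(self, gene_id: str) -> str:
        return self.windows[gene_id].sequence

    def subset(self, gene_ids) -> "PromoterSet":
        keep = [g for g in gene_ids if g in self.windows]
        return PromoterSet(windows={g: self.windows[g] for g in keep})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "PromoterSet":
        windows: dict[str, PromoterWindow] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            windows[rec.id] = PromoterWindow(
                gene_id=rec.id, sequence=seq, rel_start=0, rel_end=len(seq) - 1
            )
        return cls(windows=windows)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(w.sequence), id=g, description="")
            for g, w in self.windows.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def _parse_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.append((chrom, int(start), int(end), name, strand))
    return rows


def extract_windows(tss_bed: str | Path, genome_fasta: str | Path, window_half: int = 500) -> PromoterSet:
    """Extract TSS +/- window_half promoter windows from a genome.

    BED is 0-based half-open; the TSS is the start coordinate on the +
    strand and end-1 on the - strand.  A + strand window is the genomic
    slice [t - window_half, t + window_half + 1); a - strand window is
    the mirror-image slice reverse-complemented.  Windows clipped at a
    contig edge are flagged ``truncated``.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    windows: dict[str, PromoterWindow] = {}
    for chrom, start, end, name, strand in _parse_bed6(tss_bed):
        if chrom not in genome:
            raise ValueError(f"contig {chrom!r} missing from {genome_fasta}")
        contig_len = len(genome[chrom])
        t = start if strand == "+" else end - 1
        lo = t - window_half
        hi = t + window_half + 1  # half-open
        clipped_lo, clipped_hi = max(lo, 0), min(hi, contig_len)
        seq = str(genome[chrom][clipped_lo:clipped_hi])
        truncated = (clipped_lo != lo) or (clipped_hi != hi)
        if strand == "-":
            seq = reverse_complement(seq)
        windows[name] = PromoterWindow(
            gene_id=name,
            sequence=seq,
            rel_start=-window_half,
            rel_end=window_half,
            strand=strand,
            truncated=truncated,
        )
    return PromoterSet(windows=windows)


@dataclass(frozen=True)
class MotifEnrichmentRow:
    motif_id: str
    target_with_hit: int
    target_total: int
    background_with_hit: int
    background_total: int
    p_raw: float
    p_adj: float


def motif_enrichment(
    targets: PromoterSet,
    background: PromoterSet,
    pwms: list[PositionWeightMatrix],
    config=None,
) -> list[MotifEnrichmentRow]:
    """Per-motif hypergeometric enrichment of ZOOPS hits in target vs
    background promoters, BH-adjusted across motifs.

    Any gene present in both sets is removed from the background so the
    two sets are disjoint.
    """
    if len(targets) == 0:
        raise ValueError("empty target promoter set")
    bg = background.subset(g for g in background.windows if g not in targets)
    rows: list[tuple[str, int, int]] = []
    for pwm in pwms:
        threshold = pwm.score_fraction * max_score(pwm)
        lo5 = _lo5(pwm)
        t_hits = b_hits = 0
        for pset, bump in ((targets, "t"), (bg, "b")):
            for w in pset.windows.values():
                codes = encode(w.sequence)
                if len(codes) < pwm.length:
                    continue
                rc = _COMPLEMENT_CODE[codes][::-1]
                score = max(_scan_codes(codes, lo5), _scan_codes(rc, lo5))
                if score >= threshold:
                    if bump == "t":
                        t_hits += 1
                    else:
                        b_hits += 1
        rows.append((pwm.motif_id, t_hits, b_hits))
    n_t, n_b = len(targets), len(bg)
    praw = [
        hypergeom_tail(t, t + b, n_t, n_t + n_b) if (t + b) <= (n_t + n_b) else 1.0
        for _, t, b in rows
    ]
    padj = bh_adjust(praw)
    out = [
        MotifEnrichmentRow(
            motif_id=m,
            target_with_hit=t,
            target_total=n_t,
            background_with_hit=b,
            background_total=n_b,
            p_raw=p,
            p_adj=pa,
        )
        for (m, t, b), p, pa in zip(rows, praw, padj)
    ]
    out.sort(key=lambda r: (r.p_raw, r.motif_id))
    return out


def motif_enrichment_to_tsv(rows: list[MotifEnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttarget_with_hit\ttarget_total\tbackground_with_hit\tbackground_total\tp_raw\tp_adj\n")
        for r in rows:
            fh.write(
                f"{r.motif_id}\t{r.target_with_hit}\t{r.target_total}\t"
                f"{r.background_with_hit}\t{r.background_total}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\n"
            )
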