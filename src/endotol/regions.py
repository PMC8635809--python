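"""CpG-centric regulatory enrichment.

Three analytics share the 2x2 Fisher machinery:

* motif enrichment — PWM log-odds scanning of +/-250 bp windows around
  target CpGs versus array-background CpG windows (HOMER known-motif style);
* tile-wise peak profiles — Fisher odds ratios per 10 bp tile up to
  +/-3 kb around CpGs, target versus background, against a peak BED
  (histone marks, accessibility);
* genomic-category enrichment — feature / CpG-island-context labels of
  target CpGs versus background.

Odds ratios use the Haldane-Anscombe 0.5 correction whenever a cell is
zero; Fisher tests are two-sided; BH adjustment is applied across motifs,
tiles, or labels respectively. Any >=1 bp overlap counts as a hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, PWM, reverse_complement
from .methylation import bh_fdr

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# windows and 2x2 helpers

def windows_around(cpgs: Sequence[GenomicInterval], flank: int = 250) -> list[GenomicInterval]:
    """+/-flank bp windows around 1-bp CpG positions, clamped at 0."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out = []
    for c in cpgs:
        out.append(
            GenomicInterval(c.chrom, max(0, c.start - flank), c.start + flank + 1,
                            strand=c.strand, name=c.name)
        )
    return out


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio ad/bc, 0.5-corrected when any cell is zero."""
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_record(label: str, a: int, b: int, c: int, d: int) -> dict:
    """EnrichmentRecord row: counts, corrected OR, two-sided Fisher p."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "label": label,
        "target_hit": a,
        "target_miss": b,
        "background_hit": c,
        "background_miss": d,
        "odds_ratio": odds_ratio(a, b, c, d),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# PWM scanning

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(code: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; NaN where the L-mer has an N."""
    L = lom.shape[1]
    n = len(code) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        window = code[j : j + n]
        bad = window < 0
        valid &= ~bad
        scores += lom[np.clip(window, 0, 3), j]
    scores[~valid] = np.nan
    return scores


def pwm_scan(
    seq: str,
    pwm: PWM,
    threshold: float,
    both_strands: bool = True,
) -> list[tuple[int, str, float]]:
    """All positions with log-odds score >= threshold, sorted by position.

    Positions are 0-based starts of the L-mer on the forward strand; minus-
    strand hits are reported at their forward-strand start. L-mers containing
    N are skipped. A sequence shorter than the motif yields no hits.
    """
    lom = pwm.log_odds
    L = pwm.length
    hits: list[tuple[int, str, float]] = []
    code = _encode(seq)
    fwd = _scan_one_strand(code, lom)
    for pos in np.flatnonzero(np.nan_to_num(fwd, nan=-np.inf) >= threshold):
        hits.append((int(pos), "+", float(fwd[pos])))
    if both_strands:
        rc = _encode(reverse_complement(seq))
        rev = _scan_one_strand(rc, lom)
        n = len(seq)
        for pos in np.flatnonzero(np.nan_to_num(rev, nan=-np.inf) >= threshold):
            hits.append((int(n - L - pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def threshold_from_fraction(pwm: PWM, fraction: float = 0.8) -> float:
    """Absolute log-odds threshold as a fraction of the maximum achievable score."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * pwm.max_score


def motif_enrichment(
    target_windows: Sequence[GenomicInterval],
    background_windows: Sequence[GenomicInterval],
    fasta,
    pwms: Sequence[PWM],
    threshold: float | None = None,
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of PWM occurrences in target vs background.

    ``fasta`` is a pyfaidx.Fasta (or a path to one). A window is a hit when
    it contains >=1 occurrence on either strand at the threshold (absolute
    log-odds if ``threshold`` given, else ``score_fraction`` of each motif's
    maximum). BH adjustment runs across motifs.
    """
    if not len(target_windows) or not len(background_windows):
        raise ValueError("target and background window sets must be non-empty")
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta))

    def fetch(iv: GenomicInterval) -> str:
        return str(fasta[iv.chrom][iv.start : iv.end])

    t_seqs = [fetch(iv) for iv in target_windows]
    b_seqs = [fetch(iv) for iv in background_windows]
    rows = []
    for pwm in pwms:
        thr = threshold if threshold is not None else threshold_from_fraction(pwm, score_fraction)
        t_hit = sum(bool(pwm_scan(s, pwm, thr)) for s in t_seqs)
        b_hit = sum(bool(pwm_scan(s, pwm, thr)) for s in b_seqs)
        rec = fisher_record(pwm.name, t_hit, len(t_seqs) - t_hit, b_hit, len(b_seqs) - b_hit)
        rec["target_frac"] = t_hit / len(t_seqs)
        rec["background_frac"] = b_hit / len(b_seqs)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("label")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# tile-wise peak profiles

def _merge_peaks(peaks: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def _tile_hits(
    cpgs: Sequence[GenomicInterval],
    merged: Mapping[str, tuple[np.ndarray, np.ndarray]],
    offsets: np.ndarray,
    tile: int,
) -> np.ndarray:
    """Per-offset hit counts: tile [pos+o, pos+o+tile) overlaps any peak."""
    hits = np.zeros(len(offsets), dtype=np.int64)
    for c in cpgs:
        if c.chrom not in merged:
            continue
        starts, ends = merged[c.chrom]
        a = c.start + offsets            # tile starts
        b = a + tile                     # tile ends
        idx = np.searchsorted(starts, b, side="left")
        overlap = (idx > 0) & (ends[np.maximum(idx - 1, 0)] > a)
        hits += overlap
    return hits


def tile_peak_enrichment(
    targets: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    flank: int = 3000,
    tile: int = 10,
) -> pd.DataFrame:
    """Per-tile Fisher odds-ratio profile of peak overlap around CpGs.

    Offsets run from -flank to +flank - tile in steps of ``tile`` (600 tiles
    for the default +/-3 kb / 10 bp). For each offset, each CpG is a hit if
    the tile at that offset from its position overlaps >=1 bp of any peak;
    the 2x2 is target hits/misses versus background hits/misses.
    """
    if flank % tile != 0:
        raise ValueError("flank must be divisible by tile")
    if not len(targets) or not len(background):
        raise ValueError("target and background CpG sets must be non-empty")
    if not len(peaks):
        log.warning("empty peak list: all odds ratios are 1 under correction")
    offsets = np.arange(-flank, flank, tile)
    merged = _merge_peaks(peaks)
    t_hits = _tile_hits(targets, merged, offsets, tile)
    b_hits = _tile_hits(background, merged, offsets, tile)
    nt, nb = len(targets), len(background)
    rows = []
    for o, th, bh in zip(offsets, t_hits, b_hits):
        rec = fisher_record(int(o), int(th), nt - int(th), int(bh), nb - int(bh))
        rec["offset"] = int(o)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("offset").drop(columns="label")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# genomic-category enrichment

def category_enrichment(
    target_labels: Sequence[str],
    background_labels: Sequence[str],
) -> pd.DataFrame:
    """Per-label Fisher enrichment/depletion of target CpGs vs background.

    Each CpG carries exactly one label on the axis being tested (genomic
    feature or CpG-island context). Labels present only in targets are kept
    with a zero background cell (corrected OR) and a warning.
    """
    t = pd.Series(list(target_labels), dtype=str)
    b = pd.Series(list(background_labels), dtype=str)
    if t.empty or b.empty:
        raise ValueError("target and background label sets must be non-empty")
    labels = sorted(set(t) | set(b))
    only_t = set(t) - set(b)
    if only_t:
        log.warning("labels absent from background: %s", sorted(only_t))
    rows = []
    for lab in labels:
        a = int((t == lab).sum())
        c = int((b == lab).sum())
        rec = fisher_record(lab, a, len(t) - a, c, len(b) - c)
        rec["direction"] = "enriched" if rec["odds_ratio"] > 1 else "depleted"
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("label")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
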