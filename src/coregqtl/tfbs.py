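"""PWM-based transcription-factor binding-site prediction.

Position frequency matrices (JASPAR convention) are converted to log2-odds
position weight matrices, sequences are scanned on both strands, matches are
rescaled to a relative score in [0, 1] between the matrix's minimum and
maximum attainable scores, and an exact score-distribution p-value (the TFM
p-value: the probability under the i.i.d. background that a random word
scores at least as high) is computed by dynamic programming over a
discretized per-column score distribution. Allele-aware scoring quantifies
how a single-base variant changes the binding score of overlapping sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import VariantRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as indices (A=0, C=1, G=2, T=3, anything else -1)."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Pwm:
    """Log2-odds position weight matrix with its background model.

    ``scores`` is 4 x width with rows in A, C, G, T order. ``min_score`` and
    ``max_score`` are the column-wise minimum/maximum sums — the scores of
    the anti-consensus and consensus words.
    """

    tf_id: str
    tf_name: str
    scores: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.shape[0] != 4:
            raise ValueError("PWM scores must have 4 rows (A, C, G, T)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        self._dist_cache: dict[float, tuple[float, np.ndarray]] = {}

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.scores.argmax(axis=0))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.scores.argmin(axis=0))

    def reverse_complement(self) -> "Pwm":
        rc = self.scores[_COMPLEMENT][:, ::-1]
        return Pwm(self.tf_id, self.tf_name, rc, self.background, self.pseudocount)

    def rel_score(self, raw: float) -> float:
        span = self.max_score - self.min_score
        return float((raw - self.min_score) / span) if span > 0 else 1.0

    def score_word(self, word: str) -> float:
        idx = encode(word)
        if np.any(idx < 0) or idx.size != self.width:
            raise ValueError("word must be ACGT of PWM width")
        return float(self.scores[idx, np.arange(self.width)].sum())

    # -- discretized background score distribution ---------------------------
    def score_distribution(self, granularity: float = 1e-4) -> tuple[float, np.ndarray]:
        """Distribution of word scores under the i.i.d. background.

        Each column's four scores are shifted by the column minimum and
        rounded to multiples of ``granularity``; the distributions are then
        convolved across columns. Returns ``(min_score, probs)`` where
        ``probs[k]`` is the probability of a total score of approximately
        ``min_score + k * granularity`` (error bounded by width*granularity).
        """
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        if granularity in self._dist_cache:
            return self._dist_cache[granularity]
        col_min = self.scores.min(axis=0)
        q = np.rint((self.scores - col_min) / granularity).astype(np.int64)
        total_span = int(q.max(axis=0).sum())
        probs = np.zeros(total_span + 1)
        probs[0] = 1.0
        top = 0
        for j in range(self.width):
            new = np.zeros(top + int(q[:, j].max()) + 1)
            for b in range(4):
                shift = int(q[b, j])
                new[shift: shift + top + 1] += self.background[b] * probs[: top + 1]
            probs = new
            top = new.size - 1
        out = (self.min_score, probs)
        self._dist_cache[granularity] = out
        return out

    def exact_score_distribution(self, max_states: int = 300_000):
        """Exact distribution of word scores under the background.

        Dynamic programming over exact floating-point partial sums (the same
        left-to-right accumulation an exhaustive enumeration performs, so
        ties are handled identically). Returns ``(scores, probs)`` sorted by
        score, or None when the state count would exceed ``max_states``.
        """
        if hasattr(self, "_exact_dist"):
            return self._exact_dist
        dist: dict[float, float] = {0.0: 1.0}
        for j in range(self.width):
            new: dict[float, float] = {}
            col = self.scores[:, j]
            for s, p in dist.items():
                for b in range(4):
                    key = s + col[b]
                    new[key] = new.get(key, 0.0) + p * self.background[b]
            if len(new) > max_states:
                self._exact_dist = None
                return None
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        self._exact_dist = (scores, probs)
        return self._exact_dist


def pfm_to_pwm(pfm, background=None, pseudocount: float = 0.8) -> Pwm:
    """Convert a position frequency matrix to a log2-odds PWM.

    ``pfm`` is a Bio.motifs Motif or a 4 x width array of counts (A, C, G, T
    rows). Per cell: ``log2((count + pc*bg_b) / (total + pc) / bg_b)`` —
    the JASPAR/TFBSTools convention with pseudocount 0.8 and a uniform
    background by default.
    """
    if hasattr(pfm, "counts"):  # Bio.motifs Motif
        counts = np.array([list(pfm.counts[b]) for b in BASES], dtype=float)
        tf_id = getattr(pfm, "matrix_id", None) or "PFM"
        tf_name = getattr(pfm, "name", "") or ""
    else:
        counts = np.asarray(pfm, dtype=float)
        tf_id, tf_name = "PFM", ""
    if counts.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("PFM counts must be non-negative")
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("PFM column sums must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    p = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    scores = np.log2(p / bg[:, None])
    return Pwm(tf_id, tf_name, scores, bg, pseudocount)


@dataclass
class TfbsHit:
    """One predicted binding site.

    ``start`` is 1-based on the + strand; hits on the - strand report the
    + strand start of the covered window. ``rel_score`` rescales the raw
    log2-odds score to [0, 1] between the matrix minimum and maximum;
    ``tfm_p`` is the exact tail probability of the raw score under the
    background model.
    """

    tf_id: str
    seq_name: str
    strand: str
    start: int
    raw_score: float
    rel_score: float
    tfm_p: float = float("nan")

    @property
    def offset(self) -> int:
        """0-based offset of the window into the sequence."""
        return self.start - 1


def tfm_pvalue(pwm: Pwm, score: float, granularity: float = 1e-4) -> float:
    """Exact P(word score >= ``score``) under the i.i.d. background.

    Narrow matrices use an exact dynamic programme over the attainable
    word-score values (ties resolved identically to exhaustive enumeration);
    wider matrices fall back to a discretized convolution whose error is
    bounded by ``width * granularity`` in score units. Scores at or below
    the attainable minimum give 1.0 exactly; above the maximum, 0.0.
    """
    if score <= pwm.min_score:
        return 1.0
    if score > pwm.max_score:
        return 0.0
    exact = pwm.exact_score_distribution()
    if exact is not None:
        scores, probs = exact
        k = int(np.searchsorted(scores, score - 1e-12, side="left"))
        return float(probs[k:].sum())
    mn, probs = pwm.score_distribution(granularity)
    k = int(np.rint((score - mn) / granularity))
    k = min(max(k, 0), probs.size)
    return float(probs[k:].sum())


def scan_sequence(pwm: Pwm, seq: str, rel_threshold: float = 0.9,
                  seq_name: str = "seq", granularity: float = 1e-4,
                  with_pvalues: bool = True) -> list[TfbsHit]:
    """Score every offset of ``seq`` on both strands against ``pwm``.

    Windows containing a non-ACGT base are skipped. Hits with relative score
    >= ``rel_threshold`` are returned sorted by start position then strand.
    Sequences shorter than the matrix width yield no hits.
    """
    if not (0 <= rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in [0, 1]")
    idx = encode(seq)
    w = pwm.width
    n = idx.size - w + 1
    if n <= 0:
        return []
    hits: list[TfbsHit] = []
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = np.all(windows >= 0, axis=1)
    cols = np.arange(w)
    for strand, mat in (("+", pwm.scores), ("-", pwm.reverse_complement().scores)):
        safe = np.where(windows >= 0, windows, 0)
        raw = mat[safe, cols].sum(axis=1)
        rel = (raw - pwm.min_score) / max(pwm.max_score - pwm.min_score, 1e-300)
        for k in np.where(valid & (rel >= rel_threshold))[0]:
            p = tfm_pvalue(pwm, float(raw[k]), granularity) if with_pvalues else float("nan")
            hits.append(TfbsHit(pwm.tf_id, seq_name, strand, int(k) + 1,
                                float(raw[k]), float(rel[k]), p))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _window_score(pwm: Pwm, idx: np.ndarray, offset: int, strand: str) -> float:
    mat = pwm.scores if strand == "+" else pwm.reverse_complement().scores
    win = idx[offset: offset + pwm.width]
    if np.any(win < 0):
        return float("nan")
    return float(mat[win, np.arange(pwm.width)].sum())


def allele_aware_sites(pwms: list[Pwm], seq: str, variant: VariantRecord,
                       variant_offset: int, rel_threshold: float = 0.9,
                       p_threshold: float = 1e-5, seq_name: str = "seq",
                       granularity: float = 1e-4) -> pd.DataFrame:
    """Predicted sites overlapping a variant, scored under both alleles.

    Scans the reference and the alternate sequence; any hit covering
    ``variant_offset`` (0-based into ``seq``) that passes both the relative
    score and TFM p-value thresholds in *either* allele is reported with its
    per-allele raw scores and ``delta = alt_score - ref_score``.
    """
    if not (0 <= variant_offset < len(seq)):
        raise ValueError("variant offset outside the sequence")
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValueError("allele-aware scoring requires single-base alleles")
    if seq[variant_offset].upper() != variant.ref.upper():
        raise ValueError(
            f"reference mismatch: sequence has {seq[variant_offset]!r} at offset "
            f"{variant_offset}, variant ref is {variant.ref!r}")
    alt_seq = seq[:variant_offset] + variant.alt.upper() + seq[variant_offset + 1:]
    idx_ref = encode(seq)
    idx_alt = encode(alt_seq)
    rows = []
    for pwm in pwms:
        seen: set[tuple[str, int]] = set()
        for allele_seq in (seq, alt_seq):
            for h in scan_sequence(pwm, allele_seq, rel_threshold, seq_name,
                                   granularity):
                covers = h.offset <= variant_offset < h.offset + pwm.width
                if not covers or (h.strand, h.start) in seen:
                    continue
                if not (h.rel_score >= rel_threshold and h.tfm_p <= p_threshold):
                    continue
                seen.add((h.strand, h.start))
                ref_score = _window_score(pwm, idx_ref, h.offset, h.strand)
                alt_score = _window_score(pwm, idx_alt, h.offset, h.strand)
                rows.append({
                    "tf_id": pwm.tf_id, "tf_name": pwm.tf_name,
                    "seq": seq_name, "strand": h.strand, "start": h.start,
                    "end": h.start + pwm.width - 1,
                    "ref_score": ref_score, "alt_score": alt_score,
                    "delta": alt_score - ref_score,
                    "rel_score": max(pwm.rel_score(ref_score), pwm.rel_score(alt_score)),
                    "tfm_p": min(tfm_pvalue(pwm, ref_score, granularity),
                                 tfm_pvalue(pwm, alt_score, granularity)),
                })
    out = pd.DataFrame(rows, columns=["tf_id", "tf_name", "seq", "strand", "start",
                                      "end", "ref_score", "alt_score", "delta",
                                      "rel_score", "tfm_p"])
    return out.sort_values(["start", "strand", "tf_id"]).reset_index(drop=True)


def hits_to_frame(hits: list[TfbsHit], width_by_tf: dict[str, int] | None = None) -> pd.DataFrame:
    rows = [{"tf_id": h.tf_id, "seq": h.seq_name, "strand": h.strand,
             "start": h.start, "raw": h.raw_score, "relScore": h.rel_score,
             "tfm_p": h.tfm_p} for h in hits]
    return pd.DataFrame(rows, columns=["tf_id", "seq", "strand", "start", "raw",
                                       "relScore", "tfm_p"])


def write_hits_bed(hits: list[TfbsHit], widths: dict[str, int], path) -> None:
    """BED6 (0-based half-open) with relScore scaled to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            w = widths[h.tf_id]
            fh.write(f"{h.seq_name}\t{h.start - 1}\t{h.start - 1 + w}\t{h.tf_id}\t"
                     f"{int(round(h.rel_score * 1000))}\t{h.strand}\n")
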