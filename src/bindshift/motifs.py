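"""Hormone-response-element motif scanning and threshold calibration.

Nuclear receptors of the RAR/RXR class bind dimeric hormone response
elements (HREs): two ~6-bp half-sites (consensus near TGACCT) arranged
as a direct (DRn), inverted (IRn) or everted (ERn) repeat separated by
an n-bp spacer.  This module scores half-sites with a log-likelihood
position weight matrix, scans genomes for dimers in any geometry with
an unpenalised spacer, calibrates score thresholds to target
false-positive rates on Markov-simulated background sequence, and
compares motif frequencies between two site sets with Fisher's exact
test.

All log-likelihood scores use natural log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HalfSitePWM",
    "HREConfig",
    "MotifMatch",
    "CalibratedThreshold",
    "build_halfsite_pwm",
    "bundled_halfsite_pwm",
    "dimer_weights",
    "scan_hre",
    "scan_pwm",
    "calibrate_threshold",
    "differential_motif_frequency",
    "encode_sequence",
    "decode_sequence",
]

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass
class HalfSitePWM:
    """Log-likelihood half-site scoring model.

    ``weights[i, b] = ln(p_ib / bg_b)`` where p is the pseudocount-
    smoothed column frequency and bg the background base distribution.
    The score of an L-mer is the sum of its per-position weights.
    """

    weights: np.ndarray  # (L, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must be (L, 4)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def length(self) -> int:
        return int(self.weights.shape[0])

    def score(self, seq: str) -> float:
        enc = encode_sequence(seq)
        if enc.size != self.length or np.any(enc > 3):
            raise ValueError("sequence must be an unambiguous L-mer")
        return float(self.weights[np.arange(self.length), enc].sum())

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def revcomp_weights(self) -> np.ndarray:
        return self.weights[::-1, ::-1].copy()


def build_halfsite_pwm(
    sequences: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> HalfSitePWM:
    """Build a half-site PWM from aligned, equal-length sequences."""
    if not sequences:
        raise ValueError("need at least one aligned half-site")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("half-sites must all have the same length")
    counts = np.zeros((L, 4))
    for s in sequences:
        enc = encode_sequence(s)
        if np.any(enc > 3):
            raise ValueError(f"ambiguous base in half-site {s!r}")
        counts[np.arange(L), enc] += 1
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=np.float64)
    if pseudocount > 0:
        counts = counts + pseudocount
    elif np.any(counts == 0):
        counts = np.where(counts == 0, 1e-9, counts)  # keep weights finite
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return HalfSitePWM(np.log(freqs / background), background, pseudocount)


def bundled_halfsite_pwm() -> HalfSitePWM:
    """Half-site model built from a curated list of accepted HRE half-sites.

    The bundled alignment (``data/hre_halfsites.txt``) is an
    approximation assembled from published accepted half-site sequences;
    supply your own alignment to :func:`build_halfsite_pwm` for an
    exact reproduction of any particular scoring model.
    """
    text = resources.files("bindshift.data").joinpath("hre_halfsites.txt").read_text()
    seqs = [ln.strip().upper() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return build_halfsite_pwm(seqs)


@dataclass(frozen=True)
class HREConfig:
    """Dimer geometry: orientation and unpenalised spacer length."""

    orientation: str  # DR | IR | ER
    spacer: int

    def __post_init__(self) -> None:
        if self.orientation not in ("DR", "IR", "ER"):
            raise ValueError("orientation must be DR, IR or ER")
        if not (0 <= self.spacer <= 8):
            raise ValueError("spacer must lie in 0..8")

    @property
    def name(self) -> str:
        return f"{self.orientation}{self.spacer}"

    def footprint(self, half_length: int) -> int:
        return 2 * half_length + self.spacer


@dataclass
class MotifMatch:
    chrom: str
    start: int  # 0-based forward-strand start of the full footprint
    strand: str  # '+' or '-'
    score: float
    half_scores: tuple[float, float] | None
    motif: str


@dataclass(frozen=True)
class CalibratedThreshold:
    motif: str
    target_rate: float
    threshold: float
    achieved_rate: float
    n_seqs: int
    seq_len: int
    markov_order: int
    seed: int


def dimer_weights(pwm: HalfSitePWM, config: HREConfig) -> np.ndarray:
    """Monolithic weight matrix for a dimer: half, zero spacer, half.

    Spacer columns are all-zero so the spacer sequence is unpenalised.
    DR repeats the half-site, IR reverse-complements the downstream
    half, ER reverse-complements the upstream half.
    """
    L = pwm.length
    half, rc = pwm.weights, pwm.revcomp_weights()
    if config.orientation == "DR":
        up, down = half, half
    elif config.orientation == "IR":
        up, down = half, rc
    else:  # ER
        up, down = rc, half
    full = np.zeros((config.footprint(L), 4))
    full[:L] = up
    full[L + config.spacer :] = down
    return full


def _pwm_score_array(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score every window of ``enc``; windows containing N get -inf."""
    F = weights.shape[0]
    n = enc.size - F + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    padded = np.hstack([weights, np.full((F, 1), -np.inf)])  # column 4 = N
    for k in range(F):
        scores += padded[k, enc[k : k + n]]
    return scores


def _halfsite_match_positions(
    enc: np.ndarray, pwm: HalfSitePWM, config: HREConfig, half_threshold: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-frame dimer matches: (starts, up-half scores, down-half scores)."""
    L = pwm.length
    half, rc = pwm.weights, pwm.revcomp_weights()
    if config.orientation == "DR":
        up_w, down_w = half, half
    elif config.orientation == "IR":
        up_w, down_w = half, rc
    else:
        up_w, down_w = rc, half
    s_up = _pwm_score_array(enc, up_w)
    s_down = s_up if down_w is up_w else _pwm_score_array(enc, down_w)
    shift = L + config.spacer
    n = enc.size - config.footprint(L) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0), np.empty(0)
    a = s_up[:n]
    b = s_down[shift : shift + n]
    hit = (a >= half_threshold) & (b >= half_threshold)
    # skip any footprint containing N, spacer included
    cum_n = np.concatenate(([0], np.cumsum(enc > 3)))
    fp = config.footprint(L)
    hit &= (cum_n[fp:] - cum_n[: enc.size - fp + 1])[:n] == 0
    starts = np.flatnonzero(hit)
    return starts, a[starts], b[starts]


def scan_hre(
    genome: dict[str, str],
    pwm: HalfSitePWM,
    config: HREConfig,
    half_threshold: float = 5.0,
) -> list[MotifMatch]:
    """Scan both strands for dimer HRE matches.

    A match requires BOTH half-sites to score at or above
    ``half_threshold``; the total score is the sum of the two half
    scores and the spacer contributes nothing.  Overlapping matches are
    all reported.  Reverse-strand matches are reported at their
    forward-strand footprint start.
    """
    matches: list[MotifMatch] = []
    F = config.footprint(pwm.length)
    for chrom in sorted(genome):
        enc = encode_sequence(genome[chrom])
        for strand in "+-":
            if strand == "+":
                e = enc
            else:  # reverse complement, N (code 4) preserved
                e = np.where(enc[::-1] > 3, 4, 3 - enc[::-1]).astype(np.uint8)
            starts, a, b = _halfsite_match_positions(e, pwm, config, half_threshold)
            for j, sa, sb in zip(starts, a, b):
                start = int(j) if strand == "+" else enc.size - int(j) - F
                matches.append(
                    MotifMatch(chrom, start, strand, float(sa + sb), (float(sa), float(sb)), config.name)
                )
    matches.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return matches


def scan_pwm(
    genome: dict[str, str],
    weights: np.ndarray,
    threshold: float,
    motif: str = "pwm",
) -> list[MotifMatch]:
    """Scan both strands for matches to a monolithic PWM (score >= threshold)."""
    weights = np.asarray(weights, dtype=np.float64)
    F = weights.shape[0]
    rc_weights = weights[::-1, ::-1]
    matches: list[MotifMatch] = []
    for chrom in sorted(genome):
        enc = encode_sequence(genome[chrom])
        for strand, w in (("+", weights), ("-", rc_weights)):
            scores = _pwm_score_array(enc, w)
            for j in np.flatnonzero(scores >= threshold):
                matches.append(MotifMatch(chrom, int(j), strand, float(scores[j]), None, motif))
    matches.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return matches


def best_scores_per_sequence(
    encoded: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Per-sequence best PWM score over both strands.

    ``encoded`` is an (n_seqs, seq_len) uint8 matrix.  Sequences shorter
    than the footprint (or all-N) score -inf.
    """
    weights = np.asarray(weights, dtype=np.float64)
    F = weights.shape[0]
    n_seqs, L = encoded.shape
    nwin = L - F + 1
    if nwin <= 0:
        return np.full(n_seqs, -np.inf)
    best = np.full(n_seqs, -np.inf)
    for w in (weights, weights[::-1, ::-1]):
        pad = np.hstack([w, np.full((w.shape[0], 1), -np.inf)])
        scores = np.zeros((n_seqs, nwin))
        for k in range(F):
            scores += pad[k, encoded[:, k : k + nwin]]
        np.maximum(best, scores.max(axis=1), out=best)
    return best


def calibrate_threshold(
    weights: np.ndarray,
    markov_model,
    n_seqs: int = 1_000_000,
    seq_len: int = 100,
    target_rates: tuple[float, ...] = (0.01, 0.005, 0.001),
    seed: int = 0,
    motif: str = "pwm",
    batch: int = 100_000,
    rule: str = "closest",
) -> list[CalibratedThreshold]:
    """Score thresholds achieving target per-sequence false-positive rates.

    Simulates ``n_seqs`` background sequences from the Markov model and
    records the best match score (both strands) of each sequence.  With
    ``rule="closest"`` (default) each target rate maps to the observed
    score whose per-sequence match rate is nearest the target — PWM
    scores form a discrete lattice, so this is the threshold that
    *yields* the target rate as closely as it can be realised.
    ``rule="le"`` instead returns the smallest score whose rate does not
    exceed the target (conservative; raises when even the maximum score
    matches too often).
    """
    if rule not in ("closest", "le"):
        raise ValueError("rule must be 'closest' or 'le'")
    for r in target_rates:
        if not (0.0 < r <= 1.0):
            raise ValueError("target rates must lie in (0, 1]")
    from .synth import simulate_sequence_matrix  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    best = np.empty(n_seqs)
    done = 0
    while done < n_seqs:
        b = min(batch, n_seqs - done)
        enc = simulate_sequence_matrix(markov_model, b, seq_len, rng)
        best[done : done + b] = best_scores_per_sequence(enc, weights)
        done += b
    best_sorted = np.sort(best)
    uniq = np.unique(best_sorted)
    # count of sequences with best >= u, for each unique score u
    counts_ge = n_seqs - np.searchsorted(best_sorted, uniq, side="left")
    out = []
    for rate in target_rates:
        if rule == "le":
            ok = counts_ge <= rate * n_seqs
            if not ok.any():
                raise ValueError(f"target rate {rate} unreachable at the maximum score")
            t = float(uniq[np.argmax(ok)])
        else:
            t = float(uniq[int(np.argmin(np.abs(counts_ge - rate * n_seqs)))])
        achieved = float((best >= t).mean())
        out.append(
            CalibratedThreshold(
                motif=motif,
                target_rate=rate,
                threshold=t,
                achieved_rate=achieved,
                n_seqs=n_seqs,
                seq_len=seq_len,
                markov_order=markov_model.order,
                seed=seed,
            )
        )
    return out


def score_window(weights: np.ndarray, seq: str) -> float:
    """Best score of a footprint-length window over both strands."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(seq) != weights.shape[0]:
        raise ValueError("sequence length must equal the PWM footprint")
    enc = encode_sequence(seq)[None, :]
    return float(best_scores_per_sequence(enc, weights)[0])


def _contains_match(seq: str, weights: np.ndarray, threshold: float) -> bool:
    enc = encode_sequence(seq)[None, :]
    return bool(best_scores_per_sequence(enc, weights)[0] >= threshold)


def differential_motif_frequency(
    sequences_a: list[str],
    sequences_b: list[str],
    motif_library: dict[str, tuple[np.ndarray, float]],
) -> pd.DataFrame:
    """Compare motif occurrence between two sets of site sequences.

    ``motif_library`` maps motif id -> (weight matrix, score threshold).
    For each motif, counts sites containing at least one match on either
    strand and tests the 2x2 table (containing vs not, set A vs set B)
    with a two-sided Fisher's exact test.  Returns one row per motif
    with counts, p-value and the enriched direction.
    """
    if not sequences_a or not sequences_b:
        raise ValueError("both site sets must be non-empty")
    rows = []
    nA, nB = len(sequences_a), len(sequences_b)
    for name, (weights, threshold) in motif_library.items():
        ca = sum(_contains_match(s, weights, threshold) for s in sequences_a)
        cb = sum(_contains_match(s, weights, threshold) for s in sequences_b)
        _, p = stats.fisher_exact([[ca, nA - ca], [cb, nB - cb]], alternative="two-sided")
        if ca / nA > cb / nB:
            direction = "A"
        elif cb / nB > ca / nA:
            direction = "B"
        else:
            direction = "none"
        rows.append(
            {"motif": name, "count_A": ca, "n_A": nA, "count_B": cb, "n_B": nB,
             "p_value": float(p), "enriched_in": direction}
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
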