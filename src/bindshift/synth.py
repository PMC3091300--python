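"""Synthetic ChIP-seq study generator.

Produces genomes, planted HRE motifs, model-shaped read pileups over
Poisson background, two-condition experiment suites with shared and
condition-exclusive binding events, auxiliary "prior-state" occupancy
tracks statistically correlated with future binding, and matching
mappability / conservation tracks — everything the analysis modules
consume, with full ground truth and byte-reproducible seeding.

The generator's statistical contract:

* background reads are a homogeneous Poisson process over mappable
  positions, strand assigned uniformly;
* each binding event of strength s contributes Poisson(floor(s)) reads
  whose signed offsets follow the configured binding model, forward
  strand for upstream offsets and reverse for downstream (canonical
  ChIP fragment geometry);
* duplicate-read artifacts resample existing read positions at a
  configurable rate, to exercise the duplicate cap;
* every auxiliary track is enriched at a true event independently with
  probability equal to the suite's *informativeness*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BindingModel, default_binding_model
from .motifs import HalfSitePWM, HREConfig, decode_sequence, encode_sequence
from .reads import ReadDataset

try:  # sequential Markov sampling is the one hot loop; JIT when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "MarkovModel",
    "GroundTruth",
    "SyntheticSpec",
    "SuiteResult",
    "fit_markov_model",
    "simulate_genome",
    "simulate_sequence_matrix",
    "plant_hre_sites",
    "simulate_reads",
    "simulate_experiment_suite",
    "mouse_like_composition_model",
]


# ---------------------------------------------------------------------------
# Markov background model


@dataclass
class MarkovModel:
    """k-th order Markov model over {A,C,G,T}.

    ``transition[ctx, b]`` is P(next base = b | previous ``order`` bases
    encode to context index ``ctx``), contexts in lexicographic order
    with the most recent base least significant.  ``context_probs`` is
    the distribution used to draw the first ``order`` symbols.
    """

    order: int
    transition: np.ndarray  # (4**order, 4)
    context_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be non-negative")
        self.transition = np.asarray(self.transition, dtype=np.float64)
        n_ctx = 4**self.order
        if self.transition.shape != (n_ctx, 4):
            raise ValueError(f"transition must be ({n_ctx}, 4)")
        if np.any(self.transition < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each context distribution must sum to 1")
        if self.context_probs is None:
            self.context_probs = np.full(n_ctx, 1.0 / n_ctx)
        else:
            self.context_probs = np.asarray(self.context_probs, dtype=np.float64)
            self.context_probs = self.context_probs / self.context_probs.sum()

    @property
    def n_contexts(self) -> int:
        return 4**self.order


def mouse_like_composition_model() -> MarkovModel:
    """Order-0 model with mammalian-like base composition (42% GC)."""
    return MarkovModel(0, np.array([[0.29, 0.21, 0.21, 0.29]]))


def fit_markov_model(
    sequences: list[str] | dict[str, str], order: int = 3, pseudocount: float = 0.25
) -> MarkovModel:
    """Maximum-likelihood Markov model with pseudocount smoothing.

    Positions whose context or emitted base contains N are excluded
    from counting.  Raises when no valid transition is observed (empty
    input or order longer than every sequence).
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    if not sequences:
        raise ValueError("need at least one sequence")
    if order < 0:
        raise ValueError("order must be non-negative")
    n_ctx = 4**order
    counts = np.zeros((n_ctx, 4))
    ctx_counts = np.zeros(n_ctx)
    for seq in sequences:
        enc = encode_sequence(seq)
        if enc.size < order + 1:
            continue
        n = enc.size - order
        valid = enc[order:] < 4
        ctx = np.zeros(n, dtype=np.int64)
        for j in range(order):
            ctx = ctx * 4 + enc[j : j + n]
            valid &= enc[j : j + n] < 4
        ctx = np.where(valid, ctx % (4**order) if order else 0, 0)
        nxt = enc[order:]
        np.add.at(counts, (ctx[valid], nxt[valid]), 1)
        np.add.at(ctx_counts, ctx[valid], 1)
    if counts.sum() == 0:
        raise ValueError("no valid transitions observed; input empty or order too large")
    smoothed = counts + pseudocount
    transition = smoothed / smoothed.sum(axis=1, keepdims=True)
    ctx_probs = (ctx_counts + pseudocount) / (ctx_counts + pseudocount).sum()
    return MarkovModel(order, transition, ctx_probs)


if _HAVE_NUMBA:

    @njit(cache=True)
    def _markov_walk(cum: np.ndarray, start_ctx: int, u: np.ndarray, order: int) -> np.ndarray:  # pragma: no cover - jitted
        n = u.size
        out = np.empty(n, dtype=np.uint8)
        mask = 4 ** (order - 1) if order > 0 else 1
        ctx = start_ctx
        for i in range(n):
            row = cum[ctx]
            x = u[i]
            b = 0
            while b < 3 and x > row[b]:
                b += 1
            out[i] = b
            if order > 0:
                ctx = (ctx % mask) * 4 + b if order > 1 else b
        return out

else:  # pragma: no cover - exercised only without numba

    def _markov_walk(cum, start_ctx, u, order):
        n = u.size
        out = np.empty(n, dtype=np.uint8)
        mask = 4 ** (order - 1) if order > 0 else 1
        ctx = start_ctx
        for i in range(n):
            row = cum[ctx]
            x = u[i]
            b = 0
            while b < 3 and x > row[b]:
                b += 1
            out[i] = b
            if order > 0:
                ctx = (ctx % mask) * 4 + b if order > 1 else b
        return out


def _decode_context(ctx: int, order: int) -> np.ndarray:
    out = np.empty(order, dtype=np.uint8)
    for j in range(order - 1, -1, -1):
        out[j] = ctx % 4
        ctx //= 4
    return out


def simulate_genome(
    model: MarkovModel, length: int, n_chroms: int = 1, seed: int | np.random.Generator = 0
) -> dict[str, str]:
    """Sample ``n_chroms`` independent chromosomes of ``length`` bp."""
    if length < model.order + 1:
        raise ValueError("length must be at least order + 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(model.transition, axis=1)
    genome: dict[str, str] = {}
    for i in range(n_chroms):
        ctx = int(rng.choice(model.n_contexts, p=model.context_probs))
        head = _decode_context(ctx, model.order)
        u = rng.random(length - model.order)
        body = _markov_walk(cum, ctx, u, model.order)
        genome[f"chr{i + 1}"] = decode_sequence(np.concatenate([head, body]))
    return genome


def simulate_sequence_matrix(
    model: MarkovModel, n_seqs: int, seq_len: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_seqs, seq_len) encoded sequences, vectorised across sequences."""
    if seq_len < model.order:
        raise ValueError("sequences shorter than the model order")
    cum = np.cumsum(model.transition, axis=1)
    out = np.empty((n_seqs, seq_len), dtype=np.uint8)
    ctx = rng.choice(model.n_contexts, size=n_seqs, p=model.context_probs)
    for j in range(model.order):
        shift = 4 ** (model.order - 1 - j)
        out[:, j] = (ctx // shift) % 4
    mask = 4 ** (model.order - 1) if model.order > 0 else 1
    for j in range(model.order, seq_len):
        u = rng.random(n_seqs)
        rows = cum[ctx]
        nxt = (u[:, None] > rows[:, :3]).sum(axis=1).astype(np.uint8)
        out[:, j] = nxt
        if model.order == 1:
            ctx = nxt.astype(np.int64)
        elif model.order > 1:
            ctx = (ctx % mask) * 4 + nxt
    return out


# ---------------------------------------------------------------------------
# ground truth and planting


@dataclass
class GroundTruth:
    """Planted events, planted motif instances and the channel scaling."""

    events: list[tuple[str, int, float, str]] = field(default_factory=list)
    motifs: list[tuple[str, int, str, str]] = field(default_factory=list)  # chrom, start, strand, config
    scaling: float = 1.0

    def events_for(self, condition: str) -> list[tuple[str, int, float, str]]:
        if condition not in ("A", "B"):
            raise ValueError("condition must be 'A' or 'B'")
        keep = {"shared", f"{condition}-only"}
        return [e for e in self.events if e[3] in keep]


@dataclass
class SyntheticSpec:
    """Study conditions for a two-condition synthetic suite.

    Defaults emulate a modestly sequenced TF ChIP experiment: 0.05
    background reads/bp, point events of strength 200 (expected reads),
    and auxiliary prior-state tracks enriched at true sites with the
    given probability.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 1
    background_rate: float = 0.05
    n_shared: int = 50
    n_a_only: int = 25
    n_b_only: int = 25
    event_strength: float = 200.0
    strength_cv: float = 0.0  # lognormal coefficient of variation; 0 = fixed
    min_event_gap: int = 2_000
    binding_model: BindingModel = field(default_factory=default_binding_model)
    duplicate_rate: float = 0.0
    control_rate: float | None = None  # defaults to background_rate
    n_aux_tracks: int = 0
    informativeness: float = 1.0
    aux_strength: float = 100.0
    aux_background_rate: float = 0.02
    unmappable_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.event_strength <= 0:
            raise ValueError("rates must be non-negative and strengths positive")
        if not (0.0 <= self.informativeness <= 1.0):
            raise ValueError("informativeness must lie in [0, 1]")
        if self.duplicate_rate < 0:
            raise ValueError("duplicate rate must be non-negative")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        per = self.genome_length // self.n_chroms
        return {f"chr{i + 1}": per for i in range(self.n_chroms)}


def _sample_halfsite(
    pwm: HalfSitePWM, rng: np.random.Generator, quantile_score: float
) -> np.ndarray:
    probs = pwm.background * np.exp(pwm.weights)
    probs = probs / probs.sum(axis=1, keepdims=True)
    for _ in range(1000):
        draw = np.array(
            [rng.choice(4, p=probs[i]) for i in range(pwm.length)], dtype=np.uint8
        )
        score = pwm.weights[np.arange(pwm.length), draw].sum()
        if score >= quantile_score:
            return draw
    raise RuntimeError("could not sample a high-scoring half-site")


def _pwm_top_quantile_score(
    pwm: HalfSitePWM, rng: np.random.Generator, q: float = 0.75, n: int = 2000
) -> float:
    probs = pwm.background * np.exp(pwm.weights)
    probs = probs / probs.sum(axis=1, keepdims=True)
    draws = np.stack([rng.choice(4, size=n, p=probs[i]) for i in range(pwm.length)])
    scores = pwm.weights[np.arange(pwm.length)[:, None], draws].sum(axis=0)
    return float(np.quantile(scores, q))


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


def plant_hre_sites(
    genome: dict[str, str],
    pwm: HalfSitePWM,
    configs: list[tuple[HREConfig, float]],
    n_sites: int,
    seed: int | np.random.Generator = 0,
    positions: list[tuple[str, int]] | None = None,
    top_quantile: float = 0.75,
) -> tuple[dict[str, str], list[tuple[str, int, str, str]]]:
    """Overwrite the genome with high-scoring HRE dimers at random spots.

    ``configs`` carries (geometry, mixture weight) pairs; each planted
    instance draws a geometry from the mixture, two half-sites from the
    top quantile of the PWM's own distribution, and a uniform spacer.
    Instances never overlap each other and the genome length is
    unchanged.  ``positions`` pins the (chrom, start) of the first
    instances instead of sampling them (used to co-locate motifs with
    binding events).  Returns (modified genome, truth list of
    (chrom, start, strand, geometry-name)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_sites == 0:
        return dict(genome), []
    if not configs:
        raise ValueError("need at least one dimer geometry")
    names = [c.name for c, _ in configs]
    w = np.array([wt for _, wt in configs], dtype=np.float64)
    w = w / w.sum()
    q_score = _pwm_top_quantile_score(pwm, rng, top_quantile)
    enc = {c: encode_sequence(s).copy() for c, s in genome.items()}
    chroms = sorted(enc)
    lengths = np.array([enc[c].size for c in chroms], dtype=np.float64)
    max_fp = max(c.footprint(pwm.length) for c, _ in configs)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth: list[tuple[str, int, str, str]] = []
    attempts = 0
    placed = 0
    while placed < n_sites:
        ci = int(rng.choice(len(configs), p=w))
        config = configs[ci][0]
        fp = config.footprint(pwm.length)
        if positions is not None and placed < len(positions):
            chrom, start = positions[placed]
            if start < 0 or start + fp > enc[chrom].size:
                raise ValueError("pinned motif position overlaps a chromosome end")
        else:
            attempts += 1
            if attempts > 100 * n_sites:
                raise ValueError("genome too small to place motifs without overlap")
            chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
            if enc[chrom].size <= max_fp:
                continue
            start = int(rng.integers(0, enc[chrom].size - fp))
            if any(start < e and s < start + fp for s, e in occupied[chrom]):
                continue
        h1 = _sample_halfsite(pwm, rng, q_score)
        h2 = _sample_halfsite(pwm, rng, q_score)
        spacer = rng.integers(0, 4, size=config.spacer).astype(np.uint8)
        if config.orientation == "DR":
            dimer = np.concatenate([h1, spacer, h2])
        elif config.orientation == "IR":
            dimer = np.concatenate([h1, spacer, _revcomp_codes(h2)])
        else:  # ER
            dimer = np.concatenate([_revcomp_codes(h1), spacer, h2])
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dimer = _revcomp_codes(dimer)
        enc[chrom][start : start + fp] = dimer
        occupied[chrom].append((start, start + fp))
        truth.append((chrom, start, strand, names[ci]))
        placed += 1
    out = {c: decode_sequence(enc[c]) for c in chroms}
    return out, truth


# ---------------------------------------------------------------------------
# read simulation


def _mappable_positions(
    chrom: str, length: int, unmappable: list[tuple[str, int, int]]
) -> np.ndarray | None:
    blocks = [(s, e) for c, s, e in unmappable if c == chrom]
    if not blocks:
        return None
    mask = np.ones(length, dtype=bool)
    for s, e in blocks:
        mask[max(s, 0) : min(e, length)] = False
    return np.flatnonzero(mask)


def simulate_reads(
    truth: GroundTruth,
    spec: SyntheticSpec,
    channel: str = "signal",
    condition: str = "A",
    seed: int | np.random.Generator = 0,
    rate: float | None = None,
    event_subset: list[tuple[str, int, float, str]] | None = None,
) -> ReadDataset:
    """Simulate one sequencing channel.

    Background reads are Poisson over mappable positions with random
    strand; the signal channel adds Poisson(floor(strength)) reads per
    event at model-drawn offsets, forward strand upstream and reverse
    downstream.  The control channel is event-blind.  Duplicate
    artifacts resample existing reads at ``spec.duplicate_rate``.
    """
    if channel not in ("signal", "control"):
        raise ValueError("channel must be 'signal' or 'control'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate is None:
        rate = spec.background_rate if channel == "signal" else (
            spec.control_rate if spec.control_rate is not None else spec.background_rate
        )
    chrom_lengths = spec.chrom_lengths
    positions: dict[str, list[np.ndarray]] = {c: [] for c in chrom_lengths}
    strands: dict[str, list[np.ndarray]] = {c: [] for c in chrom_lengths}
    for chrom, L in chrom_lengths.items():
        n_bg = rng.poisson(rate * L)
        mappable = _mappable_positions(chrom, L, spec.unmappable_blocks)
        if mappable is None:
            pos = rng.integers(0, L, size=n_bg)
        else:
            pos = mappable[rng.integers(0, mappable.size, size=n_bg)]
        positions[chrom].append(np.sort(pos))
        strands[chrom].append(rng.choice(np.array([1, -1], dtype=np.int8), size=n_bg))
    if channel == "signal":
        events = event_subset if event_subset is not None else truth.events_for(condition)
        model = spec.binding_model
        for chrom, pos0, strength, _ in events:
            n_ev = rng.poisson(int(strength))
            off = model.sample_offsets(n_ev, rng)
            p = pos0 + off
            L = chrom_lengths[chrom]
            keep = (p >= 0) & (p < L)
            p, off = p[keep], off[keep]
            st = np.where(off < 0, 1, -1).astype(np.int8)
            tie = off == 0
            if tie.any():
                st[tie] = rng.choice(np.array([1, -1], dtype=np.int8), size=int(tie.sum()))
            positions[chrom].append(p)
            strands[chrom].append(st)
    pos_arr = {c: np.concatenate(v) if v else np.empty(0, dtype=np.int64) for c, v in positions.items()}
    str_arr = {c: np.concatenate(v) if v else np.empty(0, dtype=np.int8) for c, v in strands.items()}
    if spec.duplicate_rate > 0:
        for chrom in chrom_lengths:
            n = pos_arr[chrom].size
            n_dup = rng.poisson(spec.duplicate_rate * n)
            if n and n_dup:
                idx = rng.integers(0, n, size=n_dup)
                pos_arr[chrom] = np.concatenate([pos_arr[chrom], pos_arr[chrom][idx]])
                str_arr[chrom] = np.concatenate([str_arr[chrom], str_arr[chrom][idx]])
    return ReadDataset(dict(chrom_lengths), pos_arr, str_arr)


# ---------------------------------------------------------------------------
# full suite


@dataclass
class SuiteResult:
    genome: dict[str, str] | None
    datasets: dict[str, ReadDataset]
    mappability: dict[str, np.ndarray]
    conservation: dict[str, np.ndarray]
    truth: GroundTruth
    spec: SyntheticSpec


def _place_events(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[str, int, float, str]]:
    chrom_lengths = spec.chrom_lengths
    labels = (
        ["shared"] * spec.n_shared + ["A-only"] * spec.n_a_only + ["B-only"] * spec.n_b_only
    )
    n = len(labels)
    chroms = list(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=np.float64)
    margin = spec.binding_model.half_width + 10
    events: list[tuple[str, int, float, str]] = []
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    attempts = 0
    for lab in labels:
        while True:
            attempts += 1
            if attempts > 1000 * max(n, 1):
                raise ValueError("genome too small for the requested event count")
            chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
            L = chrom_lengths[chrom]
            if L <= 2 * margin:
                continue
            pos = int(rng.integers(margin, L - margin))
            if all(abs(pos - q) >= spec.min_event_gap for q in taken[chrom]):
                break
        taken[chrom].append(pos)
        if spec.strength_cv > 0:
            sigma = np.sqrt(np.log(1 + spec.strength_cv**2))
            strength = float(
                spec.event_strength * np.exp(rng.normal(-0.5 * sigma**2, sigma))
            )
        else:
            strength = spec.event_strength
        events.append((chrom, pos, strength, lab))
    return events


def simulate_experiment_suite(
    spec: SyntheticSpec,
    seed: int | None = None,
    genome_model: MarkovModel | None = None,
    halfsite_pwm: HalfSitePWM | None = None,
    motif_configs: list[tuple[HREConfig, float]] | None = None,
    n_decoy_motifs: int = 0,
    make_genome: bool = True,
) -> SuiteResult:
    """Generate a complete two-condition study with ground truth.

    Produces ``signal_A``/``signal_B`` channels (shared plus
    condition-exclusive events), a shared event-blind ``control``, and
    ``spec.n_aux_tracks`` auxiliary prior-state tracks, each enriched at
    a true event with probability ``spec.informativeness``.  When a
    half-site PWM is supplied, an HRE dimer is planted at every event
    position plus ``n_decoy_motifs`` unbound decoy instances;
    conservation is elevated over planted motifs and mappability
    defaults to fully mappable outside ``spec.unmappable_blocks``.
    """
    if seed is None:
        seed = spec.seed
    root = np.random.SeedSequence(seed)
    keys = root.spawn(8)
    rng_ev = np.random.default_rng(keys[0])
    events = _place_events(spec, rng_ev)
    truth = GroundTruth(events=events, scaling=1.0)

    genome: dict[str, str] | None = None
    if make_genome:
        gm = genome_model if genome_model is not None else mouse_like_composition_model()
        per = spec.genome_length // spec.n_chroms
        genome = simulate_genome(gm, per, spec.n_chroms, np.random.default_rng(keys[1]))
        if halfsite_pwm is not None:
            configs = motif_configs or [(HREConfig("DR", 5), 1.0)]
            fp = max(c.footprint(halfsite_pwm.length) for c, _ in configs)
            pinned = [(c, max(p - fp // 2, 0)) for c, p, _, _ in events]
            genome, motif_truth = plant_hre_sites(
                genome,
                halfsite_pwm,
                configs,
                len(pinned) + n_decoy_motifs,
                np.random.default_rng(keys[2]),
                positions=pinned,
            )
            truth.motifs = motif_truth

    datasets: dict[str, ReadDataset] = {}
    datasets["signal_A"] = simulate_reads(
        truth, spec, "signal", "A", np.random.default_rng(keys[3])
    )
    datasets["signal_B"] = simulate_reads(
        truth, spec, "signal", "B", np.random.default_rng(keys[4])
    )
    datasets["control"] = simulate_reads(
        truth, spec, "control", "A", np.random.default_rng(keys[5])
    )

    rng_aux = np.random.default_rng(keys[6])
    aux_spec = SyntheticSpec(
        genome_length=spec.genome_length,
        n_chroms=spec.n_chroms,
        background_rate=spec.aux_background_rate,
        event_strength=spec.aux_strength,
        binding_model=spec.binding_model,
        unmappable_blocks=list(spec.unmappable_blocks),
    )
    for k in range(spec.n_aux_tracks):
        enriched = [
            ev for ev in events if rng_aux.random() < spec.informativeness
        ]
        subset = [(c, p, spec.aux_strength, lab) for c, p, _, lab in enriched]
        datasets[f"aux_{k}"] = simulate_reads(
            GroundTruth(events=subset),
            aux_spec,
            "signal",
            "A",
            rng_aux,
            event_subset=subset,
        )

    mappability: dict[str, np.ndarray] = {}
    conservation: dict[str, np.ndarray] = {}
    rng_cons = np.random.default_rng(keys[7])
    for chrom, L in spec.chrom_lengths.items():
        m = np.ones(L, dtype=np.float32)
        for c, s, e in spec.unmappable_blocks:
            if c == chrom:
                m[max(s, 0) : min(e, L)] = 0.0
        mappability[chrom] = m
        cons = rng_cons.uniform(0.0, 0.2, size=L).astype(np.float32)
        conservation[chrom] = cons
    for chrom, start, _, name in truth.motifs:
        width = 12 + int(name[2:]) + 20  # footprint plus 10 bp flanks
        lo = max(start - 10, 0)
        conservation[chrom][lo : lo + width] = 0.9
    return SuiteResult(genome, datasets, mappability, conservation, truth, spec)
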