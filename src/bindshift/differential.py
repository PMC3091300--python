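"""Constitutive vs condition-exclusive site classification and site-set
comparison.

A TF profiled before and after a stimulus (here: a nuclear-receptor
ligand) yields two event sets.  A site significant in condition A is

* *constitutive* when a condition-B event lies within 200 bp;
* *A-exclusive* when (i) it is significant in A against the common
  whole-cell-extract control, (ii) no B event against that control lies
  within 200 bp, and (iii) it is also significant when A is re-called
  with the B channel substituted as the control — guarding against
  sites whose B enrichment merely falls just below the significance
  threshold;
* *ambiguous* when it passes (i) and (ii) but fails (iii).

The module also provides mappability-aware random background site
sampling and the coincidence-rate statistics used to compare site sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import BindingEvent, DetectionConfig, call_events
from .model import BindingModel
from .reads import ReadDataset

__all__ = [
    "SiteSet",
    "ExclusivityResult",
    "classify_constitutive",
    "call_exclusive",
    "random_background_sites",
    "coincidence_rate",
    "proximity_to_any",
    "saturation_threshold",
]


@dataclass
class SiteSet:
    """Labelled set of point positions (chrom, position)."""

    label: str
    sites: list[tuple[str, int]]
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.sites = sorted(set(self.sites))

    def __len__(self) -> int:
        return len(self.sites)

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for c, p in self.sites:
            out.setdefault(c, []).append(p)
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    @classmethod
    def from_events(cls, label: str, events: list[BindingEvent]) -> "SiteSet":
        return cls(label, [(e.chrom, e.peak) for e in events])


def _near(site: tuple[str, int], index: dict[str, np.ndarray], window: int) -> bool:
    chrom, pos = site
    arr = index.get(chrom)
    if arr is None or arr.size == 0:
        return False
    i = np.searchsorted(arr, pos)
    for j in (i - 1, i):
        if 0 <= j < arr.size and abs(int(arr[j]) - pos) <= window:
            return True
    return False


def classify_constitutive(
    post_sites: SiteSet, pre_sites: SiteSet, window: int = 200
) -> tuple[SiteSet, SiteSet]:
    """Split post-stimulus sites by proximity to a pre-stimulus site.

    A post site is constitutive iff some pre site lies within
    ``window`` bp (|distance| <= window, point-to-point).  Returns
    (constitutive, post-specific) site sets.
    """
    idx = pre_sites.by_chrom()
    cons, spec = [], []
    for site in post_sites.sites:
        (cons if _near(site, idx, window) else spec).append(site)
    return (
        SiteSet(f"{post_sites.label}-constitutive", cons),
        SiteSet(f"{post_sites.label}-specific", spec),
    )


@dataclass
class ExclusivityResult:
    """Partition of the two conditions' sites into four classes."""

    constitutive: SiteSet
    a_exclusive: SiteSet
    b_exclusive: SiteSet
    ambiguous: SiteSet

    def assert_partition(self, a_sites: SiteSet, b_sites: SiteSet) -> None:
        union = set(a_sites.sites) | set(b_sites.sites)
        classes = [
            set(self.constitutive.sites),
            set(self.a_exclusive.sites),
            set(self.b_exclusive.sites),
            set(self.ambiguous.sites),
        ]
        combined: set = set()
        for cl in classes:
            if combined & cl:
                raise AssertionError("site classes overlap")
            combined |= cl
        if combined != union:
            raise AssertionError("classes do not cover the site union")


def _classify_one_direction(
    sites: SiteSet,
    other_sites: SiteSet,
    cross_events: list[BindingEvent],
    window: int,
) -> tuple[list, list, list]:
    other_idx = other_sites.by_chrom()
    cross_idx = SiteSet("x", [(e.chrom, e.peak) for e in cross_events]).by_chrom()
    cons, excl, ambig = [], [], []
    for site in sites.sites:
        if _near(site, other_idx, window):
            cons.append(site)
        elif _near(site, cross_idx, window):
            excl.append(site)
        else:
            ambig.append(site)
    return cons, excl, ambig


def call_exclusive(
    signal_a: ReadDataset,
    signal_b: ReadDataset,
    wce_control: ReadDataset,
    config: DetectionConfig = DetectionConfig(),
    model0: BindingModel | None = None,
    window: int = 200,
) -> ExclusivityResult:
    """Three-criterion condition-exclusive site classification.

    Calls events for A and B against the shared control, then re-calls
    each condition with the other condition substituted as the control
    channel (criterion iii).  Sites of either condition within
    ``window`` bp of the other condition's sites are constitutive;
    remaining sites are exclusive when the substituted-control call
    confirms differential enrichment, ambiguous otherwise.
    """
    if wce_control.total == 0:
        raise ValueError("whole-cell-extract control is empty")
    events_a, _, _ = call_events(signal_a, wce_control, config, model0)
    events_b, _, _ = call_events(signal_b, wce_control, config, model0)
    a_over_b, _, _ = call_events(signal_a, signal_b, config, model0)
    b_over_a, _, _ = call_events(signal_b, signal_a, config, model0)
    sites_a = SiteSet.from_events("A", events_a)
    sites_b = SiteSet.from_events("B", events_b)
    cons_a, excl_a, ambig_a = _classify_one_direction(sites_a, sites_b, a_over_b, window)
    cons_b, excl_b, ambig_b = _classify_one_direction(sites_b, sites_a, b_over_a, window)
    result = ExclusivityResult(
        constitutive=SiteSet("constitutive", cons_a + cons_b),
        a_exclusive=SiteSet("A-exclusive", excl_a),
        b_exclusive=SiteSet("B-exclusive", excl_b),
        ambiguous=SiteSet("ambiguous", ambig_a + ambig_b),
    )
    result.assert_partition(sites_a, sites_b)
    return result


def random_background_sites(
    n: int,
    chrom_lengths: dict[str, int],
    mappability: dict[str, np.ndarray],
    exclude: SiteSet | None = None,
    seed: int | np.random.Generator = 0,
    mappability_window: int = 500,
    min_mappable_fraction: float = 0.8,
    exclusion_distance: int = 500,
) -> SiteSet:
    """Mappability-aware random genomic positions for null comparisons.

    Rejection-samples ``n`` positions that (a) lie at least
    ``exclusion_distance`` bp from every excluded site and (b) sit in a
    ``mappability_window``-bp window at least ``min_mappable_fraction``
    uniquely mappable.  Deterministic under the seed; raises when the
    feasible space appears too small (100 x n rejections).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_idx = exclude.by_chrom() if exclude is not None else {}
    chroms = sorted(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=np.float64)
    cums = {c: np.concatenate(([0.0], np.cumsum(mappability[c], dtype=np.float64))) for c in chroms}
    out: list[tuple[str, int]] = []
    rejections = 0
    half = mappability_window // 2
    while len(out) < n:
        if rejections > 100 * max(n, 1):
            raise ValueError("feasible space too small for background sampling")
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        L = chrom_lengths[chrom]
        pos = int(rng.integers(0, L))
        lo, hi = max(pos - half, 0), min(pos + half, L)
        frac = (cums[chrom][hi] - cums[chrom][lo]) / max(hi - lo, 1)
        if frac < min_mappable_fraction or _near((chrom, pos), excl_idx, exclusion_distance):
            rejections += 1
            continue
        out.append((chrom, pos))
    return SiteSet("random-background", out)


def coincidence_rate(
    sites: SiteSet,
    reference: SiteSet | list[tuple[str, int, int]],
    window: int = 200,
) -> float:
    """Fraction of ``sites`` with a reference feature within ``window`` bp.

    The reference may be a point site set (point-to-point distance) or
    a list of (chrom, start, end) intervals (distance to the interval).
    """
    if len(sites) == 0:
        raise ValueError("cannot compute a coincidence rate for an empty site set")
    if isinstance(reference, SiteSet):
        idx = reference.by_chrom()
        hits = sum(_near(s, idx, window) for s in sites.sites)
        return hits / len(sites)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in reference:
        by_chrom.setdefault(chrom, []).append((s, e))
    ivals = {c: sorted(v) for c, v in by_chrom.items()}
    hits = 0
    for chrom, pos in sites.sites:
        near = False
        for s, e in ivals.get(chrom, []):
            if s - window <= pos <= e - 1 + window:
                near = True
                break
            if s - window > pos:
                break
        hits += near
    return hits / len(sites)


def proximity_to_any(
    sites: SiteSet, collections: list[SiteSet], window: int = 200
) -> float:
    """Fraction of sites near at least one point from any collection."""
    if not collections:
        raise ValueError("need at least one reference collection")
    union = SiteSet("union", [s for col in collections for s in col.sites])
    return coincidence_rate(sites, union, window)


def saturation_threshold(
    reads: ReadDataset,
    bin_width: int = 50,
    exceed_fraction: float = 1e-5,
    exclusion_regions: list[tuple[str, int, int]] | None = None,
    read_extension: int = 200,
) -> int:
    """Smallest count t with at most ``exceed_fraction`` of windows above it.

    Reads are extended to ``read_extension`` bp (the display convention
    for pileup clustergrams); windows overlapping ``exclusion_regions``
    (e.g. control-channel artifact domains) are ignored.  Used to pick
    per-track colour-saturation levels so that only a tiny fraction of
    the genome saturates.
    """
    if not (0.0 < exceed_fraction < 1.0):
        raise ValueError("exceed_fraction must lie in (0, 1)")
    from .reads import bin_counts, extend_reads  # local to avoid re-export noise

    intervals = extend_reads(reads, (0, max(read_extension, 1)))
    binned = bin_counts(intervals, reads.chrom_lengths, bin_width, bin_width)
    counts = []
    for chrom, arr in binned.counts.items():
        mask = np.ones(arr.size, dtype=bool)
        for c, s, e in exclusion_regions or []:
            if c == chrom:
                lo = max(s // bin_width, 0)
                hi = min((e - 1) // bin_width, arr.size - 1)
                if hi >= lo:
                    mask[lo : hi + 1] = False
        counts.append(arr[mask])
    all_counts = np.concatenate(counts) if counts else np.empty(0)
    if all_counts.size == 0 or all_counts.max() == 0:
        return 0
    budget = exceed_fraction * all_counts.size
    sorted_counts = np.sort(all_counts)
    # smallest integer t with #(windows > t) <= budget
    for t in range(int(sorted_counts[-1]) + 1):
        above = all_counts.size - np.searchsorted(sorted_counts, t, side="right")
        if above <= budget:
            return t
    return int(sorted_counts[-1])
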