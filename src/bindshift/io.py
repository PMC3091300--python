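"""Readers and writers for the formats the pipeline exchanges.

All coordinates are 0-based half-open, matching BED; SAM positions are
converted on entry.  Events are written as BED6+ with -log10 corrected
p-value in the score column; per-base tracks round-trip through
bedGraph with run-length compression.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pysam

from .differential import ExclusivityResult, SiteSet
from .events import BindingEvent, EnrichedDomain
from .reads import ReadDataset
from .synth import GroundTruth

__all__ = [
    "read_alignments",
    "write_reads_bed",
    "write_events",
    "read_events",
    "write_domains",
    "write_fasta",
    "read_fasta",
    "write_bedgraph",
    "read_bedgraph",
    "write_sites_bed",
    "write_exclusivity_tsv",
    "write_ground_truth",
    "read_ground_truth",
]


class AlignmentParseError(ValueError):
    pass


def read_alignments(
    path: str | Path,
    fmt: str = "BED6",
    chrom_lengths: dict[str, int] | None = None,
) -> ReadDataset:
    """Load strand-aware 5' positions from BED6 or (headered) SAM.

    BED: the 5' end is ``start`` on + and ``end - 1`` on -.  SAM: FLAG
    bit 16 marks the reverse strand; the 5' end is the leftmost
    reference position on + and the rightmost on -.  Malformed lines
    raise with their line number; reads on chromosomes absent from
    ``chrom_lengths`` raise naming the chromosome.
    """
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "SAM":
        return _read_sam(path, chrom_lengths)
    if fmt != "BED6":
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if chrom_lengths is None:
        raise ValueError("BED input requires chrom_lengths")
    pos: dict[str, list[int]] = {}
    strand: dict[str, list[int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AlignmentParseError(f"{path}:{ln}: expected >= 6 BED fields")
            chrom, s, e, _, _, st = fields[:6]
            if chrom not in chrom_lengths:
                raise AlignmentParseError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise AlignmentParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if st not in "+-":
                raise AlignmentParseError(f"{path}:{ln}: bad strand {st!r}")
            five = start if st == "+" else end - 1
            pos.setdefault(chrom, []).append(five)
            strand.setdefault(chrom, []).append(1 if st == "+" else -1)
    return ReadDataset(
        dict(chrom_lengths),
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=np.int8) for c, v in strand.items()},
    )


def _read_sam(path: Path, chrom_lengths: dict[str, int] | None) -> ReadDataset:
    pos: dict[str, list[int]] = {}
    strand: dict[str, list[int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = chrom_lengths or {
            r: int(sam.header.get_reference_length(r)) for r in sam.references
        }
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if chrom not in lengths:
                raise AlignmentParseError(f"{path}: unknown chromosome {chrom!r}")
            if rec.is_reverse:
                five = rec.reference_end - 1
                strand.setdefault(chrom, []).append(-1)
            else:
                five = rec.reference_start
                strand.setdefault(chrom, []).append(1)
            pos.setdefault(chrom, []).append(five)
    return ReadDataset(
        dict(lengths),
        {c: np.array(v, dtype=np.int64) for c, v in pos.items()},
        {c: np.array(v, dtype=np.int8) for c, v in strand.items()},
    )


def write_reads_bed(path: str | Path, reads: ReadDataset, read_length: int = 36) -> None:
    """Write each read as a ``read_length``-bp BED6 interval at its 5' end."""
    with open(path, "w") as fh:
        for chrom in reads.chroms():
            pos, strand = reads.subset(chrom)
            L = reads.chrom_lengths[chrom]
            for i, (p, st) in enumerate(zip(pos, strand)):
                if st > 0:
                    s, e = p, min(p + read_length, L)
                else:
                    s, e = max(p - read_length + 1, 0), p + 1
                fh.write(f"{chrom}\t{s}\t{e}\tr{i}\t0\t{'+' if st > 0 else '-'}\n")


_EVENT_COLS = "# chrom\tstart\tend\tname\tscore\tstrand\tpeak\tsignal\tscaled_control\traw_p\tfold"


def write_events(
    path: str | Path, events: list[BindingEvent], header_meta: dict | None = None
) -> None:
    """BED6+ events: score = -log10 corrected p (capped at 300)."""
    with open(path, "w") as fh:
        if header_meta:
            fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
        fh.write(_EVENT_COLS + "\n")
        for i, ev in enumerate(events):
            score = min(-np.log10(max(ev.p_corrected, 1e-300)), 300.0)
            fh.write(
                f"{ev.chrom}\t{ev.start}\t{ev.end}\tevent{i}\t{score:.4f}\t.\t"
                f"{ev.peak}\t{ev.signal_count:.6g}\t{ev.scaled_control:.6g}\t"
                f"{ev.p_raw:.6e}\t{ev.fold:.6g}\n"
            )


def read_events(path: str | Path) -> list[BindingEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            score = float(f[4])
            p_corr = 10 ** (-score)
            events.append(
                BindingEvent(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    peak=int(f[6]),
                    signal_count=float(f[7]),
                    control_count=float("nan"),
                    scaled_control=float(f[8]),
                    p_raw=float(f[9]),
                    p_corrected=p_corr,
                    fold=float(f[10]),
                )
            )
    return events


def write_domains(path: str | Path, domains: list[EnrichedDomain]) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(domains):
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\tdomain{i}\t{d.p_corrected:.6e}\n")


def write_fasta(path: str | Path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bedgraph(path: str | Path, track: dict[str, np.ndarray]) -> None:
    """Run-length compressed per-base track."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(L, dtype=np.float32) for c, L in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom in out:
                out[chrom][int(s) : int(e)] = float(v)
    return out


def write_sites_bed(path: str | Path, sites: SiteSet) -> None:
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(sites.sites):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sites.label}_{i}\t0\t.\n")


def write_exclusivity_tsv(path: str | Path, result: ExclusivityResult) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tclass\n")
        for label, ss in (
            ("constitutive", result.constitutive),
            ("A-exclusive", result.a_exclusive),
            ("B-exclusive", result.b_exclusive),
            ("ambiguous", result.ambiguous),
        ):
            for chrom, pos in ss.sites:
                fh.write(f"{chrom}\t{pos}\t{label}\n")


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "events": [
            {"chrom": c, "position": p, "strength": s, "label": lab}
            for c, p, s, lab in truth.events
        ],
        "motifs": [
            {"chrom": c, "start": s, "strand": st, "config": name}
            for c, s, st, name in truth.motifs
        ],
        "scaling": truth.scaling,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        events=[
            (e["chrom"], e["position"], e["strength"], e["label"])
            for e in payload["events"]
        ],
        motifs=[
            (m["chrom"], m["start"], m["strand"], m["config"])
            for m in payload["motifs"]
        ],
        scaling=payload["scaling"],
    )
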