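"""Transcribed-unit calling from strand-specific nascent coverage.

Segmentation is a threshold/gap/length scan: maximal runs of bins at or
above a coverage threshold tau, merged across sub-threshold gaps of at most
``max_gap`` bp, discarding merged runs shorter than ``min_length`` bp.
Intervals overlapping an annotated gene (padded by the genic exclusion
margin) are genic; remaining intervals on opposite strands whose spans lie
within the pairing distance merge into single bidirectional eRNA units —
the hallmark of divergent enhancer transcription.

When tau is not given it is picked per track as the smallest integer >= 2
at which the genome-wide expected number of bins reaching it under a
Poisson background (rate = the track's mean bin coverage) falls below 0.1%
of bins. That keeps isolated background reads sub-threshold at any
sequencing depth while staying far below block-like transcription signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTracks, PipelineError

__all__ = [
    "SegmentationParams",
    "TranscriptionUnit",
    "auto_threshold",
    "segment_coverage",
    "classify_units",
    "quantify_units",
    "annotate_ernas",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold/gap/length segmentation and eRNA-pairing parameters.

    tau: minimum per-bin coverage (None = auto per pooled track);
    max_gap / min_length in bp; genic_margin pads genes before the
    genic/intergenic decision; pair_distance is the maximum separation of
    opposite-strand spans merged into one bidirectional eRNA.
    """

    tau: float | None = None
    max_gap: int = 200
    min_length: int = 200
    genic_margin: int = 1_000
    pair_distance: int = 1_000

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")
        for name in ("max_gap", "min_length", "genic_margin", "pair_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TranscriptionUnit:
    """A transcribed interval: genic, eRNA (possibly merged bidirectional
    pair), or other."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' for merged bidirectional units
    unit_class: str  # genic / eRNA / other
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"unit {self.id}: start must be < end")


def auto_threshold(values: np.ndarray, fp_fraction: float = 1e-3) -> float:
    """Background-aware coverage threshold for one (pooled) track."""
    lam = float(values.mean())
    tau = 2
    while stats.poisson.sf(tau - 1, lam) >= fp_fraction and tau < 10_000:
        tau += 1
    return float(tau)


def segment_coverage(values: np.ndarray, params: SegmentationParams,
                     bin_size: int) -> list[tuple[int, int]]:
    """Segment one binned track into bp intervals (sorted, non-overlapping).

    A run is a maximal stretch of bins with value >= tau; runs separated by
    at most ``max_gap`` bp of sub-threshold bins are merged, and merged runs
    spanning less than ``min_length`` bp are discarded. Interval bounds are
    bin-aligned, 0-based half-open. Empty input yields an empty list.
    """
    values = np.asarray(values)
    if values.size == 0:
        return []
    tau = params.tau if params.tau is not None else auto_threshold(values)
    above = np.flatnonzero(values >= tau)
    if above.size == 0:
        return []
    gap_bins = params.max_gap // bin_size
    breaks = np.flatnonzero(np.diff(above) - 1 > gap_bins)
    starts = np.concatenate(([above[0]], above[breaks + 1]))
    ends = np.concatenate((above[breaks], [above[-1]])) + 1
    keep = (ends - starts) * bin_size >= params.min_length
    return [(int(s) * bin_size, int(e) * bin_size)
            for s, e in zip(starts[keep], ends[keep])]


def _overlaps_any(start: int, end: int, starts: np.ndarray,
                  ends: np.ndarray) -> bool:
    """Interval-vs-sorted-intervals overlap (intervals may touch freely)."""
    if len(starts) == 0:
        return False
    i = np.searchsorted(starts, end)
    if i == 0:
        return False
    return bool((ends[:i] > start).any())


def classify_units(
    intervals_by_strand: dict[str, dict[str, list[tuple[int, int]]]],
    annotation,
    params: SegmentationParams,
) -> list[TranscriptionUnit]:
    """Classify segmented intervals into genic / eRNA / other units.

    ``intervals_by_strand`` maps strand -> chrom -> interval list. Intervals
    overlapping any gene padded by ``genic_margin`` become genic units.
    Remaining intergenic intervals on opposite strands within
    ``pair_distance`` of each other (span gap, 0 when overlapping) merge —
    transitively — into single eRNA units whose span is the union and whose
    id is ``chrom:start-end``; unpaired intergenic intervals become eRNAs if
    they reach ``min_length``, otherwise class ``other``. The result is
    sorted by (chrom, start, end) and independent of input ordering.
    """
    genes = annotation.genes
    units: list[TranscriptionUnit] = []
    chroms = sorted({c for per in intervals_by_strand.values() for c in per})
    for chrom in chroms:
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        gs = (sub["start"].to_numpy() - params.genic_margin).clip(min=0)
        ge = sub["end"].to_numpy() + params.genic_margin

        intergenic: list[tuple[int, int, str]] = []
        for strand in ("+", "-"):
            for start, end in sorted(intervals_by_strand.get(strand, {})
                                     .get(chrom, [])):
                if _overlaps_any(start, end, gs, ge):
                    units.append(TranscriptionUnit(
                        id=f"tu:{chrom}:{start}-{end}({strand})", chrom=chrom,
                        start=start, end=end, strand=strand,
                        unit_class="genic",
                        source_ids=(f"{chrom}:{start}-{end}({strand})",)))
                else:
                    intergenic.append((start, end, strand))

        # transitive cross-strand pairing by span distance
        intergenic.sort()
        n = len(intergenic)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            s_i, e_i, st_i = intergenic[i]
            for j in range(i + 1, n):
                s_j, e_j, st_j = intergenic[j]
                if s_j - e_i > params.pair_distance:
                    break
                if st_i != st_j:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            ivs = [intergenic[i] for i in members]
            start = min(s for s, _, _ in ivs)
            end = max(e for _, e, _ in ivs)
            strands = {st for _, _, st in ivs}
            merged = len(strands) > 1
            cls = "eRNA" if merged or (end - start) >= params.min_length \
                else "other"
            units.append(TranscriptionUnit(
                id=f"{'eRNA' if cls == 'eRNA' else 'tu'}:{chrom}:{start}-{end}",
                chrom=chrom, start=start, end=end,
                strand="." if merged else next(iter(strands)),
                unit_class=cls,
                source_ids=tuple(f"{chrom}:{s}-{e}({st})" for s, e, st in ivs)))
    units.sort(key=lambda u: (u.chrom, u.start, u.end, u.strand))
    return units


def quantify_units(units: list[TranscriptionUnit],
                   tracks: CoverageTracks) -> pd.DataFrame:
    """Integer counts per unit per sample (bin-sum convention).

    Genic units count their own strand only; eRNA and other units sum both
    strands (bidirectional transcription). Bins overlapping the unit span
    contribute fully. Units on chromosomes absent from the tracks raise.
    """
    bs = tracks.bin_size
    samples = tracks.samples
    out = np.zeros((len(units), len(samples)), dtype=np.int64)
    for ui, u in enumerate(units):
        if u.chrom not in tracks.chrom_lengths:
            raise PipelineError(f"unit {u.id} on chromosome {u.chrom!r} "
                                "absent from coverage tracks")
        b0, b1 = u.start // bs, -(-u.end // bs)
        strands = [u.strand] if u.unit_class == "genic" else ["+", "-"]
        for si, sample in enumerate(samples):
            total = 0
            for strand in strands:
                arr = tracks.data.get((sample, u.chrom, strand))
                if arr is not None:
                    total += int(arr[b0:b1].sum())
            out[ui, si] = total
    return pd.DataFrame(out, index=pd.Index([u.id for u in units],
                                            name="feature"), columns=samples)


def annotate_ernas(
    tracks: CoverageTracks,
    annotation,
    params: SegmentationParams | None = None,
) -> tuple[list[TranscriptionUnit], pd.DataFrame]:
    """Pooled-coverage eRNA annotation plus per-sample quantification.

    Units are segmented on coverage pooled across all samples (so the
    annotation cannot be biased toward one condition) and then quantified
    per sample. Returns (units, counts).
    """
    params = params or SegmentationParams()
    pooled = tracks.pooled()
    if params.tau is None:
        # one global auto-threshold across the pooled genome
        lam_all = np.concatenate([arr for arr in pooled.values()])
        params = replace(params, tau=auto_threshold(lam_all))
    intervals: dict[str, dict[str, list[tuple[int, int]]]] = {"+": {}, "-": {}}
    for (chrom, strand), arr in sorted(pooled.items()):
        intervals[strand][chrom] = segment_coverage(arr, params, tracks.bin_size)
    units = classify_units(intervals, annotation, params)
    counts = quantify_units(units, tracks)
    return units, counts


def units_to_bed(units: list[TranscriptionUnit]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [u.chrom for u in units],
        "start": [u.start for u in units],
        "end": [u.end for u in units],
        "name": [f"{u.unit_class}|{u.id}" for u in units],
        "score": 0,
        "strand": [u.strand for u in units],
    })
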