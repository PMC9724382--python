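"""Signal-track annotation, MNase replicate aggregation, gene-body flags.

Per-site experimental feature values are the coverage-weighted mean of a
track over the 23 bp target interval; bases without coverage contribute
0, and sites on chromosomes absent from a track (or in cell lines with
no track at all) get 0 — the missing-data convention for MNase.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict

import numpy as np

from .records import (
    TARGET_LEN,
    Dataset,
    GeneBodyMap,
    OffTargetRecord,
    SignalTrack,
)

logger = logging.getLogger(__name__)


class _IndexedTrack:
    """Per-chromosome sorted arrays for O(log n) interval queries."""

    def __init__(self, track: SignalTrack):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        for chrom, start, end, value in track.normalized().intervals:
            per_chrom[chrom].append((start, end, value))
        for chrom, ivs in per_chrom.items():
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            values = np.array([iv[2] for iv in ivs], dtype=float)
            self.by_chrom[chrom] = (starts, ends, values)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean over [start, end); uncovered bases are 0."""
        if chrom not in self.by_chrom:
            return 0.0
        starts, ends, values = self.by_chrom[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        ov = np.clip(ov, 0, None)
        return float((ov * values[i0:i1]).sum() / (end - start))


def annotate_track(rec: OffTargetRecord, track: SignalTrack | _IndexedTrack) -> float:
    """Mean track value across the 23 target base pairs."""
    idx = track if isinstance(track, _IndexedTrack) else _IndexedTrack(track)
    if rec.chrom not in idx.by_chrom:
        logger.warning("chromosome %s absent from track; assigning 0", rec.chrom)
        return 0.0
    return idx.mean(rec.chrom, rec.pos, rec.pos + TARGET_LEN)


def annotate_dataset(
    ds: Dataset, track: SignalTrack, feature_name: str, cell_line: str | None = None
) -> None:
    """Annotate every record (or only one cell line's) with a track mean."""
    idx = _IndexedTrack(track)
    for rec in ds.records:
        if cell_line is not None and rec.cell_line != cell_line:
            continue
        rec.experimental_scores[feature_name] = idx.mean(
            rec.chrom, rec.pos, rec.pos + TARGET_LEN
        )
    ds.refresh_manifest()


def annotate_mnase(ds: Dataset, mnase_by_cell_line: dict[str, SignalTrack]) -> None:
    """Fill the MNase feature from per-cell-line aggregated tracks.

    Records in cell lines without a track get 0 (missing-data rule).
    """
    indexed = {cl: _IndexedTrack(t) for cl, t in mnase_by_cell_line.items()}
    for rec in ds.records:
        idx = indexed.get(rec.cell_line)
        rec.experimental_scores["MNase"] = (
            0.0 if idx is None else idx.mean(rec.chrom, rec.pos, rec.pos + TARGET_LEN)
        )
    ds.refresh_manifest()


def _step_breakpoints(tracks: list[SignalTrack]) -> dict[str, np.ndarray]:
    pts: dict[str, set[int]] = defaultdict(set)
    for t in tracks:
        for chrom, start, end, _ in t.intervals:
            pts[chrom].add(start)
            pts[chrom].add(end)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in pts.items()}


def average_replicates(tracks: list[SignalTrack], name: str, cell_line: str) -> SignalTrack:
    """Position-wise arithmetic mean of replicate tracks.

    The mean is taken over all replicates on the union of covered
    positions; a replicate without coverage at a position contributes 0.
    Per-replicate coverage is logged before averaging.
    """
    for t in tracks:
        logger.info(
            "replicate %s (%s): %d intervals", t.name, cell_line, len(t.intervals)
        )
    indexed = [_IndexedTrack(t) for t in tracks]
    out: list[tuple[str, int, int, float]] = []
    for chrom, bps in _step_breakpoints(tracks).items():
        for start, end in zip(bps[:-1], bps[1:]):
            vals = [idx.mean(chrom, int(start), int(end)) for idx in indexed]
            v = float(np.mean(vals))
            if v != 0.0:
                out.append((chrom, int(start), int(end), v))
    return SignalTrack(name, cell_line, out).normalized()


def rescale_unit(track: SignalTrack) -> SignalTrack:
    """Min-max rescale track values to [0, 1]; a constant track maps to 0."""
    if not track.intervals:
        return track
    values = np.array([iv[3] for iv in track.intervals], dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        scaled = np.zeros_like(values)
    else:
        scaled = (values - lo) / (hi - lo)
    return SignalTrack(
        track.name,
        track.cell_line,
        [(c, s, e, float(v)) for (c, s, e, _), v in zip(track.intervals, scaled)],
    )


def aggregate_mnase(
    tracks_by_cell_line: dict[str, list[SignalTrack]]
) -> dict[str, SignalTrack]:
    """Average replicates per cell line, rescale each to [0,1], and combine.

    Returns the combined MNase feature keyed by cell line; annotating a
    record uses its own cell line's track (concatenation into a single
    feature column happens at annotation time).  Cell lines with an
    empty track list are omitted with a log message.
    """
    out: dict[str, SignalTrack] = {}
    for cell_line, tracks in tracks_by_cell_line.items():
        if not tracks:
            logger.info("cell line %s has no MNase tracks; omitted", cell_line)
            continue
        avg = average_replicates(tracks, "MNase", cell_line)
        out[cell_line] = rescale_unit(avg)
    return out


class _IndexedGeneBodies:
    def __init__(self, gb: GeneBodyMap):
        self.by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, start, end in gb.sorted().intervals:
            per_chrom[chrom].append((start, end))
        for chrom, ivs in per_chrom.items():
            self.by_chrom[chrom] = (
                [iv[0] for iv in ivs],
                sorted(iv[1] for iv in ivs),
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        # any interval with start < end-of-query and end > start-of-query
        n_start_before = bisect_left(starts, end)
        n_end_before = bisect_right(ends, start)
        return n_start_before > n_end_before


def flag_gene_body(rec: OffTargetRecord, gb: GeneBodyMap | _IndexedGeneBodies) -> bool:
    """True iff the 23 bp target overlaps >=1 gene-body span by >=1 bp."""
    idx = gb if isinstance(gb, _IndexedGeneBodies) else _IndexedGeneBodies(gb)
    return idx.overlaps(rec.chrom, rec.pos, rec.pos + TARGET_LEN)


def flag_dataset_gene_bodies(ds: Dataset, gb: GeneBodyMap) -> None:
    idx = _IndexedGeneBodies(gb)
    for rec in ds.records:
        rec.in_gene_body = idx.overlaps(rec.chrom, rec.pos, rec.pos + TARGET_LEN)
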