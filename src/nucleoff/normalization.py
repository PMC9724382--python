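"""Cross-study cleavage-activity harmonization and putative-site augmentation.

Raw cleavage rates come from heterogeneous assays whose frequencies span
several orders of magnitude, so each study is harmonized separately: a
Box-Cox transform (maximum-likelihood lambda over a grid) followed by an
affine rescale so the transformed rates have sample mean 0 and sample
standard deviation 2.  The resulting cleavage activity (CA) is clipped
to [-4, 4] (i.e. +-2 sigma); rates below the lowest reported assay
accuracy of 1e-5 — including the exact zeros of putative sites — are
set to -4 before any transform.

Putative off-target augmentation scans a genome for 23 bp windows on
either strand within Hamming distance <7 of any experimental target and
assumes them inactive (CA = -4).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import special, stats

from .records import (
    CONTEXT_LEN,
    SEQ_CODE,
    SEQ_VALID,
    TARGET_LEN,
    TARGET_OFFSET,
    Dataset,
    OffTargetRecord,
    encode_seq,
    reverse_complement,
)

logger = logging.getLogger(__name__)

FLOOR_THRESHOLD = 1e-5
FLOOR_VALUE = -4.0
CLIP_BOUND = 4.0
TARGET_SD = 2.0

#: Box-Cox lambda grid for maximum-likelihood selection.
LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


class NormalizationError(ValueError):
    pass


class DegenerateDistributionError(NormalizationError):
    pass


class InsufficientDataError(NormalizationError):
    pass


@dataclass
class StudyNormalization:
    study_id: str
    lmbda: float
    location: float
    scale: float
    floor_threshold: float = FLOOR_THRESHOLD
    floor_value: float = FLOOR_VALUE
    clip_bound: float = CLIP_BOUND

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyNormalization":
        return cls(**json.loads(text))


def fit_boxcox(rates, study_id: str) -> StudyNormalization:
    """Fit a per-study Box-Cox normalization to positive cleavage rates.

    Only rates strictly above the assay floor participate in the fit
    (sub-floor rates are pinned at -4 regardless).  Lambda maximizes the
    Box-Cox log-likelihood over a [-2, 2] grid (step 0.01); location and
    scale are set so the transformed fitting rates have sample mean 0
    and sample standard deviation 2 (ddof=1) before clipping.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise NormalizationError(f"{study_id}: rates must be positive for fitting")
    usable = rates[rates > FLOOR_THRESHOLD]
    if usable.size < 10:
        raise InsufficientDataError(
            f"{study_id}: only {usable.size} rates above the floor (need >=10)"
        )
    if np.all(usable == usable[0]):
        raise DegenerateDistributionError(f"{study_id}: all rates equal")
    llf = np.array([stats.boxcox_llf(l, usable) for l in LAMBDA_GRID])
    lmbda = float(LAMBDA_GRID[int(np.argmax(llf))])
    transformed = special.boxcox(usable, lmbda)
    location = float(np.mean(transformed))
    scale = float(np.std(transformed, ddof=1))
    if scale == 0.0 or not math.isfinite(scale):
        raise DegenerateDistributionError(f"{study_id}: degenerate transformed scale")
    return StudyNormalization(study_id=study_id, lmbda=lmbda, location=location, scale=scale)


def transform_unclipped(rates, norm: StudyNormalization) -> np.ndarray:
    """Box-Cox + affine rescale without the floor/clip rules (diagnostics)."""
    rates = np.asarray(rates, dtype=float)
    t = special.boxcox(rates, norm.lmbda)
    return TARGET_SD * (t - norm.location) / norm.scale


def apply_normalization(rate: float, norm: StudyNormalization) -> float:
    """Normalized cleavage activity for one raw rate.

    Monotone nondecreasing in the rate; exactly -4 below the floor
    (including rate 0); otherwise transformed then clipped to [-4, 4].
    """
    if rate < 0:
        raise NormalizationError("negative cleavage rate")
    if rate < norm.floor_threshold:
        return norm.floor_value
    ca = float(transform_unclipped(np.array([rate]), norm)[0])
    return float(np.clip(ca, -norm.clip_bound, norm.clip_bound))


def normalize_dataset(ds: Dataset) -> dict[str, StudyNormalization]:
    """Fit per-study normalizations and fill ``cleavage_activity`` in place.

    Putative records are pinned at CA = -4.  Returns the fitted
    per-study parameters.
    """
    by_study: dict[str, list[OffTargetRecord]] = {}
    for rec in ds.records:
        by_study.setdefault(rec.study_id, []).append(rec)
    norms: dict[str, StudyNormalization] = {}
    for study_id, recs in by_study.items():
        rates = np.array(
            [r.cleavage_rate for r in recs if not r.is_putative and r.cleavage_rate > FLOOR_THRESHOLD]
        )
        if rates.size >= 10:
            norm = fit_boxcox(rates, study_id)
            norms[study_id] = norm
        else:
            norm = None
        for rec in recs:
            if rec.is_putative or rec.cleavage_rate < FLOOR_THRESHOLD:
                rec.cleavage_activity = FLOOR_VALUE
            elif norm is not None:
                rec.cleavage_activity = apply_normalization(rec.cleavage_rate, norm)
            else:
                logger.warning(
                    "study %s: too few rates to fit; flooring %s", study_id, rec.record_id
                )
                rec.cleavage_activity = FLOOR_VALUE
    return norms


# --- activity bins -----------------------------------------------------------

BIN_LOWEST = "lowest"
BIN_LOW = "low"
BIN_HIGH = "high"
ACTIVITY_BINS = (BIN_LOWEST, BIN_LOW, BIN_HIGH)


def bin_activity(ca: float) -> str:
    """Assign CA to the lowest (CA=-4), low (-4<CA<=2) or high (CA>2) bin."""
    if not (FLOOR_VALUE <= ca <= CLIP_BOUND):
        raise NormalizationError(f"CA {ca} outside [-4, 4]")
    if ca == FLOOR_VALUE:
        return BIN_LOWEST
    return BIN_LOW if ca <= 2.0 else BIN_HIGH


# --- putative-site augmentation ----------------------------------------------

def _scan_strand(
    genome: str, seed_matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min Hamming distance of every 23 bp window to any seed target.

    Returns (positions, min_distance, argmin_seed) for windows whose
    23-mer and surrounding 169 bp context are all valid ACGT and fit
    inside the genome (73 bp margin each side).
    """
    raw = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    codes = SEQ_CODE[raw]
    valid = SEQ_VALID[raw]
    n_win = len(genome) - TARGET_LEN + 1
    if n_win <= 0:
        return np.array([], int), np.array([], int), np.array([], int)
    windows = np.lib.stride_tricks.sliding_window_view(codes, TARGET_LEN)
    ctx_ok = np.lib.stride_tricks.sliding_window_view(valid, CONTEXT_LEN).all(axis=1)
    pos = np.arange(n_win)
    in_range = (pos >= TARGET_OFFSET) & (pos + TARGET_LEN + TARGET_OFFSET <= len(genome))
    in_range[in_range] &= ctx_ok[pos[in_range] - TARGET_OFFSET]
    pos = pos[in_range]
    windows = windows[in_range]
    best = np.full(pos.shape, TARGET_LEN + 1, dtype=np.int32)
    arg = np.zeros(pos.shape, dtype=np.int64)
    for j in range(seed_matrix.shape[0]):
        d = (windows != seed_matrix[j]).sum(axis=1).astype(np.int32)
        better = d < best
        best[better] = d[better]
        arg[better] = j
    return pos, best, arg


def augment_putative(
    genome: dict[str, str] | str,
    seeds: list[OffTargetRecord],
    max_mismatches: int = 6,
) -> list[OffTargetRecord]:
    """Putative off-target records from a Hamming scan of the genome.

    Both strands are scanned for 23 bp windows within ``max_mismatches``
    (default 6, i.e. strictly fewer than 7 mismatches) of any seed
    target sequence.  Windows at a seed's own locus are excluded.
    Returned records carry the surrounding 169 bp context (in gRNA
    orientation), cleavage rate 0, CA = -4 and ``is_putative=True``;
    windows within 73 bp of a contig end are skipped.  Plain Hamming
    distance over the full 23 bp is used (no PAM-proximal weighting).
    """
    if isinstance(genome, str):
        genome = {"synth": genome}
    if not seeds:
        return []
    seed_matrix = np.stack([encode_seq(s.target_seq) for s in seeds])
    seed_loci = {(s.chrom, s.pos, s.strand) for s in seeds}
    out: list[OffTargetRecord] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for strand in ("+", "-"):
            scan_seq = seq if strand == "+" else reverse_complement(seq)
            pos_arr, dist, arg = _scan_strand(scan_seq, seed_matrix)
            hits = pos_arr[dist <= max_mismatches]
            hit_arg = arg[dist <= max_mismatches]
            for p, j in zip(hits, hit_arg):
                gpos = int(p) if strand == "+" else len(seq) - TARGET_LEN - int(p)
                if (chrom, gpos, strand) in seed_loci:
                    continue
                context = scan_seq[p - TARGET_OFFSET : p + TARGET_LEN + TARGET_OFFSET]
                seed = seeds[int(j)]
                out.append(
                    OffTargetRecord(
                        record_id=f"put_{chrom}_{gpos}_{strand}",
                        grna_seq=seed.grna_seq,
                        target_seq=context[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN],
                        context_seq=context,
                        chrom=chrom,
                        pos=gpos,
                        strand=strand,
                        study_id=seed.study_id,
                        cell_line=seed.cell_line,
                        cleavage_rate=0.0,
                        cleavage_activity=FLOOR_VALUE,
                        is_putative=True,
                    )
                )
    logger.info("augmentation: %d putative records from %d seeds", len(out), len(seeds))
    return out


def save_normalizations(norms: dict[str, StudyNormalization], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({k: asdict(v) for k, v in norms.items()}, indent=2))
    return path


def load_normalizations(path: str | Path) -> dict[str, StudyNormalization]:
    data = json.loads(Path(path).read_text())
    return {k: StudyNormalization(**v) for k, v in data.items()}
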