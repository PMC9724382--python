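"""Synthetic crisprSQL-shaped datasets with planted statistical structure.

The generator emulates the shape of the curated off-target corpus —
23 bp targets centered in 169 bp contexts drawn from a genome, raw
per-study cleavage rates spanning several orders of magnitude, a
putative (assumed-inactive) majority fraction of 52%, per-cell-line
MNase-like signal tracks, gene-body intervals and four binding
free-energy terms per record — while planting one known monotone link
for recovery tests: the log cleavage rate of experimental records is

    log(rate) = a_study + effect_size * z + Normal(0, noise_sd)

where z is the Shannon entropy (bits) of the dinucleotide distribution
of the context's central 147 bp.  Low-entropy (repetitive) contexts
thus carry low activity, mimicking the separation that nucleosome-
complexity scores show on real data, without depending on any scorer.

The synthetic genome is a mosaic of blocks with varying period-2
repetitiveness so that context entropy varies widely; repeat units are
drawn from the background base composition so GC content stays
uncorrelated with the planted covariate.  Putative records are mutated
copies (Hamming distance 0-6) of experimental targets planted into the
genome — the acceptance set of the Hamming-scan augmenter, constructed
directly so generation scales to large n.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nucleosome
from .energies import EnergyTerms
from .normalization import FLOOR_VALUE, normalize_dataset
from .records import (
    CONTEXT_LEN,
    PROTOSPACER_LEN,
    TARGET_LEN,
    TARGET_OFFSET,
    Dataset,
    GeneBodyMap,
    OffTargetRecord,
    SignalTrack,
    encode_seq,
    reverse_complement,
)
from .tracks import annotate_mnase, flag_dataset_gene_bodies

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_studies: int = 3
    sites_per_study: int = 300
    putative_fraction: float = 0.52
    genome_length: int = 120_000
    effect_size: float = 2.0
    noise_sd: float = 1.0
    cell_lines: tuple[str, ...] = ("HeLa", "K562", "U2OS")
    rate_floor: float = 1e-6
    gc_content: float = 0.40
    putative_repetitive_bias: float = 3.0
    chrom: str = "chrS"

    def validate(self) -> None:
        if self.n_studies < 1 or self.sites_per_study < 1:
            raise ConfigurationError("counts must be positive")
        if not (0.0 <= self.putative_fraction <= 1.0):
            raise ConfigurationError("putative_fraction must lie in [0, 1]")
        if self.genome_length < 1000:
            raise ConfigurationError("genome_length must be >= 1000")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.rate_floor <= 0:
            raise ConfigurationError("rate_floor must be positive")

    def n_experimental(self) -> int:
        return self.n_studies * self.sites_per_study

    def n_putative(self) -> int:
        pf = self.putative_fraction
        if pf >= 1.0:
            raise ConfigurationError("putative_fraction must be < 1 for generation")
        return int(round(self.n_experimental() * pf / (1.0 - pf)))


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery tests."""

    planted_covariate: dict[str, float] = field(default_factory=dict)
    true_effect_size: float = 0.0
    generating_lambda: dict[str, float] = field(default_factory=dict)


_REPEAT_BLOCK = 300  # bp; genome mosaic granularity for repetitiveness


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _mosaic_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Genome codes with block-wise period-2 repetitiveness.

    Within each block, position i copies the base two back with a
    block-specific probability r ~ U(0,1); otherwise it is an iid draw
    from the background composition.  High-r blocks converge to (XY)n
    repeats whose unit is itself background-distributed.
    """
    iid = rng.choice(4, size=length, p=_base_probs(gc)).astype(np.uint8)
    n_blocks = (length + _REPEAT_BLOCK - 1) // _REPEAT_BLOCK
    # bimodal repetitiveness: half the blocks near-random, half strongly
    # repetitive, so context entropy spans a wide range
    low = rng.uniform(0.0, 0.7, size=n_blocks)
    high = rng.uniform(0.85, 1.0, size=n_blocks)
    r_block = np.where(rng.uniform(size=n_blocks) < 0.5, low, high)
    r = np.repeat(r_block, _REPEAT_BLOCK)[:length]
    copy = rng.uniform(size=length) < r
    copy[:2] = False
    out = iid.copy()
    # resolve copy chains per parity class: each position takes the value of
    # the nearest non-copy ancestor at distance 2, 4, ...
    idx = np.arange(length)
    for parity in (0, 1):
        sel = idx[parity::2]
        src = np.where(~copy[sel], np.arange(sel.size), 0)
        src = np.maximum.accumulate(src)
        out[sel] = out[sel][src]
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _gene_bodies(rng: np.random.Generator, length: int, chrom: str) -> GeneBodyMap:
    """Alternating gene/intergenic spans covering ~40% of the genome."""
    intervals = []
    pos = int(rng.integers(0, 3000))
    while pos < length:
        gene_len = int(rng.integers(1500, 4500))
        end = min(pos + gene_len, length)
        if end > pos:
            intervals.append((chrom, pos, end))
        pos = end + int(rng.integers(1500, 7500))
    return GeneBodyMap(intervals)


def _smooth_track(
    rng: np.random.Generator, length: int, chrom: str, name: str, cell_line: str
) -> SignalTrack:
    """Smooth positive signal in 50 bp bins (random walk through softplus)."""
    bin_size = 50
    n_bins = max(1, length // bin_size)
    steps = rng.normal(0.0, 0.25, size=n_bins)
    walk = np.cumsum(steps)
    walk -= walk.mean()
    values = np.log1p(np.exp(walk))  # softplus: positive, smooth
    intervals = [
        (chrom, i * bin_size, min((i + 1) * bin_size, length), float(v))
        for i, v in enumerate(values)
    ]
    return SignalTrack(name, cell_line, intervals)


def generate_genome(
    cfg: SyntheticConfig,
) -> tuple[str, GeneBodyMap, dict[str, SignalTrack]]:
    """Synthetic genome, gene-body map and per-cell-line MNase-like track."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = _codes_to_str(_mosaic_genome(rng, cfg.genome_length, cfg.gc_content))
    gb = _gene_bodies(rng, cfg.genome_length, cfg.chrom)
    tracks = {
        cl: _smooth_track(rng, cfg.genome_length, cfg.chrom, "MNase", cl)
        for cl in cfg.cell_lines
    }
    return genome, gb, tracks


def dinucleotide_entropy(context: str) -> float:
    """Shannon entropy (bits) of the dinucleotide distribution of the
    central 147 bp of a 169 bp context — the planted covariate."""
    margin = (CONTEXT_LEN - nucleosome.WINDOW_LEN) // 2  # 11
    codes = encode_seq(context)[margin : CONTEXT_LEN - margin]
    dinucs = codes[:-1].astype(np.int64) * 4 + codes[1:]
    counts = np.bincount(dinucs, minlength=16).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _slot_entropies(genome_codes: np.ndarray, slots: np.ndarray) -> np.ndarray:
    """Dinucleotide entropy of the central 147 bp around each slot start."""
    margin = (CONTEXT_LEN - 147) // 2  # 11
    d = genome_codes[:-1].astype(np.int64) * 4 + genome_codes[1:]
    n_steps = 147 - 1
    starts = slots - TARGET_OFFSET + margin
    win = np.lib.stride_tricks.sliding_window_view(d, n_steps)[starts]
    counts = np.zeros((len(slots), 16))
    np.add.at(counts, (np.arange(len(slots))[:, None], win), 1.0)
    p = counts / n_steps
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h.sum(axis=1)


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, span: int) -> str:
    """Substitute n_mut random positions within seq[:span]."""
    s = bytearray(seq.encode("ascii"))
    if n_mut == 0:
        return seq
    positions = rng.choice(span, size=n_mut, replace=False)
    for p in positions:
        current = s[p]
        choices = [b for b in b"ACGT" if b != current]
        s[p] = choices[int(rng.integers(3))]
    return s.decode("ascii")


def generate_energy_terms(rec: OffTargetRecord, seed: int) -> EnergyTerms:
    """Synthetic CRISPRspec-style free-energy terms for one record.

    Hybridization energy rewards protospacer matches (-0.5 per matched
    base plus unit noise); spacer folding and duplex energies are drawn
    around typical magnitudes; the PAM factor is 1 for NGG and 0.4
    otherwise.  Units are arbitrary kcal/mol-like.
    """
    rng = np.random.default_rng(seed)
    matches = sum(
        a == b
        for a, b in zip(rec.grna_seq[:PROTOSPACER_LEN], rec.target_seq[:PROTOSPACER_LEN])
    )
    dg_h = -0.5 * matches + rng.normal(0.0, 1.0)
    dg_u = rng.normal(-2.0, 1.0)
    dg_o = rng.normal(-25.0, 2.0)
    delta_pam = 1.0 if rec.target_seq[21:23] == "GG" else 0.4
    return EnergyTerms(
        delta_pam=delta_pam, dG_H=dg_h, dG_U=dg_u, dG_O=dg_o
    ).with_derived()


def _build_context(genome: str, pos: int, strand: str) -> str:
    lo, hi = pos - TARGET_OFFSET, pos + TARGET_LEN + TARGET_OFFSET
    ctx = genome[lo:hi]
    return ctx if strand == "+" else reverse_complement(ctx)


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """A fully annotated synthetic dataset plus its generating truth.

    Records carry raw rates, normalized CA, the six experimental
    epigenetic scores (MNase from the synthetic tracks; the other five
    as uninformative noise), gene-body flags and energy terms.
    Base-pair computed scores are filled separately by the scoring
    stage.  Identical config and seed give an identical dataset.
    """
    cfg.validate()
    genome, gb, tracks = generate_genome(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    L = cfg.genome_length
    n_exp = cfg.n_experimental()
    n_put = cfg.n_putative()

    # experimental site loci
    lo, hi = TARGET_OFFSET, L - TARGET_LEN - TARGET_OFFSET
    exp_pos = rng.integers(lo, hi, size=n_exp)
    exp_strand = np.where(rng.uniform(size=n_exp) < 0.5, "+", "-")

    # putative slots on a disjoint grid, avoiding experimental targets
    occupied = np.zeros(L, dtype=bool)
    for p in exp_pos:
        occupied[p : p + TARGET_LEN] = True
    grid = np.arange(lo, hi, TARGET_LEN + 7)
    free = grid[~np.array([occupied[g : g + TARGET_LEN].any() for g in grid])]
    if free.size < n_put:
        raise ConfigurationError(
            f"genome too short to host {n_put} putative sites (have {free.size} slots)"
        )
    # bias putative placement toward repetitive (low-entropy) regions: the
    # synthetic analogue of putative sites concentrating at nucleosome-
    # favorable low-complexity loci in the real corpus
    if cfg.putative_repetitive_bias > 0:
        z_slot = _slot_entropies(encode_seq(genome), free)
        w = np.exp(-cfg.putative_repetitive_bias * (z_slot - z_slot.min()))
        w /= w.sum()
        put_pos = rng.choice(free, size=n_put, replace=False, p=w)
    else:
        put_pos = rng.choice(free, size=n_put, replace=False)
    put_strand = np.where(rng.uniform(size=n_put) < 0.5, "+", "-")
    # seed choice mirrors the slot bias: repetitive targets spawn most
    # putative copies, keeping the copies themselves low-complexity
    if cfg.putative_repetitive_bias > 0:
        z_exp_pre = _slot_entropies(encode_seq(genome), exp_pos)
        ws = np.exp(-cfg.putative_repetitive_bias * (z_exp_pre - z_exp_pre.min()))
        ws /= ws.sum()
        put_seed_idx = rng.choice(n_exp, size=n_put, replace=True, p=ws)
    else:
        put_seed_idx = rng.integers(0, n_exp, size=n_put)
    put_n_mut = rng.integers(0, 7, size=n_put)

    # study/cell-line assignment for experimental records
    studies = [f"study{k:02d}" for k in range(cfg.n_studies)]
    exp_study = np.repeat(np.arange(cfg.n_studies), cfg.sites_per_study)
    exp_cell = rng.integers(0, len(cfg.cell_lines), size=n_exp)

    # gRNAs: target with 0-3 protospacer mismatches
    genome_arr = bytearray(genome.encode("ascii"))
    exp_targets = []
    for i in range(n_exp):
        ctx = _build_context(genome, int(exp_pos[i]), str(exp_strand[i]))
        exp_targets.append(ctx[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN])
    exp_grna = [
        _mutate(rng, t, int(rng.integers(0, 4)), PROTOSPACER_LEN) for t in exp_targets
    ]

    # plant mutated seed copies at the putative slots
    for i in range(n_put):
        seed_target = exp_targets[int(put_seed_idx[i])]
        mutated = _mutate(rng, seed_target, int(put_n_mut[i]), TARGET_LEN)
        forward = mutated if put_strand[i] == "+" else reverse_complement(mutated)
        p = int(put_pos[i])
        genome_arr[p : p + TARGET_LEN] = forward.encode("ascii")
    genome = genome_arr.decode("ascii")

    # assemble records (contexts read from the final genome)
    records: list[OffTargetRecord] = []
    truth = SyntheticTruth(true_effect_size=cfg.effect_size)
    z_exp = np.zeros(n_exp)
    for i in range(n_exp):
        ctx = _build_context(genome, int(exp_pos[i]), str(exp_strand[i]))
        rid = f"exp{i:06d}"
        z = dinucleotide_entropy(ctx)
        z_exp[i] = z
        truth.planted_covariate[rid] = z
        records.append(
            OffTargetRecord(
                record_id=rid,
                grna_seq=exp_grna[i],
                target_seq=ctx[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN],
                context_seq=ctx,
                chrom=cfg.chrom,
                pos=int(exp_pos[i]),
                strand=str(exp_strand[i]),
                study_id=studies[int(exp_study[i])],
                cell_line=cfg.cell_lines[int(exp_cell[i])],
                cleavage_rate=0.0,  # filled below
                cleavage_activity=float("nan"),
                is_putative=False,
            )
        )
    # planted monotone link: log rate = a_study + effect * z + noise
    a_study = rng.normal(-10.0, 0.5, size=cfg.n_studies)
    eps = rng.normal(0.0, cfg.noise_sd, size=n_exp)
    log_rate = a_study[exp_study] + cfg.effect_size * z_exp + eps
    rates = np.maximum(np.exp(log_rate), cfg.rate_floor)
    for rec, r in zip(records, rates):
        rec.cleavage_rate = float(r)
    for s in studies:
        truth.generating_lambda[s] = 0.0  # rates are log-normal given z

    for i in range(n_put):
        seed_rec = records[int(put_seed_idx[i])]
        ctx = _build_context(genome, int(put_pos[i]), str(put_strand[i]))
        rid = f"put{i:06d}"
        truth.planted_covariate[rid] = dinucleotide_entropy(ctx)
        records.append(
            OffTargetRecord(
                record_id=rid,
                grna_seq=seed_rec.grna_seq,
                target_seq=ctx[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN],
                context_seq=ctx,
                chrom=cfg.chrom,
                pos=int(put_pos[i]),
                strand=str(put_strand[i]),
                study_id=seed_rec.study_id,
                cell_line=seed_rec.cell_line,
                cleavage_rate=0.0,
                cleavage_activity=FLOOR_VALUE,
                is_putative=True,
            )
        )

    ds = Dataset(records=records)
    normalize_dataset(ds)

    # experimental epigenetic annotations
    annotate_mnase(ds, tracks)
    flag_dataset_gene_bodies(ds, gb)
    noise_features = ("CTCF", "DNase I", "DRIP", "H3K4me3", "RRBS")
    for rec in ds.records:
        for name in noise_features:
            rec.experimental_scores[name] = float(rng.uniform(0.0, 1.0))
        rec.energy = generate_energy_terms(rec, int(rng.integers(0, 2**31 - 1)))
    ds.refresh_manifest()
    ds.validate()
    return ds, truth


def synthetic_adapter_table(
    batch: nucleosome.AdapterBatch, seed: int
) -> pd.DataFrame:
    """Synthetic stand-in for an external dHMM predictor's per-base TSV.

    Smooth seeded noise with the right shapes: unbounded affinity,
    occupancy in [0, 1], binary viterbi.  Uninformative by design —
    adapter-backed features act as noise channels in recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = len(batch.long_string)
    # stationary smoothed noise: local correlation only, no long-range
    # drift that could encode a record's position in the batch
    kernel = np.ones(25) / 5.0
    smooth = np.convolve(rng.normal(0.0, 1.0, size=n), kernel, mode="same")
    affinity = smooth
    occupancy = 1.0 / (1.0 + np.exp(-smooth))
    viterbi = (occupancy > 0.5).astype(float)
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "affinity": affinity,
            "occupancy": occupancy,
            "viterbi": viterbi,
        }
    )


def synthetic_adapter_scores(
    ds: Dataset, seed: int
) -> dict[str, dict[str, np.ndarray]]:
    """Adapter-backed score vectors (NuPoP, nuCpos, LeNup) for a dataset,
    produced through the real batching/parsing contract on synthetic
    per-base tables."""
    contexts = [rec.context_seq for rec in ds.records]
    rids = [rec.record_id for rec in ds.records]
    out: dict[str, dict[str, np.ndarray]] = {rid: {} for rid in rids}
    for k, (tool, offset) in enumerate(
        (("NuPoP", 0), ("nuCpos", 1), ("LeNup", 2))
    ):
        batch = nucleosome.build_adapter_batch(contexts, rids)
        table = synthetic_adapter_table(batch, seed=seed + offset)
        scores = nucleosome.adapter_scores_from_table(batch, table, tool)
        for rid, vecs in scores.items():
            out[rid].update(vecs)
    return out


def write_manifest(cfg: SyntheticConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(cfg), indent=2, default=list))
    return path
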