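"""Box-Cox harmonization, activity binning and putative augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucleoff as nf
from nucleoff.normalization import (
    DegenerateDistributionError,
    InsufficientDataError,
    NormalizationError,
    augment_putative,
    bin_activity,
    fit_boxcox,
    transform_unclipped,
)
from nucleoff.records import OffTargetRecord, reverse_complement


def test_lognormal_rates_normalize_to_sd_two():
    """Transformed rates have sample mean 0 and sd 2 (pre-clip) at n=5000."""
    rng = np.random.default_rng(42)
    rates = np.exp(rng.normal(-6, 1.5, size=5000))
    norm = fit_boxcox(rates, "s1")
    t = transform_unclipped(rates[rates > norm.floor_threshold], norm)
    assert abs(t.mean()) < 0.05
    assert abs(t.std(ddof=1) - 2.0) < 0.05


def test_mle_recovers_log_lambda_on_lognormal_rates():
    rng = np.random.default_rng(7)
    rates = np.exp(rng.normal(-4, 1.0, size=5000))
    norm = fit_boxcox(rates, "s1")
    assert -0.2 <= norm.lmbda <= 0.2


def test_degenerate_and_insufficient_inputs():
    with pytest.raises(DegenerateDistributionError):
        fit_boxcox([0.01] * 50, "s")
    with pytest.raises(InsufficientDataError):
        fit_boxcox([0.01, 0.02, 0.03], "s")
    with pytest.raises(NormalizationError):
        fit_boxcox([-1.0] * 20, "s")


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    return fit_boxcox(np.exp(rng.normal(-5, 1.2, size=2000)), "s")


def test_floor_rule_is_exact(fitted):
    assert nf.apply_normalization(1e-6, fitted) == -4.0
    assert nf.apply_normalization(0.0, fitted) == -4.0
    assert nf.apply_normalization(9.99e-6, fitted) == -4.0


def test_extreme_rates_clip_to_four(fitted):
    assert nf.apply_normalization(1e12, fitted) == 4.0


def test_negative_rate_rejected(fitted):
    with pytest.raises(NormalizationError):
        nf.apply_normalization(-0.1, fitted)


def test_normalization_monotone_and_bounded(fitted):
    rng = np.random.default_rng(11)
    rates = np.sort(np.concatenate([[0.0, 1e-7, 1e-5], np.exp(rng.normal(-5, 2, 300))]))
    cas = [nf.apply_normalization(r, fitted) for r in rates]
    assert all(b >= a for a, b in zip(cas, cas[1:]))
    assert all(-4.0 <= c <= 4.0 for c in cas)


def test_bin_boundaries():
    assert bin_activity(-4.0) == "lowest"
    assert bin_activity(-3.999) == "low"
    assert bin_activity(2.0) == "low"
    assert bin_activity(2.0001) == "high"
    with pytest.raises(NormalizationError):
        bin_activity(4.5)


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=-4.0, max_value=4.0, allow_nan=False))
def test_bins_partition_the_activity_range(ca):
    assert bin_activity(ca) in ("lowest", "low", "high")


def _seed_record(target: str, chrom: str, pos: int, strand: str = "+") -> OffTargetRecord:
    ctx = "A" * 73 + target + "A" * 73
    return OffTargetRecord(
        record_id=f"seed_{pos}", grna_seq=target, target_seq=target, context_seq=ctx,
        chrom=chrom, pos=pos, strand=strand, study_id="s", cell_line="c",
        cleavage_rate=0.5, cleavage_activity=1.0, is_putative=False,
    )


def _plant(genome: list, pos: int, seq: str) -> None:
    genome[pos : pos + len(seq)] = list(seq)


def _mutated(rng, seq: str, k: int) -> str:
    s = list(seq)
    for p in rng.choice(len(seq), size=k, replace=False):
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


def test_augmenter_finds_exact_copy_and_respects_mismatch_boundary(rng):
    genome = list(rng.choice(list("ACGT"), size=5000))
    target = "".join(rng.choice(list("ACGT"), size=23))
    _plant(genome, 1000, target)  # exact copy
    six = _mutated(rng, target, 6)
    seven = _mutated(rng, target, 7)
    _plant(genome, 2000, six)
    _plant(genome, 3000, seven)
    seed = _seed_record(target, "synth", 4000)
    hits = augment_putative("".join(genome), [seed])
    by_pos = {(h.pos, h.strand) for h in hits}
    assert (1000, "+") in by_pos
    assert (2000, "+") in by_pos
    assert (3000, "+") not in by_pos  # seven mismatches: excluded
    for h in hits:
        assert h.is_putative and h.cleavage_activity == -4.0 and h.cleavage_rate == 0.0
        assert h.target_seq == h.context_seq[73:96]


def test_augmenter_skips_seed_locus_and_handles_reverse_strand(rng):
    genome = list(rng.choice(list("ACGT"), size=2000))
    target = "".join(rng.choice(list("ACGT"), size=23))
    _plant(genome, 500, target)
    _plant(genome, 900, reverse_complement(target))
    seed = _seed_record(target, "synth", 500)
    hits = augment_putative("".join(genome), [seed])
    assert (500, "+") not in {(h.pos, h.strand) for h in hits}
    rc_hits = [h for h in hits if h.strand == "-" and h.pos == 900]
    assert len(rc_hits) == 1
    assert rc_hits[0].target_seq == target


def brute_force_scan(genome: str, seeds, max_mm=6):
    """Exhaustive per-window Hamming scan oracle (both strands)."""
    found = set()
    L = len(genome)
    for strand in ("+", "-"):
        seq = genome if strand == "+" else reverse_complement(genome)
        for p in range(73, L - 23 - 73 + 1):
            win = seq[p : p + 23]
            gpos = p if strand == "+" else L - 23 - p
            if any(
                sum(a != b for a, b in zip(win, s.target_seq)) <= max_mm for s in seeds
            ):
                found.add((gpos, strand))
    return found


def test_augmenter_matches_exhaustive_oracle_on_small_genome(rng):
    genome = list(rng.choice(list("ACGT"), size=4000))
    seeds = []
    for i, pos in enumerate((600, 1500, 2800)):
        target = "".join(rng.choice(list("ACGT"), size=23))
        _plant(genome, pos, _mutated(rng, target, int(rng.integers(0, 7))))
        seeds.append(_seed_record(target, "synth", 10_000 + i))  # loci off-genome
    genome = "".join(genome)
    hits = {(h.pos, h.strand) for h in augment_putative(genome, seeds)}
    assert hits == brute_force_scan(genome, seeds)
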