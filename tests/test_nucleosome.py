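"""Sliding windows, training-free scorers, hard-rod occupancy, adapters."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucleoff import nucleosome as nuc
from nucleoff.records import TARGET_OFFSET, encode_seq
from tests.conftest import random_context

dna = st.text(alphabet="ACGT", min_size=1, max_size=1000)


# --- windows -----------------------------------------------------------------


def test_context_yields_exactly_23_windows(rng):
    ctx = random_context(rng)
    windows = nuc.sliding_windows(ctx)
    assert len(windows) == 23
    assert windows[0] == ctx[:147]
    assert windows[22] == ctx[22:169]


def test_bad_contexts_rejected(rng):
    with pytest.raises(nuc.SequenceError):
        nuc.sliding_windows(random_context(rng, 170))
    ctx = "N" + random_context(rng)[1:]
    with pytest.raises(nuc.SequenceError):
        nuc.sliding_windows(ctx)


# --- GC147 -------------------------------------------------------------------


def test_gc147_extremes_and_counted_value(rng):
    assert nuc.gc147("G" * 147) == 1.0
    assert nuc.gc147("A" * 147) == 0.0
    win = "G" * 40 + "C" * 34 + "A" * 73  # 74 strong bases
    assert nuc.gc147(win) == pytest.approx(74 / 147)
    with pytest.raises(nuc.SequenceError):
        nuc.gc147("ACGT")


def test_gc147_matches_direct_count_oracle(rng):
    for _ in range(100):
        win = "".join(rng.choice(list("ACGT"), 147))
        expected = sum(1 for b in win if b in "GC") / 147
        assert nuc.gc147(win) == pytest.approx(expected, abs=1e-12)


# --- strong/weak -------------------------------------------------------------


def test_strong_weak_mapping():
    assert nuc.strong_weak("GCAT") == "SSWW"
    assert nuc.strong_weak("AAAA") == "WWWW"
    with pytest.raises(nuc.SequenceError):
        nuc.strong_weak("ACGN")


@settings(deadline=None, max_examples=200)
@given(dna)
def test_strong_weak_preserves_length_and_alphabet(seq):
    out = nuc.strong_weak(seq)
    assert len(out) == len(seq)
    assert set(out) <= {"S", "W"}


# --- BDM ---------------------------------------------------------------------


def bdm_oracle(seq: str, backend: nuc.BlockComplexityBackend) -> float:
    """Independent brute-force grouping: explicit block dictionary."""
    bs = backend.block_size
    groups: dict[str, int] = {}
    for k in range(len(seq) // bs):
        block = seq[k * bs : (k + 1) * bs]
        groups[block] = groups.get(block, 0) + 1
    total = 0.0
    for block, mult in groups.items():
        counts = Counter(block)
        h = -sum(c / bs * math.log2(c / bs) for c in counts.values())
        total += bs * h + math.log2(mult)
    return total


def test_bdm_repeated_block_aggregation_law(rng):
    backend = nuc.BlockComplexityBackend()
    block = "".join(rng.choice(list("ACGT"), 12))
    for k in (1, 3, 12):
        expected = backend.complexity(block) + math.log2(k)
        assert nuc.bdm(block * k, backend) == pytest.approx(expected, abs=1e-12)


def test_bdm_invariant_under_block_permutation(rng):
    backend = nuc.BlockComplexityBackend()
    blocks = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(12)]
    a = nuc.bdm("".join(blocks), backend)
    rng.shuffle(blocks)
    b = nuc.bdm("".join(blocks), backend)
    assert a == pytest.approx(b, abs=1e-12)


def test_bdm_matches_brute_force_oracle(rng):
    for alphabet, letters in (("nucleotide-4", "ACGT"), ("strong-weak-2", "SW")):
        backend = nuc.BlockComplexityBackend(alphabet=alphabet)
        for _ in range(50):
            seq = "".join(rng.choice(list(letters), int(rng.integers(12, 200))))
            assert nuc.bdm(seq, backend) == pytest.approx(
                bdm_oracle(seq, backend), abs=1e-9
            )


def test_repetitive_sequences_score_below_random(rng):
    """Period-2 repeats have low BDM; seeded random strings score higher
    in every one of 100 trials, for both alphabets."""
    nt = nuc.BlockComplexityBackend()
    sw = nuc.BlockComplexityBackend(alphabet="strong-weak-2")
    assert nuc.bdm(("AT" * 74)[:147], nt) < nuc.bdm(
        "".join(rng.choice(list("ACGT"), 147)), nt
    )
    for _ in range(100):
        rnd_nt = "".join(rng.choice(list("ACGT"), 147))
        unit = "".join(rng.choice(list("ACGT"), 2))
        rep = (unit * 74)[:147]
        assert nuc.bdm(rep, nt) < nuc.bdm(rnd_nt, nt)
        rnd_sw = "".join(rng.choice(list("SW"), 147))
        rep_sw = nuc.strong_weak(rep)
        assert nuc.bdm(rep_sw, sw) < nuc.bdm(rnd_sw, sw)


def test_bdm_alphabet_mismatch_rejected():
    with pytest.raises(nuc.SequenceError):
        nuc.bdm("SWSW" * 12, nuc.BlockComplexityBackend(alphabet="nucleotide-4"))


def test_ctm_table_mode_lookup():
    table = {b: 1.0 for b in ("".join(t) for t in itertools.product("SW", repeat=2))}
    backend = nuc.BlockComplexityBackend(
        alphabet="strong-weak-2", block_size=2, mode="ctm-table", table=table
    )
    # 3 distinct blocks, one repeated twice
    assert nuc.bdm("SWSWWSSS", backend) == pytest.approx(3.0 + math.log2(2))
    with pytest.raises(nuc.SequenceError):
        nuc.bdm("SW", nuc.BlockComplexityBackend(
            alphabet="strong-weak-2", block_size=2, mode="ctm-table", table={"SS": 1.0}
        ))


def test_bdm_profiles_match_per_window_calls(rng):
    ctx = random_context(rng)
    nt = nuc.BlockComplexityBackend()
    sw = nuc.BlockComplexityBackend(alphabet="strong-weak-2")
    prof = nuc.nucleotide_bdm_profile(ctx, nt)
    assert prof.shape == (23,)
    for i, win in enumerate(nuc.sliding_windows(ctx)):
        assert prof[i] == pytest.approx(nuc.bdm(win, nt), abs=1e-9)
    prof_sw = nuc.strong_weak_bdm_profile(ctx, sw)
    sw_ctx = nuc.strong_weak(ctx)
    for i in range(23):
        assert prof_sw[i] == pytest.approx(
            nuc.bdm(sw_ctx[i : i + 147], sw), abs=1e-9
        )


def test_homogeneous_context_gives_flat_profiles():
    # translation-invariant context: every window sees the same block content
    prof = nuc.nucleotide_bdm_profile("A" * 169)
    assert np.allclose(prof, prof[0])
    prof_sw = nuc.strong_weak_bdm_profile("C" * 169)
    assert np.allclose(prof_sw, prof_sw[0])


# --- W/S and YR schemes -------------------------------------------------------


def test_template_matching_window_attains_maximal_score():
    w = nuc.ws_template()
    window = "".join("A" if x > 0 else "G" for x in w)
    assert nuc.ws_scheme(window) == pytest.approx(np.abs(w).sum() / 147)
    wy = nuc.yr_template()
    # greedy YR placement at positive-weight offsets: "TA" covers offsets j
    # (Y at j, R at j+1); build pairs at even positive offsets
    seq = ["G"] * 147
    for j in range(0, 146, 2):
        if wy[j] > 0:
            seq[j], seq[j + 1] = "T", "A"
    score = nuc.yr_scheme("".join(seq))
    assert score > 0.8 * wy[wy > 0][::2].sum() / 146


def test_ws_invariant_within_base_categories(rng):
    win = "".join(rng.choice(list("ACGT"), 147))
    swapped = win.translate(str.maketrans("ATGC", "TACG"))
    assert nuc.ws_scheme(win) == pytest.approx(nuc.ws_scheme(swapped), abs=1e-12)


def test_yr_invariant_within_base_categories(rng):
    win = "".join(rng.choice(list("ACGT"), 147))
    swapped = win.translate(str.maketrans("CTAG", "TCGA"))  # within Y and R
    assert nuc.yr_scheme(win) == pytest.approx(nuc.yr_scheme(swapped), abs=1e-12)


def test_ws_yr_golden_values():
    """Deterministic fixed outputs recorded at first implementation."""
    assert nuc.ws_scheme("A" * 147) == pytest.approx(0.017809755026, abs=1e-9)
    assert nuc.ws_scheme("G" * 147) == pytest.approx(-0.017809755026, abs=1e-9)
    assert nuc.yr_scheme("A" * 147) == 0.0
    assert nuc.yr_scheme("G" * 147) == 0.0
    assert nuc.yr_scheme(("TA" * 74)[:147]) == pytest.approx(0.011080162371, abs=1e-9)


# --- Van der Heijden hard-rod occupancy --------------------------------------


def enumerate_hard_rod_occupancy(lK: np.ndarray, rod: int) -> np.ndarray:
    """Brute-force grand-canonical sum over all non-overlapping rod
    configurations (oracle; exponential, for tiny lattices only)."""
    S = lK.shape[0]
    L = S + rod - 1
    Z = 0.0
    occ = np.zeros(L)

    def recurse(next_start: int, weight: float, config: list):
        nonlocal Z
        Z += weight
        for b in config:
            occ[b : b + rod] += 0  # placeholder (occupancy added below)
        for s in range(next_start, S):
            recurse(s + rod, weight * math.exp(lK[s]), config + [s])

    # accumulate occupancy by a second pass: easier to recompute
    Z = 0.0
    occ[:] = 0.0

    def recurse2(next_start: int, weight: float, covered: np.ndarray):
        nonlocal Z
        Z += weight
        occ[:] += weight * covered
        for s in range(next_start, S):
            cov = covered.copy()
            cov[s : s + rod] = 1.0
            recurse2(s + rod, weight * math.exp(lK[s]), cov)

    recurse2(0, 1.0, np.zeros(L))
    return occ / Z


def test_hard_rod_recursion_matches_enumeration_oracle(rng):
    for _ in range(5):
        S = int(rng.integers(8, 20))
        rod = 5
        lK = rng.normal(-1.0, 1.0, size=S)
        occ = nuc._hard_rod_occupancy(lK[None, :], rod)[0]
        oracle = enumerate_hard_rod_occupancy(lK, rod)
        assert np.allclose(occ, oracle, atol=1e-10)


def test_vdh_output_shapes_and_range(rng):
    ctx = random_context(rng)
    occ, central = nuc.vdh_occupancy(ctx)
    assert occ.shape == (169,)
    assert central.shape == (23,)
    assert np.all(occ >= 0.0) and np.all(occ <= 1.0)
    assert np.allclose(central, occ[73:96])


def test_vdh_homopolymer_is_flat_over_target():
    occ, central = nuc.vdh_occupancy("A" * 169)
    assert central.max() - central.min() < 1e-6


def test_vdh_occupancy_increases_with_chemical_potential(rng):
    contexts = [random_context(rng) for _ in range(100)]
    codes = np.stack([encode_seq(c) for c in contexts])
    low = nuc.vdh_occupancy_batch(codes, nuc.DinucleotideEnergyModel(mu=-0.6))
    high = nuc.vdh_occupancy_batch(codes, nuc.DinucleotideEnergyModel(mu=0.4))
    assert np.all(high > low)


def test_vdh_model_validation():
    with pytest.raises(ValueError):
        nuc.DinucleotideEnergyModel(footprint=146)
    with pytest.raises(ValueError):
        nuc.DinucleotideEnergyModel(amplitude=0.3)
    with pytest.raises(nuc.SequenceError):
        nuc.vdh_occupancy("N" * 169)


# --- adapter batching ---------------------------------------------------------


def test_adapter_batch_lengths(rng):
    ctx = random_context(rng)
    assert len(nuc.build_adapter_batch([]).long_string) == 147
    batch = nuc.build_adapter_batch([ctx] * 3)
    assert len(batch.long_string) == 147 + 316 * 3
    assert [off for _, off in batch.index_map] == [147, 463, 779]
    assert batch.long_string[147 : 147 + 169] == ctx


def test_adapter_output_alignment_by_position_oracle(rng):
    contexts = [random_context(rng) for _ in range(4)]
    batch = nuc.build_adapter_batch(contexts, ["a", "b", "c", "d"])
    n = len(batch.long_string)
    table = pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "affinity": np.arange(n, dtype=float),
            "occupancy": np.arange(n, dtype=float),
            "viterbi": np.zeros(n),
        }
    )
    out = nuc.parse_adapter_output(batch, table)
    for (rid, offset) in batch.index_map:
        expected = np.arange(offset + 73, offset + 96, dtype=float)
        assert np.array_equal(out[rid]["affinity"], expected)
    # single-record batch: target values at long-string positions 147+73..147+95
    one = nuc.build_adapter_batch(contexts[:1], ["x"])
    t1 = table.iloc[: len(one.long_string)]
    got = nuc.parse_adapter_output(one, t1)["x"]["occupancy"]
    assert np.array_equal(got, np.arange(147 + 73, 147 + 96, dtype=float))


def test_truncated_adapter_table_is_alignment_error(rng):
    batch = nuc.build_adapter_batch([random_context(rng)])
    table = pd.DataFrame(
        {"position": [1], "affinity": [0.0], "occupancy": [0.0], "viterbi": [0.0]}
    )
    with pytest.raises(nuc.AlignmentError):
        nuc.parse_adapter_output(batch, table)


# --- site-level scoring -------------------------------------------------------


def test_score_site_internal_and_with_adapters(scored_dataset):
    ds, _ = scored_dataset
    rec = ds.records[0]
    bps = nuc.score_site(rec)
    assert set(bps.scores) == set(nuc.INTERNAL_SCORES)
    assert all(len(v) == 23 for v in bps.scores.values())
    # fully adapter-backed record carries all 13 computed scores
    assert len(rec.basepair_scores.scores) == 13
    # deterministic across repeated calls
    again = nuc.score_site(rec)
    for name in bps.scores:
        assert bps.scores[name] == again.scores[name]


def test_batch_scoring_matches_single_site(rng):
    contexts = [random_context(rng) for _ in range(5)]
    batch = nuc.score_contexts(contexts)
    for i, ctx in enumerate(contexts):
        assert np.allclose(batch["GC147"][i], [nuc.gc147(w) for w in nuc.sliding_windows(ctx)])
        assert np.allclose(batch["W/S scheme"][i], [nuc.ws_scheme(w) for w in nuc.sliding_windows(ctx)], atol=1e-9)
        assert np.allclose(batch["YR scheme"][i], [nuc.yr_scheme(w) for w in nuc.sliding_windows(ctx)], atol=1e-9)
        assert np.allclose(batch["Nucleotide BDM"][i], nuc.nucleotide_bdm_profile(ctx), atol=1e-9)
        occ, central = nuc.vdh_occupancy(ctx)
        assert np.allclose(batch["VanDerHeijden"][i], central, atol=1e-9)
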