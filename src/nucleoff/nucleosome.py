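"""Base-pair-resolved nucleosome organization scores.

Every (off-)target site contributes a 169 bp sequence context; sliding
a 147 bp window across it yields exactly 23 windows, and window i
centers its dyad on target base i.  Each training-free scorer maps one
147 bp window to one number, producing a 23-vector per site:

* **GC147** — G+C fraction of the window.
* **W/S scheme** — rotational-positioning score: agreement of the
  weak/strong base pattern with a dyad-centered cosine of period 10 bp
  (template table shipped with the package).
* **YR scheme** — translational-positioning score: placement of
  pyrimidine-purine (YR) dinucleotide steps against a dyad-centered
  period-10.1 template.
* **Nucleotide BDM / Strong-Weak BDM** — Block Decomposition Method
  approximation of algorithmic complexity: the window is cut into
  non-overlapping blocks, and BDM = sum over distinct blocks of
  (block complexity + log2 multiplicity).  Repetitive sequences such as
  "ATATAT..." score low.  The default backend approximates block
  complexity by block_size x Shannon entropy per symbol; a ctm-table
  backend accepts an externally supplied complexity lookup table for
  exact replication of the published CTM-based variant.
* **VanDerHeijden** — equilibrium statistical mechanics of hard rods
  (nucleosomes, footprint N=147) on the padded sequence, with a
  dinucleotide-periodicity binding energy; per-base occupancy via the
  Percus/Vanderlick forward-backward recursion, in log space.

The duration-HMM predictors (NuPoP, nuCpos) and the LeNup network are
external tools: this module only builds their padded batch input and
aligns their per-base TSV output back onto each record's target.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    CONTEXT_LEN,
    TARGET_LEN,
    TARGET_OFFSET,
    BasePairScores,
    OffTargetRecord,
    encode_seq,
    encode_seqs,
)

logger = logging.getLogger(__name__)

WINDOW_LEN = 147
N_WINDOWS = CONTEXT_LEN - WINDOW_LEN + 1  # 23
SPACER_LEN = 147

#: Computed scores produced in-package (no external adapter needed).
INTERNAL_SCORES = (
    "GC147",
    "W/S scheme",
    "YR scheme",
    "Strong-Weak BDM",
    "Nucleotide BDM",
    "VanDerHeijden",
)
#: Adapter-backed scores (external dHMM / neural predictors).
ADAPTER_SCORES = (
    "NuPoP (Occupancy)",
    "NuPoP (Affinity)",
    "NuPoP (Viterbi)",
    "nuCpos (Occupancy)",
    "nuCpos (Affinity)",
    "nuCpos (Viterbi)",
    "LeNup (H3Q85C)",
)

#: Paper-echoed adapter settings, recorded for provenance in run manifests.
ADAPTER_CONFIGS = {
    "NuPoP": {"species": 1, "model": 4},
    "nuCpos": {"species": "c", "smoothHBA": False, "ActLikePredNuPoP": True},
}


class SequenceError(ValueError):
    pass


def _check_context(context: str) -> None:
    if len(context) != CONTEXT_LEN:
        raise SequenceError(f"context length {len(context)} != {CONTEXT_LEN}")
    if "N" in context:
        raise SequenceError("'N'-containing contexts are unsupported")
    if set(context) - set("ACGT"):
        raise SequenceError("context contains non-ACGT characters")


def sliding_windows(context: str) -> list[str]:
    """The 23 sliding 147 bp windows of a 169 bp context."""
    _check_context(context)
    return [context[i : i + WINDOW_LEN] for i in range(N_WINDOWS)]


def gc147(window: str) -> float:
    """G+C fraction of a 147 bp nucleosomal window."""
    if len(window) != WINDOW_LEN:
        raise SequenceError(f"window length {len(window)} != {WINDOW_LEN}")
    return (window.count("G") + window.count("C")) / WINDOW_LEN


_SW_TABLE = str.maketrans("GCAT", "SSWW")


def strong_weak(seq: str) -> str:
    """Map G,C -> S (strong) and A,T -> W (weak)."""
    if set(seq) - set("ACGT"):
        raise SequenceError("strong_weak expects an ACGT string")
    return seq.translate(_SW_TABLE)


# --- Block Decomposition Method ----------------------------------------------

_ALPHABETS = {
    "nucleotide-4": "ACGT",
    "strong-weak-2": "SW",
}


@dataclass
class BlockComplexityBackend:
    """Block complexity source for BDM.

    ``entropy-surrogate`` scores a block as block_size x per-symbol
    Shannon entropy (bits); ``ctm-table`` looks blocks up in a
    user-supplied table (TSV: block <tab> complexity), as produced by
    Coding-Theorem-Method tooling.
    """

    alphabet: str = "nucleotide-4"
    block_size: int = 12
    mode: str = "entropy-surrogate"
    table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.mode not in ("entropy-surrogate", "ctm-table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ctm-table" and not self.table:
            raise ValueError("ctm-table mode requires a table")

    @property
    def symbols(self) -> str:
        return _ALPHABETS[self.alphabet]

    def complexity(self, block: str) -> float:
        """Complexity of one full block, in bits."""
        if self.mode == "ctm-table":
            try:
                return self.table[block]  # type: ignore[index]
            except KeyError:
                raise SequenceError(f"block {block!r} missing from CTM table")
        counts = Counter(block)
        n = len(block)
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        return len(block) * h


def load_ctm_table(path: str | Path) -> dict[str, float]:
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            block, value = line.split("\t")[:2]
            table[block] = float(value)
    return table


def bdm(seq: str, backend: BlockComplexityBackend | None = None) -> float:
    """Block Decomposition Method complexity of a string, in bits.

    The string is partitioned into non-overlapping blocks of
    ``block_size`` (a trailing remainder shorter than one block is
    dropped); BDM = sum over distinct blocks of
    ``complexity(block) + log2(multiplicity)``.
    """
    backend = backend or BlockComplexityBackend()
    if set(seq) - set(backend.symbols):
        raise SequenceError(
            f"sequence contains symbols outside alphabet {backend.alphabet!r}"
        )
    bs = backend.block_size
    if len(seq) < bs:
        raise SequenceError(f"sequence shorter than one block ({bs})")
    blocks = [seq[k * bs : (k + 1) * bs] for k in range(len(seq) // bs)]
    counts = Counter(blocks)
    return sum(backend.complexity(b) + math.log2(m) for b, m in counts.items())


def _bdm_batch(windows: np.ndarray, n_symbols: int, backend: BlockComplexityBackend) -> np.ndarray:
    """Vectorized entropy-surrogate BDM over an (..., window_len) code array."""
    bs = backend.block_size
    nb = windows.shape[-1] // bs
    blocks = windows[..., : nb * bs].reshape(*windows.shape[:-1], nb, bs)
    powers = (n_symbols ** np.arange(bs, dtype=np.int64))
    b_int = (blocks.astype(np.int64) * powers).sum(-1)
    # per-block entropy complexity
    cplx = np.zeros(b_int.shape, dtype=float)
    for s in range(n_symbols):
        cnt = (blocks == s).sum(-1)
        p = cnt / bs
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(cnt > 0, -p * np.log2(np.where(cnt > 0, p, 1.0)), 0.0)
        cplx += term
    cplx *= bs
    order = np.argsort(b_int, axis=-1, kind="stable")
    b_sorted = np.take_along_axis(b_int, order, -1)
    c_sorted = np.take_along_axis(cplx, order, -1)
    is_new = np.ones(b_sorted.shape, dtype=bool)
    is_new[..., 1:] = b_sorted[..., 1:] != b_sorted[..., :-1]
    idx = np.arange(nb)
    start_idx = np.maximum.accumulate(np.where(is_new, idx, 0), axis=-1)
    mult = (start_idx[..., :, None] == start_idx[..., None, :]).sum(-1)
    return (c_sorted * is_new).sum(-1) + (np.log2(mult) / mult).sum(-1)


def nucleotide_bdm_profile(
    context: str, backend: BlockComplexityBackend | None = None
) -> np.ndarray:
    """Per-target-base Nucleotide BDM (one value per 147 bp window)."""
    _check_context(context)
    backend = backend or BlockComplexityBackend(alphabet="nucleotide-4")
    if backend.mode == "ctm-table":
        return np.array([bdm(w, backend) for w in sliding_windows(context)])
    codes = encode_seq(context)
    windows = np.lib.stride_tricks.sliding_window_view(codes, WINDOW_LEN)
    return _bdm_batch(windows, 4, backend)


def strong_weak_bdm_profile(
    context: str, backend: BlockComplexityBackend | None = None
) -> np.ndarray:
    """Per-target-base Strong-Weak BDM (W/S-mapped windows)."""
    _check_context(context)
    backend = backend or BlockComplexityBackend(alphabet="strong-weak-2")
    if backend.alphabet != "strong-weak-2":
        raise ValueError("strong_weak_bdm_profile requires the strong-weak-2 alphabet")
    if backend.mode == "ctm-table":
        sw = strong_weak(context)
        return np.array([bdm(sw[i : i + WINDOW_LEN], backend) for i in range(N_WINDOWS)])
    codes = encode_seq(context)
    sw_codes = (codes == 1) | (codes == 2)  # S=1, W=0
    windows = np.lib.stride_tricks.sliding_window_view(
        sw_codes.astype(np.uint8), WINDOW_LEN
    )
    return _bdm_batch(windows, 2, backend)


# --- W/S and YR positioning templates ---------------------------------------


def _load_template(name: str) -> np.ndarray:
    text = resources.files("nucleoff.data").joinpath(name).read_text()
    weights = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("offset"):
            continue
        _, w = line.split("\t")
        weights.append(float(w))
    return np.array(weights)


_WS_WEIGHTS: np.ndarray | None = None
_YR_WEIGHTS: np.ndarray | None = None


def ws_template() -> np.ndarray:
    """Per-offset rotational weights (length 147), dyad at offset 73."""
    global _WS_WEIGHTS
    if _WS_WEIGHTS is None:
        _WS_WEIGHTS = _load_template("ws_template.tsv")
    return _WS_WEIGHTS


def yr_template() -> np.ndarray:
    """Per-dinucleotide-offset translational weights (length 146)."""
    global _YR_WEIGHTS
    if _YR_WEIGHTS is None:
        _YR_WEIGHTS = _load_template("yr_template.tsv")
    return _YR_WEIGHTS


def ws_scheme(window: str) -> float:
    """Rotational positioning score of a 147 bp window.

    Weak (A/T) bases count +1 and strong (G/C) bases -1 at each offset,
    weighted by the dyad-phased cosine template; higher values mean the
    W/S pattern matches the rotational ideal.  Invariant under
    substitutions within a base category.
    """
    if len(window) != WINDOW_LEN:
        raise SequenceError(f"window length {len(window)} != {WINDOW_LEN}")
    codes = encode_seq(window)
    x = np.where((codes == 0) | (codes == 3), 1.0, -1.0)
    return float((x * ws_template()).sum() / WINDOW_LEN)


def yr_scheme(window: str) -> float:
    """Translational positioning score of a 147 bp window.

    Counts pyrimidine-purine (YR) dinucleotide steps against the
    dyad-phased period-10.1 template.
    """
    if len(window) != WINDOW_LEN:
        raise SequenceError(f"window length {len(window)} != {WINDOW_LEN}")
    codes = encode_seq(window)
    is_y = (codes == 1) | (codes == 3)  # C, T
    is_r = ~is_y  # A, G
    yr = (is_y[:-1] & is_r[1:]).astype(float)
    return float((yr * yr_template()).sum() / (WINDOW_LEN - 1))


# --- Van der Heijden hard-rod occupancy --------------------------------------


@dataclass
class DinucleotideEnergyModel:
    """Dinucleotide-periodicity binding energy for the hard-rod model.

    A nucleosome footprint of N bp centered on its dyad; each
    dinucleotide step inside the footprint at offset x from the dyad
    contributes log-weight log(1 + 4B cos(2 pi x / p)) if it is
    weak-weak (A/T followed by A/T), the antiphase log(1 - 4B cos) if
    strong-strong, and 0 if mixed.  B is the probability amplitude of
    the underlying dinucleotide preference p(x) = 0.25 + B cos(.), so
    the relative weight against the uniform 0.25 is 1 + 4B cos(.).
    mu is the nucleosome chemical potential in units of kT.
    """

    footprint: int = 147
    amplitude: float = 0.16
    period: float = 10.1
    mu: float = -0.6

    def __post_init__(self) -> None:
        if self.footprint < 3 or self.footprint % 2 == 0:
            raise ValueError("footprint must be odd and >= 3")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (0 <= self.amplitude < 0.25):
            raise ValueError("amplitude must lie in [0, 0.25)")

    @property
    def pad(self) -> int:
        return (self.footprint - 1) // 2

    def step_log_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(ww, ss) log-weights per footprint dinucleotide offset."""
        n_steps = self.footprint - 1
        x = np.arange(n_steps) - self.pad  # dinucleotide start offset from dyad
        c = 4.0 * self.amplitude * np.cos(2.0 * np.pi * x / self.period)
        return np.log1p(c), np.log1p(-c)


def _hard_rod_occupancy(lK: np.ndarray, rod_len: int) -> np.ndarray:
    """Per-base occupancy of hard rods on a 1-D lattice (log-space).

    ``lK[:, s]`` is the log statistical weight (chemical potential
    included) of a rod starting at lattice site s; lattice length is
    ``S + rod_len - 1`` where S is the number of start positions.
    Percus/Vanderlick forward-backward recursion.
    """
    n, S = lK.shape
    L = S + rod_len - 1
    neg_inf = -np.inf
    lZf = np.full((n, L + 1), neg_inf)
    lZf[:, 0] = 0.0
    for i in range(1, L + 1):
        v = lZf[:, i - 1]
        if i >= rod_len:
            v = np.logaddexp(v, lK[:, i - rod_len] + lZf[:, i - rod_len])
        lZf[:, i] = v
    lZb = np.full((n, L + 1), neg_inf)
    lZb[:, L] = 0.0
    for i in range(L - 1, -1, -1):
        v = lZb[:, i + 1]
        if i < S:
            v = np.logaddexp(v, lK[:, i] + lZb[:, i + rod_len])
        lZb[:, i] = v
    lP = lK + lZf[:, :S] + lZb[:, rod_len : rod_len + S] - lZf[:, L : L + 1]
    P = np.exp(lP)
    cp = np.concatenate([np.zeros((n, 1)), np.cumsum(P, axis=1)], axis=1)
    b = np.arange(L)
    hi = np.minimum(b, S - 1) + 1
    lo = np.maximum(b - rod_len + 1, 0)
    occ = cp[:, hi] - cp[:, lo]
    return np.clip(occ, 0.0, 1.0)


def vdh_occupancy_batch(
    contexts_codes: np.ndarray, model: DinucleotideEnergyModel | None = None
) -> np.ndarray:
    """Hard-rod occupancy for a batch of encoded contexts.

    Returns occupancy aligned to the unpadded contexts: shape
    (n, context_len).
    """
    model = model or DinucleotideEnergyModel()
    n, ctx_len = contexts_codes.shape
    pad = model.pad
    padded = np.zeros((n, ctx_len + 2 * pad), dtype=np.uint8)  # pad with 'A' (code 0)
    padded[:, pad : pad + ctx_len] = contexts_codes
    is_w = (padded == 0) | (padded == 3)
    ww = (is_w[:, :-1] & is_w[:, 1:]).astype(float)
    ss = (~is_w[:, :-1] & ~is_w[:, 1:]).astype(float)
    lw_ww, lw_ss = model.step_log_weights()
    n_steps = model.footprint - 1
    ww_win = np.lib.stride_tricks.sliding_window_view(ww, n_steps, axis=1)
    ss_win = np.lib.stride_tricks.sliding_window_view(ss, n_steps, axis=1)
    lw = ww_win @ lw_ww + ss_win @ lw_ss  # (n, S) with S == ctx_len
    lK = model.mu + lw
    occ = _hard_rod_occupancy(lK, model.footprint)
    return occ[:, pad : pad + ctx_len]


def vdh_occupancy(
    context: str, model: DinucleotideEnergyModel | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy profile for one 169 bp context.

    Returns ``(occ169, central23)``: the occupancy aligned to the
    unpadded context (169 values) and its central 23 values (the
    target base pairs).
    """
    _check_context(context)
    occ = vdh_occupancy_batch(encode_seq(context)[None, :], model)[0]
    return occ, occ[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN]


# --- adapter batching for external dHMM predictors ---------------------------


@dataclass
class AdapterBatch:
    """Padded concatenation of contexts for NuPoP-style predictors.

    ``long_string`` = 147 'A' + (context + 147 'A') per record, so its
    length is 147 + 316 n; the leading and trailing spacers remove end
    effects in the external model.
    """

    long_string: str
    index_map: list[tuple[str, int]] = field(default_factory=list)
    spacer_length: int = SPACER_LEN


#: Batch size used for full-scale adapter runs (contexts per long string).
ADAPTER_CHUNK = 31_645


def build_adapter_batch(
    contexts: list[str], record_ids: list[str] | None = None
) -> AdapterBatch:
    """Concatenate contexts with 147 'A' spacers into one long string."""
    if record_ids is None:
        record_ids = [str(i) for i in range(len(contexts))]
    spacer = "A" * SPACER_LEN
    parts = [spacer]
    index_map = []
    offset = SPACER_LEN
    for rid, ctx in zip(record_ids, contexts):
        _check_context(ctx)
        index_map.append((rid, offset))
        parts.append(ctx)
        parts.append(spacer)
        offset += CONTEXT_LEN + SPACER_LEN
    return AdapterBatch("".join(parts), index_map)


def chunk_contexts(contexts: list[str], chunk: int = ADAPTER_CHUNK) -> list[list[str]]:
    return [contexts[i : i + chunk] for i in range(0, len(contexts), chunk)]


class AlignmentError(ValueError):
    pass


def parse_adapter_output(
    batch: AdapterBatch, per_base_table: pd.DataFrame
) -> dict[str, dict[str, np.ndarray]]:
    """Align an external predictor's per-base table onto each target.

    ``per_base_table`` must have one row per base of ``long_string``
    (in order) and columns ``affinity``, ``occupancy``, ``viterbi``.
    Returns ``record_id -> column -> 23-vector`` covering the target
    base pairs (context offsets [73, 96)).
    """
    required = ("affinity", "occupancy", "viterbi")
    for col in required:
        if col not in per_base_table.columns:
            raise AlignmentError(f"adapter table missing column {col!r}")
    if len(per_base_table) != len(batch.long_string):
        raise AlignmentError(
            f"adapter table has {len(per_base_table)} rows for a "
            f"{len(batch.long_string)}-base batch"
        )
    cols = {c: per_base_table[c].to_numpy(dtype=float) for c in required}
    out: dict[str, dict[str, np.ndarray]] = {}
    for rid, offset in batch.index_map:
        lo = offset + TARGET_OFFSET
        hi = lo + TARGET_LEN
        out[rid] = {c: cols[c][lo:hi].copy() for c in required}
    return out


def adapter_scores_from_table(
    batch: AdapterBatch, per_base_table: pd.DataFrame, tool: str
) -> dict[str, dict[str, np.ndarray]]:
    """Parse an adapter table and key the vectors by feature name.

    ``tool`` is "NuPoP" or "nuCpos" (three features each); for LeNup the
    single output is carried in the ``occupancy`` column and mapped to
    "LeNup (H3Q85C)".
    """
    parsed = parse_adapter_output(batch, per_base_table)
    out: dict[str, dict[str, np.ndarray]] = {}
    for rid, cols in parsed.items():
        if tool == "LeNup":
            out[rid] = {"LeNup (H3Q85C)": cols["occupancy"]}
        else:
            out[rid] = {
                f"{tool} (Affinity)": cols["affinity"],
                f"{tool} (Occupancy)": cols["occupancy"],
                f"{tool} (Viterbi)": cols["viterbi"],
            }
    return out


# --- site-level scoring -------------------------------------------------------


def score_contexts(
    contexts: list[str],
    nt_backend: BlockComplexityBackend | None = None,
    sw_backend: BlockComplexityBackend | None = None,
    vdh_model: DinucleotideEnergyModel | None = None,
    chunk: int = 512,
) -> dict[str, np.ndarray]:
    """All internal scores for a batch of contexts: name -> (n, 23) array."""
    nt_backend = nt_backend or BlockComplexityBackend(alphabet="nucleotide-4")
    sw_backend = sw_backend or BlockComplexityBackend(alphabet="strong-weak-2")
    vdh_model = vdh_model or DinucleotideEnergyModel()
    for ctx in contexts:
        _check_context(ctx)
    n = len(contexts)
    out = {name: np.zeros((n, TARGET_LEN)) for name in INTERNAL_SCORES}
    ws_w, yr_w = ws_template(), yr_template()
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        codes = encode_seqs(contexts[lo:hi])
        is_gc = ((codes == 1) | (codes == 2)).astype(float)
        win_gc = np.lib.stride_tricks.sliding_window_view(is_gc, WINDOW_LEN, axis=1)
        out["GC147"][lo:hi] = win_gc.sum(-1) / WINDOW_LEN
        x_ws = np.where((codes == 0) | (codes == 3), 1.0, -1.0)
        win_ws = np.lib.stride_tricks.sliding_window_view(x_ws, WINDOW_LEN, axis=1)
        out["W/S scheme"][lo:hi] = (win_ws @ ws_w) / WINDOW_LEN
        is_y = (codes == 1) | (codes == 3)
        yr = (is_y[:, :-1] & ~is_y[:, 1:]).astype(float)
        win_yr = np.lib.stride_tricks.sliding_window_view(yr, WINDOW_LEN - 1, axis=1)
        out["YR scheme"][lo:hi] = (win_yr @ yr_w) / (WINDOW_LEN - 1)
        if nt_backend.mode == "ctm-table":
            out["Nucleotide BDM"][lo:hi] = np.stack(
                [nucleotide_bdm_profile(c, nt_backend) for c in contexts[lo:hi]]
            )
        else:
            win_nt = np.lib.stride_tricks.sliding_window_view(codes, WINDOW_LEN, axis=1)
            out["Nucleotide BDM"][lo:hi] = _bdm_batch(win_nt, 4, nt_backend)
        if sw_backend.mode == "ctm-table":
            out["Strong-Weak BDM"][lo:hi] = np.stack(
                [strong_weak_bdm_profile(c, sw_backend) for c in contexts[lo:hi]]
            )
        else:
            sw_codes = ((codes == 1) | (codes == 2)).astype(np.uint8)
            win_sw = np.lib.stride_tricks.sliding_window_view(sw_codes, WINDOW_LEN, axis=1)
            out["Strong-Weak BDM"][lo:hi] = _bdm_batch(win_sw, 2, sw_backend)
        occ = vdh_occupancy_batch(codes, vdh_model)
        out["VanDerHeijden"][lo:hi] = occ[:, TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN]
    return out


def score_site(
    rec: OffTargetRecord,
    nt_backend: BlockComplexityBackend | None = None,
    sw_backend: BlockComplexityBackend | None = None,
    vdh_model: DinucleotideEnergyModel | None = None,
    adapter_scores: dict[str, dict[str, np.ndarray]] | None = None,
) -> BasePairScores:
    """All computed base-pair scores for one record.

    The six internal scores are always filled; NuPoP/nuCpos/LeNup slots
    are filled from ``adapter_scores`` (record_id -> score name ->
    23-vector) when provided, else left absent.
    """
    batch = score_contexts(
        [rec.context_seq], nt_backend, sw_backend, vdh_model, chunk=1
    )
    bps = BasePairScores(rec.record_id)
    for name in INTERNAL_SCORES:
        bps.scores[name] = [float(v) for v in batch[name][0]]
    if adapter_scores and rec.record_id in adapter_scores:
        for name, vec in adapter_scores[rec.record_id].items():
            if name not in ADAPTER_SCORES:
                raise ValueError(f"unknown adapter score {name!r}")
            if len(vec) != TARGET_LEN:
                raise AlignmentError(f"adapter score {name!r} is not a 23-vector")
            bps.scores[name] = [float(v) for v in vec]
    bps.validate()
    return bps


def score_dataset(
    ds,
    nt_backend: BlockComplexityBackend | None = None,
    sw_backend: BlockComplexityBackend | None = None,
    vdh_model: DinucleotideEnergyModel | None = None,
    adapter_scores: dict[str, dict[str, np.ndarray]] | None = None,
    chunk: int = 512,
) -> None:
    """Fill ``basepair_scores`` for every record of a dataset, in place."""
    contexts = [rec.context_seq for rec in ds.records]
    batch = score_contexts(contexts, nt_backend, sw_backend, vdh_model, chunk=chunk)
    for i, rec in enumerate(ds.records):
        bps = BasePairScores(rec.record_id)
        for name in INTERNAL_SCORES:
            bps.scores[name] = [float(v) for v in batch[name][i]]
        if adapter_scores and rec.record_id in adapter_scores:
            for name, vec in adapter_scores[rec.record_id].items():
                bps.scores[name] = [float(v) for v in vec]
        rec.basepair_scores = bps
    ds.refresh_manifest()
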