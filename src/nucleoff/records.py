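"""Domain types for gRNA-(off-)target records and genomic annotations.

An off-target site is described by its 23 bp target duplex (20 nt
protospacer + 3 nt PAM) centered inside a 169 bp sequence context, a raw
per-study cleavage rate, and a cross-study normalized cleavage activity
(CA) on the clipped [-4, 4] scale.  Putative (augmented) sites are
sequence-similar loci assumed inactive, pinned at CA = -4.

Coordinates are 0-based half-open throughout.  The 169 = 73 + 23 + 73
geometry means the target occupies context offsets [73, 96), so the
147 bp window starting at offset i (i = 0..22) centers its dyad on
target base i.  Reverse-strand records store ``context_seq`` already
reverse-complemented into gRNA orientation, which keeps every
sequence-based scorer strand-agnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .energies import EnergyTerms

logger = logging.getLogger(__name__)

CONTEXT_LEN = 169
TARGET_LEN = 23
TARGET_OFFSET = 73  # target = context[73:96]
PROTOSPACER_LEN = 20

DNA_ALPHABET = frozenset("ACGT")

CA_FLOOR = -4.0
CA_CLIP = 4.0


class SchemaError(ValueError):
    """A required column or feature is missing from an input table."""


class RecordError(ValueError):
    """A record violates a structural invariant."""


@dataclass(frozen=True)
class Feature:
    name: str          # display name, as used in figures/tables
    slug: str          # column-safe identifier
    kind: str          # "experimental" | "computed"
    is_binary: bool    # binary scores aggregate by median, others by mean
    internal: bool     # computable in-package (vs adapter-backed)


#: The 19 epigenetic features: 6 experimental + 13 computed
#: nucleosome-organization scores.  Viterbi outputs are hard state-path
#: indicators and are marked binary (median aggregation); everything
#: else aggregates by mean across the 23 target base pairs.
FEATURES: tuple[Feature, ...] = (
    Feature("CTCF", "ctcf", "experimental", False, False),
    Feature("DNase I", "dnase_i", "experimental", False, False),
    Feature("DRIP", "drip", "experimental", False, False),
    Feature("H3K4me3", "h3k4me3", "experimental", False, False),
    Feature("MNase", "mnase", "experimental", False, False),
    Feature("RRBS", "rrbs", "experimental", False, False),
    Feature("GC147", "gc147", "computed", False, True),
    Feature("W/S scheme", "ws_scheme", "computed", False, True),
    Feature("YR scheme", "yr_scheme", "computed", False, True),
    Feature("Strong-Weak BDM", "sw_bdm", "computed", False, True),
    Feature("Nucleotide BDM", "nt_bdm", "computed", False, True),
    Feature("NuPoP (Occupancy)", "nupop_occupancy", "computed", False, False),
    Feature("NuPoP (Affinity)", "nupop_affinity", "computed", False, False),
    Feature("NuPoP (Viterbi)", "nupop_viterbi", "computed", True, False),
    Feature("nuCpos (Occupancy)", "nucpos_occupancy", "computed", False, False),
    Feature("nuCpos (Affinity)", "nucpos_affinity", "computed", False, False),
    Feature("nuCpos (Viterbi)", "nucpos_viterbi", "computed", True, False),
    Feature("VanDerHeijden", "vdh", "computed", False, True),
    Feature("LeNup (H3Q85C)", "lenup_h3q85c", "computed", False, False),
)

EXPERIMENTAL_FEATURES = tuple(f for f in FEATURES if f.kind == "experimental")
COMPUTED_FEATURES = tuple(f for f in FEATURES if f.kind == "computed")
FEATURE_BY_NAME = {f.name: f for f in FEATURES}
FEATURE_BY_SLUG = {f.slug: f for f in FEATURES}

#: The three derived CRISPRspec binding-energy model features.
ENERGY_FEATURES = ("e_rna_dna", "e_rna_dna_corr", "e_grnafold")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: A=0, C=1, G=2, T=3; anything else maps to 0 (callers must pre-screen).
SEQ_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    SEQ_CODE[_b] = _i
SEQ_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    SEQ_VALID[_b] = True


def encode_seq(seq: str) -> np.ndarray:
    """2-bit integer codes (A=0, C=1, G=2, T=3) for an ACGT string."""
    return SEQ_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_seqs(seqs: Iterable[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) code matrix."""
    return np.stack([encode_seq(s) for s in seqs])


@dataclass
class BasePairScores:
    """Base-pair-resolved computed scores for one site.

    ``scores`` maps a computed-feature name to a length-23 vector, one
    value per target base pair.
    """

    record_id: str
    scores: dict[str, list[float]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, vec in self.scores.items():
            if name not in FEATURE_BY_NAME or FEATURE_BY_NAME[name].kind != "computed":
                raise RecordError(f"unknown computed score {name!r}")
            if len(vec) != TARGET_LEN:
                raise RecordError(
                    f"score {name!r} has length {len(vec)}, expected {TARGET_LEN}"
                )
            if not all(math.isfinite(v) for v in vec):
                raise RecordError(f"score {name!r} contains non-finite values")


@dataclass
class OffTargetRecord:
    record_id: str
    grna_seq: str
    target_seq: str
    context_seq: str
    chrom: str
    pos: int
    strand: str
    study_id: str
    cell_line: str
    cleavage_rate: float
    cleavage_activity: float  # NaN until normalized
    is_putative: bool
    in_gene_body: bool = False
    experimental_scores: dict[str, float] = field(default_factory=dict)
    energy: EnergyTerms | None = None
    basepair_scores: BasePairScores | None = None

    def validate(self, require_ca: bool = True) -> None:
        if len(self.context_seq) != CONTEXT_LEN:
            raise RecordError(
                f"{self.record_id}: context length {len(self.context_seq)} != {CONTEXT_LEN}"
            )
        if len(self.target_seq) != TARGET_LEN or len(self.grna_seq) != TARGET_LEN:
            raise RecordError(f"{self.record_id}: target/gRNA must be {TARGET_LEN} bp")
        central = self.context_seq[TARGET_OFFSET : TARGET_OFFSET + TARGET_LEN]
        if self.target_seq != central:
            raise RecordError(
                f"{self.record_id}: target_seq differs from central 23 bp of context"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"{self.record_id}: bad strand {self.strand!r}")
        if self.cleavage_rate < 0:
            raise RecordError(f"{self.record_id}: negative cleavage rate")
        ca = self.cleavage_activity
        if require_ca or not math.isnan(ca):
            if math.isnan(ca):
                raise RecordError(f"{self.record_id}: cleavage_activity unset")
            if not (CA_FLOOR <= ca <= CA_CLIP):
                raise RecordError(f"{self.record_id}: CA {ca} outside [-4, 4]")
            if self.is_putative and ca != CA_FLOOR:
                raise RecordError(f"{self.record_id}: putative record with CA != -4")
        if self.basepair_scores is not None:
            self.basepair_scores.validate()

    def has_n_context(self) -> bool:
        return "N" in self.context_seq

    def copy(self) -> "OffTargetRecord":
        bps = self.basepair_scores
        return replace(
            self,
            experimental_scores=dict(self.experimental_scores),
            basepair_scores=None
            if bps is None
            else BasePairScores(bps.record_id, {k: list(v) for k, v in bps.scores.items()}),
        )


@dataclass
class SignalTrack:
    """A genomic signal on 0-based half-open intervals (bedGraph semantics)."""

    name: str
    cell_line: str
    intervals: list[tuple[str, int, int, float]] = field(default_factory=list)

    def normalized(self) -> "SignalTrack":
        """Sort intervals and check they are non-overlapping per chromosome."""
        ivs = sorted(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if a[0] == b[0] and b[1] < a[2]:
                raise RecordError(
                    f"track {self.name}: overlapping intervals on {a[0]} at {b[1]}"
                )
        for chrom, start, end, value in ivs:
            if not math.isfinite(value):
                raise RecordError(f"track {self.name}: non-finite value on {chrom}")
            if end <= start:
                raise RecordError(f"track {self.name}: empty interval on {chrom}")
        return SignalTrack(self.name, self.cell_line, ivs)


@dataclass
class GeneBodyMap:
    """Gene-body spans (BED3 semantics); not cell-line specific."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def sorted(self) -> "GeneBodyMap":
        return GeneBodyMap(sorted(self.intervals))


@dataclass
class Dataset:
    records: list[OffTargetRecord] = field(default_factory=list)
    feature_manifest: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self, require_ca: bool = True) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise RecordError(f"duplicate record_id {rec.record_id}")
            seen.add(rec.record_id)
            rec.validate(require_ca=require_ca)

    def refresh_manifest(self) -> None:
        """Recompute the ordered feature manifest from annotated records.

        Experimental features come first, then computed scores, in
        registry order — only names present on at least one record are
        listed.  A fully annotated dataset carries all 19.
        """
        present_exp = set()
        present_comp = set()
        for rec in self.records:
            present_exp.update(rec.experimental_scores)
            if rec.basepair_scores is not None:
                present_comp.update(rec.basepair_scores.scores)
        self.feature_manifest = [
            f.name
            for f in FEATURES
            if (f.kind == "experimental" and f.name in present_exp)
            or (f.kind == "computed" and f.name in present_comp)
        ]


def drop_n_contexts(records: Iterable[OffTargetRecord]) -> list[OffTargetRecord]:
    """Drop records whose context contains 'N' (scorers cannot handle them)."""
    kept, dropped = [], 0
    for rec in records:
        if rec.has_n_context():
            dropped += 1
        else:
            kept.append(rec)
    if dropped:
        logger.info("dropped %d record(s) with 'N'-containing contexts", dropped)
    return kept
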