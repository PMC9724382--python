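"""Dataset, track, gene-body and sequence IO.

Datasets round-trip through columnar Parquet (primary) or CSV with a
flat wide schema: one column per scalar field, ``epi_<slug>`` for the
six experimental scores, ``en_*`` for energy terms, and
``bp_<slug>_<i>`` (i = 00..22) for each base-pair-resolved computed
score.  Tracks are 4-column bedGraph, gene bodies BED3, sequences FASTA.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energies import EnergyTerms
from .records import (
    FEATURE_BY_NAME,
    FEATURES,
    TARGET_LEN,
    BasePairScores,
    Dataset,
    GeneBodyMap,
    OffTargetRecord,
    SchemaError,
    SignalTrack,
    drop_n_contexts,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "record_id",
    "grna_seq",
    "target_seq",
    "context_seq",
    "chrom",
    "pos",
    "strand",
    "study_id",
    "cell_line",
    "cleavage_rate",
    "is_putative",
)

_ENERGY_COLUMNS = {
    "en_delta_pam": "delta_pam",
    "en_dg_h": "dG_H",
    "en_dg_u": "dG_U",
    "en_dg_o": "dG_O",
    "en_e_rna_dna": "e_rna_dna",
    "en_e_rna_dna_corr": "e_rna_dna_corr",
    "en_e_grnafold": "e_grnafold",
    "en_dg_b": "dG_B",
}


def _bp_columns(slug: str) -> list[str]:
    return [f"bp_{slug}_{i:02d}" for i in range(TARGET_LEN)]


def to_frame(ds: Dataset) -> pd.DataFrame:
    """Flatten a Dataset into the wide tabular schema."""
    rows = []
    for rec in ds.records:
        row: dict[str, object] = {
            "record_id": rec.record_id,
            "grna_seq": rec.grna_seq,
            "target_seq": rec.target_seq,
            "context_seq": rec.context_seq,
            "chrom": rec.chrom,
            "pos": rec.pos,
            "strand": rec.strand,
            "study_id": rec.study_id,
            "cell_line": rec.cell_line,
            "cleavage_rate": rec.cleavage_rate,
            "cleavage_activity": rec.cleavage_activity,
            "is_putative": rec.is_putative,
            "in_gene_body": rec.in_gene_body,
        }
        for name, value in rec.experimental_scores.items():
            row[f"epi_{FEATURE_BY_NAME[name].slug}"] = value
        if rec.energy is not None:
            for col, attr in _ENERGY_COLUMNS.items():
                row[col] = getattr(rec.energy, attr)
        if rec.basepair_scores is not None:
            for name, vec in rec.basepair_scores.scores.items():
                slug = FEATURE_BY_NAME[name].slug
                for col, v in zip(_bp_columns(slug), vec):
                    row[col] = v
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=list(REQUIRED_COLUMNS) + ["cleavage_activity", "in_gene_body"]
        )
    df = pd.DataFrame(rows)
    # stable column order: base columns first, then epi/en/bp in registry order
    base = [
        "record_id", "grna_seq", "target_seq", "context_seq", "chrom", "pos",
        "strand", "study_id", "cell_line", "cleavage_rate", "cleavage_activity",
        "is_putative", "in_gene_body",
    ]
    ordered = base + [c for c in _canonical_extra_columns() if c in df.columns]
    rest = [c for c in df.columns if c not in ordered]
    return df[ordered + rest]


def _canonical_extra_columns() -> list[str]:
    cols = [f"epi_{f.slug}" for f in FEATURES if f.kind == "experimental"]
    cols += list(_ENERGY_COLUMNS)
    for f in FEATURES:
        if f.kind == "computed":
            cols += _bp_columns(f.slug)
    return cols


def from_frame(df: pd.DataFrame, validate: bool = True) -> Dataset:
    """Rebuild a Dataset from the wide schema, enforcing record invariants.

    Rows whose context contains 'N' are dropped with a logged count.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    has_ca = "cleavage_activity" in df.columns
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        energy = None
        if any(col in d and _finite(d[col]) for col in _ENERGY_COLUMNS):
            energy = EnergyTerms(
                **{attr: _get_float(d, col) for col, attr in _ENERGY_COLUMNS.items()}
            )
        exp_scores = {}
        for f in FEATURES:
            if f.kind == "experimental" and _finite(d.get(f"epi_{f.slug}")):
                exp_scores[f.name] = float(d[f"epi_{f.slug}"])
        bps = None
        for f in FEATURES:
            if f.kind != "computed":
                continue
            cols = _bp_columns(f.slug)
            if cols[0] in d and _finite(d[cols[0]]):
                if bps is None:
                    bps = BasePairScores(str(d["record_id"]))
                bps.scores[f.name] = [float(d[c]) for c in cols]
        records.append(
            OffTargetRecord(
                record_id=str(d["record_id"]),
                grna_seq=str(d["grna_seq"]),
                target_seq=str(d["target_seq"]),
                context_seq=str(d["context_seq"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                strand=str(d["strand"]),
                study_id=str(d["study_id"]),
                cell_line=str(d["cell_line"]),
                cleavage_rate=float(d["cleavage_rate"]),
                cleavage_activity=float(d["cleavage_activity"])
                if has_ca and _finite(d.get("cleavage_activity"))
                else math.nan,
                is_putative=bool(d["is_putative"]),
                in_gene_body=bool(d.get("in_gene_body", False)),
                experimental_scores=exp_scores,
                energy=energy,
                basepair_scores=bps,
            )
        )
    records = drop_n_contexts(records)
    ds = Dataset(records=records)
    ds.refresh_manifest()
    if validate:
        ds.validate(require_ca=False)
    return ds


def _finite(v: object) -> bool:
    try:
        return v is not None and math.isfinite(float(v))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return False


def _get_float(d: dict, col: str) -> float:
    v = d.get(col)
    return float(v) if _finite(v) else math.nan


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "parquet"


def read_dataset(path: str | Path, format: str | None = None) -> Dataset:
    """Read a dataset from Parquet or CSV and validate every row."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return from_frame(df)


def write_dataset(ds: Dataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset; ``read_dataset`` on the result reproduces it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    df = to_frame(ds)
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# --- tracks / intervals / sequences -----------------------------------------


def read_bedgraph(path: str | Path, name: str = "", cell_line: str = "") -> SignalTrack:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            intervals.append((chrom, int(start), int(end), float(value)))
    return SignalTrack(name or Path(path).stem, cell_line, intervals).normalized()


def write_bedgraph(track: SignalTrack, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, start, end, value in track.normalized().intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
    return path


def read_bed3(path: str | Path) -> GeneBodyMap:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return GeneBodyMap(intervals).sorted()


def write_bed3(gb: GeneBodyMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, start, end in gb.sorted().intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path
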