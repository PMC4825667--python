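"""Plain-text readers and writers for every pipeline artifact.

All intermediate artifacts are TSV / FASTA / JASPAR text so any stage can be
run standalone or fed real data prepared to the same schema. Each writer's
output is accepted by its paired reader.

Formats
-------
* count tables: TSV, ``fragment_id`` then one ``t<hours>`` column per time
  point, integer counts;
* fitness tables: TSV ``fragment_id, cf_slope, r_squared, n_timepoints``;
* fragment intervals: BED-like TSV ``locus, start, end, fragment_id`` in
  ORC-anchored coordinates, CLOSED on both ends (documented in the header);
* PFMs: JASPAR text (``>ID NAME`` plus four labeled count rows);
* sequences: FASTA via Bio.SeqIO.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import AnchoredInterval
from .motifs import PFM
from .synthetic import CountMatrix, Fragment, MutantOligo

__all__ = [
    "write_fasta", "read_fasta",
    "write_count_table", "read_count_table",
    "write_fitness_table", "read_fitness_table",
    "write_fragments_bed", "read_fragments_bed",
    "write_regions_bed",
    "write_substitutions", "read_substitutions",
    "write_pfm_collection", "read_pfm_collection",
]

_BED_HEADER = ("# ORC-anchored CLOSED intervals: position 0 = first nucleotide of "
               "the T-rich strand of the ORC site; both endpoints included.")


# -- FASTA ------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# -- count tables -----------------------------------------------------------

def _hours_label(t: float) -> str:
    return f"t{t:g}"


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.columns = [_hours_label(t) for t in cm.timepoints]
    df.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "fragment_id":
        raise ValueError(f"{path}: first column must be 'fragment_id', "
                         f"got {df.index.name!r}")
    hours = []
    for col in df.columns:
        m = re.fullmatch(r"t(\d+(?:\.\d+)?)", str(col))
        if not m:
            raise ValueError(f"{path}: column {col!r} is not of the form t<hours>")
        hours.append(float(m.group(1)))
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {row!r} (ragged table?)")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.rint(vals)):
            raise ValueError(f"{path}: non-integer count")
        vals = np.rint(vals).astype(np.int64)
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(f"{path}: negative count at row {df.index[i]!r}, "
                         f"column {df.columns[j]!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate fragment id {dup!r}")
    out = pd.DataFrame(vals, index=df.index, columns=hours)
    return CountMatrix(out)


# -- fitness tables ---------------------------------------------------------

def write_fitness_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="fragment_id")


# -- BED-like interval tables -----------------------------------------------

def write_fragments_bed(fragments: Sequence[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        fh.write("locus\tstart\tend\tfragment_id\n")
        for f in fragments:
            fh.write(f"{f.locus}\t{f.interval.start}\t{f.interval.end}\t{f.id}\n")


def read_fragments_bed(path: str | Path) -> list[tuple[str, AnchoredInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("locus\t"):
                continue
            locus, start, end, fid = line.rstrip("\n").split("\t")
            out.append((locus, AnchoredInterval(int(start), int(end)), fid))
    return out


def write_regions_bed(regions, path: str | Path) -> None:
    """Write DifferentialRegion records (interval, mean_delta, kind)."""
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        fh.write("start\tend\tmean_delta\tkind\n")
        for r in regions:
            fh.write(f"{r.interval.start}\t{r.interval.end}\t"
                     f"{r.mean_delta:.4f}\t{r.kind}\n")


# -- oligo substitution tables ----------------------------------------------

def write_substitutions(oligos: Sequence[MutantOligo], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("oligo_id\tposition\tref\talt\n")
        for o in oligos:
            for pos, ref, alt in o.substitutions:
                fh.write(f"{o.id}\t{pos}\t{ref}\t{alt}\n")


def read_substitutions(path: str | Path) -> dict[str, list[tuple[int, str, str]]]:
    out: dict[str, list[tuple[int, str, str]]] = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        out.setdefault(str(row.oligo_id), []).append(
            (int(row.position), str(row.ref), str(row.alt)))
    return out


# -- JASPAR PFM collections -------------------------------------------------

_ROW_RE = re.compile(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$")


def write_pfm_collection(pfms: Sequence[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.id} {p.name}\n")
            for base, row in zip("ACGT", p.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def _validate_jaspar_structure(lines: list[str], path) -> None:
    """Cheap structural pass so malformed records fail with a line number."""
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}:{i + 1}: expected '>' header, got {line!r}")
        rows = []
        j = i + 1
        while j < len(lines) and lines[j].strip() and not lines[j].startswith(">"):
            m = _ROW_RE.match(lines[j].strip())
            if not m:
                raise ValueError(f"{path}:{j + 1}: malformed count row {lines[j]!r}")
            rows.append((m.group(1), m.group(2).split()))
            j += 1
        if [r[0] for r in rows] != ["A", "C", "G", "T"]:
            raise ValueError(
                f"{path}:{i + 1}: record {line!r} must have exactly 4 rows "
                f"labeled A, C, G, T; got {[r[0] for r in rows]}")
        widths = {len(r[1]) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"{path}:{i + 1}: record {line!r} has ragged rows")
        i = j


def read_pfm_collection(path: str | Path, pseudocount: float = 0.5,
                        background=(0.25, 0.25, 0.25, 0.25)) -> list[PFM]:
    """Parse a JASPAR-format PFM file into the package's PFM objects."""
    with open(path) as fh:
        lines = fh.readlines()
    _validate_jaspar_structure(lines, path)
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PFM(m.matrix_id or m.name, m.name, counts,
                       pseudocount=pseudocount, background=tuple(background)))
    return out
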