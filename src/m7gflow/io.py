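"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV with ``#``-prefixed metadata/header comments; calls
are BED-like (0-based half-open).  Writer/reader pairs round-trip.
"""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError
from .expression import CountMatrix
from .codonstats import GeneSet
from .reference import TRNAGene
from .tracseq import EndCountProfile, SiteCallResult
from .translation import GeneModel, LibraryCounts


# ---------------------------------------------------------------- FASTA

def write_trna_fasta(genes: Sequence[TRNAGene], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_cds_fasta(genes: Sequence[GeneModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.cds), id=g.gene_id,
                  description=f"transcript_length={g.transcript_length}")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> list[GeneModel]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tl = None
        for tok in rec.description.split():
            if tok.startswith("transcript_length="):
                tl = int(tok.split("=", 1)[1])
        genes.append(
            GeneModel(gene_id=rec.id, cds=str(rec.seq), transcript_length=tl)
        )
    if not genes:
        raise FormatError(f"{path}: no CDS records")
    return genes


# ---------------------------------------------------------------- pileups

def write_pileups(lib: Mapping[str, EndCountProfile], path: str | Path) -> None:
    """TSV of (trna_id, position, count); library size in a comment line."""
    sizes = {p.library_size for p in lib.values()}
    if len(sizes) > 1:
        raise InputError("profiles disagree on library_size")
    with open(path, "w") as fh:
        fh.write(f"# library_size={sizes.pop() if sizes else 0}\n")
        fh.write("# columns: trna_id\tposition\tcount\n")
        for tid in sorted(lib):
            for pos, c in enumerate(lib[tid].counts):
                fh.write(f"{tid}\t{pos}\t{int(c)}\n")


def read_pileups(path: str | Path) -> dict[str, EndCountProfile]:
    library_size = None
    rows: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "library_size=" in line:
                    library_size = int(line.split("library_size=")[1].split()[0])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            tid, pos_s, count_s = parts
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            rows.setdefault(tid, {})[pos] = count
    if library_size is None:
        raise FormatError(f"{path}: missing library_size line")
    out = {}
    for tid, posmap in rows.items():
        n = max(posmap) + 1
        counts = np.zeros(n, dtype=np.int64)
        for pos, c in posmap.items():
            counts[pos] = c
        out[tid] = EndCountProfile(tid, counts, library_size)
    return out


# ---------------------------------------------------------------- count matrix

def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """TSV with a two-line header: sample ids, then condition labels."""
    with open(path, "w") as fh:
        cols = list(matrix.data.columns)
        fh.write("id\t" + "\t".join(cols) + "\n")
        fh.write("condition\t" + "\t".join(matrix.conditions[c] for c in cols) + "\n")
        for rid, row in matrix.data.iterrows():
            fh.write(rid + "\t" + "\t".join(str(v) for v in row) + "\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_line = fh.readline().rstrip("\n").split("\t")
        if not header or cond_line[0] != "condition":
            raise FormatError(f"{path}: expected two-line header")
        samples = header[1:]
        conditions = dict(zip(samples, cond_line[1:]))
        index, rows = [], []
        for lineno, line in enumerate(fh, 3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise FormatError(f"{path}:{lineno}: wrong column count")
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative count")
            index.append(parts[0])
            rows.append(vals)
    data = pd.DataFrame(rows, index=index, columns=samples)
    if (data == data.round()).all().all():
        data = data.astype(np.int64)
    return CountMatrix(data=data, conditions=conditions)


# ---------------------------------------------------------------- calls (BED)

def write_calls(result: SiteCallResult, path: str | Path) -> None:
    """BED-like 0-based half-open intervals of scored candidate positions."""
    with open(path, "w") as fh:
        fh.write("# columns: trna_id\tstart\tend\tscore\tcoverage\tmotif_ok\tcalled\n")
        for c in result.calls:
            fh.write(
                f"{c.trna_id}\t{c.position}\t{c.position + 1}\t"
                f"{c.score:.6g}\t{c.coverage}\t"
                f"{int(c.motif_ok)}\t{int(c.called)}\n"
            )


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["trna_id", "start", "end", "score", "coverage",
               "motif_ok", "called"],
    )
    df["motif_ok"] = df["motif_ok"].astype(bool)
    df["called"] = df["called"].astype(bool)
    return df


# ---------------------------------------------------------------- library counts

def write_library_counts(lib: LibraryCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_id={lib.library_id}\n")
        fh.write(f"# library_type={lib.library_type}\n")
        fh.write(f"# condition={lib.condition}\n")
        fh.write(f"# library_total={lib.library_total}\n")
        fh.write("# columns: gene_id\tcount\n")
        for gid in sorted(lib.counts):
            fh.write(f"{gid}\t{lib.counts[gid]}\n")


def read_library_counts(path: str | Path) -> LibraryCounts:
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body and not body.startswith("columns"):
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                c = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count") from exc
            if c < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            counts[parts[0]] = c
    for key in ("library_id", "library_type", "condition", "library_total"):
        if key not in meta:
            raise FormatError(f"{path}: missing header field {key}")
    return LibraryCounts(
        library_id=meta["library_id"],
        library_type=meta["library_type"],
        condition=meta["condition"],
        counts=counts,
        library_total=int(meta["library_total"]),
    )


# ---------------------------------------------------------------- footprints

def write_footprints(
    fps: Mapping[str, tuple[np.ndarray, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: gene_id\tfive_prime_pos\tlength\n")
        for gid in sorted(fps):
            positions, lengths = fps[gid]
            for p, ln in zip(positions, lengths):
                fh.write(f"{gid}\t{int(p)}\t{int(ln)}\n")


def read_footprints(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    acc: dict[str, tuple[list[int], list[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gid, pos_s, len_s = parts
            try:
                pos, ln = int(pos_s), int(len_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            acc.setdefault(gid, ([], []))[0].append(pos)
            acc[gid][1].append(ln)
    return {
        gid: (np.array(p, dtype=np.int64), np.array(l, dtype=np.int64))
        for gid, (p, l) in acc.items()
    }


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets; duplicate members within a set are dropped with a warning."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT needs name, description, >=1 gene"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                print(
                    f"warning: {path}:{lineno}: duplicate genes in set "
                    f"{name!r} deduplicated",
                    file=sys.stderr,
                )
            sets.append(GeneSet(name=name, members=frozenset(uniq)))
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(
                gs.name + "\tsynthetic\t" + "\t".join(sorted(gs.members)) + "\n"
            )


# ---------------------------------------------------------------- peak table

def read_peak_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV: nucleoside id, normalized peak area."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                table[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric area") from exc
    if not table:
        raise FormatError(f"{path}: empty peak table")
    return table


# ---------------------------------------------------------------- manifest

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    run_dir: str | Path,
    command: str,
    params: dict,
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Record command, parameters, input digests and seed for reproducibility."""
    from . import __version__

    manifest = {
        "command": command,
        "params": params,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    path = run_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
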