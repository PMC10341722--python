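"""File formats: FASTA, GFF3 coding intervals, BED6, family/PWM text, run reports."""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from divrep.align import LocalAlignment
from divrep.encoding import EncodedSequence, decode_sequence, encode_sequence
from divrep.iterate import RepeatFamily
from divrep.pwm import WeightMatrix, read_pwm, write_pwm
from divrep.scan import Hit


def read_fasta(path: str | Path) -> list[tuple[str, EncodedSequence]]:
    """All records of a FASTA file as (id, encoded sequence), order preserved."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, encode_sequence(str(rec.seq))))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[tuple[str, EncodedSequence]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(decode_sequence(seq)), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def concatenate_records(
    records: list[tuple[str, EncodedSequence]], spacer: int = 100
) -> EncodedSequence:
    """Join records with N spacers (for whole-assembly scans on explicit request)."""
    pieces = []
    for k, (_, seq) in enumerate(records):
        if k:
            pieces.append(np.full(spacer, -1, dtype=np.int8))
        pieces.append(seq.codes)
    return EncodedSequence(np.concatenate(pieces))


def read_gff_cds(path: str | Path) -> list[tuple[int, int]]:
    """1-based inclusive CDS intervals from a GFF3 file (all records pooled)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return [(f.start, f.end) for f in db.features_of_type("CDS")]


def write_bed(
    hits: Iterable[Hit], path: str | Path, name: str = "rep", chrom: str = "seq"
) -> None:
    """BED6 export of hit intervals: 0-based half-open, score = round(10 Z),
    strand '+' (the scan covers one strand)."""
    with open(path, "w") as fh:
        for k, h in enumerate(hits, 1):
            fh.write(
                f"{chrom}\t{h.genome_start - 1}\t{h.genome_end}\t"
                f"{name}.{k}\t{round(10 * h.z)}\t+\n"
            )


def write_truth_bed(truth, path: str | Path, chrom: str = "seq") -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(truth.copies, 1):
            strand = "-" if c.reverse else "+"
            fh.write(f"{chrom}\t{c.start - 1}\t{c.end}\tcopy.{k}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    return rows


# ---------------------------------------------------------------------------
# Family record text format
#
#   # family <id> members <n> mean_z <v>
#   > <k> <genome_start> <genome_end> <z> <pwm_start> <pwm_end>
#   <aligned bases, '-' at insertions>
#   <aligned column mask, '*' aligned / '-' deletion>

_BASES = {1: "A", 2: "T", 3: "C", 4: "G", 0: "-"}


def render_alignment(aln: LocalAlignment) -> tuple[str, str]:
    row1 = "".join(_BASES[int(b)] for b in aln.aligned_seq)
    row2 = "".join("*" if c > 0 else "-" for c in aln.aligned_cols)
    return row1, row2


def write_family(family: RepeatFamily, fh) -> None:
    fh.write(
        f"# family {family.family_id} members {family.n_members} "
        f"mean_z {family.mean_z:.6g} significant {int(family.significant)}\n"
    )
    for k, h in enumerate(family.hits, 1):
        a = h.alignment
        fh.write(
            f"> {k} {h.genome_start} {h.genome_end} {h.z:.6g} "
            f"{a.pwm_start} {a.pwm_end}\n"
        )
        row1, row2 = render_alignment(a)
        fh.write(row1 + "\n")
        fh.write(row2 + "\n")


def read_family(fh) -> list[dict]:
    """Parse family records back into dicts with coordinates, z and the
    reconstructed aligned pair (bases with 0 gaps, ascending columns)."""
    header = fh.readline()
    if not header.startswith("# family"):
        raise ValueError("not a family file")
    records = []
    while True:
        line = fh.readline()
        if not line:
            break
        if not line.startswith("> "):
            raise ValueError(f"malformed record header: {line!r}")
        _, k, start, end, z, j0, jmax = line.split()
        row1 = fh.readline().rstrip("\n")
        row2 = fh.readline().rstrip("\n")
        bases = np.array([{"A": 1, "T": 2, "C": 3, "G": 4, "-": 0}[c] for c in row1], dtype=np.int64)
        cols = np.zeros(len(row2), dtype=np.int64)
        col = int(j0)
        for i, c in enumerate(row2):
            if c == "*":
                cols[i] = col
                col += 1
        records.append(
            {
                "index": int(k),
                "genome_start": int(start),
                "genome_end": int(end),
                "z": float(z),
                "pwm_start": int(j0),
                "pwm_end": int(jmax),
                "aligned_seq": bases,
                "aligned_cols": cols,
            }
        )
    return records


def write_family_files(
    families: list[RepeatFamily], out_dir: str | Path, chrom: str = "seq"
) -> list[Path]:
    """Per family: fam<k>.txt records, pwm<k>.txt matrix, fam<k>.bed intervals."""
    if not families:
        raise ValueError("no families to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fam in families:
        fam_path = out_dir / f"fam{fam.family_id}.txt"
        with open(fam_path, "w") as fh:
            write_family(fam, fh)
        paths.append(fam_path)
        if fam.matrix is not None:
            pwm_path = out_dir / f"pwm{fam.family_id}.txt"
            with open(pwm_path, "w") as fh:
                write_pwm(fam.matrix, fh)
            paths.append(pwm_path)
        bed_path = out_dir / f"fam{fam.family_id}.bed"
        write_bed(fam.hits, bed_path, name=f"fam{fam.family_id}", chrom=chrom)
        paths.append(bed_path)
    return paths


def write_run_report(
    path: str | Path,
    config: dict,
    seed: int | None,
    families: list[RepeatFamily],
    noise_band: tuple[float, float] | None = None,
) -> None:
    report = {
        "config": config,
        "seed": seed,
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "noise_band": noise_band,
        "families": [
            {
                "family_id": f.family_id,
                "n_members": f.n_members,
                "mean_z": None if np.isnan(f.mean_z) else f.mean_z,
                "total_bases": f.total_bases,
                "significant": f.significant,
                "restart_trajectory": [
                    [n, None if np.isnan(z) else z] for n, z in f.trajectory
                ],
            }
            for f in families
        ],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_run_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


__all__ = [
    "read_fasta", "write_fasta", "concatenate_records", "read_gff_cds",
    "write_bed", "write_truth_bed", "read_bed", "render_alignment",
    "write_family", "read_family", "write_family_files",
    "write_run_report", "read_run_report", "read_pwm", "write_pwm",
    "WeightMatrix",
]
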