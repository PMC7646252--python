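"""Format readers/writers (FASTQ/FASTA/TSV/JSON) and run manifests.

TSV files are tab-delimited UTF-8 with a header row and no quoting; FASTQ is
plain 4-line records handled through Biopython.  Malformed records raise with
the offending position where the underlying parser reports one.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_QUAL_OFFSET = 33


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """FASTQ -> list of (id, sequence, quality-string) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + _QUAL_OFFSET) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    records = []
    for read_id, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [
            ord(c) - _QUAL_OFFSET for c in qual
        ]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; empty files raise."""
    out = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not out:
        raise ValueError(f"empty or invalid FASTA reference: {path}")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_tsv(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str} if "cell_id" in required else None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stages: dict[str, list[str]], meta: dict) -> Path:
    """JSON manifest with per-stage output checksums (no timestamps: runs with
    identical config and seed produce byte-identical manifests)."""
    out_dir = Path(out_dir)
    manifest = {"meta": meta, "stages": {}}
    for stage, files in stages.items():
        manifest["stages"][stage] = {
            f: sha256_file(out_dir / f) for f in sorted(files)
        }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
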