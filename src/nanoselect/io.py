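"""On-disk formats: FASTA references, the sigtab signal container, chunk
sets, and an optional multi-read FAST5 adapter.

sigtab is a plain directory format for labelled raw reads:

* ``reads.tsv`` — columns read_id, species, class_label, channel,
  offset_bytes, n_samples, digitisation, range, offset (fixed order);
* ``signals.bin`` — concatenated little-endian signed 16-bit samples;
* ``truth.tsv`` (optional) — read_id, base_index, first_sample, last_sample.

Chunk sets use a ``manifest.tsv`` plus a float32 little-endian block.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidArgumentError
from .preprocess import CLASS_LABELS, ChunkDataset
from .simulate import ReferencePool, SignalRead, uniform_kmer_bias

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_sigtab",
    "read_sigtab",
    "write_chunks",
    "read_chunks",
    "read_multi_fast5",
]

READS_COLUMNS = [
    "read_id",
    "species",
    "class_label",
    "channel",
    "offset_bytes",
    "n_samples",
    "digitisation",
    "range",
    "offset",
]


def write_fasta(sequences: dict[str, str] | ReferencePool, path: str | Path) -> None:
    if isinstance(sequences, ReferencePool):
        sequences = {
            f"{sequences.name}_{i}": s for i, s in enumerate(sequences.sequences)
        }
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def fasta_to_pool(path: str | Path, name: str = "pool") -> ReferencePool:
    seqs = list(read_fasta(path).values())
    return ReferencePool(name=name, sequences=seqs, kmer_bias=uniform_kmer_bias())


def write_sigtab(reads: list[SignalRead], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    offset = 0
    with open(directory / "reads.tsv", "w", newline="") as fh, open(
        directory / "signals.bin", "wb"
    ) as bh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(READS_COLUMNS)
        for read in reads:
            data = read.dac.astype("<i2").tobytes()
            writer.writerow(
                [
                    read.read_id,
                    read.species,
                    read.class_label,
                    read.channel,
                    offset,
                    read.n_samples,
                    read.digitisation,
                    read.range,
                    read.offset,
                ]
            )
            bh.write(data)
            offset += len(data)

    if any(r.base_to_sample is not None for r in reads):
        with open(directory / "truth.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["read_id", "base_index", "first_sample", "last_sample"])
            for read in reads:
                for base_index, first, last in read.base_to_sample or []:
                    writer.writerow([read.read_id, base_index, first, last])


def read_sigtab(directory: str | Path) -> list[SignalRead]:
    directory = Path(directory)
    signals = np.fromfile(directory / "signals.bin", dtype="<i2")

    truth: dict[str, list[tuple[int, int, int]]] = {}
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        with open(truth_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                truth.setdefault(row["read_id"], []).append(
                    (int(row["base_index"]), int(row["first_sample"]), int(row["last_sample"]))
                )

    reads: list[SignalRead] = []
    with open(directory / "reads.tsv", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != READS_COLUMNS:
            raise InvalidArgumentError(f"reads.tsv must have columns {READS_COLUMNS}")
        for row in reader:
            start = int(row["offset_bytes"]) // 2
            n = int(row["n_samples"])
            reads.append(
                SignalRead(
                    read_id=row["read_id"],
                    species=row["species"],
                    class_label=row["class_label"],
                    dac=signals[start : start + n],
                    channel=int(row["channel"]),
                    base_to_sample=truth.get(row["read_id"]),
                    digitisation=float(row["digitisation"]),
                    range=float(row["range"]),
                    offset=float(row["offset"]),
                )
            )
    return reads


def write_chunks(dataset: ChunkDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    block = dataset.X.astype("<f4")
    block.tofile(directory / "chunks.bin")
    with open(directory / "manifest.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "species", "class_label", "row", "n_values"])
        for i in range(len(dataset)):
            writer.writerow(
                [
                    dataset.read_ids[i],
                    dataset.species[i],
                    CLASS_LABELS[dataset.y[i]],
                    i,
                    dataset.X.shape[1],
                ]
            )


def read_chunks(directory: str | Path) -> ChunkDataset:
    directory = Path(directory)
    rows: list[dict] = []
    with open(directory / "manifest.tsv", newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if not rows:
        raise InvalidArgumentError("empty chunk manifest")
    n_values = int(rows[0]["n_values"])
    X = np.fromfile(directory / "chunks.bin", dtype="<f4").reshape(len(rows), n_values)
    y = np.array([CLASS_LABELS.index(r["class_label"]) for r in rows], dtype=int)
    return ChunkDataset(
        X=X,
        y=y,
        read_ids=[r["read_id"] for r in rows],
        species=[r["species"] for r in rows],
    )


def read_multi_fast5(
    path: str | Path, species: str = "", class_label: str = "target"
) -> list[SignalRead]:
    """Adapter for multi-read FAST5 files (Raw/Signal + channel_id layout).

    Species and class labels are not stored in FAST5 and must be supplied.
    """
    import h5py

    reads: list[SignalRead] = []
    with h5py.File(str(path), "r") as fh:
        for key in fh:
            if not key.startswith("read_"):
                continue
            grp = fh[key]
            signal = np.asarray(grp["Raw/Signal"][:], dtype=np.int16)
            ch = grp["channel_id"].attrs
            reads.append(
                SignalRead(
                    read_id=key[len("read_") :],
                    species=species,
                    class_label=class_label,
                    dac=signal,
                    channel=int(ch.get("channel_number", 1)),
                    digitisation=float(ch.get("digitisation", 8192.0)),
                    range=float(ch.get("range", 1400.0)),
                    offset=float(ch.get("offset", 0.0)),
                )
            )
    return reads
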