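"""FASTQ and sample-sheet I/O.

FASTQ records are carried around as a lightweight named tuple; parsing goes
through Biopython's fast FastqGeneralIterator.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str


class Sample(NamedTuple):
    name: str
    group: str
    barcode: str


def read_fastq(path) -> list[FastqRead]:
    with open(path) as fh:
        return [FastqRead(t, s, q) for t, s, q in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_sample_sheet(samples: Iterable[Sample], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["barcode", "sample_id", "group"])
        for s in samples:
            w.writerow([s.barcode, s.name, s.group])


def read_sample_sheet(path) -> list[Sample]:
    samples = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(reader.fieldnames) < {
            "barcode",
            "sample_id",
            "group",
        }:
            raise ValueError(f"malformed sample sheet: {path}")
        for row in reader:
            samples.append(Sample(row["sample_id"], row["group"], row["barcode"]))
    return samples


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
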