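"""Barcode demultiplexing and sliding-window quality filtering.

Mirrors the standard RAD demultiplexer settings used for bisulfite libraries:
single-error barcode rescue (safe because barcodes are kept at pairwise
Hamming distance >= 3), the default window quality rule (discard a read when
the mean Phred score in any window of 15% of the read length drops below 10),
and *no* restriction-site check, so the bisulfite-converted cut-site remnant
is retained for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ioutils import FastqRead

PHRED_OFFSET = 33


def _pairwise_hamming_ok(barcodes: list[str], min_dist: int = 3) -> None:
    if len({len(b) for b in barcodes}) > 1:
        raise ValueError("barcodes must all have the same length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            d = sum(x != y for x, y in zip(a, b))
            if d < min_dist:
                raise ValueError(
                    f"barcodes {a!r} and {b!r} are only {d} apart; "
                    f"single-error rescue would be ambiguous"
                )


def quality_filter(
    read: FastqRead, window_frac: float = 0.15, min_mean_q: float = 10.0
) -> bool:
    """True if the read passes the sliding-window quality rule.

    The window length is ``window_frac`` of the read length, rounded half-up
    (minimum 1); windows slide one base at a time; the read is discarded as
    soon as any window mean drops below ``min_mean_q``.
    """
    if len(read.qual) != len(read.seq):
        raise ValueError("quality string length differs from sequence length")
    n = len(read.seq)
    if n == 0:
        return False
    w = max(1, int(window_frac * n + 0.5))
    quals = [ord(c) - PHRED_OFFSET for c in read.qual]
    running = sum(quals[:w])
    thresh = min_mean_q * w
    if running < thresh:
        return False
    for i in range(w, n):
        running += quals[i] - quals[i - w]
        if running < thresh:
            return False
    return True


@dataclass
class DemuxResult:
    by_sample: dict[str, list[FastqRead]]
    unassigned: list[FastqRead] = field(default_factory=list)
    discarded: list[FastqRead] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {s: len(r) for s, r in self.by_sample.items()}
        c["unassigned"] = len(self.unassigned)
        c["discarded"] = len(self.discarded)
        return c


def demultiplex(
    reads,
    barcode_to_sample: dict[str, str],
    max_bc_mismatch: int = 1,
    window_frac: float = 0.15,
    min_mean_q: float = 10.0,
    min_payload: int = 6,
) -> DemuxResult:
    """Assign reads to samples by barcode, with single-error rescue.

    A read is assigned iff exactly one barcode lies within ``max_bc_mismatch``
    of its prefix; the barcode is trimmed from assigned reads.  Reads failing
    the window quality rule, or too short to carry the barcode plus the
    diagnostic cut-site remnant (``min_payload`` bases), are discarded.
    """
    barcodes = list(barcode_to_sample)
    if not barcodes:
        raise ValueError("no barcodes supplied")
    _pairwise_hamming_ok(barcodes)
    bc_len = len(barcodes[0])

    exact = dict(barcode_to_sample)
    result = DemuxResult(by_sample={s: [] for s in barcode_to_sample.values()})

    for read in reads:
        if len(read.seq) < bc_len + min_payload or not quality_filter(
            read, window_frac, min_mean_q
        ):
            result.discarded.append(read)
            continue
        prefix = read.seq[:bc_len]
        sample = exact.get(prefix)
        if sample is None and max_bc_mismatch > 0:
            hits = [
                s
                for b, s in barcode_to_sample.items()
                if sum(x != y for x, y in zip(prefix, b)) <= max_bc_mismatch
            ]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            result.unassigned.append(read)
        else:
            result.by_sample[sample].append(
                FastqRead(read.id, read.seq[bc_len:], read.qual[bc_len:])
            )
    return result
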