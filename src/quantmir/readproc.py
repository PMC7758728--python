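"""Raw-read parsing and inline-barcode demultiplexing.

Reads carry the 3'-ligation layout ``NNNN - insert - NNNNNN - barcode(5) -
adapter``: locating the 3' adapter exposes, right-to-left, the 5-nt sample
barcode, the 6-nt UMI block, the insert, and the leading 4-nt UMI block.
The two random-nucleotide blocks are concatenated in read order into a
single 10-nt UMI.  Inserts outside 18-30 nt are rejected, as are reads in
which no adapter can be located.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

UMI_A_LEN = 4
UMI_B_LEN = 6
BARCODE_LEN = 5
INSERT_MIN = 18
INSERT_MAX = 30

_MIN_PAYLOAD = UMI_A_LEN + INSERT_MIN + UMI_B_LEN + BARCODE_LEN

REJECT_NO_ADAPTER = "no_adapter"
REJECT_BAD_LENGTH = "bad_length"


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    insert: str
    umi: str       # 4-nt block + 6-nt block, in read order
    barcode: str


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass
class DemuxReport:
    total: int = 0
    per_sample: dict = field(default_factory=dict)
    undetermined: int = 0
    rejected: dict = field(default_factory=dict)

    @property
    def assigned(self) -> int:
        return sum(self.per_sample.values())

    def conserves_counts(self) -> bool:
        return self.total == self.assigned + self.undetermined + sum(self.rejected.values())

    def to_json(self) -> str:
        d = asdict(self)
        d["assigned"] = self.assigned
        return json.dumps(d, indent=2, sort_keys=True)


def _find_adapter(raw: str, adapter: str, min_overlap: int, max_mismatch: int) -> int:
    """Leftmost adapter start, or -1.

    Full-length occurrence first (exact, then <= max_mismatch mismatches),
    falling back to an exact adapter *prefix* of >= min_overlap nt at the
    read end (the adapter runs off the read).
    """
    pos = raw.find(adapter)
    if pos != -1:
        return pos
    la = len(adapter)
    if max_mismatch > 0 and len(raw) >= la:
        for start in range(len(raw) - la + 1):
            mm = 0
            for a, b in zip(raw[start : start + la], adapter):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                return start
    for k in range(min(la - 1, len(raw)), min_overlap - 1, -1):
        if raw.endswith(adapter[:k]):
            return len(raw) - k
    return -1


def parse_read(raw: str, adapter3: str, min_overlap: int = 10,
               max_mismatch: int | None = None, read_id: str = "") -> ParsedRead | Rejection:
    """Parse one raw read into insert/UMI/barcode, or reject it.

    ``max_mismatch`` defaults to one mismatch per 10 adapter nucleotides for
    the full-length adapter search; the terminal-prefix fallback is exact.
    """
    raw = raw.strip().upper()
    if not raw:
        return Rejection(read_id, REJECT_NO_ADAPTER)
    adapter3 = adapter3.strip().upper()
    if len(adapter3) < min_overlap:
        raise ValueError("adapter3 shorter than min_overlap")
    if max_mismatch is None:
        max_mismatch = len(adapter3) // 10

    pos = _find_adapter(raw, adapter3, min_overlap, max_mismatch)
    if pos == -1:
        return Rejection(read_id, REJECT_NO_ADAPTER)
    payload = raw[:pos]
    if len(payload) < _MIN_PAYLOAD:
        return Rejection(read_id, REJECT_BAD_LENGTH)
    barcode = payload[-BARCODE_LEN:]
    umi_b = payload[-(BARCODE_LEN + UMI_B_LEN) : -BARCODE_LEN]
    insert = payload[UMI_A_LEN : -(BARCODE_LEN + UMI_B_LEN)]
    if not (INSERT_MIN <= len(insert) <= INSERT_MAX):
        return Rejection(read_id, REJECT_BAD_LENGTH)
    return ParsedRead(read_id=read_id, insert=insert,
                      umi=payload[:UMI_A_LEN] + umi_b, barcode=barcode)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def validate_barcode_map(barcode_map: dict[str, str]) -> None:
    codes = list(barcode_map)
    for c in codes:
        if len(c) != BARCODE_LEN:
            raise ValueError(f"barcode {c!r} is not {BARCODE_LEN} nt")
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            if _hamming(a, b) < 2:
                raise ValueError(f"barcodes {a!r} and {b!r} are within Hamming distance 1")


def demultiplex(parsed: Iterable[ParsedRead | Rejection],
                barcode_map: dict[str, str]
                ) -> tuple[dict[str, list[ParsedRead]], DemuxReport]:
    """Route parsed reads to samples by exact barcode match.

    Unknown barcodes fall into the ``undetermined`` bucket; rejections are
    tallied by reason.  Counts are conserved: total == assigned +
    undetermined + rejected.
    """
    validate_barcode_map(barcode_map)
    streams: dict[str, list[ParsedRead]] = {s: [] for s in barcode_map.values()}
    undetermined: list[ParsedRead] = []
    report = DemuxReport(per_sample={s: 0 for s in barcode_map.values()})
    for item in parsed:
        report.total += 1
        if isinstance(item, Rejection):
            report.rejected[item.reason] = report.rejected.get(item.reason, 0) + 1
            continue
        sample = barcode_map.get(item.barcode)
        if sample is None:
            report.undetermined += 1
            undetermined.append(item)
        else:
            report.per_sample[sample] += 1
            streams[sample].append(item)
    streams["undetermined"] = undetermined
    return streams, report


def parse_stream(reads: Iterable[tuple[str, str]], adapter3: str,
                 min_overlap: int = 10, max_mismatch: int | None = None
                 ) -> Iterator[ParsedRead | Rejection]:
    for rid, seq in reads:
        yield parse_read(seq, adapter3, min_overlap=min_overlap,
                         max_mismatch=max_mismatch, read_id=rid)
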