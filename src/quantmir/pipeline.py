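"""End-to-end orchestration: raw reads -> per-sample calibrated quantification.

Thin glue over readproc, assign and quant: parse every read against the 3'
adapter, demultiplex on the inline barcode, assign each insert to a
reference with isomiR classification, UMI-collapse, and calibrate against
the spike-in ladder.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .assign import Assigner, Assignment
from .quant import SampleQuant, quantify_sample
from .readproc import DemuxReport, ParsedRead, demultiplex, parse_stream
from .references import ReferenceSet
from .simlib import DEFAULT_ADAPTER3

QUANTIFIABLE_CLASSES = frozenset({"miRNA", "piRNA", "spikein"})


def assign_parsed(parsed: Iterable[ParsedRead], ref: ReferenceSet,
                  assigner: Assigner | None = None
                  ) -> list[tuple[ParsedRead, Assignment]]:
    assigner = assigner or Assigner(ref)
    return [(p, assigner(p.insert)) for p in parsed]


def quantify_library(reads: Iterable[tuple[str, str]], ref: ReferenceSet,
                     barcode_map: Mapping[str, str], n_embryos: int,
                     adapter3: str = DEFAULT_ADAPTER3,
                     min_overlap: int = 10,
                     stage: str | None = None, condition: str | None = None,
                     control_means: Mapping[str, float] | None = None,
                     calibration_method: str = "median",
                     correct_collisions: bool = True
                     ) -> tuple[dict[str, SampleQuant], DemuxReport]:
    """Run the full pipeline on one FASTQ's worth of (read_id, sequence) pairs.

    Returns one :class:`SampleQuant` per demultiplexed sample (the
    ``undetermined`` bucket is demultiplexed but not quantified).
    """
    streams, report = demultiplex(
        parse_stream(reads, adapter3, min_overlap=min_overlap),
        dict(barcode_map))
    assigner = Assigner(ref)
    out: dict[str, SampleQuant] = {}
    for sample, parsed in streams.items():
        if sample == "undetermined" or not parsed:
            continue
        records = []
        for p, a in assign_parsed(parsed, ref, assigner):
            if a.ref_class in QUANTIFIABLE_CLASSES:
                records.append((a.ref_id, p.insert, p.umi))
        out[sample] = quantify_sample(
            sample, records, ref, n_embryos, stage=stage, condition=condition,
            control_means=control_means, calibration_method=calibration_method,
            correct_collisions=correct_collisions)
    return out, report
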