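"""Reference model for small-RNA quantification.

Holds the molecules a library read can originate from: mature miRNAs located
on their pre-miRNA hairpins (miRBase-style 1-based inclusive coordinates),
piRNAs used as an internal normalization control, and the synthetic spike-in
oligo ladder that anchors absolute quantification.  Family membership (e.g.
the miR-35 family, miR-35..miR-42, and the miR-51 family, miR-51..miR-56)
is carried alongside because depletion summaries aggregate by family.

Sequences are stored internally in DNA letters (U -> T), since raw reads are
DNA-space; FASTA output is written back in RNA letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fold import loop_midpoint

_ALPHABET = set("ACGT")

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

MATURE_MIN_LEN = 18
MATURE_MAX_LEN = 30
SEED_START = 2  # 1-based, inclusive
SEED_END = 8


class ReferenceError(ValueError):
    """Raised when a reference set fails validation."""


def normalize_seq(seq: str) -> str:
    """Uppercase, U->T; reject non-nucleotide letters."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ReferenceError(f"invalid nucleotide(s) {sorted(bad)} in {seq!r}")
    return s


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def revcomp(seq: str) -> str:
    return "".join(WC[c] for c in reversed(seq))


def seed_of(sequence: str) -> str:
    """The seed region, nucleotides 2-8 (1-based inclusive) of a miRNA.

    The seed is the principal determinant of target specificity; two miRNAs
    differing only outside positions 2-8 are expected to share targets.
    """
    s = normalize_seq(sequence)
    if len(s) < SEED_END:
        raise ValueError(f"sequence shorter than {SEED_END} nt has no seed")
    return s[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    hairpin_id: str
    arm: str  # "5p" or "3p"
    sequence: str
    start: int  # 1-based inclusive on hairpin
    end: int
    family_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.arm not in ("5p", "3p"):
            raise ReferenceError(f"{self.id}: arm must be 5p or 3p, got {self.arm!r}")
        n = len(self.sequence)
        if not (MATURE_MIN_LEN <= n <= MATURE_MAX_LEN):
            raise ReferenceError(f"{self.id}: mature length {n} outside 18-30 nt")
        if self.end - self.start + 1 != n:
            raise ReferenceError(f"{self.id}: coordinates [{self.start},{self.end}] "
                                 f"inconsistent with length {n}")


@dataclass(frozen=True)
class Hairpin:
    id: str
    sequence: str
    # Downstream genomic sequence, used to distinguish templated 3' extensions
    # from non-templated tailing at the hairpin boundary.
    context3: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        object.__setattr__(self, "context3", normalize_seq(self.context3) if self.context3 else "")
        if len(self.sequence) < 40:
            raise ReferenceError(f"hairpin {self.id}: length {len(self.sequence)} < 40 nt")

    @property
    def template(self) -> str:
        """Hairpin plus downstream context: everything genome-templated."""
        return self.sequence + self.context3


@dataclass(frozen=True)
class SpikeInOligo:
    id: str
    sequence: str
    molecules_per_embryo: float

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if not (MATURE_MIN_LEN <= len(self.sequence) <= MATURE_MAX_LEN):
            raise ReferenceError(f"spike-in {self.id}: length outside 18-30 nt")
        if not (self.molecules_per_embryo > 0):
            raise ReferenceError(f"spike-in {self.id}: molecules_per_embryo must be > 0")


@dataclass
class ReferenceSet:
    matures: list[MatureMiRNA]
    hairpins: dict[str, Hairpin]
    pirnas: dict[str, str]  # id -> sequence
    spikeins: list[SpikeInOligo]
    families: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.pirnas = {pid: normalize_seq(s) for pid, s in self.pirnas.items()}
        self.validate()

    # -- lookups -------------------------------------------------------
    def mature(self, mirna_id: str) -> MatureMiRNA:
        for m in self.matures:
            if m.id == mirna_id:
                return m
        raise KeyError(mirna_id)

    def family_of(self, mirna_id: str) -> str | None:
        """Family id of a miRNA, or None if it has no annotated family."""
        m = self.mature(mirna_id)  # KeyError for unknown ids
        return m.family_id

    def family_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.families.values():
            out.update(members)
        return out

    @property
    def mirna_ids(self) -> set[str]:
        return {m.id for m in self.matures}

    @property
    def pirna_ids(self) -> set[str]:
        return set(self.pirnas)

    @property
    def spikein_ids(self) -> set[str]:
        return {s.id for s in self.spikeins}

    def sequence_of(self, ref_id: str) -> str:
        for m in self.matures:
            if m.id == ref_id:
                return m.sequence
        if ref_id in self.pirnas:
            return self.pirnas[ref_id]
        for s in self.spikeins:
            if s.id == ref_id:
                return s.sequence
        raise KeyError(ref_id)

    def all_sequences(self) -> list[str]:
        return ([m.sequence for m in self.matures]
                + list(self.pirnas.values())
                + [s.sequence for s in self.spikeins])

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids: list[str] = ([m.id for m in self.matures] + list(self.hairpins)
                          + list(self.pirnas) + [s.id for s in self.spikeins])
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ReferenceError(f"duplicate reference id {i!r}")
            seen.add(i)

        for m in self.matures:
            hp = self.hairpins.get(m.hairpin_id)
            if hp is None:
                raise ReferenceError(f"{m.id}: hairpin {m.hairpin_id!r} not found")
            sub = hp.sequence[m.start - 1 : m.end]
            if sub != m.sequence:
                raise ReferenceError(
                    f"{m.id}: sequence does not match hairpin {m.hairpin_id} "
                    f"at [{m.start},{m.end}]")
            mid = loop_midpoint(hp.sequence)
            if m.arm == "5p" and not (m.end - 1 <= mid):
                raise ReferenceError(f"{m.id}: annotated 5p but lies 3' of the loop midpoint")
            if m.arm == "3p" and not (m.start - 1 >= mid):
                raise ReferenceError(f"{m.id}: annotated 3p but lies 5' of the loop midpoint")

        for fam, members in self.families.items():
            known = self.mirna_ids
            for mem in members:
                if mem not in known:
                    raise ReferenceError(f"family {fam}: unknown member {mem!r}")


# ---------------------------------------------------------------------------
# spike-in ladder
# ---------------------------------------------------------------------------

def min_alignment_mismatches(a: str, b: str) -> int:
    """Minimum Hamming distance over all full overlaps of the shorter in the longer."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, d)
    return best


def make_spikein_ladder(avoid: list[str] | None = None, n: int = 8,
                        low: float = 20.0, ratio: float = 500.0,
                        length: int = 22, min_dist: int = 4,
                        rng_seed: int = 101) -> list[SpikeInOligo]:
    """Build the default spike-in ladder: ``n`` oligos, concentrations geometric
    from ``low`` to ``low*ratio`` molecules per embryo (default 20..10,000, a
    500-fold range).

    Sequences are composition-balanced shuffled ``length``-mers screened so
    every oligo sits >= ``min_dist`` mismatches from each sequence in
    ``avoid`` (and from each other) at every alignment offset, so spike-ins
    can never collide with endogenous references.
    """
    avoid = [normalize_seq(s) for s in (avoid or [])]
    rng = np.random.default_rng(rng_seed)
    base = list("ACGT" * (length // 4) + "ACGT"[: length % 4])
    out: list[SpikeInOligo] = []
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < n:
        attempts += 1
        if attempts > 10000:
            raise ReferenceError("could not design spike-in ladder with requested distance")
        cand = base[:]
        rng.shuffle(cand)
        s = "".join(cand)
        if all(min_alignment_mismatches(s, other) >= min_dist for other in avoid + seqs):
            seqs.append(s)
    for i, s in enumerate(seqs):
        conc = low * ratio ** (i / (n - 1))
        out.append(SpikeInOligo(id=f"spike-{i + 1}", sequence=s, molecules_per_embryo=conc))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reference(matures_fasta, hairpins_fasta, annotation_tsv,
                   pirnas_fasta, spikein_tsv) -> ReferenceSet:
    """Load and validate a reference set from FASTA + TSV files.

    ``annotation_tsv`` columns: id, hairpin_id, arm, start, end, family_id
    (empty family_id = no family).  ``spikein_tsv`` columns: id, sequence,
    molecules_per_embryo.
    """
    mat_seqs = {k: normalize_seq(v) for k, v in _read_fasta(Path(matures_fasta)).items()}
    hp_seqs = _read_fasta(Path(hairpins_fasta))
    pir_seqs = {k: normalize_seq(v) for k, v in _read_fasta(Path(pirnas_fasta)).items()}

    ann = pd.read_csv(annotation_tsv, sep="\t", dtype={"family_id": "string"})
    matures: list[MatureMiRNA] = []
    for row in ann.itertuples(index=False):
        if row.id not in mat_seqs:
            raise ReferenceError(f"annotation row {row.id!r} missing from matures FASTA")
        fam = None if pd.isna(row.family_id) or row.family_id == "" else str(row.family_id)
        matures.append(MatureMiRNA(
            id=str(row.id), hairpin_id=str(row.hairpin_id), arm=str(row.arm),
            sequence=mat_seqs[row.id], start=int(row.start), end=int(row.end),
            family_id=fam))

    context_path = Path(str(hairpins_fasta) + ".context")
    contexts: dict[str, str] = {}
    if context_path.exists():
        contexts = _read_fasta(context_path)
    hairpins = {hid: Hairpin(id=hid, sequence=seq, context3=contexts.get(hid, ""))
                for hid, seq in hp_seqs.items()}

    sp = pd.read_csv(spikein_tsv, sep="\t")
    spikeins = [SpikeInOligo(id=str(r.id), sequence=str(r.sequence),
                             molecules_per_embryo=float(r.molecules_per_embryo))
                for r in sp.itertuples(index=False)]

    families: dict[str, list[str]] = {}
    for m in matures:
        if m.family_id:
            families.setdefault(m.family_id, []).append(m.id)

    return ReferenceSet(matures=matures, hairpins=hairpins, pirnas=pir_seqs,
                        spikeins=spikeins, families=families)


def write_reference(ref: ReferenceSet, outdir) -> dict[str, Path]:
    """Write a reference set to FASTA/TSV; inverse of :func:`load_reference`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matures_fasta": outdir / "matures.fa",
        "hairpins_fasta": outdir / "hairpins.fa",
        "annotation_tsv": outdir / "annotation.tsv",
        "pirnas_fasta": outdir / "pirnas.fa",
        "spikein_tsv": outdir / "spikeins.tsv",
    }

    def fasta(path: Path, items: list[tuple[str, str]]):
        with open(path, "w") as fh:
            for name, seq in items:
                fh.write(f">{name}\n{to_rna(seq)}\n")

    fasta(paths["matures_fasta"], [(m.id, m.sequence) for m in ref.matures])
    fasta(paths["hairpins_fasta"], [(h.id, h.sequence) for h in ref.hairpins.values()])
    ctx = [(h.id, h.context3) for h in ref.hairpins.values() if h.context3]
    if ctx:
        fasta(Path(str(paths["hairpins_fasta"]) + ".context"), ctx)
    fasta(paths["pirnas_fasta"], list(ref.pirnas.items()))

    ann = pd.DataFrame([{"id": m.id, "hairpin_id": m.hairpin_id, "arm": m.arm,
                         "start": m.start, "end": m.end,
                         "family_id": m.family_id or ""} for m in ref.matures])
    ann.to_csv(paths["annotation_tsv"], sep="\t", index=False)
    sp = pd.DataFrame([{"id": s.id, "sequence": to_rna(s.sequence),
                        "molecules_per_embryo": s.molecules_per_embryo}
                       for s in ref.spikeins])
    sp.to_csv(paths["spikein_tsv"], sep="\t", index=False)
    return paths
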