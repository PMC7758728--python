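"""Synthetic small-RNA library generator with recorded ground truth.

Emulates the quantitative sequencing design the analysis assumes: per-embryo
miRNA abundance profiles by developmental stage, depletion conditions acting
through per-miRNA retention factors, an 8-oligo spike-in ladder spanning a
500-fold concentration range added per embryo, PCR duplication disambiguated
by a 10-nt random UMI split into a 4-nt and a 6-nt block around the insert,
a 5-nt inline 3' barcode, ~1%-level cross-contamination from a decoy pool,
and mirtron-specific 3'-end heterogeneity (single-nucleotide non-templated
U tailing, 1-nt trimming).

Each simulated read has the layout of the ligation product downstream of the
sequencing primer::

    NNNN - insert(18-30 nt) - NNNNNN - XXXXX(barcode) - 3' adapter ...

Every random draw is recorded in a :class:`GroundTruth` object so the
pipeline's estimates can be compared against what was actually generated.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .references import (MatureMiRNA, Hairpin, ReferenceSet, SpikeInOligo,
                         make_spikein_ladder, min_alignment_mismatches,
                         normalize_seq, revcomp)

STAGES = ("2cell", "gastrulation", "3fold", "L1")

# Portion of the 3' linker that follows the barcode in the ligation product.
DEFAULT_ADAPTER3 = "AGATCGGAAGAGCACACGTCT"

_MIN_STRUCTURE = 4 + 18 + 6 + 5 + 10  # UMIa + min insert + UMIb + barcode + adapter anchor

_LETTERS = np.array(list("ACGT"))


@dataclass
class StageProfile:
    """Per-embryo molecule counts for one stage and genotype."""

    stage: str
    molecules: dict[str, float]
    n_embryos: int = 100

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        for rid, v in self.molecules.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"molecule count for {rid} must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.molecules.values()))


@dataclass
class ConditionConfig:
    """Depletion-condition phenomenology.

    ``retention`` maps miRNA id -> fraction of WT molecules remaining (missing
    ids default to 1.0).  ``mirtron_mods`` maps a mirtron-derived miRNA id to
    its 3'-end heterogeneity probabilities: ``p_nta_u`` (single non-templated
    U appended) and ``p_trim1`` (one terminal nucleotide removed).
    """

    retention: dict[str, float] = field(default_factory=dict)
    mirtron_mods: dict[str, dict[str, float]] = field(default_factory=dict)
    contamination_rate: float = 0.0

    def __post_init__(self):
        for rid, r in self.retention.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"retention for {rid} outside [0,1]: {r}")
        for rid, mods in self.mirtron_mods.items():
            p_nta = mods.get("p_nta_u", 0.0)
            p_trim = mods.get("p_trim1", 0.0)
            if not (0.0 <= p_nta <= 1.0 and 0.0 <= p_trim <= 1.0 and p_nta + p_trim <= 1.0):
                raise ValueError(f"mirtron mod probabilities for {rid} invalid")
        if not (0.0 <= self.contamination_rate <= 1.0):
            raise ValueError("contamination_rate outside [0,1]")


@dataclass
class PrepModel:
    """Library-prep model: ligation capture, PCR duplication, read geometry."""

    pcr_dup_mean: float = 4.0  # mean reads per ligated molecule (shifted geometric)
    read_length: int = 50
    barcode: str = "TGACA"
    adapter3: str = DEFAULT_ADAPTER3
    error_rate: float = 0.0
    rng_seed: int = 0
    capture_efficiency: float = 0.05  # molecules -> ligated molecules

    def __post_init__(self):
        self.barcode = normalize_seq(self.barcode)
        self.adapter3 = normalize_seq(self.adapter3)
        if len(self.barcode) != 5:
            raise ValueError("barcode must be 5 nt")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        if self.pcr_dup_mean < 1:
            raise ValueError("pcr_dup_mean must be >= 1")
        if not (0 < self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be in (0,1]")


@dataclass
class GroundTruth:
    """Everything the simulator drew, at per-read and per-reference grain."""

    reads: pd.DataFrame    # read_id, ref_id, insert, umi, barcode, event
    per_ref: pd.DataFrame  # ref_id, molecules_per_embryo, ligated, reads, n_exact, n_nta, n_trim

    @property
    def n_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def make_wt_profile(ref: ReferenceSet, stage: str, total_molecules: float,
                    family_share: float = 0.5, rng_seed: int = 0,
                    n_embryos: int = 100, sigma: float = 1.5) -> StageProfile:
    """Draw a wild-type per-embryo abundance profile.

    Individual abundances are lognormal (shape ``sigma``), then rescaled so
    that the annotated family members (e.g. miR-35fam + miR-51fam) jointly
    carry ``family_share`` of ``total_molecules`` and everything sums to
    ``total_molecules`` — mirroring the observation that the two early-embryo
    families make up about half of total miRNA content.
    """
    if total_molecules <= 0:
        raise ValueError("total_molecules must be > 0")
    if not (0.0 <= family_share < 1.0):
        raise ValueError("family_share must be in [0,1)")
    members = sorted(ref.family_members() & ref.mirna_ids)
    others = sorted(ref.mirna_ids - set(members))
    if family_share > 0 and not members:
        raise ValueError("reference set has no family members")
    if not others:
        raise ValueError("reference set has no non-family miRNAs")

    rng = np.random.default_rng(rng_seed)
    molecules: dict[str, float] = {}
    for group, share in ((members, family_share), (others, 1.0 - family_share)):
        if not group:
            continue
        draws = rng.lognormal(mean=0.0, sigma=sigma, size=len(group))
        scale = share * total_molecules / draws.sum() if share > 0 else 0.0
        for rid, d in zip(group, draws):
            molecules[rid] = float(d * scale)
    return StageProfile(stage=stage, molecules=molecules, n_embryos=n_embryos)


def apply_depletion(profile: StageProfile, cond: ConditionConfig) -> StageProfile:
    """Multiply each miRNA by its retention factor; drop fully-depleted ids."""
    out: dict[str, float] = {}
    for rid, v in profile.molecules.items():
        kept = v * cond.retention.get(rid, 1.0)
        if kept > 0:
            out[rid] = kept
    return StageProfile(stage=profile.stage, molecules=out, n_embryos=profile.n_embryos)


# ---------------------------------------------------------------------------
# synthetic reference sets
# ---------------------------------------------------------------------------

def make_reference(n_other: int = 16, n_pirnas: int = 20, rng_seed: int = 7,
                   mature_length: int = 22, ladder_kwargs: dict | None = None) -> ReferenceSet:
    """Build a self-consistent synthetic reference set.

    Contains the miR-35 family (mir-35..mir-42, 8 members), the miR-51 family
    (mir-51..mir-56, 6 members), ``n_other`` family-less miRNAs (the first
    named lsy-6), ``n_pirnas`` 21U piRNAs, and the default 8-oligo spike-in
    ladder.  Each hairpin is a perfect stem-loop with the mature on the 3p
    arm and a short downstream genomic context whose first base is non-T, so
    a simulated non-templated U tail is always distinguishable from a
    templated extension.
    """
    rng = np.random.default_rng(rng_seed)
    fam35 = [f"mir-{i}" for i in range(35, 43)]
    fam51 = [f"mir-{i}" for i in range(51, 57)]
    others = ["lsy-6"] + [f"mir-x{i:02d}" for i in range(1, n_other)]
    families = {"miR-35fam": fam35, "miR-51fam": fam51}
    fam_lookup = {m: f for f, ms in families.items() for m in ms}

    def rand_seq(n: int) -> str:
        return "".join(_LETTERS[rng.integers(0, 4, size=n)])

    matures: list[MatureMiRNA] = []
    hairpins: dict[str, Hairpin] = {}
    seqs: list[str] = []
    for name in fam35 + fam51 + others:
        while True:
            mat = rand_seq(mature_length)
            if all(min_alignment_mismatches(mat, s) >= 4 for s in seqs):
                break
        seqs.append(mat)
        loop = rand_seq(8)
        hp_seq = revcomp(mat) + loop + mat
        ctx = "".join(_LETTERS[[rng.integers(0, 3)]]) + rand_seq(5)  # starts A/C/G
        hid = f"{name}-pre"
        hairpins[hid] = Hairpin(id=hid, sequence=hp_seq, context3=ctx)
        start = mature_length + 8 + 1
        matures.append(MatureMiRNA(
            id=name, hairpin_id=hid, arm="3p", sequence=mat,
            start=start, end=start + mature_length - 1,
            family_id=fam_lookup.get(name)))

    pirnas: dict[str, str] = {}
    for i in range(1, n_pirnas + 1):
        while True:
            s = "T" + rand_seq(20)
            if all(min_alignment_mismatches(s, q) >= 4 for q in seqs):
                break
        seqs.append(s)
        pirnas[f"21ur-{i}"] = s

    spikeins = make_spikein_ladder(avoid=seqs, rng_seed=rng_seed + 1,
                                   **(ladder_kwargs or {}))
    return ReferenceSet(matures=matures, hairpins=hairpins, pirnas=pirnas,
                        spikeins=spikeins, families=families)


def _decoy_pool(ref: ReferenceSet, n: int, rng: np.random.Generator) -> list[str]:
    """Alphabet-shuffled contaminant sequences, >= 4 mismatches from all refs."""
    avoid = ref.all_sequences()
    pool: list[str] = []
    mats = [m.sequence for m in ref.matures]
    i = 0
    while len(pool) < n:
        base = list(mats[i % len(mats)])
        i += 1
        rng.shuffle(base)
        s = "".join(base)
        if all(min_alignment_mismatches(s, q) >= 4 for q in avoid + pool):
            pool.append(s)
    return pool


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _umi_strings(rng: np.random.Generator, n: int) -> list[str]:
    arr = _LETTERS[rng.integers(0, 4, size=(n, 10))]
    return ["".join(row) for row in arr]


def simulate_library(profile: StageProfile, cond: ConditionConfig,
                     ref: ReferenceSet, prep: PrepModel
                     ) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Simulate one barcoded library from one sample.

    Per reference, ligated molecules ~ Poisson(molecules x n_embryos x
    capture_efficiency); each ligated molecule gets one 10-nt UMI and a
    shifted-geometric number of PCR-duplicate reads (mean ``pcr_dup_mean``).
    Spike-ins are always included at their ladder concentrations per embryo.
    Returns the reads as (read_id, sequence) pairs plus the ground truth.
    """
    if prep.read_length < _MIN_STRUCTURE:
        raise ValueError(
            f"read_length {prep.read_length} cannot contain the minimal read "
            f"structure ({_MIN_STRUCTURE} nt)")
    rng = np.random.default_rng(prep.rng_seed)
    n_emb = profile.n_embryos
    eff = prep.capture_efficiency
    p_dup = 1.0 / prep.pcr_dup_mean

    sources: list[tuple[str, str, float, dict | None]] = []
    for rid in sorted(profile.molecules):
        sources.append((rid, ref.sequence_of(rid), profile.molecules[rid],
                        cond.mirtron_mods.get(rid)))
    for sp in ref.spikeins:
        sources.append((sp.id, sp.sequence, sp.molecules_per_embryo, None))

    reads: list[tuple[str, str]] = []
    rd_ids: list[str] = []
    rd_ref: list[str] = []
    rd_insert: list[str] = []
    rd_umi: list[str] = []
    rd_event: list[str] = []
    per_ref_rows: list[dict] = []
    counter = 0

    def emit(rid: str, seq: str, mol_per_embryo: float, mods: dict | None,
             n_lig: int | None = None) -> int:
        nonlocal counter
        if n_lig is None:
            n_lig = int(rng.poisson(mol_per_embryo * n_emb * eff))
        row = {"ref_id": rid, "molecules_per_embryo": mol_per_embryo,
               "ligated": n_lig, "reads": 0,
               "n_exact": 0, "n_nta": 0, "n_trim": 0}
        if n_lig == 0:
            per_ref_rows.append(row)
            return 0
        p_nta = mods.get("p_nta_u", 0.0) if mods else 0.0
        p_trim = mods.get("p_trim1", 0.0) if mods else 0.0
        u = rng.random(n_lig)
        umis = _umi_strings(rng, n_lig)
        dups = rng.geometric(p_dup, size=n_lig)
        for k in range(n_lig):
            if u[k] < p_nta:
                insert, event = seq + "T", "nta"
                row["n_nta"] += 1
            elif u[k] < p_nta + p_trim:
                insert, event = seq[:-1], "trim1"
                row["n_trim"] += 1
            else:
                insert, event = seq, "exact"
                row["n_exact"] += 1
            umi = umis[k]
            full = umi[:4] + insert + umi[4:] + prep.barcode + prep.adapter3
            if len(full) < prep.read_length:
                full = full + "A" * (prep.read_length - len(full))
            full = full[: prep.read_length]
            for _ in range(int(dups[k])):
                rid_read = f"r{counter:08d}"
                counter += 1
                out = full
                if prep.error_rate > 0:
                    nerr = rng.binomial(len(out), prep.error_rate)
                    if nerr:
                        pos = rng.choice(len(out), size=nerr, replace=False)
                        chars = list(out)
                        for p in pos:
                            chars[p] = _LETTERS[(("ACGT".index(chars[p])
                                                 + rng.integers(1, 4)) % 4)]
                        out = "".join(chars)
                reads.append((rid_read, out))
                rd_ids.append(rid_read)
                rd_ref.append(rid)
                rd_insert.append(insert)
                rd_umi.append(umi)
                rd_event.append(event)
                row["reads"] += 1
        per_ref_rows.append(row)
        return n_lig

    total_lig = 0
    for rid, seq, mol, mods in sources:
        total_lig += emit(rid, seq, mol, mods)

    if cond.contamination_rate > 0 and total_lig > 0:
        n_contam = int(rng.poisson(cond.contamination_rate * total_lig))
        if n_contam > 0:
            pool = _decoy_pool(ref, min(20, max(1, n_contam)), rng)
            which = rng.integers(0, len(pool), size=n_contam)
            counts = np.bincount(which, minlength=len(pool))
            for di, c in enumerate(counts):
                if c:
                    emit(f"decoy-{di + 1}", pool[di], 0.0, None, n_lig=int(c))

    gt = GroundTruth(
        reads=pd.DataFrame({"read_id": rd_ids, "ref_id": rd_ref,
                            "insert": rd_insert, "umi": rd_umi,
                            "barcode": prep.barcode, "event": rd_event}),
        per_ref=pd.DataFrame(per_ref_rows),
    )
    return reads, gt


def write_fastq(reads: list[tuple[str, str]], path) -> Path:
    """Write reads as FASTQ (gzip if the path ends in .gz); constant quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def read_fastq(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTQ file (gzip transparent)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out: list[tuple[str, str]] = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header.strip().lstrip("@"), seq))
    return out


def default_barcodes(n: int = 3) -> dict[str, str]:
    """Pairwise Hamming-distance >= 2 barcode -> sample map for simulations."""
    codes = ["TGACA", "ACTGG", "GTCTC", "CAGAT", "TCGGT", "AGATC"]
    if n > len(codes):
        raise ValueError("at most 6 default barcodes available")
    return {codes[i]: f"S{i + 1}" for i in range(n)}
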