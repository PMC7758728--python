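"""Rule-based mirtron engineering from a pre-miRNA hairpin.

A mirtron is an intron whose spliced lariat folds into a pre-miRNA hairpin
and therefore bypasses the Microprocessor, entering the miRNA pathway at
the Dicer step.  Converting a pre-miRNA hairpin into a mirtron requires:

1. grafting a 3' splice-acceptor consensus (6 nt ending in AG) onto the
   hairpin 3' end, so the spliceosome can excise the intron;
2. compensatory changes on the 5p arm wherever the graft broke a base pair,
   so the hairpin secondary structure — and hence Dicer processing — is
   retained (assessed by a structure predictor, here the package's
   max-pairing fold, with a pluggable alternative backend);
3. validation: the intron must start with the canonical GT donor (mirtron
   5' arms invariably start with G), end in AG, preserve the mature 3p
   seed (nts 2-8), and stay within a base-pair-distance budget of the
   original structure.

A seed-mutant variant (control construct that should not rescue targets)
swaps a fixed number of paired seed positions together with their 5p
partners, preserving the pair count of the hairpin.

Branch-point placement is not scored: branch-point motifs are permissive
enough that essentially any A near the 3' splice site supports lariat
formation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fold import Structure, bp_distance, fold
from .references import WC, Hairpin, MatureMiRNA, normalize_seq, seed_of

ACCEPTOR_LEN = 6
DEFAULT_ACCEPTOR6 = "TTTCAG"  # pyrimidine-rich, canonical AG
DEFAULT_MAX_BP_DISTANCE = 4

# preferred substitutions for seed mutants: transversions that keep a clean
# Watson-Crick pair after the compensatory partner change
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


class DesignError(ValueError):
    """Raised when the input violates a hard design rule."""


@dataclass(frozen=True)
class SpliceConsensus:
    acceptor6: str = DEFAULT_ACCEPTOR6
    donor2: str = "GT"

    def __post_init__(self):
        object.__setattr__(self, "acceptor6", normalize_seq(self.acceptor6))
        object.__setattr__(self, "donor2", normalize_seq(self.donor2))
        if len(self.acceptor6) != ACCEPTOR_LEN or not self.acceptor6.endswith("AG"):
            raise DesignError("acceptor6 must be 6 nt ending in AG")
        if self.donor2 != "GT":
            raise DesignError("donor2 must be the canonical GT")


@dataclass
class MirtronDesign:
    intron: str
    changes: list[tuple[int, str, str, str]]  # (1-based position, from, to, arm)
    structure_before: Structure
    structure_after: Structure
    bp_distance: int
    validations: dict[str, bool] = field(default_factory=dict)
    mature_start: int | None = None  # 1-based on the intron
    mature_end: int | None = None

    @property
    def accepted(self) -> bool:
        return bool(self.validations) and all(self.validations.values())

    @property
    def mature_sequence(self) -> str | None:
        if self.mature_start is None:
            return None
        return self.intron[self.mature_start - 1 : self.mature_end]


def graft_acceptor(hairpin_seq: str, consensus: SpliceConsensus) -> str:
    """Replace the last 6 nt of the hairpin with the splice-acceptor consensus."""
    s = normalize_seq(hairpin_seq)
    if len(s) <= ACCEPTOR_LEN:
        raise DesignError("hairpin must be longer than the 6-nt acceptor window")
    return s[:-ACCEPTOR_LEN] + consensus.acceptor6


def compensate_5p(original: str, grafted: str,
                  protect: range | None = None,
                  fold_backend: Callable[[str], Structure] = fold) -> MirtronDesign:
    """Restore pairing broken by the acceptor graft via 5p-arm changes.

    For every grafted 3p position that was paired in the original fold, the
    5' partner is mutated to the Watson-Crick complement of the new base;
    positions unpaired in the original are left untouched.  ``protect``
    marks 0-based positions (the mature 3p arm) that must not receive
    compensatory changes.  Returns a partial design (no validations yet).
    """
    original = normalize_seq(original)
    grafted = normalize_seq(grafted)
    if len(original) != len(grafted):
        raise DesignError("grafted sequence must have the hairpin's length")
    n = len(original)
    window = range(n - ACCEPTOR_LEN, n)
    diffs = [p for p in range(n) if original[p] != grafted[p]]
    if any(p not in window for p in diffs):
        raise DesignError("grafted sequence differs outside the last 6 nt")

    st_before = fold_backend(original)
    partner = {}
    for i, j in st_before.pairs:
        partner[i] = j
        partner[j] = i

    changes: list[tuple[int, str, str, str]] = [
        (p + 1, original[p], grafted[p], "3p") for p in diffs]
    proposals: list[tuple[int, str]] = []
    for p in diffs:
        q = partner.get(p)
        if q is None or q in window:
            continue  # unpaired, or partnered within the grafted window itself
        if protect is not None and q in protect:
            raise DesignError(
                f"compensatory change at position {q + 1} would fall inside "
                "the mature 3p arm")
        new = WC[grafted[p]]
        if grafted[q] != new:
            proposals.append((q, new))

    # Greedy acceptance: under a global max-pairing fold a Watson-Crick
    # partner swap can occasionally rearrange distant pairs, so each
    # compensatory change is kept only if it does not move the structure
    # further from the original.
    seq = list(grafted)
    st_after = fold_backend(grafted)
    best_dist = bp_distance(st_after, st_before)
    for q, new in proposals:
        old = seq[q]
        seq[q] = new
        st_try = fold_backend("".join(seq))
        d = bp_distance(st_try, st_before)
        if d <= best_dist:
            best_dist, st_after = d, st_try
            changes.append((q + 1, old, new, "5p"))
        else:
            seq[q] = old
    compensated = "".join(seq)
    return MirtronDesign(intron=compensated, changes=changes,
                         structure_before=st_before, structure_after=st_after,
                         bp_distance=best_dist)


def design_mirtron(pre_mirna: Hairpin, mature_3p: MatureMiRNA,
                   consensus: SpliceConsensus | None = None,
                   max_bp_distance: int = DEFAULT_MAX_BP_DISTANCE,
                   fold_backend: Callable[[str], Structure] = fold) -> MirtronDesign:
    """Design a mirtron that delivers ``mature_3p`` Microprocessor-free.

    Failing validation rules are reported as flags on the returned design;
    a design is accepted only if all flags hold.  Hard input violations
    (mature on the 5p arm; seed overlapping the grafted window) raise
    :class:`DesignError`.
    """
    consensus = consensus or SpliceConsensus()
    if mature_3p.arm != "3p":
        raise DesignError("mirtron matures must sit on the 3p arm "
                          "(the 5p arm starts with the G of the splice donor)")
    if mature_3p.hairpin_id != pre_mirna.id:
        raise DesignError("mature does not belong to this hairpin")
    original = pre_mirna.sequence
    n = len(original)
    # last 0-based seed position on the hairpin (mature nt 8)
    seed_last = mature_3p.start - 1 + 7
    if seed_last >= n - ACCEPTOR_LEN:
        raise DesignError("mature seed overlaps the 6-nt splice-acceptor window")

    grafted = graft_acceptor(original, consensus)
    design = compensate_5p(original, grafted,
                           protect=range(mature_3p.start - 1, mature_3p.end),
                           fold_backend=fold_backend)
    design.mature_start = mature_3p.start
    design.mature_end = mature_3p.end
    intron = design.intron
    design.validations = {
        "starts_GT": intron.startswith(consensus.donor2),
        "ends_AG": intron.endswith("AG"),
        "seed_preserved": seed_of(design.mature_sequence) == seed_of(mature_3p.sequence),
        "structure_ok": design.bp_distance <= max_bp_distance,
    }
    return design


def seed_mutant(design: MirtronDesign, n_swaps: int = 3, rng_seed: int = 0,
                fold_backend: Callable[[str], Structure] = fold) -> MirtronDesign:
    """Swap ``n_swaps`` paired seed bases (with compensatory 5p changes).

    Substitutions prefer transversions; each swapped seed position's fold
    partner is mutated to the Watson-Crick complement, so the mutant folds
    with exactly as many base pairs as the input design.  The mutant seed
    differs from the design's seed at exactly ``n_swaps`` positions.
    """
    if design.mature_start is None:
        raise DesignError("design lacks mature coordinates")
    if n_swaps == 0:
        return design
    intron = design.intron
    st = fold_backend(intron)
    partner = {}
    for i, j in st.pairs:
        partner[i] = j
        partner[j] = i
    seed_pos = list(range(design.mature_start, design.mature_start + 7))  # 0-based nts 2-8
    seed_set = set(seed_pos)
    eligible = [p for p in seed_pos if p in partner and partner[p] not in seed_set]
    if len(eligible) < n_swaps:
        raise DesignError(
            f"only {len(eligible)} paired seed positions; cannot swap {n_swaps}")
    rng = np.random.default_rng(rng_seed)
    chosen = sorted(rng.choice(len(eligible), size=n_swaps, replace=False).tolist())
    positions = [eligible[i] for i in chosen]

    def substitutions(base: str) -> list[str]:
        pref = _TRANSVERSION[base]
        return [pref] + [b for b in "ACGT" if b not in (base, pref)]

    target_pairs = st.n_pairs
    options = [substitutions(intron[p]) for p in positions]
    for combo in itertools.product(*options):
        seq = list(intron)
        muts: list[tuple[int, str, str, str]] = []
        for p, new in zip(positions, combo):
            muts.append((p + 1, seq[p], new, "3p"))
            seq[p] = new
            q = partner[p]
            comp = WC[new]
            if seq[q] != comp:
                muts.append((q + 1, seq[q], comp, "5p"))
                seq[q] = comp
        mutant = "".join(seq)
        st_mut = fold_backend(mutant)
        if st_mut.n_pairs != target_pairs:
            continue
        return MirtronDesign(
            intron=mutant, changes=list(design.changes) + muts,
            structure_before=st, structure_after=st_mut,
            bp_distance=bp_distance(st_mut, st),
            validations={**design.validations, "seed_preserved": False},
            mature_start=design.mature_start, mature_end=design.mature_end)
    raise DesignError("no substitution combination preserves the pair count")
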