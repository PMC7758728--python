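"""Reference assignment and isomiR classification.

Each insert is matched against the reference set with a fixed class priority
for exact hits (spike-in > piRNA > mature miRNA) and, failing that, an
isomiR alignment against each hairpin: the insert 5' end may sit within +/-2
nt of the annotated mature 5' end, the genome-templated body must match with
zero mismatches, the 3' end may be trimmed (<=4 nt) or extended along the
template (<=4 nt), and up to 3 trailing nucleotides that disagree with the
next templated base(s) are classified as a non-templated tail (NTA) — the
signature of, e.g., mirtron uridylation.  Inserts matching more than one
reference equally well are flagged ambiguous rather than arbitrarily placed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .references import ReferenceSet

REF_CLASSES = ("miRNA", "piRNA", "spikein", "unassigned", "ambiguous")
ISO_CLASSES = ("exact", "iso5p", "iso3p_trim", "iso3p_ext_templated", "nta")

MAX_OFFSET5 = 2
MAX_TRIM3 = 4
MAX_EXT3 = 4
MAX_TAIL = 3


@dataclass(frozen=True)
class Assignment:
    ref_id: str | None
    ref_class: str
    iso_class: str | None = None
    offset5: int = 0
    trim3: int = 0
    ext3: int = 0
    tail: str = ""
    length: int | None = None  # insert length, kept for end profiles


def _iso_class(offset5: int, trim3: int, ext3: int, tail: str) -> str:
    if tail:
        return "nta"
    if offset5 != 0:
        return "iso5p"
    if trim3 > 0:
        return "iso3p_trim"
    if ext3 > 0:
        return "iso3p_ext_templated"
    return "exact"


class Assigner:
    """Assign inserts against one reference set, with per-insert caching.

    Identical inserts are frequent in real and simulated libraries (every PCR
    duplicate and every molecule of the same species shares a sequence), so
    results are memoized by insert string.
    """

    def __init__(self, ref: ReferenceSet, max_offset5: int = MAX_OFFSET5,
                 max_trim3: int = MAX_TRIM3, max_ext3: int = MAX_EXT3,
                 max_tail: int = MAX_TAIL):
        self.max_offset5 = max_offset5
        self.max_trim3 = max_trim3
        self.max_ext3 = max_ext3
        self.max_tail = max_tail

        def index(pairs: Iterable[tuple[str, str]]) -> dict[str, list[str]]:
            d: dict[str, list[str]] = {}
            for rid, seq in pairs:
                d.setdefault(seq, []).append(rid)
            return d

        self._spike_exact = index((s.id, s.sequence) for s in ref.spikeins)
        self._pirna_exact = index(ref.pirnas.items())
        self._mature_exact = index((m.id, m.sequence) for m in ref.matures)
        # (mirna_id, template string, 0-based mature start, mature length)
        self._windows = [
            (m.id, ref.hairpins[m.hairpin_id].template, m.start - 1,
             m.end - m.start + 1)
            for m in sorted(ref.matures, key=lambda m: m.id)
        ]
        self._cache: dict[str, Assignment] = {}

    # -- exact stage ---------------------------------------------------
    def _exact(self, insert: str) -> Assignment | None:
        for table, ref_class in ((self._spike_exact, "spikein"),
                                 (self._pirna_exact, "piRNA"),
                                 (self._mature_exact, "miRNA")):
            ids = table.get(insert)
            if ids:
                if len(ids) > 1:
                    return Assignment(None, "ambiguous", length=len(insert))
                return Assignment(ids[0], ref_class, "exact", length=len(insert))
        return None

    # -- isomiR stage --------------------------------------------------
    def _isomir_candidates(self, insert: str) -> list[tuple[tuple, Assignment]]:
        L = len(insert)
        out: list[tuple[tuple, Assignment]] = []
        for rid, tpl, s0, mlen in self._windows:
            e0 = s0 + mlen
            for off in range(-self.max_offset5, self.max_offset5 + 1):
                a = s0 + off
                if a < 0:
                    continue
                # maximal genome-templated prefix of the insert at this anchor
                t = 0
                tl = len(tpl)
                while t < L and a + t < tl and insert[t] == tpl[a + t]:
                    t += 1
                tail = insert[t:]
                if len(tail) > self.max_tail or t == 0:
                    continue
                end = a + t
                trim3 = max(0, e0 - end)
                ext3 = max(0, end - e0)
                if trim3 > self.max_trim3 or ext3 > self.max_ext3:
                    continue
                cost = abs(off) + trim3 + ext3 + len(tail)
                key = (cost, abs(off), off < 0, trim3, ext3, len(tail), rid)
                out.append((key, Assignment(
                    rid, "miRNA", _iso_class(off, trim3, ext3, tail),
                    offset5=off, trim3=trim3, ext3=ext3, tail=tail, length=L)))
        return out

    def __call__(self, insert: str) -> Assignment:
        cached = self._cache.get(insert)
        if cached is not None:
            return cached
        result = self._exact(insert)
        if result is None:
            cands = self._isomir_candidates(insert)
            if not cands:
                result = Assignment(None, "unassigned", length=len(insert))
            else:
                cands.sort(key=lambda kv: kv[0])
                best_key, best = cands[0]
                # a second reference at the same deviation cost -> ambiguous
                rivals = {a.ref_id for k, a in cands if k[0] == best_key[0]}
                if len(rivals) > 1:
                    result = Assignment(None, "ambiguous", length=len(insert))
                else:
                    result = best
        self._cache[insert] = result
        return result


def assign_read(insert: str, ref: ReferenceSet, **kwargs) -> Assignment:
    """Assign one insert; deterministic for a given reference set.

    For bulk use construct an :class:`Assigner` once; this helper caches one
    default-parameter assigner on the reference set object.
    """
    if kwargs:
        return Assigner(ref, **kwargs)(insert)
    assigner = getattr(ref, "_default_assigner", None)
    if assigner is None:
        assigner = Assigner(ref)
        ref._default_assigner = assigner
    return assigner(insert)


def end_profile(assignments: Sequence[Assignment]) -> dict:
    """Summarize 3'/5'-end heterogeneity for one reference.

    Returns iso-class fractions (summing to 1), the fraction of NTA tails
    consisting solely of U, the insert-length histogram, and the modal
    length (ties resolved toward the shorter length).
    """
    if not assignments:
        raise ValueError("end_profile requires at least one assignment")
    n = len(assignments)
    fracs = {c: 0.0 for c in ISO_CLASSES}
    tails: list[str] = []
    hist: dict[int, int] = {}
    for a in assignments:
        if a.iso_class is None:
            raise ValueError("end_profile requires classified assignments")
        fracs[a.iso_class] += 1
        if a.tail:
            tails.append(a.tail)
        if a.length is not None:
            hist[a.length] = hist.get(a.length, 0) + 1
    fracs = {c: v / n for c, v in fracs.items()}
    u_frac = (sum(1 for t in tails if set(t) == {"T"}) / len(tails)) if tails else None
    modal = min((length for length, c in hist.items()
                 if c == max(hist.values())), default=None)
    return {"iso_fractions": fracs, "u_tail_fraction": u_frac,
            "length_hist": dict(sorted(hist.items())), "modal_length": modal}
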