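"""RNA secondary-structure prediction by maximum base pairing.

A self-contained Nussinov-style dynamic program over Watson-Crick (A-U, G-C)
and G-U wobble pairs with a minimum hairpin-loop size of three unpaired
nucleotides.  It returns the structure with the maximum number of base pairs;
ties are broken deterministically toward 5'-most pairing during traceback.
An external thermodynamic predictor can be plugged in anywhere a
``fold``-shaped callable is accepted, as long as it returns a
:class:`Structure`.

Sequences are handled in DNA space internally (U -> T), matching the rest of
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MIN_LOOP = 3

_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G-U wobble pairing in DNA letters."""
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class Structure:
    """A pseudoknot-free secondary structure.

    ``pairs`` holds 0-based (i, j) tuples with i < j; ``dotbracket`` is the
    equivalent dot-bracket string.
    """

    dotbracket: str
    pairs: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _normalize(seq: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def fold(seq: str, min_loop: int = MIN_LOOP) -> Structure:
    """Fold ``seq`` into its maximum base-pairing structure.

    The DP table N[i][j] stores the maximum number of pairs on seq[i..j];
    traceback prefers pairing the 3' base with its 5'-most compatible
    partner, making the result deterministic.
    """
    s = _normalize(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")

    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(s[k], s[j]):
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + 1 + inner)
            N[i][j] = best

    pairs: set[tuple[int, int]] = set()

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop:
            target = N[i][j]
            if target == 0:
                return
            chosen = None
            for k in range(i, j - min_loop):
                if can_pair(s[k], s[j]):
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if left + 1 + inner == target:
                        chosen = k
                        break
            if chosen is None:
                j -= 1
                continue
            pairs.add((chosen, j))
            if chosen + 1 <= j - 1:
                traceback(chosen + 1, j - 1)
            j = chosen - 1
            if j <= i:
                return

    traceback(0, n - 1)

    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return Structure(dotbracket="".join(db), pairs=frozenset(pairs))


def bp_distance(a: Structure, b: Structure) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets."""
    return len(a.pairs ^ b.pairs)


def loop_midpoint(seq: str) -> float:
    """Midpoint of the hairpin loop of the max-pairing fold.

    Defined as the midpoint of the innermost base pair (the pair with the
    smallest span); for sequences that fold without any pair, the sequence
    midpoint is returned.  Used to decide which half of a hairpin an arm
    occupies.
    """
    st = fold(seq)
    if not st.pairs:
        return (len(seq) - 1) / 2.0
    i, j = min(st.pairs, key=lambda ij: (ij[1] - ij[0], ij[0]))
    return (i + j) / 2.0
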