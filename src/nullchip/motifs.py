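"""Degenerate 8-mer over-representation in target versus background promoters.

The scan is unbiased: no prior motif model is imposed beyond the length
restriction. Candidate words observed in the target promoters are tested
for per-promoter presence (either strand) against the background with a
one-sided hypergeometric test, then greedily merged into degenerate
patterns with at most two alternative bases per position. Found motifs can
be compared against the published forkhead-box binding consensus patterns
(RYMAAYA, TATTTRT, AATTTGT).

The choice of test statistic is isolated in :func:`presence_pvalue` so a
binomial or Fisher variant is a drop-in replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC.items()}
_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")

KNOWN_FOX_CONSENSUS = ("RYMAAYA", "TATTTRT", "AATTTGT")


class MotifError(ValueError):
    pass


Pattern = tuple[frozenset, ...]


def parse_pattern(text: str) -> Pattern:
    """Parse an IUPAC string, optionally with [X/Y] bracket alternatives."""
    out: list[frozenset] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            alts = [c for c in text[i + 1:j].upper() if c not in "/|,"]
            sets = [IUPAC.get(c) for c in alts]
            if any(s is None for s in sets):
                raise MotifError(f"invalid code inside {text[i:j+1]!r}")
            out.append(frozenset().union(*sets))
            i = j + 1
        else:
            s = IUPAC.get(ch.upper())
            if s is None:
                raise MotifError(f"invalid IUPAC code {ch!r} in pattern {text!r}")
            out.append(s)
            i += 1
    return tuple(out)


def pattern_to_string(pattern: Pattern, bracket: bool = True) -> str:
    """Render a pattern, using Table-style [X/Y] brackets for 2-base positions."""
    parts = []
    for p in pattern:
        if len(p) == 1 or not bracket:
            parts.append(_SET_TO_CODE[frozenset(p)])
        elif len(p) == 2:
            a, b = sorted(p)
            parts.append(f"[{a}/{b}]")
        else:
            parts.append(_SET_TO_CODE[frozenset(p)])
    return "".join(parts)


def reverse_complement_pattern(pattern: Pattern) -> Pattern:
    return tuple(frozenset(b.translate(_COMPLEMENT) for b in p) for p in reversed(pattern))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_at(seq: str, pos: int, pattern: Pattern) -> bool:
    return all(seq[pos + i] in p for i, p in enumerate(pattern))


def scan_motif(pattern, sequences, expected_length: int | None = None):
    """Count pattern matches per sequence on either strand.

    A start position matching both the pattern and its reverse complement
    counts once. Returns a list of counts aligned with `sequences` (a list
    of strings or a dict, in which case a dict of counts is returned).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if expected_length is not None and len(pattern) != expected_length:
        raise MotifError(f"pattern has length {len(pattern)}, expected {expected_length}")
    rc = reverse_complement_pattern(pattern)
    k = len(pattern)

    def count(seq: str) -> int:
        seq = seq.upper()
        hits = 0
        for pos in range(len(seq) - k + 1):
            if _matches_at(seq, pos, pattern) or _matches_at(seq, pos, rc):
                hits += 1
        return hits

    if isinstance(sequences, dict):
        return {sid: count(s) for sid, s in sequences.items()}
    return [count(s) for s in sequences]


def presence_pvalue(k_target: int, n_target: int, k_background: int,
                    n_background: int) -> float:
    """One-sided hypergeometric tail for motif presence.

    Population = all surveyed promoters, of which k_target + k_background
    contain the motif; the target set is the draw. Returns P(X >= k_target).
    """
    N = n_target + n_background
    K = k_target + k_background
    return float(hypergeom.sf(k_target - 1, N, K, n_target))


@dataclass
class DegenerateMotif:
    pattern: Pattern
    promoter_count: int
    p_min: float
    p_max: float
    words: tuple[str, ...]  # concrete member words, ascending p

    @property
    def label(self) -> str:
        return pattern_to_string(self.pattern)


def _word_presence(seqs: dict[str, str], k: int) -> dict[str, set]:
    """Map canonical k-mer -> set of sequence ids containing it on either strand."""
    presence: dict[str, set] = {}
    for sid, seq in seqs.items():
        seq = seq.upper()
        seen = set()
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" in w:
                continue
            seen.add(min(w, reverse_complement(w)))
        for w in seen:
            presence.setdefault(w, set()).add(sid)
    return presence


def _compatible(pattern: Pattern, word: str) -> int | None:
    """If `word` can widen `pattern` at <=1 position (max 2 bases per
    position), return the number of widened positions, else None."""
    widened = 0
    for p, c in zip(pattern, word):
        if c in p:
            continue
        if len(p) >= 2:
            return None
        widened += 1
        if widened > 1:
            return None
    return widened


def _widen(pattern: Pattern, word: str) -> Pattern:
    return tuple(p if c in p else frozenset(p | {c}) for p, c in zip(pattern, word))


def enumerate_and_test(targets: dict[str, str], background: dict[str, str],
                       k: int = 8, alpha: float = 0.05,
                       min_support: int = 5,
                       max_candidates: int = 2000) -> list[DegenerateMotif]:
    """Unbiased over-representation scan of degenerate k-mers.

    Enumerates concrete k-mers present in the target promoters, tests
    per-promoter presence against the background with a one-sided
    hypergeometric test, then greedily merges significant words (ascending
    p) into degenerate patterns with at most two alternatives per position,
    widening one position at a time. Motifs are ranked by their best
    member-word p-value; the p-range across concrete variants is reported.

    The support filter (`min_support`) counts presence in targets and
    background combined: the hypergeometric test conditions on that total,
    so filtering on it leaves the test's calibration intact, whereas
    filtering on target-only support would select for the very statistic
    being tested.
    """
    if not targets or not background:
        raise MotifError("both target and background sets must be non-empty")
    if len(background) < 10:
        raise MotifError("background smaller than 10 sequences gives unstable "
                         "presence frequencies; refuse to test")

    t_presence = _word_presence(targets, k)
    b_presence = _word_presence(background, k)
    n_t, n_b = len(targets), len(background)

    scored = []
    for w, ids in t_presence.items():
        total = len(ids) + len(b_presence.get(w, ()))
        if total < min_support:
            continue
        p = presence_pvalue(len(ids), n_t, len(b_presence.get(w, ())), n_b)
        if p < alpha:
            scored.append((p, w))
    scored.sort()
    scored = scored[:max_candidates]

    merged: list[dict] = []  # {"pattern", "words": [(p, w)]}
    for p, w in scored:
        best = None
        for m in merged:
            widened = _compatible(m["pattern"], w)
            if widened is not None and (best is None or widened < best[1]):
                best = (m, widened)
        if best is None:
            merged.append({"pattern": parse_pattern(w), "words": [(p, w)]})
        else:
            m, _ = best
            m["pattern"] = _widen(m["pattern"], w)
            m["words"].append((p, w))

    out = []
    for m in merged:
        words = m["words"]
        prom = set()
        for _, w in words:
            prom |= t_presence.get(w, set())
        out.append(DegenerateMotif(
            pattern=m["pattern"],
            promoter_count=len(prom),
            p_min=min(p for p, _ in words),
            p_max=max(p for p, _ in words),
            words=tuple(w for _, w in words)))
    out.sort(key=lambda mo: (mo.p_min, -mo.promoter_count, mo.label))
    return out


def match_known(motif, consensus_patterns=KNOWN_FOX_CONSENSUS) -> dict[str, str]:
    """Classify a motif against each published consensus.

    complete: every concrete variant of the motif contains, in some gapless
    alignment window, a full instantiation of the consensus (or of its
    reverse complement). partial: the best alignment over variants matches
    at >= 6 positions. Otherwise none.
    """
    if isinstance(motif, DegenerateMotif):
        pattern = motif.pattern
    elif isinstance(motif, str):
        pattern = parse_pattern(motif)
    else:
        pattern = motif

    variants = [""]
    for p in pattern:
        variants = [v + c for v in variants for c in sorted(p)]

    report = {}
    for cons in consensus_patterns:
        cpats = [parse_pattern(cons)]
        cpats.append(reverse_complement_pattern(cpats[0]))
        best_per_variant = []
        for v in variants:
            best = 0
            for cp in cpats:
                span = len(v) - len(cp)
                offsets = range(span + 1) if span >= 0 else [0]
                for off in offsets:
                    hits = sum(1 for i, p in enumerate(cp)
                               if off + i < len(v) and v[off + i] in p)
                    best = max(best, hits)
            best_per_variant.append((best, len(min(cpats, key=len))))
        full = min(cpats, key=len)
        clen = len(full)
        if all(b >= clen for b, _ in best_per_variant):
            report[cons] = "complete"
        elif max(b for b, _ in best_per_variant) >= 6:
            report[cons] = "partial"
        else:
            report[cons] = "none"
    return report
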