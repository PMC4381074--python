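"""Discriminative IUPAC motif elicitation in UTR sequence sets.

Short motifs (4-8 nt by default) enriched in a positive set of UTRs relative
to a reference set (typically the complete 5'UTR or 3'UTR collection) are
found by an iterative discriminative search: exact words present in the
positives are scored by a one-tailed Fisher exact test on sequence-level
presence counts, the best words are generalized position-by-position into
2- and 3-letter IUPAC classes by hill-climbing on the Fisher p-value, and
the best refined motif is reported with a Bonferroni-style E-value
(p times the number of candidates scored in the iteration).  Its sites are
then erased (masked with N) from both sets and the search repeats until no
motif reaches the E-value threshold.

Matching is single-strand only: the inputs are mRNA-sense UTRs, so
reverse-complement matching would be wrong here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "Motif",
    "DiscoveryRun",
    "SequenceSet",
    "parse_iupac",
    "render_iupac",
    "match_sites",
    "presence_counts",
    "fisher_p",
    "discover_motifs",
    "scan_counts",
]

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SEP = 5


def parse_iupac(word: str) -> Tuple[FrozenSet[str], ...]:
    """Parse a motif word into per-position base classes.

    Accepts plain bases and bracketed classes in either the comma-separated
    rendering ``C[C,G,A]GCGC`` or the compact one ``C[CGA]GCGC``.
    """
    classes: List[FrozenSet[str]] = []
    i = 0
    while i < len(word):
        ch = word[i]
        if ch == "[":
            j = word.index("]", i)
            letters = [c for c in word[i + 1 : j].upper() if c != ","]
            if not letters or any(c not in _BASES for c in letters):
                raise ValueError(f"invalid IUPAC class {word[i:j+1]!r}")
            classes.append(frozenset(letters))
            i = j + 1
        else:
            if ch.upper() not in _BASES:
                raise ValueError(f"invalid motif letter {ch!r}")
            classes.append(frozenset(ch.upper()))
            i += 1
    if not classes:
        raise ValueError("empty motif")
    return tuple(classes)


def render_iupac(classes: Sequence[FrozenSet[str]]) -> str:
    """Render per-position classes as e.g. ``C[C,G,A]GCGC`` (sorted letters)."""
    parts = []
    for cls in classes:
        letters = sorted(cls)
        parts.append(letters[0] if len(letters) == 1 else "[" + ",".join(letters) + "]")
    return "".join(parts)


@dataclass
class Motif:
    """An IUPAC motif with its discriminative statistics."""

    word: str
    pos_with: int
    pos_total: int
    ref_with: int
    ref_total: int
    p: float
    e: float
    iteration: int = 0

    @property
    def width(self) -> int:
        return len(parse_iupac(self.word))

    @property
    def classes(self) -> Tuple[FrozenSet[str], ...]:
        return parse_iupac(self.word)


class SequenceSet:
    """A set of DNA sequences packed for fast IUPAC matching.

    Sequences are concatenated into one uint8 code array with separators, so
    a motif can be matched against the whole set with a handful of
    vectorized comparisons.  ``erase`` masks matched sites with N in place.
    """

    def __init__(self, seqs: Sequence[str]) -> None:
        self.seqs: List[str] = [s.upper() for s in seqs]
        for s in self.seqs:
            if any(c not in _CODE for c in set(s)):
                bad = sorted(set(s) - set(_CODE))
                raise ValueError(f"invalid sequence letters: {bad}")
        self._arr: Optional[np.ndarray] = None
        self._starts: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.seqs)

    def _pack(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._arr is None:
            starts = []
            codes = []
            offset = 0
            lut = np.full(256, _SEP, dtype=np.uint8)
            for c, v in _CODE.items():
                lut[ord(c)] = v
            for s in self.seqs:
                starts.append(offset)
                codes.append(lut[np.frombuffer(s.encode(), dtype=np.uint8)])
                codes.append(np.array([_SEP], dtype=np.uint8))
                offset += len(s) + 1
            self._arr = (
                np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint8)
            )
            self._starts = np.asarray(starts, dtype=np.int64)
        return self._arr, self._starts

    def match(self, classes: Sequence[FrozenSet[str]]) -> Tuple[np.ndarray, np.ndarray]:
        """All sites of the motif: (sequence indices, in-sequence offsets)."""
        arr, starts = self._pack()
        w = len(classes)
        if arr.size < w:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        accept = np.zeros((w, 6), dtype=bool)
        for j, cls in enumerate(classes):
            for letter in cls:
                accept[j, _CODE[letter]] = True
        m = arr.size - w + 1
        ok = accept[0][arr[:m]]
        for j in range(1, w):
            ok &= accept[j][arr[j : m + j]]
        idx = np.nonzero(ok)[0]
        seq_idx = np.searchsorted(starts, idx, side="right") - 1
        return seq_idx, idx - starts[seq_idx]

    def presence(self, classes: Sequence[FrozenSet[str]]) -> int:
        """Number of sequences containing at least one site."""
        seq_idx, _ = self.match(classes)
        return int(np.unique(seq_idx).size)

    def erase(self, classes: Sequence[FrozenSet[str]]) -> int:
        """Mask every site with N (in place); returns the number of sites."""
        seq_idx, offs = self.match(classes)
        w = len(classes)
        by_seq: Dict[int, List[int]] = {}
        for si, off in zip(seq_idx.tolist(), offs.tolist()):
            by_seq.setdefault(si, []).append(off)
        for si, positions in by_seq.items():
            chars = list(self.seqs[si])
            for p in positions:
                chars[p : p + w] = "N" * w
            self.seqs[si] = "".join(chars)
        self._arr = None
        self._starts = None
        return int(seq_idx.size)

    def word_presence(self, widths: Sequence[int]) -> Dict[bytes, int]:
        """Presence count per exact word (no N) for every requested width."""
        return {w: len(ids) for w, ids in self.word_seq_ids(widths).items()}

    def word_seq_ids(self, widths: Sequence[int]) -> Dict[bytes, List[int]]:
        """For each exact word (no N), the ids of sequences containing it.

        Any IUPAC motif is a union of exact words, so presence counts of
        class motifs reduce to unions of these id lists — the workhorse of
        the refinement loop.
        """
        ids: Dict[bytes, List[int]] = {}
        for si, s in enumerate(self.seqs):
            b = s.encode()
            seen = set()
            for w in widths:
                for i in range(len(b) - w + 1):
                    word = b[i : i + w]
                    if b"N" not in word:
                        seen.add(word)
            for word in seen:
                ids.setdefault(word, []).append(si)
        return ids


def match_sites(motif: str | Sequence[FrozenSet[str]], seq: str) -> List[int]:
    """All start positions of a motif in one sequence (overlaps included).

    N in the sequence satisfies no motif position; matching is on the given
    strand only.
    """
    classes = parse_iupac(motif) if isinstance(motif, str) else tuple(motif)
    seq = seq.upper()
    w = len(classes)
    out = []
    for i in range(len(seq) - w + 1):
        if all(seq[i + j] in cls for j, cls in enumerate(classes)):
            out.append(i)
    return out


def presence_counts(
    motif: str | Sequence[FrozenSet[str]], seqs: Sequence[str]
) -> Tuple[int, int]:
    """(number of sequences with >= 1 site, set size)."""
    classes = parse_iupac(motif) if isinstance(motif, str) else tuple(motif)
    if not seqs:
        return 0, 0
    ss = seqs if isinstance(seqs, SequenceSet) else SequenceSet(seqs)
    return ss.presence(classes), len(ss)


def fisher_p(pos_with: int, pos_total: int, ref_with: int, ref_total: int) -> float:
    """One-tailed Fisher exact p for enrichment in the positive set.

    The p-value is the upper hypergeometric tail of the 2x2 presence table:
    the probability of drawing at least ``pos_with`` motif-bearing sequences
    when ``pos_total`` sequences are sampled from the pooled collection.
    """
    for name, v in [
        ("pos_with", pos_with),
        ("pos_total", pos_total),
        ("ref_with", ref_with),
        ("ref_total", ref_total),
    ]:
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if pos_with > pos_total or ref_with > ref_total:
        raise ValueError("inconsistent 2x2 counts")
    M = pos_total + ref_total
    n_with = pos_with + ref_with
    return float(stats.hypergeom.sf(pos_with - 1, M, n_with, pos_total))


@dataclass
class DiscoveryRun:
    """Result of an iterative discriminative motif search."""

    motifs: List[Motif]
    candidates_scored: List[int]
    erasure_log: List[Dict[str, int]]
    widths: Tuple[int, ...]
    e_thresh: float
    n_pos: int
    n_ref: int


def _generalizations(cls: FrozenSet[str]) -> List[FrozenSet[str]]:
    """Strict supersets of a base class with 2 or 3 letters."""
    out = []
    for k in (2, 3):
        for combo in itertools.combinations(_BASES, k):
            sup = frozenset(combo)
            if cls < sup:
                out.append(sup)
    return out


def discover_motifs(
    pos: Sequence[str],
    ref: Sequence[str],
    widths: Iterable[int] = range(4, 9),
    e_thresh: float = 0.05,
    max_motifs: int = 50,
    top_q: int = 100,
    seed: Optional[int] = None,
    exclude_positives: bool = True,
) -> DiscoveryRun:
    """Iteratively report motifs enriched in ``pos`` versus ``ref``.

    Each iteration (1) scores every exact word of the requested widths
    present in the positives by the Fisher exact test on presence counts,
    (2) hill-climbs the ``top_q`` best words by generalizing one position at
    a time into 2-/3-letter IUPAC classes — a step is kept only when the
    p-value improvement survives a Bonferroni correction over the
    refinement round, since the climb adapts to the data — and (3) reports
    the best motif by E-value if it beats the threshold, erasing its sites
    from both sets before continuing.

    The E-value is the Fisher p times the size of the search space that
    could have produced the motif: the number of enumerated words, times
    (6 x width) for every accepted generalization step (and never less
    than the number of candidates actually evaluated).  Without the
    depth-dependent factor the adaptive climb is anti-conservative on null
    data: it navigates toward accidentally extreme presence tables that a
    correction over only the evaluated candidates does not cover.

    Deterministic: ties on p are broken lexicographically on the rendered
    word; ``seed`` is accepted for interface symmetry but the procedure
    involves no random draws.
    """
    widths = tuple(sorted(set(int(w) for w in widths)))
    if not widths or min(widths) < 3 or max(widths) > 8:
        raise ValueError(f"widths must lie in 3..8: {widths}")
    if not pos or not ref:
        raise ValueError("both sequence sets must be non-empty")
    if exclude_positives:
        pos_set = set(s.upper() for s in pos)
        ref = [s for s in ref if s.upper() not in pos_set]
        if not ref:
            raise ValueError("reference empty after removing positive sequences")
    pos_ss = SequenceSet(pos)
    ref_ss = SequenceSet(ref)
    n_pos, n_ref = len(pos_ss), len(ref_ss)

    motifs: List[Motif] = []
    scored_per_iter: List[int] = []
    erasure_log: List[Dict[str, int]] = []

    for iteration in range(1, max_motifs + 1):
        pos_ids = pos_ss.word_seq_ids(widths)
        ref_ids = ref_ss.word_seq_ids(widths)
        words = sorted(pos_ids)  # lexicographic for deterministic ties
        if not words:
            break
        k = np.array([len(pos_ids[w]) for w in words], dtype=np.int64)
        r = np.array([len(ref_ids.get(w, ())) for w in words], dtype=np.int64)
        pvals = stats.hypergeom.sf(k - 1, n_pos + n_ref, k + r, n_pos)
        n_scored = len(words)

        order = np.lexsort((np.arange(len(words)), pvals))[:top_q]
        cache: Dict[str, float] = {
            words[i].decode(): float(pvals[i]) for i in range(len(words))
        }

        def class_presence(
            classes: Tuple[FrozenSet[str], ...], ids: Dict[bytes, List[int]]
        ) -> int:
            # a class motif matches exactly where one of its exact words does
            seen: set = set()
            for combo in itertools.product(*(sorted(c) for c in classes)):
                seen.update(ids.get("".join(combo).encode(), ()))
            return len(seen)

        def evaluate(classes: Tuple[FrozenSet[str], ...]) -> float:
            nonlocal n_scored
            key = render_iupac(classes)
            if key in cache:
                return cache[key]
            p = fisher_p(
                class_presence(classes, pos_ids),
                n_pos,
                class_presence(classes, ref_ids),
                n_ref,
            )
            cache[key] = p
            n_scored += 1
            return p

        n_words_iter = len(words)

        def e_value_at(p: float, width: int, depth: int) -> float:
            # Bonferroni over the implicit search space: all enumerated
            # words, times the (6w) single-position generalizations per
            # accepted climbing step.  Never below the count of candidates
            # actually evaluated, so E >= p always holds.
            implicit = float(n_words_iter) * float(6 * width) ** depth
            return p * max(implicit, float(n_scored))

        best_e = np.inf
        best_p = np.inf
        best_classes: Optional[Tuple[FrozenSet[str], ...]] = None

        def consider(classes: Tuple[FrozenSet[str], ...], p: float, depth: int) -> None:
            nonlocal best_e, best_p, best_classes
            e = e_value_at(p, len(classes), depth)
            if e < best_e or (
                e == best_e
                and best_classes is not None
                and render_iupac(classes) < render_iupac(best_classes)
            ):
                best_e, best_p, best_classes = e, p, classes

        for i in order:
            classes = tuple(frozenset(chr(c)) for c in words[i])
            cur_p = float(pvals[i])
            depth = 0
            consider(classes, cur_p, depth)
            improved = True
            while improved:
                improved = False
                step_best_p, step_best = cur_p, None
                n_tried = 0
                for j, cls in enumerate(classes):
                    for sup in _generalizations(cls):
                        cand = classes[:j] + (sup,) + classes[j + 1 :]
                        p = evaluate(cand)
                        n_tried += 1
                        if p < step_best_p or (
                            step_best is not None
                            and p == step_best_p
                            and render_iupac(cand) < render_iupac(step_best)
                        ):
                            step_best_p, step_best = p, cand
                # selection-aware acceptance: a step is taken by the best of
                # n_tried candidates, and such steps are attempted for every
                # seed word, so the improvement must survive a Bonferroni
                # over the whole refinement round — otherwise hill-climbing
                # on noise manufactures significance out of nothing
                round_size = max(n_tried, 1) * max(len(order), 1)
                if step_best is not None and step_best_p * round_size < cur_p:
                    classes, cur_p = step_best, step_best_p
                    depth += 1
                    consider(classes, cur_p, depth)
                    improved = True

        scored_per_iter.append(n_scored)
        if best_classes is None:
            break
        e_value = best_e
        if e_value >= e_thresh:
            break
        word = render_iupac(best_classes)
        motifs.append(
            Motif(
                word=word,
                pos_with=pos_ss.presence(best_classes),
                pos_total=n_pos,
                ref_with=ref_ss.presence(best_classes),
                ref_total=n_ref,
                p=best_p,
                e=e_value,
                iteration=iteration,
            )
        )
        erased_pos = pos_ss.erase(best_classes)
        erased_ref = ref_ss.erase(best_classes)
        erasure_log.append(
            {"iteration": iteration, "pos_sites": erased_pos, "ref_sites": erased_ref}
        )

    return DiscoveryRun(
        motifs=motifs,
        candidates_scored=scored_per_iter,
        erasure_log=erasure_log,
        widths=widths,
        e_thresh=e_thresh,
        n_pos=n_pos,
        n_ref=n_ref,
    )


def scan_counts(
    motifs_5p: Sequence[str | Motif],
    motifs_3p: Sequence[str | Motif],
    utr5: str,
    utr3: str,
) -> int:
    """Total site count of 5' motifs in the 5'UTR plus 3' motifs in the 3'UTR.

    Site-level: overlapping sites all count, unlike the sequence-level
    presence statistic used for discovery.
    """

    def word(m: str | Motif) -> str:
        return m.word if isinstance(m, Motif) else m

    total = 0
    for m in motifs_5p:
        total += len(match_sites(word(m), utr5))
    for m in motifs_3p:
        total += len(match_sites(word(m), utr3))
    return total
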