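"""Constraint-adhering codeword sets and their concatenation rules.

A *codebook* is a set ``C`` of DNA words of uniform length ``n`` that all
satisfy sequence constraints imposed by synthesis and sequencing chemistry:
bounded GC content evaluated over fixed, non-overlapping intervals, a cap on
homopolymer run length, and the absence of undesired motifs.  Restricting the
admissible sequence space costs information capacity; the price in bits per
base is

    redundancy = 2 - log2(|C|) / n

which is zero for the unconstrained codebook (|C| = 4^n) and 2 for a single
codeword.

Because constraints can also be violated *between* two individually valid
codewords (a homopolymer or motif forming across the junction), a codebook is
accompanied by a *concatenation scheme*: a mapping from codeword suffixes to
the sets of codeword prefixes that must not follow them.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio import SeqIO

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: exhaustive enumeration guard for generate_codebook
MAX_ENUM_LENGTH = 16

_ENUM_CHUNK = 1 << 20


class CodebookError(ValueError):
    """Raised for invalid codebooks, schemes, or unsatisfiable constraints."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_word(word: str) -> int:
    """Map a DNA string to its base-4 integer code (A=0, C=1, G=2, T=3)."""
    code = 0
    for ch in word:
        code = (code << 2) | BASE_INDEX[ch]
    return code


def decode_word(code: int, length: int) -> str:
    out = []
    for shift in range(2 * (length - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def _check_dna(s: str, what: str) -> str:
    s = s.upper()
    if not s or any(ch not in BASE_INDEX for ch in s):
        raise CodebookError(f"{what} must be a nonempty string over ACGT, got {s!r}")
    return s


@dataclass(frozen=True)
class ConstraintSpec:
    """User-facing sequence constraints.

    GC bounds are fractions applied to every *complete* ``gc_interval``-wide
    window, anchored at position 0 (consecutive, non-overlapping windows; a
    trailing partial window is exempt).  ``hp_max`` caps homopolymer run
    length; ``None`` disables the cap.  ``forbidden_motifs`` are screened
    case-insensitively on the forward strand; set ``revcomp_motifs`` to also
    screen their reverse complements.
    """

    gc_min: float = 0.0
    gc_max: float = 1.0
    gc_interval: int = 1
    hp_max: int | None = None
    forbidden_motifs: tuple[str, ...] = ()
    revcomp_motifs: bool = False

    def __post_init__(self):
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise CodebookError("need 0 <= gc_min <= gc_max <= 1")
        if self.gc_interval < 1:
            raise CodebookError("gc_interval must be >= 1")
        if self.hp_max is not None and self.hp_max < 1:
            raise CodebookError("hp_max must be >= 1")
        motifs = tuple(_check_dna(m, "forbidden motif") for m in self.forbidden_motifs)
        object.__setattr__(self, "forbidden_motifs", motifs)

    @property
    def effective_motifs(self) -> tuple[str, ...]:
        motifs = list(self.forbidden_motifs)
        if self.revcomp_motifs:
            for m in self.forbidden_motifs:
                rc = reverse_complement(m)
                if rc not in motifs:
                    motifs.append(rc)
        return tuple(motifs)

    def gc_constrained(self) -> bool:
        return self.gc_min > 0.0 or self.gc_max < 1.0


@dataclass(frozen=True)
class Violation:
    kind: str       # "homopolymer" | "gc" | "motif"
    position: int   # 0-based start of the offending run/window/occurrence
    detail: str


@dataclass(frozen=True)
class ValidationResult:
    passed: bool
    violations: tuple[Violation, ...]

    def __bool__(self) -> bool:
        return self.passed


class Codebook:
    """An immutable set of uniform-length DNA codewords."""

    def __init__(self, words):
        words = [_check_dna(w, "codeword") for w in words]
        if not words:
            raise CodebookError("codebook is empty")
        n = len(words[0])
        for w in words:
            if len(w) != n:
                raise CodebookError(
                    f"mixed codeword lengths: {w!r} has length {len(w)}, expected {n}"
                )
        if len(set(words)) != len(words):
            dup = next(w for w in words if words.count(w) > 1)
            raise CodebookError(f"duplicate codeword {dup!r}")
        self._words = tuple(sorted(words))
        self._word_length = n
        self._codes = np.array([encode_word(w) for w in self._words], dtype=np.uint64)

    @property
    def words(self) -> tuple[str, ...]:
        return self._words

    @property
    def word_length(self) -> int:
        return self._word_length

    @property
    def codes(self) -> np.ndarray:
        """Sorted base-4 integer codes of all words (uint64)."""
        return self._codes

    def __len__(self) -> int:
        return len(self._words)

    def __contains__(self, word: str) -> bool:
        return word.upper() in set(self._words)

    def __iter__(self):
        return iter(self._words)

    def __repr__(self) -> str:
        return f"Codebook(|C|={len(self)}, n={self._word_length})"

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, w in enumerate(self._words):
                fh.write(f">cw{i}\n{w}\n")


class ConcatenationScheme:
    """Forbidden codeword suffix -> prefix pairs.

    A junction is forbidden when the already-emitted sequence ends with a key
    and the next codeword starts with one of the key's values.  Keys are
    matched against the rolling suffix of the whole emitted stream, so rules
    longer than a single codeword (e.g. a homopolymer accumulating over
    several short words) still apply.
    """

    def __init__(self, forbidden: dict | None = None):
        norm: dict[str, frozenset[str]] = {}
        for key, vals in (forbidden or {}).items():
            key = _check_dna(key, "scheme suffix")
            if isinstance(vals, str):
                vals = [vals]
            norm[key] = frozenset(_check_dna(v, "scheme prefix") for v in vals)
        self._forbidden = norm
        self._max_suffix = max((len(k) for k in norm), default=0)

    @property
    def forbidden_pairs(self) -> dict[str, frozenset[str]]:
        return dict(self._forbidden)

    @property
    def max_suffix_length(self) -> int:
        return self._max_suffix

    def __len__(self) -> int:
        return len(self._forbidden)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ConcatenationScheme)
            and self._forbidden == other._forbidden
        )

    def forbidden_after(self, context: str) -> tuple[str, ...]:
        """Minimal set of forbidden next-word prefixes given the emitted suffix.

        Returns prefixes sorted by (length, lexicographic); no returned prefix
        is an extension of another (the shorter rule subsumes it).
        """
        hits: set[str] = set()
        for key, prefixes in self._forbidden.items():
            if context.endswith(key):
                hits |= prefixes
        minimal = []
        for p in sorted(hits, key=lambda s: (len(s), s)):
            if not any(p.startswith(q) for q in minimal):
                minimal.append(p)
        return tuple(minimal)

    def allows(self, left: str, right: str) -> bool:
        """Whether codeword/stream ``left`` may be followed by word ``right``."""
        return not any(right.startswith(p) for p in self.forbidden_after(left))

    def to_json(self) -> str:
        return json.dumps(
            {k: sorted(v) for k, v in sorted(self._forbidden.items())}, indent=0
        )


def load_codebook(path) -> Codebook:
    """Read a codebook from FASTA, one codeword per record.

    Headers are ignored and record order is not semantic.  Mixed lengths,
    non-ACGT symbols, duplicates, or an empty file are fatal.
    """
    words = []
    first_len = None
    for rec in SeqIO.parse(str(path), "fasta"):
        w = str(rec.seq).upper()
        if any(ch not in BASE_INDEX for ch in w) or not w:
            raise CodebookError(f"record {rec.id!r}: non-ACGT symbol in {w!r}")
        if first_len is None:
            first_len = len(w)
        elif len(w) != first_len:
            raise CodebookError(
                f"mixed codeword lengths: record {rec.id!r} has length "
                f"{len(w)}, expected {first_len}"
            )
        if w in set(words):
            raise CodebookError(f"record {rec.id!r}: duplicate codeword {w!r}")
        words.append(w)
    if not words:
        raise CodebookError(f"no codewords found in {path}")
    return Codebook(words)


def load_concatenation_scheme(path) -> ConcatenationScheme:
    """Read a concatenation scheme from JSON ({suffix: [prefix, ...]}).

    An empty document means unrestricted concatenation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise CodebookError("concatenation scheme must be a JSON object")
    return ConcatenationScheme(doc)


def redundancy(codebook: Codebook) -> float:
    """Bits per base spent on constraint adherence: 2 - log2(|C|)/n."""
    return 2.0 - math.log2(len(codebook)) / codebook.word_length


def validate_sequence(seq: str, spec: ConstraintSpec) -> ValidationResult:
    """Check a DNA string against a constraint spec, reporting every violation.

    Homopolymer runs longer than ``hp_max``, complete GC windows outside
    [gc_min, gc_max], and every motif occurrence (overlaps included) are
    reported with 0-based positions.  The empty string passes vacuously.
    """
    seq = seq.upper()
    if any(ch not in BASE_INDEX for ch in seq):
        raise CodebookError(f"sequence contains non-ACGT symbols: {seq!r}")
    violations: list[Violation] = []

    if spec.hp_max is not None:
        pos = 0
        for base, group in itertools.groupby(seq):
            run = len(list(group))
            if run > spec.hp_max:
                violations.append(
                    Violation("homopolymer", pos, f"run of {run} {base} > {spec.hp_max}")
                )
            pos += run

    if spec.gc_constrained():
        g = spec.gc_interval
        for start in range(0, len(seq) - g + 1, g):
            window = seq[start : start + g]
            frac = sum(ch in "GC" for ch in window) / g
            if not (spec.gc_min - 1e-9 <= frac <= spec.gc_max + 1e-9):
                violations.append(
                    Violation("gc", start, f"GC {frac:.3f} outside "
                              f"[{spec.gc_min}, {spec.gc_max}] in {g} nt window")
                )

    for motif in spec.effective_motifs:
        start = seq.find(motif)
        while start != -1:
            violations.append(Violation("motif", start, f"occurrence of {motif}"))
            start = seq.find(motif, start + 1)

    violations.sort(key=lambda v: (v.position, v.kind))
    return ValidationResult(not violations, tuple(violations))


def _enumerate_codes(spec: ConstraintSpec, n: int) -> np.ndarray:
    """All base-4 codes of length-n words satisfying ``spec``, sorted."""
    motifs = spec.effective_motifs
    motif_digits = [np.array([BASE_INDEX[c] for c in m], dtype=np.uint8)
                    for m in motifs if len(m) <= n]
    g = spec.gc_interval
    gc_active = spec.gc_constrained() and g <= n
    if gc_active:
        lo_cnt = math.ceil(spec.gc_min * g - 1e-9)
        hi_cnt = math.floor(spec.gc_max * g + 1e-9)
    kept = []
    total = 4 ** n
    for lo in range(0, total, _ENUM_CHUNK):
        codes = np.arange(lo, min(lo + _ENUM_CHUNK, total), dtype=np.uint64)
        digits = np.empty((len(codes), n), dtype=np.uint8)
        for j in range(n):
            digits[:, j] = (codes >> np.uint64(2 * (n - 1 - j))) & np.uint64(3)
        mask = np.ones(len(codes), dtype=bool)
        if gc_active:
            is_gc = (digits == 1) | (digits == 2)
            for start in range(0, n - g + 1, g):
                cnt = is_gc[:, start : start + g].sum(axis=1)
                mask &= (cnt >= lo_cnt) & (cnt <= hi_cnt)
        if spec.hp_max is not None and spec.hp_max < n:
            eq = digits[:, 1:] == digits[:, :-1]
            windows = sliding_window_view(eq, spec.hp_max, axis=1)
            mask &= ~windows.all(axis=2).any(axis=1)
        for md in motif_digits:
            L = len(md)
            for off in range(n - L + 1):
                mask &= ~(digits[:, off : off + L] == md).all(axis=1)
        kept.append(codes[mask])
    return np.concatenate(kept)


def _junction_scheme(spec: ConstraintSpec, n: int) -> ConcatenationScheme:
    """Suffix->prefix pairs whose junction would breach hp_max or a motif.

    Homopolymer rule: a run of hp_max+1 identical bases split as a+b across
    the boundary yields the pair (x^a -> x^b) for every split with b <= n
    (splits needing a longer next-word prefix are caught one junction later,
    once the run has accumulated into the rolling suffix).  Motif rules come
    from every boundary-spanning split of each motif.
    """
    pairs: dict[str, set[str]] = {}

    def add(suffix: str, prefix: str) -> None:
        pairs.setdefault(suffix, set()).add(prefix)

    if spec.hp_max is not None:
        for x in BASES:
            for a in range(1, spec.hp_max + 1):
                b = spec.hp_max + 1 - a
                if 1 <= b <= n:
                    add(x * a, x * b)
    for m in spec.effective_motifs:
        for i in range(1, len(m)):
            if len(m) - i <= n:
                add(m[:i], m[i:])
    return ConcatenationScheme({k: sorted(v) for k, v in pairs.items()})


def generate_codebook(spec: ConstraintSpec, n: int) -> tuple[Codebook, ConcatenationScheme]:
    """Enumerate all length-``n`` words satisfying ``spec`` plus the junction scheme.

    Exhaustive over the 4^n sequence space (guarded at n <= 16).  GC bounds
    are evaluated over each complete ``gc_interval`` window inside the word;
    motifs must be no longer than ``n``.
    """
    if not (1 <= n <= MAX_ENUM_LENGTH):
        raise CodebookError(f"codeword length must be in [1, {MAX_ENUM_LENGTH}], got {n}")
    for m in spec.effective_motifs:
        if len(m) > n:
            raise CodebookError(
                f"forbidden motif {m!r} is longer than the codeword length {n}"
            )
    codes = _enumerate_codes(spec, n)
    if len(codes) == 0:
        raise CodebookError(f"constraints unsatisfiable at length {n}")
    words = [decode_word(int(c), n) for c in codes]
    return Codebook(words), _junction_scheme(spec, n)
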