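"""Constrained random generation of stimuli and trial plans.

Every generator is a pure function of its parameters and a seeded
:class:`numpy.random.Generator`: identical seeds give identical outputs.
Grid coordinates are 0-based ``(row, col)``, row-major.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from openwmb.errors import ConfigurationError, PoolValidationError

#: The 11 lowercase consonants used as memoranda across the verbal tasks
#: (monosyllabic in Portuguese). Fixed order for reproducibility.
LETTER_ALPHABET: tuple[str, ...] = ("b", "c", "d", "f", "g", "p", "q", "t", "v", "x", "z")

#: Colors of the binding-task palette.
BINDING_PALETTE: tuple[str, ...] = ("red", "yellow", "blue", "green")

#: 5x4 binding grid: 4 rows x 5 columns. The four colored letters occupy a
#: central display region covering three cells, leaving 17 cells eligible
#: for the colored crosses.
BINDING_GRID_SHAPE: tuple[int, int] = (4, 5)
DEFAULT_BINDING_LETTER_CELLS: tuple[tuple[int, int], ...] = ((1, 2), (2, 2), (1, 1))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Letters (reading / operation span memoranda)
# ---------------------------------------------------------------------------

def sample_letter_sequence(k: int, rng) -> tuple[str, ...]:
    """Draw ``k`` distinct letters from the 11-consonant alphabet.

    Within a block of complex-span trials each letter appears at most once,
    so ``k`` may not exceed the alphabet size.
    """
    if not 1 <= k <= len(LETTER_ALPHABET):
        raise ConfigurationError(
            f"k={k} outside the capacity of the {len(LETTER_ALPHABET)}-letter alphabet"
        )
    rng = _as_rng(rng)
    idx = rng.choice(len(LETTER_ALPHABET), size=k, replace=False)
    return tuple(LETTER_ALPHABET[i] for i in idx)


# ---------------------------------------------------------------------------
# Operation-span equations
# ---------------------------------------------------------------------------

#: type_code -> (op1, op2, is_correct); op1 in {"*", "/"}, op2 in {"+", "-"}.
EQUATION_TYPES: dict[int, tuple[str, str, bool]] = {
    1: ("*", "+", True),
    2: ("*", "+", False),
    3: ("*", "-", True),
    4: ("*", "-", False),
    5: ("/", "+", True),
    6: ("/", "+", False),
    7: ("/", "-", True),
    8: ("/", "-", False),
}


@dataclass(frozen=True)
class Equation:
    """A two-term arithmetic verification item, e.g. ``(5 * 2) + 4 = 14``.

    The first term is a multiplication or an integer division of operands in
    1..9 with a result in 1..20; the second term adds or subtracts an integer
    in 1..9, again landing in 1..20. Incorrect proposed results differ from
    the true result by at most 2 (and stay >= 1).
    """

    a: int
    b: int
    op1: str
    first_result: int
    c: int
    op2: str
    correct_result: int
    proposed_result: int
    is_correct: bool
    type_code: int

    def text(self) -> str:
        return f"({self.a} {self.op1} {self.b}) {self.op2} {self.c} = {self.proposed_result}"


def enumerate_equation_operands(op1: str, op2: str) -> list[tuple[int, int, int]]:
    """All admissible ``(a, b, c)`` for the given operator pair.

    Both intermediate and final results must be integers in [1, 20];
    division requires ``a`` divisible by ``b``.
    """
    out = []
    for a in range(1, 10):
        for b in range(1, 10):
            if op1 == "*":
                first = a * b
            else:
                if a % b != 0:
                    continue
                first = a // b
            if not 1 <= first <= 20:
                continue
            for c in range(1, 10):
                second = first + c if op2 == "+" else first - c
                if 1 <= second <= 20:
                    out.append((a, b, c))
    return out


_EQUATION_SETS = {
    (op1, op2): enumerate_equation_operands(op1, op2)
    for op1 in ("*", "/")
    for op2 in ("+", "-")
}


def make_equation(type_code: int, rng) -> Equation:
    """Sample an equation uniformly from the admissible set of its type."""
    if type_code not in EQUATION_TYPES:
        raise ConfigurationError(f"unknown equation type_code {type_code}")
    rng = _as_rng(rng)
    op1, op2, is_correct = EQUATION_TYPES[type_code]
    pool = _EQUATION_SETS[(op1, op2)]
    a, b, c = pool[rng.integers(len(pool))]
    first = a * b if op1 == "*" else a // b
    correct = first + c if op2 == "+" else first - c
    if is_correct:
        proposed = correct
    else:
        # Uniform offset in {-2, -1, +1, +2}; redrawn if the lure would
        # fall below 1.
        while True:
            proposed = correct + int(rng.choice([-2, -1, 1, 2]))
            if proposed >= 1:
                break
    return Equation(a, b, op1, first, c, op2, correct, proposed, is_correct, type_code)


# ---------------------------------------------------------------------------
# Symmetry-span matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetryMatrix:
    """An 8x8 black/white grid, mirror-symmetric about the vertical axis or
    differing in exactly one mirrored pair of cells."""

    cells: tuple[tuple[int, ...], ...]
    is_symmetric: bool
    mismatch_cell: Optional[tuple[int, int]] = None

    def as_array(self) -> np.ndarray:
        return np.array(self.cells, dtype=int)


def make_symmetry_matrix(
    symmetric: bool, rng, black_range: tuple[int, int] = (20, 28)
) -> SymmetryMatrix:
    """Build an 8x8 symmetry-judgment matrix.

    Symmetric matrices mirror a random left half. Asymmetric matrices flip
    one cell of the right half so exactly one of the 32 mirrored pairs
    differs; the total black count stays within ``black_range``.
    """
    rng = _as_rng(rng)
    lo, hi = black_range
    while True:
        n_half = int(rng.integers((lo + 1) // 2, hi // 2 + 1))
        half = np.zeros(32, dtype=int)
        half[rng.choice(32, size=n_half, replace=False)] = 1
        left = half.reshape(8, 4)
        grid = np.concatenate([left, left[:, ::-1]], axis=1)
        mismatch = None
        if not symmetric:
            r = int(rng.integers(8))
            c = int(rng.integers(4, 8))
            grid[r, c] ^= 1
            mismatch = (r, c)
        if lo <= int(grid.sum()) <= hi:
            return SymmetryMatrix(
                tuple(tuple(int(v) for v in row) for row in grid), symmetric, mismatch
            )


# ---------------------------------------------------------------------------
# N-back sequences
# ---------------------------------------------------------------------------

NBACK_GRID_SHAPE: tuple[int, int] = (3, 3)


@dataclass(frozen=True)
class NBackItem:
    letter: str
    cell: tuple[int, int]
    is_target: bool
    scored: bool


def make_nback_sequence(n_total: int, target_ratio: float, rng) -> list[NBackItem]:
    """Generate a 2-back letter-in-grid sequence.

    The first two items are unscored lead-ins. Exactly
    ``target_ratio * (n_total - 2)`` scored items repeat both the letter and
    the cell of the item two positions back; every non-target genuinely
    mismatches its 2-back item in letter and/or cell. Lure frequency
    (letter-only or cell-only repeats) is not controlled.
    """
    if n_total < 3:
        raise ConfigurationError("n_total must be at least 3")
    n_scored = n_total - 2
    n_targets_f = target_ratio * n_scored
    n_targets = round(n_targets_f)
    if abs(n_targets_f - n_targets) > 1e-9:
        raise ConfigurationError(
            f"target_ratio {target_ratio} infeasible for {n_scored} scored items"
        )
    rng = _as_rng(rng)
    target_positions = {
        2 + int(i) for i in rng.choice(n_scored, size=n_targets, replace=False)
    }
    n_cells = NBACK_GRID_SHAPE[0] * NBACK_GRID_SHAPE[1]
    items: list[NBackItem] = []
    for i in range(n_total):
        if i in target_positions:
            back = items[i - 2]
            items.append(NBackItem(back.letter, back.cell, True, True))
            continue
        while True:
            letter = LETTER_ALPHABET[rng.integers(len(LETTER_ALPHABET))]
            flat = int(rng.integers(n_cells))
            cell = (flat // NBACK_GRID_SHAPE[1], flat % NBACK_GRID_SHAPE[1])
            if i < 2 or (letter, cell) != (items[i - 2].letter, items[i - 2].cell):
                break
        items.append(NBackItem(letter, cell, False, i >= 2))
    return items


# ---------------------------------------------------------------------------
# Memory-updating trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpdatingOperation:
    frame_index: int  # 0..2
    delta: int  # [-8, +8] \ {0}


@dataclass(frozen=True)
class UpdatingTrialSpec:
    """Three digits updated by six signed operations (two per frame, never
    two consecutive on the same frame, three sums and three subtractions),
    with every intermediate and final value in [1, 9]."""

    initial_digits: tuple[int, int, int]
    operations: tuple[UpdatingOperation, ...]
    final_digits: tuple[int, int, int]

    def replay(self) -> tuple[int, int, int]:
        """Re-apply the operations to the initial digits."""
        state = list(self.initial_digits)
        for op in self.operations:
            state[op.frame_index] += op.delta
        return tuple(state)


def make_updating_trial(rng) -> UpdatingTrialSpec:
    """Constructive-rejection sampling of an updating trial."""
    rng = _as_rng(rng)
    while True:
        # Frame order: each of the 3 frames exactly twice, no immediate repeat.
        frames = [0, 0, 1, 1, 2, 2]
        for _ in range(100):
            rng.shuffle(frames)
            if all(frames[i] != frames[i + 1] for i in range(5)):
                break
        else:  # pragma: no cover - vanishingly unlikely
            continue
        signs = [1, 1, 1, -1, -1, -1]
        rng.shuffle(signs)
        initial = tuple(int(v) for v in rng.integers(1, 10, size=3))
        state = list(initial)
        ops: list[UpdatingOperation] = []
        ok = True
        for f, s in zip(frames, signs):
            if s > 0:
                choices = [d for d in range(1, 9) if 1 <= state[f] + d <= 9]
            else:
                choices = [-d for d in range(1, 9) if 1 <= state[f] - d <= 9]
            if not choices:
                ok = False
                break
            delta = int(choices[rng.integers(len(choices))])
            state[f] += delta
            ops.append(UpdatingOperation(f, delta))
        if ok:
            return UpdatingTrialSpec(initial, tuple(ops), tuple(state))


# ---------------------------------------------------------------------------
# Binding-and-maintenance trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingTrialSpec:
    """Four colored letters bound to four same-colored cross locations, a
    retention interval of 1000 or 8000 ms, and a lowercase probe letter shown
    in a cell that does or does not match the probed binding."""

    letter_colors: tuple[tuple[str, str], ...]
    cross_cells: tuple[tuple[tuple[int, int], str], ...]
    probe_letter: str
    probe_cell: tuple[int, int]
    delay_ms: int
    is_match: bool


def binding_eligible_cells(
    letter_cells: Sequence[tuple[int, int]] = DEFAULT_BINDING_LETTER_CELLS,
) -> list[tuple[int, int]]:
    """Cells of the 5x4 grid outside the central letter-display region."""
    blocked = set(letter_cells)
    rows, cols = BINDING_GRID_SHAPE
    return [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in blocked]


def make_binding_trial(
    is_match: bool,
    delay_ms: int,
    rng,
    letter_cells: Sequence[tuple[int, int]] = DEFAULT_BINDING_LETTER_CELLS,
) -> BindingTrialSpec:
    if delay_ms not in (1000, 8000):
        raise ConfigurationError("delay_ms must be 1000 or 8000")
    rng = _as_rng(rng)
    eligible = binding_eligible_cells(letter_cells)
    letters = sample_letter_sequence(4, rng)
    colors = list(BINDING_PALETTE)
    rng.shuffle(colors)
    letter_colors = tuple((lt.upper(), col) for lt, col in zip(letters, colors))
    cross_colors = list(BINDING_PALETTE)
    rng.shuffle(cross_colors)
    cell_idx = rng.choice(len(eligible), size=4, replace=False)
    cross_cells = tuple(
        (eligible[i], col) for i, col in zip(cell_idx, cross_colors)
    )
    probe_upper, probe_color = letter_colors[rng.integers(4)]
    matched_cell = next(cell for cell, col in cross_cells if col == probe_color)
    if is_match:
        probe_cell = matched_cell
    else:
        others = [cell for cell in eligible if cell != matched_cell]
        probe_cell = others[rng.integers(len(others))]
    return BindingTrialSpec(
        letter_colors, cross_cells, probe_upper.lower(), probe_cell, delay_ms, is_match
    )


def make_binding_block(n_trials: int, rng) -> list[BindingTrialSpec]:
    """A block with equal numbers of the four (match x delay) conditions,
    in shuffled order."""
    if n_trials % 4 != 0:
        raise ConfigurationError("binding block size must be a multiple of 4")
    rng = _as_rng(rng)
    conditions = [(m, d) for m in (True, False) for d in (1000, 8000)]
    plan = conditions * (n_trials // 4)
    rng.shuffle(plan)
    return [make_binding_trial(m, d, rng) for m, d in plan]


# ---------------------------------------------------------------------------
# Multimodal-span sequences
# ---------------------------------------------------------------------------

MULTIMODAL_GRID_SHAPE: tuple[int, int] = (4, 4)


@dataclass(frozen=True)
class MultimodalSequence:
    """An ordered sequence of (letter, cell) pairs on a 4x4 grid; letters and
    cells are each distinct within the sequence."""

    items: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def length(self) -> int:
        return len(self.items)


def make_multimodal_sequence(length: int, rng) -> MultimodalSequence:
    if not 3 <= length <= 11:
        raise ConfigurationError("multimodal sequence length must be in 3..11")
    rng = _as_rng(rng)
    letters = sample_letter_sequence(length, rng)
    n_cells = MULTIMODAL_GRID_SHAPE[0] * MULTIMODAL_GRID_SHAPE[1]
    flat = rng.choice(n_cells, size=length, replace=False)
    cells = [(int(f) // MULTIMODAL_GRID_SHAPE[1], int(f) % MULTIMODAL_GRID_SHAPE[1]) for f in flat]
    return MultimodalSequence(tuple(zip(letters, cells)))


# ---------------------------------------------------------------------------
# Sentence pool (reading span)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SentenceItem:
    """A reading-span sentence: 11 or 12 words, 45-57 characters, with a
    flag marking syntactically correct items."""

    text: str
    is_correct: bool
    word_count: int = field(default=0)
    char_count: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "word_count", len(self.text.split()))
        object.__setattr__(self, "char_count", len(self.text))

    def violations(self) -> list[str]:
        out = []
        if self.word_count not in (11, 12):
            out.append(f"word_count={self.word_count} not in {{11, 12}}")
        if not 45 <= self.char_count <= 57:
            out.append(f"char_count={self.char_count} not in [45, 57]")
        return out


def load_sentence_pool(path) -> list[SentenceItem]:
    """Load a tab-delimited sentence pool with columns ``text`` and
    ``is_correct`` (0/1). Raises :class:`PoolValidationError` naming the
    first malformed line or listing constraint-violating sentences."""
    path = Path(path)
    items: list[SentenceItem] = []
    bad: list[str] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["text", "is_correct"]:
            raise PoolValidationError(
                f"{path}: expected header 'text<TAB>is_correct', got {header!r}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise PoolValidationError(
                    f"{path}:{lineno}: malformed row {line!r}", line=lineno
                )
            item = SentenceItem(parts[0], parts[1] == "1")
            problems = item.violations()
            if problems:
                bad.append(f"line {lineno}: {item.text!r}: {'; '.join(problems)}")
            items.append(item)
    if bad:
        raise PoolValidationError(
            f"{path}: {len(bad)} sentences violate constraints:\n" + "\n".join(bad),
            offending=bad,
        )
    return items


def pool_balance(items: Iterable[SentenceItem]) -> tuple[int, int]:
    """(number of syntactically correct, number of incorrect) sentences."""
    items = list(items)
    n_correct = sum(it.is_correct for it in items)
    return n_correct, len(items) - n_correct


# -- placeholder pool generation -------------------------------------------

_SUBJECTS = [
    "the young girl", "the old man", "the tall boy", "the kind nurse",
    "the wise tutor", "the calm pilot", "the shy clerk", "the bold cook",
]
_VERBS_OK = ["reads", "holds", "keeps", "finds", "takes", "moves", "draws", "sells"]
_VERBS_BAD = ["read", "hold", "keep", "find", "take", "move", "draw", "sell"]
_OBJECTS = [
    "a small book", "a worn map", "a blue cup", "a thin rope",
    "an old coin", "a torn note", "a red ball", "a long list",
]
_TAILS = [
    "near the quiet park",
    "under the pale moon",
    "along the steep road",
    "inside the dim hall",
    "by the old stone wall",
    "after the long noisy trip",
    "behind the tall iron gate",
]


def generate_placeholder_pool(n: int, rng) -> list[SentenceItem]:
    """Template-generated stand-in pool for the reading span.

    Synthetic: real reading-span corpora are licensed and not reproducible
    from printed sources. Sentences are assembled from word banks under the
    11/12-word and 45-57-character constraints; half carry a planted
    subject-verb agreement error and are flagged incorrect.
    """
    if n % 2 != 0:
        raise ConfigurationError("pool size must be even for a 50/50 split")
    rng = _as_rng(rng)
    items: list[SentenceItem] = []
    seen = set()
    while len(items) < n:
        correct = len(items) % 2 == 0
        subj = _SUBJECTS[rng.integers(len(_SUBJECTS))]
        verb = (_VERBS_OK if correct else _VERBS_BAD)[rng.integers(len(_VERBS_OK))]
        obj = _OBJECTS[rng.integers(len(_OBJECTS))]
        tail = _TAILS[rng.integers(len(_TAILS))]
        text = f"{subj} {verb} {obj} {tail}"
        item = SentenceItem(text, correct)
        if item.violations() or text in seen:
            continue
        seen.add(text)
        items.append(item)
    return items


def write_sentence_pool(items: Iterable[SentenceItem], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("text\tis_correct\n")
        for it in items:
            fh.write(f"{it.text}\t{int(it.is_correct)}\n")


def default_sentence_pool() -> list[SentenceItem]:
    """The placeholder pool shipped with the package (120 sentences)."""
    path = Path(__file__).parent / "data" / "sentence_pool_synthetic.tsv"
    return load_sentence_pool(path)
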