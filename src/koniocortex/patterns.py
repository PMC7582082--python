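"""Alphanumeric stimulus bank and presentation schedules.

The model is trained on eleven alphanumeric patterns drawn on a 5x3 binary
grid: the digits 0-9 plus the letter X used in the short-term-memory test.
Competitive learning only requires the patterns to be pairwise distinct; the
canonical glyphs shipped here are additionally designed so that every pair
of digits differs in at least three pixels and no digit is a near-superset
of another, which gives every digit a few reliably distinctive pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GRID_SHAPE = (5, 3)
N_COMPONENTS = GRID_SHAPE[0] * GRID_SHAPE[1]

DIGIT_LABELS = tuple(str(d) for d in range(10))
ALL_LABELS = DIGIT_LABELS + ("X",)

# Rows are space-separated top to bottom; '1' = active pixel.
CANONICAL_GLYPHS = {
    "0": "010 101 101 101 010",
    "1": "010 110 010 010 111",
    "2": "110 001 010 100 111",
    "3": "111 001 011 001 111",
    "4": "101 101 111 001 001",
    "5": "111 100 110 001 110",
    "6": "100 100 111 101 111",
    "7": "111 001 001 010 010",
    "8": "111 101 010 101 111",
    "9": "011 101 111 001 110",
    "X": "101 101 010 101 101",
}


def _parse_glyph(spec: str) -> np.ndarray:
    bits = [int(c) for c in spec.replace(" ", "")]
    if len(bits) != N_COMPONENTS:
        raise ValueError(f"glyph must have {N_COMPONENTS} pixels, got {len(bits)}")
    return np.asarray(bits, dtype=float)


@dataclass(frozen=True)
class PatternBank:
    """Ordered collection of 15-component stimulus vectors."""

    labels: tuple[str, ...]
    vectors: dict[str, np.ndarray]
    grid_shape: tuple[int, int] = GRID_SHAPE

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.vectors):
            raise ValueError("labels and vectors disagree")
        seen = []
        for lab in self.labels:
            v = self.vectors[lab]
            if v.shape != (N_COMPONENTS,):
                raise ValueError(f"vector for {lab!r} must have {N_COMPONENTS} components")
            if not v.any():
                raise ValueError(f"vector for {lab!r} is all-zero")
            for w in seen:
                if np.array_equal(v, w):
                    raise ValueError("bank vectors must be pairwise distinct")
            seen.append(v)

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[label]

    def as_grid(self, label: str) -> np.ndarray:
        return self.vectors[label].reshape(self.grid_shape)

    def matrix(self, labels=None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.stack([self.vectors[lab] for lab in labels])


def make_pattern_bank(glyphs: dict[str, str] | None = None) -> PatternBank:
    """Build the canonical 11-pattern bank (or one from custom glyph strings)."""
    glyphs = CANONICAL_GLYPHS if glyphs is None else glyphs
    labels = tuple(glyphs)
    vectors = {lab: _parse_glyph(spec) for lab, spec in glyphs.items()}
    return PatternBank(labels=labels, vectors=vectors)


def scale_stimulus(vector: np.ndarray, divisor: float) -> np.ndarray:
    """Divide every component by ``divisor`` (stimulus reduction, e.g. /2)."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return np.asarray(vector, dtype=float) / divisor


@dataclass
class PresentationSchedule:
    """Which labels are presented each epoch, and for how many iterations."""

    epochs_total: int
    active_labels: list[str] = field(default_factory=lambda: list(DIGIT_LABELS))
    iterations_per_pattern: int = 8
    replaced_label: str | None = None
    randomize_order: bool = False

    @property
    def iterations_per_epoch(self) -> int:
        return len(self.active_labels) * self.iterations_per_pattern

    def epoch_order(self, rng: np.random.Generator | None = None) -> list[str]:
        order = list(self.active_labels)
        if self.randomize_order:
            if rng is None:
                raise ValueError("randomized order requires an rng")
            rng.shuffle(order)
        return order


def substitute_pattern(
    schedule: PresentationSchedule,
    rng: np.random.Generator,
    forced_label: str | None = None,
) -> PresentationSchedule:
    """Replace one active digit with 'X' (the short-term-memory task).

    The replaced digit is drawn from ``rng`` unless ``forced_label`` names it
    explicitly. Calling this twice on the same schedule is an error.
    """
    if "X" in schedule.active_labels:
        raise ValueError("'X' already substituted into the schedule")
    if forced_label is not None:
        if forced_label not in schedule.active_labels:
            raise ValueError(f"{forced_label!r} not active")
        removed = forced_label
    else:
        removed = schedule.active_labels[int(rng.integers(len(schedule.active_labels)))]
    new_active = list(schedule.active_labels)
    new_active[new_active.index(removed)] = "X"
    return replace(schedule, active_labels=new_active, replaced_label=removed)


# -- plain-text interchange ---------------------------------------------------

def bank_to_text(bank: PatternBank) -> str:
    """Render the bank as labelled 0/1 grids separated by blank lines."""
    blocks = []
    for lab in bank.labels:
        rows = ["".join(str(int(x)) for x in row) for row in bank.as_grid(lab)]
        blocks.append("\n".join([f">{lab}"] + rows))
    return "\n\n".join(blocks) + "\n"


def bank_from_text(text: str) -> PatternBank:
    glyphs: dict[str, str] = {}
    for block in text.strip().split("\n\n"):
        lines = block.strip().splitlines()
        if not lines or not lines[0].startswith(">"):
            raise ValueError("each block must start with a '>label' line")
        glyphs[lines[0][1:].strip()] = " ".join(lines[1:])
    return make_pattern_bank(glyphs)


def bank_to_table(bank: PatternBank) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = [{"label": lab, **{f"p{i}": v for i, v in enumerate(bank.vectors[lab])}}
            for lab in bank.labels]
    return pd.DataFrame(rows)


def write_bank(bank: PatternBank, path) -> None:
    with open(path, "w") as fh:
        fh.write(bank_to_text(bank))


def read_bank(path) -> PatternBank:
    with open(path) as fh:
        return bank_from_text(fh.read())
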