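"""The 19-node international 10-20 scalp montage used throughout the package.

Network nodes are the 19 standard 10-20 electrodes; A1/A2 (earlobes) are
reference channels only and never appear in connectivity matrices. Odd
labels sit over the left hemisphere, even labels over the right, and
z-suffixed labels on the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NODE_LABELS: tuple[str, ...] = (
    "Fp1", "F3", "C3", "P3", "O1",
    "Fp2", "F4", "C4", "P4", "O2",
    "F7", "T3", "T5", "F8", "T4", "T6",
    "Fz", "Cz", "Pz",
)
REFERENCE_LABELS: tuple[str, str] = ("A1", "A2")
MIDLINE_LABELS: frozenset[str] = frozenset({"Fz", "Cz", "Pz"})

_HOMOLOG_BASE = {
    "Fp1": "Fp2", "F3": "F4", "F7": "F8", "C3": "C4",
    "T3": "T4", "T5": "T6", "P3": "P4", "O1": "O2", "A1": "A2",
}

# Scalp neighbourhoods on the 10-20 grid, used for the zero-lag
# volume-conduction-like mixing operator of the simulator.
NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7", "Fz"),
    "Fp2": ("Fp1", "F4", "F8", "Fz"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "Pz", "O2"),
    "O2": ("T6", "P4", "Pz", "O1"),
}


def _full_pairs() -> dict[str, str]:
    pairs = dict(_HOMOLOG_BASE)
    pairs.update({v: k for k, v in _HOMOLOG_BASE.items()})
    return pairs


@dataclass(frozen=True)
class Montage:
    """Electrode layout: 19 network nodes plus the two ear references.

    ``homolog_pairs`` maps every lateral label to its mirror across the
    sagittal plane (an involution); midline labels have no homolog.
    """

    labels: tuple[str, ...] = NODE_LABELS
    reference_labels: tuple[str, str] = REFERENCE_LABELS
    homolog_pairs: dict[str, str] = field(default_factory=_full_pairs)
    midline: frozenset[str] = MIDLINE_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 19:
            raise ValueError(f"expected 19 network nodes, got {len(self.labels)}")
        if len(set(self.labels)) != 19:
            raise ValueError("montage labels must be unique")
        for lab in self.labels:
            if lab in self.midline:
                if lab in self.homolog_pairs:
                    raise ValueError(f"midline label {lab} must not have a homolog")
            elif lab not in self.homolog_pairs:
                raise ValueError(f"lateral label {lab} missing from homolog pairs")
        for a, b in self.homolog_pairs.items():
            if self.homolog_pairs.get(b) != a:
                raise ValueError(f"homolog mapping is not an involution at {a}<->{b}")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Node labels followed by the A1/A2 references (recording order)."""
        return self.labels + self.reference_labels

    def mirror_label(self, label: str) -> str:
        """Homolog of ``label``; midline labels map to themselves."""
        if label in self.midline:
            return label
        try:
            return self.homolog_pairs[label]
        except KeyError:
            raise KeyError(f"label {label!r} has no homolog in the montage") from None

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_MONTAGE = Montage()
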